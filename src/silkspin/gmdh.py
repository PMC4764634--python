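"""GMDH-type polynomial neural network for fiber-diameter prediction.

The group method of data handling (GMDH) grows a layered network of
polynomial neurons.  Each neuron is an explicit polynomial in a small
subset of its layer's inputs (raw covariates or previous-layer neurons);
coefficients are fitted by ordinary least squares on a training subset and
neurons survive according to their squared error on a held-out *selection*
subset — the classic external criterion.  The whole network collapses to a
grand polynomial, which is the method's selling point over opaque MLPs.

Two entry points matter:

* :func:`frozen_table2_model` — the published two-layer model for
  electrospun silk fibroin (one hidden neuron ``N1`` over distance, speed,
  concentration, flow rate and voltage; an output polynomial over speed,
  flow rate and ``N1``).  Concentration enters as a mass fraction
  (10 % -> 0.10): the ``502124*X1^4`` term only contributes a sane ~50 nm
  at X1 = 0.1.
* :func:`fit_gmdh` — a trainer that builds such models from data, with
  candidate neurons drawn from pure powers ``x^k`` (k = 1..max_degree) of
  input subsets, matching the family of the published model (no
  cross-product terms).
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .dataset import COVARIATE_NAMES, Dataset, ElectrospinningSample

__all__ = [
    "MonomialTerm",
    "PolyNeuron",
    "PolynomialModel",
    "GmdhConfig",
    "frozen_table2_model",
    "evaluate",
    "evaluate_many",
    "fit_gmdh",
    "export_polynomial",
    "parse_polynomial",
    "ModelStructureError",
    "GmdhFitError",
]

logger = logging.getLogger(__name__)

_COVARIATE_REFS = ("X1", "X2", "X3", "X4", "X5")

#: Default per-covariate affine encoding (scale, offset) applied before
#: evaluation: concentration percent -> fraction, all others identity.
DEFAULT_INPUT_ENCODING = ((0.01, 0.0), (1.0, 0.0), (1.0, 0.0), (1.0, 0.0), (1.0, 0.0))


class ModelStructureError(ValueError):
    """Polynomial model references an undeclared input or is malformed."""


class GmdhFitError(RuntimeError):
    """Training failed (e.g. every candidate neuron was rank-deficient)."""


@dataclass(frozen=True)
class MonomialTerm:
    """One monomial ``coefficient * prod(input_i ** exponents_i)`` over a
    neuron's declared inputs; the all-zero exponent vector is the constant."""

    exponents: tuple[int, ...]
    coefficient: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", tuple(int(e) for e in self.exponents))
        if any(e < 0 for e in self.exponents):
            raise ModelStructureError("monomial exponents must be non-negative")


@dataclass(frozen=True)
class PolyNeuron:
    """A polynomial neuron: a named sum of monomials over declared inputs.

    ``input_refs`` entries are either covariate refs ``"X1"``..``"X5"``
    (post-encoding) or names of neurons from earlier layers.
    """

    name: str
    input_refs: tuple[str, ...]
    terms: tuple[MonomialTerm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_refs", tuple(self.input_refs))
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.input_refs:
            raise ModelStructureError(f"neuron {self.name}: empty input list")
        k = len(self.input_refs)
        n_const = 0
        for t in self.terms:
            if len(t.exponents) != k:
                raise ModelStructureError(
                    f"neuron {self.name}: exponent vector length {len(t.exponents)} "
                    f"!= input count {k}"
                )
            if not any(t.exponents):
                n_const += 1
        if n_const > 1:
            raise ModelStructureError(f"neuron {self.name}: more than one constant term")

    def value(self, inputs: np.ndarray) -> np.ndarray:
        """Evaluate on an (n, k) matrix of input columns."""
        out = np.zeros(inputs.shape[0])
        for t in self.terms:
            mono = np.full(inputs.shape[0], t.coefficient)
            for j, e in enumerate(t.exponents):
                if e:
                    mono = mono * inputs[:, j] ** e
            out += mono
        return out


@dataclass(frozen=True)
class PolynomialModel:
    """Layered GMDH network culminating in a single output polynomial."""

    layers: tuple[tuple[PolyNeuron, ...], ...]
    output: PolyNeuron
    input_encoding: tuple[tuple[float, float], ...] = DEFAULT_INPUT_ENCODING

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(tuple(layer) for layer in self.layers))
        object.__setattr__(
            self, "input_encoding", tuple((float(a), float(b)) for a, b in self.input_encoding)
        )
        if len(self.input_encoding) != 5:
            raise ModelStructureError("input_encoding must cover the five covariates")
        known = set(_COVARIATE_REFS)
        for layer in self.layers:
            for neuron in layer:
                for ref in neuron.input_refs:
                    if ref not in known:
                        raise ModelStructureError(
                            f"neuron {neuron.name}: unresolved input reference {ref!r}"
                        )
            known |= {n.name for n in layer}
        for ref in self.output.input_refs:
            if ref not in known:
                raise ModelStructureError(
                    f"output neuron: unresolved input reference {ref!r}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def neuron_dict(n: PolyNeuron) -> dict:
            return {
                "name": n.name,
                "inputs": list(n.input_refs),
                "terms": [
                    {"exponents": list(t.exponents), "coefficient": t.coefficient}
                    for t in n.terms
                ],
            }

        return {
            "format": "silkspin-gmdh-1",
            "input_encoding": [list(pair) for pair in self.input_encoding],
            "layers": [[neuron_dict(n) for n in layer] for layer in self.layers],
            "output": neuron_dict(self.output),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PolynomialModel":
        def neuron(d: dict) -> PolyNeuron:
            return PolyNeuron(
                name=d["name"],
                input_refs=tuple(d["inputs"]),
                terms=tuple(
                    MonomialTerm(tuple(t["exponents"]), float(t["coefficient"]))
                    for t in d["terms"]
                ),
            )

        return cls(
            layers=tuple(tuple(neuron(n) for n in layer) for layer in doc["layers"]),
            output=neuron(doc["output"]),
            input_encoding=tuple(tuple(pair) for pair in doc["input_encoding"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PolynomialModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def frozen_table2_model() -> PolynomialModel:
    """The published two-layer polynomial for silk-fibroin fiber diameter.

    One hidden neuron::

        N1 = 57.899 - 0.978409*X4 - 0.0118487*X5 + 502124*X1^4
             + 144.964*X2 + 0.0842974*X3^2

    and the output polynomial::

        d = -84.2446 + 0.00342148*X5 - 24.1294*X2 + 100.383*X2^4
            + 1.65187*N1 - 4.80264e-6*N1^3

    with X1 = concentration (as mass fraction), X2 = flow rate (cc/h),
    X3 = voltage (kV), X4 = distance (cm), X5 = collector speed (rpm).
    """
    n1 = PolyNeuron(
        name="N1",
        input_refs=("X4", "X5", "X1", "X2", "X3"),
        terms=(
            MonomialTerm((0, 0, 0, 0, 0), 57.899),
            MonomialTerm((1, 0, 0, 0, 0), -0.978409),
            MonomialTerm((0, 1, 0, 0, 0), -0.0118487),
            MonomialTerm((0, 0, 4, 0, 0), 502124.0),
            MonomialTerm((0, 0, 0, 1, 0), 144.964),
            MonomialTerm((0, 0, 0, 0, 2), 0.0842974),
        ),
    )
    out = PolyNeuron(
        name="d",
        input_refs=("X5", "X2", "N1"),
        terms=(
            MonomialTerm((0, 0, 0), -84.2446),
            MonomialTerm((1, 0, 0), 0.00342148),
            MonomialTerm((0, 1, 0), -24.1294),
            MonomialTerm((0, 4, 0), 100.383),
            MonomialTerm((0, 0, 1), 1.65187),
            MonomialTerm((0, 0, 3), -4.80264e-6),
        ),
    )
    return PolynomialModel(layers=((n1,),), output=out)


# -- evaluation ----------------------------------------------------------


def _as_covariate_matrix(samples) -> np.ndarray:
    if isinstance(samples, Dataset):
        return samples.covariate_matrix()
    if isinstance(samples, ElectrospinningSample):
        return samples.covariates()[None, :]
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 5:
        raise ModelStructureError(f"expected 5 covariates, got shape {arr.shape}")
    return arr


def _encoded(model: PolynomialModel, raw: np.ndarray) -> dict[str, np.ndarray]:
    values = {}
    for j, ref in enumerate(_COVARIATE_REFS):
        a, b = model.input_encoding[j]
        values[ref] = a * raw[:, j] + b
    return values


def evaluate_many(model: PolynomialModel, samples) -> np.ndarray:
    """Predicted diameters (nm) for a Dataset, sample, or (n, 5) array."""
    raw = _as_covariate_matrix(samples)
    values = _encoded(model, raw)
    for layer in model.layers:
        for neuron in layer:
            cols = np.column_stack([values[ref] for ref in neuron.input_refs])
            values[neuron.name] = neuron.value(cols)
    cols = np.column_stack([values[ref] for ref in model.output.input_refs])
    return model.output.value(cols)


def evaluate(model: PolynomialModel, sample) -> float:
    """Predicted diameter (nm) for a single sample."""
    return float(evaluate_many(model, sample)[0])


# -- training ------------------------------------------------------------


@dataclass(frozen=True)
class GmdhConfig:
    """Knobs of the layer-wise GMDH search.

    ``selection_fraction`` of the training data is held out as the
    external selection set that ranks candidate neurons; the rest fits
    their coefficients.  The criterion is averaged over
    ``n_selection_splits`` random fit/selection partitions, which tames
    its variance on samples as small as the 29-run design; with
    ``extreme_holdout`` five additional partitions hold out the rows
    most extreme in each covariate, penalizing candidates whose
    high-degree terms extrapolate badly toward the design edges.  ``max_degree`` bounds the pure powers ``x^k`` in
    the candidate term pool (the published model uses powers up to 4).
    ``min_improvement`` is the relative selection-error improvement a new
    term or layer must deliver to be accepted, and ``coefficient_cap``
    bounds each standardized coefficient to that multiple of the response
    standard deviation — together the guard against stacks of
    near-collinear powers whose huge cancelling coefficients explode
    outside the training hull.
    """

    max_layers: int = 3
    max_neurons_per_layer: int = 3
    max_terms_per_neuron: int = 6
    max_degree: int = 4
    max_inputs_per_neuron: int = 5
    selection_fraction: float = 0.3
    n_selection_splits: int = 5
    extreme_holdout: bool = True
    min_improvement: float = 0.02
    coefficient_cap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if not (0.0 <= self.min_improvement < 1.0):
            raise ValueError("min_improvement must lie in [0, 1)")
        if self.coefficient_cap <= 0:
            raise ValueError("coefficient_cap must be > 0")
        if not (0.0 < self.selection_fraction < 1.0):
            raise ValueError("selection_fraction must lie in (0, 1)")
        for name in ("max_layers", "max_neurons_per_layer", "max_terms_per_neuron",
                     "max_inputs_per_neuron", "n_selection_splits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _ols_standardized(cols: np.ndarray, y: np.ndarray, cap_abs: float | None):
    """OLS of y on [1, cols] with internal column standardization.

    Returns raw-scale coefficients (leading constant first), or None when
    the standardized design is rank-deficient (collinear candidate) or
    any standardized coefficient exceeds ``cap_abs`` — the conditioning
    guard against cancelling near-collinear power stacks.
    """
    n, k = cols.shape
    if k == 0:
        return np.array([float(np.mean(y))])
    mean = cols.mean(axis=0)
    std = cols.std(axis=0)
    if np.any(std <= 0):
        return None
    z = (cols - mean) / std
    design = np.column_stack([np.ones(n), z])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    if cap_abs is not None and np.max(np.abs(coef[1:])) > cap_abs:
        return None
    raw = coef[1:] / std
    const = coef[0] - float(raw @ mean)
    return np.concatenate([[const], raw])


def _term_columns(inputs: np.ndarray, exps: list[tuple[int, ...]]) -> np.ndarray:
    cols = []
    for e in exps:
        col = np.ones(inputs.shape[0])
        for j, p in enumerate(e):
            if p:
                col = col * inputs[:, j] ** p
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((inputs.shape[0], 0))


@dataclass
class _Candidate:
    input_refs: tuple[str, ...]
    exponents: list[tuple[int, ...]]   # non-constant terms, in selection order
    coefficients: np.ndarray           # [const, coef per term]
    selection_sse: float


def _fit_candidate(
    refs: tuple[str, ...],
    all_in: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    config: GmdhConfig,
) -> _Candidate | None:
    """Greedy forward selection of pure-power terms for one input subset.

    The constant is always present; candidate terms are ``x_j^k`` for
    each input j and k = 1..max_degree.  A term set is scored by the
    selection-subset SSE of coefficients fitted on the fit subset,
    averaged over the fit/selection partitions (the external criterion);
    terms are added while that score improves by at least
    ``min_improvement``, up to ``max_terms_per_neuron`` terms.  The
    accepted structure's coefficients are then refitted on the whole
    training sample.
    """
    k = len(refs)
    pool = [
        tuple(p if j == i else 0 for j in range(k))
        for i in range(k)
        for p in range(1, config.max_degree + 1)
    ]
    cap_abs = config.coefficient_cap * max(float(np.std(y)), 1e-12)

    def score(trial: list[tuple[int, ...]]):
        cols_all = _term_columns(all_in, trial)
        total = 0.0
        for fit_idx, sel_idx in splits:
            split_coefs = _ols_standardized(cols_all[fit_idx], y[fit_idx], cap_abs)
            if split_coefs is None:
                return None
            pred = split_coefs[0] + cols_all[sel_idx] @ split_coefs[1:]
            sse = float(np.sum((y[sel_idx] - pred) ** 2))
            if not np.isfinite(sse):
                return None
            total += sse
        full_coefs = _ols_standardized(cols_all, y, cap_abs)
        if full_coefs is None:
            return None
        return total / len(splits), full_coefs

    chosen: list[tuple[int, ...]] = []
    base = score([])
    assert base is not None
    current = _Candidate(refs, [], base[1], base[0])
    while len(chosen) + 1 < config.max_terms_per_neuron and pool:
        best_step = None
        for e in pool:
            res = score(chosen + [e])
            if res is None:
                continue
            if best_step is None or res[0] < best_step[0]:
                best_step = (res[0], e, res[1])
        if best_step is None:
            break
        sse, e, coefs = best_step
        if sse >= current.selection_sse * (1.0 - max(config.min_improvement, 1e-12)):
            break
        chosen.append(e)
        pool.remove(e)
        current = _Candidate(refs, list(chosen), coefs, sse)
        if sse <= 1e-18 * max(1.0, float(y @ y)):
            break  # selection error at the numerical floor: exact fit
    return current


def _candidate_to_neuron(cand: _Candidate, name: str) -> PolyNeuron:
    k = len(cand.input_refs)
    terms = [MonomialTerm((0,) * k, float(cand.coefficients[0]))]
    for e, c in zip(cand.exponents, cand.coefficients[1:]):
        terms.append(MonomialTerm(e, float(c)))
    return PolyNeuron(name=name, input_refs=cand.input_refs, terms=tuple(terms))


def _prune(model_layers, output: PolyNeuron, encoding) -> PolynomialModel:
    """Drop neurons not reachable from the output."""
    by_name = {n.name: n for layer in model_layers for n in layer}
    needed: set[str] = set()
    stack = [r for r in output.input_refs if r in by_name]
    while stack:
        name = stack.pop()
        if name in needed:
            continue
        needed.add(name)
        stack.extend(r for r in by_name[name].input_refs if r in by_name)
    layers = []
    for layer in model_layers:
        kept = tuple(n for n in layer if n.name in needed)
        if kept:
            layers.append(kept)
    return PolynomialModel(layers=tuple(layers), output=output, input_encoding=encoding)


def fit_gmdh(train: Dataset, config: GmdhConfig = GmdhConfig()) -> PolynomialModel:
    """Build a polynomial network layer by layer from training data.

    Candidate neurons (one per input subset of size <=
    ``max_inputs_per_neuron``) have their term structure chosen by least
    squares on the internal fit subset and ranked by squared error on the
    disjoint selection subset; the accepted structures are then refitted
    on the full training sample and the best ``max_neurons_per_layer``
    survive to feed the next layer.  Growth stops when a layer fails to
    improve the best selection error or ``max_layers`` is reached; the
    returned model's output is the overall best neuron, with unreachable
    neurons pruned.
    """
    if not train.has_diameters:
        raise GmdhFitError("training dataset has no measured diameters")
    n = len(train)
    if n <= config.max_terms_per_neuron:
        raise GmdhFitError(
            f"need more than max_terms_per_neuron={config.max_terms_per_neuron} "
            f"samples, got {n}"
        )
    rng = np.random.default_rng(config.seed)
    n_sel = max(1, int(round(config.selection_fraction * n)))
    n_sel = min(n_sel, n - 2)
    splits = []
    for _ in range(config.n_selection_splits):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[n_sel:]), np.sort(perm[:n_sel])))

    raw = train.covariate_matrix()
    y = train.diameters()
    if config.extreme_holdout:
        # hold out the rows farthest from each covariate's median, so the
        # criterion also measures behaviour toward the design edges
        for j in range(raw.shape[1]):
            dev = np.abs(raw[:, j] - np.median(raw[:, j]))
            order = np.argsort(-dev, kind="stable")
            splits.append((np.sort(order[n_sel:]), np.sort(order[:n_sel])))
    encoding = DEFAULT_INPUT_ENCODING
    values = {}
    for j, ref in enumerate(_COVARIATE_REFS):
        a, b = encoding[j]
        values[ref] = a * raw[:, j] + b

    available = list(_COVARIATE_REFS)
    all_layers: list[tuple[PolyNeuron, ...]] = []
    best_overall: tuple[float, PolyNeuron] | None = None
    neuron_counter = 0

    for _layer_index in range(config.max_layers):
        candidates: list[tuple[float, int, tuple[str, ...], _Candidate]] = []
        max_sub = min(config.max_inputs_per_neuron, len(available))
        for size in range(1, max_sub + 1):
            for refs in itertools.combinations(available, size):
                all_in = np.column_stack([values[r] for r in refs])
                cand = _fit_candidate(refs, all_in, y, splits, config)
                if cand is None:
                    logger.debug("skipping rank-deficient candidate over %s", refs)
                    continue
                # rank: selection SSE, then fewer terms, then input indices
                candidates.append((cand.selection_sse, len(cand.exponents), refs, cand))
        if not candidates:
            if best_overall is None:
                raise GmdhFitError("every candidate neuron was rank-deficient")
            break
        candidates.sort(key=lambda item: (item[0], item[1], item[2]))
        survivors = candidates[: config.max_neurons_per_layer]

        layer_best_sse = survivors[0][0]
        if best_overall is not None and layer_best_sse >= best_overall[0] * (
            1.0 - max(config.min_improvement, 1e-12)
        ):
            break
        floor = 1e-18 * max(1.0, float(y @ y))
        stop_after_layer = layer_best_sse <= floor

        layer_neurons = []
        for sse, _nt, _refs, cand in survivors:
            neuron_counter += 1
            neuron = _candidate_to_neuron(cand, f"N{neuron_counter}")
            layer_neurons.append(neuron)
            cols = np.column_stack([values[r] for r in neuron.input_refs])
            values[neuron.name] = neuron.value(cols)
            if best_overall is None or sse < best_overall[0]:
                best_overall = (sse, neuron)
        all_layers.append(tuple(layer_neurons))
        available = list(_COVARIATE_REFS) + [n.name for n in layer_neurons]
        if stop_after_layer:
            break

    assert best_overall is not None
    out_neuron = best_overall[1]
    output = PolyNeuron(name="d", input_refs=out_neuron.input_refs, terms=out_neuron.terms)
    body = [tuple(n for n in layer if n.name != out_neuron.name) for layer in all_layers]
    return _prune([tuple(l) for l in body if l], output, encoding)


# -- human-readable formula export / parse -------------------------------


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _term_text(coefficient: float, refs, exponents) -> str:
    factors = [_fmt(abs(coefficient))]
    for ref, e in zip(refs, exponents):
        if e == 1:
            factors.append(ref)
        elif e > 1:
            factors.append(f"{ref}^{e}")
    return "*".join(factors)


def _neuron_text(neuron: PolyNeuron) -> str:
    parts = []
    for i, t in enumerate(neuron.terms):
        text = _term_text(t.coefficient, neuron.input_refs, t.exponents)
        if i == 0:
            parts.append(text if t.coefficient >= 0 else f"-{text}")
        else:
            parts.append(("+ " if t.coefficient >= 0 else "- ") + text)
    return f"{neuron.name} = " + " ".join(parts)


def export_polynomial(model: PolynomialModel) -> str:
    """Render the model as signed-term formulas, one line per neuron,
    preceded by the covariate encoding.  :func:`parse_polynomial` inverts
    this rendering to 12 significant digits."""
    lines = []
    for j, (ref, name) in enumerate(zip(_COVARIATE_REFS, COVARIATE_NAMES)):
        a, b = model.input_encoding[j]
        rhs = name if a == 1.0 else f"{_fmt(a)}*{name}"
        if b:
            rhs += f" + {_fmt(b)}" if b > 0 else f" - {_fmt(abs(b))}"
        lines.append(f"{ref} = {rhs}")
    for layer in model.layers:
        for neuron in layer:
            lines.append(_neuron_text(neuron))
    lines.append(_neuron_text(model.output))
    return "\n".join(lines) + "\n"


_TERM_SPLIT = re.compile(r"\s+([+-])\s+")
_FACTOR = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\^(\d+))?$")


def _parse_terms(expr: str, refs: tuple[str, ...]) -> tuple[MonomialTerm, ...]:
    pieces = _TERM_SPLIT.split(expr.strip())
    signed = [("+", pieces[0])]
    signed += [(pieces[i], pieces[i + 1]) for i in range(1, len(pieces), 2)]
    terms = []
    for sign, body in signed:
        body = body.strip()
        neg = sign == "-"
        if body.startswith("-"):
            neg = not neg
            body = body[1:]
        factors = body.split("*")
        try:
            coefficient = float(factors[0])
            var_factors = factors[1:]
        except ValueError:
            coefficient = 1.0
            var_factors = factors
        exps = [0] * len(refs)
        for fac in var_factors:
            m = _FACTOR.match(fac.strip())
            if m is None:
                raise ModelStructureError(f"cannot parse factor {fac!r}")
            name, power = m.group(1), int(m.group(2) or 1)
            if name not in refs:
                raise ModelStructureError(f"unknown input {name!r} in term {body!r}")
            exps[refs.index(name)] += power
        terms.append(MonomialTerm(tuple(exps), -coefficient if neg else coefficient))
    return tuple(terms)


def parse_polynomial(text: str) -> PolynomialModel:
    """Parse the output of :func:`export_polynomial` back into a model.

    Layer membership is recovered from the dependency depth of each
    neuron; the final formula line is the output neuron.
    """
    encoding = list(DEFAULT_INPUT_ENCODING)
    neuron_lines: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, rhs = line.partition("=")
        name, rhs = name.strip(), rhs.strip()
        if name in _COVARIATE_REFS:
            j = _COVARIATE_REFS.index(name)
            m = re.match(
                r"^(?:([0-9.eE+-]+)\*)?([a-z_]+)(?:\s*([+-])\s*([0-9.eE+-]+))?$", rhs
            )
            if m is None or m.group(2) != COVARIATE_NAMES[j]:
                raise ModelStructureError(f"cannot parse encoding line {line!r}")
            a = float(m.group(1)) if m.group(1) else 1.0
            b = float(m.group(4)) if m.group(4) else 0.0
            if m.group(3) == "-":
                b = -b
            encoding[j] = (a, b)
        else:
            neuron_lines.append((name, rhs))
    if not neuron_lines:
        raise ModelStructureError("no neuron formulas found")

    known_neurons: dict[str, PolyNeuron] = {}
    depth: dict[str, int] = {}
    parsed: list[PolyNeuron] = []
    for name, rhs in neuron_lines:
        ref_names = sorted(
            {f for f in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", rhs) if not _is_number(f)},
            key=lambda r: (r not in _COVARIATE_REFS, r),
        )
        refs = tuple(r for r in ref_names if r in _COVARIATE_REFS or r in known_neurons)
        if not refs:
            refs = ("X1",)  # constant-only formula still needs a declared input
        terms = _parse_terms(rhs, refs)
        neuron = PolyNeuron(name=name, input_refs=refs, terms=terms)
        parsed.append(neuron)
        known_neurons[name] = neuron
        depth[name] = 1 + max(
            (depth[r] for r in refs if r in depth), default=0
        )
    output = parsed[-1]
    body = parsed[:-1]
    if body:
        max_depth = max(depth[n.name] for n in body)
        layers = tuple(
            tuple(n for n in body if depth[n.name] == d) for d in range(1, max_depth + 1)
        )
    else:
        layers = ()
    return PolynomialModel(layers=layers, output=output, input_encoding=tuple(encoding))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
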