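"""Feed-forward neural network for fiber-diameter prediction.

A multilayer perceptron with logistic-sigmoid hidden units

    O = 1 / (1 + exp(-net)),    net = sum_i w_i x_i

and a linear output unit, trained either by batch back-propagation
(w_ij <- w_ij + eta * delta_j * O_i, with the output delta t - O and
hidden deltas O(1-O) * sum_k delta_k w_jk) or by Levenberg-Marquardt on
the full Jacobian.  Diameter targets are affinely scaled to [0.1, 0.9]
so the hidden-layer sigmoid-derivative form of the deltas is preserved
while regression targets may exceed [0, 1]; inputs are scaled the same
way from their training ranges.  Biases are weights from a constant-1
input (the last column of each weight matrix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Dataset, ElectrospinningSample

__all__ = [
    "MlpModel",
    "AnnTrainConfig",
    "forward",
    "predict_ann",
    "predict_matrix",
    "backprop_deltas",
    "weight_gradients",
    "fit_ann",
    "AnnModelError",
    "AnnTrainingError",
]

_WORK_LO, _WORK_HI = 0.1, 0.9


class AnnModelError(ValueError):
    """Inconsistent network shapes or scalings."""


class AnnTrainingError(RuntimeError):
    """Training diverged or could not proceed."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class MlpModel:
    """Weights plus the affine input/output scalings of a 5-h-...-1 MLP.

    ``weights[l]`` has shape (n_out, n_in + 1); the last column is the
    bias.  ``input_scaling`` holds per-covariate (a, b) with
    z = a*x + b; ``output_scaling`` is a single (a, b) applied to the
    diameter in nm.  Both must be invertible (a != 0).
    """

    hidden_sizes: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    input_scaling: tuple[tuple[float, float], ...]
    output_scaling: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        object.__setattr__(
            self, "weights", tuple(np.asarray(w, dtype=float) for w in self.weights)
        )
        sizes = (5,) + self.hidden_sizes + (1,)
        if len(self.weights) != len(sizes) - 1:
            raise AnnModelError(
                f"expected {len(sizes) - 1} weight matrices, got {len(self.weights)}"
            )
        for l, w in enumerate(self.weights):
            want = (sizes[l + 1], sizes[l] + 1)
            if w.shape != want:
                raise AnnModelError(f"layer {l}: weight shape {w.shape}, expected {want}")
        if len(self.input_scaling) != 5:
            raise AnnModelError("input_scaling must cover the five covariates")
        for a, _ in list(self.input_scaling) + [self.output_scaling]:
            if a == 0:
                raise AnnModelError("scaling maps must be invertible (slope != 0)")

    def scale_inputs(self, raw: np.ndarray) -> np.ndarray:
        a = np.array([s[0] for s in self.input_scaling])
        b = np.array([s[1] for s in self.input_scaling])
        return raw * a + b

    def scale_output(self, nm: np.ndarray) -> np.ndarray:
        a, b = self.output_scaling
        return nm * a + b

    def unscale_output(self, scaled: np.ndarray) -> np.ndarray:
        a, b = self.output_scaling
        return (scaled - b) / a

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "silkspin-mlp-1",
            "hidden_sizes": list(self.hidden_sizes),
            "weights": [w.tolist() for w in self.weights],
            "input_scaling": [list(p) for p in self.input_scaling],
            "output_scaling": list(self.output_scaling),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MlpModel":
        return cls(
            hidden_sizes=tuple(doc["hidden_sizes"]),
            weights=tuple(np.array(w, dtype=float) for w in doc["weights"]),
            input_scaling=tuple(tuple(p) for p in doc["input_scaling"]),
            output_scaling=tuple(doc["output_scaling"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MlpModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class AnnTrainConfig:
    """Training hyperparameters.

    ``hidden_sizes=None`` selects a single hidden layer whose size is
    chosen from ``size_search`` by held-out error within the training
    set.  The Marquardt damping starts at ``lm_damping_init`` and is
    multiplied by ``lm_damping_up`` on a rejected step, divided by
    ``lm_damping_down`` on an accepted one.
    """

    algorithm: str = "levenberg_marquardt"  # or "backprop"
    learning_rate: float = 0.1
    lm_damping_init: float = 1e-3
    lm_damping_up: float = 10.0
    lm_damping_down: float = 10.0
    max_iterations: int = 300
    convergence_tol: float = 1e-12
    seed: int = 0
    hidden_sizes: tuple[int, ...] | None = (6,)
    size_search: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10)
    online: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ("backprop", "levenberg_marquardt"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


# -- forward pass --------------------------------------------------------


def _activations(model: MlpModel, scaled_inputs: np.ndarray) -> list[np.ndarray]:
    """Per-layer activations for an (n, 5) scaled input matrix; the last
    entry is the linear output (n, 1)."""
    acts = [scaled_inputs]
    a = scaled_inputs
    n_layers = len(model.weights)
    for l, w in enumerate(model.weights):
        net = a @ w[:, :-1].T + w[:, -1]
        a = net if l == n_layers - 1 else _sigmoid(net)
        acts.append(a)
    return acts


def _as_matrix(samples) -> np.ndarray:
    if isinstance(samples, Dataset):
        return samples.covariate_matrix()
    if isinstance(samples, ElectrospinningSample):
        return samples.covariates()[None, :]
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def predict_matrix(model: MlpModel, samples) -> np.ndarray:
    """Predicted diameters (nm) for a Dataset, sample, or (n, 5) array."""
    raw = _as_matrix(samples)
    acts = _activations(model, model.scale_inputs(raw))
    return model.unscale_output(acts[-1][:, 0])


def forward(model: MlpModel, sample) -> float:
    """Predicted diameter (nm) for a single sample."""
    return float(predict_matrix(model, sample)[0])


def predict_ann(model: MlpModel, data: Dataset) -> list[float]:
    """Elementwise forward pass, order-preserving."""
    if len(data) == 0:
        return []
    return [float(v) for v in predict_matrix(model, data)]


# -- gradients -----------------------------------------------------------


def _deltas_from_acts(model: MlpModel, acts: list[np.ndarray], targets: np.ndarray):
    """Error deltas per trainable layer (input layer excluded), scaled
    space.  Output (linear): delta = t - O.  Hidden: O(1-O) * sum_k
    delta_k w_jk."""
    n_layers = len(model.weights)
    deltas: list[np.ndarray] = [None] * n_layers
    deltas[-1] = targets[:, None] - acts[-1]
    for l in range(n_layers - 2, -1, -1):
        back = deltas[l + 1] @ model.weights[l + 1][:, :-1]
        a = acts[l + 1]
        deltas[l] = a * (1.0 - a) * back
    return deltas


def backprop_deltas(model: MlpModel, sample, target_nm: float) -> list[np.ndarray]:
    """Per-neuron error deltas for one sample and target (nm), computed
    in the network's scaled space; one array per trainable layer, the
    last being the output unit's delta."""
    raw = _as_matrix(sample)
    acts = _activations(model, model.scale_inputs(raw))
    t = model.scale_output(np.array([float(target_nm)]))
    return [d[0] for d in _deltas_from_acts(model, acts, t)]


def weight_gradients(model: MlpModel, sample, target_nm: float) -> list[np.ndarray]:
    """Gradients of E = 1/2 (t - O)^2 (scaled space) with respect to each
    weight matrix, assembled from the backprop deltas: dE/dw_ij =
    -delta_j * O_i."""
    raw = _as_matrix(sample)
    acts = _activations(model, model.scale_inputs(raw))
    t = model.scale_output(np.array([float(target_nm)]))
    deltas = _deltas_from_acts(model, acts, t)
    grads = []
    for l, d in enumerate(deltas):
        prev = np.concatenate([acts[l][0], [1.0]])
        grads.append(-np.outer(d[0], prev))
    return grads


def _output_jacobian(model: MlpModel, acts: list[np.ndarray]) -> np.ndarray:
    """d(output)/d(weights) for every sample, flattened: (n, n_params)."""
    n = acts[0].shape[0]
    n_layers = len(model.weights)
    g = np.ones((n, 1))  # d out / d out
    cols: list[np.ndarray] = [None] * n_layers
    for l in range(n_layers - 1, -1, -1):
        prev = np.concatenate([acts[l], np.ones((n, 1))], axis=1)
        cols[l] = np.einsum("ni,nj->nij", g, prev).reshape(n, -1)
        if l > 0:
            # g becomes d out / d net_{l-1}; layer l-1 is always sigmoid
            a = acts[l]
            g = (g @ model.weights[l][:, :-1]) * a * (1.0 - a)
    return np.concatenate(cols, axis=1)


def _pack(weights) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights])


def _unpack(theta: np.ndarray, like) -> tuple[np.ndarray, ...]:
    out = []
    k = 0
    for w in like:
        out.append(theta[k : k + w.size].reshape(w.shape))
        k += w.size
    return tuple(out)


# -- training ------------------------------------------------------------


def _build_scalings(train: Dataset):
    cov = train.covariate_matrix()
    lo, hi = cov.min(axis=0), cov.max(axis=0)
    input_scaling = []
    for j in range(5):
        if hi[j] > lo[j]:
            a = (_WORK_HI - _WORK_LO) / (hi[j] - lo[j])
            b = _WORK_LO - a * lo[j]
        else:  # constant covariate: map to the middle of the working range
            a, b = 1.0, 0.5 - lo[j]
        input_scaling.append((float(a), float(b)))
    d = train.diameters()
    dlo, dhi = float(d.min()), float(d.max())
    if dhi > dlo:
        a = (_WORK_HI - _WORK_LO) / (dhi - dlo)
        b = _WORK_LO - a * dlo
    else:
        a, b = 1.0, 0.5 - dlo
    return tuple(input_scaling), (float(a), float(b))


def _init_model(train: Dataset, hidden_sizes: tuple[int, ...], rng) -> MlpModel:
    input_scaling, output_scaling = _build_scalings(train)
    sizes = (5,) + tuple(hidden_sizes) + (1,)
    weights = tuple(
        rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l] + 1))
        for l in range(len(sizes) - 1)
    )
    return MlpModel(tuple(hidden_sizes), weights, input_scaling, output_scaling)


def _mse(model: MlpModel, x_scaled, t_scaled) -> float:
    out = _activations(model, x_scaled)[-1][:, 0]
    with np.errstate(over="ignore", invalid="ignore"):
        return float(np.mean((t_scaled - out) ** 2))


def _train_backprop(model, x_scaled, t_scaled, config) -> MlpModel:
    weights = [w.copy() for w in model.weights]
    n = x_scaled.shape[0]
    best = (np.inf, None)
    prev_mse = np.inf
    for it in range(config.max_iterations):
        current = replace(model, weights=tuple(weights))
        if config.online:
            for i in range(n):
                acts = _activations(current, x_scaled[i : i + 1])
                deltas = _deltas_from_acts(current, acts, t_scaled[i : i + 1])
                for l, d in enumerate(deltas):
                    prev = np.concatenate([acts[l], np.ones((1, 1))], axis=1)
                    weights[l] = weights[l] + config.learning_rate * d.T @ prev
                current = replace(model, weights=tuple(weights))
        else:
            acts = _activations(current, x_scaled)
            deltas = _deltas_from_acts(current, acts, t_scaled)
            for l, d in enumerate(deltas):
                prev = np.concatenate([acts[l], np.ones((n, 1))], axis=1)
                weights[l] = weights[l] + config.learning_rate * d.T @ prev
            current = replace(model, weights=tuple(weights))
        m = _mse(current, x_scaled, t_scaled)
        if not np.isfinite(m):
            raise AnnTrainingError(f"back-propagation diverged at iteration {it + 1}")
        if m < best[0]:
            best = (m, current)
        if abs(prev_mse - m) < config.convergence_tol:
            break
        prev_mse = m
    return best[1] if best[1] is not None else model


def _train_lm(model, x_scaled, t_scaled, config) -> MlpModel:
    theta = _pack(model.weights)
    lam = config.lm_damping_init
    current = replace(model, weights=_unpack(theta, model.weights))
    acts = _activations(current, x_scaled)
    r = t_scaled - acts[-1][:, 0]
    sse = float(r @ r)
    best = (sse, current)
    for it in range(config.max_iterations):
        J = _output_jacobian(current, acts)
        jtj = J.T @ J
        jtr = J.T @ r
        accepted = False
        for _ in range(60):
            try:
                step = np.linalg.solve(jtj + lam * np.eye(jtj.shape[0]), jtr)
            except np.linalg.LinAlgError:
                lam *= config.lm_damping_up
                continue
            trial_theta = theta + step
            trial = replace(model, weights=_unpack(trial_theta, model.weights))
            trial_acts = _activations(trial, x_scaled)
            trial_r = t_scaled - trial_acts[-1][:, 0]
            trial_sse = float(trial_r @ trial_r)
            if not np.isfinite(trial_sse):
                raise AnnTrainingError(f"Levenberg-Marquardt diverged at iteration {it + 1}")
            if trial_sse < sse:
                theta, current, acts, r = trial_theta, trial, trial_acts, trial_r
                improvement = sse - trial_sse
                sse = trial_sse
                lam = max(lam / config.lm_damping_down, 1e-15)
                accepted = True
                break
            lam *= config.lm_damping_up
            if lam > 1e12:
                break
        if sse < best[0]:
            best = (sse, current)
        if not accepted:
            break
        if improvement < config.convergence_tol * max(sse, 1e-300):
            break
    return best[1]


def fit_ann(train: Dataset, config: AnnTrainConfig = AnnTrainConfig()) -> MlpModel:
    """Train an MLP on diameters, returning the best-seen-MSE model.

    Weights start uniform in [-0.5, 0.5] under ``config.seed``.  With
    ``hidden_sizes=None`` the single hidden layer's size is picked from
    ``config.size_search`` by error on an internal 80/20 holdout of the
    training set, then the winner is retrained on the full training set.
    """
    if not train.has_diameters:
        raise AnnTrainingError("training dataset has no measured diameters")
    if len(train) < 5:
        raise AnnTrainingError(f"need at least 5 training samples, got {len(train)}")
    rng = np.random.default_rng(config.seed)
    if config.hidden_sizes is None:
        n = len(train)
        perm = rng.permutation(n)
        n_val = max(1, int(round(0.2 * n)))
        ids = np.array([s.sample_id for s in train.samples])
        val_ids = ids[perm[:n_val]]
        fit_ids = ids[perm[n_val:]]
        inner_train = train.subset(fit_ids)
        inner_val = train.subset(val_ids)
        best = None
        for h in config.size_search:
            sub = replace(config, hidden_sizes=(h,))
            try:
                m = _fit_fixed(inner_train, sub, np.random.default_rng(config.seed + 1))
            except AnnTrainingError:
                continue
            val_mse = float(
                np.mean((predict_matrix(m, inner_val) - inner_val.diameters()) ** 2)
            )
            if best is None or val_mse < best[0]:
                best = (val_mse, h)
        if best is None:
            raise AnnTrainingError("hidden-size search failed for every size")
        config = replace(config, hidden_sizes=(best[1],))
        rng = np.random.default_rng(config.seed + 2)
    return _fit_fixed(train, config, rng)


def _fit_fixed(train: Dataset, config: AnnTrainConfig, rng) -> MlpModel:
    model = _init_model(train, config.hidden_sizes, rng)
    x_scaled = model.scale_inputs(train.covariate_matrix())
    t_scaled = model.scale_output(train.diameters())
    if config.algorithm == "backprop":
        return _train_backprop(model, x_scaled, t_scaled, config)
    return _train_lm(model, x_scaled, t_scaled, config)
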