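"""Synthetic electrospinning datasets for model-recovery testing.

Real diameter data comes from a 29-run hand-picked design; for testing
the trainers we need datasets whose ground truth is known exactly.  The
generator samples the five process covariates uniformly in the design
ranges (concentration 10-12 % w/v, flow 0.1-0.6 cc/h, voltage 12-30 kV,
distance 8-12 cm, collector speed 200-2500 rpm) and produces diameters
from a configurable polynomial ground truth plus Gaussian noise,
truncated below at 1 nm so high noise cannot yield non-physical values.

A grid mode reuses the 29 printed covariate rows verbatim, regenerating
only the responses, for tests that want the real design geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, ElectrospinningSample
from .gmdh import PolynomialModel, evaluate_many

__all__ = ["GroundTruth", "generate_dataset", "DEFAULT_COVARIATE_RANGES"]

#: (low, high) per covariate, in the units of the design table.
DEFAULT_COVARIATE_RANGES = (
    (10.0, 12.0),    # concentration, % w/v
    (0.1, 0.6),      # flow rate, cc/h
    (12.0, 30.0),    # voltage, kV
    (8.0, 12.0),     # distance, cm
    (200.0, 2500.0), # collector speed, rpm
)


@dataclass(frozen=True)
class GroundTruth:
    """Polynomial ground truth for the diameter response.

    ``terms`` are ``(exponent-vector over the 5 raw covariates,
    coefficient)`` pairs, evaluated on the covariates in their stored
    units (concentration in percent).  Alternatively, ``model`` names a
    full layered polynomial network whose prediction is used as the
    noiseless response — handy for self-consistency checks against the
    published model.
    """

    terms: tuple[tuple[tuple[int, ...], float], ...] = ()
    noise_sd: float = 0.0  # nm
    covariate_ranges: tuple[tuple[float, float], ...] = DEFAULT_COVARIATE_RANGES
    model: PolynomialModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "terms",
            tuple((tuple(int(p) for p in e), float(c)) for e, c in self.terms),
        )
        object.__setattr__(
            self,
            "covariate_ranges",
            tuple((float(lo), float(hi)) for lo, hi in self.covariate_ranges),
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.covariate_ranges) != 5:
            raise ValueError("covariate_ranges must cover the five covariates")
        for lo, hi in self.covariate_ranges:
            if not lo < hi:
                raise ValueError(f"invalid covariate range ({lo}, {hi})")
        if self.model is None and not self.terms:
            raise ValueError("ground truth needs at least one term (or a model)")
        for e, _ in self.terms:
            if len(e) != 5 or any(p < 0 for p in e):
                raise ValueError(f"bad exponent vector {e}")

    def response(self, covariates: np.ndarray) -> np.ndarray:
        """Noiseless diameter for an (n, 5) covariate matrix."""
        cov = np.asarray(covariates, dtype=float)
        if self.model is not None:
            return evaluate_many(self.model, cov)
        out = np.zeros(cov.shape[0])
        for exps, coefficient in self.terms:
            mono = np.full(cov.shape[0], coefficient)
            for j, p in enumerate(exps):
                if p:
                    mono = mono * cov[:, j] ** p
            out += mono
        return out

    @classmethod
    def constant(cls, value: float, noise_sd: float = 0.0) -> "GroundTruth":
        return cls(terms=(((0, 0, 0, 0, 0), value),), noise_sd=noise_sd)


def generate_dataset(
    truth: GroundTruth,
    n: int,
    seed: int,
    grid_mode: bool = False,
    name: str = "synthetic",
) -> Dataset:
    """Sample a dataset from a known ground truth.

    Covariates are uniform in ``truth.covariate_ranges``; diameters are
    the polynomial response plus ``N(0, noise_sd)`` noise, truncated below
    at 1 nm (after noise).  With ``grid_mode`` the covariates are the 29
    printed design rows (cycled if ``n`` > 29) and only responses are
    generated.  Bit-identical under a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if grid_mode:
        from .dataset import load_table1

        base = load_table1().covariate_matrix()
        reps = int(np.ceil(n / base.shape[0]))
        cov = np.tile(base, (reps, 1))[:n]
    else:
        lows = np.array([lo for lo, _ in truth.covariate_ranges])
        highs = np.array([hi for _, hi in truth.covariate_ranges])
        cov = rng.uniform(lows, highs, size=(n, 5))
    clean = truth.response(cov)
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
    diameter = np.maximum(clean + noise, 1.0)
    samples = tuple(
        ElectrospinningSample(
            sample_id=i + 1,
            concentration=float(cov[i, 0]),
            flow_rate=float(cov[i, 1]),
            voltage=float(cov[i, 2]),
            distance=float(cov[i, 3]),
            collector_speed=float(cov[i, 4]),
            diameter=float(diameter[i]),
        )
        for i in range(n)
    )
    return Dataset(samples, name=name)
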