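"""Experimental design table for electrospun silk fibroin nanofibers.

Each sample records five process covariates — solution concentration
(% w/v), flow rate (cc/h), applied voltage (kV), needle-collector distance
(cm), collector rotation speed (rpm) — and the measured mean fiber
diameter (nm).  The 29-run design used throughout the package ships as an
in-source fixture (:func:`load_table1`); user data round-trips through a
fixed-schema CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ElectrospinningSample",
    "Dataset",
    "SplitResult",
    "COVARIATE_NAMES",
    "CSV_COLUMNS",
    "load_table1",
    "read_dataset",
    "write_dataset",
    "split_dataset",
    "DatasetError",
    "SchemaError",
]

#: Covariate order used everywhere a sample is treated as a vector.
COVARIATE_NAMES = ("concentration", "flow_rate", "voltage", "distance", "collector_speed")

#: Fixed CSV header (diameter column optional for prediction-only sets).
CSV_COLUMNS = (
    "sample_id",
    "concentration_pct",
    "flow_rate_cc_h",
    "voltage_kv",
    "distance_cm",
    "collector_speed_rpm",
    "diameter_nm",
)


class DatasetError(ValueError):
    """Invalid dataset content (invariant violation, bad split size...)."""


class SchemaError(DatasetError):
    """CSV file does not match the documented column schema."""


@dataclass(frozen=True)
class ElectrospinningSample:
    """One electrospinning run: five process covariates plus, optionally,
    the measured mean fiber diameter.

    ``concentration`` is stored as the printed percent value (10.0 means
    "10 % w/v"); model input encoders are responsible for any unit
    conversion (the polynomial network converts to mass fraction).
    """

    sample_id: int
    concentration: float  # % w/v
    flow_rate: float      # cc/h
    voltage: float        # kV
    distance: float       # cm
    collector_speed: float  # rpm
    diameter: float | None = None  # nm; None for prediction-only inputs

    def __post_init__(self) -> None:
        if int(self.sample_id) != self.sample_id or self.sample_id <= 0:
            raise DatasetError(f"sample_id must be a positive integer, got {self.sample_id!r}")
        if not (1.0 <= self.concentration <= 50.0):
            raise DatasetError(
                f"sample {self.sample_id}: concentration {self.concentration} % outside [1, 50]"
            )
        for name in ("flow_rate", "voltage", "distance"):
            if getattr(self, name) <= 0:
                raise DatasetError(f"sample {self.sample_id}: {name} must be > 0")
        if self.collector_speed < 0:
            raise DatasetError(f"sample {self.sample_id}: collector_speed must be >= 0")
        if self.diameter is not None and self.diameter <= 0:
            raise DatasetError(f"sample {self.sample_id}: diameter must be > 0 when present")

    def covariates(self) -> np.ndarray:
        """The five covariates as a vector, in :data:`COVARIATE_NAMES` order."""
        return np.array(
            [self.concentration, self.flow_rate, self.voltage, self.distance, self.collector_speed],
            dtype=float,
        )


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of samples with unique ids; either every sample
    carries a measured diameter or none does."""

    samples: tuple[ElectrospinningSample, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate sample_id values: {dup}")
        flags = {s.diameter is not None for s in self.samples}
        if len(flags) > 1:
            raise DatasetError("mixed dataset: some samples have diameters, others do not")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def has_diameters(self) -> bool:
        return bool(self.samples) and self.samples[0].diameter is not None

    def diameters(self) -> np.ndarray:
        if not self.has_diameters:
            raise DatasetError(f"dataset {self.name!r} has no measured diameters")
        return np.array([s.diameter for s in self.samples], dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """(n, 5) matrix of covariates in sample order."""
        return np.array([s.covariates() for s in self.samples], dtype=float)

    def subset(self, ids) -> "Dataset":
        """Samples with the given ids, preserving original order."""
        wanted = set(ids)
        missing = wanted - {s.sample_id for s in self.samples}
        if missing:
            raise DatasetError(f"unknown sample ids: {sorted(missing)}")
        return Dataset(
            tuple(s for s in self.samples if s.sample_id in wanted),
            name=self.name,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": [s.sample_id for s in self.samples],
            "concentration_pct": [s.concentration for s in self.samples],
            "flow_rate_cc_h": [s.flow_rate for s in self.samples],
            "voltage_kv": [s.voltage for s in self.samples],
            "distance_cm": [s.distance for s in self.samples],
            "collector_speed_rpm": [s.collector_speed for s in self.samples],
        }
        if self.has_diameters:
            cols["diameter_nm"] = [s.diameter for s in self.samples]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive train/test partition of a dataset's sample ids."""

    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_ids", tuple(self.train_ids))
        object.__setattr__(self, "test_ids", tuple(self.test_ids))
        if set(self.train_ids) & set(self.test_ids):
            raise DatasetError("train and test ids overlap")


# 29-run design: (id, % w/v, cc/h, kV, cm, rpm, nm).
_TABLE1 = (
    (1, 10, 0.1, 20, 12, 200, 134.19),
    (2, 10, 0.3, 20, 12, 200, 168.49),
    (3, 10, 0.4, 20, 12, 200, 185.35),
    (4, 10, 0.6, 20, 12, 200, 226.74),
    (5, 10, 0.4, 20, 12, 800, 167.71),
    (6, 10, 0.4, 20, 12, 1500, 159.96),
    (7, 10, 0.4, 20, 12, 2500, 159.09),
    (8, 10, 0.3, 22, 12, 800, 188.46),
    (9, 10, 0.3, 20, 12, 1500, 158.09),
    (10, 10, 0.3, 20, 12, 2500, 156.35),
    (11, 10, 0.4, 15, 10, 200, 158.62),
    (12, 10, 0.4, 17.5, 10, 200, 175.19),
    (13, 10, 0.4, 20, 10, 200, 182.91),
    (14, 10, 0.4, 22.5, 10, 200, 203.69),
    (15, 10, 0.4, 20, 8, 200, 183.65),
    (16, 10, 0.4, 22, 8, 200, 192.79),
    (17, 10, 0.4, 24, 8, 200, 215.31),
    (18, 10, 0.4, 26, 8, 200, 216.76),
    (19, 12, 0.3, 19, 12, 600, 217.42),
    (20, 12, 0.4, 22, 12, 600, 250.26),
    (21, 12, 0.5, 22, 12, 600, 259.33),
    (22, 12, 0.6, 22, 12, 600, 260.93),
    (23, 12, 0.5, 23, 12, 600, 259.90),
    (24, 12, 0.5, 25, 12, 600, 268.60),
    (25, 12, 0.6, 25, 12, 600, 277.80),
    (26, 12, 0.2, 12, 12, 400, 197.91),
    (27, 12, 0.2, 16, 12, 400, 203.50),
    (28, 12, 0.2, 26, 12, 400, 219.75),
    (29, 12, 0.2, 30, 12, 400, 263.26),
)


def load_table1() -> Dataset:
    """The 29-run silk-fibroin electrospinning design, values as printed
    (concentration in percent)."""
    return Dataset(
        tuple(
            ElectrospinningSample(sid, c, f, v, d, s, diam)
            for sid, c, f, v, d, s, diam in _TABLE1
        ),
        name="table1",
    )


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as CSV with the fixed header.

    The ``diameter_nm`` column is present iff the dataset carries measured
    diameters.  ``read_dataset(write_dataset(d)) == d`` to full printed
    precision.
    """
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path, has_diameter: bool = True) -> Dataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Parameters
    ----------
    path
        CSV file with the documented header.
    has_diameter
        Whether a ``diameter_nm`` column is required (True) or must be
        absent (False).  A mismatch raises :class:`SchemaError`.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected header {','.join(CSV_COLUMNS[:-1])}")
    expected = list(CSV_COLUMNS) if has_diameter else list(CSV_COLUMNS[:-1])
    got = list(frame.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise SchemaError(f"{path}: {'; '.join(parts)}")
    samples = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        values = {}
        for col, raw in zip(expected, row):
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: line {row_number}: non-numeric value {raw!r} in column {col}"
                )
        samples.append(
            ElectrospinningSample(
                sample_id=int(values["sample_id"]),
                concentration=values["concentration_pct"],
                flow_rate=values["flow_rate_cc_h"],
                voltage=values["voltage_kv"],
                distance=values["distance_cm"],
                collector_speed=values["collector_speed_rpm"],
                diameter=values.get("diameter_nm"),
            )
        )
    return Dataset(tuple(samples), name=str(path))


def split_dataset(dataset: Dataset, train_fraction: float = 0.7, seed: int = 0) -> SplitResult:
    """Uniformly random train/test partition, reproducible under ``seed``.

    The train size is ``round(train_fraction * N)`` with Python's
    round-half-to-even rule, so the 29-sample design splits 20/9 at the
    conventional 70/30 ratio.
    """
    n = len(dataset)
    if n < 3:
        raise DatasetError(f"need at least 3 samples to split, got {n}")
    if not (0.0 < train_fraction < 1.0):
        raise DatasetError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    ids = np.array([s.sample_id for s in dataset.samples])
    perm = rng.permutation(n)
    train = np.sort(ids[perm[:n_train]])
    test = np.sort(ids[perm[n_train:]])
    return SplitResult(tuple(int(i) for i in train), tuple(int(i) for i in test), seed=seed)
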