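"""Core containers, readers/writers, configuration and seed management.

Tabular artifacts (connectivity matrices, design tables, per-parcel maps) live
in delimited text; large arrays may use a single-file ``.npz`` container. Both
carry parcel identifiers so that downstream stages never rely on positional
conventions alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DesignError, InputShapeError, InputValueError

logger = logging.getLogger("gradplast")

#: Named task-based networks used for a-priori summaries (attention and
#: interoception track attention-focused training, emotion/empathy the
#: socio-affective module, theory_of_mind the socio-cognitive module).
NETWORKS = ("attention", "interoception", "emotion", "empathy", "theory_of_mind")

#: Training-module order per cohort in the crossover design. Both training
#: cohorts start with the attention module; the latter two modules are swapped
#: between cohorts so each serves as the other's active control. The retest
#: control cohort (RCC) is scanned on the same schedule but never trained;
#: TC3 completes a single socio-affective module.
CROSSOVER_ORDER = {
    "TC1": ("Presence", "Affect", "Perspective"),
    "TC2": ("Presence", "Perspective", "Affect"),
    "TC3": ("Affect",),
    "RCC": (),
}

TIMEPOINTS = ("T0", "T1", "T2", "T3")

DESIGN_COLUMNS = ("subject_id", "cohort", "timepoint", "tm", "age", "sex", "interval_index")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Symmetric parcel-by-parcel functional association matrix.

    The diagonal is ignored by every downstream operation; values are
    unitless association strengths (typically correlations).
    """

    values: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputShapeError(f"connectivity matrix must be square, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise InputValueError("connectivity matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max()
        if asym > 1e-10:
            raise InputValueError(f"connectivity matrix asymmetric (max |A-A'| = {asym:.3e})")
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        if len(self.parcel_ids) != self.values.shape[0]:
            raise InputShapeError("parcel_ids length does not match matrix size")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class Parcellation:
    """Integer label per mesh vertex; 0 marks unassigned vertices."""

    vertex_labels: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self):
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=int)
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        present = set(np.unique(self.vertex_labels)) - {0}
        expected = set(range(1, len(self.parcel_ids) + 1))
        if not expected <= present:
            missing = sorted(expected - present)
            raise InputValueError(f"parcels missing from vertex_labels: {missing[:5]}...")


@dataclass
class NetworkWeights:
    """Per-parcel weight vector for each named a-priori network."""

    weights: dict[str, np.ndarray]

    def __post_init__(self):
        self.weights = {str(k): np.asarray(v, dtype=float) for k, v in self.weights.items()}
        for name, w in self.weights.items():
            if not np.isfinite(w).all():
                raise InputValueError(f"network {name!r} has non-finite weights")
            if not np.any(w != 0):
                raise InputValueError(f"network {name!r} has all-zero weights")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.weights[name]


def _expected_tm(cohort: str, timepoint: str) -> str:
    """Training module completed in the interval ending at *timepoint*."""
    k = TIMEPOINTS.index(timepoint)
    order = CROSSOVER_ORDER[cohort]
    if k == 0 or k > len(order):
        return "None"
    return order[k - 1]


def validate_design(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a longitudinal design table and return a normalized copy.

    Checks uniqueness of (subject, timepoint), positive ages, binary sex
    codes, and that each row's training module matches the cohort's
    crossover ordering.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    df = frame.loc[:, list(DESIGN_COLUMNS)].copy()
    df["tm"] = df["tm"].fillna("None").astype(str)
    df["subject_id"] = df["subject_id"].astype(str)

    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        pair = df.loc[dup, ["subject_id", "timepoint"]].iloc[0].tolist()
        raise DesignError(f"duplicate (subject, timepoint) row: {pair}")
    bad_cohort = set(df["cohort"]) - set(CROSSOVER_ORDER)
    if bad_cohort:
        raise DesignError(f"unknown cohorts: {sorted(bad_cohort)}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise DesignError(f"unknown timepoints: {sorted(bad_tp)}")
    if (df["age"] <= 0).any():
        raise DesignError("ages must be positive")
    if not df["sex"].isin([0, 1]).all():
        raise DesignError("sex must be coded 0/1")
    for _, row in df.iterrows():
        want = _expected_tm(row["cohort"], row["timepoint"])
        if row["tm"] != want:
            raise DesignError(
                f"subject {row['subject_id']} ({row['cohort']}, {row['timepoint']}): "
                f"tm={row['tm']!r} inconsistent with crossover order (expected {want!r})"
            )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, format: str | None = None) -> ConnectivityMatrix:
    """Read a connectivity matrix from delimited text or an ``.npz`` container.

    Mild asymmetry (max |A - A'| <= 1e-8, e.g. from printing precision) is
    repaired by averaging with the transpose; anything larger is an error.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "tsv"
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            values = z["values"]
            parcel_ids = [str(p) for p in z["parcel_ids"]]
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        parcel_ids = [str(c) for c in df.columns]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise InputShapeError(f"matrix in {path} is not square: {values.shape}")
    if np.isnan(values).any():
        raise InputValueError(f"matrix in {path} contains NaN entries")
    asym = np.abs(values - values.T).max()
    if asym > 1e-8:
        raise InputValueError(f"matrix in {path} asymmetric beyond tolerance ({asym:.3e} > 1e-8)")
    values = 0.5 * (values + values.T)
    return ConnectivityMatrix(values=values, parcel_ids=tuple(parcel_ids))


def write_matrix(m: ConnectivityMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "tsv"
    if format == "npz":
        np.savez(path, values=m.values, parcel_ids=np.array(m.parcel_ids))
    else:
        pd.DataFrame(m.values, index=list(m.parcel_ids), columns=list(m.parcel_ids)).to_csv(
            path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a longitudinal design table (TSV/CSV)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[""])
    return validate_design(frame)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    design.to_csv(path, sep=sep, index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration with explicit defaults for every stage.

    Defaults mirror the study settings: retain the top 10% of each
    connectivity row, diffusion-map density parameter 0.5 at diffusion time
    0, ten computed components with the first three reported, 12
    intracortical surfaces grouped into three depth compartments, and
    five-fold cross-validation repeated 100 times with a 100-point
    log-spaced lasso penalty grid on [1e-4, 1].
    """

    density: float = 0.10
    embedding_alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    n_components_report: int = 3
    n_parcels: int = 400
    n_surfaces: int = 12
    compartments: dict = field(
        default_factory=lambda: {"superficial": [1, 4], "middle": [5, 8], "deep": [9, 12]}
    )
    folds: int = 5
    reps: int = 100
    n_select: int = 7
    alpha_grid_min: float = 1e-4
    alpha_grid_max: float = 1.0
    alpha_grid_size: int = 100
    n_perm: int = 1000
    fdr_q: float = 0.05
    use_interval_index: bool = True
    sex_coding: dict = field(default_factory=lambda: {"male": 0, "female": 1})
    center_ages: bool = True
    seed: int = 0
    #: settings forwarded to the synthetic-study generator (pipeline runs)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.density <= 1):
            raise ConfigError(f"density must lie in (0, 1], got {self.density}")
        if not (0 <= self.embedding_alpha <= 1):
            raise ConfigError(f"embedding_alpha must lie in [0, 1], got {self.embedding_alpha}")
        if self.n_components_report > self.n_components:
            raise ConfigError("n_components_report cannot exceed n_components")
        if self.n_surfaces < 1:
            raise ConfigError("n_surfaces must be >= 1")
        if self.folds < 2 or self.reps < 1:
            raise ConfigError("folds must be >= 2 and reps >= 1")
        if not (0 < self.alpha_grid_min <= self.alpha_grid_max):
            raise ConfigError("alpha grid bounds must satisfy 0 < min <= max")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must lie in (0, 1), got {self.fdr_q}")

    @classmethod
    def from_dict(cls, data: Mapping | None) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def alpha_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.alpha_grid_min), np.log10(self.alpha_grid_max), self.alpha_grid_size
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; missing keys are filled with defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"configuration in {path} is not a mapping")
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def rng_from_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive *n* independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31)).astype(np.int64)
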