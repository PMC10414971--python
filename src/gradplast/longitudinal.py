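"""Longitudinal change maps and mixed-effects training contrasts.

Inference runs on subject-specific change maps — per-parcel differences of
metric maps at consecutive scans — with the model

    delta ~ 1 + age + sex + interval_index + TM + (1 | subject)

fit by REML per parcel. The TM contrast compares the mean change during
one training module against another (or against untrained retest-control
intervals); p-values are FDR-corrected across parcels within a contrast
and effect sizes use the convention ``d = t / sqrt(df)`` with the residual
degrees of freedom of the fixed-effects design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InputShapeError, InputValueError
from .io_core import TIMEPOINTS, logger
from .lmm import fit_random_intercept

__all__ = ["ChangeTable", "ContrastResult", "change_maps", "fit_contrast",
           "fdr_bh", "group_anova"]


@dataclass
class ChangeTable:
    """Per-interval change rows: design covariates plus a feature matrix."""

    frame: pd.DataFrame  # subject_id, cohort, interval, tm, age, sex, interval_index
    values: np.ndarray   # (n_rows, n_features)
    feature_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.frame) != self.values.shape[0]:
            raise InputShapeError("frame and values row counts differ")
        if not self.feature_ids:
            self.feature_ids = tuple(f"f{i:03d}" for i in range(self.values.shape[1]))

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ContrastResult:
    """Per-feature Wald statistics for one training-module contrast."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d: np.ndarray
    df: int
    description: str
    estimate: np.ndarray = field(default=None)


def change_maps(maps: dict, design: pd.DataFrame) -> ChangeTable:
    """Difference metric maps at consecutive timepoints per subject.

    ``maps`` is keyed by ``(subject_id, timepoint)``. One row is emitted
    per interval whose both endpoints are present; the row carries the
    module trained during that interval (``"None"`` for untrained
    intervals) and the covariates of the later scan. Missing-endpoint
    intervals are dropped and counted in the log.
    """
    rows, deltas = [], []
    dropped = 0
    design = design.set_index(["subject_id", "timepoint"], drop=False)
    for sid in design["subject_id"].unique():
        tps = [tp for tp in TIMEPOINTS if (sid, tp) in design.index]
        for a, b in zip(tps[:-1], tps[1:]):
            if TIMEPOINTS.index(b) - TIMEPOINTS.index(a) != 1:
                continue
            if (sid, a) not in maps or (sid, b) not in maps:
                dropped += 1
                continue
            post = design.loc[(sid, b)]
            rows.append((sid, post["cohort"], f"{a}-{b}", post["tm"], post["age"],
                         post["sex"], post["interval_index"]))
            deltas.append(np.asarray(maps[(sid, b)], dtype=float)
                          - np.asarray(maps[(sid, a)], dtype=float))
    if dropped:
        logger.info("change_maps: dropped %d intervals with a missing endpoint", dropped)
    frame = pd.DataFrame(
        rows, columns=["subject_id", "cohort", "interval", "tm", "age", "sex",
                       "interval_index"]
    )
    return ChangeTable(frame=frame, values=np.vstack(deltas) if deltas else np.empty((0, 0)))


def _contrast_rows(ct: ChangeTable, tm_a: str, tm_b: str) -> tuple[np.ndarray, np.ndarray]:
    frame = ct.frame
    in_a = (frame["tm"] == tm_a).to_numpy()
    if tm_b == "RCC":
        in_b = ((frame["tm"] == "None") & (frame["cohort"] == "RCC")).to_numpy()
    else:
        in_b = (frame["tm"] == tm_b).to_numpy()
    return in_a, in_b


def fit_contrast(
    ct: ChangeTable,
    contrast: tuple[str, str],
    use_interval_index: bool = True,
    center_ages: bool = True,
    covariate_maps: np.ndarray | None = None,
    q_level: float = 0.05,
) -> ContrastResult:
    """Mixed-effects contrast of change between two training conditions.

    ``contrast = (tm_a, tm_b)`` compares module ``tm_a`` against module
    ``tm_b`` (or the untrained retest intervals when ``tm_b == "RCC"``).
    Per feature, change is modeled on intercept, centered age, sex,
    interval index and a module indicator with a subject random intercept
    (REML); the Wald t of the indicator is returned with two-sided p,
    BH-FDR q across features, and ``d = t / sqrt(df)``. An optional
    per-row-per-feature ``covariate_maps`` array (e.g. concurrent
    thickness change) is added as a feature-specific nuisance column.
    """
    tm_a, tm_b = contrast
    in_a, in_b = _contrast_rows(ct, tm_a, tm_b)
    for name, mask in ((tm_a, in_a), (tm_b, in_b)):
        groups_with = ct.frame.loc[mask, "subject_id"].nunique()
        if mask.sum() < 3 or groups_with == 0:
            raise InputValueError(f"condition {name!r} has fewer than 3 observations")
    keep = in_a | in_b
    frame = ct.frame.loc[keep]
    Y = ct.values[keep]
    age = frame["age"].to_numpy(dtype=float)
    if center_ages:
        age = age - age.mean()
    cols = [np.ones(keep.sum()), age, frame["sex"].to_numpy(dtype=float)]
    if use_interval_index:
        cols.append(frame["interval_index"].to_numpy(dtype=float))
    cols.append(in_a[keep].astype(float))
    X = np.column_stack(cols)
    groups = frame["subject_id"].to_numpy()

    if covariate_maps is None:
        fit = fit_random_intercept(X, Y, groups)
        c = np.zeros(X.shape[1])
        c[-1] = 1.0
        t = fit.contrast_t(c)
        est = fit.beta[-1]
        df = fit.df
    else:
        cov = np.asarray(covariate_maps, dtype=float)[keep]
        ts, ests = [], []
        for j in range(Y.shape[1]):
            Xj = np.column_stack([X, cov[:, j]])
            fitj = fit_random_intercept(Xj, Y[:, j], groups)
            c = np.zeros(Xj.shape[1])
            c[-2] = 1.0
            ts.append(fitj.contrast_t(c)[0])
            ests.append(fitj.beta[-2, 0])
        t, est = np.asarray(ts), np.asarray(ests)
        df = keep.sum() - X.shape[1] - 1

    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    _, q = fdr_bh(p, q_level)
    d = t / np.sqrt(df)
    return ContrastResult(t=t, p=p, q=q, d=d, df=df,
                          description=f"{tm_a} vs {tm_b}", estimate=est)


def fdr_bh(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InputShapeError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise InputValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return reject, q


def group_anova(values: np.ndarray, labels: np.ndarray) -> tuple[float, int, int, float]:
    """One-way ANOVA of a per-parcel map across parcel groups.

    Returns ``(F, df_between, df_within, p)``. Degenerate separation
    (zero within-group variance) yields p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InputValueError("need at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise InputValueError("every group needs at least 2 members")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = scipy.stats.f_oneway(*samples)
    df1 = len(uniq) - 1
    df2 = values.shape[0] - len(uniq)
    if np.isinf(F) or (np.isnan(p) and np.isfinite(F)):
        p = 0.0
    return float(F), df1, df2, float(p)
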