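"""Progression statistics over quantification matrices.

Hierarchical clustering (euclidean distance, complete linkage), temporal
category annotation of PTM sites, fold changes against the earliest time
point, Welch t-tests, and Pearson correlation of per-peptide measures with
(log-transformed) insoluble Tau burden.

p-values are uncorrected; rows with missing values are dropped from
clustering by default (mean imputation available behind a flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "CorrelationRow",
    "TEMPORAL_CATEGORIES",
    "annotate_temporal",
    "correlate_with_burden",
    "fold_change_vs_baseline",
    "hierarchical_cluster",
    "rank_top_correlating",
    "welch_t_test",
]

TEMPORAL_CATEGORIES = (
    "all_timepoints",
    "pre_onset",
    "concomitant_with_onset",
    "post_onset",
)


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram over matrix rows.

    ``linkage_matrix`` is in scipy format (merge heights non-decreasing for
    complete linkage); ``row_order`` is the leaf traversal order expressed
    in the input's row labels; ``dropped_rows`` lists rows removed for
    missing values.
    """

    row_order: list
    linkage_matrix: np.ndarray
    labels: list
    dropped_rows: list
    fingerprint: int

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()


def hierarchical_cluster(
    matrix: pd.DataFrame, impute_missing: bool = False
) -> ClusterResult:
    """Cluster matrix rows with euclidean distance and complete linkage.

    Rows containing missing values are dropped with a log line unless
    ``impute_missing`` is set, in which case they are filled with the
    column mean. Ties are resolved deterministically by input row order
    (lower row index merges first); leaf order is scipy's recursive
    traversal of the resulting dendrogram.
    """
    df = matrix.astype(float)
    dropped: list = []
    if df.isna().any().any():
        if impute_missing:
            df = df.fillna(df.mean(axis=0))
        else:
            mask = df.isna().any(axis=1)
            dropped = list(df.index[mask])
            logger.info("dropping %d rows with missing values", len(dropped))
            df = df.loc[~mask]
    if len(df) < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    values = df.to_numpy()
    Z = linkage(values, method="complete", metric="euclidean")
    order = leaves_list(Z)
    return ClusterResult(
        row_order=[df.index[i] for i in order],
        linkage_matrix=Z,
        labels=list(df.index),
        dropped_rows=dropped,
        fingerprint=hash(values.tobytes()),
    )


def annotate_temporal(
    binary: pd.DataFrame,
    onset: float,
    timepoints: Sequence[float] | None = None,
) -> dict[str, str]:
    """Classify each site's binary presence vector over ordered time points.

    Present at every time point -> ``all_timepoints``; otherwise by the
    first time point with presence: before the onset key -> ``pre_onset``,
    equal -> ``concomitant_with_onset``, after -> ``post_onset``. Sites
    absent everywhere are excluded from the result.
    """
    if timepoints is None:
        timepoints = [float(c) for c in binary.columns]
    timepoints = list(timepoints)
    if sorted(timepoints) != timepoints:
        raise ValueError("time points must be ordered ascending")
    if onset not in timepoints:
        raise ValueError(f"onset {onset} not among time points {timepoints}")
    out: dict[str, str] = {}
    for site, row in binary.iterrows():
        present = [t for t, v in zip(timepoints, row.to_numpy()) if v]
        if not present:
            continue
        if len(present) == len(timepoints):
            out[site] = "all_timepoints"
            continue
        first = present[0]
        if first < onset:
            out[site] = "pre_onset"
        elif first == onset:
            out[site] = "concomitant_with_onset"
        else:
            out[site] = "post_onset"
    return out


def fold_change_vs_baseline(
    values: Sequence[float], times: Sequence[float]
) -> dict[float, float]:
    """Per-time-point mean fold change relative to the earliest time point.

    ``fold(t) = mean(values at t) / mean(values at baseline)`` where the
    baseline is the earliest time point with at least one value. A zero
    baseline mean yields NaN folds with a log line.
    """
    if len(values) != len(times):
        raise ValueError("values and times must have equal length")
    by_time: dict[float, list[float]] = {}
    for v, t in zip(values, times):
        by_time.setdefault(float(t), []).append(float(v))
    baseline = min(by_time)
    base_mean = float(np.mean(by_time[baseline]))
    folds: dict[float, float] = {}
    for t in sorted(by_time):
        if base_mean == 0:
            logger.warning("baseline mean is 0; fold at t=%s undefined", t)
            folds[t] = float("nan")
        else:
            folds[t] = float(np.mean(by_time[t])) / base_mean
    return folds


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test.

    Degenerate inputs (n < 2, or zero variance in both groups with unequal
    means) raise; identical constant groups return ``(0.0, 1.0)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class CorrelationRow:
    """Pearson correlation of one peptide/site measure with burden."""

    label: str
    r: float  # NaN when either vector is constant
    n: int
    start: int | None = None  # canonical start, used for tie-breaking


def correlate_with_burden(
    x: Sequence[float],
    burden: Sequence[float],
    log_transform: bool = True,
    label: str = "",
    start: int | None = None,
) -> CorrelationRow:
    """Pearson r between a per-sample measure and (log10) Tau burden.

    Pairs with missing values are dropped; fewer than 3 complete pairs or a
    constant vector yield ``r = NaN``.
    """
    xs = np.asarray(x, dtype=float)
    bs = np.asarray(burden, dtype=float)
    if xs.shape != bs.shape:
        raise ValueError("x and burden must have equal length")
    if log_transform:
        if np.any(bs[np.isfinite(bs)] <= 0):
            raise ValueError("burden must be > 0 for log transform")
        bs = np.log10(bs)
    keep = np.isfinite(xs) & np.isfinite(bs)
    xs, bs = xs[keep], bs[keep]
    n = int(len(xs))
    if n < 3 or np.ptp(xs) == 0 or np.ptp(bs) == 0:
        return CorrelationRow(label=label, r=float("nan"), n=n, start=start)
    import warnings

    with warnings.catch_warnings():
        # clipped fractions can differ only at float epsilon; r is still
        # well defined for ranking purposes
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        r = float(stats.pearsonr(xs, bs).statistic)
    return CorrelationRow(label=label, r=r, n=n, start=start)


def rank_top_correlating(
    table: Sequence[CorrelationRow] | Mapping[str, Sequence[CorrelationRow]],
    k: int | None = None,
) -> list[str]:
    """Rank labels by |r| descending (averaged across conditions when a
    mapping of condition -> rows is given); ties break by canonical start.

    ``k`` larger than the table returns everything; NaN correlations sort
    last.
    """
    if isinstance(table, Mapping):
        acc: dict[str, list[CorrelationRow]] = {}
        for rows in table.values():
            for row in rows:
                acc.setdefault(row.label, []).append(row)
        merged = []
        for lab, lab_rows in acc.items():
            finite = [abs(r.r) for r in lab_rows if math.isfinite(r.r)]
            merged.append(
                CorrelationRow(
                    label=lab,
                    r=float(np.mean(finite)) if finite else float("nan"),
                    n=sum(r.n for r in lab_rows),
                    start=lab_rows[0].start,
                )
            )
        rows = merged
    else:
        rows = list(table)
    if not rows:
        raise ValueError("empty correlation table")

    def key(row: CorrelationRow):
        mag = abs(row.r)
        return (-(mag if math.isfinite(mag) else -1.0), row.start if row.start is not None else 10**9)

    ordered = [row.label for row in sorted(rows, key=key)]
    return ordered if k is None else ordered[: max(k, 0)]
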