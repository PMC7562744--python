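"""Decompose a mark's global change into locally driven vs genome-wide driven.

A global shift of a histone modification can arise in two ways: signal can
accumulate at enriched loci only ("peaks"), or it can change uniformly over
peaks and background alike. On quantitative (globally rescaled) per-bin fold
changes the two mechanisms separate cleanly: a locally driven change moves
the peak-bin median but not the background median, a genome-wide driven one
moves both by a similar amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

TAU_LOG2_DEFAULT = 0.25
DELTA_LOG2_DEFAULT = 0.5


@dataclass
class MASummary:
    """Mean coverage (x) vs log2 fold change (y) with coverage-quartile summaries."""

    coverage: pd.Series
    log2fc: pd.Series
    quartile_bounds: np.ndarray
    quartile_of: pd.Series
    quartile_medians: np.ndarray
    quartile_iqrs: np.ndarray


def ma_summary(fc_table: pd.Series, coverage_table: pd.Series) -> MASummary:
    """Summarize per-bin fold changes by quartile of mean coverage.

    `coverage_table` is the mean of the two conditions' input-normalized
    coverage per bin; quartiles partition the bins into four equal-size
    groups (ties broken by rank, so sizes differ by at most 1).
    """
    common = fc_table.index.intersection(coverage_table.index)
    if len(common) < 4:
        raise ValueError("need at least 4 shared bins for quartiles")
    fc = fc_table.loc[common]
    cov = coverage_table.loc[common]
    ranks = cov.rank(method="first")
    quartile = pd.qcut(ranks, 4, labels=False)
    bounds = np.quantile(cov, [0.0, 0.25, 0.5, 0.75, 1.0])
    medians = np.array([fc[quartile == q].median() for q in range(4)])
    iqrs = np.array(
        [np.subtract(*np.percentile(fc[quartile == q], [75, 25])) for q in range(4)]
    )
    return MASummary(
        coverage=cov,
        log2fc=fc,
        quartile_bounds=bounds,
        quartile_of=quartile,
        quartile_medians=medians,
        quartile_iqrs=iqrs,
    )


@dataclass
class GlobalChangeClass:
    """Decision on the mechanism behind a global change."""

    label: str  # none | locally_driven | genome_wide_driven | mixed
    peak_median: float
    background_median: float
    tau_log2: float
    delta_log2: float

    def summary(self) -> str:
        return (
            f"{self.label}: peak median {self.peak_median:+.3f}, background "
            f"median {self.background_median:+.3f} (tau={self.tau_log2}, "
            f"delta={self.delta_log2})"
        )


def classify_global_change(
    ma: MASummary,
    peak_mask: pd.Series | np.ndarray,
    tau_log2: float = TAU_LOG2_DEFAULT,
    delta_log2: float = DELTA_LOG2_DEFAULT,
) -> GlobalChangeClass:
    """Classify a change as none / locally_driven / genome_wide_driven / mixed.

    Uses the median quantitative-mode fold change over peak bins and over
    background bins. `tau_log2` is the minimal median magnitude that counts
    as a change; `delta_log2` the maximal peak-background difference still
    read as a uniform shift.
    """
    mask = pd.Series(np.asarray(peak_mask, dtype=bool), index=ma.log2fc.index)
    if mask.all() or (~mask).all():
        raise ValueError("peak mask must leave both peak and background bins")
    mp = float(ma.log2fc[mask].median())
    mb = float(ma.log2fc[~mask].median())
    if abs(mp) < tau_log2 and abs(mb) < tau_log2:
        label = "none"
    elif abs(mb) < tau_log2 <= abs(mp):
        label = "locally_driven"
    elif (
        abs(mp) >= tau_log2
        and abs(mb) >= tau_log2
        and np.sign(mp) == np.sign(mb)
        and abs(mp - mb) < delta_log2
    ):
        label = "genome_wide_driven"
    else:
        label = "mixed"
    return GlobalChangeClass(label, mp, mb, tau_log2, delta_log2)


@dataclass
class ClusterAssignment:
    """Gene clusters ordered 1..k by descending mean enrichment."""

    labels: pd.Series  # gene_id -> cluster 1..k
    centers: pd.DataFrame  # cluster x score columns
    k: int
    seed: int

    def genes_in(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def kmeans_stratify(
    scores: pd.DataFrame, k: int = 5, seed: int = 0, restarts: int = 50
) -> ClusterAssignment:
    """Stratify genes by k-means on per-gene enrichment scores.

    `scores` is gene x condition (e.g. log2 chip/input in two cell types).
    Clusters are relabeled 1..k by descending mean center value, so labels
    are invariant to initialization permutation; fixed seed gives a
    deterministic assignment.
    """
    if k > len(scores):
        raise ValueError("more clusters than genes")
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(values)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[int(r)] for r in raw], index=scores.index, name="cluster")
    centers = pd.DataFrame(
        km.cluster_centers_[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=scores.columns,
    )
    return ClusterAssignment(labels=labels, centers=centers, k=k, seed=seed)


def cluster_summaries(
    assignment: ClusterAssignment,
    global_fc: pd.Series,
    expression_fc: pd.Series,
) -> pd.DataFrame:
    """Per-cluster medians and IQRs of global-mode mark FC and expression FC.

    Tables are keyed by gene id; clusters with no genes present in a table
    get NaN summaries and an explicit ``empty`` flag.
    """
    rows = []
    for c in range(1, assignment.k + 1):
        genes = assignment.genes_in(c)
        fc = global_fc.reindex(genes).dropna()
        ex = expression_fc.reindex(genes).dropna()
        empty = len(fc) == 0 and len(ex) == 0

        def _med_iqr(v):
            if len(v) == 0:
                return np.nan, np.nan
            return float(v.median()), float(np.subtract(*np.percentile(v, [75, 25])))

        fc_med, fc_iqr = _med_iqr(fc)
        ex_med, ex_iqr = _med_iqr(ex)
        rows.append(
            {
                "cluster": c,
                "n_genes": int(len(genes)),
                "global_fc_median": fc_med,
                "global_fc_iqr": fc_iqr,
                "expression_fc_median": ex_med,
                "expression_fc_iqr": ex_iqr,
                "empty": empty,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
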