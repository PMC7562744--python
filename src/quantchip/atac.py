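"""Treatment-responsive open-chromatin regions and mark co-occurrence.

Responsive ATAC peaks are selected by their loading on a chosen principal
component of the variance-stabilized peak x sample count matrix (top n by
absolute loading), split into losing (ATAC-Down) and gaining (ATAC-Up)
accessibility by the sign of the mean cross-condition fold change.
Selected peaks are annotated to genomic features with a fixed precedence
(promoter-TSS > TTS > exon > intron > intergenic), matched to enhancers,
and summarized for H3K79me2 co-occurrence on intronic peaks per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

DOWN, UP, BACKGROUND = "ATAC-Down", "ATAC-Up", "background-ATAC"


def _log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    depth = counts.sum(axis=0)
    return np.log2(counts.div(depth, axis=1) * 1e6 + pseudocount)


@dataclass
class LoadingSelection:
    """Top-|loading| peak selection on one principal component."""

    component: int  # 1-based
    loadings: pd.Series  # per peak
    selected: pd.Index
    direction: pd.Series  # selected peak -> ATAC-Down / ATAC-Up
    background: pd.Index
    mean_log2fc: pd.Series  # per peak, treatment vs control
    explained_variance_ratio: float

    def peaks_in(self, cls: str) -> pd.Index:
        if cls == BACKGROUND:
            return self.background
        return self.direction.index[self.direction == cls]


def pc_loading_select(
    counts: pd.DataFrame,
    condition_of: dict[str, str] | pd.Series,
    *,
    component: int = 1,
    n: int = 2000,
    control: str = "DMSO",
) -> LoadingSelection:
    """Select the n peaks with the highest |loading| on a principal component.

    `counts` is peak x sample (raw counts; variance-stabilized internally
    as log2(CPM + 1)); `condition_of` maps sample -> condition, with
    exactly two conditions. The direction class of a selected peak comes
    from the sign of its mean treatment-vs-control log2 fold change, not
    from the loading sign (which is arbitrary). Remaining peaks form the
    background set.
    """
    if n > len(counts):
        raise ValueError("cannot select more peaks than provided")
    cond = pd.Series(condition_of)
    conditions = sorted(cond.unique())
    if len(conditions) != 2 or control not in conditions:
        raise ValueError("need exactly two conditions including the control")
    treatment = [c for c in conditions if c != control][0]
    X = _log2_cpm(counts)
    if np.allclose(X.to_numpy().std(axis=1), 0):
        raise ValueError("degenerate count matrix: no variance across samples")
    pca = PCA(n_components=min(len(X.columns), component + 1))
    pca.fit(X.to_numpy().T)  # samples as observations, peaks as features
    load = pd.Series(pca.components_[component - 1], index=counts.index, name="loading")
    order = load.abs().sort_values(ascending=False, kind="stable")
    selected = order.index[:n]
    ctrl_cols = cond.index[cond == control]
    trt_cols = cond.index[cond == treatment]
    fc = X[trt_cols].mean(axis=1) - X[ctrl_cols].mean(axis=1)
    direction = pd.Series(
        np.where(fc.loc[selected] < 0, DOWN, UP), index=selected, name="direction"
    )
    return LoadingSelection(
        component=component,
        loadings=load,
        selected=selected,
        direction=direction,
        background=counts.index.difference(selected),
        mean_log2fc=fc,
        explained_variance_ratio=float(pca.explained_variance_ratio_[component - 1]),
    )


def annotate_peaks(
    peaks: pd.DataFrame,
    genome,
    enhancers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate peaks to genomic features with a fixed precedence.

    Precedence: promoter-TSS (TSS-1000..+100, strand-aware) > TTS (+-1 kb)
    > exon > intron (within a gene span but not exonic) > intergenic; an
    overlap of >= 1 bp counts. Adds the assigned ``gene_id`` where the
    category implies one, the enhancer flag (>= 1 bp overlap with the
    enhancer set) and the enhancer class (intronic if the peak overlaps a
    gene, intergenic otherwise).
    """
    genes = genome.genes
    exons = genome.exons.merge(genome.genes[["gene_id", "chrom"]], on="gene_id")
    plus = genes["strand"].values == "+"
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": np.maximum(np.where(plus, genes["tss"].values - 1000, genes["tss"].values - 100), 0),
            "end": np.where(plus, genes["tss"].values + 100, genes["tss"].values + 1000),
            "gene_id": genes["gene_id"].values,
        }
    )
    tts = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": np.maximum(genes["tts"].values - 1000, 0),
            "end": genes["tts"].values + 1000,
            "gene_id": genes["gene_id"].values,
        }
    )
    gene_spans = genes[["chrom", "start", "end", "gene_id"]]
    exon_iv = exons[["chrom", "start", "end", "gene_id"]]

    def _first_hit(peak_row, table):
        sub = table[table["chrom"] == peak_row["chrom"]]
        if sub.empty:
            return None
        ov = np.minimum(peak_row["end"], sub["end"].to_numpy()) - np.maximum(
            peak_row["start"], sub["start"].to_numpy()
        )
        hits = np.flatnonzero(ov >= 1)
        if hits.size == 0:
            return None
        return sub["gene_id"].iloc[hits[0]]

    annotations, gene_ids = [], []
    for _, p in peaks.iterrows():
        for label, table in (
            ("promoter-TSS", prom),
            ("TTS", tts),
            ("exon", exon_iv),
            ("intron", gene_spans),
        ):
            gid = _first_hit(p, table)
            if gid is not None:
                annotations.append(label)
                gene_ids.append(gid)
                break
        else:
            annotations.append("intergenic")
            gene_ids.append(None)
    out = peaks.copy()
    out["annotation"] = annotations
    out["gene_id"] = gene_ids
    if enhancers is not None and len(enhancers):
        from .genome import overlap_any

        out["enhancer"] = overlap_any(out, enhancers)
    else:
        out["enhancer"] = False
    out["enhancer_class"] = np.where(
        ~out["enhancer"],
        "other",
        np.where(out["gene_id"].notna(), "intronic", "intergenic"),
    )
    return out


def enhancer_fc_summary(
    selection: LoadingSelection,
    annotated_peaks: pd.DataFrame,
    fc_table: pd.Series | None = None,
    gene_fc: pd.Series | None = None,
) -> dict:
    """Accessibility fold-change distribution per enhancer class.

    Summarizes the selected (dynamic) peaks overlapping enhancers, split
    into intronic and intergenic classes; optionally pairs each peak's FC
    with the expression FC of its assigned gene for scatter export. Empty
    classes are flagged rather than raised.
    """
    fc = fc_table if fc_table is not None else selection.mean_log2fc
    ann = annotated_peaks.set_index("peak_id")
    sel = ann.loc[ann.index.intersection(selection.selected)]
    enh = sel[sel["enhancer"]]
    summary, flags = {}, []
    for cls in ("intronic", "intergenic"):
        vals = fc.reindex(enh.index[enh["enhancer_class"] == cls]).dropna()
        if len(vals) == 0:
            flags.append(cls)
            summary[cls] = {"n": 0, "median": float("nan"), "iqr": float("nan")}
        else:
            summary[cls] = {
                "n": int(len(vals)),
                "median": float(vals.median()),
                "iqr": float(np.subtract(*np.percentile(vals, [75, 25]))),
            }
    pairs = None
    if gene_fc is not None:
        with_gene = sel[sel["gene_id"].notna()]
        pairs = pd.DataFrame(
            {
                "peak_id": with_gene.index,
                "peak_log2fc": fc.reindex(with_gene.index).to_numpy(),
                "gene_id": with_gene["gene_id"].to_numpy(),
                "gene_log2fc": gene_fc.reindex(with_gene["gene_id"]).to_numpy(),
                "enhancer": with_gene["enhancer"].to_numpy(),
            }
        ).dropna(subset=["gene_log2fc"])
    return {"classes": summary, "empty_classes": flags, "gene_pairs": pairs}


def mark_fraction_by_class(
    selection: LoadingSelection,
    annotated_peaks: pd.DataFrame,
    marked_genes: pd.Series,
) -> pd.DataFrame:
    """Fraction of genes with intronic peaks per class that carry H3K79me2.

    For each class (ATAC-Down, ATAC-Up, background-ATAC), collect the
    protein-coding genes having at least one peak of that class annotated
    as intronic, and report the fraction flagged as H3K79me2-marked.
    Empty classes yield NaN with a flag.
    """
    ann = annotated_peaks.set_index("peak_id")
    rows = []
    for cls in (DOWN, UP, BACKGROUND):
        ids = selection.peaks_in(cls)
        sub = ann.loc[ann.index.intersection(ids)]
        genes = sub.loc[(sub["annotation"] == "intron") & sub["gene_id"].notna(), "gene_id"].unique()
        if len(genes) == 0:
            rows.append({"class": cls, "n_genes": 0, "fraction_marked": float("nan"), "empty": True})
            continue
        marked = marked_genes.reindex(genes).fillna(False).astype(bool)
        rows.append(
            {
                "class": cls,
                "n_genes": int(len(genes)),
                "fraction_marked": float(marked.mean()),
                "empty": False,
            }
        )
    return pd.DataFrame(rows).set_index("class")


@dataclass
class MwuResult:
    statistic: float
    pvalue: float
    method: str  # exact | asymptotic
    all_tied: bool = False


def mwu_compare(group_a, group_b) -> MwuResult:
    """Two-sided Mann-Whitney U comparison of two densities.

    Exact null distribution for group sizes <= 8 without ties; normal
    approximation with tie correction otherwise. If every value is tied
    across both groups the comparison is vacuous: p = 1 with a flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MwuResult(statistic=len(a) * len(b) / 2.0, pvalue=1.0, method="degenerate", all_tied=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not has_ties:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return MwuResult(statistic=float(res.statistic), pvalue=float(res.pvalue), method=method)


@dataclass
class PairedTTestResult:
    t: float
    df: int
    pvalue: float
    mean_diff: float  # control minus treatment
    alternative: str
    zero_variance: bool = False


def paired_onesided_ttest(
    control, treatment, alternative: str = "decrease"
) -> PairedTTestResult:
    """One-sided paired t-test on per-locus %input values.

    Differences are control - treatment; ``decrease`` tests whether the
    signal decreases under treatment (differences > 0), ``increase`` the
    opposite. With zero variance of the differences the p-value is 0 or 1
    by the sign of the mean difference (0.5 at exactly zero), flagged.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-D")
    if len(c) < 2:
        raise ValueError("need at least 2 pairs")
    diff = c - t
    df = len(c) - 1
    if np.std(diff, ddof=1) == 0:
        md = float(diff.mean())
        if md == 0:
            return PairedTTestResult(0.0, df, 0.5, md, alternative, zero_variance=True)
        in_alt = (md > 0) == (alternative == "decrease")
        return PairedTTestResult(
            float(np.inf if md > 0 else -np.inf), df, 0.0 if in_alt else 1.0,
            md, alternative, zero_variance=True,
        )
    scipy_alt = {"decrease": "greater", "increase": "less"}[alternative]
    res = scipy.stats.ttest_rel(c, t, alternative=scipy_alt)
    return PairedTTestResult(
        t=float(res.statistic),
        df=df,
        pvalue=float(res.pvalue),
        mean_diff=float(diff.mean()),
        alternative=alternative,
    )
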