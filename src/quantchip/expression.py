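"""Relating histone-mark dynamics to transcriptional dynamics.

The central object is :class:`MarkExpressionModel`: an L1-regularized linear
model of per-gene expression log2 fold change on per-gene mark log2 fold
changes (one feature per mark plus the H3K79me2:H3K27ac interaction).
Features are ranked by the penalty at which each coefficient first enters
the lasso path — a sparsity-based relevance ordering — and the reported fit
carries both the in-sample and the cross-validated R².

The module also houses the smaller association statistics used around the
model: an OLS slope with confidence interval, the phi coefficient of a 2x2
table, marker-gene up/down ratios, and promoter-peak ECDF comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV, lasso_path, ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, cross_val_score

INTERACTION = "H3K79me2:H3K27ac"
PADJ_DE = 0.05  # treatment DEG definition
PADJ_DIFFERENTIATION = 0.01  # differentiation DEG: also |log2FC| > 1
LFC_DIFFERENTIATION = 1.0


def build_delta_matrix(
    fc_tables: dict[str, pd.Series],
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the gene x feature matrix of mark and expression changes.

    `fc_tables` maps mark name to a per-gene log2FC Series (indexed by
    gene id, quantified on the mark's feature window); `de_table` has
    columns ``gene_id, log2fc, padj``. One row per gene present in every
    input; the interaction column is the product of the H3K79me2 and
    H3K27ac columns. Genes missing any mark are dropped (count logged).
    """
    de = de_table.set_index("gene_id")
    common = de.index
    for series in fc_tables.values():
        common = common.intersection(series.index)
    mat = pd.DataFrame(index=common)
    for mark, series in fc_tables.items():
        mat[mark] = series.reindex(common)
    if "H3K79me2" in mat.columns and "H3K27ac" in mat.columns:
        mat[INTERACTION] = mat["H3K79me2"] * mat["H3K27ac"]
    mat["expr_log2fc"] = de["log2fc"].reindex(common)
    mat["padj"] = de["padj"].reindex(common)
    n_dropped = len(de) - len(common)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d genes missing mark quantification", n_dropped
        )
    mat.index.name = "gene_id"
    return mat.dropna()


@dataclass
class MarkExpressionResults:
    """Fitted regularized mark->expression model."""

    features: list[str]
    coef: pd.Series  # original scale
    intercept: float
    ranking: list[str]  # by descending path-entry penalty
    entry_alpha: pd.Series
    alpha: float  # penalty chosen by cross-validation
    r2: float  # in-sample at the chosen penalty
    r2_cv: float
    n_obs: int
    dropped_constant: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.features].to_numpy() @ self.coef.to_numpy()

    def plot_observed_vs_predicted(self, X: pd.DataFrame, y: pd.Series, ax=None):
        """Scatter of observed expression log2FC against model predictions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict(X)
        ax.scatter(pred, y, s=4, alpha=0.4, rasterized=True)
        lim = [min(pred.min(), y.min()), max(pred.max(), y.max())]
        ax.plot(lim, lim, color="0.4", lw=1)
        ax.set_xlabel("predicted expression log2FC")
        ax.set_ylabel("observed expression log2FC")
        ax.set_title(f"R² = {self.r2:.2f} (CV {self.r2_cv:.2f})")
        return ax

    def summary(self) -> str:
        lines = [
            "Regularized mark -> expression model",
            f"  n = {self.n_obs} genes, penalty alpha = {self.alpha:.4g}",
            f"  R2 (in-sample) = {self.r2:.3f}, R2 (cross-validated) = {self.r2_cv:.3f}",
            "  rank feature             coef      entry-penalty",
        ]
        for i, feat in enumerate(self.ranking, 1):
            lines.append(
                f"  {i:>4} {feat:<18} {self.coef[feat]:+.4f}   "
                f"{self.entry_alpha[feat]:.4g}"
            )
        if self.dropped_constant:
            lines.append(f"  dropped constant features: {self.dropped_constant}")
        return "\n".join(lines)


class MarkExpressionModel:
    """L1-regularized linear model of expression change on mark changes.

    Parameters
    ----------
    delta_matrix : output of :func:`build_delta_matrix` (or any frame with
        feature columns plus ``expr_log2fc``).
    features : columns to use; defaults to every column except
        ``expr_log2fc``/``padj``.
    l1_ratio : 1.0 fits a lasso (default); values in (0, 1) an elastic net.
    """

    def __init__(
        self,
        delta_matrix: pd.DataFrame,
        features: list[str] | None = None,
        l1_ratio: float = 1.0,
    ):
        self.data = delta_matrix
        self.features = features or [
            c for c in delta_matrix.columns if c not in ("expr_log2fc", "padj")
        ]
        if not 0 < l1_ratio <= 1:
            raise ValueError("l1_ratio must be in (0, 1]")
        self.l1_ratio = l1_ratio

    def fit(self, folds: int = 10, seed: int = 0, alpha: float | None = None) -> MarkExpressionResults:
        """Fit with the penalty chosen by seeded K-fold cross-validation.

        Features are standardized to unit variance before fitting;
        coefficients are reported back on the original scale. Pass `alpha`
        to skip the cross-validated penalty search.
        """
        import warnings

        X = self.data[self.features].to_numpy(dtype=float)
        y = self.data["expr_log2fc"].to_numpy(dtype=float)
        sd = X.std(axis=0)
        constant = sd == 0
        dropped = [f for f, c in zip(self.features, constant) if c]
        if dropped:
            warnings.warn(f"excluding constant features: {dropped}", stacklevel=2)
        feats = [f for f in self.features if f not in dropped]
        X = X[:, ~constant]
        sd = sd[~constant]
        mu = X.mean(axis=0)
        Z = (X - mu) / sd

        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        if alpha is None:
            if self.l1_ratio == 1.0:
                search = LassoCV(cv=cv, random_state=seed).fit(Z, y)
            else:
                search = ElasticNetCV(l1_ratio=self.l1_ratio, cv=cv, random_state=seed).fit(Z, y)
            alpha = float(search.alpha_)

        # entry order along the regularization path (largest penalty at
        # which each coefficient first becomes nonzero)
        alphas, coefs, _ = lasso_path(Z, y, eps=1e-4, alphas=200)
        entry = np.full(len(feats), -np.inf)
        for j in range(len(feats)):
            nz = np.flatnonzero(np.abs(coefs[j]) > 0)
            if nz.size:
                entry[j] = alphas[nz[0]]
        entry_alpha = pd.Series(entry, index=feats)
        order = sorted(
            feats, key=lambda f: (-entry_alpha[f], f)
        )

        model_cls = Lasso if self.l1_ratio == 1.0 else (
            lambda alpha: ElasticNet(alpha=alpha, l1_ratio=self.l1_ratio)
        )
        final = model_cls(alpha=alpha).fit(Z, y)
        r2 = float(final.score(Z, y))
        r2_cv = float(np.mean(cross_val_score(model_cls(alpha=alpha), Z, y, cv=cv, scoring="r2")))
        coef_orig = pd.Series(final.coef_ / sd, index=feats)
        intercept = float(final.intercept_ - np.sum(final.coef_ * mu / sd))
        return MarkExpressionResults(
            features=feats,
            coef=coef_orig,
            intercept=intercept,
            ranking=order,
            entry_alpha=entry_alpha,
            alpha=float(alpha),
            r2=r2,
            r2_cv=r2_cv,
            n_obs=len(y),
            dropped_constant=dropped,
        )


@dataclass
class SlopeEstimate:
    beta: float
    ci_low: float
    ci_high: float
    stderr: float
    n: int

    def summary(self) -> str:
        return (
            f"OLS slope beta = {self.beta:.4g} "
            f"[95% CI {self.ci_low:.4g}, {self.ci_high:.4g}], n = {self.n}"
        )


def slope_estimate(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> SlopeEstimate:
    """Ordinary least-squares slope of y on x with a 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return SlopeEstimate(
        beta=float(res.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        stderr=float(res.bse[1]),
        n=len(x),
    )


def phi_association(
    flags_a: np.ndarray | pd.Series, flags_b: np.ndarray | pd.Series
) -> tuple[float, np.ndarray]:
    """Phi coefficient of two binary vectors, with the 2x2 table.

    Table layout: rows = flags_a (True, False), columns = flags_b
    (True, False). phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); a zero
    margin makes phi undefined and returns NaN.
    """
    a_arr = np.asarray(flags_a, dtype=bool)
    b_arr = np.asarray(flags_b, dtype=bool)
    if a_arr.shape != b_arr.shape:
        raise ValueError("flag vectors must be the same length")
    a = int(np.sum(a_arr & b_arr))
    b = int(np.sum(a_arr & ~b_arr))
    c = int(np.sum(~a_arr & b_arr))
    d = int(np.sum(~a_arr & ~b_arr))
    table = np.array([[a, b], [c, d]])
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return float("nan"), table
    phi = (a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins]))
    return float(phi), table


def phi_from_table(table: np.ndarray) -> float:
    """Phi coefficient from an explicit 2x2 table [[a, b], [c, d]]."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(np.prod(margins)))


def marker_gene_ratio(
    de_table: pd.DataFrame,
    markers: dict[str, list[str]],
    padj_cut: float = PADJ_DE,
) -> pd.DataFrame:
    """Fraction of each marker set that is differentially expressed up/down.

    Gene ratio: n(DE & direction & marker) / n(marker). Marker ids absent
    from the DE universe stay in the denominator and are counted in the
    ``n_missing`` flag column. Duplicated marker ids are de-duplicated.
    """
    de = de_table.set_index("gene_id")
    rows = []
    for set_name, gene_ids in markers.items():
        ids = pd.Index(pd.unique(pd.Series(gene_ids)))
        if len(ids) == 0:
            raise ValueError(f"marker set {set_name!r} is empty")
        present = ids.intersection(de.index)
        sub = de.loc[present]
        sig = sub["padj"] < padj_cut
        n_up = int((sig & (sub["log2fc"] > 0)).sum())
        n_down = int((sig & (sub["log2fc"] < 0)).sum())
        rows.append(
            {
                "set": set_name,
                "n_markers": len(ids),
                "n_missing": len(ids) - len(present),
                "n_up": n_up,
                "n_down": n_down,
                "ratio_up": n_up / len(ids),
                "ratio_down": n_down / len(ids),
            }
        )
    return pd.DataFrame(rows).set_index("set")


def map_peaks_to_promoters(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window: tuple[int, int] = (-1000, 500),
) -> pd.DataFrame:
    """Map peaks to genes whose promoter window they overlap (>= 1 bp).

    The promoter is [TSS+window[0], TSS+window[1]) on the gene strand.
    Returns a (peak_id, gene_id) frame; a peak may hit several promoters.
    """
    up, down = -window[0], window[1]
    plus = genes["strand"].values == "+"
    p_start = np.where(plus, genes["tss"].values - up, genes["tss"].values - down)
    p_end = np.where(plus, genes["tss"].values + down, genes["tss"].values + up)
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": np.maximum(p_start, 0),
            "end": p_end,
            "gene_id": genes["gene_id"].values,
        }
    )
    pairs = []
    for chrom, p in peaks.groupby("chrom", sort=False):
        sub = prom[prom["chrom"] == chrom]
        if sub.empty:
            continue
        ps = p["start"].to_numpy()[:, None]
        pe = p["end"].to_numpy()[:, None]
        ov = (np.minimum(pe, sub["end"].to_numpy()[None, :])
              - np.maximum(ps, sub["start"].to_numpy()[None, :])) >= 1
        qi, si = np.nonzero(ov)
        for q, s_ in zip(qi, si):
            pairs.append((p["peak_id"].iloc[q], sub["gene_id"].iloc[s_]))
    return pd.DataFrame(pairs, columns=["peak_id", "gene_id"])


@dataclass
class EcdfSet:
    """ECDFs of promoter-peak fold changes for up/down/all gene classes."""

    ecdfs: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (x sorted, F(x))
    ks: dict[str, float]  # class vs background KS distance
    omitted: list[str]

    def median_shift(self, cls: str) -> float:
        x, _ = self.ecdfs[cls]
        bg, _ = self.ecdfs["all"]
        return float(np.median(x) - np.median(bg))


def promoter_peak_ecdf(
    peak_fc: pd.DataFrame,
    peak_to_gene: pd.DataFrame,
    de_table: pd.DataFrame,
    padj_cut: float = PADJ_DE,
) -> EcdfSet:
    """ECDFs of peak log2FC over promoters of up-, down- and all genes.

    `peak_fc` has columns ``peak_id, log2fc``; `peak_to_gene` maps peaks to
    promoter genes (from :func:`map_peaks_to_promoters`). Classes with
    fewer than 2 peaks are omitted and flagged. Reports the two-sample
    Kolmogorov-Smirnov distance of each DEG class against the background
    of all annotated genes.
    """
    de = de_table.set_index("gene_id")
    merged = peak_to_gene.merge(peak_fc, on="peak_id")
    merged = merged.join(de[["log2fc", "padj"]], on="gene_id", rsuffix="_expr")
    sig = merged["padj"] < padj_cut
    classes = {
        "up": merged.loc[sig & (merged["log2fc_expr"] > 0), "log2fc"].to_numpy(),
        "down": merged.loc[sig & (merged["log2fc_expr"] < 0), "log2fc"].to_numpy(),
        "all": merged["log2fc"].to_numpy(),
    }
    ecdfs, ks, omitted = {}, {}, []
    for name, vals in classes.items():
        if len(vals) < 2:
            omitted.append(name)
            continue
        x = np.sort(vals)
        ecdfs[name] = (x, np.arange(1, len(x) + 1) / len(x))
    for name in ("up", "down"):
        if name in ecdfs and "all" in ecdfs:
            ks[name] = float(scipy.stats.ks_2samp(classes[name], classes["all"]).statistic)
    return EcdfSet(ecdfs=ecdfs, ks=ks, omitted=omitted)
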