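"""Genome model, feature windows and interval arithmetic.

Coordinates are 0-based half-open throughout. A :class:`GenomeModel` carries
chromosome sizes, gene/transcript/exon annotation and enhancer intervals; it
is the container both the synthetic-data generator and the analysis stages
operate on. :class:`FeatureWindowSpec` encodes the per-mark quantification
windows around TSS/TTS used for fold-change estimation (active promoter
marks on a narrow promoter, elongation marks on an extended promoter or the
transcription termination site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as qio


@dataclass
class GenomeModel:
    """Chromosomes, gene annotation and enhancers.

    Attributes
    ----------
    chromosomes : DataFrame with columns ``chrom``, ``length``.
    genes : DataFrame with ``gene_id, chrom, start, end, strand, tss, tts``.
    transcripts : DataFrame with ``gene_id, transcript_id, chrom, strand,
        start, end`` (one row per transcript; ``start < end`` genomic).
    exons : DataFrame with ``gene_id, transcript_id, start, end``.
    enhancers : DataFrame with ``chrom, start, end, enh_class`` in
        {"intronic", "intergenic"} and boolean ``tf_bound``.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame
    enhancers: pd.DataFrame

    def validate(self) -> None:
        sizes = dict(zip(self.chromosomes["chrom"], self.chromosomes["length"]))
        for _, g in self.genes.iterrows():
            L = sizes[g["chrom"]]
            if not (0 <= g["start"] < g["end"] <= L):
                raise ValueError(f"gene {g['gene_id']} outside chromosome bounds")
        for _, e in self.enhancers.iterrows():
            if not (0 <= e["start"] < e["end"] <= sizes[e["chrom"]]):
                raise ValueError("enhancer outside chromosome bounds")

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qio.write_tsv(self.chromosomes, outdir / "chromosomes.tsv")
        qio.write_tsv(self.genes, outdir / "genes.tsv")
        qio.write_tsv(self.transcripts, outdir / "transcripts.tsv")
        qio.write_tsv(self.exons, outdir / "exons.tsv")
        qio.write_tsv(self.enhancers, outdir / "enhancers.tsv")

    @classmethod
    def from_dir(cls, indir) -> "GenomeModel":
        from pathlib import Path

        indir = Path(indir)
        return cls(
            chromosomes=qio.read_tsv(indir / "chromosomes.tsv"),
            genes=qio.read_tsv(indir / "genes.tsv"),
            transcripts=qio.read_tsv(indir / "transcripts.tsv"),
            exons=qio.read_tsv(indir / "exons.tsv"),
            enhancers=qio.read_tsv(indir / "enhancers.tsv"),
        )


@dataclass(frozen=True)
class WindowRule:
    """Strand-aware window around an anchor: [anchor-upstream, anchor+downstream)."""

    anchor: str  # "TSS" or "TTS"
    upstream: int
    downstream: int

    def __post_init__(self):
        if self.anchor not in ("TSS", "TTS"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.upstream + self.downstream <= 0:
            raise ValueError("degenerate window")


@dataclass
class FeatureWindowSpec:
    """Per-mark quantification window rules."""

    rules: dict[str, WindowRule] = field(default_factory=dict)

    @classmethod
    def preset(cls, name: str = "quantify") -> "FeatureWindowSpec":
        """Two shipped presets.

        ``quantify`` (default): narrow promoter TSS±1 kb for H3K4me3/H3K27ac/
        H3K4me1; extended promoter TSS−1 kb..+3 kb for H3K79me2/H3K27me3/
        H3K9me3; TTS−3 kb..+0.5 kb for H3K36me3.

        ``ma_bins``: wider promoter windows (TSS±2 kb) for the promoter marks,
        TSS..+3 kb for H3K79me2 and TTS−3 kb for H3K36me3, as used when
        binning genes for MA-style comparisons.
        """
        if name == "quantify":
            rules = {
                "H3K4me3": WindowRule("TSS", 1000, 1000),
                "H3K27ac": WindowRule("TSS", 1000, 1000),
                "H3K4me1": WindowRule("TSS", 1000, 1000),
                "H3K79me2": WindowRule("TSS", 1000, 3000),
                "H3K27me3": WindowRule("TSS", 1000, 3000),
                "H3K9me3": WindowRule("TSS", 1000, 3000),
                "H3K36me3": WindowRule("TTS", 3000, 500),
            }
        elif name == "ma_bins":
            rules = {
                "H3K4me3": WindowRule("TSS", 2000, 2000),
                "H3K27ac": WindowRule("TSS", 2000, 2000),
                "H3K4me1": WindowRule("TSS", 2000, 2000),
                "H3K79me2": WindowRule("TSS", 0, 3000),
                "H3K27me3": WindowRule("TSS", 1000, 3000),
                "H3K9me3": WindowRule("TSS", 1000, 3000),
                "H3K36me3": WindowRule("TTS", 3000, 0),
            }
        else:
            raise ValueError(f"unknown window preset {name!r}")
        return cls(rules)

    def windows(self, genes: pd.DataFrame, mark: str) -> pd.DataFrame:
        """Compute per-gene windows for `mark`, strand-aware, clipped at 0.

        Returns a DataFrame with ``gene_id, chrom, start, end``.
        """
        if mark not in self.rules:
            raise KeyError(f"no window rule for mark {mark!r}")
        rule = self.rules[mark]
        anchor = np.where(
            genes["strand"].values == "+",
            genes["tss"].values if rule.anchor == "TSS" else genes["tts"].values,
            genes["tss"].values if rule.anchor == "TSS" else genes["tts"].values,
        )
        plus = genes["strand"].values == "+"
        start = np.where(plus, anchor - rule.upstream, anchor - rule.downstream)
        end = np.where(plus, anchor + rule.downstream, anchor + rule.upstream)
        return pd.DataFrame(
            {
                "gene_id": genes["gene_id"].values,
                "chrom": genes["chrom"].values,
                "start": np.maximum(start, 0).astype(int),
                "end": end.astype(int),
            }
        )


def write_genes_bed12(model: GenomeModel, path) -> None:
    """Write the gene annotation as BED12 (one row per transcript)."""
    rows = []
    exons_by_tx = {t: e for t, e in model.exons.groupby("transcript_id", sort=False)}
    for _, tx in model.transcripts.iterrows():
        ex = exons_by_tx[tx["transcript_id"]].sort_values("start")
        sizes = (ex["end"] - ex["start"]).astype(int)
        starts = (ex["start"] - tx["start"]).astype(int)
        rows.append(
            (
                tx["chrom"], int(tx["start"]), int(tx["end"]), tx["transcript_id"],
                0, tx["strand"], int(tx["start"]), int(tx["end"]), "0,0,0",
                len(ex),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, starts)) + ",",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def tile_genome(chromosomes: pd.DataFrame, bin_size: int = 2000) -> pd.DataFrame:
    """Tile every chromosome into fixed-size bins (last bin clipped).

    Returns a DataFrame with ``region_id, chrom, start, end``; region ids are
    consecutive integers in genome order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    for _, row in chromosomes.iterrows():
        starts = np.arange(0, row["length"], bin_size)
        ends = np.minimum(starts + bin_size, row["length"])
        frames.append(pd.DataFrame({"chrom": row["chrom"], "start": starts, "end": ends}))
    bins = pd.concat(frames, ignore_index=True)
    bins.insert(0, "region_id", np.arange(len(bins)))
    return bins


def assign_to_bins(
    chroms: np.ndarray, positions: np.ndarray, bins: pd.DataFrame
) -> np.ndarray:
    """Map genomic positions to disjoint bins; -1 where no bin contains the position."""
    out = np.full(len(positions), -1, dtype=int)
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = positions[mask]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        res = np.full(len(pos), -1, dtype=int)
        res[ok] = sub["region_id"].to_numpy()[idx[ok]]
        out[mask] = res
    return out


def overlap_any(
    query: pd.DataFrame, subject: pd.DataFrame, min_overlap: int = 1
) -> np.ndarray:
    """Boolean per query interval: overlaps any subject interval by >= min_overlap bp.

    Both frames need ``chrom, start, end``; subject intervals may overlap
    each other.
    """
    query = query.reset_index(drop=True)
    hit = np.zeros(len(query), dtype=bool)
    subject_by_chrom = {c: s for c, s in subject.groupby("chrom", sort=False)}
    for chrom, q in query.groupby("chrom", sort=False):
        s = subject_by_chrom.get(chrom)
        if s is None:
            continue
        qs = q["start"].to_numpy()[:, None]
        qe = q["end"].to_numpy()[:, None]
        ss = s["start"].to_numpy()[None, :]
        se = s["end"].to_numpy()[None, :]
        ov = np.minimum(qe, se) - np.maximum(qs, ss)
        hit[q.index.to_numpy()] = (ov >= min_overlap).any(axis=1)
    return hit
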