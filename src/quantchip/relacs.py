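"""Barcode demultiplexing, UMI deduplication, counting and global scaling.

Multiplexed quantitative ChIP-seq pools differently barcoded samples into a
single immunoprecipitation; because the samples share one IP, the number of
reads allocated to each sample after demultiplexing carries quantitative
meaning. Genome-wide, input-normalized read-count ratios between conditions
("global scaling factors") therefore measure global shifts of a histone
modification that per-sample depth normalization would silently absorb.

Read prefix layout: 4 bp UMI followed by an 8 bp sample barcode. Duplicates
are collapsed on exact (UMI, chromosome, position, strand); the UMI is too
short for error correction, so no correction is attempted. Reads with
mapping quality <= 5 are discarded (strictly greater than 5 is kept).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import assign_to_bins

DEFAULT_MAPQ_MIN = 5


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RelacsBarcodeScheme:
    """Sample barcode layout: UMI prefix then a fixed-length sample barcode."""

    barcode_to_sample: dict[str, str]
    umi_length: int = 4
    barcode_length: int = 8
    max_mismatch: int = 1

    def __post_init__(self):
        if self.umi_length <= 0 or self.barcode_length <= 0:
            raise ValueError("UMI and barcode lengths must be positive")
        samples = list(self.barcode_to_sample.values())
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate barcodes across samples")
        for bc in self.barcode_to_sample:
            if len(bc) != self.barcode_length:
                raise ValueError(f"barcode {bc!r} has wrong length")
        # unambiguous assignment requires pairwise distance > 2 * max_mismatch
        for a, b in itertools.combinations(self.barcode_to_sample, 2):
            if _hamming(a, b) <= 2 * self.max_mismatch:
                raise ValueError(
                    f"barcodes {a!r} and {b!r} too close for max_mismatch="
                    f"{self.max_mismatch}"
                )

    @property
    def prefix_length(self) -> int:
        return self.umi_length + self.barcode_length

    @classmethod
    def default(cls, sample_ids: list[str], umi_length: int = 4,
                barcode_length: int = 8, max_mismatch: int = 1) -> "RelacsBarcodeScheme":
        """Assign well-separated barcodes to the given samples."""
        if barcode_length != 8:
            raise ValueError("the default barcode set is defined for 8 bp barcodes")
        if len(sample_ids) > 64:
            raise ValueError("too many samples for the default barcode set (max 64)")
        # 8-mers with pairwise Hamming distance >= 4: four doubled symbols
        # (a, b, c, a^b^c) over GF(4); any two codewords differ in >= 2
        # symbols, hence >= 4 nucleotides.
        alphabet = "ACGT"
        mapping = {}
        for i, sid in enumerate(sample_ids):
            a, b, c = (i >> 4) & 3, (i >> 2) & 3, i & 3
            code = (a, b, c, a ^ b ^ c)
            mapping["".join(2 * alphabet[x] for x in code)] = sid
        return cls(mapping, umi_length, barcode_length, max_mismatch)


@dataclass
class SampleCountTable:
    """Per-sample deduplicated, mapq-filtered fragment counts.

    `genome_total` is the genome-wide number of retained fragments;
    `counts` holds per-bin values indexed by ``region_id``.
    """

    sample_id: str
    role: str  # "chip" | "input"
    mark: str
    condition: str
    replicate: int
    genome_total: int
    counts: pd.Series
    units: str = "pairs"

    def __post_init__(self):
        if self.role not in ("chip", "input"):
            raise ValueError(f"role must be chip/input, got {self.role!r}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.genome_total < 0:
            raise ValueError("negative genome total")

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("count").reset_index()
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class GlobalScaleEstimate:
    """All pairwise input-normalized condition ratios for one mark.

    For replicate a of condition A and replicate b of condition B the ratio
    is (chip_b/input_b) / (chip_a/input_a) on genome-wide totals; `mean` is
    the geometric mean over the n_A*n_B comparisons (so that the A->B and
    B->A estimates are exact reciprocals), `sd` the standard deviation of
    the ratios on the linear scale.
    """

    mark: str
    condition_a: str
    condition_b: str
    ratios: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    log2_mean: float = field(init=False)
    log2_sd: float = field(init=False)

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        if (r <= 0).any():
            raise ValueError("ratios must be positive")
        self.ratios = r
        self.log2_mean = float(np.mean(np.log2(r)))
        self.log2_sd = float(np.std(np.log2(r), ddof=1)) if r.size > 1 else 0.0
        self.mean = float(2.0 ** self.log2_mean)
        self.sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0

    @property
    def n_comparisons(self) -> int:
        return int(self.ratios.size)

    def to_dict(self) -> dict:
        return {
            "mark": self.mark,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "ratios": self.ratios.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "log2_mean": self.log2_mean,
            "log2_sd": self.log2_sd,
            "n_comparisons": self.n_comparisons,
        }

    def summary(self) -> str:
        return (
            f"Global scaling factor {self.mark} {self.condition_a} -> "
            f"{self.condition_b}: {self.mean:.3g} (log2 {self.log2_mean:+.3f}), "
            f"sd {self.sd:.3g}, N = {self.n_comparisons} pairwise comparisons"
        )


@dataclass
class EpzRetention:
    """Treatment retention: remaining global signal as percent of control."""

    estimate: GlobalScaleEstimate

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.estimate.mean

    @property
    def sd_pct(self) -> float:
        return 100.0 * self.estimate.sd

    def summary(self) -> str:
        return (
            f"{self.estimate.mark}: {self.retention_pct:.1f}% +/- "
            f"{self.sd_pct:.1f}% of the {self.estimate.condition_a} level "
            f"(N = {self.estimate.n_comparisons})"
        )


# ---------------------------------------------------------------------------
# operations


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxResult:
    assigned: dict[str, pd.DataFrame]  # sample -> (read_id, umi)
    unassigned: pd.DataFrame  # (read_id, reason)

    @property
    def n_assigned(self) -> int:
        return sum(len(df) for df in self.assigned.values())


def demultiplex(reads, scheme: RelacsBarcodeScheme) -> DemuxResult:
    """Partition reads by sample barcode; the UMI travels with each read.

    `reads` is an iterable of (read_id, sequence, quality) triples (e.g.
    from :func:`quantchip.io.read_fastq`). Every read lands either in
    exactly one sample or in the unassigned set with a reason.
    """
    barcodes = list(scheme.barcode_to_sample)
    per_sample: dict[str, list] = {s: [] for s in scheme.barcode_to_sample.values()}
    unassigned = []
    u, b = scheme.umi_length, scheme.barcode_length
    for read_id, seq, _qual in reads:
        if len(seq) < u + b:
            unassigned.append((read_id, "read shorter than UMI+barcode prefix"))
            continue
        umi = seq[:u]
        bc = seq[u : u + b]
        sample = scheme.barcode_to_sample.get(bc)
        if sample is None and scheme.max_mismatch > 0:
            dists = [(_hamming(bc, known), known) for known in barcodes]
            best = min(dists)
            if best[0] <= scheme.max_mismatch:
                sample = scheme.barcode_to_sample[best[1]]
        if sample is None:
            unassigned.append((read_id, "no barcode within mismatch budget"))
        else:
            per_sample[sample].append((read_id, umi))
    assigned = {
        s: pd.DataFrame(rows, columns=["read_id", "umi"])
        for s, rows in per_sample.items()
    }
    return DemuxResult(
        assigned=assigned,
        unassigned=pd.DataFrame(unassigned, columns=["read_id", "reason"]),
    )


def umi_deduplicate(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse reads to one representative per (UMI, chrom, position, strand).

    Returns the surviving reads and the number removed. UMIs are grouped by
    exact match only.
    """
    required = {"umi", "chrom", "pos", "strand"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"reads missing coordinate columns: {sorted(missing)}")
    if reads[["chrom", "pos"]].isna().any().any():
        raise ValueError("reads with missing coordinates cannot be deduplicated")
    dedup = reads.drop_duplicates(subset=["umi", "chrom", "pos", "strand"], keep="first")
    return dedup, len(reads) - len(dedup)


def count_reads(
    reads: pd.DataFrame,
    bins: pd.DataFrame,
    *,
    sample_id: str,
    role: str,
    mark: str,
    condition: str,
    replicate: int = 1,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> SampleCountTable:
    """Count mapq-filtered fragments per bin by fragment midpoint.

    Fragments with mapq <= `mapq_min` are excluded (the filter is strictly
    greater-than). `bins` must be disjoint intervals with ``region_id``.
    """
    if "mapq" in reads.columns:
        reads = reads[reads["mapq"] > mapq_min]
    mid = reads["pos"].to_numpy()
    if "fragment_length" in reads.columns:
        mid = mid + reads["fragment_length"].to_numpy() // 2
    idx = assign_to_bins(reads["chrom"].to_numpy(), mid, bins)
    counted = pd.Series(idx[idx >= 0]).value_counts()
    counts = pd.Series(0, index=pd.Index(bins["region_id"], name="region_id"), dtype=int)
    counts.loc[counted.index] = counted.values
    return SampleCountTable(
        sample_id=sample_id,
        role=role,
        mark=mark,
        condition=condition,
        replicate=replicate,
        genome_total=int(len(reads)),
        counts=counts,
    )


def _totals(samples: list[SampleCountTable]) -> np.ndarray:
    t = np.array([s.genome_total for s in samples], dtype=float)
    if (t <= 0).any():
        raise ValueError("zero genome-wide count; cannot form ratios")
    return t


def global_scale(
    chip_a: list[SampleCountTable],
    input_a: list[SampleCountTable],
    chip_b: list[SampleCountTable],
    input_b: list[SampleCountTable],
) -> GlobalScaleEstimate:
    """Estimate the global scaling factor of condition B relative to A.

    ChIP and input lists are replicate-matched within each condition; all
    cross-condition replicate pairings contribute a ratio (n_A * n_B
    comparisons). No pseudocount: genome-wide totals are large and a zero
    input total is an error.
    """
    if len(chip_a) != len(input_a) or len(chip_b) != len(input_b):
        raise ValueError("each ChIP sample needs a matched input")
    ca, ia = _totals(chip_a), _totals(input_a)
    cb, ib = _totals(chip_b), _totals(input_b)
    enr_a = ca / ia
    enr_b = cb / ib
    ratios = (enr_b[None, :] / enr_a[:, None]).ravel()
    return GlobalScaleEstimate(
        mark=chip_a[0].mark,
        condition_a=chip_a[0].condition,
        condition_b=chip_b[0].condition,
        ratios=ratios,
    )


def epz_retention(
    chip_dmso: list[SampleCountTable],
    input_dmso: list[SampleCountTable],
    chip_epz: list[SampleCountTable],
    input_epz: list[SampleCountTable],
) -> EpzRetention:
    """Global signal retained under treatment, as percent of the control level."""
    return EpzRetention(global_scale(chip_dmso, input_dmso, chip_epz, input_epz))


def _mean_enrichment(
    chips: list[SampleCountTable],
    inputs: list[SampleCountTable],
    count_pseudocount: float,
) -> pd.Series:
    """Replicate-averaged depth-normalized, input-normalized bin enrichment."""
    enr = None
    for chip, inp in zip(chips, inputs):
        c = (chip.counts + count_pseudocount) / chip.genome_total
        i = (inp.counts + count_pseudocount) / inp.genome_total
        e = c / i
        enr = e if enr is None else enr + e
    return enr / len(chips)


def local_log2fc(
    chip_a: list[SampleCountTable],
    input_a: list[SampleCountTable],
    chip_b: list[SampleCountTable],
    input_b: list[SampleCountTable],
    *,
    mode: str = "traditional",
    scale: GlobalScaleEstimate | float | None = None,
    pseudocount: float = 0.0,
    count_pseudocount: float = 1.0,
) -> pd.Series:
    """Per-bin log2 fold change of input-normalized coverage, B vs A.

    ``traditional`` mode normalizes every sample to its own sequencing depth,
    which absorbs any genome-wide shift. ``quantitative`` mode multiplies the
    condition-B enrichment by the global scaling factor before the ratio, so
    genome-wide shifts reappear as a constant offset of log2(scale).
    `count_pseudocount` is added to bin counts to keep empty bins finite;
    `pseudocount` is added to the enrichment ratios themselves.
    """
    if pseudocount < 0 or count_pseudocount < 0:
        raise ValueError("pseudocounts must be non-negative")
    if mode not in ("traditional", "quantitative"):
        raise ValueError(f"unknown mode {mode!r}")
    enr_a = _mean_enrichment(chip_a, input_a, count_pseudocount)
    enr_b = _mean_enrichment(chip_b, input_b, count_pseudocount)
    if mode == "quantitative":
        if scale is None:
            scale = global_scale(chip_a, input_a, chip_b, input_b)
        factor = scale.mean if isinstance(scale, GlobalScaleEstimate) else float(scale)
        enr_b = enr_b * factor
    fc = np.log2((enr_b + pseudocount) / (enr_a + pseudocount))
    fc.name = "log2fc"
    return fc
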