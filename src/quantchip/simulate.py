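"""Synthetic multi-omics data with known ground truth.

Emulates the structure of a barcoded quantitative ChIP-seq study of in vitro
neuronal differentiation: two cell types (mESC, NPC48h) x two treatments
(DMSO control, a DOT1L inhibitor) x two biological replicates, profiled for
seven histone modifications plus input, with matched expression changes,
a chromatin-state segmentation, and ATAC-seq peak counts.

Every generator takes an explicit configuration (:class:`TruthConfig`) whose
defaults encode the study conditions: genome-wide scale factors of 3.9 for
H3K79me2 and 1/2.3 for H3K27ac during differentiation, treatment retention
of 44.9% (mESC) and 64.2% (NPC48h) of the control H3K79me2 level, negative
binomial counts with dispersion 0.05 on 2 kb bins, and expression changes
linearly coupled to mark changes (H3K27ac 0.8, H3K36me3 0.5, H3K79me2 0.4,
interaction 0.3; Gaussian noise sd 0.5). Fixed seed implies byte-identical
outputs; each (sample, stage) draws from its own child RNG stream so partial
regeneration is reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import FeatureWindowSpec, GenomeModel, tile_genome, overlap_any
from .relacs import RelacsBarcodeScheme, SampleCountTable

MARKS = ("H3K4me1", "H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "H3K36me3", "H3K79me2")
REFERENCE = ("mESC", "DMSO")


def _rng(seed: int, *keys) -> np.random.Generator:
    """Child RNG stream keyed by (seed, stage, sample...) strings."""
    entropy = [seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class TruthConfig:
    """Ground-truth parameters of the simulated study."""

    seed: int = 0
    # genome layout
    n_chromosomes: int = 2
    chromosome_length: int = 6_000_000
    n_genes: int = 300
    n_enhancers: int = 100
    tf_bound_fraction: float = 0.5
    bin_size: int = 2000
    # design
    marks: tuple = MARKS
    cell_types: tuple = ("mESC", "NPC48h")
    treatments: tuple = ("DMSO", "EPZ")
    n_replicates: int = 2
    # true global scale factors (dimensionless ratios, reference mESC/DMSO)
    differentiation_scale: dict = field(
        default_factory=lambda: {
            "H3K4me1": 1.0,
            "H3K4me3": 1.0,
            "H3K9me3": 1.2,
            "H3K27ac": 1.0 / 2.3,
            "H3K27me3": 1.0,
            "H3K36me3": 1.2,
            "H3K79me2": 3.9,
        }
    )
    epz_scale: dict = field(
        default_factory=lambda: {
            "mESC": {"H3K79me2": 0.449},
            "NPC48h": {"H3K79me2": 0.642},
        }
    )
    # whether a mark's global change is uniform (genome-wide driven) or
    # confined to its enriched loci (locally driven)
    change_mode: dict = field(
        default_factory=lambda: {m: "uniform" for m in MARKS} | {"H3K36me3": "peak_only"}
    )
    peak_effect_log2: dict = field(default_factory=lambda: {m: 3.0 for m in MARKS})
    marked_gene_fraction: dict = field(default_factory=lambda: {m: 0.6 for m in MARKS})
    # counts
    depth: int = 200_000
    dispersion: float = 0.05
    count_family: str = "nb"  # "nb" (Poisson when dispersion == 0) | "expected"
    # expression coupling
    coupling_beta: dict = field(
        default_factory=lambda: {"H3K27ac": 0.8, "H3K36me3": 0.5, "H3K79me2": 0.4}
    )
    coupling_interaction: float = 0.3
    expression_noise_sd: float = 0.5
    de_signal_threshold: float = 0.5
    # accessibility
    treatment_effect_log2: float = -0.5
    atac_n_background: int = 200
    atac_up_fraction: float = 0.05
    atac_intron_down_fraction: float = 0.15
    marked_fraction_by_class: dict = field(
        default_factory=lambda: {"ATAC-Down": 0.62, "ATAC-Up": 0.25, "background-ATAC": 0.34}
    )
    # segmentation
    n_states: int = 15
    state_fractions: tuple = tuple([1.0 / 15] * 15)
    promoter_state_groups: dict = field(
        default_factory=lambda: {1: -1.0, 2: -0.5, 3: 0.0, 4: 0.5, 5: 1.0}
    )
    group_sd: float = 0.2

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("invalid genome dimensions")
        if self.n_genes < 0 or self.n_enhancers < 0:
            raise ValueError("negative feature counts")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for mark, s in self.differentiation_scale.items():
            if s <= 0:
                raise ValueError(f"scale for {mark} must be positive")
        for cell in self.epz_scale.values():
            if any(s <= 0 for s in cell.values()):
                raise ValueError("treatment scales must be positive")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if len(self.state_fractions) != self.n_states:
            raise ValueError("one fraction per state required")

    def true_scale(self, mark: str, cell_type: str, treatment: str) -> float:
        """Expected genome-total chip scale relative to the reference sample."""
        s = 1.0
        if cell_type != REFERENCE[0]:
            s *= self.differentiation_scale.get(mark, 1.0)
        if treatment != REFERENCE[1]:
            s *= self.epz_scale.get(cell_type, {}).get(mark, 1.0)
        return s

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: TruthConfig) -> GenomeModel:
    """Lay out genes and enhancers deterministically under the config seed.

    Genes occupy evenly spaced slots; each gene gets 1-2 transcripts and 3
    exons; enhancers alternate between intronic (inside a gene's first
    intron) and intergenic (in the gap after a gene slot).
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    chroms = pd.DataFrame(
        {
            "chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
            "length": config.chromosome_length,
        }
    )
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes)) if config.n_genes else 0
    slot = config.chromosome_length // max(per_chrom, 1)
    if config.n_genes and slot < 40_000:
        raise ValueError("chromosomes too short for the requested gene count")
    genes, transcripts, exons = [], [], []
    gi = 0
    for ci in range(config.n_chromosomes):
        for s in range(per_chrom):
            if gi >= config.n_genes:
                break
            slot_start = s * slot
            glen = int(rng.integers(8000, 20001))
            gstart = slot_start + int(rng.integers(8000, max(slot - glen - 8000, 8001)))
            gend = gstart + glen
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi:05d}"
            tss, tts = (gstart, gend) if strand == "+" else (gend, gstart)
            genes.append((gid, f"chr{ci + 1}", gstart, gend, strand, tss, tts))
            n_tx = 2 if rng.random() < 0.3 else 1
            for t in range(n_tx):
                shift = 0 if t == 0 else int(rng.integers(500, 2000))
                txs = gstart + shift if strand == "+" else gstart
                txe = gend if strand == "+" else gend - shift
                tid = f"{gid}.t{t + 1}"
                transcripts.append((gid, tid, f"chr{ci + 1}", strand, txs, txe))
                # three exons per transcript at fixed relative positions
                tlen = txe - txs
                bounds = [0, tlen // 6, tlen // 3, tlen // 2, 2 * tlen // 3, tlen]
                for e in range(3):
                    exons.append((gid, tid, txs + bounds[2 * e], txs + bounds[2 * e + 1]))
            gi += 1
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tts"]
    )
    tx_df = pd.DataFrame(
        transcripts, columns=["gene_id", "transcript_id", "chrom", "strand", "start", "end"]
    )
    ex_df = pd.DataFrame(exons, columns=["gene_id", "transcript_id", "start", "end"])

    enh = []
    for ei in range(config.n_enhancers):
        tf_bound = bool(rng.random() < config.tf_bound_fraction)
        if ei % 2 == 0 and len(genes_df):
            # intronic: inside the first intron of a random gene
            g = genes_df.iloc[int(rng.integers(len(genes_df)))]
            gex = ex_df[ex_df["gene_id"] == g["gene_id"]].sort_values("start")
            lo, hi = int(gex.iloc[0]["end"]), int(gex.iloc[1]["start"])
            if hi - lo > 700:
                start = lo + int(rng.integers(0, hi - lo - 600))
                enh.append((g["chrom"], start, start + 500, "intronic", tf_bound))
                continue
        # intergenic: in the gap after a random gene slot
        ci = int(rng.integers(config.n_chromosomes))
        if len(genes_df):
            sub = genes_df[genes_df["chrom"] == f"chr{ci + 1}"]
            g = sub.iloc[int(rng.integers(len(sub)))]
            start = int(g["end"]) + 2000 + int(rng.integers(0, 3000))
        else:
            start = int(rng.integers(0, config.chromosome_length - 600))
        enh.append((f"chr{ci + 1}", start, start + 500, "intergenic", tf_bound))
    enh_df = pd.DataFrame(enh, columns=["chrom", "start", "end", "enh_class", "tf_bound"])
    # drop intergenic enhancers that accidentally overlap a gene
    if len(enh_df) and len(genes_df):
        inter = enh_df["enh_class"] == "intergenic"
        bad = overlap_any(enh_df, genes_df[["chrom", "start", "end"]]) & inter.to_numpy()
        enh_df = enh_df[~bad].reset_index(drop=True)
    model = GenomeModel(chroms, genes_df, tx_df, ex_df, enh_df)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# ChIP counts


@dataclass
class SimulatedExperiment:
    """All simulated ChIP/input samples plus the ground truth that made them."""

    config: TruthConfig
    genome: GenomeModel
    bins: pd.DataFrame
    samples: list  # SampleCountTable
    expected: dict  # sample_id -> np.ndarray of per-bin expectations
    peak_bins: dict  # mark -> boolean array over bins
    marked_genes: dict  # mark -> list of gene ids

    def get(self, *, mark: str, cell_type: str, treatment: str, role: str = "chip"):
        cond = f"{cell_type}_{treatment}"
        out = [
            s
            for s in self.samples
            if s.condition == cond and s.role == role and (role == "input" or s.mark == mark)
        ]
        return sorted(out, key=lambda s: s.replicate)


def _draw_counts(rng, mu: np.ndarray, config: TruthConfig) -> np.ndarray:
    if config.count_family == "expected":
        return np.rint(mu).astype(int)
    if config.count_family != "nb":
        raise ValueError(f"unknown count family {config.count_family!r}")
    if config.dispersion == 0:
        return rng.poisson(mu)
    n = 1.0 / config.dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_chip_counts(
    genome: GenomeModel,
    config: TruthConfig,
    windows: FeatureWindowSpec | None = None,
) -> SimulatedExperiment:
    """Simulate per-bin ChIP and input counts for the full design.

    Expected chip count per bin = depth x base rate x peak enrichment x true
    global scale (uniform mode) — or with the scale folded into peak bins
    only (peak_only mode), keeping the genome-total ratio at the configured
    truth. Matched inputs are flat and condition-independent.
    """
    config.validate()
    windows = windows or FeatureWindowSpec.preset("quantify")
    bins = tile_genome(genome.chromosomes, config.bin_size)
    nb = len(bins)
    peak_bins, marked_genes = {}, {}
    rng_marks = _rng(config.seed, "marked_genes")
    for mark in config.marks:
        n_marked = int(round(config.marked_gene_fraction.get(mark, 0.6) * len(genome.genes)))
        chosen = rng_marks.choice(len(genome.genes), size=n_marked, replace=False)
        gsub = genome.genes.iloc[np.sort(chosen)]
        marked_genes[mark] = gsub["gene_id"].tolist()
        win = windows.windows(gsub, mark)
        peak_bins[mark] = overlap_any(bins, win, min_overlap=config.bin_size // 2)

    samples, expected = [], {}
    for cell in config.cell_types:
        for treat in config.treatments:
            cond = f"{cell}_{treat}"
            for rep in range(1, config.n_replicates + 1):
                # matched input: flat, condition-independent expectation
                sid = f"input_{cond}_rep{rep}"
                mu_in = np.full(nb, config.depth / nb)
                cnt = _draw_counts(_rng(config.seed, "counts", sid), mu_in, config)
                samples.append(
                    SampleCountTable(
                        sample_id=sid,
                        role="input",
                        mark="input",
                        condition=cond,
                        replicate=rep,
                        genome_total=int(cnt.sum()),
                        counts=pd.Series(cnt, index=bins["region_id"].values),
                    )
                )
                expected[sid] = mu_in
                for mark in config.marks:
                    base = np.ones(nb)
                    base[peak_bins[mark]] = 2.0 ** config.peak_effect_log2.get(mark, 3.0)
                    total0 = base.sum()
                    s = config.true_scale(mark, cell, treat)
                    rate = base.copy()
                    if config.change_mode.get(mark, "uniform") == "uniform" or s == 1.0:
                        rate *= s
                    else:
                        pk = peak_bins[mark]
                        peak_total = base[pk].sum()
                        f = 1.0 + (s - 1.0) * total0 / peak_total
                        if f <= 0:
                            raise ValueError(
                                f"peak_only scale {s} for {mark} not attainable"
                            )
                        rate[pk] *= f
                    mu = config.depth * rate / total0
                    sid = f"{mark}_{cond}_rep{rep}"
                    cnt = _draw_counts(_rng(config.seed, "counts", sid), mu, config)
                    samples.append(
                        SampleCountTable(
                            sample_id=sid,
                            role="chip",
                            mark=mark,
                            condition=cond,
                            replicate=rep,
                            genome_total=int(cnt.sum()),
                            counts=pd.Series(cnt, index=bins["region_id"].values),
                        )
                    )
                    expected[sid] = mu
    return SimulatedExperiment(
        config=config,
        genome=genome,
        bins=bins,
        samples=samples,
        expected=expected,
        peak_bins=peak_bins,
        marked_genes=marked_genes,
    )


# ---------------------------------------------------------------------------
# barcoded reads


@dataclass
class EmittedReads:
    fastq: object  # path
    alignments: object  # path to tagged-alignment TSV
    truth: pd.DataFrame  # read_id, sample_id, umi, is_duplicate
    scheme: RelacsBarcodeScheme


def emit_barcoded_reads(
    samples: list[SampleCountTable],
    bins: pd.DataFrame,
    scheme: RelacsBarcodeScheme,
    fastq_path,
    tsv_path,
    *,
    dup_rate: float = 0.0,
    fragment_length: int = 200,
    insert_length: int = 24,
    seed: int = 0,
) -> EmittedReads:
    """Emit pooled barcoded reads for the given sample count tables.

    Each read is 4 bp UMI + 8 bp sample barcode + insert. Unique reads
    reproduce the per-bin counts exactly (distinct positions within a bin);
    a fraction `dup_rate` of the emitted reads are UMI+position duplicates
    of unique reads. The TSV mirrors the FASTQ record-for-record with
    mapping coordinates and mapq.
    """
    from . import io as qio

    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    alphabet = np.array(list("ACGT"))
    sample_to_barcode = {v: k for k, v in scheme.barcode_to_sample.items()}
    records = []  # (read_id, seq, qual)
    rows = []  # alignment TSV rows
    truth = []
    bins_idx = bins.set_index("region_id")
    for table in samples:
        if table.sample_id not in sample_to_barcode:
            raise ValueError(f"sample {table.sample_id} missing from barcode scheme")
        rng = _rng(seed, "reads", table.sample_id)
        barcode = sample_to_barcode[table.sample_id]
        chrom_parts, pos_parts = [], []
        nonzero = table.counts[table.counts > 0]
        for region_id, c in nonzero.items():
            b = bins_idx.loc[region_id]
            span = int(b["end"] - b["start"])
            lo = fragment_length // 2 if b["start"] == 0 else 0
            avail = span - lo
            replace = c > avail
            offs = rng.choice(avail, size=int(c), replace=bool(replace)) + lo
            # fragment midpoints stay inside the bin, so counting by midpoint
            # reproduces the table exactly
            pos_parts.append(int(b["start"]) + offs - fragment_length // 2)
            chrom_parts.extend([b["chrom"]] * int(c))
        n_unique = len(chrom_parts)
        positions = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=int)
        strands = np.where(rng.random(n_unique) < 0.5, "+", "-")
        umi_mat = alphabet[rng.integers(0, 4, size=(n_unique, scheme.umi_length))]
        umis = ["".join(row) for row in umi_mat]
        uniques = list(zip(chrom_parts, positions.tolist(), strands.tolist(), umis))
        n_dup = int(round(n_unique * dup_rate / (1.0 - dup_rate))) if dup_rate else 0
        dup_sources = rng.integers(0, n_unique, size=n_dup) if n_dup else []
        emit = [(u, False) for u in uniques] + [(uniques[i], True) for i in dup_sources]
        ins_mat = alphabet[rng.integers(0, 4, size=(len(emit), insert_length))]
        qual = "I" * (scheme.umi_length + scheme.barcode_length + insert_length)
        for i, ((chrom, pos, strand, umi), is_dup) in enumerate(emit):
            read_id = f"{table.sample_id}:{i:07d}"
            seq = umi + barcode + "".join(ins_mat[i])
            records.append((read_id, seq, qual))
            rows.append((read_id, chrom, pos, strand, 30, fragment_length))
            truth.append((read_id, table.sample_id, umi, is_dup))
    # deterministic pooling order: shuffle with the master stream
    order = _rng(seed, "reads", "pool").permutation(len(records))
    records = [records[i] for i in order]
    rows = [rows[i] for i in order]
    qio.write_fastq(records, fastq_path)
    aln = pd.DataFrame(rows, columns=qio.ALIGNMENT_COLS)
    qio.write_tsv(aln, tsv_path)
    truth_df = pd.DataFrame(truth, columns=["read_id", "sample_id", "umi", "is_duplicate"])
    return EmittedReads(fastq=fastq_path, alignments=tsv_path, truth=truth_df, scheme=scheme)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genome: GenomeModel,
    config: TruthConfig,
    delta_ptm: pd.DataFrame,
    *,
    stage: str = "expression",
) -> pd.DataFrame:
    """Expression log2FC linearly coupled to mark changes.

    log2FC = sum_m beta_m * Delta_m + beta_int * Delta_H3K79me2 *
    Delta_H3K27ac + N(0, noise_sd). Adjusted p-values: genes whose
    deterministic signal exceeds `de_signal_threshold` in absolute value
    draw from U(0, 0.01); the rest draw from the U(0, 1) null, so a small
    nominal fraction of uncoupled genes crosses any DEG cutoff by chance.
    """
    missing = [m for m in config.coupling_beta if m not in delta_ptm.columns]
    if missing:
        raise ValueError(f"delta_ptm missing mark columns: {missing}")
    for m in ("H3K79me2", "H3K27ac"):
        if m not in delta_ptm.columns:
            raise ValueError(f"delta_ptm missing mark columns: ['{m}']")
    rng = _rng(config.seed, stage)
    signal = np.zeros(len(delta_ptm))
    for mark, beta in config.coupling_beta.items():
        signal = signal + beta * delta_ptm[mark].to_numpy()
    signal = signal + config.coupling_interaction * (
        delta_ptm["H3K79me2"].to_numpy() * delta_ptm["H3K27ac"].to_numpy()
    )
    noise = (
        rng.normal(0.0, config.expression_noise_sd, size=len(delta_ptm))
        if config.expression_noise_sd > 0
        else 0.0
    )
    log2fc = signal + noise
    coupled = np.abs(signal) > config.de_signal_threshold
    padj = np.where(
        coupled,
        rng.uniform(0.0, 0.01, size=len(delta_ptm)),
        rng.uniform(0.0, 1.0, size=len(delta_ptm)),
    )
    return pd.DataFrame(
        {
            "gene_id": delta_ptm.index
            if delta_ptm.index.name == "gene_id"
            else delta_ptm.get("gene_id", delta_ptm.index),
            "log2fc": log2fc,
            "padj": padj,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmentation


def simulate_segmentation(
    genome: GenomeModel, config: TruthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Chromatin-state segmentation tiling the genome, plus H3K4me3 peaks.

    Each gene's promoter window (TSS-1000, +500, strand-aware) is forced to
    the gene's assigned promoter state (drawn uniformly from the configured
    promoter-state groups); everything else is tiled with random segments
    drawn from the state priors. Returns (segmentation, h3k4me3 peak BED,
    per-gene promoter-state assignment).
    """
    config.validate()
    rng = _rng(config.seed, "segmentation")
    group_states = sorted(config.promoter_state_groups)
    genes = genome.genes
    gene_state = pd.Series(
        rng.choice(group_states, size=len(genes)), index=genes["gene_id"].values
    )
    plus = genes["strand"].values == "+"
    p_start = np.where(plus, genes["tss"].values - 1000, genes["tss"].values - 500)
    p_end = np.where(plus, genes["tss"].values + 500, genes["tss"].values + 1000)
    forced = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": np.maximum(p_start, 0),
            "end": p_end,
            "state": gene_state.values,
        }
    )
    states = np.arange(1, config.n_states + 1)
    segments = []
    for _, row in genome.chromosomes.iterrows():
        sub = forced[forced["chrom"] == row["chrom"]].sort_values("start")
        pos = 0
        intervals = list(zip(sub["start"], sub["end"], sub["state"])) + [
            (row["length"], row["length"], 0)
        ]
        for fs, fe, st in intervals:
            while pos < fs:
                seg_len = min(int(rng.integers(1000, 5001)), fs - pos)
                s = int(rng.choice(states, p=config.state_fractions))
                segments.append((row["chrom"], pos, pos + seg_len, s))
                pos += seg_len
            if fe > fs:
                segments.append((row["chrom"], max(pos, fs), fe, int(st)))
                pos = fe
    seg = pd.DataFrame(segments, columns=["chrom", "start", "end", "state"])
    seg = seg[seg["end"] > seg["start"]].reset_index(drop=True)
    # H3K4me3 peaks at most promoters (the rest fall back to full gene span)
    has_peak = rng.random(len(genes)) < 0.8
    peaks = pd.DataFrame(
        {
            "chrom": genes["chrom"].values[has_peak],
            "start": np.maximum(genes["tss"].values[has_peak] - 300, 0),
            "end": genes["tss"].values[has_peak] + 300,
        }
    )
    return seg, peaks, gene_state


def simulate_state_expression(
    gene_state: pd.Series, config: TruthConfig, *, stage: str = "state_expression"
) -> pd.DataFrame:
    """Per-gene expression log2FC ~ N(group mean, group_sd) by promoter state."""
    rng = _rng(config.seed, stage)
    means = gene_state.map(config.promoter_state_groups).to_numpy(dtype=float)
    fc = rng.normal(means, config.group_sd)
    return pd.DataFrame({"gene_id": gene_state.index, "log2fc": fc})


# ---------------------------------------------------------------------------
# accessibility


def simulate_atac_counts(
    genome: GenomeModel, config: TruthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ATAC peaks with per-sample counts and known direction classes.

    Peaks sit on every enhancer, in the first intron of every gene, and at
    random intergenic background positions. TF-bound enhancer peaks and a
    matching set of intronic peaks lose accessibility under treatment by
    `treatment_effect_log2`; a small fraction gains the same amount. Returns
    (peaks, counts wide table, truth with per-peak true log2FC and class).
    """
    config.validate()
    rng = _rng(config.seed, "atac")
    peaks = []
    for _, e in genome.enhancers.iterrows():
        peaks.append((e["chrom"], e["start"] - 100, e["end"] + 100, "enhancer", e["tf_bound"], None))
    gene_chrom = genome.genes.set_index("gene_id")["chrom"]
    for gid, gex in genome.exons.groupby("gene_id", sort=False):
        first_tx = gex["transcript_id"].iloc[0]
        gex = gex[gex["transcript_id"] == first_tx].sort_values("start")
        lo, hi = int(gex.iloc[0]["end"]), int(gex.iloc[1]["start"])
        if hi - lo > 900:
            start = (lo + hi) // 2 - 200
            peaks.append((gene_chrom.loc[gid], start, start + 400, "intronic", False, gid))
    for _ in range(config.atac_n_background):
        ci = int(rng.integers(config.n_chromosomes))
        start = int(rng.integers(0, config.chromosome_length - 500))
        peaks.append((f"chr{ci + 1}", start, start + 400, "background", False, None))
    df = pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "placement", "tf_bound", "gene_id_hint"]
    )
    df["start"] = df["start"].clip(lower=0)
    df.insert(0, "peak_id", [f"peak{i:05d}" for i in range(len(df))])

    # true treatment effect per peak
    effect = np.zeros(len(df))
    responsive_down = df["tf_bound"].to_numpy().copy()
    intronic = (df["placement"] == "intronic").to_numpy()
    # a minority of intronic peaks also responds (loses accessibility);
    # most open chromatin stays unaffected, as in a sparse perturbation
    intron_idx = np.flatnonzero(intronic)
    n_down = int(round(config.atac_intron_down_fraction * len(intron_idx)))
    down_introns = rng.choice(intron_idx, size=n_down, replace=False)
    responsive_down[down_introns] = True
    effect[responsive_down] = config.treatment_effect_log2
    up_candidates = np.flatnonzero(~responsive_down)
    n_up = int(round(config.atac_up_fraction * len(df)))
    up_idx = rng.choice(up_candidates, size=min(n_up, len(up_candidates)), replace=False)
    effect[up_idx] = -config.treatment_effect_log2
    truth_class = np.where(
        effect < 0, "ATAC-Down", np.where(effect > 0, "ATAC-Up", "background-ATAC")
    )

    base = rng.uniform(50, 200, size=len(df))
    counts = {}
    for treat in config.treatments:
        mult = 2.0 ** effect if treat != "DMSO" else np.ones(len(df))
        for rep in range(1, config.n_replicates + 1):
            mu = base * mult * rng.uniform(0.9, 1.1)
            counts[f"ATAC_{treat}_rep{rep}"] = _draw_counts(
                _rng(config.seed, "atac_counts", treat, rep), mu, config
            )
    counts_df = pd.DataFrame(counts, index=df["peak_id"])
    truth = pd.DataFrame(
        {
            "peak_id": df["peak_id"],
            "true_log2fc": effect,
            "true_class": truth_class,
            "placement": df["placement"],
            "gene_id": df.get("gene_id_hint"),
        }
    )
    return df.drop(columns=["placement", "tf_bound", "gene_id_hint"]), counts_df, truth


def simulate_marked_flags(
    atac_truth: pd.DataFrame, config: TruthConfig
) -> pd.Series:
    """Per-gene H3K79me2-marked flags conditional on intronic-peak class.

    Genes whose intronic ATAC peak lost accessibility are marked with the
    configured ATAC-Down probability, and likewise for gaining and
    unchanged peaks — the co-occurrence structure the class-wise marking
    fractions are estimated from.
    """
    rng = _rng(config.seed, "marked_flags")
    sub = atac_truth[(atac_truth["placement"] == "intronic") & atac_truth["gene_id"].notna()]
    # precedence when a gene has several intronic peaks: Down > Up > background
    rank = {"ATAC-Down": 0, "ATAC-Up": 1, "background-ATAC": 2}
    cls = (
        sub.assign(rank=sub["true_class"].map(rank))
        .sort_values("rank")
        .drop_duplicates("gene_id")
        .set_index("gene_id")["true_class"]
    )
    p = cls.map(config.marked_fraction_by_class).to_numpy(dtype=float)
    return pd.Series(rng.random(len(cls)) < p, index=cls.index, name="marked")
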