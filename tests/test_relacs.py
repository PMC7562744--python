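"""Demultiplexing, deduplication, counting and global-scale estimation."""

import numpy as np
import pandas as pd
import pytest

from quantchip.genome import tile_genome
from quantchip.relacs import (
    RelacsBarcodeScheme,
    count_reads,
    demultiplex,
    epz_retention,
    global_scale,
    local_log2fc,
    umi_deduplicate,
)

from conftest import make_table


@pytest.fixture
def scheme():
    return RelacsBarcodeScheme.default(["s1", "s2"])


class TestBarcodeScheme:
    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RelacsBarcodeScheme({"AAAAAAAA": "s1", "CCCCCCCC": "s1"})

    def test_too_close_barcodes_rejected(self):
        with pytest.raises(ValueError, match="too close"):
            RelacsBarcodeScheme({"AAAAAAAA": "s1", "AAAAAAAC": "s2"}, max_mismatch=1)

    def test_default_set_is_well_separated(self):
        from quantchip.relacs import _hamming

        sch = RelacsBarcodeScheme.default([f"s{i}" for i in range(64)])
        bcs = list(sch.barcode_to_sample)
        dmin = min(_hamming(a, b) for i, a in enumerate(bcs) for b in bcs[i + 1 :])
        assert dmin >= 4


class TestDemultiplex:
    def test_exact_and_one_mismatch_assigned(self, scheme):
        bc = next(iter(scheme.barcode_to_sample))
        sample = scheme.barcode_to_sample[bc]
        mutated = ("T" if bc[0] != "T" else "G") + bc[1:]
        reads = [
            ("r0", "ACGT" + bc + "AAAA", "I" * 16),
            ("r1", "ACGT" + mutated + "AAAA", "I" * 16),
        ]
        res = demultiplex(reads, scheme)
        assert list(res.assigned[sample]["read_id"]) == ["r0", "r1"]
        assert res.assigned[sample]["umi"].tolist() == ["ACGT", "ACGT"]

    def test_distant_barcode_unassigned(self, scheme):
        bc = next(iter(scheme.barcode_to_sample))
        far = "".join("T" if c == "A" else "A" for c in bc)  # flip >= 3 positions
        res = demultiplex([("r0", "ACGT" + far + "AAAA", "I" * 16)], scheme)
        assert res.n_assigned == 0
        assert res.unassigned["reason"].iloc[0] == "no barcode within mismatch budget"

    def test_short_read_unassigned_with_reason(self, scheme):
        res = demultiplex([("r0", "ACGTAC", "IIIIII")], scheme)
        assert "shorter" in res.unassigned["reason"].iloc[0]

    def test_partition_is_exhaustive(self, scheme):
        bc = list(scheme.barcode_to_sample)
        reads = [(f"r{i}", "AAAA" + bc[i % 2] + "AAAA", "I" * 16) for i in range(10)]
        reads.append(("short", "AA", "II"))
        res = demultiplex(reads, scheme)
        assert res.n_assigned + len(res.unassigned) == len(reads)


class TestUmiDeduplicate:
    def test_same_umi_position_collapses(self):
        df = pd.DataFrame(
            {"umi": ["ACGT", "ACGT"], "chrom": ["chr1"] * 2, "pos": [100, 100],
             "strand": ["+", "+"]}
        )
        dedup, removed = umi_deduplicate(df)
        assert len(dedup) == 1 and removed == 1

    def test_different_umis_survive(self):
        df = pd.DataFrame(
            {"umi": ["ACGT", "TTTT"], "chrom": ["chr1"] * 2, "pos": [100, 100],
             "strand": ["+", "+"]}
        )
        dedup, removed = umi_deduplicate(df)
        assert len(dedup) == 2 and removed == 0

    def test_missing_coordinates_error(self):
        with pytest.raises(ValueError, match="coordinate"):
            umi_deduplicate(pd.DataFrame({"umi": ["ACGT"], "pos": [1], "strand": ["+"]}))


class TestCountReads:
    def _bins(self):
        return tile_genome(pd.DataFrame({"chrom": ["chr1"], "length": [20_000]}), 2000)

    def test_mapq_equal_to_cutoff_excluded(self):
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [100, 300, 500], "strand": ["+"] * 3,
             "mapq": [5, 6, 30], "umi": ["A"] * 3, "fragment_length": [200] * 3}
        )
        tab = count_reads(reads, self._bins(), sample_id="s", role="chip",
                          mark="m", condition="c")
        assert tab.genome_total == 2  # mapq 5 dropped, strictly greater kept

    def test_empty_bin_counts_zero(self):
        reads = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "strand": ["+"], "mapq": [30],
             "fragment_length": [200]}
        )
        tab = count_reads(reads, self._bins(), sample_id="s", role="chip",
                          mark="m", condition="c")
        assert tab.counts.iloc[-1] == 0 and tab.counts.sum() == 1

    def test_uniform_reads_spread_multinomially(self):
        rng = np.random.default_rng(0)
        n = 1000
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * n, "pos": rng.integers(0, 19_800, n),
             "strand": ["+"] * n, "mapq": [30] * n, "fragment_length": [200] * n}
        )
        tab = count_reads(reads, self._bins(), sample_id="s", role="chip",
                          mark="m", condition="c")
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert (np.abs(tab.counts.values - 100) < 3 * sigma).all()


class TestGlobalScale:
    def test_forced_arithmetic(self):
        est = global_scale(
            [make_table([0], total=1_000_000)], [make_table([0], total=2_000_000, role="input")],
            [make_table([0], total=4_000_000, condition="B")],
            [make_table([0], total=2_000_000, role="input", condition="B")],
        )
        assert est.mean == pytest.approx(4.0)
        assert est.n_comparisons == 1

    def test_identical_samples_unit_ratio_zero_sd(self):
        chip = [make_table([0], total=500), make_table([0], total=500, replicate=2)]
        inp = [make_table([0], total=400, role="input"),
               make_table([0], total=400, role="input", replicate=2)]
        est = global_scale(chip, inp, chip, inp)
        assert est.mean == pytest.approx(1.0)
        assert est.sd == pytest.approx(0.0)
        assert est.n_comparisons == 4

    def test_zero_input_raises(self):
        with pytest.raises(ValueError, match="zero genome-wide"):
            global_scale(
                [make_table([0], total=10)], [make_table([0], total=0, role="input")],
                [make_table([0], total=10)], [make_table([0], total=5, role="input")],
            )

    def test_forward_backward_product_is_one(self, small_experiment):
        kw = dict(mark="H3K79me2")
        ca = small_experiment.get(cell_type="mESC", treatment="DMSO", **kw)
        ia = small_experiment.get(cell_type="mESC", treatment="DMSO", role="input", **kw)
        cb = small_experiment.get(cell_type="NPC48h", treatment="DMSO", **kw)
        ib = small_experiment.get(cell_type="NPC48h", treatment="DMSO", role="input", **kw)
        fwd = global_scale(ca, ia, cb, ib)
        bwd = global_scale(cb, ib, ca, ia)
        assert fwd.mean * bwd.mean == pytest.approx(1.0, rel=1e-12)

    def test_invariant_under_subsampling(self, small_experiment):
        # thinning every sample to ~50% leaves the expectation unchanged
        rng = np.random.default_rng(42)

        def thin(tables):
            out = []
            for t in tables:
                c = rng.binomial(t.counts.values, 0.5)
                out.append(make_table(c, role=t.role, condition=t.condition))
            return out

        kw = dict(mark="H3K79me2")
        ca = small_experiment.get(cell_type="mESC", treatment="DMSO", **kw)
        ia = small_experiment.get(cell_type="mESC", treatment="DMSO", role="input", **kw)
        cb = small_experiment.get(cell_type="NPC48h", treatment="DMSO", **kw)
        ib = small_experiment.get(cell_type="NPC48h", treatment="DMSO", role="input", **kw)
        full = global_scale(ca, ia, cb, ib)
        sub = global_scale(thin(ca), thin(ia), thin(cb), thin(ib))
        # 3 sigma on a ratio of four ~40k-count totals is well under 5%
        assert sub.mean == pytest.approx(full.mean, rel=0.05)

    def test_retention_of_identical_conditions_is_100pct(self):
        chip = [make_table([0], total=1000)]
        inp = [make_table([0], total=800, role="input")]
        ret = epz_retention(chip, inp, chip, inp)
        assert ret.retention_pct == pytest.approx(100.0)

    def test_retention_half_signal(self):
        ret = epz_retention(
            [make_table([0], total=1000)], [make_table([0], total=800, role="input")],
            [make_table([0], total=500, condition="EPZ")],
            [make_table([0], total=800, role="input", condition="EPZ")],
        )
        assert ret.retention_pct == pytest.approx(50.0)


class TestLocalLog2FC:
    def _cond(self, chip_counts, input_counts, condition):
        chip = make_table(chip_counts, condition=condition)
        inp = make_table(input_counts, role="input", condition=condition)
        return [chip], [inp]

    def test_traditional_mode_absorbs_uniform_scaling(self):
        a = np.array([100, 200, 300, 400])
        ca, ia = self._cond(a, np.full(4, 250), "A")
        cb, ib = self._cond(a * 4, np.full(4, 250), "B")
        fc = local_log2fc(ca, ia, cb, ib, mode="traditional", count_pseudocount=0)
        np.testing.assert_allclose(fc.values, 0.0, atol=1e-12)

    def test_quantitative_mode_restores_global_shift(self):
        a = np.array([100, 200, 300, 400])
        ca, ia = self._cond(a, np.full(4, 250), "A")
        cb, ib = self._cond(a * 4, np.full(4, 250), "B")
        fc = local_log2fc(ca, ia, cb, ib, mode="quantitative", scale=4.0,
                          count_pseudocount=0)
        np.testing.assert_allclose(fc.values, 2.0, atol=1e-12)

    def test_modes_differ_by_constant_log2_scale(self, small_experiment):
        kw = dict(mark="H3K79me2")
        ca = small_experiment.get(cell_type="mESC", treatment="DMSO", **kw)
        ia = small_experiment.get(cell_type="mESC", treatment="DMSO", role="input", **kw)
        cb = small_experiment.get(cell_type="NPC48h", treatment="DMSO", **kw)
        ib = small_experiment.get(cell_type="NPC48h", treatment="DMSO", role="input", **kw)
        est = global_scale(ca, ia, cb, ib)
        trad = local_log2fc(ca, ia, cb, ib, mode="traditional", pseudocount=0)
        quant = local_log2fc(ca, ia, cb, ib, mode="quantitative", scale=est,
                             pseudocount=0)
        np.testing.assert_allclose(
            (quant - trad).values, np.log2(est.mean), atol=1e-9
        )

    def test_negative_pseudocount_rejected(self):
        ca, ia = self._cond([1], [1], "A")
        with pytest.raises(ValueError):
            local_log2fc(ca, ia, ca, ia, mode="traditional", pseudocount=-1)


class TestDemuxRoundTrip:
    def test_pipeline_reproduces_truth_counts_exactly(self, tiny_experiment, tmp_path):
        """Emit -> demux -> dedup -> count must reproduce the truth table."""
        import quantchip.io as qio
        from quantchip import emit_barcoded_reads

        pool = [
            s for s in tiny_experiment.samples
            if s.condition == "NPC48h_DMSO" and s.replicate == 2
        ]
        scheme = RelacsBarcodeScheme.default([s.sample_id for s in pool])
        em = emit_barcoded_reads(
            pool, tiny_experiment.bins, scheme,
            tmp_path / "r.fastq", tmp_path / "a.tsv", dup_rate=0.3, seed=5,
        )
        res = demultiplex(qio.read_fastq(em.fastq), scheme)
        aln = qio.read_tsv(em.alignments)
        assert len(res.unassigned) == 0
        for s in pool:
            df = res.assigned[s.sample_id].merge(aln, on="read_id")
            dedup, _ = umi_deduplicate(df)
            tab = count_reads(
                dedup, tiny_experiment.bins, sample_id=s.sample_id, role=s.role,
                mark=s.mark, condition=s.condition, replicate=s.replicate,
            )
            assert (tab.counts.values == s.counts.values).all()
            assert tab.genome_total == s.genome_total
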