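"""Accessibility selection, peak annotation and the statistics oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from quantchip.atac import (
    BACKGROUND,
    DOWN,
    UP,
    annotate_peaks,
    enhancer_fc_summary,
    mark_fraction_by_class,
    mwu_compare,
    paired_onesided_ttest,
    pc_loading_select,
)


def _counts(n_peaks=30, seed=0, responsive=None, effect=-1.5):
    """Peak x sample counts with a condition-linked effect on some peaks."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(100, 300, n_peaks)
    cols = {}
    for cond in ("DMSO", "EPZ"):
        mult = np.ones(n_peaks)
        if cond == "EPZ" and responsive is not None:
            mult[responsive] = 2.0 ** effect
        for rep in (1, 2):
            cols[f"{cond}_{rep}"] = rng.poisson(base * mult)
    counts = pd.DataFrame(cols, index=[f"p{i}" for i in range(n_peaks)])
    cond_of = {c: c.split("_")[0] for c in counts.columns}
    return counts, cond_of


class TestPcLoadingSelect:
    def test_condition_linked_peak_ranked_first(self):
        counts, cond_of = _counts(responsive=[4], effect=-3.0)
        sel = pc_loading_select(counts, cond_of, n=1)
        assert list(sel.selected) == ["p4"]
        assert sel.direction["p4"] == DOWN

    def test_direction_partitions_selection(self):
        responsive = list(range(10))
        counts, cond_of = _counts(responsive=responsive)
        sel = pc_loading_select(counts, cond_of, n=10)
        assert set(sel.direction.unique()) <= {DOWN, UP}
        assert len(sel.selected) == 10
        assert len(sel.background) == 20

    def test_degenerate_matrix_raises(self):
        counts = pd.DataFrame(
            {c: [100] * 5 for c in ["DMSO_1", "DMSO_2", "EPZ_1", "EPZ_2"]},
            index=[f"p{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="degenerate"):
            pc_loading_select(counts, {c: c.split("_")[0] for c in counts.columns}, n=2)

    def test_selecting_more_than_available_raises(self):
        counts, cond_of = _counts()
        with pytest.raises(ValueError, match="more peaks"):
            pc_loading_select(counts, cond_of, n=1000)

    def test_invariant_to_depth_rescaling(self):
        counts, cond_of = _counts(responsive=[2, 3])
        sel1 = pc_loading_select(counts, cond_of, n=5)
        scaled = counts.copy()
        scaled["DMSO_1"] = scaled["DMSO_1"] * 4  # depth x4 absorbed by CPM
        sel2 = pc_loading_select(scaled, cond_of, n=5)
        assert set(sel1.selected) == set(sel2.selected)


class TestAnnotatePeaks:
    @pytest.fixture(scope="class")
    def annotated(self, small_genome):
        g = small_genome.genes.iloc[0]
        plus = g["strand"] == "+"
        tss, tts = g["tss"], g["tts"]
        gex = small_genome.exons[
            small_genome.exons["gene_id"] == g["gene_id"]
        ].sort_values("start")
        exon1, exon2 = gex.iloc[0], gex.iloc[1]
        intron_pos = exon1["end"] + 50
        # the middle exon is far from both TSS and TTS windows
        peaks = pd.DataFrame(
            {
                "peak_id": ["at_tss", "at_tts", "in_exon", "in_intron", "nowhere"],
                "chrom": [g["chrom"]] * 5,
                "start": [tss - 50, tts - 50, exon2["start"] + 10, intron_pos, 5],
                "end": [tss + 50, tts + 50, exon2["start"] + 60, intron_pos + 50, 100],
            }
        )
        return peaks, annotate_peaks(peaks, small_genome, small_genome.enhancers)

    def test_each_peak_gets_exactly_one_annotation(self, annotated):
        _, ann = annotated
        assert ann["annotation"].notna().all()
        assert set(ann["annotation"]) <= {"promoter-TSS", "TTS", "exon", "intron", "intergenic"}

    def test_promoter_precedence_over_exon(self, annotated):
        _, ann = annotated
        row = ann.set_index("peak_id").loc["at_tss"]
        assert row["annotation"] == "promoter-TSS"

    def test_categories_match_construction(self, annotated):
        _, ann = annotated
        a = ann.set_index("peak_id")["annotation"]
        assert a["at_tts"] == "TTS"
        assert a["in_exon"] == "exon"
        assert a["in_intron"] == "intron"
        assert a["nowhere"] == "intergenic"

    def test_intergenic_enhancer_peak(self, small_genome):
        enh = small_genome.enhancers
        e = enh[enh["enh_class"] == "intergenic"].iloc[0]
        peaks = pd.DataFrame(
            {"peak_id": ["pe"], "chrom": [e["chrom"]],
             "start": [e["start"]], "end": [e["end"]]}
        )
        ann = annotate_peaks(peaks, small_genome, enh)
        assert ann["enhancer"].iloc[0]
        assert ann["enhancer_class"].iloc[0] == "intergenic"


class TestEnhancerFcSummary:
    def _selection(self, peak_ids, directions, background, fc):
        from quantchip.atac import LoadingSelection

        return LoadingSelection(
            component=1,
            loadings=pd.Series(1.0, index=peak_ids + background),
            selected=pd.Index(peak_ids),
            direction=pd.Series(directions, index=peak_ids),
            background=pd.Index(background),
            mean_log2fc=fc,
            explained_variance_ratio=0.9,
        )

    def test_seeded_loss_appears_in_both_classes(self, small_genome):
        enh = small_genome.enhancers
        peaks = enh.copy().reset_index(drop=True)
        peaks.insert(0, "peak_id", [f"e{i}" for i in range(len(peaks))])
        annotated = annotate_peaks(
            peaks[["peak_id", "chrom", "start", "end"]], small_genome, enh
        )
        fc = pd.Series(-0.5, index=peaks["peak_id"])
        sel = self._selection(
            list(peaks["peak_id"]), [DOWN] * len(peaks), [], fc
        )
        out = enhancer_fc_summary(sel, annotated, fc)
        for cls in ("intronic", "intergenic"):
            assert out["classes"][cls]["median"] < 0

    def test_no_enhancer_peaks_flagged(self, small_genome):
        peaks = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [10], "end": [60]}
        )
        annotated = annotate_peaks(peaks, small_genome, None)
        sel = self._selection(["p0"], [DOWN], [], pd.Series(0.0, index=["p0"]))
        out = enhancer_fc_summary(sel, annotated)
        assert set(out["empty_classes"]) == {"intronic", "intergenic"}


class TestMarkFractionByClass:
    def _inputs(self, small_genome, marked_value):
        genes = small_genome.genes
        n = min(30, len(genes))
        exon_first = small_genome.exons.groupby("gene_id").first()
        rows = []
        for i, (gid, ex) in enumerate(exon_first.iterrows()):
            if i >= n:
                break
            chrom = genes.set_index("gene_id").loc[gid, "chrom"]
            rows.append((f"p{i}", chrom, ex["end"] + 10, ex["end"] + 110))
        peaks = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
        annotated = annotate_peaks(peaks, small_genome, None)
        intron_peaks = annotated[annotated["annotation"] == "intron"]["peak_id"]
        ids = list(intron_peaks)
        third = max(len(ids) // 3, 1)
        from quantchip.atac import LoadingSelection

        sel = LoadingSelection(
            component=1,
            loadings=pd.Series(1.0, index=peaks["peak_id"]),
            selected=pd.Index(ids[: 2 * third]),
            direction=pd.Series(
                [DOWN] * third + [UP] * third, index=ids[: 2 * third]
            ),
            background=pd.Index(ids[2 * third :]),
            mean_log2fc=pd.Series(0.0, index=peaks["peak_id"]),
            explained_variance_ratio=0.5,
        )
        marked = pd.Series(marked_value, index=genes["gene_id"].values)
        return sel, annotated, marked

    def test_all_marked_gives_one(self, small_genome):
        sel, annotated, marked = self._inputs(small_genome, True)
        out = mark_fraction_by_class(sel, annotated, marked)
        present = out[~out["empty"]]
        assert (present["fraction_marked"] == 1.0).all()

    def test_seeded_fractions_recovered_within_binomial_tolerance(self):
        """0.6 / 0.25 / 0.35 marking per class at n = 500 genes per class."""
        from quantchip.atac import LoadingSelection

        rng = np.random.default_rng(31)
        probs = {DOWN: 0.6, UP: 0.25, BACKGROUND: 0.35}
        n_per = 500
        rows, marked, directions = [], {}, {}
        for ci, (cls, p) in enumerate(probs.items()):
            for i in range(n_per):
                pid, gid = f"{ci}_{i}", f"gene{ci}_{i}"
                rows.append((pid, "chr1", 100, 200, "intron", gid))
                marked[gid] = bool(rng.random() < p)
                directions[pid] = cls
        annotated = pd.DataFrame(
            rows, columns=["peak_id", "chrom", "start", "end", "annotation", "gene_id"]
        )
        sel_ids = [p for p, c in directions.items() if c != BACKGROUND]
        sel = LoadingSelection(
            component=1,
            loadings=pd.Series(1.0, index=annotated["peak_id"]),
            selected=pd.Index(sel_ids),
            direction=pd.Series({p: directions[p] for p in sel_ids}),
            background=pd.Index([p for p, c in directions.items() if c == BACKGROUND]),
            mean_log2fc=pd.Series(0.0, index=annotated["peak_id"]),
            explained_variance_ratio=0.5,
        )
        out = mark_fraction_by_class(sel, annotated, pd.Series(marked))
        for cls, p in probs.items():
            assert out.loc[cls, "fraction_marked"] == pytest.approx(p, abs=0.05)

    def test_none_marked_gives_zero(self, small_genome):
        sel, annotated, marked = self._inputs(small_genome, False)
        out = mark_fraction_by_class(sel, annotated, marked)
        present = out[~out["empty"]]
        assert (present["fraction_marked"] == 0.0).all()


def _permutation_mwu_p(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    import scipy.stats

    pooled = np.concatenate([a, b])
    n = len(a)
    obs = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
    obs_dev = abs(obs - len(a) * len(b) / 2)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = scipy.stats.mannwhitneyu(
            pooled[mask], pooled[~mask], alternative="two-sided", method="asymptotic"
        ).statistic
        if abs(u - len(a) * len(b) / 2) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMwuCompare:
    def test_disjoint_small_groups_exact_p(self):
        res = mwu_compare([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert min(res.statistic, 9 - res.statistic) == 0
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = mwu_compare([2.0, 2.0], [2.0, 2.0])
        assert res.all_tied
        assert res.pvalue == 1.0

    def test_exact_branch_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 4)
            res = mwu_compare(a, b)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(_permutation_mwu_p(a, b), abs=1e-9)

    def test_large_separation_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        res = mwu_compare(a, b)
        assert res.method == "asymptotic"
        assert res.pvalue < 1e-10

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mwu_compare([], [1.0])


class TestPairedTTest:
    def test_worked_example_closed_form(self):
        dmso = [1.0, 1.1, 0.9, 1.0]
        epz = [2.0, 2.2, 1.9, 2.1]
        res = paired_onesided_ttest(dmso, epz, alternative="increase")
        diff = np.array(dmso) - np.array(epz)
        t_expect = diff.mean() / (diff.std(ddof=1) / 2)
        assert res.t == pytest.approx(t_expect)
        assert res.t == pytest.approx(-36.37, abs=0.01)
        assert res.df == 3
        assert res.pvalue == pytest.approx(2.28e-5, rel=0.05)

    def test_equal_vectors_p_half(self):
        res = paired_onesided_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.pvalue == 0.5

    def test_one_sided_is_half_two_sided_in_alternative_direction(self):
        rng = np.random.default_rng(2)
        c = rng.normal(1.0, 0.1, 6)
        t = c - 0.2  # decrease under treatment
        import scipy.stats

        one = paired_onesided_ttest(c, t, alternative="decrease")
        two = scipy.stats.ttest_rel(c, t).pvalue
        assert one.pvalue == pytest.approx(two / 2)

    def test_zero_variance_flagged(self):
        res = paired_onesided_ttest([2.0, 3.0], [1.0, 2.0], alternative="decrease")
        assert res.zero_variance
        assert res.pvalue == 0.0

    def test_type_one_error_calibrated(self):
        # size of the test at alpha = 0.05 under the paired null, n = 4
        rng = np.random.default_rng(7)
        n_sim, hits = 2000, 0
        for _ in range(n_sim):
            c = rng.normal(0, 1, 4)
            t = rng.normal(0, 1, 4)
            if paired_onesided_ttest(c, t).pvalue < 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.015)
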