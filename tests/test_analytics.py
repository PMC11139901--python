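"""Tests for recovery rates, fold changes, composition, logos and scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lariatkit as lk
from lariatkit.analytics import (
    annotate_functional_score,
    bp_composition,
    build_logo_pfm,
    fold_change,
    pearson_chi2_2x2,
    pfm_from_sequences,
    position_enrichment,
    recovery_rate,
    spliced_unspliced_ratio,
    u12_u2_contrast,
)
from lariatkit.mapping import BranchpointTable, LariatCall


def bp_table(per_intron: dict, n_mapped: int, n_bp_shift: int = 0) -> BranchpointTable:
    rows = [(iid, 1000 + n_bp_shift, n) for iid, n in per_intron.items()]
    df = pd.DataFrame(rows, columns=["intron_id", "bp_position", "support"])
    return BranchpointTable(df, n_lariat=int(df["support"].sum()), n_mapped=n_mapped)


class TestRecoveryRate:
    @pytest.mark.parametrize("lariat,mapped,expect", [
        (0, 10**6, 0.0),
        (50, 10**6, 50.0),
        (37, 2_500_000, 14.8),
    ])
    def test_arithmetic(self, lariat, mapped, expect):
        assert recovery_rate(lariat, mapped) == pytest.approx(expect)

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            recovery_rate(5, 0)

    def test_linear_in_lariat_count(self):
        rates = [recovery_rate(n, 10**6) for n in (10, 20, 40)]
        assert rates[1] == 2 * rates[0] and rates[2] == 2 * rates[1]


class TestFoldChange:
    def test_identical_tables_give_unity(self):
        t = bp_table({"a": 10, "b": 5}, 10**6)
        fc = fold_change(t, t)
        assert (fc["fold_change"] == 1.0).all()
        assert fold_change(t, t, level="set") == 1.0

    def test_scaled_copy_gives_global_20(self):
        a = bp_table({"a": 200, "b": 400}, 10**6)
        b = bp_table({"a": 10, "b": 20}, 10**6)
        assert fold_change(a, b, level="set") == pytest.approx(20.0)

    def test_depth_normalization(self):
        # same counts at twice the depth halve the normalized level
        a = bp_table({"a": 100}, 2 * 10**6)
        b = bp_table({"a": 100}, 10**6)
        assert fold_change(a, b, level="set") == pytest.approx(0.5)

    def test_pseudocount_recorded_and_applied(self):
        a = bp_table({"a": 8}, 10**6)
        b = bp_table({"b": 4}, 10**6)
        fc = fold_change(a, b, pseudocount=0.5)
        assert fc.attrs["pseudocount"] == 0.5
        assert fc.loc["a", "fold_change"] == pytest.approx(8.5 / 0.5)

    def test_both_zero_set_level_rejected(self):
        a = bp_table({}, 10**6)
        with pytest.raises(ValueError):
            fold_change(a, a, level="set")

    def test_survival_regime_recovered_through_sampling(self, toy):
        """Monte-Carlo oracle: survival 0.05 with Poisson noise at 1e4
        lariat reads recovers a global fold change in [17, 23]."""
        genome, introns, _ = toy
        kin = lk.DebranchKinetics(base_survival=0.05)
        ab = lk.simulate_lariat_abundance(introns, 1e4 / len(introns), kin,
                                          seed=31, genome=genome)
        a = bp_table(dict(ab["null"]), 10**6)
        b = bp_table(dict(ab["active"]), 10**6)
        assert 17.0 <= fold_change(a, b, level="set") <= 23.0


class TestBpComposition:
    def test_all_a_calls(self):
        calls = [LariatCall(f"r{i}", "x", "g", 100, "A") for i in range(4)]
        comp = bp_composition(calls)
        assert comp["A"] == 1.0 and comp[["C", "G", "T"]].sum() == 0.0

    def test_planted_composition_recovered(self, toy, toy_index, toy_reads):
        genome, introns, _ = toy
        reads, truth = toy_reads
        lariat_ids = set(truth.reads.loc[truth.reads.read_class == "lariat", "read_id"])
        calls = lk.map_lariats_split(
            [r for r in reads if r.read_id in lariat_ids], genome, introns,
            index=toy_index, prefilter_linear=False)
        comp = bp_composition([c for c in calls if c.passed])
        n = sum(c.passed for c in calls)
        lo, hi = stats.binom.interval(0.95, n, 0.78)
        assert lo / n <= comp["A"] <= hi / n

    def test_a_fraction_lower_under_a_biased_debranching(self, toy):
        genome, introns, _ = toy
        kin = lk.DebranchKinetics(
            base_survival=0.03,
            branch_rates={"A": 1.0, "C": 0.5, "G": 0.5, "T": 0.5})
        ab = lk.simulate_lariat_abundance(introns, 50.0, kin, genome=genome)
        frac = lambda col: (ab.loc[ab.branch_base == "A", col].sum() / ab[col].sum())
        assert frac("expected_active") < frac("expected_null")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bp_composition([])


class TestLogoPfm:
    def test_single_sequence_gives_01_columns(self):
        pfm = pfm_from_sequences(["ACGT"])
        assert set(np.unique(pfm.to_numpy())) == {0.0, 1.0}
        assert pfm.loc["A", 0] == 1.0 and pfm.loc["T", 3] == 1.0

    def test_branch_window_dominated_by_planted_context(self, toy, toy_index, toy_reads):
        genome, introns, _ = toy
        reads, _ = toy_reads
        calls = lk.map_lariats_split(reads, genome, introns, index=toy_index)
        calls = lk.filter_intron_circles(calls, introns)
        pfm = build_logo_pfm(calls, genome, introns, anchor="bp", window=(5, 5))
        # planted YTNAY: position 0 (the branch) mostly A; -2 always T
        assert pfm.loc["A", 5] > 0.5
        assert pfm.loc["T", 3] == pytest.approx(1.0)
        assert np.allclose(pfm.sum(axis=0), 1.0)

    def test_five_ss_logo_starts_gt(self, toy, toy_index, toy_reads):
        genome, introns, _ = toy
        reads, _ = toy_reads
        calls = lk.map_lariats_split(reads, genome, introns, index=toy_index)
        pfm = build_logo_pfm(calls, genome, introns, anchor="five_ss",
                             window=(0, 7), top_n=10)
        assert pfm.loc["G", 0] == 1.0 and pfm.loc["T", 1] == 1.0

    def test_top_n_larger_than_available_warns(self, toy, toy_index, toy_reads):
        genome, introns, _ = toy
        reads, _ = toy_reads
        calls = lk.map_lariats_split(reads, genome, introns, index=toy_index)
        with pytest.warns(UserWarning, match="available"):
            build_logo_pfm(calls, genome, introns, anchor="five_ss",
                           window=(0, 5), top_n=10_000)

    def test_strand_symmetry(self, toy, toy_index, toy_reads):
        """Minus-strand calls give the same logo as equivalent plus-strand
        calls: windows are strand-corrected."""
        genome, introns, _ = toy
        reads, _ = toy_reads
        calls = lk.map_lariats_split(reads, genome, introns, index=toy_index)
        calls = lk.filter_intron_circles(calls, introns)
        plus = [c for c in calls if c.passed and
                next(i for i in introns if i.intron_id == c.intron_id).strand == "+"]
        minus = [c for c in calls if c.passed and c not in plus and c.passed]
        for sub in (plus, minus):
            pfm = build_logo_pfm(sub, genome, introns, anchor="bp", window=(2, 1))
            assert pfm.loc["T", 0] == pytest.approx(1.0)  # YTNAY "T" at -2


def test_render_logo_writes_svg(tmp_path):
    from lariatkit.analytics import render_logo

    pfm = pfm_from_sequences(["CTGAC", "CTAAC", "TTGAT", "CTCAC"])
    out = tmp_path / "logo.svg"
    render_logo(pfm, out, title="branch site")
    assert out.exists() and out.stat().st_size > 0


class TestChiSquare:
    def test_identical_sets_stat_zero_p_one(self):
        stat, p = pearson_chi2_2x2(np.array([[30, 70], [30, 70]]))
        assert stat == 0.0 and p == 1.0

    def test_textbook_formula_worked_example(self):
        obs = np.array([[30, 70], [10, 90]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - exp) ** 2 / exp).sum()
        stat, _ = pearson_chi2_2x2(obs)
        assert stat == pytest.approx(by_hand)

    def test_matches_reference_library_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            obs = rng.integers(1, 200, size=(2, 2))
            stat, p = pearson_chi2_2x2(obs)
            ref_stat, ref_p, _, _ = stats.chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(ref_stat)
            assert p == pytest.approx(ref_p)

    def test_continuity_correction_never_increases_statistic(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            obs = rng.integers(1, 100, size=(2, 2))
            assert pearson_chi2_2x2(obs, True)[0] <= pearson_chi2_2x2(obs)[0]

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(np.array([[0, 0], [5, 5]]))

    def test_position_enrichment_identical_sets(self, toy):
        genome, introns, _ = toy
        # pick two introns differing at intron position 3 (the first variable
        # base after the invariant GT) so neither margin of the table is empty
        base_at_3 = lambda i: genome.base(i.contig, i.rel_to_genomic(2), i.strand)
        i0 = introns[0]
        i1 = next(i for i in introns if base_at_3(i) != base_at_3(i0))
        calls = [LariatCall(f"a{k}", i.intron_id, i.gene_id, i.true_bp_genomic, "A")
                 for k, i in enumerate([i0] * 10 + [i1] * 10)]
        res = position_enrichment(calls, calls, genome, introns, 3, base_at_3(i0))
        assert res["statistic"] == 0.0 and res["p"] == 1.0
        assert res["frac_a"] == res["frac_b"] == 0.5


class TestSplicedUnsplicedRatio:
    def test_pure_classes_and_mixture(self, toy):
        genome, introns, genes = toy
        counts = {
            "linear_mRNA": lk.uniform_counts([g.gene_id for g in genes], 300),
            "pre_mRNA": lk.uniform_counts([g.gene_id for g in genes], 100),
        }
        reads, _ = lk.simulate_reads(genome, introns, counts, read_len=60,
                                     seed=17, genes=genes)
        df = spliced_unspliced_ratio(reads, genome, genes, introns, pseudocount=0.5)
        assert not df.empty
        # 3:1 mRNA:pre-mRNA mixture: pooled ratio near 3 after accounting for
        # the different junction-coverage footprints
        pooled = df["spliced"].sum() / df["unspliced"].sum()
        n_s, n_u = df["spliced"].sum(), df["unspliced"].sum()
        p_hat = n_s / (n_s + n_u)
        se = np.sqrt(p_hat * (1 - p_hat) / (n_s + n_u))
        lo = (p_hat - 2.6 * se) / (1 - p_hat + 2.6 * se)
        hi = (p_hat + 2.6 * se) / (1 - p_hat - 2.6 * se)
        # a pre-mRNA read can span either of two boundaries per intron,
        # so expected spliced:unspliced is 3:2 here, not 3:1
        assert lo <= 1.5 <= hi

    def test_all_spliced_uses_pseudocount(self, toy):
        genome, introns, genes = toy
        counts = {"linear_mRNA": lk.uniform_counts([g.gene_id for g in genes], 200)}
        reads, _ = lk.simulate_reads(genome, introns, counts, read_len=60,
                                     seed=18, genes=genes)
        df = spliced_unspliced_ratio(reads, genome, genes, introns, pseudocount=0.5)
        assert (df["unspliced"] == 0).all()
        assert (df["ratio"] == df["spliced"] / 0.5).all()

    def test_uncovered_introns_excluded(self, toy):
        genome, introns, genes = toy
        gene = genes[0]
        counts = {"linear_mRNA": {gene.gene_id: 50}}
        reads, _ = lk.simulate_reads(genome, introns, counts, read_len=60,
                                     seed=19, genes=genes)
        df = spliced_unspliced_ratio(reads, genome, genes, introns)
        assert set(df["intron_id"]) <= set(gene.intron_ids)


class TestU12Contrast:
    def _fc_frame(self, vals):
        return pd.DataFrame({"fold_change": pd.Series(vals)})

    def test_identical_distributions_ratio_one(self):
        _, introns, _ = lk.make_genome(20, seed=2, u12_fraction=1.0)
        fc = self._fc_frame({i.intron_id: 5.0 for i in introns})
        res = u12_u2_contrast(fc, introns)
        assert res["ratio"] == pytest.approx(1.0)

    def test_single_intron_per_class(self):
        _, introns, _ = lk.make_genome(1, seed=2, u12_fraction=1.0)
        u12 = next(i for i in introns if i.intron_class == "U12")
        u2 = next(i for i in introns if i.intron_class == "U2")
        fc = self._fc_frame({u12.intron_id: 12.0, u2.intron_id: 20.0})
        assert u12_u2_contrast(fc, introns)["ratio"] == pytest.approx(0.6)

    def test_u12_survival_twice_u2_gives_half_ratio(self, ):
        """Expectation oracle: if U12 lariats survive debranching twice as
        well, their knockout enrichment is half the U2 enrichment."""
        genome, introns, _ = lk.make_genome(20, seed=6, u12_fraction=1.0)
        kin = lk.DebranchKinetics(base_survival=0.05, u12_rate_factor=np.log(0.1) / np.log(0.05))
        ab = lk.simulate_lariat_abundance(introns, 100.0, kin, genome=genome)
        cls = {i.intron_id: i.intron_class for i in introns}
        fc = self._fc_frame(
            {iid: ab.loc[iid, "expected_null"] / ab.loc[iid, "expected_active"]
             for iid in ab.index})
        res = u12_u2_contrast(fc, introns)
        assert res["ratio"] == pytest.approx(0.5)

    def test_missing_class_rejected(self):
        _, introns, _ = lk.make_genome(4, seed=2, u12_fraction=0.0)
        fc = self._fc_frame({i.intron_id: 1.0 for i in introns})
        with pytest.raises(ValueError):
            u12_u2_contrast(fc, introns)


class TestFunctionalScoreAnnotation:
    def test_constant_track(self):
        track = {"c": np.full(100, 2.5)}
        out = annotate_functional_score([("c", 50)], track)
        assert out.iloc[0] == 2.5

    def test_spike_at_bp_plus_3(self):
        track = {"c": np.zeros(100)}
        track["c"][53] = 9.0
        assert annotate_functional_score([("c", 50)], track).iloc[0] == 9.0

    def test_matches_brute_force_window_max(self):
        rng = np.random.default_rng(23)
        track = {"c": rng.normal(size=500)}
        positions = [("c", int(p)) for p in rng.integers(6, 494, size=50)]
        out = annotate_functional_score(positions, track, window=11)
        for (_, p) in positions:
            assert out[("c", p)] == pytest.approx(track["c"][p - 5 : p + 6].max())

    def test_edge_truncation_warns(self):
        track = {"c": np.arange(20.0)}
        with pytest.warns(UserWarning, match="truncated"):
            out = annotate_functional_score([("c", 2)], track)
        assert out.iloc[0] == 7.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            annotate_functional_score([("c", 5)], {"c": np.zeros(10)}, window=10)
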