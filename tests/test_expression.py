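import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import small_config
from ltrperturb.expression import (
    annotate_distance,
    classify_reciprocal,
    de_table,
    de_test,
    decile_analysis,
    distance_bin_tests,
    orientation_summary,
    overlap_enrichment,
    rank_sum_test,
    size_factors,
)
from ltrperturb.io import CountMatrix, GeneModel, RepeatInstance
from ltrperturb.simulate import simulate_counts, simulate_genes, simulate_repeat_genome
from oracles import fisher_two_sided_oracle, ranksum_exact_oracle


def _matrix(values, n_rec=2, n_ctl=4):
    cols = [f"r{i}" for i in range(n_rec)] + [f"c{i}" for i in range(n_ctl)]
    cond = {f"r{i}": "recruitment" for i in range(n_rec)}
    cond.update({f"c{i}": "control_a" if i % 2 else "control_b" for i in range(n_ctl)})
    df = pd.DataFrame(values, columns=cols,
                      index=[f"g{i}" for i in range(len(values))])
    return CountMatrix(df, cond)


class TestDeTest:
    def test_identical_counts_are_null(self):
        m = _matrix(np.full((50, 6), 100))
        de = de_test(m)
        assert np.allclose(de["lfc"], 0)
        assert (de["pvalue"] > 0.99).all()

    def test_noise_free_fourfold_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(200, 2000, size=300)
        vals = np.tile(base[:, None], (1, 6))
        vals[:30, :2] *= 4  # planted 4x in the recruitment samples
        de = de_test(_matrix(vals))
        assert np.allclose(de["lfc"][:30], 2.0, atol=0.1)
        assert np.allclose(de["lfc"][30:], 0.0, atol=0.05)

    def test_size_factors_absorb_library_depth(self):
        rng = np.random.default_rng(1)
        base = rng.integers(100, 1000, size=200)
        vals = np.tile(base[:, None], (1, 6)).astype(float)
        vals[:, 0] *= 2.0  # one sample sequenced twice as deep
        m = _matrix(vals.astype(int))
        sf = size_factors(m.counts)
        assert sf["r0"] / sf["r1"] == pytest.approx(2.0, rel=0.01)

    def test_single_replicate_group_rejected(self):
        m = _matrix(np.full((10, 6), 50))
        m.conditions = {s: ("recruitment" if s == "r0" else "control_a")
                        for s in m.sample_ids}
        with pytest.raises(ValueError):
            de_test(m)

    def test_recovery_of_planted_reciprocal_effects(self):
        cfg = small_config(
            chrom_lengths={"chr1": 900_000},
            repeat_segments={"chr1": [(10_000, 110_000)]},
            gene_strata=((60, 1_000, 140_000), (540, 420_000, 780_000)),
        )
        genome, inst, truth = simulate_repeat_genome(cfg)
        genes, truth = simulate_genes(cfg, inst, truth)
        act = simulate_counts(cfg, genes, truth, "activation")
        rep = simulate_counts(cfg, genes, truth, "repression")
        labels = classify_reciprocal(de_table(de_test(act), de_test(rep)))
        t = truth.gene_effects
        planted = set(t.index[t.act_effect >= 1])
        recovered = set(labels.index[labels == "reciprocal"])
        tp = len(planted & recovered)
        assert tp / len(planted) >= 0.8
        assert (len(recovered) - tp) <= 0.1 * max(1, len(recovered))


class TestClassify:
    def _de(self, rows):
        return pd.DataFrame(
            rows, columns=["lfc_a", "padj_a", "lfc_i", "padj_i"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_definitions(self):
        de = self._de([
            (+2.0, 0.01, -1.5, 0.01),   # reciprocal
            (+2.0, 0.01, -1.0, 0.20),   # a_only
            (-1.0, 0.20, -1.0, 0.01),   # i_only
            (+1.0, 0.01, +1.0, 0.01),   # both_same_direction
            (-1.0, 0.01, +1.0, 0.01),   # both_other_pattern
            (+0.2, 0.50, +0.1, 0.60),   # nonsig
        ])
        got = classify_reciprocal(de).tolist()
        assert got == [
            "reciprocal", "a_only", "i_only",
            "both_same_direction", "both_other_pattern", "nonsig",
        ]

    def test_labels_partition_gene_set(self):
        rng = np.random.default_rng(2)
        de = self._de(
            np.column_stack([
                rng.normal(size=200), rng.uniform(size=200),
                rng.normal(size=200), rng.uniform(size=200),
            ])
        )
        labels = classify_reciprocal(de)
        assert len(labels) == 200
        assert labels.value_counts().sum() == 200

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError):
            classify_reciprocal(pd.DataFrame({"lfc_a": [1.0], "padj_a": [0.01]}))


class TestDistance:
    def _inst(self, s, e, strand="+"):
        return RepeatInstance("chr1", s, e, strand, "LTR5HS", f"L_{s}")

    def test_plus_strand_upstream_sign(self):
        g = GeneModel("g1", "chr1", "+", 200_000, (200_000, 210_000))
        ann = annotate_distance([g], [self._inst(150_000, 151_000)], "LTR5HS")
        assert ann.loc["g1", "signed_distance"] == -49_500
        assert ann.loc["g1", "side"] == "upstream"

    def test_minus_strand_flips_sign(self):
        g = GeneModel("g1", "chr1", "-", 200_000, (190_000, 200_001))
        ann = annotate_distance([g], [self._inst(150_000, 151_000)], "LTR5HS")
        assert ann.loc["g1", "signed_distance"] == +49_500
        assert ann.loc["g1", "side"] == "downstream"

    def test_orientation_same_when_strands_match(self):
        g = GeneModel("g1", "chr1", "+", 200_000, (200_000, 210_000))
        ann = annotate_distance([g], [self._inst(150_000, 151_000, "+")], "LTR5HS")
        assert ann.loc["g1", "orientation"] == "same"
        ann2 = annotate_distance([g], [self._inst(150_000, 151_000, "-")], "LTR5HS")
        assert ann2.loc["g1", "orientation"] == "opposite"

    def test_downstream_mode(self):
        g = GeneModel("g1", "chr1", "+", 100_000, (100_000, 110_000))
        ann = annotate_distance([g], [self._inst(150_000, 151_000, "-")], "LTR5HS")
        assert ann.loc["g1", "downstream_mode"] == "convergent"

    def test_chromosome_without_instance_gets_infinite_distance(self):
        g = GeneModel("g1", "chr9", "+", 1000, (1000, 2000))
        ann = annotate_distance([g], [self._inst(0, 1000)], "LTR5HS")
        assert np.isinf(ann.loc["g1", "abs_distance"])

    def test_family_absent_everywhere_rejected(self):
        g = GeneModel("g1", "chr1", "+", 1000, (1000, 2000))
        with pytest.raises(ValueError):
            annotate_distance([g], [], "LTR5HS")


class TestDecile:
    def test_ten_genes_one_per_decile(self):
        genes = [f"g{i}" for i in range(10)]
        labels = pd.Series("nonsig", index=genes)
        dist = pd.DataFrame(
            {"abs_distance": np.arange(10) * 1000.0}, index=genes
        )
        table = decile_analysis(labels, dist)
        assert (table["nonsig"] == 1).all()

    def test_counts_conserved_per_label(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(97)]
        labels = pd.Series(rng.choice(["reciprocal", "nonsig"], 97), index=genes)
        dist = pd.DataFrame({"abs_distance": rng.uniform(0, 1e6, 97)}, index=genes)
        table = decile_analysis(labels, dist)
        for lab in ("reciprocal", "nonsig"):
            assert table[lab].sum() == (labels == lab).sum()

    def test_too_few_genes_rejected(self):
        labels = pd.Series("nonsig", index=["g1"])
        dist = pd.DataFrame({"abs_distance": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            decile_analysis(labels, dist)


class TestRankSum:
    def test_branches_agree_near_switchover(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(40):
            n1, n2 = int(rng.integers(6, 11)), int(rng.integers(8, 13))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            p_exact = rank_sum_test(x, y, switchover=30)
            p_norm = rank_sum_test(x, y, switchover=0)
            if p_exact >= 0.05:
                assert abs(p_norm - p_exact) / p_exact < 0.10
                checked += 1
        assert checked >= 20

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6).tolist()
        y = rng.normal(size=7).tolist()
        assert rank_sum_test(x, y) == pytest.approx(ranksum_exact_oracle(x, y))

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            p = rank_sum_test(rng.normal(size=15), rng.normal(size=40))
            hits += p < 0.05
        # continuity-corrected test should be at or below nominal level
        assert hits / n_sim < 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestDistanceBins:
    def _setup(self, signed):
        genes = [f"g{i}" for i in range(len(signed))]
        dist = pd.DataFrame(
            {"signed_distance": np.asarray(signed, dtype=float)}, index=genes
        )
        de = pd.DataFrame({"lfc_a": np.zeros(len(signed))}, index=genes)
        return de, dist

    def test_bin_centre_rounding_rule(self):
        signed = [10_000] * 5 + [30_000] * 5 + [500_000] * 30 + [-500_000] * 30
        de, dist = self._setup(signed)
        res = distance_bin_tests(de, dist)
        centres = {b.center: b.n_genes for b in res}
        assert centres[0] == 5         # +10 kb rounds to bin 0
        assert centres[40_000] == 5    # +30 kb rounds to +40 kb
        assert centres[440_000] == 30  # far pool, downstream side

    def test_reference_required(self):
        de, dist = self._setup([10_000] * 30)
        with pytest.raises(ValueError):
            distance_bin_tests(de, dist)


class TestFisher:
    @pytest.mark.parametrize("table", [(3, 2, 1, 4), (0, 5, 5, 0), (2, 2, 2, 2), (7, 1, 2, 6)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)

    def test_independent_sets_have_unit_odds(self):
        universe = {f"g{i}" for i in range(400)}
        set_a = {f"g{i}" for i in range(0, 400, 2)}     # evens
        set_b = {f"g{i}" for i in range(0, 400, 4)} | {
            f"g{i}" for i in range(1, 400, 4)
        }  # half of each parity: independent of A
        odds, p = overlap_enrichment(set_a, set_b, universe)
        assert odds == pytest.approx(1.0, abs=0.05)
        assert p > 0.5

    def test_symmetric_table_p_one(self):
        odds, p = overlap_enrichment(
            {"a", "b", "c"}, {"a", "d", "e"},
            {"a", "b", "c", "d", "e"},
        )
        assert 0 < p <= 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), set(), set())


class TestOrientation:
    def test_all_upstream_same(self):
        genes = ["g1", "g2"]
        dist = pd.DataFrame(
            {"side": ["upstream", "upstream"], "orientation": ["same", "same"]},
            index=genes,
        )
        t = orientation_summary(genes, dist)
        assert t.loc["upstream", "same"] == 2
        assert t.values.sum() == 2

    def test_marginals_equal_set_size(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        dist = pd.DataFrame(
            {"side": rng.choice(["upstream", "downstream"], 40),
             "orientation": rng.choice(["same", "opposite"], 40)},
            index=genes,
        )
        assert orientation_summary(genes, dist).values.sum() == 40


class TestBH:
    def test_uniform_pvalues_yield_few_discoveries(self):
        rng = np.random.default_rng(8)
        discoveries = [
            multipletests(rng.uniform(size=2000), alpha=0.05, method="fdr_bh")[0].sum()
            for _ in range(100)
        ]
        assert np.mean(discoveries) <= 0.05 * 2000
        assert np.mean(discoveries) < 1.0
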