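import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltrperturb.guides import (
    GenomeIndex,
    GuideCandidate,
    correlate_coverage_with_signal,
    coverage_summary,
    CoverageRecord,
    enumerate_seed_candidates,
    map_guides_to_instances,
    score_offtargets,
    select_guides,
)
from ltrperturb.io import GenomeSequence, RepeatInstance, revcomp
from oracles import (
    naive_candidates,
    naive_instance_coverage,
    naive_offtarget_counts,
    naive_seed_hits,
    spearman_oracle,
)


def _genome_with(seq: str, pad: str = "A" * 50) -> tuple[GenomeSequence, RepeatInstance]:
    full = pad + seq + pad
    g = GenomeSequence({"chr1": full})
    inst = RepeatInstance("chr1", len(pad), len(pad) + len(seq), "+", "FAM", "i1")
    return g, inst


class TestEnumerate:
    def test_no_pam_on_either_strand_gives_empty(self):
        # alternating ACAC... has no GG and no CC
        g, inst = _genome_with("ACAC" * 20, pad="ACAC" * 10)
        assert enumerate_seed_candidates(g, [inst], "FAM") == []

    def test_single_pam_yields_single_seed(self):
        seed = "ACACACACACACACAC"
        g, inst = _genome_with("T" + seed + "AGG" + "T", pad="ATAT" * 10)
        cands = enumerate_seed_candidates(g, [inst], "FAM")
        assert [c.seed_seq for c in cands] == [seed]

    def test_matches_brute_force_scan(self, small_sim):
        cfg, genome, instances = small_sim
        cands = enumerate_seed_candidates(genome, instances, cfg.target_family)
        expected = naive_candidates(genome, instances, cfg.target_family)
        assert {c.seed_seq for c in cands} == expected
        assert len(cands) == len(expected)  # each seed exactly once

    def test_missing_family_errors(self, small_sim):
        _cfg, genome, instances = small_sim
        with pytest.raises(ValueError):
            enumerate_seed_candidates(genome, instances, "NOPE")


@pytest.fixture(scope="module")
def scored(small_sim):
    cfg, genome, instances = small_sim
    cands = enumerate_seed_candidates(genome, instances, cfg.target_family)
    out = score_offtargets(
        cands, genome, ["LTR5HS", "LTR5A", "LTR5B"], instances,
        target_family=cfg.target_family,
    )
    return cfg, genome, instances, out


class TestScoring:
    def test_counts_match_dense_scan_oracle(self, scored):
        cfg, genome, instances, cands = scored
        rng = random.Random(1)
        for c in rng.sample(cands, 12):
            expected = naive_offtarget_counts(
                genome, instances, ["LTR5HS", "LTR5A", "LTR5B"], c.seed_seq
            )
            assert c.offtarget_counts == expected, c.seed_seq

    def test_masked_family_hits_never_counted(self, scored):
        cfg, genome, instances, cands = scored
        # every hit of a consensus-derived seed inside masked instances is
        # excluded, so candidates living only there have zero off-targets
        only_masked = [c for c in cands if sum(c.offtarget_counts) == 0]
        assert only_masked  # the family shares its consensus: many such seeds

    def test_background_exact_copy_counts_once(self):
        seed = "ACGTACGTTGCATGCA"
        body = "T" + seed + "AGG" + "T"
        pad = "ATCTT" * 30
        full = pad + body + pad + seed + "CGG" + pad
        g = GenomeSequence({"chr1": full})
        inst = RepeatInstance("chr1", len(pad), len(pad) + len(body), "+", "FAM", "i1")
        (c,) = score_offtargets(
            [GuideCandidate(seed)], g, ["FAM"], [inst], target_family="FAM"
        )
        assert c.offtarget_counts[0] == 1  # the copy outside the masked instance
        assert c.ontarget_instances[0] == 1

    def test_masking_monotonicity(self, small_sim):
        cfg, genome, instances = small_sim
        cands = enumerate_seed_candidates(genome, instances, cfg.target_family)[:40]
        idx = GenomeIndex(genome)
        small = score_offtargets(
            [GuideCandidate(c.seed_seq) for c in cands], genome, ["LTR5HS"],
            instances, target_family="LTR5HS", index=idx,
        )
        large = score_offtargets(
            [GuideCandidate(c.seed_seq) for c in cands], genome,
            ["LTR5HS", "LTR5A", "LTR5B"], instances, target_family="LTR5HS", index=idx,
        )
        for s, l in zip(small, large):
            assert all(a >= b for a, b in zip(s.offtarget_counts, l.offtarget_counts))


class TestSelection:
    def _mk(self, seed, off, on0=0):
        c = GuideCandidate(seed)
        c.offtarget_counts = off
        c.ontarget_instances = [on0] * 4
        return c

    def test_zero_offtarget_ties_broken_by_coverage(self):
        a = self._mk("A" * 16, [0, 0, 0, 0], on0=5)
        b = self._mk("C" * 16, [0, 0, 0, 0], on0=9)
        assert select_guides([a, b], 1)[0] is b

    def test_lexicographic_offtarget_key(self):
        a = self._mk("A" * 16, [0, 5, 0, 0])
        b = self._mk("C" * 16, [0, 0, 9, 9])
        assert select_guides([a, b], 1)[0] is b

    def test_short_candidate_list_returned_whole(self):
        cands = [self._mk("A" * 16, [0, 0, 0, 0])] * 5
        assert len(select_guides(cands, 12)) == 5

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            select_guides([], 0)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_selection_invariant_under_permutation(self, rnd):
        cands = [
            self._mk(
                "".join(rnd.choice("ACGT") for _ in range(16)),
                [rnd.randint(0, 3) for _ in range(4)],
                rnd.randint(0, 9),
            )
            for _ in range(30)
        ]
        ref = [c.seed_seq for c in select_guides(cands, 12)]
        shuffled = cands[:]
        rnd.shuffle(shuffled)
        assert [c.seed_seq for c in select_guides(shuffled, 12)] == ref

    def test_removing_unselected_candidate_preserves_selection(self):
        rnd = random.Random(7)
        cands = [
            self._mk(
                "".join(rnd.choice("ACGT") for _ in range(16)),
                [rnd.randint(0, 3) for _ in range(4)],
                rnd.randint(0, 9),
            )
            for _ in range(25)
        ]
        sel = select_guides(cands, 12)
        chosen = {c.seed_seq for c in sel}
        survivors = [c for c in cands if c.seed_seq in chosen or rnd.random() < 0.5]
        assert [c.seed_seq for c in select_guides(survivors, 12)] == [
            c.seed_seq for c in sel
        ]


class TestCoverage:
    def test_pam_filter_controls_counting(self):
        seed = "ACGTACGTTGCATGCA"
        pad = "ATCTT" * 20
        good = pad + seed + "AGG" + pad
        bad = pad + seed + "ATG" + pad
        g = GenomeSequence({"chr1": good, "chr2": bad})
        insts = [
            RepeatInstance("chr1", 0, len(good), "+", "FAM", "i_good"),
            RepeatInstance("chr2", 0, len(bad), "+", "FAM", "i_bad"),
        ]
        records, hits = map_guides_to_instances(
            [GuideCandidate(seed)], g, insts, ["FAM"]
        )
        by_id = {r.instance_id: r for r in records}
        assert by_id["i_good"].guides_matching[0] == 1
        assert by_id["i_bad"].guides_matching == [0, 0, 0, 0]

    def test_records_match_dense_scan_oracle(self, small_sim):
        cfg, genome, instances = small_sim
        cands = enumerate_seed_candidates(genome, instances, cfg.target_family)
        scored = score_offtargets(
            cands, genome, ["LTR5HS", "LTR5A", "LTR5B"], instances,
            target_family=cfg.target_family,
        )
        sel = select_guides(scored, 6)
        fams = ["LTR5HS", "LTR5A", "LTR5B"]
        records, _ = map_guides_to_instances(sel, genome, instances, fams)
        expected = naive_instance_coverage(
            genome, instances, fams, [c.seed_seq for c in sel]
        )
        got = {r.instance_id: r.guides_matching for r in records}
        assert got == expected

    def test_coverage_nesting_in_mismatches(self, small_sim):
        cfg, genome, instances = small_sim
        cands = enumerate_seed_candidates(genome, instances, cfg.target_family)
        sel = select_guides(
            score_offtargets(
                cands, genome, ["LTR5HS", "LTR5A", "LTR5B"], instances,
                target_family=cfg.target_family,
            ),
            12,
        )
        records, _ = map_guides_to_instances(
            sel, genome, instances, ["LTR5HS", "LTR5A", "LTR5B"]
        )
        for r in records:
            gm = r.guides_matching
            assert all(gm[m] <= gm[m + 1] for m in range(3))

    def test_summary_monotone_in_threshold_and_mismatches(self, small_sim):
        cfg, genome, instances = small_sim
        cands = enumerate_seed_candidates(genome, instances, cfg.target_family)
        sel = select_guides(
            score_offtargets(
                cands, genome, ["LTR5HS"], instances, target_family="LTR5HS"
            ),
            12,
        )
        records, _ = map_guides_to_instances(sel, genome, instances, ["LTR5HS"])
        summ = coverage_summary(records, thresholds=(1, 2, 4))
        for (_fam, m), grp in summ.groupby(["family", "mismatches"]):
            fr = grp.sort_values("threshold")["fraction"].tolist()
            assert fr == sorted(fr, reverse=True)
        for (_fam, t), grp in summ.groupby(["family", "threshold"]):
            fr = grp.sort_values("mismatches")["fraction"].tolist()
            assert fr == sorted(fr)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            coverage_summary([])


class TestPlantedCoverage:
    def test_planted_guides_reproduce_coverage_table_exactly(self):
        # low-entropy background with no PAM outside the planted sites, so
        # the coverage table equals the planting plan with no stray hits
        rnd = random.Random(3)
        guides = []
        while len(guides) < 4:
            s = "".join(rnd.choice("ACT") for _ in range(16))  # no G: PAM only where planted
            if s not in guides and "GG" not in s and "CC" not in s:
                guides.append(s)
        plan = {  # instance -> planted guide indices
            "i0": [0, 1, 2, 3],
            "i1": [0, 1],
            "i2": [3],
            "i3": [],
        }
        filler = "ATCTT"
        chrom_parts, instances, pos = [], [], 0
        for iid, gidx in plan.items():
            chrom_parts.append(filler * 30)
            pos += 150
            body = "".join(guides[k] + "AGG" + filler for k in gidx) or filler * 5
            instances.append(
                RepeatInstance("chr1", pos, pos + len(body), "+", "FAM", iid)
            )
            chrom_parts.append(body)
            pos += len(body)
        chrom_parts.append(filler * 30)
        g = GenomeSequence({"chr1": "".join(chrom_parts)})
        records, _ = map_guides_to_instances(
            [GuideCandidate(s) for s in guides], g, instances, ["FAM"]
        )
        got = {r.instance_id: r.guides_matching[0] for r in records}
        assert got == {iid: len(gidx) for iid, gidx in plan.items()}
        summ = coverage_summary(records, thresholds=(1, 2, 4))
        at = lambda m, t: float(
            summ[(summ.mismatches == m) & (summ.threshold == t)]["fraction"].iloc[0]
        )
        assert at(0, 1) == 0.75
        assert at(0, 2) == 0.5
        assert at(0, 4) == 0.25


class TestSpearman:
    def _records(self, counts):
        return [
            CoverageRecord(f"i{k}", "FAM", [c] * 4) for k, c in enumerate(counts)
        ]

    def test_perfect_monotone_gives_one(self):
        recs = self._records([1, 2, 3, 5, 9])
        signal = {f"i{k}": float(v) for k, v in enumerate([1, 2, 3, 5, 9])}
        rho, n = correlate_coverage_with_signal(recs, signal)
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_negated_signal_gives_minus_one(self):
        recs = self._records([1, 2, 3, 5, 9])
        signal = {f"i{k}": -float(v) for k, v in enumerate([1, 2, 3, 5, 9])}
        rho, _ = correlate_coverage_with_signal(recs, signal)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 6, 20).tolist()
        sig = rng.normal(size=20).tolist()
        recs = self._records(counts)
        signal = {f"i{k}": sig[k] for k in range(20)}
        rho, _ = correlate_coverage_with_signal(recs, signal)
        assert abs(rho - spearman_oracle(counts, sig)) < 1e-12

    def test_too_few_pairs_rejected(self):
        recs = self._records([1, 2])
        with pytest.raises(ValueError):
            correlate_coverage_with_signal(recs, {"i0": 1.0, "i1": 2.0})
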