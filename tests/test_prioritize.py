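import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bvf.mendel import BulkDesign
from bvf.prioritize import (
    FilterThresholds,
    bulk_subtract,
    consequence_filter,
    hard_filter,
    locus_gene_counts,
    score_candidates,
    snp_index,
    write_igv_batch,
)

from conftest import make_variant, random_variants

MUT = BulkDesign("mutant", 4)
WT = BulkDesign("wildtype", 6, het_count=3)


def oracle_filter(variants, t):
    """One-line-per-rule re-statement of the retention contract."""
    kept = []
    for v in variants:
        dp = v.dp if v.dp is not None else (
            None if v.ad_ref is None else v.ad_ref + v.ad_alt)
        if (dp is None and t.min_dp > 0) or (dp is not None and dp < t.min_dp):
            continue
        if v.gq is not None and v.gq < t.min_gq:
            continue
        if v.qd is not None and v.qd < t.min_qd:
            continue
        ab = v.allele_balance
        if ab is not None and ab < t.min_ab:
            continue
        kept.append(v)
    return kept


class TestHardFilter:
    def test_depth_boundary(self):
        v = make_variant(dp=5, ad_ref=0, ad_alt=5)
        assert hard_filter([v], FilterThresholds(min_dp=6)) == []
        assert hard_filter([v], FilterThresholds(min_dp=5)) == [v]

    def test_zero_thresholds_are_identity(self):
        variants = random_variants(50, seed=3)
        t = FilterThresholds(min_ab=0, min_dp=0, min_gq=0, min_qd=0)
        assert hard_filter(variants, t) == variants

    def test_het_call_needs_skewed_balance(self):
        balanced = make_variant(ad_ref=15, ad_alt=15, dp=30)
        skewed = make_variant(ad_ref=27, ad_alt=3, dp=30)
        hom = make_variant(ad_ref=0, ad_alt=30, dp=30)
        kept = hard_filter([balanced, skewed, hom], FilterThresholds())
        assert kept == [skewed, hom]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle_on_random_fixture(self, seed):
        variants = random_variants(200, seed=seed)
        for t in (
            FilterThresholds(),
            FilterThresholds(min_ab=0.6, min_dp=10, min_gq=30, min_qd=10),
        ):
            assert hard_filter(variants, t) == oracle_filter(variants, t)

    def test_stricter_thresholds_give_subset(self):
        variants = random_variants(200, seed=9)
        loose = set(id(v) for v in hard_filter(variants, FilterThresholds()))
        strict = hard_filter(
            variants, FilterThresholds(min_ab=0.9, min_dp=20, min_qd=10)
        )
        assert all(id(v) in loose for v in strict)


class TestConsequenceFilter:
    def test_synonymous_only_dropped(self):
        v = make_variant(effects=(("synonymous_variant", "G1", "G1.1"),))
        assert consequence_filter([v]) == []

    def test_one_matching_effect_among_three_retains(self):
        v = make_variant(
            effects=(
                ("synonymous_variant", "G1", "G1.1"),
                ("frameshift_variant", "G1", "G1.2"),
                ("upstream_gene_variant", "G2", "G2.1"),
            )
        )
        assert consequence_filter([v]) == [v]

    def test_human_readable_dialect_matches(self):
        v = make_variant(effects=(("missense variation", "G1", "G1.1"),))
        assert consequence_filter([v]) == [v]

    def test_locus_and_gene_counts(self):
        # 10 loci spread over 4 genes, counted by hand
        genes = ["GA", "GA", "GB", "GB", "GB", "GC", "GC", "GC", "GC", "GD"]
        variants = [
            make_variant(pos=100 + i, effects=(("missense_variant", g, g + ".1"),))
            for i, g in enumerate(genes)
        ]
        assert locus_gene_counts(variants) == (10, 4)

    def test_pipeline_monotonicity(self):
        variants = random_variants(150, seed=4)
        conseq = consequence_filter(variants)
        both = hard_filter(conseq, FilterThresholds())
        assert set(v.key for v in both) <= set(v.key for v in conseq)
        assert set(v.key for v in conseq) <= set(v.key for v in variants)


class TestBulkSubtract:
    def test_identical_inputs(self):
        a = random_variants(20, seed=1)
        a_spec, b_spec, common = bulk_subtract(a, list(a))
        assert a_spec == [] and b_spec == [] and len(common) == 20

    def test_disjoint_inputs(self):
        a = random_variants(10, seed=1)
        b = [make_variant(pos=v.pos + 100000) for v in random_variants(10, seed=2)]
        a_spec, b_spec, common = bulk_subtract(a, b)
        assert common == [] and len(a_spec) == 10 and len(b_spec) == 10

    def test_partial_overlap_set_arithmetic(self):
        a = [make_variant(pos=1000 + i) for i in range(20)]
        b = [make_variant(pos=1013 + i) for i in range(20)]  # 7 shared keys
        a_spec, b_spec, common = bulk_subtract(a, b)
        assert (len(a_spec), len(b_spec), len(common)) == (13, 13, 7)

    def test_duplicate_key_rejected(self):
        v = make_variant()
        with pytest.raises(ValueError, match="duplicate"):
            bulk_subtract([v, v], [])

    @given(st.sets(st.integers(1, 60)), st.sets(st.integers(1, 60)))
    def test_partition_conservation(self, pos_a, pos_b):
        a = [make_variant(pos=p) for p in sorted(pos_a)]
        b = [make_variant(pos=p) for p in sorted(pos_b)]
        a_spec, b_spec, common = bulk_subtract(a, b)
        assert len(a_spec) + len(common) == len(a)
        assert len(b_spec) + len(common) == len(b)
        assert {v.key for v in a_spec} | {v.key for v in common} == {
            v.key for v in a
        }


class TestScoreCandidates:
    def _ev(self, candidates, mut, wt):
        mut_ev = {c.key: mut[i] for i, c in enumerate(candidates)}
        wt_ev = {c.key: wt[i] for i, c in enumerate(candidates)}
        return mut_ev, wt_ev

    def test_causal_like_evidence_ranks_first(self):
        causal = make_variant(pos=500, effects=(("frameshift_variant", "GX", "GX.1"),))
        decoy_absent = make_variant(pos=100)  # wildtype bulk shows no alt
        decoy_het = make_variant(pos=900)  # wildtype bulk at 0.5
        cands = [causal, decoy_absent, decoy_het]
        mut_ev, wt_ev = self._ev(
            cands, [(0, 25), (0, 25), (0, 25)], [(18, 6), (24, 0), (12, 12)]
        )
        scores = score_candidates(cands, MUT, WT, mut_ev, wt_ev)
        assert scores[0].key == causal.key
        assert scores[0].rank == 1 and scores[0].status == "ok"
        # all scores recomputable from the stated sort keys
        ranked = [s for s in scores if s.rank is not None]
        assert ranked == sorted(
            ranked,
            key=lambda s: (s.status == "incompatible", s.combined,
                           s.effect_rank, s.variant.pos),
        )

    def test_low_mutant_fraction_flagged_incompatible(self):
        v = make_variant()
        mut_ev, wt_ev = self._ev([v], [(13, 12)], [(18, 6)])
        (s,) = score_candidates([v], MUT, WT, mut_ev, wt_ev)
        assert s.status == "incompatible"
        assert s.rank is not None  # flagged candidates still ranked, last

    def test_effect_severity_breaks_ties(self):
        frameshift = make_variant(
            pos=300, effects=(("frameshift_variant", "G", "G.1"),)
        )
        missense = make_variant(pos=100)  # earlier position but milder effect
        mut_ev, wt_ev = self._ev(
            [frameshift, missense], [(0, 25), (0, 25)], [(18, 6), (18, 6)]
        )
        scores = score_candidates([frameshift, missense], MUT, WT, mut_ev, wt_ev)
        assert scores[0].key == frameshift.key

    def test_missing_evidence_is_unranked(self):
        v = make_variant()
        (s,) = score_candidates([v], MUT, WT, {}, {})
        assert s.status == "no-evidence" and s.rank is None

    def test_fisher_combination_value(self):
        import math

        from bvf.mendel import binomial_consistency

        v = make_variant()
        mut_ev, wt_ev = self._ev([v], [(1, 24)], [(18, 6)])
        (s,) = score_candidates([v], MUT, WT, mut_ev, wt_ev)
        expect = -2 * (
            math.log(binomial_consistency(24, 25, 1.0))
            + math.log(binomial_consistency(6, 24, 0.25))
        )
        assert s.combined == pytest.approx(expect)


class TestSnpIndex:
    def test_full_support_site(self):
        pts, _ = snp_index([make_variant(ad_ref=0, ad_alt=10)])
        assert pts[0].snp_index == 1.0

    def test_three_sites_one_window(self):
        variants = [
            make_variant(pos=100, ad_ref=8, ad_alt=2, dp=10),
            make_variant(pos=200, ad_ref=6, ad_alt=4, dp=10),
            make_variant(pos=300, ad_ref=4, ad_alt=6, dp=10),
        ]
        _, windows = snp_index(variants, window_size=1000, step=1000)
        assert len(windows) == 1
        assert windows[0].window_mean == pytest.approx(0.4)

    def test_zero_depth_sites_skipped(self):
        pts, _ = snp_index([make_variant(ad_ref=0, ad_alt=0, dp=0)])
        assert pts == []

    def test_windows_match_naive_recomputation(self):
        rng = np.random.default_rng(12)
        variants = []
        for i in range(100):
            dp = int(rng.integers(1, 40))
            alt = int(rng.integers(0, dp + 1))
            variants.append(
                make_variant(pos=int(rng.integers(1, 50000)) + i * 997,
                             dp=dp, ad_ref=dp - alt, ad_alt=alt)
            )
        window, step = 10000, 2500
        pts, windows = snp_index(variants, window, step)
        # brute-force oracle over every step-offset window
        expected = {}
        max_pos = max(p.pos for p in pts)
        start = 0
        while start <= max_pos:
            inside = [p.snp_index for p in pts if start < p.pos <= start + window]
            if inside:
                expected[start] = sum(inside) / len(inside)
            start += step
        assert {w.start0: w.window_mean for w in windows} == pytest.approx(expected)


class TestIgvBatch:
    def test_goto_arithmetic(self):
        v = make_variant(chrom="chr11", pos=1_000_000)
        text = write_igv_batch([v], "soy", "snaps", flank_bp=500)
        assert "goto chr11:999500-1000500" in text

    def test_empty_candidates_header_only(self):
        text = write_igv_batch([], "soy", "snaps")
        assert text == "new\ngenome soy\nsnapshotDirectory snaps\n"

    def test_three_candidates_in_genomic_order(self):
        vs = [make_variant(pos=p) for p in (300, 100, 200)]
        lines = write_igv_batch(vs, "g", "d", flank_bp=10).splitlines()
        gotos = [l for l in lines if l.startswith("goto")]
        assert gotos == ["goto Chr01:90-110", "goto Chr01:190-210",
                        "goto Chr01:290-310"]
        assert sum(1 for l in lines if l.startswith("snapshot ")) == 3
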