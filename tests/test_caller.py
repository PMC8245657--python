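import itertools

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from neoprofiler import (AlleleCountSite, CallerParams, TranscriptModel,
                         call_somatic_variants, classify_variant,
                         fisher_somatic_p, summarize_mutations)
from neoprofiler.caller import SomaticVariant, passes_filters
from neoprofiler.errors import (ConsistencyError, CoordinateError, InputError,
                                StateError)
from .oracles import fisher_two_sided_oracle


def site(t_ref, t_alt, n_ref, n_alt, ref="A", alt="G", pos=10, tid="GENE0001"):
    return AlleleCountSite(tid, pos, ref, alt, t_ref, t_alt, n_ref, n_alt)


class TestFisherP:
    def test_identical_rows_give_p_one(self):
        assert fisher_somatic_p(site(2, 0, 2, 0)) == pytest.approx(1.0)

    def test_two_by_two_cross_table(self):
        # margins (2,2;2,2): observed [[0,2],[2,0]] has probability 1/6 and
        # only its mirror ties it, so p = 2/6 = 1/3
        assert fisher_somatic_p(site(0, 2, 2, 0)) == pytest.approx(1 / 3)

    def test_clear_somatic_site_is_significant(self):
        assert fisher_somatic_p(site(90, 10, 100, 0)) < 0.05

    def test_no_reads_at_all_rejected(self):
        with pytest.raises(InputError):
            fisher_somatic_p(site(0, 0, 0, 0))

    def test_matches_enumeration_oracle_exhaustively_small(self):
        # exhaustive over all tables with margins <= 12 (the full <= 30
        # sweep runs in the acceptance suite)
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if a + b > 12 or c + d > 12 or a + c > 12 or b + d > 12:
                continue
            if a + b == 0 or c + d == 0:
                continue
            mine = fisher_somatic_p(site(a, b, c, d))
            assert mine == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    @given(st.integers(0, 80), st.integers(0, 80),
           st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_and_transpose_invariant(self, a, b, c, d):
        """Cross-check against scipy's independent implementation and the
        row/column-swap symmetry of the exact test."""
        if a + b == 0 or c + d == 0:
            return
        p = fisher_somatic_p(site(a, b, c, d))
        assert 0 < p <= 1
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], abs=1e-9)
        if a + c > 0 and b + d > 0:
            p_t = fisher_somatic_p(site(a, c, b, d))    # transpose
            assert p == pytest.approx(p_t, abs=1e-9)


class TestSixFilters:
    def test_empty_input_empty_output(self):
        assert call_somatic_variants([], CallerParams()) == []

    def test_boundary_vaf_ten_percent_passes(self):
        calls = call_somatic_variants([site(90, 10, 100, 0)])
        assert len(calls) == 1
        v = calls[0]
        assert v.tumor_vaf == pytest.approx(0.10)
        assert v.fisher_p < 0.05

    def test_variant_depth_three_fails(self):
        assert call_somatic_variants([site(97, 3, 100, 0)]) == []

    def test_normal_vaf_exactly_two_percent_fails(self):
        # normal VAF threshold is strict: 2/100 = 0.02 is NOT < 2%
        assert call_somatic_variants([site(70, 30, 98, 2)]) == []
        assert len(call_somatic_variants([site(70, 30, 99, 1)])) == 1

    @pytest.mark.parametrize("t_ref,t_alt,n_ref,n_alt", [
        (5, 4, 100, 0),      # tumor depth 9 < 10
        (90, 10, 9, 0),      # normal depth 9 < 10
    ])
    def test_depth_filter_applies_to_both_samples(self, t_ref, t_alt,
                                                  n_ref, n_alt):
        assert call_somatic_variants([site(t_ref, t_alt, n_ref, n_alt)]) == []

    def test_output_follows_input_order(self):
        sites = [site(80, 20, 100, 0, pos=30), site(90, 10, 100, 0, pos=5)]
        calls = call_somatic_variants(sites)
        assert [c.cds_position for c in calls] == [30, 5]

    def test_relaxing_any_threshold_never_shrinks_call_set(self):
        import numpy as np
        rng = np.random.default_rng(42)
        sites = [site(int(a), int(b), int(c), int(d), pos=i + 1)
                 for i, (a, b, c, d) in enumerate(
                     rng.integers(0, 60, size=(200, 4)))
                 if a + b > 0 and c + d > 0]
        base = CallerParams()
        called = {v.cds_position for v in call_somatic_variants(sites, base)}
        relaxed = [
            CallerParams(min_depth=5),
            CallerParams(min_variant_depth=2),
            CallerParams(min_tumor_vaf=0.05),
            CallerParams(max_normal_vaf=0.10),
            CallerParams(max_fisher_p=0.20),
        ]
        for params in relaxed:
            now = {v.cds_position for v in call_somatic_variants(sites, params)}
            assert called <= now


# codons: ATG AAA GAT TGG CCC TAA
MODEL = TranscriptModel("GENE_T", "ATGAAAGATTGGCCCTAA", exon_boundaries=())
# same CDS with an exon junction after base 9 (splice window = 8..11)
MODEL_JUNC = TranscriptModel("GENE_T", "ATGAAAGATTGGCCCTAA",
                             exon_boundaries=(9,))


def _variant(pos, ref, alt):
    s = AlleleCountSite("GENE_T", pos, ref, alt, 80, 20, 100, 0)
    return SomaticVariant(site=s, fisher_p=1e-6, tumor_vaf=0.2,
                          normal_vaf=0.0)


class TestClassification:
    def test_trp_to_stop_is_stopgain(self):
        # TGG codon 4; position 11 G->A makes TAG
        v = classify_variant(_variant(11, "G", "A"), MODEL)
        assert v.mutation_class == "stopgain"
        assert (v.ref_aa, v.alt_aa, v.protein_position) == ("W", "*", 4)

    def test_synonymous_lysine(self):
        # AAA codon 2 -> AAG, both Lys
        v = classify_variant(_variant(6, "A", "G"), MODEL)
        assert v.mutation_class == "sSNV"
        assert v.ref_aa == v.alt_aa == "K"

    def test_missense_asp_to_glu(self):
        model = TranscriptModel("G2", "ATGGATAAATTTCCCTAA", ())
        # GAT codon 2 -> GAA: position 6 T->A
        s = AlleleCountSite("G2", 6, "T", "A", 80, 20, 100, 0)
        v = classify_variant(
            SomaticVariant(site=s, fisher_p=0.0, tumor_vaf=.2, normal_vaf=0),
            model)
        assert v.mutation_class == "nsSNV"
        assert (v.ref_aa, v.alt_aa, v.protein_position) == ("D", "E", 2)

    def test_splice_window_takes_precedence(self):
        # positions 8..11 flank the junction: splicing regardless of the
        # codon-level effect (position 11 would otherwise be a stopgain)
        for pos, ref, alt in ((9, "T", "C"), (11, "G", "A")):
            v = classify_variant(_variant(pos, ref, alt), MODEL_JUNC)
            assert v.mutation_class == "splicing"

    def test_indel_token(self):
        s = AlleleCountSite("GENE_T", 5, "A", "+", 80, 20, 100, 0)
        v = classify_variant(
            SomaticVariant(site=s, fisher_p=0.0, tumor_vaf=.2, normal_vaf=0),
            MODEL)
        assert v.mutation_class == "INDEL"

    def test_stoploss(self):
        # terminal TAA at 16..18; 17 A->G gives TGA (still stop, sSNV-ish)
        # but 16 T->C gives CAA = Gln -> stoploss
        v = classify_variant(_variant(16, "T", "C"), MODEL)
        assert v.mutation_class == "stoploss"
        assert v.ref_aa == "*" and v.alt_aa == "Q"

    def test_position_outside_cds_rejected(self):
        with pytest.raises(CoordinateError):
            classify_variant(_variant(19, "A", "G"), MODEL)

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            classify_variant(_variant(6, "C", "G"), MODEL)


class TestSummary:
    def test_empty_summary(self):
        s = summarize_mutations([])
        assert s["total"] == 0
        assert s["nssnv_fraction"] is None
        assert all(v == 0 for v in s["counts"].values())

    def test_counts_and_fraction(self):
        variants = ([classify_variant(_variant(6, "A", "G"), MODEL)] * 3
                    + [classify_variant(_variant(11, "G", "A"), MODEL)] * 1)
        model2 = TranscriptModel("G2", "ATGGATAAATTTCCCTAA", ())
        ns = classify_variant(SomaticVariant(
            site=AlleleCountSite("G2", 6, "T", "A", 80, 20, 100, 0),
            fisher_p=0.0, tumor_vaf=.2, normal_vaf=0), model2)
        variants += [ns] * 5
        s = summarize_mutations(variants)
        assert s["total"] == 9
        assert sum(s["counts"].values()) == 9
        assert s["nssnv_fraction"] == pytest.approx(5 / 9)

    def test_unclassified_variant_rejected(self):
        with pytest.raises(StateError):
            summarize_mutations([_variant(6, "A", "G")])


def test_filter_predicate_matches_caller(small_cohort):
    patient = small_cohort[0]
    params = CallerParams()
    called = {(v.transcript_id, v.cds_position)
              for v in call_somatic_variants(patient.allele_counts, params)}
    manual = {(s.transcript_id, s.cds_position)
              for s in patient.allele_counts if passes_filters(s, params)}
    assert called == manual
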