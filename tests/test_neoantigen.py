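import numpy as np
import pytest

from neoprofiler import (AlleleCountSite, BindingPrediction, NeoantigenParams,
                         TranscriptModel, build_neoantigen_records,
                         enumerate_mutant_peptides, filter_binders,
                         mutation_read_count, neoantigen_load,
                         select_vaccine_candidates)
from neoprofiler.caller import SomaticVariant, call_somatic_variants, \
    classify_variant
from neoprofiler.errors import InputError
from neoprofiler.neoantigen import NeoantigenRecord
from neoprofiler.pipeline import profile_patient


def _nssnv(tid="G1", pos=6, ppos=2, ref="T", alt="A", ref_aa="D", alt_aa="E"):
    s = AlleleCountSite(tid, pos, ref, alt, 80, 20, 100, 0)
    return SomaticVariant(site=s, fisher_p=1e-8, tumor_vaf=.2, normal_vaf=0,
                          mutation_class="nsSNV", gene_symbol=tid,
                          ref_aa=ref_aa, alt_aa=alt_aa, protein_position=ppos)


def _prediction(seq, allele="HLA-A*02:01", ic50=100.0, variant=None):
    wt = ("A" if seq[0] != "A" else "G") + seq[1:]
    from neoprofiler import MutantPeptide
    pep = MutantPeptide(seq, 0, wt, variant)
    return BindingPrediction(pep, allele, ic50)


class TestFilterBinders:
    def test_strict_threshold_boundary(self):
        params = NeoantigenParams()
        kept = filter_binders([_prediction("KLAEDVTF", ic50=499.9)], params)
        assert len(kept) == 1
        dropped = filter_binders([_prediction("KLAEDVTF", ic50=500.0)], params)
        assert dropped == []

    def test_empty_input(self):
        assert filter_binders([], NeoantigenParams()) == []


class TestMutationReadCount:
    def test_absent_variant_counts_zero(self):
        assert mutation_read_count({}, _nssnv()) == 0

    def test_expression_eligibility_thresholds(self):
        counts = {("G1", 6): 1}
        v = _nssnv()
        c = mutation_read_count(counts, v)
        assert c >= 1                      # eligible under the load criterion
        assert not c >= 2                  # not under the CTL-candidate rule

    def test_mode_selects_column(self):
        counts = {("G1", 6): (7, 3)}
        v = _nssnv()
        assert mutation_read_count(counts, v, "covering") == 7
        assert mutation_read_count(counts, v, "mutant_supporting") == 3

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            mutation_read_count({("G1", 6): -1}, _nssnv())


MODEL = TranscriptModel("G1", "ATGGATAAATTTCCCGGGTTAAGAGAAATTCCGTATGCGTGA", ())


def _records(rna_count=1, ic50s=(100.0, 300.0, 499.0),
             alleles=("HLA-A*02:01",)):
    v = _nssnv()
    protein, pos = MODEL.protein, 2
    peps = enumerate_mutant_peptides(
        protein[:1] + "E" + protein[2:], pos, (8, 9),
        wildtype_protein=protein, source_variant=v)[:len(ic50s)]
    assert len(peps) == len(ic50s)
    preds = tuple(BindingPrediction(p, a, ic)
                  for a in alleles for p, ic in zip(peps, ic50s))
    return [NeoantigenRecord(v, preds, rna_count)]


class TestNeoantigenLoad:
    def test_no_records_zero_load(self):
        assert neoantigen_load([], NeoantigenParams()) == 0

    def test_three_distinct_peptides_load_three(self):
        records = _records()
        assert neoantigen_load(records, NeoantigenParams()) == 3

    def test_counting_units(self):
        records = _records(alleles=("HLA-A*02:01", "HLA-B*07:02"))
        assert neoantigen_load(
            records, NeoantigenParams(load_counting_unit="distinct_peptides")
        ) == 3
        assert neoantigen_load(
            records,
            NeoantigenParams(load_counting_unit="peptide_allele_pairs")) == 6
        assert neoantigen_load(
            records, NeoantigenParams(load_counting_unit="variants")) == 1

    def test_records_require_passing_predictions(self):
        with pytest.raises(InputError):
            NeoantigenRecord(_nssnv(), (), 1)


class TestBuildRecords:
    def test_read_count_filter_drops_unexpressed(self, toy_model):
        v = _nssnv()
        models = {"G1": MODEL}
        recs1, nb1 = build_neoantigen_records(
            [v], models, ["HLA-A*02:01"], toy_model, {("G1", 6): 1},
            NeoantigenParams(min_rna_read_count=1))
        recs2, nb2 = build_neoantigen_records(
            [v], models, ["HLA-A*02:01"], toy_model, {("G1", 6): 1},
            NeoantigenParams(min_rna_read_count=2))
        assert nb1 == nb2            # binder count ignores expression
        assert len(recs2) == 0
        assert neoantigen_load(recs2) == 0

    def test_non_nssnv_rejected(self, toy_model):
        v = _nssnv()
        bad = SomaticVariant(site=v.site, fisher_p=0, tumor_vaf=.2,
                             normal_vaf=0, mutation_class="sSNV")
        with pytest.raises(InputError):
            build_neoantigen_records([bad], {"G1": MODEL}, ["X"], toy_model,
                                     {})

    def test_homozygous_genotype_invariance(self, toy_model):
        """Under distinct-peptide counting, duplicating a homozygous allele
        leaves the load unchanged (fully expressed variant)."""
        v = _nssnv()
        models = {"G1": MODEL}
        rna = {("G1", 6): 5}
        loads = []
        for alleles in (["HLA-A*02:01"], ["HLA-A*02:01", "HLA-A*02:01"]):
            recs, _ = build_neoantigen_records([v], models, alleles,
                                               toy_model, rna)
            loads.append(neoantigen_load(recs))
        assert loads[0] == loads[1]


class TestThresholdMonotonicity:
    def test_load_monotone_in_both_thresholds(self, reference_panel,
                                              small_cohort, toy_model):
        models = {m.gene_symbol: m for m in reference_panel}
        for patient in small_cohort[:3]:
            calls = call_somatic_variants(patient.allele_counts)
            nssnvs = [classify_variant(v, models[v.transcript_id])
                      for v in calls]
            nssnvs = [v for v in nssnvs if v.mutation_class == "nsSNV"]
            prev = None
            for thr in (500.0, 250.0, 50.0):
                recs, _ = build_neoantigen_records(
                    nssnvs, models, patient.hla_alleles, toy_model,
                    patient.rna_read_counts,
                    NeoantigenParams(ic50_threshold_nm=thr))
                load = neoantigen_load(recs)
                assert prev is None or load <= prev
                prev = load
            prev = None
            for min_rc in (1, 2, 5):
                params = NeoantigenParams(min_rna_read_count=min_rc)
                recs, _ = build_neoantigen_records(
                    nssnvs, models, patient.hla_alleles, toy_model,
                    patient.rna_read_counts, params)
                load = neoantigen_load(recs, params)
                assert prev is None or load <= prev
                prev = load


def test_pipeline_conservation(reference_panel, small_cohort, toy_model):
    """records <= nsSNVs <= called variants, per patient."""
    models = {m.gene_symbol: m for m in reference_panel}
    from neoprofiler import CallerParams, NeoantigenParams as NP
    for patient in small_cohort:
        profile, classified, records = profile_patient(
            patient, models, CallerParams(), NP(), toy_model)
        n_nssnv = sum(v.mutation_class == "nsSNV" for v in classified)
        assert len(records) <= n_nssnv <= len(classified)
        assert profile.n_nssnv == n_nssnv


class TestVaccineCandidates:
    def _expressed_records(self):
        v = _nssnv()
        protein = MODEL.protein
        pos = 8
        sub = "E" if protein[pos - 1] != "E" else "K"
        mut = protein[:pos - 1] + sub + protein[pos:]
        peps = enumerate_mutant_peptides(mut, pos, (8, 9),
                                         wildtype_protein=protein,
                                         source_variant=v)
        assert len(peps) >= 10
        preds = tuple(
            BindingPrediction(p, "HLA-A*02:06", 100.0 + 10 * i)
            for i, p in enumerate(peps))
        return [NeoantigenRecord(v, preds, 3)]

    def test_no_record_meets_read_count(self):
        records = _records(rna_count=1)
        assert select_vaccine_candidates(records, "HLA-A*02:01",
                                         min_read_count=2) == []

    def test_top_k_limits_output(self):
        records = self._expressed_records()
        out = select_vaccine_candidates(records, "HLA-A*02:06", top_k=10)
        assert len(out) == 10
        ic50s = [c.ic50_nm for c in out]
        assert ic50s == sorted(ic50s)
        assert all(c.wildtype_sequence for c in out)

    def test_equal_ic50_ties_broken_lexicographically(self):
        v = _nssnv()
        from neoprofiler import MutantPeptide
        p1 = MutantPeptide("EAAAAAAA", 0, "AAAAAAAA", v)
        p2 = MutantPeptide("ECCCCCCC", 0, "ACCCCCCC", v)
        preds = (BindingPrediction(p2, "X", 50.0),
                 BindingPrediction(p1, "X", 50.0))
        recs = [NeoantigenRecord(v, preds, 5)]
        out = select_vaccine_candidates(recs, "X")
        assert [c.sequence for c in out] == ["EAAAAAAA", "ECCCCCCC"]

    def test_unknown_allele_rejected(self):
        with pytest.raises(InputError):
            select_vaccine_candidates(self._expressed_records(), "HLA-Z*01:01",
                                      patient_alleles=["HLA-A*02:06"])
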