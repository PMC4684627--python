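"""Molecular-diagnosis assignment and cohort yields."""

import numpy as np
import pytest

from hlhpanel.diagnosis import (
    InheritanceModel,
    classify_cohort,
    classify_patient,
    cohort_yield,
    trigger_table,
)
from hlhpanel.model import (
    AnnotatedVariant,
    Consequence,
    DeletionCall,
    ExternalAllele,
    GenotypeCall,
    PatientRecord,
    Zygosity,
)
from hlhpanel.panel import default_genes
from hlhpanel.synthetic_data import SimulationConfig, simulate_cohort
from hlhpanel.variant_filter import FilterConfig, run_cascade

MODEL = InheritanceModel.from_genes(default_genes())


def var(gene, pos, conseq=Consequence.MISSENSE, chrom=None, damaging=True, hgvs=""):
    chrom = chrom or {"PRF1": "chr10", "XIAP": "chrX", "STX11": "chr6"}.get(gene, "chr1")
    return AnnotatedVariant(
        chrom, pos, "G", "A", gene, conseq, hgvs_c=hgvs,
        sift_pred="deleterious" if damaging else "tolerated",
        polyphen_pred=None if damaging else "benign",
    )


def patient(pid="P1", age=0.5, sex="F", trigger="none"):
    return PatientRecord(pid, age, sex, trigger=trigger)


class TestClassifyPatient:
    def test_homozygous_ar_variant_diagnosed(self):
        v = var("PRF1", 100, hgvs="c.659G>A")
        res = classify_patient(
            patient(), [v], [GenotypeCall("P1", v.key, Zygosity.HOM)], MODEL
        )
        assert (res.status, res.causal_gene, res.disease_label) == (
            "diagnosed", "PRF1", "FHL2",
        )
        assert len(res.causal_variants) == 1

    def test_compound_het_diagnosed(self):
        v1 = var("PRF1", 272, hgvs="c.272C>T")
        v2 = var("PRF1", 1288, hgvs="c.1288G>T")
        gts = [
            GenotypeCall("P1", v1.key, Zygosity.HET),
            GenotypeCall("P1", v2.key, Zygosity.HET),
        ]
        res = classify_patient(patient(), [v1, v2], gts, MODEL)
        assert res.status == "diagnosed" and res.disease_label == "FHL2"
        assert len(res.causal_variants) == 2
        assert "compound" in res.notes

    def test_single_damaging_het_is_vus_only(self):
        v = var("PRF1", 272, hgvs="c.272C>T")
        res = classify_patient(
            patient(), [v], [GenotypeCall("P1", v.key, Zygosity.HET)], MODEL
        )
        assert res.status == "vus_only"

    def test_single_benign_het_is_undiagnosed(self):
        v = var("PRF1", 9, damaging=False)
        res = classify_patient(
            patient(), [v], [GenotypeCall("P1", v.key, Zygosity.HET)], MODEL
        )
        assert res.status == "undiagnosed"

    def test_same_position_het_pair_not_compound(self):
        # two alts at one position are candidate same-allele, flagged
        a = AnnotatedVariant("chr10", 500, "G", "A", "PRF1", Consequence.MISSENSE,
                             sift_pred="deleterious")
        b = AnnotatedVariant("chr10", 500, "G", "T", "PRF1", Consequence.MISSENSE,
                             sift_pred="deleterious")
        gts = [
            GenotypeCall("P1", a.key, Zygosity.HET),
            GenotypeCall("P1", b.key, Zygosity.HET),
        ]
        res = classify_patient(patient(), [a, b], gts, MODEL)
        assert res.status != "diagnosed"
        assert "same-allele" in res.notes

    def test_hemizygous_xl_male_diagnosed(self):
        v = var("XIAP", 877, hgvs="c.877G>A")
        res = classify_patient(
            patient(sex="M"), [v], [GenotypeCall("P1", v.key, Zygosity.HEMI)], MODEL
        )
        assert (res.status, res.disease_label) == ("diagnosed", "XLP2")

    def test_female_xl_het_is_carrier_not_diagnosed(self):
        v = var("XIAP", 877)
        res = classify_patient(
            patient(sex="F"), [v], [GenotypeCall("P1", v.key, Zygosity.HET)], MODEL
        )
        assert res.status != "diagnosed"

    def test_deletion_calls_complete_diagnoses(self):
        hemi = DeletionCall("P1", "XIAP", "XIAP_amp001", "XIAP_amp013", 13,
                            "hemizygous", 0.002)
        res = classify_patient(patient(sex="M"), [], [], MODEL, deletion_calls=[hemi])
        assert (res.status, res.disease_label) == ("diagnosed", "XLP2")
        hom = DeletionCall("P1", "STX11", "STX11_amp003", "STX11_amp008", 6,
                           "homozygous", 0.004)
        res = classify_patient(patient(sex="F"), [], [], MODEL, deletion_calls=[hom])
        assert (res.status, res.disease_label) == ("diagnosed", "FHL4")

    def test_external_allele_completes_compound_het(self):
        v = var("UNC13D", 569, Consequence.SPLICE_REGION, chrom="chr17")
        ext = ExternalAllele("P1", "UNC13D", "intronic inversion", Zygosity.HET)
        res = classify_patient(
            patient(), [v], [GenotypeCall("P1", v.key, Zygosity.HET)], MODEL,
            external_alleles=[ext],
        )
        assert (res.status, res.disease_label) == ("diagnosed", "FHL3")

    def test_background_polymorphism_never_changes_status(self):
        v = var("PRF1", 100)
        bg = var("LYST", 50, damaging=False)
        gts = [
            GenotypeCall("P1", v.key, Zygosity.HOM),
            GenotypeCall("P1", bg.key, Zygosity.HET),
        ]
        with_bg = classify_patient(patient(), [v, bg], gts, MODEL)
        without = classify_patient(patient(), [v], gts[:1], MODEL)
        assert (with_bg.status, with_bg.causal_gene) == (without.status, without.causal_gene)

    def test_planted_truth_recovered_completely(self, panel):
        genes, amplicons = panel
        cfg = SimulationConfig(seed=23, n_samples=40)
        variants, genotypes, patients, truth = simulate_cohort(genes, amplicons, cfg)
        survivors, _ = run_cascade(variants, FilterConfig(), mode="patient")
        keys = {v.key for v in survivors}
        kept = [g for g in genotypes if g.variant_key in keys]
        model = InheritanceModel.from_genes(genes)
        results = classify_cohort(patients, survivors, kept, model)
        for r in results:
            assert r.status == truth.labels[r.patient_id]["status"]
            if r.status == "diagnosed":
                assert r.causal_gene == truth.labels[r.patient_id]["gene"]
                assert 1 <= len(r.causal_variants) <= 2


class TestCohortYield:
    def _results(self, statuses):
        return [
            type("R", (), {"patient_id": pid, "status": s})()
            for pid, s in statuses.items()
        ]

    def test_overall_and_binned_percentages(self):
        patients = (
            [patient(f"D{i}", 0.5) for i in range(13)]
            + [patient(f"D{i}", 3.0) for i in range(13, 22)]
            + [patient(f"U{i}", 0.5) for i in range(7)]
            + [patient(f"U{i}", 30.0) for i in range(7, 36)]
        )
        statuses = {p.id: ("diagnosed" if p.id.startswith("D") else "undiagnosed")
                    for p in patients}
        y = cohort_yield(self._results(statuses), patients)
        assert y.overall == (22, 58)
        assert round(y.pct(y.overall)) == 38
        assert y.per_bin["0-1"] == (13, 20)
        assert y.pct(y.per_bin["0-1"]) == pytest.approx(65.0)

    def test_unknown_age_excluded_from_bins_only(self):
        pats = [patient("a", None), patient("b", 0.5)]
        statuses = {"a": "diagnosed", "b": "undiagnosed"}
        y = cohort_yield(self._results(statuses), pats)
        assert y.overall == (1, 2)
        assert sum(d for _, d in y.per_bin.values()) == 1
        assert y.pediatric == (1, 2)  # unknown age counted pediatric

    def test_empty_cohort_no_division_error(self):
        y = cohort_yield([], [])
        assert y.overall == (0, 0)
        assert np.isnan(y.pct(y.overall))

    def test_missing_result_is_an_error(self):
        with pytest.raises(ValueError, match="without a diagnosis result"):
            cohort_yield([], [patient("a", 1.0)])


class TestTriggerTable:
    def _mk(self, spec):
        patients, results = [], []
        for i, (status, trig) in enumerate(spec):
            p = patient(f"P{i}", 1.0, trigger=trig)
            patients.append(p)
            results.append(type("R", (), {"patient_id": p.id, "status": status})())
        return results, patients

    def test_published_counts(self):
        spec = (
            [("undiagnosed", "EBV")] * 22 + [("undiagnosed", "none")] * 14
            + [("diagnosed", "other_infection")] * 4 + [("diagnosed", "none")] * 18
        )
        results, patients = self._mk(spec)
        assert trigger_table(results, patients).tolist() == [[22, 14], [4, 18]]

    def test_no_triggers_gives_empty_present_column(self):
        results, patients = self._mk([("diagnosed", "none")] * 3)
        table = trigger_table(results, patients)
        assert table[:, 0].sum() == 0

    def test_order_invariance(self):
        spec = [("undiagnosed", "EBV"), ("diagnosed", "none"), ("vus_only", "malignancy")]
        results, patients = self._mk(spec)
        fwd = trigger_table(results, patients)
        rev = trigger_table(results[::-1], patients[::-1])
        assert (fwd == rev).all()

    def test_unknown_trigger_excluded_by_default(self):
        results, patients = self._mk([("diagnosed", "unknown"), ("diagnosed", "EBV")])
        assert trigger_table(results, patients).sum() == 1
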