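"""Domain types, panel loading and round-trip I/O."""

import pandas as pd
import pytest

from hlhpanel.io import (
    load_coverage,
    load_panel,
    load_patients,
    load_variants,
    read_report,
    write_coverage,
    write_gene_config,
    write_panel_bed,
    write_patients,
    write_report,
    write_variants_tsv,
    write_variants_vcf,
)
from hlhpanel.model import (
    Amplicon,
    AnnotatedVariant,
    Consequence,
    CoverageMatrix,
    GenotypeCall,
    Inheritance,
    PanelGene,
    PatientRecord,
    Zygosity,
    age_bin_of,
    normalize_consequence,
)
from hlhpanel.panel import AMPLICON_COUNTS, default_panel


class TestDomainTypes:
    def test_xl_gene_must_be_on_chrx(self):
        with pytest.raises(ValueError, match="XL"):
            PanelGene("XIAP", "chr3", Inheritance.XL, "XLP2")
        with pytest.raises(ValueError):
            PanelGene("PRF1", "chrX", Inheritance.AR, "FHL2")

    def test_default_panel_composition(self):
        genes, amplicons = default_panel()
        assert len(genes) == 12
        xl = {g.name for g in genes if g.inheritance is Inheritance.XL}
        assert xl == {"SH2D1A", "XIAP", "MAGT1"}
        ids = [a.id for a in amplicons]
        assert len(ids) == len(set(ids))
        assert all(125 <= a.length <= 175 for a in amplicons)
        for gene in genes:
            n = sum(1 for a in amplicons if a.gene == gene.name)
            assert n == AMPLICON_COUNTS[gene.name]

    def test_zero_length_amplicon_rejected(self):
        with pytest.raises(ValueError, match="end"):
            Amplicon("STX11_a1", "STX11", "chr6", 100, 100)

    def test_variant_invariants(self):
        with pytest.raises(ValueError, match="ref equals alt"):
            AnnotatedVariant("chr1", 5, "A", "A", "LYST", Consequence.MISSENSE)
        with pytest.raises(ValueError, match="MAF"):
            AnnotatedVariant("chr1", 5, "A", "G", "LYST", Consequence.MISSENSE, maf=1.5)

    @pytest.mark.parametrize(
        "age,expected",
        [(0.0, "0-1"), (0.9, "0-1"), (1.0, "1-5"), (11.9, "5-12"), (16, "12-18"),
         (18.0, "18+"), (70, "18+"), (None, None)],
    )
    def test_age_bins(self, age, expected):
        assert age_bin_of(age) == expected

    def test_dialect_normalization(self):
        assert normalize_consequence("missense_variant") is Consequence.MISSENSE
        assert normalize_consequence("splice_acceptor_variant") is Consequence.SPLICE_ACCEPTOR
        assert normalize_consequence("weird_new_term") is Consequence.OTHER


class TestPanelIO:
    def test_bed_round_trip_and_counts(self, tmp_path, panel):
        genes, amplicons = panel
        bed = tmp_path / "panel.bed"
        cfg = tmp_path / "genes.yaml"
        write_panel_bed(amplicons, bed)
        write_gene_config(genes, cfg)
        genes2, amplicons2 = load_panel(bed, cfg)
        assert [g.name for g in genes2] == [g.name for g in genes]
        assert [(a.id, a.start, a.end) for a in amplicons2] == [
            (a.id, a.start, a.end) for a in amplicons
        ]

    def test_355_interval_bed(self, tmp_path, genes):
        # an alternative design of 355 primer pairs loads intact
        bed = tmp_path / "p.bed"
        with open(bed, "w") as fh:
            for i in range(355):
                g = genes[i % 12]
                fh.write(f"{g.chromosome}\t{i * 200}\t{i * 200 + 150}\t{g.name}_x{i}\n")
        cfg = tmp_path / "genes.yaml"
        write_gene_config(genes, cfg)
        got_genes, got_amps = load_panel(bed, cfg)
        assert len(got_amps) == 355
        assert len(got_genes) == 12

    def test_empty_bed_ok(self, tmp_path, genes):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        cfg = tmp_path / "genes.yaml"
        write_gene_config(genes, cfg)
        _, amps = load_panel(bed, cfg)
        assert amps == []

    def test_malformed_and_unknown_gene_lines(self, tmp_path, genes):
        cfg = tmp_path / "genes.yaml"
        write_gene_config(genes, cfg)
        bad = tmp_path / "bad.bed"
        bad.write_text("chr6\t100\t100\tSTX11_a1\n")
        with pytest.raises(ValueError, match="malformed interval"):
            load_panel(bad, cfg)
        unknown = tmp_path / "unk.bed"
        unknown.write_text("chr7\t1\t200\tNOTAGENE_a1\n")
        with pytest.raises(ValueError, match="NOTAGENE"):
            load_panel(unknown, cfg)


def _toy_variants():
    v1 = AnnotatedVariant("chr10", 100, "G", "A", "PRF1", Consequence.MISSENSE,
                          hgvs_c="c.100G>A", maf=0.001, sift_pred="deleterious")
    v2 = AnnotatedVariant("chrX", 555, "C", "T", "XIAP", Consequence.STOP_GAINED)
    gts = [
        GenotypeCall("S1", v1.key, Zygosity.HOM),
        GenotypeCall("S2", v1.key, Zygosity.HET),
        GenotypeCall("S1", v2.key, Zygosity.HEMI),
    ]
    return [v1, v2], gts


class TestVariantIO:
    def test_tsv_round_trip(self, tmp_path):
        variants, gts = _toy_variants()
        path = tmp_path / "v.tsv"
        write_variants_tsv(variants, gts, path)
        got_v, got_g = load_variants(path, sex={"S1": "M", "S2": "F"})
        assert {v.key for v in got_v} == {v.key for v in variants}
        assert {(g.sample_id, g.variant_key, g.zygosity) for g in got_g} == {
            (g.sample_id, g.variant_key, g.zygosity) for g in gts
        }
        got = {v.key: v for v in got_v}
        orig = variants[0]
        assert got[orig.key].maf == pytest.approx(0.001)
        assert got[orig.key].sift_pred == "deleterious"

    def test_hemi_requires_male_on_x(self, tmp_path):
        v = AnnotatedVariant("chr10", 9, "G", "T", "PRF1", Consequence.MISSENSE)
        path = tmp_path / "v.tsv"
        write_variants_tsv([v], [GenotypeCall("S1", v.key, Zygosity.HEMI)], path)
        with pytest.raises(ValueError, match="hemizygous"):
            load_variants(path, sex={"S1": "M"})

    def test_246_row_table_loads_fully(self, tmp_path):
        # a cohort-scale table: 246 distinct annotated variants
        rows = []
        for i in range(246):
            rows.append({
                "chrom": "chr17", "pos": 1000 + i, "ref": "A", "alt": "G",
                "gene": "UNC13D", "consequence": "missense", "hgvs_c": "",
                "hgvs_p": "", "maf": 0.01, "sift": "", "polyphen": "",
                "cadd": "", "sample": f"S{i % 58}", "zygosity": "het",
            })
        path = tmp_path / "cohort.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        variants, gts = load_variants(path)
        assert len(variants) == 246
        assert len(gts) == 246

    def test_vcf_zygosity_and_round_trip(self, tmp_path):
        variants, gts = _toy_variants()
        path = tmp_path / "v.vcf"
        write_variants_vcf(variants, gts, ["S1", "S2"], path)
        got_v, got_g = load_variants(path, sex={"S1": "M", "S2": "F"})
        assert {v.key for v in got_v} == {v.key for v in variants}
        zyg = {(g.sample_id, g.variant_key): g.zygosity for g in got_g}
        assert zyg[("S1", variants[0].key)] is Zygosity.HOM
        assert zyg[("S1", variants[1].key)] is Zygosity.HEMI  # GT "1", male, chrX

    def test_multiallelic_split_conserves_observations(self, tmp_path):
        path = tmp_path / "ma.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n')
            fh.write('##INFO=<ID=CSQ,Number=A,Type=String,Description="c">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n")
            fh.write(
                "chr10\t77\t.\tG\tA,T\t.\tPASS\tGENE=PRF1;CSQ=missense,stop_gained"
                "\tGT\t1/2\t0/1\n"
            )
        variants, gts = load_variants(path)
        assert len(variants) == 2  # one per alt
        # S1 carries both alts het; S2 one: three (sample, alt) observations
        assert len(gts) == 3
        assert all(g.zygosity is Zygosity.HET for g in gts)

    def test_record_without_consequence_skipped(self, tmp_path):
        path = tmp_path / "nc.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n")
            fh.write("chr10\t77\t.\tG\tA\t.\tPASS\tGENE=PRF1\tGT\t0/1\n")
        variants, gts = load_variants(path)
        assert variants == [] and gts == []


class TestReportsAndTables:
    def test_coverage_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[100.0, 3.0], [250.0, 0.0]], index=["S1", "S2"], columns=["A_a1", "A_a2"]
        )
        m = CoverageMatrix(depth=df)
        path = tmp_path / "cov.tsv"
        write_coverage(m, path)
        got = load_coverage(path)
        pd.testing.assert_frame_equal(got.depth, df, check_names=False)

    def test_negative_depth_rejected(self):
        df = pd.DataFrame([[-1.0]], index=["S1"], columns=["A_a1"])
        with pytest.raises(ValueError):
            CoverageMatrix(depth=df)

    def test_patient_round_trip(self, tmp_path):
        patients = [
            PatientRecord("P1", 0.5, "M", trigger="EBV"),
            PatientRecord("P2", None, "F", consanguinity="yes"),
        ]
        path = tmp_path / "pat.tsv"
        write_patients(patients, path)
        got = load_patients(path)
        assert got == patients

    def test_report_determinism_and_round_trip(self, tmp_path):
        df = pd.DataFrame({"group": ["overall"], "n": [22], "denominator": [58]})
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(df, p1)
        write_report(df, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(read_report(p1), df)
        write_report(df, tmp_path / "a.md", format="md")
        assert "| overall | 22 | 58 |" in (tmp_path / "a.md").read_text()
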