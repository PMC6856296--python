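import random
import warnings

import pytest

from epicohort.cohort_table import (
    CohortLedger,
    CohortVariantRecord,
    FamilyHistory,
    InheritanceMode,
    LedgerParseError,
    LedgerValidationError,
    Segregation,
    Sex,
    Tier,
    VariantAnnotation,
    VariantType,
    Zygosity,
    distinct_patients,
    ledger_from_vcf,
    load_fixture,
    read_ledger,
    write_ledger,
)

from conftest import make_record

PRINTED_HEADER = (
    "P\tS\tGENE\tINH\tZYG\tVFS\tFH\tCLINVAR\tDBSNP\tMAF\tTYPE\tISP\tGERP"
    "\tREFSEQ\tVARIANT\n"
)


def printed_row(p="1", gene="SCN1A", inh="AD", zyg="HT", vfs="DE NOVO",
                fh="-", clinvar="-", dbsnp="-", maf="-", vtype="MISS",
                isp="0.7", gerp="5.0", refseq="NM_1.1", hgvs="c.1A>G",
                sex="F"):
    return "\t".join(
        [p, sex, gene, inh, zyg, vfs, fh, clinvar, dbsnp, maf, vtype, isp,
         gerp, refseq, hgvs]
    ) + "\n"


# ---------------------------------------------------------------------------
# record / ledger validation


class TestRecordValidation:
    def test_requires_patient(self):
        with pytest.raises(LedgerValidationError, match="patient"):
            make_record(patient_ids=[])

    def test_duplicate_patient_within_record(self):
        with pytest.raises(LedgerValidationError, match="duplicate"):
            make_record(patient_ids=["1", "1"])

    @pytest.mark.parametrize("field,value", [("condel_score", 1.2), ("maf", -0.1)])
    def test_score_ranges(self, field, value):
        with pytest.raises(LedgerValidationError):
            make_record(**{field: value})

    def test_hemizygous_requires_x_linked(self):
        with pytest.raises(LedgerValidationError, match="hemizygous"):
            make_record(zygosity=Zygosity.HE)
        make_record(
            zygosity=Zygosity.HE,
            inheritance_mode=frozenset({InheritanceMode.XL}),
        )

    def test_de_novo_excludes_positive_family_history(self):
        with pytest.raises(LedgerValidationError, match="family history"):
            make_record(family_history=FamilyHistory.POSITIVE)

    def test_cnv_has_no_scores(self):
        with pytest.raises(LedgerValidationError, match="CNV"):
            make_record(variant_type=VariantType.CNV)
        make_record(
            variant_type=VariantType.CNV, condel_score=None, gerp_score=None
        )

    def test_ledger_triple_uniqueness(self):
        rec = make_record()
        with pytest.raises(LedgerValidationError, match="duplicate"):
            CohortLedger(records=[rec, make_record()])

    def test_ledger_n_cohort_floor(self):
        with pytest.raises(LedgerValidationError, match="n_cohort"):
            CohortLedger(records=[make_record(patient_ids=["1", "2"])], n_cohort=1)


# ---------------------------------------------------------------------------
# printed dialect


class TestPrintedDialect:
    def test_header_only_is_empty_ledger(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(PRINTED_HEADER)
        ledger = read_ledger(path, dialect="printed")
        assert len(ledger) == 0

    def test_multi_patient_row(self, tmp_path):
        # 3 rows, one listing "1, 2" -> 3 records, 4 distinct patients
        path = tmp_path / "multi.tsv"
        path.write_text(
            PRINTED_HEADER
            + printed_row(p="1, 2", hgvs="c.1A>G")
            + printed_row(p="3", hgvs="c.2A>G")
            + printed_row(p="4", hgvs="c.3A>G")
        )
        ledger = read_ledger(path, dialect="printed")
        assert len(ledger) == 3
        assert distinct_patients(ledger) == {"1", "2", "3", "4"}

    def test_continuation_row_inherits_same_gene_cells(self, tmp_path):
        path = tmp_path / "cont.tsv"
        path.write_text(
            PRINTED_HEADER
            + printed_row(p="9", gene="PCCA", inh="AR", vfs="TRANS")
            + printed_row(p="", sex="", gene="PCCA", inh="", zyg="",
                          vfs="", hgvs="c.2A>G")
            + printed_row(p="", sex="", gene="OTHER", inh="", zyg="",
                          vfs="", hgvs="c.3A>G")
        )
        ledger = read_ledger(path, dialect="printed")
        first, second, third = ledger.records
        assert second.patient_ids == ["9"]
        assert second.segregation is Segregation.IN_TRANS
        assert second.inheritance_mode == {InheritanceMode.AR}
        # gene change: blanks stay absent rather than leaking across genes
        assert third.inheritance_mode == frozenset()
        assert third.segregation is Segregation.NOT_AVAILABLE
        assert third.zygosity is Zygosity.UNKNOWN

    def test_section_headers_assign_tiers(self, tmp_path):
        path = tmp_path / "sections.tsv"
        path.write_text(
            PRINTED_HEADER
            + "INCOMPLETE PENETRANCE\n"
            + printed_row(p="1", vfs="MAT")
            + "DATA FROM PROGENITORS UNAVAILABLE\n"
            + printed_row(p="2", vfs="NA", hgvs="c.9A>G")
        )
        ledger = read_ledger(path, dialect="printed")
        assert ledger.records[0].tier is Tier.VUS_INCOMPLETE_PENETRANCE
        assert ledger.records[1].tier is Tier.VUS_NO_PROGENITOR_DATA

    def test_corrupted_maf_normalized_to_absent(self, tmp_path):
        path = tmp_path / "maf.tsv"
        path.write_text(
            PRINTED_HEADER
            + printed_row(p="1", maf="8.1E+00")
            + printed_row(p="2", maf="8,9E-106", hgvs="c.2A>G")
            + printed_row(p="3", maf="0.007", hgvs="c.3A>G")
        )
        ledger = read_ledger(path, dialect="printed")
        assert ledger.records[0].maf is None
        assert ledger.records[1].maf is None
        assert ledger.records[2].maf == pytest.approx(0.007)
        assert len(ledger.normalizations) == 2

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(PRINTED_HEADER + "only\ttwo\n")
        with pytest.raises(LedgerParseError, match="line 2"):
            read_ledger(path, dialect="printed")

    def test_unknown_token_is_listed(self, tmp_path):
        path = tmp_path / "tok.tsv"
        path.write_text(PRINTED_HEADER + printed_row(vtype="WIBBLE"))
        with pytest.raises(LedgerValidationError, match="WIBBLE"):
            read_ledger(path, dialect="printed")


# ---------------------------------------------------------------------------
# canonical dialect round-trip


class TestCanonicalDialect:
    def test_round_trip_byte_identical(self, tmp_path, table1a):
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_ledger(table1a, f1)
        again = read_ledger(f1, dialect="canonical", n_cohort=table1a.n_cohort)
        write_ledger(again, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert len(again) == len(table1a)

    def test_out_of_range_condel_rejected(self, tmp_path, table1a):
        f1 = tmp_path / "a.tsv"
        write_ledger(table1a, f1)
        text = f1.read_text().replace("\t0.73\t", "\t1.73\t")
        f1.write_text(text)
        with pytest.raises(LedgerValidationError):
            read_ledger(f1, dialect="canonical", n_cohort=246)

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text(PRINTED_HEADER)
        with pytest.raises(ValueError, match="dialect"):
            read_ledger(path, dialect="csv")


# ---------------------------------------------------------------------------
# fixtures


class TestFixtures:
    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            load_fixture("table9Z")

    def test_table1a_integrity(self, table1a):
        assert len(table1a) == 107
        assert len(distinct_patients(table1a)) == 104
        assert len({r.gene for r in table1a}) == 48
        assert all(r.tier is Tier.PATHOGENIC_TABLE for r in table1a)

    def test_table1b_subsection_patients(self, table1b):
        per_tier = {}
        for rec in table1b:
            per_tier.setdefault(rec.tier, set()).update(rec.patient_ids)
        assert len(per_tier[Tier.VUS_FUNCTIONAL_VALIDATION]) == 4
        assert len(per_tier[Tier.VUS_INCOMPLETE_PENETRANCE]) == 8
        assert len(per_tier[Tier.VUS_OLIGOGENIC]) == 6
        assert len(per_tier[Tier.VUS_NO_PROGENITOR_DATA]) == 9

    def test_no_progenitor_records(self, table1b):
        assert (
            sum(1 for r in table1b if r.tier is Tier.VUS_NO_PROGENITOR_DATA)
            == 13
        )

    def test_distinct_patients_order_invariant(self, table1a):
        shuffled = list(table1a.records)
        random.Random(0).shuffle(shuffled)
        permuted = CohortLedger(records=shuffled, n_cohort=table1a.n_cohort)
        assert distinct_patients(permuted) == distinct_patients(table1a)

    def test_distinct_patients_idempotent_union(self):
        ledger = CohortLedger(
            records=[
                make_record(patient_ids=["7"], hgvs="c.1A>G"),
                make_record(patient_ids=["7"], hgvs="c.2A>G"),
            ]
        )
        assert distinct_patients(ledger) == {"7"}

    def test_empty_ledger_distinct_patients(self):
        assert distinct_patients(CohortLedger(records=[], n_cohort=5)) == set()


# ---------------------------------------------------------------------------
# VCF ingest

VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="low qual">
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "cohort.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def _ann(*keys):
    return {
        key: VariantAnnotation(gene=f"GENE{i + 1}")
        for i, key in enumerate(keys)
    }


class TestVcfIngest:
    def test_all_pass_pairs(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t1/1\n"
            "1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\t0/1\n"
            "1\t300\t.\tG\tA\t50\tPASS\t.\tGT\t0/0\t0/1\n",
        )
        ann = _ann(("1", 100, "A", "G"), ("1", 200, "C", "T"), ("1", 300, "G", "A"))
        ledger = ledger_from_vcf(path, ann)
        assert len(ledger) == 6  # 2 samples x 3 variants
        zyg = {
            (rec.patient_ids[0], rec.hgvs): rec.zygosity for rec in ledger
        }
        assert zyg[("S1", "1:g.100A>G")] is Zygosity.HT
        assert zyg[("S2", "1:g.100A>G")] is Zygosity.HO

    def test_non_pass_row_excluded(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0/1\n"
            "1\t200\t.\tC\tT\t50\tq10\t.\tGT\t0/1\t0/1\n",
        )
        ann = _ann(("1", 100, "A", "G"), ("1", 200, "C", "T"))
        ledger = ledger_from_vcf(path, ann)
        assert len(ledger) == 2
        assert all("200" not in rec.hgvs for rec in ledger)

    def test_missing_annotation_warns_and_skips(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0/1\n"
            "1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\t0/1\n",
        )
        ann = _ann(("1", 100, "A", "G"))
        with pytest.warns(UserWarning, match="no annotation"):
            ledger = ledger_from_vcf(path, ann)
        assert len(ledger) == 2
        assert ledger.normalizations == ["skipped variants without annotation: 1"]
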