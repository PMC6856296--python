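"""Cohort variant ledgers: data model, TSV dialects, fixtures, VCF ingest.

A *ledger* is an ordered collection of variant records for a screened cohort.
Two on-disk dialects are supported:

``canonical``
    One record per line, explicit columns, semicolon-separated patient ids.
    Written by :func:`write_ledger`; round-trips byte-identically.
``printed``
    Mirrors the layout of a published cohort table: continuation rows with a
    blank patient cell extend the previous patient, section-header lines set
    the tier of subsequent rows, and several null markers / corrupted
    frequency tokens are normalized on read.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Sex",
    "Zygosity",
    "Segregation",
    "FamilyHistory",
    "VariantType",
    "InheritanceMode",
    "Tier",
    "CohortVariantRecord",
    "CohortLedger",
    "LedgerParseError",
    "LedgerValidationError",
    "read_ledger",
    "write_ledger",
    "load_fixture",
    "distinct_patients",
    "ledger_from_vcf",
    "FIXTURE_N_COHORT",
]

#: Total screened patients behind the packaged fixtures.
FIXTURE_N_COHORT = 246


class LedgerParseError(ValueError):
    """A ledger file could not be parsed; carries the offending line number."""


class LedgerValidationError(ValueError):
    """A record or ledger violates a domain invariant."""


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class Zygosity(str, Enum):
    HT = "HT"
    HO = "HO"
    HE = "HE"
    MOS = "MOS"
    UNKNOWN = "unknown"


class Segregation(str, Enum):
    DE_NOVO = "DE_NOVO"
    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    IN_TRANS = "IN_TRANS"
    NOT_AVAILABLE = "NOT_AVAILABLE"
    ONGOING = "ONGOING"


class FamilyHistory(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class VariantType(str, Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE = "SPLICE"
    CNV = "CNV"
    INFRAME_INDEL = "INFRAME_INDEL"


class InheritanceMode(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


class Tier(str, Enum):
    PATHOGENIC_TABLE = "PATHOGENIC_TABLE"
    VUS_FUNCTIONAL_VALIDATION = "VUS_FUNCTIONAL_VALIDATION"
    VUS_INCOMPLETE_PENETRANCE = "VUS_INCOMPLETE_PENETRANCE"
    VUS_OLIGOGENIC = "VUS_OLIGOGENIC"
    VUS_NO_PROGENITOR_DATA = "VUS_NO_PROGENITOR_DATA"


@dataclass
class CohortVariantRecord:
    """One ledger row: a variant observed in one or more patients.

    A row listing several patients (a shared variant) is a single record
    whose ``patient_ids`` has length > 1; it counts once for variant totals
    and once per id for patient totals.
    """

    patient_ids: list[str]
    gene: str
    hgvs: str
    sex: Sex = Sex.UNKNOWN
    inheritance_mode: frozenset[InheritanceMode] = frozenset()
    zygosity: Zygosity = Zygosity.UNKNOWN
    segregation: Segregation = Segregation.NOT_AVAILABLE
    family_history: FamilyHistory = FamilyHistory.UNKNOWN
    clinvar_label: Optional[str] = None
    dbsnp_id: Optional[str] = None
    maf: Optional[float] = None
    variant_type: VariantType = VariantType.MISSENSE
    condel_score: Optional[float] = None
    gerp_score: Optional[float] = None
    refseq: str = ""
    tier: Optional[Tier] = None

    def __post_init__(self) -> None:
        self.inheritance_mode = frozenset(self.inheritance_mode)
        self.validate()

    def validate(self) -> None:
        if not self.patient_ids:
            raise LedgerValidationError("record has no patient identifiers")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise LedgerValidationError(
                f"duplicate patient ids within record: {self.patient_ids}"
            )
        if not self.gene:
            raise LedgerValidationError("record has no gene symbol")
        for name, value in (("condel_score", self.condel_score), ("maf", self.maf)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise LedgerValidationError(
                    f"{name}={value!r} outside [0, 1] for gene {self.gene}"
                )
        if (
            self.zygosity is Zygosity.HE
            and InheritanceMode.XL not in self.inheritance_mode
        ):
            raise LedgerValidationError(
                f"hemizygous record in non-X-linked gene {self.gene}"
            )
        if (
            self.segregation is Segregation.DE_NOVO
            and self.family_history is FamilyHistory.POSITIVE
        ):
            raise LedgerValidationError(
                f"de novo record with positive family history ({self.gene})"
            )
        if self.variant_type is VariantType.CNV and (
            self.condel_score is not None or self.gerp_score is not None
        ):
            raise LedgerValidationError(
                f"CNV record carries point-variant scores ({self.gene})"
            )


@dataclass
class CohortLedger:
    """Ordered variant records plus the size of the screened cohort."""

    records: list[CohortVariantRecord]
    n_cohort: int = 0

    #: Normalizations applied while reading (printed dialect only).
    normalizations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cohort <= 0:
            self.n_cohort = max(1, len(distinct_patients(self)))
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            for pid in rec.patient_ids:
                key = (pid, rec.gene, rec.hgvs)
                if key in seen:
                    raise LedgerValidationError(
                        f"duplicate (patient, gene, hgvs) triple: {key}"
                    )
                seen.add(key)
        n_distinct = len(distinct_patients(self))
        if self.n_cohort < n_distinct:
            raise LedgerValidationError(
                f"n_cohort={self.n_cohort} < {n_distinct} distinct patients"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def distinct_patients(ledger: CohortLedger) -> set[str]:
    """Union of patient identifiers across all records."""
    out: set[str] = set()
    for rec in ledger.records:
        out.update(rec.patient_ids)
    return out


# ---------------------------------------------------------------------------
# token parsing

_ABSENT = {"", "-", "–", "NA", "N/A", "ND", "."}

_SEGREGATION_TOKENS = {
    "DE NOVO": Segregation.DE_NOVO,
    "DE_NOVO": Segregation.DE_NOVO,
    "MAT": Segregation.MATERNAL,
    "MATERNAL": Segregation.MATERNAL,
    "PAT": Segregation.PATERNAL,
    "PATERNAL": Segregation.PATERNAL,
    "TRANS": Segregation.IN_TRANS,
    "IN_TRANS": Segregation.IN_TRANS,
    "NA": Segregation.NOT_AVAILABLE,
    "NOT_AVAILABLE": Segregation.NOT_AVAILABLE,
    "EN CURSO": Segregation.ONGOING,
    "ONGOING": Segregation.ONGOING,
}

_TYPE_TOKENS = {
    "MISS": VariantType.MISSENSE,
    "MISSENSE": VariantType.MISSENSE,
    "NON": VariantType.NONSENSE,
    "NONSENSE": VariantType.NONSENSE,
    "FS": VariantType.FRAMESHIFT,
    "FRAMESHIFT": VariantType.FRAMESHIFT,
    "SP": VariantType.SPLICE,
    "SPL": VariantType.SPLICE,
    "SPLICE": VariantType.SPLICE,
    "CNV": VariantType.CNV,
    "NONFS": VariantType.INFRAME_INDEL,
    "INFRAME_INDEL": VariantType.INFRAME_INDEL,
}

_INH_TOKENS = {
    "AD": InheritanceMode.AD,
    "AR": InheritanceMode.AR,
    "XL": InheritanceMode.XL,
    "XLR": InheritanceMode.XL,
    "XLD": InheritanceMode.XL,
}

# MAF exponents below this are typographic corruption, not frequencies.
_MIN_PLAUSIBLE_MAF = 1e-30


def _is_absent(token: str) -> bool:
    return token.strip() in _ABSENT


def _parse_enum(token: str, table: Mapping[str, object], what: str, lineno: int):
    key = token.strip().upper()
    if key not in table:
        raise LedgerValidationError(
            f"line {lineno}: unknown {what} token {token!r}"
        )
    return table[key]


def _parse_inheritance(token: str, lineno: int) -> frozenset[InheritanceMode]:
    if _is_absent(token):
        return frozenset()
    modes = set()
    for part in re.split(r"[,/]", token):
        part = part.strip()
        if part:
            modes.add(_parse_enum(part, _INH_TOKENS, "inheritance", lineno))
    return frozenset(modes)


def _parse_maf_printed(
    token: str, lineno: int, notes: list[str]
) -> Optional[float]:
    """Printed-dialect MAF: tolerate comma decimals and corrupted exponents."""
    if _is_absent(token):
        return None
    cleaned = token.strip().replace(",", ".")
    try:
        value = float(cleaned)
    except ValueError:
        raise LedgerParseError(f"line {lineno}: unparseable MAF {token!r}") from None
    if value > 1.0 or (0.0 < value < _MIN_PLAUSIBLE_MAF):
        notes.append(
            f"line {lineno}: corrupted MAF {token!r} normalized to absent"
        )
        return None
    if value < 0.0:
        raise LedgerValidationError(f"line {lineno}: negative MAF {token!r}")
    return value


def _parse_float(token: str, lineno: int, what: str) -> Optional[float]:
    if _is_absent(token):
        return None
    try:
        return float(token.strip().replace(",", "."))
    except ValueError:
        raise LedgerParseError(
            f"line {lineno}: unparseable {what} {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# printed dialect

_PRINTED_COLUMNS = 15

_SECTION_TIERS = (
    ("FUNCTIONAL VALIDATION", Tier.VUS_FUNCTIONAL_VALIDATION),
    ("INCOMPLETE PENETRANCE", Tier.VUS_INCOMPLETE_PENETRANCE),
    ("OLIGOGENIC", Tier.VUS_OLIGOGENIC),
    ("PROGENITORS", Tier.VUS_NO_PROGENITOR_DATA),
)


def _section_tier(line: str) -> Optional[Tier]:
    upper = line.upper()
    for needle, tier in _SECTION_TIERS:
        if needle in upper:
            return tier
    return None


def _read_printed(
    lines: Iterable[str],
    default_tier: Optional[Tier],
    n_cohort: Optional[int],
) -> CohortLedger:
    notes: list[str] = []
    records: list[CohortVariantRecord] = []
    tier = default_tier
    prev: Optional[CohortVariantRecord] = None

    it = iter(enumerate(lines, start=1))
    try:
        _, header = next(it)
    except StopIteration:
        raise LedgerParseError("empty file: missing header") from None
    if header.split("\t")[0].strip().upper() != "P":
        raise LedgerParseError("line 1: not a printed-dialect header")

    for lineno, raw in it:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            section = _section_tier(fields[0])
            if section is None:
                raise LedgerParseError(
                    f"line {lineno}: unrecognized section header {fields[0]!r}"
                )
            tier = section
            continue
        if len(fields) != _PRINTED_COLUMNS:
            raise LedgerParseError(
                f"line {lineno}: expected {_PRINTED_COLUMNS} columns, "
                f"got {len(fields)}"
            )
        (p, s, gene, inh, zyg, vfs, fh, clinvar, dbsnp, maf, vtype, isp, gerp,
         refseq, hgvs) = (f.strip() for f in fields)

        continuation = _is_absent(p)
        if continuation:
            if prev is None:
                raise LedgerParseError(
                    f"line {lineno}: continuation row before any patient row"
                )
            patient_ids = list(prev.patient_ids)
            sex = prev.sex
        else:
            patient_ids = [t.strip() for t in p.split(",") if t.strip()]
            sex = Sex.UNKNOWN if _is_absent(s) else _parse_enum(
                s, {"F": Sex.F, "M": Sex.M}, "sex", lineno
            )

        gene = gene.upper()
        same_gene = continuation and prev is not None and prev.gene == gene

        if _is_absent(inh):
            modes = prev.inheritance_mode if same_gene else frozenset()
        else:
            modes = _parse_inheritance(inh, lineno)
        if _is_absent(zyg):
            zygosity = prev.zygosity if same_gene else Zygosity.UNKNOWN
        else:
            zygosity = _parse_enum(
                zyg, {z.name: z for z in Zygosity if z is not Zygosity.UNKNOWN},
                "zygosity", lineno,
            )
        if _is_absent(vfs):
            segregation = (
                prev.segregation if same_gene else Segregation.NOT_AVAILABLE
            )
        else:
            segregation = _parse_enum(vfs, _SEGREGATION_TOKENS, "segregation", lineno)

        if fh == "+":
            family_history = FamilyHistory.POSITIVE
        elif fh in {"-", "–"}:
            family_history = FamilyHistory.NEGATIVE
        else:
            family_history = FamilyHistory.UNKNOWN

        rec = CohortVariantRecord(
            patient_ids=patient_ids,
            sex=sex,
            gene=gene,
            inheritance_mode=modes,
            zygosity=zygosity,
            segregation=segregation,
            family_history=family_history,
            clinvar_label=None if _is_absent(clinvar) else clinvar,
            dbsnp_id=None if _is_absent(dbsnp) else dbsnp,
            maf=_parse_maf_printed(maf, lineno, notes),
            variant_type=_parse_enum(vtype, _TYPE_TOKENS, "variant type", lineno),
            condel_score=_parse_float(isp, lineno, "CONDEL"),
            gerp_score=_parse_float(gerp, lineno, "GERP"),
            refseq=refseq,
            hgvs=hgvs,
            tier=tier,
        )
        records.append(rec)
        prev = rec

    ledger = CohortLedger(records=records, n_cohort=n_cohort or 0)
    ledger.normalizations = notes
    return ledger


# ---------------------------------------------------------------------------
# canonical dialect

_CANONICAL_HEADER = [
    "patient_ids", "sex", "gene", "inheritance_mode", "zygosity",
    "segregation", "family_history", "clinvar", "dbsnp", "maf",
    "variant_type", "condel", "gerp", "refseq", "hgvs", "tier",
]


def _fmt_float(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def _read_canonical(lines: Iterable[str], n_cohort: Optional[int]) -> CohortLedger:
    it = iter(enumerate(lines, start=1))
    try:
        _, header = next(it)
    except StopIteration:
        raise LedgerParseError("empty file: missing header") from None
    cols = header.rstrip("\n").split("\t")
    if cols != _CANONICAL_HEADER:
        raise LedgerParseError("line 1: header does not match canonical dialect")

    records = []
    for lineno, raw in it:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_CANONICAL_HEADER):
            raise LedgerParseError(
                f"line {lineno}: expected {len(_CANONICAL_HEADER)} columns, "
                f"got {len(fields)}"
            )
        row = dict(zip(_CANONICAL_HEADER, fields))
        maf = _parse_float(row["maf"], lineno, "maf")
        condel = _parse_float(row["condel"], lineno, "condel")
        if maf is not None and not 0.0 <= maf <= 1.0:
            raise LedgerValidationError(
                f"line {lineno}: maf {maf} outside [0, 1]"
            )
        if condel is not None and not 0.0 <= condel <= 1.0:
            raise LedgerValidationError(
                f"line {lineno}: condel {condel} outside [0, 1]"
            )
        records.append(
            CohortVariantRecord(
                patient_ids=[t for t in row["patient_ids"].split(";") if t],
                sex=_parse_enum(
                    row["sex"], {s.value.upper(): s for s in Sex}, "sex", lineno
                ),
                gene=row["gene"],
                inheritance_mode=_parse_inheritance(
                    row["inheritance_mode"], lineno
                ),
                zygosity=_parse_enum(
                    row["zygosity"],
                    {z.value.upper(): z for z in Zygosity},
                    "zygosity",
                    lineno,
                ),
                segregation=_parse_enum(
                    row["segregation"], _SEGREGATION_TOKENS, "segregation", lineno
                ),
                family_history=_parse_enum(
                    row["family_history"],
                    {f.value.upper(): f for f in FamilyHistory},
                    "family history",
                    lineno,
                ),
                clinvar_label=row["clinvar"] or None,
                dbsnp_id=row["dbsnp"] or None,
                maf=maf,
                variant_type=_parse_enum(
                    row["variant_type"], _TYPE_TOKENS, "variant type", lineno
                ),
                condel_score=condel,
                gerp_score=_parse_float(row["gerp"], lineno, "gerp"),
                refseq=row["refseq"],
                hgvs=row["hgvs"],
                tier=Tier(row["tier"]) if row["tier"] else None,
            )
        )
    return CohortLedger(records=records, n_cohort=n_cohort or 0)


def read_ledger(
    path: str | Path,
    dialect: str = "canonical",
    *,
    default_tier: Optional[Tier] = None,
    n_cohort: Optional[int] = None,
) -> CohortLedger:
    """Read a validated ledger from ``path``.

    Parameters
    ----------
    path
        TSV file in the requested dialect.
    dialect
        ``"canonical"`` or ``"printed"``.
    default_tier
        Printed dialect only: tier of rows preceding any section header.
    n_cohort
        Total screened patients; defaults to the distinct-patient count.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        lines = handle.readlines()
    if dialect == "printed":
        return _read_printed(lines, default_tier, n_cohort)
    if dialect == "canonical":
        return _read_canonical(lines, n_cohort)
    raise ValueError(f"unknown ledger dialect {dialect!r}")


def write_ledger(ledger: CohortLedger, path: str | Path) -> None:
    """Write ``ledger`` in the canonical dialect (UTF-8 TSV)."""
    path = Path(path)
    out = ["\t".join(_CANONICAL_HEADER)]
    for rec in ledger.records:
        out.append(
            "\t".join(
                [
                    ";".join(rec.patient_ids),
                    rec.sex.value,
                    rec.gene,
                    ",".join(sorted(m.value for m in rec.inheritance_mode)),
                    rec.zygosity.value,
                    rec.segregation.value,
                    rec.family_history.value,
                    rec.clinvar_label or "",
                    rec.dbsnp_id or "",
                    _fmt_float(rec.maf),
                    rec.variant_type.value,
                    _fmt_float(rec.condel_score),
                    _fmt_float(rec.gerp_score),
                    rec.refseq,
                    rec.hgvs,
                    rec.tier.value if rec.tier else "",
                ]
            )
        )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# fixtures

_FIXTURES = {
    "table1A": ("table1A.tsv", Tier.PATHOGENIC_TABLE),
    "table1B": ("table1B.tsv", None),
}


def load_fixture(name: str) -> CohortLedger:
    """Load a packaged cohort-table transcription.

    ``table1A`` is the pathogenic/likely-pathogenic table (all records tier
    ``PATHOGENIC_TABLE``); ``table1B`` the uncertain-significance table whose
    four section headers assign the VUS tiers. See
    ``data/transcription_notes.txt`` for the normalizations applied during
    transcription.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}"
        )
    filename, tier = _FIXTURES[name]
    ref = resources.files("epicohort.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return read_ledger(
            path, dialect="printed", default_tier=tier, n_cohort=FIXTURE_N_COHORT
        )


# ---------------------------------------------------------------------------
# VCF ingest

@dataclass(frozen=True)
class VariantAnnotation:
    """Caller-supplied annotation for one VCF site."""

    gene: str
    variant_type: VariantType = VariantType.MISSENSE
    condel_score: Optional[float] = None
    gerp_score: Optional[float] = None
    maf: Optional[float] = None


def ledger_from_vcf(
    vcf_path: str | Path,
    annotations: Mapping[tuple[str, int, str, str], VariantAnnotation],
    *,
    n_cohort: Optional[int] = None,
) -> CohortLedger:
    """Build a ledger from an annotated VCF.

    One record is emitted per (sample, variant) pair for every variant whose
    FILTER is PASS/missing. ``annotations`` maps
    ``(chrom, pos, ref, alt)`` to :class:`VariantAnnotation`; variants absent
    from the mapping are skipped with one warning each. Segregation is set to
    ``NOT_AVAILABLE`` and tier left unassigned.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is a hard dep in CI
        raise RuntimeError("cyvcf2 is required for VCF ingest") from exc

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[CohortVariantRecord] = []
    n_skipped = 0
    for variant in vcf:
        if variant.FILTER is not None:  # cyvcf2: None means PASS or '.'
            continue
        alt = variant.ALT[0] if variant.ALT else ""
        key = (variant.CHROM, variant.POS, variant.REF, alt)
        ann = annotations.get(key)
        if ann is None:
            n_skipped += 1
            warnings.warn(
                f"no annotation for variant {key}; skipped", stacklevel=2
            )
            continue
        hgvs = f"{variant.CHROM}:g.{variant.POS}{variant.REF}>{alt}"
        gt_types = variant.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        for sample, gt in zip(samples, gt_types):
            zygosity = {1: Zygosity.HT, 3: Zygosity.HO}.get(
                int(gt), Zygosity.UNKNOWN
            )
            records.append(
                CohortVariantRecord(
                    patient_ids=[sample],
                    gene=ann.gene.upper(),
                    hgvs=hgvs,
                    zygosity=zygosity,
                    segregation=Segregation.NOT_AVAILABLE,
                    maf=ann.maf,
                    variant_type=ann.variant_type,
                    condel_score=ann.condel_score,
                    gerp_score=ann.gerp_score,
                    refseq=variant.CHROM,
                )
            )
    ledger = CohortLedger(records=records, n_cohort=n_cohort or 0)
    ledger.normalizations = [f"skipped variants without annotation: {n_skipped}"]
    return ledger
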