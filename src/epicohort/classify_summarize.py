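"""Prioritization filters, tier-assignment rules, and cohort summaries.

The tier rules implement only the study's explicit segregation / frequency
rules (de novo in a dominant or X-linked gene; recessive biallelic; inherited
from an unaffected progenitor or non-zero population frequency; missing
progenitor data). They are deliberately NOT an ACMG evidence engine, and the
tier names differ from ACMG terms to avoid conflation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohort_table import (
    CohortLedger,
    CohortVariantRecord,
    InheritanceMode,
    Segregation,
    FamilyHistory,
    Tier,
    VariantType,
    Zygosity,
    distinct_patients,
)

__all__ = [
    "FrequencyProfile",
    "AssignedTier",
    "TierAssignment",
    "CohortSummary",
    "DeNovoFraction",
    "prioritize",
    "assign_tier",
    "summarize_cohort",
    "de_novo_fraction",
    "breakdowns",
    "gene_modes",
    "audit_classification",
]

DEFAULT_MAF_THRESHOLD = 0.01

_UNAVAILABLE_SEGREGATION = {Segregation.NOT_AVAILABLE, Segregation.ONGOING}
_INHERITED_SEGREGATION = {Segregation.MATERNAL, Segregation.PATERNAL}
_DOMINANT_OR_XL = {InheritanceMode.AD, InheritanceMode.XL}


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-database minor allele frequencies for one variant."""

    thousand_genomes: Optional[float] = None
    exac: Optional[float] = None
    evs: Optional[float] = None
    gnomad: Optional[float] = None
    in_house: Optional[float] = None

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")

    def present(self) -> list[float]:
        return [v for v in self.__dict__.values() if v is not None]


def prioritize(
    record: CohortVariantRecord,
    freq: FrequencyProfile,
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> bool:
    """Retain a variant iff every present database MAF is below ``threshold``.

    Absent values count as passing (an unseen variant is rare by default).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    return all(value < threshold for value in freq.present())


class AssignedTier(str, Enum):
    SUPPORTS_PATHOGENIC = "SUPPORTS_PATHOGENIC"
    UNCERTAIN_INCOMPLETE_PENETRANCE = "UNCERTAIN_INCOMPLETE_PENETRANCE"
    UNCERTAIN_NEEDS_VALIDATION = "UNCERTAIN_NEEDS_VALIDATION"
    UNCLASSIFIED_NO_PROGENITOR_DATA = "UNCLASSIFIED_NO_PROGENITOR_DATA"
    NOT_PRIORITIZED = "NOT_PRIORITIZED"


@dataclass(frozen=True)
class TierAssignment:
    record: CohortVariantRecord
    assigned_tier: AssignedTier
    triggered_rules: tuple[str, ...]


def assign_tier(
    record: CohortVariantRecord,
    parental_data_available: bool = True,
    freq: Optional[FrequencyProfile] = None,
) -> TierAssignment:
    """Assign a tier by the study's segregation/frequency rules, in order.

    R1  dominant or X-linked gene, de novo            -> SUPPORTS_PATHOGENIC
    R2  recessive gene, in-trans biallelic/homozygous -> SUPPORTS_PATHOGENIC
    R3  dominant gene, family history not positive,
        inherited from an unaffected progenitor or
        MAF present and > 0       -> UNCERTAIN_INCOMPLETE_PENETRANCE
    R4  dominant or X-linked gene inherited with
        positive family history                       -> SUPPORTS_PATHOGENIC
    R5  dominant or X-linked gene, segregation
        unavailable/ongoing, no parental data  -> UNCLASSIFIED_NO_PROGENITOR_DATA

    Every firing rule is recorded; the assigned tier follows the first.
    Records matching no rule fall back to UNCERTAIN_NEEDS_VALIDATION. When a
    frequency profile is supplied and fails :func:`prioritize`, the record is
    NOT_PRIORITIZED with no triggered rules.

    The positive-family-history exemption applies to both branches of R3:
    with a positive family history an inherited dominant-gene variant is not
    demoted for incomplete penetrance.
    """
    if freq is not None and not prioritize(record, freq):
        return TierAssignment(record, AssignedTier.NOT_PRIORITIZED, ())

    modes = record.inheritance_mode
    dominant_or_xl = bool(modes & _DOMINANT_OR_XL)
    dominant = InheritanceMode.AD in modes
    inherited = record.segregation in _INHERITED_SEGREGATION
    fired: list[tuple[str, AssignedTier]] = []

    if dominant_or_xl and record.segregation is Segregation.DE_NOVO:
        fired.append(("R1", AssignedTier.SUPPORTS_PATHOGENIC))
    if InheritanceMode.AR in modes and (
        record.segregation is Segregation.IN_TRANS
        or record.zygosity is Zygosity.HO
    ):
        fired.append(("R2", AssignedTier.SUPPORTS_PATHOGENIC))
    if (
        dominant
        and record.family_history is not FamilyHistory.POSITIVE
        and (inherited or (record.maf is not None and record.maf > 0))
    ):
        fired.append(("R3", AssignedTier.UNCERTAIN_INCOMPLETE_PENETRANCE))
    if (
        dominant_or_xl
        and inherited
        and record.family_history is FamilyHistory.POSITIVE
    ):
        fired.append(("R4", AssignedTier.SUPPORTS_PATHOGENIC))
    if (
        dominant_or_xl
        and record.segregation in _UNAVAILABLE_SEGREGATION
        and not parental_data_available
    ):
        fired.append(("R5", AssignedTier.UNCLASSIFIED_NO_PROGENITOR_DATA))

    if not fired:
        return TierAssignment(
            record, AssignedTier.UNCERTAIN_NEEDS_VALIDATION, ("fallback",)
        )
    rules = tuple(rule for rule, _ in fired)
    return TierAssignment(record, fired[0][1], rules)


# ---------------------------------------------------------------------------
# summaries


def gene_modes(ledger: CohortLedger) -> dict[str, str]:
    """Resolve each gene to one of dominant / recessive / x_linked / unknown.

    Modes are unioned over the gene's records; X-linked wins whenever XL is
    present, then dominant whenever AD is present (so dual "AR,AD" genes
    whose cohort event is heterozygous dominant count as dominant), then
    recessive.
    """
    union: dict[str, set[InheritanceMode]] = {}
    for rec in ledger.records:
        union.setdefault(rec.gene, set()).update(rec.inheritance_mode)
    out = {}
    for gene, modes in union.items():
        if InheritanceMode.XL in modes:
            out[gene] = "x_linked"
        elif InheritanceMode.AD in modes:
            out[gene] = "dominant"
        elif InheritanceMode.AR in modes:
            out[gene] = "recessive"
        else:
            out[gene] = "unknown"
    return out


@dataclass(frozen=True)
class DeNovoFraction:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def de_novo_fraction(table1A: CohortLedger) -> DeNovoFraction:
    """De novo share among dominant/X-linked patients with family data.

    A patient enters the denominator when they carry at least one record
    whose own inheritance annotation includes AD or XL, excluding in-trans
    biallelic configurations, with a completed family study (segregation not
    NA/ongoing). The numerator counts those whose qualifying record is de
    novo. Raises on a zero denominator.
    """
    qualifying: dict[str, set[Segregation]] = {}
    for rec in table1A.records:
        if not rec.inheritance_mode & _DOMINANT_OR_XL:
            continue
        if rec.segregation is Segregation.IN_TRANS:
            continue
        for pid in rec.patient_ids:
            qualifying.setdefault(pid, set()).add(rec.segregation)
    denominator = numerator = 0
    for segs in qualifying.values():
        informative = segs - _UNAVAILABLE_SEGREGATION
        if not informative:
            continue
        denominator += 1
        if Segregation.DE_NOVO in informative:
            numerator += 1
    if denominator == 0:
        raise ZeroDivisionError(
            "no dominant/X-linked patients with completed family studies"
        )
    return DeNovoFraction(numerator=numerator, denominator=denominator)


def breakdowns(table1A: CohortLedger):
    """Gene-mode, variant-type, and segregation breakdowns of a ledger.

    Gene modes are counted once per gene (see :func:`gene_modes`); variant
    types and segregation labels once per record.
    """
    modes = gene_modes(table1A)
    genes_by_mode = Counter(modes.values())
    variant_type_counts = Counter(
        rec.variant_type.value for rec in table1A.records
    )
    segregation_counts = Counter(
        rec.segregation.value for rec in table1A.records
    )
    return dict(genes_by_mode), dict(variant_type_counts), dict(segregation_counts)


@dataclass
class CohortSummary:
    n_cohort: int
    n_diagnosed: int
    n_variants: int
    n_genes: int
    genes_by_mode: dict[str, int]
    variant_type_counts: dict[str, int]
    segregation_counts: dict[str, int]
    per_gene_patient_counts: dict[str, int]
    n_cnv: int
    de_novo: Optional[DeNovoFraction]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_diagnosed > self.n_cohort:
            raise ValueError("n_diagnosed exceeds n_cohort")
        if sum(self.genes_by_mode.values()) != self.n_genes:
            raise ValueError("genes_by_mode does not sum to n_genes")
        if sum(self.variant_type_counts.values()) != self.n_variants:
            raise ValueError("variant_type_counts does not sum to n_variants")

    @property
    def diagnostic_yield(self) -> float:
        return self.n_diagnosed / self.n_cohort

    @property
    def diagnostic_yield_percent(self) -> int:
        return round(100.0 * self.diagnostic_yield)

    #: CNV involvement uses *diagnosed* patients as denominator (recorded in
    #: metadata); this is the only denominator consistent with reporting CNV
    #: involvement as a share of solved cases.
    @property
    def cnv_involvement(self) -> float:
        if self.n_diagnosed == 0:
            return 0.0
        return self._n_cnv_patients / self.n_diagnosed

    @property
    def cnv_involvement_percent(self) -> int:
        return round(100.0 * self.cnv_involvement)

    _n_cnv_patients: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_cohort": self.n_cohort,
            "n_diagnosed": self.n_diagnosed,
            "diagnostic_yield": self.diagnostic_yield,
            "diagnostic_yield_percent": self.diagnostic_yield_percent,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "genes_by_mode": self.genes_by_mode,
            "variant_type_counts": self.variant_type_counts,
            "segregation_counts": self.segregation_counts,
            "per_gene_patient_counts": self.per_gene_patient_counts,
            "n_cnv": self.n_cnv,
            "cnv_involvement": self.cnv_involvement,
            "cnv_involvement_percent": self.cnv_involvement_percent,
            "de_novo": None
            if self.de_novo is None
            else {
                "numerator": self.de_novo.numerator,
                "denominator": self.de_novo.denominator,
                "percent": self.de_novo.percent,
                "percent_rounded": self.de_novo.percent_rounded,
            },
            "metadata": self.metadata,
        }


def summarize_cohort(
    table1A: CohortLedger,
    table1B: Optional[CohortLedger] = None,
    n_cohort: Optional[int] = None,
) -> CohortSummary:
    """Cohort-level summary statistics from the pathogenic-table ledger.

    Variant, gene, and CNV counts come from ``table1A``; ``table1B`` is
    accepted for per-gene counts across both tables (exposed in metadata
    consumers) but does not enter the headline numbers.
    """
    n_cohort = n_cohort if n_cohort is not None else table1A.n_cohort
    diagnosed = distinct_patients(table1A)
    if n_cohort < len(diagnosed):
        raise ValueError(
            f"n_cohort={n_cohort} smaller than {len(diagnosed)} diagnosed patients"
        )
    genes_by_mode, type_counts, seg_counts = breakdowns(table1A)

    per_gene: dict[str, set[str]] = {}
    cnv_patients: set[str] = set()
    for rec in table1A.records:
        per_gene.setdefault(rec.gene, set()).update(rec.patient_ids)
        if rec.variant_type is VariantType.CNV:
            cnv_patients.update(rec.patient_ids)

    try:
        dn = de_novo_fraction(table1A) if table1A.records else None
    except ZeroDivisionError:
        dn = None

    summary = CohortSummary(
        n_cohort=n_cohort,
        n_diagnosed=len(diagnosed),
        n_variants=len(table1A.records),
        n_genes=len(per_gene),
        genes_by_mode=genes_by_mode,
        variant_type_counts=type_counts,
        segregation_counts=seg_counts,
        per_gene_patient_counts={g: len(p) for g, p in per_gene.items()},
        n_cnv=type_counts.get(VariantType.CNV.value, 0),
        de_novo=dn,
        metadata={
            "cnv_involvement_denominator": "diagnosed_patients",
            "de_novo_denominator": (
                "dominant_or_x_linked_patients_with_family_data"
                "_excluding_in_trans"
            ),
        },
    )
    summary._n_cnv_patients = len(cnv_patients)
    return summary


# ---------------------------------------------------------------------------
# classification-rule audit

_EXPECTED_BY_TIER = {
    Tier.PATHOGENIC_TABLE: AssignedTier.SUPPORTS_PATHOGENIC,
    Tier.VUS_FUNCTIONAL_VALIDATION: AssignedTier.UNCERTAIN_NEEDS_VALIDATION,
    Tier.VUS_INCOMPLETE_PENETRANCE: AssignedTier.UNCERTAIN_INCOMPLETE_PENETRANCE,
    Tier.VUS_OLIGOGENIC: AssignedTier.UNCERTAIN_NEEDS_VALIDATION,
    Tier.VUS_NO_PROGENITOR_DATA: AssignedTier.UNCLASSIFIED_NO_PROGENITOR_DATA,
}


def audit_classification(
    *ledgers: CohortLedger,
) -> tuple[float, pd.DataFrame]:
    """Re-derive each fixture record's tier from the rules and compare.

    Parental data is assumed unavailable exactly for records in the
    no-progenitor-data section. Returns the match rate and an exceptions
    table with one row per mismatching record (patients, gene, table tier,
    rule-derived tier, triggered rules) — the table encodes clinical judgment
    the mechanical rules cannot capture, so the exceptions report is a
    first-class output, not an error.
    """
    n_total = n_match = 0
    rows = []
    for ledger in ledgers:
        for rec in ledger.records:
            if rec.tier is None:
                continue
            expected = _EXPECTED_BY_TIER[rec.tier]
            parental = rec.tier is not Tier.VUS_NO_PROGENITOR_DATA
            assignment = assign_tier(rec, parental_data_available=parental)
            n_total += 1
            if assignment.assigned_tier is expected:
                n_match += 1
            else:
                rows.append(
                    {
                        "patients": ";".join(rec.patient_ids),
                        "gene": rec.gene,
                        "hgvs": rec.hgvs,
                        "table_tier": rec.tier.value,
                        "expected": expected.value,
                        "assigned": assignment.assigned_tier.value,
                        "triggered_rules": ",".join(assignment.triggered_rules),
                    }
                )
    exceptions = pd.DataFrame(
        rows,
        columns=[
            "patients", "gene", "hgvs", "table_tier",
            "expected", "assigned", "triggered_rules",
        ],
    )
    rate = n_match / n_total if n_total else float("nan")
    return rate, exceptions
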