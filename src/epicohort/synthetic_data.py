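"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their config (which carries the seed):
the same config yields the same output on every run and platform. Internally
each generated quantity draws from its own numbered stream derived from the
single seed, so adding a new field to a generator does not perturb the draws
of existing fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_table import (
    CohortLedger,
    CohortVariantRecord,
    FamilyHistory,
    InheritanceMode,
    Segregation,
    Sex,
    Tier,
    VariantType,
    Zygosity,
)
from .constraint import GeneVariantCounts
from .cooccurrence import PopulationPanel
from .scores import Group, Metric, ScoreSample

__all__ = [
    "PanelSimConfig",
    "CohortSimConfig",
    "ScoreModel",
    "simulate_count_panel",
    "simulate_population_panel",
    "simulate_cohort_ledger",
    "simulate_score_samples",
    "GERP_RANGE",
]

#: Documented range of the conservation score; values are clipped here.
GERP_RANGE = (-12.3, 6.17)

# stable stream ids; append only, never renumber
_STREAMS = {
    "totals": 0,
    "noise": 1,
    "poisson": 2,
    "diagnosed": 3,
    "mode": 4,
    "gene": 5,
    "vtype": 6,
    "family": 7,
    "denovo": 8,
    "parent": 9,
    "sex": 10,
    "scores": 11,
    "vus": 12,
    "vus_tier": 13,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# count panel (constraint input)


@dataclass(frozen=True)
class PanelSimConfig:
    """Linear-Gaussian model for per-gene missense vs total counts."""

    n_genes: int
    seed: int
    # floor keeps depletion visible above the noise at the smallest totals
    totals_range: tuple[int, int] = (300, 2000)
    slope: float = 0.45
    intercept: float = 5.0
    noise_sd: float = 8.0
    depleted_genes: tuple[str, ...] = ()
    depletion_factor: float = 0.5
    round_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.totals_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid totals_range {self.totals_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.depleted_genes and not 0.0 < self.depletion_factor < 1.0:
            raise ValueError("depletion_factor must lie in (0, 1)")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def simulate_count_panel(config: PanelSimConfig) -> list[GeneVariantCounts]:
    """Draw per-gene missense/synonymous counts under the linear model.

    Totals are uniform over ``totals_range``; expected missense is
    ``intercept + slope * total`` times ``depletion_factor`` for designated
    intolerant genes, with Gaussian noise, rounded (unless disabled) and
    clipped to ``[0, total]``.
    """
    genes = config.gene_names()
    unknown = set(config.depleted_genes) - set(genes)
    if unknown:
        raise ValueError(f"depleted genes not in panel: {sorted(unknown)}")
    lo, hi = config.totals_range
    totals = _rng(config.seed, "totals").integers(lo, hi + 1, size=config.n_genes)
    noise = _rng(config.seed, "noise").normal(
        0.0, config.noise_sd, size=config.n_genes
    )
    depleted = np.isin(genes, list(config.depleted_genes))
    mean = config.intercept + config.slope * totals.astype(float)
    mean = np.where(depleted, mean * config.depletion_factor, mean)
    missense = mean + noise
    if config.round_counts:
        missense = np.rint(missense)
    missense = np.clip(missense, 0, totals)
    out = []
    for gene, total, n_miss in zip(genes, totals, missense):
        n_miss_int = int(round(float(n_miss)))
        if abs(n_miss_int - float(n_miss)) > 1e-9:
            raise ValueError(
                "non-integer missense count with rounding disabled; choose "
                "integral intercept/slope*total or enable round_counts"
            )
        out.append(
            GeneVariantCounts(
                gene=str(gene),
                n_missense=n_miss_int,
                n_synonymous=int(total) - n_miss_int,
            )
        )
    return out


# ---------------------------------------------------------------------------
# population panel (co-occurrence input)


def simulate_population_panel(
    n_samples: int,
    gene_lambdas: Mapping[str, float],
    seed: int,
) -> PopulationPanel:
    """Independent Poisson counts per sample per gene."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    for gene, lam in gene_lambdas.items():
        if lam < 0:
            raise ValueError(f"negative rate for gene {gene}")
    rng = _rng(seed, "poisson")
    counts = {
        gene: rng.poisson(lam, size=n_samples)
        for gene, lam in gene_lambdas.items()
    }
    return PopulationPanel(n_samples=n_samples, gene_sample_counts=counts)


# ---------------------------------------------------------------------------
# cohort ledgers


@dataclass(frozen=True)
class ScoreModel:
    """Truncated-normal score distributions for control vs pathogenic."""

    gerp_control: tuple[float, float] = (1.5, 2.5)
    gerp_pathogenic: tuple[float, float] = (5.0, 0.8)
    condel_control: tuple[float, float] = (0.35, 0.12)
    condel_pathogenic: tuple[float, float] = (0.65, 0.10)


def _truncated_normal(
    rng: np.random.Generator,
    mu: float,
    sd: float,
    low: float,
    high: float,
    size: int,
) -> np.ndarray:
    a, b = (low - mu) / sd, (high - mu) / sd
    dist = stats.truncnorm(a, b, loc=mu, scale=sd)
    return dist.ppf(rng.uniform(size=size))


@dataclass(frozen=True)
class CohortSimConfig:
    """Generating process for table-1A/1B-like cohort ledgers."""

    n_patients: int
    seed: int
    p_diagnosed: float = 0.42
    #: dominant / recessive / x_linked probabilities
    mode_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)
    p_de_novo_given_dominant_with_family_data: float = 0.82
    p_family_data: float = 0.70
    #: missense/nonsense/frameshift/splice/CNV/in-frame probabilities
    type_mix: tuple[float, float, float, float, float, float] = (
        0.60, 0.14, 0.12, 0.04, 0.08, 0.02,
    )
    p_vus_given_undiagnosed: float = 0.15
    n_genes_per_mode: int = 12
    scores: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "p_diagnosed",
            "p_de_novo_given_dominant_with_family_data",
            "p_family_data",
            "p_vus_given_undiagnosed",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for name in ("mode_mix", "type_mix"):
            mix = getattr(self, name)
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector")


_MODE_LABELS = ("dominant", "recessive", "x_linked")
_TYPE_ORDER = (
    VariantType.MISSENSE,
    VariantType.NONSENSE,
    VariantType.FRAMESHIFT,
    VariantType.SPLICE,
    VariantType.CNV,
    VariantType.INFRAME_INDEL,
)
_MODE_TO_INH = {
    "dominant": frozenset({InheritanceMode.AD}),
    "recessive": frozenset({InheritanceMode.AR}),
    "x_linked": frozenset({InheritanceMode.XL}),
}
_VUS_TIERS = (
    Tier.VUS_FUNCTIONAL_VALIDATION,
    Tier.VUS_INCOMPLETE_PENETRANCE,
    Tier.VUS_OLIGOGENIC,
    Tier.VUS_NO_PROGENITOR_DATA,
)


def simulate_cohort_ledger(
    config: CohortSimConfig,
) -> tuple[CohortLedger, CohortLedger, dict]:
    """Generate (pathogenic-table ledger, VUS-table ledger, truth record).

    Each diagnosed patient receives one pathogenic-tier record whose mode,
    segregation, variant type and scores follow the config; a configurable
    share of undiagnosed patients receives one VUS record. The truth record
    stores the generating parameters plus realized counts.
    """
    seed = config.seed
    n = config.n_patients
    diagnosed = _rng(seed, "diagnosed").uniform(size=n) < config.p_diagnosed
    mode_idx = _rng(seed, "mode").choice(3, size=n, p=config.mode_mix)
    gene_idx = _rng(seed, "gene").integers(config.n_genes_per_mode, size=n)
    type_idx = _rng(seed, "vtype").choice(
        len(_TYPE_ORDER), size=n, p=config.type_mix
    )
    has_family = _rng(seed, "family").uniform(size=n) < config.p_family_data
    is_denovo = (
        _rng(seed, "denovo").uniform(size=n)
        < config.p_de_novo_given_dominant_with_family_data
    )
    parent_pick = _rng(seed, "parent").uniform(size=n) < 0.5
    is_male = _rng(seed, "sex").uniform(size=n) < 0.5
    vus_draw = _rng(seed, "vus").uniform(size=n) < config.p_vus_given_undiagnosed
    vus_tier_idx = _rng(seed, "vus_tier").integers(len(_VUS_TIERS), size=n)
    score_rng = _rng(seed, "scores")

    gene_prefix = {"dominant": "ADG", "recessive": "ARG", "x_linked": "XLG"}

    def _scores(vtype: VariantType, pathogenic: bool):
        if vtype is not VariantType.MISSENSE:
            return None, None
        model = config.scores
        gerp_mu, gerp_sd = (
            model.gerp_pathogenic if pathogenic else model.gerp_control
        )
        condel_mu, condel_sd = (
            model.condel_pathogenic if pathogenic else model.condel_control
        )
        gerp = _truncated_normal(score_rng, gerp_mu, gerp_sd, *GERP_RANGE, size=1)
        condel = _truncated_normal(
            score_rng, condel_mu, condel_sd, 0.0, 1.0, size=1
        )
        return float(condel[0]), float(gerp[0])

    table_a: list[CohortVariantRecord] = []
    table_b: list[CohortVariantRecord] = []
    for i in range(n):
        pid = f"P{i + 1:05d}"
        sex = Sex.M if is_male[i] else Sex.F
        mode = _MODE_LABELS[mode_idx[i]]
        gene = f"{gene_prefix[mode]}{gene_idx[i] + 1:03d}"
        vtype = _TYPE_ORDER[type_idx[i]]

        if diagnosed[i]:
            if mode == "recessive":
                segregation = Segregation.IN_TRANS
                zygosity = Zygosity.HO
            elif has_family[i]:
                if is_denovo[i]:
                    segregation = Segregation.DE_NOVO
                else:
                    segregation = (
                        Segregation.MATERNAL
                        if parent_pick[i]
                        else Segregation.PATERNAL
                    )
                zygosity = (
                    Zygosity.HE
                    if mode == "x_linked" and sex is Sex.M
                    else Zygosity.HT
                )
            else:
                segregation = Segregation.NOT_AVAILABLE
                zygosity = (
                    Zygosity.HE
                    if mode == "x_linked" and sex is Sex.M
                    else Zygosity.HT
                )
            condel, gerp = _scores(vtype, pathogenic=True)
            if vtype is VariantType.CNV:
                condel = gerp = None
            table_a.append(
                CohortVariantRecord(
                    patient_ids=[pid],
                    sex=sex,
                    gene=gene,
                    inheritance_mode=_MODE_TO_INH[mode],
                    zygosity=zygosity,
                    segregation=segregation,
                    family_history=FamilyHistory.NEGATIVE,
                    variant_type=vtype,
                    condel_score=condel,
                    gerp_score=gerp,
                    refseq=f"NM_{gene}",
                    hgvs=f"c.{i + 1}A>G",
                    tier=Tier.PATHOGENIC_TABLE,
                )
            )
        elif vus_draw[i]:
            tier = _VUS_TIERS[vus_tier_idx[i]]
            if tier is Tier.VUS_INCOMPLETE_PENETRANCE:
                segregation = (
                    Segregation.MATERNAL
                    if parent_pick[i]
                    else Segregation.PATERNAL
                )
            else:
                segregation = Segregation.NOT_AVAILABLE
            condel, gerp = _scores(VariantType.MISSENSE, pathogenic=False)
            table_b.append(
                CohortVariantRecord(
                    patient_ids=[pid],
                    sex=sex,
                    gene=f"ADG{gene_idx[i] + 1:03d}",
                    inheritance_mode=_MODE_TO_INH["dominant"],
                    zygosity=Zygosity.HT,
                    segregation=segregation,
                    family_history=FamilyHistory.NEGATIVE,
                    variant_type=VariantType.MISSENSE,
                    condel_score=condel,
                    gerp_score=gerp,
                    refseq=f"NM_ADG{gene_idx[i] + 1:03d}",
                    hgvs=f"c.{i + 1}C>T",
                    tier=tier,
                )
            )

    truth = {
        "config": {
            "n_patients": config.n_patients,
            "seed": config.seed,
            "p_diagnosed": config.p_diagnosed,
            "mode_mix": list(config.mode_mix),
            "p_de_novo_given_dominant_with_family_data": (
                config.p_de_novo_given_dominant_with_family_data
            ),
            "p_family_data": config.p_family_data,
            "type_mix": list(config.type_mix),
            "p_vus_given_undiagnosed": config.p_vus_given_undiagnosed,
        },
        "n_diagnosed": int(diagnosed.sum()),
        "n_vus_records": len(table_b),
    }
    ledger_a = CohortLedger(records=table_a, n_cohort=n)
    ledger_b = CohortLedger(records=table_b, n_cohort=n)
    return ledger_a, ledger_b, truth


# ---------------------------------------------------------------------------
# score samples (case vs control)


def simulate_score_samples(
    gene: str,
    metric: Metric,
    n_case: int,
    n_control: int,
    seed: int,
    *,
    control_mu: float = 0.0,
    control_sd: float = 1.0,
    shift: float = 2.0,
) -> tuple[ScoreSample, ScoreSample]:
    """Case and control score samples with a mean shift of ``shift * sd``.

    GERP samples are truncated to :data:`GERP_RANGE`, CONDEL samples to
    ``[0, 1]``.
    """
    rng = _rng(seed, "scores")
    low, high = GERP_RANGE if metric is Metric.GERP else (0.0, 1.0)
    case = _truncated_normal(
        rng, control_mu + shift * control_sd, control_sd, low, high, n_case
    )
    control = _truncated_normal(rng, control_mu, control_sd, low, high, n_control)
    return (
        ScoreSample(gene=gene, group=Group.CASE, metric=metric, values=tuple(case)),
        ScoreSample(
            gene=gene, group=Group.CONTROL, metric=metric, values=tuple(control)
        ),
    )
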