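"""Poisson model for rare missense co-occurrence.

Given per-gene rates of rare (MAF < 0.005) missense carriage, computes the
probability of seeing two rare variants in one gene, or at least one rare
variant in each of several genes simultaneously, under independence across
genes and across the two alleles of one gene (no linkage, no phase).

Two rate estimators are provided because "the frequency of samples fulfilling
those conditions" is ambiguous between a per-individual variant rate and a
carrier fraction:

``mean_count``
    lambda = mean per-sample count (the default).
``carrier_frequency``
    lambda = -ln(1 - f) with f the fraction of samples carrying >= 1 variant
    (the rate of a Poisson with the observed zero-truncation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PopulationPanel",
    "RateEstimate",
    "CooccurrenceResult",
    "Scenario",
    "estimate_lambda",
    "prob_two_hits_one_gene",
    "prob_one_hit_each",
    "simulate_cooccurrence",
    "read_panel_tsv",
]

DEFAULT_MAF_THRESHOLD = 0.005


class Scenario(str, Enum):
    TWO_HITS_ONE_GENE = "TWO_HITS_ONE_GENE"
    ONE_HIT_EACH_GENE = "ONE_HIT_EACH_GENE"


@dataclass
class PopulationPanel:
    """Per-sample counts of rare missense variants, per gene."""

    n_samples: int
    gene_sample_counts: dict[str, np.ndarray]
    maf_threshold: float = DEFAULT_MAF_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        clean = {}
        for gene, counts in self.gene_sample_counts.items():
            arr = np.asarray(counts, dtype=int)
            if arr.shape != (self.n_samples,):
                raise ValueError(
                    f"gene {gene}: count vector length {arr.shape} != "
                    f"n_samples {self.n_samples}"
                )
            if (arr < 0).any():
                raise ValueError(f"gene {gene}: negative counts")
            clean[gene] = arr
        self.gene_sample_counts = clean

    @property
    def genes(self) -> list[str]:
        return list(self.gene_sample_counts)


@dataclass(frozen=True)
class RateEstimate:
    gene: str
    lam: float
    estimator: str
    standard_error: float


@dataclass(frozen=True)
class CooccurrenceResult:
    scenario: Scenario
    genes: tuple[str, ...]
    lambdas: tuple[float, ...]
    probability: float


def estimate_lambda(
    panel: PopulationPanel,
    gene: str,
    estimator: str = "mean_count",
) -> RateEstimate:
    """Poisson rate of rare missense carriage for ``gene``.

    ``mean_count``: lam = mean count, SE = sqrt(lam / n).
    ``carrier_frequency``: lam = -ln(1 - f) with f the carrier fraction,
    SE by the delta method; f = 1 makes the rate unidentifiable.
    """
    if gene not in panel.gene_sample_counts:
        raise KeyError(f"gene {gene!r} not in panel")
    counts = panel.gene_sample_counts[gene]
    n = panel.n_samples
    if estimator == "mean_count":
        lam = float(counts.mean())
        se = math.sqrt(lam / n)
    elif estimator == "carrier_frequency":
        f = float((counts > 0).mean())
        if f >= 1.0:
            raise ValueError(
                f"gene {gene}: every sample is a carrier; rate unidentifiable"
            )
        lam = -math.log1p(-f)
        # d(-ln(1-f))/df = 1/(1-f); Var(f) = f(1-f)/n
        se = math.sqrt(f * (1.0 - f) / n) / (1.0 - f)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RateEstimate(gene=gene, lam=lam, estimator=estimator, standard_error=se)


def prob_two_hits_one_gene(lam: float) -> float:
    """P(X >= 2) for X ~ Poisson(lam) = 1 - e^-lam (1 + lam)."""
    if lam < 0:
        raise ValueError("rate must be non-negative")
    # -expm1 keeps precision for tiny rates where 1 - e^-lam(1+lam) cancels
    return float(-math.expm1(-lam) - lam * math.exp(-lam))


def prob_one_hit_each(lams: Sequence[float]) -> float:
    """P(every gene has >= 1 hit) = prod_i (1 - e^-lam_i), independent genes."""
    if len(lams) < 2:
        raise ValueError("need rates for at least two genes")
    if any(lam < 0 for lam in lams):
        raise ValueError("rates must be non-negative")
    prob = 1.0
    for lam in lams:
        prob *= -math.expm1(-lam)
    return float(prob)


def two_hits_result(gene: str, lam: float) -> CooccurrenceResult:
    return CooccurrenceResult(
        scenario=Scenario.TWO_HITS_ONE_GENE,
        genes=(gene,),
        lambdas=(lam,),
        probability=prob_two_hits_one_gene(lam),
    )


def one_hit_each_result(
    genes: Sequence[str], lams: Sequence[float]
) -> CooccurrenceResult:
    if len(genes) != len(lams):
        raise ValueError("genes and lambdas must have equal length")
    return CooccurrenceResult(
        scenario=Scenario.ONE_HIT_EACH_GENE,
        genes=tuple(genes),
        lambdas=tuple(float(l) for l in lams),
        probability=prob_one_hit_each(list(lams)),
    )


@dataclass(frozen=True)
class EmpiricalProbability:
    scenario: Scenario
    probability: float
    n_draws: int
    wilson_low: float
    wilson_high: float


def simulate_cooccurrence(
    lams: Sequence[float],
    n_samples: int,
    n_reps: int,
    seed: int,
    confidence: float = 0.99,
) -> dict[Scenario, EmpiricalProbability]:
    """Monte-Carlo check of both closed forms.

    Draws independent Poisson counts per gene for ``n_samples * n_reps``
    individuals and reports the empirical frequency of each scenario with a
    Wilson confidence interval. With one rate only the two-hit scenario is
    reported; the two-hit frequency refers to the first gene.
    """
    if n_reps <= 0 or n_samples <= 0:
        raise ValueError("n_samples and n_reps must be positive")
    if not lams:
        raise ValueError("need at least one rate")
    if any(lam < 0 for lam in lams):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    total = n_samples * n_reps
    counts = rng.poisson(lam=np.asarray(lams, dtype=float), size=(total, len(lams)))

    out: dict[Scenario, EmpiricalProbability] = {}

    def _wilson(successes: int) -> EmpiricalProbability:
        low, high = proportion_confint(
            successes, total, alpha=1.0 - confidence, method="wilson"
        )
        return EmpiricalProbability(
            scenario=Scenario.TWO_HITS_ONE_GENE,  # overwritten below
            probability=successes / total,
            n_draws=total,
            wilson_low=float(low),
            wilson_high=float(high),
        )

    two_hit = _wilson(int((counts[:, 0] >= 2).sum()))
    out[Scenario.TWO_HITS_ONE_GENE] = EmpiricalProbability(
        Scenario.TWO_HITS_ONE_GENE, two_hit.probability, total,
        two_hit.wilson_low, two_hit.wilson_high,
    )
    if len(lams) >= 2:
        each = _wilson(int((counts >= 1).all(axis=1).sum()))
        out[Scenario.ONE_HIT_EACH_GENE] = EmpiricalProbability(
            Scenario.ONE_HIT_EACH_GENE, each.probability, total,
            each.wilson_low, each.wilson_high,
        )
    return out


def read_panel_tsv(path, maf_threshold: float = DEFAULT_MAF_THRESHOLD) -> PopulationPanel:
    """Read a panel from wide (sample x gene) or long (sample, gene, count) TSV."""
    frame = pd.read_csv(path, sep="\t")
    if {"sample", "gene", "count"}.issubset(frame.columns):
        wide = frame.pivot_table(
            index="sample", columns="gene", values="count", fill_value=0
        )
    else:
        if "sample" not in frame.columns:
            raise ValueError("panel TSV needs a 'sample' column")
        wide = frame.set_index("sample")
    return PopulationPanel(
        n_samples=len(wide),
        gene_sample_counts={
            str(gene): wide[gene].to_numpy(dtype=int) for gene in wide.columns
        },
        maf_threshold=maf_threshold,
    )
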