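"""Case-vs-control comparison of deleteriousness scores (GERP, CONDEL).

Scores are consumed as annotations; nothing here recomputes conservation or
consensus deleteriousness. Control values per gene are caller-supplied
(typically extracted from population databases or generated synthetically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_table import CohortVariantRecord, VariantType

__all__ = [
    "Metric",
    "Group",
    "ScoreSample",
    "ScoreComparison",
    "FiveNumberSummary",
    "DiscordanceFlag",
    "summarize_scores",
    "compare_case_control",
    "flag_discordant_scores",
]

#: Exact rank-sum null is enumerated when n_case * n_control is at most this
#: and the pooled values are tie-free.
EXACT_LIMIT = 400


class Metric(str, Enum):
    GERP = "GERP"
    CONDEL = "CONDEL"


class Group(str, Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class ScoreSample:
    """Score values for one gene, one metric, one group."""

    gene: str
    group: Group
    metric: Metric
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.metric is Metric.CONDEL and any(
            not 0.0 <= v <= 1.0 for v in self.values
        ):
            raise ValueError("CONDEL values must lie in [0, 1]")


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


@dataclass(frozen=True)
class ScoreComparison:
    gene: str
    metric: Metric
    n_case: int
    n_control: int
    rank_sum_statistic: float
    p_value: float
    case_median: float
    control_median: float
    method: str


def summarize_scores(sample: ScoreSample) -> FiveNumberSummary:
    """Five-number summary using linear interpolation (R type-7) quartiles."""
    if not sample.values:
        raise ValueError("cannot summarize an empty score sample")
    values = np.asarray(sample.values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return FiveNumberSummary(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
    )


def compare_case_control(
    case: ScoreSample,
    control: ScoreSample,
    sidedness: str = "two_sided",
) -> ScoreComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Uses the exact null distribution when ``n_case * n_control <=``
    :data:`EXACT_LIMIT` and the pooled values are tie-free, otherwise the
    normal approximation with continuity and tie correction.
    """
    if sidedness != "two_sided":
        raise ValueError("only two_sided comparisons are supported")
    if case.metric is not control.metric:
        raise ValueError(
            f"mixed metrics: {case.metric.value} vs {control.metric.value}"
        )
    if case.gene != control.gene:
        raise ValueError(f"mixed genes: {case.gene} vs {control.gene}")
    if not case.values or not control.values:
        raise ValueError("both samples must be non-empty")

    x = np.asarray(case.values, dtype=float)
    y = np.asarray(control.values, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(x) * len(y) <= EXACT_LIMIT:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return ScoreComparison(
        gene=case.gene,
        metric=case.metric,
        n_case=len(x),
        n_control=len(y),
        rank_sum_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        case_median=float(np.median(x)),
        control_median=float(np.median(y)),
        method=method,
    )


class DiscordanceFlag(str, Enum):
    #: Conserved position but innocuous-looking amino-acid change.
    HIGH_GERP_LOW_CONDEL = "HIGH_GERP_LOW_CONDEL"
    #: CONDEL exceeds every control variant in the gene.
    CONDEL_ABOVE_CONTROL_MAX = "CONDEL_ABOVE_CONTROL_MAX"


def flag_discordant_scores(
    record: CohortVariantRecord,
    gene_control_summary: Mapping[Metric, FiveNumberSummary],
) -> set[DiscordanceFlag]:
    """Flags for a missense record against its gene's control distribution.

    Missing scores or non-missense records yield no flags.
    """
    flags: set[DiscordanceFlag] = set()
    if record.variant_type is not VariantType.MISSENSE:
        return flags
    gerp_ctl = gene_control_summary.get(Metric.GERP)
    condel_ctl = gene_control_summary.get(Metric.CONDEL)
    if (
        record.gerp_score is not None
        and record.condel_score is not None
        and gerp_ctl is not None
        and condel_ctl is not None
        and record.gerp_score > gerp_ctl.q3
        and record.condel_score < condel_ctl.q1
    ):
        flags.add(DiscordanceFlag.HIGH_GERP_LOW_CONDEL)
    if (
        record.condel_score is not None
        and condel_ctl is not None
        and record.condel_score > condel_ctl.maximum
    ):
        flags.add(DiscordanceFlag.CONDEL_ABOVE_CONTROL_MAX)
    return flags
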