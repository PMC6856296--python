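"""Per-gene mutation-tolerance z-scores.

The tolerance of a gene to missense variation is scored by regressing, across
genes, the number of missense variants on the total number of missense plus
synonymous variants (ordinary least squares with intercept) and taking the
studentized residual as the z-score. Genes with fewer missense variants than
the fit predicts get negative z-scores and are read as missense-intolerant.

Input counts are assumed to come from a population panel with
ClinVar-pathogenic variants already removed; that filter belongs to panel
preparation, not to this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GeneVariantCounts",
    "RegressionFit",
    "ConstraintResult",
    "fit_missense_regression",
    "compute_zscores",
    "rank_intolerance",
    "results_to_frame",
]


class ConstraintEstimationError(ValueError):
    """The regression cannot be estimated from the supplied counts."""


@dataclass(frozen=True)
class GeneVariantCounts:
    """Distinct missense / synonymous variant counts for one gene."""

    gene: str
    n_missense: int
    n_synonymous: int

    def __post_init__(self) -> None:
        if self.n_missense < 0 or self.n_synonymous < 0:
            raise ValueError(f"negative counts for gene {self.gene}")

    @property
    def total(self) -> int:
        return self.n_missense + self.n_synonymous


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    residual_standard_error: float
    n_genes: int


@dataclass(frozen=True)
class ConstraintResult:
    gene: str
    total: int
    fitted_missense: float
    raw_residual: float
    leverage: float
    zscore: float
    #: True when studentization is undefined (leverage 1 or gene excluded).
    undefined: bool = False


def _check_counts(counts: Sequence[GeneVariantCounts]) -> None:
    genes = [c.gene for c in counts]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in counts")


def fit_missense_regression(
    counts: Iterable[GeneVariantCounts],
) -> RegressionFit:
    """OLS of ``n_missense`` on ``n_missense + n_synonymous`` across genes.

    Genes with a zero total are excluded from the fit. Raises
    :class:`ConstraintEstimationError` with fewer than 3 informative genes or
    a degenerate (constant) predictor.
    """
    counts = list(counts)
    _check_counts(counts)
    used = [c for c in counts if c.total > 0]
    if len(used) < 3:
        raise ConstraintEstimationError(
            f"need >= 3 genes with nonzero totals, have {len(used)}"
        )
    x = np.array([c.total for c in used], dtype=float)
    y = np.array([c.n_missense for c in used], dtype=float)
    if np.ptp(x) == 0:
        raise ConstraintEstimationError("all gene totals identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    # scale = SSR / (n - 2); residual standard error is its square root
    return RegressionFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        residual_standard_error=float(math.sqrt(model.scale)),
        n_genes=len(used),
    )


def compute_zscores(
    counts: Iterable[GeneVariantCounts],
    studentization: Literal["internal", "external"] = "internal",
) -> list[ConstraintResult]:
    """Studentized residuals of the missense-count regression, per gene.

    ``internal`` divides each raw residual by ``s * sqrt(1 - h_i)`` with the
    whole-sample residual standard error ``s``; ``external`` uses the
    leave-one-out estimate of ``s``. Genes with zero totals, or leverage 1,
    are returned flagged ``undefined`` with a NaN z-score rather than
    silently dropped.
    """
    if studentization not in ("internal", "external"):
        raise ValueError(f"unknown studentization {studentization!r}")
    counts = list(counts)
    _check_counts(counts)
    used = [c for c in counts if c.total > 0]
    if len(used) < 3:
        raise ConstraintEstimationError(
            f"need >= 3 genes with nonzero totals, have {len(used)}"
        )
    x = np.array([c.total for c in used], dtype=float)
    y = np.array([c.n_missense for c in used], dtype=float)
    if np.ptp(x) == 0:
        raise ConstraintEstimationError("all gene totals identical")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    influence = model.get_influence()
    leverage = influence.hat_matrix_diag
    fitted = model.fittedvalues
    resid = model.resid
    if math.sqrt(model.scale) < 1e-12:
        # perfect fit: every gene sits on the line, all z-scores are 0
        student = np.zeros_like(resid)
    elif studentization == "internal":
        student = influence.resid_studentized_internal
    else:
        student = influence.resid_studentized_external

    by_gene: dict[str, ConstraintResult] = {}
    for i, c in enumerate(used):
        h = float(leverage[i])
        undefined = bool(1.0 - h <= 1e-12)
        z = float("nan") if undefined else float(student[i])
        by_gene[c.gene] = ConstraintResult(
            gene=c.gene,
            total=c.total,
            fitted_missense=float(fitted[i]),
            raw_residual=float(resid[i]),
            leverage=h,
            zscore=z,
            undefined=undefined,
        )
    out = []
    for c in counts:
        if c.gene in by_gene:
            out.append(by_gene[c.gene])
        else:  # zero-total gene: excluded from the fit, flagged
            out.append(
                ConstraintResult(
                    gene=c.gene,
                    total=0,
                    fitted_missense=float("nan"),
                    raw_residual=float("nan"),
                    leverage=float("nan"),
                    zscore=float("nan"),
                    undefined=True,
                )
            )
    return out


def rank_intolerance(
    results: Iterable[ConstraintResult], k: int
) -> list[str]:
    """The ``k`` most missense-intolerant genes: ascending z, ties by symbol.

    Genes with undefined z-scores are excluded from the ranking.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    ranked = sorted(
        (r for r in results if not r.undefined and not math.isnan(r.zscore)),
        key=lambda r: (r.zscore, r.gene),
    )
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds {len(ranked)} rankable genes")
    return [r.gene for r in ranked[:k]]


def results_to_frame(results: Iterable[ConstraintResult]) -> pd.DataFrame:
    """Tabular view (gene, total, fitted, residual, leverage, zscore)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "total": r.total,
                "fitted": r.fitted_missense,
                "residual": r.raw_residual,
                "leverage": r.leverage,
                "zscore": r.zscore,
                "undefined": r.undefined,
            }
            for r in results
        ]
    )


def read_counts_tsv(path) -> list[GeneVariantCounts]:
    """Read a gene/n_missense/n_synonymous TSV."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "n_missense", "n_synonymous"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return [
        GeneVariantCounts(
            gene=str(row.gene),
            n_missense=int(row.n_missense),
            n_synonymous=int(row.n_synonymous),
        )
        for row in frame.itertuples()
    ]
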