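"""Per-locus GWAS efficiency statistics and threshold summaries.

The efficiency of an association result is the log-transformed p-value per
analyzed person,

    xi = -log10(p) / N,

and the relative efficiency of a larger study (subscript 1) against a
smaller one (subscript 2) is rho = xi_1 / xi_2. Under a homogeneous genetic
effect the expected association z-statistic grows like sqrt(N), -log10 p
like N, and rho -> 1; persistent deviation from rho = 1 is the signature of
between-sample heterogeneity in genetic effects.

The p-value gain delta_p = -(log10 p_larger - log10 p_smaller) classifies
each locus: the larger study's p-value got larger (delta_p < 0), decreased
by at most two orders of magnitude (0 <= delta_p <= 2), or decreased
substantially (delta_p > 2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DegenerateError, ValidationError
from .pvalues import neglog10p_from_p
from .summary_io import PairedLocus

__all__ = [
    "ChangeCategory",
    "EfficiencyResult",
    "ThresholdSummary",
    "Cutoffs",
    "efficiency_xi",
    "xi_from_neglog10p",
    "relative_efficiency",
    "delta_p",
    "delta_p_from_neglog10",
    "classify_locus",
    "evaluate_pair",
    "evaluate_pairs",
    "threshold_summary",
    "results_to_frame",
    "write_results",
]


class ChangeCategory(enum.Enum):
    """How the p-value changed going from the smaller to the larger study."""

    LARGER_P = "larger_p"
    MINOR_DECREASE = "minor_decrease"
    SUBSTANTIAL_DECREASE = "substantial_decrease"


def xi_from_neglog10p(neglog10_p, n):
    """Efficiency xi = -log10(p) / N from an already log-transformed p."""
    L = np.asarray(neglog10_p, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(~np.isfinite(L)) or np.any(L < 0):
        raise ValidationError("-log10 p must be finite and non-negative")
    if np.any(n_arr < 1):
        raise ValidationError("n must be >= 1")
    out = L / n_arr
    return float(out) if out.ndim == 0 else out


def efficiency_xi(p, n):
    """Efficiency xi = -log10(p) / N.

    ``p`` must lie in (0, 1]. For p-values beyond double precision use
    :func:`xi_from_neglog10p`, the log-space entry point.
    """
    return xi_from_neglog10p(neglog10p_from_p(p), n)


def relative_efficiency(xi_larger, xi_smaller):
    """rho = xi_larger / xi_smaller (larger study on top, by convention)."""
    x1 = np.asarray(xi_larger, dtype=float)
    x2 = np.asarray(xi_smaller, dtype=float)
    if np.any(x2 <= 0.0):
        raise DegenerateError("xi of the smaller study is 0 (its p-value is 1); rho undefined")
    out = x1 / x2
    return float(out) if out.ndim == 0 else out


def delta_p_from_neglog10(neglog10_p_larger, neglog10_p_smaller):
    """delta_p on already log-transformed p-values: L_larger - L_smaller."""
    out = np.asarray(neglog10_p_larger, dtype=float) - np.asarray(neglog10_p_smaller, dtype=float)
    return float(out) if out.ndim == 0 else out


def delta_p(p_larger_study, p_smaller_study):
    """p-value gain delta_p = -(log10 p_larger - log10 p_smaller).

    Positive when the larger study's p-value is smaller (the expected
    direction under homogeneity); negative when it got larger.
    """
    return delta_p_from_neglog10(
        neglog10p_from_p(p_larger_study), neglog10p_from_p(p_smaller_study)
    )


def classify_locus(delta_p_value: float) -> ChangeCategory:
    """Classify a p-value change; the two-orders boundary is inclusive."""
    if delta_p_value < 0.0:
        return ChangeCategory.LARGER_P
    if delta_p_value <= 2.0:
        return ChangeCategory.MINOR_DECREASE
    return ChangeCategory.SUBSTANTIAL_DECREASE


@dataclass(frozen=True)
class EfficiencyResult:
    """xi, rho, delta_p and change category for one paired locus."""

    locus_id: str
    trait: str
    n_larger: int
    n_smaller: int
    neglog10_p_larger: float
    neglog10_p_smaller: float
    xi_larger: float
    xi_smaller: float
    rho: float
    delta_p: float
    category: ChangeCategory


def evaluate_pair(pair: PairedLocus) -> EfficiencyResult:
    """Compute all efficiency statistics for one paired locus."""
    L1, L2 = pair.larger.neglog10_p, pair.smaller.neglog10_p
    xi1 = xi_from_neglog10p(L1, pair.larger.n)
    xi2 = xi_from_neglog10p(L2, pair.smaller.n)
    rho = relative_efficiency(xi1, xi2)
    dp = delta_p_from_neglog10(L1, L2)
    return EfficiencyResult(
        locus_id=pair.locus_id,
        trait=pair.larger.trait,
        n_larger=pair.larger.n,
        n_smaller=pair.smaller.n,
        neglog10_p_larger=L1,
        neglog10_p_smaller=L2,
        xi_larger=xi1,
        xi_smaller=xi2,
        rho=rho,
        delta_p=dp,
        category=classify_locus(dp),
    )


def evaluate_pairs(pairs) -> list[EfficiencyResult]:
    return [evaluate_pair(p) for p in pairs]


@dataclass(frozen=True)
class Cutoffs:
    """Relative-efficiency cutoffs for the threshold summary.

    ``lower`` are one-sided cutoffs (count of rho strictly below each);
    ``bands`` are open intervals, counting rho strictly outside each.
    Defaults reproduce the published summary table: rho < 0.9, rho < 0.8,
    rho outside (0.9, 1.1), rho outside (0.8, 1.2).
    """

    lower: tuple[float, ...] = (0.9, 0.8)
    bands: tuple[tuple[float, float], ...] = ((0.9, 1.1), (0.8, 1.2))


@dataclass
class ThresholdSummary:
    """Counts and one-decimal percentages of loci per rho cutoff."""

    base: int
    counts: dict[str, int]
    percentages: dict[str, float]
    comparison_label: str

    def to_frame(self) -> pd.DataFrame:
        row: dict[str, object] = {"base": self.base}
        for key in self.counts:
            row[f"n[{key}]"] = self.counts[key]
            row[f"pct[{key}]"] = self.percentages[key]
        row["comparison"] = self.comparison_label
        return pd.DataFrame([row])


def _pct_half_up(count: int, base: int) -> float:
    """Percentage rounded half-up to one decimal, computed exactly."""
    frac = Decimal(count * 100) / Decimal(base)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def threshold_summary(results, cutoffs: Cutoffs = Cutoffs(), comparison_label: str = "") -> ThresholdSummary:
    """Tabulate how many loci fall below / outside each rho cutoff.

    ``results`` is a collection of :class:`EfficiencyResult` or a plain
    sequence of rho values. All comparisons are strict: boundary values
    count as inside the band.
    """
    rhos = np.asarray(
        [r.rho if isinstance(r, EfficiencyResult) else float(r) for r in results], dtype=float
    )
    if rhos.size == 0:
        raise ValidationError("threshold_summary requires at least one locus")
    base = int(rhos.size)
    counts: dict[str, int] = {}
    for c in cutoffs.lower:
        counts[f"rho<{c:g}"] = int(np.sum(rhos < c))
    for lo, hi in cutoffs.bands:
        counts[f"outside({lo:g},{hi:g})"] = int(np.sum((rhos < lo) | (rhos > hi)))
    pct = {k: _pct_half_up(v, base) for k, v in counts.items()}
    return ThresholdSummary(base=base, counts=counts, percentages=pct, comparison_label=comparison_label)


_RESULT_COLUMNS = [
    "locus_id",
    "trait",
    "n_larger",
    "n_smaller",
    "p_larger",
    "p_smaller",
    "neglog10_p_larger",
    "neglog10_p_smaller",
    "xi_larger",
    "xi_smaller",
    "rho",
    "delta_p",
    "category",
]


def results_to_frame(results: list[EfficiencyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "locus_id": r.locus_id,
                "trait": r.trait,
                "n_larger": r.n_larger,
                "n_smaller": r.n_smaller,
                "p_larger": 10.0 ** (-r.neglog10_p_larger),
                "p_smaller": 10.0 ** (-r.neglog10_p_smaller),
                "neglog10_p_larger": r.neglog10_p_larger,
                "neglog10_p_smaller": r.neglog10_p_smaller,
                "xi_larger": r.xi_larger,
                "xi_smaller": r.xi_smaller,
                "rho": r.rho,
                "delta_p": r.delta_p,
                "category": r.category.value,
            }
        )
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(results: list[EfficiencyResult], path) -> None:
    df = results_to_frame(results)
    float_cols = df.columns.difference(["locus_id", "trait", "category", "n_larger", "n_smaller"])
    for col in float_cols:
        df[col] = df[col].map(lambda v: f"{v:.10g}")
    df.to_csv(path, sep="\t", index=False)
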