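"""Synthetic paired GWAS summary statistics with known effect structure.

For a quantitative trait with residual standard deviation sigma = 1, the
association z-statistic of a biallelic SNP with minor allele frequency f,
per-allele effect b, and analyzed sample size N is approximately

    z ~ Normal(b * sqrt(2 f (1 - f) N), 1).

The generator draws one such z per locus per study, converts it to a
two-sided p-value in log space, and emits two study panels in the standard
summary-statistics schema. Heterogeneity between studies is expressed by a
multiplicative shift of the larger study's effect, b_1 = b (1 + delta); the
smaller study keeps b_2 = b, so attenuation (delta < 0) in the larger,
later study drives the relative efficiency rho = xi_1/xi_2 below 1. In the
large-N limit -log10 p / N -> b^2 f(1-f) / ln 10, hence rho -> (1 + delta)^2.

A nested or partially overlapping sample pair is modelled by correlating
the two studies' z-statistics (bivariate normal; r = sqrt(N2/N1) for full
nesting under homogeneity). A mixture scenario — a fraction w of the larger
study's sample carrying no effect — reduces, at the level of the pooled
z-statistic, to the same arithmetic with delta = -w (the effective
meta-analytic effect is b(1 - w)); see :func:`delta_from_null_mixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pvalues import neglog10p_from_abs_z
from .summary_io import LocusRecord, StudyPanel

__all__ = [
    "SimConfig",
    "SimResult",
    "RhoSweepSummary",
    "simulate_pair_study",
    "homogeneity_rho_sweep",
    "power_curve",
    "delta_from_null_mixture",
]


def delta_from_null_mixture(null_carrier_fraction: float) -> float:
    """Heterogeneity delta equivalent to a fraction of effect-free carriers.

    If a fraction w of the larger study's sample carries b = 0 while the
    rest carries b, the fixed-effects pooled estimate has expectation
    b (1 - w), i.e. the same non-centrality as delta = -w.
    """
    if not (0.0 <= null_carrier_fraction <= 1.0):
        raise ValidationError("null_carrier_fraction must be in [0, 1]")
    return -null_carrier_fraction


def _as_array(value, n_loci: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_loci, float(arr))
    if arr.shape != (n_loci,):
        raise ValidationError(f"{name} must be scalar or length {n_loci}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SimConfig:
    """Specification of one synthetic two-study experiment.

    ``n1`` is the larger study's sample size; ``heterogeneity_delta``
    multiplies the larger study's effect by (1 + delta). ``null_fraction``
    sets a random subset of loci to b = 0. All per-locus fields accept a
    scalar or a length-``n_loci`` sequence.
    """

    n_loci: int
    n1: int
    n2: int
    maf: float | Sequence[float] = 0.25
    effect_b: float | Sequence[float] = 0.05
    heterogeneity_delta: float | Sequence[float] = 0.0
    null_fraction: float = 0.0
    overlap_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValidationError("n_loci must be >= 1")
        if not (self.n1 >= self.n2 >= 1):
            raise ValidationError("need n1 >= n2 >= 1 (study 1 is the larger study)")
        if not (0.0 <= self.null_fraction <= 1.0):
            raise ValidationError("null_fraction must be in [0, 1]")
        if not (0.0 <= self.overlap_correlation < 1.0):
            raise ValidationError("overlap_correlation must be in [0, 1)")
        maf = _as_array(self.maf, self.n_loci, "maf")
        if np.any(maf <= 0.0) or np.any(maf > 0.5):
            raise ValidationError("maf values must lie in (0, 0.5]")
        _as_array(self.effect_b, self.n_loci, "effect_b")
        _as_array(self.heterogeneity_delta, self.n_loci, "heterogeneity_delta")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(maf, effect_b, heterogeneity_delta) broadcast to length n_loci."""
        return (
            _as_array(self.maf, self.n_loci, "maf"),
            _as_array(self.effect_b, self.n_loci, "effect_b"),
            _as_array(self.heterogeneity_delta, self.n_loci, "heterogeneity_delta"),
        )

    def mean_z(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus non-centralities (mean z) of the larger and smaller study."""
        maf, b, delta = self.arrays()
        a = b * np.sqrt(2.0 * maf * (1.0 - maf))  # per-sqrt(N) non-centrality, sigma = 1
        return a * (1.0 + delta) * np.sqrt(self.n1), a * np.sqrt(self.n2)


@dataclass
class SimResult:
    """Two simulated panels plus the deterministic large-N limit of rho."""

    panel_larger: StudyPanel
    panel_smaller: StudyPanel
    true_rho_limit: np.ndarray
    config: SimConfig


def _draw_correlated_z(rng, mean1, mean2, r, size):
    e1 = rng.standard_normal(size)
    e2 = r * e1 + np.sqrt(1.0 - r * r) * rng.standard_normal(size)
    return mean1 + e1, mean2 + e2


def simulate_pair_study(config: SimConfig) -> SimResult:
    """Draw one pair of study panels from ``config``; reproducible from its seed."""
    rng = np.random.default_rng(config.seed)
    maf, b, delta = config.arrays()
    b = b.copy()
    n_null = int(round(config.null_fraction * config.n_loci))
    if n_null:
        null_idx = rng.choice(config.n_loci, size=n_null, replace=False)
        b[null_idx] = 0.0
    a = b * np.sqrt(2.0 * maf * (1.0 - maf))
    mean1 = a * (1.0 + delta) * np.sqrt(config.n1)
    mean2 = a * np.sqrt(config.n2)
    z1, z2 = _draw_correlated_z(rng, mean1, mean2, config.overlap_correlation, config.n_loci)
    L1 = neglog10p_from_abs_z(z1)
    L2 = neglog10p_from_abs_z(z2)

    se1 = 1.0 / (np.sqrt(2.0 * maf * (1.0 - maf)) * np.sqrt(config.n1))
    se2 = 1.0 / (np.sqrt(2.0 * maf * (1.0 - maf)) * np.sqrt(config.n2))

    def _panel(label, n, L, z, se):
        records = [
            LocusRecord(
                locus_id=f"L{j + 1:04d}",
                snp_id=f"rs{j + 1:06d}",
                trait="SIM",
                n=int(n),
                neglog10_p=float(L[j]),
                effect=float(z[j] * se[j]),
                se=float(se[j]),
            )
            for j in range(config.n_loci)
        ]
        return StudyPanel(study_label=label, trait_family="synthetic", records=records)

    with np.errstate(invalid="ignore"):
        true_rho_limit = np.where(b != 0.0, (1.0 + delta) ** 2, np.nan)
    return SimResult(
        panel_larger=_panel(f"sim_larger[seed={config.seed}]", config.n1, L1, z1, se1),
        panel_smaller=_panel(f"sim_smaller[seed={config.seed}]", config.n2, L2, z2, se2),
        true_rho_limit=true_rho_limit,
        config=config,
    )


@dataclass(frozen=True)
class RhoSweepSummary:
    """Distribution summary of rho over homogeneous replicates."""

    n_values: int
    mean: float
    median: float
    mean_log: float
    median_log: float
    q025: float
    q25: float
    q75: float
    q975: float


def _simulate_L_matrix(config: SimConfig, n_rep: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """(n_rep, n_loci) matrices of -log10 p for both studies."""
    mean1, mean2 = config.mean_z()
    z1, z2 = _draw_correlated_z(
        rng, mean1[None, :], mean2[None, :], config.overlap_correlation, (n_rep, config.n_loci)
    )
    return neglog10p_from_abs_z(z1), neglog10p_from_abs_z(z2)


def homogeneity_rho_sweep(config: SimConfig, n_rep: int) -> RhoSweepSummary:
    """Monte-Carlo distribution of rho under homogeneity (delta = 0).

    Simulates ``n_rep`` replicate panels, computes rho per locus per
    replicate, and summarizes. Demonstrates the homogeneity fixed point:
    for strong loci the distribution concentrates around 1.
    """
    _, _, delta = config.arrays()
    if np.any(delta != 0.0):
        raise ValidationError("homogeneity_rho_sweep requires heterogeneity_delta = 0")
    rng = np.random.default_rng(config.seed)
    L1, L2 = _simulate_L_matrix(config, n_rep, rng)
    with np.errstate(divide="ignore"):
        log_rho = np.log(L1) - np.log(L2) + np.log(config.n2) - np.log(config.n1)
    log_rho = log_rho[np.isfinite(log_rho)]
    rho = np.exp(log_rho)
    q = np.quantile(rho, [0.025, 0.25, 0.75, 0.975])
    return RhoSweepSummary(
        n_values=int(rho.size),
        mean=float(rho.mean()),
        median=float(np.median(rho)),
        mean_log=float(log_rho.mean()),
        median_log=float(np.median(log_rho)),
        q025=float(q[0]),
        q25=float(q[1]),
        q75=float(q[2]),
        q975=float(q[3]),
    )


def power_curve(
    config: SimConfig,
    deltas: Sequence[float],
    alpha: float = 0.05,
    n_rep: int = 2_000,
) -> pd.DataFrame:
    """Rejection rate of the delta-method rho test across a heterogeneity grid.

    For each delta the base config is re-run with that (scalar) heterogeneity
    while the underlying normal draws are shared across grid points (common
    random numbers), so power differences along the grid are not masked by
    Monte-Carlo noise. Returns a DataFrame with columns ``delta``,
    ``rejection_rate``, ``n_tests``.
    """
    if len(deltas) == 0:
        raise ValidationError("deltas grid must be non-empty")
    from .inference import delta_test_arrays

    rng = np.random.default_rng(config.seed)
    maf, b, _ = config.arrays()
    a = b * np.sqrt(2.0 * maf * (1.0 - maf))
    r = config.overlap_correlation
    e1 = rng.standard_normal((n_rep, config.n_loci))
    e2 = r * e1 + np.sqrt(1.0 - r * r) * rng.standard_normal((n_rep, config.n_loci))

    rows = []
    for delta in deltas:
        mean1 = a * (1.0 + float(delta)) * np.sqrt(config.n1)
        mean2 = a * np.sqrt(config.n2)
        L1 = neglog10p_from_abs_z(mean1[None, :] + e1)
        L2 = neglog10p_from_abs_z(mean2[None, :] + e2)
        ok = (L1 > 0) & (L2 > 0)
        res = delta_test_arrays(L1[ok], L2[ok], config.n1, config.n2, r)
        rows.append(
            {
                "delta": float(delta),
                "rejection_rate": float(np.mean(res["p_value"] < alpha)),
                "n_tests": int(res["p_value"].size),
            }
        )
    return pd.DataFrame(rows, columns=["delta", "rejection_rate", "n_tests"])
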