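"""Per-locus tests of H0: rho = 1 (no heterogeneity between studies).

Because rho is a positive ratio, testing is done on the ln(rho) scale.
Writing L_i = -log10 p_i for the larger (i = 1) and smaller (i = 2) study,

    ln rho_hat = ln L1 - ln L2 + ln(N2 / N1),

and treating each association z-statistic as Normal(mean |z_i|, variance 1).

The default statistic is score-type: a common per-person non-centrality c
is fitted under H0 from the pooled observation, the mean and variance of
ln rho* under that fitted null are evaluated exactly (Gauss-Hermite
quadrature of ln L(|z|) moments, z ~ Normal(c sqrt(N_i), 1)), and

    z_stat = (ln rho_hat - E0[ln rho*]) / sd0(ln rho*)

is referred to the standard normal, two-sided. Centering matters because
E0[ln rho*] is not exactly 0 at finite non-centrality (the log-order terms
of -log10 p grow sub-quadratically), and exact moments matter because
first-order propagation understates the spread of ln L below |z| ~ 3.5.
The classical first-order delta form — z_stat = ln rho_hat / se with
Var(ln L_i) ~= (sd_neglog10p(|z_i|) / L_i)^2 at the observed z — remains
available as ``variance="first_order"``. Correlated studies (r =
sqrt(N2/N1) for a nested subsample under homogeneity, 0 for independent
ones) contribute -2 r sd(ln L1) sd(ln L2) to the variance.

A parametric Monte-Carlo alternative serves as the reference oracle: under
H0 a common per-person non-centrality is fitted from the pooled observation,
z-pairs are re-simulated, and the observed rho_hat is ranked against the
null distribution of rho*.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import DegenerateError, ValidationError
from .pvalues import abs_z_from_neglog10p, neglog10p_from_abs_z, sd_neglog10p
from .summary_io import PairedLocus

__all__ = [
    "TestMethod",
    "NullSpec",
    "RhoInference",
    "SignificanceCounts",
    "nested_overlap_correlation",
    "p_to_abs_z",
    "rho_test_delta",
    "rho_test_mc",
    "rho_tests",
    "significance_summary",
    "inferences_to_frame",
]

_Z_UNSTABLE = 1e-8


class TestMethod(enum.Enum):
    DELTA = "delta"
    MONTE_CARLO = "monte_carlo"


def nested_overlap_correlation(n_small: int, n_large: int) -> float:
    """Correlation of z-statistics when the smaller sample is nested in the
    larger one: sqrt(N_small / N_large) under homogeneity."""
    if not (0 < n_small <= n_large):
        raise ValidationError("need 0 < n_small <= n_large")
    return float(np.sqrt(n_small / n_large))


@dataclass(frozen=True)
class NullSpec:
    """Null-hypothesis configuration for the rho test."""

    assume_independent: bool = True
    overlap_correlation: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 <= self.overlap_correlation < 1.0):
            raise ValidationError("overlap_correlation must be in [0, 1)")
        if self.assume_independent and self.overlap_correlation != 0.0:
            raise ValidationError("overlap_correlation must be 0 when assume_independent")


@dataclass(frozen=True)
class RhoInference:
    """Point estimate and test of H0: rho = 1 for one locus."""

    locus_id: str
    rho_hat: float
    se_log_rho: float
    z_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool
    method: TestMethod
    alpha: float
    unstable: bool = False
    seed: int | None = None


def p_to_abs_z(p=None, neglog10_p=None):
    """|z| with two-sided tail probability p; log-space safe.

    Supply either ``p`` in (0, 1] or its ``neglog10_p``; -log10 p values of
    several hundred round-trip with relative error below 1e-6.
    """
    if (p is None) == (neglog10_p is None):
        raise ValidationError("supply exactly one of p or neglog10_p")
    if p is not None:
        from .pvalues import neglog10p_from_p

        neglog10_p = neglog10p_from_p(p)
    return abs_z_from_neglog10p(neglog10_p)


def _two_sided_normal_p(z_stat):
    return special.erfc(np.abs(z_stat) / np.sqrt(2.0))


# Gauss-Hermite rule for moments under z ~ N(mu, 1); an even node count
# avoids the node at z = 0 where ln L diverges.
_GH_NODES, _GH_W = np.polynomial.hermite_e.hermegauss(300)
_GH_W = _GH_W / _GH_W.sum()


def _moments_ln_L(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact (mean, variance) of ln L(|z|) for z ~ Normal(mu, 1), by quadrature."""
    z = np.abs(np.asarray(mu, dtype=float)[..., None] + _GH_NODES)
    ln_L = np.log(neglog10p_from_abs_z(z))
    mean = np.sum(_GH_W * ln_L, axis=-1)
    var = np.sum(_GH_W * (ln_L - mean[..., None]) ** 2, axis=-1)
    return mean, var


def delta_test_arrays(L1, L2, n1, n2, overlap_correlation=0.0, variance: str = "exact"):
    """Vectorized core of the rho test on the ln(rho) scale.

    Parameters are -log10 p and sample sizes of the larger (1) and smaller
    (2) study. ``variance="exact"`` (default) gives the null-centered
    score-type statistic with quadrature moments; ``"first_order"`` gives
    the classical uncentered delta-method Wald form. Returns a dict of
    arrays: ``rho``, ``log_rho``, ``null_mean_log_rho``, ``se_log_rho``,
    ``z_stat``, ``p_value``, ``unstable``.
    """
    if variance not in ("exact", "first_order"):
        raise ValidationError(f"variance must be 'exact' or 'first_order', got {variance!r}")
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(L1 <= 0.0) or np.any(L2 <= 0.0):
        raise DegenerateError("rho test undefined when a study's p-value is 1 (xi = 0)")
    z1 = abs_z_from_neglog10p(L1)
    z2 = abs_z_from_neglog10p(L2)
    r = float(overlap_correlation)
    log_rho = np.log(L1) - np.log(L2) + np.log(n2) - np.log(n1)
    if variance == "exact":
        c = _fit_common_noncentrality(z1, z2, n1, n2)
        m1, v1 = _moments_ln_L(c * np.sqrt(n1))
        m2, v2 = _moments_ln_L(c * np.sqrt(n2))
        null_mean = m1 - m2 + np.log(n2) - np.log(n1)
        sd_ln1, sd_ln2 = np.sqrt(v1), np.sqrt(v2)
    else:
        null_mean = np.zeros(np.shape(log_rho))
        sd_ln1 = sd_neglog10p(z1) / L1
        sd_ln2 = sd_neglog10p(z2) / L2
    se = np.sqrt(sd_ln1**2 + sd_ln2**2 - 2.0 * r * sd_ln1 * sd_ln2)
    z_stat = (log_rho - null_mean) / se
    return {
        "rho": np.exp(log_rho),
        "log_rho": log_rho,
        "null_mean_log_rho": null_mean,
        "se_log_rho": se,
        "z_stat": z_stat,
        "p_value": _two_sided_normal_p(z_stat),
        "unstable": (np.minimum(z1, z2) < _Z_UNSTABLE),
    }


def rho_test_delta(
    pair: PairedLocus, null_spec: NullSpec = NullSpec(), variance: str = "exact"
) -> RhoInference:
    """Normal-model Wald test of H0: rho = 1 on the ln(rho) scale."""
    out = delta_test_arrays(
        pair.larger.neglog10_p,
        pair.smaller.neglog10_p,
        pair.larger.n,
        pair.smaller.n,
        null_spec.overlap_correlation,
        variance=variance,
    )
    q = float(special.ndtri(1.0 - null_spec.alpha / 2.0))
    log_rho = float(out["log_rho"])
    se = float(out["se_log_rho"])
    p_value = float(out["p_value"])
    unstable = bool(out["unstable"])
    if unstable:
        warnings.warn(
            f"{pair.locus_id}: |z| below {_Z_UNSTABLE:g}; delta approximation unstable, "
            "consider the Monte-Carlo test",
            stacklevel=2,
        )
    return RhoInference(
        locus_id=pair.locus_id,
        rho_hat=float(out["rho"]),
        se_log_rho=se,
        z_stat=float(out["z_stat"]),
        p_value=p_value,
        ci_low=float(np.exp(log_rho - q * se)),
        ci_high=float(np.exp(log_rho + q * se)),
        significant=bool(p_value < null_spec.alpha),
        method=TestMethod.DELTA,
        alpha=null_spec.alpha,
        unstable=unstable,
    )


def _fit_common_noncentrality(z1: float, z2: float, n1: float, n2: float) -> float:
    """Least-squares fit of the shared per-person non-centrality c under H0,
    where z_i ~ Normal(c sqrt(N_i), 1): c = (sqrt(N1) z1 + sqrt(N2) z2) / (N1 + N2)."""
    return (np.sqrt(n1) * z1 + np.sqrt(n2) * z2) / (n1 + n2)


def rho_test_mc(
    pair: PairedLocus,
    null_spec: NullSpec = NullSpec(),
    n_rep: int = 10_000,
    seed: int = 0,
) -> RhoInference:
    """Parametric Monte-Carlo test of H0: rho = 1.

    Fits a common per-person non-centrality from the pooled observation,
    simulates ``n_rep`` correlated z-pairs under the null, and ranks the
    observed rho_hat two-sidedly against the simulated rho* (add-one
    percentile, so p-values are never 0). Deterministic given ``seed``.
    """
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    L1, L2 = pair.larger.neglog10_p, pair.smaller.neglog10_p
    if L1 <= 0.0 or L2 <= 0.0:
        raise DegenerateError("rho test undefined when a study's p-value is 1 (xi = 0)")
    n1, n2 = float(pair.larger.n), float(pair.smaller.n)
    z1 = abs_z_from_neglog10p(L1)
    z2 = abs_z_from_neglog10p(L2)
    c = _fit_common_noncentrality(z1, z2, n1, n2)
    r = null_spec.overlap_correlation

    rng = np.random.default_rng(seed)
    e1 = rng.standard_normal(n_rep)
    e2 = r * e1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n_rep)
    z1_star = np.abs(c * np.sqrt(n1) + e1)
    z2_star = np.abs(c * np.sqrt(n2) + e2)
    L1_star = neglog10p_from_abs_z(z1_star)
    L2_star = neglog10p_from_abs_z(z2_star)
    with np.errstate(divide="ignore"):
        log_rho_star = np.log(L1_star) - np.log(L2_star) + np.log(n2) - np.log(n1)
    ok = np.isfinite(log_rho_star)
    if not np.any(ok):
        warnings.warn(f"{pair.locus_id}: degenerate Monte-Carlo null (all replicates at p = 1)", stacklevel=2)
    log_rho_star = log_rho_star[ok]
    m = log_rho_star.size

    log_rho_obs = float(np.log(L1) - np.log(L2) + np.log(n2) - np.log(n1))
    n_le = int(np.sum(log_rho_star <= log_rho_obs))
    n_ge = int(np.sum(log_rho_star >= log_rho_obs))
    p_value = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (m + 1))

    se = float(np.std(log_rho_star, ddof=1)) if m > 1 else float("nan")
    null_mean = float(np.mean(log_rho_star)) if m else float("nan")
    q = float(special.ndtri(1.0 - null_spec.alpha / 2.0))
    return RhoInference(
        locus_id=pair.locus_id,
        rho_hat=float(np.exp(log_rho_obs)),
        se_log_rho=se,
        z_stat=(log_rho_obs - null_mean) / se if se > 0 else float("nan"),
        p_value=p_value,
        ci_low=float(np.exp(log_rho_obs - q * se)),
        ci_high=float(np.exp(log_rho_obs + q * se)),
        significant=bool(p_value < null_spec.alpha),
        method=TestMethod.MONTE_CARLO,
        alpha=null_spec.alpha,
        seed=seed,
    )


def rho_tests(
    pairs,
    null_spec: NullSpec = NullSpec(),
    method: TestMethod = TestMethod.DELTA,
    bonferroni: bool = False,
    n_rep: int = 10_000,
    seed: int = 0,
) -> list[RhoInference]:
    """Run the rho test for every pair; optional Bonferroni adjustment of
    the significance threshold (alpha / number of loci)."""
    pairs = list(pairs)
    alpha = null_spec.alpha / len(pairs) if bonferroni else null_spec.alpha
    spec = NullSpec(null_spec.assume_independent, null_spec.overlap_correlation, alpha)
    out = []
    for i, pair in enumerate(pairs):
        if method is TestMethod.DELTA:
            out.append(rho_test_delta(pair, spec))
        else:
            out.append(rho_test_mc(pair, spec, n_rep=n_rep, seed=seed + i))
    return out


@dataclass(frozen=True)
class SignificanceCounts:
    """How many loci deviate significantly from rho = 1, and in which direction."""

    significant_below: int
    significant_above: int
    non_significant: int

    @property
    def base(self) -> int:
        return self.significant_below + self.significant_above + self.non_significant


def significance_summary(inferences) -> SignificanceCounts:
    inferences = list(inferences)
    if not inferences:
        raise ValidationError("significance_summary requires at least one inference")
    below = sum(1 for r in inferences if r.significant and r.rho_hat < 1.0)
    above = sum(1 for r in inferences if r.significant and r.rho_hat > 1.0)
    return SignificanceCounts(below, above, len(inferences) - below - above)


def inferences_to_frame(inferences: list[RhoInference]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": r.locus_id,
            "rho_hat": r.rho_hat,
            "se_log_rho": r.se_log_rho,
            "z_stat": r.z_stat,
            "p_value": r.p_value,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "significant": r.significant,
            "method": r.method.value,
            "seed": r.seed,
        }
        for r in inferences
    ]
    return pd.DataFrame(rows)
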