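# Methods

## The efficiency measure

For one locus in one study reporting a two-sided association p-value `p`
from an analyzed sample of `N` individuals, the efficiency is

    xi = -log10(p) / N,

the log-transformed p-value extracted per person. For a pair of studies of
the same trait — subscript 1 the larger sample, 2 the smaller — the
relative efficiency is `rho = xi_1 / xi_2`.

The motivation is the standard quantitative-trait association model: with
minor allele frequency `f`, per-allele effect `b`, and residual trait
standard deviation `sigma`, the association z-statistic is approximately
Normal with unit variance and mean (non-centrality)

    E[z] = b * sqrt(2 f (1 - f) N) / sigma.

Since `-log10 p ~ z^2 / (2 ln 10)` up to logarithmic terms, the expectation
of `-log10 p` grows linearly in `N` when the same `b` drives both studies,
so `rho -> 1`: homogeneity is a fixed point. Persistent deviation of `rho`
from 1 — most interestingly `rho < 1`, the larger study extracting less
signal per person — indicates heterogeneity of the genetic effect between
the two study populations. The companion quantity
`delta_p = -(log10 p_larger - log10 p_smaller)` classifies each locus: the
p-value got **larger** in the larger study (`delta_p < 0`), decreased by at
most two orders of magnitude (**minor decrease**, `0 <= delta_p <= 2`,
boundary inclusive), or decreased **substantially** (`delta_p > 2`).

All p-values are carried as `-log10 p` end to end. Conversions between
p-values and |z| go through `scipy.special.log_ndtr` / `ndtri_exp` in log
space, so meta-analysis tails far beyond the double underflow threshold
(`-log10 p` of several hundred) survive round trips with relative error
below 1e-6 (measured: ~4e-14).

## Pairing and selection rules

Studies are paired locus-by-locus on the gene label (optionally on the
index SNP). The "larger" study is designated **per locus**, not per panel:
large meta-analyses occasionally analyze fewer individuals than an older
study for individual SNPs. Exact sample-size ties take the first panel as
larger and carry an explicit tie flag — real meta-analysis pairs never tie
exactly, but the behavior must be defined. Loci present in only one panel,
or present with conflicting traits, are omitted and reported with reasons,
so pair counts always reconcile with panel sizes.

Two further selection rules mirror common multi-trait practice: a
sample-size gap filter (`larger.n - smaller.n >= min_gap`, boundary
inclusive, e.g. 10,000 individuals) restricts comparisons to pairs whose
sizes genuinely differ; and for lipid panels reporting each SNP against TC,
LDL, HDL and TG, the single best-associated trait per SNP (smallest p) is
selected, with exact ties broken by the canonical trait order TC, LDL,
HDL, TG and flagged. The gap filter is defined on the per-locus designated
larger/smaller records (an absolute gap), which is the only reading
consistent with the studies' stated sizes.

## Threshold summaries

`threshold_summary` counts loci with `rho < 0.9`, `rho < 0.8`, and `rho`
strictly outside the open bands `(0.9, 1.1)` and `(0.8, 1.2)` (cutoffs
configurable). All comparisons are strict, so boundary values fall inside
the band; `rho` is not rounded before comparison. Percentages are computed
exactly as rationals and rounded half-up to one decimal. The outside-band
count is always at least the corresponding one-sided count, since
`{rho < c}` is a subset of `{rho outside (c, c')}`.

## Testing rho = 1

Because `rho` is a positive ratio, inference is done on `ln rho`. Writing
`L_i = -log10 p_i`,

    ln rho_hat = ln L1 - ln L2 + ln(N2 / N1).

Each study's evidence is modelled as `z_i ~ Normal(|z_i|, 1)` with
`L_i = L(z_i) = -log10(2 Phi(-|z_i|))`.

The default statistic is score-type. Under H0 a common per-person
non-centrality is fitted by least squares from the pooled observation,
`c = (sqrt(N1) z1 + sqrt(N2) z2) / (N1 + N2)`, and the exact mean and
variance of `ln L(|z|)` under `z ~ Normal(c sqrt(N_i), 1)` are evaluated by
Gauss–Hermite quadrature (300 nodes; an even count avoids the singular
point z = 0). Then

    z_stat = (ln rho_hat - E0[ln rho*]) / sd0(ln rho*)

is referred to the standard normal, two-sided. Two refinements over the
textbook first-order delta method matter here:

- **Centering.** `E0[ln rho*]` is not exactly 0 at finite non-centrality,
  because `-log10 p` grows sub-quadratically in `z` (logarithmic correction
  terms); at mean z of 6 vs 8.5 the null mean of `ln rho*` is about -0.03.
- **Exact moments.** First-order propagation
  (`Var(ln L) ~ (sd_neglog10p(|z|)/L)^2`) understates the spread of
  `ln L` below `|z| ~ 3.5`, where the left tail of `L(z)` near `z = 0`
  contributes; quadrature moments track the Monte-Carlo truth within ~1%
  down to `|z| = 3`.

The first-order uncentered Wald form remains available
(`variance="first_order"`) and is pinned by unit tests to its documented
formula. Measured operating characteristics of the default test (one CPU,
seconds): type-I error 0.047–0.051 at alpha = 0.05 for smaller-study mean z
from 6 to 30; analytic se within a factor 0.99–1.02 of the Monte-Carlo sd
of `ln rho*` for both |z| >= 3; power against multiplicative attenuation of
the larger study's effect increasing in |delta| (~0.60 at delta = -0.5 at
the non-centrality floor 6).

Confidence intervals are plain normal intervals around the estimate,
`exp(ln rho_hat ± z_{1-alpha/2} se)`; they may disagree with the centered
test by O(|E0[ln rho*]|) near the boundary, which is documented behavior.

The Monte-Carlo companion (`rho_test_mc`) simulates z-pairs under the
fitted null — bivariate normal when the studies overlap — and ranks the
observed `ln rho_hat` two-sidedly with an add-one percentile, so its
p-values are bounded below by `2/(n_rep + 1)` and are never 0. It is the
reference oracle for the analytic test and the advised fallback when
either |z| is near 0, where the normal-model moments become unstable
(flagged at |z| < 1e-8).

Study overlap: cross-study comparisons default to independence; for a
nested subsample (e.g. a genotyping-array subset of the full meta-analysis)
the z-statistics correlate as `r = sqrt(N_small / N_large)` under
homogeneity, and the variance subtracts `2 r sd1 sd2`. Per-locus tests are
reported without multiplicity adjustment by default (a Bonferroni option
exists), matching how per-locus significance is usually read in this
setting.

## The synthetic generator

`simulate_pair_study` draws, per locus and study,
`z ~ Normal(b sqrt(2 f (1-f) N) / sigma, 1)` with `sigma = 1` (effects in
residual-SD units), converts through the log-space tail machinery, and
emits panels in the same TSV schema the readers consume (round-trip
lossless). Defaults — 0.25 MAF, per-allele effects around 0.02 SD, sample
sizes of order 1e5–3e5 — produce smaller-study non-centralities around 6,
i.e. loci hovering at genome-wide significance, which is the hard regime
for the test. Heterogeneity multiplies the **larger** study's effect by
`(1 + delta)`; attenuation (`delta < 0`) in the larger, later study is the
scenario of interest, driving `rho -> (1 + delta)^2 < 1` in the large-N
limit. A mixture scenario (a fraction `w` of the larger sample carrying no
effect) reduces to `delta = -w` at the level of the pooled z-statistic.
Overlapping samples are modelled as correlated z-statistics; `null_fraction`
sets a random subset of loci to `b = 0` (their two-sided p-values are
verified uniform).

What the generator does **not** emulate: linkage disequilibrium between
loci, winner's-curse ascertainment of the discovery study, case-control
traits, between-cohort fixed-effects machinery inside each meta-analysis,
and real covariance of per-SNP sample sizes. Passing calibration here
therefore shows the statistics behave correctly under the stated normal
model — not that real study pairs satisfy that model.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen as the package's own
defaults: 10,000 replicates for the homogeneity limit (mean rho within
[0.98, 1.02] at mean z >= 30), 2,000 replicates for type-I/power (exact
binomial banding), 50–100 pairs at 20,000 replicates each for oracle
agreement. The power grid shares its underlying normal draws across delta
values (common random numbers), so monotonicity is not masked by
Monte-Carlo noise. All randomness flows from a single integer seed through
`numpy.random.default_rng`; every stochastic output records its seed, and
CLI runs write a `params.json` sufficient to reproduce outputs
byte-for-byte.

Degenerate inputs are explicit errors rather than NaNs: p = 1 in the
smaller study makes `rho` undefined (`DegenerateError`, CLI exit code 3);
invalid rows in input TSVs are reported with file line numbers (exit
code 2).

## Known limitations

- The per-locus test conditions on the reported (p, N) pairs; it does not
  model uncertainty in effective sample size or imputation quality.
- Partial, unquantified overlap between two meta-analyses biases the
  independent-studies test toward conservatism (true correlation makes the
  null spread smaller); only fully nested overlap is modelled exactly.
- `xi` deliberately uses only (p, N): no allele-frequency or effect-size
  standardization across traits, so rho comparisons across trait families
  are qualitative.
- Near the significance floor (|z| of either study below ~3) the normal
  model for `ln L` is skewed; the MC test is the safer choice there.
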