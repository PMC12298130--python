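# Methods

## Scope and data model

The package assesses heavy-metal contamination of lake surface sediments
from a small survey: a per-site concentration table (mg/kg dry weight) for
As, Cd, Cr, Cu, Mn, Ni, Pb and Zn, optionally with an Al reference column,
plus parameter tables — geochemical background values, biological toxicity
factors, USEPA toxicological constants (RfD, SF, ABS) and per-group
exposure distributions. Because surveys of this kind are typically
published only as summary statistics (per-element min/max/median/mean/SD
plus a named best-fit distribution family for n ≈ 15 sites), the package
treats the summary table as a first-class input: distribution specs are
fitted to it analytically and a synthetic-survey generator can materialize
per-site tables consistent with it.

## Pollution and ecological-risk indices

I_geo = log2(c/(1.5·C0)); the 1.5 factor absorbs lithogenic variability of
the background. EF is the double ratio (c_i/c_ref)/(C0_i/C0_ref) with Al
as the conservative reference. C_f = c/C0. All classification schemes use
left-open right-closed intervals, so a value exactly on a breakpoint falls
in the lower category (EF = 1.0 is "Uncontaminated").

The single ecological risk index is exposed in two modes because the
literature is not uniform. The default `paper` mode computes
E_i = T_r/C_f = T_r·C0/c, which decreases with concentration; it is the
formula printed and used by the study whose results this package
reproduces, and it does reproduce every reported per-element E_i mean from
the summary table. The `standard` mode is the classical Hakanson product
T_r·C_f. The composite RI sums E_i over a configurable subset; the default
subset {As, Cd, Cr, Cu, Pb, Zn} excludes Mn and Ni because the reported
composite value (32.83) equals the reported per-element means summed over
exactly those six (all eight would give 35.10). The background table is a
single Dongting-basin sediment row used for all indices; sample standard
deviations use the n−1 denominator, and CV% = 100·sd/mean.

A note on averaging: reported survey means of I_geo are per-site averages
of a concave function and therefore sit below I_geo evaluated at the mean
concentration, by approximately cv²/(2 ln 2) — under 0.008 for every
element here. Deterministic recovery checks from summary means account for
this offset; per-site reproduction requires the synthetic generator.

## Distribution fitting and selection

Seven continuous families are supported — normal, lognormal, logistic,
Gumbel max/min ("maximum/minimum extreme value" in commercial MC tools),
triangular, uniform — plus a point mass. Location-scale parameters are
inverted analytically from (mean, sd): logistic scale s = sd·√3/π; Gumbel
scale β = sd·√6/π with location mean ∓ γβ (γ = 0.5772…, Euler–Mascheroni);
lognormal log-space parameters from σ² = ln(1 + (sd/mean)²),
μ = ln(mean) − σ²/2, so a "mean ± sd" row in a parameter table keeps its
arithmetic meaning. Triangular specs are built from the
mode (min, max) convention with mean (min + mode + max)/3.

Family selection computes the fully-specified Anderson–Darling statistic
A² = −n − (1/n)Σ(2i−1)[ln F(x_(i)) + ln(1 − F(x_(n+1−i)))] for each
moment-fitted candidate and keeps the minimum, breaking ties by the listed
family order. The triangular candidate takes its support from the sample
extremes and its mode from 3·median − 2·mean clamped into range; because
its CDF is exactly 0/1 at the sample extremes, the clipped log terms
penalize it heavily, which is a known conservative bias of extreme-based
triangular fits. Method-of-moments rather than maximum likelihood is used
throughout: at n = 15 it is stable, closed-form and reproducible. Family
discrimination at n = 15 is intrinsically noisy — symmetric families
(normal/logistic) are close to indistinguishable — so selection claims are
tested as majorities or pluralities over seed ensembles, not per-seed.

One family substitution is deliberate: the Zn column's reported "binomial"
family is carried as a (truncated) normal, since a discrete count family
cannot be moment-fitted to continuous mg/kg concentrations without an
unstated rounding convention; any family can be forced via the params file.

## Monte Carlo engine

Plain Monte Carlo, default 10,000 iterations. Every input receives an
independent child stream of the master seed (spawned by sorted key, so
results are independent of mapping order); no inter-element correlation is
imposed, as none is published. Concentration specs are truncated at zero
(by rejection resampling). Outputs are summarized as mean, n−1 sd,
linear-interpolation percentiles at {2.5, 5, 50, 95, 97.5} (both the 90%
and 95% central bands, since "95% confidence level" is not operationalized
in the source workflow), empirical category probabilities, and threshold
exceedance fractions. Non-finite output draws are excluded with a logged
count; more than 1% non-finite aborts the run, so silent degradation is
impossible.

## Health risk

CDD_ing = c·IR·ED·EF·CF/(BW·AT) and CDD_derm = c·SA·AF·ABS·ED·EF·CF/(BW·AT).
Non-carcinogenic AT is 365·ED days (ED cancels); carcinogenic AT is
365·70 days for all groups, including children (ED 18, no latency
adjustment). SA is configured in m² and converted to cm² (×10⁴) to match
AF's mg/(cm²·day); without this conversion all dermal doses would be four
orders of magnitude too small to be meaningful. Point-estimate mode
collapses each exposure distribution to its nominal value — triangular
mode (EF 345 d/a, child BW 29.30 kg, SA modes), lognormal mean (adult BW
67.55/57.59 kg, AF 0.49/0.65) — which is the convention that reproduces
the reported ingestion hazard indices exactly. Probabilistic mode samples
the full distributions, sharing one set of exposure draws across elements
within an iteration (one simulated individual) while concentrations vary
independently. Elements without an RfD or SF for a pathway are skipped
with a logged notice (e.g. Cr and Pb have ingestion-only slope factors;
Cu, Mn, Ni, Zn have none), never imputed as zero; Hg is carried in the
toxicity table but inert without concentration data. CR classification:
negligible below 1e-6, acceptable in [1e-6, 1e-4), unacceptable above.

Known discrepancy: under the published slope factors the mean ingestion CR
ordering across elements is Cr > As > Cd > Pb (c·SF with Cr at
107.07 × 0.5 dominates); the source study reports As > Cd > Cr > Pb, which
no linear dose model can produce from its own printed parameter tables.
The package computes the ordering faithfully from the tables and flags the
reported ordering as unreproducible in its test suite. Reported dermal HI
means and tail exceedance percentages are likewise not exactly
recoverable: they depend on unpublished parameter draws, and the child AF
lognormal (0.65 ± 1.2, CV > 1) makes tail fractions hypersensitive to
parameterization. These are covered by qualitative property checks
(group ordering, sign structure) instead.

## Sensitivity

Contribution to variance of input j is sign(ρ_j)·100·ρ_j²/Σ_k ρ_k² with ρ
the Spearman correlation between input and output draws — the convention
of commercial MC risk tools. Absolute contributions sum to 100%; rank
correlation makes the measure invariant to monotone input transforms.
Inputs without variation are excluded from normalization; a Pearson
variant on raw values is available. This is a correlation-based screening
measure, not a variance decomposition: it is accurate for monotone,
roughly additive models and has no Sobol-style interaction terms.

## Synthetic survey generator

Each element column is drawn from its summary-fitted family,
rejection-sampled into the observed [min, max]; the Al column is the Al
background times a fixed enrichment ratio (default 1.8727, back-solved so
that (mean_i/background_i)/ratio matches the reported mean EF of all eight
elements simultaneously — only the ratio, not the absolute Al level,
affects EF) with 5% relative Gaussian noise. Site ids are S01…S15; tables
are rounded to 4 decimals and written with byte-stable formatting, so one
seed yields one byte-identical CSV.

Calibration: sample moments of 15 draws scatter far too much for seed
search alone to match targets tightly (the relative sampling error of an
sd at n = 15 is ≈ 1/√(2n) ≈ 18%), so `calibrate_to_targets` keeps columns
already within tolerance and affine-rescales the rest to the exact target
mean and sd, preserving the drawn shape. Rescaled values may fall slightly
outside the observed extremes; positivity is enforced, and truncation-induced
sd shrinkage is absorbed by the rescale. What the generator does *not*
emulate: inter-element correlation, spatial gradients (the emulated survey
reports spatial homogeneity), measurement error and detection limits.
Passing tests on synthetic tables therefore demonstrate correctness of the
index arithmetic and the statistical machinery under the stated marginal
structure, not robustness to correlated or spatially structured real data.

## Problem sizes and numerical choices

Monte Carlo checks use the study-scale 10,000 iterations; seed-ensemble
checks (family recovery, standard-error scaling) use 40–100 replicate
seeds at survey size n = 15; sampling-moment checks use 1e5 draws with
CLT-based tolerances (4 standard errors). CDF values inside the A² sum are
clipped to [1e-12, 1 − 1e-12]. Truncation resampling aborts after 1,000
rounds if the truncation region has negligible mass. RI summation uses
exact (fsum) accumulation so the composite is invariant to element order.
Default master seed is 2025; every published-value check in the test suite
fixes its seed explicitly.
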