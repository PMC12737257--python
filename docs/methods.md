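# Methods

`sorisk` implements an integrated, source-oriented risk assessment for
heavy metal(loid)s (HMs) in soils and sediments, of the kind applied to
reservoir drawdown zones and other mixed land-use settings: deterministic
pollution and ecological indices, probabilistic (1D and nested 2D Monte
Carlo) human health risk, an uncertainty-weighted positive matrix
factorization (PMF) receptor model, and the coupling that attributes
ecological and health risk to pollution sources. This note records the
models, the parameter choices that matter, the numerical decisions, and
the limits of what the synthetic test bed can show.

## Pollution and ecological indices

For sample *i* and element *j* with concentration C_ij (mg/kg) and
regional background S_j:

* pollution index `PI_ij = C_ij / S_j`; per sample the Nemerow integrated
  index `NIPI_i = sqrt((PI_ave,i² + PI_max,i²)/2)` combines the mean and
  the worst single element so one hot element is not diluted by the
  panel size.
* Hakanson single-element ecological risk `Er_ij = Tr_j · C_ij / B_j`
  with toxicity coefficient Tr_j; `RI_i = Σ_j Er_ij`; and the
  Nemerow-style comprehensive ecological index
  `NIRI_i = sqrt((Er_ave,i² + Er_max,i²)/2)`.

Shipped toxicity coefficients are the Hakanson set extended with Mn:
Hg 40, Cd 30, As 10, Pb/Cu/Ni 5, Cr 2, Zn 1, Mn 1. Fe has no coefficient
and is excluded from Er/RI/NIRI (it remains in PI/NIPI); both the set and
the exclusion are configuration, not logic. Background values default to
Henan-province surface-soil values (Fe converted from g/kg to mg/kg at
load through an explicit per-element unit declaration; everything
internal is mg/kg).

Grade schemes are ordered (label, lower-bound) lists with half-open
intervals; a value exactly on a break belongs to the higher grade. The
defaults are the standard Nemerow PI/NIPI breaks, the Hakanson Er and RI
breaks, and a NIRI scheme mirroring the Er breaks. All schemes are data
and can be replaced wholesale.

Report output rounds to 2 decimals, half away from zero (the convention
of published survey tables, not banker's rounding). Descriptive
statistics use the sample SD (n−1); CV = SD/mean.

## Human health risk

The exposure model is the USEPA residential-soil three-pathway set.
With soil concentration C (mg/kg):

* ingestion `ADD = C·IR_ing·EF·ED·CF/(BW·AT)`
* dermal `ADD = C·SA·AF·ABS·EF·ED·CF/(BW·AT)`
* inhalation `ADD = C·IR_inh·EF·ED/(PEF·BW·AT)`

with `AT = ED·365` d for non-carcinogenic endpoints and `AT = 70·365` d
for carcinogenic ones (both configurable). `HQ = ADD/RfD` sums over
elements and pathways to the hazard index HI (threshold 1);
`CR = ADD·SF` sums over the elements carrying slope factors — default
carcinogen set {As, Cd, Cr, Ni, Pb} — to TCR (threshold 1e-4). All three
pathways are summed by default; pathway selection is a scenario switch.
Reference doses and slope factors are USEPA RSL/IRIS-style values as
commonly used in the soil-HM risk literature, stored in
`sorisk.defaults` and overridable per element and pathway. No
bioavailability adjustment is applied: doses are computed from total
concentrations, which is conservative.

HI and TCR are linear (degree-1 homogeneous and additive) in the
concentration vector. That linearity is load-bearing: it is what makes
an exact per-source decomposition of risk possible.

Exposure parameters carry distributions (point, truncated-at-zero
normal, lognormal parameterised by arithmetic mean/SD, uniform,
triangular). The shipped catalogue uses values standard in Chinese soil
HM probabilistic risk assessment: child IR_ing lognormal(200, 100)
mg/day and adult lognormal(100, 50); BW normal(15, 2) / (60, 8) kg
truncated at zero; EF triangular(180, 350, 365) d/yr; IR_inh 7.5 / 14.5
m³/day, ED 6 / 24 yr, SA 2800 / 5700 cm², AF 0.2 / 0.07 mg/cm²/day,
ABS 0.001, PEF 1.36e9 m³/kg, CF 1e-6 kg/mg as points. The deterministic
kernel evaluates at distribution means. With these defaults child risks
dominate adult risks for any fixed concentration vector.

## Monte Carlo engines

**1D.** Each iteration draws every exposure parameter independently and
one concentration vector, resampled uniformly from the observed samples
of the land-use stratum — resampling whole rows preserves inter-element
correlation without imposing a parametric joint distribution. Risk
realizations are computed in a factored form: per-iteration pathway
kernels (dose per unit concentration) times precomputed per-sample
toxicity-weighted concentration sums. This is algebraically the
deterministic kernel rearranged, so point-mass distributions collapse to
the deterministic result (to float associativity, ~1e-12 relative), and
the full 10,000 × 200 nested design runs vectorised in a few seconds.
Parameters are assumed independent; no copula support.

**Sensitivity.** Contribution to variance in the rank-correlation
convention: parameter q contributes `sign(ρ_q)·ρ_q²/Σ_r ρ_r²·100` where
ρ is the Spearman correlation between its draws and the risk output.
Point-valued parameters are excluded (no variance to contribute);
absolute contributions sum to 100%. Sobol indices are out of scope.

**2D.** The most sensitive parameter (IR_ing in practice) is drawn
n_outer times in an outer loop representing uncertainty; each outer
value is held fixed while the inner loop draws the remaining parameters
n_inner times (variability). Defaults mirror the standard design
(10,000 inner × 200 outer = 2,000,000 pooled realizations, 200
probability curves). The outer loop reuses the parameter's variability
distribution as its uncertainty distribution — the two are not
separately identified by available data, and this is recorded as an
assumption. Pooled statistics satisfy the law of total variance
(checked in tests to 1e-9 relative).

**Intake threshold.** The critical soil ingestion rate is found on the
mean risk as a function of IR_ing with all other draws frozen once
(common random numbers), which makes the function deterministic and, by
dose linearity, monotone increasing. Bisection narrows the crossing to
0.01 mg/day and one secant step on the final bracket then lands exactly
on the crossing for risk linear in IR_ing. An unbracketed limit returns
a no-crossing result rather than raising.

## PMF receptor model

The concentration matrix is factored as `x_ij = Σ_k g_ik f_kj + e_ij`
(g, f ≥ 0), minimising `Q = Σ_ij ((x_ij − Σ_k g_ik f_kj)/u_ij)²` with
cell-wise uncertainties

* `u = sqrt((EF_j·x)² + (0.5·MDL_j)²)` when x strictly exceeds the
  method detection limit, and
* `u = (5/6)·MDL_j` otherwise (a value exactly at the MDL uses this
  branch).

MDLs and error fractions are required inputs for real data; synthetic
fixtures use MDL = 5% of background and error fraction 0.1.

**Optimisation.** Weighted multiplicative NMF updates with weight matrix
1/u² (iteration cap 5000, relative ΔQ tolerance 1e-8, denominators
guarded at 1e-12); Q is non-increasing along iterations, which the test
suite verifies numerically. The best of n_starts random initialisations
is kept. When several starts tie at the minimum Q (within 0.5%
relative), the factorization has a flat rotational ridge and Q cannot
discriminate; the tie is broken toward the solution with the lowest
per-element loading-fraction entropy, i.e. the sparsest profiles. The
rationale: physical source profiles are tracer-sparse (each source
dominated by a few marker elements), and on a flat ridge the sparse
endpoint is the vertex solution, whereas a pure best-Q pick would be
decided by floating-point noise. This is a tie-break among converged
solutions, not rotational exploration; Fpeak-style tools and
bootstrap/displacement error estimation are out of scope.

**Scale convention.** Each contribution column is normalised to unit
mean and the profile row rescaled, leaving the reconstruction invariant;
profiles then read as mg/kg per average-sample contribution.

**Diagnostics.** `Q_robust` recomputes Q after inflating the uncertainty
of cells with |scaled residual| > 4 to the residual magnitude (their
contribution becomes 1), so a handful of outliers cannot dominate;
`Q_robust/Q_true` near 1 indicates a well-specified model. Also
reported: fraction of scaled residuals in [−3, 3], per-element R²
between observed and reconstructed concentrations, and a Q-versus-k scan
(`factor_number_scan`). Factor-number selection is reported, never
automated. A Spearman correlation matrix with p-values is available as a
source-identification aid.

**Factor summaries.** `factor_loading_pct` gives each factor's percent
of every element's reconstructed mass (mean contribution × profile,
normalised per element). `factor_contribution_pct` averages the loading
fractions over elements, so each element carries equal weight; a
mass-weighted total would be dominated entirely by Fe and Mn, whose
concentrations are orders of magnitude above the trace elements. This is
the package's resolution of a normalisation that receptor-model reports
rarely state explicitly.

Recovery tests match estimated to true factors by Hungarian assignment
on cosine similarity. The assignment is computed on per-element loading
fractions — raw profile rows are Fe/Mn-dominated and nearly collinear,
so cosines on them cannot discriminate factors — while the reported
similarities are cosines of the raw profile rows.

## Source-oriented risk

With a fitted solution, each source's share of each element's observed
mean concentration is `C_j^(k) = loading_frac_kj · mean_i x_ij`; shares
sum to the observed means exactly. Pushing each source's concentration
vector through the risk kernels gives exact additive decompositions of
the summed ecological risk and of HI and TCR (conservation is asserted
to 1e-9 relative).

Ecological shares are computed on the additive Σ_j Er decomposition. The
comprehensive NIRI itself — a quadratic mean — has no unique exact
decomposition, so NIRI is reported for the totals while the shares use
the additive surrogate; this choice is deliberate and surfaced here
rather than buried. Health shares default to mean-concentration
(population-level) attribution; an `mcs` mode evaluates mean risks under
parameter draws shared across sources (common random numbers), which by
linearity differs from the deterministic shares only through the mild
nonlinearity of the dose equations in the exposure parameters.
`priority_ranking` orders sources by share per metric (ties keep factor
order) and, within the top source, orders elements by their risk weight
to name the control priority pair.

## Synthetic data generator

The generator realises the receptor-model equation generatively:
`x = G F + ε` with `ε ~ N(0, max(relative_sd·(GF), floor_sd))`,
heteroscedastic noise mirroring the PMF uncertainty form so weighted
fitting is well-specified. Negative draws are truncated at zero and
counted; more than 1% truncation triggers a warning. Defaults:
relative_sd 0.05, floor_sd 1e-4 mg/kg.

The default study spec emulates a 24-sample survey of 10 elements
(Pb, Cu, Mn, Ni, Zn, Cd, Cr, Hg, As, Fe) across four balanced land-use
strata (farmland, forest, grassland, flooded; 6 samples each) mixed from
four sources: traffic (Pb-anchored, loading also on Cu/Mn/Ni/Cd/Fe),
agriculture (Hg-anchored, with Cd and Cr), natural parent material
(As-anchored, with Fe/Ni/Mn), and atmospheric deposition (Zn-anchored).
Profiles are loading anchors scaled by the target survey means;
contributions are lognormal (σ = 0.4) draws modulated by per-stratum
source intensities and normalised to exact unit column mean, so
pre-noise element means equal the survey targets exactly and generated
means land within a few percent.

Two design features exist for identifiability, and they are also the
more realistic structure: profiles are tracer-sparse (each source has
exact zeros on some elements), and each source is absent from one
stratum (agriculture from the flooded shore, atmospheric deposition from
ploughed farmland, traffic from forest, parent-material input from
sediment). Without such sparsity a nonnegative factorization is
rotationally non-identifiable — truth-initialised and random-initialised
fits reach identical Q with materially different contribution splits —
and no optimiser could be expected to recover the generating structure.

**What the generator does not emulate:** spatial autocorrelation,
wet/dry-cycle temporal dynamics, censoring at detection limits (beyond
zero-truncation), analytical batch effects, and any real covariance
beyond the four-source mixing. Passing recovery tests therefore show
that the estimation machinery is correct under the stated generative
model, not that four sources or these profiles describe any particular
field site.

## Problem sizes and numerical choices

The test suite runs the full nested 2D design once at the published
sizes (10,000 × 200) — a few seconds vectorised — and otherwise uses
reduced iteration counts (hundreds to a few thousand) chosen so the
whole suite completes in well under a minute; acceptance-grade PMF fits
use 10–30 random starts. Random state is handled through
`numpy.random.default_rng` with explicit seeds everywhere; the pipeline
expands one master seed into fixed named substreams per stage so any
stage can be rerun in isolation. Pipeline outputs are a pure function of
inputs, configuration and seeds, and reruns are byte-identical.

## Known limitations

* At the default survey size (24 samples, 4 sources, 5% noise) the
  rotational uncertainty of the factorization leaves an intrinsic
  spread of roughly ±3–6 percentage points in recovered source
  contributions across generator seeds, even with the sparsity
  tie-break; per-source contribution estimates at this sample size
  should be read with that uncertainty in mind.
* The ecological share decomposition is exact for ΣEr but is a
  surrogate for the non-additive NIRI.
* Exposure parameters are treated as mutually independent; synergistic
  or offsetting dependencies between pathways are not modelled.
* Total-concentration doses ignore bioavailable fractions; thresholds
  such as the critical ingestion rate inherit that conservatism.
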