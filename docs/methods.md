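# Methods

## The measurement principle

Above-ground nuclear weapons testing nearly doubled atmospheric ¹⁴C between
1955 and 1963; since the test ban the level has relaxed back toward the
pre-bomb baseline. DNA incorporates carbon at the atmospheric concentration
prevailing when it is synthesized, so the genomic ¹⁴C concentration of a cell
population is a weighted average over the synthesis dates of its DNA. For
human cardiomyocytes — which renew slowly but continue to synthesize DNA
through nuclear polyploidization and binucleation — this makes the measured
Δ¹⁴C of sorted cardiomyocyte nuclei an integral constraint on the
population's renewal history.

Throughout, Δ¹⁴C is the decay-corrected per-mille deviation from the oxalic
acid standard as AMS laboratories report it, and all arithmetic is done on
the fraction value F = 1 + Δ¹⁴C/1000. Time is a decimal calendar year;
calendar dates convert via day-of-year/365.25. No δ¹³C fractionation or
decay correction is applied here — those happen upstream at the AMS lab.

## Population-balance model

A population of constant size renews at rate r(t) (fraction of cells
replaced per year, birth and death balanced). Each cell carries
G(t) = π(t)·ν(t) diploid-genome units:

* π(t) — nuclear genome copies per nucleus = degree of nuclear ploidy / 100;
* ν(t) — mean nuclei per cell = 1 + binucleated fraction.

Both are prescribed, non-decreasing, piecewise-linear trajectories. All new
DNA — from renewal, polyploidization, or binucleation — is synthesized at the
current atmospheric F(t); death removes DNA at the pool-average concentration
(well-mixed, age-independent death, the standard assumption in retrospective
birth-dating models). The pool-average fraction value C(t) then satisfies

    dC/dt = k(t)·(F(t) − C(t)),   k(t) = r(t) + G′(t)/G(t),

with C(birth) = F(birth): prenatal DNA is dated to birth, since gestation is
short against the curve's dynamics. k(t) is the total per-genome DNA
synthesis rate; its additive components

    renewal r·G,   polyploidization π′·ν,   binucleation π·ν′

define the synthesis-origin decomposition. Annual DNA synthesis per cell is
∫(r·G + G′)dt over a calendar year.

**Newborn genome content.** By default newborn cells carry the prevailing
mean genome content G(t), which keeps the prescribed G trajectory
self-consistent (G′ is then the ploidy/binucleation flux alone) and makes the
pre-disease synthesis budget renewal-dominated. Because death is well-mixed,
the alternative assumption — diploid newborns that catch up through extra
polyploidization — leaves C(t) unchanged and only reallocates the
decomposition; it is available as `newborn_policy="diploid"`, which
attributes the catch-up flux r·(G−1) to polyploidization and binucleation in
proportion to the cell's excess content from each source.

**Trajectories.** π and ν ramp linearly from (1, 1) at birth to the healthy
adult values (degree of nuclear ploidy 176.9%, binucleated fraction 19.3%)
over the first 10 years of life — polyploidization of the healthy human heart
completes in childhood — then hold until disease onset, then ramp linearly to
the subject's measured values at tissue procurement. The 10-year maturation
span is a config parameter. Measured values below the healthy plateau (noise
can produce them) are clamped up to preserve monotonicity.

**Phases.** The two-phase model fixes renewal before disease onset at the
healthy 0.55%/year and fits one post-onset rate. The three-phase model adds
an LVAD-implantation boundary and fits post-onset and post-implant rates
separately (whether the literature's responder rate covers the whole
post-onset interval or only the support interval is ambiguous; both modes are
implemented, and the two-phase reading defines the responder rate here). The
constant model fits a single lifelong rate.

## Numerics

The ODE is linear, so it is solved *exactly* with integrating factors,
segment by segment. Segments are split at atmospheric-curve knots,
trajectory knots and phase boundaries (G′ discontinuities never straddle a
step) and capped at 0.25 years. Within a segment K(t) = ∫k dt has the closed
form r·Δt + ln(G(t)/G(t₀)); the inhomogeneous integral is evaluated with
8-point Gauss–Legendre quadrature. On these short, smooth integrands the
quadrature error is far below 1e-8 relative; the solver reproduces the
analytic solution of a step-atmosphere scenario to ~1e-11 and agrees with an
independent discrete-time parcel simulation (`cohort_oracle`, first-order,
dt = 0.01 y) to better than 1e-3 in F units across randomized scenarios.
All rate-independent quantities are precomputed per subject, so one forward
evaluation costs ~30 µs — the requirement for 2×10⁵-draw MCMC.

Curve interpolation is linear (splines would break monotone-segment
inversion) and never extrapolates. Curve inversion returns every crossing of
the target value, each located by linear interpolation in its bracketing
segment; coincident knot hits are deduplicated at 1e-12 years. Annual
synthesis uses Simpson's rule on knot-aligned segments, exact because G is
piecewise quadratic.

## Genomic ¹⁴C age

The average genomic ¹⁴C age inverts the curve for the measured F within
[birth, collection]. One crossing → a definite synthesis date; several
(typical for pre-1963 births, which can match on both bomb-pulse limbs) →
status `ambiguous`, reported with all candidates and never silently
resolved; summaries exclude pre-1963 births by default. Quartiles use linear
interpolation between order statistics (type 7), since no convention is
stated in the source literature. Measurement error is not propagated into
age intervals — ages are the quick point-estimate view; full uncertainty
lives in the Bayesian fit.

## Bayesian inference

The likelihood is Gaussian in F: the AMS accuracy, quoted at 2σ relative
(1–3%, default 2%), is halved to 1σ and scaled by the measured F. The prior
on each free rate is log-uniform on [1e-4, 1e2] %/year — fitted rates span
at least four decades (0.01%/y to 3.1%/y), and a scale-neutral prior treats
them symmetrically. Sampling is single-chain adaptive Metropolis in log-rate
space (1–2 free parameters): proposal scale adapted in batches of 200 during
a 10 000-draw burn-in toward 30% acceptance, then frozen (so the retained
200 000 draws satisfy detailed balance). Acceptance fraction and effective
sample size (integrated autocorrelation time) are always reported; ESS < 100
flags the result as non-converged rather than raising. Identical seed,
config and data give bit-identical output.

Group fits share the free post-onset (and post-implant) rate across
subjects, each contributing its own dates and cytometry to a joint
likelihood (`group_mode="joint"`); pooling per-subject posterior draws
(`"merge"`) is available as the alternative reading of group-level results.
Sort purity enters as a data-quality gate (warning below 0.9), not as a
likelihood correction: purity correction of Δ¹⁴C happens upstream at the
DNA-fraction level.

**Identifiability.** A renewal rate r is detectable only through the F
displacement it accumulates, roughly r × duration × |F_atm − C|. At 2% (2σ)
measurement accuracy this floor sits near 0.1%/year for a single subject
with a 10–20-year disease history. Below it the likelihood is flat across
the low-rate decades and the posterior median is set by the prior's shape —
posterior medians of truly low rates (~0.03%/y) are therefore
prior-dominated, while their credibility intervals remain well calibrated.
This is a property of the measurement, not of the sampler; it is visible in
the wide credibility ranges that accompany low fitted medians.

## Synthetic cohorts

The generator emulates the *structure* of a transplant-cohort dataset:
births uniform on 1940–1995, procurement 2018–2023, disease durations
uniform on 1–20 years (onset at least 18 years after birth), LVAD support
3–43 months, per-subject ploidy and binucleation endpoints from truncated
normals anchored to published group summaries (healthy 176.9 ± 20.1% /
19.3 ± 3.0%; NICM 291.7 ± 67.5% / 34.6 ± 5.1%; ICM 221.1 ± 39.2% /
35.2 ± 5.5%; SDs converted from IQRs assuming approximate normality — an
emulation convenience, not a claim about the real cohorts; LVAD groups reuse
the NICM values since they comprise both etiologies), sort purity
0.951 ± 0.033 truncated to (0.5, 1], and 2σ accuracy uniform on 1–3%.
True rates default to the published medians (healthy 0.55, NICM 0.03, ICM
0.01, responder 3.1, nonresponder 0.02 %/year). Noise-free predictions come
from the same forward model and Gaussian noise is added at the sampled
accuracy; a ground-truth sidecar carries the latent scenario so recovery can
be verified exactly.

What the generator does **not** emulate: clinical covariates, selection
effects, real atmospheric fine structure (the bundled curve is a stylized
flat/linear-rise/exponential-decay pulse: pre-bomb −5‰, peak 970‰ at 1963.5,
e-folding 16 years, tabulated at 0.25-year steps), inter-lab AMS biases, or
any correlation between ploidy and renewal beyond the prescribed
trajectories. Passing recovery tests therefore demonstrates the estimator's
correctness under the model's own assumptions, not robustness to their
violation.

Per-subject random streams are spawned from the cohort seed keyed by
(group, subject index), so enlarging one group never changes another
subject's draws.

## Problem sizes used by the test suite

The shipped tests run reduced-but-honest workloads: oracle agreement on 50
randomized scenarios at dt = 0.01; parameter recovery with 20 subjects per
true rate at 20 000 retained draws (the full 200 000-draw budget is the
library default); noise calibration on 1000 subjects. These sizes keep the
whole suite under a few minutes on one core while leaving every assertion at
its stated tolerance.

## Known limitations

* Cell number is constant: disease-phase cardiomyocyte loss, hypertrophy and
  age-structured death are outside the model.
* The ploidy/nucleation trajectories are prescribed, not inferred; only
  their endpoints are data-driven.
* Nucleation classes stop at binucleated; ploidy classes at 16n.
* No hemispheric mixing, seasonal cycles or reservoir corrections in the
  atmospheric module; users supplying a real calibration curve must provide
  a single merged table covering every subject's lifespan.
* Very low renewal rates are prior-dominated (see Identifiability above).
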