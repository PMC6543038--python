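# Methods

This note documents the models, conventions and numerical choices behind
`scentstress`, and what the synthetic-data validation does and does not
establish.

## Behavioral quantification

Tracking traces are uniformly sampled coordinate series (default 10 Hz — a
rate sufficient to resolve freezing bouts of 1 s and longer) over a 12-min
arena session: 2 min adaptation followed by 10 min of scent exposure in a
45 cm cage with the pad at one end. Speed is the central-difference derivative
of position (one-sided at the ends). A frame is *freezing* iff it lies in a
maximal run of frames with speed below a threshold whose duration reaches a
minimum bout length. Defaults are 1.0 cm/s and 2.0 s; commercial tracking
packages do not standardize these, so both are exposed in the pipeline config
and all freezing metrics are monotone in them (tightening the threshold or
lengthening the minimum bout can only reduce freezing time).

Avoidance metrics use the distance |x − pad_position| along the cage's long
axis, with the pad modeled at the end wall. The cage is divided into 12 equal
3.75 cm zones indexed from the pad; zone freezing is expressed as percent of
the animal's total freezing time. Zone totals, per-minute freezing totals and
heat-map mass are exact partitions of the exposure duration and freezing time
respectively, and the tests assert these conservation identities.

The EPM score is open/(open + closed) arm time over a 300 s session; center
time is excluded from both numerator and denominator, and a session with no
arm time at all has an undefined score (an error, not a 0).

## Freezing-phenotype classification

Evidence for bimodality: 1-D Gaussian mixtures with k = 1..3 components are
fit by EM (scikit-learn backend) from 20 seeded initializations per k, and
compared by AIC = 2p − 2lnL with p = 3k − 1 free parameters (free weights,
means, unequal variances). Akaike weights exp(−Δ/2), normalized, summarize
the evidence split.

The unequal-variance 1-D mixture likelihood is unbounded: a component may
collapse onto a few near-duplicate observations with vanishing variance,
producing arbitrarily large spurious likelihood "spikes" that systematically
drag AIC toward too many components. The fitter therefore discards restarts
whose smallest component sd falls below 20% of the data sd or whose smallest
weight accounts for fewer than ~1.5 observations, keeping the best
non-degenerate restart (if every restart collapses, the candidate is refit
with the variance bound imposed as a covariance regularizer). For freezing
percentages (cohort sd ≈ 20–25 points) the bound corresponds to a minimum
meaningful subpopulation spread of ~4–5 points. With this constraint, on
62 draws from a well-separated 50/50 mixture (means 20 and 60, sd 10) AIC
selects k = 2 in ≈ 99/100 seeded cohorts, and k = 1 in the majority of
single-Gaussian cohorts — without it, quasi-singular k = 3 solutions win
roughly half the time, which no analyst would accept as evidence of
trimodality.

Subgrouping is deliberately simple and independent of the mixture fit: sort
by freezing, take the bottom and top round(n/3) as low-/high-freezing
(62 → 21/20/21), or halves for a median split (even n required). The middle
tertile is kept with an explicit label rather than dropped silently.

## Corticosterone

Profiles are the four samples at 0/30/60/120 min. The total response is
Σ (C_t − C_0) over the three post-exposure points (the 0-min term is
identically zero, so this equals the sum over all four); it is invariant to a
shared assay offset and linear in concentration, both asserted as property
tests. Missing samples are an error — the statistic is defined only on the
full profile. Correlations with freezing and EPM scores use Pearson r with
the t-transform p-value on the subjects present in both tables.

## ROI-level connectivity and the screens

Preprocessing operates on T×R regionally-averaged BOLD matrices with motion
(3 translations mm, 3 rotations rad) and nuisance (white matter, ventricle)
channels, in a fixed, logged order:

1. drop the first 10 volumes (steady-state magnetization);
2. framewise displacement FD_t = Σ|Δtrans| + r·Σ|Δrot| with r = 5 mm (a rat
   brain radius), FD_1 = 0; the flag sits on the arriving volume t and
   removal takes t − 1, t, t + 1; runs losing more than 20% of their
   post-trim volumes are excluded;
3. censored volumes are linearly interpolated, the series is band-pass
   filtered 0.01–0.1 Hz with a zero-phase order-3 Butterworth
   (forward–backward; measured: ≥ 99% amplitude at 0.05 Hz, ≤ 1% at DC and
   0.3 Hz), and the censored volumes are dropped again — interpolation exists
   only to keep gap edges from leaking through the filter;
4. motion and nuisance channels are filtered identically and regressed out
   by OLS with an intercept (constant channels are ignored; genuinely
   collinear designs raise, naming the redundant columns).

Connectivity is the Pearson correlation of the cleaned series over kept
volumes (≥ 30 required), Fisher-z transformed with r clipped to ±(1 − 1e−12).
The brain-wide screen correlates each edge's z across subjects with the
behavior score (Pearson on z rather than r: the variance-stabilized scale is
the appropriate one for across-subject linear statistics), converts to
two-sided p with n − 2 df, and controls FDR with Benjamini–Hochberg across
all R(R−1)/2 edges — 2211 for the 67-region parcellation. Group differences
use pooled-variance t per edge at FDR 0.01; batch adjustment refits single
edges with a mixed model (group fixed effect, random intercept per batch,
REML), which reduces exactly to the OLS group contrast when only one batch
exists; seed profiles are one-sample t tests on each region's z with the
seed, FDR-corrected across R − 1 regions.

## Synthetic cohort generator

Every generator is a pure function of (config, seed); identical inputs give
bit-identical outputs. Defaults mirror the study design: 23 controls plus 62
exposed animals, exposed phenotypes drawn 50/50 low/high.

*Tracking*: a two-state semi-Markov bout process. Freeze bouts are
2.5 s + Gamma(shape 8) with mean 6 s; mobile bout means are set from the
target freezing fraction, and both states' durations are rescaled so the
session's detectable freezing occupancy (accounting for the ~1 frame the
central-difference speed shaves off each bout edge) matches the target —
recovered freezing fractions land within ~2 percentage points of the plan.
Position follows an Ornstein–Uhlenbeck walk whose attractor is the cage
midpoint for controls and 8 cm (low) / 14 cm (high) from the far wall for
exposed animals, planting the avoidance gradient; frozen frames hold position
up to 0.1 mm jitter.

*CORT*: phenotype mean vectors (control flat at 50 ng/ml; high 150 at
30 min only; low 150/140 at 30/60, 65 at 120) plus Gaussian noise (sd
15 ng/ml), clipped at zero. The paper the paradigm follows does not publish
raw concentrations, so the baselines are conventional rat plasma values, not
claims — the orderings (low total response > high > control ≈ 0) are the
planted truth the tests check.

*EPM*: scores Normal per phenotype (low 0.20, control/high 0.35, sd 0.08),
center time ~30 s, arm times filling exactly 300 s.

*BOLD*: a latent-factor construction. Uncoupled regions share a global
factor giving a uniform baseline correlation (0.10). Each of the 15 coupled
region pairs gets its own factor whose loading is solved exactly from the
subject's target correlation tanh(μ + β·z_score + η), with μ = 0.25 (Fisher
z), slope β = ±0.085 (6 positive, 9 negative) and a per-subject trait scatter
η ~ N(0, 0.12²). The scatter term makes the across-subject edge–behavior
correlation an explicit design quantity, β/√(β² + ση² + σ_est²) ≈ 0.55,
rather than an artifact of correlation-estimation noise; coupled regions are
kept off the global factor so their score-dependent variance cannot leak weak
couplings into adjacent edges. On top sit slow sinusoidal drift (< 0.01 Hz),
high-frequency contamination (> 0.1 Hz), smoothed in-band nuisance channels
added to all regions, and motion traces with small jitter plus Poisson-placed
one-volume translation spikes of 0.3–0.5 mm — each preprocessing step has
real work to do, and a pipeline that skipped one would fail the recovery
tests.

With these defaults the BH-0.05 screen on 62-subject cohorts recovers ~90% of
planted edges at a mean false-discovery proportion ≈ 0.05 (20 seeds), and
fully null cohorts stay at or below nominal FDR (50 seeds).

What the generator does **not** emulate: hemodynamic response shape, spatial
structure or physiological (cardiac/respiratory) noise in BOLD; correlated
motion–signal artifacts; assay nonlinearity in CORT; learning or habituation
dynamics within the session. Passing tests therefore demonstrate that the
analysis code is correct and calibrated under the stated generative model,
not that the biological effect sizes are attainable in any particular real
dataset.

## Problem sizes and runtime

The validation suite runs the full study geometry where it matters (62
subjects × 67 regions × 2400 volumes for screen calibration: 20 planted and
50 null cohorts; 100 + 30 cohorts for mixture selection) and a reduced
cohort (16 subjects, 12 regions, 400 volumes) for end-to-end plumbing tests;
the full suite completes in a few minutes on one CPU.

## Known limitations

- Multiple runs per subject are averaged on the Fisher-z scale before
  subject-level analysis; the current pipeline generates one run per subject.
- The mixed-model batch adjustment is fit per edge on demand (the top
  group-difference edges in the report), not across all 2211 edges.
- The tertile split's cut values are data-dependent; with heavily tied
  freezing values the stable-sort tie-break makes group membership depend on
  input order, as documented.
- The 12-zone freezing distribution is reported from the pad-end wall; zone
  centers are at 1.875 + 3.75(k−1) cm from the pad.
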