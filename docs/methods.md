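# Methods

## The experimental model

The unit of analysis is a paired replicate of a two-arm choice bioassay: an
unloaded control arm (the load rests on metal spacers) and a loaded treatment
arm (the load rests on the wooden block), each recording clay mass deposited,
initial and leftover wood mass, and the inter-paver volume before and after
the trial.  Two study conditions are built into the package as generator
defaults: a year-long field experiment (18 colony-scale pairs, ~245 kg load,
13 pairs with contact to both arms) and a 30-day laboratory experiment
(32 group-scale pairs, single-paver load, 21 included).  Replicate inclusion
is an explicit observational flag (contact to both arms), never inferred from
the measurements.  Masses are held in grams internally; a `mass_unit="kg"`
switch on the CSV reader converts field-scale records on entry.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the published summary values; it is the package's test bed, not a behavioural
simulation.

**Margins.**  Masses and volumes are zero-truncated normals.  Because
truncation shifts moments, each margin's underlying (μ, σ) is solved
numerically so that the *truncated* distribution's mean and SD equal the
published summary values exactly (`truncnorm_params`).  A zero-truncated
normal cannot have a coefficient of variation ≥ 1 (the exponential limit),
so margins such as the field loaded-arm leftover wood (39.22 ± 62.19 g) fall
back to the naive parameterization; `truncated_moments` reports the moments
actually realized, and the tests check convergence against those, not against
the unreachable targets.  Leftover wood is additionally truncated above at
the replicate's own initial wood mass; the resulting small downward shift of
its mean is physical and is verified in the tests against a quadrature
oracle that integrates over the initial-wood distribution.

**Coupling.**  In the loaded arm, clay mass and leftover wood are joined by a
Gaussian copula targeting a Spearman rank correlation `coupling_rho`
(default −0.8; the studies report an inverse relation but no coefficient, so
a moderately strong value was fixed once as the study condition).  The
Spearman target is converted to the copula's Pearson parameter via
ρ_P = 2 sin(πρ_S/6), so the rank correlation survives the monotone marginal
transforms.  The unloaded arm is drawn independently.  A within-pair
correlation of the two arms' leftovers is exposed (`arm_consumption_rho`)
and defaults to 0, as no value is published.

**Volumes.**  The unloaded inter-paver volume is fixed by the spacers
(final = initial).  The loaded volume shrinks linearly in the fraction of
wood consumed, `final = initial · (1 − s · consumed)`, with the slope `s`
calibrated per scale so the published mean initial and final volumes are
reproduced at the published mean consumption (field 12,840 → 6,903 cm³;
lab 207.21 → 34.15 cm³), clipped to keep the volume positive.  One initial
volume mean/SD pair is used for both arms (the loaded-arm published values;
the unloaded ones differ by ≲2%).

**Activity onsets.**  The three period onsets are drawn on the published
integer ranges (1–3, 2–8, 10–22 days) from maximum-entropy (exponentially
tilted) discrete distributions whose means equal the published 1.3, 3.6 and
19.6 days *exactly*.  A discrete uniform on the ranges was rejected because
its means (2, 5, 16) contradict the published averages.  The ordering
t₁ < t₂ is enforced by resampling the first two onsets jointly; the third
onset's range lies above the second's, so its marginal — the one the
acceptance check estimates — is untouched by the rejection.  The exact
conditional means of the ordered (t₁, t₂) pair (1.1904, 3.7610, from
enumerating the joint pmf) are the test oracles for the first two onsets.

**What the generator does not emulate:** within-colony heterogeneity,
temporal correlation of measurement error, partial-contact replicates, and
any dependence of clay deposition on colony size.  Passing tests demonstrate
that the pipeline recovers the parameters and structure it assumes, not that
real termite data satisfy those assumptions.

## Classical battery

ANOVA is the standard balanced one-way sum-of-squares decomposition with an
upper-tail F p-value (implemented directly so the degenerate zero
within-group-variance case is an explicit flagged result; cross-checked in
tests against `scipy.stats.f_oneway` and the squared-t identity).  The
two-sample Kolmogorov-Smirnov test delegates to `scipy.stats.ks_2samp`
(asymptotic p).  Lilliefors normality uses the KS distance to a normal with
estimated mean/SD and a seeded Monte-Carlo null (standard-normal samples of
the same size, add-one p-value convention), since the composite null
invalidates the standard KS table; the table-based `statsmodels`
implementation serves as an independent cross-check in the tests.

Beta marginals are fitted by closed-form method of moments on data rescaled
to (0, 1) (percent values clamped to [0.01, 99.99] because the beta support
is open; optional MLE refinement).  Leftover wood is expressed as percent of
initial wood; clay per residual volume as percent of the across-arm maximum
(a scale-invariant normalization; the published analysis normalizes "to
percentage values" without stating the reference).  The predictive joint
model draws n paired samples (default 10,000) from the fitted betas joined
by a Gaussian copula whose rank correlation is estimated from the data
(`independent` available); "statistical smoothing" is the parametric fit
itself.  Kurtosis is reported per margin (standardized fourth moment, excess)
and jointly as Mardia's multivariate kurtosis minus the Gaussian value
d(d+2) = 8; the loaded-minus-unloaded sign decides the platykurtic call.
No multiple-testing correction is applied anywhere, matching the original
analysis.

## Bayesian substitution model

Success criterion: clay mass strictly above the mean over the *included
loaded arms of the same experiment*, and leftover wood strictly below 50% of
initial.  Ties count as failures (conservative, deterministic).  Note that
with the threshold at the sample's own mean, a sample can never be all
successes — at most roughly half of draws from a right-skewed distribution
exceed their own mean — so posterior medians from this criterion are
intrinsically moderate; the tests therefore check the *contrast* between a
strong-substitution regime and a null regime rather than an absolute level.

Both prior readings are implemented and always named in the output:
`jeffreys` = Beta(½, ½) (default) and `uniform` = Beta(1, 1).  Updating is
conjugate and sequential with full history, so trajectory plots of the
updating process are reproducible; exchangeability (order invariance) and
batch equivalence are property-tested.

**HDR intervals.**  For an interior-mode beta (a, b > 1) the lower endpoint
of [l, F⁻¹(F(l) + mass)] is optimized (bounded scalar minimization,
xatol 10⁻¹²); the contained mass is exact by construction and checked to
10⁻⁶.  Monotone densities anchor the interval at a boundary: [0, q_mass]
for a ≤ 1 ≤ b and [q_{1−mass}, 1] for b ≤ 1 ≤ a; Beta(1, 1) returns the
centred interval.  A U-shaped posterior (a, b < 1) has no single
highest-density interval, so the equal-tailed interval is returned with a
warning and flagged via the `method` field.  A grid-search oracle at 10⁻⁴
quantile resolution verifies narrowest-width optimality in the tests, and a
500-simulation study checks ≥ 97% coverage of a known success probability by
the nominal 99% interval.

## Energetics and mechanics

Lifting work is `m_clay (1 + w) g d̄` with water ratio w = 1 by default and
d̄ the mass-fraction-weighted mineral source depth (kaolinite 47% @ 22.8 cm,
boehmite 23% @ 31.5 cm, gibbsite 10% @ 11.0 cm).  The fractions sum to 0.80;
the default uses them unnormalized (d̄ = 0.1906 m; unidentified wall mass is
treated as locally available), with `normalize=True` (d̄ = 0.2383 m) as a
switch — the published cost estimate sits between the two conventions and
cannot be reproduced exactly under either, so every assumption is an explicit
parameter.  Wood energy is `m_wood · GE · (1 − lignin)` with GE = 20 kJ g⁻¹
(a standard softwood gross calorific value; the source cites species-average
values without printing one) and lignin = 0.29.  The published wood-energy
figure matches kilojoules although labelled joules; the module computes
joules and kilojoules explicitly and records the ratio convention in the
budget's metadata rather than silently adopting the inconsistency.
g = 9.80665 m s⁻².

Wall capacity is σ·A with MPa·cm² → N conversion; the deliverable is the
comparison against the imposed load, not the trailing digits.  The rigidity
ratio compares second moments of area at equal mass (equal cross-section),
(r_o² + r_i²)/(r_o² − r_i²), with an equal-outer-radius variant behind a
flag.

## Activity segmentation

The three verbal period definitions are reduced to per-replicate
first-passage events on the daily two-level contact scale: period 1 starts at
the first day with any full contact; period 2 at the first day with unloaded
full contact and loaded none; period 3 at the first day at or after the
period-2 onset with loaded full contact or observed building.  Replicates
missing a transition are flagged, not averaged.  Resolution is daily —
observations were daily — with interpolation only for plotting.  Kernel
activity curves use a Gaussian KDE over contact-day mass (per-day full
contact frequencies as weights), Silverman bandwidth by default, evaluated
on a grid extended four bandwidths past the data so the density integrates
to 1 within 10⁻³; a single-day mass degenerates to an explicit Gaussian
kernel of bandwidth 1 day.

## Pipeline and problem sizes

`run_pipeline` chains the stages with per-stage seeds derived from the master
seed by fixed offsets (stage index), making isolated stage re-runs
reproducible and full bundles byte-identical under identical seed + config
(stage wall-times are excluded from the persisted JSON).  Default problem
sizes: 10,000 bootstrap draws per joint model, 2,000 synthetic timelines for
the onset-recovery summary, 500 simulations for the coverage study — all
chosen as comfortably converged for the statistics involved while keeping a
full run in seconds.

## Known limitations

- The success count, and hence the posterior median, depends on the
  within-sample mean-clay threshold; with small n it is sensitive to single
  extreme clay values.
- The Gaussian copula is one of many couplings consistent with fixed beta
  marginals; only its rank correlation is identified by the data.
- The energetics model prices gravitational lifting only — no metabolic
  locomotion or excavation costs — so its ROI is an upper bound.
- Moment-matched truncated normals cannot represent margins with CV ≥ 1;
  those margins are sampled with truncation-shifted moments (documented
  above).
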