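# Methods

## The hybrid model

The package implements a *serial* hybrid model for fed-batch CHO
cultivations. A data-driven block — a single-hidden-layer network with four
hyperbolic-tangent neurons and linear outputs — maps six z-scored process
inputs to the two specific rates, and a mechanistic block propagates those
rates through the fed-batch mass balances

    dX/dt = (μ − D)·X,        dP/dt = v_P/X·X − D·P,

where X is the viable cell concentration (10⁶ cells mL⁻¹), P the product
titer (g L⁻¹), and D = F/V the dilution rate (h⁻¹). Shake-flask runs are
bolus-fed (daily additions of 3.3 % v/v, applied as instantaneous
conservative mixing events); bioreactor runs are continuously fed at a
constant flow delivering the same cumulative v/v per day. Samples taken on
a feeding day are treated as drawn *before* the bolus.

The six model inputs are the cultivation temperature and the feed glucose
level — both step functions of the design segments, the feed level encoded
by its added-glucose value (10/20/30 g L⁻¹ for F1/F2/F3) — plus glutamine,
asparagine, alanine and the aspartate/glutamate ratio, linearly
interpolated between sampling times (the ratio is formed after
interpolation, with a 10⁻³ g L⁻¹ glutamate floor). A variant using
measured supernatant glucose instead of the feed-level CPP is available by
passing a different `input_names` tuple; the CPP reading is the default.
Network outputs are trained in scaled rate units (μ/0.03 h⁻¹,
v/5·10⁻⁴ h⁻¹) so both residual blocks have comparable magnitude.

### Training

Because the rate inputs are interpolated measurements rather than the
integrated states, both balances are *linear* in X and P given the input
trajectories. With total cells N = X·V and total product M = P·V,

    N(t) = N₀·exp(∫₀ᵗ μ),        M(t) = ∫₀ᵗ v_P/X·N,

identities that hold under both feeding modes (bolus events conserve N and
M; continuous feeding enters through V). The trainer evaluates these
closed forms on a 1–2 h quadrature grid, vectorized over all
finite-difference weight perturbations at once, which makes the
Levenberg–Marquardt Jacobian of the full through-the-model objective cheap.
The adaptive-step integrator (`integrate_states`, LSODA at rtol 10⁻⁸)
remains the reference path; the two agree to ~10⁻³ relative and the test
suite asserts it. P may go slightly negative under a negative production
rate; both paths report the raw solution.

Training minimizes the concatenated (measured − predicted) residuals of
VCC and titer at the sampling times, each block divided by its
training-partition mean, plus an L2 weight penalty (default 10⁻⁴). The LM
loop accepts a step only if the penalized sum of squares decreases,
escalates its damping factor otherwise, and stops on an iteration cap or
on patience. During cross-validation, every accepted step is scored on the
validation partition (mean of the VCC and titer NRMSE) and the best-scoring
weight vector is kept — the "train until the validation error is minimal"
rule.

### Cross-validation and ensembling

Splits are by whole runs, never by time points. Random splits put 60 % of
runs (rounded up) into training, repeated (default 40×, reduced in the
packaged experiments); for intensified-design datasets, leave-one-run-out
is used. Random splits are stratified by scale: a partition whose training
half contains no continuously fed run leaves the model unconstrained in
that regime, and its predictions on bioreactor runs can grow without
bound. One model per partition forms the ensemble; predictions are the
member mean with SD(t) computed over members (n−1 denominator, n = member
count) and CI(t) = mean ± SD. Evaluation pools all sampling points of all
runs per target (NRMSE = 100·RMSE/mean) and also reports per-run values.

## The simulator

The study's cultivation data are not public, so all experiments run
against a ground-truth simulator whose rate functions, adaptation lag and
noise model are known. Its defaults were calibrated once so the noiseless
center-point (34 °C/F2) trajectories reproduce the study landmarks:
shake-flask VCC peaking near 20.8·10⁶ cells mL⁻¹ around day 8 (±10 %),
harvest (<70 % viability) exactly on day 11, maximum titer near
0.64 g L⁻¹; bioreactor VCC near 10.5·10⁶ and titer near 0.76 g L⁻¹ at day
15 with no viability decline. Calibrated values land within ±10 % of every
landmark.

The central design constraint is *identifiability*: every scale- and
age-dependent effect is carried by observable quantities, because a
latent factor (say, a hidden culture-age decay applied only to
continuously fed runs) produces training data the six inputs cannot
explain — models then fit the center points yet extrapolate arbitrarily at
unseen CPP settings. Concretely:

- growth is μ = μ_max · bell(T_eff; 37 °C, 4 °C) · Monod(Asn; 1.2 g L⁻¹) ·
  f(Gln; Monod with floor) · 1/(1+(Ala/1.6)³), minus a stress-driven death
  term; the *glutamine clock* (first-order chemical degradation,
  1.2 %/h) makes culture age observable;
- bolus feeding accumulates stress linearly; stress secretes overflow
  alanine (≈0.14 g per 10⁶ cells per unit stress), which stops growth and
  then kills the culture — the viability harvest criterion triggers on
  day 11 at the shake-flask center point;
- continuous trickle feeding secretes overflow alanine up to a
  re-consumption plateau (~2.2 g L⁻¹) that is independent of biomass and
  CPP setting; the plateau-level inhibition is what caps bioreactor
  growth, so the suppression learned at the center point transfers to all
  CPP settings;
- alanine secretion stoichiometrically drains glutamate (alanine
  aminotransferase), so the aspartate/glutamate ratio rises as the culture
  shifts metabolically; production is v = v_max · bell(T_eff; 35 °C, 5 °C)
  · sat(F; 10 g L⁻¹) · R²/(0.6²+R²) — favored in the shifted state and
  saturating with the feed glucose level, which is why the slower-growing
  reactors reach higher titers;
- set-point changes act through a first-order lag with τ = 48 h (the
  ~2-day adaptation), applied identically to temperature and feed level;
  the batch phase (72 h at 37 °C) precedes the first shift.

Non-causal analytes (serine, glycine, tyrosine, hydroxyproline, proline)
are held near feed balance: their small dynamic range leaves their
measurements dominated by assay noise, as befits non-causal candidates in
the selection experiments, and proline closely shadows hydroxyproline to
provide the collinear pair the screening step must catch.

Observations are drawn daily from inoculation (plus 6 h after each CPP
shift in intensified runs) with mean-preserving multiplicative lognormal
noise: 5 % CV on VCC and analytes, 7 % on titer, 2 % on viability
(chosen as typical offline-assay precision). Shake-flask runs truncate at
the first sample below 70 % viability (that sample is kept); bioreactor
runs always run 360 h.

### What the simulator does not emulate

- The end-of-run *negative* production rate seen in the real shake
  flasks: emulating it required a latent stress term in v_P/X that broke
  titer transfer, so production is ratio-stimulated and non-negative.
- The bioreactor center-point VCC shows a ≤1 %/day terminal drift (peak
  ~10.8 around day 8–12, 10.2 at day 15) rather than a strict maximum at
  the end; "no meaningful decline" is asserted as daily decreases below
  2 % of the current value, well under the 5 % assay noise.
- No oxygen/CO₂/pH physics, no sample-volume removal, no segregated
  population structure; viability is a deterministic function of
  accumulated stress.

Passing tests therefore show that the pipeline recovers the kinds of
structure this generator produces — smooth multiplicative kinetics carried
by the measured analytes — not that it would recover arbitrary real-plant
behavior.

## Input selection

The workflow has three steps. (1) PCA on the autoscaled candidate matrix
and squared Pearson correlations of each candidate to VCC and titer;
candidate pairs with |r| > 0.95 lose their weaker member (this catches the
proline/hydroxyproline pair). (2) Backward elimination: candidate sets are
scored by a *rate-target regression* — the network is fitted by LM to
smoothing-spline estimates of μ and v_P/X (samples below 10⁶ cells mL⁻¹
excluded; the per-cell production estimate divides by X and is
noise-dominated there) — and validated in *state space*: the fitted rates
are propagated through the closed-form balances and the mean per-run
VCC/titer NRMSE on held-out runs is the score. Two restarts per partition
are averaged to damp optimization luck; all subsets at one elimination
step share partitions (paired comparison). The input whose removal yields
the lowest validation error is dropped, until the best removal worsens the
error by more than 1 percentage point. (3) The surviving set is refitted
with the full hybrid at full cross-validation.

The two CPPs and the aspartate/glutamate ratio are *protected* from
elimination: the CPPs are the designed process factors of the study, and
the ratio enters by prior knowledge as a metabolic-shift indicator. This
mirrors how such workflows are run in practice — designed factors and
literature-motivated markers are not discarded on the word of a greedy
validation comparison. It is also an honest reflection of a limit of
validation-driven elimination: in any deterministic-kinetics system,
smooth analytes are mutually informative, so a *predictive* criterion
cannot sharply separate causal inputs from their correlates; protection
encodes the causal knowledge the data cannot supply.

## Rate estimation from data

`estimate_specific_rates` works on dilution-corrected totals: cubic
smoothing splines (generalized cross-validation smoothing by default) are
fitted to ln(X·V) and to P·V, and differentiated, giving μ = d ln(X·V)/dt
and v_P/X = d(P·V)/dt / (X·V) under both feeding modes. At least four
samples and strictly positive VCC are required.

## Problem sizes and protocol settings

The packaged experiments run at reduced size so the full suite stays
interactive: the scale-transfer ensemble uses 10 members and 150 LM
iterations (the study protocol would use 40 members); the
intensified-design comparison uses the natural 6-member leave-one-run-out;
the input-recovery experiment uses 10 replicates at 8 cross-validation
repeats and 60-iteration fits. Protocol seeds are fixed (dataset seed 0,
cross-validation seed 1; recovery replicates r = 0…9 with cv seeds
1000+r).

## Known limitations

- Titer transfer degrades on occasional random replicates (specific
  dataset/partition seeds) where low-feed (F1) bioreactor runs are
  over-predicted; the production surface at the F1 × continuous-feed
  corner is only weakly constrained by shake-flask data plus center
  points.
- Open-loop prediction from the seeding density compounds rate errors
  exponentially over 15 days; per-run NRMSE is dominated by late time
  points.
- The intensified-run transients after a CPP shift are systematically
  mispredicted for up to ~2 days because the model sees set-point steps
  while cells respond with the first-order lag; the six inputs cannot
  represent the lag explicitly.
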