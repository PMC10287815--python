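# Methods

`pelvimech` re-implements, as a tested pipeline, the quantitative analysis
of a four-arm rat simulated-childbirth-injury experiment: planar biaxial
vaginal-wall biomechanics, urethral/pudendal electrophysiology, and the
group-level statistics. Because no raw data from such experiments are
publicly deposited, the package ships a synthetic-cohort generator with
fully known ground truth; every analysis step is validated by parameter
recovery against that truth. This note documents the models, the defaults
and why they were chosen, the numerical decisions, and what passing tests
do and do not demonstrate.

## Tissue model and biaxial simulation

Each specimen's loading response per axis a ∈ {x (longitudinal),
y (transverse)} is the exponential strain-stiffening law

    σ_a(ε) = A_a (e^{B_a ε} − 1),        dσ_a/dε = A_a B_a e^{B_a ε},

with ε engineering strain as a fraction and σ nominal stress in MPa. This
is the simplest law with a toe region, a quasi-linear terminal region, and
a closed-form tangent, which makes it a convenient oracle. Defaults
A = 0.04 MPa, B = 10 put the terminal tangent modulus at 21.6 % strain at
≈3.5 MPa and the peak force on a 10 mm × 1.5 mm cross-section at ≈4.6 N —
inside the range of a 5 N load cell.

The strain command is an exact triangle wave: 10 cycles at each of 4.6, 10,
15.7 and 21.6 % strain, 100 %strain/min, sampled at 30 Hz. Preconditioning
multiplies cycle c's stress by `1 − precond_drop · precond_rate^(c−1)`
(defaults 0.15, 0.6), which makes cycles 8–10 agree to 0.27 % — consistent
with steady state being reached within ten cycles. Hysteresis scales the
unloading limb by `eta` (default 0.8) relative to loading, with both limbs
passing through zero stress at zero strain; this keeps the unloading branch
below loading (dissipative) at the cost of a stress discontinuity exactly
at load reversal (see "turnaround artifact" below). The 0.1 N preload is
treated as the tared reference state, so simulated forces are
preload-referenced. Additive Gaussian force noise defaults to 0.01 N
(≈0.2 % of full scale, a typical load-cell accuracy).

## Biomechanics analysis

- **Stress/strain**: nominal stress, force over the *initial* cross-section
  (thickness × 10 mm loaded width by default; the effective width is
  configurable because rake-span conventions differ between labs).
- **Cycle segmentation**: troughs of the strain signal (prominence half the
  smallest protocol level) delimit cycles; each splits at its strain
  maximum into loading/unloading and is assigned to the nearest protocol
  level, ties to the lower level. A level with fewer than three detected
  cycles raises an error naming the level.
- **Steady cycles**: the last 3 of 10 cycles per level.
- **Mean slope**: the average of first-order least-squares slopes of the
  loading and the unloading limb; per-cycle values are averaged over the
  three steady cycles. Averaging per-cycle *metrics* (rather than averaging
  curves point-wise before fitting) is robust to sample misalignment across
  cycles; a "pooled" fit through the concatenated points is available as
  the alternative order.
- **Tangent modulus**: least-squares slope of the loading limb restricted
  to the last 1 % strain below the cycle's peak, averaged over the steady
  cycles. Fewer than two samples in the window is an error (it indicates an
  insufficient sample rate), as is a window wider than the limb.
- **Anisotropy index**: AI = longitudinal / transverse tangent modulus per
  specimen and strain level.

**What the window slope estimates.** The continuous least-squares slope of
A(e^{Bε} − 1) over [ε_p − w, ε_p] equals

    A e^{B m} · 3(Bh cosh Bh − sinh Bh)/(B² h³),   m = ε_p − w/2,  h = w/2,

i.e. for Bh ≪ 1 it is the true tangent at the *window midpoint*, not at the
window edge. Relative to the tangent at ε_p the estimator therefore carries
an irreducible ≈e^{−Bw/2} factor (≈5 % at B = 10, w = 1 % strain). Oracle
tests compare against the midpoint form; recovery bounds against the
edge-tangent truth budget for the bias.

**Turnaround artifact.** Because the hysteresis model drops stress
discontinuously at load reversal, the strain-maximum sample of a cycle can
be the first post-reversal (unloading-branch) point whenever the triangle
peak falls between samples; including it biases the narrow window fit by up
to tens of percent. The analyzer trims the final loading sample when its
stress breaks monotonicity — the usual turnaround-artifact exclusion in
cyclic-test analysis. With this rule, noise-free 30 Hz estimates agree with
the closed form to ≤0.5 %.

## Electrophysiology model and analysis

Spike trains are Poisson processes with a 1 ms absolute refractory period,
implemented as a renewal process (inter-spike interval = 1 ms + Exp(λ)).
The realised mean rate is therefore λ/(1 + λτ), not λ; all recovery tests
use this dead-time-corrected rate as truth (38.46 Hz for nominal 40 Hz).
Spikes are 2 ms biphasic (single sine cycle) templates with peak-to-peak
amplitude ~ Normal(120, 20) μV on Gaussian noise of 5 μV, at a 10 kHz
sampling rate. EUS EMG defaults: 10 Hz baseline, 45 Hz at peak pressure;
pudendal ENG uses the same rates for rest/brushing. A leak-point-pressure
trial holds at 8 cm H₂O, ramps to 42 cm H₂O (the leak marker is placed at
the peak, which falls exactly on a sample), and releases; pressure noise is
tied to the shared noise scale (0.05 cm H₂O per μV of `noise_sd`) so a
noise-free configuration is exactly noise-free everywhere.

Analysis:

- **LPP** = max pressure near the leak marker − mean pressure over the
  baseline window (invariant to constant offsets).
- **Spike detection**: threshold at noise center + 4.5 × spread on the
  band-limited voltage, upward crossings, 1 ms refractory. The noise spread
  is estimated on a quiet reference window via the MAD (robust to the
  baseline spikes that inevitably contaminate it); a plain SD estimator and
  other thresholds are configurable. 4.5 SD was chosen from the Rice
  up-crossing rate ν₀e^{−θ²/2σ²}: at 3 SD, band-limited Gaussian noise
  alone crosses ≈15–20 times/s — which would swamp 10–45 Hz firing rates —
  while 4.5 SD predicts ≈0.03/s. Amplitude per spike is the peak-to-peak
  within −1/+2 ms of the crossing (the crossing sits at wave onset, so a
  symmetric ±1 ms window would clip the negative lobe).
- **Segment metrics**: rate = count/duration over the annotated 1-s
  windows; amplitude = mean peak-to-peak (0 if no spikes). Outcomes are
  stimulated-minus-baseline differences, averaged over an animal's trials
  (3–6 LPP trials, 5–10 ENG trials); a metric with no trials is missing
  (NaN), never zero.

## Cohort structure

Four groups — sham+VEH, PNC+VD+VEH, PNC+VD+MSC, PNC+VD+RGTA — with default
sizes 12/7/9/7 (the biomechanics-arm sizes). Group effects are
multiplicative factors on (A_x, A_y, rate_stim, p_leak):

| group        | A_x | A_y | rate_stim | p_leak excess |
|--------------|-----|-----|-----------|----------------|
| sham+VEH     | 1.0 | 1.0 | 1.0       | 1.0            |
| PNC+VD+VEH   | 0.7 | 0.7 | 0.6       | 0.75           |
| PNC+VD+MSC   | 1.0 | 1.0 | 0.6       | 0.75           |
| PNC+VD+RGTA  | 1.0 | 0.7 | 0.6       | 0.75           |

These encode the qualitative pattern of the experiment — injury lowers
stiffness ~30 % on both axes (the same 30 % the power analysis assumes) and
degrades urethral/pudendal function; MSC restores stiffness but not
function; RGTA restores longitudinal stiffness only, so its true AI is
1/0.7 ≈ 1.43 — they are modelling choices, not measured values, since the
source experiment reports only bar charts. Between-animal variability is a
unit-mean log-normal factor per parameter family (CV 0.10 by default): one
common stiffness scale shared by both axes (so within-group AI truth is
exact), one for the stimulated rate, one for the leak-pressure excess over
baseline. Everything is reproducible from a single integer seed via spawned
seed sequences.

## Statistics

- Summaries as mean ± SEM (sd/√n, ddof = 1); n counts non-missing values.
- **Kruskal–Wallis** (scipy, tie-corrected) with **Dunn's post hoc test**
  implemented here: z = (R̄_i − R̄_j)/√[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i +
  1/n_j)], two-sided normal p, Bonferroni-adjusted by default (Holm or none
  configurable). All-identical data degenerate to H = 0, p = 1. Verified
  against the exact two-group identity z² = H.
- **Two-way mixed ANOVA** (between group × within strain level) via
  pingouin; its between-group F is exactly the one-way ANOVA on subject
  means. Animals missing a level are excluded with a logged warning.
  Pairwise group contrasts are two-sample t-tests within each level,
  Bonferroni-adjusted over the full pair × level family. No sphericity
  correction is applied to the within terms by default.
- **Mixed model for AI**: AI ~ group × level with a per-specimen random
  intercept (statsmodels MixedLM, REML). Contrasts are Wald z-tests on
  fixed-effect linear combinations with large-sample normal inference —
  MixedLM does not expose Satterthwaite degrees of freedom; at the package's
  cohort sizes this is mildly anticonservative per raw contrast, which the
  Bonferroni family correction absorbs (verified by a null familywise-error
  simulation). A singular fit (random-intercept variance ≈ 0) falls back to
  OLS with a warning.
- **Sample size**: smallest per-group n for a two-sided two-sample t-test
  (statsmodels noncentral-t power). The assumed coefficient of variation
  (`relative_sd`) is a required argument. With a 30 % difference, α = 0.05,
  power 0.9 and relative_sd = 0.15 (d = 2.0) the result is n = 7.

## Problem sizes used in validation

Null calibration runs on outcome-level null tables (4 groups × 8, shared
distribution; for the ANOVA a random intercept of SD 1 plus residual SD
0.5) — 1000 replicates for Kruskal–Wallis, 800 for the mixed ANOVA —
because the statistical layer's calibration is a property of the tests, not
of trace simulation. Pattern reproduction runs 100 full trace-level cohort
replicates (12/7/9/7 animals each) through simulation, per-specimen
analysis and group aggregation. Ephys recovery uses 200 one-second windows.

## Known limitations

- The generator emulates the *statistical structure* the pipeline assumes
  (nonlinear anisotropic elasticity, preconditioning, Poisson-like firing,
  pressure ramps), not tissue biology: no viscoelastic rate dependence, no
  permanent set, no bursting or motor-unit structure, no anesthesia
  effects. Passing recovery tests shows the estimators are correct for data
  of this structure, not that real tissue satisfies the model.
- All noise magnitudes and group-effect sizes are configurable stand-ins;
  the source experiment publishes no variance components.
- The tangent-modulus estimator is a windowed secant; its ≈e^{−Bw/2} offset
  from the edge tangent is inherent to the definition, cancels in AI, and
  must be kept in mind when comparing absolute moduli across window widths.
- The mixed model uses a random intercept only; random slopes over strain
  level are not fitted.
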