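# Methods

`reachstop` implements the measurement-and-analysis chain of a VR
reach-trajectory stop-signal experiment on chocolate cue reactivity —
trajectory kinematics, gaze dwell, indirect SSRT, implicit-association
D-scores, group statistics, and penalized intake prediction — together with
a synthetic cohort generator whose ground truth makes every stage testable
by parameter recovery.

## Synthetic cohort

### Reach model

Hand depth follows a minimum-jerk point-to-point profile,

    x1(t) = D (10 τ³ − 15 τ⁴ + 6 τ⁵),   τ = (t − IT) / T,

with object depth D (default 0.5705 m: the cohorts this emulates showed a
mean approach of 54.6 cm terminating ~2.45 cm before the object), initiation
time IT (per-trial draw around a participant latent, ~N(300, 40) ms across
participants) and reach duration T set per participant and category from the
latent peak velocity via PV = 1.875·D/T. The closed forms

    PV = 1.875 · D / T          (at τ = 0.5)
    PA = (10/√3) · D / T²       (at τ = (3 − √3)/6)

serve as independent oracles for the extraction stage. Because the profile
pins peak acceleration to peak velocity and duration, PA is not a free
parameter: the configured chocolate-minus-neutral PV shift (−0.02 m/s,
applied by rescaling T) induces the PA category effect rather than an
independent `pa` shift. Small lateral (2 cm sine arc) and vertical (5 cm
rise; the start sits slightly below the target) components ride on the
depth progress, and isotropic Gaussian position noise (default SD 1 mm)
emulates tracker jitter. After the movement ends — object contact on go
trials, halt on successful stops — the hand retracts at 0.15 m/s (capped at
4 cm), which keeps the depth maximum sharp instead of leaving a noise-level
plateau; without it the segmentation argmax would wander over the
post-movement samples.

### Stop trials

The stop signal is scheduled at IT + SSD (the delay counts from detected
movement onset, as in dynamic-starting-line designs). The participant's
stopping latency L is drawn per trial (~N(latent, 40) ms; chocolate latents
average 247 ms, neutral 260 ms). From stop-signal onset the depth velocity
decays linearly to zero over L, so the braked hand advances v_s·L/2 beyond
the onset position; a stop *succeeds* iff it halts outside the 2 cm
collision radius around the object. Ground truth for a successful stop is
therefore exact: TTS = L, BD = v_s·L/2, maxZ = x1(onset) + BD. Failed stops
complete the reach.

One SSD staircase per participant spans both stimulus categories (the delay
adapts to the participant's stopping ability, not to the stimulus; a
per-category staircase would let the TTS category effect drag the two SSD
equilibria apart and confound every stop-trial kinematic contrast). The
staircase starts at 200 ms and steps asymmetrically: +25 ms after a
successful stop, −75 ms after a failed one, clamped to [50, 450] ms. Its
equilibrium success rate is step_down/(step_up+step_down) = 75%, matching
the 70–76% cohort-level stop success such immersive tasks produce — higher
than the ~50% a symmetric tracker yields, because participants get
objectively easier stop geometry than a web key-press task. The web-based
stop-signal generator keeps the conventional symmetric ±50 ms staircase
tracking 50%.

### Category effects and their heterogeneity

Configured effects (chocolate minus neutral): PV −0.02 m/s, TTS −13 ms,
first dwell +107 ms, total dwell +216 ms. Chocolate latents are the primary
draws (they enter the intake model); the neutral value subtracts a
*per-participant* effect drawn around the configured mean with SD 35 ms
(TTS), 75 ms (first dwell) and 120 ms (total dwell). A constant shift for
everyone would make paired contrasts implausibly clean (t ≈ 70 for dwell);
the chosen spreads put group-level t and ηp² values in the range such
studies report. The PV effect needs no explicit spread — staircase wander
and trial sampling already give its contrast realistic noise.

### Gaze

Gaze is generated directly as per-sample AOI-collision booleans (no saccade
physiology): a first fixation bout from stimulus onset whose duration is
the participant's dwell latent plus noise, a 3-sample detachment, then a
second bout carrying the remaining total dwell (stop trials add 120 ms,
since the trial continues past the halt). The realized frame counts are
stored as ground truth, so dwell extraction can be checked exactly.

### Web tasks and intake

The web stop-signal session races independent normal go (per-participant
mean ~N(693, 154) ms, trial SD 120 ms) and stop (latent SSRT ~N(326, 68) ms,
trial SD 50 ms) finishing times; 2% go omissions. The SC-IAT session draws
RTs around block means separated by d_true·σ_within (σ = 150 ms), 7%
errors. Note the improved D-algorithm's error penalty inflates the pooled
SD, so the extracted D is attenuated (~0.7×) relative to the latent — a
property of the scoring convention, not a defect.

Intake (kcal) comes from a sparse linear model over the 16 standardized
true features: intercept 529, weights +60 (trait craving), −60 (chocolate
SSRT) and +45 (total dwell) kcal per population SD, Gaussian noise
SD 192 kcal, floored at 0. The noise is calibrated so the linear signal
explains ≈20% of intake variance (realized R² = 0.198 at large n), the
regime in which feature selection is hard but feasible at n = 72.
Standardization inside the generator uses fixed population norms, not
sample statistics, so intake is a deterministic function of a participant's
features given the seed.

## Extraction

Trials are centred to the first sample and segmented from stimulus onset to
the *earliest* attainment of maximal depth displacement. Positions are
smoothed with a 5-sample centred moving average (shrinking at the edges),
speed is the magnitude of the central-difference velocity vector (a
depth-only switch exists), smoothed again before peak-picking; acceleration
is the derivative of the smoothed speed, matching a "change in speed"
reading rather than the acceleration-vector magnitude. At 120 Hz this chain
biases the minimum-jerk PV by ≈−0.3% and PA by ≈−0.5% (well inside the 1% /
2% oracle tolerances) and keeps the PV bias under 1 mm-noise below 2%.
Initiation is the interpolated time the 3D displacement first exceeds 1 cm
(the real task's dynamic-starting-line threshold is unknown; 1 cm is a
configurable default, not a claim about the original). Kinematic parameters
of *failed* stop trials are masked before aggregation — stopping latency,
braking distance and displacement are defined on successful stops — while
stop accuracy, SSD and IT remain. Cell means apply a single-pass 2.5 SD
outlier filter per variable (sample SD, n−1; zero-SD cells remove nothing),
and cells with fewer than 5 usable trials are flagged. Time-standardized
trajectories (101 linear-interpolation steps) are produced for averaging
and plotting only; peaks always come from the unstandardized series.

No SSRT is estimated from the VR data: with ~75% stop success the stopping
probability sits outside the band the integration method needs, so the VR
task contributes direct measures only.

## Scoring

**SSRT (web task):** integration method with omission replacement. Go
omissions are replaced by the maximum observed go RT, go RTs sorted, and
SSRT = RT(n) − mean SSD with n = clamp(ceil(p_respond·N_go), 1, N_go).
Results are withheld (flagged) when p_respond ∉ [0.25, 0.75] or mean
signal-respond RT exceeds mean go RT. Scored per category; go trials with
choice errors are retained by default. On a single 400-trial race the
estimator is unbiased to ~1 ms; note that scoring a 400-trial session
*split* over two categories leaves a ≈+10–15 ms transient bias, because the
staircase spends its first trials ramping from 200 ms toward equilibrium
and deflates the mean SSD — visible in the realistic web sessions, absent
in the dedicated race simulation.

**D-score (SC-IAT):** improved-algorithm conventions — trials > 10 s
dropped; participant invalid if > 10% of trials are faster than 300 ms or
overall accuracy < 70%; error RTs replaced by block correct-mean + 600 ms;
d = (mean_incompatible − mean_compatible) / pooled SD over all penalized
RTs of both test blocks. Negative d = avoidance pairing faster. All
thresholds configurable; the exact variant used by any given study's
supplement may differ.

## Inference

Paired t-tests report Cohen's d = t/√n (mean difference over the SD of
differences) — this convention reproduces printed effect sizes from their
(t, n) pairs. The 2×2 Category × Trial-type within-subject ANOVA is
computed by `pingouin.rm_anova` with listwise deletion, ηp² attached as
F·df₁/(F·df₁ + df₂); in a 2×2 design every effect equals the squared paired
t on its difference contrast, which the tests use as an independent oracle.
With all cells identical (zero effect and zero error variance) F is
reported as 0 with p = 1. Correlations use pairwise deletion; no
multiple-testing correction is applied (α = 0.05 throughout, matching the
analysis style this mirrors).

## Intake models

OLS, elastic net and Lasso on the standardized predictors, outcome in kcal.
The elastic-net mixing parameter is grid-searched over {0.1, …, 0.9} with,
per mixing value, 50 log-spaced penalties descending four decades from the
null-model penalty max|Xᵀ(y−ȳ)|/(n·l1_ratio); Lasso is the same search at
mixing 1.0. Selection minimizes 5-fold cross-validated MAE (fixed-seed
shuffled folds; standardization refit inside each training fold).
`mae_in` is the refit model's training MAE; `mae_out` the mean held-out
MAE of the selected configuration. Complete-case analysis. Only the pure
L1 penalty zeroes coefficients, so feature selection is read off the Lasso.

## Problem sizes and what the tests show

The test suite runs the generator at full per-participant fidelity but
scales cohort size to each question: recovery oracles use 500 noiseless
stop trials; the race validation 10 seeds × 400 trials; support recovery 20
seeds × n = 72 feature tables; the PV-effect power check 10 seeds × 72
participants × 400 VR trials; pipeline determinism n = 8 end to end. Passing
these shows the chain is internally correct against known ground truth —
it does not certify behaviour on real recordings, whose noise is neither
Gaussian nor isotropic, whose reaches are not minimum-jerk, and whose gaze
streams contain structured dropout. The generator also leaves the
predictors essentially uncorrelated apart from the built-in race-equilibrium
link (SSD ≈ go RT − SSRT) and the PV–PA coupling, whereas real biometric
predictor sets are strongly intercorrelated; support-recovery results
should be read with that in mind.

## Known limitations

- Successful stops halt at the staircase equilibrium margin (~10 cm short
  of the object), farther than the ~2.5 cm real cohorts show; matching that
  geometry would need a sharper success/failure transition than the linear
  brake model provides.
- The latent `bd_choc`/`maxz_choc`/`fa_rate` features are drawn
  independently for the intake model rather than derived from the simulated
  staircase, so their extracted counterparts recover distribution, not
  per-participant values (they carry zero weight by default).
- D-score attenuation (penalty-inflated pooled SD) is inherited from the
  scoring convention and not corrected.
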