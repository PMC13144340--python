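# Methods

This note documents the generative model, the analysis pipeline, the
inference machinery and the numerical and design choices behind
`framesync`, together with what the synthetic cohort does and does not
emulate.

## Generative model of the synthetic cohort

The generator (`framesync.simulate`) emulates a within-subject
naturalistic-viewing experiment: every participant watches the same clip
set — `n_stimuli` unique stimuli, each once per framing condition
(neutral, threat, blame), each clip about one topic — in one long run at a
fixed TR.

**Shared signal.** Each clip (stimulus × frame segment) owns two latent
time courses `s_A`, `s_B`: white noise smoothed with a moving-average
kernel (default width 4 volumes ≈ 6 s, band-limiting them the way sluggish
hemodynamics band-limit real BOLD) and standardized to zero mean, unit
variance over the segment. Participant `i`'s signal voxels during a clip
in frame `f` receive

    κ_f · ( cos θ_i · s_A + sin θ_i · s_B ),

where the mixing angle θ_i = γ_f · (π/2) · u_i, with u_i the participant's
coupling covariate mapped affinely from its observed range onto [0, 1].
The latents are drawn independently per *clip*, not per stimulus: each of
the 36 clips is a distinct video, and independent latents keep the
analytic ISC formula below exact and the unmatched-segment baseline
exactly null. Signal voxels form one compact central cluster
(`signal_voxel_fraction` of the mask, default 10%) so cluster-based
spatial statistics face a realistic target.

**Noise and confounds.** Every voxel carries stationary AR(1) noise with
marginal standard deviation σ (innovation sd σ·√(1−φ²), so the marginal
variance does not move with φ); each participant gets a slow global drift
(random linear + half-cosine over the run, amplitude `drift_amplitude`)
and a linear leak of six simulated motion parameters (standardized random
walks) into all voxels with amplitude `motion_amplitude`. The motion
parameters are written out as the nuisance table, so the
nuisance-regression stage has something real to remove; the run-scale
drift is deliberately *not* in the nuisance set — within a one-minute
segment its variance contribution is negligible once Pearson centering is
applied, and the unmatched-segment baseline is the pipeline's answer to
whatever shared slow structure remains.

**Analytic oracle.** With unit-variance latents and independent noise, the
population correlation of two participants' signal voxels is

    r(i, j; f) = κ_f² · cos(θ_i − θ_j) / (κ_f² + σ²),

implemented as `expected_pair_isc` and used throughout the tests: κ = σ =
1 and equal angles give r = 0.5; κ = 0 or orthogonal angles give r = 0.

**Default parameters.** 27 participants, 8×8×8 grid (2.5 mm voxels),
TR 1.5 s, 12 stimuli × 3 frames, 100 s segments with a 6 s gap (the
inter-stimulus interval is a parameter, not a fixed constant, since the
experimental design leaves it open), κ = 0.8 / 0.5 / 0.4 for neutral /
threat / blame (neutral clips synchronize viewers most — the effect
direction the analysis is built to detect), σ = 1, φ = 0.3, γ = 0.5,
drift and motion amplitudes 0.5. `gamma_proximity` accepts a per-frame
mapping to plant frame-specific proximity effects (e.g. strongest under
blame). The survey generator defaults plant anger shifts of 1.26 (threat)
and 2.06 (blame), a weak fear shift, and a blame-induced sharing drop on
0–20 scales, with participant-level random intercepts; clipping to the
scale bounds is kept mild (baseline mid-scale, item noise sd 3) so OLS
recovery is unbiased.

**What the generator does not emulate.** No hemodynamic-response
convolution (latents stand in for already-convolved responses), no
anatomy, no spatial noise correlation, no multi-echo structure, no
scanner-specific artifacts, no missing data. Passing tests therefore
demonstrate that the *statistical machinery* is correct and calibrated
under a faithful dependence structure (shared stimuli, pairs sharing
participants, autocorrelated noise, motion confounds) — not that effect
sizes transfer to real scanners.

## Preprocessing

Nuisance regression projects every voxel onto the orthogonal complement of
[intercept | regressors] per run (per-run rather than per-segment: one
linear fit over the full time series, matching how motion parameters are
estimated). Segments are cut by volume: a volume belongs to a clip if its
acquisition onset lies in [onset, onset + duration) — half-open, so no
volume is double-assigned — and the first 8 volumes (12 s at TR 1.5 s) of
each segment are dropped to skip the hemodynamic transient. Exclusion is
counted in volumes, not seconds, to stay TR-agnostic. Segments shorter
than 10 volumes after exclusion are refused: Pearson correlation below
that is too unstable to average. Masked voxels are vectorized in a single
canonical order (ascending linear index, x fastest) so maps from all
stages align by construction.

## ISC maps and baseline correction

Pair maps are per-voxel Pearson correlations over a segment,
Fisher-transformed with |r| clamped at 1 − 1e−7 (finite z, displacement
< 1e−6 anywhere realistic). Zero-variance voxels yield r = 0 with a logged
count rather than NaN, keeping map algebra total. Condition maps are
arithmetic means of z-maps within (pair, frame) or (pair, frame, topic).

The baseline for a pair averages z-maps over *ordered* unmatched segment
combinations (A of i vs B ≠ A of j) across all frames and topics — ordered
rather than unordered because r(i_A, j_B) ≠ r(i_B, j_A); all combinations
when there are ≤ 200, otherwise a seeded uniform subsample of 200 (the
cap bounds cost; the seed is recorded). Unequal segment lengths are
truncated to the shorter segment — truncation avoids interpolation
artifacts. Baseline subtraction is always applied on the proximity-
regression path and is a flag for condition contrasts, mirroring where
the correction matters: dyadic regressions compare *levels* of synchrony
across pairs, which stimulus-nonspecific correlation contaminates, while
condition contrasts difference it out within pair.

## Contrast inference

The GLM per voxel has one indicator per condition plus a mean-effect
regressor per participant pair (all blocks but the first, keeping full
column rank); contrasts are tested one-sided as t = c'β̂ / se(c'β̂), with
|t| capped at 1e6 in zero-residual degeneracies (totality without
affecting ranks).

**TFCE.** `TFCE(p) = Σ_{h = dh, 2dh, …} e_h(p)^E · h^H · dh` with E = 0.5,
H = 2, 6-connectivity and dh = max|t|/100 per map unless fixed — the
enhancement method's conventional settings, all configurable. Negative
values are enhanced on the negated map and re-signed.

**Permutation scheme.** Framing labels are exchangeable only within a
participant pair's samples. Two schemes are implemented:

- *Coherent within-stimulus relabeling* (default,
  `permute_and_correct_segments`): each permutation draws one frame
  relabeling per stimulus and applies it to every pair's segment maps
  before re-averaging conditions. Samples still only move between
  conditions of their own pair, but the relabeling is shared across
  pairs. This matters because pairs are *not* independent: two pairs
  sharing a participant share that participant's noise, and all pairs
  share the stimulus set, so per-pair values carry coherent
  participant-by-segment and segment-level components. A shared
  relabeling preserves that dependence under the null; in Monte-Carlo
  the scheme is calibrated (familywise error ≈ 5% under equal coupling
  with shared signal present), and the relabeling space (3!)^n_stimuli
  is ample.
- *Independent per-pair relabeling* (`permute_and_correct`): each pair's
  condition labels are shuffled independently. This is the most literal
  reading of pair-blocked exchangeability and is retained for
  sensitivity analysis, but it treats pairs as independent; with shared
  stimulus-locked signal its null is too narrow (measured ≈ 20–25%
  familywise error at nominal 5% on the same simulations), which is why
  it is not the default.

The familywise-corrected p at voxel v is
p(v) = (1 + #{permutation max-TFCE ≥ observed TFCE(v)}) / (n_perm + 1):
the unpermuted labeling contributes the "+1", making the test exact with
floor 1/(n_perm + 1). Correction across a contrast family takes the null
maximum over all contrasts' TFCE maps per permutation. When the
relabeling space is not larger than n_perm it is enumerated exhaustively
(with a warning) and p = #{≥ observed}/N with the identity among the N.

**Tail approximation.** p-values at or below 0.10 can be refined by
fitting a generalized Pareto distribution (maximum likelihood, location
fixed at the threshold) to the null exceedances above the 90th
percentile: p = P(tail) · GPD-survival(observed − threshold). The fit is
screened with an Anderson–Darling statistic against the fitted
distribution (rejection bound 2.5, a conventional case-3 critical value);
a failed screen, a degenerate tail, or fewer than 60 null values falls
back to the empirical p with a warning.

## Proximity regression

Covariates are z-scored across participants before proximity construction
(making 21-point attitude scales and composite authoritarianism scores
commensurable); the regressor for pair (i, j) is −|x_i − x_j|, zero only
for identical scores. Each variable is tested by its partial t with all
other columns held in the model. The permutation null operates at the
*subject* level: shuffle the tested covariate's scores over participants,
rebuild that proximity column, refit. Response-residualization schemes
permute rows of the outcome, which has no subject-level analogue for
dyadic regressors; the design-side scheme used here respects the
dependence of pairs sharing a participant, and its calibration is
verified empirically (type-I Monte-Carlo within [2%, 9%] at nominal 5%).
A zero-variance covariate is refused (its column would be all zeros), and
participants with missing scores are dropped from all pairs with a logged
count — dyadic imputation is out of scope. Condition moderation contrasts
proximity effects between conditions by regressing the per-pair
difference map with the same machinery; swapping the conditions negates
the statistic map exactly.

## Behavioral stage

Composites are means of configurable item sets (defaults: six negative
items for negative affect, six positive for positive affect, two
designated items each for fear and anger — the item membership is
configuration, not code, since composite definitions are study-specific).
Framing models are OLS with the neutral frame as reference;
within-subject tables get participant fixed-effect dummies, which by
Frisch–Waugh–Lovell equal participant demeaning while keeping the
residual degrees of freedom right. "I do not know" responses are treated
as missing and row-dropped per model. Interaction models either cross the
given factors fully or, when an explicit term list is supplied, refuse
any interaction whose marginal terms are absent.

## Problem sizes used in the test suite

Monte-Carlo checks run at desk scale, chosen once: oracle equivalence on
a 4×4×4×60, 4-participant toy; analytic recovery with 3 participants and
102 segments on a 6×6×6 grid; contrast type-I calibration over 200
equal-coupling datasets (6 participants, 4 stimuli × 3 frames, 4×4×4
grid) at 250 permutations; contrast power over 50 datasets
(10 participants, 6 stimuli, 6×6×6, κ 0.8 vs 0.4 at σ = 1); proximity
power over 50 and null calibration over 200 datasets (8 participants,
4 stimuli, 4×4×4, κ = σ = 1, γ = 1 or 0); behavioral coverage over 100
surveys of n = 1800. Segment durations in these runs are 60 s (40
volumes, 32 after transient exclusion).

## Known limitations

- Permutation calibration is demonstrated under the generator's
  dependence structure; real data add spatial noise correlation and
  nonstationarities the simulations do not model.
- The coherent relabeling scheme requires a balanced design (every pair
  holds every stimulus × frame segment); unbalanced data currently only
  fit the independent scheme.
- The GPD tail refinement uses a fixed 90th-percentile threshold rather
  than adaptive threshold lowering.
- Behavioral models are linear; ordinal/multinomial outcomes and
  mediation are out of scope.
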