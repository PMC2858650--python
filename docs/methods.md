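# Methods

This note documents the models, algorithms, default parameters and
numerical choices behind `aepstats`, and what its verification
experiments do and do not establish.

## The analysis problem

A two-group longitudinal AEP study: each subject hears two near-identical
speech tokens ("mba", −20 ms voice-onset time; "ba", −10 ms) in blocks of
400 trials per session, over up to four sessions; one group additionally
performs a 50-trial 2AFC identification task between sessions. The
scientific questions are whether the auditory P2 grows across sessions,
where/when on the scalp the growth is reliable, whether it is larger for
the task group and retained months later, and whether it tracks
behavioral sensitivity (d′).

## Synthetic study generator

No public data accompany this design, so the generator is a first-class
component: it plants known structure and returns the ground truth needed
to verify every analysis stage.

**Evoked morphology.** Each component (P1, N1, P2) is a Gaussian bump in
time — amplitude `A` (µV), latency `ℓ` (ms after acoustic onset), width
`w` = half-width at half maximum — multiplied by a per-electrode
topography. The kernel's support is truncated at ±3.5 w so pre-stimulus
samples are exactly zero. Defaults: P1 (+1 µV, 60 ms, 12 ms), N1 (−4 µV,
110 ms, 22 ms), P2 (+3 µV, 180 ms, 30 ms), all with a vertex-maximal
topography. The stimulus-internal silence delays all latencies by 50 ms
("mba") or 60 ms ("ba"); with it, P2 peaks at 230/240 ms post trigger.

**Planted effects.** The default effect plan adds +0.5/+1.0 µV to P2 in
sessions 2/3 at the temporal-occipital electrodes TP9/IZ/TP10, doubled in
group 2 (the task group). The footprint is exactly those three
electrodes (no spatial falloff) so recovery tests have a sharp oracle.
Session 4 retains a fraction of the session-3 gain: 0.8 in group 2, 0.1
in group 1, matching the qualitative retention pattern the analysis is
meant to detect. N1 gains are zero by default but available.

**Noise.** Gaussian, spatially correlated across channels with
`exp(−d/λ)` structure over schematic cap distances, temporally smoothed
with an 8 ms Gaussian (unit-variance preserving). Default single-trial
standard deviation is 15 µV per channel. Artifact trials (default rate
0.05) receive a 90–150 µV blink transient on the eye channels that
decays over frontal scalp; smaller routine blinks hit the eye channels
only. Ground-truth artifact indices are produced by applying the ±70 µV
rule itself to the baseline-corrected trials (the stage at which the
pipeline screens), so the rejection-log comparison is exact by
construction rather than approximate.

**Subject heterogeneity.** Each subject carries a multiplicative
amplitude factor per component (sd 0.05) and a latency shift (sd 2 ms),
constant across sessions. These magnitudes are deliberately modest:
session-constant subject effects do not cancel in the condition means
that task-PLS decomposes, and if they exceed the planted session effect
the leading latent variable becomes a group-sampling nuisance rather
than the session effect the generator is supposed to plant. The defaults
keep the condition-mean nuisance below the planted effect at the study's
sample size (10/group). Real between-subject variability is larger;
consequently, passing recovery tests show the machinery recovers planted
structure under the study's intended regime, not that MC-PLS retains
power when stable subject heterogeneity dominates — a genuine limitation
of testing the largest singular value (see Limitations).

**Behavioral observer.** Equal-variance Gaussian signal detection: on
"mba" trials the internal response is N(d′, 1), on "ba" trials N(0, 1);
the observer answers "mba" above a criterion (default d′/2, unbiased).
Planted d′ per (group, session) defaults to small values (0.2–0.5),
i.e. near-chance identification of a pre-voicing contrast.

**Determinism.** One master seed drives a `SeedSequence` tree; identical
configuration + seed reproduce every trial bit-exactly.

## Preprocessing

Fixed order: baseline correction (mean over −100–0 ms per trial and
channel) → artifact rejection (drop trials whose absolute voltage
exceeds 70 µV on any channel, eye channels included; a trial exactly at
70 µV is retained) → arithmetic averaging → band-pass → common-average
reference (instantaneous mean of the 59 scalp electrodes subtracted; eye
channels never enter the reference). Each stage stamps a provenance
record once; repeating a stage raises an error (re-referencing is
mathematically idempotent and keeps a single record).

The band-pass emulates an "analog simulation" recording filter: causal
Butterworth high-pass, 1.0 Hz, order 4 (24 dB/octave) cascaded with a
low-pass, 20 Hz, order 2 (12 dB/octave), applied forward-only so the
implementation matches the asymmetric slopes; a zero-phase option
(`zero_phase=True`, forward-backward, which doubles the effective order)
exists but is off by default. The causal filter delays the P2 peak by
roughly its ~11 ms group delay; peak windows are wide enough to absorb
this.

## Peak and ROI quantification

Peak amplitude is the extremum of the component's polarity within its
search window, relative to the (zero-mean) pre-stimulus baseline; ties
resolve to the earliest sample; a window-edge extremum is flagged
`boundary` instead of being discarded — a deterministic replacement for
manual peak confirmation. Default windows (ms post trigger): P1
[80, 160], N1 [120, 220], P2 [190, 320], chosen to accommodate the
50–60 ms silence delay; they are configurable and recorded in output
metadata. ROI values are unweighted means over the ROI's electrodes
(vertex = CZ; anterior-central = FC1/FZ/FC2; temporal-occipital =
TP9/IZ/TP10). Windowed P2 amplitude for brain-behavior correlations is
the 190–290 ms mean.

## Task-PLS

Rows of the data matrix are subject × condition observations ordered by
(group, session, subject); columns are electrode-major (electrode,
latency) pairs over 0–300 ms inclusive (301 samples at 1 kHz × 59
electrodes = 17 759 columns); eye channels are excluded; one stimulus
per matrix, because the 10 ms acoustic latency difference between the
tokens would otherwise masquerade as an effect.

Mean-centering: each condition's column mean minus the grand mean of
condition means; rows sum to zero, so one singular value is structurally
zero. The SVD runs on the conditions × conditions cross-product
(6 × 6 for 2 groups × 3 sessions): eigenvalues below `λ_max · 1e−12` are
set to exact zeros (they are rank-deficiency artifacts whose square
root would otherwise inflate to ~1e−8), `V = Mᵀ U Σ⁻¹` for the non-null
part, and each LV's sign is fixed by making the largest-magnitude design
saliency positive. The feature dimension is never materialized beyond
one matrix. Non-rotated PLS normalizes the contrast, takes
`v = Mᵀ c / ‖Mᵀ c‖` and `s = ‖Mᵀ c‖`; exactly one LV.

**Permutation test** (default 500 resamples): session labels are
permuted within subject and whole subjects are permuted across groups —
a restricted scheme that respects the repeated-measures structure (both
operations are exchangeable under the null, so the test is valid by
construction). `p_k = (#{s_k^perm ≥ s_k} + 1)/(n + 1)`, which cannot be
zero with finite resamples.

**Bootstrap ratios** (default 500 resamples): subjects are resampled
with replacement within group, keeping each subject's session rows
together; a draw that would empty a condition cell is redrawn and
logged (impossible with whole-subject resampling, but guarded). Each
refit LV is sign-aligned to the original by the sign of the salience dot
product — no Procrustes rotation, adequate for the single-contrast and
dominant-LV uses here and a documented limitation for higher LVs. BSRs
divide the singular-value-weighted salience (`v_k s_k`, the scale on
which saliencies are reported) by its bootstrap standard deviation;
|BSR| > 3 marks stable features. Weighted rather than unit-normalized
saliencies matter: normalized directions have artificially small
bootstrap spread under the null, which would inflate BSRs.

## Repeated-measures ANOVA

Balanced designs only: every subject in every within-cell exactly once,
equal group sizes; anything else raises (no imputation, no
sum-of-squares-type ambiguity). Each subject's within-cell profile is
projected onto a full orthonormal basis of per-factor Helmert contrasts;
the basis splits the total SS exactly into the between-subjects stratum
and one stratum per non-empty within-factor subset S, with error term
S × Subject(Group). F for a within effect (and its Group interaction)
uses its stratum error; partial η² = SS_effect/(SS_effect + SS_error).

Greenhouse-Geisser ε = (Σλ)²/(d·Σλ²) over eigenvalues of the stratum's
contrast-score covariance, estimated from the *pooled within-group*
covariance (df N−G) — the convention of mainstream commercial ANOVA
software; pingouin's mixed-model ε differs because it ignores the group
structure, so the cross-validation tests compare ε on single-group
designs (where the conventions coincide) and SS/F/p on mixed designs.
ε is applied to both numerator and denominator df whenever the stratum
has more than one contrast; a degenerate (all-zero) covariance returns
the lower bound 1/d with a flag. Constant data yield F = 0 (0/0 is
reported as absence of effect, p = 1).

Post-hoc: pairwise paired t-tests between factor levels (collapsing
other factors), Bonferroni-multiplied and capped at 1; a two-level
factor returns its single comparison unadjusted. Simple main effects
re-fit the model on the sliced data, using the slice's own error term
(per-level strata) — the pooled-error alternative is deliberately not
offered, to keep each simple effect interpretable on its own data.

Retention contrasts are separate two-level Session ANOVAs (Session 1 vs
4 and 3 vs 4) at the temporal-occipital electrodes.

## Behavioral scoring

Hits = "mba" trials answered "mba"; correct rejections = "ba" answered
"ba"; d′ = z(H) − z(FA) with rates clamped to [1/(2N), 1 − 1/(2N)]
(N = 25 per class), which keeps d′ finite at ceiling (H = 1 → 0.98,
d′ contribution 2.054). Paired t-tests (one- or two-tailed, df n−1),
pooled-variance independent t (df n₁+n₂−2); zero-variance differences
are flagged degenerate rather than reported as infinite statistics.
Brain-behavior association: Pearson r between d′ and mean 190–290 ms P2
amplitude (CZ and temporal-occipital ROI) for all session pairings,
two-tailed p from the t-transform with df n−2.

## Verification experiments and problem sizes

The experiments in `aepstats.experiments` (run by the test suite and by
`scripts/acceptance.py`) use these sizes, chosen as the smallest runs
that make the Monte-Carlo bands meaningful:

- *Planted-effect recovery*: 20 replicates of the default plan at
  10 subjects/group, sessions 1–3, 500 permutations and 500 bootstraps
  on the full 60 × 17 759 matrix. Noise is generated at the evoked
  level with sd `noise_sd/√(retained trials)` (0.051 µV for 1 µV
  single-trial noise, 400 trials, 5% artifacts) — simulating 24 000
  single trials per replicate would change nothing statistically, since
  only the trial-averaged evokeds enter the analysis. Reported: LV1
  rejection rate, fraction of supra-threshold |BSR| mass inside the
  planted TP9/IZ/TP10 × 190–290 ms set, mean LV1 covariance fraction.
- *Null calibration*: 200 replicates with zero planted gains, same
  design, on a 10 ms temporal grid (59 × 31 columns). Permutation
  calibration depends only on row exchangeability, not column count, so
  the coarser grid affects runtime only. The ANOVA null uses 200
  replicates of a 2 × 10 × 3 Gaussian table.
- *Observer recovery*: 1000 replicates of the 50-trial observer at
  d′ = 1.

## Known limitations

- MC-PLS tests the largest singular value; when stable between-subject
  differences dominate the condition means (large subject heterogeneity,
  small n), LV1 captures group-sampling structure and the session effect
  loses power. The non-rotated contrast is the robust alternative in
  that regime.
- Bootstrap LV alignment is sign-only; saliencies of non-dominant LVs
  may mix under resampling (no Procrustes rotation).
- The ANOVA engine is balanced-only by design; studies with dropout
  (e.g. variable retention samples) need a mixed-effects model, which is
  out of scope.
- The generator's noise is stationary and Gaussian; it does not emulate
  alpha rhythms, drift, line noise, or latency *shifts across sessions*
  (only amplitude effects are planted by default), so passing tests do
  not certify behavior under those real-data features.
- Preprocessing is causal by default; absolute peak latencies include
  the filter's group delay (~11 ms at P2 frequencies). Comparisons
  across conditions are unaffected since all conditions share it.
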