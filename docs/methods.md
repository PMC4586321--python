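# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, and what the synthetic-data tests do and do not show
about real recordings.

## Paradigm generation

Each block holds exactly 127 stimuli — 11 randT, 28 each randS1/randS2/randS3,
and 8 predictive runs predS1→predS2→predS3→predT — at a fixed 1150 ms
stimulus-onset asynchrony (150 ms stimulus + 1000 ms blank). Composition is
exact, not stochastic. The generator shuffles 95 singleton stimuli plus 8
run-units uniformly (placing runs at uniformly random non-overlapping
positions, adjacency allowed) and rejection-samples orderings until no
*accidental* left→up→right→down shape run exists outside the labelled runs;
an unlabelled run would break the analysis' premise that predictiveness is
fully label-determined. The acceptance probability per draw is high, so the
retry budget (1000) is unreachable in practice and exhausting it raises.
Blocks are independent; onsets and positions restart per block (no analysis
crosses block boundaries).

## Synthetic EEG and behavior

Epochs span −700…+800 ms around onset at 512 Hz (sample times k/sfreq,
768 samples). Each epoch is a deterministic component waveform plus i.i.d.
Gaussian noise (default sd 20 µV per channel-sample):

* **CNV**: linear ramp from −500 ms to onset (inclusive), zero afterwards.
  Parameterized by slope (µV/s); the default onset amplitudes are −3 µV for
  unpredictable stimuli, −5/−6 µV before predS3/predT (preparatory
  enhancement). The ramp shape is a modelling choice — only the measurement
  windows are prescribed by the analysis.
* **P3**: Gaussian bump with peak amplitude, latency, and width given as
  FWHM (default 150 ms). Standards peak at 4 µV/450 ms, predictive S2/S3 at
  6/7 µV (predictive-value encoding); targets at 10 µV, 500 ms for randT vs
  440 ms for predT (prediction shortens latency; amplitude unchanged).
* **Topography**: per-group electrode weights; the frontal (Fz) share of
  both components rises monotonically over the age groups 12–14 → 14–17 →
  18–24 while the parietal share (target P3 at Pz) falls — the "frontal
  shift" the scalp ANOVAs are meant to detect. Unlisted electrodes get a
  small default weight (0.25).
* **Behavior**: per target, a press with probability hit_p at onset +
  Normal(rt_mean, 90 ms) truncated to the 100–1100 ms response window
  (truncation, not resampling, keeps the hit probability exactly hit_p);
  per standard, a false alarm with probability fa_p uniform in the window.
  Hit rates rise (0.84/0.90/0.95) and FA rates fall (0.010/0.006/0.003)
  with age; RT means are age-invariant (405 ms random, 345 ms predicted —
  a 60 ms benefit at every age, matching the pattern of a mature
  predictive system), since the study's age effect on RT was null.
* **Between-subject variability**: one multiplicative amplitude scale
  (sd 0.15) and one additive RT offset (sd 30 ms) per subject.

What the generator does **not** emulate: 1/f spectra and channel covariance
(noise is white and spatially independent), ocular/muscular artifacts (the
ICA cleaning step of real pipelines is a no-op here; the artifact-threshold
rule is exercised only by injected transients in tests), volume conduction
(weights are free numbers, not a forward model), trial-to-trial latency
jitter, and any subject-level coupling between ERP effect sizes and
behavioral benefit — so the delta-vs-RT-benefit correlations are null in
simulation even though the detection power of the corresponding ANOVAs is
high. Passing tests therefore validate the *estimators and inference code*,
not claims about real EEG.

`null_effect_config()` removes every group and predictability difference
(all conditions get the middle group's random-condition parameters) and is
the data-generating null for false-positive-rate checks.

## Behavioral scoring

A press in (onset+100, onset+1100] ms after a target is a hit (RT = press −
onset); after a random standard, a false alarm. With the paradigm's SOA the
windows of successive stimuli never overlap, so each press matches at most
one stimulus; the implementation still prefers the earliest unclaimed target
for robustness under non-default timing. Presses before the first stimulus
or in the dead zones are ignored with a logged warning. The FA percentage
uses only randS1–3 in the denominator; presses after predS1–predS3 are
tallied separately and excluded. d′ applies the 1/(2N) clamp to rates of
exactly 0 or 1, where N is the corresponding trial count; the clamp requires
N explicitly rather than assuming a session length.

## Trial selection, equalization, averaging

Six independent exclusion rules (boolean columns, so application is
idempotent and order-free): standards after a target; standards immediately
before or after a press (literal adjacency: the stimulus straddling each
press); randS2 preceded by randS1 but not followed by randS3 (a potential
predS2); missed targets; targets preceded by fewer than three standards; and
absolute amplitude > 100 µV on any channel within −700…700 ms. The
threshold interprets "excessive muscular activity" as an absolute-amplitude
criterion (configurable); nothing in the measurement windows depends on the
exact convention since synthetic noise never approaches it.

Condition pairs (randS1,predS1), (randS2,predS2), (randS3,predS3),
(randT,predT) are equalized *after* all exclusions by randomly subsampling
the larger condition's clean trials to the smaller's count, deterministically
per seed. Averages are pointwise means over clean trials; the pooled
"standards" ERP is the unweighted mean of the randS1/randS2/randS3 ERPs so
each standard type contributes equally despite unequal counts.

Windows are half-open [start, end) ms — CNV [−150, 0), P3 [350, 600),
baseline [−100, 0) — except peak picking, which scans the closed window
[250, 750] ms and breaks ties toward the earliest latency. Filtering is a
zero-phase 0.5–30 Hz band-pass (4th-order Butterworth per edge,
forward–backward, applied to averaged ERPs, not single trials): passband
gain at 10 Hz within ~1% of unity, ~−50 dB at 60 Hz. The order is average →
filter → (baseline for post-stimulus measures); pre-stimulus CNV measures
are never baseline-corrected.

Bad-channel repair uses spherical-spline interpolation on the unit-sphere
montage (Legendre-series g function, order m = 4, 50 terms, ridge
regularization 1e−5, at most 2 bad channels with ≥ 20 good ones) — the
canonical defaults for 64-channel montages. Electrode coordinates come from
the bundled BioSemi-64 standard montage, re-normalized to unit radius.

Topography normalization divides the per-electrode vector by its Euclidean
norm over the electrodes entering the corresponding ANOVA (Fz, Cz, Pz by
default) — the vector-scaling method that removes overall-amplitude
differences before comparing scalp distributions. It is scale-invariant,
sign-preserving, and undefined (an error) for an all-zero vector.

## Statistics

**Mixed rmANOVA.** Classical sums-of-squares decomposition for one
between-subject factor (age group) and one within-subject factor (electrode
or predictability); either factor may be absent. The Greenhouse–Geisser
epsilon is the Box epsilon of the *pooled within-group* covariance of the
within-subject levels (the SPSS/STATISTICA convention; pingouin's mixed
ANOVA pools across groups instead, which is why the cross-check test pins
epsilon on one-group data where the conventions coincide, and F/p
everywhere). Within-subject effects report p at (ε·df₁, ε·df₂). Epsilon is
clipped to [1/(k−1), 1] and equals 1 for k = 2 by construction.

The GG correction is conservative wherever a significance decision is at
stake: numerically, p_GG ≥ p_unc below a df/ε-dependent crossover that stays
above p ≈ 0.13 over the designs in scope, and correction can never flip a
non-significant effect to significant at α = 0.05. For small F (p already
far above any α) shrinking both dfs can *lower* the tail probability; the
tests assert the property on the meaningful domain and document this
counterintuitive region rather than clamping the p-value, which no standard
implementation does.

**Observed power** is 1 − CDF of the noncentral F at the ε-adjusted critical
value, with noncentrality λ = F·df₁·ε — i.e. the sample F taken as the
noncentrality per numerator df, the "observed power" convention of classical
GUI packages. The convention is pinned by a golden test because packages
disagree; power is monotone in F at fixed dfs.

**Randomization test.** Statistic T = (ΣA)² + (ΣB)², a monotone transform
of the between-group sum of squares at fixed group sizes, so the test is
direction-free (two-sided). Sampled p-values use add-one smoothing
(1 + #{T ≥ T_obs})/(n + 1), so p ≥ 1/(n+1) > 0; when the number of distinct
splits is ≤ 20,000 the full enumeration replaces sampling and p is the exact
tail proportion (the observed split counts itself, so p > 0). Tail
comparisons use a small relative tolerance so exact ties in T are counted.

**Correlations** report Pearson r, the least-squares slope b of y on x
(x is age or the behavioral measure; y the ERP measure, matching how such
results are conventionally plotted), and the two-sided t-based p with n−2
df.

**Battery layout.** (a) one-way age ANOVAs on hits/FA/d′/RT plus
predictability × age rmANOVAs on hits and RT; (b) electrode × age rmANOVAs
on raw and normalized CNV/P3 for pooled standards and randT; (c) where a
scalp interaction is significant, per-electrode age ANOVAs followed by
pairwise randomization post-hocs; (d) predictability × age rmANOVAs on CNV
at Cz (S2/S3/T pairs), standard-P3 at CPz (S2/S3), and target-P3 peak
amplitude and latency at CPz; (e) correlations of normalized Fz/Pz measures
with age and d′, and of the predictability deltas (CNV amplitude, target-P3
latency) with the RT benefit. No multiplicity correction is applied beyond
GG and the randomization post-hocs, mirroring the source analysis; a
Bonferroni layer can be added downstream from the emitted tables.

## Problem sizes and reproducibility

Default simulations use 15-block sessions and 12 subjects per group; the
power checks and worked examples run 5-block sessions (635 stimuli per
subject) on a reduced 8-electrode montage — the four analysis electrodes
plus neighbors — which preserves every analyzed quantity while keeping
simulation cheap; these sizes are the package's chosen verification
conditions, stated here so they can be scaled up. Every stochastic stage
(paradigm ordering, simulation, equalization subsampling, randomization
tests) takes an explicit seed; a rerun with the same resolved config is
byte-identical, and the pipeline writes the resolved config, per-rule trial
counts, and all intermediate tables alongside the report.

## Known limitations

* White, spatially independent noise understates real ERP measurement error
  correlations; detection-rate results transfer to real data only
  qualitatively.
* The generator draws behavioral and ERP effects independently per subject,
  so cross-domain correlations (deltas vs RT benefit) have no simulated
  signal.
* The randomization statistic follows the published verbal description up
  to an ambiguity in its third step; the implemented T is the reading that
  yields a valid two-sample location test, documented rather than asserted
  as the original code's behavior.
* Peak-based P3 latency is biased by noise asymmetry at low trial counts;
  the pipeline measures peaks on averaged, filtered ERPs only.
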