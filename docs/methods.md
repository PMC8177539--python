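# Methods

This note documents the statistical procedures the package implements, the
choices made where a procedure was genuinely underdetermined, what the
synthetic data generator does and does not emulate, and the limitations a
user should know before trusting a result.

## Data model

An annotation event is a coded facial action with an onset and offset in
session-relative seconds; it occupies the closed-open interval
`[onset, offset)`, which prevents double counting at shared boundaries.
Zero-duration events are legal: coders sometimes mark near-instant actions,
and these count toward frequency while contributing nothing to duration.
Clips are 30 s by default, each tied to a horse, a group (PRI, the
heterogeneous privately-owned cohort; UNI, the homogeneous university
cohort) and a condition (baseline, transportation, isolation).

Footage marked unscorable (visibility code VC74) is handled conservatively:
events wholly inside a VC74 span are removed, partial overlaps are kept
untrimmed so observed durations are never edited. Occurrence denominators
are not rescaled by visible time; with near-complete visibility the bias is
negligible, and rescaling would silently change the meaning of "frequency
per clip".

## Ear-flicker index

An *ears forward* (EAD101) and an *ear rotator* (EAD104) occurring within
1 s constitute one "ear flicker". Proximity is measured onset-to-onset —
onsets are the coders' most reliable timestamps; offsets depend on when a
muscle is judged fully relaxed. Pairing is greedy over the onset-sorted
stream: each unconsumed ear event takes the earliest subsequent
opposite-code event inside the window, ties broken by position after
sorting. Greedy pairing is deterministic, conserves counts
(n₁₀₁ + n₁₀₄ = 2·flickers + residual ears), and guarantees the defining
property that no residual EAD101 onset lies within 1 s of a residual
EAD104 onset. It is not guaranteed to be a *maximum* pairing; the test
suite compares it against an exhaustive matching oracle, and on realistic
streams the difference is rare and at most one pair.

## Frequency-based selection

Within an intervention pool and a control pool, occurrences are counted per
code (the composite flicker is its own code; its constituents are not
counted separately; VC74 is excluded). A code is selected when it accounts
for ≥ 5% of the intervention pool's occurrences *and* its per-clip mean
frequency is higher under intervention. The threshold is read inclusively
at one-decimal precision (5.0% qualifies). The reported difference,
100·(f_int − f_ctl)/f_ctl, uses per-clip means rather than pooled counts so
unbalanced pool sizes do not bias it; when a code never occurs in control
the difference is reported as infinite rather than silently dropped.

This rule has no significance component: under a no-effect null, any code
whose share clears the threshold is "selected" whenever a sampling
fluctuation puts its mean difference above zero (probability ≈ 1/2). The
selection is a screening device, not a test; the co-occurrence contrast
and the per-code paired tests carry the inferential weight.

## Co-occurrence contrast

For one clip and window size `ows`, a directed graph counts, for every
ordered pair of occurrences of distinct codes, the pairs with onset lag in
`[0, ows]`; simultaneous onsets count in both directions, and same-code
pairs are excluded so a repetitive single action cannot masquerade as
co-occurrence. Windows are anchored at event onsets rather than on a fixed
grid, so results do not depend on grid phase. A code's per-clip statistic
is its degree rate: summed in- plus out-weight per minute, which makes
mixed clip lengths comparable (with uniform 30-s clips it is a constant
factor). Edge weights, and hence degree rates, are non-decreasing in `ows`.

Profiles are averaged per horse and condition, and each code is scored by
the mean per-horse intervention-minus-control difference, tested with a
paired t-test across horses (the design pairs at the horse level). Codes
with a positive score are ranked as selected; those with p < 0.05 are
flagged significant. P-values are reported per window size without
correction across window sizes or codes — the output mirrors a per-cell
table — and a Holm adjustment across codes is available behind a flag.

A property worth knowing: the trigger side of a genuine onset coupling
gains only ~`prob` extra degree per occurrence, while its chance-pair
degree variance grows with overall background density. In dense streams
(tens of events per 30 s) the *response* code remains detectable (it gains
whole occurrences, each pairing with several neighbors) long after the
*trigger* code's signal has sunk below the noise. The planted-coupling
validation therefore uses a sparse, controlled stream (~9–10 events per
clip, trigger at 2 occurrences/clip, coupling probability 0.9, equal rates
in both pools so the coupling is the only planted difference); measured
recovery power at 20 horses × 3 clips/condition is ≈ 95%.

## Per-clip metrics and paired tests

Each clip×code cell carries the occurrence count and the maximum
single-occurrence duration; the maximum (not mean or total) is the duration
statistic, being robust to fragmented coding of one sustained action.
Group comparisons use the Wilcoxon signed-rank test on per-horse means,
exact null distribution at small n (scipy's automatic switch), zero
differences dropped, p = 1 when every difference is zero. The signed-rank
test was chosen over the paired t for consistency with the heart-rate
analysis and robustness at 10–28 horses; the paired t is available behind a
flag for sensitivity analyses. Significance bands are the conventional
0.05/0.01/0.001 stars.

Inter-coder agreement is the event-level ratio 2·N_matched/(N₁+N₂). Two
events match when they carry the same code and their intervals overlap by
at least `min_overlap` seconds (default 0: any overlap, including touching
boundaries — the least arbitrary criterion, and configurable). The matched
count is the per-code *maximum* bipartite matching rather than a greedy
sweep: maximum matching makes the ratio symmetric in the coders and equal
to 1 exactly when a perfect matching exists, properties a greedy sweep can
violate when a long annotation bridges two short ones.

## Heart rate

Commercial R-R filters are proprietary; the package uses an explicit,
documented rule of comparable strength. With instantaneous rate
HR_i = 60000/rr_i, beat *i* is rejected when it deviates from the median of
the 5-beat window centered on it by more than
max(6 bpm, 0.15 × median) — the 6 bpm floor is the "protection zone" below
which nothing is ever flagged; the 15% relative band mimics a
medium-strength setting; the window is truncated at recording edges. The
pass repeats on surviving intervals until stable, making the filter
idempotent by construction. All three parameters are exposed. More than
25% rejection triggers a signal-quality warning.

Mean heart rate for a clip is computed over the five-minute window from
2 min 15 s before clip start to 2 min 15 s after clip end, time-weighted
(beats per elapsed in-window time), so it equals 60000/rr exactly on a
constant series regardless of placement. Windows covered less than 50% by
the recording raise an error rather than return a misleading mean.
Contrasts are paired Wilcoxon tests on per-horse means: one test for the
PRI group (transportation vs baseline, reported raw) and a two-test family
for the UNI group (isolation and transportation vs baseline), Holm-adjusted.

## Classification

Each clip is a vector of per-code frequency and/or maximum duration
(frequency block first, codes sorted; absent codes are zeros). Following
the original protocol, features are built from the raw stream without
ear-flicker merging. Evaluation is leave-one-out with everything nested
inside the fold: standardization is fitted on the n−1 training clips only
(frequency counts and durations in seconds are incommensurate without it),
C is chosen from {0.01, 0.1, 1, 10, 100} by stratified 5-fold CV accuracy
on those clips with ties resolved toward the smaller C (stronger
regularization), and a linear SVM with class weights inversely proportional
to class frequencies predicts the held-out clip. Nesting the tuning avoids
the optimistic bias of a globally tuned C; a `global_c` argument reproduces
the other reading for sensitivity. Globally constant features are dropped
with a warning. Precision and recall take intervention as the positive
class; under label shuffling the leave-one-out accuracy sits at the
majority-class share, which the tests verify as a leakage guard.

## Synthetic data generator

The generator exists so every stage is testable without any recordings. Per
clip, each code's occurrences are a Poisson process at a condition-adjusted
rate with uniform onsets; durations are log-normal (positive, right-skewed,
matching blink-vs-hold heterogeneity), truncated at the clip end.
Condition effects are per-code rate multipliers. Temporal structure is
injected by triggered couplings — each trigger occurrence spawns a response
at a random lag with some probability — because that is precisely the
structure the co-occurrence method targets; the ear flicker is one such
coupling (55% of EAD101 events spawn an EAD104 within U(0,1) s, in every
condition). R-R series use a per-horse baseline rate drawn from a
group-specific normal, additive condition shifts, 6% multiplicative
jitter, and 1% artifact beats (shortened to 40% or doubled) for the filter
to remove.

The default configuration mirrors the emulated study's design: 28 horses,
18 PRI (baseline + transportation) and 10 UNI (plus isolation), one 30-s
clip per horse and condition, sessions long enough that every five-minute
heart-rate window fits. Rates are calibrated exactly in expectation to 26
annotations per baseline clip, 57 per transportation clip and 38 per
isolation clip, with the increase concentrated on eye-white, nostril and
mouth codes and only mild changes in blinks; heart-rate parameters target
group means of roughly 54→77 bpm (PRI) and 35→65 bpm (isolation) /
88 bpm (transportation) for UNI. Identical seeds give byte-identical
output files.

What the generator does **not** emulate: within-horse rate heterogeneity
and temporal autocorrelation beyond the planted couplings, coder error
(annotations are exact), dropout of unusable footage (designs are
complete), VC74 spans, circadian heart-rate drift, and realistic HRV
spectra. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes, at the study's scale — not that real coded video
satisfies those assumptions.

## Numerical and degenerate-input choices

Paired tests return p = 1 when all differences vanish, and p = 0 when all
differences are equal and nonzero (a t-statistic at infinity). Empty coder
pairs have agreement 1 by convention (vacuous). Occurrence pools with zero
clips, filters on fewer than five beats, contrasts with fewer than two
paired horses, and feature matrices with fewer than two clips per class all
raise errors rather than degrade silently. Condition-calibration in the
generator is exact in expectation because expected totals are linear in the
jointly scaled rates (coupled responses are proportional to their trigger's
rate), with a first-order correction for responses that fall beyond the
clip end.

## Problem sizes used in validation

Simulation-based checks run at deliberately moderate sizes chosen to keep
the full suite fast while leaving clear statistical margins: rate-doubling
recovery over 100 seeds at 20 clips per condition; coupling recovery over
25 seeds at 20 horses; null-model checks over 40–100 seeds; generator
calibration over 840 clips per condition. The acceptance script runs the
study-sized configuration (66 clips) end to end in well under a minute.
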