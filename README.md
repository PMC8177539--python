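# facs-affect

Analysis of equine facial-action annotation streams and heart-rate
recordings under putatively stressful management interventions
(road transportation, social isolation).

Horses code their facial behavior richly, and the Equine Facial Action
Coding System (EquiFACS) turns it into data: trained coders mark the onset
and offset of anatomically defined action units (AUs, e.g. AU101 *inner
brow raiser*), action descriptors (ADs, e.g. AD38 *nostril dilator*) and
ear action descriptors (EADs) in 30-second video clips. This package is a
tested, reusable implementation of the full analysis chain for such data in
a paired intervention-vs-baseline design, for ethologists and veterinary
researchers who have event tables (e.g. exported from ELAN) and R-R
interval recordings, and want the statistics — not the video handling.

## What it computes

- **Event I/O and validation** (`events_io`) — annotation tables
  (`video_id,code,onset,offset`), clip metadata, Polar HRM / R-R CSV files;
  removal of footage marked unscorable (VC74).
- **"Ear flicker" facial movement index** (`fmi`) — an *ears forward*
  (EAD101) and an *ear rotator* (EAD104) occurring within 1 s are merged
  into one composite event, so constituents are never double-counted.
- **Frequency-based selection, "HFI method"** (`hfi`) — codes holding
  ≥ 5% of intervention occurrences and more frequent per clip during
  intervention than control, with occurrence shares and the relative
  frequency difference 100·(f_int − f_ctl)/f_ctl.
- **Co-occurrence method** (`cooccur`) — per clip and observation window
  size (OWS), a directed graph counts ordered code pairs with onset lag in
  [0, OWS]; each code's degree rate is contrasted between conditions with a
  paired t-test across horses.
- **Per-clip metrics** (`metrics`) — frequency and maximum duration per
  code, Wilcoxon signed-rank paired tests on per-horse means, and the
  Wexler inter-coder agreement ratio 2·N_matched/(N₁+N₂).
- **Heart rate** (`heartrate`) — artifact rejection by a median
  protection-zone rule (6 bpm zone, 15% relative band, 5-beat window),
  time-weighted mean heart rate over a 5-minute window anchored 2 min 15 s
  before each clip, Wilcoxon contrasts with Holm correction within the
  isolation-group family.
- **Classification** (`classify`) — leave-one-out linear SVM
  (intervention vs control) on per-clip frequency/max-duration features,
  with per-fold standardization and nested stratified 5-fold selection of
  C; reports precision, recall and accuracy.
- **Synthetic studies** (`synthetic`) — marked Poisson event streams with
  per-condition rate multipliers, triggered couplings (including the
  ear-flicker structure), log-normal durations, and per-horse R-R series
  with condition shifts and artifact beats. The default configuration
  emulates a 28-horse crossover study calibrated to ≈26/38/57 annotations
  per baseline/isolation/transportation clip.

## Worked example

```python
import facs_affect as fa

config = fa.default_study_config()
dataset = fa.generate(config, seed=42)

events = fa.apply_fmi(fa.drop_unscorable(dataset.events))
table = fa.occurrence_table(events, dataset.clips)
print(fa.hfi_select(table).round(1).to_string())

windows = fa.clip_windows(dataset.rr_series, dataset.clips)
print(fa.hr_tests(windows).round(4).to_string(index=False))

summary = fa.summarize(fa.drop_unscorable(dataset.events), dataset.clips)
features = fa.build_features(summary, dataset.clips, mode="both")
report = fa.loo_evaluate(features, seed=7)
print(f"LOO accuracy {report.accuracy:.1f}%  precision {report.precision:.1f}%  "
      f"recall {report.recall:.1f}%")
```

prints

```
                 share_intervention  share_control  freq_intervention  freq_control  freq_difference
FMI_EAR_FLICKER                14.7           11.0                6.5           2.5            164.8
AU145                          14.1           16.3                6.2           3.7             69.5
EAD104                         12.6           14.4                5.6           3.2             71.7
AD38                           10.0            7.8                4.4           1.8            152.6
AU47                            7.4            8.7                3.3           2.0             67.5
AD1                             6.1            4.9                2.7           1.1            142.4
AU101                           5.9            7.6                2.6           1.7             53.5
EAD101                          5.1            8.9                2.3           2.0             13.2
group                   contrast  n_horses  mean_intervention  mean_baseline  p_raw  p_adj
  PRI transportation vs baseline        18            83.8196        60.9637  0.000 0.0000
  UNI      isolation vs baseline        10            64.1814        34.2784  0.002 0.0039
  UNI transportation vs baseline        10            87.3306        34.2784  0.002 0.0039
LOO accuracy 95.5%  precision 100.0%  recall 92.1%
```

Reading it: the ear flicker, nostril dilator (AD38) and eye-white increase
(AD1) more than double their per-clip frequency under intervention while
blinks rise modestly — the planted structure of the default generator.
Heart rate rises in every contrast (Holm-adjusted p < 0.01), and the
frequency+duration features separate intervention from baseline clips
almost perfectly under leave-one-out evaluation.

The same steps are available from a shell:

```sh
facs-affect synth --out study/ --seed 42
facs-affect hfi --events study/events.csv --clips study/clips.csv
facs-affect hr --rr study/hrm --clips study/clips.csv
facs-affect classify --events study/events.csv --clips study/clips.csv --codes all
```

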