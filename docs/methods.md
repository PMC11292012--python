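# Methods

This note documents the models, estimators and numerical choices behind
`blinklab`, and what the synthetic validation does and does not establish.

## Signal model and EAR extraction

The pipeline starts at per-frame eye landmarks (six 2-D points per eye in
pixel units); face detection and landmark inference are upstream concerns of
whatever mesh model produced the table.  EAR uses image-plane coordinates
only — a depth coordinate, if present in input files, is ignored — and all
distances are absolute values, so the image y-down convention is
observationally irrelevant.

Frames whose landmarks are non-finite are kept but flagged invalid; their
EAR samples are gap-masked and filled by linear interpolation between the
nearest valid neighbours (edge gaps hold the nearest valid value).  The
detector therefore never sees missing samples, while QC can report the gap
fraction per eye.  Timestamps must be strictly increasing and agree with the
nominal frame rate to 1% or extraction refuses the file.

Palpebral fissure height is the larger of the two lid-pair vertical
separations (which chord carries the maximum is unspecified upstream and
irrelevant at closure, where both vanish).  The paretic/contralateral height
ratio is the ratio of *medians over blink-free frames*, in percent; the
median keeps residual blink contamination from dragging the open-eye height
down, and blink frames from either eye are excluded using the detected
events.

## Blink detection

Detection runs per eye, independently; inter-eye synchrony is out of scope.

* **Smoothing** — centred moving average, default 25 ms (6 samples at
  240 fps).  Pure noise suppression before thresholding; constant signals
  pass through unchanged.
* **Baseline** — rolling 75th percentile of the smoothed signal over a
  centred 30 s window, evaluated on a 250 ms grid and linearly interpolated
  (the percentile of a 7200-sample window changes negligibly over 60
  samples).  Because the upper percentile of a noisy signal sits on the
  noise envelope rather than on the open-eye level, the Gaussian quantile
  offset z₀.₇₅·σ̂ is subtracted, with σ̂ the smoothed-noise SD estimated
  robustly from median absolute successive differences of the raw trace.
  This matters for slow shallow blinks, whose crossing times shift by
  (offset / slope).  An all-zero trace yields an all-zero baseline with a
  warning, and downstream detection counts nothing.
* **Hysteresis thresholding** — a candidate triggers when the smoothed EAR
  falls to or below θp·baseline (θp = 0.7) and releases once it recovers to
  0.85·baseline; re-dips before release belong to the same candidate.
  Ties at a threshold always classify toward closure.
* **Timing** — onset/offset are the crossing times of the θp·baseline
  level, linearly interpolated between samples; duration is the full width
  of the closure at the counting threshold.
* **Cleanup** — candidates closer than 50 ms merge (minimum EAR is the
  minimum over parts); durations outside [33 ms, 2000 ms] are discarded
  (sub-frame noise; sustained closures are not blinks).
* **Classification** — every surviving event is *counted* (pupil covered)
  by construction; it is *complete* (lids meet) when its minimum EAR
  ≤ θc = 0.10.

θp = 0.7 is chosen so that the shallow partial blinks of an acutely paretic
eye (floor ≈ 0.13 against a 0.24 baseline) still count, matching the
nonzero paretic blink counts reported clinically; θc = 0.10 separates
healthy and synkinetic complete closures (floors 0.02–0.06) from
acute-paretic partial ones (0.13).

## Per-eye summary

The blink-free average EAR averages the smoothed signal over the union of
the first 3 s of every inter-blink interval (shorter intervals contribute
wholly), estimating habitual openness clear of the closures.  Minimum and
maximum EAR are recording-global extremes of the smoothed trace; because a
recording-global minimum cannot exceed the deepest single closure, the mean
of per-blink minima is exposed alongside (`min_ear_blinkmean`) — the two
answer different clinical questions, and published per-eye "minimum" values
are more consistent with the per-blink reading in the synkinesis group.
Counts are normalised to 20 minutes (`count × 1200 / duration`), the study's
recording length, so the factor is 1 there; mean duration averages all
counted blinks (not only complete ones).  Empty quantities are NaN, never 0.
Per-minute time courses bin counted events by onset into half-open minute
bins; a boundary onset belongs to the later bin.

## Group statistics

Healthy controls have no paretic side, so sides are aligned before
comparison: patients contribute paretic → `paretic_like` and contralateral
→ `contra_like`; controls contribute left → `paretic_like` and right →
`contra_like` (controls show no side difference, so the assignment is a
labelling convention).  Paired side comparisons use the two-sided Wilcoxon
signed-rank test with zero differences dropped and ties mid-ranked (≥ 5
nonzero differences required).  Independent three-group comparisons use
one-way ANOVA; the post-hoc pairwise tests are Welch two-sample t-tests
with p multiplied by 3 and capped at 1 (the Bonferroni family is the three
group pairs).  Blink-PROM associations use Spearman's rho, two-sided,
unadjusted — the correlation analysis is exploratory.  Significance is 0.05
throughout; no FDR control anywhere.  The questionnaire instruments
themselves are not re-scored: FaCE domains (0–100), FDI physical (−25–100)
and FDI social/total (0–100) enter as numbers and are range-checked only.

## Synthetic generator

The generator is EAR-level, not video-level: it emulates the signal the
landmark front-end would deliver, not the video.  One preset per published
per-eye condition (healthy eye; acute palsy and synkinesis, paretic and
contralateral), each carrying the published baseline EAR, blink rate, mean
duration and complete-closure share; default recordings are 20 min at
240 fps, the study's conditions.

* **Onsets** — renewal process: inter-onset gap = 0.5 s refractory +
  exponential extra gap, giving the target mean rate.  Gaps are extended
  where consecutive blink waveforms would otherwise overlap (< 2% of gaps
  at the slowest preset; rate bias < 0.1%).  Real inter-blink intervals are
  overdispersed relative to exponential; only mean rates are targeted.
* **Waveform** — raised-cosine dip from the instantaneous open-eye level to
  a floor: the complete-closure floor with probability `p_complete`, else
  the subject's partial floor.  Partial floors are subject-level constants
  so the recording-global minimum recovers them.  Each dip is sized so its
  full width at the θp·(local open level) equals the drawn duration —
  generator and detector speak the same duration language, including under
  drift.  Durations are normal, floor-clipped at 60 ms (clipping, not
  resampling: resampling would shift the slow acute mean by ~+14 ms,
  clipping by ~+2.7 ms).
* **Drift and noise** — a zero-mean sinusoid (amplitude 0.02, period 300 s)
  modulates the open-eye level only; a closed eye is closed regardless of
  openness drift, so floors are anchored.  I.i.d. Gaussian sample noise
  (σ = 0.01) is added last and the signal clipped at 0.  These defaults
  exercise baseline tracking while keeping the default detector's
  false-positive rate at zero on blink-free stretches.
* **Excursions** — occasional wide-opening bumps (≈ 2/min, placed clear of
  blinks) give the maximum-EAR statistic realistic headroom.
* **Landmarks** — `emit_landmarks` inverts the EAR formula into six-point
  geometry whose per-frame EAR equals the trace exactly; a `fissure_scale`
  scales an eye's landmark set uniformly, leaving EAR invariant while
  fissure heights scale linearly (the acute-palsy and synkinesis height
  ratios, 96% and 88%, live as module constants).
* **Cohorts** — default composition 30 healthy / 6 acute / 24 synkinesis,
  paretic sides drawn with the observed left/right proportions.  A
  subject-level lognormal rate multiplier (log-SD 0.7), duration multiplier
  (log-SD 0.15) and openness shift (SD 0.03) are shared by both eyes, so
  between-subject scatter is of the magnitude clinical tables report.
  PROM scores are truncated normals with the published group means/SDs at
  the instrument bounds, independent of blink parameters by default; a
  `coupling` knob in [0, 1] reorders eye-comfort scores so their ranks
  follow the paretic-side rate (for power-testing the correlation
  analysis).

Everything is driven by one integer seed and bit-reproducible.

## What the synthetic validation shows — and does not

Recovery tests demonstrate that the pipeline returns the generating
parameters of a signal model *designed to be detectable*: stereotyped
waveforms, stationary noise, no gaps, no motion artefacts, no camera
dropouts, and floors safely separated from thresholds.  Passing them shows
internal consistency of detector, metrics and statistics, not performance
on real video, where landmark jitter is heteroscedastic (noise shrinks as
the lids meet), blinks are asymmetric (fast close, slow reopen) and
inter-blink intervals are overdispersed.

Known quantitative limits, measured on the generator's own conditions:

* Threshold-crossing times on noisy signals are first-passage quantities:
  detected onsets sit slightly early and offsets slightly late (the
  hysteresis band keeps near-threshold re-dips attached), widening slow
  shallow blinks by ~8 ms at the acute-paretic preset's 0.36 EAR/s crossing
  slope.  Brisk healthy blinks are unaffected (< 1 ms).  Onset jitter is
  σ_noise/slope — ~2 ms for healthy, ~11 ms for acute blinks.
* A recording-global minimum under additive noise lies below the true
  closure floor by the extreme-value deviation of the smoothed noise
  (~0.010 over a 20-min healthy recording).
* The published acute-paretic frequency SD (8.1/min at a mean of 2.3/min)
  exceeds what any unimodal positive rate model reproduces at that mean;
  the cohort generator targets means and realistic scatter, not that SD.
* The synkinesis-paretic partial floor is set to 0.12, not at the complete
  threshold 0.10, so partial blinks classify as partial under measurement
  noise rather than by coin flip.

## Problem sizes

Recovery checks use ten 20-minute, 240-fps recordings per profile
(288 000 samples each); oracle equivalence uses 200 randomised short
traces; the null simulations use 2000 replicates; the cohort check renders
the full 30/6/24 cohort at study conditions.  The fissure-ratio computation
in `scripts/acceptance.py` uses a 60-s recording (14 400 frames), ample for
a deterministic geometric ratio.
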