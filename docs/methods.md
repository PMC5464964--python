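# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `pcnacycle`. Units: time is handled in hours
internally with the frame interval given in minutes (converted in one
place); pixel coordinates are 0-based `(row, col)`; intensities are
arbitrary fluorescence units (AFU).

## 1. The synthetic movie generator

The generator (`pcnacycle.simulate`) renders 2-D multi-channel movies whose
reporter dynamics emulate an endogenously tagged PCNA cell line, together
with exhaustive ground truth (per-frame label maps, lineage, event times,
programmed compartment levels). It exists so that every downstream stage —
segmentation, tracking, classification, quantification — can be validated
quantitatively without any external data.

### Per-cell program

Each cell carries a deterministic program:

- **Phase durations.** G1 ~ TruncNormal(mean 7.7 h, sd 3.0 h, floor 1 h);
  S fixed at 10 h (equal to the PCNA expression ramp); G2 fixed at 4 h;
  M fixed at 0.5 h. The G1 distribution reproduces the reported average
  G1 length of unperturbed RPE-1-like cells; S and G2 are fixed because the
  diffuse-PCNA ramp defines S and nothing in the emulated system constrains
  G2 beyond "a few hours". The 1-h floor keeps degenerate programs out.
- **Diffuse nuclear PCNA.** Baseline `pcna_base` (default 100 AFU with 8%
  cell-to-cell CV) through G1; linear ramp over S to `pcna_plateau_fold`
  (default 2.0) times the baseline; plateau through G2. Daughters start at
  `mother_plateau / 2`, i.e. at the mother's baseline for a 2-fold plateau,
  so the fold change is stationary across generations.
- **Replication foci.** During S only: Gaussian spots confined to the
  nucleus whose count (5 → 20), sigma (1 → 1.5 px) and amplitude (0.3 →
  0.8 × baseline) all increase linearly across S. These stipulations encode
  the qualitative biology (foci become larger and brighter toward late S) at
  magnitudes chosen so that (a) the within-nucleus intensity SD rises
  monotonically through S and peaks at the S end, well above the Poisson
  noise floor, and (b) the foci's contribution to the *mean* stays ≈15%,
  far below the 30% one-frame drop that defines NEBD — so the S/G2 width
  peak and the NEBD detector cannot confuse each other by construction.
- **Mitosis.** At NEBD the nuclear PCNA signal redistributes over a 1.6×
  (linear) elliptical footprint at 40% of its pre-NEBD nuclear level; the
  chromatin channel condenses to a half-area concentric core at 2× its
  interphase level while the remaining nucleoplasm dims to 20%. At division
  the mother disappears and two daughters of half the mother's area appear
  at ±1.5 mother radii.
- **Quiescence (starvation mode).** No cell enters S phase; nuclear PCNA
  decays exponentially with half-time `decline_halftime` (default 16 h,
  i.e. ~88% loss over 48 h — a gradual decline on the starvation
  timescale) beginning 1–3 h after movie start.
- **Co-reporters.** `s_onset_ramp` (cyclin A2 / geminin-like): off until
  `onset_offset_min` after the PCNA ramp onset — defaults 45 min for the
  cyclin A2-like channel and 16 min for a geminin-like channel — then a
  linear rise to a plateau, degraded at NEBD. `g1_peak` (cyclin D1-like):
  an early-G1 rise, a decrease around S entry and a late recovery; 14% of
  cells instead decrease continuously from birth ("class I") and have
  their G1 shortened to 60%, and daughters inherit half the mother's
  pre-division level with 3% noise, making sister initial levels nearly
  identical. `constant` is available for extraction tests. Co-reporter
  cytoplasm is rendered in a 2× elliptical footprint around the nucleus.

### Rendering and noise

Nuclei are filled ellipses (axis ratio drawn in [1.0, 1.3], random
orientation); a pixel belongs to a nucleus when its center lies inside, and
true labels are disjoint by first-come assignment. Motion is a per-cell
Gaussian random walk (default sd 0.5 px/frame ≈ 3 µm/h at 10-min frames and
1 µm/px — realistic for slowly migrating epithelial nuclei, and slow enough
that the contact-free regime the tracking properties assume actually holds;
see §3). Noise is `Poisson(I·s)/s` shot noise (s = 1) plus additive Gaussian
(sd 2 AFU = 2% of the PCNA baseline); both are switchable for noise-free
oracles. Initial placement is a jittered grid (auto-sized image) or
rejection sampling with a retry budget (explicit image size).

Division geometry is placed deterministically against the known state of the
movie: the division axis is the candidate angle (16 candidates from a random
base angle) whose two daughter positions have the largest clearance from the
image margins and from every other cell alive at that frame. This models
the empirical fact that crowded/edge mitoses orient along the free space,
and keeps daughter–neighbor collisions out of the default regime.

### What the generator does *not* emulate

No photobleaching, illumination gradients, stage drift, focus loss, 3-D
structure, apoptosis, cell crowding/contact inhibition, or irregular
nuclear shapes. Passing tests therefore demonstrate the *algorithmic*
correctness of the pipeline under controlled conditions — correct event
definitions, correct linking logic, correct calibration arithmetic — not
robustness to every artifact of real microscopy. Parameters that a real
deployment would tune (thresholds, windows, ring geometry) are all exposed
in configuration.

## 2. Segmentation

Per frame: Gaussian smooth (sigma 1 px) → subtract the 5th percentile of
the frame → threshold → fill holes → watershed split on the distance
transform (seeds = local maxima ≥ `split_min_distance` = 10 px apart; ties
resolve to the lowest (row, col)) → area filter (60–6000 px). Labels are
4-connected.

**Threshold choice.** Per-frame Otsu is unstable when dim G1 nuclei (low
PCNA) coexist with bright S/G2 nuclei: the threshold is dragged toward the
bright class and can cut off dim nuclei and mitotic footprints entirely —
exactly the low-PCNA G1 weakness the local re-segmentation step exists for.
The default is therefore a two-pass scheme: a permissive *triangle*
threshold (stable, near the noise floor) detects candidate regions, with a
robust floor of median + 6 MAD so that a frame without nuclei yields no
detections; then each region's boundary is re-drawn at `refine_fraction`
(default 0.5) of that region's own median interior level, which recovers
the geometric half-maximum edge for dim and bright nuclei alike (IoU ≥ 0.99
against truth on noise-free frames). `otsu` and `fixed` thresholds remain
selectable; all adaptive variants are invariant under global positive
rescaling of the raster.

**Local re-segmentation** (`local_resegment`): within the bounding box of a
prior mask (from an adjacent frame) dilated by 2× the smoothing sigma,
recompute a local Otsu threshold and return the connected component with
maximal overlap with the prior. Tracking invokes it for frames where a
track's area falls >30% below its rolling-median area. Constant or
saturated frames produce an empty label map with a warning, not an
exception.

## 3. Tracking and lineage

Greedy linking by maximal Jaccard overlap between consecutive frames
(minimum 0.15), with two guards: an area-ratio gate (next/prev area within
[0.33, 3]) so that the 2.56×-area mitotic footprint never links onto a
half-size daughter, and a nearest-centroid fallback (≤ 12 px) only for
labels with no qualifying overlap. Tie-breaks: larger overlap, then smaller
centroid distance, then lower label id — fully deterministic.

Gap closing merges a terminated track with a later-born one when the gap is
1–2 frames, the centroid jump is within `max_displacement × (gap+1)`, and
the area ratio is within [0.5, 2]. A gap of 0 (consecutive frames) is never
merged — that case belongs to the linker, and merging it could fuse a
mother with a daughter born the next frame.

Divisions are detected after linking: a track that terminates before the
movie end, shows a ≥30% one-frame drop of its smoothed nuclear PCNA mean
within the trailing 5 frames (the NEBD signature), and has exactly two
candidate tracks born within 3 frames and 42 px, becomes a mother; among
candidate pairs the one whose summed area best matches the mother's
pre-mitotic median area wins, then proximity, then ids. A single plausible
daughter is left as a termination (logged), never a one-daughter division.
The resulting forest is acyclic by construction with exactly 0 or 2
daughters per track.

## 4. Phase classification

Features per tracked frame: background-subtracted nuclear mean and
within-mask pixel SD ("distribution width"; IQR available as a config
alternative — whether to normalize the width by the mean is left
configurable and off by default). Missing frames inside a track span stay
NaN; nothing is interpolated. Smoothing: centered running median, window 3
frames — the smallest window that suppresses single-frame detector noise
without shifting onsets.

- **G1/S** (`detect_g1s`): baseline = median of the smoothed series over
  the first 4 h after birth; candidate onset = first frame exceeding
  `baseline + max(0.10·baseline, 4·MAD)` that persists 3 frames; the MAD
  term exists because a co-reporter's pre-onset baseline is ≈0 after
  background subtraction, making a purely multiplicative threshold
  degenerate — the same rule therefore serves PCNA and co-reporter onset
  detection. The onset is refined by a two-segment flat-then-ramp
  least-squares changepoint fit over [birth, candidate + 3]; the returned
  frame is the fitted corner (the last pre-ramp frame). Both threshold
  terms scale with the data, so the estimate is scale invariant.
- **S/G2** (`detect_sg2`): argmax of the smoothed width over the open
  interval (G1/S, NEBD), ties to the *latest* frame (the width maximum
  sits at the end of S). Intervals shorter than 3 frames or with constant
  width are flagged undefined.
- **NEBD** (`detect_mitosis_events`): smoothed mean drop
  `sm(f+1) ≤ 0.7·sm(f)`; the event frame is f+1, the first frame at the
  redistributed level, matching the ground-truth convention (first frame
  at/after the event). When a chromatin width series is present, the raw
  (unsmoothed — a condensation peak can last one frame) width must reach a
  local maximum within ±2 frames of the drop.
- **Quiescence** (`classify_quiescence`): no G1/S onset, a tolerant
  (≤ +5% upticks) non-increasing run of ≥ 24 h, and a drop below 60% of
  the birth-window level. The decline onset is refined by a
  flat-then-declining changepoint fit on log intensities, because the flat
  pre-decline segment is itself "non-increasing within tolerance" and
  would bias a run-start estimate early.
- **Phase labels** (`assign_phases`): G1 = [birth, G1/S), S = [G1/S,
  S/G2), G2 = [S/G2, NEBD), M = [NEBD, division]; G0 from the decline
  onset onward; anything unresolvable is "unknown". Any ordering violation
  voids the labels and flags the track inconsistent.

Track alignment (`align_tracks`) shifts series on the shared acquisition
grid to put t = 0 at a chosen event; out-of-span positions are NaN, never
extrapolated.

**Event-frame conventions.** Truth event frames are the first frame at or
after the continuous event time (ceil); the changepoint detectors return
the last pre-transition frame (floor). The systematic half-frame difference
cancels in every within-pipeline comparison (channel-vs-channel G1/S
agreement, onset lags) and is well inside the ±2-frame recovery tolerance
used against truth.

## 5. Quantification and statistics

Cytoplasmic signal is measured in an annulus 2–6 px outside the nucleus
edge (Euclidean distance), excluding all nuclei and dropping pixels claimed
by more than one ring — conservative and deterministic. The background is
the 5th percentile of pixels outside every nucleus and ring, per frame;
note that on a pure-noise frame this estimator sits ≈1.6 noise-sd below the
mean, which bounds the residual of "empty" channels.

Calibration: `total = intensity / tagged_fraction` (defaults: cyclin A2
0.5 — the tagged allele is expressed at a level similar to the untagged
one; cyclin B1 0.30; cyclin D1 0.73) and
`standardized = intensity · (E_ref/E) / k_fluor`, linear in intensity and
inversely proportional to exposure. Population curves: per-time mean with
the 2.5th/97.5th percentile band over non-missing values (the literal
"95% of the values" reading, rather than a parametric interval).

Cyclin D1 kinetic classes: class I requires every smoothed G1 step ≤ +τ
(τ = 2% of the birth level) *and* a net decrease > τ from birth to G1/S;
an exactly constant series shows no decrease and is class II — the net-
decrease clause is the documented tie-break that makes "continuously
decreasing" mean what it says. Decrease onset: first run of ≥ 3 negative
smoothed first differences. Slopes: least-squares over a 5-frame window in
AFU/h.

Spearman's rho (average ranks) and the two-sided Mann–Whitney U are
implemented in-package: U is the rank-sum statistic; for both group sizes
≤ 8 the p value enumerates all C(n+m, n) assignments of the pooled ranks
(valid under ties), otherwise a normal approximation with tie correction
and 0.5 continuity correction is used. Both agree with independent
brute-force enumerations and with scipy on their common domain (tested).

## 6. Problem sizes

The bundled benchmarks simulate one 50-founder default movie (~190 frames
of ~470×530 px, three channels) and analyse it twice (once per segmentation
channel) — about five minutes on one CPU; unit tests use 2–6-cell movies.
These sizes were chosen as the smallest at which the benchmarked claims are
meaningful (≥36 cells for the paired-channel comparisons, ≥50 for the
onset-lag median), and all scale up linearly via `SimulationParams`.

## 7. Known limitations

- The linker is greedy, not a global assignment; it is exact in the
  contact-free default regime but will swap identities under sustained
  deep overlap of equal-sized nuclei.
- NEBD detection needs the mitotic footprint to be segmented; a cell whose
  entire M phase falls in dropped frames yields a termination instead of a
  division.
- The two-segment changepoint assumes one flat-to-ramp transition within
  its fit window; double onsets (e.g. re-entry after transient arrest) are
  outside its model.
- Quiescence needs ≥ 24 h of observation by default (configurable); shorter
  tracks are flagged unknown rather than classified.
- The percentile background estimator is biased low by ≈1.6σ on
  signal-free regions; all downstream comparisons are made on identically
  processed series, so the bias cancels within an experiment.
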