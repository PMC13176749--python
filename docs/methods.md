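# Methods

This note documents the models, conventions and numerical choices behind
`cbctqa`, in the order data flows through the pipeline.

## Dosimetry reduction

A TLD read-out is modelled as `ecc · value`, where the element correction
coefficient (ECC) is an abstract multiplicative calibration factor
(default 1). Glow-curve processing, annealing schedules and reader hardware
are out of scope: read-outs enter as dose values in mSv. For the diagnostic
photon energies involved the radiation weighting factor is 1, so absorbed
dose (mGy) and equivalent dose (mSv) are treated as numerically
interchangeable and mSv is used throughout.

**Background subtraction.** The mean of the dedicated background chips is
subtracted from every field read-out, after ECC application (calibration
precedes field use; the alternative order differs only when ECC ≠ 1 and is
not what a calibrated-chip workflow implies). Negative corrected values can
arise when a field dose is at background level; the default policy keeps
them with a warning, because clamping would bias low-dose regions upward.
A `clamp` policy (floor at 0, warned) is available by configuration.

**Region aggregation.** Chips sharing a region and protocol are merged into
mean, sample SD (n−1 denominator; 0 for a single chip), min and max. With
duplicate chips the sample SD reduces to |v₁−v₂|/√2, which is how the
reference study's printed ±SD values arise from its printed min/max. Means
are always recomputed from constituent values, never taken from printed
summaries — this makes the pipeline robust to transcription errors in
summary rows (the bundled study contains one such misprint, see
`cbctqa/reference.py`).

**Effective dose.** ED = Σ w_T · D_T over regions carrying a weighting
factor. A region absent from the table is an error (no silent default); a
region marked excluded (`-` in the CSV) contributes nothing and is logged.
The factor set is used exactly as supplied: the bundled study's set sums to
1.52 (it up-weights every measured salivary/mucosal structure individually),
which is reported as a warning and never renormalised, since renormalising
would silently change every published ED. The canonical ICRP-103 category
weights (sum 1.0) ship alongside for comparison
(`reference.icrp103_reference_weighting`).

**Comparison statistics.** Dose reduction is 100·(ref − cmp)/ref and may be
negative. The average absorbed dose is the unweighted mean over *all*
measured regions, including ED-excluded ones (this is the convention the
reference study's 16-region averages follow). Lateral ratios divide the
right-side by the left-side region mean for `right_*`/`left_*` name pairs.
The exposure summary compares any shared subset of
{exposure time, mAs, air kerma, DAP, DLP, CTDIw, CTDIvol}.

## VOI statistics and image-quality metrics

**Rasterisation.** A pixel belongs to a VOI iff its centre lies inside the
ellipse inscribed in the diameter×diameter bounding box, boundary inclusive.
Centres may be half-integer; a diameter-6 VOI has 32 pixels at a
half-integer centre and 29 at an integer centre. Area is reported in px²
(pixel count) and in mm² when pixel spacing is known. Statistics are
min/max/mean/sample SD over the selected pixels. No HU floor clamping is
applied by the analysis — values clipped at −1000 in real exports were
clipped by the scanner, and the synthetic generator emulates that at
generation time instead.

**Aggregation.** Per slice region × protocol × entity, the three (or more)
VOI means are summarised by their mean, sample SD, min/max and
Dmax = maxᵢ |meanᵢ − mean|. The metric noise term is this *between-VOI*
sample SD of the soft-tissue means, not the within-VOI pixel SD — the only
reading under which all 18 published metric values reproduce from the
published per-VOI table:

* SNR = bone mean / soft-tissue SD,
* CNR = |bone mean − soft-tissue mean| / soft-tissue SD,
* DIN = |bone mean − soft-tissue mean| / soft-tissue Dmax.

These operative forms were fixed by reverse-verification against every
published region×protocol cell (agreement ≤ 0.03 everywhere, tested at
≤ 0.05/0.1). Air VOIs are collected, aggregated and profiled but enter no
metric. Zero noise (SD or Dmax = 0) is an error, not infinity.

**Ratios and rounding.** Unrounded quick/regular ratios divide the unrounded
metrics. The *report* ratio column follows the published convention of
computing from 2-decimal metric values and rounding the quotient to 2
decimals; both are retained. All report rounding is half-up (doses 3
decimals, percentages 2, metrics/ratios 2, lateral ratios 1); the JSON
report always carries full precision.

## Synthetic phantom generator

The generator provides the statistical structure the analysis assumes, not
anatomical realism (no projection/reconstruction simulation, beam hardening
or metal artifacts).

**TLD studies.** Read-out = true_dose·(1 + N(0, cv)) + background;
background chips get background·(1 + N(0, cv)). Noise is multiplicative
because TLD precision is dose-proportional; Gaussian is adequate at these
CVs. Defaults mirror the reference design: 2 chips/region, 3 background
chips, background 0.077 mSv, CV 5%. At cv = 0 the pipeline recovers every
true dose and the ED exactly (tested).

**Slices.** Default geometry is a head analogue scaled to the image: air
background, soft-tissue disc (radius 0.45·min side), bone arch annulus
(0.30–0.40), two air sinus cavities, with three suggested VOI sites per
entity validated to lie inside their entity. Pixels are
N(entity mean, within_sd · √(reference_mas/protocol_mas)) — quantum noise
∝ 1/√mAs, so a 14.4 mAs "quick" slice is √1.5 noisier than the 21.6 mAs
reference — and each suggested VOI site receives a mean offset
N(0, between_sd), a dose-independent structural drift. Defaults
(means 1800/0/−1000 HU; within SD 180/120/50; between SD 150/50/40 for
bone/soft/air) are set to the scale of the reference study's within-VOI and
between-VOI dispersions; the true decomposition in a physical phantom is not
identifiable from summary tables, so these are documented as synthetic.
Images are quantized to integer HU and floored at −1000, emulating the
scanner's unsigned 16-bit export (intercept −1000, slope 1), which makes the
DICOM round-trip exact.

What passing synthetic tests shows: the reduction chain is unbiased and
correctly propagates the configured noise structure. What it does not show:
robustness to reconstruction artifacts, non-Gaussian or spatially correlated
noise, or VOI mis-placement, none of which the generator emulates.

**Estimator behaviour worth knowing.** With only three soft-tissue VOIs the
sample SD in the metric denominators is a 2-degree-of-freedom estimate:
1/SD is strongly right-skewed, so the *median* estimated CNR sits well above
the asymptotic contrast/dispersion value (≈ 20% above at n = 3 under the
default noise mix). The tests therefore check the estimator against a
direct statistical simulation of the same statistic, and separately verify
convergence to contrast/between-SD as the VOI count grows. The quick/regular
SNR ratio is better behaved (the bias largely cancels): its Monte-Carlo
median over 500 independent seed pairs at 14.4 vs 21.6 mAs falls near
√(14.4/21.6) ≈ 0.816, bracketing the reference study's observed 0.83–0.90.

## Problem sizes and determinism

Monte-Carlo tests use 96×96-pixel slices (the geometry is scale-free; VOI
counts, not image size, set the estimator variance), 150–500 seeds per
property, and 200 replicate TLD studies — sizes at which the checked
medians/means are stable to well inside the asserted bands. Every random
draw flows from an explicit `numpy` Generator seed; there is no global
random state. All file writers are byte-deterministic (fixed column order
and number formatting, LF endings, content-derived DICOM UIDs, fixed DICOM
dates), so identical inputs produce identical reports.

## Known limitations

* Only the two bundled weighting tables ship; the ICRP remainder-organ
  mean-dose formalism is not implemented.
* DICOM support is single-frame, uncompressed grayscale only (multi-frame
  and compressed transfer syntaxes error with guidance); no PACS, DICOMDIR
  or anonymisation tooling.
* No MTF/spatial-resolution measurement and no automatic VOI placement;
  VOIs are user-specified, as in the manual workflow the pipeline encodes.
* VOIs are 2-D regions on single slices; no 3-D volumetric metrics.
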