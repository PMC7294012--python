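# Methods

## Problem and model

Impulse noise replaces a random subset of image pixels with outlier values
and leaves the rest untouched. For a clean image `S` and corruption rate
`p ∈ [0, 1]`, each pixel is independently replaced with probability `p` by

* **fixed-valued** (salt-and-pepper) noise: `η_min` or `η_max` (the extremes
  of the 8-bit range, mixed 50/50 by default), or
* **random-valued** noise: an integer drawn uniformly on `[η_min, η_max]`.

Random-valued impulses are the harder case: they need not be extremes of
their neighborhood and cannot be recognized by value alone.

The denoiser is a *switching* filter: it first classifies every pixel as
corrupted or clean, then restores only the corrupted ones, so clean pixels
pass through bit-identical. That contract is asserted throughout the test
suite and in every benchmark run.

### Detection: windowed robust statistics and mROR

For every pixel, a 5×5 reflect-padded window yields the adaptive median
AMED and the adaptive median absolute deviation AMAD = med |y − AMED| over
the window sample `y`. NAMAD = AMAD / 0.6457 converts the robust scale to
standard-deviation-like units (0.6457 is the normalizer adopted by the
method this package implements; the conventional normal-consistency
constant is 0.6745 — the value is configurable). The modified robust
outlyingness ratio is the studentized deviation

    mROR(i, j) = |x(i, j) − AMED(i, j)| / max(NAMAD(i, j), ε),

with `ε = 1e-6` guarding flat windows (AMAD = 0): a pixel equal to its
window median scores 0 there, a deviating pixel scores very large but
finite. Pixels are partitioned into four clusters by impulse-likelihood:
mROR > 3, (2, 3], (1, 2], ≤ 1. The intervals are right-closed; exact
boundary hits are measure-zero for real images.

Detection compares the deviation |x − AMED| against a per-cluster
threshold, in two stages:

* **coarse** — 4 iterations with thresholds (45, 30, 20, 15) for clusters
  1–4. Each iteration recomputes the statistics on the current working
  image, flags pixels, restores the new flags with the adaptive fuzzy
  median, and feeds the restored image forward; as the working image
  approaches the clean image, impulses hidden by dense corruption surface.
* **fine** — 2 iterations with strictly smaller thresholds (34, 25, 16, 11)
  on the coarse-restored image, catching low-amplitude residuals.

The mask is the union over all iterations; a flagged pixel is never
unflagged (its value has been replaced, so later rules cannot re-judge it).
A zero-new-flag iteration terminates its stage — a pure optimization with a
bit-identical result. The iteration caps (4 coarse, 2 fine) are enforced;
pushing further degrades the restoration by eroding clean structure.

**Threshold provenance.** No closed form exists for the eight thresholds.
They were calibrated once with `scripts/calibrate_thresholds.py`, a grid
search over scale factors applied to fixed cluster profiles, maximizing
mean detection F1 on textured phantoms at 10–40% noise of both kinds. The
coarse profile ratio 3 : 2 : 4/3 : 1 mirrors the cluster cuts; decreasing
thresholds from the most to the least impulse-like cluster encode that a
high-mROR pixel needs less corroborating deviation.

### Restoration

**Adaptive fuzzy median (AFM)** restores flagged pixels inside the
detection loop. A window grows from 3×3 (by 2, up to 11×11) while the clean
sample is unusable: fewer than 3 clean values, or the clean median sits at
a singleton extreme of the clean sample (a lone surviving outlier — the
mask-aware analogue of the classic "median is an impulse" trigger; a literal
window-extreme test would loop forever under salt-only corruption of flat
regions). Clean values are combined with triangular fuzzy weights centered
on their median, half-width 20 intensity units, floored at 1e-3 so the
aggregate is always defined: values far from the local consensus are
down-weighted. Spread → ∞ recovers the clean mean, spread → 0 the clean
median (both checked numerically). All restorations in one pass read the
input image; cascading happens only across detector iterations.

**Mask-restricted reference NL-means** produces the final image. The
reference is the coarse/fine-restored working image the detector produces —
the cleanest estimate the pipeline itself constructs (an external reference
can be supplied instead). For each flagged pixel `p`, candidates are the
clean pixels `q` in a 21×21 search window; the weight is
`exp(−d(p, q) / h²)` with `h = 10` and `d` the mean squared difference of
the 7×7 patches around `p` and `q` in the reference, averaged over
positions where both patches are clean. Pairs with clean overlap below 50%
of the patch are incomparable (zero weight). The restored value is the
weighted average of the reference intensities at the candidates — a convex
combination, hence bounded by the contributing reference range. Patch
weighting is uniform (no Gaussian kernel); `h → ∞` recovers the unweighted
clean-candidate mean (checked to 1e-6). A pixel with no comparable
candidate falls back to the AFM estimate. The implementation sweeps search
offsets with box filters, which is algebraically identical to the
per-candidate definition (asserted in tests against a direct loop).

### Metrics

MSE is the mean squared pixel difference; PSNR = 10 log10(255² / MSE) dB
with the peak fixed at 255 by the 8-bit convention. A perfect restoration
reports the `inf` sentinel in tables, never a float.

## Synthetic phantom

All tests and benchmarks run on a seeded phantom: constant background
(default 90) with a linear illumination ramp (amplitude 30), 3 soft
Gaussian-profile bright blobs standing in for masses (contrast 60, radii
8–24 px), 12 near-point bright specks standing in for microcalcifications
(contrast 80), and a correlated random texture field (σ = 6 intensity
units, correlation length 0.8 px) standing in for parenchymal tissue.
Generation is a pure function of the spec and seed.

The texture field matters: on a texture-free image a whole-image median
filter is nearly lossless, so comparisons between switching and
non-switching denoisers degenerate. Fine-scale clean structure is exactly
what is at stake in impulse denoising, and the phantom must contain some.

What the phantom does **not** emulate: the heavy-tailed, spatially varying
texture of real parenchyma, anatomic edges (skin line, pectoral muscle),
scanner blur, and the fact that real microcalcifications are the diagnostic
signal. Passing tests show the machinery is correct and the comparisons
behave as the theory predicts on controlled fixtures — not that the
measured PSNR values transfer to clinical mammograms. Note also the
detector/restorer cannot distinguish a bright isolated speck from an
impulse; on the phantom, speck centers are flagged and smoothed away. This
is an inherent single-frame ambiguity of impulse detection, shared by the
method implemented here.

## Measured behavior and known limitations

* Detection on 256×256 phantoms with 10–40% salt-and-pepper noise: recall
  1.00, false-positive rate ≤ 0.005 at the default thresholds; recall is
  non-decreasing in impulse amplitude.
* For **random-valued** noise, detection recall at the F1-calibrated
  thresholds is ≈ 0.75–0.86: impulses whose value lands near the local
  background are below any deviation threshold. Those misses dominate the
  pipeline's residual error at low noise ratios.
* The classic two-level adaptive median baseline replaces only pixels that
  are extremes of their (grown) window. Under salt-and-pepper noise it
  clearly beats the standard median at every ratio; under random-valued
  noise it collapses (mid-range impulses pass through), falling more than
  10 dB below the standard median at 30–50%. The PSNR ordering
  pipeline > adaptive median > standard median should therefore be expected
  under fixed-valued noise, while under random-valued noise the adaptive
  median drops to last place and the pipeline leads at 30–50%; at 10%
  random-valued noise the standard median is within ~1 dB of the pipeline
  on the phantom (its blur penalty is smallest where the phantom is
  smoothest).
* Benchmark problem sizes: 128×128 phantoms with 5 seeds per condition for
  the PSNR tables and 256×256 for detection scoring — chosen as the study
  scale for routine reproduction; all numbers are recomputed at run time by
  `scripts/acceptance.py`.

## Numerical choices

* Pixels are float64 in [0, 255] end-to-end; quantization (round-half-up)
  happens only at file write, so weighted averages lose no precision
  mid-pipeline. Reads rescale wider integer dtypes by dtype-max division
  and collapse color to BT.601 luminance.
* Reflect (symmetric) padding everywhere a window crosses the border —
  `np.pad(mode="symmetric")` and `scipy.ndimage` `mode="reflect"` agree on
  this convention; an `exclude_partial` border policy is available for the
  windowed statistics.
* Medians of even-sized samples are midpoint-interpolated (numpy
  convention), relevant only for the `exclude_partial` border policy and
  clean-subsample medians.
* Degenerate inputs: images smaller than 16×16 are rejected everywhere
  (5×5 windows plus borders need room); flat mROR maps put every pixel in
  cluster 4; an all-flagged window falls back to its plain median; NL-means
  with no valid candidate falls back to AFM.
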