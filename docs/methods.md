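# Methods

This note records the model behind `petstd`, the parameter choices that
matter, what the synthetic test bed does and does not probe, and the
numerical decisions taken where the design was genuinely open.

## The standardization model

Let `I` be a 3-D PET volume, either activity concentration (AC, Bq/mL) or
SUV.  The method assumes:

1. `min(I) ≈ 0` (air background around the body);
2. the histogram of a body-torso scan is bimodal — a background mode at ≈ 0
   and a body mode — so thresholding at the global mean isolates the body;
3. uptake in comparable *normal* tissue should be similar across subjects,
   while the extreme upper tail (hot lesions, physiologically avid organs)
   is arbitrarily variable between subjects and carries no cross-subject
   meaning;
4. the dominant technical corruption is approximately multiplicative per
   scan ("scanner gain").

Under these assumptions a per-image affine map anchored on histogram
landmarks below the chaotic tail cancels the gain exactly, and the only real
question is where the usable part of the histogram ends.  That is the role
of the upper percentile β: during calibration, δ_O(b) — the coefficient of
variation across the calibration cohort of the reference-organ mean after
rescaling each image by `[p_α(I), p_b(I)] → [0, s_max]` — is evaluated on a
grid of `b`, and β is the largest `b` attaining the minimum.  Below the
chaotic-tail onset δ_O is small and flat (the rescaling cancels the gain);
once `p_b` enters the tail it inherits the tail's cross-subject chaos and
δ_O rises sharply, so the "largest minimizer" rule places β directly below
the onset.

Within the β search only the two-landmark map λ can be used: the standard
median `s_m` is itself defined as the cohort mean of `λ(p_m(I))` at the
chosen β, so the three-landmark map does not exist yet.

The per-image transformation is `ψ(I) = λ⁻¹ · η(I)` with η the continuous
two-segment piecewise-linear map `[p_α, p_m] → [s_min, s_m]`,
`[p_m, p_β] → [s_m, s_max]`, both segments extrapolated (values above p_β
map beyond s_max; nothing is clipped).  η is strictly increasing, so ranks
are preserved exactly, and the landmark triple maps exactly onto
`λ⁻¹·{0, s_m, s_max}`.  The intermediate image η(I) is never materialized;
ψ is applied as one fused voxel-wise expression (identical result, half the
memory traffic).  A body mask of the input is computed internally; no organ
segmentation is needed at transformation time.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `b_low, b_high` | 90, 100 | percentile | search window for β |
| `b_step` | 0.1 | percentile | β is meaningful to one decimal; finer steps change nothing on realistic histograms |
| `s_max` (SUV) | 5.00 | — | preserves 0.01-SUV discriminability through the mapping |
| `s_max` (AC) | 50 000 | Bq/mL | same rationale on the AC scale |
| `sd_convention` | population | — | divide-by-n SDs everywhere (δ_O, trimming, CV); a two-image cohort then has a well-defined δ; `sample` is config-exposed |
| `tie_atol` | 1e-12 | — | deltas within this of the grid minimum count as tied; see below |
| t-test | Welch | — | scanner groups have unequal sizes/variances; Student available |

`p_α` is pinned to `min(I)` and not exposed: with a near-zero background the
lower percentile carries no information, and pinning makes λ a pure
multiplication, which the λ⁻¹ estimate relies on.  The per-image rescaling
factor is computed as `s_max / (p_β − p_α)`, which reduces to
`s_max / p_β` in the min-zero case and stays correct otherwise.

`p_β` (like `p_m`) is computed over the body mask rather than the full
volume: the two landmarks then share a support, and the background mode —
whose voxel count varies with field of view — cannot influence either.
Percentiles are linear-interpolation order statistics, continuous in the
percentile argument, which keeps δ_O(b) continuous on the search grid.

**Tie-breaking.** The selection rule is "the largest b whose δ is smallest".
On a cohort differing only by gain, δ is identically zero in exact
arithmetic, but float rounding leaves residuals of order 1e-16 that would
otherwise make the argmin arbitrary; deltas within `tie_atol = 1e-12`
(absolute) of the minimum are therefore treated as tied and the largest b is
returned.  The tolerance sits far below any δ difference of statistical
origin and far above rounding noise.

**Trimming fallback.** If the ±1-SD trim were to discard every rescaling
factor, the untrimmed mean is used.  (With population SDs the case is
actually unreachable — at least one deviation is always ≤ the SD — but the
guard keeps the sample-SD configuration total.)

## Iterative strategies

Chains such as `s-AC → SUV → s-SUV` are applied left to right; every
standardization step re-calibrates on the calibration cohort *as transformed
by the preceding steps*, so a second application estimates its parameters on
the standardized calibration set.  After one application all images share
identical landmark values by construction, so a second pass is close to a
common affine rescaling and changes CV_O very little — the test bed checks
this stays within 15% relative.

## The synthetic test bed

Clinical scans are not distributed with the package; the generator replaces
them with phantoms that reproduce the *statistical premises* of the model,
deliberately and only those:

* zero background, ellipsoidal body at level 1.0 (SUV; 5000 Bq/mL for AC);
* liver and spleen ellipsoids at levels 2.5/2.0 (12 000/10 000 Bq/mL),
  each multiplied by a per-subject factor ~ N(1, organ_cv) with
  organ_cv = 0.05 — realistic between-subject biological variability;
* hot foci on 2% of body voxels by default.  Each subject draws a personal
  peak `L ~ U(8, 25)` (SUV) and focus values `~ U(8, L)`: the per-subject
  peak is what makes upper-tail percentiles genuinely chaotic *across*
  subjects.  (Foci drawn iid from a common range would produce stable order
  statistics — tails that look wild within an image but agree between
  images — and the β search would have nothing to excise.)  Foci are placed
  outside liver and spleen so that reference-organ means stay "normal",
  mirroring the use of normal calibration scans;
* one multiplicative gain per scan ~ U(0.5, 2.0) — a 4× spread, of the
  order of the between-scan AC-range variability seen clinically;
* Gaussian noise with SD = 5% of the local mean, a crude stand-in for
  reconstruction noise (noise proportional to the signal keeps pure-gain
  cohorts exactly gain-equivariant and leaves the zero background at zero,
  consistent with assumption 1).

Repeat-scan pairs share anatomy, organ factors and focus values, perturbed
by a multiplicative biological jitter `U(1 ± 0.03)` per organ, with
independent gains and noise.

What the phantoms do **not** contain: anatomy (ellipsoids suffice for a
histogram-based method), scatter/attenuation/partial-volume physics, Poisson
counting statistics, non-multiplicative scanner effects, or background
activity.  Passing tests therefore demonstrate that the implementation
realizes the model and that the model removes multiplicative technical
variability down to the biological floor — they do not certify performance
on clinical data.

**Problem sizes.** Phantoms are 24×40×40 voxels at 4 mm spacing (≈ 10 800
body voxels, ≈ 830 liver / 240 spleen voxels); cohorts of 10–20 subjects.
These sizes put sampling error well below the effects being measured while
keeping the full experiment suite at a few seconds.

**β-recovery configuration.** The upper-percentile recovery experiment
silences biology and noise (organ_cv = 0, noise = 0, foci on 5% of body
voxels): every sub-onset δ_O(b) is then zero up to rounding and the tie rule
must pin β to the last grid point below the 95th-percentile onset (94.9 —
one grid step).  With noise enabled the sub-onset plateau is tie-broken by
sampling noise and the onset is identifiable only to within the plateau,
which is the expected behaviour, not a defect; the δ_O curve still rises
sharply past the onset (checked separately).

## Numerical and degenerate-input decisions

* Volumes are float64 in memory and float32 on disk (NIfTI); 0.01-SUV
  discriminability survives float32 with large margin.  Negative voxels are
  rejected at load (PET activity is non-negative); in-memory derived images
  (Z-scores) may be negative.
* Constant volumes, empty masks, and collapsed landmark orderings
  (`p_α < p_m < p_β` violated) raise `DegenerateInputError` rather than
  producing a silent degenerate mapping.
* ψ cannot produce negatives when `p_α = min(I)`; this is asserted, never
  clamped.
* `δ_O` requires cohorts of ≥ 2; a degenerate t-test (both groups constant)
  returns p = 1 for equal means and p = 0 otherwise.
* MD_O normalizes by the number of repeat *pairs*; a single (1, 3) pair
  gives 1.0 (100%).
* The M-method baseline reuses the landmark/transform machinery with fixed
  percentiles {0, 50, 99.8} and no inverse scaling — a reduced,
  faithful-in-spirit comparator, not a full reimplementation of the original
  multi-landmark MRI method.
* The Gaussian/Z-score baselines transform the whole image even though they
  are strictly meaningful only within the reference organ; evaluation reads
  means only within organs.

## Known limitations

* Ellipsoid phantoms cannot expose failure modes tied to real anatomy
  (e.g. body masks broken by arms-down acquisitions, bladder at the field
  edge).
* The method presumes a usable body mode in the histogram; volumes that are
  mostly background or mostly lesion violate assumption 2 and will fail the
  degeneracy checks rather than standardize meaningfully.
* λ⁻¹ restores average physical magnitude but individual standardized values
  are on the standard scale, not decay-chain-traceable activities.
* CLI strategy chains support one standardization step per scale file;
  multi-pass chains with re-calibration are a library-level operation
  (`run_strategy`) because they need the whole calibration cohort.
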