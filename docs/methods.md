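# Methods

This note documents the models and numerical choices behind `axialseg`,
what the synthetic phantoms do and do not emulate, and the limitations a
user should keep in mind.

## Data model

A slice is a row-major `float64` raster with intensities in [0, 1] and an
in-plane pixel spacing in millimetres (default 0.5 mm — a 512×512 matrix
over a ~25 cm field of view); masks are boolean rasters on the same grid.
Intensity scaling on read: integer rasters are min–max normalised per
slice; floating-point data already inside [0, 1] pass through unchanged;
a constant slice normalises to all zeros so that the failure surfaces
downstream as an explicit degenerate-input error rather than at the
reader. Per-slice min–max normalisation makes histogram thresholds
comparable across inputs; it is not a cross-slice intensity
standardisation.

## Rigid registration

*Model.* Rotation about the image centre plus in-plane translation, acting
in the sampling direction: `out(x) = moving(T(x))`. Translations are
stored in millimetres of the fixed grid. `compose` and `inverse` make the
group structure explicit; the inverse-composition residual over brain
pixels defines the target-registration error (TRE) used for evaluation.

*Similarity.* Normalised mutual information, `(H(A)+H(B))/H(A,B)`, over a
32×32 joint histogram on [0, 1]. NMI is the standard choice for
cross-contrast (T1 vs FLAIR) alignment, where intensities correspond
statistically but not linearly.

*Optimisation.* Powell's method (gradient-free, deterministic from a fixed
identity start) over (rotation°, tx mm, ty mm), through a 3-level pyramid
with block-mean downsampling factors 4/2/1. The parameter tolerance scales
with the pyramid factor (0.01 at full resolution); the coarsest level gets
the largest evaluation budget. There is no randomness anywhere in the
optimiser, so registration is exactly repeatable. The returned transform
is never allowed to score below the identity: if optimisation ends worse
than doing nothing (it has not in practice), the identity is returned
flagged as non-converged.

*Capture range.* The pyramid reliably recovers offsets well beyond the
|rotation| ≤ 10°, |translation| ≤ 15 px regime the evaluation draws from;
larger, "complex" misalignments are out of scope, mirroring how such cases
are usually excluded from single-slice studies.

## Skull stripping

*Operators.* Erosion and dilation implement the translated-origin set
definitions directly (`S_xy ⊆ B`, `S_xy ∩ B ≠ ∅`), with everything
outside the raster treated as background; opening/closing are the literal
compositions. A centred all-ones square window uses a separable
minimum/maximum filter fast path that is exactly equivalent. Hole filling
floods the background from the border with 4-connectivity (8-connected
foreground), so a one-pixel subdural gap cannot leak diagonally. Under
the shared translated-origin convention, erosion/dilation duality holds
without SE reflection, and opening/closing idempotence holds for the
symmetric elements the pipeline uses; both break at the raster border,
which is irrelevant here because the head never touches it.

*Loop.* With contour `C` (the XOR of the binarised slice and its
hole-filled version) and filled head `F_I`, iteration `k` computes
`erode(fill(dilate(C, S_k)), S_k)` restricted to `F_I`, with `S_k` the
square of half-width `initial_half_width + k` (sides 3, 5, 7, …). Growth
by half-width keeps the window odd and centred. The same window is used
for dilation and erosion, so once the ring closes the composition is a
closing — approximately area-preserving — and the filled interior is
recovered without inflating into the skull. The candidate is optionally
reduced to its largest 8-connected component (default on), a guard
against disconnected debris rather than part of the core method.

*Convergence.* `th = area_fraction × area(F_I)`, default
`area_fraction = 0.4`. Tying the threshold to the filled-head area makes
it scale-invariant; 0.4 sits well below the anatomical brain/head area
ratio (~0.7–0.85 on these phantoms) and well above the area of an
unclosed contour, so it cleanly discriminates "ring closed" from "ring
still broken". Non-convergence within `max_iterations` (default 25) is a
warning, not an exception, so batch runs complete. The per-iteration area
trace is always recorded — it is the algorithm's main diagnostic, and is
non-decreasing on annular contours (the algorithm's domain; arbitrary
blob masks can violate it because closing is not monotone in window
size).

*Input channel.* Stripping runs on the fixed T1 slice of the registered
pair by default (configurable to the warped FLAIR or their mean); the T1
channel carries the sharper skull/brain boundary.

## Multi-level Otsu (MTS)

The histogram (default 256 equal-width bins on [0, 1], brain-mask pixels
only) is a discrete pdf. The k-threshold criterion is the between-class
variance `Σ_c p_c (m_c − m_I)²`, equivalently minimising within-class
variance since the two sum to the total. The search is an exact
`O(k·J²)` dynamic program over prefix moments, not the common iterative
heuristic — exactness at this problem size is cheap and lets a brute-force
enumeration serve as an independent oracle. Ties, which occur on runs of
empty bins, are broken toward the lexicographically smallest threshold
tuple, with tie detection exact because all candidate values derive from
the same prefix sums. Thresholds are reported as bin upper edges on
[0, 1]; a strictly increasing affine remapping of the bin centres leaves
the selected bins unchanged.

Tumor = top class (`intensity ≥ T_k`, default `k = 8`), then a 3×3
average filter with a 0.5 majority vote (median option available) removes
isolated bright speckle without eroding the solid tumor; the mask is
confined to the brain mask by construction. Tumor-free slices yield an
empty or near-empty mask because the scattered top-class tail pixels fail
the majority vote.

## Overlap metrics

JSC, DSC, FPR and FNR all use the union as denominator, so
`JSC = 1 − FPR − FNR` is exact and `DSC = 2·JSC/(1+JSC)`. Naming follows
the conventional orientation (FPR counts pixels the algorithm added, FNR
pixels it missed); `paper_orientation=True` swaps the two numerators for
compatibility with sources that print the opposite convention. Summaries
report mean ± sample SD (n−1), rendered to two decimals in text and at
full precision in JSON.

## Synthetic phantoms

*What is modelled.* Concentric-ellipse anatomy: skull annulus (intensity
0.90 on T1), subdural/CSF gap (0.06), brain (0.52 with iid Gaussian
texture, SD 0.05), tumor disk (0.88 on T1 — deliberately within 0.05 of
the skull, reproducing the confound that motivates stripping; 0.95 on
FLAIR, where brain is 0.45 and CSF suppressed), optional necrotic core,
additive Gaussian noise (SD 0.015), and a smooth second-order polynomial
bias field (±4% of the brain mean) standing in for RF non-homogeneity.
Gap discontinuities are short arc breaks (4–8 px) totalling
`gap_break_fraction` of the gap: long enough that the initial 3×3 window
cannot bridge them — forcing the adaptive window growth the algorithm
exists for — yet short enough to close within a handful of iterations.
The FLAIR channel is warped by a known rigid offset before its noise is
added, so the true transform is exactly recoverable in principle.

*Default evaluation suite* (`default_suite(n=20, base_seed=1)`): gap
widths cycle 3, 2, 1, 4 px with the 1-px cases broken (five of twenty are
the thin/discontinuous hard case), every sixth phantom is tumor-free,
tumor radii are drawn from 18–40 px, geometry is jittered per phantom, and
rigid offsets are uniform within |rotation| ≤ 10°, |translation| ≤ 15 px —
the inclusion regime for single-slice rigid alignment. Phantom `i` is
fully determined by `base_seed + i`.

*What is not modelled — and therefore what passing tests do not show.*
No real cortical folding, partial-volume boundaries, Rician noise,
ghosting/motion artifacts, anatomical asymmetry, or heterogeneous tumor
phenotypes (necrosis/enhancement/edema are not separated). Scores on
these phantoms characterise the implementation's correctness and the
algorithm's mechanics (e.g. that broken gaps cost iterations, not
accuracy); they are synthetic analogs, not estimates of clinical-image
performance, where overlap scores will be lower.

## Numerical choices and degenerate inputs

- Linear interpolation for all warps; values clamped to [0, 1]; points
  sampled outside the moving raster read 0.
- Otsu binarisation of a constant slice, and MTS with fewer than k+1
  occupied bins, raise a degenerate-input error; an Otsu slice with no
  holes raises "no subdural space detected".
- An empty tumor top class returns an empty result with a warning.
- Metrics on two empty masks raise rather than return NaN.
- Mask I/O roundtrips exactly (PNG {0,255} or uint8 NIfTI); 8-bit
  grayscale roundtrips within one quantisation step.

## Evaluation problem sizes

The standard evaluation uses the 20-phantom suite at 512×512: all tests
plus the from-scratch evaluation script complete in a couple of minutes on
one CPU, with registration of a pair taking ~2–3 s and stripping well
under a second. Unit tests use 256 px phantoms with proportionally scaled
geometry.

## Known limitations

- Strictly 2-D and axial; no volume processing or series assembly.
- Rigid-only registration; scaling/shear/deformation out of scope.
- The subdural contour must exist: slices where brain tissue touches the
  skull around the entire circumference (gap width 0 everywhere) have no
  hole to extract and are rejected.
- `area_fraction` is a single global constant; pathologies that shrink
  the brain far below 40% of the head area would need it lowered.
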