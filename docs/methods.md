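# Methods

## Coordinate and binning conventions

All coordinates are 0-based, half-open (BED convention); bin `k` of a region
covers `[start + k·res, start + (k+1)·res)`. Regions are snapped onto the
resolution grid — start floored, end ceiled — and the snapped region is
always reported, never silently substituted.

Track binning uses a per-base average over the **full bin width**: each bin's
value is `Σ value·overlap / res`, with uncovered bases inside a partially
covered bin contributing zero. A bin is *missing* (NaN) only when no source
interval touches it at all. This choice keeps a BED peak file — converted to
a value-1 bedGraph per the unit-track convention — on a `[0, 1]`
coverage-fraction scale, and makes `read_track` and `bed_to_track` agree
exactly where both are defined. The one asymmetry is deliberate: bigWig and
bedGraph gaps are missing (the assay reports nothing there), while bases
outside BED intervals are zero (a peak file asserts absence elsewhere).
bigWig binning goes through pyBigWig's exact interval statistics; bedGraph
inputs must be sorted and non-overlapping and are rejected otherwise.

Contact matrices come from `.cool`/`.mcool` files (HDF5, symmetric-upper
pixel storage; balancing weights applied when stored and requested, with
NaN-weight bins propagating as fully missing rows/columns) or from dense
whitespace-delimited text, which must be square, symmetric within 1e-6
relative tolerance, and sized to the region. `.hic` input is not supported.

## Signal transforms

Unit scaling maps the region's non-missing values to `[0, 1]` by local
min–max, optionally after clamping (absolute or percentile bounds) and an
optional log transform. The log transform is `log(1 + x)`: it keeps zero
finite and preserves order, which is all the downstream outer product needs.
Local (per-region) scaling is intentional — it maximizes contrast for the
displayed window — with the known cost that a window without real peaks
shows amplified noise; the clamp option is the escape hatch.

**Degenerate case** (max == min): the scaled signal is all zeros, producing
a fully transparent layer. A flat track carries no *local* enrichment, so
transparency is more honest than the alternative (all ones, a saturated
square).

**Signed tracks** (compartment eigenvector): values are split at zero into a
positive and a negative branch; negatives are multiplied by −1 before any
transform. Opposite-sign bins enter each branch as literal zeros, so a pixel
whose two bins disagree in sign has zero product in *both* branch matrices —
this is what makes A-vs-B pixels transparent rather than half-colored. Each
branch is min–max scaled independently so a weak compartment side remains
visible next to a strong one.

**Distance normalization** replaces each entry with
`(obs + 1)/(expected + 1)`, where `expected(d)` is the mean of non-missing
entries at diagonal offset `|d|` (upper and lower triangles pooled; for the
symmetric matrices this is identical to per-signed-diagonal means). The
expected profile is computed within the displayed region, keeping the
operation self-contained; entirely-missing diagonals stay missing. The +1
pseudocounts keep sparse high-distance diagonals finite and bounded.

**Pipeline order**: when both distance normalization and unit scaling are
requested, scaling is applied to whatever matrix is being displayed, i.e.
after normalization. The display weight must be in `[0, 1]`, so scaling is
always the last matrix step before coloring.

## Color model

A layer's opacity is `α = round(m·c·k·255)` with overlay strength
`k ∈ [0, 1]`. Rounding is half-away-from-zero and happens exactly once per
quantity: once when a layer is composed, and once when blended channels are
emitted. Blending itself works in real ratios, and the mixed channel is
computed as `(Σ_b rgb_b·α_b) / total` — an exact integer numerator with a
single division — so the result is exactly invariant under layer reordering
and exactly reproducible by an integer-arithmetic reference implementation.

Color mixing is linear in the 0–255 integers, with no gamma correction:
fidelity to the stated arithmetic over perceptual uniformity. Pixels with
zero total alpha take the background color (white by default) with alpha 0;
flattened PNG output composites over white, while SVG output keeps one group
per layer with per-pixel `fill-opacity`, so layers remain editable. An
optional grayscale contact-map underlay is drawn beneath the color layers at
strength `1 − k`, operationalizing the overlay-strength knob as a dial
between "plain Hi-C" and "fully painted".

chromHMM mode assigns each bin to the state with the largest base-pair
overlap (ties to the state first seen in the file), builds one binary
membership track per selected state, and colors each resulting layer with
the segmentation's own `itemRgb`. Building per-state layers and then
blending is equivalent to per-bin color mixing for non-overlapping
segmentations, and additionally allows selecting a 2–3 state subset, which
in practice is the only way the mixed colors stay distinguishable.

## Overlap quantification

"High" signal is operationalized as the track's top quantile (default
q = 0.9) because no canonical threshold exists; assignment is exclusive — a
bin in the top quantile of two marks is ambiguous and dropped. Within a
class, pixels are the unordered pairs `(i, j)`, `i ≤ j`, of same-class bins,
the diagonal included, each pair counted once so the rank-sum test sees no
duplicated observations. The test is the two-sided Wilcoxon rank-sum
(Mann–Whitney U) with normal approximation and tie correction — ties are
pervasive in 8-bit alphas — with a Monte-Carlo permutation alternative for
small samples. Empty classes are reported with NaN statistics, not raised.

## Synthetic scenes

The generator emulates what the visualizer needs to be tested against: a
power-law distance decay `(|i−j|+1)^(−γ)` (γ = 1 by default), a plaid
same-state affinity pattern over a planted state vector, optional Gaussian
loop boosts, gamma-Poisson (negative-binomial-like) counts with dispersion
0.1 to mimic Hi-C overdispersion (dispersion 0 disables sampling entirely),
ChIP-like mark tracks at level 10 on their own domain vs 0.5 background with
half-normal noise (sd 0.2), an eigenvector-like signed track (+1 on A bins,
−1 on B, noise sd 0.05), and a BED9 segmentation of the planted states.

The default scene has 200 bins at 10 kb: three marks, each owning a 20-bin
domain split into two 10-bin blocks (giving the plaid), over a 140-bin
background. Domain size was fixed at exactly 10% of bins so that the default
top-decile classification threshold falls in the gap between background and
domain signal levels — planted-structure recovery is then a sharp all-or-
nothing check rather than a fuzzy one. Intra-state contacts are enriched
1.5× over depth 100, A–B contacts depleted to 0.3×, other combinations
intermediate; this makes the leading eigenvector of the correlation of the
distance-normalized map track the planted A-vs-B contrast, which the tests
verify with their own eigendecomposition.

What the scenes do **not** emulate: mappability and copy-number artifacts,
fragment-level resolution effects, TAD/loop-extrusion stripe structure,
chromosome-wide expected profiles, or inter-chromosomal contacts. Passing
tests show the arithmetic and the pipeline are correct under controlled
structure, not that any particular biological dataset will separate as
cleanly.

## Numerical and interface choices

- Missing data is NaN throughout; a missing factor makes a missing product;
  missing never participates in min/max or expected values; missing pixels
  render transparent.
- PNG output carries no timestamps or metadata, so identical specs give
  byte-identical files; the CLI builds the same spec objects the API uses,
  making CLI and API output identical by construction.
- The cooler reader/writer implements the public cooler HDF5 schema
  (format version 3, fixed bins, symmetric-upper pixels) directly on h5py;
  multi-resolution files are addressed through the `resolutions/<res>`
  group.
- Problem sizes in the test suite (≤ 32-bin matrices for oracle checks,
  the 200-bin scene for end-to-end runs, 3 seeds for the stochastic
  recovery checks) were chosen as the smallest sizes at which the checked
  properties are non-trivial.

## Known limitations

- Only cis (single-region, square) matrices; no trans views or URL
  streaming.
- Balanced weights are used when stored; the package does not compute
  matrix balancing itself.
- The eigenvector is an input track; compartment calling itself is out of
  scope.
- SVG files draw one rectangle per opaque pixel and get large for big
  regions; PNG is the practical format beyond a few hundred bins.
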