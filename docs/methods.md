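# Methods

## Colour representation and difference

All quantitative comparisons happen in CIE 1976 L\*a\*b\*. 8-bit sRGB
triplets are normalised by 255, inverse-companded with the piecewise sRGB
gamma (IEC 61966-2-1), mapped through the linear RGB→XYZ matrix for D65
primaries, and converted to L\*a\*b\* against the reference white
[0.9504, 1.0000, 1.0888] (D65 tristimulus values normalised for relative
luminance). The white point and the CIEDE2000 parametric factors
k_L, k_C, k_H (all 1 under reference conditions) live in
`ColorConversionConfig`; they are carried for completeness, not varied by
any workflow.

The CIEDE2000 implementation follows the Sharma–Wu–Dalal reference
equations, including the a\*-axis rescaling G, the S_L/S_C/S_H weights, the
hue-rotation term R_T and the published clarifications for degenerate
chroma: when C′₁C′₂ = 0 the hue difference is set to zero and the mean hue
is the plain sum h′₁ + h′₂. Hue arithmetic is done in degrees. The scalar
and batch paths share one vectorised core, so they agree bit-for-bit; the
bundled 34-pair verification dataset is reproduced to within 1e-4 and
agreement with an independent implementation (scikit-image) is better than
1e-9 on random Lab pairs.

Lab→sRGB back-conversion (used only to express k-means centroids and
gamut-project jittered synthetic colours) inverts the same chain and clips
to the gamut; clipping is adequate because all pipeline inputs originate as
in-gamut 8-bit sRGB.

## Calibration and segmentation

White-tile calibration is a per-channel linear gain
g_c = reference_c / mean_c(patch), applied multiplicatively with half-up
rounding and clipping to [0, 255]. The reference white defaults to
(255, 255, 255) and is configurable to the nominal value of the physical
white patch. A linear gain is the minimal model consistent with a single
white reference; it cannot correct channel crosstalk or nonlinearity.

Background segmentation assumes samples on a near-black field: a pixel is
background iff max(r, g, b) ≤ τ_black (default 30 of 255, safely above
sensor noise on a black backing while keeping very dark sample tissue).
Optional 8-connected component filtering (minimum area in pixels, default
off) removes speckle. Raising τ_black can only remove foreground — the rule
is monotone. Sibling extraction crops to the foreground bounding box
(half-open, row-major, origin top-left) and blanks in-box background to
black so downstream colour tables never see it.

## Region growing

The unique-colour table is exact: hexadecimal codes of all foreground
pixels with their counts. Region growing orders colours by count
(descending; ties broken by ascending hex string so the procedure is a
total order and runs are byte-identical), then repeatedly:

1. the most frequent unassigned colour becomes a seed;
2. ΔE₀₀ from the seed to every other unassigned colour is computed;
3. all colours with ΔE₀₀ ≤ τ are absorbed — their counts accumulate onto
   the seed and they leave the pool;
4. repeat until the pool is empty.

The threshold comparison is inclusive (≤ τ). Absorption is strictly
pairwise to the seed: a colour within τ of an *absorbed* colour but beyond
τ of the seed is not merged (no transitive chaining). This is a deliberate
property of the procedure — chaining would let bins crawl across colour
space — and the test suite pins it with a three-colour configuration where
chaining would change the answer. Output percentages are accumulated counts
over the *foreground* pixel total (background is excluded upstream, so the
foreground is the natural base; percentages pre-filter sum to 100 exactly
up to float rounding).

The abundance filter keeps entries strictly above 0.1 % and deliberately
does not renormalise, so cumulative-percentage summaries of the retained
colours remain interpretable against the whole image.

The production implementation vectorises step 2; a literal pool-based
transcription of the loop (scalar ΔE₀₀, explicit list surgery) is kept in
`synthetic_fixtures` as an oracle, and the two are verified identical —
colours, order, percentages, assignments — over randomised tables at
thresholds 1–3.

Recolouring replaces every foreground pixel by its stored UC→seed
assignment rather than re-testing pixels against seeds in sequence; this is
equivalent for all colours seen during growing and guarantees raster/table
consistency. It follows that every recoloured pixel is within τ of its
original colour and that the output palette is a subset of the input
colours.

## K-means baseline

The comparison baseline clusters UC colours in Lab, weighting each colour
by its pixel count. Initial centroids are drawn count-weighted without
replacement under a caller-supplied seed. Two update rules are provided:
Hartigan–Wong (greedy single-point transfers with the W/(W±w) size
correction on the weighted within-cluster sum of squares; the default, to
match the classical statistical practice for this task) and Lloyd
(weighted mean / reassign; also used for the closed-form cases K = 1 and
K = n). Empty clusters are re-seeded from the farthest point.
Non-convergence within `max_iter` sets a flag rather than raising. Final
centroids are weighted Lab means back-converted to the nearest in-gamut
RGB — which is exactly the weakness the region grower avoids: centroid
colours need not exist in the image. Centroid recolouring assigns each
pixel to its ΔE₀₀-nearest centroid (ties → lowest index).

## Weighted profile distance and clustering

For PUC tables A and B the transport matrix is
w[i][j] = ΔE₀₀(cᵢ, cⱼ) · |pᵢ − pⱼ| with abundances in percentage points
and the absolute difference (a signed product could be negative, which a
distance cannot be). The directed distance is the sum of row minima; the
reported distance averages the two directions, the minimal convention that
yields a well-defined symmetric matrix (both directed values remain
available). The published weighting has a degeneracy worth knowing: two
profiles whose colours differ arbitrarily but whose abundance lists match
exactly are at distance zero, because |Δp| = 0 nullifies the colour term.
This is implemented as published; an alternative weighting
ΔE₀₀ · (ΔE₀₀ + |Δp|) that removes the degeneracy is available behind an
explicit `variant` flag, off by default. The triangle inequality is not
guaranteed by the min-sum construction and is not asserted anywhere.

Distances are computed on abundance-filtered tables (> 0.1 %) by default,
matching the summarisation pipeline; `min_pct=None` compares full tables.
Clustering is standard agglomerative linkage (scipy) on the precomputed
matrix; the default linkage is average (UPGMA) — a choice recorded in every
output's metadata, since different linkages give different dendrogram
heights. Dendrograms export as Newick with the ultrametric convention that
a node sits at half its merge height, so two leaves merged at height h are
each h/2 from their ancestor.

## Synthetic data

The generators emulate the relevant structure of scanned biological
samples without pretending to photorealism:

- **Patch mosaics** — exact, known colour/count composition on a black
  field; the returned UC table is construction ground truth.
- **Gradients** — bands interpolated linearly in Lab (default), giving
  near-uniform consecutive ΔE₀₀ gaps so tests can place colour chains
  precisely around a threshold; this is the structure where JPEG artefacts
  and region-growing non-transitivity are exercised.
- **Profile families** — replicate PUC tables around a base colour: fixed
  Lab offsets define a palette, N(0, σ) Lab jitter (clamped to the gamut by
  nearest in-gamut projection) and mild multiplicative abundance jitter
  emulate biological replicates. σ = 0 yields identical profiles.
  Abundance jitter matters: under the published weighting, replicates with
  *exactly* equal abundances would be mutually at distance zero.

What passing tests on these fixtures do **not** show: performance or
accuracy on real scanner output with sensor noise, demosaicing structure,
shadows at the sample boundary, or UC counts in the 10⁴–10⁵ range. The
algorithms are size-independent, but runtime on full scans is dominated by
the number of unique colours, and the synthetic suite is deliberately small
(gradients of 48–64 bands, mosaics of 60 colours, random tables up to 500
colours — sizes chosen so the whole verification runs comfortably on a
laptop while still covering every code path).

## Numerical choices

- Count ties in seed selection and percentage ties in table ordering break
  by ascending hex string; determinism is required for oracle equivalence
  and reproducible outputs.
- "Identical" in format comparison is exact integer RGB equality, not
  ΔE₀₀ = 0, avoiding float ties; "different" is ΔE₀₀ > 2 by default, the
  conventional at-a-glance perceptibility bound. JPEG export quality
  defaults to 90 and is recorded in output metadata.
- The format-comparison mask parameter leaves open whether background
  pixels are included (both analyses are legitimate; whole-image is the
  default).
- The "colour complexity" of an image is reported both as the raw UC count
  and as UC count normalised by foreground pixels, since either reading is
  defensible; consumers pick one explicitly.
- Half-up rounding in calibration (`floor(x + 0.5)`) rather than banker's
  rounding, so the scalar oracle is trivial to state.

## Limitations

- Single-illuminant, single-white-patch linear calibration only; no ICC
  profiles, no wide-gamut or >8-bit inputs.
- The white patch location is user-supplied; no automatic chart detection.
- The profile distance is not a metric (no triangle inequality) and
  inherits the equal-abundance degeneracy of its published definition.
- Hierarchical clustering heights depend on the (configurable) linkage;
  no linkage is singled out as correct.
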