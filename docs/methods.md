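# Methods

## Scope and conventions

`neband` quantifies nuclear-envelope (NE) recruitment of proteins in
2D multi-channel fluorescence fields of differentiating myoblasts.
Throughout the package: coordinates are 0-based (row, col); label maps
are integers with 0 = background; all distances are exact Euclidean
distances between pixel centres (distance transforms, never iterative
dilation with a structuring element, so there is no discretization
ambiguity and the geometry can be checked against a brute-force
per-pixel rule); intensities are raw linear camera units.

## Synthetic fields

No public raw images exist for this kind of experiment, so the package
ships a generator whose ground truth makes every stage testable.

A field contains `n_nuclei` disc nuclei with radii drawn uniformly from
`nucleus_radius_px` (default 9–14 px at 0.102 µm/px, i.e. ~1–1.4 µm
radius — deliberately small so many nuclei fit in a 256×256 test field),
placed by rejection sampling with a minimum gap (6 px) and a border
margin so measurement bands are not truncated.  A fraction
`myotube_fraction` of nuclei is arranged in chains of 2–4 inside capsule
(thickened-segment) regions that carry the cytoplasmic MHC-like marker;
capsules are the simplest shape that reproduces "syncytium containing at
least two nuclei", and mononucleated nuclei are placed outside every
capsule.  Marker (MyoG-like) labels are Bernoulli draws with
`marker_positive_fraction`.

Channel expectations are piecewise-constant mixtures:

* `dapi`: `dapi_level` on the nucleus disc;
* `marker_nuclear`: `marker_level` (positive) or `marker_negative_level`
  (negative) on the disc;
* `marker_cyto`: `mhc_level` on the capsules;
* `protein`: `cytoplasm_level` outside cells' nuclei, `nucleoplasm_level`
  inside, and `E × cytoplasm_level` on the **true NE ring** — the annulus
  of width `ne_ring_width_px` (default 4 px) straddling the disc
  boundary.  `E = ne_enrichment` is therefore exactly the NE/cytoplasm
  intensity ratio the morphometry should recover.  The ring is defined
  independently of any measurement band so ground truth is never
  circular with the measurement geometry.  Optional perinuclear Golgi:
  a `belt` annulus 2–6 px outside the nucleus at `golgi_level`, or
  `dispersed` puncta.

Image formation: Gaussian blur with `psf_sigma_px` (default 0.8 px —
the in-plane sigma of a high-NA widefield PSF sampled at ~0.1 µm/px),
then shot noise `Poisson(photon_scale·λ)/photon_scale` (so the
expectation is preserved and variance is `λ/photon_scale`;
`photon_scale = inf` disables it), then additive Gaussian read noise,
then clipping at zero as camera data are.  `background_level` defaults
to 0 (offset-subtracted data); a constant or linear-gradient background
can be enabled to probe the robustness of ratio measures.  Identical
(params, seed) reproduce bit-identical fields.

What the generator does **not** emulate: nuclear texture and
ellipticity, spatially varying PSFs, chromatic shift, out-of-focus haze,
autofluorescence, cell-to-cell intensity variability within a group, and
segmentation-hostile clumping.  Passing tests therefore demonstrate the
correctness of the measurement code and the statistical conventions, not
robustness to every real-data pathology.

## Segmentation and gating

Nuclei are segmented from the DNA channel by Gaussian smoothing (sigma
1 px), a global threshold (Otsu default; Li, mean or absolute
available), hole filling, a minimum-area filter, and optional seeded
watershed on the distance transform to split touching blobs.
Border-touching nuclei are flagged and excluded from band summaries —
their bands would be truncated and bias the means.

Nuclear-marker gating declares a nucleus positive when its mean marker
intensity is at or above a threshold.  The default `"otsu-of-means"`
rule applies Otsu's criterion to the per-field vector of nuclear means
in **exact discrete form** (between-class variance evaluated at every
split of the sorted sample, threshold at the midpoint of the optimal
split).  Histogram-binned Otsu is wrong at this sample size: with a
dozen values the whole negative cluster can fall into one 256-bin
histogram bin, and the returned bin centre then splits the cluster
itself.  The exact form is also strictly scale-invariant.  Cytoplasmic
(MHC) gating binarizes the marker (Otsu) and requires a minimum overlap
fraction (default 0.5) of the nucleus's 10-px outward band with the
mask.

`expand_labels_nearest` grows labels into the background by the exact
nearest-object rule; pixels equidistant to two objects go to the smaller
label id, which is deterministic and order-independent.

## Band geometry and measurement

Outer band k of width w with shift s around nucleus i is the set of
background pixels with nearest object i and distance in
`(s+(k−1)w, s+k·w]`.  Defaults: three 10-px bands NE/Peri/Cyto;
`shifted_outer` uses s = 5 px and names Peri/Cyto1/Cyto2 (Golgi-belt
readout); `inner` mode takes the NE object as nucleus minus its
Euclidean erosion by the NE width (4 px for lamins, 10 px for
Nesprin-1) and the erosion as the nucleoplasm.  NE-band measurement of
any other stain (e.g. α-tubulin at the NE) is the same `measure_bands`
call with the NE band — there is no separate code path.

Contested pixels between adjacent nuclei are assigned by the
nearest-object rule (keeping band areas maximal, matching
object-expansion semantics); `contested="exclude"` drops them instead.
Band means are raw arithmetic means — no background subtraction by
default, since "mean intensity" denotes raw units; a constant
subtraction is available.  Empty bands are reported absent, never NaN;
a nucleus whose erosion is empty is flagged "no nucleoplasm" and
excluded from ratios with a warning.

The half-in/half-out "straddle" variant of the outer bands is **not**
implemented; users wanting a straddled readout can combine an inner and
an outer band of half width.

**Recovering the enrichment factor.**  The rendered NE ring is ~4 px
wide, so a 10-px NE band mixes ring and plain cytoplasm and its NE/Cyto
ratio understates E (that dilution is a property of wide-band readouts,
not an error).  Recovery tests and the acceptance script therefore
measure with 1-px bands, take the first band (0,1] — which sits inside
the outer half of the ring — as NE and the band (7,8] — beyond the
blurred ring's reach — as the cytoplasm reference.  With the default
0.8-px blur this recovers E within ~3–10% across E ∈ {1,2,4,8}.

## Colocalization

Pearson's r is the sample correlation over the mask (undefined on a
constant channel: reported absent with a warning).  Manders M1 is the
fraction of channel-1 intensity on pixels where channel 2 exceeds its
threshold, M2 symmetrically; the default threshold rule is "zero"
(permissive, appropriate after background subtraction and consistent
with near-1 coefficients for co-distributed stains), with Otsu and
absolute alternatives.  Coefficients are computed within a cell/ROI
mask, not the whole field.  Costes randomization and object-based
colocalization are out of scope.

## Fusion index and fibre spacing

Connected components (8-connectivity, configurable) of the binarized
MHC mask are candidate myotubes; a nucleus belongs to the component
containing its rounded centroid (an overlap-fraction rule is available).
Components with ≥ 2 nuclei are myotubes; the index is
100 × (their nuclei) / (all nuclei).  Border-truncated myotubes are
included.  Fibre length is polyline arc length × pixel size; nucleus
spacings are arc-length gaps between consecutive centroid projections
onto the polyline (fibres curve, so arc length rather than chord), via
`shapely` projection.

## Statistics

Aggregation is two-stage and unweighted: nuclei → field mean → replicate
mean, fields weighted equally regardless of nucleus counts; replicate
means are the units for every test.  Designs: two groups → two-sided
Student's t-test (equal variances assumed by default because plain
"t-test" conventionally means the pooled form; Welch by flag); three or
more groups → one-way ANOVA F-test plus Newman–Keuls stepdown; two
crossed factors → two-way ANOVA with interaction (type-II sums of
squares) and Bonferroni-corrected comparisons of the first factor within
each level of the second, using the pooled residual MSE.

The Newman–Keuls stepdown orders the group means, tests each span-p
range against the studentized-range distribution at that span
(`scipy.stats.studentized_range`, numerical evaluation rather than
hard-coded tables), and blocks all comparisons nested inside a
non-significant range.  Unbalanced designs use the harmonic-mean n with
a warning.  Degenerate zero-variance data yield p = 1 when means are
equal (with a structured warning) so synthetic edge cases keep pipelines
running.

## Numerical and design choices

* Exact distance transforms everywhere; ties to the smaller label.
* Exact discrete Otsu for the gating-by-means rule (see above);
  histogram Otsu elsewhere (whole-image thresholds).
* Poisson/read-noise clipping at zero slightly biases means where the
  expectation is within ~2 SD of zero; convergence tests use fields
  whose expectation is everywhere well above zero.
* Problem sizes in tests and the acceptance script (256×256 fields,
  ~12 nuclei, 20 fields per condition, 1000-rep Monte-Carlo for the
  familywise-error check) were chosen as the smallest sizes at which the
  sampling error of each check is far below its tolerance.

## Known limitations

* 2D single-plane only; no time series, 3D stacks or realistic PSFs.
* Nuclei are rendered as discs; segmentation accuracy claims are for
  well-separated convex nuclei.
* The Manders thresholding convention of any given published figure is
  rarely stated; results depend on that choice and both permissive and
  Otsu rules are provided rather than a claim about which was used.
* Newman–Keuls controls the familywise error under the global null but
  is known not to control it under some partial-null configurations;
  it is provided because it is the conventional post-test for this kind
  of data, not as a recommendation.
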