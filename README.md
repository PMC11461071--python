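# neband

Quantification of nuclear-envelope (NE) protein recruitment in
fluorescence images of differentiating skeletal myoblasts.

During myogenic differentiation the centrosome is attenuated and
microtubule-organizing-centre proteins (pericentrin, AKAP6, Kif5b) are
recruited to the nuclear envelope, together with LINC-complex components
(Nesprin-1, lamins).  The standard readout for this recruitment is
image-based: segment nuclei from the DNA stain, keep only cells positive
for a differentiation marker (nuclear MyoG or cytoplasmic MHC), build
fixed-width concentric bands around or just inside each nucleus, and
compare mean stain intensities between bands.  `neband` implements that
pipeline end to end, together with the companion measurements used in
such studies (colocalization coefficients, myotube fusion index, fibre
internuclear spacing) and the replicate-level statistics, plus a
synthetic-image generator with per-nucleus ground truth so that every
stage can be validated without microscope data.

## What is computed

**Band morphometry.** For nucleus objects with label map `L`, band *k*
of width *w* (optionally shifted outward by *s*) is the set of
background pixels whose nearest object is that nucleus and whose
Euclidean distance *d* to it satisfies `s + (k−1)·w < d ≤ s + k·w`
(exact distance transform; contested pixels go to the nearest nucleus,
ties to the smaller label).  Defaults follow common practice: three
10-px outward bands **NE / Peri / Cyto**; a 5-px outward shift yielding
**Peri / Cyto1 / Cyto2** for Golgi readouts; and an *inner* mode where
the NE object is the nucleus minus its Euclidean erosion (4 px for
lamins, 10 px for Nesprin-1) and the erosion is the nucleoplasm.
Per-nucleus mean intensities give the enrichment ratios NE/Cyto and
NE/nucleoplasm.

**Colocalization.** Pearson's r over a cell mask and Manders
coefficients `M1 = Σ₁(ch1 · [ch2 > t2]) / Σ ch1` (M2 symmetric), with
zero/Otsu/absolute threshold rules.

**Fusion index.** `100 × (nuclei in MHC⁺ components containing ≥ 2
nuclei) / (all nuclei)`, with nucleus-to-component membership by
centroid containment.

**Statistics.** Two-stage unweighted aggregation (nuclei → field mean →
biological-replicate mean; replicates are the units), then Student's
t-test (two groups), one-way ANOVA with a Newman–Keuls stepdown
(studentized-range distribution evaluated numerically), or two-way ANOVA
with Bonferroni-corrected cellwise comparisons.  Stars: \*p < 0.05,
\*\*p < 0.01, \*\*\*p < 0.001, n.s. otherwise.

## Worked example

Simulate a field whose NE ring is rendered at 4× the cytoplasm level,
then run the full pipeline (segment DAPI → gate MyoG-positive nuclei →
measure bands → summarise the field):

```python
from neband import (SimulationParams, sample_layout, render_field,
                    BandSpec, quantify_field, band_profile_summary)

params = SimulationParams(ne_enrichment=4.0, photon_scale=100.0, seed=7)
truth = sample_layout(params)
field = render_field(truth, params)

spec = BandSpec()                 # outer mode: NE / Peri / Cyto, 10 px each
quant = quantify_field(field, spec=spec, gate="nuclear")
summary = band_profile_summary(
    quant.per_nucleus[["NE", "Peri", "Cyto", "NE_over_Cyto"]],
    spec.band_names,
    include=quant.per_nucleus["included"],
)
print(summary.round(3))
```

```
NE               147.633
Peri              99.958
Cyto             100.025
NE_over_Cyto       1.476
NE_minus_Cyto     47.608
n_nuclei           8.000
```

The 8 MyoG-positive, non-border nuclei show elevated intensity in the
10-px NE band (147.6) over a flat Peri/Cyto background (~100).  The raw
NE/Cyto ratio of a wide band understates the true ring enrichment
because the rendered NE ring is only 4 px wide: to *recover* the
enrichment factor, measure with 1-px bands and a distant cytoplasm
reference (`BandSpec(band_width_px=1, n_bands=8, ...)`), which returns
≈ 3.9 for a true factor of 4 (see the acceptance script).

A command-line interface mirrors the library
(`neband simulate | segment | measure | coloc | fusion | report`).

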