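# Methods

This note documents the models, parameter defaults and numerical choices
behind each stage of the pipeline, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the underlying
laboratory protocol leaves the computation under-specified.

## Movement index

The contractility statistic is the mean intensity of differential images.
For a grayscale sequence with bit depth B, frame pairs (i, i+lag) are
differenced as per-pixel absolute values, optionally floored (pixels at or
below `noise_floor` zeroed), averaged over all pixels, and divided by
2^B − 1 so 8- and 16-bit recordings are comparable; the index is the mean
over pairs. The normalization is our choice — the original readout is in
arbitrary units, so only relative comparisons (across voltages, across
culture conditions) are meaningful, and the metadata records the
convention used.

Design choices:

* **Absolute difference.** The physical signal is intensity change caused
  by moving scatterers; its sign carries no motion information, and the
  absolute value makes the operator symmetric in contraction/relaxation.
* **Pairing lag.** Consecutive frames (lag 1) by default, matching
  differencing of a contraction image against the successive relaxation
  image. When the pacing frequency f and frame rate r are known,
  `round(r / 2f)` frames — half a period — maximizes contrast (5 frames at
  10 fps and 1 Hz). Whether the original protocol thresholded differential
  images is not documented; the default `noise_floor` is 0 (raw
  averaging), and any nonzero floor is an explicit deviation recorded in
  the result object.
* **Evaluation window.** Recordings are typically scored over the final
  minutes of a stimulation session; the module takes an explicit
  `frame_range` rather than inferring one.
* The pseudo-color overlay (pixelwise maximum of differential images
  through a matplotlib colormap over the bright-field background) is
  presentational only; nothing downstream consumes it.

Per condition, three to five imaged fields are summarized as mean ± SE
(sample SD over √n).

## Segmentation

Myotubes: Gaussian smoothing (σ = 2 px) → global Otsu threshold → hole
filling → removal of objects under `min_myotube_area` (500 px at the
generator's scale) → connected components. The original delineation was
manual/Fiji; an automatic deterministic rule is used here for
reproducibility, and no claim of pixel-level equivalence is made.
Touching myotubes are *not* split: myotubes are elongated and sparse, and
any merge is visible as a single label (documented limitation). Edge
objects are kept, since whole fields are counted.

Nuclei: Otsu on the smoothed DAPI channel (σ = 1 px), then a
distance-transform watershed seeded at distance maxima ≥ 5 px apart to
split touching nuclei; objects under `min_nucleus_area` (30 px) are
dropped.

Nucleus–myotube membership uses the centroid rule: a nucleus belongs to
the myotube label under its centroid, and centroids on background yield
parent 0. Those parent-0 nuclei are the feeder-fibroblast population —
DAPI-positive but outside the α-actinin mask — and are excluded from all
per-myotube denominators. The centroid rule was chosen over fractional
overlap because it is simple, deterministic and unambiguous for nuclei
that straddle a boundary.

## Localization scoring

The positivity rule for nuclei is not specified by the source protocol;
we use a background-referenced robust threshold: a nucleus is
marker-positive iff its *median* marker intensity exceeds
mean + k·SD of the background (all pixels outside myotubes and nuclei),
k = 3 by default. The rule is scale-free and robust to a few bright
pixels; an explicit threshold can be passed when a field has no
background (e.g. confluent cultures).

The marker-positive area inside each myotube is found by Otsu restricted
to that myotube's pixels, so dim and bright myotubes are scored
comparably. The partition is defined by subtraction —
cytoplasmic = total − nuclear positive area — which makes the
conservation identity exact by construction; tests assert it per myotube.

Accumulation calls use a dual criterion (both unstated in the source
protocol, hence documented defaults): largest connected cytoplasmic
marker component ≥ `min_blob_area` (50 px) AND cytoplasmic positive area
≥ `min_cyto_fraction` (2%) of the myotube area. The blob gate rejects
scattered speckle that can dominate the area fraction; the fraction gate
rejects a single blob in a very large myotube.

Myotubes with zero detected nuclei have an undefined positive-nuclei
ratio; they are logged and excluded from ratio averages but still count
in accumulation denominators. Condition summaries pool flagged/total
myotubes; SE is computed across independent replicates when replicate
ids are provided (matching experiments repeated from the same cell
stocks), otherwise across fields, and the choice is recorded in the
summary (`se_unit`).

## Puncta

Granule detection: white top-hat with a disk of radius 5 px (removes any
structure wider than the element, including flat offsets — hence the
offset-invariance property), Otsu restricted to within-myotube pixels,
then a size gate of 4–400 px chosen to match small granule-like objects
at the generator's scale. Whether the original "p62 area" was puncta-only
or all thresholded signal is ambiguous; the module defaults to
puncta-only and offers `mode="total"` (no top-hat, no size gate), with
the mode labelled in the output. Each punctum is attributed to the
myotube under its centroid; the readout is puncta area / myotube area.

## Expression

2^−ΔCt with replicate Cts averaged arithmetically first (standard
practice; no outlier handling by default). Fold changes divide each
sample's relative expression by the mean relative expression of the basal
group per gene, so the basal mean fold is identically 1; this equals
2^−ΔΔCt and is how contraction-induced myokine induction (e.g. CXCL1
normalized to RPLP0) is reported. Samples lacking the reference gene and
non-finite Cts are excluded with warnings. Primer-efficiency correction
(Pfaffl) is out of scope.

## Statistics

Two groups: equal-variance Student's t (deliberately not Welch, matching
the source convention). More groups: one-way ANOVA with Tukey's all-pairs
or Dunnett's many-to-one procedure (scipy implementations); α = 0.05 with
stars * p<0.05, ** p<0.01. For two groups the ANOVA F equals t², asserted
to 1e-10 in tests; null calibration of both post-hoc procedures is checked
by simulation (1000 null datasets, family-wise error within binomial
tolerance of α). The statistical unit (field vs replicate) is ambiguous in
parts of the source reporting; the pipeline takes the unit explicitly
(per-field values feed `compare_groups`, or a replicate column switches
the SE unit) and refuses to guess.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:

* **Fields** (512×512 px, 8-bit): 8 myotubes per field (the imaged fields
  contained 6–12), rendered as elongated rounded ribbons (length 120–200
  px, width 16–26 px, random orientation) — the round cylinder-like
  morphology of feeder-supported myotubes — with 4–10 nuclei each and 30
  feeder nuclei outside the structural mask. Feeder nuclei carry nuclear
  marker signal (fibroblasts show nuclear TDP-43 too), which exercises
  the feeder-exclusion path.
* **Marker partition**: `marker_nuclear_fraction` sets the nuclear share
  of the marker-positive area per myotube; by default it also sets the
  fraction of marker-positive nuclei, coupling the two the way
  nucleocytoplasmic translocation does (more cytoplasmic mass ⇒ fewer
  positive nuclei), which is what the joint-pattern tests rely on.
  Cytoplasmic positive signal is scattered pixel-wise so it does not form
  blobs; accumulation-positive myotubes (exactly
  `round-half-away(fraction × n)` of them, rounding documented) receive
  1–3 bright blobs of radius 5–7 px placed via the distance transform of
  the nucleus-free cytoplasm, guaranteeing a detectable object.
* **Puncta fields**: diffuse in-myotube marker plus puncta of radius
  2.5 px placed until the requested total area fraction is met (default
  test condition 3%).
* **Videos** (256×256 px, 10 fps, 20 frames): ribbons whose displacement
  is amplitude·cos(2πft) along the axis plus a 15% shear, all moving
  objects in phase (field stimulation synchronizes contraction); 1 Hz and
  amplitude 3 px by default. `moving_area_fraction` reproduces partially
  contracting fields. The bright-field texture is a smooth random field —
  a stand-in, since real bright-field texture statistics are not modelled.
* **Ct tables**: reference gene around Ct 20, target Ct = reference +
  true ΔCt, Gaussian cycle noise.
* Noise is additive Gaussian clipped to the bit range (optional Poisson
  shot noise); intensity levels are idealized steps, not a camera model.

What passing tests therefore show: the measurement chain recovers
geometry, counts, area partitions and fractions it was asked to recover,
under controlled noise, deterministically. What they do not show:
performance on real microscopy (uneven illumination, out-of-focus light,
staining variability, true bright-field texture), for which the automatic
thresholds are a reproducible surrogate rather than a validated
equivalent of expert manual delineation.

## Numerical choices and degenerate inputs

* All generators are deterministic: same spec + seed ⇒ bit-identical
  output; the pipeline derives per-field seeds from the run seed via
  `SeedSequence` and a full run is byte-identical under a fixed seed (the
  manifest records version, seed, resolved config and output hashes).
* Flat channels segment to empty maps (not errors); flat within-myotube
  marker yields zero positive area; Otsu is never applied to constant
  data.
* Object placement uses bounded rejection sampling and raises a
  `GeometryError` naming the failing object when the field cannot
  accommodate the request.
* Problem sizes in tests and the acceptance script (5 fields × 8–10
  myotubes per condition, 10-frame videos, 1000-rep null simulations)
  were chosen so the whole suite validates every stage in about two
  minutes on one CPU.

## Known limitations

Absolute movement-index values are not comparable to any published
arbitrary-unit values; only contrasts are. Touching myotubes merge.
Headline figures from patient-derived cultures are not reproducible from
the shipped code because no raw images or per-field tables are public —
the acceptance suite is therefore property-based (exact identities,
ground-truth recovery, calibration) rather than value-matching.
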