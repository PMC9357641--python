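# Methods

`mpmbreast` implements a label-free multiphoton-excitation-microscopy (MPM)
analysis pipeline for breast tissue: synthetic phantom generation with
ground truth, per-image standardization, 64-tile cropping, blank-tile
exclusion, a trainable tile-level cancer classifier, and per-image
"malignant probability" aggregation with ROC thresholding and agreement
statistics. This note records the models, the defaults and their
rationale, and what the synthetic experiments do and do not demonstrate.

## Spectral model

Fluorophores are modelled as single Gaussian emission lines binned onto a
25-bin spectral detector covering 380–630 nm (10 nm bins) and mapped
through three band-pass filters (390/18, 480/40, 629/56 nm) into the
acquisition channels. Detector output is quantized to 12 bits (4096 gray
levels).

Peak wavelengths are fixed by the imaging physics and the tissue classes
being emulated: 480 nm for epithelial, adipose and stromal
autofluorescence, 510 nm for the dot-like puncta at normal duct edges,
570 nm for immune cells, and 390 nm — exactly half the 780 nm
excitation — for second-harmonic generation (SHG) from fibrillar
collagen. Spectral *widths* and relative amplitudes are free parameters
of the phantom, not measured quantities: autofluorescence lines default
to 80 nm FWHM and the SHG line to 12 nm, reproducing the qualitative
sharp-SHG/broad-autofluorescence contrast. Band overlap with partially
covered bins is weighted linearly by the overlap fraction; for the narrow
SHG line this uniform-within-bin approximation loses about 7% of the
in-band energy relative to continuous integration (the broad lines agree
to better than 0.5%), which is immaterial for channel separability.

## Phantom generator

Each phantom is a 1024 × 1024 px, 0.50 µm/px, 3-channel, 12-bit field
(optionally a z-stack at 3 µm steps with exponential depth attenuation,
length 40 µm). A smooth random support blob covering ~80% of the field
carries faint stromal autofluorescence; structures are placed inside it,
possibly truncated by the field edge, under an overlap budget of 25%:

* **normal duct** — epithelial annulus (outer radius 55–95 px, wall
  12–18 px) with small (3–5 px) signal-void nuclei, an empty lumen, and
  bright 510 nm puncta dotted along the outer edge;
* **adipocyte** — thin bright rim (4–6 px) around a non-fluorescent lipid
  interior, radius 30–60 px;
* **collagen fiber** — dilated random walk carrying the SHG signature;
* **DCIS** — distended duct (radius 80–140 px) filled with irregular
  high-contrast cancer texture and enlarged (6–9 px) nuclear voids, no
  edge puncta;
* **invasive nest** — confluent irregular blob (seed radius 55–90 px) of
  the same cancer texture;
* **immune infiltrate** — cluster of small bright 570 nm cells placed
  just outside a cancer margin when cancer is present.

Signals are blurred with a 1 px Gaussian point-spread function (so thin
structures remain wider than the blank rule's median window), scaled by
`signal_scale` (2500 gray levels per unit concentration), offset by a
background of 40 gray levels, degraded with additive Gaussian read noise
(sd 12 gray levels) and quantized. All randomness derives from one seed
via spawned generators, so cohorts are byte-reproducible.

Ground truth is constructed, not annotated: the cancer mask is the union
of DCIS/invasive footprints, and a tile's label is *cancer* iff more than
5% of its pixels are cancer-mask pixels — a deliberately small fraction so
that images whose malignancy occupies only a corner of a tile still count
as positives.

Cohorts assign each patient a tissue label (normal/cancerous), give ~10%
of cancerous-tissue images no malignant structures (mirroring
tumor-adjacent fields), and split patients into groups A (training) and B
(testing) randomly but stratified by tissue so both groups contain both
classes. Fields smaller than the 1024 px reference (used in tests) scale
structure counts with area since structure sizes are physical.

## Preprocessing and blank rule

The z-origin is calibrated as the first plane whose above-noise-floor
coverage reaches 90% ("signal in almost the entire field"); planes down
to 30 µm are retained and treated as independent images. Images are
standardized to mean 0 / SD 1 per channel (per-channel rather than joint,
so the sparse SHG channel is not swamped) and cropped into 128 px
(64 µm) tiles on the fixed 8 × 8 grid, row-major, origin top-left.

A tile is **blank** iff its SNR is below 20 *and* its mean raw brightness
(on [0, 1] after division by 4095) is below 0.10. The SNR is

    SNR_db = 20 log10( RMS(median3x3(tile)) / RMS(tile − median3x3(tile)) ),

i.e. a pseudo-noiseless estimate from a 3 × 3 median filter (reflected
edges) against its residual. The decibel reading of the threshold and the
window size are package choices; a linear-ratio mode is available. Blank
decisions always read raw intensities — a standardized (zero-mean) tile
would make the brightness cutoff meaningless — so blanking is invariant
to standardization order.

## Classifier

The reference training protocol (Adam, 100 epochs, learning rate 0.020,
batch size 128, model selection on a 20% tile-level validation split) is
retained as the default `TrainConfig`. The desk-scale configuration used
by the pipeline trains a compact NumPy convolutional network:

* input: each standardized 3 × 128 × 128 tile is summarized into 4 × 4
  block **mean** and block **standard deviation** planes (6 × 32 × 32).
  The deviation planes preserve fine-scale texture evidence — nuclear
  voids, edge puncta — that mean pooling alone erases; without them the
  classifier systematically confused normal duct epithelium with DCIS;
* two 3 × 3 convolution blocks (8 and 16 filters, ReLU, 2 × 2 max-pool),
  a 1024→32 dense layer and a sigmoid output;
* class-weighted binary cross-entropy: positives are weighted by
  inverse frequency times a cost asymmetry `positive_cost` (default 4),
  reflecting that a missed cancer tile is clinically costlier than a
  false alarm;
* Adam with learning rate 0.005 for 40 epochs, batch 128; the parameter
  state with the best validation *balanced* accuracy is kept (earliest
  epoch on ties). Balanced accuracy is used because selection by plain
  accuracy under a weighted objective favours majority-class collapse;
  plain accuracy is used when class weighting is off.

A tile is called positive iff its predicted probability is ≥ 0.5.
`inception_v3` is accepted as an architecture identifier but requires an
external deep-learning backend and is not trainable here; at 128 px tile
size and phantom complexity the compact network is adequate, and the
pipeline's value is the end-to-end procedure, not the weights.

## Evaluation

Blank tiles are always *predicted negative* and stay in every
denominator: the tile confusion matrix covers all 64 × n tiles, and the
per-image **malignant probability** is (positive tiles)/64. An image is
called malignant iff that ratio is ≥ 0.0625 (4 of 64 tiles); the
inclusive inequality follows the usual ROC operating-point convention and
a strict mode is available. The ROC sweeps the achievable threshold grid
{0, 1/64, …, 1, 1⁺} and integrates by trapezoid, which on this grid
equals the concordant-pair (Mann–Whitney) statistic exactly — the test
suite asserts that equivalence. The Mann–Whitney U test itself uses exact
enumeration for combined n ≤ 20 without ties and the tie-corrected normal
approximation otherwise (via SciPy); an all-tied input returns p = 1.
Cohen's kappa uses the standard marginal-chance correction with the
degenerate p_e = 1 case defined as 1 when observed agreement is also
perfect. Metrics with zero denominators return NaN markers rather than
raising.

At the image level, a file counts as *normal* iff it contains no
malignant-finding tiles, regardless of the tissue it came from — so
cancerous-tissue fields without malignant findings enter the specificity
denominator.

## Problem sizes and observed behaviour

The shipped end-to-end study uses 12 patients × 8 images (6 patients per
group), 1024 px single-plane fields — 6144 tiles, of which ~4% are blank
and ~10% are cancer — and runs in about five minutes on one CPU. Across
seeds, tile-level recall lands near 0.9 (observed 0.87–0.97), tile
precision 0.77–0.88, and image-level AUC ≥ 0.996 with sensitivity
0.95–1.0 and specificity 0.78–1.0; the regression suite pins one seed.
Tile-recall variance is driven by the ~300 positive tiles per cohort and
by boundary tiles whose cancer coverage sits just above the 5% labelling
rule.

## What the phantoms do and do not show

The generator reproduces the *mechanics* the pipeline depends on —
channel formation from emission spectra, 12-bit quantization, blank-tile
statistics, patient-disjoint generalization, tile-ratio aggregation — with
geometric primitives whose class differences (filled vs annular
epithelium, enlarged nuclei, absent puncta, SHG fibers) are idealized
stand-ins for histology. Passing the synthetic study demonstrates that
the pipeline is implemented coherently end to end and can recover planted
class structure across patients; it does not demonstrate clinical
performance, which was established on patient images that are not
publicly released. Mucinous and micropapillary subtypes, 3-D structural
continuity across z, photobleaching, depth-dependent spectral shifts and
scanner artifacts are not modelled.

## Known limitations

* The SNR formula and its decibel threshold are one reading of an
  underspecified rule; the blank counts of the clinical dataset cannot be
  reproduced and are not asserted.
* Whether clinical standardization was per channel or joint is unknown;
  per channel is implemented and flagged.
* The validation split is plain random over tiles (not stratified, not
  patient-held-out), following the stated protocol.
* Tile labels near the 5% coverage rule are intrinsically ambiguous; the
  classifier's residual misses concentrate there.
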