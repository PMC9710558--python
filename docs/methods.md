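# Methods

This note documents the models, parameters and numerical choices behind
`semiq`, and what the synthetic benchmark does and does not establish.

## Coordinate and label conventions

All geometry uses (row, col) pixel coordinates, 0-based, with pixel
centers at integers. Angles are measured counter-clockwise from the +col
axis in degrees (rows increase downward, so a vector (dr, dc) has angle
atan2(−dr, dc)); nucleus orientations are undirected and stored in
[−90, 90). Channels are identified by name (`hoechst`, `acta2`,
`acrv1`), never by index: the mapping from TIFF pages to names is
supplied at read time or taken from metadata this package writes. The
cell-type order (Sertoli, SPG, SPC, SPCII, rSPD, iSPD, eSPD) and the
stage order (I..XII) fix the component order of every probability
vector; both are persisted as a JSON sidecar with trained weights, and
loading refuses a model whose stored label order disagrees with the
current enumeration.

## Segmentation

**Intensity normalization** is a white top-hat transform: the image
minus its grey opening by a disk (default radius 100 px). Structures
smaller than the disk pass unchanged; smooth background is removed; the
output is non-negative and zero on constants. For radii above 20 px the
disk footprint is decomposed into a sequence of small footprints
(scikit-image's `decomposition="sequence"`); this approximates the disk
but remains a genuine structuring sequence, so the transform keeps every
top-hat property. Exact disks are used at small radii, where unit tests
compare against a brute-force erosion/dilation oracle pixelwise.

**Nuclei.** The builtin backend thresholds the normalized Hoechst
channel by Otsu's method, fills holes, computes the Euclidean distance
transform, seeds a watershed at local maxima separated by at least half
the expected object length (30 px → 15 px), and discards objects smaller
than (π/4)(diameter/3)². A generalist external segmenter (cellpose) is
used instead when importable; its absence triggers a logged fallback,
never an error. Pairs of nuclei closer than roughly a quarter diameter
may legitimately merge; the benchmark bar is recall ≥ 0.95 with ≤ 3 px
centroid error on non-overlapping blobs.

**Tubules.** The Acta2 channel is Otsu-thresholded; the ring is dilated
by r_d = 5 px to bridge outline gaps (≲ 10 px), enclosed regions are
filled, an opening by r_o = 15 px detaches interstitial slivers, and an
erosion by r_d undoes the dilation bias. Interiors (lumen included —
needed for lumen radii) are labeled and filtered: area within
0.5–3 × 10⁶ px and circularity 4πA/P² > 0.5. Perimeters of rasterized
regions use the Crofton estimator (4 directions); near-circular rasters
can score slightly above 1, so the filter compares unclamped values.
r_d and r_o are this package's defaults — chosen to bridge realistic
gaps without merging adjacent tubules at 0.17 µm/px — and are exposed in
the configuration. Objects touching the image border are kept but
flagged. A nucleus belongs to the tubule under its centroid pixel;
anything else is extratubular and excluded from per-tubule statistics.

## Classifiers

Both classifiers are residual CNNs implemented in NumPy inside the
package (im2col convolutions, batch normalization, manual backprop):
identity-shortcut blocks in the standard 50-layer bottleneck (3-4-6-3)
or 18-layer basic (2-2-2-2) arrangement, a 7×7/stride-2 stem with 3×3
max-pooling, global average pooling and a softmax head. A `base_width`
parameter scales all channel widths; 64 reproduces the standard widths,
and the reduced test configuration uses the 18-layer arrangement at
width 8–12 so CPU training of desk-scale fixtures takes seconds to
minutes. Training is Adam (lr 10⁻³ stepped down 10× at ⅔ of the epochs,
batch 64, cross-entropy, weight decay 10⁻⁴) with flip/90°-rotation
augmentation; the cell task additionally uses ±15% per-patch intensity
jitter (its signal is partly brightness-based and the whole-image
normalization differs slightly between sources), which is off for the
stage task whose probability layers carry calibrated values. Because a
short run sees too few batches for the batch-norm running averages to
converge, the running statistics are re-estimated by a cumulative pass
over the training data after the last epoch. Training is deterministic
given the seed up to BLAS reduction order.

Cell patches are 64 × 64 crops of the normalized Hoechst channel
centered on the rounded nucleus centroid, zero-padded at image borders
and scaled to [0, 1] by the source-image maximum. Tubule patches are
2000 × 2000 ten-channel crops centered on the tubule centroid
(Hoechst, Acta2, Acrv1 scaled by their image maxima, plus the seven
probability layers rendered over each nucleus's full mask footprint),
area-average-downsampled 4× to 500 × 500. Each tubule patch is masked to
its own tubule label before downsampling — in a dense section the
2000-px window contains neighboring tubules, and the Acta2 boundary is
what isolates individual tubules for staging. `classify()`
area-average-downsamples patches whose side is an integer multiple of
the model input, so the 500-px extraction contract feeds reduced-input
models unchanged. Argmax ties resolve to the lowest enumeration index;
confidence is the row maximum; the low-confidence filter keeps calls
with confidence ≥ 0.80 (exactly 80% is kept). Stage evaluation also
reports within-±1 cyclic accuracy, where stage s matches s±1 modulo 12.

## Morphometrics

ABP combines the two distances (nucleus centroid → nearest tubule-edge
pixel, and → tubule centroid) as d_edge/(d_edge + d_center): bounded in
[0, 1], 0 basal, 1 apical, and equal to 1 − r/R on a circular tubule.
Relative orientation is the acute angle between the undirected major
axis and the radial vector, folded into [0, 90]. The signed radial
neighbor metric is ABP(target) − ABP(reference), positive when the
target is more apical. Nearest-neighbor networks link each reference
nucleus to the Euclidean-nearest nucleus of every *other* type in the
same tubule; absent types yield no edge (missing, not zero). Pooled
pair-count matrices tally only each reference's single overall-nearest
target and are normalized by the number of contributing tubules.
Neighbor distances are centroid-to-centroid. The spermatogenic index is
eSPD/SPG per tubule (NaN without SPG) and, like all per-tubule counts,
uses post-LCF records by default.

**Lumen detection.** Within a tubule, the distance to the nearest
nucleus is computed; the lumen sits at the peak of that map. The map is
thresholded at half its maximum m, and the connected component holding
the peak is the lumen core — the lumen eroded by m/2 — so the core's
equivalent circular radius plus m/2 estimates the lumen radius. When
the nucleus-free space is a connected labyrinth rather than a compact
lumen (arrest-like tubules), that estimate overshoots; the peak distance
m is the radius of the largest inscribed nucleus-free disk and bounds
the estimate from above, so the minimum of the two is reported, capped
by the tubule radius. A tubule without nuclei degenerates to
lumen ≈ tubule, ratio 1. The half-maximum fraction is configurable.

## Batch normalization and tests

Observations form a features × samples × n_obs tensor (n_obs = 10 000 by
default; groups smaller than n_obs are resampled with replacement and
flagged). Each feature-sample z-vector is sorted ascending; each
xy-frame is then quantile-normalized across samples — with sorted
z-vectors this reduces to replacing the value at each z-rank by the mean
of that rank across samples, after which every sample of a feature
carries an identical multiset and the operation is idempotent. Ties take
midranks; both properties are tested against a brute-force rank-based
oracle. Two-group comparisons are two-sided per feature: Mann–Whitney U
(rank-based, indifferent to the z-sorting) or paired t on z-aligned
values. The paired test presumes the z-alignment reflects genuine
pairing; applied to independently drawn samples the sorted alignment is
anti-conservative, which is a property of the method itself — the
calibration test therefore uses genuinely paired data. Raw p-values are
reported (tiers at 0.01, 10⁻³, 10⁻⁵); an optional Bonferroni factor is
off by default.

## Synthetic sections

The generator emulates the structural assumptions of the pipeline, not
histological texture. Each tubule is a circular Acta2 ring (thickness
12 px, two 6-px gaps, radius drawn from 420–470 px — inside the
area-filter bracket at 0.17 µm/px) on its own canvas. Nuclei are anisotropic
Gaussian blobs with per-type size, eccentricity and brightness (Sertoli
and SPC large, eSPD small and elongated) placed by rejection sampling in
type-specific ABP bands: Sertoli/SPG basal (0.02–0.16), SPC mid
(0.25–0.45, SPC-II only at stage XII), rSPD apical with a small
stage-proportional drift, iSPD at stages IX–XII, eSPD apical
(0.60–0.78) and deeper into the lumen (0.64–0.85) at stages VI–VII.
Wild-type counts per tubule (Sertoli 12, SPG 14, SPC 50, rSPD 70,
iSPD 40, eSPD 56) enforce eSPD = 4·SPG — the ideal spermatogenic index
of 4 — in every tubule; the `meiotic_arrest` genotype drops all
post-meiotic classes. Two separation rules apply: a global minimum
centroid distance (19 px) and per-type exclusion radii
(max(10.5, 1.5 σ_major) px) so that the summed intensity of neighbors
stays bimodal and instance segmentation of the truth is well posed.
Acrv1 is rendered on spermatids plus a coherent annular arc in the
spermatid layer whose angular extent is 2π·stage/12 — the stage signal,
mirroring how the acrosomal pattern disambiguates adjacent stages; its
start angle is random per tubule. Sections compose tubules on a
jittered grid (guaranteeing ≥ 90 px gaps), scatter interstitial nuclei
outside all tubules, and add faint low-frequency background plus
Gaussian sensor noise. Every output is a pure function of
(blueprint, seed).

`make_training_set` harvests balanced truth-labeled patches. The tubule
patches' probability layers are one-hot truth classes rendered on
footprints produced by the same builtin nucleus segmentation the
pipeline uses at inference, so the layer geometry matches deployment;
cell patches are labeled by their central nucleus.

**What passing the synthetic benchmark shows — and does not.** It shows
the mechanism works end to end: segmentation recovers the objects,
the classifiers learn honest per-class signal and the morphometrics
recover composition (counts within 5%), position (mean ABP within 0.1)
and the constructed spermatogenic index. It does not show performance on
real micrographs: Gaussian blobs lack chromatin texture, real staging
cues are subtler than an arc fraction, real sections contain debris,
folds and uneven staining, and the real class balance is far from
uniform. Accuracies measured here are properties of the benchmark, not
of tissue.

## Problem sizes and defaults used by the test suite

The end-to-end check trains the cell classifier on 700 patches
(100/class, 18 epochs, 18-layer width-8) and the stage classifier on 288
patches (24/stage, 50 epochs, 18-layer width-12 at 50-px input), then
runs the full pipeline on a fresh 12-tubule section (~2 700 nuclei,
3180 × 4240 px) — the package's chosen desk-scale configuration — and
scores against generator truth: nucleus recall ≥ 0.95, cell-type
accuracy ≥ 0.90, within-±1 cyclic stage agreement ≥ 0.99. Property
suites cover top-hat and filter idempotence, closed-form circularity,
ABP/orientation invariants, brute-force nearest-neighbor and
quantile-normalization oracles, and type-I-error calibration of the
two-group tests (≥ 95% non-significant at α = 0.01 over 200 seeded
null replicates).

## Known limitations

* The builtin nucleus backend assumes roughly convex, blob-like nuclei;
  crescent or overlapping real nuclei need the external generalist
  backend.
* The lumen estimator assumes one dominant lumen; fragmented lumina
  report only the component holding the peak free distance.
* The stage classifier's probability-layer input makes it sensitive to
  upstream cell-classification quality; training layers are therefore
  rendered on segmented (not ideal) footprints.
* Quantile normalization forces identical marginals per feature across
  samples; genuine global differences between samples in a feature are
  removed along with batch effects, by design.
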