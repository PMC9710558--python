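# semiq

Quantitative analysis of mouse seminiferous tubule cross-sections from
multiplexed immunofluorescence images.

Spermatogenesis proceeds through twelve cyclic stages (I–XII) of the
seminiferous epithelium, each defined by the association of germ cells
present: Sertoli cells and spermatogonia (SPG) at the basal edge,
primary/secondary spermatocytes (SPC, SPC-II) mid-epithelium, and round,
intermediate and elongated spermatids (rSPD, iSPD, eSPD) progressing
toward the lumen. Histological scoring of these stages and cell types is
slow and subjective. `semiq` automates it for sections stained with
Hoechst (nuclei), Acta2 (peritubular smooth muscle — the tubule
boundary) and Acrv1 (acrosome — informative for staging), imaged at a
known pixel scale (default 0.17 µm/px):

1. **Segmentation** — white top-hat intensity normalization (disk radius
   100 px); nucleus instance segmentation (cellpose if available, else a
   builtin Otsu + distance-transform-watershed backend, object length
   30 px); tubule segmentation from the Acta2 ring (Otsu → dilation →
   hole fill → opening → erosion), filtered by area (0.5–3 × 10⁶ px,
   i.e. radii ≈ 68–166 µm) and circularity 4πA/P² > 0.5.
2. **Classification** — two residual CNNs: a 7-class cell typer on
   64 × 64 normalized Hoechst patches per nucleus, and a 12-stage tubule
   classifier on 2000 × 2000 crops downsampled to 500 × 500 with ten
   channels (Hoechst, Acta2, Acrv1 + the seven per-class probability
   layers rendered over each nucleus footprint). Low-confidence calls
   (< 80%) can be filtered (LCF); stage accuracy is also reported
   within ±1 cyclic stage (XII is adjacent to I).
3. **Morphometrics** — apical-basal position
   ABP = d_edge / (d_edge + d_center) ∈ [0, 1]; relative nuclear
   orientation (0° radial … 90° circumferential); per-tubule
   nearest-neighbor networks between cell types with Euclidean and
   signed radial (ΔABP) distances; the spermatogenic index
   (eSPD:SPG ≈ 4 under ideal meiosis); tubule and lumen radii.
4. **Batch normalization & statistics** — 3D quantile normalization over
   a features × samples × 10 000-observation tensor, then per-feature
   paired t or Mann–Whitney U comparisons with significance tiers
   (p ≤ 0.01, 10⁻³, 10⁻⁵).

A seeded synthetic-section generator (`semiq.synthetic`) emulates the
whole imaging geometry with exact ground truth, so every stage is
testable without microscopy data.

## Worked example

```bash
$ semiq simulate --n-tubules 2 --seed 7 --out demo
wrote synthetic section with 2 tubules, 414 nuclei to demo

$ semiq segment demo/section.ome.tif --nucleus-backend builtin --out demo_seg
413 nuclei, 2 tubules retained (0 removed by area, 0 by circularity)
```

The simulated section contains two tubules (~200 nuclei each plus
interstitial nuclei between them); the builtin segmenter recovers 413 of
the 414 generated nuclei and both tubules survive the area/circularity
filter. The composition of a tubule is biologically structured — from
the ground-truth table of the same section:

```python
>>> from semiq import synthetic as syn, morphometrics as morph
>>> from semiq.types import CellType
>>> sec = syn.generate_section(syn.SectionBlueprint(n_tubules=2, seed=7))
>>> t1 = sec.nuclei[sec.nuclei.tubule_id == 1]
>>> counts = {t: int((t1.cell_type == t.label).sum()) for t in CellType}
>>> sec.tubules.loc[0, "stage"]
'XI'
>>> {t.label: c for t, c in counts.items() if c}
{'Sertoli': 12, 'SPG': 14, 'SPC': 50, 'iSPD': 40, 'eSPD': 56}
>>> morph.spermatogenic_index(counts)
4.0
```

A stage-XI tubule carries intermediate and elongated spermatids but no
round spermatids (those are present at stages I–VIII), and the
spermatogenic index is exactly 4 — one spermatogonium yields four
spermatids under ideal meiosis.

To run everything — training both reduced classifiers on balanced
synthetic patches, then segmenting, classifying and summarizing a
section — see `semiq --help` (`train-cells`, `train-tubules`,
`classify-*` via `run-all`) or the end-to-end test in
`tests/test_acceptance.py`, which reaches ≥ 90% cell-type accuracy and
≥ 99% within-±1 stage agreement against generator truth on a 12-tubule
section.

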