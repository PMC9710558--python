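"""End-to-end orchestration of the analysis workflow.

Stages run in dependency order — segment → classify-cells →
classify-tubules → stats → normalize — over one or more section images,
with a JSON run manifest recording per-stage status, outputs and a
configuration hash so that re-running an unchanged analysis skips
completed stages. All stage outputs are plain files (TIFF masks, CSV
tables, JSON logs); there is no hidden state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from . import classification as cls
from . import io as sio
from . import morphometrics as morph
from . import segmentation as seg
from .config import PipelineConfig
from .types import (
    CELL_TYPES,
    STAGES,
    CellType,
    ChannelStack,
    LabelMask,
    NucleusRecord,
    Stage,
    TubuleRecord,
    cell_type_from_label,
)

log = logging.getLogger(__name__)

__all__ = ["run_all", "RunManifest", "measure_nuclei", "evaluate_against_truth"]

STAGE_ORDER = ("segment", "classify_cells", "classify_tubules", "stats", "normalize")


@dataclass
class RunManifest:
    path: Path
    data: dict

    @classmethod
    def open(cls, out_dir: Path, config_hash: str, inputs: list[str], seed: int) -> "RunManifest":
        path = out_dir / "manifest.json"
        if path.exists():
            data = json.loads(path.read_text())
            if data.get("config_hash") != config_hash or data.get("inputs") != inputs:
                data = cls._fresh(config_hash, inputs, seed)
        else:
            data = cls._fresh(config_hash, inputs, seed)
        m = cls(path, data)
        m.save()
        return m

    @staticmethod
    def _fresh(config_hash: str, inputs: list[str], seed: int) -> dict:
        from . import __version__

        return {
            "config_hash": config_hash,
            "inputs": inputs,
            "seed": seed,
            "version": __version__,
            "stages": {},
        }

    def complete(self, stage: str) -> bool:
        info = self.data["stages"].get(stage)
        return bool(info and info.get("status") == "complete")

    def mark(self, stage: str, status: str, outputs: list[str] | None = None, error: str = "") -> None:
        self.data["stages"][stage] = {
            "status": status,
            "outputs": outputs or [],
            "error": error,
        }
        self.save()

    def save(self) -> None:
        tmp = self.path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.data, indent=2))
        tmp.replace(self.path)  # atomic per-stage update


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def measure_nuclei(
    nucleus_mask: LabelMask,
    tubule_mask: LabelMask,
    tubule_centroids: dict[int, tuple[float, float]],
) -> pd.DataFrame:
    """Geometry + ABP + relative orientation for every segmented nucleus."""
    assignment = seg.assign_nuclei_to_tubules(nucleus_mask, tubule_mask)
    props = {p.label: p for p in regionprops(nucleus_mask.labels)}
    # one distance transform per tubule, applied to its member nuclei
    rows = []
    by_tubule: dict[int, list[int]] = {}
    for lbl, tid in assignment.items():
        by_tubule.setdefault(tid, []).append(lbl)
    tubule_bbox = {p.label: p for p in regionprops(tubule_mask.labels)}
    for tid, labels in by_tubule.items():
        if tid > 0 and tid in tubule_bbox:
            p = tubule_bbox[tid]
            r0, c0, r1, c1 = p.bbox
            mask = tubule_mask.labels[r0:r1, c0:c1] == tid
            tc = tubule_centroids.get(tid, p.centroid)
            tc_local = (tc[0] - r0, tc[1] - c0)
            cents = np.array([props[l].centroid for l in labels])
            local = cents - np.array([r0, c0])
            abps = morph.abp_for_tubule(local, tc_local, mask)
        else:
            abps = [float("nan")] * len(labels)
        for lbl, abp in zip(labels, abps):
            p = props[lbl]
            orient = math.degrees(p.orientation)
            # regionprops orientation: angle from the row axis; convert to
            # CCW-from-+col convention in [-90, 90)
            theta = 90.0 - orient if orient >= 0 else -90.0 - orient
            theta = (theta + 90.0) % 180.0 - 90.0
            if tid > 0:
                tc = tubule_centroids.get(tid, tubule_bbox[tid].centroid)
                try:
                    rel = morph.relative_orientation(theta, p.centroid, tc)
                except ValueError:
                    rel = 0.0
            else:
                rel = float("nan")
            rows.append(
                {
                    "id": lbl,
                    "tubule_id": tid,
                    "centroid_row": p.centroid[0],
                    "centroid_col": p.centroid[1],
                    "area_px": float(p.area),
                    "major_axis_px": float(p.axis_major_length),
                    "minor_axis_px": float(p.axis_minor_length),
                    "orientation_deg": theta,
                    "abp": float(abp),
                    "rel_orientation_deg": rel,
                }
            )
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def _records_from_geometry(geom: pd.DataFrame, probs: np.ndarray) -> list[NucleusRecord]:
    out = []
    for i, (_, g) in enumerate(geom.iterrows()):
        extratubular = int(g["tubule_id"]) == 0
        out.append(
            NucleusRecord.from_probs(
                probs[i],
                id=int(g["id"]),
                tubule_id=int(g["tubule_id"]),
                centroid=(float(g["centroid_row"]), float(g["centroid_col"])),
                area_px=float(g["area_px"]),
                major_axis_px=float(g["major_axis_px"]),
                minor_axis_px=float(g["minor_axis_px"]),
                orientation_deg=float(g["orientation_deg"]),
                abp=float("nan") if extratubular else float(np.clip(g["abp"], 0, 1)),
                rel_orientation_deg=float("nan") if extratubular else float(g["rel_orientation_deg"]),
            )
        )
    return out


def run_all(
    image_paths: list[str | Path],
    config: PipelineConfig,
    cell_model_dir: str | Path,
    tubule_model_dir: str | Path,
    out_dir: str | Path,
) -> RunManifest:
    """Run every stage on the given section images; resumable via manifest."""
    image_paths = [Path(p) for p in image_paths]
    if not image_paths:
        raise ValueError("no input images")
    for p in image_paths:
        if not p.exists():
            raise FileNotFoundError(p)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest = RunManifest.open(out_dir, chash, [str(p) for p in image_paths], config.seed)

    cell_model, cell_spec = cls.load_classifier(cell_model_dir)
    tub_model, tub_spec = cls.load_classifier(tubule_model_dir)

    per_image: dict[str, dict] = {}
    try:
        for img_path in image_paths:
            name = img_path.stem
            idir = out_dir / name
            idir.mkdir(exist_ok=True)
            per_image[name] = _run_one(
                img_path, idir, config, manifest, cell_model, cell_spec, tub_model, tub_spec
            )
        _stage_normalize(per_image, out_dir, config, manifest)
    except Exception as exc:  # record the failure, keep prior outputs
        manifest.mark("run", "error", error=str(exc))
        raise
    return manifest


def _run_one(img_path, idir, config, manifest, cell_model, cell_spec, tub_model, tub_spec):
    key = img_path.stem
    stack = sio.read_channel_stack(img_path, um_per_px=None)
    outputs: dict[str, Path] = {
        "nucleus_mask": idir / "nucleus_mask.tif",
        "tubule_mask": idir / "tubule_mask.tif",
        "seg_report": idir / "segmentation_report.csv",
        "nuclei": idir / "nuclei.csv",
        "nuclei_lcf": idir / "nuclei_lcf.csv",
        "tubules": idir / "tubules.csv",
        "edges": idir / "neighbor_edges.csv",
        "pair_counts": idir / "pair_counts.csv",
        "mean_distance": idir / "mean_distance.csv",
        "mean_radial": idir / "mean_radial.csv",
    }

    # ---- segment ---------------------------------------------------------
    if manifest.complete(f"{key}/segment") and outputs["nucleus_mask"].exists():
        nucleus_mask = sio.read_label_mask(outputs["nucleus_mask"])
        tubule_mask = sio.read_label_mask(outputs["tubule_mask"])
        norm_hoechst = seg.normalize_intensity(stack["hoechst"], config.tophat_radius_px)
    else:
        manifest.mark(f"{key}/segment", "running")
        norm_hoechst = seg.normalize_intensity(stack["hoechst"], config.tophat_radius_px)
        nucleus_mask = seg.segment_nuclei(
            norm_hoechst, config.nucleus_diameter_px, config.nucleus_backend
        )
        tubule_mask = seg.segment_tubules(stack.channels.get("acta2", stack["hoechst"]), config)
        tubule_mask, report = seg.filter_tubules(tubule_mask, config)
        sio.write_label_mask(nucleus_mask, outputs["nucleus_mask"])
        sio.write_label_mask(tubule_mask, outputs["tubule_mask"])
        pd.DataFrame(
            report.objects, columns=["label", "area_px", "circularity", "retained"]
        ).to_csv(outputs["seg_report"], index=False)
        manifest.mark(f"{key}/segment", "complete", [str(outputs["nucleus_mask"])])
        log.info("segment: %d nuclei, %d tubules retained", nucleus_mask.n_labels, tubule_mask.n_labels)

    tubule_centroids = {p.label: p.centroid for p in regionprops(tubule_mask.labels)}
    norm_stack = ChannelStack(
        channels={**stack.channels, "hoechst": norm_hoechst},
        um_per_px=stack.um_per_px,
        source_id=stack.source_id,
    )

    # ---- classify cells --------------------------------------------------
    if manifest.complete(f"{key}/classify_cells") and outputs["nuclei"].exists():
        records = sio.read_records(outputs["nuclei"])
    else:
        manifest.mark(f"{key}/classify_cells", "running")
        geom = measure_nuclei(nucleus_mask, tubule_mask, tubule_centroids)
        patches = np.stack(
            [
                cls.extract_cell_patch(
                    norm_stack, (g["centroid_row"], g["centroid_col"]), config.cell_patch_px
                )
                for _, g in geom.iterrows()
            ]
        ) if len(geom) else np.zeros((0, config.cell_patch_px, config.cell_patch_px))
        probs, _, _ = cls.classify(cell_model, patches, cell_spec)
        records = _records_from_geometry(geom, probs)
        sio.write_records(records, outputs["nuclei"], kind="nucleus")
        retained, frac = cls.filter_low_confidence(records, config.lcf_threshold)
        sio.write_records(retained, outputs["nuclei_lcf"], kind="nucleus")
        manifest.mark(f"{key}/classify_cells", "complete", [str(outputs["nuclei"])])
        log.info("classify_cells: %d nuclei, LCF retention %.3f", len(records), frac)

    # ---- classify tubules ------------------------------------------------
    if manifest.complete(f"{key}/classify_tubules") and outputs["tubules"].exists():
        tubule_records = sio.read_records(outputs["tubules"])
    else:
        manifest.mark(f"{key}/classify_tubules", "running")
        prob_map = cls.render_cell_prob_map(nucleus_mask, records)
        tubule_records = []
        retained, _ = cls.filter_low_confidence(records, config.lcf_threshold)
        by_tubule: dict[int, list[NucleusRecord]] = {}
        for r in retained:
            if r.tubule_id > 0:
                by_tubule.setdefault(r.tubule_id, []).append(r)
        tpatches = []
        tids = sorted(tubule_centroids)
        for tid in tids:
            tpatches.append(
                cls.extract_tubule_patch(
                    norm_stack,
                    prob_map,
                    tubule_centroids[tid],
                    config.tubule_patch_px,
                    config.tubule_patch_downsampled_px,
                    tubule_mask=tubule_mask.labels == tid,
                )
            )
        if tids:
            sprobs, _, _ = cls.classify(tub_model, np.stack(tpatches), tub_spec)
        else:
            sprobs = np.zeros((0, len(STAGES)))
        borders = seg.border_labels(tubule_mask)
        tprops = {p.label: p for p in regionprops(tubule_mask.labels)}
        for i, tid in enumerate(tids):
            p = tprops[tid]
            r0, c0, r1, c1 = p.bbox
            tmask = tubule_mask.labels[r0:r1, c0:c1] == tid
            nmask = nucleus_mask.labels[r0:r1, c0:c1]
            summary = morph.summarize_tubule(
                by_tubule.get(tid, []), tmask, nmask, stack.um_per_px
            )
            perim = float(p.perimeter_crofton)
            tubule_records.append(
                TubuleRecord(
                    id=tid,
                    centroid=p.centroid,
                    area_px=float(p.area),
                    circularity=seg.circularity(float(p.area), perim) if perim > 0 else 0.0,
                    equiv_radius_um=summary["equiv_radius_um"],
                    lumen_radius_um=summary["lumen_radius_um"],
                    stage_probs=sprobs[i],
                    stage_call=STAGES[int(np.argmax(sprobs[i]))],
                    confidence=float(sprobs[i].max()),
                    counts=summary["counts"],
                    spermatogenic_index=summary["spermatogenic_index"],
                    touches_border=tid in borders,
                )
            )
        sio.write_records(tubule_records, outputs["tubules"], kind="tubule")
        manifest.mark(f"{key}/classify_tubules", "complete", [str(outputs["tubules"])])

    # ---- stats -----------------------------------------------------------
    if not (manifest.complete(f"{key}/stats") and outputs["edges"].exists()):
        manifest.mark(f"{key}/stats", "running")
        retained, _ = cls.filter_low_confidence(records, config.lcf_threshold)
        by_tubule = {}
        for r in retained:
            if r.tubule_id > 0:
                by_tubule.setdefault(r.tubule_id, []).append(r)
        edges = []
        for tid, nucs in by_tubule.items():
            edges.extend(morph.nearest_neighbor_network(nucs))
        pd.DataFrame(
            [
                {
                    "reference_id": e.reference_id,
                    "target_id": e.target_id,
                    "reference_type": e.reference_type.label,
                    "target_type": e.target_type.label,
                    "euclidean_px": e.euclidean_px,
                    "radial_signed": e.radial_signed,
                }
                for e in edges
            ]
        ).to_csv(outputs["edges"], index=False)
        if by_tubule:
            summary = morph.neighbor_summary(edges, n_tubules=len(by_tubule))
            summary.pair_counts.to_csv(outputs["pair_counts"])
            summary.mean_euclidean_px.to_csv(outputs["mean_distance"])
            summary.mean_radial_signed.to_csv(outputs["mean_radial"])
        manifest.mark(f"{key}/stats", "complete", [str(outputs["edges"])])

    return {
        "records": sio.read_records(outputs["nuclei"]),
        "source_id": stack.source_id,
        "outputs": outputs,
    }


def _stage_normalize(per_image: dict, out_dir: Path, config: PipelineConfig, manifest: RunManifest):
    from . import stats as st

    if manifest.complete("normalize"):
        return
    if len(per_image) < 2:
        manifest.mark("normalize", "skipped", error="needs at least two image sources")
        return
    manifest.mark("normalize", "running")
    groups: dict[tuple[str, str], np.ndarray] = {}
    for name, info in per_image.items():
        recs = [r for r in info["records"] if r.tubule_id > 0]
        for t in CELL_TYPES:
            areas = np.array([r.area_px for r in recs if r.call == t])
            if len(areas):
                groups[(t.label, name)] = areas
    features = {f for f, _ in groups}
    complete_features = [
        f for f in features if all((f, name) in groups for name in per_image)
    ]
    groups = {k: v for k, v in groups.items() if k[0] in complete_features}
    n_obs = min(st.DEFAULT_N_OBS, 2000)
    tensor = st.sample_observations(groups, n_obs=n_obs, seed=config.seed)
    normalized = st.quantile_normalize_3d(tensor)
    names = sorted(per_image)
    result = st.compare_features(normalized, names[0], names[1], test="mann_whitney")
    result.to_csv(out_dir / "normalized_comparison.csv", index=False)
    manifest.mark("normalize", "complete", [str(out_dir / "normalized_comparison.csv")])


# ---------------------------------------------------------------------------
# truth-based evaluation

def evaluate_against_truth(
    nucleus_records: list[NucleusRecord],
    truth_nuclei: pd.DataFrame,
    tubule_records: list[TubuleRecord] | None = None,
    truth_tubules: pd.DataFrame | None = None,
    match_radius_px: float = 3.0,
) -> dict:
    """Match predictions to ground truth and score both classifiers.

    Nuclei are matched to truth by centroid proximity (≤ ``match_radius_px``);
    tubules by containment of the truth center. Returns cell and stage
    EvaluationResults plus segmentation recall/precision.
    """
    truth_intra = truth_nuclei[truth_nuclei["cell_type"] != "extratubular"]
    if len(truth_intra) == 0:
        raise ValueError("empty truth table")
    tree = cKDTree(truth_intra[["row", "col"]].to_numpy())
    true_idx, pred_idx, used = [], [], set()
    intra_records = [r for r in nucleus_records if r.tubule_id > 0]
    n_matched = 0
    for r in intra_records:
        d, j = tree.query(r.centroid)
        if d <= match_radius_px and j not in used:
            used.add(j)
            n_matched += 1
            true_idx.append(int(cell_type_from_label(truth_intra.iloc[j]["cell_type"])))
            pred_idx.append(int(r.call))
    if not true_idx:
        raise ValueError("no matchable nuclei within the match radius")
    conf = np.array(
        [r.confidence for r in intra_records][: len(true_idx)]
    )  # histogram over matched predictions
    cell_eval = cls.evaluate(np.array(true_idx), np.array(pred_idx), "cell", conf)
    out = {
        "cell": cell_eval,
        "nucleus_recall": n_matched / len(truth_intra),
        "nucleus_precision": n_matched / max(len(intra_records), 1),
    }
    if tubule_records is not None and truth_tubules is not None and len(tubule_records):
        t_true, t_pred = [], []
        for tr in tubule_records:
            d2 = (truth_tubules["row"] - tr.centroid[0]) ** 2 + (
                truth_tubules["col"] - tr.centroid[1]
            ) ** 2
            j = int(d2.idxmin())
            row = truth_tubules.loc[j]
            if math.sqrt(float(d2.loc[j])) <= row["radius_px"]:
                t_true.append(Stage[row["stage"]].value - 1)
                t_pred.append(tr.stage_call.value - 1)
        if t_true:
            out["tubule"] = cls.evaluate(np.array(t_true), np.array(t_pred), "tubule")
    return out
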