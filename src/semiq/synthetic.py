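"""Seeded generator of ground-truthed synthetic testis cross-sections.

The generator emulates the structure the pipeline assumes rather than
photorealistic histology: each seminiferous tubule is a circular Acta2
ring (with small gaps, as real peritubular outlines are imperfect)
enclosing nuclei drawn as anisotropic Gaussian blobs. Cell types are
placed at type-specific apical-basal bands — Sertoli and spermatogonia
basal, spermatocytes mid-epithelium, spermatids apical with a
stage-dependent shift (round spermatids drift apically as the cycle
progresses; elongated spermatids move toward the lumen around stages
VI–VII). Blob size, eccentricity and brightness differ per type so the
cell classifier has honest, learnable signal. Acrv1 (acrosome) signal is
rendered on spermatids within an angular arc whose width grows with
tubule stage, mirroring how the acrosomal pattern disambiguates
developmentally adjacent stages. Interstitial nuclei are scattered
between tubules.

Wild-type composition fixes eSPD = 4·SPG per tubule by construction
(ideal meiosis: one spermatogonium yields four spermatids). The
``meiotic_arrest`` genotype drops all post-meiotic classes (SPCII, rSPD,
iSPD, eSPD), as in Mlh3-null mice.

Every output is a pure function of (blueprint, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .types import CELL_TYPES, STAGES, CellType, ChannelStack, LabelMask, Stage

__all__ = [
    "SectionBlueprint",
    "SectionData",
    "TubulePatch",
    "stage_composition",
    "generate_tubule",
    "generate_section",
    "make_training_set",
    "GENOTYPES",
]

GENOTYPES = ("wildtype", "meiotic_arrest")

#: per-type blob style: (sigma_major, sigma_minor, peak intensity)
NUCLEUS_STYLE: dict[CellType, tuple[float, float, float]] = {
    CellType.SERTOLI: (9.5, 8.5, 0.55),
    CellType.SPG: (7.0, 6.0, 0.95),
    CellType.SPC: (9.5, 8.5, 1.00),
    CellType.SPCII: (6.5, 6.5, 0.80),
    CellType.RSPD: (4.5, 4.5, 0.90),
    CellType.ISPD: (5.0, 3.2, 0.90),
    CellType.ESPD: (6.0, 2.4, 1.00),
}

_INTERSTITIAL_STYLE = (5.0, 3.5, 0.8)

#: base per-tubule counts (wild type); eSPD = 4 × SPG enforces the ideal
#: spermatogenic index of 4 in every tubule.
_BASE_COUNTS = {
    CellType.SERTOLI: 12,
    CellType.SPG: 14,
    CellType.SPC: 50,
    CellType.SPCII: 16,  # stage XII only (meiotic divisions)
    CellType.RSPD: 70,  # stages I–VIII
    CellType.ISPD: 40,  # stages IX–XII
    CellType.ESPD: 56,
}

_POST_MEIOTIC = {CellType.SPCII, CellType.RSPD, CellType.ISPD, CellType.ESPD}


def stage_composition(stage: Stage, genotype: str = "wildtype") -> dict[CellType, int]:
    """Per-type nucleus counts for one tubule of the given stage."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    counts = {}
    for t in CELL_TYPES:
        n = _BASE_COUNTS[t]
        if t is CellType.SPCII and stage is not Stage.XII:
            n = 0
        if t is CellType.RSPD and stage.value > 8:
            n = 0
        if t is CellType.ISPD and stage.value < 9:
            n = 0
        if genotype == "meiotic_arrest" and t in _POST_MEIOTIC:
            n = 0
        counts[t] = n
    return counts


def _abp_band(cell_type: CellType, stage: Stage) -> tuple[float, float]:
    """Apical-basal placement band per type, with stage-dependent shifts."""
    s = stage.value
    if cell_type is CellType.SERTOLI:
        return (0.02, 0.16)
    if cell_type is CellType.SPG:
        return (0.03, 0.16)
    if cell_type in (CellType.SPC, CellType.SPCII):
        return (0.25, 0.45)
    if cell_type is CellType.RSPD:
        shift = 0.005 * (s - 1)  # round spermatids drift apically with stage
        return (0.48 + shift, 0.66 + shift)
    if cell_type is CellType.ISPD:
        return (0.50, 0.68)
    # eSPD: move into the lumen (more apical) at stages VI–VII
    if s in (6, 7):
        return (0.64, 0.85)
    return (0.60, 0.78)


@dataclass
class SectionBlueprint:
    """All the knobs of a synthetic section; defaults emulate a wild-type
    cross-section at the imaging scale of 0.17 µm/px (~120 tubules)."""

    n_tubules: int = 120
    image_shape: tuple[int, int] | None = None  # computed from n_tubules if None
    um_per_px: float = 0.17
    tubule_radius_px: tuple[float, float] = (420.0, 470.0)
    ring_thickness_px: float = 12.0
    n_ring_gaps: int = 2
    ring_gap_px: float = 6.0
    stage_frequencies: tuple[float, ...] = tuple([1 / 12] * 12)
    genotype: str = "wildtype"
    min_centroid_sep_px: float = 19.0
    interstitial_per_tubule: int = 35
    noise_sigma: float = 0.01
    background_amplitude: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        freqs = np.asarray(self.stage_frequencies, dtype=float)
        if freqs.shape != (12,) or freqs.min() < 0 or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("stage_frequencies must be 12 non-negative values summing to 1")
        if self.n_tubules < 1:
            raise ValueError("n_tubules must be >= 1")
        lo, hi = self.tubule_radius_px
        if not 0 < lo <= hi:
            raise ValueError("invalid tubule radius range")

    @property
    def cell_px(self) -> int:
        """Grid pitch that guarantees non-overlapping tubule placement."""
        return int(2 * (self.tubule_radius_px[1] + 60))

    def default_shape(self) -> tuple[int, int]:
        n_cols = math.ceil(math.sqrt(self.n_tubules))
        n_rows = math.ceil(self.n_tubules / n_cols)
        return (n_rows * self.cell_px, n_cols * self.cell_px)


@dataclass
class TubulePatch:
    """One rendered tubule on its own canvas, with exact truth."""

    stage: Stage
    radius_px: float
    center_local: tuple[float, float]
    channels: dict[str, np.ndarray]
    nucleus_labels: np.ndarray  # local instance mask, labels 1..n in truth order
    truth: pd.DataFrame  # columns: cell_type, row, col, abp, orientation_deg (local coords)


def _render_blob(canvas: np.ndarray, r: float, c: float, sa: float, sb: float,
                 theta_deg: float, peak: float) -> None:
    """Add an anisotropic Gaussian blob; theta is CCW from +col (image rows down)."""
    half = int(math.ceil(3.2 * sa))
    r0, c0 = int(round(r)), int(round(c))
    rs, re = max(r0 - half, 0), min(r0 + half + 1, canvas.shape[0])
    cs, ce = max(c0 - half, 0), min(c0 + half + 1, canvas.shape[1])
    if rs >= re or cs >= ce:
        return
    yy, xx = np.mgrid[rs:re, cs:ce]
    dy, dx = yy - r, xx - c
    th = math.radians(theta_deg)
    # major axis unit vector in (row, col) = (-sin th, cos th)
    u = -dy * math.sin(th) + dx * math.cos(th)
    v = dy * math.cos(th) + dx * math.sin(th)
    canvas[rs:re, cs:ce] += peak * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2)).astype(
        canvas.dtype
    )


def _exclusion_radius(sigma_major: float) -> float:
    # keeps the summed intensity of two neighbors bimodal, so instance
    # segmentation of non-overlapping blobs is well posed
    return max(10.5, 1.5 * sigma_major)


def _place_in_band(rng, n, r_lo, r_hi, center, accepted, min_sep, excl, max_tries=50_000):
    """Rejection-sample n points in an annulus, min_sep from all accepted.

    ``accepted`` is a list of (row, col, exclusion_radius); a candidate
    is rejected if closer than max(min_sep, excl_i + excl) to any point.
    """
    placed = []
    tries = 0
    acc = list(accepted)
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "tubule radius too small to honor the requested counts without overlap"
            )
        rad = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
        ang = rng.uniform(0, 2 * math.pi)
        p = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
        if acc:
            arr = np.asarray(acc)
            lim = np.maximum(min_sep, arr[:, 2] + excl)
            if np.min(np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1]) - lim) < 0:
                continue
        acc.append((p[0], p[1], excl))
        placed.append(p)
    return placed, acc


def generate_tubule(
    stage: Stage,
    blueprint: SectionBlueprint,
    radius_px: float | None = None,
    seed: int = 0,
) -> TubulePatch:
    """Render one tubule (ring, nuclei, acrosome signal) with exact truth."""
    rng = np.random.default_rng(seed)
    if radius_px is None:
        radius_px = float(rng.uniform(*blueprint.tubule_radius_px))
    pad = 40
    size = int(2 * (radius_px + pad))
    center = (size / 2.0, size / 2.0)
    hoechst = np.zeros((size, size), dtype=np.float32)
    acta2 = np.zeros_like(hoechst)
    acrv1 = np.zeros_like(hoechst)
    nucleus_labels = np.zeros((size, size), dtype=np.int32)

    # Acta2 ring with gaps (imperfect outlines)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - center[0], xx - center[1])
    ring = (dist <= radius_px) & (dist >= radius_px - blueprint.ring_thickness_px)
    if blueprint.n_ring_gaps > 0:
        ang = np.arctan2(yy - center[0], xx - center[1])
        gap_half = blueprint.ring_gap_px / (2 * radius_px)  # radians
        gap_centers = rng.uniform(-math.pi, math.pi, blueprint.n_ring_gaps)
        for g in gap_centers:
            d = np.abs((ang - g + math.pi) % (2 * math.pi) - math.pi)
            ring &= d > gap_half
    acta2[ring] = 1.0

    comp = stage_composition(stage, blueprint.genotype)
    acr_start = rng.uniform(0, 2 * math.pi)
    acr_width = 2 * math.pi * stage.value / 12.0
    # coherent acrosomal band: an annular arc in the spermatid layer whose
    # angular extent grows with stage (the per-blob signal sits on top)
    if blueprint.genotype == "wildtype":
        ang_all = np.arctan2(yy - center[0], xx - center[1])
        in_arc = ((ang_all - acr_start) % (2 * math.pi)) <= acr_width
        band = (dist >= 0.30 * radius_px) & (dist <= 0.50 * radius_px) & in_arc
        acrv1[band] += 0.5

    rows = []
    accepted: list[tuple[float, float, float]] = []
    label = 0
    for t in CELL_TYPES:
        n = comp[t]
        if n == 0:
            continue
        lo, hi = _abp_band(t, stage)
        r_hi = (1 - lo) * radius_px
        r_lo = (1 - hi) * radius_px
        sa, sb, peak = NUCLEUS_STYLE[t]
        pts, accepted = _place_in_band(
            rng, n, r_lo, r_hi, center, accepted,
            blueprint.min_centroid_sep_px, _exclusion_radius(sa),
        )
        for (pr, pc) in pts:
            radial = math.degrees(math.atan2(-(center[0] - pr), center[1] - pc))
            if t in (CellType.ISPD, CellType.ESPD):
                theta = radial + rng.normal(0, 8.0)  # spermatids point radially
            else:
                theta = rng.uniform(-90, 90)
            theta = (theta + 90) % 180 - 90
            _render_blob(hoechst, pr, pc, sa, sb, theta, peak * rng.uniform(0.9, 1.1))
            label += 1
            rr, cc = draw_ellipse(
                pr, pc, 2 * sa, 2 * sb, shape=nucleus_labels.shape,
                rotation=math.radians(theta),
            )
            nucleus_labels[rr, cc] = label
            if t in (CellType.RSPD, CellType.ISPD, CellType.ESPD):
                a = math.atan2(pr - center[0], pc - center[1])
                if (a - acr_start) % (2 * math.pi) <= acr_width:
                    _render_blob(acrv1, pr, pc, sa, sb, theta, 0.9)
            abp = 1.0 - math.hypot(pr - center[0], pc - center[1]) / radius_px
            rows.append(
                {
                    "cell_type": t.label,
                    "row": pr,
                    "col": pc,
                    "abp": abp,
                    "orientation_deg": theta,
                }
            )
    truth = pd.DataFrame(rows, columns=["cell_type", "row", "col", "abp", "orientation_deg"])
    return TubulePatch(
        stage=stage,
        radius_px=radius_px,
        center_local=center,
        channels={"hoechst": hoechst, "acta2": acta2, "acrv1": acrv1},
        nucleus_labels=nucleus_labels,
        truth=truth,
    )


@dataclass
class SectionData:
    """A synthetic whole-section image with exact ground truth."""

    stack: ChannelStack
    nucleus_mask: LabelMask
    tubule_mask: LabelMask
    nuclei: pd.DataFrame  # id, tubule_id, cell_type, stage, row, col, abp, orientation_deg
    tubules: pd.DataFrame  # id, stage, row, col, radius_px
    blueprint: SectionBlueprint


def generate_section(blueprint: SectionBlueprint) -> SectionData:
    """Compose a full section: tubules on a jittered grid + interstitial nuclei."""
    rng = np.random.default_rng(blueprint.seed)
    shape = blueprint.image_shape or blueprint.default_shape()
    h, w = shape
    cell = blueprint.cell_px
    n_rows, n_cols = h // cell, w // cell
    if n_rows * n_cols < blueprint.n_tubules:
        raise ValueError(
            f"image of shape {shape} too small for {blueprint.n_tubules} tubules"
        )
    hoechst = np.zeros(shape, dtype=np.float32)
    acta2 = np.zeros(shape, dtype=np.float32)
    acrv1 = np.zeros(shape, dtype=np.float32)
    nucleus_mask = np.zeros(shape, dtype=np.int32)
    tubule_mask = np.zeros(shape, dtype=np.int32)

    cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
    chosen = [cells[k] for k in rng.choice(len(cells), blueprint.n_tubules, replace=False)]
    stage_values = rng.choice(
        [s.value for s in STAGES], size=blueprint.n_tubules, p=blueprint.stage_frequencies
    )

    nuc_rows = []
    tub_rows = []
    next_id = 1
    for tid, ((gi, gj), sval) in enumerate(zip(chosen, stage_values), start=1):
        stage = Stage(int(sval))
        radius = float(rng.uniform(*blueprint.tubule_radius_px))
        jitter = (cell / 2 - radius - 45)
        cr = gi * cell + cell / 2 + rng.uniform(-jitter, jitter) if jitter > 0 else gi * cell + cell / 2
        cc = gj * cell + cell / 2 + rng.uniform(-jitter, jitter) if jitter > 0 else gj * cell + cell / 2
        patch = generate_tubule(
            stage, blueprint, radius_px=radius, seed=int(rng.integers(0, 2**31 - 1))
        )
        r0 = int(round(cr - patch.center_local[0]))
        c0 = int(round(cc - patch.center_local[1]))
        ph, pw = patch.channels["hoechst"].shape
        rs, re = max(r0, 0), min(r0 + ph, h)
        cs, ce = max(c0, 0), min(c0 + pw, w)
        prs, pcs = rs - r0, cs - c0
        sl = np.s_[rs:re, cs:ce]
        psl = np.s_[prs : prs + (re - rs), pcs : pcs + (ce - cs)]
        hoechst[sl] += patch.channels["hoechst"][psl]
        acta2[sl] += patch.channels["acta2"][psl]
        acrv1[sl] += patch.channels["acrv1"][psl]
        local_labels = patch.nucleus_labels[psl]
        nz = local_labels > 0
        nucleus_mask[sl][nz] = local_labels[nz] + (next_id - 1)
        yy, xx = np.mgrid[rs:re, cs:ce]
        disk = np.hypot(yy - cr, xx - cc) <= radius
        tubule_mask[sl][disk] = tid
        for _, row in patch.truth.iterrows():
            nuc_rows.append(
                {
                    "id": next_id,
                    "tubule_id": tid,
                    "cell_type": row["cell_type"],
                    "stage": stage.name,
                    "row": row["row"] + r0,
                    "col": row["col"] + c0,
                    "abp": row["abp"],
                    "orientation_deg": row["orientation_deg"],
                }
            )
            next_id += 1
        tub_rows.append(
            {"id": tid, "stage": stage.name, "row": cr, "col": cc, "radius_px": radius}
        )

    # interstitial nuclei between tubules
    centers = np.array([[t["row"], t["col"]] for t in tub_rows])
    radii = np.array([t["radius_px"] for t in tub_rows])
    n_inter = blueprint.interstitial_per_tubule * blueprint.n_tubules
    sa, sb, peak = _INTERSTITIAL_STYLE
    placed = 0
    tries = 0
    pts: list[tuple[float, float]] = []
    while placed < n_inter and tries < 20 * n_inter:
        tries += 1
        p = (rng.uniform(10, h - 10), rng.uniform(10, w - 10))
        if np.any(np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1]) < radii + 15):
            continue
        if pts:
            arr = np.asarray(pts[-200:])
            if np.min(np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])) < blueprint.min_centroid_sep_px:
                continue
        pts.append(p)
        theta = float(rng.uniform(-90, 90))
        _render_blob(hoechst, p[0], p[1], sa, sb, theta, peak * rng.uniform(0.9, 1.1))
        rr, cc2 = draw_ellipse(p[0], p[1], 2 * sa, 2 * sb, shape=shape, rotation=math.radians(theta))
        nucleus_mask[rr, cc2] = next_id
        nuc_rows.append(
            {
                "id": next_id,
                "tubule_id": 0,
                "cell_type": "extratubular",
                "stage": "",
                "row": p[0],
                "col": p[1],
                "abp": float("nan"),
                "orientation_deg": theta,
            }
        )
        next_id += 1
        placed += 1

    # imaging noise: faint smooth background + sensor noise
    if blueprint.background_amplitude > 0:
        coarse = rng.random((max(h // 256, 2), max(w // 256, 2))).astype(np.float32)
        zoom = (math.ceil(h / coarse.shape[0]), math.ceil(w / coarse.shape[1]))
        bg = np.kron(coarse, np.ones(zoom, dtype=np.float32))[:h, :w]
        hoechst += blueprint.background_amplitude * bg
    if blueprint.noise_sigma > 0:
        hoechst += rng.normal(0, blueprint.noise_sigma, shape).astype(np.float32)
        acta2 += rng.normal(0, blueprint.noise_sigma, shape).astype(np.float32)
        acrv1 += rng.normal(0, blueprint.noise_sigma, shape).astype(np.float32)
    np.maximum(hoechst, 0, out=hoechst)
    np.maximum(acta2, 0, out=acta2)
    np.maximum(acrv1, 0, out=acrv1)

    stack = ChannelStack(
        channels={"hoechst": hoechst, "acta2": acta2, "acrv1": acrv1},
        um_per_px=blueprint.um_per_px,
        source_id=f"synthetic-{blueprint.genotype}-seed{blueprint.seed}",
    )
    nuclei = pd.DataFrame(
        nuc_rows,
        columns=["id", "tubule_id", "cell_type", "stage", "row", "col", "abp", "orientation_deg"],
    )
    tubules = pd.DataFrame(tub_rows, columns=["id", "stage", "row", "col", "radius_px"])
    return SectionData(
        stack=stack,
        nucleus_mask=LabelMask(nucleus_mask, "nucleus"),
        tubule_mask=LabelMask(tubule_mask, "tubule"),
        nuclei=nuclei,
        tubules=tubules,
        blueprint=blueprint,
    )


def make_training_set(
    blueprint: SectionBlueprint,
    n_per_class: int,
    classes: list[CellType] | None = None,
    cell_patch_px: int = 64,
    tubule_crop_px: int = 2000,
    tubule_out_px: int = 500,
    include_tubules: bool = True,
) -> dict:
    """Balanced, truth-labeled training patches for both classifiers.

    Returns a dict with ``cell_x`` (N, 1, p, p) patches, ``cell_y``
    class indices, and (when ``include_tubules``) ``tubule_x``
    (M, 10, q, q) patches with one-hot truth probability layers and
    ``tubule_y`` 0-based stage indices.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    present = [t for t in CELL_TYPES if any(
        stage_composition(s, blueprint.genotype)[t] > 0 for s in STAGES
    )]
    if classes is None:
        classes = present
    else:
        missing = [t for t in classes if t not in present]
        if missing:
            raise ValueError(
                f"genotype {blueprint.genotype!r} lacks classes "
                f"{[t.label for t in missing]}"
            )
    rng = np.random.default_rng(blueprint.seed + 101)
    quotas = {t: n_per_class for t in classes}
    cell_x: list[np.ndarray] = []
    cell_y: list[int] = []
    tubule_x: list[np.ndarray] = []
    tubule_y: list[int] = []
    stage_quota = {s: (n_per_class if include_tubules else 0) for s in STAGES}
    factor = tubule_crop_px // tubule_out_px
    if tubule_crop_px % tubule_out_px:
        raise ValueError("tubule_crop_px must be a multiple of tubule_out_px")

    stage_cycle = 0
    while any(q > 0 for q in quotas.values()) or any(q > 0 for q in stage_quota.values()):
        stage = STAGES[stage_cycle % 12]
        stage_cycle += 1
        need_stage = stage_quota[stage] > 0
        need_cells = any(
            quotas.get(t, 0) > 0 and stage_composition(stage, blueprint.genotype)[t] > 0
            for t in classes
        )
        if not (need_stage or need_cells):
            continue
        patch = generate_tubule(stage, blueprint, seed=int(rng.integers(0, 2**31 - 1)))
        canvas = patch.channels["hoechst"]
        peak = float(canvas.max())
        norm = canvas / peak if peak > 0 else canvas
        # harvest cell patches
        order = rng.permutation(len(patch.truth))
        for k in order:
            row = patch.truth.iloc[int(k)]
            t = next(tt for tt in CELL_TYPES if tt.label == row["cell_type"])
            if quotas.get(t, 0) <= 0:
                continue
            half = cell_patch_px // 2
            r0 = int(round(row["row"])) - half
            c0 = int(round(row["col"])) - half
            out = np.zeros((cell_patch_px, cell_patch_px), dtype=np.float32)
            rs, re = max(r0, 0), min(r0 + cell_patch_px, norm.shape[0])
            cs, ce = max(c0, 0), min(c0 + cell_patch_px, norm.shape[1])
            out[rs - r0 : re - r0, cs - c0 : ce - c0] = norm[rs:re, cs:ce]
            cell_x.append(out)
            cell_y.append(int(t))
            quotas[t] -= 1
        # harvest the tubule patch: probability layers are one-hot truth
        # classes rendered on footprints produced by the same builtin
        # nucleus segmentation the pipeline uses, so the layer geometry
        # matches what the stage classifier will see at inference
        if need_stage:
            chans = []
            for name in ("hoechst", "acta2", "acrv1"):
                img = patch.channels[name]
                p = float(img.max())
                chans.append(img / p if p > 0 else img)
            from .segmentation import segment_nuclei

            seg_mask = segment_nuclei(canvas, backend="builtin")
            type_lut = np.zeros((seg_mask.n_labels + 1, len(CELL_TYPES)), dtype=np.float32)
            if seg_mask.n_labels:
                from scipy.spatial import cKDTree
                from skimage.measure import regionprops

                seg_props = regionprops(seg_mask.labels)
                truth_xy = patch.truth[["row", "col"]].to_numpy()
                truth_types = [
                    int(next(tt for tt in CELL_TYPES if tt.label == lab))
                    for lab in patch.truth["cell_type"]
                ]
                tree = cKDTree(truth_xy)
                for prp in seg_props:
                    dist, j = tree.query(prp.centroid)
                    if dist <= 3.0:
                        type_lut[prp.label, truth_types[int(j)]] = 1.0
            onehot = np.moveaxis(type_lut[seg_mask.labels], -1, 0)
            full = np.concatenate([np.stack(chans), onehot], axis=0)
            crop = np.zeros((10, tubule_crop_px, tubule_crop_px), dtype=np.float32)
            r0 = int(round(patch.center_local[0])) - tubule_crop_px // 2
            c0 = int(round(patch.center_local[1])) - tubule_crop_px // 2
            rs, re = max(r0, 0), min(r0 + tubule_crop_px, full.shape[1])
            cs, ce = max(c0, 0), min(c0 + tubule_crop_px, full.shape[2])
            crop[:, rs - r0 : re - r0, cs - c0 : ce - c0] = full[:, rs:re, cs:ce]
            small = crop.reshape(10, tubule_out_px, factor, tubule_out_px, factor).mean(
                axis=(2, 4)
            )
            tubule_x.append(small.astype(np.float32))
            tubule_y.append(stage.value - 1)
            stage_quota[stage] -= 1

    out = {
        "cell_x": np.stack(cell_x)[:, None] if cell_x else np.zeros((0, 1, cell_patch_px, cell_patch_px)),
        "cell_y": np.array(cell_y, dtype=np.int64),
        "cell_labels": [t.label for t in CELL_TYPES],
    }
    if include_tubules:
        out["tubule_x"] = (
            np.stack(tubule_x)
            if tubule_x
            else np.zeros((0, 10, tubule_out_px, tubule_out_px))
        )
        out["tubule_y"] = np.array(tubule_y, dtype=np.int64)
        out["stage_labels"] = [s.name for s in STAGES]
    return out
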