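"""Per-nucleus spatial statistics and per-tubule indices.

Apical-basal position (ABP) locates a nucleus between the tubule edge
(basal, 0) and the tubule centroid (apical, 1) as
``d_edge / (d_edge + d_center)``. Relative orientation is the acute
angle between the nucleus's (undirected) major axis and the radial
vector to the tubule centroid: 0° means a radially aligned nucleus, 90°
a circumferential one.

Nearest-neighbor networks connect every reference nucleus to the nearest
nucleus of each *other* cell type within the same tubule; pooled
summaries report per-tubule-normalized single-nearest-target counts and
mean Euclidean / signed-radial (ABP difference) distances per type pair.

The spermatogenic index of a tubule is its eSPD:SPG count ratio — about
four under ideal meiosis (one spermatogonium → four spermatids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .segmentation import equivalent_radius_um
from .types import CELL_TYPES, CellType, LabelMask, NucleusRecord

__all__ = [
    "apical_basal_position",
    "abp_for_tubule",
    "relative_orientation",
    "NeighborEdge",
    "nearest_neighbor_network",
    "NeighborSummary",
    "neighbor_summary",
    "spermatogenic_index",
    "tubule_lumen_radii",
    "summarize_tubule",
    "filter_improbable_classes",
]


def abp_for_tubule(
    centroids: np.ndarray, tubule_centroid: tuple[float, float], tubule_mask: np.ndarray
) -> np.ndarray:
    """ABP for many nuclei of one tubule (computes the edge map once).

    ``tubule_mask`` is the boolean mask of one tubule; every centroid
    must fall inside it.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    mask = np.asarray(tubule_mask, dtype=bool)
    d_edge_map = ndi.distance_transform_edt(mask)
    rows = np.clip(np.round(centroids[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(centroids[:, 1]).astype(int), 0, mask.shape[1] - 1)
    if not mask[rows, cols].all():
        raise ValueError("nucleus centroid outside the tubule mask")
    d_edge = d_edge_map[rows, cols].astype(float)
    d_center = np.hypot(
        centroids[:, 0] - tubule_centroid[0], centroids[:, 1] - tubule_centroid[1]
    )
    denom = d_edge + d_center
    out = np.where(denom > 0, d_edge / np.where(denom > 0, denom, 1.0), 1.0)
    return out


def apical_basal_position(
    nucleus_centroid: tuple[float, float],
    tubule_centroid: tuple[float, float],
    tubule_mask: np.ndarray,
) -> float:
    """ABP of one nucleus: 0 at the tubule edge, 1 at the tubule centroid."""
    return float(abp_for_tubule(np.array([nucleus_centroid]), tubule_centroid, tubule_mask)[0])


def _vector_angle_deg(dr: float, dc: float) -> float:
    """Angle of an image-space vector, counter-clockwise from +col, degrees."""
    return math.degrees(math.atan2(-dr, dc))


def relative_orientation(
    major_axis_deg: float,
    nucleus_centroid: tuple[float, float],
    tubule_centroid: tuple[float, float],
) -> float:
    """Acute angle (0–90°) between the nucleus major axis and the radial vector.

    0° = radially aligned (along the apical-basal axis), 90° =
    circumferential. The major axis is undirected, so the angle is folded
    into [0, 90].
    """
    dr = tubule_centroid[0] - nucleus_centroid[0]
    dc = tubule_centroid[1] - nucleus_centroid[1]
    if dr == 0 and dc == 0:
        raise ValueError("nucleus and tubule centroids coincide")
    radial = _vector_angle_deg(dr, dc)
    diff = abs(major_axis_deg - radial) % 180.0
    return min(diff, 180.0 - diff)


@dataclass
class NeighborEdge:
    """One reference→target nearest-neighbor link within a tubule.

    ``radial_signed`` is ABP(target) − ABP(reference): positive when the
    target sits more apically than the reference.
    """

    reference_id: int
    target_id: int
    reference_type: CellType
    target_type: CellType
    euclidean_px: float
    radial_signed: float

    def __post_init__(self) -> None:
        if self.reference_id == self.target_id:
            raise ValueError("an edge cannot connect a nucleus to itself")
        if not self.euclidean_px > 0:
            raise ValueError("euclidean_px must be positive")


def nearest_neighbor_network(nuclei: list[NucleusRecord]) -> list[NeighborEdge]:
    """For each reference nucleus, the nearest nucleus of every other type.

    All records must belong to one tubule. Types absent from the tubule
    simply produce no edge (missing, not zero).
    """
    if not nuclei:
        return []
    tubules = {r.tubule_id for r in nuclei}
    if len(tubules) > 1:
        raise ValueError("nearest_neighbor_network expects nuclei of a single tubule")
    by_type: dict[CellType, list[NucleusRecord]] = {}
    for r in nuclei:
        by_type.setdefault(r.call, []).append(r)
    coords = {t: np.array([r.centroid for r in rs]) for t, rs in by_type.items()}
    edges: list[NeighborEdge] = []
    for ref in nuclei:
        ref_xy = np.asarray(ref.centroid, dtype=float)[None]
        for t, rs in by_type.items():
            if t == ref.call:
                continue
            d = cdist(ref_xy, coords[t])[0]
            j = int(np.argmin(d))
            target = rs[j]
            edges.append(
                NeighborEdge(
                    reference_id=ref.id,
                    target_id=target.id,
                    reference_type=ref.call,
                    target_type=t,
                    euclidean_px=float(d[j]),
                    radial_signed=float(target.abp - ref.abp),
                )
            )
    return edges


@dataclass
class NeighborSummary:
    """7×7 matrices over (reference type, target type) pairs.

    ``pair_counts``: per-tubule-normalized counts of each reference's
    single overall-nearest target type; ``mean_euclidean_px`` /
    ``mean_radial_signed``: means over all type-pair edges. Missing pairs
    are NaN.
    """

    pair_counts: pd.DataFrame
    mean_euclidean_px: pd.DataFrame
    mean_radial_signed: pd.DataFrame


def neighbor_summary(edges: list[NeighborEdge], n_tubules: int) -> NeighborSummary:
    if n_tubules <= 0:
        raise ValueError("n_tubules must be positive")
    labels = [t.label for t in CELL_TYPES]
    counts = np.zeros((7, 7))
    dist_sum = np.zeros((7, 7))
    rad_sum = np.zeros((7, 7))
    n_edges = np.zeros((7, 7))
    # single overall-nearest target per reference nucleus
    best: dict[int, NeighborEdge] = {}
    for e in edges:
        cur = best.get(e.reference_id)
        if cur is None or e.euclidean_px < cur.euclidean_px:
            best[e.reference_id] = e
    for e in best.values():
        counts[int(e.reference_type), int(e.target_type)] += 1
    for e in edges:
        i, j = int(e.reference_type), int(e.target_type)
        n_edges[i, j] += 1
        dist_sum[i, j] += e.euclidean_px
        rad_sum[i, j] += e.radial_signed
    with np.errstate(invalid="ignore"):
        mean_d = np.where(n_edges > 0, dist_sum / np.maximum(n_edges, 1), np.nan)
        mean_r = np.where(n_edges > 0, rad_sum / np.maximum(n_edges, 1), np.nan)
    pair = counts / n_tubules

    def df(m):
        return pd.DataFrame(m, index=labels, columns=labels)
    return NeighborSummary(df(pair), df(mean_d), df(mean_r))


def spermatogenic_index(counts: dict[CellType, int]) -> float:
    """eSPD:SPG count ratio of one tubule; NaN when the tubule has no SPG."""
    spg = counts.get(CellType.SPG, 0)
    if spg == 0:
        return float("nan")
    return counts.get(CellType.ESPD, 0) / spg


def tubule_lumen_radii(
    tubule_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    um_per_px: float,
    threshold_frac: float = 0.5,
) -> tuple[float, float, float]:
    """(tubule radius µm, lumen radius µm, lumen:tubule ratio).

    The lumen is located at the point of maximal distance-to-nearest-
    nucleus inside the tubule. Thresholding the distance map at
    ``threshold_frac`` of that maximum yields the lumen core — the lumen
    eroded by ``threshold_frac·max`` — so the equivalent radius of the
    core plus the erosion depth estimates the lumen radius. A tubule
    without nuclei degenerates to lumen ≈ tubule, ratio ≈ 1.
    """
    tub = np.asarray(tubule_mask, dtype=bool)
    area = int(tub.sum())
    if area == 0:
        raise ValueError("tubule mask is empty")
    tubule_radius = equivalent_radius_um(area, um_per_px)
    nuc = np.asarray(nucleus_mask) > 0
    if not (nuc & tub).any():
        return tubule_radius, tubule_radius, 1.0
    dist = ndi.distance_transform_edt(~nuc)
    dist = np.where(tub, dist, 0.0)
    m = dist.max()
    if m <= 0:
        return tubule_radius, 0.0, 0.0
    core = dist >= threshold_frac * m
    lab, _ = ndi.label(core)
    peak = np.unravel_index(int(np.argmax(dist)), dist.shape)
    core_area = int((lab == lab[peak]).sum())
    # the core is the lumen eroded by frac*m, so adding the erosion depth
    # back recovers the free radius of a compact lumen; when the
    # nucleus-free space is a connected labyrinth instead, that equivalent
    # radius overshoots, and the peak free distance (radius of the largest
    # inscribed nucleus-free disk) is the honest bound
    lumen_radius_px = min(math.sqrt(core_area / math.pi) + threshold_frac * m, m)
    lumen_radius = min(lumen_radius_px * um_per_px, tubule_radius)
    return tubule_radius, lumen_radius, lumen_radius / tubule_radius


def summarize_tubule(
    nuclei: list[NucleusRecord],
    tubule_mask: np.ndarray,
    nucleus_mask: np.ndarray | None,
    um_per_px: float,
) -> dict:
    """Composition summary for one tubule (counts, index, radii).

    ``nuclei`` are the retained (post-LCF, if enabled) intratubular
    records of this tubule; geometry comes from the masks. Returns a dict
    of TubuleRecord fields (stage fields are filled by the classifier).
    """
    counts = {t: 0 for t in CELL_TYPES}
    for r in nuclei:
        counts[r.call] += 1
    if nucleus_mask is None:
        nucleus_mask = np.zeros_like(np.asarray(tubule_mask), dtype=np.int32)
    tubule_radius, lumen_radius, ratio = tubule_lumen_radii(
        tubule_mask, nucleus_mask, um_per_px
    )
    return {
        "counts": counts,
        "spermatogenic_index": spermatogenic_index(counts),
        "equiv_radius_um": tubule_radius,
        "lumen_radius_um": lumen_radius,
        "lumen_to_tubule_ratio": ratio,
        "n_nuclei": len(nuclei),
    }


def filter_improbable_classes(
    records: list[NucleusRecord], allowed_types: set[CellType]
) -> list[NucleusRecord]:
    """Restrict calls to biologically plausible classes and renormalize.

    Used for genotypes that cannot contain certain classes (e.g. meiotic
    arrest lacks post-meiotic cells): records *called* outside
    ``allowed_types`` are dropped; retained records have the disallowed
    probability components zeroed, the rest renormalized to sum 1, and
    the call recomputed.
    """
    if not allowed_types:
        raise ValueError("allowed_types must be non-empty")
    allowed_idx = np.array([int(t) for t in allowed_types])
    keep_mask = np.zeros(len(CELL_TYPES), dtype=bool)
    keep_mask[allowed_idx] = True
    out: list[NucleusRecord] = []
    for r in records:
        if r.call not in allowed_types:
            continue
        probs = np.where(keep_mask, r.probs, 0.0)
        s = probs.sum()
        if s <= 0:
            continue
        probs = probs / s
        out.append(
            NucleusRecord.from_probs(
                probs,
                id=r.id,
                tubule_id=r.tubule_id,
                centroid=r.centroid,
                area_px=r.area_px,
                major_axis_px=r.major_axis_px,
                minor_axis_px=r.minor_axis_px,
                orientation_deg=r.orientation_deg,
                abp=r.abp,
                rel_orientation_deg=r.rel_orientation_deg,
            )
        )
    return out
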