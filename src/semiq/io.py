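"""Image, mask and record-table I/O.

Channel stacks are multi-page TIFFs (one page per channel); when this
package writes a stack it records the channel order and pixel scale in
the TIFF description so the file can be re-read without an explicit
channel map. Record tables are UTF-8 CSV with one row per object and
probability vectors expanded into named ``prob_*`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

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
    stage_from_label,
)

__all__ = [
    "read_channel_stack",
    "write_channel_stack",
    "read_label_mask",
    "write_label_mask",
    "read_records",
    "write_records",
]


def read_channel_stack(
    path: str | Path,
    channel_map: dict[int, str] | None = None,
    um_per_px: float | None = None,
    source_id: str | None = None,
) -> ChannelStack:
    """Read a single- or multi-page TIFF into a named ChannelStack.

    ``channel_map`` assigns page indices to channel names, e.g.
    ``{0: "hoechst", 1: "acta2", 2: "acrv1"}``. If omitted, the mapping is
    taken from metadata written by :func:`write_channel_stack`. A stack
    without a ``hoechst`` channel is an error (every downstream stage
    needs the nuclear channel); other channels are optional.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = []
        for p in tf.pages:
            arr = p.asarray()
            # a (C, H, W) plane stack stored in one page counts as C pages
            if arr.ndim == 3:
                pages.extend(arr)
            else:
                pages.append(arr)
        description = tf.pages[0].description or ""
    meta: dict = {}
    if description:
        try:
            meta = json.loads(description)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        names = meta.get("channels")
        if not names:
            raise ValueError(
                f"{path}: no channel_map given and no channel metadata in the file"
            )
        channel_map = dict(enumerate(names))
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: pages differ in shape: {sorted(shapes)}")
    channels: dict[str, np.ndarray] = {}
    for idx, name in channel_map.items():
        if idx >= len(pages):
            raise ValueError(f"{path}: channel_map index {idx} beyond {len(pages)} pages")
        channels[name] = np.asarray(pages[idx])
    if "hoechst" not in channels:
        raise ValueError(f"{path}: a 'hoechst' (nuclear) channel is required")
    if um_per_px is None:
        um_per_px = float(meta.get("um_per_px", 0.17))
    if source_id is None:
        source_id = meta.get("source_id", path.stem)
    return ChannelStack(channels=channels, um_per_px=um_per_px, source_id=source_id)


def write_channel_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a ChannelStack as a multi-page TIFF with JSON metadata."""
    path = Path(path)
    names = sorted(stack.channels, key=lambda n: (n != "hoechst", n))
    meta = {"channels": names, "um_per_px": stack.um_per_px, "source_id": stack.source_id}
    data = np.stack([stack.channels[n] for n in names])
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric='minisblack')
    return path


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    labels = mask.labels
    dtype = np.uint16 if mask.n_labels < 2**16 else np.uint32
    tifffile.imwrite(Path(path), labels.astype(dtype), description=json.dumps({"kind": mask.kind}))
    return Path(path)


def read_label_mask(path: str | Path, kind: str | None = None) -> LabelMask:
    with tifffile.TiffFile(Path(path)) as tf:
        labels = tf.pages[0].asarray()
        description = tf.pages[0].description or ""
    if kind is None:
        try:
            kind = json.loads(description)["kind"]
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(f"{path}: mask kind not stored in file; pass kind=") from None
    return LabelMask(labels.astype(np.int32), kind)


# ---------------------------------------------------------------------------
# record tables

_NUCLEUS_SCALARS = [
    "id",
    "tubule_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "major_axis_px",
    "minor_axis_px",
    "orientation_deg",
    "abp",
    "rel_orientation_deg",
]
_NUCLEUS_PROBS = [f"prob_{t.label}" for t in CELL_TYPES]
_TUBULE_SCALARS = [
    "id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "circularity",
    "equiv_radius_um",
    "lumen_radius_um",
    "spermatogenic_index",
    "touches_border",
]
_TUBULE_PROBS = [f"prob_{s.name}" for s in STAGES]
_TUBULE_COUNTS = [f"count_{t.label}" for t in CELL_TYPES]


def records_to_frame(records: list) -> pd.DataFrame:
    """Convert a homogeneous list of records to a DataFrame."""
    if not records:
        raise ValueError("cannot infer record kind from an empty list; use write_records(kind=)")
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError("mixed record kinds")
    if kinds == {NucleusRecord}:
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "tubule_id": r.tubule_id,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area_px,
                "major_axis_px": r.major_axis_px,
                "minor_axis_px": r.minor_axis_px,
                "orientation_deg": r.orientation_deg,
                "abp": r.abp,
                "rel_orientation_deg": r.rel_orientation_deg,
            }
            row.update({c: p for c, p in zip(_NUCLEUS_PROBS, r.probs)})
            row["call"] = r.call.label
            row["confidence"] = r.confidence
            rows.append(row)
        return pd.DataFrame(rows, columns=_NUCLEUS_SCALARS + _NUCLEUS_PROBS + ["call", "confidence"])
    if kinds == {TubuleRecord}:
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area_px,
                "circularity": r.circularity,
                "equiv_radius_um": r.equiv_radius_um,
                "lumen_radius_um": r.lumen_radius_um,
                "spermatogenic_index": r.spermatogenic_index,
                "touches_border": r.touches_border,
            }
            row.update({c: p for c, p in zip(_TUBULE_PROBS, r.stage_probs)})
            row["stage_call"] = r.stage_call.name
            row["confidence"] = r.confidence
            row.update({f"count_{t.label}": r.counts.get(t, 0) for t in CELL_TYPES})
            rows.append(row)
        cols = _TUBULE_SCALARS + _TUBULE_PROBS + ["stage_call", "confidence"] + _TUBULE_COUNTS
        return pd.DataFrame(rows, columns=cols)
    raise ValueError(f"unsupported record type {kinds.pop().__name__}")


def write_records(records: list, path: str | Path, kind: str | None = None) -> Path:
    """Write NucleusRecords or TubuleRecords as CSV (round-trip safe to 1e-9)."""
    path = Path(path)
    if not records:
        if kind == "tubule":
            cols = _TUBULE_SCALARS + _TUBULE_PROBS + ["stage_call", "confidence"] + _TUBULE_COUNTS
        elif kind == "nucleus":
            cols = _NUCLEUS_SCALARS + _NUCLEUS_PROBS + ["call", "confidence"]
        else:
            raise ValueError("empty record list: pass kind='nucleus' or kind='tubule'")
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path
    records_to_frame(records).to_csv(path, index=False)
    return path


def _renorm(p: np.ndarray) -> np.ndarray:
    # CSV round-trips floats exactly (pandas writes repr); the renorm only
    # guards against files produced by other tools.
    s = p.sum()
    if s <= 0:
        raise ValueError("probability columns must have positive sum")
    return p / s if abs(s - 1.0) > 1e-9 else p


def read_records(path: str | Path) -> list:
    """Read a record CSV back into NucleusRecord / TubuleRecord objects."""
    df = pd.read_csv(Path(path))
    cols = set(df.columns)
    if "stage_call" in cols:
        missing = set(_TUBULE_SCALARS + _TUBULE_PROBS) - cols
        if missing:
            raise ValueError(f"{path}: missing tubule columns {sorted(missing)}")
        out = []
        for _, row in df.iterrows():
            probs = _renorm(np.array([row[c] for c in _TUBULE_PROBS], dtype=float))
            counts = {t: int(row.get(f"count_{t.label}", 0)) for t in CELL_TYPES}
            out.append(
                TubuleRecord(
                    id=int(row["id"]),
                    centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                    area_px=float(row["area_px"]),
                    circularity=float(row["circularity"]),
                    equiv_radius_um=float(row["equiv_radius_um"]),
                    lumen_radius_um=float(row["lumen_radius_um"]),
                    stage_probs=probs,
                    stage_call=stage_from_label(str(row["stage_call"])),
                    confidence=float(probs.max()),
                    counts=counts,
                    spermatogenic_index=float(row["spermatogenic_index"]),
                    touches_border=bool(row["touches_border"]),
                )
            )
        return out
    if "call" in cols:
        missing = set(_NUCLEUS_SCALARS + _NUCLEUS_PROBS) - cols
        if missing:
            raise ValueError(f"{path}: missing nucleus columns {sorted(missing)}")
        out = []
        for _, row in df.iterrows():
            probs = _renorm(np.array([row[c] for c in _NUCLEUS_PROBS], dtype=float))
            out.append(
                NucleusRecord(
                    id=int(row["id"]),
                    tubule_id=int(row["tubule_id"]),
                    centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                    area_px=float(row["area_px"]),
                    major_axis_px=float(row["major_axis_px"]),
                    minor_axis_px=float(row["minor_axis_px"]),
                    orientation_deg=float(row["orientation_deg"]),
                    abp=float(row["abp"]),
                    rel_orientation_deg=float(row["rel_orientation_deg"]),
                    probs=probs,
                    call=cell_type_from_label(str(row["call"])),
                    confidence=float(probs.max()),
                )
            )
        return out
    if df.empty:
        return []
    raise ValueError(f"{path}: neither a nucleus nor a tubule record table")
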