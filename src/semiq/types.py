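"""Domain types shared by every stage of the pipeline.

The vocabulary here mirrors mouse testis histology: a cross-section shows
seminiferous tubules (ring of smooth muscle marked by Acta2) containing
germ cells at concentric apical-basal positions, plus interstitial nuclei
between tubules. Cell types and tubule stages are fixed, ordered
enumerations; the order also fixes the component order of every
probability vector produced by the classifiers, so it must never change
once a model has been trained.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Channel names the pipeline understands. ``hoechst`` (DNA, all nuclei),
#: ``acta2`` (peritubular smooth muscle, tubule boundary) and ``acrv1``
#: (acrosome, spermatids) are required by at least one stage; extra names
#: may be registered by callers.
CHANNEL_REGISTRY: set[str] = {"hoechst", "acta2", "acrv1", "sox9", "brightfield"}

PROB_SUM_TOL = 1e-6


class CellType(enum.IntEnum):
    """The seven intratubular nucleus classes, in canonical order.

    Sertoli (somatic support cell), SPG (spermatogonia), SPC / SPCII
    (primary / secondary spermatocytes) and the round, intermediate and
    elongated spermatids (rSPD, iSPD, eSPD).
    """

    SERTOLI = 0
    SPG = 1
    SPC = 2
    SPCII = 3
    RSPD = 4
    ISPD = 5
    ESPD = 6

    @property
    def label(self) -> str:
        return _CELL_LABELS[self]


_CELL_LABELS = {
    CellType.SERTOLI: "Sertoli",
    CellType.SPG: "SPG",
    CellType.SPC: "SPC",
    CellType.SPCII: "SPCII",
    CellType.RSPD: "rSPD",
    CellType.ISPD: "iSPD",
    CellType.ESPD: "eSPD",
}

CELL_TYPES: tuple[CellType, ...] = tuple(CellType)
CELL_TYPE_LABELS: tuple[str, ...] = tuple(t.label for t in CELL_TYPES)


def cell_type_from_label(label: str) -> CellType:
    for t in CELL_TYPES:
        if t.label == label:
            return t
    raise ValueError(f"unknown cell type label {label!r}")


class Stage(enum.IntEnum):
    """The twelve cyclic seminiferous epithelium stages (I..XII).

    Stage XII is cyclically adjacent to stage I: the epithelium cycles
    through the twelve cellular associations repeatedly.
    """

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6
    VII = 7
    VIII = 8
    IX = 9
    X = 10
    XI = 11
    XII = 12

    @property
    def label(self) -> str:
        return self.name

    @property
    def successor(self) -> "Stage":
        return Stage(self.value % 12 + 1)

    @staticmethod
    def cyclic_distance(a: "Stage", b: "Stage") -> int:
        d = abs(int(a) - int(b)) % 12
        return min(d, 12 - d)


STAGES: tuple[Stage, ...] = tuple(Stage)
STAGE_LABELS: tuple[str, ...] = tuple(s.name for s in STAGES)


def stage_from_label(label: str) -> Stage:
    try:
        return Stage[label]
    except KeyError:
        raise ValueError(f"unknown stage label {label!r}") from None


@dataclass
class ChannelStack:
    """A named multi-channel 2D image at a known physical pixel scale.

    All channels share one shape; intensities are finite and non-negative.
    Channels are identified by name (not index) because microscope export
    order varies between instruments.
    """

    channels: dict[str, np.ndarray]
    um_per_px: float = 0.17
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        shapes = set()
        for name, arr in self.channels.items():
            if name not in CHANNEL_REGISTRY:
                raise ValueError(f"unknown channel name {name!r}; register it in CHANNEL_REGISTRY")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(arr)) or (arr.size and arr.min() < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class LabelMask:
    """Integer instance-segmentation mask; 0 is background."""

    labels: np.ndarray
    kind: str  # "nucleus" | "tubule"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.kind not in ("nucleus", "tubule"):
            raise ValueError(f"kind must be 'nucleus' or 'tubule', got {self.kind!r}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def compact(self) -> "LabelMask":
        """Relabel positive labels to a contiguous 1..N, preserving order."""
        present = np.unique(self.labels)
        present = present[present > 0]
        lut = np.zeros(int(self.labels.max(initial=0)) + 1, dtype=self.labels.dtype)
        lut[present] = np.arange(1, len(present) + 1, dtype=self.labels.dtype)
        return LabelMask(lut[self.labels], self.kind)


def _check_probs(probs: np.ndarray, n: int, what: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (n,):
        raise ValueError(f"{what} must have shape ({n},)")
    if probs.min() < 0:
        raise ValueError(f"{what} must be non-negative")
    if abs(probs.sum() - 1.0) > PROB_SUM_TOL:
        raise ValueError(f"{what} must sum to 1 within {PROB_SUM_TOL}")
    return probs


@dataclass
class NucleusRecord:
    """One segmented nucleus with geometry, position metrics and its call.

    ``abp`` (apical-basal position) runs from 0 at the tubule edge (basal)
    to 1 at the tubule centroid (apical); it and ``rel_orientation_deg``
    are NaN for extratubular nuclei (``tubule_id == 0``).
    """

    id: int
    tubule_id: int
    centroid: tuple[float, float]  # (row, col)
    area_px: float
    major_axis_px: float
    minor_axis_px: float
    orientation_deg: float
    abp: float
    rel_orientation_deg: float
    probs: np.ndarray
    call: CellType
    confidence: float

    def __post_init__(self) -> None:
        self.probs = _check_probs(self.probs, len(CELL_TYPES), "probs")
        if self.call != CellType(int(np.argmax(self.probs))):
            raise ValueError("call must equal argmax(probs)")
        if abs(self.confidence - float(self.probs.max())) > PROB_SUM_TOL:
            raise ValueError("confidence must equal max(probs)")
        if not -90.0 <= self.orientation_deg < 90.0:
            raise ValueError("orientation_deg must lie in [-90, 90)")
        if self.tubule_id == 0:
            if not (np.isnan(self.abp) and np.isnan(self.rel_orientation_deg)):
                raise ValueError("extratubular nuclei must have NaN abp / rel_orientation")
        else:
            if not 0.0 <= self.abp <= 1.0:
                raise ValueError("abp must lie in [0, 1]")
            if not 0.0 <= self.rel_orientation_deg <= 90.0:
                raise ValueError("rel_orientation_deg must lie in [0, 90]")

    @classmethod
    def from_probs(cls, probs: np.ndarray, **kw) -> "NucleusRecord":
        probs = np.asarray(probs, dtype=float)
        return cls(
            probs=probs,
            call=CellType(int(np.argmax(probs))),
            confidence=float(probs.max()),
            **kw,
        )


@dataclass
class TubuleRecord:
    """One retained tubule: geometry, stage call, composition and indices.

    ``spermatogenic_index`` is the eSPD:SPG count ratio (≈4 under ideal
    meiosis, one spermatogonium yielding four spermatids); it is NaN when
    the tubule contains no SPG.
    """

    id: int
    centroid: tuple[float, float]
    area_px: float
    circularity: float
    equiv_radius_um: float
    lumen_radius_um: float
    stage_probs: np.ndarray
    stage_call: Stage
    confidence: float
    counts: dict[CellType, int] = field(default_factory=dict)
    spermatogenic_index: float = float("nan")
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.stage_probs = _check_probs(self.stage_probs, len(STAGES), "stage_probs")
        if self.stage_call != STAGES[int(np.argmax(self.stage_probs))]:
            raise ValueError("stage_call must equal argmax(stage_probs)")
        if abs(self.confidence - float(self.stage_probs.max())) > PROB_SUM_TOL:
            raise ValueError("confidence must equal max(stage_probs)")
        self.counts = {CellType(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.lumen_radius_um > self.equiv_radius_um * (1 + 1e-9):
            raise ValueError("lumen radius cannot exceed tubule radius")

    @property
    def lumen_to_tubule_ratio(self) -> float:
        if self.equiv_radius_um <= 0:
            return float("nan")
        return min(1.0, self.lumen_radius_um / self.equiv_radius_um)
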