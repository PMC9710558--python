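"""Patch extraction, residual-CNN classifiers and evaluation.

Two classifiers are trained: a 7-class cell-type classifier on 64×64
normalized-Hoechst patches centered on each nucleus centroid, and a
12-stage tubule classifier on 2000×2000 crops downsampled to 500×500
with ten channels (Hoechst, Acta2, Acrv1, plus seven per-class
probability layers rendered from the cell classifier's output over each
nucleus footprint). Patches exceeding the image boundary are zero-padded.

Calls below an 80% confidence threshold can be filtered out (LCF);
stage evaluation additionally reports the within-±1 cyclic accuracy,
where stage s also matches s−1 and s+1 modulo 12 (XII is adjacent to I).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .types import (
    CELL_TYPES,
    STAGES,
    CellType,
    ChannelStack,
    LabelMask,
    NucleusRecord,
    Stage,
)

__all__ = [
    "ClassifierSpec",
    "EvaluationResult",
    "extract_cell_patch",
    "render_cell_prob_map",
    "extract_tubule_patch",
    "build_classifier",
    "train_classifier",
    "classify",
    "filter_low_confidence",
    "evaluate",
    "save_classifier",
    "load_classifier",
    "downsample_mean",
]


@dataclass
class ClassifierSpec:
    """Architecture + training hyperparameters, persisted with the weights."""

    task: str  # "cell" | "tubule"
    input_size_px: int
    n_input_channels: int
    n_classes: int
    backbone_depth: int = 50
    base_width: int = 64
    learn_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    augment: bool = True
    #: random per-patch intensity scaling during training; robust for the
    #: brightness-cued cell task, off for the stage task whose probability
    #: layers carry calibrated values
    augment_intensity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("cell", "tubule"):
            raise ValueError(f"task must be 'cell' or 'tubule', got {self.task!r}")
        expected = len(CELL_TYPES) if self.task == "cell" else len(STAGES)
        if self.n_classes != expected:
            raise ValueError(f"{self.task} task requires {expected} classes")
        if self.input_size_px <= 0 or self.n_input_channels <= 0:
            raise ValueError("input sizes must be positive")

    @classmethod
    def for_cells(cls, **kw) -> "ClassifierSpec":
        kw.setdefault("input_size_px", 64)
        return cls(task="cell", n_input_channels=1, n_classes=len(CELL_TYPES), **kw)

    @classmethod
    def for_tubules(cls, **kw) -> "ClassifierSpec":
        kw.setdefault("input_size_px", 500)
        kw.setdefault("augment_intensity", False)
        return cls(task="tubule", n_input_channels=10, n_classes=len(STAGES), **kw)

    @property
    def class_labels(self) -> tuple[str, ...]:
        if self.task == "cell":
            return tuple(t.label for t in CELL_TYPES)
        return tuple(s.name for s in STAGES)


# ---------------------------------------------------------------------------
# patch extraction

def _crop_padded(image: np.ndarray, center_rc: tuple[float, float], size: int) -> np.ndarray:
    """size×size crop centered at the rounded center, zero-padded at borders."""
    h, w = image.shape
    r0 = int(round(center_rc[0])) - size // 2
    c0 = int(round(center_rc[1])) - size // 2
    out = np.zeros((size, size), dtype=np.float32)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return out


def extract_cell_patch(
    stack: ChannelStack, centroid: tuple[float, float], size_px: int = 64
) -> np.ndarray:
    """64×64 normalized-Hoechst patch centered on a nucleus centroid.

    ``stack`` must carry the (top-hat normalized) ``hoechst`` channel;
    values are rescaled to [0, 1] by the source image maximum so that
    relative brightness between nuclei is preserved across patches.
    """
    hoechst = stack["hoechst"]
    h, w = hoechst.shape
    if not (0 <= centroid[0] < h and 0 <= centroid[1] < w):
        raise ValueError(f"centroid {centroid} outside image of shape {(h, w)}")
    patch = _crop_padded(hoechst, centroid, size_px)
    peak = float(hoechst.max())
    if peak > 0:
        patch = patch / peak
    return patch


def render_cell_prob_map(
    nucleus_mask: LabelMask, records: list[NucleusRecord], shape: tuple[int, int] | None = None
) -> np.ndarray:
    """(7, H, W) map with each nucleus footprint filled by its class probabilities."""
    if shape is None:
        shape = nucleus_mask.shape
    out = np.zeros((len(CELL_TYPES),) + tuple(shape), dtype=np.float32)
    if not records:
        return out
    prob_lut = np.zeros((nucleus_mask.n_labels + 1, len(CELL_TYPES)), dtype=np.float32)
    for r in records:
        if 0 < r.id <= nucleus_mask.n_labels:
            prob_lut[r.id] = r.probs
    rendered = prob_lut[nucleus_mask.labels]  # (H, W, 7)
    return np.moveaxis(rendered, -1, 0)


def downsample_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downsampling by an integer factor over the last two axes."""
    *lead, h, w = arr.shape
    if h % factor or w % factor:
        raise ValueError(f"shape {(h, w)} not divisible by factor {factor}")
    return arr.reshape(*lead, h // factor, factor, w // factor, factor).mean(axis=(-3, -1))


def extract_tubule_patch(
    stack: ChannelStack,
    cell_prob_map: np.ndarray,
    tubule_centroid: tuple[float, float],
    crop_px: int = 2000,
    out_px: int = 500,
    tubule_mask: np.ndarray | None = None,
) -> np.ndarray:
    """10-channel tubule patch: crop_px crop around the centroid, downsampled.

    Channel order: hoechst, acta2, acrv1, then the seven per-type
    probability layers. Intensity channels are scaled to [0, 1] by their
    source-image maxima; probability channels are already in [0, 1].
    ``tubule_mask`` (boolean, image-shaped) isolates the tubule: content
    outside it — neighboring tubules in a dense section — is zeroed, the
    role the Acta2 boundary plays when isolating individual tubules.
    """
    for name in ("hoechst", "acta2", "acrv1"):
        if name not in stack:
            raise ValueError(f"tubule patches require channel {name!r}")
    if cell_prob_map.shape != (len(CELL_TYPES),) + stack.shape:
        raise ValueError(
            f"cell_prob_map shape {cell_prob_map.shape} does not match "
            f"stack shape {stack.shape}"
        )
    if crop_px % out_px:
        raise ValueError("crop_px must be an integer multiple of out_px")
    factor = crop_px // out_px
    mask_crop = None
    if tubule_mask is not None:
        if tubule_mask.shape != stack.shape:
            raise ValueError("tubule_mask shape does not match the stack")
        mask_crop = _crop_padded(tubule_mask.astype(np.float32), tubule_centroid, crop_px)
    channels = []
    for name in ("hoechst", "acta2", "acrv1"):
        img = stack[name]
        peak = float(img.max())
        crop = _crop_padded(img, tubule_centroid, crop_px)
        channels.append(crop / peak if peak > 0 else crop)
    for k in range(len(CELL_TYPES)):
        channels.append(_crop_padded(cell_prob_map[k], tubule_centroid, crop_px))
    patch = np.stack(channels)
    if mask_crop is not None:
        patch *= mask_crop[None]
    return downsample_mean(patch, factor).astype(np.float32)


# ---------------------------------------------------------------------------
# model lifecycle

def build_classifier(spec: ClassifierSpec) -> nn.ResNet:
    """Untrained residual network matching the ClassifierSpec (softmax head)."""
    return nn.build_resnet(
        depth=spec.backbone_depth,
        in_channels=spec.n_input_channels,
        n_classes=spec.n_classes,
        base_width=spec.base_width,
        input_size=spec.input_size_px,
        seed=spec.seed,
    )


def _coerce_patches(patches: np.ndarray, spec: ClassifierSpec) -> np.ndarray:
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4 or x.shape[1] != spec.n_input_channels:
        raise ValueError(
            f"patches must be (N, {spec.n_input_channels}, H, W); got {x.shape}"
        )
    h = x.shape[2]
    if h != spec.input_size_px:
        if h % spec.input_size_px == 0:
            x = downsample_mean(x, h // spec.input_size_px).astype(np.float32)
        else:
            raise ValueError(
                f"patch size {h} incompatible with model input {spec.input_size_px}"
            )
    return x


def train_classifier(
    model: nn.ResNet,
    patches: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    allow_missing_class: bool = False,
) -> tuple[nn.ResNet, list[dict]]:
    """Train in place; returns (model, per-epoch log).

    Labels are enumeration indices (0-based for cells; stage value − 1
    for tubules). A class with zero examples is an error unless
    ``allow_missing_class`` (needed when fine-tuning on mutants that
    genuinely lack post-meiotic classes).
    """
    labels = np.asarray(labels)
    if labels.dtype.kind not in "iu":
        raise ValueError("labels must be integer class indices")
    if len(patches) == 0:
        raise ValueError("empty training set")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    missing = set(range(spec.n_classes)) - set(present.tolist())
    if missing and not allow_missing_class:
        raise ValueError(
            f"classes without examples: {sorted(missing)}; "
            "pass allow_missing_class=True to proceed"
        )
    x = _coerce_patches(patches, spec)
    log = nn.train_network(
        model,
        x,
        labels,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        lr=spec.learn_rate,
        augment=spec.augment,
        intensity_jitter=spec.augment_intensity,
        seed=spec.seed,
    )
    return model, log


def classify(
    model: nn.ResNet, patches: np.ndarray, spec: ClassifierSpec, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(probability matrix, calls, confidences) for a batch of patches.

    The probability matrix is row-stochastic; calls are argmax indices
    (ties resolve to the lowest enumeration index) and confidence is the
    row maximum.
    """
    if len(patches) == 0:
        n = spec.n_classes
        return np.zeros((0, n)), np.zeros(0, dtype=int), np.zeros(0)
    x = _coerce_patches(np.asarray(patches), spec)
    probs = model.predict_proba(x, batch_size=batch_size).astype(np.float64)
    probs /= probs.sum(axis=1, keepdims=True)
    calls = probs.argmax(axis=1)
    conf = probs.max(axis=1)
    return probs, calls, conf


def save_classifier(model: nn.ResNet, spec: ClassifierSpec, directory: str | Path) -> Path:
    meta = {"spec": asdict(spec), "class_labels": list(spec.class_labels)}
    return nn.save_network(model, directory, extra_meta=meta)


def load_classifier(directory: str | Path) -> tuple[nn.ResNet, ClassifierSpec]:
    model, meta = nn.load_network(directory)
    spec = ClassifierSpec(**meta["spec"])
    stored = meta.get("class_labels")
    if stored is not None and tuple(stored) != spec.class_labels:
        raise ValueError(
            "stored class-label order does not match the current enumeration; "
            "refusing to classify with permuted labels"
        )
    return model, spec


# ---------------------------------------------------------------------------
# confidence filtering & evaluation

def filter_low_confidence(records: list, threshold: float = 0.80) -> tuple[list, float]:
    """Drop records below the confidence threshold (exactly 0.80 is kept).

    Returns (retained records, retention fraction); the fraction is NaN
    for empty input.
    """
    if not records:
        return [], float("nan")
    retained = [r for r in records if r.confidence >= threshold]
    return retained, len(retained) / len(records)


@dataclass
class EvaluationResult:
    """Confusion matrix (rows annotated, cols predicted) and derived rates."""

    confusion: np.ndarray
    accuracy: float
    per_class_tpr: np.ndarray
    per_class_fpr: np.ndarray
    per_class_ppv: np.ndarray
    class_labels: tuple[str, ...]
    confidence_histogram: np.ndarray | None = None  # 20 bins of width 5%
    within_1_cyclic_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        if (self.confusion < 0).any():
            raise ValueError("confusion entries must be non-negative")
        total = self.confusion.sum()
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-9:
            raise ValueError("accuracy must equal trace/total")


CONFIDENCE_BIN_EDGES = np.linspace(0.0, 1.0, 21)  # 5% bins, left-closed


def confidence_histogram(confidences: np.ndarray) -> np.ndarray:
    """Counts per 5% confidence bin [x, x+0.05); the last bin includes 1.0."""
    conf = np.asarray(confidences, dtype=float)
    idx = np.minimum((conf * 20).astype(int), 19)
    return np.bincount(idx, minlength=20)


def evaluate(
    true_labels: np.ndarray,
    predicted: np.ndarray,
    task: str,
    confidences: np.ndarray | None = None,
) -> EvaluationResult:
    """Confusion matrix, accuracy, per-class rates and (for tubules) the
    within-±1 cyclic stage accuracy."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    if task == "cell":
        n, labels = len(CELL_TYPES), tuple(t.label for t in CELL_TYPES)
    elif task == "tubule":
        n, labels = len(STAGES), tuple(s.name for s in STAGES)
    else:
        raise ValueError(f"unknown task {task!r}")
    if len(true_labels) and (
        true_labels.min() < 0 or true_labels.max() >= n or predicted.min() < 0 or predicted.max() >= n
    ):
        raise ValueError(f"labels must lie in [0, {n})")
    confusion = np.zeros((n, n), dtype=int)
    np.add.at(confusion, (true_labels, predicted), 1)
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total) if total else float("nan")
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    diag = np.diag(confusion)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row > 0, diag / row, np.nan)
        ppv = np.where(col > 0, diag / col, np.nan)
        fp = col - diag
        neg = total - row
        fpr = np.where(neg > 0, fp / neg, np.nan)
    within1 = None
    if task == "tubule" and total:
        d = np.abs(true_labels - predicted) % n
        within1 = float((np.minimum(d, n - d) <= 1).mean())
    hist = confidence_histogram(confidences) if confidences is not None else None
    return EvaluationResult(
        confusion=confusion,
        accuracy=accuracy,
        per_class_tpr=tpr,
        per_class_fpr=fpr,
        per_class_ppv=ppv,
        class_labels=labels,
        confidence_histogram=hist,
        within_1_cyclic_accuracy=within1,
    )
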