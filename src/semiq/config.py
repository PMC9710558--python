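"""Pipeline configuration with defaults matching the published protocol.

Defaults: top-hat disk radius 100 px, nucleus diameter 30 px (5 µm at
0.17 µm/px), tubule area window 0.5–3 × 10^6 px (≈ radii 68–166 µm),
circularity > 0.5, low-confidence filter at 80%, 64-px cell patches and
2000→500-px tubule patches.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    tophat_radius_px: int = 100
    nucleus_diameter_px: float = 30.0
    tubule_area_px_range: tuple[float, float] = (5e5, 3e6)
    circularity_min: float = 0.5
    lcf_threshold: float = 0.80
    cell_patch_px: int = 64
    tubule_patch_px: int = 2000
    tubule_patch_downsampled_px: int = 500
    um_per_px: float = 0.17
    seed: int = 0
    # tubule segmentation morphology (the protocol says only "a small
    # amount" of dilation; these are this package's defaults)
    tubule_dilation_px: int = 5
    tubule_opening_px: int = 15
    # lumen detection: fraction of the peak nucleus-free distance at
    # which the lumen core is thresholded
    lumen_threshold_frac: float = 0.5
    nucleus_backend: str = "auto"  # auto | builtin | external

    def __post_init__(self) -> None:
        self.tubule_area_px_range = tuple(self.tubule_area_px_range)  # type: ignore[assignment]
        positive = [
            ("tophat_radius_px", self.tophat_radius_px),
            ("nucleus_diameter_px", self.nucleus_diameter_px),
            ("circularity_min", self.circularity_min),
            ("cell_patch_px", self.cell_patch_px),
            ("tubule_patch_px", self.tubule_patch_px),
            ("tubule_patch_downsampled_px", self.tubule_patch_downsampled_px),
            ("um_per_px", self.um_per_px),
            ("tubule_dilation_px", self.tubule_dilation_px),
            ("tubule_opening_px", self.tubule_opening_px),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        lo, hi = self.tubule_area_px_range
        if not (0 < lo < hi):
            raise ValueError(f"tubule_area_px_range must satisfy 0 < low < high, got {lo}, {hi}")
        if not 0.0 < self.lcf_threshold < 1.0:
            raise ValueError(f"lcf_threshold must lie in (0, 1), got {self.lcf_threshold}")
        if not 0.0 < self.lumen_threshold_frac < 1.0:
            raise ValueError("lumen_threshold_frac must lie in (0, 1)")
        if self.nucleus_backend not in ("auto", "builtin", "external"):
            raise ValueError(f"unknown nucleus_backend {self.nucleus_backend!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tubule_area_px_range"] = list(self.tubule_area_px_range)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key-value file.

    Absent keys (or an absent file) fall back to the protocol defaults;
    unknown keys and invariant violations raise ``ValueError``.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        data.update(raw)
    data.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
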