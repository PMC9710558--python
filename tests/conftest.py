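import numpy as np
import pytest

from semiq import segmentation as seg
from semiq import synthetic as syn
from semiq.types import CELL_TYPES, CellType, NucleusRecord


@pytest.fixture(scope="session")
def wt_section():
    """Small wild-type synthetic section (4 tubules) with ground truth."""
    return syn.generate_section(syn.SectionBlueprint(n_tubules=4, seed=2))


@pytest.fixture(scope="session")
def wt_segmented(wt_section):
    """Builtin segmentation of the session section (computed once)."""
    norm = seg.normalize_intensity(wt_section.stack["hoechst"], 100)
    nucleus_mask = seg.segment_nuclei(norm, 30, backend="builtin")
    tubule_mask, report = seg.filter_tubules(
        seg.segment_tubules(wt_section.stack["acta2"])
    )
    return {
        "norm_hoechst": norm,
        "nucleus_mask": nucleus_mask,
        "tubule_mask": tubule_mask,
        "report": report,
    }


@pytest.fixture(scope="session")
def separable_patches():
    """Two-class separable patch set: bright vs dim Gaussian blobs."""
    rng = np.random.default_rng(0)

    def blob(bright):
        img = np.zeros((32, 32), np.float32)
        r, c = rng.integers(10, 22, 2)
        yy, xx = np.mgrid[0:32, 0:32]
        img += (0.9 if bright else 0.35) * np.exp(
            -(((yy - r) / 4) ** 2 + ((xx - c) / 4) ** 2) / 2
        )
        img += rng.normal(0, 0.02, (32, 32)).astype(np.float32)
        return np.clip(img, 0, None)

    x = np.stack([blob(i % 2 == 0) for i in range(160)])
    y = np.array([0 if i % 2 == 0 else 1 for i in range(160)])
    return x[:120], y[:120], x[120:], y[120:]


def make_nucleus(
    id=1,
    tubule_id=1,
    centroid=(0.0, 0.0),
    probs=None,
    call=CellType.SPC,
    abp=0.5,
    **kw,
):
    """Convenience NucleusRecord factory for tests."""
    if probs is None:
        probs = np.zeros(len(CELL_TYPES))
        probs[int(call)] = 1.0
    defaults = dict(
        area_px=200.0,
        major_axis_px=18.0,
        minor_axis_px=14.0,
        orientation_deg=0.0,
        rel_orientation_deg=10.0 if tubule_id else float("nan"),
    )
    defaults.update(kw)
    if tubule_id == 0:
        abp = float("nan")
        defaults["rel_orientation_deg"] = float("nan")
    return NucleusRecord.from_probs(
        np.asarray(probs, dtype=float),
        id=id,
        tubule_id=tubule_id,
        centroid=centroid,
        abp=abp,
        **defaults,
    )
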