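"""Batch-effect normalization and two-group feature comparisons.

Observations are arranged in a 3D tensor: features (e.g. per-cell-type
nuclear area) × samples (image sources) × n_obs randomly drawn
observations (10 000 by default). Normalization sorts each
feature-sample z-vector ascending, then quantile-normalizes every
xy-frame: within each feature, the value at a given z-rank is replaced
by the mean of that rank's values across samples, so all samples of a
feature end up with identical marginal distributions while each sample's
ranking is preserved.

Two-group comparisons per feature use conventional two-sided tests:
paired t on z-aligned sorted values or Mann–Whitney U. Reported
significance tiers follow the raw-p conventions p ≤ 0.01, ≤ 1e-3 and
≤ 1e-5; no multiple-testing correction is applied by default (an
optional Bonferroni factor is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ObservationTensor",
    "sample_observations",
    "quantile_normalize_3d",
    "compare_features",
    "significance_label",
    "significance_tier",
]

DEFAULT_N_OBS = 10_000

TIERS = ((1e-5, "p<=1e-5"), (1e-3, "p<=1e-3"), (0.01, "p<=0.01"))


@dataclass
class ObservationTensor:
    """features × samples × n_obs array with axis labels and sampling metadata."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    seed: int = 0
    with_replacement: np.ndarray | None = None  # (features, samples) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be features × samples × n_obs")
        f, s, z = self.values.shape
        if z < 2:
            raise ValueError("n_obs must be at least 2")
        if len(self.feature_names) != f or len(self.sample_ids) != s:
            raise ValueError("axis labels inconsistent with tensor shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor values must be finite")
        if self.with_replacement is None:
            self.with_replacement = np.zeros((f, s), dtype=bool)

    @property
    def n_obs(self) -> int:
        return self.values.shape[2]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def sample_observations(
    groups: dict[tuple[str, str], np.ndarray],
    n_obs: int = DEFAULT_N_OBS,
    seed: int = 0,
) -> ObservationTensor:
    """Build an ObservationTensor by sampling each (feature, sample) group.

    Sampling is uniform without replacement when a group has at least
    ``n_obs`` observations, with replacement otherwise (flagged in the
    tensor metadata). Deterministic for a given seed.
    """
    features = sorted({f for f, _ in groups})
    samples = sorted({s for _, s in groups})
    for f in features:
        for s in samples:
            if (f, s) not in groups or len(np.asarray(groups[(f, s)])) == 0:
                raise ValueError(f"empty observation group for feature {f!r}, sample {s!r}")
    rng = np.random.default_rng(seed)
    values = np.empty((len(features), len(samples), n_obs))
    flagged = np.zeros((len(features), len(samples)), dtype=bool)
    for i, f in enumerate(features):
        for j, s in enumerate(samples):
            obs = np.asarray(groups[(f, s)], dtype=float)
            if len(obs) >= n_obs:
                values[i, j] = rng.choice(obs, size=n_obs, replace=False)
            else:
                values[i, j] = rng.choice(obs, size=n_obs, replace=True)
                flagged[i, j] = True
    return ObservationTensor(values, features, samples, seed=seed, with_replacement=flagged)


def quantile_normalize_3d(tensor: ObservationTensor) -> ObservationTensor:
    """3D quantile normalization (idempotent).

    Sort each feature-sample z-vector ascending; then, frame by frame,
    replace each sample's value by the mean across samples of the same
    feature at the same z-rank. Afterwards every sample of a feature
    carries an identical multiset of values and each (feature, sample)
    z-vector remains sorted.
    """
    v = np.sort(tensor.values, axis=2)
    normalized = np.broadcast_to(v.mean(axis=1, keepdims=True), v.shape).copy()
    return ObservationTensor(
        normalized,
        list(tensor.feature_names),
        list(tensor.sample_ids),
        seed=tensor.seed,
        with_replacement=tensor.with_replacement.copy(),
    )


def compare_features(
    tensor: ObservationTensor,
    sample_a: str,
    sample_b: str,
    test: str = "mann_whitney",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided p-values between two samples of one tensor.

    ``test`` is ``paired_t`` (on z-aligned sorted observations; requires
    equal n_obs, which tensors guarantee) or ``mann_whitney``.
    """
    if test not in ("paired_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    ia, ib = tensor.sample_index(sample_a), tensor.sample_index(sample_b)
    rows = []
    m = len(tensor.feature_names) if bonferroni else 1
    for i, feat in enumerate(tensor.feature_names):
        a, b = tensor.values[i, ia], tensor.values[i, ib]
        if test == "paired_t":
            if np.allclose(a, b):
                p = 1.0
            else:
                p = float(sps.ttest_rel(a, b).pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p = min(1.0, p * m)
        rows.append(
            {"feature": feat, "test": test, "p": p, "tier": significance_tier(p)}
        )
    return pd.DataFrame(rows)


def significance_label(p: float, alpha: float = 0.01) -> str:
    """'significant' iff p ≤ alpha (boundary inclusive), else 'not_significant'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return "significant" if p <= alpha else "not_significant"


def significance_tier(p: float) -> str:
    """Finest tier among p ≤ 1e-5, ≤ 1e-3, ≤ 0.01; else 'not_significant'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cut, name in TIERS:
        if p <= cut:
            return name
    return "not_significant"
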