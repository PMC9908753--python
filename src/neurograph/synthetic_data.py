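"""Synthetic multi-site two-group cohorts of ROI time series.

The group difference is planted in the inter-regional correlation structure:
case subjects get ``effect_delta`` added to their within-block correlations.
Per-site global offsets make the cohort heterogeneous across sites so that
leave-one-site-out behaviour can be exercised without real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc_network import MDD, NC, ROITimeSeries

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_per_group: int = 100
    n_rois: int = 20
    T: int = 200
    n_blocks: int = 4
    base_within_r: float = 0.35
    base_between_r: float = 0.05
    effect_delta: float = 0.3
    site_count: int = 4
    site_shift: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_rois < 2 or self.T < 3:
            raise ValueError("need n_rois >= 2 and T >= 3")
        if not 1 <= self.n_blocks <= self.n_rois:
            raise ValueError("n_blocks must lie in [1, n_rois]")
        for name in ("base_within_r", "base_between_r"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")


def nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Project to the PSD cone by eigenvalue clipping, re-unitize the diagonal."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    repaired = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def block_assignments(n_rois: int, n_blocks: int) -> np.ndarray:
    """Block index per ROI, near-equal contiguous blocks."""
    return np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(n_rois), n_blocks))]
    )


def build_group_covariance(
    spec: SyntheticCohortSpec, group: str, site: int = 0
) -> np.ndarray:
    """Block-structured correlation matrix for one group at one site.

    Within-block entries are ``base_within_r`` (+``effect_delta`` for cases),
    between-block entries ``base_between_r``; the site adds a global offset
    ``site_shift * site`` to every off-diagonal entry. The result is repaired
    to the nearest PSD correlation matrix.
    """
    if group not in (CASE, CONTROL):
        raise ValueError(f"group must be '{CASE}' or '{CONTROL}', got {group!r}")
    if not 0 <= site < spec.site_count:
        raise ValueError(f"site index {site} out of range [0, {spec.site_count})")
    blocks = block_assignments(spec.n_rois, spec.n_blocks)
    same_block = blocks[:, None] == blocks[None, :]
    within = spec.base_within_r + (spec.effect_delta if group == CASE else 0.0)
    target = np.where(same_block, within, spec.base_between_r).astype(np.float64)
    target += spec.site_shift * site
    np.fill_diagonal(target, 1.0)
    off_mask = ~np.eye(spec.n_rois, dtype=bool)
    if np.abs(target[off_mask]).max() >= 1.0:
        raise ValueError("requested off-diagonal correlations exceed magnitude 1")
    repaired = nearest_psd_correlation(target)
    if np.abs(repaired - target).max() > 0.2:
        raise ValueError(
            "correlation parameters are too indefinite to repair faithfully "
            f"(max repair distortion {np.abs(repaired - target).max():.3f})"
        )
    return repaired


def _sampling_root(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_cohort(spec: SyntheticCohortSpec) -> list[ROITimeSeries]:
    """Draw the full two-group multi-site cohort; deterministic under seed.

    Each subject's signals are T i.i.d. samples from a zero-mean multivariate
    normal with the group/site correlation matrix as covariance. Sites are
    assigned round-robin within each group.
    """
    rng = np.random.default_rng(spec.seed)
    roots = {
        (group, site): _sampling_root(build_group_covariance(spec, group, site))
        for group in (CASE, CONTROL)
        for site in range(spec.site_count)
    }
    cohort: list[ROITimeSeries] = []
    for group, label in ((CASE, MDD), (CONTROL, NC)):
        for i in range(spec.n_per_group):
            site = i % spec.site_count
            noise = rng.standard_normal((spec.n_rois, spec.T))
            signals = roots[(group, site)] @ noise
            cohort.append(
                ROITimeSeries(
                    subject_id=f"{label.lower()}_{i:04d}",
                    site_id=f"site{site}",
                    label=label,
                    signals=signals,
                )
            )
    return cohort
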