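"""ROI aggregation under partial-volume rules and normalized volumes.

Two different conventions, matching how segmentation-derived weight maps
are consumed downstream: metric means include only voxels whose
partial-volume weight strictly exceeds 0.5 (predominant-tissue rule),
whereas the region volume is the plain weight sum times the voxel
volume — every fractional voxel contributes — normalized by the total
intracranial volume (ICV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RegionDefinition:
    """A labelled region given as a partial-volume weight map in [0, 1]."""

    label: str
    weights: np.ndarray
    voxel_volume_mm3: float = 8.0  # 2 mm isotropic

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("partial-volume weights must lie in [0, 1]")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel volume must be positive")


def aggregate_region_metric(metric_map, region: RegionDefinition,
                            threshold: float = 0.5, valid=None,
                            weighted: bool = False) -> float:
    """Region mean of a metric map under the weight > threshold rule.

    Only voxels with partial-volume weight strictly greater than
    ``threshold`` (default 0.5) and, if given, a True ``valid`` flag are
    included; the mean is unweighted unless ``weighted`` is set.
    """
    m = np.asarray(metric_map, dtype=float)
    if m.shape != region.weights.shape:
        raise ValueError("metric map grid does not match region weight grid")
    include = region.weights > threshold
    if valid is not None:
        include &= np.asarray(valid, dtype=bool)
    include &= np.isfinite(m)
    if not include.any():
        raise ValueError(f"empty region '{region.label}': no voxel above "
                         f"threshold {threshold} with a valid fit")
    if weighted:
        w = region.weights[include]
        return float(np.sum(m[include] * w) / np.sum(w))
    return float(np.mean(m[include]))


def compute_normalized_volume(region: RegionDefinition, icv_mm3: float) -> float:
    """Region volume (sum of weights x voxel volume) over ICV.

    All partial-volume weights contribute — no inclusion threshold is
    applied to the volume, unlike the metric mean.
    """
    if icv_mm3 <= 0:
        raise ValueError("intracranial volume must be positive")
    return float(np.sum(region.weights) * region.voxel_volume_mm3 / icv_mm3)
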