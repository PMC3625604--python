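"""Validation metrics comparing a segmentation against ground truth.

Six scalar metrics over the ground-truth voxel set S1 and the test voxel
set S2:

* VD   — absolute volume difference, |V2 - V1| / V1 * 100 (%).
* JM   — volume overlap; default is the Jaccard index
         |S1 ∩ S2| / |S1 ∪ S2| * 100, a Dice variant
         2|S1 ∩ S2| / (|S1| + |S2|) * 100 is available by flag.
* rfp  — false-positive ratio (|S2| - |S1 ∩ S2|) / |S1| * 100,
         the overflow outside ground truth relative to ground-truth volume.
* rfn  — false-negative ratio (|S1| - |S1 ∩ S2|) / |S1| * 100.
* HD   — symmetric Hausdorff distance between the two voxel surfaces
         (worst-case disagreement), in voxel units.
* MASD — mean absolute surface distance, the average of the two directed
         mean nearest-surface distances (size-independent average
         disagreement), in voxel units.

Surfaces are the foreground voxels with at least one six-connected
background neighbour (grid faces count as background); distances are
Euclidean between voxel centres.  Identical masks score
(VD 0, JM 100, rfp 0, rfn 0, HD 0, MASD 0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AlignmentError, UndefinedMetricError
from .volumes import Mask


def _counts(gt: Mask, test: Mask) -> tuple[int, int, int]:
    if gt.data.shape != test.data.shape:
        raise AlignmentError(
            f"mask shapes differ: {gt.data.shape} vs {test.data.shape}"
        )
    v1 = int(gt.data.sum())
    v2 = int(test.data.sum())
    inter = int((gt.data & test.data).sum())
    return v1, v2, inter


def volume_difference(gt: Mask, test: Mask) -> float:
    """|V2 - V1| / V1 * 100, with V1 the ground-truth voxel count."""
    v1, v2, _ = _counts(gt, test)
    if v1 == 0:
        raise UndefinedMetricError("ground truth is empty")
    return abs(v2 - v1) / v1 * 100.0


def jaccard(gt: Mask, test: Mask, mode: str = "jaccard") -> float:
    """Volume overlap in percent; ``mode`` selects jaccard or dice."""
    v1, v2, inter = _counts(gt, test)
    union = v1 + v2 - inter
    if union == 0:
        raise UndefinedMetricError("both masks are empty")
    if mode == "jaccard":
        return inter / union * 100.0
    if mode == "dice":
        return 2.0 * inter / (v1 + v2) * 100.0
    raise UndefinedMetricError(f"unknown overlap mode {mode!r}")


def false_positive_ratio(gt: Mask, test: Mask) -> float:
    """(|S2| - |S1 ∩ S2|) / |S1| * 100 — overflow beyond ground truth."""
    v1, v2, inter = _counts(gt, test)
    if v1 == 0:
        raise UndefinedMetricError("ground truth is empty")
    return (v2 - inter) / v1 * 100.0


def false_negative_ratio(gt: Mask, test: Mask) -> float:
    """(|S1| - |S1 ∩ S2|) / |S1| * 100 — ground truth missed by the test."""
    v1, _, inter = _counts(gt, test)
    if v1 == 0:
        raise UndefinedMetricError("ground truth is empty")
    return (v1 - inter) / v1 * 100.0


def surface_voxels(m: Mask) -> np.ndarray:
    """Coordinates (n, 3) of foreground voxels with a six-connected
    background neighbour; voxels on the grid faces count as surface."""
    if not m.data.any():
        raise UndefinedMetricError("mask is empty")
    eroded = ndimage.binary_erosion(
        m.data,
        structure=ndimage.generate_binary_structure(3, 1),
        border_value=0,
    )
    return np.argwhere(m.data & ~eroded)


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each surface voxel in ``a`` to its nearest
    surface voxel in ``b``."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def hausdorff(gt: Mask, test: Mask) -> float:
    """Symmetric Hausdorff distance between the two surfaces (voxels)."""
    s1 = surface_voxels(gt)
    s2 = surface_voxels(test)
    d12 = _directed_distances(s1, s2)
    d21 = _directed_distances(s2, s1)
    return float(max(d12.max(), d21.max()))


def masd(gt: Mask, test: Mask) -> float:
    """Mean absolute surface distance: mean of the two directed mean
    nearest-surface distances (voxels)."""
    s1 = surface_voxels(gt)
    s2 = surface_voxels(test)
    d12 = _directed_distances(s1, s2)
    d21 = _directed_distances(s2, s1)
    return float(0.5 * (d12.mean() + d21.mean()))


@dataclass(frozen=True)
class MetricsReport:
    """The six validation metrics for one (ground truth, test) mask pair."""

    VD: float
    JM: float
    rfp: float
    rfn: float
    HD: float
    MASD: float
    V1: int
    V2: int
    JM_dice: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def full_report(gt: Mask, test: Mask, jm_mode: str = "jaccard") -> MetricsReport:
    """All six metrics plus the two volumes; ``jm_mode`` picks which overlap
    variant fills JM (the Dice value is always carried alongside)."""
    v1, v2, _ = _counts(gt, test)
    if v1 == 0:
        raise UndefinedMetricError("ground truth is empty")
    return MetricsReport(
        VD=volume_difference(gt, test),
        JM=jaccard(gt, test, jm_mode),
        rfp=false_positive_ratio(gt, test),
        rfn=false_negative_ratio(gt, test),
        HD=hausdorff(gt, test),
        MASD=masd(gt, test),
        V1=v1,
        V2=v2,
        JM_dice=jaccard(gt, test, "dice"),
    )
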