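"""Per-case segmentation quality metrics.

DSC = 2|A ∩ B| / (|A| + |B|)          Sørensen–Dice coefficient, in [0, 1]
RVD = (|A| − |B|) / |B|               relative volume difference

with A the estimated and B the ground-truth ROI, both voxel sets on one
grid (so voxel counts and physical volumes give identical ratios).  A
positive RVD means the method overestimates the target volume.  RVD can be
zero for disjoint masks and must always be read together with DSC.
"""

from __future__ import annotations

import dataclasses

from .image_model import EmptyMaskError, ROIMask, _require_same_grid, mask_volume_cm3

__all__ = ["CaseEvaluation", "dice", "rvd", "evaluate_case"]


def _check(est: ROIMask, gt: ROIMask) -> None:
    _require_same_grid(est.grid, gt.grid)
    if gt.is_empty:
        raise EmptyMaskError("ground truth must be non-empty")


def dice(est: ROIMask, gt: ROIMask) -> float:
    """Sørensen–Dice overlap; 1 = perfect segmentation, 0 = no overlap."""
    _check(est, gt)
    inter = int((est.indicator & gt.indicator).sum())
    return 2.0 * inter / (est.voxel_count + gt.voxel_count)


def rvd(est: ROIMask, gt: ROIMask) -> float:
    """Relative volume difference as a fraction (x100 for %); >= -1."""
    _check(est, gt)
    return (est.voxel_count - gt.voxel_count) / gt.voxel_count


@dataclasses.dataclass(frozen=True)
class CaseEvaluation:
    case_id: str
    method: str
    dsc: float
    rvd: float  # fraction; see rvd_percent
    est_volume_cm3: float
    gt_volume_cm3: float

    @property
    def rvd_percent(self) -> float:
        return 100.0 * self.rvd

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "method": self.method,
            "dsc": self.dsc,
            "rvd_percent": self.rvd_percent,
            "est_volume_cm3": self.est_volume_cm3,
            "gt_volume_cm3": self.gt_volume_cm3,
        }


def evaluate_case(
    est: ROIMask, gt: ROIMask, case_id: str = "", method: str = ""
) -> CaseEvaluation:
    """Bundle DSC, RVD and volumes for one (case, method) pair.

    An empty estimated mask is a valid outcome (DSC 0, RVD -100%): failed
    segmentations enter cohort statistics rather than being dropped.
    """
    _check(est, gt)
    return CaseEvaluation(
        case_id=case_id,
        method=method,
        dsc=dice(est, gt),
        rvd=rvd(est, gt),
        est_volume_cm3=mask_volume_cm3(est),
        gt_volume_cm3=mask_volume_cm3(gt),
    )
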