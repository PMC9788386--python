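"""Reporter-channel (intracellular ROS) quantification per cell area.

The readout is total reporter fluorescence over the total segmented cell
area of a well — mean fluorescence intensity (MFI) per cell area — then
normalised against vehicle-control wells so that the vehicle mean fold is
exactly 1.  The cell mask comes from the phase-contrast-like channel
(actin as fallback) after illumination correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ImageField
from .segment import SegmentationParams, _foreground_mask, correct_illumination


class RosError(ValueError):
    """Missing channels or vehicle reference for ROS quantification."""


@dataclass
class RosResult:
    """Per-well ROS readout; ``fold_vs_vehicle`` is NaN until normalised."""

    well_id: str
    total_cell_area: float
    total_intensity: float
    mfi_per_area: float  # NaN when undefined (zero mask area)
    fold_vs_vehicle: float = float("nan")
    qc_flags: str = ""


def ros_mfi_per_area(field: ImageField,
                     params: SegmentationParams | None = None,
                     ) -> tuple[float, float]:
    """Cell area (px^2) and summed reporter intensity of one field.

    The cell mask is thresholded from the phase channel (or actin when no
    phase channel is present); both mask and reporter channels are
    illumination-corrected first.  A zero mask area is returned as (0, 0) —
    the caller flags the well as undefined.
    """
    params = params or SegmentationParams()
    if "reporter" not in field.channels:
        raise RosError(f"field {field.well_id}/{field.field_index} has no "
                       "reporter channel")
    mask_role = "phase" if "phase" in field.channels else "actin"
    if mask_role not in field.channels:
        raise RosError("need a phase or actin channel to build the cell mask")
    # cell-sized structures exceed the default background blocks, so the
    # trend is estimated on coarse blocks with a low percentile
    body = correct_illumination(field.channels[mask_role], block=64,
                                percentile=5.0)
    reporter = correct_illumination(field.channels["reporter"], block=64,
                                    percentile=5.0)
    mask = _foreground_mask(body, params)
    area = float(mask.sum())
    if area == 0:
        return 0.0, 0.0
    return area, float(reporter[mask].sum())


def aggregate_ros(fields_by_well: Mapping[str, Sequence[ImageField]],
                  params: SegmentationParams | None = None) -> list[RosResult]:
    """Per-well MFI per cell area = sum(intensity) / sum(area) over fields."""
    out = []
    for well_id, fields in fields_by_well.items():
        area = inten = 0.0
        for fld in fields:
            a, s = ros_mfi_per_area(fld, params)
            area += a
            inten += s
        if area == 0:
            out.append(RosResult(well_id, 0.0, 0.0, float("nan"),
                                 qc_flags="undefined_no_cells"))
        else:
            out.append(RosResult(well_id, area, inten, inten / area))
    return out


def normalize_to_vehicle(results: Iterable[RosResult],
                         vehicle_wells: Sequence[str]) -> list[RosResult]:
    """Fold change versus the mean vehicle MFI (vehicle mean fold = 1.0)."""
    results = list(results)
    vehicle = [r for r in results if r.well_id in set(vehicle_wells)
               and np.isfinite(r.mfi_per_area)]
    if not vehicle:
        raise RosError("no vehicle well with a defined MFI")
    ref = float(np.mean([r.mfi_per_area for r in vehicle]))
    if ref == 0:
        raise RosError("vehicle MFI is zero; fold undefined")
    out = []
    for r in results:
        fold = r.mfi_per_area / ref if np.isfinite(r.mfi_per_area) else float("nan")
        out.append(RosResult(r.well_id, r.total_cell_area, r.total_intensity,
                             r.mfi_per_area, fold, r.qc_flags))
    return out
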