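"""Illumination correction and nuclei / cytoplasm segmentation.

Nuclei are segmented from the DNA channel by Otsu thresholding of a
Gaussian-smoothed, illumination-corrected image, followed by a
distance-transform watershed to split touching nuclei and area gates to drop
debris (including micronucleus-sized specks, which are handled separately by
the scorer).  Cytoplasm territories come from the actin channel: each
connected component of the thresholded actin mask is one cell territory, so a
bi-nucleated cell whose actin blob is unbroken yields a single territory
containing both nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import ImageField


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable gates of the segmentation stage (all in pixel units).

    ``min_nucleus_area`` sits above the micronucleus size range so MN never
    enter the main-nucleus label map; ``split_min_distance`` is the minimum
    separation of watershed seeds.  ``min_contrast`` is the smallest
    foreground-background Otsu separation accepted as real signal — below it
    the field is treated as empty rather than thresholding noise.
    """

    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    threshold_value: float = 0.0    # used when threshold_method == "fixed"
    min_nucleus_area: float = 100.0
    max_nucleus_area: float = 5000.0
    split_min_distance: int = 8
    min_cytoplasm_area: float = 400.0
    border_policy: str = "exclude_touching"  # or "keep"
    min_contrast: float = 8.0

    def __post_init__(self) -> None:
        if self.min_nucleus_area <= 0 or self.min_cytoplasm_area <= 0:
            raise ValueError("area gates must be positive")
        if self.min_nucleus_area >= self.max_nucleus_area:
            raise ValueError("min_nucleus_area must be < max_nucleus_area")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.border_policy not in ("exclude_touching", "keep"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


def correct_illumination(channel: np.ndarray, block: int = 32,
                         percentile: float = 10.0,
                         grid_sigma: float = 1.0) -> np.ndarray:
    """Remove the large-scale illumination trend from one channel.

    The background surface is estimated as a low percentile over coarse
    blocks (robust to sparse bright objects), smoothed and upsampled; only the
    trend (surface minus its minimum) is subtracted, so a perfectly flat field
    passes through unchanged and the pedestal is preserved.  All-zero images
    are returned unchanged with a warning.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.any(img):
        warnings.warn("all-zero image passed to correct_illumination",
                      stacklevel=2)
        return img.copy()
    rows, cols = img.shape
    pad_r = (-rows) % block
    pad_c = (-cols) % block
    padded = np.pad(img, ((0, pad_r), (0, pad_c)), mode="edge")
    nr, nc = padded.shape[0] // block, padded.shape[1] // block
    blocks = padded.reshape(nr, block, nc, block).transpose(0, 2, 1, 3)
    grid = np.percentile(blocks.reshape(nr, nc, -1), percentile, axis=2)
    grid = ndi.gaussian_filter(grid, grid_sigma, mode="nearest")
    bg = ndi.zoom(grid, (padded.shape[0] / nr, padded.shape[1] / nc),
                  order=1, mode="nearest", grid_mode=True)[:rows, :cols]
    out = img - (bg - bg.min())
    return np.clip(out, 0.0, None)


def _relabel_deterministic(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n ordered by each object's top-most, left-most pixel."""
    out = np.zeros_like(labels, dtype=np.int32)
    keys = []
    for prop in regionprops(labels):
        r0, c0 = min(tuple(xy) for xy in prop.coords)
        keys.append((r0, c0, prop.label))
    for new, (_, _, old) in enumerate(sorted(keys), start=1):
        out[labels == old] = new
    return out


def _remove_small(mask: np.ndarray, min_area: float) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def _foreground_mask(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Smooth + threshold with a contrast guard against empty fields."""
    sm = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    if sm.max() - sm.min() < 1e-12:
        return np.zeros(img.shape, dtype=bool)
    if params.threshold_method == "fixed":
        thr = params.threshold_value
    else:
        thr = threshold_otsu(sm)
        med = np.median(sm)
        mad = np.median(np.abs(sm - med))
        sigma = 1.4826 * mad
        if thr - med < max(params.min_contrast, 3.0 * sigma):
            return np.zeros(img.shape, dtype=bool)
    return sm > thr


def segment_nuclei(dna: np.ndarray, params: SegmentationParams | None = None,
                   ) -> np.ndarray:
    """Segment nuclei from an illumination-corrected DNA channel.

    Returns an int32 label map (0 = background), labels numbered
    deterministically by (top-most, left-most) object pixel.  Touching nuclei
    are split by a watershed seeded at local maxima of the smoothed distance
    transform; objects outside the area gates and (by default) objects
    touching the field border are removed.
    """
    params = params or SegmentationParams()
    mask = _foreground_mask(dna, params)
    mask = _remove_small(mask, params.min_nucleus_area)
    if not mask.any():
        return np.zeros(dna.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, 1.0)
    comp, _ = ndi.label(mask)
    coords = peak_local_max(dist_s, min_distance=int(params.split_min_distance),
                            labels=comp, exclude_border=False)
    markers = np.zeros(dna.shape, dtype=np.int32)
    for i, (r, c) in enumerate(sorted(map(tuple, coords)), start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = comp.astype(np.int32)
    else:
        labels = watershed(-dist_s, markers, mask=mask).astype(np.int32)
    labels = _filter_labels(labels, params.min_nucleus_area,
                            params.max_nucleus_area, params.border_policy)
    return _relabel_deterministic(labels)


def _filter_labels(labels: np.ndarray, min_area: float, max_area: float,
                   border_policy: str) -> np.ndarray:
    out = labels.copy()
    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for prop in regionprops(labels):
        drop = prop.area < min_area or prop.area > max_area
        if not drop and border_policy == "exclude_touching":
            sl = prop.slice
            drop = bool(np.any(border[sl] & (labels[sl] == prop.label)))
        if drop:
            out[out == prop.label] = 0
    return out


def segment_cytoplasm(actin: np.ndarray, nuclei: np.ndarray,
                      params: SegmentationParams | None = None) -> np.ndarray:
    """Segment cytoplasm territories from the actin channel.

    One label per connected component of the thresholded actin mask (holes
    filled), so several nuclei inside one unbroken blob share one territory.
    Components smaller than ``min_cytoplasm_area`` are dropped, and with the
    default border policy any territory touching the field border is removed
    (whole-cell scoring).
    """
    params = params or SegmentationParams()
    if actin.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: actin {actin.shape} vs nuclei "
                         f"{nuclei.shape}")
    mask = _foreground_mask(actin, params)
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, params.min_cytoplasm_area)
    labels, _ = ndi.label(mask)
    labels = _filter_labels(labels.astype(np.int32), params.min_cytoplasm_area,
                            np.inf, params.border_policy)
    return _relabel_deterministic(labels)


def count_nuclei(field: ImageField, params: SegmentationParams | None = None,
                 ) -> int:
    """Number of segmented nuclei in one field (correction + segmentation)."""
    corrected = correct_illumination(field.channels["dna"])
    return int(segment_nuclei(corrected, params).max())


def nuclei_count_normalized(fields, control_fields,
                            params: SegmentationParams | None = None) -> float:
    """Mean nuclei per field in ``fields`` over the mean in ``control_fields``.

    This is the cell-recovery readout used to verify that a separation
    treatment does not detach cells: a ratio near 1 means no cell loss.
    """
    fields = list(fields)
    control_fields = list(control_fields)
    if not fields or not control_fields:
        raise ValueError("both field collections must be non-empty")
    treated = np.mean([count_nuclei(f, params) for f in fields])
    control = np.mean([count_nuclei(f, params) for f in control_fields])
    if control == 0:
        raise ZeroDivisionError("control fields contain no nuclei; "
                                "normalized ratio undefined")
    return float(treated / control)
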