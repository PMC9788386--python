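"""Cell assembly, classification and micronucleus scoring.

Cells are assembled by assigning every segmented nucleus to the cytoplasm
territory that covers the majority of its area; nuclei with no majority owner
are cross-contaminating (they straddle territories) and are removed outright.
Cells are then classed by surviving nucleus count — mono (1), bi (2),
multi (>=3) — and micronuclei are detected only inside bi-nucleated cells,
the scoring universe of the cytokinesis-block assay.  An accepted MN must be
a small separate chromatin body: diameter between 1/16 and 1/3 of the mean
main-nucleus diameter, at least one pixel of clear cytoplasm to both main
nuclei, and DNA intensity comparable to the main nuclei.

Well endpoints follow the standard proliferation/genotoxicity definitions:

    CBPI            = (N_mono + 2 N_bi + 3 N_multi) / N_total
    %BNC            = 100 * N_bi / N_total
    MN per 1000 BNC = 1000 * N_mn / N_bi
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import regionprops

from .io import RESULTS_COLUMNS, ImageField, PlateLayout, WellSpec
from .segment import SegmentationParams, correct_illumination, \
    segment_cytoplasm, segment_nuclei


class EndpointError(ValueError):
    """Undefined endpoint (e.g. no scored cells)."""


@dataclass(frozen=True)
class MnParams:
    """Acceptance gates for micronucleus candidates.

    The size window is the classical one: an MN is smaller than a third of
    the main nucleus but larger than a sixteenth (smaller specks are noise).
    ``threshold_frac`` places the chromatin threshold this fraction of the way
    from local background to the cell's main-nucleus intensity.
    """

    min_diameter_ratio: float = 1.0 / 16.0
    max_diameter_ratio: float = 1.0 / 3.0
    intensity_bounds: tuple[float, float] = (0.5, 2.0)
    smoothing_sigma: float = 1.0
    threshold_frac: float = 0.3
    min_area_px: float = 4.0
    gap_px: int = 1


@dataclass(frozen=True)
class NucleusMeasure:
    label: int
    area: float
    centroid: tuple[float, float]
    mean_dna: float
    equiv_diameter: float


@dataclass(frozen=True)
class Micronucleus:
    """One accepted micronucleus call inside a bi-nucleated cell."""

    area: float
    equiv_diameter: float
    diameter_ratio: float
    mean_dna: float
    centroid: tuple[float, float]


@dataclass
class CellObject:
    """A cytoplasm territory with its assigned nuclei and MN calls."""

    cell_id: int
    cytoplasm_label: int
    nuclei: list[NucleusMeasure]
    classification: str  # mono | bi | multi | excluded
    touches_border: bool = False
    mn_calls: list[Micronucleus] = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


@dataclass
class WellEndpoints:
    """Per-well counts and derived endpoints."""

    n_mono: int = 0
    n_bi: int = 0
    n_multi: int = 0
    n_mn: int = 0
    cbpi: float = 1.0
    pct_bnc: float = 0.0
    mn_per_1000_bnc: float = 0.0
    qc_flags: str = ""

    @property
    def n_total_scored(self) -> int:
        return self.n_mono + self.n_bi + self.n_multi


def classify(n_nuclei: int) -> str:
    if n_nuclei == 0:
        return "excluded"
    if n_nuclei == 1:
        return "mono"
    if n_nuclei == 2:
        return "bi"
    return "multi"


def assemble_cells(nuclei: np.ndarray, cytoplasm: np.ndarray,
                   dna: np.ndarray, majority_frac: float = 0.6,
                   ) -> list[CellObject]:
    """Assemble cell objects from nucleus and cytoplasm label maps.

    A nucleus belongs to the cytoplasm label covering more than
    ``majority_frac`` of its pixels; nuclei without a majority owner are
    cross-contaminating and dropped from every cell.  Cells with zero
    surviving nuclei, or whose cytoplasm touches the field border, are marked
    ``excluded``.
    """
    if nuclei.shape != cytoplasm.shape or nuclei.shape != dna.shape:
        raise ValueError("nuclei, cytoplasm and dna must share one shape")
    owners: dict[int, list[NucleusMeasure]] = {}
    for prop in regionprops(nuclei, intensity_image=dna):
        under = cytoplasm[nuclei == prop.label]
        counts = np.bincount(under)
        counts[0] = 0  # background never owns a nucleus
        if counts.sum() == 0:
            continue
        owner = int(counts.argmax())
        if counts[owner] / prop.area <= majority_frac:
            continue  # cross-contaminating nucleus: removed from all cells
        owners.setdefault(owner, []).append(NucleusMeasure(
            label=prop.label, area=float(prop.area),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            mean_dna=float(prop.intensity_mean),
            equiv_diameter=float(prop.equivalent_diameter_area)))

    border = np.zeros(cytoplasm.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    cells: list[CellObject] = []
    for prop in regionprops(cytoplasm):
        sl = prop.slice
        touches = bool(np.any(border[sl] & (cytoplasm[sl] == prop.label)))
        nucs = sorted(owners.get(prop.label, []),
                      key=lambda n: (n.centroid[0], n.centroid[1]))
        cls = "excluded" if touches else classify(len(nucs))
        cells.append(CellObject(cell_id=prop.label, cytoplasm_label=prop.label,
                                nuclei=nucs, classification=cls,
                                touches_border=touches))
    return cells


def detect_micronuclei(cell: CellObject, nuclei: np.ndarray,
                       cytoplasm: np.ndarray, dna: np.ndarray,
                       params: MnParams | None = None) -> list[Micronucleus]:
    """Detect micronuclei inside one bi-nucleated cell.

    Non-BNC cells return an empty list by contract (MN are only scored in the
    bi-nucleated universe).  Candidates are small chromatin objects inside the
    cell's cytoplasm, excluding and not touching the main nuclei; ordering of
    the returned calls is by (row, col) of the centroid.
    """
    params = params or MnParams()
    if cell.classification != "bi":
        return []
    cyto_mask = cytoplasm == cell.cytoplasm_label
    if not cyto_mask.any():
        return []
    nuc_mean = float(np.mean([n.mean_dna for n in cell.nuclei]))
    nuc_diam = float(np.mean([n.equiv_diameter for n in cell.nuclei]))
    sm = gaussian(dna, sigma=params.smoothing_sigma, preserve_range=True)
    bg_px = sm[cyto_mask & (nuclei == 0)]
    if bg_px.size == 0:
        return []
    bg = float(np.median(bg_px))
    thr = bg + params.threshold_frac * (nuc_mean - bg)
    if thr <= bg:
        return []
    cand = (sm > thr) & cyto_mask & (nuclei == 0)
    if not cand.any():
        return []
    nuc_dilated = ndi.binary_dilation(nuclei > 0,
                                      iterations=max(1, params.gap_px))
    labels, _ = ndi.label(cand)
    lo, hi = params.intensity_bounds
    calls: list[Micronucleus] = []
    for prop in regionprops(labels, intensity_image=np.asarray(dna, dtype=np.float64)):
        if prop.area < params.min_area_px:
            continue
        # (ii) clear gap to both main nuclei after 1-px dilation
        comp = labels[prop.slice] == prop.label
        comp_dil = ndi.binary_dilation(comp)
        if np.any(comp_dil & nuc_dilated[prop.slice]):
            continue
        ratio = prop.equivalent_diameter_area / nuc_diam
        if not (params.min_diameter_ratio < ratio < params.max_diameter_ratio):
            continue
        if not (lo * nuc_mean <= prop.intensity_mean <= hi * nuc_mean):
            continue
        r, c = prop.centroid
        if not cyto_mask[int(round(r)), int(round(c))]:
            continue
        calls.append(Micronucleus(
            area=float(prop.area),
            equiv_diameter=float(prop.equivalent_diameter_area),
            diameter_ratio=float(ratio),
            mean_dna=float(prop.intensity_mean),
            centroid=(float(r), float(c))))
    calls.sort(key=lambda m: m.centroid)
    return calls


def compute_cbpi(n_mono: int, n_bi: int, n_multi: int) -> float:
    """Cytokinesis-block proliferation index, in [1, 3]."""
    total = n_mono + n_bi + n_multi
    if total <= 0:
        raise EndpointError("CBPI undefined: no scored cells")
    return (n_mono + 2 * n_bi + 3 * n_multi) / total


def compute_endpoints(cells: Iterable[CellObject]) -> WellEndpoints:
    """Aggregate the cell objects of one well into endpoint values.

    Excluded cells (border or zero nuclei) do not enter the scored totals.
    Degenerate wells are flagged: ``no_cells`` when nothing was scored,
    ``no_bnc`` when the MN rate denominator is empty.
    """
    n = {"mono": 0, "bi": 0, "multi": 0}
    n_mn = 0
    for cell in cells:
        if cell.classification in n:
            n[cell.classification] += 1
            n_mn += len(cell.mn_calls)
    ep = WellEndpoints(n_mono=n["mono"], n_bi=n["bi"], n_multi=n["multi"],
                       n_mn=n_mn)
    if ep.n_total_scored == 0:
        ep.cbpi = 0.0
        ep.qc_flags = "no_cells"
        return ep
    ep.cbpi = compute_cbpi(ep.n_mono, ep.n_bi, ep.n_multi)
    ep.pct_bnc = 100.0 * ep.n_bi / ep.n_total_scored
    if ep.n_bi == 0:
        ep.mn_per_1000_bnc = 0.0
        ep.qc_flags = "no_bnc"
    else:
        ep.mn_per_1000_bnc = 1000.0 * ep.n_mn / ep.n_bi
    return ep


def score_field(fld: ImageField, seg_params: SegmentationParams | None = None,
                mn_params: MnParams | None = None,
                ) -> tuple[list[CellObject], np.ndarray]:
    """Run the full per-field pipeline; returns cells and the cytoplasm map."""
    seg_params = seg_params or SegmentationParams()
    dna = correct_illumination(fld.channels["dna"])
    # cell bodies span more than a 32-px block, so the actin background
    # surface is estimated on coarser blocks with a lower percentile
    actin = correct_illumination(fld.channels["actin"], block=64, percentile=5.0)
    nuclei = segment_nuclei(dna, seg_params)
    cyto = segment_cytoplasm(actin, nuclei, seg_params)
    cells = assemble_cells(nuclei, cyto, dna)
    for cell in cells:
        cell.mn_calls = detect_micronuclei(cell, nuclei, cyto, dna, mn_params)
    return cells, cyto

def score_well(fields: Sequence[ImageField],
               seg_params: SegmentationParams | None = None,
               mn_params: MnParams | None = None,
               ) -> tuple[list[CellObject], WellEndpoints]:
    """Score all fields of one well and aggregate endpoints."""
    cells: list[CellObject] = []
    for fld in fields:
        fc, _ = score_field(fld, seg_params, mn_params)
        cells.extend(fc)
    return cells, compute_endpoints(cells)


def score_plate(fields: Iterable[ImageField], layout: PlateLayout,
                seg_params: SegmentationParams | None = None,
                mn_params: MnParams | None = None) -> pd.DataFrame:
    """Score a whole plate into a tidy one-row-per-well results table."""
    by_well: dict[str, list[ImageField]] = {}
    for fld in fields:
        by_well.setdefault(fld.well_id, []).append(fld)
    rows = []
    for well in layout.wells:
        wfields = by_well.get(well.well_id, [])
        _, ep = score_well(wfields, seg_params, mn_params)
        if not wfields:
            ep.qc_flags = "no_fields"
        rows.append(_result_row(well, len(wfields), ep))
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def _result_row(well: WellSpec, n_fields: int, ep: WellEndpoints) -> dict:
    return {
        "well_id": well.well_id, "group": well.group,
        "treatment": well.treatment, "concentration": well.concentration,
        "n_fields": n_fields,
        "n_mono": ep.n_mono, "n_bi": ep.n_bi, "n_multi": ep.n_multi,
        "n_total_scored": ep.n_total_scored, "n_mn": ep.n_mn,
        "cbpi": ep.cbpi, "pct_bnc": ep.pct_bnc,
        "mn_per_1000_bnc": ep.mn_per_1000_bnc, "qc_flags": ep.qc_flags,
    }
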