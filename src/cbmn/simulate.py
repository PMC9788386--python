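"""Synthetic two-channel fluorescence plates for the CBMN assay, with ground truth.

The generator emulates the imaging regimes of a cytochalasin-B-blocked
micronucleus experiment on a 96-well plate:

* a DNA channel (DAPI-like) with 1, 2 or >=3 elliptical nuclei per cell and,
  in bi-nucleated cells only, small micronucleus discs sharing the chromatin
  intensity of the main nuclei;
* an actin channel (phalloidin-like) with one filled cytoplasm blob per cell
  enclosing its nuclei;
* optionally a reporter channel (H2DCF-DA-like) and a low-contrast
  phase-contrast-like channel for cell-area normalisation;
* a smooth additive illumination gradient, Poisson shot noise and Gaussian
  read noise;
* either hard-core separated cell placement (enzymatically separated cells)
  or Neyman-Scott clustered placement (aggregated colony growth), selected by
  a single ``clustering`` knob.

Every field carries a :class:`GroundTruth` record (per-cell class, nucleus
geometry, micronucleus placements) so that segmentation and scoring can be
benchmarked with exact per-cell truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk, ellipse

from .io import ImageField, PlateLayout

# Fluorophore amplitudes (arbitrary camera units above background).
BACKGROUND_LEVEL = 20.0
DNA_AMPLITUDE = 100.0
ACTIN_AMPLITUDE = 60.0
REPORTER_BASELINE = 10.0
PHASE_BACKGROUND = 15.0
PHASE_AMPLITUDE = 25.0

#: gap (px) kept between sister nuclei within one cell
_NUCLEUS_GAP = 3.0
#: clearance (px) between a micronucleus rim and every main-nucleus rim
_MN_CLEARANCE = 4.0
#: extra cytoplasm radius beyond the nuclear extent
_CYTO_PAD = 6.0
#: minimum centre-to-centre clearance between separated cells
_HARDCORE_GAP = 6.0

CLASS_NAMES = ("mono", "bi", "multi")


class ParameterError(ValueError):
    """Invalid generator parameters."""


class GenerationError(RuntimeError):
    """Field too small / too crowded to place the requested cells."""


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters for one treatment condition.

    Defaults describe the assay's calibrated working point: cytochalasin B at
    its optimum blocks cytokinesis in about half the dividing population, so
    the mixture is centred on 50% bi-nucleated cells, with a small
    multinucleated tail and a low vehicle-level micronucleus background.
    """

    field_shape: tuple[int, int] = (512, 512)
    cells_per_field: int = 25
    clustering: float = 0.0
    p_mono: float = 0.45
    p_bi: float = 0.50
    p_multi: float = 0.05
    mn_rate: float = 0.02
    nucleus_radius_px: tuple[float, float] = (10.0, 1.5)
    mn_diameter_ratio: float = 0.2
    background_gradient: float = 0.2
    noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0
    include_reporter: bool = False
    reporter_fold: float = 1.0

    def __post_init__(self) -> None:
        rows, cols = self.field_shape
        if rows < 64 or cols < 64:
            raise ParameterError("field_shape must be at least 64x64")
        if abs(self.p_mono + self.p_bi + self.p_multi - 1.0) > 1e-9:
            raise ParameterError("p_mono + p_bi + p_multi must sum to 1")
        if min(self.p_mono, self.p_bi, self.p_multi) < 0:
            raise ParameterError("mixture probabilities must be >= 0")
        if self.cells_per_field < 0:
            raise ParameterError("cells_per_field must be >= 0")
        if self.clustering < 0:
            raise ParameterError("clustering must be >= 0")
        if self.mn_rate < 0:
            raise ParameterError("mn_rate must be >= 0")
        mean_r, sd_r = self.nucleus_radius_px
        if mean_r <= 0 or sd_r < 0:
            raise ParameterError("nucleus_radius_px must be (mean>0, sd>=0)")
        if not 0.0 < self.mn_diameter_ratio < 1.0:
            raise ParameterError("mn_diameter_ratio must be in (0, 1)")
        if self.background_gradient < 0 or self.noise_sd < 0:
            raise ParameterError("background_gradient and noise_sd must be >= 0")
        if self.reporter_fold < 0:
            raise ParameterError("reporter_fold must be >= 0")

    @property
    def class_probs(self) -> tuple[float, float, float]:
        return (self.p_mono, self.p_bi, self.p_multi)


def cytochalasin_optimum(**overrides) -> SynthParams:
    """Preset for the cytochalasin-B optimum condition.

    At the optimum cytochalasin-B dose half of the scored population is
    bi-nucleated; micronucleus background is left at zero so the mixture is a
    clean mono/bi split.
    """
    base = dict(p_mono=0.5, p_bi=0.5, p_multi=0.0, mn_rate=0.0)
    base.update(overrides)
    return SynthParams(**base)


@dataclass(frozen=True)
class NucleusTruth:
    center: tuple[float, float]  # (row, col)
    radius: float


@dataclass(frozen=True)
class MicronucleusTruth:
    center: tuple[float, float]
    diameter: float


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    cls: str  # mono | bi | multi
    center: tuple[float, float]
    cyto_radius: float
    nuclei: tuple[NucleusTruth, ...]
    micronuclei: tuple[MicronucleusTruth, ...]
    touches_border: bool


@dataclass
class GroundTruth:
    """Per-field truth: per-cell records plus per-field class and MN tallies."""

    well_id: str
    field_index: int
    cells: list[CellTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.micronuclei and c.cls != "bi":
                raise ValueError("micronuclei placed outside a bi-nucleated cell")

    @property
    def n_mono(self) -> int:
        return sum(c.cls == "mono" for c in self.cells)

    @property
    def n_bi(self) -> int:
        return sum(c.cls == "bi" for c in self.cells)

    @property
    def n_multi(self) -> int:
        return sum(c.cls == "multi" for c in self.cells)

    @property
    def n_mn(self) -> int:
        return sum(len(c.micronuclei) for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append({
                "well_id": self.well_id, "field_index": self.field_index,
                "cell_id": c.cell_id, "class": c.cls,
                "center_row": c.center[0], "center_col": c.center[1],
                "cyto_radius": c.cyto_radius,
                "n_nuclei": len(c.nuclei), "n_mn": len(c.micronuclei),
                "touches_border": c.touches_border,
                "nuclei": ";".join(f"{n.center[0]:.2f},{n.center[1]:.2f},{n.radius:.2f}"
                                   for n in c.nuclei),
                "micronuclei": ";".join(
                    f"{m.center[0]:.2f},{m.center[1]:.2f},{m.diameter:.2f}"
                    for m in c.micronuclei),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry sampling


def _sample_cell_geometry(params: SynthParams, rng: np.random.Generator):
    """Draw class, nucleus layout (relative to cell centre) and cytoplasm radius."""
    cls = CLASS_NAMES[rng.choice(3, p=params.class_probs)]
    mean_r, sd_r = params.nucleus_radius_px
    lo, hi = 0.65 * mean_r, 1.45 * mean_r
    if cls == "mono":
        k = 1
    elif cls == "bi":
        k = 2
    else:
        k = 3 + int(rng.poisson(0.5))
    radii = np.clip(rng.normal(mean_r, sd_r, size=k), lo, hi)
    theta = rng.uniform(0, 2 * math.pi)
    if k == 1:
        offsets = np.zeros((1, 2))
    elif k == 2:
        d = radii[0] + radii[1] + _NUCLEUS_GAP
        u = np.array([math.cos(theta), math.sin(theta)])
        offsets = np.stack([-0.5 * d * u, 0.5 * d * u])
    else:
        rmax = float(radii.max())
        ring = (2 * rmax + _NUCLEUS_GAP) / (2 * math.sin(math.pi / k))
        angles = theta + 2 * math.pi * np.arange(k) / k
        offsets = ring * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    extent = float(np.max(np.linalg.norm(offsets, axis=1) + radii))
    cyto_r = max(extent + _CYTO_PAD, 2.2 * mean_r)
    return cls, radii, offsets, cyto_r


def _place_cells(params: SynthParams, geoms, rng: np.random.Generator):
    """Choose a centre for each cell, fully inside the field.

    ``clustering == 0``: sequential hard-core placement (random sequential
    adsorption), cytoplasm discs disjoint with a fixed rim gap.  ``> 0``:
    Neyman-Scott cluster process with mean cluster size ``1 + clustering``;
    overlaps are allowed (that is the point of the clustered regime).
    """
    rows, cols = params.field_shape
    centers: list[np.ndarray] = []
    if not geoms:
        return centers
    if params.clustering == 0:
        # random sequential adsorption with whole-configuration restarts
        for _ in range(8):
            centers = []
            placed_r: list[float] = []
            for _, _, _, cyto_r in geoms:
                margin = cyto_r + 2.0
                if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
                    raise GenerationError("field too small for a single cell")
                for _ in range(800):
                    c = rng.uniform([margin, margin],
                                    [rows - margin, cols - margin])
                    ok = all(np.linalg.norm(c - p) >= cyto_r + pr + _HARDCORE_GAP
                             for p, pr in zip(centers, placed_r))
                    if ok:
                        centers.append(c)
                        placed_r.append(cyto_r)
                        break
                else:
                    break  # restart from scratch
            if len(centers) == len(geoms):
                break
        else:
            raise GenerationError(
                f"could not place {len(geoms)} separated cells in a "
                f"{rows}x{cols} field")
    else:
        mean_size = 1.0 + params.clustering
        n_clusters = max(1, int(round(len(geoms) / mean_size)))
        max_r = max(g[3] for g in geoms)
        margin = max_r + 2.0
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise GenerationError("field too small for a single cell")
        parents = rng.uniform([margin, margin], [rows - margin, cols - margin],
                              size=(n_clusters, 2))
        assignment = rng.integers(0, n_clusters, size=len(geoms))
        for i, (_, _, _, cyto_r) in enumerate(geoms):
            sigma = 0.9 * cyto_r
            c = parents[assignment[i]] + rng.normal(0, sigma, size=2)
            m = cyto_r + 2.0
            c = np.clip(c, [m, m], [rows - m, cols - m])
            centers.append(c)
    return centers


def _place_micronuclei(params: SynthParams, cls: str, center, radii, offsets,
                       cyto_r: float, rng: np.random.Generator):
    """Draw Poisson(mn_rate) micronuclei inside the cytoplasm of a BNC.

    Each MN is a disc of diameter ``mn_diameter_ratio`` times the mean
    main-nucleus diameter (floor 1.5 px radius), kept clear of every main
    nucleus so that the rendered chromatin bodies never touch.
    """
    if cls != "bi" or params.mn_rate == 0:
        return []
    n = int(rng.poisson(params.mn_rate))
    mean_r = float(np.mean(radii))
    mn_r = max(1.5, params.mn_diameter_ratio * mean_r)
    out: list[MicronucleusTruth] = []
    nuc_centers = np.asarray(center) + offsets
    for _ in range(n):
        for _ in range(200):
            rho = (cyto_r - mn_r - 3.0) * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            pos = np.asarray(center) + rho * np.array([math.cos(ang), math.sin(ang)])
            d = np.linalg.norm(nuc_centers - pos, axis=1)
            if not np.all(d >= radii + mn_r + _MN_CLEARANCE):
                continue
            # MN are distinct chromatin bodies: keep them clear of each other
            # too, so the rendered image stays consistent with the truth count
            if any(np.hypot(pos[0] - m.center[0], pos[1] - m.center[1])
                   < 2 * mn_r + 3.0 for m in out):
                continue
            out.append(MicronucleusTruth(center=(float(pos[0]), float(pos[1])),
                                         diameter=2.0 * mn_r))
            break
        # if no clear spot exists the MN is dropped (truth stays consistent)
    return out


# ---------------------------------------------------------------------------
# rendering


def _render_masks(params: SynthParams, truth: GroundTruth):
    shape = params.field_shape
    dna = np.zeros(shape, dtype=np.float64)
    actin = np.zeros(shape, dtype=np.float64)
    rng_tex = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.seed)), truth.field_index, 7]))
    for cell in truth.cells:
        amp = DNA_AMPLITUDE * rng_tex.uniform(0.92, 1.08)
        rr, cc = disk(cell.center, cell.cyto_radius, shape=shape)
        actin[rr, cc] = ACTIN_AMPLITUDE * rng_tex.uniform(0.9, 1.1)
        for nuc in cell.nuclei:
            ecc = rng_tex.uniform(0.0, 0.08)
            orient = rng_tex.uniform(0, math.pi)
            rr, cc = ellipse(nuc.center[0], nuc.center[1],
                             nuc.radius * (1 + ecc), nuc.radius * (1 - ecc),
                             rotation=orient, shape=shape)
            dna[rr, cc] = amp * rng_tex.uniform(0.97, 1.03)
        for mn in cell.micronuclei:
            rr, cc = disk(mn.center, mn.diameter / 2.0, shape=shape)
            dna[rr, cc] = amp * rng_tex.uniform(0.95, 1.05)
    return dna, actin


def _gradient_plane(shape, amplitude: float, rng: np.random.Generator):
    """Smooth additive illumination trend with the given peak-to-trough span."""
    rows, cols = shape
    theta = rng.uniform(0, 2 * math.pi)
    rgrid, cgrid = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols),
                               indexing="ij")
    ramp = math.cos(theta) * rgrid + math.sin(theta) * cgrid
    ramp = ramp - ramp.min()
    span = ramp.max()
    if span > 0:
        ramp = ramp / span
    return amplitude * ramp


def _apply_noise(clean: np.ndarray, params: SynthParams,
                 rng: np.random.Generator) -> np.ndarray:
    img = clean
    if params.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, size=img.shape)
    return img.astype(np.float32)


def generate_field(params: SynthParams, field_index: int = 0,
                   well_id: str = "") -> tuple[ImageField, GroundTruth]:
    """Generate one synthetic field of view plus its ground truth.

    Deterministic for a fixed ``(params.seed, field_index)``; cells are always
    placed whole (centre at least one cytoplasm radius from the border), so
    per-field truth tallies cover every rendered cell.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.seed)), int(field_index)]))
    geoms = [_sample_cell_geometry(params, rng)
             for _ in range(params.cells_per_field)]
    centers = _place_cells(params, geoms, rng)
    cells: list[CellTruth] = []
    rows, cols = params.field_shape
    for i, ((cls, radii, offsets, cyto_r), center) in enumerate(zip(geoms, centers)):
        nuclei = tuple(
            NucleusTruth(center=(float(center[0] + off[0]),
                                 float(center[1] + off[1])),
                         radius=float(r))
            for off, r in zip(offsets, radii))
        mns = tuple(_place_micronuclei(params, cls, center, radii, offsets,
                                       cyto_r, rng))
        touches = bool(center[0] - cyto_r < 0 or center[1] - cyto_r < 0
                       or center[0] + cyto_r > rows or center[1] + cyto_r > cols)
        cells.append(CellTruth(cell_id=i + 1, cls=cls,
                               center=(float(center[0]), float(center[1])),
                               cyto_radius=float(cyto_r), nuclei=nuclei,
                               micronuclei=mns, touches_border=touches))
    truth = GroundTruth(well_id=well_id, field_index=field_index, cells=cells)

    dna_mask, actin_mask = _render_masks(params, truth)
    actin_sm = ndi.gaussian_filter(actin_mask, 1.5)
    grad_dir_rng = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.seed)), int(field_index), 11]))
    g = params.background_gradient
    dna = BACKGROUND_LEVEL + dna_mask + _gradient_plane(
        params.field_shape, g * DNA_AMPLITUDE, grad_dir_rng)
    grad_dir_rng = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.seed)), int(field_index), 11]))
    actin = BACKGROUND_LEVEL + actin_sm + _gradient_plane(
        params.field_shape, g * ACTIN_AMPLITUDE, grad_dir_rng)

    noise_rng = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.seed)), int(field_index), 13]))
    channels = {"dna": _apply_noise(dna, params, noise_rng),
                "actin": _apply_noise(actin, params, noise_rng)}

    if params.include_reporter:
        cyto_bin = (actin_mask > 0).astype(np.float64)
        reporter = REPORTER_BASELINE * (
            1.0 + (params.reporter_fold - 1.0) * cyto_bin)
        grad_dir_rng = np.random.default_rng(
            np.random.SeedSequence([abs(int(params.seed)), int(field_index), 11]))
        reporter = reporter + _gradient_plane(
            params.field_shape, g * REPORTER_BASELINE, grad_dir_rng)
        phase = PHASE_BACKGROUND + PHASE_AMPLITUDE * ndi.gaussian_filter(cyto_bin, 1.5)
        channels["reporter"] = _apply_noise(reporter, params, noise_rng)
        channels["phase"] = _apply_noise(phase, params, noise_rng)

    fld = ImageField(channels=channels, well_id=well_id, field_index=field_index)
    return fld, truth


def _well_seed(base_seed: int, well_number: int) -> int:
    # splitmix-style well decorrelation, kept below 2**31
    return int((abs(int(base_seed)) * 1_000_003 + 7919 * (well_number + 1))
               % 2_147_483_647)


def iter_plate(layout: PlateLayout,
               params_per_group: Mapping[str, SynthParams],
               ) -> Iterator[tuple[ImageField, GroundTruth]]:
    """Lazily generate ``fields_per_well`` fields for every well of a layout.

    Every well in the layout must have a parameter set for its group; per-well
    seeds are derived deterministically from the group seed and well position.
    """
    missing = [w.group for w in layout.wells if w.group not in params_per_group]
    if missing:
        raise ParameterError(f"no SynthParams for group(s): {sorted(set(missing))}")
    for wi, well in enumerate(layout.wells):
        params = params_per_group[well.group]
        wparams = replace(params, seed=_well_seed(params.seed, wi))
        for fi in range(layout.fields_per_well):
            yield generate_field(wparams, field_index=fi, well_id=well.well_id)


def generate_plate(layout: PlateLayout,
                   params_per_group: Mapping[str, SynthParams],
                   ) -> tuple[list[ImageField], list[GroundTruth]]:
    """Generate a whole plate eagerly; see :func:`iter_plate`."""
    fields: list[ImageField] = []
    truths: list[GroundTruth] = []
    for fld, truth in iter_plate(layout, params_per_group):
        fields.append(fld)
        truths.append(truth)
    return fields, truths


def truths_to_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Concatenate per-field truth tables into one tidy frame."""
    frames = [t.to_frame() for t in truths if t.cells]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
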