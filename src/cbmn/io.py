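"""Image, plate-layout and results I/O with stable schemas.

Images are stored one TIFF per field of view with channels as planes; the
channel order is declared by the caller (default ``("dna", "actin")``,
optionally extended with ``"reporter"`` and ``"phase"``).  Plate layouts are
YAML or CSV; results tables are tidy CSV with one row per well.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Canonical channel roles, in the plane order used when writing TIFFs.
CHANNEL_ROLES = ("dna", "actin", "reporter", "phase")

#: Columns of a results table (one row per well).
RESULTS_COLUMNS = [
    "well_id", "group", "treatment", "concentration", "n_fields",
    "n_mono", "n_bi", "n_multi", "n_total_scored", "n_mn",
    "cbpi", "pct_bnc", "mn_per_1000_bnc", "qc_flags",
]


class LayoutError(ValueError):
    """Invalid or inconsistent plate-layout description."""


class ImageIOError(IOError):
    """Unreadable image file or channel-count mismatch."""


@dataclass
class ImageField:
    """One field of view: named 2-D channels plus acquisition metadata.

    Channels are keyed by role (``dna``, ``actin``, ``reporter``, ``phase``);
    all share one shape, 0-based row-major pixel convention.  The DNA channel
    is required for nuclear scoring; DNA + actin for cytoplasm assembly.
    """

    channels: dict[str, np.ndarray]
    well_id: str = ""
    field_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        unknown = set(self.channels) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def roles(self) -> tuple[str, ...]:
        """Present channel roles in canonical plane order."""
        return tuple(r for r in CHANNEL_ROLES if r in self.channels)


@dataclass(frozen=True)
class WellSpec:
    """One well of the plate layout."""

    well_id: str
    group: str
    treatment: str = "vehicle"
    concentration: float = 0.0
    units: str = "ug/mL"
    particle_size_nm: str = ""
    replicate: int = 1


@dataclass
class PlateLayout:
    """Plate layout: per-well treatment records plus fields per well.

    The default of 61 fields of view per well matches a full-well tiling on
    a 20x high-content run of a 96-well plate.
    """

    wells: list[WellSpec]
    fields_per_well: int = 61

    def __post_init__(self) -> None:
        if not self.wells:
            raise LayoutError("layout contains no wells")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate well_id(s): {dupes}")
        if self.fields_per_well < 1:
            raise LayoutError("fields_per_well must be >= 1")
        for w in self.wells:
            if w.concentration < 0:
                raise LayoutError(f"negative concentration in well {w.well_id}")

    def groups(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.group not in out:
                out.append(w.group)
        return out

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)


def write_field(fld: ImageField, path: str | os.PathLike) -> None:
    """Write one field as a multi-plane TIFF (planes in canonical role order)."""
    stack = np.stack([fld.channels[r] for r in fld.roles()]).astype(np.float32)
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        metadata={"axes": "CYX", "channels": ",".join(fld.roles()),
                  "well_id": fld.well_id, "field_index": fld.field_index},
    )


def read_field(path: str | os.PathLike, well_id: str = "", field_index: int = 0,
               channel_order: Sequence[str] = ("dna", "actin")) -> ImageField:
    """Read a multi-plane TIFF into an :class:`ImageField`.

    ``channel_order`` names the role of each plane; a plane-count mismatch is
    an error naming the file.
    """
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:  # pragma: no cover - passthrough
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ImageIOError(f"{path}: expected 2-D planes, got shape {arr.shape}")
    if arr.shape[0] != len(channel_order):
        raise ImageIOError(
            f"{path}: file has {arr.shape[0]} plane(s) but channel_order "
            f"declares {len(channel_order)}")
    channels = {role: np.asarray(arr[i], dtype=np.float64)
                for i, role in enumerate(channel_order)}
    return ImageField(channels=channels, well_id=well_id, field_index=field_index)


def field_filename(well_id: str, field_index: int) -> str:
    """Canonical per-field file name, e.g. ``B03_f007.tif``."""
    return f"{well_id}_f{field_index:03d}.tif"


_LAYOUT_COLUMNS = {"well_id", "group"}
_LAYOUT_OPTIONAL = {"treatment", "concentration", "units", "particle_size_nm",
                    "replicate"}


def _well_from_record(rec: Mapping) -> WellSpec:
    unknown = set(rec) - _LAYOUT_COLUMNS - _LAYOUT_OPTIONAL
    if unknown:
        raise LayoutError(f"unknown layout keys: {sorted(unknown)}")
    missing = _LAYOUT_COLUMNS - set(rec)
    if missing:
        raise LayoutError(f"layout record missing keys: {sorted(missing)}")
    return WellSpec(
        well_id=str(rec["well_id"]),
        group=str(rec["group"]),
        treatment=str(rec.get("treatment", "vehicle")),
        concentration=float(rec.get("concentration", 0.0)),
        units=str(rec.get("units", "ug/mL")),
        particle_size_nm=str(rec.get("particle_size_nm", "")),
        replicate=int(rec.get("replicate", 1)),
    )


def read_layout(path: str | os.PathLike) -> PlateLayout:
    """Read a plate layout from YAML (``wells:`` list) or CSV (one row per well)."""
    path = os.fspath(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "wells" not in doc or not doc["wells"]:
            raise LayoutError(f"{path}: layout must be a mapping with a non-empty "
                              "'wells' list")
        extra = set(doc) - {"wells", "fields_per_well"}
        if extra:
            raise LayoutError(f"{path}: unknown layout keys {sorted(extra)}")
        wells = [_well_from_record(rec) for rec in doc["wells"]]
        return PlateLayout(wells=wells,
                           fields_per_well=int(doc.get("fields_per_well", 61)))
    df = pd.read_csv(path)
    if df.empty:
        raise LayoutError(f"{path}: empty layout file")
    fields_per_well = 61
    if "fields_per_well" in df.columns:
        fields_per_well = int(df["fields_per_well"].iloc[0])
        df = df.drop(columns=["fields_per_well"])
    wells = [_well_from_record(rec) for rec in df.to_dict("records")]
    return PlateLayout(wells=wells, fields_per_well=fields_per_well)


def write_layout(layout: PlateLayout, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    recs = [{"well_id": w.well_id, "group": w.group, "treatment": w.treatment,
             "concentration": w.concentration, "units": w.units,
             "particle_size_nm": w.particle_size_nm, "replicate": w.replicate}
            for w in layout.wells]
    if path.endswith((".yaml", ".yml")):
        with open(path, "w") as fh:
            yaml.safe_dump({"fields_per_well": layout.fields_per_well,
                            "wells": recs}, fh, sort_keys=False)
    else:
        pd.DataFrame(recs).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as CSV with a fixed header."""
    table.to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "well_id" not in df.columns:
        raise ValueError(f"{path}: not a results table (no well_id column)")
    return df
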