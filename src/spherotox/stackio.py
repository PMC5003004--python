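"""Image-stack and table I/O, plus the unit and coordinate conventions.

Conventions used throughout the toolkit:

* All lengths are micrometres (μm), volumes μm³, concentrations μM.
* Voxel indices are 0-based ``[z][y][x]``; plane 0 is the bottom-most
  plane (the well bottom), z increases upward into the sample.
* Physical coordinates are reported in μm relative to the stack origin,
  the bottom-left corner of plane 0, as ``(x, y, z)``.
* XY pixel size and Z step are independent (anisotropic voxels); every
  distance or volume is computed in physical units, never voxel counts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("DAPI", "FITC", "TexasRed")


class StackParseError(ValueError):
    """Raised when a stack file cannot be interpreted as a valid Z-stack."""


class LayoutError(ValueError):
    """Raised when a plate layout fails validation."""


@dataclass
class ImageStack:
    """Multi-channel confocal Z-stack with physical calibration.

    ``data`` has shape ``(n_channels, n_planes, ny, nx)``; all channels
    share dimensions.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    well_id: str = ""
    site_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise StackParseError(
                f"stack data must be (C, Z, Y, X); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise StackParseError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) voxel grid for a named channel."""
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (has {list(self.channel_names)})"
            ) from None
        return self.data[idx]

    def plane_z_um(self, z_index: int) -> float:
        return z_index * self.z_step_um


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a plane-major multi-page TIFF with a JSON description block.

    Pages are ordered Z-major, channel-minor (plane 0 channel 0, plane 0
    channel 1, ...), with calibration and channel names stored in the
    ImageDescription tag so a round trip is lossless.
    """
    path = Path(path)
    desc = {
        "spherotox": True,
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "n_planes": stack.n_planes,
        "n_channels": stack.n_channels,
        "well_id": stack.well_id,
        "site_id": stack.site_id,
        "metadata": stack.metadata,
    }
    # (C,Z,Y,X) -> (Z,C,Y,X) page order
    pages = np.swapaxes(stack.data, 0, 1)
    tifffile.imwrite(
        path,
        pages.reshape(-1, *stack.shape_yx),
        description=json.dumps(desc),
        metadata=None,
    )
    return path


def read_stack(
    path: str | Path,
    default_pixel_size_um: float = 1.0,
    default_z_step_um: float = 10.0,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF Z-stack into an :class:`ImageStack`.

    Files written by :func:`write_stack` restore exactly. Foreign TIFFs
    (including OME-TIFF) are accepted: axes are deduced from the series
    shape and missing physical calibration falls back to the provided
    defaults with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arr = series.asarray()
            desc = tf.pages[0].description or ""
            axes = series.axes
    except (tifffile.TiffFileError, ValueError, IndexError) as exc:
        raise StackParseError(f"cannot parse {path.name}: {exc}") from exc

    meta = None
    if desc:
        try:
            cand = json.loads(desc)
            if isinstance(cand, dict) and cand.get("spherotox"):
                meta = cand
        except json.JSONDecodeError:
            meta = None

    if meta is not None:
        nz, nc = int(meta["n_planes"]), int(meta["n_channels"])
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[0] != nz * nc:
            raise StackParseError(
                f"{path.name}: expected {nz * nc} pages "
                f"({nz} planes x {nc} channels), found {arr.shape[0]}"
            )
        data = arr.reshape(nz, nc, *arr.shape[1:]).swapaxes(0, 1)
        return ImageStack(
            data=data,
            pixel_size_um=float(meta["pixel_size_um"]),
            z_step_um=float(meta["z_step_um"]),
            channel_names=meta["channel_names"],
            well_id=meta.get("well_id", ""),
            site_id=meta.get("site_id", ""),
            metadata=meta.get("metadata", {}),
        )

    # Foreign TIFF: use the series axes when informative.
    if arr.ndim == 2:
        data = arr[None, None]
    elif arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            data = arr[:, None] if axes.startswith("C") else arr[None]
        else:
            data = arr[None]  # treat pages as planes of one channel
    elif arr.ndim == 4:
        data = arr.swapaxes(0, 1) if axes.startswith("Z") else arr
    else:
        raise StackParseError(f"{path.name}: unsupported TIFF dimensionality {arr.ndim}")
    names = list(channel_names) if channel_names else [
        f"ch{i}" for i in range(data.shape[0])
    ]
    logger.warning(
        "%s carries no physical calibration; using defaults %.3g um/px, %.3g um z-step",
        path.name, default_pixel_size_um, default_z_step_um,
    )
    return ImageStack(
        data=data,
        pixel_size_um=default_pixel_size_um,
        z_step_um=default_z_step_um,
        channel_names=names,
    )


# --------------------------------------------------------------------------
# plate layouts and readout tables

PLATEMAP_ROLES = ("treated", "vehicle_control", "positive_control")


@dataclass
class PlateLayout:
    """Well/dose layout for one plate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well_id", "compound_name", "dose_uM", "replicate_id", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise LayoutError(f"plate map missing columns: {sorted(missing)}")
        dup = self.table["well_id"][self.table["well_id"].duplicated()]
        if len(dup):
            raise LayoutError(f"duplicate well ids: {sorted(dup.unique().tolist())}")
        bad_dose = self.table[self.table["dose_uM"] < 0]
        if len(bad_dose):
            raise LayoutError(
                f"negative doses in wells: {bad_dose['well_id'].tolist()}"
            )
        bad_role = self.table[~self.table["role"].isin(PLATEMAP_ROLES)]
        if len(bad_role):
            raise LayoutError(f"unknown roles in wells: {bad_role['well_id'].tolist()}")
        vc = self.table[self.table["role"] == "vehicle_control"]
        nonzero = vc[vc["dose_uM"] != 0]
        if len(nonzero):
            raise LayoutError(
                f"vehicle controls with nonzero dose: {nonzero['well_id'].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def wells(self, role: str | None = None) -> pd.DataFrame:
        if role is None:
            return self.table
        return self.table[self.table["role"] == role]


def read_platemap(path: str | Path) -> PlateLayout:
    """Read a CSV plate map (columns well_id, compound_name, dose_uM,
    replicate_id, role) with validation."""
    df = pd.read_csv(path)
    if df.empty and set(df.columns) >= {"well_id"} is False:
        warnings.warn(f"empty plate map: {path}")
    if df.empty:
        warnings.warn(f"plate map {path} contains no wells")
        df = pd.DataFrame(
            columns=["well_id", "compound_name", "dose_uM", "replicate_id", "role"]
        )
    return PlateLayout(df)


def write_platemap(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    layout.table.to_csv(path, index=False)
    return path


def write_readouts(readouts: pd.DataFrame | list, path: str | Path) -> Path:
    """Write per-well readout rows as CSV, dot-decimal, 12 significant digits."""
    path = Path(path)
    if not isinstance(readouts, pd.DataFrame):
        readouts = pd.DataFrame([r.as_dict() if hasattr(r, "as_dict") else r
                                 for r in readouts])
    readouts.to_csv(path, index=False, float_format="%.12g")
    return path


def read_readouts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
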