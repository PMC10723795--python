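"""Reading, writing, and projecting multichannel fluorescence images.

Images are held as :class:`ImageField` objects: a mapping of channel name to a
2D non-negative intensity array plus minimal acquisition metadata. Pixel
coordinates are 0-based, row-major ``(row, column)`` throughout the package,
and every mask produced downstream shares that convention.

Multi-field experiments (e.g. a screening plate exported as one TIFF per
channel per field) are described by a plain manifest CSV with columns
``field_id, well_id, path`` and an optional ``channel`` column:

* with a ``channel`` column, each row points at a single-channel TIFF and
  rows sharing a ``field_id`` are assembled into one field (the screen's
  one-file-per-channel export dialect, the default);
* without it, each row points at a multipage TIFF whose pages are named
  through a ``channel_map``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageField",
    "read_field",
    "write_field",
    "project_stack",
    "read_manifest",
    "iter_manifest_fields",
    "write_manifest",
]


@dataclass
class ImageField:
    """A registered multichannel 2D image.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D non-negative intensity array. All
        arrays must share identical dimensions.
    pixel_size_um
        Physical pixel size in micrometres, if known.
    field_id, well_id
        Identifiers linking the field to a plate layout.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    field_id: str = "field"
    well_id: str | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField requires at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if shape != first:
                raise ValueError(
                    f"channel {name!r} has shape {shape}, expected {first}"
                )
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D (shape {arr.shape})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _as_float(arr: np.ndarray) -> np.ndarray:
    """Promote unsigned/integer pixel data to float64 before arithmetic.

    Background subtraction on unsigned integers would wrap around zero;
    promoting once on read makes all downstream arithmetic safe.
    """
    return np.asarray(arr, dtype=np.float64)


def read_field(
    path: str | os.PathLike,
    channel_map: Mapping[int, str],
    *,
    field_id: str | None = None,
    well_id: str | None = None,
    pixel_size_um: float | None = None,
) -> ImageField:
    """Read a single- or multi-page TIFF into a named-channel :class:`ImageField`.

    ``channel_map`` maps page index -> channel name. Z-stacks stored as pages
    are not interpreted here; a page is one channel plane. Use
    :func:`project_stack` first for z-stacks stored as separate arrays.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of shape {data.shape}")
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-numeric pixel data ({data.dtype})")
    channels: dict[str, np.ndarray] = {}
    for index, name in channel_map.items():
        if not 0 <= index < data.shape[0]:
            raise IndexError(
                f"{path}: channel index {index} out of range for {data.shape[0]} page(s)"
            )
        channels[name] = data[index]
    return ImageField(
        channels=channels,
        pixel_size_um=pixel_size_um,
        field_id=field_id if field_id is not None else os.path.basename(path),
        well_id=well_id,
    )


def write_field(field: ImageField, path: str | os.PathLike) -> list[str]:
    """Write an :class:`ImageField` to a multipage TIFF, one page per channel.

    Returns the channel order written (page i holds channel ``order[i]``), so
    a round trip through :func:`read_field` with ``{i: order[i]}`` is
    bit-exact for integer pixel types.
    """
    order = field.channel_names
    stack = np.stack([field.channels[name] for name in order])
    tifffile.imwrite(os.fspath(path), stack, photometric="minisblack")
    return order


def project_stack(stack: np.ndarray, method: str = "sum") -> np.ndarray:
    """Project a z-stack (planes, rows, cols) into a single 2D plane.

    ``method="sum"`` gives sum-intensity projections (total-intensity
    preserving, used for nascent-RNA quantification); ``method="max"`` gives
    maximum-intensity projections (used for live imaging). A single-plane
    stack is returned unchanged.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a non-empty 3D stack, got shape {stack.shape}")
    if method == "sum":
        return _as_float(stack).sum(axis=0)
    if method == "max":
        return stack.max(axis=0)
    raise ValueError(f"unknown projection method {method!r} (use 'sum' or 'max')")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a manifest CSV (field_id, well_id, path[, channel])."""
    manifest = pd.read_csv(path, dtype=str)
    required = {"field_id", "well_id", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def write_manifest(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    rows.to_csv(path, index=False)


def iter_manifest_fields(
    manifest: pd.DataFrame,
    channel_map: Mapping[int, str] | None = None,
    *,
    root: str | os.PathLike | None = None,
) -> Iterator[ImageField]:
    """Yield :class:`ImageField` objects described by a manifest table.

    If the manifest has a ``channel`` column, rows are grouped by field and
    each row's file contributes one channel; otherwise each row is a
    multipage TIFF decoded with ``channel_map``.
    """

    def _resolve(p: str) -> str:
        return os.path.join(os.fspath(root), p) if root is not None else p

    if "channel" in manifest.columns:
        for field_id, group in manifest.groupby("field_id", sort=False):
            channels: dict[str, np.ndarray] = {}
            well = group["well_id"].iloc[0]
            for _, row in group.iterrows():
                data = tifffile.imread(_resolve(row["path"]))
                channels[row["channel"]] = np.asarray(data)
            yield ImageField(channels=channels, field_id=str(field_id), well_id=well)
    else:
        if channel_map is None:
            raise ValueError("channel_map required for multipage-TIFF manifests")
        for _, row in manifest.iterrows():
            yield read_field(
                _resolve(row["path"]),
                channel_map,
                field_id=str(row["field_id"]),
                well_id=row["well_id"],
            )
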