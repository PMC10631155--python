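"""Reading and writing segmentation masks and result tables.

The pipeline's unit of analysis is a single muscle's binary cross-section on
one transverse slice (:class:`CrossSectionMask`).  Multi-muscle segmentations
arrive as integer label volumes (:class:`LabelVolume`), conventionally stored
as NIfTI with one positive integer per muscle, or as directories of per-slice
2-D mask files (PNG or 0/1 CSV).

Conventions enforced here and relied on by every downstream module:

* the first axis of ``LabelVolume.voxels`` indexes transverse slices
  (the NIfTI reader transposes its ``(x, y, z)`` array to ``(z, y, x)``);
* pixel indices are 0-based and the physical coordinate of a pixel is its
  center, ``(index + 0.5) * spacing``;
* masks are filled regions — every foreground pixel, not just the boundary,
  belongs to the shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import MaskFormatError

logger = logging.getLogger(__name__)

#: Sentinel written to the J column for slices whose segmentation coincides
#: exactly with the rasterized fitted ellipse (zero symmetric difference).
DEGENERATE_SENTINEL = "degenerate"


@dataclass(frozen=True)
class CrossSectionMask:
    """One muscle's binary cross-section on a 2-D pixel grid.

    Parameters
    ----------
    grid : ndarray of bool, shape (rows, cols)
        Foreground = muscle.
    pixel_spacing_mm : (float, float)
        Physical size of a pixel along (row, col), strictly positive.
    slice_index : int
        Index of the transverse slice this mask was taken from.
    muscle : str
        Muscle name.
    """

    grid: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_index: int = 0
    muscle: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {grid.shape}")
        sy, sx = self.pixel_spacing_mm
        if not (sy > 0 and sx > 0):
            raise ValueError("pixel spacing must be strictly positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_foreground * self.pixel_area_mm2


@dataclass
class LabelVolume:
    """Integer label volume: voxels[slice, row, col] identifies the muscle.

    ``label_names`` maps each positive integer label to a muscle name.  Voxel
    values absent from the mapping are treated as background.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if min(self.voxels.shape) < 1:
            raise ValueError("every volume axis must have extent >= 1")
        sy, sx = self.pixel_spacing_mm
        if not (sy > 0 and sx > 0 and self.slice_thickness_mm > 0):
            raise ValueError("spacings and slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])

    def present_labels(self) -> set[int]:
        """Distinct nonzero voxel values actually present in the volume."""
        values = np.unique(self.voxels)
        return {int(v) for v in values if v != 0}


def read_label_volume(
    path: str | Path, label_names: Mapping[int, str]
) -> LabelVolume:
    """Read a NIfTI label volume into the pipeline's slice-first convention.

    The NIfTI data array is interpreted as ``(x, y, z)`` with z the
    slice-stacking (transverse) axis and transposed to ``(slice, row, col)``.
    Spacings come from the header zooms.  Voxel values not in ``label_names``
    are kept in the array but treated as background downstream; a warning is
    logged when any are present.
    """
    path = Path(path)
    if not label_names:
        raise ValueError("label_names must be non-empty")
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several concrete types
        raise OSError(f"could not read label volume {path}: {exc}") from exc

    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not (isinstance(z, Real) and z > 0) for z in zooms):
        raise MaskFormatError(f"{path}: header has no usable voxel spacing")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskFormatError(f"{path}: expected a 3-D volume, got {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise MaskFormatError(f"{path}: voxel values are not integral")
        data = rounded.astype(np.int32)
    # (x, y, z) -> (slice=z, row=y, col=x)
    voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    sx, sy, sz = (float(z) for z in zooms)

    volume = LabelVolume(
        voxels=voxels,
        pixel_spacing_mm=(sy, sx),
        slice_thickness_mm=sz,
        label_names=dict(label_names),
    )
    unknown = volume.present_labels() - set(label_names)
    if unknown:
        logger.warning(
            "%s: voxel values %s are not in label_names; treated as background",
            path,
            sorted(unknown),
        )
    return volume


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` as NIfTI, inverse of :func:`read_label_volume`."""
    path = Path(path)
    sy, sx = volume.pixel_spacing_mm
    affine = np.diag([sx, sy, volume.slice_thickness_mm, 1.0])
    # (slice, row, col) -> (x, y, z)
    data = np.ascontiguousarray(
        np.transpose(volume.voxels, (2, 1, 0)).astype(np.int16)
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, volume.slice_thickness_mm))
    nib.save(img, str(path))


def extract_slice_mask(
    volume: LabelVolume, slice_index: int, label: int
) -> CrossSectionMask:
    """Binary mask of one muscle on one transverse slice.

    Raises
    ------
    IndexError
        If ``slice_index`` is out of range.
    KeyError
        If ``label`` is not in the volume's label mapping.
    """
    if not 0 <= slice_index < volume.n_slices:
        raise IndexError(
            f"slice_index {slice_index} out of range [0, {volume.n_slices})"
        )
    if label not in volume.label_names:
        raise KeyError(f"label {label} not in label_names {sorted(volume.label_names)}")
    return CrossSectionMask(
        grid=volume.voxels[slice_index] == label,
        pixel_spacing_mm=volume.pixel_spacing_mm,
        slice_index=slice_index,
        muscle=volume.label_names[label],
    )


def read_mask_file(
    path: str | Path,
    pixel_spacing_mm: tuple[float, float],
    slice_index: int = 0,
    muscle: str = "",
) -> CrossSectionMask:
    """Read a single 2-D mask from a PNG (nonzero = foreground) or 0/1 CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".png":
        with Image.open(path) as im:
            grid = np.asarray(im.convert("L")) > 0
    elif suffix == ".csv":
        grid = np.loadtxt(path, delimiter=",", dtype=float)
        grid = np.atleast_2d(grid) != 0
    else:
        raise MaskFormatError(f"unsupported mask format: {path.suffix}")
    return CrossSectionMask(
        grid=grid,
        pixel_spacing_mm=pixel_spacing_mm,
        slice_index=slice_index,
        muscle=muscle,
    )


def read_mask_directory(
    directory: str | Path, pixel_spacing_mm: tuple[float, float]
) -> list[CrossSectionMask]:
    """Read every ``<muscle>_<slice>.png|.csv`` file in a directory.

    Files are sorted by (muscle, slice index).  The slice index is the final
    underscore-separated token of the stem.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"mask directory not found: {directory}")
    masks = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in {".png", ".csv"}:
            continue
        stem = path.stem
        muscle, _, idx = stem.rpartition("_")
        if not muscle or not idx.isdigit():
            raise MaskFormatError(
                f"{path.name}: expected file name <muscle>_<slice>{path.suffix}"
            )
        masks.append(
            read_mask_file(
                path, pixel_spacing_mm, slice_index=int(idx), muscle=muscle
            )
        )
    masks.sort(key=lambda m: (m.muscle, m.slice_index))
    return masks


def _format_value(value: object) -> object:
    if isinstance(value, bool):
        return value
    if isinstance(value, Real) and not isinstance(value, (int, np.integer)):
        v = float(value)
        if math.isnan(v):
            return DEGENERATE_SENTINEL
        return f"{v:.8g}"
    return value


def write_results_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write per-slice or per-muscle records as a CSV table.

    Column order follows the first record (or ``columns``); floats are
    rendered with 8 significant digits; NaN J values (degenerate slices) are
    written as the sentinel ``"degenerate"``.  An empty record list yields a
    header-only file; pass ``columns`` to name the header in that case.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        records = list(rows)
        df = pd.DataFrame(records, columns=columns if not records else None)
    formatted = df.map(_format_value)
    formatted.to_csv(path, index=False)
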