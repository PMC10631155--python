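"""Synthetic thigh phantom: label volumes for a three-position study.

The generator builds what the analysis assumes about real data: per muscle,
a stack of filled near-elliptical cross-sections whose axes taper smoothly
towards the muscle ends, and whose deviation from ellipticity — a one-sided
chordal "flattening" that mimics surface-contact compression of the
posterior thigh in supine lying — varies by positioning condition and muscle
group.  Optional boundary noise flips pixels within one pixel of the region
boundary, emulating segmentation jitter without disconnecting the region.

Flattening is a chordal truncation (D-shape): the fraction ``f`` of the
region's y-extent on the low-y (posterior) side is cut away.  ``f = 0``
leaves the ellipse untouched; the default study schedule gives the
hamstrings an elevation-dependent flattening while the quadriceps stay
nearly constant, so the hamstrings' J index changes across positions and
the quadriceps' barely does.

All randomness flows from a single integer seed via ``numpy``'s
``SeedSequence``; identical specs with identical seeds produce byte-identical
volumes.  The ground-truth manifest records every generating parameter per
slice.

Geometry is schematic and scaled down relative to an adult thigh so that
seven non-overlapping muscles fit a compact grid; it is not an anatomical
atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .ellipse_fit import EllipseFit
from .exceptions import GenerationError
from .jindex import pixel_center_grid
from .mask_io import CrossSectionMask, LabelVolume, write_label_volume
import logging

logger = logging.getLogger(__name__)

HAMSTRINGS = ("biceps_femoris", "semitendinosus", "semimembranosus")
QUADRICEPS = (
    "rectus_femoris",
    "vastus_intermedius",
    "vastus_lateralis",
    "vastus_medialis",
)

#: Positioning conditions and their nominal femur-to-plane angles (degrees):
#: pillow-supported knee elevation high / moderate / none.
DEFAULT_POSITIONS: tuple[tuple[str, float], ...] = (
    ("high", 15.0),
    ("moderate", 12.0),
    ("none", 8.0),
)

#: Flattening fraction per position per muscle group.  Hamstring flattening
#: tracks the positioning change; quadriceps flattening is small and constant.
DEFAULT_FLATTENING: dict[str, dict[str, float]] = {
    "none": {"hamstrings": 0.05, "quadriceps": 0.02},
    "moderate": {"hamstrings": 0.15, "quadriceps": 0.02},
    "high": {"hamstrings": 0.30, "quadriceps": 0.02},
}

MAX_FLATTENING = 0.45


@dataclass(frozen=True)
class MusclePhantomSpec:
    """Parametric description of one synthetic muscle.

    The cross-section at normalised length ``s`` in [0, 1] is an ellipse with
    semi-axes ``(a0, b0) * (4 s (1 - s)) ** taper`` (mid-length = the base
    axes, smoothly shrinking towards the ends), centered on a straight track
    from ``center_mm`` to ``center_mm + center_drift_mm``.  An explicit
    ``center_track`` overrides the linear track.
    """

    name: str
    label: int
    group: str  # "hamstrings" | "quadriceps"
    base_semi_axes_mm: tuple[float, float]
    center_mm: tuple[float, float]
    orientation_deg: float = 0.0
    center_drift_mm: tuple[float, float] = (0.0, 0.0)
    axis_taper: float = 0.15
    center_track: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        a0, b0 = self.base_semi_axes_mm
        if not a0 >= b0 > 0:
            raise ValueError("base semi-axes must satisfy a0 >= b0 > 0")
        if self.label <= 0:
            raise ValueError("label must be a positive integer")
        if self.group not in {"hamstrings", "quadriceps"}:
            raise ValueError(f"unknown muscle group {self.group!r}")

    def semi_axes_at(self, s: float) -> tuple[float, float]:
        scale = (4.0 * s * (1.0 - s)) ** self.axis_taper
        a0, b0 = self.base_semi_axes_mm
        return a0 * scale, b0 * scale

    def center_at(self, s: float, n_slices: int, slice_index: int) -> tuple[float, float]:
        if self.center_track is not None:
            return self.center_track[slice_index]
        cx, cy = self.center_mm
        dx, dy = self.center_drift_mm
        return cx + s * dx, cy + s * dy


@dataclass(frozen=True)
class PhantomStudySpec:
    """Full parametric description of a synthetic three-position study."""

    grid: tuple[int, int, int]  # (n_slices, rows, cols)
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    muscles: tuple[MusclePhantomSpec, ...]
    positions: tuple[tuple[str, float], ...] = DEFAULT_POSITIONS
    flattening_by_position: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_FLATTENING
    )
    boundary_noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [m.label for m in self.muscles]
        if len(set(labels)) != len(labels):
            raise ValueError("muscle labels must be unique")
        position_names = {name for name, _ in self.positions}
        for pos, groups in self.flattening_by_position.items():
            if pos not in position_names:
                raise ValueError(f"flattening given for unknown position {pos!r}")
            for group, f in groups.items():
                if not 0.0 <= f <= MAX_FLATTENING:
                    raise ValueError(
                        f"flattening fraction {f} for {pos}/{group} outside "
                        f"[0, {MAX_FLATTENING}]"
                    )
        if self.boundary_noise_sd_mm < 0:
            raise ValueError("boundary_noise_sd_mm must be >= 0")

    @property
    def label_names(self) -> dict[int, str]:
        return {m.label: m.name for m in self.muscles}


def default_study_spec(
    seed: int = 0,
    n_slices: int = 40,
    boundary_noise_sd_mm: float = 0.3,
    pixel_spacing_mm: tuple[float, float] = (0.65, 0.65),
    slice_thickness_mm: float = 3.0,
) -> PhantomStudySpec:
    """The canonical seven-muscle, three-position phantom study.

    Voxel geometry follows the acquisition grid of the study this package
    models (0.65 x 0.65 x 3.0 mm); muscle sizes are scaled-down schematics
    arranged with the quadriceps anterior (high y) and hamstrings posterior
    (low y).  Boundary noise defaults to about half a pixel of segmentation
    jitter.
    """
    muscles = (
        MusclePhantomSpec("rectus_femoris", 1, "quadriceps", (15.0, 12.0),
                          (50.0, 105.0), orientation_deg=10.0,
                          center_drift_mm=(3.0, -2.0)),
        MusclePhantomSpec("vastus_intermedius", 2, "quadriceps", (19.0, 11.0),
                          (72.0, 80.0), orientation_deg=0.0,
                          center_drift_mm=(-2.0, 2.0)),
        MusclePhantomSpec("vastus_lateralis", 3, "quadriceps", (20.0, 13.0),
                          (104.0, 102.0), orientation_deg=125.0,
                          center_drift_mm=(-3.0, 0.0)),
        MusclePhantomSpec("vastus_medialis", 4, "quadriceps", (14.0, 11.0),
                          (27.0, 76.0), orientation_deg=55.0,
                          center_drift_mm=(2.0, 2.0)),
        MusclePhantomSpec("biceps_femoris", 5, "hamstrings", (16.0, 12.0),
                          (100.0, 38.0), orientation_deg=160.0,
                          center_drift_mm=(-2.0, 3.0)),
        MusclePhantomSpec("semitendinosus", 6, "hamstrings", (12.0, 10.0),
                          (70.0, 30.0), orientation_deg=0.0,
                          center_drift_mm=(0.0, 2.0)),
        MusclePhantomSpec("semimembranosus", 7, "hamstrings", (14.0, 11.0),
                          (40.0, 38.0), orientation_deg=20.0,
                          center_drift_mm=(2.0, 3.0)),
    )
    return PhantomStudySpec(
        grid=(n_slices, 200, 200),
        pixel_spacing_mm=pixel_spacing_mm,
        slice_thickness_mm=slice_thickness_mm,
        muscles=muscles,
        boundary_noise_sd_mm=boundary_noise_sd_mm,
        seed=seed,
    )


def generate_ellipse_mask(
    a_mm: float,
    b_mm: float,
    orientation_deg: float,
    center_mm: tuple[float, float],
    grid_shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
    slice_index: int = 0,
    muscle: str = "",
) -> CrossSectionMask:
    """Pixel-center rasterization of an ellipse (same containment rule as the
    J-index rasterizer).  An ellipse falling entirely off-grid yields an
    empty mask with a warning."""
    if not (a_mm > 0 and b_mm > 0):
        raise ValueError("semi-axes must be positive")
    ellipse = EllipseFit(
        center=center_mm,
        semi_major_mm=max(a_mm, b_mm),
        semi_minor_mm=min(a_mm, b_mm),
        orientation_deg=orientation_deg % 180.0,
        aspect_ratio=max(a_mm, b_mm) / min(a_mm, b_mm),
        eigenvalues=((max(a_mm, b_mm) / 2) ** 2, (min(a_mm, b_mm) / 2) ** 2),
    )
    from .ellipse_fit import ellipse_contains

    pts = pixel_center_grid(grid_shape, pixel_spacing_mm)
    grid = ellipse_contains(ellipse, pts).reshape(grid_shape)
    if not grid.any():
        logger.warning(
            "ellipse at %s (a=%.1f, b=%.1f mm) rasterized to an empty mask",
            center_mm, a_mm, b_mm,
        )
    return CrossSectionMask(
        grid=grid,
        pixel_spacing_mm=pixel_spacing_mm,
        slice_index=slice_index,
        muscle=muscle,
    )


def apply_flattening(mask: CrossSectionMask, f: float) -> CrossSectionMask:
    """Chordal truncation: cut the fraction ``f`` of the y-extent on the
    low-y side.

    With foreground y-coordinates spanning [y_min, y_max], pixels with
    ``y < y_min + f * (y_max - y_min)`` are removed.  ``f = 0`` returns the
    mask unchanged.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError(f"flattening fraction must be in [0, 1), got {f}")
    if f == 0.0 or mask.n_foreground == 0:
        return mask
    sy, _ = mask.pixel_spacing_mm
    rows = np.nonzero(mask.grid)[0]
    y = (rows + 0.5) * sy
    y_min, y_max = y.min(), y.max()
    y_cut = y_min + f * (y_max - y_min)
    all_rows_y = (np.arange(mask.grid.shape[0]) + 0.5) * sy
    keep_rows = all_rows_y >= y_cut
    grid = mask.grid & keep_rows[:, None]
    return CrossSectionMask(
        grid=grid,
        pixel_spacing_mm=mask.pixel_spacing_mm,
        slice_index=mask.slice_index,
        muscle=mask.muscle,
    )


def _apply_boundary_noise(
    grid: np.ndarray, sd_mm: float, spacing: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Flip pixels within one pixel of the region boundary.

    The flip probability is ``min(0.5, 0.5 * sd_mm / mean_spacing)`` — a
    jitter standard deviation of one pixel gives every boundary pixel a
    fifty-fifty flip.
    """
    if sd_mm == 0.0 or not grid.any():
        return grid
    mean_spacing = float(np.mean(spacing))
    p = min(0.5, 0.5 * sd_mm / mean_spacing)
    structure = ndimage.generate_binary_structure(2, 1)
    inner = grid & ~ndimage.binary_erosion(grid, structure)
    outer = ndimage.binary_dilation(grid, structure) & ~grid
    band = inner | outer
    flips = band & (rng.random(grid.shape) < p)
    return grid ^ flips


@dataclass(frozen=True)
class PhantomStudy:
    """Output of :func:`generate_study`: volumes, landmarks, ground truth."""

    spec: PhantomStudySpec
    volumes: dict[str, LabelVolume]
    landmarks: "object"  # pandas DataFrame; typed loosely to avoid import cycle
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        """Write NIfTI volumes, the landmark CSV and the YAML manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for position, volume in self.volumes.items():
            write_label_volume(volume, out_dir / f"{position}.nii.gz")
        self.landmarks.to_csv(out_dir / "landmarks.csv", index=False)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def _phantom_landmarks(spec: PhantomStudySpec) -> "object":
    """Femur landmarks tilted by each position's nominal elevation angle."""
    import pandas as pd

    length = 400.0  # mm, schematic femur length
    records = []
    for position, angle_deg in spec.positions:
        theta = np.radians(angle_deg)
        records.append(
            {
                "study": "phantom",
                "position": position,
                "proximal_x": 0.0,
                "proximal_y": 0.0,
                "proximal_z": 0.0,
                "distal_x": 0.0,
                "distal_y": length * np.sin(theta),
                "distal_z": length * np.cos(theta),
            }
        )
    return pd.DataFrame.from_records(records)


def generate_study(spec: PhantomStudySpec) -> PhantomStudy:
    """Generate one label volume per positioning condition.

    Each muscle's per-slice ellipse is rasterized, truncated by the
    position/group flattening fraction, and jittered by boundary noise; the
    per-(position, muscle, slice) random streams are spawned deterministically
    from ``spec.seed``.  Overlapping muscle labels on any slice abort with a
    :class:`GenerationError`.
    """
    n_slices, n_rows, n_cols = spec.grid
    volumes: dict[str, LabelVolume] = {}
    manifest: dict = {
        "seed": spec.seed,
        "grid": list(spec.grid),
        "pixel_spacing_mm": list(spec.pixel_spacing_mm),
        "slice_thickness_mm": spec.slice_thickness_mm,
        "boundary_noise_sd_mm": spec.boundary_noise_sd_mm,
        "positions": {},
    }
    root = np.random.SeedSequence(spec.seed)
    position_seeds = root.spawn(len(spec.positions))

    for (position, angle_deg), pos_seed in zip(spec.positions, position_seeds):
        voxels = np.zeros((n_slices, n_rows, n_cols), dtype=np.int16)
        flattening = spec.flattening_by_position.get(position, {})
        pos_manifest: dict = {"angle_deg": angle_deg, "muscles": {}}
        muscle_seeds = pos_seed.spawn(len(spec.muscles))
        for muscle, m_seed in zip(spec.muscles, muscle_seeds):
            f = float(flattening.get(muscle.group, 0.0))
            slice_records = []
            slice_seeds = m_seed.spawn(n_slices)
            for k, s_seed in enumerate(slice_seeds):
                s = (k + 0.5) / n_slices
                a, b = muscle.semi_axes_at(s)
                cx, cy = muscle.center_at(s, n_slices, k)
                mask = generate_ellipse_mask(
                    a, b, muscle.orientation_deg, (cx, cy),
                    (n_rows, n_cols), spec.pixel_spacing_mm,
                    slice_index=k, muscle=muscle.name,
                )
                mask = apply_flattening(mask, f)
                grid = _apply_boundary_noise(
                    mask.grid, spec.boundary_noise_sd_mm,
                    spec.pixel_spacing_mm, np.random.default_rng(s_seed),
                )
                overlap = grid & (voxels[k] != 0)
                if overlap.any():
                    raise GenerationError(
                        f"muscle {muscle.name} overlaps an earlier label on "
                        f"slice {k} of position {position}"
                    )
                voxels[k][grid] = muscle.label
                slice_records.append(
                    {
                        "slice": k,
                        "a_mm": float(a),
                        "b_mm": float(b),
                        "center_mm": [float(cx), float(cy)],
                        "orientation_deg": float(muscle.orientation_deg),
                        "flattening": f,
                        "foreground_pixels": int(grid.sum()),
                    }
                )
            pos_manifest["muscles"][muscle.name] = {
                "label": muscle.label,
                "group": muscle.group,
                "flattening": f,
                "slices": slice_records,
            }
        volumes[position] = LabelVolume(
            voxels=voxels,
            pixel_spacing_mm=spec.pixel_spacing_mm,
            slice_thickness_mm=spec.slice_thickness_mm,
            label_names=spec.label_names,
        )
        manifest["positions"][position] = pos_manifest

    return PhantomStudy(
        spec=spec,
        volumes=volumes,
        landmarks=_phantom_landmarks(spec),
        manifest=manifest,
    )
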