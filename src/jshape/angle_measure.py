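"""Digital goniometer: angle between the femoral axis and the imaging plane.

Knee elevation during supine MRI tilts the femur relative to the transverse
imaging plane.  The elevation is quantified as the angle between the
anatomical axis of the femur (a line through two user-supplied landmarks, in
the volume's physical coordinate system) and the normal vector of the
transverse imaging plane (by construction the slice-stacking direction,
(0, 0, 1) by default)::

    angle = arccos(|unit(distal - proximal) . normal|)    in [0, 90] degrees

The absolute value folds the result into [0, 90] so the landmark order does
not matter.  Landmark selection on the femur is up to the user; nothing here
detects bone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateAxisError

_MIN_SEPARATION_MM = 1e-6


@dataclass(frozen=True)
class FemurAxis:
    """Two landmarks on the femoral anatomical axis, mm."""

    proximal_mm: tuple[float, float, float]
    distal_mm: tuple[float, float, float]

    def direction(self) -> np.ndarray:
        d = np.asarray(self.distal_mm, float) - np.asarray(self.proximal_mm, float)
        norm = float(np.linalg.norm(d))
        if norm <= _MIN_SEPARATION_MM:
            raise DegenerateAxisError(
                f"femur landmarks coincide (separation {norm:.2e} mm)"
            )
        return d / norm


@dataclass(frozen=True)
class PlaneNormal:
    """Unit normal of the transverse imaging plane."""

    vector: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, float)
        if abs(float(np.linalg.norm(v)) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")


def femur_plane_angle(axis: FemurAxis, normal: PlaneNormal = PlaneNormal()) -> float:
    """Angle in degrees, in [0, 90], between femoral axis and plane normal."""
    d = axis.direction()
    n = np.asarray(normal.vector, float)
    cos_angle = min(1.0, abs(float(np.dot(d, n))))
    return math.degrees(math.acos(cos_angle))


def read_landmark_table(path: str | Path) -> pd.DataFrame:
    """Read the landmark CSV: study, position, proximal_x/y/z, distal_x/y/z."""
    df = pd.read_csv(path)
    required = {"study", "position"} | {
        f"{end}_{ax}" for end in ("proximal", "distal") for ax in "xyz"
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    return df


def angles_from_landmarks(
    landmarks: pd.DataFrame, normal: PlaneNormal = PlaneNormal()
) -> pd.DataFrame:
    """Measured angle per (study, position) row of a landmark table."""
    records = []
    for _, row in landmarks.iterrows():
        axis = FemurAxis(
            proximal_mm=(row["proximal_x"], row["proximal_y"], row["proximal_z"]),
            distal_mm=(row["distal_x"], row["distal_y"], row["distal_z"]),
        )
        records.append(
            {
                "study": row["study"],
                "position": row["position"],
                "angle_deg": femur_plane_angle(axis, normal),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["study", "position", "angle_deg"]
    )
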