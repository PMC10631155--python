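"""Study orchestration: per-slice J indices, per-muscle summaries, and
percentage change between positioning conditions.

The public surface follows the model/results pattern: :class:`ShapeStudy`
is constructed from a :class:`StudyConfig` plus per-position label volumes
(one subject) or per-subject dictionaries of them; ``fit()`` runs every
slice through point cloud -> moment ellipse -> J index and returns a
:class:`StudyResults` holding four tables:

``slices``
    one row per (subject, position, muscle, slice) that passed the
    ``min_pixels`` inclusion threshold, with areas, pixel counts and J;
``summaries``
    mean +/- sample SD of J per (subject, position, muscle), plus pooled
    rows (subject ``"ALL"``): the cross-subject mean of subject means;
``comparisons``
    percentage change of mean J for every non-reference position against
    the reference, per muscle — reported as a magnitude, with the signed
    difference retained;
``angles``
    measured femur-to-plane angles when a landmark table is supplied.

Percentage change uses the reference condition's mean as denominator::

    percent_change = |mean_b - mean_ref| / mean_ref * 100

Slices whose segmentation equals the rasterized fitted ellipse exactly
(zero symmetric difference) are flagged degenerate, excluded from means and
counted separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .angle_measure import PlaneNormal, angles_from_landmarks
from .ellipse_fit import fit_ellipse_to_mask
from .exceptions import ConfigError, EmptySummaryError
from .jindex import JIndexResult, compute_j_index
from .mask_io import LabelVolume, extract_slice_mask, write_results_table

logger = logging.getLogger(__name__)

#: The seven thigh muscles of the study design.
DEFAULT_MUSCLES = (
    "vastus_lateralis",
    "vastus_intermedius",
    "vastus_medialis",
    "rectus_femoris",
    "semimembranosus",
    "semitendinosus",
    "biceps_femoris",
)

SLICE_COLUMNS = [
    "study", "position", "muscle", "slice_index", "mask_pixels",
    "mask_area_mm2", "ellipse_area_mm2", "intersection_mm2", "sym_diff_mm2",
    "j", "degenerate",
]
SUMMARY_COLUMNS = [
    "study", "position", "muscle", "n_slices", "mean_j", "sd_j", "n_degenerate",
]
COMPARISON_COLUMNS = [
    "study", "muscle", "position_a", "position_b",
    "mean_j_a", "mean_j_b", "diff_j", "percent_change",
]


@dataclass(frozen=True)
class PositionCondition:
    """A positioning condition and its nominal elevation angle in degrees."""

    name: str
    angle_deg: float


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a positioning study.

    Defaults encode the three-condition design: high (15 deg), moderate
    (12 deg) and no (8 deg) knee elevation, with the no-elevation condition
    as reference, and the seven segmented thigh muscles.
    """

    positions: tuple[PositionCondition, ...] = (
        PositionCondition("high", 15.0),
        PositionCondition("moderate", 12.0),
        PositionCondition("none", 8.0),
    )
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    reference_position: str = "none"
    min_pixels: int = 10
    label_names: Mapping[int, str] | None = None
    ellipse_scaling: str = "moment"

    def __post_init__(self) -> None:
        names = [p.name for p in self.positions]
        if len(set(names)) != len(names):
            raise ConfigError("position names must be unique")
        if self.reference_position not in names:
            raise ConfigError(
                f"reference position {self.reference_position!r} not among "
                f"positions {names}"
            )
        if len(set(self.muscles)) != len(self.muscles):
            raise ConfigError("muscle names must be unique")
        if self.min_pixels < 1:
            raise ConfigError("min_pixels must be >= 1")
        if self.ellipse_scaling not in {"moment", "area"}:
            raise ConfigError(f"unknown ellipse scaling {self.ellipse_scaling!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a YAML config with keys positions (name -> angle), muscles,
        labels (label -> muscle), reference_position, min_pixels,
        ellipse_scaling."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs: dict = {}
        if "positions" in raw:
            kwargs["positions"] = tuple(
                PositionCondition(str(name), float(angle))
                for name, angle in raw["positions"].items()
            )
        if "muscles" in raw:
            kwargs["muscles"] = tuple(raw["muscles"])
        if "labels" in raw:
            kwargs["label_names"] = {int(k): str(v) for k, v in raw["labels"].items()}
        for key in ("reference_position", "min_pixels", "ellipse_scaling"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass(frozen=True)
class MuscleSummary:
    """Mean +/- SD of J over included slices for one muscle in one position."""

    muscle: str
    position: str
    n_slices: int
    mean_j: float
    sd_j: float
    n_degenerate: int = 0
    study: str = "study"


@dataclass(frozen=True)
class PositionComparison:
    """Percentage change of mean J between two positions for one muscle."""

    muscle: str
    position_a: str
    position_b: str
    percent_change: float
    mean_j_a: float
    mean_j_b: float
    diff_j: float
    study: str = "study"


def summarize_muscle(
    results: Sequence[JIndexResult],
    muscle: str,
    position: str,
    min_pixels: int = 10,
    study: str = "study",
) -> MuscleSummary:
    """Aggregate per-slice J values into mean +/- sample SD.

    Slices with fewer than ``min_pixels`` foreground pixels are dropped;
    degenerate slices are counted but excluded from the mean.  SD uses the
    n-1 denominator and is 0 for a single slice.
    """
    surviving = [r for r in results if r.mask_pixels >= min_pixels]
    included = [r.j for r in surviving if not r.degenerate]
    n_degenerate = sum(1 for r in surviving if r.degenerate)
    if not included:
        raise EmptySummaryError(
            f"no non-degenerate slice of {muscle} in {position} passed the "
            f"min_pixels={min_pixels} filter"
        )
    mean_j = float(np.mean(included))
    sd_j = float(np.std(included, ddof=1)) if len(included) > 1 else 0.0
    return MuscleSummary(
        muscle=muscle,
        position=position,
        n_slices=len(included),
        mean_j=mean_j,
        sd_j=sd_j,
        n_degenerate=n_degenerate,
        study=study,
    )


def percent_change(
    reference: MuscleSummary, other: MuscleSummary
) -> PositionComparison:
    """Magnitude of the relative change of mean J against the reference."""
    if reference.muscle != other.muscle:
        raise ConfigError(
            f"cannot compare {reference.muscle!r} with {other.muscle!r}"
        )
    if reference.mean_j <= 0 or math.isnan(reference.mean_j):
        raise EmptySummaryError(
            f"reference mean J for {reference.muscle} is not positive"
        )
    diff = other.mean_j - reference.mean_j
    return PositionComparison(
        muscle=reference.muscle,
        position_a=reference.position,
        position_b=other.position,
        percent_change=abs(diff) / reference.mean_j * 100.0,
        mean_j_a=reference.mean_j,
        mean_j_b=other.mean_j,
        diff_j=diff,
        study=reference.study,
    )


class ShapeStudy:
    """Cross-sectional shape model of a positioning study.

    Parameters
    ----------
    config : StudyConfig
    volumes : mapping
        Either ``{position: LabelVolume}`` for a single subject, or
        ``{subject: {position: LabelVolume}}`` for several.
    landmarks : DataFrame, optional
        Femur landmark table (study, position, proximal_x/y/z, distal_x/y/z);
        enables the goniometer output.
    study_id : str
        Subject identifier used in the single-subject form.
    """

    def __init__(
        self,
        config: StudyConfig,
        volumes: Mapping[str, LabelVolume] | Mapping[str, Mapping[str, LabelVolume]],
        landmarks: pd.DataFrame | None = None,
        study_id: str = "study",
    ) -> None:
        self.config = config
        self.landmarks = landmarks
        first = next(iter(volumes.values()), None)
        if isinstance(first, LabelVolume):
            self.volumes: dict[str, dict[str, LabelVolume]] = {
                study_id: dict(volumes)  # type: ignore[arg-type]
            }
        else:
            self.volumes = {k: dict(v) for k, v in volumes.items()}  # type: ignore[union-attr]
        position_names = [p.name for p in config.positions]
        for subject, per_position in self.volumes.items():
            missing = set(position_names) - set(per_position)
            if missing:
                raise ConfigError(
                    f"subject {subject!r} lacks input for positions {sorted(missing)}"
                )

    @classmethod
    def from_phantom(
        cls, phantom: "object", config: StudyConfig | None = None
    ) -> "ShapeStudy":
        """Build a study directly from a :class:`~jshape.synthetic_data.PhantomStudy`."""
        if config is None:
            positions = tuple(
                PositionCondition(name, angle) for name, angle in phantom.spec.positions
            )
            config = StudyConfig(
                positions=positions,
                muscles=tuple(m.name for m in phantom.spec.muscles),
                reference_position=positions[-1].name,
                label_names=phantom.spec.label_names,
            )
        return cls(
            config,
            phantom.volumes,
            landmarks=phantom.landmarks,
            study_id="phantom",
        )

    def _labels_for(self, volume: LabelVolume) -> dict[int, str]:
        labels = dict(self.config.label_names or volume.label_names)
        return {
            lab: name for lab, name in labels.items() if name in self.config.muscles
        }

    def fit(self) -> "StudyResults":
        """Run every slice through ellipse fitting and J-index scoring."""
        rows = []
        for subject, per_position in self.volumes.items():
            for position in (p.name for p in self.config.positions):
                volume = per_position[position]
                labels = self._labels_for(volume)
                if not labels:
                    raise ConfigError(
                        f"no configured muscle label found for subject "
                        f"{subject!r} position {position!r}"
                    )
                present = volume.present_labels()
                for label, muscle in sorted(labels.items()):
                    if label not in present:
                        logger.warning(
                            "muscle %s (label %d) absent from every slice of "
                            "%s/%s", muscle, label, subject, position,
                        )
                        continue
                    for k in range(volume.n_slices):
                        mask = extract_slice_mask(volume, k, label)
                        if mask.n_foreground < self.config.min_pixels:
                            continue
                        fit = fit_ellipse_to_mask(
                            mask, scaling=self.config.ellipse_scaling
                        )
                        res = compute_j_index(mask, fit)
                        rows.append(
                            {
                                "study": subject,
                                "position": position,
                                "muscle": muscle,
                                "slice_index": k,
                                "mask_pixels": res.mask_pixels,
                                "mask_area_mm2": res.mask_area_mm2,
                                "ellipse_area_mm2": res.ellipse_area_mm2,
                                "intersection_mm2": res.intersection_mm2,
                                "sym_diff_mm2": res.sym_diff_mm2,
                                "j": res.j,
                                "degenerate": res.degenerate,
                            }
                        )
        slices = pd.DataFrame(rows, columns=SLICE_COLUMNS)
        summaries = self._summarize(slices)
        comparisons = self._compare(summaries)
        angles = None
        if self.landmarks is not None:
            angles = angles_from_landmarks(self.landmarks, PlaneNormal())
        return StudyResults(self, slices, summaries, comparisons, angles)

    def _summarize(self, slices: pd.DataFrame) -> pd.DataFrame:
        records = []
        position_names = [p.name for p in self.config.positions]
        subjects = sorted(self.volumes)
        for position in position_names:
            for muscle in self.config.muscles:
                per_subject_means = []
                for subject in subjects:
                    sub = slices[
                        (slices["study"] == subject)
                        & (slices["position"] == position)
                        & (slices["muscle"] == muscle)
                    ]
                    if sub.empty:
                        continue
                    included = sub[~sub["degenerate"]]["j"]
                    n_degenerate = int(sub["degenerate"].sum())
                    if included.empty:
                        logger.warning(
                            "all slices of %s in %s/%s are degenerate",
                            muscle, subject, position,
                        )
                        continue
                    mean_j = float(included.mean())
                    sd_j = float(included.std(ddof=1)) if len(included) > 1 else 0.0
                    per_subject_means.append(mean_j)
                    records.append(
                        {
                            "study": subject,
                            "position": position,
                            "muscle": muscle,
                            "n_slices": int(len(included)),
                            "mean_j": mean_j,
                            "sd_j": sd_j,
                            "n_degenerate": n_degenerate,
                        }
                    )
                if per_subject_means:
                    # pooled row: unweighted mean of subject means
                    records.append(
                        {
                            "study": "ALL",
                            "position": position,
                            "muscle": muscle,
                            "n_slices": len(per_subject_means),
                            "mean_j": float(np.mean(per_subject_means)),
                            "sd_j": (
                                float(np.std(per_subject_means, ddof=1))
                                if len(per_subject_means) > 1
                                else 0.0
                            ),
                            "n_degenerate": 0,
                        }
                    )
        return pd.DataFrame(records, columns=SUMMARY_COLUMNS)

    def _compare(self, summaries: pd.DataFrame) -> pd.DataFrame:
        ref_name = self.config.reference_position
        records = []
        for study in sorted(summaries["study"].unique()):
            sub = summaries[summaries["study"] == study]
            for muscle in self.config.muscles:
                ref = sub[(sub["position"] == ref_name) & (sub["muscle"] == muscle)]
                if ref.empty:
                    continue
                mean_ref = float(ref["mean_j"].iloc[0])
                if mean_ref <= 0:
                    continue
                for position in (p.name for p in self.config.positions):
                    if position == ref_name:
                        continue
                    other = sub[
                        (sub["position"] == position) & (sub["muscle"] == muscle)
                    ]
                    if other.empty:
                        continue
                    mean_other = float(other["mean_j"].iloc[0])
                    diff = mean_other - mean_ref
                    records.append(
                        {
                            "study": study,
                            "muscle": muscle,
                            "position_a": ref_name,
                            "position_b": position,
                            "mean_j_a": mean_ref,
                            "mean_j_b": mean_other,
                            "diff_j": diff,
                            "percent_change": abs(diff) / mean_ref * 100.0,
                        }
                    )
        return pd.DataFrame(records, columns=COMPARISON_COLUMNS)


@dataclass
class StudyResults:
    """Fitted results of a :class:`ShapeStudy`."""

    model: ShapeStudy
    slices: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    angles: pd.DataFrame | None = None

    def summary(self) -> str:
        """Human-readable per-muscle table: mean J per position and the
        percentage change of each non-reference position vs the reference."""
        cfg = self.model.config
        lines = [
            "Cross-sectional shape study (J index vs fitted ellipse)",
            f"reference position: {cfg.reference_position}",
            "",
        ]
        pooled = self.summaries[self.summaries["study"] == "ALL"]
        pos_names = [p.name for p in cfg.positions]
        header = f"{'muscle':<20}" + "".join(f"{p:>12}" for p in pos_names)
        header += "".join(
            f"{'Δ% ' + p:>12}"
            for p in pos_names
            if p != cfg.reference_position
        )
        lines.append(header)
        lines.append("-" * len(header))
        comp = self.comparisons[self.comparisons["study"] == "ALL"]
        for muscle in cfg.muscles:
            row = f"{muscle:<20}"
            for p in pos_names:
                m = pooled[(pooled["muscle"] == muscle) & (pooled["position"] == p)]
                row += f"{m['mean_j'].iloc[0]:>12.3f}" if not m.empty else f"{'--':>12}"
            for p in pos_names:
                if p == cfg.reference_position:
                    continue
                c = comp[(comp["muscle"] == muscle) & (comp["position_b"] == p)]
                row += (
                    f"{c['percent_change'].iloc[0]:>11.1f}%"
                    if not c.empty
                    else f"{'--':>12}"
                )
            lines.append(row)
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write slices.csv, summaries.csv, comparisons.csv (and angles.csv)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables: list[tuple[str, pd.DataFrame | None, list[str]]] = [
            ("slices", self.slices, SLICE_COLUMNS),
            ("summaries", self.summaries, SUMMARY_COLUMNS),
            ("comparisons", self.comparisons, COMPARISON_COLUMNS),
        ]
        if self.angles is not None:
            tables.append(("angles", self.angles, list(self.angles.columns)))
        for name, table, columns in tables:
            path = out_dir / f"{name}.csv"
            write_results_table(table, path, columns=columns)
            paths[name] = path
        return paths

    def plot_summary(self, ax=None):
        """Bar chart of mean J +/- SD per muscle per position (pooled rows)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        cfg = self.model.config
        pooled = self.summaries[self.summaries["study"] == "ALL"]
        muscles = list(cfg.muscles)
        width = 0.8 / len(cfg.positions)
        x = np.arange(len(muscles))
        for i, pos in enumerate(p.name for p in cfg.positions):
            means, sds = [], []
            for muscle in muscles:
                m = pooled[(pooled["muscle"] == muscle) & (pooled["position"] == pos)]
                means.append(float(m["mean_j"].iloc[0]) if not m.empty else np.nan)
                sds.append(float(m["sd_j"].iloc[0]) if not m.empty else 0.0)
            ax.bar(x + i * width, means, width, yerr=sds, capsize=2, label=pos)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(muscles, rotation=30, ha="right")
        ax.set_ylabel("mean J index")
        ax.legend(title="knee elevation")
        return ax


def run_study(
    config: StudyConfig,
    inputs: Mapping[str, LabelVolume] | Mapping[str, Mapping[str, LabelVolume]],
    landmarks: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> StudyResults:
    """One-call pipeline: build a :class:`ShapeStudy`, fit it, optionally
    write the result tables."""
    results = ShapeStudy(config, inputs, landmarks=landmarks).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
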