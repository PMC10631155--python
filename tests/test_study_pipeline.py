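"""Study orchestration: summaries, percent change, full-pipeline runs."""

import math

import numpy as np
import pandas as pd
import pytest

from jshape import (
    JIndexResult,
    MuscleSummary,
    PositionCondition,
    ShapeStudy,
    StudyConfig,
    extract_slice_mask,
    j_index_of_mask,
    percent_change,
    run_study,
    summarize_muscle,
)
from jshape.exceptions import ConfigError, EmptySummaryError


def jres(j, pixels=100, degenerate=False):
    return JIndexResult(
        intersection_mm2=1.0, sym_diff_mm2=0.0 if degenerate else 1.0,
        j=math.nan if degenerate else j, mask_area_mm2=float(pixels),
        ellipse_area_mm2=float(pixels), degenerate=degenerate,
        mask_pixels=pixels, intersection_pixels=1,
        sym_diff_pixels=0 if degenerate else 1,
    )


class TestSummarizeMuscle:
    def test_mean_and_sample_sd(self):
        s = summarize_muscle([jres(1.0), jres(2.0), jres(3.0)], "st", "high")
        assert s.mean_j == pytest.approx(2.0)
        assert s.sd_j == pytest.approx(1.0)
        assert s.n_slices == 3

    def test_single_slice_sd_zero(self):
        s = summarize_muscle([jres(2.5)], "st", "high")
        assert (s.mean_j, s.sd_j) == (2.5, 0.0)

    def test_degenerate_excluded_but_counted(self):
        s = summarize_muscle([jres(1.0), jres(2.0), jres(0, degenerate=True)],
                             "st", "high")
        assert s.mean_j == pytest.approx(1.5)
        assert s.n_degenerate == 1
        assert s.n_slices == 2

    def test_min_pixels_filter_and_empty_summary(self):
        small = jres(5.0, pixels=3)
        s = summarize_muscle([small, jres(1.0)], "st", "high", min_pixels=10)
        assert s.n_slices == 1
        with pytest.raises(EmptySummaryError):
            summarize_muscle([small], "st", "high", min_pixels=10)


class TestPercentChange:
    def summary(self, mean, position="none", muscle="st"):
        return MuscleSummary(muscle=muscle, position=position, n_slices=5,
                             mean_j=mean, sd_j=0.1)

    def test_forced_arithmetic(self):
        c = percent_change(self.summary(2.000), self.summary(1.728, "high"))
        assert c.percent_change == pytest.approx(13.6)
        assert c.diff_j == pytest.approx(-0.272)

    def test_identity_is_zero_and_doubling_is_100(self):
        assert percent_change(self.summary(2.0), self.summary(2.0, "high")
                              ).percent_change == 0.0
        assert percent_change(self.summary(1.0), self.summary(2.0, "high")
                              ).percent_change == pytest.approx(100.0)

    def test_muscle_mismatch_and_zero_reference(self):
        with pytest.raises(ConfigError):
            percent_change(self.summary(1.0), self.summary(1.0, muscle="bf"))
        with pytest.raises(EmptySummaryError):
            percent_change(self.summary(0.0), self.summary(1.0, "high"))


class TestStudyConfig:
    def test_reference_must_be_a_position(self):
        with pytest.raises(ConfigError):
            StudyConfig(reference_position="sideways")

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "study.yaml"
        cfg_path.write_text(
            "positions:\n  high: 15\n  moderate: 12\n  none: 8\n"
            "muscles: [semitendinosus, rectus_femoris]\n"
            "labels: {6: semitendinosus, 1: rectus_femoris}\n"
            "reference_position: none\nmin_pixels: 12\n"
        )
        cfg = StudyConfig.from_yaml(cfg_path)
        assert cfg.min_pixels == 12
        assert cfg.label_names == {6: "semitendinosus", 1: "rectus_femoris"}
        assert [p.angle_deg for p in cfg.positions] == [15, 12, 8]


@pytest.fixture(scope="module")
def fitted(small_phantom_study):
    return ShapeStudy.from_phantom(small_phantom_study).fit()


class TestRunStudy:
    def test_every_position_muscle_covered(self, fitted):
        got = set(zip(fitted.slices["position"], fitted.slices["muscle"]))
        assert len(got) == 21  # 3 positions x 7 muscles

    def test_pipeline_equals_composition(self, fitted, small_phantom_study):
        """run_study rows match manually chaining extract -> fit -> J."""
        volume = small_phantom_study.volumes["high"]
        spec_muscle = small_phantom_study.spec.muscles[5]
        sub = fitted.slices[
            (fitted.slices["position"] == "high")
            & (fitted.slices["muscle"] == spec_muscle.name)
        ]
        for _, row in sub.iterrows():
            mask = extract_slice_mask(volume, int(row["slice_index"]),
                                      spec_muscle.label)
            _, res = j_index_of_mask(mask)
            assert row["j"] == pytest.approx(res.j, rel=1e-12)
            assert row["mask_pixels"] == res.mask_pixels

    def test_angles_table_reports_nominal_elevations(self, fitted):
        angles = fitted.angles.set_index("position")["angle_deg"]
        assert angles["high"] == pytest.approx(15.0, abs=1e-6)
        assert angles["moderate"] == pytest.approx(12.0, abs=1e-6)
        assert angles["none"] == pytest.approx(8.0, abs=1e-6)

    def test_determinism_byte_identical_tables(self, small_phantom_study, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            ShapeStudy.from_phantom(small_phantom_study).fit().save(out)
        for name in ("slices", "summaries", "comparisons", "angles"):
            assert (out1 / f"{name}.csv").read_bytes() == (
                out2 / f"{name}.csv"
            ).read_bytes()

    def test_summary_text_mentions_all_muscles(self, fitted):
        text = fitted.summary()
        for muscle in fitted.model.config.muscles:
            assert muscle in text

    def test_missing_position_input_is_config_error(self, small_phantom_study):
        config = ShapeStudy.from_phantom(small_phantom_study).config
        volumes = dict(small_phantom_study.volumes)
        volumes.pop("moderate")
        with pytest.raises(ConfigError):
            ShapeStudy(config, volumes)

    def test_multi_subject_pooled_rows_are_mean_of_subject_means(
        self, small_phantom_study
    ):
        model = ShapeStudy.from_phantom(small_phantom_study)
        two = ShapeStudy(
            model.config,
            {"s1": small_phantom_study.volumes, "s2": small_phantom_study.volumes},
        )
        res = two.fit()
        pooled = res.summaries[res.summaries["study"] == "ALL"]
        per_subject = res.summaries[res.summaries["study"] != "ALL"]
        for _, row in pooled.iterrows():
            subs = per_subject[
                (per_subject["position"] == row["position"])
                & (per_subject["muscle"] == row["muscle"])
            ]["mean_j"]
            assert row["mean_j"] == pytest.approx(float(np.mean(subs)), rel=1e-12)


class TestNoiselessSelfConsistency:
    def test_constant_flattening_gives_near_zero_percent_change(self):
        """Identical generation conditions at every position: percent changes
        reflect discretization only and stay below 2%."""
        from jshape import default_study_spec, generate_study

        spec = default_study_spec(seed=3, n_slices=6, boundary_noise_sd_mm=0.0)
        flat = {pos: {"hamstrings": 0.2, "quadriceps": 0.2}
                for pos, _ in spec.positions}
        spec = type(spec)(
            grid=spec.grid, pixel_spacing_mm=spec.pixel_spacing_mm,
            slice_thickness_mm=spec.slice_thickness_mm, muscles=spec.muscles,
            positions=spec.positions, flattening_by_position=flat,
            boundary_noise_sd_mm=0.0, seed=3,
        )
        res = ShapeStudy.from_phantom(generate_study(spec)).fit()
        comp = res.comparisons[res.comparisons["study"] == "ALL"]
        assert (comp["percent_change"] < 2.0).all()
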