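"""Synthetic-data generators: determinism, ground-truth consistency, motion."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from myofield.motion import differential_image
from myofield.synth import (
    GeometryError,
    MotionSpec,
    SceneSpec,
    generate_contraction_sequence,
    generate_expression_table,
    generate_fluorescence_field,
    round_half_away,
)


class TestSpecs:
    @pytest.mark.parametrize(
        "kwargs, message",
        [
            ({"amplitude": -1}, "amplitude"),
            ({"frequency": 0}, "frequency"),
            ({"frame_rate": 1.5, "frequency": 1.0}, "frame_rate"),
            ({"n_frames": 1}, "n_frames"),
            ({"moving_area_fraction": 1.5}, "moving_area_fraction"),
        ],
    )
    def test_motion_spec_validation_names_the_field(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            MotionSpec(**kwargs)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            ({"marker_nuclear_fraction": 1.2}, "marker_nuclear_fraction"),
            ({"accumulation_fraction": -0.1}, "accumulation_fraction"),
            ({"puncta_area_fraction": 2.0}, "puncta_area_fraction"),
            ({"n_myotubes": -1}, "n_myotubes"),
            ({"noise_sd": -1}, "noise_sd"),
            ({"bit_depth": 12}, "bit_depth"),
        ],
    )
    def test_scene_spec_validation_names_the_field(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            SceneSpec(**kwargs)

    @pytest.mark.parametrize("x, expected", [(0.5, 1), (2.4, 2), (2.5, 3), (0.0, 0)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestContractionSequence:
    def test_zero_amplitude_zero_noise_gives_identical_frames(self):
        seq, _ = generate_contraction_sequence(
            MotionSpec(amplitude=0.0, noise_sd=0.0, n_frames=10, seed=3)
        )
        assert all((seq.frames[0] == f).all() for f in seq.frames)

    def test_deterministic_under_fixed_seed(self):
        spec = dict(amplitude=2.0, noise_sd=1.5, n_frames=6, seed=9)
        a, _ = generate_contraction_sequence(MotionSpec(**spec))
        b, _ = generate_contraction_sequence(MotionSpec(**spec))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_centroid_displacement_is_twice_amplitude(self):
        # cosine displacement: +A at phase 0, -A at phase pi (frame 5 at 10 fps, 1 Hz)
        seq, truth = generate_contraction_sequence(
            MotionSpec(amplitude=3.0, frequency=1.0, frame_rate=10.0,
                       n_frames=10, n_objects=1, seed=5)
        )
        assert truth.frame_offsets[0] == pytest.approx(3.0)
        assert truth.frame_offsets[5] == pytest.approx(-3.0)
        c0 = np.array(ndi.center_of_mass(seq.frames[0] > 80))
        c5 = np.array(ndi.center_of_mass(seq.frames[5] > 80))
        assert np.linalg.norm(c0 - c5) == pytest.approx(6.0, abs=0.5)

    def test_moving_area_fraction_selects_objects(self):
        _, truth = generate_contraction_sequence(
            MotionSpec(moving_area_fraction=0.0, n_frames=4, seed=2)
        )
        assert not truth.objects["moving"].any()
        _, truth = generate_contraction_sequence(
            MotionSpec(moving_area_fraction=1.0, n_frames=4, seed=2)
        )
        assert truth.objects["moving"].all()

    def test_mean_absolute_difference_monotone_in_amplitude(self):
        """More deformation must mean more inter-frame contrast (noiseless)."""
        mads = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            seq, _ = generate_contraction_sequence(
                MotionSpec(amplitude=amp, noise_sd=0.0, n_frames=10, seed=11)
            )
            diffs = [differential_image(seq.frames[i], seq.frames[i + 1]).values.mean()
                     for i in range(9)]
            mads.append(np.mean(diffs))
        assert all(a < b for a, b in zip(mads, mads[1:]))


class TestFluorescenceField:
    def test_deterministic_under_fixed_seed(self):
        spec = dict(seed=13, noise_sd=2.0, accumulation_fraction=0.25)
        f1, _ = generate_fluorescence_field(SceneSpec(**spec))
        f2, _ = generate_fluorescence_field(SceneSpec(**spec))
        for name in f1.channels:
            np.testing.assert_array_equal(f1[name], f2[name])

    def test_structural_channel_support_equals_myotube_labels(self, clean_field):
        field, truth = clean_field
        np.testing.assert_array_equal(field["structural"] > 100, truth.myotube_labels > 0)

    def test_feeder_nuclei_lie_outside_structural_mask(self, clean_field):
        field, truth = clean_field
        feeders = truth.nuclei[truth.nuclei["parent"] == 0]
        assert len(feeders) > 0
        for _, row in feeders.iterrows():
            sel = truth.nucleus_labels == row["nucleus_label"]
            assert not (truth.myotube_labels[sel] > 0).any()

    def test_zero_accumulation_fraction_flags_nothing(self, clean_field):
        _, truth = clean_field
        assert not truth.myotubes["accumulation"].any()

    def test_accumulation_count_follows_rounding_rule(self):
        _, truth = generate_fluorescence_field(
            SceneSpec(seed=21, n_myotubes=10, accumulation_fraction=0.3)
        )
        assert truth.myotubes["accumulation"].sum() == 3

    def test_fully_nuclear_marker_leaves_cytoplasm_at_baseline(self):
        field, truth = generate_fluorescence_field(
            SceneSpec(seed=11, marker_nuclear_fraction=1.0, n_feeder_nuclei=0, noise_sd=0.0)
        )
        cytoplasm = (truth.myotube_labels > 0) & (truth.nucleus_labels == 0)
        assert (field["marker"][cytoplasm] == field["marker"].min()).all()

    def test_marker_partition_matches_requested_fraction(self, accumulation_fields):
        # noiseless rendering: nuclear share of positive area within 2% of spec
        for _, truth in accumulation_fields[:2]:
            t = truth.myotubes[~truth.myotubes["accumulation"]]
            share = t["nuclear_marker_area"] / (
                t["nuclear_marker_area"] + t["cytoplasmic_marker_area"]
            )
            assert (np.abs(share - 0.7) < 0.02).all()

    def test_puncta_area_matches_requested_fraction(self, puncta_field):
        field, truth = puncta_field
        total = (truth.myotube_labels > 0).sum()
        assert truth.puncta_area / total == pytest.approx(0.03, rel=0.1)
        # puncta rendered bright inside the mask
        assert (field["marker"][truth.puncta_mask] > 150).all()

    def test_infeasible_geometry_raises_after_bounded_retries(self):
        with pytest.raises(GeometryError, match="place"):
            generate_fluorescence_field(
                SceneSpec(field_shape=(128, 128), n_myotubes=30, seed=0,
                          max_placement_tries=30)
            )

    def test_sixteen_bit_output(self):
        field, _ = generate_fluorescence_field(SceneSpec(seed=5, bit_depth=16, n_myotubes=4))
        assert field["structural"].dtype == np.uint16


class TestExpressionTable:
    def test_zero_noise_gives_exact_delta_ct(self):
        t = generate_expression_table(4, {"MYOG": 4.0}, ct_noise_sd=0.0, seed=0)
        wide = t.pivot(index="sample_id", columns="gene", values="ct")
        np.testing.assert_allclose(wide["MYOG"] - wide["RPLP0"], 4.0)

    def test_deterministic_under_fixed_seed(self):
        a = generate_expression_table(5, {"CXCL1": 2.0}, ct_noise_sd=0.3, seed=8)
        b = generate_expression_table(5, {"CXCL1": 2.0}, ct_noise_sd=0.3, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_noisy_mean_delta_ct_within_three_se(self):
        # Normal(4, 0.2) over 100 samples: mean within 4 +/- 3 * 0.2/sqrt(100)
        t = generate_expression_table(100, {"MYOG": 4.0}, ct_noise_sd=0.2, seed=1)
        wide = t.pivot(index="sample_id", columns="gene", values="ct")
        assert (wide["MYOG"] - wide["RPLP0"]).mean() == pytest.approx(4.0, abs=0.06)

    def test_per_condition_delta_ct_maps(self):
        t = generate_expression_table(
            2, {"basal": {"CXCL1": 6.0}, "eps": {"CXCL1": 5.0}}, ct_noise_sd=0.0, seed=0
        )
        assert set(t["condition"]) == {"basal", "eps"}
        eps = t[t["condition"] == "eps"].pivot(index="sample_id", columns="gene", values="ct")
        np.testing.assert_allclose(eps["CXCL1"] - eps["RPLP0"], 5.0)

    def test_validation(self):
        with pytest.raises(ValueError, match="n_samples"):
            generate_expression_table(0, {"A": 1.0})
        with pytest.raises(ValueError, match="ct_noise_sd"):
            generate_expression_table(1, {"A": 1.0}, ct_noise_sd=-1)
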