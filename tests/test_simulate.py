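"""Synthetic study generator: determinism, degradation and reader model."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

from contourqa import (
    BinaryMask,
    MaskPair,
    ReaderModel,
    SyntheticStudyConfig,
    cohen_kappa,
    compute_record,
    degrade,
    dice,
    generate_mask,
    generate_plane_predictions,
    generate_study,
    majority_vote,
    simulate_readers,
    threshold_reader_model,
)
from contourqa.masks import MetricRecord
from contourqa.simulate import parse_severity_distribution


class TestGenerateMask:
    def test_deterministic(self):
        a = generate_mask((32, 32), 5)
        b = generate_mask((32, 32), 5)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_nonempty_and_interior(self):
        for seed in range(30):
            m = generate_mask((24, 40), seed)
            assert m.area() > 0
            for ax in range(2):
                border = [slice(None)] * 2
                for edge in (0, -1):
                    border[ax] = edge
                    assert m.grid[tuple(border)].sum() == 0

    def test_area_within_bounds(self):
        for seed in range(50):
            m = generate_mask((16, 16), seed)
            frac = m.area() / m.grid.size
            assert 0.02 <= frac <= 0.60

    def test_connected_many_seeds_2d(self):
        structure = np.ones((3, 3))
        for seed in range(500):
            m = generate_mask((24, 24), seed)
            _, n = ndimage.label(m.grid, structure=structure)
            assert n == 1

    def test_connected_3d(self):
        structure = np.ones((3, 3, 3))
        for seed in range(100):
            m = generate_mask((12, 12, 12), seed)
            assert 0.02 <= m.area() / m.grid.size <= 0.60
            _, n = ndimage.label(m.grid, structure=structure)
            assert n == 1

    def test_degenerate_grid_names_dimension(self):
        with pytest.raises(ValueError, match="dimension 1 is 6"):
            generate_mask((16, 6), 0)


class TestDegrade:
    def test_severity_zero_identity(self):
        m = generate_mask((32, 32), 1)
        out = degrade(m, 0.0, ("boundary_jitter", "translation", "rough_edges"), seed=3)
        np.testing.assert_array_equal(out.grid, m.grid)
        assert dice(MaskPair(m, out)) == 1.0

    def test_deterministic(self):
        m = generate_mask((32, 32), 2)
        a = degrade(m, 0.7, ("boundary_jitter",), seed=9)
        b = degrade(m, 0.7, ("boundary_jitter",), seed=9)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_translation_budget_and_shape_preserved(self):
        g = np.zeros((40, 40), dtype=np.uint8)
        g[15:25, 15:25] = 1
        m = BinaryMask(g)
        out = degrade(m, 1.0, ("translation",), seed=4, max_shift=5)
        assert out.area() == m.area()  # pure shift, object away from edges
        com_before = np.array(ndimage.center_of_mass(m.grid))
        com_after = np.array(ndimage.center_of_mass(out.grid))
        shift = com_after - com_before
        assert np.linalg.norm(shift) <= 5.0 + 1e-9
        np.testing.assert_array_equal(
            out.grid, np.roll(m.grid, np.round(shift).astype(int), axis=(0, 1))
        )

    def test_unknown_mode_lists_valid_modes(self):
        m = generate_mask((16, 16), 0)
        with pytest.raises(ValueError, match="boundary_jitter"):
            degrade(m, 0.5, ("smudge",), seed=0)

    def test_severity_anticorrelates_with_dice(self):
        gen = np.random.default_rng(11)
        sev = gen.uniform(0, 1, 200)
        dcs = []
        for i, s in enumerate(sev):
            m = generate_mask((64, 64), i)
            d = degrade(m, float(s), ("boundary_jitter", "translation", "rough_edges"), seed=i)
            dcs.append(dice(MaskPair(m, d)))
        rho = spearmanr(sev, dcs).statistic
        assert rho < -0.5

    def test_mean_dice_nonincreasing_across_severity_bins(self):
        bins = np.linspace(0, 1, 6)
        means = []
        for lo, hi in zip(bins, bins[1:]):
            dcs = []
            for i in range(40):
                m = generate_mask((48, 48), i)
                s = float((lo + hi) / 2)
                d = degrade(m, s, ("boundary_jitter", "translation"), seed=1000 + i)
                dcs.append(dice(MaskPair(m, d)))
            means.append(np.mean(dcs))
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))

    def test_dropout_and_blob_modes_move_in_expected_direction(self):
        m = generate_mask((48, 48), 3)
        dropped = degrade(m, 0.8, ("dropout",), seed=5)
        assert dropped.area() < m.area()
        with_blob = degrade(m, 0.8, ("false_positive_blob",), seed=5)
        assert with_blob.area() > m.area()
        _, n = ndimage.label(with_blob.grid, structure=np.ones((3, 3)))
        assert n >= 2  # spurious component is disjoint

    def test_empty_mask_stays_empty_without_blob_mode(self):
        e = BinaryMask(np.zeros((16, 16), dtype=np.uint8))
        out = degrade(e, 0.9, ("boundary_jitter", "translation", "rough_edges"), seed=2)
        assert out.is_empty()


class TestPlanePredictions:
    def test_severity_zero_planes_identical_to_mask(self):
        m = generate_mask((32, 32), 7)
        ps = generate_plane_predictions(m, 0.0, 3, seed=1)
        for p in ps.predictions:
            np.testing.assert_array_equal(p.grid, m.grid)

    def test_reproducible_set(self):
        m = generate_mask((32, 32), 7)
        a = generate_plane_predictions(m, 0.5, 3, seed=1)
        b = generate_plane_predictions(m, 0.5, 3, seed=1)
        for pa, pb in zip(a.predictions, b.predictions):
            np.testing.assert_array_equal(pa.grid, pb.grid)

    def test_planes_are_independent_degradations(self):
        m = generate_mask((32, 32), 7)
        ps = generate_plane_predictions(m, 0.6, 3, seed=1)
        assert not np.array_equal(ps.predictions[0].grid, ps.predictions[1].grid)

    def test_fusion_beats_median_plane_dice(self):
        # regression guard frozen from an oracle run: fused >= median single-plane
        # DC on at least 80% of 200 simulated slices at moderate severity
        wins = 0
        for i in range(200):
            m = generate_mask((64, 64), i)
            ps = generate_plane_predictions(m, 0.5, 3, seed=i)
            fused = majority_vote(ps)
            singles = [dice(MaskPair(m, p)) for p in ps.predictions]
            if dice(MaskPair(m, fused)) >= np.median(singles):
                wins += 1
        assert wins >= 160


def _records_from_dice(dices):
    return [
        MetricRecord(
            slice_id=f"s{i}", dice=d, hd95=5.0, precision=0.9, sensitivity=0.9, pixel_accuracy=0.95
        )
        for i, d in enumerate(dices)
    ]


class TestSimulateReaders:
    def test_boundary_value_goes_to_better_category(self):
        model = ReaderModel(
            quality_weights=(1, 0, 0, 0, 0),
            category_cutpoints=(0.2, 0.5, 0.8),
            reader_noise_sd=0.0,
            standardize=False,
        )
        recs = _records_from_dice([0.1, 0.2, 0.5, 0.8, 0.9])
        panels = simulate_readers(recs, model)
        assert [p.answers[0] for p in panels] == ["A", "B", "C", "D", "D"]

    def test_zero_noise_unanimous_panels(self):
        model = threshold_reader_model("dice", 0.6, noise_sd=0.0)
        recs = _records_from_dice(np.linspace(0.2, 1.0, 30))
        panels = simulate_readers(recs, model)
        for p in panels:
            assert len(set(p.answers)) == 1
        a1 = [p.answers[0] in "CD" for p in panels]
        a2 = [p.answers[1] in "CD" for p in panels]
        assert cohen_kappa(a1, a2) == pytest.approx(1.0)

    def test_hard_threshold_model_accepts_at_boundary(self):
        model = threshold_reader_model("dice", 0.85, noise_sd=0.0)
        recs = _records_from_dice([0.84, 0.85, 0.86])
        panels = simulate_readers(recs, model)
        assert [p.answers[0] in "CD" for p in panels] == [False, True, True]

    def test_large_noise_drives_pairwise_kappa_to_zero(self):
        model = ReaderModel(reader_noise_sd=60.0, seed=3)
        gen = np.random.default_rng(0)
        recs = _records_from_dice(gen.uniform(0.3, 1.0, 1000))
        panels = simulate_readers(recs, model)
        a = [p.answers[0] in "CD" for p in panels]
        b = [p.answers[1] in "CD" for p in panels]
        assert abs(cohen_kappa(a, b)) < 0.1

    def test_weight_length_validated(self):
        model = ReaderModel(quality_weights=(1.0, 2.0))
        with pytest.raises(ValueError, match="quality_weights"):
            simulate_readers(_records_from_dice([0.5]), model)

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ReaderModel(category_cutpoints=(0.5, 0.5, 0.8))


class TestGenerateStudy:
    def test_complete_rows_without_empties(self):
        cfg = SyntheticStudyConfig(n_slices=10, empty_fraction=0.0, grid_shape=(32, 32), seed=2)
        study = generate_study(cfg)
        assert len(study.table) == 10
        assert not study.table[["dice", "hd95", "precision", "sensitivity"]].isna().any().any()

    def test_exact_empty_count(self):
        cfg = SyntheticStudyConfig(n_slices=100, empty_fraction=0.2, grid_shape=(24, 24), seed=3)
        study = generate_study(cfg)
        assert int(study.table.empty_truth.sum()) == 20

    def test_byte_identical_serialization_under_fixed_seed(self):
        cfg = SyntheticStudyConfig(n_slices=20, grid_shape=(32, 32), seed=9)
        a = generate_study(cfg).table.to_csv(index=False)
        b = generate_study(cfg).table.to_csv(index=False)
        assert a == b

    def test_severity_distribution_spec_strings(self):
        assert parse_severity_distribution("uniform:0,0.5") == ("uniform", 0.0, 0.5)
        assert parse_severity_distribution("constant:0.3") == ("constant", 0.3)
        with pytest.raises(ValueError, match="unknown severity"):
            parse_severity_distribution("zipf:2")

    def test_config_validation(self):
        with pytest.raises(ValueError, match="empty_fraction"):
            SyntheticStudyConfig(empty_fraction=1.0)
        with pytest.raises(ValueError, match="dimension 0 is 4"):
            SyntheticStudyConfig(grid_shape=(4, 32))
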