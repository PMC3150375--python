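"""Measurement pipeline: segmentation recovery, aggregation, t-test, qPCR."""

import numpy as np
import pandas as pd
import pytest

from perfuse import synthetic_imaging as si
from perfuse.quantify import (
    SegmentationParams,
    aggregate_condition,
    cell_area,
    fit_standard_curve,
    fold_increase,
    relative_expression,
    segment_phase,
    sox1_fraction,
    ttest_unpaired_equal_var,
    QpcrRecord,
)
from perfuse.quantify.qpcr import StandardCurveError
from perfuse.transport import InvalidParameterError


class TestSegmentPhase:
    @pytest.mark.parametrize("seed,target,sigma", [
        (31, 0.05, 0.02), (32, 0.10, 0.02), (33, 0.30, 0.03), (34, 0.60, 0.03),
    ])
    def test_recovers_ground_truth_area(self, seed, target, sigma):
        scene, truth = si.sample_scene(seed, target_area_fraction=target,
                                       n_colonies=10)
        img = si.render_phase(scene, si.RenderSpec(noise_sigma=sigma))
        measured = cell_area(segment_phase(img))
        assert measured == pytest.approx(truth.area_fraction, rel=0.15)

    def test_constant_image_yields_empty_mask(self):
        with pytest.warns(UserWarning, match="constant image"):
            mask = segment_phase(np.full((64, 64), 0.5))
        assert not mask.any()

    def test_ring_interior_filled(self):
        # bright rim with dark interior: fill-holes must include the interior
        img = np.zeros((128, 128))
        rr, cc = np.mgrid[0:128, 0:128]
        radius = np.hypot(rr - 64, cc - 64)
        img[(radius > 30) & (radius < 35)] = 1.0
        mask = segment_phase(img, SegmentationParams(threshold_method="fixed",
                                                     fixed_threshold=0.5))
        assert mask[64, 64]
        assert mask.sum() >= np.pi * 30 ** 2

    def test_nested_scenes_measure_monotonically(self):
        scene, _ = si.sample_scene(35, target_area_fraction=0.1)
        grown = si.grow_scene(scene, 3.0)
        a_small = cell_area(segment_phase(si.render_phase(scene)))
        a_big = cell_area(segment_phase(si.render_phase(grown)))
        assert a_small <= a_big

    def test_integer_images_supported(self):
        scene, truth = si.sample_scene(36, target_area_fraction=0.2)
        img16 = si.to_integer_image(si.render_phase(scene), 16)
        measured = cell_area(segment_phase(img16))
        assert measured == pytest.approx(truth.area_fraction, rel=0.15)


class TestCellArea:
    def test_extremes_and_half(self):
        assert cell_area(np.zeros((8, 8), bool)) == 0.0
        assert cell_area(np.ones((8, 8), bool)) == 1.0
        checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
        assert cell_area(checker) == 0.5


class TestFoldIncrease:
    def test_arithmetic(self):
        assert fold_increase(0.3, 0.3) == 1.0
        assert fold_increase(0.0, 0.3) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            fold_increase(0.3, 0.0)

    def test_sixfold_growth_through_full_pipeline(self):
        scene, _ = si.sample_scene(41, target_area_fraction=0.075)
        grown = si.grow_scene(scene, 6.0)
        spec = si.RenderSpec(noise_sigma=0.02)
        a0 = cell_area(segment_phase(si.render_phase(scene, spec)))
        a5 = cell_area(segment_phase(si.render_phase(grown, spec)))
        assert fold_increase(a5, a0) == pytest.approx(6.0, rel=0.15)


class TestSox1Fraction:
    def test_reporter_everywhere(self):
        scene, _ = si.sample_scene(51, target_area_fraction=0.2)
        marked = si.set_reporter_fraction(scene, 1.0)
        truth = si.ground_truth(marked)
        fluor = si.render_fluorescence(marked, truth)
        res = sox1_fraction(truth.cell_mask, fluor)
        assert res.sox1_area_fraction_of_cells == pytest.approx(1.0, abs=0.02)

    def test_no_signal_gives_zero(self):
        scene, truth = si.sample_scene(52, target_area_fraction=0.2)
        spec = si.RenderSpec(noise_sigma=0.02)
        blank = si.ground_truth(si.set_reporter_fraction(scene, 0.0))
        fluor = si.render_fluorescence(scene, blank, spec)
        res = sox1_fraction(truth.cell_mask, fluor)
        assert res.sox1_area_fraction_of_cells == 0.0

    def test_half_reporter_recovered(self):
        scene, _ = si.sample_scene(53, target_area_fraction=0.2, n_colonies=10)
        marked = si.set_reporter_fraction(scene, 0.5)
        truth = si.ground_truth(marked)
        spec = si.RenderSpec(noise_sigma=0.02)
        mask = segment_phase(si.render_phase(marked, spec))
        fluor = si.render_fluorescence(marked, truth, spec)
        res = sox1_fraction(mask, fluor)
        assert res.sox1_area_fraction_of_cells == pytest.approx(0.5, abs=0.05)

    def test_empty_phase_mask_flagged(self):
        res = sox1_fraction(np.zeros((32, 32), bool), np.zeros((32, 32)))
        assert not res.defined
        assert np.isnan(res.sox1_area_fraction_of_cells)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            sox1_fraction(np.zeros((32, 32), bool), np.zeros((16, 16)))


def toy_measurements():
    # 2 experiments × 2 chambers × 2 images, hand-checkable numbers
    rows = []
    values = {
        (0, 0): [0.10, 0.12], (0, 1): [0.20, 0.22],
        (1, 0): [0.30, 0.32], (1, 1): [0.40, 0.42],
    }
    for (exp, cham), vals in values.items():
        for v in vals:
            rows.append({"condition": "A", "experiment": exp,
                         "chamber": cham, "value": v})
    return pd.DataFrame(rows)


class TestAggregateCondition:
    def test_hand_computed_hierarchy(self):
        # chamber means: .11 .21 .31 .41 → experiment means: .16 .36
        # condition mean 0.26, sd over experiments = 0.1414
        s = aggregate_condition(toy_measurements(), "A")
        assert s.per_experiment_means == pytest.approx({0: 0.16, 1: 0.36})
        assert s.mean == pytest.approx(0.26)
        assert s.sd == pytest.approx(np.std([0.16, 0.36], ddof=1))
        assert s.n_experiments == 2

    def test_single_image_passthrough(self):
        df = pd.DataFrame([{"condition": "A", "experiment": 0,
                            "chamber": 0, "value": 0.42}])
        s = aggregate_condition(df, "A")
        assert s.mean == 0.42
        assert s.sd == 0.0

    def test_identical_chambers_zero_sd(self):
        df = pd.DataFrame([
            {"condition": "A", "experiment": e, "chamber": c, "value": 0.3}
            for e in range(3) for c in range(3)])
        assert aggregate_condition(df, "A").sd == 0.0

    def test_fold_against_baseline(self):
        s = aggregate_condition(toy_measurements(), "A", baseline=0.13)
        assert s.fold_increase == pytest.approx(2.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(InvalidParameterError):
            aggregate_condition(pd.DataFrame({"value": [1.0]}), "A")


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_unpaired_equal_var([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        # pooled variance 1, se = sqrt(2/3), t = -3/se, df = 4
        t, p = ttest_unpaired_equal_var([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_swap_symmetry(self):
        t1, p1 = ttest_unpaired_equal_var([1, 2, 3], [4, 5, 6])
        t2, p2 = ttest_unpaired_equal_var([4, 5, 6], [1, 2, 3])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_cases(self):
        assert ttest_unpaired_equal_var([2, 2], [2, 2]) == (0.0, 1.0)
        t, p = ttest_unpaired_equal_var([2, 2], [3, 3])
        assert p == 0.0 and np.isinf(t)

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            ttest_unpaired_equal_var([1.0], [2.0, 3.0])

    def test_matches_hand_pooled_variance_formula(self, rng):
        from scipy import stats as ss
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
            t, p = ttest_unpaired_equal_var(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_hand = 2 * ss.t.sf(abs(t_hand), na + nb - 2)
            assert t == pytest.approx(t_hand, abs=1e-9)
            assert p == pytest.approx(p_hand, abs=1e-9)


def perfect_series(slope=-3.3219280948873626, intercept=22.0, n=5):
    logs = -np.arange(n, dtype=float)  # 10-fold dilutions
    return [(x, slope * x + intercept) for x in logs]


class TestStandardCurve:
    def test_perfect_tenfold_series(self):
        curve = fit_standard_curve(perfect_series(), gene="Sox1")
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_rejected(self):
        with pytest.raises(StandardCurveError):
            fit_standard_curve(perfect_series(n=2))

    def test_ct_offset_moves_intercept_only(self):
        base = fit_standard_curve(perfect_series())
        shifted = fit_standard_curve(
            [(x, ct + 3.0) for x, ct in perfect_series()])
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.intercept == pytest.approx(base.intercept + 3.0)
        assert shifted.efficiency == pytest.approx(base.efficiency)

    def test_positive_slope_rejected(self):
        with pytest.raises(StandardCurveError, match="slope"):
            fit_standard_curve([(x, -ct) for x, ct in perfect_series()])

    def test_noisy_series_rejected_by_r2(self, rng):
        pts = [(x, ct + rng.normal(0, 3.0)) for x, ct in perfect_series(n=8)]
        with pytest.raises(StandardCurveError, match="r²"):
            fit_standard_curve(pts, min_r_squared=0.999)


class TestRelativeExpression:
    @pytest.fixture
    def curves(self):
        return {g: fit_standard_curve(perfect_series(), gene=g)
                for g in ("Sox1", "Gapdh")}

    def test_control_normalises_to_one(self, curves):
        records = [QpcrRecord("ctrl", "Sox1", 24.0), QpcrRecord("ctrl", "Gapdh", 18.0),
                   QpcrRecord("perf", "Sox1", 24.0), QpcrRecord("perf", "Gapdh", 18.0)]
        out = relative_expression(records, curves, control_sample="ctrl")
        assert np.allclose(out["fold_vs_control"], 1.0)

    def test_one_slope_unit_is_tenfold(self, curves):
        m = abs(curves["Sox1"].slope)
        records = [QpcrRecord("ctrl", "Sox1", 24.0), QpcrRecord("ctrl", "Gapdh", 18.0),
                   QpcrRecord("perf", "Sox1", 24.0 - m), QpcrRecord("perf", "Gapdh", 18.0)]
        out = relative_expression(records, curves, control_sample="ctrl")
        fold = out.loc[(out["sample"] == "perf") & (out["gene"] == "Sox1"),
                       "fold_vs_control"].iloc[0]
        assert fold == pytest.approx(10.0, rel=1e-9)

    def test_reference_gene_fold_is_identically_one(self, curves):
        records = [QpcrRecord(s, "Gapdh", ct)
                   for s, ct in [("ctrl", 18.0), ("a", 20.0), ("b", 15.0)]]
        out = relative_expression(records, curves, control_sample="ctrl")
        assert np.allclose(out["fold_vs_control"], 1.0)

    def test_global_ct_shift_per_sample_is_invariant(self, curves):
        records = [QpcrRecord("ctrl", "Sox1", 24.0), QpcrRecord("ctrl", "Gapdh", 18.0),
                   QpcrRecord("perf", "Sox1", 23.0), QpcrRecord("perf", "Gapdh", 17.5)]
        shifted = [QpcrRecord(r.sample, r.gene,
                              r.ct + (2.0 if r.sample == "perf" else 0.0))
                   for r in records]
        out1 = relative_expression(records, curves, control_sample="ctrl")
        out2 = relative_expression(shifted, curves, control_sample="ctrl")
        pd.testing.assert_frame_equal(
            out1[["sample", "gene", "fold_vs_control"]],
            out2[["sample", "gene", "fold_vs_control"]])

    def test_sample_without_reference_skipped_with_warning(self, curves):
        records = [QpcrRecord("ctrl", "Sox1", 24.0), QpcrRecord("ctrl", "Gapdh", 18.0),
                   QpcrRecord("orphan", "Sox1", 23.0)]
        with pytest.warns(UserWarning, match="orphan"):
            out = relative_expression(records, curves, control_sample="ctrl")
        assert "orphan" not in set(out["sample"])

    def test_missing_curve_rejected(self, curves):
        records = [QpcrRecord("ctrl", "Fgf5", 30.0), QpcrRecord("ctrl", "Gapdh", 18.0)]
        with pytest.raises(InvalidParameterError, match="Fgf5"):
            relative_expression(records, curves, control_sample="ctrl")
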