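import numpy as np
import pytest
from scipy import stats

from sproutsim.config import SimulationConfig
from sproutsim.experiments import (
    PRESET_NAMES,
    BatchResult,
    BatchSpec,
    area_reach_correlation,
    compare_samples,
    compare_to_control,
    min_max_change_percent,
    preset_conditions,
    preset_experiment,
    run_batch,
    sweep,
)
from sproutsim.metrics import SimulationResult


def small_spec(num_sim=3, base_seed=0, **cfg_kw):
    base = dict(
        rows=12, cols=12, ini_ec=8, n_vegf=30, n_svegfr1=6, num_cycles=8,
        p_execute=0.5, seed=0,
    )
    base.update(cfg_kw)
    return BatchSpec(SimulationConfig(**base), num_sim, base_seed)


def fake_batch(areas, reaches=None):
    """BatchResult with prescribed per-replicate metrics (no grids)."""
    areas = np.asarray(areas, dtype=float)
    if reaches is None:
        reaches = np.zeros_like(areas)
    results = [
        SimulationResult(final_grid=None, ec_series=np.array([0]),
                         area=float(a), reach=int(r), seed=i)
        for i, (a, r) in enumerate(zip(areas, reaches))
    ]
    return BatchResult(
        spec=None, results=results, mean_area=float(areas.mean()),
        mean_reach=float(np.mean(reaches)), ci95_area=(0.0, 0.0),
    )


class TestRunBatch:
    def test_seed_schedule(self):
        batch = run_batch(small_spec(num_sim=3, base_seed=100))
        assert [r.seed for r in batch.results] == [100, 101, 102]

    def test_frozen_dynamics_degenerate_ci(self):
        spec = small_spec(num_sim=4, p_execute=0.0)
        batch = run_batch(spec)
        expected = spec.base_config.ini_ec / spec.base_config.grid_area
        assert batch.mean_area == expected
        assert batch.ci95_area == (expected, expected)

    def test_growth_above_initial_vessel(self):
        batch = run_batch(small_spec(num_sim=5))
        assert batch.mean_area > 8 / 144

    def test_ci_brackets_mean(self):
        batch = run_batch(small_spec(num_sim=5))
        lo, hi = batch.ci95_area
        assert lo <= batch.mean_area <= hi

    def test_replicate_frame_columns(self):
        frame = run_batch(small_spec(num_sim=2)).to_frame("cond")
        for col in ("condition_id", "seed", "final_ec_count", "area", "reach"):
            assert col in frame.columns
        assert len(frame) == 2


class TestSweep:
    def test_empty_values(self):
        assert sweep(small_spec(), "n_vegf", []) == []

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            sweep(small_spec(), "vegf_count", [1])

    def test_order_preserved_and_fields_fixed(self):
        out = sweep(small_spec(num_sim=2), "n_vegf", [5, 40])
        assert [v for v, _ in out] == [5, 40]
        for v, batch in out:
            assert batch.spec.base_config.n_vegf == v
            assert batch.spec.base_config.n_svegfr1 == 6

    def test_vegf_monotone_effect_small_scale(self):
        # more VEGF, same inhibitor -> larger mean network area
        out = sweep(small_spec(num_sim=8, n_svegfr1=4), "n_vegf", [0, 120])
        assert out[1][1].mean_area > out[0][1].mean_area


class TestCompare:
    def test_batch_against_itself(self):
        batch = run_batch(small_spec(num_sim=5))
        report = compare_to_control(batch, batch)
        assert report.mean_difference == 0.0
        assert report.p_value > 0.9

    def test_non_overlapping_samples_tiny_p(self):
        rng = np.random.default_rng(0)
        a = fake_batch(0.30 + 0.01 * rng.random(50))
        b = fake_batch(0.10 + 0.01 * rng.random(50))
        report = compare_to_control(a, b)
        assert report.p_value < 1e-6
        assert report.mean_difference == pytest.approx(0.2, abs=0.01)
        lo, hi = report.ci95_difference
        assert lo <= report.mean_difference <= hi

    def test_zero_variance_identical_batches(self):
        report = compare_samples([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert report == type(report)(0.0, 1.0, 0.0, (0.0, 0.0))

    def test_too_small_batches_rejected(self):
        with pytest.raises(ValueError):
            compare_samples([1.0], [1.0, 2.0])

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        report = compare_samples(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert report.t_statistic == pytest.approx(t)
        assert report.p_value == pytest.approx(p)


class TestAreaReachCorrelation:
    def test_perfect_monotone(self):
        rho, _ = area_reach_correlation([fake_batch([1, 2, 3], [1, 2, 3])])
        assert rho == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        rho, _ = area_reach_correlation([fake_batch([1, 2, 3], [3, 2, 1])])
        assert rho == pytest.approx(-1.0)

    def test_pools_across_batches(self):
        rho, _ = area_reach_correlation(
            [fake_batch([1, 2], [1, 2]), fake_batch([3, 4], [3, 4])]
        )
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            area_reach_correlation([fake_batch([1, 2], [1, 2])])


class TestMinMaxChange:
    def test_flat_sweep_is_zero(self):
        b = fake_batch([0.01] * 3)
        assert min_max_change_percent([(0, b), (1, b)], b) == 0.0

    def test_percent_of_control_arithmetic(self):
        # a 0.01 -> 0.0168 span over a 0.01 control mean is a 68% change
        ref = fake_batch([0.01] * 3)
        hi = fake_batch([0.0168] * 3)
        assert min_max_change_percent([(0, ref), (1, hi)], ref) == pytest.approx(68.0)

    def test_alternative_denominators(self):
        ref = fake_batch([0.02] * 3)
        hi = fake_batch([0.03] * 3)
        swp = [(0, ref), (1, hi)]
        assert min_max_change_percent(swp, ref, "min") == pytest.approx(50.0)
        assert min_max_change_percent(swp, ref, "grid") == pytest.approx(1.0)

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            min_max_change_percent([], fake_batch([0.01]))


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_conditions("fig42")

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_all_presets_instantiate(self, name):
        conds = preset_conditions(name)
        assert conds

    def test_added_ado_control_condition(self):
        conds = preset_conditions("added_ado")
        control = [c for c in conds if c.is_control]
        assert len(control) == 1
        cfg = control[0].config
        assert (cfg.n_vegf, cfg.n_svegfr1, cfg.n_ado) == (40000, 8000, 0)
        assert cfg.ruleset == "R2"

    def test_comparison_panel_combination_condition(self):
        conds = {c.label: c.config for c in preset_conditions("comparison_panel")}
        combo = conds["added_combination"]
        assert (combo.n_vegf, combo.n_svegfr1, combo.n_ado) == (40000, 20000, 10000)

    def test_verification_presets_run_100_cycles(self):
        for name in ("verification_vegf", "verification_svegfr1"):
            assert all(c.config.num_cycles == 100 for c in preset_conditions(name))

    def test_combined_ratio2_proportion(self):
        for cond in preset_conditions("combined_ratio2"):
            if not cond.is_control:
                added_sv = cond.config.n_svegfr1 - 8000
                assert added_sv == 2 * cond.config.n_ado

    def test_preset_condition_order_and_labels(self):
        labels = [c.label for c in preset_conditions("comparison_panel")]
        assert labels == [
            "control", "added_svegfr1", "added_ado", "added_combination"
        ]

    def test_preset_result_tables(self):
        from sproutsim.experiments import Condition, PresetResult

        spec = small_spec(num_sim=2)
        batches = [run_batch(spec), run_batch(BatchSpec(spec.base_config, 2, 2))]
        conds = [
            Condition("control", spec.base_config, is_control=True),
            Condition("treated", spec.base_config),
        ]
        res = PresetResult("demo", conds, batches)
        assert res.control is batches[0]
        summary = res.summary_frame()
        assert list(summary["condition_id"]) == ["control", "treated"]
        assert (summary["n"] == 2).all()
        frame = res.replicate_frame()
        assert len(frame) == 4
        assert set(frame["condition_id"]) == {"control", "treated"}
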