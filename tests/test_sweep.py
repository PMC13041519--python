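import json

import numpy as np
import pandas as pd
import pytest

from avistrike import (
    FrontalSilhouette,
    LightScenario,
    aggregate_by_behavior,
    aggregate_by_cell,
    build_grid,
    run_cell,
    run_sweep,
    write_outputs,
)
from avistrike.sweep import records_to_frame


def tiny_grid(**overrides):
    cfg = {
        "escape_speed": {"start": 3.0, "stop": 9.0, "count": 2},
        "delay": {"start": 0.0, "stop": 0.5, "count": 2},
        "d_min": {"start": 2.0, "stop": 12.0, "count": 3},
        "approach_speed": {"start": 70.47, "stop": 270.97, "count": 2},
        "beta": {"start": 0.5, "stop": 8.5, "count": 2},
        "iterations": 40,
    }
    cfg.update(overrides)
    return build_grid(cfg)


class TestGridConstruction:
    def test_default_axis_lengths(self):
        grid = build_grid()
        assert grid.axis_lengths == (3, 9, 11, 10, 15, 10)
        assert grid.iterations == 500

    def test_default_total_predictions(self):
        assert build_grid().total_predictions == 222_750_000

    def test_published_increments(self):
        grid = build_grid()
        np.testing.assert_allclose(np.diff(grid.escape_speeds), 2.0)
        np.testing.assert_allclose(np.diff(grid.delays), 0.1)
        np.testing.assert_allclose(np.diff(grid.d_mins), 14.35 / 9 - 1 / 9)
        assert np.diff(grid.d_mins)[0] == pytest.approx(1.4833, abs=1e-4)
        assert np.diff(grid.approach_speeds)[0] == pytest.approx(14.3214, abs=1e-4)
        assert np.diff(grid.betas)[0] == pytest.approx(0.8889, abs=1e-4)

    def test_single_point_grid(self):
        grid = build_grid(
            {k: {"start": v, "stop": v, "count": 1}
             for k, v in [("escape_speed", 5.0), ("delay", 0.1), ("d_min", 3.0),
                          ("approach_speed", 100.0), ("beta", 1.0)]}
            | {"iterations": 1, "scenarios": {"none": {"p_away": 0.42}}}
        )
        assert grid.total_predictions == 1

    def test_malformed_config_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            build_grid({"escape_speed": "fast"})
        with pytest.raises(ValueError):
            build_grid({"delay": {"start": 1.0, "stop": 0.0, "count": 5}})
        with pytest.raises(ValueError):
            build_grid({"beta": {"start": 0.5, "stop": 8.5, "count": 0}})


class TestRunCell:
    def test_fast_escaper_mostly_clears_and_times_match_scalar_api(self, small_sil):
        """A near-vehicle-speed escaper clears the width in the vast majority
        of draws, and every record's phase-one times agree with the scalar
        kinematics functions evaluated at the sampled inputs."""
        from avistrike import AnimalParams, VehicleParams, time_available, time_needed

        records = run_cell(
            small_sil, 1.15, sa=60.0, delta=0.0, d_min=2.0, sv=70.47, beta=1.0,
            scenario=LightScenario.default("none"), iterations=500, seed=5,
        )
        assert len(records) == 500
        colliders = [r for r in records if r.collision_possible]
        assert len(colliders) < 75
        assert all(r.p_collision == 0.0 for r in records if not r.collision_possible)
        v = VehicleParams.from_silhouette(70.47, small_sil)
        for r in records[::25]:
            a = AnimalParams(l=1.15, sa=r.sa, delta=r.delta, d_fid=r.d_fid,
                             theta=r.theta, d_min=r.d_min)
            assert r.t_a == pytest.approx(time_needed(a), abs=1e-12)
            assert r.t_v == pytest.approx(time_available(a, v), abs=1e-12)
            assert r.collision_possible == (r.t_a >= r.t_v)

    def test_outrun_vehicle_rejected(self, small_sil):
        """An animal faster than the vehicle can make the closing speed
        non-positive for away angles, which is outside the model's domain."""
        with pytest.raises(ValueError, match="closing speed"):
            run_cell(
                small_sil, 1.15, sa=500.0, delta=0.0, d_min=2.0, sv=70.47,
                beta=1.0, scenario=LightScenario.default("none"),
                iterations=100, seed=5,
            )

    def test_solid_silhouette_certain_hit_when_in_bounds(self):
        sil = FrontalSilhouette(np.ones((20, 200), dtype=np.uint8), width_m=14.35)
        records = run_cell(
            sil, 1.15, sa=1.0, delta=1.0, d_min=7.0, sv=270.97, beta=0.5,
            scenario=LightScenario.default("none"), iterations=200, seed=9,
        )
        hits = [r for r in records if r.collision_possible]
        assert hits
        for r in hits:
            if 1.0 < r.d_collision < 13.35:  # window fully inside the grid
                assert r.p_collision == 1.0

    def test_same_seed_identical_records(self, small_sil):
        kw = dict(sa=5.0, delta=0.2, d_min=5.0, sv=100.0, beta=2.0,
                  scenario=LightScenario.default("blue"), iterations=50, seed=11)
        assert run_cell(small_sil, 1.15, **kw) == run_cell(small_sil, 1.15, **kw)

    def test_escape_implies_zero_probability(self, small_sil):
        records = run_cell(
            small_sil, 1.15, sa=9.0, delta=0.3, d_min=6.0, sv=80.0, beta=4.0,
            scenario=LightScenario.default("blue"), iterations=300, seed=13,
        )
        for r in records:
            if not r.collision_possible:
                assert r.p_collision == 0.0
            assert 0.0 <= r.p_collision <= 1.0

    def test_bernoulli_mode_draws_outcomes(self, small_sil):
        records = run_cell(
            small_sil, 1.15, sa=3.0, delta=0.5, d_min=7.0, sv=150.0, beta=1.0,
            scenario=LightScenario.default("none"), iterations=100, seed=17,
            mode="bernoulli",
        )
        assert all(r.outcome in (True, False) for r in records)
        for r in records:
            if r.p_collision == 0.0:
                assert r.outcome is False


class TestRunSweep:
    def test_deterministic_and_complete(self, small_sil):
        grid = tiny_grid()
        a = run_sweep(grid, small_sil, seed=42)
        b = run_sweep(grid, small_sil, seed=42)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert len(a.cells) == grid.n_cells
        assert a.manifest["total_predictions"] == grid.total_predictions
        assert a.cells["mean_p"].between(0, 1).all()

    def test_streamed_curves_match_record_aggregation(self, small_sil):
        grid = tiny_grid(iterations=30)
        res = run_sweep(grid, small_sil, seed=7, collect_records=True)
        # per-cell means recomputed from raw records
        per_cell = res.records.groupby(
            ["scenario", "sa", "delta", "d_min", "sv", "beta"], sort=False
        )["p_collision"].mean()
        np.testing.assert_allclose(
            np.sort(per_cell.to_numpy()), np.sort(res.cells["mean_p"].to_numpy())
        )
        # binned angle curve recomputed from raw records
        streamed = res.behavior_curve("theta").table
        recomputed = aggregate_by_behavior(res.records, axis="theta").table
        merged = streamed.merge(
            recomputed, on=["scenario", "value"], suffixes=("_s", "_r"), how="outer"
        )
        assert merged.notna().all().all()
        np.testing.assert_allclose(merged["mean_p_s"], merged["mean_p_r"])
        assert merged["n_s"].sum() == grid.total_predictions

    def test_expectation_and_bernoulli_agree(self, small_sil):
        grid = tiny_grid(iterations=300)
        exp = run_sweep(grid, small_sil, seed=3, mode="expectation")
        ber = run_sweep(grid, small_sil, seed=3, mode="bernoulli")
        m_exp = exp.cells["mean_p"].mean()
        m_ber = ber.cells["mean_p"].mean()
        n = grid.total_predictions
        se = float(np.sqrt(m_exp * (1 - m_exp) / n))
        assert abs(m_exp - m_ber) < 3 * se + 1e-9

    def test_dmin_beyond_silhouette_rejected(self, small_sil):
        grid = tiny_grid(d_min={"start": 1.0, "stop": 20.0, "count": 3})
        with pytest.raises(ValueError, match="width"):
            run_sweep(grid, small_sil, seed=1)


class TestAggregation:
    def _synthetic_records(self):
        rows = []
        for sa, p in [(1.0, 0.2), (3.0, 0.4)]:
            for i in range(10):
                rows.append(
                    dict(scenario="none", sa=sa, delta=0.0, d_min=1.0, sv=70.0,
                         beta=0.5, theta=45.0, d_fid=50.0, away=False, t_a=1.0,
                         t_v=0.5, collision_possible=True, d_collision=7.0,
                         p_collision=p, outcome=None)
                )
        return pd.DataFrame(rows)

    def test_grand_mean_of_two_cells(self):
        curve = aggregate_by_cell(self._synthetic_records())
        assert curve.table["mean_p"].iloc[0] == pytest.approx(0.3)

    def test_marginal_keeps_cells_separate(self):
        curve = aggregate_by_cell(self._synthetic_records(), axis="sa")
        assert dict(zip(curve.table["value"], curve.table["mean_p"])) == pytest.approx(
            {1.0: 0.2, 3.0: 0.4}
        )

    def test_all_zero_records_give_zero_curves(self):
        df = self._synthetic_records().assign(p_collision=0.0)
        assert (aggregate_by_cell(df, axis="sa").table["mean_p"] == 0).all()

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_by_cell(pd.DataFrame())

    def test_behavior_bins_reproduce_linear_probability(self, rng):
        """Records with p = theta / 180 recover the line at bin precision."""
        theta = rng.uniform(0.01, 179.99, size=20_000)
        df = pd.DataFrame(
            dict(scenario="none", theta=theta, d_fid=50.0, p_collision=theta / 180.0)
        )
        curve = aggregate_by_behavior(df, axis="theta", bin_width=0.1).table
        expected = (curve["value"] + 0.05) / 180.0
        assert (curve["mean_p"] - expected).abs().max() <= 0.05 / 180.0 + 1e-12
        assert curve["n"].sum() == len(df)


class TestOutputs:
    def test_csv_rows_and_manifest(self, small_sil, tmp_path):
        grid = tiny_grid(
            escape_speed={"start": 5.0, "stop": 5.0, "count": 1},
            delay={"start": 0.0, "stop": 0.0, "count": 1},
            d_min={"start": 7.0, "stop": 7.0, "count": 1},
            approach_speed={"start": 100.0, "stop": 100.0, "count": 1},
            beta={"start": 1.0, "stop": 1.0, "count": 1},
            iterations=10,
            scenarios={"none": {"p_away": 0.42}},
        )
        res = run_sweep(grid, small_sil, seed=2, collect_records=True)
        paths = write_outputs(res, tmp_path / "out")
        records_lines = paths["records"].read_text().splitlines()
        assert len(records_lines) == 1 + 10  # header + one row per prediction
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["total_predictions"] == 10 == np.prod(
            manifest["axis_lengths"]
        ) * manifest["iterations"]

    def test_rerun_byte_identical(self, small_sil, tmp_path):
        grid = tiny_grid(iterations=15)
        for d in ("a", "b"):
            write_outputs(run_sweep(grid, small_sil, seed=21), tmp_path / d)
        for name in ("cells.csv", "grand_means.csv", "behavior_theta.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_record_frame_columns(self, small_sil):
        records = run_cell(
            small_sil, 1.15, sa=5.0, delta=0.1, d_min=3.0, sv=100.0, beta=1.0,
            scenario=LightScenario.default("red"), iterations=5, seed=1,
        )
        frame = records_to_frame(records)
        assert list(frame.columns)[:6] == ["scenario", "sa", "delta", "d_min", "sv", "beta"]
        assert len(frame) == 5
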