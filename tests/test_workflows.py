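import numpy as np
import pytest

from dataclasses import replace

from xtalscale import reflection_data as rd
from xtalscale import workflows as wf
from xtalscale.models import ModelConfig
from xtalscale.synthetic import GroundTruth, generate_filter_fixture, \
    generate_sweeps

FAST = dict(selection="all", combine=False)


def rms_scale_error(state):
    t = state.table
    ok = rd.usable(t)
    ratio = t["g"].to_numpy()[ok] / t["g_true"].to_numpy()[ok]
    ratio /= ratio.mean()
    return float(np.sqrt(np.mean((ratio - 1.0) ** 2)))


class TestScale:
    def test_pass_through_when_everything_disabled(self, sim_single_sweep):
        table, sweeps, truth = sim_single_sweep
        cfg = wf.ScalingRunConfig(
            selection="all", combine=False, error_model=False,
            outlier_rejection=False, full_matrix=False,
            model_config=ModelConfig(scale=False, decay=False,
                                     absorption=False))
        state = wf.scale(table, sweeps, truth.space_group, cfg)
        np.testing.assert_allclose(state.table["g"].to_numpy(), 1.0)
        np.testing.assert_array_equal(state.table["I_work"],
                                      state.table["I_prof"])
        assert state.cycle_log == []

    def test_noise_free_recovery_tight(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=4.0, sweep_width=60.0,
                            scale_amplitude=0.2, decay_B_final=2.0,
                            mean_I=1e8, background=1e-3)
        table, sweeps, truth = generate_sweeps(truth, seed=51)
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        state = wf.scale(table, sweeps, truth.space_group, cfg)
        assert rms_scale_error(state) < 0.005

    def test_scaling_improves_agreement(self, sim_single_sweep):
        table, sweeps, truth = sim_single_sweep
        cfg = wf.ScalingRunConfig(**FAST)
        state = wf.scale(table, sweeps, truth.space_group, cfg)
        before = state.table.assign(g=1.0)
        from xtalscale.merging import r_metrics
        ok = rd.usable(state.table)
        gid = state.table["group_id"].to_numpy()[ok]
        I = state.table["I_work"].to_numpy()[ok]
        _, rmeas_after, _ = r_metrics(
            gid, I, state.table["g"].to_numpy()[ok])
        _, rmeas_before, _ = r_metrics(gid, I, np.ones(ok.sum()))
        assert rmeas_after < rmeas_before

    def test_uncertainties_propagated(self, sim_single_sweep):
        table, sweeps, truth = sim_single_sweep
        cfg = wf.ScalingRunConfig(**FAST)
        state = wf.scale(table, sweeps, truth.space_group, cfg)
        assert state.minimizer is not None
        assert state.minimizer.covariance is not None
        ok = rd.usable(state.table)
        var_g = state.table["var_g"].to_numpy()[ok]
        assert np.all(var_g >= 0) and var_g.max() > 0

    def test_rescaling_own_output_is_stable(self, sim_single_sweep):
        table, sweeps, truth = sim_single_sweep
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        s1 = wf.scale(table, sweeps, truth.space_group, cfg)
        s2 = wf.scale(s1.table, sweeps, truth.space_group, cfg,
                      initial_models=s1.models)
        g1 = s1.table["g"].to_numpy()
        g2 = s2.table["g"].to_numpy()
        assert np.sqrt(np.mean((g2 / g1 - 1.0) ** 2)) < 1e-3
        phi1 = [c["phi"] for c in s1.cycle_log if c["stage"] ==
                "full_matrix"][-1]
        phi2 = [c["phi"] for c in s2.cycle_log if c["stage"] ==
                "full_matrix"][-1]
        assert phi2 == pytest.approx(phi1, rel=1e-3)

    def test_injected_outliers_flagged(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=5.0, sweep_width=45.0,
                            scale_amplitude=0.1, mean_I=1200.0,
                            outlier_fraction=0.01)
        table, sweeps, truth = generate_sweeps(truth, seed=53)
        cfg = wf.ScalingRunConfig(**FAST)
        state = wf.scale(table, sweeps, truth.space_group, cfg)
        t = state.table
        injected = t["injected_outlier"].to_numpy().astype(bool)
        flagged = (t["flags"].to_numpy() & rd.OUTLIER) > 0
        # most injected outliers are caught, few clean rows sacrificed
        assert flagged[injected].mean() > 0.7
        assert flagged[~injected].mean() < 0.02


class TestReferenceScaling:
    def test_identity_reference_keeps_identity_model(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=3.0, sweep_width=40.0,
                            scale_amplitude=0.0, mean_I=1e8,
                            background=1e-3)
        table, sweeps, truth = generate_sweeps(truth, seed=61)
        merged = table.drop_duplicates(["h", "k", "l"])[["h", "k", "l"]]
        merged = merged.assign(
            I=table.drop_duplicates(["h", "k", "l"])["I_true"].to_numpy())
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        state = wf.scale_against_reference(table, sweeps, truth.space_group,
                                           merged, cfg)
        g = state.table["g"].to_numpy()
        assert np.sqrt(np.mean((g - 1.0) ** 2)) < 0.01

    def test_known_scale_recovered_with_fixed_targets(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=3.0, sweep_width=60.0,
                            scale_amplitude=0.2, mean_I=1e8,
                            background=1e-3)
        table, sweeps, truth = generate_sweeps(truth, seed=63)
        merged = table.drop_duplicates(["h", "k", "l"])[["h", "k", "l"]]
        merged = merged.assign(
            I=table.drop_duplicates(["h", "k", "l"])["I_true"].to_numpy())
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        state = wf.scale_against_reference(table, sweeps, truth.space_group,
                                           merged, cfg)
        t = state.table
        ok = rd.usable(t)
        ratio = t["g"].to_numpy()[ok] / t["g_true"].to_numpy()[ok]
        assert np.sqrt(np.mean((ratio - 1.0) ** 2)) < 0.01

    def test_zero_overlap_is_an_error(self, sim_single_sweep):
        import pandas as pd
        table, sweeps, truth = sim_single_sweep
        ref = pd.DataFrame({"h": [40], "k": [41], "l": [42], "I": [1.0]})
        with pytest.raises(ValueError, match="reference"):
            wf.scale_against_reference(table, sweeps, truth.space_group,
                                       ref, wf.ScalingRunConfig(**FAST))


class TestIncremental:
    def test_identical_sweeps_converge_to_same_profile(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=4.0, sweep_width=45.0,
                            n_sweeps=2, scale_amplitude=0.15, mean_I=1200.0)
        table, sweeps, truth = generate_sweeps(truth, seed=71)
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        s0 = table[table["sweep_id"] == "sweep0"].copy()
        s1 = table[table["sweep_id"] == "sweep1"].copy()
        st0 = wf.scale(s0, {"sweep0": sweeps["sweep0"]}, truth.space_group,
                       cfg)
        st = wf.scale_incremental(st0, s1, {"sweep1": sweeps["sweep1"]},
                                  cfg)
        assert set(st.models) == {"sweep0", "sweep1"}
        assert rms_scale_error(st) < 0.02
        # merged data set grows
        assert len(st.merged()) >= len(st0.merged())

    def test_empty_addition_warns_and_keeps_state(self, sim_single_sweep):
        import pandas as pd
        table, sweeps, truth = sim_single_sweep
        cfg = wf.ScalingRunConfig(error_model=False, **FAST)
        st0 = wf.scale(table, sweeps, truth.space_group, cfg)
        with pytest.warns(UserWarning, match="empty"):
            st = wf.scale_incremental(st0, pd.DataFrame(), {}, cfg)
        assert st is st0


class TestScaleAndFilter:
    CFG = dict(model="kb", selection="all", combine=False,
               error_model=False, filter_partition="sweep",
               filter_max_percent_removed=20.0)

    def test_scrambled_subset_excluded_in_first_cycle(self):
        table, sweeps, truth = generate_filter_fixture(
            10, [3], 3.0, seed=5, mode="scramble")
        cfg = wf.ScalingRunConfig(**self.CFG)
        state = wf.scale_and_filter(table, sweeps, truth.space_group, cfg)
        hist = state.report["filter_history"]
        assert hist[0]["applied"] == ["sweep3"]
        excluded = (state.table["flags"].to_numpy() & rd.EXCLUDED) > 0
        assert set(state.table["sweep_id"][excluded]) == {"sweep3"}

    def test_homogeneous_fixture_no_exclusions(self):
        table, sweeps, truth = generate_filter_fixture(
            8, [], 1.0, seed=6)
        cfg = wf.ScalingRunConfig(**self.CFG)
        state = wf.scale_and_filter(table, sweeps, truth.space_group, cfg)
        assert state.report["observations_removed"] == 0

    def test_zero_removal_budget(self):
        table, sweeps, truth = generate_filter_fixture(
            10, [3], 3.0, seed=5, mode="scramble")
        cfg = wf.ScalingRunConfig(**{**self.CFG,
                                     "filter_max_percent_removed": 0.0})
        state = wf.scale_and_filter(table, sweeps, truth.space_group, cfg)
        assert state.report["observations_removed"] == 0

    def test_never_exceeds_removal_budget(self):
        table, sweeps, truth = generate_filter_fixture(
            10, [2, 3, 4], 5.0, seed=8, mode="scramble")
        cfg = wf.ScalingRunConfig(**{**self.CFG,
                                     "filter_max_percent_removed": 15.0})
        state = wf.scale_and_filter(table, sweeps, truth.space_group, cfg)
        assert state.report["observations_removed"] <= 0.15 * len(table)


class TestCrossValidation:
    def test_noise_free_work_and_free_near_zero(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, multiplicity=4.0, sweep_width=40.0,
                            scale_amplitude=0.15, mean_I=1e8,
                            background=1e-3)
        table, sweeps, truth = generate_sweeps(truth, seed=81)
        cfg = wf.ScalingRunConfig(error_model=False, full_matrix=False,
                                  **FAST)
        out = wf.cross_validate(table, sweeps, truth.space_group, cfg,
                                n_folds=2)
        assert out["mean"]["work_r_meas"] < 1e-3
        assert out["mean"]["free_r_meas"] < 1e-3
        assert len(out["folds"]) == 2

    def test_overparameterized_model_has_larger_free_gap(self):
        truth = GroundTruth(cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                            d_min=2.5, sweep_width=24.0, multiplicity=2.0,
                            mean_I=150.0, background=30.0,
                            scale_amplitude=0.2)
        table, sweeps, truth = generate_sweeps(truth, seed=21)
        base = wf.ScalingRunConfig(
            model="physical", error_model=False, full_matrix=False,
            model_config=ModelConfig(decay=False, absorption=False), **FAST)
        over = replace(base, model_config=ModelConfig(
            decay=False, absorption=False, scale_spacing=0.1))
        gaps = {}
        for name, cfg in (("default", base), ("fine", over)):
            out = wf.cross_validate(table, sweeps, truth.space_group, cfg,
                                    n_folds=2)
            gaps[name] = out["mean"]["free_r_meas"] - \
                out["mean"]["work_r_meas"]
        assert gaps["fine"] > gaps["default"]


class TestCLI:
    def test_simulate_then_scale_round_trip(self, tmp_path):
        from click.testing import CliRunner
        from xtalscale.cli import main
        runner = CliRunner()
        sim = tmp_path / "sim.tsv"
        res = runner.invoke(main, [
            "simulate", "--sweep-width", "30", "--multiplicity", "3",
            "--d-min", "3.0", "--scale-amplitude", "0.15",
            "--seed", "3", "--output", str(sim)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "scaled.tsv"
        rep = tmp_path / "report.json"
        res = runner.invoke(main, [
            "scale", str(sim), "--selection", "all", "--combine", "off",
            "--json-report", str(rep), "--output", str(out),
            "--merged-output", str(tmp_path / "merged.tsv")])
        assert res.exit_code == 0, res.output
        import json
        report = json.loads(rep.read_text())
        assert report["merging"]["overall"]["r_meas"] is not None
        table, sg, sweeps = rd.read_reflection_table(out)
        assert len(table) > 0 and "sweep0" in sweeps
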