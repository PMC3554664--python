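"""Numerical integration of the coupled system and peak extraction."""

import numpy as np
import pytest

from azipkpd import model_core as mc
from azipkpd.simulate import (
    SimulationResult,
    default_grid,
    peak_features,
    pk_mass_balance,
    simulate_study_arm,
)


@pytest.fixture(scope="module")
def lps_run(truth):
    return simulate_study_arm(
        truth.arm("lps"), truth.cascade,
        grid=default_grid(0.0, 96.0, 0.05), conversion=truth.conversion,
    )


class TestSteadyState:
    def test_control_arm_holds_baselines_over_120h(self, params):
        result = simulate_study_arm(
            params.arm("control"), params.cascade,
            grid=default_grid(0.0, 120.0, 0.5), conversion=params.conversion,
        )
        for analyte, baseline in (
            ("PCs", 49.8), ("KYN", 104.3), ("FST", 51.3), ("TST", 108.2)
        ):
            drift = np.abs(result.trajectories[analyte] - baseline) / baseline
            assert drift.max() < 1e-4      # within 0.01%

    def test_azi_only_arm_is_indistinguishable_from_control(self, truth):
        result = simulate_study_arm(
            truth.arm("azi_only"), truth.cascade,
            grid=default_grid(-1.0 / 3.0, 48.0, 0.1),
            conversion=truth.conversion,
        )
        assert np.allclose(result.trajectories["PCs"], 49.8, rtol=1e-6)
        assert np.allclose(result.trajectories["KYN"], 104.3, rtol=1e-6)
        # drug itself is present
        assert result.trajectories["AZI"].max() > 1.0


class TestPKAgreement:
    def test_ode_matches_closed_form_for_both_compounds(self, truth):
        grid = default_grid(0.0, 120.0, 0.5)
        result = simulate_study_arm(
            truth.arm("lps"), truth.cascade, grid=grid,
            conversion=truth.conversion,
        )
        closed = mc.pk_concentration(
            truth.lps_pk["normal"], 0.8, grid, conversion=truth.conversion
        )
        scale = closed.max()
        assert np.abs(result.trajectories["LPS"] - closed).max() / scale < 1e-6

        result = simulate_study_arm(
            truth.arm("azi_only"), truth.cascade,
            grid=default_grid(-1.0 / 3.0, 120.0, 0.5),
            conversion=truth.conversion,
        )
        t = result.time_h - mc.AZI_PREDOSE_TIME_H
        closed = mc.pk_concentration(truth.azi_pk["normal"], 100.0, t)
        assert (
            np.abs(result.trajectories["AZI"] - closed).max() / closed.max()
            < 1e-6
        )

    def test_pk_mass_balance_conserved(self, azi_normal):
        bal = pk_mass_balance(azi_normal, 100.0, horizon=120.0)
        assert bal["residual"] < 1e-6
        assert bal["eliminated"] > bal["central"]


class TestEventHandling:
    def test_pre_dose_timing_has_small_nonzero_effect(self, truth):
        grid = default_grid(0.0, 48.0, 0.1)
        arm = truth.arm("lps_azi")
        shifted = mc.StudyArm(
            label="lps_azi_t0",
            doses=tuple(
                mc.DoseEvent(0.0, d.compound_label, d.amount_per_kg, d.route)
                for d in arm.doses
            ),
            azi_pk=arm.azi_pk,
            lps_pk=arm.lps_pk,
        )
        peak_pre = peak_features(
            simulate_study_arm(arm, truth.cascade, grid=grid,
                               conversion=truth.conversion), "PCs"
        )
        peak_t0 = peak_features(
            simulate_study_arm(shifted, truth.cascade, grid=grid,
                               conversion=truth.conversion), "PCs"
        )
        rel = abs(peak_pre.value - peak_t0.value) / peak_pre.value
        assert 0.0 < rel < 0.05

    def test_dose_without_pk_parameters_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_study_arm(
                mc.StudyArm("bad", (mc.DoseEvent(0.0, "LPS", 0.8),)),
                truth.cascade,
            )

    def test_invalid_grid_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_study_arm(
                truth.arm("control"), truth.cascade,
                grid=np.array([0.0, 2.0, 1.0]),
            )


class TestGridRefinement:
    def test_halving_step_changes_pc_peak_by_under_a_tenth_percent(self, truth):
        arm = truth.arm("lps")
        peaks = []
        for step in (0.2, 0.1):
            result = simulate_study_arm(
                arm, truth.cascade, grid=default_grid(0.0, 48.0, step),
                conversion=truth.conversion,
            )
            peaks.append(peak_features(result, "PCs").value)
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 1e-3


class TestPeakFeatures:
    def test_constant_trajectory_flagged_at_boundary(self):
        res = SimulationResult(
            time_h=np.arange(5.0),
            trajectories={"PCs": np.full(5, 49.8)},
        )
        pk = peak_features(res, "PCs")
        assert pk.at_boundary
        assert pk.value == 49.8
        assert pk.time_h == 0.0

    def test_quadratic_refinement_matches_closed_form_tmax(self, truth):
        result = simulate_study_arm(
            truth.arm("azi_only"), truth.cascade,
            grid=default_grid(-1.0 / 3.0, 24.0, 0.25),
            conversion=truth.conversion,
        )
        pk = peak_features(result, "AZI")
        tmax, _ = mc.pk_tmax_thalf(truth.azi_pk["normal"])
        assert pk.time_h - mc.AZI_PREDOSE_TIME_H == pytest.approx(
            tmax, abs=0.02
        )

    def test_triangle_apex_recovered(self):
        t = np.arange(11.0)
        res = SimulationResult(
            time_h=t, trajectories={"KYN": 10.0 - np.abs(t - 5.0)}
        )
        pk = peak_features(res, "KYN")
        assert pk.time_h == pytest.approx(5.0)
        assert pk.value == pytest.approx(10.0)
        assert not pk.at_boundary

    def test_missing_analyte_rejected(self, lps_run):
        with pytest.raises(KeyError):
            peak_features(lps_run, "cortisol")


class TestDiseaseProgression:
    def test_peak_ordering_cytokines_kynurenine_behavior(self, lps_run):
        t_pc = peak_features(lps_run, "PCs").time_h
        t_kyn = peak_features(lps_run, "KYN").time_h
        t_fst = peak_features(lps_run, "FST").time_h
        t_tst = peak_features(lps_run, "TST").time_h
        assert t_pc < t_kyn < t_fst
        assert t_kyn < t_tst

    def test_azi_attenuates_cytokine_peak(self, truth, lps_run):
        combo = simulate_study_arm(
            truth.arm("lps_azi"), truth.cascade,
            grid=default_grid(-1.0 / 3.0, 96.0, 0.05),
            conversion=truth.conversion,
        )
        assert (
            peak_features(combo, "PCs").value
            < peak_features(lps_run, "PCs").value
        )

    def test_pc_peak_monotone_in_azi_dose(self, truth):
        # dose ladder 0, 25, 100, 400 mg/kg on top of the LPS challenge
        peaks = []
        base = truth.arm("lps_azi")
        for dose in (0.0, 25.0, 100.0, 400.0):
            doses = tuple(
                mc.DoseEvent(d.time, d.compound_label,
                             dose if d.compound_label == "AZI"
                             else d.amount_per_kg, d.route)
                for d in base.doses
            )
            arm = mc.StudyArm("ladder", doses, base.azi_pk, base.lps_pk)
            result = simulate_study_arm(
                arm, truth.cascade, grid=default_grid(-1.0 / 3.0, 48.0, 0.1),
                conversion=truth.conversion,
            )
            peaks.append(peak_features(result, "PCs").value)
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_long_format_export_round_trips(self, lps_run):
        frame = lps_run.to_frame()
        assert set(frame.columns) == {"arm", "analyte", "time_h", "value"}
        sub = frame[frame["analyte"] == "PCs"]
        assert np.array_equal(sub["value"].to_numpy(),
                              lps_run.trajectories["PCs"])
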