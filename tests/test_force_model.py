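"""Force profiles, CoM velocity reconstruction and stride work cost."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import quadgait as qg
from quadgait.force_model import stride_integral


def weight_support_amplitude_oracle(duty_factor: float, gravity: float = 1.0) -> float:
    """Independent amplitude oracle: average four overlapping half-sines
    over one stride by quadrature and solve for the amplitude whose
    stride-averaged total vertical force equals gravity."""
    mean_per_unit_amplitude, _ = quad(
        lambda t: math.sin(math.pi * t / duty_factor), 0.0, duty_factor
    )
    return gravity / (4.0 * mean_per_unit_amplitude)


class TestVerticalAmplitude:
    @pytest.mark.parametrize("df", [0.5, 0.55, 0.65, 0.75, 0.9, 1.0])
    def test_matches_quadrature_oracle(self, df):
        assert qg.vertical_amplitude(df) == pytest.approx(
            weight_support_amplitude_oracle(df), rel=1e-12
        )

    def test_closed_form_endpoints(self):
        assert qg.vertical_amplitude(1.0) == pytest.approx(math.pi / 8, rel=1e-12)
        assert qg.vertical_amplitude(0.5) == pytest.approx(math.pi / 4, rel=1e-12)

    def test_weight_support_exact_for_any_df(self):
        # stride-mean of the summed vertical limb forces equals gravity
        for df in (0.51, 0.6, 0.72, 0.84, 0.99):
            az = qg.vertical_amplitude(df, gravity=1.0)
            mean_total = 4.0 * az * quad(
                lambda t: math.sin(math.pi * t / df), 0.0, df
            )[0]
            assert abs(mean_total - 1.0) < 1e-9

    @pytest.mark.parametrize("df,g", [(0.0, 1.0), (-0.2, 1.0), (0.7, 0.0), (0.7, -1.0)])
    def test_domain_errors(self, df, g):
        with pytest.raises(qg.ConfigError):
            qg.vertical_amplitude(df, g)


class TestFootfallSchedule:
    def test_even_spacing_at_25(self):
        sched = qg.footfall_schedule(25.0)
        assert [sched[l] for l in (qg.LH, qg.LF, qg.RH, qg.RF)] == [0.0, 0.25, 0.5, 0.75]

    def test_trot_diagonal_pairs(self):
        sched = qg.footfall_schedule(50.0)
        assert sched[qg.LH] == sched[qg.RF] == 0.0
        assert sched[qg.RH] == sched[qg.LF] == 0.5

    def test_pace_ipsilateral_pairs(self):
        sched = qg.footfall_schedule(0.0)
        assert sched[qg.LH] == sched[qg.LF] == 0.0
        assert sched[qg.RH] == sched[qg.RF] == 0.5

    @pytest.mark.parametrize("phase", [-1.0, 100.0, 150.0])
    def test_domain_error(self, phase):
        with pytest.raises(qg.ConfigError):
            qg.footfall_schedule(phase)


@pytest.mark.parametrize("variant", ["base", "sloth", "bias", "full"])
def test_force_series_invariants(variant):
    cfg = qg.variant_config(variant, 0.7, 37.5)
    for limb, fs in qg.all_limb_forces(cfg).items():
        tau = (fs.times - fs.onset * cfg.stride_period) % cfg.stride_period
        swing = tau >= cfg.stance_period
        assert np.all(fs.forces[swing] == 0.0)
        assert np.all(fs.forces[:, 2] >= 0.0)


def test_full_sine_integrates_to_zero_without_bias():
    cfg = qg.GaitConfig(0.7, 37.5)
    for fs in qg.all_limb_forces(cfg).values():
        impulse = stride_integral(fs.forces[:, 0], cfg.stride_period)
        assert abs(impulse) < 1e-6


def test_bias_impulses_split_hind_forward_fore_backward():
    cfg = qg.variant_config("bias", 0.7, 25.0)
    impulses = {
        limb: stride_integral(fs.forces[:, 0], cfg.stride_period)
        for limb, fs in qg.all_limb_forces(cfg).items()
    }
    assert impulses[qg.LH] > 0 and impulses[qg.RH] > 0
    assert impulses[qg.LF] < 0 and impulses[qg.RF] < 0
    # hind/fore biases cancel; residual is trapezoid error at stance edges
    assert abs(sum(impulses.values())) < 1e-6


def test_suspended_reverses_fore_aft_only():
    upright = qg.GaitConfig(0.68, 40.0)
    suspended = qg.GaitConfig(0.68, 40.0, orientation="suspended")
    for limb in qg.LIMBS:
        fu = qg.limb_force_series(upright, limb).forces
        fs = qg.limb_force_series(suspended, limb).forces
        np.testing.assert_array_equal(fs[:, 0], -fu[:, 0])
        np.testing.assert_array_equal(fs[:, 2], fu[:, 2])


class TestComVelocities:
    def test_zero_mean_vertical_and_lateral(self):
        cfg = qg.variant_config("full", 0.72, 30.0)
        com = qg.com_velocities(qg.all_limb_forces(cfg), cfg)
        assert abs(com.velocities[:, 1].mean()) < 1e-9
        assert abs(com.velocities[:, 2].mean()) < 1e-9
        assert com.velocities[:, 0].mean() == pytest.approx(com.mean_forward_speed, abs=1e-9)
        assert np.all(com.velocities[:, 0] > 0)

    def test_insufficient_mean_speed_raises(self):
        cfg = qg.GaitConfig(0.7, 25.0, mean_forward_speed=1e-6)
        with pytest.raises(qg.ConfigError, match="mean_forward_speed"):
            qg.com_velocities(qg.all_limb_forces(cfg), cfg)

    @pytest.mark.parametrize("df,sign", [(0.65, -1), (0.80, 1)])
    def test_early_stance_vertical_velocity_sign_at_trot_phasing(self, df, sign):
        # downward in the first half of hind stance at low duty factor,
        # upward at high duty factor
        cfg = qg.GaitConfig(df, 50.0)
        com = qg.com_velocities(qg.all_limb_forces(cfg), cfg)
        mask = cfg.time_grid() < 0.5 * cfg.stance_period
        assert np.sign(com.velocities[mask, 2].mean()) == sign


class TestLimbPower:
    def test_zero_force_gives_zero_power(self):
        cfg = qg.GaitConfig(0.7, 25.0)
        forces = qg.all_limb_forces(cfg)
        com = qg.com_velocities(forces, cfg)
        null = qg.ForceSeries(
            limb=qg.LH, onset=0.0, times=cfg.time_grid(),
            forces=np.zeros((cfg.samples_per_stride, 3)),
        )
        assert np.all(qg.limb_power_series(null, com) == 0.0)

    def test_grid_mismatch_raises(self):
        cfg = qg.GaitConfig(0.7, 25.0)
        forces = qg.all_limb_forces(cfg)
        com = qg.com_velocities(forces, cfg)
        other = qg.limb_force_series(qg.GaitConfig(0.7, 25.0, samples_per_stride=512), qg.LH)
        with pytest.raises(ValueError):
            qg.limb_power_series(other, com)

    @pytest.mark.parametrize("variant", ["base", "full"])
    def test_signed_work_balances_over_a_stride(self, variant):
        # no net change of CoM kinetic energy over a periodic cycle
        cfg = qg.variant_config(variant, 0.7, 25.0)
        forces = qg.all_limb_forces(cfg)
        com = qg.com_velocities(forces, cfg)
        powers = [qg.limb_power_series(fs, com) for fs in forces.values()]
        signed = stride_integral(sum(powers), cfg.stride_period)
        positive = sum(
            stride_integral(np.maximum(p, 0.0), cfg.stride_period) for p in powers
        )
        negative = sum(
            stride_integral(np.maximum(-p, 0.0), cfg.stride_period) for p in powers
        )
        cost = qg.stride_work_cost(cfg)
        assert abs(signed) < 1e-5 * cost
        # per-limb positive work balances per-limb negative work
        assert positive == pytest.approx(negative, rel=1e-5)


class TestStrideWorkCost:
    def test_half_stride_phase_shift_symmetry(self):
        # planar model: phases P and P+50 are equivalent
        for df in (0.6, 0.8):
            c1 = qg.stride_work_cost(qg.GaitConfig(df, 30.0))
            c2 = qg.stride_work_cost(qg.GaitConfig(df, 80.0))
            assert c2 == pytest.approx(c1, rel=1e-9)

    def test_medial_forces_break_phase_shift_symmetry(self):
        cfg = qg.variant_config("full", 0.65, 25.0)
        c25 = qg.stride_work_cost(cfg)
        c75 = qg.stride_work_cost(cfg.at(phase_pct=75.0))
        assert abs(c25 - c75) > 1e-4 * c25

    def test_time_reversal_symmetry_without_bias(self):
        cfg = qg.GaitConfig(0.7, 30.0, mean_forward_speed=1.0)
        c1 = qg.stride_work_cost(cfg)
        c2 = qg.stride_work_cost(cfg.at(phase_pct=70.0))
        assert c2 == pytest.approx(c1, rel=1e-4)

    @pytest.mark.parametrize(
        "df,expected", [(0.65, {25.0, 75.0}), (0.85, {0.0, 50.0})]
    )
    def test_work_minimizing_phases_switch_family_at_high_duty_factor(
        self, df, expected, phase_grid
    ):
        costs = np.array([qg.stride_work_cost(qg.GaitConfig(df, p)) for p in phase_grid])
        winners = set(phase_grid[costs <= costs.min() * (1 + 1e-9)])
        assert winners == expected

    def test_phase_ranking_invariant_to_doubling_mean_speed(self, phase_grid):
        from scipy.stats import spearmanr

        half = phase_grid[phase_grid < 50.0]
        for df in (0.65, 0.85):
            rows = {}
            for v0 in (1.0, 2.0):
                cfg = qg.GaitConfig(df, 0.0, mean_forward_speed=v0)
                rows[v0] = np.array(
                    [qg.stride_work_cost(cfg.at(phase_pct=float(p))) for p in half]
                )
            assert np.argmin(rows[1.0]) == np.argmin(rows[2.0])
            rho = spearmanr(rows[1.0], rows[2.0]).statistic
            assert rho > 0.999

    def test_grid_convergence(self):
        c2048 = qg.stride_work_cost(qg.GaitConfig(0.7, 25.0, samples_per_stride=2048))
        c4096 = qg.stride_work_cost(qg.GaitConfig(0.7, 25.0, samples_per_stride=4096))
        assert abs(c4096 - c2048) / c2048 < 1e-3


class TestStanceAngle:
    def test_default_ratio_near_thirty_degrees(self):
        assert qg.stance_angle(0.2) == pytest.approx(30.0, abs=2.0)

    def test_vanishes_without_fore_aft_force(self):
        assert qg.stance_angle(0.0) == 0.0

    def test_monotonic_in_ratio(self):
        angles = [qg.stance_angle(r) for r in (0.05, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(angles, angles[1:]))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"duty_factor": 0.5},
        {"duty_factor": 1.0},
        {"phase_pct": 100.0},
        {"phase_pct": -5.0},
        {"fore_aft_ratio": -0.1},
        {"gravity": 0.0},
        {"stride_period": -1.0},
        {"orientation": "inverted"},
        {"samples_per_stride": 128},
        {"mean_forward_speed": 0.0},
    ],
)
def test_config_validation(kwargs):
    base = {"duty_factor": 0.7, "phase_pct": 25.0}
    with pytest.raises(qg.ConfigError):
        qg.GaitConfig(**{**base, **kwargs})


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    df=st.floats(0.55, 0.95),
    phase=st.floats(0.0, 49.999),
)
def test_phase_shift_symmetry_property(df, phase):
    """cost(P) == cost(P + 50) for any planar (medial-free) configuration."""
    cfg = qg.GaitConfig(df, phase, bias_ratio=0.1, samples_per_stride=512)
    c1 = qg.stride_work_cost(cfg)
    c2 = qg.stride_work_cost(cfg.at(phase_pct=phase + 50.0))
    assert c2 == pytest.approx(c1, rel=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(df=st.floats(0.52, 0.99), phase=st.floats(0.0, 99.999))
def test_discrete_weight_support_property(df, phase):
    """Summed vertical limb force averages to gravity on the grid."""
    cfg = qg.GaitConfig(df, phase, samples_per_stride=4096)
    total_fz = sum(fs.forces[:, 2] for fs in qg.all_limb_forces(cfg).values())
    assert total_fz.mean() == pytest.approx(cfg.gravity, abs=5e-6)
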