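"""Exoskeleton geometry, spring mechanics and actuation-timing mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exosweep.exo import (ExoGeometry, ExoSetting, added_mass_moments,
                          resting_length_for_timing, spring_ankle_torque,
                          spring_energy, spring_force, spring_length,
                          spring_moment_arm, spring_torque_series)
from exosweep.sweep import build_grid


def _coordinate_oracle(r1, r2, offset, theta):
    """Place both attachment points explicitly in the hinge frame."""
    p_foot = np.array([r2, 0.0])
    gamma = offset + theta
    p_shank = r1 * np.array([np.cos(gamma), np.sin(gamma)])
    d = p_shank - p_foot
    length = np.hypot(*d)
    # perpendicular distance from the hinge (origin) to the spring line
    arm = abs(p_foot[0] * d[1] - p_foot[1] * d[0]) / length
    return length, arm


class TestSpringGeometry:
    def test_collinear_arms(self):
        g = ExoGeometry(shank_attach_r=0.1, foot_attach_r=0.1,
                        attach_offset_angle=np.pi)
        assert spring_length(0.0, g) == pytest.approx(0.2, abs=1e-12)

    def test_three_four_five_triangle(self):
        g = ExoGeometry(shank_attach_r=0.3, foot_attach_r=0.4,
                        attach_offset_angle=np.pi / 2)
        assert spring_length(0.0, g) == pytest.approx(0.5, abs=1e-12)

    def test_matches_coordinate_oracle(self, rng):
        for _ in range(200):
            r1, r2 = rng.uniform(0.05, 0.5, 2)
            offset = rng.uniform(0.3, 2.8)
            theta = rng.uniform(-0.6, 0.6)
            g = ExoGeometry(shank_attach_r=r1, foot_attach_r=r2,
                            attach_offset_angle=offset)
            length, arm = _coordinate_oracle(r1, r2, offset, theta)
            assert spring_length(theta, g) == pytest.approx(length, abs=1e-9)
            assert abs(spring_moment_arm(theta, g)) == pytest.approx(arm,
                                                                     abs=1e-9)

    def test_torque_equals_cross_product_oracle(self, rng):
        for _ in range(100):
            r1, r2 = rng.uniform(0.05, 0.5, 2)
            offset = rng.uniform(0.3, 2.8)
            theta = rng.uniform(-0.6, 0.6)
            force = rng.uniform(0.0, 500.0)
            g = ExoGeometry(shank_attach_r=r1, foot_attach_r=r2,
                            attach_offset_angle=offset)
            p_foot = np.array([r2, 0.0])
            gamma = offset + theta
            p_shank = r1 * np.array([np.cos(gamma), np.sin(gamma)])
            u = (p_shank - p_foot) / np.linalg.norm(p_shank - p_foot)
            fv = force * u        # tension pulls the foot point shank-ward
            tq = p_foot[0] * fv[1] - p_foot[1] * fv[0]
            assert spring_ankle_torque(theta, force, g) == pytest.approx(
                tq, abs=1e-9 * max(1.0, force))

    def test_moment_arm_is_length_derivative(self, geometry):
        theta = np.linspace(-0.4, 0.2, 2001)
        L = spring_length(theta, geometry)
        num = np.gradient(L, theta)
        assert np.allclose(spring_moment_arm(theta, geometry)[5:-5],
                           num[5:-5], rtol=1e-4, atol=1e-7)


class TestSpringForceEnergy:
    def test_slack_cable_produces_no_force(self):
        assert spring_force(0.30, L0=0.31, k=5500.0) == 0.0
        assert spring_force(0.31, L0=0.31, k=5500.0) == 0.0  # tie at L0

    @pytest.mark.parametrize("k,expect", [(5500.0, 110.0), (17500.0, 350.0)])
    def test_hookean_tension(self, k, expect):
        assert spring_force(0.32, L0=0.30, k=k) == pytest.approx(expect)

    def test_energy_values(self):
        assert spring_energy(0.30, L0=0.31, k=5500.0) == 0.0
        assert spring_energy(0.32, L0=0.30, k=5500.0) == pytest.approx(1.1)

    def test_energy_is_path_independent(self, rng):
        lengths = 0.30 + np.abs(rng.normal(0, 0.02, 50))
        loop = np.concatenate([lengths, lengths[::-1]])
        e = spring_energy(loop, L0=0.30, k=8000.0)
        assert e[0] == e[-1]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            spring_force(0.3, L0=0.3, k=0.0)
        with pytest.raises(ValueError):
            spring_force(0.3, L0=-0.1, k=100.0)
        with pytest.raises(ValueError):
            spring_ankle_torque(0.0, -5.0, ExoGeometry())


@settings(derandomize=True, max_examples=100)
@given(r1=st.floats(0.05, 0.5), r2=st.floats(0.05, 0.5),
       offset=st.floats(0.3, 2.8), theta=st.floats(-0.6, 0.6),
       k=st.floats(100.0, 2e4), stretch0=st.floats(-0.05, 0.05))
def test_spring_force_is_energy_gradient(r1, r2, offset, theta, k, stretch0):
    """Tension equals the length-derivative of the stored elastic energy
    for any geometry, stiffness and (possibly slack) resting length."""
    g = ExoGeometry(shank_attach_r=r1, foot_attach_r=r2,
                    attach_offset_angle=offset)
    L = float(spring_length(theta, g))
    L0 = L - stretch0
    if L0 <= 1e-3:
        return
    h = 1e-7
    dE = (spring_energy(L + h, L0, k) - spring_energy(L - h, L0, k)) / (2 * h)
    if abs(L - L0) < 2 * h:     # kink at the slack point
        return
    assert spring_force(L, L0, k) == pytest.approx(dE, rel=1e-5, abs=1e-4)


class TestActuationTiming:
    def test_boundary_tau_equals_window_start(self, clean_trial, geometry):
        L0 = resting_length_for_timing(clean_trial, geometry, 15.0)
        idx = clean_trial.events.foot_flat
        assert L0 == pytest.approx(
            float(spring_length(clean_trial.ankle_angle[idx], geometry)),
            abs=1e-12)

    def test_late_tau_uses_nearest_sample(self, clean_trial, geometry):
        L0 = resting_length_for_timing(clean_trial, geometry, 60.0)
        idx = int(np.searchsorted(clean_trial.stance_fraction, 0.60))
        assert L0 == pytest.approx(
            float(spring_length(clean_trial.ankle_angle[idx], geometry)),
            abs=1e-12)

    def test_matches_exhaustive_scan(self, clean_trial, geometry):
        """On a trial whose spring length is non-decreasing over [15%, 60%],
        the first length-crossing sample equals the first sample at tau."""
        s = clean_trial.stance_fraction
        L = spring_length(clean_trial.ankle_angle, geometry)
        band = (s >= 0.15) & (s <= 0.60)
        assert np.all(np.diff(L[band]) >= 0)
        for tau in (20.0, 35.0, 55.0):
            L0 = resting_length_for_timing(clean_trial, geometry, tau)
            scan = next(i for i in range(len(s))
                        if s[i] >= 0.15 and L[i] >= L0 - 1e-12)
            assert scan == int(np.searchsorted(s, tau / 100.0))

    def test_resting_length_non_decreasing_in_tau(self, clean_trial, geometry):
        taus = np.arange(15.0, 60.1, 5.0)
        L0s = [resting_length_for_timing(clean_trial, geometry, t)
               for t in taus]
        assert np.all(np.diff(L0s) >= 0)

    def test_invalid_tau_and_coverage(self, clean_trial, geometry):
        with pytest.raises(ValueError):
            resting_length_for_timing(clean_trial, geometry, 10.0)
        with pytest.raises(ValueError):
            resting_length_for_timing(clean_trial, geometry, 65.0)

    def test_zero_force_before_engagement_for_all_grid_cells(
            self, clean_trial, geometry):
        s = clean_trial.stance_fraction
        for setting in build_grid():
            tau = setting.actuation_timing_tau
            fitted = setting.with_resting_length(
                resting_length_for_timing(clean_trial, geometry, tau))
            torque = spring_torque_series(clean_trial, geometry, fitted)
            assert np.all(torque[s < tau / 100.0] == 0.0)

    def test_torque_plantarflexion_positive_when_engaged(self, clean_trial,
                                                         geometry):
        setting = ExoSetting(8000.0, 15.0).with_resting_length(
            resting_length_for_timing(clean_trial, geometry, 15.0))
        torque = spring_torque_series(clean_trial, geometry, setting)
        assert np.all(torque >= 0.0)
        assert torque.max() > 0.0

    def test_disengaged_setting_produces_no_torque(self, clean_trial,
                                                   geometry):
        setting = ExoSetting(8000.0, 15.0, engaged=False)
        assert np.all(spring_torque_series(clean_trial, geometry, setting)
                      == 0.0)

    def test_elastic_bookkeeping_closes(self, clean_trial, geometry):
        """Energy released from engagement to the last sample equals energy
        stored at peak stretch minus residual stored energy."""
        setting = ExoSetting(12000.0, 20.0).with_resting_length(
            resting_length_for_timing(clean_trial, geometry, 20.0))
        theta = np.linspace(clean_trial.ankle_angle[clean_trial.events.foot_flat],
                            clean_trial.ankle_angle.max(), 2000001)
        L = spring_length(theta, geometry)
        E = spring_energy(L, setting.resting_length_L0, setting.stiffness_k)
        F = spring_force(L, setting.resting_length_L0, setting.stiffness_k)
        tq = spring_ankle_torque(theta, F, geometry)
        # mechanical work of the spring torque over the loading path equals
        # the stored-energy difference (fine grid; torque = dE/dtheta)
        work = np.trapezoid(tq, theta)
        assert abs(work - (E[-1] - E[0])) < 1e-9
        assert E[-1] > 0.0


class TestAddedMass:
    def test_zero_masses_zero_adjustment(self, clean_trial):
        g = ExoGeometry(bracket_mass_foot=0.0, bracket_mass_shank=0.0)
        assert np.all(added_mass_moments(clean_trial, g) == 0.0)

    def test_horizontal_segment_value(self, clean_trial):
        g = ExoGeometry(bracket_mass_foot=0.3, mass_lever_foot=0.1,
                        bracket_mass_shank=0.0)
        adj = added_mass_moments(clean_trial, g)
        idx = int(np.argmin(np.abs(clean_trial.ankle_angle)))
        assert adj[idx, 0] == pytest.approx(0.3 * 9.81 * 0.1, rel=1e-3)

    def test_matches_point_mass_oracle(self, clean_trial, geometry):
        adj = added_mass_moments(clean_trial, geometry)
        g = 9.81
        for i in (0, 17, 48, 90):
            th_a = clean_trial.ankle_angle[i]
            th_k = clean_trial.knee_angle[i]
            p_foot = geometry.mass_lever_foot * np.array(
                [np.cos(th_a), -np.sin(th_a)])
            p_shank = geometry.mass_lever_shank * np.array(
                [np.cos(th_k), -np.sin(th_k)])
            assert adj[i, 0] == pytest.approx(
                geometry.bracket_mass_foot * g * p_foot[0], abs=1e-12)
            assert adj[i, 1] == pytest.approx(
                geometry.bracket_mass_shank * g * p_shank[0], abs=1e-12)
            assert adj[i, 2] == 0.0
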