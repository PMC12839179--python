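"""Passive ankle exoskeleton: bracket geometry, spring, actuation timing.

The device is a foot bracket and a posterior shank bracket hinged at the
ankle axis, connected by a tension-only spring (spring + cable + delay
device). The spring runs between an attachment at radius ``foot_attach_r``
on the foot bracket and ``shank_attach_r`` on the shank bracket; the
included angle between the two attachment arms is ``attach_offset_angle``
at neutral ankle angle and opens with dorsiflexion, so dorsiflexion
stretches the spring and spring tension produces a plantarflexion torque.

Actuation timing is realized purely as a spring resting length: the delay
hardware is modeled by its computational effect (zero force until the
spring length first exceeds the resting length chosen for the requested
percent of stance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gait import GaitTrial

__all__ = [
    "ExoGeometry", "ExoSetting", "spring_length", "spring_moment_arm",
    "resting_length_for_timing", "spring_force", "spring_ankle_torque",
    "spring_energy", "spring_torque_series", "added_mass_moments",
    "GRAVITY", "STIFFNESS_RANGE", "TIMING_RANGE",
]

GRAVITY = 9.81  # m/s^2

#: Stiffness and timing ranges of the study grid (N/m, % of stance).
STIFFNESS_RANGE = (5500.0, 17500.0)
TIMING_RANGE = (15.0, 60.0)


@dataclass(frozen=True)
class ExoGeometry:
    """Bracket attachment geometry and added-mass model parameters.

    The defaults are declared package constants (the physical device is
    described only qualitatively): the shank attachment sits 0.30 m above
    the hinge on the posterior shank bracket, the foot attachment 0.20 m
    from the hinge on a posterior heel lever of the foot bracket, and the
    included angle at neutral ankle keeps the spring posterior to the
    hinge, with a near-constant moment arm of ~0.20 m, throughout stance.
    This places the device's rotational stiffness k*arm^2 for the 5.5 to
    17.5 kN/m spring grid in the range (~220 to 700 N*m/rad) spanned by
    clutched elastic ankle exoskeletons of this class. Bracket masses act as
    point masses at ``mass_lever_*`` from the respective joint in the
    quasi-static added-mass model.
    """

    shank_attach_r: float = 0.30
    foot_attach_r: float = 0.20
    attach_offset_angle: float = 0.86   # rad, ~49 deg at neutral ankle
    bracket_mass_foot: float = 1.10
    bracket_mass_shank: float = 0.60
    mass_lever_foot: float = 0.16
    mass_lever_shank: float = 0.08

    def __post_init__(self) -> None:
        if self.shank_attach_r <= 0 or self.foot_attach_r <= 0:
            raise ValueError("attachment radii must be positive")
        if self.bracket_mass_foot < 0 or self.bracket_mass_shank < 0:
            raise ValueError("bracket masses must be non-negative")


@dataclass(frozen=True)
class ExoSetting:
    """One grid cell: spring stiffness, actuation timing, derived resting
    length. ``engaged=False`` models the worn-but-never-actuated device."""

    stiffness_k: float
    actuation_timing_tau: float
    resting_length_L0: float | None = None
    engaged: bool = True

    def __post_init__(self) -> None:
        if self.stiffness_k <= 0:
            raise ValueError("stiffness must be positive")
        if self.resting_length_L0 is not None and self.resting_length_L0 <= 0:
            raise ValueError("resting length must be positive")

    def with_resting_length(self, L0: float) -> "ExoSetting":
        return replace(self, resting_length_L0=float(L0))


def spring_length(ankle_angle, geometry: ExoGeometry):
    """Distance between the two spring attachment points (law of cosines).

    The included angle is ``attach_offset_angle + ankle_angle`` with the
    dorsiflexion-positive ankle angle; smooth and strictly positive except
    in the degenerate collinear-overlap case.
    """
    gamma = geometry.attach_offset_angle + np.asarray(ankle_angle, float)
    r1, r2 = geometry.shank_attach_r, geometry.foot_attach_r
    return np.sqrt(np.maximum(r1 * r1 + r2 * r2 - 2 * r1 * r2 * np.cos(gamma),
                              0.0))


def spring_moment_arm(ankle_angle, geometry: ExoGeometry):
    """Perpendicular moment arm of the spring line of action about the
    hinge: dL/d(ankle angle) = r1 r2 sin(gamma) / L."""
    gamma = geometry.attach_offset_angle + np.asarray(ankle_angle, float)
    L = spring_length(ankle_angle, geometry)
    r1, r2 = geometry.shank_attach_r, geometry.foot_attach_r
    return np.where(L > 0, r1 * r2 * np.sin(gamma) / np.where(L > 0, L, 1.0),
                    0.0)


def resting_length_for_timing(trial: GaitTrial, geometry: ExoGeometry,
                              tau: float) -> float:
    """Resting length that makes the spring first engage at ``tau`` % stance.

    L0 is the spring length at the first sample with stance_fraction >=
    tau/100 of the trial's (pre-computed) ankle kinematics, so force is
    zero strictly before that sample.
    """
    if not (TIMING_RANGE[0] <= tau <= TIMING_RANGE[1]):
        raise ValueError(f"tau must be within {TIMING_RANGE}, got {tau}")
    s = trial.stance_fraction
    if s[0] > 0.15 or s[-1] < tau / 100.0:
        raise ValueError(f"trial does not cover stance fractions "
                         f"[0.15, {tau / 100.0}]")
    idx = int(np.searchsorted(s, tau / 100.0))
    return float(spring_length(trial.ankle_angle[idx], geometry))


def spring_force(length, L0: float, k: float):
    """Tension-only Hooke force: k*(length-L0) for length > L0, else 0.

    The spring attaches through a cable, which cannot push; ties at
    exactly L0 produce zero force.
    """
    if k <= 0:
        raise ValueError("stiffness must be positive")
    if L0 <= 0:
        raise ValueError("resting length must be positive")
    stretch = np.asarray(length, float) - L0
    return k * np.where(stretch > 0, stretch, 0.0)


def spring_ankle_torque(ankle_angle, force, geometry: ExoGeometry):
    """Plantarflexion-positive ankle torque of the spring tension."""
    force = np.asarray(force, float)
    if np.any(force < 0):
        raise ValueError("spring force must be non-negative")
    return force * spring_moment_arm(ankle_angle, geometry)


def spring_energy(length, L0: float, k: float):
    """Stored elastic energy 0.5*k*max(0, length-L0)^2 (path-independent)."""
    if k <= 0:
        raise ValueError("stiffness must be positive")
    stretch = np.maximum(np.asarray(length, float) - L0, 0.0)
    return 0.5 * k * stretch * stretch


def spring_torque_series(trial: GaitTrial, geometry: ExoGeometry,
                         setting: ExoSetting) -> np.ndarray:
    """Spring ankle-torque time series for one trial and grid cell.

    Derives L0 from the trial's kinematics when the setting does not carry
    one; an ``engaged=False`` setting (exoskeleton worn, never actuated)
    yields all zeros.
    """
    if not setting.engaged:
        return np.zeros(trial.n_samples)
    L0 = setting.resting_length_L0
    if L0 is None:
        L0 = resting_length_for_timing(trial, geometry,
                                       setting.actuation_timing_tau)
    L = spring_length(trial.ankle_angle, geometry)
    F = spring_force(L, L0, setting.stiffness_k)
    # the gravity-actuated delay hardware, reduced to its computational
    # effect: no force strictly before the engagement sample, even if the
    # early-stance plantarflexion dip stretches the cable past L0
    F = np.where(trial.stance_fraction
                 < setting.actuation_timing_tau / 100.0, 0.0, F)
    return np.asarray(spring_ankle_torque(trial.ankle_angle, F, geometry))


def added_mass_moments(trial: GaitTrial, geometry: ExoGeometry) -> np.ndarray:
    """Quasi-static gravitational moment increments from the bracket masses.

    Returns an (n, 3) array of additional (ankle, knee, hip) moments the
    muscles must produce. Each bracket is a point mass at its lever from
    the joint it loads (foot bracket about the ankle, shank bracket about
    the knee); the orientation factor is the cosine of the joint angle, so
    a horizontal segment gives the full m*g*lever moment. Zero masses give
    a zero adjustment; the inertial contribution is neglected.
    """
    adj = np.zeros((trial.n_samples, 3))
    g = GRAVITY
    adj[:, 0] = (geometry.bracket_mass_foot * g * geometry.mass_lever_foot
                 * np.cos(trial.ankle_angle))
    adj[:, 1] = (geometry.bracket_mass_shank * g * geometry.mass_lever_shank
                 * np.cos(trial.knee_angle))
    return adj
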