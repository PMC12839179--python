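"""Muscle metabolic energetics (Umberger-family heat + work partition).

Per-muscle metabolic rate is the sum of an activation/maintenance heat
rate, a shortening/lengthening heat rate (all mass-specific, scaled by
muscle mass) and the positive mechanical work rate of the fiber. Heat
coefficients follow the published empirical model family for human
muscle:

* activation + maintenance: (128*ft + 25) W/kg at full activation
  (25 W/kg for a pure slow-twitch muscle), scaled by activation^0.6 and,
  above optimal fiber length, by 0.4 + 0.6*f_L;
* shortening heat coefficient: 100/v̄max_slow (slow twitch, with
  v̄max_slow = v̄max/2.5) and 153/v̄max (fast twitch), scaled by
  activation^2; lengthening coefficient 4x the slow shortening
  coefficient, scaled by activation;
* an aerobic scaling factor of 1.5 multiplies all heat terms (steady
  walking is primarily aerobic);
* mechanical work rate = fiber force x fiber velocity when shortening;
  eccentric (negative) fiber work is excluded, its cost being carried by
  the lengthening heat term;
* the total rate is clamped at >= 0, and basal (resting) heat is
  excluded, so absolute energies are model-relative while energy
  *differences* between conditions are unaffected.

Total energy per foot contact is the trapezoidal time integral of each
ipsilateral muscle's rate over the simulation window, summed and
normalized by body mass (J/kg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .muscles import (MuscleParams, MuscleState, force_length,
                      muscle_kinematics)
from .redundancy import ActivationSolution
from .gait import GaitTrial

__all__ = [
    "UMBERGER", "EnergyResult", "metabolic_rate", "metabolic_rate_components",
    "integrate_energy", "total_energy", "trial_energy",
]

log = logging.getLogger(__name__)

#: Energetics coefficient table (documented in the module docstring).
UMBERGER = {
    "act_maint_slow": 25.0,     # W/kg at full activation, slow twitch
    "act_maint_fast_extra": 128.0,  # additional W/kg per unit fast fraction
    "activation_exponent": 0.6,
    "shortening_slow_numerator": 100.0,  # -> alpha_S(slow) = 100/v̄max_slow
    "shortening_fast_numerator": 153.0,  # -> alpha_S(fast) = 153/v̄max
    "slow_vmax_divisor": 2.5,   # v̄max_slow = v̄max / 2.5
    "lengthening_multiplier": 4.0,  # alpha_L = 4 * alpha_S(slow)
    "aerobic_scale": 1.5,
}


@dataclass
class EnergyResult:
    """Per-muscle energies (J) and body-mass-normalized total (J/kg)."""

    muscle_names: tuple[str, ...]
    per_muscle_energy: np.ndarray        # J
    heat_activation_maintenance: np.ndarray  # J
    heat_shortening_lengthening: np.ndarray  # J
    mechanical_work: np.ndarray          # J
    total_energy_per_kg: float           # J per kg body mass
    window: slice


def metabolic_rate_components(state: MuscleState, force, params: MuscleParams
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(activation+maintenance heat, shortening/lengthening heat, work)
    rates in W for a fiber state series; each heat term is >= 0."""
    a = np.asarray(state.activation, float)
    l = np.asarray(state.norm_fiber_length, float)
    v = np.asarray(state.norm_fiber_velocity, float)  # shortening +
    ft = params.fast_twitch_fraction
    U = UMBERGER
    S = U["aerobic_scale"]
    A = a ** U["activation_exponent"]

    h_am = (U["act_maint_slow"] + U["act_maint_fast_extra"] * ft) * A
    h_am = np.where(l > 1.0, h_am * (0.4 + 0.6 * force_length(l)), h_am)

    vmax_slow = params.v_max / U["slow_vmax_divisor"]
    alpha_s = (U["shortening_slow_numerator"] / vmax_slow * (1.0 - ft)
               + U["shortening_fast_numerator"] / params.v_max * ft)
    alpha_l = U["lengthening_multiplier"] * (U["shortening_slow_numerator"]
                                             / vmax_slow)
    h_short = alpha_s * v * a ** 2
    h_length = alpha_l * (-v) * a
    h_sl = np.where(v >= 0.0, h_short, h_length)
    h_sl = np.where(l > 1.0, h_sl * force_length(l), h_sl)

    fiber_vel = v * params.v_max * params.l_opt      # m/s, shortening +
    work = np.maximum(np.asarray(force, float) * fiber_vel, 0.0)

    mass = params.muscle_mass
    return (np.maximum(mass * S * h_am, 0.0),
            np.maximum(mass * S * h_sl, 0.0),
            work)


def metabolic_rate(state: MuscleState, force, params: MuscleParams):
    """Total metabolic rate (W), clamped at >= 0; zero at zero activation
    (basal rate excluded)."""
    h_am, h_sl, work = metabolic_rate_components(state, force, params)
    return np.maximum(h_am + h_sl + work, 0.0)


def integrate_energy(rate: np.ndarray, time: np.ndarray) -> float:
    """Trapezoidal integral of a metabolic-rate series (J)."""
    rate = np.asarray(rate, float)
    time = np.asarray(time, float)
    if rate.shape != time.shape:
        raise ValueError("rate and time series must have equal length")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    return float(np.trapezoid(rate, time))


def total_energy(per_muscle: list[float], muscles: list[MuscleParams],
                 side: str, subject_mass: float,
                 window: slice = slice(None)) -> EnergyResult:
    """Sum ipsilateral per-muscle energies and normalize by body mass.

    Muscles on the contralateral side are excluded from the sum.
    """
    if subject_mass <= 0:
        raise ValueError("subject mass must be positive")
    keep = [i for i, m in enumerate(muscles) if m.side == side]
    if not keep:
        log.warning("no ipsilateral muscles for side %s; total energy is 0",
                    side)
    names = tuple(muscles[i].name for i in keep)
    energies = np.array([per_muscle[i] for i in keep], float)
    return EnergyResult(
        muscle_names=names,
        per_muscle_energy=energies,
        heat_activation_maintenance=np.full(len(keep), np.nan),
        heat_shortening_lengthening=np.full(len(keep), np.nan),
        mechanical_work=np.full(len(keep), np.nan),
        total_energy_per_kg=float(energies.sum() / subject_mass),
        window=window,
    )


def trial_energy(trial: GaitTrial, solution: ActivationSolution,
                 muscles: list[MuscleParams]) -> EnergyResult:
    """Energy expenditure of one solved foot contact.

    Integrates each ipsilateral muscle's metabolic rate over the
    simulation window actually solved and reports the ipsilateral sum per
    kg body mass.
    """
    side_muscles = [m for m in muscles if m.side == trial.side]
    by_name = {m.name: m for m in side_muscles}
    if tuple(by_name) != solution.muscle_names:
        side_muscles = [by_name[n] for n in solution.muscle_names]

    nm = len(side_muscles)
    e_am = np.zeros(nm)
    e_sl = np.zeros(nm)
    e_w = np.zeros(nm)
    w = solution.window
    for i, params in enumerate(side_muscles):
        st = muscle_kinematics(trial, params)
        state = MuscleState(
            activation=solution.activations[:, i],
            norm_fiber_length=np.asarray(st.norm_fiber_length)[w],
            norm_fiber_velocity=np.asarray(st.norm_fiber_velocity)[w],
        )
        h_am, h_sl, work = metabolic_rate_components(
            state, solution.forces[:, i], params)
        e_am[i] = integrate_energy(h_am, solution.time)
        e_sl[i] = integrate_energy(h_sl, solution.time)
        e_w[i] = integrate_energy(work, solution.time)
    per_muscle = e_am + e_sl + e_w
    return EnergyResult(
        muscle_names=solution.muscle_names,
        per_muscle_energy=per_muscle,
        heat_activation_maintenance=e_am,
        heat_shortening_lengthening=e_sl,
        mechanical_work=e_w,
        total_energy_per_kg=float(per_muscle.sum() / trial.subject_mass),
        window=w,
    )
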