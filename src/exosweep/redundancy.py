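"""Static-optimization muscle redundancy solver.

At every time step of the simulation window the required sagittal joint
moments (net inverse-dynamics moments minus exoskeleton spring torque,
plus bracket added-mass adjustments) are distributed over the ipsilateral
muscles by the classical static-optimization program

    min  sum(a_i^2) + w * sum(r_j^2)
    s.t. sum_i F_i(a_i) * arm_ij + r_j = M_j,   0 <= a_i <= 1,

where forces are affine in activation under the rigid-tendon Hill model,
making each step a strictly convex box-constrained QP with a unique
minimizer. Reserve actuators r_j (penalized with weight w) guarantee
feasibility and flag settings whose moment demands exceed muscular
capacity instead of crashing the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import exo as _exo
from ._boxqp import solve_activation_qp
from .gait import GaitTrial
from .muscles import (JOINTS, MuscleParams, MuscleState, active_force_gain,
                      muscle_kinematics, passive_force)

__all__ = [
    "ActivationSolution", "required_moments", "solve_static_optimization",
    "solve_trial", "TrialDynamics", "DEFAULT_RESERVE_WEIGHT",
    "RESERVE_FEASIBLE_THRESHOLD",
]

#: Penalty weight on reserve (slack) joint actuators.
DEFAULT_RESERVE_WEIGHT = 1e3
#: A step whose reserve magnitude exceeds this (N·m) is flagged infeasible.
RESERVE_FEASIBLE_THRESHOLD = 2.0


@dataclass
class ActivationSolution:
    """Per-step activations/forces over the simulation window."""

    time: np.ndarray                 # (nt,)
    activations: np.ndarray          # (nt, nm), in [0, 1]
    forces: np.ndarray               # (nt, nm), N (incl. passive)
    reserve_moments: np.ndarray      # (nt, 3), N·m
    objective: np.ndarray            # (nt,), sum a^2 per step
    feasible: np.ndarray             # (nt,) bool
    muscle_names: tuple[str, ...]
    window: slice                    # indices into the parent trial


def required_moments(trial: GaitTrial, exo_torque: np.ndarray | None = None,
                     mass_adjustment: np.ndarray | None = None) -> np.ndarray:
    """(n, 3) joint moments the muscles must produce.

    Ankle requirement = net ankle moment - exoskeleton plantarflexion
    torque + added-mass adjustment; knee/hip = net moment + adjustment.
    Negative requirements pass through unchanged (antagonists resist).
    """
    req = trial.net_moments().copy()
    if exo_torque is not None:
        exo_torque = np.asarray(exo_torque, float)
        if exo_torque.shape[0] != trial.n_samples:
            raise ValueError("exo torque series must share the trial grid")
        req[:, 0] -= exo_torque
    if mass_adjustment is not None:
        mass_adjustment = np.asarray(mass_adjustment, float)
        if mass_adjustment.shape != req.shape:
            raise ValueError("mass adjustment must be (n, 3)")
        req += mass_adjustment
    return req


def solve_static_optimization(required: np.ndarray, states: list[MuscleState],
                              params: list[MuscleParams],
                              reserve_weight: float = DEFAULT_RESERVE_WEIGHT,
                              q: np.ndarray | None = None) -> dict:
    """Solve one time step; ``states`` hold scalar fiber states.

    ``q`` gives the moment-aligned joint coordinates for angle-dependent
    moment arms (defaults to zeros). Returns a dict with activations,
    forces, reserves, objective and the feasibility flag.
    """
    if not params:
        raise ValueError("muscle set is empty")
    required = np.asarray(required, float)
    q = np.zeros(3) if q is None else np.asarray(q, float)

    nm = len(params)
    G = np.zeros((3, nm))
    passive = np.zeros(3)
    gains = np.zeros(nm)
    f_pass = np.zeros(nm)
    for i, (st, p) in enumerate(zip(states, params)):
        gains[i] = float(np.asarray(active_force_gain(st, p)))
        f_pass[i] = (p.f_max * float(passive_force(st.norm_fiber_length))
                     * np.cos(p.pennation))
        for j, joint in enumerate(JOINTS):
            if p.spans(joint):
                arm = float(p.moment_arm(joint, q[j]))
                G[j, i] = gains[i] * arm
                passive[j] += f_pass[i] * arm

    b = required - passive
    a = solve_activation_qp(G, b, reserve_weight)
    reserves = b - G @ a
    return {
        "activations": a,
        "forces": a * gains + f_pass,
        "reserves": reserves,
        "objective": float(a @ a),
        "feasible": bool(np.all(np.abs(reserves) <= RESERVE_FEASIBLE_THRESHOLD)),
    }


class TrialDynamics:
    """Setting-independent precomputation for one trial.

    Fiber states, activation-to-moment gain matrices, passive moments and
    the QP normal matrices depend only on the trial's kinematics, so a
    sweep builds them once per foot contact and re-solves only for the
    changing required-moment series.
    """

    def __init__(self, trial: GaitTrial, muscles: list[MuscleParams],
                 reserve_weight: float = DEFAULT_RESERVE_WEIGHT):
        self.trial = trial
        self.reserve_weight = float(reserve_weight)
        self.muscles = [m for m in muscles if m.side == trial.side]
        if not self.muscles:
            raise ValueError("muscle set is empty for side " + trial.side)
        self.window = trial.window_slice()
        self.time = trial.time[self.window]
        nt = self.time.size
        nm = len(self.muscles)

        self.states = [muscle_kinematics(trial, m) for m in self.muscles]
        q_all = -trial.angles()
        w = self.window
        self.norm_len = np.column_stack(
            [np.asarray(st.norm_fiber_length)[w] for st in self.states])
        self.norm_vel = np.column_stack(
            [np.asarray(st.norm_fiber_velocity)[w] for st in self.states])
        self.gains = np.column_stack(
            [np.asarray(active_force_gain(st, m))[w]
             for st, m in zip(self.states, self.muscles)])
        self.f_passive = np.column_stack(
            [(m.f_max * passive_force(np.asarray(st.norm_fiber_length)[w])
              * np.cos(m.pennation))
             for st, m in zip(self.states, self.muscles)])

        # arm[t, j, i] for the window; zero where the muscle does not span j.
        self.arms = np.zeros((nt, 3, nm))
        for i, m in enumerate(self.muscles):
            for j, joint in enumerate(JOINTS):
                if m.spans(joint):
                    self.arms[:, j, i] = m.moment_arm(joint, q_all[w, j])
        self.G = self.arms * self.gains[:, None, :]
        self.passive_moments = np.einsum("tji,ti->tj", self.arms,
                                         self.f_passive)
        eye = np.eye(nm)
        self.H = eye[None] + self.reserve_weight * np.einsum(
            "tji,tjk->tik", self.G, self.G)

    def solve(self, required: np.ndarray) -> ActivationSolution:
        """Distribute a (nt, 3) required-moment series (window grid)."""
        nt, nm = self.gains.shape
        required = np.asarray(required, float)
        if required.shape != (nt, 3):
            raise ValueError(f"required moments must be {(nt, 3)}")
        b = required - self.passive_moments
        acts = np.empty((nt, nm))
        for t in range(nt):
            acts[t] = solve_activation_qp(self.G[t], b[t],
                                          self.reserve_weight, H=self.H[t])
        reserves = b - np.einsum("tji,ti->tj", self.G, acts)
        return ActivationSolution(
            time=self.time,
            activations=acts,
            forces=acts * self.gains + self.f_passive,
            reserve_moments=reserves,
            objective=np.einsum("ti,ti->t", acts, acts),
            feasible=np.all(np.abs(reserves) <= RESERVE_FEASIBLE_THRESHOLD,
                            axis=1),
            muscle_names=tuple(m.name for m in self.muscles),
            window=self.window,
        )

    def required_for(self, setting: _exo.ExoSetting | None,
                     geometry: _exo.ExoGeometry | None) -> np.ndarray:
        """Window-sliced required moments for one condition.

        ``setting=None`` with ``geometry=None`` is unassisted baseline (no
        torque, no bracket mass); ``setting=None`` with a geometry applies
        bracket mass only (worn, no spring); otherwise both.
        """
        trial = self.trial
        torque = None
        adjustment = None
        if geometry is not None:
            adjustment = _exo.added_mass_moments(trial, geometry)
            if setting is not None:
                torque = _exo.spring_torque_series(trial, geometry, setting)
        return required_moments(trial, torque, adjustment)[self.window]


def solve_trial(trial: GaitTrial, exo_setting: _exo.ExoSetting | None,
                geometry: _exo.ExoGeometry | None,
                muscles: list[MuscleParams],
                reserve_weight: float = DEFAULT_RESERVE_WEIGHT
                ) -> ActivationSolution:
    """Solve the simulation window of one foot contact.

    The window runs from 15% of stance (foot flat) to the maximum
    plantarflexion after toe off; only ipsilateral-leg muscles are
    recruited. ``exo_setting=None`` solves the unassisted condition; pass
    a geometry with ``exo_setting=None`` for the worn-but-unactuated
    condition.
    """
    dyn = TrialDynamics(trial, muscles, reserve_weight)
    return dyn.solve(dyn.required_for(exo_setting, geometry))
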