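"""Hill-type muscle set and muscle-joint kinematics (rigid tendon).

Eight sagittal-plane muscles per leg (soleus, medial/lateral
gastrocnemius, tibialis anterior, vasti, rectus femoris, hamstrings,
gluteus maximus) carry the ankle-assistance mechanics the exoskeleton
sweep probes. Parameters ship as package data (``data/muscles.csv``) and
are scaled to the subject (forces with mass, lengths with height).

Sign conventions. Moment arms are stored in *moment-aligned* joint
coordinates q: ankle plantarflexion-positive, knee and hip
extension-positive (q = -angle for the trial's dorsiflexion/flexion
-positive angles). In these coordinates a muscle's joint torque is simply
force x arm in the same convention as the trial's net moments, and the
path identity arm(q) = -dL/dq holds, so musculotendon length change is
-∫ arm dq. Plantarflexor ankle arms are positive, the tibialis anterior's
negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .gait import GaitTrial

__all__ = [
    "JOINTS", "MuscleParams", "MuscleState", "default_muscle_set",
    "muscle_kinematics", "muscle_force", "force_length", "force_velocity",
    "passive_force", "SPECIFIC_TENSION", "MUSCLE_DENSITY",
    "BASE_SUBJECT_MASS", "BASE_SUBJECT_HEIGHT",
]

JOINTS = ("ankle", "knee", "hip")

#: Specific tension (N/m^2) and density (kg/m^3) used to derive muscle mass
#: from f_max and l_opt for the energetics model.
SPECIFIC_TENSION = 2.5e5
MUSCLE_DENSITY = 1059.7

#: Subject the parameter table is written for.
BASE_SUBJECT_MASS = 75.0
BASE_SUBJECT_HEIGHT = 1.75

# Force-length / force-velocity curve shape constants.
_FL_WIDTH = 0.45          # Gaussian width of the active force-length curve
_FV_AF = 0.30             # Hill force-velocity curvature (concentric)
_FV_ECC_SLOPE = 4.0       # eccentric rise rate
_FV_ECC_MAX = 1.5         # eccentric force plateau
_PASSIVE_STRAIN = 0.70    # passive curve reaches f_max at ~70% fiber strain


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type and energetic parameters for one muscle of one leg."""

    name: str
    side: str
    f_max: float                 # N, max isometric force (subject-scaled)
    l_opt: float                 # m, optimal fiber length
    tendon_slack: float          # m (rigid tendon: fixed at this length)
    v_max: float                 # optimal fiber lengths per second
    pennation: float             # rad
    fast_twitch_fraction: float
    muscle_mass: float           # kg, from f_max/l_opt via specific tension
    ref_norm_fiber_length: float
    moment_arm_coeffs: tuple     # ((c0, c1) per joint) in q coordinates

    def __post_init__(self) -> None:
        if min(self.f_max, self.l_opt, self.v_max, self.muscle_mass) <= 0:
            raise ValueError(f"{self.name}: non-positive parameter")
        if not 0.0 <= self.fast_twitch_fraction <= 1.0:
            raise ValueError(f"{self.name}: fast_twitch_fraction outside [0,1]")

    def spans(self, joint: str) -> bool:
        c0, c1 = self.moment_arm_coeffs[JOINTS.index(joint)]
        return c0 != 0.0 or c1 != 0.0

    def moment_arm(self, joint: str, q: float | np.ndarray):
        """Moment arm (m) at moment-aligned joint coordinate q."""
        c0, c1 = self.moment_arm_coeffs[JOINTS.index(joint)]
        return c0 + c1 * np.asarray(q, float)


@dataclass
class MuscleState:
    """Fiber state series for Hill/energetics evaluation."""

    activation: np.ndarray | float      # in [0, 1]
    norm_fiber_length: np.ndarray | float   # l / l_opt
    norm_fiber_velocity: np.ndarray | float  # v / (v_max l_opt), shortening +


def _load_table() -> pd.DataFrame:
    text = resources.files("exosweep").joinpath("data/muscles.csv").read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def default_muscle_set(subject_mass: float = 87.6,
                       subject_height: float = 1.86) -> list[MuscleParams]:
    """Both-leg muscle set scaled to the subject.

    f_max scales linearly with body mass and lengths with height relative
    to the base subject of the shipped table; moment arms are left
    unscaled. Returns 16 muscles (8 per side), left side first.
    """
    if subject_mass <= 0 or subject_height <= 0:
        raise ValueError("subject mass and height must be positive")
    mass_scale = subject_mass / BASE_SUBJECT_MASS
    len_scale = subject_height / BASE_SUBJECT_HEIGHT
    table = _load_table()
    muscles = []
    for side in ("left", "right"):
        for row in table.itertuples(index=False):
            f_max = row.f_max * mass_scale
            l_opt = row.l_opt * len_scale
            muscles.append(MuscleParams(
                name=row.name, side=side, f_max=f_max, l_opt=l_opt,
                tendon_slack=row.tendon_slack * len_scale, v_max=row.v_max,
                pennation=np.radians(row.pennation_deg),
                fast_twitch_fraction=row.fast_twitch_fraction,
                muscle_mass=MUSCLE_DENSITY * l_opt * f_max / SPECIFIC_TENSION,
                ref_norm_fiber_length=row.ref_norm_fiber_length,
                moment_arm_coeffs=(
                    (row.arm_ankle_c0, row.arm_ankle_c1),
                    (row.arm_knee_c0, row.arm_knee_c1),
                    (row.arm_hip_c0, row.arm_hip_c1),
                ),
            ))
    return muscles


def path_length_change(params: MuscleParams, q: np.ndarray) -> np.ndarray:
    """Musculotendon length change from the neutral posture, -∫ arm dq
    summed over spanned joints; closed form for the linear arm polynomials."""
    q = np.atleast_2d(q)
    dL = np.zeros(q.shape[0])
    for j in range(len(JOINTS)):
        c0, c1 = params.moment_arm_coeffs[j]
        dL -= c0 * q[:, j] + 0.5 * c1 * q[:, j] ** 2
    return dL


def muscle_kinematics(trial: GaitTrial, params: MuscleParams) -> MuscleState:
    """Rigid-tendon fiber length/velocity series for one muscle.

    The tendon stays at slack length, so the whole musculotendon length
    change is taken up by the fiber (divided by cos pennation). Velocity
    is the sampled derivative of the fiber-length series, shortening
    positive. Activation is left unset (zeros).
    """
    q = -np.column_stack([trial.ankle_angle, trial.knee_angle,
                          trial.hip_angle])  # moment-aligned coordinates
    dL = path_length_change(params, q)
    fiber = params.ref_norm_fiber_length * params.l_opt + dL / np.cos(params.pennation)
    if np.any(fiber <= 0):
        raise ValueError(f"degenerate geometry: non-positive fiber length "
                         f"for muscle {params.name}")
    vel = np.gradient(fiber, trial.time)          # m/s, lengthening +
    return MuscleState(
        activation=np.zeros(trial.n_samples),
        norm_fiber_length=fiber / params.l_opt,
        norm_fiber_velocity=-vel / (params.v_max * params.l_opt),
    )


def force_length(norm_length):
    """Active force-length curve: Gaussian with maximum 1 at l/l_opt = 1."""
    x = np.asarray(norm_length, float) - 1.0
    return np.exp(-(x / _FL_WIDTH) ** 2)


def force_velocity(norm_velocity):
    """Hill force-velocity curve, shortening-positive normalized velocity.

    f_V(0) = 1 and f_V(1) = 0 concentrically; eccentric force rises to a
    plateau of 1.5.
    """
    v = np.asarray(norm_velocity, float)
    conc = np.where(v < 1.0, (1.0 - v) / (1.0 + np.abs(v) / _FV_AF), 0.0)
    ecc = (1.0 - _FV_ECC_MAX * _FV_ECC_SLOPE * v) / (1.0 - _FV_ECC_SLOPE * v)
    return np.where(v >= 0.0, conc, np.minimum(ecc, _FV_ECC_MAX))


def passive_force(norm_length):
    """Passive elastic fiber force, normalized to f_max (gentle cubic toe)."""
    x = np.maximum(np.asarray(norm_length, float) - 1.0, 0.0)
    return (x / _PASSIVE_STRAIN) ** 3


def active_force_gain(state: MuscleState, params: MuscleParams):
    """dF/d(activation): f_max * f_L * f_V * cos(pennation) (N)."""
    return (params.f_max * force_length(state.norm_fiber_length)
            * force_velocity(state.norm_fiber_velocity)
            * np.cos(params.pennation))


def muscle_force(state: MuscleState, params: MuscleParams,
                 include_passive: bool = True):
    """Tendon-direction muscle force for a given state.

    force = a * f_max * f_L(l) * f_V(v) * cos(pennation) + passive term.
    """
    a = np.asarray(state.activation, float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation outside [0, 1]")
    force = a * active_force_gain(state, params)
    if include_passive:
        force = force + (params.f_max * passive_force(state.norm_fiber_length)
                         * np.cos(params.pennation))
    return force
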