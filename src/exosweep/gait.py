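"""Synthetic stance-phase gait trials.

Generates single-subject walking trials (sagittal joint angles and net
joint moments for ankle, knee and hip) with the statistical structure a
stiffness/timing exoskeleton sweep needs: a normative, band-limited
waveform per signal plus seeded trial-to-trial amplitude and phase
perturbations.

Conventions
-----------
* ``stance_fraction`` is 0 at heel strike and 1 at toe off; samples after
  toe off carry values > 1 up to the maximum plantarflexion angle of the
  push-off tail, so the whole simulation window lives in one coordinate.
* Angles are radians: ankle dorsiflexion-positive, knee and hip
  flexion-positive.
* Net moments are N·m: ankle plantarflexion-positive, knee and hip
  extension-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "GaitEvents",
    "GaitTrial",
    "generate_trial",
    "generate_cohort",
    "DEFAULT_SPEED",
    "DEFAULT_STANCE_DURATION",
    "DEFAULT_NOISE_SD",
    "STANCE_TAIL_FRACTION",
]

#: Reference walking speed (m/s) at which the normative waveforms are defined.
DEFAULT_SPEED = 1.25
#: Default stance duration in seconds (order of a 100 Hz capture, ~1 s stance).
DEFAULT_STANCE_DURATION = 0.65
#: Default trial-to-trial waveform perturbation (fractional amplitude SD).
DEFAULT_NOISE_SD = 0.005
#: Trials extend past toe off (stance_fraction 1.0) to this value so the
#: post-toe-off maximum plantarflexion is always inside the sampled window.
STANCE_TAIL_FRACTION = 1.15

# Normative stance waveforms as (stance_fraction, value) control points of a
# cubic spline. Shapes follow textbook adult overground walking: brief
# plantarflexion after heel strike, progressive dorsiflexion to a
# mid-to-late-stance peak, rapid plantarflexion through toe off; the net
# ankle moment is single-peaked plantarflexion, maximal in late stance,
# with the usual small dorsiflexor moment during loading response and a
# low shoulder through foot-flat. Moments are in N·m per kg body mass and
# are scaled by subject mass (and mildly by speed) at generation time.
_ANKLE_ANGLE_PTS = (
    (0.00, 0.000), (0.07, -0.080), (0.15, -0.050), (0.20, 0.020),
    (0.25, 0.090), (0.30, 0.140), (0.35, 0.155), (0.40, 0.162),
    (0.45, 0.166), (0.55, 0.172), (0.65, 0.177), (0.72, 0.180),
    (0.80, 0.155), (0.88, 0.040), (0.95, -0.150), (1.00, -0.280),
    (1.05, -0.380), (1.10, -0.420), (1.15, -0.410),
)
_ANKLE_MOMENT_PTS = (
    (0.00, 0.000), (0.05, -0.100), (0.10, -0.040), (0.13, 0.020),
    (0.15, 0.120), (0.20, 0.250), (0.25, 0.320), (0.30, 0.370),
    (0.35, 0.400), (0.40, 0.430), (0.45, 0.450), (0.50, 0.480),
    (0.55, 0.560), (0.62, 0.780), (0.70, 1.150), (0.78, 1.380),
    (0.85, 1.150), (0.92, 0.600), (1.00, 0.000), (1.05, -0.020),
    (1.10, -0.020), (1.15, -0.010),
)
_KNEE_ANGLE_PTS = (
    (0.00, 0.090), (0.15, 0.280), (0.30, 0.300), (0.45, 0.220),
    (0.60, 0.130), (0.75, 0.100), (0.85, 0.150), (1.00, 0.420),
    (1.10, 0.650), (1.15, 0.720),
)
_KNEE_MOMENT_PTS = (
    (0.00, -0.050), (0.10, 0.250), (0.20, 0.480), (0.30, 0.400),
    (0.45, 0.150), (0.60, -0.060), (0.75, -0.160), (0.85, -0.200),
    (0.95, -0.100), (1.00, 0.000), (1.15, 0.000),
)
_HIP_ANGLE_PTS = (
    (0.00, 0.520), (0.20, 0.400), (0.40, 0.220), (0.60, 0.020),
    (0.80, -0.120), (0.95, -0.100), (1.05, 0.020), (1.15, 0.150),
)
_HIP_MOMENT_PTS = (
    (0.00, 0.300), (0.10, 0.620), (0.25, 0.450), (0.40, 0.180),
    (0.55, -0.150), (0.70, -0.440), (0.85, -0.620), (0.95, -0.350),
    (1.00, -0.120), (1.10, 0.000), (1.15, 0.000),
)

_ANGLE_SIGNALS = ("ankle_angle", "knee_angle", "hip_angle")
_MOMENT_SIGNALS = ("ankle_moment", "knee_moment", "hip_moment")
_WAVEFORM_PTS = {
    "ankle_angle": _ANKLE_ANGLE_PTS,
    "knee_angle": _KNEE_ANGLE_PTS,
    "hip_angle": _HIP_ANGLE_PTS,
    "ankle_moment": _ANKLE_MOMENT_PTS,
    "knee_moment": _KNEE_MOMENT_PTS,
    "hip_moment": _HIP_MOMENT_PTS,
}

_SPLINES = {
    name: CubicSpline([p[0] for p in pts], [p[1] for p in pts], bc_type="natural")
    for name, pts in _WAVEFORM_PTS.items()
}


@dataclass(frozen=True)
class GaitEvents:
    """Sample indices of the stance events used to window the simulation."""

    heel_strike: int
    foot_flat: int          # first sample at >= 15% of stance
    toe_off: int            # first sample at >= 100% of stance
    max_plantarflexion: int  # ankle-angle minimum of the push-off tail


@dataclass
class GaitTrial:
    """One foot contact: uniformly sampled stance-phase kinematics/kinetics."""

    time: np.ndarray
    stance_fraction: np.ndarray
    ankle_angle: np.ndarray
    knee_angle: np.ndarray
    hip_angle: np.ndarray
    ankle_moment: np.ndarray
    knee_moment: np.ndarray
    hip_moment: np.ndarray
    side: str
    subject_mass: float
    subject_height: float
    events: GaitEvents = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(self.stance_fraction) < 0):
            raise ValueError("stance_fraction must be non-decreasing")
        for name in _ANGLE_SIGNALS:
            if np.any(np.abs(getattr(self, name)) >= np.pi / 2):
                raise ValueError(f"{name} outside +/- pi/2")
        if self.events is None:
            self.events = locate_events(self.stance_fraction, self.ankle_angle)
        ev = self.events
        if not (ev.heel_strike < ev.foot_flat < ev.toe_off < ev.max_plantarflexion):
            raise ValueError("events must be ordered heel strike < foot flat < "
                             "toe off < max plantarflexion")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def angles(self) -> np.ndarray:
        """(n, 3) array of ankle/knee/hip angles."""
        return np.column_stack([self.ankle_angle, self.knee_angle, self.hip_angle])

    def net_moments(self) -> np.ndarray:
        """(n, 3) array of ankle/knee/hip net moments."""
        return np.column_stack([self.ankle_moment, self.knee_moment, self.hip_moment])

    def window_slice(self) -> slice:
        """Simulation window: foot flat (15% stance) through maximum
        plantarflexion after toe off, inclusive."""
        return slice(self.events.foot_flat, self.events.max_plantarflexion + 1)


def locate_events(stance_fraction: np.ndarray, ankle_angle: np.ndarray) -> GaitEvents:
    """Derive the four stance events from sampled data.

    Maximum plantarflexion is the ankle-angle minimum over the post-toe-off
    tail (the waveform minimum over the simulated window).
    """
    s = np.asarray(stance_fraction)
    foot_flat = int(np.searchsorted(s, 0.15))
    toe_off = int(np.searchsorted(s, 1.0))
    tail = np.asarray(ankle_angle)[toe_off:]
    if tail.size == 0:
        raise ValueError("trial does not extend past toe off")
    max_pf = toe_off + int(np.argmin(tail))
    return GaitEvents(0, foot_flat, toe_off, max_pf)


def _moment_speed_scale(speed: float) -> float:
    # Net moments grow mildly with speed around the normative 1.25 m/s.
    return 1.0 + 0.3 * (speed - DEFAULT_SPEED) / DEFAULT_SPEED


def generate_trial(
    speed: float = DEFAULT_SPEED,
    stance_duration: float = DEFAULT_STANCE_DURATION,
    subject_mass: float = 87.6,
    subject_height: float = 1.86,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    n_samples: int = 100,
    side: str = "left",
) -> GaitTrial:
    """Generate one synthetic foot contact.

    The trial spans heel strike to just past the post-toe-off maximum
    plantarflexion (stance_fraction 0 to 1.15) on a uniform time grid of
    ``n_samples`` points. Each of the six waveforms receives an independent
    multiplicative amplitude factor ~ Normal(1, noise_sd) and an additive
    phase shift ~ Normal(0, noise_sd * stance_duration / 10); identical
    arguments with an identical seed are bit-reproducible.
    """
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    if n_samples < 50:
        raise ValueError("n_samples must be at least 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, STANCE_TAIL_FRACTION, n_samples)
    time = s * stance_duration
    m_scale = subject_mass * _moment_speed_scale(speed)

    signals = {}
    for name in _ANGLE_SIGNALS + _MOMENT_SIGNALS:
        amp = 1.0 + noise_sd * rng.standard_normal()
        phase_t = rng.normal(0.0, noise_sd * stance_duration / 10.0)
        s_eval = np.clip(s - phase_t / stance_duration, 0.0, STANCE_TAIL_FRACTION)
        base = _SPLINES[name](s_eval)
        scale = amp if name in _ANGLE_SIGNALS else amp * m_scale
        signals[name] = base * scale

    return GaitTrial(
        time=time,
        stance_fraction=s,
        ankle_angle=signals["ankle_angle"],
        knee_angle=signals["knee_angle"],
        hip_angle=signals["hip_angle"],
        ankle_moment=signals["ankle_moment"],
        knee_moment=signals["knee_moment"],
        hip_moment=signals["hip_moment"],
        side=side,
        subject_mass=subject_mass,
        subject_height=subject_height,
    )


def generate_cohort(
    n_contacts: int = 10,
    base_params: dict | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> list[GaitTrial]:
    """Generate a balanced cohort of foot contacts (alternating left/right).

    Each trial draws its perturbations from an independent child stream of
    the single cohort seed, so the cohort is reproducible as a whole while
    trials differ pairwise whenever ``noise_sd > 0``.
    """
    if n_contacts < 2 or n_contacts % 2 != 0:
        raise ValueError("n_contacts must be even and >= 2")
    params = dict(base_params or {})
    params.pop("noise_sd", None)
    params.pop("seed", None)
    params.pop("side", None)

    trials = []
    for i in range(n_contacts):
        child_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
                         % (2 ** 31))
        side = "left" if i % 2 == 0 else "right"
        trials.append(generate_trial(noise_sd=noise_sd, seed=child_seed,
                                     side=side, **params))
    return trials
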