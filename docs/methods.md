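# Methods

This note records the models behind `exosweep`, the parameters that
matter, the design choices that were genuinely open, and what the
synthetic data do and do not establish.

## Simulation window and conventions

Each foot contact is simulated from 15% of stance (foot flat) to the
maximum plantarflexion angle after toe off, sampled on a uniform time
grid (default 100 samples spanning stance fractions 0–1.15 of a 0.65 s
stance). Using this window keeps exactly one spring loading/unloading
cycle in view and excludes swing. Angles are radians, dorsiflexion- and
flexion-positive; net moments are N·m, plantarflexion- and
extension-positive. Internally the muscle-path machinery works in
"moment-aligned" coordinates q = −angle so that moment arm = −∂L/∂q and
joint torque = force × arm hold in the same convention as the net
moments; plantarflexor ankle arms are positive and the tibialis
anterior's is negative.

## Synthetic gait generator

Six normative waveforms (three angles, three moments) are cubic splines
through fixed control points; moments are per-kg and scale with subject
mass (and mildly with speed). Trial-to-trial variability multiplies each
waveform by an amplitude factor ~ N(1, σ) and shifts its phase by
~ N(0, σ·T/10), independently per waveform, from one seeded stream per
trial; a cohort draws child seeds from a single cohort seed and
alternates left/right labels.

The waveform shapes are normative adult overground walking, with two
features chosen deliberately because the device physics depends on them:

* dorsiflexion excursion is concentrated between 15% and 35% of stance
  and plateaus afterwards (≈ +0.14 rad by 30%, peak 0.18 rad at ~72%).
  Consequently a spring engaging early captures nearly the whole
  excursion while a spring engaging after ~40% finds almost no stretch
  left — late actuation timings are nearly inert, and energy change
  becomes insensitive to stiffness there;
* the net ankle moment has the usual dorsiflexor dip during loading
  response, a mid-stance shoulder of ~0.3–0.5 N·m/kg, and a late-stance
  push-off peak of ~1.4 N·m/kg. The mid-stance shoulder sets where an
  over-stiff spring's torque overshoots the requirement.

Default noise σ = 0.005. This is deliberately smaller than the 5–7%
stride-to-stride variability of real gait: the study design this package
emulates resolves ~1% between-condition energy differences across 10
contacts with an *unpaired* one-way ANOVA, which presupposes
within-condition repeatability at the sub-percent scale. The generator
reproduces that effective repeatability rather than raw biological
variability; with realistic σ the same contrasts would require a paired
analysis. This is the main respect in which passing tests do not speak
to real data.

## Exoskeleton model

The device is a foot bracket and posterior shank bracket hinged at the
ankle, connected by a spring + cable + gravity-actuated delay device.
Only the computational effect of the delay hardware is modeled: zero
spring force strictly before the engagement sample. The spring is
tension-only (a cable cannot push), Hookean above its resting length,
with stored energy ½k·max(0, L−L0)².

Geometry defaults (declared package constants — the physical device is
described only qualitatively): shank attachment 0.30 m above the hinge,
foot attachment 0.20 m behind it on a posterior heel lever, included
angle 0.86 rad at neutral ankle. This yields a near-constant spring
moment arm ≈ 0.20 m and hence rotational stiffnesses k·r² ≈ 220–700
N·m/rad across the 5.5–17.5 kN/m grid — the operating range of clutched
elastic ankle exoskeletons of this class, and large enough that the
stiff end of the grid over-assists mid-stance. A much shorter foot lever
(e.g. 0.10 m) would cap the device at ~45–140 N·m/rad, where stiffer
springs are monotonically beneficial and no interior structure exists;
this is why the heel-lever radius is a load-bearing constant.

Actuation timing τ maps to resting length by trigonometry on the
trial's own (pre-computed) kinematics: L0 equals the spring length at
the first sample with stance fraction ≥ τ/100, so longer resting
lengths give later timings.

Bracket masses (foot 1.10 kg including spring and delay wheel, shank
0.60 kg) enter as quasi-static gravitational moment increments
m·g·lever·cos(joint angle) at the ankle and knee. The model omits the
inertial cost of accelerating the added distal mass, so the worn-device
penalty (~+0.7% here vs ~+1% reported for comparable hardware) is a
lower bound.

## Muscles and redundancy

Eight sagittal muscles per leg: soleus, medial/lateral gastrocnemius,
tibialis anterior, vasti, rectus femoris, hamstrings, gluteus maximus.
`tib_ant` carries the whole dorsiflexor compartment (TA+EDL+EHL,
f_max 1550 N) and `rect_fem` the hip-flexor compartment (1800 N), so the
eight actuators can balance all three sagittal moments. Forces scale
linearly with body mass, lengths with height. Tendons are rigid; fiber
velocity therefore absorbs the whole musculotendon velocity, compensated
by v_max = 12 l_opt/s. Moment arms are linear polynomials of joint
angle. Active force–length is a Gaussian (width 0.45) peaking at 1;
force–velocity is a Hill hyperbola (curvature 0.3) with eccentric
plateau 1.5; the passive curve is a gentle cubic in fiber strain.

Per time step, activations solve

    min Σ aᵢ² + w Σ rⱼ²   s.t.   Σᵢ Fᵢ(aᵢ)·armᵢⱼ + rⱼ = Mⱼ,  0 ≤ aᵢ ≤ 1

with reserve weight w = 10³ (N·m)⁻²-scale penalty. Forces are affine in
activation under the rigid tendon, so each step is a strictly convex
box-constrained QP solved by a small primal active-set method (with a
bounded-least-squares fallback); the matrices that depend only on
kinematics are precomputed once per trial and reused across all 250 grid
cells, which is what keeps a 2,500-simulation sweep under a minute.
Steps whose reserve magnitude exceeds 2 N·m are flagged infeasible
rather than failing; with the default model this occurs only in late
push-off, where the biarticular coupling saturates (see limitations).

Why over-stiff springs cost energy here, with kinematics prescribed:
once spring torque exceeds the required ankle moment, the surplus must
be resisted by dorsiflexor activation, and recruiting a muscle from rest
is metabolically expensive (the a^0.6 heat term has unbounded slope at
zero) while the offloaded plantarflexors save at a much lower marginal
rate. A second, subtler channel acts during push-off: the late-stance
hip-flexion demand pins rectus femoris, whose knee-extension side effect
must be countered by gastrocnemius knee flexion, whose ankle
plantarflexion surplus — once the spring has already unloaded the
ankle — must be countered by tibialis anterior. Both channels grow
superlinearly with stiffness; together with the saturating relief they
produce the interior structure of the sweep (global minimum at the
earliest timing and lowest stiffness, energy cost above baseline
everywhere at 17.5 kN/m).

## Energetics

Per-muscle metabolic rate = muscle mass × (activation/maintenance heat +
shortening/lengthening heat) + positive fiber work rate, with
coefficients from the published empirical model family: activation +
maintenance (25 + 128·ft) W/kg scaled by a^0.6 and, above optimal
length, by 0.4 + 0.6·f_L; shortening coefficients 100/v̄max_slow
(v̄max_slow = v̄max/2.5) and 153/v̄max scaled by a²; lengthening
coefficient 4× the slow shortening coefficient scaled by a; an aerobic
scale of 1.5 on all heat terms. Eccentric fiber work is excluded (its
cost is carried by the lengthening heat term) and the total rate is
clamped at ≥ 0. Basal heat is excluded, so absolute J/kg totals are
model-relative; condition *differences* are unaffected. Muscle mass
derives from f_max and l_opt via a specific tension of 250 kPa and
density 1059.7 kg/m³. Energy is the trapezoidal time integral over the
simulation window, summed over ipsilateral muscles only and divided by
body mass.

## Sweep and statistics

Δ% = 100·(E_setting − E_baseline)/E_baseline paired per contact, then
averaged. Baseline excludes the device entirely; the no-actuation
condition carries bracket mass with the spring never engaged. The grid
is built by integer index so endpoints are exact. Minima: global argmin
with ties broken toward lower stiffness then earlier timing; local
minima are cells strictly below all 4-neighbors. The quadratic fit is
OLS of mean Δ% on (1, k, k²) at one timing slice; the vertex −c1/(2c2)
is reported only when c2 > 0 (on the default subject the 15% slice rises
from the grid's soft edge and flattens, so the fitted parabola is
concave and the optimum sits at the boundary, 5.5 kN/m). Conditions
BL / EXO-NA / EXO-S1 (global minimum cell) / EXO-S2 (best other local
minimum) are compared by Shapiro–Wilk normality checks, classical
one-way ANOVA (hand-computed sums of squares) and Tukey HSD on the
studentized range (distribution delegated to scipy), α = 0.05, means ±
SD.

## Numerical choices

* Active-set QP: bound clipping exact at [0,1]; KKT tolerance 1e-12;
  200-iteration cap with scipy BVLS fallback (never observed to
  trigger).
* Engagement uses strict inequality L > L0; a tie produces zero force,
  removing sample-grid coincidences.
* Spring resting length is re-derived from each contact's own noisy
  kinematics, mirroring a per-trial device fit.
* Fiber velocity by `np.gradient` on the sampled fiber-length series.
* All randomness flows from one seed through named per-trial
  substreams (`SeedSequence([seed, i])`); zero-noise trials are
  bit-identical across seeds.
* .sto/.mot/CSV writers print 17 significant digits, so round trips are
  lossless well past the required 12.

## Known limitations

* Problem sizes: 100 samples per trial, 10 contacts, 8 muscles per leg —
  chosen as the smallest configuration that resolves the grid structure
  cleanly; the per-contact window solve is ~83 QP steps.
* Prescribed kinematics (pure substitution): the model cannot express
  kinematic adaptation to the device, which experimentally damps both
  the benefit of good settings and the cost of bad ones.
* Rigid tendon overestimates fiber velocities during push-off; the
  v_max = 12 compensation is crude.
* The quasi-static added-mass model understates the metabolic penalty of
  distal mass (no inertial term).
* Late push-off saturates the plantarflexor and hip-flexor compartments,
  leaving knee/hip reserve moments of up to ~25 N·m on a few steps
  (flagged, not hidden). A richer muscle set would absorb these.
* The 10 contacts are replicate strides of one synthetic subject;
  between-subject generalization is out of scope.
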