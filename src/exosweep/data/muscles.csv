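# Sagittal-plane lower-limb muscle set (one leg; mirrored to both sides at load time).
# Parameters are literature-anchored nominal values for a ~75 kg, 1.75 m adult
# (max isometric forces and optimal fiber lengths in the range of the Delp/
# Rajagopal lower-limb model families; fast-twitch fractions from the muscle
# energetics literature). f_max scales linearly with subject mass and l_opt /
# tendon_slack with subject height at load time.
# Lumped compartments: "vasti" = VL+VM+VI; "hamstrings" = SM+ST+BF long head;
# "tib_ant" carries the full dorsiflexor compartment (TA+EDL+EHL) and
# "rect_fem" the hip-flexor compartment, so sagittal moment balance is
# feasible with eight actuators per leg. v_max = 12 l_opt/s compensates the
# rigid-tendon assumption (fiber velocity absorbs the whole musculotendon
# velocity that a compliant tendon would partly take up).
# Moment arms are linear polynomials arm(q) = c0 + c1*q in moment-aligned joint
# coordinates q (ankle plantarflexion-positive, knee/hip extension-positive),
# meters; a zero polynomial means the muscle does not span that joint.
# ref_norm_fiber_length is the normalized fiber length at the neutral posture
# (all q = 0) used by the rigid-tendon fiber kinematics.
name,f_max,l_opt,tendon_slack,v_max,pennation_deg,fast_twitch_fraction,ref_norm_fiber_length,arm_ankle_c0,arm_ankle_c1,arm_knee_c0,arm_knee_c1,arm_hip_c0,arm_hip_c1
soleus,3549,0.050,0.250,12,25,0.19,0.84,0.048,-0.005,0,0,0,0
med_gastroc,1558,0.060,0.400,12,17,0.49,0.91,0.045,-0.005,-0.012,0,0,0
lat_gastroc,683,0.059,0.385,12,12,0.49,0.91,0.044,-0.005,-0.012,0,0,0
tib_ant,1550,0.098,0.220,12,5,0.35,0.98,-0.042,0.004,0,0,0,0
vasti,4530,0.087,0.160,12,3,0.48,0.82,0,0,0.042,0,0,0
rect_fem,1800,0.076,0.350,12,14,0.61,0.95,0,0,0.030,0,-0.050,0
hamstrings,2594,0.080,0.330,12,11,0.44,0.88,0,0,-0.030,0,0.055,0.005
glut_max,1944,0.147,0.125,12,22,0.45,0.82,0,0,0,0,0.055,0.008
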