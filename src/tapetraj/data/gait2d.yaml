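# Planar gait model fixture: skeleton anthropometry, foot-ground contact,
# muscle roster with via-point path geometry and Hill parameters.
#
# All values are representative defaults for a generic adult model (~72.5 kg,
# ~1.0 m pelvis height); they are fixture data, not measured quantities, and
# no acceptance result depends on the specific numbers.  Path points are
# given for the RIGHT leg in the local frame of the named body (m); the left
# leg mirrors them.  Tendon slack lengths are derived at build time so that
# the neutral pose puts each fiber at its optimal length
# (l_T_slack = l_MT(q=0) - l_M_opt cos(alpha_opt)).

skeleton:
  bodies:
    # name, parent, coord, joint point in parent frame, com in own frame, mass, inertia
    - {name: pelvis,  parent: null,    coord: null, joint: [0.0,  0.0],  com: [0.0,  0.0],   mass: 11.78, inertia: 0.10}
    - {name: torso,   parent: pelvis,  coord: 3,    joint: [0.0,  0.08], com: [0.0,  0.30],  mass: 33.87, inertia: 1.40}
    - {name: thigh_r, parent: pelvis,  coord: 4,    joint: [0.0, -0.08], com: [0.0, -0.18],  mass: 8.81,  inertia: 0.15}
    - {name: shank_r, parent: thigh_r, coord: 5,    joint: [0.0, -0.41], com: [0.0, -0.19],  mass: 3.49,  inertia: 0.055}
    - {name: foot_r,  parent: shank_r, coord: 6,    joint: [0.0, -0.43], com: [0.05, -0.025], mass: 1.13, inertia: 0.007}
    - {name: thigh_l, parent: pelvis,  coord: 7,    joint: [0.0, -0.08], com: [0.0, -0.18],  mass: 8.81,  inertia: 0.15}
    - {name: shank_l, parent: thigh_l, coord: 8,    joint: [0.0, -0.41], com: [0.0, -0.19],  mass: 3.49,  inertia: 0.055}
    - {name: foot_l,  parent: shank_l, coord: 9,    joint: [0.0, -0.43], com: [0.05, -0.025], mass: 1.13, inertia: 0.007}

contact:
  stiffness: 2.0e+6       # N/m^1.5, plane-strain Hertz coefficient
  dissipation: 2.0        # s/m, Hunt-Crossley
  mu_dynamic: 0.8
  mu_viscous: 0.5
  smooth_penetration: 600.0   # 1/m
  smooth_slip: 50.0           # s/m
  radius: 0.035               # m
  spheres:                    # per foot, in the foot frame
    - {point: [-0.05, -0.045]}   # heel
    - {point: [0.16, -0.045]}    # toe

# Joint-angle ranges of the gait problem (rad); also the polynomial-fit grid.
joint_ranges:
  hip: [-0.8, 0.8]
  knee: [-2.1, 0.1]
  ankle: [-0.9, 0.6]

muscles:
  iliopsoas:
    path: [[pelvis, [0.03, 0.03]], [thigh, [0.02, -0.08]]]
    spans: [hip]
    F_max: 1500.0
    l_M_opt: 0.09
    alpha_opt: 0.14
  glutei:
    path: [[pelvis, [-0.06, 0.02]], [thigh, [-0.01, -0.10]]]
    spans: [hip]
    F_max: 2000.0
    l_M_opt: 0.10
    alpha_opt: 0.0
  hamstrings:
    path: [[pelvis, [-0.06, 0.0]], [shank, [-0.025, -0.05]]]
    spans: [hip, knee]
    F_max: 2500.0
    l_M_opt: 0.10
    alpha_opt: 0.26
  rectus_femoris:
    path: [[pelvis, [0.04, -0.01]], [thigh, [0.04, -0.38]], [shank, [0.03, -0.06]]]
    spans: [hip, knee]
    F_max: 1200.0
    l_M_opt: 0.08
    alpha_opt: 0.09
  vasti:
    path: [[thigh, [0.03, -0.15]], [thigh, [0.04, -0.38]], [shank, [0.03, -0.06]]]
    spans: [knee]
    F_max: 3500.0
    l_M_opt: 0.08
    alpha_opt: 0.05
  biceps_femoris_sh:
    path: [[thigh, [-0.02, -0.15]], [shank, [-0.025, -0.06]]]
    spans: [knee]
    F_max: 800.0
    l_M_opt: 0.11
    alpha_opt: 0.2
  gastrocnemius:
    path: [[thigh, [-0.015, -0.36]], [foot, [-0.06, -0.02]]]
    spans: [knee, ankle]
    F_max: 2000.0
    l_M_opt: 0.05
    alpha_opt: 0.3
  soleus:
    path: [[shank, [-0.02, -0.12]], [foot, [-0.06, -0.02]]]
    spans: [ankle]
    F_max: 3500.0
    l_M_opt: 0.05
    alpha_opt: 0.44
  tibialis_anterior:
    path: [[shank, [0.02, -0.20]], [shank, [0.03, -0.41]], [foot, [0.10, -0.01]]]
    spans: [ankle]
    F_max: 1200.0
    l_M_opt: 0.07
    alpha_opt: 0.1
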