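# Methods

## Model

A rigid cargo is carried by `n_tot` uninformed ants occupying `n_max`
binding sites, plus `G` informed ants that pull toward the opening of a
linear obstacle.  Uninformed ants are *pullers* (force `f0` along their
pulling axis `p_i`) or *lifters* (no force; in this implementation their
friction-reduction role is taken as complete, so the friction term is zero
throughout).  Role switching is a force-sensing process with rates

    r(l→p) = k_c exp(+f_tot·p_i / F_ind),   r(p→l) = k_c exp(−f_tot·p_i / F_ind)

and the motion is overdamped: `f_tot = γ v`.  `F_ind` sets the force scale
above which an individual yields to the group; small `F_ind` (or a large
group) produces a ferromagnetic-like ordered pull.

### Reduced 1D system

With sites split into fixed front/back pools, averaging the switching
kinetics yields

    ẋ = v
    v̇ = q(x, v) = k_c [ n sinh(v/f_ind) − 2 (v + g tanh(x/ε)) cosh(v/f_ind) ]
                  − v (g/ε) sech²(x/ε)

with `n = f0 n_tot/γ`, `g = f0 G/γ`, `f_ind = F_ind/γ`.  The tanh profile
regularizes the informed pull over a length `ε` comparable to the cargo
radius (the geometric projection of a ring cargo's restoring pull is matched
by tanh to within 0.13·g for ε = r; see `restoring_force(mode="projection2d")`).

**The ε → 0 limit.** The sech² term is the spatial derivative of the
restoring profile; along a trajectory it integrates to a velocity change
`Δv = −g Δtanh(x/ε)`.  In the sharp-opening limit this is an impulse at
x = 0: a cargo arriving with speed `u > 2g` crosses and keeps `u − 2g`; a
slower cargo penetrates the profile only partially and is reflected
elastically.  The piecewise integrator (`integrate` with `eps=0`) runs the
smooth half-space fields with event-located crossings applying exactly this
rule, and flags a reflection as capture by the convergent mode (for any
finite ε the origin is then a strongly damped stable focus; the impulse
model does not resolve the final boundary-layer spiral and simply ends the
orbit at the origin).

### Critical lines

* **Hopf**: the origin Jacobian is `[[0, 1], [−2k_c g/ε, k_c(n/f_ind − 2) − g/ε]]`;
  its trace vanishes at `f_c1 = (n/2)/(1 + g/(2 k_c ε))`, reproducing the
  closed form and checked against finite differences and a trace-zero root
  solve to 1e−6.  `f_c1 → 0` as ε → 0.
* **Homoclinic** (`f_c2`): in each half-space the velocity nullclines solve
  `(n/2) tanh(v/f_ind) = v ± g`; tangency gives the transition velocities
  `v± = ±g ∓ √((n/2)(n/2 − f))` and the scalar fixed-point equation
  `f = (n/2) sech²((−g + √((n/2)(n/2 − f)))/f)`.  The equation has two roots
  on (0, n/2); the smaller is the homoclinic threshold (the larger lies
  beyond the saddle-node and corresponds to the second tangency of the same
  geometry).  The root is found by scanning for the first sign change and
  Brent refinement to residual < 1e−10, and is cross-checked by an
  independent escape/return bisection of the simulated flow (agreement to
  1e−3; at n = 0.8, g = 0.1: f_c2 = 0.2076).
* **Saddle-node of cycles** (`f_c3`): on the section x = 0 the half-return
  map `H` sends a post-crossing speed through one half-space excursion and
  one crossing; by the (x,v) → (−x,−v) symmetry, symmetric limit cycles are
  fixed points of `H`.  A cycle exists iff `max_v (H(v) − v) ≥ 0`; the
  maximum is located on a 25-point grid with bounded local refinement, and
  `f_c3` is the bisection point (width 1e−3) where the maximum changes sign
  (at n = 0.8, g = 0.1: f_c3 = 0.2575).  This one-parameter scan replaces
  pseudo-arclength continuation; the unstable cycle (separatrix) is
  available as the lower fixed point of `H`.

Phases: (i) `f_ind < f_c2` — convergence coexists with unbounded escape;
(ii) `f_c2 ≤ f_ind < f_c3` — convergence coexists with relaxation
oscillations; (iii) `f_ind ≥ f_c3` — global convergence.  For finite ε
points below `f_c1` are flagged `unstable_no_bistability`.

## Stochastic simulators

Both simulators are exact Gillespie chains: waiting times
`dt = ln(1/u)/R_tot` with `u` uniform on (0, 1], event classes chosen by
cumulative-rate comparison in the fixed order attach → detach → role-switch
→ forget → orient, the cargo drifting ballistically between events, and the
velocity recomputed as `f_tot/γ` after every event (the overdamped reading;
an incremental velocity update is inconsistent with `f_tot = γv` and does
not reduce to the mean-field system).

**1D schemes.** (i) role switching only (fixed, fully occupied uninformed
population; constant external `G`); (ii) plus uninformed attachment
(`k_on` per empty site, side chosen uniformly among sides with capacity,
role drawn from the single-site equilibrium `N_p = 1/(1+e^{−2 f·p/F_ind})`)
and detachment (`k_off` per ant, removed type drawn from the same
equilibrium); (iii) attachments are instead informed site-occupying ants
that forget at `k_forget`, so the restoring force fluctuates.  Populations
are initialized at the stationary occupancy means of the corresponding
kinetics, which for the standard parameter tables reproduce the nominal
`n_tot ≈ 80` and `G ≈ 10` of the reference point (g, f_ind) = (0.1, 0.23).
The tiny-system stationary distribution matches the exact master equation,
and the one-step expectation of the puller-imbalance drift matches the
mean-field tug-of-war term exactly.

**2D ring cargo.** `n_max` sites sit at angles `2πk/n_max` on a ring of
radius r touching a wall (y = 0, contact at y = r) with an opening at x = 0
narrower than any cargo.  Reconstruction choices where the source algorithm
is underspecified:

* *Pulling axes are pinned outward radial by the grip geometry.*  This is
  what bounds the persistence of the collective pull — exactly the role of
  the fixed front/back pools in 1D.  Letting pullers reorient their axes
  freely onto the force direction removes the individuality bound entirely
  (all axes collapse onto one direction and the walk never turns; excursions
  exceed hundreds of cm at every size, and no convergence occurs).
* *Re-orientation relocates.*  The `k_orient` event moves a puller to the
  empty site whose direction best aligns with the sensed force ("orients its
  position"); with no empty site or no improvement it is a no-op.
* *Ants sense the force transmitted to motion*, i.e. the force sum with the
  wall-normal component cancelled by the reaction during contact — the 2D
  generalization of the overdamped identification `f_tot = γv`.  Using the
  raw force sum instead creates an absorbing state (the group orders
  straight into the wall at the opening and freezes there at every cargo
  size), which contradicts the persistent oscillations of large cargoes.
* *Informed ants pull from the cargo center toward the opening center*, unit
  force each; `γ(r) = (f0/0.14)·(r/0.5)`, anchored to the observed
  single-ant speed `f0/γ = 0.14` cm/s for the small cargo and scaled
  linearly with radius (γ = 20, 40, 80 for r = 0.5, 1, 2).
* Cargo rotation is not simulated; relocation along the ring stands in for
  it.  Translational contact is sliding (normal displacement and velocity
  zeroed), and the cargo can never pass the opening.

## Trajectory analysis

Convergent episodes are maximal intervals with `|x| < x_bound`,
`|v| < v_bound` (and `y < y_bound` in 2D) lasting longer than
`min_duration`; everything else is oscillatory.  Presets: 1D — 0.1 cm,
0.1 cm/s, 5 s; 2D — r, 0.1 cm/s, 4 s with `y < 2r`.

The velocity entering the thresholds must be a time-averaged estimate: a
single role switch changes the cargo speed by `f0/γ` (0.14 cm/s for the
small 2D cargo, above the 0.1 cm/s criterion), and in the 1D convergent
state the instantaneous velocity oscillates around ±g = ±0.1 cm/s — the
criterion value — with sign flips every ~1 s.  The standard pipelines are
therefore: 1D (`prepare_1d`) — 0.1 s grid, central differences of the 2.1 s
moving-average position; 2D (`prepare_2d`) — 1 s grid, central differences
(2 s support).  Segment durations follow the discrete run-length convention
(number of sub-threshold samples × grid step, clipped at the trace edges),
so dwell durations partition the analyzed window.  Turning points are
velocity sign changes outside convergent segments; exponential tails are
fitted by maximum likelihood on exceedances with exact chi-square confidence
intervals and a Kolmogorov–Smirnov diagnostic.

## Synthetic data

`make_fixture_trajectory` plants known convergent windows (sub-threshold
noise at the origin) inside a super-threshold sinusoidal carrier, providing
exact ground truth for the segmentation.  It emulates the *shape* of tracked
center-of-mass tables, not their physics: no event-time structure, no
correlated velocity noise, no wall geometry.  Passing segmentation tests on
fixtures therefore certifies the detector logic, not the simulators — those
are validated separately against the master equation, the mean-field drift,
and the stationary occupancies.

The simulators themselves generate all other test data at run time.  Neither
they nor the fixtures model pheromone fields, cargo flexibility or squeezing
through the opening, heterogeneous individuality among ants, or the finite
frame of a real arena (the wall is effectively infinite).

## Problem sizes and tolerances

ODE integration uses LSODA with rtol 1e−8/atol 1e−10 (1e−10/1e−12 for
return maps); nullcline and threshold roots are bracketed Brent solves
(residual < 1e−10); bisections in `f_ind` stop at width 1e−3, matching the
two-decimal precision at which the thresholds are quoted.  Stochastic
checks in the test suite use 3000 s runs (1–4 seeds) for the 1D schemes and
1500–2000 s runs for the 2D cargo; the acceptance script uses 20 × 1800 s
replicates for the small-cargo dwell statistic, collecting ~150 episodes
(Monte-Carlo standard error ≈ 0.2 s).  Random draws all flow through
per-run `numpy` generators seeded explicitly; identical seeds reproduce
trajectories exactly.

## Known limitations

* The 2D simulator is a reconstruction; its dwell statistic is sensitive to
  the sensing and re-orientation choices above at the ~10% level.
* The ε = 0 integrator ends orbits at the first reflection; the final
  boundary-layer spiral (time scale ε/g) is not resolved.
* The homoclinic threshold equation's second root and the behaviour at very
  small g (< 0.01) are untested territory; the phase-diagram helper assumes
  the first-root branch.
* `exponential_tail_fit` assumes independent exceedances; turning times of
  strongly periodic (large-cargo) motion violate this and should be read as
  descriptive only.
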