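# Methods

## The controller in brief

A stimulation lookup table over (shoulder angle, elbow angle, stiffness) is
built in five steps: (1) measure, with the arm held stationary at every
node of a sampling grid, the passive torques and each electrode's
stimulation-to-active-torque curve; (2) for every node and stiffness level
assemble the balanced-torque system `x = A c` (two rows per joint: flexion
target `S - Pf`, extension target `-S - Pe`; one column per electrode
holding its signed maximum torques); (3) solve for the scale vector `c` by
least-squares minimum norm with `c` bounded to `[0, 1]`, and convert `c` to
stimulation by inverting the measured curves at `c_i` times the recorded
maximum; (4) apply each node's stimulation to the free arm and record where
it actually settles; (5) key the final table by those achieved postures and
interpolate between nodes at query time, linearly and one dimension at a
time.

## The synthetic plant

The controller is exercised against a synthetic planar two-link arm
(horizontal plane, no gravity) with six muscles: anterior/posterior deltoid
(shoulder, ±40 Nm peak), brachialis / triceps lateral head (elbow, ±30 Nm),
and the biarticular biceps / triceps long head (±10 Nm shoulder, ±25 Nm
elbow). Link lengths are 0.33 m and 0.45 m; the workspace is shoulder
15–85°, elbow 20–130°. Flexion torques are positive.

**Passive torques.** Each joint has two one-sided exponential components,
one resisting approach to each range limit: `Pf = 2.5·exp(-(θ-θ_lo)/15°)`
and `Pe = -2.5·exp(-(θ_hi-θ)/15°)` Nm. The 15° length constant makes them
appreciable only within ~25° of a limit, and symmetry makes them cancel
exactly at mid-range, which is therefore the passive rest posture. The
2.5 Nm limit amplitude keeps even the lowest stiffness level (3 Nm)
feasible at the range limits (the extension-side target `-S - Pe` never
changes sign inside the workspace).

**Activation and force–length.** Stimulation `u ∈ [0,1]` maps to activation
through a normalised logistic with threshold 0.1 and saturation 0.9 (5 % /
95 % points), exactly 0 at `u = 0` and 1 at `u = 1`. Torque at a joint is
`activation × peak × fl(θ) × capacity`, with a Gaussian force–length factor
`fl` of width 60° and floor 0.3. Flexor optima sit 20° below and extensor
optima 20° above each joint's mid-range. This flexor/extensor offset is a
deliberate design choice: if every muscle at a joint shared one
force–length curve, balanced co-contraction would add *zero* net rotational
stiffness and mid-workspace equilibria would be only marginally stable.
With the offset, each side's torque falls off in the direction it acts,
so co-contraction produces restoring stiffness roughly proportional to `S`
(~3.5 Nm/rad at `S = 8` Nm) — the physical premise behind treating `S` as a
stiffness command. This is still several-fold softer than a human arm under
comparable co-contraction; consequences are discussed under Limitations.

**Electrodes and spillover.** The default arm has one dedicated electrode
per muscle. Two spillover variants replace the biceps channel with a single
electrode recruiting two hypothetical monoarticular flexors: scenario A
(the commoner shape) recruits the elbow flexor (25 Nm, threshold 0.1) first
and the shoulder flexor (10 Nm, threshold 0.45) later, so both torques rise
monotonically but their ratio drifts with current; scenario B (the rarer
shape) has the elbow flexor (12 Nm) saturate early (by u ≈ 0.45) while the
shoulder flexor (20 Nm, threshold 0.35) keeps growing, so the joint-torque
ordering reverses across the range.

**Fatigue.** Marked muscles lose a constant fraction of torque capacity per
second (`capacity = max(0, 1 - rate·t)`), independent of instantaneous
stimulation. This deliberately matches the constant-rate framing of the
fatigue study; usage-dependent fatigue is out of scope.

**Statics and dynamics.** Because both passive components and the
force–length factors are local to a joint, the net static torque at each
joint depends only on that joint's angle; equilibria are found by damped
Newton per joint (vectorised over thousands of nodes), with a
scan-and-bisect fallback, and accepted only where `dτ/dθ < 0` at both
joints (stable). The forward dynamics used for reach simulations are
standard two-link rigid-body equations (uniform-rod links of 2.0 and
1.7 kg) integrated with fixed-step RK4 at 1 ms, with joint viscous damping
that grows linearly with total recruitment (0.8 + 2.0 × Σactivation
Nm·s/rad), reflecting the damping increase observed with co-contraction.

## Numerical choices

* **Bounded minimum-norm solve.** The unconstrained minimum-norm solution
  uses a pseudoinverse with a 1e-12 relative singular-value cutoff. Bounds
  are enforced one violation at a time, largest first: negative scales drop
  their column (muscles cannot push), scales above one are fixed at the
  maximum and their torque subtracted from the targets. On near-degenerate
  systems — typically two nearly proportional biarticular columns — this
  greedy order can clamp the wrong column first, so a KKT stationarity
  check follows and, in the rare suboptimal case, a box-constrained
  least-squares polish (BVLS) restores the optimal residual. Zero columns
  are dropped before solving. A node is flagged infeasible when the final
  residual norm exceeds 1e-6 Nm.
* **Curve inversion.** Measured sweeps (default 101 even steps, truncated
  once torque has started changing and then stops changing by < 0.01 Nm
  over three consecutive steps) are inverted with a Fritsch–Carlson
  monotone cubic interpolant and a safeguarded vectorised Newton, ties
  breaking toward lower stimulation (less injected charge). Piecewise-linear
  inversion was rejected: on a 101-sample sigmoid it leaves ~2e-3 Nm of
  round-trip error, enough to move this plant's equilibria by ~0.03°; the
  monotone cubic brings the measured-node placement error below 1e-3 cm.
* **Spillover iteration.** Coefficient change is measured as the vector
  norm (per-element available as an option); tolerance 0.001, cap 1000.
  The reference joint of a multi-muscle channel is the one with the larger
  measured maximum torque. A converged run that needed `k` solves reports
  `k - 1` iterations, so a channel whose ratio is already consistent counts
  as 1. A lockstep batched implementation (equivalent to the per-system
  routine to 1e-12) runs the 3795-system censuses in seconds.
* **Fatigue-study numerics.** Demonstrating that standard and rebalanced
  tables are *identical* when fresh requires resolving sub-1e-6 cm endpoint
  differences, so that experiment calibrates with 1601-step sweeps and
  solves equilibria to 1e-10 Nm; all other defaults stay at 101 steps and
  1e-6 Nm.
* **Table queries.** Linear interpolation one dimension at a time
  (shoulder, elbow, stiffness); cubic per-dimension interpolation is
  available behind a flag but is not the default. Queries outside the
  sampled hull extrapolate linearly from the edge cell and are flagged;
  more than 10° beyond the hull is refused. Final tables correct the query
  point by the locally interpolated achieved-minus-intended offset (exact
  whenever verification reproduces the intended postures, i.e. for
  noise-free calibration), and near-node corrected queries snap to the node
  so a measured node returns its stored stimulation bit-identically.

## The simulated user

Centre-out reaches (default: 8 targets, 14 cm radius, 1.3 s) follow a
minimum-jerk bell-shaped speed profile at a 50 ms command cadence.
Commanded stiffness is scheduled from commanded speed,
`S = S_max - (S_max - S_min)·|v|/v_peak` over [3, 13] Nm — stiff at rest
and at the target, compliant at peak speed. With visual feedback on, the
commanded velocity direction is re-aimed from the current fingertip toward
the target each loop before integrating; after the profile ends the user
keeps steering, adding a fraction (0.7) of the remaining visual error to
the commanded position every 0.4 s — sparse corrections, because
corrections faster than the arm's settling time (~0.5 s on this compliant
plant) wind up and oscillate, the same instability seen when feedback
controllers outrun an FES arm's response. Commanded endpoints are clamped
to the reachable annulus and the calibrated workspace before table lookup.

## What the synthetic setting does and does not show

The plant has the structural features the controller must cope with —
redundancy, biarticular coupling, sigmoidal recruitment, one-sided passive
stiffening, spillover, fatigue — so passing tests show the *algorithmic*
pipeline is correct: exact self-consistency at calibrated nodes, exact
torque bookkeeping, convergent spillover iteration, conservation of
behaviour under work rebalancing. It does not have Hill-type
activation/contraction dynamics, tendon compliance, realistic moment-arm
variation, gravity, or measurement noise by default (a seeded Gaussian
noise mode exists for robustness studies), so absolute error magnitudes do
not transfer to a specific musculoskeletal model or patient arm.

Two quantitative consequences of this plant are worth stating plainly:

* Its co-contraction stiffness (~3.5 Nm/rad at `S = 8`) is low, so the
  stimulation-interpolation error of a sparse 20°-calibrated table produces
  a workspace-median fingertip error of ≈1.1 cm (0.28 cm at 10°, 0.07 cm at
  5°, 0 at 1°), with the largest errors in the 10°-wide band beyond the
  last 20° sample line where extrapolation is needed. A stiffer plant
  yields proportionally smaller errors from the same stimulation error.
* Rebalancing work away from fatiguing muscles always reduces the torque
  deficits and always improves the achieved-stiffness error, but its effect
  on *fingertip* error depends on arm geometry: when the two fatiguing
  muscles are antagonists on different joints (anterior deltoid + triceps
  lateral, or posterior deltoid + brachialis), the standard table's larger
  but correlated shoulder-extension and elbow-flexion drifts partially
  cancel in Cartesian space, and its median fingertip error can come out
  slightly *below* the rebalanced table's despite larger joint errors. In
  the other nine scenarios, and for stiffness error in all eleven,
  rebalancing dominates at every timestep.

## Problem sizes

Default study sizes match the workspace definitions throughout: 5° grids
with 11 stiffness levels give 3795 systems per census; the resolution sweep
evaluates on the full 1° grid (7881 postures); the fatigue study runs all
11 scenarios at 5 s timesteps over 100 s. All of these complete in seconds
to a couple of minutes on a single core thanks to the vectorised
equilibrium and curve kernels.
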