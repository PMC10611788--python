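# Methods

This note documents the models implemented in `topoloop`, the defaults and
their rationale, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Tethered worm-like-chain Monte Carlo

The DNA is a chain of `n_segments` rigid segments of length *l* (default
10 nm), anchored at the origin with the first and last segment tangents held
parallel to the force axis (the tether/bead geometry of a magnetic-tweezers
experiment).  The energy in units of k_BT is

    E = (L_p/l) Σ_i (1 − cos θ_i)  −  (F/k_BT) z_end  +  (2π² L_t / L_c)(ΔLk − ΔWr)²

* `bend_persistence` L_p = 50 nm and `segment_length` l = 10 nm are the
  canonical coarse-grained values for double-stranded DNA; `twist_persistence`
  L_t = 109 nm and T = 296 K (23 °C) match the measured torsional response
  of the substrates this models.
* The chain does not carry explicit per-segment twist.  Twist is eliminated
  adiabatically: for a fixed linking-number offset ΔLk, the twist is
  ΔTw = ΔLk − ΔWr by conservation of linking number, and the quadratic
  torsional term above is the resulting effective energy.  It is the unique
  quadratic form whose difference under exchanging two chains between
  linking-number replicas reduces to
  ΔE = (4π² L_t / L_c)(ΔLk_i − ΔLk_j)(ΔWr_i − ΔWr_j), the modified
  Metropolis criterion used for replica exchange.

**Writhe.**  The open chain is closed virtually by long straight extensions
along the force axis from both ends, joined far from the chain
(10 × contour length).  Because both terminal tangents are constrained to
the force axis, the closure continues the chain smoothly and contributes no
writhe of its own.  The writhe of the closed polygon is the exact Gauss
double sum over segment pairs; each pair term is the signed solid angle of
the spherical quadrilateral of inter-endpoint directions, evaluated as two
van Oosterom–Strackee triangles (2·atan2 forms).  This evaluation is
branch-safe: it degrades gracefully to zero for nearly collinear segment
pairs, where normalized face normals (the textbook arcsin form) become
numerically ill-conditioned.  During sampling the writhe is maintained
incrementally — only Gauss terms involving segments changed by a move are
re-evaluated; pairs inside a rigidly co-rotated block are invariant — and the
unit tests verify the incremental value agrees with full recomputation to
10⁻⁸ turns after long runs.

**Moves.**  Crankshaft rotations turn an interior subchain about the axis
through its boundary vertices; pivot rotations turn the tail beyond a random
interior vertex about a random axis.  Rotation angles are uniform on
±`move_amplitude` (default 50°).  A literal pivot of the whole tail would
rotate the last segment off the force axis and violate the anchoring
constraint; with crankshaft moves fixing both axis endpoints, the end vertex
could then never move and the extension would not be sampled.  The pivot
therefore rotates the tail *up to the penultimate vertex* and re-appends the
final vertex along the force axis (v_N = v_{N−1} + l ẑ).  This preserves all
bond lengths and both terminal tangents exactly, samples the extension, and
remains a symmetric proposal, so detailed balance holds.

**Replica exchange and saving.**  One replica per entry of `dlk_grid`
(ΔLk labels are fixed to replicas; exchanges swap conformations).  Each cycle
applies `local_moves_per_cycle` move trials per replica (default 1000)
followed by exchange trials between neighboring linking numbers on
alternating parity.  All replicas are saved after
`exchange_saves_threshold` (default 5) successful exchanges between any
neighboring pair, until `save_target` saves (default 25 000).  A
single-replica run has no exchange partners; there, each cycle counts toward
the save cadence instead.

**Knot rejection.**  Segments may pass through each other during moves, so
topology is enforced by a knot check every `knot_check_interval` moves
(default 1000) and before every save: the closed chain is projected onto a
generic plane (random re-projection on degeneracies) and the Alexander
determinant |Δ(−1)| is computed from the underpass matrix; at t = −1 the two
crossing types give identical rows, so crossing signs are not needed.  A
knotted replica is reverted to its last knot-free checkpoint.  Determinant-1
knots (e.g. some high-order torus knots) are invisible to this invariant;
they are irrelevant at the chain sizes sampled here.

**Two-kink bend.**  The bent-DNA variant freezes two adjacent interior
joints at 60° each (a flat-bottomed 'V' of 120° total) and excludes them
from move proposals, so the bend is rigid under all accepted moves.

**Equilibration.**  Runs start from a straight (or constructed bent) chain
with `burn_in_cycles` of unsaved sampling.  A drift check on the saved
extension series (last third versus middle third, 5% of the mean) sets a
per-replica warning flag.  The sampled mean extension at ΔLk = 0 agrees with
the worm-like-chain force-extension interpolation within a few percent; the
residual offset is the known discretization bias of a 10 nm bead-rod chain
(the effective persistence length of the (1 − cos θ) discretization is a few
percent below L_p).

## Loop-capture kinetics

Site-to-site distances R are pooled over saved conformations for vertex
pairs at contour separation ≥ 10 segments (100 nm); a bare adjacency cutoff
would trivially saturate the R < R_T bin with neighboring vertices that topo
II cannot bridge.  The normalized histogram is Boltzmann-inverted,
F(R) = −ln p(R) in k_BT (no Jacobian correction: F is the potential of mean
force of the 1-D distance marginal; a Jacobian-corrected variant would
change only the effective 1-D diffusion picture, not the fitted kinetics,
and is deliberately not applied).  Empty interior bins are filled by linear
interpolation in F.

The mean first-passage time to a crossing (two sites within R_T = 10 nm)
for a walker started from the equilibrated uncrossed state, absorbing at R_T
and reflecting at the largest populated distance L, is the standard triple
integral quoted in the README; it is evaluated with nested cumulative
trapezoid sums (O(n) after prefix sums) on at least 200 bins, and is
invariant under additive shifts of F.  On a flat profile it reproduces the
closed form (L − R_T)²/(3D) to 10⁻⁴ relative at 10⁴ bins.

The effective diffusion coefficient D (default 10⁷ nm²/s, the order of
magnitude for short DNA-segment diffusion) sets the absolute scale of the
crossing rate k = 1/⟨T⟩; absolute loops/s values are therefore
calibration-dependent through D, while the shape of k(σ, F) and everything
fit from relative comparisons are not.

Relaxation: dΔLk/dt = −sign(ΔLk) · V_max(F) · k/(k + k_1/2), with
V_max = 3.4 / 3.1 / 3.0 turns/s at 0.5 / 1.1 / 1.6 pN fixed from
buckled-state relaxation rates and k_1/2 the single global fit parameter.
Trajectories are integrated with fixed-step RK4 (sub-stepped; the fully
relaxed state is absorbing), k(σ) linearly interpolated in |σ| with
edge-clamping (warned) outside the table, and ΔLk ↔ σ converted with
Lk0 = n_bp/10.5 (10.5 bp per helical turn).  The χ² fit pools all forces
with SEM weights when available (unit weights otherwise), minimizes over
log₁₀ k_1/2 on a bounded interval, and reports the Δχ² = 1 half-width.  A
writhe-only alternative (rate = V|W|/(|W| + w_half)) is provided for model
comparison; on data generated by the loop-capture model it fits strictly
worse.

## Substrate mechanics

* Twist/writhe partition: pre-buckling ΔTw = (L_t,eff/L_t) ΔLk with
  L_t,eff = 78.9 nm and L_t = 109 nm; past the buckling transition the twist
  freezes and all further turns become writhe.  Torque is linear
  pre-buckling, τ = 2π k_BT L_t,eff ΔLk / L_c (k_BT = 4.09 pN·nm at 23 °C),
  clipped at the plateau values +7.7/−7.6 pN·nm.
* Naked calibration: central parabola capped by two linear plectonemic
  wings, value-continuous with independent wing slopes (the buckling
  transition is a slope discontinuity).  Seven parameters, least squares.
* Chromatin calibration: the slope function is piecewise linear (s₁ → s₂ →
  s₃ with two linear ramps), so the extension is three linear regimes joined
  by two parabolic joins with C¹ continuity — 8 parameters.  The
  buckling-like transitions w_t± (intercepts of the middle line with the
  outer lines) coincide with the ramp centers by construction.  A fit is
  rejected as "not chromatin-like" when the middle regime collapses, the
  outer slopes do not bracket a shallow plateau, or the middle region
  carries parabolic sag beyond the noise (a naked pre-buckled response).
* Census: N_out = release(2→6 pN)/72 bp, N_in = release(high salt)/75 bp
  (nearest integer, ties to even), N_nuc = (N_out + N_in)/2, composition
  acceptable when |N_in − N_out|/N_in ≤ 0.15.  Selection requires the
  peak-extension-based N_nuc in 50 ± 5 and both w_t± within the 95% CI bands
  of benchmark lines versus N_nuc.

## Trace analysis

Sliding filters are centered moving averages whose window shrinks
*symmetrically* at the edges; this preserves linear trends exactly, so
filtered magnet-turn ramps keep their slope and integrated clamp rates
reproduce the total turns relaxed to well under 1%.  Clamp rate is
−d(magnet turns)/dt after 20 s filtering; its magnitude is the topo rate.
A pause is a maximal interval with |rate| below 0.5 turns/s (the duration
criterion, > 30 s, is physical; the rate floor is a package default chosen
well below the slowest saturated rate and well above filtered noise).
Activity records end at the first pause; records with no pause are censored
at the trace end.  The active fraction at x is the share of records still
active among those under observation (censored records contribute until
their censoring point), with proportion SE √(p(1−p)/n).  Lifetimes and
processivities come from unweighted least squares of f = exp(−x/μ) with
f(0) = 1 fixed; a censoring-aware exponential MLE (lifelines) is provided
and agrees within quoted uncertainties on synthetic data.  A censored
record's processivity abscissa is the turns relaxed up to censoring.

Pre-buckled supercoiling states are reconstructed from rewinding steps as
ΔLk_pre = ΔLk_after − n_added + r_buckled(t_rewind + 1 s), with ΔLk_after
from the mean extension over 1 s after the rewind inverted through the
buckled calibration branch matching the winding sign.  The direct method
aligns relaxation traces at the first upward crossing of the
buckling-transition extension (the tether must first have visited the
buckled branch), averages on a common grid, and maps the mean extension
through the pre-buckled branch.

## Feedback clamp

A proportional controller: every 5 frames at 40 fps, the mean extension
error times the gain (0.05 turns/s per nm) sets the magnet rate
(zero-order hold), saturated at ±10 turns/s — an explicit package default
standing in for an unspecified instrument limit; rapid open-loop winding
uses 40 turns/s.  Positive error commands winding toward lower extension
(branch-aware sign).  The loop settles within ~1/(gain·|calibration slope|)
≈ 0.4 s; steady-state tracking leaves a constant extension offset of
(enzyme rate)/gain, which does not bias the rate readout.  Assertions about
steady state exclude the first 5 s.

## Synthetic data

The generators emulate: 40 fps extension traces with Ornstein–Uhlenbeck
noise (15 nm SD, 50 ms correlation time — a package choice matching typical
trace thickness at this force); strand passages of −2·sign(ΔLk) turns at
exponential waiting times with rate V_max k(σ)/(k + k_1/2)/2 events/s;
exponential enzyme lifetimes (pre-buckled naked default 8.9 min);
Poisson-initiated pauses with lognormal durations (median 60 s, shape 0.5;
the initiation rate makes ~40% of 30-min traces contain a pause);
contaminating second-enzyme binding at the memoryless rate implied by 17%
per 30 min; naked calibrations built from the worm-like-chain extension
fraction with ~3% parabolic dip at buckling and force-dependent plectoneme
slopes; chromatin curves whose plateau width is N_nuc × 1 turn with a slight
negative slope and peak extension reduced by ~50 nm of wrapped DNA per
nucleosome.  The default crossing-rate table for trace generation is the
parametric stand-in k(σ) = k_sat u⁴/(1 + u⁴), u = σ/σ_buckle (k_sat = 200
loops/s), which has the same shape as tables computed from the Monte Carlo
ensembles but keeps fixtures fast; both routes are supported.

Not emulated: camera/bead image formation, instrument latency beyond the
5-frame controller block, sequence-dependent elasticity, electrostatics,
nucleosome structural transitions beyond the turn-absorption phenomenology,
and drift/low-frequency noise.  Passing tests therefore demonstrate the
correctness and statistical calibration of the algorithms under the stated
measurement model, not robustness to instrument systematics absent from it.

## Problem sizes used in the test and acceptance runs

The sampler checks use 48-segment chains (480 nm) with a ΔLk grid of
{0, 1, 2, 3}, 150 local moves per cycle and 150 saves after 80 burn-in
cycles, and 16–32-segment chains for unit and bent-chain tests; parameter
recovery uses 200 activity records × 20 seeds and three-force relaxation
time courses with 5% noise.  These sizes were chosen so each statistical
assertion retains several-σ margins at its stated tolerance while the whole
suite stays lightweight on a single CPU.  The headline chromatin
quantity (turns per nucleosome) is computed at full scale: a 50-nucleosome
fiber scanned from −40 to +70 turns.

## Known limitations

* Replica-exchange acceptance falls quickly with ΔLk spacing on short
  chains (the torsional stiffness 2π²L_t/L_c grows as chains shrink); grids
  with unit spacing are advisable below ~1 kb equivalent length.
* The Alexander determinant does not detect determinant-1 knots.
* Absolute crossing rates scale with the effective diffusion coefficient D;
  only ratios and fitted Michaelis constants are calibration-independent.
* The exponential survival fit is a curve fit to the empirical active
  fraction; for heavily censored ensembles it returns a flagged lower bound
  rather than an estimate.
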