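# Methods

This note documents the models, numerical methods and design choices behind
`selfreplicator`, in the order the package builds them up.

## 1. The self-replicator model

The cell is two catalytic machineries and a precursor pool. Metabolic
machinery *M* converts substrate to precursors at rate
v_M = e_M(1/β − r); gene-expression machinery *R* polymerizes precursors
into new machinery at rate v_R = k_R · r · p/(K_R + p), a fraction α going
to *R* and 1 − α to *M*. Volume is proportional to total machinery mass,
Vol = β(M + R), which makes the growth rate μ = β·v_R and closes the
concentration dynamics (module `model`).

Assumptions inherited from this construction:

* population-level description; no explicit cell division,
* no macromolecule degradation and no maintenance flux,
* the substrate term is folded into a constant nutrient efficiency e_M
  (substrate constant or in excess over the experiment's horizon),
* two protein classes only; the RNA/protein mass ratio is proportional to
  the machinery fraction r̂ with conversion γ.

Nondimensionalization (p̂ = βp, r̂ = βr, t̂ = k_R·t) leaves the environment
E_M = e_M/k_R and K = βK_R. Reference values: E_M = 1, K = 0.003
(equivalent to e_M = k_R = 3.6 h⁻¹, K_R = 1 g L⁻¹, β = 0.003 L g⁻¹).
Because r + m = 1/β, the state box {p̂ ≥ 0, 0 ≤ r̂ ≤ 1} is forward
invariant; property tests assert this on random closed loops.

## 2. Steady states and the closed-form optimum

For constant α ∈ (0, 1) the nontrivial fixed point is the "+" root of a
quadratic in p̂ (the "−" root is negative for all admissible parameters;
a test checks this), with r̂* = α. Stability is decided from the
numerically differentiated Jacobian (central differences, relative step
1e-7) rather than a transcribed symbolic Jacobian; the fixed-point residual
tolerance (1e-10) and identity tolerance (1e-12) are package-wide constants
in `config.NumericConfig`. The trivial fixed point (0, 1) exists for every
α and is a saddle for α < 1; at the degenerate boundaries α ∈ {0, 1} the
limiting fixed points are returned with an explicit `degenerate` flag and a
warning.

Maximizing μ̂* along the precursor nullcline gives p̂*_opt = √(K·E_M) and
the closed forms for α*_opt and μ̂*_opt quoted in the README. Eliminating
E_M instead of p̂ gives the **optimal steady-state curve**

    g(p̂) = p̂(K + p̂) / (p̂² + 2Kp̂ + K),

the machinery level that maximizes growth at a given precursor abundance.
The two parameterizations must agree identically; the package treats
g(p̂*_opt(E_M)) = α*_opt(E_M) to 1e-10 over E_M ∈ [0.01, 100] as a release
gate (it is also how the algebraic form of g was pinned down, since the two
routes uniquely determine each other given μ̂*_opt(p̂) = p̂²/(p̂²+2Kp̂+K)).
A brute-force 10⁴-point grid maximization over α serves as the independent
oracle for the closed form on random (E_M, K) draws.

## 3. Feedback strategies

Three static feedback laws satisfy the admissibility conditions (no
memory; a unique stable, non-trivial closed-loop steady state; that steady
state optimal):

* **nutrient-only** f(E_M) = α*_opt(E_M) — constant after the shift,
* **precursor-only** g(p̂) — follows the optimal curve,
* **on-off** h(p̂, r̂) — 0 above the curve, 1 below, α*_opt on the optimal
  point (relative point-matching tolerance 1e-6).

Biochemical surrogates: f is well approximated by a Michaelis–Menten curve
E_M/(E_M + K_mE) and g by a Hill curve p̂²/(p̂² + K_mp²). The constants
K_mE, K_mp are not free knobs of the theory, so they are least-squares
fitted once over documented domains (E_M ∈ [0.01, 10] geometric grid,
p̂ ∈ [0, 1] uniform grid) and cached; both approximations stay within 0.05
of the exact laws, and a 2× finer fitting grid moves the constants by <1%.

Closed-loop simulation always uses the continuous surrogate of h,
g(p̂)ⁿ/(g(p̂)ⁿ + r̂ⁿ) with n = 100 (exposed as a knob), evaluated in log
space. This sidesteps sliding-mode (Filippov) regularization on the switch
manifold. The surrogate's closed-loop equilibrium is offset from the exact
optimum by O(ln((1−r̂*)/r̂*)/n) — zero at E_M = 1 where r̂* = 1/2 — and a
test verifies the offset shrinks like 1/n. Tolerances asserted on on-off
convergence account for this bias rather than pretending integration
accuracy.

## 4. Closed-loop simulation

`simulate.integrate_closed_loop` integrates the augmented state
(p̂, r̂, ln Vol) with SciPy's implicit Radau method, rtol 1e-10 /
atol 1e-12 (the n = 100 switch makes the loop stiff), reporting on 2000
evenly spaced times. Carrying ln Vol as a state avoids re-quadrature of μ̂;
biomass ratios are formed in log space,
Vol/Vol_ref = exp(logVol − logVol_ref), with monotone interpolation when
grids differ. Halving the tolerances moves the final log-volume by < 1e-6.

The canonical upshift starts at the optimal steady state of
pre_factor·E_M (default 0.2) and integrates under the post-shift E_M over
t̂ ∈ [0, 30]. The horizon is a package choice (the transient completes by
t̂ ≈ 10–15); a test verifies the reported ratios are horizon-stable
(extending the horizon 1.5× changes them by < 1e-3). The
precursor-vs-nutrient biomass gain is likewise reported at the
horizon-stable final time: both loops converge to the same steady state, so
their log-volume difference is constant from t̂ ≈ 15 onward. Downshifts
(pre_factor > 1) are allowed but carry no tuned defaults.

## 5. The optimal control problem

Maximize J = ∫ μ̂ dt̂ with α(·) ∈ [0, 1]. The infinite-horizon (overtaking)
problem is truncated to τ̂ = 30 with the terminal state anchored to the
optimal steady state by a quadratic penalty (weight 1e4). The anchoring
removes the truncation artifact of dumping precursors just before τ̂: with
a weak anchor the optimizer trades ~2e-2 of terminal-state accuracy for
~1e-3 of objective; with the default weight the terminal state matches the
optimum to ~2e-5 and the solution grows at exactly μ̂*_opt once converged,
which is what makes biomass ratios horizon-stable.

**Solver.** The problem is discretized first and optimized second: the
control is piecewise constant on N intervals (default 1000; the
`fine_preset` uses 4000), states are propagated by fixed-step classical
RK4 (2 substeps per interval), and the gradient of J with respect to every
interval's α is computed by an exact discrete adjoint sweep through the
stored RK4 stages (numba-compiled kernels in `_shooting`; a test checks
the adjoint against finite differences). A projected quasi-Newton
iteration (L-BFGS-B) over the box [0,1]^N then converges to projected
gradient norms ~1e-7. The initial guess is the on-off closed-loop profile
(already ~98% optimal, with the right arc structure); the fallback is the
constant optimal allocation with a small seeded perturbation. Objective
changes under grid doubling are < 1e-5 relative.

A Hermite–Simpson collocation transcription of the same problem
(`transcribe`) provides the verification surface: a decision vector sampled
from an accurately simulated trajectory satisfies the defect constraints to
< 1e-8 and its Simpson-quadrature objective matches the integrated
log-volume to < 1e-6.

**Arc structure.** `classify_arcs` labels nodes bang-0/bang-1 within a band
ε_b = 0.05 of the bounds; a sustained intermediate run (≥ 5 nodes, flat,
near α*_opt) is the singular arc, while isolated intermediate cells between
bangs are grid-resolution transition cells absorbed into the switch time.
Halving ε_b moves switch times by less than two node spacings. On the
canonical upshift the solution is bang1 → bang0 → bang1 → singular with the
plateau at α = 0.5.

**Chattering is represented only up to grid resolution.** The true entry
into the singular arc involves infinitely many switches, but the arc
durations shrink super-geometrically here: switching-time optimization of
the explicit bang sequence shows the fourth bang arc is shorter than any
practical grid cell and its objective contribution lies below attainable
solver tolerances, so the computed control resolves two full alternations
and represents the remaining chattering as sub-grid, cell-averaged
(fractional) values decaying onto the plateau. This is a resolution limit
of every fixed-grid direct method on this problem, not of a particular
solver.

**Switching curve.** φ(p̂) is sampled by solving the problem from several
initial states bracketing the optimum and recording the state at each
bang-to-bang switch; chattering switches accumulate at the optimal steady
state, so the curve passes through it. An isotonic cleanup removes
O(node-spacing) jitter. Closing the loop on the estimated φ (with the same
smooth switch device) recovers the direct solution's biomass to well within
1%.

## 6. Growth-law fitting

`growth_laws` maps the closed-form optimum to the two measured growth laws:
across media (e_M varies, quasi-linear α–μ relation at high growth) and
within a medium under a translation inhibitor (k_R scaled down by a
per-dose multiplier, negatively sloped relation). The measured RNA/protein
ratio enters as r̂* = α*_opt = γ·ratio.

**Synthetic data.** The generator emulates the classical design: 6 media
(default e_M = 0.5…4.8 h⁻¹, spanning μ ≈ 0.4–1.7 h⁻¹ at k_R = 2.23 h⁻¹),
5 inhibitor doses as shared k_R multipliers (1, 0.8, 0.6, 0.45, 0.3),
multiplicative Gaussian noise (default 5% relative, matching typical
reported error bars) applied independently to rate and ratio, γ = 1.35
calibrated so ratios sit in the measured 0.1–0.5 range. Deterministic given
a seed. What it does **not** emulate: correlated errors between the two
coordinates, dose-dependent error growth, deviations of real cells from
exact growth-rate optimality, and any non-proportionality in the
RNA-to-machinery conversion — so passing recovery tests demonstrate the
estimator is consistent under the model's own assumptions, not that the
model is true.

**Loss.** The default loss is the summed squared *relative* residual of
predicted vs measured (μ, ratio) jointly, with free parameters
(k_R, γ, one e_M per medium, one multiplier per dose). Sharing each
medium's e_M across its dose series is what makes k_R identifiable: a
tempting shortcut — eliminating e_M per point by inverting the μ relation
and scoring only the ratio coordinate — discards that constraint and leaves
a nearly flat k_R·γ ridge along which noise pushes k_R to the search
bounds. The shortcut is retained as `loss="ratio_inversion"` for
comparison. Optimization: SciPy differential evolution (popsize 15×dim,
up to 500 generations, Sobol initialization, vectorized objective, recorded
seed) with an L-BFGS-B polish; bounds k_R ∈ [0.1, 20] h⁻¹, γ ∈ [0.1, 10],
e_M ∈ [0.01, 50] h⁻¹, dose multipliers ∈ (0.01, 1]. Noiseless synthetic
data is recovered to ~1e-4 relative; at 5% noise the median error over
seeded replicates is a few percent for k_R and γ. K is fixed, not fitted —
it is not identifiable from this data and is set from literature scales.

## 7. The reduced ppGpp read-out

The alarmone ppGpp rises when ribosomes stall on uncharged tRNA and
inhibits rRNA transcription — a one-molecule integrator of precursor
supply and ribosome demand. The reduction in `ppgpp` (quasi-steady-state
in the fast variables):

1. charging capacity follows the precursor pool with effective
   cooperativity, q(p̂) = p̂^H/(K_t^H + p̂^H) — a lumped description of the
   multi-step coupling between the amino-acid pool and charged-tRNA supply;
2. uncharged-tRNA fraction from the supply/demand balance,
   u = ρr̂/(q(p̂) + ρr̂);
3. RelA synthesis ∝ stalled ribosomes, S = k_syn·r̂·u; hydrolysis
   Michaelian with a small basal leak, V_max·G/(K_h + G) + k_basal·G.
   With K_h ≪ K_I the balance is zero-order ultrasensitive: G jumps when S
   approaches the hydrolysis capacity;
4. read-out α = K_I/(K_I + G).

A purely first-order sink cannot serve here: with the exponent-1 read-out
it caps ppGpp at k_syn·r̂/k_deg, which for small r̂ never reaches K_I, and
its response is Michaelian rather than switch-like.

**Calibration (run once, then frozen).** K_I = 50 µM, V_max = 1000 µM/h,
K_h = 0.1 µM, k_basal = 0.01 h⁻¹ and ρ = 0.01 set the scales; k_syn is
anchored so that α equals α*_opt exactly at the optimal steady state of
E_M = 1; the two shape constants (H ≈ 3.01, K_t ≈ 0.0704) minimize the
maximal deviation of the α = 0.5 locus from the optimal curve g over
p̂ ∈ [0.002, 0.12], keeping the locus within one default grid cell of g.
`calibrate_ppgpp_params()` reproduces the frozen defaults from scratch and
a test enforces that. The resulting surface is monotone in each argument,
switches over < 10% of g(p̂) in r̂ (10–90% width), and agrees with the
on-off surface on ≥ 95% of the default grid outside a 0.02 band around the
curve. Only the static
surface comparison is in scope; the ppGpp loop is not simulated
dynamically.

## 8. Key constants

| constant | default | units | meaning / why |
|---|---|---|---|
| E_M | 1.0 | — | reference rich medium (e_M = k_R) |
| K | 0.003 | — | βK_R at literature scales |
| pre_factor | 0.2 | — | poor-to-rich upshift magnitude |
| horizon τ̂ | 30 | — | transient over by t̂≈15; ratios horizon-stable |
| N | 1000 (4000 fine) | — | control intervals; J stable to 1e-5 under doubling |
| terminal weight | 1e4 | — | anchors terminal state to ~2e-5 |
| Hill n (on-off surrogate) | 100 | — | smoothing of the discontinuous law |
| ode rtol/atol | 1e-10 / 1e-12 | — | stiff switch; final log-vol stable to 1e-6 |
| k_R | 2.23 | 1/h | documented translation constant for growth-law curves |
| γ | 1.35 | — | RNA/protein → machinery-fraction conversion |
| DE settings | 15×dim, ≤500 gen, seed | — | recorded for reproducibility |

## 9. Known limitations

* No substrate depletion, degradation, maintenance or division — by model
  design.
* The chattering entry is resolved only to grid resolution (see §5); arc
  counts beyond two alternations are not meaningful for fixed-grid direct
  methods on this problem.
* The quantitative biomass ratios depend on the scenario (pre_factor,
  E_M, K); the *ordering* nutrient-only < precursor-only < on-off < optimal
  is the robust statement.
* Feedback strategies are costless: no resources are diverted to sensing
  or regulation, so ratios are upper bounds on what a real implementation
  could achieve.
* The ppGpp reduction is a minimal effective mechanism calibrated to the
  optimal curve; its constants are not fitted to kinetic measurements, and
  only the steady-state surface is compared.
* Growth-law fitting assumes cells sit exactly at the growth-optimal
  allocation in every condition; systematic suboptimality in real data
  would bias (k_R, γ).
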