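# Methods

## Model

The generalized repressilator is a cycle of `n` genes in which the protein
product of gene `j−1` represses transcription of gene `j` (1-based indices,
periodic boundary `p_0 ≡ p_n`).  Per gene, with mRNA `m_j` and protein `p_j`
as dimensionless concentrations and all rates in min⁻¹:

    dm_j/dt = c1 · H(p_{j−1}) − c2 · m_j
    dp_j/dt = c3 · m_j − c4 · p_j ,      H(p) = 1 / (1 + (p/K)^h)

Defaults are a Hill exponent `h = 2` and unit repression threshold `K = 1`;
both are configurable but every closed-form result quoted below (pitchfork at
c = 2, dimerized levels `p_u p_d = 1`, `p_u + p_d = c`) is specific to the
default form.  The dimensionless combination

    c = c1 · c3 / (c2 · c4)

controls the entire bifurcation structure: at a steady state all information
about the four rates enters only through `c`.  Parameter sweeps hold
`c2, c3, c4` fixed and move `c1`.

Two named parameter sets are built in: `table1` (c2 = 0.12, c3 = 0.16,
c4 = 0.06, c1 set through `c`), the family used for all bifurcation sweeps,
and `fig3` (n = 18, c1 = 2.6, c2 = 0.12, c3 = 0.2, c4 = 0.06, hence
c ≈ 72.2), the reference ring for induction, control and robustness studies.

Rates may be per-gene vectors (heterogeneous genes); the lumped `c` then
uses gene-averaged rates and is only approximate.

## Fixed points and mode reduction

The symmetric equilibrium solves `p_m (1 + p_m²) = c` (monotone cubic;
bracketed Brent root-finding on [0, max(c, 1)]).  Even rings additionally
have, for c ≥ 2, two "dimerized" equilibria alternating
`p_u = (c + √(c²−4))/2` and `p_d = (c − √(c²−4))/2` around the ring; odd
rings cannot close an alternating pattern, which is the origin of their
oscillation.

Because the ring is translation invariant, the 2n×2n Jacobian at the
symmetric point is block circulant and splits into n independent 2×2 modes;
mode k (phase θ = 2πk/n) has eigenvalues solving

    (λ + c2)(λ + c4) = c1 c3 H′(p_m) e^{−iθ} .

The real mode k = n/2 (even n) crosses zero at the pitchfork — exactly c = 2
for the default Hill form, independent of n.  Complex modes cross the
imaginary axis at Hopf points, each spawning a travelling-wave orbit branch;
crossings are located by a 600-point scan over c ∈ [0.001, 30] plus Brent
bisection (tolerance 1e−6 in c; conjugate modes k and n−k reported once,
tagged min(k, n−k)).  The mode reduction is verified in the test suite
against dense eigensolves at random parameter sets.

A note on published values: the θ = 2π/3 mode appears in three rings
(n = 6, 12, 18) of the reference sweep and is one mathematical quantity; the
package computes c* = 4.711 for it, and periods/locations of all other
crossings agree with the published table to printed precision.  Where the
historical table disagrees with itself at that mode (4.68 vs 4.71), the
computed value stands.

## Periodic orbits and Floquet analysis

Orbits are found by single shooting: solve `φ_T(y) − y = 0` with the section
`y[0] = const` (first mRNA pinned) for the 2n+1 unknowns (anchor, period).
Practical details that mattered:

- **Root solver.**  The closure system is solved with MINPACK's Powell
  dogleg (`scipy.optimize.root(method="hybr")`, xtol 1e−13).  The first
  branch carries one strongly unstable direction (|μ| ≈ 6 near emergence for
  n = 6), which makes a plain damped Newton overshoot and stall; the
  trust-region dogleg converges in a few dozen function evaluations.
- **Deflation.**  The symmetric fixed point satisfies the closure equations
  for *any* period and sits close to small-amplitude initial guesses; the
  residual is multiplied by `1 + σ/‖y − y_fp‖` so the solver cannot slide
  onto it, and a landing within 1e−4 of the fixed point is rejected.
- **Initial guesses.**  From a Hopf point: symmetric point plus
  `amplitude × Re(v_k)` with the mode-k eigenvector phase rotated so the
  m₁-displacement vanishes — the anchor then sits on a section the orbit
  must cross, at maximal transversality.  The default amplitude is 0.2
  because the first branch emerges steeply (at 5% above c* the orbit already
  lies at distance ≈ 0.8 from the fixed point; tiny guesses collapse onto
  the fixed point).  From a transient: integrate a seeded random state for
  ~20 reference periods and harvest the tail (works for the weakly unstable
  long rings; pointless for small n where escape is fast).
- **Monodromy.**  The variational equations `dΦ/dt = J(y(t))Φ` are
  integrated alongside the state with DOP853 at rtol 1e−11/atol 1e−13; the
  Floquet multipliers are the eigenvalues of Φ(T).  The trivial multiplier
  (closest to 1+0i) is excluded from stability counts; |μ| > 1 + 1e−6
  counts as unstable; quasi-stable ⇔ exactly one unstable direction.
- **Determinant identity.**  `det M = exp(−n(c2+c4)T)` since the Jacobian
  trace is constant.  For n ≥ 10 this is ~e^{−430} — far below what one
  fundamental-matrix determinant resolves in double precision — so the
  check is evaluated on the log scale with the fundamental matrix split
  into sub-interval factors (~10 nats of contraction each) whose
  `slogdet` values add exactly (the product telescopes).  Agreement is at
  the 1e−12 level.
- **Continuation.**  Natural-parameter stepping in c (default step 0.25,
  halved on failure, abort below 1e−4) with re-shooting from the previous
  anchor; a period jump above 20% is treated as a lost branch.  These
  branches have no folds in the ranges studied, so arclength continuation
  was not needed.

## Deterministic simulation and diagnostics

`solve_ivp` RK45 with rtol = tol, atol = tol/1000 (default tol 1e−8;
tight-tolerance orbit work uses DOP853 as above).  Piecewise-constant
induction signals restart the integrator exactly at each switching time, so
signal bookkeeping is event-exact.

Peak detection is `scipy.signal.find_peaks` with prominence ≥ 0.1 of the
trace's dynamic range.  An oscillation summary counts, per observed gene,
peaks whose prominence is both ≥ 25% of the gene's first peak (decaying
ring-down stops counting eventually) and ≥ 5% of the gene's mean level
(numerical ripples around a settled fixed point never count); *sustained*
means every observed gene reaches the requested count (default 5).

Waveform similarity is a normalized mean-square score in [0, 1]: the
reference's cycles (between consecutive peaks) are phase-resampled to 256
points and averaged; the test trace is cut into windows of one *reference*
period anchored at its own peaks, each min–max normalized; the score is
`1 − mean MSE / var(reference cycle)`, clipped to [0, 1].  Identical shapes
score 1 at any amplitude or phase; an aperiodic trace fills the windows with
unrelated structure and scores near 0.  (The originally reported similarity
statistic used an unspecified normalized mean-square measure; this
construction is the package's own and is documented as such.)

## Stochastic simulation

Gillespie's direct method on the 4n birth/death reactions, with propensities
`ω c1 H(P_{j−1}/ω)`, `c2 M_j`, `c3 M_j`, `c4 P_j`; ω (default 50) is the
copy-number scale, chosen so that traces are visibly noisy yet structured —
the original study says only "low copy numbers".  The inner loop is
numba-compiled; the legacy NumPy RNG inside the compiled core is seeded once
per trace, so traces are bit-reproducible, including across the chunked
closed-loop runs.  Traces are recorded on a uniform grid (piecewise-constant
interpolation of the jump process).

Noisy periods are estimated from the first positive-lag maximum (above 0.1,
prominence 0.05) of the autocorrelation of the moving-average-smoothed
protein count, with parabolic sub-grid refinement; the default smoothing
window is a tenth of the expected period.  Peak counting is not used at low
copy number.  Switching diagnostics classify each sample's protein vector by
distance to the two dimerized patterns, relative to the distance between the
patterns, leaving anything farther than 30% from both (travelling-wave
episodes) unclassified.

At ω = 50 the even-ring stochastic period tracks the deterministic
quasi-stable orbit within a few percent; the odd-ring period inflation
("slightly larger" in the source) is real but small at this ω (~0.2%), so
the corresponding test averages autocorrelation estimates over all genes of
20 long traces to resolve the sign.

## Control

Induction is an *additive* mRNA production term on one gene (light-driven
transcription), never a state clamp.  The open-loop STOP–KICK protocol,
with T the reference quasi-stable period: STOP on gene j for 1.5 T
(amplitude c1) → settle 0.5 T → KICK on gene j+1 for 0.5 T (amplitude c1) →
free run.  The STOP initializes the ring into the dimerized state with
gene j up regardless of history; the KICK launches the two-kink wave.  A
final STOP terminates the oscillation.

The closed-loop controller watches two adjacent proteins; when one falls
below threshold and its refractory time has elapsed, a KICK fires on that
gene.  Defaults (`ControllerConfig.for_period`): threshold 0.1 p_u, KICK
width T/4, refractory T — at most one kick per gene per cycle.  Wider kicks
with short refractory (e.g. width T/2, refractory = width) measurably
entrain the wave away from its natural period (−32% in deterministic runs),
violating the design goal that on-phase kicks perturb the period by < 5%;
the chosen defaults keep the shift at ~0.5–5%.  A terminating STOP also
disengages the threshold rule, because relaunching from rest is exactly the
controller's switch-on behaviour.  Readout delay (fluorophore maturation)
is an optional constant lag, default 0 — a few minutes against periods of
hundreds.

## Robustness analysis

Inducibility is probed over a hypercube of relative rate variations (±5, 10
or 20%) around a reference set, sampled with a reverse-radix-scrambled
Halton sequence (per-dimension van der Corput in the first d primes with the
digit permutation 0→0, d→b−d; RNG-free and reproducible; plain Halton
available as `scramble="none"`).  The default varies all 4n per-gene rates
independently; a 4-dimensional global mode is provided for identical genes.

The same fixed STOP–KICK protocol — timed and scaled at the *reference*
point — is applied to every sample, from a zero initial state, at
integration tolerance 1e−6; a sample is "induced at k" when every gene shows
at least k qualifying peaks after the KICK.  The reference period is
bootstrapped without RNG: the ring starts at its dimerized fixed point, one
KICK (width 0.9 × the linear wave-mode period 2π/Im λ_{n/2−1}) launches the
wave, and the settled tail yields the period and the reference cycle; if the
wave is short-lived (small rings) the decaying launch's inter-peak spacing
is used instead.  Reported: induced fraction per threshold, coefficient of
variation of induced periods, mean waveform similarity to the reference
cycle.

A scale caveat, measured with this package: at a few hundred samples in 4n
dimensions, the Halton bases larger than the sample count complete no full
cycle, so those marginals are biased and neighboring high-prime dimensions
are correlated; the ring-averaged rate dispersion then sits 2–3× above the
1/√n independence value and *grows* with ring length.  The induced fraction
is insensitive to this, but the decrease of the period CV with ring length —
a ~1% effect produced by per-gene averaging — is swamped by it and only
becomes resolvable at sample counts (≈10⁴) where every base cycles many
times.  The period-CV trend should therefore not be read off few-hundred-
sample runs.

The reference rate set for the cross-ring robustness comparison is the
18-gene reference set (c1 = 2.6, c2 = 0.12, c3 = 0.2, c4 = 0.06) for every
ring length: rates are gene-level properties and the genes are treated as
identical, so ring length is the only thing that varies along the trend.
At these rates the measured quasi-stable periods are ≈ 247, 314, 385, 449,
578 min for n = 8, 10, 12, 14, 18 — linear in n with the expected
half-slope of odd rings.  The documented trend checks (and the bundled
recomputation script) use 200 quasi-random samples per ring, which
reproduces the monotone trends with binomial uncertainty of a few percent;
the full-scale study would use 10⁴.

## Travelling-wave diagnostics

The per-gene distance `|Δp_j| = min(|p_u − p_j|, |p_d − p_j|)` vanishes on
the dimerized background and is large at a kink; kinks are contiguous
circular runs of `|Δp| > 0.25 (p_u − p_d)`, each reduced to its
delta-weighted circular centroid.  (For odd rings the levels come from the
two-gene system — the alternating pattern itself cannot close, which is why
the kink exists.)  Kink speed is the mean least-squares slope of
nearest-matched, circularly unwrapped kink tracks; frames where a kink core
briefly dips below threshold between toggles are skipped without resetting
the track.

Geometry worth stating because it is easy to get wrong: a passing kink
*toggles* a gene between the up and down levels, so successive upregulation
events advance by **two** ring positions.  In odd rings the single kink must
pass every gene twice per protein period (once up, once down): measured
speed × period = 2n.  In even rings the two indistinguishable kinks exchange
positions after half a revolution each: speed × period = n/2, and the
activation order consists of two interleaved step-2 trains (odd- and
even-indexed genes) moving in the same direction, with antipodal genes
nearly simultaneous.  The `sequential` flag of `activation_order` tests
exactly this structure.  Kink annihilation (two kinks colliding, returning
the even ring to the dimerized state) is what terminates the quasi-stable
transient.

## What the synthetic conditions do and do not show

All inputs are generated in-package: random initial states are uniform per
coordinate on [0, p_u] (the biologically occupied box), parameter samples
are quasi-random, and stochastic traces come from the exact jump process.
The model omits transcriptional leak, delays, cell growth/dilution,
extrinsic noise and promoter logic; passing tests therefore demonstrate
properties of the idealized ring circuit — attractor structure,
quasi-stability, switchability, robustness trends — not quantitative
predictions for a wet-lab implementation.  Test problem sizes (rings up to
n = 20, 50–200 robustness samples, 10–20 stochastic seeds) are chosen so the
full suite runs in minutes while keeping every qualitative conclusion
stable under resampling; the statistically marginal odd-ring period
inflation is the one check that needs the larger (20 × 30-period) ensemble.

## Known limitations

- Single shooting struggles for very long, very unstable orbits; the
  branches studied (n ≤ 18, first few branches) are well within its range.
- No fold/torus/period-doubling detection along branches; the studied
  branches terminate or leave the sweep range without such events.
- The robustness bootstrap assumes the reference ring supports (at least a
  short-lived) wave; far from the studied parameter region it will raise
  rather than silently report zeros.
- Per-gene heterogeneous rings lose the exact circulant reduction; only
  simulation-based analyses apply there.
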