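# Methods

## Scope and model

The package implements two experimental likelihood targets and the
optimization loop that uses them to refine structure predictions through
a differentiable predictor interface.

### Crystallographic target (LLGI)

Observed data are merged intensities `(Iobs, σI)` per Miller index.
Reflections are mapped to the reciprocal ASU (CCP4 convention via
gemmi), systematic absences removed, centric flags and epsilon factors
derived from the space-group operators, and equal-count resolution bins
built in `1/d³` order (default ≥ 60/bin; bins under 10 reflections are
merged with a neighbour for normalization statistics).

Effective amplitudes: the true normalized amplitude `E` has a Wilson
prior (acentric `2E·e^{−E²}`, centric `√(2/π)·e^{−E²/2}`); the intensity
likelihood is Gaussian.  Posterior mean `μ₁` and second moment `μ₂` are
computed per reflection by 64-point Gauss–Legendre quadrature over the
likelihood's support (`E² ∈ Iobs ± 8σI`, normalized units).  The
two-moment match to the effective-amplitude error model sets

    Dobs² = 1 + μ₁² − μ₂ ,   Ee = μ₁ / Dobs ,

then `Ee` is rescaled per bin to `⟨Ee²⟩ = 1`.  `Dobs = 1` exactly in the
zero-σI limit and is non-increasing in `σI`.  Because the paper-level
pipeline delegates this step to external preprocessing, this quadrature
construction is this package's own; its limiting behaviour and
monotonicity are what the rest of the pipeline relies on, and they are
tested directly.  Note the no-information limit of this construction is
`Dobs ≈ 0.89` (acentric), not 0: an unmeasured reflection still obeys
Wilson statistics.

The LLGI itself follows the Rice (acentric) and Woolfson (centric)
conditional densities stated in the README, evaluated through
numerically stable `ln I₀` (scaled Bessel) and `ln cosh` primitives.

### σA estimation

Per bin, `σA` maximizes the summed LLGI.  First and second derivatives
with respect to `σA` are analytic: with `t = Dobs·σA`, `u = 1 − t²`,
`X = Ee·EC`, `S = Ee² + EC²`, `r = I₁/I₀`,

    acentric: d ln p/dt = 2t/u − 2tS/u² + r(2tX/u)·2X(1+t²)/u²

and analogously with `tanh` for centric reflections; second derivatives
follow by another differentiation (`r' = 1 − r² − r/a`).  These formulas
are verified against finite differences in the tests.  The Newton step
is safeguarded: steps are capped at 0.25, non-concave curvature falls
back to a damped gradient-sign step, and every iterate is clamped to
`[0.015, 0.99]`.  Convergence at `|Δσ| < 1e−4` (≤ 50 iterations).
Refinement uses the work reflections.

### Cryo-EM target

Half maps are Fourier-transformed; terms inside the resolution cutoff on
a unique hemisphere are binned equal-count in `1/d³`.  Per shell,

    S = max(0, ⟨Re F₁F₂*⟩ − √(2/n)·N),   N = ⟨|F₁ − F₂|²⟩ / 4,

where `N` is the noise power of the averaged map and the `√(2/n)·N`
subtraction removes the expected sampling fluctuation of the cross term
in an n-term shell (without it, pure-noise shells would show spurious
`Dobs ≈ n^{−1/4}`; with signal present the correction is O(1/√n) and
negligible).  `Dobs = √(S/(S+N))`, equal to `√(2·FSC/(1+FSC))` — the
error factor appropriate to the *averaged* map rather than one half-map.
Observed amplitudes are normalized per shell to `⟨Ee²⟩ = 1`.

Model Fourier terms are computed by direct summation at the map
frequencies (no gridding), with phases conjugated to match the numpy FFT
sign convention.  The per-term LLG (README) is evaluated from complex
components (`Ee·Ecalc·cos Δφ = Ee·(Re F·cos φobs + Im F·sin φobs)/‖F‖`)
so phase gradients stay smooth.  σA per shell reuses the safeguarded
Newton machinery with the analytic derivatives of this target.

Anisotropic/directional noise modelling is out of scope; shells are
spherical.  X-ray form factors are used for the toy-scale cryo-EM path.

### Structure factors and normalization

Direct summation over atoms and symmetry operators with IT92 4-Gaussian
form factors (gemmi coefficients), isotropic Debye–Waller, occupancies,
hydrogens ignored by default.  This is exact and keeps gradients simple;
it is intended for ≤ ~500 atoms and ~10⁴ reflections (an FFT path is a
deliberate non-goal).  `EC = |Fc| / √(ε⟨|Fc|²/ε⟩_bin)`; the per-bin
means stay inside the autodiff graph so coordinate gradients include the
normalization response.  A two-parameter Babinet bulk-solvent factor
`(1 − k_sol·e^{−B_sol s²/4})` plus per-bin residual scaling is fitted by
least squares against the observed amplitudes when requested; the fitted
scales are treated as constants of the current model (EC is invariant to
per-bin scaling, so this only affects R factors).

R factors use the posterior-mean amplitudes and a variance-matching
scale `k = √(ΣFo²/ΣFc²)` on the work set — the convention under which an
uncorrelated model tends to the Wilson limit `2 − √2 ≈ 0.586`.

### Differentiation strategy

All gradients flow through a minimal reverse-mode autodiff tape over
numpy arrays (`autodiff.py`): elementwise arithmetic with broadcasting,
matmul, reductions, gather/scatter, segment sums for per-bin statistics,
and `ln I₀`/`ln cosh` primitives.  Ops applied to plain ndarrays
evaluate eagerly with no recording, so the same target code serves fast
numeric evaluation (line searches, Newton iterations) and gradient
computation.  Gradients are exact to machine precision (validated
against central differences down to FD roundoff).

Three quantities are deliberately *stop-gradients*: the pseudo-B values
(B factors are derived from confidence, not refined), the fitted scale
parameters, and the alignment/rigid-body pose within one iteration
(gradients to the bias are taken at the refined pose held fixed; at an
interior optimum of the pose the neglected term vanishes to first
order).  σA is re-estimated each iteration and likewise held fixed
during backpropagation.

### Geometry

pLDDT → pseudo-B via `B = (8π²/3)(1.5·e^{0.7−0.01·pLDDT})²`;
pseudo-B → weight by the three-branch rule (1 below 11.5 Å², linear to
0.5 at 40 Å², `0.5·e^{−(B−40)}` above), continuous at both breakpoints.
Weighted Kabsch uses weighted centroids and the SVD of the weighted
cross-covariance with determinant correction; a rank-deficient
(collinear) configuration raises an error.  Rigid-body refinement does
gradient ascent on the 6 pose parameters: at each step the rotation is
re-based at the current pose (axis-angle increment about the weighted
centroid, where the derivative is the exact cross-product formula), with
a backtracking line search that uses cheap value-only evaluations and
stops when the first-order expected gain drops below 1e−3 LLG units.
Domain lists (user-supplied residue ranges) are refined independently.

### Refinement loop

AdamW (β = 0.9/0.999, ε = 1e−8) with decoupled weight decay set to 0 —
a nonzero decay would pull the multiplicative bias toward 0 rather than
its neutral value 1.  Separate learning rates for `w` and `b`
(phase 1: 1.0 / 0.05; phase 2: 1e−3 both).  The L2 restraint is the
weighted *sum* of squared Cα distances (so its weight `ω = 1e−11` is
chain-length dependent, as documented).  Phase 1 runs three traces of
100 iterations at a 3 Å cutoff; traces beyond the first start from a
small seeded Gaussian jitter (σ = 0.02) on `b`, the package's choice for
the unspecified trace diversification (trace 0 is unjittered so a
zero-iteration run returns the unbiased prediction exactly).  Ties in
best-trace selection go to the lowest index.  Phase 2 runs up to 500
iterations at full resolution with `ω = 0` and early stop when the best
LLG improves by < 0.1 for 50 consecutive iterations.  The returned model
is the best-LLG iterate overall.  Given one master seed the whole run is
bitwise reproducible.

MSA subsample ranking scores each candidate profile (always including
the full profile) by one shot of predict → weighted Kabsch → rigid-body
refinement → σA → LLG and sorts descending; subsampling itself is
uniform over sequences (profiles by column frequency over the
23-category alphabet).

## Synthetic data and the toy predictor

The generator emulates the shapes and statistics of real inputs, not
their physics:

- **Toy models** are self-avoiding Cα traces (3.8 Å steps, ≥ 3.2 Å
  non-consecutive separation, compact bounding sphere), carbon atoms,
  B = 20 Å², in an orthorhombic cell with padding.  The default space
  group is P2₁2₁2₁ — non-polar, so the amplitude-only crystallographic
  likelihood determines all translations.
- **Reflections**: `I_true = |Fc|²` complete to `dmin`;
  `σI = noise_frac·(⟨I⟩_bin + I_true)/2`, Gaussian noise (not Poisson,
  for analytic tractability); 5% stratified test set.
- **Half-maps**: band-limited Gaussian-atom density plus independent
  white noise; the `snr` parameter is the per-half-map signal-to-noise
  power ratio in the `dmin` shell, so the half-map FSC there is
  `snr/(snr+1)`.
- **Profiles**: column frequencies of a synthetic 64-deep alignment with
  a dominant category per column; cluster 0 is the full alignment,
  further clusters random halves.
- **Toy predictor**: a *test double*, not a folding model.  Output =
  `base_coords + readout(δ)` where `δ` is the per-residue mean profile
  deviation from `m0` and `readout` is a fixed per-residue linear map
  `R²³ → R³` with bounded norm (≤ 5 Å at unit bias); pLDDT =
  `clip(100 − 10·‖displacement‖, 30, 100)`.  Linearity makes the loop's
  optimum identifiable, so recovery experiments are conclusive about the
  optimization machinery — and silent about whether a real network's
  highly non-convex profile→structure map would cooperate.  Passing
  tests therefore validate the targets, gradients, and schedule, not
  performance on real data.

The standard recovery benchmark: 50 residues, 2.0 Å data, 10% intensity
noise, predictor base coordinates displaced 1 Å rms from the truth with
the readout constructed so a bias exists that cancels the perturbation
exactly.  Problem sizes throughout (40–50 residues, ~1000–3000 unique
reflections, ~500 map terms) were chosen so every stage is exact-summation
tractable and the full five-seed benchmark completes in minutes on one
CPU core.

## Numerical choices

- Quadrature windows follow the likelihood support; adaptive reference
  integrations in the tests use breakpoints there (a plain adaptive rule
  can miss a near-delta posterior).
- `ln I₀` via `i0e`, `ln cosh` via `log1p(e^{−2|x|})`: no overflow to
  arguments ≥ 1e4.
- Degenerate inputs: non-positive σI, unknown elements/space groups,
  grid mismatches, hkl mismatches, < 3 effective alignment points, and
  `Dobs·σA ≥ 1` all raise explicit errors; empty normalization bins are
  an error, under-populated bins a warning plus merge.
- Work/test split by largest-remainder stratification per bin: global
  count within ±1 of the requested fraction, per-bin within ±2.

## Known limitations

- Direct summation scales as O(atoms × reflections); large structures
  need an FFT path that is out of scope here.
- The effective-amplitude construction is a stated stand-in for the
  external preprocessing used at paper scale; it matches that
  construction's intent (two-moment effective-amplitude model) but was
  not compared against the external implementation.
- Anomalous scattering, twinning, anisotropic ADPs, masked-solvent
  models, directional cryo-EM noise, and PAE-derived domain splitting
  are all out of scope.
- The pose and pseudo-B stop-gradients make each optimizer step an
  approximation to the fully differentiated loss; the end-to-end
  recovery tests show the approximation optimizes well on the toy
  system.
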