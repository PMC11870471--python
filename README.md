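# llgrad

Differentiable experimental-likelihood targets for structural model
refinement, and an inference-time optimization loop that steers a
structure predictor toward experimental data by biasing its MSA cluster
profile.

## The problem

Predicted protein structures often miss the conformation actually present
in a crystal or a cryo-EM map — flipped loops, shifted domains,
ligand-induced rearrangements.  Refining predictions directly in
Cartesian space struggles to cross the energy barriers between such
states.  An alternative is to keep the predictor fixed and optimize its
*input representation*: a multiplicative/additive bias `(w, b)` applied
to the MSA cluster profile `m0` (shape `[clusters x residues x 23]`), so
that the predicted structure maximizes the likelihood of the measured
data.  That requires experimental target functions that are (a) proper
likelihoods with an explicit treatment of measurement error and (b)
differentiable end-to-end with respect to atomic coordinates.

This package implements those targets and the surrounding machinery at
desk scale, with a pluggable predictor interface and a linear toy
predictor so the whole loop runs and is testable on one CPU without
trained network weights.

## The targets

**Crystallography** uses the log-likelihood gain on intensity (LLGI).
With `Ee` the effective observed normalized amplitude, `EC` the
calculated normalized amplitude, `Dobs ∈ [0,1]` the measurement-error
factor, `σA` the model-quality correlation per resolution bin, and
`t = Dobs·σA`, `u = 1 − t²`:

    acentric:  p(Ee;EC) = (2Ee/u) · exp(−(Ee² + t²EC²)/u) · I₀(2t·Ee·EC/u)
    centric:   p(Ee;EC) = √(2/(πu)) · exp(−(Ee² + t²EC²)/(2u)) · cosh(t·Ee·EC/u)
    LLGI = ln p(Ee;EC) − ln p(Ee)         (p(Ee): Wilson distribution)

`σA` is refined per bin by safeguarded Newton–Raphson on analytic
first/second derivatives, clamped to `[0.015, 0.99]`.  `Ee` and `Dobs`
come from a French–Wilson-style posterior of the Wilson prior given
`(Iobs, σI)`, computed by 64-point Gauss–Legendre quadrature.

**Cryo-EM** scores each Fourier term of the averaged half-map against the
model with

    LLG = 2t·Ee·Ecalc·cos Δφ / u − t²(Ee² + Ecalc²)/u − ln u

where the signal power per shell comes from the half-map cross-term,
noise from the half-map difference, and `Dobs = √(S/(S+N)) =
√(2·FSC/(1+FSC))`.

Structure factors are computed by direct summation over atoms and
space-group operators (4-Gaussian form factors, isotropic B), on a small
reverse-mode autodiff tape, so `d(LLG)/d(coords)` and the chain back to
the profile bias are exact.

## The loop

Per iteration: bias the profile, predict, convert pLDDT to pseudo-B
(`B = (8π²/3)(1.5·e^{0.7−0.01·pLDDT})²`), align to the reference by
confidence-weighted Kabsch, rigid-body-refine the pose against the LLG,
re-estimate `σA`, then take one AdamW step on `(w, b)` minimizing
`−LLG + ω·Σ wᵢ‖xᵢ − x_ref,i‖²`.  Phase 1 runs three traces at high
learning rates (1.0 / 0.05) with a 3 Å cutoff and `ω = 1e−11`; the
best-LLG trace seeds phase 2 (both learning rates 1e−3, full resolution,
no restraint, early stop when the LLG gains < 0.1 for 50 iterations).

## Worked example

```bash
python examples/04_profile_bias_refinement.py
```

prints (shortened schedule of the default protocol):

```
LLG: 34.3 (start) -> 1486.6 (best)
Ca RMSD to truth: 0.97 A (unbiased prediction) -> 0.05 A
Rwork/Rfree of the refined model: 0.280/0.332
```

The toy predictor's unbiased output is the ground truth displaced by
1 Å rms; optimizing the profile bias against simulated 2 Å diffraction
data recovers the truth to 0.05 Å and raises the data likelihood
accordingly.  The other examples demonstrate simulation and scoring
(`01`), half-map noise modelling (`02`), rigid-body pose recovery
(`03`), and likelihood ranking of MSA subsamples (`05`).

A thin CLI wraps the same functions: `llgrad simulate`, `llgrad sfcalc`,
`llgrad llg`, `llgrad refine` (see `llgrad --help`).

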