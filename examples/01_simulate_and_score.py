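"""Simulate a toy crystal, score the true model, and report R factors.

Builds a 40-residue Ca-trace model in a P212121 cell, simulates noisy
intensities to 2.2 A, derives effective amplitudes Ee and error factors
Dobs, refines sigmaA per resolution bin, and prints the total
log-likelihood gain plus Rwork/Rfree for the generating model.
"""

import numpy as np

from llgrad import synthetic
from llgrad.scatter import compute_structure_factors, normalize_to_E, \
    solvent_and_scale
from llgrad.xtal import llg_total, r_factors, refine_sigmaA

model = synthetic.make_toy_model(40, seed=7)
sym = synthetic.toy_cell(model, padding=4.0)
refls, binning = synthetic.simulate_reflections(model, sym, dmin=2.2,
                                                noise_frac=0.05, seed=7)
print(f"cell {tuple(float(x) for x in sym.unit_cell[:3])} {sym.space_group}; "
      f"{len(refls)} reflections in {binning.n_bins} bins, "
      f"{int(refls.is_test.sum())} in the free set")

sf = compute_structure_factors(model, sym, refls)
EC = normalize_to_E(sf, refls, binning)
sA = refine_sigmaA(refls, EC)
total = float(llg_total(refls, EC, sA))
sf_scaled, scale = solvent_and_scale(sf, refls, binning, fit_solvent=False)
rwork, rfree = r_factors(refls, sf_scaled)

print(f"LLG(work) = {total:.1f}  (~{total / refls.work.sum():.2f}/reflection)")
print("sigmaA per bin:", np.round(sA.values, 3))
print(f"Rwork = {rwork:.4f}  Rfree = {rfree:.4f}")
print("High sigmaA (near the 0.99 clamp) and low R say the model explains")
print("the simulated data up to the injected 5% intensity noise.")
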