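"""Shared fixtures: small simulated crystallographic problems.

Everything is generated programmatically; nothing is loaded from disk.
"""

import numpy as np
import pytest

from llgrad import synthetic
from llgrad.scatter import compute_structure_factors, normalize_to_E
from llgrad.xtal import refine_sigmaA


@pytest.fixture(scope="session")
def toy_problem():
    """40-residue toy model with P212121 data at 2.2 A, 5% noise."""
    model = synthetic.make_toy_model(40, seed=7)
    sym = synthetic.toy_cell(model, padding=4.0)
    refls, binning = synthetic.simulate_reflections(
        model, sym, dmin=2.2, noise_frac=0.05, seed=7)
    return model, sym, refls, binning


@pytest.fixture(scope="session")
def toy_problem_solved(toy_problem):
    """The toy problem plus EC and refined sigmaA for the true model."""
    model, sym, refls, binning = toy_problem
    sf = compute_structure_factors(model, sym, refls)
    EC = normalize_to_E(sf, refls, binning)
    sA = refine_sigmaA(refls, EC)
    return model, sym, refls, binning, sf, EC, sA


def rmsd(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
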