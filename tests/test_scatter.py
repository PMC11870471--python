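"""Structure factors: values, symmetry, scaling, normalization, gradients."""

import numpy as np
import pytest

from llgrad import autodiff as ad
from llgrad import synthetic
from llgrad.model import AtomicModel, FormFactorTable
from llgrad.reflections import ReflectionSet, make_bins
from llgrad.scatter import (add_fixed_partial, compute_structure_factors,
                            normalize_to_E, solvent_and_scale)
from llgrad.symmetry import CrystalSymmetry
from llgrad.xtal import llg_total


def _model(coords, b=15.0):
    coords = np.atleast_2d(coords)
    n = len(coords)
    return AtomicModel(coords=coords, element=np.array(["C"] * n),
                       occupancy=np.ones(n), b_iso=np.full(n, b))


def _refls(sym, dmin):
    hkl = synthetic.full_hkl_set(sym, dmin)
    refls = ReflectionSet(hkl=hkl, I_obs=np.zeros(len(hkl)),
                          sigma_I=np.ones(len(hkl)), d=sym.d_spacing(hkl))
    from llgrad.reflections import assign_centric_epsilon
    return assign_centric_epsilon(refls, sym)


def test_single_atom_at_origin():
    """One carbon at the origin in P1: Fc = f_C(s) exp(-B s^2/4), real."""
    sym = CrystalSymmetry((15, 15, 15, 90, 90, 90), "P 1")
    refls = _refls(sym, 3.0)
    model = _model(np.zeros((1, 3)), b=20.0)
    sf = compute_structure_factors(model, sym, refls)
    ff = FormFactorTable()
    stol2 = 1.0 / (4 * refls.d ** 2)
    expect = ff.evaluate("C", stol2) * np.exp(-20.0 * stol2)
    assert np.allclose(ad.value(sf.imag), 0.0, atol=1e-10)
    assert np.allclose(ad.value(sf.real), expect, rtol=1e-10)
    assert np.all(ad.value(sf.real) > 0)


def test_form_factor_f0_is_electron_count():
    ff = FormFactorTable()
    for el, z in (("C", 6), ("N", 7), ("O", 8), ("S", 16)):
        assert abs(ff.f0(el) - z) / z < 0.01


def test_unknown_element_errors():
    ff = FormFactorTable()
    with pytest.raises(ValueError, match="Xx"):
        ff.evaluate("Xx", np.array([0.01]))


def test_centrosymmetric_pair_real():
    sym = CrystalSymmetry((18, 18, 18, 90, 90, 90), "P 1")
    refls = _refls(sym, 3.0)
    x = np.array([2.3, -1.1, 0.7])
    sf = compute_structure_factors(_model(np.stack([x, -x])), sym, refls)
    assert np.allclose(ad.value(sf.imag), 0.0, atol=1e-9)


@pytest.mark.parametrize("sg", ["P 21", "P 21 21 21", "C 2"])
def test_symmetry_expansion_oracle(sg):
    """Fc in a symmetric group equals the P1 sum over expanded copies."""
    rng = np.random.default_rng(5)
    coords = rng.uniform(2, 10, size=(20, 3))
    sym = CrystalSymmetry((25, 26, 27, 90, 90, 90), sg)
    refls = _refls(sym, 2.5)
    sf = compute_structure_factors(_model(coords), sym, refls)

    p1 = CrystalSymmetry((25, 26, 27, 90, 90, 90), "P 1")
    orth, frac = sym.orth_matrix, sym.frac_matrix
    expanded = []
    for op in sym.sym_ops:
        xf = (frac @ coords.T).T
        expanded.append((orth @ (xf @ op.rot.T + op.tran).T).T)
    expanded = np.vstack(expanded)
    refls_p1 = ReflectionSet(hkl=refls.hkl, I_obs=refls.I_obs,
                             sigma_I=refls.sigma_I, d=refls.d)
    sf_p1 = compute_structure_factors(_model(expanded), p1, refls_p1)
    assert np.allclose(sf.f_complex, sf_p1.f_complex, rtol=1e-8, atol=1e-8)


def test_friedel_symmetry_p1():
    rng = np.random.default_rng(6)
    sym = CrystalSymmetry((20, 20, 20, 90, 90, 90), "P 1")
    hkl = rng.integers(-4, 5, size=(50, 3))
    hkl = hkl[np.any(hkl != 0, axis=1)]
    both = np.vstack([hkl, -hkl])
    refls = ReflectionSet(hkl=both, I_obs=np.zeros(len(both)),
                          sigma_I=np.ones(len(both)), d=sym.d_spacing(both))
    sf = compute_structure_factors(_model(rng.uniform(0, 15, (10, 3))),
                                   sym, refls)
    f = sf.f_complex
    n = len(hkl)
    assert np.allclose(f[:n], np.conj(f[n:]), rtol=1e-10)


def test_b_iso_increase_damps_amplitudes(toy_problem):
    model, sym, refls, _ = toy_problem
    f1 = compute_structure_factors(model, sym, refls).f_abs
    hot = model.with_coords(model.coords)
    hot.b_iso = model.b_iso + 30.0
    f2 = compute_structure_factors(hot, sym, refls).f_abs
    assert np.all(f2 < f1)


def test_coordinate_gradients_through_llg_chain(toy_problem_solved):
    """d(LLG)/d(coords) through scatter -> normalize -> LLGI vs FD."""
    model, sym, refls, binning, _, _, sA = toy_problem_solved

    def f(coords):
        sf = compute_structure_factors(model, sym, refls, coords=coords)
        EC = normalize_to_E(sf, refls, binning)
        return llg_total(refls, EC, sA)

    L, g = ad.grad(f, model.coords)
    rng = np.random.default_rng(0)
    eps = 1e-4
    for _ in range(6):
        i, j = rng.integers(len(model)), rng.integers(3)
        cp, cm = model.coords.copy(), model.coords.copy()
        cp[i, j] += eps
        cm[i, j] -= eps
        fd = (ad.value(f(cp)) - ad.value(f(cm))) / (2 * eps)
        assert abs(fd - g[i, j]) <= 1e-4 * abs(fd) + 1e-6


def test_b_factor_gradients(toy_problem_solved):
    """The chain also differentiates exactly with respect to b_iso."""
    model, sym, refls, binning, _, _, sA = toy_problem_solved

    def f(b):
        sf = compute_structure_factors(model, sym, refls, b_iso=b)
        EC = normalize_to_E(sf, refls, binning)
        return llg_total(refls, EC, sA)

    L, g = ad.grad(f, model.b_iso)
    eps = 1e-3
    for i in (0, 7, 19):
        bp, bm = model.b_iso.copy(), model.b_iso.copy()
        bp[i] += eps
        bm[i] -= eps
        fd = (ad.value(f(bp)) - ad.value(f(bm))) / (2 * eps)
        assert abs(fd - g[i]) <= 1e-4 * abs(fd) + 1e-8


def test_add_fixed_partial():
    sym = CrystalSymmetry((18, 18, 18, 90, 90, 90), "P 1")
    refls = _refls(sym, 3.0)
    rng = np.random.default_rng(7)
    sf_a = compute_structure_factors(_model(rng.uniform(0, 12, (6, 3))),
                                     sym, refls)
    sf_b = compute_structure_factors(_model(rng.uniform(0, 12, (4, 3))),
                                     sym, refls)
    zero = compute_structure_factors(
        AtomicModel(coords=np.zeros((1, 3)), element=np.array(["C"]),
                    occupancy=np.zeros(1), b_iso=np.ones(1)), sym, refls)
    # additive identities
    assert np.allclose(add_fixed_partial(sf_a, zero).f_complex,
                       sf_a.f_complex)
    assert np.allclose(add_fixed_partial(zero, sf_b).f_complex,
                       sf_b.f_complex)
    # triangle inequality on amplitudes
    tot = add_fixed_partial(sf_a, sf_b)
    assert np.all(tot.f_abs <= sf_a.f_abs + sf_b.f_abs + 1e-9)

    # gradients flow only through the moving part
    coords = rng.uniform(0, 12, (6, 3))
    model = _model(coords)

    def f(c):
        sf = compute_structure_factors(model, sym, refls, coords=c)
        out = add_fixed_partial(sf, sf_b)
        return ad.sum_(out.amplitude())

    _, g = ad.grad(f, coords)
    assert np.all(np.isfinite(g)) and np.any(g != 0)


def test_hkl_mismatch_errors():
    sym = CrystalSymmetry((18, 18, 18, 90, 90, 90), "P 1")
    r1, r2 = _refls(sym, 3.0), _refls(sym, 4.0)
    sf1 = compute_structure_factors(_model(np.ones((2, 3))), sym, r1)
    sf2 = compute_structure_factors(_model(np.ones((2, 3))), sym, r2)
    with pytest.raises(ValueError, match="hkl"):
        add_fixed_partial(sf1, sf2)


def test_solvent_recovery_and_scale_invariance(toy_problem):
    """Generate-then-fit recovers (k_sol, B_sol); EC ignores data scale."""
    model, sym, refls, binning = toy_problem
    from dataclasses import replace
    from llgrad.reflections import effective_amplitudes, split_work_test
    sf = compute_structure_factors(model, sym, refls)
    s2 = 1.0 / refls.d ** 2
    ftrue = 2.0 * sf.f_abs * (1 - 0.35 * np.exp(-46.0 * s2 / 4))
    noise_free = replace(refls, I_obs=ftrue ** 2,
                         sigma_I=np.maximum(1e-4 * ftrue ** 2, 1e-10))
    noise_free = effective_amplitudes(noise_free, binning)
    noise_free = split_work_test(noise_free, seed=1)
    _, scale = solvent_and_scale(sf, noise_free, binning)
    assert abs(scale.k_sol - 0.35) < 0.02
    assert abs(scale.b_sol - 46.0) < 2.0

    # k_sol = 0 -> pure per-bin rescaling
    _, scale0 = solvent_and_scale(sf, noise_free, binning, fit_solvent=False)
    assert scale0.k_sol == 0.0

    # multiplying I_obs by 4 changes the scale but not EC
    EC1 = ad.value(normalize_to_E(sf, refls, binning))
    scaled = replace(refls, I_obs=4 * refls.I_obs, sigma_I=4 * refls.sigma_I)
    scaled = effective_amplitudes(scaled, binning)
    EC2 = ad.value(normalize_to_E(sf, scaled, binning))
    assert np.allclose(EC1, EC2, rtol=1e-12)


def test_normalize_to_e_brute_force(toy_problem):
    """EC matches an independent two-pass reimplementation."""
    model, sym, refls, binning = toy_problem
    sf = compute_structure_factors(model, sym, refls)
    EC = ad.value(normalize_to_E(sf, refls, binning))
    famp = sf.f_abs
    eps = refls.epsilon.astype(float)
    expect = np.empty_like(famp)
    for b in range(binning.n_bins):
        m = refls.bin_id == b
        s = np.mean(famp[m] ** 2 / eps[m])
        expect[m] = famp[m] / np.sqrt(eps[m] * s)
    assert np.allclose(EC, expect, rtol=1e-9)
    # epsilon-weighted second moment is exactly 1 on the normalization set
    for b in range(binning.n_bins):
        m = refls.bin_id == b
        assert abs(np.mean(EC[m] ** 2) - 1.0) < 1e-9


def test_constant_amplitude_bin_gives_unit_E():
    sym = CrystalSymmetry((18, 18, 18, 90, 90, 90), "P 1")
    n = 40
    hkl = np.column_stack([np.arange(1, n + 1), np.zeros(n, int),
                           np.zeros(n, int)])
    refls = ReflectionSet(hkl=hkl, I_obs=np.ones(n), sigma_I=np.ones(n),
                          d=np.linspace(9, 8, n),
                          epsilon=np.ones(n, int),
                          centric=np.zeros(n, bool))
    binning = make_bins(refls, target_per_bin=n)
    from llgrad.scatter import StructureFactorSet
    sf = StructureFactorSet(hkl=hkl, d=refls.d, real=np.full(n, 3.7),
                            imag=np.zeros(n))
    EC = ad.value(normalize_to_E(sf, refls, binning))
    assert np.allclose(EC, 1.0, rtol=1e-9)
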