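"""Symmetry attributes, reflection I/O, binning, and Ee/Dobs posteriors."""

import numpy as np
import pytest
from scipy.integrate import quad

import gemmi
from llgrad.reflections import (ReflectionSet, assign_centric_epsilon,
                                effective_amplitudes, make_bins,
                                read_reflections, split_work_test, write_mtz)
from llgrad.symmetry import CrystalSymmetry
from llgrad import synthetic

SGS = ["P 1", "P -1", "P 21", "P 21 21 21", "C 2", "P 2 2 2"]


@pytest.mark.parametrize("sg", SGS)
def test_group_closure(sg):
    sym = CrystalSymmetry((30, 40, 50, 90, 90 if "C" not in sg else 100, 90), sg)
    assert sym.check_group_closure()


@pytest.mark.parametrize("sg", SGS)
def test_centric_epsilon_match_gemmi(sg):
    """Own sym-op implementation agrees with gemmi's tabulated flags."""
    sym = CrystalSymmetry((30, 40, 50, 90, 90, 90), sg)
    rng = np.random.default_rng(0)
    hkl = rng.integers(-6, 7, size=(200, 3))
    hkl = hkl[np.any(hkl != 0, axis=1)]
    ops = gemmi.SpaceGroup(sg).operations()
    cen_gemmi = np.array([ops.is_reflection_centric(h.tolist()) for h in hkl])
    eps_gemmi = np.array([ops.epsilon_factor(h.tolist()) for h in hkl])
    assert np.array_equal(sym.centric_flags(hkl), cen_gemmi)
    assert np.array_equal(sym.epsilon_factors(hkl), eps_gemmi)


def test_centric_special_cases():
    p1 = CrystalSymmetry((20, 25, 30, 80, 85, 95), "P 1")
    hkl = np.array([[1, 2, 3], [0, 1, 0], [-2, 4, 1]])
    assert not p1.centric_flags(hkl).any()
    assert np.array_equal(p1.epsilon_factors(hkl), [1, 1, 1])
    pbar1 = CrystalSymmetry((20, 25, 30, 80, 85, 95), "P -1")
    assert pbar1.centric_flags(hkl).all()
    p222 = CrystalSymmetry((20, 25, 30, 90, 90, 90), "P 2 2 2")
    assert p222.epsilon_factors(np.array([[3, 0, 0]]))[0] == 2


def test_systematic_absences_brute_force():
    """Phase-shift criterion: 2_1 along c makes (0,0,odd) absent in P212121."""
    sym = CrystalSymmetry((20, 25, 30, 90, 90, 90), "P 21 21 21")
    assert sym.is_absent(np.array([[0, 0, 1]]))[0]
    assert not sym.is_absent(np.array([[0, 0, 2]]))[0]
    assert not sym.is_absent(np.array([[1, 2, 3]]))[0]
    # cross-check a batch against gemmi
    rng = np.random.default_rng(1)
    hkl = rng.integers(-5, 6, size=(100, 3))
    ops = sym.gemmi_sg.operations()
    expect = np.array([ops.is_systematically_absent(h.tolist()) for h in hkl])
    assert np.array_equal(sym.is_absent(hkl), expect)


def test_mtz_roundtrip(tmp_path, toy_problem):
    """Write-then-read returns identical hkl, I, sigma."""
    model, sym, refls, binning = toy_problem
    path = tmp_path / "toy.mtz"
    write_mtz(path, refls, sym)
    back, sym2 = read_reflections(path)
    order_a = np.lexsort(refls.hkl.T)
    order_b = np.lexsort(back.hkl.T)
    assert np.array_equal(refls.hkl[order_a], back.hkl[order_b])
    assert np.allclose(refls.I_obs[order_a], back.I_obs[order_b], rtol=1e-6)
    assert np.allclose(refls.sigma_I[order_a], back.sigma_I[order_b], rtol=1e-6)
    assert sym2.space_group.replace(" ", "") == sym.space_group.replace(" ", "")


def test_absent_reflection_removed_on_read(tmp_path):
    """A systematically absent (0,0,1) in P212121 is dropped by the reader."""
    sym = CrystalSymmetry((20, 25, 30, 90, 90, 90), "P 21 21 21")
    hkl = np.array([[0, 0, 1], [0, 0, 2], [1, 1, 1]])
    refls = ReflectionSet(hkl=hkl, I_obs=np.array([5.0, 6.0, 7.0]),
                          sigma_I=np.ones(3), d=sym.d_spacing(hkl))
    path = tmp_path / "abs.mtz"
    write_mtz(path, refls, sym)
    back, _ = read_reflections(path)
    assert len(back) == 2
    assert not any((back.hkl == [0, 0, 1]).all(axis=1))


def test_amplitude_only_file_errors(tmp_path):
    """A file without intensity columns raises and names what is available."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.set_cell_for_all(gemmi.UnitCell(20, 20, 20, 90, 90, 90))
    mtz.add_dataset("d")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    mtz.set_data(np.array([[1.0, 2.0, 3.0, 10.0, 1.0]]))
    path = tmp_path / "amponly.mtz"
    mtz.write_to_file(str(path))
    with pytest.raises(ValueError, match="F"):
        read_reflections(path)


def test_refln_cif_reading(tmp_path):
    cif_text = """data_test
_cell.length_a 20.0
_cell.length_b 25.0
_cell.length_c 30.0
_cell.angle_alpha 90.0
_cell.angle_beta 90.0
_cell.angle_gamma 90.0
_symmetry.space_group_name_H-M 'P 21 21 21'
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.intensity_meas
_refln.intensity_sigma
1 1 1 100.0 5.0
0 0 2 50.0 2.0
0 0 1 10.0 1.0
"""
    path = tmp_path / "r.cif"
    path.write_text(cif_text)
    refls, sym = read_reflections(path, dialect="cif")
    assert len(refls) == 2  # (0,0,1) absent
    assert sym.space_group == "P 21 21 21"


@pytest.mark.parametrize("n,target,expect_bins", [
    (1000, 100, 10), (30, 100, 1)])
def test_make_bins_counts(n, target, expect_bins):
    rng = np.random.default_rng(0)
    d = np.sort(rng.uniform(2.0, 20.0, size=n))[::-1]
    refls = ReflectionSet(hkl=np.zeros((n, 3), int), I_obs=np.ones(n),
                          sigma_I=np.ones(n), d=d)
    binning = make_bins(refls, target_per_bin=target)
    assert binning.n_bins == expect_bins
    counts = np.bincount(refls.bin_id, minlength=binning.n_bins)
    assert counts.sum() == n
    if expect_bins > 1:
        assert np.all(counts == n // expect_bins)
    # bins ordered by decreasing d
    for b in range(binning.n_bins - 1):
        assert refls.d[refls.bin_id == b].min() >= refls.d[refls.bin_id == b + 1].max() - 1e-12


def test_make_bins_remainder():
    rng = np.random.default_rng(1)
    n = 1049
    d = rng.uniform(2.0, 20.0, size=n)
    refls = ReflectionSet(hkl=np.zeros((n, 3), int), I_obs=np.ones(n),
                          sigma_I=np.ones(n), d=d)
    binning = make_bins(refls, target_per_bin=100)
    counts = np.bincount(refls.bin_id, minlength=binning.n_bins)
    assert binning.n_bins == 10
    assert np.all(np.abs(counts - 105) <= 5)
    # assignment rule maps every reflection to exactly one bin
    assert np.array_equal(np.sort(np.unique(refls.bin_id)),
                          np.arange(binning.n_bins))


def test_split_work_test_properties():
    rng = np.random.default_rng(2)
    n = 2000
    d = rng.uniform(2.0, 20.0, size=n)
    refls = ReflectionSet(hkl=np.zeros((n, 3), int), I_obs=np.ones(n),
                          sigma_I=np.ones(n), d=d)
    make_bins(refls, target_per_bin=200)
    out1 = split_work_test(refls, fraction=0.05, seed=11)
    out2 = split_work_test(refls, fraction=0.05, seed=11)
    assert abs(out1.is_test.sum() - 100) <= 1
    assert np.array_equal(out1.is_test, out2.is_test)  # determinism
    for b in np.unique(refls.bin_id):
        m = refls.bin_id == b
        assert abs(out1.is_test[m].sum() - 0.05 * m.sum()) <= 2


def test_effective_amplitudes_zero_sigma_limit():
    """sigma_I -> 0: Ee -> sqrt(I / eps <I/eps>), Dobs -> 1."""
    rng = np.random.default_rng(3)
    n = 800
    E = np.abs(rng.normal(size=n) + 1j * rng.normal(size=n)) / np.sqrt(2)
    I = E ** 2
    refls = ReflectionSet(hkl=np.zeros((n, 3), int), I_obs=I,
                          sigma_I=np.full(n, 1e-9), d=np.linspace(10, 2, n),
                          centric=np.zeros(n, bool), epsilon=np.ones(n, int))
    binning = make_bins(refls, target_per_bin=400)
    out = effective_amplitudes(refls, binning)
    assert np.all(np.abs(out.Dobs - 1.0) < 1e-6)
    for b in range(binning.n_bins):
        m = out.bin_id == b
        expect = np.sqrt(I[m] / np.mean(I[m]))
        expect /= np.sqrt(np.mean(expect ** 2))
        assert np.allclose(out.Ee[m], expect, rtol=1e-5)


def test_effective_amplitudes_negative_intensity():
    """Slightly negative I with large sigma gives finite positive Ee."""
    n = 60
    I = np.full(n, -0.5)
    I[: n // 2] = 2.0  # anchor the bin normalization
    refls = ReflectionSet(hkl=np.zeros((n, 3), int), I_obs=I,
                          sigma_I=np.full(n, 1.5), d=np.linspace(8, 7, n),
                          centric=np.zeros(n, bool), epsilon=np.ones(n, int))
    binning = make_bins(refls, target_per_bin=n)
    out = effective_amplitudes(refls, binning)
    assert np.all(np.isfinite(out.Ee))
    assert np.all(out.Ee > 0)
    assert np.all((out.Dobs >= 0) & (out.Dobs <= 1))


def test_dobs_monotone_in_sigma():
    """Doubling sigma_I at fixed I_obs cannot increase Dobs."""
    n = 400
    rng = np.random.default_rng(4)
    I = rng.chisquare(2, size=n)
    base = dict(hkl=np.zeros((n, 3), int), d=np.linspace(9, 8, n),
                centric=np.zeros(n, bool), epsilon=np.ones(n, int))
    results = []
    for s in (0.1, 0.2):
        refls = ReflectionSet(I_obs=I, sigma_I=np.full(n, s), **base)
        binning = make_bins(refls, target_per_bin=n)
        results.append(effective_amplitudes(refls, binning).Dobs)
    assert np.all(results[1] <= results[0] + 1e-9)


def test_posterior_moments_vs_adaptive_quadrature():
    """64-point Gauss-Legendre matches scipy adaptive integration."""
    from llgrad.reflections import _wilson_posterior_moments
    cases = [(1.3, 0.4, False), (-0.2, 0.8, False), (2.5, 0.05, False),
             (0.7, 0.3, True), (-0.5, 1.2, True)]
    I_n = np.array([c[0] for c in cases])
    s_n = np.array([c[1] for c in cases])
    cen = np.array([c[2] for c in cases])
    mu1, mu2 = _wilson_posterior_moments(I_n, s_n, cen)
    for i, (In, sn, c) in enumerate(cases):
        def integrand(E, k):
            prior = (np.sqrt(2 / np.pi) * np.exp(-E ** 2 / 2) if c
                     else 2 * E * np.exp(-E ** 2))
            return E ** k * prior * np.exp(-0.5 * ((In - E ** 2) / sn) ** 2)

        # breakpoints at the likelihood support keep the adaptive rule
        # from missing a narrow posterior spike
        pts = sorted({np.sqrt(max(In - 8 * sn, 0.0)),
                      np.sqrt(max(In, 0.0)),
                      np.sqrt(max(In, 0.0) + 8 * sn)})
        kw = dict(limit=400, points=pts)
        z = quad(integrand, 0, 8, args=(0,), **kw)[0]
        m1 = quad(integrand, 0, 8, args=(1,), **kw)[0] / z
        m2 = quad(integrand, 0, 8, args=(2,), **kw)[0] / z
        assert abs(mu1[i] - m1) < 1e-6
        assert abs(mu2[i] - m2) < 1e-6


def test_per_bin_normalization_on_wilson_data(toy_problem):
    """After effective_amplitudes, per-bin <Ee^2> is 1 within 10%."""
    _, _, refls, binning = toy_problem
    for b in range(binning.n_bins):
        m = refls.bin_id == b
        assert 0.9 < np.mean(refls.Ee[m] ** 2) < 1.1


def test_nonpositive_sigma_errors():
    refls = ReflectionSet(hkl=np.zeros((20, 3), int), I_obs=np.ones(20),
                          sigma_I=np.zeros(20), d=np.linspace(9, 8, 20),
                          centric=np.zeros(20, bool),
                          epsilon=np.ones(20, int))
    binning = make_bins(refls, target_per_bin=20)
    with pytest.raises(ValueError, match="sigma_I"):
        effective_amplitudes(refls, binning)
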