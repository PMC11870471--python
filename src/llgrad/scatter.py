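"""Differentiable structure factors by direct summation.

F(h) = sum_ops sum_atoms occ * f(s) * exp(-B s^2 / 4) * exp(2 pi i h . (R x + t))

evaluated over the atoms of an :class:`AtomicModel` and the symmetry
operations of the crystal.  Coordinates (and optionally B factors) may be
:class:`autodiff.Var` nodes, in which case every downstream scalar obtains
exact first derivatives with respect to them.  Direct summation (no FFT)
is exact and keeps the gradients trivial; it is intended for the
desk-scale regime (hundreds of atoms, thousands of reflections).

Amplitude normalization (EC), per-bin scaling against the observations and
a two-parameter Babinet bulk-solvent correction live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import autodiff as ad
from .model import AtomicModel, FormFactorTable
from .reflections import ReflectionSet, ResolutionBinning
from .symmetry import CrystalSymmetry

__all__ = [
    "StructureFactorSet", "compute_structure_factors", "add_fixed_partial",
    "solvent_and_scale", "normalize_to_E", "ScaleModel",
]

_FF = FormFactorTable()


@dataclass
class StructureFactorSet:
    """hkl-aligned complex Fourier coefficients, held as real/imag parts.

    ``real``/``imag`` are ndarrays or autodiff Vars; use :meth:`amplitude`
    (graph-aware) or the numeric convenience properties.
    """

    hkl: np.ndarray
    d: np.ndarray
    real: object
    imag: object

    def amplitude(self, floor: float = 1e-12):
        return ad.sqrt(ad.square(self.real) + ad.square(self.imag) + floor)

    @property
    def f_complex(self) -> np.ndarray:
        return ad.value(self.real) + 1j * ad.value(self.imag)

    @property
    def f_abs(self) -> np.ndarray:
        return np.abs(self.f_complex)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.f_complex)


def compute_structure_factors(model: AtomicModel, sym: CrystalSymmetry,
                              refls: ReflectionSet, coords=None, b_iso=None,
                              ignore_hydrogens: bool = True,
                              conjugate: bool = False) -> StructureFactorSet:
    """Direct-summation structure factors.

    ``coords`` (n_atoms, 3 orthogonal Angstrom) and ``b_iso`` may be Vars to
    obtain gradients; they default to the model's arrays.  ``conjugate``
    negates all phases (used for matching the numpy FFT sign convention of
    map Fourier terms).
    """
    coords = model.coords if coords is None else coords
    b_iso = model.b_iso if b_iso is None else b_iso
    hkl = refls.hkl.astype(float)
    d = refls.d
    stol2 = 1.0 / (4.0 * d ** 2)

    keep = np.ones(len(model), dtype=bool)
    if ignore_hydrogens:
        keep = np.asarray(model.element) != "H"
    kidx = np.nonzero(keep)[0]
    # per-(reflection, atom) weights: occ * f(s) * Debye-Waller
    w0 = np.empty((len(hkl), len(kidx)))
    occ = model.occupancy[keep]
    for el in np.unique(model.element[keep]):
        m = np.asarray(model.element[keep]) == el
        f = _FF.evaluate(str(el), stol2)
        w0[:, m] = f[:, None]
    w0 = w0 * occ[None, :]
    b_k = ad.take(b_iso, kidx) if ad.is_var(b_iso) else np.asarray(b_iso)[keep]
    dw = ad.exp(ad.mul(-stol2[:, None], ad.reshape(b_k, (1, len(kidx)))
                       if ad.is_var(b_k) else b_k[None, :]))
    w = ad.mul(w0, dw)

    if ad.is_var(coords):
        coords_k = ad.take(coords, kidx)
    else:
        coords_k = np.asarray(coords)[keep]
    frac = ad.matmul(coords_k, sym.frac_matrix.T)  # (n_atoms, 3)

    sign = -1.0 if conjugate else 1.0
    A = 0.0
    B = 0.0
    for op in sym.sym_ops:
        hR = hkl @ op.rot  # (n_refl, 3)
        shift = 2.0 * np.pi * (hkl @ op.tran)  # (n_refl,)
        phase = ad.add(ad.mul(2.0 * np.pi, ad.transpose(
            ad.matmul(frac, hR.T))), shift[:, None])  # (n_refl, n_atoms)
        phase = ad.mul(sign, phase)
        s_ph, c_ph = ad.sincos(phase)
        A = ad.add(A, ad.sum_(ad.mul(w, c_ph), axis=1))
        B = ad.add(B, ad.sum_(ad.mul(w, s_ph), axis=1))
    return StructureFactorSet(hkl=refls.hkl, d=d, real=A, imag=B)


def add_fixed_partial(sf: StructureFactorSet,
                      sf_fixed: StructureFactorSet) -> StructureFactorSet:
    """Complex sum with a fixed contribution (no gradients through it)."""
    if sf.hkl.shape != sf_fixed.hkl.shape or np.any(sf.hkl != sf_fixed.hkl):
        raise ValueError("hkl sets differ between moving and fixed parts")
    return StructureFactorSet(hkl=sf.hkl, d=sf.d,
                              real=ad.add(sf.real, ad.value(sf_fixed.real)),
                              imag=ad.add(sf.imag, ad.value(sf_fixed.imag)))


@dataclass
class ScaleModel:
    k_bin: np.ndarray        # per-bin isotropic scale on amplitudes
    k_sol: float
    b_sol: float

    def solvent_factor(self, d: np.ndarray) -> np.ndarray:
        s2 = 1.0 / d ** 2
        return 1.0 - self.k_sol * np.exp(-self.b_sol * s2 / 4.0)


def solvent_and_scale(sf: StructureFactorSet, refls: ReflectionSet,
                      binning: ResolutionBinning,
                      fit_solvent: bool = True) -> tuple[StructureFactorSet, ScaleModel]:
    """Scale |Fc| to the observed amplitudes; optional Babinet solvent term.

    The Babinet correction multiplies Fc by (1 - k_sol exp(-B_sol s^2/4)),
    fitted with an overall scale by least squares on the work reflections,
    followed by a per-bin residual scale.  The fitted factors are treated
    as constants of the current model (no gradients through the fit).
    """
    if refls.F_obs is None:
        raise ValueError("effective_amplitudes must run first (needs F_obs)")
    famp = np.abs(ad.value(sf.real) + 1j * ad.value(sf.imag))
    work = refls.work
    fo = refls.F_obs[work]
    fc = np.maximum(famp[work], 1e-12)
    s2 = 1.0 / refls.d[work] ** 2

    if fit_solvent:
        def resid(p):
            k, ks, bs = p
            return np.log(np.maximum(k * fc * np.abs(1.0 - ks * np.exp(-bs * s2 / 4.0)),
                                     1e-12)) - np.log(np.maximum(fo, 1e-12))

        k0 = np.sum(fo * fc) / np.sum(fc * fc)
        fit = least_squares(resid, x0=[max(k0, 1e-6), 0.2, 50.0],
                            bounds=([1e-9, 0.0, 1.0], [np.inf, 0.95, 500.0]))
        k_all, k_sol, b_sol = fit.x
    else:
        k_all = np.sum(fo * fc) / np.sum(fc * fc)
        k_sol, b_sol = 0.0, 0.0

    sol = 1.0 - k_sol * np.exp(-b_sol / (4.0 * refls.d ** 2))
    scaled_abs = k_all * famp * np.abs(sol)
    # per-bin residual scale from work reflections
    k_bin = np.ones(binning.n_bins)
    for b in range(binning.n_bins):
        m = work & (refls.bin_id == b)
        if m.sum() >= 3:
            k_bin[b] = (np.sum(refls.F_obs[m] * scaled_abs[m])
                        / max(np.sum(scaled_abs[m] ** 2), 1e-12))
    factor = k_all * np.abs(sol) * k_bin[refls.bin_id]
    out = StructureFactorSet(hkl=sf.hkl, d=sf.d,
                             real=ad.mul(sf.real, factor),
                             imag=ad.mul(sf.imag, factor))
    return out, ScaleModel(k_bin=k_bin, k_sol=float(k_sol), b_sol=float(b_sol))


def normalize_to_E(sf: StructureFactorSet, refls: ReflectionSet,
                   binning: ResolutionBinning):
    """Normalized calculated amplitudes EC = |Fc| / sqrt(eps <|Fc|^2/eps>_bin).

    Returns a Var (or ndarray) aligned with ``refls``; per-bin
    <EC^2/eps> = 1 by construction.  The per-bin means stay inside the
    computation graph, so gradients include the normalization response.
    """
    if refls.bin_id is None or refls.epsilon is None:
        raise ValueError("bins and epsilon factors must be assigned")
    counts = np.bincount(refls.bin_id, minlength=binning.n_bins)
    if np.any(counts == 0):
        raise ValueError("empty resolution bin in normalization")
    eps = refls.epsilon.astype(float)
    amp = sf.amplitude()
    f2e = ad.div(ad.square(amp), eps)
    mean2 = ad.div(ad.segment_sum(f2e, refls.bin_id, binning.n_bins),
                   counts.astype(float))
    denom = ad.sqrt(ad.mul(eps, ad.take(mean2, refls.bin_id)))
    return ad.div(amp, denom)
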