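"""Cryo-EM Fourier-term log-likelihood-gain with half-map noise modelling.

Signal and noise power are estimated per resolution bin from the two
half-maps: the signal from the correlation of their Fourier terms and the
noise from their differences,

    S = max(0, <Re F1 conj(F2)>),   N = <|F1 - F2|^2> / 4,

where N is the noise power of the averaged map Fobs = (F1 + F2)/2.  The
per-term error factor is Dobs = sqrt(S / (S + N)) (equivalently
sqrt(2 FSC / (1 + FSC)) in terms of the half-map Fourier shell
correlation), applied bin-wise.  For a single Fourier term the LLG is

    LLG = 2 t Ee Ecalc cos(dphi) / u - t^2 (Ee^2 + Ecalc^2) / u - ln u

with t = Dobs sigmaA, u = 1 - t^2 and dphi the observed-vs-calculated
phase difference.  sigmaA per bin is refined with the same safeguarded
Newton machinery as the crystallographic target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .model import AtomicModel
from .reflections import ReflectionSet
from .scatter import compute_structure_factors
from .symmetry import CrystalSymmetry
from .xtal import SIGMAA_MAX, SIGMAA_MIN, SigmaABins

__all__ = [
    "FourierMapData", "estimate_signal_noise", "cryoem_llg_term",
    "estimate_sigmaA_cryoem", "cryoem_llg_total", "model_map_terms",
]


@dataclass
class FourierMapData:
    """Per-Fourier-term cryo-EM observations inside the resolution cutoff."""

    hkl: np.ndarray            # (n, 3) integer box frequencies (hemisphere)
    d: np.ndarray              # (n,) resolution, Angstrom
    Ee: np.ndarray             # (n,) normalized observed amplitude
    phi_obs: np.ndarray        # (n,) observed phase, radians
    Dobs: np.ndarray           # (n,) error factor in [0, 1]
    bin_id: np.ndarray         # (n,)
    n_bins: int
    box: tuple                 # (a, b, c) box edge lengths, Angstrom
    signal: np.ndarray = None  # per-bin signal power
    noise: np.ndarray = None   # per-bin noise power (averaged map)
    fsc: np.ndarray = None     # per-bin half-map FSC
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def sym(self) -> CrystalSymmetry:
        a, b, c = self.box
        return CrystalSymmetry((a, b, c, 90.0, 90.0, 90.0), "P 1")


def _box_frequencies(shape, box, dmin):
    """Unique-hemisphere integer frequencies with d >= dmin."""
    na, nb, nc = shape
    a, b, c = box
    h = np.fft.fftfreq(na, 1.0 / na).astype(int)
    k = np.fft.fftfreq(nb, 1.0 / nb).astype(int)
    l = np.fft.fftfreq(nc, 1.0 / nc).astype(int)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    s2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    with np.errstate(divide="ignore"):
        d = 1.0 / np.sqrt(s2)
    hemi = ((hkl[:, 2] > 0)
            | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0))
            | ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0)))
    keep = hemi & (d >= dmin) & np.isfinite(d)
    flat = np.ravel_multi_index(
        ((hkl[keep, 0] % na), (hkl[keep, 1] % nb), (hkl[keep, 2] % nc)),
        (na, nb, nc))
    return hkl[keep], d[keep], flat


def estimate_signal_noise(halfmap1: np.ndarray, halfmap2: np.ndarray,
                          box: tuple, n_bins: int = 10,
                          dmin: float = 8.0) -> FourierMapData:
    """Half-map signal/noise estimation and observed-term preparation."""
    if halfmap1.shape != halfmap2.shape:
        raise ValueError("half-map grids differ")
    F1 = np.fft.fftn(halfmap1).ravel()
    F2 = np.fft.fftn(halfmap2).ravel()
    hkl, d, flat = _box_frequencies(halfmap1.shape, box, dmin)
    F1, F2 = F1[flat], F2[flat]
    Fobs = 0.5 * (F1 + F2)

    # equal-count bins in 1/d^3
    order = np.argsort(1.0 / d ** 3, kind="stable")
    bin_id = np.empty(len(d), dtype=int)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bin_id[idx] = b

    S = np.empty(n_bins)
    N = np.empty(n_bins)
    fsc = np.empty(n_bins)
    for b in range(n_bins):
        m = bin_id == b
        cross = np.mean(np.real(F1[m] * np.conj(F2[m])))
        N[b] = np.mean(np.abs(F1[m] - F2[m]) ** 2) / 4.0
        # noise-bias correction: under pure noise the bin-mean cross term
        # fluctuates with std sqrt(2/n) * N, which would otherwise give
        # spurious signal in empty bins; negligible once S >> N/sqrt(n)
        sigma0 = np.sqrt(2.0 / max(m.sum(), 1)) * N[b]
        S[b] = max(cross - sigma0, 0.0)
        p1 = np.mean(np.abs(F1[m]) ** 2)
        p2 = np.mean(np.abs(F2[m]) ** 2)
        fsc[b] = cross / max(np.sqrt(p1 * p2), 1e-300)
    Dobs_bin = np.sqrt(S / np.maximum(S + N, 1e-300))
    Dobs = Dobs_bin[bin_id]

    amp = np.abs(Fobs)
    mean2 = np.array([np.mean(amp[bin_id == b] ** 2) for b in range(n_bins)])
    Ee = amp / np.sqrt(np.maximum(mean2[bin_id], 1e-300))
    return FourierMapData(hkl=hkl, d=d, Ee=Ee, phi_obs=np.angle(Fobs),
                          Dobs=Dobs, bin_id=bin_id, n_bins=n_bins, box=box,
                          signal=S, noise=N, fsc=fsc)


def cryoem_llg_term(Ee, Ecalc, delta_phi, Dobs, sigmaA):
    """Single-term cryo-EM LLG (vectorized over ndarray inputs)."""
    t = np.asarray(Dobs) * np.asarray(sigmaA)
    if np.any(t >= 1.0):
        raise ValueError("Dobs * sigmaA must be < 1")
    u = 1.0 - t * t
    return (2.0 * t * Ee * Ecalc * np.cos(delta_phi) / u
            - t * t * (Ee ** 2 + Ecalc ** 2) / u - np.log(u))


def model_map_terms(map_data: FourierMapData, model: AtomicModel,
                    coords=None, b_iso=None):
    """Model Fourier terms at the map frequencies (direct summation).

    Returns (real, imag) in the numpy-FFT sign convention of the map terms
    (phases conjugated relative to the crystallographic convention), as
    Vars when ``coords`` is a Var.
    """
    refls = ReflectionSet(hkl=map_data.hkl, I_obs=np.zeros(len(map_data)),
                          sigma_I=np.ones(len(map_data)), d=map_data.d)
    sf = compute_structure_factors(model, map_data.sym, refls,
                                   coords=coords, b_iso=b_iso, conjugate=True)
    return sf.real, sf.imag


def _normalized_components(map_data: FourierMapData, real, imag):
    """Ecalc components normalized to per-bin <Ecalc^2> = 1."""
    p2 = ad.add(ad.square(real), ad.square(imag))
    counts = np.bincount(map_data.bin_id, minlength=map_data.n_bins).astype(float)
    mean2 = ad.div(ad.segment_sum(p2, map_data.bin_id, map_data.n_bins), counts)
    denom = ad.sqrt(ad.take(mean2, map_data.bin_id))
    return ad.div(real, denom), ad.div(imag, denom)


def cryoem_llg_total(map_data: FourierMapData, model: AtomicModel,
                     sigmaA: SigmaABins, coords=None, b_iso=None):
    """Summed Eq.-style LLG over all terms; differentiable in coordinates.

    The cos(dphi) cross term is evaluated from complex components,
    Ee Ecalc cos(dphi) = Ee (Re Fc cos(phi_obs) + Im Fc sin(phi_obs)) / |Fc|_norm,
    which keeps the phase dependence smooth for gradients.
    """
    real, imag = model_map_terms(map_data, model, coords=coords, b_iso=b_iso)
    er, ei = _normalized_components(map_data, real, imag)
    t = map_data.Dobs * sigmaA.per_reflection(map_data.bin_id)
    u = 1.0 - t * t
    cross = ad.add(ad.mul(np.cos(map_data.phi_obs) * map_data.Ee, er),
                   ad.mul(np.sin(map_data.phi_obs) * map_data.Ee, ei))
    e2 = ad.add(ad.square(er), ad.square(ei))
    terms = ad.sub(ad.mul(2.0 * t / u, cross),
                   ad.add(ad.mul(t * t / u, ad.add(map_data.Ee ** 2, e2)),
                          np.log(u)))
    return ad.sum_(terms)


def estimate_sigmaA_cryoem(map_data: FourierMapData, model: AtomicModel,
                           coords=None, max_iter: int = 50,
                           tol: float = 1e-4) -> SigmaABins:
    """Per-bin sigmaA maximizing the summed cryo-EM LLG (safeguarded Newton).

    Uses P = Ee Ecalc cos(dphi) and S = Ee^2 + Ecalc^2 per term:
        dLLG/dt = 2P(1+t^2)/u^2 - 2tS/u^2 + 2t/u
        d2LLG/dt2 = 4tP(3+t^2)/u^3 - 2S(1+3t^2)/u^3 + 2(1+t^2)/u^2
    with t = Dobs sigmaA, chain-ruled through Dobs per term.
    """
    real, imag = model_map_terms(map_data, model, coords=coords)
    real, imag = ad.value(real), ad.value(imag)
    er, ei = _normalized_components(map_data, real, imag)
    ec = np.hypot(er, ei)
    dphi = np.arctan2(ei, er) - map_data.phi_obs
    P = map_data.Ee * ec * np.cos(dphi)
    S = map_data.Ee ** 2 + ec ** 2
    vals = np.empty(map_data.n_bins)
    for b in range(map_data.n_bins):
        m = map_data.bin_id == b
        D, Pb, Sb = map_data.Dobs[m], P[m], S[m]
        s = 0.5
        for _ in range(max_iter):
            t = D * s
            u = 1.0 - t * t
            g = float(np.sum(D * (2.0 * Pb * (1 + t * t) / u ** 2
                                  - 2.0 * t * Sb / u ** 2 + 2.0 * t / u)))
            h = float(np.sum(D ** 2 * (4.0 * t * Pb * (3 + t * t) / u ** 3
                                       - 2.0 * Sb * (1 + 3 * t * t) / u ** 3
                                       + 2.0 * (1 + t * t) / u ** 2)))
            step = -g / h if h < 0 else 0.1 * np.sign(g)
            step = float(np.clip(step, -0.25, 0.25))
            s_new = float(np.clip(s + step, SIGMAA_MIN, SIGMAA_MAX))
            if abs(s_new - s) < tol:
                s = s_new
                break
            s = s_new
        vals[b] = s
    return SigmaABins(vals)
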