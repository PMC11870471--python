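"""Crystallographic log-likelihood-gain-on-intensity (LLGI) target.

For acentric reflections the conditional density of the effective
normalized amplitude Ee given the calculated EC is a Rice distribution,

    p_a(Ee; EC) = 2 Ee / u * exp(-(Ee^2 + t^2 EC^2)/u) * I0(2 t Ee EC / u)

and for centric reflections a Woolfson distribution,

    p_c(Ee; EC) = sqrt(2/(pi u)) * exp(-(Ee^2 + t^2 EC^2)/(2u)) * cosh(t Ee EC / u)

with t = Dobs * sigmaA and u = 1 - t^2.  The LLGI is the log ratio against
the corresponding Wilson density p(Ee).  sigmaA, the resolution-dependent
correlation between true and calculated normalized structure factors, is
refined per resolution bin by a safeguarded Newton-Raphson iteration on
analytic first and second derivatives, clamped to [0.015, 0.99].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as _sp

from . import autodiff as ad
from .reflections import ReflectionSet
from .scatter import StructureFactorSet, normalize_to_E

__all__ = [
    "SigmaABins", "llgi_acentric", "llgi_centric", "llg_total",
    "refine_sigmaA", "r_factors", "SIGMAA_MIN", "SIGMAA_MAX",
]

SIGMAA_MIN = 0.015
SIGMAA_MAX = 0.99


@dataclass
class SigmaABins:
    """Per-resolution-bin sigmaA values, clamped to [0.015, 0.99]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.clip(np.asarray(self.values, dtype=float),
                              SIGMAA_MIN, SIGMAA_MAX)

    def per_reflection(self, bin_id: np.ndarray) -> np.ndarray:
        return self.values[bin_id]

    @classmethod
    def initial(cls, n_bins: int, value: float = 0.7) -> "SigmaABins":
        return cls(np.full(n_bins, value))


def _check_ts(Dobs, sigmaA):
    t = ad.value(Dobs) * ad.value(sigmaA)
    if np.any(t >= 1.0) or np.any(t < 0.0):
        raise ValueError("Dobs * sigmaA must lie in [0, 1)")


def llgi_acentric(Ee, EC, Dobs, sigmaA):
    """Per-reflection acentric LLGI; EC may be an autodiff Var."""
    _check_ts(Dobs, sigmaA)
    t = ad.mul(Dobs, sigmaA)
    u = ad.sub(1.0, ad.square(t))
    Ee2 = ad.square(Ee)
    arg = ad.div(ad.mul(2.0, ad.mul(t, ad.mul(Ee, EC))), u)
    quad = ad.div(ad.add(Ee2, ad.square(ad.mul(t, EC))), u)
    return ad.add(ad.sub(ad.sub(Ee2, quad), ad.log(u)), ad.log_i0(arg))


def llgi_centric(Ee, EC, Dobs, sigmaA):
    """Per-reflection centric LLGI; EC may be an autodiff Var."""
    _check_ts(Dobs, sigmaA)
    t = ad.mul(Dobs, sigmaA)
    u = ad.sub(1.0, ad.square(t))
    Ee2 = ad.square(Ee)
    arg = ad.div(ad.mul(t, ad.mul(Ee, EC)), u)
    quad = ad.div(ad.add(Ee2, ad.square(ad.mul(t, EC))), ad.mul(2.0, u))
    return ad.add(ad.sub(ad.sub(ad.mul(0.5, Ee2), quad),
                         ad.mul(0.5, ad.log(u))), ad.log_cosh(arg))


def llg_total(refls: ReflectionSet, EC, sigmaA: SigmaABins, use: str = "work",
              mask: np.ndarray | None = None):
    """Summed LLGI over a reflection subset, dispatching centric/acentric.

    ``EC`` is the normalized calculated amplitude (Var or ndarray) aligned
    with ``refls``; differentiability flows through it.  ``mask`` further
    restricts the set (e.g. a low-resolution cutoff).
    """
    if use == "work":
        sel = refls.work
    elif use == "test":
        sel = ~refls.work
    elif use == "all":
        sel = np.ones(len(refls), dtype=bool)
    else:
        raise ValueError(f"use must be work/test/all, got {use!r}")
    if mask is not None:
        sel = sel & mask
    sA = sigmaA.per_reflection(refls.bin_id)
    total = 0.0
    for centric, fn in ((False, llgi_acentric), (True, llgi_centric)):
        m = sel & (refls.centric == centric)
        if not np.any(m):
            continue
        part = fn(refls.Ee[m], ad.take(EC, m) if ad.is_var(EC) else EC[m],
                  refls.Dobs[m], sA[m])
        total = ad.add(total, ad.sum_(part))
    return total


# -- analytic sigmaA derivatives ----------------------------------------
# In terms of t = Dobs*sigmaA, u = 1-t^2, X = Ee*EC, S = Ee^2+EC^2:
#   acentric: dlnp/dt = 2t/u - 2tS/u^2 + r(a) * 2X(1+t^2)/u^2, a = 2tX/u
#   centric:  dlnp/dt =  t/u -  tS/u^2 + tanh(c) * X(1+t^2)/u^2, c = tX/u
# with r = I1/I0; second derivatives follow by differentiating again
# (r' = 1 - r^2 - r/a).  d/dsigmaA = Dobs * d/dt.

def _dllg_acentric(t, Ee, EC, out2=True):
    u = 1.0 - t * t
    X = Ee * EC
    S = Ee * Ee + EC * EC
    a = 2.0 * t * X / u
    r = _sp.i1e(a) / _sp.i0e(a)
    g = 2.0 * X * (1.0 + t * t) / (u * u)  # da/dt
    d1 = 2.0 * t / u - 2.0 * t * S / (u * u) + r * g
    if not out2:
        return d1, None
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.where(a > 1e-8, 1.0 - r * r - r / np.maximum(a, 1e-300), 0.5)
    d2 = (2.0 * (1.0 + t * t) / (u * u)
          - 2.0 * S * (1.0 + 3.0 * t * t) / (u ** 3)
          + rp * g * g + r * 4.0 * t * X * (3.0 + t * t) / (u ** 3))
    return d1, d2


def _dllg_centric(t, Ee, EC, out2=True):
    u = 1.0 - t * t
    X = Ee * EC
    S = Ee * Ee + EC * EC
    c = t * X / u
    th = np.tanh(c)
    g = X * (1.0 + t * t) / (u * u)
    d1 = t / u - t * S / (u * u) + th * g
    if not out2:
        return d1, None
    d2 = ((1.0 + t * t) / (u * u) - S * (1.0 + 3.0 * t * t) / (u ** 3)
          + (1.0 - th * th) * g * g + th * 2.0 * t * X * (3.0 + t * t) / (u ** 3))
    return d1, d2


def sigmaA_gradient(sigma: float, Ee, EC, Dobs, centric) -> tuple[float, float]:
    """Summed d/dsigmaA and d2/dsigmaA2 of the bin LLG at ``sigma``."""
    t = Dobs * sigma
    g = h = 0.0
    for cen, fn in ((False, _dllg_acentric), (True, _dllg_centric)):
        m = centric == cen
        if not np.any(m):
            continue
        d1, d2 = fn(t[m], Ee[m], EC[m])
        g += float(np.sum(Dobs[m] * d1))
        h += float(np.sum(Dobs[m] ** 2 * d2))
    return g, h


def refine_sigmaA(refls: ReflectionSet, EC, sA_init: SigmaABins | None = None,
                  max_iter: int = 50, tol: float = 1e-4,
                  use_work: bool = True) -> SigmaABins:
    """Per-bin Newton-Raphson refinement of sigmaA on the work reflections.

    Non-positive curvature falls back to a damped step along the gradient
    sign; every iterate is clamped to [0.015, 0.99].
    """
    ECv = ad.value(EC)
    n_bins = int(refls.bin_id.max()) + 1
    vals = (SigmaABins.initial(n_bins).values if sA_init is None
            else np.array(sA_init.values, dtype=float))
    sel_all = refls.work if use_work else np.ones(len(refls), dtype=bool)
    for b in range(n_bins):
        m = sel_all & (refls.bin_id == b)
        if not np.any(m):
            continue
        Ee, ECb = refls.Ee[m], ECv[m]
        Dobs, cen = refls.Dobs[m], refls.centric[m]
        s = float(np.clip(vals[b], SIGMAA_MIN, SIGMAA_MAX))
        for _ in range(max_iter):
            g, h = sigmaA_gradient(s, Ee, ECb, Dobs, cen)
            if h < 0.0:
                step = -g / h
            else:  # non-concave region: damped gradient-sign step
                step = 0.1 * np.sign(g)
            step = float(np.clip(step, -0.25, 0.25))
            s_new = float(np.clip(s + step, SIGMAA_MIN, SIGMAA_MAX))
            if abs(s_new - s) < tol:
                s = s_new
                break
            s = s_new
        vals[b] = s
    return SigmaABins(vals)


def r_factors(refls: ReflectionSet, sf: StructureFactorSet):
    """(Rwork, Rfree) on posterior-mean amplitudes vs scaled |Fc|.

    R = sum | |Fo| - k |Fc| | / sum |Fo| with the variance-matching scale
    k = sqrt(sum Fo^2 / sum Fc^2) from the work set (the convention under
    which an uncorrelated model tends to the Wilson limit 2 - sqrt(2)).
    Rfree is None when there is no test set.
    """
    if refls.F_obs is None:
        raise ValueError("effective_amplitudes must run first (needs F_obs)")
    fc = sf.f_abs
    fo = refls.F_obs
    work = refls.work
    denom = np.sum(fc[work] ** 2)
    k = np.sqrt(np.sum(fo[work] ** 2) / denom) if denom > 0 else 0.0

    def _r(m):
        return float(np.sum(np.abs(fo[m] - k * fc[m])) / np.sum(fo[m]))

    rwork = _r(work)
    rfree = _r(~work) if np.any(~work) else None
    return rwork, rfree
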