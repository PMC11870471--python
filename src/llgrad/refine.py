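"""Inference-time refinement by MSA-profile biasing.

The loop optimizes a multiplicative/additive bias (w, b) on the MSA
cluster profile m0.  Each iteration: apply the bias, run the predictor,
convert pLDDT to pseudo-B, align the prediction to the reference by
weighted Kabsch, refine the pose against the likelihood (rigid-body),
re-estimate sigmaA per bin, evaluate the loss

    L = -LLG + omega_L2 * sum_i w_i || x_aligned,i - x_ref,i ||^2

and take one AdamW step on (w, b) with separate learning rates.  Two
phases: an adventurous phase 1 (high learning rates, low-resolution
cutoff, L2 restraint on, several independent traces) and a fine-tuning
phase 2 (small learning rates, full resolution, no restraint, early
stopping); the best-LLG phase-1 trace seeds phase 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .cryoem import FourierMapData, cryoem_llg_total, estimate_sigmaA_cryoem
from .geometry import (Pose, plddt_to_pseudoB, pseudoB_to_weight,
                       rigid_body_refine, weighted_kabsch)
from .model import AtomicModel
from .reflections import ReflectionSet, ResolutionBinning
from .scatter import compute_structure_factors, normalize_to_E
from .symmetry import CrystalSymmetry
from .xtal import SigmaABins, llg_total, r_factors, refine_sigmaA

__all__ = [
    "BiasParams", "RefinementConfig", "XtalTarget", "CryoEMTarget",
    "apply_bias", "l2_restraint", "RefinementState", "iterate_once",
    "run_refinement", "rank_subsampled_profiles", "TraceResult", "AdamW",
]


def apply_bias(m0: np.ndarray, w, b):
    """Biased profile w * m0 + b (elementwise, no renormalization)."""
    if ad.value(w).shape != m0.shape or ad.value(b).shape != m0.shape:
        raise ValueError("bias shapes must match the profile")
    return ad.add(ad.mul(w, m0), b)


def l2_restraint(x_aligned, x_ref: np.ndarray, weights: np.ndarray):
    """Weighted sum of squared Ca distances (graph-aware)."""
    if ad.value(x_aligned).shape != np.asarray(x_ref).shape:
        raise ValueError("coordinate arrays differ in length")
    d2 = ad.sum_(ad.square(ad.sub(x_aligned, x_ref)), axis=1)
    return ad.sum_(ad.mul(np.asarray(weights, dtype=float), d2))


@dataclass
class BiasParams:
    """Multiplicative and additive profile bias, shaped like m0."""

    w: np.ndarray
    b: np.ndarray

    @classmethod
    def initial(cls, m0: np.ndarray) -> "BiasParams":
        return cls(np.ones_like(m0), np.zeros_like(m0))


@dataclass
class RefinementConfig:
    lr_mul_phase1: float = 1.0
    lr_add_phase1: float = 0.05
    lr_phase2: float = 1e-3
    omega_l2: float = 1e-11
    n_iter_phase1: int = 100
    n_iter_phase2: int = 500
    n_traces: int = 3
    phase1_dmin: float = 3.0
    early_stop_delta: float = 0.1
    early_stop_patience: int = 50
    rbr_steps: int = 3
    trace_jitter: float = 0.02
    seed: int = 0


class AdamW:
    """Decoupled-weight-decay Adam on a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lrs: list[float],
                 betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lrs = list(lrs)
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        for p, g, m, v, lr in zip(self.params, grads, self.m, self.v,
                                  self.lrs):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


class XtalTarget:
    """Crystallographic LLG target bound to one reflection dataset."""

    def __init__(self, refls: ReflectionSet, sym: CrystalSymmetry,
                 binning: ResolutionBinning, template: AtomicModel):
        self.refls = refls
        self.sym = sym
        self.binning = binning
        self.template = template
        self._subsets: dict = {}

    def _subset(self, dmin: float | None):
        """Reflections (and remapped bins) above a low-resolution cutoff."""
        if dmin is None:
            return self.refls, self.binning, np.arange(self.binning.n_bins)
        key = round(dmin, 6)
        if key not in self._subsets:
            sub = self.refls.select(self.refls.d >= dmin)
            kept, new_id = np.unique(sub.bin_id, return_inverse=True)
            sub.bin_id = new_id
            sub_binning = ResolutionBinning(n_bins=len(kept),
                                            edges=self.binning.edges)
            self._subsets[key] = (sub, sub_binning, kept)
        return self._subsets[key]

    def llg(self, coords, b_iso, sigmaA: SigmaABins,
            dmin: float | None = None, use: str = "work"):
        refls, binning, kept = self._subset(dmin)
        sf = compute_structure_factors(self.template, self.sym, refls,
                                       coords=coords, b_iso=b_iso)
        EC = normalize_to_E(sf, refls, binning)
        return llg_total(refls, EC, SigmaABins(sigmaA.values[kept]), use=use)

    def refine_sigmaA(self, coords, b_iso,
                      sA: SigmaABins | None = None) -> SigmaABins:
        sf = compute_structure_factors(self.template, self.sym, self.refls,
                                       coords=ad.value(coords),
                                       b_iso=ad.value(b_iso))
        EC = normalize_to_E(sf, self.refls, self.binning)
        return refine_sigmaA(self.refls, EC, sA_init=sA)

    def metrics(self, coords, b_iso) -> dict:
        sf = compute_structure_factors(self.template, self.sym, self.refls,
                                       coords=ad.value(coords),
                                       b_iso=ad.value(b_iso))
        rwork, rfree = r_factors(self.refls, sf)
        return {"r_work": rwork, "r_free": rfree}


class CryoEMTarget:
    """Cryo-EM Fourier-term LLG target bound to half-map statistics."""

    def __init__(self, map_data: FourierMapData, template: AtomicModel):
        self.map_data = map_data
        self.template = template

    def resolution_mask(self, dmin):
        return None  # the map statistics already carry their cutoff

    def llg(self, coords, b_iso, sigmaA: SigmaABins,
            dmin: float | None = None, use: str = "work"):
        return cryoem_llg_total(self.map_data, self.template, sigmaA,
                                coords=coords, b_iso=b_iso)

    def refine_sigmaA(self, coords, b_iso, sA=None) -> SigmaABins:
        return estimate_sigmaA_cryoem(self.map_data, self.template,
                                      coords=ad.value(coords))

    def metrics(self, coords, b_iso) -> dict:
        return {}


@dataclass
class RefinementState:
    bias: BiasParams
    optimizer: AdamW
    sigmaA: SigmaABins | None = None
    pose: Pose = field(default_factory=Pose.identity)
    llg_history: list = field(default_factory=list)
    best_llg: float = -np.inf
    best_bias: BiasParams | None = None
    best_coords: np.ndarray | None = None
    best_plddt: np.ndarray | None = None


@dataclass
class TraceResult:
    llg_history: list
    best_llg: float
    bias: BiasParams
    coords: np.ndarray            # best x_RBR
    plddt: np.ndarray
    sigmaA: SigmaABins
    pose: Pose
    metrics: dict = field(default_factory=dict)


def iterate_once(state: RefinementState, predictor, target, config,
                 m0: np.ndarray, x_ref: np.ndarray, weights_ref: np.ndarray,
                 dmin: float | None, omega_l2: float,
                 seed: int = 0) -> RefinementState:
    """One full refinement step; mutates and returns ``state``."""
    w = ad.Var(state.bias.w)
    b = ad.Var(state.bias.b)
    profile = apply_bias(m0, w, b)
    coords, plddt = predictor(profile, seed)
    pseudo_b = plddt_to_pseudoB(plddt)

    # alignment pose from the weighted Kabsch problem (Ca only), then
    # rigid-body refinement against the likelihood; gradients to the bias
    # are taken at the refined pose held fixed
    pose_k = weighted_kabsch(ad.value(coords), x_ref, weights_ref)
    sA = state.sigmaA or SigmaABins.initial(
        getattr(target, "binning", None).n_bins
        if hasattr(target, "binning") else target.map_data.n_bins)

    def llg_fn(c):
        return target.llg(c, pseudo_b, sA, dmin=dmin)

    pose = rigid_body_refine(ad.value(coords), pose_k, llg_fn,
                             steps=config.rbr_steps)
    x_rbr = pose.apply(coords)

    sA = target.refine_sigmaA(x_rbr, pseudo_b, state.sigmaA)
    state.sigmaA = sA

    llg = target.llg(x_rbr, pseudo_b, sA, dmin=dmin)
    loss = ad.sub(0.0, llg)
    if omega_l2 > 0.0:
        x_al = pose_k.apply(coords)
        loss = ad.add(loss, ad.mul(
            omega_l2, l2_restraint(x_al, x_ref, weights_ref)))
    if not np.isfinite(ad.value(loss)):
        raise ValueError("non-finite loss; trace aborted")
    loss.backward()

    llg_val = float(ad.value(llg))
    state.llg_history.append(llg_val)
    if llg_val > state.best_llg:
        state.best_llg = llg_val
        state.best_bias = BiasParams(state.bias.w.copy(),
                                     state.bias.b.copy())
        state.best_coords = ad.value(x_rbr).copy()
        state.best_plddt = np.array(plddt)
    state.pose = pose

    state.optimizer.step([w.grad, b.grad])
    return state


def _new_state(m0, lr_mul, lr_add, jitter: float, rng) -> RefinementState:
    bias = BiasParams.initial(m0)
    if jitter > 0.0:
        bias.b += jitter * rng.normal(size=m0.shape)
    opt = AdamW([bias.w, bias.b], [lr_mul, lr_add])
    return RefinementState(bias=bias, optimizer=opt)


def run_refinement(m0: np.ndarray, predictor, target,
                   config: RefinementConfig, x_ref: np.ndarray,
                   plddt_ref: np.ndarray) -> TraceResult:
    """Two-phase multi-trace refinement; returns the best model overall."""
    weights_ref = pseudoB_to_weight(plddt_to_pseudoB(plddt_ref))
    trace_rngs = [np.random.default_rng((config.seed + 7919 * k) % (2 ** 31))
                  for k in range(config.n_traces)]

    traces: list[RefinementState] = []
    for k in range(config.n_traces):
        state = _new_state(m0, config.lr_mul_phase1, config.lr_add_phase1,
                           config.trace_jitter if k > 0 else 0.0,
                           trace_rngs[k])
        for _ in range(config.n_iter_phase1):
            state = iterate_once(state, predictor, target, config, m0,
                                 x_ref, weights_ref,
                                 dmin=config.phase1_dmin,
                                 omega_l2=config.omega_l2, seed=k)
        if config.n_iter_phase1 == 0:  # evaluate the starting point once
            state = _evaluate_only(state, predictor, target, config, m0,
                                   x_ref, weights_ref)
        traces.append(state)

    best_idx = int(np.argmax([t.best_llg for t in traces]))  # lowest index wins ties
    state = traces[best_idx]

    # phase 2: fine-tune from the best phase-1 bias at full resolution
    bias = BiasParams(state.best_bias.w.copy(), state.best_bias.b.copy())
    opt = AdamW([bias.w, bias.b], [config.lr_phase2, config.lr_phase2])
    state2 = RefinementState(bias=bias, optimizer=opt, sigmaA=None)
    best_seen = -np.inf
    stall = 0
    for _ in range(config.n_iter_phase2):
        state2 = iterate_once(state2, predictor, target, config, m0,
                              x_ref, weights_ref, dmin=None,
                              omega_l2=0.0, seed=best_idx)
        if state2.llg_history[-1] > best_seen + config.early_stop_delta:
            best_seen = state2.llg_history[-1]
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    if config.n_iter_phase2 == 0:
        state2 = _evaluate_only(state2, predictor, target, config, m0,
                                x_ref, weights_ref)

    final = state2 if state2.best_llg >= state.best_llg else state
    history = [t.llg_history for t in traces] + [state2.llg_history]
    metrics = target.metrics(final.best_coords,
                             plddt_to_pseudoB(final.best_plddt))
    return TraceResult(llg_history=history, best_llg=final.best_llg,
                       bias=final.best_bias, coords=final.best_coords,
                       plddt=final.best_plddt, sigmaA=final.sigmaA,
                       pose=final.pose, metrics=metrics)


def _evaluate_only(state, predictor, target, config, m0, x_ref,
                   weights_ref) -> RefinementState:
    """Score the current bias without an optimizer step (no-op loop)."""
    profile = apply_bias(m0, state.bias.w, state.bias.b)
    coords, plddt = predictor(profile, 0)
    pseudo_b = plddt_to_pseudoB(plddt)
    pose = weighted_kabsch(ad.value(coords), x_ref, weights_ref)
    x = ad.value(pose.apply(coords))
    sA = target.refine_sigmaA(x, pseudo_b, state.sigmaA)
    llg_val = float(ad.value(target.llg(x, pseudo_b, sA)))
    state.sigmaA = sA
    state.llg_history.append(llg_val)
    state.best_llg = llg_val
    state.best_bias = BiasParams(state.bias.w.copy(), state.bias.b.copy())
    state.best_coords = x
    state.best_plddt = np.array(plddt)
    state.pose = pose
    return state


def rank_subsampled_profiles(profiles: list[np.ndarray], predictor, target,
                             x_ref: np.ndarray, plddt_ref: np.ndarray,
                             labels: list | None = None,
                             rbr_steps: int = 10):
    """Score profiles by single-shot predict -> align -> RBR -> LLG.

    Returns a list of (label, llg) sorted by decreasing LLG; order among
    equal scores follows the input order.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    weights_ref = pseudoB_to_weight(plddt_to_pseudoB(plddt_ref))
    labels = list(range(len(profiles))) if labels is None else list(labels)
    scored = []
    for lab, prof in zip(labels, profiles):
        coords, plddt = predictor(prof, 0)
        coords = ad.value(coords)
        pseudo_b = plddt_to_pseudoB(plddt)
        pose = weighted_kabsch(coords, x_ref, weights_ref)
        sA0 = target.refine_sigmaA(pose.apply(coords), pseudo_b, None)

        def llg_fn(c):
            return target.llg(c, pseudo_b, sA0)

        pose = rigid_body_refine(coords, pose, llg_fn, steps=rbr_steps)
        x = pose.apply(coords)
        sA = target.refine_sigmaA(x, pseudo_b, None)
        scored.append((lab, float(ad.value(target.llg(x, pseudo_b, sA)))))
    order = sorted(range(len(scored)), key=lambda i: -scored[i][1])
    return [scored[i] for i in order]
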