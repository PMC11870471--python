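"""Desk-scale synthetic fixtures: toy models, simulated data, toy predictor.

Everything the refinement loop consumes can be generated here without
external data: a self-avoiding Ca-trace model, Wilson/Gaussian-noise
crystallographic intensities simulated from it, band-limited half-maps
with controlled signal-to-noise, a [clusters x residues x 23] MSA cluster
profile from a synthetic alignment, and a *toy predictor* — a linear,
exactly differentiable stand-in for an AF2-class network that maps
profile-bias deviations to per-residue 3-D displacements.  The toy
predictor is a test double with an identifiable optimum, not a folding
model; its linearity is what makes loop-recovery experiments conclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .model import AtomicModel
from .reflections import (ReflectionSet, assign_centric_epsilon,
                          effective_amplitudes, make_bins, split_work_test)
from .scatter import compute_structure_factors
from .symmetry import CrystalSymmetry

__all__ = [
    "make_toy_model", "simulate_reflections", "simulate_halfmaps",
    "ToyFoldSpec", "toy_predictor", "make_profile", "make_subsample_profiles",
    "SyntheticDataset", "recovery_benchmark",
]

N_PROFILE_CATEGORIES = 23  # 20 amino acids + unknown + gap + mask


def make_toy_model(n_res: int, seed: int = 0, b_iso: float = 20.0,
                   compact_radius: float | None = None) -> AtomicModel:
    """Self-avoiding helix-like Ca trace with 3.8 A consecutive spacing.

    A seeded random walk with fixed 3.8 A steps, directional persistence
    (helix-like local curvature) and rejection of steps that come within
    3.2 A of a previous residue or leave a compact bounding sphere.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    rng = np.random.default_rng(seed)
    step = 3.8
    radius = compact_radius if compact_radius is not None else 2.2 * n_res ** (1 / 3)
    coords = [np.zeros(3)]
    direction = _unit(rng.normal(size=3))
    while len(coords) < n_res:
        placed = False
        for _ in range(200):
            cand_dir = _unit(direction + 0.9 * rng.normal(size=3))
            cand = coords[-1] + step * cand_dir
            prev = np.array(coords[:-1]) if len(coords) > 1 else None
            clash = (prev is not None
                     and np.min(np.linalg.norm(prev - cand, axis=1)) < 3.2)
            centroid = np.mean(coords, axis=0)
            if not clash and np.linalg.norm(cand - centroid) < radius:
                coords.append(cand)
                direction = cand_dir
                placed = True
                break
        if not placed:  # backtrack one residue and retry
            if len(coords) > 1:
                coords.pop()
            direction = _unit(rng.normal(size=3))
    xyz = np.array(coords)
    xyz -= xyz.min(axis=0)
    xyz += 2.0  # keep atoms off the cell origin / axes
    return AtomicModel(
        coords=xyz, element=np.array(["C"] * n_res),
        occupancy=np.ones(n_res), b_iso=np.full(n_res, b_iso),
        plddt=np.full(n_res, 90.0),
        residue_id=np.arange(1, n_res + 1),
        chain_id=np.array(["A"] * n_res),
        meta={"seed": seed, "kind": "toy-ca-trace"})


def _unit(v):
    return v / np.linalg.norm(v)


def toy_cell(model: AtomicModel, padding: float = 5.0,
             space_group: str = "P 21 21 21") -> CrystalSymmetry:
    """Orthorhombic cell enclosing the model with the requested padding.

    The default space group is P212121: non-polar, so the amplitude-only
    crystallographic likelihood determines all translations (in P1 a
    global translation leaves every |F| unchanged).
    """
    span = model.coords.max(axis=0) + padding  # model starts near origin
    abc = np.ceil(span + padding)
    return CrystalSymmetry((abc[0], abc[1], abc[2], 90.0, 90.0, 90.0),
                           space_group)


def full_hkl_set(sym: CrystalSymmetry, dmin: float) -> np.ndarray:
    """Unique reciprocal-ASU Miller indices complete to dmin, no absences."""
    a, b, c = sym.unit_cell[:3]
    hmax = int(np.floor(a / dmin)) + 1
    kmax = int(np.floor(b / dmin)) + 1
    lmax = int(np.floor(c / dmin)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = sym.d_spacing(hkl)
    hkl = hkl[d >= dmin]
    hkl = sym.map_to_asu(hkl)
    hkl = np.unique(hkl, axis=0)
    return hkl[~sym.is_absent(hkl)]


def simulate_reflections(model: AtomicModel, sym: CrystalSymmetry,
                         dmin: float = 2.0, noise_frac: float = 0.1,
                         seed: int = 0, target_per_bin: int = 200):
    """Noisy intensities I = |Fc|^2 + N(0, sigma_I) complete to dmin.

    sigma_I = noise_frac * (<I>_bin + I_true) / 2; the returned set has
    centric/epsilon flags, bins, Ee/Dobs and a 5% test split assigned.
    Returns (ReflectionSet, ResolutionBinning).
    """
    rng = np.random.default_rng(seed)
    hkl = full_hkl_set(sym, dmin)
    d = sym.d_spacing(hkl)
    refls = ReflectionSet(hkl=hkl, I_obs=np.zeros(len(hkl)),
                          sigma_I=np.ones(len(hkl)), d=d,
                          meta={"dmin": dmin, "noise_frac": noise_frac,
                                "seed": seed})
    refls = assign_centric_epsilon(refls, sym)
    sf = compute_structure_factors(model, sym, refls)
    I_true = sf.f_abs ** 2
    binning = make_bins(refls, target_per_bin=target_per_bin)
    mean_I = np.array([I_true[refls.bin_id == b].mean()
                       for b in range(binning.n_bins)])
    sigma = np.maximum(noise_frac * (mean_I[refls.bin_id] + I_true) / 2.0,
                       1e-6 * np.maximum(mean_I[refls.bin_id], 1e-30))
    I_obs = I_true + rng.normal(size=len(hkl)) * sigma
    refls.I_obs = I_obs
    refls.sigma_I = sigma
    refls.meta["I_true"] = I_true
    refls = effective_amplitudes(refls, binning)
    refls = split_work_test(refls, fraction=0.05, seed=seed)
    return refls, binning


def simulate_halfmaps(model: AtomicModel, box: float | tuple,
                      voxel: float = 2.0, dmin: float = 8.0,
                      snr: float = 4.0, seed: int = 0):
    """Two noisy half-maps of Gaussian-atom density band-limited to dmin.

    ``snr`` is the per-half-map signal-to-noise power ratio in the dmin
    resolution shell (so the half-map FSC there is snr / (snr + 1)).
    White Gaussian noise is added independently to each half.
    Returns (halfmap1, halfmap2, box_tuple).
    """
    box = (box, box, box) if np.isscalar(box) else tuple(box)
    shape = tuple(int(np.ceil(b / voxel)) for b in box)
    rng = np.random.default_rng(seed)
    sym = CrystalSymmetry((box[0], box[1], box[2], 90, 90, 90), "P 1")
    na, nb, nc = shape

    h = np.fft.fftfreq(na, 1.0 / na).astype(int)
    k = np.fft.fftfreq(nb, 1.0 / nb).astype(int)
    l = np.fft.fftfreq(nc, 1.0 / nc).astype(int)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    s2 = ((hkl[:, 0] / box[0]) ** 2 + (hkl[:, 1] / box[1]) ** 2
          + (hkl[:, 2] / box[2]) ** 2)
    inside = (s2 > 0) & (s2 <= 1.0 / dmin ** 2)

    refls = ReflectionSet(hkl=hkl[inside], I_obs=np.zeros(inside.sum()),
                          sigma_I=np.ones(inside.sum()),
                          d=1.0 / np.sqrt(s2[inside]))
    sf = compute_structure_factors(model, sym, refls, conjugate=True)
    F = np.zeros(len(hkl), dtype=complex)
    F[inside] = sf.f_complex

    # noise level set by signal power in the dmin shell
    shell = inside & (s2 >= 0.8 / dmin ** 2)
    sig_power = np.mean(np.abs(F[shell]) ** 2)
    noise_power = sig_power / max(snr, 1e-9)  # per half-map, per Fourier term
    n_vox = na * nb * nc
    # white real-space noise of variance v gives Fourier power v * n_vox
    noise_sigma = np.sqrt(noise_power / n_vox)

    density = np.real(np.fft.ifftn(F.reshape(shape)))
    half1 = density + rng.normal(size=shape) * noise_sigma
    half2 = density + rng.normal(size=shape) * noise_sigma
    return half1, half2, box


@dataclass
class ToyFoldSpec:
    """Linear profile-to-structure map standing in for a predictor network.

    The predictor output is ``base_coords + readout(delta)`` where delta is
    the per-residue mean profile deviation from ``m0`` across clusters and
    readout is a bounded per-residue linear map (23 -> 3).  pLDDT is a
    deterministic, decreasing function of displacement magnitude.
    """

    base_coords: np.ndarray        # (n_res, 3)
    readout: np.ndarray            # (n_res, 23, 3), bounded
    m0: np.ndarray                 # (n_clusters, n_res, 23) reference profile
    plddt_slope: float = 10.0      # pLDDT drop per Angstrom of displacement
    max_displacement: float = 5.0  # readout bound at unit bias

    def __post_init__(self):
        # enforce the displacement bound per residue
        norms = np.linalg.norm(self.readout.reshape(len(self.readout), -1),
                               axis=1)
        over = norms > self.max_displacement
        if np.any(over):
            self.readout = self.readout.copy()
            self.readout[over] *= (self.max_displacement / norms[over]
                                   )[:, None, None]


def toy_predictor(spec: ToyFoldSpec):
    """Differentiable predictor closure: profile -> (coords, pLDDT).

    The returned callable accepts the biased profile (Var or ndarray) and
    a seed (unused: the map is deterministic) and returns coordinates in
    the same graph plus numeric per-residue pLDDT.
    """
    n_res = len(spec.base_coords)

    def predict(profile, seed: int = 0):
        delta = ad.sub(profile, spec.m0)
        n_clusters = spec.m0.shape[0]
        mean_delta = ad.div(ad.sum_(delta, axis=0), float(n_clusters))
        # displacement[r, j] = sum_k mean_delta[r, k] * readout[r, k, j]
        md3 = ad.reshape(mean_delta, (n_res, N_PROFILE_CATEGORIES, 1))
        disp = ad.sum_(ad.mul(md3, spec.readout), axis=1)  # (n_res, 3)
        coords = ad.add(spec.base_coords, disp)
        dmag = np.linalg.norm(ad.value(disp), axis=1)
        plddt = np.clip(100.0 - spec.plddt_slope * dmag, 30.0, 100.0)
        return coords, plddt

    return predict


def make_profile(n_clusters: int, n_res: int, seed: int = 0,
                 depth: int = 64):
    """Random MSA cluster profile from a synthetic alignment.

    Returns ``(m0, alignment)``: ``m0`` has shape
    [n_clusters, n_res, 23] with stochastic rows; cluster 0 is the
    column-frequency profile of the full alignment, further clusters come
    from random halves.  ``alignment`` is the (depth, n_res) category
    matrix for subsampling.
    """
    if n_clusters < 1 or n_res < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    # columns have a dominant category plus noise, like a real alignment
    dominant = rng.integers(0, 20, size=n_res)
    alignment = np.where(rng.random((depth, n_res)) < 0.7,
                         dominant[None, :],
                         rng.integers(0, N_PROFILE_CATEGORIES,
                                      size=(depth, n_res)))
    profiles = [profile_from_alignment(alignment)]
    for _ in range(n_clusters - 1):
        sub = rng.choice(depth, size=depth // 2, replace=False)
        profiles.append(profile_from_alignment(alignment[sub]))
    return np.stack(profiles), alignment


def profile_from_alignment(alignment: np.ndarray) -> np.ndarray:
    """(n_res, 23) column-frequency profile of a category alignment."""
    n_res = alignment.shape[1]
    prof = np.zeros((n_res, N_PROFILE_CATEGORIES))
    for r in range(n_res):
        prof[r] = np.bincount(alignment[:, r],
                              minlength=N_PROFILE_CATEGORIES)
    return prof / alignment.shape[0]


def make_subsample_profiles(alignment: np.ndarray, n_clusters: int,
                            depth: int, n_subsamples: int, seed: int = 0):
    """Uniform-random sequence subsamples -> cluster profiles.

    Each subsample picks ``depth`` sequences without replacement and
    tiles its column-frequency profile across clusters.  Picking the full
    alignment depth reproduces the full profile exactly.
    """
    rng = np.random.default_rng(seed)
    full_depth = alignment.shape[0]
    out = []
    for _ in range(n_subsamples):
        sub = rng.choice(full_depth, size=min(depth, full_depth),
                         replace=False)
        prof = profile_from_alignment(alignment[sub])
        out.append(np.tile(prof[None], (n_clusters, 1, 1)))
    return out


@dataclass
class SyntheticDataset:
    """A complete refinement problem with known ground truth."""

    truth: AtomicModel
    reference: AtomicModel          # perturbed starting/reference model
    sym: CrystalSymmetry
    refls: ReflectionSet | None
    binning: object | None
    m0: np.ndarray
    fold_spec: ToyFoldSpec
    params: dict = field(default_factory=dict)


def recovery_benchmark(seed: int = 0, n_res: int = 50, dmin: float = 2.0,
                       noise_frac: float = 0.1, perturbation: float = 1.0,
                       n_clusters: int = 4) -> SyntheticDataset:
    """The standard loop-recovery fixture.

    The data are simulated from a ground-truth model; the toy predictor's
    base coordinates are the truth displaced by a seeded random
    perturbation of RMS ``perturbation`` Angstrom, and the linear readout
    is constructed so that a profile bias exists which cancels the
    perturbation exactly (the loop's identifiable optimum).
    """
    rng = np.random.default_rng(seed)
    truth = make_toy_model(n_res, seed=seed)
    sym = toy_cell(truth, padding=4.0)
    refls, binning = simulate_reflections(truth, sym, dmin=dmin,
                                          noise_frac=noise_frac, seed=seed)
    pert = rng.normal(size=(n_res, 3))
    pert *= perturbation / np.sqrt(np.mean(np.sum(pert ** 2, axis=1)))
    base = truth.coords + pert

    m0, alignment = make_profile(n_clusters, n_res, seed=seed)
    readout = rng.normal(size=(n_res, N_PROFILE_CATEGORIES, 3))
    readout *= 2.0 / np.linalg.norm(readout.reshape(n_res, -1),
                                    axis=1)[:, None, None]
    spec = ToyFoldSpec(base_coords=base, readout=readout, m0=m0)
    reference = truth.with_coords(base)  # the unbiased prediction
    reference.plddt = np.full(n_res, 100.0)
    return SyntheticDataset(
        truth=truth, reference=reference, sym=sym, refls=refls,
        binning=binning, m0=m0, fold_spec=spec,
        params={"seed": seed, "n_res": n_res, "dmin": dmin,
                "noise_frac": noise_frac, "perturbation": perturbation,
                "alignment": alignment})
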