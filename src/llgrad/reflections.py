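"""Observed crystallographic reflection data and derived quantities.

A :class:`ReflectionSet` holds per-reflection observations (Miller index,
intensity, uncertainty) plus everything the likelihood targets need:
centric flags, epsilon factors, equal-count resolution bins, effective
normalized amplitudes Ee with error factors Dobs, and a stratified
work/test split for cross-validated R factors.

Ee and Dobs are computed from the intensity posterior under a Wilson
prior (a French & Wilson-style truncation), evaluated by 64-point
Gauss-Legendre quadrature per reflection, with a two-moment match to the
effective-amplitude error model:

    Dobs * Ee = E[E | Iobs],   Dobs^2 Ee^2 + (1 - Dobs^2) = E[E^2 | Iobs]

so that Dobs -> 1 as sigma_I -> 0 and Ee is the posterior-mean normalized
amplitude in that limit.  Ee is then rescaled per bin to <Ee^2> = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .symmetry import CrystalSymmetry

__all__ = [
    "ReflectionSet", "ResolutionBinning", "read_reflections",
    "write_mtz", "assign_centric_epsilon", "make_bins",
    "effective_amplitudes", "split_work_test",
]

_GL_POINTS = 64


@dataclass
class ResolutionBinning:
    """Equal-count resolution bins, ordered by decreasing d (in 1/d^3)."""

    n_bins: int
    edges: np.ndarray  # (n_bins + 1,) d-spacing boundaries, decreasing

    def assign(self, d: np.ndarray) -> np.ndarray:
        s3 = 1.0 / np.asarray(d) ** 3
        inner = 1.0 / self.edges[1:-1] ** 3  # increasing
        return np.searchsorted(inner, s3, side="right")


@dataclass
class ReflectionSet:
    """Per-reflection crystallographic observations and derived columns."""

    hkl: np.ndarray                  # (n, 3) int
    I_obs: np.ndarray                # (n,)
    sigma_I: np.ndarray              # (n,)
    d: np.ndarray                    # (n,) resolution, Angstrom
    centric: np.ndarray | None = None
    epsilon: np.ndarray | None = None
    bin_id: np.ndarray | None = None
    Ee: np.ndarray | None = None
    Dobs: np.ndarray | None = None
    F_obs: np.ndarray | None = None  # posterior-mean amplitude, data scale
    is_test: np.ndarray | None = None
    mean_I_bin: np.ndarray | None = None  # per-bin <I/eps> used to normalize
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def work(self) -> np.ndarray:
        if self.is_test is None:
            return np.ones(len(self), dtype=bool)
        return ~self.is_test

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        cols = {}
        for name in ("hkl", "I_obs", "sigma_I", "d", "centric", "epsilon",
                     "bin_id", "Ee", "Dobs", "F_obs", "is_test"):
            v = getattr(self, name)
            cols[name] = None if v is None else v[mask]
        return ReflectionSet(**cols, mean_I_bin=self.mean_I_bin,
                             meta=dict(self.meta))


def read_reflections(path, dialect: str | None = None,
                     intensity_col: str | None = None,
                     sigma_col: str | None = None):
    """Read intensities and symmetry from an MTZ or reflection-CIF file.

    Returns ``(ReflectionSet, CrystalSymmetry)`` with reflections mapped to
    the reciprocal ASU, resolutions computed from the cell, and systematic
    absences removed.  Centric/epsilon, bins, Ee/Dobs and the test split
    are *not* assigned here; see the dedicated functions.
    """
    path = str(path)
    if dialect is None:
        dialect = "mtz" if path.lower().endswith(".mtz") else "cif"
    if dialect == "mtz":
        hkl, I, sig, cell, sg = _read_mtz(path, intensity_col, sigma_col)
    elif dialect == "cif":
        hkl, I, sig, cell, sg = _read_refln_cif(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        sym = CrystalSymmetry(cell, sg)
    except Exception as e:  # unknown space group symbol
        raise ValueError(f"unknown space group {sg!r}") from e

    hkl = sym.map_to_asu(hkl)
    keep = ~sym.is_absent(hkl)
    hkl, I, sig = hkl[keep], I[keep], sig[keep]
    d = sym.d_spacing(hkl)
    refls = ReflectionSet(hkl=hkl, I_obs=I, sigma_I=sig, d=d,
                          meta={"source": path, "space_group": sg})
    return refls, sym


def _read_mtz(path, intensity_col, sigma_col):
    mtz = gemmi.read_mtz_file(path)
    cols = {c.label: c for c in mtz.columns}
    if intensity_col is None:
        j = [c.label for c in mtz.columns if c.type == "J"]
        if not j:
            raise ValueError(
                "no intensity (type J) column found; available columns: "
                + ", ".join(f"{c.label}({c.type})" for c in mtz.columns))
        intensity_col = j[0]
    if sigma_col is None:
        cand = "SIG" + intensity_col
        q = [c.label for c in mtz.columns if c.type == "Q"]
        sigma_col = cand if cand in cols else (q[0] if q else None)
        if sigma_col is None:
            raise ValueError(
                "no intensity-uncertainty (type Q) column found; available "
                "columns: " + ", ".join(c.label for c in mtz.columns))
    arr = np.array(mtz, copy=True)
    labels = [c.label for c in mtz.columns]
    hkl = arr[:, [labels.index("H"), labels.index("K"), labels.index("L")]]
    I = arr[:, labels.index(intensity_col)]
    sig = arr[:, labels.index(sigma_col)]
    ok = np.isfinite(I) & np.isfinite(sig)
    cell = (mtz.cell.a, mtz.cell.b, mtz.cell.c,
            mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    return (hkl[ok].astype(int), I[ok].astype(float), sig[ok].astype(float),
            cell, mtz.spacegroup.hm)


def _read_refln_cif(path):
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def num(tag):
        v = block.find_value(tag)
        return None if v is None else float(v)

    cell = tuple(num(f"_cell.{t}") for t in
                 ("length_a", "length_b", "length_c",
                  "angle_alpha", "angle_beta", "angle_gamma"))
    sg = block.find_value("_symmetry.space_group_name_H-M")
    if sg is None:
        sg = block.find_value("_space_group.name_H-M_alt")
    if sg is None:
        raise ValueError("no space-group symbol in CIF")
    sg = sg.strip("'\"")
    table = block.find("_refln.", ["index_h", "index_k", "index_l",
                                   "intensity_meas", "intensity_sigma"])
    if len(table) == 0:
        loop_tags = [t for t in (block.get_mmcif_category_names() or [])]
        raise ValueError("no _refln.intensity_meas/_refln.intensity_sigma "
                         f"loop found; categories: {loop_tags}")
    rows = [[row[i] for i in range(5)] for row in table]
    arr = np.array(rows, dtype=float)
    return (arr[:, :3].astype(int), arr[:, 3], arr[:, 4], cell, sg)


def write_mtz(path, refls: ReflectionSet, sym: CrystalSymmetry):
    """Write observed columns plus any derived columns (Ee, Dobs, bins, free)."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = sym.gemmi_sg
    mtz.set_cell_for_all(sym.cell)
    ds = mtz.add_dataset("llgrad")
    mtz.add_column("I", "J")
    mtz.add_column("SIGI", "Q")
    data = [refls.hkl.astype(float), refls.I_obs[:, None], refls.sigma_I[:, None]]
    for name, col, typ in (("Ee", refls.Ee, "R"), ("DOBS", refls.Dobs, "R"),
                           ("BIN", refls.bin_id, "R")):
        if col is not None:
            mtz.add_column(name, typ)
            data.append(np.asarray(col, dtype=float)[:, None])
    if refls.is_test is not None:
        mtz.add_column("FreeR_flag", "I")
        data.append(refls.is_test.astype(float)[:, None])
    mtz.set_data(np.hstack(data))
    mtz.write_to_file(str(path))


def assign_centric_epsilon(refls: ReflectionSet,
                           sym: CrystalSymmetry) -> ReflectionSet:
    """Centric flags and epsilon factors from the symmetry operations."""
    return replace(refls,
                   centric=sym.centric_flags(refls.hkl),
                   epsilon=sym.epsilon_factors(refls.hkl))


def make_bins(refls: ReflectionSet, target_per_bin: int = 200,
              min_per_bin: int | None = None) -> ResolutionBinning:
    """Equal-count resolution bins in 1/d^3 order; assigns ``bin_id``."""
    n = len(refls)
    floor = max(50, target_per_bin // 2) if min_per_bin is None else min_per_bin
    n_bins = max(1, int(round(n / target_per_bin)))
    while n_bins > 1 and n // n_bins < floor:
        n_bins -= 1
    order = np.argsort(1.0 / refls.d ** 3, kind="stable")
    bin_id = np.empty(n, dtype=int)
    # spread the remainder one-per-bin over the first bins
    base, rem = divmod(n, n_bins)
    start = 0
    edges_d = [float(np.max(refls.d))]
    d_sorted = refls.d[order]
    for b in range(n_bins):
        cnt = base + (1 if b < rem else 0)
        bin_id[order[start:start + cnt]] = b
        hi = start + cnt
        if b < n_bins - 1:
            edges_d.append(float(0.5 * (d_sorted[hi - 1] + d_sorted[hi])))
        start = hi
    edges_d.append(float(np.min(refls.d)))
    refls.bin_id = bin_id
    return ResolutionBinning(n_bins=n_bins, edges=np.array(edges_d))


def _wilson_posterior_moments(I_n, s_n, centric):
    """Posterior mean and second moment of the true normalized amplitude E.

    ``I_n``/``s_n`` are intensity and sigma in normalized units (divided by
    eps * <I/eps>_bin).  The prior is Wilson: acentric p(E) = 2 E exp(-E^2),
    centric p(E) = sqrt(2/pi) exp(-E^2 / 2); the likelihood is Gaussian in
    intensity.  Integrals use per-reflection 64-point Gauss-Legendre nodes.
    """
    nodes, weights = np.polynomial.legendre.leggauss(_GL_POINTS)
    # the Gaussian intensity likelihood confines the posterior to
    # E^2 in I_n +/- 8 s_n; the prior can only narrow this further
    lo = np.sqrt(np.maximum(I_n - 8.0 * s_n, 0.0))
    hi = np.sqrt(np.maximum(I_n, 0.0) + 8.0 * s_n)
    half = 0.5 * (hi - lo)
    E = lo[:, None] + half[:, None] * (nodes[None, :] + 1.0)  # (n, 64)
    w = half[:, None] * weights[None, :]

    log_lik = -0.5 * ((I_n[:, None] - E ** 2) / s_n[:, None]) ** 2
    log_prior = np.where(centric[:, None],
                         -0.5 * E ** 2,
                         np.log(np.maximum(E, 1e-300)) - E ** 2)
    log_f = log_lik + log_prior
    log_f -= log_f.max(axis=1, keepdims=True)
    f = np.exp(log_f) * w
    z = f.sum(axis=1)
    mu1 = (f * E).sum(axis=1) / z
    mu2 = (f * E ** 2).sum(axis=1) / z
    return mu1, mu2


def effective_amplitudes(refls: ReflectionSet,
                         binning: ResolutionBinning) -> ReflectionSet:
    """Compute Ee, Dobs and posterior-mean amplitudes F_obs.

    Requires I_obs, sigma_I, epsilon, centric and bin_id.  Bins with fewer
    than 10 reflections are merged with their lower-resolution neighbour
    for the normalization statistics (a warning is emitted).
    """
    if refls.epsilon is None or refls.centric is None:
        raise ValueError("assign_centric_epsilon must run first")
    if refls.bin_id is None:
        raise ValueError("make_bins must run first")
    if np.any(refls.sigma_I <= 0):
        raise ValueError("sigma_I must be positive for all reflections")

    n_bins = binning.n_bins
    bin_id = refls.bin_id.copy()
    counts = np.bincount(bin_id, minlength=n_bins)
    for b in np.nonzero(counts < 10)[0]:
        if n_bins == 1:
            break
        import warnings
        neighbour = b - 1 if b > 0 else b + 1
        warnings.warn(f"resolution bin {b} has {counts[b]} reflections; "
                      f"merged with bin {neighbour} for normalization")
        bin_id[bin_id == b] = neighbour

    eps = refls.epsilon.astype(float)
    Ieps = refls.I_obs / eps
    sums = np.bincount(bin_id, weights=Ieps, minlength=n_bins)
    cnts = np.maximum(np.bincount(bin_id, minlength=n_bins), 1)
    mean_I = sums / cnts
    mean_I = np.maximum(mean_I, 1e-12 * np.max(np.abs(mean_I)))

    scale = eps * mean_I[bin_id]
    I_n = refls.I_obs / scale
    s_n = np.maximum(refls.sigma_I / scale, 1e-10)

    mu1, mu2 = _wilson_posterior_moments(I_n, s_n, refls.centric)
    dobs2 = np.clip(1.0 + mu1 ** 2 - mu2, 1e-12, 1.0)
    Dobs = np.sqrt(dobs2)
    Ee_raw = mu1 / Dobs

    # per-bin renormalization so <Ee^2> = 1
    e2 = np.bincount(bin_id, weights=Ee_raw ** 2, minlength=n_bins) / cnts
    Ee = Ee_raw / np.sqrt(np.maximum(e2[bin_id], 1e-12))

    F_obs = mu1 * np.sqrt(scale)
    return replace(refls, Ee=Ee, Dobs=Dobs, F_obs=F_obs,
                   bin_id=refls.bin_id, mean_I_bin=mean_I)


def split_work_test(refls: ReflectionSet, fraction: float = 0.05,
                    seed: int = 0) -> ReflectionSet:
    """Stratified-random free-set flags: per-bin counts by largest remainder."""
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if refls.bin_id is None:
        raise ValueError("make_bins must run first")
    rng = np.random.default_rng(seed)
    n = len(refls)
    n_test = int(round(fraction * n))
    bins = np.unique(refls.bin_id)
    sizes = np.array([np.sum(refls.bin_id == b) for b in bins])
    quota = fraction * sizes
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = n_test - base.sum()
    if short > 0:
        base[np.argsort(-rem, kind="stable")[:short]] += 1
    is_test = np.zeros(n, dtype=bool)
    for b, k in zip(bins, base):
        idx = np.nonzero(refls.bin_id == b)[0]
        pick = rng.choice(idx, size=min(k, len(idx)), replace=False)
        is_test[pick] = True
    out = replace(refls, is_test=is_test)
    out.meta = dict(refls.meta, test_fraction=fraction, test_seed=seed)
    return out
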