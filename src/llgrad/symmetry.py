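"""Crystal symmetry: unit cell, space group, and symmetry operations.

Thin, array-oriented wrapper around gemmi's space-group tables.  Rotation
parts act on Miller indices as row vectors (h' = h R); translations are in
fractional coordinates.  The reciprocal-ASU mapping and Friedel merging
follow the standard CCP4 convention via gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["CrystalSymmetry", "SymOp"]


@dataclass(frozen=True)
class SymOp:
    """One space-group operation: x' = R x + t (fractional coordinates)."""

    rot: np.ndarray   # (3, 3) integer rotation part
    tran: np.ndarray  # (3,) fractional translation

    def compose(self, other: "SymOp") -> "SymOp":
        return SymOp(self.rot @ other.rot,
                     (self.rot @ other.tran + self.tran) % 1.0)


@dataclass
class CrystalSymmetry:
    """Unit cell plus space-group operations.

    Parameters
    ----------
    unit_cell : (a, b, c, alpha, beta, gamma) in Angstrom / degrees.
    space_group : Hermann-Mauguin symbol, e.g. ``"P 21 21 21"``.
    """

    unit_cell: tuple
    space_group: str
    sym_ops: list = field(default_factory=list)

    def __post_init__(self):
        self._cell = gemmi.UnitCell(*self.unit_cell)
        self._sg = gemmi.SpaceGroup(self.space_group)
        if not self.sym_ops:
            den = float(gemmi.Op.DEN)
            for op in self._sg.operations():
                rot = np.array(op.rot, dtype=float) / den
                if not np.allclose(rot, np.round(rot)):
                    raise ValueError(f"non-integral rotation in {self.space_group}")
                self.sym_ops.append(SymOp(np.round(rot).astype(int),
                                          np.array(op.tran, dtype=float) / den))

    # -- gemmi handles ---------------------------------------------------
    @property
    def cell(self) -> gemmi.UnitCell:
        return self._cell

    @property
    def gemmi_sg(self) -> gemmi.SpaceGroup:
        return self._sg

    @property
    def n_ops(self) -> int:
        return len(self.sym_ops)

    # -- geometry --------------------------------------------------------
    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 orthogonal->fractional matrix (a along x convention)."""
        return np.array(self._cell.frac.mat)

    @property
    def orth_matrix(self) -> np.ndarray:
        return np.array(self._cell.orth.mat)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) for an (n, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # 1/d^2 = h^T (B B^T) h with B the reciprocal orthogonalization
        B = self.frac_matrix  # rows are reciprocal basis vectors (a*, b*, c*)
        s_vec = hkl @ B
        inv_d2 = np.sum(s_vec * s_vec, axis=1)
        return 1.0 / np.sqrt(inv_d2)

    # -- reflection attributes -------------------------------------------
    def is_absent(self, hkl: np.ndarray) -> np.ndarray:
        """Systematic-absence flags by the phase-shift criterion.

        A reflection is absent iff some operation fixes hkl (h R = h) with a
        translation for which h.t is not an integer.
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        absent = np.zeros(len(hkl), dtype=bool)
        for op in self.sym_ops:
            fixed = np.all(hkl @ op.rot == hkl, axis=1)
            phase = hkl @ op.tran
            absent |= fixed & (np.abs(phase - np.round(phase)) > 1e-9)
        return absent

    def centric_flags(self, hkl: np.ndarray) -> np.ndarray:
        """True iff some operation maps hkl to -hkl."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        cen = np.zeros(len(hkl), dtype=bool)
        for op in self.sym_ops:
            cen |= np.all(hkl @ op.rot == -hkl, axis=1)
        return cen

    def epsilon_factors(self, hkl: np.ndarray) -> np.ndarray:
        """Multiplicity factor: number of rotation parts fixing hkl."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        eps = np.zeros(len(hkl), dtype=int)
        for op in self.sym_ops:
            eps += np.all(hkl @ op.rot == hkl, axis=1)
        return eps

    def map_to_asu(self, hkl: np.ndarray) -> np.ndarray:
        """Map Miller indices to the reciprocal asymmetric unit (+Friedel)."""
        asu = gemmi.ReciprocalAsu(self._sg)
        ops = self._sg.operations()
        out = np.empty_like(np.atleast_2d(np.asarray(hkl, dtype=int)))
        for i, h in enumerate(np.atleast_2d(hkl)):
            out[i], _ = asu.to_asu([int(h[0]), int(h[1]), int(h[2])], ops)
        return out

    def check_group_closure(self) -> bool:
        """Brute-force group property: composition stays in the op set."""
        keys = {self._op_key(op) for op in self.sym_ops}
        for a in self.sym_ops:
            for b in self.sym_ops:
                if self._op_key(a.compose(b)) not in keys:
                    return False
        ident = SymOp(np.eye(3, dtype=int), np.zeros(3))
        return self._op_key(ident) in keys

    @staticmethod
    def _op_key(op: SymOp) -> tuple:
        return (tuple(op.rot.ravel()), tuple(np.round(op.tran % 1.0, 6)))
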