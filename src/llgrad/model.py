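"""Atomic models and X-ray scattering factors.

:class:`AtomicModel` is a flat array container (one row per atom) with
per-residue pLDDT confidence carried alongside, since the refinement loop
derives isotropic displacement parameters (pseudo-B) from confidence at
every iteration.  PDB/mmCIF reading and writing goes through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = ["AtomicModel", "FormFactorTable", "read_model", "write_pdb"]


@dataclass
class AtomicModel:
    coords: np.ndarray                 # (n_atoms, 3) orthogonal Angstrom
    element: np.ndarray                # (n_atoms,) element symbols
    occupancy: np.ndarray              # (n_atoms,) in [0, 1]
    b_iso: np.ndarray                  # (n_atoms,) Angstrom^2, > 0
    plddt: np.ndarray | None = None    # (n_atoms,) per-residue confidence
    residue_id: np.ndarray | None = None
    chain_id: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(np.asarray(self.b_iso) <= 0):
            raise ValueError("b_iso must be positive")
        if self.plddt is not None and (np.any(np.asarray(self.plddt) < 0)
                                       or np.any(np.asarray(self.plddt) > 100)):
            raise ValueError("plddt must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def ca_mask(self) -> np.ndarray:
        names = self.meta.get("atom_name")
        if names is None:
            return np.ones(len(self), dtype=bool)  # toy models: all-Ca
        return np.asarray(names) == "CA"

    def with_coords(self, coords) -> "AtomicModel":
        return replace(self, coords=np.asarray(coords, dtype=float))


def read_model(path) -> AtomicModel:
    """Read a PDB or mmCIF model (coordinates, occupancy, B, element)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords, elem, occ, b, res_id, ch_id, names, plddt = [], [], [], [], [], [], [], []
    mdl = st[0]
    for chain in mdl:
        for res in chain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elem.append(atom.element.name)
                occ.append(atom.occ)
                b.append(max(atom.b_iso, 1e-3))
                res_id.append(res.seqid.num)
                ch_id.append(chain.name)
                names.append(atom.name)
                # predicted models conventionally store pLDDT in the B column
                plddt.append(atom.b_iso if 0.0 <= atom.b_iso <= 100.0 else np.nan)
    return AtomicModel(
        coords=np.array(coords), element=np.array(elem),
        occupancy=np.array(occ), b_iso=np.array(b),
        plddt=None,
        residue_id=np.array(res_id), chain_id=np.array(ch_id),
        meta={"atom_name": np.array(names), "source": str(path)})


def write_pdb(path, model: AtomicModel, cell=None, space_group="P 1"):
    st = gemmi.Structure()
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell)
        st.spacegroup_hm = space_group
    md = gemmi.Model("1")
    names = model.meta.get("atom_name")
    chains: dict[str, gemmi.Chain] = {}
    for i in range(len(model)):
        cid = str(model.chain_id[i]) if model.chain_id is not None else "A"
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        chain = chains[cid]
        rid = int(model.residue_id[i]) if model.residue_id is not None else i + 1
        if len(chain) == 0 or chain[-1].seqid.num != rid:
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(rid, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(names[i]) if names is not None else "CA"
        atom.element = gemmi.Element(str(model.element[i]))
        atom.pos = gemmi.Position(*model.coords[i])
        atom.occ = float(model.occupancy[i])
        atom.b_iso = float(model.b_iso[i])
        chain[-1].add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.write_pdb(str(path))


class FormFactorTable:
    """4-Gaussian + constant X-ray scattering factors (IT92 coefficients).

    f(s) = sum_i a_i exp(-b_i s^2) + c  with  s = sin(theta)/lambda.
    """

    def __init__(self):
        self._cache: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}

    def _coefs(self, element: str):
        if element not in self._cache:
            el = gemmi.Element(element)
            if el.atomic_number == 0:
                raise ValueError(f"unknown element {element!r}")
            co = el.it92.get_coefs()
            self._cache[element] = (np.array(co[:4]), np.array(co[4:8]),
                                    float(co[8]))
        return self._cache[element]

    def evaluate(self, element: str, stol2: np.ndarray) -> np.ndarray:
        """f at (sin theta / lambda)^2 = ``stol2`` = 1 / (4 d^2)."""
        a, b, c = self._coefs(element)
        return (a[None, :] * np.exp(-b[None, :] * np.asarray(stol2)[:, None])
                ).sum(axis=1) + c

    def f0(self, element: str) -> float:
        a, b, c = self._coefs(element)
        return float(a.sum() + c)
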