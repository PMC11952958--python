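"""Atomic structure handling: reading, residue addressing, geometry, symmetry expansion.

Structures are held in a light array-backed container (:class:`StructureModel`)
so that downstream geometry (pair distances, cross-link mapping, Debye curves)
is plain numpy. Parsing of PDB/mmCIF, unit cells and space-group operators is
delegated to gemmi.

Residues are addressed by *author* numbering, the numbering printed in PDB
files and used in the literature (e.g. K214 of NF90). Internal indices are
never part of the public surface.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import cdist


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class ResidueLookupError(KeyError):
    """Raised when a residue address does not resolve in a model."""


class MissingCellError(ValueError):
    """Raised when a crystallographic operation needs a cell the model lacks."""


@dataclass(frozen=True)
class ResidueAddress:
    """Address of one residue (optionally one atom) under author numbering."""

    chain: str
    resnum: int
    atom: str = "CA"

    def __post_init__(self):
        if self.resnum <= 0:
            raise ValueError(f"residue number must be positive, got {self.resnum}")


@dataclass
class StructureModel:
    """Array-backed atomic model.

    Parallel arrays over atoms; ``cell`` is (a, b, c, alpha, beta, gamma) in
    Å / degrees and ``symmetry_ops`` is a list of (3x3 rotation, translation)
    pairs acting on fractional coordinates, identity included exactly once.
    """

    chain: np.ndarray          # str per atom
    resnum: np.ndarray         # int per atom (author numbering)
    resname: np.ndarray        # str per atom
    atom_name: np.ndarray      # str per atom
    element: np.ndarray        # str per atom
    xyz: np.ndarray            # (n, 3) float, Å
    occupancy: np.ndarray      # float per atom
    cell: tuple | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] | None = None
    model_id: str = "1"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atom coordinates")
        if self.symmetry_ops is not None:
            n_id = sum(
                1
                for rot, tr in self.symmetry_ops
                if np.allclose(rot, np.eye(3)) and np.allclose(tr, 0.0)
            )
            if n_id != 1:
                raise ValueError("symmetry operator list must contain the identity exactly once")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def chains(self) -> list[str]:
        return sorted(set(self.chain.tolist()))

    def heavy_mask(self) -> np.ndarray:
        elem = np.char.upper(self.element.astype(str))
        return elem != "H"

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            resname=self.resname[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            xyz=self.xyz[mask],
            occupancy=self.occupancy[mask],
            cell=self.cell,
            symmetry_ops=self.symmetry_ops,
            model_id=self.model_id,
        )

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> rot @ x + trans (Cartesian Å)."""
        out = copy.copy(self)
        out.xyz = self.xyz @ np.asarray(rot, float).T + np.asarray(trans, float)
        return out

    def residues(self, chain: str | None = None) -> list[tuple[str, int]]:
        keys = list(zip(self.chain.tolist(), self.resnum.tolist()))
        seen, out = set(), []
        for k in keys:
            if (chain is None or k[0] == chain) and k not in seen:
                seen.add(k)
                out.append(k)
        return out


@dataclass
class SymmetryCopy:
    """One symmetry/lattice copy produced by :func:`symmetry_expand`."""

    xyz: np.ndarray
    op_index: int
    lattice_shift: tuple[int, int, int]
    is_identity: bool = field(default=False)


def _dedup_altlocs(atoms):
    """Keep highest-occupancy conformer per (chain, resnum, atom name); ties by altloc order."""
    best = {}
    for a in atoms:
        key = (a["chain"], a["resnum"], a["atom_name"])
        prev = best.get(key)
        if prev is None:
            best[key] = a
        else:
            if (a["occ"], _neg_altloc(a["altloc"])) > (prev["occ"], _neg_altloc(prev["altloc"])):
                best[key] = a
    return list(best.values())


def _neg_altloc(alt: str):
    # higher rank for earlier letters; '' outranks everything
    if not alt:
        return 1000
    return -ord(alt)


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The first model is used (a warning is emitted if the file holds several).
    Unit cell and space-group symmetry operators are recorded when present.
    Altloc conformers are collapsed to the highest-occupancy one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; using the first")
    model = st[0]

    atoms = []
    for ch in model:
        for res in ch:
            for at in res:
                atoms.append(
                    dict(
                        chain=ch.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occ=at.occ,
                        altloc=at.altloc,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms in first model")
    atoms = _dedup_altlocs(atoms)
    atoms.sort(key=lambda a: (a["chain"], a["resnum"], a["atom_name"]))

    cell = None
    ops = None
    ucell = st.cell
    if ucell is not None and ucell.a > 1.0 and ucell.volume > 1.0:
        cell = (ucell.a, ucell.b, ucell.c, ucell.alpha, ucell.beta, ucell.gamma)
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
        if sg is not None:
            ops = []
            for op in sg.operations():
                rot = np.array(op.rot, dtype=float) / op.DEN
                tran = np.array(op.tran, dtype=float) / op.DEN
                ops.append((rot, tran))

    return StructureModel(
        chain=np.array([a["chain"] for a in atoms]),
        resnum=np.array([a["resnum"] for a in atoms], dtype=int),
        resname=np.array([a["resname"] for a in atoms]),
        atom_name=np.array([a["atom_name"] for a in atoms]),
        element=np.array([a["element"] for a in atoms]),
        xyz=np.array([[a["x"], a["y"], a["z"]] for a in atoms], dtype=float),
        occupancy=np.array([a["occ"] for a in atoms], dtype=float),
        cell=cell,
        symmetry_ops=ops,
        model_id=str(getattr(model, "name", None) or getattr(model, "num", 1)),
    )


def write_pdb(model: StructureModel, path: str | Path, spacegroup: str = "P 1") -> None:
    """Write a model as a minimal PDB file (CRYST1 included when a cell is set)."""
    st = gemmi.Structure()
    st.name = "model"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
        st.spacegroup_hm = spacegroup
    gm = gemmi.Model("1")
    for ch_name in model.chains():
        ch = gemmi.Chain(ch_name)
        mask = model.chain == ch_name
        idx = np.where(mask)[0]
        cur_res = None
        for i in idx:
            rn = int(model.resnum[i])
            if cur_res is None or cur_res.seqid.num != rn:
                cur_res = gemmi.Residue()
                cur_res.name = str(model.resname[i])
                cur_res.seqid = gemmi.SeqId(rn, " ")
                ch.add_residue(cur_res)
                cur_res = ch[-1]
            at = gemmi.Atom()
            at.name = str(model.atom_name[i])
            at.element = gemmi.Element(str(model.element[i]))
            at.pos = gemmi.Position(*model.xyz[i])
            at.occ = float(model.occupancy[i])
            cur_res.add_atom(at)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def residue_anchor(model: StructureModel, address: ResidueAddress) -> tuple[np.ndarray, bool]:
    """Coordinates of the anchor atom of a residue (default Cα).

    Returns ``(xyz, is_center)`` where ``is_center`` is True when the named
    atom is absent (e.g. ligands) and the residue geometric center was used.
    """
    mask = (model.chain == address.chain) & (model.resnum == address.resnum)
    if not mask.any():
        present = model.resnum[model.chain == address.chain]
        if present.size:
            rng = f"{present.min()}–{present.max()}"
            raise ResidueLookupError(
                f"residue {address.resnum} not in chain {address.chain} "
                f"(residues present: {rng})"
            )
        raise ResidueLookupError(f"chain {address.chain!r} not in model "
                                 f"(chains: {model.chains()})")
    at = mask & (model.atom_name == address.atom)
    if at.any():
        return model.xyz[at][0].copy(), False
    return model.xyz[mask].mean(axis=0), True


def max_pairwise_distance(model: StructureModel, mask: np.ndarray | None = None,
                          include_hydrogens: bool = False) -> float:
    """Exact maximum pairwise atomic distance (Å).

    Hydrogens are excluded by default. The maximum distance is attained on
    convex-hull vertices, so for large models the O(n²) scan runs on the hull
    only; the result is exact either way.
    """
    sel = np.ones(model.n_atoms, bool) if mask is None else np.asarray(mask, bool).copy()
    if not include_hydrogens:
        sel &= model.heavy_mask()
    pts = model.xyz[sel]
    if len(pts) < 2:
        raise ValueError("need at least 2 selected atoms")
    if len(pts) > 300:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate geometry (collinear); fall back to full scan
    return float(cdist(pts, pts).max())


def _frac_matrices(cell: tuple) -> tuple[np.ndarray, np.ndarray]:
    uc = gemmi.UnitCell(*cell)
    orth = np.array(uc.orth.mat.tolist(), dtype=float)
    frac = np.array(uc.frac.mat.tolist(), dtype=float)
    return orth, frac


def symmetry_expand(
    model: StructureModel,
    center: Sequence[float],
    radius: float,
    lattice_range: int = 2,
) -> list[SymmetryCopy]:
    """All symmetry/lattice copies with ≥1 atom within ``radius`` Å of ``center``.

    Lattice translations are searched over the integer block
    ``[-lattice_range, lattice_range]^3``; the identity copy is always included.
    """
    if model.cell is None:
        raise MissingCellError(
            "model has no unit cell; run without symmetry (single-copy mode) "
            "or supply cell parameters"
        )
    if not np.isfinite(radius):
        raise ValueError("radius must be finite")
    ops = model.symmetry_ops or [(np.eye(3), np.zeros(3))]
    orth, frac = _frac_matrices(model.cell)
    center = np.asarray(center, float)
    xyz_frac = model.xyz @ frac.T

    shifts = np.array(
        [(i, j, k)
         for i in range(-lattice_range, lattice_range + 1)
         for j in range(-lattice_range, lattice_range + 1)
         for k in range(-lattice_range, lattice_range + 1)],
        dtype=int,
    )
    copies: list[SymmetryCopy] = []
    for oi, (rot, tran) in enumerate(ops):
        base = xyz_frac @ rot.T + tran
        is_id_op = np.allclose(rot, np.eye(3)) and np.allclose(tran, 0.0)
        for sh in shifts:
            cart = (base + sh) @ orth.T
            d2 = np.einsum("ij,ij->i", cart - center, cart - center)
            if d2.min() <= radius * radius:
                is_identity = is_id_op and not sh.any()
                copies.append(SymmetryCopy(cart, oi, tuple(int(s) for s in sh), is_identity))
    if not any(c.is_identity for c in copies):
        # identity always included, by contract
        cart = xyz_frac @ orth.T
        copies.insert(0, SymmetryCopy(cart, 0, (0, 0, 0), True))
    return copies


def concat_models(models: Iterable[StructureModel], chain_suffixes: bool = True) -> StructureModel:
    """Concatenate copies into one model, disambiguating chain ids with numeric suffixes."""
    models = list(models)
    chains, resnums, resnames, atoms, elems, xyzs, occs = [], [], [], [], [], [], []
    for k, m in enumerate(models):
        suffix = "" if (k == 0 or not chain_suffixes) else str(k + 1)
        chains.append(np.array([c + suffix for c in m.chain]))
        resnums.append(m.resnum)
        resnames.append(m.resname)
        atoms.append(m.atom_name)
        elems.append(m.element)
        xyzs.append(m.xyz)
        occs.append(m.occupancy)
    return StructureModel(
        chain=np.concatenate(chains),
        resnum=np.concatenate(resnums),
        resname=np.concatenate(resnames),
        atom_name=np.concatenate(atoms),
        element=np.concatenate(elems),
        xyz=np.vstack(xyzs),
        occupancy=np.concatenate(occs),
    )


def min_intermodel_distance(a_xyz: np.ndarray, b_xyz: np.ndarray) -> float:
    """Minimum distance between two point sets (cKDTree)."""
    d, _ = cKDTree(b_xyz).query(a_xyz, k=1)
    return float(d.min())
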