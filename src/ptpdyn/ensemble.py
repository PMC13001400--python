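"""Coordinate ensembles, PDB/NPZ I/O and loop selections.

The central container is :class:`CoordinateEnsemble`: a stack of frames over a
fixed atom table.  Structures and multi-model trajectories are read and written
as PDB through biotite; the package's own array container (NPZ) holds larger
synthetic ensembles losslessly.

Residue numbering policy: author numbering from the input file is kept as-is,
1-based, and never renumbered internally.  Different PTPs use different
numbering conventions, so variant tables and structures must share a numbering;
agreement is checked through wild-type residue names where possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.info import mass as element_mass
from biotite.structure.io.pdb import PDBFile

BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class LoopDefinition:
    """Named residue selection anchoring loop-level metrics.

    Residue ids follow the author numbering of the structure the definition is
    applied to (1-based, inclusive).  Canonical PTP loop names are WPD, P, Q
    and E; any other label is treated as a custom loop.
    """

    name: str
    residue_ids: list[int]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.residue_ids) == 0:
            raise ValueError(f"loop {self.name!r}: residue id list is empty")
        ids = list(self.residue_ids)
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"loop {self.name!r}: residue ids must be strictly increasing")

    @classmethod
    def from_range(cls, name: str, start: int, stop: int, chain_id: str | None = None) -> "LoopDefinition":
        return cls(name, list(range(start, stop + 1)), chain_id)


@dataclass
class CoordinateEnsemble:
    """Frames of Cartesian coordinates over a fixed atom table.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Angstrom.
    atoms : DataFrame
        One row per atom with columns ``res_id, res_name, atom_name, chain_id,
        element, mass, hetero, ca_only``.
    frame_spacing : float, optional
        Time between frames, in the caller's unit; purely metadata.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_spacing: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but frames carry "
                f"{self.coords.shape[1]} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atoms["atom_name"].to_numpy() == "CA")

    def frame(self, i: int) -> "CoordinateEnsemble":
        """Single-frame view (copy) of frame ``i``."""
        return CoordinateEnsemble(self.coords[i : i + 1].copy(), self.atoms, self.frame_spacing)

    # ---- I/O -------------------------------------------------------------

    def to_pdb(self, path) -> None:
        """Write as (multi-model) PDB, one MODEL per frame."""
        n = self.n_atoms
        template = AtomArray(n)
        template.coord = self.coords[0].astype(np.float32)
        template.chain_id = self.atoms["chain_id"].fillna("A").to_numpy(dtype="U4")
        template.res_id = self.atoms["res_id"].to_numpy(dtype=int)
        template.res_name = self.atoms["res_name"].to_numpy(dtype="U5")
        template.atom_name = self.atoms["atom_name"].to_numpy(dtype="U6")
        template.element = self.atoms["element"].to_numpy(dtype="U2")
        template.hetero = self.atoms["hetero"].to_numpy(dtype=bool)
        stack = AtomArrayStack(self.n_frames, n)
        for key in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
            stack.set_annotation(key, template.get_annotation(key))
        stack.coord = self.coords.astype(np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    def to_npz(self, path) -> None:
        """Write to the package's lossless array container."""
        np.savez(
            str(path),
            coords=self.coords,
            res_id=self.atoms["res_id"].to_numpy(dtype=int),
            res_name=self.atoms["res_name"].to_numpy(dtype="U5"),
            atom_name=self.atoms["atom_name"].to_numpy(dtype="U6"),
            chain_id=self.atoms["chain_id"].fillna("A").to_numpy(dtype="U4"),
            element=self.atoms["element"].to_numpy(dtype="U2"),
            hetero=self.atoms["hetero"].to_numpy(dtype=bool),
        )

    @classmethod
    def from_npz(cls, path) -> "CoordinateEnsemble":
        with np.load(str(path)) as data:
            atoms = _build_atom_table(
                res_id=data["res_id"],
                res_name=data["res_name"],
                atom_name=data["atom_name"],
                chain_id=data["chain_id"],
                element=data["element"],
                hetero=data["hetero"],
            )
            return cls(data["coords"], atoms)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    # two-letter elements that occur in proteins/ligands
    if name[:2].upper() in {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA"} and len(name) <= 2:
        return name[:2].capitalize()
    return name[0].upper()


def _safe_mass(element: str) -> float:
    try:
        m = element_mass(element)
    except KeyError:
        m = None
    return float(m) if m is not None else 0.0


def _build_atom_table(res_id, res_name, atom_name, chain_id, element, hetero) -> pd.DataFrame:
    atoms = pd.DataFrame(
        {
            "res_id": np.asarray(res_id, dtype=int),
            "res_name": np.char.strip(np.asarray(res_name, dtype="U5")),
            "atom_name": np.char.strip(np.asarray(atom_name, dtype="U6")),
            "chain_id": np.char.strip(np.asarray(chain_id, dtype="U4")),
            "element": np.char.strip(np.asarray(element, dtype="U2")),
            "hetero": np.asarray(hetero, dtype=bool),
        }
    )
    empty = atoms["element"] == ""
    if empty.any():
        atoms.loc[empty, "element"] = [_guess_element(n) for n in atoms.loc[empty, "atom_name"]]
    atoms["mass"] = [_safe_mass(e) for e in atoms["element"]]
    # flag residues whose only heavy atom is the Calpha (coarse / incomplete models)
    heavy = atoms[atoms["element"] != "H"]
    ca_only_keys = set()
    for key, grp in heavy.groupby(["chain_id", "res_id"], sort=False):
        if set(grp["atom_name"]) == {"CA"}:
            ca_only_keys.add(key)
    atoms["ca_only"] = [
        (c, r) in ca_only_keys for c, r in zip(atoms["chain_id"], atoms["res_id"])
    ]
    return atoms


def ensemble_from_arrays(
    coords: np.ndarray,
    res_ids,
    res_names=None,
    atom_names=None,
    chain_id: str = "A",
    elements=None,
) -> CoordinateEnsemble:
    """Build an ensemble directly from arrays (synthetic data, tests).

    Defaults describe a Calpha bead model: one CA carbon per residue.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    res_ids = np.asarray(res_ids, dtype=int)
    if res_names is None:
        res_names = np.full(n, "ALA")
    if atom_names is None:
        atom_names = np.full(n, "CA")
    if elements is None:
        elements = np.array([_guess_element(a) for a in atom_names])
    atoms = _build_atom_table(
        res_id=res_ids,
        res_name=np.asarray(res_names, dtype="U5"),
        atom_name=np.asarray(atom_names, dtype="U6"),
        chain_id=np.full(n, chain_id, dtype="U4"),
        element=np.asarray(elements, dtype="U2"),
        hetero=np.zeros(n, dtype=bool),
    )
    return CoordinateEnsemble(coords, atoms)


def load_structure(path, model_index: int | None = None) -> CoordinateEnsemble:
    """Read a PDB file (or NPZ container) into a :class:`CoordinateEnsemble`.

    Parameters
    ----------
    path : path-like
        ``.npz`` is dispatched to the array container; anything else is parsed
        as PDB.  Multi-MODEL files become multi-frame ensembles.
    model_index : int, optional
        0-based model to extract; default keeps every model as a frame.
    """
    spath = str(path)
    if spath.endswith(".npz"):
        ens = CoordinateEnsemble.from_npz(spath)
        if model_index is not None:
            if not 0 <= model_index < ens.n_frames:
                raise IndexError(f"model {model_index} out of range (0..{ens.n_frames - 1})")
            return ens.frame(model_index)
        return ens
    try:
        pdb = PDBFile.read(spath)
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise StructureFormatError(f"cannot parse PDB file {spath}: {exc}") from exc
    if isinstance(stack, AtomArray):
        stack = AtomArrayStack(1, stack.array_length())  # pragma: no cover
    n_models = stack.stack_depth()
    if model_index is not None:
        if not 0 <= model_index < n_models:
            raise IndexError(f"model {model_index} out of range (0..{n_models - 1})")
        coords = np.asarray(stack.coord[model_index : model_index + 1], dtype=float)
    else:
        coords = np.asarray(stack.coord, dtype=float)
    atoms = _build_atom_table(
        res_id=stack.res_id,
        res_name=stack.res_name,
        atom_name=stack.atom_name,
        chain_id=stack.chain_id,
        element=stack.element,
        hetero=stack.hetero,
    )
    ens = CoordinateEnsemble(coords, atoms)
    ens.metadata["source"] = spath
    return ens


def select_loop(
    ensemble: CoordinateEnsemble,
    loop: LoopDefinition,
    mode: str = "ca",
) -> np.ndarray:
    """Atom indices of a loop, ordered by residue id.

    ``mode='ca'`` selects Calpha atoms only; ``mode='heavy'`` all non-hydrogen
    atoms.  A loop residue missing from the structure (or missing its CA in
    ``ca`` mode) is an error naming the residue — selections never silently
    shrink.
    """
    if mode not in ("ca", "heavy"):
        raise ValueError(f"unknown selection mode {mode!r}")
    atoms = ensemble.atoms
    in_chain = (
        np.ones(len(atoms), dtype=bool)
        if loop.chain_id is None
        else (atoms["chain_id"].to_numpy() == loop.chain_id)
    )
    names = atoms["atom_name"].to_numpy()
    elements = atoms["element"].to_numpy()
    res_ids = atoms["res_id"].to_numpy()
    wanted = (names == "CA") if mode == "ca" else (elements != "H")
    indices: list[int] = []
    for rid in loop.residue_ids:
        hits = np.flatnonzero(in_chain & wanted & (res_ids == rid))
        if hits.size == 0:
            chain = loop.chain_id or "any"
            raise KeyError(
                f"loop {loop.name!r}: residue {rid} (chain {chain}) has no "
                f"{'CA atom' if mode == 'ca' else 'heavy atoms'} in the structure"
            )
        indices.extend(hits.tolist())
    return np.asarray(indices, dtype=int)


def warn_if_ca_only(ensemble: CoordinateEnsemble) -> int:
    """Warn about residues modelled without side chains; return their count."""
    flagged = ensemble.atoms.loc[ensemble.atoms["ca_only"], ["chain_id", "res_id"]]
    n = flagged.drop_duplicates().shape[0]
    if n:
        warnings.warn(f"{n} residue(s) carry only a CA atom", stacklevel=2)
    return n
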