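"""Read and write conformational ensembles as multi-model PDB files.

An ensemble is a set of conformations of one protein sequence.  All members
must share an identical atom count and ordering so that downstream Cartesian
PCA is well defined; this is validated on construction.  Parsing and
serialization of the PDB format itself is delegated to :mod:`biotite`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb

__all__ = [
    "Structure",
    "StructureEnsemble",
    "EnsembleIOError",
    "read_ensemble",
    "extract_ca",
    "write_ensemble",
]

_WEIGHT_TOL = 1e-9


class EnsembleIOError(ValueError):
    """Structured error for malformed or inconsistent ensemble input."""


@dataclass
class Structure:
    """One conformation: parallel arrays of atom names, residue ids, coordinates (Å)."""

    atom_names: Sequence[str]
    residue_ids: Sequence[int]
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise EnsembleIOError(
                f"model {self.model_id}: coords must be (n_atoms, 3), got {self.coords.shape}"
            )
        if len(self.atom_names) != len(self.coords):
            raise EnsembleIOError(
                f"model {self.model_id}: {len(self.atom_names)} atom names for "
                f"{len(self.coords)} coordinates"
            )
        if len(self.residue_ids) != len(self.coords):
            raise EnsembleIOError(
                f"model {self.model_id}: residue_ids length mismatch"
            )
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleIOError(f"model {self.model_id}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class StructureEnsemble:
    """A weighted set of conformations with identical atom layout.

    ``weights`` are per-member probabilities (normalized on construction);
    ``source_label`` records provenance (e.g. which generator produced it).
    """

    members: list[Structure]
    weights: np.ndarray | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise EnsembleIOError("ensemble must contain at least one member")
        n0 = self.members[0].n_atoms
        for m in self.members:
            if m.n_atoms != n0:
                raise EnsembleIOError(
                    f"model {m.model_id} has {m.n_atoms} atoms, expected {n0}"
                )
        if self.weights is None:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.members),):
                raise EnsembleIOError("weights must align 1:1 with members")
            if np.any(self.weights < 0):
                raise EnsembleIOError("weights must be non-negative")
            total = self.weights.sum()
            if total <= 0:
                raise EnsembleIOError("weights must have positive total")
            if abs(total - 1.0) > _WEIGHT_TOL:
                self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_atoms(self) -> int:
        return self.members[0].n_atoms

    def coord_array(self) -> np.ndarray:
        """Stack member coordinates into an (N, n_atoms, 3) array."""
        return np.stack([m.coords for m in self.members])


def _structure_from_atoms(atoms: struc.AtomArray, model_id: int) -> Structure:
    return Structure(
        atom_names=list(atoms.atom_name),
        residue_ids=[int(r) for r in atoms.res_id],
        coords=np.asarray(atoms.coord, dtype=float),
        model_id=model_id,
    )


def _read_one_file(path: Path) -> list[Structure]:
    pdb_file = _pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise EnsembleIOError(f"{path}: no models found")
    out = []
    for i in range(1, n_models + 1):
        atoms = pdb_file.get_structure(model=i)
        out.append(_structure_from_atoms(atoms, model_id=i))
    return out


def read_ensemble(path_or_paths, label: str = "") -> StructureEnsemble:
    """Read a conformational ensemble from PDB input.

    Accepts a multi-model PDB file, a directory of single-model PDB files
    (read in sorted name order), or an explicit sequence of file paths.
    Members receive uniform weights 1/N.  A mixed atom count across models
    raises :class:`EnsembleIOError` naming the offending model.
    """
    if isinstance(path_or_paths, (str, os.PathLike)):
        p = Path(path_or_paths)
        if p.is_dir():
            paths = sorted(q for q in p.iterdir() if q.suffix.lower() == ".pdb")
            if not paths:
                raise EnsembleIOError(f"{p}: directory contains no .pdb files")
        else:
            if not p.exists():
                raise EnsembleIOError(f"{p}: no such file")
            paths = [p]
    else:
        paths = [Path(q) for q in path_or_paths]
        if not paths:
            raise EnsembleIOError("empty input path list")

    members: list[Structure] = []
    for q in paths:
        for s in _read_one_file(q):
            s.model_id = len(members) + 1
            members.append(s)
    return StructureEnsemble(members=members, source_label=label or str(paths[0]))


def extract_ca(ensemble: StructureEnsemble) -> StructureEnsemble:
    """Reduce every member to its Cα trace, preserving residue order and weights.

    Raises :class:`EnsembleIOError` naming the first residue lacking a CA atom.
    Idempotent on Cα-only input.
    """
    new_members = []
    for m in ensemble.members:
        names = np.asarray(m.atom_names)
        res = np.asarray(m.residue_ids)
        mask = names == "CA"
        seen = set(res[mask].tolist())
        for rid in res:
            if int(rid) not in seen:
                raise EnsembleIOError(
                    f"model {m.model_id}: residue {int(rid)} has no CA atom"
                )
        new_members.append(
            Structure(
                atom_names=["CA"] * int(mask.sum()),
                residue_ids=[int(r) for r in res[mask]],
                coords=m.coords[mask],
                model_id=m.model_id,
            )
        )
    return StructureEnsemble(
        members=new_members,
        weights=np.array(ensemble.weights, copy=True),
        source_label=ensemble.source_label,
    )


def _atom_array(member: Structure) -> struc.AtomArray:
    n = member.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(member.coords, dtype=np.float32)
    atoms.atom_name = np.asarray(member.atom_names)
    atoms.res_id = np.asarray(member.residue_ids, dtype=int)
    atoms.res_name = np.full(n, "ALA")
    atoms.chain_id = np.full(n, "A")
    atoms.hetero = np.zeros(n, dtype=bool)
    # Element from the atom name's leading letter (CA -> C for calpha traces).
    atoms.element = np.asarray([str(nm)[0] for nm in member.atom_names])
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    return atoms


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write the ensemble as a standard multi-model PDB (MODEL serials 1..N)."""
    stack = struc.stack([_atom_array(m) for m in ensemble.members])
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    if len(ensemble) == 1 and not any(
        ln.startswith("MODEL") for ln in pdb_file.lines
    ):
        # keep the MODEL/ENDMDL framing even for a single conformation
        pdb_file.lines = ["MODEL        1"] + pdb_file.lines + ["ENDMDL"]
    pdb_file.write(str(path))
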