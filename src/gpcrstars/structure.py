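"""Atomic-coordinate container and PDB I/O.

A :class:`Structure` keys residues by :class:`~gpcrstars.numbering.ResidueID`
and holds named atoms with Å coordinates — just enough topology for the
distance/angle metrics this package computes.  Reading and writing of the
fixed-column PDB format is delegated to biotite; multi-MODEL files map to a
list of structures sharing one topology (the portable stand-in for
trajectory frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .numbering import NumberingMap, ResidueID

__all__ = ["Atom", "Residue", "Structure", "PDBFormatError", "read_pdb", "write_pdb"]


class PDBFormatError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def add(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise ValueError(f"duplicate atom name {atom.name} in residue {self.res_name}")
        self.atoms[atom.name] = atom


class Structure:
    """Residue-keyed atomic model with an optional generic-numbering map."""

    def __init__(self, numbering: Optional[NumberingMap] = None) -> None:
        self.residues: dict[ResidueID, Residue] = {}
        self.numbering = numbering

    # -- construction -------------------------------------------------

    def add_atom(
        self,
        rid: ResidueID,
        res_name: str,
        name: str,
        coord: Iterable[float],
        element: str = "",
    ) -> None:
        res = self.residues.get(rid)
        if res is None:
            res = self.residues[rid] = Residue(res_name)
        elif res.res_name != res_name:
            raise ValueError(
                f"residue {rid} declared as both {res.res_name} and {res_name}"
            )
        if not element:
            element = name.lstrip("0123456789")[:1]
        res.add(Atom(name=name, element=element, coord=np.asarray(coord, dtype=float)))

    # -- access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, rid: ResidueID) -> bool:
        return rid in self.residues

    def residue(self, key: Union[ResidueID, str]) -> Residue:
        """Residue by ID or by generic-number string (needs a numbering map)."""
        rid = self._resolve(key)
        try:
            return self.residues[rid]
        except KeyError:
            raise KeyError(f"residue {rid} not present in structure") from None

    def _resolve(self, key: Union[ResidueID, str]) -> ResidueID:
        if isinstance(key, ResidueID):
            return key
        if self.numbering is None:
            raise ValueError("structure has no numbering map attached; address by ResidueID")
        return self.numbering.lookup(key)

    def atom(self, key: Union[ResidueID, str], atom_name: str) -> Atom:
        res = self.residue(key)
        try:
            return res.atoms[atom_name]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} missing from residue {self._resolve(key)} ({res.res_name})"
            ) from None

    def coord(self, key: Union[ResidueID, str], atom_name: str) -> np.ndarray:
        return self.atom(key, atom_name).coord

    def iter_atoms(self) -> Iterator[tuple[ResidueID, Residue, Atom]]:
        for rid, res in self.residues.items():
            for atom in res.atoms.values():
                yield rid, res, atom

    def ca_coords(self, rids: Optional[Iterable[ResidueID]] = None) -> np.ndarray:
        """Cα coordinate matrix over *rids* (default: every residue with a CA)."""
        if rids is None:
            coords = [r.atoms["CA"].coord for r in self.residues.values() if "CA" in r.atoms]
        else:
            coords = [self.coord(rid, "CA") for rid in rids]
        return np.array(coords, dtype=float)

    def same_topology(self, other: "Structure") -> bool:
        if self.residues.keys() != other.residues.keys():
            return False
        for rid, res in self.residues.items():
            o = other.residues[rid]
            if res.res_name != o.res_name or res.atoms.keys() != o.atoms.keys():
                return False
        return True

    # -- transforms ---------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with every coordinate mapped to ``R @ x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = Structure(numbering=self.numbering)
        for rid, res, atom in self.iter_atoms():
            out.add_atom(rid, res.res_name, atom.name, rotation @ atom.coord + translation, atom.element)
        return out


# -- PDB reading ------------------------------------------------------

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _prescan(path: Path) -> None:
    """Report malformed ATOM/HETATM records with their line number."""
    n_atoms = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n_atoms += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"{path}, line {lineno}: truncated ATOM record")
            for lo, hi in _COORD_SLICES:
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBFormatError(
                        f"{path}, line {lineno}: unparsable coordinate field {line[lo:hi]!r}"
                    ) from None
            try:
                int(line[22:26])
            except ValueError:
                raise PDBFormatError(
                    f"{path}, line {lineno}: unparsable residue number {line[22:26]!r}"
                ) from None
    if n_atoms == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")


def _from_atom_array(arr: bst.AtomArray, numbering: Optional[NumberingMap]) -> Structure:
    out = Structure(numbering=numbering)
    ins = arr.get_annotation("ins_code") if "ins_code" in arr.get_annotation_categories() else [""] * arr.array_length()
    for i in range(arr.array_length()):
        rid = ResidueID(str(arr.chain_id[i]) or "A", int(arr.res_id[i]), str(ins[i]).strip())
        out.add_atom(
            rid,
            str(arr.res_name[i]),
            str(arr.atom_name[i]),
            arr.coord[i],
            str(arr.element[i]),
        )
    return out


def read_pdb(
    path: Union[str, Path],
    numbering: Optional[NumberingMap] = None,
    model: Optional[int] = None,
) -> Union[Structure, list[Structure]]:
    """Read a PDB file.

    Returns a single :class:`Structure` for single-MODEL files (or when
    *model* selects one), otherwise a list of structures in MODEL order.
    Alternate locations resolve to the highest-occupancy conformer (ties
    keep the first, i.e. altloc ``A``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model is not None:
        arr = pdb.get_structure(model=model, altloc="occupancy")
        return _from_atom_array(arr, numbering)
    if n_models == 1:
        return _from_atom_array(pdb.get_structure(model=1, altloc="occupancy"), numbering)
    return [
        _from_atom_array(pdb.get_structure(model=m, altloc="occupancy"), numbering)
        for m in range(1, n_models + 1)
    ]


def write_pdb(path: Union[str, Path], structures: Union[Structure, list[Structure]]) -> None:
    """Write one structure (single MODEL) or several (multi-MODEL, one topology)."""
    if isinstance(structures, Structure):
        frames = [structures]
    else:
        frames = list(structures)
        first = frames[0]
        for f in frames[1:]:
            if not f.same_topology(first):
                raise ValueError("multi-MODEL output requires identical topology in all frames")
    template = frames[0]
    n = sum(len(res.atoms) for res in template.residues.values())
    arrays = []
    for frame in frames:
        arr = bst.AtomArray(n)
        i = 0
        for rid, res, atom in frame.iter_atoms():
            arr.chain_id[i] = rid.chain
            arr.res_id[i] = rid.seqnum
            arr.res_name[i] = res.res_name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element or atom.name[:1]
            arr.coord[i] = atom.coord
            arr.hetero[i] = False
            i += 1
        arrays.append(arr)
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))
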