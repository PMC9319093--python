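"""Per-frame analysis of ordered coordinate frames.

Frames are plain :class:`~gpcrstars.structure.Structure` objects sharing one
topology (ingested from multi-MODEL PDB files — the portable stand-in for MD
trajectories, sampled here at 100 ps/frame by convention).  The module
applies single-frame geometry metrics frame-by-frame, computes RMSD series
against frame 1 after Cα superposition, and derives simple geometric
protein–ligand interaction fingerprints with their cross-frame persistence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch
from .numbering import ResidueID
from .structure import Structure

__all__ = [
    "Trajectory",
    "MetricSeries",
    "metric_series",
    "rmsd_series",
    "interaction_fingerprint",
    "persistence",
]

#: Default sampling interval: one stored frame per 100 ps of simulated time.
DEFAULT_FRAME_INTERVAL_PS = 100.0


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology."""

    frames: list[Structure]
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        first = self.frames[0]
        for i, frame in enumerate(self.frames[1:], start=2):
            if not frame.same_topology(first):
                raise ValueError(f"frame {i} does not share the topology of frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.frames), dtype=float) * self.frame_interval_ps


@dataclass
class MetricSeries:
    """A named per-frame scalar series; failed frames are NaN gaps."""

    name: str
    times_ps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ps.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def min(self) -> float:
        return float(np.nanmin(self.values))

    @property
    def max(self) -> float:
        return float(np.nanmax(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times_ps, self.name: self.values})


def metric_series(
    traj: Trajectory,
    metric: Callable[[Structure], float],
    name: str = "metric",
) -> MetricSeries:
    """Evaluate a single-frame metric independently on every frame.

    A failure on frame 1 is an error (the metric is not computable on this
    topology); failures on later frames become NaN gaps, never interpolated.
    """
    values = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        try:
            values[i] = float(metric(frame))
        except Exception:
            if i == 0:
                raise
            values[i] = math.nan
    return MetricSeries(name=name, times_ps=traj.times_ps, values=values)


def rmsd_series(
    traj: Trajectory,
    selection: Optional[Sequence[tuple[ResidueID, str]]] = None,
    name: str = "rmsd",
) -> MetricSeries:
    """Cα (or custom-selection) RMSD of each frame versus frame 1.

    Each frame is rigidly superposed onto frame 1 over the selection before
    the RMSD is taken over the same selection; frame 1 scores exactly 0.
    """
    if len(traj) < 2:
        raise ValueError("an RMSD series needs at least 2 frames")

    def coords(frame: Structure) -> np.ndarray:
        if selection is None:
            return frame.ca_coords()
        return np.array([frame.coord(rid, nm) for rid, nm in selection])

    ref = coords(traj.frames[0])
    values = [0.0]
    for frame in traj.frames[1:]:
        _, _, value = kabsch(coords(frame), ref)
        values.append(value)
    return MetricSeries(name=name, times_ps=traj.times_ps, values=np.array(values))


# -- interaction fingerprints -----------------------------------------

#: Geometric contact criteria (defaults; override per call).
HBOND_HEAVY_CUTOFF = 3.5   # Å, donor–acceptor heavy atoms
HBOND_ANGLE_MIN = 120.0    # degrees, D–H···A when an H is present
HYDROPHOBIC_CUTOFF = 4.0   # Å, any C–C pair
AROMATIC_CUTOFF = 5.5      # Å, ring centroid to ring centroid
_H_BOND_LENGTH = 1.3       # Å, H considered bonded to its heavy atom

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

Contact = tuple[ResidueID, str]  # (protein residue, interaction class)


def _polar(atoms) -> list[np.ndarray]:
    return [a.coord for a in atoms if a.element in ("N", "O")]


def _ring_centroid(res) -> Optional[np.ndarray]:
    names = RING_ATOMS.get(res.res_name)
    if names is None:
        return None
    coords = [res.atoms[n].coord for n in names if n in res.atoms]
    if len(coords) < 3:
        return None
    return np.mean(coords, axis=0)


def _hbond_between(res_a, res_b, cutoff: float, angle_min: float) -> bool:
    """Polar-heavy-atom contact, angle-gated when hydrogens exist."""
    for a in res_a.atoms.values():
        if a.element not in ("N", "O"):
            continue
        for b in res_b.atoms.values():
            if b.element not in ("N", "O"):
                continue
            if np.linalg.norm(a.coord - b.coord) > cutoff:
                continue
            hydrogens = []
            for res, heavy, other in ((res_a, a, b), (res_b, b, a)):
                for h in res.atoms.values():
                    if h.element == "H" and np.linalg.norm(h.coord - heavy.coord) <= _H_BOND_LENGTH:
                        hydrogens.append((heavy, h, other))
            if not hydrogens:
                return True
            for heavy, h, other in hydrogens:
                v1 = heavy.coord - h.coord
                v2 = other.coord - h.coord
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= angle_min:
                    return True
    return False


def interaction_fingerprint(
    frame: Structure,
    ligand: Iterable[ResidueID],
    hbond_cutoff: float = HBOND_HEAVY_CUTOFF,
    hbond_angle_min: float = HBOND_ANGLE_MIN,
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
    aromatic_cutoff: float = AROMATIC_CUTOFF,
) -> set[Contact]:
    """Protein residues contacting the ligand group, by interaction class.

    Classes: ``hbond`` (polar heavy atoms within 3.5 Å, D–H···A ≥ 120° when
    hydrogens are present), ``hydrophobic-contact`` (any C–C pair ≤ 4.0 Å),
    ``aromatic-proximal`` (ring centroids ≤ 5.5 Å; Phe/Tyr/Trp/His ring
    templates).  Residues whose ring template is unknown are skipped for the
    aromatic class with a warning.
    """
    ligand_ids = set(ligand)
    if not ligand_ids:
        raise ValueError("ligand selection is empty")
    missing = [rid for rid in ligand_ids if rid not in frame]
    if missing:
        raise KeyError(f"ligand residues not in topology: {missing}")

    lig_res = [frame.residues[rid] for rid in sorted(ligand_ids)]
    lig_carbons = [a.coord for r in lig_res for a in r.atoms.values() if a.element == "C"]
    lig_rings = []
    for rid, res in zip(sorted(ligand_ids), lig_res):
        c = _ring_centroid(res)
        if c is not None:
            lig_rings.append(c)
        elif res.res_name in RING_ATOMS:
            warnings.warn(f"incomplete ring for ligand residue {rid}; skipped")

    contacts: set[Contact] = set()
    for rid, res in frame.residues.items():
        if rid in ligand_ids:
            continue
        for lr in lig_res:
            if _hbond_between(lr, res, hbond_cutoff, hbond_angle_min):
                contacts.add((rid, "hbond"))
                break
        res_carbons = [a.coord for a in res.atoms.values() if a.element == "C"]
        if lig_carbons and res_carbons:
            pc = np.asarray(res_carbons)
            lc = np.asarray(lig_carbons)
            if np.min(np.linalg.norm(pc[:, None, :] - lc[None, :, :], axis=-1)) <= hydrophobic_cutoff:
                contacts.add((rid, "hydrophobic-contact"))
        if lig_rings:
            centroid = _ring_centroid(res)
            if centroid is not None and any(
                np.linalg.norm(centroid - c) <= aromatic_cutoff for c in lig_rings
            ):
                contacts.add((rid, "aromatic-proximal"))
    return contacts


def persistence(fingerprints: Sequence[set[Contact]]) -> pd.DataFrame:
    """Fraction of frames each (residue, class) contact is present in.

    Returns a frame sorted by fraction descending, then residue order;
    invariant to frame reordering.
    """
    if not fingerprints:
        raise ValueError("need at least one frame of fingerprints")
    n = len(fingerprints)
    counts: dict[Contact, int] = {}
    for fp in fingerprints:
        for contact in fp:
            counts[contact] = counts.get(contact, 0) + 1
    rows = [
        {
            "residue": str(rid),
            "interaction": cls,
            "fraction": counts[(rid, cls)] / n,
        }
        for rid, cls in sorted(counts, key=lambda c: (-counts[c], c[0], c[1]))
    ]
    return pd.DataFrame(rows, columns=["residue", "interaction", "fraction"])
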