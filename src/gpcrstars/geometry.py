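"""Activation-state geometry metrics for class A GPCR models.

Implements the structural readouts used to judge whether a 7-TM model sits
in an inactive conformation:

* **ionic lock** — the R3.50 ↔ S6.33 hydrogen bond at the cytoplasmic ends
  of TM3/TM6; measured as the serine OG to nearest arginine side-chain
  hydrogen distance (plus the heavy-atom N–O distance and the N–H···O
  angle).
* **aspartate cage** — the intra-helical R3.50 ↔ D3.49 salt bridge of the
  DRY motif; minimum side-chain heteroatom–heteroatom distance.
* **TM3–TM6 cytoplasmic distance** — mean Cα separation of the last five
  cytoplasmic residues of TM3 (3.51–3.55) and TM6 (6.30–6.34); ~10–12 Å in
  inactive and ~15–16 Å in active class A structures.

plus rigid Kabsch superposition / RMSD used by the trajectory series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .numbering import NumberingMap, ResidueID
from .structure import Structure

__all__ = [
    "LockGeometry",
    "ionic_lock",
    "aspartate_cage",
    "tm3_tm6_distance",
    "classify_state",
    "kabsch",
    "superpose",
    "rmsd",
]

#: Arginine side-chain hydrogens and the nitrogen each is bonded to.
ARG_H_PARENT = {
    "HE": "NE",
    "HH11": "NH1",
    "HH12": "NH1",
    "HH21": "NH2",
    "HH22": "NH2",
}
ARG_N_DONORS = ("NE", "NH1", "NH2")
ASP_O_ACCEPTORS = ("OD1", "OD2")

#: Salt-bridge call threshold (heteroatom–heteroatom, Å); companion output
#: only — raw distances are always reported.
SALT_BRIDGE_CUTOFF = 4.0


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex *b* in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


@dataclass(frozen=True)
class LockGeometry:
    """Ionic-lock measurement.

    ``h_distance`` is None when the model carries no arginine side-chain
    hydrogens (many generators emit heavy atoms only); ``no_distance`` is
    then the reported value and ``has_hydrogens`` flags the degradation.
    """

    no_distance: float
    h_distance: Optional[float] = None
    nho_angle: Optional[float] = None
    has_hydrogens: bool = True

    @property
    def distance(self) -> float:
        """The ranking distance: H···O when available, else N–O."""
        return self.h_distance if self.h_distance is not None else self.no_distance


def ionic_lock(
    structure: Structure,
    numbering: Optional[NumberingMap] = None,
    arg: Union[str, ResidueID] = "3.50",
    ser: Union[str, ResidueID] = "6.33",
) -> LockGeometry:
    """Measure the R3.50 ↔ S6.33 ionic lock.

    ``h_distance`` is the minimum over arginine side-chain hydrogens of the
    distance to the serine OG; ``no_distance`` the minimum over the three
    side-chain nitrogens; ``nho_angle`` the N–H···O angle at the hydrogen
    realising the minimum.
    """
    nmap = numbering or structure.numbering
    if (isinstance(arg, str) or isinstance(ser, str)) and nmap is None:
        raise ValueError("generic-number selections require a numbering map")
    resolve = lambda k: structure.residue(nmap.lookup(k) if isinstance(k, str) else k)  # noqa: E731
    arg_res, ser_res = resolve(arg), resolve(ser)
    if "OG" not in ser_res.atoms:
        raise KeyError("serine 6.33 has no OG atom; cannot measure the ionic lock")
    og = ser_res.atoms["OG"].coord

    n_atoms = {n: arg_res.atoms[n].coord for n in ARG_N_DONORS if n in arg_res.atoms}
    if not n_atoms:
        raise KeyError("arginine 3.50 has no side-chain nitrogens (NE/NH1/NH2)")
    no_distance = min(float(np.linalg.norm(c - og)) for c in n_atoms.values())

    h_atoms = {h: arg_res.atoms[h].coord for h in ARG_H_PARENT if h in arg_res.atoms}
    if not h_atoms:
        return LockGeometry(no_distance=no_distance, has_hydrogens=False)
    best_name, best_coord = min(
        h_atoms.items(), key=lambda kv: np.linalg.norm(kv[1] - og)
    )
    h_distance = float(np.linalg.norm(best_coord - og))
    parent = ARG_H_PARENT[best_name]
    angle = None
    if parent in arg_res.atoms:
        angle = _angle(arg_res.atoms[parent].coord, best_coord, og)
    return LockGeometry(
        no_distance=no_distance, h_distance=h_distance, nho_angle=angle, has_hydrogens=True
    )


def aspartate_cage(
    structure: Structure,
    numbering: Optional[NumberingMap] = None,
    arg: Union[str, ResidueID] = "3.50",
    asp: Union[str, ResidueID] = "3.49",
) -> tuple[float, bool]:
    """Minimum R3.50 {NE,NH1,NH2} × D3.49 {OD1,OD2} distance (Å).

    Returns ``(distance, is_salt_bridge)`` where the boolean applies the
    4.0 Å convention; the raw distance is the primary result.
    """
    nmap = numbering or structure.numbering
    resolve = lambda k: structure.residue(nmap.lookup(k) if isinstance(k, str) else k)  # noqa: E731
    arg_res, asp_res = resolve(arg), resolve(asp)
    ns = [arg_res.atoms[n].coord for n in ARG_N_DONORS if n in arg_res.atoms]
    os_ = [asp_res.atoms[o].coord for o in ASP_O_ACCEPTORS if o in asp_res.atoms]
    if not ns:
        raise KeyError("arginine 3.50 has no side-chain nitrogens")
    if not os_:
        raise KeyError("aspartate 3.49 has no carboxylate oxygens")
    d = min(float(np.linalg.norm(n - o)) for n in ns for o in os_)
    return d, d <= SALT_BRIDGE_CUTOFF


TM3_CYTO = ("3.51", "3.52", "3.53", "3.54", "3.55")
TM6_CYTO = ("6.30", "6.31", "6.32", "6.33", "6.34")

PairingMode = Literal["paired", "index", "all-pairs"]


def tm3_tm6_distance(
    structure: Structure,
    numbering: Optional[NumberingMap] = None,
    mode: PairingMode = "paired",
) -> float:
    """Mean cytoplasmic Cα distance between TM3 (3.51–3.55) and TM6 (6.30–6.34).

    ``paired`` (default) aligns the cytoplasmic ends — TM3 runs down while
    TM6 runs up, so 3.51 pairs with 6.34, 3.52 with 6.33, … ; ``index``
    pairs 3.51 with 6.30 onward; ``all-pairs`` averages the full 5×5 matrix.
    """
    nmap = numbering or structure.numbering
    if nmap is None:
        raise ValueError("tm3_tm6_distance requires a numbering map")

    def ca(gn: str) -> np.ndarray:
        rid = nmap.lookup(gn)
        res = structure.residue(rid)
        if "CA" not in res.atoms:
            raise KeyError(f"missing Cα for generic number {gn} (residue {rid})")
        return res.atoms["CA"].coord

    p3 = np.array([ca(g) for g in TM3_CYTO])
    p6 = np.array([ca(g) for g in TM6_CYTO])
    if mode == "paired":
        d = np.linalg.norm(p3 - p6[::-1], axis=1)
    elif mode == "index":
        d = np.linalg.norm(p3 - p6, axis=1)
    elif mode == "all-pairs":
        d = np.linalg.norm(p3[:, None, :] - p6[None, :, :], axis=-1).ravel()
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    return float(d.mean())


def classify_state(
    distance: float,
    inactive_max: float = 12.0,
    active_min: float = 14.0,
) -> str:
    """Label a TM3–TM6 distance: ≤12 Å inactive, ≥14 Å active, else ambiguous."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if inactive_max >= active_min:
        raise ValueError("inactive_max must be below active_min")
    if distance <= inactive_max:
        return "inactive"
    if distance >= active_min:
        return "active"
    return "intermediate-ambiguous"


# -- superposition ----------------------------------------------------


def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) mapping ``mobile`` onto ``reference`` as ``R @ x + t``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection; rotation is ill-determined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, value


def _selection_coords(
    structure: Structure, selection: Optional[Sequence[tuple[ResidueID, str]]]
) -> np.ndarray:
    if selection is None:
        return structure.ca_coords()
    return np.array([structure.coord(rid, name) for rid, name in selection])


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: Optional[Sequence[tuple[ResidueID, str]]] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose *mobile* onto *reference* over *selection* (default: all Cα)."""
    P = _selection_coords(mobile, selection)
    Q = _selection_coords(reference, selection)
    return kabsch(P, Q)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD of two matched (n, 3) arrays, no fitting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
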