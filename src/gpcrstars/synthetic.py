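"""Synthetic inputs with known ground truth for every analysis stage.

Everything the pipeline consumes can be generated here, seeded and
reproducible: quality-score tables whose star totals are known by
construction, idealized 7-TM Cα bundles whose ionic-lock / aspartate-cage /
TM3–TM6 metrics hit requested targets, noisy multi-frame trajectories with
controlled metric drift, and two-class docking-score tables whose
population AUC has the closed form Φ(|Δμ| / (σ√2)).

The generators dial the *inputs* a structural-biology workflow would see;
they make no attempt at physically realistic side-chain packing — pseudo
side-chain atoms are placed by constrained geometry, which is exactly
enough for distance metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import geometry
from .numbering import AnchorSet, NumberingMap, ResidueID, build_numbering, gpr18_anchors
from .stars import MetricSpec, assign_stars, bin_interval, default_specs
from .structure import Structure
from .trajectory import Trajectory

__all__ = [
    "BundleSpec",
    "ScoreSimSpec",
    "gen_quality_table",
    "build_bundle",
    "gen_trajectory",
    "gen_docking_scores",
]

# Ideal alpha-helix geometry.
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å, Cα distance from the axis
N_H_BOND = 1.01        # Å, N–H bond length used for pseudo-hydrogens


# --------------------------------------------------------------------
# Quality-score tables
# --------------------------------------------------------------------


def gen_quality_table(
    n_models: int,
    seed: int,
    profile: Optional[dict[str, Optional[int]]] = None,
    specs: Optional[Sequence[MetricSpec]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample quality records with star counts known by construction.

    *profile* maps metric name → target stars (0–3) or ``None`` for a
    missing value; metrics not mentioned get a random star count per model.
    Returns ``(records, expected_star_table)`` where the expectation comes
    from the construction, not from re-binning.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    specs = list(specs) if specs is not None else default_specs()
    profile = profile or {}
    rng = np.random.default_rng(seed)
    records = []
    expected_rows = {}
    for m in range(n_models):
        model_id = f"SYN_{m + 1}"
        rec: dict[str, object] = {"model_id": model_id}
        exp: dict[str, float] = {}
        for spec in specs:
            target = profile.get(spec.name, int(rng.integers(0, 4)))
            if target is None:
                rec[spec.name] = math.nan
                exp[spec.name] = 0.0
                continue
            rec[spec.name] = _sample_in_bin(spec, int(target), rng)
            exp[spec.name] = spec.weight * target
        exp["total"] = sum(exp.values())
        expected_rows[model_id] = exp
        records.append(rec)
    records_df = pd.DataFrame(records)
    expected = pd.DataFrame.from_dict(expected_rows, orient="index")
    expected.index.name = "model_id"
    return records_df, expected


_PERCENT_METRICS = {"errat", "verify3d", "rama_core", "rama_disallowed"}


def _sample_in_bin(spec: MetricSpec, stars: int, rng: np.random.Generator) -> float:
    margin = max(abs(spec.thresholds[0] - spec.thresholds[2]), 1e-2)
    lo, hi = bin_interval(spec, stars, margin=margin)
    if spec.name == "labelled_residues":
        lo_i, hi_i = max(0, math.ceil(lo)), math.floor(hi)
        value = float(rng.integers(lo_i, hi_i + 1))
    else:
        value = float(rng.uniform(lo, hi))
        if spec.name in _PERCENT_METRICS:
            value = min(max(value, 0.0), 100.0)
    assert assign_stars(value, spec) == stars, (spec.name, stars, value)
    return value


# --------------------------------------------------------------------
# Idealized 7-TM bundles
# --------------------------------------------------------------------


@dataclass(frozen=True)
class BundleSpec:
    """Geometry targets for an idealized 7-TM Cα bundle.

    The seven helix axes sit on a circle; odd helices run toward the
    cytoplasm, even ones back up, so the cytoplasmic ends of TM3 and TM6
    face each other as in a real receptor.  ``target_*`` values are the
    distances the geometry module should measure on the built structure.
    """

    circle_radius: float = 10.0
    target_tm3_tm6: float = 11.0      # Å, mean cytoplasmic Cα distance
    target_lock: float = 2.8          # Å, S6.33 OG to nearest R3.50 H
    target_cage: float = 2.8          # Å, R3.50 N to D3.49 O minimum
    include_hydrogens: bool = True
    chain: str = "A"

    def __post_init__(self) -> None:
        for name in ("circle_radius", "target_tm3_tm6", "target_lock", "target_cage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _helix_ca(
    axis_xy: np.ndarray, n_res: int, downward: bool, phase: float
) -> np.ndarray:
    """Cα trace of one ideal helix centred at z = 0."""
    idx = np.arange(n_res, dtype=float)
    theta = np.radians(phase + HELIX_TWIST * idx)
    x = axis_xy[0] + HELIX_RADIUS * np.cos(theta)
    y = axis_xy[1] + HELIX_RADIUS * np.sin(theta)
    z = (n_res / 2.0 - idx) * HELIX_RISE if downward else (idx - n_res / 2.0) * HELIX_RISE
    return np.column_stack([x, y, z])


def _build_backbone(
    spec: BundleSpec, anchors: AnchorSet, tm6_shift: float
) -> tuple[Structure, NumberingMap]:
    nmap = build_numbering(anchors, chain=spec.chain)
    tm_spans = {s.segment: s for s in anchors.spans if s.segment <= 7}
    structure = Structure(numbering=nmap)
    angles = {seg: 2 * math.pi * (i / 7.0) for i, seg in enumerate(sorted(tm_spans))}
    # TM6's axis slides along the TM3→TM6 line to calibrate the cytoplasmic
    # distance; tm6_shift > 0 moves it toward TM3.
    ax3 = spec.circle_radius * np.array([math.cos(angles[3]), math.sin(angles[3])])
    ax6 = spec.circle_radius * np.array([math.cos(angles[6]), math.sin(angles[6])])
    u36 = (ax3 - ax6) / np.linalg.norm(ax3 - ax6)
    for seg, span in sorted(tm_spans.items()):
        axis = spec.circle_radius * np.array([math.cos(angles[seg]), math.sin(angles[seg])])
        if seg == 6:
            axis = axis + tm6_shift * u36
        n_res = span.end - span.start + 1
        downward = seg % 2 == 1
        coords = _helix_ca(axis, n_res, downward=downward, phase=math.degrees(angles[seg]) + 180.0)
        for i, seq in enumerate(range(span.start, span.end + 1)):
            rid = ResidueID(spec.chain, seq)
            gn = nmap.generic_number(rid)
            res_name = {"3.49": "ASP", "3.50": "ARG", "6.33": "SER"}.get(str(gn), "ALA")
            structure.add_atom(rid, res_name, "CA", coords[i], element="C")
    return structure, nmap


def _place_side_chains(structure: Structure, nmap: NumberingMap, spec: BundleSpec) -> None:
    ca350 = structure.coord(nmap.lookup("3.50"), "CA")
    ca633 = structure.coord(nmap.lookup("6.33"), "CA")
    gap = float(np.linalg.norm(ca350 - ca633))
    if spec.target_lock + N_H_BOND + 2.4 > gap:
        raise ValueError(
            f"infeasible target_lock {spec.target_lock:.2f} Å: exceeds the "
            f"TM3–TM6 side-chain gap ({gap:.2f} Å between Cα atoms)"
        )
    u = (ca350 - ca633) / gap
    og = ca633 + 2.4 * u
    arg_rid = nmap.lookup("3.50")
    asp_rid = nmap.lookup("3.49")
    ser_rid = nmap.lookup("6.33")
    structure.add_atom(ser_rid, "SER", "OG", og, element="O")

    v = (ca350 - og) / np.linalg.norm(ca350 - og)
    w = np.cross(v, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(v, np.array([1.0, 0.0, 0.0]))
    w /= np.linalg.norm(w)

    ne = og + (spec.target_lock + N_H_BOND) * v
    nh1 = ne + 1.3 * w
    nh2 = ne - 1.3 * w
    structure.add_atom(arg_rid, "ARG", "NE", ne, element="N")
    structure.add_atom(arg_rid, "ARG", "NH1", nh1, element="N")
    structure.add_atom(arg_rid, "ARG", "NH2", nh2, element="N")
    if spec.include_hydrogens:
        # HE sits on the NE→OG segment: N–H···O is collinear and HE is the
        # nearest hydrogen to OG by construction.
        structure.add_atom(arg_rid, "ARG", "HE", og + spec.target_lock * v, element="H")
        structure.add_atom(arg_rid, "ARG", "HH11", nh1 + N_H_BOND * v, element="H")
        structure.add_atom(arg_rid, "ARG", "HH12", nh1 + N_H_BOND * w, element="H")
        structure.add_atom(arg_rid, "ARG", "HH21", nh2 + N_H_BOND * v, element="H")
        structure.add_atom(arg_rid, "ARG", "HH22", nh2 - N_H_BOND * w, element="H")
    # Carboxylate pseudo-oxygens: OD1 exactly target_cage from NH1 along w,
    # every other N×O pair strictly farther.
    od1 = nh1 + spec.target_cage * w
    od2 = od1 + 1.2 * w
    structure.add_atom(asp_rid, "ASP", "OD1", od1, element="O")
    structure.add_atom(asp_rid, "ASP", "OD2", od2, element="O")


def build_bundle(
    spec: BundleSpec,
    anchors: Optional[AnchorSet] = None,
    tol: float = 0.01,
    max_iter: int = 30,
) -> tuple[Structure, NumberingMap]:
    """Build a 7-TM bundle whose measured metrics match the spec targets.

    The TM6 axis position is calibrated by fixed-point iteration until the
    measured (paired-mode) TM3–TM6 cytoplasmic distance is within *tol* of
    the target; lock and cage side-chain pseudo-atoms are then placed by
    exact construction.
    """
    anchors = anchors or gpr18_anchors()
    shift = 0.0
    structure = nmap = None
    for _ in range(max_iter):
        structure, nmap = _build_backbone(spec, anchors, tm6_shift=shift)
        measured = geometry.tm3_tm6_distance(structure, nmap, mode="paired")
        err = measured - spec.target_tm3_tm6
        if abs(err) <= tol:
            break
        shift += err
    else:
        raise ValueError(
            f"could not calibrate TM3–TM6 distance to {spec.target_tm3_tm6} Å "
            f"(last error {err:.3f} Å); target may be infeasible for this bundle"
        )
    _place_side_chains(structure, nmap, spec)
    return structure, nmap


# --------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------


def gen_trajectory(
    spec: BundleSpec,
    n_frames: int,
    noise_sd: float = 0.0,
    drift: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    anchors: Optional[AnchorSet] = None,
) -> tuple[Trajectory, NumberingMap]:
    """Noisy multi-frame trajectory of a bundle with optional metric drift.

    *drift* maps target names (``tm3_tm6``, ``lock``, ``cage``) to
    (start, end) values interpolated linearly across frames; each frame is
    rebuilt to its interpolated targets, then per-atom Gaussian noise of
    *noise_sd* Å is added.  Deterministic for a given seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    drift = drift or {}
    valid = {"tm3_tm6", "lock", "cage"}
    unknown = set(drift) - valid
    if unknown:
        raise ValueError(f"unknown drift targets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    anchors = anchors or gpr18_anchors()

    frames: list[Structure] = []
    nmap = None
    for f in range(n_frames):
        t = f / (n_frames - 1) if n_frames > 1 else 0.0
        frame_spec = spec
        updates = {}
        for key, attr in (("tm3_tm6", "target_tm3_tm6"), ("lock", "target_lock"), ("cage", "target_cage")):
            if key in drift:
                a, b = drift[key]
                updates[attr] = a + t * (b - a)
        if updates:
            frame_spec = replace(spec, **updates)
        structure, nmap = build_bundle(frame_spec, anchors=anchors)
        if noise_sd > 0:
            noisy = Structure(numbering=structure.numbering)
            for rid, res, atom in structure.iter_atoms():
                noisy.add_atom(
                    rid, res.res_name, atom.name,
                    atom.coord + rng.normal(0.0, noise_sd, size=3), atom.element,
                )
            structure = noisy
        frames.append(structure)
    return Trajectory(frames=frames), nmap


# --------------------------------------------------------------------
# Docking scores
# --------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreSimSpec:
    """Two-class Gaussian docking-score simulation.

    Defaults mirror a typical screening library composition of 26 actives
    against 98 inactives.  With shared sd, the population AUC is
    Φ(|mean_active − mean_inactive| / (sd·√2)).
    """

    n_active: int = 26
    n_inactive: int = 98
    mean_active: float = -9.0
    mean_inactive: float = -7.5
    sd: float = 1.0
    seed: int = 0
    direction: str = "lower-better"

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes need at least one ligand")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.direction not in ("lower-better", "higher-better"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def analytic_auc(self) -> float:
        return float(norm.cdf(abs(self.mean_active - self.mean_inactive) / (self.sd * math.sqrt(2.0))))


def gen_docking_scores(spec: ScoreSimSpec) -> tuple[pd.DataFrame, float]:
    """Simulated ligand score table and the analytic population AUC.

    For ``lower-better`` direction the active class should have the lower
    (better) mean for the empirical AUC to approach the analytic value.
    """
    rng = np.random.default_rng(spec.seed)
    active = rng.normal(spec.mean_active, spec.sd, size=spec.n_active)
    inactive = rng.normal(spec.mean_inactive, spec.sd, size=spec.n_inactive)
    df = pd.DataFrame(
        {
            "ligand_id": [f"ACT_{i+1}" for i in range(spec.n_active)]
            + [f"INA_{i+1}" for i in range(spec.n_inactive)],
            "label": [True] * spec.n_active + [False] * spec.n_inactive,
            "score": np.concatenate([active, inactive]),
        }
    )
    return df, spec.analytic_auc
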