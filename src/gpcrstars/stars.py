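"""Quartile-binned "Stars" aggregation of protein model quality metrics.

Each of twelve global quality functions (ERRAT, Verify3D, PROVE, the
Ramachandran core/disallowed percentages, labelled-residue count, RWplus,
MolProbity, Rosetta energy, DFIRE, GOAP, OPUS-PSP, predicted global quality)
is binned into 0–3 stars by three ordered boundary values; the two
Ramachandran percentages carry weight 0.5 each, so their contribution is a
half-star-granular composite in [0, 3].  The weighted star sum over all
metrics (maximum 36 under the default twelve-metric scheme) is the model's
preliminary rank score.

Boundaries can either be the published reference ranges (packaged as
:func:`default_specs`) or derived from a model population's quartiles
(:func:`derive_thresholds`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MetricSpec",
    "assign_stars",
    "bin_interval",
    "derive_thresholds",
    "ramachandran_substar",
    "total_stars",
    "star_table",
    "default_specs",
    "load_specs",
    "save_specs",
    "load_quality_table",
]

Direction = Literal["higher-better", "lower-better"]

#: Canonical metric column names, in report order.
METRICS = (
    "errat",
    "verify3d",
    "prove",
    "rama_core",
    "rama_disallowed",
    "labelled_residues",
    "rwplus",
    "molprobity",
    "rosetta",
    "dfire",
    "goap",
    "opus_psp",
    "predicted_global_quality",
)

#: Header synonyms accepted by :func:`load_quality_table` (lower-cased, stripped).
_HEADER_SYNONYMS = {
    "model": "model_id",
    "model_id": "model_id",
    "errat": "errat",
    "errat [%]": "errat",
    "verify3d": "verify3d",
    "verify 3d": "verify3d",
    "verify 3d [%]": "verify3d",
    "prove": "prove",
    "prove [%]": "prove",
    "rama_core": "rama_core",
    "core": "rama_core",
    "core [%]": "rama_core",
    "rama_disallowed": "rama_disallowed",
    "disall": "rama_disallowed",
    "disall [%]": "rama_disallowed",
    "labelled_residues": "labelled_residues",
    "labelled residues": "labelled_residues",
    "labell. residues": "labelled_residues",
    "rwplus": "rwplus",
    "rw+": "rwplus",
    "rw+ [kcal/mol]": "rwplus",
    "molprobity": "molprobity",
    "molprob": "molprobity",
    "rosetta": "rosetta",
    "rosetta energy scores": "rosetta",
    "dfire": "dfire",
    "dfire scores": "dfire",
    "goap": "goap",
    "goap scores": "goap",
    "opus_psp": "opus_psp",
    "opus-psp": "opus_psp",
    "opus-psp scores": "opus_psp",
    "opus-pspscores": "opus_psp",
    "predicted_global_quality": "predicted_global_quality",
    "pred.globalquality": "predicted_global_quality",
    "predicted global quality": "predicted_global_quality",
    "rama_labelled": "rama_labelled",
    "chi_labelled": "chi_labelled",
}


@dataclass(frozen=True)
class MetricSpec:
    """Star-binning rule for one metric.

    ``thresholds`` are the 3-, 2- and 1-star boundaries, ordered from best
    to worst quality; a value on the favourable side of a boundary
    (inclusive) earns at least that many stars.  A metric where the 1-star
    and 0-star printed bounds coincide is expressed by simply repeating the
    rule structure: value meeting the 1-star bound earns 1 star, anything
    else 0.
    """

    name: str
    direction: Direction
    thresholds: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("higher-better", "lower-better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        t3, t2, t1 = self.thresholds
        ordered = t3 >= t2 >= t1 if self.direction == "higher-better" else t3 <= t2 <= t1
        if not ordered:
            raise ValueError(
                f"{self.name}: thresholds {self.thresholds} are not ordered "
                f"from best to worst for direction {self.direction}"
            )


def assign_stars(value: Union[float, None], spec: MetricSpec) -> int:
    """Bin one metric value into 0–3 (unweighted) stars.

    Missing values (``None`` or NaN) earn 0 stars.  Boundaries are
    inclusive: a value exactly at the 1-star floor earns 1 star.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return 0
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{spec.name}: non-finite value {value}")
    t3, t2, t1 = spec.thresholds
    if spec.direction == "higher-better":
        meets = lambda v, t: v >= t  # noqa: E731
    else:
        meets = lambda v, t: v <= t  # noqa: E731
    if meets(value, t3):
        return 3
    if meets(value, t2):
        return 2
    if meets(value, t1):
        return 1
    return 0


def bin_interval(spec: MetricSpec, stars: int, margin: float = 1.0) -> tuple[float, float]:
    """Closed interval of values earning exactly *stars* under *spec*.

    Open-ended bins (3 stars on the favourable side, 0 stars on the
    unfavourable side) are capped *margin* beyond the nearest boundary so the
    result is always finite — used by the synthetic generator to sample
    values with a known star count.
    """
    if stars not in (0, 1, 2, 3):
        raise ValueError("stars must be in {0,1,2,3}")
    t3, t2, t1 = spec.thresholds
    eps = 1e-9
    if spec.direction == "higher-better":
        edges = {3: (t3, t3 + margin), 2: (t2, t3 - eps), 1: (t1, t2 - eps), 0: (t1 - margin, t1 - eps)}
    else:
        edges = {3: (t3 - margin, t3), 2: (t3 + eps, t2), 1: (t2 + eps, t1), 0: (t1 + eps, t1 + margin)}
    lo, hi = edges[stars]
    if lo > hi:
        raise ValueError(f"{spec.name}: empty {stars}-star bin (coincident boundaries)")
    return lo, hi


def derive_thresholds(
    values: Sequence[float],
    direction: Direction,
    name: str = "derived",
    weight: float = 1.0,
) -> MetricSpec:
    """Derive star boundaries from a population's quartiles.

    The three boundaries sit at Q3/Q2/Q1 (for higher-better; mirrored for
    lower-better), partitioning the population into four roughly equal bins.
    """
    arr = np.asarray([v for v in values if v is not None and math.isfinite(v)], dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 finite values to derive quartile thresholds")
    if np.ptp(arr) == 0:
        raise ValueError("degenerate population: all values identical")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    if direction == "higher-better":
        thresholds = (float(q3), float(q2), float(q1))
    else:
        thresholds = (float(q1), float(q2), float(q3))
    return MetricSpec(name=name, direction=direction, thresholds=thresholds, weight=weight)


def ramachandran_substar(
    core: Union[float, None],
    disallowed: Union[float, None],
    core_spec: MetricSpec,
    disallowed_spec: MetricSpec,
) -> float:
    """Composite Ramachandran contribution: 0.5·stars(core) + 0.5·stars(disallowed).

    Half-star values are legitimate; a missing component contributes 0.
    """
    return core_spec.weight * assign_stars(core, core_spec) + disallowed_spec.weight * assign_stars(
        disallowed, disallowed_spec
    )


def total_stars(record: Mapping[str, float], specs: Iterable[MetricSpec]) -> float:
    """Weighted star total of one quality record over *specs*.

    *record* maps metric names to values; absent or NaN entries contribute
    zero stars.
    """
    total = 0.0
    for spec in specs:
        total += spec.weight * assign_stars(record.get(spec.name), spec)
    return total


def star_table(records: pd.DataFrame, specs: Sequence[MetricSpec]) -> pd.DataFrame:
    """Per-model weighted stars for each metric plus the total.

    *records* must carry a ``model_id`` column plus metric columns named as
    in the specs.  Returns a frame indexed by ``model_id`` with one weighted
    star column per metric and a ``total`` column.
    """
    if "model_id" not in records.columns:
        raise ValueError("records must have a model_id column")
    if records["model_id"].duplicated().any():
        dupes = records.loc[records["model_id"].duplicated(), "model_id"].tolist()
        raise ValueError(f"duplicate model_id(s): {dupes}")
    rows = {}
    for _, rec in records.iterrows():
        stars = {
            spec.name: spec.weight * assign_stars(rec.get(spec.name), spec) for spec in specs
        }
        stars["total"] = sum(stars.values())
        rows[rec["model_id"]] = stars
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "model_id"
    return out


# --- published reference ranges -------------------------------------------

# The twelve-metric reference binning scheme.  Ramachandran core/disallowed
# each weigh 0.5.  The published GOAP and OPUS-PSP rows print coincident
# 1-star and 0-star bounds; that degenerates cleanly to "1 star iff the value
# meets the 1-star bound, else 0", which is what the cascading comparison in
# assign_stars yields with the 1-star boundary below.
_DEFAULT_SPEC_ROWS = [
    ("errat", "higher-better", (100.0, 99.0, 98.0), 1.0),
    ("verify3d", "higher-better", (73.0, 67.0, 61.0), 1.0),
    ("prove", "lower-better", (2.8, 3.2, 3.6), 1.0),
    ("rama_core", "higher-better", (94.4, 93.7, 93.0), 0.5),
    ("rama_disallowed", "lower-better", (0.0, 0.4, 0.8), 0.5),
    ("labelled_residues", "lower-better", (3.0, 5.0, 7.0), 1.0),
    ("rwplus", "lower-better", (-79000.0, -78250.0, -77500.0), 1.0),
    ("molprobity", "lower-better", (1.0, 1.2, 1.4), 1.0),
    ("rosetta", "lower-better", (-750.0, -675.0, -600.0), 1.0),
    ("dfire", "lower-better", (-649.0, -641.0, -633.0), 1.0),
    ("goap", "lower-better", (-37200.0, -36000.0, -34800.0), 1.0),
    ("opus_psp", "lower-better", (-5770.0, -5650.0, -5530.0), 1.0),
    ("predicted_global_quality", "higher-better", (0.26, 0.24, 0.22), 1.0),
]


def default_specs() -> list[MetricSpec]:
    """The published reference star ranges for the twelve-metric scheme."""
    return [MetricSpec(n, d, t, w) for n, d, t, w in _DEFAULT_SPEC_ROWS]


def save_specs(specs: Iterable[MetricSpec], path: Union[str, Path]) -> None:
    payload = [
        {
            "name": s.name,
            "direction": s.direction,
            "thresholds": list(s.thresholds),
            "weight": s.weight,
        }
        for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_specs(path: Union[str, Path]) -> list[MetricSpec]:
    payload = json.loads(Path(path).read_text())
    return [
        MetricSpec(
            name=row["name"],
            direction=row["direction"],
            thresholds=tuple(row["thresholds"]),
            weight=row.get("weight", 1.0),
        )
        for row in payload
    ]


def load_quality_table(
    path: Union[str, Path],
    rescale_energy_columns: bool = True,
) -> pd.DataFrame:
    """Read a quality-score table (CSV/TSV) into canonical columns.

    ``-`` or empty cells are missing values.  Header synonyms matching the
    published table layout are normalised.  When *rescale_energy_columns* is
    true (default), the ``rwplus`` and ``goap`` columns are multiplied by 10
    on ingest: published tables print these two statistical potentials at a
    tenth of the scale their star ranges use (e.g. −7987 against a 3-star
    bound of −79,000), and the rescale reconciles the two.  Separate
    ``rama_labelled``/``chi_labelled`` columns, if present, are summed into
    ``labelled_residues``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=["-", ""], skipinitialspace=True)
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HEADER_SYNONYMS:
            renames[col] = _HEADER_SYNONYMS[key]
    df = df.rename(columns=renames)
    if "model_id" not in df.columns:
        raise ValueError("quality table must have a model/model_id column")
    if "labelled_residues" not in df.columns and {"rama_labelled", "chi_labelled"} <= set(df.columns):
        df["labelled_residues"] = df["rama_labelled"].fillna(0) + df["chi_labelled"].fillna(0)
    if rescale_energy_columns:
        for col in ("rwplus", "goap"):
            if col in df.columns:
                df[col] = df[col] * 10.0
    keep = ["model_id"] + [m for m in METRICS if m in df.columns]
    return df[keep]
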