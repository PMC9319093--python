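"""Binding-pocket residue fingerprints across models.

Pocket-prediction services emit, per model, a list of pocket-lining
residues.  Stacking those lists into a binary model × residue matrix makes
the predictions comparable: consensus residues (predicted for at least k
models) outline the receptor's putative orthosteric site, and pairwise
Jaccard similarity quantifies how much two models' pockets agree.

Residues are keyed by generic number where one exists; deep-loop positions
without a generic number are keyed by their residue ID with a composite
column label (e.g. ``res:A:175``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .numbering import GenericNumber, ResidueID

__all__ = [
    "PocketPrediction",
    "build_matrix",
    "consensus",
    "jaccard_similarity",
    "load_predictions",
    "write_matrix",
    "read_matrix",
]

ResidueKey = Union[GenericNumber, ResidueID]


def _column_label(key: ResidueKey) -> str:
    if isinstance(key, GenericNumber):
        return str(key)
    return f"res:{key.chain}:{key.seqnum}{key.icode}"


def _column_sort_key(label: str) -> tuple:
    # Generic numbers first, in topology order: a loop segment "ab" sits
    # between helices a and b (45.x between TM4 and TM5).  Residue-ID
    # columns trail, ordered by (chain, seqnum).
    if label.startswith("res:"):
        _, chain, num = label.split(":")
        digits = "".join(ch for ch in num if ch.isdigit())
        return (1, 0.0, int(digits), chain + num)
    seg, _, pos = label.partition(".")
    seg = int(seg)
    order = float(seg) if seg < 10 else (seg // 10 + seg % 10) / 2.0
    return (0, order, int(pos), "")


@dataclass(frozen=True)
class PocketPrediction:
    """One model's predicted pocket residues (unique), with optional size."""

    model_id: str
    residues: frozenset[ResidueKey]
    pocket_size: Optional[int] = None

    @classmethod
    def from_labels(
        cls, model_id: str, labels: Iterable[str], pocket_size: Optional[int] = None
    ) -> "PocketPrediction":
        """Parse residue labels: ``"3.50"`` style or ``"res:A:175"`` style."""
        keys: set[ResidueKey] = set()
        for label in labels:
            label = str(label).strip()
            if label.startswith("res:"):
                _, chain, num = label.split(":")
                digits = "".join(ch for ch in num if ch.isdigit())
                icode = num[len(digits):]
                keys.add(ResidueID(chain, int(digits), icode))
            else:
                keys.add(GenericNumber.parse(label))
        return cls(model_id=model_id, residues=frozenset(keys), pocket_size=pocket_size)


def build_matrix(predictions: Sequence[PocketPrediction]) -> pd.DataFrame:
    """Binary model × residue matrix; cell 1 iff the model predicts the residue.

    Columns are ordered by segment then position (generic numbers), with
    residue-ID-keyed loop columns trailing.
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    ids = [p.model_id for p in predictions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model_id in predictions")
    columns = sorted(
        {_column_label(k) for p in predictions for k in p.residues}, key=_column_sort_key
    )
    data = np.zeros((len(predictions), len(columns)), dtype=int)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, p in enumerate(predictions):
        for key in p.residues:
            data[i, col_index[_column_label(key)]] = 1
    out = pd.DataFrame(data, index=ids, columns=columns)
    out.index.name = "model_id"
    return out


def consensus(matrix: pd.DataFrame, min_models: int) -> list[str]:
    """Residue labels predicted by at least *min_models* models.

    Ordered by prediction frequency (descending), ties by column position.
    """
    n_rows = len(matrix)
    if not 1 <= min_models <= n_rows:
        raise ValueError(f"min_models must lie in [1, {n_rows}]")
    counts = matrix.sum(axis=0)
    keep = counts[counts >= min_models]
    order = {c: j for j, c in enumerate(matrix.columns)}
    return sorted(keep.index, key=lambda c: (-keep[c], order[c]))


def jaccard_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard index of the models' residue sets.

    Symmetric; the diagonal is 1 for nonempty rows (0 for empty ones).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two models")
    m = matrix.to_numpy(dtype=bool)
    inter = (m[:, None, :] & m[None, :, :]).sum(axis=-1)
    union = (m[:, None, :] | m[None, :, :]).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def load_predictions(path: Union[str, Path]) -> list[PocketPrediction]:
    """Read per-model predictions from JSON.

    Layout: ``{"predictions": [{"model_id": ..., "residues": [...],
    "pocket_size": ...}, ...]}``; residues as generic-number strings or
    ``res:<chain>:<seqnum>`` labels.
    """
    payload = json.loads(Path(path).read_text())
    return [
        PocketPrediction.from_labels(
            row["model_id"], row["residues"], row.get("pocket_size")
        )
        for row in payload["predictions"]
    ]


def write_matrix(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    matrix.to_csv(path)


def read_matrix(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, index_col="model_id")
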