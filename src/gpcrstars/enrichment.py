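"""Virtual-screening enrichment: potency labelling, ROC curves and AUC.

Ligands with experimental IC50 below a potency threshold (default 10 μM,
strict inequality) are labelled active; docking scores are then asked to
rank actives ahead of inactives.  The AUC is the tie-aware Mann–Whitney
statistic (ties credited ½), which equals the trapezoidal area under the
tie-aware ROC curve exactly and is invariant under any strictly monotone
transform of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .ranking import v3_stars

__all__ = [
    "POTENCY_THRESHOLD_UM",
    "EnrichmentResult",
    "label_by_potency",
    "roc_auc",
    "compare_models",
    "load_ligand_table",
]

#: Default activity cutoff: IC50 strictly below 10 μM counts as active.
POTENCY_THRESHOLD_UM = 10.0

#: Score direction presets: affinity-style scores grow with predicted
#: binding ("higher-better"); Vina-style energies are more negative when
#: better ("lower-better", the default).
Direction = Literal["lower-better", "higher-better"]


@dataclass(frozen=True)
class EnrichmentResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_active: int
    n_inactive: int

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def label_by_potency(
    potencies_um: Sequence[float],
    threshold_um: float = POTENCY_THRESHOLD_UM,
) -> np.ndarray:
    """Boolean active labels: potency strictly below the threshold.

    A ligand at exactly the threshold is inactive.
    """
    pot = np.asarray(potencies_um, dtype=float)
    if np.any(~np.isfinite(pot)) or np.any(pot <= 0):
        raise ValueError("potencies must be positive and finite")
    return pot < threshold_um


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "lower-better",
) -> EnrichmentResult:
    """Tie-aware ROC curve and Mann–Whitney AUC of docking scores.

    AUC = P(random active outranks random inactive), ties counted ½ —
    computed from midranks, so it matches the trapezoidal area under the
    returned ROC curve exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_active = int(labels.sum())
    n_inactive = int((~labels).sum())
    if n_active == 0 or n_inactive == 0:
        raise ValueError("need at least one active and one inactive ligand")
    # Orient so that larger oriented score = more likely active.
    oriented = -scores if direction == "lower-better" else scores
    ranks = rankdata(oriented, method="average")
    u = ranks[labels].sum() - n_active * (n_active + 1) / 2.0
    auc = float(u / (n_active * n_inactive))
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), oriented, drop_intermediate=False)
    return EnrichmentResult(
        fpr=fpr, tpr=tpr, auc=auc, n_active=n_active, n_inactive=n_inactive
    )


def compare_models(
    score_tables: dict[str, pd.DataFrame],
    direction: Direction = "lower-better",
    threshold_um: float = POTENCY_THRESHOLD_UM,
) -> pd.DataFrame:
    """Per-model AUC and V3 stars from ligand score tables.

    Each table needs ``ligand_id``, ``score`` and either ``label`` (bool) or
    ``ic50_uM``.  Differing ligand sets across models trigger a warning, not
    an error.
    """
    import warnings

    ligand_sets = {m: frozenset(t["ligand_id"]) for m, t in score_tables.items()}
    if len(set(ligand_sets.values())) > 1:
        warnings.warn("models were scored on differing ligand sets; AUCs are not strictly comparable")
    rows = []
    for model_id, table in score_tables.items():
        if "label" in table.columns:
            labels = table["label"].astype(bool).to_numpy()
        elif "ic50_uM" in table.columns:
            labels = label_by_potency(table["ic50_uM"].to_numpy(), threshold_um)
        else:
            raise ValueError(f"{model_id}: table needs a label or ic50_uM column")
        result = roc_auc(table["score"].to_numpy(), labels, direction=direction)
        rows.append(
            {
                "model_id": model_id,
                "auc": result.auc,
                "v3": v3_stars(result.auc),
                "n_active": result.n_active,
                "n_inactive": result.n_inactive,
            }
        )
    return pd.DataFrame(rows)


def load_ligand_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a ligand CSV with columns ligand_id, score and ic50_uM or label."""
    df = pd.read_csv(path)
    if "ligand_id" not in df.columns or "score" not in df.columns:
        raise ValueError("ligand table needs ligand_id and score columns")
    return df
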