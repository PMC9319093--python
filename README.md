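# gpcrstars

Ranking and activation-state analysis for GPCR homology models.

When a receptor has no experimentally solved structure — the situation for
most orphan class A GPCRs, such as the lipid receptor GPR18 — candidate
models come from many prediction methods and must be ranked before docking
or dynamics work can start. `gpcrstars` implements that selection workflow
as a tested library:

- **Stars aggregation** — twelve global protein-quality functions (ERRAT,
  Verify3D, PROVE, Ramachandran core/disallowed, labelled residues, RWplus,
  MolProbity, Rosetta energy, DFIRE, GOAP, OPUS-PSP, predicted global
  quality) are each binned into 0–3 stars by quartile-style value ranges
  and summed with weights into a model total in [0, 36]. The two
  Ramachandran percentages carry weight ½ each, so totals have half-star
  granularity.
- **Secondary V1/V2/V3 ranking** — the star total (V1), the ionic-lock
  distance R3.50↔S6.33 in Å (V2) and the enrichment-test AUC (V3) are each
  binned into 0–3 stars; models are ranked by V1+V2+V3 descending.
- **Generic numbering** — Ballesteros–Weinstein positions (`3.50`, `45.52`,
  …) assigned from per-segment anchor annotations, so geometry code
  addresses residues the way the GPCR literature does.
- **Activation-state geometry** — ionic lock (S6.33 OG to nearest R3.50
  side-chain hydrogen, plus N–O distance and N–H···O angle), the
  R3.50↔D3.49 aspartate-cage salt bridge, and the mean cytoplasmic
  TM3–TM6 Cα distance (3.51–3.55 vs 6.30–6.34; ≤12 Å inactive, ≥14 Å
  active), with Kabsch superposition/RMSD.
- **Trajectory series** — any metric evaluated per frame over multi-MODEL
  PDB frame sets, RMSD-vs-frame-1 series, and geometric protein–ligand
  interaction fingerprints with cross-frame persistence.
- **Enrichment** — strict IC50 < 10 μM activity labelling, tie-aware
  ROC/AUC (midrank Mann–Whitney), and per-model AUC → V3 tables.
- **Pocket fingerprints** — binary model × residue matrices from predicted
  pocket residue lists, consensus extraction and Jaccard similarity.
- **Synthetic data** — seeded generators for every input: quality tables
  with star totals known by construction, idealized 7-TM Cα bundles whose
  lock/cage/TM3–TM6 metrics hit requested targets, noisy drifting
  trajectories, and two-class Gaussian docking scores with analytic AUC
  Φ(|Δμ|/(σ√2)).

## Worked example

Score the packaged quality table and rank the models:

```python
from importlib.resources import files
from gpcrstars.stars import default_specs, load_quality_table, star_table
from gpcrstars.ranking import load_secondary_table, rank_models

data = files("gpcrstars.data")
records = load_quality_table(str(data / "gpr18_quality_table.csv"))
print(star_table(records, default_specs())["total"])
ranked = rank_models(load_secondary_table(str(data / "gpr18_secondary_table.csv")))
print(ranked[["rank", "model_id", "v1", "v2", "v3", "v1_v2_v3"]].to_string(index=False))
```

```
model_id
AF-DM     19.0
CF-DM      3.5
PF-DM      2.5
TR_1      32.0
TTA_5     16.0
CIT_1     22.0
IT_1      11.5
PY3_10     4.0
Name: total, dtype: float64
 rank model_id  v1  v2  v3  v1_v2_v3
    1    CIT_1   2   3   3         8
    2     TR_1   3   2   1         6
    3    TTA_5   1   2   3         6
    4     IT_1   0   3   3         6
    5   PY3_10   0   3   3         6
    6    CF-DM   0   2   3         5
    7    PF-DM   0   2   2         4
    8    AF-DM   1   1   1         3
```

The star totals are weighted sums of per-metric star assignments; `CIT_1`
tops the final ranking because a middling star total (22 → V1 = 2) combines
with a tight 2.09 Å ionic lock (V2 = 3) and an AUC of 0.811 (V3 = 3). Note
the CF-DM and PF-DM totals (3.5 and 2.5) computed from their quality rows:
see `docs/methods.md` for why those two rows are not reproducible against
their originally reported totals.

Build a synthetic inactive-state bundle and measure it:

```python
from gpcrstars import geometry
from gpcrstars.synthetic import BundleSpec, build_bundle

s, nmap = build_bundle(BundleSpec(target_tm3_tm6=11.0, target_lock=2.09))
d = geometry.tm3_tm6_distance(s, nmap)
print(round(d, 2), geometry.classify_state(d))          # 11.01 inactive
print(round(geometry.ionic_lock(s, nmap).h_distance, 2)) # 2.09
```

A thin CLI mirrors the library: `gpcrstars stars`, `gpcrstars rank`,
`gpcrstars roc`, and `gen-quality`/`gen-bundle`/`gen-trajectory`/
`gen-scores` for the synthetic generators (all seeded).

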