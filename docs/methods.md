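# Methods

## The model-selection problem

For a receptor without an experimental structure, candidate homology/folding
models differ along three weakly correlated axes: stereochemical quality,
conformational state, and practical usefulness for ligand screening.
`gpcrstars` encodes a selection procedure that scores all three and combines
them into a single descending ranking. Nothing in the package computes the
underlying quality functions, docking scores or pocket predictions — those
are consumed as tables; the package's contribution is the aggregation,
geometry and ranking layer, plus generators that make every stage testable
without external services.

## Stars aggregation

Each of twelve quality metrics is binned into 0–3 stars by three ordered
boundary values (`MetricSpec`). Boundaries are inclusive exactly as their
comparators read: a Verify3D of 61.0 meets the `≥61` one-star floor. The
Ramachandran core and disallowed percentages carry weight 0.5 each and are
summed after binning, giving a composite in [0, 3] with half-star steps;
all other metrics weigh 1.0, so the twelve-metric total lies in [0, 36]
with 0.5 granularity. A missing metric contributes zero stars rather than
invalidating the record — models from methods that do not emit a given
score are simply not credited for it.

Two numerical conventions in the reference ranges deserve note:

- **RWplus/GOAP scale.** Published per-model tables print these two
  statistical potentials at one tenth of the scale their star ranges use
  (−7987 against a 3-star bound of −79,000). The loader multiplies both
  columns by 10 on ingest behind `rescale_energy_columns` (default on).
  Under this convention six of the eight packaged models reproduce their
  reported totals exactly; under no other scaling does any model reproduce.
- **Coincident worst-bin bounds.** The GOAP and OPUS-PSP rows print
  identical 1-star and 0-star bounds; this degenerates to "1 star iff the
  value meets the bound, else 0", consistent with every other row's
  structure.

Two packaged models, CF-DM and PF-DM, do **not** reproduce their originally
reported totals (we compute 3.5 and 2.5 against reported 11.5 and 8.5)
under any binning we tried; their quality rows appear to have been scored
with additional information not present in the printed table. They are kept
in the fixture for the secondary ranking (whose inputs are the reported
totals) and excluded from exact-match tests.

Thresholds can alternatively be derived from a model population's quartiles
(`derive_thresholds`): boundaries at Q3/Q2/Q1 oriented by the metric's
quality direction, which partitions the population into four roughly equal
bins (each n/4 ± 1 for continuous data). The published ranges are the
default because they are what the reference results were scored with.

## Secondary ranking

V1 bins the star total at floors 27/20/13; V2 bins the ionic-lock distance
at 2.5/3.5/4.5 Å; V3 bins the enrichment AUC at 0.79/0.77/0.75. Models sort
by V1+V2+V3 descending. The coarse sums tie often, and no tie policy is
stated with the reference results, so the package fixes a deterministic
order: total stars descending, then lock distance ascending, then model id.
This affects only presentation order, never the sums.

## Generic numbering

Within a segment, the generic position is a pure offset from the X.50
anchor (`seqnum − anchor = position − 50`); loops use the same convention
(the conserved EL2 cysteine is 45.50). The packaged GPR18 annotation
chooses spans that cover every literature-labelled residue (22 TM pairs
plus the EL2 and 2.x pocket labels) with disjoint ascending ranges; exact
span termini are a working choice — the receptor's true helix ends are not
published — and users can override the annotation file. Insertion codes
participate in residue identity but are rejected inside spans, where offset
arithmetic would be ill-defined.

## Geometry

- **Ionic lock.** Reported as the distance from the S6.33 side-chain
  oxygen to the nearest R3.50 side-chain hydrogen, with the N–O distance
  and the N–H···O angle as companions. Models without hydrogens are common;
  the measurement then degrades to the heavy-atom N–O minimum and is
  flagged (`has_hydrogens=False`) instead of guessing proton positions.
- **Aspartate cage.** Minimum over R3.50 {NE, NH1, NH2} × D3.49
  {OD1, OD2}; a companion boolean applies the common 4.0 Å salt-bridge
  convention, but the raw distance is the primary output.
- **TM3–TM6 distance.** The mean Cα separation of 3.51–3.55 and 6.30–6.34
  is ambiguous in how residues pair. Default `paired` mode aligns the
  cytoplasmic ends (3.51↔6.34, …, 3.55↔6.30 — TM3 runs down, TM6 up);
  `index` and `all-pairs` modes cover the other plausible readings. State
  labels: ≤12 Å inactive, ≥14 Å active, the gap in between
  intermediate-ambiguous; both bounds configurable.
- **Superposition.** Kabsch least squares with a proper-rotation
  correction; collinear selections are rejected (the rotation about the
  line is undetermined). Tests cross-check against Horn's quaternion
  method.

## Trajectories and fingerprints

Frames are multi-MODEL PDB files sharing one topology; 100 ps/frame is the
default time base. Metrics are evaluated independently per frame; a failure
after frame 1 becomes an explicit NaN gap, never an interpolation. RMSD
series superpose each frame onto frame 1 over the selection (default all
Cα) before measuring.

Interaction fingerprints are purely geometric and their thresholds are
package defaults, exposed in the call signature: hydrogen bond at
donor–acceptor heavy-atom distance ≤ 3.5 Å (gated by a D–H···A angle
≥ 120° when hydrogens exist), hydrophobic contact at any C–C pair ≤ 4.0 Å,
aromatic proximity at ring-centroid distance ≤ 5.5 Å using standard
Phe/Tyr/Trp/His ring templates. Residues without a known ring template are
skipped for the aromatic class with a warning. Persistence is the fraction
of frames a (residue, class) contact appears in — invariant to frame order.

## Enrichment

Activity labelling is strictly `IC50 < threshold` (default 10 μM): a ligand
at exactly 10 μM is inactive. AUC is the midrank Mann–Whitney statistic
(ties credited ½), which is identical to the trapezoidal area under the
tie-aware ROC curve and invariant under monotone score transforms. Score
direction is explicit: `lower-better` (Vina-style energies, the default)
or `higher-better` (affinity-style scores).

## Synthetic generators

The generators define the test conditions, not a tuning surface:

- **Quality tables** sample each metric uniformly inside the value range of
  a chosen star bin, so the expected star table is known by construction;
  integer metrics (labelled residues) sample integers inside the bin.
- **Bundles** are ideal α-helices (1.5 Å rise, 100°/residue twist, 2.3 Å
  Cα radius) on a 10 Å circle, seven helices with alternating direction,
  numbered by the packaged GPR18 annotation. The TM6 axis position is
  calibrated by fixed-point iteration until the measured paired-mode
  TM3–TM6 distance is within 0.01 Å of target; lock and cage side-chain
  pseudo-atoms are then placed by exact constrained geometry (collinear
  N–H···O with the hydrogen at exactly the target distance; OD1 at exactly
  the target cage distance with every other pair strictly farther).
  Rotamer realism is deliberately out of scope — distances are all the
  downstream metrics consume. Infeasible targets (a lock longer than the
  inter-helix gap) raise instead of silently degrading.
- **Trajectories** rebuild the bundle per frame with linearly interpolated
  metric targets (drift) and add per-atom Gaussian noise from a seeded
  generator; identical seeds give bit-identical frames.
- **Docking scores** draw the two classes from equal-variance normals, for
  which the population AUC has the closed form Φ(|Δμ|/(σ√2)); the default
  class sizes are 26 actives / 98 inactives, a typical screening-library
  composition. Empirical AUC at n = 1000/class is checked against the
  closed form within three Hanley–McNeil standard errors.

Because the bundles are idealized and the side chains are pseudo-atoms,
passing tests demonstrate the correctness of the measurement and ranking
machinery — not that any real receptor model is well-scored; real models
bring loop regions, alternate conformers and missing atoms that only the
degradation paths here (missing hydrogens, NaN gaps, missing metrics)
emulate.

## Problem sizes

The packaged analyses are desk-scale: 8 models × 12 metrics for the star
tables, 5+5 Cα atoms for TM3–TM6, bundles of ~230 residues, trajectories of
4–10 frames, and score tables of 124–2000 ligands. These sizes exercise
every code path while keeping the full suite and the acceptance script in
the seconds range.

## Known limitations

- Star thresholds reproduce the published reference ranges; re-deriving
  them from a different model population changes totals by design.
- The ionic-lock angle is reported only at the minimizing hydrogen.
- Pocket fingerprints treat predictions as sets; prediction confidence
  scores are not consumed.
- No binary trajectory formats (DCD/XTC) in core; multi-MODEL PDB is the
  interchange format, and an adapter can convert externally.
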