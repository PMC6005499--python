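# Methods

This note records the models, parameter choices, and numerical conventions
behind `alloscreen`, and what the synthetic-data experiments do and do not
demonstrate.

## Scope and design shape

The package is organised stage by stage, mirroring how a selectivity-aware
structure-based screen is actually run: `cluster` (ensemble reduction),
`perception` (interaction detection), `hypothesis` (merging and
serialisation), `screen` (fitting, FitValue, funnel), `validation` (decoys
and retrieval statistics), `geometry` (open/closed state criteria),
`synthetic` (seeded input generators), with `chem` supplying the molecular
data model and properties.  Out of scope by design: homology modelling, MD
production runs, docking, toxicity/ADMET prediction, and wet-lab assays —
the funnel exposes named pass-through hooks where external toxicity or
docking tables can be injected, but never computes them.

## Trajectory clustering

Pairwise RMSD uses optimal least-squares (Kabsch) superposition by
default; the atom selection is configurable through the MDAnalysis
selection language and defaults to all atoms (the original workflow does
not state its selection, so none is hard-coded).  Two partitioners are
implemented because the source procedure describes gromos-style peeling
while naming single linkage: *gromos* (default) repeatedly extracts the
maximum-neighbour frame with its neighbours; *single linkage* takes
connected components under the cut-off.  Neighbourhood uses strict
`RMSD < cutoff`; ties in neighbour counts, representative selection, and
cluster ordering all resolve to the lowest frame index, making results
order-deterministic.  `find_cutoff_for_k` bisects the cut-off on
[0, max(RMSD)] to a 1e-4 Å interval; since the cluster count is only
guaranteed monotone for single linkage, a target count that is never hit
returns the nearest achievable count flagged `exact=False` rather than an
exception.

## Interaction perception

Thresholds live in one `GeometricRules` object (H-bond 2.5–3.8 Å, ≥ 130°
at the donor hydrogen; hydrophobic ≥ 3 receptor apolar carbons within
5.0 Å of a ligand group centroid; π-stacking ≤ 4.5 Å/≤ 30° face or
≤ 5.5 Å/60–120° edge).  These are conventional crystallographic values;
commercial perception tools do not publish theirs, so every number is
configuration, not constant.  Receptor typing is residue-template based
(backbone N/O plus standard side-chain donors, acceptors, apolar carbons,
and aromatic rings); ligand typing comes from the chemical graph: donors
are N/O bearing hydrogens, acceptors are N/O excluding amide nitrogens and
aromatic N–H, hydrophobic groups are maximal connected sets of
non-aromatic carbons (plus halogens) with no heteroatom neighbour, and
aromatic rings come from the smallest ring set.

One deliberate refinement: aromatic-ring atoms are excluded from
hydrophobic groups on both sides.  A stacked ring pair always places ring
carbons within hydrophobic range of the partner ring's centroid, so
counting ring carbons as hydrophobes would make every aromatic stack also
fire a hydrophobic contact and no planted feature multiset could ever be
recovered exactly.  This also matches how such features are reported in
practice (a benzofuran ring as an aromatic feature; ethyl and bromo
substituents as the hydrophobes — a lone halogen on an aromatic ring forms
its own single-atom group).

Receptor donors whose hydrogens are not resolvable pass the H-bond test on
distance alone; ligand donors always use explicit or valence-derived
hydrogens.  Features default to radius 1.5 Å and unit weight, so the
maximum FitValue of a hypothesis equals its feature count, which keeps
scores on the familiar 0–5 scale for five-feature hypotheses.

## Hypothesis merging

Same-type features across aligned snapshots are grouped by single linkage
on center distance at `merge_radius` (default 1.5 Å, the feature radius);
groups supported by at least `min_support` source hypotheses survive as
their unweighted centroid with the default radius and the normalised mean
direction.  Curated "essential" interactions are expressed as provenance
tags listed in `essential_override`, never as hard-coded residue logic.
Merging requires a shared `frame_of_reference` tag and does not superpose:
alignment is the caller's responsibility and is recorded, not inferred.
The JSON schema is versioned; `type`, `center`, and `radius` are required
per feature, `weight`/`direction`/`provenance` have defaults.

## Fitting and FitValue

Correspondence search enumerates injective, type-compatible assignments of
hypothesis features to ligand features with at least `min_features`
matches (default 4, because four-feature matches are deliberately kept to
admit novel scaffolds; the threshold and the match count are independent
knobs).  Backtracking prunes pairs whose inter-feature distances disagree
by more than the summed tolerance radii; an acceptance suite verifies the
pruned search equals exhaustive enumeration.  Each surviving assignment is
scored after Kabsch superposition; an assignment is valid only if every
mapped feature lies inside its tolerance sphere, and the best
(fit_value, n_matched) wins with ties going to the first assignment in
deterministic enumeration order.  Note that re-superposition makes the
score an optimum: displacing a single feature of a perfect hit by d does
not subtract exactly w·(d/r)² because the superposition redistributes the
error; bounds, not naive per-feature arithmetic, are therefore what the
tests assert.  Thresholds are inclusive (≥) throughout — a molecule at
exactly the threshold is a hit.

## Drug-likeness

Lipinski's rule is the strict all-four test with inclusive bounds.  QED is
computed from seven properties (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM);
desirability functions are the published asymmetric double sigmoids as
shipped (versioned) by RDKit's QED module, and both the unweighted
geometric mean and the weighted variant are reported.  The original
method's eighth term (structural alerts) is outside this workflow's scope
and is omitted from both means.  A floor of 1e-6 on each desirability
keeps the logarithms finite without affecting the QED → 0 limit.  The
funnel's QED cut uses the weighted variant and is strict (> 0.50).
Property computation runs on the implicit-hydrogen graph (explicit
hydrogens distort degree-based rotatable-bond matching), reduces salts to
the largest fragment, and is conformer-independent by construction.

## Validation

The confusion table is parameterised the way retrieval statistics are
written in the pharmacophore literature: D database size, A actives, Ht
retrieved, TP actives retrieved, with TN = D − A − (Ht − TP) required
non-negative.  E = (TP·D)/(Ht·A);
GH = [TP(3A+Ht)/(4HtA)]·[1 − (Ht−TP)/(D−A)].  The GH grouping follows the
standard Güner–Henry reading, confirmed by the identity GH = 1 at perfect
retrieval; GH lies in [0, 1] for every valid table (property-tested).
Test-set classification calls a molecule active iff FitValue ≥ θ *and* it
matches the full feature count; with θ = 2.94 and full match 5 this
reproduces the reference 19-molecule PTP1B test set's tallies (8/10
actives, 5/5 less-actives correct).

Decoy windows default to ΔMW 25 Da, ΔROTB 1, ΔHBD 1, ΔHBA 1, ΔALOGP 1.0
with a path-fingerprint Tanimoto cap of 0.75 (RDKit path fingerprint,
maxPath 5, 1024 bits — parameters recorded for reproducibility).  These
follow the conventions of the decoy-construction tools that state their
descriptors but not their windows; all are configurable.  Sampling is
uniform, seeded, and never reuses a decoy across actives; shortfalls name
the failing active.

## Geometry criteria

Each criterion is a distance between centroids of two (residue, atom-name)
selections, averaged over frames, compared against open/closed reference
values with a tolerance; the overall call is a majority vote with ties
indeterminate.  The shipped PTP1B criteria file contains placeholder
WPD-loop/catalytic-site/helix distances clearly marked as editable
assumptions — the framework (six-or-seven configurable criteria, averaging,
vote) is the deliverable, not the constants.

## Synthetic data: what it emulates and what it does not

Generators are deterministic given (parameters, seed) and carry ground
truth sufficient to predict every downstream result at zero noise.

* **Toy complexes** place minimal amino-acid fragments (Gly backbone
  donor/acceptor, Leu side-chain cluster, Phe ring) around a small
  multifunctional ligand so each planted interaction satisfies the
  perception rules with margin; the noise knob displaces receptor atoms by
  a bounded amount (uniform in [0, noise]), so recovery claims are
  worst-case over that radius rather than Gaussian-tail statements.
* **Hit libraries** realise feature arrangements as chemically valid
  graphs (amine/ether/alkyl/phenyl units on spacer chains) whose conformer
  coordinates are set directly; poses are synthetic, not energy-minimised,
  and a per-molecule alkyl pad (2–8 carbons, parked away from the
  pharmacophore) spreads library compositions the way a vendor catalogue
  would.  Dual binders carry a second conformer reproducing the
  anti-target.  Non-hit guarantees assume hypothesis centers are separated
  by more than twice the feature radius.
* **Decoy pools** build constitutional analogues of each active: a random
  linearly-biased carbon tree plus benzene rings, with degree-2 N/O
  spliced into C–C edges and degree-1 N/O attached terminally.  This
  preserves the molecular formula and donor/acceptor environments exactly
  (so the property windows are satisfiable at useful rates) while path
  fingerprints diverge; distractors are long alkanes violating the MW
  window.
* **Two-state trajectories** jitter two reference conformations whose
  displacement is iteratively rescaled to a requested minimum RMSD after
  superposition, with separability requiring inter-state RMSD > 4×jitter.

Passing on these inputs demonstrates algorithmic correctness — exact
recovery of planted structure, oracle equivalence, monotonicity, closed
forms — not performance on real chemistry: real binding sites have
correlated motions, water and charge effects the rules ignore, and real
libraries are not built from the hypothesis under test.  Counts from the
original full-scale screen that depended on a commercial catalogue and
external tools (the 393932 → … → 94 → 35 cascade) are treated as workflow
shape, not as reproducible targets.

## Problem sizes in the shipped experiments

The acceptance script and tests use 60-frame trajectories (20 atoms),
100 toy complexes, 25-molecule screening libraries, 12 actives × 36 decoys
= 432 decoys from pools of ~700 candidates, 500 random matrices (n ≤ 8)
for clustering oracles, 200 random instances for the fitting oracle, and
10,000 random confusion tables; the whole acceptance run completes in
about 15 seconds on one CPU.  These sizes were chosen as the smallest that
exercise every code path with non-trivial combinatorics.

## Known limitations

Direction vectors are carried and merged but not scored during fitting
(center-distance scoring only).  Receptor typing covers the 20 standard
amino acids; cofactors and metals are not typed.  Ligand bond-order
perception from PDB input uses RDKit's valence-based determination and
falls back to connectivity-only (flagged on the complex) when it fails.
The conformer embedder is a convenience wrapper around RDKit ETKDG for
2D-only inputs; conformer ensembles are otherwise treated as inputs, and
recorded generator settings from upstream tools (e.g. a 255-conformer cap
at a 4 kcal/mol window) are carried as metadata only.
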