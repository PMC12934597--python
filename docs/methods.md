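# Methods

This note documents the model behind `mgvs`, the assumptions it makes, the
default parameters, the scope of the synthetic input generators, the
numerical choices that make runs reproducible, and the known limitations.

## Model

The pipeline assumes a generative model has already produced a set of
candidate binders, some of which are synthetically inaccessible. Rather
than constrain the generator, `mgvs` retrieves close analogs of the best
candidates from a purchasable library and quantifies what the analogs
retain of the originals: docking score and binding-mode interactions.

### Anonymous-graph edit distance

Similarity for analog retrieval is the exact graph edit distance between
**anonymous graphs**: heavy-atom skeletons with hydrogens removed and all
element and bond-order labels discarded. Two molecules at GED 0 therefore
share a topology but may differ in every atom type (benzene, cyclohexane
and pyridine are all the same 6-cycle).

The edit set is: add a terminal node, delete a degree-1 node, add an edge,
delete a non-bridge edge. Each edit maps a connected graph to a connected
graph, and each edit has an inverse edit in the set, so the shortest-path
distance over this move graph is symmetric and satisfies the triangle
inequality by construction; identity of indiscernibles holds up to graph
isomorphism, which is exactly the equivalence the anonymous representation
is meant to induce.

Implementation: graphs are keyed by the canonical SMILES of an all-carbon,
all-single-bond realization of the skeleton, which reduces isomorphism to
string equality (validated exhaustively against true isomorphism over all
connected 6-node graphs). Distance queries run A\* over edit space with an
admissible, consistent lower bound
`max(|Δn| + |Δ(m − n)|, ceil(L1(sorted degree sequences, zero-padded) / 2))`
(each edit changes node/edge counts by at most one and moves the degree
sequence by at most 2 in L1). A library is indexed by bucketing compounds
per canonical key; a query searches buckets in ascending lower-bound order
and stops once enough compounds are resolved strictly below the next
bucket's bound, which is lossless. An independent brute-force breadth-first
oracle (`exact_ged_reference`) exists solely to validate the optimized
search and is exercised by the acceptance tests.

Ties at equal GED are broken by topological path-based fingerprint Tanimoto
distance, then compound id; a circular (radius-2) fingerprint distance is
reported alongside.

### Filters

Generated molecules pass a three-part filter before query selection:

- **Structural rules**: no cumulated double bonds (a carbon carrying two
  non-aromatic double bonds — allenes, ketenes, isocyanates; hypervalent
  sulfonyl/phosphoryl/nitro oxo groups are explicitly *not* cumulenes and
  pass); rings only of size 5 or 6; fused systems of at most 4 rings
  (configurable); no ring systems in which three or more rings are
  pairwise fused ("ring loop", e.g. adamantane-like cages).
- **PAINS**: RDKit's built-in PAINS filter catalog.
- **Drug-likeness window** on computed properties, defaults
  `mw ∈ [150, 500]`, `logp ≤ 5`, `hbd ≤ 5`, `hba ≤ 10`,
  `rot_bonds ≤ 10`; every bound is configurable and inverted ranges are a
  configuration error.

### Synthetic accessibility estimate

`chemio.sa_score` is a self-contained complexity-penalty heuristic on the
conventional 1–10 scale (lower = easier): penalties for molecule size,
stereocenters, spiro and bridgehead atoms, macrocycles, unusual elements
and formal charges are summed and squashed with `1 + 9(1 − e^(−p/4))`. It
is deterministic and monotone in structural complexity, which is all the
pipeline needs for relative comparisons. It is **not** calibrated against
any external fragment-frequency database and its absolute values should
not be compared with other published SA scales.

### Docking

Conformers are embedded with seeded ETKDG, deduplicated by Butina
clustering on heavy-atom RMSD (cutoff 1.0 Å), relaxed with MMFF94, and
scored through a pluggable engine adapter (`dock(rec, mol_h, conf_idx,
receptor) -> (score, coords)`). The best (minimum) score over conformers
represents the molecule. Queries are ranked by **ligand efficiency**,
`vina / heavy_atoms`, to counter the size bias of empirical scoring
functions; raw-score ranking is available via configuration.

The **mock engine** used by tests and fixtures scores
`-0.3 · heavy_atoms + U` with `U` a stable-hash pseudo-random value in
`[-1.5, +1.5]` keyed on (canonical SMILES, receptor name, seed), plus a
+10 kcal/mol penalty for poses whose centroid leaves the docking box. It
reproduces the size bias that makes efficiency normalization meaningful,
scores identical molecules identically, and is fully deterministic. The
external engine adapter shells out to any Vina-compatible executable and
parses only its documented output grammar (stdout table or
`REMARK VINA RESULT` lines).

### Interaction detection and matching

Purely geometric, with inclusive cutoffs (distances in Å, angles in
degrees):

| interaction          | distance | angle                |
|----------------------|----------|----------------------|
| hydrogen bond (D–A)  | ≤ 3.5    | D–H–A ≥ 120          |
| hydrophobic (C–C)    | ≤ 3.8    | —                    |
| salt bridge (centroids) | ≤ 4.0 | —                    |
| π-stack parallel     | ≤ 4.0    | plane angle ≤ 30, offset ≤ 2.0 |
| π-stack perpendicular | ≤ 5.5   | plane angle 50–90, offset ≤ 2.0 |
| π–cation             | ≤ 4.0    | —                    |

Receptor donors lacking explicit hydrogens get idealized ones from the
residue's local covalent frame (tetrahedral / trigonal / bisector); rotor
orientations are deterministic but not optimized against the environment.
Hydrophobic contacts inside π-stacked ring pairs are discarded, and
duplicate contacts per (kind, partner set) keep the shortest instance.

Query/hit matching compares interactions at **atom** or **residue**
resolution, over **all** kinds or a **specific-only** scope that drops
hydrophobic contacts. Pooled statistics report, per kind and overall, the
fraction of hits sharing all / at least one of their query's interactions,
plus per-query top-1 and any-hit rollups.

### Evaluation statistics

ΔVina = analog score − query score (negative = analog better). The
baseline comparison draws random library subsets of the hit-set size and
compares the median top-k ligand efficiency (20 repeats), plus a Welch
unequal-variance t-test on the full efficiency vectors. The pool-size
curve is the running-minimum ΔVina within the top-k analogs, averaged over
queries with a normal 95% band (mean ± 1.96 SE); it is non-increasing by
construction. Distance–score association uses Spearman rank correlation,
returning NaN with a warning on constant input.

## Synthetic input generators (scope)

`mgvs.synthfix` exists to make the pipeline testable without external
data. Its generators are deliberately simple and are **not** generative
models:

- `make_generated_set` samples a fixed pool of 24 hand-curated drug-like
  scaffolds and adds 0–2 methyl decorations.
- `make_library` grows libraries by recorded random edits (terminal
  add/remove, 5/6-ring open/close) from seed SMILES; the edit count upper
  bounds the true GED to the seed, enabling planted-recovery tests.
- `plant_complex` builds minimal receptor–ligand complexes realizing
  requested interactions at exact geometry, one isolated site per spec,
  30 Å apart; a self-check verifies realized geometry to 0.05 Å / 2° and
  the absence of unintended directional contacts within 1.2× of any
  distance cutoff.

## Numerical choices and determinism

- Conformer embedding, library growth and baseline subsampling are all
  seeded; the mock engine is hash-keyed, not stateful.
- Ranking ties break on the secondary metric, then compound id; hit ties
  break on fingerprint distance, then id.
- TSV artifacts use fixed float formats; JSON artifacts round floats to 10
  decimals, map non-finite values to null, and sort keys — two identical
  runs are byte-identical (asserted in the acceptance tests).
- Planted distances are exact by construction (anchor at site, partner at
  site + (d, 0, 0)), so at-cutoff distance detection is exact. Planted
  angles carry ~1e−13 arccos round-trip noise, so angle boundaries are
  tested at ±1° rather than exactly at the cutoff.

## Performance envelope

Exact GED is exponential in the radius. The defaults
(`max_ged = 12`) are safe only because the bucket lower bounds prune
almost everything at realistic library scales; searches that must *prove*
large distances on drug-sized molecules (≈ 14 heavy atoms) are practical
up to radius 2 (sub-second to a few seconds per query against a ~200
compound index) and up to radius 3 only for small skeletons (≲ 7 heavy
atoms). Fixtures and tests are sized accordingly.

## Limitations

- The anonymous-graph representation ignores chemistry by design; a GED-1
  analog can be chemically very different (e.g., N→C swaps are distance
  0). Fingerprint tie-breaking mitigates but does not remove this.
- The mock engine's score is a size term plus hash noise: suitable for
  testing determinism, ranking plumbing and size-bias handling, not for
  any chemical conclusion.
- Receptor hydrogen placement is idealized and environment-blind; rotable
  donors (e.g. serine OH) may point away from a real acceptor.
- The SA heuristic is uncalibrated (see above).
- `ExternalVinaEngine` depends on Open Babel for PDBQT preparation and
  has only been exercised against the documented Vina output grammar, not
  against a live engine in this repository's test suite.
- Statistics assume independent observations; analogs of the same query
  are correlated, so p-values from the pooled tests are optimistic and
  should be read as descriptive.
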