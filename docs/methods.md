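# Methods

## Structure input

Structures are read with gemmi from PDB or mmCIF; only the Cα trace of one
polymer chain is kept, since all downstream computation (superposition,
RMSD, distance metrics) operates on Cα coordinates. Policy decisions, fixed
here rather than configurable:

* model 1 only for multi-model (NMR) entries;
* altloc conformers resolve to the highest occupancy, ties toward `'A'`;
* waters and non-polymer HETATM records are excluded; modified amino acids
  with a Cα are kept with one-letter code `'X'`;
* chain `"auto"` selects the first chain with ≥ 20 Cα atoms, else the first
  with any Cα;
* coordinates are carried in Å exactly as read.

Consecutive Cα–Cα distances are validated against [2.5, 4.5] Å; larger gaps
are recorded as chain breaks rather than errors, because missing loops are
routine in crystal structures. The dataset-level resolution filter removes
structures with a recorded resolution *strictly above* 4 Å; entries without
a resolution record (NMR, predicted models) are retained, since the filter
targets poorly resolved crystal structures specifically.

## Pairwise alignment

The aligner is a CE-style fragment-seeded iterative superposition, not a
reimplementation of any particular web server's algorithm: secondary-
structure-graph matchers are not published in implementable detail, and the
downstream pipeline needs only (RMSD, N_sup) per pair. Consequently
per-pair numbers from other software are reproduced only approximately;
when exact published per-pair tables are available they can be ingested
directly through the table mode, bypassing alignment.

Parameters (all exposed on `AlignParams` / CLI flags):

| parameter | default | meaning |
|---|---|---|
| `fragment` | 8 | gapless seed fragment length (residues) |
| `n_seeds` | 20 | seeds refined to convergence, ranked by fragment RMSD |
| `d0` | 3.0 Å | distance scale of the DP similarity 1/(1+(d/d0)²) |
| `dcut` | 5.0 Å | matched pairs farther than this are dropped before re-superposition |
| `gap` | 0.5 | linear DP gap penalty per skipped residue |
| `tol_rmsd` | 1e-4 Å | convergence threshold on ΔRMSD (with Δn_aligned = 0) |
| `max_iter` | 50 | iteration cap per seed |
| `min_core` | 12 | minimum matched pairs for a valid alignment |

Determinism: seed fragments are scored by a closed-form batched Kabsch
objective and ranked by RMSD with a stable sort; DP tie-breaks prefer the
diagonal (match) move, then the gap in the second structure. There is no
randomness anywhere in the aligner. The result is made exactly symmetric in
its two arguments by computing on the id-sorted order and transposing.
Pairs that never reach `min_core` matched residues return a no-alignment
result (N_sup = 0, RMSD = NaN) instead of raising; matrix assembly imputes
such SAS entries as 1.5 × the largest observed SAS (flagged), because the
least-squares tree and network fits require finite matrices, and sets
1−Q = 1.

The Kabsch solver corrects the reflection branch by the determinant sign of
the cross-covariance SVD, so the returned rotation is always proper;
rank-deficient (collinear) inputs still return the proper-rotation optimum.

## Distance metrics

SAS = RMSD × 100 / N_sup. Qscore = N_sup² / ((1 + (RMSD/r0)²) · n_a · n_b)
with r0 = 3.0 Å by default (exposed as a flag; the SSM convention). SAS is
undefined at N_sup = 0 (handled by imputation above); 1−Q lies in [0, 1)
for any real alignment. Matrix text output keeps ≥ 10 significant digits;
printed reports round to 3 decimals. Both a strict PHYLIP square-matrix
dialect (10-character names) and a relaxed tab-separated dialect are
written; square and lower-triangle dialects are read.

When a supplied table carries both a 1−Q column and the fields needed to
recompute Q, discrepancies beyond 0.005 are flagged and logged, never
silently reconciled; flagged rows stay in the analysis.

## Fitch–Margoliash trees

The criterion is Σ_{i<j} (d_ij − p_ij)² / d_ij^power with power = 2 (the
classic weighting; exposed as a parameter). Zero off-diagonal distances
would make a weight infinite, so they are replaced — for weighting only —
by (smallest positive d)/10. Truly duplicate taxa (zero distance and
identical matrix rows) raise a degeneracy error naming the pair.

Branch lengths for a fixed topology solve the weighted non-negative least
squares on the path-incidence system (rows = leaf pairs, columns = edges);
the unconstrained normal-equations solution is accepted when it is already
non-negative (it then equals the constrained optimum), otherwise the
active-set NNLS solver runs. Negative lengths never appear in output.

Topology search: stepwise taxon addition followed by first-improvement NNI
scanning until a full pass yields no improving move (acceptance strictly
decreases the objective, so termination is guaranteed). Placement of each
new taxon is scored cheaply — existing branch lengths fixed, only the
attachment position and pendant length optimized (2-variable box-
constrained LS) — followed by a full refit after each insertion. Restarts
(default 10, seed default 1729) shuffle the addition order; the shuffle
acts on the canonical sorted label order, making the search invariant to
the input matrix's label ordering. For n > 10 the search ranks candidate
topologies by the unconstrained least-squares objective (a lower bound that
coincides with the constrained optimum whenever the fit is non-negative)
and applies the exact NNLS fit to the final tree; at n ≤ 10, where
exhaustive oracles are feasible, scoring is exact throughout. SPR/global
rearrangements are not implemented — NNI only; this is a known limitation
relative to exhaustive search for difficult matrices.

## Neighbor-Net

The agglomerative ordering follows the canonical two-level selection:
cluster pairs minimize Q(A,B) = (m−2)·d(A,B) − Σ_C d(A,C) − Σ_C d(B,C)
over cluster-averaged distances; within the chosen clusters the node pair
minimizes the same criterion with the member nodes treated as singleton
clusters. Linked triples (x,y,z) reduce to two replacement nodes with the
2/3–1/3 distance mixtures (d(u,t) = ⅔d(x,t) + ⅓d(y,t), mirrored for v, and
d(u,v) = (d(x,y)+d(x,z)+d(y,z))/3). Expanding the reduction stack yields
the circular order; ties break toward the lexicographically smallest pair
of represented labels, so the output is deterministic, and the returned
cycle is canonicalised (smallest label first, smaller neighbour second).

Split weights: all n(n−1)/2 interval splits of the circular order are
fitted by ordinary (unweighted) non-negative least squares ‖Aw − d‖; this
is one of the variance options offered by interactive network software and
is recorded here as the package's dialect. Splits below `wmin` = 1e-6 are
dropped. On additive (tree) metrics the recovered split set equals the
tree's bipartitions with weights equal to branch lengths (theorem-backed,
and asserted in tests); on circular-decomposable metrics the residual is
numerically zero. Output is a SplitsTree-compatible NEXUS SPLITS block.

## Synthetic generator

The generator emulates the *shape* of a real structure-phylogenetics
study, not protein physics:

* **Folds** are idealized Cα traces — helices with 1.5 Å rise, 2.3 Å
  radius, 100°/residue twist (3.83 Å chord); strand zigzags with 3.4 Å
  rise; loops as direction-correlated random walks at 3.8 Å steps —
  concatenated with random inter-segment rotations. No side chains, no
  packing, no self-avoidance guarantees.
* **Evolution** along a tree adds i.i.d. Gaussian coordinate noise with
  σ = `noise_per_unit_branch` × branch length per branch, plus
  Poisson(`indel_rate` × length) terminal deletions of 1–4 residues.
  Per-branch random streams derive from a stable hash of the leaf set
  behind the branch, so subtree simulations are reproducible in isolation.
  Defaults: noise 0.15 Å per unit branch, indel rate 0.1 per unit branch.
* **Distance fixtures** are patristic matrices plus symmetric truncated
  Gaussian noise, clamped strictly positive.
* The **supplementary-shaped table** generator builds a 61-structure,
  7-clade pairwise table whose within-clade mean N_sup/SAS/1−Q levels
  follow the published per-clade summaries of the 61-structure
  nucleotidyltransferase-fold comparison, with the constant between-clade
  levels solved at run time so the overall means land at the published
  124.2 residues / 3.148 SAS. Both metric columns are ultrametric up to
  mean-centred jitter (between-clade level above every within-clade
  level), so clade recovery is exact by construction; per-stratum jitter
  is mean-centred, keeping realised stratum means at their targets (N_sup
  rounds to integers, so its realised means — which the generator returns
  — can shift by a fraction of a residue). RMSD is derived as
  SAS·N_sup/100, making the table internally consistent; the 1−Q column
  is generated directly rather than from the Q formula, as a supplied
  score column.

Because the noise model accumulates *variance* per branch, the expected
RMSD between two leaves is the square root of a path sum of squared branch
lengths — a concave transform of an additive metric, which preserves tree
hierarchy only when that variance metric is ultrametric. The end-to-end
benchmark therefore evolves structures along a variance-balanced tree:
`symmetric_clade_tree` (four groups of three on a balanced backbone;
durations 1.5 backbone / 2.0 stem / 0.5+0.5 within) passed through
`sqrt_branch_lengths`. Under these conditions the full pipeline
(align → SAS → Fitch–Margoliash) recovers the generating topology in
≥ 9/10 seeded 12-taxon replicates with ~64-residue chains. Passing tests
under these conditions demonstrates internal consistency of the chain, not
performance on real, flexibly divergent proteins.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path at interactive turnaround: 61 taxa for the
table-mode statistics and clade recovery (2 search restarts), n ≤ 16 for
additive-matrix exact-fit checks, exhaustive topology oracles at n = 4, 5,
and ten 12-taxon replicates of ~64-residue structures for the end-to-end
recovery rate.

## Known limitations

* The aligner is sequential (no topology-independent correspondences) and
  rigid (no flexible/multi-domain alignment); it is validated by
  properties and construction-based oracles, not against any external
  server's per-pair output.
* Tree search is NNI-based; pathological matrices may need more restarts.
* No bootstrap or split-confidence machinery: distance matrices from
  structural superposition offer no straightforward resampling unit.
* The synthetic evolution model has no sequence component, no insertions,
  and no structural constraints beyond the initial ideal geometry.
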