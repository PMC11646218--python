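# foldphylo

Structure-based phylogenetics from Cα traces.

Protein tertiary structure diverges far more slowly than sequence, so
superposition of folds can recover evolutionary relationships among proteins
whose sequences have long since lost detectable similarity — deep
superfamilies such as the polβ-like nucleotidyltransferases, where a common
catalytic core (a small β-sheet backed by helices, with three acidic
catalytic residues) is shared by RNA-modifying polymerases, DNA repair and
replicative polymerases, antibiotic-modifying enzymes and signalling
nucleotidyltransferases across all domains of life and their viruses.
`foldphylo` implements the complete distance-based pipeline for this kind of
analysis, for structural biologists and molecular evolutionists who want a
scriptable, fully testable alternative to chaining web servers and GUI
tools.

## The method

1. **Pairwise superposition.** Every pair of structures is aligned
   sequence-independently by a fragment-seeded iterative aligner: gapless
   fragment pairs that superpose well (Kabsch) seed a rigid transform;
   residue correspondences are re-derived by dynamic programming over the
   similarity S(i,j) = 1/(1 + (d_ij/d0)²) and re-superposed until
   convergence. Each pair yields an RMSD and N_sup, the number of
   superimposed residues.
2. **Structural distances.** Two normalised metrics per pair:
   - SAS = RMSD × 100 / N_sup (lower = more similar, unbounded above);
   - 1 − Q, with the Qscore Q = N_sup² / ((1 + (RMSD/r0)²) · n_a · n_b),
     which also accounts for the lengths of both proteins (1 − Q ∈ [0, 1)).
3. **Trees.** Unrooted trees are fitted to each distance matrix under the
   Fitch–Margoliash weighted least-squares criterion
   Σ_{i<j} (d_ij − p_ij)² / d_ij², with non-negative branch lengths
   (NNLS on the path-incidence system) and a stepwise-addition + NNI
   topology search with seeded restarts.
4. **Networks.** Neighbor-Net circular split systems expose conflicting
   signal the trees average away: agglomerative ordering of the taxa around
   a circle, then non-negative least-squares weights for all interval
   splits; output is SplitsTree-compatible NEXUS.
5. **Clade statistics.** A table-ingest mode consumes a pairwise-comparison
   table (TSV/CSV/xlsx with per-pair RMSD, N_sup, SAS, 1−Q), computes
   overall and per-clade means, and checks which configured clades are
   recovered as exact bipartitions of the inferred trees.

A synthetic generator (`foldphylo.synthetic`) produces idealized Cα folds
evolved along known trees, additive(+noise) distance matrices, and
clade-structured pairwise tables, so every stage of the pipeline is testable
against known ground truth without downloading a single structure.

## Worked example

Generate a synthetic 61-structure pairwise table with seven clades, then
compute clade statistics and recovery:

```sh
python - <<'EOF'
import pandas as pd
from foldphylo.synthetic import make_supplementary_twin, write_pairwise_table
table, clade_map, _ = make_supplementary_twin(seed=2)
write_pairwise_table(table, "pairs61.tsv")
pd.DataFrame([{"id": k, "clade": v} for k, v in clade_map.items()]).to_csv(
    "clades61.tsv", sep="\t", index=False)
EOF
foldphylo clade-stats --pairs pairs61.tsv --clades clades61.tsv --report report.tsv
```

prints

```
SAS: 7/7 clades recovered
1-Q: 7/7 clades recovered
Robinson-Foulds distance between SAS and 1-Q trees: 94
wrote report to report.tsv
```

and `report.tsv` begins

```
scope   mean_n_aligned  mean_sas  mean_one_minus_q  n_pairs
all     124.196         3.148     0.937             1830
1       235.044         1.178     0.753             45
2       245.000         1.376     0.756             15
```

i.e. all seven clades appear as exact bipartitions in the trees from both
metrics (the large Robinson–Foulds distance between the two trees comes
from within-clade rearrangements, which are weakly determined), the mean
pairwise comparison superposes ~124 residues at a mean SAS of 3.15, and
within-clade comparisons are much tighter (e.g. clade 1: 235 residues at
SAS 1.18).

The structure-level pipeline works from a manifest of PDB/mmCIF files
(columns `id`, `path`, `chain`, …; a resolution filter drops crystal
structures poorer than 4 Å):

```sh
foldphylo simulate --outdir sim --n-taxa 8 --seed 4        # synthetic demo input
foldphylo pipeline --manifest sim/manifest.tsv --tree sas.nwk --network sas.nex
```

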