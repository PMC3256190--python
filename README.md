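# seabarcode

A toolkit for evaluating multi-locus DNA-barcoding systems for plants,
built around the seagrass use case: choosing among plastid barcode loci
(a slow coding locus such as *rbcL*, an intermediate one such as *matK*,
and a fast, indel-rich intergenic spacer such as *trnH-psbA*) for a small
clade whose species are morphologically plastic and hard to tell apart.

Given per-locus alignments and a taxon table — or a simulated dataset
with known truth — the package runs the complete computational
evaluation such a study needs:

* **Site composition** — every alignment column is classified as
  conserved, variable, singleton or parsimony-informative (PIC: at least
  two states, each in at least two sequences), per locus and per locus
  combination.
* **Barcoding gap** — uncorrected *p*-distances (mismatches over sites
  where both rows carry an unambiguous base; pairwise deletion),
  partitioned into intra- and inter-group sets at species or genus rank;
  the gap statistic is min(inter) − max(intra) and the overlap fraction
  is the share of intra distances ≥ min(inter).
* **Tree methods** — neighbour joining, maximum parsimony (Fitch length,
  NNI search) and maximum likelihood (Felsenstein pruning under
  JC69/K2P/HKY85/GTR, optional +Γ and +I; NNI with Brent branch-length
  optimisation), each with nonparametric bootstrap, plus majority-rule
  consensus and Robinson–Foulds topology comparison.
* **Species resolution** — a species is *resolved* when its sequences
  form an exclusive clade whose support passes a threshold (default
  50%); per-method reports aggregate into mean ± SE tables across
  methods and locus combinations.
* **Character-based barcoding** — pure, simple characteristic attributes
  (CAs): column states fixed within a clade and absent outside it;
  queries are classified by the fraction of a clade's CAs they match.
* **Inverted repeats** — dynamic-programming alignment of a spacer
  against its own reverse complement (match +3, mismatch −4, gap −12,
  score threshold 40), with cross-taxon conservation summaries.
* **In-silico PCR and identification** — degenerate-primer matching with
  IUPAC expansion, amplicon prediction, and rank-level identification
  (species / genus / family) against a local reference library by scored
  local alignment.
* **Simulator** — a rank-structured ultrametric taxonomy (families →
  genera → species → individuals) with per-locus rate multipliers,
  indels recorded so the emitted alignment is exact, and plantable
  diagnostic columns and inverted repeats for round-trip tests.

Tree-method aggregates cover NJ, MP and ML; Bayesian inference is out of
scope and every report says so.

## Worked example

```python
from seabarcode.simdata import SimulationConfig, simulate_dataset
from seabarcode.sitestats import site_composition
from seabarcode.distances import distance_matrix, partition_distances
from seabarcode.trees import bootstrap_support
from seabarcode.resolution import species_resolution

truth = simulate_dataset(SimulationConfig(seed=1))

for name, aln in truth.alignments.items():
    print(name, site_composition(aln).pct_pic)

rep = partition_distances(distance_matrix(truth.alignments["spacer-like"]),
                          truth.metadata, rank="genus")
print("inter mean", round(rep.summaries["inter"]["mean"], 3),
      "gap", round(rep.gap_stat, 3))

tree = bootstrap_support(truth.alignments["matK-like"], "nj",
                         reps=100, seed=5)
print("resolution %", species_resolution(tree, truth.metadata).resolution_pct)
```

prints

```
rbcL-like 16.4
matK-like 38.8
spacer-like 65.2
inter mean 0.251 gap 0.053
resolution % 100.0
```

— the fast spacer carries the most parsimony-informative sites (65% vs
16% for the slow locus), its inter-generic *p*-distances (mean 25%) sit
clear of the intra-generic ones (positive gap 0.053), and a 100-replicate
NJ bootstrap on the intermediate locus resolves all 15 simulated species.

The same stages are available from the shell:

```bash
seabarcode simulate --seed 1 --outdir data/
seabarcode sites data/rbcL-like.fasta data/matK-like.fasta
seabarcode gap data/spacer-like.fasta --taxa data/taxa.tsv --rank genus
seabarcode tree data/matK-like.fasta --method nj --reps 100
seabarcode run --seed 1 --outdir report/
```

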