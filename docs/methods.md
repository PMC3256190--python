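# Methods

This note documents the models, conventions and design choices behind
`seabarcode`, in the order the pipeline runs them.

## Data model and missing-data conventions

Sequences are uppercase IUPAC DNA with `-` (alignment gap, an inferred
indel) kept distinct from `?` (missing data, e.g. a locus never sequenced
for a taxon). One convention governs every statistic in the package:
**gaps, `?` and ambiguity codes are non-comparable** — they are excluded
from site classification, from *p*-distance denominators, and are
union-neutral (treated as "could be anything") in parsimony and
integrated out in likelihood. Ambiguity codes are deliberately *not*
expanded into candidate bases for site statistics or distances; the
deterministic convention matches common phylogenetics practice and keeps
all counts reproducible. Printed column coordinates are 1-based
inclusive everywhere.

Supermatrices concatenate per-locus alignments over the union of taxa;
a taxon missing a locus carries `?` across that partition, and a
duplicate (taxon, locus) record is an error rather than an overwrite.

## Site composition

A column with fewer than two unambiguous bases is *indeterminate* and
excluded from the percentage denominator (the choice of denominator is
stated in every report because percentages are meaningless without it).
Otherwise it is *conserved* (one state), *parsimony-informative* (at
least two states, each with multiplicity ≥ 2) or a *singleton* (variable
but not informative). Two identities hold by construction and are
property-tested: conserved + variable = denominator and singleton + PIC
= variable. Percentages are reported to one decimal. A `gap_as_state`
flag lets indel-rich spacers count `-` as a fifth state for sensitivity
analyses; it is off by default.

## Distances and the barcoding gap

*p*-distance = mismatches / comparable sites under pairwise deletion; a
pair with zero comparable sites is *undefined* and excluded from gap
sets (silently scoring it 0 or 1 would bias the gap) but counted in the
report. Gap analysis partitions all defined pairs at a chosen rank —
genus is the default minimal unit, mirroring sampling designs where
most species have one or two individuals — and summarises:

* `gap_stat` = min(inter) − max(intra), positive iff the distributions
  separate;
* `overlap_fraction` = share of intra values ≥ min(inter);
* histograms over half-open bins of width 0.5% (the 0–20% axis
  granularity typical of barcoding-gap figures), emitted both as counts
  and as relative frequencies since conventions differ.

Both extreme statistics ride on single order statistics: on a slow locus
where conspecific pairs differ by ~1 substitution the realised min/max
gap is fragile even when the means separate cleanly. Tests therefore
check the strict gap on the fast spacer and on the concatenated matrix,
and mean separation on the slow locus.

## Tree methods

**NJ** is the canonical Q-criterion agglomeration. Ties break toward the
lowest (row, column) index pair, negative branch lengths are clamped to
zero with the total deficit recorded on the tree — documented
determinism was preferred over faithfulness to any particular legacy
implementation.

**Parsimony** uses Fitch counting (bitmask sets, vectorised over
columns; missing data are union-neutral). The search runs NNI hill
climbing from an NJ start plus seeded random-order stepwise-addition
starts, returning all co-optimal topologies found. On six taxa the
search provably reaches the exhaustive minimum in tests.

**Likelihood** is Felsenstein pruning under JC69, K2P, HKY85 or GTR,
with optional discrete-gamma rate variation (four mean-of-quantile
categories) and a proportion-invariant class implemented as a rate-0
category of weight *p*inv (gamma rates are not rescaled by 1/(1−*p*inv),
following the common PhyML/RAxML convention). The rate matrix is scaled
to mean rate 1 so branch lengths are expected substitutions per site.
Branch optimisation caches up/down partial vectors so each Brent
evaluation costs O(patterns × 16); partials refresh once per sweep. The
ML search alternates branch sweeps with NNI until no improvement exceeds
1e−6 log-likelihood units. Likelihoods are checked against the two-taxon
JC69 closed form to 1e−10 and for invariance under re-rooting.

**Bootstrap** resamples columns of the (concatenated) matrix with
replacement, ignoring partition boundaries — the default behaviour of
mainstream tree software; per-partition resampling is available by
flag. Split frequencies are mapped onto the point-estimate tree as
percent supports. **Majority-rule consensus** keeps splits with
frequency > threshold (≥ 1.0 gives the strict consensus); topology
comparison reports shared and conflicting splits plus the
Robinson–Foulds distance, cross-checked against dendropy's
implementation in tests.

Bayesian inference is not implemented; every aggregate over "methods"
covers {NJ, MP, ML} and labels itself accordingly.

## Species resolution

"Species resolution" is rarely defined operationally in barcoding
papers; here it is fixed and printed in every report: a species with ≥ 2
sequences is resolved iff its group-versus-rest bipartition is in the
tree (a rooting-invariant monophyly test) *and* that split's support
meets the threshold (default 50%). Singletons cannot demonstrate
exclusivity and are excluded from the denominator by default
(`count_if_supported` is available because singleton-heavy sampling
makes any choice material — the flag keeps it auditable). "Average
branch support" averages only nodes at or above the threshold, i.e.
support among well-resolved clades. Cross-method aggregation reports
unweighted means with standard errors; a single-method SE is reported
as 0 with a note.

## Character-based barcoding

Only *pure, simple* CAs are implemented: a state present in 100% of
clade members with a determinate character at that column and absent
from all non-members. Private or compound (multi-column) diagnostics are
out of scope — single-nucleotide diagnostics are what published CA
tables report, and compound logic multiplies complexity without a
validation surface. Outside-group missing data do not violate absence
(permissive reading; a strict flag exists); gap states may be diagnostic
behind a flag since spacer diagnostics can be indel-borne. CA counts are
reported with the alignment length as denominator ("12/845"-style),
because the denominator depends on the trimmed region analysed.
Classification scores a query as matched/total CAs per clade; the unique
top scorer at or above 0.8 wins, anything else is unassigned.

## Inverted repeats

A sequence is aligned against its own reverse complement by local
dynamic programming with the classic EMBOSS `einverted` scoring (match
+3, mismatch −4, gap 12) at a score threshold of 40 — the threshold a
short (~300–400 nt) spacer fragment needs; all four numbers are
parameters. A 14-bp perfect stem scores exactly 42 (reported) and a
13-bp stem 39 (below threshold), which the tests pin down. Hits are
reported greedily by descending score, ties leftmost; reported regions
are masked and the scan repeats, so hits never overlap. Aligned input is
scanned ungapped with coordinates mapped back, and per-row hit
footprints can be projected into alignment columns for within- vs
between-clade Jaccard conservation summaries.

## In-silico PCR and identification

Primer matching expands IUPAC codes positionally on both strands with a
mismatch budget; amplicons are all convergent binding combinations
within a product-size cap, lengths inclusive of both primers. The six
published seagrass primer pairs ship bundled (rbcL P609/P610 with its
599-bp product; matK P607/P608 and P646/P647; rps16-trnQ; ITS;
trnH-psbA).

Identification deliberately does *not* reimplement BLAST statistics:
conclusions such workflows draw rest on identity, overlap and the
taxonomy of the top hits, so the package searches a *local* reference
library with scored local alignment (match +1, mismatch −1, open −2,
extend −0.5) and reads the rank level from the hits inside a 0.5-point
identity band of the best hit: one species at ≥ 99% identity → S, one
genus at ≥ 95 → G, one family at ≥ 90 → F, else O above the 80 floor,
else unassigned. These thresholds are configurable surrogates — the
level-coding rule behind published identification tables is not stated
anywhere — and are echoed in every result object.

## Simulator

The generator emulates a regional barcoding study of a small clade:

* **Taxonomy tree**: ultrametric and rank-structured — 4 families, 10
  genera, 15 species, 2 individuals each (30 tips) by default, with
  node heights (expected substitutions/site at the slow-locus rate)
  root 0.022 > family crown 0.012 > genus crown 0.005 > conspecific
  divergence 0.0015. These defaults were chosen so the slow locus stays
  mostly conserved, genera separate cleanly at the intermediate locus,
  and the fast spacer exceeds 20% inter-generic *p*-distance with
  intra-generic distances under 6% — without saturating. Controlled
  clade structure was preferred over birth–death realism because the
  resolution statistics need known monophyly.
* **Loci**: rate multipliers 1 : 3 : 8 encode the qualitative
  slow/intermediate/fast ordering of coding–coding–spacer locus trios;
  lengths default to 599, 845 and 400 nt. The spacer adds Poisson
  indels (rate 0.05 events/site per unit branch length, geometric
  lengths, mean 4) — because the simulator places every indel itself it
  emits the *true* alignment, so no multiple-sequence-alignment step
  exists anywhere in the pipeline, and alignment error is explicitly
  outside what these simulations test.
* **Planted features**: a 14-bp-stem inverted repeat written into one
  genus's spacer rows (contiguous in each row's ungapped sequence), and
  optionally diagnostic columns fixed inside a clade and set to a
  different state outside — both recorded in a truth registry for
  round-trip tests.
* Substitutions follow JC69 (or HKY85) transition probabilities per
  branch; everything is bit-for-bit reproducible from (config, seed).

Known simplifications: inserted segments in two sibling lineages can
occasionally be assigned the same alignment column (treated as
homologous when they are not); planted features overwrite evolved
states rather than evolving from the stem ancestor; no rate variation
across sites within a locus beyond the locus multiplier; no
hybridisation, heteroplasmy or demography. Passing tests therefore show
correctness of the statistics and searches on clean, truly-aligned
data, not robustness to alignment error or model misspecification.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default 30-tip design
with 100 NJ bootstrap replicates for seed-robust checks and 30
replicates per method for the full NJ/MP/ML sweep over all seven locus
combinations — sizes chosen so a complete evaluation stays in the
minutes range on one core while keeping bootstrap Monte-Carlo error on
supports near ±3 points. Brent branch optimisation is bounded to
[1e−8, 10] substitutions/site with xatol 1e−7; ML stops when no NNI or
branch move gains more than 1e−6 log-likelihood units; all searches
break ties toward the lowest index. Degenerate inputs (single-row
alignments, all-singleton species sets, empty inter-group distance
sets) raise typed errors or report `None` rather than fabricating a
number.
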