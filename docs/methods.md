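# Methods

This note documents the models, conventions and design choices behind
`taxamark`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sequence semantics

Sequences are strings over the 15 IUPAC nucleotide codes (plus `-` in
aligned alphabets); input is case-normalised and `.` is read as `-`. RNA
`U` is rejected rather than silently mapped to `T`, so RNA input fails
loudly. The degeneracy of a primer is the product over positions of each
code's base-set size; `N` contributes 4, `R/Y/S/W/K/M` contribute 2. The
complement table commutes with base-set complementation, which makes
reverse complement an involution on degenerate strings — both properties
are enforced by tests.

## Pairwise alignment and identity

All pairwise alignments are global with free end gaps. DNA scoring is
match +1 / mismatch −1 / gap open −5 / extend −1; proteins use BLOSUM62
with open −11 / extend −1. Three identity conventions coexist and are
deliberately kept distinct:

* **marker identity** (identity matrices, Table-style outputs):
  100 × identical pairs / columns where *neither* sequence has a gap. This
  approximates the percent identities common MSA tools report. Because an
  optimal alignment need not be unique, each pair is aligned in canonical
  (lexicographic) argument order so that identity(a,b) = identity(b,a)
  exactly.
* **clustering identity** (75% protein floor): matches / columns of the
  end-trimmed core region, internal gaps counting as mismatch, with a
  mutual-coverage floor (default 80% of both sequences inside the core).
  The coverage floor is our choice; the identity threshold alone would
  merge domain-sharing proteins of very different length.
* **presence identity** (90/90 locus calling): matches / representative
  residues in the core region; coverage is the fraction of the
  representative inside the core. Gaps in the member against representative
  residues count as mismatch.

Marker identity tracks true divergence closely up to roughly 45%
divergence; beyond that, free-end-gap alignments of near-random pairs
inflate identity (the aligner pushes disagreement into excluded gap
columns). The synthetic generator therefore keeps pairwise divergence
below that regime (see below).

## Pan-genome stage

Clustering is a deterministic greedy centroid pass: proteins sorted by
decreasing length (ties by genome and CDS id), each joining the first
cluster whose *founding* centroid it matches at the identity/coverage
floors, else founding a new cluster. If a genome would contribute a second
member, the member with the better centroid identity stays and the other
founds a paralog cluster. This reproduces the identity-threshold semantics
of graph-based pan-genome tools without external binaries, at the cost of
centroid-order dependence (mitigated by the canonical sort, which makes the
result independent of input order). Core loci are those present in every
genome. Alleles are assigned by exact string match among present members,
ids in first-occurrence order over lexicographically sorted genomes.
Candidate markers are core loci ranked by representative nucleotide length
("longest gene" reading of allele size; ranking by distinct-allele count is
available as an alternative key).

## Marker ranking

Discriminability statistics (min/mean/max) are computed over strictly
interspecific pairs; intraspecific pairs are excluded. Ranking is by
ascending mean interspecific identity, ties by ascending max, then locus
id. Mean was chosen as the primary key because min is noise-sensitive
(one aberrant pair) and max alone ignores typical separation; min and max
are always reported alongside.

## Primer design

Column consensus is the *union* IUPAC code over observed bases (any gap
makes the column unusable): a degenerate primer must anneal to every known
variant, so majority consensus would be wrong here. Conserved windows are
gap-free windows (default lengths 18–25) whose consensus degeneracy stays
under a cap (default 64, the degeneracy of the published group-level
primers). Group-level pairs take a forward window plus the reverse
complement of a downstream window, with the expected product measured on
the degapped reference record (first record unless named); for tractability
each forward window is paired with its single best admissible reverse
window (lowest degeneracy, then largest product) rather than ranking the
full quadratic cross-product.

Species-specific design computes the consensus over target-species rows
only (degeneracy cap default 8) and requires each primer to carry at least
2 mismatches against *every* non-target record, with at least one in the 3
terminal 3'-positions in the orientation it anneals (extension is most
sensitive to 3' mismatches). These thresholds are package defaults — the
underlying wet-lab design rules of interactive primer tools are not
published — and are configurable. Every returned pair is cross-validated
by the in-silico PCR engine on the same input: positive on all target
records, negative on all others. Melting temperatures use the Wallace rule
2(A+T)+4(G+C), reported as a [min, max] range over the least- and most-GC
expansions of degenerate codes; the rule is refused beyond 30 nt.

## In-silico PCR

A primer binds where every position is IUPAC-compatible (base-set
intersection non-empty), with zero mismatches allowed in the 3'-terminal
seed (default 3 positions) and a total mismatch budget (default 0). The
zero default is the strictest reproducible rule: the effective stringency
of a wet-lab annealing temperature cannot be known in silico, so
permissiveness is opt-in rather than baked in. Template ambiguity codes
match permissively by default (an `N` from sequencing matches anything); a
strict mode treats template `N` as mismatch. Products require the two
primers on opposite strands with 3' ends facing, include both primer
footprints (standard size convention), and are capped at 3 kb by default.
A specificity cell is "+" iff at least one product lies within ±20% of the
assay's expected size.

## Phylogeny and haplotypes

K2P distances use pairwise deletion (columns with a gap or ambiguity in
either sequence are dropped for that pair), preserving signal on partial
Sanger fragments; complete deletion is available since distance-software
defaults differ by configuration. Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0)
raises a named error rather than returning infinity.

Neighbour joining follows Saitou–Nei with the standard Q-criterion. Two
conventions are pinned to make reconstruction fully deterministic: ties in
Q break on the lexicographically smallest label pair (internal nodes carry
the smallest leaf label beneath them), and negative branch lengths are
clamped to zero with the deficit moved to the sister edge (preserving the
path length through the join). Trees are stored unrooted (trifurcating
traversal root); a two-leaf tree splits its single edge at the midpoint in
newick output. Bootstrap resamples columns with replacement, rebuilds
K2P+NJ per replicate, and scores each internal bipartition as the
percentage of successful replicates containing it; saturated replicates
are dropped, and more than 10% dropped is an error.

Haplotypes are exact-match equivalence classes after complete deletion of
columns holding a gap or ambiguity in *any* record (the convention of
standard haplotype software); a flag keeps such columns as extra states
instead. Ids follow first occurrence.

## Synthetic species groups

The generator emulates the toolkit's target situation: a recognised
bacterial species group genotyped at loci spanning the useful divergence
range (an rRNA-like locus near 1.6% interspecific divergence and a
protein-marker-like locus near 33%, i.e. identities ~98% vs ~67%).

Sequences evolve under the exact K2P continuous-time transition matrix
with transition/transversion ratio κ (default 2), rates normalised to one
expected substitution per site per unit time. A requested expected
p-distance is converted to a branch time by numerically inverting the
analytic p(t) curve, so composition along a tree is exact and the K2P
distance estimator recovers branch times without bias — parameter recovery
is a clean end-to-end test (the acceptance script measures ~0.5% relative
error at p = 0.10 over 50 seeds).

The species tree is a random coalescent-topology ultrametric tree whose
node heights are compressed into the deepest 30% of the tree depth. The
compression encodes two facts about named species groups: every pair of
species is clearly and comparably diverged (no near-zero species
distances), and no pair drifts into the >45% divergence regime where
alignment identity becomes unreliable. Branch lengths are then scaled so
the *mean* pairwise interspecific p-distance equals the locus target
(solved numerically); intraspecific divergence is applied as independent
star branches around each species sequence and is not included in the
calibration (defaults are ≤0.5%, a second-order effect). Loci are
generated as codon-multiple nucleotide sequences with protein
translations, so pan-genome stages consume the output directly.

A locus flagged for planted primer sites carries two 20-nt windows
conserved across all genomes (substrate for degenerate design) and, per
species, two distinct 20-nt windows 150 bp apart (pairwise Hamming
distance ≥ 8; substrate for species-specific design — a specific *pair*
needs two discriminating anneal sites). Coordinates are recorded in the
truth object so primer and specificity stages can be scored without
re-simulation.

The 17-species preset uses 500-nt loci at 33% and 1.6% interspecific
divergence with one strain per species. Locus length is a deliberate
scale-down from typical marker amplicons (~1 kb): it keeps the 100-seed
all-vs-all ranking experiment (2 × 136 alignments per seed) to a couple of
minutes on one CPU while leaving the identity contrast between the two
loci at >30 points, far above simulation noise.

What the generator does *not* model: indels (alignments of simulated data
are trivial), recombination, gene gain/loss dynamics, rate variation
across sites, and base-composition bias. Passing tests on synthetic data
therefore demonstrate correctness of the estimators and design rules under
the K2P model, not robustness to real-data alignment ambiguity or model
misspecification; the packaged published identity tables provide the
real-data anchor for the ranking statistics.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and 1-based inclusive in
reports. Random processes take explicit seeds (numpy `default_rng`);
identical seeds give byte-identical outputs. Identity matrices validate
symmetry (1e-9), diagonal 100, and range [0, 100] on construction.
Distance matrices validate symmetry, zero diagonal and non-negativity.
Degenerate expansion refuses above a cap (default 4096) to keep
enumeration honest. The published reference tables and primer set ship as
TSV package data under `taxamark/data/` and load through
`taxamark.datasets`.

## Known limitations

* Clustering is greedy and centroid-based; it does not split paralog
  clusters by tree structure, and very divergent domain architectures can
  chain under permissive thresholds.
* The Wallace Tm rule is a screening heuristic, not a thermodynamic model;
  no hairpin/dimer screening is performed.
* In-silico specificity at 0 mismatches is conservative relative to
  wet-lab PCR at moderate annealing temperatures; reproducing a published
  +/− pattern may require exploring the 0–1 mismatch settings.
* NJ is the only tree method; no likelihood or Bayesian inference.
* Identity values above ~55% divergence are reported but not meaningful
  (alignment degeneracy); the generator avoids that regime by design.
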