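# Methods

This note records the models, algorithms and design choices behind
`minihal`, with the defaults and the reasoning where the design was
genuinely open.

## Sequence QC and aliasing

"Non-IUPAC" is interpreted as anything outside the 20 standard residues
plus the ambiguity/extended codes B, Z, X, U, J, O. Input is uppercased
first; a single terminal `*` (a stop marker common in predicted proteomes)
is accepted and stripped, while an internal `*` fails the check — so
sequences with internal stops are rejected rather than truncated. For
duplicated headers the first occurrence is kept and later copies rejected
(deterministic, order-stable). Empty sequences get their own rejection
code. Aliases are `g<G>_p<N>` with both ordinals 1-based and zero-padded
to a fixed width so lexicographic and numeric order coincide; the alias map
is a bijection persisted as TSV.

## Similarity graph

The parser accepts the 12-column tabular dialect; rows above the e-value
cutoff (default 1e-1) and self-hits are dropped, and duplicate
(query, subject) rows collapse to the minimal-evalue row so the directed
graph is well defined. The e-value → weight transform is
w = min(−log₁₀E, 200), symmetrized by the maximum over both directions,
with E = 0 mapped to the cap. How the original toolchain converted
e-values into MCL input is not fully specified anywhere we could rely on;
this transform mirrors standard `mcxdeblast` practice, keeps weights
finite and positive, and is documented configuration rather than a claim
of parity. Best hits are indexed per (query, target genome), with ties
broken by lowest e-value, then highest bit score, then lexicographically
smallest subject alias — making the index independent of input row order.

## Markov clustering

MCL is implemented from scratch on scipy CSC matrices. Initialization adds
a self-loop per node equal to its maximum incident edge weight (1.0 for
isolated nodes) and normalizes columns. Each iteration expands (M ← M·M),
inflates (entrywise power, prune entries < 1e-8, renormalize columns) and
stops when the largest entry change falls below 1e-6 or after 200
iterations. Clusters are read from the limit matrix as attractor systems:
attractors are nodes with mass on their own diagonal, systems are
connected components of the attractor-induced subgraph, and every other
node joins the system of its strongest attractor (ties → lexicographically
smallest attractor alias). Pruning threshold, tolerance, iteration cap and
overlap resolution are unspecified by the original description (which
called the external MCL binary); the values above follow common MCL
practice. Parity with the MCL binary is at the level of cluster
composition on well-separated graphs, not bit-exact; correctness is
checked against a dense brute-force twin of the same update rules.

## Ortholog selection and filtering

Candidates must be single-copy (≤ 1 member per genome), have ≥ 2 members
(size-1 clusters cannot contribute to an alignment) and cover at least
`min_taxon_fraction` of the genomes. The sweep is filtered from the most
stringent (highest) inflation downwards; within one clustering, candidates
are processed by decreasing size and then by smallest member alias, a
content-based tie-break that makes the accepted set independent of
presentation order. A candidate is accepted iff it also passes best-hit
consistency and shares no protein with previously accepted clusters.

Best-hit consistency is evaluated per (member, genome) pair restricted to
genomes represented in the cluster: if the member has a best hit into that
genome, it must be a cluster member. The per-genome reading (rather than
a single overall best hit) follows the reciprocal-best-hit tradition and
stays meaningful when taxa are missing. A violation rejects the whole
cluster rather than trimming the offending member.

## Alignment and editing

The built-in aligner exists so the pipeline runs with no external
binaries: a neighbor-joining guide tree over 6-mer cosine distances,
then progressive profile–profile Needleman–Wunsch–Gotoh with BLOSUM62,
affine gaps (open 10, extend 0.5), mean-of-pairs column scoring, and
output rows in input order. It makes no claim of MUSCLE parity; adapters
emit command lines for MUSCLE (`-stable`), MAFFT, CLUSTALW and PROBCONS
for users who have them.

`remgaps` deletes every gap-containing column. The Gblocks-style trimmer
classifies a column as nonconserved iff it contains any gap or its most
frequent residue occurs fewer than floor(n/2)+1 times; maximal
nonconserved runs longer than the allowance are deleted; remaining blocks
are trimmed so they start and end on conserved columns; blocks shorter
than the minimum are dropped. Only the two quoted knobs per setting are
honored — conservative (4, 10) and liberal (8, 5); Gblocks' 85%
flank-position criterion is replaced by the block-end trimming, and
bit-exact Gblocks parity is a non-goal. Note that
|remgaps| ≤ |conservative| ≤ |liberal| is a tendency on realistic inputs,
not a theorem, and is not asserted.

## Supermatrix

Trim first, then normalize: alignments that pass the minimum-length filter
are keyed by organism (aliases exchanged for sanitized organism names,
alphanumeric + underscore for PHYLIP/Newick safety), absent genomes are
filled with `?`, and clusters are concatenated in lexicographic cluster-id
order (determinism; the original order is unspecified). Partition entries
are 1-based inclusive and must tile [1, L] exactly; the partition file uses
the RAxML protein dialect `MODEL, cluster = start-end`.

## Substitution models and likelihood

Five published empirical exchangeability sets (Dayhoff, JTT, WAG, LG,
RtREV) are stored as PAML-style lower-triangle text files with provenance
headers. Q is built as S·diag(π), scaled to one expected substitution per
unit time; P(t) comes from the symmetric eigendecomposition of
D^{1/2} Q D^{-1/2} (cached per model). Likelihood is Felsenstein pruning
over compressed site patterns with per-node rescaling; `?`, `-`, `X` and
other non-standard codes are fully ambiguous states. +F uses observed
alignment frequencies (pseudocount 0.05 to avoid zeros); +G averages over
four equal-probability discrete-gamma categories with category rates equal
to the mean of each quantile bin.

Model ranking is by AIC = 2k − 2 lnL with branch lengths held fixed on a
common NJ base tree across all 20 candidates (the "fast optimization"
analogue — only the gamma shape is optimized, by golden section on
[0.05, 50]); k counts 1 for +G and 19 for +F, 0 for a base empirical
model, branch lengths excluded because they are shared. +I variants and
AICc/BIC strategies are intentionally out of the default roster. Frequency
ties for the single most-frequent best model break to the
lexicographically smallest name.

## Distance trees

Pairwise distances maximize Σ log(π_a P_ab(t)) over shared unambiguous
columns (pairwise deletion — necessary for `?`-padded supermatrices), by
golden section on [1e-6, 10]; a pair with zero comparable columns is a
hard error naming the pair. NJ uses the Studier–Keppler Q criterion with
ties broken to the smallest index pair; negative branch lengths are
clamped to zero and the clamped total is recorded (zero on additive
inputs). The bootstrap resamples columns with replacement (seeded), runs
NJ per replicate, and summarizes with a majority-rule consensus containing
exactly the bipartitions in strictly more than 50% of replicates,
annotated with integer percentages ("strict majority rule" is read as
>50% majority-rule consensus, which is what a bootstrap summary requires).
Consensus branch lengths are means over the replicates containing the
split. An outgroup, when given, roots the tree on the outgroup's pendant
edge. The NJ distance analysis deliberately uses JTT with no rate
variation among sites regardless of the AIC results, matching the
pipeline's distance-analysis convention.

## Pipeline mechanics

Nine steps (qc, graph, sweep, filter, align, trim, concat, models, trees)
communicate only through files under the output directory, so each stage
is independently invocable and the full run equals the composition of the
stage commands. The manifest stores the config, the seed and a SHA-256
fingerprint per declared product; resume re-runs from the first step that
is not done or whose products changed, and re-running with a different
aligner invalidates the align step and everything downstream. All
randomness (only the bootstrap consumes any) derives from the config seed,
so interrupted-and-resumed runs are byte-identical to uninterrupted ones.
Local parallelism hooks exist at the cluster level; grid-engine submission
is out of scope.

## Synthetic fixture

The generator emulates the pipeline's input regime: per family an ancestor
drawn from JTT stationary frequencies is evolved by independent site
substitutions (rate 0.15 per unit depth by default) down a random
coalescent-shaped genome tree (recorded in the truth table);
lineage-restricted families occupy a genome subset; paralog-contaminated
families add recent (t = 0.05) within-genome duplicates in a fraction of
genomes, which keeps the duplicate tightly linked to its source so the
family fails the single-copy rule at every inflation. The hit table is
synthesized, not searched: within-family pairs get e-values from a
monotone identity map (100% identity → 1e-180; at the 20% baseline →
above the 1e-1 cutoff), cross-family pairs appear only under a
configurable contamination fraction. Defaults for the standard validation
fixture: 5 genomes, 20 single-copy families, 5 paralog-contaminated
families, 120-residue ancestors — large enough for every filter to act,
small enough to run everywhere.

What the generator does *not* emulate: indel evolution (alignments of
fixture data are therefore nearly gap-free and `remgaps` barely acts on
them — the trimming rules are instead exercised on random gapped
alignments), domain shuffling, compositional heterogeneity, and realistic
e-value statistics. Passing tests on fixtures demonstrate the pipeline's
logic and numerics, not alignment quality on real divergent proteomes.

## Problem sizes used in the checks

The validation suite runs MCL-oracle comparisons on ≤ 30-node graphs,
exhaustive-likelihood comparisons on 5-taxon, ≤ 30-column alignments,
model-recovery simulations at 500 columns × 10 replicates, NJ recovery on
20 random 8-taxon additive matrices, and full pipeline runs on 4–5-genome
fixtures with 10–25 families; these sizes make every check exact or
near-exhaustive while keeping the whole suite fast.

## Known limitations

- The Gblocks-style trimmer and built-in aligner are documented
  simplifications, not drop-in replacements for Gblocks/MUSCLE.
- Model ranks under the fixed-base-tree approximation can differ from
  ProtTest's on real data; +I is absent from the default roster.
- Maximum-likelihood and parsimony tree search are out of scope; adapters
  only emit RAxML/PhyML command lines.
- Heavy missing data can make a taxon pair share zero comparable columns,
  which aborts the distance analysis by design (the offending pair is
  named).
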