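# minihal

A self-contained phylogenomic pipeline: from unaligned predicted proteomes
(one FASTA file per genome) plus all-vs-all protein similarity results to
filtered single-copy ortholog clusters, edited alignments, concatenated
super alignments with partition/model metadata, and bootstrapped
neighbor-joining species trees.

## Who this is for

Building a multi-gene species tree from a set of sequenced genomes requires
a long chain of bookkeeping-heavy steps before any phylogenetics happens:
sanitizing heterogeneous FASTA headers, clustering an all-vs-all similarity
graph into putative ortholog groups, discarding groups contaminated by
paralogs or missing too many taxa, aligning and trimming each group, and
stitching everything into a partitioned supermatrix. `minihal` automates
that chain end to end and also ships a synthetic-proteome generator with
planted orthology, so the whole pipeline can be exercised and validated
without any external binaries or genome downloads.

## The method

1. **QC + aliasing.** Sequences with duplicated headers, non-IUPAC
   residues or empty bodies are removed; survivors get short unique aliases
   `g<G>_p<N>` with a persisted bijective map back to the original headers.
2. **Similarity graph.** 12-column tabular hits (BLAST `-outfmt 6`
   dialect, e-value cutoff 1e-1) become a weighted graph with
   w(u,v) = max over directions of min(−log₁₀E, 200), plus a per-genome
   best-hit index (lowest e-value, then highest bit score).
3. **Markov clustering.** A from-scratch sparse MCL (expansion →
   entrywise inflation → pruning, to convergence) is run across the
   inflation sweep 1.1, 1.2, 1.3, 1.4, 1.5, 1.7, 2.0, 2.5, 3.0, 3.5, 4.0,
   4.5, 5.0 — low inflation yields few large clusters, high inflation many
   small ones, accommodating slow- and fast-evolving genes.
4. **Ortholog filtering.** Only single-copy clusters (≤ 1 protein per
   genome) covering at least a configurable fraction of the taxa are kept;
   candidates are processed from the most stringent inflation down, must be
   best-hit consistent (no member's per-genome best hit may lie outside the
   cluster) and may not overlap anything already accepted.
5. **Alignment + editing.** Each cluster is aligned (built-in progressive
   aligner, or MUSCLE/MAFFT/CLUSTALW/PROBCONS adapters) and edited three
   ways: `remgaps` (drop every gap-containing column), Gblocks-style
   conservative (max 4 contiguous nonconserved positions, min block 10)
   and liberal (8 / 5).
6. **Supermatrices.** Alignments passing the minimum-length filter are
   normalized to the full taxon set (`?` for missing genomes) and
   concatenated into three super alignments with RAxML-dialect partition
   files.
7. **Model selection.** For each cluster alignment, five empirical
   amino-acid models (Dayhoff, JTT, WAG, LG, RtREV) × {+G, +F} variants are
   ranked by AIC = 2k − 2 lnL (Felsenstein pruning likelihood on a fixed NJ
   base tree); outputs include per-alignment best models, full ranked
   tables, a best-model frequency summary and per-partition assignments.
8. **Trees.** Pairwise ML distances under JTT (no rate variation), Saitou–
   Nei neighbor joining, column bootstrap, and a majority-rule (>50%)
   consensus with integer percentage supports — one tree per super
   alignment, optionally rooted on an outgroup.

## Worked example

```bash
python - <<'EOF'
from minihal import fixtures, pipeline

spec = fixtures.FixtureSpec(n_genomes=4, n_single_copy_families=8,
                            n_paralog_families=2, ancestor_length=100, seed=7)
fixtures.write_fixture(spec, "example/in")
cfg = pipeline.RunConfig(input_dir="example/in", output_dir="example/out",
                         bootstrap_replicates=20, min_alignment_length=30, seed=3)
pipeline.run(cfg)
print(open("example/out/trees/remgaps.nwk").read())
EOF
```

prints the bootstrapped NJ consensus for the remgaps supermatrix, e.g.

```
(genome01:0.056082,genome02:0.063074,(genome03:0.005538,genome04:0.019892)100:1.027435);
```

— the two most recently diverged simulated genomes (genome03, genome04)
are grouped with 100% bootstrap support, and branch lengths are expected
substitutions per site. `example/out/` also contains the QC report and
alias map, the accepted cluster table with its rejection log, per-cluster
alignments in all three edits, three supermatrices with partition files,
AIC model-selection tables, and a manifest that lets `minihal resume`
restart an interrupted run at the first uncompleted step.

The same run is available from the shell:

```bash
minihal run --input-dir example/in --output-dir example/out --seed 3
minihal resume example/out          # no-op if the run completed
```

and every stage (`qc`, `graph`, `cluster`, `filter`, `align`, `trim`,
`concat`, `models`, `tree`) is an individual subcommand over the same
files.

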