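"""Synthetic multi-genome proteomes with planted orthology structure.

Every pipeline stage is testable without external binaries or downloads:
this module simulates proteomes for ``n_genomes`` genomes containing

* *single-copy* families — one ortholog per genome in every genome;
* *lineage-restricted* families — present only in a random subset of
  genomes (a chosen coverage fraction), emulating gene loss / annotation
  gaps;
* *paralog-contaminated* families — single-copy families in which some
  genomes carry a recent within-genome duplicate, which must keep the
  family out of the accepted single-copy set.

Per family an ancestor sequence is drawn from JTT stationary frequencies
and evolved by independent site substitutions (no indels) down a random
coalescent-shaped genome tree; the tree is recorded in the truth table so
tree-recovery tests can compare against it.  An all-vs-all hit table in the
12-column tabular dialect is synthesized from pairwise identities through a
monotone identity→e-value map (identical pair → the 1e-180 floor; pairs at
the unrelated baseline fall above the 1e-1 cutoff), which is the only
property graph construction consumes.  Real e-value statistics are not
emulated.  Generation is a pure function of the spec (seeded).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import seqio
from .models import AA_ORDER, load_model
from .njtree import Node, PhyloTree
from .seqio import ProteomeSet, SequenceRecord

EVALUE_FLOOR_EXP = 180.0   # identity 100% -> 1e-180
IDENTITY_BASELINE = 20.0   # identity at/below this maps above the cutoff


@dataclasses.dataclass
class FixtureSpec:
    n_genomes: int = 5
    n_single_copy_families: int = 20
    lineage_restricted_coverages: tuple[float, ...] = ()
    n_paralog_families: int = 5
    paralog_genome_fraction: float = 0.4  # fraction of genomes carrying a duplicate
    ancestor_length: int = 120
    branch_rate: float = 0.15  # expected substitutions/site per tree depth unit
    contamination: float = 0.0  # fraction of cross-family pairs given sub-cutoff hits
    n_corrupt: int = 0          # planted QC-failing entries per fixture
    seed: int = 0


@dataclasses.dataclass
class TruthTable:
    families: dict[str, frozenset[str]]           # family_id -> member aliases
    family_class: dict[str, str]                  # single_copy | lineage_restricted | paralogous
    coverage: dict[str, float]
    genome_tree: PhyloTree
    corrupt_headers: list[tuple[str, str, str]]   # genome_id, header, reason


def _random_coalescent(genomes: list[str], rng: np.random.Generator) -> PhyloTree:
    nodes = [Node(name=g, length=0.0) for g in genomes]
    heights = {id(n): 0.0 for n in nodes}
    k = len(nodes)
    h = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - heights[id(a)]
        b.length = h - heights[id(b)]
        parent = Node(children=[a, b], length=0.0)
        heights[id(parent)] = h
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [parent]
    return PhyloTree(nodes[0], rooted=True)


def _evolve(seq: np.ndarray, t: float, model, rng: np.random.Generator) -> np.ndarray:
    p = model.transition_matrix(t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(seq.shape[0])
    return np.array([np.searchsorted(cum[s], x) for s, x in zip(seq, u)], dtype=np.int8)


def _evolve_down_tree(
    root_seq: np.ndarray, tree: PhyloTree, rate: float, model, rng
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        child_seq = _evolve(seq, (node.length or 0.0) * rate, model, rng)
        if not node.children:
            out[node.name] = child_seq
        else:
            for c in node.children:
                walk(c, child_seq)

    walk(tree.root, root_seq)
    return out


def generate_proteomes(spec: FixtureSpec) -> tuple[ProteomeSet, TruthTable]:
    """Simulate the proteomes and truth table in memory."""
    rng = np.random.default_rng(spec.seed)
    model = load_model("JTT")
    genomes = [f"genome{i + 1:02d}" for i in range(spec.n_genomes)]
    tree = _random_coalescent(genomes, rng)
    aa = np.array(list(AA_ORDER))

    # family plan: (family_id, class, genome -> n_copies)
    plan: list[tuple[str, str, dict[str, int]]] = []
    fid = 0
    for _ in range(spec.n_single_copy_families):
        plan.append((f"fam{fid:03d}", "single_copy", {g: 1 for g in genomes}))
        fid += 1
    for cov in spec.lineage_restricted_coverages:
        k = max(2, int(round(cov * spec.n_genomes)))
        present = sorted(rng.choice(spec.n_genomes, size=k, replace=False))
        plan.append(
            (f"fam{fid:03d}", "lineage_restricted", {genomes[i]: 1 for i in present})
        )
        fid += 1
    for _ in range(spec.n_paralog_families):
        ndup = max(1, int(round(spec.paralog_genome_fraction * spec.n_genomes)))
        dup = set(rng.choice(spec.n_genomes, size=ndup, replace=False))
        plan.append(
            (f"fam{fid:03d}", "paralogous",
             {g: (2 if i in dup else 1) for i, g in enumerate(genomes)})
        )
        fid += 1

    per_genome: dict[str, list[tuple[str, np.ndarray]]] = {g: [] for g in genomes}
    fam_members_headers: dict[str, list[tuple[str, str]]] = {}
    for fam_id, fclass, copies in plan:
        anc = rng.choice(20, size=spec.ancestor_length, p=model.frequencies).astype(np.int8)
        tips = _evolve_down_tree(anc, tree, spec.branch_rate, model, rng)
        members: list[tuple[str, str]] = []
        for g in genomes:
            for c in range(copies.get(g, 0)):
                seq = tips[g]
                if c > 0:  # recent duplicate: slight extra divergence
                    seq = _evolve(seq, 0.05, model, rng)
                header = f"{fam_id}|{g}|copy{c + 1} hypothetical protein"
                per_genome[g].append((header, seq))
                members.append((g, header))
        fam_members_headers[fam_id] = members

    # materialize records; aliases via the standard mapping
    records = {
        g: [
            SequenceRecord(h, "", g, "".join(aa[s]))
            for h, s in per_genome[g]
        ]
        for g in genomes
    }
    pset = seqio.build_alias_map(
        ProteomeSet(genomes, records, {}, [])
    )
    h2a = pset.header_to_alias()

    families = {
        fam_id: frozenset(h2a[h] for _, h in members)
        for fam_id, members in fam_members_headers.items()
    }
    fclass = {fam_id: c for fam_id, c, _ in plan}
    coverage = {
        fam_id: len({g for g, _ in fam_members_headers[fam_id]}) / spec.n_genomes
        for fam_id in families
    }
    corrupt: list[tuple[str, str, str]] = []
    if spec.n_corrupt:
        kinds = ["duplicate_header", "non_iupac_characters", "empty_sequence"]
        for i in range(spec.n_corrupt):
            g = genomes[i % len(genomes)]
            kind = kinds[i % 3]
            if kind == "duplicate_header":
                corrupt.append((g, records[g][0].original_header, kind))
            elif kind == "non_iupac_characters":
                corrupt.append((g, f"corrupt{i} bad residues", kind))
            else:
                corrupt.append((g, f"corrupt{i} empty", kind))
    truth = TruthTable(families, fclass, coverage, tree, corrupt)
    return pset, truth


def _identity(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    n = min(arr_a.size, arr_b.size)
    return 100.0 * float(np.mean(arr_a[:n] == arr_b[:n]))


def identity_to_evalue(pid: float) -> float:
    """Monotone decreasing identity -> e-value map used by the fixture."""
    expo = (pid - IDENTITY_BASELINE) / (100.0 - IDENTITY_BASELINE) * EVALUE_FLOOR_EXP
    return 10.0 ** (-min(max(expo, -2.0), EVALUE_FLOOR_EXP))


def synth_hit_table(
    pset: ProteomeSet, truth: TruthTable, spec: FixtureSpec, path: str | Path
) -> dict[str, int]:
    """Write the all-vs-all 12-column hit table; returns bookkeeping counts.

    Within-family pairs get e-values from the identity map (both directions
    plus self-hits); cross-family pairs appear only for the configured
    contamination fraction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_alias = pset.by_alias()
    lines: list[tuple[str, str, float, int, float, float]] = []
    surviving = 0

    def add_pair(a: str, b: str, evalue: float, pid: float) -> None:
        nonlocal surviving
        length = len(by_alias[a].residues)
        bits = max(20.0, pid * length / 50.0)
        lines.append((a, b, pid, length, evalue, bits))
        if a != b and evalue <= 0.1:
            surviving += 1

    fam_list = sorted(truth.families)
    for fam in fam_list:
        members = sorted(truth.families[fam])
        for a in members:
            add_pair(a, a, identity_to_evalue(100.0), 100.0)  # self-hit (parser drops)
            for b in members:
                if b <= a:
                    continue
                pid = _identity(by_alias[a].residues, by_alias[b].residues)
                ev = identity_to_evalue(pid)
                add_pair(a, b, ev, pid)
                add_pair(b, a, ev, pid)
    if spec.contamination > 0:
        aliases = sorted(by_alias)
        fam_of = {a: f for f, mem in truth.families.items() for a in mem}
        n_extra = int(spec.contamination * len(aliases))
        for _ in range(n_extra):
            a, b = rng.choice(len(aliases), size=2, replace=False)
            a, b = aliases[a], aliases[b]
            if fam_of[a] != fam_of[b]:
                add_pair(a, b, 1e-5, 30.0)
                add_pair(b, a, 1e-5, 30.0)

    with open(path, "w") as fh:
        for q, s, pid, length, ev, bits in lines:
            fh.write(
                f"{q}\t{s}\t{pid:.2f}\t{length}\t0\t0\t1\t{length}\t1\t{length}\t"
                f"{ev:.3g}\t{bits:.1f}\n"
            )
    return {"rows_written": len(lines), "surviving_after_filter": surviving}


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write per-genome FASTA files (with planted corrupt entries), the hit
    table and the truth table; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pset, truth = generate_proteomes(spec)
    paths: dict[str, Path] = {}
    corrupt_by_genome: dict[str, list[tuple[str, str]]] = {}
    for g, h, kind in truth.corrupt_headers:
        corrupt_by_genome.setdefault(g, []).append((h, kind))
    for g in pset.genomes:
        p = outdir / f"{g}.fasta"
        with open(p, "w") as fh:
            for rec in pset.records[g]:
                fh.write(f">{rec.original_header}\n{rec.residues}\n")
            for h, kind in corrupt_by_genome.get(g, []):
                if kind == "duplicate_header":
                    fh.write(f">{h}\nMKVLRANDMDUP\n")
                elif kind == "non_iupac_characters":
                    fh.write(f">{h}\nMKV9LE#\n")
                else:
                    fh.write(f">{h}\n\n")
        paths[g] = p
    hits = outdir / "allvsall.tsv"
    synth_hit_table(pset, truth, spec, hits)
    paths["hits"] = hits
    ttab = outdir / "truth.tsv"
    with open(ttab, "w") as fh:
        fh.write("family_id\tclass\tcoverage\tmembers\n")
        for fam in sorted(truth.families):
            fh.write(
                f"{fam}\t{truth.family_class[fam]}\t{truth.coverage[fam]:.3f}\t"
                f"{','.join(sorted(truth.families[fam]))}\n"
            )
        fh.write(f"#genome_tree\t{truth.genome_tree.newick()}\n")
    paths["truth"] = ttab
    return paths
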