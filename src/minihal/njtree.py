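"""Distance phylogenetics: ML distances, neighbor joining, bootstrap consensus.

The distance endpoint of the pipeline: pairwise maximum-likelihood distances
under an amino-acid substitution model (JTT by default, no rate variation
among sites), Saitou-Nei neighbor joining with the Studier-Keppler Q
criterion, non-parametric bootstrap over alignment columns, and a
majority-rule (>50%) consensus tree with integer percentage supports,
optionally rooted on an outgroup's pendant edge.

Trees are plain parent/child node structures serializable to Newick
(branch lengths at 6 decimals, supports as internal node labels).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .models import AA_ORDER, SubstitutionModel, _AA_INDEX, _golden_section_max


class MissingDistanceError(ValueError):
    """A pair of sequences shares no comparable column."""


@dataclasses.dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = dataclasses.field(default_factory=list)

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclasses.dataclass
class PhyloTree:
    root: Node
    rooted: bool = False
    clamped_negative_total: float = 0.0

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self) -> str:
        return _to_newick(self.root) + ";"


@dataclasses.dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal


# ---------------------------------------------------------------------------
# Newick serialization

def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.6f}"


def _to_newick(node: Node) -> str:
    if not node.children:
        return f"{node.name}{_fmt_len(node.length)}"
    inner = ",".join(_to_newick(c) for c in node.children)
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}{_fmt_len(node.length)}"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (supports as internal labels)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            assert s[pos] == ")", f"expected ')' at {pos}"
            pos += 1
            label = _read_token()
            if label:
                if node.children:
                    node.support = int(float(label))
                else:
                    node.name = label
        else:
            node.name = _read_token()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = float(_read_token())
        return node

    def _read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    root = parse_node()
    return PhyloTree(root, rooted=len(root.children) == 2)


# ---------------------------------------------------------------------------
# ML distances

def _pair_counts(row_i: str, row_j: str) -> np.ndarray:
    a = np.array([_AA_INDEX.get(c, 20) for c in row_i], dtype=np.int8)
    b = np.array([_AA_INDEX.get(c, 20) for c in row_j], dtype=np.int8)
    ok = (a < 20) & (b < 20)
    counts = np.zeros((20, 20))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


def ml_distance(
    row_i: str,
    row_j: str,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Pairwise ML distance: t maximizing sum log(pi_a P_ab(t)) over shared
    columns (pairwise deletion of ambiguous/missing positions)."""
    counts = _pair_counts(row_i, row_j)
    if counts.sum() == 0:
        raise MissingDistanceError("no comparable columns between sequence pair")
    logpi = np.log(model.frequencies)

    def f(t: float) -> float:
        p = np.maximum(model.transition_matrix(t), 1e-300)
        return float(np.sum(counts * (logpi[:, None] + np.log(p))))

    # identical (or near-identical) pairs: maximum sits at the lower bound
    if f(bounds[0]) >= f(bounds[0] * 2):
        return bounds[0]
    t, _ = _golden_section_max(f, bounds[0], bounds[1], tol=1e-6)
    return t


def distance_matrix(rows: dict[str, str], model: SubstitutionModel) -> DistanceMatrix:
    taxa = list(rows)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = ml_distance(rows[taxa[i]], rows[taxa[j]], model)
            except MissingDistanceError as exc:
                raise MissingDistanceError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                ) from exc
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with the Studier-Keppler criterion.

    Ties in Q break to the smallest (i, j) index pair; negative branch
    lengths are clamped to zero and the clamped total recorded on the tree.
    Unrooted: the root node is the final 3-way (or 2-way for n=3 joins)
    junction.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [Node(name=t) for t in dm.taxa]
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, m, m)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0]:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        parent = Node()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final 3-point join
    i, j, k = active
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root, rooted=False, clamped_negative_total=clamped)


# ---------------------------------------------------------------------------
# bipartitions and consensus

def bipartitions(tree: PhyloTree, ref: str | None = None) -> dict[frozenset, float | None]:
    """Non-trivial splits as the leaf set on the side NOT containing ``ref``
    (default: first leaf), mapped to the subtending branch length."""
    taxa = frozenset(tree.leaf_names())
    if ref is None:
        ref = min(taxa)
    out: dict[frozenset, float | None] = {}

    def below(node: Node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        got = frozenset().union(*(below(c) for c in node.children))
        return got

    def visit(node: Node, is_root: bool) -> None:
        for c in node.children:
            if c.children:
                side = below(c)
                if 1 < len(side) < len(taxa) - 1:
                    key = side if ref not in side else taxa - side
                    out[key] = c.length
            visit(c, False)

    visit(tree.root, True)
    return out


def majority_consensus(
    trees: list[PhyloTree], outgroup: str | None = None
) -> PhyloTree:
    """Majority-rule (>50%) consensus with integer percentage supports.

    Splits are canonicalized relative to the outgroup (or the alphabetically
    first taxon), so every kept clade excludes it; compatible majority
    clades nest, and the tree is assembled by containment.  Clade branch
    lengths are averaged over the replicates containing the clade; leaf
    branch lengths over all replicates.
    """
    if not trees:
        raise ValueError("no trees to summarize")
    taxa = sorted(trees[0].leaf_names())
    ref = outgroup if outgroup is not None else taxa[0]
    if ref not in taxa:
        raise KeyError(f"outgroup {ref!r} is not a taxon of the trees")
    nrep = len(trees)
    count: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    leaf_lengths: dict[str, list[float]] = {t: [] for t in taxa}
    for t in trees:
        for split, ln in bipartitions(t, ref=ref).items():
            count[split] = count.get(split, 0) + 1
            if ln is not None:
                lengths.setdefault(split, []).append(ln)
        for leaf in t.root.leaves():
            if leaf.length is not None:
                leaf_lengths[leaf.name].append(leaf.length)

    kept = [s for s, c in count.items() if c * 2 > nrep]
    kept.sort(key=lambda s: (len(s), sorted(s)))  # small clades first

    leaf_nodes = {
        t: Node(name=t, length=(float(np.mean(leaf_lengths[t])) if leaf_lengths[t] else None))
        for t in taxa
    }
    # containment forest: attach each clade over its current top-level nodes
    top: dict[frozenset, Node] = {frozenset([t]): leaf_nodes[t] for t in taxa}
    for clade in kept:
        inside = {k: v for k, v in top.items() if k <= clade}
        node = Node(
            support=round(100.0 * count[clade] / nrep),
            length=(float(np.mean(lengths[clade])) if lengths.get(clade) else None),
            children=[inside[k] for k in sorted(inside, key=lambda k: sorted(k))],
        )
        for k in inside:
            del top[k]
        top[clade] = node
    root = Node(children=[top[k] for k in sorted(top, key=lambda k: sorted(k))])
    tree = PhyloTree(root, rooted=False)
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the outgroup's pendant edge (the outgroup must be attached at
    the top level, as guaranteed by consensus canonicalization)."""
    children = tree.root.children
    og = [c for c in children if not c.children and c.name == outgroup]
    if not og:
        raise KeyError(f"outgroup {outgroup!r} not at the root level")
    og_node = og[0]
    rest = [c for c in children if c is not og_node]
    half = (og_node.length or 0.0) / 2.0
    og_node.length = half
    if len(rest) == 1:
        ingroup = rest[0]
        ingroup.length = (ingroup.length or 0.0) + half
    else:
        ingroup = Node(children=rest, length=half)
    root = Node(children=[og_node, ingroup])
    return PhyloTree(root, rooted=True, clamped_negative_total=tree.clamped_negative_total)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_consensus(
    rows: dict[str, str],
    model: SubstitutionModel,
    replicates: int,
    seed: int,
    outgroup: str | None = None,
) -> PhyloTree:
    """Column bootstrap + NJ per replicate + majority-rule consensus."""
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    taxa = list(rows)
    if outgroup is not None and outgroup not in taxa:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    ncol = len(next(iter(rows.values())))
    arrs = {t: np.frombuffer(rows[t].encode(), dtype="S1") for t in taxa}
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        sampled = {t: arrs[t][idx].tobytes().decode() for t in taxa}
        trees.append(neighbor_joining(distance_matrix(sampled, model)))
    return majority_consensus(trees, outgroup=outgroup)
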