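"""Independent brute-force oracles used by the test suite.

Everything here is deliberately simple and slow, and shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from minihal.models import AA_ORDER

# ---------------------------------------------------------------------------
# dense MCL twin


def dense_mcl(
    weights: dict[tuple[str, str], float],
    nodes: list[str],
    inflation: float,
    prune_threshold: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[frozenset]:
    """Dense NumPy implementation of the same expansion/inflation/pruning
    update rules, with its own attractor-basin interpretation."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for (u, v), w in weights.items():
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m = m / m.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        new = m @ m
        new = np.power(new, inflation)
        new[new < prune_threshold] = 0.0
        s = new.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        new = new / s
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new

    eps = prune_threshold
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:
        attractors = list(range(n))
    comp = {a: a for a in attractors}

    def root(a: int) -> int:
        while comp[a] != a:
            comp[a] = comp[comp[a]]
            a = comp[a]
        return a

    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > eps or m[b, a] > eps):
                ra, rb = root(a), root(b)
                if ra != rb:
                    comp[rb] = ra
    groups: dict[int, set] = {}
    for i in range(n):
        if i in comp:
            groups.setdefault(root(i), set()).add(nodes[i])
        else:
            cands = [(-(m[a, i]), nodes[a], a) for a in attractors if m[a, i] > eps]
            if cands:
                _, _, a = min(cands)
                groups.setdefault(root(a), set()).add(nodes[i])
            else:
                groups.setdefault(i, set()).add(nodes[i])
    return sorted((frozenset(g) for g in groups.values()), key=min)


# ---------------------------------------------------------------------------
# exhaustive likelihood oracle


def exhaustive_log_likelihood(rows: dict[str, str], tree, model) -> float:
    """Sum over all 20^(n internal nodes) ancestral state assignments."""
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    root = getattr(tree, "root", tree)
    internals: list = []
    edges: list[tuple[int, int | None, float, str | None]] = []

    def collect(node, parent_pos):
        if node.children:
            pos = len(internals)
            internals.append(node)
            if parent_pos is not None:
                edges.append((parent_pos, pos, node.length or 0.0, None))
            for c in node.children:
                collect(c, pos)
        else:
            edges.append((parent_pos, None, node.length or 0.0, node.name))

    collect(root, None)
    pmats = {}
    for _, _, t, _ in edges:
        if t not in pmats:
            pmats[t] = model.transition_matrix(t)
    pi = model.frequencies
    ncol = len(next(iter(rows.values())))
    codes = {name: [aa_index.get(c, -1) for c in s] for name, s in rows.items()}
    total = 0.0
    for col in range(ncol):
        colsum = 0.0
        for assign in itertools.product(range(20), repeat=len(internals)):
            p = pi[assign[0]]
            for parent_pos, child_pos, t, leaf in edges:
                a = assign[parent_pos]
                if leaf is None:
                    p *= pmats[t][a, assign[child_pos]]
                else:
                    b = codes[leaf][col]
                    p *= 1.0 if b < 0 else pmats[t][a, b]
            colsum += p
        total += np.log(colsum)
    return float(total)


# ---------------------------------------------------------------------------
# pairwise affine-gap alignment score oracle


def pairwise_affine_score(
    a: str, b: str, score, gap_open: float, gap_extend: float
) -> float:
    """Best affine-gap global alignment score (plain-loop Gotoh)."""
    na, nb = len(a), len(b)
    NEG = -1e18
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)
    Y = np.full((na + 1, nb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, nb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + score(
                a[i - 1], b[j - 1]
            )
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return float(max(M[na, nb], X[na, nb], Y[na, nb]))


# ---------------------------------------------------------------------------
# random additive distance matrices with known topology


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary unrooted topology with branch lengths in [0.1, 1].

    Returns (taxa, exact path-distance matrix, set of non-trivial splits
    canonicalized to exclude the first taxon).
    """

    class N:
        __slots__ = ("children", "length", "name")

        def __init__(self, name=None, length=0.0):
            self.children = []
            self.length = length
            self.name = name

    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [N(t, float(rng.uniform(0.1, 1.0))) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = N(length=float(rng.uniform(0.1, 1.0)))
        p.children = [nodes[i], nodes[j]]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = N(length=0.0)
    root.children = nodes

    leaf_edges: dict[str, list[tuple[int, float]]] = {}

    def collect(node, acc):
        acc = acc + [(id(node), node.length)]
        if not node.children:
            leaf_edges[node.name] = acc
        else:
            for c in node.children:
                collect(c, acc)

    for c in root.children:
        collect(c, [])

    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(taxa):
        ea = dict(leaf_edges[a])
        for j in range(i + 1, n_taxa):
            eb = dict(leaf_edges[taxa[j]])
            shared = set(ea) & set(eb)
            dist = (
                sum(ea.values())
                + sum(eb.values())
                - 2 * sum(ea[e] for e in shared)
            )
            d[i, j] = d[j, i] = dist

    splits: set[frozenset] = set()
    allset = frozenset(taxa)

    def below(node):
        if not node.children:
            return frozenset([node.name])
        s = frozenset().union(*(below(c) for c in node.children))
        if 1 < len(s) < n_taxa - 1:
            splits.add(s if taxa[0] not in s else allset - s)
        return s

    below(root)
    return taxa, d, splits


# ---------------------------------------------------------------------------
# simulation of alignments under a model on a fixed tree


def simulate_alignment(tree, model, ncol: int, rng: np.random.Generator) -> dict[str, str]:
    """Independent-site simulation under the model's CTMC down the tree."""
    aa = np.array(list(AA_ORDER))
    root = getattr(tree, "root", tree)
    out: dict[str, str] = {}

    def sample_child(seq_codes, t):
        p = model.transition_matrix(t)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(seq_codes))
        return np.array(
            [np.searchsorted(cum[s], x) for s, x in zip(seq_codes, u)], dtype=int
        )

    root_seq = rng.choice(20, size=ncol, p=model.frequencies)

    def walk(node, seq):
        child = sample_child(seq, node.length or 0.0)
        if not node.children:
            out[node.name] = "".join(aa[child])
        else:
            for c in node.children:
                walk(c, child)

    for c in root.children:
        walk(c, root_seq)
    return out
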