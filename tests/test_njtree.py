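"""ML distances, neighbor joining, Newick round trips, consensus semantics."""

import numpy as np
import pytest

from _oracles import random_additive_tree, simulate_alignment
from minihal import njtree
from minihal.models import load_model
from minihal.njtree import (
    DistanceMatrix,
    MissingDistanceError,
    Node,
    PhyloTree,
    bipartitions,
    bootstrap_consensus,
    majority_consensus,
    ml_distance,
    neighbor_joining,
    parse_newick,
)


@pytest.fixture(scope="module")
def jtt():
    return load_model("JTT")


# ---------------------------------------------------------------------------
# distances

def test_identical_sequences_near_zero_distance(jtt):
    s = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT" * 2
    assert ml_distance(s, s, jtt) <= 1e-4


def test_distance_symmetric_and_missing_error(jtt):
    a = "MKVLWAALLVTFLAGCQAKV"
    b = "MLVLWAELLVSFLAGCQARV"
    assert ml_distance(a, b, jtt) == pytest.approx(ml_distance(b, a, jtt))
    with pytest.raises(MissingDistanceError):
        ml_distance("??--", "MK??"[::-1], jtt)


def test_distance_estimates_simulated_divergence(jtt, rng):
    t_true = 0.5
    tree = PhyloTree(Node(children=[
        Node(name="a", length=t_true / 2), Node(name="b", length=t_true / 2)
    ]))
    errs = []
    for _ in range(5):
        rows = simulate_alignment(tree, jtt, 1000, rng)
        errs.append(abs(ml_distance(rows["a"], rows["b"], jtt) - t_true))
    assert np.median(errs) < 0.1


# ---------------------------------------------------------------------------
# neighbor joining

def test_quartet_additive_recovery_exact():
    # tree ((A:1,B:1):2,(C:1,D:1)): d(A,B)=2, d(C,D)=2, cross = 4
    taxa = ["A", "B", "C", "D"]
    d = np.array([
        [0, 2, 4, 4],
        [2, 0, 4, 4],
        [4, 4, 0, 2],
        [4, 4, 2, 0],
    ], dtype=float)
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    splits = bipartitions(tree)
    assert frozenset({"C", "D"}) in splits
    assert splits[frozenset({"C", "D"})] == pytest.approx(2.0)
    assert tree.clamped_negative_total == 0.0


def test_three_taxon_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(["x", "y", "z"], d))
    lengths = {l.name: l.length for l in tree.root.leaves()}
    assert lengths == {"x": pytest.approx(1.0), "y": pytest.approx(2.0),
                       "z": pytest.approx(3.0)}
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_random_additive_topologies_recovered(rng):
    for _ in range(8):
        taxa, d, true_splits = random_additive_tree(8, rng)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        got = set(bipartitions(tree))
        assert got == true_splits
        assert tree.clamped_negative_total == pytest.approx(0.0, abs=1e-9)
        # unrooted fully resolved: 2n-3 edges
        n_edges = sum(1 for node in tree.root.walk() if node is not tree.root)
        assert n_edges == 2 * 8 - 3


def test_nj_agrees_with_external_reference(rng):
    """Cross-check topology against an independent NJ (scikit-bio)."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    taxa, d, _ = random_additive_tree(7, rng)
    ours = set(bipartitions(neighbor_joining(DistanceMatrix(taxa, d))))
    ref_tree = skbio_nj(SkbioDM(d, ids=taxa))
    ref = set(bipartitions(parse_newick(str(ref_tree)), ref=taxa[0]))
    assert ours == ref


# ---------------------------------------------------------------------------
# newick

def test_newick_round_trip():
    nwk = "(A:0.100000,(B:0.200000,C:0.300000)85:0.050000,D:0.400000);"
    tree = parse_newick(nwk)
    assert tree.newick() == nwk
    inner = tree.root.children[1]
    assert inner.support == 85 and inner.length == pytest.approx(0.05)


# ---------------------------------------------------------------------------
# consensus

def _quartet(topology):
    """Quartet tree from a nested-pair spec like (('A','B'),('C','D'))."""
    (a, b), (c, d) = topology
    return PhyloTree(Node(children=[
        Node(name=a, length=1.0),
        Node(name=b, length=1.0),
        Node(children=[Node(name=c, length=1.0), Node(name=d, length=1.0)],
             length=1.0),
    ]))


def test_unanimous_replicates_give_full_support():
    trees = [_quartet((("A", "B"), ("C", "D"))) for _ in range(10)]
    cons = majority_consensus(trees)
    splits = {
        frozenset(l.name for l in n.leaves()): n.support
        for n in cons.root.walk()
        if n.children and n is not cons.root
    }
    assert splits == {frozenset({"C", "D"}): 100}


def test_even_split_yields_no_conflicting_bipartition():
    trees = [_quartet((("A", "B"), ("C", "D"))) for _ in range(5)]
    trees += [_quartet((("A", "C"), ("B", "D"))) for _ in range(5)]
    cons = majority_consensus(trees)
    internal = [n for n in cons.root.walk() if n.children and n is not cons.root]
    assert internal == []  # strictly-greater-than-50% rule


def test_supports_in_majority_range():
    trees = [_quartet((("A", "B"), ("C", "D"))) for _ in range(6)]
    trees += [_quartet((("A", "C"), ("B", "D"))) for _ in range(4)]
    cons = majority_consensus(trees)
    supports = [n.support for n in cons.root.walk() if n.support is not None]
    assert supports == [60]


def test_bootstrap_deterministic_and_rooted(jtt, rng):
    tree5 = PhyloTree(Node(children=[
        Node(children=[Node(name="a", length=0.1), Node(name="b", length=0.1)],
             length=0.3),
        Node(children=[Node(name="c", length=0.1), Node(name="d", length=0.1)],
             length=0.3),
        Node(name="e", length=0.6),
    ]))
    rows = simulate_alignment(tree5, jtt, 300, rng)
    t1 = bootstrap_consensus(rows, jtt, replicates=10, seed=77)
    t2 = bootstrap_consensus(rows, jtt, replicates=10, seed=77)
    assert t1.newick() == t2.newick()  # byte-identical
    rooted = bootstrap_consensus(rows, jtt, replicates=10, seed=77, outgroup="e")
    assert rooted.rooted and len(rooted.root.children) == 2
    names = [l.name for l in rooted.root.children[0].leaves()]
    assert names == ["e"]
    with pytest.raises(KeyError):
        bootstrap_consensus(rows, jtt, replicates=2, seed=1, outgroup="nope")
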