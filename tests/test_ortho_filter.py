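"""Single-copy selection, best-hit consistency and the redundancy filter."""

import pytest

from minihal import mcl, ortho_filter, similarity
from minihal.mcl import Clustering
from minihal.ortho_filter import filter_sweep, select_single_copy
from minihal.seqio import ProteomeSet, SequenceRecord
from minihal.similarity import SimilarityGraph


def make_pset(genome_aliases):
    genomes = sorted(genome_aliases)
    records = {
        g: [SequenceRecord(a, a, g, "MKVL") for a in genome_aliases[g]]
        for g in genomes
    }
    amap = {a: a for g in genomes for a in genome_aliases[g]}
    return ProteomeSet(genomes, records, amap, [])


def make_graph(pset, best_hits):
    genome_of = {r.alias: r.genome_id for r in pset.all_records()}
    return SimilarityGraph(sorted(genome_of), {}, best_hits, genome_of)


@pytest.fixture()
def five_genomes():
    return make_pset({f"G{i}": [f"G{i}_a", f"G{i}_b"] for i in range(1, 6)})


def test_single_copy_rule(five_genomes):
    log = []
    clustering = Clustering(2.0, [
        frozenset({"G1_a", "G1_b"}),                       # two proteins, one genome
        frozenset({"G1_a"}),                               # singleton
        frozenset({"G1_a", "G2_a", "G3_a", "G4_a"}),       # 4/5 taxa
    ], 10, True)
    got = select_single_copy(clustering, five_genomes, 0.8, log)
    assert [sorted(c.members) for c in got] == [["G1_a", "G2_a", "G3_a", "G4_a"]]
    reasons = {tuple(sorted(m)): r for m, _i, r in log}
    assert reasons[("G1_a", "G1_b")] == ortho_filter.REJECT_NOT_SINGLE_COPY
    assert reasons[("G1_a",)] == ortho_filter.REJECT_TOO_SMALL


def test_taxon_fraction_threshold(five_genomes):
    c3 = frozenset({"G1_a", "G2_a", "G3_a"})  # 60% coverage
    clustering = Clustering(2.0, [c3], 5, True)
    assert select_single_copy(clustering, five_genomes, 0.6)
    assert not select_single_copy(clustering, five_genomes, 0.8)
    with pytest.raises(ValueError):
        select_single_copy(clustering, five_genomes, 0.0)


def test_best_hit_consistency(five_genomes):
    members = frozenset({"G1_a", "G2_a", "G3_a"})
    cand = ortho_filter.CandidateCluster(members, 2.0,
                                         frozenset({"G1", "G2", "G3"}), 0.6)
    internal = make_graph(five_genomes, {
        ("G1_a", "G2"): "G2_a", ("G1_a", "G3"): "G3_a",
        ("G2_a", "G1"): "G1_a", ("G3_a", "G1"): "G1_a",
    })
    assert ortho_filter.best_hit_consistent(cand, internal)
    # best hit into a cluster genome lands outside the cluster
    external = make_graph(five_genomes, {("G1_a", "G2"): "G2_b"})
    assert not ortho_filter.best_hit_consistent(cand, external)
    # a hit into a genome NOT in the cluster does not matter
    outside = make_graph(five_genomes, {("G1_a", "G5"): "G5_b"})
    assert ortho_filter.best_hit_consistent(cand, outside)


def test_sweep_takes_most_stringent_copy_first(five_genomes):
    fam = frozenset({"G1_a", "G2_a", "G3_a", "G4_a", "G5_a"})
    sweep = [
        Clustering(1.5, [fam], 5, True),
        Clustering(5.0, [fam], 5, True),
    ]
    graph = make_graph(five_genomes, {})
    got = filter_sweep(sweep, graph, five_genomes, 0.8)
    assert len(got.accepted) == 1
    assert got.accepted[0].inflation == 5.0
    assert any(r == ortho_filter.REJECT_OVERLAPS_ACCEPTED
               for _m, i, r in got.rejection_log if i == 1.5)


def test_single_clustering_sweep_equals_direct_selection(five_genomes):
    fam = frozenset({"G1_a", "G2_a", "G3_a", "G4_a"})
    clustering = Clustering(2.0, [fam], 5, True)
    graph = make_graph(five_genomes, {})
    got = filter_sweep([clustering], graph, five_genomes, 0.8)
    direct = select_single_copy(clustering, five_genomes, 0.8)
    assert [c.members for c in got.accepted] == [c.members for c in direct]
    with pytest.raises(ValueError):
        filter_sweep([], graph, five_genomes, 0.8)


def test_accepted_clusters_disjoint_and_monotone(five_genomes):
    fam1 = frozenset({"G1_a", "G2_a", "G3_a", "G4_a", "G5_a"})
    fam2 = frozenset({"G1_b", "G2_b", "G3_b"})
    overlap = frozenset({"G1_a", "G2_b", "G4_a"})
    sweep = [
        Clustering(5.0, [fam1, fam2], 5, True),
        Clustering(2.0, [overlap], 5, True),
    ]
    graph = make_graph(five_genomes, {})
    got = filter_sweep(sweep, graph, five_genomes, 0.5)
    seen = set()
    for c in got.accepted:
        assert not (c.members & seen)
        seen |= c.members
    # raising the coverage floor never accepts more clusters
    n_low = len(filter_sweep(sweep, graph, five_genomes, 0.5).accepted)
    n_high = len(filter_sweep(sweep, graph, five_genomes, 1.0).accepted)
    assert n_high <= n_low
    # at fraction 1, accepted clusters contain one protein of every genome
    for c in filter_sweep(sweep, graph, five_genomes, 1.0).accepted:
        assert c.taxa == frozenset(five_genomes.genomes)


def test_order_independence_of_equal_candidates(five_genomes):
    fam1 = frozenset({"G1_a", "G2_a", "G3_a"})
    fam2 = frozenset({"G1_b", "G2_b", "G3_b"})
    graph = make_graph(five_genomes, {})
    a = filter_sweep([Clustering(2.0, [fam1, fam2], 5, True)], graph, five_genomes, 0.5)
    b = filter_sweep([Clustering(2.0, [fam2, fam1], 5, True)], graph, five_genomes, 0.5)
    assert [c.members for c in a.accepted] == [c.members for c in b.accepted]
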