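"""Selection and filtering of candidate ortholog clusters.

From the union of clusterings across the inflation sweep, only single-copy
clusters (at most one protein per genome) covering at least a minimum
fraction of the taxa are candidates.  Candidates are processed starting
from the most stringent (highest) inflation so that a family enters the
accepted set once, from the tightest clustering that recovers it; a
candidate is additionally required to be best-hit consistent (no member may
have a per-genome best hit outside the cluster, for genomes represented in
the cluster) and disjoint from everything already accepted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .mcl import Clustering
from .seqio import ProteomeSet
from .similarity import SimilarityGraph

REJECT_NOT_SINGLE_COPY = "not_single_copy"
REJECT_BELOW_TAXON_FRACTION = "below_taxon_fraction"
REJECT_OVERLAPS_ACCEPTED = "overlaps_accepted"
REJECT_BEST_HIT_VIOLATION = "best_hit_violation"
REJECT_TOO_SMALL = "too_small"


@dataclasses.dataclass(frozen=True)
class CandidateCluster:
    members: frozenset[str]
    inflation: float
    taxa: frozenset[str]
    taxon_fraction: float


@dataclasses.dataclass
class ClusterSet:
    accepted: list[CandidateCluster]
    rejection_log: list[tuple[frozenset[str], float, str]]  # members, inflation, reason


def _candidate(members: frozenset[str], inflation: float,
               genome_of: dict[str, str], n_genomes: int) -> CandidateCluster:
    taxa = frozenset(genome_of[m] for m in members)
    return CandidateCluster(members, inflation, taxa, len(taxa) / n_genomes)


def select_single_copy(
    clustering: Clustering,
    proteomes: ProteomeSet,
    min_taxon_fraction: float,
    rejection_log: list | None = None,
) -> list[CandidateCluster]:
    """Keep clusters with >= 2 members, at most one member per genome, and
    taxon coverage >= ``min_taxon_fraction``; log everything else."""
    if not 0 < min_taxon_fraction <= 1:
        raise ValueError("min_taxon_fraction must lie in (0, 1]")
    genome_of = {r.alias: r.genome_id for r in proteomes.all_records()}
    n_genomes = len(proteomes.genomes)
    out = []
    for members in clustering.clusters:
        cand = _candidate(members, clustering.inflation, genome_of, n_genomes)
        if len(members) < 2:
            reason = REJECT_TOO_SMALL
        elif len(cand.taxa) < len(members):
            reason = REJECT_NOT_SINGLE_COPY
        elif cand.taxon_fraction < min_taxon_fraction:
            reason = REJECT_BELOW_TAXON_FRACTION
        else:
            out.append(cand)
            continue
        if rejection_log is not None:
            rejection_log.append((members, clustering.inflation, reason))
    return out


def best_hit_consistent(cluster: CandidateCluster, graph: SimilarityGraph) -> bool:
    """True iff every member's best hit into each other cluster genome
    (when one exists) is itself a cluster member."""
    for p in cluster.members:
        own = graph.genome_of[p]
        for g in cluster.taxa:
            if g == own:
                continue
            hit = graph.best_hits.get((p, g))
            if hit is not None and hit not in cluster.members:
                return False
    return True


def filter_sweep(
    clusterings: list[Clustering],
    graph: SimilarityGraph,
    proteomes: ProteomeSet,
    min_taxon_fraction: float,
) -> ClusterSet:
    """Most-stringent-first non-redundancy filter across the sweep.

    Clusterings are visited in decreasing inflation order; within one
    clustering, candidates go by decreasing size then lexicographically
    smallest member alias (a content-based, order-independent tie-break).
    """
    if not clusterings:
        raise ValueError("empty inflation sweep")
    accepted: list[CandidateCluster] = []
    used: set[str] = set()
    log: list[tuple[frozenset[str], float, str]] = []
    for clustering in sorted(clusterings, key=lambda c: -c.inflation):
        cands = select_single_copy(clustering, proteomes, min_taxon_fraction, log)
        cands.sort(key=lambda c: (-len(c.members), min(c.members)))
        for cand in cands:
            if cand.members & used:
                log.append((cand.members, cand.inflation, REJECT_OVERLAPS_ACCEPTED))
            elif not best_hit_consistent(cand, graph):
                log.append((cand.members, cand.inflation, REJECT_BEST_HIT_VIOLATION))
            else:
                accepted.append(cand)
                used |= cand.members
    return ClusterSet(accepted, log)


def cluster_id(index: int, width: int = 4) -> str:
    return f"c{index + 1:0{width}d}"


def write_cluster_table(cs: ClusterSet, proteomes: ProteomeSet, path: str | Path) -> None:
    by_alias = proteomes.by_alias()
    with open(path, "w") as fh:
        fh.write("cluster_id\tinflation\tgenome_id\talias\toriginal_header\n")
        for i, c in enumerate(cs.accepted):
            cid = cluster_id(i)
            for a in sorted(c.members):
                rec = by_alias[a]
                fh.write(f"{cid}\t{c.inflation}\t{rec.genome_id}\t{a}\t{rec.original_header}\n")


def write_rejection_log(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("inflation\treason\tmembers\n")
        for members, inflation, reason in cs.rejection_log:
            fh.write(f"{inflation}\t{reason}\t{','.join(sorted(members))}\n")
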