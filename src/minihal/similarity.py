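"""All-vs-all similarity results: parsing, graph construction, best hits.

The similarity search itself is external (any tool emitting the 12-column
BLAST tabular dialect works, at an e-value cutoff of 1e-1); this module
turns its output into a weighted protein graph.  Edge weights are
``min(-log10(E), cap)`` symmetrized by the maximum over both directions,
which keeps weights finite when E underflows to zero and mirrors the
standard practice for feeding BLAST e-values to Markov clustering.

Per-genome best hits (lowest e-value, then highest bitscore, then smallest
subject alias) are indexed here because the ortholog filters consume them.
"""

from __future__ import annotations

import dataclasses
import shlex
from pathlib import Path

from .seqio import ProteomeSet

DEFAULT_EVALUE_CUTOFF = 1e-1
DEFAULT_WEIGHT_CAP = 200.0


class HitParseError(ValueError):
    pass


class UnknownAliasError(KeyError):
    pass


@dataclasses.dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float


@dataclasses.dataclass
class SimilarityGraph:
    nodes: list[str]
    # (query, subject) -> (evalue, bitscore); self-hits excluded
    directed_edges: dict[tuple[str, str], tuple[float, float]]
    # (query, target_genome) -> subject alias
    best_hits: dict[tuple[str, str], str]
    genome_of: dict[str, str]


def parse_tabular_hits(
    path: str | Path,
    alias_map: dict[str, str] | None = None,
    cutoff_evalue: float = DEFAULT_EVALUE_CUTOFF,
) -> list[HitRecord]:
    """Parse a 12-column tabular hit file.

    Self-hits and rows above the e-value cutoff are dropped; duplicate
    (query, subject) rows collapse to the minimal-evalue row (ties keep the
    higher bitscore).  If ``alias_map`` is given, aliases not present in it
    raise :class:`UnknownAliasError`.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise HitParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rec = HitRecord(
                    query=parts[0],
                    subject=parts[1],
                    percent_identity=float(parts[2]),
                    align_length=int(parts[3]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.evalue < 0:
                raise HitParseError(f"{path}:{lineno}: negative e-value")
            if alias_map is not None:
                for a in (rec.query, rec.subject):
                    if a not in alias_map:
                        raise UnknownAliasError(
                            f"{path}:{lineno}: alias {a!r} not in alias map"
                        )
            if rec.query == rec.subject or rec.evalue > cutoff_evalue:
                continue
            key = (rec.query, rec.subject)
            prev = best.get(key)
            if (
                prev is None
                or rec.evalue < prev.evalue
                or (rec.evalue == prev.evalue and rec.bitscore > prev.bitscore)
            ):
                best[key] = rec
    return list(best.values())


def build_graph(hits: list[HitRecord], proteomes: ProteomeSet) -> SimilarityGraph:
    """Build the directed similarity graph over all QC-surviving proteins.

    Isolated nodes are kept.  ``best_hits[q, g]`` is q's subject in genome g
    with minimal evalue; ties break by highest bitscore then smallest alias,
    so the index is independent of input row order.
    """
    genome_of = {r.alias: r.genome_id for r in proteomes.all_records()}
    nodes = sorted(genome_of)
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    for h in hits:
        edges[(h.query, h.subject)] = (h.evalue, h.bitscore)
        g = genome_of[h.subject]
        key = (h.query, g)
        cand = (h.evalue, -h.bitscore, h.subject)
        if key not in best or cand < best[key]:
            best[key] = cand
    best_hits = {k: v[2] for k, v in best.items()}
    return SimilarityGraph(nodes, edges, best_hits, genome_of)


def edge_weights(
    graph: SimilarityGraph, cap: float = DEFAULT_WEIGHT_CAP
) -> dict[tuple[str, str], float]:
    """Symmetric positive weights: max over directions of min(-log10(E), cap).

    E = 0 maps to the cap.  Keys are unordered pairs stored as sorted tuples.
    """
    import math

    weights: dict[tuple[str, str], float] = {}
    for (q, s), (ev, _bs) in graph.directed_edges.items():
        w = cap if ev <= 0.0 else min(-math.log10(ev), cap)
        key = (q, s) if q < s else (s, q)
        if w > weights.get(key, 0.0):
            weights[key] = w
    return weights


def search_command(
    query_fasta: str | Path,
    database: str | Path,
    out_path: str | Path,
    n_genomes: int,
    cutoff_evalue: float = DEFAULT_EVALUE_CUTOFF,
) -> list[str]:
    """Command line for an external all-vs-all protein search.

    Soft filtering of low-complexity segments (mask during seeding only) and
    a per-query hit limit equal to the number of genomes compared; the
    command is constructed here but never executed by the library itself.
    """
    return [
        "blastp",
        "-query", str(query_fasta),
        "-db", str(database),
        "-out", str(out_path),
        "-outfmt", "6",
        "-evalue", str(cutoff_evalue),
        "-seg", "yes",
        "-soft_masking", "true",
        "-max_target_seqs", str(n_genomes),
    ]


def format_search_command(args: list[str]) -> str:
    return shlex.join(args)
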