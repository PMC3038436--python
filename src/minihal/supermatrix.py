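"""Supermatrix assembly: taxon normalization, concatenation, partitions.

Trimmed cluster alignments (keyed by genome after the alias→organism
substitution) are normalized to a common ordered taxon set — genomes absent
from a cluster get a row of ``?`` — and concatenated in lexicographic
cluster order.  The partition map records each cluster's 1-based inclusive
column range and its assigned substitution model, and serializes to the
RAxML protein partition dialect (``WAG, c0001 = 1-120``).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

from .seqio import read_alignment, write_alignment
from .trim import ClusterAlignment

MISSING = "?"
TRIM_MODES = ("remgaps", "gblocks_conservative", "gblocks_liberal")


@dataclasses.dataclass(frozen=True)
class PartitionEntry:
    cluster_id: str
    start: int  # 1-based inclusive
    end: int
    model_name: str


@dataclasses.dataclass
class PartitionMap:
    entries: list[PartitionEntry]

    def validate(self) -> None:
        pos = 1
        for e in self.entries:
            if e.start != pos or e.end < e.start:
                raise ValueError(f"partition entries must tile contiguously: {e}")
            pos = e.end + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1].end if self.entries else 0


@dataclasses.dataclass
class SuperAlignment:
    taxa: list[str]
    matrix: dict[str, str]
    partitions: PartitionMap
    mode: str

    def validate(self) -> None:
        self.partitions.validate()
        L = self.partitions.total_length
        for t in self.taxa:
            if len(self.matrix[t]) != L:
                raise ValueError(f"row {t} length != sum of partition lengths")


def sanitize_name(name: str) -> str:
    """Organism names made PHYLIP/Newick-safe: alphanumeric + underscore."""
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def normalize(aln: ClusterAlignment, taxa: list[str]) -> ClusterAlignment:
    """Fill absent genomes with ``?`` rows and order rows by ``taxa``."""
    aln.validate()
    if len(set(aln.rows)) != len(aln.rows):
        raise ValueError("duplicate genome row")
    unknown = set(aln.rows) - set(taxa)
    if unknown:
        raise ValueError(f"alignment rows not in taxon set: {sorted(unknown)}")
    width = aln.columns
    rows = {t: aln.rows.get(t, MISSING * width) for t in taxa}
    return ClusterAlignment(aln.cluster_id, rows)


def concatenate(
    alns: list[ClusterAlignment],
    taxa: list[str],
    models: dict[str, str],
    mode: str,
) -> SuperAlignment:
    """Concatenate normalized alignments (lexicographic cluster_id order)."""
    ordered = sorted(alns, key=lambda a: a.cluster_id)
    entries = []
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for a in ordered:
        if list(a.rows) != list(taxa):
            raise ValueError(f"alignment {a.cluster_id} is not normalized to the taxon set")
        w = a.columns
        entries.append(
            PartitionEntry(a.cluster_id, pos, pos + w - 1, models.get(a.cluster_id, "JTT"))
        )
        pos += w
        for t in taxa:
            parts[t].append(a.rows[t])
    sup = SuperAlignment(
        list(taxa), {t: "".join(parts[t]) for t in taxa}, PartitionMap(entries), mode
    )
    sup.validate()
    return sup


def write_partition_file(pm: PartitionMap, path: str | Path) -> None:
    pm.validate()
    with open(path, "w") as fh:
        for e in pm.entries:
            fh.write(f"{e.model_name}, {e.cluster_id} = {e.start}-{e.end}\n")


def read_partition_file(path: str | Path) -> PartitionMap:
    entries = []
    pat = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            m = pat.match(line)
            if not m:
                raise ValueError(f"bad partition line: {line!r}")
            entries.append(
                PartitionEntry(m.group(2), int(m.group(3)), int(m.group(4)), m.group(1))
            )
    pm = PartitionMap(entries)
    pm.validate()
    return pm


def write_supermatrix(sup: SuperAlignment, basepath: str | Path) -> dict[str, Path]:
    """Write FASTA + relaxed PHYLIP + partition file + TSV summary."""
    basepath = Path(basepath)
    out = {
        "fasta": basepath.with_suffix(".fasta"),
        "phylip": basepath.with_suffix(".phy"),
        "partitions": basepath.with_suffix(".partitions.txt"),
        "summary": basepath.with_suffix(".partitions.tsv"),
    }
    write_alignment(sup.matrix, out["fasta"], "fasta")
    write_alignment(sup.matrix, out["phylip"], "relaxed_phylip")
    write_partition_file(sup.partitions, out["partitions"])
    with open(out["summary"], "w") as fh:
        fh.write("cluster_id\tstart\tend\tmodel\twidth\n")
        for e in sup.partitions.entries:
            fh.write(f"{e.cluster_id}\t{e.start}\t{e.end}\t{e.model_name}\t{e.end - e.start + 1}\n")
    return out


def read_supermatrix(basepath: str | Path, mode: str) -> SuperAlignment:
    basepath = Path(basepath)
    rows = read_alignment(basepath.with_suffix(".fasta"), "fasta")
    pm = read_partition_file(basepath.with_suffix(".partitions.txt"))
    sup = SuperAlignment(list(rows), rows, pm, mode)
    sup.validate()
    return sup
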