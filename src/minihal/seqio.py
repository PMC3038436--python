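"""Sequence input/output, quality control and alias mapping.

Predicted proteomes arrive as one FASTA file per genome with arbitrary,
center-specific header conventions.  Before anything downstream can run,
every sequence is quality-checked (duplicate headers, non-IUPAC residues,
empty sequences are rejected) and assigned a short unique alias of the form
``g<G>_p<N>`` so that later stages never have to parse free-text headers.
The original headers are kept in a bijective alias map and can be restored
exactly at any point.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

# 20 standard residues plus ambiguity/extended codes; '*' handled separately
# (accepted as a terminal stop marker only, and stripped).
IUPAC_PROTEIN = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUJO")

REJECT_DUPLICATE = "duplicate_header"
REJECT_NON_IUPAC = "non_iupac_characters"
REJECT_EMPTY = "empty_sequence"


class EmptyProteomeError(ValueError):
    """No sequence of a genome survived quality control."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One quality-checked protein sequence."""

    original_header: str
    alias: str          # empty until build_alias_map has run
    genome_id: str
    residues: str


@dataclasses.dataclass(frozen=True)
class QCReportEntry:
    genome_id: str
    header: str
    reason: str  # one of the REJECT_* constants


@dataclasses.dataclass
class ProteomeSet:
    """Per-genome record lists plus the alias map and QC report."""

    genomes: list[str]
    records: dict[str, list[SequenceRecord]]
    alias_map: dict[str, str]          # alias -> original_header
    qc_report: list[QCReportEntry]

    def all_records(self) -> Iterable[SequenceRecord]:
        for g in self.genomes:
            yield from self.records[g]

    def header_to_alias(self) -> dict[str, str]:
        return {h: a for a, h in self.alias_map.items()}

    def by_alias(self) -> dict[str, SequenceRecord]:
        return {r.alias: r for r in self.all_records()}


def _clean_residues(raw: str) -> str | None:
    """Uppercase, strip a single terminal '*'; None if non-IUPAC characters remain."""
    s = raw.upper()
    if s.endswith("*"):
        s = s[:-1]
    if not s:
        return s
    if set(s) <= IUPAC_PROTEIN:
        return s
    return None


def read_fasta_qc(
    path: str | Path, genome_id: str
) -> tuple[list[SequenceRecord], list[QCReportEntry]]:
    """Read one genome's FASTA and apply quality control.

    Duplicated headers keep their first occurrence; later copies are
    rejected.  Sequences with characters outside the accepted protein
    alphabet, or empty sequences, are rejected with their own reason codes.

    Raises
    ------
    EmptyProteomeError
        If no sequence survives.
    """
    records: list[SequenceRecord] = []
    rejected: list[QCReportEntry] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        if header in seen:
            rejected.append(QCReportEntry(genome_id, header, REJECT_DUPLICATE))
            continue
        seen.add(header)
        cleaned = _clean_residues(str(entry.seq))
        if cleaned is None:
            rejected.append(QCReportEntry(genome_id, header, REJECT_NON_IUPAC))
        elif cleaned == "":
            rejected.append(QCReportEntry(genome_id, header, REJECT_EMPTY))
        else:
            records.append(SequenceRecord(header, "", genome_id, cleaned))
    if not records:
        raise EmptyProteomeError(
            f"no sequence of genome {genome_id!r} survived quality control ({path})"
        )
    return records, rejected


def read_proteomes(paths: dict[str, str | Path]) -> ProteomeSet:
    """QC every genome FASTA and assign aliases; genome order = dict order."""
    genomes = list(paths)
    records: dict[str, list[SequenceRecord]] = {}
    report: list[QCReportEntry] = []
    for g in genomes:
        recs, rej = read_fasta_qc(paths[g], g)
        records[g] = recs
        report.extend(rej)
    pset = ProteomeSet(genomes, records, {}, report)
    return build_alias_map(pset)


def build_alias_map(proteomes: ProteomeSet) -> ProteomeSet:
    """Assign ``g<G>_p<N>`` aliases (1-based ordinals, zero-padded so that
    lexicographic and numeric order coincide) and record the bijection."""
    gw = len(str(len(proteomes.genomes)))
    pw = max((len(str(len(v))) for v in proteomes.records.values()), default=1)
    alias_map: dict[str, str] = {}
    new_records: dict[str, list[SequenceRecord]] = {}
    for gi, g in enumerate(proteomes.genomes, start=1):
        out = []
        for pi, rec in enumerate(proteomes.records[g], start=1):
            alias = f"g{gi:0{gw}d}_p{pi:0{pw}d}"
            alias_map[alias] = rec.original_header
            out.append(dataclasses.replace(rec, alias=alias))
        new_records[g] = out
    return ProteomeSet(proteomes.genomes, new_records, alias_map, proteomes.qc_report)


# ---------------------------------------------------------------------------
# alias map / QC report persistence (TSV)

def write_alias_map(pset: ProteomeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("alias\tgenome_id\toriginal_header\n")
        for rec in pset.all_records():
            fh.write(f"{rec.alias}\t{rec.genome_id}\t{rec.original_header}\n")


def read_alias_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """alias -> (genome_id, original_header)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            alias, genome_id, header = line.rstrip("\n").split("\t", 2)
            out[alias] = (genome_id, header)
    return out


def write_qc_report(pset: ProteomeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\theader\treason\n")
        for e in pset.qc_report:
            fh.write(f"{e.genome_id}\t{e.header}\t{e.reason}\n")


# ---------------------------------------------------------------------------
# alignment writers/readers

def write_fasta(rows: dict[str, str], path: str | Path) -> None:
    recs = [_BioRecord(Seq(s), id=n, description="") for n, s in rows.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_alignment(rows: dict[str, str], path: str | Path, format: str = "fasta") -> None:
    """Write an alignment matrix as FASTA or relaxed PHYLIP.

    All rows must have equal length and unique names.
    """
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
    if format == "fasta":
        write_fasta(rows, path)
    elif format == "relaxed_phylip":
        ncol = lengths.pop() if lengths else 0
        width = max((len(n) for n in rows), default=0)
        with open(path, "w") as fh:
            fh.write(f" {len(rows)} {ncol}\n")
            for name, seq in rows.items():
                fh.write(f"{name:<{width}}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def read_alignment(path: str | Path, format: str = "fasta") -> dict[str, str]:
    if format == "fasta":
        return read_fasta(path)
    if format == "relaxed_phylip":
        rows: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().split()
            nrow, ncol = int(header[0]), int(header[1])
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                rows[name] = seq.strip()
        if len(rows) != nrow or any(len(s) != ncol for s in rows.values()):
            raise ValueError(f"PHYLIP file {path} does not match its header")
        return rows
    raise ValueError(f"unknown alignment format {format!r}")
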