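"""Cluster alignment and alignment editing.

Each accepted ortholog cluster is aligned (external aligner adapters are
supported; a built-in progressive aligner makes the pipeline self-contained)
and then edited three ways, each trading alignment length against alignment
quality:

* ``remgaps`` — delete every column containing a gap (the strictest edit);
* Gblocks-style *conservative* — nonconserved runs longer than 4 removed,
  surviving blocks must be at least 10 columns;
* Gblocks-style *liberal* — the same with 8 and 5, keeping the most data.

A column counts as nonconserved when it contains any gap or when its most
frequent residue occurs in fewer than floor(n/2)+1 rows.  After removing
long nonconserved runs the remaining segments are trimmed so they start and
end on conserved columns, and segments shorter than the block minimum are
dropped.  No bit-exact parity with the original Gblocks program is claimed.

The built-in aligner is progressive: a neighbor-joining guide tree from
6-mer cosine distances, then profile-profile Needleman-Wunsch-Gotoh with
BLOSUM62 scores and affine gaps (open 10, extend 0.5).  Row order of the
output equals input order.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

from .njtree import DistanceMatrix, Node, neighbor_joining

GAP = "-"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5
GUIDE_KMER = 6

CONSERVATIVE = ("gblocks", 4, 10)
LIBERAL = ("gblocks", 8, 5)


@dataclasses.dataclass
class TrimSettings:
    mode: str  # {remgaps, gblocks}
    max_contiguous_nonconserved: int = 4
    min_block_length: int = 10

    def __post_init__(self) -> None:
        if self.mode == "gblocks":
            if self.max_contiguous_nonconserved < 1 or self.min_block_length < 1:
                raise ValueError("gblocks settings must be >= 1")


CONSERVATIVE_SETTINGS = TrimSettings("gblocks", 4, 10)
LIBERAL_SETTINGS = TrimSettings("gblocks", 8, 5)


@dataclasses.dataclass
class ClusterAlignment:
    cluster_id: str
    rows: dict[str, str]  # name -> gapped residues, equal lengths

    @property
    def columns(self) -> int:
        return len(next(iter(self.rows.values()), ""))

    def validate(self) -> None:
        if len({len(s) for s in self.rows.values()}) > 1:
            raise ValueError(f"ragged alignment {self.cluster_id}")


# ---------------------------------------------------------------------------
# built-in progressive aligner

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AIDX = {a: i for i, a in enumerate(_ALPHA)}
_NSYM = len(_ALPHA)
_SCORE = np.zeros((_NSYM + 1, _NSYM + 1))  # last index = gap, scores 0
for _a in _ALPHA:
    for _b in _ALPHA:
        _SCORE[_AIDX[_a], _AIDX[_b]] = _BLOSUM[_a][_b]


def _encode_profile(rows: list[str]) -> np.ndarray:
    """(ncols, nsym+1) count profile; unknown residues count as X."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, _NSYM + 1))
    xi = _AIDX["X"]
    for r in rows:
        for j, c in enumerate(r):
            prof[j, _NSYM if c == GAP else _AIDX.get(c, xi)] += 1
    return prof


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh affine-gap global alignment of two profiles."""
    pa, pb = _encode_profile(rows_a), _encode_profile(rows_b)
    na, nb = pa.shape[0], pb.shape[0]
    wa, wb = len(rows_a), len(rows_b)
    # mean-of-pairs column score
    col = (pa @ _SCORE @ pb.T) / (wa * wb)

    NEG = -1e18
    m = np.full((na + 1, nb + 1), NEG)
    x = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A)
    y = np.full((na + 1, nb + 1), NEG)  # gap in A (consume B)
    m[0, 0] = 0.0
    for i in range(1, na + 1):
        x[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, nb + 1):
        y[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    for i in range(1, na + 1):
        ci = col[i - 1]
        mi1, xi1, yi1 = m[i - 1], x[i - 1], y[i - 1]
        mi, xi_, yi = m[i], x[i], y[i]
        for j in range(1, nb + 1):
            best_prev = max(mi1[j - 1], xi1[j - 1], yi1[j - 1])
            mi[j] = best_prev + ci[j - 1]
            xi_[j] = max(mi1[j] - GAP_OPEN, xi1[j] - GAP_EXTEND)
            yi[j] = max(mi[j - 1] - GAP_OPEN, yi[j - 1] - GAP_EXTEND)

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = na, nb
    state = int(np.argmax([m[i, j], x[i, j], y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("M")
            prev = [m[i - 1][j - 1], x[i - 1][j - 1], y[i - 1][j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 or j == 0:
            out_a.append("X")
            state = 0 if m[i - 1][j] - GAP_OPEN >= x[i - 1][j] - GAP_EXTEND else 1
            i -= 1
        else:
            out_a.append("Y")
            state = 0 if m[i][j - 1] - GAP_OPEN >= y[i][j - 1] - GAP_EXTEND else 2
            j -= 1
    ops = out_a[::-1]

    def expand(rows: list[str], consume: set[str]) -> list[str]:
        out = []
        for r in rows:
            buf = []
            k = 0
            for op in ops:
                if op in consume:
                    buf.append(r[k])
                    k += 1
                else:
                    buf.append(GAP)
            out.append("".join(buf))
        return out

    return expand(rows_a, {"M", "X"}), expand(rows_b, {"M", "Y"})


def _kmer_distance(a: str, b: str, k: int = GUIDE_KMER) -> float:
    ca = Counter(a[i : i + k] for i in range(max(len(a) - k + 1, 1)))
    cb = Counter(b[i : i + k] for i in range(max(len(b) - k + 1, 1)))
    dot = sum(ca[w] * cb.get(w, 0) for w in ca)
    na = np.sqrt(sum(v * v for v in ca.values()))
    nb = np.sqrt(sum(v * v for v in cb.values()))
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - dot / (na * nb))


def align_sequences(named_seqs: list[tuple[str, str]]) -> dict[str, str]:
    """Progressive alignment; output rows keyed by name, in input order."""
    if len(named_seqs) < 2:
        raise ValueError("alignment requires at least 2 sequences")
    names = [n for n, _ in named_seqs]
    seqs = dict(named_seqs)
    if len(names) == 2:
        a, b = _profile_align([seqs[names[0]]], [seqs[names[1]]])
        merged = {names[0]: a[0], names[1]: b[0]}
        return {n: merged[n] for n in names}

    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[names[i]], seqs[names[j]])
    guide = neighbor_joining(DistanceMatrix(names, d))

    def merge(node: Node) -> tuple[list[str], list[str]]:
        if not node.children:
            return [node.name], [seqs[node.name]]
        parts = [merge(c) for c in node.children]
        cur_names, cur_rows = parts[0]
        for nm, rw in parts[1:]:
            a, b = _profile_align(cur_rows, rw)
            cur_names, cur_rows = cur_names + nm, a + b
        return cur_names, cur_rows

    got_names, got_rows = merge(guide.root)
    merged = dict(zip(got_names, got_rows))
    return {n: merged[n] for n in names}


def align_cluster(
    cluster_id: str,
    named_seqs: list[tuple[str, str]],
    aligner: str = "builtin",
) -> ClusterAlignment:
    """Align one cluster's sequences; only the built-in aligner executes in
    process, external adapters raise unless their binary is configured."""
    if aligner == "builtin":
        rows = align_sequences(named_seqs)
    else:
        raise ConfigurationError(
            f"aligner adapter {aligner!r} requires an external executable; "
            "use aligner='builtin' or run the adapter command manually"
        )
    aln = ClusterAlignment(cluster_id, rows)
    for name, seq in named_seqs:  # adapter contract
        assert rows[name].replace(GAP, "") == seq
    return aln


class ConfigurationError(RuntimeError):
    pass


def aligner_command(aligner: str, in_fasta: str, out_fasta: str) -> list[str]:
    """Command lines for the supported external aligner adapters."""
    commands = {
        "muscle": ["muscle", "-stable", "-in", in_fasta, "-out", out_fasta],
        "mafft": ["mafft", "--anysymbol", in_fasta],
        "clustalw": ["clustalw", f"-INFILE={in_fasta}", "-OUTPUT=FASTA",
                     f"-OUTFILE={out_fasta}"],
        "probcons": ["probcons", in_fasta],
    }
    if aligner not in commands:
        raise ConfigurationError(f"unknown aligner adapter {aligner!r}")
    return commands[aligner]


# ---------------------------------------------------------------------------
# alignment editing

def remgaps(aln: ClusterAlignment) -> ClusterAlignment:
    """Delete every column that contains at least one gap."""
    aln.validate()
    names = list(aln.rows)
    cols = list(zip(*aln.rows.values()))
    kept = [c for c in cols if GAP not in c]
    rows = {n: "".join(c[i] for c in kept) for i, n in enumerate(names)}
    return ClusterAlignment(aln.cluster_id, rows)


def _conserved_mask(aln: ClusterAlignment) -> np.ndarray:
    """True where a column has no gap and a majority residue
    (count >= floor(n/2) + 1)."""
    names = list(aln.rows)
    n = len(names)
    need = n // 2 + 1
    mask = np.zeros(aln.columns, dtype=bool)
    cols = list(zip(*aln.rows.values()))
    for j, col in enumerate(cols):
        if GAP in col:
            continue
        if Counter(col).most_common(1)[0][1] >= need:
            mask[j] = True
    return mask


def gblocks_like(aln: ClusterAlignment, settings: TrimSettings) -> ClusterAlignment:
    """Block trimming: remove long nonconserved runs, trim block ends to
    conserved columns, drop short blocks."""
    if settings.mode != "gblocks":
        raise ValueError("gblocks_like requires gblocks-mode settings")
    aln.validate()
    conserved = _conserved_mask(aln)
    ncol = aln.columns

    # 1-2) delete maximal nonconserved runs longer than the allowance
    keep = np.ones(ncol, dtype=bool)
    j = 0
    while j < ncol:
        if not conserved[j]:
            k = j
            while k < ncol and not conserved[k]:
                k += 1
            if k - j > settings.max_contiguous_nonconserved:
                keep[j:k] = False
            j = k
        else:
            j += 1

    # 3) blocks = maximal kept runs
    blocks: list[list[int]] = []
    cur: list[int] = []
    for j in range(ncol):
        if keep[j]:
            cur.append(j)
        elif cur:
            blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)

    # 4) trim each block to start/end on conserved columns
    trimmed: list[list[int]] = []
    for b in blocks:
        lo, hi = 0, len(b) - 1
        while lo <= hi and not conserved[b[lo]]:
            lo += 1
        while hi >= lo and not conserved[b[hi]]:
            hi -= 1
        if lo <= hi:
            trimmed.append(b[lo : hi + 1])

    # 5) drop blocks below the minimum length
    final_cols = [j for b in trimmed if len(b) >= settings.min_block_length for j in b]

    names = list(aln.rows)
    rows = {n: "".join(aln.rows[n][j] for j in final_cols) for n in names}
    return ClusterAlignment(aln.cluster_id, rows)


def trim_alignment(aln: ClusterAlignment, mode: str) -> ClusterAlignment:
    if mode == "remgaps":
        return remgaps(aln)
    if mode == "gblocks_conservative":
        return gblocks_like(aln, CONSERVATIVE_SETTINGS)
    if mode == "gblocks_liberal":
        return gblocks_like(aln, LIBERAL_SETTINGS)
    raise ValueError(f"unknown trim mode {mode!r}")


def min_length_filter(
    alns: list[ClusterAlignment], min_len: int
) -> list[ClusterAlignment]:
    """Keep alignments at least ``min_len`` columns wide, preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [a for a in alns if a.columns >= min_len]
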