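"""Built-in aligner contract and alignment editing rules."""

import numpy as np
import pytest

from _oracles import pairwise_affine_score
from minihal import trim
from minihal.trim import (
    CONSERVATIVE_SETTINGS,
    LIBERAL_SETTINGS,
    ClusterAlignment,
    TrimSettings,
    align_cluster,
    gblocks_like,
    min_length_filter,
    remgaps,
)


def random_alignment(rng, n_rows=4, n_cols=40, gap_p=0.15, cid="c1"):
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    p = np.full(21, (1 - gap_p) / 20)
    p[20] = gap_p
    rows = {
        f"r{i}": "".join(aa[rng.choice(21, size=n_cols, p=p)]) for i in range(n_rows)
    }
    return ClusterAlignment(cid, rows)


# ---------------------------------------------------------------------------
# aligner

def test_identical_sequences_align_gap_free():
    aln = align_cluster("c1", [("a", "MKVLW"), ("b", "MKVLW")])
    assert aln.rows == {"a": "MKVLW", "b": "MKVLW"}


def test_pairwise_matches_needleman_wunsch_oracle():
    a, b = "ACDEFGHIKL", "ACDEGHIKL"  # one deletion
    aln = align_cluster("c1", [("x", a), ("y", b)])
    # oracle: optimal affine-gap score with the same scoring scheme
    from minihal.trim import _BLOSUM, GAP_EXTEND, GAP_OPEN

    best = pairwise_affine_score(
        a, b, lambda p, q: float(_BLOSUM[p][q]), GAP_OPEN, GAP_EXTEND
    )
    # score the produced alignment
    got = 0.0
    state = None
    for p, q in zip(aln.rows["x"], aln.rows["y"]):
        if p != "-" and q != "-":
            got += float(_BLOSUM[p][q])
            state = None
        else:
            cur = "x" if q == "-" else "y"
            got += -(GAP_EXTEND if state == cur else GAP_OPEN)
            state = cur
    assert got == pytest.approx(best)
    assert aln.rows["x"].replace("-", "") == a
    assert aln.rows["y"].replace("-", "") == b


def test_aligner_round_trip_and_input_order(rng):
    seqs = []
    base = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT"
    for i in range(5):
        s = list(base)
        for _ in range(6):  # point mutations
            s[int(rng.integers(len(s)))] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
        del s[int(rng.integers(len(s)))]
        seqs.append((f"s{i}", "".join(s)))
    aln = align_cluster("c1", seqs)
    assert list(aln.rows) == [n for n, _ in seqs]  # input order kept
    for n, s in seqs:
        assert aln.rows[n].replace("-", "") == s
    assert len({len(r) for r in aln.rows.values()}) == 1


def test_unknown_adapter_raises_and_commands_build():
    with pytest.raises(trim.ConfigurationError):
        align_cluster("c", [("a", "MK"), ("b", "MK")], aligner="muscle")
    cmd = trim.aligner_command("muscle", "in.fasta", "out.fasta")
    assert cmd[0] == "muscle" and "-stable" in cmd
    with pytest.raises(trim.ConfigurationError):
        trim.aligner_command("tcoffee", "a", "b")


# ---------------------------------------------------------------------------
# remgaps

def test_remgaps_examples():
    aln = ClusterAlignment("c", {"a": "AC-A", "b": "ACGA"})
    assert remgaps(aln).rows == {"a": "ACA", "b": "ACA"}
    clean = ClusterAlignment("c", {"a": "ACGA", "b": "ACGT"})
    assert remgaps(clean).rows == clean.rows


def test_remgaps_matches_column_scan_oracle(rng):
    for _ in range(20):
        aln = random_alignment(rng)
        got = remgaps(aln)
        names = list(aln.rows)
        cols = list(zip(*(aln.rows[n] for n in names)))
        kept = [c for c in cols if "-" not in c]
        expected = {n: "".join(c[i] for c in kept) for i, n in enumerate(names)}
        assert got.rows == expected
        assert "-" not in "".join(got.rows.values())


# ---------------------------------------------------------------------------
# gblocks-style trimming

def _block_alignment():
    """12 conserved + 5 nonconserved (gapped) + 12 conserved columns."""
    c1, gap, c2 = "ACDEFGHIKLMN", "WWWWW", "PQRSTVWYACDE"
    row_a = c1 + gap + c2
    row_b = c1 + "-----" + c2
    return ClusterAlignment("c", {"a": row_a, "b": row_b})


def test_gblocks_conserved_alignment_unchanged():
    rows = {"a": "ACDEFGHIKLMNPQRSTVWY", "b": "ACDEFGHIKLMNPQRSTVWY"}
    aln = ClusterAlignment("c", rows)
    assert gblocks_like(aln, CONSERVATIVE_SETTINGS).rows == rows


def test_gblocks_conservative_removes_long_run():
    got = gblocks_like(_block_alignment(), CONSERVATIVE_SETTINGS)
    assert got.columns == 24  # run of 5 > 4 removed, both 12-blocks kept


def test_gblocks_liberal_retains_short_run():
    got = gblocks_like(_block_alignment(), LIBERAL_SETTINGS)
    assert got.columns == 29  # run of 5 <= 8 stays inside one block


def test_gblocks_settings_validation():
    with pytest.raises(ValueError):
        TrimSettings("gblocks", 0, 10)
    with pytest.raises(ValueError):
        gblocks_like(_block_alignment(), TrimSettings("remgaps"))


@pytest.mark.parametrize("settings", [CONSERVATIVE_SETTINGS, LIBERAL_SETTINGS])
def test_gblocks_invariants_on_random_alignments(rng, settings):
    for _ in range(30):
        aln = random_alignment(rng, n_rows=int(rng.integers(2, 7)),
                               n_cols=int(rng.integers(10, 80)))
        got = gblocks_like(aln, settings)
        # column subsequence property
        names = list(aln.rows)
        in_cols = list(zip(*(aln.rows[n] for n in names)))
        out_cols = list(zip(*(got.rows[n] for n in names))) if got.columns else []
        it = iter(range(len(in_cols)))
        for oc in out_cols:
            assert any(in_cols[i] == oc for i in it)
        # nonconserved runs in the output never exceed the allowance
        conserved = trim._conserved_mask(got) if got.columns else np.array([], bool)
        run = 0
        for flag in conserved:
            run = 0 if flag else run + 1
            assert run <= settings.max_contiguous_nonconserved


def test_trim_row_order_independent(rng):
    aln = random_alignment(rng, n_rows=5, n_cols=60)
    rev = ClusterAlignment(aln.cluster_id, dict(reversed(list(aln.rows.items()))))
    for settings in (CONSERVATIVE_SETTINGS, LIBERAL_SETTINGS):
        a = gblocks_like(aln, settings)
        b = gblocks_like(rev, settings)
        assert {n: s for n, s in a.rows.items()} == {n: s for n, s in b.rows.items()}


def test_min_length_filter():
    alns = [ClusterAlignment(f"c{i}", {"a": "A" * n, "b": "C" * n})
            for i, n in enumerate([5, 100, 99])]
    assert [a.cluster_id for a in min_length_filter(alns, 100)] == ["c1"]
    assert len(min_length_filter(alns, 1)) == 3
    with pytest.raises(ValueError):
        min_length_filter(alns, 0)
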