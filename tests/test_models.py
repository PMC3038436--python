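"""Substitution-model machinery: CTMC, pruning likelihood, AIC ranking."""

import dataclasses

import numpy as np
import pytest

from _oracles import exhaustive_log_likelihood, simulate_alignment
from minihal import models
from minihal.models import (
    ModelScore,
    discrete_gamma_rates,
    load_model,
    log_likelihood,
    rank_models,
    summarize_models,
)
from minihal.njtree import Node, PhyloTree


@pytest.fixture(scope="module")
def jtt():
    return load_model("JTT")


def tree_2taxon(t=0.3):
    return PhyloTree(Node(children=[
        Node(name="a", length=t / 2), Node(name="b", length=t / 2)
    ]), rooted=True)


def tree_5taxon():
    return PhyloTree(Node(children=[
        Node(children=[Node(name="a", length=0.1), Node(name="b", length=0.2)],
             length=0.15),
        Node(children=[Node(name="c", length=0.12),
                       Node(children=[Node(name="d", length=0.3),
                                      Node(name="e", length=0.05)], length=0.08)],
             length=0.1),
    ]))


def test_transition_matrix_identity_and_ergodic_limit(jtt):
    assert np.allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-12)
    p = jtt.transition_matrix(1000.0)
    assert np.abs(p - jtt.frequencies[None, :]).max() < 1e-6
    with pytest.raises(ValueError):
        jtt.transition_matrix(-0.1)


@pytest.mark.parametrize("name", models.MODEL_NAMES)
def test_models_are_proper_reversible_ctmcs(name):
    m = load_model(name)
    assert m.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
    for t in (0.05, 0.7, 2.3):
        p = m.transition_matrix(t)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-9
        flux = m.frequencies[:, None] * p
        assert np.abs(flux - flux.T).max() < 1e-8  # detailed balance


def test_chapman_kolmogorov(jtt):
    for s, t in ((0.1, 0.4), (0.25, 1.3)):
        lhs = jtt.transition_matrix(s) @ jtt.transition_matrix(t)
        assert np.abs(lhs - jtt.transition_matrix(s + t)).max() < 1e-8


def test_discrete_gamma_rates_mean_one():
    for alpha in (0.2, 1.0, 5.0):
        r = discrete_gamma_rates(alpha)
        assert r.shape == (4,)
        assert np.all(np.diff(r) > 0)
        assert r.mean() == pytest.approx(1.0, abs=1e-8)
    assert np.abs(discrete_gamma_rates(1e5) - 1).max() < 0.02


def test_two_taxon_closed_form(jtt, rng):
    t = 0.47
    tree = tree_2taxon(t)
    aa = np.array(list(models.AA_ORDER))
    rows = {
        "a": "".join(aa[rng.integers(0, 20, 40)]),
        "b": "".join(aa[rng.integers(0, 20, 40)]),
    }
    lnl = log_likelihood(rows, tree, jtt)
    p = jtt.transition_matrix(t)
    pi = jtt.frequencies
    expected = sum(
        np.log(pi[models._AA_INDEX[x]] * p[models._AA_INDEX[x], models._AA_INDEX[y]])
        for x, y in zip(rows["a"], rows["b"])
    )
    assert lnl == pytest.approx(expected, abs=1e-9)


def test_all_ambiguous_column_contributes_zero(jtt):
    tree = tree_2taxon()
    base = {"a": "MK", "b": "ML"}
    plus = {"a": "MK?", "b": "ML-"}
    assert log_likelihood(plus, tree, jtt) == pytest.approx(
        log_likelihood(base, tree, jtt), abs=1e-10
    )


def test_rerooting_invariance(jtt, rng):
    tree = tree_5taxon()
    rows = simulate_alignment(tree, jtt, 25, rng)
    lnl = log_likelihood(rows, tree, jtt)
    # reroot: pull 'c' side up as root child arrangement
    r = tree.root
    alt = PhyloTree(Node(children=[
        r.children[1].children[0],
        Node(children=[r.children[1].children[1],
                       Node(children=r.children[0].children,
                            length=r.children[0].length + r.children[1].length)],
             length=0.0),
    ]))
    assert log_likelihood(rows, alt, jtt) == pytest.approx(lnl, abs=1e-8)


def test_pruning_equals_exhaustive_oracle(jtt, rng):
    tree = tree_5taxon()
    rows = simulate_alignment(tree, jtt, 10, rng)
    rows = {k: v[:8] + "?X" for k, v in rows.items()}  # include ambiguity
    assert log_likelihood(rows, tree, jtt) == pytest.approx(
        exhaustive_log_likelihood(rows, tree, jtt), abs=1e-6
    )


def test_gamma_with_huge_alpha_converges_to_no_gamma(jtt, rng):
    tree = tree_5taxon()
    rows = simulate_alignment(tree, jtt, 30, rng)
    plain = log_likelihood(rows, tree, jtt)
    g = dataclasses.replace(jtt, plus_G=True, alpha=1e4)
    assert log_likelihood(rows, tree, g) == pytest.approx(plain, abs=1e-3)


def test_aic_arithmetic_and_penalty_ordering():
    s = ModelScore("a", "X", -1234.5, 1, 2 * 1 - 2 * -1234.5)
    assert s.aic == 2471.0
    # identical lnL, smaller k ranks first
    lo = ModelScore("a", "Low", -100.0, 1, 2 * 1 + 200.0)
    hi = ModelScore("a", "High", -100.0, 19, 2 * 19 + 200.0)
    assert sorted([hi, lo], key=lambda x: (x.aic, x.model_name))[0] is lo


def test_true_generating_matrix_wins_aic(rng):
    wag = load_model("WAG")
    tree = tree_5taxon()
    rows = simulate_alignment(tree, wag, 400, rng)
    scores = rank_models(rows, tree, model_names=("WAG", "Dayhoff"))
    best_wag = min(s.aic for s in scores if s.model_name.startswith("WAG"))
    best_day = min(s.aic for s in scores if s.model_name.startswith("Dayhoff"))
    assert best_wag < best_day
    assert scores == sorted(scores, key=lambda s: (s.aic, s.model_name))
    for s in scores:
        assert s.aic == pytest.approx(2 * s.k - 2 * s.lnL)


def test_summarize_models_counting_and_tie_break():
    def mk(aid, name):
        return [ModelScore(aid, name, -10.0, 0, 20.0)]

    best, tables, freq, one = summarize_models(
        {"a1": mk("a1", "WAG"), "a2": mk("a2", "WAG"), "a3": mk("a3", "JTT")}
    )
    assert best == {"a1": "WAG", "a2": "WAG", "a3": "JTT"}
    assert freq == {"WAG": 2, "JTT": 1} and one == "WAG"
    # single alignment: its best model is the choice
    _, _, _, only = summarize_models({"a": mk("a", "LG+G")})
    assert only == "LG+G"
    # tie -> lexicographically smallest
    _, _, _, tie = summarize_models({"a": mk("a", "WAG"), "b": mk("b", "JTT")})
    assert tie == "JTT"
    with pytest.raises(ValueError):
        summarize_models({})
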