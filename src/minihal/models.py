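"""Amino-acid substitution models, pruning likelihoods and AIC ranking.

Five published empirical exchangeability sets (Dayhoff, JTT, WAG, LG,
RtREV) are shipped as PAML-style lower-triangle text files.  Each defines a
time-reversible CTMC rate matrix Q_ij = s_ij * pi_j (i != j), scaled so the
expected number of substitutions per unit time equals one.  Transition
matrices P(t) = exp(Qt) come from the symmetric eigendecomposition of
D^1/2 Q D^-1/2 (D = diag(pi)), which is cached per model.

Likelihoods are computed by Felsenstein's pruning algorithm over compressed
site patterns, with per-node rescaling to avoid underflow.  Optional model
extensions: ``+F`` replaces the model's stationary frequencies with the
frequencies observed in the alignment, and ``+G`` averages the column
likelihood over four equal-probability discrete-gamma rate categories
(category rates = mean of each quantile bin).

Model choice follows the Akaike information criterion, AIC = 2k - 2 lnL,
with branch lengths held fixed on a common base tree across all candidate
models (a fast-optimization scheme: only the gamma shape is optimized per
variant).  Ranked tables, a per-alignment best-model list, a best-model
frequency summary and per-cluster model assignments for the partition file
are derived from the scores.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from collections import Counter

import numpy as np
from scipy.stats import gamma as _gamma_dist

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
MODEL_NAMES = ("Dayhoff", "JTT", "WAG", "LG", "RtREV")
N_GAMMA_CATEGORIES = 4


def _read_paml(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle exchangeabilities + frequencies from a data file."""
    text = (
        importlib.resources.files("minihal")
        .joinpath(f"data/{name.lower()}.dat")
        .read_text()
    )
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    tri, freqs = rows[:19], np.array(rows[19])
    s = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        s[i, : len(row)] = row
    s = s + s.T
    freqs = freqs / freqs.sum()
    return s, freqs


@dataclasses.dataclass
class SubstitutionModel:
    """An empirical AA model, optionally with +F frequencies and +G rates."""

    name: str
    exchangeabilities: np.ndarray  # 20x20 symmetric, zero diagonal
    frequencies: np.ndarray       # length 20, sums to 1
    plus_F: bool = False
    plus_G: bool = False
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self._decompose()

    def _decompose(self) -> None:
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.sum(pi * np.diag(q))  # expected rate
        q /= mu
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        sym = (sym + sym.T) / 2.0
        lam, u = np.linalg.eigh(sym)
        self._lam = lam
        self._u = u
        self._d = d

    @property
    def variant_name(self) -> str:
        return self.name + ("+G" if self.plus_G else "") + ("+F" if self.plus_F else "")

    @property
    def free_params(self) -> int:
        # branch lengths are shared across candidates and excluded
        return (1 if self.plus_G else 0) + (19 if self.plus_F else 0)

    def with_frequencies(self, freqs: np.ndarray) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.exchangeabilities, np.asarray(freqs, dtype=float),
            plus_F=True, plus_G=self.plus_G, alpha=self.alpha,
        )

    def rates(self) -> np.ndarray:
        """Per-category relative rates (mean 1)."""
        if not self.plus_G:
            return np.array([1.0])
        return discrete_gamma_rates(self.alpha, N_GAMMA_CATEGORIES)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1; t = 0 gives the identity."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        e = np.exp(self._lam * t)
        d = self._d
        p = (self._u * e[None, :]) @ self._u.T
        p = (p / d[:, None]) * d[None, :]
        return np.clip(p, 0.0, None)


def discrete_gamma_rates(alpha: float, k: int = N_GAMMA_CATEGORIES) -> np.ndarray:
    """Mean-of-quantile-bin category rates for a mean-one gamma."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = _gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = _gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    return k * (upper - lower)


def load_model(name: str, plus_F: bool = False, plus_G: bool = False,
               alpha: float = 1.0) -> SubstitutionModel:
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    s, freqs = _read_paml(name)
    return SubstitutionModel(name, s, freqs, plus_F=plus_F, plus_G=plus_G, alpha=alpha)


# ---------------------------------------------------------------------------
# likelihood

def encode_alignment(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Rows to integer codes; anything outside the 20 standard residues
    (gaps, '?', X, B, Z, ...) codes as 20 = fully ambiguous."""
    names = list(rows)
    mat = np.full((len(names), len(next(iter(rows.values()), ""))), 20, dtype=np.int8)
    for i, n in enumerate(names):
        mat[i] = [_AA_INDEX.get(c, 20) for c in rows[n]]
    return names, mat


def observed_frequencies(rows: dict[str, str], pseudocount: float = 0.05) -> np.ndarray:
    counts = Counter()
    for s in rows.values():
        counts.update(c for c in s if c in _AA_INDEX)
    v = np.array([counts.get(a, 0) for a in AA_ORDER], dtype=float) + pseudocount
    return v / v.sum()


def log_likelihood(rows: dict[str, str], tree, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a tree with branch lengths.

    ``tree`` is any object with a ``root`` node exposing ``children``
    (list), ``name`` and ``length``; leaves are matched to alignment rows by
    name.  Missing data symbols are treated as fully ambiguous.  With
    ``plus_G`` the column likelihood averages over the discrete-gamma
    categories.
    """
    names, mat = encode_alignment(rows)
    index = {n: i for i, n in enumerate(names)}
    root = getattr(tree, "root", tree)
    for leaf in _leaves(root):
        if leaf.name not in index:
            raise KeyError(f"tree leaf {leaf.name!r} missing from alignment")

    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    npat = patterns.shape[0]
    # leaf partials: identity row for a residue, ones for ambiguity
    eye21 = np.vstack([np.eye(20), np.ones(20)])

    rates = model.rates()
    total = np.zeros(npat)
    pi = model.frequencies
    per_rate = []
    for r in rates:
        logscale = np.zeros(npat)

        def prune(node):
            nonlocal logscale
            if not node.children:
                return eye21[patterns[:, index[node.name]]]
            part = np.ones((npat, 20))
            for child in node.children:
                p = model.transition_matrix(max(child.length or 0.0, 0.0) * r)
                part = part * (prune(child) @ p.T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            return part / mx[:, None]

        partial = prune(root)
        per_rate.append(np.log(np.maximum(partial @ pi, 1e-300)) + logscale)
    stacked = np.stack(per_rate)  # (ncat, npat)
    m = stacked.max(axis=0)
    total = m + np.log(np.mean(np.exp(stacked - m[None, :]), axis=0))
    return float(np.dot(total, counts))


def _leaves(node):
    if not node.children:
        yield node
    else:
        for c in node.children:
            yield from _leaves(c)


# ---------------------------------------------------------------------------
# AIC ranking

@dataclasses.dataclass(frozen=True)
class ModelScore:
    alignment_id: str
    model_name: str
    lnL: float
    k: int
    aic: float


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-3,
                        max_iter: int = 60) -> tuple[float, float]:
    """Maximize a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, max(fc, fd)


def rank_models(
    rows: dict[str, str],
    base_tree,
    alignment_id: str = "aln",
    model_names: tuple[str, ...] = MODEL_NAMES,
    alpha_bounds: tuple[float, float] = (0.05, 50.0),
) -> list[ModelScore]:
    """Score every (matrix) x {base, +G, +F, +G+F} variant by AIC.

    Branch lengths of ``base_tree`` are held fixed; only the gamma shape is
    optimized (golden-section).  Ties in AIC break by model name.
    """
    obs = observed_frequencies(rows)
    scores = []
    for name in model_names:
        base = load_model(name)
        for plus_G in (False, True):
            for plus_F in (False, True):
                model = base.with_frequencies(obs) if plus_F else base
                if plus_G:
                    def f(alpha, _m=model):
                        m = dataclasses.replace(_m, plus_G=True, alpha=alpha)
                        return log_likelihood(rows, base_tree, m)
                    _, lnl = _golden_section_max(f, *alpha_bounds)
                    model = dataclasses.replace(model, plus_G=True)
                else:
                    lnl = log_likelihood(rows, base_tree, model)
                k = model.free_params
                scores.append(
                    ModelScore(alignment_id, model.variant_name, lnl, k, 2 * k - 2 * lnl)
                )
    scores.sort(key=lambda s: (s.aic, s.model_name))
    return scores


def summarize_models(
    ranked: dict[str, list[ModelScore]]
) -> tuple[dict[str, str], dict[str, list[ModelScore]], dict[str, int], str]:
    """The four summary outputs of model testing.

    Returns (best model per alignment, ranked tables, frequency of
    top-ranked models, single most-frequent best model).  A frequency tie
    picks the lexicographically smallest model name.
    """
    if not ranked:
        raise ValueError("no alignments scored")
    best = {aid: scores[0].model_name for aid, scores in ranked.items()}
    freq = Counter(best.values())
    top = min(m for m, c in freq.items() if c == max(freq.values()))
    return best, ranked, dict(freq), top


def write_best_models(best: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("alignment_id\tbest_model\n")
        for aid in sorted(best):
            fh.write(f"{aid}\t{best[aid]}\n")


def write_ranked_models(ranked: dict[str, list[ModelScore]], path) -> None:
    with open(path, "w") as fh:
        fh.write("alignment_id\trank\tmodel\tlnL\tk\taic\n")
        for aid in sorted(ranked):
            for rank, s in enumerate(ranked[aid], start=1):
                fh.write(f"{aid}\t{rank}\t{s.model_name}\t{s.lnL:.6f}\t{s.k}\t{s.aic:.6f}\n")


def write_model_frequencies(freq: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("model\tn_best\n")
        for m in sorted(freq, key=lambda m: (-freq[m], m)):
            fh.write(f"{m}\t{freq[m]}\n")
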