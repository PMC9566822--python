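"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — brute-force scans, closed-form
formulas, textbook linear algebra, a pure-Python Gibbs sampler — and shares
no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math
import re
import unicodedata

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# brute-force lexicon matcher: substring scan with manual boundary checks
def _is_word_char(c: str) -> bool:
    return c.isalnum() or c in "_'"


def brute_force_match(text: str, lexicon_entries: dict) -> set[str]:
    """All subgroups whose terms occur in text at word boundaries."""
    norm = unicodedata.normalize("NFKC", text).casefold()
    norm_ws = re.sub(r"\s+", " ", norm)
    groups: set[str] = set()
    for term, gs in lexicon_entries.items():
        t = re.sub(r"\s+", " ", term)
        start = 0
        while True:
            i = norm_ws.find(t, start)
            if i < 0:
                break
            before_ok = i == 0 or not _is_word_char(norm_ws[i - 1])
            j = i + len(t)
            after_ok = j == len(norm_ws) or not _is_word_char(norm_ws[j])
            if before_ok and after_ok:
                groups |= set(gs)
                break
            start = i + 1
    return groups


# ---------------------------------------------------------------------------
# Wilson score interval, coded directly from the closed form
def wilson_formula(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return center - half, center + half


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank: literal enumeration over all 2^n sign assignments
def wilcoxon_brute_force(diffs: np.ndarray) -> tuple[float, float]:
    """(W, exact two-sided p) by enumerating every sign vector."""
    d = diffs[diffs != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_low, w_high = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    n_assign = 2**n
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_all = signs @ ranks
    count = int(np.sum((w_all <= w_low + 1e-9) | (w_all >= w_high - 1e-9)))
    return w_obs, count / n_assign


# ---------------------------------------------------------------------------
# textbook OLS via normal equations with explicit inference
def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> dict:
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    ybar = y.mean()
    ss_tot = float(((y - ybar) ** 2).sum())
    ss_res = float(resid @ resid)
    df_model = p - 1
    if ss_res == 0:
        fval = np.inf if ss_tot > 0 else 0.0
        f_p = 0.0 if ss_tot > 0 else 1.0
    else:
        fval = ((ss_tot - ss_res) / df_model) / (ss_res / dof)
        f_p = float(stats.f.sf(fval, df_model, dof))
    return {"beta": beta, "se": se, "t": t, "p": pvals, "F": fval, "F_p": f_p}


# ---------------------------------------------------------------------------
# naive pure-Python collapsed Gibbs sampler for LDA
def naive_gibbs_lda(docs, K, V, alpha, beta, n_sweeps, seed):
    """Independent reference sampler; returns (z, n_kw, n_dk, n_k)."""
    rng = np.random.default_rng(seed)
    flat = [(d, w) for d, doc in enumerate(docs) for w in doc]
    D = len(docs)
    z = [int(rng.integers(K)) for _ in flat]
    n_kw = np.zeros((K, V), dtype=int)
    n_dk = np.zeros((D, K), dtype=int)
    n_k = np.zeros(K, dtype=int)
    for (d, w), k in zip(flat, z):
        n_kw[k, w] += 1
        n_dk[d, k] += 1
        n_k[k] += 1
    for _ in range(n_sweeps):
        for i, (d, w) in enumerate(flat):
            k = z[i]
            n_kw[k, w] -= 1
            n_dk[d, k] -= 1
            n_k[k] -= 1
            probs = (n_dk[d] + alpha) * (n_kw[:, w] + beta) / (n_k + V * beta)
            probs = probs / probs.sum()
            k = int(rng.choice(K, p=probs))
            z[i] = k
            n_kw[k, w] += 1
            n_dk[d, k] += 1
            n_k[k] += 1
    return z, n_kw, n_dk, n_k


# ---------------------------------------------------------------------------
# heldout perplexity by direct summation given explicit phi and theta
def perplexity_direct(phi: np.ndarray, theta: np.ndarray, docs) -> float:
    total, n = 0.0, 0
    for d, doc in enumerate(docs):
        for w in doc:
            p = 0.0
            for k in range(phi.shape[0]):
                p += theta[d, k] * phi[k, w]
            total += math.log(p)
            n += 1
    return math.exp(-total / n)


# ---------------------------------------------------------------------------
# UMass coherence by direct pairwise counting
def umass_direct(top_terms_per_topic, docs) -> float:
    doc_sets = [set(d) for d in docs]
    topic_scores = []
    for top in top_terms_per_topic:
        pair_scores = []
        for i in range(1, len(top)):
            for j in range(i):
                wi, wj = top[i], top[j]
                co = sum(1 for s in doc_sets if wi in s and wj in s)
                dj = sum(1 for s in doc_sets if wj in s)
                pair_scores.append(math.log((co + 1) / max(dj, 1)))
        topic_scores.append(sum(pair_scores) / len(pair_scores))
    return sum(topic_scores) / len(topic_scores)


def greedy_matched_cosine(phi_est: np.ndarray, phi_true: np.ndarray) -> float:
    """Mean cosine similarity under greedy one-to-one topic matching."""
    a = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    sim = a @ b.T
    scores = []
    for _ in range(sim.shape[0]):
        k, j = np.unravel_index(np.argmax(sim), sim.shape)
        scores.append(float(sim[k, j]))
        sim[k, :] = -np.inf
        sim[:, j] = -np.inf
    return float(np.mean(scores))
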