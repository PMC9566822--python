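"""Topic modelling of matched tweets: preprocessing, collapsed-Gibbs LDA,
perplexity/coherence diagnostics, model-size selection, and topic-share
time series.

The sampler is latent Dirichlet allocation with symmetric Dirichlet priors
(α on doc-topic mixtures, β on topic-word distributions) fitted by collapsed
Gibbs sampling: document and topic distributions are integrated out and the
per-token topic assignments are resampled in sweeps.  Defaults follow the
common convention α = 50/K, β = 0.01.

The model object / results object split follows statsmodels: build a
:class:`GibbsLDA` from tokenized documents, call ``fit()`` and work with the
returned :class:`LdaResults`.
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _gibbs
from .trends import period_key

logger = logging.getLogger(__name__)

__all__ = [
    "TokenizedDoc",
    "Vocabulary",
    "LdaState",
    "GibbsLDA",
    "LdaResults",
    "load_default_stopwords",
    "preprocess_for_topics",
    "fit_lda",
    "log_perplexity",
    "umass_coherence",
    "select_num_topics",
    "topic_share_series",
]

_TOKEN_RE = re.compile(r"[a-z][a-z0-9_']*")


@dataclass
class TokenizedDoc:
    doc_id: str
    tokens: list[int]  # vocabulary indices; unigrams plus adjoined bigrams


@dataclass
class Vocabulary:
    index: dict[str, int]
    tokens: list[str]
    doc_freq: np.ndarray

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        return self.index[token]

    def word(self, i: int) -> str:
        return self.tokens[i]


def load_default_stopwords() -> frozenset[str]:
    """Packaged snapshot of a standard English stopword list."""
    path = Path(str(resources.files("mhpulse").joinpath("data", "stopwords_en.txt")))
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def preprocess_for_topics(
    texts: Sequence[str],
    stopwords: Optional[Iterable[str]] = None,
    bigram_min_count: int = 5,
    doc_ids: Optional[Sequence[str]] = None,
) -> tuple[list[TokenizedDoc], Vocabulary]:
    """Tokenize tweets for topic modelling.

    Lower-cases (NFKC), keeps letter-initial tokens only (numbers and
    symbol runs drop out), removes stopwords, and adjoins bigrams of
    adjacent surviving tokens that occur at least ``bigram_min_count`` times
    in the corpus (as ``left_right`` tokens appended to the document).
    Documents empty after cleaning are dropped with a logged count; all
    documents empty is an error.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    stop = {unicodedata.normalize("NFKC", w).casefold() for w in stopwords}
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(texts))]

    unigrams_per_doc: list[list[str]] = []
    for text in texts:
        norm = unicodedata.normalize("NFKC", text).casefold()
        toks = [t for t in _TOKEN_RE.findall(norm) if t not in stop]
        unigrams_per_doc.append(toks)

    bigram_counts: dict[tuple[str, str], int] = {}
    for toks in unigrams_per_doc:
        for a, b in zip(toks, toks[1:]):
            bigram_counts[(a, b)] = bigram_counts.get((a, b), 0) + 1
    keep_bigrams = {bg for bg, c in bigram_counts.items() if c >= bigram_min_count}

    token_lists: list[list[str]] = []
    for toks in unigrams_per_doc:
        bigrams = [f"{a}_{b}" for a, b in zip(toks, toks[1:]) if (a, b) in keep_bigrams]
        token_lists.append(toks + bigrams)

    vocab_index: dict[str, int] = {}
    doc_freq: dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            doc_freq[t] = doc_freq.get(t, 0) + 1
    for t in sorted(doc_freq):
        vocab_index[t] = len(vocab_index)

    docs: list[TokenizedDoc] = []
    n_dropped = 0
    for doc_id, toks in zip(doc_ids, token_lists):
        if not toks:
            n_dropped += 1
            continue
        docs.append(TokenizedDoc(doc_id=str(doc_id), tokens=[vocab_index[t] for t in toks]))
    if n_dropped:
        logger.info("dropped %d documents empty after cleaning", n_dropped)
    if not docs:
        raise ValueError("all documents empty after cleaning")
    tokens = sorted(vocab_index, key=vocab_index.get)
    df = np.array([doc_freq[t] for t in tokens], dtype=np.int64)
    return docs, Vocabulary(index=vocab_index, tokens=tokens, doc_freq=df)


@dataclass
class LdaState:
    """Sufficient statistics of a collapsed-Gibbs LDA fit."""

    K: int
    alpha: float
    beta: float
    z: np.ndarray          # topic assignment per token position
    n_kw: np.ndarray       # K × V topic-word counts
    n_dk: np.ndarray       # D × K doc-topic counts
    n_k: np.ndarray        # per-topic token totals
    rng_seed: int
    doc_ids: list[str] = field(default_factory=list)

    @property
    def V(self) -> int:
        return self.n_kw.shape[1]

    @property
    def D(self) -> int:
        return self.n_dk.shape[0]

    def check_invariants(self, doc_of: Optional[np.ndarray] = None,
                         word_of: Optional[np.ndarray] = None) -> None:
        """Count-conservation checks; with token arrays, full z-consistency."""
        if np.any(self.n_kw < 0) or np.any(self.n_dk < 0) or np.any(self.n_k < 0):
            raise AssertionError("negative counts")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise AssertionError("n_kw row sums != n_k")
        if self.n_dk.sum() != self.n_k.sum():
            raise AssertionError("doc-topic and topic totals disagree")
        if doc_of is not None and word_of is not None:
            n_kw = np.zeros_like(self.n_kw)
            n_dk = np.zeros_like(self.n_dk)
            np.add.at(n_kw, (self.z, word_of), 1)
            np.add.at(n_dk, (doc_of, self.z), 1)
            if not (np.array_equal(n_kw, self.n_kw) and np.array_equal(n_dk, self.n_dk)):
                raise AssertionError("counts inconsistent with assignments z")

    def phi(self) -> np.ndarray:
        """Posterior-mean topic-word distributions (K × V, rows sum to 1)."""
        return (self.n_kw + self.beta) / (self.n_k[:, None] + self.V * self.beta)

    def theta(self) -> np.ndarray:
        """Posterior-mean doc-topic mixtures (D × K, rows sum to 1)."""
        lengths = self.n_dk.sum(axis=1, keepdims=True)
        return (self.n_dk + self.alpha) / (lengths + self.K * self.alpha)


def _flatten(docs: Sequence[TokenizedDoc]) -> tuple[np.ndarray, np.ndarray]:
    doc_of = np.concatenate([np.full(len(d.tokens), i, dtype=np.int32)
                             for i, d in enumerate(docs)])
    word_of = np.concatenate([np.asarray(d.tokens, dtype=np.int32) for d in docs])
    return doc_of, word_of


class GibbsLDA:
    """LDA model over tokenized documents, fitted by collapsed Gibbs sampling."""

    def __init__(
        self,
        docs: Sequence[TokenizedDoc],
        n_vocab: int,
        K: int,
        alpha: Optional[float] = None,
        beta: float = 0.01,
        vocabulary: Optional[Vocabulary] = None,
    ):
        if K < 2:
            raise ValueError("K must be >= 2")
        if not docs:
            raise ValueError("no documents")
        if any(not d.tokens for d in docs):
            raise ValueError("empty documents must be dropped before fitting")
        total_tokens = sum(len(d.tokens) for d in docs)
        if K > total_tokens:
            raise ValueError(f"K={K} exceeds total token count {total_tokens}")
        self.docs = list(docs)
        self.n_vocab = int(n_vocab)
        self.K = int(K)
        self.alpha = float(alpha) if alpha is not None else 50.0 / K
        self.beta = float(beta)
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("concentrations must be positive")
        self.vocabulary = vocabulary
        self._doc_of, self._word_of = _flatten(self.docs)

    def fit(self, n_iterations: int = 1000, seed: int = 0,
            check_invariants: bool = False) -> "LdaResults":
        """Run ``n_iterations`` full Gibbs sweeps from a seeded random init."""
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        state = _gibbs.seed_state(seed)
        z, n_kw, n_dk, n_k = _gibbs.init_assignments(
            self._doc_of, self._word_of, self.K, self.n_vocab, state
        )
        lda_state = LdaState(
            K=self.K, alpha=self.alpha, beta=self.beta, z=z,
            n_kw=n_kw, n_dk=n_dk, n_k=n_k, rng_seed=seed,
            doc_ids=[d.doc_id for d in self.docs],
        )
        for sweep in range(n_iterations):
            _gibbs.gibbs_sweep(self._doc_of, self._word_of, z, n_kw, n_dk, n_k,
                               self.alpha, self.beta, state)
            if check_invariants:
                lda_state.check_invariants()
        lda_state.check_invariants(self._doc_of, self._word_of)
        return LdaResults(model=self, state=lda_state)


class LdaResults:
    """Fitted-model view over an :class:`LdaState`."""

    def __init__(self, model: GibbsLDA, state: LdaState):
        self.model = model
        self.state = state

    def phi(self) -> np.ndarray:
        return self.state.phi()

    def theta(self) -> np.ndarray:
        return self.state.theta()

    def modal_topics(self) -> dict[str, int]:
        """Hard topic assignment per document (argmax of smoothed counts)."""
        theta = self.theta()
        modal = theta.argmax(axis=1)
        return {doc_id: int(k) for doc_id, k in zip(self.state.doc_ids, modal)}

    def top_terms(self, topic: int, n: int = 20) -> list[tuple[str, float]]:
        phi_k = self.phi()[topic]
        order = np.argsort(phi_k)[::-1][:n]
        vocab = self.model.vocabulary
        names = [vocab.word(i) if vocab is not None else str(i) for i in order]
        return list(zip(names, phi_k[order].tolist()))

    def summary(self, top_n: int = 10) -> pd.DataFrame:
        rows = []
        for k in range(self.state.K):
            terms = self.top_terms(k, top_n)
            rows.append({
                "topic_id": k,
                "tokens": int(self.state.n_k[k]),
                "top_terms": " ".join(t for t, _ in terms),
            })
        return pd.DataFrame(rows)

    def log_likelihood(self) -> float:
        """Training-corpus log-likelihood under posterior-mean estimates."""
        phi = self.phi()
        theta = self.theta()
        total = 0.0
        for i, d in enumerate(self.model.docs):
            probs = theta[i] @ phi[:, d.tokens]
            total += float(np.log(probs).sum())
        return total


def fit_lda(
    corpus: Sequence[TokenizedDoc],
    K: int,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    n_iterations: int = 1000,
    seed: int = 0,
    n_vocab: Optional[int] = None,
    vocabulary: Optional[Vocabulary] = None,
    check_invariants: bool = False,
) -> LdaState:
    """Functional wrapper over :class:`GibbsLDA`; returns the fitted state."""
    if n_vocab is None:
        n_vocab = len(vocabulary) if vocabulary is not None else (
            max(max(d.tokens) for d in corpus) + 1
        )
    model = GibbsLDA(corpus, n_vocab, K, alpha=alpha, beta=beta, vocabulary=vocabulary)
    return model.fit(n_iterations=n_iterations, seed=seed,
                     check_invariants=check_invariants).state


def log_perplexity(
    state: LdaState,
    heldout: Sequence[TokenizedDoc],
    n_fold_in: int = 30,
    seed: int = 12345,
) -> float:
    """Held-out perplexity exp(−mean per-token log-likelihood).

    Token probabilities are Σ_k θ_dk φ_kw under posterior-mean topic-word
    estimates; held-out doc-topic mixtures come from ``n_fold_in`` Gibbs
    sweeps with the topic-word counts frozen.  Out-of-vocabulary tokens are
    dropped (counted in the log).
    """
    V = state.V
    kept_docs: list[TokenizedDoc] = []
    n_oov = 0
    for d in heldout:
        toks = [t for t in d.tokens if 0 <= t < V]
        n_oov += len(d.tokens) - len(toks)
        if toks:
            kept_docs.append(TokenizedDoc(d.doc_id, toks))
    if n_oov:
        logger.info("dropped %d out-of-vocabulary heldout tokens", n_oov)
    if not kept_docs:
        raise ValueError("no in-vocabulary heldout tokens")

    phi = state.phi()
    doc_of, word_of = _flatten(kept_docs)
    rng = _gibbs.seed_state(seed)
    n_dk = _gibbs.fold_in_sweeps(doc_of, word_of, state.n_kw, state.n_k,
                                 state.K, state.alpha, state.beta,
                                 n_fold_in, rng)
    lengths = n_dk.sum(axis=1, keepdims=True)
    theta = (n_dk + state.alpha) / (lengths + state.K * state.alpha)

    total_ll = 0.0
    n_tokens = 0
    for i, d in enumerate(kept_docs):
        probs = theta[i] @ phi[:, d.tokens]
        total_ll += float(np.log(probs).sum())
        n_tokens += len(d.tokens)
    return math.exp(-total_ll / n_tokens)


def umass_coherence(
    state: LdaState,
    corpus: Sequence[TokenizedDoc],
    top_n: int = 10,
) -> float:
    """Mean UMass coherence over topics.

    Per topic: mean over ordered top-term pairs (i ranked below j) of
    log[(D(w_i, w_j) + 1) / D(w_j)], with document co-occurrence counts from
    the training corpus.  A top term absent from the corpus contributes with
    its document frequency floored at 1, so absence never raises.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    phi = state.phi()
    doc_sets = [set(d.tokens) for d in corpus]

    scores = []
    for k in range(state.K):
        top = np.argsort(phi[k])[::-1][:top_n]
        df = {w: sum(1 for s in doc_sets if w in s) for w in top}
        pair_scores = []
        for i in range(1, len(top)):
            for j in range(i):
                wi, wj = int(top[i]), int(top[j])
                co = sum(1 for s in doc_sets if wi in s and wj in s)
                pair_scores.append(math.log((co + 1) / max(df[wj], 1)))
        scores.append(float(np.mean(pair_scores)))
    return float(np.mean(scores))


def select_num_topics(
    corpus: Sequence[TokenizedDoc],
    K_grid: Sequence[int],
    seeds: Sequence[int] = (0,),
    n_vocab: Optional[int] = None,
    vocabulary: Optional[Vocabulary] = None,
    n_iterations: int = 200,
    heldout_fraction: float = 0.2,
    perplexity_tolerance: float = 0.05,
    coherence_top_n: int = 10,
    beta: float = 0.01,
) -> tuple[int, pd.DataFrame]:
    """Choose the topic count K from a grid by perplexity and coherence.

    For each K (averaged over seeds) the corpus is split into train/held-out
    parts, a model fitted, and held-out perplexity plus UMass coherence
    recorded.  The selected K maximizes coherence among those K whose
    perplexity is within ``perplexity_tolerance`` (relative) of the grid
    minimum.  The full diagnostic table is returned so users can apply any
    other rule.
    """
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    if n_vocab is None:
        n_vocab = len(vocabulary) if vocabulary is not None else (
            max(max(d.tokens) for d in corpus) + 1
        )
    rows = []
    for K in K_grid:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            n_held = max(1, int(len(corpus) * heldout_fraction))
            perm = rng.permutation(len(corpus))
            held_idx = set(perm[:n_held].tolist())
            train = [d for i, d in enumerate(corpus) if i not in held_idx]
            held = [d for i, d in enumerate(corpus) if i in held_idx]
            model = GibbsLDA(train, n_vocab, K, beta=beta, vocabulary=vocabulary)
            res = model.fit(n_iterations=n_iterations, seed=seed)
            perp = log_perplexity(res.state, held, seed=seed)
            coh = umass_coherence(res.state, train, top_n=coherence_top_n)
            rows.append({"K": K, "seed": seed, "perplexity": perp, "coherence": coh})
    diag = pd.DataFrame(rows)
    by_k = diag.groupby("K", as_index=False)[["perplexity", "coherence"]].mean()
    p_min = by_k["perplexity"].min()
    band = by_k[by_k["perplexity"] <= p_min * (1 + perplexity_tolerance)]
    selected = int(band.loc[band["coherence"].idxmax(), "K"])
    return selected, diag


def topic_share_series(
    assignments: Mapping[str, int],
    doc_dates: Mapping[str, "date"],
    granularity: str = "month",
    K: Optional[int] = None,
) -> pd.DataFrame:
    """Per-period topic shares from modal document-topic assignments.

    Shares within each period sum to 1 over topics; periods with no
    documents are omitted.
    """
    if K is None:
        K = max(assignments.values()) + 1
    rows: dict[tuple, np.ndarray] = {}
    for doc_id, topic in assignments.items():
        start, end = period_key(doc_dates[doc_id], granularity)
        key = (start, end)
        if key not in rows:
            rows[key] = np.zeros(K, dtype=np.int64)
        rows[key][topic] += 1
    out = []
    for (start, end), counts in sorted(rows.items()):
        total = counts.sum()
        for k in range(K):
            out.append({
                "period_start": start, "period_end": end, "granularity": granularity,
                "topic_id": k, "n_docs": int(counts[k]),
                "share": counts[k] / total,
            })
    return pd.DataFrame(out)
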