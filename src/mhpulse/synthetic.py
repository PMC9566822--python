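"""Seeded synthetic tweet corpora with known ground truth.

Every downstream stage of the pipeline is testable against this generator:
it plants mental-health keyword occurrences at cohort-specific rates, a
health-care-worker subpopulation identifiable from profile descriptions,
state-resolvable geography (including multi-state users exercising the
removal rule), spam users, URL/retweet/non-English noise, topic structure
from the LDA generative process, and state-specific post-policy step and
slope changes in the daily matched-tweet proportion.

Design notes
------------
* One global seed drives independent per-component substreams
  (users, volumes, noise, topics, text, timestamps), so adding a component
  never perturbs another's draws, and regeneration is bit-identical.
* Nuisance categories (URL, retweet, non-English) are mutually exclusive
  per tweet, which makes the expected filter-cascade accounting exact.
* Spam users emit exactly ``spam_threshold + 100`` matching tweets, so the
  spam filter's effect is deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .ingest import TweetRecord
from .lexicon import SUBGROUPS, MentalHealthLexicon, load_default_mh_lexicon

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_its_series",
    "generate_lda_corpus",
    "write_corpus",
]

COHORTS = ("general", "hcw")

# descriptions that must never match the HCW dictionary
_GENERAL_DESCRIPTIONS = (
    "coffee lover and amateur photographer",
    "sports fan. opinions my own",
    "parent of two, gardener",
    "software tinkerer",
    "",
)
_HCW_DESCRIPTION_TEMPLATES = (
    "ICU {term} at a teaching hospital",
    "{term}, opinions my own",
    "proud {term} fighting the pandemic",
)
_HCW_TERMS = ("doctor", "nurse", "physician", "paramedic", "pharmacist")


def _index_words(n: int) -> list[str]:
    """Pure-letter vocabulary words (zaaa, zaab, ...): never stopwords,
    numbers, or lexicon terms."""
    words = []
    for i in range(n):
        s = ""
        x = i
        for _ in range(4):
            s = chr(97 + x % 26) + s
            x //= 26
        words.append("z" + s)
    return words


@dataclass
class SynthConfig:
    """Study conditions for corpus generation (defaults are the reference
    configuration; see the methods note for the rationale behind each)."""

    n_users: int = 1000
    hcw_fraction: float = 0.01
    states: Sequence[tuple[str, float]] = (
        ("Michigan", 0.24),
        ("Pennsylvania", 0.24),
        ("Ohio", 0.20),
        ("North Carolina", 0.18),
        ("Texas", 0.14),
    )
    date_range: tuple[date, date] = (date(2020, 2, 1), date(2020, 5, 31))
    policy_dates: Mapping[str, date] = field(default_factory=lambda: {
        "Michigan": date(2020, 3, 24),
        "North Carolina": date(2020, 3, 30),
        "Ohio": date(2020, 3, 23),
        "Pennsylvania": date(2020, 4, 1),
    })
    # per-tweet subgroup emission probabilities, (cohort, subgroup) -> prob;
    # general rates follow the reported per-symptom tweet shares of a COVID
    # stream (~1% anxiety/depression, ~0.1% insomnia/addiction), HCW higher
    baseline_rates: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("general", "anxiety"): 0.0103,
        ("general", "depression"): 0.0126,
        ("general", "insomnia"): 0.0013,
        ("general", "addiction"): 0.0009,
        ("hcw", "anxiety"): 0.0110,
        ("hcw", "depression"): 0.0152,
        ("hcw", "insomnia"): 0.0025,
        ("hcw", "addiction"): 0.0014,
    })
    # state -> (step change delta, slope change gamma) on the daily-proportion scale
    its_effects: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "Michigan": (-0.0214, 0.002),
        "North Carolina": (-0.0228, 0.0017),
        "Ohio": (-0.0117, 0.0012),
        "Pennsylvania": (0.0288, -0.0012),
    })
    its_window_days: int = 15
    noise_sd: float = 0.003
    # (K_true, vocab_size, mean doc length, alpha, beta)
    topic_params: tuple[int, int, float, float, float] = (5, 200, 8.0, 0.1, 0.01)
    nuisance_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "url": 0.30, "retweet": 0.20, "non_english": 0.10, "multi_state_user": 0.05,
    })
    spam_users: int = 0
    spam_threshold: int = 1000
    tweets_per_user_mean: float = 10.0
    geotag_fraction: float = 0.19
    location_fraction: float = 0.30
    cohort_topic_weights: Optional[Mapping[str, Sequence[float]]] = None
    seed: int = 0

    def validate(self) -> None:
        probs = [self.hcw_fraction, self.geotag_fraction, self.location_fraction]
        probs += list(self.baseline_rates.values())
        probs += list(self.nuisance_fractions.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        nf = self.nuisance_fractions
        if nf.get("url", 0) + nf.get("retweet", 0) + nf.get("non_english", 0) >= 1.0:
            raise ValueError("per-tweet nuisance fractions must sum to < 1")
        start, end = self.date_range
        if (end - start).days < 31:
            raise ValueError("date_range must span at least 31 days")
        for state, pdate in self.policy_dates.items():
            if state in self.its_effects:
                lo = pdate - timedelta(days=self.its_window_days)
                hi = pdate + timedelta(days=self.its_window_days - 1)
                if lo < start or hi > end:
                    raise ValueError(
                        f"date span too short for the ±{self.its_window_days}-day "
                        f"policy window of {state}"
                    )
        weights = [w for _, w in self.states]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("state sampling probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated corpus."""

    tweet_subgroups: dict[str, list[str]]       # tweet id -> planted labels
    tweet_topics: dict[str, int]                # tweet id -> dominant topic
    user_cohort: dict[str, str]
    user_state: dict[str, Optional[str]]
    true_phi: np.ndarray                        # K_true × V topic-word simplex rows
    its_effects: dict[str, tuple[float, float]]
    spam_user_ids: list[str]
    multi_state_user_ids: list[str]
    noise_tweet_ids: dict[str, list[str]]       # category -> tweet ids
    stage_counts: dict[str, int]                # expected FilterReport fields
    n_tweets: int = 0

    def to_json(self) -> dict:
        return {
            "tweet_subgroups": self.tweet_subgroups,
            "tweet_topics": self.tweet_topics,
            "user_cohort": self.user_cohort,
            "user_state": self.user_state,
            "true_phi": self.true_phi.tolist(),
            "its_effects": {s: list(v) for s, v in self.its_effects.items()},
            "spam_user_ids": self.spam_user_ids,
            "multi_state_user_ids": self.multi_state_user_ids,
            "noise_tweet_ids": self.noise_tweet_ids,
            "stage_counts": self.stage_counts,
            "n_tweets": self.n_tweets,
        }


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            for i in range(n)]


def generate_its_series(
    beta0: float,
    beta1: float,
    delta: float,
    gamma: float,
    n_pre: int,
    n_post: int,
    sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Daily proportion series from the segmented-linear model.

    y_t = beta0 + beta1 t + delta P_t + gamma t P_t + N(0, sigma²),
    t = 1..n_pre+n_post, P_t = 1 from t = n_pre + 1 onward.
    """
    if n_pre < 2 or n_post < 2:
        raise ValueError("n_pre and n_post must each be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.arange(1, n_pre + n_post + 1, dtype=float)
    P = (t > n_pre).astype(float)
    y = beta0 + beta1 * t + delta * P + gamma * t * P
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=y.size)
    return y


def generate_lda_corpus(
    K_true: int,
    vocab_size: int,
    n_docs: int,
    alpha: float,
    beta: float,
    seed: int = 0,
    doc_length: float = 60.0,
    phi: Optional[np.ndarray] = None,
) -> tuple[list[list[int]], np.ndarray]:
    """Documents drawn i.i.d. from the LDA generative process.

    Returns token-index documents and the true K×V topic-word matrix
    (rows drawn from Dirichlet(beta) unless ``phi`` is given).  Document
    lengths are Poisson(doc_length) floored at 1.
    """
    if K_true < 2:
        raise ValueError("K_true must be >= 2")
    if vocab_size <= K_true:
        raise ValueError("vocab_size must exceed K_true")
    if alpha <= 0 or beta <= 0:
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    if phi is None:
        phi = rng.dirichlet(np.full(vocab_size, beta), size=K_true)
    docs: list[list[int]] = []
    for _ in range(n_docs):
        theta = rng.dirichlet(np.full(K_true, alpha))
        n = max(1, int(rng.poisson(doc_length)))
        topics = rng.choice(K_true, size=n, p=theta)
        words = [int(rng.choice(vocab_size, p=phi[k])) for k in topics]
        docs.append(words)
    return docs, phi


def _state_day_multiplier(config: SynthConfig, base_p: float,
                          state: str, day: date,
                          noise: float) -> float:
    """Target any-match proportion for (state, day), relative to baseline.

    Inside the ±window around the state's policy date the segmented model
    p(t) = base + delta*P + gamma*t*P applies (t = 1..2w as in the ITS
    design); elsewhere p = base.  Gaussian day-level noise is added on the
    proportion scale.
    """
    p = base_p
    if state in config.its_effects and state in config.policy_dates:
        pdate = config.policy_dates[state]
        w = config.its_window_days
        start = pdate - timedelta(days=w)
        offset = (day - start).days
        if 0 <= offset < 2 * w:
            t = offset + 1.0
            P = 1.0 if day >= pdate else 0.0
            delta, gamma = config.its_effects[state]
            p = base_p + delta * P + gamma * t * P
    p = p + noise
    return float(min(1.0, max(1e-6, p))) / base_p


def generate_corpus(
    config: SynthConfig,
    lexicon: Optional[MentalHealthLexicon] = None,
) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate a time-sorted tweet stream and its ground truth."""
    config.validate()
    if lexicon is None:
        lexicon = load_default_mh_lexicon()
    terms_by_group = {
        g: sorted(t for t, gs in lexicon.entries.items() if g in gs)
        for g in SUBGROUPS
    }

    (rng_users, rng_vol, rng_noise, rng_topics, rng_text,
     rng_time, rng_geo, rng_daily) = _substreams(config.seed, 8)

    K_true, V, doc_len, t_alpha, t_beta = config.topic_params
    vocab_words = _index_words(V)
    true_phi = rng_topics.dirichlet(np.full(V, t_beta), size=K_true)

    state_names = [s for s, _ in config.states]
    state_probs = np.array([p for _, p in config.states], dtype=float)

    # --- users ---------------------------------------------------------
    users = []
    n_regular = config.n_users
    multi_frac = config.nuisance_fractions.get("multi_state_user", 0.0)
    for i in range(n_regular):
        uid = f"u{i:06d}"
        cohort = "hcw" if rng_users.random() < config.hcw_fraction else "general"
        state = state_names[int(rng_users.choice(len(state_names), p=state_probs))]
        multi = rng_users.random() < multi_frac
        second = None
        if multi:
            others = [s for s in state_names if s != state]
            second = others[int(rng_users.integers(len(others)))]
        if cohort == "hcw":
            tmpl = _HCW_DESCRIPTION_TEMPLATES[int(rng_users.integers(len(_HCW_DESCRIPTION_TEMPLATES)))]
            desc = tmpl.format(term=_HCW_TERMS[int(rng_users.integers(len(_HCW_TERMS)))])
        else:
            desc = _GENERAL_DESCRIPTIONS[int(rng_users.integers(len(_GENERAL_DESCRIPTIONS)))]
        users.append(dict(uid=uid, cohort=cohort, state=state, second=second,
                          multi=multi, desc=desc, spam=False))
    for j in range(config.spam_users):
        uid = f"spam{j:04d}"
        state = state_names[int(rng_users.choice(len(state_names), p=state_probs))]
        users.append(dict(uid=uid, cohort="general", state=state, second=None,
                          multi=False, desc="deals deals deals", spam=True))

    start, end = config.date_range
    n_days = (end - start).days + 1
    all_days = [start + timedelta(days=i) for i in range(n_days)]

    # pre-draw day-level proportion noise per state so that substreams stay
    # independent of per-tweet draws
    day_noise = {
        (s, d): float(rng_daily.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        for s in state_names for d in all_days
    }
    base_any = {
        c: 1.0 - float(np.prod([1.0 - config.baseline_rates[(c, g)] for g in SUBGROUPS]))
        for c in COHORTS
    }

    weights_by_cohort = {}
    for c in COHORTS:
        w = None
        if config.cohort_topic_weights is not None:
            w = config.cohort_topic_weights.get(c)
        weights_by_cohort[c] = (np.asarray(w, dtype=float) / np.sum(w)
                                if w is not None else np.full(K_true, 1.0 / K_true))

    # --- tweets --------------------------------------------------------
    records: list[TweetRecord] = []
    gt_subgroups: dict[str, list[str]] = {}
    gt_topics: dict[str, int] = {}
    noise_ids: dict[str, list[str]] = {"url": [], "retweet": [], "non_english": []}
    tweet_counter = 0
    nf = config.nuisance_fractions
    p_url, p_rt, p_ne = nf.get("url", 0.0), nf.get("retweet", 0.0), nf.get("non_english", 0.0)

    for user in users:
        if user["spam"]:
            n_tweets = config.spam_threshold + 100
        else:
            n_tweets = max(1, int(rng_vol.poisson(config.tweets_per_user_mean)))
        cohort = user["cohort"]
        for j in range(n_tweets):
            tid = f"t{tweet_counter:08d}"
            tweet_counter += 1
            day = all_days[int(rng_time.integers(n_days))]
            seconds = int(rng_time.integers(86400))
            created = datetime.combine(day, time(0, 0), tzinfo=timezone.utc) + timedelta(seconds=seconds)

            if user["spam"]:
                category = "clean"
            else:
                u = rng_noise.random()
                if u < p_url:
                    category = "url"
                elif u < p_url + p_rt:
                    category = "retweet"
                elif u < p_url + p_rt + p_ne:
                    category = "non_english"
                else:
                    category = "clean"

            # planted subgroup labels
            if user["spam"]:
                g = SUBGROUPS[int(rng_noise.integers(len(SUBGROUPS)))]
                labels = [g]
            else:
                mult = _state_day_multiplier(
                    config, base_any[cohort], user["state"], day,
                    day_noise.get((user["state"], day), 0.0),
                )
                labels = [
                    g for g in SUBGROUPS
                    if rng_noise.random() < min(1.0, config.baseline_rates[(cohort, g)] * mult)
                ]

            # text: LDA topic tokens plus one lexicon term per planted label
            alpha_vec = t_alpha * K_true * weights_by_cohort[cohort]
            theta = rng_text.dirichlet(alpha_vec)
            n_tok = max(3, int(rng_text.poisson(doc_len)))
            topic_draws = rng_text.choice(K_true, size=n_tok, p=theta)
            word_idx = [int(rng_text.choice(V, p=true_phi[k])) for k in topic_draws]
            tokens = [vocab_words[i] for i in word_idx]
            dominant = int(np.bincount(topic_draws, minlength=K_true).argmax())
            inserted_terms = []
            for g in labels:
                terms = terms_by_group[g]
                term = terms[int(rng_text.integers(len(terms)))]
                pos = int(rng_text.integers(len(tokens) + 1))
                tokens.insert(pos, term)
                inserted_terms.append(term)
            text = " ".join(tokens)
            if category == "url":
                text += " https://t.co/zzz"

            # geography
            place = ""
            location = ""
            if user["multi"]:
                st = user["state"] if j % 2 == 0 else user["second"]
                place = f"Cityville, {st}"
            elif rng_geo.random() < config.geotag_fraction:
                place = f"Cityville, {user['state']}"
            if rng_geo.random() < config.location_fraction:
                location = f"somewhere in {user['state']}"

            rec = TweetRecord(
                tweet_id=tid,
                text=text,
                created_at=created,
                lang="es" if category == "non_english" else "en",
                is_retweet=(category == "retweet"),
                has_url=(category == "url"),
                user_id=user["uid"],
                user_description=user["desc"],
                user_location=location,
                place=place,
            )
            records.append(rec)
            # ground-truth labels take the lexicon's subgroup view of the
            # inserted terms (a term may map to several subgroups)
            if inserted_terms:
                gt_subgroups[tid] = sorted(
                    set().union(*(lexicon.entries[t] for t in inserted_terms))
                )
            else:
                gt_subgroups[tid] = []
            gt_topics[tid] = dominant
            if category in noise_ids:
                noise_ids[category].append(tid)

    records.sort(key=lambda r: (r.created_at, r.tweet_id))

    # --- expected filter-cascade accounting ----------------------------
    stage = {"input_count": len(records), "removed_non_english": 0,
             "removed_retweets": 0, "removed_url": 0, "removed_no_match": 0,
             "removed_spam_user": 0, "output_count": 0}
    matched_per_user: dict[str, int] = {}
    survivors: list[tuple[str, str]] = []  # (tweet id, user id)
    for rec in records:
        if rec.lang != "en":
            stage["removed_non_english"] += 1
        elif rec.is_retweet:
            stage["removed_retweets"] += 1
        elif rec.has_url:
            stage["removed_url"] += 1
        elif not gt_subgroups[rec.tweet_id]:
            stage["removed_no_match"] += 1
        else:
            survivors.append((rec.tweet_id, rec.user_id))
            matched_per_user[rec.user_id] = matched_per_user.get(rec.user_id, 0) + 1
    spam_like = {u for u, n in matched_per_user.items() if n > config.spam_threshold}
    for _, uid in survivors:
        if uid in spam_like:
            stage["removed_spam_user"] += 1
    stage["output_count"] = len(survivors) - stage["removed_spam_user"]

    gt = GroundTruth(
        tweet_subgroups=gt_subgroups,
        tweet_topics=gt_topics,
        user_cohort={u["uid"]: u["cohort"] for u in users},
        user_state={u["uid"]: (None if u["multi"] else u["state"]) for u in users},
        true_phi=true_phi,
        its_effects={s: tuple(v) for s, v in config.its_effects.items()},
        spam_user_ids=[u["uid"] for u in users if u["spam"]],
        multi_state_user_ids=[u["uid"] for u in users if u["multi"]],
        noise_tweet_ids=noise_ids,
        stage_counts=stage,
        n_tweets=len(records),
    )
    return records, gt


def write_corpus(
    records: Sequence[TweetRecord],
    ground_truth: GroundTruth,
    stream_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> None:
    """Write the JSON-lines tweet stream and (optionally) the ground truth."""
    stream_path = Path(stream_path)
    with stream_path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json(), ensure_ascii=False) + "\n")
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps(ground_truth.to_json(), indent=None, sort_keys=True),
            encoding="utf-8",
        )
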