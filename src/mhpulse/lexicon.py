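"""Lexicon data models and keyword classifiers.

Three classifiers drive cohort identification in the pipeline:

* :func:`match_subgroups` — labels a tweet with mental-health symptom
  subgroups (anxiety, depression, insomnia, addiction) by case-insensitive
  word-boundary keyword matching against a curated lexicon;
* :func:`identify_hcw` — flags a user as a health-care worker from their
  profile description using an occupation/degree/association dictionary,
  with token-exact matching for short ambiguous acronyms such as ``MD``;
* :func:`resolve_state` / :func:`assign_user_state` — resolves a user's
  US state from the GPS-derived ``place`` field (primary evidence) with
  fallback to the self-reported ``location`` field, and excludes users
  associated with more than one state.

All classifiers take the lexicon object as input, so the packaged
representative term lists can be swapped for site-specific curated lists
without code changes.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MentalHealthLexicon",
    "HCWLexicon",
    "StateGazetteer",
    "MatchResult",
    "match_subgroups",
    "identify_hcw",
    "resolve_state",
    "assign_user_state",
    "load_default_mh_lexicon",
    "load_default_hcw_lexicon",
    "load_default_gazetteer",
]

SUBGROUPS = ("anxiety", "depression", "insomnia", "addiction")

_WORD = r"[0-9A-Za-z_']"


def _normalize(text: str) -> str:
    """NFKC-normalize and lower-case; tweets contain stylized unicode."""
    return unicodedata.normalize("NFKC", text).casefold()


def _term_pattern(term: str) -> re.Pattern:
    # multi-word phrases match as contiguous token sequences, tolerant of
    # repeated whitespace; '#' acts as a boundary so "#anxiety" matches
    words = [re.escape(w) for w in term.split()]
    body = r"\s+".join(words)
    return re.compile(rf"(?<!{_WORD}){body}(?!{_WORD})")


def _token_set(text: str) -> list[str]:
    return re.findall(r"[0-9A-Za-z']+", text)


@dataclass
class MentalHealthLexicon:
    """Term -> subgroup-set mapping for the four mental-health subgroups."""

    entries: dict[str, frozenset[str]]
    _patterns: dict[str, re.Pattern] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for term, groups in self.entries.items():
            t = _normalize(" ".join(term.split()))
            if not t:
                raise ValueError("empty lexicon term")
            if not groups:
                raise ValueError(f"term {term!r} maps to no subgroup")
            unknown = set(groups) - set(SUBGROUPS)
            if unknown:
                raise ValueError(f"unknown subgroups {unknown} for term {term!r}")
            clean[t] = frozenset(groups) | clean.get(t, frozenset())
        self.entries = clean
        self._patterns = {t: _term_pattern(t) for t in clean}

    @property
    def terms(self) -> list[str]:
        return sorted(self.entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "MentalHealthLexicon":
        """Load a two-column (term TAB subgroup) UTF-8 file; '#' comments."""
        entries: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                term, group = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"malformed lexicon line: {line!r}") from exc
            entries.setdefault(term.strip(), set()).add(group.strip())
        return cls({t: frozenset(g) for t, g in entries.items()})


@dataclass
class HCWLexicon:
    """Health-care-worker dictionary: occupation, degree and association terms.

    ``short_acronyms`` is the subset (e.g. ``MD``, ``RN``) that only counts
    when it appears as an exact-case standalone token — lower-case "md" in
    running text is not evidence of a medical degree.
    """

    occupation_terms: frozenset[str]
    degree_terms: frozenset[str]
    association_terms: frozenset[str]
    short_acronyms: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.occupation_terms, self.degree_terms, self.association_terms]
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("occupation/degree/association sets must be disjoint")
        if not self.short_acronyms <= union:
            raise ValueError("short_acronyms must be a subset of the term union")

    @property
    def all_terms(self) -> frozenset[str]:
        return self.occupation_terms | self.degree_terms | self.association_terms

    @classmethod
    def from_file(cls, path: str | Path) -> "HCWLexicon":
        classes: dict[str, set[str]] = {"occupation": set(), "degree": set(), "association": set()}
        acronyms: set[str] = set()
        n_rows = 0
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, klass, flag = line.split("\t")
            if klass not in classes:
                raise ValueError(f"unknown HCW term class {klass!r}")
            classes[klass].add(term)
            n_rows += 1
            if flag.strip() == "1":
                acronyms.add(term)
        lex = cls(
            occupation_terms=frozenset(classes["occupation"]),
            degree_terms=frozenset(classes["degree"]),
            association_terms=frozenset(classes["association"]),
            short_acronyms=frozenset(acronyms),
        )
        if len(lex.all_terms) != n_rows:
            raise ValueError("duplicate terms across HCW lexicon classes")
        return lex


@dataclass
class StateGazetteer:
    """Alias (full name or USPS abbreviation) -> canonical US state name."""

    aliases: dict[str, str]

    def __post_init__(self) -> None:
        by_canon: dict[str, int] = {}
        for canon in self.aliases.values():
            by_canon[canon] = by_canon.get(canon, 0) + 1
        bad = [c for c, n in by_canon.items() if n < 2]
        if bad:
            raise ValueError(f"states reachable from <2 aliases: {bad}")

    @property
    def canonical_states(self) -> frozenset[str]:
        return frozenset(self.aliases.values())

    @property
    def abbreviations(self) -> frozenset[str]:
        return frozenset(a for a in self.aliases if len(a) == 2)

    @classmethod
    def from_file(cls, path: str | Path) -> "StateGazetteer":
        aliases: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, canon = line.split("\t")
            if alias in aliases:
                raise ValueError(f"duplicate gazetteer alias {alias!r}")
            aliases[alias] = canon
        return cls(aliases)


@dataclass
class MatchResult:
    tweet_id: str
    subgroups: frozenset[str]
    matched_terms: list[tuple[str, str]]  # (term, subgroup) in text order

    def __post_init__(self) -> None:
        union = frozenset(g for _, g in self.matched_terms)
        if union != self.subgroups:
            raise ValueError("subgroups must equal the union of matched-term subgroups")


def match_subgroups(
    text: str, lexicon: MentalHealthLexicon, tweet_id: str = ""
) -> Optional[MatchResult]:
    """Match mental-health lexicon terms in ``text`` at word boundaries.

    Case-insensitive after NFKC normalization; multi-word phrases match as
    contiguous token sequences; a tweet may carry multiple subgroups.
    Returns ``None`` when no term matches.
    """
    norm = _normalize(text)
    hits: list[tuple[int, str, str]] = []
    for term, pattern in lexicon._patterns.items():
        for m in pattern.finditer(norm):
            for group in sorted(lexicon.entries[term]):
                hits.append((m.start(), term, group))
    if not hits:
        return None
    hits.sort()
    matched = [(term, group) for _, term, group in hits]
    return MatchResult(
        tweet_id=tweet_id,
        subgroups=frozenset(g for _, g in matched),
        matched_terms=matched,
    )


def identify_hcw(
    description: str,
    lexicon: HCWLexicon,
    gazetteer: Optional[StateGazetteer] = None,
) -> bool:
    """True iff the profile description matches ≥1 health-care-worker keyword.

    Long terms match case-insensitively at word boundaries.  Short acronyms
    require exact-case standalone tokens, and when a gazetteer is supplied a
    co-occurrence guard suppresses acronyms that double as state
    abbreviations (``MD``, ``LA``...) whenever another state alias appears in
    the description — "Road trip through MD and VA" is geography, not a
    medical degree.
    """
    if not description:
        return False
    norm = _normalize(description)
    for term in lexicon.all_terms:
        if term in lexicon.short_acronyms:
            continue
        if _term_pattern(_normalize(term)).search(norm):
            return True
    raw_tokens = re.findall(r"[0-9A-Za-z']+", description)
    state_abbrevs = gazetteer.abbreviations if gazetteer is not None else frozenset()
    for acro in lexicon.short_acronyms:
        if acro not in raw_tokens:
            continue
        if gazetteer is not None and acro in state_abbrevs:
            other_abbrev = any(
                t != acro and len(t) == 2 and t.isupper() and t in state_abbrevs
                for t in raw_tokens
            )
            if other_abbrev or _resolve_fullname(description, gazetteer):
                continue
        return True
    return False


def _resolve_fullname(text: str, gazetteer: StateGazetteer) -> Optional[str]:
    norm = _normalize(text)
    for alias, canon in gazetteer.aliases.items():
        if len(alias) == 2:
            continue
        if _term_pattern(_normalize(alias)).search(norm):
            return canon
    return None


def _scan_state(text: str, gazetteer: StateGazetteer) -> Optional[str]:
    """Scan one free-text field for a state alias.

    Full names (case-insensitive) are preferred over USPS abbreviations
    (exact upper-case tokens); on conflict between full names the longest
    alias wins, so "Kansas City, Missouri" resolves to Missouri.
    """
    if not text:
        return None
    norm = _normalize(text)
    full_hits: list[tuple[int, str]] = []  # (alias length, canonical)
    for alias, canon in gazetteer.aliases.items():
        if len(alias) == 2:
            continue
        if _term_pattern(_normalize(alias)).search(norm):
            full_hits.append((len(alias), canon))
    if full_hits:
        full_hits.sort(reverse=True)
        return full_hits[0][1]
    tokens = re.findall(r"[A-Za-z]+", text)
    for tok in tokens:
        if len(tok) == 2 and tok.isupper() and tok in gazetteer.aliases:
            return gazetteer.aliases[tok]
    return None


def resolve_state(
    place: str, location: str, gazetteer: StateGazetteer
) -> Optional[str]:
    """Resolve a US state, preferring GPS-derived ``place`` over ``location``."""
    return _scan_state(place, gazetteer) or _scan_state(location, gazetteer)


#: sentinel for users tied to more than one state (dropped from geographic analyses)
EXCLUDED = "__excluded__"


def assign_user_state(
    user_tweets: Sequence[tuple[object, Optional[str]]]
) -> Optional[str]:
    """Assign one state per user from their per-tweet resolutions.

    Returns the state when exactly one distinct state resolves, ``None`` when
    none do (user kept for non-geographic analyses), and :data:`EXCLUDED`
    when ≥2 distinct states resolve — such users are removed from geographic
    analyses entirely.
    """
    user_ids = {getattr(rec, "user_id", None) for rec, _ in user_tweets}
    user_ids.discard(None)
    if len(user_ids) > 1:
        raise ValueError(f"records from multiple users passed: {sorted(user_ids)}")
    states = {s for _, s in user_tweets if s is not None}
    if not states:
        return None
    if len(states) > 1:
        return EXCLUDED
    return next(iter(states))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mhpulse").joinpath("data", name)))


def load_default_mh_lexicon() -> MentalHealthLexicon:
    return MentalHealthLexicon.from_file(_data_path("mh_lexicon.tsv"))


def load_default_hcw_lexicon() -> HCWLexicon:
    return HCWLexicon.from_file(_data_path("hcw_lexicon.tsv"))


def load_default_gazetteer() -> StateGazetteer:
    return StateGazetteer.from_file(_data_path("state_gazetteer.tsv"))
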