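"""Tweet-stream ingestion and the preprocessing filter cascade.

The cascade mirrors the study design for building a mental-health tweet
corpus from a COVID-19 tweet stream: keep English, original (non-retweet),
URL-free tweets that match the mental-health lexicon, then drop users who
posted more than ``spam_threshold`` (default 1000) matching tweets during
the study period.  Stage order is fixed:

    language → retweet → URL → lexicon match → spam user

and each record is removed at exactly one stage, so the per-stage counts
telescope back to the input count.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .lexicon import MentalHealthLexicon, match_subgroups

logger = logging.getLogger(__name__)

__all__ = ["TweetRecord", "FilterReport", "read_tweet_stream", "apply_filters"]


@dataclass
class TweetRecord:
    """One social-media post with the metadata subset the pipeline uses."""

    tweet_id: str
    text: str
    created_at: datetime
    lang: str
    is_retweet: bool
    has_url: bool
    user_id: str
    user_description: str = ""
    user_location: str = ""
    place: str = ""

    @classmethod
    def from_json(cls, obj: dict) -> "TweetRecord":
        """Build from one JSON-lines record (Twitter-v1.1-like schema)."""
        created = datetime.fromisoformat(obj["created_at"])
        if created.tzinfo is None:
            created = created.replace(tzinfo=timezone.utc)
        user = obj.get("user", {})
        entities = obj.get("entities")
        if entities is not None:
            has_url = bool(entities.get("urls"))
        else:
            # regex fallback for records lacking entity annotations
            has_url = bool(_URL_RE.search(obj["text"]))
        place = obj.get("place") or {}
        return cls(
            tweet_id=str(obj["id_str"]),
            text=obj["text"],
            created_at=created,
            lang=obj.get("lang", "und"),
            is_retweet=bool(obj.get("retweeted", False)),
            has_url=has_url,
            user_id=str(user.get("id_str", "")),
            user_description=user.get("description") or "",
            user_location=user.get("location") or "",
            place=place.get("full_name") or "" if isinstance(place, dict) else str(place),
        )

    def to_json(self) -> dict:
        return {
            "id_str": self.tweet_id,
            "text": self.text,
            "created_at": self.created_at.isoformat(),
            "lang": self.lang,
            "retweeted": self.is_retweet,
            "entities": {"urls": (["about:blank"] if self.has_url else [])},
            "user": {
                "id_str": self.user_id,
                "description": self.user_description,
                "location": self.user_location,
            },
            "place": {"full_name": self.place} if self.place else None,
        }


_URL_RE = re.compile(r"https?://\S+|\bt\.co/\S+")


@dataclass
class FilterReport:
    """Per-stage accounting of the filter cascade (telescoping)."""

    input_count: int = 0
    removed_non_english: int = 0
    removed_retweets: int = 0
    removed_url: int = 0
    removed_no_match: int = 0
    removed_spam_user: int = 0
    output_count: int = 0

    def validate(self) -> None:
        removed = (
            self.removed_non_english
            + self.removed_retweets
            + self.removed_url
            + self.removed_no_match
            + self.removed_spam_user
        )
        if self.input_count != self.output_count + removed:
            raise ValueError(
                f"filter report does not telescope: {self.input_count} != "
                f"{self.output_count} + {removed}"
            )

    def to_json(self) -> dict:
        return asdict(self)


def read_tweet_stream(
    path: str | Path, max_malformed_fraction: float = 0.10
) -> list[TweetRecord]:
    """Read a JSON-lines tweet stream in file order.

    Malformed lines are counted, logged, and skipped; more than
    ``max_malformed_fraction`` malformed lines raises (probable schema
    mismatch).  Duplicate tweet ids keep the first occurrence.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    seen: set[str] = set()
    n_lines = 0
    n_malformed = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            try:
                rec = TweetRecord.from_json(json.loads(line))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                n_malformed += 1
                logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
                continue
            if rec.tweet_id in seen:
                logger.warning("duplicate tweet id %s at line %d; keeping first", rec.tweet_id, lineno)
                continue
            seen.add(rec.tweet_id)
            records.append(rec)
    if n_lines and n_malformed / n_lines > max_malformed_fraction:
        raise ValueError(
            f"{n_malformed}/{n_lines} malformed lines in {path}: probable schema mismatch"
        )
    return records


def apply_filters(
    records: Sequence[TweetRecord],
    lexicon: MentalHealthLexicon,
    spam_threshold: int = 1000,
) -> tuple[list[TweetRecord], FilterReport]:
    """Apply the preprocessing cascade and return kept records plus a report.

    Kept records are English-language, original, URL-free, match ≥1
    mental-health lexicon term, and belong to users with at most
    ``spam_threshold`` matching tweets (strictly more are removed — a user
    with exactly the threshold is kept).
    """
    if spam_threshold < 1:
        raise ValueError("spam_threshold must be >= 1")
    report = FilterReport(input_count=len(records))

    stage: list[TweetRecord] = []
    for rec in records:
        if rec.lang != "en":
            report.removed_non_english += 1
        else:
            stage.append(rec)

    stage2: list[TweetRecord] = []
    for rec in stage:
        if rec.is_retweet:
            report.removed_retweets += 1
        else:
            stage2.append(rec)

    stage3: list[TweetRecord] = []
    for rec in stage2:
        if rec.has_url:
            report.removed_url += 1
        else:
            stage3.append(rec)

    matched: list[TweetRecord] = []
    per_user: dict[str, int] = {}
    for rec in stage3:
        if match_subgroups(rec.text, lexicon, rec.tweet_id) is None:
            report.removed_no_match += 1
        else:
            matched.append(rec)
            per_user[rec.user_id] = per_user.get(rec.user_id, 0) + 1

    spam_users = {u for u, n in per_user.items() if n > spam_threshold}
    kept: list[TweetRecord] = []
    for rec in matched:
        if rec.user_id in spam_users:
            report.removed_spam_user += 1
        else:
            kept.append(rec)

    report.output_count = len(kept)
    report.validate()
    return kept, report
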