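"""Pipeline orchestration: configuration, stage execution, reports.

Stages run in a fixed order — ingest → lexicon → trends → topics → compare
→ its — and every stage's outputs are written to plain files before the
next stage starts, so a failed run leaves the completed stages' outputs
intact and independently inspectable.  A single global seed makes the full
run deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import build_paired_series, wilcoxon_signed_rank
from .ingest import TweetRecord, apply_filters, read_tweet_stream
from .its import DailySeries, SegmentedITS, sensitivity_analysis
from .lexicon import (
    EXCLUDED,
    HCWLexicon,
    MentalHealthLexicon,
    StateGazetteer,
    assign_user_state,
    identify_hcw,
    load_default_gazetteer,
    load_default_hcw_lexicon,
    load_default_mh_lexicon,
    match_subgroups,
    resolve_state,
)
from .topics import (
    GibbsLDA,
    preprocess_for_topics,
    select_num_topics,
    topic_share_series,
    umass_coherence,
)
from .trends import aggregate_proportions, period_key

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "write_reports"]

STAGES = ("ingest", "lexicon", "trends", "topics", "compare", "its")

_TOPIC_KEYS = {"K", "alpha", "beta", "iterations", "bigram_min_count",
               "k_grid", "seeds", "select", "heldout_fraction",
               "perplexity_tolerance"}
_ITS_KEYS = {"policy_dates", "window", "sensitivity", "cov_type"}
_TOP_KEYS = {"input", "output_dir", "lexicon", "hcw_lexicon", "gazetteer",
             "study_start", "study_end", "spam_threshold",
             "granularity_trends", "granularity_compare", "granularity_topics",
             "topics", "its", "seed", "stages"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input: str
    output_dir: str
    lexicon: Optional[str] = None
    hcw_lexicon: Optional[str] = None
    gazetteer: Optional[str] = None
    study_start: Optional[date] = None
    study_end: Optional[date] = None
    spam_threshold: int = 1000
    granularity_trends: str = "week"
    granularity_compare: str = "week"
    granularity_topics: str = "month"
    topics: dict = field(default_factory=dict)
    its: dict = field(default_factory=dict)
    seed: int = 0
    stages: Optional[list[str]] = None

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw or {})

    def validate(self) -> None:
        bad_t = set(self.topics) - _TOPIC_KEYS
        if bad_t:
            raise ValueError(f"unknown topics config keys: {sorted(bad_t)}")
        bad_i = set(self.its) - _ITS_KEYS
        if bad_i:
            raise ValueError(f"unknown its config keys: {sorted(bad_i)}")
        wanted = self.stages or list(STAGES)
        unknown_stages = set(wanted) - set(STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        deps = {"ingest": [], "lexicon": ["ingest"], "trends": ["lexicon"],
                "topics": ["ingest"], "compare": ["trends"], "its": ["trends"]}
        for stage in wanted:
            missing = [d for d in deps[stage] for _ in [0] if d not in wanted]
            if missing:
                raise ValueError(f"stage {stage!r} requires stages {missing}")
        if "its" in wanted and self.its and not self.its.get("policy_dates"):
            raise ValueError("ITS requested but its.policy_dates is missing/empty")
        for g in (self.granularity_trends, self.granularity_compare, self.granularity_topics):
            if g not in ("day", "week", "month"):
                raise ValueError(f"unknown granularity {g!r}")

    def resolved(self) -> dict:
        out = {
            "input": self.input, "output_dir": self.output_dir,
            "lexicon": self.lexicon, "hcw_lexicon": self.hcw_lexicon,
            "gazetteer": self.gazetteer,
            "study_start": str(self.study_start) if self.study_start else None,
            "study_end": str(self.study_end) if self.study_end else None,
            "spam_threshold": self.spam_threshold,
            "granularity_trends": self.granularity_trends,
            "granularity_compare": self.granularity_compare,
            "granularity_topics": self.granularity_topics,
            "topics": dict(self.topics), "its": dict(self.its),
            "seed": self.seed, "stages": self.stages or list(STAGES),
        }
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_counts: dict[str, dict] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stage_counts": self.stage_counts,
            "stage_seconds": self.stage_seconds,
            "warnings": self.warnings,
        }


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages end to end; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True), encoding="utf-8"
    )
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    wanted = config.stages or list(STAGES)

    mh_lex = (MentalHealthLexicon.from_file(config.lexicon)
              if config.lexicon else load_default_mh_lexicon())
    hcw_lex = (HCWLexicon.from_file(config.hcw_lexicon)
               if config.hcw_lexicon else load_default_hcw_lexicon())
    gaz = (StateGazetteer.from_file(config.gazetteer)
           if config.gazetteer else load_default_gazetteer())

    ctx: dict[str, Any] = {}

    def _run(stage: str, fn) -> None:
        if stage not in wanted:
            return
        t0 = _time.perf_counter()
        try:
            fn()
        except Exception as exc:  # abort naming the stage; earlier outputs kept
            raise PipelineError(stage, str(exc)) from exc
        manifest.stage_seconds[stage] = round(_time.perf_counter() - t0, 3)

    # ---- ingest -------------------------------------------------------
    def _ingest() -> None:
        records = read_tweet_stream(config.input)
        if config.study_start or config.study_end:
            lo = config.study_start or date.min
            hi = config.study_end or date.max
            records = [r for r in records if lo <= r.created_at.date() <= hi]
        kept, report = apply_filters(records, mh_lex, config.spam_threshold)
        with (outdir / "filtered.jsonl").open("w", encoding="utf-8") as fh:
            for rec in kept:
                fh.write(json.dumps(rec.to_json(), ensure_ascii=False) + "\n")
        (outdir / "filter_report.json").write_text(
            json.dumps(report.to_json(), indent=2), encoding="utf-8")
        ctx["records"] = records
        ctx["kept"] = kept
        ctx["report"] = report
        manifest.stage_counts["ingest"] = report.to_json()

    _run("ingest", _ingest)
    if "ingest" not in wanted:
        raise PipelineError("ingest", "pipeline cannot run without the ingest stage")

    # ---- lexicon: per-tweet subgroups, per-user cohort and state ------
    def _lexicon() -> None:
        records, kept = ctx["records"], ctx["kept"]
        match_rows = []
        for rec in kept:
            m = match_subgroups(rec.text, mh_lex, rec.tweet_id)
            for g in sorted(m.subgroups):
                match_rows.append({
                    "tweet_id": rec.tweet_id, "user_id": rec.user_id,
                    "date": rec.created_at.date().isoformat(), "subgroup": g,
                })
        matches = pd.DataFrame(match_rows)

        # denominator stream: language/retweet/URL-filtered COVID tweets
        denom_records = [r for r in records
                         if r.lang == "en" and not r.is_retweet and not r.has_url]
        per_user: dict[str, list] = {}
        for rec in denom_records:
            per_user.setdefault(rec.user_id, []).append(rec)
        user_rows = []
        for uid, recs in sorted(per_user.items()):
            states = [(r, resolve_state(r.place, r.user_location, gaz)) for r in recs]
            state = assign_user_state(states)
            hcw = identify_hcw(recs[0].user_description, hcw_lex, gaz)
            user_rows.append({
                "user_id": uid,
                "cohort": "hcw" if hcw else "general",
                "state": "" if state is None else state,
                "excluded_multi_state": state == EXCLUDED,
                "n_tweets": len(recs),
            })
        users = pd.DataFrame(user_rows)
        _write_csv(matches, outdir / "matches.csv")
        _write_csv(users, outdir / "users.csv")
        ctx["matches"] = matches
        ctx["users"] = users
        ctx["denom_records"] = denom_records
        manifest.stage_counts["lexicon"] = {
            "matched_tweets": int(matches["tweet_id"].nunique()) if len(matches) else 0,
            "users": len(users),
            "hcw_users": int((users["cohort"] == "hcw").sum()) if len(users) else 0,
            "excluded_multi_state_users": int(users["excluded_multi_state"].sum()) if len(users) else 0,
        }

    _run("lexicon", _lexicon)

    # ---- trends -------------------------------------------------------
    def _trends() -> None:
        matches, users = ctx["matches"], ctx["users"]
        denom_records = ctx["denom_records"]
        user_state = dict(zip(users["user_id"], users["state"]))
        excluded = set(users.loc[users["excluded_multi_state"], "user_id"])

        denom = pd.DataFrame({
            "date": [r.created_at.date() for r in denom_records],
            "user_id": [r.user_id for r in denom_records],
        })
        denom["count"] = 1
        matched = matches.copy()
        matched["date"] = pd.to_datetime(matched["date"]).dt.date

        # subgroup proportions over the whole stream
        totals = denom.groupby("date", as_index=False)["count"].sum()
        sub = aggregate_proportions(matched, totals,
                                    granularity=config.granularity_trends,
                                    strata=("subgroup",))
        _write_csv(sub, outdir / "trends_subgroup.csv")

        # state-level proportions (monthly), geographically assignable users only
        denom_geo = denom.copy()
        denom_geo["state"] = denom_geo["user_id"].map(user_state)
        denom_geo = denom_geo[(denom_geo["state"] != "") &
                              (~denom_geo["user_id"].isin(excluded))]
        matched_geo = matched.copy()
        matched_geo["state"] = matched_geo["user_id"].map(user_state)
        matched_geo = matched_geo[(matched_geo["state"].notna()) &
                                  (matched_geo["state"] != "") &
                                  (~matched_geo["user_id"].isin(excluded))]
        matched_geo = matched_geo.drop_duplicates(["tweet_id"])  # any-subgroup level
        totals_geo = denom_geo.groupby(["date", "state"], as_index=False)["count"].sum()
        state_tab = aggregate_proportions(matched_geo, totals_geo,
                                          granularity="month", strata=("state",))
        _write_csv(state_tab, outdir / "trends_state.csv")
        ctx["denom_frame"] = denom
        ctx["denom_geo"] = denom_geo
        ctx["matched_frame"] = matched
        ctx["matched_geo"] = matched_geo
        manifest.stage_counts["trends"] = {
            "subgroup_points": len(sub), "state_points": len(state_tab),
        }

    _run("trends", _trends)

    # ---- topics -------------------------------------------------------
    def _topics() -> None:
        kept = ctx["kept"]
        tcfg = config.topics
        texts = [r.text for r in kept]
        ids = [r.tweet_id for r in kept]
        docs, vocab = preprocess_for_topics(
            texts, bigram_min_count=int(tcfg.get("bigram_min_count", 5)), doc_ids=ids
        )
        K = int(tcfg.get("K", 16))
        if tcfg.get("select") and tcfg.get("k_grid"):
            K, diag = select_num_topics(
                docs, [int(k) for k in tcfg["k_grid"]],
                seeds=[int(s) for s in tcfg.get("seeds", [config.seed])],
                vocabulary=vocab,
                n_iterations=int(tcfg.get("iterations", 200)),
                heldout_fraction=float(tcfg.get("heldout_fraction", 0.2)),
                perplexity_tolerance=float(tcfg.get("perplexity_tolerance", 0.05)),
            )
            _write_csv(diag, outdir / "topics_selection.csv")
        model = GibbsLDA(docs, len(vocab), K,
                         alpha=tcfg.get("alpha"), beta=float(tcfg.get("beta", 0.01)),
                         vocabulary=vocab)
        res = model.fit(n_iterations=int(tcfg.get("iterations", 500)), seed=config.seed)
        _write_csv(res.summary(top_n=20), outdir / "topic_summaries.csv")

        with (outdir / "vocabulary.tsv").open("w", encoding="utf-8") as fh:
            fh.write("index\ttoken\tdoc_freq\n")
            for i, tok in enumerate(vocab.tokens):
                fh.write(f"{i}\t{tok}\t{int(vocab.doc_freq[i])}\n")
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        mmwrite(str(outdir / "topic_word_counts.mtx"), csr_matrix(res.state.n_kw))

        assignments = res.modal_topics()
        dates = {r.tweet_id: r.created_at.date() for r in kept}
        shares = topic_share_series(assignments, dates,
                                    granularity=config.granularity_topics, K=K)
        _write_csv(shares, outdir / "topic_shares.csv")
        assign_df = pd.DataFrame(
            {"tweet_id": list(assignments), "topic_id": list(assignments.values())}
        )
        _write_csv(assign_df, outdir / "topic_assignments.csv")
        ctx["topic_assignments"] = assignments
        ctx["K"] = K
        manifest.stage_counts["topics"] = {
            "documents": len(docs), "vocabulary": len(vocab), "K": K,
        }

    _run("topics", _topics)

    # ---- compare ------------------------------------------------------
    def _compare() -> None:
        users = ctx["users"]
        denom = ctx["denom_frame"].copy()
        matched = ctx["matched_frame"]
        cohort_of = dict(zip(users["user_id"], users["cohort"]))
        denom["cohort"] = denom["user_id"].map(cohort_of)
        gran = config.granularity_compare
        rows = []
        for subgroup in sorted(matched["subgroup"].unique()):
            msub = matched[matched["subgroup"] == subgroup].copy()
            msub["cohort"] = msub["user_id"].map(cohort_of)
            per_cohort = {}
            for cohort in ("hcw", "general"):
                tot = (denom[denom["cohort"] == cohort]
                       .groupby("date", as_index=False)["count"].sum())
                mm = msub[msub["cohort"] == cohort]
                if mm.empty or tot.empty:
                    per_cohort = None
                    break
                per_cohort[cohort] = aggregate_proportions(
                    mm, tot, granularity=gran, strata=())
            if per_cohort is None:
                continue
            try:
                pairs = build_paired_series(per_cohort["hcw"], per_cohort["general"], gran)
            except ValueError as exc:
                manifest.warnings.append(f"compare[{subgroup}]: {exc}")
                continue
            res = wilcoxon_signed_rank(pairs)
            rows.append({
                "subgroup": subgroup,
                "hcw_median_pct": 100 * res.median_x,
                "hcw_q1_pct": 100 * res.iqr_x[0], "hcw_q3_pct": 100 * res.iqr_x[1],
                "general_median_pct": 100 * res.median_y,
                "general_q1_pct": 100 * res.iqr_y[0], "general_q3_pct": 100 * res.iqr_y[1],
                "W": res.W, "n_effective": res.n_effective,
                "p_value": res.p_value, "method": res.method,
            })
        cols = ["subgroup", "hcw_median_pct", "hcw_q1_pct", "hcw_q3_pct",
                "general_median_pct", "general_q1_pct", "general_q3_pct",
                "W", "n_effective", "p_value", "method"]
        table = pd.DataFrame(rows, columns=cols)
        _write_csv(table, outdir / "compare_cohorts.csv")
        manifest.stage_counts["compare"] = {"subgroups_tested": len(table)}

    _run("compare", _compare)

    # ---- its ----------------------------------------------------------
    def _its() -> None:
        icfg = config.its
        policy_dates = {
            s: (d if isinstance(d, date) else date.fromisoformat(str(d)))
            for s, d in (icfg.get("policy_dates") or {}).items()
        }
        if not policy_dates:
            manifest.stage_counts["its"] = {"states": 0}
            return
        window = int(icfg.get("window", 15))
        sens_windows = [int(w) for w in icfg.get("sensitivity", [])]
        cov_type = icfg.get("cov_type", "nonrobust")
        denom_geo, matched_geo = ctx["denom_geo"], ctx["matched_geo"]
        rows, sens_rows = [], []
        for state, pdate in sorted(policy_dates.items()):
            tot = (denom_geo[denom_geo["state"] == state]
                   .groupby("date", as_index=False)["count"].sum())
            num = (matched_geo[matched_geo["state"] == state]
                   .groupby("date", as_index=False)
                   .size().rename(columns={"size": "numerator"}))
            daily = tot.merge(num, on="date", how="left").fillna({"numerator": 0})
            pairs = [(d, k / n) for d, k, n in
                     zip(daily["date"], daily["numerator"], daily["count"])]
            try:
                series = DailySeries.from_pairs(pairs)
                fit = SegmentedITS.from_series(series, pdate, window).fit(cov_type=cov_type)
            except ValueError as exc:
                manifest.warnings.append(f"its[{state}]: {exc}")
                continue
            row = {"state": state, "policy_date": pdate.isoformat()}
            row.update(fit.to_row())
            rows.append(row)
            if sens_windows:
                try:
                    sens = sensitivity_analysis(series, pdate, sens_windows, cov_type)
                    sens.insert(0, "state", state)
                    sens_rows.append(sens)
                except ValueError as exc:
                    manifest.warnings.append(f"its-sensitivity[{state}]: {exc}")
        its_cols = ["state", "policy_date", "intercept", "time", "policy",
                    "time_policy", "p_intercept", "p_time", "p_policy",
                    "p_time_policy", "f_statistic", "f_pvalue",
                    "durbin_watson", "window_days"]
        table = pd.DataFrame(rows, columns=its_cols)
        _write_csv(table, outdir / "its_policy.csv")
        if sens_rows:
            _write_csv(pd.concat(sens_rows, ignore_index=True),
                       outdir / "its_sensitivity.csv")
        manifest.stage_counts["its"] = {"states": len(table)}

    _run("its", _its)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_json(), indent=2, sort_keys=True), encoding="utf-8")
    return manifest


def write_reports(output_dir: str | Path) -> dict:
    """Collect the table-shaped stage outputs into one JSON summary.

    Reads the CSVs a pipeline run wrote under ``output_dir`` and writes
    ``summary.json`` with explicit empty-section markers for stages that
    produced no output.
    """
    outdir = Path(output_dir)
    summary: dict[str, Any] = {}
    for name, fname in [
        ("filter_report", "filter_report.json"),
        ("trends_subgroup", "trends_subgroup.csv"),
        ("trends_state", "trends_state.csv"),
        ("topic_summaries", "topic_summaries.csv"),
        ("topic_shares", "topic_shares.csv"),
        ("compare_cohorts", "compare_cohorts.csv"),
        ("its_policy", "its_policy.csv"),
        ("its_sensitivity", "its_sensitivity.csv"),
    ]:
        path = outdir / fname
        if not path.exists():
            summary[name] = {"empty": True}
        elif fname.endswith(".json"):
            summary[name] = json.loads(path.read_text(encoding="utf-8"))
        else:
            try:
                df = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                summary[name] = {"empty": True}
                continue
            summary[name] = {"rows": len(df), "columns": list(df.columns)}
            if len(df) == 0:
                summary[name]["empty"] = True
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    return summary
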