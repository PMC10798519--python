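"""End-to-end pipeline: stream -> corpora -> tables, as machine-readable files.

``run_pipeline`` reads a JSON-Lines stream, builds the keyword corpus and
topic sub-corpus, partitions both by credibility class and period, and
writes the full table suite (corpus summary, exposure statistics, retweeted
fractions, latency quantiles, network compositions, centrality summaries,
domain rankings, top-k authors, account profiles) plus a run manifest.
Every output carries unrounded values alongside printed-precision columns,
and every table is sorted so reports are independent of input record order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .corpus import (
    CorpusPartition,
    CredClass,
    corpus_summary,
    filter_keywords,
    partition_credibility,
)
from .domains import normalize_domain_list
from .influence import (
    DEFAULT_CREATION_CUTOFF,
    account_profiles,
    authors_cohort,
    domain_popularity,
    top_authors,
    user_table,
)
from .network import analyze_graph, build_graph, classify_nodes
from .records import PeriodWindows, load_line_list, read_tweet_stream
from .temporal import (
    daily_volume,
    first_retweet_latency,
    potential_exposure,
    retweeted_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths, windows, and thresholds driving one analysis run."""

    stream_path: Path
    lowcred_path: Path
    keywords_path: Path
    topic_keywords_path: Path | None = None
    windows: PeriodWindows = field(default_factory=PeriodWindows.march_2021_study)
    domain_threshold: int = 20
    top_k: int = 100
    creation_cutoff: date = DEFAULT_CREATION_CUTOFF
    out_dir: Path = Path("credflow_out")
    seed: int = 0
    topic_only: bool = False
    strict_authors: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent
        windows = raw.get("windows")
        if windows is not None:
            windows = PeriodWindows(
                tuple(
                    (
                        w["label"],
                        date.fromisoformat(str(w["start"])),
                        date.fromisoformat(str(w["end"])),
                    )
                    for w in windows
                )
            )
        else:
            windows = PeriodWindows.march_2021_study()

        def _path(key, default=None):
            if key in raw and raw[key] is not None:
                p = Path(raw[key])
                return p if p.is_absolute() else base / p
            return default

        return cls(
            stream_path=_path("stream_path"),
            lowcred_path=_path("lowcred_path"),
            keywords_path=_path("keywords_path"),
            topic_keywords_path=_path("topic_keywords_path"),
            windows=windows,
            domain_threshold=int(raw.get("domain_threshold", 20)),
            top_k=int(raw.get("top_k", 100)),
            creation_cutoff=date.fromisoformat(
                str(raw.get("creation_cutoff", DEFAULT_CREATION_CUTOFF))
            ),
            out_dir=_path("out_dir", Path("credflow_out")),
            seed=int(raw.get("seed", 0)),
            topic_only=bool(raw.get("topic_only", False)),
            strict_authors=bool(raw.get("strict_authors", False)),
        )

    def validate_paths(self) -> None:
        for name in ("stream_path", "lowcred_path", "keywords_path"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} missing or does not exist: {p}")
        if self.topic_keywords_path is not None and not Path(
            self.topic_keywords_path
        ).exists():
            raise FileNotFoundError(
                f"topic_keywords_path does not exist: {self.topic_keywords_path}"
            )


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / f"{name}.csv", index=False)


def _temporal_tables(corpora: dict[str, dict], windows: PeriodWindows):
    exposure_rows, fraction_rows, latency_rows, volume_frames = [], [], [], []
    for corpus_name, classes in corpora.items():
        for class_name, recs in classes.items():
            exp = potential_exposure(recs, windows)
            exposure_rows.append(
                {
                    "corpus": corpus_name,
                    "dataset": class_name,
                    "mean_followers_per_record": exp.mean,
                    "sd_followers_per_record": exp.sd,
                    "mean_printed": exp.mean_printed,
                    "sd_printed": exp.sd_printed,
                }
            )
            vol = daily_volume(recs, windows)
            volume_frames.append(
                pd.DataFrame(
                    {
                        "corpus": corpus_name,
                        "dataset": class_name,
                        "date": vol.index,
                        "count": vol.to_numpy(),
                    }
                )
            )
            for period in windows.labels:
                start, end = windows.span(period)
                period_recs = [
                    r for r in recs if start <= r.created_at.date() <= end
                ]
                frac = retweeted_fraction(period_recs, windows)
                fraction_rows.append(
                    {
                        "corpus": corpus_name,
                        "dataset": class_name,
                        "period": period,
                        "retweeted_pct": frac,
                    }
                )
                lat = first_retweet_latency(period_recs)
                if lat.n_retweeted:
                    q = lat.latencies["minutes"].quantile([0.25, 0.5, 0.75])
                    latency_rows.append(
                        {
                            "corpus": corpus_name,
                            "dataset": class_name,
                            "period": period,
                            "n_retweeted": lat.n_retweeted,
                            "q25_min": q[0.25],
                            "median_min": q[0.5],
                            "q75_min": q[0.75],
                        }
                    )
    return (
        pd.DataFrame(exposure_rows),
        pd.DataFrame(fraction_rows),
        pd.DataFrame(
            latency_rows,
            columns=[
                "corpus", "dataset", "period", "n_retweeted",
                "q25_min", "median_min", "q75_min",
            ],
        ),
        pd.concat(volume_frames, ignore_index=True),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = config.windows

    parsed = read_tweet_stream(config.stream_path)
    logger.info("stream: %d records in, %d skipped", len(parsed), parsed.n_skipped)
    keywords = load_line_list(config.keywords_path)
    lowcred = normalize_domain_list(load_line_list(config.lowcred_path))

    corpus_records = filter_keywords(parsed.records, keywords)
    logger.info(
        "keyword filter: %d -> %d records", len(parsed), len(corpus_records)
    )
    partitions: dict[str, CorpusPartition] = {}
    if not config.topic_only:
        partitions["full"] = partition_credibility(corpus_records, lowcred, windows)
    if config.topic_keywords_path is not None:
        topic_keywords = load_line_list(config.topic_keywords_path)
        topic_records = filter_keywords(corpus_records, topic_keywords)
        logger.info(
            "topic filter: %d -> %d records", len(corpus_records), len(topic_records)
        )
        partitions["topic"] = partition_credibility(
            topic_records, lowcred, windows, topic=True
        )
    if not partitions:
        raise ValueError("nothing to analyze: topic_only set but no topic keywords")

    # --- corpus summary -------------------------------------------------
    summary = corpus_summary(
        partitions.get("full", partitions.get("topic")),
        partitions.get("topic") if "full" in partitions else None,
    )
    _write(summary, out_dir, "corpus_summary")
    summary.to_json(out_dir / "corpus_summary.json", orient="records", indent=2)

    # --- temporal -------------------------------------------------------
    corpora = {
        name: {
            "full": part.records(),
            "residual": part.records(cls=CredClass.RESIDUAL),
            "low_credibility": part.records(cls=CredClass.LOW_CREDIBILITY),
        }
        for name, part in partitions.items()
    }
    exposure, fractions, latencies, volumes = _temporal_tables(corpora, windows)
    _write(exposure, out_dir, "exposure")
    _write(fractions, out_dir, "retweeted_fractions")
    _write(latencies, out_dir, "latency_quantiles")
    _write(volumes, out_dir, "daily_volume")

    # --- networks -------------------------------------------------------
    composition_rows, centrality_rows = [], []
    graphs: dict[tuple[str, str], dict[str, object]] = {}
    for corpus_name, part in partitions.items():
        for cls in (CredClass.RESIDUAL, CredClass.LOW_CREDIBILITY):
            period_graphs = {}
            for period in windows.labels:
                G = build_graph(part.records(period=period, cls=cls))
                period_graphs[period] = G
                if G.number_of_nodes() == 0:
                    continue
                report = analyze_graph(G)
                comp = report.composition.copy()
                comp.insert(0, "corpus", corpus_name)
                comp.insert(1, "dataset", cls.value)
                comp.insert(2, "period", period)
                comp["n_nodes"] = report.composition.attrs["n_nodes"]
                composition_rows.append(comp)
                cent = report.centrality_stats.copy()
                cent.insert(0, "corpus", corpus_name)
                cent.insert(1, "dataset", cls.value)
                cent.insert(2, "period", period)
                centrality_rows.append(cent)
            graphs[(corpus_name, cls.value)] = period_graphs
    if composition_rows:
        _write(pd.concat(composition_rows, ignore_index=True), out_dir, "composition")
        _write(
            pd.concat(centrality_rows, ignore_index=True),
            out_dir,
            "centrality_summary",
        )

    # --- domains and authors -------------------------------------------
    for corpus_name, part in partitions.items():
        pop = domain_popularity(part, config.domain_threshold)
        _write(pop, out_dir, f"domain_popularity_{corpus_name}")
    rankings: dict[tuple[str, str], pd.DataFrame] = {}
    for (corpus_name, cls_name), period_graphs in graphs.items():
        usable = {
            lab: G for lab, G in period_graphs.items() if G.number_of_nodes() >= 2
        }
        if not usable:
            continue
        ranking = top_authors(usable, config.top_k)
        rankings[(corpus_name, cls_name)] = ranking
        _write(ranking, out_dir, f"top_authors_{corpus_name}_{cls_name}")

    # --- account profiles ----------------------------------------------
    profiles_out = {}
    tests_frames = []
    for corpus_name, part in partitions.items():
        for cls in (None, CredClass.RESIDUAL, CredClass.LOW_CREDIBILITY):
            cls_name = cls.value if cls else "full"
            recs = part.records(cls=cls) if cls else part.records()
            users = user_table(recs)
            if users.empty:
                continue
            cohorts = {"userbase": users}
            if cls is not None:
                node_classes: dict = {}
                for period_graph in graphs[(corpus_name, cls_name)].values():
                    node_classes.update(classify_nodes(period_graph))
                authors = authors_cohort(
                    users, node_classes, strict=config.strict_authors
                )
                if not authors.empty:
                    cohorts["authors"] = authors
                ranking = rankings.get((corpus_name, cls_name))
                if ranking is not None and not ranking.empty:
                    top_ids = set(ranking["user_id"])
                    top_users = users[users["user_id"].isin(top_ids)]
                    if not top_users.empty:
                        cohorts["top_influential"] = top_users.reset_index(drop=True)
            profs, tests = account_profiles(cohorts, cutoff=config.creation_cutoff)
            profiles_out[f"{corpus_name}/{cls_name}"] = {
                name: {
                    "n": p.n,
                    "verified_pct": p.verified_pct,
                    "share_since_cutoff_pct": p.share_since_cutoff_pct,
                    "follower_median": p.follower_median,
                    "creation_year_hist": {
                        str(k): int(v) for k, v in p.creation_year_hist.items()
                    },
                    "follower_log_hist": {
                        str(k): int(v) for k, v in p.follower_log_hist.items()
                    },
                }
                for name, p in profs.items()
            }
            if not tests.empty:
                tests.insert(0, "corpus", corpus_name)
                tests.insert(1, "dataset", cls_name)
                tests_frames.append(tests)
    (out_dir / "account_profiles.json").write_text(
        json.dumps(profiles_out, indent=2, sort_keys=True), encoding="utf-8"
    )
    if tests_frames:
        _write(pd.concat(tests_frames, ignore_index=True), out_dir, "cohort_rank_tests")

    manifest = {
        "credflow_version": __version__,
        "seed": config.seed,
        "n_records_read": len(parsed),
        "n_lines_skipped": parsed.n_skipped,
        "n_corpus_records": len(corpus_records),
        "counts": {
            name: {
                "outside_windows": part.n_outside_windows,
                **{
                    f"{per}/{c.value}": part.count(per, c)
                    for per in windows.labels
                    for c in CredClass
                },
            }
            for name, part in partitions.items()
        },
        "status": "ok",
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
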