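"""End-to-end pipeline: simulate → screen → extract → QC → compare.

Every stage is seeded from the single pipeline seed, so a run is fully
reproducible from (config, seed). The run directory receives the corpus,
the QC report, the cohort summary table, the aggregate and per-study
comparison tables, a JSON manifest with the stage counts (the processing
funnel), and a log.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import equivalence, extraction, glove, io, literature, qc, screen, synthetic
from .catalog import TestCatalog
from .equivalence import BoundarySpec, CohortComparison
from .synthetic import LabPanelSpec
from .text import preprocess
from .types import CohortSummary

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    n_posts: int = 2000
    style_mix: Optional[dict[str, float]] = None
    classifier: str = "cnn"             # "cnn" or "keyword"
    n_labeled: int = 400
    threshold: float = 0.5
    embed_dim: int = 50
    embed_window: int = 5
    embed_epochs: int = 25
    reprocess_z: float = qc.REPROCESS_Z
    removal_z: float = qc.REMOVAL_Z
    min_count: int = qc.MIN_COUNT
    reprocess_widen: float = 1.5
    cohen_d: float = equivalence.DEFAULT_COHEN_D
    alpha: float = equivalence.DEFAULT_ALPHA
    catalog_path: Optional[str] = None
    posts_path: Optional[str] = None    # use an existing corpus instead
    outdir: str = "forumlab_run"

    def __post_init__(self) -> None:
        if self.classifier not in ("cnn", "keyword"):
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        for name in ("reprocess_z", "removal_z", "min_count", "cohen_d", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    counts: dict[str, int] = field(default_factory=dict)
    summary: Optional[pd.DataFrame] = None
    aggregate_table: Optional[pd.DataFrame] = None
    per_study_table: Optional[pd.DataFrame] = None


def _seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, n)]


def cohort_from_summary(frame: pd.DataFrame) -> dict[str, CohortSummary]:
    """CohortSummary side from a cohort summary table (post-removal)."""
    return {
        r.test: CohortSummary(r.test, int(r.n), float(r.mean), float(r.sd))
        for r in frame.itertuples()
        if r.n >= 2 and r.sd > 0
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    catalog = (
        TestCatalog.from_file(config.catalog_path)
        if config.catalog_path else TestCatalog.default()
    )
    spec = LabPanelSpec(catalog)
    seeds = _seeds(config.seed, 4)
    counts: dict[str, int] = {}

    # -- stage 1: corpus ---------------------------------------------------
    truth = None
    if config.posts_path:
        posts = io.load_posts(config.posts_path)
        log.info("loaded %d posts from %s", len(posts), config.posts_path)
    else:
        posts, truth = synthetic.generate_corpus(
            spec, config.style_mix, config.n_posts, seed=seeds[0]
        )
        io.write_posts(posts, outdir / "corpus.jsonl")
        synthetic.write_truth_json(truth, outdir / "truth.json")
        log.info("generated %d posts", len(posts))
    counts["posts"] = len(posts)

    # -- stage 2: screen ---------------------------------------------------
    if config.classifier == "keyword" or truth is None:
        model = screen.KeywordScreen(catalog, threshold=config.threshold)
        log.info("screening with the keyword rule")
    else:
        model = train_screen_from_truth(
            posts, truth, config, seed=seeds[1]
        )
        metrics = screen.evaluate_screen(model, model.holdout)
        log.info("CNN held-out accuracy %.3f (n=%d)",
                 metrics["accuracy"], metrics["n"])
    decisions = screen.screen(model, posts, threshold=config.threshold)
    flagged_ids = {pid for pid, _, flag in decisions if flag}
    flagged_posts = [p for p in posts if p.id in flagged_ids]
    counts["flagged_posts"] = len(flagged_posts)
    log.info("flagged %d/%d posts", len(flagged_posts), len(posts))

    # -- stage 3: extract (with one reprocessing pass) ---------------------
    observations, rejections, cycle_notes, mentions_by_obs = _extract(
        flagged_posts, catalog
    )
    counts["posts_with_mentions"] = len({o.post_id for o in observations})
    counts["observations"] = len(observations)
    counts["rejections"] = len(rejections)

    observations = _reprocess(
        observations, mentions_by_obs, catalog, config
    )
    sets = extraction.assemble_test_sets(observations, cycle_notes)
    for ts in sets:
        extraction.compute_derived(ts)
    counts["test_sets"] = len(sets)
    counts["observations_after_dedup"] = sum(len(t.observations) for t in sets)

    # -- stage 4: QC -------------------------------------------------------
    report = qc.qc_report(sets, config.reprocess_z, config.removal_z)
    summary = qc.summarize_cohort(
        sets, min_count=config.min_count, removal_z=config.removal_z,
        test_order=catalog.test_ids,
    )
    counts["observations_after_outliers"] = int(summary["n"].sum())
    io.write_table(report.to_frame(), outdir / "qc_report.tsv")
    io.write_table(qc.render_summary_table(summary), outdir / "cohort_summary.tsv")
    _write_rejections(rejections, outdir / "rejections.tsv")

    # -- stage 5: compare against the literature ---------------------------
    agg_frame, per_frame = compare_to_literature(
        cohort_from_summary(summary),
        BoundarySpec(config.cohen_d, config.alpha),
    )
    if agg_frame is not None:
        io.write_table(agg_frame, outdir / "comparison_aggregate.tsv", decimals=2)
    io.write_table(per_frame, outdir / "comparison_per_study.tsv", decimals=2)

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("funnel: %s", counts)
    return PipelineResult(
        outdir=outdir, counts=counts, summary=summary,
        aggregate_table=agg_frame, per_study_table=per_frame,
    )


def train_screen_from_truth(
    posts, truth, config: PipelineConfig, seed: int
) -> screen.ScreenModel:
    """Embeddings on the whole corpus, CNN on a labeled sample of it."""
    token_seqs = [preprocess(p.text) for p in posts]
    table = glove.train_embeddings(
        token_seqs, d=config.embed_dim, window=config.embed_window,
        epochs=config.embed_epochs, seed=seed,
    )
    labels = truth.labels()
    rng = np.random.default_rng(seed + 1)
    idx = rng.permutation(len(posts))[: config.n_labeled]
    labeled = [(token_seqs[i], labels[posts[i].id]) for i in idx]
    hyper = screen.ScreenHyper(threshold=config.threshold)
    return screen.train_screen(labeled, table, hyper, seed=seed + 2)


def _extract(flagged_posts, catalog):
    observations, rejections = [], []
    mentions_by_obs = []
    cycle_notes = {}
    for post in flagged_posts:
        for mention in extraction.find_mentions(post, catalog):
            resolved = extraction.resolve_mention(mention, catalog)
            if isinstance(resolved, extraction.Rejection):
                rejections.append(resolved)
            else:
                observations.append(resolved)
                mentions_by_obs.append(mention)
        phase = extraction.find_cycle_phase(post)
        if phase:
            cycle_notes.setdefault((post.author, post.day), phase)
    return observations, rejections, cycle_notes, mentions_by_obs


def _reprocess(observations, mentions, catalog, config: PipelineConfig):
    """One reprocessing pass: uncertain or |z|>2 observations are re-run
    through unit inference with widened plausibility; confident re-readings
    replace uncertain ones, everything else is left as recorded."""
    by_test: dict[str, list[int]] = {}
    for i, obs in enumerate(observations):
        by_test.setdefault(obs.test_id, []).append(i)
    n_changed = 0
    for test_id, idxs in by_test.items():
        flagged = qc.flag_reprocess(
            [observations[i] for i in idxs], config.reprocess_z
        )
        flagged_ids = {id(o) for o in flagged}
        for i in idxs:
            obs = observations[i]
            if id(obs) not in flagged_ids or not obs.uncertain:
                continue
            status, value, uncertain = extraction.infer_unit(
                obs.test_id, mentions[i].value, mentions[i].unit, catalog,
                widen=config.reprocess_widen,
            )
            if status == "ok" and not uncertain and value != obs.value:
                obs.value = value
                obs.uncertain = False
                n_changed += 1
    if n_changed:
        log.info("reprocessing changed %d observations", n_changed)
    return observations


def compare_to_literature(
    cohort: dict[str, CohortSummary],
    spec: BoundarySpec = BoundarySpec(),
    studies: Optional[dict[str, dict[str, CohortSummary]]] = None,
):
    """Compare a cohort against the per-study literature and the
    sample-size-weighted aggregate of the reporting studies."""
    studies = studies or literature.study_summaries()
    per_res = CohortComparison(cohort, studies, spec).fit()
    aggregate = {}
    for test_id in cohort:
        contributing = [
            ref[test_id] for ref in studies.values() if test_id in ref
        ]
        if contributing:
            aggregate[test_id] = equivalence.aggregate_mean(contributing)
    agg_frame = None
    if aggregate:
        agg_res = CohortComparison(cohort, {"aggregate": aggregate}, spec).fit()
        agg_frame = agg_res.to_frame()
    return agg_frame, per_res.to_frame()


def reproduce_published_tables(
    spec: BoundarySpec = BoundarySpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Literature-only reproduction mode: run the comparison procedure on
    the published summary statistics (forum cohort vs published aggregate,
    and forum cohort vs each study)."""
    cohort = literature.subreddit_summaries()
    agg_res = CohortComparison(
        cohort, {"aggregate": literature.published_aggregate_summaries()}, spec
    ).fit()
    per_res = CohortComparison(cohort, literature.study_summaries(), spec).fit()
    return agg_res.to_frame(), per_res.to_frame()


def _write_rejections(rejections, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "test": r.test_id, "value": r.value, "unit": r.unit or "",
                "post_id": r.post_id, "reason": r.reason,
            }
            for r in rejections
        ],
        columns=["test", "value", "unit", "post_id", "reason"],
    )
    io.write_table(frame, path, decimals=3)


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("forumlab")
    root.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "pipeline.log").resolve()
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(outdir / "pipeline.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(fh)
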