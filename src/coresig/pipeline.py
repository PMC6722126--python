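"""End-to-end orchestration: per-cohort signature selection and cross-study
comparison, with deterministic JSON/TSV artifacts.

Per cohort the stages are: read pool and expression -> trim to the pool ->
rank genes (SRVS and/or ANOVA) -> LOO CR curve over top-n vectors ->
select the best classifier -> gene-set permutation significance ->
random-gene baseline curve. Across cohorts: Jaccard similarity of the
selected gene sets, a factor ANOVA on the similarity values, and summary
statistics of the per-cohort CRs.

Every artifact embeds the seed and a hash of the effective configuration;
two runs with equal hashes produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classification, cross_study, permutation, ranking
from .data_io import ExpressionDataset, read_expression_tsv, read_gene_pool, trim_to_pool
from .ranking import ANOVA, POOL_ALL, SRVS, SRVSConfig

logger = logging.getLogger(__name__)

METHOD_CHOICES = ("srvs", "anova", "pool_all", "all")


@dataclass
class RunConfig:
    """Configuration of one per-cohort run."""

    expression_path: str
    labels_path: str
    pool_path: str
    out_dir: str
    method: str = "all"
    srvs: SRVSConfig = field(default_factory=SRVSConfig)
    permutation_runs: int = 5000
    baseline_reps: int = 300
    baseline_n_values: tuple[int, ...] | None = None
    n_max: int | None = None
    universe: str = "all"          # "all" measured genes or "pool"
    classifier: str = "centroid"   # or "nn1"
    seed: int = 0
    cohort_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHOD_CHOICES:
            raise ValueError(f"method must be one of {METHOD_CHOICES}")
        if self.permutation_runs < 1 or self.baseline_reps < 1:
            raise ValueError("permutation runs and baseline reps must be >= 1")
        if self.universe not in ("all", "pool"):
            raise ValueError("universe must be 'all' or 'pool'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the effective analysis parameters (the output location
        does not affect the science, so it is excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_paths(config: RunConfig) -> None:
    for name in ("expression_path", "labels_path", "pool_path"):
        path = Path(getattr(config, name))
        if not path.exists():
            raise FileNotFoundError(f"{name.replace('_path', '')} file not "
                                    f"found: {path}")


def run_cohort(config: RunConfig) -> dict[str, classification.ClassifierResult]:
    """Execute every stage for one cohort; returns per-method results and
    writes JSON/TSV artifacts plus a parameter log under ``out_dir``."""
    _check_paths(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        pool = read_gene_pool(config.pool_path)
    except Exception as exc:
        raise RuntimeError(f"stage read_gene_pool failed: {exc}") from exc
    try:
        full = read_expression_tsv(config.expression_path, config.labels_path,
                                   metadata=dict(config.metadata))
    except Exception as exc:
        raise RuntimeError(f"stage read_expression failed: {exc}") from exc
    try:
        trimmed = trim_to_pool(full, pool)
    except Exception as exc:
        raise RuntimeError(f"stage trim_to_pool failed: {exc}") from exc

    universe = full if config.universe == "all" else trimmed
    cohort = config.cohort_id or full.metadata.get("cohort_id") or "cohort"

    srvs_cfg = config.srvs
    if srvs_cfg.seed is None:
        srvs_cfg = dataclasses.replace(srvs_cfg, seed=config.seed)

    results: dict[str, classification.ClassifierResult] = {}
    rankings: list[ranking.RankedGeneList] = []

    def _selected(ranked: ranking.RankedGeneList) -> classification.ClassifierResult:
        n_max = config.n_max or len(ranked)
        n_max = min(n_max, len(ranked))
        curve = classification.cr_curve(trimmed, ranked, n_max,
                                        classifier=config.classifier)
        return classification.select_best(curve, ranked)

    try:
        if config.method in ("srvs", "all"):
            ranked = ranking.srvs_scores(trimmed, srvs_cfg)
            rankings.append(ranked)
            results[SRVS] = _selected(ranked)
        if config.method in ("anova", "all"):
            ranked = ranking.anova_scores(trimmed)
            rankings.append(ranked)
            results[ANOVA] = _selected(ranked)
        if config.method in ("pool_all", "all"):
            results[POOL_ALL] = classification.pool_classifier(
                trimmed, classifier=config.classifier)
    except Exception as exc:
        raise RuntimeError(f"stage ranking/classification failed: {exc}") from exc

    try:
        for method, result in results.items():
            result.permutation = permutation.permutation_pvalue(
                universe, k=result.best_n, observed_cr=result.max_cr,
                runs=config.permutation_runs, seed=config.seed + 1,
                classifier=config.classifier)
        n_values = config.baseline_n_values or tuple(
            range(1, min(30, universe.n_genes) + 1))
        baseline = permutation.baseline_curve(
            universe, n_values, reps=config.baseline_reps,
            seed=config.seed + 2, classifier=config.classifier)
    except Exception as exc:
        raise RuntimeError(f"stage permutation failed: {exc}") from exc

    _write_cohort_artifacts(config, cohort, results, rankings, baseline, out_dir)
    return results


def _write_cohort_artifacts(config, cohort, results, rankings, baseline,
                            out_dir: Path) -> None:
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "cohort_id": cohort, "metadata": dict(config.metadata)}
    for method, result in results.items():
        payload = dict(stamp)
        payload.update(result.to_dict())
        path = out_dir / f"{cohort}_{method}_result.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if rankings:
        ranking.write_scores_tsv(rankings, out_dir / f"{cohort}_scores.tsv")
    baseline.to_tsv(out_dir / f"{cohort}_baseline.tsv")
    log = dict(stamp)
    log["config"] = config.to_dict()
    (out_dir / f"{cohort}_run.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")


def results_frame(per_cohort: Mapping[str, Mapping[str, classification.ClassifierResult]]
                  ) -> pd.DataFrame:
    """Tidy per-cohort results table for :func:`cross_study.summarize_studies`."""
    rows = []
    for cohort, methods in per_cohort.items():
        for method, result in methods.items():
            perm = result.permutation
            rows.append({"cohort_id": cohort, "method": method,
                         "cr": result.max_cr,
                         "perm_p": perm.reported if perm is not None else float("nan")})
    return pd.DataFrame(rows)


def run_collection(configs: Sequence[RunConfig],
                   similarity_methods: tuple[str, ...] = (SRVS, ANOVA)
                   ) -> tuple["cross_study.SimilarityMatrix",
                              "cross_study.AnovaTable",
                              "cross_study.CrossStudySummary"]:
    """Run (or gather) >= 2 cohorts and compare them: Jaccard similarity
    matrix of selected gene sets, factor ANOVA on the similarity values,
    and cross-study summary statistics."""
    if len(configs) < 2:
        raise ValueError("need at least 2 cohorts")
    per_cohort: dict[str, dict[str, classification.ClassifierResult]] = {}
    factors: dict[tuple[str, str], dict] = {}
    for i, config in enumerate(configs):
        results = run_cohort(config)
        cohort = config.cohort_id or f"cohort{i+1}"
        per_cohort[cohort] = results
        for method in results:
            factors[(cohort, method)] = {
                "brain_region": config.metadata.get("brain_region", "unknown"),
                "ethnicity": config.metadata.get("ethnicity", "unknown"),
                "method": method,
            }
    return compare_results(per_cohort, factors, similarity_methods)


def compare_results(per_cohort: Mapping[str, Mapping[str, classification.ClassifierResult]],
                    factors: Mapping[tuple[str, str], Mapping[str, str]],
                    similarity_methods: tuple[str, ...] = (SRVS, ANOVA)
                    ) -> tuple["cross_study.SimilarityMatrix",
                               "cross_study.AnovaTable",
                               "cross_study.CrossStudySummary"]:
    if len(per_cohort) < 2:
        raise ValueError("need at least 2 successful cohorts")
    sets = [(cohort, method, set(methods[method].gene_vector))
            for cohort, methods in per_cohort.items()
            for method in similarity_methods if method in methods]
    sim = cross_study.jaccard_matrix(sets)
    # a factor observed at a single level carries no contrast; drop it
    candidate_names = ("brain_region", "ethnicity", "method")
    factor_names = tuple(
        name for name in candidate_names
        if len({factors[label].get(name, label[1] if name == "method" else None)
                for label in sim.labels}) >= 2)
    if not factor_names:
        raise ValueError("no cohort factor varies across the collection")
    anova = cross_study.similarity_anova(sim, factors, factor_names=factor_names)
    summary = cross_study.summarize_studies(results_frame(per_cohort))
    return sim, anova, summary
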