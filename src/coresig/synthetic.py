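"""Synthetic case/control cohorts with known ground truth.

The generator emulates preprocessed (log-scale) microarray brain-expression
cohorts: each gene has a Gaussian baseline (mean drawn from
``base_mean_range``, SD from ``base_sd_range``), a planted subset of
informative pool genes has its case mean shifted by ``effect_size``
within-class SDs, and optional equicorrelated blocks add gene-gene
correlation. Cohort metadata (brain region, ethnicity) supports the
cross-study stage. Everything is deterministic given the seeds.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (CASE, CONTROL, ExpressionDataset, GenePool,
                      write_expression_tsv, write_gene_pool)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    """Shape and signal of one synthetic cohort.

    Defaults describe a balanced 40+40 cohort with 200 pool genes among
    1,000 measured genes, 20 informative genes, and a moderate planted
    shift of 1.5 within-class SDs — a mid-range brain expression cohort.
    """

    n_cases: int = 40
    n_controls: int = 40
    n_genome: int = 1000
    n_pool: int = 200
    n_informative: int = 20
    effect_size: float = 1.5
    base_mean_range: tuple[float, float] = (6.0, 10.0)
    base_sd_range: tuple[float, float] = (0.5, 1.5)
    correlation_block: tuple[int, float] | None = None
    cohort_id: str = "cohort"
    brain_region: str = "prefrontal cortex"
    ethnicity: str = "USA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample counts must be positive")
        if not (self.n_informative <= self.n_pool <= self.n_genome):
            raise ValueError("need n_informative <= n_pool <= n_genome")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.correlation_block is not None:
            _, rho = self.correlation_block
            if not (0.0 <= rho < 1.0):
                raise ValueError("block correlation must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Which genes carry signal, and how much."""

    informative: tuple[str, ...]
    effects: dict  # symbol -> planted shift in within-class SD units
    metadata: dict

    def to_dict(self) -> dict:
        return {"informative": list(self.informative), "effects": self.effects,
                "metadata": self.metadata}


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_pool(n_pool: int, n_genome: int, seed: int = 0
                  ) -> tuple[GenePool, list[str]]:
    """A synthetic genome of ``n_genome`` symbols and a uniform random
    ``n_pool``-gene pool (genome order preserved within the pool)."""
    if n_pool > n_genome:
        raise ValueError("n_pool must not exceed n_genome")
    genome = _symbols(n_genome)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    idx = np.sort(rng.choice(n_genome, size=n_pool, replace=False))
    return GenePool(tuple(genome[i] for i in idx)), genome


def generate_dataset(spec: CohortSpec,
                     pool: GenePool | None = None,
                     genome: Sequence[str] | None = None,
                     informative: Sequence[str] | None = None
                     ) -> tuple[ExpressionDataset, GroundTruth]:
    """One synthetic cohort and its ground truth.

    Per gene g: baseline mean mu_g ~ U(base_mean_range) and SD
    sigma_g ~ U(base_sd_range); values ~ N(mu_g, sigma_g), with the case
    mean of each informative gene shifted by effect_size * sigma_g.
    """
    if pool is None or genome is None:
        pool, genome = generate_pool(spec.n_pool, spec.n_genome, spec.seed)
    genome = list(genome)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                       spawn_key=(1,)))
    if informative is None:
        informative = tuple(sorted(
            str(g) for g in
            rng.choice(pool.symbols, size=spec.n_informative, replace=False)))
    else:
        informative = tuple(informative)
        if not set(informative) <= pool.symbol_set:
            raise ValueError("informative genes must be a subset of the pool")

    n_genes = len(genome)
    n = spec.n_cases + spec.n_controls
    mu = rng.uniform(*spec.base_mean_range, size=n_genes)
    sigma = rng.uniform(*spec.base_sd_range, size=n_genes)

    if spec.correlation_block is None:
        z = rng.standard_normal((n_genes, n))
    else:
        block, rho = spec.correlation_block
        eps = rng.standard_normal((n_genes, n))
        n_blocks = -(-n_genes // block)
        shared = rng.standard_normal((n_blocks, n))
        factor = np.repeat(shared, block, axis=0)[:n_genes]
        z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps

    values = mu[:, None] + sigma[:, None] * z
    is_case = np.zeros(n, dtype=bool)
    is_case[:spec.n_cases] = True
    info_idx = [genome.index(g) for g in informative]
    for i in info_idx:
        values[i, is_case] += spec.effect_size * sigma[i]

    sample_ids = [f"{spec.cohort_id}_S{j:04d}" for j in range(1, n + 1)]
    labels = pd.Series(np.where(is_case, CASE, CONTROL), index=sample_ids,
                       name="label")
    metadata = {"cohort_id": spec.cohort_id, "brain_region": spec.brain_region,
                "ethnicity": spec.ethnicity, "seed": spec.seed}
    expr = pd.DataFrame(values, index=genome, columns=sample_ids)
    dataset = ExpressionDataset(expr, labels, metadata)
    truth = GroundTruth(informative,
                        {g: spec.effect_size for g in informative},
                        dict(metadata))
    return dataset, truth


def generate_study_collection(specs: Sequence[CohortSpec], overlap: float,
                              seed: int = 0
                              ) -> list[tuple[ExpressionDataset, GroundTruth]]:
    """A multi-cohort collection with partially overlapping informative sets.

    All cohorts share one genome and pool. Each cohort's informative set
    takes fraction ``overlap`` from a common core; the remainder is
    cohort-specific and pairwise disjoint across cohorts.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 cohort specs")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    n_genome = specs[0].n_genome
    n_pool = specs[0].n_pool
    if any(s.n_genome != n_genome or s.n_pool != n_pool for s in specs):
        raise ValueError("all specs must share n_genome and n_pool")

    pool, genome = generate_pool(n_pool, n_genome, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    shuffled = list(rng.permutation(pool.symbols))

    core_sizes = [round(overlap * s.n_informative) for s in specs]
    core_max = max(core_sizes)
    core = shuffled[:core_max]
    cursor = core_max
    out = []
    for i, (spec, k_core) in enumerate(zip(specs, core_sizes)):
        k_specific = spec.n_informative - k_core
        if cursor + k_specific > len(shuffled):
            raise ValueError("pool too small for disjoint cohort-specific "
                             "informative sets")
        informative = tuple(sorted(core[:k_core] + shuffled[cursor:cursor + k_specific]))
        cursor += k_specific
        data_spec = dataclasses.replace(
            spec, seed=(seed * 100_003 + 1_009 * i + spec.seed) % (2 ** 31))
        out.append(generate_dataset(data_spec, pool=pool, genome=genome,
                                    informative=informative))
    return out


def write_cohort(dataset: ExpressionDataset, truth: GroundTruth,
                 pool: GenePool, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the formats data_io reads, plus ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = dataset.metadata.get("cohort_id", "cohort")
    paths = {
        "expression": out_dir / f"{cohort}_expression.tsv",
        "labels": out_dir / f"{cohort}_labels.tsv",
        "pool": out_dir / f"{cohort}_pool.txt",
        "truth": out_dir / f"{cohort}_truth.json",
    }
    write_expression_tsv(dataset, paths["expression"], paths["labels"])
    write_gene_pool(pool, paths["pool"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2,
                                         sort_keys=True) + "\n")
    return paths
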