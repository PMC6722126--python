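"""Bundled reference tables from a published 14-cohort schizophrenia
brain-expression classification study.

Two small TSVs ship with the package:

* ``scz14_classifier_results.tsv`` — per-cohort best-classifier results:
  maximum LOO classification ratio (percent) for the SRVS-selected,
  ANOVA-selected and whole-pool classifiers, the selected gene counts, and
  gene-set permutation p-values (censored entries written as ``"<x"``).
* ``scz14_cohort_info.tsv`` — cohort descriptors: case/control counts,
  number of curated pool genes measured, brain region and population.

These tables serve the results-fixture input mode: the cross-study summary
stage can be exercised against published numbers without downloading the
underlying GEO series.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

_RESULT_COLUMNS = {"srvs": "SRVS", "anova": "ANOVA", "pool": "POOL_ALL"}


def _data_path(name: str):
    return resources.files("coresig.data").joinpath(name)


def cohort_results() -> pd.DataFrame:
    """Published per-cohort classifier results, wide layout (one row per
    cohort; cr_*, n_*, p_* columns per method)."""
    with resources.as_file(_data_path("scz14_classifier_results.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"cohort_id": str})


def cohort_info() -> pd.DataFrame:
    """Published cohort descriptors (sample sizes, measured pool genes,
    brain region, population)."""
    with resources.as_file(_data_path("scz14_cohort_info.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"cohort_id": str})


def results_to_tidy(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide results table (cr_srvs/p_srvs, ...) to the tidy
    layout expected by :func:`coresig.cross_study.summarize_studies`."""
    rows = []
    for _, row in wide.iterrows():
        for key, method in _RESULT_COLUMNS.items():
            if f"cr_{key}" not in wide.columns:
                continue
            rows.append({
                "cohort_id": row["cohort_id"],
                "method": method,
                "cr": float(row[f"cr_{key}"]),
                "perm_p": row.get(f"p_{key}"),
            })
    return pd.DataFrame(rows)


def read_results_table(path) -> pd.DataFrame:
    """Read a user-supplied wide results TSV (same layout as the bundled
    table) and return the tidy form."""
    return results_to_tidy(pd.read_csv(path, sep="\t", dtype={"cohort_id": str}))
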