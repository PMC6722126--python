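"""Readers, writers and containers for expression matrices, labels and gene pools.

All gene symbols are compared case-insensitively and stored uppercased, since
public expression platforms mix symbol casing. Expression values are assumed
to be on a preprocessed, log-like scale; no normalisation is applied here.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
VALID_LABELS = (CASE, CONTROL)


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenePool:
    """A curated list of disease-associated gene symbols.

    Parameters
    ----------
    symbols
        Unique, case-normalised symbols in order of first appearance.
    ref_counts
        Number of supporting references per symbol (>= 1 each). When the
        pool file carries no counts, each occurrence of a symbol counts as
        one reference.
    """

    symbols: tuple[str, ...]
    ref_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("empty gene pool")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene pool symbols must be unique")
        if self.ref_counts is not None:
            for sym, cnt in self.ref_counts.items():
                if cnt < 1:
                    raise ValueError(f"ref_count for {sym} must be >= 1, got {cnt}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbol_set

    @property
    def symbol_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


@dataclass
class ExpressionDataset:
    """A gene-symbol x sample expression matrix with case/control labels.

    ``expr`` is genes x samples (index: uppercased symbols, columns: sample
    ids). ``labels`` maps every sample id to ``"case"`` or ``"control"``.
    ``metadata`` carries at least ``cohort_id``, ``brain_region`` and
    ``ethnicity`` when known.
    """

    expr: pd.DataFrame
    labels: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.expr.columns.has_duplicates:
            raise ValueError("duplicate sample id in expression matrix")
        missing = [s for s in self.expr.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing}")
        bad = set(self.labels.loc[list(self.expr.columns)]) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"invalid label value(s): {sorted(bad)}")
        values = self.expr.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("non-finite values in expression matrix")
        self.labels = self.labels.loc[list(self.expr.columns)]

    # -- basic views ------------------------------------------------------
    @property
    def gene_symbols(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return (self.labels.to_numpy() == CASE)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def label_vector(self) -> np.ndarray:
        """Numeric class encoding: case -> +1, control -> -1."""
        return np.where(self.is_case, 1.0, -1.0)

    def values(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Expression sub-matrix (genes x samples) as float64."""
        if genes is None:
            return self.expr.to_numpy(dtype=float)
        genes = [normalize_symbol(g) for g in genes]
        missing = [g for g in genes if g not in self.expr.index]
        if missing:
            raise KeyError(f"gene(s) not in dataset: {missing}")
        return self.expr.loc[genes].to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        genes = [normalize_symbol(g) for g in genes]
        missing = [g for g in genes if g not in self.expr.index]
        if missing:
            raise KeyError(f"gene(s) not in dataset: {missing}")
        return ExpressionDataset(self.expr.loc[genes].copy(), self.labels.copy(),
                                 dict(self.metadata))

    def require_two_per_class(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError(
                f"need >= 2 samples per class, got {self.n_cases} cases / "
                f"{self.n_controls} controls")


# ---------------------------------------------------------------------------
# gene pool
# ---------------------------------------------------------------------------

def read_gene_pool(path: str | Path) -> GenePool:
    """Read a gene pool: one symbol per line, optional tab-separated reference
    count, ``#`` comment lines ignored. Duplicate symbols are collapsed and
    their counts summed (a line without a count contributes one reference).
    """
    path = Path(path)
    symbols: list[str] = []
    counts: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sym = normalize_symbol(parts[0])
            if not sym:
                continue
            count = 1
            if len(parts) > 1 and parts[1].strip():
                try:
                    count = int(parts[1])
                except ValueError as exc:
                    raise ValueError(
                        f"malformed reference count on line {lineno} of {path}: "
                        f"{parts[1]!r}") from exc
                if count < 1:
                    raise ValueError(
                        f"malformed reference count on line {lineno} of {path}: "
                        f"{count} (must be >= 1)")
            if sym not in counts:
                symbols.append(sym)
                counts[sym] = 0
            counts[sym] += count
    if not symbols:
        raise ValueError("empty gene pool")
    return GenePool(tuple(symbols), counts)


def write_gene_pool(pool: GenePool, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sym in pool.symbols:
            if pool.ref_counts is not None:
                fh.write(f"{sym}\t{pool.ref_counts[sym]}\n")
            else:
                fh.write(f"{sym}\n")


# ---------------------------------------------------------------------------
# expression TSV + labels
# ---------------------------------------------------------------------------

def read_labels_tsv(path: str | Path) -> pd.Series:
    """Labels file: TSV with columns ``sample_id`` and ``label``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "label"}.issubset(df.columns):
        raise ValueError(f"labels file {path} must have columns sample_id, label")
    labels = df["label"].str.strip().str.lower()
    bad = set(labels) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"invalid label value(s) in {path}: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id in labels file: {dupes}")
    return pd.Series(labels.to_numpy(), index=df["sample_id"].to_numpy(), name="label")


def _frame_to_dataset(frame: pd.DataFrame, labels: pd.Series,
                      metadata: dict | None, source: str) -> ExpressionDataset:
    """Shared post-processing: symbol casing, duplicate-symbol collapse,
    non-finite row dropping, label reconciliation."""
    frame = frame.copy()
    frame.index = [normalize_symbol(str(g)) for g in frame.index]
    frame = frame.apply(pd.to_numeric, errors="coerce")

    if frame.index.has_duplicates:
        n_before = frame.shape[0]
        frame = frame.groupby(level=0, sort=False).mean()
        logger.warning("%s: collapsed %d duplicate gene symbols by mean",
                       source, n_before - frame.shape[0])

    bad_rows = ~np.isfinite(frame.to_numpy()).all(axis=1)
    if bad_rows.any():
        logger.warning("%s: dropped %d gene row(s) with non-finite values",
                       source, int(bad_rows.sum()))
        frame = frame.loc[~bad_rows]

    unlabeled = [s for s in frame.columns if s not in labels.index]
    if unlabeled:
        logger.warning("%s: dropped %d sample(s) absent from labels file: %s",
                       source, len(unlabeled), unlabeled)
        frame = frame.drop(columns=unlabeled)

    return ExpressionDataset(frame, labels, metadata or {})


def read_expression_tsv(path: str | Path, labels_path: str | Path,
                        metadata: dict | None = None) -> ExpressionDataset:
    """Read a genes x samples TSV (first column gene symbols, header of
    sample ids) plus a labels TSV. Rows with any non-finite value are
    dropped and counted; matrix samples missing from the labels file are
    dropped with a warning."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dupes = [s for s in set(sample_ids) if sample_ids.count(s) > 1]
    if dupes:
        raise ValueError(f"duplicate sample id in {path}: {sorted(dupes)}")
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.columns = sample_ids
    labels = read_labels_tsv(labels_path)
    return _frame_to_dataset(frame, labels, metadata, str(path))


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path,
                         labels_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally labels) in the TSV dialect read by
    :func:`read_expression_tsv`. Values round-trip bit-exactly (shortest
    repr of float64)."""
    frame = dataset.expr
    with Path(path).open("w") as fh:
        fh.write("gene_symbol\t" + "\t".join(map(str, frame.columns)) + "\n")
        values = frame.to_numpy()
        for gene, row in zip(frame.index, values):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    if labels_path is not None:
        with Path(labels_path).open("w") as fh:
            fh.write("sample_id\tlabel\n")
            for sid in dataset.sample_ids:
                fh.write(f"{sid}\t{dataset.labels[sid]}\n")


# ---------------------------------------------------------------------------
# GEO Series Matrix
# ---------------------------------------------------------------------------

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def read_series_matrix(path: str | Path,
                       symbol_map: str | Path | None = None,
                       labels_path: str | Path | None = None,
                       case_pattern: str | None = None,
                       collapse: str = "mean",
                       metadata: dict | None = None) -> ExpressionDataset:
    """Tolerant reader for GEO Series Matrix text files.

    The data table between the begin/end marker lines is read at probe
    level; an optional two-column ``probe<TAB>symbol`` map collapses probes
    to gene symbols (``collapse`` is ``"mean"`` or ``"max_variance"``).
    Labels come either from ``labels_path`` or, failing that, from the
    ``!Sample_characteristics`` metadata lines: a sample whose
    characteristics match the regular expression ``case_pattern`` is a
    case, any other sample a control.
    """
    path = Path(path)
    meta_lines: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = False
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            low = line.strip().lower()
            if low == _TABLE_BEGIN:
                in_table, saw_begin = True, True
                continue
            if low == _TABLE_END:
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                key, *rest = line.split("\t")
                meta_lines.setdefault(key.strip(), []).append(
                    [_unquote(t) for t in rest])
    if not saw_begin or not table_lines:
        raise ValueError(f"not a series-matrix file: {path}")

    header = [_unquote(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    probes, rows = [], []
    for line in table_lines[1:]:
        parts = [_unquote(t) for t in line.split("\t")]
        probes.append(parts[0])
        rows.append(parts[1:])
    frame = pd.DataFrame(rows, index=probes, columns=sample_ids)
    frame = frame.apply(pd.to_numeric, errors="coerce")

    if symbol_map is not None:
        mapping = {}
        with Path(symbol_map).open() as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                probe, _, sym = line.partition("\t")
                sym = normalize_symbol(sym)
                if sym:
                    mapping[probe.strip()] = sym
        keep = [p for p in frame.index if p in mapping]
        dropped = frame.shape[0] - len(keep)
        if dropped:
            logger.warning("%s: dropped %d unmapped probe(s)", path, dropped)
        frame = frame.loc[keep]
        frame.index = [mapping[p] for p in keep]
        frame = _collapse_probes(frame, collapse)

    if labels_path is not None:
        labels = read_labels_tsv(labels_path)
    elif case_pattern is not None:
        labels = _labels_from_characteristics(meta_lines, sample_ids, case_pattern)
    else:
        raise ValueError("labels_path or case_pattern required to label samples")

    return _frame_to_dataset(frame, labels, metadata, str(path))


def _collapse_probes(frame: pd.DataFrame, how: str) -> pd.DataFrame:
    """Collapse probe rows sharing a symbol; never increases the row count."""
    if not frame.index.has_duplicates:
        return frame
    if how == "mean":
        return frame.groupby(level=0, sort=False).mean()
    if how == "max_variance":
        order = pd.unique(frame.index)
        picks = []
        for sym in order:
            block = frame.loc[[sym]]
            picks.append(block.iloc[block.var(axis=1, ddof=0).to_numpy().argmax()])
        out = pd.DataFrame(picks)
        out.index = order
        return out
    raise ValueError(f"unknown collapse rule: {how!r}")


def _labels_from_characteristics(meta: Mapping[str, list[list[str]]],
                                 sample_ids: Sequence[str],
                                 case_pattern: str) -> pd.Series:
    pattern = re.compile(case_pattern, re.IGNORECASE)
    char_rows = [row for key, rows in meta.items()
                 if key.lower().startswith("!sample_characteristics")
                 for row in rows]
    if not char_rows:
        raise ValueError("no !Sample_characteristics lines to parse labels from")
    labels = []
    for j, sid in enumerate(sample_ids):
        fields = [row[j] for row in char_rows if j < len(row)]
        labels.append(CASE if any(pattern.search(f) for f in fields) else CONTROL)
    return pd.Series(labels, index=list(sample_ids), name="label")


# ---------------------------------------------------------------------------
# pool trimming
# ---------------------------------------------------------------------------

def trim_to_pool(dataset: ExpressionDataset, pool: GenePool) -> ExpressionDataset:
    """Restrict the dataset to genes present in the pool, preserving the
    dataset's gene order. Idempotent. Raises if no pool gene is measured."""
    pool_set = pool.symbol_set
    keep = [g for g in dataset.gene_symbols if g in pool_set]
    if not keep:
        raise ValueError("no pool genes measured")
    logger.info("trim_to_pool: %d of %d genes intersect the pool",
                len(keep), dataset.n_genes)
    if len(keep) == dataset.n_genes:
        return dataset
    return dataset.subset_genes(keep)
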