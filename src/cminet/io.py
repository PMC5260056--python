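"""Readers and writers for the tool's text formats.

Four tab-separated dialects, all UTF-8 with ``#``-prefixed comment lines
ignored:

* expression matrix — header row of condition labels, one label column of
  gene identifiers, genes in rows (a samples-in-rows file, the DREAM layout,
  is transposed on read);
* gold standard — three columns ``gene  gene  {0,1}``, no header, directed
  rows symmetrised to unordered pairs;
* interaction file — ``gene_a  gene_b  weight`` for every scored pair, the
  raw correlation value output;
* relation file — ``gene_a  gene_b  1`` for each retained edge (pairs below
  the cutoff are omitted unless zeros are explicitly requested).

Pairs are emitted with the lexically smaller gene first so diffs are stable.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene expression over experimental conditions (genes x conditions)."""

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        gene_ids = tuple(str(g) for g in self.gene_ids)
        condition_ids = tuple(str(c) for c in self.condition_ids)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(condition_ids)):
            raise InvalidInputError(
                f"values shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(condition_ids)} conditions"
            )
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise InvalidInputError(f"duplicate gene identifiers: {dupes}")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("expression values must be finite (no missing values)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "condition_ids", condition_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)


def _atomic_open(path: str | Path):
    """Context manager writing to a temp file then renaming into place."""
    path = Path(path)

    class _Atomic:
        def __enter__(self) -> IO[str]:
            fd, self.tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", text=True)
            self.fh = os.fdopen(fd, "w", encoding="utf-8", newline="\n")
            return self.fh

        def __exit__(self, exc_type, exc, tb) -> None:
            self.fh.close()
            if exc_type is None:
                os.replace(self.tmp, path)
            else:
                os.unlink(self.tmp)

    return _Atomic()


def read_expression(path: str | Path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Parse an expression TSV into genes x conditions orientation.

    ``orientation`` is ``"genes-in-rows"`` (native) or ``"samples-in-rows"``
    (the file is transposed after reading).  Non-numeric cells and missing
    values are format errors reported with their row/column labels.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise InvalidInputError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"expression file {path} has no data rows")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric or missing value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if orientation == "samples-in-rows":
        numeric = numeric.T
    index = [str(i) for i in numeric.index]
    if len(set(index)) != len(index):
        raise FormatError(f"duplicate gene labels in {path}")
    return ExpressionMatrix(
        gene_ids=tuple(index),
        condition_ids=tuple(str(c) for c in numeric.columns),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, precision: int | None = 6) -> None:
    """Write an expression matrix as genes-in-rows TSV (atomic)."""
    fmt = (lambda v: f"{v:.{precision}f}") if precision is not None else (lambda v: format(float(v), ".17g"))
    with _atomic_open(path) as fh:
        fh.write("gene\t" + "\t".join(expr.condition_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def _ordered_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def write_network(state, prefix: str | Path, emit_zeros: bool = False, precision: int | None = 6) -> tuple[Path, Path]:
    """Write the interaction (weights) and relation (0/1) files for a network.

    The interaction file records the final score of every evaluated pair; the
    relation file lists retained edges as 1-rows.  With ``emit_zeros`` every
    pair appears in the relation file with an explicit 0/1 — impractical at
    genome scale, hence off by default.  Returns the two paths written.
    """
    prefix = Path(prefix)
    interaction = prefix.with_name(prefix.name + ".interaction.tsv")
    relation = prefix.with_name(prefix.name + ".relation.tsv")
    labels = state.gene_labels
    fmt = (lambda v: f"{v:.{precision}f}") if precision is not None else (lambda v: format(float(v), ".17g"))
    n = len(labels)
    pairs = sorted(
        (*_ordered_pair(labels[i], labels[j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    with _atomic_open(interaction) as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, i, j in pairs:
            fh.write(f"{a}\t{b}\t{fmt(state.weights[i, j])}\n")
    with _atomic_open(relation) as fh:
        fh.write("gene_a\tgene_b\trelation\n")
        for a, b, i, j in pairs:
            if state.adjacency[i, j]:
                fh.write(f"{a}\t{b}\t1\n")
            elif emit_zeros:
                fh.write(f"{a}\t{b}\t0\n")
    return interaction, relation


def read_interactions(path: str | Path) -> dict[tuple[str, str], float]:
    """Read an interaction file into a pair-to-weight mapping."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse interaction file {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"interaction file {path} needs three columns")
    out: dict[tuple[str, str], float] = {}
    for a, b, w in df.itertuples(index=False):
        out[_ordered_pair(str(a), str(b))] = float(w)
    return out


def read_relations(path: str | Path) -> set[tuple[str, str]]:
    """Read a relation file into the set of retained (1-labelled) pairs."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse relation file {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"relation file {path} needs three columns")
    out: set[tuple[str, str]] = set()
    for a, b, rel in df.itertuples(index=False):
        if int(rel) == 1:
            out.add(_ordered_pair(str(a), str(b)))
    return out


def read_gold(path: str | Path, universe: Iterable[str] | None = None):
    """Read a DREAM-format gold standard (gene, gene, 0/1; no header).

    Directed and duplicate rows collapse to unordered pairs; 1-rows are
    positives and 0-rows only widen the known gene universe.  ``universe``
    optionally supplies the full gene label list (e.g. from the expression
    matrix) when the gold file does not mention every gene.
    """
    from .evaluation import GoldStandard

    positives: set[tuple[str, str]] = set()
    genes: set[str] = set(str(g) for g in universe) if universe is not None else set()
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse gold standard {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"gold standard {path} needs three columns")
    for a, b, label in df.iloc[:, :3].itertuples(index=False):
        a, b = str(a), str(b)
        if label not in ("0", "1"):
            raise FormatError(f"gold standard label must be 0 or 1, got {label!r} in {path}")
        genes.update((a, b))
        if a == b:
            continue
        if label == "1":
            positives.add(_ordered_pair(a, b))
    return GoldStandard(positive_pairs=frozenset(positives), genes=tuple(sorted(genes)))


def write_gold(positive_pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write unordered positive pairs as DREAM-format 1-rows (atomic)."""
    rows = sorted(_ordered_pair(a, b) for a, b in positive_pairs)
    with _atomic_open(path) as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\t1\n")
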