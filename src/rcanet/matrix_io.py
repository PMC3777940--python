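"""Input/output for expression, binding and result matrices.

All files are plain UTF-8 tab-separated text with '.' decimal marks and no
quoting.  Matrices are stored genes-in-rows: the expression matrix is
N genes x M samples, the connectivity and coefficient matrices are
N genes x L regulators.  Identifier matching is exact, case-sensitive
string equality — symbol aliasing belongs upstream of this tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    IdentifierCollisionError,
    ParseError,
    ShapeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "BindingTable",
    "ConnectivityMatrix",
    "read_expression",
    "read_binding",
    "build_connectivity",
    "write_outputs",
    "write_matrix",
    "read_matrix",
]

#: significant digits used when printing float matrices
FLOAT_DIGITS = 12


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise IdentifierCollisionError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Gene expression values, N genes (rows) x M samples (columns)."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError("expression matrix must be at least 1 x 1")
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ShapeError(
                f"expression matrix {n}x{m} does not match "
                f"{len(self.gene_ids)} gene IDs / {len(self.sample_ids)} sample IDs"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class BindingTable:
    """Deduplicated set of (regulator_id, gene_id) binding pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        for reg, gene in self.pairs:
            if not reg or not gene:
                raise ValidationError(
                    f"binding pair with empty identifier: ({reg!r}, {gene!r})"
                )

    @property
    def regulator_ids(self) -> list[str]:
        """Regulators in sorted order (set membership has no input order)."""
        return sorted({r for r, _ in self.pairs})

    def targets_of(self, regulator_id: str) -> set[str]:
        return {g for r, g in self.pairs if r == regulator_id}


@dataclass
class ConnectivityMatrix:
    """Binary binding indicator matrix C, N genes x L regulators."""

    values: np.ndarray
    gene_ids: list[str]
    regulator_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.regulator_ids = list(self.regulator_ids)
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("connectivity entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        n, l = self.values.shape
        if len(self.gene_ids) != n or len(self.regulator_ids) != l:
            raise ShapeError(
                f"connectivity {n}x{l} does not match "
                f"{len(self.gene_ids)} genes / {len(self.regulator_ids)} regulators"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.regulator_ids, "regulator")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.values.shape[1]

    def target_counts(self) -> dict[str, int]:
        """Retained target count per regulator (column sums)."""
        sums = self.values.sum(axis=0)
        return {r: int(s) for r, s in zip(self.regulator_ids, sums)}


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First row: sample IDs (the first header cell is ignored).  First
    column: gene IDs.  Every data cell must parse as a finite float;
    a non-numeric cell raises :class:`ParseError` naming its coordinates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise FormatError(f"{path}: expression table has no data cells")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dup = next(g for i, g in enumerate(gene_ids) if g in gene_ids[:i])
        raise IdentifierCollisionError(f"{path}: duplicate gene ID {dup!r}")
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for i, s in enumerate(sample_ids) if s in sample_ids[:i])
        raise IdentifierCollisionError(f"{path}: duplicate sample ID {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ParseError(
                f"{path}: cannot parse cell at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}: {df.iloc[i, j]!r}"
            )
        values[:, j] = parsed.to_numpy()
    if not np.isfinite(values).all():
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ParseError(
            f"{path}: non-finite value at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)


def read_binding(path, format: str = "pairs") -> BindingTable:
    """Read regulator-target binding evidence.

    ``format='pairs'``: two tab-separated columns, regulator then gene,
    one pair per line.  ``format='sets'``: GMT-like — regulator ID, then
    its target gene IDs, tab-separated on one line (a second
    description-style column is tolerated only insofar as every non-first
    field is taken as a gene ID).  Duplicate pairs are dropped with a log
    message; empty lines are skipped with a warning.
    """
    if format not in ("pairs", "sets"):
        raise ValidationError(f"unknown binding format {format!r}")
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                logger.warning("%s: skipping empty line %d", path, lineno)
                continue
            fields = [f.strip() for f in line.split("\t")]
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno} has fewer than 2 fields"
                )
            if format == "pairs":
                new = [(fields[0], fields[1])]
            else:
                new = [(fields[0], g) for g in fields[1:]]
            for p in new:
                if p in pairs:
                    n_dup += 1
                else:
                    pairs.add(p)
    if n_dup:
        logger.info("%s: dropped %d duplicate binding pairs", path, n_dup)
    return BindingTable(pairs=pairs)


def build_connectivity(
    binding: BindingTable,
    expr: ExpressionMatrix,
    regulator_ids: Sequence[str],
    drop_empty: bool = False,
) -> ConnectivityMatrix:
    """Intersect binding pairs with the expression matrix's genes.

    Entry (i, l) is 1 iff regulator l binds gene i and gene i is present
    in ``expr``.  Binding pairs whose gene is absent from the expression
    matrix are dropped (count logged).  A regulator left with zero targets
    is a hard error unless ``drop_empty`` — its activity profile would be
    undefined.
    """
    regulator_ids = list(regulator_ids)
    if not regulator_ids:
        raise ValidationError("regulator_ids must be non-empty")
    _check_unique(regulator_ids, "regulator")
    if not binding.pairs:
        raise ValidationError("binding table is empty")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    values = np.zeros((expr.n_genes, len(regulator_ids)), dtype=np.int8)
    reg_index = {r: l for l, r in enumerate(regulator_ids)}
    n_dropped = 0
    for reg, gene in binding.pairs:
        l = reg_index.get(reg)
        if l is None:
            continue
        i = gene_index.get(gene)
        if i is None:
            n_dropped += 1
            continue
        values[i, l] = 1
    if n_dropped:
        logger.info(
            "dropped %d binding pairs whose gene is absent from the "
            "expression matrix", n_dropped,
        )
    counts = values.sum(axis=0)
    empty = [r for r, c in zip(regulator_ids, counts) if c == 0]
    if empty:
        if drop_empty:
            logger.warning(
                "dropping regulators with no targets in the expression "
                "matrix: %s", ", ".join(empty),
            )
            keep = [l for l, c in enumerate(counts) if c > 0]
            if not keep:
                raise ValidationError(
                    "no regulator has any target in the expression matrix"
                )
            values = values[:, keep]
            regulator_ids = [regulator_ids[l] for l in keep]
        else:
            raise ValidationError(
                "regulator(s) with no targets in the expression matrix: "
                + ", ".join(empty)
            )
    conn = ConnectivityMatrix(
        values=values, gene_ids=list(expr.gene_ids), regulator_ids=regulator_ids
    )
    logger.info("retained targets per regulator: %s", conn.target_counts())
    return conn


def _float_fmt(x: float) -> str:
    return f"{x:.{FLOAT_DIGITS}g}"


def write_matrix(values: np.ndarray, row_ids, col_ids, path, corner: str = "id") -> None:
    """Write a labelled matrix as TSV (12 significant digits)."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.index.name = corner
    df.to_csv(path, sep="\t", float_format=f"%.{FLOAT_DIGITS}g")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read back a TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_outputs(Y, pvals, modules, out_dir) -> dict[str, Path]:
    """Write the fit/significance results of a run to ``out_dir``.

    Produces fixed filenames: ``Y.tsv`` (genes x regulators coefficients),
    ``pvalues.tsv`` (empirical P-values, same shape), ``modules.tsv``
    (long format: regulator, gene, score, p, direction), and
    ``network.sif`` (Cytoscape-style edge list
    ``regulator<TAB>regulates<TAB>gene``).  ``Y``, ``pvals`` or
    ``modules`` may each be None to skip that file.

    Returns a dict of the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}
    if Y is not None:
        p = out_dir / "Y.tsv"
        write_matrix(Y.values, Y.gene_ids, Y.regulator_ids, p)
        written["Y"] = p
    if pvals is not None:
        p = out_dir / "pvalues.tsv"
        write_matrix(pvals.values, pvals.gene_ids, pvals.regulator_ids, p)
        written["pvalues"] = p
    if modules is not None:
        rows = []
        for mod in modules:
            for gene_id, score, pv, direction in mod.members:
                rows.append((mod.regulator_id, gene_id, score, pv, direction))
        mod_df = pd.DataFrame(
            rows, columns=["regulator", "gene", "score", "p", "direction"]
        )
        p = out_dir / "modules.tsv"
        mod_df.to_csv(p, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g")
        written["modules"] = p
        p = out_dir / "network.sif"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("regulator\tinteraction\tgene\n")
            for mod in modules:
                for gene_id, _, _, _ in mod.members:
                    fh.write(f"{mod.regulator_id}\tregulates\t{gene_id}\n")
        written["network"] = p
    return written
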