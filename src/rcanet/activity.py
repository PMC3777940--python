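"""Regulator activity profiles.

A regulator's activity across samples is summarised by the median
expression of its bound genes: ``Z[l, m] = median{ X[i, m] : C[i, l] = 1 }``.
The median makes the profile robust to the minority of bound genes that a
regulator does not actually control in the profiled condition.  Z is
computed once from the full inputs and held fixed while the coefficient
matrix is learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ValidationError
from .matrix_io import ConnectivityMatrix, ExpressionMatrix

__all__ = ["ActivityMatrix", "build_activity"]


@dataclass
class ActivityMatrix:
    """Regulator activity profiles Z, L regulators x M samples."""

    values: np.ndarray
    regulator_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.regulator_ids = list(self.regulator_ids)
        self.sample_ids = list(self.sample_ids)
        l, m = self.values.shape
        if len(self.regulator_ids) != l or len(self.sample_ids) != m:
            raise ValidationError(
                f"activity matrix {l}x{m} does not match "
                f"{len(self.regulator_ids)} regulators / {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("activity matrix contains non-finite values")

    @property
    def n_regulators(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def build_activity(
    expr: ExpressionMatrix,
    conn: ConnectivityMatrix,
    standardize: bool = False,
) -> ActivityMatrix:
    """Median expression of each regulator's bound genes, per sample.

    ``expr`` and ``conn`` must carry the same genes in the same order.
    The median of an even-sized target set is the mean of the two middle
    order statistics.  With ``standardize`` each activity row is centred
    and scaled to unit standard deviation (off by default: coefficient
    magnitudes are then on the scale of the expression data).
    """
    if expr.gene_ids != conn.gene_ids:
        raise AlignmentError(
            "expression and connectivity matrices carry different gene IDs "
            "or orders"
        )
    L = conn.n_regulators
    Z = np.empty((L, expr.n_samples), dtype=float)
    for l in range(L):
        rows = np.flatnonzero(conn.values[:, l] == 1)
        if rows.size == 0:
            raise ValidationError(
                f"regulator {conn.regulator_ids[l]!r} has no targets; "
                "activity is undefined"
            )
        Z[l, :] = np.median(expr.values[rows, :], axis=0)
    if standardize:
        mu = Z.mean(axis=1, keepdims=True)
        sd = Z.std(axis=1, keepdims=True)
        if (sd == 0).any():
            flat = [conn.regulator_ids[l] for l in np.flatnonzero(sd.ravel() == 0)]
            raise ValidationError(
                f"cannot standardize constant activity profile(s): {flat}"
            )
        Z = (Z - mu) / sd
    return ActivityMatrix(
        values=Z,
        regulator_ids=list(conn.regulator_ids),
        sample_ids=list(expr.sample_ids),
    )
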