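"""Sparse coefficient-matrix learning.

Given expression X (N x M) and fixed regulator activities Z (L x M), find
the coefficient matrix Y (N x L) minimising the squared Frobenius
residual ``||X - Y Z||_F^2`` subject to every column of Y holding a fixed
L1/L2 sparseness.  The solver is projected gradient descent: take a
gradient step on the unconstrained objective, then re-project each Y
column to the target sparseness with its L2 norm unchanged.  A
backtracking acceptance rule (halve the step until the projected
candidate does not increase the objective) makes the trace provably
non-increasing; a ``fixed_step`` mode runs the plain fixed-step loop
instead.

Non-zero entries of the fitted Y quantify inferred regulator-gene
interactions; C enters only through Z, so Y may place weight on genes
without prior binding evidence — that is how novel targets are predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .activity import ActivityMatrix, build_activity
from .errors import ShapeError, ValidationError
from .matrix_io import ConnectivityMatrix, ExpressionMatrix
from .sparseness import SparsenessTarget, project_sparse

__all__ = [
    "DecompositionConfig",
    "CoefficientMatrix",
    "FitResult",
    "objective",
    "init_Y",
    "update_step",
    "fit",
]

#: smallest step size tried before the update is declared stagnant
STEP_FLOOR = 1e-12


@dataclass(frozen=True)
class DecompositionConfig:
    """Parameters of the sparse decomposition.

    Parameters
    ----------
    sparseness : float
        Target sparseness of every Y column, in [0, 1].
    nonneg : bool
        Constrain Y to be non-negative (default).  In signed mode the
        projection acts on magnitudes and restores signs.
    step_size : float
        Initial gradient step; adapted by backtracking unless
        ``fixed_step``.
    tol : float
        Convergence threshold on the relative change of the objective.
    max_iters : int
        Iteration cap.
    seed : int
        Seed for the random initialisation of Y.
    init_scale : float
        Upper bound of the uniform initial entries of Y.
    project : bool
        Apply the sparseness projection.  Disabling it reduces the solver
        to plain gradient descent on the least-squares objective (used
        for sanity checks against the closed form).
    fixed_step : bool
        Run the literal fixed-step update without backtracking.
    restarts : int
        Number of random initialisations tried; the run with the lowest
        final objective is kept.  The constrained problem is non-convex
        and a single start occasionally sticks in a poorer optimum;
        restart seeds derive deterministically from ``seed``.
    mask_to_connectivity : bool
        Ablation mode: zero Y entries where C is 0 after every update.
    standardize_activity : bool
        Standardise each activity row before fitting.
    """

    sparseness: float = 0.7
    nonneg: bool = True
    step_size: float = 0.1
    tol: float = 1e-6
    max_iters: int = 2000
    seed: int = 0
    init_scale: float = 1.0
    project: bool = True
    fixed_step: bool = False
    restarts: int = 3
    mask_to_connectivity: bool = False
    standardize_activity: bool = False

    def __post_init__(self):
        if not (0.0 <= self.sparseness <= 1.0):
            raise ValidationError(
                f"sparseness must be in [0, 1], got {self.sparseness}"
            )
        if self.step_size <= 0:
            raise ValidationError(f"step_size must be positive, got {self.step_size}")
        if self.tol <= 0:
            raise ValidationError(f"tol must be positive, got {self.tol}")
        if self.max_iters < 1:
            raise ValidationError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.init_scale <= 0:
            raise ValidationError(
                f"init_scale must be positive, got {self.init_scale}"
            )
        if self.restarts < 1:
            raise ValidationError(f"restarts must be >= 1, got {self.restarts}")

    @property
    def target(self) -> SparsenessTarget:
        return SparsenessTarget(s=self.sparseness, nonneg=self.nonneg)


@dataclass
class CoefficientMatrix:
    """Fitted regulatory components Y, N genes x L regulators."""

    values: np.ndarray
    gene_ids: list[str]
    regulator_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.regulator_ids = list(self.regulator_ids)
        n, l = self.values.shape
        if len(self.gene_ids) != n or len(self.regulator_ids) != l:
            raise ShapeError(
                f"coefficient matrix {n}x{l} does not match "
                f"{len(self.gene_ids)} genes / {len(self.regulator_ids)} regulators"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("coefficient matrix contains non-finite values")


@dataclass
class FitResult:
    """Everything a decomposition run produces."""

    Y: CoefficientMatrix
    Z: ActivityMatrix
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def objective(X, Y, Z) -> float:
    """Squared Frobenius residual ``sum((X - Y Z)**2)``.

    Accepts the labelled matrix types or bare arrays.
    """
    Xv = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    Yv = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    Zv = Z.values if hasattr(Z, "values") else np.asarray(Z, dtype=float)
    if Yv.shape[1] != Zv.shape[0] or Xv.shape != (Yv.shape[0], Zv.shape[1]):
        raise ShapeError(
            f"non-conformable shapes X{Xv.shape}, Y{Yv.shape}, Z{Zv.shape}"
        )
    R = Xv - Yv @ Zv
    return float(np.sum(R * R))


def _project_columns(Yv: np.ndarray, config: DecompositionConfig) -> np.ndarray:
    """Column-wise sparseness projection honouring the config's modes."""
    n = Yv.shape[0]
    if not config.project:
        return Yv
    if n < 2:
        # a length-1 column cannot carry a sparseness constraint;
        # handle it as a magnitude
        return np.abs(Yv) if config.nonneg else Yv
    out = np.empty_like(Yv)
    target = config.target
    for l in range(Yv.shape[1]):
        col = Yv[:, l]
        if not np.any(col):
            # the projection is undefined at zero; nudge the first entry
            col = col.copy()
            col[0] = 1e-12
        out[:, l] = project_sparse(col, target)
    return out


def init_Y(
    n: int, l: int, config: DecompositionConfig, gene_ids=None, regulator_ids=None
) -> CoefficientMatrix:
    """Random initial Y: i.i.d. uniform on (0, init_scale], then projected
    column-wise to the configured sparseness.  Reproducible from the seed."""
    if n < 1 or l < 1:
        raise ValidationError(f"Y dimensions must be >= 1, got {n}x{l}")
    rng = np.random.default_rng(config.seed)
    # uniform on (0, scale]: avoid exact zeros so every column projects
    values = (1.0 - rng.random((n, l))) * config.init_scale
    values = _project_columns(values, config)
    return CoefficientMatrix(
        values=values,
        gene_ids=list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n)],
        regulator_ids=(
            list(regulator_ids) if regulator_ids is not None else [f"r{j}" for j in range(l)]
        ),
    )


def update_step(
    Y: CoefficientMatrix,
    X: ExpressionMatrix,
    Z: ActivityMatrix,
    config: DecompositionConfig,
    step_size: float | None = None,
    conn: ConnectivityMatrix | None = None,
) -> tuple[CoefficientMatrix, float, bool]:
    """One projected-gradient update of Y.

    The gradient of the squared residual is ``2 (Y Z - X) Z^T``; the
    constant 2 is absorbed into the step size.  Unless ``fixed_step``,
    the step is halved until the projected candidate does not increase
    the objective (down to a floor, at which point the update is declared
    stagnant and Y returned unchanged).

    Returns ``(Y_new, step_used, improved)``.
    """
    step = config.step_size if step_size is None else step_size
    Xv, Yv, Zv = X.values, Y.values, Z.values
    G = (Yv @ Zv - Xv) @ Zv.T
    f0 = objective(Xv, Yv, Zv)

    def candidate(eta: float) -> np.ndarray:
        W = Yv - eta * G
        W = _project_columns(W, config)
        if config.mask_to_connectivity and conn is not None:
            W = np.where(conn.values == 1, W, 0.0)
        return W

    if config.fixed_step:
        W = candidate(step)
        return (
            CoefficientMatrix(W, Y.gene_ids, Y.regulator_ids),
            step,
            objective(Xv, W, Zv) < f0,
        )

    while step >= STEP_FLOOR:
        W = candidate(step)
        if objective(Xv, W, Zv) <= f0:
            return CoefficientMatrix(W, Y.gene_ids, Y.regulator_ids), step, True
        step *= 0.5
    # stagnation: no step at any size improves the projected objective
    return Y, step, False


def _fit_single(
    X: ExpressionMatrix,
    C: ConnectivityMatrix,
    Z: ActivityMatrix,
    config: DecompositionConfig,
) -> FitResult:
    """One decomposition run from one random initialisation."""
    Y = init_Y(
        X.n_genes, C.n_regulators, config,
        gene_ids=X.gene_ids, regulator_ids=C.regulator_ids,
    )
    if config.mask_to_connectivity:
        masked = np.where(C.values == 1, Y.values, 0.0)
        masked = _project_columns(masked, config)
        Y = CoefficientMatrix(masked, Y.gene_ids, Y.regulator_ids)
    trace = [objective(X, Y, Z)]
    converged = False
    step = config.step_size
    iters = 0
    for iters in range(1, config.max_iters + 1):
        Y, step_used, improved = update_step(Y, X, Z, config, step_size=step, conn=C)
        f = objective(X, Y, Z)
        trace.append(f)
        if not config.fixed_step:
            if not improved:
                converged = True  # stagnant at the step floor
                break
            # reuse the accepted step, probing a larger one next round
            step = min(step_used * 2.0, config.step_size * 1024)
        prev = trace[-2]
        if abs(prev - f) < config.tol * max(1.0, prev):
            converged = True
            break
    return FitResult(Y=Y, Z=Z, objective_trace=trace, converged=converged, iterations=iters)


def fit(
    X: ExpressionMatrix,
    C: ConnectivityMatrix,
    config: DecompositionConfig,
) -> FitResult:
    """Run the full decomposition: build Z, initialise Y, iterate updates.

    A run stops when the relative objective change drops below
    ``config.tol`` (``converged=True``), when the step size stagnates at
    its floor (also reported converged), or at ``max_iters``.  With
    ``config.restarts > 1`` that is repeated from several random
    initialisations (seeds derived deterministically from
    ``config.seed``) and the run with the lowest final objective is
    returned — the sparseness constraint set is non-convex, so single
    starts occasionally stick in poorer optima.
    """
    Z = build_activity(X, C, standardize=config.standardize_activity)
    if config.restarts == 1:
        return _fit_single(X, C, Z, config)
    seeds = [config.seed] + [
        int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(config.restarts - 1)
    ]
    best: FitResult | None = None
    for s in seeds:
        res = _fit_single(X, C, Z, replace(config, seed=s))
        if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
            best = res
    return best
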