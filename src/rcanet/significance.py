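"""Permutation null, empirical P-values, module calling, overlap tests.

Whether a fitted coefficient is large "by chance" is judged against a
randomized-binding null: each regulator's target set is replaced by a
uniformly drawn gene set of the same size, the activity matrix is rebuilt
and Y refit with identical settings, and this is repeated B times.  Null
values are pooled per regulator column (across genes and runs, B*N draws
per regulator) and an observed score's empirical P-value is its add-one
right-tail probability in that pool, so P is never zero and is bounded
below by 1/(B*N+1).  A per-gene pooling mode (gene i against its own B
null values) is available for sensitivity analysis.

The default test statistic is the *contribution score*
``|Y[i, l]| * ||z_l||_2`` — the size of regulator l's modelled effect on
gene i — rather than the raw coefficient.  The two differ materially:
the coefficient scale is inversely coupled to the activity scale, and
null activity profiles (medians of random gene sets) are systematically
flatter than real ones, which inflates null coefficients and would mask
every true target.  The contribution score is invariant to that
Y <-> Z scale ambiguity; raw-coefficient comparison remains available.

Modules are then the genes that clear both a P-value cutoff and a
coefficient floor, optionally truncated to the top-k coefficients.
Overlap between two regulators' target sets is scored with the
hypergeometric upper tail plus the observed/expected ratio R.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .activity import build_activity
from .decomposition import CoefficientMatrix, DecompositionConfig, fit
from .errors import ShapeError, ValidationError
from .matrix_io import ConnectivityMatrix, ExpressionMatrix

__all__ = [
    "NullDistribution",
    "PValueMatrix",
    "RegulatoryModule",
    "permutation_null",
    "empirical_pvalues",
    "bh_adjust",
    "extract_modules",
    "overlap_significance",
    "intersect_regulator_targets",
]


@dataclass
class NullDistribution:
    """Pooled null scores per regulator from B randomized-binding runs."""

    per_regulator_null: dict[str, np.ndarray]
    B: int
    seeds: list[int]
    #: statistic the pools hold: "contribution" (|y| * ||z||) or "coefficient"
    score: str = "coefficient"
    #: per-gene null values, shape (B, N, L); kept only when requested
    per_gene: np.ndarray | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self):
        if self.B < 1:
            raise ValidationError(f"B must be >= 1, got {self.B}")
        for reg, pool in self.per_regulator_null.items():
            if len(pool) == 0:
                raise ValidationError(f"empty null pool for regulator {reg!r}")


@dataclass
class PValueMatrix:
    """Empirical P-values, N genes x L regulators, each in (0, 1]."""

    values: np.ndarray
    gene_ids: list[str]
    regulator_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, l = self.values.shape
        if len(self.gene_ids) != n or len(self.regulator_ids) != l:
            raise ShapeError("P-value matrix labels do not match its shape")
        if not ((self.values > 0) & (self.values <= 1)).all():
            raise ValidationError("P-values must lie in (0, 1]")


@dataclass
class RegulatoryModule:
    """A regulator with its called target genes.

    ``members`` is a list of ``(gene_id, score, p, direction)`` tuples
    sorted by descending |score|; ``direction`` is 'over', 'under' or
    'unspecified'.
    """

    regulator_id: str
    members: list[tuple[str, float, float, str]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _, _ in self.members]

    def gene_set(self) -> set[str]:
        return set(self.gene_ids)


def _random_connectivity(
    C: ConnectivityMatrix, rng: np.random.Generator
) -> ConnectivityMatrix:
    """Redraw every regulator's target set uniformly, preserving its size."""
    n = C.n_genes
    values = np.zeros_like(C.values)
    sizes = C.values.sum(axis=0)
    for l, k in enumerate(sizes):
        picks = rng.choice(n, size=int(k), replace=False)
        values[picks, l] = 1
    return ConnectivityMatrix(
        values=values, gene_ids=list(C.gene_ids), regulator_ids=list(C.regulator_ids)
    )


def contribution_scores(Y: CoefficientMatrix, Z) -> np.ndarray:
    """``|Y[i, l]| * ||z_l||_2``: the modelled effect size of regulator l
    on gene i, invariant to the Y <-> Z scale ambiguity."""
    Zv = Z.values if hasattr(Z, "values") else np.asarray(Z, dtype=float)
    if Zv.shape[0] != Y.values.shape[1]:
        raise ShapeError(
            f"Y has {Y.values.shape[1]} regulators but Z has {Zv.shape[0]} rows"
        )
    return np.abs(Y.values) * np.linalg.norm(Zv, axis=1)[None, :]


def permutation_null(
    X: ExpressionMatrix,
    C: ConnectivityMatrix,
    config: DecompositionConfig,
    B: int = 1000,
    seed: int = 0,
    score: str = "contribution",
    keep_per_gene: bool = False,
) -> NullDistribution:
    """Build the randomized-binding null by refitting Y B times.

    Every run draws, for each regulator jointly, a random target set of
    the same size as its true one (without replacement from all genes in
    X), rebuilds Z, and refits Y with the supplied config (the fit seed
    is derived from ``seed`` per run).  With ``score='contribution'``
    (default) each run's coefficients are scaled by that run's activity
    row norms before pooling, so the pooled values are comparable with
    the observed fit regardless of how flat the null activities are.
    Fully reproducible from ``seed``.
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    if score not in ("contribution", "coefficient"):
        raise ValidationError(f"unknown score mode {score!r}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(B)
    L = C.n_regulators
    pools: list[list[np.ndarray]] = [[] for _ in range(L)]
    per_gene = (
        np.empty((B, X.n_genes, L), dtype=float) if keep_per_gene else None
    )
    run_seeds: list[int] = []
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        fit_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        run_seeds.append(fit_seed)
        C_b = _random_connectivity(C, rng)
        res = fit(X, C_b, replace(config, seed=fit_seed))
        if score == "contribution":
            vals = contribution_scores(res.Y, res.Z)
        else:
            vals = res.Y.values
        for l in range(L):
            pools[l].append(vals[:, l])
        if per_gene is not None:
            per_gene[b] = vals
    per_regulator = {
        reg: np.concatenate(pools[l]) for l, reg in enumerate(C.regulator_ids)
    }
    return NullDistribution(
        per_regulator_null=per_regulator,
        B=B,
        seeds=run_seeds,
        score=score,
        per_gene=per_gene,
        gene_ids=list(X.gene_ids) if keep_per_gene else None,
    )


def empirical_pvalues(
    Y: CoefficientMatrix,
    null: NullDistribution,
    Z=None,
    pool: str = "column",
    ties: str = "random",
    seed: int = 0,
) -> PValueMatrix:
    """Add-one right-tail empirical P-values of the observed coefficients.

    ``p(i, l) = (1 + #{v in null_l : v > s[i, l]} + t) / (1 + |null_l|)``
    where ``s`` is the observed statistic — the contribution score
    ``|Y| * ||z_l||`` when the null was built in its default mode (pass
    the observed fit's activity matrix as ``Z``), or the raw coefficient
    otherwise — and ``t`` handles null values exactly equal to it.
    The sparse fit leaves many coefficients exactly zero, so ties carry
    real mass: with ``ties='random'`` (default) each tied count is
    weighted by an independent uniform draw (seeded; deterministic for a
    given ``seed``), which makes the P-values exactly uniform under the
    null; ``ties='conservative'`` counts every tie (the plain >=
    estimator), which is valid but piles the zero coefficients onto
    p = 1.  Either way P is never zero and never exceeds 1.

    With ``pool='column'`` the null for regulator l is its pooled B*N
    draws; with ``pool='per-gene'`` gene i is compared only against its
    own B null values (requires the null to have been built with
    ``keep_per_gene=True``).  Monotone in the conservative mode: a larger
    coefficient never gets a larger P.
    """
    if ties not in ("random", "conservative"):
        raise ValidationError(f"unknown tie mode {ties!r}")
    rng = np.random.default_rng(seed)
    n, l_count = Y.values.shape
    if null.score == "contribution":
        if Z is None:
            raise ValidationError(
                "this null pools contribution scores; pass the observed "
                "fit's activity matrix as Z"
            )
        observed = contribution_scores(Y, Z)
    else:
        observed = Y.values
    P = np.empty((n, l_count), dtype=float)
    if pool == "column":
        for l, reg in enumerate(Y.regulator_ids):
            if reg not in null.per_regulator_null:
                raise KeyError(f"regulator {reg!r} missing from the null")
            pool_vals = np.sort(null.per_regulator_null[reg])
            K = pool_vals.size
            lo = np.searchsorted(pool_vals, observed[:, l], side="left")
            hi = np.searchsorted(pool_vals, observed[:, l], side="right")
            gt = K - hi
            eq = hi - lo
            if ties == "random":
                t = rng.random(n) * eq
            else:
                t = eq.astype(float)
            P[:, l] = (1.0 + gt + t) / (1.0 + K)
    elif pool == "per-gene":
        if null.per_gene is None:
            raise ValidationError(
                "per-gene P-values require a null built with keep_per_gene=True"
            )
        if null.gene_ids != Y.gene_ids:
            raise ValidationError("gene IDs of Y and the per-gene null differ")
        gt = (null.per_gene > observed[None, :, :]).sum(axis=0)
        eq = (null.per_gene == observed[None, :, :]).sum(axis=0)
        if ties == "random":
            t = rng.random((n, l_count)) * eq
        else:
            t = eq.astype(float)
        P = (1.0 + gt + t) / (1.0 + null.B)
    else:
        raise ValidationError(f"unknown pooling mode {pool!r}")
    return PValueMatrix(
        values=P, gene_ids=list(Y.gene_ids), regulator_ids=list(Y.regulator_ids)
    )


def bh_adjust(pvals: PValueMatrix) -> PValueMatrix:
    """Benjamini-Hochberg adjusted P-values, computed per regulator column."""
    adj = np.empty_like(pvals.values)
    for l in range(pvals.values.shape[1]):
        adj[:, l] = multipletests(pvals.values[:, l], method="fdr_bh")[1]
    return PValueMatrix(
        values=adj, gene_ids=list(pvals.gene_ids), regulator_ids=list(pvals.regulator_ids)
    )


def extract_modules(
    Y: CoefficientMatrix,
    pvals: PValueMatrix,
    p_cutoff: float = 0.05,
    top_k: int | None = None,
    min_score: float = 0.0,
    directions: Mapping[str, str] | None = None,
) -> list[RegulatoryModule]:
    """Call each regulator's module: genes with low P and high coefficient.

    A gene joins regulator l's module when ``p(i, l) < p_cutoff`` and
    ``|Y[i, l]| > min_score``; the module is sorted by |coefficient|
    descending (gene ID ascending on ties) and truncated to ``top_k`` if
    given.  ``directions`` optionally maps gene IDs to 'over'/'under'
    labels carried through to the output.
    """
    if not (0.0 < p_cutoff <= 1.0):
        raise ValidationError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    if Y.gene_ids != pvals.gene_ids or Y.regulator_ids != pvals.regulator_ids:
        raise ValidationError("Y and P-value matrices are not aligned")
    modules = []
    for l, reg in enumerate(Y.regulator_ids):
        score = Y.values[:, l]
        keep = (pvals.values[:, l] < p_cutoff) & (np.abs(score) > min_score)
        idx = np.flatnonzero(keep)
        order = sorted(idx, key=lambda i: (-abs(score[i]), Y.gene_ids[i]))
        if top_k is not None:
            order = order[:top_k]
        members = [
            (
                Y.gene_ids[i],
                float(score[i]),
                float(pvals.values[i, l]),
                directions.get(Y.gene_ids[i], "unspecified") if directions else "unspecified",
            )
            for i in order
        ]
        modules.append(RegulatoryModule(regulator_id=reg, members=members))
    return modules


def overlap_significance(
    setA: Iterable[str], setB: Iterable[str], universe_size: int
) -> tuple[float, float]:
    """Hypergeometric overlap of two gene sets.

    Returns ``(p, ratio)`` where p is the upper-tail probability of
    observing at least the actual overlap when |B| genes are drawn
    without replacement from a universe containing |A| marked genes, and
    ratio R = observed / expected overlap
    = ``overlap * universe / (|A| * |B|)``.
    """
    A, B = set(setA), set(setB)
    if len(A | B) > universe_size:
        raise ValidationError(
            f"universe of {universe_size} smaller than the union of the two "
            f"sets ({len(A | B)})"
        )
    k = len(A & B)
    if not A or not B:
        return 1.0, float("nan")
    p = float(hypergeom.sf(k - 1, universe_size, len(A), len(B)))
    ratio = k * universe_size / (len(A) * len(B))
    return p, float(ratio)


def intersect_regulator_targets(
    modules: Sequence[RegulatoryModule],
    regulator_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Co-target table: which regulators (and groups) call each gene.

    Returns a DataFrame indexed by gene with one boolean column per
    regulator, one per group (a group calls a gene if ANY of its members
    does — e.g. "NF-kB" as the union of its subunits), and an
    ``n_regulators`` count.  Only genes called by at least one module
    appear.
    """
    if not modules:
        raise ValidationError("no modules supplied")
    regs = [m.regulator_id for m in modules]
    by_reg = {m.regulator_id: m.gene_set() for m in modules}
    genes = sorted(set().union(*by_reg.values()))
    data = {r: [g in by_reg[r] for g in genes] for r in regs}
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"), dtype=bool)
    df["n_regulators"] = df[regs].sum(axis=1).astype(int)
    if regulator_groups:
        for name, members in regulator_groups.items():
            unknown = [r for r in members if r not in by_reg]
            if unknown:
                raise KeyError(
                    f"group {name!r} references unknown regulator(s): {unknown}"
                )
            df[name] = df[list(members)].any(axis=1)
    return df
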