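"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.linalg import null_space

import rcanet as rc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_expr() -> rc.ExpressionMatrix:
    """3 genes x 2 samples, hand-written values."""
    return rc.ExpressionMatrix(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture
def tiny_conn(tiny_expr) -> rc.ConnectivityMatrix:
    """r1 binds g1+g3, r2 binds g2."""
    return rc.ConnectivityMatrix(
        values=np.array([[1, 0], [0, 1], [1, 0]]),
        gene_ids=tiny_expr.gene_ids,
        regulator_ids=["r1", "r2"],
    )


# ---------------------------------------------------------------------------
# independent oracles


def grid_min_distance(v: np.ndarray, l1: float, l2: float,
                      n_grid: int = 720) -> tuple[float, float]:
    """Brute-force the constraint set {w >= 0, ||w||_1 = l1, ||w||_2 = l2}
    for n <= 4 by enumerating support patterns and gridding the
    sphere-hyperplane intersection on each.

    Returns ``(min_distance_to_v, grid_margin)`` where the margin bounds
    the discretisation error (the distance function is 1-Lipschitz in
    the grid point).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    assert n <= 4
    eps = 1e-9
    best = np.inf
    margin = 0.0
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            cands = []
            if k == 1:
                if abs(l1 - l2) <= 1e-7:
                    cands.append(np.array([l2]))
            elif k == 2:
                disc = 2 * l2 * l2 - l1 * l1
                if disc >= -eps:
                    r = np.sqrt(max(disc, 0.0))
                    a, b = (l1 + r) / 2.0, (l1 - r) / 2.0
                    if b >= -eps:
                        cands.append(np.array([a, b]))
                        cands.append(np.array([b, a]))
            else:
                rho_sq = l2 * l2 - l1 * l1 / k
                if rho_sq < -eps:
                    continue
                rho = np.sqrt(max(rho_sq, 0.0))
                center = np.full(k, l1 / k)
                basis = null_space(np.ones((1, k)))  # k x (k-1) orthonormal
                if k == 3:
                    theta = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
                    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
                    step = rho * 2 * np.pi / n_grid
                else:  # k == 4: grid the 2-sphere of directions
                    n_phi = max(8, n_grid // 8)
                    phi = np.linspace(0, np.pi, n_phi)
                    theta = np.linspace(0, 2 * np.pi, n_grid // 4, endpoint=False)
                    P, T = np.meshgrid(phi, theta, indexing="ij")
                    dirs = np.stack(
                        [np.sin(P) * np.cos(T), np.sin(P) * np.sin(T), np.cos(P)],
                        axis=-1,
                    ).reshape(-1, 3)
                    step = rho * (np.pi / n_phi + 2 * np.pi / (n_grid // 4))
                pts = center + dirs @ basis.T * rho
                ok = (pts >= -1e-7).all(axis=1)
                if ok.any():
                    cands.extend(np.clip(pts[ok], 0.0, None))
                    margin = max(margin, step)
            for c in cands:
                w = np.zeros(n)
                w[list(support)] = c
                best = min(best, float(np.linalg.norm(w - v)))
    return best, margin


def brute_force_overlap_tail(universe: int, size_a: int, size_b: int,
                             observed: int) -> float:
    """Exact P[overlap >= observed] by enumerating every draw of a
    size_b subset from the universe against a fixed size_a set."""
    marked = set(range(size_a))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(universe), size_b):
        total += 1
        if len(marked & set(draw)) >= observed:
            hits += 1
    return hits / total
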