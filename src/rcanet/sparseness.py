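"""L1/L2 sparseness measure and the fixed-norm sparseness projection.

The sparseness of a vector v of length n is defined from the ratio of its
L1 and L2 norms::

    sparseness(v) = (sqrt(n) - ||v||_1 / ||v||_2) / (sqrt(n) - 1)

It equals 1 exactly when v has a single non-zero element and 0 exactly
when all elements are equal (in absolute value it is computed on |v|, so
the measure is well defined for signed vectors too).  The projection
operator maps a vector to the closest point (Euclidean distance) whose L2
norm is unchanged and whose L1 norm is set so that the projected vector
attains a requested sparseness.  Both are the building blocks of the
sparse decomposition: every column of the coefficient matrix is held at a
fixed sparseness throughout the fit.

The projection is the alternating hyperplane-projection / sphere-scaling /
zero-clamping scheme of Hoyer-style non-negative sparse coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, UndefinedMeasureError, ValidationError

__all__ = [
    "SparsenessTarget",
    "hoyer_sparseness",
    "target_l1",
    "project_sparse",
]


@dataclass(frozen=True)
class SparsenessTarget:
    """Desired sparseness for a projected vector.

    Parameters
    ----------
    s : float
        Target sparseness in [0, 1]; 1 = single non-zero, 0 = constant.
    nonneg : bool
        If True the projected vector is constrained to be element-wise
        non-negative.  If False the projection acts on magnitudes and the
        original signs are restored afterwards.
    """

    s: float
    nonneg: bool = True

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ValidationError(
                f"sparseness target must be in [0, 1], got {self.s}"
            )


def hoyer_sparseness(v) -> float:
    """Sparseness of a vector, in [0, 1], from its L1/L2 norm ratio.

    Computed on absolute values; invariant under non-zero scaling.

    Raises
    ------
    ValidationError
        If the vector has fewer than 2 elements.
    UndefinedMeasureError
        If the vector is identically zero.
    """
    a = np.abs(np.asarray(v, dtype=float).ravel())
    n = a.size
    if n < 2:
        raise ValidationError(f"sparseness needs a vector of length >= 2, got {n}")
    l2 = float(np.sqrt(a @ a))
    if l2 == 0.0:
        raise UndefinedMeasureError("sparseness is undefined for the zero vector")
    l1 = float(a.sum())
    rn = np.sqrt(n)
    # clip float round-off: the exact value lies in [0, 1]
    return float(np.clip((rn - l1 / l2) / (rn - 1.0), 0.0, 1.0))


def target_l1(l2: float, n: int, s: float) -> float:
    """L1 norm that a length-n vector of given L2 norm must have to attain
    sparseness ``s``: ``L1 = L2 * (sqrt(n) - s * (sqrt(n) - 1))``."""
    if l2 <= 0:
        raise ValidationError(f"l2 must be positive, got {l2}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if not (0.0 <= s <= 1.0):
        raise ValidationError(f"s must be in [0, 1], got {s}")
    rn = np.sqrt(n)
    return float(l2 * (rn - s * (rn - 1.0)))


def _project_l1_l2_nonneg(
    x: np.ndarray, l1: float, l2: float, max_iter: int, tol: float
) -> np.ndarray:
    """Project non-negative ``x`` onto {w >= 0, ||w||_1 = l1, ||w||_2 = l2}.

    Alternates: move to the hyperplane sum(w) = l1, scale along the line
    through the hyperplane's uniform point to reach the sphere ||w|| = l2,
    clamp negatives to zero and redistribute.  Each clamped coordinate
    stays at zero, so the loop terminates in at most n passes.
    """
    n = x.size
    zero = np.zeros(n, dtype=bool)
    # start on the sum hyperplane
    s = x + (l1 - x.sum()) / n
    for _ in range(max_iter):
        n_free = n - int(zero.sum())
        if n_free == 1:
            s = np.zeros(n)
            s[~zero] = l2
            return s
        m = np.where(zero, 0.0, l1 / n_free)
        d = s - m
        a = float(d @ d)
        b = 2.0 * float(m @ d)
        c = float(m @ m) - l2 * l2
        if a <= (1e-12 * l2) ** 2:  # |d| is float noise relative to scale
            # s sits exactly on the uniform midpoint, so every point of the
            # sphere-hyperplane intersection is equidistant; pick the
            # direction that favours the lowest free index (deterministic
            # tie-break) and scale along it instead.
            first_free = int(np.flatnonzero(~zero)[0])
            d = np.where(zero, 0.0, -1.0 / n_free)
            d[first_free] += 1.0
            a = float(d @ d)
            b = 2.0 * float(m @ d)
            c = float(m @ m) - l2 * l2
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            disc = 0.0
        alpha = (-b + np.sqrt(disc)) / (2.0 * a)
        s = m + alpha * d
        neg = s < -tol
        if not neg.any():
            np.clip(s, 0.0, None, out=s)
            return s
        zero |= neg
        s[zero] = 0.0
        n_free = n - int(zero.sum())
        if n_free == 0:
            raise ConvergenceError("sparseness projection clamped all entries")
        s[~zero] += (l1 - s[~zero].sum()) / n_free
    raise ConvergenceError(
        f"sparseness projection did not converge in {max_iter} iterations",
        iterations=max_iter,
    )


def project_sparse(
    v,
    target: SparsenessTarget,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> np.ndarray:
    """Project ``v`` to the requested sparseness with unchanged L2 norm.

    The returned vector w satisfies ``||w||_2 == ||v||_2`` (to ``tol``
    relative) and ``hoyer_sparseness(w) == target.s`` (to 1e-6).  With
    ``target.nonneg`` the output is non-negative; otherwise magnitudes are
    projected and the signs of ``v`` restored.  Ties (several equidistant
    solutions, e.g. equal entries at s = 1) are broken toward the lowest
    index.

    Raises
    ------
    UndefinedMeasureError
        If ``v`` is identically zero.
    ConvergenceError
        If the inner clamping loop fails to terminate.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise ValidationError(f"projection needs a vector of length >= 2, got {n}")
    mag = np.abs(v)
    l2 = float(np.sqrt(mag @ mag))
    if l2 == 0.0:
        raise UndefinedMeasureError("cannot project the zero vector")
    signs = np.where(v < 0, -1.0, 1.0)

    if target.s >= 1.0 - 1e-12:
        # single support: keep the largest-magnitude entry (lowest index wins)
        w = np.zeros(n)
        w[int(np.argmax(mag))] = l2
    elif target.s <= 1e-12:
        # constant vector with the same L2 norm
        w = np.full(n, l2 / np.sqrt(n))
    else:
        l1 = target_l1(l2, n, target.s)
        w = _project_l1_l2_nonneg(mag, l1, l2, max_iter=max_iter, tol=tol)
        # renormalise away accumulated round-off on the sphere
        w *= l2 / np.sqrt(w @ w)
    if not target.nonneg:
        w = signs * w
    return w
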