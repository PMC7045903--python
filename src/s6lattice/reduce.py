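"""Selling reduction: drive all six Selling scalars nonpositive.

A lattice basis is Selling reduced when every pairwise dot product
among the four vectors a, b, c, d = -a-b-c is nonpositive.  Reduction
proceeds by the classical Selling exchange: while some scalar
s_i = p.q is positive, replace

    p -> -p,   r -> r + p,   t -> t + p,   q -> q

where r, t are the two vectors other than p and q.  The four-vector
sum stays zero, the lattice is unchanged (the induced basis change on
(a, b, c) is unimodular, det = +/-1), and the norm sum
|a|^2+|b|^2+|c|^2+|d|^2 strictly decreases by exactly 2 p.q, which
guarantees termination for any positive-definite lattice.

The accumulated basis change is reported both as a 3x3 integer matrix
on (a, b, c) and as its 6x6 lift on the Selling scalars, so the whole
reduction can be replayed in either space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import CellBasis
from .lift import lift_matrix3
from .s6 import InvalidS6Error, e3_to_s6, s6_to_basis

__all__ = ["ReductionResult", "selling_reduce", "reduce_basis"]

# scalar index -> (p, q) positions in the four-vector list [a, b, c, d];
# p is the vector that gets negated by the exchange.
_PAIRS = ((1, 2), (0, 2), (0, 1), (0, 3), (1, 3), (2, 3))


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of a Selling reduction."""

    s_reduced: np.ndarray  # the six nonpositive scalars
    m3_total: np.ndarray  # accumulated integer basis change, |det| = 1
    m6_total: np.ndarray  # lift(m3_total), exact integers
    steps: int

    @property
    def basis(self) -> CellBasis:
        """Canonical-frame basis of the reduced cell."""
        return s6_to_basis(self.s_reduced)


def _exchange_matrix3(i: int) -> np.ndarray:
    """Integer 3x3 induced on (a, b, c) by the exchange at scalar i.

    Built from the 4x4 exchange on (a, b, c, d) by eliminating
    d = -a-b-c.  Always unimodular (det = +/-1).
    """
    p, q = _PAIRS[i]
    others = [k for k in range(4) if k not in (p, q)]
    t4 = np.eye(4, dtype=np.int64)
    t4[p, p] = -1
    for r in others:
        t4[r, p] += 1
    # eliminate d: column j (j<3) of the 3x3 is t4[k, j] - t4[k, 3]
    return t4[:3, :3] - t4[:3, 3:4]


_EXCHANGES = tuple(_exchange_matrix3(i) for i in range(6))


def reduce_basis(basis: CellBasis, tol: float = 1e-9, max_steps: int = 1000) -> ReductionResult:
    """Selling-reduce an edge-vector basis.

    Parameters
    ----------
    basis
        Any nondegenerate cell basis.
    tol
        Relative tolerance: a scalar counts as positive only when it
        exceeds ``tol * max|s_i|``, so near-boundary zeros terminate.
    max_steps
        Safety bound; exceeded only for invalid input (each step
        strictly shrinks the norm sum, so valid lattices terminate).
    """
    b0 = np.asarray(basis.matrix, dtype=float)
    m3_total = np.eye(3, dtype=np.int64)
    steps = 0
    while True:
        current = m3_total @ b0
        rows4 = np.vstack([current, -current.sum(axis=0)])
        s = np.array([rows4[p] @ rows4[q] for p, q in _PAIRS])
        threshold = tol * max(1e-300, float(np.abs(s).max()))
        i = int(np.argmax(s))  # most positive scalar; ties -> lowest index
        if s[i] <= threshold:
            return ReductionResult(
                s_reduced=s,
                m3_total=m3_total,
                m6_total=lift_matrix3(m3_total),
                steps=steps,
            )
        if steps >= max_steps:
            raise RuntimeError(
                f"Selling reduction did not converge within {max_steps} steps; "
                "the input does not describe a positive-definite lattice or the "
                "tolerance is too tight"
            )
        m3_total = _EXCHANGES[i] @ m3_total
        steps += 1


def selling_reduce(s, tol: float = 1e-9, max_steps: int = 1000) -> ReductionResult:
    """Selling-reduce an S6 vector.

    The scalars must describe a valid lattice (positive-definite
    implied Gram matrix); :class:`~s6lattice.s6.InvalidS6Error` is
    raised otherwise.  On success ``is_reduced(result.s_reduced)``
    holds and ``result.m6_total @ s`` equals ``result.s_reduced`` to
    rounding error.
    """
    arr = np.asarray(s, dtype=float).ravel()
    if arr.shape != (6,):
        raise InvalidS6Error(f"expected 6 Selling scalars, got shape {arr.shape}")
    basis = s6_to_basis(arr)  # validates positive definiteness
    return reduce_basis(basis, tol=tol, max_steps=max_steps)
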