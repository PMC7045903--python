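"""Lift a 3x3 cell transformation to the equivalent 6x6 matrix on S6.

Any linear transformation M of cell bases induces a linear
transformation of the Selling scalars: converting to edge vectors,
applying M, and converting back to scalars is linear in the scalars.
The 6x6 matrix of that induced map is built column by column from six
degenerate "basis cells": cells whose Selling-scalar vector is the
*negative* of an S6 unit vector.  (The positive unit vectors cannot be
realized by real edge vectors -- a unit dot product between distinct
unit basis vectors forces d = -a-b-c to have nonzero products with
them -- so the negatives are used, and each column picks up a sign.)

For basis cell B_j with scalars -e_j,

    column_j( lift(M) ) = - E3toS6( M . B_j ),

and the defining property is the commutation relation

    E3toS6( M . B ) = lift(M) . E3toS6( B )   for every basis B.

The construction is polynomial (quadratic) in the entries of M, so an
integer or rational M yields an exactly integer or rational 6x6
matrix; the integer path here runs in exact arithmetic.  The lift is
multiplicative, lift(AB) = lift(A) lift(B), and
det lift(M) = (det M)^4.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .cells import CellBasis
from .s6 import e3_to_s6

__all__ = ["make_basis_cells", "lift_matrix3", "BASIS_CELL_ROWS"]

# The six degenerate cells, index-aligned with the S6 components
# [b.c, a.c, a.b, a.d, b.d, c.d].  Cells 4-6 put a single unit vector
# in row a, b or c (so only the matching d-product, -1, survives);
# cells 1-3 use an antiparallel unit pair in the two participating
# rows, which makes d vanish and leaves the single pair product -1.
BASIS_CELL_ROWS: tuple[tuple[tuple[int, int, int], ...], ...] = (
    ((0, 0, 0), (1, 0, 0), (-1, 0, 0)),  # -> [-1, 0, 0, 0, 0, 0]
    ((1, 0, 0), (0, 0, 0), (-1, 0, 0)),  # -> [0, -1, 0, 0, 0, 0]
    ((1, 0, 0), (-1, 0, 0), (0, 0, 0)),  # -> [0, 0, -1, 0, 0, 0]
    ((1, 0, 0), (0, 0, 0), (0, 0, 0)),  # -> [0, 0, 0, -1, 0, 0]
    ((0, 0, 0), (1, 0, 0), (0, 0, 0)),  # -> [0, 0, 0, 0, -1, 0]
    ((0, 0, 0), (0, 0, 0), (1, 0, 0)),  # -> [0, 0, 0, 0, 0, -1]
)


def make_basis_cells() -> list[CellBasis]:
    """The six degenerate basis cells, as (unchecked) CellBasis objects."""
    return [CellBasis.degenerate(rows) for rows in BASIS_CELL_ROWS]


def _exact_s6(rows: list[list]) -> list:
    """Selling scalars of three exact (int/Fraction) row vectors."""
    a, b, c = rows
    d = [-(a[k] + b[k] + c[k]) for k in range(3)]

    def dot(u, v):
        return u[0] * v[0] + u[1] * v[1] + u[2] * v[2]

    return [dot(b, c), dot(a, c), dot(a, b), dot(a, d), dot(b, d), dot(c, d)]


def _is_exact(m: np.ndarray) -> bool:
    if m.dtype == object:
        return all(isinstance(x, (int, Fraction, np.integer)) for x in m.ravel())
    return np.issubdtype(m.dtype, np.integer)


def lift_matrix3(m: np.ndarray | list) -> np.ndarray:
    """The 6x6 matrix on Selling scalars equivalent to a 3x3 matrix.

    Parameters
    ----------
    m
        Any 3x3 matrix acting on stacked row-vector bases by left
        multiplication.  Integer (or Fraction) entries trigger exact
        arithmetic and an exact integer/rational result (an object
        array); float entries give a float result.

    Returns
    -------
    6x6 array S with ``e3_to_s6(apply_matrix3(m, B)) == S @ e3_to_s6(B)``
    for every basis B.
    """
    marr = np.asarray(m)
    if marr.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {marr.shape}")
    if _is_exact(marr):
        mm = [[int(x) if isinstance(x, (int, np.integer)) else x for x in row] for row in marr.tolist()]
        cols = []
        for rows in BASIS_CELL_ROWS:
            transformed = [
                [sum(mm[i][k] * rows[k][j] for k in range(3)) for j in range(3)]
                for i in range(3)
            ]
            cols.append([-x for x in _exact_s6(transformed)])
        out = np.empty((6, 6), dtype=object)
        for j, col in enumerate(cols):
            for i in range(6):
                out[i, j] = col[i]
        return out
    mf = marr.astype(float)
    out = np.empty((6, 6), dtype=float)
    for j, rows in enumerate(BASIS_CELL_ROWS):
        transformed = mf @ np.asarray(rows, dtype=float)
        out[:, j] = -e3_to_s6(CellBasis.degenerate(transformed))
    return out


def _verify_basis_cells() -> None:
    """Each basis cell must map to exactly -e_j under E3toS6."""
    for j, rows in enumerate(BASIS_CELL_ROWS):
        s = _exact_s6([list(r) for r in rows])
        expect = [0] * 6
        expect[j] = -1
        if s != expect:
            raise AssertionError(f"basis cell {j + 1} maps to {s}, expected {expect}")


_verify_basis_cells()
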