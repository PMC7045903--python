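"""The S6 representation: Selling scalars of a lattice.

A lattice basis a, b, c together with the auxiliary vector
d = -a - b - c has six pairwise dot products, the Selling scalars,

    s = [b.c, a.c, a.b, a.d, b.d, c.d]    (angstrom^2),

which form a point in the six-dimensional space S6.  The scalars are
rotation invariant, so S6 represents the cell itself rather than any
particular orientation of it.  A cell is *Selling reduced* when all
six scalars are nonpositive; reduced cells are the natural domain for
the Delone classification and for the centering matrices in the
catalog module.

The squared edge norms are linear in the scalars:

    |a|^2 = -(s2+s3+s4),  |b|^2 = -(s1+s3+s5),
    |c|^2 = -(s1+s2+s6),  |d|^2 = -(s4+s5+s6),

and summing gives the sum rule
s1+...+s6 = -(|a|^2+|b|^2+|c|^2+|d|^2)/2.
"""

from __future__ import annotations

import math

import numpy as np

from .cells import CellBasis, InvalidBasisError

__all__ = ["InvalidS6Error", "e3_to_s6", "s6_to_basis", "is_reduced", "norms_squared", "s6_gram"]


class InvalidS6Error(ValueError):
    """Raised for S6 vectors that do not correspond to a real lattice."""


def e3_to_s6(basis: CellBasis) -> np.ndarray:
    """Selling scalars [b.c, a.c, a.b, a.d, b.d, c.d] of a basis.

    d = -a-b-c is recomputed internally.  Degenerate basis cells
    (zero rows) are allowed; the scalars are plain dot products.
    """
    a, b, c = basis.a_vec, basis.b_vec, basis.c_vec
    d = -a - b - c
    return np.array(
        [
            np.dot(b, c),
            np.dot(a, c),
            np.dot(a, b),
            np.dot(a, d),
            np.dot(b, d),
            np.dot(c, d),
        ]
    )


def norms_squared(s) -> tuple[float, float, float, float]:
    """Squared norms (|a|^2, |b|^2, |c|^2, |d|^2) implied by the scalars."""
    s1, s2, s3, s4, s5, s6 = (float(x) for x in np.asarray(s).ravel())
    return (
        -(s2 + s3 + s4),
        -(s1 + s3 + s5),
        -(s1 + s2 + s6),
        -(s4 + s5 + s6),
    )


def s6_gram(s) -> np.ndarray:
    """Gram matrix of (a, b, c) implied by an S6 vector."""
    s1, s2, s3 = (float(x) for x in np.asarray(s).ravel()[:3])
    aa, bb, cc, _ = norms_squared(s)
    return np.array([[aa, s3, s2], [s3, bb, s1], [s2, s1, cc]])


def is_reduced(s, tol: float = 1e-9) -> bool:
    """True iff all six Selling scalars are <= tol."""
    arr = np.asarray(s, dtype=float).ravel()
    if arr.shape != (6,):
        raise InvalidS6Error(f"expected 6 Selling scalars, got shape {arr.shape}")
    return bool(arr.max() <= tol)


def s6_to_basis(s) -> CellBasis:
    """Canonical-frame basis whose Selling scalars equal ``s``.

    Any rotation of the result has the same scalars; the canonical
    frame (a along +x, b in xy with b_y > 0, c_z > 0) fixes one
    deterministic representative:

        a = (|a|, 0, 0)
        b = (s3/|a|, +sqrt(|b|^2 - b_x^2), 0)
        c = (s2/|a|, (s1 - b_x c_x)/b_y, +sqrt(|c|^2 - c_x^2 - c_y^2))

    Validity is decided by positive definiteness of the implied Gram
    matrix (leading principal minors, with a small relative slack),
    not merely by scalar signs: zero scalars on the reduced-domain
    boundary are fine, but the scalars must come from a real lattice.

    Raises
    ------
    InvalidS6Error
        Naming the first violated quantity (a nonpositive derived
        squared norm, or a nonpositive principal minor of the Gram).
    """
    arr = np.asarray(s, dtype=float).ravel()
    if arr.shape != (6,):
        raise InvalidS6Error(f"expected 6 Selling scalars, got shape {arr.shape}")
    aa, bb, cc, dd = norms_squared(arr)
    for name, val in (("|a|^2", aa), ("|b|^2", bb), ("|c|^2", cc), ("|d|^2", dd)):
        if val <= 0:
            raise InvalidS6Error(f"derived squared norm {name} = {val:.6g} is not positive")
    g = s6_gram(arr)
    scale = max(aa, bb, cc)
    minors = (g[0, 0], np.linalg.det(g[:2, :2]), np.linalg.det(g))
    for k, minor in enumerate(minors, start=1):
        if minor <= -1e-12 * scale**k or minor <= 0:
            raise InvalidS6Error(
                f"Gram matrix is not positive definite: leading principal minor "
                f"{k} = {minor:.6g} is not positive"
            )
    s1, s2, s3 = arr[0], arr[1], arr[2]
    na = math.sqrt(aa)
    bx = s3 / na
    by = math.sqrt(bb - bx * bx)
    cx = s2 / na
    cy = (s1 - bx * cx) / by
    cz = math.sqrt(cc - cx * cx - cy * cy)
    return CellBasis([[na, 0.0, 0.0], [bx, by, 0.0], [cx, cy, cz]])


def parse_s6(text: str) -> np.ndarray:
    """Parse an S6 vector from six numbers (text) or a JSON array."""
    import json
    import re

    stripped = text.strip()
    if stripped.startswith("["):
        vals = json.loads(stripped)
    else:
        vals = [float(p) for p in re.split(r"[,\s]+", stripped) if p]
    arr = np.asarray(vals, dtype=float).ravel()
    if arr.shape != (6,):
        raise InvalidS6Error(f"expected 6 Selling scalars, got {arr.size}")
    return arr
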