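"""The 24 canonical Delone types and their centering transformations.

Delone's classification sorts every Bravais lattice into one of 24
canonical types according to the zero/equality pattern of its reduced
Selling scalars.  For each type there is a fixed transformation from
the Selling-reduced primitive cell to the conventional (possibly
centered) cell; the 3x3 matrices here follow the Burzlaff-Zimmermann
(1985) orientation and act on row-vector bases by left
multiplication.  The matching 6x6 matrices on Selling scalars are
*computed* from the 3x3 ones by the lift construction, never stored
independently, so the two representations cannot drift apart.

Type symbols use the modernized lettering: cubic C (was K),
tetragonal T (was Q), triclinic A (was T), plus R (rhombohedral),
O (orthorhombic), M (monoclinic) and H (hexagonal).  The magnitude of
the 3x3 determinant equals the centering multiplicity: 1 for
primitive, 2 for body (I) and base (S) centering, 3 for the
rhombohedral R centering, 4 for face (F) centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lift import lift_matrix3
from .s6 import InvalidS6Error, norms_squared, s6_gram

__all__ = ["DeloneEntry", "catalog", "get_entry", "center_cell", "SYMBOLS"]

# symbol -> (lattice character, 3x3 primitive->centered matrix or None for identity)
_RAW: tuple[tuple[str, str, list[list[int]] | None], ...] = (
    ("C1", "cI", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
    ("C3", "cF", [[1, 1, 0], [-1, 1, 0], [1, 1, 2]]),
    ("C5", "cP", None),
    ("R1", "hR", [[1, -1, 0], [0, 1, -1], [1, 1, 1]]),
    ("R3", "hR", [[1, 0, 0], [0, 0, 1], [1, 3, 2]]),
    ("T1", "tI", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
    ("T2", "tI", [[1, 0, 0], [0, 1, 0], [1, 1, 2]]),
    ("T5", "tP", None),
    ("O1A", "oF", [[1, 1, 0], [-1, 1, 0], [1, 1, 2]]),
    ("O1B", "oI", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
    ("O2", "oI", [[1, 0, 0], [0, 1, 0], [1, 1, 2]]),
    ("O3", "oI", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
    ("O4", "oS", [[1, -1, 0], [1, 1, 0], [0, 0, 1]]),
    ("O5", "oP", None),
    ("M1A", "mS", [[-1, -1, -1], [1, -1, 0], [0, 0, 1]]),
    ("M1B", "mS", [[0, 1, 1], [1, 1, 0], [-1, 0, -1]]),
    ("M2A", "mS", [[-1, -1, -2], [0, 1, 0], [1, 0, 0]]),
    ("M2B", "mS", [[0, 1, 1], [1, 1, 0], [-1, 0, -1]]),
    ("M3", "mS", [[-1, -1, -2], [0, 1, 0], [1, 0, 0]]),
    ("M4", "mP", None),
    ("A1", "aP", None),
    ("A2", "aP", None),
    ("A3", "aP", None),
    ("H4", "hP", None),
)

SYMBOLS: tuple[str, ...] = tuple(sym for sym, _, _ in _RAW)

# centering letter (2nd character of the lattice symbol) -> multiplicity
CENTERING_MULTIPLICITY = {"P": 1, "I": 2, "S": 2, "R": 3, "F": 4}


@dataclass(frozen=True)
class DeloneEntry:
    """One canonical Delone type with its centering transformation."""

    symbol: str
    lattice_character: str
    m3: np.ndarray = field(repr=False)  # exact integer 3x3, object dtype
    m6: np.ndarray = field(repr=False)  # exact integer 6x6 = lift(m3)

    @property
    def is_identity(self) -> bool:
        return all(self.m3[i, j] == (1 if i == j else 0) for i in range(3) for j in range(3))

    @property
    def multiplicity(self) -> int:
        """Centering multiplicity = |det m3| = cell-volume ratio."""
        m = self.m3
        det = (
            m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
            - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
            + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
        )
        return abs(int(det))


def _build() -> dict[str, DeloneEntry]:
    identity = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
    entries = {}
    for sym, lattice, m3 in _RAW:
        arr = np.empty((3, 3), dtype=object)
        src = identity if m3 is None else m3
        for i in range(3):
            for j in range(3):
                arr[i, j] = int(src[i][j])
        arr.setflags(write=False)
        m6 = lift_matrix3(arr)
        m6.setflags(write=False)
        entries[sym] = DeloneEntry(sym, lattice, arr, m6)
    return entries


_ENTRIES = _build()


def catalog() -> list[DeloneEntry]:
    """All 24 entries in canonical order (C1 ... H4)."""
    return [_ENTRIES[sym] for sym in SYMBOLS]


def get_entry(symbol: str) -> DeloneEntry:
    """Look up a Delone type by symbol (case-insensitive)."""
    key = symbol.strip().upper()
    if key not in _ENTRIES:
        raise KeyError(
            f"unknown Delone type {symbol!r}; valid symbols: {', '.join(SYMBOLS)}"
        )
    return _ENTRIES[key]


def center_cell(symbol: str, s) -> np.ndarray:
    """Apply a Delone type's centering transformation to an S6 vector.

    Computes ``m6 @ s`` -- equivalent to transforming the edge
    vectors with ``m3`` and reconverting to Selling scalars, but
    without leaving S6.  The input should describe a valid lattice
    (positive-definite implied Gram matrix) and, for the catalog
    matrices to be crystallographically meaningful, be Selling
    reduced.
    """
    entry = get_entry(symbol)
    arr = np.asarray(s, dtype=float).ravel()
    if arr.shape != (6,):
        raise InvalidS6Error(f"expected 6 Selling scalars, got shape {arr.shape}")
    aa, bb, cc, dd = norms_squared(arr)
    for name, val in (("|a|^2", aa), ("|b|^2", bb), ("|c|^2", cc), ("|d|^2", dd)):
        if val <= 0:
            raise InvalidS6Error(f"derived squared norm {name} = {val:.6g} is not positive")
    g = s6_gram(arr)
    if np.linalg.det(g) <= 0 or g[0, 0] <= 0 or np.linalg.det(g[:2, :2]) <= 0:
        raise InvalidS6Error("S6 vector does not describe a positive-definite lattice")
    return entry.m6.astype(float) @ arr
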