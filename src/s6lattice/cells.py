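"""Unit cells as parameter sextuples and as edge-vector bases.

A crystallographic unit cell is given either by six parameters
``[a, b, c, alpha, beta, gamma]`` (lengths in angstroms, angles in
degrees) or by three edge vectors stacked as the *rows* of a 3x3
matrix.  Two bases related by a proper rotation describe the same
cell, so a canonical orientation is fixed for reproducibility:
``a`` along +x, ``b`` in the xy-plane with positive y-component,
and ``c`` with positive z-component (right-handed frame).

Transformation matrices act on a basis by *left* multiplication of
the stacked row-vector matrix, i.e. ``a' = m11*a + m12*b + m13*c``
and so on.  This is the Burzlaff-Zimmermann (1985) convention used
throughout the package, notably by the Delone centering catalog.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "UnitCell",
    "CellBasis",
    "InvalidCellError",
    "InvalidBasisError",
    "cell_to_basis",
    "basis_to_cell",
    "apply_matrix3",
    "parse_cell",
    "parse_matrix3",
    "parse_cryst1",
]

# Absolute tolerance on the Gram determinant, scaled by (abc)^2.
GRAM_DET_TOL = 1e-9


class InvalidCellError(ValueError):
    """Raised for cell parameters that do not describe a real lattice."""


class InvalidBasisError(ValueError):
    """Raised for degenerate (rank < 3) edge-vector bases."""


@dataclass(frozen=True)
class UnitCell:
    """Six cell parameters: lengths in angstroms, angles in degrees.

    Validity requires positive lengths, each angle strictly inside
    (0, 180), and a positive-definite metric (Gram) matrix --
    equivalently each angle smaller than the sum of the other two
    and the three angles summing to less than 360 degrees.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"edge length {name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise InvalidCellError(f"angle {name} must lie in (0, 180) degrees, got {ang}")
        g = self.gram()
        det = np.linalg.det(g)
        scale = (self.a * self.b * self.c) ** 2
        if det <= GRAM_DET_TOL * scale:
            raise InvalidCellError(
                "cell parameters give a non-positive-definite metric "
                f"(Gram determinant {det:.3e} <= tolerance); the angles are not "
                "jointly realizable in three dimensions"
            )

    def gram(self) -> np.ndarray:
        """Metric tensor G with G[i,j] the dot product of edges i and j."""
        a, b, c = self.a, self.b, self.c
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.gram())))

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


class CellBasis:
    """Three cell-edge vectors stacked as rows of a 3x3 matrix.

    The auxiliary fourth vector ``d = -a - b - c`` used by the
    Selling/Delone formalism is always derived, never stored.
    Ordinary construction rejects rank-deficient bases; the
    degenerate single- and two-row cells used to build the S6 lift
    are created through :meth:`degenerate`.
    """

    __slots__ = ("_m",)

    def __init__(self, rows: np.ndarray | list) -> None:
        m = np.asarray(rows, dtype=float)
        if m.shape != (3, 3):
            raise InvalidBasisError(f"expected a 3x3 array of edge vectors, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise InvalidBasisError("basis vectors must be finite")
        if abs(np.linalg.det(m)) <= 1e-12 * max(1.0, float(np.abs(m).max()) ** 3):
            raise InvalidBasisError("edge vectors are linearly dependent (rank < 3)")
        self._m = m
        self._m.setflags(write=False)

    @classmethod
    def degenerate(cls, rows: np.ndarray | list) -> "CellBasis":
        """Construct without the rank check (lift basis cells only)."""
        self = object.__new__(cls)
        m = np.asarray(rows, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise InvalidBasisError("degenerate basis still requires a finite 3x3 array")
        object.__setattr__(self, "_m", m)
        return self

    @property
    def matrix(self) -> np.ndarray:
        return self._m

    @property
    def a_vec(self) -> np.ndarray:
        return self._m[0]

    @property
    def b_vec(self) -> np.ndarray:
        return self._m[1]

    @property
    def c_vec(self) -> np.ndarray:
        return self._m[2]

    @property
    def d_vec(self) -> np.ndarray:
        return -self._m[0] - self._m[1] - self._m[2]

    def volume(self) -> float:
        return abs(float(np.linalg.det(self._m)))

    def __repr__(self) -> str:
        return f"CellBasis({self._m.tolist()!r})"


def cell_to_basis(cell: UnitCell) -> CellBasis:
    """Place a cell in the canonical right-handed frame.

    ``a`` lies along +x; ``b`` in the xy-plane with ``b_y > 0``;
    ``c`` has ``c_z > 0``.  This is the standard crystallographic
    orthogonalization (one fixed representative of the
    rotation-equivalence class of bases).
    """
    a, b, c = cell.a, cell.b, cell.c
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    cx = c * cb
    cy = c * (ca - cb * cg) / sg
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        # UnitCell validation makes this unreachable for valid input.
        raise InvalidCellError("cell parameters give a non-real c_z component")
    return CellBasis(
        [
            [a, 0.0, 0.0],
            [b * cg, b * sg, 0.0],
            [cx, cy, math.sqrt(cz_sq)],
        ]
    )


def basis_to_cell(basis: CellBasis) -> UnitCell:
    """Recover the six cell parameters from an edge-vector basis.

    The result depends only on the rotation-equivalence class of the
    basis (lengths and angles are rotation invariant).
    """
    av, bv, cv = basis.a_vec, basis.b_vec, basis.c_vec
    a = float(np.linalg.norm(av))
    b = float(np.linalg.norm(bv))
    c = float(np.linalg.norm(cv))

    def angle(u: np.ndarray, v: np.ndarray, nu: float, nv: float) -> float:
        cosang = float(np.dot(u, v)) / (nu * nv)
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    return UnitCell(a, b, c, angle(bv, cv, b, c), angle(av, cv, a, c), angle(av, bv, a, b))


def apply_matrix3(m: np.ndarray | list, basis: CellBasis) -> CellBasis:
    """Apply a 3x3 transformation to a basis by left multiplication.

    Row i of the result is ``m[i,0]*a + m[i,1]*b + m[i,2]*c``.  The
    lattice volume scales by ``|det m|``.  Degenerate inputs (the
    lift's basis cells) stay degenerate and are passed through.
    """
    mm = np.asarray(m, dtype=float)
    if mm.shape != (3, 3):
        raise ValueError(f"transformation must be 3x3, got shape {mm.shape}")
    rows = mm @ basis.matrix
    if abs(np.linalg.det(basis.matrix)) <= 1e-12:
        # degenerate lift basis cells stay degenerate
        return CellBasis.degenerate(rows)
    return CellBasis(rows)


# ---------------------------------------------------------------------------
# parsing


def parse_cell(text: str) -> UnitCell:
    """Parse a cell from text: six numbers, a JSON object, or CRYST1.

    Accepts whitespace- or comma-separated ``a b c alpha beta gamma``,
    a JSON object with those six keys, or a PDB CRYST1 record.
    """
    stripped = text.strip()
    if stripped.startswith("CRYST1"):
        return parse_cryst1(stripped)
    if stripped.startswith("{"):
        obj = json.loads(stripped)
        try:
            return UnitCell(
                float(obj["a"]), float(obj["b"]), float(obj["c"]),
                float(obj["alpha"]), float(obj["beta"]), float(obj["gamma"]),
            )
        except KeyError as exc:
            raise InvalidCellError(f"JSON cell is missing key {exc}") from None
    parts = re.split(r"[,\s]+", stripped)
    parts = [p for p in parts if p]
    if len(parts) != 6:
        raise InvalidCellError(f"expected 6 cell parameters, got {len(parts)}: {stripped!r}")
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise InvalidCellError(f"non-numeric cell parameter: {exc}") from None
    return UnitCell(*vals)


def parse_cryst1(line: str) -> UnitCell:
    """Parse a PDB CRYST1 fixed-column record (columns 7-54).

    Columns 7-15, 16-24, 25-33 hold a, b, c; columns 34-40, 41-47,
    48-54 hold alpha, beta, gamma.  Trailing space-group and Z
    fields are ignored.
    """
    if not line.startswith("CRYST1"):
        raise InvalidCellError("not a CRYST1 record (line must start with 'CRYST1')")
    if len(line.rstrip("\n")) < 54:
        raise InvalidCellError(
            f"CRYST1 record truncated: need at least 54 columns, got {len(line.rstrip())}"
        )
    spans = [(6, 15), (15, 24), (24, 33), (33, 40), (40, 47), (47, 54)]
    vals = []
    for lo, hi in spans:
        field = line[lo:hi]
        try:
            vals.append(float(field))
        except ValueError:
            raise InvalidCellError(
                f"CRYST1 columns {lo + 1}-{hi} are not numeric: {field!r}"
            ) from None
    return UnitCell(*vals)


def parse_matrix3(text: str) -> np.ndarray:
    """Parse a 3x3 matrix from nine row-major numbers or nested JSON.

    Integer entries are preserved exactly (object array of ints /
    Fractions) so that downstream lifting can run in exact
    arithmetic; otherwise a float array is returned.
    """
    stripped = text.strip()
    if stripped.startswith("["):
        rows = json.loads(stripped)
        flat = [x for row in rows for x in row]
    else:
        parts = [p for p in re.split(r"[,\s]+", stripped) if p]
        flat = []
        for p in parts:
            if "/" in p:
                flat.append(Fraction(p))
            elif re.fullmatch(r"[+-]?\d+", p):
                flat.append(int(p))
            else:
                flat.append(float(p))
    if len(flat) != 9:
        raise ValueError(f"expected 9 matrix entries, got {len(flat)}")
    if all(isinstance(x, (int, Fraction)) or float(x).is_integer() for x in flat):
        exact = [Fraction(x) if not isinstance(x, (int, Fraction)) else x for x in flat]
        exact = [int(x) if isinstance(x, Fraction) and x.denominator == 1 else x for x in exact]
        m = np.empty((3, 3), dtype=object)
        for i in range(3):
            for j in range(3):
                m[i, j] = exact[3 * i + j]
        return m
    return np.array(flat, dtype=float).reshape(3, 3)
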