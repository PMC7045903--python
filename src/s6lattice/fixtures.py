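"""Deterministic random-cell generation for tests and benchmarks.

Cells are drawn with edge lengths uniform in a requested range and
angles uniform in (30, 150) degrees, rejection-sampled until the
implied metric is positive definite (i.e. the three angles are
jointly realizable).  With ``reduced_only`` each cell is additionally
Selling-reduced, so its scalars are all nonpositive -- the domain the
Delone centering matrices expect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import InvalidCellError, UnitCell, basis_to_cell, cell_to_basis
from .reduce import reduce_basis

__all__ = ["FixtureSpec", "generate_cells"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random-cell draw."""

    n: int
    length_range: tuple[float, float] = (2.0, 50.0)
    seed: int = 0
    reduced_only: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"need 0 < min <= max edge length, got {self.length_range}")


def random_cell(rng: np.random.Generator, length_range: tuple[float, float] = (2.0, 50.0)) -> UnitCell:
    """One random valid cell (rejection sampling on the angle triple)."""
    lo, hi = length_range
    while True:
        a, b, c = rng.uniform(lo, hi, size=3)
        alpha, beta, gamma = rng.uniform(30.0, 150.0, size=3)
        try:
            return UnitCell(a, b, c, alpha, beta, gamma)
        except InvalidCellError:
            continue


def generate_cells(spec: FixtureSpec) -> list[UnitCell]:
    """Draw ``spec.n`` valid cells, deterministically under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    for _ in range(spec.n):
        cell = random_cell(rng, spec.length_range)
        if spec.reduced_only:
            cell = basis_to_cell(reduce_basis(cell_to_basis(cell)).basis)
        cells.append(cell)
    return cells
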