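import math

import numpy as np
import pytest

from s6lattice import (
    CellBasis,
    apply_matrix3,
    basis_to_cell,
    catalog,
    center_cell,
    e3_to_s6,
    get_entry,
    lift_matrix3,
    reduce_basis,
    s6_to_basis,
)
from s6lattice.catalog import CENTERING_MULTIPLICITY, SYMBOLS
from s6lattice.s6 import InvalidS6Error

from conftest import random_reduced_s6

# Unambiguously printed rows of the published S6 listings, keyed by
# (symbol, 1-based row index).
PRINTED_ROWS = {
    ("C1", 4): [0, 0, 0, 0, 2, 2],
    ("C1", 5): [0, 0, 0, 2, 0, 2],
    ("C1", 6): [0, 0, 0, 2, 2, 0],
    ("R1", 6): [0, 0, 0, 2, 1, 0],
    ("R3", 3): [0, 1, 0, 0, 0, 0],
    ("R3", 5): [0, 1, 0, 0, 0, 3],
    ("R3", 6): [0, 1, 2, 2, 9, 6],
    ("T1", 4): [0, 0, 0, 0, 2, 2],
    ("T1", 5): [0, 0, 0, 2, 0, 2],
    ("T1", 6): [0, 0, 0, 2, 2, 0],
    ("T2", 3): [0, 0, 1, 0, 0, 0],
    ("T2", 4): [0, 0, 0, 2, 0, 0],
    ("T2", 5): [0, 0, 0, 0, 2, 0],
    ("T2", 6): [0, 0, 0, 2, 2, 4],
    ("O1B", 4): [0, 0, 0, 0, 2, 2],
    ("O1B", 5): [0, 0, 0, 2, 0, 2],
    ("O1B", 6): [0, 0, 0, 2, 2, 0],
    ("O2", 3): [0, 0, 1, 0, 0, 0],
    ("O2", 4): [0, 0, 0, 2, 0, 0],
    ("O2", 5): [0, 0, 0, 0, 2, 0],
    ("O2", 6): [0, 0, 0, 2, 2, 4],
    ("O3", 4): [0, 0, 0, 0, 2, 2],
    ("O3", 5): [0, 0, 0, 2, 0, 2],
    ("O3", 6): [0, 0, 0, 2, 2, 0],
    ("O4", 1): [1, 1, 0, 0, 0, 0],
    ("O4", 4): [1, 1, 4, 2, 0, 0],
    ("M1A", 2): [0, 0, 0, 0, 0, 1],
    ("M1A", 4): [0, 0, 0, 0, 2, 0],
    ("M1A", 5): [2, 0, 4, 0, 2, 0],
    ("M1A", 6): [2, 0, 0, 0, 0, 0],
    ("M1B", 4): [0, 0, 2, 0, 2, 0],
    ("M1B", 5): [2, 0, 0, 0, 2, 0],
    ("M1B", 6): [2, 0, 2, 0, 0, 0],
    ("M2A", 1): [0, 0, 1, 0, 0, 0],
    ("M2A", 4): [2, 2, 0, 0, 0, 4],
    ("M2A", 5): [2, 0, 0, 0, 0, 0],
    ("M2A", 6): [0, 2, 0, 0, 0, 0],
    ("M2B", 4): [0, 0, 2, 0, 2, 0],
    ("M2B", 5): [2, 0, 0, 0, 2, 0],
    ("M2B", 6): [2, 0, 2, 0, 0, 0],
    ("M3", 1): [0, 0, 1, 0, 0, 0],
    ("M3", 4): [2, 2, 0, 0, 0, 4],
    ("M3", 5): [2, 0, 0, 0, 0, 0],
    ("M3", 6): [0, 2, 0, 0, 0, 0],
}


class TestCatalogStructure:
    def test_24_entries_in_order(self):
        entries = catalog()
        assert len(entries) == 24
        assert [e.symbol for e in entries] == list(SYMBOLS)

    def test_exactly_eight_identity_entries(self):
        identities = [e.symbol for e in catalog() if e.is_identity]
        assert identities == ["C5", "T5", "O5", "M4", "A1", "A2", "A3", "H4"]

    def test_determinant_matches_centering_multiplicity(self):
        for e in catalog():
            centering = e.lattice_character[1].upper()
            assert e.multiplicity == CENTERING_MULTIPLICITY[centering], e.symbol

    def test_m6_is_exact_lift_of_m3(self):
        for e in catalog():
            assert np.array_equal(e.m6, lift_matrix3(e.m3)), e.symbol

    def test_shared_matrix_entries_have_identical_m6(self):
        group = [get_entry(sym) for sym in ("C1", "T1", "O1B", "O3")]
        for e in group[1:]:
            assert np.array_equal(e.m3, group[0].m3)
            assert np.array_equal(e.m6, group[0].m6)


class TestPrintedRows:
    @pytest.mark.parametrize("key", sorted(PRINTED_ROWS), ids=lambda k: f"{k[0]}-row{k[1]}")
    def test_lift_reproduces_published_row(self, key):
        """Each published S6 row equals the lifted row, integer-exactly."""
        symbol, row = key
        m6_row = [int(x) for x in get_entry(symbol).m6[row - 1]]
        assert m6_row == PRINTED_ROWS[key]


class TestGetEntry:
    def test_c1(self):
        e = get_entry("C1")
        assert e.lattice_character == "cI"
        assert e.m3.tolist() == [[0, 1, 1], [1, 0, 1], [1, 1, 0]]

    def test_case_insensitive(self):
        assert get_entry("m1a").symbol == "M1A"

    def test_old_delone_symbol_rejected(self):
        with pytest.raises(KeyError, match="valid symbols"):
            get_entry("K1")


class TestCenterCell:
    def test_identity_type_is_noop(self, rng):
        s = random_reduced_s6(rng)
        assert np.allclose(center_cell("C5", s), s)

    def test_t2_component_six_closed_form(self, rng):
        """Row 6 of T2 reads 2*s4 + 2*s5 + 4*s6."""
        for _ in range(20):
            s = random_reduced_s6(rng)
            out = center_cell("T2", s)
            assert math.isclose(out[5], 2 * s[3] + 2 * s[4] + 4 * s[5], rel_tol=1e-12)

    def test_s6_route_matches_e3_route(self, rng):
        """m6 @ s equals transforming edge vectors then reconverting."""
        for e in catalog():
            for _ in range(100):
                s = random_reduced_s6(rng)
                via_s6 = center_cell(e.symbol, s)
                via_e3 = e3_to_s6(apply_matrix3(e.m3.astype(float), s6_to_basis(s)))
                scale = max(1.0, float(np.abs(via_e3).max()))
                assert np.allclose(via_s6, via_e3, rtol=1e-9, atol=1e-9 * scale)

    def test_centered_volume_is_multiplicity_times_primitive(self, rng):
        for e in catalog():
            if e.is_identity:
                continue
            s = random_reduced_s6(rng)
            basis = s6_to_basis(s)
            centered = apply_matrix3(e.m3.astype(float), basis)
            assert math.isclose(centered.volume(), e.multiplicity * basis.volume(),
                                rel_tol=1e-9)

    def test_invalid_s6_propagates(self):
        with pytest.raises(InvalidS6Error):
            center_cell("T2", [1.0, 0, 0, -1, -1, -1])


class TestCrystallographicSanity:
    """The centering matrices must map known reduced primitive cells to
    their conventional centered cells (cube, hexagonal cell, ...)."""

    def test_bcc_primitive_centers_to_cube(self):
        # primitive bcc basis (cube edge 2): already Selling reduced
        prim = CellBasis([[1, 1, -1], [1, -1, 1], [-1, 1, 1]])
        assert max(e3_to_s6(prim)) <= 0
        cell = basis_to_cell(apply_matrix3(get_entry("C1").m3.astype(float), prim))
        assert np.allclose(cell.parameters(), (2, 2, 2, 90, 90, 90), rtol=1e-12)

    def test_fcc_primitive_centers_to_cube(self):
        # Selling-reduced primitive fcc basis (cube edge 1)
        prim = CellBasis([[0.5, 0.5, 0], [-0.5, 0.5, 0], [0, -0.5, 0.5]])
        assert max(e3_to_s6(prim)) <= 0
        cell = basis_to_cell(apply_matrix3(get_entry("C3").m3.astype(float), prim))
        assert np.allclose(cell.parameters(), (1, 1, 1, 90, 90, 90), rtol=1e-12)

    def test_rhombohedral_primitive_centers_to_hexagonal(self):
        from s6lattice import UnitCell, cell_to_basis

        prim = cell_to_basis(UnitCell(3.0, 3.0, 3.0, 100, 100, 100))
        assert max(e3_to_s6(prim)) <= 0
        cell = basis_to_cell(apply_matrix3(get_entry("R1").m3.astype(float), prim))
        a, b, c, alpha, beta, gamma = cell.parameters()
        assert math.isclose(a, b, rel_tol=1e-9)
        assert math.isclose(alpha, 90, abs_tol=1e-9)
        assert math.isclose(beta, 90, abs_tol=1e-9)
        assert math.isclose(gamma, 120, abs_tol=1e-9)
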