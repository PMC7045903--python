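# Methods

## The representation

A lattice basis is three edge vectors **a**, **b**, **c**, stacked as the
rows of a 3×3 matrix; the auxiliary vector **d** = −**a** − **b** − **c**
is always derived, never stored, so the four-vector sum is zero by
construction. Two bases related by a proper rotation describe the same
cell; the package works with one fixed representative per equivalence
class, the canonical right-handed frame (**a** along +x, **b** in the
xy-plane with positive y-component, **c** with positive z-component).

The Selling scalars of a basis are the six pairwise dot products

    s = [b·c, a·c, a·b, a·d, b·d, c·d]   (Å²),

a point in **S⁶**. They are rotation invariant and determine the cell
completely: the squared norms are linear in the scalars
(|a|² = −(s₂+s₃+s₄) and cyclic variants), and with them the full Gram
matrix of (**a**, **b**, **c**) is recovered. Summing the four norm
identities gives the sum rule Σsᵢ = −(|a|²+|b|²+|c|²+|d|²)/2, used as a
cheap internal consistency check in the tests.

### Inverse map

`s6_to_basis` rebuilds the canonical-frame basis by Cholesky-style
substitution: |a| = √(−s₂−s₃−s₄), a = (|a|,0,0), b_x = s₃/|a|,
b_y = +√(|b|²−b_x²), c_x = s₂/|a|, c_y = (s₁−b_x c_x)/b_y,
c_z = +√(|c|²−c_x²−c_y²). The positive square roots fix one member of the
rotation-equivalence class deterministically; any rotation of the result
has the same scalars, so this choice is a convention, not a constraint.
Validity is decided by positive definiteness of the implied Gram matrix
(leading principal minors must be strictly positive), not merely by scalar
signs: zero scalars on the reduced-domain boundary are legal, while scalar
sets whose Gram is indefinite are rejected with a message naming the first
violated quantity. The error path is exercised against a brute-force
eigenvalue test in the suite.

## The lift

The core operation converts a 3×3 matrix *M* acting on bases (by left
multiplication of the stacked rows, a′ = m₁₁**a** + m₁₂**b** + m₁₃**c**)
into the 6×6 matrix acting on Selling scalars. Converting to edge vectors,
applying *M* and converting back is linear in the scalars, so the induced
map has a matrix, determined by its action on a basis of **S⁶**.

The positive S⁶ unit vectors cannot be realized by real edge vectors: a
unit dot product between distinct unit vectors forces nonzero products
with **d**. Their negatives can. Six degenerate "basis cells" are used,
index-aligned with the scalar positions:

- positions 4–6: a single unit vector in row **a**, **b** or **c**
  (only the matching d-product, −1, survives);
- positions 1–3: an antiparallel unit pair in the two participating rows,
  which makes **d** vanish and leaves the single pair product −1.

Each two-row cell's second nonzero row is (−1,0,0); that this is the
unique choice producing exactly one −1 scalar is verified at import time
rather than assumed. With basis cell Bⱼ mapping to −eⱼ,

    column j of lift(M) = − e3_to_s6(M · Bⱼ),

and the defining (and tested) property is the commutation relation
e3_to_s6(M·B) = lift(M)·e3_to_s6(B) for every basis B. The construction is
quadratic in the entries of M, so integer or rational input yields an
exactly integer or rational 6×6 matrix; the integer path runs in pure
Python exact arithmetic and catalog comparisons are integer equality, not
approximate. No symbolic algebra system is involved: the closed forms that
could be generated symbolically are equivalent to the numeric column
construction, which is the contract the tests pin down (homomorphism
lift(AB) = lift(A)lift(B), inverse mapping to inverse, and
det lift(M) = (det M)⁴ checked with an independent exact determinant).

## The Delone catalog

The 24 canonical Delone types C1…H4 each carry a fixed transformation from
the Selling-reduced primitive cell to the conventional (possibly centered)
cell. The 3×3 matrices follow the Burzlaff–Zimmermann (1985) orientation —
matrices applied to the *left* of row-vector bases and of S⁶ vectors; note
that the later 1992 listing is the transpose. The 6×6 matrices are never
stored: they are computed from the 3×3 matrices by the lift at import, so
the two representations cannot drift apart, and every published row of the
6×6 listings is reproduced integer-exactly in the tests.

|det m3| equals the centering multiplicity: 1 for primitive (P, aP, hP),
2 for body- (I) and base-centered (S), 3 for rhombohedral (R), 4 for
face-centered (F). Eight types (C5, T5, O5, M4, A1–A3, H4) are identity
transformations. Some matrices repeat across types (C1/T1/O1B/O3;
M1B/M2B; M2A/M3); each symbol keeps its own entry, since the Delone type
is the lookup key. Where published listings are ambiguous, the stored
matrices were fixed by requiring the lift to reproduce every unambiguous
6×6 row together with the determinant/multiplicity constraint (a unique
solution for the monoclinic types), and, where rows alone underdetermine
the matrix (R1, O4, C3/O1A), by the standard crystallographic setting:
R1 is the rhombohedral→hexagonal change a_hex = a−b, b_hex = b−c,
c_hex = a+b+c; O4 the base-centering a′ = a−b, b′ = a+b; C3/O1A the
face-centering with rows (1,1,0), (−1,1,0), (1,1,2). Each such choice is
validated physically in the suite: the matrix must map a Selling-reduced
primitive bcc/fcc/rhombohedral cell to the conventional cube or hexagonal
cell of the right volume.

Deciding *which* Delone type a given cell belongs to (lattice
identification) is out of scope; the catalog applies a chosen type.

## Selling reduction

While some scalar sᵢ = p·q is positive, the classical exchange replaces
p → −p and adds p to the two vectors other than p and q. The four-vector
sum stays zero and the norm sum |a|²+|b|²+|c|²+|d|² decreases by exactly
2p·q, which bounds the step count for any positive-definite lattice; the
suite verifies the closed-form decrease at every step. Tie-breaking is
deterministic: the most positive scalar is exchanged, lowest index on
ties. The scalar that gets negated is the first member of the pair in the
ordering (b,c), (a,c), (a,b), (a,d), (b,d), (c,d).

Bookkeeping runs on the induced integer 3×3 matrix on (**a**, **b**, **c**)
(eliminating **d**), accumulated exactly; each elementary exchange is
unimodular (det ±1), so the lattice and cell volume are preserved. The
accumulated matrix is reported together with its 6×6 lift, so the whole
reduction can be replayed purely inside S⁶
(m6_total·s_input = s_reduced). No update rule expressed directly on the
scalars is attempted, and no canonical ordering of the reduced scalars is
applied after sign reduction — the reduced vector is reported as produced,
which the tests show is unique up to permutation for generic lattices.

Defaults: relative tolerance 1e-9 (a scalar counts as positive only above
1e-9·max|sᵢ|, so near-boundary zeros terminate), max_steps 1000 (reached
only for invalid input; random cells with axis ratios up to 100:1 reduce
in far fewer steps).

## Synthetic cells

The test generator draws edge lengths uniform in a requested range
(default 2–50 Å, spanning small-molecule to protein cells) and angles
uniform in (30°, 150°), rejection-sampling the angle triple until the
metric is positive definite; with `reduced_only` each cell is
Selling-reduced first. The generator covers generic (triclinic) lattices
well but produces exactly symmetric cells (cubic, hexagonal …) with
probability zero, so catalog behavior on high-symmetry input is covered
separately by constructed bcc/fcc/rhombohedral fixtures. It also does not
emulate measurement noise: all cells are exact lattices, so passing tests
say nothing about the stability of Delone-type *assignment* under
experimental error (assignment itself is out of scope).

## Numerical choices

- Cell validity: Gram determinant > 1e-9·(abc)²; angle parameters strictly
  inside (0°, 180°).
- Basis validity: |det| > 1e-12 relative to the largest entry cubed;
  the degenerate lift basis cells bypass this check through a separate
  constructor and are accepted by `e3_to_s6` (dot products need no rank).
- Round-trip accuracy: parameter and S⁶ round trips hold to 1e-9 relative
  in the suite (1e-10 for the parameter round trip alone).
- Problem sizes in the suite and acceptance script — 500 commutation
  pairs, 1000 round-trip cells, 1000 reduction traces, 200 exact
  homomorphism checks — keep the full run under ten seconds while
  exercising every code path; the checked identities are exact, so larger
  samples would add confidence only against vanishingly rare
  floating-point corner cases.

## Known limitations

- The inverse `s6_to_basis` returns one canonical representative; callers
  comparing bases directly (rather than scalars or parameters) must
  account for the rotation freedom.
- Exact arithmetic applies to integer/rational matrices only; float
  matrices take a float path with ordinary rounding.
- S⁶ distances, boundary projections, Niggli (G⁶) reduction and Bravais
  lattice identification are intentionally absent.
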