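# s6lattice

Crystallographic lattices as Selling/Delone scalars, and the algebra that
moves between the 3×3 and 6×6 pictures.

A unit cell with edge vectors **a**, **b**, **c** and auxiliary vector
**d** = −**a** − **b** − **c** is represented by its six Selling scalars

```
s = [b·c, a·c, a·b, a·d, b·d, c·d]        (Å²)
```

a point in the six-dimensional space **S⁶**. The scalars are invariant under
rotation, so **S⁶** describes the cell itself rather than any particular
orientation. A cell is *Selling reduced* when all six scalars are
nonpositive; the 24 canonical Delone types classify Bravais lattices by the
zero/equality pattern of the reduced scalars.

The package provides, for structural biologists and crystallographers who
work with reduced cells (indexing, lattice comparison, database searches):

- **`cells`** — cells as parameter sextuples `[a, b, c, α, β, γ]` or as
  row-vector bases, with a fixed canonical frame; parsing from text, JSON
  and PDB `CRYST1` records. Transformation matrices act on bases by left
  multiplication (Burzlaff–Zimmermann convention).
- **`s6`** — the forward map `e3_to_s6` and a deterministic inverse
  `s6_to_basis` (validity decided by positive definiteness of the implied
  Gram matrix).
- **`lift`** — the core operation: any 3×3 cell transformation *M* lifts to
  the unique 6×6 matrix on Selling scalars with

  ```
  e3_to_s6(M·B) = lift(M) · e3_to_s6(B)      for every basis B,
  ```

  built column by column from six degenerate basis cells whose scalars are
  the *negatives* of the S⁶ unit vectors (the positive unit vectors are not
  realizable by real edge vectors). Integer input gives an exactly integer
  result; `lift(AB) = lift(A)·lift(B)` and `det lift(M) = (det M)⁴`.
- **`catalog`** — the 24 Delone types (C1…H4) with their
  primitive→centered matrices in both spaces; the 6×6 matrices are always
  computed from the 3×3 ones by the lift. `|det m3|` equals the centering
  multiplicity (I/S: 2, R: 3, F: 4).
- **`reduce`** — Selling reduction by the classical exchange steps, with
  the accumulated unimodular basis change reported in both spaces.
- a CLI (`s6lattice lift|cell2s6|s62cell|reduce|center|catalog|fixtures`)
  and a deterministic random-cell generator for testing.

## Worked example

Lift the body-centering matrix of Delone type T2 (tetragonal *tI*) and
apply it to a reduced cell:

```pycon
>>> import numpy as np, s6lattice as sl
>>> m6 = sl.lift_matrix3(np.array([[1,0,0],[0,1,0],[1,1,2]], dtype=object))
>>> print(m6)
[[1 0 0 0 -1 0]
 [0 1 0 -1 0 0]
 [0 0 1 0 0 0]
 [0 0 0 2 0 0]
 [0 0 0 0 2 0]
 [0 0 0 2 2 4]]
>>> s = sl.e3_to_s6(sl.cell_to_basis(sl.UnitCell(1, 1, 1, 90, 90, 90)))
>>> np.round(sl.center_cell("T2", s), 12)
array([ 1.,  1.,  0., -2., -2., -8.])
```

Row 6 of the lifted matrix, `[0, 0, 0, 2, 2, 4]`, says the new scalar
`c′·d′` equals `2s₄ + 2s₅ + 4s₆`; on the unit cube
(`s = [0,0,0,−1,−1,−1]`) the centered cell has `c′·d′ = −8`. (The centered
cell is no longer reduced — two of its scalars are positive.) The same
answer comes from transforming the edge vectors first and converting
afterwards — that commutation is the package's defining correctness
property and is tested on hundreds of random (matrix, cell) pairs.

Selling-reduce a cell from the command line:

```
$ s6lattice reduce "2 2 2 60 70 80"
{
  "s6_input": [2.0, 1.3680805733, 0.694592710668,
               -6.06267328397, -6.69459271067, -7.3680805733],
  "s6_reduced": [-0.673487862635, -2.0, -0.694592710668,
                 -1.30540728933, -2.6319194267, -1.32651213737],
  "m3_total": [[0, 1, 0], [-1, 0, 0], [0, -1, 1]],
  "m6_total": [[0, -1, 1, 0, 0, 0], ...],
  "steps": 4
}
```

The reduced scalars are all nonpositive, `m3_total` is unimodular (the
lattice is unchanged), and `m6_total·s_input = s_reduced` replays the whole
reduction inside S⁶.

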