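# Methods

## Strength-weighted graphs and the ten indices

A strength-weighted graph G_sw = (G, (w_v, s_v), s_e) carries a vertex
weight, a vertex strength and an edge strength, all non-negative exact
numbers (`int` or `fractions.Fraction`; floats are rejected at
construction).  Distances are always unweighted shortest-path edge counts —
strengths never enter distance computation.  The *plain profile*
(w_v ≡ 1, s_v ≡ 0, s_e ≡ 1) recovers the ordinary molecular graph, and
every index then equals its classical value; this reduction is asserted in
the tests.

Conventions that matter and are easy to get wrong:

* vertex–edge distance d(u, f) = min over the endpoints of f; edge–edge
  distance D(e, f) = min over the endpoints of e of d(·, f).  D(e, e) = 0
  and edges sharing a vertex are at distance 0 (this is *not* the
  line-graph convention).
* closeness cardinalities use strict inequality: vertices/edges equidistant
  from both endpoints of an edge belong to neither side.  No half-split
  variant is implemented.  On bipartite graphs the vertex split is total
  (n_u + n_v = Σ w_v), which the tests assert for every generated structure.
* Wve and Szev carry a factor ½ and are exact rationals in general; on the
  tessellations they are integers, and the acceptance checks assert that.

All-pairs distances are computed by BFS (scipy.sparse.csgraph on a CSR
adjacency) and cached per graph.  Index evaluation is vectorised over the
shared distance table: int64 arrays when all weights are integers (values
here stay far below 2^63; the largest generated instance, 5,206 atoms and
6,896 bonds, gives index values ≈ 2.6 × 10^11), object (Fraction) arrays
otherwise.  Both paths run the same formulas, so the exactness of the
rational path validates the fast path on small inputs.

## Tessellation geometry

The kekulene unit is the union of the 12 hexagonal cells at cell-distance
exactly 2 from a central cell; that crown has 48 atoms, 60 bonds, 24 rim
atoms of degree 3, and a coronene-shaped cavity.  Cells are addressed by
axial coordinates; atoms live at integer *doubled* coordinates
(cell (q, r) has corners (2q+r±1, 3r±1), (2q+r, 3r±2)), so fused hexagons
share atoms by exact equality and the embedding with unit bond length is
(X·√3/2, Y/2).

The published description of the two rectangular meshes is a figure the
text does not fully specify, so the geometry was *derived* from hard
constraints rather than read off a picture: the generator had to satisfy,
simultaneously, the closed-form vertex/edge count formulas over a (m, n)
sweep and the published exact integer values of all ten indices at several
(m, n).  The count algebra alone forces rows to be m units fused through
catacondensed 3-hexagon chains (34m+14 atoms per row, unit centers 4 cells
apart), rows stacked one cell-layer apart with one bridging hexagon above
each unit center, plus, per row junction, 18 extra atoms / 24 extra bonds
forming one 5-hexagon hook (one doubly-fused and four singly-fused
hexagons).  A cluster search over candidate hook placements against the
Wiener oracle left exactly two placements — mirror images yielding
isomorphic graphs (the left end is used).  Type-II caps *both* junction
ends, the second hook being the point-inversion image of the first.  The
resulting generators reproduce, with no free parameters left:

* both count formulas for 1 ≤ n ≤ 4, 1 ≤ m ≤ 10;
* all ten indices of Type-I at (m5, n2) and (m8, n3), and the seven
  non-erratum indices at (m6, n2) and (m9, n3);
* all ten indices of Type-II at (m5, n2) and (m6, n2) except the published
  Szev/Szt (which are off by an exact factor-2 slip, see below);
* the published "old" unhooked sheet counts and Wiener values, as a
  byproduct of the same row/bridge core.

Vertex ids are assigned lexicographically in doubled coordinates, so
generated structures, exports and reports are byte-stable.

## Cut method

Θ is evaluated on all O(|E|²) edge pairs from the cached distance table and
closed into Θ* by union–find; no lattice-specific shortcut is assumed
(correctness first — the largest instances used here take seconds).  The
quotient by a class has the components of G − F as vertices, with
w(C) = Σ w_v, s(C) = Σ s_v + Σ s_e over interior edges, and bundled cut
edges carrying summed strengths.  Two safety properties are enforced, not
assumed: a class whose removal fails to separate some class edge's
endpoints raises (classes of these coronoids are always cuts, but the code
does not rely on it), and weight/strength conservation of every quotient is
asserted in the tests.

One wrinkle the displayed index definitions hide: Schultz and Gutman use an
effective degree, and for the *decomposition* the effective degree of a
contracted component must be its classical **degree mass**
d_Q(C) + 2·s(C) — each interior edge contributes twice to the component's
total degree — whereas the definition as displayed reads d + s.  Both
coincide on plain graphs (s_v = 0).  The quotient evaluation therefore uses
`degree_mass=True`; with it, direct = cuts holds for all ten indices on
every structure tested, including weighted inputs for the purely
distance-based indices.

The decomposition identity is an empirically asserted contract: direct
computation remains the reference result in any disagreement.

Class signatures (sorted multiset of quotient (w, s) pairs plus cut
strength) are the comparison currency against the published quotient
tables; the geometric class labels of the source (ACZ/OBZ/VRZ/TH/H/...)
depend on figure orientation and are not reproduced.  At (m5, n2) Type-I
the partition has 48 classes; the (7, 6)-component/cut-4 signature occurs
seven times (the published table itself lists seven such families across
its TH and corner-acute rows).

## Closed forms and erratum adjudication

The printed polynomials (ten indices × two types × two regimes, numerators
over 15, PI over 3) are transcribed verbatim into a JSON bank keyed by
monomial exponents, including the entries that are provably misprinted;
static flags mark the two printing anomalies visible on the face of the
source (the boundary-regime Type-I We/Wve pair printed as identical copies,
and a garbled `1248*` token in the interior-regime Type-II PI entry, read
as 1248m because that reading reproduces the printed table).  Every
division by 15/3 is checked exact at evaluation time; a failure raises
rather than rounding.

`adjudicate_errata` classifies each entry empirically: evaluate the printed
polynomial on a regime grid (boundary: n ∈ {1,2,3}; interior: n ∈ {1,2,3},
m ∈ 3n..3n+3 — small enough for seconds-scale runs, dense enough to catch
every known deviation) and compare with brute force on the generated
structure.  Outcomes on that grid:

* confirmed: all boundary-regime Type-I entries except We/Wve; interior
  Type-I W, We, Szv, Sze, PI, S, Gut.
* errata: the identically-printed Type-I We/Wve pair; interior-regime
  Wve/Szev/Szt of both types (consistently wrong in polynomial *and*
  printed table); Type-II Szev/Szt everywhere (exactly 2× the definition's
  value — a dropped ½); and all Type-II boundary entries for n ≥ 3, which
  trace to a quotient-weight misprint in the source's own bookkeeping table
  (its junction-cut component split evaluates to fewer atoms than one row,
  which is impossible; correcting that single split reproduces the
  brute-force Wiener value to the digit at two independent (m, n)).

For erratum entries the adjudicator refits the correct polynomial by exact
rational elimination on brute-force points.  On the boundary regime the
bivariate support collapses along m = 3n−1, so only the line-restricted
univariate form (degree ≤ 5, fitted at n = 1..6) is determined; it is
stored with an explicit `line_restricted` marker and never extrapolated off
the line.  The refitted We/Wve forms reproduce the printed table columns
including the largest (n = 7) column, which lies outside the fitted range —
evidence the fit recovered the true polynomial.  Interior-regime refits of
the n⁵-support entries would need n > 3 grids and are reported as
underdetermined under the default grid rather than guessed.

## Problem sizes and runtime

The test suite generates everything it needs at run time: fixtures
(paths/cycles/hexagon chains), kekulene, and tessellations up to ~3,800
atoms (the n = 6 fit point); the full suite runs in well under a minute on
one CPU.  The acceptance script touches only the ≤ 484-atom instances and
runs in about a second.

## Limitations

* The generators cover the two tessellation types and the kekulene unit;
  the "old" reference sheet appears only as printed comparison values, its
  construction is not exported.
* `index_via_cuts` recomputes the Θ*-partition unless one is passed in;
  callers computing several indices should use `cuts_compute_all` or share
  a partition explicitly.
* For weighted inputs with s_v > 0 the Schultz/Gutman decomposition
  reproduces the degree-mass convention, not the displayed d + s form
  (they differ only off the plain profile).
* Closed forms exist only for m ≥ 3n−1; the generators, direct computation
  and cut method work for every m, n ≥ 1.
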