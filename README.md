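# kektess

Distance-based topological indices of **strength-weighted graphs** and of the
**rectangular kekulene tessellations** RK(m,n), computed three independent
ways and cross-validated against each other.

Kekulene is the doughnut-shaped cycloarene C₄₈H₂₄ — twelve benzene rings
fused into a closed macrocycle.  Arranged in an m × n rectangular mesh it
yields two families of large coronoid polycyclic aromatic hydrocarbons,
RK(m,n) Type-I and Type-II, whose molecular graphs this package generates on
an exact hexagonal lattice (Type-I: |V| = 36mn−2m+32n−18,
|E| = 48mn+40n−4m−24; Type-II: |V| = 36mn+50n−2m−36, |E| = 48mn+64n−4m−48).
Such distance-based descriptors feed QSPR/QSAR models in cheminformatics,
where exact integer values — not floating-point approximations — are the
point of the exercise.

For any simple connected graph (optionally carrying vertex weights w_v,
vertex strengths s_v and edge strengths s_e) the package computes ten
indices exactly:

* Wiener `W = Σ_{u<v} w(u)w(v) d(u,v)`, edge-Wiener `We`, vertex-edge-Wiener
  `Wve` (distance sums over vertex, edge and mixed pairs; edge–edge distance
  is the min-endpoint convention `D(e,f) = min_{x∈e} d(x,f)`),
* the Szeged family `Szv = Σ_e s_e n_u n_v`, `Sze = Σ_e s_e m_u m_v`,
  `Szev = ½ Σ_e s_e (n_u m_v + n_v m_u)`, `Szt = Szv + Sze + 2 Szev`, where
  n/m count (weighted) vertices/edges strictly nearer one endpoint,
* Padmakar–Ivan `PI = Σ_e s_e (m_u + m_v)`,
* Schultz `S` and Gutman `Gut` (degree-and-distance sums).

Three computation routes are implemented and compared:

1. **direct** — brute force from the definitions over the BFS distance table;
2. **cuts** — the cut method: the Djoković–Winkler relation Θ
   (`d(u,c)+d(v,d) ≠ d(u,d)+d(v,c)`) is closed transitively into the
   Θ*-partition of the edge set; every class of these coronoids is an edge
   cut, and each index is the sum of its values on the strength-weighted
   quotient graphs G/F_i;
3. **closed_form** — published closed-form polynomials in (m, n) for both
   tessellation types in the regimes m = 3n−1 and m > 3n−1, stored verbatim
   in a JSON coefficient bank, together with an empirical erratum
   adjudicator that classifies every entry against brute force and refits
   corrected polynomials where the data determine them (several printed
   entries are demonstrably wrong; the package flags them rather than
   silently repairing the source).

All arithmetic on the computation path is exact (integers and
`fractions.Fraction`); no floating point touches an index value.

## Worked example

```
$ kektess build --type I -m 5 -n 2
RK(5,2) Type-I: |V|=396 |E|=516
count formulas: |V| ok, |E| ok

$ kektess indices --type I -m 5 -n 2 --method direct,cuts,closed_form
W     direct=1529326  cuts=1529326  closed_form=1529326
We    direct=2441352  cuts=2441352  closed_form=2439672  [closed-form entry flagged as erratum]
Wve   direct=1932744  cuts=1932744  closed_form=2439672  [closed-form entry flagged as erratum]
Szv   direct=14122936  cuts=14122936  closed_form=14122936
Sze   direct=22602448  cuts=22602448  closed_form=22602448
Szev  direct=17870172  cuts=17870172  closed_form=17870172
Szt   direct=72465728  cuts=72465728  closed_form=72465728
PI    direct=261520  cuts=261520  closed_form=261520
S     direct=7935312  cuts=7935312  closed_form=7935312
Gut   direct=10293184  cuts=10293184  closed_form=10293184
```

Reading: the 396-atom Type-I sheet at (m=5, n=2) has Wiener index 1,529,326
— the sum of shortest-path distances over all 78,210 atom pairs — and the
definition-level computation agrees with the 48-class cut decomposition on
all ten indices.  The closed-form route agrees too, except on the two
entries whose printed polynomials are a known misprint (the edge-Wiener and
vertex-edge-Wiener expressions were printed as identical copies); the CLI
exits 0 because the disagreement is confined to erratum-flagged entries.

The same from Python:

```python
from kektess import build_rk, compute_all, cuts_compute_all

swg = build_rk("I", 5, 2).to_swg()
vals = compute_all(swg)          # {'W': 1529326, 'PI': 261520, ...}
assert vals == cuts_compute_all(swg)
```

Other entry points: `kektess reproduce --table 3` recomputes a published
index table column by column with per-cell agreement flags;
`kektess build ... --out x.graphml` (or `.tsv`, `.json`, `.sdf`) exports
structures; `kektess.adjudicate_errata()` returns the full closed-form
classification report.

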