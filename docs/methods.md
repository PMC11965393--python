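# Methods

## Model

All computations operate on hydrogen-suppressed carbon skeletons of
benzenoid hydrocarbons: simple, connected, undirected graphs with maximum
degree 3 that are bipartite (even-ring systems).  Domination follows the
closed-neighborhood convention — a vertex dominates itself and its
neighbors.  This convention is forced by the structure of the theory: the
singleton sets of complete graphs and the alternating 5-set
{v2, v4, v6, v8, v10} of naphthalene are minimal dominating sets only under
closed neighborhoods.

A minimal dominating set (M.D.S.) is a dominating set in which every member
has a *private closed neighbor* — some vertex dominated by it alone.  The
domination degree `d_d(v)` counts the M.D.S.'s containing `v`.  Ten indices
are edge sums of symmetric functionals `φ(d_d(u), d_d(v))` (see
`domentropy.indices` for the exact forms), and each index induces a Shannon
entropy of its normalized edge-weight distribution.

Two functional forms deserve note:

* **DAZ (augmented Zagreb)** uses the denominator `d_d(u)·d_d(v) − 2`
  (product minus 2), not the classical `d_d(u)+d_d(v) − 2`.  The
  two-fused-hexagon worked value 11.85 is reproduced only by the
  product-minus-2 form, so that form is implemented; a degree pair with
  product exactly 2 (it occurs, e.g., on the 5-vertex path) is a domain
  error rather than a silent infinity.
* **DABC** has a zero summand exactly on a (1, 1) degree pair (e.g. the
  single edge of K2); the entropy convention `0·ln 0 = 0` covers this case.

## Enumeration algorithm

`D` dominates iff `D` hits every closed neighborhood, i.e. `D` is a
transversal of the hypergraph `{N[v] : v ∈ V}`.  The enumerator therefore
branches on the lowest-index vertex not yet dominated and adds, in turn,
each member of its closed neighborhood.  Two facts make this exact and
fast:

1. every minimal dominating set appears as some leaf (at each step the
   chosen vertex's neighborhood must be hit by any extension);
2. private neighborhoods only shrink as the set grows, so any branch in
   which some chosen vertex has already lost all private closed neighbors
   can be pruned — no minimal set lies below it (irredundance pruning).

Leaves are dominating sets; those passing the private-neighbor minimality
test are collected, deduplicated by bitmask, and sorted lexicographically.
Determinism is structural (no randomness, no hash-order dependence).  Sets
are bitmasks internally; the default vertex cap of 32 reflects that
representation and the intended problem sizes (largest catalog graphs:
n = 26, which enumerate in roughly a second; the full 29-molecule table
takes on the order of ten seconds on one CPU).  An independent brute-force
oracle (all 2^n subsets, n ≤ 16) backs the property tests; the two routes
agree on hundreds of random connected graphs and on all small paths,
cycles, stars, and complete graphs.

## Catalog encoding

The 29 skeletons are stored as frozen edge lists generated once from
explicit ring-fusion declarations (`RingFusionSpec`).  Gluing is by
declaration only, never by drawing-plane coincidence, which is what allows
helicenes: pentahelicene and hexahelicene are ortho-fused chains whose
terminal rings must *not* fuse even though a planar lattice drawing would
overlap them.  Catacondensed systems are encoded as attachment-edge chains
or trees (attachment 3 = linear step, 2/4 = the two turns); pericondensed
systems (pyrene, perylene, the benzopyrenes, benzo[ghi]perylene, coronene)
are given as axial hexagon coordinates from which fusion declarations are
derived.

Because isomer identity matters (the entropies of, say, the twelve C22H14
catafusenes differ only in the third decimal), every catalog structure was
verified against its tabulated total Hückel π-electron energy — computed
from the adjacency spectrum as twice the sum of the bonding eigenvalues —
which is distinct for each isomer in the catalog and matched to the fourth
decimal in all 29 cases.  This also fixed the less obvious structures:
benzo[g]chrysene is the *branched* five-ring catafusene (a triphenylene
core with an angularly extended arm) and dibenzo[b,g]phenanthrene the
straight-then-double-turn chain.  Naphthalene is stored with the
conventional two-ring labeling (shared edge v2–v3) so that the degree
vector reads (10, 8, 8, 10, 9, 9, 10, 9, 9, 10) in display order.

The embedded property table (BP, LogP, MR, E, FP, P, MW, XLogP3, C, PE) is
a frozen transcription of the published compilation of
PubChem/ChemSpider-sourced values.  It is consumed as data: the BH27
molecular-weight entry (328.4) disagrees with the standard value for
benzo[ghi]perylene (276.33) but is kept as published; π-electronic energy
is never recomputed at run time.

## Entropy computation

Entropies use the numerically stable form
`ln W − (1/W) Σ w ln w` rather than the algebraically identical product
form `ln W − (1/W) ln Π w^w`, whose inner product overflows for DM3*
weights in the tens of thousands.  Equivalence of the two forms is asserted
(in log space) to 1e-10 in the tests.  Display rounding to 4 decimals
happens only at the formatting layer; regressions use full-precision
entropies.  (Whether the reference regressions used rounded or
full-precision entropies is unknowable from the outside; both choices
reproduce the correlation coefficients to about three decimals, so the
choice is immaterial at the reported tolerance.)

### Comparison with the published reference table

Regenerating all 290 entropy cells reproduces the published reference
within ±0.001 in 284 cells.  The six exceptions are evidence of misprints
in the reference, not model disagreement:

* **BH27/E_DM1 (printed 3.3281)** and **BH28/E_DAZ (printed 3.4359)**
  exceed the theoretical maximum `ln m` for their graphs
  (`ln 27 = 3.2958`, `ln 31 = 3.4340`) — impossible for any entropy.
  The computed values (3.2937, 3.4340) respect the bound.
* **BH11/BH12, columns E_DF and E_DM3***: the printed values are
  transposed between the pentacene and benzo[a]tetracene rows.  Our BH11
  values equal the printed BH12 cells and vice versa, and within a row
  E_DF must track E_DM2/E_DHM closely (the weight vectors
  `a²+b²`, `ab`, `(a+b)²` are near-proportional when degrees are nearly
  homogeneous) — the printed rows violate this, the computed rows obey it.
* **BH27/E_DM3* (printed 3.2781, computed 3.2771)**: 0.0010 apart, in the
  one row already containing an impossible cell.

The comparison utility (`compare_with_published`, CLI
`entropies --all --compare`) itemizes exactly these cells and flags
bound-exceeding published values.  The corresponding whole-table acceptance
test asserts the strict per-cell criterion and is expected to fail on the
itemized cells; it is kept strict deliberately so the discrepancy list
stays visible.

One further reference slip: the worked-example value `DGA = 10.968` for
naphthalene is inconsistent with its own printed four-term sum, which
evaluates to 10.9697 (rounds to 10.970).  The package reports the exact
formula value; at two decimals both agree on 10.97.

## QSPR layer

Ordinary least squares with intercept (statsmodels).  Reported statistics:
`r` as a magnitude (slopes carry the sign), residual standard error
`SE = √(RSS/(n−k−1))`, overall `F` with `(k, n−k−1)` degrees of freedom and
its tail probability.  For simple fits the identity `F = r²(n−2)/(1−r²)`
holds by construction and is asserted.  The five-predictor multilinear
design (E_DABC, E_DM2, E_DHM, E_DM2*, E_DM3*) is strongly collinear on
benzenoids — the predictors are near-affine transforms of one another — so
individual coefficients are ill-determined (huge, opposite-signed) while
r/SE/F are stable; each fit carries a condition-number diagnostic and the
meaningful comparison surface is r/SE/F, never the coefficient vector.

## Scope and limitations

* Exact enumeration is exponential in the worst case; the package targets
  chemical-graph sizes (default cap 32 vertices, overridable).  No
  approximate or heuristic enumeration is provided.
* The catalog covers the 29 built-in benzenoids; arbitrary molecules enter
  via edge-list files or ring-fusion specs, not SMILES/SDF (no chemistry
  perception of any kind is performed).
* Degree-based, eccentricity-based, or Ve-degree entropies from the wider
  literature are not implemented; neither are the classical
  (vertex-degree) versions of the ten indices.
* The QSPR layer is descriptive OLS, as is conventional for this class of
  analysis: no cross-validation, variable selection, or nonlinear models.
* The random-graph generator exists solely to exercise the enumerator
  against the oracle in tests; it makes no attempt to emulate chemical
  graphs (no degree cap, no bipartiteness), which is intentional — the
  enumerator's correctness claim is for arbitrary connected graphs.
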