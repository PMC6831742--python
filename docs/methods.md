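# Methods

This note records the models, conventions and numerical choices behind
chargekit, and what the synthetic study does and does not demonstrate.

## Molecular graphs

Molecules are undirected graphs: atoms (restricted to C, H, N, O, P, S,
F, Cl, Br, I) are vertices, bonds are edges, with optional Cartesian
coordinates in Å. Graph invariants are enforced at construction: no
self-loops or duplicate edges, and per-atom bond-order sums bounded by
hard valence caps (C 4, N 4, O 2, H 1, P 5, S 6, halogens 1).

**Bond perception.** PDB input without CONECT records gets bonds from
geometry: atoms i, j are bonded iff 0.4 Å ≤ d(i,j) ≤ r_cov(i) +
r_cov(j) + 0.45 Å, with standard single-bond covalent radii (C 0.76,
H 0.31, N 0.71, O 0.66, P 1.07, S 1.05, F 0.57, Cl 1.02, Br 1.20,
I 1.39 Å). The 0.4 Å floor rejects steric-clash artifacts. Candidates
are accepted shortest-first; bonds that would exceed a valence cap are
dropped. Perceived bonds are all order 1 and the molecule is flagged
`orders_reliable = False`, which switches carbon hybridization to its
geometric fallback.

**Ring perception.** Rings are the fundamental cycle basis of a DFS
spanning tree rooted at atom 0, children visited in index order. Each
non-tree edge closes exactly one ring (the tree path between its
endpoints), so the basis size is exactly |E| − |V| + C. This is *not*
the smallest-set-of-smallest-rings: in fused systems a basis ring can
be larger than the chemist's perceived ring. The choice is deliberate —
a deterministic, provably sized construction directly tied to the DFS —
and the per-atom ring statistics (count, min/max size, fused-system
size) expose both counts and sizes so downstream features tolerate
either reading. Rings sharing at least one atom are merged
transitively into ring systems.

**SMILES subset and 3D fallback.** The SMILES reader covers
organic-subset and bracket atoms, aromatic lowercase c/n/o/s/p,
explicit bonds `- = # :`, branches and ring closures; stereochemistry
is rejected, not ignored. Implicit hydrogens fill default valences
(aromatic bonds count 1.5). Because radial features need coordinates,
SMILES input gets a deterministic breadth-first embedding: every bond
is placed at 1.5 Å along the template direction (tetrahedral-first set
of 14 unit vectors) farthest from directions already used at the parent
atom. Chains therefore come out straight and rings are generally not
closed metrically. The embedding is a geometry stand-in sufficient for
coarse radial environment counts — it is not a conformer — and such
molecules are flagged `coords_approximate`.

## The 61-feature encoding

Each atom maps to a fixed 61-slot vector; the schema (names and order)
is immutable and hashed, and models refuse tables encoded under a
different schema. Layout: element one-hot (slots 1–10), carbon
hybridization one-hot sp/sp2/sp3 (11–13), ring block — in-ring flag,
ring count, min/max ring size, fused-system ring and atom counts
(14–19), level-1 neighbor element counts (20–29), degree (30), level-2
neighbor element counts with shortest-path semantics (31–40), radial
counts: three search radii × five element bins {C, N, O, other-heavy, H}
(41–55), single/double/triple bond counts (56–58), aromatic-bond flag
(59), formal charge (60), molecule heavy-atom count (61).

Default radii are 2.0 / 4.0 / 6.0 Å — bonded shell, second shell, and
through-space environment at typical organic geometry — and are
configurable. Radial counts are cumulative in the radius, hence
monotone across the triple. The distance comparison carries a 1e-9
slack so counts are stable under rigid-body transforms even when a
distance sits exactly on a radius (straight embedded chains place
atoms at exact multiples of 1.5 Å). Carbon hybridization uses bond
orders when they are reliable (any triple bond → sp, any double or
aromatic → sp2, else sp3) and falls back to geometry otherwise
(two neighbors at ≥ 155° → sp, degree 3 → sp2, else sp3).

Whole-molecule encoding uses a vectorized path (distance matrix against
element one-hots, shared ring info and adjacency) that agrees exactly,
row by row, with the per-atom reference implementation; the agreement is
itself under test.

## Charge models and metrics

One regressor per element, fitted only on that element's rows (at least
10 labeled rows required). Defaults follow common practice for this
task: random forest with 500 trees, distance-weighted k-nearest
neighbors with k = 7 and Minkowski order 2, and ordinary least squares
as the baseline; all seeded. The train:test split is a uniform random
permutation with p_train = 0.2 — the literal reading of a 1:4
train:test ratio — configurable, and unstratified.

Metrics: RMSE in units of e; NRMSE = RMSE normalized by the range of
the true values, in percent; R² is the squared Pearson correlation,
with the coefficient of determination reported alongside (the two
diverge for biased predictors; Pearson² is the headline number).
Cross-element summaries are unweighted means. All three metrics are
verified against independent direct-summation implementations to 1e-12.

Model bundles persist as a JSON manifest (element, algorithm,
hyperparameters, schema hash, seed, payload name) plus one joblib
payload per element; loading refuses a bundle whose schema hash differs
from the running encoder's.

## Charge post-processing

For united-atom force fields, every hydrogen bonded to a carbon
(nonpolar by the GROMOS convention) is removed and its charge added to
that carbon; hydrogens on N/O/S are polar and kept. The merge conserves
total charge exactly. Predicted charges rarely sum to the intended
integer total, so the excess (net − target) is removed by an equal
per-atom shift — idempotent and difference-preserving; the default
target is the sum of formal charges. PQR output writes charges with 12
decimals so the adjusted net total survives serialization to well
below 1e-9; GROMOS topology emission (bonded terms, charge groups) is
out of scope.

## Fingerprints

Dataset diversity is measured with exact linear path fragments: every
simple path of 2–7 heavy atoms, rendered as element symbols joined by
bond marks (`- = # :`) and canonicalized as the lexicographically
smaller reading direction. Sets are exact (no hashing), so Tanimoto
coefficients |A∩B|/|A∪B| carry no collision noise; hashed-bitvector
implementations of the same fragment definition differ only through
collisions. Simple paths only — ring-closure bonds appear in fragments
but a fragment never revisits an atom.

## Synthetic corpus and charge oracle

The generator emulates a diverse small-molecule screening corpus at
desk scale: 5–25 heavy atoms per molecule (drug-like range), heavy
elements drawn with carbon-dominated weights (C 0.70, O 0.13, N 0.08,
S 0.03, F 0.02, Cl 0.02, P 0.01, Br 0.005, I 0.005 — an organic
library's mix), grown as a random tree under valence caps with
occasional double bonds (p = 0.15 per new bond), then with probability
0.6 one or two ring closures between valence-available atoms at graph
distance 3–6 (4–7-membered rings), hydrogens to fill default valences,
and the deterministic embedding for coordinates. Saturated dead-end
draws are retried; generation is reproducible per (seed, index).

Charge labels come from a damped electronegativity-equalization
scheme. Starting from q = 0, iteration k = 1..6 transfers, along every
bond (i, j),

    dq = 0.5^k · (χ_eff(j) − χ_eff(i)) / 3 · (2 / (deg_i + deg_j))²

from the more to the less electronegative side (the less
electronegative atom becomes more positive), with Pauling χ⁰ and
χ_eff(a) = χ⁰(a) · (1 + q_a)². The quadratic charge feedback makes
transfers self-limiting, and the degree attenuation (a hardness-style
weight) couples each transfer to the bonded environment of both
partners. Both couplings are essential to the oracle's role as a
*nonlinear* learning target: with a static χ the label would collapse
to a linear function of the level-1 neighbor counts, which ordinary
least squares recovers exactly and which therefore could not
discriminate between model families. Transfers are pairwise
antisymmetric, so total charge is conserved (the float sum is ~1e-16;
tests assert 1e-12). The oracle is a synthetic labeler with the three
properties the study needs — deterministic, graph-local and
charge-conserving — not a reproduction of any published charge scheme.

**What the synthetic study shows, and what it does not.** Passing the
recovery study shows the pipeline is self-consistent: the 61 features
carry enough local information to recover a graph-local charge
function, the per-element routing and splitting are sound, and the
model-family ordering (forest over linear baseline) holds for a
nonlinear target. It does *not* show that real reference charges —
which reflect database lookups, geometry optimization and
quantum-chemical refinement — are equally learnable, nor that the
synthetic chemical space matches any real screening library.

## Study sizes and numerical conventions

The oracle-recovery study generates molecules in batches of 2,500
until every target element (C, H, N, O) has enough atoms that the 1:4
split leaves ≥ 4,000 in the training part; nitrogen, the scarcest,
sets the corpus at roughly 20,000 molecules (~680,000 atoms). Training
rows are capped at 4,500 and held-out test rows at 40,000 per element
(seed-deterministic heads of the shuffled split) to bound
random-forest cost; metrics are insensitive to the test-row cap.
Encoding-contract and conservation sweeps use 1,000 molecules;
diversity summaries use 200 (19,900 pairs).

Degenerate inputs are rejected rather than patched: empty molecules,
zero-range NRMSE denominators, constant inputs to R², hydrogens with
zero bonds at the merge step, splits with fewer than five rows. Ties
in bond perception are broken by (distance, index order); all iteration
orders are index-deterministic, so every artifact of a run — feature
CSVs, model manifests, PQR files — is byte-stable for a fixed seed.

## Known limitations

* No aromaticity model is inferred; aromatic flags come only from the
  input format (SDF order-4 bonds, lowercase SMILES atoms).
* The SMILES reader is a connectivity subset: no stereochemistry,
  isotopes, or multi-component dot notation.
* The embedding is not a conformer generator; radial features from
  SMILES input describe an idealized, often self-overlapping geometry.
* Basis rings are not SSSR; ring-size features in fused systems can
  exceed the smallest chemical ring.
* Charges from the bundled models are only as good as their training
  labels; the shipped study trains on the synthetic oracle, so models
  intended for production use must be retrained on reference charges.
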