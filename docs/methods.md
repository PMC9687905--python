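# Methods

## Structure preparation

Input is fixed-column PDB text. Only the first MODEL of multi-model (NMR)
files is read; when several chains are present the caller selects one, with
the first chain in the file as the default. Preparation removes waters,
HETATM ligands and ions, nonstandard residues (dropped with a warning
rather than remapped — e.g. MSE), every hydrogen/deuterium, and for
alternate locations keeps the highest-occupancy conformer (ties go to
altloc `A`). Coordinates are Cartesian angstroms throughout; crystal
symmetry and symmetry mates are not considered.

Hydrogens are then rebuilt internally at idealized covalent geometry so
that every structure enters bond detection uniformly protonated, whatever
was or was not solved experimentally. Placement rules:

- **sp2 in-plane** (backbone amide, Asn/Gln amide, Arg guanidinium, His
  NE2, Trp NE1): the hydrogen lies in the plane of the two heavy-atom
  neighbors, along the external bisector; amide N–H for residue *i* sits in
  the C(i−1)–N–CA plane.
- **sp3 staggered** (Lys NZ, N-terminal amine): three hydrogens at
  tetrahedral geometry, staggered against the preceding bond.
- **Rotatable hydroxyls** (Ser/Thr/Tyr): one hydrogen at the staggered
  torsion (of 60°/180°/300°) that maximizes clearance from the other atoms
  of the residue. These positions satisfy the covalent constraints but are
  one arbitrary choice out of a rotamer continuum; bond detection treats
  them like any other donor hydrogen.

Bond lengths are N–H 1.00 Å and O–H 0.96 Å; every placed hydrogen records
its parent heavy atom. Residues missing the frame atoms needed for a
placement have that hydrogen skipped with a warning. Protonation states
assume pH ≈ 7: Asp/Glu deprotonated (acceptors only), Lys/Arg protonated,
His neutral with the NE2–H tautomer (ND1 accepts, NE2 donates). Proline
contributes no amide hydrogen, and the N-terminal convention is applied to
any residue whose predecessor (in file order, same chain) lacks a backbone
C. pKa calculation and Asn/Gln/His flip optimization are out of scope.
Pre-protonated input (e.g. from an external protonation tool) bypasses
placement via `--pre-protonated`; hydrogens are then attached to the
nearest heavy atom within 1.3 Å.

## Donor/acceptor roles and bond criteria

The role table lives in `src/hbgraph/data/roles.yaml` and can be edited
without code changes. Donors: backbone N (except proline), Arg NE/NH1/NH2,
Lys NZ, His NE2, Trp NE1, Asn ND2, Gln NE2, Ser OG, Thr OG1, Tyr OH, and
the N-terminal amine. Acceptors: backbone O and OXT, Asp OD1/OD2, Glu
OE1/OE2, Asn OD1, Gln OE1, His ND1, Ser OG, Thr OG1, Tyr OH, Met SD.
Hydroxyl oxygens are both donor and acceptor. An acceptor's antecedents are
its covalently bonded heavy atoms (backbone O→C, carboxylate O→CG/CD, His
ND1→CG and CE1, Met SD→CG and CE); with several antecedents, a bond is
accepted if the criteria hold for any one of them, and likewise for
multiple donor hydrogens.

A candidate D/H/A/AA passes when d(D,A) ≤ 3.9 Å, d(H,A) ≤ 2.5 Å, and each
of ∠D–H–A, ∠H–A–AA, ∠D–A–AA strictly exceeds 90° (the middle atom is the
vertex). Distance bounds are inclusive, angle bounds strict; candidates
with coincident atoms (undefined angles) are rejected with a degenerate
flag. Same-residue donor–acceptor pairs are excluded; sequence-adjacent
pairs are *not* excluded — only the geometric criteria decide. All five
measurements are stored on every emitted bond so the decision can be
re-audited from the graph file alone.

The neighbor search bins acceptors into a cell list with 3.9 Å cells; each
donor queries the 27 surrounding cells (closed-ball convention, wider
shells for larger radii). An exhaustive all-pairs search with the same
contract serves as the test oracle; the two must agree exactly.

Energy-based scoring, water-mediated bonds, salt-bridge annotation and
π-interactions are non-goals.

## Molecular graphs

Nodes are all role atoms, bonded or not — singletons stay in the graph with
degree 0. Each donor–acceptor pair contributes one undirected edge no
matter how many H/AA combinations pass. Coordinate-free graphs weight every
edge 1.0; coordinate-based graphs use the D–A distance in Å as-is (no
inversion or kernel — the two modes deliberately share edge sets so that
any performance difference is attributable to the weights). Graphs
serialize to a single JSON document or to node/edge TSV tables.

## GCN embedding and classifier

Input features are the one-hot role encoding, columns fixed as (donor,
acceptor, both). Each layer aggregates with Â = D^(−1/2)(A+I)D^(−1/2)
(degrees computed on A+I, so singletons are well defined; for weighted
graphs the degrees are weighted sums) and transforms with a shared weight
matrix followed by ReLU. Defaults: L = 3 layers, 64 units per layer. The
activation and widths are package conventions, exposed as parameters.
Matrices are dense — graphs here have at most ~1000 nodes.

Training broadcasts each graph's class label to all of its nodes and
minimizes the node-level cross-entropy over the GCN weights and a linear
classification matrix Θ on the concatenated per-node features, using Adam
(standard moment decays, lr 1e−3 by default, batch size 4 graphs, 50
epochs). This node-level objective exploits within-graph substructure; the
graph-level decision is then made by a logistic-regression head (L2
penalty, unit inverse regularization strength, lbfgs) refit on the
mean-pooled embeddings — Θ is used only to shape the representation during
training and is discarded for prediction. With `concat=False` the pooled
feature is the last layer alone (the ablation mode). `epochs=0` returns the
initialized network with the head fit on untrained embeddings, which is a
useful random-features baseline.

Mean pooling makes the embedding invariant to node order and node count;
the invariance is exact up to floating-point associativity and is tested at
1e−6 absolute in double precision. Forward/backward passes are implemented
directly in numpy (the model is small enough that an autodiff framework
would add nothing but a dependency) and the gradients are verified against
central finite differences in the test suite.

The estimator `HBCompareClassifier` follows the scikit-learn protocol
(`fit`/`predict`/`predict_proba`/`get_params`, fitted attributes with
trailing underscores), so it composes with sklearn model-selection
utilities; `train_gcn`/`predict`/`tune_hyperparams`/`evaluate` are thin
functional wrappers.

## Evaluation protocol

Each dataset is split per class at 4:1 (test share rounded to nearest, at
least one test member per class). `evaluate` repeats this for `n_splits`
seeded splits (default 10) and reports mean ± standard deviation of
accuracy (correct/total, recomputed from stored confusion counts), macro
F1, and AUC-ROC (one-vs-rest macro for multi-class; plain AUC for binary).
Macro averaging and one-vs-rest are conventions chosen for robustness to
mild class imbalance. Optional tuning grid-searches lr ∈ {5e−4, 1e−4,
5e−3, 1e−3}, batch ∈ {1, 2, 4, 8, 16} and L ∈ 1..6 with stratified 5-fold
CV on the training portion only; the default selection keys on the single
best fold's accuracy (ties toward better mean), with mean-across-folds
selection available via `selection="mean"`. Test indices never reach
tuning or training, which the suite asserts by instrumentation. A master
seed derives all split/fold/init seeds through a fixed integer hash, so any
single split is reproducible in isolation and all derived seeds stay below
2³¹.

## Synthetic fixtures

- **Ideal helix**: poly-Ala backbone built by natural-extension-reference-
  frame chaining from φ = −57°, ψ = −47°, ω = 180° and textbook bond
  lengths/angles, carbonyl O in the peptide plane. This geometry places
  O(i)···N(i+4) at ≈ 2.9–3.0 Å with near-linear N–H···O, inside the
  feasibility envelope, so the complete i→i+4 ladder is a known answer for
  end-to-end detection tests.
- **Random structures**: rigid ideal-geometry residues (Ala/Gly/Ser/Asn/
  Lys/Asp) at random positions and orientations with ≥ 1.5 Å inter-atomic
  separation, in a box sized for a heavy-atom density of 0.04 Å⁻³ — dense
  enough that bonds occur, sparse enough that placement succeeds. The
  arrangement is deliberately non-physical between residues; it exists to
  exercise every code path of the search, not to model proteins.
- **Graph families**: classes defined by a node-count range, an edge
  probability over donor→acceptor-compatible pairs, and a role
  distribution. Classes share the role distribution (checked by a
  chi-square homogeneity test at generation, recorded in metadata), so
  classifier signal can come only from topology — mirroring the scientific
  claim that topology alone distinguishes subfamilies. The default
  benchmark uses edge densities 0.05 vs 0.15 with 60 graphs per class of
  40–70 nodes.

What passing on these fixtures does **not** show: robustness to real
crystallographic noise, missing atoms/residues, chain breaks, alternate
protonation states, or subfamily differences far subtler than a 3× density
gap. Real subfamily datasets require curated PDB downloads and are outside
the test scope.

## Numerical choices and degenerate inputs

- Distance comparisons are plain `<=` in double precision; the lattice and
  brute-force searches use the same convention so they agree exactly.
- Angle computations clamp cosines to [−1, 1]; arms shorter than 1e−9 Å
  are degenerate and rejected.
- Adjacency symmetry is validated before normalization; asymmetric input
  is an error, not silently symmetrized.
- Empty graphs cannot be pooled or trained on (explicit errors); edgeless
  graphs are fine (Â = I).
- Grid-search ties break toward better mean fold accuracy, then grid
  order, making tuning deterministic per seed.

## Problem sizes used in verification

The shipped verification runs use 100 random structures of 30–80 residues
for the search oracle, 500-atom clouds with 100 queries for the lattice,
20 graphs × 100 permutations for invariance, and the 60-graphs-per-class
two-density family with 10 splits for classification — sizes at which every
check runs in seconds to a few minutes on a single CPU while exercising the
full pipeline.

## Known limitations

- Hydroxyl hydrogen torsions are a deterministic convention; detected bond
  sets involving Ser/Thr/Tyr donors can differ from those produced by other
  protonation tools.
- His tautomer/flip states are fixed, not optimized.
- The first-model/first-chain convention for NMR ensembles and multi-chain
  entries is a package convention, not a statement about how any external
  dataset was curated.
- Coordinate-based weights enter the GCN raw (larger distance ⇒ larger
  weight); no claim is made that this weighting is optimal, only that it
  isolates the contribution of coordinates relative to the binary mode.
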