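# Methods

## Problem setting

A ternary complex is a two-protein-one-ligand assembly: an E3 ligase
(protein1), a degrader small molecule, and a protein of interest (protein2).
The package predicts the assembled structure from the monomers. Two modes of
action are supported:

* **protac** — the bifunctional degrader has an anchor (binds the E3) and a
  warhead (binds the POI) joined by a linker. Anchor and warhead binding
  poses are known from unbound binary structures, so the pocket point pairs
  are inputs, and the network's job is the ligand (linker) conformation and
  the confidence estimate. Forty ligand conformers are sampled and ranked.
* **mgd** — molecular glues have no unbound protocol; all four pocket point
  sets are predicted by the decoder from a single conformer, with the
  protein inputs re-posed by a seeded random rigid motion so inference never
  sees the answer pose.

## Architecture and its invariances

**Featurization.** Ligands are atom graphs: 10 chemistry features per atom
(atomic number, chirality tag, total degree, formal charge, implicit and
total hydrogen counts, radical electrons, hybridization code, aromaticity,
ring membership), bidirectional edges for atom pairs closer than 4 Å
(an otherwise isolated atom is connected to its nearest neighbour), edge
features = 16 Gaussian radial-basis bins over [0, cutoff] plus a bonded
flag and bond order. Proteins are residue graphs anchored at C\alpha with a
learned 21-type embedding (20 canonical + UNK), symmetrized 10-nearest-
neighbour edges capped at 30 Å. Angle-based edge features are omitted: the
source material names them without an encoding, and distances suffice for
every contract tested here. Pocket membership enters as a learned hidden
vector summed onto masked nodes.

**Encoder.** M layers alternate intra-graph message passing, ternary
inter-graph attention, an equivariant coordinate update, and a convex
feature update with trade-off β (default 0.5). Protein1 and protein2 share
parameters (one parameter set serves both), making the network symmetric
under protein exchange; training adds explicit swap augmentation. The
coordinate update moves each node along unit directions to its own-graph
neighbours with invariant scalar magnitudes (ε = 1e-8 guards coincident
points), so outputs are equivariant under *independent* rigid motions of
each graph — the property the acceptance suite asserts at 1e-4 relative
(realized deviations are ~1e-14). Cross-graph attention sees no geometry at
all, so embeddings are exactly invariant.

The geometric constraint Ψ defaults to per-node displacement-norm clipping
(cap 5 Å per layer); a `ligand-distance-projection` mode instead relaxes
ligand bonded distances toward the reference conformer (three half-step
sweeps, equivariant). Defaults M = 5, hidden 64; the reduced test
configuration is M = 2, hidden 16, one decoder layer.

**Decoder.** Learned pocket-point queries (K = 8 per set; K ≥ 3 is required
by rigid alignment) plus one PAE query attend over the concatenation of the
encoder's final embeddings, each node tagged with a learned graph-identity
embedding. Each attention step carries a residual connection. This is a
deliberate design decision: a residual-free stack of row-stochastic
attentions is an averaging operator, and in practice the K query rows
collapse onto a single row — a symmetric fixed point that gradient descent
cannot leave, which makes pocket-point learning impossible. With residuals
the same equations train reliably. Attention is single-head by default
(head count configurable); each of the four pocket sets has its own
extraction attention, and pocket points are convex combinations of the
source graph's coordinates — equivariant because the weights are
coordinate-free. The PAE head is an MLP with softplus output (non-negative,
in Å). A `NaivePocketDecoder` baseline (top-attended-node pooling) is kept
as an ablation hook.

**Assembly.** Kabsch superposition via SVD with determinant correction;
point correspondence is index-wise; collinear sources raise a degeneracy
error. No post-assembly relaxation — clashed poses are scored as-is.

## Training objective

Six unweighted terms (weights configurable):

1. `l_lig` — MSE between the **assembled** ligand and the native ligand.
   Because the encoder is equivariant to the ligand's input pose, a pose-
   sensitive loss on raw encoder coordinates could not vanish across random
   input poses; the assembled coordinates are the model's actual output and
   make the term minimizable.
2. `l_kabsch_lig` — MSE after optimal superposition (conformation only).
3. `l_ot1`, `l_ot2` — exact optimal-transport losses for the two pocket
   pairs (Hungarian assignment, uniform weights; mean squared cost). Each
   pair shares one *joint* assignment so that the two sets' row
   correspondence stays consistent for Kabsch. Targets are **interface
   midpoints**: each moving-entity pocket point paired with its nearest
   protein1 residue, supervised in protein1's frame for the p1-side set and
   mapped through the known training displacement for the attached set.
   Midpoints are the only frame-consistent choice for an equivariant
   network, and they nearly halve the distance each set must reach outside
   its graph's convex hull.
4. `l_intersection` — hinge-squared clearance penalty: 2 Å where a ligand
   atom is involved, 4 Å residue–residue, matching the curation cutoffs. It
   is zero on any clash-free pose, including the native fixture.
5. `l_pae` — L1 between the PAE and the realized RMSD of assembled
   protein2.

Rotations and translations inside losses and training-time assembly are
computed by SVD on detached values; gradients flow through the transformed
coordinates but not through R, t (a standard stable approximation).
Degenerate (collapsed) pocket sets early in training fall back to an
identity transform rather than aborting.

One training step: optional p1/p2 swap (probability 0.5), a conformer from
the pre-generated pool (50 for chemical ligands; synthetic point ligands
have a single native conformation), translation of protein1's centroid to
the origin, random rigid displacement of the ligand and protein2 (uniform
rotation, translation in a ±5 Å box), Gaussian noise at level 2
(σ = 0.02·level on coordinates and float features), forward pass, loss,
Adam update (default lr 1e-4, global gradient-norm clip 1.0). Everything is
reproducible from one seed.

## Tiny-overfit protocol

The single-complex recovery experiment (reduced model, ≤ 500 steps) uses
lr 5e-3 halved every 150 steps, Polyak averaging of the last 150 steps, and
swap augmentation off (a single-complex fit has no symmetry to learn). The
objective is non-convex and roughly a quarter of initialisations stall in a
partially collapsed pocket optimum, so several random restarts are fitted
(each within the step budget) and the winner is chosen by the mean OT
pocket loss over the final 20 *training* steps — model selection on the
training objective only. The selected run reduces the total loss by > 95%
and reassembles protein2 to ~0.1–0.5 Å interface RMSD on fresh random
displacements.

## Synthetic fixtures

`ternadock.synthetic` generates the study systems: two C\alpha-trace
α-helices (2.3 Å radius, 1.5 Å rise, 100°/residue; residue types assigned
cyclically so every residue of a 20-mer is uniquely typed) bridged by a
12-atom carbon coil, with ≥ 3 sub-4 Å ligand contacts per protein, no
inter-entity pair under 2 Å, and a tilted contact arm giving direct
protein–protein residue pairs in the 4–5 Å window (native contacts for
Fnat without violating the 4 Å clearance of the intersection term). The
generator returns exact pocket correspondences and the native pose, which
is what makes the assembly round trip exact (< 1e-4 Å, realized ~1e-14)
and the planted-curation counts deterministic. Planted violations
(resolution, R-free, contacts, clash, buffer code, chain length) each trip
exactly one gate.

What the fixtures do **not** emulate: real folds, side chains, ligand
chemistry beyond a bonded chain, crystallographic noise, or the size and
diversity of a curated corpus. Passing tests therefore demonstrate the
correctness of the machinery — equivariance, exact assembly, objective
behaviour, metric definitions, leakage-free splitting — not benchmark
accuracy on experimental degrader complexes.

## Curation, splitting, sampling

Quality gate: X-ray method, resolution ≤ 3.5 Å, R-free ≤ 0.26 (both
inclusive), with a whitelist that overrides the quality and clash gates
only — never the buffer-ligand gate. Geometry gates: ≥ 3 ligand atoms
within 4 Å (inclusive) of protein atoms; no inter-entity heavy-atom pair
strictly under 2 Å; ten crystallization-buffer codes excluded; chain
minimum 7 residues in protac corpora and 3 in mgd corpora. Filters are
independent predicates, so the surviving set is order-independent.

Clustering is greedy incremental at 50% identity (global alignment,
matches over alignment length, Biopython aligner); the contract is the
partition property, not the tool, and a large-corpus deployment could swap
in a dedicated clustering program behind the same interface. Splitting
removes every cluster touching a test entry from training; non-test members
are kept for validation only when their ligand's Tanimoto similarity
(1024-bit Morgan fingerprints, radius 2) to every test ligand is below
0.85. Training entries are drawn cluster-uniformly, representative with
probability 0.2, otherwise a uniform member.

## Metrics

DockQ uses the standard constants (5 Å contact, 10 Å interface, 8.5/1.5 Å
scales); CAPRI classes are the DockQ bands 0.23/0.49/0.80. The receptor
for LRMS is the larger protein; backbone falls back to C\alpha for trace
models. Acceptable rank returns the first 1-based index with
DockQ ≥ 0.23, sentinel 41 otherwise. SASA is Shrake–Rupley with a
golden-spiral sampling (960 points, probe 1.4 Å) over a united-atom radius
table; BSA(A,B) = SASA(A) + SASA(B) − SASA(A∪B), totalled over the three
entity pairs, with a helper averaging the five lowest-PAE predictions.
Agreement with other SASA implementations is approximate (radius tables
differ); the test suite cross-checks against biotite's implementation at a
15% tolerance and the analytic sphere at 1%.

## Numerical notes

Float64 throughout. Softmax uses a detached max-shift; softplus and its
gradient are computed in overflow-safe form. The Kabsch degeneracy test is
`sv_2 < 1e-8 · ‖A‖`. RDKit conformer seeds are offset by one internally
because the embedder treats seeds 0 and 1 identically. PAE ties in ranking
break by ascending seed.

## Known limitations

* Encoder coordinate updates move nodes only along own-graph edge
  directions (the literal update rule); absolute ligand docking therefore
  happens at assembly, not in the encoder.
* Per-residue PAE matrices are out of scope; the PAE is one scalar per
  prediction.
* Training is single-sample-per-step (batch_size is reserved); multi-GPU
  and full-corpus training are not implemented.
* The protac-mode assumption that unbound pocket atom indices align 1:1
  with the candidate ligand is accepted as input, as is conventional for
  the unbound evaluation protocol.
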