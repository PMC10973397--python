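# Methods

## Model

pocketforge models the conditional distribution p(**L** | **P**, **I**) of
a ligand **L** (atoms with 3D positions) given a pocket **P** and a
per-protein-atom interaction condition **I** (7 one-hot classes: anion,
cation, H-bond donor, H-bond acceptor, aromatic, hydrophobic,
non-interacting). The distribution is factorized autoregressively over
atom placements; each step predicts the next atom's type (vocabulary
C, N, O, F, P, S, Cl, Br, I, plus STOP) and then, given the type, its
position.

Two positional dummy atoms travel with the partial ligand: the
**center-of-mass dummy** (fixed at the start point) and the
**atom-of-interest dummy** (co-located with the current anchor). They
carry only a flag bit and a position, are treated as ligand nodes during
embedding, and are dropped from all outputs.

**Embedding.** Ligand nodes (element one-hot + dummy flags) and pocket
atoms (element / charge-sign / aromatic / ring blocks with the condition
concatenated) are projected to a shared hidden width and updated by
residual message-passing layers on the graph of all atom pairs within
8 Å. Edge features are Gaussian expansions of interatomic distance
(16 bins over 0–8 Å by default). Raw coordinates never enter the
network, only pairwise distances, so every output is E(3)-invariant by
construction; permutation equivariance over pocket atoms follows from
the scatter-sum aggregation.

Two numerical choices matter here and were found necessary rather than
cosmetic:

* messages are aggregated as a **sum scaled by 1/√degree**. A plain mean
  is count-blind: whether an anchor still has an unplaced bonded
  neighbor is a neighbor-*counting* question, and with mean aggregation
  the decoder demonstrably could not resolve STOP-vs-place states;
* the residual update MLP of each layer is **zero-initialized**, so the
  stack starts as the identity. Without this, sum-style aggregation on
  densely connected complexes diverges at initialization.

**Heads.** Per-anchor type heads (one for ligand anchors, one for pocket
anchors) map (anchor hidden, atom-of-interest hidden, z) to a
log-distribution over the type vocabulary + STOP. Distance heads
additionally receive the committed type one-hot and emit a distribution
over a fixed distance grid (25 Gaussian bins over 0–5 Å by default,
σ = one bin width). Conditioning every head on the atom-of-interest
embedding is what lets an anchor's prediction depend on *where* the next
atom attaches; the atom-of-interest is part of the partial complex, so
this stays within the model's stated information set.

**VAE.** An encoder pools the invariant embeddings of the complete
complex into a diagonal-Gaussian posterior q(z | **L**, **P**, **I**)
(latent width 8 in the desk-scale configuration). At generation time z
is drawn from the standard-normal prior.

## Training

Each epoch traverses every complex along a fresh random trajectory: the
first atom is uniform over the ligand; each later atom is uniform over
the unplaced covalent neighbors of the current anchor; anchors are
re-drawn uniformly after every event; an exhausted anchor receives a
STOP target and retires. Teacher forcing supplies the true partial
complex at every step.

Losses per placement step: cross-entropy of the type target against
every anchor's predicted distribution (averaged within the ligand-anchor
and pocket-anchor sets and summed — the one-hot target makes the literal
forward KL infinite off-support, so cross-entropy is the finite
reading), plus the forward KL of each predicted distance distribution
against the Gaussian-expanded true distance. STOP steps contribute the
type term only. The ELBO adds β·KL(q(z|·) ‖ N(0, I)) with β = 1.

Distance targets are **smoothed with a 5% uniform mixture**. A state
reached by random traversal can admit several next atoms, so a single
sharp Gaussian target is sometimes one mode of a mixture; without
smoothing the forward KL charges ~27 nats (the numerical floor) for any
probability the model correctly spreads across modes, and that noise
dominates training.

Optimization is Adam (default learning rate 1e-3; the desk-scale runs
use 5e-3 decaying linearly to 1e-4, which was needed for the rare
STOP-discrimination states to be memorized cleanly). Ligand-side anchors
include the two dummies at every step, so the anchor set is non-empty at
step one.

## Generation

From a start point (given, or the pocket centroid) the sampler
iterates: embed the partial complex; combine type log-likelihoods as
Σ ligand anchors + λ · Σ pocket anchors (softmax with temperature);
on STOP, retire the anchor; otherwise score a spherical candidate grid
around the anchor — radii 1.1–1.9 Å in 0.1 Å steps, 192 quasi-uniform
directions by default — by the same λ-combination of distance
log-likelihoods (bin lookup at each candidate's distance to each
anchor), mask candidates within 1.2 Å of any existing heavy atom
(excluding the anchor itself; an all-clash step is a dead end and
retires the anchor), and sample one. The anchor is then re-drawn
uniformly from available atoms. Generation ends when no atom is
available or the atom budget is reached; bonds are perceived on the
result.

The pocket coefficient λ is 1 while the anchor is within 4 Å of the
nearest pocket atom, decays linearly, and reaches 0 at 8 Å — the
pocket's vote fades where no short-range interaction is possible. The
same λ applies to type and position.

The candidate grid directions and the initialization noise (translation
σ 0.5 Å; rotation about a random axis with |angle| ~ N(0, 15°), applied
rigidly so internal coordinates are exactly preserved) are expressed in
a local frame built from the pocket geometry (centroid direction +
farthest-atom direction, orthonormalized). Scores are invariant and the
grid co-moves, so a rigid motion of pocket and start point transports
the entire generation — a property the tests exercise directly.

Bond perception connects atoms within 1.25× the covalent-radius sum,
assigns single bonds, patches common formal charges (e.g. tetravalent
N → N⁺), and flags anything RDKit's valence model still rejects;
delegation to the OpenBabel command-line perceiver via an SDF round-trip
is available behind a config switch.

## Interaction profiling

Reference-free conditions come from residue/atom-name template rules for
the standard amino acids (charged groups of Asp/Glu/Lys/Arg, backbone
and side-chain donors/acceptors, the aromatic ring systems of
Phe/Tyr/Trp/His, apolar side-chain carbons), with element-level
fallbacks for non-standard residues. The rule set is a reconstruction
of standard protein chemistry; atoms matching several classes resolve by
the priority anion/cation > donor > acceptor > aromatic > hydrophobic,
on the grounds that charged and directional classes are rarer and more
informative.

Reference-based detection is purely geometric, with config-exposed
thresholds: H-bonds at donor–acceptor heavy-atom distance ≤ 4.1 Å (donor
angle ≥ 100° enforced only when explicit donor hydrogens exist — crystal
structures usually lack them); hydrophobic contacts between apolar
carbons ≤ 4.0 Å; salt bridges between opposite formally charged group
centroids ≤ 5.5 Å; π–π stacking between ring centroids ≤ 5.5 Å with
inter-plane angle ≤ 30° (parallel) or 60–90° (T-shaped). Atom pairs
belonging to opposite charged groups count as salt bridges, never
additionally as H-bonds, keeping the four types disjoint on the fixture
oracles.

Interaction fingerprints allot 4 bits per pocket atom (H-bond,
hydrophobic, salt bridge, π–π, in pocket-atom order). An atom engaged in
several types sets several bits — multi-hot rather than forcing one
class — so no detected contact is discarded. Similarity is the cosine of
two fingerprints for one target, defined as 0 when either vector is
empty.

## Synthetic fixtures and what they do (not) show

The fixture module builds free-floating amino-acid functional-group
clusters with PDB-legal metadata plus 1–8-atom ligands, constructed so
that *exactly* one designed motif is present, with built-in margins
against every other detection cutoff; the expected interaction list is
returned as ground truth and the profiler is required to match it
exactly. Each complex is placed in a random rigid frame derived from its
seed.

Two purpose-built complexes drive the learning tests:

* **overfit complex** — an ALA backbone fragment accepting an H-bond
  from a hexanol-like chain. With a single heteroatom at a chain end,
  the next atom's element is determined by the teacher-forced state at
  almost every step, so teacher-forced type recovery measures
  memorization, not irreducible trajectory ambiguity.
* **twin-site pair** — one pocket with two chemically identical carbonyl
  acceptor sites and two mirrored methanol-like reference ligands. The
  condition (which site's oxygen is marked) is the *only* signal
  distinguishing the sites, so the reference-vs-masked similarity gap
  isolates the effect of conditioning. An earlier design with two
  chemically different sites failed this purpose: the model could read
  the interaction from the pocket elements alone and masking cost
  nothing.

These fixtures are deliberately minimal. They contain no secondary
structure, no water, no protonation ambiguity, no crystallographic
noise, and ligands far below drug size; passing tests demonstrate that
the machinery is correct and that conditioning is causally effective at
this scale, not that the model generalizes to real pockets or produces
drug-like chemistry. Scaffold metrics on generated sets are likewise
degenerate at this molecule size (most generations are acyclic and share
the empty scaffold).

## Desk-scale configuration and problem sizes

`ModelConfig.toy()`: hidden width 48, 3 message layers, latent 8, k = 8
pocket neighbors, 25 distance bins over 0–5 Å, 16 edge bins. Training
runs used by the tests and the acceptance script: 600 epochs on the
single overfit complex and 400 epochs on the twin-site pair (tens of
seconds each on one CPU); generation studies use 50 molecules per
condition per seed across 5 seeds, with 64 candidate directions and a
4-atom budget. The package defaults (hidden 128, 4 layers, latent 64,
k = 16, 50 bins, 192 directions) are sized for larger complexes.

## Known limitations

* Bond-order assignment beyond single bonds relies on RDKit sanitization
  or the optional OpenBabel path; aromatic ring closure is rare at the
  generated-molecule sizes exercised here.
* The reference-free rule set covers the 20 standard residues; exotic
  cofactors fall back to element rules.
* The type combination is a product of per-anchor experts: it sharpens
  toward consensus, which is faithful to the factorization but means
  minority atom types are undersampled when anchors disagree; the
  temperature parameter trades this off.
* Water-mediated interactions, halogen bonds, cation–π and metal
  coordination are out of scope of the four-type profiler.
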