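# Methods

## Problem and model

`geosec` treats secondary-structure assignment as node classification on
a residue graph whose construction uses no primary-sequence information:
whether two residues are joined by an edge, and every feature on that
edge, depends only on inter-atomic distances.  This makes the method
applicable when the chain ordering is unknown — partial models,
fragmented traces, Cα-only output of map-tracing tools.

### Distance-only dihedral cosines

For four points {i−3, i−2, i−1, i}, let α, β, γ be the face angles at
vertex i−2 (between the vectors toward i−3/i−1, i−1/i, and i−3/i).  The
trihedron cosine law gives

cos ω = (cos γ − cos α cos β) / (sin α sin β),

with each face cosine obtained from the planar law of cosines on the six
pairwise distances.  The implementation computes the three face cosines
explicitly and applies the identity; this is algebraically identical to
the fully expanded closed form in terms of the six distances, and the
test suite verifies agreement with the coordinate-based dihedral to
1e−9 over thousands of random configurations.

Only cosines are produced.  The sign of ω is fundamentally unrecoverable
from distances (a configuration and its mirror image share all pairwise
distances), so every downstream feature is a cosine.  One consequence
worth knowing: in cosine space the right-handed helix basin
(φ ≈ −57°) and the left-handed one (φ ≈ +57°) coincide.

Numerical policy: face cosines and cos ω may exceed 1 in magnitude by at
most 1e−9 (rounding) and are clamped; beyond that the distances are
declared non-Euclidean and rejected.  Collinear triples (|sin| = 0 in
the denominator) are degenerate.  Inside featurization, degeneracy and
missing atoms produce *masked* features (sentinel 0 plus a mask bit),
never exceptions, so partial structures survive the pipeline.

### Generalized φ/ψ and the Cα pseudo-dihedral

For an ordered residue pair (k, l):

* cos φ_kl over (C of k, N of l, CA of l, C of l);
* cos ψ_kl over (N of k, CA of k, C of k, N of l).

For l = k+1 in sequence these are exactly the classical φ of l and ψ of
k.  The atom assignment for non-adjacent pairs is a design choice (the
definition has no canonical extension); this convention was picked
because it degenerates to the textbook angles and keeps the sender (k)
in the "previous residue" role, so the message arriving at a node
describes that node's φ as seen from the sender.

On Cα-only structures the pseudo-dihedral Φ_ab places CA(a) and CA(b)
in the inner two positions; the outer positions are the spatially
nearest remaining Cα to CA(a) and then to CA(b).  Distance ties are
broken by residue list index (lower wins) so the choice is
deterministic; this matters only for exactly symmetric synthetic
configurations.

### Residue graph

Residue distance = minimum over retained heavy-atom pairs (CA–CA in Cα
mode).  Method A: k-nearest neighbors (default k = 2), symmetrized by
union — an undirected edge exists if either endpoint selects the other;
union rather than intersection so that no selection is discarded.
Method B: edge iff distance strictly below τ (default 3 Å).  Both
defaults give closely overlapping edge sets on backbone structures.
k-NN ties are broken by residue index.  Sequence-adjacent pairs are
*not* excluded from the candidate set — nothing in the construction
distinguishes them.

Because φ_kl ≠ φ_lk, each undirected edge stores one feature vector per
direction, and every consumer (message passing, node aggregation) reads
the direction oriented toward the receiving node.

Node features are the per-channel mean of unmasked incoming edge
features, optionally concatenated with a 21-way residue-type one-hot
(20 amino acids + UNK; enabled by default).  Isolated nodes get a zero
vector with mask bits cleared.

### FOS baseline

Per-node means of the incident edge feature triple (distance, cos φ,
cos ψ) — ℝ³ — classified by a k-nearest-neighbor majority vote
(Euclidean metric, ties to the smallest class id; backed by
scikit-learn).  A configuration flag appends per-channel variances
(ℝ⁶).  The ℝ³ mean is the default: the mean-plus-variance variant is
retained because neighborhood variances are the natural second
descriptor, but with the tiny (2-edge) neighborhoods of a k = 2 graph
the variance estimates are noisy and did not help.  Defaults for the
classifier: k = 20 on clean inputs, k = 60 under cosine noise (larger
votes smooth the noisier feature space).

### Message-passing classifier

Two edge-conditioned convolution layers.  At layer t:

m_v = Σ_{w∈N(v)} reshape(N_t(e_wv)) · h_w,  h_v ← Θ_t h_v + m_v,

with a ReLU after the first update only.  N_t is a four-layer perceptron
(widths edge_dim → 32 → 32 → 32 → hidden·input, ReLU between layers)
mapping the directed edge feature to a hidden×input matrix — the
"h_w · N(e_vw)" form read as a matrix–vector product, which is what
makes the convolution edge-conditioned.  Readout: hidden → 32 →
n_classes perceptron with softmax.  h⁰ is the aggregated-edge node
feature (± one-hot); initializations are Glorot-uniform from the config
seed.

Training: protein-level 70/30 split (seeded shuffle; residue-level
splits would leak a protein's residues across the boundary),
cross-entropy loss with optional inverse-frequency class weights
(default off — the synthetic classes are roughly balanced and unweighted
training is one fewer moving part), Adam (lr 3e−3), 60 epochs by
default, one graph per gradient step.  The state returned is the best
validation-macro-F1 epoch.  Forward, backward and the optimizer are
plain numpy; gradients were verified against central finite differences.
Everything is deterministic for a fixed seed.

Parameter count at defaults (3-class, all-atom, one-hot on): ~230k,
dominated by the layer-0 filter head (32 → 64·24).  Desk-scale training
(60 proteins ≈ 3500 residues) takes on the order of a minute per 25
epochs on one CPU core.

### Noise channels

* **Distances** (std η₁, Å): Gaussian noise on the off-diagonal entries
  of the 4×4 quadruple distance matrix, followed by PSD repair.  The
  projection operates on *squared* distances — classical double
  centering G = −½ J D J requires squared entries to make G a Gram
  matrix; plain distances are squared on entry and un-squared on return.
  The projection is idempotent and is the identity on valid squared
  Euclidean distance matrices.
* **Cosines** (std η₂, dimensionless): i.i.d. Gaussian noise added to
  cos ω, clamped to [−1, 1] (arccos requires it); masked entries are
  untouched.  This is the channel used in all classifier robustness
  experiments.
* **Face angles** (std in radians): additive noise on (α, β, γ) before
  the trihedron identity — kept as a separate optional channel and not
  used in the main pipeline.

The Monte-Carlo routine reports, per (ω, η₂) condition, both the mean
absolute and the RMS angular error of arccos(clamp(cos ω + ε)).  The two
statistics differ materially: at ω = 90°, η₂ = 0.05, the delta method
gives a mean absolute error of η₂·√(2/π)·(180/π) ≈ 2.28° while the RMS
is η₂·(180/π) ≈ 2.87°; near ω = 0°/180° the arccos is badly conditioned
and both inflate (~1/sin ω).  Across ω ∈ {30°,…,150°} and
η₂ ∈ {0.05, 0.1} the per-condition RMS spans ≈ 2.9–13.2°, i.e. 3–14° at
nearest-degree precision, which is the band quoted for this kind of
noise level; the acceptance script reports the RMS extremes.

### Evaluation

Macro precision/recall divide by the full class count d of the scheme,
so classes absent from a test set contribute 0 — deliberately, to keep
scores comparable across test sets.  F1 is the harmonic mean of macro P
and macro R (not the mean of per-class F1).  Element segmentation is by
maximal runs of equal labels; the boundary-error profile assigns each
misclassified residue inside a true α/β element its distance-to-
extremity w (extremity = 1), and `trim_element_limits` relabels the
outer w residues of each element as Other (elements shorter than 2w+1
dissolve) for limit-excluded re-scoring.

Label schemes collapse DSSP states with α = {H} and β = {E} only (G, I,
B go to Other).  DSSP itself never states a unique collapse; this strict
rule is the most common convention, and the mapping tables are arguments
of `map_labels` for anyone wanting G/I counted as helix.

## Synthetic data: what it emulates and what it does not

The generator grows backbones by natural-extension (NeRF) placement with
ideal bond lengths (N–CA 1.46, CA–C 1.52, C–N 1.33, C–O 1.23 Å), ideal
angles, trans peptide bonds (ω = 180°), and per-residue (φ, ψ) of
−57/−47° (α), −139/+135° (β), or coil drawn as φ ~ −U(95°, 150°),
ψ ~ U(−30°, 30°).  The coil region was chosen in *cosine* space:
because cosines are even, the usual "anywhere outside the α/β basins"
rule fails (e.g. the left-handed region φ ≈ +57° collides with the α
basin), so coil occupies a region whose (cos φ, cos ψ) box is disjoint
from both.  Gaussian jitter (default 5°, the generator's stand-in for
coordinate error and thermal spread) is added to the dihedrals; the
three classes remain separable up to ≈ 10° jitter.  Residue types are
drawn uniformly — carrying no class information, unlike real sequences.

Datasets default to 60 proteins of 40–80 residues, segment classes drawn
at weights (0.4, 0.3, 0.3) with lengths α 6–14, β 4–8, coil 3–8 —
roughly the element-length statistics of globular proteins.

Not emulated: side chains, inter-strand hydrogen bonding (strands are
isolated, not paired into sheets), and — most consequentially — compact
tertiary folds.  Synthetic chains are extended, so nearly all graph
edges join sequence-adjacent residues.  Passing label-recovery tests on
this data demonstrates that the geometric features separate the classes
and that the models learn them; it does *not* demonstrate performance on
real structures, where long-range contact edges are abundant and
reference labels are themselves model outputs.

One measured consequence: robustness to residue ablation is weaker here
than the method shows on real data.  On compact folds, removing a
residue leaves its neighbors with redundant spatial contacts; on an
extended synthetic chain it always severs local connectivity and creates
gap edges whose distances lie outside the training feature
distribution.  With the default study (60 proteins, jitter 5°, k = 2),
held-out macro F1 drops ≈ 2.7 / 6.0 / 10.8 / 13.3 points at
5 / 10 / 15 / 20 % ablation — under 10 points through 10 % but not at
20 %.  The corresponding robustness test encodes the sub-10-point
expectation at both 10 % and 20 % and is expected to fail at 20 % on
synthetic data; the limitation is the generator's topology, not the
classifier.

## Known limitations

* Cosine-only features cannot distinguish mirror-image conformations.
* The Cα pseudo-dihedral depends on nearest-neighbor anchor choices that
  can switch discontinuously under coordinate noise.
* FOS features of isolated nodes are a zero sentinel, indistinguishable
  from a genuine zero-mean neighborhood; the mask is available but the
  k-NN baseline does not consume it.
* Training is single-threaded, full-batch-per-graph numpy; adequate at
  desk scale, not engineered for thousands of structures.
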