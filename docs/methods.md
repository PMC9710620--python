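# Methods

This note documents the models, numerical conventions and design choices
behind the package, and states what the synthetic experiments do and do not
establish about real data.

## Diffusion states and DSD

The single-network embedding is the diffusion state He_t(u): entry *j* is
the expected number of visits to node *j* by a simple degree-normalized
random walk of length *t* started at *u*.  Two conventions are fixed here:

* **The start counts as one visit** (the k = 0 term of He_t = Σ_{k≤t} P^k),
  so He_0 = I, DSD is well defined at t = 0, and each row of He_t sums to
  t + 1.  The choice changes He but cancels in all DSD differences for
  t ≥ 1, so it matters only to code that consumes raw diffusion states.
* **Converged diffusion states.**  He_t itself diverges entrywise (visits
  accumulate along the stationary distribution π = deg/Σdeg); only row
  *differences* converge.  The converged object is computed spectrally:
  with S = D^{-1/2} A D^{-1/2} = U diag(λ) Uᵀ, the geometric sums
  Σ_{k≤t} λ^k tend to 1/(1 − λ) for |λ| < 1; the λ = 1 (stationary)
  component is row-constant and set to 0.  On bipartite graphs the walk has
  period 2 and λ = −1 contributes an oscillating term with no limit; it is
  assigned its even-t subsequence limit (1), so the closed form matches a
  long even-step iteration — the independent oracle it is tested against.
  A lazy-walk option (self-probability 1/2) is available when a strictly
  convergent walk is preferred on bipartite-ish graphs.

DSD is the L1 distance between diffusion-state rows.  Metric axioms
(including the triangle inequality, exhaustively over triples at 1e-9) are
asserted in the test suite for both fixed-t and converged variants.

## Landmarks

Landmarks are reciprocal best hits from two precomputed BLAST-tabular
files.  The best hit per query maximizes bitscore, with ties broken by
percent identity and then lexicographic subject id — bitscore rather than
e-value because minimal hit tables may omit e-values.  The coverage and
identity thresholds (q, p) are applied to *both* direction rows of a pair,
the stricter and reproducible reading of thresholding "reciprocal best
hits" as pairs.  Defaults (90, 85) suit closely related species; a relaxed
preset (75, 50) is provided for distant pairs where the strict thresholds
leave too few landmarks to anchor the co-embedding (on the order of tens of
landmarks is already workable; selection errors at relaxed thresholds add
noise rather than failure).

## Co-embedding

The model kernel is the symmetrized diffusion-state matrix
D₁ = (He + Heᵀ)/2 with negative eigenvalues clipped to zero — raw
diffusion-state matrices are not symmetric, and the factorization
N = V·Λ^{1/2} needs real square roots of the spectrum.  A regularized-Laplacian kernel (I + L)⁻¹, PSD by
construction, is available through `factorize_kernel` for fidelity with the
original co-embedding formulation.

Target nodes solve the underdetermined landmark system N_L · C₂ᵀ = T_L,
where T_L are landmark rows of the *target kernel* (symmetrized target
diffusion states — the similarity-matrix reading; it is the one under which
co-embedding a network with itself over all landmarks reproduces the model
kernel exactly).  The Moore–Penrose pseudoinverse (SVD, relative cutoff
1e-10·σ_max) gives the minimum-norm solution; with full-row-rank N_L the
landmark similarities are reconstructed to 1e-8, and the solution's
Frobenius norm is minimal among all solutions (both tested, the latter
against random null-space perturbations).

Two ranking conventions coexist and are deliberately opposite:
cross-species neighbors rank by **similarity descending** on D₁₂; target
neighbors rank by **distance ascending** on the pairwise L1 matrix of
target diffusion states.  D₁₂ rows always align to model nodes and columns
to target nodes.

## The vote

`VoteConfig(d=20, c=10, alpha=1.5, top_r=3)` is the recommended operating
point.  "d nearest" means the d nearest *labeled* proteins — unlabeled
nodes are skipped until d labeled voters are found, which maximizes voter
count in sparse-label regimes (a strict-window variant would simply drop
unlabeled neighbors; the skipping convention is the default and only
implemented one).  α multiplies the *target-species* votes.  Confidences
are normalized vote mass, which supplies the thresholds for F-max and
Resnik scoring.  Ties break lexicographically by term id, then node id,
making every prediction bit-reproducible.  A protein with no labeled voter
in either pool abstains, and abstentions score as errors.

The six homology baselines replace the cross-embedding pool with direct
hits (top hit / first 100 hits by bitscore / hits passing (p, q) = (85, 90);
each optionally extended by the hits' own c nearest labeled model-network
DSD neighbors).  All model-side voters carry weight 1; hit-plus-neighborhood
variants weight the hit and its neighbors identically.  Duplicate voters
are counted once.

## Evaluation

* **Accuracy**: percent of test proteins whose rank-1 label is among their
  true terms.
* **F-max**: precision at threshold τ averages only over proteins with at
  least one prediction above τ; recall averages over all test proteins;
  F1* maximizes the harmonic mean over τ.  The τ grid defaults to the
  distinct emitted confidences plus 0 — both scores are piecewise constant
  in τ, so this maximizes exactly over achievable thresholds.  Thresholding
  is strict (confidence > τ).
* **Resnik**: information accretion ia(v) = −log Pr(v | parents(v)), with
  i(term) summing ia over the ancestor closure.  The natural log is the
  default (the base uniformly rescales Resnik and nothing else; tests that
  quote values "in bits" pass base 2).  On a DAG the "least" common
  ancestor is ambiguous; the common ancestor of maximal information content
  is used, the standard Resnik-on-DAG generalization.  Disjoint components
  share a virtual root of zero information.  When conditional probabilities
  are not supplied with the ontology they are estimated by counting over
  the ancestor-closed annotation corpus: Pr(v | P(v)) =
  #(proteins with v) / #(proteins with all parents of v).
* Annotation sets (truth and predictions) are **ancestor-closed** before
  scoring, excluding ontology roots (a root annotates everything and would
  award a free correct term to every protein); an ancestor inherits the
  maximum confidence of its descendants.
* **Inverted k-fold CV** trains on one fold and scores the other k − 1, so
  larger k means sparser training labels.  Defaults: 5 reshuffled runs;
  reports carry per-fold metric lists plus train/test-size bookkeeping
  (asserted: each fold trains on ⌊A/k⌋±1 annotated proteins).
* **Grid search** over (c, d, α) uses standard 5-fold CV on a random half
  of the labeled proteins, ranking by mean accuracy; the held-out half is
  never touched during the search.

Per-namespace experiments (BP and MF) are run independently; a report
carries the namespace it was computed on.

## Synthetic species pairs

The generator produces everything the pipeline consumes, deterministically
under one seed:

* **Networks.**  The model species comes from a duplication–divergence
  process (n = 300 by default; retention 0.7; largest connected component),
  giving the hub-dominated degree structure PPI networks have — exactly
  the regime DSD's hub-damping targets.  A small-world alternative
  (`generator="small_world"`) provides evenly sized modules.  The target
  copies the induced subgraph over `n_orthologs` BFS-contiguous nodes,
  rewires each copied edge with probability `rewire_prob` (default 0.3 —
  cross-species interactome overlap is low, and lower rewiring makes the
  co-embedding unrealistically sharp), and attaches the remaining
  species-specific nodes preferentially.
* **Hit tables.**  Ortholog pairs get mutual rows; "strong" pairs
  (`n_strong_pairs`, default all) draw identity/coverage above the (90, 85)
  preset, the rest stay mutual-best but sub-threshold.  Decoy hits
  (`decoy_hit_rate` = 0.3) are one-directional, far below threshold, and
  directed at ortholog-paired subjects whose best hit is always their
  partner — so thresholded RBH selection provably recovers exactly the
  planted strong pairs (tested at precision = recall = 1 over seeds).
* **GO DAG and labels.**  A layered DAG with `n_terms` assignable leaf
  terms; conditional probabilities are constant within a layer (a depth-1
  ontology has uniform information accretion).  Leaf terms are dealt
  round-robin across the model network's modularity communities so every
  term stays populated at mid-range counts; each protein draws labels from
  its community's terms; ortholog partners inherit each label independently
  with probability `ortholog_label_fidelity` (default 0.8 — partial
  functional conservation); target annotations are subsampled to
  `label_density` (default 0.6).

What the generator does **not** emulate: real sequence evolution (hit
identities are drawn, not aligned), assay biases and false-positive edges,
the extreme size asymmetry of real network pairs, shared protein complexes
spanning species, and the heavy-tailed term-frequency distribution of real
GO corpora.  Passing tests therefore establish the *mechanics* of the
method (identities, recoveries, orderings, trend direction) at desk scale,
not absolute performance levels on real interactomes.

## The scaled-down comparison experiment

`mundo.pipeline.trend_experiment` fixes the study conditions once: two
300-node species, 150 planted orthologs of which 20 anchor the
co-embedding, 20 GO terms filtered to the 5–150 count window, fully
annotated ground truth, default vote parameters, 10-fold inverted CV.
Full annotation is an experiment-design choice, not a realism claim: a
k = 10 training fold must still exceed d = 20 for neighbor voting to stay
local, as it is on full-size networks — at 60% density the training fold
(18 nodes) would collapse the DSD pool into a global label prior.  Under
these conditions the single-network source weakens as k grows, the
co-embedding source stays flat, and the combined vote leads both in at
least 4 of 5 seeds of the reference batch (on the 5-seed mean it leads in
every batch probed; individual seeds can produce narrow wins for the
co-embedding-only vote).  One CV reshuffle per seed and 300-node networks
keep the whole experiment at a few minutes on one CPU.

## Known limitations

* Dense linear algebra throughout: O(n³) eigendecompositions and solves
  cap practical network sizes at a few thousand nodes per species; the
  interface leaves room for approximate diffusion-state backends.
* The hit-table consumer assumes precomputed BLAST-tabular files; the
  package never invokes an aligner.
* Identifier namespaces are taken at face value; no RefSeq/UniProt mapping.
* Confidences are normalized vote mass, not calibrated probabilities.
* Genetic and physical interactions are not distinguished; if a network
  file mixes them, they are all edges.
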