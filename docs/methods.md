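# Methods

## Problem

Given many 3-D configurations (conformers, isomers, perturbed
geometries) of each molecule in a collection, we want a model that
orders the configurations of an *unseen* molecule by a scalar property
— typically an energy, where the lowest-energy configuration is the
screening target. The model never needs to predict the property's
value, only the within-molecule ordering, so it is trained as a
pairwise ranker rather than a regressor.

## Scoring model

Each configuration is a set of atomic numbers Z_i and positions r_i
(Å). The scorer consumes only Z and the dense matrix of interatomic
distances d_ij, which makes it invariant to rigid rotations and
translations by construction; permutation invariance follows from
summing over atoms and neighbours.

1. **Embedding.** x_i^0 = a_{Z_i}, a learned per-element table of
   width F.
2. **Atom-wise layers.** Dense maps x → xW + b with weights shared
   across atoms.
3. **Distance features.** Each d_ij is expanded on a grid of Gaussians
   e_k(d) = exp(−γ (d − μ_k)²). Library default: 300 centres, μ_k =
   0.0, 0.1, …, 29.9 Å, γ magnitude 1.0. (Written with a signed
   prefactor the exponent must be negative for a decaying basis; the
   configuration stores the magnitude.)
4. **Interaction (message passing).** Atom i receives
   m_i = Σ_{j≠i} φ(d_ij) · x_j ⊙ W_f(e(d_ij)),
   where W_f is a two-layer filter MLP (dense → ssp → dense) and
   φ(d) = 1 − 6u⁵ + 15u⁴ − 10u³, u = d/r_cut, clamped to 0 beyond
   r_cut — a quintic cutoff with φ(0)=1, φ(r_cut)=0 and vanishing
   slope at both ends. The update is residual:
   x_i ← x_i + W_u(m_i) with a second two-layer MLP. r_cut is
   *learned*: it is reparameterised as softplus(raw) to stay positive
   (initialised at 10 Å for the library default, 6 Å in the synthetic
   experiments whose geometries span ≲ 8 Å).
5. **Prediction layer.** p_i = u ⊙ E_i + w1 ⊙ A1_i + w2 ⊙ A2_i with
   learned length-F vectors, merging the raw embedding E with the two
   final atom-wise outputs A1, A2 (a skip connection that shortens
   gradient paths).
6. **Readout.** Scalar score = linear map of Σ_i p_i. Summing (rather
   than averaging) keeps the score size-extensive.

All activations are the shifted softplus ssp(x) = ln(0.5 eˣ + 0.5),
computed as softplus(x) − ln 2 for overflow safety.

**Block order.** The network alternates atom-wise and interaction
blocks, with one additional atom-wise layer *after* the final
interaction (T interactions ⇒ T+1 atom-wise layers). Tapping "the two
final atom-wise layers" for the prediction layer then brackets the
last interaction; without the extra layer the last interaction's
update MLP would not influence the output at all (its gradient is
identically zero — this was caught by the end-to-end gradient check in
the test suite, which compares every analytic gradient against central
differences).

## Ranking objectives

The Siamese ranker applies the *same* scorer (shared weights) to both
members of a within-molecule pair and converts the score difference
into P(a outranks b) = logistic(s_a − s_b). Antisymmetry
(p(a,b)+p(b,a)=1) and reflexivity (p(x,x)=0.5) are therefore exact,
and the induced pairwise preferences are transitive: ranking a group by
its branch scores is identical to aggregating all pairwise
probabilities. Each unordered pair is emitted once in a random
orientation — emitting both orders would add no information.

* **Pairwise entropy** — cross-entropy against the comparison label
  (1,0) / (0,1) / (0.5,0.5) for t_a > t_b / < / =, in the stable form
  softplus(Δ) − l₁Δ. Ties are kept (the soft label is handled
  natively); the tie comparison uses an exact equality by default with
  an optional absolute tolerance.
* **Pairwise squared** — (Δscore − Δt)², regression of score
  differences onto property differences.
* **Pointwise** — (score − t)², the conventional regression baseline;
  ranking then sorts predicted values.

Training uses Adam (0.9/0.999), seeded shuffling, 64-example batches,
learning rate 1e-4 and up to 60 epochs by default. The optimiser and
initialisation schemes (embedding N(0, 1/F), fan-in-scaled uniform for
dense layers) are this package's choices; early stopping is available
but off by default. For the squared objectives the targets are
standardised with training-set statistics — an affine transform that
leaves within-group orderings untouched but conditions the loss scale.

## Evaluation

Per held-out molecule the predicted order (ascending score = lowest
property first, configurable) is compared with the true order:

* **rank MAE** — mean |predicted rank − true rank|;
* **Spearman ρ** — Pearson correlation of the rank vectors, average
  ranks on ties, undefined (dropped and counted) for zero variance;
* **nDCG** — linear gain: the item of true rank r has relevance n − r;
  discount 1/log₂(position+1); normalised by the ideal ordering. This
  convention is stated because nDCG values are only comparable within
  one gain/discount choice;
* **top-1 frequency** — fraction of molecules whose predicted best
  configuration is truly best (any tied minimum counts).

Group-level values are aggregated as mean, sample SD, and a
normal-approximation 95% CI half-width (1.96·sd/√n); both SD and CI
are reported since "±" conventions differ between studies.

## Synthetic data

`synthdata` generates seeded conformer ensembles: per group one random
point cloud (4–8 atoms from {H, C, N, O}, minimum interatomic distance
0.8 Å by rejection sampling inside a 4 Å box) plus Gaussian-perturbed
copies (σ = 0.3 Å default, 12 conformers per group). Two analytic
properties are attached:

* `energy` = Σ_{i<j} Z_i Z_j / d_ij — smooth, invariant to exactly the
  transformations the scorer is invariant to; a stand-in for absolute
  energetic properties;
* `gap` — a difference of a nearest-neighbour term and a long-range
  term, emulating difference-type properties whose molecule-level
  offsets largely cancel.

`attach_offsets` adds a per-group Gaussian constant to `energy`,
emulating the huge between-molecule scale differences of total
energies. Within-group pair labels and property differences are
invariant to these offsets, while a pointwise regression target is
dominated by them — the mechanism the offset experiment probes.

These fixtures are random point clouds, not chemically valid
molecules, and their property surfaces are far smoother than DFT
energies. Passing the recovery experiment shows the pipeline can learn
and transfer within-group orderings across unseen "molecules"; it does
not quantify accuracy on real quantum-chemistry data.

## Headline experiments

`molrank.experiments.run_experiment` wires the pipeline end to end at
desk scale (single CPU, minutes): 30 training + 10 held-out molecules
(molecule-level split so no configuration of a test molecule is ever
trained on), 12 conformers each, scorer with F = 64 features and T = 2
interaction steps over an RBF grid of 64 centres on [0, 8) Å (the
generated geometries span only a few Å, so the 30 Å library default
grid would waste most of its centres), 30 pairs per group, batch 64,
up to 40 epochs at learning rate 3e-3 (chosen once in a pilot as the
largest rate that trains smoothly at this model size; the 1e-4 library
default suits larger budgets). The untrained-scorer baseline evaluates
the same architecture at initialisation.

The offset variant multiplies the mean within-group `energy` spread by
100 to set the offset σ, then trains pairwise-entropy and pointwise
models under identical budgets. Every random draw derives from the
single experiment seed, and re-running from a manifest reproduces all
metric tables bit-identically (single-threaded numpy arithmetic).

## Numerical choices and limitations

* Gradients come from a small in-repo reverse-mode autodiff engine
  over float64 numpy arrays; every primitive and a full forward pass
  are verified against central differences (tolerance 1e-6 /
  rel 1e-4).
* Distances are computed densely (all pairs, no neighbour list) —
  exact and adequate at these molecule sizes; pairwise probabilities
  are clipped away from {0,1} only in the reporting-level loss
  helper, the training loss uses the softplus form and needs no
  clipping.
* Batching pads to the largest molecule with an explicit mask; masked
  atoms contribute exactly zero to messages and readout (verified
  against a loop-based single-structure oracle to 1e-6).
* Ties in predicted scores break by structure id (stable, seeded runs
  reproduce exactly).
* Not implemented: periodic boundary conditions, forces/coordinate
  gradients, neighbour lists, GPU execution, listwise objectives, and
  parsing of native quantum-chemistry archive formats (HDF5
  ensembles); structures enter via (extended) XYZ or embedding tables.
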