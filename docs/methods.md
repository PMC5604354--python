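# Methods

## Problem and targets

Each residue of a protein chain contributes two backbone dihedral
angles: phi (about N–Cα) and psi (about Cα–C), reported in degrees in
(−180, 180]. The first residue of a chain has no phi and the last no
psi; these are represented by an explicit mask, excluded from every loss
and error average, and written as `NA` in angle tables (a literal 360.0
on input — the DSSP placeholder — is likewise mapped to undefined).

Networks regress the four trigonometric targets sin φ, cos φ, sin ψ,
cos ψ, which removes the periodicity discontinuity at ±180°. Decoding
uses the two-argument arctangent atan2(sin, cos) rather than the naive
tan⁻¹(sin/cos): the latter is quadrant-ambiguous, while atan2 recovers
the angle uniquely even from unnormalized network outputs. The decoded
range is (−180, 180], with the atan2 output −180 folded onto +180.

Errors are computed on the circle: the signed difference P − E is
range-reduced to (−180, 180], equivalently the minimizer over
k ∈ {−1, 0, 1} of |P + 360k − E|, so no residue error can exceed 180°.
The half-open convention resolves the tie at exactly 180° of
displacement, where both signs have equal magnitude. Pooled wrapped MAE
per angle is the headline metric; model pairs are compared by two-sided
paired t-tests on per-residue absolute errors, paired by residue. A
difference vector that is identically zero leaves the t statistic
undefined; by convention p = 1 is returned so sweep tables never abort.
Pairwise tables report raw p-values with no multiplicity correction.

## Feature encoding

Each residue is a 56-vector, all entries in [0, 1], in this fixed,
versioned block order (layout `v1`):

| block    | width | content |
|----------|------:|---------|
| pssm     | 20 | PSI-BLAST log-odds profile, squashed by the logistic 1/(1+e⁻ˣ) |
| physchem | 7  | steric parameter, polarizability, van der Waals volume, hydrophobicity, isoelectric point, helix/sheet propensity; a built-in residue-type table, min–max scaled over the 20 types |
| ss8      | 8  | 8-state secondary-structure probabilities |
| cn15     | 15 | 15-class contact-number probabilities |
| sa       | 1  | solvent accessibility (exposed = 1, buried = 0) |
| disorder | 1  | disorder probability |
| fragsion | 4  | fragment-derived angle feature (below) |

The logistic squashing of integer log-odds scores is a choice; any
monotone map onto [0, 1] would serve, and the logistic keeps the
informative ±5 range away from saturation. 3-state secondary structure
and real-valued contact number are accepted as alternate layouts for
feature-ablation experiments.

**Fragment feature.** Fragment libraries provide, for each position, a
set of candidate 3-mer backbone conformations; the circular mean of the
fragment angles is a crude per-residue angle prediction P. (The circular
mean, atan2 of mean sine and mean cosine, is used rather than the
arithmetic mean, which is wrong across the ±180° seam.) Its error
statistics are residue-type specific: for each type the mean (avg) and
standard deviation (std) of the wrapped signed errors are tabulated on a
calibration subset. Seven types — C, D, G, H, N, S, T — have error
distributions too irregular for a location summary (glycine's
Ramachandran freedom being the extreme case); their avg and std are
fixed at zero. The emitted feature is α = wrap(P − avg) per angle,
encoded as ((sin α)+1)/2 and ((cos α)+1)/2 — four values for phi and
psi. The wrap is essential: a bare subtraction can leave (−360, 360).
The std column is carried in the table (and its serialization) for
diagnostics and the zero-set flag but does not enter the emitted values.

**Windows.** The input for residue i concatenates the feature vectors of
residues i−k … i+k, w = 2k+1 odd, giving w·56 inputs (392 for the
default w = 7); positions beyond the termini contribute zero vectors. A
padding-indicator channel was considered and rejected to keep the
56-wide per-residue layout. Window sizes default per architecture to the
values that model selection favors (11 for the feed-forward net, 7 for
its pre-trained variant and the recurrent net, 3 for the conditional-RBM
variant): recurrent models need less window context because state flows
along the chain.

## Architectures and training

All four models share the output convention (linear 4-unit readout) and
the masked least-squares loss E = ½ Σ (pred − true)², with components of
undefined angles excluded. Hidden units are logistic sigmoids; the
default hidden stack is 500-200-50 (the benchmark uses 64-32, see
below). Gradients are exact backpropagation, and every gradient path in
the repository is verified against central finite differences
(ε = 10⁻⁶) in the test suite. The finite-difference comparison uses
relative error |num − ana| / max(|num| + |ana|, 10⁻⁴); coordinates where
both gradients are below the floor are compared absolutely, because
there the central difference is dominated by cancellation noise.

Optimization is by minibatch SGD or Adam (default Adam, lr 10⁻³, batch
64); gradients are averaged over the minibatch so step sizes are
independent of batch and sequence length. The optimizer is deliberately
pluggable — the architectures and their gradients, not the optimizer,
are the substance, and correctness is enforced by the gradient oracle.
Weight initialization is Glorot-uniform on ±√(6/(fan_in+fan_out)).
Divergence (non-finite loss) aborts training and surfaces the last
finite checkpoint. All randomness flows from a single integer seed;
identical (seed, config, data) reproduces training bit-for-bit.

**RBM pre-training (DRBM).** Adjacent hidden layers are trained greedily
as RBMs with the standard bipartite energy E(v,h) = −b·v − c·h − hᵀWᵀv
by CD-1 (defaults: lr 0.01, 20 epochs, batch 32, sequential corpus-order
minibatches). Real-valued inputs in [0, 1] are treated as Bernoulli
mean-field values clamped on the visible layer. Hidden states are
sampled binary during the Gibbs step; visible reconstructions use the
sigmoid probabilities without sampling, a standard variance-reduction
choice. Each trained RBM's hidden probabilities become the next layer's
visible data. The linear readout is appended *at zero*: the first
fine-tuning steps then fit a linear probe on the frozen pre-trained
features before the whole stack adjusts jointly — appending a random
readout instead injects large initial errors that can saturate the
pre-trained hidden layers. Exact log-likelihoods and their gradients for
tiny RBMs (≤ 20 total units) are computed by enumeration as a
verification oracle only; CD-1 updates averaged over many seeds align
with the exact gradient (cosine > 0.9), and ascent along the exact
gradient increases the likelihood monotonically.

**Recurrent network (DRNN).** Only the first hidden layer is recurrent:
h⁽ᵗ⁾ = σ(W x⁽ᵗ⁾ + U h⁽ᵗ⁻¹⁾ + b), sweeping N→C with h⁽⁰⁾ = 0; deeper
layers and the readout are applied per residue. Gradients come from
backpropagation through time. The memory length m is the truncation
horizon: the error signal of each residue's loss traverses at most m
recurrent transitions (default 5; at m ≥ L the implementation switches
to an exact single-pass full BPTT, and the truncated path at horizon
L−1 agrees with it to machine precision). With U = 0 the model
reproduces the feed-forward network exactly.

**Conditional-RBM pre-training (DReRBM).** The first layer is
pre-trained as an RBM whose visible and hidden biases are shifted
linearly by the previous residue's hidden state (weights V and U). At
each epoch the mean-field hidden trajectory of every sequence is
computed under the current parameters — h⁽ᵗ⁻¹⁾ is the previous residue's
hidden *probability* vector, never a binary sample, again for variance
reduction — and CD-1 updates run with the shifted biases; the V and U
gradients are the per-sample bias gradients scaled by h⁽ᵗ⁻¹⁾. Deeper
layers are pre-trained as plain RBMs on the propagated hidden data (the
method leaves their treatment open; plain stacking is the simplest
consistent choice). The learned hidden-to-hidden coupling Uᵀ becomes the
initial recurrent weight matrix; fine-tuning is ordinary truncated BPTT.
With the couplings frozen at zero the procedure consumes the random
stream identically to plain stacked pre-training and reproduces it
bit-for-bit — the conditional and plain CD updates share one inner
routine by construction.

## Synthetic data generator

The generator stands in for a curated structure-derived corpus and its
five external feature programs. A sticky three-state Markov chain
(self-transition 0.9, uniform otherwise) walks along the chain; states
carry Ramachandran-basin angle means — helix (−63, −43), sheet
(−120, 135), coil a two-component mixture of a polyproline-II-like
basin (−75, 145, weight 0.7) and the left-handed helix region
(60, 45, 0.3) — plus wrapped Gaussian noise, default sd 15°. Wrapped
normal was chosen over von Mises for directly interpretable moments;
at 15° the two are practically indistinguishable. Chain lengths default
to [30, 500] (the benchmark draws 30–120); sequence letters follow
state-biased residue propensities so all 20 types, including the whole
zero-set, are exercised.

Feature blocks are drawn with state-dependent distributions so the
angles are learnable: ss8 concentrates ~0.8 of its mass on the true
state's letters, the PSSM favors state-typical residues (+4 vs −2
log-odds, integer noise sd 2), cn15 peaks at state-typical neighbor
counts (7/9/4 for helix/sheet/coil), solvent exposure and disorder rates
are state-typical, and fragment predictions are simulated as truth plus
wrapped noise (200 fragments, sd 30°) and then pushed through the real
fragment-feature pipeline, with the error table calibrated on the first
≤ 100 proteins of a dataset. Because the fragment means err by only
about 30/√200 ≈ 2.1°, the fragment feature is strongly informative —
deliberately so, mirroring how informative fragment libraries are in
practice; trained models on this generator can reach MAEs of a few
degrees, well below the 15° basin noise, because the features encode the
noise realization, not only the state.

What the generator does **not** emulate: long-range (contact-mediated)
correlations between distant residues, residue-type-dependent basin
shapes (e.g., glycine/proline peculiarities beyond propensity biases),
realistic Ramachandran densities, and feature-generator failure modes
(homology-poor PSSMs, secondary-structure mispredictions correlated over
segments). Passing benchmarks on this generator therefore demonstrate
that the architectures, gradients, encodings and selection procedures
work end-to-end — not that the real-data accuracies of the original
study are reproduced, which would require its curated datasets and
external feature tools.

## Benchmark and verification scales

The end-to-end benchmark (test suite and acceptance script) uses 200
generated proteins, lengths 30–120, default basin noise, an 80/20
protein-level split, window 7 for all architectures, hidden sizes 64-32,
memory length 5, 20 fine-tuning epochs for the feed-forward pair and 8
for the recurrent pair, pre-training at module defaults. These sizes
were chosen once as the package's standing benchmark configuration;
each architecture must beat the circular-mean baseline's held-out
wrapped MAE by at least 20 % on both angles (observed margins are far
larger). Convergence of the pre-trained variants is compared by first
passage to half the randomly-initialized counterpart's initial-epoch
loss — the halving convention the training contract itself uses — at
equal seed; the pre-trained variant must be no slower. Generative
pre-training here mainly buys a better starting region: with an
adaptive optimizer the randomly initialized nets catch up and can
overtake later in training, consistent with pre-training acting as a
regularizer rather than an accelerator of terminal convergence.

Protein-level (never residue-level) splits are used everywhere,
including 5-fold cross-validation, since residues of one protein are
strongly dependent. Greedy forward feature selection scores candidate
groups by the arithmetic mean of phi and psi MAE and breaks ties by the
declared group order.

## Known limitations

* Visible units are Bernoulli mean-field only; no Gaussian-visible RBM,
  persistent CD, or parallel tempering.
* Recurrence is single-direction N→C with a zero initial state; no
  gated units or bidirectionality.
* The enumeration oracle is limited to ≤ 20 total units by design.
* The fragment feature's std column is tabulated but unused by the
  emitted features; the encoding intentionally carries location
  information only.
* CLI training loads whole datasets into memory; chains are capped at
  10,000 residues.
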