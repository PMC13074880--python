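# Methods

## Problem setting

The package models acute-toxicity endpoints — (species, administration
route, metric) combinations such as *rat / oral / LD50* — as related
regression tasks over a shared pool of small molecules. Dose labels are
stored as −log10(dose in mol/kg), so larger values mean more toxic.
Labels are scarce and unevenly distributed across endpoints, and the
underlying assays are noisy, so the model is built to (i) share structure
across endpoints, (ii) output a full predictive distribution rather than a
point, and (iii) use the decomposed predictive uncertainty to decide which
unlabeled molecules are worth annotating next.

## Model

**Molecular graphs.** Each molecule is an undirected heavy-atom graph.
Atoms carry a 96-dimensional feature vector: a 44-slot element one-hot
(43 named elements plus an "other" catch-all, so exotic elements degrade
gracefully instead of crashing), 17-slot one-hots for heavy-atom degree,
implicit-hydrogen count and total valence (values above 16 clamp to the
last slot), and one aromaticity flag. Hydrogens are implicit.

**Shared encoder.** L graph-convolution layers with symmetric degree
normalization over the self-loop-augmented neighborhood,

    h_v^(l+1) = σ( Σ_{u ∈ N(v) ∪ {v}}  h_u^(l) W^(l) / sqrt(deg(v) deg(u)) ),

followed by a permutation-invariant readout (mean by default; sum and max
are available). σ is ReLU by default. The self loop guarantees deg ≥ 1.

**Per-endpoint mixture decoders.** A two-hidden-layer MLP per endpoint
maps the shared embedding z to a C-component Gaussian mixture: C weight
logits (softmax → π), C means, and C raw variances passed through
softplus plus a 1e-6 floor. For classification endpoints the decoder
emits per-component logit vectors μ_c and matching variances used in a
stochastic softmax, softmax(μ_c + σ²_c · γ) with γ ~ N(0, 1). Note the
*variance* (not the standard deviation) scales the noise; this is the
formulation implemented by default, with `classification_noise="std"`
available as the conventional reparameterization.

**Training loss.** Per endpoint the default loss is the weight-weighted
sum of component negative log-densities at the observed label,

    L_k = − Σ_c π_c(z) · log p(y | μ_c(z), σ²_c(z)),

which upper-bounds the true mixture NLL (Jensen). The standard
`−log Σ_c π_c p(y|·)` is available via `loss="mixture_nll"`. The
multi-task objective is the sum over endpoints of per-endpoint batch
*means*, so endpoints with many labels cannot numerically drown scarce
ones inside a batch. Optimization is Adam (lr 1e-3, weight decay 1e-5,
50 epochs, batch size 64 by default).

A consequence of the default loss being linear in π: for a given sample
the optimum puts all weight on the best component, so trained mixture
weights tend to concentrate (the decoder learns to route each embedding
to one component). This matters for the uncertainty decomposition below.

**Implementation.** The network is plain NumPy/SciPy with hand-derived
gradients and an Adam optimizer implemented in the package; batches are
assembled as block-diagonal sparse normalized adjacencies. All gradients
are verified against central finite differences in the test suite, and
the graph-convolution forward pass against a dense loop-based oracle.

## Uncertainty decomposition and query score

For regression mixtures the predictive variance splits exactly (law of
total variance) into

* aleatoric U_al = Σ_c π_c σ²_c — mixture-weighted component variance,
  the irreducible assay-noise part, and
* epistemic U_ep = Σ_c π_c (μ_c − Σ_c π_c μ_c)² — the weighted spread of
  component means, the reducible model-disagreement part.

For classification both parts come from T Monte-Carlo draws (component
from π, then noise): U_al is the mean entropy of the drawn class
probabilities, U_total the entropy of their mean, and U_ep = U_total −
U_al (nonnegative by concavity). Entropies are in nats. T defaults to 20
and each molecule gets an id-derived stream so pool scores are
order-independent.

The annotation utility is U = α·U_ep + (1−α)·U_al with α = 0.75 by
default. Components are combined raw (both in squared-label units for
regression); no rank normalization is applied by default.

## Active acquisition protocol

The dataset is scaffold-split 8:1:1 (Bemis–Murcko groups are atomic;
groups are assigned largest-first to the most under-filled set, with a
seeded shuffle breaking size ties). Each endpoint starts from a random
10% of its training labels; each round scores that endpoint's current
unlabeled pool, queries the top ceil(10%) by utility (ties broken by
ascending molecule id), reveals those labels, and retrains the multitask
model from scratch with a fresh round-derived seed. The 10% budget is
relative to the *current* pool, so absolute budgets shrink slightly over
rounds. A molecule queried for endpoint k reveals only endpoint k's
label. Pool updates are set-theoretic and validated every round: labeled
and unlabeled stay disjoint and their union is conserved.

## Synthetic benchmarks

Real multi-species dose collections are large and external, so all tests
run on generated data with known truth. Molecules are built
combinatorially from ring cores (benzene, pyridine, furan, thiophene,
pyrrole, cyclohexane, cyclopentane), optional linkers, second rings and
substituents, giving pools spanning hundreds of Bemis–Murcko scaffolds.
Labels are

    y_k(x) = base + ρ·g(d(x)) + (1−ρ)·h_k(d(x)) + ε,  ε ~ N(0, s²(x)),

where d(x) is an 8-dimensional descriptor vector (size, ring count,
heteroatom fraction, aromatic fraction, N/O/halogen counts, branching),
g is a shared random tanh expansion, h_k endpoint-specific ones, and the
noise sd s(x) interpolates linearly in heavy-atom count between 0.2 and
0.6 — a heteroscedastic, size-linked noise model that gives the aleatoric
head a real signal to find. ρ defaults to 0.5. The surfaces use a
moderately high-frequency random expansion (8 tanh units, input weight
scale 3) so that fitting them needs substantially more labels than the
initial 10% seed provides; with the earlier, smoother surfaces the model
reached the noise floor at the initial budget and acquisition order could
not matter at all.

Presets: `small` — 300 molecules, 2 endpoints with label fractions
(1.0, 0.2), a 64-dim 2-layer encoder and 30 epochs, sized for unit
tests; `medium` — 2000 molecules, 5 endpoints with fractions
(1.0, 0.6, 0.3, 0.15, 0.08) and the full default configuration (3-layer
128-dim encoder, C = 4, 50 epochs), used for acquisition-efficiency
studies.

What the generator does *not* emulate: real structure–activity
relationships, activity cliffs, inter-endpoint mechanistic structure
beyond a shared smooth term, assay-protocol artifacts, or the chemical
diversity of real screening collections. Passing the synthetic checks
shows the machinery is correct and the decomposition behaves as
designed; it does not certify predictive performance on real toxicity
data.

## Numerical choices and degenerate inputs

* Variance heads: softplus + 1e-6 floor; mixture weights via softmax of
  unconstrained logits.
* Dose transform uses base 10 (configurable); dose ≤ 0 is a domain error.
* Scaffold split with fewer groups than sets leaves the small sets empty
  with a warning rather than failing.
* Budgets use ceiling rounding, capped at the pool size.
* Max readout backward splits gradient evenly across exactly tied maxima
  (symmetric atoms tie exactly and move together).
* NaN query scores abort selection naming the offending molecule;
  querying an already-labeled id raises (double-labeling guard).
* The NLL trace is evaluated on the full visible labeled set after each
  epoch, so a zero learning rate yields an exactly constant trace.

## Known limitations

* Because the default loss is linear in the mixture weights, trained
  weights concentrate on one component per sample and the epistemic term
  U_ep is typically orders of magnitude smaller than U_al; with α = 0.75
  the fused score is then dominated by the aleatoric part, which tracks
  assay noise rather than model error. On the medium benchmark, where
  noise is independent of the surfaces' difficulty, uncertainty-driven
  acquisition is statistically indistinguishable from random sampling
  (final-round differences of ~0.007 RMSE against a seed-to-seed
  training spread of ~0.02). The `mixture_nll` loss form keeps
  multimodal weights and is the recommended switch when the
  decomposition itself is the object of study.
* Retraining from scratch each round makes rounds independent but leaves
  noticeable seed-to-seed variance in round metrics.
* Classification endpoints are supported and tested on synthetic binary
  tasks only.
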