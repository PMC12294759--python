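# Methods

## The masked network

The classifier is a feed-forward network over four classes — cancer,
cancer-prone chronic inflammatory disease (CP-CID), non-cancer-prone
chronic inflammatory disease (NCP-CID), normal — with hidden layers that
mirror a biological hierarchy. Layer 0 holds genes, layer 1 pathways,
layer 2 superpathways (the builder accepts any depth ≥ 2). Each pair of
adjacent layers contributes a binary mask `S^l ∈ {0,1}^{n_{l+1} × n_l}`
whose nonzeros are the known child→parent memberships, and the layer
computes

    h^{l+1} = f((S^l ⊙ W^l) h^l + b^l),

so the Hadamard product zeroes every weight the prior does not license, at
every forward pass — masked positions are *structurally* ineffective, not
merely regularized, and a test perturbs them to confirm the output is
invariant. The output head is dense (`softmax(W_out h + b_out)`); hidden
entities need a connection budget, class logits do not. Training minimises
mean cross-entropy with Adam; the trainable parameter count is the mask
nonzeros plus biases plus the head, which for realistic hierarchies is a
small fraction of the dense equivalent.

Defaults, all overridable: 500 epochs, batch 32, learning rate 1e-3, ReLU
hidden activation (tanh available — the choice affects attribution
saturation), one bias vector per hidden layer. Initialization is
Glorot-uniform on unmasked entries and exactly zero on masked ones; hidden
biases start at 0.01 under ReLU because narrow masked layers (a handful of
pathway neurons) can otherwise begin with every unit inactive and receive
no gradient at all. Prediction ties break toward the lowest class index.
No early stopping and no class weighting. Everything is NumPy; gradients
for training and attribution come from hand-written reverse-mode
backpropagation through the forward contract, and conductance additionally
uses a forward-mode directional derivative.

Inputs are TPM-like non-negative matrices. The model applies
`log2(v + 1)` followed by per-gene z-scaling, with the statistics fitted on
the training fold only and stored for held-out data; a gene constant in the
training fold gets unit scale. Whether to standardize at all is a
configuration choice — raw TPM magnitudes span orders of magnitude and
would dominate both optimisation and attribution deltas, so the transform
is the default.

Evaluation uses stratified k-fold cross-validation (default 5) preserving
per-class proportions, reporting weighted precision, recall and F1 per fold
and pooled over held-out predictions; a `train`-on-everything path exists
for the interpretability stage, which conventionally explains a model
fitted to the complete dataset.

## Attribution

All three methods explain the same scalar: the **pre-softmax logit** of a
chosen class (a probability flag exists). The logit is numerically stable
under class saturation; empirically the probability target also degrades
both inter-method agreement and cross-category separation on synthetic
cohorts, so the logit remains the default. Attribution operates in the
model's input space (after preprocessing), with the zero vector — i.e. the
training-set mean expression profile — as baseline.

**Integrated Gradients.** The path integral of the input gradient from
baseline to input. Two quadratures: the literal right-endpoint Riemann sum

    IG_i = (x_i − x'_i) Σ_{k=1..m} ∂F(x' + (k/m)(x − x'))/∂x_i · (1/m)

and Gauss–Legendre nodes/weights mapped to [0, 1] (the default; its error
decays much faster than the Riemann sum's O(1/m)). Both are exact on linear
models for any m ≥ 1. Completeness — attributions summing to
F(x) − F(x') — is verified against directly evaluated spans and against a
100,000-step reference integration.

**Conductance.** IG pushed onto hidden neurons: neuron y's total
conductance is `Σ_i (x_i − x'_i) ∫ ∂F/∂y · ∂y/∂x_i dα`. Per quadrature
node the implementation multiplies the output-side gradient ∂F/∂y
(reverse-mode from the logit to the layer) by the input-side directional
derivative of y along x − x' (forward-mode from the input), which computes
the i-sum without materialising the per-input Jacobian. Summing a hidden
layer's total conductances recovers F(x) − F(x'); summing over a named
neuron set gives exact set-level (pathway-group) conductance. Conductance
of the output layer is undefined and rejected.

**Kernel SHAP.** Shapley values approximated by weighted linear regression
over coalitions: coalition members keep their value from x, the rest are
pinned to a background vector (default: the same zero baseline as IG, for
cross-method comparability; a training-mean option exists). The efficiency
axiom `Σ φ_i = F(x) − F(background)` is enforced exactly by eliminating one
feature from the least-squares system. When `2^n − 2` coalitions fit within
the query budget, all are used with exact Shapley-kernel weights
`(n−1)/(C(n,s)·s·(n−s))`, which recovers exact Shapley values (verified
against a brute-force average over feature orderings); otherwise coalitions
are drawn in complementary pairs with sizes following the kernel-weight
distribution and unit regression weights, the sampling distribution
absorbing the kernel.

Defaults follow the framework's standard settings: m = 800 for all three
budgets. Dataset-level attribution keeps only samples whose argmax
prediction equals their label and attributes each against its true class;
rankings are the mean absolute sample-level attribution, descending, with
lexicographic tie-breaks.

## Consistency analysis

Agreement between two ranked lists is the intersection fraction
`|top_k(A) ∩ top_k(B)| / k` (a Jaccard option exists) at k ∈
{10, 30, 50, 100} by default. The composite "total score" across IG and
SHAP min–max scales each method's mean-|attribution| vector to [0, 1]
before summing — the two methods live on different scales, and a degenerate
(constant) vector maps to zero so it cannot dominate. Top-fraction
selection takes `ceil(f · N)` genes (default f = 0.05). The semantic
gene-refinement step is a pluggable deterministic predicate (the shipped
implementation is a keep-list file); it preserves rank order among kept
genes and records drop reasons.

## The disease rule

`prone ⇔ (RR > 2) ∨ (HR > 2) ∨ (SIR > 1.4)`, strict inequalities, absent
statistics contributing nothing; diseases documented only through an
inverse association with cancer carry a protective flag that forces
not-prone; a disease with no statistic and no flag is an error rather than
a silent default. The shipped registry encodes the published values
(asthma HR 1.36; psoriasis RR 1.21; rheumatoid arthritis SIR 1.20;
ulcerative colitis SIR 2.4 and RR 2.4; Crohn's disease RR 2.5; NASH HR
7.62; hepatitis B HR 15.77; Alzheimer's disease and IBS protective) and
yields the 5 NCP / 4 CP reference split. The rule is monotone: raising any
one statistic can only move a disease toward prone.

## The synthetic cohort

The generator emulates the statistical structure the framework assumes,
not any real dataset. Per gene a baseline log2 level is drawn from
N(3, 1.5²); a sample's log2 value adds `effect_size` on the genes planted
for its class plus N(0, noise_sd²) noise, then is exponentiated to a
TPM-like positive scale. Labels are balanced; the normal class is the
unshifted baseline; the three planted sets (cancer, CP-CID, NCP-CID) are
pairwise disjoint by construction. Pathways take contiguous gene blocks
(optionally overlapping); planted genes are strided across the first
pathways so several pathways carry signal for every class while the
remainder stay uninformative — giving pathway-level conductance real
structure to find. Everything is deterministic under the spec's seed.

The frozen "strong-effect" cohort used for end-to-end runs: 200 genes,
20 pathways of 10 genes, 4 superpathways, 100 samples per class, 20 planted
genes per non-normal class, effect 2.0, noise 0.5 (log2 scale), seed
20250711.

What passing synthetic tests shows — and does not. The generator has no
batch effects, no library-size variation, no gene–gene correlation beyond
the planted shifts, and log-normal marginals rather than empirical ones.
Success here demonstrates the machinery (masking, training, attribution,
ranking) behaves as specified under known ground truth; it does not
establish performance on real transcriptomes.

### Observed behaviour at the frozen cohort

Two findings from running the full workflow across training seeds are worth
recording, because they are properties of the setting rather than bugs:

* **Inter-method agreement is robust.** The IG-vs-SHAP top-10 intersection
  within a class is 0.8–1.0 across seeds — the two methods see the same
  model through different lenses and agree.
* **Cross-category separation and exhaustive planted-gene recovery are
  not.** The CP-vs-NCP top-20 intersection ranges from 0.20 to 0.35, and
  each class's IG top-20 typically contains 30–90% of its own 20 planted
  genes, with much of the remainder filled by *other* classes' planted
  genes. Two mechanisms drive this. First, with a 4-neuron superpathway
  bottleneck feeding a 4-class softmax, every class logit carries
  substantial gradient on other classes' discriminative genes (their
  absence is evidence *for* the class), and mean-absolute ranking counts
  that negative evidence at full weight. Second, the 20 planted genes of a
  class are statistically exchangeable, so a converged classifier needs
  only a subset of them; cross-entropy saturates early (the cohort
  separates within a few dozen of the 500 epochs) and the unused genes
  keep near-zero gradients thereafter. At realistic scale — top-100 lists
  drawn from ~10⁴ genes — the same collision is diluted by the base rate;
  the 200-gene cohort exposes it. Attribution finds what the model uses,
  which is not necessarily everything the generator planted.

## Problem sizes and numerical choices

The test suite runs entirely on small cohorts: toy nets of ~12 genes for
oracle comparisons, the frozen 200-gene cohort for end-to-end checks, and a
reduced null experiment (30 genes, 60 samples per class, 120 epochs, 3-fold
CV, 5 seeds) verifying that with zero effect size held-out weighted F1 sits
at the 0.25 chance level within Monte-Carlo error (±0.12, three binomial
standard errors at that sample size). Quadrature tolerances (1e-3 against
high-resolution integration, 1e-6 against exact Shapley) follow from the
m = 800 budgets. All randomness flows through explicit seeds; stage seeds
derive from one global seed via SeedSequence and stay below 2³¹.

## Known limitations

* The semantic gene-filter is an interface with a deterministic mock; no
  live language-model adapter is included.
* No GPU path; the NumPy implementation targets desk-scale cohorts.
* Gene-set enrichment, survival analysis and external-database lookups are
  out of scope; the analysis layer stops at rankings, overlaps and
  selections.
* The conductance quadrature discretises the path integral directly; other
  published approximations differ in interior-point handling and may give
  slightly different per-neuron values at small m.
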