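# Methods

This note documents the models implemented in `ppifuse`, the defaults and
the reasoning behind them, what the synthetic benchmark does and does not
emulate, and the numerical choices a maintainer should know about.

## Feature extraction

**Auto-covariance (AC).** Proteins are encoded on 14 physicochemical
scales: hydrophilicity, flexibility, accessibility, turn propensity,
exposed surface, polarizability, antigenic propensity, hydrophobicity (two
scales), net charge index, polarity (two scales), solvent-accessible
surface area, and side-chain volume. The bundled 20×14 table
(`ppifuse/data/scale_table.csv`) is assembled from standard published
indices and can be overridden by any CSV with the same shape; unit tests
use synthetic tables so correctness never rests on the bundled values. The
lag-g auto-covariance uses the full-length scale mean and a 1/(L−g)
normalizer; the maximum gap defaults to G = 2, giving 28 values per protein
and 56 per pair, the counts the architecture was designed around. AC is
translation-invariant and quadratic in scale units, so per-column
standardization matters: columns are z-scored with the training mean and
sample (n−1) SD, then min–max scaled with the training extrema of the
z-scores; held-out values are clipped to [0, 1] and zero-variance columns
map to 0. Sequences must be strictly canonical (20 letters) because the
scale lookup is undefined otherwise; the FASTA reader offers a skip-with-
warning mode for survey data.

**GO LCA clustering.** Term depth is the longest ascending path to the
namespace root (the usual GO level convention). Pair LCAs are taken over
the union of both proteins' terms, per namespace; the deduplicated anchors
are sorted deepest-first and each claims its not-yet-claimed descendant
subgraph. Deepest-first is a genuine design choice (the sort direction of
"hierarchical levels" is ambiguous): it yields more, smaller, more specific
clusters, and its alternative (shallow-first) collapses almost everything
into root-anchored clusters. The per-term contribution to a cluster's
feature is the node count of the shortest ascending path to the anchor,
inclusive, so a term sitting on the anchor counts 1. Terms shared by both
proteins count twice (multiset semantics). Clusters are learned from
training pairs only; test-pair terms outside every cluster contribute
nothing, which prevents test-set leakage into the feature space.

**Improved semantic similarity.** One scalar per namespace compares the two
proteins' cluster-indexed profiles. The weights come from the cubic map
with ρ = 2.59 and E₀ = 0.7 — ρ just below 3√3/2 ≈ 2.598 keeps the orbit
chaotic while confined to (0, 1); the score is therefore deterministic
given the cluster count. The denominator repeats the first profile's sum
as printed in the method's definition; `symmetric_denominator=True`
substitutes the second profile, making the score symmetric. The
SR-transformed cosine (`ssd_cosine`) is shipped as a reference baseline
only, because no concrete relation matrix SR is defined for this task; it
defaults to the identity and is not part of the default feature vector.

## Predictors

**mRNN.** A single LSTM cell with input size 1 scans the pair's feature
vector as a length-T sequence of scalars; the final hidden state feeds
three dense layers (tanh, tanh, logistic). The cell-state update
c_t = f_t∘c_{t−1} + i_t∘g_t is the standard completion of the published
gate equations, which omit that line. Hidden size defaults to 16 and the
head to 16→8→1; forget-gate biases start at 1 so the state persists early
in training. Training is SGD with momentum 0.9, learning rate 0.01,
mini-batch 70, 50 epochs, minimizing the binary cross-entropy.

**DBN.** One RBM layer of 50 hidden units (configurable stack) is
pre-trained for 50 epochs with CD-1 — momentum 0.5 for the first five
epochs then 0.9, weight cost 2·10⁻⁴ — and the stack plus a logistic head is
fine-tuned for 100 epochs with dropout 0.1 on the hidden layer. The exact
likelihood gradient of the RBM is intractable; CD-1 is the universal
surrogate and is consistent with the momentum/weight-cost hyper-parameter
family. Inputs must be min–max normalized to [0, 1] (done once per run on
the training rows, held-out rows clipped).

**Gradient convention.** All gradient-based training in this package —
BPTT, DBN fine-tuning, and the CD-1 statistics — applies the learning rate
per sample (batch-summed gradients). This is the convention of the classic
DBN toolboxes these hyper-parameter names come from, and it is what makes
the fixed epoch budgets (50/100) sufficient: with batch-mean gradients the
same budgets leave both models at their initial loss. The LSTM additionally
clips the global gradient norm at 1.0, standard practice for recurrent
training at a fixed step size.

## Fusion and optimization

The two models' MAPEs on a held-out validation split give the initial
fusion weights w₁ = MAPE_mRNN/(MAPE_mRNN + MAPE_DBN), w₂ = 1 − w₁. Two
deliberate deviations from the printed formulas are documented flags: MAPE
uses absolute errors (signed relative errors can cancel to a meaningless
zero), and the printed weight formulas give the lower-error model the
smaller weight — the literal form is the default and `invert=True` swaps
the numerators. Note that with 0/1 labels as "actuals" the MAPE of every
negative pair is ε-guarded, so the absolute MAPE values are enormous; only
their ratio matters, and it remains well-behaved. MAPEs are computed on
validation, not training, data so overfit models cannot grab weight.

AISSO then tunes the 2-vector of (pre-normalization) fusion weights in
[0, 1]² against the validation MSE of the fused scores, seeded with the
MAPE weights. Per candidate and iteration: a shark-smell move (velocity =
η·Rand·(−∇OF) + φ·Rand·v_prev, central finite differences with step 10⁻³,
descent sign because the objective is a minimization; the magnitude capped
at |β·v_prev| with the sign of the capped term; position += velocity·Δt),
then an Aquila contour proposal X₂ = X_best·Lévy(D) + X_R + (Π−K)·ra with
the spiral terms r = r₁ + 0.00565·D₁, θ = −0.005·D₁ + 3π/2 and the mixing
variate ra = |r₃| from the ICMIC map x ← sin(a/x). Defaults follow the
published constants: population 10, 25 iterations, η = φ = β = 0.5,
Δt = 0.1, Lévy s = 0.01, β_Lévy = 1.5 (σ as printed, without the Mantegna
1/β exponent; a flag restores it), mutation fraction and scale δ = 0.1.

Where the hybridization was genuinely open, this package's scheme is: both
the shark move and the Aquila proposal are accepted greedily per candidate;
each iteration a δ-fraction of non-best candidates and the incumbent best
receive greedy Gauss mutation (σ = δ·range); the global best is elitist.
Momentum and the velocity limiter track the raw (pre-limit) velocity
sequence — with β = 0.5 a limiter chained on the limited velocity would
extinguish movement geometrically instead of damping it. Greedy acceptance
makes the best-so-far trace provably non-increasing, which the tests assert
on every run. Lévy numerators/denominators are standard normal (Mantegna's
method); the printed "random integer among 0 & 1" is unusable literally
because |RI₂|^(1/β) would be 0 or 1.

## Evaluation

Regression-style metrics (MAE, MARE, MASE, MSE, MSRE, RAE, RMSE) compare
the continuous fused scores to the 0/1 labels; MARE/MSRE guard zero actuals
with ε = 10⁻⁸, RAE normalizes by deviation from the label mean, and MASE
uses the naive one-step scale (and is therefore order-dependent — it is the
one metric excluded from permutation-invariance checks). Accuracy
thresholds at 0.5 with ties counted positive. Run-level statistics over
repeated optimizer runs use the minimization convention and the sample
(n−1) standard deviation.

## Synthetic benchmark

The generator emulates the structure the method assumes, not any real
proteome:

- **Latent functional groups** (default 3). Each group has a softmax-normal
  residue profile; sequences (default length 150–400) are drawn from it
  with short run-length repeats, so group identity is visible both in the
  mean physicochemical profile and in the lag auto-covariances.
- **Modular ontologies.** Each namespace DAG (default 60 terms) has one
  subtree per group under the root; within a module, nodes attach to 1–2
  existing members (diamonds included). Proteins draw 6–12 terms, 95 % from
  their own module. Uniform random attachment instead of modules makes
  nearly every pair's LCA the root and destroys the clustering signal — the
  modular layout is the regime the LCA method is designed for, and the
  6–12 / 95 % defaults correspond to well-curated annotation sets.
- **Labels.** P(interact) = logistic(β₀ + β_sig·z), where z is the sum of
  the standardized shared-annotation count and the standardized correlation
  of the two proteins' mean physicochemical profiles; β₀ is solved by
  bisection so the expected positive fraction matches the configuration
  (default 0.5). β_sig = 0 severs labels from features entirely — the null
  calibration; the default β_sig = 3 gives z an AUC ≳ 0.9 against labels.

What passing tests do show: every stage recovers a planted signal of the
kind it was built for, at realistic sample sizes (400 pairs, 60 % training),
and the whole pipeline is leakage-free and bit-reproducible. What they do
not show: performance on real interactomes — real sequences are not
mixture-of-multinomial, real GO DAGs are far larger and annotation noise is
not uniform, and real interaction labels are not a logistic function of two
summary statistics.

Problem sizes in the default test suite and acceptance script (400–2000
pairs, 120–150 proteins, 60-term namespaces, 20 optimizer seeds) were
chosen as the smallest sizes at which the statistical checks have
reasonable power; everything regenerates programmatically from seeds.

## Numerical choices and degenerate inputs

- Logistic functions use the numerically stable two-branch form; scores are
  clipped to [10⁻¹², 1−10⁻¹²] inside the cross-entropy.
- Zero-variance AC columns map to 0 with a warning; held-out features are
  clipped into the training min–max box.
- LCA ties (equal depth) break lexicographically; disconnected terms fall
  back to the namespace root.
- Both MAPEs zero → fusion weights (0.5, 0.5); weight vectors at the AISSO
  bounds are renormalized to sum 1 (an all-zero vector means equal weights).
- The ICMIC iterate is nudged by 10⁻¹² if it hits exactly 0; |RI₂| in the
  Lévy step is floored at 10⁻¹².
- All randomness flows through `numpy.random.Generator` seeds derived from
  one run seed, so every artifact is bit-reproducible.

## Known limitations

- The LSTM treats a feature vector as a scalar time series; this is the
  published architecture, but it is a weak inductive bias for flat feature
  vectors and the DBN usually earns the larger fusion weight.
- The velocity limiter ratio β = 0.5 damps the shark move heavily; most of
  AISSO's late-stage progress comes from the greedy Gauss refinement.
- Cross-namespace LCAs, information-content similarity weighting, deep
  (>1 hidden layer) DBNs by default, and GPU execution are out of scope.
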