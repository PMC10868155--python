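# Methods

## Model and pipeline

The package infers a weighted functional association network from a
genes × conditions expression matrix in four stages.

**Pre-processing.** Counts/abundances are transformed entrywise by
`log2(x+1)` (proportional rather than additive changes; the pseudocount of
1 keeps zeros at zero, which matters when 80–95% of entries are zero) and
each gene's row is divided by its own maximum so all values lie in [0,1],
the range of the decoder's sigmoid output. All-zero genes are carried
through but excluded from pair scoring, where their correlation would be
undefined. No library-size normalization, highly-variable-gene selection
or batch correction is applied: the method deliberately scores *all*
genes, including understudied ones that selection heuristics tend to drop.
A `log=False` path exists for matrices that arrive already log-scaled
(common for proteomics intensity exports); by default proteomics
abundances are treated like counts.

**VAE embedding.** Genes are observations, conditions are features. The
encoder is `x → ReLU(W1 x) → (mu, log sigma²)` with linear heads; the
decoder is `z → ReLU(W4 z) → sigmoid(W5 h)`; one hidden layer on each
side. The loss is `w_recon · recon + w_kl · KL` with `w_recon = 0.9`,
`w_kl = 0.1`. Reconstruction is per-feature binary cross-entropy (inputs
and outputs both live in [0,1]) summed over features and averaged over the
batch; squared error is available via `recon_loss="mse"`. KL is the
closed-form divergence between the per-gene latent Gaussian and the prior
N(1, 0.1²), summed over latent dimensions and averaged over the batch.
The off-origin, tight prior is unusual relative to the standard N(0, I)
but is implemented as specified for the method; it keeps latent
coordinates near 1 and penalizes per-gene variance, acting as a strong
information bottleneck. Summing (not averaging) BCE over features keeps
the 0.9/0.1 weighting meaningful regardless of the number of conditions;
we verified that re-weighting as if BCE were feature-averaged (the other
common convention) collapses the posterior to the prior on our fixtures
and destroys the embedding.

Training uses the reparameterization trick (`z = mu + sigma · eps`) and
Adam (default lr 1e-3). Mini-batches shuffle genes each epoch; weight
initialization is Glorot-uniform; `mu`/`log sigma²` biases start at the
prior. All randomness — init, shuffling, reparameterization noise —
derives from one integer seed, and two runs with identical data, config
and seed produce bit-identical embeddings (single-threaded NumPy is
deterministic). The embedding is the deterministic encoder mean `mu`, not
a stochastic sample, so downstream correlations are reproducible.

The implementation is plain NumPy with hand-derived gradients. This keeps
the package CPU-only and dependency-light, makes determinism trivial to
guarantee, and is fast at the scales the package targets (hundreds to
tens of thousands of genes; the heavy dimension — conditions — only
enters through two matrix products per batch).

**Scoring.** Every unordered gene pair is scored by the Pearson
correlation of the two genes' latent mean vectors. The correlation matrix
is computed in row blocks, streaming pairs above a configurable score
floor, so atlas-scale inputs (~2·10⁸ pairs) do not need all pairs in RAM.
Genes whose latent vector has zero variance are excluded and reported.
Ranking is by score descending with lexicographic `(gene1, gene2)`
tie-break, making ranked benchmarks reproducible byte-for-byte.

**Benchmarking, calibration, combination.** Against a membership-mode
gold standard (gene → pathway map), a ranked pair is TP if the genes share
a group, FP if both are mapped but share none, excluded otherwise. In
pairs mode (interaction lists) a pair absent from the list counts FP only
if both genes occur somewhere in the list; `strict_fp=True` restores the
harsher all-absent-are-FP reading. Local precision `y = TP/(TP+FP)` in a
sliding window (default 1000 evaluable pairs, step 100; both
configurable, and small fixtures use proportionally smaller windows) is
fitted as a function of the window's mean score `x` with
`y = a0 + a1·x + a2/(1 + exp(a3·(x − a4)))` by Nelder–Mead least squares.
The fit is deterministic: a fixed start grid (`a2 ∈ {0.5, 1}`,
`a3 ∈ {−20, −5, 5}`, `a4` at the x quartiles, `a0 = min y`, `a1 = 0`),
two chained simplex runs per start, lowest SSE wins with ties broken by
grid order. Starting `a4` only at the median leaves the simplex in a local
minimum whenever the precision transition sits off-center, so the
quartile starts are load-bearing. Probabilities are
`clip(curve(score), 0, 1)`; the number of clamped pairs is logged. An
unconstrained fit can be non-monotone even though the conversion is meant
to be rank-preserving, so monotonicity is checked on the observed score
range and a warning (or the `isotonic=True` fallback, which substitutes
the isotonic regression of precision on score) handles violations.

Calibrated networks are merged over the union of their pairs with
prior-corrected noisy-OR: `q_i = max(0, (p_i − prior)/(1 − prior))`,
`p = 1 − Π(1 − q_i)`, result `prior + p·(1 − prior)`. The default prior
is 0, under which absent evidence is neutral and the combined probability
never falls below either source. The rule is associative, so combining
more than two sources is well-defined.

## Synthetic data generator

`generate_fixture` emulates the two properties that motivate the method:
sparsity and redundancy. Genes belong to modules; each module is "on" in
a random subset of cell clusters (subset size uniform on
[1, n_clusters − 1], so no module is silent or ubiquitous) and off
elsewhere. On-state counts are lognormal with mean `mean_expression = 10`
(a well-expressed gene in a 10x-style matrix) and multiplicative sigma
`noise_sd = 0.5`; background genes fluctuate independently of clusters;
entrywise Bernoulli dropout (default 0.8) zeroes entries; every cell is
duplicated `redundancy_factor` times (default 3) with fresh dropout per
copy. The module map doubles as the membership gold standard, with
background genes left unmapped so their pairs are excluded — as real
pathway databases do for genes they never annotated.

What the generator does *not* emulate: library-size variation between
cells, gene-regulatory dynamics, compositional effects, doublets, or
count discreteness (values are continuous lognormals). Tests passing on
these fixtures therefore demonstrate that the pipeline recovers planted
block co-expression under dropout and redundancy, not that it handles
every artifact of real single-cell chemistry.

## Problem sizes and training schedules

The default VAE configuration (hidden 256, latent 48, 50 epochs, batch
32, lr 1e-3, BCE) is an atlas-scale setting: with tens of thousands of
genes an epoch contains enough gradient steps for Adam at lr 1e-3 to
converge within tens of epochs. The test and acceptance experiments run
at fixture scale — 220 genes × 1500 conditions (5 modules × 40 genes, 20
background genes, 10 clusters × 50 cells, redundancy 3, dropout 0.8) —
where an epoch is only 7 mini-batches. `small_data_config()` is the
documented schedule for this regime: lr 3e-4 with 1000 epochs (similar
total step count, finer steps), latent 16 (the planted structure has rank
≈ 10), and squared-error reconstruction, whose smaller gradients relative
to the KL term regularize against memorizing per-gene noise. On the
fixture this schedule ranks the top-1000 evaluable pairs perfectly
(TP=1000/FP=0 across generator seeds), whereas raw log-count PCC leaves
14–43 false positives from modules with overlapping cluster activity —
the package's central claim, reproduced end to end by
`scripts/acceptance.py`. Training runtime at fixture scale is a few
minutes on one CPU; all other stages are seconds.

## Numerical choices and edge cases

- Missing cells (empty/NA) load as 0, matching sparse-count semantics;
  NaN/Inf after loading, negative values and duplicate gene ids are hard
  errors.
- All-zero rows survive scaling untouched (no 0/0), and zero-variance
  latent rows are excluded from scoring rather than scored 0.
- BCE is computed from logits (`softplus(l) − x·l`) and the calibration
  logistic through a saturating sigmoid, so neither overflows.
- Network TSVs are read back with exact (`round_trip`) float parsing, so
  parse → re-serialize is byte-identical; the ranking's total order
  (score desc, then lexicographic) makes every output file reproducible
  from config + seed.
- `kl_to_prior` is validated against a 10⁶-sample Monte-Carlo estimate,
  pairwise scoring against a scalar brute-force loop (≤1e-12), and the
  calibration function against its scalar formula (≤1e-12).

## Known limitations

- The VAE trains full-batch epochs in memory; matrices far beyond ~10⁵
  conditions should be subsampled or chunked by the caller.
- Calibration requires a gold standard with enough mapped genes for at
  least one full window; coverage mismatches between matrix and gold
  standard namespaces are reported, not repaired (identifiers are taken
  verbatim).
- The unconstrained calibration fit can be non-monotone on pathological
  window sets; the isotonic fallback trades the parametric form for
  guaranteed monotonicity.
- Embedding quality at very small gene counts (tens of genes) is
  training-noise-limited; the raw-PCC baseline can be competitive there.
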