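# Methods

This note documents the models, the numerical choices, and the reasoning
behind the package's defaults. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A cohort is an `n_samples × n_snps` integer matrix of alternative-allele
counts: `{0,1,2}` per diploid genotype, `{0,1}` per haplotype (two haplotype
rows per individual sum to its genotype row). Each sample carries one class
label `y` — binary disease status or one of K population indices. VCF
positions (1-based) are converted to 0-based, half-open intervals
internally; the TSV dialect (`sample_id`, `label`, one column per variant)
exists for human-inspectable fixtures.

Every SNP belongs to exactly one gene. A SNP inside exactly one annotated
interval is assigned there; a SNP covered by zero or several intervals goes
to the gene on its chromosome with the nearest midpoint, ties to the earlier
gene in genomic order. Dropping intergenic SNPs is not an option because the
embedding must cover the full genotype; the nearest-midpoint rule is the
package's choice among the reasonable completions. Missing genotype calls
and multi-allelic sites are hard errors: imputation and allele splitting are
out of scope, and silently guessing calls would contaminate every downstream
metric.

## Gene-wise PCA codec

One PCA per gene, fitted on training samples only (synthetic and test data
are encoded with the frozen codec, so no information leaks into the
evaluation). The retained count is

    r_g = clip( argmin_r { cumulative EVR(r) ≥ threshold }, 1, min(8, s_g, n_train − 1) )

with `threshold = 0.99` by default. The threshold form was chosen because it
targets the reconstruction-loss budget directly; 8 is the fixed slot width,
so wider genes simply truncate. A constant gene keeps one (zero-variance)
component. Component signs are fixed by making each component's
largest-magnitude loading positive, which makes fitted codecs reproducible
across sample orderings (exact up to LAPACK rounding only when the
eigenvalue spectrum is non-degenerate; with tied eigenvalues the retained
subspace, and hence the reconstruction, is still stable even though
individual components are not unique).

Decoding is transpose-projection plus the gene mean, rounded to the nearest
integer and clipped to the valid allele-count range — the values are counts,
so rounding is the correct quantizer. The gene axis is padded to
`G_pad = smallest multiple of 2^depth ≥ G` (full-scale instance: depth 11;
desk-scale default: depth 3), and the `(G_pad, 8)` binary clamp mask marks
the `Σ_g r_g` live slots. `apply_clamp` (multiply by the mask) is enforced
after every operation that could touch padded slots.

## Diffusion

The diffusion process follows the standard Gaussian formulation: linear
β-schedule, `ᾱ_t = Π(1−β_i)`, forward marginal
`x_t = √ᾱ_t x₀ + √(1−ᾱ_t) ε`, ε-prediction MSE over live slots only,
ancestral sampling with posterior variance
`β̃_t = β_t (1−ᾱ_{t−1})/(1−ᾱ_t)`. All T steps are used at generation time —
step-skipping trades away sample quality — and classifier-free guidance is
off (hooks exist but conditioning through the label embedding alone proved
sufficient and guidance has no accuracy benefit in this regime). Noise is
drawn only at live slots; padded slots are never noised. Time reaches the
denoisers as normalized `t/T ∈ [0,1]`.

Defaults: `T = 1000`, `β ∈ [1e-4, 0.02]` at full scale. Desk-scale runs use
`T = 200` with `β ∈ [1e-4, 0.1]`: the β-range is rescaled so that
`ᾱ_T ≈ 3e-5` matches the full-scale schedule, i.e. the chain still ends in
(numerically) pure noise. Without this rescaling a short chain retains a
`√ᾱ_T ≈ 0.4` imprint of the data at its endpoint and sampling from N(0, I)
starts out of distribution.

Two stabilizing choices matter at desk scale:

* **Top-level residual in every denoiser** (`ε̂ = x_t + correction`). At high
  noise the optimal prediction approaches `ε ≈ x_t`; forcing that
  near-identity map through a halving U-Net bottleneck is exactly what small
  networks learn slowest, and in controlled two-class experiments the
  residual variant reaches class-conditional generation in ~100 epochs where
  the plain variant fails to.
* **Clip-denoised sampling** (optional, on in the pipeline): at each reverse
  step the implied clean sample `x̂₀ = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t` is clipped
  to per-slot bounds recorded from the training embedding (margin 1.2)
  before the posterior mean is formed. PCA coefficients of genotype data are
  bounded by construction, so the bounds are a property of the data space,
  not a tuning knob; without the clip, ε̂ errors early in the chain are
  amplified by up to `1/√ᾱ_T`.

One-shot reconstruction — noise `x₀` to level t, invert in a single step,
report `‖x₀ − x_p‖` over live slots — is logged on a held-out split at
`t = T/2` during training as a generation-quality proxy; it weights exactly
the high-noise regime that ancestral sampling traverses first.

## Denoiser architectures

All four map `(x: n×G_pad×8, t, y)` to `ε̂` of the same shape and are
drop-in interchangeable in the diffusion core. Conditioning is a 32-dim
sinusoidal embedding of t plus a learned class embedding (an extra "null"
index serves unconditional use), summed, and injected additively inside the
up-projection blocks (U-Nets) or as two dedicated tokens (transformer).

* **MLP U-Net**: each level fully connects the flattened gene axis; down
  blocks halve it, up blocks concatenate the matching down activation. No
  attention. Position-aware but parameter-hungry.
* **CNN U-Net**: 1-D convolutions (kernel 5) along the gene axis with the 8
  coefficient slots as channels; average-pool 2 down, nearest-neighbour
  upsample + skip concatenation up. Few parameters, translation-equivariant,
  hence no absolute positional information.
* **Combined**: the convex combination `(1−λ(t))·MLP + λ(t)·CNN` with one
  scalar λ per noise level, produced by a 2-layer perceptron with sigmoid
  output. The sigmoid pins `λ ∈ [0,1]` so the mixture can never leave the
  convex hull of its parts; a single scalar (rather than per-channel
  weights) keeps the two submodels' roles interpretable as a function of
  noise level. Both submodels and the mixer receive gradients through the
  combined output only.
* **Transformer**: genes are grouped into patches (default 8 genes → one
  token), linearly embedded, given learnable positional embeddings, and
  prefixed with a t-token and a y-token; a 2-layer pre-norm encoder with
  4-head self-attention processes the sequence and the gene tokens are
  projected back and un-patched.

At the desk-scale default (G_pad = 64, depth 3) the parameter counts order
as MLP-based (≈0.8 M) > transformer (≈78 k) > CNN (≈64 k), mirroring the
full-scale ordering of these architecture families. Layer counts, widths and
activations (SiLU) are the package's own choices; checkpoints record the
architecture tag, config, seed and codec fingerprint.

The networks (and the CNN/transformer classifiers) run on `genodiff._nn`, a
compact float64 reverse-mode autodiff core over numpy with exactly the
required op set; determinism under a seeded generator is part of its
contract, which the manifest checksums rely on.

## Evaluation metrics

Nearest-neighbour adversarial accuracy uses leave-one-out within-set
neighbours (without the exclusion the within-set distance is identically
zero and the metric degenerates) and a strict inequality, so exact distance
ties count as 0, matching the indicator as written. When set sizes differ,
the larger set is subsampled without replacement to the smaller (seeded),
keeping neighbourhood densities comparable. Metrics are computed in the PCA
embedding space on live slots — the generator's native space; a decode-space
audit is additionally available. Cosine distance of a zero vector is defined
as 1.

Privacy loss is reported exactly as `AA_truth^train,syn − AA_truth^test,syn`;
the mean-based variant `(AA_truth+AA_syn)/2` difference is also reported,
but only as a secondary diagnostic, since underfitting on one side and
overfitting on the other can cancel within the mean.

Recovery rate `R = a_s/a_r` (×100 on the percent scale in tables) is
computed by one shared routine; classifier cells never re-derive it. All
accuracies are evaluated on real held-out data only. The duplicate audit
reports minimum cross-set L1/L2/cosine distances, the arg-min pair, and the
count of pairs with L2 < 1e-6 (decode-space exact equality is the stricter
alternative check).

## Cohort simulator

Each gene receives `k ~ U{1..min(max_rank, s_g)}` prototype haplotype
columns with ancestral allele frequencies `U(0.1, 0.5)`; every SNP copies
one prototype (each prototype backs at least one SNP) or, with probability
0.3, its allele complement. The centered per-gene matrix therefore has rank
exactly ≤ k: the low-rank linkage structure the codec assumes is *planted*,
not approximated, which gives the codec tests an exact oracle. An
independent per-entry perturbation (default rate 0.002, the order of a
typical genotyping-error rate) adds full-rank noise that the 99% codec must
absorb, keeping the fidelity benchmark non-degenerate; with the rate at 0
the encode→decode round-trip is exactly lossless.

Population structure follows the Balding–Nichols model: subpopulation
frequencies `Beta(p(1−F)/F, (1−p)(1−F)/F)` around each ancestral `p`
(`F = 0` degenerates to equality). Disease labels come from a liability
threshold: per-gene standardized latent dosages of the causal genes, effects
`N(0, effect_size²/n_causal)`, Gaussian noise, thresholded at the sample
`(1−prevalence)`-quantile, so realized prevalence is exact. The generator
also returns the oracle Bayes accuracy `E[Φ(|S−τ|/σ)]` of the rule that
observes the genetic liability exactly; because τ is a sample quantile this
oracle carries `O(1/√n)` finite-sample bias, which the null-model tests
account for.

What the simulator does **not** emulate: between-gene LD (genes are
independent given population; real recombination correlates neighbours),
realistic allele-frequency spectra, coalescent ancestry, relatedness, and
the perfect within-block LD of the copy model is stronger than real
within-gene correlation. Passing tests therefore demonstrate that the
pipeline machinery is correct and that the method works where its structural
assumptions hold — not that these accuracy levels transfer to any real
cohort.

## Desk-scale study conditions

The documented toy configuration (`pipeline.toy_config`) is a 768-sample
diploid cohort of 60 genes (5–20 SNPs each, planted rank ≤ 4, 30 causal
genes, effect size 3, liability noise 0.5), codec depth 3 (G_pad = 64,
~141 live slots), combined denoiser, T = 200, 150 epochs of Adam at 2e-3,
batch 64, 25% held-out test split. These sizes were chosen once as the
smallest cohort on which the polygenic signal, the codec compression and the
diffusion training all operate in their intended regimes while a complete
run stays in the minutes range on one CPU core.

The oracle-vs-empirical classifier comparison uses n = 6000 samples with 100
causal genes of 300 (max rank 2): with ~500 embedding features and effects
spread over 100 genes, a few thousand training samples are required before
an MLP can approach the generating model's Bayes accuracy; at n = 2000 the
estimation gap is an order of 10–25 accuracy points regardless of effect
size, so a comparison there would measure sample-size starvation rather
than learnability.

## Known limitations

* The autodiff core is single-threaded float64 numpy; full-scale instances
  (G_pad = 18 432, millions of samples-steps) are out of reach — the package
  demonstrates the method at desk scale and is structured so the model code
  would port directly to a tensor framework.
* Ancestral sampling cost is linear in T and in the model's forward cost;
  the transformer denoiser dominates generation cost at equal quality.
* The NNAA subsample size quantizes AA values at 1/n; privacy-loss values
  are comparable only between runs sharing the subsample seed and size.
* The simulator's exact low-rank genes make the codec's job easier than real
  LD would; the genotyping-error knob is the only full-rank component.
* Differential-privacy accounting and membership-inference attacks are
  explicitly out of scope; the duplicate audit and NNAA are necessary, not
  sufficient, privacy evidence.
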