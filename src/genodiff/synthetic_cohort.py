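"""Synthetic genotype/haplotype cohorts with gene-blocked linkage structure.

The simulator emulates the statistical features the generation pipeline
assumes of real cohorts, at desk scale and with no downloads:

* genes of 5-100 SNP sites whose within-gene SNP matrix has low effective
  rank — each gene carries ``k`` latent "prototype" haplotypes and every SNP
  is a copy (or allele-flipped complement) of one prototype, so the centered
  per-gene matrix has rank at most ``k``, the redundancy the PCA codec
  exploits;
* population allele-frequency differentiation under a Balding–Nichols model
  with a single differentiation parameter ``fst``;
* a polygenic binary label: a liability that sums small effects over many
  causal genes plus Gaussian noise, thresholded at a prevalence quantile.

An optional independent per-entry perturbation rate mimics genotyping error;
with it set to zero the planted rank is exact and the codec round-trip is
lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort_io import Gene, GeneMap, GenotypeMatrix, PloidyMode, Variant

_GENE_SPACING = 1000  # bp between simulated gene intervals
_SNP_SPACING = 10     # bp between SNP sites inside a gene


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one simulated cohort.

    ``snps_per_gene`` bounds are inclusive; per-gene latent rank is drawn
    uniformly in ``[1, min(max_rank, s_g)]``. ``fst`` is the Balding–Nichols
    differentiation parameter (0 = a single panmictic population).
    ``genotype_error_rate`` is the probability that an entry is independently
    perturbed after the low-rank draw.
    """

    n_samples: int = 1000
    n_genes: int = 200
    snps_per_gene: tuple[int, int] = (5, 100)
    max_rank: int = 8
    complement_prob: float = 0.3
    genotype_error_rate: float = 0.002
    n_populations: int = 1
    fst: float = 0.0
    n_causal_genes: int = 20
    effect_size: float = 1.0
    liability_noise: float = 1.0
    prevalence: float = 0.5
    ploidy_mode: PloidyMode = PloidyMode.GENOTYPE
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.snps_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("snps_per_gene must satisfy 1 <= lo <= hi")
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not (1 <= self.max_rank):
            raise ValueError("max_rank must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")


@dataclass
class GeneStructure:
    """Latent-factor blueprint of one simulated gene."""

    gene: Gene
    rank: int
    snp_factor: np.ndarray      # (s_g,) index of the prototype each SNP copies
    snp_complement: np.ndarray  # (s_g,) bool; True = SNP is the allele complement
    ancestral_freqs: np.ndarray  # (rank,) ancestral alt-allele frequencies

    @property
    def size(self) -> int:
        return len(self.snp_factor)


def generate_gene_structure(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[Variant], GeneMap, list[GeneStructure]]:
    """Lay out non-overlapping genes and draw each gene's latent blueprint."""
    lo, hi = config.snps_per_gene
    sizes = rng.integers(lo, hi + 1, size=config.n_genes)
    structures: list[GeneStructure] = []
    variants: list[Variant] = []
    snp_to_gene: list[int] = []
    pos = 0
    for gi, s in enumerate(sizes):
        s = int(s)
        width = s * _SNP_SPACING + _SNP_SPACING
        gene = Gene(f"G{gi:05d}", "chr1", pos, pos + width)
        k = int(rng.integers(1, min(config.max_rank, s) + 1))
        # every factor backs at least one SNP so the planted rank is exact
        factor = np.concatenate([np.arange(k), rng.integers(0, k, size=s - k)])
        rng.shuffle(factor)
        complement = rng.random(s) < config.complement_prob
        freqs = rng.uniform(0.1, 0.5, size=k)
        structures.append(GeneStructure(gene, k, factor, complement, freqs))
        for j in range(s):
            variants.append(Variant("chr1", pos + _SNP_SPACING // 2 + j * _SNP_SPACING, "A", "C"))
            snp_to_gene.append(gi)
        pos += width + _GENE_SPACING
    gene_map = GeneMap(genes=[st.gene for st in structures], snp_to_gene=np.array(snp_to_gene))
    return variants, gene_map, structures


def _population_freqs(
    structures: list[GeneStructure], config: CohortConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Balding–Nichols subpopulation frequencies, one (K, rank) array per gene."""
    out = []
    f = config.fst
    for st in structures:
        p = st.ancestral_freqs
        if f == 0.0:
            freqs = np.tile(p, (config.n_populations, 1))
        else:
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            freqs = rng.beta(a, b, size=(config.n_populations, len(p)))
        out.append(freqs)
    return out


@dataclass
class Cohort:
    """A simulated cohort bundled with its generative ground truth."""

    matrix: GenotypeMatrix
    gene_map: GeneMap
    structures: list[GeneStructure]
    gene_scores: np.ndarray  # (n_individuals, n_genes) standardized latent dosages
    populations: np.ndarray  # (n_individuals,)
    bayes_accuracy: float | None = None


def _perturb(values: np.ndarray, hi: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return values
    mask = rng.random(values.shape) < rate
    delta = rng.choice([-1, 1], size=values.shape)
    return np.where(mask, np.clip(values + delta, 0, hi), values)


def generate_haplotypes(config: CohortConfig, rng: np.random.Generator) -> Cohort:
    """Haplotype-mode cohort: two binary rows per individual, population labels."""
    cfg = replace(config, ploidy_mode=PloidyMode.HAPLOTYPE)
    return _generate(cfg, rng)


def generate_genotypes(config: CohortConfig, rng: np.random.Generator) -> Cohort:
    """Genotype-mode cohort ({0,1,2} entries) with polygenic disease labels."""
    cfg = replace(config, ploidy_mode=PloidyMode.GENOTYPE)
    cohort = _generate(cfg, rng)
    labels, bayes = assign_disease_labels(cohort.gene_scores, cfg, rng)
    cohort.matrix.labels = labels
    cohort.bayes_accuracy = bayes
    return cohort


def _generate(config: CohortConfig, rng: np.random.Generator) -> Cohort:
    variants, gene_map, structures = generate_gene_structure(config, rng)
    pop_freqs = _population_freqs(structures, config, rng)
    n = config.n_samples
    populations = rng.integers(0, config.n_populations, size=n)

    hap_mode = config.ploidy_mode == PloidyMode.HAPLOTYPE
    n_rows = 2 * n if hap_mode else n
    values = np.empty((n_rows, sum(st.size for st in structures)), dtype=np.int8)
    gene_scores = np.empty((n, len(structures)))

    col = 0
    for gi, (st, freqs) in enumerate(zip(structures, pop_freqs)):
        p = freqs[populations]  # (n, rank)
        h1 = (rng.random((n, st.rank)) < p).astype(np.int8)
        h2 = (rng.random((n, st.rank)) < p).astype(np.int8)
        if hap_mode:
            a = h1[:, st.snp_factor]
            b = h2[:, st.snp_factor]
            a = np.where(st.snp_complement, 1 - a, a)
            b = np.where(st.snp_complement, 1 - b, b)
            block = np.empty((2 * n, st.size), dtype=np.int8)
            block[0::2] = a
            block[1::2] = b
        else:
            proto = h1 + h2  # (n, rank) in {0,1,2}
            block = proto[:, st.snp_factor]
            block = np.where(st.snp_complement, 2 - block, block).astype(np.int8)
        dosage = (h1[:, 0] + h2[:, 0]).astype(np.float64)
        sd = dosage.std()
        gene_scores[:, gi] = (dosage - dosage.mean()) / sd if sd > 0 else 0.0
        values[:, col : col + st.size] = block
        col += st.size

    hi = 1 if hap_mode else 2
    values = _perturb(values, hi, config.genotype_error_rate, rng).astype(np.int8)

    if hap_mode:
        sample_ids = [f"S{i:05d}_{h}" for i in range(n) for h in ("A", "B")]
        labels = np.repeat(populations, 2)
    else:
        sample_ids = [f"S{i:05d}" for i in range(n)]
        labels = np.zeros(n, dtype=np.intp)
    matrix = GenotypeMatrix(values, sample_ids, variants, labels, config.ploidy_mode)
    return Cohort(matrix, gene_map, structures, gene_scores, populations)


def assign_disease_labels(
    gene_scores: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Polygenic liability-threshold labels plus the oracle Bayes accuracy.

    Liability = sum of per-gene effects times standardized latent dosages over
    the causal genes, plus Gaussian noise; individuals above the
    (1 - prevalence) liability quantile are cases. The oracle accuracy is that
    of the Bayes rule that observes the genetic liability component exactly.
    """
    if not (0.0 < config.prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    n, n_genes = gene_scores.shape
    causal = rng.choice(n_genes, size=config.n_causal_genes, replace=False)
    effects = rng.normal(0.0, config.effect_size / np.sqrt(config.n_causal_genes), size=len(causal))
    genetic = gene_scores[:, causal] @ effects
    noise = rng.normal(0.0, config.liability_noise, size=n)
    liability = genetic + noise
    threshold = np.quantile(liability, 1.0 - config.prevalence)
    labels = (liability > threshold).astype(np.intp)
    if config.liability_noise > 0:
        bayes = float(np.mean(stats.norm.cdf(np.abs(genetic - threshold) / config.liability_noise)))
    else:
        bayes = 1.0
    return labels, bayes
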