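"""Gene-wise PCA codec: compress SNP blocks to at most 8 coefficients per gene.

Within a gene, linkage disequilibrium makes SNP columns highly redundant, so
an independent PCA per gene compresses each block of 5-100 allele-count
columns to between 1 and 8 principal-component coefficients with negligible
loss. Per-gene coefficient vectors are zero-padded to a fixed width of 8 and
stacked along the gene axis, which is itself zero-padded up to the next
multiple of ``2**depth`` so a U-Net can halve it ``depth`` times. Padded
slots carry no information and are clamped to exactly zero throughout
training and generation; the binary ``clamp_mask`` records which slots are
live.

Decoding inverts the projection per gene, adds back the mean, rounds to the
nearest allele count, and clips to the valid range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .cohort_io import GeneMap, GenotypeMatrix, PloidyMode, Variant

PC_WIDTH = 8  # fixed per-gene coefficient slot width


def pad_gene_axis(n_genes: int, depth: int) -> int:
    """Smallest multiple of ``2**depth`` that is >= n_genes."""
    if n_genes < 1:
        raise ValueError("gene count must be positive")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    block = 1 << depth
    return ((n_genes + block - 1) // block) * block


def choose_pc_count(
    explained_variance: np.ndarray, s_g: int, n_train: int, threshold: float = 0.99
) -> int:
    """Number of PCs to retain for one gene.

    Smallest r whose cumulative explained-variance ratio reaches ``threshold``,
    clipped into [1, min(8, s_g, n_train - 1)]. An all-zero spectrum (constant
    gene) retains a single component.
    """
    ev = np.asarray(explained_variance, dtype=np.float64)
    if (ev < -1e-12).any() or (np.diff(ev) > 1e-9).any():
        raise ValueError("explained-variance spectrum must be non-negative and non-increasing")
    cap = max(1, min(PC_WIDTH, s_g, n_train - 1))
    total = ev.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(ev) / total
    r = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return int(np.clip(r, 1, cap))


@dataclass
class GenePCACodec:
    """Frozen per-gene PCA parameters.

    For gene g: ``means[g]`` (length s_g), ``components[g]`` (r_g x s_g,
    orthonormal rows), retained count ``ranks[g]`` in [1, 8]. ``depth`` fixes
    the gene-axis padding; the codec is fitted on training samples only and
    then applied unchanged to any matrix with the same SNP layout.
    """

    means: list[np.ndarray]
    components: list[np.ndarray]
    ranks: np.ndarray
    gene_map: GeneMap
    depth: int
    ploidy_mode: PloidyMode
    threshold: float

    @property
    def n_genes(self) -> int:
        return len(self.means)

    @property
    def padded_genes(self) -> int:
        return pad_gene_axis(self.n_genes, self.depth)

    @property
    def n_snps(self) -> int:
        return int(sum(len(m) for m in self.means))

    def clamp_mask(self) -> np.ndarray:
        """(G_pad, 8) binary mask; 1 marks a live coefficient slot."""
        mask = np.zeros((self.padded_genes, PC_WIDTH))
        for g, r in enumerate(self.ranks):
            mask[g, :r] = 1.0
        return mask

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {
            "ranks": self.ranks,
            "depth": np.array(self.depth),
            "threshold": np.array(self.threshold),
            "ploidy": np.array(self.ploidy_mode.value),
            "snp_to_gene": self.gene_map.snp_to_gene,
            "gene_table": np.array(
                [(g.gene_id, g.chrom, str(g.start), str(g.end)) for g in self.gene_map.genes]
            ),
        }
        for g in range(self.n_genes):
            arrays[f"mean_{g}"] = self.means[g]
            arrays[f"comp_{g}"] = self.components[g]
        np.savez_compressed(path, **arrays)

    @staticmethod
    def load(path: str | Path) -> "GenePCACodec":
        from .cohort_io import Gene

        with np.load(path, allow_pickle=False) as z:
            ranks = z["ranks"]
            genes = [
                Gene(gid, chrom, int(start), int(end)) for gid, chrom, start, end in z["gene_table"]
            ]
            gene_map = GeneMap(genes=genes, snp_to_gene=z["snp_to_gene"])
            return GenePCACodec(
                means=[z[f"mean_{g}"] for g in range(len(ranks))],
                components=[z[f"comp_{g}"] for g in range(len(ranks))],
                ranks=ranks,
                gene_map=gene_map,
                depth=int(z["depth"]),
                ploidy_mode=PloidyMode(str(z["ploidy"])),
                threshold=float(z["threshold"]),
            )


@dataclass
class GeneEmbedding:
    """n x G_pad x 8 coefficient tensor plus its clamp mask and labels."""

    tensor: np.ndarray      # (n, G_pad, 8) float64; exactly 0 at padded slots
    clamp_mask: np.ndarray  # (G_pad, 8)
    labels: np.ndarray      # (n,)
    depth: int
    n_genes: int            # live genes before padding

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[2] != PC_WIDTH:
            raise ValueError(f"tensor must be (n, G_pad, {PC_WIDTH})")
        if self.clamp_mask.shape != self.tensor.shape[1:]:
            raise ValueError("clamp_mask shape must match tensor (G_pad, 8)")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    def live_values(self) -> np.ndarray:
        """(n, n_live) view of the live coefficient slots, flattened."""
        return self.tensor.reshape(self.n_samples, -1)[:, self.clamp_mask.ravel() > 0]

    def subset(self, idx: np.ndarray) -> "GeneEmbedding":
        return GeneEmbedding(
            self.tensor[idx], self.clamp_mask, self.labels[idx], self.depth, self.n_genes
        )

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            # track_times off so identical embeddings are byte-identical
            fh.create_dataset(
                "tensor", data=self.tensor, chunks=True, compression="gzip", track_times=False
            )
            fh.create_dataset("clamp_mask", data=self.clamp_mask, track_times=False)
            fh.create_dataset("labels", data=self.labels, track_times=False)
            fh.attrs["depth"] = self.depth
            fh.attrs["n_genes"] = self.n_genes

    @staticmethod
    def load(path: str | Path) -> "GeneEmbedding":
        with h5py.File(path, "r") as fh:
            return GeneEmbedding(
                tensor=fh["tensor"][...],
                clamp_mask=fh["clamp_mask"][...],
                labels=fh["labels"][...],
                depth=int(fh.attrs["depth"]),
                n_genes=int(fh.attrs["n_genes"]),
            )


def apply_clamp(tensor: np.ndarray, clamp_mask: np.ndarray) -> np.ndarray:
    """Zero the padded slots, leave live slots untouched. Idempotent."""
    if tensor.shape[-2:] != clamp_mask.shape:
        raise ValueError(f"shape mismatch: tensor {tensor.shape} vs mask {clamp_mask.shape}")
    return tensor * clamp_mask


def fit_codec(
    train: GenotypeMatrix,
    gene_map: GeneMap,
    depth: int = 3,
    threshold: float = 0.99,
) -> GenePCACodec:
    """Fit one independent PCA per gene on that gene's SNP columns only.

    The PC count per gene follows :func:`choose_pc_count`. Component signs are
    fixed so the largest-magnitude loading of each component is positive,
    making fitted codecs reproducible across sample orderings.
    """
    if train.n_samples < 2:
        raise ValueError("codec fitting needs at least 2 training samples")
    if gene_map.snp_to_gene.shape[0] != train.n_snps:
        raise ValueError("gene map does not cover the matrix SNP layout")
    counts = gene_map.snp_counts()
    if (counts < 1).any():
        empty = [gene_map.genes[i].gene_id for i in np.where(counts < 1)[0]]
        raise ValueError(f"genes without any assigned SNP: {empty}")
    means, components, ranks = [], [], []
    n = train.n_samples
    for g in range(gene_map.n_genes):
        cols = gene_map.snp_indices(g)
        block = train.values[:, cols].astype(np.float64)
        mu = block.mean(axis=0)
        centered = block - mu
        # full spectrum via SVD of the centered block
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        explained = svals ** 2 / max(n - 1, 1)
        r = choose_pc_count(explained, s_g=block.shape[1], n_train=n, threshold=threshold)
        comp = vt[:r]
        # sign convention: largest-|loading| entry positive
        for row in comp:
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                row *= -1.0
        means.append(mu)
        components.append(comp)
        ranks.append(r)
    return GenePCACodec(
        means=means,
        components=components,
        ranks=np.array(ranks, dtype=np.intp),
        gene_map=gene_map,
        depth=depth,
        ploidy_mode=train.ploidy_mode,
        threshold=threshold,
    )


def encode(matrix: GenotypeMatrix, codec: GenePCACodec) -> GeneEmbedding:
    """Project each gene's centered SNP block onto its retained components."""
    if matrix.n_snps != codec.n_snps:
        raise ValueError(
            f"SNP count mismatch: matrix has {matrix.n_snps}, codec expects {codec.n_snps}"
        )
    n = matrix.n_samples
    g_pad = codec.padded_genes
    tensor = np.zeros((n, g_pad, PC_WIDTH))
    for g in range(codec.n_genes):
        cols = codec.gene_map.snp_indices(g)
        centered = matrix.values[:, cols].astype(np.float64) - codec.means[g]
        r = int(codec.ranks[g])
        tensor[:, g, :r] = centered @ codec.components[g].T
    return GeneEmbedding(
        tensor=tensor,
        clamp_mask=codec.clamp_mask(),
        labels=matrix.labels.copy(),
        depth=codec.depth,
        n_genes=codec.n_genes,
    )


def decode(
    embedding: GeneEmbedding,
    codec: GenePCACodec,
    variants: list[Variant] | None = None,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Reconstruct allele counts: transpose-projection, add mean, round, clip."""
    if embedding.tensor.shape[1] != codec.padded_genes:
        raise ValueError("embedding gene-axis length does not match codec layout")
    if not np.array_equal(embedding.clamp_mask, codec.clamp_mask()):
        raise ValueError("embedding clamp mask does not match codec layout")
    n = embedding.n_samples
    hi = 2 if codec.ploidy_mode == PloidyMode.GENOTYPE else 1
    values = np.empty((n, codec.n_snps), dtype=np.int8)
    for g in range(codec.n_genes):
        cols = codec.gene_map.snp_indices(g)
        r = int(codec.ranks[g])
        recon = embedding.tensor[:, g, :r] @ codec.components[g] + codec.means[g]
        values[:, cols] = np.clip(np.rint(recon), 0, hi).astype(np.int8)
    if variants is None:
        variants = [Variant("chr1", i, "A", "C") for i in range(codec.n_snps)]
    if sample_ids is None:
        sample_ids = [f"D{i:05d}" for i in range(n)]
    return GenotypeMatrix(values, sample_ids, variants, embedding.labels, codec.ploidy_mode)


def genotype_mismatch_fraction(a: GenotypeMatrix, b: GenotypeMatrix) -> float:
    """Fraction of genotype entries on which two matrices disagree."""
    if a.values.shape != b.values.shape:
        raise ValueError("matrices must have identical shape")
    return float(np.mean(a.values != b.values))
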