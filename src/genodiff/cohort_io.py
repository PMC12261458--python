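"""Genotype/haplotype matrices, gene maps, and their on-disk formats.

A cohort is held as a :class:`GenotypeMatrix`: an ``n_samples x n_snps``
integer matrix of alternative-allele counts ({0,1,2} for diploid genotypes,
{0,1} for haplotypes) with per-sample class labels (disease status or
population index). SNP sites are tied to genes through a :class:`GeneMap`;
every SNP belongs to exactly one gene, which is the unit the PCA codec
compresses.

Supported formats: VCF v4.2 (GT field only, via cyvcf2 for reading) and a
human-inspectable TSV dialect (first column sample_id, second column label,
remaining columns one per variant). Positions are 1-based in VCF and
converted to 0-based, half-open intervals internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class PloidyMode(str, enum.Enum):
    GENOTYPE = "genotype"
    HAPLOTYPE = "haplotype"


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def key(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}:{self.alt}"

    @staticmethod
    def from_key(key: str) -> "Variant":
        chrom, pos, ref, alt = key.rsplit(":", 3)
        return Variant(chrom, int(pos) - 1, ref, alt)


@dataclass
class GenotypeMatrix:
    values: np.ndarray  # (n_samples, n_snps) int8
    sample_ids: list[str]
    variants: list[Variant]
    labels: np.ndarray  # (n_samples,) int
    ploidy_mode: PloidyMode = PloidyMode.GENOTYPE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n == 0:
            raise ValueError("empty sample list")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must equal n_samples")
        if len(self.variants) != m:
            raise ValueError("variants length must equal n_snps")
        hi = 2 if self.ploidy_mode == PloidyMode.GENOTYPE else 1
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > hi:
            raise ValueError(f"allele counts must lie in [0, {hi}] for {self.ploidy_mode.value} mode")
        by_chrom: dict[str, int] = {}
        for v in self.variants:
            if v.chrom in by_chrom and v.pos < by_chrom[v.chrom]:
                raise ValueError(f"variant positions not sorted on {v.chrom}")
            by_chrom[v.chrom] = v.pos

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            variants=self.variants,
            labels=self.labels[idx],
            ploidy_mode=self.ploidy_mode,
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GeneMap:
    genes: list[Gene]
    snp_to_gene: np.ndarray  # (n_snps,) gene index

    def __post_init__(self) -> None:
        self.snp_to_gene = np.asarray(self.snp_to_gene, dtype=np.intp)
        order = [(g.chrom, g.start) for g in self.genes]
        if order != sorted(order):
            raise ValueError("genes must be in genomic order (chromosome, start)")
        if len(self.snp_to_gene) and (
            self.snp_to_gene.min() < 0 or self.snp_to_gene.max() >= len(self.genes)
        ):
            raise ValueError("snp_to_gene indices out of range")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def snp_counts(self) -> np.ndarray:
        return np.bincount(self.snp_to_gene, minlength=len(self.genes))

    def snp_indices(self, gene_index: int) -> np.ndarray:
        return np.where(self.snp_to_gene == gene_index)[0]


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(variants: list[Variant], genes: list[Gene]) -> GeneMap:
    """Assign every SNP site to exactly one gene.

    A SNP inside exactly one gene interval goes to that gene. A SNP covered by
    several (overlapping) genes, or by none, goes to the gene on the same
    chromosome whose midpoint is nearest; ties break to the gene that comes
    first in genomic order.
    """
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start))
    genes_sorted = [genes[i] for i in order]
    by_chrom: dict[str, list[int]] = {}
    for gi, g in enumerate(genes_sorted):
        by_chrom.setdefault(g.chrom, []).append(gi)

    orphans = sorted({v.chrom for v in variants} - set(by_chrom))
    if orphans:
        raise ValueError(f"SNPs on chromosomes without genes: {orphans}")

    assignment = np.empty(len(variants), dtype=np.intp)
    cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for c, idxs in by_chrom.items():
        starts = np.array([genes_sorted[i].start for i in idxs])
        ends = np.array([genes_sorted[i].end for i in idxs])
        mids = np.array([genes_sorted[i].midpoint for i in idxs])
        cache[c] = (np.asarray(idxs), starts, ends, mids)

    for si, v in enumerate(variants):
        idxs, starts, ends, mids = cache[v.chrom]
        inside = np.where((starts <= v.pos) & (v.pos < ends))[0]
        if len(inside) == 1:
            assignment[si] = idxs[inside[0]]
        else:
            pool = inside if len(inside) > 1 else np.arange(len(idxs))
            d = np.abs(mids[pool] - v.pos)
            # np.argmin takes the first minimum: earlier gene in genomic order
            assignment[si] = idxs[pool[int(np.argmin(d))]]
    return GeneMap(genes=genes_sorted, snp_to_gene=assignment)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_LABEL_HEADER = "##genodiff_labels="


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str = "tsv_matrix") -> None:
    path = Path(path)
    if format == "tsv_matrix":
        _write_tsv(matrix, path)
    elif format == "vcf":
        _write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_genotypes(
    path: str | Path, format: str = "tsv_matrix", haplotypes: bool = False
) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_matrix":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path, haplotypes=haplotypes)
    raise ValueError(f"unknown format: {format!r}")


def _write_tsv(matrix: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        matrix.values,
        columns=[v.key() for v in matrix.variants],
    )
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"#ploidy={matrix.ploidy_mode.value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#ploidy="):
            raise ValueError(f"{path}: line 1: expected '#ploidy=' header")
        mode = PloidyMode(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    if df.columns[:2].tolist() != ["sample_id", "label"]:
        raise ValueError(f"{path}: line 2: expected columns sample_id, label, <variants...>")
    variants = [Variant.from_key(c) for c in df.columns[2:]]
    return GenotypeMatrix(
        values=df.iloc[:, 2:].to_numpy(dtype=np.int8),
        sample_ids=df["sample_id"].astype(str).tolist(),
        variants=variants,
        labels=df["label"].to_numpy(),
        ploidy_mode=mode,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    """Write GT-only VCF v4.2. Haplotype matrices must contain consecutive
    row pairs per individual (written as phased GT a|b)."""
    hap = matrix.ploidy_mode == PloidyMode.HAPLOTYPE
    if hap:
        if matrix.n_samples % 2:
            raise ValueError("haplotype matrix needs an even number of rows (two per individual)")
        pair_ids = []
        for i in range(0, matrix.n_samples, 2):
            a, b = matrix.sample_ids[i], matrix.sample_ids[i + 1]
            stem = a[:-2] if a.endswith("_A") and b.endswith("_B") else a
            pair_ids.append(stem)
            if matrix.labels[i] != matrix.labels[i + 1]:
                raise ValueError(f"haplotype pair rows {i},{i+1} disagree on label")
        col_ids = pair_ids
        labels = matrix.labels[::2]
    else:
        col_ids = matrix.sample_ids
        labels = matrix.labels

    contigs = sorted({v.chrom for v in matrix.variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(_LABEL_HEADER + ",".join(f"{s}:{l}" for s, l in zip(col_ids, labels)))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(col_ids))
    for j, v in enumerate(matrix.variants):
        col = matrix.values[:, j]
        if hap:
            gts = [f"{col[i]}|{col[i + 1]}" for i in range(0, len(col), 2)]
        else:
            gts = [["0/0", "0/1", "1/1"][x] for x in col]
        lines.append(
            f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path, haplotypes: bool = False) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    label_map: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith(_LABEL_HEADER):
            for item in line[len(_LABEL_HEADER):].split(","):
                s, l = item.rsplit(":", 1)
                label_map[s] = int(l)

    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic site {rec.CHROM}:{rec.POS} (record {rec_no})")
        variants.append(Variant(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        gts = rec.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(samples) if haplotypes else len(samples), dtype=np.int8)
        for si, gt in enumerate(gts):
            a, b, phased = int(gt[0]), int(gt[1]), bool(gt[2])
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[si]} at {rec.CHROM}:{rec.POS}"
                )
            if haplotypes:
                if not phased:
                    raise ValueError(
                        f"unphased call for sample {samples[si]} at {rec.CHROM}:{rec.POS}; "
                        "haplotype mode requires phased GT"
                    )
                col[2 * si], col[2 * si + 1] = a, b
            else:
                col[si] = a + b
        columns.append(col)
    if not variants:
        raise ValueError(f"{path}: no variant records")

    values = np.stack(columns, axis=1)
    if haplotypes:
        sample_ids = [f"{s}_{h}" for s in samples for h in ("A", "B")]
        labels = np.repeat([label_map.get(s, 0) for s in samples], 2)
        mode = PloidyMode.HAPLOTYPE
    else:
        sample_ids = samples
        labels = np.array([label_map.get(s, 0) for s in samples])
        mode = PloidyMode.GENOTYPE
    return GenotypeMatrix(values, sample_ids, variants, labels, mode)


# ---------------------------------------------------------------------------
# gene map files (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gene_map.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_genes_bed(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected 4 columns (chrom start end gene_id)")
            genes.append(Gene(parts[3], parts[0], int(parts[1]), int(parts[2])))
    return genes
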