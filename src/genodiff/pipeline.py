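"""End-to-end orchestration: simulate → embed → train → generate → decode → evaluate.

A pipeline run is a pure function of (config, seed): every stage draws its
randomness from child generators of one root seed, every produced file is
recorded in a :class:`RunManifest` with a SHA-256 checksum, and rerunning
with the same config reproduces deterministic stages bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifiers import ClassifierSpec, recovery_experiment
from .cohort_io import write_gene_map, write_genotypes
from .diffusion_core import DiffusionConfig, embedding_clip_bound, sample, train_denoiser
from .denoisers import build_denoiser
from .evaluation import duplicate_audit, privacy_loss
from .gene_embedding import (
    GeneEmbedding,
    decode,
    encode,
    fit_codec,
    genotype_mismatch_fraction,
    pad_gene_axis,
)
from .synthetic_cohort import CohortConfig, generate_genotypes


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    reports: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": sha256_file(path)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def toy_config(seed: int = 0) -> dict:
    """The documented desk-scale configuration: a 60-gene diploid cohort
    (padded to 64 genes at depth 3), T=200 diffusion, combined MLP+CNN
    denoiser. Runs end to end in minutes on one CPU core."""
    return {
        "seed": seed,
        "cohort": {
            "n_samples": 768,
            "n_genes": 60,
            "snps_per_gene": [5, 20],
            "max_rank": 4,
            "n_causal_genes": 30,
            "effect_size": 3.0,
            "liability_noise": 0.5,
            "genotype_error_rate": 0.002,
        },
        "codec": {"depth": 3, "threshold": 0.99},
        "diffusion": {
            "arch": "combined",
            "T": 200,
            # beta range rescaled so alpha_bar(T) matches the T=1000 default
            "beta_start": 1e-4,
            "beta_end": 0.1,
            "epochs": 150,
            "batch_size": 64,
            "learning_rate": 2e-3,
        },
        "test_fraction": 0.25,
        "classifiers": ["mlp"],
    }


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages in order, halting on the first error.

    Writes the simulated cohort, gene map, codec, embeddings, model
    checkpoint, decoded synthetic cohort, evaluation reports, and a manifest
    with checksums into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=seed, version=__version__)
    root = np.random.default_rng(seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("simulate", "split", "train", "generate", "evaluate", "classify"),
            root.integers(0, 2**31 - 1, size=6),
        )
    }
    manifest.reports["stage_seeds"] = stage_seeds

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    cohort_kwargs = {**config.get("cohort", {}), "seed": seed}
    if "snps_per_gene" in cohort_kwargs:
        cohort_kwargs["snps_per_gene"] = tuple(cohort_kwargs["snps_per_gene"])
    cohort_cfg = CohortConfig(**cohort_kwargs)
    cohort = generate_genotypes(cohort_cfg, np.random.default_rng(stage_seeds["simulate"]))
    write_genotypes(cohort.matrix, out / "cohort.tsv", "tsv_matrix")
    write_gene_map(cohort.gene_map, out / "genes.bed")
    manifest.record("cohort", out / "cohort.tsv")
    manifest.record("gene_map", out / "genes.bed")
    manifest.timings["simulate"] = time.perf_counter() - t0

    # --- split & embed ----------------------------------------------------
    t0 = time.perf_counter()
    n = cohort.matrix.n_samples
    rng_split = np.random.default_rng(stage_seeds["split"])
    perm = rng_split.permutation(n)
    n_test = int(round(config.get("test_fraction", 0.25) * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train_mx = cohort.matrix.subset(train_idx)
    test_mx = cohort.matrix.subset(test_idx)

    codec_cfg = config.get("codec", {})
    codec = fit_codec(
        train_mx,
        cohort.gene_map,
        depth=codec_cfg.get("depth", 3),
        threshold=codec_cfg.get("threshold", 0.99),
    )
    codec.save(out / "codec.npz")
    manifest.record("codec", out / "codec.npz")
    emb_train = encode(train_mx, codec)
    emb_test = encode(test_mx, codec)
    emb_train.save(out / "train_embedding.h5")
    emb_test.save(out / "test_embedding.h5")
    manifest.record("train_embedding", out / "train_embedding.h5")
    manifest.record("test_embedding", out / "test_embedding.h5")

    decoded = decode(encode(cohort.matrix, codec), codec, variants=cohort.matrix.variants)
    mismatch = genotype_mismatch_fraction(cohort.matrix, decoded)
    manifest.reports["codec"] = {
        "mismatch_pct": 100.0 * mismatch,
        "padded_genes": codec.padded_genes,
        "live_slots": int(codec.ranks.sum()),
    }
    manifest.timings["embed"] = time.perf_counter() - t0

    # --- train ------------------------------------------------------------
    t0 = time.perf_counter()
    diff_cfg_in = dict(config.get("diffusion", {}))
    arch = diff_cfg_in.pop("arch", "combined")
    diff_cfg = DiffusionConfig(depth=codec.depth, seed=seed, **diff_cfg_in)
    g_pad = pad_gene_axis(codec.n_genes, codec.depth)
    n_classes = int(cohort.matrix.labels.max()) + 1
    model = build_denoiser(arch, g_pad, codec.depth, n_classes, seed=seed)
    history = train_denoiser(
        model, emb_train, diff_cfg, rng=np.random.default_rng(stage_seeds["train"])
    )
    model.save(out / "model.npz", seed=seed, codec_fingerprint=sha256_file(out / "codec.npz"))
    manifest.record("model", out / "model.npz")
    log = history.to_frame()
    log.to_csv(out / "training_log.csv", index=False)
    manifest.record("training_log", out / "training_log.csv")
    manifest.reports["training"] = {
        "arch": arch,
        "first_loss": history.loss[0],
        "last_loss": history.loss[-1],
        "recon_series": list(history.recon_error),
        "n_parameters": model.n_parameters(),
    }
    manifest.timings["train"] = time.perf_counter() - t0

    # --- generate & decode ------------------------------------------------
    t0 = time.perf_counter()
    schedule = diff_cfg.schedule()
    rng_gen = np.random.default_rng(stage_seeds["generate"])
    per_class = [int((train_mx.labels == c).sum()) for c in range(n_classes)]
    clip_bound = embedding_clip_bound(emb_train)
    chunks, labels = [], []
    for c, n_c in enumerate(per_class):
        chunks.append(
            sample(model, n_c, c, schedule, emb_train.clamp_mask, rng_gen, x0_clip=clip_bound)
        )
        labels.extend([c] * n_c)
    syn_emb = GeneEmbedding(
        tensor=np.concatenate(chunks, axis=0),
        clamp_mask=emb_train.clamp_mask,
        labels=np.array(labels),
        depth=codec.depth,
        n_genes=codec.n_genes,
    )
    syn_emb.save(out / "synthetic_embedding.h5")
    manifest.record("synthetic_embedding", out / "synthetic_embedding.h5")
    syn_matrix = decode(syn_emb, codec, variants=cohort.matrix.variants)
    write_genotypes(syn_matrix, out / "synthetic_cohort.tsv", "tsv_matrix")
    manifest.record("synthetic_cohort", out / "synthetic_cohort.tsv")
    manifest.timings["generate"] = time.perf_counter() - t0

    # --- evaluate ---------------------------------------------------------
    t0 = time.perf_counter()
    eval_seed = stage_seeds["evaluate"]
    pl = privacy_loss(
        emb_train.live_values(), emb_test.live_values(), syn_emb.live_values(), seed=eval_seed
    )
    audit = duplicate_audit(emb_train.live_values(), syn_emb.live_values())
    manifest.reports["nnaa"] = {
        "aa_truth_train": pl.train_report.aa_truth,
        "aa_syn_train": pl.train_report.aa_syn,
        "aa_truth_test": pl.test_report.aa_truth,
        "aa_syn_test": pl.test_report.aa_syn,
        "privacy_loss": pl.privacy_loss,
        "privacy_loss_mean_aa": pl.privacy_loss_mean_aa,
    }
    manifest.reports["duplicates"] = {
        "min_distance": audit.min_distance,
        "duplicate_count": audit.duplicate_count,
    }
    manifest.timings["evaluate"] = time.perf_counter() - t0

    # --- classify (train-synthetic-test-real) -----------------------------
    t0 = time.perf_counter()
    specs = [
        ClassifierSpec(architecture=a, n_classes=n_classes, seed=stage_seeds["classify"] % 10000)
        for a in config.get("classifiers", ["mlp"])
    ]
    grid = recovery_experiment(emb_train, emb_test, {arch: syn_emb}, specs)
    grid.to_frame().to_csv(out / "recovery.csv", index=False)
    manifest.record("recovery", out / "recovery.csv")
    manifest.reports["recovery"] = {
        f"{g}/{c}": {"a_r": cell.a_r, "a_s": cell.a_s, "recovery": cell.recovery}
        for (g, c), cell in grid.cells.items()
    }
    manifest.timings["classify"] = time.perf_counter() - t0

    manifest.save(out / "manifest.json")
    return manifest
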