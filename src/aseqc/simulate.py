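"""Synthetic allelic-count cohorts with controlled contamination.

Samples are drawn from the same binomial logit-normal generative process the
estimator assumes: per gene, a depth t from a configurable law, a latent
reference ratio lambda with logit(lambda) ~ Normal(mu, sigma), and
r ~ Binomial(t, p).  Genotype-mismatch contamination mixes a fraction ``c`` of
reads from a second individual at the sample's heterozygous sites: at each
site the contaminator is hom-ref, het or hom-alt with configurable
probabilities, contributing an expected reference ratio of 1, a fresh
logit-normal draw, or 0 respectively, so

    p = (1 - c) * lambda + c * lambda_contaminator.

This emulates RNA/DNA mismatch contamination at the allelic-count level (the
quantity the dispersion score reacts to), not at the read level.

The canonical contamination design is a quadratic ladder of 21 levels,
(k/20)^2 for k = 0..20: 0%, 0.25%, 1%, 2.25%, ..., 100%.

Randomness: one master seed; each sample consumes an independent stream
spawned by a stable key, so enlarging a cohort never perturbs previously
generated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exceptions import ValidationError
from .io import GENE_COLUMNS, write_counts

__all__ = [
    "SimulationConfig",
    "simulate_sample",
    "simulate_variant_sample",
    "contamination_level_series",
    "simulate_benchmark_cohort",
    "write_benchmark_cohort",
]

_GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic sample (or a cohort of them).

    Defaults emulate a clean short-read cohort: 5000 informative genes per
    sample, mild reference bias (mu = 0.1 log allelic fold change), baseline
    extra-binomial dispersion sigma = 0.3, and per-gene depths uniform on
    [20, 200] so the default [5, 5000] total-count filter drops nothing.
    """

    n_genes: int = 5000
    mu: float = 0.1
    sigma: float = 0.3
    depth_law: tuple = ("uniform", 20, 200)
    contamination: float = 0.0
    contaminator_genotype_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int = 0
    n_samples: int = 1

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        if not (0.0 <= self.contamination <= 1.0):
            raise ValidationError("contamination must be in [0, 1]")
        probs = np.asarray(self.contaminator_genotype_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("contaminator_genotype_probs must be 3 probabilities summing to 1")
        if self.depth_law[0] not in ("uniform", "lognormal"):
            raise ValidationError(f"unknown depth law '{self.depth_law[0]}'")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "mu": self.mu,
            "sigma": self.sigma,
            "depth_law": list(self.depth_law),
            "contamination": self.contamination,
            "contaminator_genotype_probs": list(self.contaminator_genotype_probs),
            "seed": self.seed,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "depth_law" in d:
            d["depth_law"] = tuple(d["depth_law"])
        if "contaminator_genotype_probs" in d:
            d["contaminator_genotype_probs"] = tuple(d["contaminator_genotype_probs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stream_rng(seed: int, stream: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=stream))


def _draw_depths(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = int(law[1]), int(law[2])
        return rng.integers(lo, hi + 1, size=n)
    meanlog, sdlog = float(law[1]), float(law[2])
    t = np.round(rng.lognormal(meanlog, sdlog, size=n))
    return np.clip(t, 5, 5000).astype(np.int64)


def simulate_sample(
    config: SimulationConfig,
    sample_id: str = "S00",
    stream: tuple[int, ...] = (0,),
) -> pd.DataFrame:
    """Generate one sample's gene-level allelic counts.

    ``stream`` selects the sample's independent RNG substream under the
    config's master seed; the same (seed, stream) always reproduces the same
    records regardless of what else was generated.
    """
    rng = _stream_rng(config.seed, stream)
    n = config.n_genes
    t = _draw_depths(rng, config.depth_law, n)
    lam = expit(rng.normal(config.mu, config.sigma, size=n))

    c = config.contamination
    genotype = rng.choice(3, size=n, p=np.asarray(config.contaminator_genotype_probs))
    lam_het = expit(rng.normal(config.mu, config.sigma, size=n))
    lam_cont = np.choose(genotype, [np.ones(n), lam_het, np.zeros(n)])
    p = (1.0 - c) * lam + c * lam_cont

    r = rng.binomial(t, p)
    width = max(6, len(str(n)))
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "gene_id": [f"G{i:0{width}d}" for i in range(n)],
            "ref_count": r.astype(np.int64),
            "alt_count": (t - r).astype(np.int64),
            "total_count": t.astype(np.int64),
        }
    )[GENE_COLUMNS]


def simulate_variant_sample(
    config: SimulationConfig,
    sample_id: str = "S00",
    stream: tuple[int, ...] = (0,),
    max_variants_per_gene: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a phASER-style variant-level table plus its variant->gene map.

    Each gene carries 1..max_variants_per_gene heterozygous sites sharing the
    gene's latent ratio, each with its own depth, mirroring the situation the
    most-expressed-SNP aggregation rule resolves.  Returns (variants, map)
    where ``map`` has columns (variant_id, gene_id).
    """
    rng = _stream_rng(config.seed, stream + (1,))
    gene = simulate_sample(config, sample_id=sample_id, stream=stream)
    rows = []
    map_rows = []
    pos = 1000
    for _, g in gene.iterrows():
        n_var = int(rng.integers(1, max_variants_per_gene + 1))
        lam_hat = (g.ref_count + 0.5) / (g.total_count + 1.0)
        for v in range(n_var):
            t = int(_draw_depths(rng, config.depth_law, 1)[0])
            r = int(rng.binomial(t, lam_hat))
            vid = f"{g.gene_id}_v{v}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "contig": "chr1",
                    "position": pos,
                    "variant_id": vid,
                    "ref_allele": "A",
                    "alt_allele": "G",
                    "ref_count": r,
                    "alt_count": t - r,
                    "total_count": t,
                }
            )
            map_rows.append({"variant_id": vid, "gene_id": g.gene_id})
            pos += 1000
    return pd.DataFrame(rows), pd.DataFrame(map_rows)


def contamination_level_series() -> list[float]:
    """The 21-level quadratic contamination ladder (k/20)^2, k = 0..20.

    First four values: 0, 0.0025, 0.01, 0.0225; last: 1.0.
    """
    return [(k / 20.0) ** 2 for k in range(21)]


def simulate_benchmark_cohort(
    config: SimulationConfig, levels: list[float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``config.n_samples`` samples at each contamination level.

    Returns (records, truth) where truth has columns (sample_id, level).
    Streams are keyed by (level index, replicate index), so extending either
    axis leaves existing samples bit-identical.
    """
    if levels is None:
        levels = contamination_level_series()
    frames = []
    truth = []
    for li, level in enumerate(levels):
        level_config = replace(config, contamination=float(level))
        for rep in range(config.n_samples):
            sid = f"L{li:02d}R{rep:02d}"
            frames.append(simulate_sample(level_config, sample_id=sid, stream=(li, rep)))
            truth.append({"sample_id": sid, "level": float(level)})
    records = pd.concat(frames, ignore_index=True)
    return records, pd.DataFrame(truth)


def write_benchmark_cohort(
    config: SimulationConfig, out_prefix, levels: list[float] | None = None
) -> dict[str, Path]:
    """Write a benchmark cohort: long-format counts, truth table and config YAML."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_benchmark_cohort(config, levels=levels)
    paths = {
        "counts": Path(f"{out_prefix}.counts.tsv"),
        "truth": Path(f"{out_prefix}.truth.tsv"),
        "config": Path(f"{out_prefix}.config.yaml"),
    }
    write_counts(records, paths["counts"], dialect="long")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    config.to_yaml(paths["config"])
    return paths
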