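"""Synthetic cage-level RNA-seq experiments with planted ground truth.

The generator emulates the structure of a two-stock (Pol-line, Russian) by
four-diet (sucrose-only reference plus three protein/lipid diets: pollen,
Chlorella, spirulina) hoarding-cage study. Each library is one cage pool.
Counts are negative binomial with a parametric dispersion-mean trend
``Var = mu + alpha(mu) mu^2``, ``alpha(mu) = a0 + a1/mu``; on the log2 mean
scale genes receive a uniform baseline, gene-specific colony random
intercepts, a protein/lipid diet program, a stock program with lncRNA-biased
membership, a stock-specific viral multiplier, and a weight program driven
by a per-cage latent nutritional score ``z`` that also drives the cage's
mean head+thorax dry mass.

The emitted :class:`GroundTruth` records every planted membership so that
downstream recovery tests (differential expression, random-forest and SVM
feature selection, enrichment) can score themselves against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CountMatrix,
    read_counts,
    read_samples,
    write_annotation,
    write_counts,
    write_samples,
)

REFERENCE_DIET = "sugar"

_VIRUS_NAMES = ("DWV_A", "DWV_B", "ABPV", "IAPV", "SBV")


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Design constants and effect sizes of a synthetic cage experiment.

    Defaults reproduce the study layout: 4 Pol-line + 3 Russian source
    colonies, 4 cages per colony per diet, 4 diets -> 112 cage libraries.
    Effect sizes (log2 units) and the weight model (mg) are simulator
    parameters with field-realistic defaults, not measured values.
    """

    n_genes: int = 12000
    n_colonies_per_stock: int | Mapping[str, int] = field(
        default_factory=lambda: {"pol_line": 4, "russian": 3}
    )
    cages_per_colony_per_diet: int = 4
    stocks: Sequence[str] = ("pol_line", "russian")
    diets: Sequence[str] = ("sugar", "pollen", "chlorella", "spirulina")
    frac_lncRNA: float = 0.15
    n_viral: int = 5
    n_diet_program: int = 3000
    diet_lfc: float = 1.0
    n_stock_program: int = 600
    stock_lfc: float = 0.8
    lncRNA_bias: float = 4.0
    n_weight_program: int = 300
    weight_beta: float = 2.0
    weight_noise_sd: float = 1.0
    weight_baseline_mg: float = 25.0
    baseline_logmean_range: tuple[float, float] = (1.0, 9.0)
    dispersion_a0: float = 0.05
    dispersion_a1: float = 2.0
    libsize_lognormal_sd: float = 0.3
    colony_sd: float = 0.2
    viral_stock_lfc: float = -1.5
    seed: int = 0

    def colonies_for(self, stock: str) -> int:
        if isinstance(self.n_colonies_per_stock, Mapping):
            try:
                return int(self.n_colonies_per_stock[stock])
            except KeyError:
                raise ConfigError(f"n_colonies_per_stock missing stock {stock!r}")
        return int(self.n_colonies_per_stock)

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "cages_per_colony_per_diet": self.cages_per_colony_per_diet,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1 (got {v})")
        for stock in self.stocks:
            if self.colonies_for(stock) < 1:
                raise ConfigError(f"need >= 1 colony for stock {stock!r}")
        if not 0 < self.frac_lncRNA < 1:
            raise ConfigError("frac_lncRNA must be in (0, 1)")
        if list(self.diets).count(REFERENCE_DIET) != 1:
            raise ConfigError(f"diets must include exactly one {REFERENCE_DIET!r}")
        if len(self.stocks) != 2:
            raise ConfigError("exactly two stocks are supported")
        if self.n_viral < 0 or self.n_viral >= self.n_genes:
            raise ConfigError("n_viral must be in [0, n_genes)")
        n_regular = self.n_genes - self.n_viral
        for name, size in (
            ("n_diet_program", self.n_diet_program),
            ("n_stock_program", self.n_stock_program),
            ("n_weight_program", self.n_weight_program),
        ):
            if size < 0 or size > n_regular:
                raise ConfigError(
                    f"{name}={size} exceeds the {n_regular} non-viral genes"
                )
        if self.lncRNA_bias <= 0:
            raise ConfigError("lncRNA_bias must be positive")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 < 0:
            raise ConfigError("dispersion trend requires a0 > 0, a1 >= 0")
        lo, hi = self.baseline_logmean_range
        if not lo < hi:
            raise ConfigError("baseline_logmean_range must be (lo, hi) with lo < hi")


@dataclass
class GroundTruth:
    """Planted memberships and latent variables emitted by the simulator."""

    diet_program: set[str]
    stock_program: set[str]
    weight_program: set[str]
    lncRNA_ids: set[str]
    viral_ids: set[str]
    latent_score_per_cage: pd.Series
    true_weights_mg: pd.Series

    def to_json(self) -> str:
        payload = {
            "diet_program": sorted(self.diet_program),
            "stock_program": sorted(self.stock_program),
            "weight_program": sorted(self.weight_program),
            "lncRNA_ids": sorted(self.lncRNA_ids),
            "viral_ids": sorted(self.viral_ids),
            "latent_score_per_cage": self.latent_score_per_cage.to_dict(),
            "true_weights_mg": self.true_weights_mg.to_dict(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            diet_program=set(d["diet_program"]),
            stock_program=set(d["stock_program"]),
            weight_program=set(d["weight_program"]),
            lncRNA_ids=set(d["lncRNA_ids"]),
            viral_ids=set(d["viral_ids"]),
            latent_score_per_cage=pd.Series(d["latent_score_per_cage"]),
            true_weights_mg=pd.Series(d["true_weights_mg"]),
        )


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    samples: pd.DataFrame
    truth: GroundTruth

    def __post_init__(self) -> None:
        if list(self.counts.sample_ids) != list(self.samples["sample_id"]):
            raise ValueError("count columns must align with sample table rows")


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for stock in config.stocks:
        for c in range(config.colonies_for(stock)):
            colony = f"{stock}_col{c + 1}"
            for diet in config.diets:
                for cage in range(config.cages_per_colony_per_diet):
                    rows.append(
                        {
                            "sample_id": f"{stock}.{diet}.{colony}.cage{cage + 1}",
                            "stock": stock,
                            "diet": diet,
                            "colony": colony,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_experiment(config: SimConfig) -> SyntheticDataset:
    """Draw one synthetic experiment; bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    samples = _sample_table(config)
    n_samples = len(samples)

    n_viral = config.n_viral
    viral_ids = [
        _VIRUS_NAMES[i] if i < len(_VIRUS_NAMES) else f"virus_{i + 1}"
        for i in range(n_viral)
    ]
    n_regular = config.n_genes - n_viral
    width = max(5, len(str(n_regular)))
    regular_ids = [f"gene_{i + 1:0{width}d}" for i in range(n_regular)]
    gene_ids = viral_ids + regular_ids

    is_lnc = np.zeros(config.n_genes, dtype=bool)
    lnc_mask_regular = rng.random(n_regular) < config.frac_lncRNA
    is_lnc[n_viral:] = lnc_mask_regular
    biotype = np.where(is_lnc, "lncRNA", "protein_coding")
    biotype[:n_viral] = "viral"

    regular_idx = np.arange(n_viral, config.n_genes)
    diet_idx = rng.choice(regular_idx, size=config.n_diet_program, replace=False)
    # lncRNA-biased membership of the stock program (odds multiplier)
    w = np.where(is_lnc[regular_idx], config.lncRNA_bias, 1.0)
    stock_idx = rng.choice(
        regular_idx, size=config.n_stock_program, replace=False, p=w / w.sum()
    )
    weight_idx = rng.choice(regular_idx, size=config.n_weight_program, replace=False)

    baseline = rng.uniform(*config.baseline_logmean_range, size=config.n_genes)

    # per-gene effect signs/magnitudes
    diet_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    stock_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    gamma = rng.uniform(0.3, 0.7, size=config.n_genes)  # log2 per unit z

    colonies = samples["colony"].unique()
    colony_offsets = {
        col: rng.normal(0.0, config.colony_sd, size=config.n_genes)
        for col in colonies
    }

    is_pl = (samples["diet"] != REFERENCE_DIET).to_numpy()
    z = rng.normal(np.where(is_pl, 1.0, 0.0), 1.0)
    weight_noise = rng.normal(0.0, config.weight_noise_sd, size=n_samples)
    true_weight = config.weight_baseline_mg + config.weight_beta * z
    observed_weight = np.maximum(true_weight + weight_noise, 0.1)

    in_diet = np.zeros(config.n_genes, dtype=bool)
    in_diet[diet_idx] = True
    in_stock = np.zeros(config.n_genes, dtype=bool)
    in_stock[stock_idx] = True
    in_weight = np.zeros(config.n_genes, dtype=bool)
    in_weight[weight_idx] = True
    is_viral = np.zeros(config.n_genes, dtype=bool)
    is_viral[:n_viral] = True

    alt_stock = config.stocks[1]
    log2mu = np.empty((config.n_genes, n_samples))
    for j in range(n_samples):
        row = samples.iloc[j]
        lm = baseline + colony_offsets[row["colony"]]
        if row["diet"] != REFERENCE_DIET:
            lm = lm + np.where(in_diet, diet_sign * config.diet_lfc, 0.0)
        if row["stock"] == alt_stock:
            lm = lm + np.where(in_stock, stock_sign * config.stock_lfc, 0.0)
            lm = lm + np.where(is_viral, config.viral_stock_lfc, 0.0)
        lm = lm + np.where(in_weight, gamma * z[j], 0.0)
        log2mu[:, j] = lm

    mu = np.exp2(log2mu)
    libsize_factor = np.exp(
        rng.normal(0.0, config.libsize_lognormal_sd, size=n_samples)
    )
    mean = mu * libsize_factor[None, :]
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu
    # NB with Var = m + alpha m^2: shape n = 1/alpha, p = n / (n + m)
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mean)
    counts = rng.negative_binomial(n_param, p_param)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"]),
        pd.Series(biotype, index=gene_ids),
    )
    samples = samples.assign(weight_mg=observed_weight)
    sample_index = pd.Index(samples["sample_id"])
    truth = GroundTruth(
        diet_program={gene_ids[i] for i in diet_idx},
        stock_program={gene_ids[i] for i in stock_idx},
        weight_program={gene_ids[i] for i in weight_idx},
        lncRNA_ids={g for g, l in zip(gene_ids, is_lnc) if l},
        viral_ids=set(viral_ids),
        latent_score_per_cage=pd.Series(z, index=sample_index),
        true_weights_mg=pd.Series(true_weight, index=sample_index),
    )
    return SyntheticDataset(cm, samples, truth)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write counts TSV, samples CSV, annotation TSV and truth JSON.

    Round-trips losslessly through :func:`read_fixture`.
    """
    if dataset.counts.n_genes == 0:
        raise ValueError("refusing to write a fixture with no genes")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.csv",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth.json",
    }
    write_counts(dataset.counts, paths["counts"])
    write_samples(dataset.samples, paths["samples"])
    write_annotation(dataset.counts, paths["annotation"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    cm = read_counts(directory / "counts.tsv", directory / "annotation.tsv")
    samples = read_samples(directory / "samples.csv")
    truth = GroundTruth.from_json((directory / "truth.json").read_text())
    return SyntheticDataset(cm, samples, truth)


def config_from_yaml(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "baseline_logmean_range" in raw:
        raw["baseline_logmean_range"] = tuple(raw["baseline_logmean_range"])
    return SimConfig(**raw)
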