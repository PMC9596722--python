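"""Synthetic two-group microarray cohorts with planted structure.

The generator emulates the statistical shape of the harmonized GSE75010
cohorts: per gene, log2 expression is Gaussian with a group-specific mean
and SD (independent across genes by default), group sizes default to the
published 77/80 and 96/77, and the 17 circadian candidate genes take the
published per-group means and SDs.  On top of that it can add null
background genes, gene sets whose members share a common case shift (in
SD units) to create pathway-level signal, an optional equicorrelation
block inside each planted set, and preterm flags (independent of
expression unless a preterm-specific shift is requested).

All randomness flows from an explicit integer seed; the same config and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .io import ExpressionMatrix, GeneSetCollection, PhenotypeTable, normalize_gene


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GeneSimSpec:
    """Per-gene group means and SDs on the log2 scale."""

    gene_id: str
    mu_control: float
    mu_case: float
    sigma_control: float
    sigma_case: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_id", normalize_gene(self.gene_id))
        if not (np.isfinite(self.mu_control) and np.isfinite(self.mu_case)):
            raise ConfigError(f"{self.gene_id}: means must be finite")
        if self.sigma_control <= 0 or self.sigma_case <= 0:
            raise ConfigError(f"{self.gene_id}: sigmas must be strictly positive")


@dataclass(frozen=True)
class PlantedSetSpec:
    """A gene set whose members share a common case shift (SD units)."""

    name: str
    genes: tuple[str, ...]
    shift: float  # mu_case = mu_control + shift * sigma, per member gene

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(normalize_gene(g) for g in self.genes))
        if not np.isfinite(self.shift):
            raise ConfigError(f"planted set {self.name}: shift must be finite")
        if not self.genes:
            raise ConfigError(f"planted set {self.name}: no genes")


@dataclass(frozen=True)
class CohortSimConfig:
    n_control: int
    n_case: int
    gene_specs: tuple[GeneSimSpec, ...] = ()
    n_background_genes: int = 0
    background_mean_range: tuple[float, float] = (6.0, 10.0)
    background_sd_range: tuple[float, float] = (0.25, 0.75)
    preterm_fraction_control: float = 0.0
    preterm_fraction_case: float = 0.0
    planted_sets: tuple[PlantedSetSpec, ...] = ()
    equicorrelation_rho: float = 0.0  # within each planted set
    preterm_shift: Mapping[str, float] = field(default_factory=dict)
    cohort_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ConfigError("group sizes must be >= 2")
        for name, frac in (
            ("preterm_fraction_control", self.preterm_fraction_control),
            ("preterm_fraction_case", self.preterm_fraction_case),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.equicorrelation_rho < 1.0:
            raise ConfigError("equicorrelation_rho must lie in [0, 1)")
        names = [s.gene_id for s in self.gene_specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate gene ids in gene_specs")


def table1_defaults(
    dataset: str | int,
    seed: int = 0,
    n_background_genes: int = 0,
    **overrides,
) -> CohortSimConfig:
    """Simulation config matching a published GSE75010 cohort.

    ``dataset`` is ``"157"``, ``"173"`` or ``"157-term"``; gene specs
    carry the published per-group means/SDs of the 17 circadian genes and
    group sizes are (77, 80), (96, 77) or (42, 31) respectively.
    """
    key = str(dataset)
    if key not in reference.GENE_STATS:
        raise ConfigError(
            f"unknown dataset {dataset!r}; choose from {sorted(reference.GENE_STATS)}"
        )
    n_control, n_case = reference.GROUP_SIZES[key]
    specs = tuple(
        GeneSimSpec(g, mu_c, mu_p, sd_c, sd_p)
        for g, (mu_c, sd_c, mu_p, sd_p) in reference.GENE_STATS[key].items()
    )
    cfg = CohortSimConfig(
        n_control=n_control,
        n_case=n_case,
        gene_specs=specs,
        n_background_genes=n_background_genes,
        cohort_label=f"GSE75010-{key}-synthetic",
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def gene_spec(config: CohortSimConfig, gene: str) -> GeneSimSpec:
    """Look up one gene's simulation spec."""
    gene = normalize_gene(gene)
    for spec in config.gene_specs:
        if spec.gene_id == gene:
            return spec
    raise KeyError(gene)


def _resolve_specs(config: CohortSimConfig, rng: np.random.Generator) -> list[GeneSimSpec]:
    """Materialize the full gene list: explicit, background, planted."""
    specs = list(config.gene_specs)
    known = {s.gene_id for s in specs}
    lo, hi = config.background_mean_range
    slo, shi = config.background_sd_range
    for i in range(config.n_background_genes):
        name = f"BG{i + 1:05d}"
        if name in known:
            raise ConfigError(f"background gene name collides: {name}")
        mu = float(rng.uniform(lo, hi))
        sd = float(rng.uniform(slo, shi))
        specs.append(GeneSimSpec(name, mu, mu, sd, sd))  # null gene
        known.add(name)
    by_name = {s.gene_id: i for i, s in enumerate(specs)}
    for pset in config.planted_sets:
        for g in pset.genes:
            if g in by_name:
                i = by_name[g]
                s = specs[i]
                specs[i] = GeneSimSpec(
                    s.gene_id, s.mu_control,
                    s.mu_control + pset.shift * s.sigma_control,
                    s.sigma_control, s.sigma_case,
                )
            else:
                mu = float(rng.uniform(lo, hi))
                sd = float(rng.uniform(slo, shi))
                specs.append(
                    GeneSimSpec(g, mu, mu + pset.shift * sd, sd, sd)
                )
                by_name[g] = len(specs) - 1
    return specs


def simulate_cohort(config: CohortSimConfig) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Draw one cohort: a log2 expression matrix and its phenotype table.

    Control samples come first (S0001..), then cases.  Per gene, values
    are independent Gaussians with the group-specific mean/SD; inside a
    planted set, a positive ``equicorrelation_rho`` mixes in a shared
    per-sample factor (Gaussian copula construction) without changing the
    marginal means/SDs.
    """
    rng = np.random.default_rng(config.seed)
    specs = _resolve_specs(config, rng)
    n_c, n_p = config.n_control, config.n_case
    n_total = n_c + n_p
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    conditions = ["non-PE"] * n_c + ["PE"] * n_p

    # standard-normal draws, then scaled per group
    Z = rng.standard_normal((len(specs), n_total))
    rho = config.equicorrelation_rho
    if rho > 0 and config.planted_sets:
        idx = {s.gene_id: i for i, s in enumerate(specs)}
        for pset in config.planted_sets:
            rows = [idx[g] for g in pset.genes]
            shared = rng.standard_normal(n_total)
            Z[rows] = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * Z[rows]

    mu = np.array(
        [[s.mu_control] * n_c + [s.mu_case] * n_p for s in specs]
    )
    sigma = np.array(
        [[s.sigma_control] * n_c + [s.sigma_case] * n_p for s in specs]
    )
    X = mu + sigma * Z

    preterm = np.concatenate(
        [
            rng.random(n_c) < config.preterm_fraction_control,
            rng.random(n_p) < config.preterm_fraction_case,
        ]
    )
    if config.preterm_shift:
        idx = {s.gene_id: i for i, s in enumerate(specs)}
        for gene, shift in config.preterm_shift.items():
            g = normalize_gene(gene)
            if g not in idx:
                raise ConfigError(f"preterm_shift gene {g} not simulated")
            X[idx[g], preterm] += shift

    values = pd.DataFrame(X, index=[s.gene_id for s in specs], columns=sample_ids)
    expr = ExpressionMatrix(values, cohort_label=config.cohort_label)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "condition": conditions,
                "preterm": preterm,
                "dataset_id": config.cohort_label,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return expr, pheno


def planted_genesets(config: CohortSimConfig) -> GeneSetCollection:
    """The planted sets of a config as a gene-set collection."""
    return GeneSetCollection(
        {p.name: (f"planted shift {p.shift:+g} SD", p.genes) for p in config.planted_sets}
    )


def simulate_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    gene_pool: Sequence[str],
    seed: int = 0,
    prefix: str = "RANDSET",
) -> GeneSetCollection:
    """Random gene sets sampled without replacement within each set."""
    lo, hi = set_size_range
    pool = [normalize_gene(g) for g in gene_pool]
    if not pool:
        raise ConfigError("gene pool is empty")
    if lo < 1 or hi < lo:
        raise ConfigError("invalid set size range")
    if hi > len(pool):
        raise ConfigError(
            f"requested set size up to {hi} exceeds pool size {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=size, replace=False)
        sets[f"{prefix}_{i + 1:03d}"] = (
            f"random set of {size}",
            tuple(pool[j] for j in members),
        )
    return GeneSetCollection(sets)
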