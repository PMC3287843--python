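"""Synthetic mini-exome generator with known ground truth.

Emulates the structure of an exome-like case-control resource: several
subpopulations, a rare-skewed allele-frequency spectrum, genes of
variable SNP counts, a small causal-gene subset with per-SNP effect
sizes, and many binary phenotype replicates drawn on one fixed genotype
matrix.

The mechanisms are deliberately simple and fully disclosed:

* ancestral minor-allele frequencies are drawn from a rare-skewed Beta
  distribution;
* per-population frequencies follow the Balding-Nichols model, a Beta
  with mean q and variance F_st * q * (1 - q);
* dominant-coded genotypes are Bernoulli draws of the diploid carrier
  probability 1 - (1 - q)^2;
* disease status follows a logistic liability with per-population
  intercepts (equal unless confounding is enabled) plus the sum of
  carried causal effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import GenotypePanel, GeneMap, PhenotypeReplicates, build_gene_map, compute_maf

logger = logging.getLogger("rvbench")

#: Beta shape parameters of the ancestral MAF spectrum.  The second
#: shape was solved so that 87.2% of frequencies fall below 0.05,
#: matching the rare-variant share of a typical mini-exome panel.
MAF_SPECTRUM = (0.25, 12.12)
#: frequencies below this are redrawn (effectively monomorphic sites)
MIN_ANCESTRAL_MAF = 0.001

_REPLICATE_RETRY_CAP = 100


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror the full-scale study design this generator
    emulates: 697 individuals in 7 subpopulations, ~3,205 genes with a
    mean of ~7.6 SNPs each, ~1.1% of genes causal, and 200 phenotype
    replicates on one fixed genotype matrix.  `scaled_profile` gives the
    small test-size counterpart.
    """

    n_individuals: int = 697
    population_sizes: tuple[int, ...] = (100, 100, 100, 100, 100, 100, 97)
    F_st: float = 0.10
    n_genes: int = 3205
    gene_size_min: int = 1
    gene_size_max: int = 50
    gene_size_mean: float = 7.6
    maf_spectrum: tuple[float, float] = MAF_SPECTRUM
    causal_gene_fraction: float = 0.0115
    causal_snps_per_gene: tuple[int, int] = (1, 8)
    beta_range: tuple[float, float] = (0.5, 2.0)
    prevalence_baseline: tuple[float, ...] | None = None  # logit intercepts/pop
    baseline_prevalence: float = 0.30
    nonsynonymous_fraction: float = 0.55
    n_replicates: int = 200
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self):
        if sum(self.population_sizes) != self.n_individuals:
            raise ValueError("population sizes must sum to n_individuals")
        if not 0 <= self.F_st < 1:
            raise ValueError("F_st must be in [0, 1)")
        if not 0 <= self.causal_gene_fraction <= 1:
            raise ValueError("causal_gene_fraction must be in [0, 1]")

    @property
    def n_populations(self) -> int:
        return len(self.population_sizes)

    def intercepts(self) -> np.ndarray:
        """Per-population logistic intercepts (equal by default)."""
        if self.prevalence_baseline is not None:
            if len(self.prevalence_baseline) != self.n_populations:
                raise ValueError("prevalence_baseline length must match populations")
            return np.asarray(self.prevalence_baseline, dtype=float)
        base = float(np.log(self.baseline_prevalence / (1 - self.baseline_prevalence)))
        return np.full(self.n_populations, base)


def scaled_profile(**overrides) -> SimConfig:
    """Scaled-down profile keeping the full pipeline fast: 200
    individuals in 2 populations, 150 genes, 20 replicates."""
    params = dict(
        n_individuals=200,
        population_sizes=(100, 100),
        F_st=0.10,
        n_genes=150,
        n_replicates=20,
        n_chromosomes=6,
        causal_gene_fraction=0.08,
    )
    params.update(overrides)
    return SimConfig(**params)


def null_profile(**overrides) -> SimConfig:
    """Unconfounded null: one population, no causal SNPs."""
    params = dict(
        n_individuals=200,
        population_sizes=(200,),
        F_st=0.0,
        n_genes=150,
        n_replicates=20,
        n_chromosomes=6,
        causal_gene_fraction=0.0,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def _gene_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """SNPs per gene: shifted Poisson clipped to [min, max]."""
    lam = max(config.gene_size_mean - config.gene_size_min, 0.0)
    sizes = config.gene_size_min + rng.poisson(lam, size=config.n_genes)
    return np.clip(sizes, config.gene_size_min, config.gene_size_max)


def draw_population_frequencies(config: SimConfig, rng: np.random.Generator | None = None,
                                n_snps: int | None = None):
    """Ancestral and per-population minor-allele frequencies.

    Returns ``(q, pop_freq)`` with `q` of length n_snps and `pop_freq`
    of shape (n_populations, n_snps).  Per-population frequencies follow
    Balding-Nichols: Beta(q(1-F)/F, (1-q)(1-F)/F); F_st = 0 copies the
    ancestral frequency exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if n_snps is None:
        n_snps = int(_gene_sizes(config, np.random.default_rng(config.seed)).sum())
    a, b = config.maf_spectrum
    q = rng.beta(a, b, size=n_snps)
    bad = (q < MIN_ANCESTRAL_MAF) | (q > 0.5)
    while bad.any():
        q[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (q < MIN_ANCESTRAL_MAF) | (q > 0.5)
    F = config.F_st
    if F == 0.0:
        pop = np.tile(q, (config.n_populations, 1))
    else:
        scale = (1.0 - F) / F
        pop = rng.beta(
            np.tile(q * scale, (config.n_populations, 1)),
            np.tile((1.0 - q) * scale, (config.n_populations, 1)),
        )
    return q, np.clip(pop, 0.0, 1.0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def generate_genotypes(config: SimConfig, frequencies=None):
    """Simulate the fixed genotype matrix and its annotation.

    Returns ``(panel, annotation, gene_map, truth)`` where `truth`
    additionally carries ancestral and per-population frequencies.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _gene_sizes(config, rng)
    n_snps = int(sizes.sum())
    if frequencies is None:
        q, pop_freq = draw_population_frequencies(config, rng, n_snps=n_snps)
    else:
        q, pop_freq = frequencies
        if pop_freq.shape != (config.n_populations, len(q)) or len(q) != n_snps:
            raise ValueError("frequencies inconsistent with config")

    pop_labels = np.repeat(
        [f"pop{k + 1}" for k in range(config.n_populations)], config.population_sizes
    )
    # diploid carrier probability per individual x SNP
    pop_index = np.repeat(np.arange(config.n_populations), config.population_sizes)
    carrier_p = 1.0 - (1.0 - pop_freq[pop_index]) ** 2
    calls = (rng.random(carrier_p.shape) < carrier_p).astype(np.int8)

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_individuals)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    gene_ids = np.repeat([f"gene{g + 1:04d}" for g in range(config.n_genes)], sizes)
    # genes spread across chromosomes so cross-chromosome pairs exist
    gene_chrom = np.array(
        [f"chr{(g % config.n_chromosomes) + 1}" for g in range(config.n_genes)]
    )
    chrom = np.repeat(gene_chrom, sizes)

    n_causal_genes = int(round(config.causal_gene_fraction * config.n_genes))
    causal_genes = rng.choice(config.n_genes, size=n_causal_genes, replace=False)
    causal = np.zeros(n_snps, dtype=bool)
    beta = np.zeros(n_snps)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    lo, hi = config.causal_snps_per_gene
    for g in causal_genes:
        start, stop = offsets[g], offsets[g + 1]
        k = min(int(rng.integers(lo, hi + 1)), stop - start)
        chosen = rng.choice(np.arange(start, stop), size=k, replace=False)
        causal[chosen] = True
        beta[chosen] = rng.uniform(*config.beta_range, size=k)

    nonsyn = rng.random(n_snps) < config.nonsynonymous_fraction
    nonsyn |= causal  # causal variants are functional by construction

    sample_maf = np.array([compute_maf(calls[:, j]) for j in range(n_snps)])
    annotation = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chrom,
            "gene_id": gene_ids,
            "maf": sample_maf,
            "nonsynonymous": nonsyn,
            "causal": causal,
            "beta": beta,
        }
    )
    panel = GenotypePanel(sample_ids=sample_ids, snp_ids=snp_ids, calls=calls)
    gene_map = build_gene_map(panel, annotation)
    truth = annotation.copy()
    truth["ancestral_q"] = q
    for k in range(config.n_populations):
        truth[f"q_pop{k + 1}"] = pop_freq[k]
    return panel, annotation, gene_map, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_replicates(panel: GenotypePanel, annotation: pd.DataFrame,
                        config: SimConfig) -> PhenotypeReplicates:
    """Draw binary phenotype replicates on the fixed genotypes.

    Individual i in population k is affected with probability
    ``logistic(intercept_k + sum_j causal beta_j * call_ij)``.  Each
    replicate has its own seed derived from the master seed; replicates
    with zero cases or zero controls are redrawn (logged) up to a cap.
    """
    ann = annotation.set_index("snp_id")
    causal_cols = np.flatnonzero(ann["causal"].reindex(panel.snp_ids).to_numpy())
    beta = ann["beta"].reindex(panel.snp_ids).to_numpy()[causal_cols]
    intercepts = config.intercepts()
    pop_index = np.repeat(np.arange(config.n_populations), config.population_sizes)
    eta = intercepts[pop_index]
    if causal_cols.size:
        eta = eta + panel.calls[:, causal_cols].astype(float) @ beta
    prob = expit(eta)

    statuses = np.empty((config.n_replicates, panel.n_samples), dtype=np.int8)
    master = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    for r, child in enumerate(master.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        for attempt in range(_REPLICATE_RETRY_CAP):
            draw = (rng.random(panel.n_samples) < prob).astype(np.int8)
            if 0 < draw.sum() < panel.n_samples:
                break
            logger.warning("replicate %d: degenerate draw, retrying", r)
        else:
            raise RuntimeError(f"replicate {r}: could not draw a mixed phenotype")
        statuses[r] = draw

    ethnicity = list(
        np.repeat([f"pop{k + 1}" for k in range(config.n_populations)],
                  config.population_sizes)
    )
    return PhenotypeReplicates(
        replicate_ids=[f"rep{r + 1:03d}" for r in range(config.n_replicates)],
        statuses=statuses,
        ethnicity=ethnicity,
    )


def confounding_scenario(config: SimConfig, strength: float) -> SimConfig:
    """Spread per-population prevalence intercepts by +/- `strength`.

    Effect sizes are untouched; strength 0 returns the config unchanged,
    so matched confounded/unconfounded runs differ only in intercepts.
    The spread is symmetric around the baseline intercept.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return config
    base = config.intercepts()
    spread = np.linspace(-strength, strength, config.n_populations)
    return replace(config, prevalence_baseline=tuple(base + spread))


def simulate_dataset(config: SimConfig):
    """Full draw: genotypes, annotation, gene map, truth table, replicates."""
    panel, annotation, gene_map, truth = generate_genotypes(config)
    replicates = simulate_replicates(panel, annotation, config)
    return panel, annotation, gene_map, truth, replicates
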