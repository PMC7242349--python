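"""Synthetic genomic-selection data with controlled outlier contamination.

The generator emulates an F2 experimental cross: every chromosome carries
equi-spaced biallelic markers, each individual inherits two gametes whose
allele states form a first-order Markov chain with Haldane recombination
between adjacent markers, and the genotype is the allele dosage in {0, 1, 2}.
Phenotypes are additive in a small set of QTL (markers chosen among the
simulated ones, Cockerham-style centered coding) plus Gaussian noise scaled
so the realized narrow-sense heritability matches the requested target.
Contamination replaces a fixed fraction of phenotypes by values pushed
beyond mean +/- `outlier_margin` standard deviations, recording ground truth
so detector recall/precision can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "SimulationConfig",
    "MarkerMap",
    "TruthRecord",
    "haldane_recombination",
    "simulate_genotypes",
    "simulate_phenotype",
    "inject_outliers",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults reproduce the reference simulation design: 200 individuals,
    1000 markers on 10 chromosomes of 100 cM, heritability 0.5 and 5 % of
    phenotypes contaminated beyond +/- 3 SD.
    """

    n_individuals: int = 200
    n_chromosomes: int = 10
    markers_per_chromosome: int = 100
    chromosome_length: float = 100.0  # cM
    n_qtl: int = 10
    qtl_effect_scale: float = 1.0
    heritability: float = 0.5
    outlier_fraction: float = 0.05
    outlier_margin: float = 3.0  # SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ConfigurationError("need at least one chromosome and one marker")
        if self.chromosome_length < 0:
            raise ConfigurationError("chromosome_length must be non-negative")
        if not 0.0 < self.heritability < 1.0:
            raise ConfigurationError("heritability must lie strictly in (0, 1)")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ConfigurationError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_margin <= 0:
            raise ConfigurationError("outlier_margin must be positive")
        if self.n_qtl < 1 or self.n_qtl > self.n_markers:
            raise ConfigurationError("n_qtl must lie in [1, total marker count]")
        if self.qtl_effect_scale <= 0:
            raise ConfigurationError("qtl_effect_scale must be positive")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass(frozen=True)
class MarkerMap:
    """Genetic map: per-marker chromosome index (1-based) and position in cM."""

    chromosome: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.chromosome) != len(self.position_cm):
            raise ConfigurationError("chromosome and position arrays differ in length")
        for c in np.unique(self.chromosome):
            pos = self.position_cm[self.chromosome == c]
            if np.any(np.diff(pos) < 0):
                raise ConfigurationError(f"positions decrease within chromosome {c}")

    def __len__(self) -> int:
        return len(self.chromosome)


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset (QTL model and contamination)."""

    qtl_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    qtl_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    genetic_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    outlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    original_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "outlier_indices": self.outlier_indices.tolist(),
            "original_values": self.original_values.tolist(),
        }


def haldane_recombination(distance_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction r = (1 - exp(-2 d / 100)) / 2 for map distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_cm, dtype=float) / 100.0))


def _marker_positions(config: SimulationConfig) -> MarkerMap:
    m = config.markers_per_chromosome
    if m == 1:
        pos_one = np.array([config.chromosome_length / 2.0])
    else:
        pos_one = np.linspace(0.0, config.chromosome_length, m)
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), m)
    pos = np.tile(pos_one, config.n_chromosomes)
    return MarkerMap(chromosome=chrom, position_cm=pos)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, MarkerMap]:
    """Simulate F2 allele dosages in {0,1,2} for ``config.n_markers`` markers.

    Each of the two gametes per individual is a Markov chain along every
    chromosome: the allele at the first marker is Bernoulli(1/2) and switches
    between adjacent markers with the Haldane probability for their spacing.
    Markers at identical positions are therefore perfectly linked.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    marker_map = _marker_positions(config)
    m = config.markers_per_chromosome
    r = haldane_recombination(np.diff(marker_map.position_cm[:m]))  # shared spacing

    chunks = []
    for _ in range(config.n_chromosomes):
        # allele state of both gametes at every marker, shape (n, 2, m)
        first = rng.random((n, 2, 1)) < 0.5
        if m > 1:
            switches = rng.random((n, 2, m - 1)) < r
            states = np.concatenate([first, switches], axis=2)
            alleles = np.bitwise_xor.accumulate(states, axis=2)
        else:
            alleles = first
        chunks.append(alleles.sum(axis=1, dtype=np.int64))
    genotypes = np.concatenate(chunks, axis=1)
    return genotypes, marker_map


def simulate_phenotype(
    genotypes: np.ndarray,
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Additive phenotype y = sum_q a_q (g_q - 1) + e at the target heritability.

    QTL are placed at marker positions, spread round-robin over chromosomes;
    effects are N(0, qtl_effect_scale^2).  The residual variance is set to
    Var(g) (1 - h^2) / h^2 so that Var(g) / Var(y) targets ``heritability``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, p = genotypes.shape
    if p != len(marker_map):
        raise ConfigurationError("genotype matrix and marker map disagree on marker count")

    per_chrom = [np.flatnonzero(marker_map.chromosome == c) for c in
                 range(1, config.n_chromosomes + 1)]
    qtl = np.empty(config.n_qtl, dtype=int)
    for q in range(config.n_qtl):
        qtl[q] = rng.choice(per_chrom[q % config.n_chromosomes])
    qtl = np.sort(qtl)
    effects = rng.normal(0.0, config.qtl_effect_scale, size=config.n_qtl)

    # Cockerham additive coding: dosage centered at the F2 expectation (1)
    g = (genotypes[:, qtl] - 1.0) @ effects
    var_g = g.var()
    if var_g == 0:
        raise ConfigurationError(
            "genetic variance is zero (all QTL monomorphic); use another seed or more QTL"
        )
    sigma_e = np.sqrt(var_g * (1.0 - config.heritability) / config.heritability)
    y = g + rng.normal(0.0, sigma_e, size=n)
    truth = TruthRecord(qtl_indices=qtl, qtl_effects=effects, genetic_values=g)
    return y, truth


def inject_outliers(
    phenotype: np.ndarray,
    fraction: float,
    margin: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replace round(fraction * n) entries by values beyond mean +/- margin * SD.

    A replaced value is mu + s (margin + u) sigma with random sign s and
    u ~ Uniform(0, 1), where mu and sigma are the mean/SD of the input vector,
    so every contaminated entry exceeds the margin strictly but boundedly.

    Returns (contaminated vector, contaminated indices, original values).
    """
    if not 0.0 <= fraction < 0.5:
        raise ConfigurationError("outlier fraction must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float).copy()
    n = len(y)
    k = int(np.floor(fraction * n + 0.5))  # round half-up; 5% of 200 -> exactly 10
    if k == 0:
        return y, np.empty(0, dtype=int), np.empty(0)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    mu, sigma = y.mean(), y.std()
    signs = rng.choice([-1.0, 1.0], size=k)
    u = rng.random(k)
    u[u == 0.0] = np.finfo(float).tiny  # keep the margin strict
    originals = y[idx].copy()
    y[idx] = mu + signs * (margin + u) * sigma
    return y, idx, originals


def simulate_dataset(config: SimulationConfig):
    """Full generator: genotypes, map, contaminated phenotype and ground truth.

    Returns a :class:`~gslens.pipeline_io.GSDataset` plus a :class:`TruthRecord`.
    All draws come from a single seeded stream, so a config reproduces its
    dataset bit-for-bit.
    """
    from .pipeline_io import GSDataset  # deferred: pipeline_io imports are heavier

    rng = np.random.default_rng(config.seed)
    genotypes, marker_map = simulate_genotypes(config, rng)
    y_clean, truth = simulate_phenotype(genotypes, marker_map, config, rng)
    y, out_idx, originals = inject_outliers(
        y_clean, config.outlier_fraction, config.outlier_margin, rng
    )
    truth = dataclasses.replace(truth, outlier_indices=out_idx, original_values=originals)
    individual_ids = [f"ind{i + 1}" for i in range(config.n_individuals)]
    marker_ids = [
        f"chr{c}_m{j + 1}"
        for c in range(1, config.n_chromosomes + 1)
        for j in range(config.markers_per_chromosome)
    ]
    dataset = GSDataset(
        individual_ids=individual_ids,
        marker_ids=marker_ids,
        genotypes=genotypes.astype(float),
        phenotype=y,
        marker_map=marker_map,
    )
    return dataset, truth
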