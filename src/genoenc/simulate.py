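"""Synthetic genotype/trait generator.

Markers are independent biallelic loci in Hardy-Weinberg proportions with
minor-allele frequencies drawn uniformly from a configured range.  The
trait signal is parameterized as *category means* rather than dosage
coefficients: each causal marker contributes a genotypic value per
category, with homozygotes at ``-a`` and ``+a`` (sign optionally
randomized) and the heterozygote at the additive midpoint, perturbed for a
configurable fraction of causal markers ("dominance degree").  That
parameterization spans the regimes where the plain ordinal encoding is
optimal (purely additive) through those where trait-aware encodings help
(heterogeneous effect sizes, dominance, mixed signs).  Optional pairwise
epistasis adds product-style interaction values among causal markers.

Gaussian noise is scaled so the realized heritability matches the target:
``sigma_e^2 = var(g) * (1 - h2) / h2``.  Everything is reproducible from
the config seed; genotypes and trait use separate child streams so either
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, TraitVector, ValidationError


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the package's reference benchmark: 300 samples,
    200 markers of which 60 are causal, half the causal markers with a
    dominance deviation, randomized effect signs, heritability 0.6.
    """

    n: int = 300
    m: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 60
    additive_scale: float = 1.0
    dominance_degree: float = 0.5
    dominance_scale: float = 1.0
    sign_mixing: bool = True
    epistatic_pairs: int = 0
    epistasis_scale: float = 0.5
    h2: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must sit inside (0, 0.5]")
        if not 0 < self.n_causal <= self.m:
            raise ValidationError("n_causal must be in [1, m]")
        if not 0 < self.h2 <= 1:
            raise ValidationError("heritability must be in (0, 1]")
        if not 0 <= self.dominance_degree <= 1:
            raise ValidationError("dominance_degree must be in [0, 1]")
        if self.epistatic_pairs < 0 or self.epistatic_pairs > (
            self.n_causal * (self.n_causal - 1) // 2
        ):
            raise ValidationError("epistatic_pairs exceeds causal pair count")


@dataclass(frozen=True)
class SimulationTruth:
    """Generative values behind a simulated trait."""

    causal_markers: tuple[str, ...]
    category_values: dict[str, tuple[float, float, float]]
    pair_values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    sigma_e_sq: float = 0.0
    realized_h2: float = 1.0
    seed: int = 0


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Independent markers in Hardy-Weinberg proportions, seeded."""
    rng = _rng(cfg, 0)
    q = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.m)
    p0 = (1 - q) ** 2
    p1 = 2 * q * (1 - q)
    r = rng.random((cfg.n, cfg.m))
    values = ((r > p0) .astype(np.int8) + (r > p0 + p1).astype(np.int8))
    return GenotypeMatrix(
        tuple(f"s{i:05d}" for i in range(cfg.n)),
        tuple(f"m{j:05d}" for j in range(cfg.m)),
        values,
    )


def simulate_trait(
    G: GenotypeMatrix, cfg: SimulationConfig
) -> tuple[TraitVector, SimulationTruth]:
    """Draw a trait over ``G`` per the config's genetic architecture."""
    if G.n_markers != cfg.m or G.n_samples != cfg.n:
        raise ValidationError("genotype matrix does not match the config")
    rng = _rng(cfg, 1)
    causal = np.sort(rng.choice(cfg.m, cfg.n_causal, replace=False))
    a = cfg.additive_scale * np.abs(rng.normal(size=cfg.n_causal))
    sign = (
        rng.choice([-1.0, 1.0], size=cfg.n_causal)
        if cfg.sign_mixing
        else np.ones(cfg.n_causal)
    )
    dominant = rng.random(cfg.n_causal) < cfg.dominance_degree
    het_dev = np.where(
        dominant, rng.normal(size=cfg.n_causal) * cfg.dominance_scale * a, 0.0
    )
    vcat = np.column_stack([-sign * a, het_dev, sign * a])  # (n_causal, 3)

    gvals = vcat[np.arange(cfg.n_causal)[np.newaxis, :], G.values[:, causal]]
    genetic = gvals.sum(axis=1)

    pair_values: dict[tuple[str, str], np.ndarray] = {}
    if cfg.epistatic_pairs:
        # unordered pairs among causal markers, product-style cell values
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < cfg.epistatic_pairs:
            i, j = rng.choice(cfg.n_causal, 2, replace=False)
            chosen.add((min(i, j), max(i, j)))
        base = np.outer([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        for i, j in sorted(chosen):
            w = cfg.epistasis_scale * rng.normal()
            grid = w * base
            ids = (G.marker_ids[causal[i]], G.marker_ids[causal[j]])
            pair_values[ids] = grid
            genetic = genetic + grid[G.values[:, causal[i]], G.values[:, causal[j]]]

    var_g = float(genetic.var())
    if np.ptp(genetic) == 0:
        raise ValidationError(
            "simulated genetic variance is zero (no polymorphic causal marker)"
        )
    if cfg.h2 < 1:
        sigma_e_sq = var_g * (1 - cfg.h2) / cfg.h2
        noise = rng.normal(0.0, np.sqrt(sigma_e_sq), cfg.n)
    else:
        sigma_e_sq = 0.0
        noise = np.zeros(cfg.n)
    y = genetic + noise
    realized_h2 = var_g / float(y.var())
    truth = SimulationTruth(
        causal_markers=tuple(G.marker_ids[j] for j in causal),
        category_values={
            G.marker_ids[causal[c]]: tuple(float(v) for v in vcat[c])
            for c in range(cfg.n_causal)
        },
        pair_values=pair_values,
        sigma_e_sq=float(sigma_e_sq),
        realized_h2=float(realized_h2),
        seed=cfg.seed,
    )
    return TraitVector(G.sample_ids, y), truth


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, TraitVector, SimulationTruth]:
    """Convenience: genotypes and trait from one config."""
    G = simulate_genotypes(cfg)
    y, truth = simulate_trait(G, cfg)
    return G, y, truth
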