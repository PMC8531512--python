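"""Synthetic multi-environment wheat trial generator.

Produces genotypes and replicated plot phenotypes with *known* additive,
environmental, genotype-by-environment and residual components, so that
every downstream stage (QC, GRM, REML, heritability, cross-validation)
can be verified against ground truth.

The generative model for a plot value is

    y_ijk = env_mean_i + g_j + gE_ij + eps_ijk

where ``g`` is driven by ``n_qtl`` markers with i.i.d. normal effects,
rescaled post hoc so the realized genic variance equals ``var_g``
exactly; ``gE`` is drawn i.i.d. per (line, environment) with variance
``var_ge`` (compound-symmetric interaction, independent across
environments); and ``eps`` is i.i.d. per plot with variance ``var_e``.

Genotypes are unlinked biallelic SNPs in Hardy-Weinberg proportions with
allele frequencies drawn from ``maf_range`` and positions placed
uniformly along the chromosomes (no linkage disequilibrium, no pedigree
structure -- see the package methods note for what that implies).

The default configuration emulates the structure of a CIMMYT spring
wheat panel: 141 lines, 14,563 SNPs on the 21 wheat chromosomes, four
environments (two locations x two years), two replicates, with grain
yield variance components (0.05, 0.15, 0.33) on the ton/ha scale.
Named presets cover the other traits and smaller test scenarios.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SimulationTruth",
    "WHEAT_CHROMOSOMES",
    "WHEAT_CHROM_LENGTHS_MB",
    "PRESETS",
    "get_preset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_trial",
]


class ConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


#: the 21 bread wheat chromosomes with approximate physical lengths (Mb)
WHEAT_CHROMOSOMES = [
    "1A", "1B", "1D", "2A", "2B", "2D", "3A", "3B", "3D", "4A", "4B", "4D",
    "5A", "5B", "5D", "6A", "6B", "6D", "7A", "7B", "7D",
]
WHEAT_CHROM_LENGTHS_MB = [
    594.0, 689.0, 495.0, 780.0, 801.0, 651.0, 750.0, 830.0, 615.0, 744.0,
    673.0, 509.0, 709.0, 713.0, 566.0, 618.0, 720.0, 473.0, 736.0, 750.0,
    638.0,
]


@dataclass(frozen=True)
class SimulationConfig:
    """Trial dimensions and true variance components.

    Defaults describe the emulated wheat panel (141 lines, 14,563 SNPs,
    4 environments, 2 replicates) with grain-yield-like components.
    """

    n_lines: int = 141
    n_markers: int = 14563
    n_chromosomes: int = 21
    chrom_lengths: tuple = tuple(WHEAT_CHROM_LENGTHS_MB)
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    n_environments: int = 4
    n_reps: int = 2
    env_means: tuple | None = (7.87, 8.76, 7.06, 7.26)
    var_g: float = 0.05
    var_ge: float = 0.15
    var_e: float = 0.33
    n_qtl: int = 300
    trait: str = "GRYLD"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_markers", "n_chromosomes", "n_environments", "n_reps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigError("chrom_lengths length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigError("chrom_lengths must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must lie in (0, 0.5] with lo <= hi")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for name in ("var_g", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ConfigError("n_qtl must satisfy 0 <= n_qtl <= n_markers")
        if self.n_qtl == 0 and self.var_g > 0:
            raise ConfigError("n_qtl is 0 but var_g > 0: genetic variance unattainable")
        if self.env_means is not None and len(self.env_means) != self.n_environments:
            raise ConfigError("env_means length must equal n_environments")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def environments(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_environments)]

    @property
    def resolved_env_means(self) -> np.ndarray:
        if self.env_means is None:
            return np.zeros(self.n_environments)
        return np.asarray(self.env_means, dtype=float)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated trial, for recovery tests."""

    marker_effects: np.ndarray          # per-marker additive effect (0 off-QTL)
    true_gebv: pd.Series                # per line, overall breeding value g
    true_env_deviation: pd.DataFrame    # lines x environments gE draws
    realized_h2_within: pd.Series       # per environment, from realized variances
    realized_h2_across: float
    config: SimulationConfig = field(repr=False, default=None)


def _rng_children(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(3)]


def _complete_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeMatrix:
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, config.n_markers)
    dosages = rng.binomial(2, p, size=(config.n_lines, config.n_markers)).astype(float)

    lengths = np.asarray(config.chrom_lengths, dtype=float)
    weights = lengths / lengths.sum()
    chrom_idx = rng.choice(config.n_chromosomes, size=config.n_markers, p=weights)
    pos = rng.uniform(0.0, lengths[chrom_idx])
    order = np.lexsort((pos, chrom_idx))
    dosages = dosages[:, order]
    if config.n_chromosomes == 21:
        chrom_names = np.array(WHEAT_CHROMOSOMES)
    else:
        chrom_names = np.array([f"chr{i + 1}" for i in range(config.n_chromosomes)])
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{i + 1:06d}" for i in range(config.n_markers)],
            "chromosome": chrom_names[chrom_idx[order]],
            "position": pos[order],
        }
    )
    line_ids = np.array([f"L{i + 1:04d}" for i in range(config.n_lines)])
    return GenotypeMatrix(dosages, line_ids, markers)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate unlinked SNP dosages, deterministically under the seed."""
    rng_geno, rng_mask, _ = _rng_children(config.seed)
    g = _complete_genotypes(config, rng_geno)
    if config.missing_rate > 0:
        mask = rng_mask.random(g.dosages.shape) < config.missing_rate
        g.dosages[mask] = np.nan
    return g


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Simulate replicated plot phenotypes forward from the genotypes.

    Requires complete (imputed) genotypes; the genetic values are linear
    in the marker dosages, rescaled so that the sample variance of g over
    lines equals ``var_g`` exactly.
    """
    if np.isnan(genotypes.dosages).any():
        raise ValueError("genotypes contain missing calls; impute first or simulate "
                         "with missing_rate=0")
    if genotypes.n_markers != config.n_markers or genotypes.n_lines != config.n_lines:
        raise ConfigError("genotype dimensions do not match n_lines/n_markers")
    if config.var_g == config.var_ge == config.var_e == 0 and config.n_reps < 2:
        warnings.warn(
            "all variance components are zero with a single replicate: "
            "heritability is undefined downstream",
            stacklevel=2,
        )

    rng = _rng_children(config.seed)[2]
    L, E, R = config.n_lines, config.n_environments, config.n_reps

    beta = np.zeros(config.n_markers)
    if config.var_g > 0:
        qtl = rng.choice(config.n_markers, size=config.n_qtl, replace=False)
        raw = rng.normal(size=config.n_qtl)
        Wc = genotypes.dosages[:, qtl] - genotypes.dosages[:, qtl].mean(axis=0)
        g_raw = Wc @ raw
        sd = g_raw.std(ddof=1)
        if sd == 0:
            raise ConfigError("var_g > 0 but QTL genotypes carry no variation "
                              "(n_lines or maf_range too small)")
        scale = np.sqrt(config.var_g) / sd
        beta[qtl] = raw * scale
        g = g_raw * scale
    else:
        if config.n_qtl > 0:
            rng.choice(config.n_markers, size=config.n_qtl, replace=False)
            rng.normal(size=config.n_qtl)  # keep the stream aligned
        g = np.zeros(L)

    gE = rng.normal(0.0, np.sqrt(config.var_ge), size=(L, E))
    eps = rng.normal(0.0, np.sqrt(config.var_e), size=(E, R, L))
    env_means = config.resolved_env_means

    values = env_means[:, None, None] + g[None, None, :] + gE.T[:, None, :] + eps
    envs = config.environments
    records = pd.DataFrame(
        {
            "environment": np.repeat(envs, R * L),
            "rep": np.tile(np.repeat(np.arange(1, R + 1), L), E),
            "genotype": np.tile(genotypes.line_ids, E * R),
            "trait": config.trait,
            "value": values.ravel(),
        }
    )
    table = PhenotypeTable(records)

    var = lambda x: float(np.var(x, ddof=1)) if np.size(x) > 1 else 0.0
    h2_within = {}
    for i, env in enumerate(envs):
        vg_i = var(g + gE[:, i])
        ve_i = var(eps[i])
        denom = vg_i + ve_i / R
        h2_within[env] = vg_i / denom if denom > 0 else np.nan
    vg, vge, ve = var(g), var(gE), var(eps)
    denom = vg + vge / E + ve / (E * R)
    h2_across = vg / denom if denom > 0 else np.nan

    truth = SimulationTruth(
        marker_effects=beta,
        true_gebv=pd.Series(g, index=genotypes.line_ids, name="gebv"),
        true_env_deviation=pd.DataFrame(gE, index=genotypes.line_ids, columns=envs),
        realized_h2_within=pd.Series(h2_within),
        realized_h2_across=h2_across,
        config=config,
    )
    return table, truth


def simulate_trial(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, SimulationTruth]:
    """Genotypes, phenotypes and truth in one call.

    Phenotypes are always computed from the complete genotypes; the
    missingness mask is applied to the returned genotype matrix
    afterwards, so the truth does not depend on ``missing_rate``.
    """
    rng_geno, rng_mask, _ = _rng_children(config.seed)
    g = _complete_genotypes(config, rng_geno)
    table, truth = simulate_phenotypes(g, config)
    if config.missing_rate > 0:
        mask = rng_mask.random(g.dosages.shape) < config.missing_rate
        g.dosages[mask] = np.nan
    return g, table, truth


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

_BASE = SimulationConfig()

#: Scenario presets addressable by name.  The ``wheat-*`` presets carry the
#: emulated panel's dimensions with each trait's across-environment variance
#: components and per-environment means; ``gxe-*`` are the scheme-comparison
#: scenarios (moderate/high within-environment heritability with
#: var_g / var_ge >= 2); ``small-test`` is a fast end-to-end scenario and
#: ``zero-noise`` a degenerate one with heritability exactly 1.
PRESETS: dict[str, SimulationConfig] = {
    "wheat-gryld": _BASE,
    "wheat-dthd": _BASE.replace(
        trait="DTHD", var_g=8.94, var_ge=2.29, var_e=3.74,
        env_means=(81.96, 79.26, 94.85, 103.71),
    ),
    "wheat-daysmt": _BASE.replace(
        trait="DAYSMT", var_g=4.00, var_ge=1.94, var_e=2.83,
        env_means=(124.82, 124.67, 148.73, 144.52),
    ),
    "wheat-tgw": _BASE.replace(
        trait="TGW", var_g=9.90, var_ge=7.41, var_e=7.10,
        env_means=(54.66, 46.22, 45.48, 44.30),
    ),
    "gxe-moderate-h2": _BASE.replace(
        trait="SIM_M", n_markers=2000, n_qtl=300,
        var_g=1.0, var_ge=0.5, var_e=2.0, env_means=(10.0, 11.0, 9.5, 10.5),
    ),
    "gxe-high-h2": _BASE.replace(
        trait="SIM_H", n_markers=2000, n_qtl=300,
        var_g=1.0, var_ge=0.25, var_e=0.7, env_means=(10.0, 11.0, 9.5, 10.5),
    ),
    "small-test": _BASE.replace(
        trait="SIM_S", n_lines=100, n_markers=1000, n_chromosomes=5,
        chrom_lengths=(100.0,) * 5, n_qtl=100,
        var_g=1.0, var_ge=0.5, var_e=2.0, env_means=(10.0, 11.0, 9.5, 10.5),
    ),
    "zero-noise": _BASE.replace(
        trait="SIM_Z", n_lines=100, n_markers=500, n_chromosomes=5,
        chrom_lengths=(100.0,) * 5, n_qtl=100,
        var_g=1.0, var_ge=0.0, var_e=0.0, env_means=(10.0, 11.0, 9.5, 10.5),
    ),
}


def get_preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    """Look up a preset by name, optionally overriding the seed or fields."""
    try:
        config = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if seed is not None:
        overrides["seed"] = seed
    return config.replace(**overrides) if overrides else config
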