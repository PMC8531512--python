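"""Stage-1 phenotypic analysis of replicated multi-environment trials.

Two random-effects models are fitted to plot-level data by REML, with
the grand mean as the only fixed effect:

within one environment
    y_ik = mu + Rep_i + Gen_k + e_ik

across environments
    y_ijk = mu + Env_i + Rep_j(Env_i) + Gen_k + (Env x Gen)_ik + e_ijk

All non-mean terms are random with identity kernels.  Balanced complete
grids are solved exactly through the orthogonal-strata restricted
likelihood (fast, with Fisher-information standard errors); unbalanced
data fall back to the EM-REML engine, which handles missing plots
natively.  Genotype BLUPs come from the mixed-model equations at the
REML estimates.

Broad-sense heritability at the entry-mean level:

    H2_within = s2_g / (s2_g + s2_e / nReps)
    H2_across = s2_g / (s2_g + s2_ge / nEnvs + s2_e / (nEnvs * nReps))

Genetic correlations between traits are Pearson correlations among
across-environment genotype BLUPs (the META-R convention); phenotypic
correlations are Pearson correlations among raw genotype means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import mixed_model as mm

__all__ = [
    "PHENOTYPE_COLUMNS",
    "PhenotypeTable",
    "VarianceComponents",
    "TrialModelFit",
    "CorrelationTables",
    "PCASummary",
    "UndefinedHeritabilityError",
    "fit_within_env",
    "fit_across_env",
    "heritability_within",
    "heritability_across",
    "trait_correlations",
    "trait_pca",
]

PHENOTYPE_COLUMNS = ["environment", "rep", "genotype", "trait", "value"]


class UndefinedHeritabilityError(ZeroDivisionError):
    """All variance components are zero: heritability is undefined."""


@dataclass
class PhenotypeTable:
    """Long-format plot records: environment, rep, genotype, trait, value."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        self.data = self.data[PHENOTYPE_COLUMNS].reset_index(drop=True)
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise ValueError("phenotype values must be finite")
        key = ["environment", "rep", "genotype", "trait"]
        if self.data.duplicated(subset=key).any():
            raise ValueError("duplicate (environment, rep, genotype, trait) records")

    @classmethod
    def read_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def environments(self) -> list:
        return sorted(self.data["environment"].unique())

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique())

    def subset(self, trait=None, environment=None) -> pd.DataFrame:
        df = self.data
        if trait is not None:
            if trait not in set(df["trait"]):
                raise KeyError(f"trait {trait!r} not in table")
            df = df[df["trait"] == trait]
        if environment is not None:
            if environment not in set(df["environment"]):
                raise KeyError(f"environment {environment!r} not in table")
            df = df[df["environment"] == environment]
        return df


@dataclass
class VarianceComponents:
    """REML variance components of a trial model (all clamped >= 0)."""

    sigma2_g: float
    sigma2_e: float
    sigma2_ge: float | None = None
    n_envs: int = 1
    n_reps: int = 1
    extras: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma2_ge is not None and self.sigma2_ge < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class TrialModelFit:
    kind: str  # "within_env" | "across_env"
    trait: str
    mu: float
    blups: pd.Series
    components: VarianceComponents
    environment: str | None = None
    rep_effects: pd.Series | None = None
    env_effects: pd.Series | None = None
    interaction: pd.Series | None = None  # MultiIndex (environment, genotype)
    loglik: float = np.nan
    converged: bool = True
    method: str = ""
    log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability_within(v: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability within one environment."""
    denom = v.sigma2_g + v.sigma2_e / v.n_reps
    if denom <= 0:
        raise UndefinedHeritabilityError("sigma2_g + sigma2_e/nReps is zero")
    return v.sigma2_g / denom


def heritability_across(v: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability across environments."""
    s2ge = 0.0 if v.sigma2_ge is None else v.sigma2_ge
    denom = v.sigma2_g + s2ge / v.n_envs + v.sigma2_e / (v.n_envs * v.n_reps)
    if denom <= 0:
        raise UndefinedHeritabilityError("all variance components are zero")
    return v.sigma2_g / denom


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------


def _codes(values) -> tuple[np.ndarray, np.ndarray]:
    cats = pd.Categorical(values)
    return cats.codes.astype(int), cats.categories.to_numpy()


def _onehot(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _solve_mme(y, factors, s2e):
    """Henderson's mixed-model equations with identity kernels.

    ``factors`` is a list of (name, codes, n_levels, sigma2).  Terms with
    zero variance are dropped (their BLUPs are exactly zero).  Returns
    (mu, {name: blup array}).
    """
    n = len(y)
    # floor keeps the equations well-conditioned in the noiseless limit
    s2e = max(s2e, 1e-8 * max(float(np.var(y)), 1.0))
    blocks = [sp.csr_matrix(np.ones((n, 1)))]
    active = [(name, c, q, s2) for name, c, q, s2 in factors if s2 > 0]
    for _, codes, q, _ in active:
        blocks.append(_onehot(codes, q))
    W = sp.hstack(blocks, format="csr")
    C = (W.T @ W).tolil()
    offset = 1
    for _, _, q, s2 in active:
        lam = s2e / s2
        for i in range(q):
            C[offset + i, offset + i] += lam
        offset += q
    sol = spsolve(C.tocsc(), W.T @ y)
    sol = np.atleast_1d(sol)
    mu = float(sol[0])
    blups = {}
    offset = 1
    for name, _, q, _ in active:
        blups[name] = sol[offset : offset + q]
        offset += q
    for name, _, q, _ in factors:
        if name not in blups:
            blups[name] = np.zeros(q)
    return mu, blups


def _is_complete_grid(df: pd.DataFrame, keys: list[str]) -> bool:
    sizes = df.groupby(keys, observed=True).size()
    n_cells = int(np.prod([df[k].nunique() for k in keys]))
    return len(sizes) == n_cells and bool((sizes == 1).all())


# ---------------------------------------------------------------------------
# within-environment model
# ---------------------------------------------------------------------------


def fit_within_env(p: PhenotypeTable, environment, trait) -> TrialModelFit:
    """REML fit of y = mu + Rep + Gen + e for one trait in one environment."""
    df = p.subset(trait=trait, environment=environment)
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    R = df["rep"].nunique()
    if R < 2:
        warnings.warn(
            "fewer than two replicates: genotype and residual variances are "
            "confounded and heritability is undefined",
            stacklevel=2,
        )

    if R >= 2 and _is_complete_grid(df, ["rep", "genotype"]):
        return _fit_within_balanced(df, environment, trait)
    return _fit_within_em(df, environment, trait)


def _fit_within_balanced(df, environment, trait) -> TrialModelFit:
    pv = df.pivot(index="rep", columns="genotype", values="value")
    Y = pv.to_numpy()
    R, L = Y.shape
    ybar = Y.mean()
    rep_m = Y.mean(axis=1)
    gen_m = Y.mean(axis=0)
    ss_rep = L * float(((rep_m - ybar) ** 2).sum())
    ss_gen = R * float(((gen_m - ybar) ** 2).sum())
    resid = Y - rep_m[:, None] - gen_m[None, :] + ybar
    ss_res = float((resid**2).sum())

    dims = np.array([R - 1, L - 1, (R - 1) * (L - 1)])
    ssv = np.array([ss_rep, ss_gen, ss_res])
    coef = np.array([[L, 0, 1], [0, R, 1], [0, 0, 1]], dtype=float)
    fit = mm.reml_from_strata(dims, ssv, coef, ["rep", "genotype", "residual"])
    s2_rep, s2_g, s2_e = fit.components
    se = dict(zip(fit.names, fit.std_errors()))

    codes_rep, levels_rep = _codes(df["rep"])
    codes_gen, levels_gen = _codes(df["genotype"])
    mu, blups = _solve_mme(
        df["value"].to_numpy(dtype=float),
        [("rep", codes_rep, R, s2_rep), ("genotype", codes_gen, L, s2_g)],
        s2_e,
    )
    vc = VarianceComponents(
        sigma2_g=float(s2_g), sigma2_e=float(s2_e), n_envs=1, n_reps=R,
        extras={"sigma2_rep": float(s2_rep)},
        std_errors={"sigma2_g": se["genotype"], "sigma2_e": se["residual"],
                    "sigma2_rep": se["rep"]},
    )
    return TrialModelFit(
        kind="within_env", trait=trait, environment=environment, mu=mu,
        blups=pd.Series(blups["genotype"], index=levels_gen, name=trait),
        rep_effects=pd.Series(blups["rep"], index=levels_rep),
        components=vc,
        # strata likelihood differs from the dense restricted likelihood by
        # the constant 0.5*log(n) from the fixed-mean stratum
        loglik=fit.loglik - 0.5 * np.log(Y.size),
        converged=fit.converged,
        method="strata_reml",
    )


def _fit_within_em(df, environment, trait) -> TrialModelFit:
    y = df["value"].to_numpy(dtype=float)
    codes_rep, levels_rep = _codes(df["rep"])
    codes_gen, levels_gen = _codes(df["genotype"])
    R, L = len(levels_rep), len(levels_gen)
    terms = [
        mm.RandomTerm("rep", _onehot(codes_rep, R).toarray(), levels=levels_rep),
        mm.RandomTerm("genotype", _onehot(codes_gen, L).toarray(), levels=levels_gen),
    ]
    sol = mm.reml_multi_kernel(mm.MixedModelProblem(y, np.ones((len(y), 1)), terms))
    vc = VarianceComponents(
        sigma2_g=sol.components["genotype"], sigma2_e=sol.components["residual"],
        n_envs=1, n_reps=R, extras={"sigma2_rep": sol.components["rep"]},
    )
    return TrialModelFit(
        kind="within_env", trait=trait, environment=environment,
        mu=float(sol.beta[0]),
        blups=pd.Series(sol.blups["genotype"], index=levels_gen, name=trait),
        rep_effects=pd.Series(sol.blups["rep"], index=levels_rep),
        components=vc, loglik=sol.loglik, converged=sol.converged, method="em_reml",
        log=[f"em iterations: {sol.n_iter}"],
    )


# ---------------------------------------------------------------------------
# across-environment model
# ---------------------------------------------------------------------------


def fit_across_env(p: PhenotypeTable, trait, solve_effects: bool = True) -> TrialModelFit:
    """REML fit of y = mu + Env + Rep(Env) + Gen + Env x Gen + e.

    ``solve_effects=False`` skips the BLUP solve and returns variance
    components only (useful in simulation studies where only the
    components matter).
    """
    df = p.subset(trait=trait)
    if df["environment"].nunique() < 2:
        raise ValueError("single environment: use fit_within_env")
    if _is_complete_grid(df, ["environment", "rep", "genotype"]):
        return _fit_across_balanced(df, trait, solve_effects)
    return _fit_across_em(df, trait)


def _fit_across_balanced(df, trait, solve_effects) -> TrialModelFit:
    pv = df.pivot_table(index=["environment", "rep"], columns="genotype", values="value")
    envs = pv.index.get_level_values(0).unique()
    reps = pv.index.get_level_values(1).unique()
    E, R, L = len(envs), len(reps), pv.shape[1]
    Y = pv.to_numpy().reshape(E, R, L)

    ybar = Y.mean()
    env_m = Y.mean(axis=(1, 2))                      # (E,)
    envrep_m = Y.mean(axis=2)                        # (E, R)
    gen_m = Y.mean(axis=(0, 1))                      # (L,)
    envgen_m = Y.mean(axis=1)                        # (E, L)

    ss_env = R * L * float(((env_m - ybar) ** 2).sum())
    ss_rep = L * float(((envrep_m - env_m[:, None]) ** 2).sum())
    ss_gen = E * R * float(((gen_m - ybar) ** 2).sum())
    inter = envgen_m - env_m[:, None] - gen_m[None, :] + ybar
    ss_ge = R * float((inter**2).sum())
    resid = Y - envrep_m[:, :, None] - envgen_m[:, None, :] + env_m[:, None, None]
    ss_res = float((resid**2).sum())

    dims = np.array([
        E - 1,
        E * (R - 1),
        L - 1,
        (E - 1) * (L - 1),
        E * (R - 1) * (L - 1),
    ])
    ssv = np.array([ss_env, ss_rep, ss_gen, ss_ge, ss_res])
    coef = np.array(
        [
            [R * L, L, 0, R, 1],
            [0, L, 0, 0, 1],
            [0, 0, E * R, R, 1],
            [0, 0, 0, R, 1],
            [0, 0, 0, 0, 1],
        ],
        dtype=float,
    )
    names = ["env", "rep", "genotype", "gxe", "residual"]
    fit = mm.reml_from_strata(dims, ssv, coef, names)
    s2_env, s2_rep, s2_g, s2_ge, s2_e = fit.components
    se = dict(zip(names, fit.std_errors()))

    vc = VarianceComponents(
        sigma2_g=float(s2_g), sigma2_e=float(s2_e), sigma2_ge=float(s2_ge),
        n_envs=E, n_reps=R,
        extras={"sigma2_env": float(s2_env), "sigma2_rep": float(s2_rep)},
        std_errors={"sigma2_g": se["genotype"], "sigma2_ge": se["gxe"],
                    "sigma2_e": se["residual"], "sigma2_env": se["env"],
                    "sigma2_rep": se["rep"]},
    )
    result = TrialModelFit(
        kind="across_env", trait=trait, mu=float(ybar),
        blups=pd.Series(dtype=float), components=vc,
        loglik=fit.loglik - 0.5 * np.log(Y.size),
        converged=fit.converged, method="strata_reml",
    )
    if not solve_effects:
        return result

    codes_env, levels_env = _codes(df["environment"])
    codes_gen, levels_gen = _codes(df["genotype"])
    envrep = df["environment"].astype(str) + "/" + df["rep"].astype(str)
    codes_er, levels_er = _codes(envrep)
    eg_codes = codes_env * L + codes_gen
    mu, blups = _solve_mme(
        df["value"].to_numpy(dtype=float),
        [
            ("env", codes_env, E, s2_env),
            ("rep", codes_er, len(levels_er), s2_rep),
            ("genotype", codes_gen, L, s2_g),
            ("gxe", eg_codes, E * L, s2_ge),
        ],
        s2_e,
    )
    inter_index = pd.MultiIndex.from_product(
        [levels_env, levels_gen], names=["environment", "genotype"]
    )
    result.mu = mu
    result.blups = pd.Series(blups["genotype"], index=levels_gen, name=trait)
    result.env_effects = pd.Series(blups["env"], index=levels_env)
    result.rep_effects = pd.Series(blups["rep"], index=levels_er)
    result.interaction = pd.Series(blups["gxe"], index=inter_index)
    return result


def _fit_across_em(df, trait) -> TrialModelFit:
    y = df["value"].to_numpy(dtype=float)
    codes_env, levels_env = _codes(df["environment"])
    codes_gen, levels_gen = _codes(df["genotype"])
    envrep = df["environment"].astype(str) + "/" + df["rep"].astype(str)
    codes_er, levels_er = _codes(envrep)
    E, L = len(levels_env), len(levels_gen)
    eg_codes = codes_env * L + codes_gen
    inter_index = pd.MultiIndex.from_product(
        [levels_env, levels_gen], names=["environment", "genotype"]
    )
    terms = [
        mm.RandomTerm("env", _onehot(codes_env, E).toarray(), levels=levels_env),
        mm.RandomTerm("rep", _onehot(codes_er, len(levels_er)).toarray(), levels=levels_er),
        mm.RandomTerm("genotype", _onehot(codes_gen, L).toarray(), levels=levels_gen),
        mm.RandomTerm("gxe", _onehot(eg_codes, E * L).toarray(), levels=inter_index),
    ]
    sol = mm.reml_multi_kernel(mm.MixedModelProblem(y, np.ones((len(y), 1)), terms))
    R = df["rep"].nunique()
    vc = VarianceComponents(
        sigma2_g=sol.components["genotype"], sigma2_e=sol.components["residual"],
        sigma2_ge=sol.components["gxe"], n_envs=E, n_reps=R,
        extras={"sigma2_env": sol.components["env"], "sigma2_rep": sol.components["rep"]},
    )
    return TrialModelFit(
        kind="across_env", trait=trait, mu=float(sol.beta[0]),
        blups=pd.Series(sol.blups["genotype"], index=levels_gen, name=trait),
        env_effects=pd.Series(sol.blups["env"], index=levels_env),
        rep_effects=pd.Series(sol.blups["rep"], index=levels_er),
        interaction=pd.Series(sol.blups["gxe"], index=inter_index),
        components=vc, loglik=sol.loglik, converged=sol.converged, method="em_reml",
        log=[f"em iterations: {sol.n_iter}"],
    )


# ---------------------------------------------------------------------------
# correlations and PCA
# ---------------------------------------------------------------------------


@dataclass
class CorrelationTables:
    genetic: pd.DataFrame
    phenotypic: pd.DataFrame


def trait_correlations(
    fits: Mapping[str, TrialModelFit], table: PhenotypeTable
) -> CorrelationTables:
    """Genetic (BLUP-BLUP) and phenotypic (raw genotype mean) Pearson
    correlations among traits, pairwise-complete over genotypes."""
    if len(fits) < 2:
        raise ValueError("need at least two traits")
    blups = pd.DataFrame({t: f.blups for t, f in fits.items()})
    traits = list(blups.columns)
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            shared = blups[[a, b]].dropna()
            if len(shared) < 3:
                raise ValueError(f"traits {a!r} and {b!r} share fewer than 3 genotypes")
    genetic = blups.corr(method="pearson", min_periods=3)
    means = (
        table.data.groupby(["trait", "genotype"], observed=True)["value"]
        .mean()
        .unstack(level="trait")
    )
    phenotypic = means[traits].corr(method="pearson", min_periods=3)
    return CorrelationTables(genetic=genetic, phenotypic=phenotypic)


@dataclass
class PCASummary:
    explained_pct: pd.Series
    loadings: pd.DataFrame
    dropped: list = field(default_factory=list)


def trait_pca(blups: pd.DataFrame) -> PCASummary:
    """PCA of a genotype-by-variable BLUP matrix, centered and unit-scaled.

    Missing cells are mean-filled; constant columns are dropped with a
    warning.  Explained variances are percentages summing to 100.
    """
    from sklearn.decomposition import PCA

    X = blups.apply(lambda c: c.fillna(c.mean()))
    sd = X.std(ddof=1)
    dropped = list(X.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    if X.shape[1] < 2:
        raise ValueError("need at least two non-constant variables")
    Z = (X - X.mean()) / sd
    pca = PCA()
    pca.fit(Z.to_numpy())
    k = pca.n_components_
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCASummary(
        explained_pct=pd.Series(pca.explained_variance_ratio_ * 100.0, index=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=comp_names),
        dropped=dropped,
    )
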