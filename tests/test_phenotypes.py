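"""Trial-model, heritability, correlation and PCA tests.

REML fits are checked against a derivative-free maximization of the
densely-evaluated restricted likelihood (an independent code path) and
against classical balanced-ANOVA moment estimators.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from megblup import mixed_model as mm
from megblup import phenotypes as ph
from megblup import simulate as sim
from megblup.phenotypes import VarianceComponents as VC


def make_table(rows):
    return ph.PhenotypeTable(
        pd.DataFrame(rows, columns=["environment", "rep", "genotype", "trait", "value"])
    )


def balanced_table(values, trait="T", envs=None):
    """values: array (n_env, n_rep, n_gen) -> long table."""
    values = np.asarray(values, dtype=float)
    E, R, L = values.shape
    envs = envs or [f"E{i+1}" for i in range(E)]
    rows = []
    for i in range(E):
        for j in range(R):
            for k in range(L):
                rows.append((envs[i], j + 1, f"G{k}", trait, values[i, j, k]))
    return make_table(rows)


def direct_reml_oracle(df, across):
    """Independent REML: Nelder-Mead on the dense restricted likelihood."""
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    env = pd.Categorical(df["environment"])
    gen = pd.Categorical(df["genotype"])
    onehot = lambda c, q: np.eye(q)[c]
    terms = []
    if across:
        er = pd.Categorical(df["environment"].astype(str) + "/" + df["rep"].astype(str))
        eg = pd.Categorical(
            df["environment"].astype(str) + ":" + df["genotype"].astype(str)
        )
        terms = [
            mm.RandomTerm("env", onehot(env.codes, len(env.categories))),
            mm.RandomTerm("rep", onehot(er.codes, len(er.categories))),
            mm.RandomTerm("genotype", onehot(gen.codes, len(gen.categories))),
            mm.RandomTerm("gxe", onehot(eg.codes, len(eg.categories))),
        ]
    else:
        rep = pd.Categorical(df["rep"])
        terms = [
            mm.RandomTerm("rep", onehot(rep.codes, len(rep.categories))),
            mm.RandomTerm("genotype", onehot(gen.codes, len(gen.categories))),
        ]
    problem = mm.MixedModelProblem(y, np.ones((n, 1)), terms)
    names = [t.name for t in terms] + ["residual"]

    def neg(x):
        comps = dict(zip(names, np.exp(x)))
        return -mm.restricted_loglik(problem, comps)

    vary = np.var(y, ddof=1)
    best = None
    for start in (np.full(len(names), vary / len(names)), np.full(len(names), vary)):
        res = optimize.minimize(
            neg, np.log(start), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 6000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return dict(zip(names, np.exp(best.x))), -best.fun


class TestHeritabilityFormulas:
    @pytest.mark.parametrize(
        "s2g,s2e,expected",
        [(10.98, 4.04, 0.84), (0.29, 0.63, 0.48), (26.59, 8.92, 0.86), (0.21, 0.15, 0.74)],
    )
    def test_within_reported_rows(self, s2g, s2e, expected):
        """Entry-mean H2 for the wheat panel's per-environment variance
        components, at 2 replicates."""
        h2 = ph.heritability_within(VC(s2g, s2e, n_reps=2))
        assert round(h2, 2) == expected

    @pytest.mark.parametrize(
        "s2g,s2ge,s2e,expected",
        [(8.94, 2.29, 3.74, 0.90), (4.00, 1.94, 2.83, 0.83), (9.90, 7.41, 7.10, 0.78)],
    )
    def test_across_reported_rows(self, s2g, s2ge, s2e, expected):
        h2 = ph.heritability_across(VC(s2g, s2e, s2ge, n_envs=4, n_reps=2))
        assert round(h2, 2) == expected

    def test_limits(self):
        assert ph.heritability_within(VC(0.0, 1.0, n_reps=2)) == 0.0
        assert ph.heritability_within(VC(1.0, 0.0, n_reps=2)) == 1.0
        assert ph.heritability_across(VC(2.0, 0.0, 0.0, n_envs=4, n_reps=2)) == 1.0
        with pytest.raises(ph.UndefinedHeritabilityError):
            ph.heritability_within(VC(0.0, 0.0, n_reps=2))
        with pytest.raises(ph.UndefinedHeritabilityError):
            ph.heritability_across(VC(0.0, 0.0, 0.0, n_envs=2, n_reps=2))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        s2g=st.floats(0.01, 50), s2e=st.floats(0.01, 50), s2ge=st.floats(0.01, 50),
        delta=st.floats(0.01, 10),
        n_envs=st.integers(1, 6), n_reps=st.integers(1, 4),
    )
    def test_monotonicity_and_consistency(self, s2g, s2e, s2ge, delta, n_envs, n_reps):
        base_w = ph.heritability_within(VC(s2g, s2e, n_reps=n_reps))
        assert 0 <= base_w <= 1
        assert ph.heritability_within(VC(s2g + delta, s2e, n_reps=n_reps)) > base_w
        assert ph.heritability_within(VC(s2g, s2e + delta, n_reps=n_reps)) < base_w
        base_a = ph.heritability_across(VC(s2g, s2e, s2ge, n_envs=n_envs, n_reps=n_reps))
        assert 0 <= base_a <= 1
        assert ph.heritability_across(VC(s2g + delta, s2e, s2ge, n_envs=n_envs, n_reps=n_reps)) > base_a
        assert ph.heritability_across(VC(s2g, s2e + delta, s2ge, n_envs=n_envs, n_reps=n_reps)) < base_a
        assert ph.heritability_across(VC(s2g, s2e, s2ge + delta, n_envs=n_envs, n_reps=n_reps)) < base_a
        # across with a single environment and no interaction = within
        assert ph.heritability_across(
            VC(s2g, s2e, 0.0, n_envs=1, n_reps=n_reps)
        ) == pytest.approx(ph.heritability_within(VC(s2g, s2e, n_reps=n_reps)))


class TestWithinEnv:
    def test_noiseless_limit(self):
        g_true = np.array([3.0, -1.0, 0.5, 2.0, -4.0, 1.5])
        values = np.tile(10 + g_true, (1, 2, 1)).reshape(1, 2, 6)
        fit = ph.fit_within_env(balanced_table(values), "E1", "T")
        assert fit.components.sigma2_e == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.blups.to_numpy(), g_true - g_true.mean(), atol=1e-5)
        assert ph.heritability_within(fit.components) == pytest.approx(1.0, abs=1e-8)

    def test_matches_direct_reml_oracle(self):
        rng = np.random.default_rng(31)
        L, R = 6, 2
        vals = (
            10
            + rng.normal(0, 1.4, L)[None, None, :]
            + rng.normal(0, 0.5, R)[None, :, None]
            + rng.normal(0, 0.8, (1, R, L))
        )
        table = balanced_table(vals)
        fit = ph.fit_within_env(table, "E1", "T")
        oracle, oracle_ll = direct_reml_oracle(table.subset(trait="T", environment="E1"), across=False)
        assert fit.components.sigma2_g == pytest.approx(oracle["genotype"], rel=1e-3)
        assert fit.components.sigma2_e == pytest.approx(oracle["residual"], rel=1e-3)

    def test_matches_anova_moment_estimators_when_interior(self):
        rng = np.random.default_rng(37)
        L, R = 30, 3
        vals = (
            rng.normal(0, 2.0, L)[None, None, :]
            + np.array([1.0, -2.0, 0.5])[None, :, None]
            + rng.normal(0, 1.0, (1, R, L))
        )
        fit = ph.fit_within_env(balanced_table(vals), "E1", "T")
        # the equivalence only holds when every moment estimate is interior
        assert fit.components.extras["sigma2_rep"] > 0
        Y = vals[0]  # (R, L)
        ms_gen = R * ((Y.mean(axis=0) - Y.mean()) ** 2).sum() / (L - 1)
        ms_res = (
            (Y - Y.mean(axis=0) - Y.mean(axis=1, keepdims=True) + Y.mean()) ** 2
        ).sum() / ((R - 1) * (L - 1))
        assert fit.components.sigma2_e == pytest.approx(ms_res, rel=1e-3)
        assert fit.components.sigma2_g == pytest.approx((ms_gen - ms_res) / R, rel=1e-3)

    def test_unbalanced_uses_em_and_matches_oracle(self):
        rng = np.random.default_rng(41)
        L, R = 8, 2
        vals = (
            5
            + rng.normal(0, 1.2, L)[None, None, :]
            + rng.normal(0, 0.4, R)[None, :, None]
            + rng.normal(0, 0.7, (1, R, L))
        )
        table = balanced_table(vals)
        df = table.data.drop(index=[2, 9]).reset_index(drop=True)  # two missing plots
        fit = ph.fit_within_env(ph.PhenotypeTable(df), "E1", "T")
        assert fit.method == "em_reml"
        assert fit.blups.sum() == pytest.approx(0.0, abs=1e-6)
        oracle, oracle_ll = direct_reml_oracle(df, across=False)
        # EM approaches a boundary optimum slowly; the likelihood gap stays
        # small even when formal convergence is not reached
        assert fit.loglik == pytest.approx(oracle_ll, abs=5e-3)
        assert fit.components.sigma2_g == pytest.approx(oracle["genotype"], rel=0.05)
        assert fit.components.sigma2_e == pytest.approx(oracle["residual"], rel=0.05)

    def test_blup_shrinkage_and_zero_sum(self):
        rng = np.random.default_rng(43)
        vals = rng.normal(0, 1, (1, 2, 10)) + rng.normal(0, 1, 10)[None, None, :]
        fit = ph.fit_within_env(balanced_table(vals), "E1", "T")
        dev = vals[0].mean(axis=0) - vals.mean()
        assert np.all(np.abs(fit.blups.to_numpy()) <= np.abs(dev) + 1e-8)
        assert fit.blups.sum() == pytest.approx(0.0, abs=1e-8)
        assert fit.rep_effects.sum() == pytest.approx(0.0, abs=1e-8)

    def test_recovery_of_known_components(self):
        """Simulating at the DTHD-like truth (10.98, 4.04) with 141 lines
        and 2 reps, the 95% sampling band around the REML estimate covers
        the truth in at least 90% of seeds, per component."""
        truth = {"sigma2_g": 10.98, "sigma2_e": 4.04}
        hits = {k: 0 for k in truth}
        n_seeds = 100
        base = sim.SimulationConfig(
            n_lines=141, n_markers=150, n_chromosomes=1, chrom_lengths=(100.0,),
            n_environments=1, n_reps=2, env_means=(82.0,),
            var_g=10.98, var_ge=0.0, var_e=4.04, n_qtl=100, trait="DTHD",
        )
        for seed in range(n_seeds):
            _, table, _ = sim.simulate_trial(base.replace(seed=seed))
            fit = ph.fit_within_env(table, "E1", "DTHD")
            est = {"sigma2_g": fit.components.sigma2_g, "sigma2_e": fit.components.sigma2_e}
            for k in truth:
                if abs(est[k] - truth[k]) <= 1.96 * fit.components.std_errors[k]:
                    hits[k] += 1
        for k, n_hit in hits.items():
            assert n_hit >= 0.90 * n_seeds, f"{k}: covered in only {n_hit}/{n_seeds} seeds"

    def test_lookup_errors(self):
        table = balanced_table(np.zeros((1, 2, 3)) + np.arange(3))
        with pytest.raises(KeyError):
            ph.fit_within_env(table, "E9", "T")
        with pytest.raises(KeyError):
            ph.fit_within_env(table, "E1", "nope")


class TestAcrossEnv:
    def test_duplicated_environment_gives_zero_interaction(self):
        rng = np.random.default_rng(47)
        one_env = rng.normal(0, 1, (1, 2, 12)) + rng.normal(0, 1.5, 12)[None, None, :]
        values = np.concatenate([one_env, one_env], axis=0)
        fit = ph.fit_across_env(balanced_table(values), "T")
        assert fit.components.sigma2_ge == pytest.approx(0.0, abs=1e-8)

    def test_matches_direct_reml_oracle(self):
        rng = np.random.default_rng(53)
        E, R, L = 3, 2, 8
        vals = (
            rng.normal(0, 1.0, E)[:, None, None]
            + rng.normal(0, 0.3, (E, R))[:, :, None]
            + rng.normal(0, 1.2, L)[None, None, :]
            + rng.normal(0, 0.8, (E, L))[:, None, :]
            + rng.normal(0, 0.6, (E, R, L))
        )
        table = balanced_table(vals)
        fit = ph.fit_across_env(table, "T")
        oracle, oracle_ll = direct_reml_oracle(table.data, across=True)
        assert fit.loglik == pytest.approx(oracle_ll, abs=2e-3)
        assert fit.components.sigma2_g == pytest.approx(oracle["genotype"], rel=5e-3, abs=1e-4)
        assert fit.components.sigma2_ge == pytest.approx(oracle["gxe"], rel=5e-3, abs=1e-4)
        assert fit.components.sigma2_e == pytest.approx(oracle["residual"], rel=5e-3, abs=1e-4)

    def test_balanced_strata_agrees_with_em(self, small_trial):
        _, _, table, _ = small_trial
        sub = ph.PhenotypeTable(
            table.data[table.data["genotype"].isin(table.genotypes[:30])]
        )
        strata = ph.fit_across_env(sub, "SIM_S")
        em = ph._fit_across_em(sub.subset(trait="SIM_S"), "SIM_S")
        assert strata.method == "strata_reml" and em.method == "em_reml"
        assert strata.components.sigma2_g == pytest.approx(em.components.sigma2_g, rel=1e-2)
        assert strata.components.sigma2_e == pytest.approx(em.components.sigma2_e, rel=1e-2)
        np.testing.assert_allclose(strata.blups, em.blups, atol=1e-4)

    def test_blups_sum_to_zero_and_interaction_shape(self, small_trial):
        _, _, table, _ = small_trial
        fit = ph.fit_across_env(table, "SIM_S")
        assert fit.blups.sum() == pytest.approx(0.0, abs=1e-6)
        assert fit.env_effects.sum() == pytest.approx(0.0, abs=1e-6)
        assert fit.interaction.sum() == pytest.approx(0.0, abs=1e-5)
        assert len(fit.interaction) == 4 * 100

    def test_single_environment_redirects(self):
        table = balanced_table(np.arange(6, dtype=float).reshape(1, 2, 3))
        with pytest.raises(ValueError, match="fit_within_env"):
            ph.fit_across_env(table, "T")


class TestCorrelations:
    def _two_trait_table(self, rho=0.9, n=300, noise_var=0.1, seed=59, duplicate=False):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0, 1, n)
        g2 = rho * g1 + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        rows = []
        for env in ("E1", "E2"):
            for rep in (1, 2):
                noise1 = rng.normal(0, np.sqrt(noise_var), n)
                noise2 = noise1 if duplicate else rng.normal(0, np.sqrt(noise_var), n)
                for k in range(n):
                    rows.append((env, rep, f"G{k}", "T1", g1[k] + noise1[k]))
                    rows.append((env, rep, f"G{k}", "T2", g2[k] + noise2[k]))
        return make_table(rows)

    def _fits(self, table):
        return {t: ph.fit_across_env(table, t) for t in table.traits}

    def test_duplicated_trait_correlates_perfectly(self):
        table = self._two_trait_table(rho=1.0, duplicate=True)
        corr = ph.trait_correlations(self._fits(table), table)
        assert corr.genetic.loc["T1", "T2"] == pytest.approx(1.0, abs=1e-6)
        assert corr.phenotypic.loc["T1", "T2"] == pytest.approx(1.0, abs=1e-6)

    def test_known_genetic_correlation_recovered(self):
        """BLUP-BLUP correlation recovers a true genetic correlation of 0.9
        up to the attenuation from entry-mean noise (a factor of
        1/(1 + noise/(4 reps)) here)."""
        table = self._two_trait_table(rho=0.9, noise_var=0.1)
        corr = ph.trait_correlations(self._fits(table), table)
        r_gen = corr.genetic.loc["T1", "T2"]
        r_phe = corr.phenotypic.loc["T1", "T2"]
        expected = 0.9 / (1 + 0.1 / 4)
        assert r_gen == pytest.approx(expected, abs=0.05)
        assert r_gen == pytest.approx(0.9, abs=0.08)
        # phenotypic (raw-mean) correlation never exceeds the BLUP-based
        # one; with balanced data the two coincide (BLUPs are shrunken means)
        assert r_phe <= r_gen + 1e-9

    def test_independent_traits_near_zero(self):
        table = self._two_trait_table(rho=0.0, n=400)
        corr = ph.trait_correlations(self._fits(table), table)
        assert abs(corr.genetic.loc["T1", "T2"]) < 3 / np.sqrt(400)

    def test_too_few_shared_genotypes(self):
        table = self._two_trait_table(n=30)
        fits = self._fits(table)
        fits["T2"] = ph.TrialModelFit(
            kind="across_env", trait="T2", mu=0.0,
            blups=fits["T2"].blups.iloc[:2], components=fits["T2"].components,
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            ph.trait_correlations(fits, table)


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10, dtype=float)
        out = ph.trait_pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert out.explained_pct.iloc[0] == pytest.approx(100.0, abs=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3)),
                         columns=list("abc"))
        out = ph.trait_pca(X)
        corr = np.corrcoef((X - X.mean()).to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(out.explained_pct, eig / eig.sum() * 100, rtol=1e-8)
        assert out.explained_pct.sum() == pytest.approx(100.0)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            out = ph.trait_pca(X)
        assert out.dropped == ["c"]
        assert list(out.loadings.index) == ["a", "b"]


class TestPhenotypeTable:
    def test_duplicate_records_rejected(self):
        rows = [("E1", 1, "G1", "T", 1.0), ("E1", 1, "G1", "T", 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            make_table(rows)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_table([("E1", 1, "G1", "T", np.nan)])
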