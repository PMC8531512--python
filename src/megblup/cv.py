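"""Genomic prediction cross-validation: SE_CV1, ME_CV1 and ME_CV2.

The response in every scheme is the stage-1 per-environment genotype
BLUP (one adjusted value per line and environment); raw plot data never
enters the prediction stage.  Prediction accuracy is the Pearson
correlation between predicted genetic values and the observed BLUPs of
the validation set.

SE_CV1
    Baseline single-environment GBLUP.  Within each environment
    independently, lines are split into k folds; each fold's phenotypes
    are masked, the model y = mu + g + e with g ~ N(0, s2_g * G) is
    fitted on the remainder and the fold is predicted through G.  The
    k-fold split is re-randomized over repeats.

ME_CV1
    Multi-environment GBLUP (fixed environment intercepts, main genetic
    effect with kernel G shared across environments, G-by-E effect with
    kernel I (x) G).  A fold's lines are masked in *every* environment
    simultaneously; their cells are predicted as Env_i + g_j + gE_ij and
    accuracy is computed per environment.

ME_CV2
    Leave-one-environment-out with the same ME model.  All records of
    one environment are masked; its lines are predicted by the main
    genetic effect alone (the held-out environment's intercept and
    interaction are unestimable, and Pearson accuracy is invariant to
    the missing location shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mixed_model as mm
from .genotypes import GRM
from .phenotypes import PhenotypeTable, fit_within_env

__all__ = [
    "CVScheme",
    "CVResult",
    "UndefinedAccuracyError",
    "make_folds",
    "stage1_blups",
    "prediction_accuracy",
    "run_se_cv1",
    "run_me_cv1",
    "run_me_cv2",
]

RECORD_COLUMNS = ["trait", "environment", "scheme", "repeat", "fold", "n_test", "accuracy"]


class UndefinedAccuracyError(ValueError):
    """Pearson accuracy undefined (constant predictions or observations)."""


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation protocol parameters.

    ``n_folds``/``n_repeats`` apply to the CV1 schemes (defaults follow
    the 5-fold x 50-repeat protocol); ME_CV2 is deterministic
    leave-one-environment-out and ignores both.
    """

    scheme: str = "SE_CV1"
    n_folds: int = 5
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("SE_CV1", "ME_CV1", "ME_CV2"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme != "ME_CV2" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2 for CV1 schemes")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """Per-fold accuracies plus aggregation helpers."""

    records: pd.DataFrame
    scheme: str
    master_seed: int
    fold_seeds: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of accuracy per trait x environment."""
        return (
            self.records.groupby(["trait", "environment", "scheme"], observed=True)["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def overall(self) -> pd.DataFrame:
        """Mean accuracy per trait (averaged over environments and folds)."""
        return (
            self.records.groupby(["trait", "scheme"], observed=True)["accuracy"]
            .mean()
            .reset_index()
        )


def make_folds(line_ids, n_folds: int, seed) -> np.ndarray:
    """Random fold assignment with sizes differing by at most one.

    Deterministic under the seed; the first ``n % n_folds`` folds carry
    the extra line each.
    """
    n = len(line_ids)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the number of lines ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, n_folds)
    sizes = np.array([base + (1 if f < extra else 0) for f in range(n_folds)])
    assignment = np.empty(n, dtype=int)
    start = 0
    for f, size in enumerate(sizes):
        assignment[perm[start : start + size]] = f
        start += size
    return assignment


def _repeat_seeds(master_seed: int, n_repeats: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n_repeats)]


def prediction_accuracy(predicted, observed) -> float:
    """Sample Pearson correlation between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        raise UndefinedAccuracyError("zero variance in predictions or observations")
    return float(np.corrcoef(predicted, observed)[0, 1])


def _safe_accuracy(predicted, observed, context: str) -> float:
    try:
        return prediction_accuracy(predicted, observed)
    except (ValueError, UndefinedAccuracyError) as exc:
        warnings.warn(f"{context}: accuracy recorded as missing ({exc})", stacklevel=3)
        return np.nan


def stage1_blups(table: PhenotypeTable, trait, environments=None) -> pd.DataFrame:
    """Adjusted per-environment phenotypes: mu + genotype BLUP from the
    within-environment trial model, as a genotype x environment frame."""
    envs = environments if environments is not None else table.environments
    cols = {}
    for env in envs:
        fit = fit_within_env(table, env, trait)
        cols[env] = fit.mu + fit.blups
    return pd.DataFrame(cols)


def _aligned_kernel(blups: pd.DataFrame, grm: GRM) -> np.ndarray:
    idx = grm.index_of(blups.index)
    return grm.values[np.ix_(idx, idx)]


def run_se_cv1(blups: pd.DataFrame, grm: GRM, scheme: CVScheme, trait: str = "trait") -> CVResult:
    """Single-environment GBLUP accuracy under repeated k-fold CV1."""
    if scheme.scheme != "SE_CV1":
        raise ValueError("scheme.scheme must be 'SE_CV1'")
    K = _aligned_kernel(blups, grm)
    lines = blups.index.to_numpy()
    n = len(lines)
    seeds = _repeat_seeds(scheme.seed, scheme.n_repeats)
    rows = []
    for env in blups.columns:
        y_all = blups[env].to_numpy(dtype=float)
        for rep, rep_seed in enumerate(seeds):
            folds = make_folds(lines, scheme.n_folds, rep_seed)
            for f in range(scheme.n_folds):
                test = folds == f
                train = ~test
                assert not np.any(test & train) and np.all(test | train)
                if test.sum() < 3:
                    warnings.warn(f"fold {f} has <3 test lines; recorded as missing")
                    rows.append((trait, env, "SE_CV1", rep, f, int(test.sum()), np.nan))
                    continue
                Z = np.eye(n)[train]
                problem = mm.MixedModelProblem(
                    y_all[train], np.ones((int(train.sum()), 1)),
                    [mm.RandomTerm("genetic", Z, K, levels=lines)],
                )
                sol = mm.reml_single_kernel(problem)
                pred = sol.blups["genetic"][test]
                acc = _safe_accuracy(pred, y_all[test], f"SE_CV1 {env} rep {rep} fold {f}")
                rows.append((trait, env, "SE_CV1", rep, f, int(test.sum()), acc))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return CVResult(records, "SE_CV1", scheme.seed, seeds)


def run_me_cv1(blups: pd.DataFrame, grm: GRM, scheme: CVScheme, trait: str = "trait") -> CVResult:
    """Multi-environment GBLUP accuracy with fold lines masked in every
    environment simultaneously."""
    if scheme.scheme != "ME_CV1":
        raise ValueError("scheme.scheme must be 'ME_CV1'")
    if blups.shape[1] < 2:
        raise ValueError("ME_CV1 requires at least two environments")
    K = _aligned_kernel(blups, grm)
    lines = blups.index.to_numpy()
    envs = list(blups.columns)
    Y_all = blups.to_numpy(dtype=float).T  # (E, n)
    seeds = _repeat_seeds(scheme.seed, scheme.n_repeats)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        folds = make_folds(lines, scheme.n_folds, rep_seed)
        for f in range(scheme.n_folds):
            test = folds == f
            train = ~test
            assert not np.any(test & train) and np.all(test | train)
            train_idx = np.where(train)[0]
            sol = mm.reml_gxe_spectral(Y_all[:, train_idx], K, train_idx)
            pred_cells = (
                sol.env_effects[:, None] + sol.g_hat[None, :] + sol.ge_hat
            )  # (E, n)
            for i, env in enumerate(envs):
                if test.sum() < 3:
                    warnings.warn(f"fold {f} has <3 test lines; recorded as missing")
                    rows.append((trait, env, "ME_CV1", rep, f, int(test.sum()), np.nan))
                    continue
                acc = _safe_accuracy(
                    pred_cells[i, test], Y_all[i, test], f"ME_CV1 {env} rep {rep} fold {f}"
                )
                rows.append((trait, env, "ME_CV1", rep, f, int(test.sum()), acc))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return CVResult(records, "ME_CV1", scheme.seed, seeds)


def run_me_cv2(blups: pd.DataFrame, grm: GRM, trait: str = "trait") -> CVResult:
    """Leave-one-environment-out accuracy of the multi-environment model.

    Deterministic: one record per held-out environment.  Predictions for
    the held-out environment are the main genetic BLUPs; accuracy is
    location invariant, so the unestimable environment intercept drops
    out.
    """
    if blups.shape[1] < 2:
        raise ValueError("ME_CV2 requires at least two environments")
    if blups.shape[1] == 2:
        warnings.warn("only two environments: each model trains on a single environment")
    K = _aligned_kernel(blups, grm)
    envs = list(blups.columns)
    Y_all = blups.to_numpy(dtype=float).T  # (E, n)
    n = Y_all.shape[1]
    rows = []
    for i, env in enumerate(envs):
        keep = [j for j in range(len(envs)) if j != i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sol = mm.reml_gxe_spectral(Y_all[keep], K, np.arange(n))
        acc = _safe_accuracy(sol.g_hat, Y_all[i], f"ME_CV2 {env}")
        rows.append((trait, env, "ME_CV2", 0, i, n, acc))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return CVResult(records, "ME_CV2", 0, [])
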