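"""Model evaluation: replicated cross-validation, across-environment
validation, and improvement summaries.

Accuracy is the Pearson correlation between predicted genetic values and
observed phenotypes on held-out lines.  One cross-validation replicate
shuffles the lines into k folds and rotates the test fold; accuracy is
pooled across folds within a replicate (one r per replicate), and the
mean and standard error are taken across replicates — two seeded sets of
fifty replicates by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import replicate_stream
from .mixed_models import (
    fit_covariate_gs,
    fit_gblup,
    fit_multitrait_gs,
    fit_sri_regression,
)

logger = logging.getLogger(__name__)

MODELS = ("unigs", "srir", "gs_sri", "multigs")


@dataclass
class CVConfig:
    """Cross-validation settings (defaults: 5-fold, 2 x 50 replicates)."""

    k: int = 5
    replicate_sets: int = 2
    replicates_per_set: int = 50
    seed: int = 0
    model: str = "unigs"
    stage: str | None = None
    sri: str | None = None            # "all" or a single index name
    test_secondary: str = "observed"  # or "hidden"
    min_fold_size: int = 5
    aggregate: str = "replicate"      # one r per replicate, or "fold"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.test_secondary not in ("observed", "hidden"):
            raise ValueError("test_secondary must be 'observed' or 'hidden'")
        if self.aggregate not in ("replicate", "fold"):
            raise ValueError("aggregate must be 'replicate' or 'fold'")

    @property
    def train_fraction(self) -> float:
        return 1.0 - 1.0 / self.k

    @property
    def n_replicates(self) -> int:
        return self.replicate_sets * self.replicates_per_set


@dataclass
class AccuracyResult:
    """Per-replicate accuracies with replicate-level summaries."""

    model: str
    trait: str
    environment: str
    stage: str | None
    accuracies: np.ndarray
    set_means: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        a = np.asarray(self.accuracies)
        if a.size < 2:
            return 0.0
        return float(a.std(ddof=1) / np.sqrt(a.size))


def _pearson(a, b) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])


def _predict_fold(model, y, G, X_sri, train, test, cfg: CVConfig):
    """Train on ``train`` indices, return predictions for ``test``."""
    if model == "unigs":
        fit = fit_gblup(y[train], G[np.ix_(train, train)])
        return fit.predict(G[np.ix_(test, train)])
    if model == "srir":
        fit = fit_sri_regression(y[train], X_sri[train])
        return fit.predict(X_sri[test])
    if model == "gs_sri":
        fit = fit_covariate_gs(y[train], X_sri[train], G[np.ix_(train, train)])
        return fit.predict(
            G[np.ix_(test, train)], X_new=X_sri[test], include_fixed=True
        )
    if model == "multigs":
        n = len(y)
        Y = np.column_stack([y, X_sri]).astype(float)
        Y[test, 0] = np.nan
        if cfg.test_secondary == "hidden":
            Y[test, 1:] = np.nan
        cols = ["primary"] + [f"sec{j}" for j in range(X_sri.shape[1])]
        fit = fit_multitrait_gs(
            pd.DataFrame(Y, columns=cols), G, min_obs_per_trait=cfg.min_fold_size
        )
        return fit.gebv.iloc[test, 0].to_numpy()
    raise ValueError(f"unknown model {model!r}")


def kfold_cv(
    y,
    G: np.ndarray,
    X_sri: np.ndarray | None = None,
    cfg: CVConfig | None = None,
    trait: str = "trait",
    environment: str = "E1",
) -> AccuracyResult:
    """Replicated k-fold cross-validation for one trait and environment.

    ``y`` holds genotype-level values (BLUEs), ``G`` the matching
    relationship matrix, and ``X_sri`` the secondary-trait matrix
    required by every model except ``unigs``.  Each replicate shuffles
    the lines with its own child seed, so the accuracy vector is fully
    reproducible and folds partition the line set exactly.
    """
    cfg = cfg or CVConfig()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if G.shape != (n, n):
        raise ValueError(f"G shape {G.shape} does not match {n} lines")
    if cfg.model != "unigs":
        if X_sri is None:
            raise ValueError(f"model {cfg.model!r} requires secondary traits")
        X_sri = np.asarray(X_sri, dtype=float)
        if X_sri.ndim == 1:
            X_sri = X_sri[:, None]
    if n // cfg.k < cfg.min_fold_size:
        raise ValueError(
            f"{n} lines in {cfg.k} folds leaves fewer than "
            f"{cfg.min_fold_size} test lines per fold"
        )

    accuracies = np.empty(cfg.n_replicates)
    for rep in range(cfg.n_replicates):
        rng = replicate_stream(cfg.seed, "cv", rep)
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.k)
        pred = np.empty(n)
        fold_rs = []
        for f, test in enumerate(folds):
            train = np.concatenate([folds[j] for j in range(cfg.k) if j != f])
            p = _predict_fold(cfg.model, y, G, X_sri, train, test, cfg)
            # fold models carry their own baselines; align them before
            # pooling so between-fold offsets cannot masquerade as
            # (anti-)signal — a zero-heritability trait then calibrates
            # to zero accuracy
            pred[test] = p - np.mean(p)
            fold_rs.append(_pearson(p, y[test]))
        if cfg.aggregate == "replicate":
            accuracies[rep] = _pearson(pred, y)
        else:
            accuracies[rep] = float(np.mean(fold_rs))

    set_means = [
        float(np.mean(s))
        for s in np.array_split(accuracies, cfg.replicate_sets)
    ]
    return AccuracyResult(
        model=cfg.model, trait=trait, environment=environment,
        stage=cfg.stage, accuracies=accuracies, set_means=set_means,
    )


def independent_validation(
    y_train,
    y_test,
    G: np.ndarray,
    X_sri_train: np.ndarray | None = None,
    X_sri_test: np.ndarray | None = None,
    model: str = "unigs",
    trait: str = "trait",
    train_env: str = "E1",
    test_env: str = "E2",
) -> AccuracyResult:
    """Across-environment validation: train in one year, predict the next.

    ``y_train`` and ``y_test`` are BLUEs of the same lines in two
    environments (pandas Series indexed by line, or aligned arrays); when
    indexed, the analysis restricts to the line intersection and logs the
    count.  Prediction for the test environment uses genotypes plus the
    test environment's secondary traits — the scenario where spectra
    have been collected but plots are not harvested.
    """
    if train_env == test_env:
        raise ValueError("train and test environments must differ")
    if isinstance(y_train, pd.Series) and isinstance(y_test, pd.Series):
        common = y_train.index.intersection(y_test.index)
        dropped = max(len(y_train), len(y_test)) - len(common)
        if dropped:
            logger.info(
                "line sets differ across environments: restricted to %d "
                "common lines (%d dropped)", len(common), dropped,
            )
        y_train = y_train.loc[common]
        y_test = y_test.loc[common]
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    n = y_train.size

    if model in ("srir", "gs_sri", "multigs") and X_sri_test is None:
        raise ValueError(
            f"model {model!r} requires test-environment secondary traits"
        )
    if X_sri_train is not None:
        X_sri_train = np.atleast_2d(np.asarray(X_sri_train, float))
        if X_sri_train.shape[0] != n:
            X_sri_train = X_sri_train.T
    if X_sri_test is not None:
        X_sri_test = np.atleast_2d(np.asarray(X_sri_test, float))
        if X_sri_test.shape[0] != n:
            X_sri_test = X_sri_test.T

    if model == "unigs":
        fit = fit_gblup(y_train, G)
        pred = fit.gebv_train
    elif model == "srir":
        fit = fit_sri_regression(y_train, X_sri_train)
        pred = fit.predict(X_sri_test)
    elif model == "gs_sri":
        fit = fit_covariate_gs(y_train, X_sri_train, G)
        pred = fit.predict(G, X_new=X_sri_test, include_fixed=True)
    elif model == "multigs":
        from .mixed_models import conditional_multitrait_blup, fit_multitrait_em

        Y_fit = np.column_stack([y_train, X_sri_train])
        vc = fit_multitrait_em(Y_fit, G)
        Y_pred = np.column_stack(
            [np.full(n, np.nan), X_sri_test]
        )
        gebv, _ = conditional_multitrait_blup(Y_pred, G, vc.H, vc.R)
        pred = gebv[:, 0]
    else:
        raise ValueError(f"unknown model {model!r}")

    acc = _pearson(pred, y_test)
    return AccuracyResult(
        model=model, trait=trait, environment=f"{train_env}->{test_env}",
        stage=None, accuracies=np.array([acc]),
    )


# ---------------------------------------------------------------------------
# improvement arithmetic
# ---------------------------------------------------------------------------

def round_improvement(x: float) -> float:
    """Reporting precision: whole percent unless a decimal is demanded.

    Rounds to one decimal first, then to a whole percent whenever the
    one-decimal value sits within 0.25 of an integer (so 34.9 -> 35 and
    22.2 -> 22, while 2.5 and 3.6 keep their decimal).
    """
    r1 = float(np.round(x, 1))
    nearest = float(np.round(r1))
    return nearest if abs(r1 - nearest) < 0.25 else r1


def summarize_improvement(
    acc_univariate: dict, acc_with_sri: dict
) -> pd.DataFrame:
    """Percent accuracy gain from adding secondary traits, per environment.

    Inputs map environment -> accuracy for the univariate baseline and
    the secondary-trait model.  Improvement is
    100 * (a_with - a_uni) / a_uni; a non-positive baseline makes the
    ratio undefined and is reported as missing.  A final ``average`` row
    holds the unweighted mean across environments, rounded by the same
    rule as the per-environment values.
    """
    rows = []
    raw = []
    for env in acc_univariate:
        a0 = acc_univariate[env]
        a1 = acc_with_sri[env]
        if a0 is None or a0 <= 0:
            logger.warning(
                "environment %s: baseline accuracy %s not positive; "
                "improvement undefined", env, a0,
            )
            imp = np.nan
        else:
            imp = 100.0 * (a1 - a0) / a0
            raw.append(imp)
        rows.append({
            "environment": env,
            "accuracy_univariate": a0,
            "accuracy_with_sri": a1,
            "improvement_pct": imp,
            "improvement_display": round_improvement(imp)
            if np.isfinite(imp) else np.nan,
        })
    avg = float(np.mean(raw)) if raw else np.nan
    rows.append({
        "environment": "average",
        "accuracy_univariate": np.nan,
        "accuracy_with_sri": np.nan,
        "improvement_pct": avg,
        "improvement_display": round_improvement(avg)
        if np.isfinite(avg) else np.nan,
    })
    return pd.DataFrame(rows)
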