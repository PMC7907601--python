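"""Augmented-design adjustment and broad-sense heritability.

Field trials place unreplicated entries alongside replicated check
cultivars in every block.  The fixed-effects model

    y_ij = mu + block_i + check_j (+ gen_j) + e_ij

is fitted per environment with sum-to-zero constraints; block effects are
estimable from the checks, and each unreplicated entry's adjusted mean
(BLUE) is its observation minus the estimated block deviation — the
classical augmented-design adjustment, which preserves within-block
ranking of entries.

Broad-sense heritability H2 = sigma2_g / (sigma2_g + sigma2_e) comes from
the same layout with genotype random (block fixed), on a plot basis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixed_models import reml_single_trait

_REQUIRED = ("environment", "block_id", "genotype_id", "is_check")


def _validate_plots(plots: pd.DataFrame, trait: str) -> None:
    missing = [c for c in _REQUIRED if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing columns {missing}")
    if trait not in plots.columns:
        raise ValueError(f"trait column {trait!r} not in plot table")


def _effect_code(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns."""
    levels = sorted(pd.unique(labels))
    L = len(levels)
    X = np.zeros((len(labels), max(L - 1, 0)))
    idx = {lv: i for i, lv in enumerate(levels)}
    for row, lv in enumerate(labels):
        i = idx[lv]
        if i < L - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X, levels


def _block_effects_one_env(env_df: pd.DataFrame, trait: str) -> pd.Series:
    """Estimate block deviations from the replicated checks (OLS)."""
    checks = env_df[env_df["is_check"].astype(bool)]
    empty_blocks = set(env_df["block_id"]) - set(checks["block_id"])
    if empty_blocks:
        raise ValueError(
            f"block(s) without checks — block effect inestimable: "
            f"{sorted(empty_blocks)}"
        )
    y = checks[trait].to_numpy(dtype=float)
    Xb, blocks = _effect_code(checks["block_id"])
    Xc, _ = _effect_code(checks["genotype_id"])
    X = np.column_stack([np.ones(len(y)), Xb, Xc])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    nb = len(blocks)
    b = coef[1:nb] if nb > 1 else np.array([])
    effects = np.append(b, -b.sum()) if nb > 1 else np.zeros(1)
    return pd.Series(effects, index=blocks)


def fit_acbd_blue(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Genotype-level BLUEs per environment from augmented-design plots.

    Returns a tidy table ``environment, genotype_id, trait, value,
    is_check``: entries are observation minus the block deviation; checks
    are the mean of their block-adjusted observations.
    """
    _validate_plots(plots, trait)
    out = []
    for env, env_df in plots.groupby("environment", sort=False):
        dup = (
            env_df[~env_df["is_check"].astype(bool)]
            .groupby("genotype_id").size()
        )
        dup = dup[dup > 1]
        if len(dup):
            raise ValueError(
                f"duplicated non-check entries in environment {env!r}: "
                f"{dup.index.tolist()[:5]}"
            )
        beff = _block_effects_one_env(env_df, trait)
        adj = env_df[trait].to_numpy(dtype=float) - beff.loc[
            env_df["block_id"]
        ].to_numpy()
        tmp = env_df[["genotype_id", "is_check"]].copy()
        tmp["value"] = adj
        blue = (
            tmp.groupby(["genotype_id", "is_check"], as_index=False)["value"]
            .mean()
        )
        blue.insert(0, "environment", env)
        blue.insert(2, "trait", trait)
        out.append(blue)
    return pd.concat(out, ignore_index=True)[
        ["environment", "genotype_id", "trait", "value", "is_check"]
    ]


def broad_sense_h2(plots: pd.DataFrame, trait: str) -> pd.Series:
    """Plot-basis broad-sense heritability per environment.

    One-random-effect REML with genotype random and mean + block fixed;
    H2 = sigma2_g / (sigma2_g + sigma2_e), clamped to [0, 1].  Requires
    replication (the checks) to separate genotype from plot error.
    """
    _validate_plots(plots, trait)
    out = {}
    for env, env_df in plots.groupby("environment", sort=False):
        counts = env_df.groupby("genotype_id").size()
        if (counts < 2).all():
            raise ValueError(
                f"no replicated genotypes in environment {env!r}: "
                "H2 is not estimable"
            )
        y = env_df[trait].to_numpy(dtype=float)
        Xb, _ = _effect_code(env_df["block_id"])
        X = np.column_stack([np.ones(len(y)), Xb])
        genos = pd.unique(env_df["genotype_id"])
        gidx = pd.Series(range(len(genos)), index=genos)
        Z = np.zeros((len(y), len(genos)))
        Z[np.arange(len(y)), gidx.loc[env_df["genotype_id"]].to_numpy()] = 1.0
        vc = reml_single_trait(y, K=Z @ Z.T, X=X)
        h2 = vc.sigma2_a / (vc.sigma2_a + vc.sigma2_e)
        out[env] = float(np.clip(h2, 0.0, 1.0))
    return pd.Series(out, name=f"H2_{trait}")
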