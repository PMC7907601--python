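"""Quantitative-genetic parameter estimators.

Narrow-sense heritability from the animal model (genomic relationship
matrix as the additive covariance), genetic correlation from the
bivariate model's genetic covariance matrix, and phenotypic correlation
with the usual significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import sample_variance_factor
from .mixed_models import fit_multitrait_em, reml_single_trait


@dataclass
class GeneticParams:
    """Estimates for one trait or trait pair."""

    trait: str | tuple
    h2: float | None = None
    r_G: float | None = None
    sigma2_a: float | None = None
    sigma2_e: float | None = None
    cov_A: float | None = None
    at_boundary: bool = False
    clamped: bool = False


def narrow_sense_h2(y, G, trait: str = "trait") -> GeneticParams:
    """Genomic h2 = sigma2_a / (sigma2_a + sigma2_e) from single-trait REML.

    ``G`` is the genomic relationship matrix aligned with ``y``.  The
    genetic variance is reported on the sample scale (REML component
    times the expected sample variance of genetic values per unit
    variance, see :func:`phenogs.genomics.sample_variance_factor`): in
    inbred or family-structured panels the VanRaden G has mean diagonal
    above one, and without this conversion the plain component ratio
    understates the variance fraction realized among the study lines.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.std() == 0:
        raise ValueError("response has zero variance: h2 undefined")
    G = np.asarray(G, dtype=float)
    vc = reml_single_trait(y, K=G)
    var_g = sample_variance_factor(G) * vc.sigma2_a
    h2 = var_g / (var_g + vc.sigma2_e)
    return GeneticParams(
        trait=trait,
        h2=float(np.clip(h2, 0.0, 1.0)),
        sigma2_a=var_g,
        sigma2_e=vc.sigma2_e,
        at_boundary=vc.at_boundary,
    )


def genetic_correlation(yA, yB, G, traits=("A", "B")) -> GeneticParams:
    """r_G between two traits from the bivariate genomic model.

    Fits the two-trait EM-REML model and reads r_G off the genetic
    covariance matrix H; values that numerically overshoot |1| are
    clamped with a flag, never silently.
    """
    yA = np.asarray(yA, dtype=float).ravel()
    yB = np.asarray(yB, dtype=float).ravel()
    if yA.size != yB.size:
        raise ValueError("trait vectors differ in length")
    Y = np.column_stack([yA, yB])
    vc = fit_multitrait_em(Y, np.asarray(G, dtype=float), traits=list(traits))
    r, clamped = vc.genetic_correlation(0, 1)
    return GeneticParams(
        trait=tuple(traits),
        r_G=r,
        cov_A=float(vc.H[0, 1]),
        sigma2_a=float(vc.H[0, 0]),
        clamped=clamped,
        at_boundary=clamped,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PhenotypicCorrelation:
    r: float
    p_value: float
    stars: str
    n: int


def phenotypic_correlation(x, y) -> PhenotypicCorrelation:
    """Pearson r with a two-sided t-test and star annotation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mask = np.isfinite(x) & np.isfinite(y)
    r, p = stats.pearsonr(x[mask], y[mask])
    return PhenotypicCorrelation(
        r=float(r), p_value=float(p), stars=significance_stars(p),
        n=int(mask.sum()),
    )


def phenotypic_correlation_table(
    blue: pd.DataFrame, trait_a: str, trait_b: str
) -> pd.DataFrame:
    """Per-environment phenotypic correlation between two traits.

    ``blue`` is the tidy genotype-level table (environment, genotype_id,
    trait, value); output mirrors the usual trait-by-index correlation
    tables: one row per environment with r, p and stars.
    """
    wide = blue.pivot_table(
        index=["environment", "genotype_id"], columns="trait", values="value"
    )
    for tr in (trait_a, trait_b):
        if tr not in wide.columns:
            raise KeyError(f"trait {tr!r} not present in BLUE table")
    rows = []
    for env, df in wide.groupby(level="environment"):
        pc = phenotypic_correlation(df[trait_a], df[trait_b])
        rows.append({
            "environment": env, "trait_a": trait_a, "trait_b": trait_b,
            "r": pc.r, "p_value": pc.p_value, "stars": pc.stars, "n": pc.n,
        })
    return pd.DataFrame(rows)
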