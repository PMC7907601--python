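"""Synthetic NAM population with known ground truth.

Generates everything the analysis pipeline consumes, so every stage is
testable without field data: a nested association mapping panel (half-sib
RIL families sharing one common parent, advanced by repeated selfing with
recombination), genetically correlated primary and secondary traits with
controlled heritabilities, 16-band plot spectra whose derived indices
track latent index targets, and an augmented field layout with replicated
checks.

The generator inverts the model the analysis assumes: marker effects are
drawn from a multivariate normal whose covariance induces the requested
genetic correlations, breeding values are the centered marker matrix
times those effects, and per-environment residuals carry the requested
residual correlation.  All randomness flows from one root seed through
named substreams (genotypes / effects / residuals / layout /
reflectance), so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .genomics import MarkerMatrix

DEFAULT_TRAITS = ("yield", "GPC", "NDVI", "NWI", "PRI")

_DEFAULT_H2 = {"yield": 0.3, "GPC": 0.6, "NDVI": 0.8, "NWI": 0.8, "PRI": 0.7}

_DEFAULT_GCORR = np.array(
    [
        [1.0, 0.3, 0.6, 0.5, 0.3],
        [0.3, 1.0, 0.4, 0.3, 0.3],
        [0.6, 0.4, 1.0, 0.5, 0.4],
        [0.5, 0.3, 0.5, 1.0, 0.3],
        [0.3, 0.3, 0.4, 0.3, 1.0],
    ]
)

#: 16 instrument band centers (nm); includes every wavelength the eight
#: indices reference.
DEFAULT_BANDS = (
    430, 460, 510, 531, 550, 570, 610, 640,
    680, 700, 730, 780, 800, 880, 900, 970,
)

# typical green-canopy baseline reflectance per band (fractions)
_BASELINE = {
    430: 0.05, 460: 0.05, 510: 0.08, 531: 0.10, 550: 0.12, 570: 0.10,
    610: 0.08, 640: 0.07, 680: 0.06, 700: 0.18, 730: 0.35, 780: 0.46,
    800: 0.48, 880: 0.46, 900: 0.45, 970: 0.35,
}

# senescence between heading and grain filling: NIR drops, red rises
_STAGE_SHIFT = {
    "heading": {},
    "grain_filling": {680: +0.01, 780: -0.03, 800: -0.03, 880: -0.03, 900: -0.03},
}

# latent axis -> {band: amplitude per standardized target unit}
# red-band amplitude kept small enough that R680 stays well above the
# reflectance floor: ratio indices (SR) are unbounded in 1/R680
_AXES = {
    "greenness": {680: -0.012, 780: +0.06, 800: +0.06},
    "water": {970: +0.04},
    "pigment": {531: +0.015},
    "ncpi": {430: -0.01},
    "ari": {700: +0.04},
}

_AXIS_GROUPS = {
    "greenness": ("NDVI", "SR", "GNDVI"),
    "water": ("NWI", "WI"),
    "pigment": ("PRI",),
    "ncpi": ("NCPI",),
    "ari": ("ARI",),
}


def _as_corr(mat, t: int, name: str) -> np.ndarray:
    M = np.asarray(mat, dtype=float)
    if M.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    w = np.linalg.eigvalsh((M + M.T) / 2.0)
    if w.min() < -1e-10:
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")
    return M


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with field-realistic defaults.

    The default panel mirrors a NAM population: 32 half-sib families of
    recombinant inbred lines (one common parent), five generations of
    selfing, three environments, and an augmented layout with 15-20%
    replicated check plots.  Secondary-trait heritabilities exceed the
    primary ones, as canopy indices do in practice.
    """

    n_families: int = 32
    lines_per_family: int = 20
    n_markers: int = 2000
    n_chromosomes: int = 10
    map_length_per_chrom: float = 1.0       # morgans
    selfing_generations: int = 5
    trait_names: tuple = DEFAULT_TRAITS
    target_h2: dict = field(default_factory=lambda: dict(_DEFAULT_H2))
    genetic_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_GCORR.copy())
    residual_corr: np.ndarray | None = None  # default: 0.2 off-diagonal
    n_environments: int = 3
    check_fraction: float = 0.175
    n_checks: int = 3
    n_blocks: int = 8
    block_effect_sd: float = 0.5            # x phenotypic SD of entries
    plot_error_sd: float = 0.2              # x phenotypic SD of entries
    marker_missing_rate: float = 0.0
    low_maf_fraction: float = 0.0           # markers seeded with rare alleles
    band_wavelengths: tuple = DEFAULT_BANDS
    reflectance_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        if self.n_markers % self.n_chromosomes != 0:
            raise ValueError(
                f"n_markers ({self.n_markers}) must divide evenly across "
                f"{self.n_chromosomes} chromosomes"
            )
        for tr in self.trait_names:
            h2 = self.target_h2.get(tr)
            if h2 is None:
                raise ValueError(f"target_h2 missing trait {tr!r}")
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"target_h2[{tr!r}]={h2} outside [0, 1]")
        self.genetic_corr = _as_corr(self.genetic_corr, t, "genetic_corr")
        if self.residual_corr is None:
            self.residual_corr = np.full((t, t), 0.2) + 0.8 * np.eye(t)
        self.residual_corr = _as_corr(self.residual_corr, t, "residual_corr")
        if not 0.0 <= self.check_fraction < 1.0:
            raise ValueError(f"check_fraction {self.check_fraction} outside [0, 1)")
        if not 0.0 <= self.marker_missing_rate < 1.0:
            raise ValueError("marker_missing_rate outside [0, 1)")

    @property
    def n_lines(self) -> int:
        return self.n_families * self.lines_per_family

    @property
    def environments(self) -> list:
        return [f"E{i + 1}" for i in range(self.n_environments)]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the trait simulator."""

    true_breeding_values: pd.DataFrame   # line x trait
    true_marker_effects: pd.DataFrame    # marker x trait
    realized_h2: pd.Series
    realized_genetic_corr: pd.DataFrame


# ---------------------------------------------------------------------------
# genotypes: RIL meiosis under a Haldane map
# ---------------------------------------------------------------------------

def _meiosis(h1, h2, pos, map_len, rng):
    """One gamete per row of (h1, h2): Poisson crossovers, Haldane map.

    ``h1, h2`` are (n, m) haplotype arrays over markers at map positions
    ``pos`` (morgans); crossover counts are Poisson(map_len), positions
    uniform, and the starting haplotype is random per meiosis.
    """
    n, m = h1.shape
    k = rng.poisson(map_len, size=n)
    kmax = int(k.max()) if n else 0
    if kmax == 0:
        xovers = np.full((n, 1), np.inf)
    else:
        xovers = rng.uniform(0.0, map_len, size=(n, kmax))
        mask = np.arange(kmax)[None, :] >= k[:, None]
        xovers[mask] = np.inf
    start = rng.integers(0, 2, size=n)
    # parity of crossovers left of each marker decides the source haplotype
    crossings = (xovers[:, :, None] < pos[None, None, :]).sum(axis=1)
    use_h2 = (crossings + start[:, None]) % 2 == 1
    return np.where(use_h2, h2, h1)


def simulate_nam_genotypes(config: SimulationConfig) -> MarkerMatrix:
    """Simulate a NAM panel: families of selfed RILs from one common parent.

    Founder haplotypes are drawn per locus i.i.d. Bernoulli with allele
    frequency ~ U(0.1, 0.9) (optionally a fraction of rare-allele markers
    for QC testing); each family is (common parent x founder_i) advanced
    by ``selfing_generations`` rounds of selfing with recombination.
    Returns minor-allele counts {0, 1, 2} with NaN injected at
    ``marker_missing_rate``.
    """
    rng = substream(config.seed, "genotypes")
    M = config.n_markers
    m_per_chrom = M // config.n_chromosomes
    chrom_pos = [
        np.sort(rng.uniform(0.0, config.map_length_per_chrom, size=m_per_chrom))
        for _ in range(config.n_chromosomes)
    ]

    freq = rng.uniform(0.1, 0.9, size=M)
    if config.low_maf_fraction > 0:
        n_low = int(round(config.low_maf_fraction * M))
        low_idx = rng.choice(M, size=n_low, replace=False)
        freq[low_idx] = rng.uniform(0.0, 0.05, size=n_low)
    common = (rng.random(M) < freq).astype(np.int8)

    geno = np.empty((config.n_lines, M), dtype=float)
    families = []
    line_ids = []
    row = 0
    for fam in range(config.n_families):
        founder = (rng.random(M) < freq).astype(np.int8)
        L = config.lines_per_family
        # F1 of every line in the family: common x founder
        h1 = np.tile(common, (L, 1)).astype(np.int8)
        h2 = np.tile(founder, (L, 1)).astype(np.int8)
        for _ in range(config.selfing_generations):
            new1 = np.empty_like(h1)
            new2 = np.empty_like(h2)
            ofs = 0
            for c in range(config.n_chromosomes):
                pos = chrom_pos[c]
                sl = slice(ofs, ofs + m_per_chrom)
                new1[:, sl] = _meiosis(
                    h1[:, sl], h2[:, sl], pos, config.map_length_per_chrom, rng
                )
                new2[:, sl] = _meiosis(
                    h1[:, sl], h2[:, sl], pos, config.map_length_per_chrom, rng
                )
                ofs += m_per_chrom
            h1, h2 = new1, new2
        geno[row:row + L] = (h1 + h2).astype(float)
        fam_label = f"F{fam + 1:02d}"
        families += [fam_label] * L
        line_ids += [f"{fam_label}_L{j + 1:03d}" for j in range(L)]
        row += L

    # orient to minor-allele counts
    p = geno.mean(axis=0) / 2.0
    flip = p > 0.5
    geno[:, flip] = 2.0 - geno[:, flip]

    if config.marker_missing_rate > 0:
        miss = rng.random(geno.shape) < config.marker_missing_rate
        geno[miss] = np.nan

    marker_ids = []
    chroms = []
    positions = []
    for c in range(config.n_chromosomes):
        for j in range(m_per_chrom):
            marker_ids.append(f"M{c + 1:02d}_{j + 1:04d}")
            chroms.append(c + 1)
            positions.append(chrom_pos[c][j])
    gdf = pd.DataFrame(geno, index=pd.Index(line_ids, name="line"),
                       columns=marker_ids)
    pos_df = pd.DataFrame(
        {"marker": marker_ids, "chrom": chroms, "pos": positions}
    )
    fam_s = pd.Series(families, index=gdf.index, name="family")
    return MarkerMatrix(gdf, positions=pos_df, families=fam_s)


# ---------------------------------------------------------------------------
# traits: correlated breeding values + per-environment residuals
# ---------------------------------------------------------------------------

def simulate_traits(
    markers: MarkerMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Correlated trait values per genotype and environment, plus truth.

    Per-marker effect vectors are multivariate normal with the requested
    genetic correlation; each trait's effect column is rescaled so the
    realized breeding-value variance is one, making the residual variance
    (1 - h2)/h2 deliver the target heritability.  A trait with target
    h2 = 0 has all-zero effects and pure noise phenotypes; h2 = 1 yields
    phenotype == breeding value exactly.
    """
    rng = substream(config.seed, "effects")
    rng_resid = substream(config.seed, "residuals")
    traits = list(config.trait_names)
    t = len(traits)
    X = markers.geno.to_numpy(dtype=float)
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    W = X - X.mean(axis=0)
    n, m = W.shape

    Lg = np.linalg.cholesky(config.genetic_corr + 1e-12 * np.eye(t))
    E = rng.standard_normal((m, t)) @ Lg.T
    BV = W @ E
    sigma_e = np.empty(t)
    for j, tr in enumerate(traits):
        h2 = config.target_h2[tr]
        if h2 == 0.0:
            E[:, j] = 0.0
            BV[:, j] = 0.0
            sigma_e[j] = 1.0
            continue
        s = BV[:, j].std()
        if s <= 0:
            raise ValueError(
                f"no genetic variation segregating for trait {tr!r}"
            )
        E[:, j] /= s
        BV[:, j] /= s
        sigma_e[j] = math.sqrt((1.0 - h2) / h2)

    Lr = np.linalg.cholesky(config.residual_corr + 1e-12 * np.eye(t))
    rows = []
    resid_var = np.zeros(t)
    for env in config.environments:
        resid = (rng_resid.standard_normal((n, t)) @ Lr.T) * sigma_e
        resid_var += resid.var(axis=0) / config.n_environments
        vals = BV + resid
        for j, tr in enumerate(traits):
            rows.append(pd.DataFrame({
                "environment": env,
                "genotype_id": markers.line_ids,
                "trait": tr,
                "value": vals[:, j],
            }))
    table = pd.concat(rows, ignore_index=True)

    bv_df = pd.DataFrame(BV, index=markers.line_ids, columns=traits)
    gvar = BV.var(axis=0)
    realized_h2 = pd.Series(
        np.where(gvar + resid_var > 0, gvar / (gvar + resid_var), 0.0),
        index=traits, name="realized_h2",
    )
    with np.errstate(invalid="ignore"):
        rcorr = np.corrcoef(BV, rowvar=False) if t > 1 else np.ones((1, 1))
    truth = SimulationTruth(
        true_breeding_values=bv_df,
        true_marker_effects=pd.DataFrame(E, index=markers.marker_ids,
                                         columns=traits),
        realized_h2=realized_h2,
        realized_genetic_corr=pd.DataFrame(rcorr, index=traits, columns=traits),
    )
    return table, truth


# ---------------------------------------------------------------------------
# field layout: augmented blocks with replicated checks
# ---------------------------------------------------------------------------

def checks_per_block(check_fraction: float, plots_per_block: int) -> int:
    """Check plots per block: round(fraction x plots), but at least 2."""
    return max(2, int(round(check_fraction * plots_per_block)))


def simulate_field_layout(
    genotype_values: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Assign genotypes to augmented blocks and add block / plot noise.

    Unreplicated entries appear exactly once per environment; the named
    checks appear once in every block.  Block effects and plot errors are
    drawn per trait with standard deviations ``block_effect_sd`` and
    ``plot_error_sd`` expressed as multiples of that trait's phenotypic
    SD among entries (zero SD means plot value == genotype value).
    Returns a wide plot table: environment, block_id, plot_id,
    genotype_id, is_check, one column per trait.
    """
    rng = substream(config.seed, "layout")
    traits = list(config.trait_names)
    out = []
    for env, env_df in genotype_values.groupby("environment", sort=False):
        wide = env_df.pivot_table(
            index="genotype_id", columns="trait", values="value", sort=False
        )[traits]
        lines = wide.index.to_numpy()
        n = len(lines)
        n_blocks = config.n_blocks
        entries_per_block = math.ceil(n / n_blocks)
        n_checks = config.n_checks
        sd = wide.to_numpy().std(axis=0)

        # check genotypes: constant genotypic value within environment
        check_ids = [f"CHECK_{i + 1}" for i in range(n_checks)]
        check_vals = wide.to_numpy().mean(axis=0) + rng.standard_normal(
            (n_checks, len(traits))
        ) * sd

        order = rng.permutation(n)
        block_eff = rng.standard_normal((n_blocks, len(traits))) * (
            config.block_effect_sd * sd
        )
        rows = []
        for b in range(n_blocks):
            entry_idx = order[b * entries_per_block:(b + 1) * entries_per_block]
            block_genos = [(lines[i], False, wide.to_numpy()[i]) for i in entry_idx]
            block_genos += [
                (check_ids[c], True, check_vals[c]) for c in range(n_checks)
            ]
            for geno_id, is_check, gvals in block_genos:
                noise = rng.standard_normal(len(traits)) * (
                    config.plot_error_sd * sd
                )
                rows.append(
                    [env, f"B{b + 1:02d}", geno_id, is_check]
                    + list(gvals + block_eff[b] + noise)
                )
        df = pd.DataFrame(
            rows, columns=["environment", "block_id", "genotype_id", "is_check"]
            + traits,
        )
        df.insert(2, "plot_id", [f"{env}_P{i + 1:04d}" for i in range(len(df))])
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# reflectance: latent-axis canopy model
# ---------------------------------------------------------------------------

def simulate_reflectance(
    sri_values: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Emit 16-band spectra whose indices track the latent index targets.

    ``sri_values`` carries metadata columns (plot or genotype ids,
    environment, optionally stage) plus one column per index target
    (NDVI, NWI, PRI, ...).  Each target is standardized and mapped onto a
    latent physiological axis (greenness / water / pigment plus dedicated
    pigment-band axes), which shifts the relevant bands linearly around a
    green-canopy baseline.  Records without a stage column are emitted
    for both growth stages.  All reflectances lie in (0, 1).
    """
    from .spectral import INDEX_NAMES, resolve_band_map

    bands = list(config.band_wavelengths)
    resolve_band_map(bands)   # errors early if a required wavelength is absent
    rng = substream(config.seed, "reflectance")

    meta_cols = [
        c for c in ("plot_id", "genotype_id", "environment", "stage")
        if c in sri_values.columns
    ]
    idx_cols = [c for c in sri_values.columns if c in INDEX_NAMES]
    if not idx_cols:
        raise ValueError("no index target columns found in sri_values")

    if "stage" in sri_values.columns:
        frames = [sri_values]
    else:
        frames = []
        for stage in ("heading", "grain_filling"):
            f = sri_values.copy()
            f["stage"] = stage
            frames.append(f)
        meta_cols.append("stage")
    full = pd.concat(frames, ignore_index=True)
    n = len(full)

    # standardized axis scores: mean of the z-scores of each axis's targets
    z = {}
    for axis, members in _AXIS_GROUPS.items():
        present = [c for c in members if c in idx_cols]
        if not present:
            continue
        zs = []
        for c in present:
            v = full[c].to_numpy(dtype=float)
            s = v.std()
            zs.append((v - v.mean()) / s if s > 0 else np.zeros(n))
        z[axis] = np.clip(np.mean(zs, axis=0), -3.5, 3.5)

    spectra = {}
    for wl in bands:
        base = _BASELINE.get(wl, 0.2)
        vals = np.full(n, base)
        for stage, shifts in _STAGE_SHIFT.items():
            if wl in shifts:
                vals = vals + shifts[wl] * (full["stage"] == stage).to_numpy()
        for axis, score in z.items():
            amp = _AXES[axis].get(wl)
            if amp:
                vals = vals + amp * score
        vals = vals + rng.standard_normal(n) * config.reflectance_noise_sd
        spectra[f"R{wl}"] = np.clip(vals, 0.01, 0.999)

    panel = full[meta_cols].copy()
    for k, v in spectra.items():
        panel[k] = v
    return panel


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig):
    """Run the full generator: genotypes, traits, layout, spectra.

    Returns ``(markers, genotype_values, plots, reflectance, truth)`` —
    the complete synthetic study a field season would have produced.
    """
    markers = simulate_nam_genotypes(config)
    values, truth = simulate_traits(markers, config)
    plots = simulate_field_layout(values, config)
    idx_cols = [c for c in config.trait_names
                if c in ("NDVI", "NWI", "WI", "SR", "GNDVI", "PRI", "NCPI", "ARI")]
    sri_latent = plots[["plot_id", "genotype_id", "environment"] + idx_cols]
    reflectance = simulate_reflectance(sri_latent, config)
    return markers, values, plots, reflectance, truth
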