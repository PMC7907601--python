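"""File formats and run manifests.

Tabular conventions:

* genotype CSV — lines in rows, markers in columns, cells in
  {0, 1, 2, NA} (imputed files may hold fractional dosages in [0, 2]);
* phenotype CSV — tidy long: environment, genotype_id, trait, value;
* plot CSV — wide: environment, block_id, plot_id, genotype_id,
  is_check, one column per trait;
* reflectance CSV — plot metadata plus one ``R<nm>`` column per band.

VCF import maps GT fields to minor-allele counts; multiallelic records
are skipped with a logged count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import MarkerMatrix

logger = logging.getLogger(__name__)


def read_genotypes(path, fmt: str = "csv") -> MarkerMatrix:
    """Read a line x marker genotype matrix from CSV or VCF."""
    if fmt == "csv":
        return _read_genotypes_csv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df.isna().to_numpy()
    bad = (~raw_na) & (np.isnan(vals) | (vals < 0) | (vals > 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"unparseable genotype cell {df.iat[r, c]!r} at line "
            f"{df.index[r]!r}, marker {df.columns[c]!r}"
        )
    out = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return MarkerMatrix(out)


def _read_genotypes_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows, ids = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        g = np.asarray(v.gt_types, dtype=float)
        code = np.select([g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], np.nan)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        rows.append(code)
    if n_multi:
        logger.warning("skipped %d multiallelic VCF records", n_multi)
    geno = pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="line"), columns=ids
    )
    # orient to minor-allele counts
    p = geno.mean(axis=0, skipna=True) / 2.0
    flip = p > 0.5
    geno.loc[:, flip] = 2.0 - geno.loc[:, flip]
    return MarkerMatrix(geno)


def write_genotypes(m: MarkerMatrix, path) -> None:
    out = m.geno.copy()
    # write clean integer codes where the data are integral
    if np.allclose(out.fillna(0) % 1, 0):
        out = out.astype("Int64")
    out.to_csv(path, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"environment", "genotype_id", "trait", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_plots(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"environment", "block_id", "genotype_id", "is_check"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"plot CSV missing columns {sorted(missing)}")
    return df


def read_reflectance(path) -> pd.DataFrame:
    from .spectral import band_columns

    df = pd.read_csv(path)
    if not band_columns(df):
        raise ValueError("reflectance CSV has no band columns (R<nm>)")
    return df


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, stages: list) -> Path:
    """Machine-readable run manifest (no timestamps: reruns are
    byte-identical)."""
    from . import __version__

    manifest = {
        "package": "phenogs",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
        "stages": list(stages),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
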