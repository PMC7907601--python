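"""Spectral reflectance indices from multiband canopy reflectance.

A plot is scanned at 16 wavebands between 420 and 980 nm at two growth
stages (heading, grain filling); repeated scans are averaged per plot
before any index is computed (index-of-mean, not mean-of-index).  Eight
indices are derived:

====== =====================================  ==========================
 name   formula                                physiology
====== =====================================  ==========================
 NDVI   (R800 - R680)/(R800 + R680)            biomass / greenness
 NWI    (R970 - R880)/(R970 + R880)            plant water status
 WI     R970 / R900                            plant water status
 SR     R800 / R680                            green biomass
 GNDVI  (R780 - R550)/(R780 + R550)            chlorophyll content
 PRI    (R531 - R570)/(R531 + R570)            carotenoids
 NCPI   (R680 - R430)/(R680 + R430)            chlorophyll pigments
 ARI    R800 * (1/R550 - 1/R700)               anthocyanins
====== =====================================  ==========================

Instrument band centers rarely coincide exactly with the nominal
wavelengths above, so each required wavelength is resolved to the
nearest available band within a configurable maximum distance.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("heading", "grain_filling")

#: wavelength (nm) -> role in the index formulas
REQUIRED_WAVELENGTHS = (430, 531, 550, 570, 680, 700, 780, 800, 880, 900, 970)

#: index -> (numerator-style lambda over resolved band dict)
INDEX_NAMES = ("NDVI", "NWI", "WI", "SR", "GNDVI", "PRI", "NCPI", "ARI")

_DENOM_GUARD = 1e-9

_META_COLS = ("plot_id", "genotype_id", "environment", "stage")


def band_columns(df: pd.DataFrame) -> dict[int, str]:
    """Map wavelength -> column name for columns named like ``R680``."""
    out = {}
    for col in df.columns:
        m = re.fullmatch(r"R(\d+)", str(col))
        if m:
            out[int(m.group(1))] = col
    return out


def resolve_band_map(
    available_nm, required=REQUIRED_WAVELENGTHS, max_distance_nm: float = 15.0
) -> dict[int, int]:
    """Nearest-band matching: required wavelength -> available wavelength.

    Raises if any required wavelength has no band within
    ``max_distance_nm``, naming the wavelength and the indices needing it.
    """
    available = np.asarray(sorted(available_nm), dtype=float)
    needs = {
        430: ["NCPI"], 531: ["PRI"], 550: ["GNDVI", "ARI"], 570: ["PRI"],
        680: ["NDVI", "SR", "NCPI"], 700: ["ARI"], 780: ["GNDVI"],
        800: ["NDVI", "SR", "ARI"], 880: ["NWI"], 900: ["WI"], 970: ["NWI", "WI"],
    }
    out = {}
    for wl in required:
        j = int(np.abs(available - wl).argmin())
        if abs(available[j] - wl) > max_distance_nm:
            raise ValueError(
                f"no band within {max_distance_nm} nm of {wl} nm "
                f"(required by {', '.join(needs.get(wl, ['?']))})"
            )
        out[wl] = int(available[j])
    return out


def normalize_reflectance(panel: pd.DataFrame) -> pd.DataFrame:
    """Accept percent or fractional reflectance; return fractions.

    Instruments report either scale; values are treated as percent and
    divided by 100 whenever the panel maximum exceeds 1.5.
    """
    cols = list(band_columns(panel).values())
    out = panel.copy()
    if len(cols) and np.nanmax(out[cols].to_numpy(dtype=float)) > 1.5:
        logger.info("reflectance looks like percent; dividing bands by 100")
        out[cols] = out[cols] / 100.0
    return out


def average_plot_reflectance(
    raw_scans: pd.DataFrame, expected_plots=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average repeated scans to one record per plot x stage.

    Returns ``(panel, exclusion_report)``; the report lists any plot in
    ``expected_plots`` with zero scans (plots are never silently
    dropped — absence is reported).  Scans with mismatched band sets
    (NaN in some bands of a plot) raise.
    """
    bands = band_columns(raw_scans)
    if not bands:
        raise ValueError("no reflectance columns (expected names like 'R680')")
    cols = list(bands.values())
    if raw_scans[cols].isna().any().any():
        bad = raw_scans[cols].isna().any(axis=0)
        raise ValueError(
            f"mismatched band sets across scans: missing values in "
            f"{bad.index[bad].tolist()}"
        )
    keys = [c for c in _META_COLS if c in raw_scans.columns]
    panel = raw_scans.groupby(keys, as_index=False, sort=False)[cols].mean()

    if expected_plots is not None:
        seen = set(panel["plot_id"])
        missing = [p for p in expected_plots if p not in seen]
        report = pd.DataFrame({"plot_id": missing, "reason": "zero scans"})
    else:
        report = pd.DataFrame(columns=["plot_id", "reason"])
    return panel, report


def compute_indices(
    panel: pd.DataFrame, max_distance_nm: float = 15.0
) -> pd.DataFrame:
    """Compute the eight spectral reflectance indices for every record.

    Any index whose denominator band is <= 1e-9 is set to NaN (never
    +/-inf) and the event is logged.  Metadata columns present in the
    panel (plot/genotype/environment/stage) are carried through.
    """
    panel = normalize_reflectance(panel)
    bands = band_columns(panel)
    bmap = resolve_band_map(bands.keys(), max_distance_nm=max_distance_nm)

    def R(wl: int) -> np.ndarray:
        return panel[bands[bmap[wl]]].to_numpy(dtype=float)

    def safe_div(num, den, name):
        den = np.asarray(den, dtype=float)
        bad = np.abs(den) <= _DENOM_GUARD
        if bad.any():
            logger.warning(
                "%s: %d record(s) with near-zero denominator set missing",
                name, int(bad.sum()),
            )
        out = np.where(bad, np.nan, num / np.where(bad, np.nan, den))
        return out

    r430, r531, r550, r570 = R(430), R(531), R(550), R(570)
    r680, r700, r780, r800 = R(680), R(700), R(780), R(800)
    r880, r900, r970 = R(880), R(900), R(970)

    out = panel[[c for c in _META_COLS if c in panel.columns]].copy()
    out["NDVI"] = safe_div(r800 - r680, r800 + r680, "NDVI")
    out["NWI"] = safe_div(r970 - r880, r970 + r880, "NWI")
    out["WI"] = safe_div(r970, r900, "WI")
    out["SR"] = safe_div(r800, r680, "SR")
    out["GNDVI"] = safe_div(r780 - r550, r780 + r550, "GNDVI")
    out["PRI"] = safe_div(r531 - r570, r531 + r570, "PRI")
    out["NCPI"] = safe_div(r680 - r430, r680 + r430, "NCPI")
    out["ARI"] = r800 * (safe_div(1.0, r550, "ARI") - safe_div(1.0, r700, "ARI"))
    return out
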