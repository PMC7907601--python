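"""Marker quality control, imputation, and the genomic relationship matrix.

Genotypes are coded as minor-allele counts {0, 1, 2} with NaN for missing,
held in a pandas DataFrame with lines in rows and markers in columns (the
natural orientation for the n << p panels of genomic selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = (0.0, 1.0, 2.0)


@dataclass
class MarkerMatrix:
    """Line x marker genotype codes (minor-allele counts, NaN = missing)."""

    geno: pd.DataFrame
    positions: pd.DataFrame | None = None  # columns: marker, chrom, pos
    families: pd.Series | None = None      # line -> family label

    def __post_init__(self) -> None:
        vals = self.geno.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = np.argwhere(~np.isin(vals, VALID_CODES) & np.isfinite(vals))
            r, c = bad[0]
            raise ValueError(
                f"invalid genotype code {vals[r, c]!r} at line "
                f"{self.geno.index[r]!r}, marker {self.geno.columns[c]!r}"
            )

    @property
    def line_ids(self) -> pd.Index:
        return self.geno.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.geno.columns

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def marker_missing_rate(self) -> pd.Series:
        return self.geno.isna().mean(axis=0)

    def line_missing_rate(self) -> pd.Series:
        return self.geno.isna().mean(axis=1)

    def maf(self) -> pd.Series:
        """Minor allele frequency per marker, over observed calls."""
        p = self.geno.mean(axis=0, skipna=True) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, lines=None, markers=None) -> "MarkerMatrix":
        geno = self.geno
        if lines is not None:
            geno = geno.loc[lines]
        if markers is not None:
            geno = geno[markers]
        pos = self.positions
        if pos is not None and markers is not None:
            pos = pos[pos["marker"].isin(geno.columns)].reset_index(drop=True)
        fam = self.families
        if fam is not None and lines is not None:
            fam = fam.loc[geno.index]
        return MarkerMatrix(geno, pos, fam)


@dataclass
class QCReport:
    """Counts removed at each quality-control step, in the order applied."""

    n_lines_in: int
    n_markers_in: int
    lines_removed_missing: int
    markers_removed_missing: int
    markers_removed_maf: int
    n_lines_out: int
    n_markers_out: int
    removed_lines: list = field(default_factory=list)
    removed_markers_missing: list = field(default_factory=list)
    removed_markers_maf: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("lines_in", self.n_lines_in),
            ("markers_in", self.n_markers_in),
            ("lines_removed_missing", self.lines_removed_missing),
            ("markers_removed_missing", self.markers_removed_missing),
            ("markers_removed_maf", self.markers_removed_maf),
            ("lines_out", self.n_lines_out),
            ("markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


@dataclass
class GRM:
    """Genomic relationship matrix among lines (VanRaden method 1)."""

    values: np.ndarray
    line_ids: pd.Index
    n_clipped_eigenvalues: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)

    def subset(self, lines) -> np.ndarray:
        idx = self.line_ids.get_indexer(lines)
        if (idx < 0).any():
            missing = [l for l, i in zip(lines, idx) if i < 0]
            raise KeyError(f"lines absent from GRM: {missing[:5]}")
        return self.values[np.ix_(idx, idx)]


def sample_variance_factor(G: np.ndarray) -> float:
    """Expected sample variance of genetic values per unit sigma2_a.

    For g ~ N(0, G sigma2_a), E[var_n(g)] = sigma2_a * (tr G - 1'G1/n)/(n-1).
    In panels of inbred or related lines the mean diagonal of a VanRaden
    G exceeds one, so this factor converts the REML variance component to
    the genetic variance realized among the study lines — the scale on
    which heritability is usually quoted.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    return float((np.trace(G) - G.sum() / n) / (n - 1))


def qc_filter(
    m: MarkerMatrix,
    max_marker_missing: float = 0.20,
    max_line_missing: float = 0.10,
    min_maf: float = 0.10,
) -> tuple[MarkerMatrix, QCReport]:
    """Apply the standard three-step marker QC.

    Order: lines with > ``max_line_missing`` missing calls are dropped
    first, then markers with > ``max_marker_missing`` missing, then markers
    with MAF < ``min_maf`` (MAF computed after the missingness filters).
    Markers at exactly the MAF threshold are retained.
    """
    for name, thr in (("max_marker_missing", max_marker_missing),
                      ("max_line_missing", max_line_missing),
                      ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")

    n_lines_in, n_markers_in = m.n_lines, m.n_markers

    line_rate = m.line_missing_rate()
    keep_lines = line_rate.index[line_rate <= max_line_missing]
    removed_lines = line_rate.index.difference(keep_lines).tolist()
    if len(keep_lines) == 0:
        raise ValueError("line missingness filter removed every line")
    step1 = m.subset(lines=keep_lines)

    mk_rate = step1.marker_missing_rate()
    keep_mk = mk_rate.index[mk_rate <= max_marker_missing]
    removed_mk_missing = mk_rate.index.difference(keep_mk).tolist()
    if len(keep_mk) == 0:
        raise ValueError("marker missingness filter removed every marker")
    step2 = step1.subset(markers=keep_mk)

    maf = step2.maf()
    keep_maf = maf.index[maf >= min_maf]
    removed_maf = maf.index.difference(keep_maf).tolist()
    if len(keep_maf) == 0:
        raise ValueError("MAF filter removed every marker")
    out = step2.subset(markers=keep_maf)

    report = QCReport(
        n_lines_in=n_lines_in,
        n_markers_in=n_markers_in,
        lines_removed_missing=len(removed_lines),
        markers_removed_missing=len(removed_mk_missing),
        markers_removed_maf=len(removed_maf),
        n_lines_out=out.n_lines,
        n_markers_out=out.n_markers,
        removed_lines=removed_lines,
        removed_markers_missing=removed_mk_missing,
        removed_markers_maf=removed_maf,
    )
    return out, report


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing codes by the per-marker mean of observed codes."""
    all_missing = m.geno.isna().all(axis=0)
    if all_missing.any():
        bad = m.geno.columns[all_missing].tolist()
        raise ValueError(f"cannot impute all-missing markers: {bad[:5]}")
    filled = m.geno.fillna(m.geno.mean(axis=0, skipna=True))
    return MarkerMatrix(filled.astype(float), m.positions, m.families)


def compute_grm(m: MarkerMatrix, eig_floor: float = 1e-8) -> GRM:
    """VanRaden method 1: G = WW' / (2 sum p(1-p)), W column-centered by 2p.

    Eigenvalues below ``eig_floor`` are clipped up to it so the returned
    matrix is usable wherever a positive-definite covariance is required.
    """
    X = m.geno.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("GRM requires complete genotypes; run impute_missing first")
    p = X.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0

    w, V = np.linalg.eigh(G)
    n_clip = int((w < eig_floor).sum())
    if n_clip:
        logger.info("GRM conditioning: clipped %d eigenvalues to %g", n_clip, eig_floor)
        w = np.clip(w, eig_floor, None)
        G = (V * w) @ V.T
        G = (G + G.T) / 2.0
    return GRM(G, m.line_ids, n_clipped_eigenvalues=n_clip)
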