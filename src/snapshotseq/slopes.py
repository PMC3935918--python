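"""Intron density slopes: the direct readout of relative synthesis rate.

Each intron's 100-bin density profile is fit by ordinary least squares; in
transcription direction the model predicts a constant negative slope
``-c0S * Talpha`` whose magnitude is proportional to the gene's synthesis
rate.  Goodness of fit is summarized as a true-discovery rate
``TDR = 1 - Phi(slope / SE)``: the complement of the one-tailed probability
of a slope at least this negative under the null of no trend.

Usable introns (long enough, enough informative bins) are aggregated to a
per-gene slope with a length- and TDR^2-weighted quadrature error, and the
expression and goodness-of-fit filters select the cohort handed to the
solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lifecycle import DEFAULT_TALPHA

N_BINS = 100
MIN_NONZERO_BINS = 20
MIN_INTRON_BP = 5_000
MIN_TSS_OFFSET_BP = 5_000
D3INT_WINDOW_BP = 10_000

SPIKE_FOLD = 10.0
MAX_SPIKE_BINS = 5


@dataclass(frozen=True)
class IntronSlopeFit:
    """OLS fit of one intron's binned density profile."""

    slope: float  # density per bp, transcription direction
    se: float
    tdr: float
    n_bins_used: int
    usable: bool
    reason: str = ""


def tdr_from_z(z: float) -> float:
    """TDR = 1 - Phi(z) for z = slope/SE; more-negative slopes -> TDR -> 1."""
    return float(stats.norm.sf(z))


def fit_intron_slope(
    midpoints_bp,
    densities,
    min_nonzero_bins: int = MIN_NONZERO_BINS,
    include_zero_bins: bool = False,
    spike_fold: float = SPIKE_FOLD,
    max_spike_bins: int = MAX_SPIKE_BINS,
) -> IntronSlopeFit:
    """Least-squares slope of an intron's binned density profile.

    Parameters
    ----------
    midpoints_bp
        Bin midpoint positions in bp from the intron's 5' end (transcription
        direction).
    densities
        Normalized density per bin.
    include_zero_bins
        Fit over all bins instead of only nonzero ones (used by the
        counting-noise experiment, where sparse introns would otherwise have
        no estimate at all).

    A bin is a density spike if it exceeds ``spike_fold`` times the median
    nonzero density; spike bins are dropped, and the intron is unusable when
    more than ``max_spike_bins`` bins are spikes (spikes typically betray an
    embedded non-coding RNA, not the nascent-transcription profile).
    """
    x = np.asarray(midpoints_bp, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape:
        raise ValueError("midpoints and densities must have the same shape")

    nonzero = y > 0
    spikes = np.zeros_like(nonzero)
    if nonzero.any():
        med = np.median(y[nonzero])
        spikes = y > spike_fold * med
        if spikes.sum() > max_spike_bins:
            return IntronSlopeFit(np.nan, np.nan, np.nan, 0, False, "spiky")

    keep = (~spikes) & (nonzero | include_zero_bins)
    n = int(keep.sum())
    if n < (2 if include_zero_bins else min_nonzero_bins):
        return IntronSlopeFit(np.nan, np.nan, np.nan, n, False, "too_few_bins")

    res = stats.linregress(x[keep], y[keep])
    slope, se = float(res.slope), float(res.stderr)
    if not np.isfinite(se) or se == 0:
        # zero residual variance (noiseless data): slope is exact
        tdr = 1.0 if slope < 0 else (0.0 if slope > 0 else 0.5)
        return IntronSlopeFit(slope, 0.0, tdr, n, True)
    return IntronSlopeFit(slope, se, tdr_from_z(slope / se), n, True)


def fit_intron_slopes_table(
    intron_bins: pd.DataFrame,
    min_nonzero_bins: int = MIN_NONZERO_BINS,
    **kwargs,
) -> pd.DataFrame:
    """Fit every intron in a long-format bin table.

    ``intron_bins`` columns: gene_id, intron_ordinal, midpoint_bp, density,
    and intron_bp (constant per intron).  Returns one row per intron with the
    fit and the intron's length/ordinal metadata.
    """
    rows = []
    cols = ["gene_id", "intron_ordinal"]
    for (gene_id, ordinal), grp in intron_bins.groupby(cols, sort=True):
        fit = fit_intron_slope(
            grp["midpoint_bp"].to_numpy(),
            grp["density"].to_numpy(),
            min_nonzero_bins=min_nonzero_bins,
            **kwargs,
        )
        rows.append(
            {
                "gene_id": gene_id,
                "intron_ordinal": ordinal,
                "intron_bp": float(grp["intron_bp"].iloc[0]),
                "tss_offset_bp": float(grp["tss_offset_bp"].iloc[0])
                if "tss_offset_bp" in grp
                else np.nan,
                "slope": fit.slope,
                "se": fit.se,
                "tdr": fit.tdr,
                "n_bins_used": fit.n_bins_used,
                "usable": fit.usable,
            }
        )
    return pd.DataFrame(rows)


def fit_intron_slopes_matrix(
    meta: pd.DataFrame,
    midpoints: np.ndarray,
    densities: np.ndarray,
    min_nonzero_bins: int = MIN_NONZERO_BINS,
    spike_fold: float = SPIKE_FOLD,
    max_spike_bins: int = MAX_SPIKE_BINS,
) -> pd.DataFrame:
    """Vectorized equivalent of :func:`fit_intron_slopes_table`.

    ``midpoints`` and ``densities`` are (n_introns, n_bins) arrays aligned
    with the rows of ``meta`` (gene_id, intron_ordinal, intron_bp and
    optionally tss_offset_bp).  Produces the same numbers as the per-intron
    scalar path; used where cohorts have tens of thousands of introns.
    """
    X = np.asarray(midpoints, dtype=float)
    Y = np.asarray(densities, dtype=float)
    n_int, _ = Y.shape

    nonzero = Y > 0
    any_nz = nonzero.any(axis=1)
    med = np.full(n_int, np.inf)
    if any_nz.any():
        med[any_nz] = np.nanmedian(
            np.where(nonzero[any_nz], Y[any_nz], np.nan), axis=1
        )
    spikes = Y > spike_fold * med[:, None]
    spiky = spikes.sum(axis=1) > max_spike_bins

    keep = (~spikes) & nonzero
    n = keep.sum(axis=1).astype(float)
    ok = (~spiky) & (n >= min_nonzero_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        sx = np.where(keep, X, 0.0).sum(axis=1)
        sy = np.where(keep, Y, 0.0).sum(axis=1)
        xm, ym = sx / n, sy / n
        dx = np.where(keep, X - xm[:, None], 0.0)
        dy = np.where(keep, Y - ym[:, None], 0.0)
        sxx = (dx**2).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        syy = (dy**2).sum(axis=1)
        slope = sxy / sxx
        sse = np.maximum(syy - slope * sxy, 0.0)
        se = np.sqrt(sse / np.maximum(n - 2, 1) / sxx)
        z = np.where(se > 0, slope / se, np.where(slope < 0, -np.inf, np.where(slope > 0, np.inf, 0.0)))
    tdr = stats.norm.sf(z)

    out = meta.reset_index(drop=True).copy()
    if "tss_offset_bp" not in out.columns:
        out["tss_offset_bp"] = np.nan
    out["slope"] = np.where(ok, slope, np.nan)
    out["se"] = np.where(ok, se, np.nan)
    out["tdr"] = np.where(ok, tdr, np.nan)
    out["n_bins_used"] = np.where(ok, n, keep.sum(axis=1)).astype(int)
    out["usable"] = ok
    return out[
        ["gene_id", "intron_ordinal", "intron_bp", "tss_offset_bp",
         "slope", "se", "tdr", "n_bins_used", "usable"]
    ]


def aggregate_gene_slope(slopes, ses, tdrs, intron_lengths) -> tuple[float, float, float]:
    """Combine one gene's usable intron slopes.

    The gene slope is the arithmetic mean of intron slopes; its error
    combines the intron SEs in quadrature with weights proportional to
    intron length times squared TDR, ``eps_g = sqrt(sum(w_i^2 eps_i^2)) /
    sum(w_i)``; the gene TDR comes from the z-score slope/eps.
    """
    slopes = np.asarray(slopes, dtype=float)
    ses = np.asarray(ses, dtype=float)
    tdrs = np.asarray(tdrs, dtype=float)
    w = np.asarray(intron_lengths, dtype=float) * tdrs**2
    if len(slopes) == 0:
        raise ValueError("no usable introns")
    slope_g = float(np.mean(slopes))
    wsum = float(np.sum(w))
    if wsum == 0:
        return slope_g, np.nan, np.nan
    eps_g = float(np.sqrt(np.sum(w**2 * ses**2)) / wsum)
    if eps_g == 0:
        tdr_g = 1.0 if slope_g < 0 else (0.0 if slope_g > 0 else 0.5)
    else:
        tdr_g = tdr_from_z(slope_g / eps_g)
    return slope_g, eps_g, tdr_g


def gene_slopes_table(
    intron_fits: pd.DataFrame,
    min_intron_bp: float = MIN_INTRON_BP,
    min_tss_offset_bp: float | None = MIN_TSS_OFFSET_BP,
) -> pd.DataFrame:
    """Aggregate per-intron fits to per-gene slopes.

    An intron contributes only if its fit is usable, it is at least
    ``min_intron_bp`` long and (when TSS offsets are known and the filter is
    on) starts more than ``min_tss_offset_bp`` downstream of the TSS, where
    promoter-proximal pausing would bend the profile.
    """
    f = intron_fits[intron_fits["usable"]].copy()
    f = f[f["intron_bp"] >= min_intron_bp]
    if min_tss_offset_bp is not None and f["tss_offset_bp"].notna().any():
        f = f[~(f["tss_offset_bp"] <= min_tss_offset_bp)]
    rows = []
    for gene_id, grp in f.groupby("gene_id", sort=True):
        slope, eps, tdr = aggregate_gene_slope(
            grp["slope"], grp["se"], grp["tdr"], grp["intron_bp"]
        )
        rows.append(
            {
                "gene_id": gene_id,
                "slope": slope,
                "se": eps,
                "tdr": tdr,
                "n_introns_used": len(grp),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "slope", "se", "tdr", "n_introns_used"]
    )


def filter_genes_for_model(
    gene_slopes: pd.DataFrame,
    gene_densities: pd.DataFrame,
    coding: pd.Series | None = None,
    min_tdr: float = 0.90,
    max_d_int: float = 1.00,
    max_d_exn: float = 50.0,
) -> pd.DataFrame:
    """Select the gene cohort used to solve the model.

    Keeps genes with consensus slope TDR >= ``min_tdr``, mean intron density
    <= ``max_d_int`` (removes density spikes), mean exon density <=
    ``max_d_exn`` (avoids a few very highly expressed genes dominating), and
    coding genes only when a coding flag is supplied.  Raises with per-filter
    diagnostics if nothing survives.
    """
    df = gene_slopes.merge(
        gene_densities[["gene_id", "d_int", "d_exn"]], on="gene_id", how="inner"
    )
    counts = {"input": len(df)}
    m_tdr = df["tdr"] >= min_tdr
    m_int = df["d_int"] <= max_d_int
    m_exn = df["d_exn"] <= max_d_exn
    mask = m_tdr & m_int & m_exn
    counts.update(
        fail_tdr=int((~m_tdr).sum()),
        fail_d_int=int((~m_int).sum()),
        fail_d_exn=int((~m_exn).sum()),
    )
    if coding is not None:
        m_cod = df["gene_id"].map(coding).fillna(False).astype(bool)
        counts["fail_coding"] = int((~m_cod).sum())
        mask &= m_cod
    out = df[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no genes pass the model filters: {counts}")
    return out


def compute_d3int(
    intron_windows: pd.DataFrame, window_bp: float = D3INT_WINDOW_BP
) -> pd.DataFrame:
    """Per-gene D_3'INT: mean density over the 3'-most 10 kb of each intron.

    ``intron_windows`` has one row per intron with columns gene_id,
    intron_ordinal, d3int (mean density over the window -- the whole intron
    when shorter than ``window_bp``).  Returns per-gene mean and within-gene
    standard error (ddof=1; NaN for single-intron genes).
    """
    rows = []
    for gene_id, grp in intron_windows.groupby("gene_id", sort=True):
        vals = grp["d3int"].to_numpy(dtype=float)
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(
            {
                "gene_id": gene_id,
                "d3int": float(np.mean(vals)),
                "d3int_se": se,
                "n_introns": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "d3int", "d3int_se", "n_introns"])


def proxy_consistency(gene_slopes: pd.DataFrame, d3int: pd.DataFrame) -> tuple[float, float]:
    """Log-log regression of |gene slope| on D_3'INT.

    Both quantities are proportional to c0S (the latter up to the Tp term),
    so a slope near 1 indicates that D_3'INT tracks the direct slope-based
    synthesis readout.  Non-positive values are excluded pairwise; requires
    at least 10 usable genes.
    """
    df = gene_slopes.drop(columns=["d3int", "d3int_se"], errors="ignore").merge(
        d3int[["gene_id", "d3int"]], on="gene_id"
    )
    df = df[(df["slope"] < 0) & (df["d3int"] > 0)]
    if len(df) < 10:
        raise ValueError(f"need >= 10 genes with usable slope and D_3'INT, got {len(df)}")
    res = stats.linregress(np.log(df["d3int"]), np.log(-df["slope"]))
    return float(res.slope), float(res.intercept)
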