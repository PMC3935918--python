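"""Meta-intron profiles: the "guillotine" blade and base.

An intron's expected density profile is a declining blade (nascent
transcripts, height ``c0S*Talpha*L``) on a flat base (fully transcribed,
not yet degraded introns, height ``c0S*Tp``).  Aggregating long introns
aligned at their 3' ends separates the two: the fitted line's intercept at
the 3' terminus estimates the base and its slope times the window width
estimates the blade.  Because only the base contains the processing time,
a splicing defect raises the base without touching the blade -- the
condition comparison implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

META_WINDOW_BP = 50_000
META_MIN_INTRONS_PER_GENE = 10
META_POSITION_BIN_BP = 100


@dataclass
class MetaIntronProfile:
    """3'-anchored aggregated profiles per intron ordinal.

    ``profiles``: long table (ordinal, pos_from_3p_bp, density, n_introns).
    ``blade_base``: per ordinal the fitted base height (density at the 3'
    terminus), blade height (fitted drop across the window) and slope.
    """

    profiles: pd.DataFrame
    blade_base: pd.DataFrame
    window_bp: float


def _interp_extrap(x, xp, fp):
    """Piecewise-linear interpolation with linear extrapolation at the ends."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        s0 = (fp[1] - fp[0]) / (xp[1] - xp[0])
        s1 = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[lo] = fp[0] + s0 * (x[lo] - xp[0])
        y[hi] = fp[-1] + s1 * (x[hi] - xp[-1])
    return y


def meta_intron_profile(
    intron_bins: pd.DataFrame,
    window_bp: float = META_WINDOW_BP,
    min_introns_per_gene: int = META_MIN_INTRONS_PER_GENE,
    min_intron_bp: float | None = None,
    position_bin_bp: float = META_POSITION_BIN_BP,
    max_ordinal: int = 10,
    use_median: bool = False,
) -> MetaIntronProfile:
    """Aggregate intron profiles aligned at their 3' ends.

    Only introns longer than the window (default 50 kb) from genes with at
    least ``min_introns_per_gene`` introns contribute; each contributing
    intron's binned profile is resampled onto a common 3'-anchored position
    grid.  Positionwise mean (or median) per ordinal, then an OLS line
    gives base (intercept at the 3' end) and blade (drop across the
    window) -- exact on noiseless model profiles.
    """
    if min_intron_bp is None:
        min_intron_bp = window_bp
    ngenes = intron_bins.groupby("gene_id")["intron_ordinal"].transform("max")
    sel = intron_bins[
        (intron_bins["intron_bp"] > min_intron_bp)
        & (ngenes >= min_introns_per_gene)
        & (intron_bins["intron_ordinal"] <= max_ordinal)
    ]
    grid = np.arange(position_bin_bp / 2.0, window_bp, position_bin_bp)

    prof_rows = []
    bb_rows = []
    for ordn, grp in sel.groupby("intron_ordinal", sort=True):
        curves = []
        for (_, _), g in grp.groupby(["gene_id", "intron_ordinal"]):
            g = g.sort_values("midpoint_bp")
            L = float(g["intron_bp"].iloc[0])
            # positions measured from the 3' end, increasing into the intron
            xp = L - g["midpoint_bp"].to_numpy()[::-1]
            fp = g["density"].to_numpy()[::-1]
            curves.append(_interp_extrap(grid, xp, fp))
        if not curves:
            continue
        mat = np.vstack(curves)
        agg = np.median(mat, axis=0) if use_median else mat.mean(axis=0)
        res = stats.linregress(grid, agg)
        base = float(res.intercept)
        blade = float(abs(res.slope) * window_bp)
        for p, d in zip(grid, agg):
            prof_rows.append((int(ordn), float(p), float(d), len(curves)))
        bb_rows.append(
            {
                "ordinal": int(ordn),
                "n_introns": len(curves),
                "base": base,
                "blade": blade,
                "slope": float(res.slope),
            }
        )
    profiles = pd.DataFrame(
        prof_rows, columns=["ordinal", "pos_from_3p_bp", "density", "n_introns"]
    )
    blade_base = pd.DataFrame(
        bb_rows, columns=["ordinal", "n_introns", "base", "blade", "slope"]
    )
    if blade_base.empty:
        import logging

        logging.getLogger(__name__).warning(
            "no introns qualify for the meta-intron profile"
        )
    return MetaIntronProfile(profiles=profiles, blade_base=blade_base, window_bp=window_bp)


def condition_compare(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    blade_base_a: pd.DataFrame,
    blade_base_b: pd.DataFrame,
    ordinals=range(2, 11),
) -> dict:
    """Compare two conditions: feature-class read fractions and blade/base.

    ``features_*`` are feature tables with rdbp (read-fraction fold changes
    cancel library size); blade/base fold changes are tested across intron
    ordinals 2-10 with paired two-tailed t-tests, following the meta-intron
    comparison logic: slower splicing raises the base (p small) but not the
    blade (p large), while a synthesis change raises both.
    """
    folds = {}
    for cls in ("JXN5", "JXN3", "INT", "EXN"):
        fa = _class_fraction(features_a, cls)
        fb = _class_fraction(features_b, cls)
        folds[cls] = fb / fa if fa > 0 else np.nan

    bb = blade_base_a.merge(blade_base_b, on="ordinal", suffixes=("_a", "_b"))
    bb = bb[bb["ordinal"].isin(list(ordinals))]
    if bb.empty:
        raise ValueError("no shared intron ordinals between conditions")
    out = {
        "read_fraction_fold": folds,
        "base_fold": float((bb["base_b"] / bb["base_a"]).mean()),
        "blade_fold": float((bb["blade_b"] / bb["blade_a"]).mean()),
        "n_ordinals": len(bb),
    }
    if len(bb) >= 2:
        t_base = stats.ttest_rel(bb["base_b"], bb["base_a"])
        t_blade = stats.ttest_rel(bb["blade_b"], bb["blade_a"])
        out["base_p"] = float(t_base.pvalue)
        out["blade_p"] = float(t_blade.pvalue)
    return out


def _class_fraction(features: pd.DataFrame, cls: str) -> float:
    total = features["rdbp"].sum()
    return features.loc[features["feature_class"] == cls, "rdbp"].sum() / total


def sawtooth_trend(d3int: pd.DataFrame, min_introns: int = 3) -> tuple[pd.DataFrame, dict]:
    """Ordinal trend of D_3'INT along genes.

    Under co-transcriptional splicing the 3'-end density of each intron in
    a gene is set by the same ``c0S*Tp`` and shows no systematic ordinal
    trend; obligate post-transcriptional splicing (or uniform premature
    termination) predicts a monotone decline.  Fits a per-gene OLS slope of
    D_3'INT against intron ordinal (genes with >= ``min_introns``) and
    tests the cohort mean slope against zero.
    """
    rows = []
    for gene_id, grp in d3int.groupby("gene_id", sort=True):
        if len(grp) < min_introns:
            continue
        res = stats.linregress(grp["intron_ordinal"], grp["d3int"])
        mean_d = float(grp["d3int"].mean())
        rows.append(
            {
                "gene_id": gene_id,
                "ordinal_slope": float(res.slope),
                "relative_slope": float(res.slope / mean_d) if mean_d > 0 else np.nan,
                "n_introns": len(grp),
            }
        )
    per_gene = pd.DataFrame(rows, columns=["gene_id", "ordinal_slope", "relative_slope", "n_introns"])
    if per_gene.empty:
        return per_gene, {"mean_relative_slope": np.nan, "t": np.nan, "p": np.nan, "n_genes": 0}
    vals = per_gene["relative_slope"].dropna()
    t = stats.ttest_1samp(vals, 0.0)
    cohort = {
        "mean_relative_slope": float(vals.mean()),
        "t": float(t.statistic),
        "p": float(t.pvalue),
        "n_genes": int(len(vals)),
    }
    return per_gene, cohort
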