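"""End-to-end convenience layer: dataset/tables -> slopes -> cohort -> fit.

These helpers wire the stages together the way the command-line tool does:
fit per-intron slopes, aggregate to genes, compute D_3'INT, apply the
model filters, and assemble the :class:`~snapshotseq.solver.SnapShotModel`.
They accept either a synthetic dataset (fast array path) or the density
tables produced by quantification.
"""

from __future__ import annotations

import pandas as pd

from . import slopes as _slopes
from .quantify import DensityTable
from .solver import MonteCarloConfig, SnapShotModel, SnapShotResults


def intron_slope_fits(source, **kwargs) -> pd.DataFrame:
    """Per-intron slope fits from a dataset or a :class:`DensityTable`."""
    from .simulate import SyntheticDataset

    if isinstance(source, SyntheticDataset):
        return _slopes.fit_intron_slopes_matrix(
            source.intron_meta, source.bin_midpoints, source.bin_densities, **kwargs
        )
    bins = source.intron_bins if isinstance(source, DensityTable) else source
    return _slopes.fit_intron_slopes_table(bins, **kwargs)


def gene_slope_table(
    source,
    min_intron_bp: float = _slopes.MIN_INTRON_BP,
    min_tss_offset_bp: float | None = _slopes.MIN_TSS_OFFSET_BP,
    **fit_kwargs,
) -> pd.DataFrame:
    """Aggregated per-gene slopes with D_3'INT attached."""
    fits = intron_slope_fits(source, **fit_kwargs)
    gs = _slopes.gene_slopes_table(
        fits, min_intron_bp=min_intron_bp, min_tss_offset_bp=min_tss_offset_bp
    )
    d3 = _d3int_table(source)
    if d3 is not None:
        gs = gs.merge(
            _slopes.compute_d3int(d3)[["gene_id", "d3int", "d3int_se"]],
            on="gene_id",
            how="left",
        )
    return gs


def _d3int_table(source):
    from .simulate import SyntheticDataset

    if isinstance(source, SyntheticDataset):
        return source.densities.d3int
    if isinstance(source, DensityTable):
        return source.d3int
    return None


def eligible_cohort(
    gene_slopes: pd.DataFrame,
    gene_densities: pd.DataFrame,
    coding: pd.Series | None = None,
    **filter_kwargs,
) -> pd.DataFrame:
    """The filtered gene set handed to the solver."""
    return _slopes.filter_genes_for_model(
        gene_slopes, gene_densities, coding=coding, **filter_kwargs
    )


def fit_snapshot(
    dataset,
    config: MonteCarloConfig | None = None,
    seed: int | None = None,
    **filter_kwargs,
) -> SnapShotResults:
    """Full inverse pipeline on a synthetic dataset.

    Fits intron slopes, filters the cohort, and runs the Monte Carlo solve
    on the gene-level densities and waiting times; returns the results
    object (its ``model.data`` carries the eligible cohort).
    """
    gs = gene_slope_table(dataset)
    cohort = eligible_cohort(gs, dataset.densities.genes, **filter_kwargs)
    model = SnapShotModel.from_tables(
        cohort, dataset.densities.genes, dataset.waiting, config=config
    )
    return model.fit(seed=seed)
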