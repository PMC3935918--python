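"""Synthetic total RNA-Seq cohorts with known lifecycle parameters.

The generator draws gene structures (exon/intron counts and lengths),
places them on linear chromosomes, assigns each gene a synthesis rate and
the shared processing times, evaluates the closed-form steady-state
densities of every feature, and converts them to read counts with Poisson
counting noise at a configurable sequencing depth (or exactly, in
noiseless mode).  Ground truth is stored alongside, so every downstream
stage -- slope fitting, filtering, the Monte Carlo solver, meta-intron
profiles, bimodality analyses -- can be validated against known answers.

Defaults emulate the slope-informative cohort of the method: genes with
~10 introns of median 15 kb (the meta-intron analyses require many long
introns) and a log-normal synthesis-rate distribution centered on a
well-expressed gene (~30 RPKM exonic) at the standard 10M x 35 bp depth.
What the generator deliberately does not model: sequence-composition
library bias, mappability holes, and alternative isoforms other than the
optional retained-intron and non-consecutive-splice toggles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .lifecycle import DEFAULT_TALPHA, LifecycleParams, waiting_times
from .quantify import DensityTable, STANDARD_READ_BASES
from .slopes import N_BINS
from . import slopes as _slopes


@dataclass(frozen=True)
class BimodalConfig:
    """Two-mode synthesis-rate distribution with an off fraction.

    Medians are in density per minute (divide by 60 for the internal
    per-second c0S); sigmas are in log10 units (decades).
    """

    off_fraction: float = 0.3
    low_fraction: float = 0.35  # of all genes; remainder is high
    low_median_per_min: float = 0.003
    low_sigma_decades: float = 0.3
    high_median_per_min: float = 0.1
    high_sigma_decades: float = 0.4


@dataclass(frozen=True)
class LayoutConfig:
    """Linear-chromosome layout and optional low-near-high planting."""

    n_chromosomes: int = 4
    gap_log_median: float = float(np.log(30_000.0))
    gap_sigma: float = 0.7
    coupling_enrichment: float = 1.0  # multiplies P(low) next to a high gene


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort."""

    n_genes: int = 200
    # gene geometry (lognormal lengths, bp)
    n_introns_mean: float = 10.0  # Poisson, minimum 1
    intron_len_log_median: float = float(np.log(15_000.0))
    intron_len_sigma: float = 0.8
    exon_len_log_median: float = float(np.log(150.0))
    exon_len_sigma: float = 0.5
    last_exon_log_median: float = float(np.log(1_000.0))
    last_exon_sigma: float = 0.5
    min_intron_bp: int = 200
    min_exon_bp: int = 50
    # kinetics (seconds); c0S lognormal in density/minute
    T5: float = 90.0
    T3: float = 45.0
    Tgamma: float = 25.0
    Tmu: float = 7_200.0
    Talpha: float = DEFAULT_TALPHA
    c0S_median_per_min: float = 0.1
    c0S_sigma_decades: float = 0.5
    bimodal: BimodalConfig | None = None
    # sequencing
    total_reads: float = 1.0e7
    read_length: int = 35
    noiseless: bool = False
    # isoform toggles
    nonconsecutive_splice_rate: float = 0.01
    retained_intron_fraction: float = 0.0
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    @property
    def depth_scale(self) -> float:
        """Read-bases relative to the standard 10M x 35 bp library."""
        return self.total_reads * self.read_length / STANDARD_READ_BASES


@dataclass
class SyntheticAnnotation:
    """Generated gene models plus optional expression-mode labels."""

    gene_models: list[GeneModel]
    modes: pd.Series | None  # index gene_id, values off/low/high
    config: SimulationConfig


@dataclass
class SyntheticDataset:
    """A simulated snapshot: densities plus ground truth."""

    gene_models: list[GeneModel]
    truth: pd.DataFrame  # gene_id, c0S (per s), T5, T3, Tgamma, Tmu, mode
    densities: DensityTable
    waiting: pd.DataFrame  # gene_id, tt_5ss, tt_3ss, tt_int, tt_exn, tt_exnjxn
    intron_meta: pd.DataFrame  # gene_id, intron_ordinal, intron_bp, tss_offset_bp
    bin_midpoints: np.ndarray  # (n_introns, N_BINS) bp from intron 5' end
    bin_densities: np.ndarray  # (n_introns, N_BINS)
    config: SimulationConfig


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig, seed: int | None = None) -> SyntheticAnnotation:
    """Draw gene structures and place them on linear chromosomes.

    When a bimodal synthesis config is present, each gene also receives an
    expression-mode label; with ``layout.coupling_enrichment > 1`` the
    probability that a gene adjacent to a high-mode gene is low (rather
    than off) is multiplied accordingly -- the planted neighborhood
    structure used to validate the proximity statistics.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    lay = cfg.layout

    n_introns = np.maximum(1, rng.poisson(cfg.n_introns_mean, size=n))

    chrom_of = np.sort(rng.integers(0, lay.n_chromosomes, size=n))
    strands = rng.choice(["+", "-"], size=n)

    modes = None
    if cfg.bimodal is not None:
        modes = _assign_modes(rng, cfg.bimodal, chrom_of, lay.coupling_enrichment)

    models = []
    cursor = {c: 10_000 for c in range(lay.n_chromosomes)}
    for g in range(n):
        ni = int(n_introns[g])
        ex = _lengths(rng, ni + 1, cfg.exon_len_log_median, cfg.exon_len_sigma, cfg.min_exon_bp)
        ex[-1] = _lengths(rng, 1, cfg.last_exon_log_median, cfg.last_exon_sigma, cfg.min_exon_bp)[0]
        iv = _lengths(rng, ni, cfg.intron_len_log_median, cfg.intron_len_sigma, cfg.min_intron_bp)

        chrom = f"chr{chrom_of[g] + 1}"
        gap = int(np.exp(rng.normal(lay.gap_log_median, lay.gap_sigma)))
        start = cursor[chrom_of[g]] + gap

        # forward-genomic tiling; transcription order follows strand
        lens = np.empty(2 * ni + 1, dtype=int)
        order_ex, order_iv = (ex, iv) if strands[g] == "+" else (ex[::-1], iv[::-1])
        lens[0::2] = order_ex
        lens[1::2] = order_iv
        edges = start + np.concatenate([[0], np.cumsum(lens)])
        exons = [(int(edges[2 * k]), int(edges[2 * k + 1])) for k in range(ni + 1)]
        introns = [(int(edges[2 * k + 1]), int(edges[2 * k + 2])) for k in range(ni)]
        if strands[g] == "-":
            exons = exons[::-1]
            introns = introns[::-1]
        cursor[chrom_of[g]] = int(edges[-1])

        models.append(
            GeneModel(
                gene_id=f"g{g + 1:05d}",
                chromosome=chrom,
                strand=str(strands[g]),
                exons=exons,
                introns=introns,
                coding=True,
            )
        )

    mode_series = None
    if modes is not None:
        mode_series = pd.Series(modes, index=[m.gene_id for m in models], name="mode")
    return SyntheticAnnotation(gene_models=models, modes=mode_series, config=cfg)


def _lengths(rng, k, log_median, sigma, minimum):
    return np.maximum(minimum, np.exp(rng.normal(log_median, sigma, size=k))).astype(int)


def _assign_modes(rng, bim: BimodalConfig, chrom_of, enrichment):
    """off/low/high labels with optional low-next-to-high planting."""
    n = len(chrom_of)
    p_high = max(0.0, 1.0 - bim.off_fraction - bim.low_fraction)
    high = rng.random(n) < p_high
    # adjacency on the placement order within each chromosome
    adj_high = np.zeros(n, dtype=bool)
    left_same = np.r_[False, chrom_of[1:] == chrom_of[:-1]]
    right_same = np.r_[chrom_of[:-1] == chrom_of[1:], False]
    adj_high[1:] |= high[:-1] & left_same[1:]
    adj_high[:-1] |= high[1:] & right_same[:-1]

    rest = ~high
    denom = bim.off_fraction + bim.low_fraction
    p_low_base = bim.low_fraction / denom if denom > 0 else 0.0
    p_low = np.where(adj_high, np.minimum(1.0, p_low_base * enrichment), p_low_base)
    low = rest & (rng.random(n) < p_low)
    modes = np.where(high, "high", np.where(low, "low", "off"))
    return modes


def draw_parameters(
    annotation: SyntheticAnnotation, seed: int | None = None
) -> pd.DataFrame:
    """Ground-truth per-gene parameters for a generated annotation.

    Shared processing times come straight from the config; c0S is
    log-normal (single mode) or mixture-of-modes when a bimodal config is
    present (off genes get c0S = 0).  Internal c0S units are density per
    second.
    """
    cfg = annotation.config
    rng = np.random.default_rng(seed)
    gene_ids = [m.gene_id for m in annotation.gene_models]
    n = len(gene_ids)
    ln10 = np.log(10.0)

    if cfg.bimodal is None:
        mu = np.log(cfg.c0S_median_per_min / 60.0)
        c0s = np.exp(rng.normal(mu, cfg.c0S_sigma_decades * ln10, size=n))
        mode = np.full(n, "expressed")
    else:
        bim = cfg.bimodal
        if annotation.modes is not None:
            mode = annotation.modes.to_numpy()
        else:
            u = rng.random(n)
            mode = np.where(
                u < bim.off_fraction,
                "off",
                np.where(u < bim.off_fraction + bim.low_fraction, "low", "high"),
            )
        c0s = np.zeros(n)
        for name, med, sig in (
            ("low", bim.low_median_per_min, bim.low_sigma_decades),
            ("high", bim.high_median_per_min, bim.high_sigma_decades),
        ):
            sel = mode == name
            c0s[sel] = np.exp(
                rng.normal(np.log(med / 60.0), sig * ln10, size=int(sel.sum()))
            )

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "c0S": c0s,
            "T5": cfg.T5,
            "T3": cfg.T3,
            "Tgamma": cfg.Tgamma,
            "Tmu": cfg.Tmu,
            "mode": mode,
        }
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(
    gene_models: list[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> SyntheticDataset:
    """Evaluate the forward model and add Poisson counting noise.

    Per-feature expected read-bases are the closed-form density times
    feature bp times the depth scale; observed counts are Poisson draws of
    the expected *read* count (rdbp / read length), or the exact
    expectation in noiseless mode.  The result carries the same
    :class:`~snapshotseq.quantify.DensityTable` the quantification stage
    would produce from reads.
    """
    rng = np.random.default_rng(seed)
    r = cfg.read_length
    sigma = r - 1
    scale = cfg.depth_scale
    ta = cfg.Talpha
    truth_ix = truth.set_index("gene_id")

    retained: set[tuple[str, int]] = set()
    if cfg.retained_intron_fraction > 0:
        for gm in gene_models:
            for k in range(1, gm.n_introns + 1):
                if rng.random() < cfg.retained_intron_fraction:
                    retained.add((gm.gene_id, k))

    feat_rows, gene_rows, wt_rows, meta_rows = [], [], [], []
    mid_blocks, dens_blocks = [], []
    d3_rows = []

    def observe(expected_rdbp):
        """rdbp after counting noise (Poisson on read-bases per bin)."""
        if cfg.noiseless:
            return expected_rdbp
        lam = np.asarray(expected_rdbp, dtype=float) * scale
        return rng.poisson(lam) / scale

    for gm in gene_models:
        tr = truth_ix.loc[gm.gene_id]
        par = LifecycleParams(
            c0S=float(tr["c0S"]), T5=float(tr["T5"]), T3=float(tr["T3"]),
            Tgamma=float(tr["Tgamma"]), Tmu=float(tr["Tmu"]), Talpha=ta,
        )
        lam_ex = gm.exon_lengths.astype(float)
        lam_iv = gm.intron_lengths.astype(float)
        wt = waiting_times(lam_ex, lam_iv, ta)
        wt_rows.append(
            {
                "gene_id": gm.gene_id,
                "tt_5ss": wt.tt_5ss, "tt_3ss": 0.0, "tt_int": wt.tt_int,
                "tt_exn": wt.tt_exn, "tt_exnjxn": wt.tt_exnjxn,
            }
        )
        c = par.c0S
        n_iv = gm.n_introns
        tss_off = gm.intron_tss_offsets()

        # ---- exons ----
        w_e = _per_exon_wait(lam_ex, lam_iv, ta)
        d_exn_e = c * (w_e + par.T5 + par.T3 + par.Tmu)
        rd_exn = observe(d_exn_e * lam_ex)
        for k, (rd, bp) in enumerate(zip(rd_exn, lam_ex), start=1):
            feat_rows.append((gm.gene_id, "EXN", k, float(bp), float(rd)))

        # ---- introns: 100-bin profiles ----
        if n_iv:
            binw = lam_iv / N_BINS  # (n_iv,)
            mids = (np.arange(N_BINS) + 0.5)[None, :] * binw[:, None]
            prof = c * (ta * (lam_iv[:, None] - mids) + par.Tp)
            d5 = c * (ta * lam_iv + par.T5)
            d3ss = np.full(n_iv, c * (par.T5 + par.T3))
            for k in range(n_iv):
                if (gm.gene_id, k + 1) in retained:
                    prof[k] = c * (ta * (lam_iv[k] - mids[k]) + par.T5 + par.T3 + par.Tmu)
                    d5[k] = c * (ta * lam_iv[k] + par.T5 + par.Tmu)
                    d3ss[k] = c * (par.T5 + par.T3 + par.Tmu)
            rd_bins = observe(prof * binw[:, None])
            dens_bins = rd_bins / binw[:, None]
            mid_blocks.append(mids)
            dens_blocks.append(dens_bins)
            rd_iv = rd_bins.sum(axis=1)
            for k in range(n_iv):
                feat_rows.append((gm.gene_id, "INT", k + 1, float(lam_iv[k]), float(rd_iv[k])))
                meta_rows.append(
                    (gm.gene_id, k + 1, float(lam_iv[k]), float(tss_off[k]),
                     (gm.gene_id, k + 1) in retained)
                )

            # ---- splice sites ----
            rd_5 = observe(d5 * sigma)
            rd_3 = observe(d3ss * sigma)
            for k in range(n_iv):
                feat_rows.append((gm.gene_id, "JXN5", k + 1, float(sigma), float(rd_5[k])))
                feat_rows.append((gm.gene_id, "JXN3", k + 1, float(sigma), float(rd_3[k])))

            # ---- exon-exon junctions (consecutive) ----
            wj = _per_junction_wait(lam_ex, lam_iv, ta)
            d_jxn = c * (wj + par.Tmu)
            rd_j = observe(d_jxn * sigma)
            gene_d_exnjxn = float(rd_j.sum() / (sigma * n_iv) * 1.0)

            # ---- D_3'INT windows ----
            wbp = np.minimum(lam_iv, _slopes.D3INT_WINDOW_BP)
            tt_tail = ta * wbp / 2.0  # mean remaining transcription over the window
            d3_exp = c * (tt_tail + par.Tp)
            for k in range(n_iv):
                if (gm.gene_id, k + 1) in retained:
                    d3_exp[k] = c * (tt_tail[k] + par.T5 + par.T3 + par.Tmu)
            rd_d3 = observe(d3_exp * wbp)
            for k in range(n_iv):
                d3_rows.append(
                    (gm.gene_id, k + 1, float(wbp[k]), float(rd_d3[k] / wbp[k]))
                )
        else:
            gene_d_exnjxn = 0.0

        # ---- gene-level class densities (sum rdbp / sum bp) ----
        gene_rows.append(
            {
                "gene_id": gm.gene_id,
                "d_exn": float(rd_exn.sum() / lam_ex.sum()),
                "d_int": float(rd_iv.sum() / lam_iv.sum()) if n_iv else 0.0,
                "d_5ss": float(rd_5.sum() / (sigma * n_iv)) if n_iv else 0.0,
                "d_3ss": float(rd_3.sum() / (sigma * n_iv)) if n_iv else 0.0,
                "d_spl": gene_d_exnjxn,
                "d_exnjxn": gene_d_exnjxn,
            }
        )

    features = pd.DataFrame(
        feat_rows, columns=["gene_id", "feature_class", "ordinal", "bp", "rdbp"]
    )
    features["mappable_bp"] = features["bp"]
    features["excluded"] = False
    features["density"] = features["rdbp"] / features["bp"]

    genes = pd.DataFrame(gene_rows)
    meta = pd.DataFrame(
        meta_rows,
        columns=["gene_id", "intron_ordinal", "intron_bp", "tss_offset_bp", "retained"],
    )
    mid = np.concatenate(mid_blocks) if mid_blocks else np.empty((0, N_BINS))
    dens = np.concatenate(dens_blocks) if dens_blocks else np.empty((0, N_BINS))

    bins_df = _bins_frame(meta, mid, dens)
    d3 = pd.DataFrame(d3_rows, columns=["gene_id", "intron_ordinal", "bp", "d3int"])

    density = DensityTable(
        features=features,
        genes=genes,
        intron_bins=bins_df,
        d3int=d3,
        total_read_bases=cfg.total_reads * r,
        scale=1.0,  # densities already on the standard scale
    )
    return SyntheticDataset(
        gene_models=gene_models,
        truth=truth,
        densities=density,
        waiting=pd.DataFrame(wt_rows),
        intron_meta=meta,
        bin_midpoints=mid,
        bin_densities=dens,
        config=cfg,
    )


def _per_exon_wait(lam_ex, lam_iv, ta):
    n = len(lam_iv)
    w = np.empty(n + 1)
    for e in range(n):
        w[e] = ta * (lam_ex[e] / 2.0 + lam_ex[e + 1 : n].sum() + lam_iv[e:].sum())
    w[n] = -ta * lam_ex[n] / 2.0
    return w


def _per_junction_wait(lam_ex, lam_iv, ta):
    n = len(lam_iv)
    w = np.empty(n)
    for s in range(n):
        w[s] = ta * (lam_ex[s + 1 : n].sum() + lam_iv[s + 1 :].sum())
    return w


def _bins_frame(meta: pd.DataFrame, mid: np.ndarray, dens: np.ndarray) -> pd.DataFrame:
    n_int = len(meta)
    if n_int == 0:
        return pd.DataFrame(
            columns=["gene_id", "intron_ordinal", "bin", "midpoint_bp", "bp",
                     "rdbp", "density", "intron_bp", "tss_offset_bp"]
        )
    binw = meta["intron_bp"].to_numpy()[:, None] / N_BINS
    return pd.DataFrame(
        {
            "gene_id": np.repeat(meta["gene_id"].to_numpy(), N_BINS),
            "intron_ordinal": np.repeat(meta["intron_ordinal"].to_numpy(), N_BINS),
            "bin": np.tile(np.arange(N_BINS), n_int),
            "midpoint_bp": mid.ravel(),
            "bp": np.repeat(binw.ravel(), N_BINS),
            "rdbp": (dens * binw).ravel(),
            "density": dens.ravel(),
            "intron_bp": np.repeat(meta["intron_bp"].to_numpy(), N_BINS),
            "tss_offset_bp": np.repeat(meta["tss_offset_bp"].to_numpy(), N_BINS),
        }
    )


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None
) -> SyntheticDataset:
    """Annotation + parameters + dataset in one reproducible call."""
    ss = np.random.SeedSequence(seed)
    s_ann, s_par, s_dat = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    ann = simulate_annotation(cfg, seed=s_ann)
    truth = draw_parameters(ann, seed=s_par)
    return simulate_dataset(ann.gene_models, truth, cfg, seed=s_dat)


# ---------------------------------------------------------------------------
# read emission (for end-to-end I/O tests)
# ---------------------------------------------------------------------------

def emit_reads(dataset: SyntheticDataset, seed: int | None = None) -> pd.DataFrame:
    """Emit read alignments (chrom/key, start, length, strand) from a dataset.

    Poisson read starts are placed uniformly within exons and per intron
    bin, junction reads start within the r-1 positions that cross each
    boundary, and consecutive splice junctions emit reads keyed to the
    splice library; a configurable fraction of splice events joins
    non-consecutive exons.  Intended for small-depth pipeline tests.
    """
    rng = np.random.default_rng(seed)
    cfg = dataset.config
    r = cfg.read_length
    scale = cfg.depth_scale
    rows = []
    truth_ix = dataset.truth.set_index("gene_id")
    bins = dataset.densities.intron_bins
    geo = {gm.gene_id: gm for gm in dataset.gene_models}

    for gm in dataset.gene_models:
        tr = truth_ix.loc[gm.gene_id]
        par = LifecycleParams(
            c0S=float(tr["c0S"]), T5=float(tr["T5"]), T3=float(tr["T3"]),
            Tgamma=float(tr["Tgamma"]), Tmu=float(tr["Tmu"]), Talpha=cfg.Talpha,
        )
        c = par.c0S
        strand = gm.strand
        # exon-body reads
        w_e = _per_exon_wait(gm.exon_lengths.astype(float), gm.intron_lengths.astype(float), cfg.Talpha)
        for (s, e), w in zip(gm.exons, w_e):
            lam = c * (w + par.T5 + par.T3 + par.Tmu) * (e - s) * scale / r
            for pos in _starts(rng, lam, s, e, r):
                rows.append((gm.chromosome, pos, r, strand))
        # intron reads per bin
        sub = bins[bins["gene_id"] == gm.gene_id]
        for (ordn), grp in sub.groupby("intron_ordinal"):
            i_s, i_e = sorted(geo[gm.gene_id].introns[int(ordn) - 1])
            L = i_e - i_s
            binw = L / N_BINS
            for _, b in grp.iterrows():
                lam = b["density"] * binw * scale / r
                off0 = b["bin"] * binw
                if strand == "+":
                    lo, hi = i_s + off0, i_s + off0 + binw
                else:
                    hi = i_e - off0
                    lo = hi - binw
                for pos in _starts(rng, lam, int(lo), int(hi), r):
                    rows.append((gm.chromosome, pos, r, strand))
        # junction reads (crossing starts)
        for k, (s, e) in enumerate(gm.introns, start=1):
            b5, b3 = (s, e) if strand == "+" else (e, s)
            d5 = c * (cfg.Talpha * (e - s) + par.T5)
            d3 = c * (par.T5 + par.T3)
            for b, d in ((b5, d5), (b3, d3)):
                lam = d * (r - 1) * scale / r
                n = rng.poisson(lam)
                starts = rng.integers(b - r + 1, b, size=n)
                for pos in starts:
                    rows.append((gm.chromosome, int(pos), r, strand))
        # splice-junction reads
        wj = _per_junction_wait(gm.exon_lengths.astype(float), gm.intron_lengths.astype(float), cfg.Talpha)
        n_ex = len(gm.exons)
        for sidx in range(gm.n_introns):
            lam = c * (wj[sidx] + par.Tmu) * (r - 1) * scale / r
            n = rng.poisson(lam)
            for _ in range(n):
                if n_ex > 2 and rng.random() < cfg.nonconsecutive_splice_rate:
                    a = rng.integers(1, n_ex - 1)
                    b = rng.integers(a + 2, n_ex + 1)
                else:
                    a, b = sidx + 1, sidx + 2
                rows.append((f"{gm.gene_id}|{a}|{b}", 0, r, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand"])


def _starts(rng, lam, lo, hi, r):
    n = rng.poisson(max(lam, 0.0))
    if n == 0 or hi - lo < 1:
        return []
    return rng.integers(lo, max(lo + 1, hi - r + 1), size=n).tolist()


# ---------------------------------------------------------------------------
# counting-noise error experiment
# ---------------------------------------------------------------------------

def noise_error_experiment(
    intron_lengths=(1_000.0, 10_000.0, 100_000.0),
    processing_times=(6.0, 60.0, 600.0),
    depths=(1.0e7, 1.0e8, 1.0e9),
    n_reps: int = 50,
    seed: int | None = None,
    c0S_per_min: float = 1.0,
    T5_T3_Tgamma_split=(0.5625, 0.28125, 0.15625),
    Tmu: float = 7_200.0,
    exon_bp: float = 1_000.0,
    read_length: int = 35,
    Talpha: float = DEFAULT_TALPHA,
) -> pd.DataFrame:
    """Median relative errors over an (L, Tp, depth) grid.

    For each cell a single-intron gene is simulated ``n_reps`` times with
    Poisson counting noise at the given depth; the table reports median
    relative errors of the measured intron and exon densities, of the
    fitted intron slope, and of the solved processing times.  Slopes are
    fit over all 100 bins (zeros included) so that sparse cells still
    produce an estimate.
    """
    rng = np.random.default_rng(seed)
    r = read_length
    sigma = r - 1.0
    c = c0S_per_min / 60.0
    rows = []
    mids_unit = (np.arange(N_BINS) + 0.5) / N_BINS
    f5, f3, fg = T5_T3_Tgamma_split

    for L in intron_lengths:
        binw = L / N_BINS
        mids = mids_unit * L
        x = mids - mids.mean()
        sxx = float((x**2).sum())
        for Tp in processing_times:
            T5, T3, Tg = f5 * Tp, f3 * Tp, fg * Tp
            prof = c * (Talpha * (L - mids) + Tp)  # (N_BINS,)
            true_slope = -c * Talpha
            true_dint = c * (Talpha * L / 2.0 + Tp)
            # two-exon gene, equal exons: tt_exn averages to
            #   (half first exon + intron) and (-half last exon) weighted equally
            tt_exn = (Talpha * (exon_bp / 2.0 + L) - Talpha * exon_bp / 2.0) / 2.0
            true_dexn = c * (tt_exn + T5 + T3 + Tmu)
            d5, d3ss = c * (Talpha * L + T5), c * (T5 + T3)
            tt = np.array([Talpha * L, 0.0, Talpha * L / 2.0, tt_exn])
            truth_T = np.array([T5, T3, Tg, Tmu])
            for depth in depths:
                s = depth * r / STANDARD_READ_BASES
                cnt = rng.poisson(prof * binw * s, size=(n_reps, N_BINS))
                dens = cnt / (binw * s)
                slope_hat = (dens @ x) / sxx
                dint_hat = cnt.sum(axis=1) / (L * s)
                exn_cnt = rng.poisson(true_dexn * 2 * exon_bp * s, size=n_reps)
                dexn_hat = exn_cnt / (2 * exon_bp * s)
                c5 = rng.poisson(d5 * sigma * s, size=n_reps)
                c3 = rng.poisson(d3ss * sigma * s, size=n_reps)
                d5_hat = c5 / (sigma * s)
                d3_hat = c3 / (sigma * s)

                c0s_hat = np.where(slope_hat < 0, -slope_hat / Talpha, np.nan)
                D = np.stack([d5_hat, d3_hat, dint_hat, dexn_hat], axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rhs = D / c0s_hat[:, None] - tt
                    t5h = rhs[:, 0]
                    t3h = rhs[:, 1] - t5h
                    tgh = rhs[:, 2] - t5h - t3h
                    tmh = rhs[:, 3] - t5h - t3h
                    That = np.stack([t5h, t3h, tgh, tmh], axis=1)
                    terr = np.nanmedian(np.abs(That / truth_T - 1.0), axis=0)

                rows.append(
                    {
                        "intron_bp": L,
                        "Tp": Tp,
                        "depth_reads": depth,
                        "err_slope": float(np.median(np.abs(slope_hat / true_slope - 1.0))),
                        "err_d_int": float(np.median(np.abs(dint_hat / true_dint - 1.0))),
                        "err_d_exn": float(np.median(np.abs(dexn_hat / true_dexn - 1.0))),
                        "err_T5": float(terr[0]),
                        "err_T3": float(terr[1]),
                        "err_Tgamma": float(terr[2]),
                        "err_Tmu": float(terr[3]),
                    }
                )
    return pd.DataFrame(rows)
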