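"""Read-to-feature assignment and density normalization.

Uniquely aligned, strand-specific reads are attributed base-by-base to the
exon/intron partition of each gene; reads crossing an exon-intron boundary
additionally feed the junction (JXN5/JXN3) features, and reads aligned to
the splice pseudochromosome feed the exon-exon (SPL) features.  Raw
read-base counts (rdbp) become normalized densities by dividing by the
feature's mappable bases and rescaling to the standard library of 10 million
35-bp reads, so libraries of different size and read length are directly
comparable.  Dividing a density by 0.35 converts it to RPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import FeatureSet
from .slopes import N_BINS

logger = logging.getLogger(__name__)

#: read-bases of the standard library: 10 million reads of 35 bp
STANDARD_READ_BASES = 1.0e7 * 35.0


@dataclass
class FeatureCounts:
    """Raw read-base counts per feature, before normalization."""

    features: pd.DataFrame  # feature table + rdbp column
    splices: pd.DataFrame  # splice table + reads, rdbp columns
    intron_bins: pd.DataFrame  # per intron x bin: midpoint_bp, bp, rdbp, ...
    d3int_windows: pd.DataFrame  # per intron window: bp, rdbp
    intergenic_rdbp: float
    total_read_bases: float
    read_length: int


def read_reads_tsv(path) -> pd.DataFrame:
    """Load a simple alignment table: chrom, start, length, strand.

    Splice-library alignments use the library key (``gene|a|b``) as chrom.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "length", "strand"],
        comment="#",
        dtype={"chrom": str, "start": int, "length": int, "strand": str},
    )
    return df


def read_sam(path, min_mapq: int = 10) -> pd.DataFrame:
    """Load uniquely mapped reads from SAM/BAM via pysam.

    Unmapped, secondary/supplementary and low-MAPQ (< ``min_mapq``)
    alignments are dropped; mates of a pair are treated as two reads.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.query_length or aln.infer_query_length() or 0,
                    "-" if aln.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand"])


def assign_reads(
    reads: pd.DataFrame, feature_set: FeatureSet, n_bins: int = N_BINS
) -> FeatureCounts:
    """Attribute aligned read bases to features.

    Each aligned base lands in the unique EXN/INT feature containing it
    (exon priority was already resolved when transcripts were merged).
    Reads whose span crosses an exon-intron boundary contribute their full
    length to that boundary's JXN feature; reads aligned to a splice key
    contribute to the corresponding SPL feature.  Reads on no annotated
    gene are tallied in an intergenic bucket.
    """
    tab = feature_set.table
    feat = tab.copy()
    feat["rdbp"] = 0.0

    # genomic partition: EXN + INT intervals per (chrom, strand)
    part = {}
    body = feat[feat["feature_class"].isin(["EXN", "INT"])]
    for (chrom, strand), grp in body.groupby(["chromosome", "strand"]):
        g = grp.sort_values("start")
        part[(chrom, strand)] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g.index.to_numpy(),
        )

    # boundaries for junction features: position, feature row
    bounds = {}
    jxn = feat[feat["feature_class"].isin(["JXN5", "JXN3"])]
    sigma = feature_set.sigma
    for (chrom, strand), grp in jxn.groupby(["chromosome", "strand"]):
        pos = ((grp["start"] + grp["end"]) // 2).to_numpy()  # the boundary itself
        order = np.argsort(pos)
        bounds[(chrom, strand)] = (pos[order], grp.index.to_numpy()[order])

    # intron bin scaffolding
    introns = feat[feat["feature_class"] == "INT"]
    bin_index, bin_edges = _intron_bins(feature_set, introns, n_bins)
    bin_rdbp = {k: np.zeros(n_bins) for k in bin_index}

    d3 = feature_set.d3int_windows.copy()
    d3["bp"] = d3["end"] - d3["start"]
    d3["rdbp"] = 0.0
    d3_lookup = {
        (row["gene_id"], row["intron_ordinal"]): (int(row["start"]), int(row["end"]), i)
        for i, row in d3.iterrows()
    }

    spl = feature_set.splices.copy()
    spl["reads"] = 0
    spl["rdbp"] = 0.0
    spl_lookup = {
        f"{r['gene_id']}|{r['exon_a']}|{r['exon_b']}": i for i, r in spl.iterrows()
    }

    gene_of = feat["gene_id"]
    class_of = feat["feature_class"]
    ord_of = feat["ordinal"]

    intergenic = 0.0
    total_read_bases = float(reads["length"].sum())
    rdbp_col = feat.columns.get_loc("rdbp")
    rdbp_arr = feat["rdbp"].to_numpy()

    for chrom, start, length, strand in reads[
        ["chrom", "start", "length", "strand"]
    ].itertuples(index=False):
        if chrom in spl_lookup:
            i = spl_lookup[chrom]
            spl.iat[i, spl.columns.get_loc("reads")] += 1
            spl.iat[i, spl.columns.get_loc("rdbp")] += length
            continue
        key = (chrom, strand)
        end = start + length
        assigned = 0.0
        if key in part:
            starts, ends, rows_idx = part[key]
            k = np.searchsorted(ends, start, side="right")
            while k < len(starts) and starts[k] < end:
                ov = min(end, ends[k]) - max(start, starts[k])
                if ov > 0:
                    fi = rows_idx[k]
                    rdbp_arr[fi] += ov
                    assigned += ov
                    if class_of[fi] == "INT":
                        ikey = (gene_of[fi], ord_of[fi])
                        _add_to_bins(
                            bin_rdbp, bin_edges, ikey,
                            max(start, starts[k]), min(end, ends[k]),
                        )
                        if ikey in d3_lookup:
                            ws, we, di = d3_lookup[ikey]
                            wov = min(end, we) - max(start, ws)
                            if wov > 0:
                                d3.at[di, "rdbp"] += wov
                k += 1
        if key in bounds:
            pos, rows_idx = bounds[key]
            lo = np.searchsorted(pos, start, side="right")
            hi = np.searchsorted(pos, end, side="left")
            for k in range(lo, hi):
                rdbp_arr[rows_idx[k]] += length
        if assigned == 0.0:
            intergenic += length

    feat["rdbp"] = rdbp_arr

    bins_df = _bins_to_frame(feature_set, bin_index, bin_edges, bin_rdbp, n_bins)
    return FeatureCounts(
        features=feat,
        splices=spl,
        intron_bins=bins_df,
        d3int_windows=d3,
        intergenic_rdbp=intergenic,
        total_read_bases=total_read_bases,
        read_length=feature_set.read_length,
    )


def _intron_geometry(feature_set: FeatureSet):
    """Intron (start, end, strand, tss_offset) per (gene, ordinal)."""
    tab = feature_set.table
    ints = tab[tab["feature_class"] == "INT"]
    geo = {}
    for (gene, k), grp in ints.groupby(["gene_id", "ordinal"]):
        geo[(gene, k)] = (
            int(grp["start"].min()),
            int(grp["end"].max()),
            grp["strand"].iloc[0],
        )
    return geo


def _intron_bins(feature_set: FeatureSet, introns: pd.DataFrame, n_bins: int):
    geo = _intron_geometry(feature_set)
    edges = {}
    for key, (s, e, strand) in geo.items():
        edges[key] = (s, e, strand, (e - s) / n_bins)
    return list(edges), edges


def _add_to_bins(bin_rdbp, bin_edges, key, os_, oe):
    s, e, strand, w = bin_edges[key]
    arr = bin_rdbp[key]
    n = len(arr)
    for p0 in range(os_, oe):  # per-base; read spans are short
        off = (p0 - s) if strand == "+" else (e - 1 - p0)
        b = min(int(off / w), n - 1)
        arr[b] += 1.0


def _bins_to_frame(feature_set, bin_index, bin_edges, bin_rdbp, n_bins):
    rows = []
    for key in bin_index:
        s, e, strand, w = bin_edges[key]
        arr = bin_rdbp[key]
        for b in range(n_bins):
            rows.append(
                {
                    "gene_id": key[0],
                    "intron_ordinal": key[1],
                    "bin": b,
                    "midpoint_bp": (b + 0.5) * w,
                    "bp": w,
                    "rdbp": arr[b],
                    "intron_bp": e - s,
                    "tss_offset_bp": np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DensityTable:
    """Normalized densities at the standard 10M x 35 bp library scale."""

    features: pd.DataFrame  # feature rows + density
    genes: pd.DataFrame  # per gene: d_exn, d_int, d_5ss, d_3ss, d_spl, d_exnjxn
    intron_bins: pd.DataFrame  # per intron bin densities (slope input)
    d3int: pd.DataFrame  # per intron window densities
    total_read_bases: float
    scale: float  # STANDARD_READ_BASES / total_read_bases

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


_CLASS_COLS = {
    "EXN": "d_exn",
    "INT": "d_int",
    "JXN5": "d_5ss",
    "JXN3": "d_3ss",
    "SPL": "d_spl",
}


def normalize_densities(
    counts: FeatureCounts,
    mappability: pd.DataFrame | None = None,
    total_read_bases: float | None = None,
) -> DensityTable:
    """Convert raw rdbp counts into standard-library densities.

    ``D_f = (rdbp_f / mappable_bp_f) * (1e7 * 35) / total_read_bases``.
    Gene-class densities divide the class's total rdbp by its total
    mappable bases (total contributions over total bases available), and
    features with zero mappable bases are excluded with a flag.
    """
    total = float(total_read_bases or counts.total_read_bases)
    if total <= 0:
        raise ValueError("total aligned read-bases must be positive")
    scale = STANDARD_READ_BASES / total

    feat = counts.features.copy()
    if mappability is not None:
        key = ["gene_id", "feature_class", "ordinal"]
        m = mappability.groupby(key, as_index=False)["mappable_bp"].sum()
        feat = feat.merge(m, on=key, how="left")
        feat["mappable_bp"] = feat["mappable_bp"].fillna(feat["bp"])
        # distribute class-level mappable bp proportionally across split rows
        tot_bp = feat.groupby(key)["bp"].transform("sum")
        feat["mappable_bp"] = feat["mappable_bp"] * feat["bp"] / tot_bp
    else:
        feat["mappable_bp"] = feat["bp"].astype(float)

    feat["excluded"] = feat["mappable_bp"] <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        feat["density"] = np.where(
            feat["excluded"], np.nan, feat["rdbp"] / feat["mappable_bp"] * scale
        )

    ok = feat[~feat["excluded"]]
    body = ok[ok["feature_class"].isin(_CLASS_COLS)]
    agg = body.groupby(["gene_id", "feature_class"]).agg(
        rdbp=("rdbp", "sum"), bp=("mappable_bp", "sum")
    )
    agg["density"] = agg["rdbp"] / agg["bp"] * scale
    genes = (
        agg["density"]
        .unstack("feature_class")
        .rename(columns=_CLASS_COLS)
        .reindex(columns=list(_CLASS_COLS.values()))
        .fillna(0.0)
        .reset_index()
    )

    # splice junctions aggregated separately (effective length sigma each)
    sigma = counts.read_length - 1
    spl = counts.splices
    if len(spl):
        g = spl.groupby("gene_id")["rdbp"].sum()
        genes["d_exnjxn"] = genes["gene_id"].map(
            g / (sigma * spl.groupby("gene_id").size()) * scale
        ).fillna(0.0)
    else:
        genes["d_exnjxn"] = 0.0

    bins = counts.intron_bins.copy()
    bins["density"] = bins["rdbp"] / bins["bp"] * scale

    d3 = counts.d3int_windows.copy()
    d3["d3int"] = d3["rdbp"] / d3["bp"] * scale

    return DensityTable(
        features=feat,
        genes=genes,
        intron_bins=bins,
        d3int=d3[["gene_id", "intron_ordinal", "bp", "d3int"]],
        total_read_bases=total,
        scale=scale,
    )


def consecutive_splice_fraction(
    splices: pd.DataFrame, min_reads_nonconsecutive: int = 2
) -> tuple[float, pd.DataFrame]:
    """Fraction of exon-exon splice reads joining consecutive exons.

    Non-consecutive junctions supported by fewer than
    ``min_reads_nonconsecutive`` reads are treated as undetected and drop
    out entirely.  Returns the genome-wide fraction (NaN when no splice
    reads) and a per-gene table.
    """
    spl = splices.copy()
    drop = (~spl["consecutive"]) & (spl["reads"] < min_reads_nonconsecutive)
    spl.loc[drop, "reads"] = 0

    def frac(grp):
        tot = grp["reads"].sum()
        if tot == 0:
            return np.nan
        return grp.loc[grp["consecutive"], "reads"].sum() / tot

    overall = frac(spl)
    per_gene = (
        spl.groupby("gene_id").apply(frac, include_groups=False).rename("consecutive_fraction").reset_index()
    )
    return float(overall) if overall == overall else np.nan, per_gene


def retained_intron_filter(density: DensityTable) -> pd.DataFrame:
    """Flag introns whose splice sites look exonic (retained/shortened).

    In a retained (or 3'/5'-shortened) intron the boundary sequence lives as
    long as the mature mRNA, so both splice-site densities rise from the
    intronic level toward the exonic level.  An intron is flagged when both
    D_5'SS and D_3'SS are closer, on a log scale, to the gene's D_EXN than
    to the gene's typical intronic density (the median of its per-intron
    densities -- the retained intron's own density is itself elevated, so
    it cannot serve as the reference); flagged introns are excluded from
    model fitting.
    """
    feat = density.features
    piv = (
        feat[feat["feature_class"].isin(["JXN5", "JXN3", "INT"])]
        .groupby(["gene_id", "ordinal", "feature_class"])
        .apply(
            lambda g: g["rdbp"].sum() / g["mappable_bp"].sum() * density.scale,
            include_groups=False,
        )
        .unstack("feature_class")
        .reset_index()
        .rename(
            columns={"JXN5": "d_5ss", "JXN3": "d_3ss", "INT": "d_int",
                     "ordinal": "intron_ordinal"}
        )
    )
    gene_exn = density.genes.set_index("gene_id")["d_exn"]
    piv["d_exn"] = piv["gene_id"].map(gene_exn)
    piv["d_int_ref"] = piv.groupby("gene_id")["d_int"].transform("median")

    usable = (
        (piv[["d_5ss", "d_3ss", "d_int_ref", "d_exn"]] > 0).all(axis=1)
    )
    if (piv["d_exn"] <= 0).any():
        logger.warning(
            "%d introns lack exonic density; retained-intron flag unavailable",
            int((piv["d_exn"] <= 0).sum()),
        )
    vals = piv[["d_5ss", "d_3ss", "d_int_ref", "d_exn"]]
    lg = np.log(vals.where(vals > 0))
    closer5 = (lg["d_5ss"] - lg["d_exn"]).abs() < (lg["d_5ss"] - lg["d_int_ref"]).abs()
    closer3 = (lg["d_3ss"] - lg["d_exn"]).abs() < (lg["d_3ss"] - lg["d_int_ref"]).abs()
    piv["retained"] = (closer5 & closer3 & usable).to_numpy()
    return piv[
        ["gene_id", "intron_ordinal", "d_5ss", "d_3ss", "d_int", "d_int_ref",
         "d_exn", "retained"]
    ]
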