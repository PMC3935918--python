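"""Gene-centric feature models built from a transcript annotation.

Alternative transcripts of a gene are merged into a single representative
gene: exons are the union of all isoforms' exons (any base exonic in any
transcript is exonic), introns are the gaps between merged exons.  From the
merged model the quantification features are enumerated: exons (EXN, with
UTR5/CDS/UTR3 subclasses when CDS is annotated), introns (INT), the
exon->intron (JXN5) and intron->exon (JXN3) boundary windows, and all
intragenic exon-exon splice junctions (SPL).

Coordinates are 0-based half-open on the forward genomic strand throughout;
ordinal numbering of exons and introns follows transcription direction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("UTR5", "CDS", "UTR3", "EXN", "INT", "JXN5", "JXN3", "SPL")


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class GeneModel:
    """Merged exon/intron structure of one gene.

    ``exons`` and ``introns`` are lists of (start, end) half-open genomic
    intervals in *transcription* order: for a minus-strand gene exon ordinal
    1 has the largest genomic coordinate.  They alternate and tile the gene
    span without gaps or overlap.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = True
    cds: tuple[int, int] | None = None  # genomic CDS span (merged)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        self._check_tiling()

    def _check_tiling(self) -> None:
        ex = self.exons if self.strand == "+" else self.exons[::-1]
        iv = self.introns if self.strand == "+" else self.introns[::-1]
        if len(iv) != len(ex) - 1:
            raise ValueError("n_introns must equal n_exons - 1")
        for k, (s, e) in enumerate(ex):
            if e <= s:
                raise ValueError(f"malformed exon interval {(s, e)}")
            if k < len(iv):
                i_s, i_e = iv[k]
                if i_s != e or (k + 1 < len(ex) and i_e != ex[k + 1][0]):
                    raise ValueError("exons and introns must alternate and tile the span")

    # -- geometry -------------------------------------------------------
    @property
    def tss(self) -> int:
        s, e = self.exons[0]
        return s if self.strand == "+" else e

    @property
    def tes(self) -> int:
        s, e = self.exons[-1]
        return e if self.strand == "+" else s

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for s, e in self.exons for c in (s, e)]
        return min(coords), max(coords)

    @property
    def exon_lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.exons])

    @property
    def intron_lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.introns])

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def intron_tss_offsets(self) -> np.ndarray:
        """Transcribed bp from the TSS to each intron's (5') start."""
        lam = self.exon_lengths
        lint = self.intron_lengths
        out = np.empty(len(lint), dtype=float)
        acc = 0.0
        for i in range(len(lint)):
            acc += lam[i]
            out[i] = acc
            acc += lint[i]
        return out


def build_gene_models(
    transcripts: list[dict], coding_only: bool = False
) -> list[GeneModel]:
    """Merge transcript records into one :class:`GeneModel` per gene.

    Each record is a dict with keys ``gene_id``, ``chromosome``, ``strand``,
    ``exons`` (list of half-open genomic intervals) and optionally ``cds``
    (a genomic (start, end) span) and ``coding`` (bool).  Malformed exon
    intervals are rejected with a warning; overlapping exons of different
    isoforms are merged by union, so a region intronic in one isoform but
    exonic in another ends up exonic.
    """
    by_gene: dict[str, list[dict]] = {}
    for t in transcripts:
        by_gene.setdefault(t["gene_id"], []).append(t)

    models = []
    for gene_id, txs in by_gene.items():
        exons: list[tuple[int, int]] = []
        cds_spans = []
        coding = any(t.get("coding", bool(t.get("cds"))) for t in txs)
        chrom = txs[0]["chromosome"]
        strand = txs[0]["strand"]
        for t in txs:
            for s, e in t["exons"]:
                if e <= s:
                    logger.warning(
                        "rejecting malformed exon %s:%d-%d of gene %s", chrom, s, e, gene_id
                    )
                    continue
                exons.append((int(s), int(e)))
            if t.get("cds"):
                cds_spans.append(tuple(t["cds"]))
        if not exons:
            logger.warning("gene %s has no valid exons; skipped", gene_id)
            continue
        if coding_only and not coding:
            continue
        merged = _merge_intervals(exons)
        introns = [
            (merged[k][1], merged[k + 1][0]) for k in range(len(merged) - 1)
        ]
        cds = None
        if cds_spans:
            cds = (min(s for s, _ in cds_spans), max(e for _, e in cds_spans))
        if strand == "-":
            merged = merged[::-1]
            introns = introns[::-1]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                exons=merged,
                introns=introns,
                coding=coding,
                cds=cds,
            )
        )
    return models


# ---------------------------------------------------------------------------
# feature enumeration
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Enumerated features of a gene cohort.

    ``table``: one row per feature interval with columns gene_id, chromosome,
    strand, feature_class, ordinal, start, end, bp (an INT feature may span
    several rows when bases shared with an overlapping same-strand gene's
    exons were excised).  ``splices``: one row per exon pair (SPL features).
    ``d3int_windows``: the 3'-most window of each intron used for D_3'INT.
    ``read_length``: the read length the junction geometry was built for.
    """

    table: pd.DataFrame
    splices: pd.DataFrame
    d3int_windows: pd.DataFrame
    read_length: int

    @property
    def sigma(self) -> int:
        """Effective junction length r - 1."""
        return self.read_length - 1


def enumerate_features(
    gene_models: list[GeneModel],
    read_length: int = 35,
    d3int_window_bp: int = 10_000,
) -> FeatureSet:
    """Enumerate EXN/INT/JXN/SPL features for a cohort of gene models.

    Junction windows span ``r - 1`` bases on each side of the boundary and
    carry effective length ``sigma = r - 1``.  A gene with N introns gets
    N JXN5 + N JXN3 features and N(N+1)/2 SPL features (all exon pairs).
    Bases exonic in an overlapping same-strand gene are excluded from INT
    features so nothing is counted twice.
    """
    if read_length < 2:
        raise ValueError("read length must be >= 2")
    sigma = read_length - 1

    # same-strand exonic intervals per (chrom, strand) for INT exclusion
    exonic: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for gm in gene_models:
        exonic.setdefault((gm.chromosome, gm.strand), {})[gm.gene_id] = sorted(gm.exons)

    rows, splice_rows, d3_rows = [], [], []
    for gm in gene_models:
        others = [
            iv
            for gid, ivals in exonic[(gm.chromosome, gm.strand)].items()
            if gid != gm.gene_id
            for iv in ivals
        ]
        others = _merge_intervals(others) if others else []

        def add(cls, ordinal, s, e, bp=None):
            rows.append(
                {
                    "gene_id": gm.gene_id,
                    "chromosome": gm.chromosome,
                    "strand": gm.strand,
                    "feature_class": cls,
                    "ordinal": ordinal,
                    "start": int(s),
                    "end": int(e),
                    "bp": int(bp if bp is not None else e - s),
                }
            )

        for k, (s, e) in enumerate(gm.exons, start=1):
            add("EXN", k, s, e)
            if gm.cds is not None:
                c0, c1 = gm.cds
                for cls, ps, pe in _partition_exon(s, e, c0, c1, gm.strand):
                    if pe > ps:
                        add(cls, k, ps, pe)

        for k, (s, e) in enumerate(gm.introns, start=1):
            for ps, pe in _subtract(s, e, others):
                add("INT", k, ps, pe)
            # junction windows around the transcription-direction boundaries
            if gm.strand == "+":
                b5, b3 = s, e  # exon->intron at s, intron->exon at e
            else:
                b5, b3 = e, s
            add("JXN5", k, b5 - sigma, b5 + sigma, bp=sigma)
            add("JXN3", k, b3 - sigma, b3 + sigma, bp=sigma)
            # 3'-most window for D_3'INT
            w = min(e - s, d3int_window_bp)
            if gm.strand == "+":
                d3_rows.append((gm.gene_id, k, e - w, e))
            else:
                d3_rows.append((gm.gene_id, k, s, s + w))

        n_ex = len(gm.exons)
        for a in range(1, n_ex):
            for b in range(a + 1, n_ex + 1):
                splice_rows.append(
                    {
                        "gene_id": gm.gene_id,
                        "exon_a": a,
                        "exon_b": b,
                        "consecutive": b == a + 1,
                    }
                )

    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chromosome", "strand", "feature_class",
            "ordinal", "start", "end", "bp",
        ],
    )
    splices = pd.DataFrame(
        splice_rows, columns=["gene_id", "exon_a", "exon_b", "consecutive"]
    )
    d3int = pd.DataFrame(
        d3_rows, columns=["gene_id", "intron_ordinal", "start", "end"]
    )
    return FeatureSet(table=table, splices=splices, d3int_windows=d3int, read_length=read_length)


def _partition_exon(s, e, c0, c1, strand):
    """Split one exon into UTR/CDS pieces given the genomic CDS span."""
    left = ("UTR5" if strand == "+" else "UTR3", s, min(e, c0))
    mid = ("CDS", max(s, c0), min(e, c1))
    right = ("UTR3" if strand == "+" else "UTR5", max(s, c1), e)
    return [p for p in (left, mid, right) if p[2] > p[1]]


def _subtract(s, e, blocks):
    """Remove sorted disjoint ``blocks`` from the interval [s, e)."""
    out = []
    cur = s
    for bs, be in blocks:
        if be <= cur or bs >= e:
            continue
        if bs > cur:
            out.append((cur, bs))
        cur = max(cur, be)
    if cur < e:
        out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# splice library
# ---------------------------------------------------------------------------

def build_splice_library(
    gene_models: list[GeneModel], read_length: int = 35, genome=None
) -> pd.DataFrame:
    """Pseudochromosome records for every intragenic exon pair.

    Each record carries the minimal flanking sequence: the last ``r - 1``
    transcribed bases of the upstream exon joined to the first ``r - 1`` of
    the downstream exon (sequence present only when a genome is supplied).
    """
    sigma = read_length - 1
    rows = []
    for gm in gene_models:
        n_ex = len(gm.exons)
        for a in range(1, n_ex):
            for b in range(a + 1, n_ex + 1):
                seq = None
                if genome is not None:
                    up = _exon_tail(genome, gm, a, sigma, tail=True)
                    down = _exon_tail(genome, gm, b, sigma, tail=False)
                    seq = up + down
                rows.append(
                    {
                        "key": f"{gm.gene_id}|{a}|{b}",
                        "gene_id": gm.gene_id,
                        "exon_a": a,
                        "exon_b": b,
                        "consecutive": b == a + 1,
                        "sequence": seq,
                    }
                )
    return pd.DataFrame(rows)


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _exon_tail(genome, gm: GeneModel, ordinal: int, k: int, tail: bool) -> str:
    """Last (tail=True) or first k transcribed bases of an exon."""
    s, e = gm.exons[ordinal - 1]
    chrom = str(genome[gm.chromosome][s:e])
    seq = chrom if gm.strand == "+" else _revcomp(chrom)
    return seq[-k:] if tail else seq[:k]


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

def compute_mappability(
    feature_set: FeatureSet, genome=None, read_length: int | None = None
) -> pd.DataFrame:
    """Per-feature mappable-base fraction from exact k-mer uniqueness.

    A base is mappable when the read-length k-mer starting there occurs
    exactly once in the genome (strand-collapsed).  With no genome, every
    fraction defaults to 1.0; a feature on a missing chromosome also
    defaults to 1.0 with a warning.
    """
    r = read_length or feature_set.read_length
    tab = feature_set.table[["gene_id", "feature_class", "ordinal", "start", "end", "bp"]].copy()
    if genome is None:
        tab["mappable_bp"] = tab["bp"]
        tab["mappability"] = 1.0
        return tab

    seqs = {name: str(genome[name][:]).upper() for name in genome.keys()}
    counts: dict[str, int] = {}
    for seq in seqs.values():
        for i in range(len(seq) - r + 1):
            kmer = seq[i : i + r]
            key = min(kmer, _revcomp(kmer))
            counts[key] = counts.get(key, 0) + 1

    chrom_of = feature_set.table["chromosome"]
    mappable = []
    for (_, row), chrom in zip(tab.iterrows(), chrom_of):
        seq = seqs.get(chrom)
        if seq is None:
            logger.warning("no sequence for chromosome %s; mappability defaults to 1", chrom)
            mappable.append(row["bp"])
            continue
        n = 0
        for i in range(int(row["start"]), int(row["end"])):
            if i + r <= len(seq):
                kmer = seq[i : i + r]
                if counts.get(min(kmer, _revcomp(kmer)), 0) == 1:
                    n += 1
        mappable.append(min(n, row["bp"]))
    tab["mappable_bp"] = mappable
    tab["mappability"] = tab["mappable_bp"] / tab["bp"]
    return tab


# ---------------------------------------------------------------------------
# GTF / BED12 I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[dict]:
    """Parse transcript records from a GTF file (gene_id/transcript_id keys)."""
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("exon", "CDS"):
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            rec = tx.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "transcript_id": tid,
                    "chromosome": f[0],
                    "strand": f[6],
                    "exons": [],
                    "cds": None,
                },
            )
            start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
            if f[2] == "exon":
                rec["exons"].append((start, end))
            else:
                c = rec["cds"]
                rec["cds"] = (start, end) if c is None else (min(c[0], start), max(c[1], end))
    for rec in tx.values():
        rec["coding"] = rec["cds"] is not None
    return list(tx.values())


def write_gtf(gene_models: list[GeneModel], path) -> None:
    """Write one representative transcript per merged gene model."""
    with open(path, "w") as fh:
        for gm in gene_models:
            attrs = f'gene_id "{gm.gene_id}"; transcript_id "{gm.gene_id}.t1";'
            for s, e in sorted(gm.exons):
                fh.write(
                    f"{gm.chromosome}\tsnapshotseq\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t{attrs}\n"
                )
            if gm.cds is not None:
                c0, c1 = gm.cds
                fh.write(
                    f"{gm.chromosome}\tsnapshotseq\tCDS\t{c0 + 1}\t{c1}\t.\t{gm.strand}\t.\t{attrs}\n"
                )


def read_bed12(path) -> list[dict]:
    """Parse transcript records from a BED12 file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            thick = (int(f[6]), int(f[7]))
            out.append(
                {
                    "gene_id": name,
                    "transcript_id": name,
                    "chromosome": chrom,
                    "strand": strand,
                    "exons": exons,
                    "cds": thick if thick[1] > thick[0] else None,
                    "coding": thick[1] > thick[0],
                }
            )
    return out


def write_features_bed(feature_set: FeatureSet, path) -> None:
    """Features as BED6+ with name = gene:class:ordinal."""
    tab = feature_set.table
    with open(path, "w") as fh:
        for _, row in tab.iterrows():
            name = f"{row['gene_id']}:{row['feature_class']}:{row['ordinal']}"
            fh.write(
                f"{row['chromosome']}\t{row['start']}\t{row['end']}\t{name}\t0\t{row['strand']}\n"
            )


def write_splice_library(splice_lib: pd.DataFrame, fasta_path, key_path) -> None:
    """Write the splice pseudochromosome FASTA and its TSV key."""
    with open(key_path, "w") as fh:
        splice_lib.drop(columns=["sequence"]).to_csv(fh, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for _, row in splice_lib.iterrows():
            seq = row["sequence"] or ""
            fh.write(f">{row['key']}\n{seq}\n")
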