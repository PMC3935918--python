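"""Gene-model merging, feature enumeration, splice library, mappability, I/O."""

import numpy as np
import pytest

import snapshotseq.annotation as an


def _tx(gene, exons, strand="+", chrom="chr1", cds=None):
    return {
        "gene_id": gene,
        "transcript_id": f"{gene}.t",
        "chromosome": chrom,
        "strand": strand,
        "exons": exons,
        "cds": cds,
    }


class TestBuildGeneModels:
    def test_identity_merge_three_exons(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 100), (200, 300), (400, 500)])]
        )[0]
        assert gm.n_introns == 2
        assert gm.introns == [(100, 200), (300, 400)]
        assert gm.exon_lengths.tolist() == [100, 100, 100]

    def test_retained_intron_region_becomes_exonic(self):
        """An isoform retaining intron 1 makes that region EXN in the merge."""
        gm = an.build_gene_models(
            [
                _tx("g", [(0, 100), (200, 300), (400, 500)]),
                _tx("g", [(0, 300)]),  # retains the first intron
            ]
        )[0]
        assert gm.exons[0] == (0, 300)
        assert gm.introns == [(300, 400)]

    def test_minus_strand_ordinals_follow_transcription(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 100), (200, 300), (400, 500)], strand="-")]
        )[0]
        assert gm.exons[0] == (400, 500)  # exon 1 = largest coordinate
        assert gm.introns[0] == (300, 400)
        assert gm.tss == 500

    def test_malformed_interval_rejected_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            gm = an.build_gene_models(
                [_tx("g", [(0, 100), (300, 200), (400, 500)])]
            )[0]
        assert "malformed" in caplog.text
        assert gm.exons == [(0, 100), (400, 500)]

    def test_single_exon_gene_allowed(self):
        gm = an.build_gene_models([_tx("g", [(0, 500)])])[0]
        assert gm.n_introns == 0

    def test_coding_only_filter(self):
        models = an.build_gene_models(
            [
                _tx("c", [(0, 100), (200, 300)], cds=(10, 250)),
                _tx("nc", [(1000, 1100)]),
            ],
            coding_only=True,
        )
        assert [m.gene_id for m in models] == ["c"]

    def test_tss_offsets(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 100), (200, 300), (500, 600)])]
        )[0]
        assert gm.intron_tss_offsets().tolist() == [100.0, 300.0]


class TestEnumerateFeatures:
    def test_splice_pairs_count(self):
        """3 exons -> 3 SPL features (1-2, 2-3, 1-3) = C(3,2)."""
        gm = an.build_gene_models([_tx("g", [(0, 100), (200, 300), (400, 500)])])
        fs = an.enumerate_features(gm, read_length=35)
        assert len(fs.splices) == 3
        pairs = set(zip(fs.splices["exon_a"], fs.splices["exon_b"]))
        assert pairs == {(1, 2), (2, 3), (1, 3)}
        assert fs.splices["consecutive"].sum() == 2

    def test_junction_effective_length(self):
        gm = an.build_gene_models([_tx("g", [(0, 100), (200, 300)])])
        fs = an.enumerate_features(gm, read_length=35)
        jxn = fs.table[fs.table["feature_class"].isin(["JXN5", "JXN3"])]
        assert (jxn["bp"] == 34).all()
        j5 = jxn[jxn["feature_class"] == "JXN5"].iloc[0]
        assert (j5["start"], j5["end"]) == (100 - 34, 100 + 34)

    def test_no_introns_no_junctions(self):
        gm = an.build_gene_models([_tx("g", [(0, 500)])])
        fs = an.enumerate_features(gm, read_length=35)
        assert set(fs.table["feature_class"]) == {"EXN"}
        assert fs.splices.empty

    def test_partition_covers_span_without_overlap(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 100), (250, 400), (600, 900)])]
        )
        fs = an.enumerate_features(gm, read_length=35)
        body = fs.table[fs.table["feature_class"].isin(["EXN", "INT"])]
        ivals = sorted(zip(body["start"], body["end"]))
        assert ivals[0][0] == 0 and ivals[-1][1] == 900
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert e1 == s2  # contiguous, no overlap

    def test_overlapping_gene_exons_cut_from_introns(self):
        """Bases exonic in a same-strand neighbor leave the INT feature."""
        models = an.build_gene_models(
            [
                _tx("a", [(0, 100), (1000, 1100)]),
                _tx("b", [(400, 500), (2000, 2100)]),
            ]
        )
        fs = an.enumerate_features(models, read_length=35)
        int_a = fs.table[
            (fs.table["gene_id"] == "a") & (fs.table["feature_class"] == "INT")
        ]
        assert int_a["bp"].sum() == 900 - 100  # 100 bp of b's exon removed
        assert len(int_a) == 2  # split around the foreign exon

    def test_cds_partition(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 100), (200, 300)], cds=(50, 250))]
        )
        fs = an.enumerate_features(gm, read_length=35)
        sub = fs.table[fs.table["feature_class"].isin(["UTR5", "CDS", "UTR3"])]
        assert sub.groupby("feature_class")["bp"].sum().to_dict() == {
            "CDS": 100, "UTR3": 50, "UTR5": 50,
        }

    def test_minus_strand_d3int_window_at_genomic_start(self):
        gm = an.build_gene_models(
            [_tx("g", [(20_000, 20_100), (0, 100)], strand="-")]
        )
        fs = an.enumerate_features(gm, read_length=35)
        w = fs.d3int_windows.iloc[0]
        # intron spans (100, 20000); its 3' end (transcription) is genomic start
        assert (w["start"], w["end"]) == (100, 10_100)


class TestSpliceLibraryAndGtf:
    def test_record_count_is_choose_2(self):
        gm = an.build_gene_models(
            [_tx("g", [(0, 50), (100, 150), (200, 250), (300, 350)])]
        )
        lib = an.build_splice_library(gm, read_length=10)
        assert len(lib) == 6  # C(4, 2)
        assert lib["key"].is_unique

    def test_sequences_join_exon_flanks(self, tmp_path):
        genome = {"chr1": "ACGTACGTAA" + "C" * 10 + "GGTTGGTTGG"}
        gm = an.build_gene_models([_tx("g", [(0, 10), (20, 30)])])
        lib = an.build_splice_library(gm, read_length=5, genome=genome)
        assert lib["sequence"].iloc[0] == "GTAA" + "GGTT"

    def test_gtf_roundtrip_idempotent(self, tmp_path):
        """Rebuilding from the serialized merged annotation is a no-op."""
        models = an.build_gene_models(
            [
                _tx("a", [(0, 100), (200, 300), (400, 500)]),
                _tx("b", [(900, 1000), (1200, 1300)], strand="-"),
            ]
        )
        path = tmp_path / "m.gtf"
        an.write_gtf(models, path)
        again = an.build_gene_models(an.read_gtf(path))
        assert {m.gene_id: m.exons for m in again} == {
            m.gene_id: m.exons for m in models
        }
        assert {m.gene_id: m.strand for m in again} == {"a": "+", "b": "-"}

    def test_bed12_reader(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text(
            "chr1\t100\t500\tgx\t0\t+\t150\t450\t0\t2\t100,100\t0,300\n"
        )
        gm = an.build_gene_models(an.read_bed12(bed))[0]
        assert gm.exons == [(100, 200), (400, 500)]
        assert gm.cds == (150, 450)
        assert gm.coding


class TestMappability:
    def test_default_without_genome_is_one(self):
        gm = an.build_gene_models([_tx("g", [(0, 100), (200, 300)])])
        fs = an.enumerate_features(gm, read_length=35)
        m = an.compute_mappability(fs)
        assert (m["mappability"] == 1.0).all()

    def test_unique_genome_fully_mappable(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        genome = {"chr1": seq}
        gm = an.build_gene_models([_tx("g", [(0, 100), (200, 300)])])
        fs = an.enumerate_features(gm, read_length=12)
        m = an.compute_mappability(fs, genome=genome, read_length=12)
        exn = m[m["feature_class"] == "EXN"]
        assert (exn["mappability"] == 1.0).all()

    def test_duplicated_block_matches_bruteforce_oracle(self):
        """A duplicated 100-bp block inside an intron lowers its mappable
        fraction by exactly the brute-force k-mer count."""
        rng = np.random.default_rng(1)
        r = 10
        block = "".join(rng.choice(list("ACGT"), size=100))
        intron_seq = (
            "".join(rng.choice(list("ACGT"), size=400))
            + block
            + "".join(rng.choice(list("ACGT"), size=500))
        )
        seq = (
            "".join(rng.choice(list("ACGT"), size=100))  # exon 1
            + intron_seq
            + "".join(rng.choice(list("ACGT"), size=100))  # exon 2
            + block  # second copy, outside the gene
        )
        genome = {"chr1": seq}
        gm = an.build_gene_models([_tx("g", [(0, 100), (1100, 1200)])])
        fs = an.enumerate_features(gm, read_length=r)
        m = an.compute_mappability(fs, genome=genome, read_length=r)
        got = m[m["feature_class"] == "INT"]["mappable_bp"].iloc[0]

        # independent oracle: exhaustive k-mer scan
        def canon(kmer):
            comp = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            return min(kmer, comp)

        counts = {}
        for i in range(len(seq) - r + 1):
            counts[canon(seq[i : i + r])] = counts.get(canon(seq[i : i + r]), 0) + 1
        expect = sum(
            1 for i in range(100, 1100) if counts[canon(seq[i : i + r])] == 1
        )
        assert got == expect
        assert got < 1000  # the duplicated block really is unmappable
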