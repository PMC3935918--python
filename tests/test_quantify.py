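"""Read assignment, density normalization and isoform diagnostics."""

import numpy as np
import pandas as pd
import pytest

import snapshotseq as ss
import snapshotseq.annotation as an
import snapshotseq.quantify as qt


def _feature_set():
    """Plus-strand 3-exon gene: exons (0,1000),(2000,3000),(9000,10000)."""
    models = an.build_gene_models(
        [
            {
                "gene_id": "g",
                "transcript_id": "g.t",
                "chromosome": "chr1",
                "strand": "+",
                "exons": [(0, 1000), (2000, 3000), (9000, 10000)],
            }
        ]
    )
    return an.enumerate_features(models, read_length=35)


def _reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand"])


class TestAssignReads:
    def test_read_inside_intron(self):
        counts = qt.assign_reads(_reads([("chr1", 2500, 35, "+")]), _feature_set())
        # start 2500 is inside exon 2; use intron 1 instead
        counts2 = qt.assign_reads(_reads([("chr1", 1500, 35, "+")]), _feature_set())
        row = counts2.features.query("feature_class == 'INT' and ordinal == 1")
        assert row["rdbp"].iloc[0] == 35

    def test_boundary_read_feeds_junction_and_partition(self):
        """A read straddling exon1/intron1 splits bases between EXN and INT
        and contributes its whole length to JXN5 ordinal 1."""
        fs = _feature_set()
        counts = qt.assign_reads(_reads([("chr1", 990, 35, "+")]), fs)
        f = counts.features
        assert f.query("feature_class == 'EXN' and ordinal == 1")["rdbp"].iloc[0] == 10
        assert f.query("feature_class == 'INT' and ordinal == 1")["rdbp"].iloc[0] == 25
        assert f.query("feature_class == 'JXN5' and ordinal == 1")["rdbp"].iloc[0] == 35
        assert f.query("feature_class == 'JXN3'")["rdbp"].sum() == 0

    def test_splice_library_read(self):
        fs = _feature_set()
        counts = qt.assign_reads(_reads([("g|1|3", 0, 35, "+")]), fs)
        row = counts.splices.query("exon_a == 1 and exon_b == 3")
        assert row["reads"].iloc[0] == 1 and row["rdbp"].iloc[0] == 35
        assert not row["consecutive"].iloc[0]

    def test_wrong_strand_read_is_intergenic(self):
        counts = qt.assign_reads(_reads([("chr1", 2500, 35, "-")]), _feature_set())
        assert counts.intergenic_rdbp == 35
        assert counts.features["rdbp"].sum() == 0

    def test_conservation_of_read_bases(self):
        """All genic read bases land in exactly one EXN/INT feature."""
        rng = np.random.default_rng(0)
        reads = _reads(
            [("chr1", int(s), 35, "+") for s in rng.integers(0, 9965, size=200)]
        )
        counts = qt.assign_reads(reads, _feature_set())
        body = counts.features[counts.features["feature_class"].isin(["EXN", "INT"])]
        assert body["rdbp"].sum() + counts.intergenic_rdbp == 200 * 35

    def test_d3int_window_counts(self):
        fs = _feature_set()
        # intron 2 spans (3000, 9000), 6 kb < 10 kb -> whole intron window
        counts = qt.assign_reads(_reads([("chr1", 4000, 35, "+")]), fs)
        w = counts.d3int_windows.query("intron_ordinal == 2")
        assert w["rdbp"].iloc[0] == 35 and w["bp"].iloc[0] == 6000


class TestNormalize:
    def test_worked_density_example(self):
        """100 contained 35-bp reads on a 1-kb feature at 10M x 35 bp -> D = 3.5."""
        counts = qt.FeatureCounts(
            features=pd.DataFrame(
                [{"gene_id": "g", "feature_class": "INT", "ordinal": 1,
                  "bp": 1000, "rdbp": 3500.0}]
            ),
            splices=pd.DataFrame(columns=["gene_id", "exon_a", "exon_b",
                                          "consecutive", "reads", "rdbp"]),
            intron_bins=pd.DataFrame(columns=["gene_id", "intron_ordinal", "bin",
                                              "midpoint_bp", "bp", "rdbp",
                                              "intron_bp", "tss_offset_bp"]),
            d3int_windows=pd.DataFrame(columns=["gene_id", "intron_ordinal",
                                                "start", "end", "bp", "rdbp"]),
            intergenic_rdbp=0.0,
            total_read_bases=1e7 * 35,
            read_length=35,
        )
        dens = qt.normalize_densities(counts)
        assert dens.features["density"].iloc[0] == pytest.approx(3.5)
        # doubling the library halves the density
        dens2 = qt.normalize_densities(counts, total_read_bases=2e7 * 35)
        assert dens2.features["density"].iloc[0] == pytest.approx(1.75)

    def test_normalizing_standard_library_is_identity(self):
        fs = _feature_set()
        counts = qt.assign_reads(_reads([("chr1", 1500, 35, "+")]), fs)
        dens = qt.normalize_densities(counts, total_read_bases=qt.STANDARD_READ_BASES)
        assert dens.scale == 1.0

    def test_density_rpkm_factor(self):
        """Density / RPKM = 0.35 for any feature length and count."""
        for bp, n_reads in ((1000, 100), (5000, 7), (35, 1)):
            d = (n_reads * 35 / bp) * 1.0  # standard library
            rpkm = n_reads / (bp / 1000) / 10  # 10M reads
            assert d / rpkm == pytest.approx(0.35)
            assert ss.DENSITY_PER_RPKM == 0.35

    def test_zero_mappable_bases_excluded(self):
        fs = _feature_set()
        counts = qt.assign_reads(_reads([("chr1", 1500, 35, "+")]), fs)
        mapp = fs.table[["gene_id", "feature_class", "ordinal", "bp"]].copy()
        mapp["mappable_bp"] = mapp["bp"]
        mapp.loc[
            (mapp["feature_class"] == "INT") & (mapp["ordinal"] == 1), "mappable_bp"
        ] = 0
        dens = qt.normalize_densities(counts, mappability=mapp)
        bad = dens.features.query("feature_class == 'INT' and ordinal == 1")
        assert bad["excluded"].all()
        assert np.isnan(bad["density"]).all()


class TestConsecutiveSpliceFraction:
    def _spl(self, counts):
        rows = []
        for (a, b), n in counts.items():
            rows.append(
                {"gene_id": "g", "exon_a": a, "exon_b": b,
                 "consecutive": b == a + 1, "reads": n, "rdbp": 35.0 * n}
            )
        return pd.DataFrame(rows)

    def test_arithmetic_example(self):
        frac, _ = qt.consecutive_splice_fraction(
            self._spl({(1, 2): 50, (2, 3): 45, (1, 3): 5})
        )
        assert frac == pytest.approx(0.95)

    def test_all_consecutive(self):
        frac, _ = qt.consecutive_splice_fraction(self._spl({(1, 2): 10, (2, 3): 3}))
        assert frac == 1.0

    def test_single_read_nonconsecutive_excluded(self):
        frac, _ = qt.consecutive_splice_fraction(
            self._spl({(1, 2): 50, (2, 3): 49, (1, 3): 1})
        )
        assert frac == 1.0

    def test_zero_reads_undefined(self):
        frac, _ = qt.consecutive_splice_fraction(self._spl({(1, 2): 0}))
        assert np.isnan(frac)

    def test_simulated_rate_recovered(self):
        """Read emission with a 1% non-consecutive rate shows up in the
        genome-wide consecutive fraction."""
        cfg = ss.SimulationConfig(
            n_genes=12, nonconsecutive_splice_rate=0.05,
            intron_len_log_median=np.log(2000.0), total_reads=2e6,
        )
        ds = ss.simulate_cohort(cfg, seed=41)
        reads = ss.simulate.emit_reads(ds, seed=42)
        fs = an.enumerate_features(ds.gene_models, read_length=35)
        counts = qt.assign_reads(reads, fs)
        frac, per_gene = qt.consecutive_splice_fraction(counts.splices)
        assert 0.85 < frac < 0.99


class TestRetainedIntronFilter:
    def test_flag_rates_on_simulated_retention(self):
        """Introns emitted with the mRNA lifetime are flagged (>95%), normal
        introns are not."""
        cfg = ss.SimulationConfig(n_genes=60, retained_intron_fraction=0.15)
        ds = ss.simulate_cohort(cfg, seed=51)
        flags = qt.retained_intron_filter(ds.densities).merge(
            ds.intron_meta[["gene_id", "intron_ordinal", "retained"]],
            on=["gene_id", "intron_ordinal"],
            suffixes=("", "_true"),
        )
        truly = flags["retained_true"]
        assert truly.sum() > 20
        assert flags.loc[truly, "retained"].mean() > 0.95
        assert flags.loc[~truly, "retained"].mean() < 0.05

    def test_intronic_level_sites_not_flagged(self, noiseless_heterogeneous):
        flags = qt.retained_intron_filter(noiseless_heterogeneous.densities)
        assert not flags["retained"].any()


class TestEndToEndReads:
    def test_read_pipeline_matches_direct_densities(self):
        """Emitted reads -> assign -> normalize reproduces the simulated
        gene-level densities within counting tolerance."""
        cfg = ss.SimulationConfig(
            n_genes=10, intron_len_log_median=np.log(3000.0),
            intron_len_sigma=0.3, total_reads=4e6, n_introns_mean=4.0,
        )
        ds = ss.simulate_cohort(cfg, seed=61)
        reads = ss.simulate.emit_reads(ds, seed=62)
        fs = an.enumerate_features(ds.gene_models, read_length=35)
        counts = qt.assign_reads(reads, fs)
        dens = qt.normalize_densities(
            counts, total_read_bases=cfg.total_reads * 35
        )
        got = dens.genes.set_index("gene_id")
        want = ds.densities.genes.set_index("gene_id")
        # D_EXN is count-rich; compare the strongest genes
        both = got.join(want, lsuffix="_got", rsuffix="_want")
        strong = both[both["d_exn_want"] > both["d_exn_want"].median()]
        ratios = strong["d_exn_got"] / strong["d_exn_want"]
        assert np.all((ratios > 0.8) & (ratios < 1.2))

    def test_sam_reader(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
            "r1\t0\tchr1\t1501\t60\t35M\t*\t0\t0\t" + "A" * 35 + "\t*\n"
            "r2\t16\tchr1\t2501\t60\t35M\t*\t0\t0\t" + "A" * 35 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 35 + "\t*\n"
            "r4\t0\tchr1\t3001\t5\t35M\t*\t0\t0\t" + "A" * 35 + "\t*\n"
        )
        reads = qt.read_sam(sam, min_mapq=10)
        assert len(reads) == 2  # unmapped and low-MAPQ dropped
        assert reads["start"].tolist() == [1500, 2500]
        assert reads["strand"].tolist() == ["+", "-"]
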