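"""Slope fitting, TDR, gene aggregation, filters and D_3'INT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snapshotseq as ss
from snapshotseq import slopes as sl


def _bins(L, densities):
    mids = (np.arange(sl.N_BINS) + 0.5) * (L / sl.N_BINS)
    return mids, np.asarray(densities, dtype=float)


class TestFitIntronSlope:
    def test_constant_profile_is_null(self):
        mids, y = _bins(10_000, np.full(100, 0.5))
        fit = sl.fit_intron_slope(mids, y)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.tdr == pytest.approx(0.5)

    def test_tdr_at_z_minus_two(self):
        """slope/SE = -2 corresponds to TDR = Phi(2) ~ 0.9772."""
        assert sl.tdr_from_z(-2.0) == pytest.approx(0.97725, abs=1e-4)

    def test_noiseless_model_profile_recovers_slope(self):
        """c0S = 0.01/min gives slope -c0S*Talpha = -2.778e-6 per bp."""
        p = ss.LifecycleParams(c0S=0.01 / 60, T5=90, T3=45, Tgamma=25, Tmu=7200)
        L = 8000
        mids = (np.arange(100) + 0.5) * (L / 100)
        y = ss.predict_intron_profile(p, L, mids)
        fit = sl.fit_intron_slope(mids, y)
        assert fit.slope == pytest.approx(-2.778e-6, rel=1e-3)
        assert fit.tdr == 1.0

    def test_binning_invariance(self):
        """On noiseless linear input, the 100-bin fit equals the per-base fit."""
        p = ss.LifecycleParams(c0S=1e-3, T5=90, T3=45, Tgamma=25, Tmu=7200)
        L = 5000
        mids, y = (np.arange(100) + 0.5) * 50.0, None
        y = ss.predict_intron_profile(p, L, mids)
        x_base = np.arange(L) + 0.5
        y_base = ss.predict_intron_profile(p, L, np.arange(L))
        res = stats.linregress(x_base, y_base)
        fit = sl.fit_intron_slope(mids, y, min_nonzero_bins=20)
        assert fit.slope == pytest.approx(res.slope, rel=1e-9)

    def test_too_few_nonzero_bins_refused(self):
        mids, y = _bins(10_000, np.r_[np.ones(19), np.zeros(81)])
        fit = sl.fit_intron_slope(mids, y)
        assert not fit.usable and fit.reason == "too_few_bins"

    def test_spiky_intron_dropped(self):
        y = np.full(100, 0.5)
        y[::10] = 100.0  # ten 200x spikes
        mids, y = _bins(10_000, y)
        fit = sl.fit_intron_slope(mids, y)
        assert not fit.usable and fit.reason == "spiky"

    def test_spike_bins_excluded_from_fit(self):
        p = ss.LifecycleParams(c0S=1e-3, T5=90, T3=45, Tgamma=25, Tmu=7200)
        mids = (np.arange(100) + 0.5) * 80.0
        y = ss.predict_intron_profile(p, 8000, mids).copy()
        y[50] = 100.0  # one spike
        fit = sl.fit_intron_slope(mids, y)
        assert fit.usable and fit.n_bins_used == 99
        assert fit.slope == pytest.approx(-p.c0S * p.Talpha, rel=1e-9)

    def test_tdr_monotone_in_slope(self):
        """At fixed SE, a more negative slope has strictly larger TDR."""
        zs = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        tdrs = [sl.tdr_from_z(z) for z in zs]
        assert all(a > b for a, b in zip(tdrs, tdrs[1:]))

    def test_matrix_path_matches_scalar_path(self, noisy_cohort):
        ds = noisy_cohort
        n = 40
        meta = ds.intron_meta.iloc[:n]
        fast = sl.fit_intron_slopes_matrix(
            meta, ds.bin_midpoints[:n], ds.bin_densities[:n]
        )
        for i in range(n):
            ref = sl.fit_intron_slope(ds.bin_midpoints[i], ds.bin_densities[i])
            assert bool(fast["usable"].iloc[i]) == ref.usable
            if ref.usable:
                assert fast["slope"].iloc[i] == pytest.approx(ref.slope, rel=1e-10)
                assert fast["se"].iloc[i] == pytest.approx(ref.se, rel=1e-8)
                assert fast["tdr"].iloc[i] == pytest.approx(ref.tdr, abs=1e-10)


class TestGeneAggregation:
    def test_single_intron_passthrough(self):
        s, e, t = sl.aggregate_gene_slope([-2e-6], [1e-7], [0.99], [8000])
        assert s == -2e-6 and e == pytest.approx(1e-7)

    def test_mean_of_two_slopes(self):
        s, _, _ = sl.aggregate_gene_slope(
            [-2e-6, -4e-6], [1e-7, 1e-7], [0.9, 0.9], [5000, 5000]
        )
        assert s == pytest.approx(-3e-6)

    def test_quadrature_error_equal_weights(self):
        """Equal slopes, SEs and weights give eps_g = eps / sqrt(2)."""
        _, e, _ = sl.aggregate_gene_slope(
            [-2e-6, -2e-6], [1e-7, 1e-7], [0.95, 0.95], [5000, 5000]
        )
        assert e == pytest.approx(1e-7 / np.sqrt(2))

    def test_gene_tdr_from_z(self):
        s, e, t = sl.aggregate_gene_slope([-2e-6, -2e-6], [1e-6, 1e-6], [0.9, 0.9], [1, 1])
        assert t == pytest.approx(stats.norm.sf(s / e))


class TestGeneFilters:
    def _gs(self, **over):
        row = dict(gene_id="g1", slope=-2e-6, se=1e-7, tdr=0.95, n_introns_used=2)
        row.update(over)
        return pd.DataFrame([row])

    def _dens(self, d_int=0.5, d_exn=10.0):
        return pd.DataFrame([{"gene_id": "g1", "d_int": d_int, "d_exn": d_exn}])

    def test_tdr_boundary(self):
        kept = sl.filter_genes_for_model(self._gs(tdr=0.90), self._dens())
        assert len(kept) == 1
        with pytest.raises(ValueError):
            sl.filter_genes_for_model(self._gs(tdr=0.89), self._dens())

    def test_density_boundaries_inclusive(self):
        kept = sl.filter_genes_for_model(self._gs(), self._dens(d_int=1.00, d_exn=50.0))
        assert len(kept) == 1
        with pytest.raises(ValueError):
            sl.filter_genes_for_model(self._gs(), self._dens(d_int=1.01))

    def test_coding_filter(self):
        coding = pd.Series({"g1": False})
        with pytest.raises(ValueError):
            sl.filter_genes_for_model(self._gs(), self._dens(), coding=coding)

    def test_empty_result_reports_diagnostics(self):
        with pytest.raises(ValueError, match="fail_tdr"):
            sl.filter_genes_for_model(self._gs(tdr=0.5), self._dens())

    def test_positive_slope_genes_fail_tdr_filter(self):
        """Simulated genes with positive (wrong-sign) slopes never reach the
        TDR >= 0.9 cohort."""
        rng = np.random.default_rng(4)
        rows = []
        for g in range(20):
            z = rng.normal(2.0, 0.5)  # positive slope, z > 0 => TDR < 0.5
            rows.append(
                dict(gene_id=f"p{g}", slope=2e-6, se=2e-6 / z, tdr=sl.tdr_from_z(z),
                     n_introns_used=1)
            )
        gs = pd.DataFrame(rows)
        dens = pd.DataFrame({"gene_id": gs["gene_id"], "d_int": 0.5, "d_exn": 10.0})
        with pytest.raises(ValueError):
            sl.filter_genes_for_model(gs, dens)

    def test_short_and_tss_proximal_introns_excluded(self):
        fits = pd.DataFrame(
            [
                dict(gene_id="g1", intron_ordinal=1, intron_bp=8000.0,
                     tss_offset_bp=200.0, slope=-1e-6, se=1e-7, tdr=0.99,
                     n_bins_used=90, usable=True),
                dict(gene_id="g1", intron_ordinal=2, intron_bp=3000.0,
                     tss_offset_bp=20_000.0, slope=-1e-6, se=1e-7, tdr=0.99,
                     n_bins_used=90, usable=True),
                dict(gene_id="g1", intron_ordinal=3, intron_bp=9000.0,
                     tss_offset_bp=30_000.0, slope=-5e-6, se=1e-7, tdr=0.99,
                     n_bins_used=90, usable=True),
            ]
        )
        gs = sl.gene_slopes_table(fits)
        # only intron 3 survives (1 is TSS-proximal, 2 is short)
        assert gs["n_introns_used"].iloc[0] == 1
        assert gs["slope"].iloc[0] == pytest.approx(-5e-6)


class TestD3Int:
    def test_window_mean_closed_form(self):
        """20-kb noiseless intron: D_3'INT = c0S*(Tp + Talpha*10000/2) ~ 0.0406."""
        p = ss.LifecycleParams(c0S=1.667e-4, T5=90, T3=45, Tgamma=25, Tmu=7200)
        L, W = 20_000, 10_000
        x = np.arange(L - W, L)
        d3 = ss.predict_intron_profile(p, L, x).mean()
        assert d3 == pytest.approx(1.667e-4 * (160 + (1 / 60) * W / 2), rel=1e-3)
        assert d3 == pytest.approx(0.0406, abs=5e-4)

    def test_short_intron_uses_whole_intron(self):
        fs = ss.annotation.enumerate_features(
            [_gene_with_intron(4000)], read_length=35
        )
        w = fs.d3int_windows.iloc[0]
        assert w["end"] - w["start"] == 4000

    def test_uniform_density_gives_zero_se(self):
        d3 = pd.DataFrame(
            {"gene_id": "g1", "intron_ordinal": [1, 2, 3], "d3int": 0.7}
        )
        out = sl.compute_d3int(d3)
        assert out["d3int"].iloc[0] == pytest.approx(0.7)
        assert out["d3int_se"].iloc[0] == pytest.approx(0.0)


class TestProxyConsistency:
    def test_constant_tp_gives_unit_slope(self, noiseless_heterogeneous):
        """Both |slope| and D_3'INT are proportional to c0S when Tp is
        shared, so the log-log regression slope is ~1 (variation in the
        Talpha*W/2 term across intron-length mixes keeps it near, not at, 1)."""
        ds = noiseless_heterogeneous
        gs = ss.gene_slope_table(ds)
        d3 = sl.compute_d3int(ds.densities.d3int)
        slope, _ = sl.proxy_consistency(gs, d3)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_too_few_genes_rejected(self):
        gs = pd.DataFrame({"gene_id": ["a"], "slope": [-1e-6]})
        d3 = pd.DataFrame({"gene_id": ["a"], "d3int": [0.1]})
        with pytest.raises(ValueError):
            sl.proxy_consistency(gs, d3)


def _gene_with_intron(L):
    from snapshotseq.annotation import GeneModel

    return GeneModel(
        gene_id="g1",
        chromosome="chr1",
        strand="+",
        exons=[(0, 100), (100 + L, 200 + L)],
        introns=[(100, 100 + L)],
    )
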