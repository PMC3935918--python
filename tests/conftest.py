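"""Shared fixtures: small gene geometries and session-scoped synthetic cohorts."""

import numpy as np
import pytest

import snapshotseq as ss


@pytest.fixture
def params():
    """The reference parameter set used throughout: T5=90, T3=45, Tgamma=25,
    Tmu=7200 s with c0S = 0.01 density/min."""
    return ss.LifecycleParams(c0S=1.0 / 6000.0, T5=90.0, T3=45.0, Tgamma=25.0, Tmu=7200.0)


@pytest.fixture
def two_exon_wt():
    """2-exon gene, 1 kb exons, 6 kb intron (worked example geometry)."""
    return ss.waiting_times([1000, 1000], [6000])


@pytest.fixture(scope="session")
def noiseless_homogeneous():
    """Noiseless cohort with identical gene geometry and parameters."""
    cfg = ss.SimulationConfig(
        n_genes=30,
        noiseless=True,
        intron_len_sigma=0.0,
        exon_len_sigma=0.0,
        last_exon_sigma=0.0,
        c0S_sigma_decades=0.0,
        n_introns_mean=8.0,
    )
    ann = ss.simulate_annotation(cfg, seed=7)
    # intron counts are Poisson: prune to the modal count so geometry is identical
    from collections import Counter

    counts = Counter(m.n_introns for m in ann.gene_models)
    keep_n = counts.most_common(1)[0][0]
    ann.gene_models = [m for m in ann.gene_models if m.n_introns == keep_n]
    truth = ss.draw_parameters(ann, seed=8)
    truth = truth[truth["gene_id"].isin([m.gene_id for m in ann.gene_models])]
    return ss.simulate_dataset(ann.gene_models, truth.reset_index(drop=True), cfg, seed=9)


@pytest.fixture(scope="session")
def noiseless_heterogeneous():
    """Noiseless cohort with realistic (varying) geometry and rates."""
    cfg = ss.SimulationConfig(n_genes=60, noiseless=True)
    return ss.simulate_cohort(cfg, seed=17)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Poisson-noise cohort at the standard depth (shared across tests)."""
    cfg = ss.SimulationConfig(n_genes=400)
    return ss.simulate_cohort(cfg, seed=23)
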