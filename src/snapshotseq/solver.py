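"""Inverse model: Monte Carlo estimation of the four processing times.

The forward model (:mod:`.lifecycle`) makes each feature density linear in
the processing times ``T = (T5, T3, Tgamma, Tmu)`` once the synthesis scale
``c0S`` is fixed by the intron slope.  Writing the aggregated densities as
``D = c0S * (T_t + M T)`` with the known waiting times ``T_t`` and a 4x4
0/1 coefficient matrix ``M``, the system is solved exactly by inverting
``M`` -- equivalently by the closed-form back-substitution used here.

Single genes are too noisy to invert: the estimator repeatedly draws small
random samples of filtered genes, perturbs each gene's slope by its fitted
standard error, aggregates slopes and densities geometrically, solves, and
keeps only all-positive solutions.  The accepted solutions form the
sampling distributions summarized by :class:`SnapShotResults`.

The public surface follows the statsmodels convention: build a
:class:`SnapShotModel` from per-gene tables, call :meth:`~SnapShotModel.fit`,
and read estimates, intervals and diagnostics off the returned results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lifecycle import DEFAULT_TALPHA, FeatureDensityVector, WaitingTimes

#: coefficient matrix of T = (T5, T3, Tgamma, Tmu) in D/c0S - T_t,
#: rows ordered (5'SS, 3'SS, INT, EXN)
M_COEFF = np.array(
    [
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [1, 1, 1, 0],
        [1, 1, 0, 1],
    ],
    dtype=float,
)

TIME_NAMES = ("T5", "T3", "Tgamma", "Tmu")
GENE_COLUMNS = ("slope", "se", "d_5ss", "d_3ss", "d_int", "d_exn",
                "tt_5ss", "tt_3ss", "tt_int", "tt_exn")


def solve_sample(densities, waiting_times, c0S: float) -> np.ndarray:
    """Closed-form solve of the 4x4 system for one aggregated sample.

    Parameters
    ----------
    densities
        (D_5'SS, D_3'SS, D_INT, D_EXN) or a :class:`FeatureDensityVector`.
    waiting_times
        (T_t,5'SS, T_t,3'SS=0, T_t,INT, T_t,EXN) or a :class:`WaitingTimes`.
    c0S
        Synthesis scale in density per second; must be positive.

    Returns the T vector with no positivity enforcement -- exact inverse of
    :func:`snapshotseq.lifecycle.predict_densities`.
    """
    if isinstance(densities, FeatureDensityVector):
        densities = densities.as_vector()
    if isinstance(waiting_times, WaitingTimes):
        waiting_times = waiting_times.as_vector()
    d = np.asarray(densities, dtype=float)
    tt = np.asarray(waiting_times, dtype=float)
    if c0S <= 0:
        raise ValueError("c0S must be positive")
    if np.any(d[:4] <= 0):
        raise ValueError("all four feature densities must be positive")
    rhs = d / c0S - tt
    t5 = rhs[0]
    t3 = rhs[1] - t5
    tgamma = rhs[2] - t5 - t3
    tmu = rhs[3] - t5 - t3
    return np.array([t5, t3, tgamma, tmu])


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings of the resampling estimator."""

    sample_size: int = 5
    max_samples: int = 200_000
    min_valid: int = 2_000
    Talpha: float = DEFAULT_TALPHA
    tt_aggregation: str = "matched"  # or "geometric" / "arithmetic"
    max_slope_redraws: int = 100
    chunk_size: int = 5_000

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.min_valid > self.max_samples:
            raise ValueError("min_valid must be <= max_samples")
        if self.tt_aggregation not in ("matched", "geometric", "arithmetic"):
            raise ValueError("tt_aggregation must be 'matched', 'geometric' or 'arithmetic'")


class SnapShotModel:
    """Steady-state mRNA lifecycle model over a filtered gene cohort.

    Parameters
    ----------
    data
        One row per eligible gene with columns ``slope`` (negative, density
        per bp), ``se`` (slope standard error), feature densities ``d_5ss``,
        ``d_3ss``, ``d_int``, ``d_exn`` and waiting times ``tt_5ss``,
        ``tt_3ss``, ``tt_int``, ``tt_exn`` (seconds).  An optional
        ``gene_id`` column is carried through for diagnostics.
    config
        Monte Carlo settings; by default samples of 5 genes are drawn until
        2,000 valid solutions are found or 200,000 samples are exhausted.

    Examples
    --------
    >>> model = SnapShotModel.from_tables(gene_slopes, densities, waiting)
    ...                                                   # doctest: +SKIP
    >>> res = model.fit(seed=0)                           # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, config: MonteCarloConfig | None = None):
        missing = [c for c in GENE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"gene table is missing columns {missing}")
        if len(data) == 0:
            raise ValueError("gene table is empty")
        self.data = data.reset_index(drop=True)
        self.config = config or MonteCarloConfig()
        if len(self.data) < self.config.sample_size:
            raise ValueError("fewer genes than the Monte Carlo sample size")

    @classmethod
    def from_tables(
        cls,
        gene_slopes: pd.DataFrame,
        gene_densities: pd.DataFrame,
        gene_waiting_times: pd.DataFrame,
        config: MonteCarloConfig | None = None,
    ) -> "SnapShotModel":
        """Assemble the model from the slope, density and geometry tables.

        Each input has a ``gene_id`` key column; only genes present in all
        three tables are used.
        """
        df = (
            gene_slopes[["gene_id", "slope", "se"]]
            .merge(
                gene_densities[["gene_id", "d_5ss", "d_3ss", "d_int", "d_exn"]],
                on="gene_id",
            )
            .merge(
                gene_waiting_times[
                    ["gene_id", "tt_5ss", "tt_3ss", "tt_int", "tt_exn"]
                ],
                on="gene_id",
            )
        )
        return cls(df, config=config)

    def fit(self, seed: int | None = None) -> "SnapShotResults":
        """Run the Monte Carlo inversion and return the results object."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        df = self.data
        n = len(df)
        k = cfg.sample_size

        slope = df["slope"].to_numpy(dtype=float)
        se = np.nan_to_num(df["se"].to_numpy(dtype=float), nan=0.0)
        D = df[["d_5ss", "d_3ss", "d_int", "d_exn"]].to_numpy(dtype=float)
        TT = df[["tt_5ss", "tt_3ss", "tt_int", "tt_exn"]].to_numpy(dtype=float)

        accepted: list[np.ndarray] = []
        n_drawn = 0
        n_valid = 0
        n_discarded_zero = 0
        n_discarded_slope = 0

        while n_valid < cfg.min_valid and n_drawn < cfg.max_samples:
            chunk = min(cfg.chunk_size, cfg.max_samples - n_drawn)
            sol, dz, ds = self._solve_chunk(rng, chunk, n, k, slope, se, D, TT)
            n_drawn += chunk
            n_discarded_zero += dz
            n_discarded_slope += ds
            valid = np.all(sol > 0, axis=1) & np.all(np.isfinite(sol), axis=1)
            if valid.any():
                accepted.append(sol[valid])
                n_valid += int(valid.sum())

        samples = (
            np.concatenate(accepted) if accepted else np.empty((0, 4), dtype=float)
        )
        converged = len(samples) >= cfg.min_valid
        return SnapShotResults(
            model=self,
            samples=pd.DataFrame(samples, columns=list(TIME_NAMES)),
            n_samples_drawn=n_drawn,
            n_valid=len(samples),
            n_discarded_zero_density=n_discarded_zero,
            n_discarded_bad_slope=n_discarded_slope,
            converged=converged,
            seed=seed,
        )

    def _solve_chunk(self, rng, chunk, n, k, slope, se, D, TT):
        """Draw and solve ``chunk`` samples; fully vectorized."""
        cfg = self.config
        # sample k genes without replacement per row
        r = rng.random((chunk, n))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]

        # Gaussian slope noise; a perturbed slope >= 0 has no defined
        # synthesis rate, so redraw that gene's noise a bounded number of
        # times before giving up on the sample.
        s = slope[idx] + rng.standard_normal((chunk, k)) * se[idx]
        bad = s >= 0
        tries = 0
        while bad.any() and tries < cfg.max_slope_redraws:
            s[bad] = slope[idx][bad] + rng.standard_normal(int(bad.sum())) * se[idx][bad]
            bad = s >= 0
            tries += 1
        sample_ok = ~bad.any(axis=1)
        n_bad_slope = int((~sample_ok).sum())

        with np.errstate(divide="ignore", invalid="ignore"):
            c0s = np.exp(np.mean(np.log(-s), axis=1)) / cfg.Talpha  # (chunk,)

            d = D[idx]  # (chunk, k, 4)
            pos = d > 0
            npos = pos.sum(axis=1)  # (chunk, 4)
            logd = np.where(pos, np.log(np.where(pos, d, 1.0)), 0.0)
            d_agg = np.exp(logd.sum(axis=1) / np.maximum(npos, 1))
        all_features = np.all(npos > 0, axis=1)
        n_zero = int((~all_features & sample_ok).sum())

        tt = TT[idx]  # (chunk, k, 4)
        rhs_total = d_agg / c0s[:, None]  # geomean_g(tt_g + offset) per feature
        if cfg.tt_aggregation == "matched":
            offsets = _matched_offsets(tt, rhs_total)
        else:
            if cfg.tt_aggregation == "geometric":
                tt_agg = _geomean_with_fallback(tt)
            else:
                tt_agg = tt.mean(axis=1)
            offsets = rhs_total - tt_agg

        t5 = offsets[:, 0]
        t3 = offsets[:, 1] - t5
        tg = offsets[:, 2] - t5 - t3
        tm = offsets[:, 3] - t5 - t3
        sol = np.stack([t5, t3, tg, tm], axis=1)
        sol[~(sample_ok & all_features)] = np.nan
        return sol, n_zero, n_bad_slope


def _matched_offsets(tt: np.ndarray, rhs: np.ndarray, n_iter: int = 40) -> np.ndarray:
    """Solve geomean_g(tt_g + o) = rhs for the shared offset o, per feature.

    Each gene in a sample predicts density c0S_g * (tt_g + o_f), where the
    offset o_f is the gene-shared combination of processing times entering
    feature f.  The geometric density aggregation therefore measures
    geomean_g(tt_g + o_f), not geomean(tt_g) + o_f; inverting the former
    (Newton on a monotone 1-D function) keeps the solve exact on noiseless
    cohorts with heterogeneous gene geometry, where subtracting an
    aggregated waiting time would bias every processing time upward.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        o = rhs - tt.mean(axis=1)  # arithmetic-consistent start
        floor = -tt.min(axis=1) + 1e-9  # domain: tt_g + o > 0
        o = np.maximum(o, floor + 1e-6)
        log_rhs = np.log(rhs)
        for _ in range(n_iter):
            arg = tt + o[:, None, :]
            bad = arg <= 0
            arg = np.where(bad, 1e-300, arg)
            f = np.log(arg).mean(axis=1) - log_rhs
            fp = (1.0 / arg).mean(axis=1)
            step = f / fp
            o = np.maximum(o - step, floor)
    o[~np.isfinite(rhs) | (rhs <= 0)] = np.nan
    return o


def _geomean_with_fallback(tt: np.ndarray) -> np.ndarray:
    """Per-component geometric mean over axis 1, arithmetic where any
    value is non-positive (T_t,3'SS is identically 0; T_t,EXN can be
    negative for short final-exon-dominated genes)."""
    allpos = np.all(tt > 0, axis=1)  # (chunk, 4)
    arith = tt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        geo = np.exp(np.log(np.where(tt > 0, tt, 1.0)).mean(axis=1))
    return np.where(allpos, geo, arith)


class SnapShotResults:
    """Accepted Monte Carlo solutions and their summaries.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per accepted (all-positive) solution, columns T5, T3,
        Tgamma, Tmu in seconds.
    params : pandas.Series
        Geometric means of the accepted solutions (the distributions are
        close to log-normal).
    """

    def __init__(
        self,
        model: SnapShotModel,
        samples: pd.DataFrame,
        n_samples_drawn: int,
        n_valid: int,
        n_discarded_zero_density: int,
        n_discarded_bad_slope: int,
        converged: bool,
        seed: int | None,
    ):
        self.model = model
        self.samples = samples
        self.n_samples_drawn = n_samples_drawn
        self.n_valid = n_valid
        self.n_discarded_zero_density = n_discarded_zero_density
        self.n_discarded_bad_slope = n_discarded_bad_slope
        self.converged = converged
        self.seed = seed

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.exp(np.log(self.samples).mean(axis=0)), index=list(TIME_NAMES)
        )

    @property
    def medians(self) -> pd.Series:
        return self.samples.median()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Percentile interval of the accepted-solution distributions."""
        lo = self.samples.quantile(alpha / 2)
        hi = self.samples.quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "SnapShot-Seq Monte Carlo solution",
            "=" * 58,
            f"genes: {len(self.model.data):>6}   samples drawn: {self.n_samples_drawn:>8}"
            f"   valid: {self.n_valid:>7}",
            f"discarded (zero-density feature): {self.n_discarded_zero_density}   "
            f"(unusable slope): {self.n_discarded_bad_slope}",
            "-" * 58,
            f"{'time':>8} {'geo mean':>10} {'median':>10} {'2.5%':>10} {'97.5%':>10}",
        ]
        gm, med = self.params, self.medians
        for name in TIME_NAMES:
            lines.append(
                f"{name:>8} {gm[name]:>10.4g} {med[name]:>10.4g} "
                f"{ci.loc[name, 'lower']:>10.4g} {ci.loc[name, 'upper']:>10.4g}"
            )
        lines.append("=" * 58)
        lines.append("all times in seconds; intervals are Monte Carlo percentiles")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SnapShotResults: {self.n_valid} valid of {self.n_samples_drawn} samples>"


def monte_carlo_solve(
    gene_slopes: pd.DataFrame,
    gene_densities: pd.DataFrame,
    gene_waiting_times: pd.DataFrame,
    config: MonteCarloConfig | None = None,
    seed: int | None = None,
) -> SnapShotResults:
    """Functional wrapper: build a :class:`SnapShotModel` and fit it."""
    return SnapShotModel.from_tables(
        gene_slopes, gene_densities, gene_waiting_times, config=config
    ).fit(seed=seed)


def stability_and_lifetime(gene_densities: pd.DataFrame) -> pd.DataFrame:
    """Per-gene simplified synthesis/stability readouts.

    Relative synthesis rate is D_3'INT itself; relative mRNA stability is
    the expression-to-synthesis ratio D_EXN / D_3'INT (absolute lifetimes
    need the full model solve).  Genes with zero D_3'INT get NaN stability.
    """
    req = {"gene_id", "d_exn", "d3int"}
    if not req.issubset(gene_densities.columns):
        raise ValueError(f"need columns {sorted(req)}")
    out = gene_densities[["gene_id", "d_exn", "d3int"]].copy()
    out["synthesis_proxy"] = out["d3int"]
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = out["d_exn"] / out["d3int"]
    out["stability"] = np.where(out["d3int"] > 0, stability, np.nan)
    return out
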