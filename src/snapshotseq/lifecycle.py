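"""Steady-state forward model of the mRNA life cycle.

At steady state every RNA species is present in a total RNA-Seq library in
proportion to its mean lifetime, so the normalized read density of a genomic
feature equals the (fused) synthesis rate ``c0S`` times the feature's total
duration.  A feature's duration decomposes into a geometry-determined
"transcription waiting time" plus the processing times shared by all genes:

* ``T5``  -- lariat formation: 5'SS cleavage, destroys the 5'SS junction
* ``T3``  -- exon ligation: 3'SS cleavage and exon joining
* ``Tgamma`` -- survival of the excised intron lariat until degradation
* ``Tmu`` -- lifetime of the mature mRNA

Transcription elongates at a uniform rate ``1/Talpha`` (default 60 bp/s,
i.e. 3.6 kb/min), so waiting times are ``Talpha`` times feature lengths.
The closed-form densities implemented here are linear in the four processing
times, which is what makes the inverse problem (see :mod:`.solver`) a 4x4
linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default elongation time constant, seconds per bp (3.6 kb/min)
DEFAULT_TALPHA = 1.0 / 60.0

#: density units per RPKM for a 10M x 35 bp standard library
DENSITY_PER_RPKM = 0.35

LARIAT_MODELS = ("I", "IIa", "IIb", "IIc", "III")


@dataclass(frozen=True)
class LifecycleParams:
    """Kinetic parameters of one gene (or a shared cohort).

    ``c0S`` fuses the per-cell initiation rate ``S`` with the sample constant
    ``c0`` (density per transcript); only the product is identifiable.  All
    times are seconds; ``Talpha`` is seconds per transcribed bp.
    """

    c0S: float
    T5: float
    T3: float
    Tgamma: float
    Tmu: float
    Talpha: float = DEFAULT_TALPHA

    def __post_init__(self) -> None:
        if self.c0S < 0:
            raise ValueError("c0S must be >= 0")
        for name in ("T5", "T3", "Tgamma", "Tmu", "Talpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def Tp(self) -> float:
        """Total intron processing time T5 + T3 + Tgamma (seconds)."""
        return self.T5 + self.T3 + self.Tgamma

    def as_vector(self) -> np.ndarray:
        """Processing times as the solver's T vector (T5, T3, Tgamma, Tmu)."""
        return np.array([self.T5, self.T3, self.Tgamma, self.Tmu])


@dataclass(frozen=True)
class WaitingTimes:
    """Geometry-determined mean transcription waiting times of one gene (s).

    ``tt_3ss`` is identically zero: a 3' splice site comes into existence
    only once its intron is fully transcribed.
    """

    tt_5ss: float
    tt_int: float
    tt_exn: float
    tt_exnjxn: float
    tt_3ss: float = 0.0

    def as_vector(self) -> np.ndarray:
        """Waiting times ordered as (5'SS, 3'SS, INT, EXN)."""
        return np.array([self.tt_5ss, self.tt_3ss, self.tt_int, self.tt_exn])


@dataclass(frozen=True)
class FeatureDensityVector:
    """Model-predicted normalized densities for one gene."""

    d_5ss: float
    d_3ss: float
    d_int: float
    d_exn: float
    d_exnjxn: float
    slope_int: float

    def as_vector(self) -> np.ndarray:
        """Densities ordered as (5'SS, 3'SS, INT, EXN)."""
        return np.array([self.d_5ss, self.d_3ss, self.d_int, self.d_exn])


def waiting_times(
    exon_lengths, intron_lengths, Talpha: float = DEFAULT_TALPHA
) -> WaitingTimes:
    """Mean transcription waiting times for a gene's feature classes.

    Parameters
    ----------
    exon_lengths, intron_lengths
        Lengths in bp, ordered 5'->3' in transcription direction; a gene with
        N introns has N+1 exons.

    Notes
    -----
    Per-feature waiting times are averaged over base positions and then
    length-weighted across features of a class (total read-bases over total
    bases), which is why squared lengths appear for introns:
    ``tt_int = Talpha * sum(L_i^2) / (2 * sum(L_i))``.

    Exon *e* (of N+1) waits for the rest of itself (half its length on
    average) plus all downstream exons and introns up to the end of the last
    intron; the last exon instead carries a negative lag of half its own
    length, because its bases are created *after* the clock that starts the
    mature-mRNA countdown.

    The exon-exon junction *s* waits for transcription from the end of
    intron *s* to the end of intron N (zero for the last junction).
    """
    exon_lengths = np.asarray(exon_lengths, dtype=float)
    intron_lengths = np.asarray(intron_lengths, dtype=float)
    n = len(intron_lengths)
    if len(exon_lengths) != n + 1:
        raise ValueError("a gene with N introns must have N+1 exons")
    if np.any(exon_lengths < 1) or (n and np.any(intron_lengths < 1)):
        raise ValueError("feature lengths must be >= 1 bp")

    if n == 0:
        # singleton exon: D_EXN = c0S (Talpha*Lambda/2 + Tmu); no other features
        return WaitingTimes(
            tt_5ss=np.nan,
            tt_int=np.nan,
            tt_exn=Talpha * exon_lengths[0] / 2.0,
            tt_exnjxn=np.nan,
        )

    tt_int = Talpha * np.sum(intron_lengths**2) / (2.0 * np.sum(intron_lengths))

    # equal effective junction lengths -> simple mean over introns
    tt_5ss = Talpha * float(np.mean(intron_lengths))

    # downstream transcription per exon: introns i>=e and internal exons e'>e
    w = np.empty(n + 1)
    for e in range(n):  # exons 1..N (0-based e)
        w[e] = Talpha * (
            exon_lengths[e] / 2.0
            + np.sum(exon_lengths[e + 1 : n])  # internal downstream exons
            + np.sum(intron_lengths[e:])
        )
    w[n] = -Talpha * exon_lengths[n] / 2.0  # last exon: negative lag
    tt_exn = float(np.sum(exon_lengths * w) / np.sum(exon_lengths))

    # junction s waits from end of intron s to end of intron N
    wj = np.empty(n)
    for s in range(n):
        wj[s] = Talpha * (
            np.sum(exon_lengths[s + 1 : n]) + np.sum(intron_lengths[s + 1 :])
        )
    tt_exnjxn = float(np.mean(wj))  # equal effective lengths per junction

    return WaitingTimes(
        tt_5ss=float(tt_5ss),
        tt_int=float(tt_int),
        tt_exn=tt_exn,
        tt_exnjxn=tt_exnjxn,
    )


def predict_densities(
    params: LifecycleParams, wt: WaitingTimes
) -> FeatureDensityVector:
    """Closed-form steady-state densities for one gene.

    Each density is ``c0S`` times (waiting time + the processing times the
    feature survives through); the intron slope is ``-c0S * Talpha``.
    """
    p, c = params, params.c0S
    return FeatureDensityVector(
        d_5ss=c * (wt.tt_5ss + p.T5),
        d_3ss=c * (p.T5 + p.T3),
        d_int=c * (wt.tt_int + p.T5 + p.T3 + p.Tgamma),
        d_exn=c * (wt.tt_exn + p.T5 + p.T3 + p.Tmu),
        d_exnjxn=c * (wt.tt_exnjxn + p.Tmu),
        slope_int=-c * p.Talpha,
    )


def predict_intron_profile(params: LifecycleParams, L: float, x) -> np.ndarray:
    """Per-base intron density ``D(x) = c0S * (Talpha*(L-x) + Tp)``.

    ``x`` is distance from the intron's 5' end in transcription direction,
    ``0 <= x < L``.  The profile is the "guillotine": a declining blade of
    height ``c0S*Talpha*L`` (nascent transcripts) on a flat base of height
    ``c0S*Tp`` (fully transcribed, not yet degraded introns).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= L):
        raise ValueError("x must satisfy 0 <= x < L")
    return params.c0S * (params.Talpha * (L - x) + params.Tp)


def mean_intron_density(params: LifecycleParams, L: float) -> float:
    """Average of the intron profile: ``c0S * (Talpha*L/2 + Tp)``."""
    return params.c0S * (params.Talpha * L / 2.0 + params.Tp)


@dataclass(frozen=True)
class LariatModelPrediction:
    """End-difference predictions under one lariat-degradation mechanism."""

    model: str
    delta_d_intron_ends: float
    delta_d_splice_sites: float
    profile: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)


def splice_site_and_lariat_predictions(
    params: LifecycleParams,
    L: float,
    lariat_model: str = "IIb",
    n_points: int = 101,
) -> LariatModelPrediction:
    """Intron-end vs splice-site density differences under lariat models.

    The 5'SS-3'SS density difference ``c0S*(Talpha*L - T3)`` is independent
    of how the excised lariat is degraded (splice sites are destroyed by the
    catalytic steps, before lariat degradation begins) and changes sign at
    ``L = T3/Talpha``.  The intron-end difference depends on the mechanism:

    * ``IIb`` -- chew-through much faster than elongation: the lariat
      persists intact for ``Tgamma`` and vanishes; ends differ by
      ``c0S*Talpha*L`` (the baseline model).
    * ``I`` / ``IIa`` -- a 3'->5' exonuclease at 1x / 10x the polymerase
      speed adds a 5'-biased extra occupancy; the end difference grows to
      ``c0S*(Talpha + Talpha/k)*L`` with k the speed ratio.
    * ``IIc`` / ``III`` -- a 5'->3' exonuclease at 10x / 1x polymerase speed
      cancels part (or, at equal speed, all) of the nascent decline:
      ``c0S*(Talpha - Talpha/k)*L``.

    The returned ``profile`` is the expected per-base occupancy: base at
    distance x lives ``Talpha*(L-x) + T5 + T3 + Tgamma`` plus the
    exonuclease arrival lag for its position.
    """
    if lariat_model not in LARIAT_MODELS:
        raise ValueError(f"unknown lariat model {lariat_model!r}; expected one of {LARIAT_MODELS}")
    p = params
    x = np.linspace(0.0, L, n_points, endpoint=False)
    base_life = p.Talpha * (L - x) + p.T5 + p.T3 + p.Tgamma

    speed = {"I": 1.0, "IIa": 10.0, "IIc": 10.0, "III": 1.0}
    if lariat_model == "IIb":
        extra = np.zeros_like(x)
        rate_term = 0.0
    elif lariat_model in ("I", "IIa"):
        k = speed[lariat_model]
        extra = (p.Talpha / k) * (L - x)  # 3'->5': 5' bases outlive 3' bases
        rate_term = p.Talpha / k
    else:  # IIc, III: 5'->3'
        k = speed[lariat_model]
        extra = (p.Talpha / k) * x
        rate_term = -p.Talpha / k

    profile = p.c0S * (base_life + extra)
    delta_ends = p.c0S * (p.Talpha + rate_term) * L
    delta_ss = p.c0S * (p.Talpha * L - p.T3)
    return LariatModelPrediction(
        model=lariat_model,
        delta_d_intron_ends=float(delta_ends),
        delta_d_splice_sites=float(delta_ss),
        profile=profile,
        positions=x,
    )


def slope_to_c0s(slope: float, Talpha: float = DEFAULT_TALPHA) -> float:
    """Convert an intron density slope (per bp) to c0S (density per second).

    ``c0S = -slope / Talpha``; as a rule of thumb ``3600 * |slope|`` is c0S
    in density per minute for the default elongation rate.
    """
    return -slope / Talpha
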