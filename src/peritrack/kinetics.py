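"""Transcription kinetics: induction-curve fitting and derived rates.

The mean number of gene-bound polymerases per cell after induction follows

    <N>(t) = a (1 − e^(−b t)),    a = k_on / k_off,    b = k_off,

the mean of an immigration–death process with constant arrival rate k_on
(pseudo-first-order: promoter search + initiation, lumped) and independent
per-polymerase departure rate k_off (set by the elongation duration).  From
the fitted (a, b) and the gene length L follow

    elongation rate = L · k_off        elongation time = 1 / k_off
    k_on = a · b                       search time     = 1 / k_on

The module also fits first-order mRNA decay (rifampicin chase), converts
steady-state abundance ratios into production-rate ratios via the half-life
correction, recovers elongation rates from two-probe onset times, and
computes Miller units for the β-galactosidase assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from peritrack.fluorquant import InductionSeries

__all__ = [
    "KineticEstimate",
    "DecayFit",
    "model_mean",
    "fit_induction",
    "derive_rates",
    "fit_decay",
    "corrected_production_ratio",
    "estimate_onset",
    "elongation_rate_from_onsets",
    "miller_units",
]


@dataclass(frozen=True)
class KineticEstimate:
    """Fitted plateau/rate pair and the derived transcription parameters."""

    a: float  # plateau, mean transcribing polymerases per cell
    b: float  # min^-1, equals k_off
    a_se: float
    b_se: float
    k_on_per_min: float  # pseudo-first-order aggregate, a * b
    k_off_per_min: float
    elongation_rate_bp_s: float  # L * k_off
    elongation_time_s: float  # 1 / k_off
    search_time_s: float  # 1 / k_on
    gene_length_bp: float
    plateau_reached: bool = True  # False when b * t_max < 1

    def __post_init__(self) -> None:
        for name in ("a", "b", "k_on_per_min", "k_off_per_min", "gene_length_bp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def k_on_prime_per_min(self, rnap_total: float = 35.0) -> float:
        """Per-polymerase on-rate k'_on = k_on / [RNAP_total]."""
        return self.k_on_per_min / rnap_total


@dataclass(frozen=True)
class DecayFit:
    """Log-linear first-order decay fit."""

    half_life_min: float
    half_life_se_min: float
    decay_constant_per_min: float
    intercept: float  # fitted log-abundance at t = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.half_life_min, math.log(2) / self.decay_constant_per_min):
            raise ValueError("half-life must equal ln2 / decay constant")


def model_mean(a: float, b: float, t) -> np.ndarray | float:
    """Mean bound-polymerase count a(1 − e^(−bt)); t in the units of 1/b."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = a * (1.0 - np.exp(-b * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def derive_rates(
    a: float, b: float, gene_length_bp: float, a_se: float = 0.0, b_se: float = 0.0,
    plateau_reached: bool = True,
) -> KineticEstimate:
    """Derived transcription parameters from the fitted (a, b); b in min^-1."""
    if a <= 0 or b <= 0 or gene_length_bp <= 0:
        raise ValueError("a, b and gene length must be positive")
    k_on = a * b
    return KineticEstimate(
        a=a,
        b=b,
        a_se=a_se,
        b_se=b_se,
        k_on_per_min=k_on,
        k_off_per_min=b,
        elongation_rate_bp_s=gene_length_bp * b / 60.0,
        elongation_time_s=60.0 / b,
        search_time_s=60.0 / k_on,
        gene_length_bp=gene_length_bp,
        plateau_reached=plateau_reached,
    )


def fit_induction(series: InductionSeries, gene_length_bp: float = 4500.0) -> KineticEstimate:
    """Weighted nonlinear least squares of a(1 − e^(−bt)) to an induction curve.

    Times are taken in seconds (as stored in the series) and b is reported
    in min^-1.  Points are weighted by 1/SEM² when per-point dispersion is
    available, unweighted otherwise.  A series whose span covers less than
    one e-folding of b gets ``plateau_reached=False``.
    """
    counts = series.counts if series.counts is not None else series.intensity
    t_min = series.times_s / 60.0
    if t_min.size < 5:
        raise ValueError("induction fit needs at least 5 time points")
    sd = np.asarray(series.sd, dtype=float)
    n = np.asarray(series.n, dtype=float)
    sem = sd / np.sqrt(n)
    sigma = sem if np.all(sem > 0) else None

    a0 = max(float(np.max(counts)), 1e-6)
    b0 = 1.0
    try:
        popt, pcov = curve_fit(
            lambda t, a, b: a * (1.0 - np.exp(-b * t)),
            t_min,
            counts,
            p0=[a0, b0],
            sigma=sigma,
            absolute_sigma=False,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"induction fit did not converge: {exc}") from exc
    a, b = popt
    a_se, b_se = np.sqrt(np.diag(pcov))
    return derive_rates(
        a, b, gene_length_bp, a_se=float(a_se), b_se=float(b_se),
        plateau_reached=bool(b * t_min[-1] >= 1.0),
    )


def fit_decay(times_min, abundances) -> DecayFit:
    """Ordinary least squares of log abundance vs time; half-life = ln2/|slope|."""
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.size < 3:
        raise ValueError("decay fit needs at least 3 points")
    if np.any(y <= 0):
        raise ValueError("abundances must be positive for the log fit")
    res = linregress(t, np.log(y))
    if res.slope >= 0:
        raise ValueError("log-abundance slope is non-negative: no decay to fit")
    lam = -res.slope
    half_life = math.log(2) / lam
    se = math.log(2) / lam**2 * res.stderr  # delta method on the slope
    return DecayFit(
        half_life_min=half_life,
        half_life_se_min=float(se),
        decay_constant_per_min=lam,
        intercept=float(res.intercept),
    )


def corrected_production_ratio(
    abundance_ratio: float, half_life_num_min: float, half_life_den_min: float
) -> float:
    """Production-rate ratio from a steady-state abundance ratio.

    At steady state abundance = production × mean lifetime, so a strain pair
    with abundance ratio R (numerator over denominator strain) and
    half-lives (τ_num, τ_den) has production ratio R · τ_den / τ_num.
    """
    if abundance_ratio <= 0 or half_life_num_min <= 0 or half_life_den_min <= 0:
        raise ValueError("abundance ratio and half-lives must be positive")
    return abundance_ratio * half_life_den_min / half_life_num_min


def estimate_onset(times, values, threshold_frac: float = 0.02) -> float:
    """Onset time of a delayed linear ramp by back-extrapolation.

    Fits a line to the clearly rising part (values above ``threshold_frac``
    of the maximum) and returns its x-intercept.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    rising = v > threshold_frac * v.max()
    if rising.sum() < 2:
        raise ValueError("ramp has fewer than 2 rising points")
    res = linregress(t[rising], v[rising])
    if res.slope <= 0:
        raise ValueError("ramp does not rise")
    return float(-res.intercept / res.slope)


def elongation_rate_from_onsets(
    onset_near_s: float, onset_far_s: float, separation_bp: float
) -> float:
    """Elongation rate from the onset delay between two probe positions."""
    if separation_bp <= 0:
        raise ValueError("probe separation must be positive")
    dt = onset_far_s - onset_near_s
    if dt <= 0:
        raise ValueError("far-probe onset must follow the near-probe onset")
    return separation_bp / dt


def miller_units(od420: float, t_min: float, volume_ml: float, od660: float) -> float:
    """β-galactosidase activity, 1000 · OD420 / (t · V · OD660)."""
    if t_min <= 0 or volume_ml <= 0 or od660 <= 0:
        raise ValueError("reaction time, volume and OD660 must be positive")
    return 1000.0 * od420 / (t_min * volume_ml * od660)
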