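"""Extraction of growth rate, mid-exponential point and CRP activity.

The per-group algorithm (one analysis group = CRP reporter, sigma-70
reporter and promoterless background wells grown in parallel on one
condition and day):

1.  The instantaneous growth rate is the time derivative of log OD,
    estimated as the least-squares slope of ln(OD) versus time over a
    sliding 2-hour window (15 points at the 9-min cadence).
2.  The growth rate is resampled at 30 points equally spaced in
    log(OD) between OD = 0.001 and OD = 0.1 — working in OD space
    makes the downstream steps insensitive to lag-phase differences
    between repeats.
3.  The mid-exponential point OD_midexp is the centre of the 13-point
    running window with the smallest standard deviation of the growth
    rate (the "steadiest growth" window), subject to a floor of
    OD = 0.01 below which reporter signals are too dim to trust.
4.  Promoter activity PA = (dGFP/dt)/OD of each reporter is averaged
    over a 2-hour window centred at the time the culture reaches
    OD_midexp.
5.  CRP activity is PA(crp) / PA(sigma70).  The sigma-70 promoter is
    constitutive, so its activity tracks the overall transcription/
    growth machinery; the ratio therefore measures the *fraction* of
    cellular resources allocated to CRP-controlled genes, in units
    that cancel reporter gain and plate-reader calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from growthlaw.plate_io import PlateExperiment, WellSeries, subtract_background

__all__ = [
    "GrowthTrace",
    "GrowthPhenotype",
    "PipelineConfig",
    "log_od_growth_rate",
    "resample_to_log_od_grid",
    "find_midexp",
    "promoter_activity",
    "crp_activity",
    "analyze_group",
    "analyze_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the extraction algorithm, with standard defaults.

    window_hours      span of the sliding derivative window (h)
    window_points     number of points in the window when the cadence is
                      not 9 min; by default derived from window_hours
                      (rounded to an odd count)
    grid_n            number of log-OD resampling levels
    od_lo, od_hi      OD range of the resampling grid
    sd_window         running-s.d. window length (grid points)
    od_floor          minimum OD accepted for the mid-exponential point
    smooth_gfp        use the same sliding-window slope for dGFP/dt as
                      for the OD derivative (two-point differences
                      otherwise)
    """

    window_hours: float = 2.0
    window_points: int | None = None
    grid_n: int = 30
    od_lo: float = 0.001
    od_hi: float = 0.1
    sd_window: int = 13
    od_floor: float = 0.01
    smooth_gfp: bool = True

    def points_for(self, times_min: np.ndarray) -> int:
        """Window length in samples covering ``window_hours`` (odd)."""
        if self.window_points is not None:
            return self.window_points
        dt = float(np.median(np.diff(times_min)))
        n = int(round(self.window_hours * 60.0 / dt)) + 1
        if n % 2 == 0:
            n += 1
        return max(n, 3)


@dataclass
class GrowthTrace:
    """Per-timepoint instantaneous growth rate of one well."""

    times: np.ndarray          # min
    log_od: np.ndarray
    rate: np.ndarray           # h^-1; NaN where the window does not fit
    window_points: int


@dataclass
class GrowthPhenotype:
    """Per-condition growth phenotype extracted from one analysis group."""

    mu: float                  # growth rate at mid-exponential (h^-1)
    od_midexp: float
    pa_crp: float              # promoter activities (GFP OD^-1 h^-1)
    pa_sigma70: float
    crp_star: float            # pa_crp / pa_sigma70
    qc: list[str] = field(default_factory=list)


def _sliding_slope(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Centred least-squares slope of y vs t over a sliding window.

    Returns dy/dt at each point; NaN at the ends where the full window
    does not fit.  Vectorized via the closed-form OLS slope
    cov(t, y)/var(t) computed with cumulative sums.
    """
    n = len(t)
    out = np.full(n, np.nan)
    if n < window:
        return out
    half = window // 2
    # sliding windows (n - window + 1, window)
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    num = ((tw - tm) * (yw - ym)).sum(axis=1)
    den = ((tw - tm) ** 2).sum(axis=1)
    out[half:n - half] = num / den
    return out


def log_od_growth_rate(series: WellSeries,
                       config: PipelineConfig = PipelineConfig()) -> GrowthTrace:
    """Instantaneous growth rate from the log-OD derivative (h^-1).

    The slope of ln(OD) versus time over the centred sliding window
    (15 points = 2 h at 9-min sampling).  Points where OD <= 0 are
    excluded before the log; endpoints without a full window carry NaN.
    """
    pos = series.od > 0
    t = series.times[pos]
    window = config.points_for(series.times)
    if pos.sum() < window:
        raise ValueError(
            f"well {series.meta.well}: fewer than {window} positive-OD samples")
    log_od = np.log(series.od[pos])
    rate_per_min = _sliding_slope(t, log_od, window)
    return GrowthTrace(times=t, log_od=log_od,
                       rate=rate_per_min * 60.0, window_points=window)


def resample_to_log_od_grid(trace: GrowthTrace,
                            config: PipelineConfig = PipelineConfig()
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Growth rate at OD levels equally spaced in log(OD).

    For each of ``grid_n`` levels between ``od_lo`` and ``od_hi`` the
    time of the *first upward crossing* of that OD is located by linear
    interpolation, and the growth rate is linearly interpolated in time
    at that moment.  Levels the culture never reaches (saturation below
    od_hi) are NaN.  Returns ``(od_levels, rates)``.
    """
    od = np.exp(trace.log_od)
    levels = np.exp(np.linspace(math.log(config.od_lo),
                                math.log(config.od_hi), config.grid_n))
    if float(np.nanmax(od)) <= config.od_lo:
        raise ValueError("no growth: OD never exceeds the lower grid bound")
    rates = np.full(config.grid_n, np.nan)
    valid = ~np.isnan(trace.rate)
    t_valid = trace.times[valid]
    r_valid = trace.rate[valid]
    if len(t_valid) < 2:
        return levels, rates
    for j, lev in enumerate(levels):
        t_cross = _first_upward_crossing(trace.times, od, lev)
        if t_cross is None:
            continue
        if t_cross < t_valid[0] or t_cross > t_valid[-1]:
            continue  # crossing happens where no rate estimate exists
        rates[j] = np.interp(t_cross, t_valid, r_valid)
    return levels, rates


def _first_upward_crossing(t: np.ndarray, od: np.ndarray,
                           level: float) -> float | None:
    """Time of the first upward crossing of ``level``, or None."""
    above = od >= level
    if above[0]:
        return float(t[0])
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    # linear interpolation between the straddling samples
    f = (level - od[i]) / (od[i + 1] - od[i])
    return float(t[i] + f * (t[i + 1] - t[i]))


def find_midexp(od_levels: np.ndarray, rates: np.ndarray,
                config: PipelineConfig = PipelineConfig()
                ) -> tuple[float, float]:
    """OD and growth rate at the steadiest-growth (mid-exponential) point.

    Scans every run of ``sd_window`` consecutive defined grid points and
    picks the window with the smallest sample s.d. of the growth rate;
    the centre level is OD_midexp and the rate at that level is mu.
    Windows centred below ``od_floor`` are only used if no window at or
    above the floor exists — reporter signal is too dim below it.  Ties
    break toward lower OD.  Raises if fewer than ``sd_window``
    consecutive levels are defined.
    """
    w = config.sd_window
    defined = ~np.isnan(rates)
    candidates: list[tuple[float, float, float]] = []  # (sd, od_centre, rate_centre)
    for start in range(0, len(rates) - w + 1):
        if not defined[start:start + w].all():
            continue
        seg = rates[start:start + w]
        centre = start + w // 2
        candidates.append((float(np.std(seg, ddof=1)),
                           float(od_levels[centre]), float(rates[centre])))
    if not candidates:
        raise ValueError(
            f"fewer than {w} consecutive defined log-OD grid points")
    eligible = [c for c in candidates if c[1] >= config.od_floor]
    if eligible:
        # minimal s.d.; ties broken toward lower OD (stable ordering)
        eligible.sort(key=lambda c: (c[0], c[1]))
        _, od_mid, mu = eligible[0]
    else:
        # nothing at or above the floor: take the lowest available window
        candidates.sort(key=lambda c: c[1])
        _, od_mid, mu = candidates[0]
    return od_mid, mu


def promoter_activity(series: WellSeries, od_midexp: float,
                      config: PipelineConfig = PipelineConfig()
                      ) -> tuple[float, list[str]]:
    """Promoter activity PA = (dGFP/dt)/OD averaged at mid-exponential.

    dGFP/dt uses the same sliding least-squares slope as the OD
    derivative (``config.smooth_gfp``, default) or two-point central
    differences; the pointwise ratio to OD is averaged over a
    ``window_hours`` window centred at the time OD first reaches
    ``od_midexp``.  Reported per hour (GFP OD^-1 h^-1).

    Returns ``(pa, qc_flags)``; a window truncated by the ends of the
    series is used as-is with a ``"pa_window_truncated"`` flag.
    """
    qc: list[str] = []
    t = series.times
    window = config.points_for(t)
    if config.smooth_gfp:
        dgfp = _sliding_slope(t, series.gfp, window)      # GFP per min
    else:
        dgfp = np.gradient(series.gfp, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa_t = np.where(series.od > 0, dgfp / series.od, np.nan) * 60.0
    t_mid = _first_upward_crossing(t, series.od, od_midexp)
    if t_mid is None:
        raise ValueError(
            f"well {series.meta.well}: OD never reaches od_midexp={od_midexp}")
    half_span = config.window_hours * 60.0 / 2.0
    in_window = (t >= t_mid - half_span) & (t <= t_mid + half_span)
    if t_mid - half_span < t[0] or t_mid + half_span > t[-1]:
        qc.append("pa_window_truncated")
    vals = pa_t[in_window]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError(
            f"well {series.meta.well}: no promoter-activity estimates in the "
            "mid-exponential window")
    return float(np.mean(vals)), qc


def crp_activity(pa_crp: float, pa_sigma70: float) -> float:
    """CRP activity: PA of the CRP reporter over PA of the sigma-70 reporter.

    Dimensionless; the constitutive sigma-70 promoter normalizes out
    reporter gain and overall expression capacity, leaving the fraction
    of transcriptional resources directed at CRP targets.
    """
    if not pa_sigma70 > 0:
        raise ValueError("sigma70 promoter activity must be positive")
    return pa_crp / pa_sigma70


def analyze_group(wells: list[WellSeries],
                  config: PipelineConfig = PipelineConfig()) -> GrowthPhenotype:
    """Run the full extraction on one analysis group of three wells.

    Growth rate and OD_midexp come from the reporter wells' OD traces
    (mean of the CRP and sigma-70 wells, which are replicate cultures
    of the same condition); promoter activities are computed per
    reporter after background subtraction.
    """
    by_rep = {w.meta.reporter: w for w in wells}
    for rep in ("crp", "sigma70", "promoterless"):
        if rep not in by_rep:
            raise ValueError(f"analysis group lacks a {rep} well")
    corrected = subtract_background(wells)
    by_corr = {w.meta.reporter: w for w in corrected}

    mus, ods = [], []
    for rep in ("crp", "sigma70"):
        trace = log_od_growth_rate(by_corr[rep], config)
        levels, rates = resample_to_log_od_grid(trace, config)
        od_mid, mu = find_midexp(levels, rates, config)
        mus.append(mu)
        ods.append(od_mid)
    mu = float(np.mean(mus))
    od_midexp = float(np.exp(np.mean(np.log(ods))))

    qc: list[str] = []
    pa_crp, q1 = promoter_activity(by_corr["crp"], od_midexp, config)
    pa_sig, q2 = promoter_activity(by_corr["sigma70"], od_midexp, config)
    qc.extend(q1)
    qc.extend(q2)
    if mu <= 0:
        qc.append("nonpositive_growth_rate")
    star = crp_activity(pa_crp, pa_sig)
    return GrowthPhenotype(mu=mu, od_midexp=od_midexp, pa_crp=pa_crp,
                           pa_sigma70=pa_sig, crp_star=star, qc=qc)


def analyze_experiment(exp: PlateExperiment,
                       config: PipelineConfig = PipelineConfig()
                       ) -> pd.DataFrame:
    """Extract one phenotype row per analysis group of an experiment.

    Returns a tidy frame with columns carbon_source, camp_mM,
    perturbation, day, mu, crp_star, od_midexp, pa_crp, pa_sigma70, qc.
    Groups whose extraction fails (no growth, missing wells, ...) are
    skipped with a logged reason.
    """
    rows = []
    for key, wells in sorted(exp.groups().items(), key=lambda kv: str(kv[0])):
        strain, carbon, camp, perturbation, day = key
        try:
            ph = analyze_group(wells, config)
        except ValueError as e:
            logger.warning("group %s skipped: %s", key, e)
            continue
        rows.append({
            "strain": strain, "carbon_source": carbon, "camp_mM": camp,
            "perturbation": perturbation, "day": day,
            "mu": ph.mu, "crp_star": ph.crp_star,
            "od_midexp": ph.od_midexp, "pa_crp": ph.pa_crp,
            "pa_sigma70": ph.pa_sigma70, "qc": ";".join(ph.qc),
        })
    return pd.DataFrame(rows)
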