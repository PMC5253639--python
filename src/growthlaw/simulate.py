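"""Synthetic plate-reader experiments with known ground truth.

The original study's raw time series were never deposited, so every
pipeline stage is validated against generated data whose true growth
rate, promoter activities and CRP activity are known by construction.
The generator emulates the relevant structure of a robotic plate-reader
run:

* lag-shifted logistic OD growth (lag, exponential window, saturation
  well above the OD 0.001-0.1 analysis range);
* GFP accumulating as the integral of promoter activity times OD, plus
  an autofluorescence component proportional to OD; the promoterless
  strain carries autofluorescence only;
* three reporter strains (crp, sigma70, promoterless) grown in
  parallel per condition and day;
* multiplicative log-normal OD noise, additive Gaussian GFP noise, and
  day effects: one multiplicative factor per day on growth rate
  (sigma = 4%) and one on CRP activity (sigma = 12%), shared by all
  wells run that day, reflecting plate-reader calibration and
  inoculum-state variation between runs.

Defaults: the 9-min sampling cadence and the exogenous cAMP dose list
match the study design; the carrying capacity of 1.6 OD units follows
from 2 g l^-1 carbon source at a biomass yield of ~0.4 g dry weight
per g and ~0.5 g dry weight per litre per OD unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from growthlaw.model import ModelParams, closed_loop_state, growth_rate
from growthlaw.plate_io import PlateExperiment, WellMeta, WellSeries

__all__ = [
    "SimSpec",
    "DoseResponse",
    "CAMP_DOSES_MM",
    "simulate_well",
    "simulate_group",
    "simulate_ocurve_experiment",
    "simulate_cline_experiment",
]

#: Exogenous cAMP doses (mM) used for open-loop O-curve titration.
CAMP_DOSES_MM = (10.0, 5.0, 2.5, 1.25, 0.625, 0.31, 0.15, 0.078, 0.039, 0.0)


@dataclass(frozen=True)
class SimSpec:
    """All knobs of one simulated well/group.

    od0                inoculation OD (1:500 dilution of an overnight culture)
    lag_h              lag-phase duration (h)
    mu                 exponential growth rate (h^-1)
    capacity           carrying capacity (OD units)
    crp_star           true CRP activity = PA(crp)/PA(sigma70)
    pa_sigma70         sigma-70 promoter activity (GFP OD^-1 h^-1)
    autofluorescence   background fluorescence per OD unit
    od_noise           sigma of multiplicative log-normal OD noise
    gfp_noise          s.d. of additive Gaussian GFP noise
    day_mu_sigma       sigma of the per-day log-normal factor on mu
    day_crp_sigma      sigma of the per-day log-normal factor on crp_star
    interval_min       sampling cadence (min)
    duration_h         run length (h); None = long enough to pass OD 0.2
    seed               RNG seed for this spec
    """

    od0: float = 5e-4
    lag_h: float = 2.0
    mu: float = 0.6
    capacity: float = 1.6
    crp_star: float = 1.0
    pa_sigma70: float = 1000.0
    autofluorescence: float = 150.0
    od_noise: float = 0.01
    gfp_noise: float = 0.5
    day_mu_sigma: float = 0.04
    day_crp_sigma: float = 0.12
    interval_min: float = 9.0
    duration_h: float | None = None
    max_duration_h: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("od_noise", "gfp_noise", "day_mu_sigma", "day_crp_sigma",
                     "autofluorescence", "lag_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not 0 < self.od0 < self.capacity:
            raise ValueError("need 0 < od0 < capacity")

    def times_min(self) -> np.ndarray:
        dur = self.duration_h
        if dur is None:
            # reach OD 0.2 with margin for the 2-h promoter-activity
            # window; a run is never longer than max_duration_h (wells
            # that cannot grow that fast stay flat and are rejected
            # downstream, as in a real plate run)
            dur = self.lag_h + math.log(0.2 / self.od0) / self.mu + 3.0
            dur = min(dur, self.max_duration_h)
        n = int(dur * 60.0 / self.interval_min) + 1
        return np.arange(n) * self.interval_min


def _clean_od(spec: SimSpec, times_min: np.ndarray) -> np.ndarray:
    """Noise-free lagged-logistic OD trajectory."""
    t_h = times_min / 60.0
    tau = np.maximum(t_h - spec.lag_h, 0.0)
    K, n0 = spec.capacity, spec.od0
    e = np.exp(spec.mu * tau)
    return K * n0 * e / (K + n0 * (e - 1.0))


def _clean_gfp(spec: SimSpec, times_min: np.ndarray, od: np.ndarray,
               pa: float) -> np.ndarray:
    """GFP = integral of PA * OD (trapezoid) + autofluorescence * OD."""
    t_h = times_min / 60.0
    incr = 0.5 * np.diff(t_h) * (od[1:] + od[:-1]) * pa
    signal = np.concatenate([[0.0], np.cumsum(incr)])
    return signal + spec.autofluorescence * od


def simulate_well(spec: SimSpec, reporter: str, meta: WellMeta | None = None,
                  rng: np.random.Generator | None = None) -> WellSeries:
    """Simulate one well of the given reporter strain.

    Promoter activity is ``spec.pa_sigma70`` for the sigma-70 reporter,
    ``spec.crp_star * spec.pa_sigma70`` for the CRP reporter and 0 for
    the promoterless background strain.  Reproducible: the same spec
    and seed give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if meta is None:
        meta = WellMeta(well="sim", reporter=reporter)
    times = spec.times_min()
    od = _clean_od(spec, times)
    pa = {"crp": spec.crp_star * spec.pa_sigma70,
          "sigma70": spec.pa_sigma70,
          "promoterless": 0.0}[reporter]
    gfp = _clean_gfp(spec, times, od, pa)
    if spec.od_noise > 0:
        od = od * np.exp(rng.normal(0.0, spec.od_noise, size=len(od)))
    if spec.gfp_noise > 0:
        gfp = gfp + rng.normal(0.0, spec.gfp_noise, size=len(gfp))
    return WellSeries(times=times, od=od, gfp=gfp, meta=meta)


def simulate_group(spec: SimSpec, *, strain: str = "wild_type",
                   carbon_source: str = "", camp_mM: float = 0.0,
                   perturbation: str = "", day: int = 1,
                   well_prefix: str = "W",
                   rng: np.random.Generator | None = None,
                   apply_day_effect: bool = True) -> list[WellSeries]:
    """Simulate one analysis group: crp + sigma70 + promoterless wells.

    The three strains share the growth parameters of the condition (the
    same medium, same day), but carry independent measurement noise.
    When ``apply_day_effect`` is set (the default for stand-alone use)
    a day factor is drawn from the spec's day sigmas; experiment-level
    generators draw day factors themselves, once per day, and disable
    this.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    eff = spec
    if apply_day_effect:
        f_mu = math.exp(rng.normal(0.0, spec.day_mu_sigma))
        f_crp = math.exp(rng.normal(0.0, spec.day_crp_sigma))
        eff = dc_replace(spec, mu=spec.mu * f_mu, crp_star=spec.crp_star * f_crp)
    wells = []
    for i, reporter in enumerate(("crp", "sigma70", "promoterless")):
        meta = WellMeta(well=f"{well_prefix}{i}", strain=strain,
                        reporter=reporter, carbon_source=carbon_source,
                        camp_mM=camp_mM, perturbation=perturbation, day=day)
        wells.append(simulate_well(eff, reporter, meta=meta, rng=rng))
    return wells


@dataclass(frozen=True)
class DoseResponse:
    """Saturating map from exogenous cAMP dose to achieved C-sector size.

    A Hill curve ``C(d) = C_at_sat * d^h / (K^h + d^h)``: monotone
    non-decreasing and bounded by ``C_at_sat``.  The study never printed
    a dose-response, so this is a generic saturating shape whose range
    covers the O-curve maxima of interest.
    """

    C_at_sat: float = 0.7
    K_mM: float = 0.6
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.C_at_sat <= 1) or self.K_mM <= 0 or self.hill <= 0:
            raise ValueError("invalid dose-response parameters")

    def __call__(self, dose_mM: float) -> float:
        if dose_mM < 0:
            raise ValueError("dose must be >= 0")
        if dose_mM == 0:
            return 0.0
        dh = dose_mM ** self.hill
        return self.C_at_sat * dh / (self.K_mM ** self.hill + dh)


_MIN_MU = 1e-6  # wells on conditions that cannot grow stay flat


def _day_factors(spec: SimSpec, n_days: int,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    return [(math.exp(rng.normal(0.0, spec.day_mu_sigma)),
             math.exp(rng.normal(0.0, spec.day_crp_sigma)))
            for _ in range(n_days)]


def simulate_ocurve_experiment(params: ModelParams, dose: DoseResponse,
                               camp_doses=CAMP_DOSES_MM, n_days: int = 3,
                               seed: int = 0, *, spec: SimSpec = SimSpec(),
                               carbon_source: str = "carbon",
                               crp_scale: float = 3.0,
                               include_endogenous: bool = True
                               ) -> tuple[PlateExperiment, pd.DataFrame]:
    """Simulate a full open-loop O-curve titration (plus endogenous wells).

    For each cAMP dose the achieved C-sector size is ``dose(camp)``,
    the growth rate comes from the allocation model (``params.gamma``
    sets the h^-1 rate unit) and the true CRP activity is
    ``crp_scale * C``.  Per day, one growth-rate factor and one CRP
    factor are drawn and shared across all of that day's wells.  The
    endogenous (wild-type, closed-loop) group per day uses the model's
    closed-loop steady state.  Returns the experiment and a ground-truth
    table with nominal and day-realized values.
    """
    rng = np.random.default_rng(seed)
    factors = _day_factors(spec, n_days, rng)
    exp = PlateExperiment(source=f"simulated:ocurve:{carbon_source}")
    truth_rows = []
    widx = 0

    conditions: list[tuple[str, float, float, float]] = []
    for camp in camp_doses:
        C = dose(camp)
        mu_nom = growth_rate(params, C) if C > 0 or params.input(0.0) > 0 else 0.0
        conditions.append(("open_loop", camp, C, mu_nom))
    if include_endogenous:
        ss = closed_loop_state(params)
        conditions.append(("wild_type", 0.0, ss.C, ss.mu))

    for day in range(1, n_days + 1):
        f_mu, f_crp = factors[day - 1]
        for strain, camp, C, mu_nom in conditions:
            crp_nom = crp_scale * C
            mu_day = max(mu_nom * f_mu, _MIN_MU)
            crp_day = crp_nom * f_crp
            gspec = dc_replace(spec, mu=mu_day, crp_star=crp_day)
            wells = simulate_group(
                gspec, strain=strain, carbon_source=carbon_source,
                camp_mM=camp, day=day, well_prefix=f"W{widx:03d}_",
                rng=rng, apply_day_effect=False)
            exp.wells.extend(wells)
            widx += 1
            truth_rows.append({
                "carbon_source": carbon_source, "strain": strain,
                "camp_mM": camp, "day": day, "C": C,
                "mu_nominal": mu_nom, "crp_star_nominal": crp_nom,
                "mu_day": mu_day, "crp_star_day": crp_day,
            })
    return exp, pd.DataFrame(truth_rows)


def simulate_cline_experiment(params_base: ModelParams,
                              beta_per_source: dict[str, float],
                              n_days: int = 3, seed: int = 0, *,
                              spec: SimSpec = SimSpec(),
                              crp_scale: float = 3.0,
                              crp_star_offsets: dict[str, float] | None = None,
                              inputs: dict | None = None
                              ) -> tuple[PlateExperiment, pd.DataFrame]:
    """Simulate wild-type growth across carbon sources — the C-line.

    One closed-loop steady state per source (its ``beta``, and its
    input function if given in ``inputs``, substituted into
    ``params_base``); day effects are shared across sources within
    a day.  ``crp_star_offsets`` shifts selected sources off the line
    (emulating a ribose-like outlier) without touching their growth
    rate.
    """
    if len(beta_per_source) < 1:
        raise ValueError("need at least one carbon source")
    crp_star_offsets = crp_star_offsets or {}
    inputs = inputs or {}
    rng = np.random.default_rng(seed)
    factors = _day_factors(spec, n_days, rng)
    exp = PlateExperiment(source="simulated:cline")
    truth_rows = []
    widx = 0
    for day in range(1, n_days + 1):
        f_mu, f_crp = factors[day - 1]
        for source, beta in beta_per_source.items():
            p_src = dc_replace(params_base, beta=beta)
            if source in inputs:
                p_src = dc_replace(p_src, input=inputs[source])
            ss = closed_loop_state(p_src)
            crp_nom = crp_scale * ss.C + crp_star_offsets.get(source, 0.0)
            mu_day = max(ss.mu * f_mu, _MIN_MU)
            crp_day = crp_nom * f_crp
            gspec = dc_replace(spec, mu=mu_day, crp_star=crp_day)
            wells = simulate_group(
                gspec, strain="wild_type", carbon_source=source,
                camp_mM=0.0, day=day, well_prefix=f"C{widx:03d}_",
                rng=rng, apply_day_effect=False)
            exp.wells.extend(wells)
            widx += 1
            truth_rows.append({
                "carbon_source": source, "strain": "wild_type",
                "camp_mM": 0.0, "day": day, "beta": beta, "C": ss.C,
                "mu_nominal": ss.mu, "crp_star_nominal": crp_nom,
                "mu_day": mu_day, "crp_star_day": crp_day,
            })
    return exp, pd.DataFrame(truth_rows)
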