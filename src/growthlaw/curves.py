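"""O-curve / C-line assembly, optimality classification and model fitting.

Vocabulary (see :mod:`growthlaw.model` for the underlying theory):

O-curve
    Growth rate versus CRP activity in the *open-loop* circuit (cAMP
    synthesis and degradation deleted, CRP activity set by exogenous
    cAMP doses).  Inverse-U shaped; its maximum is the best growth
    achievable on that carbon source by tuning CRP activity alone.
C-line
    The near-linear locus of (CRP*, growth rate) points traced by
    wild-type (closed-loop) cells across carbon sources — the growth
    law itself.
Endogenous control point
    The wild-type (CRP*, mu) pair on a given carbon source: the point
    the feedback circuit actually chooses.

Feedback control is *optimal* on a source when the endogenous growth
rate matches the O-curve maximum; the classification below calls a
source sub-optimal when the relative shortfall exceeds a threshold
(default 5%) with one-sided t-test support across day replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

import lmfit

from growthlaw.model import InputFunction, ModelParams, closed_loop_state, mu_curve

__all__ = [
    "OCurve",
    "CLine",
    "OptimalityReport",
    "FitResult",
    "assemble_ocurve",
    "assemble_cline",
    "parabolic_max",
    "classify_optimality",
    "fit_cline_linear",
    "fit_model_global",
]


@dataclass
class OCurve:
    """Empirical O-curve for one carbon source.

    ``points`` holds one row per cAMP dose with day-replicate means and
    standard errors; ``per_day`` keeps the underlying day-level values
    so the maximum can be re-estimated per day for the t-test.
    """

    carbon_source: str
    points: pd.DataFrame            # camp_mM, crp_star, crp_star_se, mu, mu_se, n_days
    per_day: pd.DataFrame           # day, camp_mM, crp_star, mu
    endogenous: dict | None = None  # crp_star, crp_star_se, mu, mu_se, n_days
    endogenous_per_day: pd.DataFrame | None = None
    max_crp_star: float = math.nan
    max_mu: float = math.nan
    max_flags: tuple[str, ...] = ()


@dataclass
class CLine:
    """Empirical C-line: one (CRP*, mu) point per carbon source."""

    points: pd.DataFrame            # carbon_source, crp_star, crp_star_se, mu, mu_se, n_days
    excluded: list[str] = field(default_factory=list)


@dataclass
class OptimalityReport:
    """Is the endogenous operating point at the O-curve maximum?"""

    carbon_source: str
    gap: float                      # (mu_max - mu_endogenous) / mu_endogenous
    classification: str             # "optimal" | "sub-optimal"
    p_value: float | None
    n_days: int
    flags: tuple[str, ...] = ()


@dataclass
class FitResult:
    """Joint model fit to O-curves and C-line."""

    k1_ratio: float                 # k1 / k2
    kf_ratio: float                 # kf / k2
    scale: float                    # CRP* units per unit of model C
    gamma: float                    # rate unit (h^-1)
    beta: dict[str, float]          # per carbon source
    r2_ocurves: float
    r2_cline: float | None
    chisqr: float
    residuals: pd.DataFrame | None = None
    flags: tuple[str, ...] = ()


def _mean_se(values: np.ndarray) -> tuple[float, float | None, int]:
    v = np.asarray(values, dtype=float)
    n = len(v)
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / math.sqrt(n)) if n >= 2 else None
    return mean, se, n


def assemble_ocurve(phenotypes: pd.DataFrame, carbon_source: str, *,
                    open_loop_strain: str = "open_loop",
                    endogenous_strain: str = "wild_type") -> OCurve:
    """Build an O-curve from per-(condition, day) phenotype rows.

    ``phenotypes`` is the frame produced by
    :func:`growthlaw.pipeline.analyze_experiment`; open-loop rows (one
    per cAMP dose and day) are averaged over days into dose points with
    s.e. of the mean, ordered by CRP activity, and the maximum is
    interpolated by a parabolic fit through the best point and its two
    flanking neighbours.  Rows of the wild-type strain give the
    endogenous control point.
    """
    df = phenotypes[phenotypes["carbon_source"] == carbon_source]
    if "strain" in df.columns:
        ol = df[df["strain"] == open_loop_strain]
        endo = df[df["strain"] == endogenous_strain]
    else:
        ol, endo = df, df.iloc[0:0]
    if ol["camp_mM"].nunique() < 3:
        raise ValueError(
            f"{carbon_source}: need phenotypes for >= 3 cAMP doses, "
            f"got {ol['camp_mM'].nunique()}")

    rows = []
    for camp, sub in ol.groupby("camp_mM"):
        crp_m, crp_se, n = _mean_se(sub["crp_star"].to_numpy())
        mu_m, mu_se, _ = _mean_se(sub["mu"].to_numpy())
        rows.append({"camp_mM": camp, "crp_star": crp_m,
                     "crp_star_se": crp_se, "mu": mu_m, "mu_se": mu_se,
                     "n_days": n})
    points = pd.DataFrame(rows).sort_values("crp_star").reset_index(drop=True)

    endogenous = None
    endo_per_day = None
    if len(endo):
        crp_m, crp_se, n = _mean_se(endo["crp_star"].to_numpy())
        mu_m, mu_se, _ = _mean_se(endo["mu"].to_numpy())
        endogenous = {"crp_star": crp_m, "crp_star_se": crp_se,
                      "mu": mu_m, "mu_se": mu_se, "n_days": n}
        endo_per_day = endo[["day", "crp_star", "mu"]].reset_index(drop=True)

    (x_max, y_max), flags = parabolic_max(
        list(zip(points["crp_star"], points["mu"])))
    return OCurve(carbon_source=carbon_source, points=points,
                  per_day=ol[["day", "camp_mM", "crp_star", "mu"]].reset_index(drop=True),
                  endogenous=endogenous, endogenous_per_day=endo_per_day,
                  max_crp_star=x_max, max_mu=y_max, max_flags=flags)


def assemble_cline(phenotypes: pd.DataFrame, *,
                   strain: str = "wild_type",
                   exclude: list[str] | None = None) -> CLine:
    """Build the C-line from wild-type phenotypes across carbon sources."""
    df = phenotypes
    if "strain" in df.columns:
        df = df[df["strain"] == strain]
    rows = []
    for source, sub in df.groupby("carbon_source"):
        crp_m, crp_se, n = _mean_se(sub["crp_star"].to_numpy())
        mu_m, mu_se, _ = _mean_se(sub["mu"].to_numpy())
        rows.append({"carbon_source": source, "crp_star": crp_m,
                     "crp_star_se": crp_se, "mu": mu_m, "mu_se": mu_se,
                     "n_days": n})
    points = pd.DataFrame(rows).sort_values("mu").reset_index(drop=True)
    return CLine(points=points, excluded=list(exclude or []))


def parabolic_max(points: list[tuple[float, float]]
                  ) -> tuple[tuple[float, float], tuple[str, ...]]:
    """Interpolated maximum of an ordered (x, y) point set.

    The vertex of the parabola through the best point and its two
    flanking neighbours, exact for any true quadratic.  A best point at
    either end of the curve is returned unmodified with a ``boundary``
    flag; collinear triplets return the middle point with a
    ``degenerate`` flag.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a parabolic maximum")
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    if np.any(np.diff(xs) <= 0):
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
    tied = np.flatnonzero(ys == ys.max())
    i = int(tied[len(tied) // 2])   # middle of a tied (flat) run
    if i == 0 or i == len(xs) - 1:
        return (float(xs[i]), float(ys[i])), ("boundary",)
    x1, x2, x3 = xs[i - 1:i + 2]
    y1, y2, y3 = ys[i - 1:i + 2]
    s_left = (y2 - y1) / (x2 - x1)
    s_right = (y3 - y2) / (x3 - x2)
    a = (s_right - s_left) / (x3 - x1)          # quadratic coefficient
    if a == 0.0:
        return (float(x2), float(y2)), ("degenerate",)
    # vertex of y = y2 + b (x - x2) + a (x - x2)(x - x1)-style Newton form
    b = s_left + a * (x2 - x1)                  # dy/dx at x2
    x_v = x2 - b / (2.0 * a)
    y_v = y2 + b * (x_v - x2) + a * (x_v - x2) ** 2
    return (float(x_v), float(y_v)), ()


def classify_optimality(ocurve: OCurve, *, gap_threshold: float = 0.05,
                        alpha: float = 0.05) -> OptimalityReport:
    """Decide whether endogenous control is optimal on this source.

    The relative gap ``(mu_max - mu_endog)/mu_endog`` is computed from
    the day-averaged curve.  Statistical support comes from re-fitting
    the parabolic maximum on each day's own curve and a one-sided
    paired t-test of (mu_max_day - mu_endog_day) > 0 across days
    (Welch's unpaired one-sided test when the day sets do not match).
    Sub-optimal requires both gap > ``gap_threshold`` and
    p < ``alpha``.
    """
    if ocurve.endogenous is None:
        raise ValueError(f"{ocurve.carbon_source}: no endogenous control point")
    if not math.isfinite(ocurve.max_mu):
        raise ValueError(f"{ocurve.carbon_source}: O-curve maximum undefined")
    mu_endog = ocurve.endogenous["mu"]
    gap = (ocurve.max_mu - mu_endog) / mu_endog
    flags = list(ocurve.max_flags)

    # per-day parabolic maxima
    day_max: dict[int, float] = {}
    for day, sub in ocurve.per_day.groupby("day"):
        pts = list(zip(sub["crp_star"], sub["mu"]))
        if len(pts) < 3:
            continue
        (_, y), _ = parabolic_max(sorted(pts))
        day_max[int(day)] = y
    endo_by_day = {}
    if ocurve.endogenous_per_day is not None:
        endo_by_day = {int(r.day): float(r.mu)
                       for r in ocurve.endogenous_per_day.itertuples()}

    common = sorted(set(day_max) & set(endo_by_day))
    p_value: float | None = None
    n_days = len(common)
    if n_days >= 2:
        diffs = np.array([day_max[d] - endo_by_day[d] for d in common])
        if np.std(diffs, ddof=1) == 0:
            p_value = 0.0 if diffs.mean() > 0 else 1.0
            flags.append("zero_variance_diffs")
        else:
            p_value = float(stats.ttest_1samp(
                diffs, 0.0, alternative="greater").pvalue)
    elif day_max and endo_by_day:
        a = np.array(list(day_max.values()))
        b = np.array(list(endo_by_day.values()))
        n_days = min(len(a), len(b))
        if len(a) >= 2 and len(b) >= 2:
            p_value = float(stats.ttest_ind(
                a, b, equal_var=False, alternative="greater").pvalue)
            flags.append("welch_unpaired")
        else:
            flags.append("insufficient_replicates")
    else:
        flags.append("insufficient_replicates")

    sub_optimal = gap > gap_threshold and (p_value is not None
                                           and p_value < alpha)
    return OptimalityReport(
        carbon_source=ocurve.carbon_source, gap=float(gap),
        classification="sub-optimal" if sub_optimal else "optimal",
        p_value=p_value, n_days=n_days, flags=tuple(flags))


def fit_cline_linear(cline: CLine) -> tuple[float, float, float]:
    """Ordinary least-squares line through the C-line points.

    Regresses CRP* on growth rate (the growth-law orientation: CRP*
    declines roughly linearly as growth speeds up); sources in
    ``cline.excluded`` are left out.  Returns (slope, intercept, R^2).
    """
    pts = cline.points[~cline.points["carbon_source"].isin(cline.excluded)]
    if len(pts) < 3:
        raise ValueError("need >= 3 non-excluded points for a line fit")
    mu = pts["mu"].to_numpy()
    crp = pts["crp_star"].to_numpy()
    if np.ptp(mu) == 0:
        raise ValueError("degenerate spread in growth rate")
    res = stats.linregress(mu, crp)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


# ---------------------------------------------------------------------------
# global model fit
# ---------------------------------------------------------------------------

def _default_sigma(se: pd.Series) -> np.ndarray:
    """Inverse-variance weights where s.e. is available, else the mean s.e."""
    se = se.to_numpy(dtype=float)
    good = np.isfinite(se) & (se > 0)
    fallback = float(np.mean(se[good])) if good.any() else 1.0
    return np.where(good, se, fallback)


def fit_model_global(ocurves: list[OCurve], cline: CLine | None = None, *,
                     inputs: dict[str, InputFunction] | None = None,
                     n_starts: int = 20, seed: int = 0,
                     keep_residuals: bool = True) -> FitResult:
    """Fit the allocation model jointly to O-curves and the C-line.

    Shared free parameters: the half-constant ratios k1/k2 and kf/k2
    (k2 = 1 fixes the concentration unit), the measurement scale ``s``
    mapping model C to measured CRP* (reporter units are arbitrary),
    and the rate unit ``gamma`` (h^-1).  Each carbon source gets its
    own import rate ``beta``.  O-curve points contribute residuals of
    predicted mu at the measured CRP* (C = CRP*/s); C-line points
    contribute residuals on both coordinates of the closed-loop
    prediction.  Residuals are weighted by measurement s.e. where
    available.  Multi-start Levenberg-Marquardt (``n_starts`` seeded
    random restarts) with best-of reporting guards against local
    minima.  Goodness of fit is R^2 on growth rate, per dataset.
    """
    inputs = inputs or {}
    sources_o = [oc.carbon_source for oc in ocurves]
    sources_c = list(cline.points["carbon_source"]) if cline is not None else []
    cline_pts = (cline.points[~cline.points["carbon_source"]
                              .isin(cline.excluded)]
                 if cline is not None else None)
    sources_c = list(cline_pts["carbon_source"]) if cline_pts is not None else []
    all_sources = list(dict.fromkeys(sources_o + sources_c))

    # observation tables
    obs_o = []
    for oc in ocurves:
        pts = oc.points
        obs_o.append({
            "source": oc.carbon_source,
            "crp": pts["crp_star"].to_numpy(dtype=float),
            "mu": pts["mu"].to_numpy(dtype=float),
            "sig": _default_sigma(pts["mu_se"]),
        })
    if cline_pts is not None and len(cline_pts):
        c_mu = cline_pts["mu"].to_numpy(dtype=float)
        c_crp = cline_pts["crp_star"].to_numpy(dtype=float)
        c_sig_mu = _default_sigma(cline_pts["mu_se"])
        c_sig_crp = _default_sigma(cline_pts["crp_star_se"])
    else:
        c_mu = np.empty(0)

    mu_all = np.concatenate([o["mu"] for o in obs_o]) if obs_o else np.empty(0)
    crp_all = np.concatenate([o["crp"] for o in obs_o]) if obs_o else np.empty(0)
    mu_scale = float(np.max(mu_all)) if len(mu_all) else 1.0
    crp_scale0 = float(np.max(crp_all)) if len(crp_all) else 1.0

    def make_params(rng: np.random.Generator | None) -> lmfit.Parameters:
        p = lmfit.Parameters()
        jitter = (lambda: math.exp(rng.normal(0.0, 0.5))) if rng else (lambda: 1.0)
        p.add("k1_ratio", value=1.0 * jitter(), min=0.02, max=50.0)
        p.add("kf_ratio", value=1.0 * jitter(), min=0.02, max=50.0)
        p.add("scale", value=1.3 * crp_scale0 * jitter(),
              min=0.5 * crp_scale0, max=50.0 * crp_scale0)
        p.add("gamma", value=2.5 * mu_scale * jitter(),
              min=0.5 * mu_scale, max=100.0 * mu_scale)
        for src in all_sources:
            p.add(f"beta_{_safe(src)}", value=4.0 * mu_scale * jitter(),
                  min=1e-3, max=1e4)
        return p

    def model_params(v: dict, src: str) -> ModelParams:
        return ModelParams(beta=v[f"beta_{_safe(src)}"], gamma=v["gamma"],
                           k1=v["k1_ratio"], k2=1.0, kf=v["kf_ratio"],
                           input=inputs.get(src, InputFunction()))

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        s = v["scale"]
        out = []
        for o in obs_o:
            C = o["crp"] / s
            bad = C >= 1.0
            C_eval = np.clip(C, 0.0, 1.0 - 1e-9)
            mu_pred = mu_curve(model_params(v, o["source"]), C_eval)
            r = (mu_pred - o["mu"]) / o["sig"]
            # soft penalty for CRP* values the scale cannot accommodate
            r = np.where(bad, r + 1e3 * (C - 1.0 + 1e-9), r)
            out.append(r)
        if len(c_mu):
            for j, src in enumerate(sources_c):
                ss = closed_loop_state(model_params(v, src))
                out.append(np.array([
                    (ss.mu - c_mu[j]) / c_sig_mu[j],
                    (s * ss.C - c_crp[j]) / c_sig_crp[j],
                ]))
        return np.concatenate(out)

    rng_master = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        p0 = make_params(None if start == 0 else rng_master)
        try:
            res = lmfit.minimize(residuals, p0, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("global model fit failed to converge from any start")

    v = best.params.valuesdict()
    flags = []
    for name, par in best.params.items():
        if par.vary and par.value is not None:
            span = par.max - par.min
            if (par.value - par.min) < 1e-6 * span or \
               (par.max - par.value) < 1e-6 * span:
                flags.append(f"pinned:{name}")

    # R^2 on growth rate
    def r2(y, yhat):
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan

    resid_rows = []
    preds_o, obs_mu_o = [], []
    for o in obs_o:
        C = np.clip(o["crp"] / v["scale"], 0.0, 1.0 - 1e-9)
        mu_pred = mu_curve(model_params(v, o["source"]), C)
        preds_o.append(mu_pred)
        obs_mu_o.append(o["mu"])
        if keep_residuals:
            for c, m, mp in zip(o["crp"], o["mu"], mu_pred):
                resid_rows.append({"dataset": "ocurve", "source": o["source"],
                                   "crp_star": c, "mu_obs": m, "mu_pred": mp})
    r2_o = r2(np.concatenate(obs_mu_o), np.concatenate(preds_o))

    r2_c = None
    if len(c_mu):
        mu_pred_c = []
        for src in sources_c:
            ss = closed_loop_state(model_params(v, src))
            mu_pred_c.append(ss.mu)
            if keep_residuals:
                resid_rows.append({"dataset": "cline", "source": src,
                                   "crp_star": v["scale"] * ss.C,
                                   "mu_obs": c_mu[sources_c.index(src)],
                                   "mu_pred": ss.mu})
        r2_c = r2(c_mu, np.array(mu_pred_c))

    return FitResult(
        k1_ratio=float(v["k1_ratio"]), kf_ratio=float(v["kf_ratio"]),
        scale=float(v["scale"]), gamma=float(v["gamma"]),
        beta={src: float(v[f"beta_{_safe(src)}"]) for src in all_sources},
        r2_ocurves=float(r2_o), r2_cline=None if r2_c is None else float(r2_c),
        chisqr=float(best.chisqr),
        residuals=pd.DataFrame(resid_rows) if keep_residuals else None,
        flags=tuple(flags))


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)
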