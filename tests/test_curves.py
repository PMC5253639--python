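"""O-curve assembly, parabolic maxima, optimality calls, model fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from growthlaw.curves import (CLine, OCurve, assemble_cline, assemble_ocurve,
                              classify_optimality, fit_cline_linear,
                              fit_model_global, parabolic_max)
from growthlaw.model import (InputFunction, ModelParams, closed_loop_state,
                             model_ocurve, mu_curve)

# cAMP-dose -> C levels used to lay out synthetic curve tables (the
# saturating titration of the generator's dose-response)
C_DOSES = np.array([0.043, 0.081, 0.14, 0.238, 0.357, 0.473, 0.565,
                    0.625, 0.66])


# ---------------------------------------------------------------------------
# parabolic maximum
# ---------------------------------------------------------------------------

def test_parabolic_max_symmetric_triplet():
    (x, y), flags = parabolic_max([(1, 1), (2, 2), (3, 1)])
    assert (x, y) == (2.0, 2.0)
    assert flags == ()


def test_parabolic_max_terminal_best_point_flagged():
    (x, y), flags = parabolic_max([(0, 0), (1, 1), (2, 1.5)])
    assert (x, y) == (2.0, 1.5)
    assert flags == ("boundary",)


def test_parabolic_max_collinear_degenerate():
    (x, y), flags = parabolic_max([(0, 0), (1, 1), (2, 2), (3, 1), (4, 0)])
    # interior best has equal slopes on a symmetric tent only at the apex
    (x2, y2), flags2 = parabolic_max([(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)])
    assert flags2 == ("degenerate",)
    assert (x2, y2) == (1.0, 1.0)


@settings(derandomize=True, max_examples=50)
@given(a=st.floats(-5, -0.01), xv=st.floats(0.5, 2.5),
       yv=st.floats(0.1, 10), dx=st.floats(0.2, 1.0))
def test_parabolic_max_exact_on_true_quadratics(a, xv, yv, dx):
    xs = [xv - 1.5 * dx, xv - 0.4 * dx, xv + dx]
    pts = [(x, yv + a * (x - xv) ** 2) for x in xs]
    (x, y), flags = parabolic_max(sorted(pts))
    if flags == ():  # interior best point
        assert x == pytest.approx(xv, abs=1e-9 * max(1, abs(xv)))
        assert y == pytest.approx(yv, rel=1e-9)


def test_parabolic_max_near_model_optimum():
    p = ModelParams(beta=4.0)
    oc = model_ocurve(p)
    xs = np.array([oc.C_opt - 0.07, oc.C_opt + 0.01, oc.C_opt + 0.09])
    pts = list(zip(xs, mu_curve(p, xs)))
    (x, y), _ = parabolic_max(pts)
    assert x == pytest.approx(oc.C_opt, rel=0.02)
    assert y == pytest.approx(oc.mu_opt, rel=0.02)


# ---------------------------------------------------------------------------
# O-curve assembly
# ---------------------------------------------------------------------------

def _phenotype_table(mu_of_c, crp_scale=3.0, n_days=3, noise=0.0, seed=0,
                     endog=None, source="lactose"):
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, n_days + 1):
        for i, c in enumerate(C_DOSES):
            rows.append({"strain": "open_loop", "carbon_source": source,
                         "camp_mM": float(i), "perturbation": "", "day": day,
                         "mu": mu_of_c(c) * (1 + noise * rng.normal()),
                         "crp_star": crp_scale * c})
        if endog is not None:
            c_e, mu_e = endog
            rows.append({"strain": "wild_type", "carbon_source": source,
                         "camp_mM": 0.0, "perturbation": "", "day": day,
                         "mu": mu_e * (1 + noise * rng.normal()),
                         "crp_star": crp_scale * c_e})
    return pd.DataFrame(rows)


def test_assemble_ocurve_bookkeeping():
    p = ModelParams(beta=4.0, gamma=2.0)
    phen = _phenotype_table(lambda c: mu_curve(p, np.array([c]))[0])
    oc = assemble_ocurve(phen, "lactose")
    assert len(oc.points) == len(C_DOSES)
    assert (oc.points["n_days"] == 3).all()
    assert oc.points["crp_star"].is_monotonic_increasing
    # identical replicates -> zero s.e.
    assert np.allclose(oc.points["mu_se"], 0.0)


def test_assemble_ocurve_requires_three_doses():
    phen = _phenotype_table(lambda c: c)
    phen = phen[phen.camp_mM < 2]
    with pytest.raises(ValueError, match="3 cAMP doses"):
        assemble_ocurve(phen, "lactose")


def test_assemble_ocurve_se_tracks_injected_noise():
    p = ModelParams(beta=4.0, gamma=2.0)
    sigma = 0.05
    ses, mus = [], []
    for seed in range(20):
        phen = _phenotype_table(lambda c: mu_curve(p, np.array([c]))[0],
                                noise=sigma, seed=seed)
        oc = assemble_ocurve(phen, "lactose")
        ses.extend(oc.points["mu_se"] / oc.points["mu"])
    # s.e. of the mean of 3 replicates of c.v. sigma is sigma/sqrt(3)
    assert np.mean(ses) == pytest.approx(sigma / math.sqrt(3), rel=0.5)


# ---------------------------------------------------------------------------
# optimality classification
# ---------------------------------------------------------------------------

def _study_curve(gap, day_sigma=0.0, tech_sigma=0.0, seed=0, n_days=3):
    """Phenotypes whose true O-curve max exceeds the endogenous point by
    ``gap``, with shared per-day factors and per-point technical noise."""
    p = ModelParams(beta=4.0, gamma=2.0)
    rng = np.random.default_rng(seed)
    rows = []
    mu_endog = closed_loop_state(p).mu / (1 + gap)
    oc_ref = model_ocurve(p)
    for day in range(1, n_days + 1):
        f = math.exp(rng.normal(0, day_sigma)) if day_sigma else 1.0
        for i, c in enumerate(C_DOSES):
            mu = mu_curve(p, np.array([c]))[0] * (oc_ref.mu_opt and 1.0)
            mu *= f * (1 + tech_sigma * rng.normal())
            rows.append({"strain": "open_loop", "carbon_source": "s",
                         "camp_mM": float(i), "perturbation": "", "day": day,
                         "mu": mu, "crp_star": 3.0 * c})
        rows.append({"strain": "wild_type", "carbon_source": "s",
                     "camp_mM": 0.0, "perturbation": "", "day": day,
                     "mu": mu_endog * f * (1 + tech_sigma * rng.normal()),
                     "crp_star": 3.0 * closed_loop_state(p).C})
    return pd.DataFrame(rows)


def test_equal_max_and_endogenous_is_optimal():
    phen = _study_curve(gap=0.0)
    oc = assemble_ocurve(phen, "s")
    rep = classify_optimality(oc)
    assert rep.classification == "optimal"
    assert abs(rep.gap) < 0.01


def test_large_gap_is_suboptimal():
    phen = _study_curve(gap=0.5, day_sigma=0.04, tech_sigma=0.01, seed=5)
    rep = classify_optimality(assemble_ocurve(phen, "s"))
    assert rep.gap == pytest.approx(0.5, abs=0.1)
    assert rep.classification == "sub-optimal"
    assert rep.p_value < 0.003


def test_classification_scale_invariance():
    phen = _study_curve(gap=0.3, day_sigma=0.04, tech_sigma=0.01, seed=2)
    rep0 = classify_optimality(assemble_ocurve(phen, "s"))
    phen2 = phen.assign(mu=phen["mu"] * 7.3)
    rep1 = classify_optimality(assemble_ocurve(phen2, "s"))
    assert rep1.gap == pytest.approx(rep0.gap, rel=1e-9)
    assert rep1.classification == rep0.classification
    assert rep1.p_value == pytest.approx(rep0.p_value, rel=1e-6)


def test_single_day_classification_is_flagged():
    phen = _study_curve(gap=0.3, n_days=1)
    rep = classify_optimality(assemble_ocurve(phen, "s"))
    assert rep.p_value is None
    assert "insufficient_replicates" in rep.flags
    assert rep.classification == "optimal"  # no statistical support


def test_monte_carlo_power_thirty_percent_gap():
    """A 30% gap with 4% day noise over 3 days is detected (sub-optimal,
    p < 0.003) in at least 95% of simulations."""
    hits = 0
    n = 300
    for seed in range(n):
        phen = _study_curve(gap=0.3, day_sigma=0.04, tech_sigma=0.01,
                            seed=seed)
        rep = classify_optimality(assemble_ocurve(phen, "s"))
        hits += (rep.classification == "sub-optimal"
                 and rep.p_value < 0.003)
    assert hits / n >= 0.95


# ---------------------------------------------------------------------------
# C-line fits
# ---------------------------------------------------------------------------

def _cline_from_model(betas, noise=0.0, seed=0, outlier=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i, b in enumerate(betas):
        ss = closed_loop_state(ModelParams(beta=b, gamma=2.0))
        crp = 3.0 * ss.C
        name = f"src{i}"
        if outlier is not None and i == outlier:
            name = "outlier"
            crp += 1.0
        rows.append({"carbon_source": name,
                     "crp_star": crp * (1 + noise * rng.normal()),
                     "crp_star_se": noise * crp if noise else None,
                     "mu": ss.mu * (1 + noise * rng.normal()),
                     "mu_se": noise * ss.mu if noise else None, "n_days": 3})
    return CLine(points=pd.DataFrame(rows))


def test_collinear_points_give_perfect_line():
    pts = pd.DataFrame({
        "carbon_source": list("abcd"),
        "mu": [0.2, 0.4, 0.6, 0.8],
        "crp_star": [2.0, 1.6, 1.2, 0.8],
        "crp_star_se": [None] * 4, "mu_se": [None] * 4, "n_days": [3] * 4})
    slope, intercept, r2 = fit_cline_linear(CLine(points=pts))
    assert slope == pytest.approx(-2.0)
    assert intercept == pytest.approx(2.4)
    assert r2 == pytest.approx(1.0)


def test_model_cline_is_nearly_linear_with_noise():
    cline = _cline_from_model(np.geomspace(0.5, 20, 12), noise=0.02, seed=1)
    slope, _, r2 = fit_cline_linear(cline)
    assert slope < 0          # growth law: CRP* falls as growth quickens
    assert r2 > 0.9


def test_outlier_exclusion_improves_fit():
    cline = _cline_from_model(np.geomspace(0.5, 20, 10), noise=0.01,
                              seed=2, outlier=4)
    _, _, r2_with = fit_cline_linear(cline)
    cline.excluded = ["outlier"]
    _, _, r2_without = fit_cline_linear(cline)
    assert r2_without > r2_with


def test_cline_fit_needs_spread_and_points():
    pts = pd.DataFrame({"carbon_source": ["a", "b", "c"],
                        "mu": [0.5, 0.5, 0.5], "crp_star": [1, 2, 3],
                        "crp_star_se": [None] * 3, "mu_se": [None] * 3,
                        "n_days": [1] * 3})
    with pytest.raises(ValueError, match="degenerate"):
        fit_cline_linear(CLine(points=pts))


# ---------------------------------------------------------------------------
# global model fit
# ---------------------------------------------------------------------------

def _curve_tables(betas, gamma=2.0, k1=1.0, kf=1.0, scale=3.0, noise=0.0,
                  seed=0, inputs=None):
    rng = np.random.default_rng(seed)
    inputs = inputs or {}
    ocurves, rows = [], []
    for i, b in enumerate(betas):
        name = f"s{i}"
        p = ModelParams(beta=b, gamma=gamma, k1=k1, k2=1.0, kf=kf,
                        input=inputs.get(name, InputFunction()))
        mu = mu_curve(p, C_DOSES)
        mu_obs = mu * (1 + noise * rng.normal(size=len(mu)))
        pts = pd.DataFrame({
            "camp_mM": np.arange(len(C_DOSES), dtype=float),
            "crp_star": scale * C_DOSES, "crp_star_se": 0.01,
            "mu": mu_obs, "mu_se": np.maximum(noise * mu, 1e-6),
            "n_days": 3}).sort_values("crp_star").reset_index(drop=True)
        (xm, ym), fl = parabolic_max(list(zip(pts.crp_star, pts.mu)))
        ocurves.append(OCurve(name, pts, pts.assign(day=1), None, None,
                              xm, ym, fl))
        ss = closed_loop_state(p)
        rows.append({"carbon_source": name,
                     "crp_star": scale * ss.C * (1 + noise * rng.normal()),
                     "crp_star_se": max(noise * scale * ss.C, 1e-6),
                     "mu": ss.mu * (1 + noise * rng.normal()),
                     "mu_se": max(noise * ss.mu, 1e-6), "n_days": 3})
    return ocurves, CLine(points=pd.DataFrame(rows))


def test_noise_free_self_fit_is_essentially_perfect():
    ocurves, cline = _curve_tables([1.0, 4.0, 16.0])
    fit = fit_model_global(ocurves, cline, n_starts=4, seed=0)
    assert fit.r2_ocurves >= 0.999
    assert fit.r2_cline >= 0.999


def test_parameter_recovery_with_three_percent_noise():
    betas = np.geomspace(1, 50, 5)
    fit = None
    ocurves, cline = _curve_tables(betas, noise=0.03, seed=11)
    fit = fit_model_global(ocurves, cline, n_starts=6, seed=1)
    for i, b in enumerate(betas):
        assert fit.beta[f"s{i}"] == pytest.approx(b, rel=0.15)
    assert fit.k1_ratio == pytest.approx(1.0, abs=0.25)
    assert fit.kf_ratio == pytest.approx(1.0, abs=0.25)


def test_parameter_recovery_rate_across_replicates():
    """The recovery bounds hold in >= 90% of seeded replicates."""
    betas = np.geomspace(1, 50, 5)
    ok = 0
    n = 25
    for rep in range(n):
        ocurves, cline = _curve_tables(betas, noise=0.03, seed=100 + rep)
        fit = fit_model_global(ocurves, cline, n_starts=4, seed=rep)
        good = all(abs(fit.beta[f"s{i}"] / b - 1) < 0.15
                   for i, b in enumerate(betas))
        good &= abs(fit.k1_ratio - 1) < 0.25 and abs(fit.kf_ratio - 1) < 0.25
        ok += good
    assert ok / n >= 0.9


def test_fit_independent_of_row_order():
    ocurves, cline = _curve_tables([2.0, 8.0], noise=0.02, seed=3)
    fit0 = fit_model_global(ocurves, cline, n_starts=3, seed=0)
    # shuffle the dose rows of each O-curve; assembly order must not matter
    shuffled = []
    for oc in ocurves:
        pts = oc.points.sample(frac=1.0, random_state=1)
        pts = pts.sort_values("crp_star").reset_index(drop=True)
        shuffled.append(OCurve(oc.carbon_source, pts, oc.per_day, None, None,
                               oc.max_crp_star, oc.max_mu, oc.max_flags))
    fit1 = fit_model_global(shuffled, cline, n_starts=3, seed=0)
    assert fit1.chisqr == pytest.approx(fit0.chisqr, rel=1e-9)
    for k in fit0.beta:
        assert fit1.beta[k] == pytest.approx(fit0.beta[k], rel=1e-6)
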