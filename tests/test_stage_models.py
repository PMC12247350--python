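"""Zero-inflated beta and Gaussian mixed models for stage comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from trackfidelity.stage_models import (STAGE_ORDER, fit_gaussian_mixed,
                                        fit_zib_mixed, zib_negloglik, _design)


def simulate_overlap(rng, n_birds, p_zero, beta_mean, phi=20.0, sd_bird=0.0,
                     stages=STAGE_ORDER, n_years=2):
    rows = []
    b = rng.normal(0, sd_bird, n_birds)
    for i in range(n_birds):
        for s in stages:
            for _ in range(n_years):
                pz = special.expit(special.logit(p_zero[s]) + b[i])
                if rng.random() < pz:
                    y = 0.0
                else:
                    mu = special.expit(special.logit(beta_mean[s]) + b[i])
                    y = rng.beta(mu * phi, (1 - mu) * phi)
                rows.append({"bird_id": f"b{i}", "stage": s, "overlap_prop": y,
                             "min_center_dist_km": np.nan})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def zib_fit():
    rng = np.random.default_rng(0)
    p_zero = {"breeding": 0.7, "south_migration": 0.7,
              "wintering": 0.1, "north_migration": 0.9}
    beta_mean = {"breeding": 0.2, "south_migration": 0.2,
                 "wintering": 0.5, "north_migration": 0.1}
    df = simulate_overlap(rng, 100, p_zero, beta_mean, sd_bird=0.3)
    return fit_zib_mixed(df), p_zero, beta_mean


def test_zib_recovers_stage_probabilities_and_means(zib_fit):
    fit, p_zero, beta_mean = zib_fit
    summary = fit.extra["stage_summary"].set_index("stage")
    for s in STAGE_ORDER:
        assert abs(summary.loc[s, "p_zero"] - p_zero[s]) < 0.1
        assert abs(summary.loc[s, "beta_mean"] - beta_mean[s]) < 0.1


def test_zib_wintering_contrasts_significant(zib_fit):
    fit, _, _ = zib_fit
    coef = fit.coef.set_index("term")
    # wintering has far lower zero-inflation and higher conditional mean
    assert coef.loc["zi_stage[wintering]", "estimate"] < 0
    assert coef.loc["zi_stage[wintering]", "p"] < 0.01
    assert coef.loc["cond_stage[wintering]", "estimate"] > 0
    assert coef.loc["cond_stage[wintering]", "p"] < 0.01


def test_zib_loglik_decomposes_without_random_effect():
    """With sd_b ~ 0 the joint likelihood equals the sum of an independent
    Bernoulli part and a beta part."""
    rng = np.random.default_rng(1)
    df = simulate_overlap(rng, 40, {s: 0.4 for s in STAGE_ORDER},
                          {s: 0.3 for s in STAGE_ORDER}, sd_bird=0.0)
    y = df["overlap_prop"].to_numpy()
    X, _ = _design(df["stage"], STAGE_ORDER)
    birds, idx = np.unique(df["bird_id"], return_inverse=True)
    theta = np.zeros(2 * len(STAGE_ORDER) + 2)
    theta[0] = special.logit(0.4)
    theta[len(STAGE_ORDER)] = special.logit(0.3)
    phi = 20.0
    theta[-2] = np.log(phi)
    theta[-1] = np.log(1e-8)           # variance ~ 0
    ll = -zib_negloglik(theta, y, X, idx, len(birds))
    is_zero = y == 0
    bern = np.sum(np.log(np.where(is_zero, 0.4, 0.6)))
    nz = y[~is_zero]
    a, b = 0.3 * phi, 0.7 * phi
    beta_ll = np.sum(stats.beta.logpdf(nz, a, b))
    assert ll == pytest.approx(bern + beta_ll, abs=1e-4)


def test_zib_quadrature_node_count_stable():
    rng = np.random.default_rng(2)
    df = simulate_overlap(rng, 30, {s: 0.5 for s in STAGE_ORDER},
                          {s: 0.3 for s in STAGE_ORDER}, sd_bird=0.4)
    f20 = fit_zib_mixed(df, n_nodes=20)
    y = df["overlap_prop"].to_numpy()
    y = np.where(y >= 1.0, 1.0 - 1e-6, y)
    X, _ = _design(df["stage"], f20.extra["stage_order"])
    birds, idx = np.unique(df["bird_id"], return_inverse=True)
    theta = np.concatenate([
        f20.coef["estimate"].to_numpy()[:-2],
        [np.log(f20.extra["phi"]), 0.5 * np.log(f20.sigma2_id)]])
    ll20 = -zib_negloglik(theta, y, X, idx, len(birds), n_nodes=20)
    ll40 = -zib_negloglik(theta, y, X, idx, len(birds), n_nodes=40)
    assert abs(ll20 - ll40) < 1e-4


def test_zib_relabelling_stages_permutes_coefficients():
    rng = np.random.default_rng(3)
    p_zero = {"breeding": 0.6, "south_migration": 0.3,
              "wintering": 0.15, "north_migration": 0.8}
    beta_mean = {"breeding": 0.25, "south_migration": 0.35,
                 "wintering": 0.5, "north_migration": 0.15}
    df = simulate_overlap(rng, 60, p_zero, beta_mean, sd_bird=0.2)
    fit1 = fit_zib_mixed(df, stage_order=STAGE_ORDER)
    order2 = [STAGE_ORDER[0]] + STAGE_ORDER[:0:-1]
    fit2 = fit_zib_mixed(df, stage_order=order2)
    s1 = fit1.extra["stage_summary"].set_index("stage")
    s2 = fit2.extra["stage_summary"].set_index("stage")
    for s in STAGE_ORDER:
        assert s1.loc[s, "p_zero"] == pytest.approx(s2.loc[s, "p_zero"], abs=5e-3)


def test_zib_rejects_out_of_range_response():
    df = pd.DataFrame({"bird_id": ["a", "b"], "stage": ["breeding", "wintering"],
                       "overlap_prop": [0.5, 1.2]})
    with pytest.raises(ValueError):
        fit_zib_mixed(df)


def test_zib_exact_ones_shrunk_and_counted():
    rng = np.random.default_rng(4)
    df = simulate_overlap(rng, 30, {s: 0.3 for s in STAGE_ORDER},
                          {s: 0.5 for s in STAGE_ORDER}, sd_bird=0.2)
    df.loc[df.index[:3], "overlap_prop"] = 1.0
    fit = fit_zib_mixed(df)
    assert fit.extra["n_shrunk_ones"] == 3


def simulate_distance(rng, n_birds, means, sd_bird=5.0, sd_res=10.0, n_years=2):
    rows = []
    b = rng.normal(0, sd_bird, n_birds)
    for i in range(n_birds):
        for s, m in means.items():
            for _ in range(n_years):
                rows.append({"bird_id": f"b{i}", "stage": s,
                             "min_center_dist_km": m + b[i] + rng.normal(0, sd_res)})
    return pd.DataFrame(rows)


def test_gaussian_wintering_contrast_negative_and_significant():
    rng = np.random.default_rng(5)
    means = {"breeding": 160.0, "south_migration": 200.0,
             "wintering": 10.0, "north_migration": 250.0}
    df = simulate_distance(rng, 100, means)
    fit = fit_gaussian_mixed(df)
    coef = fit.coef.set_index("term")
    assert coef.loc["stage[wintering]", "estimate"] < -100
    assert coef.loc["stage[wintering]", "p"] < 1e-6


def test_gaussian_identical_distances_give_zero_contrasts():
    df = pd.DataFrame({
        "bird_id": np.repeat([f"b{i}" for i in range(10)], 4),
        "stage": STAGE_ORDER * 10,
        "min_center_dist_km": 50.0})
    fit = fit_gaussian_mixed(df)
    contrasts = fit.coef[fit.coef["term"] != "intercept"]["estimate"]
    np.testing.assert_allclose(contrasts, 0.0, atol=1e-8)


def test_gaussian_matches_balanced_decomposition():
    """On a balanced design, the REML bird variance equals the closed-form
    two-way estimate from bird-level means."""
    rng = np.random.default_rng(6)
    means = {s: 100.0 for s in STAGE_ORDER}
    df = simulate_distance(rng, 40, means, sd_bird=8.0, sd_res=5.0, n_years=1)
    fit = fit_gaussian_mixed(df)
    wide = df.pivot_table(index="bird_id", columns="stage",
                          values="min_center_dist_km")
    k = wide.shape[1]
    msb = k * wide.mean(axis=1).var(ddof=1)
    msw = float(fit.extra["sigma2_res"])
    assert fit.sigma2_id == pytest.approx((msb - msw) / k, rel=1e-4, abs=1e-4)
    assert fit.converged


def test_gaussian_rejects_nonfinite():
    df = pd.DataFrame({"bird_id": ["a", "a"], "stage": ["breeding", "wintering"],
                       "min_center_dist_km": [1.0, np.inf]})
    with pytest.raises(ValueError):
        fit_gaussian_mixed(df)
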