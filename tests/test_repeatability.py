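"""Random-intercept variance components, bootstrap CIs, LRT and FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from trackfidelity.repeatability import (band_repeatability_profile,
                                         event_repeatability, fdr_adjust,
                                         fit_random_intercept, lrt_sigma_id,
                                         repeatability)


def simulate(rng, n_ind, n_rep, s_id, s_res, mu=100.0):
    ids = np.repeat(np.arange(n_ind), n_rep)
    y = mu + rng.normal(0, s_id, n_ind)[ids] + rng.normal(0, s_res, len(ids))
    return y, ids


def test_reml_matches_balanced_anova_closed_form():
    rng = np.random.default_rng(1)
    y, ids = simulate(rng, 25, 4, 2.0, 1.0)
    fit = fit_random_intercept(y, ids)
    df = pd.DataFrame({"y": y, "g": ids})
    msw = df.groupby("g")["y"].var(ddof=1).mean()
    msb = 4 * df.groupby("g")["y"].mean().var(ddof=1)
    assert fit.sigma2_res == pytest.approx(msw, abs=1e-6)
    assert fit.sigma2_id == pytest.approx((msb - msw) / 4, abs=1e-6)


def test_reml_matches_mixedlm_on_unbalanced_data():
    rng = np.random.default_rng(2)
    ids = np.concatenate([np.repeat(np.arange(15), 3), np.repeat(np.arange(15, 30), 2)])
    y = rng.normal(0, 1.5, 30)[ids] + rng.normal(0, 1.0, len(ids))
    fit = fit_random_intercept(y, ids)
    m = sm.MixedLM(y, np.ones((len(y), 1)), groups=ids).fit(reml=True)
    assert fit.sigma2_id == pytest.approx(float(np.asarray(m.cov_re)[0, 0]), abs=1e-3)
    assert fit.sigma2_res == pytest.approx(float(m.scale), abs=1e-3)


def test_monte_carlo_recovery_large_balanced_design():
    rng = np.random.default_rng(3)
    y, ids = simulate(rng, 200, 5, 2.0, 1.0)
    fit = fit_random_intercept(y, ids)
    assert abs(fit.sigma2_id - 4.0) / 4.0 < 0.15
    assert abs(fit.sigma2_res - 1.0) < 0.15


def test_constant_within_individual_gives_R_one():
    ids = np.repeat(np.arange(5), 3)
    y = np.array([10.0, 10, 10, 20, 20, 20, 30, 30, 30, 40, 40, 40, 50, 50, 50])
    fit = fit_random_intercept(y, ids)
    assert fit.repeatability == pytest.approx(1.0)
    assert fit.sigma2_res == 0.0


def test_permuted_ids_estimate_near_boundary():
    rng = np.random.default_rng(4)
    y, ids = simulate(rng, 40, 3, 3.0, 1.0)
    ids_perm = rng.permutation(ids)
    fit = fit_random_intercept(y, ids_perm)
    total = fit.sigma2_id + fit.sigma2_res
    assert fit.sigma2_id / total < 0.15


def test_singleton_only_design_rejected():
    with pytest.raises(ValueError, match="inestimable|single"):
        fit_random_intercept(np.arange(5.0), np.arange(5))
    with pytest.raises(ValueError, match="2 individuals"):
        fit_random_intercept(np.array([1.0, 2.0]), np.array([0, 0]))


def test_R_invariant_to_affine_transform():
    rng = np.random.default_rng(5)
    y, ids = simulate(rng, 30, 3, 2.0, 1.0)
    r1 = fit_random_intercept(y, ids).repeatability
    r2 = fit_random_intercept(3.5 * y - 200.0, ids).repeatability
    assert r1 == pytest.approx(r2, abs=1e-6)


def test_duplicating_every_bird_preserves_point_estimate():
    rng = np.random.default_rng(6)
    y, ids = simulate(rng, 20, 3, 2.0, 1.0)
    y2 = np.concatenate([y, y])
    ids2 = np.concatenate([ids, ids + 1000])
    r1 = fit_random_intercept(y, ids).repeatability
    r2 = fit_random_intercept(y2, ids2).repeatability
    # exact for ML; REML's degrees-of-freedom correction shifts it by O(1/n)
    assert r1 == pytest.approx(r2, abs=0.01)


def test_repeatability_reproducible_and_ci_ordering():
    rng = np.random.default_rng(7)
    y, ids = simulate(rng, 30, 3, np.sqrt(0.6), np.sqrt(0.4))
    e1 = repeatability(y, ids, n_boot=500, seed=1)
    e2 = repeatability(y, ids, n_boot=500, seed=1)
    assert (e1.R, e1.ci_low, e1.ci_high) == (e2.R, e2.ci_low, e2.ci_high)
    assert e1.ci_low <= e1.ci_high
    assert 0.0 <= e1.R <= 1.0


def test_no_bootstrap_gives_point_estimate_only():
    rng = np.random.default_rng(8)
    y, ids = simulate(rng, 10, 3, 1.0, 1.0)
    est = repeatability(y, ids, n_boot=0)
    assert est.ci_low is None and est.ci_high is None


def test_ci_width_shrinks_with_more_individuals():
    widths = []
    for n_ind in (10, 30, 100):
        rng = np.random.default_rng(100 + n_ind)
        y, ids = simulate(rng, n_ind, 3, np.sqrt(0.6), np.sqrt(0.4))
        e = repeatability(y, ids, n_boot=500, seed=n_ind)
        widths.append(e.ci_high - e.ci_low)
    assert widths[0] > widths[2]


def test_strong_signal_has_small_lrt_p():
    rng = np.random.default_rng(9)
    y, ids = simulate(rng, 40, 4, 3.0, 1.0)
    assert lrt_sigma_id(y, ids) < 1e-6


def test_fdr_adjust_hand_computed_step_up():
    adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
    assert fdr_adjust([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
    raw = np.array([0.001, 0.3, 0.04, 0.9])
    adj = fdr_adjust(raw)
    assert (adj >= raw - 1e-12).all()
    order = np.argsort(raw)
    assert (np.diff(adj[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        fdr_adjust([-0.1])


def band_frame(rng, n_ind, n_years, bands, sd_between, sd_within):
    rows = []
    for b in bands:
        icpt = rng.normal(0, sd_between(b), n_ind)
        for i in range(n_ind):
            for y in range(n_years):
                rows.append({"bird_id": f"b{i}", "cycle_year": 2019 + y,
                             "direction": "south", "band_low_lat": b,
                             "kind": "entry_date",
                             "value": 200.0 + icpt[i] + rng.normal(0, sd_within(b))})
    return pd.DataFrame(rows)


def test_band_profile_rises_where_between_variance_dominates():
    """Latitude-dependent variance structure: strong individual signal at low
    (wintering-side) bands, none at high (breeding-side) bands."""
    rng = np.random.default_rng(10)
    obs = band_frame(rng, 25, 4, bands=range(15, 60, 5),
                     sd_between=lambda b: 10.0 if b < 35 else 0.5,
                     sd_within=lambda b: 3.0 if b < 35 else 8.0)
    prof = band_repeatability_profile(obs, kind="entry_date", direction="south",
                                      n_boot=0, seed=0)
    low = prof[prof["band_low_lat"] < 35]["R"].mean()
    high = prof[prof["band_low_lat"] >= 35]["R"].mean()
    assert low > 0.8 and high < 0.3
    assert "p_fdr" in prof.columns and (prof["p_fdr"] >= prof["p_lrt"] - 1e-12).all()


def test_band_profile_skips_single_individual_bands():
    rng = np.random.default_rng(11)
    obs = band_frame(rng, 3, 3, bands=[40], sd_between=lambda b: 5.0,
                     sd_within=lambda b: 2.0)
    solo = pd.DataFrame([{"bird_id": "only", "cycle_year": 2019, "direction": "south",
                          "band_low_lat": 41, "kind": "entry_date", "value": 100.0}])
    prof = band_repeatability_profile(pd.concat([obs, solo]), kind="entry_date",
                                      direction="south", n_boot=0)
    assert list(prof["band_low_lat"]) == [40]


def test_event_repeatability_table_shape():
    rng = np.random.default_rng(12)
    rows = []
    for var, sb in [("wintering_arrival", 12.0), ("breeding_departure", 2.0)]:
        icpt = rng.normal(0, sb, 15)
        for i in range(15):
            for y in range(3):
                rows.append({"bird_id": f"b{i}", "cycle_year": 2019 + y,
                             "variable": var, "value": icpt[i] + rng.normal(0, 4.0)})
    out = event_repeatability(pd.DataFrame(rows), n_boot=0, seed=0)
    out = out.set_index("variable")
    assert out.loc["wintering_arrival", "R"] > out.loc["breeding_departure", "R"]
    assert (out["n_ind"] == 15).all()
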