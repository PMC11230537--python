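"""Knapp-Hartung engine: tau2 estimators, pooling, heterogeneity, meta-regression."""
import json
import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from motivmeta.effects import EffectEstimate
from motivmeta.meta import (
    heterogeneity,
    meta_regression_kh,
    pool_random_kh,
    significance,
    subgroup_analysis,
    tau2_dl,
    tau2_pm,
    tau2_reml,
    forest_data,
)
from motivmeta.simulate import simulate_meta_effects

from _oracles import (
    heterogeneity_oracle,
    kh_pool_oracle,
    reml_grid_oracle,
    reml_loglik,
    tau2_dl_oracle,
)


def make_effects(yi, vi):
    return [
        EffectEstimate(study_id=f"s{i}", yi=float(y), vi=float(v), measure="smd")
        for i, (y, v) in enumerate(zip(yi, vi))
    ]


def test_tau2_dl_toy_hand_value():
    yi, vi = [0.1, 0.5, 0.9], [0.04] * 3
    assert tau2_dl(make_effects(yi, vi)) == pytest.approx(tau2_dl_oracle(yi, vi), abs=1e-12)
    # hand evaluation: equal weights 25; Q = 25 * 0.32 = 8; c = 75 - 1875/75 = 50
    assert tau2_dl(make_effects(yi, vi)) == pytest.approx((8 - 2) / 50)


def test_tau2_identical_effects_zero_and_truncation():
    effects = make_effects([0.3] * 5, [0.02] * 5)
    assert tau2_dl(effects) == 0.0
    assert tau2_reml(effects) == 0.0
    assert tau2_pm(effects) == 0.0
    # Q below its expectation truncates to exactly 0
    rng = np.random.default_rng(5)
    yi = 0.2 + rng.normal(0, 0.01, size=6)
    effects = make_effects(yi, [0.5] * 6)
    assert tau2_dl(effects) == 0.0


def test_reml_matches_grid_oracle():
    yi = [0.05, 0.42, 0.21, 0.65, -0.1]
    vi = [0.03, 0.07, 0.02, 0.09, 0.05]
    ours = tau2_reml(make_effects(yi, vi))
    grid = reml_grid_oracle(yi, vi, upper=1.0)
    assert ours == pytest.approx(grid, abs=1e-4)
    # our estimate sits at (or above) the oracle's restricted likelihood
    assert reml_loglik(ours, yi, vi) >= reml_loglik(grid, yi, vi) - 1e-8


def test_reml_consistency_at_large_k():
    effects = simulate_meta_effects(200, mu=0.3, tau2=0.05, vi_range=(0.01, 0.03), seed=11)
    assert tau2_reml(effects) == pytest.approx(0.05, abs=0.015)
    assert tau2_dl(effects) == pytest.approx(0.05, abs=0.02)
    assert tau2_pm(effects) == pytest.approx(0.05, abs=0.02)


def test_pool_kh_matches_brute_force(rng):
    for _ in range(25):
        k = int(rng.integers(3, 13))
        yi = rng.normal(0.2, 0.4, size=k)
        vi = rng.uniform(0.01, 0.2, size=k)
        effects = make_effects(yi, vi)
        res = pool_random_kh(effects, tau2_method="DL")
        t2 = tau2_dl_oracle(list(yi), list(vi))
        mu, se, ci, p = kh_pool_oracle(list(yi), list(vi), t2)
        assert res.mu_hat == pytest.approx(mu, abs=1e-10)
        assert res.se_kh == pytest.approx(se, abs=1e-10)
        assert res.ci == pytest.approx(ci, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        q, qp, i2 = heterogeneity_oracle(list(yi), list(vi))
        assert res.Q == pytest.approx(q, abs=1e-10)
        assert res.I2 == pytest.approx(i2, abs=1e-10)


def test_pool_bounds_and_order_invariance(rng):
    yi = rng.normal(size=8)
    vi = rng.uniform(0.01, 0.1, size=8)
    res = pool_random_kh(make_effects(yi, vi))
    assert yi.min() <= res.mu_hat <= yi.max()
    perm = rng.permutation(8)
    res2 = pool_random_kh(make_effects(yi[perm], vi[perm]))
    assert res2.mu_hat == pytest.approx(res.mu_hat, abs=1e-12)


def test_tau2_zero_forced_recovers_fixed_effect(rng):
    yi = rng.normal(size=6)
    vi = rng.uniform(0.01, 0.1, size=6)
    res = pool_random_kh(make_effects(yi, vi), tau2_override=0.0)
    fe = np.sum(yi / vi) / np.sum(1 / vi)
    assert res.mu_hat == pytest.approx(fe, abs=1e-12)


def test_k2_uses_t1_quantile():
    effects = make_effects([0.2, 0.6], [0.04, 0.04])
    res = pool_random_kh(effects, tau2_method="DL")
    half_width = (res.ci[1] - res.ci[0]) / 2
    assert half_width == pytest.approx(12.706204736174698 * res.se_kh, rel=1e-12)
    wald_half = 1.959963984540054 * res.se_kh
    assert half_width > 6 * wald_half


def test_single_study_degenerate_path():
    res = pool_random_kh(make_effects([0.4], [0.04]))
    assert res.k == 1
    assert math.isnan(res.tau2) and math.isnan(res.Q) and math.isnan(res.I2)
    assert res.ci == pytest.approx((0.4 - 1.959963984540054 * 0.2, 0.4 + 1.959963984540054 * 0.2))


def test_two_identical_studies_trivial():
    res = pool_random_kh(make_effects([0.3, 0.3], [0.05, 0.05]), tau2_method="DL")
    assert res.mu_hat == pytest.approx(0.3)
    assert res.Q == pytest.approx(0.0)
    assert res.I2 == 0.0


def test_heterogeneity_at_printed_threshold():
    # Q = 10 with k = 6 gives I2 = 0.5, exactly the substantial cut-off
    assert max(0.0, (10 - 5) / 10) == 0.5
    effects = make_effects([0.0, 1.0], [0.1, 0.1])
    het = heterogeneity(effects)
    q, qp, i2 = heterogeneity_oracle([0.0, 1.0], [0.1, 0.1])
    assert het["Q"] == pytest.approx(q, abs=1e-12)
    assert het["I2"] == pytest.approx(i2, abs=1e-12)
    assert math.isnan(heterogeneity(make_effects([0.1], [0.1]))["Q"])


def test_subgroup_equals_per_level_pooling(rng):
    effects = simulate_meta_effects(12, mu=0.2, tau2=0.02, seed=3)
    labels = ["high"] * 5 + ["moderate"] * 4 + ["low"] * 3
    sub = subgroup_analysis(effects, labels)
    for level, members in (("high", effects[:5]), ("moderate", effects[5:9]), ("low", effects[9:])):
        solo = pool_random_kh(members)
        assert sub[level].mu_hat == pytest.approx(solo.mu_hat, abs=1e-12)
        assert sub[level].se_kh == pytest.approx(solo.se_kh, abs=1e-12)
    empty = subgroup_analysis(effects[:5], ["high"] * 5)
    assert empty["low"] is None and empty["moderate"] is None
    with pytest.raises(ValueError, match="unknown"):
        subgroup_analysis(effects[:2], ["high", "extreme"])


def test_metareg_two_level_fixed_effect_identity(rng):
    """With tau2 forced to 0 the contrast equals the difference of the
    levels' fixed-effect inverse-variance means."""
    yi = rng.normal(0.3, 0.2, size=10)
    vi = rng.uniform(0.02, 0.1, size=10)
    labels = ["high"] * 6 + ["low"] * 4
    effects = make_effects(yi, vi)
    reg = meta_regression_kh(effects, labels, tau2_override=0.0)
    w = 1 / vi
    mean_high = np.sum(w[:6] * yi[:6]) / np.sum(w[:6])
    mean_low = np.sum(w[6:] * yi[6:]) / np.sum(w[6:])
    contrast = reg.coefficients.set_index("term").loc["low_vs_high", "beta"]
    assert contrast == pytest.approx(mean_low - mean_high, abs=1e-10)
    assert reg.coefficients.set_index("term").loc["intercept", "beta"] == pytest.approx(
        mean_high, abs=1e-10
    )


def test_metareg_reference_level_invariance(rng):
    effects = simulate_meta_effects(15, mu=0.2, tau2=0.03, seed=8)
    labels = ["high"] * 6 + ["moderate"] * 5 + ["low"] * 4
    p_ref_high = meta_regression_kh(effects, labels, reference_level="high")
    p_ref_low = meta_regression_kh(effects, labels, reference_level="low")
    assert p_ref_high.omnibus_p == pytest.approx(p_ref_low.omnibus_p, abs=1e-10)
    assert p_ref_high.omnibus_stat == pytest.approx(p_ref_low.omnibus_stat, abs=1e-10)
    # relabeling levels leaves the omnibus test unchanged
    relabeled = ["moderate" if l == "high" else "high" if l == "moderate" else l for l in labels]
    p_relabel = meta_regression_kh(effects, relabeled)
    assert p_relabel.omnibus_p == pytest.approx(p_ref_high.omnibus_p, abs=1e-10)


def test_metareg_degenerate_inputs():
    effects = simulate_meta_effects(6, mu=0.1, tau2=0.01, seed=2)
    with pytest.raises(ValueError):
        meta_regression_kh(effects, ["high"] * 6)
    reg = meta_regression_kh(effects, ["high", "high", "low", "low", "high", "low"])
    assert reg.dropped_levels == ["moderate"]
    assert reg.omnibus_df == (1, 4)


@pytest.mark.parametrize("p,expected", [(0.045, True), (0.110, False), (0.05, False)])
def test_significance_threshold(p, expected):
    assert significance(p) is expected


def test_forest_data_structure(rng):
    effects = simulate_meta_effects(5, mu=0.2, tau2=0.02, seed=4)
    pooled = pool_random_kh(effects)
    df = forest_data(effects, pooled)
    assert list(df["study_id"])[-1] == "POOLED"
    assert df["weight"].iloc[:-1].sum() == pytest.approx(1.0)
    assert df["yi"].iloc[-1] == pytest.approx(pooled.mu_hat)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_kh_reml_against_metafor(tmp_path):
    """External cross-check: pooled KH result and residual-REML meta-regression
    against the metafor package on one fixed dataset."""
    effects = simulate_meta_effects(10, mu=0.3, tau2=0.04, seed=21)
    labels = ["high"] * 4 + ["moderate"] * 3 + ["low"] * 3
    yi = ", ".join(f"{e.yi!r}" for e in effects)
    vi = ", ".join(f"{e.vi!r}" for e in effects)
    mods = ", ".join(f"'{l}'" for l in labels)
    script = tmp_path / "check.R"
    script.write_text(f"""
suppressMessages(library(metafor))
yi <- c({yi}); vi <- c({vi})
mods <- factor(c({mods}), levels=c('high','moderate','low'))
fit <- rma(yi, vi, method='REML', test='knha')
reg <- rma(yi, vi, mods=~mods, method='REML', test='knha')
cat(jsonlite::toJSON(list(mu=fit$beta[1], se=fit$se, tau2=fit$tau2,
    ci=c(fit$ci.lb, fit$ci.ub), Q=fit$QE, I2=fit$I2,
    omnibus_F=reg$QM, omnibus_p=reg$QMp, tau2_res=reg$tau2), digits=12))
""")
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    res = pool_random_kh(effects, tau2_method="REML")
    assert res.mu_hat == pytest.approx(ref["mu"][0], abs=1e-6)
    assert res.se_kh == pytest.approx(ref["se"][0], abs=1e-6)
    assert res.tau2 == pytest.approx(ref["tau2"][0], abs=1e-6)
    assert res.ci[0] == pytest.approx(ref["ci"][0], abs=1e-6)
    assert res.ci[1] == pytest.approx(ref["ci"][1], abs=1e-6)
    # metafor's I2 is model-based (tau2 over tau2 + typical v), so compare Q only
    assert res.Q == pytest.approx(ref["Q"][0], abs=1e-6)
    # residual-REML convergence criteria differ slightly between implementations
    reg = meta_regression_kh(effects, labels, tau2_method="REML")
    assert reg.tau2_residual == pytest.approx(ref["tau2_res"][0], abs=1e-5)
    assert reg.omnibus_stat == pytest.approx(ref["omnibus_F"][0], rel=1e-5)
    assert reg.omnibus_p == pytest.approx(ref["omnibus_p"][0], rel=1e-5)
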