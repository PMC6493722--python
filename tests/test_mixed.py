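"""Mixed models, BH-FDR, kappa and diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screamkit.mixed import (
    BinomialMixedModel,
    LinearMixedModel,
    PrunePolicy,
    bh_adjust,
    cohen_kappa,
    diagnose_and_prune,
    fit_effect_model,
    run_all_models,
    support_model,
)
from screamkit.synth import StudyConfig, simulate_study


def _lmm_data(rng, n=200, nc=10, ne=25, beta=(1.0, 0.5, -0.3, 0.2), tau_c=0.7, tau_e=0.5, sigma=1.0):
    caller = rng.integers(nc, size=n)
    event = rng.integers(ne, size=n)
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    u = rng.normal(0, tau_c, nc)
    v = rng.normal(0, tau_e, ne)
    y = X @ np.asarray(beta) + u[caller] + v[event] + rng.normal(0, sigma, n)
    return y, X, {"caller": caller, "event": event}


def test_reml_fit_matches_statsmodels_mixedlm(rng):
    import statsmodels.formula.api as smf

    y, X, groups = _lmm_data(rng)
    ours = LinearMixedModel().fit(y, X, groups)
    df = pd.DataFrame(
        {"y": y, "x1": X[:, 1], "x2": X[:, 2],
         "caller": groups["caller"], "event": groups["event"], "g": 1}
    )
    ref = smf.mixedlm(
        "y ~ x1*x2", df, groups="g",
        vc_formula={"caller": "0+C(caller)", "event": "0+C(event)"},
    ).fit(reml=True)
    np.testing.assert_allclose(ours.beta_, ref.fe_params.values, rtol=1e-3, atol=1e-4)
    np.testing.assert_allclose(ours.se_, ref.bse_fe.values, rtol=2e-2)
    np.testing.assert_allclose(ours.sigma2_, ref.scale, rtol=1e-3)
    np.testing.assert_allclose(
        sorted(ours.varcomps_.values()), sorted(ref.vcomp), rtol=1e-2, atol=1e-3
    )


def test_zero_random_variance_gives_equal_r2(rng):
    y, X, groups = _lmm_data(rng, tau_c=0.0, tau_e=0.0)
    m = LinearMixedModel().fit(y, X, groups)
    assert m.r2_conditional_ - m.r2_marginal_ < 0.03
    assert all(v < 0.15 * m.sigma2_ for v in m.varcomps_.values())


def test_wald_ci_covers_true_effect(rng):
    covered = 0
    reps = 120
    for _ in range(reps):
        y, X, groups = _lmm_data(rng, n=120, nc=8, ne=15)
        m = LinearMixedModel().fit(y, X, groups)
        w = m.wald()
        covered += w["ci_low"][1] <= 0.5 <= w["ci_high"][1]
    assert 0.88 <= covered / reps <= 0.99


def test_type_one_error_is_calibrated_under_the_null(rng):
    rejections = 0
    reps = 500
    for _ in range(reps):
        y, X, groups = _lmm_data(rng, n=120, nc=10, ne=15, beta=(1.0, 0.0, 0.3, 0.0))
        m = LinearMixedModel().fit(y, X, groups)
        rejections += m.wald()["p"][1] < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_binomial_glmm_recovers_signs_and_scale(rng):
    n, nc = 400, 26
    caller = rng.integers(nc, size=n)
    role = rng.integers(0, 2, n).astype(float)
    u = rng.normal(0, 0.5, nc)
    eta = -0.4 - 1.9 * role + u[caller]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    m = BinomialMixedModel().fit(y, np.column_stack([np.ones(n), role]), {"caller": caller})
    assert m.beta_[1] < 0
    assert abs(m.beta_[1] + 1.9) < 3 * m.se_[1]


def test_bh_examples_and_oracle(rng):
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        ours = bh_adjust(p)
        # brute-force step-up
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            brute[i] = prev
        np.testing.assert_allclose(ours, brute, atol=1e-12)
        np.testing.assert_allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.2])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_is_order_preserving_and_bounded(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_kappa_identical_and_formula_and_renaming():
    a = ["x", "y", "x", "y", "x"]
    assert cohen_kappa(a, a).kappa == pytest.approx(1.0)

    # 2x2 confusion ((20, 5), (5, 20)): po = 0.8, pe = 0.5, kappa = 0.6
    coder_a = ["p"] * 25 + ["q"] * 25
    coder_b = ["p"] * 20 + ["q"] * 5 + ["p"] * 5 + ["q"] * 20
    res = cohen_kappa(coder_a, coder_b)
    assert res.observed_agreement == pytest.approx(0.8)
    assert res.expected_agreement == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.6)

    from sklearn.metrics import cohen_kappa_score

    assert res.kappa == pytest.approx(cohen_kappa_score(coder_a, coder_b))

    renamed = {"p": "AA", "q": "BB"}
    res2 = cohen_kappa([renamed[v] for v in coder_a], [renamed[v] for v in coder_b])
    assert res2.kappa == pytest.approx(res.kappa)


def test_kappa_chance_agreement_is_near_zero(rng):
    ks = []
    for _ in range(50):
        a = rng.integers(0, 3, 300)
        b = rng.integers(0, 3, 300)
        ks.append(cohen_kappa(a, b).kappa)
    assert abs(np.mean(ks)) < 0.03


def test_kappa_undefined_for_single_shared_category():
    res = cohen_kappa(["a"] * 10, ["a"] * 10)
    assert not res.defined


def test_tolerance_quantization_feeds_kappa():
    from screamkit.mixed import quantize_for_kappa

    a = [10.0, 12.4, 30.0, 45.2]
    b = [10.3, 12.0, 29.8, 44.9]  # all within the 1 s tolerance
    res = cohen_kappa(quantize_for_kappa(a, 1.0), quantize_for_kappa(b, 1.0))
    assert res.observed_agreement == 1.0
    with pytest.raises(ValueError):
        quantize_for_kappa(a, 0.0)


def _study_tables(seed=31):
    study = simulate_study(dataclasses.replace(StudyConfig(), seed=seed), render_audio=False)
    gt = study.ground_truth
    ann = study.annotations
    df = ann.merge(gt[["scream_id", "duration", "noise_mix"]], on="scream_id")
    return df


def test_effect_model_recovers_role_effect_on_duration():
    df = _study_tables()
    rows, model = fit_effect_model(df, "duration")
    role = next(r for r in rows if r.effect == "role[victim]")
    assert role.estimate > 0
    assert role.p < 0.001
    assert role.ci_low <= role.estimate <= role.ci_high
    assert 0 <= model.r2_marginal_ <= model.r2_conditional_ <= 1


def test_run_all_models_yields_36_adjusted_p_values(default_tables):
    call, bout = default_tables
    ledger = run_all_models(call, bout)
    ok = ledger.dropna(subset=["p"])
    assert len(ok) == 36
    assert (ok["p_adjusted"] >= ok["p"] - 1e-12).all()
    assert set(ok["effect"]) == {
        "role[victim]", "severity[severe]", "role[victim]:severity[severe]"
    }
    assert ok["response"].nunique() == 12


def test_support_model_matches_configured_probabilities():
    df = _study_tables(seed=77).drop_duplicates("bout_id")
    rows, model = support_model(df)
    effects = {r.effect: r for r in rows}
    assert effects["role[victim]"].estimate < 0  # victims get less support
    assert model.r2_marginal_ <= model.r2_conditional_ <= 1


def test_outlier_diagnostics_flag_injected_point():
    df = _study_tables(seed=13)
    df = df.copy()
    clean, log = diagnose_and_prune(df, "duration", PrunePolicy(resid_threshold=4.0))
    assert log["removed_outliers"] == 0 and log["removed_callers"] == []
    assert log["n_outliers_flagged"] == 0

    spiked = df.reset_index(drop=True).copy()
    spiked.loc[10, "duration"] = spiked["duration"].mean() + 15 * spiked["duration"].std()
    cleaned, log = diagnose_and_prune(
        spiked, "duration", PrunePolicy(remove_outliers=True, resid_threshold=4.0)
    )
    assert log["removed_outliers"] >= 1
    assert 10 in log["outlier_rows"]
    assert len(cleaned) <= len(spiked) - 1
    assert "estimates_after" in log


def test_report_is_structural_and_deterministic(default_tables):
    from screamkit.report import build_report, render_markdown, to_json

    call, bout = default_tables
    ledger = run_all_models(call, bout)
    sup, _ = support_model(bout)
    kappa = cohen_kappa(["a", "b"] * 10, ["a", "b"] * 10)
    rep = build_report(
        effect_ledger=ledger, support_effects=sup,
        kappa={"severity": kappa.kappa}, seed=11,
    )
    md1 = render_markdown(rep)
    md2 = render_markdown(build_report(
        effect_ledger=ledger, support_effects=sup,
        kappa={"severity": kappa.kappa}, seed=11,
    ))
    assert md1 == md2
    assert "Fixed-effect ledger" in md1 and "Support model" in md1
    assert "role[victim]" in md1
    empty = render_markdown(build_report())
    assert "absent" in empty
    to_json(rep)  # must serialize without error
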