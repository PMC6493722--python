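"""Discriminant machinery: filters, Fisher axes, subsets, permutation engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screamkit.dfa import (
    CorrelationFilter,
    DFADesign,
    DesignInfeasibleError,
    FisherDiscriminant,
    SymmetrizingScaler,
    balanced_subsets,
    jackknife_classify,
    run_pdfa,
)
from screamkit.features import CALL_FEATURES


def test_correlation_filter_drops_duplicates_and_logs(rng):
    x = rng.standard_normal((100, 3))
    X = np.column_stack([x, x[:, 0]])  # duplicated column, r = 1
    f = CorrelationFilter(0.8).fit(X)
    assert len(f.retained_) == 3
    assert len(f.dropped_) == 1
    dropped, kept, r = f.dropped_[0]
    assert {dropped, kept} <= {0, 3}
    assert abs(r) == pytest.approx(1.0)


def test_correlation_filter_removes_one_of_a_correlated_pair(rng):
    a = rng.standard_normal(500)
    b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(500)  # r ~ 0.9
    c = rng.standard_normal(500)
    f = CorrelationFilter(0.8).fit(np.column_stack([a, b, c]))
    assert len(f.retained_) == 2
    assert 2 in f.retained_


def test_correlation_filter_keeps_independent_columns(rng):
    X = rng.standard_normal((200, 5))
    f = CorrelationFilter(0.8).fit(X)
    assert list(f.retained_) == [0, 1, 2, 3, 4]
    assert f.dropped_ == []


def test_scaler_standardizes_and_reduces_skew(rng):
    X = np.column_stack(
        [rng.standard_normal(400), np.exp(rng.standard_normal(400))]  # symmetric, log-normal
    )
    sc = SymmetrizingScaler().fit(X)
    Z = sc.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)
    assert sc.transforms_[0] == "identity"
    assert sc.transforms_[1] in ("log", "sqrt")
    assert abs(stats.skew(Z[:, 1])) < abs(stats.skew(X[:, 1]))


def test_fisher_separates_well_separated_clouds(rng):
    X = np.vstack([rng.normal(0, 0.3, (40, 4)), rng.normal(5, 0.3, (40, 4))])
    y = np.array([0] * 40 + [1] * 40)
    clf = FisherDiscriminant().fit(X, y)
    assert (clf.predict(X) == y).mean() == 1.0


def test_fisher_is_at_chance_for_identical_distributions(rng):
    accs = []
    for _ in range(30):
        X = rng.standard_normal((120, 4))
        y = np.tile([0, 1, 2], 40)  # all classes present in both halves
        clf = FisherDiscriminant().fit(X[:60], y[:60])
        accs.append((clf.predict(X[60:]) == y[60:]).mean())
    assert abs(np.mean(accs) - 1 / 3) < 0.06


def test_fisher_matches_whitened_nearest_centroid_oracle(rng):
    """On two-class problems the Fisher rule equals nearest centroid in
    within-class-whitened space; check label-for-label on 100 instances."""
    from scipy import linalg

    for _ in range(100):
        n, p = 30, 3
        X = rng.standard_normal((n, p)) + np.repeat(rng.normal(0, 2, (2, p)), n // 2, axis=0)
        y = np.repeat([0, 1], n // 2)
        clf = FisherDiscriminant().fit(X, y)
        got = clf.predict(X)

        means = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
        Sw = sum(
            (X[y == k] - means[k]).T @ (X[y == k] - means[k]) for k in (0, 1)
        ) + 1e-8 * np.trace(np.eye(p)) * np.eye(p)
        W = linalg.inv(linalg.cholesky(Sw, lower=True))
        Xw = X @ W.T
        mw = means @ W.T
        d2 = ((Xw[:, None, :] - mw[None]) ** 2).sum(axis=2)
        oracle = np.argmin(d2, axis=1)
        assert (got == oracle).all()


def test_fisher_handles_singular_scatter_with_ridge(rng):
    X = np.zeros((20, 3))
    X[:, 0] = np.repeat([0.0, 1.0], 10)  # two constant columns -> singular Sw
    y = np.repeat([0, 1], 10)
    clf = FisherDiscriminant().fit(X, y)
    assert (clf.predict(X) == y).all()


def test_jackknife_cross_validation_equals_classification_on_same_points(rng):
    X = np.vstack([rng.normal(0, 0.2, (20, 3)), rng.normal(4, 0.2, (20, 3))])
    y = np.repeat([0, 1], 20)
    train = np.arange(40)
    cls, cv = jackknife_classify(X, y, train, holdout_idx=train)
    assert cls == cv == 100.0


def test_jackknife_is_at_chance_with_permuted_labels(rng):
    X = rng.standard_normal((200, 5))
    y = rng.permutation(np.repeat([0, 1], 100))
    cvs = []
    for _ in range(20):
        train = rng.choice(200, 100, replace=False)
        cvs.append(jackknife_classify(X, y, train)[1])
    assert abs(np.mean(cvs) - 50.0) < 8.0


def _crossed_table(rng, n_ind=4, per_cell=5):
    rows = []
    for i in range(n_ind):
        for role in ("aggressor", "victim"):
            for sev in ("mild", "severe"):
                for _ in range(per_cell):
                    rows.append({"caller_id": f"i{i}", "role": role, "severity": sev})
    t = pd.DataFrame(rows)
    for c in CALL_FEATURES:
        t[c] = rng.standard_normal(len(t))
    return t


def test_balanced_subsets_draw_equal_cell_counts(rng):
    table = _crossed_table(rng, n_ind=4, per_cell=5)
    design = DFADesign(test_factor="caller_id", control_factor=["role", "severity"])
    train, info = balanced_subsets(table, design, rng)
    sub = table.iloc[train]
    counts = sub.groupby(["caller_id", "role", "severity"]).size()
    assert counts.nunique() == 1  # equal training counts per individual x cell
    assert counts.iloc[0] == round(0.5 * 5)
    # a holdout remains in every cell
    assert len(train) < len(table)


def test_balanced_design_infeasible_raises(rng):
    table = _crossed_table(rng, n_ind=2, per_cell=2)
    table = table[~((table.caller_id == "i0") & (table.severity == "severe"))]
    table = table[~((table.caller_id == "i1") & (table.role == "victim"))]
    design = DFADesign(test_factor="caller_id", control_factor=["role", "severity"])
    with pytest.raises(DesignInfeasibleError):
        balanced_subsets(table.reset_index(drop=True), design, rng)


def test_individual_missing_a_cell_is_excluded(rng):
    table = _crossed_table(rng, n_ind=4, per_cell=4)
    table = table[~((table.caller_id == "i3") & (table.severity == "severe"))].reset_index(drop=True)
    design = DFADesign(test_factor="caller_id", control_factor=["role", "severity"])
    train, info = balanced_subsets(table, design, rng)
    assert "i3" not in set(table.iloc[train]["caller_id"])
    assert len(info["levels"]) == 3


def test_plain_mode_draws_half_of_each_level(rng):
    table = _crossed_table(rng, n_ind=3, per_cell=5)
    design = DFADesign(test_factor="caller_id", mode="plain", train_fraction=0.5)
    train, _ = balanced_subsets(table, design, rng)
    sub = table.iloc[train]
    for _, n in sub.groupby("caller_id").size().items():
        assert n == 10  # half of 20


def test_pdfa_is_deterministic_given_seed(rng):
    table = _crossed_table(rng, n_ind=4, per_cell=6)
    # add a weak signature so the result is non-trivial
    sig = {f"i{k}": rng.normal(0, 1, len(CALL_FEATURES)) for k in range(4)}
    for c_i, c in enumerate(CALL_FEATURES):
        table[c] += table["caller_id"].map(lambda i: sig[i][c_i])
    design = DFADesign(
        test_factor="caller_id", control_factor=["role", "severity"],
        n_resamples=5, n_permutations=50, seed=123,
    )
    r1 = run_pdfa(table, CALL_FEATURES, design)
    r2 = run_pdfa(table, CALL_FEATURES, design)
    assert r1.as_dict() == r2.as_dict()
    assert r1.permutation_trace == r2.permutation_trace


def test_pdfa_null_run_is_not_significant(rng):
    table = _crossed_table(rng, n_ind=4, per_cell=8)
    design = DFADesign(
        test_factor="caller_id", control_factor=["role", "severity"],
        n_resamples=10, n_permutations=100, seed=5,
    )
    res = run_pdfa(table, CALL_FEATURES, design)
    assert res.p_crossvalidation > 0.01
    assert abs(res.expected_crossvalidation - 25.0) < 8.0  # chance, 4 balanced classes


def test_reduced_replication_preserves_identity_recovery(default_tables):
    call, _ = default_tables
    design = DFADesign(
        test_factor="caller_id", control_factor=["role", "severity"],
        mode="balanced_crossed", n_resamples=20, n_permutations=200, seed=17,
    )
    res = run_pdfa(call, CALL_FEATURES, design)
    assert res.observed_crossvalidation > res.expected_crossvalidation + 5
    assert res.p_crossvalidation <= 0.02
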