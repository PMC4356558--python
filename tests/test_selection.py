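import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from respsig import (
    SimConfig,
    anova_filter,
    backward_eliminate,
    bh_fdr,
    generate,
    kld_error,
    loocv_decision_values,
    train_linear_svm,
)
from respsig.io import labels_from_sheet
from respsig.selection import AnovaGeneFilter, f_oneway_two_class
from respsig.svm import SignatureSVM

from conftest import make_sheet


# ---------------------------------------------------------------- bh_fdr


def brute_force_bh(p):
    """Step-up rule applied literally: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * n / j for j in range(rank_pos, n + 1)), 1.0
        )
    return q


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_fdr_examples(p, expected):
    assert bh_fdr(p) == pytest.approx(expected)


def test_bh_fdr_empty():
    assert bh_fdr([]).size == 0


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_fdr_matches_brute_force(p):
    assert bh_fdr(p) == pytest.approx(brute_force_bh(p), abs=1e-12)


# ---------------------------------------------------------------- ANOVA filter


def test_f_equals_t_squared():
    """For two groups the one-way F is the square of the pooled-variance t."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(size=(5, 8))
        b = rng.normal(size=(7, 8))
        X = np.vstack([a, b])
        y = np.array([1] * 5 + [-1] * 7)
        F, p = f_oneway_two_class(X, y)
        t = stats.ttest_ind(a, b, axis=0, equal_var=True)
        assert F == pytest.approx(t.statistic**2, abs=1e-10)
        assert p == pytest.approx(t.pvalue, abs=1e-10)


def test_constant_gene_ranks_last():
    x = pd.DataFrame(
        [[5.0, 5.0, 5.0, 5.0], [1.0, 1.1, 2.0, 2.1], [0.2, 0.1, 0.2, 0.3]],
        index=["CONST", "SIG", "N1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    sheet = make_sheet(2, 2)
    sheet["sample_id"] = ["s1", "s2", "s3", "s4"]
    table = anova_filter(x, sheet, K=1)
    assert table.loc["CONST", "p_value"] == 1.0
    assert table.loc["CONST", "rank"] == 3
    assert table.loc["SIG", "selected"]


def test_filter_selects_k_smallest_and_is_gene_order_invariant(small_cohort):
    x, sheet, _ = small_cohort
    t1 = anova_filter(x, sheet, K=20)
    shuffled = x.sample(frac=1.0, random_state=1)
    t2 = anova_filter(shuffled, sheet, K=20)
    assert set(t1.index[t1["selected"]]) == set(t2.index[t2["selected"]])
    sel_p = t1.loc[t1["selected"], "p_value"]
    unsel_p = t1.loc[~t1["selected"], "p_value"]
    assert sel_p.max() <= unsel_p.min() + 1e-15
    assert sorted(t1["rank"]) == list(range(1, len(x.index) + 1))
    assert (t1["q_value"] >= t1["p_value"] - 1e-15).all()


def test_filter_recovers_signal_genes():
    cfg = SimConfig(seed=2)  # defaults: 2000 genes, 50 signal, effect 1.5
    x, sheet, truth = generate(cfg)
    table = anova_filter(x, sheet, K=100)
    selected = set(table.index[table["selected"]])
    assert len(selected & set(truth.signal_gene_ids)) >= 45


# ---------------------------------------------------------------- KLD error


def test_kld_confident_correct_is_zero():
    d = np.array([50.0, 50.0, -50.0])
    y = np.array([1, 1, -1])
    assert kld_error(d, y) < 1e-12


def test_kld_uninformative_is_ln2():
    assert kld_error(np.zeros(5), np.array([1, 1, -1, -1, 1])) == pytest.approx(
        np.log(2)
    )


def test_kld_direct_evaluation():
    val = kld_error(np.array([1.0, -1.0]), np.array([1, -1]))
    assert val == pytest.approx(-np.log(1 / (1 + np.exp(-1))))  # ~0.3133


def test_kld_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        kld_error([1.0], [1, -1])


# ---------------------------------------------------------------- linear SVM


def test_max_margin_toy_decision_values():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1, 1])
    model = SignatureSVM(C=1e6).fit(X, y)
    d = model.decision_function(X)
    assert d[0] < 0 < d[1]
    assert abs(d) == pytest.approx([1.0, 1.0], abs=1e-6)


def test_duplicating_samples_leaves_hyperplane_unchanged():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(2, 1, (10, 3)), rng.normal(-2, 1, (10, 3))])
    y = np.array([1] * 10 + [-1] * 10)
    m1 = SignatureSVM(C=100.0).fit(X, y)
    m2 = SignatureSVM(C=100.0).fit(np.vstack([X, X]), np.concatenate([y, y]))
    assert m1.coef_ == pytest.approx(m2.coef_, abs=1e-8)
    assert m1.intercept_ == pytest.approx(m2.intercept_, abs=1e-8)


def test_separable_training_error_zero(small_cohort):
    x, sheet, truth = small_cohort
    model = train_linear_svm(x, sheet, truth.signal_gene_ids, C=100.0)
    y = labels_from_sheet(sheet.set_index("sample_id").loc[list(x.columns)])
    pred = model.predict(x.loc[truth.signal_gene_ids].to_numpy().T)
    assert (pred == y).all()


def test_single_class_rejected():
    with pytest.raises(ValueError, match="single class"):
        SignatureSVM().fit(np.zeros((3, 2)), np.array([1, 1, 1]))


# ---------------------------------------------------------------- LOOCV


def test_loocv_separated_points_correctly_signed():
    X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
    y = np.array([-1, -1, 1, 1])
    d = loocv_decision_values(X, y, C=10.0)
    assert (np.sign(d) == y).all()


def test_loocv_extreme_outlier_misclassified():
    X = np.array([[-2.0], [-1.8], [-2.2], [1.8], [2.2], [-30.0]])
    y = np.array([-1, -1, -1, 1, 1, 1])  # last positive sits deep in negatives
    d = loocv_decision_values(X, y, C=10.0)
    assert d[-1] < 0


def test_loocv_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(1, 1, (6, 4)), rng.normal(-1, 1, (6, 4))])
    y = np.array([1] * 6 + [-1] * 6)
    d = loocv_decision_values(X, y)
    perm = rng.permutation(12)
    d_perm = loocv_decision_values(X[perm], y[perm])
    assert d_perm == pytest.approx(d[perm], abs=1e-5)


def test_loocv_single_class_fold_aborts():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1, -1, -1])
    with pytest.raises(ValueError, match="single-class"):
        loocv_decision_values(X, y)


# ---------------------------------------------------------------- elimination


def be_cohort(seed):
    cfg = SimConfig(n_genes=50, n_signal_genes=5, effect_size_mean=2.0,
                    noise_sd=0.3, n_resp_compounds=5, n_nonresp_compounds=10,
                    replicates_per_compound=3, n_vehicle_replicates=3, seed=seed)
    return generate(cfg)


def test_single_candidate_base_case(small_cohort):
    x, sheet, truth = small_cohort
    elim = backward_eliminate(x, sheet, [truth.signal_gene_ids[0]])
    assert elim.signature_ == [truth.signal_gene_ids[0]]


def test_trace_bookkeeping_and_selected_minimum():
    x, sheet, truth = be_cohort(0)
    elim = backward_eliminate(x, sheet, list(x.index))
    trace = elim.trace_
    assert trace["n_removed"].iloc[0] == 0
    assert trace["n_removed"].iloc[-1] == len(x.index) - 1
    assert np.isfinite(trace["kld_error"]).all()
    sel = trace.loc[elim.selection_step_]
    assert sel["kld_error"] <= trace["kld_error"].iloc[0]
    assert len(elim.signature_) == len(x.index) - sel["n_removed"]


def test_elimination_reproducible_bit_for_bit():
    x, sheet, _ = be_cohort(1)
    e1 = backward_eliminate(x, sheet, list(x.index))
    e2 = backward_eliminate(x, sheet, list(x.index))
    pd.testing.assert_frame_equal(e1.trace_, e2.trace_)
    assert e1.signature_ == e2.signature_


def test_elimination_retains_signal_genes():
    x, sheet, truth = be_cohort(11)
    elim = backward_eliminate(x, sheet, list(x.index))
    assert len(set(elim.signature_) & set(truth.signal_gene_ids)) >= 4


def test_chunked_elimination_geometry():
    """step=5/eval_every=5 still ends at one gene with a complete trace."""
    x, sheet, _ = be_cohort(2)
    candidates = list(x.index)[:23]
    elim = backward_eliminate(x, sheet, candidates, step=5, eval_every=5)
    assert elim.trace_["n_removed"].iloc[-1] == 22
    assert len(elim.signature_) == 23 - elim.trace_.loc[elim.selection_step_, "n_removed"]


def test_global_min_rule_exposed():
    x, sheet, _ = be_cohort(3)
    elim = backward_eliminate(x, sheet, list(x.index)[:20], selection_rule="global_min")
    assert (
        elim.trace_.loc[elim.selection_step_, "kld_error"]
        == elim.trace_["kld_error"].min()
    )


def test_anova_filter_estimator_transform_roundtrip(small_cohort):
    x, sheet, _ = small_cohort
    y = labels_from_sheet(sheet.set_index("sample_id").loc[list(x.columns)])
    flt = AnovaGeneFilter(K=15).fit(x.to_numpy().T, y, feature_names=list(x.index))
    reduced = flt.transform(x.to_numpy().T)
    assert reduced.shape == (x.shape[1], 15)
    assert flt.get_support().sum() == 15
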