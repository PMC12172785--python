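"""Group inference: conversion, t-tests, contrast coding, REML fitter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from faceconn.hlm import (DEFAULT_CODING, ContrastCoding, HLMError,
                          RandomInterceptHLM, convert_self_connections,
                          fit_hlm, revised_model, study_t_tests)


def test_self_connection_conversion_analytic_cases():
    assert convert_self_connections(0.0) == -0.5
    assert convert_self_connections(np.log(2.0)) == pytest.approx(-1.0)
    assert convert_self_connections(-np.log(2.0)) == pytest.approx(-0.25)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=-20, max_value=20),
       st.floats(min_value=-20, max_value=20))
def test_conversion_negative_and_monotone_decreasing(x1, x2):
    y1, y2 = convert_self_connections(x1), convert_self_connections(x2)
    assert y1 < 0 and y2 < 0
    if x2 - x1 > 1e-9:
        assert y1 > y2


def test_contrast_codes_exact_values():
    c = DEFAULT_CODING
    assert c.avsb == {"A": 0.5, "B": -0.5, "C": 0.0, "D": 0.0}
    assert c.abvsc == {"A": 0.25, "B": 0.25, "C": -0.5, "D": 0.0}
    assert c.abcvsd["A"] == pytest.approx(1 / 6)
    assert c.abcvsd["D"] == -0.5
    assert c.mvsp == {"mid-luteal": 0.5, "early-follicular": -0.5, "none": 0.0}
    # zero-sum against the contrasted level
    assert sum(c.abcvsd.values()) == pytest.approx(0.0)
    assert sum(c.abvsc.values()) == pytest.approx(0.0)


def test_contrast_columns_orthogonal_on_balanced_cohort():
    studies = np.repeat(["A", "B", "C", "D"], 10)
    cols = {name: np.array([m[s] for s in studies])
            for name, m in DEFAULT_CODING.study_columns().items()}
    names = list(cols)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            assert cols[names[i]] @ cols[names[j]] == pytest.approx(0.0, abs=1e-12)
        assert cols[names[i]].sum() == pytest.approx(0.0, abs=1e-12)


def _table(values, study, participant, hormone="none", matrix="B:faces",
           source="OFA", target="FFA", session=1):
    n = len(values)
    as_list = lambda x: [x] * n if np.isscalar(x) or isinstance(x, str) else list(x)
    return pd.DataFrame(dict(matrix=as_list(matrix), source=as_list(source),
                             target=as_list(target), value=values,
                             study=as_list(study), participant=as_list(participant),
                             session=as_list(session), hormone=as_list(hormone)))


def test_t_test_hand_computed_oracle():
    tab = _table([0.1, 0.2, 0.3], "A", ["p1", "p2", "p3"])
    rep = study_t_tests(tab, alpha=0.05)
    row = rep.iloc[0]
    assert row["t"] == pytest.approx(2 * np.sqrt(3), rel=1e-12)
    assert row["p"] == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2), rel=1e-12)
    assert row["n_tests"] == 1
    assert row["threshold"] == pytest.approx(0.05)


def test_bonferroni_threshold_six_connections():
    rows = []
    conns = [("OFA", "FFA"), ("OFA", "STS"), ("FFA", "OFA"),
             ("FFA", "STS"), ("STS", "OFA"), ("STS", "FFA")]
    rng = np.random.default_rng(0)
    for src, tgt in conns:
        rows.append(_table(rng.normal(0, 1, 8), "A",
                           [f"p{i}" for i in range(8)], source=src, target=tgt))
    rep = study_t_tests(pd.concat(rows, ignore_index=True), alpha=0.05)
    assert (rep["n_tests"] == 6).all()
    assert rep["threshold"].iloc[0] == pytest.approx(0.05 / 6)
    # flagging equals brute-force comparison
    np.testing.assert_array_equal(rep["significant"], rep["p"] < 0.05 / 6)


def test_t_test_zero_variance_flagged_not_nan():
    tab = _table([0.9] * 20, "A", [f"p{i}" for i in range(20)])
    rep = study_t_tests(tab)
    row = rep.iloc[0]
    assert row["degenerate"]
    assert row["p"] == 0.0 and row["significant"]
    tab0 = _table([0.0] * 20, "A", [f"p{i}" for i in range(20)])
    assert study_t_tests(tab0).iloc[0]["p"] == 1.0


def test_t_tests_split_hormone_study_by_session():
    t1 = _table([0.1, 0.2, 0.3], "C", ["p1", "p2", "p3"],
                hormone="mid-luteal", session=1)
    t2 = _table([0.4, 0.5, 0.6], "C", ["p1", "p2", "p3"],
                hormone="early-follicular", session=2)
    rep = study_t_tests(pd.concat([t1, t2], ignore_index=True))
    assert sorted(rep["group"]) == ["C1", "C2"]


def test_self_connections_excluded_from_tests():
    tab = pd.concat([_table([0.1, 0.2, 0.3], "A", ["p1", "p2", "p3"]),
                     _table([-0.5, -0.5, -0.5], "A", ["p1", "p2", "p3"],
                            matrix="A", source="OFA", target="OFA")],
                    ignore_index=True)
    rep = study_t_tests(tab)
    assert len(rep) == 1
    assert rep.iloc[0]["source"] != rep.iloc[0]["target"]


# -- the REML fitter -------------------------------------------------------

def test_constant_response_degenerate():
    tab = _table([0.7] * 12, ["A"] * 6 + ["B"] * 6,
                 [f"p{i // 2}" for i in range(12)])
    fit = fit_hlm(tab)
    assert fit.degenerate
    assert fit.params["intercept"] == pytest.approx(0.7)
    assert fit.sigma_u2 == 0.0 and fit.sigma_e2 == 0.0
    assert abs(fit.params.drop("intercept")).max() == pytest.approx(0.0)


def test_balanced_two_study_intercept_equals_mean_of_study_means():
    rng = np.random.default_rng(2)
    n = 20
    y_a = 0.8 + rng.normal(0, 0.3, n)
    y_b = 0.2 + rng.normal(0, 0.3, n)
    tab = _table(np.concatenate([y_a, y_b]), ["A"] * n + ["B"] * n,
                 [f"p{i}" for i in range(2 * n)])
    fit = fit_hlm(tab)
    # contrast coding on a balanced design: beta0 is the grand mean =
    # mean of the two study means, for any variance ratio (GLS closed form)
    assert fit.params["intercept"] == pytest.approx(
        (y_a.mean() + y_b.mean()) / 2, abs=1e-8)
    assert fit.params["AvsB"] == pytest.approx(y_a.mean() - y_b.mean(), abs=1e-8)


def test_zero_variance_ratio_reproduces_ols():
    rng = np.random.default_rng(3)
    n = 30
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = x @ [0.5, 1.0] + rng.normal(0, 0.4, n)
    groups = np.array([f"g{i % 10}" for i in range(n)])
    model = RandomInterceptHLM(y, x, groups, ["intercept", "slope"])
    beta0, *_rest = model._gls(0.0)
    ols = np.linalg.lstsq(x, y, rcond=None)[0]
    np.testing.assert_allclose(beta0, ols, atol=1e-12)


def test_reml_against_statsmodels_mixedlm():
    """Independent cross-check of the variance components and effects."""
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(4)
    n_g, per = 25, 4
    groups = np.repeat([f"g{i}" for i in range(n_g)], per)
    u = np.repeat(rng.normal(0, 0.4, n_g), per)
    x1 = rng.normal(size=n_g * per)
    y = 0.6 + 0.3 * x1 + u + rng.normal(0, 0.5, n_g * per)
    df = pd.DataFrame(dict(y=y, x1=x1, g=groups))
    sm_fit = smf.mixedlm("y ~ x1", df, groups=df["g"]).fit(reml=True)
    x = np.column_stack([np.ones(len(y)), x1])
    fit = RandomInterceptHLM(y, x, groups, ["intercept", "x1"]).fit()
    assert fit.params["intercept"] == pytest.approx(sm_fit.params["Intercept"], abs=1e-5)
    assert fit.params["x1"] == pytest.approx(sm_fit.params["x1"], abs=1e-5)
    assert fit.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)
    assert fit.sigma_u2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
    assert fit.bse["intercept"] == pytest.approx(sm_fit.bse["Intercept"], rel=1e-3)


def test_rank_deficiency_names_collinear_terms():
    n = 12
    x = np.column_stack([np.ones(n), np.arange(n), 2 * np.arange(n)])
    with pytest.raises(HLMError, match="dup"):
        RandomInterceptHLM(np.zeros(n), x, np.arange(n) % 4,
                           ["intercept", "slope", "dup"])


def test_matrix_specific_term_sets():
    rng = np.random.default_rng(6)

    def rows(study, matrix, n, hormone="none", session=1):
        return _table(rng.normal(0.3, 0.2, n), study,
                      [f"{study}{i}" for i in range(n)], hormone=hormone,
                      matrix=matrix, session=session)

    # emotion observed in A and B only: AvsB kept, no hormone
    tab = pd.concat([rows("A", "B:emotion", 10), rows("B", "B:emotion", 10)],
                    ignore_index=True)
    fit = fit_hlm(tab)
    assert list(fit.params.index) == ["intercept", "AvsB"]

    # fame: intercept-only
    tab = pd.concat([rows("D", "B:fame", 10)], ignore_index=True)
    fit = fit_hlm(tab)
    assert list(fit.params.index) == ["intercept"]

    # full cohort, B:faces: all contrasts + hormone
    parts = [rows("A", "B:faces", 8), rows("B", "B:faces", 8),
             rows("C", "B:faces", 8, hormone="mid-luteal"),
             rows("C", "B:faces", 8, hormone="early-follicular", session=2),
             rows("D", "B:faces", 8)]
    tab = pd.concat(parts, ignore_index=True)
    fit = fit_hlm(tab)
    assert list(fit.params.index) == ["intercept", "AvsB", "ABvsC", "ABCvsD", "MvsP"]


def test_revised_model_single_connection_single_row():
    tab = _table(np.random.default_rng(1).normal(0.5, 0.2, 12),
                 ["A"] * 6 + ["B"] * 6, [f"p{i}" for i in range(12)])
    rep = revised_model(tab)
    assert len(rep.pooled) == 1
    assert rep.pooled.iloc[0]["n_tests"] == 1
    assert {"estimate", "p", "significant", "threshold"} <= set(rep.pooled.columns)
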