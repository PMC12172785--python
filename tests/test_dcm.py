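"""Variational inversion: self-consistency, determinism, oracles."""

import numpy as np
import pytest

from faceconn.dcm import (DCM, DCMResults, InversionSettings, PriorSpec,
                          build_layout, fit_model_space, information_criteria,
                          invert)
from faceconn.model_space import ModelSpace, enumerate_model_space
from faceconn.params import DCMParameters
from faceconn.simulate import BOLDTimeSeries, sample_bold

from conftest import boxcar_design

FAST = InversionSettings(n_starts=1, central_final_jacobian=False, max_iter=48)


@pytest.fixture(scope="module")
def small_fit(faces_space, pooled_mean_params):
    des = boxcar_design(n_scans=80, ratio=8)
    data = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.04, seed=0)
    model = DCM(data, des, faces_space.full_model, settings=FAST)
    return model, model.fit()


def test_layout_free_parameter_counts(faces_space):
    priors = PriorSpec()
    full = build_layout(faces_space.full_model, ("faces",), priors)
    # 6 A + 3 self + 6 B + 1 C + 3 eps + 3 tau
    assert full.n == 22
    fwd = build_layout(faces_space.forward_only_model, ("faces",), priors)
    assert fwd.n == 2 + 3 + 2 + 1 + 6
    # A-class priors tighter than B-class
    a_vars = full.prior_var[[lab[0] == "A" for lab in full.labels]]
    b_vars = full.prior_var[[lab[0] == "B" for lab in full.labels]]
    assert a_vars.max() < b_vars.min()


def test_inversion_at_prior_self_consistency(faces_space):
    # noise-free data generated at the prior mean (everything 0): the
    # posterior must stay at the prior and F must be finite
    des = boxcar_design(n_scans=64, ratio=8)
    params = DCMParameters.zeros()
    data = sample_bold(params, des, 2.0, noise_sd=0.0, seed=0)
    res = DCM(data, des, faces_space.full_model, settings=FAST).fit()
    assert np.all(np.abs(res.posterior_mean) < 1e-3)
    assert np.isfinite(res.free_energy)


def test_inversion_deterministic(small_fit, faces_space):
    model, res1 = small_fit
    res2 = DCM(model.data, model.design, faces_space.full_model,
               settings=FAST).fit()
    np.testing.assert_array_equal(res1.posterior_mean, res2.posterior_mean)
    np.testing.assert_array_equal(res1.posterior_cov, res2.posterior_cov)
    assert res1.free_energy == res2.free_energy
    assert res1.f_trace == res2.f_trace


def test_free_energy_trace_monotone(small_fit):
    _model, res = small_fit
    diffs = np.diff(res.f_trace)
    assert np.all(diffs >= 0)


def test_complexity_nonnegative_at_optimum(small_fit):
    model, res = small_fit
    y = model.predict(res.posterior_mean)
    jac = model._jacobian(res.posterior_mean, y0=y)
    _f, _sigma, _h, extras = model._free_energy(res.posterior_mean, y, jac, res.h)
    assert extras["kl_theta"] >= 0
    assert extras["kl_h"] >= 0


def test_posterior_covariance_symmetric_psd(small_fit):
    _model, res = small_fit
    cov = res.posterior_cov
    np.testing.assert_allclose(cov, cov.T, atol=1e-12)
    eigvals = np.linalg.eigvalsh(cov)
    assert eigvals.min() > -1e-10


def test_shrinkage_limit_tight_prior(faces_space, pooled_mean_params):
    # with a near-zero prior variance on B, posterior B collapses to the
    # prior mean even though the data carry strong face modulation
    des = boxcar_design(n_scans=80, ratio=8)
    data = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.04, seed=1)
    tight = PriorSpec(var_b=1e-8)
    res = DCM(data, des, faces_space.full_model, priors=tight,
              settings=FAST).fit()
    b_idx = [i for i, lab in enumerate(res.labels) if lab[0] == "B"]
    assert np.max(np.abs(res.posterior_mean[b_idx])) < 1e-3


def test_linear_regime_matches_gls_oracle(faces_space):
    """Tiny amplitudes: posterior ~ GLS on the linearized forward model."""
    des = boxcar_design(n_scans=100, ratio=8)
    space = faces_space
    truth_theta = 0.02  # tiny drive: response linear in parameters
    params = DCMParameters.zeros()
    params = DCMParameters(a=params.a, b={"faces": np.zeros((3, 3))},
                           c=np.array([truth_theta, 0, 0]))
    data = sample_bold(params, des, 2.0, noise_sd=0.0, seed=0)
    model = DCM(data, des, space.full_model, settings=FAST)
    res = model.fit()

    theta0 = model.layout.prior_mean
    y0 = model.predict(theta0)
    jac = model._jacobian(theta0, central=True)
    lam = np.exp(res.h)
    lam_rows = np.repeat(lam, data.n_scans)
    pi_prior = np.diag(1.0 / model.layout.prior_var)
    resid = (data.y - y0).T.reshape(-1)
    gls = np.linalg.solve((jac.T * lam_rows) @ jac + pi_prior,
                          jac.T @ (lam_rows * resid))
    c_idx = [i for i, lab in enumerate(res.labels) if lab[0] == "C"][0]
    assert res.posterior_mean[c_idx] == pytest.approx(gls[c_idx], rel=0.1)


def test_information_criteria_formulas(small_fit):
    _model, res = small_fit
    aic, bic = information_criteria(res)
    assert aic == pytest.approx(res.log_likelihood - res.n_params)
    assert bic == pytest.approx(res.log_likelihood
                                - 0.5 * res.n_params * np.log(res.n_scans))
    # two models with identical likelihood: aic difference is the
    # parameter-count difference; bic difference is (dk/2) ln n
    from dataclasses import replace
    r5 = replace(res, n_params=5, aic=res.log_likelihood - 5)
    r7 = replace(res, n_params=7, aic=res.log_likelihood - 7)
    assert r5.aic - r7.aic == pytest.approx(2.0)
    n = np.exp(2.0)
    bic5 = res.log_likelihood - 0.5 * 5 * np.log(n)
    bic7 = res.log_likelihood - 0.5 * 7 * np.log(n)
    assert bic5 - bic7 == pytest.approx(2.0)


def test_fit_model_space_serial_equals_parallel(pooled_mean_params):
    space = enumerate_model_space(["faces"])
    tiny = ModelSpace(structures=tuple(
        type(space.structures[0])(id=i + 1, a_mask=s.a_mask, b_masks=s.b_masks,
                                  c_mask=s.c_mask)
        for i, s in enumerate([space.forward_only_model, space.full_model])),
        modulator_names=("faces",))
    des = boxcar_design(n_scans=48, ratio=4)
    data = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.05, seed=2)
    serial = fit_model_space(data, des, tiny, settings=FAST, n_jobs=1)
    parallel = fit_model_space(data, des, tiny, settings=FAST, n_jobs=2)
    assert [r.model_id for r in serial] == [1, 2]
    for rs, rp in zip(serial, parallel):
        np.testing.assert_array_equal(rs.posterior_mean, rp.posterior_mean)
        assert rs.free_energy == rp.free_energy


def test_fit_model_space_full_24(pooled_mean_params, faces_space):
    des = boxcar_design(n_scans=40, ratio=4)
    data = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.08, seed=3)
    fast = InversionSettings(n_starts=1, central_final_jacobian=False, max_iter=16)
    results = fit_model_space(data, des, faces_space, settings=fast)
    assert [r.model_id for r in results] == list(range(1, 25))
    assert all(np.isfinite(r.free_energy) for r in results)


def test_masked_parameters_absent_from_results(small_fit, faces_space):
    _model, res = small_fit
    labels = set(res.labels)
    # full model: every inter-regional pair appears
    assert ("B", "OFA", "FFA", "faces") in labels
    fwd = faces_space.forward_only_model
    des = boxcar_design(n_scans=48, ratio=4)
    data = sample_bold(DCMParameters.zeros(), des, 2.0, noise_sd=0.05, seed=4)
    res_fwd = DCM(data, des, fwd, settings=FAST).fit()
    assert ("B", "FFA", "OFA", "faces") not in set(res_fwd.labels)


def test_modulator_missing_from_design_rejected(faces_space):
    space = enumerate_model_space(["faces", "emotion"])
    des = boxcar_design(n_scans=32, ratio=4)  # no emotion input
    data = BOLDTimeSeries(tr=2.0, y=np.random.default_rng(0).normal(size=(32, 3)))
    with pytest.raises(Exception, match="emotion"):
        DCM(data, des, space.full_model)


def test_summary_renders(small_fit):
    _model, res = small_fit
    text = res.summary()
    assert "free energy" in text
    assert "OFA->FFA" in text
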