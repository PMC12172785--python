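"""Forward model: closed-form oracles and qualitative response contracts."""

import numpy as np
import pytest
from scipy.linalg import expm

from faceconn.params import DCMParameters, HemodynamicConstants
from faceconn.simulate import (BOLDTimeSeries, IntegrationInstability,
                               StimulusDesign, hemodynamics, neural_dynamics,
                               predict_bold, sample_bold)

from conftest import boxcar_design


def test_zero_parameters_zero_input_stay_at_rest():
    des = boxcar_design(n_scans=32)
    params = DCMParameters.zeros()
    des0 = StimulusDesign(dt=des.dt, inputs={"faces": np.zeros(des.n_micro)})
    traj = neural_dynamics(params, des0)
    np.testing.assert_array_equal(traj, np.zeros_like(traj))


def test_unforced_decay_matches_scalar_closed_form():
    # a_logscale = 0, no coupling: each state decays as exp(-0.5 t)
    dt = 0.125
    n = 256
    des = StimulusDesign(dt=dt, inputs={"faces": np.zeros(n)})
    params = DCMParameters.zeros()
    z0 = np.array([1.0, -2.0, 0.5])
    traj = neural_dynamics(params, des, z0=z0)
    t_end = dt * np.arange(1, n + 1)
    expected = z0[None, :] * np.exp(-0.5 * t_end)[:, None]
    np.testing.assert_allclose(traj, expected, rtol=1e-6, atol=1e-9)


def test_neural_trajectory_matches_matrix_exponential_oracle(pooled_mean_params):
    """Piecewise-constant input, B=0: segment-wise expm closed form."""
    p = pooled_mean_params
    params = DCMParameters(a=p.a, b={"faces": np.zeros((3, 3))}, c=p.c)
    des = boxcar_design(tr=2.0, n_scans=50, ratio=16)
    traj = neural_dynamics(params, des)

    a_eff = params.a_effective
    u = des.inputs["faces"]
    z = np.zeros(3)
    expected = np.empty_like(traj)
    step = expm(a_eff * des.dt)
    a_inv = np.linalg.inv(a_eff)
    # z' = A z + C u with u constant on each step: exact propagation
    for k in range(des.n_micro):
        const = params.c * u[k]
        z = step @ z + a_inv @ (step - np.eye(3)) @ const
        expected[k] = z
    rel_rms = np.sqrt(np.mean((traj - expected) ** 2) / np.mean(expected ** 2))
    assert rel_rms < 1e-3


def test_hemodynamics_resting_fixed_point():
    des = boxcar_design(n_scans=16)
    params = DCMParameters.zeros()
    y = hemodynamics(np.zeros((des.n_micro, 3)), params, des)
    np.testing.assert_allclose(y, 0.0, atol=1e-12)


def test_hemodynamic_impulse_response_shape():
    dt = 0.125
    n = 480  # 60 s
    des = StimulusDesign(dt=dt, inputs={"faces": np.zeros(n)})
    z = np.zeros((n, 3))
    z[8:16, 0] = 1.0  # 1 s neural burst in OFA
    y = hemodynamics(z, DCMParameters.zeros(), des)
    ofa = y[:, 0]
    assert ofa.max() > 0
    peak = int(np.argmax(ofa))
    assert 16 < peak < n // 2            # peaks after the burst
    assert abs(ofa[-1]) < 0.05 * ofa.max()  # returns toward baseline
    np.testing.assert_allclose(y[:, 1:], 0.0, atol=1e-12)  # other regions silent


def test_low_amplitude_response_scales_with_epsilon():
    dt = 0.125
    n = 480
    des = StimulusDesign(dt=dt, inputs={"faces": np.zeros(n)})
    z = np.zeros((n, 3))
    z[8:16, 0] = 0.01  # low amplitude: near-linear regime
    p1 = DCMParameters.zeros()
    p2 = DCMParameters.zeros(eps_logdev=np.log(2.0) * np.ones(3))
    y1 = hemodynamics(z, p1, des)
    y2 = hemodynamics(z, p2, des)
    ratio = y2[:, 0].max() / y1[:, 0].max()
    assert abs(ratio - 2.0) / 2.0 < 0.1


def test_sample_bold_deterministic_and_centered(pooled_mean_params):
    des = boxcar_design(n_scans=64)
    a = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.0, seed=7)
    b = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.0, seed=8)
    np.testing.assert_array_equal(a.y, b.y)  # noise-free: seed irrelevant
    assert np.all(np.abs(a.y.mean(axis=0)) < 1e-10)
    c1 = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.05, seed=7)
    c2 = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.05, seed=7)
    np.testing.assert_array_equal(c1.y, c2.y)


def test_sample_bold_noise_sd_law_of_large_numbers(pooled_mean_params):
    des = boxcar_design(n_scans=512, ratio=4)
    clean = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.0, seed=3)
    noisy = sample_bold(pooled_mean_params, des, 2.0, noise_sd=0.05, seed=3)
    resid_sd = (noisy.y - clean.y).std()
    assert abs(resid_sd - 0.05) / 0.05 < 0.2


def test_tr_must_be_integer_multiple_of_dt(pooled_mean_params):
    des = boxcar_design(tr=2.0, n_scans=32, ratio=8)  # dt = 0.25
    with pytest.raises(ValueError, match="integer multiple"):
        predict_bold(pooled_mean_params, des, tr=1.9)


def test_integration_step_convergence(pooled_mean_params):
    y16 = predict_bold(pooled_mean_params, boxcar_design(n_scans=100, ratio=16), 2.0)
    y32 = predict_bold(pooled_mean_params, boxcar_design(n_scans=100, ratio=32), 2.0)
    rel = np.sqrt(np.mean((y16 - y32) ** 2) / np.mean(y32 ** 2))
    assert rel < 1e-3


def test_unconnected_region_stays_silent():
    # drive OFA only; no couplings at all: FFA and STS produce exactly 0
    des = boxcar_design(n_scans=64)
    params = DCMParameters(a=np.zeros((3, 3)), b={"faces": np.zeros((3, 3))},
                           c=np.array([1.0, 0.0, 0.0]))
    y = predict_bold(params, des, 2.0)
    assert y[:, 0].std() > 0
    np.testing.assert_allclose(y[:, 1:], 0.0, atol=1e-12)


def test_instability_error_reports_time_index():
    des = boxcar_design(n_scans=64)
    a = np.zeros((3, 3))
    a[1, 0] = a[0, 1] = 5.0  # strong positive loop: divergence
    params = DCMParameters(a=a, b={"faces": np.zeros((3, 3))},
                           c=np.array([2.0, 0, 0]))
    with pytest.raises(IntegrationInstability) as exc_info:
        predict_bold(params, des, 2.0)
    assert exc_info.value.time_index >= 0


def test_bold_time_series_validation():
    with pytest.raises(ValueError):
        BOLDTimeSeries(tr=2.0, y=np.zeros((1, 3)))      # too few scans
    with pytest.raises(ValueError):
        BOLDTimeSeries(tr=2.0, y=np.full((5, 3), np.nan))


def test_design_validation():
    with pytest.raises(ValueError, match="faces"):
        StimulusDesign(dt=0.25, inputs={"emotion": np.zeros(8)})
    with pytest.raises(ValueError, match="nonnegative"):
        StimulusDesign(dt=0.25, inputs={"faces": -np.ones(8)})
    with pytest.raises(ValueError, match="same length"):
        StimulusDesign(dt=0.25, inputs={"faces": np.zeros(8),
                                        "emotion": np.zeros(9)})
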