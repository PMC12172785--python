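"""Synthetic cohort generator: ground truth, designs, cohort shape."""

import numpy as np
import pytest

from faceconn.cohort import (GroundTruth, StudyConfig, build_design,
                             default_ground_truth, default_study_configs,
                             generate_cohort, recovery_design)
from faceconn.regions import FFA, OFA, STS


def test_default_ground_truth_pooled_estimates(truth):
    m = truth.mean
    bf = m.b["faces"]
    assert bf[FFA, OFA] == pytest.approx(0.92)
    assert bf[STS, OFA] == pytest.approx(0.77)
    assert bf[OFA, FFA] == pytest.approx(-1.13)
    assert bf[STS, FFA] == pytest.approx(-0.31)
    assert bf[FFA, STS] == pytest.approx(-0.4)
    be = m.b["emotion"]
    assert be[STS, OFA] == pytest.approx(0.35)
    assert be[STS, FFA] == pytest.approx(-0.19)
    assert m.c[OFA] == pytest.approx(1.42)
    assert m.a[FFA, OFA] == pytest.approx(0.08)
    assert m.a[OFA, FFA] == pytest.approx(-0.19)
    np.testing.assert_array_equal(m.b["fame"], 0.0)
    # a_logscale 0 => effective self-connections -0.5 Hz everywhere
    np.testing.assert_allclose(m.self_connections_hz, -0.5)


def test_block_design_structure():
    des = build_design("block", ("emotion",), tr=2.0, n_scans=150, seed=5)
    faces = des.inputs["faces"]
    emo = des.inputs["emotion"]
    assert set(np.unique(faces)) <= {0.0, 1.0}
    # emotion only during face blocks
    assert np.all(faces[emo > 0] == 1.0)
    assert 0 < emo.sum() < faces.sum()
    # face and control blocks alternate: face on-mass is about half the
    # non-gap time (within one block of parity)
    dt = des.dt
    block_len = 16.0 / dt
    n_face_blocks = faces.sum() / block_len
    assert n_face_blocks == int(n_face_blocks)


def test_emotion_fraction_of_face_blocks():
    des = build_design("block", ("emotion",), tr=2.0, n_scans=300, seed=0)
    dt = des.dt
    block = int(16.0 / dt)
    n_face = int(des.inputs["faces"].sum()) // block
    n_emo = int(des.inputs["emotion"].sum()) // block
    assert n_emo == round(0.75 * n_face)


def test_event_design_exact_fame_count():
    des = build_design("event", ("fame",), tr=2.0, n_scans=300, seed=9)
    dt = des.dt
    dur = max(1, int(round(0.6 / dt)))
    n_events = int(des.inputs["faces"].sum()) // dur
    n_famous = int(des.inputs["fame"].sum()) // dur
    assert n_events > 20
    assert n_famous == round(0.5 * n_events)
    assert np.all(des.inputs["faces"][des.inputs["fame"] > 0] == 1.0)


def test_design_kind_modulator_compatibility():
    with pytest.raises(ValueError):
        build_design("block", ("fame",))
    with pytest.raises(ValueError):
        build_design("event", ("emotion",))
    with pytest.raises(ValueError):
        build_design("mixed", ())


def test_design_deterministic_given_seed():
    a = build_design("event", ("fame",), seed=3)
    b = build_design("event", ("fame",), seed=3)
    for k in a.inputs:
        np.testing.assert_array_equal(a.inputs[k], b.inputs[k])


def test_default_cohort_shape():
    # shape only: tiny sessions keep simulation fast
    configs = [StudyConfig(**{**c.__dict__, "n_scans": 40}) for c in default_study_configs()]
    cohort = generate_cohort(configs, seed=0, microtime_ratio=4)
    cov = cohort.covariates()
    assert list(cov["study"].unique()) == ["A", "B", "C", "D"]
    participants = cov.groupby("study")["participant"].nunique()
    assert participants.to_dict() == {"A": 23, "B": 27, "C": 17, "D": 16}
    # study C: exactly one mid-luteal and one early-follicular session each
    for _, sub in cov[cov.study == "C"].groupby("participant"):
        assert sorted(sub["hormone"]) == ["early-follicular", "mid-luteal"]
    # study D: 5-9 event-design sessions per participant
    d_sessions = cov[cov.study == "D"].groupby("participant")["session"].max()
    assert d_sessions.between(5, 9).all()
    assert set(d_sessions) != {5}  # the range is actually sampled


def test_degenerate_variance_gives_identical_participants():
    truth = GroundTruth(mean=default_ground_truth().mean, sd_a=0.0, sd_b=0.0, sd_c=0.0)
    cfg = [StudyConfig(label="C", n_participants=3, sessions_per_participant=1,
                       modulators=(), n_scans=40, noise_sd=0.0)]
    cohort = generate_cohort(cfg, truth, seed=0, microtime_ratio=4)
    ys = [r.data.y for r in cohort.records]
    np.testing.assert_array_equal(ys[0], ys[1])
    np.testing.assert_array_equal(ys[0], ys[2])


def test_cohort_reproducible_from_seed():
    cfg = [StudyConfig(label="A", n_participants=2, modulators=("emotion",),
                       n_scans=40)]
    c1 = generate_cohort(cfg, seed=5, microtime_ratio=4)
    c2 = generate_cohort(cfg, seed=5, microtime_ratio=4)
    for r1, r2 in zip(c1.records, c2.records):
        np.testing.assert_array_equal(r1.data.y, r2.data.y)
    c3 = generate_cohort(cfg, seed=6, microtime_ratio=4)
    assert not np.array_equal(c1.records[0].data.y, c3.records[0].data.y)


def test_population_mean_of_draws(truth):
    rng = np.random.default_rng(0)
    n = 200
    draws = [truth.draw(rng) for _ in range(n)]
    b_of = np.array([d.b["faces"][FFA, OFA] for d in draws])
    se = truth.sd_b / np.sqrt(n)
    assert abs(b_of.mean() - 0.92) < 3 * se
    a_fo = np.array([d.a[OFA, FFA] for d in draws])
    assert abs(a_fo.mean() - (-0.19)) < 3 * (truth.sd_a / np.sqrt(n))


def test_recovery_design_layout():
    des = recovery_design(tr=2.0, n_scans=100, microtime_ratio=8)
    u = des.inputs["faces"]
    assert des.n_micro == 800
    # 16 s on / 4 s off: duty cycle 0.8
    assert u.mean() == pytest.approx(0.8, abs=0.02)


def test_study_config_validation():
    with pytest.raises(ValueError):
        StudyConfig(label="X", n_participants=0)
    with pytest.raises(ValueError):
        StudyConfig(label="X", n_participants=1, modulators=("scrambled",))
    with pytest.raises(ValueError):
        StudyConfig(label="X", n_participants=1, design_kind="mixed")
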