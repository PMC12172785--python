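"""Synthetic multi-study cohorts with the structure the analysis assumes.

Four study archetypes are emulated, mirroring a typical multi-site
face-perception corpus:

* study A — block design, face blocks of four expression types (three
  emotional, one neutral) alternating with house/control blocks,
  23 participants x 1 session, "emotion" modulator;
* study B — like A with two expression types, 27 participants x 1 session;
* study C — block design, neutral faces only, all-female sample measured
  twice (mid-luteal and early-follicular phase), 17 participants x 2
  sessions;
* study D — event-related famous/non-famous paradigm, 16 participants x
  5-9 sessions, "fame" modulator.

Participant-level connectivity parameters are drawn from a Gaussian
population around configurable means (defaulting to the pooled
cross-study estimates: e.g. face presentation boosting OFA→FFA coupling
by +0.92 Hz and OFA→STS by +0.77 Hz while suppressing FFA→OFA feedback
by −1.13 Hz), truncated to dynamically stable draws, then pushed through
the generative model with additive Gaussian scanner noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import DCMParameters, HemodynamicConstants
from .regions import DEFAULT_REGIONS, FFA, OFA, STS
from .simulate import (BOLDTimeSeries, IntegrationInstability, StimulusDesign,
                       predict_bold, sample_bold)

HORMONE_LEVELS = ("mid-luteal", "early-follicular", "none")


@dataclass(frozen=True)
class StudyConfig:
    """Shape and acquisition parameters of one synthetic study."""

    label: str
    n_participants: int
    sessions_per_participant: int | tuple[int, int] = 1  # fixed or inclusive range
    design_kind: str = "block"           # "block" | "event"
    modulators: tuple[str, ...] = ()     # subset of {"emotion", "fame"}
    hormone_covariate: bool = False
    tr: float = 2.0
    n_scans: int = 200
    noise_sd: float | None = None        # None: calibrated to SNR ~ 1

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.design_kind not in ("block", "event"):
            raise ValueError(f"unknown design_kind {self.design_kind!r}")
        if not set(self.modulators) <= {"emotion", "fame"}:
            raise ValueError(f"modulators must be within {{'emotion','fame'}}, got {self.modulators}")
        s = self.sessions_per_participant
        lo, hi = (s, s) if isinstance(s, int) else s
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid sessions_per_participant {s!r}")

    def session_range(self) -> tuple[int, int]:
        s = self.sessions_per_participant
        return (s, s) if isinstance(s, int) else tuple(s)


def default_study_configs() -> list[StudyConfig]:
    """The four-study cohort shape: A 23x1, B 27x1, C 17x2, D 16x(5-9)."""
    return [
        StudyConfig(label="A", n_participants=23, sessions_per_participant=1,
                    design_kind="block", modulators=("emotion",)),
        StudyConfig(label="B", n_participants=27, sessions_per_participant=1,
                    design_kind="block", modulators=("emotion",)),
        StudyConfig(label="C", n_participants=17, sessions_per_participant=2,
                    design_kind="block", modulators=(), hormone_covariate=True),
        StudyConfig(label="D", n_participants=16, sessions_per_participant=(5, 9),
                    design_kind="event", modulators=("fame",)),
    ]


@dataclass(frozen=True)
class GroundTruth:
    """Population model generating per-participant parameters.

    ``mean`` holds the population-mean parameter set; per-participant
    draws add independent Gaussian deviations with class-specific SDs
    (``sd_a`` on endogenous entries incl. log-scale self-connections,
    ``sd_b``/``sd_c`` on modulatory and driving entries). Entries whose
    population mean and SD are both zero stay exactly zero.
    """

    mean: DCMParameters
    sd_a: float = 0.1
    sd_b: float = 0.25
    sd_c: float = 0.25

    def __post_init__(self) -> None:
        if min(self.sd_a, self.sd_b, self.sd_c) < 0:
            raise ValueError("between-participant SDs must be >= 0")

    def draw(self, rng: np.random.Generator) -> DCMParameters:
        m = self.mean
        a = m.a + rng.normal(0.0, self.sd_a, size=(3, 3))
        b = {k: v + rng.normal(0.0, self.sd_b, size=(3, 3)) for k, v in m.b.items()}
        for bm in b.values():
            np.fill_diagonal(bm, 0.0)
        c = m.c.copy()
        drive = m.c != 0
        c[drive] += rng.normal(0.0, self.sd_c, size=int(drive.sum()))
        return replace(m, a=a, b=b, c=c)


def default_ground_truth() -> GroundTruth:
    """Population means set to the pooled cross-study estimates.

    A: OFA→FFA +0.08, FFA→OFA −0.19; C(OFA) +1.42; B "faces": OFA→FFA
    +0.92, OFA→STS +0.77, FFA→OFA −1.13, FFA→STS −0.31, STS→FFA −0.4;
    B "emotion": OFA→STS +0.35, FFA→STS −0.19; B "fame" all zero. All
    other inter-regional entries zero; a_logscale 0 (self-connections
    −0.5 Hz under the conversion).
    """
    a = np.zeros((3, 3))
    a[FFA, OFA] = 0.08
    a[OFA, FFA] = -0.19
    b_faces = np.zeros((3, 3))
    b_faces[FFA, OFA] = 0.92
    b_faces[STS, OFA] = 0.77
    b_faces[OFA, FFA] = -1.13
    b_faces[STS, FFA] = -0.31
    b_faces[FFA, STS] = -0.4
    b_emotion = np.zeros((3, 3))
    b_emotion[STS, OFA] = 0.35
    b_emotion[STS, FFA] = -0.19
    c = np.zeros(3)
    c[OFA] = 1.42
    mean = DCMParameters(a=a, b={"faces": b_faces, "emotion": b_emotion,
                                 "fame": np.zeros((3, 3))}, c=c)
    return GroundTruth(mean=mean)


# -- designs ---------------------------------------------------------------

#: block-design layout (seconds); a cycle is face-block, gap, control-block, gap
BLOCK_ON_S = 16.0
BLOCK_GAP_S = 4.0
#: fraction of face-block types carrying an emotional expression (3 of 4)
EMOTION_BLOCK_FRACTION = 0.75
#: event-design layout
EVENT_DURATION_S = 0.6
EVENT_ISI_S = (3.0, 6.0)
FAME_FRACTION = 0.5


def build_design(kind: str, modulators: tuple[str, ...] = (), tr: float = 2.0,
                 n_scans: int = 200, seed: int | np.random.Generator = 0,
                 microtime_ratio: int = 16,
                 block_on_s: float = BLOCK_ON_S, block_gap_s: float = BLOCK_GAP_S,
                 emotion_fraction: float = EMOTION_BLOCK_FRACTION,
                 fame_fraction: float = FAME_FRACTION) -> StimulusDesign:
    """Sampled input functions for one session.

    Block kind: face and control blocks alternate, separated by gaps;
    "faces" is 1 during any face block; "emotion" (if requested) is 1
    only during the emotional subset of face blocks, assigned by an
    exact-count shuffle of block types. Event kind: brief face events
    with jittered inter-stimulus intervals; "fame" (if requested) marks
    an exact fraction of events as famous, again by exact-count shuffle.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "block":
        if "fame" in modulators:
            raise ValueError('modulator "fame" requires an event design')
    elif kind == "event":
        if "emotion" in modulators:
            raise ValueError('modulator "emotion" requires a block design')
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    dt = tr / microtime_ratio
    n_micro = n_scans * microtime_ratio
    faces = np.zeros(n_micro)
    inputs: dict[str, np.ndarray] = {"faces": faces}

    if kind == "block":
        on = int(round(block_on_s / dt))
        gap = int(round(block_gap_s / dt))
        starts = []
        t = gap
        face_block = True
        while t + on <= n_micro:
            if face_block:
                starts.append(t)
                faces[t:t + on] = 1.0
            t += on + gap
            face_block = not face_block
        if "emotion" in modulators:
            emotion = np.zeros(n_micro)
            n_blocks = len(starts)
            n_emo = int(round(emotion_fraction * n_blocks))
            flags = np.zeros(n_blocks, dtype=bool)
            flags[:n_emo] = True
            rng.shuffle(flags)
            for s, is_emo in zip(starts, flags):
                if is_emo:
                    emotion[s:s + on] = 1.0
            inputs["emotion"] = emotion
    else:
        dur = max(1, int(round(EVENT_DURATION_S / dt)))
        lo, hi = EVENT_ISI_S
        starts = []
        t = int(round(lo / dt))
        while t + dur <= n_micro:
            starts.append(t)
            faces[t:t + dur] = 1.0
            isi = rng.uniform(lo, hi)
            t += dur + int(round(isi / dt))
        if "fame" in modulators:
            fame = np.zeros(n_micro)
            n_events = len(starts)
            n_famous = int(round(fame_fraction * n_events))
            flags = np.zeros(n_events, dtype=bool)
            flags[:n_famous] = True
            rng.shuffle(flags)
            for s, is_famous in zip(starts, flags):
                if is_famous:
                    fame[s:s + dur] = 1.0
            inputs["fame"] = fame

    return StimulusDesign(dt=dt, inputs=inputs)


def recovery_design(tr: float = 2.0, n_scans: int = 400,
                    on_s: float = 16.0, off_s: float = 4.0,
                    microtime_ratio: int = 16) -> StimulusDesign:
    """Deterministic faces on/off benchmark design for recovery experiments.

    A high-duty boxcar (16 s faces, 4 s rest by default): the network
    spends most of the run in its face-modulated state, while the short
    rests expose the return-to-baseline dynamics — a layout chosen for
    identifiability of the coupling parameters rather than fidelity to
    any particular paradigm.
    """
    dt = tr / microtime_ratio
    n_micro = n_scans * microtime_ratio
    u = np.zeros(n_micro)
    t = 0
    on = True
    while t < n_micro:
        dur = int(round((on_s if on else off_s) / dt))
        if on:
            u[t:t + dur] = 1.0
        t += dur
        on = not on
    return StimulusDesign(dt=dt, inputs={"faces": u})


# -- cohort generation -----------------------------------------------------

@dataclass(frozen=True)
class SessionRecord:
    study: str
    participant: str
    session: int
    hormone: str                      # mid-luteal | early-follicular | none
    data: BOLDTimeSeries
    design: StimulusDesign


@dataclass
class CohortDataset:
    """Generated sessions plus the bookkeeping needed for recovery scoring."""

    records: list[SessionRecord]
    truth: GroundTruth
    participant_params: dict[tuple[str, str], DCMParameters]
    noise_sd: dict[str, float]
    seed: int

    def covariates(self) -> pd.DataFrame:
        rows = [
            dict(study=r.study, participant=r.participant, session=r.session,
                 hormone=r.hormone)
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @property
    def studies(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.study not in seen:
                seen.append(r.study)
        return seen

    def sessions_of(self, study: str) -> list[SessionRecord]:
        return [r for r in self.records if r.study == study]


def _stable(params: DCMParameters, modulators: tuple[str, ...]) -> bool:
    """Eigenvalue check: A_eff and A_eff + each single modulator's B stable."""
    a_eff = params.a_effective
    mats = [a_eff]
    combined = a_eff.copy()
    for m in ("faces", *modulators):
        bm = params.b.get(m)
        if bm is not None:
            mats.append(a_eff + bm)
            combined = combined + bm
    mats.append(combined)
    return all(np.max(np.linalg.eigvals(m).real) < -1e-3 for m in mats)


def calibrate_noise_sd(truth_mean: DCMParameters, design: StimulusDesign,
                       tr: float, n_scans: int) -> float:
    """Noise SD giving signal-SD/noise-SD ~ 1 for the population mean."""
    sig = predict_bold(truth_mean, design, tr, n_scans=n_scans)
    return float(np.sqrt(np.mean(np.var(sig, axis=0))))


def generate_cohort(configs: list[StudyConfig] | None = None,
                    truth: GroundTruth | None = None,
                    seed: int = 0,
                    microtime_ratio: int = 16,
                    max_redraws: int = 50) -> CohortDataset:
    """Draw a full multi-study cohort; reproducible from ``seed``.

    Per participant, individual parameters are drawn from the population
    model and redrawn (up to ``max_redraws``) until dynamically stable;
    per session, a design is sampled and the BOLD series simulated with
    additive Gaussian noise. Every random stream is keyed by
    (seed, study, participant, session), so any subset regenerates
    identically.
    """
    configs = default_study_configs() if configs is None else configs
    if not configs:
        raise ValueError("configs must be non-empty")
    truth = default_ground_truth() if truth is None else truth

    records: list[SessionRecord] = []
    participant_params: dict[tuple[str, str], DCMParameters] = {}
    noise_by_study: dict[str, float] = {}

    for s_idx, cfg in enumerate(configs):
        mean_masked = _restrict_modulators(truth.mean, cfg.modulators)
        ref_design = build_design(cfg.design_kind, cfg.modulators, cfg.tr,
                                  cfg.n_scans, seed=np.random.default_rng([seed, s_idx, 0]),
                                  microtime_ratio=microtime_ratio)
        noise_sd = cfg.noise_sd if cfg.noise_sd is not None else calibrate_noise_sd(
            mean_masked, ref_design, cfg.tr, cfg.n_scans)
        noise_by_study[cfg.label] = noise_sd

        lo, hi = cfg.session_range()
        for p_idx in range(cfg.n_participants):
            prng = np.random.default_rng([seed, s_idx, p_idx + 1, 0])
            pid = f"{cfg.label}{p_idx + 1:02d}"

            n_sessions = int(prng.integers(lo, hi + 1)) if hi > lo else lo
            if cfg.hormone_covariate:
                if n_sessions != 2:
                    raise ValueError(
                        f"study {cfg.label}: hormone covariate requires exactly 2 sessions")
                phases = ["mid-luteal", "early-follicular"]
                prng.shuffle(phases)

            # truncation to stability: the eigenvalue screen rejects
            # linearly unstable draws cheaply; the simulation attempt
            # also catches transient (non-normal) excursions that break
            # the hemodynamic model
            sessions = None
            for _ in range(max_redraws):
                cand = _restrict_modulators(truth.draw(prng), cfg.modulators)
                if not _stable(cand, cfg.modulators):
                    continue
                try:
                    trial = []
                    for sess in range(1, n_sessions + 1):
                        srng = np.random.default_rng([seed, s_idx, p_idx + 1, sess])
                        design = build_design(cfg.design_kind, cfg.modulators, cfg.tr,
                                              cfg.n_scans, seed=srng,
                                              microtime_ratio=microtime_ratio)
                        data = sample_bold(cand, design, cfg.tr, noise_sd=noise_sd,
                                           seed=srng, n_scans=cfg.n_scans)
                        trial.append((sess, design, data))
                except IntegrationInstability:
                    continue
                params, sessions = cand, trial
                break
            if sessions is None:
                raise RuntimeError(
                    f"study {cfg.label}, participant {p_idx + 1}: no stable parameter draw "
                    f"in {max_redraws} attempts")
            participant_params[(cfg.label, pid)] = params
            for sess, design, data in sessions:
                hormone = phases[sess - 1] if cfg.hormone_covariate else "none"
                records.append(SessionRecord(study=cfg.label, participant=pid,
                                             session=sess, hormone=hormone,
                                             data=data, design=design))

    return CohortDataset(records=records, truth=truth,
                         participant_params=participant_params,
                         noise_sd=noise_by_study, seed=seed)


def _restrict_modulators(params: DCMParameters, modulators: tuple[str, ...]) -> DCMParameters:
    """Keep only the B matrices a study's paradigm actually manipulates."""
    keep = ("faces", *modulators)
    return replace(params, b={k: v for k, v in params.b.items() if k in keep})
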