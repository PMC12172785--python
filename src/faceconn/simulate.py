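"""Forward simulation: bilinear neural dynamics, balloon hemodynamics, BOLD sampling.

The generative model is the deterministic bilinear DCM

    dz/dt = (A_eff + sum_j u_j(t) B(j)) z + C u(t)

coupled, per region, to the balloon/Windkessel hemodynamic model

    s' = eps*z - kappa*s - gamma*(f - 1)
    f' = s
    tau*v' = f - v^(1/alpha)
    tau*q' = f*(1 - (1-E0)^(1/f))/E0 - v^(1/alpha) * q/v

with the static BOLD observation
    y = V0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v)).

Integration is fixed-step on the microtime grid; RK4 by default, explicit
Euler selectable. Observed series are decimated to scan onsets,
mean-centered per region, and optionally corrupted with i.i.d. Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .params import DCMParameters
from .regions import DEFAULT_REGIONS, RegionSet

#: Default microtime bins per scan (dt = tr / MICROTIME_RATIO).
MICROTIME_RATIO = 16
#: Divergence guard on |z| (Hz-domain neural states).
STATE_BOUND = 1e3


class IntegrationInstability(RuntimeError):
    """Raised when a trajectory leaves the admissible region.

    Attributes
    ----------
    time_index : int
        Microtime index of the first inadmissible step.
    """

    def __init__(self, message: str, time_index: int):
        super().__init__(f"{message} at microtime index {time_index}")
        self.time_index = time_index


@dataclass(frozen=True)
class StimulusDesign:
    """Sampled experimental input functions on the microtime grid.

    ``inputs`` maps input names to arrays of identical length; the
    driving input "faces" must be present and nonnegative. Input order
    for matrix algebra is: "faces" first, then the remaining names in
    insertion order.
    """

    dt: float
    inputs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if "faces" not in self.inputs:
            raise ValueError('design must include the driving input "faces"')
        arrays = {k: np.asarray(v, dtype=float) for k, v in self.inputs.items()}
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError(f"all inputs must have the same length, got {lengths}")
        for name, v in arrays.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"input {name!r} contains non-finite values")
        if np.any(arrays["faces"] < 0):
            raise ValueError('driving input "faces" must be nonnegative')
        object.__setattr__(self, "inputs", arrays)

    @property
    def n_micro(self) -> int:
        return len(next(iter(self.inputs.values())))

    @property
    def input_names(self) -> tuple[str, ...]:
        names = list(self.inputs)
        names.remove("faces")
        return ("faces", *names)

    def input_matrix(self) -> np.ndarray:
        """(n_micro, n_inputs) array, columns in :attr:`input_names` order."""
        return np.column_stack([self.inputs[n] for n in self.input_names])

    @property
    def duration(self) -> float:
        return self.n_micro * self.dt


@dataclass(frozen=True)
class BOLDTimeSeries:
    """Observed (or simulated) BOLD signal: n_scans x 3, mean-centered."""

    tr: float
    y: np.ndarray
    regions: RegionSet = field(default=DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3:
            raise ValueError("y must be n_scans x 3")
        if y.shape[0] < 2:
            raise ValueError("need at least 2 scans")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        object.__setattr__(self, "y", y)

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]


def _method_code(method: str) -> int:
    try:
        return {"rk4": _core.METHOD_RK4, "euler": _core.METHOD_EULER}[method]
    except KeyError:
        raise ValueError(f"unknown integration method {method!r}; use 'rk4' or 'euler'") from None


def _b_stack(params: DCMParameters, design: StimulusDesign) -> np.ndarray:
    bs = np.zeros((len(design.input_names), 3, 3))
    for k, name in enumerate(design.input_names):
        if name in params.b:
            bs[k] = params.b[name]
    return bs


def neural_dynamics(
    params: DCMParameters,
    design: StimulusDesign,
    z0: np.ndarray | None = None,
    method: str = "rk4",
    bound: float = STATE_BOUND,
) -> np.ndarray:
    """Integrate the neural states on the microtime grid.

    Returns the (n_micro, 3) trajectory; row k holds the state at the end
    of microtime step k. Raises :class:`IntegrationInstability` if any
    state exceeds ``bound`` in magnitude.
    """
    z0 = np.zeros(3) if z0 is None else np.asarray(z0, dtype=float)
    if not np.all(np.isfinite(z0)):
        raise ValueError("z0 must be finite")
    traj, status = _core.neural_trajectory(
        params.a_effective, _b_stack(params, design), params.c,
        design.input_matrix(), design.dt, z0, _method_code(method), bound,
    )
    if status != _core.STATUS_OK:
        raise IntegrationInstability("neural state exceeded bound", status)
    return traj


def hemodynamics(
    neural: np.ndarray,
    params: DCMParameters,
    design: StimulusDesign,
    method: str = "rk4",
) -> np.ndarray:
    """Balloon-model BOLD response to a given neural trajectory.

    Returns the (n_micro, 3) BOLD signal on the microtime grid (not
    mean-centered, not decimated).
    """
    neural = np.asarray(neural, dtype=float)
    if not np.all(np.isfinite(neural)):
        raise ValueError("neural trajectory must be finite")
    h = params.hemo
    y, _states, status = _core.hemo_trajectory(
        neural, design.dt,
        h.epsilon * np.exp(params.eps_logdev), h.tau * np.exp(params.tau_logdev),
        h.kappa, h.gamma, h.alpha, h.e0, h.v0, h.k1, h.k2, h.k3,
        _method_code(method),
    )
    if status != _core.STATUS_OK:
        raise IntegrationInstability("hemodynamic state left admissible band", status)
    return y


def predict_bold(
    params: DCMParameters,
    design: StimulusDesign,
    tr: float,
    n_scans: int | None = None,
    method: str = "rk4",
    bound: float = STATE_BOUND,
) -> np.ndarray:
    """Noise-free mean-centered BOLD at scan onsets (the likelihood predictor)."""
    ratio = tr / design.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"tr ({tr}) must be an integer multiple of dt ({design.dt})")
    ratio = int(round(ratio))
    max_scans = design.n_micro // ratio
    n_scans = max_scans if n_scans is None else n_scans
    if n_scans > max_scans:
        raise ValueError(f"design supports at most {max_scans} scans, requested {n_scans}")
    h = params.hemo
    y, status = _core.bold_predict(
        params.a_effective, _b_stack(params, design), params.c,
        design.input_matrix(), design.dt,
        h.epsilon * np.exp(params.eps_logdev), h.tau * np.exp(params.tau_logdev),
        h.kappa, h.gamma, h.alpha, h.e0, h.v0, h.k1, h.k2, h.k3,
        ratio, n_scans, _method_code(method), bound,
    )
    if status != _core.STATUS_OK:
        raise IntegrationInstability("forward model left admissible region", status)
    return y


def sample_bold(
    params: DCMParameters,
    design: StimulusDesign,
    tr: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_scans: int | None = None,
    method: str = "rk4",
) -> BOLDTimeSeries:
    """Simulate an observed BOLD series: decimate, mean-center, add noise.

    Deterministic given ``seed`` (an int or a Generator).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y = predict_bold(params, design, tr, n_scans=n_scans, method=method)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return BOLDTimeSeries(tr=tr, y=y)
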