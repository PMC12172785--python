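"""Numeric parameter sets for one dynamic causal model.

Couplings follow the bilinear neural model

    dz/dt = (A_eff + sum_j u_j(t) B(j)) z + C u(t)

with A_eff equal to A except on the diagonal, where the self-connection
is parameterized in log-scale: the effective recurrent rate of region r
is -0.5 * exp(a_logscale[r]) Hz, negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_space import NetworkStructure


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon/Windkessel constants shared by all regions.

    kappa : signal decay rate (1/s); gamma : flow-dependent feedback
    rate (1/s); tau : mean transit time (s); alpha : vessel stiffness
    exponent; e0 : resting oxygen extraction fraction; epsilon :
    neuronal efficacy (how strongly neural activity drives the
    vasodilatory signal); v0 : resting venous blood volume fraction.
    The BOLD observation constants are the conventional
    k1 = 7*e0, k2 = 2, k3 = 2*e0 - 0.2.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    epsilon: float = 1.0
    v0: float = 0.04

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "e0", "epsilon", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hemodynamic constant {name} must be strictly positive")

    @property
    def k1(self) -> float:
        return 7.0 * self.e0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.e0 - 0.2


@dataclass(frozen=True)
class DCMParameters:
    """Full parameter set of one subject's DCM.

    Attributes
    ----------
    a : (3, 3) array
        Off-diagonal: endogenous inter-regional couplings (Hz).
        Diagonal: log-scale self-connection parameters (unitless);
        effective self-coupling is ``-0.5 * exp(a[r, r])``.
    b : dict[str, (3, 3) array]
        Modulatory coupling changes (Hz) per input; zero diagonal.
    c : (3,) array
        Driving-input strengths (Hz per unit input).
    hemo : HemodynamicConstants
        Shared constants; per-region deviations of epsilon and tau are
        expressed through ``eps_logdev`` and ``tau_logdev``.
    eps_logdev, tau_logdev : (3,) array
        Log-deviations: region r uses epsilon * exp(eps_logdev[r]) and
        tau * exp(tau_logdev[r]).
    """

    a: np.ndarray
    b: dict[str, np.ndarray] = field(default_factory=dict)
    c: np.ndarray = field(default_factory=lambda: np.zeros(3))
    hemo: HemodynamicConstants = field(default_factory=HemodynamicConstants)
    eps_logdev: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tau_logdev: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (3, 3):
            raise ValueError("a must be 3x3")
        b = {k: np.asarray(v, dtype=float) for k, v in self.b.items()}
        for name, bm in b.items():
            if bm.shape != (3, 3):
                raise ValueError(f"b[{name!r}] must be 3x3")
            if np.any(np.diag(bm) != 0.0):
                raise ValueError(f"b[{name!r}] diagonal must be exactly 0")
        c = np.asarray(self.c, dtype=float)
        if c.shape != (3,):
            raise ValueError("c must be length 3")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "eps_logdev", np.asarray(self.eps_logdev, dtype=float))
        object.__setattr__(self, "tau_logdev", np.asarray(self.tau_logdev, dtype=float))

    @property
    def a_effective(self) -> np.ndarray:
        """A with the diagonal converted to Hz: -0.5 * exp(a_logscale)."""
        a_eff = self.a.copy()
        np.fill_diagonal(a_eff, -0.5 * np.exp(np.diag(self.a)))
        return a_eff

    @property
    def self_connections_hz(self) -> np.ndarray:
        return -0.5 * np.exp(np.diag(self.a))

    def masked(self, structure: NetworkStructure) -> "DCMParameters":
        """Zero every entry the structure's masks disallow.

        The diagonal of ``a`` (log-scale self-connections) is kept:
        self-connections are always present.
        """
        a = self.a.copy()
        off = ~np.eye(3, dtype=bool)
        a[off] *= structure.a_mask[off]
        b = {}
        for name, bm in self.b.items():
            mask = structure.b_masks.get(name)
            b[name] = bm * mask if mask is not None else np.zeros((3, 3))
        c = self.c * structure.c_mask
        return replace(self, a=a, b=b, c=c)

    @classmethod
    def zeros(cls, modulators: tuple[str, ...] = ("faces",), **kwargs) -> "DCMParameters":
        """All couplings zero (a_logscale 0 ⇒ self-connections -0.5 Hz)."""
        return cls(
            a=np.zeros((3, 3)),
            b={m: np.zeros((3, 3)) for m in modulators},
            c=np.zeros(3),
            **kwargs,
        )
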