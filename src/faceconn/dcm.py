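"""Bayesian inversion of one DCM: variational Laplace under shrinkage priors.

The model class :class:`DCM` pairs one session's BOLD series and design
with one candidate network structure; :meth:`DCM.fit` maximizes the
variational free energy

    F = accuracy - complexity
      = E_q[ln p(y | theta, lambda)] - KL(q(theta) || p(theta)) - KL(q(h) || p(h))

over a fixed-form Gaussian posterior q(theta) by damped Gauss-Newton
ascent (Levenberg-style: the damping grows when a proposed step lowers F
and shrinks when it raises it, so the recorded F trace of accepted steps
is non-decreasing by construction). Observation noise is modelled as
i.i.d. Gaussian per region with a log-precision hyperparameter h_r under
a Gaussian hyperprior, updated by Newton steps inside each iteration.

F approximates the log model evidence and is the default model-comparison
criterion; AIC and BIC are also computed from the posterior-mode
log-likelihood as alternative (log-evidence-scale) criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from .model_space import EDGE_BITS, ModelSpace, NetworkStructure
from .params import DCMParameters, HemodynamicConstants
from .regions import DEFAULT_REGIONS
from .simulate import BOLDTimeSeries, StimulusDesign

LN2PI = float(np.log(2.0 * np.pi))

#: cap on the noise log-precision; exactly noise-free data would otherwise
#: drive h to +inf
H_MAX = 32.0
H_MIN = -16.0


class InversionError(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian shrinkage priors by parameter class.

    Endogenous (A) couplings get tighter priors than modulatory (B)
    couplings: the endogenous backbone is assumed close to zero a priori
    while condition effects are comparatively unconstrained. All prior
    means are zero (a_logscale 0 corresponds to a -0.5 Hz
    self-connection). The observation-noise hyperprior is Gaussian on
    the per-region log precision.
    """

    var_a_off: float = 1.0 / 16.0
    var_a_logscale: float = 1.0 / 64.0
    var_b: float = 1.0
    var_c: float = 1.0
    var_eps: float = 1.0 / 64.0
    var_tau: float = 1.0 / 64.0
    h_mean: float = 4.0
    h_var: float = 4.0

    def __post_init__(self) -> None:
        for name in ("var_a_off", "var_a_logscale", "var_b", "var_c", "var_eps", "var_tau", "h_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InversionSettings:
    """Numerical controls of the variational scheme."""

    method: str = "rk4"               # integrator for predictions
    microtime_ratio: int = 16         # microtime bins per scan
    max_iter: int = 96
    tol: float = 1e-3                 # convergence: dF below tol ...
    tol_consecutive: int = 3          # ... for this many accepted steps
    fd_step: float = 1e-3             # finite-difference step
    damping0: float = 1.0 / 64.0
    damping_max: float = 1e7
    ridge: float = 1e-8               # curvature regularization
    state_bound: float = 1e3
    central_final_jacobian: bool = True
    # multi-start: the free-energy surface is multimodal; extra starts
    # perturb the coupling parameters deterministically and the best
    # final F wins
    n_starts: int = 3
    restart_scale: float = 0.25
    restart_seed: int = 74_321        # data-independent, fixed


@dataclass(frozen=True)
class ParamLayout:
    """Mapping between the free-parameter vector and the full parameter set."""

    kind: np.ndarray      # int8 codes, see _core
    ii: np.ndarray
    jj: np.ndarray
    mm: np.ndarray
    labels: tuple[tuple[str, str, str, str], ...]   # (matrix, source, target, input)
    prior_mean: np.ndarray
    prior_var: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)


def build_layout(structure: NetworkStructure, modulators: tuple[str, ...],
                 priors: PriorSpec) -> ParamLayout:
    """Free parameters of one structure, in canonical order.

    Order: A off-diagonal (edge-bit order), a_logscale (3), B per
    modulator (edge-bit order), C, epsilon log-deviations (3), tau
    log-deviations (3). Only mask-admitted entries are free.
    """
    labels = structure.regions.labels
    kind, ii, jj, mm, labs, p_mean, p_var = [], [], [], [], [], [], []

    def add(k, i, j, m, lab, var):
        kind.append(k); ii.append(i); jj.append(j); mm.append(m)
        labs.append(lab); p_mean.append(0.0); p_var.append(var)

    for src, tgt in EDGE_BITS:
        if structure.a_mask[tgt, src]:
            add(_core.K_A_OFF, tgt, src, 0, ("A", labels[src], labels[tgt], ""), priors.var_a_off)
    for r in range(3):
        add(_core.K_A_DIAG, r, r, 0, ("Aself", labels[r], labels[r], ""), priors.var_a_logscale)
    for m_idx, mod in enumerate(modulators):
        bmask = structure.b_masks.get(mod)
        if bmask is None:
            continue
        for src, tgt in EDGE_BITS:
            if bmask[tgt, src]:
                add(_core.K_B, tgt, src, m_idx, ("B", labels[src], labels[tgt], mod), priors.var_b)
    for r in range(3):
        if structure.c_mask[r]:
            add(_core.K_C, r, 0, 0, ("C", "input", labels[r], "faces"), priors.var_c)
    for r in range(3):
        add(_core.K_EPS, r, r, 0, ("Heps", labels[r], labels[r], ""), priors.var_eps)
    for r in range(3):
        add(_core.K_TAU, r, r, 0, ("Htau", labels[r], labels[r], ""), priors.var_tau)

    return ParamLayout(
        kind=np.asarray(kind, dtype=np.int8),
        ii=np.asarray(ii, dtype=np.int8),
        jj=np.asarray(jj, dtype=np.int8),
        mm=np.asarray(mm, dtype=np.int8),
        labels=tuple(labs),
        prior_mean=np.asarray(p_mean),
        prior_var=np.asarray(p_var),
    )


@dataclass
class DCMResults:
    """Posterior summary of one subject-session x model inversion."""

    model_id: int
    labels: tuple[tuple[str, str, str, str], ...]
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    log_likelihood: float
    aic: float
    bic: float
    n_params: int
    n_scans: int
    h: np.ndarray                      # noise log-precision per region
    converged: bool
    n_iter: int
    f_trace: list[float] = field(default_factory=list)

    @property
    def final_delta_f(self) -> float:
        if len(self.f_trace) < 2:
            return float("nan")
        return self.f_trace[-1] - self.f_trace[-2]

    def param_dict(self) -> dict[tuple[str, str, str, str], float]:
        """Posterior means keyed by (matrix, source, target, input)."""
        return {lab: float(v) for lab, v in zip(self.labels, self.posterior_mean)}

    def param_sd(self) -> dict[tuple[str, str, str, str], float]:
        sd = np.sqrt(np.clip(np.diag(self.posterior_cov), 0.0, None))
        return {lab: float(v) for lab, v in zip(self.labels, sd)}

    def plot_trace(self, ax=None):
        """Accepted free-energy trace of the winning ascent."""
        import matplotlib.pyplot as plt
        if ax is None:
            _fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(self.f_trace, marker="o", ms=3)
        ax.set_xlabel("accepted step")
        ax.set_ylabel("free energy F")
        ax.set_title(f"model #{self.model_id}")
        return ax

    def summary(self) -> str:
        lines = [
            f"DCM inversion, model #{self.model_id}",
            f"  free energy F = {self.free_energy:.3f}   AIC = {self.aic:.3f}   BIC = {self.bic:.3f}",
            f"  free parameters: {self.n_params}, scans: {self.n_scans}, "
            f"iterations: {self.n_iter}, converged: {self.converged}",
            f"  {'parameter':<28s}{'mean':>10s}{'sd':>10s}",
        ]
        sds = self.param_sd()
        for lab, mean in self.param_dict().items():
            matrix, src, tgt, inp = lab
            name = f"{matrix} {src}->{tgt}" + (f" [{inp}]" if inp and matrix == "B" else "")
            lines.append(f"  {name:<28s}{mean:>10.4f}{sds[lab]:>10.4f}")
        return "\n".join(lines)


def information_criteria(results: DCMResults) -> tuple[float, float]:
    """(AIC, BIC) on the log-evidence scale (larger is better).

    AIC = ln p(y|theta_map) - k; BIC = ln p(y|theta_map) - (k/2) ln(n_scans).
    The three criteria (F, AIC, BIC) need not agree on model ranking and
    are returned without reconciliation.
    """
    return results.aic, results.bic


class DCM:
    """One session's data + design + candidate structure, ready to fit.

    Parameters
    ----------
    data : BOLDTimeSeries
        Mean-centered region time series.
    design : StimulusDesign
        Sampled inputs on the microtime grid; must contain every
        modulator the structure's B-masks reference.
    structure : NetworkStructure
        Binary A/B/C masks of the candidate model.
    priors, settings : optional
        Shrinkage priors and numerical controls.
    """

    def __init__(self, data: BOLDTimeSeries, design: StimulusDesign,
                 structure: NetworkStructure, priors: PriorSpec | None = None,
                 settings: InversionSettings | None = None,
                 hemo: HemodynamicConstants | None = None):
        self.data = data
        self.design = design
        self.structure = structure
        self.priors = priors or PriorSpec()
        self.settings = settings or InversionSettings()
        self.hemo = hemo or HemodynamicConstants()

        ratio = data.tr / design.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise InversionError(f"tr ({data.tr}) must be an integer multiple of design dt ({design.dt})")
        self.ratio = int(round(ratio))
        if data.n_scans * self.ratio > design.n_micro:
            raise InversionError("design too short for the data")
        missing = [m for m in structure.b_masks if m not in design.inputs]
        if missing:
            raise InversionError(f"structure references modulators absent from design: {missing}")
        self.modulators = tuple(n for n in design.input_names if n in structure.b_masks)
        self.layout = build_layout(structure, self.modulators, self.priors)

    # -- forward-model plumbing -------------------------------------------

    def _sim_args(self):
        lay = self.layout
        h = self.hemo
        n_mod = max(1, len(self.design.input_names))
        u = self.design.input_matrix()
        return dict(
            kind=lay.kind, ii=lay.ii, jj=lay.jj, mm=lay.mm,
            a_base=np.zeros((3, 3)), b_base=np.zeros((u.shape[1], 3, 3)),
            c_base=np.zeros(3), eps_base=np.zeros(3), tau_base=np.zeros(3),
            u=u, dt=self.design.dt, ratio=self.ratio, n_scans=self.data.n_scans,
            kappa=h.kappa, gamma=h.gamma, tau0=h.tau, alpha=h.alpha, e0=h.e0,
            eps0=h.epsilon, v0=h.v0, k1c=h.k1, k2c=h.k2, k3c=h.k3,
            method={"rk4": _core.METHOD_RK4, "euler": _core.METHOD_EULER}[self.settings.method],
            bound=self.settings.state_bound,
        )

    def predict(self, theta: np.ndarray) -> np.ndarray | None:
        """Mean-centered predicted BOLD; None if the trajectory diverged."""
        a = self._sim_args()
        y, status = _core.predict_from_theta(theta, a["kind"], a["ii"], a["jj"], a["mm"],
                                             a["a_base"], a["b_base"], a["c_base"],
                                             a["eps_base"], a["tau_base"], a["u"], a["dt"],
                                             a["ratio"], a["n_scans"], a["kappa"], a["gamma"],
                                             a["tau0"], a["alpha"], a["e0"], a["eps0"], a["v0"],
                                             a["k1c"], a["k2c"], a["k3c"], a["method"], a["bound"])
        return None if status != _core.STATUS_OK else y

    def _jacobian(self, theta: np.ndarray, y0: np.ndarray | None = None,
                  central: bool = False) -> np.ndarray | None:
        a = self._sim_args()
        if central or y0 is None:
            jac, status = _core.jacobian_fd(theta, a["kind"], a["ii"], a["jj"], a["mm"],
                                            a["a_base"], a["b_base"], a["c_base"],
                                            a["eps_base"], a["tau_base"], a["u"], a["dt"],
                                            a["ratio"], a["n_scans"], a["kappa"], a["gamma"],
                                            a["tau0"], a["alpha"], a["e0"], a["eps0"], a["v0"],
                                            a["k1c"], a["k2c"], a["k3c"], a["method"], a["bound"],
                                            self.settings.fd_step)
            return None if status != _core.STATUS_OK else jac
        # one-sided differences reusing the baseline prediction
        p = len(theta)
        n = self.data.n_scans
        jac = np.empty((n * 3, p))
        h = self.settings.fd_step
        for idx in range(p):
            th = theta.copy()
            th[idx] += h
            y_hi = self.predict(th)
            if y_hi is None:
                return None
            jac[:, idx] = ((y_hi - y0) / h).T.reshape(-1)
        return jac

    # -- free energy pieces -----------------------------------------------

    def _free_energy(self, theta: np.ndarray, y: np.ndarray, jac: np.ndarray,
                     h: np.ndarray):
        """Evaluate F at theta with its own Laplace posterior.

        Returns (F, sigma (posterior covariance), h_new, extras).
        The noise log-precisions are re-optimized (Newton) inside.
        """
        pr = self.priors
        n = self.data.n_scans
        p = len(theta)
        pi_prior = 1.0 / self.layout.prior_var
        d = theta - self.layout.prior_mean
        resid = (self.data.y - y)            # n x 3
        sse = np.sum(resid * resid, axis=0)  # per region

        jr = [jac[r * n:(r + 1) * n, :] for r in range(3)]
        jtj = [j.T @ j for j in jr]

        h = h.copy()
        for _ in range(4):
            lam = np.exp(np.clip(h, H_MIN, H_MAX))
            prec = sum(lam[r] * jtj[r] for r in range(3)) + np.diag(pi_prior)
            prec[np.diag_indices_from(prec)] += self.settings.ridge
            sigma = np.linalg.inv(prec)
            trace_r = np.array([np.sum(jtj[r] * sigma) for r in range(3)])
            g_r = sse + trace_r
            # Newton on each region's log precision
            grad = -0.5 * (lam * g_r - n) - (h - pr.h_mean) / pr.h_var
            hess = -0.5 * lam * g_r - 1.0 / pr.h_var
            h = np.clip(h - grad / hess, H_MIN, H_MAX)

        lam = np.exp(np.clip(h, H_MIN, H_MAX))
        prec = sum(lam[r] * jtj[r] for r in range(3)) + np.diag(pi_prior)
        prec[np.diag_indices_from(prec)] += self.settings.ridge
        sigma = np.linalg.inv(prec)
        sigma = 0.5 * (sigma + sigma.T)
        trace_r = np.array([np.sum(jtj[r] * sigma) for r in range(3)])
        g_r = sse + trace_r

        accuracy = -0.5 * float(np.sum(lam * g_r - n * h + n * LN2PI))
        sign, logdet_sigma = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf, sigma, h, None
        logdet_prior = float(np.sum(np.log(self.layout.prior_var)))
        kl_theta = 0.5 * (float(pi_prior @ np.diag(sigma)) + float(pi_prior @ (d * d))
                          - p + logdet_prior - logdet_sigma)
        var_h = 1.0 / (0.5 * lam * g_r + 1.0 / pr.h_var)
        kl_h = float(np.sum(0.5 * ((h - pr.h_mean) ** 2 / pr.h_var + var_h / pr.h_var
                                   - 1.0 - np.log(var_h / pr.h_var))))
        f = accuracy - kl_theta - kl_h
        extras = dict(lam=lam, sse=sse, resid=resid, kl_theta=kl_theta, kl_h=kl_h,
                      accuracy=accuracy)
        return f, sigma, h, extras

    # -- the fit loop ------------------------------------------------------

    def fit(self, extra_starts: list[np.ndarray] | None = None) -> DCMResults:
        """Maximize F by damped Gauss-Newton with deterministic multi-start.

        ``extra_starts`` adds caller-supplied start vectors (e.g. warm
        starts from a richer model's posterior) to the standard ones;
        the run with the highest final F wins.
        """
        st = self.settings
        # extra starts consume the start budget: n_starts is the total
        # number of ascents, supplied starts first, then the standard
        # prior-mean start and deterministic perturbations of it
        starts = [np.asarray(t, dtype=float) for t in (extra_starts or [])]
        starts.append(self.layout.prior_mean.copy())
        for s_idx in range(1, max(1, st.n_starts)):
            theta0 = self.layout.prior_mean.copy()
            rng = np.random.default_rng([st.restart_seed, s_idx])
            coupling = np.isin(self.layout.kind,
                               [_core.K_A_OFF, _core.K_B, _core.K_C])
            theta0[coupling] += rng.normal(0.0, st.restart_scale,
                                           size=int(coupling.sum()))
            starts.append(theta0)
        starts = starts[:max(max(1, st.n_starts), len(extra_starts or []))]
        runs = []
        for theta0 in starts:
            run = self._fit_from(theta0)
            if run is not None:
                runs.append(run)
        if not runs and extra_starts:
            # supplied starts all inadmissible: fall back to the prior mean
            run = self._fit_from(self.layout.prior_mean.copy())
            if run is not None:
                runs.append(run)
        if not runs:
            raise InversionError("no start produced an admissible trajectory")
        f_best, best, f_trace, it, converged = max(runs, key=lambda r: r[0])
        return self._package(f_best, best, f_trace, it, converged)

    def _fit_from(self, theta0: np.ndarray):
        """One damped Gauss-Newton ascent from a given start.

        Returns None when the start's trajectory is inadmissible (the
        caller falls back to the remaining starts).
        """
        st = self.settings
        lay = self.layout
        n = self.data.n_scans
        pi_prior = 1.0 / lay.prior_var

        theta = theta0.copy()
        h = np.full(3, self.priors.h_mean)
        y = self.predict(theta)
        if y is None:
            return None
        jac = self._jacobian(theta, y0=y)
        if jac is None:
            return None
        f_best, sigma, h, extras = self._free_energy(theta, y, jac, h)
        if not np.isfinite(f_best):
            return None
        best = dict(theta=theta, y=y, jac=jac, sigma=sigma, h=h, extras=extras)

        f_trace = [f_best]
        damping = st.damping0
        small_steps = 0
        converged = False
        it = 0
        while it < st.max_iter:
            it += 1
            jr = best["jac"]
            lam = best["extras"]["lam"]
            resid_vec = best["extras"]["resid"].T.reshape(-1)
            lam_rows = np.repeat(lam, n)
            grad = jr.T @ (lam_rows * resid_vec) - pi_prior * (best["theta"] - lay.prior_mean)
            prec = (jr.T * lam_rows) @ jr + np.diag(pi_prior)
            # Levenberg damping scales the curvature diagonal
            prec_d = prec + damping * np.diag(np.diag(prec))
            try:
                step = np.linalg.solve(prec_d, grad)
            except np.linalg.LinAlgError:
                prec_d[np.diag_indices_from(prec_d)] += 1e-6
                step = np.linalg.solve(prec_d, grad)

            cand = best["theta"] + step
            y_c = self.predict(cand)
            accepted = False
            if y_c is not None:
                jac_c = self._jacobian(cand, y0=y_c)
                if jac_c is not None:
                    f_c, sigma_c, h_c, extras_c = self._free_energy(cand, y_c, jac_c, best["h"])
                    if np.isfinite(f_c) and f_c > f_best:
                        delta = f_c - f_best
                        f_best = f_c
                        best = dict(theta=cand, y=y_c, jac=jac_c, sigma=sigma_c,
                                    h=h_c, extras=extras_c)
                        f_trace.append(f_best)
                        damping = max(damping / 4.0, 1e-8)
                        accepted = True
                        small_steps = small_steps + 1 if delta < st.tol else 0
                        if small_steps >= st.tol_consecutive:
                            converged = True
                            break
            if not accepted:
                damping *= 8.0
                if damping > st.damping_max:
                    # no admissible ascent direction left: treat as converged
                    converged = len(f_trace) >= 2
                    break
        return f_best, best, f_trace, it, converged

    def _package(self, f_best, best, f_trace, it, converged) -> DCMResults:
        st = self.settings
        lay = self.layout
        p = lay.n
        n = self.data.n_scans
        if st.central_final_jacobian:
            jac_f = self._jacobian(best["theta"], central=True)
            if jac_f is not None:
                _f, sigma_f, h_f, ex_f = self._free_energy(best["theta"], best["y"], jac_f, best["h"])
                if np.isfinite(_f):
                    # refined Laplace curvature at the optimum; F itself keeps
                    # the accepted-trace value for monotonicity of the record
                    best["sigma"], best["h"], best["extras"] = sigma_f, h_f, ex_f

        lam = best["extras"]["lam"]
        sse = best["extras"]["sse"]
        log_lik = -0.5 * float(np.sum(lam * sse - n * np.log(lam) + n * LN2PI))
        aic = log_lik - p
        bic = log_lik - 0.5 * p * float(np.log(n))

        return DCMResults(
            model_id=self.structure.id,
            labels=lay.labels,
            posterior_mean=best["theta"],
            posterior_cov=best["sigma"],
            free_energy=float(f_trace[-1]),
            log_likelihood=log_lik,
            aic=float(aic),
            bic=float(bic),
            n_params=p,
            n_scans=n,
            h=best["h"],
            converged=converged,
            n_iter=it,
            f_trace=[float(v) for v in f_trace],
        )


def invert(data: BOLDTimeSeries, design: StimulusDesign, structure: NetworkStructure,
           priors: PriorSpec | None = None,
           settings: InversionSettings | None = None) -> DCMResults:
    """Functional wrapper: ``DCM(data, design, structure, ...).fit()``."""
    return DCM(data, design, structure, priors=priors, settings=settings).fit()


def fit_model_space(data: BOLDTimeSeries, design: StimulusDesign, space: ModelSpace,
                    priors: PriorSpec | None = None,
                    settings: InversionSettings | None = None,
                    n_jobs: int = 1, warm_start: bool = True) -> list[DCMResults]:
    """Invert every structure of a model space for one session.

    With ``warm_start`` (default) the fully parameterized structure
    (last in the space) is inverted first and every sparser structure
    receives its masked posterior as an additional start vector — the
    nested optima are excellent initializations and this both speeds up
    and stabilizes the batch. Results are ordered by model id and
    independent of ``n_jobs``. Per-model failures are re-raised with the
    model id attached.
    """
    if len(space) == 0:
        raise ValueError("model space is empty")

    warm: dict[tuple, float] | None = None
    if warm_start:
        full = space.structures[-1]
        try:
            full_res = DCM(data, design, full, priors=priors, settings=settings).fit()
            warm = dict(zip(full_res.labels, full_res.posterior_mean))
        except InversionError:
            warm = None

    def one(structure: NetworkStructure) -> DCMResults:
        try:
            model = DCM(data, design, structure, priors=priors, settings=settings)
            extra = None
            if warm is not None:
                theta0 = model.layout.prior_mean.copy()
                for i, lab in enumerate(model.layout.labels):
                    if lab in warm:
                        theta0[i] = warm[lab]
                extra = [theta0]
            return model.fit(extra_starts=extra)
        except Exception as exc:
            raise InversionError(f"model #{structure.id}: {exc}") from exc

    structures = space.structures if warm is None else space.structures[:-1]
    if n_jobs == 1:
        results = [one(s) for s in structures]
    else:
        from joblib import Parallel, delayed
        results = list(Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in structures))
    if warm is not None:
        results.append(full_res)
    return results
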