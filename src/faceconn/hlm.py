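"""Cross-study pooling of connectivity parameters.

Two inference layers operate on the long-format cohort table of
subject-session connection estimates (the BMA point estimates):

* per-study two-sided one-sample t-tests per connection, Bonferroni
  corrected within each matrix (self-connections are excluded — they are
  negative by construction);
* one hierarchical linear model (HLM) per connection and matrix,

      y_i = β0 + β1·AvsB_i + β2·ABvsC_i + β3·ABCvsD_i + γ·MvsP_i + u_i + ε_i,

  with a participant random intercept u_i ~ N(0, σu²) and residual
  ε_i ~ N(0, σε²), fitted by restricted maximum likelihood profiled over
  the single variance ratio ψ = σu²/σε². The study and hormone factors
  enter through zero-sum Helmert/contrast codes, so the fixed intercept
  β0 is the average effect across studies — the quantity pooled into the
  "revised" group model. Matrices observed in fewer studies drop the
  inapplicable terms (no hormone or C/D contrasts for the emotion
  modulator; intercept-only for fame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .regions import DEFAULT_REGIONS

logger = logging.getLogger(__name__)

MATRICES = ("A", "B:faces", "B:emotion", "B:fame", "C")


def convert_self_connections(a_logscale: float | np.ndarray) -> float | np.ndarray:
    """Self-connection in Hz from its log-scale parameter: -0.5 * exp(x).

    Strictly negative and monotone decreasing in the input; 0 maps to
    -0.5 Hz.
    """
    x = np.asarray(a_logscale, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("a_logscale must be finite")
    out = -0.5 * np.exp(x)
    return float(out) if out.ndim == 0 else out


def cohort_table(bma_by_session: dict[str, "BMAResult"],
                 covariates: pd.DataFrame) -> pd.DataFrame:
    """Long-format table: one row per (connection, subject-session).

    Connection keys: matrix in {A, B:faces, B:emotion, B:fame, C},
    source, target. Self-connections are converted to Hz. Hemodynamic
    nuisance parameters are not connectivity and are omitted.
    """
    cov = covariates.set_index(
        covariates["study"] + "/" + covariates["participant"] + "/" + covariates["session"].astype(str))
    rows = []
    for sid, bma in bma_by_session.items():
        if sid not in cov.index:
            raise KeyError(f"session {sid!r} missing from covariates")
        meta = cov.loc[sid]
        for (matrix, src, tgt, inp), value in bma.params.items():
            if matrix == "A":
                key = "A"
            elif matrix == "Aself":
                key = "A"
                value = convert_self_connections(value)
            elif matrix == "B":
                key = f"B:{inp}"
            elif matrix == "C":
                key = "C"
            else:
                continue  # hemodynamic nuisance parameters
            rows.append(dict(matrix=key, source=src, target=tgt, value=float(value),
                             study=meta["study"], participant=meta["participant"],
                             session=int(meta["session"]), hormone=meta["hormone"]))
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        raise ValueError("cohort table has missing covariates")
    return df


# -- contrast coding -------------------------------------------------------

@dataclass(frozen=True)
class ContrastCoding:
    """Zero-sum contrast codes for the study and hormone factors.

    Sequential Helmert-style contrasts: each new study is compared with
    the (equally weighted) average of the previously entered ones, so
    the intercept is interpretable as the average across studies.
    """

    avsb: dict = field(default_factory=lambda: {"A": 0.5, "B": -0.5, "C": 0.0, "D": 0.0})
    abvsc: dict = field(default_factory=lambda: {"A": 0.25, "B": 0.25, "C": -0.5, "D": 0.0})
    abcvsd: dict = field(default_factory=lambda: {"A": 1 / 6, "B": 1 / 6, "C": 1 / 6, "D": -0.5})
    mvsp: dict = field(default_factory=lambda: {"mid-luteal": 0.5, "early-follicular": -0.5, "none": 0.0})

    def study_columns(self) -> dict[str, dict]:
        return {"AvsB": self.avsb, "ABvsC": self.abvsc, "ABCvsD": self.abcvsd}


DEFAULT_CODING = ContrastCoding()


# -- per-study t-tests -----------------------------------------------------

def _study_group(row) -> str:
    """Grouping key for reporting: repeated-measures studies split by session."""
    return row["study"] if row["hormone"] == "none" else f"{row['study']}{row['session']}"


def study_t_tests(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided one-sample t-tests per connection, per matrix, per study.

    Hormone-manipulation studies (sessions with a hormone phase) are
    reported per session. Self-connections (source == target) are
    excluded. The per-matrix Bonferroni threshold is alpha / n where n is
    the number of inter-regional connections tested in that matrix.
    Zero-variance samples are flagged ``degenerate`` and given the exact
    limiting p (0 for a nonzero mean, 1 otherwise) rather than NaN.
    """
    t = table[table["source"] != table["target"]].copy()
    t["group"] = t.apply(_study_group, axis=1)
    rows = []
    for (group, matrix), sub in t.groupby(["group", "matrix"], sort=True):
        conns = sub.groupby(["source", "target"], sort=True)
        n_tests = conns.ngroups
        thresh = alpha / n_tests
        for (src, tgt), cell in conns:
            vals = cell["value"].to_numpy()
            if len(vals) < 2:
                raise ValueError(
                    f"need >= 2 observations for {matrix} {src}->{tgt} in group {group}")
            mean = float(np.mean(vals))
            degenerate = bool(np.var(vals) < 1e-24)
            if degenerate:
                tstat = np.inf * np.sign(mean) if mean != 0 else 0.0
                p = 0.0 if mean != 0 else 1.0
            else:
                res = stats.ttest_1samp(vals, 0.0)
                tstat, p = float(res.statistic), float(res.pvalue)
            rows.append(dict(group=group, matrix=matrix, source=src, target=tgt,
                             n=len(vals), mean=mean, t=tstat, p=p,
                             n_tests=n_tests, threshold=thresh,
                             significant=bool(p < thresh), degenerate=degenerate))
    return pd.DataFrame(rows)


# -- the random-intercept model -------------------------------------------

class HLMError(RuntimeError):
    pass


@dataclass
class HLMFit:
    """REML fit of one connection's random-intercept model."""

    params: pd.Series          # fixed effects
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    sigma_u2: float
    sigma_e2: float
    n_obs: int
    n_groups: int
    converged: bool
    degenerate: bool
    method: str = "reml"
    use_t: bool = True

    def summary(self) -> str:
        lines = [f"Random-intercept HLM ({self.method.upper()}), n={self.n_obs}, "
                 f"participants={self.n_groups}",
                 f"  sigma_u^2={self.sigma_u2:.5f}  sigma_e^2={self.sigma_e2:.5f}  "
                 f"df={self.df_resid:.0f}" + ("  [degenerate]" if self.degenerate else ""),
                 f"  {'term':<12s}{'estimate':>12s}{'SE':>12s}{'t':>10s}{'p':>12s}"]
        for name in self.params.index:
            lines.append(f"  {name:<12s}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                         f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>12.3g}")
        return "\n".join(lines)


class RandomInterceptHLM:
    """y = X beta + u_participant + eps, single variance ratio, REML.

    The variance ratio psi = sigma_u^2 / sigma_e^2 is profiled: for any
    psi the fixed effects are the exact GLS solution, so the outer
    problem is a 1-D REML criterion minimized over log(psi). Intercept
    and slope p-values use a t reference with between-within residual
    degrees of freedom n_obs - n_fixed - n_participants + 1 (switchable
    to a normal reference with ``use_t=False``).
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, groups: np.ndarray,
                 names: list[str], use_t: bool = True):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.names = list(names)
        self.use_t = use_t
        if self.x.ndim != 2 or self.x.shape[0] != len(self.y):
            raise HLMError("design matrix / response shape mismatch")
        rank = np.linalg.matrix_rank(self.x)
        if rank < self.x.shape[1]:
            culprits = _collinear_columns(self.x, self.names)
            raise HLMError(f"rank-deficient design; collinear terms: {culprits}")
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise HLMError("need >= 2 participants")
        self._group_rows = [np.flatnonzero(codes == g) for g in range(self.n_groups)]

    # GLS pieces for V = I + psi * Z Z' (block diagonal per group)
    def _gls(self, psi: float):
        p = self.x.shape[1]
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet_v = 0.0
        for rows in self._group_rows:
            xg = self.x[rows]
            yg = self.y[rows]
            ng = len(rows)
            c = psi / (1.0 + psi * ng)
            sx = xg.sum(axis=0)
            sy = yg.sum()
            xtvx += xg.T @ xg - c * np.outer(sx, sx)
            xtvy += xg.T @ yg - c * sx * sy
            ytvy += yg @ yg - c * sy * sy
            logdet_v += np.log1p(psi * ng)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = float(ytvy - beta @ xtvy)
        return beta, xtvx, rss, logdet_v

    def _reml_crit(self, log_psi: float) -> float:
        psi = np.exp(log_psi)
        n, p = self.x.shape
        _beta, xtvx, rss, logdet_v = self._gls(psi)
        rss = max(rss, 1e-300)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(rss / (n - p)) + logdet_v + logdet_x

    def fit(self) -> HLMFit:
        n, p = self.x.shape
        y_var = float(np.var(self.y))
        degenerate = y_var < 1e-24
        if degenerate:
            beta, *_ = self._gls(0.0)
            psi, sigma_e2 = 0.0, 0.0
            converged = True
        else:
            res = optimize.minimize_scalar(self._reml_crit, bounds=(-14.0, 14.0),
                                           method="bounded",
                                           options={"xatol": 1e-10})
            converged = bool(res.success)
            # compare against the sigma_u^2 = 0 boundary
            crit0 = self._reml_crit(-np.inf) if False else None
            psi = float(np.exp(res.x))
            beta, xtvx, rss, _ = self._gls(psi)
            c_best = self._reml_crit(res.x)
            c_zero = _reml_crit_at_zero(self)
            if c_zero <= c_best:
                psi = 0.0
                beta, xtvx, rss, _ = self._gls(0.0)
            sigma_e2 = rss / (n - p)
        sigma_u2 = psi * sigma_e2

        if degenerate:
            bse = np.zeros(p)
            tvals = np.where(beta != 0, np.inf * np.sign(beta), 0.0)
            pvals = np.where(beta != 0, 0.0, 1.0)
            df = float(max(n - p - self.n_groups + 1, 1))
        else:
            _beta, xtvx, rss, _ = self._gls(psi)
            cov = sigma_e2 * np.linalg.inv(xtvx)
            bse = np.sqrt(np.diag(cov))
            tvals = beta / bse
            df = float(max(n - p - self.n_groups + 1, 1))
            if self.use_t:
                pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
            else:
                pvals = 2.0 * stats.norm.sf(np.abs(tvals))
            pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        idx = pd.Index(self.names)
        return HLMFit(params=pd.Series(beta, index=idx),
                      bse=pd.Series(bse, index=idx),
                      tvalues=pd.Series(tvals, index=idx),
                      pvalues=pd.Series(pvals, index=idx),
                      df_resid=df, sigma_u2=float(sigma_u2), sigma_e2=float(sigma_e2),
                      n_obs=n, n_groups=self.n_groups, converged=converged,
                      degenerate=degenerate, use_t=self.use_t)


def _reml_crit_at_zero(model: RandomInterceptHLM) -> float:
    n, p = model.x.shape
    _beta, xtvx, rss, _ = model._gls(0.0)
    rss = max(rss, 1e-300)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    return (n - p) * np.log(rss / (n - p)) + logdet_x if sign > 0 else np.inf


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    culprits = []
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(x[:, trial]) < len(trial):
            culprits.append(names[j])
        else:
            keep.append(j)
    return culprits


# -- per-connection model construction ------------------------------------

def _design_for_matrix(sub: pd.DataFrame, matrix: str,
                       coding: ContrastCoding) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design per matrix rules, dropping inapplicable terms.

    A, B:faces, C: all study contrasts + hormone. B:emotion: no hormone,
    only contrasts among emotion-carrying studies. B:fame: intercept only.
    Constant (zero-variance) candidate columns are dropped so the design
    stays full rank on partial cohorts.
    """
    n = len(sub)
    cols = [np.ones(n)]
    names = ["intercept"]
    if matrix == "B:fame":
        return np.column_stack(cols), names
    studies_present = set(sub["study"].unique())
    study_cols = coding.study_columns()
    if matrix == "B:emotion":
        study_cols = {"AvsB": coding.avsb}
    candidates = []
    for name, mapping in study_cols.items():
        if not set(mapping) >= studies_present:
            raise HLMError(f"contrast {name} lacks codes for studies {studies_present - set(mapping)}")
        candidates.append((name, sub["study"].map(mapping).to_numpy(dtype=float)))
    if matrix in ("A", "B:faces", "C"):
        candidates.append(("MvsP", sub["hormone"].map(coding.mvsp).to_numpy(dtype=float)))
    # sequential contrasts: keep a term only if it is non-constant and
    # linearly independent of the terms already entered
    for name, col in candidates:
        if np.var(col) <= 1e-24:
            continue
        trial = np.column_stack(cols + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            cols.append(col)
            names.append(name)
    return np.column_stack(cols), names


def fit_hlm(table: pd.DataFrame, coding: ContrastCoding = DEFAULT_CODING,
            use_t: bool = True) -> HLMFit:
    """Fit the random-intercept HLM on one connection's rows.

    ``table`` must be the cohort table restricted to a single
    (matrix, source, target) combination.
    """
    if table.empty:
        raise HLMError("empty table")
    matrices = table["matrix"].unique()
    conns = table[["matrix", "source", "target"]].drop_duplicates()
    if len(conns) != 1:
        raise HLMError(f"table must cover exactly one connection, got {len(conns)}")
    matrix = matrices[0]
    x, names = _design_for_matrix(table, matrix, coding)
    model = RandomInterceptHLM(table["value"].to_numpy(), x,
                               table["participant"].to_numpy(), names, use_t=use_t)
    return model.fit()


@dataclass
class RevisedModelReport:
    """Pooled (HLM) and per-study views of the cohort's connectivity."""

    pooled: pd.DataFrame
    per_study: pd.DataFrame
    alpha: float
    coding: ContrastCoding

    def significant_edges(self) -> pd.DataFrame:
        return self.pooled[self.pooled["significant"]].reset_index(drop=True)

    def to_dot(self) -> str:
        """GraphViz DOT export of the significant pooled connections."""
        lines = ["digraph revised_model {", "  rankdir=LR;"]
        for label in DEFAULT_REGIONS.labels:
            lines.append(f"  {label};")
        for _, row in self.significant_edges().iterrows():
            if row["source"] == "input":
                continue
            style = "solid" if row["estimate"] > 0 else "dashed"
            lines.append(
                f'  {row["source"]} -> {row["target"]} '
                f'[label="{row["matrix"]} {row["estimate"]:+.2f}", style={style}];')
        lines.append("}")
        return "\n".join(lines)

    def summary(self) -> str:
        sig = self.significant_edges()
        lines = [f"Revised model: {len(sig)} significant pooled connections "
                 f"(per-matrix Bonferroni at alpha={self.alpha})"]
        for _, row in sig.iterrows():
            lines.append(f"  {row['matrix']:<10s} {row['source']:>6s} -> {row['target']:<6s} "
                         f"{row['estimate']:+.3f}  (p={row['p']:.2e})")
        return "\n".join(lines)


def revised_model(table: pd.DataFrame, coding: ContrastCoding = DEFAULT_CODING,
                  alpha: float = 0.05, use_t: bool = True) -> RevisedModelReport:
    """Pooled intercept tests per connection with per-matrix Bonferroni.

    Runs one HLM per (matrix, source, target), flags intercepts whose p
    falls under alpha / n with n the number of inter-regional connections
    tested in that matrix, and pairs the pooled report with the
    per-study t-test report.
    """
    inter = table[table["source"] != table["target"]]
    rows = []
    for matrix, msub in inter.groupby("matrix", sort=True):
        conns = msub.groupby(["source", "target"], sort=True)
        n_tests = conns.ngroups
        thresh = alpha / n_tests
        for (src, tgt), cell in conns:
            try:
                fit = fit_hlm(cell, coding, use_t=use_t)
            except HLMError as exc:
                raise HLMError(f"{matrix} {src}->{tgt}: {exc}") from exc
            rows.append(dict(matrix=matrix, source=src, target=tgt,
                             estimate=float(fit.params["intercept"]),
                             se=float(fit.bse["intercept"]),
                             p=float(fit.pvalues["intercept"]),
                             df=fit.df_resid, sigma_u2=fit.sigma_u2,
                             sigma_e2=fit.sigma_e2, n_tests=n_tests,
                             threshold=thresh,
                             significant=bool(fit.pvalues["intercept"] < thresh),
                             degenerate=fit.degenerate))
    pooled = pd.DataFrame(rows)
    per_study = study_t_tests(table, alpha=alpha)
    return RevisedModelReport(pooled=pooled, per_study=per_study, alpha=alpha,
                              coding=coding)
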