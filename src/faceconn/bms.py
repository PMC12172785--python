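"""Group-level model comparison and per-subject model averaging.

Random-effects Bayesian model selection (RFX-BMS) treats the model
identity as a random variable across subjects: the population frequency
vector r of the K candidate models carries a Dirichlet posterior,
estimated by the variational scheme

    g_nk ∝ exp( lnE_nk + ψ(α_k) − ψ(Σ_j α_j) )        (subject n's model posterior)
    α_k  = α0 + Σ_n g_nk

iterated to convergence, where lnE is the log-evidence matrix (free
energy by default, AIC or BIC selectable) and ψ the digamma function.
Expected posterior model probabilities are α/Σα; the exceedance
probability of model k — the probability that k is more frequent in the
population than every competitor — is estimated by Monte-Carlo draws
from Dirichlet(α).

Bayesian model averaging (BMA) collapses one subject-session's model
space onto a single parameter set: posterior means are averaged across
all models, weighted by each model's posterior probability
(softmax of the evidences over the full space; parameters a model
excludes contribute zero for that model's weight share).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .dcm import DCMResults

logger = logging.getLogger(__name__)

CRITERIA = ("f", "aic", "bic")


@dataclass(frozen=True)
class EvidenceMatrix:
    """Log evidences: rows = subject-sessions, columns = model ids."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    model_ids: tuple[int, ...]
    criterion: str = "f"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("evidence must be 2-D (subjects x models)")
        if v.shape != (len(self.row_ids), len(self.model_ids)):
            raise ValueError("evidence shape does not match row/model ids")
        bad = np.argwhere(~np.isfinite(v))
        if bad.size:
            n, k = bad[0]
            raise ValueError(
                f"non-finite evidence for subject {self.row_ids[n]!r}, "
                f"model #{self.model_ids[k]}")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]


def evidence_matrix(results_by_session: dict[str, list[DCMResults]],
                    criterion: str = "f") -> EvidenceMatrix:
    """Assemble an evidence matrix from per-session inversion lists."""
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    attr = {"f": "free_energy", "aic": "aic", "bic": "bic"}[criterion]
    row_ids = tuple(results_by_session)
    model_ids = None
    rows = []
    for sid, results in results_by_session.items():
        ids = tuple(r.model_id for r in results)
        if model_ids is None:
            model_ids = ids
        elif ids != model_ids:
            raise ValueError(f"session {sid!r} covers a different model set")
        rows.append([getattr(r, attr) for r in results])
    return EvidenceMatrix(values=np.asarray(rows), row_ids=row_ids,
                          model_ids=model_ids, criterion=criterion)


@dataclass(frozen=True)
class BMSResult:
    """Random-effects model-selection summary for one group."""

    dirichlet_alpha: np.ndarray
    expected_probs: np.ndarray
    exceedance_probs: np.ndarray
    model_ids: tuple[int, ...]
    criterion: str
    draws: int
    seed: int
    subject_posteriors: np.ndarray = field(repr=False, default=None)

    @property
    def winning_model(self) -> int:
        """Model id with the highest expected probability (lowest id on ties)."""
        p = self.expected_probs
        best = int(np.argmax(p))
        ties = np.flatnonzero(np.isclose(p, p[best], rtol=0, atol=1e-12))
        if len(ties) > 1:
            logger.warning("BMS tie among models %s; reporting lowest id",
                           [self.model_ids[t] for t in ties])
            best = int(ties.min())
        return self.model_ids[best]

    def summary(self) -> str:
        lines = [f"RFX-BMS ({self.criterion.upper()}), {len(self.model_ids)} models; "
                 f"winner: #{self.winning_model}",
                 f"  {'model':>6s}{'alpha':>10s}{'P(post)':>10s}{'P(exc)':>10s}"]
        for k, mid in enumerate(self.model_ids):
            lines.append(f"  {mid:>6d}{self.dirichlet_alpha[k]:>10.3f}"
                         f"{self.expected_probs[k]:>10.4f}{self.exceedance_probs[k]:>10.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of posterior and exceedance probabilities per model."""
        import matplotlib.pyplot as plt
        if ax is None:
            _fig, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(len(self.model_ids))
        ax.bar(x - 0.2, self.expected_probs, width=0.4, label="posterior")
        ax.bar(x + 0.2, self.exceedance_probs, width=0.4, label="exceedance")
        ax.set_xticks(x)
        ax.set_xticklabels([str(m) for m in self.model_ids], fontsize=7)
        ax.set_xlabel("model")
        ax.set_ylabel("probability")
        ax.legend(frameon=False)
        return ax


def dirichlet_exceedance(alpha: np.ndarray, draws: int = 100_000,
                         seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet(alpha) vector.

    Component k's exceedance is the frequency with which a draw attains
    its maximum at k.
    """
    alpha = np.asarray(alpha, dtype=float)
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=draws)
    wins = np.argmax(samples, axis=1)
    return np.bincount(wins, minlength=len(alpha)) / draws


def rfx_bms(evidence: EvidenceMatrix, prior_alpha: float = 1.0,
            draws: int = 100_000, seed: int = 0,
            tol: float = 1e-9, max_iter: int = 10_000) -> BMSResult:
    """Variational Dirichlet scheme for random-effects model selection."""
    if evidence.n_subjects < 1 or evidence.n_models < 2:
        raise ValueError("need >= 1 subject and >= 2 models")
    ln_e = evidence.values - evidence.values.max(axis=1, keepdims=True)
    k = evidence.n_models
    alpha = np.full(k, prior_alpha, dtype=float)
    for _ in range(max_iter):
        log_u = ln_e + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = prior_alpha + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    exceedance = dirichlet_exceedance(alpha, draws=draws, seed=seed)
    return BMSResult(dirichlet_alpha=alpha, expected_probs=expected,
                     exceedance_probs=exceedance, model_ids=evidence.model_ids,
                     criterion=evidence.criterion, draws=draws, seed=seed,
                     subject_posteriors=g)


@dataclass(frozen=True)
class BMAResult:
    """Probability-weighted average parameters for one subject-session."""

    session_id: str
    model_ids: tuple[int, ...]
    weights: np.ndarray
    params: dict[tuple[str, str, str, str], float]

    def as_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.params.keys(),
                                        names=["matrix", "source", "target", "input"])
        return pd.Series(list(self.params.values()), index=idx, name=self.session_id)


def bma_weights(free_energies: np.ndarray) -> np.ndarray:
    """Posterior model probabilities from log evidences (softmax)."""
    f = np.asarray(free_energies, dtype=float)
    w = np.exp(f - f.max())
    return w / w.sum()


def subject_bma(inversions: list[DCMResults], session_id: str = "") -> BMAResult:
    """Average posterior means over the full model space (no Occam's window).

    Weights are the normalized evidences exp(F - max F); a parameter
    absent from a model contributes 0 under that model's weight.
    """
    if not inversions:
        raise ValueError("no inversions to average")
    ids = [r.model_id for r in inversions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids in inversion list")
    f = np.array([r.free_energy for r in inversions])
    w = bma_weights(f)
    keys: list = []
    for r in inversions:
        for lab in r.labels:
            if lab not in keys:
                keys.append(lab)
    avg = {key: 0.0 for key in keys}
    for weight, r in zip(w, inversions):
        pd_r = r.param_dict()
        for key in keys:
            avg[key] += weight * pd_r.get(key, 0.0)
    return BMAResult(session_id=session_id, model_ids=tuple(ids), weights=w,
                     params=avg)


def study_bms_report(evidence_by_group: dict[str, EvidenceMatrix],
                     prior_alpha: float = 1.0, draws: int = 100_000,
                     seed: int = 0) -> tuple[dict[str, BMSResult], pd.DataFrame]:
    """One RFX-BMS per group (study, or study x session for repeated designs).

    Returns the per-group results plus a tidy table with the winning
    model and both probability vectors' maxima.
    """
    results: dict[str, BMSResult] = {}
    rows = []
    for group, ev in evidence_by_group.items():
        res = rfx_bms(ev, prior_alpha=prior_alpha, draws=draws, seed=seed)
        results[group] = res
        win = res.winning_model
        k = res.model_ids.index(win)
        rows.append(dict(group=group, n_subjects=ev.n_subjects,
                         winning_model=win,
                         posterior_prob=res.expected_probs[k],
                         exceedance_prob=res.exceedance_probs[k],
                         criterion=ev.criterion))
    return results, pd.DataFrame(rows)
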