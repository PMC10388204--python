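"""Per-trace Gaussian-emission hidden Markov modeling.

Each smFRET efficiency trajectory is modeled as a K-state HMM with
Normal emissions on the efficiency axis.  Two fitting routes are
provided:

* :func:`baum_welch` — maximum likelihood EM (guaranteed non-decreasing
  log-likelihood);
* :func:`vb_em` — variational Bayes with conjugate priors (Dirichlet
  over the initial distribution and each transition row, Normal-Gamma
  over each state's emission mean/precision), returning the evidence
  lower bound (ELBO).  The ELBO approximates the log marginal likelihood
  of the trace under a K-state model and is the quantity whose per-trace
  mean selects the number of conformational states
  (:func:`select_states`), in the spirit of the vbFRET analysis of
  Bronson et al.

Fitted models are always reported in canonical order (means strictly
ascending), so results are invariant to state relabeling.
:func:`viterbi` idealizes a trajectory: each frame's efficiency is
replaced by the fitted mean of its most-probable state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from ._kernels import forward_backward_core, viterbi_core

logger = logging.getLogger(__name__)

__all__ = [
    "HmmModel",
    "FitResult",
    "IdealizedTrajectory",
    "PriorSpec",
    "forward_backward",
    "baum_welch",
    "vb_em",
    "select_states",
    "viterbi",
]

_VAR_FLOOR = 1e-8


@dataclass
class HmmModel:
    """K-state Gaussian-emission HMM in canonical (mean-sorted) order."""

    K: int
    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.initial.shape != (self.K,) or self.transition.shape != (self.K, self.K):
            raise ValueError("initial/transition shape mismatch")
        if self.means.shape != (self.K,) or self.variances.shape != (self.K,):
            raise ValueError("means/variances shape mismatch")
        if np.any(self.initial < -1e-12) or abs(self.initial.sum() - 1) > 1e-10:
            raise ValueError("initial must be a probability vector")
        if np.any(self.transition < -1e-12) or np.any(
            np.abs(self.transition.sum(axis=1) - 1) > 1e-10
        ):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if self.K > 1 and np.any(np.diff(self.means) <= 0):
            raise ValueError("means must be strictly increasing (canonical order)")

    def log_emission(self, series: np.ndarray) -> np.ndarray:
        x = np.asarray(series, dtype=float)[:, None]
        return -0.5 * (
            np.log(2 * np.pi * self.variances) + (x - self.means) ** 2 / self.variances
        )


def _canonicalize(pi, A, means, variances):
    order = np.argsort(means, kind="stable")
    # break exact mean ties so canonical order stays strict
    means = means[order].copy()
    for k in range(1, len(means)):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + 1e-12
    return pi[order], A[np.ix_(order, order)], means, variances[order]


@dataclass
class FitResult:
    model: HmmModel
    objective: float  # log-likelihood (ML) or ELBO (VB)
    n_iterations: int
    converged: bool
    restarts_used: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False


@dataclass
class IdealizedTrajectory:
    """Viterbi state path with each frame replaced by its state's mean."""

    state_path: np.ndarray
    idealized_efficiency: np.ndarray
    trace_id: str = ""
    frame_dt: float = 0.1
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.state_path)


def forward_backward(model: HmmModel, series: np.ndarray):
    """Log-likelihood and per-frame posterior state probabilities."""
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    loglik, gamma, _ = forward_backward_core(
        model.initial, model.transition, model.log_emission(x)
    )
    return float(loglik), gamma


# ---------------------------------------------------------------------------
# Initialization shared by ML and VB fits

def _init_means(x: np.ndarray, K: int, rng: np.random.Generator, jitter: bool) -> np.ndarray:
    """Initial emission means.

    The first restart uses quantile-spread means refined by 1-D k-means
    (Lloyd).  Further restarts draw K random data points (sorted, plus a
    small Normal(0, 0.02) jitter): k-means-style starts tend to merge
    close, unequally occupied states, and sampled starts are the reliable
    way to escape those optima at K >= 4.
    """
    if not jitter:
        means = np.quantile(x, (np.arange(K) + 0.5) / K)
        for _ in range(10):
            labels = np.argmin(np.abs(x[:, None] - means), axis=1)
            for k in range(K):
                sel = labels == k
                if sel.any():
                    means[k] = x[sel].mean()
        return np.sort(means)
    means = rng.choice(x, size=K, replace=len(x) < K)
    return np.sort(means + rng.normal(0.0, 0.02, size=K))


def _init_params(x: np.ndarray, K: int, rng: np.random.Generator, jitter: bool):
    means = _init_means(x, K, rng, jitter)
    var = max(np.var(x) / max(K, 1), 10 * _VAR_FLOOR)
    variances = np.full(K, var)
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    return pi, A, means, variances


def _gauss_logB(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    return -0.5 * (
        np.log(2 * np.pi * variances) + (x[:, None] - means) ** 2 / variances
    )


def baum_welch(
    series: np.ndarray,
    K: int,
    init_strategy: str = "quantile-kmeans",
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood EM fit; best of ``n_restarts`` kept.

    The log-likelihood is non-decreasing across iterations (EM guarantee,
    asserted); convergence when the increment drops below ``tol``.
    Collapsing variances are floored at 1e-8 with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= 2 * K:
        raise ValueError(f"series length {len(x)} too short for K={K}")
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    failures = 0
    for r in range(n_restarts):
        try:
            pi, A, means, variances = _init_params(x, K, rng, jitter=r > 0)
            lls: list[float] = []
            converged = False
            for it in range(max_iter):
                ll, gamma, xi = forward_backward_core(pi, A, _gauss_logB(x, means, variances))
                if lls and ll < lls[-1] - 1e-7:
                    raise RuntimeError("EM log-likelihood decreased")
                done = len(lls) > 0 and abs(ll - lls[-1]) < tol
                lls.append(ll)
                if done:
                    converged = True
                    break
                # M-step
                pi = gamma[0] / gamma[0].sum()
                rowsum = xi.sum(axis=1, keepdims=True)
                A = np.where(rowsum > 0, xi / np.maximum(rowsum, 1e-300), 1.0 / K)
                A = A / A.sum(axis=1, keepdims=True)
                Nk = gamma.sum(axis=0)
                means = (gamma * x[:, None]).sum(axis=0) / np.maximum(Nk, 1e-300)
                variances = (gamma * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(
                    Nk, 1e-300
                )
                if np.any(variances < _VAR_FLOOR):
                    logger.warning("variance collapse; flooring at %g", _VAR_FLOOR)
                    variances = np.maximum(variances, _VAR_FLOOR)
            pi, A, means, variances = _canonicalize(pi, A, means, variances)
            fit = FitResult(
                model=HmmModel(K, pi, A, means, variances),
                objective=lls[-1],
                n_iterations=len(lls),
                converged=bool(converged),
                restarts_used=r + 1,
                objective_trace=np.array(lls),
            )
            if best is None or fit.objective > best.objective:
                best = fit
        except (RuntimeError, ValueError, FloatingPointError) as exc:
            failures += 1
            logger.debug("restart %d failed: %s", r, exc)
    if best is None:
        raise RuntimeError(f"all {n_restarts} Baum-Welch restarts failed")
    best.restarts_used = n_restarts
    return best


# ---------------------------------------------------------------------------
# Variational Bayes

@dataclass
class PriorSpec:
    """Conjugate hyperparameters for the VB fit.

    Symmetric Dirichlet(alpha) over the initial vector and each
    transition row; Normal-Gamma over each emission (mean, precision):
    precision ~ Gamma(a0, b0), mean | precision ~ N(m0, 1/(kappa0 *
    precision)).  ``m0 = None`` centers the prior at the series mean.
    Defaults are weak so the data dominate.

    The transition prior is sparse (alpha_A = 0.05 < 1): single-molecule
    state networks are sparse (most transitions connect neighbouring
    conformations), and a uniform alpha = 1 prior charges every fitted
    state for transitions that never occur, which systematically biases
    evidence-based state-count selection low on ~200-frame traces.
    """

    alpha_pi: float = 1.0
    alpha_A: float = 0.05
    m0: float | None = None
    kappa0: float = 0.25
    a0: float = 2.5
    b0: float = 0.01


def _kl_dirichlet(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.sum(), v.sum()
    return float(
        gammaln(su)
        - gammaln(u).sum()
        - gammaln(sv)
        + gammaln(v).sum()
        + ((u - v) * (digamma(u) - digamma(su))).sum()
    )


def _kl_normal_gamma(m, kappa, a, b, m0, kappa0, a0, b0) -> float:
    kl_gamma = (
        (a - a0) * digamma(a) - gammaln(a) + gammaln(a0) + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )
    kl_normal = 0.5 * (
        np.log(kappa / kappa0) + kappa0 / kappa + kappa0 * (a / b) * (m - m0) ** 2 - 1.0
    )
    return float(np.sum(kl_gamma + kl_normal))


def vb_em(
    series: np.ndarray,
    K: int,
    prior_spec: PriorSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Variational EM; objective is the evidence lower bound (ELBO).

    The ELBO is non-decreasing across iterations (VB guarantee,
    asserted).  The reported model is the posterior mean: Dirichlet means
    for initial/transition, Normal-Gamma means for emissions (variance =
    b/a, the inverse mean precision).
    """
    prior = prior_spec or PriorSpec()
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        # no data: q = p, ELBO = 0; report the prior predictive
        m0 = prior.m0 if prior.m0 is not None else 0.5
        model = HmmModel(
            K,
            np.full(K, 1 / K),
            np.full((K, K), 1 / K),
            m0 + np.arange(K) * 1e-9,
            np.full(K, prior.b0 / prior.a0),
        )
        logger.warning("vb_em called with empty series: degenerate prior fit")
        return FitResult(model, 0.0, 0, False, 0, degenerate=True)
    if len(x) <= 2 * K:
        raise ValueError(f"series length {len(x)} too short for K={K}")
    m0 = float(np.mean(x)) if prior.m0 is None else prior.m0
    u_pi0 = np.full(K, prior.alpha_pi)
    u_A0 = np.full((K, K), prior.alpha_A)
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    failures = 0
    for r in range(n_restarts):
        try:
            fit = _vb_single(x, K, prior, m0, u_pi0, u_A0, tol, max_iter, rng, jitter=r > 0)
            if best is None or fit.objective > best.objective:
                best = fit
        except (RuntimeError, ValueError, FloatingPointError) as exc:
            failures += 1
            logger.debug("VB restart %d failed: %s", r, exc)
    if best is None:
        raise RuntimeError(f"all {n_restarts} VB restarts failed")
    best.restarts_used = n_restarts
    return best


def _vb_single(x, K, prior, m0, u_pi0, u_A0, tol, max_iter, rng, jitter):
    T = len(x)
    # initialize q from hard k-means responsibilities
    means = _init_means(x, K, rng, jitter)
    labels = np.argmin(np.abs(x[:, None] - means), axis=1)
    gamma = np.zeros((T, K))
    gamma[np.arange(T), labels] = 1.0
    gamma = 0.9 * gamma + 0.1 / K
    xi = np.zeros((K, K))
    counts = np.bincount(labels[:-1] * K + labels[1:], minlength=K * K).reshape(K, K)
    xi[:] = counts + 0.1

    def m_step(gamma, xi):
        w_pi = u_pi0 + gamma[0]
        w_A = u_A0 + xi
        Nk = gamma.sum(axis=0)
        xbar = (gamma * x[:, None]).sum(axis=0) / np.maximum(Nk, 1e-300)
        S = (gamma * (x[:, None] - xbar) ** 2).sum(axis=0)
        kappa = prior.kappa0 + Nk
        m = (prior.kappa0 * m0 + Nk * xbar) / kappa
        a = prior.a0 + 0.5 * Nk
        b = (
            prior.b0
            + 0.5 * S
            + 0.5 * prior.kappa0 * Nk * (xbar - m0) ** 2 / (prior.kappa0 + Nk)
        )
        return w_pi, w_A, m, kappa, a, b

    w_pi, w_A, m, kappa, a, b = m_step(gamma, xi)
    elbos: list[float] = []
    converged = False
    for it in range(max_iter):
        # E-step with geometric-mean ("tilde") parameters
        ln_pi = digamma(w_pi) - digamma(w_pi.sum())
        ln_A = digamma(w_A) - digamma(w_A.sum(axis=1, keepdims=True))
        ln_lam = digamma(a) - np.log(b)
        logB = 0.5 * (ln_lam - np.log(2 * np.pi)) - 0.5 * (
            1.0 / kappa + (a / b) * (x[:, None] - m) ** 2
        )
        lnZ, gamma, xi = forward_backward_core(np.exp(ln_pi), np.exp(ln_A), logB)
        elbo = (
            lnZ
            - _kl_dirichlet(w_pi, u_pi0)
            - sum(_kl_dirichlet(w_A[j], u_A0[j]) for j in range(K))
            - _kl_normal_gamma(m, kappa, a, b, m0, prior.kappa0, prior.a0, prior.b0)
        )
        if elbos and elbo < elbos[-1] - 1e-7:
            raise RuntimeError("ELBO decreased")
        done = len(elbos) > 0 and abs(elbo - elbos[-1]) < tol
        elbos.append(float(elbo))
        if done:
            converged = True
            break
        w_pi, w_A, m, kappa, a, b = m_step(gamma, xi)

    pi = w_pi / w_pi.sum()
    A = w_A / w_A.sum(axis=1, keepdims=True)
    variances = np.maximum(b / a, _VAR_FLOOR)
    pi, A, means, variances = _canonicalize(pi, A, m.copy(), variances)
    return FitResult(
        model=HmmModel(K, pi, A, means, variances),
        objective=elbos[-1],
        n_iterations=len(elbos),
        converged=bool(converged),
        restarts_used=1,
        objective_trace=np.array(elbos),
    )


# ---------------------------------------------------------------------------

def _n_params(K: int) -> int:
    # free parameters of a K-state Gaussian HMM
    return (K - 1) + K * (K - 1) + 2 * K


def select_states(
    series_list: list[np.ndarray],
    K_range=range(1, 7),
    criterion: str = "evidence",
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-5,
    max_iter: int = 300,
    prior_spec: PriorSpec | None = None,
) -> tuple[int, pd.DataFrame]:
    """Select the number of conformational states.

    Every trace is fitted independently at each K; the per-K score is the
    mean per-trace objective — the mean ELBO ("evidence", default) or the
    mean -BIC/2 ("bic").  The selected K maximizes the mean score; exact
    ties go to the smaller K (parsimony).

    Returns ``(K_star, table)`` where ``table`` has one row per K with
    the mean and per-trace objectives.
    """
    Ks = sorted(K_range)
    if not Ks:
        raise ValueError("K_range must be non-empty")
    if criterion not in ("evidence", "bic"):
        raise ValueError("criterion must be 'evidence' or 'bic'")
    usable = [s for s in series_list if len(s) > 2 * Ks[-1]]
    if len(usable) < len(series_list):
        logger.warning(
            "select_states: dropped %d traces shorter than 2*K_max+1 frames",
            len(series_list) - len(usable),
        )
    series_list = usable
    if not series_list:
        raise ValueError("no traces long enough for the requested K range")
    rows = []
    for K in Ks:
        scores = np.empty(len(series_list))
        for i, series in enumerate(series_list):
            s = int(np.random.default_rng([seed, K, i]).integers(2**31))
            if criterion == "evidence":
                fit = vb_em(
                    series, K, prior_spec=prior_spec, tol=tol, max_iter=max_iter,
                    n_restarts=n_restarts, seed=s,
                )
                scores[i] = fit.objective
            else:
                fit = baum_welch(
                    series, K, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=s
                )
                scores[i] = fit.objective - 0.5 * _n_params(K) * np.log(len(series))
        rows.append({"K": K, "mean_objective": scores.mean(), "scores": scores})
    table = pd.DataFrame(rows)
    means = table["mean_objective"].to_numpy()
    K_star = int(table["K"].iloc[int(np.argmax(means))])  # argmax: first max wins -> smaller K
    if (means == means.max()).sum() > 1:
        logger.info("select_states tie; choosing smallest K=%d", K_star)
    return K_star, table


def viterbi(model: HmmModel, series: np.ndarray, trace_id: str = "", frame_dt: float = 0.1,
            metadata: dict | None = None) -> IdealizedTrajectory:
    """Most-probable state path; idealized efficiency = state mean.

    Deterministic; ties in the dynamic program break toward the lower
    state index.
    """
    x = np.asarray(series, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(model.initial, 1e-300))
        log_A = np.log(np.maximum(model.transition, 1e-300))
    path, _ = viterbi_core(log_pi, log_A, model.log_emission(x))
    return IdealizedTrajectory(
        state_path=path,
        idealized_efficiency=model.means[path],
        trace_id=trace_id,
        frame_dt=frame_dt,
        metadata=metadata or {},
    )
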