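"""Model fitting and comparison for the bandit learner family.

Each model is fitted per subject by MAP estimation in an unconstrained
(transformed) space: unit-range parameters (learning rates, volatility
learning rate) go through a sigmoid link, positive parameters (noise
variances, inverse temperatures) through an exponential link.  The Gaussian
prior on every transformed parameter has mean 0 and variance 6.25 — wide
enough that the likelihood dominates whenever the data are informative.

Subjects are then combined by an empirical-Bayes hierarchy: the group prior
mean/variance of each model's transformed parameters is re-estimated from
responsibility-weighted Laplace posteriors, and per-subject MAP fits are
repeated under the updated priors.  Model comparison uses per-subject
Laplace evidences in a random-effects scheme whose summary is the
exceedance probability (XP): the posterior probability that a model is the
most frequent in the population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .bandit import BanditConfig, BanditSession, simulate_agent
from .models import ModelParams, ModelSpec, session_nll

__all__ = [
    "TransformSpec",
    "SubjectFit",
    "GroupFit",
    "map_fit",
    "hierarchical_fit",
    "exceedance_probability",
    "parameter_recovery",
]

#: parameters constrained to the unit interval (sigmoid link)
_UNIT_PARAMS = frozenset({"a", "a_pos", "a_neg", "lam"})
#: everything else free in the family is positive (exponential link)
_POS_PARAMS = frozenset({"v", "sigma2", "v0", "betaV", "betaU"})


@dataclass(frozen=True)
class TransformSpec:
    """Per-parameter links and the Gaussian prior in transformed space."""

    prior_mean: float = 0.0
    prior_variance: float = 6.25
    #: optional upper bounds for scaled-sigmoid links, e.g. {"betaV": 20.0}
    upper_bounds: dict = field(default_factory=dict)

    def link(self, name: str) -> str:
        if name in self.upper_bounds:
            return "scaled_sigmoid"
        if name in _UNIT_PARAMS:
            return "sigmoid"
        if name in _POS_PARAMS:
            return "exp"
        raise KeyError(f"no link registered for parameter {name!r}")

    def to_native(self, name: str, x: float) -> float:
        link = self.link(name)
        if link == "sigmoid":
            return float(special.expit(x))
        if link == "scaled_sigmoid":
            return float(self.upper_bounds[name] * special.expit(x))
        return float(np.exp(np.clip(x, -50, 50)))

    def to_transformed(self, name: str, value: float) -> float:
        link = self.link(name)
        if link == "sigmoid":
            value = np.clip(value, 1e-12, 1 - 1e-12)
            return float(special.logit(value))
        if link == "scaled_sigmoid":
            frac = np.clip(value / self.upper_bounds[name], 1e-12, 1 - 1e-12)
            return float(special.logit(frac))
        return float(np.log(max(value, 1e-300)))


@dataclass
class SubjectFit:
    """One subject × one model: MAP optimum and evidence terms."""

    spec: ModelSpec
    params_native: dict
    params_transformed: np.ndarray
    nll: float
    log_evidence: float
    hessian_diag: np.ndarray
    bic: float
    n_trials: int
    converged: bool = True


@dataclass
class GroupFit:
    """Hierarchy output: group priors, responsibilities, model frequencies."""

    specs: list
    prior_mean: dict        # model name -> (n_free,) transformed means
    prior_variance: dict    # model name -> (n_free,) transformed variances
    responsibilities: np.ndarray  # (n_subjects, n_models), rows sum to 1
    dirichlet_alpha: np.ndarray   # (n_models,)
    xp: np.ndarray                # (n_models,)
    subject_fits: list            # list over subjects of {model name: SubjectFit}
    n_iter: int = 0
    converged: bool = True


def _native_params(theta: np.ndarray, names: tuple, transform: TransformSpec) -> ModelParams:
    values = {n: transform.to_native(n, x) for n, x in zip(names, theta)}
    return ModelParams().with_values(**values)


def _objective(theta, session, spec, names, transform, mu, var):
    params = _native_params(np.asarray(theta, float), names, transform)
    try:
        nll = session_nll(session, spec, params)
    except (FloatingPointError, ValueError):
        return 1e10
    prior = 0.5 * np.sum((theta - mu) ** 2 / var) + 0.5 * np.sum(np.log(2 * np.pi * var))
    return nll + prior


def _fd_hessian_diag(fun, x, h=1e-3):
    """Diagonal finite-difference Hessian, floored positive."""
    d = np.empty_like(x)
    f0 = fun(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        d[i] = (fun(x + e) - 2 * f0 + fun(x - e)) / h**2
    return np.clip(d, 1e-6, None)


def map_fit(
    session: BanditSession,
    spec: ModelSpec,
    transform: TransformSpec | None = None,
    prior_mean: np.ndarray | None = None,
    prior_variance: np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> SubjectFit:
    """MAP fit of one model to one session, with multi-start optimization.

    The Laplace approximation of the log model evidence is
    ``-J(theta*) + (d/2) log(2 pi) - (1/2) log det H`` with ``J`` the
    penalized objective and ``H`` its (diagonal finite-difference) Hessian.
    """
    if transform is None:
        transform = TransformSpec()
    names = spec.free_params()
    d = len(names)
    mu = np.full(d, transform.prior_mean) if prior_mean is None else np.asarray(prior_mean, float)
    var = np.full(d, transform.prior_variance) if prior_variance is None else np.asarray(prior_variance, float)

    rng = np.random.default_rng(seed)
    starts = [mu]
    starts += [mu + np.sqrt(np.minimum(var, 1.0)) * rng.standard_normal(d) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _objective, x0, args=(session, spec, names, transform, mu, var),
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all MAP restarts failed for model {spec.name}")

    theta = best.x
    hess = _fd_hessian_diag(
        lambda x: _objective(x, session, spec, names, transform, mu, var), theta
    )
    log_evidence = -best.fun + 0.5 * d * np.log(2 * np.pi) - 0.5 * np.sum(np.log(hess))
    params = _native_params(theta, names, transform)
    nll = session_nll(session, spec, params)
    bic = 2.0 * nll + d * np.log(session.n_trials)
    return SubjectFit(
        spec=spec,
        params_native={n: getattr(params, n) for n in names},
        params_transformed=theta,
        nll=nll,
        log_evidence=float(log_evidence),
        hessian_diag=hess,
        bic=float(bic),
        n_trials=session.n_trials,
        converged=bool(best.success),
    )


def hierarchical_fit(
    sessions: list,
    specs: list,
    transform: TransformSpec | None = None,
    max_iter: int = 10,
    tol: float = 1e-2,
    n_starts: int = 4,
    seed: int = 0,
    n_xp_draws: int = 100_000,
) -> GroupFit:
    """Empirical-Bayes hierarchical fit across subjects and models.

    Iterates (1) per-subject MAP fits under the current group priors,
    (2) responsibility updates from per-subject Laplace evidences,
    (3) responsibility-weighted re-estimation of the group prior mean and
    variance in transformed space.  Starts from the N(0, 6.25) prior.
    """
    if len(sessions) < 2:
        raise ValueError("hierarchical_fit requires at least 2 subjects")
    if transform is None:
        transform = TransformSpec()
    n_sub, n_mod = len(sessions), len(specs)
    mu = {s.name: np.full(len(s.free_params()), transform.prior_mean) for s in specs}
    var = {s.name: np.full(len(s.free_params()), transform.prior_variance) for s in specs}
    resp = np.full((n_sub, n_mod), 1.0 / n_mod)

    fits: list = [dict() for _ in range(n_sub)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_ev = np.empty((n_sub, n_mod))
        for i, sess in enumerate(sessions):
            for j, spec in enumerate(specs):
                fit = map_fit(
                    sess, spec, transform,
                    prior_mean=mu[spec.name], prior_variance=var[spec.name],
                    n_starts=n_starts, seed=seed + 1000 * it + 10 * i + j,
                )
                fits[i][spec.name] = fit
                log_ev[i, j] = fit.log_evidence
        # responsibilities from evidences
        lw = log_ev - log_ev.max(axis=1, keepdims=True)
        resp = np.exp(lw)
        resp /= resp.sum(axis=1, keepdims=True)
        # group prior re-estimation
        max_shift = 0.0
        for j, spec in enumerate(specs):
            r = resp[:, j]
            if r.sum() < 1e-8:
                continue
            thetas = np.stack([fits[i][spec.name].params_transformed for i in range(n_sub)])
            post_var = np.stack([1.0 / fits[i][spec.name].hessian_diag for i in range(n_sub)])
            new_mu = (r[:, None] * thetas).sum(0) / r.sum()
            new_var = (r[:, None] * ((thetas - new_mu) ** 2 + post_var)).sum(0) / r.sum()
            new_var = np.clip(new_var, 1e-3, transform.prior_variance)
            max_shift = max(max_shift, np.abs(new_mu - mu[spec.name]).max())
            mu[spec.name], var[spec.name] = new_mu, new_var
        if max_shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("hierarchical_fit did not converge; returning last iterate")

    log_ev = np.array([[fits[i][s.name].log_evidence for s in specs] for i in range(n_sub)])
    alpha, xp = _bms(log_ev, seed=seed, n_draws=n_xp_draws)
    return GroupFit(
        specs=list(specs), prior_mean=mu, prior_variance=var,
        responsibilities=resp, dirichlet_alpha=alpha, xp=xp,
        subject_fits=fits, n_iter=it, converged=converged,
    )


def _bms(log_evidences: np.ndarray, seed: int = 0, n_draws: int = 100_000,
         max_iter: int = 200, tol: float = 1e-6):
    """Random-effects Bayesian model selection (variational Dirichlet update)."""
    L = np.asarray(log_evidences, float)
    n_sub, n_mod = L.shape
    if n_mod == 1:
        return np.array([n_sub + 1.0]), np.array([1.0])
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = L + special.digamma(alpha) - special.digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        g = u / u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=n_mod) / n_draws
    return alpha, xp


def exceedance_probability(log_evidences: np.ndarray, seed: int = 0,
                           n_draws: int = 100_000) -> np.ndarray:
    """Per-model exceedance probability from a subjects × models evidence matrix.

    XP_k is the posterior probability that model k's population frequency
    exceeds all others, estimated from Dirichlet draws of the random-effects
    frequency posterior.  Sums to 1 over models.
    """
    L = np.asarray(log_evidences, float)
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    _, xp = _bms(L, seed=seed, n_draws=n_draws)
    return xp


def parameter_recovery(
    spec: ModelSpec,
    true_param_grid: dict,
    n_trials: int = 300,
    config: BanditConfig | None = None,
    transform: TransformSpec | None = None,
    seed: int = 0,
    n_starts: int = 4,
):
    """Simulate → fit → tabulate recovery of generating parameters.

    ``true_param_grid`` maps free-parameter names to per-subject value arrays
    (equal lengths = number of synthetic subjects).  Returns a dict with the
    true/recovered tables and per-parameter Pearson r (``nan`` for a
    degenerate single-value grid).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    names = spec.free_params()
    lengths = {len(v) for v in true_param_grid.values()}
    if len(lengths) != 1:
        raise ValueError("all parameter grids must have equal length")
    n_sub = lengths.pop()
    if config is None:
        config = BanditConfig(n_trials=n_trials)
    else:
        config = BanditConfig(**{**config.__dict__, "n_trials": n_trials})

    true = {n: np.asarray(true_param_grid.get(n, np.full(n_sub, getattr(ModelParams(), n))), float)
            for n in names}
    recovered = {n: np.empty(n_sub) for n in names}
    for i in range(n_sub):
        params = ModelParams().with_values(**{n: true[n][i] for n in names})
        sess = simulate_agent(config, spec, params, seed=seed + i)
        fit = map_fit(sess, spec, transform, n_starts=n_starts, seed=seed + 7919 * (i + 1))
        for n in names:
            recovered[n][i] = fit.params_native[n]
    corr = {}
    for n in names:
        t, r = true[n], recovered[n]
        if np.ptp(t) < 1e-12:
            corr[n] = float("nan")
        else:
            corr[n] = float(np.corrcoef(t, r)[0, 1])
    return {"true": true, "recovered": recovered, "pearson_r": corr, "n_trials": n_trials}
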