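"""Multinomial mixed-effects logistic regression for polysome association.

The model links a ribosome's categorical state (or translocon population)
to a categorical outcome -- e.g. in-polysome vs not, or the class of its
leading/trailing neighbor.  For outcome category k (vs a reference
category) of a ribosome with state s in tomogram t:

    log-odds(outcome = k | s, t) = beta_{k,s} + u_{k,t},
    u_{k,t} ~ Normal(0, sigma_k^2)  independent across tomograms and
    non-reference categories,

so the tomogram index is a random effect absorbing sample and imaging
variability.  Fixed effects use cell-means coding (one log-odds per
state and non-reference outcome).

Estimation maximizes the Laplace-approximated marginal likelihood (the
per-tomogram random-effect integral is replaced by its Gaussian
approximation at the mode); for binary outcomes an adaptive Gauss-Hermite
refinement is available.  The zero-variance constraint reduces the model to
the pooled multinomial logit with its closed-form solution.

Downstream inference: predicted probabilities at u = 0 with delta-method
confidence intervals on the log-odds scale, two-sided Wald contrasts
between states, step-up Hochberg multiple-testing adjustment, and fold
increases over the random-association probability (the outcome's fractional
abundance).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .particle_io import ParticleTable

__all__ = [
    "AssociationObservation",
    "ModelConfig",
    "AssociationFit",
    "fit_association_model",
    "wald_contrast",
    "hochberg_adjust",
    "fold_increase",
    "abundance_table",
    "ConvergenceError",
]

_PREFERRED_REFERENCES = ("none", "not-in-polysome", "not_in_polysome")
_BETA_BOUND = 30.0


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach a stationary point."""


@dataclasses.dataclass(frozen=True)
class AssociationObservation:
    """One ribosome: grouping key, categorical predictor, categorical response."""

    tomogram_id: str
    state: str
    outcome: str


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Fitting configuration.

    ``random_effect_variance`` fixes sigma^2 when given (0.0 selects the
    closed-form pooled multinomial logit); ``None`` estimates it.
    ``estimation_method`` is ``"laplace"`` or ``"agq"`` (adaptive
    Gauss-Hermite; binary outcomes only).
    """

    reference_category: str | None = None
    ci_level: float = 0.95
    max_iterations: int = 500
    convergence_tolerance: float = 1e-8
    estimation_method: str = "laplace"
    random_effect_variance: float | None = None
    n_quadrature: int = 21

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.estimation_method not in ("laplace", "agq"):
            raise ValueError(f"unknown estimation_method {self.estimation_method!r}")


@dataclasses.dataclass
class AssociationFit:
    """Fitted model: coefficients, covariance, predictions, diagnostics."""

    states: list[str]
    outcomes: list[str]  # non-reference categories, model order
    reference: str
    coefficients: np.ndarray  # (K-1, S) log-odds vs reference
    covariance: np.ndarray  # ((K-1)*S, (K-1)*S), beta block, C-order (k, s)
    random_intercept_sd: np.ndarray  # (K-1,)
    predicted: pd.DataFrame  # state, outcome, probability, ci_low, ci_high
    loglik: float
    converged: bool
    n_obs: int
    n_tomograms: int
    ci_level: float
    separation_states: list[str] = dataclasses.field(default_factory=list)

    def coef_index(self, outcome: str, state: str) -> int:
        return self.outcomes.index(outcome) * len(self.states) + self.states.index(state)

    def predicted_probability(self, state: str, outcome: str) -> float:
        sel = (self.predicted["state"] == state) & (self.predicted["outcome"] == outcome)
        return float(self.predicted.loc[sel, "probability"].iloc[0])


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations[["tomogram_id", "state", "outcome"]].copy()
    else:
        df = pd.DataFrame(
            [(o.tomogram_id, o.state, o.outcome) for o in observations],
            columns=["tomogram_id", "state", "outcome"],
        )
    if df.empty:
        raise ValueError("no observations")
    return df.astype({"tomogram_id": str, "state": str, "outcome": str})


def _choose_reference(outcomes: Sequence[str], counts: Mapping[str, int],
                      config: ModelConfig) -> str:
    if config.reference_category is not None:
        if config.reference_category not in outcomes:
            raise ValueError(
                f"reference category {config.reference_category!r} not observed"
            )
        return config.reference_category
    for cand in _PREFERRED_REFERENCES:
        if cand in outcomes:
            return cand
    return max(outcomes, key=lambda k: (counts[k], k))


class _LaplaceObjective:
    """Negative Laplace (or AGQ) log marginal likelihood over (beta, log sd).

    Sufficient statistics are per-tomogram count tensors n[t, s, k] with the
    reference category last; the inner random-effect modes are found by a
    damped, batched Newton iteration and warm-started between evaluations.
    """

    def __init__(self, n_tsk: np.ndarray, method: str = "laplace",
                 n_quadrature: int = 21, fixed_sd: np.ndarray | None = None):
        self.n = n_tsk  # (T, S, K) reference last
        self.T, self.S, self.K = n_tsk.shape
        self.N_ts = n_tsk.sum(axis=2)  # (T, S)
        self.method = method
        self.fixed_sd = fixed_sd
        self.u = np.zeros((self.T, self.K - 1))
        if method == "agq":
            if self.K != 2:
                raise ValueError("adaptive quadrature supports binary outcomes only")
            self._gh_x, self._gh_w = np.polynomial.hermite.hermgauss(n_quadrature)

    # -- parameter packing -------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nb = (self.K - 1) * self.S
        beta = theta[:nb].reshape(self.K - 1, self.S)
        if self.fixed_sd is not None:
            sd = self.fixed_sd
        else:
            sd = np.exp(theta[nb:])
        return beta, sd

    def n_params(self) -> int:
        nb = (self.K - 1) * self.S
        return nb if self.fixed_sd is not None else nb + (self.K - 1)

    # -- inner problem -----------------------------------------------------
    def _eta_prob(self, beta: np.ndarray, u: np.ndarray):
        # eta: (T, S, K) with reference (last) fixed at 0
        eta = np.zeros((self.T, self.S, self.K))
        eta[:, :, : self.K - 1] = beta[None, :, :].transpose(0, 2, 1) + u[:, None, :]
        lse = special.logsumexp(eta, axis=2)
        prob = np.exp(eta - lse[:, :, None])
        return eta, lse, prob

    def _penalized_loglik(self, beta, sd, u):
        """h_t(u) per tomogram: conditional loglik + log prior density."""
        eta, lse, _ = self._eta_prob(beta, u)
        ll = (self.n * eta).sum(axis=(1, 2)) - (self.N_ts * lse).sum(axis=1)
        prior = -0.5 * (u**2 / sd**2 + np.log(2 * np.pi * sd**2)).sum(axis=1)
        return ll + prior

    def _solve_modes(self, beta: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched damped Newton for the per-tomogram posterior modes.

        Returns modes (T, K-1) and negative Hessians (T, K-1, K-1).
        """
        u = self.u.copy()
        inv_var = 1.0 / sd**2
        h = self._penalized_loglik(beta, sd, u)
        for _ in range(100):
            _, _, prob = self._eta_prob(beta, u)
            pk = prob[:, :, : self.K - 1]
            grad = (self.n[:, :, : self.K - 1] - self.N_ts[:, :, None] * pk).sum(axis=1)
            grad -= u * inv_var[None, :]
            gnorm = np.abs(grad).max()
            # negative Hessian: sum_s N_ts (diag(p) - p p^T) + diag(1/sd^2)
            neg_hess = -np.einsum("tsk,tsl->tkl", self.N_ts[:, :, None] * pk, pk)
            idx = np.arange(self.K - 1)
            neg_hess[:, idx, idx] += (self.N_ts[:, :, None] * pk).sum(axis=1)
            neg_hess[:, idx, idx] += inv_var[None, :]
            if gnorm < 1e-10:
                break
            step = np.linalg.solve(neg_hess, grad[:, :, None])[:, :, 0]
            # damped update: halve steps that decrease the penalized loglik
            scale = np.ones(self.T)
            for _damp in range(30):
                u_new = u + scale[:, None] * step
                h_new = self._penalized_loglik(beta, sd, u_new)
                bad = h_new < h - 1e-12
                if not bad.any():
                    break
                scale[bad] *= 0.5
            u, h = u_new, np.maximum(h, h_new)
        self.u = u
        return u, neg_hess

    # -- objective ---------------------------------------------------------
    def neg_loglik(self, theta: np.ndarray) -> float:
        beta, sd = self.unpack(theta)
        u_hat, neg_hess = self._solve_modes(beta, sd)
        h_mode = self._penalized_loglik(beta, sd, u_hat)
        if self.method == "laplace" or self.K != 2:
            _, logdet = np.linalg.slogdet(neg_hess)
            ll = h_mode + 0.5 * (self.K - 1) * np.log(2 * np.pi) - 0.5 * logdet
        else:
            # adaptive Gauss-Hermite centered at the Laplace mode
            c = neg_hess[:, 0, 0]
            scale = np.sqrt(2.0 / c)
            nodes = u_hat[:, 0:1] + scale[:, None] * self._gh_x[None, :]
            hv = np.stack(
                [
                    self._penalized_loglik(beta, sd, nodes[:, i : i + 1])
                    for i in range(len(self._gh_x))
                ],
                axis=1,
            )
            ll = special.logsumexp(
                hv + self._gh_x[None, :] ** 2 + np.log(self._gh_w)[None, :], axis=1
            ) + np.log(scale)
        return -float(ll.sum())


def _pooled_fit(n_sk: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Closed-form multinomial logit with no random effect.

    beta_{k,s} = log(n_{s,k} / n_{s,ref}); covariance blocks per state are
    the inverse multinomial Fisher information.  States with empty cells are
    capped at +/-30 (separation).
    """
    S, K = n_sk.shape
    separated: list[int] = []
    beta = np.empty((K - 1, S))
    cov = np.zeros(((K - 1) * S, (K - 1) * S))
    for s in range(S):
        row = n_sk[s]
        if np.any(row == 0):
            separated.append(s)
        with np.errstate(divide="ignore"):
            b = np.log(row[:-1]) - np.log(row[-1])
        beta[:, s] = np.clip(b, -_BETA_BOUND, _BETA_BOUND)
        safe = np.maximum(row, 0.5)
        block = np.diag(1.0 / safe[:-1]) + 1.0 / safe[-1]
        ids = [k * S + s for k in range(K - 1)]
        cov[np.ix_(ids, ids)] = block
    return beta, cov, separated


def _numeric_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    p = len(x)
    hess = np.empty((p, p))
    hs = step * (1.0 + np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return hess


def fit_association_model(
    observations: Iterable[AssociationObservation] | pd.DataFrame,
    config: ModelConfig = ModelConfig(),
) -> AssociationFit:
    """Fit the multinomial mixed-effects logistic regression.

    Parameters
    ----------
    observations
        DataFrame with columns ``tomogram_id, state, outcome`` or an
        iterable of :class:`AssociationObservation`.
    config
        Reference category, CI level, estimation method.

    Returns
    -------
    AssociationFit
        Coefficients on the log-odds scale, their covariance, per-category
        random-intercept standard deviations, and predicted probabilities at
        u = 0 with delta-method confidence intervals.
    """
    df = _as_frame(observations)
    states = sorted(df["state"].unique())
    outcome_counts = df["outcome"].value_counts().to_dict()
    all_outcomes = sorted(outcome_counts)
    if len(all_outcomes) < 2:
        raise ValueError("need >= 2 outcome categories")
    tomos = sorted(df["tomogram_id"].unique())
    reference = _choose_reference(all_outcomes, outcome_counts, config)
    nonref = [k for k in all_outcomes if k != reference]
    order = nonref + [reference]

    # count tensor n[t, s, k], reference last
    t_idx = df["tomogram_id"].map({t: i for i, t in enumerate(tomos)}).to_numpy()
    s_idx = df["state"].map({s: i for i, s in enumerate(states)}).to_numpy()
    k_idx = df["outcome"].map({k: i for i, k in enumerate(order)}).to_numpy()
    T, S, K = len(tomos), len(states), len(order)
    n_tsk = np.zeros((T, S, K), dtype=float)
    np.add.at(n_tsk, (t_idx, s_idx, k_idx), 1.0)

    n_sk = n_tsk.sum(axis=0)
    separated_idx = [
        s for s in range(S) if np.count_nonzero(n_sk[s]) <= 1
    ]
    if separated_idx:
        warnings.warn(
            "complete separation for state(s) "
            f"{[states[s] for s in separated_idx]}: all observations in one "
            "outcome category; standard errors are inflated/unreliable",
            stacklevel=2,
        )

    fixed_var = config.random_effect_variance
    if fixed_var is not None and fixed_var == 0.0:
        if len(tomos) < 2:
            raise ValueError("need >= 2 tomograms")
        beta, cov, sep_pooled = _pooled_fit(n_sk)
        sd = np.zeros(K - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(n_sk / n_sk.sum(axis=1, keepdims=True))
        loglik = float(np.nansum(np.where(n_sk > 0, n_sk * logp, 0.0)))
        fit = AssociationFit(
            states=states, outcomes=nonref, reference=reference,
            coefficients=beta, covariance=cov, random_intercept_sd=sd,
            predicted=pd.DataFrame(), loglik=loglik, converged=True,
            n_obs=len(df), n_tomograms=T, ci_level=config.ci_level,
            separation_states=[states[s] for s in sep_pooled],
        )
        fit.predicted = _predict(fit, config.ci_level)
        return fit

    if len(tomos) < 2:
        raise ValueError("need >= 2 tomograms for a tomogram random effect")

    fixed_sd = None if fixed_var is None else np.full(K - 1, np.sqrt(fixed_var))
    obj = _LaplaceObjective(
        n_tsk, method=config.estimation_method,
        n_quadrature=config.n_quadrature, fixed_sd=fixed_sd,
    )
    beta0, _, _ = _pooled_fit(np.maximum(n_sk, 0.0) + 0.5)
    x0 = beta0.ravel()
    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * ((K - 1) * S)
    if fixed_sd is None:
        x0 = np.concatenate([x0, np.full(K - 1, np.log(0.5))])
        bounds += [(np.log(1e-4), np.log(50.0))] * (K - 1)

    res = optimize.minimize(
        obj.neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
        options={
            "maxiter": config.max_iterations,
            "ftol": config.convergence_tolerance,
            "gtol": 1e-6,
        },
    )
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or gnorm < 1e-2
    if not converged and not separated_idx:
        raise ConvergenceError(
            f"mixed-model fit did not converge after {res.nit} iterations "
            f"(max |gradient| = {gnorm:.3g})"
        )
    # under separation the optimum sits on the beta bound; keep the boundary
    # solution (SEs are flagged unreliable) instead of failing
    theta = res.x
    beta, sd = obj.unpack(theta)

    hess = _numeric_hessian(obj.neg_loglik, theta)
    nb = (K - 1) * S
    try:
        cov_all = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov_all)) or np.any(np.diag(cov_all)[:nb] < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
        d = np.diag(cov_all).copy()
        if np.any(d[:nb] < 0):
            warnings.warn("non-PD observed information; SEs are unreliable",
                          stacklevel=2)
            cov_all = np.abs(cov_all)
    cov = cov_all[:nb, :nb]

    fit = AssociationFit(
        states=states, outcomes=nonref, reference=reference,
        coefficients=beta, covariance=cov, random_intercept_sd=sd,
        predicted=pd.DataFrame(), loglik=-float(res.fun), converged=True,
        n_obs=len(df), n_tomograms=T, ci_level=config.ci_level,
        separation_states=[states[s] for s in separated_idx],
    )
    fit.predicted = _predict(fit, config.ci_level)
    return fit


def _predict(fit: AssociationFit, ci_level: float) -> pd.DataFrame:
    """Predicted probabilities at u = 0 with delta-method CIs.

    The standard error of each probability comes from the softmax Jacobian
    and the coefficient covariance of the state; the interval is built on
    the logit scale and back-transformed, so it respects [0, 1].
    """
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    S = len(fit.states)
    Km1 = len(fit.outcomes)
    rows = []
    for s_i, s in enumerate(fit.states):
        eta = np.concatenate([fit.coefficients[:, s_i], [0.0]])
        p = np.exp(eta - special.logsumexp(eta))
        ids = [k * S + s_i for k in range(Km1)]
        sigma = fit.covariance[np.ix_(ids, ids)]
        for k_i, outcome in enumerate(list(fit.outcomes) + [fit.reference]):
            pk = p[k_i]
            # d p_k / d beta_l = p_k (delta_kl - p_l), l over non-reference
            grad = -pk * p[:Km1]
            if k_i < Km1:
                grad[k_i] += pk
            var = float(grad @ sigma @ grad)
            se_p = np.sqrt(max(var, 0.0))
            if 0.0 < pk < 1.0 and se_p > 0.0:
                se_logit = se_p / (pk * (1.0 - pk))
                lo = special.expit(special.logit(pk) - z * se_logit)
                hi = special.expit(special.logit(pk) + z * se_logit)
            else:
                lo = hi = pk
            rows.append((s, outcome, pk, lo, hi))
    return pd.DataFrame(
        rows, columns=["state", "outcome", "probability", "ci_low", "ci_high"]
    )


def wald_contrast(
    fit: AssociationFit,
    contrasts: Sequence[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Wald tests for state contrasts on the log-odds scale.

    Each contrast is ``(state_a, state_b, outcome)``; the statistic is
    ``(beta_{k,a} - beta_{k,b}) / se`` against the standard normal.  By
    default, all state pairs for every non-reference outcome.
    """
    if contrasts is None:
        contrasts = [
            (a, b, k)
            for k in fit.outcomes
            for i, a in enumerate(fit.states)
            for b in fit.states[i + 1:]
        ]
    rows = []
    for a, b, outcome in contrasts:
        ia, ib = fit.coef_index(outcome, a), fit.coef_index(outcome, b)
        est = float(fit.coefficients.ravel()[ia] - fit.coefficients.ravel()[ib])
        var = (
            fit.covariance[ia, ia] + fit.covariance[ib, ib] - 2 * fit.covariance[ia, ib]
        )
        se = float(np.sqrt(max(var, 0.0)))
        if a == b:
            est, zval, p = 0.0, 0.0, 1.0
        elif se == 0.0:
            zval, p = np.inf * np.sign(est) if est else 0.0, 0.0 if est else 1.0
        else:
            zval = est / se
            p = float(2.0 * stats.norm.sf(abs(zval)))
        rows.append((a, b, outcome, est, se, zval, p))
    return pd.DataFrame(
        rows,
        columns=["state_a", "state_b", "outcome", "estimate", "se", "z", "p_raw"],
    )


def hochberg_adjust(p_values) -> np.ndarray:
    """Step-up Hochberg adjustment, returned in input order.

    Sort p ascending; adjusted_(m) = p_(m) and, stepping down,
    adjusted_(i) = min(adjusted_(i+1), (m - i + 1) * p_(i)); clip at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    sp = p[order]
    adj = np.empty(m)
    adj[m - 1] = sp[m - 1]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i + 1], (m - i) * sp[i])
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fold_increase(
    fit: AssociationFit,
    abundances: Mapping[str, float],
) -> pd.DataFrame:
    """Fold increase over random association, per (state, outcome).

    The modelled mean and CI bounds are divided by the outcome category's
    fractional abundance (the random-association probability); a fold of 1
    means no enrichment.  Intended for logarithmic-axis display.
    """
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 (got {total:.6g})")
    rows = []
    for row in fit.predicted.itertuples(index=False):
        if row.outcome not in abundances:
            continue
        a = abundances[row.outcome]
        if a <= 0.0:
            raise ValueError(f"zero abundance for category {row.outcome!r}")
        rows.append(
            (row.state, row.outcome, row.probability / a,
             row.ci_low / a, row.ci_high / a)
        )
    return pd.DataFrame(
        rows, columns=["state", "outcome", "fold", "fold_ci_low", "fold_ci_high"]
    )


def abundance_table(table, field: str = "state_label") -> pd.Series:
    """Fractional abundance of each category of ``field`` in the dataset."""
    if isinstance(table, ParticleTable):
        values = table.df[field]
    elif isinstance(table, pd.DataFrame):
        values = table[field]
    else:
        values = pd.Series(list(table))
    if len(values) == 0:
        raise ValueError("empty table")
    counts = values.value_counts(sort=False)
    return counts / counts.sum()
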