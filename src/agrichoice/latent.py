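"""Latent-class conditional logit with covariate-driven class membership.

S classes each carry their own utility coefficients; membership follows
a multinomial logit on unit-level covariates with the last class as the
zero reference.  Estimation is EM (posterior-weighted conditional logit
per class plus a weighted membership logit) followed by a quasi-Newton
polish of the full mixture likelihood, best of several seeded starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .mnl import (
    ConvergenceError,
    GroupedDesign,
    fit_mnl,
    mnl_loglik,
    null_loglik,
    situation_logprobs,
)

__all__ = [
    "LCLParameters",
    "LCLFit",
    "InformationCriteria",
    "WaldResult",
    "class_membership_probs",
    "lcl_loglik",
    "fit_lcl",
    "information_criteria",
    "select_classes",
    "wald_joint_test",
]


class InformationCriteria(NamedTuple):
    aic: float
    bic: float
    caic: float


def information_criteria(ll: float, k: int, n: int) -> InformationCriteria:
    """AIC = -2LL + 2k; BIC = -2LL + k ln n; CAIC = -2LL + k(ln n + 1)."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return InformationCriteria(
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        caic=-2.0 * ll + k * (np.log(n) + 1.0),
    )


def class_membership_probs(lam: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Softmax membership probabilities; ``lam`` is (S-1, q), reference last."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    eta = np.column_stack([Z @ lam.T, np.zeros(len(Z))])
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite membership utilities")
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LCLParameters:
    beta: np.ndarray  # (S, p)
    lam: np.ndarray  # (S-1, q); reference class S is identically zero
    columns: tuple[str, ...] = ()
    z_columns: tuple[str, ...] = ()

    @property
    def S(self) -> int:
        return self.beta.shape[0]

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta.ravel(), self.lam.ravel()])

    @classmethod
    def unpack(cls, theta, S, p, q, columns=(), z_columns=()):
        beta = np.asarray(theta[: S * p], dtype=float).reshape(S, p)
        lam = np.asarray(theta[S * p :], dtype=float).reshape(max(S - 1, 0), q)
        return cls(beta=beta, lam=lam, columns=columns, z_columns=z_columns)


def _unit_ptr(gd: GroupedDesign) -> np.ndarray:
    u = gd.unit_of_group
    boundaries = np.flatnonzero(np.diff(u)) + 1
    return np.concatenate(([0], boundaries, [len(u)]))


def _log_softmax_rows(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1, keepdims=True)
    return eta - m - np.log(np.exp(eta - m).sum(axis=1, keepdims=True))


def _class_logp(beta_s: np.ndarray, gd: GroupedDesign):
    return situation_logprobs(beta_s, gd)


def _lcl_components(params: LCLParameters, gd: GroupedDesign, uptr: np.ndarray):
    """Per-unit class log-joint matrix and related pieces.

    Returns (M, logpi, logp_list, probs_list) where M[n, s] =
    log pi_s(Z_n) + sum over the unit's situations of log P(chosen|s).
    """
    S = params.S
    logp_list, probs_list = [], []
    for s in range(S):
        logp, probs = _class_logp(params.beta[s], gd)
        logp_list.append(logp)
        probs_list.append(probs)
    A = np.column_stack(
        [np.add.reduceat(lp, uptr[:-1]) for lp in logp_list]
    )  # (n_units, S)
    if S > 1:
        eta = np.column_stack([gd.Z @ params.lam.T, np.zeros(gd.n_units)])
    else:
        eta = np.zeros((gd.n_units, 1))
    logpi = _log_softmax_rows(eta)
    return logpi + A, logpi, logp_list, probs_list


def lcl_loglik(params: LCLParameters, gd: GroupedDesign) -> float:
    """Mixture log-likelihood via log-sum-exp over classes per unit."""
    if gd.n_units == 0:
        raise ValueError("no mixture units in the data")
    if params.S > 1 and gd.Z is None:
        raise ValueError("grouped design lacks membership covariates")
    uptr = _unit_ptr(gd)
    M, _, _, _ = _lcl_components(params, gd, uptr)
    m = M.max(axis=1)
    return float((m + np.log(np.exp(M - m[:, None]).sum(axis=1))).sum())


def _ll_grad(params: LCLParameters, gd: GroupedDesign, uptr: np.ndarray):
    """Log-likelihood, posteriors, and analytic gradient in packed order."""
    S, p = params.beta.shape
    M, logpi, logp_list, probs_list = _lcl_components(params, gd, uptr)
    m = M.max(axis=1, keepdims=True)
    e = np.exp(M - m)
    denom = e.sum(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(denom[:, 0])).sum())
    w = e / denom  # posteriors (n_units, S)

    grad_beta = np.empty((S, p))
    x_ch = gd.X[gd.chosen]
    for s in range(S):
        w_g = w[gd.unit_of_group, s]
        probs = probs_list[s]
        xbar = np.add.reduceat(gd.X * probs[:, None], gd.group_ptr[:-1], axis=0)
        grad_beta[s] = w_g @ (x_ch - xbar)
    if S > 1:
        pi = np.exp(logpi)
        grad_lam = (w - pi)[:, : S - 1].T @ gd.Z
    else:
        grad_lam = np.zeros((0, gd.Z.shape[1] if gd.Z is not None else 0))
    grad = np.concatenate([grad_beta.ravel(), grad_lam.ravel()])
    return ll, grad, w, np.exp(logpi)


def _fit_membership(lam0, Z, w, gtol=1e-7):
    """Weighted multinomial membership logit (concave M-step)."""
    n, q = Z.shape
    S = w.shape[1]

    def negll(theta):
        lam = theta.reshape(S - 1, q)
        eta = np.column_stack([Z @ lam.T, np.zeros(n)])
        logpi = _log_softmax_rows(eta)
        ll = float((w * logpi).sum())
        pi = np.exp(logpi)
        grad = (w - pi)[:, : S - 1].T @ Z
        return -ll, -grad.ravel()

    res = scipy.optimize.minimize(
        negll, np.asarray(lam0, float).ravel(), jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": 200},
    )
    return res.x.reshape(S - 1, q)


@dataclass
class LCLFit:
    params: LCLParameters
    loglik: float
    ics: InformationCriteria
    class_shares: np.ndarray  # mean prior membership probabilities
    posterior: np.ndarray  # (n_units, S)
    assigned_share: np.ndarray  # modal-posterior assignment fractions
    n_units: int
    k: int
    converged: bool
    em_history: list
    pseudo_r2: float
    cov: np.ndarray | None = None
    wald: "WaldResult | None" = None
    _gd: GroupedDesign | None = field(default=None, repr=False)

    def coef_frame(self) -> pd.DataFrame:
        S = self.params.S
        df = pd.DataFrame(
            self.params.beta.T,
            index=list(self.params.columns),
            columns=[f"class_{s + 1}" for s in range(S)],
        )
        return df


def _canonicalize(params: LCLParameters, gd: GroupedDesign) -> LCLParameters:
    """Relabel classes by descending mean prior share; reference last."""
    S = params.S
    if S == 1:
        return params
    pi = class_membership_probs(params.lam, gd.Z)
    order = np.argsort(-pi.mean(axis=0), kind="stable")
    beta = params.beta[order]
    # rebuild lambda relative to the new reference (last after reorder)
    q = params.lam.shape[1]
    lam_full = np.vstack([params.lam, np.zeros(q)])[order]
    lam = lam_full[: S - 1] - lam_full[S - 1]
    return LCLParameters(
        beta=beta, lam=lam, columns=params.columns, z_columns=params.z_columns
    )


def fit_lcl(
    gd: GroupedDesign,
    S: int,
    seed: int = 0,
    n_starts: int = 10,
    max_em: int = 200,
    em_tol: float = 1e-7,
    gtol: float = 1e-5,
    polish: bool = True,
    compute_cov: bool = False,
) -> LCLFit:
    """EM + quasi-Newton latent-class fit, best of ``n_starts`` starts."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if S > 1 and gd.Z is None:
        raise ValueError(
            "grouped design was built without membership covariates; "
            "pass membership_covariates to grouped_design()"
        )
    uptr = _unit_ptr(gd)
    p = gd.p
    q = gd.Z.shape[1] if gd.Z is not None else 1
    base = fit_mnl(gd)

    if S == 1:
        params = LCLParameters(
            beta=base.params[None, :],
            lam=np.zeros((0, q)),
            columns=gd.columns,
            z_columns=gd.z_columns,
        )
        ll = base.loglik
        k = p
        ics = information_criteria(ll, k, gd.n_units)
        post = np.ones((gd.n_units, 1))
        return LCLFit(
            params=params, loglik=ll, ics=ics,
            class_shares=np.ones(1), posterior=post,
            assigned_share=np.ones(1), n_units=gd.n_units, k=k,
            converged=base.converged, em_history=[ll],
            pseudo_r2=1.0 - ll / null_loglik(gd), cov=base.cov, _gd=gd,
        )

    rng = np.random.default_rng(seed)
    best = None
    for _start in range(n_starts):
        beta = base.params[None, :] + rng.normal(scale=0.5, size=(S, p))
        lam = rng.normal(scale=0.2, size=(S - 1, q))
        params = LCLParameters(beta=beta, lam=lam, columns=gd.columns,
                               z_columns=gd.z_columns)
        history: list[float] = []
        ll_prev = -np.inf
        collapsed = False
        for _it in range(max_em):
            ll, _, w, pi = _ll_grad(params, gd, uptr)
            history.append(ll)
            if ll < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
                raise RuntimeError(
                    f"EM decreased the log-likelihood: {ll_prev} -> {ll}"
                )
            if w.mean(axis=0).min() < 1e-4:
                warnings.warn("class collapsed during EM; restarting")
                collapsed = True
                break
            if ll - ll_prev < em_tol * (1.0 + abs(ll)):
                break
            ll_prev = ll
            # M-step: weighted conditional logit per class
            new_beta = np.empty_like(params.beta)
            for s in range(S):
                w_g = w[gd.unit_of_group, s]
                m = fit_mnl(
                    gd, start=params.beta[s], weights=w_g,
                    gtol=1e-6, maxiter=60, check_rank=False, strict=False,
                )
                new_beta[s] = m.params
            new_lam = _fit_membership(params.lam, gd.Z, w)
            params = LCLParameters(beta=new_beta, lam=new_lam,
                                   columns=gd.columns, z_columns=gd.z_columns)
        if collapsed:
            continue
        if polish:
            theta0 = params.pack()

            def negll(theta):
                pp = LCLParameters.unpack(theta, S, p, q)
                ll_, g_, _, _ = _ll_grad(pp, gd, uptr)
                return -ll_, -g_

            res = scipy.optimize.minimize(
                negll, theta0, jac=True, method="BFGS",
                options={"gtol": gtol, "maxiter": 500},
            )
            if -res.fun >= history[-1] - 1e-8:
                params = LCLParameters.unpack(res.x, S, p, q,
                                              columns=gd.columns,
                                              z_columns=gd.z_columns)
                history.append(-res.fun)
        ll_final = history[-1]
        if best is None or ll_final > best[0]:
            best = (ll_final, params, history)

    if best is None:
        raise ConvergenceError("all latent-class starts collapsed or failed")
    ll, params, history = best
    params = _canonicalize(params, gd)
    ll, grad, w, pi = _ll_grad(params, gd, uptr)
    shares = pi.mean(axis=0)
    assigned = np.bincount(w.argmax(axis=1), minlength=S) / gd.n_units
    k = S * p + (S - 1) * q
    ics = information_criteria(ll, k, gd.n_units)
    converged = bool(np.max(np.abs(grad)) < max(10 * gtol * (1 + abs(ll) / 100), 1e-3))
    fit = LCLFit(
        params=params, loglik=ll, ics=ics, class_shares=shares,
        posterior=w, assigned_share=assigned, n_units=gd.n_units, k=k,
        converged=converged, em_history=history,
        pseudo_r2=1.0 - ll / null_loglik(gd), _gd=gd,
    )
    if compute_cov:
        fit.cov = _full_covariance(fit, gd)
    return fit


def _full_covariance(fit: LCLFit, gd: GroupedDesign) -> np.ndarray:
    """Inverse observed information via central differences of the gradient."""
    uptr = _unit_ptr(gd)
    S, p = fit.params.beta.shape
    q = fit.params.lam.shape[1] if S > 1 else (gd.Z.shape[1] if gd.Z is not None else 1)
    theta = fit.params.pack()
    dim = len(theta)

    def grad_at(t):
        pp = LCLParameters.unpack(t, S, p, q)
        _, g, _, _ = _ll_grad(pp, gd, uptr)
        return g

    H = np.empty((dim, dim))
    for j in range(dim):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_at(tp) - grad_at(tm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return scipy.linalg.pinvh(-H)


class WaldResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def wald_joint_test(
    fit: LCLFit,
    restrictions: str = "all",
) -> WaldResult:
    """Wald chi-square test of joint-zero restrictions.

    ``restrictions``: "all" tests every non-reference membership
    coefficient together with all class-difference terms beta_s -
    beta_S; "membership" tests only the membership coefficients;
    "membership_covariates" excludes the membership intercepts.
    """
    if fit.params.S < 2:
        raise ValueError("Wald test needs S >= 2")
    if fit.cov is None:
        if fit._gd is None:
            raise ValueError("fit carries no covariance and no data reference")
        fit.cov = _full_covariance(fit, fit._gd)
    S, p = fit.params.beta.shape
    q = fit.params.lam.shape[1]
    dim = S * p + (S - 1) * q
    rows = []
    if restrictions == "all":
        for s in range(S - 1):
            for j in range(p):
                r = np.zeros(dim)
                r[s * p + j] = 1.0
                r[(S - 1) * p + j] = -1.0
                rows.append(r)
    if restrictions in ("all", "membership"):
        for s in range(S - 1):
            for j in range(q):
                r = np.zeros(dim)
                r[S * p + s * q + j] = 1.0
                rows.append(r)
    elif restrictions == "membership_covariates":
        for s in range(S - 1):
            for j in range(1, q):
                r = np.zeros(dim)
                r[S * p + s * q + j] = 1.0
                rows.append(r)
    elif restrictions != "all":
        raise ValueError(f"unknown restrictions {restrictions!r}")
    R = np.vstack(rows)
    theta = fit.params.pack()
    r = R @ theta
    V = R @ fit.cov @ R.T
    try:
        stat = float(r @ scipy.linalg.solve(V, r, assume_a="pos"))
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular restricted covariance") from exc
    df = len(rows)
    return WaldResult(statistic=stat, df=df,
                      pvalue=float(scipy.stats.chi2.sf(stat, df)))


@dataclass
class SelectionResult:
    chosen_S: int
    criterion: str
    table: pd.DataFrame
    fits: dict
    errors: dict


def select_classes(
    gd: GroupedDesign,
    S_range,
    criterion: str = "bic",
    **fit_kwargs,
) -> SelectionResult:
    """Fit each S and pick the argmin of the chosen criterion."""
    S_range = list(S_range)
    if not S_range:
        raise ValueError("empty S range")
    if criterion not in ("aic", "bic", "caic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows, fits, errors = [], {}, {}
    for S in S_range:
        try:
            fit = fit_lcl(gd, S, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            errors[S] = exc
            rows.append({"S": S, "loglik": np.nan, "aic": np.nan,
                         "bic": np.nan, "caic": np.nan})
            continue
        fits[S] = fit
        rows.append({"S": S, "loglik": fit.loglik, "aic": fit.ics.aic,
                     "bic": fit.ics.bic, "caic": fit.ics.caic})
    table = pd.DataFrame(rows).set_index("S")
    if not fits:
        raise ConvergenceError(f"no class count could be fitted: {errors}")
    chosen = int(table[criterion].idxmin())
    return SelectionResult(chosen_S=chosen, criterion=criterion, table=table,
                           fits=fits, errors=errors)
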