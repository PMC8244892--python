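"""Conditional (multinomial) logit: likelihood, gradient, and MLE.

All estimators in this package operate on a :class:`GroupedDesign`, a
row-sorted view of the long-format data with situation and mixture-unit
boundaries precomputed, so likelihood evaluations are pure vectorized
segment operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .data import (
    SITUATION_KEY,
    AttributeScheme,
    ChoiceDataset,
    build_design_matrix,
)

__all__ = [
    "GroupedDesign",
    "MNLFit",
    "RankError",
    "ConvergenceError",
    "grouped_design",
    "choice_probabilities",
    "mnl_loglik",
    "fit_mnl",
    "mcfadden_r2",
]


class RankError(ValueError):
    """Design matrix is collinear on the informative (within-situation) rows."""


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class GroupedDesign:
    """Row-sorted design matrix with situation/unit segment structure."""

    X: np.ndarray  # (n_rows, p)
    columns: tuple[str, ...]
    chosen: np.ndarray  # bool (n_rows,)
    group_ptr: np.ndarray  # (G+1,) row offsets per situation
    unit_of_group: np.ndarray  # (G,) unit index per situation
    n_units: int
    Z: np.ndarray | None = None  # (n_units, q) membership covariates (incl. intercept)
    z_columns: tuple[str, ...] = ()
    unit_ids: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_ptr) - 1

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def group_of_row(self) -> np.ndarray:
        g = np.zeros(self.n_rows, dtype=np.int64)
        g[self.group_ptr[1:-1]] = 1
        return np.cumsum(g)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.diff(self.group_ptr)

    @property
    def chosen_rows(self) -> np.ndarray:
        return np.flatnonzero(self.chosen)


def grouped_design(
    ds: ChoiceDataset,
    scheme: AttributeScheme | None = None,
    unit: str = "plot",
    membership_covariates: tuple[str, ...] | None = None,
) -> GroupedDesign:
    """Build the grouped design matrix from a validated dataset.

    ``unit`` ("plot" or "respondent") sets the mixture unit used by the
    latent-class and attendance models.  ``membership_covariates`` picks
    covariate columns for the membership logit; an intercept column is
    prepended automatically.
    """
    scheme = scheme or ds.scheme
    dm = build_design_matrix(ds, scheme)
    df = ds.df  # already key-sorted by from_frame
    if unit == "plot":
        unit_key = ["respondent_id", "plot_id"]
    elif unit == "respondent":
        unit_key = ["respondent_id"]
    else:
        raise ValueError(f"unknown unit {unit!r}")

    unit_codes, unit_uniques = pd.factorize(
        pd.MultiIndex.from_frame(df[unit_key]), sort=False
    )
    grp_codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(df[list(SITUATION_KEY)]), sort=False
    )
    # rows are sorted by keys, so codes are non-decreasing
    boundaries = np.flatnonzero(np.diff(grp_codes)) + 1
    group_ptr = np.concatenate(([0], boundaries, [len(df)]))
    unit_of_group = unit_codes[group_ptr[:-1]]
    n_units = int(unit_codes.max()) + 1

    Z = None
    z_columns: tuple[str, ...] = ()
    if membership_covariates is not None:
        missing = [c for c in membership_covariates if c not in df.columns]
        if missing:
            raise KeyError(f"membership covariates not in data: {missing}")
        first_rows = np.searchsorted(unit_codes, np.arange(n_units))
        zvals = df.iloc[first_rows][list(membership_covariates)].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n_units), zvals])
        z_columns = ("intercept",) + tuple(membership_covariates)

    return GroupedDesign(
        X=dm.values,
        columns=dm.columns,
        chosen=df["chosen"].to_numpy(dtype=bool),
        group_ptr=group_ptr,
        unit_of_group=unit_of_group,
        n_units=n_units,
        Z=Z,
        z_columns=z_columns,
        unit_ids=np.asarray(unit_uniques),
    )


def choice_probabilities(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Softmax choice probabilities for one situation's rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("a situation needs >= 2 alternatives")
    u = X @ np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite utilities")
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def _segment_logsumexp(u: np.ndarray, gd: GroupedDesign):
    """Per-situation logsumexp of utilities plus row-level probabilities."""
    ptr = gd.group_ptr
    gmax = np.maximum.reduceat(u, ptr[:-1])
    e = np.exp(u - np.repeat(gmax, gd.group_sizes))
    denom = np.add.reduceat(e, ptr[:-1])
    lse = gmax + np.log(denom)
    probs = e / np.repeat(denom, gd.group_sizes)
    return lse, probs


def situation_logprobs(beta: np.ndarray, gd: GroupedDesign):
    """log P(chosen) per situation and row probabilities."""
    u = gd.X @ beta
    lse, probs = _segment_logsumexp(u, gd)
    logp = u[gd.chosen] - lse
    return logp, probs


def mnl_loglik(
    beta: np.ndarray,
    gd: GroupedDesign,
    weights: np.ndarray | None = None,
):
    """Log-likelihood and analytic gradient (optionally situation-weighted)."""
    beta = np.asarray(beta, dtype=float)
    logp, probs = situation_logprobs(beta, gd)
    if weights is None:
        ll = float(logp.sum())
        grad = gd.X[gd.chosen].sum(axis=0) - probs @ gd.X
    else:
        ll = float(weights @ logp)
        w_row = np.repeat(weights, gd.group_sizes)
        grad = (
            weights[:, None] * gd.X[gd.chosen]
        ).sum(axis=0) - (w_row * probs) @ gd.X
    return ll, grad


def _information(beta, gd: GroupedDesign, weights=None) -> np.ndarray:
    """Observed information (negative Hessian) of the MNL log-likelihood."""
    _, probs = situation_logprobs(np.asarray(beta, float), gd)
    w_grp = np.ones(gd.n_groups) if weights is None else np.asarray(weights, float)
    w_row = np.repeat(w_grp, gd.group_sizes) * probs
    A = gd.X.T @ (gd.X * w_row[:, None])
    xbar = np.add.reduceat(gd.X * probs[:, None], gd.group_ptr[:-1], axis=0)
    B = (xbar * w_grp[:, None]).T @ xbar
    return A - B


def _check_rank(gd: GroupedDesign) -> None:
    # center within situation: only within-situation variation identifies beta
    means = np.add.reduceat(gd.X, gd.group_ptr[:-1], axis=0) / gd.group_sizes[:, None]
    Xc = gd.X - np.repeat(means, gd.group_sizes, axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < gd.p:
        _, _, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:])
        names = [gd.columns[i] for i in dropped]
        raise RankError(f"collinear design columns: {names}")


@dataclass
class MNLFit:
    params: np.ndarray
    columns: tuple[str, ...]
    loglik: float
    cov: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    pseudo_r2: float
    trace: list

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se}, index=list(self.columns)
        )


def null_loglik(gd: GroupedDesign) -> float:
    """Equal-shares log-likelihood: -sum over situations of ln J."""
    return float(-np.log(gd.group_sizes).sum())


def mcfadden_r2(ll_fit: float, gd: GroupedDesign) -> float:
    """1 - LL/LL0 against the equal-shares base model."""
    ll0 = null_loglik(gd)
    if ll0 == 0.0:
        raise ZeroDivisionError("equal-shares log-likelihood is zero")
    return 1.0 - ll_fit / ll0


def fit_mnl(
    gd: GroupedDesign,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    weights: np.ndarray | None = None,
    check_rank: bool = True,
    strict: bool = True,
) -> MNLFit:
    """Quasi-Newton MLE from beta = 0 with analytic gradient.

    Covariance is the inverse observed information at the optimum.
    """
    if check_rank:
        _check_rank(gd)
    # precondition: optimize on columns normalized by their within-situation
    # spread so convergence is invariant to the cost scaling convention
    means = np.add.reduceat(gd.X, gd.group_ptr[:-1], axis=0) / gd.group_sizes[:, None]
    Xc = gd.X - np.repeat(means, gd.group_sizes, axis=0)
    col_scale = np.sqrt((Xc**2).mean(axis=0))
    col_scale[col_scale < 1e-12] = 1.0
    x0 = np.zeros(gd.p) if start is None else np.asarray(start, dtype=float)
    trace: list[float] = []

    def negll(b_scaled):
        ll, g = mnl_loglik(b_scaled / col_scale, gd, weights=weights)
        trace.append(ll)
        return -ll, -g / col_scale

    res = scipy.optimize.minimize(
        negll, x0 * col_scale, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    res.x = res.x / col_scale
    _, grad = mnl_loglik(res.x, gd, weights=weights)
    grad = grad / col_scale  # convergence judged on the preconditioned scale
    # gradient of a summed log-likelihood scales with n; accept a small
    # absolute residual even when the line search reports precision loss
    converged = bool(np.max(np.abs(grad)) < max(gtol, 1e-3))
    if strict and not converged and not res.success:
        raise ConvergenceError(
            f"MNL did not converge: {res.message} (|grad|_inf = "
            f"{np.max(np.abs(grad)):.3g})",
            trace=trace,
        )
    info = _information(res.x, gd, weights=weights)
    cov = scipy.linalg.pinvh(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return MNLFit(
        params=res.x,
        columns=gd.columns,
        loglik=-res.fun,
        cov=cov,
        se=se,
        converged=converged,
        n_iter=res.nit,
        pseudo_r2=mcfadden_r2(-res.fun, gd),
        trace=trace,
    )
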