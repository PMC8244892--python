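"""Endogenous attribute attendance: mixture over attendance subsets.

Each free component (a design-matrix column, or a joint block of
columns sharing one attendance parameter) is attended with probability
pi = logistic(gamma), independently across components and fixed across a
unit's choice situations.  The likelihood marginalizes the conditional
logit over all attendance subsets; ignored components have their
coefficients zeroed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from .latent import InformationCriteria, _unit_ptr, information_criteria
from .mnl import ConvergenceError, GroupedDesign, fit_mnl, null_loglik

__all__ = [
    "AttendanceStructure",
    "EAAParameters",
    "EAAFit",
    "CapacityError",
    "enumerate_attendance_sets",
    "eaa_loglik",
    "fit_eaa",
    "fit_joint_exclusion",
]

MAX_FREE_COMPONENTS = 16


class CapacityError(ValueError):
    """More free attendance components than the 2^16 subset cap allows."""


@dataclass(frozen=True)
class AttendanceStructure:
    """Partition of design-matrix columns into attendance components.

    ``always``: columns attended with probability one.  ``free``: one
    tuple of columns per free component; singleton tuples are individual
    attributes, longer tuples are joint blocks sharing one attendance
    parameter.
    """

    columns: tuple[str, ...]
    always: tuple[str, ...] = ()
    free: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        listed = list(self.always) + [c for comp in self.free for c in comp]
        if sorted(listed) != sorted(self.columns):
            extra = set(listed) - set(self.columns)
            missing = set(self.columns) - set(listed)
            raise ValueError(
                f"attendance structure must partition the design columns "
                f"(extra={sorted(extra)}, missing={sorted(missing)})"
            )
        if len(listed) != len(set(listed)):
            raise ValueError("a column appears in more than one component")
        if len(self.free) > MAX_FREE_COMPONENTS:
            raise CapacityError(
                f"{len(self.free)} free components exceed the "
                f"2^{MAX_FREE_COMPONENTS} subset cap"
            )
        if not self.free:
            raise ValueError("at least one free component is required")

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple("+".join(comp) for comp in self.free)

    def masks(self) -> np.ndarray:
        """(2^F, p) boolean column masks, one per attendance subset."""
        p = len(self.columns)
        col_idx = {c: i for i, c in enumerate(self.columns)}
        base = np.zeros(p, dtype=bool)
        for c in self.always:
            base[col_idx[c]] = True
        comp_cols = [
            np.array([col_idx[c] for c in comp], dtype=int) for comp in self.free
        ]
        subsets = list(itertools.product((False, True), repeat=self.n_free))
        masks = np.empty((len(subsets), p), dtype=bool)
        attend = np.array(subsets, dtype=bool)  # (2^F, F)
        for i, row in enumerate(attend):
            m = base.copy()
            for f, on in enumerate(row):
                if on:
                    m[comp_cols[f]] = True
            masks[i] = m
        return masks

    def attend_matrix(self) -> np.ndarray:
        """(2^F, F) attendance indicator per subset (same order as masks)."""
        return np.array(
            list(itertools.product((False, True), repeat=self.n_free)), dtype=bool
        )

    @classmethod
    def individual(
        cls, columns, always: tuple[str, ...] = ()
    ) -> "AttendanceStructure":
        """Every non-pinned column its own free component."""
        free = tuple((c,) for c in columns if c not in always)
        return cls(columns=tuple(columns), always=tuple(always), free=free)

    @classmethod
    def joint_block(
        cls, columns, block: tuple[str, ...]
    ) -> "AttendanceStructure":
        """One joint block; every remaining column always attended."""
        block = tuple(block)
        if not block:
            raise ValueError("joint block must be non-empty")
        missing = [c for c in block if c not in columns]
        if missing:
            raise KeyError(f"block columns not in design: {missing}")
        always = tuple(c for c in columns if c not in block)
        if not always:
            raise ValueError("joint block cannot cover every design column")
        return cls(columns=tuple(columns), always=always, free=(block,))


@dataclass
class EAAParameters:
    beta: np.ndarray  # (p,)
    gamma: np.ndarray  # (F,) attendance logits per free component
    structure: AttendanceStructure

    @property
    def attendance_probs(self) -> np.ndarray:
        return scipy.special.expit(self.gamma)

    @property
    def ana_probs(self) -> dict:
        """Probability each free component is ignored (1 - attendance)."""
        pis = self.attendance_probs
        return {
            name: float(1.0 - pi)
            for name, pi in zip(self.structure.component_names, pis)
        }


def enumerate_attendance_sets(params: EAAParameters):
    """All attendance subsets with their prior probabilities.

    Returns a list of (attended column tuple, prior); priors sum to 1.
    """
    st = params.structure
    masks = st.masks()
    attend = st.attend_matrix()
    logpri = _subset_log_priors(params.gamma, attend)
    pri = np.exp(logpri)
    out = []
    for mask, prob in zip(masks, pri):
        cols = tuple(c for c, on in zip(st.columns, mask) if on)
        out.append((cols, float(prob)))
    return out


def _subset_log_priors(gamma: np.ndarray, attend: np.ndarray) -> np.ndarray:
    """log prior of each subset: sum of Bernoulli(pi) log-masses."""
    log_pi = -np.logaddexp(0.0, -gamma)  # log sigmoid(g)
    log_1mpi = -np.logaddexp(0.0, gamma)
    # select-then-sum (not matmul) so +-inf gammas stay well defined
    return np.where(attend, log_pi, log_1mpi).sum(axis=1)


def _unit_class_logp(beta_masked: np.ndarray, gd: GroupedDesign, uptr) -> np.ndarray:
    """(n_units, n_subsets) log-likelihood of each unit under each mask."""
    U = gd.X @ np.ascontiguousarray(beta_masked.T)  # (n_rows, C)
    sizes = gd.group_sizes
    J = sizes[0]
    if (sizes == J).all():
        # uniform situation size: reshape beats ragged reduceat
        G = gd.n_groups
        U3 = U.reshape(G, J, -1)
        gmax = U3.max(axis=1)
        E3 = np.exp(U3 - gmax[:, None, :])
        denom = E3.sum(axis=1)
        probs = (E3 / denom[:, None, :]).reshape(U.shape)
    else:
        gmax = np.maximum.reduceat(U, gd.group_ptr[:-1], axis=0)
        E = np.exp(U - np.repeat(gmax, sizes, axis=0))
        denom = np.add.reduceat(E, gd.group_ptr[:-1], axis=0)
        probs = E / np.repeat(denom, sizes, axis=0)
    logp = U[gd.chosen] - gmax - np.log(denom)  # (G, C)
    A = np.add.reduceat(logp, uptr[:-1], axis=0)  # (n_units, C)
    return A, probs


def eaa_loglik(params: EAAParameters, gd: GroupedDesign) -> float:
    """Marginal log-likelihood over attendance subsets (log-sum-exp)."""
    ll, _ = _eaa_ll_grad(params.beta, params.gamma, params.structure, gd,
                         _unit_ptr(gd), want_grad=False)
    return ll


def _eaa_ll_grad(beta, gamma, st: AttendanceStructure, gd, uptr, want_grad=True,
                 cache=None):
    if cache is None:
        masks = st.masks()  # (C, p)
        attend = st.attend_matrix()  # (C, F)
    else:
        masks, attend = cache
    beta_masked = beta[None, :] * masks
    A, probs = _unit_class_logp(beta_masked, gd, uptr)
    logpri = _subset_log_priors(gamma, attend)
    M = A + logpri[None, :]
    m = M.max(axis=1, keepdims=True)
    e = np.exp(M - m)
    denom = e.sum(axis=1, keepdims=True)
    ll = float((m[:, 0] + np.log(denom[:, 0])).sum())
    if not want_grad:
        return ll, None
    w = e / denom  # posterior subset weights (n_units, C)
    x_ch = gd.X[gd.chosen]
    W_grp = w[gd.unit_of_group]  # (G, C)
    W_row = np.repeat(W_grp, gd.group_sizes, axis=0)  # (n_rows, C)
    # sum over situations of w * (x_chosen - E[x]) for every subset at once
    T = x_ch.T @ W_grp - gd.X.T @ (W_row * probs)  # (p, C)
    grad_beta = (masks * T.T).sum(axis=0)
    pi = scipy.special.expit(gamma)
    W_attend = w @ attend  # (n_units, F) posterior attendance probs
    grad_gamma = (W_attend - pi).sum(axis=0)
    return ll, np.concatenate([grad_beta, grad_gamma])


@dataclass
class EAAFit:
    params: EAAParameters
    loglik: float
    ana_probs: dict
    ics: InformationCriteria
    n_units: int
    k: int
    converged: bool
    boundary_flags: dict
    pseudo_r2: float
    columns: tuple[str, ...] = ()
    start_loglik: float | None = None
    cov: np.ndarray | None = None

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params.beta}, index=list(self.columns))


def fit_eaa(
    gd: GroupedDesign,
    structure: AttendanceStructure | None = None,
    seed: int = 0,
    n_starts: int = 3,
    gtol: float = 1e-6,
    maxiter: int = 1000,
    gamma_fixed: np.ndarray | None = None,
) -> EAAFit:
    """Maximize the attendance-mixture likelihood (multistart L-BFGS).

    The first start embeds the plain conditional logit (its coefficients
    with attendance logits at +2); additional starts perturb it.  When
    ``gamma_fixed`` is given (per free component, NaN = free) those
    attendance logits are held at the supplied values.
    """
    if structure is None:
        structure = AttendanceStructure.individual(gd.columns)
    uptr = _unit_ptr(gd)
    F = structure.n_free
    p = gd.p
    base = fit_mnl(gd)

    fixed = np.full(F, np.nan) if gamma_fixed is None else np.asarray(
        gamma_fixed, dtype=float
    )
    free_g = np.isnan(fixed)

    def expand_gamma(gfree):
        g = fixed.copy()
        g[free_g] = gfree
        return g

    cache = (structure.masks(), structure.attend_matrix())

    def negll(theta):
        beta = theta[:p]
        gamma = expand_gamma(theta[p:])
        ll, grad = _eaa_ll_grad(beta, gamma, structure, gd, uptr, cache=cache)
        g = np.concatenate([grad[:p], grad[p:][free_g]])
        return -ll, -g

    rng = np.random.default_rng(seed)
    start0 = np.concatenate([base.params, np.full(free_g.sum(), 2.0)])
    start_ll = -negll(start0)[0]
    best = None
    for i in range(n_starts):
        x0 = start0 if i == 0 else start0 + rng.normal(
            scale=0.5, size=start0.shape
        )
        res = scipy.optimize.minimize(
            negll, x0, jac=True, method="L-BFGS-B",
            options={"gtol": gtol, "maxiter": maxiter, "ftol": 1e-12},
        )
        if best is None or -res.fun > -best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("EAA optimization failed")
    ll = -best.fun
    if ll < start_ll - 1e-8:
        # optimizer contract: never worse than the MNL-embedded start
        ll = start_ll
        best_x = start0
    else:
        best_x = best.x
    beta = best_x[:p]
    gamma = expand_gamma(best_x[p:])
    params = EAAParameters(beta=beta, gamma=gamma, structure=structure)
    boundary = {
        name: bool(abs(g) > 6.0)
        for name, g in zip(structure.component_names, gamma)
    }
    k = p + int(free_g.sum())
    ics = information_criteria(ll, k, gd.n_units)
    return EAAFit(
        params=params, loglik=ll, ana_probs=params.ana_probs, ics=ics,
        n_units=gd.n_units, k=k, converged=bool(best.success),
        boundary_flags=boundary, pseudo_r2=1.0 - ll / null_loglik(gd),
        columns=gd.columns, start_loglik=start_ll,
    )


def fit_joint_exclusion(
    gd: GroupedDesign,
    block: tuple[str, ...],
    seed: int = 0,
    n_starts: int = 3,
    exclusion_prob: float | None = None,
) -> EAAFit:
    """Joint-exclusion variant: the block's columns share one attendance
    parameter (all-in or all-out); every other column is always attended.

    ``exclusion_prob`` pins the block's exclusion probability instead of
    estimating it (0 reduces to the full-attendance conditional logit).
    """
    structure = AttendanceStructure.joint_block(gd.columns, tuple(block))
    gamma_fixed = None
    if exclusion_prob is not None:
        if not 0.0 <= exclusion_prob <= 1.0:
            raise ValueError("exclusion_prob must be in [0, 1]")
        attend = np.clip(1.0 - exclusion_prob, 1e-12, 1 - 1e-12)
        gamma_fixed = np.array([scipy.special.logit(attend)])
    fit = fit_eaa(
        gd, structure, seed=seed, n_starts=n_starts, gamma_fixed=gamma_fixed
    )
    return fit
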