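"""Choice-set design: full factorial, D-efficiency, and swap search.

The efficiency score is the normalized D-criterion of the multinomial
logit information matrix under a fixed prior (zero by default), with the
determinant scaled against a per-column variance bound so that a fully
orthogonal, maximally balanced design scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AttributeScheme, Profile, enumerate_full_factorial

__all__ = [
    "ChoiceDesign",
    "ConfigurationError",
    "enumerate_full_factorial",
    "d_efficiency",
    "generate_design",
    "design_to_frame",
    "design_from_frame",
]


class ConfigurationError(ValueError):
    """Design request cannot be satisfied (e.g. distinctness infeasible)."""


@dataclass
class ChoiceDesign:
    """A design: ordered choice sets of designed profiles.

    A status-quo slot is appended to every set when the design is turned
    into survey alternatives; ``status_quo_profile`` is that slot's
    default profile (current practice, zeros unless overridden).
    """

    sets: tuple[tuple[Profile, ...], ...]
    efficiency: float | None = None
    rng_seed: int | None = None
    status_quo_profile: Profile | None = None

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_alts(self) -> int:
        return len(self.sets[0]) if self.sets else 0

    def profiles(self) -> list[Profile]:
        """All designed profiles in set order (status quo excluded)."""
        return [p for s in self.sets for p in s]

    def distinct_profiles(self) -> set[Profile]:
        return set(self.profiles())

    def alternatives(self, scheme: AttributeScheme) -> tuple[tuple[Profile, ...], ...]:
        """Sets with the status-quo slot appended."""
        sq = self.status_quo_profile or Profile.status_quo(scheme)
        return tuple(s + (sq,) for s in self.sets)


def _design_model_width(scheme: AttributeScheme) -> int:
    return len(scheme.cost_levels) - 1 + len(scheme.binary_attributes)


def _model_matrix(profiles, scheme: AttributeScheme) -> np.ndarray:
    """Main-effects design-stage matrix.

    The monetary attribute enters as level dummies (base = lowest level)
    so the D-criterion rewards spreading profiles over all price levels;
    a continuous coding degenerates to a two-point cost distribution.
    """
    cost = scheme.cost_attribute
    cost_codes = {lvl: i for i, lvl in enumerate(cost.codes)}
    n_levels = len(cost.codes)
    rows = []
    for p in profiles:
        dummies = [0.0] * (n_levels - 1)
        lvl = cost_codes[float(p.levels[cost.name])]
        if lvl > 0:
            dummies[lvl - 1] = 1.0
        row = dummies + [float(p.levels[a.name]) for a in scheme.binary_attributes]
        rows.append(row)
    return np.asarray(rows, dtype=float)


def _information_matrix(design: ChoiceDesign, scheme: AttributeScheme, prior: np.ndarray) -> np.ndarray:
    """Mean (over sets) MNL information of the main-effects model."""
    k = _design_model_width(scheme)
    M = np.zeros((k, k))
    for s in design.sets:
        X = _model_matrix(s, scheme)
        u = X @ prior
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        xb = p @ X
        Xc = X - xb
        M += Xc.T @ (Xc * p[:, None])
    return M / len(design.sets)


def _efficiency_bound(scheme: AttributeScheme, n_alts: int) -> float:
    """Hadamard-style determinant bound: product of max per-column variances.

    For a 0/1 dummy over m alternatives the variance is at most
    f(1-f) with f = floor(m/2)/m; for the cost column it is the two-point
    split between the extreme levels.  Orthogonal balanced designs attain
    the product, so the normalized score is 1 there and < 1 elsewhere.
    """
    m = n_alts
    f = (m // 2) / m
    v_col = f * (1.0 - f)
    return v_col ** _design_model_width(scheme)


def d_efficiency(
    design: ChoiceDesign,
    scheme: AttributeScheme,
    prior: np.ndarray | None = None,
) -> float:
    """Normalized D-efficiency in [0, 1]; singular information scores 0."""
    if not design.sets:
        raise ConfigurationError("empty design")
    k = _design_model_width(scheme)
    if prior is None:
        prior = np.zeros(k)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (k,):
        raise ConfigurationError(
            f"prior must have length {k} (cost-level dummies + binary attributes)"
        )
    M = _information_matrix(design, scheme, prior)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular information matrix; design carries no information")
        return 0.0
    bound = _efficiency_bound(scheme, design.n_alts)
    eff = np.exp((logdet - np.log(bound)) / k)
    return float(min(eff, 1.0))


def _logdet_objective(sets, scheme, prior) -> float:
    d = ChoiceDesign(sets=tuple(tuple(s) for s in sets))
    M = _information_matrix(d, scheme, prior)
    sign, logdet = np.linalg.slogdet(M)
    return logdet if sign > 0 else -np.inf


def generate_design(
    scheme: AttributeScheme,
    n_sets: int,
    n_alts: int,
    seed: int = 0,
    prior: np.ndarray | None = None,
    pinned: tuple[Profile, ...] = (),
    n_iter: int = 4000,
) -> ChoiceDesign:
    """Coordinate-swap hill climb for a D-efficient design.

    Starts from a seeded random draw of distinct profiles (any pinned
    profiles are placed first and never mutated) and accepts a random
    single-attribute level change whenever the information log-det does
    not decrease.  Deterministic given ``seed``.
    """
    factorial = enumerate_full_factorial(scheme)
    if n_sets * n_alts > len(factorial):
        raise ConfigurationError(
            f"{n_sets}x{n_alts} distinct profiles requested but the full "
            f"factorial has only {len(factorial)}"
        )
    pinned = tuple(pinned)
    if len(set(pinned)) != len(pinned):
        raise ConfigurationError("pinned profiles must be distinct")
    if len(pinned) > n_sets * n_alts:
        raise ConfigurationError("more pinned profiles than design slots")
    for p in pinned:
        p.validate(scheme)
        if p not in factorial:
            raise ConfigurationError("pinned profile outside the full factorial")

    k = _design_model_width(scheme)
    if prior is None:
        prior = np.zeros(k)
    prior = np.asarray(prior, dtype=float)
    rng = np.random.default_rng(seed)

    pool = [p for p in factorial if p not in pinned]
    order = rng.permutation(len(pool))
    flat = list(pinned) + [pool[i] for i in order[: n_sets * n_alts - len(pinned)]]
    sets = [flat[i * n_alts : (i + 1) * n_alts] for i in range(n_sets)]

    best = _logdet_objective(sets, scheme, prior)
    start_obj = best
    names = list(scheme.names)
    n_pinned = len(pinned)

    for _ in range(n_iter):
        si = int(rng.integers(n_sets))
        ai = int(rng.integers(n_alts))
        if si * n_alts + ai < n_pinned:
            continue  # pinned slot
        attr = names[int(rng.integers(len(names)))]
        a = scheme[attr]
        current = sets[si][ai].levels[attr]
        choices = [c for c in a.codes if c != current]
        new_level = choices[int(rng.integers(len(choices)))]
        new_levels = dict(sets[si][ai].levels)
        new_levels[attr] = new_level
        candidate = Profile(levels=new_levels)
        others = {p for j, s in enumerate(sets) for i, p in enumerate(s) if (j, i) != (si, ai)}
        if candidate in others:
            continue
        old = sets[si][ai]
        sets[si][ai] = candidate
        obj = _logdet_objective(sets, scheme, prior)
        if obj >= best:
            best = obj
        else:
            sets[si][ai] = old

    design = ChoiceDesign(
        sets=tuple(tuple(s) for s in sets),
        rng_seed=seed,
        status_quo_profile=Profile.status_quo(scheme),
    )
    design.efficiency = d_efficiency(design, scheme, prior)
    if start_obj > -np.inf and best < start_obj:  # pragma: no cover - guarded
        raise AssertionError("hill climb decreased the objective")
    return design


def design_to_frame(design: ChoiceDesign, scheme: AttributeScheme) -> pd.DataFrame:
    """One row per set x alternative with raw attribute levels."""
    rows = []
    for si, s in enumerate(design.sets):
        for ai, p in enumerate(s):
            row = {"set_id": si, "alternative_id": ai}
            row.update({name: p.levels[name] for name in scheme.names})
            rows.append(row)
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame, scheme: AttributeScheme) -> ChoiceDesign:
    sets = []
    for _, grp in df.sort_values(["set_id", "alternative_id"]).groupby("set_id"):
        profiles = []
        for _, row in grp.iterrows():
            levels = {name: row[name] for name in scheme.names}
            for a in scheme.binary_attributes:
                levels[a.name] = int(levels[a.name])
            profiles.append(Profile(levels=levels))
        sets.append(tuple(profiles))
    return ChoiceDesign(
        sets=tuple(sets), status_quo_profile=Profile.status_quo(scheme)
    )
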