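"""Study-shaped synthetic populations, soil profiles, and choice data.

Generators draw covariates from configurable marginal distributions,
grade simulated soil chemistry per hub, and produce long-format choice
data under either the latent-class or the attendance-mixture
data-generating process.  Every stage draws from its own substream of
the master seed so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.special

from .data import (
    AttributeScheme,
    ChoiceDataset,
    Profile,
    build_design_matrix,
    default_scheme,
)
from .design import ChoiceDesign, generate_design
from .soil import (
    SOIL_PARAMETERS,
    DEGREES,
    LimitationThresholds,
    SoilProfile,
    classify_plot,
    default_thresholds,
    fertility_level,
)

__all__ = [
    "ClassSpec",
    "AttendanceSpec",
    "SimulationConfig",
    "study_config",
    "small_config",
    "eaa_config",
    "simulate_population",
    "simulate_choices_lcl",
    "simulate_choices_eaa",
]

HUBS = ("ADH2", "ADH3", "ADH4", "ADH5", "ADH6")

# Default marginal rates for the emulated survey population; joint
# independence across covariates is an assumption of the generator.
DEFAULT_COVARIATES = {
    "gender": {"dist": "bernoulli", "p": 0.5161},
    "education": {"dist": "bernoulli", "p": 0.45},
    "active_members": {"dist": "poisson", "lam": 6.74},
    "credit": {"dist": "bernoulli", "p": 0.1381},
    "acreage": {"dist": "lognormal", "mean": 3.8, "sigma": 0.6},
    "fallow": {"dist": "exponential", "mean": 2.0},
}

# Representative value ranges per limitation degree used when drawing a
# parameter conditional on a target degree.  Open-ended top/bottom
# intervals get a finite cap/floor.
_DEGREE_RANGES = {
    "organic_matter": [(2.0, 4.0), (1.5, 2.0), (1.0, 1.5), (0.5, 1.0), (0.05, 0.5)],
    "total_nitrogen": [
        (0.08, 0.16),
        (0.06, 0.08),
        (0.045, 0.06),
        (0.03, 0.045),
        (0.005, 0.03),
    ],
    "phosphorus": [(20.0, 40.0), (15.0, 20.0), (10.0, 15.0), (5.0, 10.0), (0.5, 5.0)],
    "potassium": [(0.4, 0.8), (0.3, 0.4), (0.2, 0.3), (0.1, 0.2), (0.01, 0.1)],
    "exchangeable_bases": [(10.0, 20.0), (7.5, 10.0), (5.0, 7.5), (2.0, 5.0), (0.2, 2.0)],
    "base_saturation": [(60.0, 95.0), (50.0, 60.0), (30.0, 50.0), (15.0, 30.0), (2.0, 15.0)],
    "cec": [(25.0, 40.0), (15.0, 25.0), (10.0, 15.0), (5.0, 10.0), (0.5, 5.0)],
    "ph": [(6.0, 6.5), (5.5, 6.0), (5.3, 5.5), (5.2, 5.3), (4.2, 5.2)],
}

# Class-specific utility coefficients used as the default truth of the
# three-class generator, aligned to the default design columns
# [status_quo, cost, restoration, accessibility, benefits, conservation,
#  maintenance, maintenance_x_cost, accessibility_x_cost].
DEFAULT_CLASS_BETA = np.array(
    [
        [-0.14, 0.04, 1.17, 0.33, 0.67, 0.14, 0.10, 0.03, 0.05],
        [-3.10, -0.05, 1.89, 0.65, 0.99, -1.68, 0.03, -0.05, -0.01],
        [-3.44, -0.34, 3.83, 0.98, 3.81, 0.81, -0.11, -0.08, -0.10],
    ]
)
DEFAULT_CLASS_SHARES = (0.33, 0.31, 0.36)

# Single-class truth of the attendance generator, aligned to the
# no-interaction design columns [status_quo, cost, restoration,
# accessibility, benefits, conservation, maintenance].
DEFAULT_EAA_BETA = np.array([-3.28, -0.10, 2.13, 0.66, 1.92, 2.95, -0.15])


@dataclass(frozen=True)
class ClassSpec:
    """Latent-class truth: per-class beta plus shares or membership lam."""

    beta: np.ndarray  # (S, p) aligned to scheme.design_columns
    shares: tuple | None = None  # intercept-only membership if given
    lam: np.ndarray | None = None  # (S-1, q) on (intercept + covariates)
    membership_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.shares is not None:
            sh = np.asarray(self.shares, dtype=float)
            if not np.isclose(sh.sum(), 1.0):
                raise ValueError("class shares must sum to 1")
            if (sh <= 0).any():
                raise ValueError("class shares must be positive")

    @property
    def S(self) -> int:
        return self.beta.shape[0]

    def membership_lam(self) -> np.ndarray:
        """(S-1, q) membership coefficients implied by the spec."""
        q = 1 + len(self.membership_covariates)
        if self.lam is not None:
            lam = np.asarray(self.lam, dtype=float)
            if lam.shape != (self.S - 1, q):
                raise ValueError(f"lam must have shape {(self.S - 1, q)}")
            return lam
        lam = np.zeros((self.S - 1, q))
        if self.shares is not None:
            sh = np.asarray(self.shares, dtype=float)
            lam[:, 0] = np.log(sh[:-1] / sh[-1])
        return lam


@dataclass(frozen=True)
class AttendanceSpec:
    """Attendance-mixture truth: ignore probabilities per component.

    ``pi_ignore`` maps a design column to its ignore probability; columns
    absent from the map and from any block are always attended.
    ``blocks`` lists (columns tuple, ignore probability) pairs whose
    members are jointly attended or ignored.
    """

    pi_ignore: dict = field(default_factory=dict)
    blocks: tuple = ()

    def __post_init__(self):
        for name, p in self.pi_ignore.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pi_ignore[{name!r}] must be in [0, 1]")
        for cols, p in self.blocks:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"block {cols}: probability must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_respondents: int = 962
    n_plots: int = 1047
    n_situations: int = 4
    n_designed_alts: int = 4
    scheme: AttributeScheme = field(default_factory=default_scheme)
    class_spec: ClassSpec | None = None
    attendance_spec: AttendanceSpec | None = None
    covariate_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    severe_parameters: dict = field(
        default_factory=lambda: {
            "ADH2": ("phosphorus", "exchangeable_bases", "cec"),
            "ADH3": ("cec",),
            "ADH4": ("phosphorus", "exchangeable_bases", "cec"),
            "ADH5": ("phosphorus",),
            "ADH6": ("phosphorus", "exchangeable_bases", "cec"),
        }
    )
    severe_prob: float = 0.7
    thresholds: LimitationThresholds = field(default_factory=default_thresholds)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_plots < self.n_respondents:
            raise ValueError("need at least one plot per respondent")
        if self.n_plots > 2 * self.n_respondents:
            raise ValueError("generator allocates at most 2 plots per respondent")
        if not 0.0 <= self.severe_prob <= 1.0:
            raise ValueError("severe_prob must be in [0, 1]")

    def resolved_class_spec(self) -> ClassSpec:
        if self.class_spec is not None:
            return self.class_spec
        return ClassSpec(
            beta=DEFAULT_CLASS_BETA,
            shares=DEFAULT_CLASS_SHARES,
            membership_covariates=("gender", "credit"),
        )

    def streams(self) -> dict:
        """Named independent RNG substreams of the master seed."""
        ss = np.random.SeedSequence(self.rng_seed)
        names = ("population", "soil", "design", "class", "attendance", "choice")
        children = ss.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale preset: 962 respondents, 1,047 plots, 4 x (4+1)."""
    return SimulationConfig(rng_seed=seed, **overrides)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Quick preset for tests and pipeline smoke runs."""
    overrides.setdefault("n_respondents", 40)
    overrides.setdefault("n_plots", 44)
    return SimulationConfig(rng_seed=seed, **overrides)


def eaa_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset with an attendance-mixture truth mirroring the reported
    high-ANA pattern (sustainability mostly ignored)."""
    overrides.setdefault("n_respondents", 500)
    overrides.setdefault("n_plots", 520)
    spec = AttendanceSpec(
        pi_ignore={
            "status_quo": 0.69,
            "restoration": 0.07,
            "benefits": 0.13,
            "conservation": 0.86,
            "maintenance": 0.52,
        }
    )
    overrides.setdefault("attendance_spec", spec)
    scheme = default_scheme().with_interactions(())
    overrides.setdefault("scheme", scheme)
    return SimulationConfig(rng_seed=seed, **overrides)


def _draw_covariate(rng, spec, n):
    dist = spec["dist"]
    if dist == "bernoulli":
        return rng.binomial(1, spec["p"], size=n).astype(float)
    if dist == "poisson":
        return rng.poisson(spec["lam"], size=n).astype(float)
    if dist == "lognormal":
        sigma = float(spec["sigma"])
        mu = np.log(float(spec["mean"])) - sigma**2 / 2.0
        return rng.lognormal(mu, sigma, size=n)
    if dist == "exponential":
        return rng.exponential(float(spec["mean"]), size=n)
    if dist == "normal":
        return rng.normal(float(spec["mean"]), float(spec["sd"]), size=n)
    raise ValueError(f"unknown covariate distribution {dist!r}")


def _draw_soil(rng, hub, cfg: SimulationConfig) -> SoilProfile:
    severe = set(cfg.severe_parameters.get(hub, ()))
    values = {}
    for param in SOIL_PARAMETERS:
        if param in severe:
            # mass on degrees IV-V with the configured probability
            if rng.random() < cfg.severe_prob:
                deg = 3 + rng.integers(2)
            else:
                deg = rng.integers(3)
        else:
            deg = rng.choice(5, p=(0.15, 0.25, 0.3, 0.2, 0.1))
        lo, hi = _DEGREE_RANGES[param][deg]
        values[param] = float(rng.uniform(lo, hi))
    return SoilProfile(**values)


def simulate_population(cfg: SimulationConfig) -> pd.DataFrame:
    """One row per plot: respondent/plot keys, covariates, soil grades.

    Extra plots (beyond one per respondent) go to a seeded random subset
    of respondents; plot covariates are the respondent's, soil varies by
    plot.
    """
    streams = cfg.streams()
    rng = streams["population"]
    soil_rng = streams["soil"]
    n = cfg.n_respondents

    resp = pd.DataFrame({"respondent_id": np.arange(n)})
    for name, spec in cfg.covariate_distributions.items():
        resp[name] = _draw_covariate(rng, spec, n)
    resp["hub"] = rng.choice(HUBS, size=n)

    extra = cfg.n_plots - n
    extra_ids = rng.choice(n, size=extra, replace=False)
    plot_resp = np.concatenate([np.arange(n), np.sort(extra_ids)])
    plot_resp.sort(kind="stable")
    rows = resp.set_index("respondent_id").loc[plot_resp].reset_index()
    rows["plot_id"] = rows.groupby("respondent_id").cumcount()

    soil_cols = {p: np.empty(len(rows)) for p in SOIL_PARAMETERS}
    fert = np.empty(len(rows), dtype=int)
    worst = []
    for i, hub in enumerate(rows["hub"]):
        sp = _draw_soil(soil_rng, hub, cfg)
        lp = classify_plot(sp, cfg.thresholds)
        for p in SOIL_PARAMETERS:
            soil_cols[p][i] = getattr(sp, p)
        fert[i] = fertility_level(lp.worst_degree)
        worst.append(lp.worst_degree)
    for p in SOIL_PARAMETERS:
        rows[p] = soil_cols[p]
    rows["fertility_level"] = fert
    rows["worst_degree"] = worst
    for hub in HUBS[1:]:
        rows[f"hub_{hub}"] = (rows["hub"] == hub).astype(float)
    return rows


def _design_for(cfg: SimulationConfig, design: ChoiceDesign | None) -> ChoiceDesign:
    if design is not None:
        return design
    rng = cfg.streams()["design"]
    return generate_design(
        cfg.scheme,
        n_sets=cfg.n_situations,
        n_alts=cfg.n_designed_alts,
        seed=int(rng.integers(2**31)),
    )


def _stack_rows(cfg, population, design, chosen_matrix):
    """Assemble the long-format frame from per-(plot, situation) choices."""
    scheme = cfg.scheme
    alts = design.alternatives(scheme)
    n_plots = len(population)
    n_sit = len(alts)
    n_alt = len(alts[0])
    rows_per_plot = n_sit * n_alt

    attr_block = np.empty((rows_per_plot, len(scheme.names)))
    sq_block = np.empty(rows_per_plot)
    sit_block = np.repeat(np.arange(n_sit), n_alt)
    alt_block = np.tile(np.arange(n_alt), n_sit)
    for t, profiles in enumerate(alts):
        for j, prof in enumerate(profiles):
            r = t * n_alt + j
            attr_block[r] = [prof.levels[name] for name in scheme.names]
            sq_block[r] = float(prof.is_status_quo)

    df = pd.DataFrame(
        np.tile(attr_block, (n_plots, 1)), columns=list(scheme.names)
    )
    df["status_quo"] = np.tile(sq_block, n_plots)
    df["situation_id"] = np.tile(sit_block, n_plots)
    df["alternative_id"] = np.tile(alt_block, n_plots)
    df["respondent_id"] = np.repeat(
        population["respondent_id"].to_numpy(), rows_per_plot
    )
    df["plot_id"] = np.repeat(population["plot_id"].to_numpy(), rows_per_plot)

    chosen = np.zeros(len(df), dtype=int)
    base = np.arange(n_plots * n_sit) * n_alt
    chosen[base + chosen_matrix.ravel()] = 1
    df["chosen"] = chosen

    cov_cols = [
        c
        for c in population.columns
        if c not in ("respondent_id", "plot_id", "hub", "worst_degree")
    ]
    for c in cov_cols:
        df[c] = np.repeat(population[c].to_numpy(), rows_per_plot)
    for a in scheme.binary_attributes:
        df[a.name] = df[a.name].astype(int)
    return df, cov_cols


def _alt_design_matrix(cfg, design):
    """(n_sit * n_alt, p) design matrix of one plot's alternatives."""
    scheme = cfg.scheme
    alts = design.alternatives(scheme)
    from .data import profiles_to_frame  # local import to avoid cycle

    flat = [p for s in alts for p in s]
    frame = profiles_to_frame(flat, scheme)
    frame["chosen"] = 0
    # minimal frame for build_design_matrix via a lightweight shim
    class _Shim:
        def __init__(self, df, scheme):
            self.df = df
            self.scheme = scheme

    dm = build_design_matrix(_Shim(frame, scheme), scheme)
    return dm.values, len(alts), len(alts[0])


def simulate_choices_lcl(
    cfg: SimulationConfig, design: ChoiceDesign | None = None
) -> ChoiceDataset:
    """Latent-class DGP: draw a class per plot, then logit choices."""
    spec = cfg.resolved_class_spec()
    population = simulate_population(cfg)
    design = _design_for(cfg, design)
    streams = cfg.streams()
    class_rng, choice_rng = streams["class"], streams["choice"]

    X, n_sit, n_alt = _alt_design_matrix(cfg, design)
    n_plots = len(population)

    q_cols = list(spec.membership_covariates)
    Z = np.column_stack(
        [np.ones(n_plots)] + [population[c].to_numpy(dtype=float) for c in q_cols]
    )
    lam = spec.membership_lam()
    eta = np.column_stack([Z @ lam.T, np.zeros(n_plots)])
    eta -= eta.max(axis=1, keepdims=True)
    pi = np.exp(eta)
    pi /= pi.sum(axis=1, keepdims=True)
    classes = np.array(
        [class_rng.choice(spec.S, p=pi[i]) for i in range(n_plots)]
    )

    # per-class choice probabilities for the shared alternative block
    chosen = np.empty((n_plots, n_sit), dtype=int)
    U = X @ spec.beta.T  # (rows_per_plot, S)
    for s in range(spec.S):
        us = U[:, s].reshape(n_sit, n_alt)
        us = us - us.max(axis=1, keepdims=True)
        ps = np.exp(us)
        ps /= ps.sum(axis=1, keepdims=True)
        idx = np.flatnonzero(classes == s)
        if len(idx) == 0:
            continue
        draws = choice_rng.random((len(idx), n_sit))
        cum = ps.cumsum(axis=1)
        chosen[idx] = (draws[:, :, None] > cum[None, :, :]).sum(axis=2)

    df, cov_cols = _stack_rows(cfg, population, design, chosen)
    df["true_class"] = np.repeat(classes, n_sit * n_alt)
    return ChoiceDataset.from_frame(
        df, cfg.scheme, covariates=tuple(cov_cols) + ("true_class",)
    )


def simulate_choices_eaa(
    cfg: SimulationConfig, design: ChoiceDesign | None = None
) -> ChoiceDataset:
    """Attendance DGP: draw a per-plot attendance subset, then choices."""
    if cfg.attendance_spec is None:
        raise ValueError("attendance_spec is required for the EAA generator")
    spec = cfg.attendance_spec
    if cfg.class_spec is not None and cfg.class_spec.S == 1:
        beta = cfg.class_spec.beta[0]
    else:
        beta = DEFAULT_EAA_BETA
    population = simulate_population(cfg)
    design = _design_for(cfg, design)
    streams = cfg.streams()
    att_rng, choice_rng = streams["attendance"], streams["choice"]

    scheme = cfg.scheme
    columns = scheme.design_columns
    beta = np.asarray(beta, dtype=float)
    if len(beta) < len(columns):  # pad interaction columns with zeros
        beta = np.concatenate([beta, np.zeros(len(columns) - len(beta))])
    beta = beta[: len(columns)]
    X, n_sit, n_alt = _alt_design_matrix(cfg, design)
    n_plots = len(population)

    col_idx = {c: i for i, c in enumerate(columns)}
    components = [((c,), p) for c, p in spec.pi_ignore.items()] + [
        (tuple(cols), p) for cols, p in spec.blocks
    ]
    masks = np.ones((n_plots, len(columns)), dtype=bool)
    for cols, p_ignore in components:
        ignored = att_rng.random(n_plots) < p_ignore
        for c in cols:
            masks[ignored, col_idx[c]] = False

    chosen = np.empty((n_plots, n_sit), dtype=int)
    for i in range(n_plots):
        u = (X * (beta * masks[i])).sum(axis=1).reshape(n_sit, n_alt)
        u = u - u.max(axis=1, keepdims=True)
        ps = np.exp(u)
        ps /= ps.sum(axis=1, keepdims=True)
        draws = choice_rng.random(n_sit)
        chosen[i] = (draws[:, None] > ps.cumsum(axis=1)).sum(axis=1)

    df, cov_cols = _stack_rows(cfg, population, design, chosen)
    return ChoiceDataset.from_frame(df, scheme, covariates=tuple(cov_cols))
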