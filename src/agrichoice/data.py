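"""Domain types and I/O for long-format stated-choice data.

A choice dataset is stored long: one row per respondent x plot x choice
situation x alternative.  Binary attribute levels are coded 0/1, the
monetary attribute carries its raw currency value, and a ``status_quo``
indicator marks the opt-out alternative in every situation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Attribute",
    "AttributeScheme",
    "Profile",
    "ChoiceDataset",
    "DesignMatrix",
    "SchemaError",
    "ValidationError",
    "CodingError",
    "default_scheme",
    "read_choice_data",
    "write_choice_data",
    "build_design_matrix",
    "plan_sample_size",
    "KEY_COLUMNS",
    "SITUATION_KEY",
]

KEY_COLUMNS = ("respondent_id", "plot_id", "situation_id", "alternative_id")
SITUATION_KEY = ("respondent_id", "plot_id", "situation_id")
STATUS_QUO_COLUMN = "status_quo"
CHOSEN_COLUMN = "chosen"


class SchemaError(ValueError):
    """A required column or config key is missing or malformed."""


class ValidationError(ValueError):
    """Data violate a structural invariant (e.g. chosen counts)."""


class CodingError(ValueError):
    """An attribute level cannot be mapped to its numeric code."""


@dataclass(frozen=True)
class Attribute:
    """One choice attribute: a name, a kind, and its ordered levels.

    Binary attributes list two level labels in code order (label for
    code 0 first); the monetary attribute lists its currency levels.
    """

    name: str
    kind: str  # "binary" | "monetary"
    levels: tuple

    def __post_init__(self):
        if self.kind not in ("binary", "monetary"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(
                f"binary attribute {self.name!r} must have exactly 2 levels, "
                f"got {len(self.levels)}"
            )
        if self.kind == "monetary" and len(self.levels) < 2:
            raise SchemaError(f"monetary attribute {self.name!r} needs >= 2 levels")

    @property
    def codes(self) -> tuple:
        """Numeric codes in level order (0/1 for binary, raw for monetary)."""
        if self.kind == "binary":
            return (0, 1)
        return tuple(float(v) for v in self.levels)


@dataclass(frozen=True)
class AttributeScheme:
    """The attribute design of the experiment.

    Exactly one attribute is monetary ("cost").  ``cost_scale`` divides
    raw cost before it enters any design matrix; estimated cost
    coefficients are therefore per ``cost_scale`` currency units.
    ``interactions`` lists (binary attribute, cost attribute) pairs that
    enter as dummy x scaled-cost product columns.
    """

    attributes: tuple[Attribute, ...]
    cost_scale: float = 10_000.0
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names")
        monetary = [a for a in self.attributes if a.kind == "monetary"]
        if len(monetary) != 1:
            raise SchemaError(
                f"scheme must have exactly one monetary attribute, got {len(monetary)}"
            )
        if not self.cost_scale > 0:
            raise SchemaError("cost_scale must be > 0")
        for left, right in self.interactions:
            if right != monetary[0].name:
                raise SchemaError(
                    f"interaction ({left}, {right}): second member must be the "
                    f"monetary attribute {monetary[0].name!r}"
                )
            if left not in names or self[left].kind != "binary":
                raise SchemaError(f"interaction refers to unknown/non-binary {left!r}")

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def cost_attribute(self) -> Attribute:
        return next(a for a in self.attributes if a.kind == "monetary")

    @property
    def binary_attributes(self) -> tuple[Attribute, ...]:
        return tuple(a for a in self.attributes if a.kind == "binary")

    @property
    def cost_levels(self) -> tuple[float, ...]:
        return self.cost_attribute.codes

    @property
    def design_columns(self) -> tuple[str, ...]:
        """Deterministic design-matrix column order."""
        cols = [STATUS_QUO_COLUMN, self.cost_attribute.name]
        cols += [a.name for a in self.binary_attributes]
        cols += [f"{left}_x_{right}" for left, right in self.interactions]
        return tuple(cols)

    def n_profiles(self) -> int:
        return math.prod(len(a.codes) for a in self.attributes)

    def with_interactions(self, interactions) -> "AttributeScheme":
        return replace(self, interactions=tuple(tuple(p) for p in interactions))

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a.name, "kind": a.kind, "levels": list(a.levels)}
                for a in self.attributes
            ],
            "cost_scale": self.cost_scale,
            "interactions": [list(p) for p in self.interactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeScheme":
        try:
            attrs = tuple(
                Attribute(a["name"], a["kind"], tuple(a["levels"]))
                for a in d["attributes"]
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise SchemaError(f"scheme config missing key {exc}") from exc
        return cls(
            attributes=attrs,
            cost_scale=float(d.get("cost_scale", 10_000.0)),
            interactions=tuple(tuple(p) for p in d.get("interactions", ())),
        )


def default_scheme() -> AttributeScheme:
    """The default attribute scheme: five binary attributes plus cost.

    Cost levels are CFAF/ha; interactions are maintenance x cost and
    accessibility x cost.
    """
    return AttributeScheme(
        attributes=(
            Attribute("restoration", "binary", ("slow", "quick")),
            Attribute("accessibility", "binary", ("difficult", "easy")),
            Attribute("benefits", "binary", ("impossible", "possible")),
            Attribute("conservation", "binary", ("temporary", "long")),
            Attribute("maintenance", "binary", ("less", "regular")),
            Attribute("cost", "monetary", (0.0, 70_000.0, 100_000.0, 150_000.0, 220_000.0)),
        ),
        cost_scale=10_000.0,
        interactions=(("maintenance", "cost"), ("accessibility", "cost")),
    )


@dataclass(frozen=True)
class Profile:
    """A technology profile: one coded level per attribute."""

    levels: dict
    is_status_quo: bool = False

    def __post_init__(self):
        object.__setattr__(self, "levels", dict(self.levels))

    def __hash__(self):
        return hash((tuple(sorted(self.levels.items())), self.is_status_quo))

    def __eq__(self, other):
        if not isinstance(other, Profile):
            return NotImplemented
        return (
            self.levels == other.levels and self.is_status_quo == other.is_status_quo
        )

    def validate(self, scheme: AttributeScheme) -> None:
        missing = set(scheme.names) - set(self.levels)
        if missing:
            raise CodingError(f"profile missing levels for {sorted(missing)}")
        for a in scheme.attributes:
            v = self.levels[a.name]
            if a.kind == "binary" and v not in (0, 1):
                raise CodingError(
                    f"attribute {a.name!r}: level {v!r} is not a 0/1 code"
                )

    @classmethod
    def status_quo(cls, scheme: AttributeScheme, levels: dict | None = None) -> "Profile":
        base = {name: 0 for name in scheme.names}
        base[scheme.cost_attribute.name] = 0.0
        if levels:
            base.update(levels)
        return cls(levels=base, is_status_quo=True)


@dataclass
class ChoiceDataset:
    """Validated long-format choice data.

    ``df`` holds key columns, the ``status_quo`` flag, coded attribute
    columns, the ``chosen`` indicator, and any covariate columns (which
    must be constant within a plot).
    """

    df: pd.DataFrame
    scheme: AttributeScheme
    covariates: tuple[str, ...] = ()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        scheme: AttributeScheme,
        covariates: tuple[str, ...] | None = None,
    ) -> "ChoiceDataset":
        required = list(KEY_COLUMNS) + [STATUS_QUO_COLUMN, CHOSEN_COLUMN] + list(
            scheme.names
        )
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if covariates is None:
            covariates = tuple(c for c in df.columns if c not in required)
        else:
            missing = [c for c in covariates if c not in df.columns]
            if missing:
                raise SchemaError(f"missing covariate columns: {missing}")
        df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
        ds = cls(df=df, scheme=scheme, covariates=tuple(covariates))
        ds.validate()
        return ds

    def validate(self) -> None:
        df = self.df
        for a in self.scheme.binary_attributes:
            bad = ~df[a.name].isin([0, 1])
            if bad.any():
                raise CodingError(
                    f"attribute {a.name!r}: non-binary codes in rows "
                    f"{df.index[bad][:5].tolist()}"
                )
        sub = df[list(KEY_COLUMNS) + [CHOSEN_COLUMN] + list(self.covariates)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValidationError(f"missing values in columns {bad}; no imputation")
        grp = df.groupby(list(SITUATION_KEY), sort=False)
        chosen_counts = grp[CHOSEN_COLUMN].sum()
        bad = chosen_counts[chosen_counts != 1]
        if len(bad):
            raise ValidationError(
                f"situations without exactly one chosen row: {bad.index[:5].tolist()}"
            )
        sizes = grp.size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValidationError(
                f"situations with < 2 alternatives: {small.index[:5].tolist()}"
            )
        if self.covariates:
            nun = df.groupby(["respondent_id", "plot_id"], sort=False)[
                list(self.covariates)
            ].nunique()
            varying = nun.columns[(nun > 1).any()].tolist()
            if varying:
                raise ValidationError(
                    f"covariates vary within a plot: {varying}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_plots(self) -> int:
        return len(self.df.groupby(["respondent_id", "plot_id"]).size())

    @property
    def n_situations(self) -> int:
        return len(self.df.groupby(list(SITUATION_KEY)).size())

    def counts(self) -> dict:
        return {
            "rows": self.n_rows,
            "respondents": self.n_respondents,
            "plots": self.n_plots,
            "situations": self.n_situations,
        }


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric regressor matrix aligned to a ChoiceDataset's rows."""

    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column name/shape mismatch")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def read_choice_data(
    path,
    scheme: AttributeScheme,
    covariates: tuple[str, ...] | None = None,
) -> ChoiceDataset:
    """Read a UTF-8 CSV with header into a validated ChoiceDataset."""
    df = pd.read_csv(path)
    return ChoiceDataset.from_frame(df, scheme, covariates=covariates)


def write_choice_data(ds: ChoiceDataset, path) -> None:
    ds.df.to_csv(path, index=False)


def build_design_matrix(ds: ChoiceDataset, scheme: AttributeScheme | None = None) -> DesignMatrix:
    """Assemble the alternative-specific regressor matrix.

    Column order: status-quo constant, scaled cost, binary dummies in
    scheme order, then interaction products (dummy x scaled cost).
    """
    scheme = scheme or ds.scheme
    df = ds.df
    cost_name = scheme.cost_attribute.name
    cols: list[np.ndarray] = []
    cols.append(df[STATUS_QUO_COLUMN].to_numpy(dtype=float))
    cost = df[cost_name].to_numpy(dtype=float) / scheme.cost_scale
    cols.append(cost)
    for a in scheme.binary_attributes:
        v = df[a.name].to_numpy(dtype=float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise CodingError(f"attribute {a.name!r}: unknown level code")
        cols.append(v)
    for left, _right in scheme.interactions:
        dummy = df[left].to_numpy(dtype=float)
        cols.append(dummy * cost)
    values = np.column_stack(cols)
    return DesignMatrix(values=values, columns=scheme.design_columns)


def plan_sample_size(t_crit: float, cv: float, d: float) -> int:
    """Plot-count planning: ceil(t^2 * Cv^2 / d^2).

    ``cv`` and ``d`` are fractions (0.5126 for 51.26%).
    """
    for name, v in (("t_crit", t_crit), ("cv", cv), ("d", d)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite number")
    return int(math.ceil(t_crit**2 * cv**2 / d**2))


def profiles_to_frame(profiles, scheme: AttributeScheme) -> pd.DataFrame:
    """Tabulate profiles, one row each, attribute columns in scheme order."""
    rows = []
    for p in profiles:
        row = {name: p.levels[name] for name in scheme.names}
        row[STATUS_QUO_COLUMN] = int(p.is_status_quo)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(scheme.names) + [STATUS_QUO_COLUMN])


def enumerate_full_factorial(scheme: AttributeScheme) -> list[Profile]:
    """All distinct level combinations in lexicographic (scheme) order."""
    level_sets = [a.codes for a in scheme.attributes]
    out = []
    for combo in itertools.product(*level_sets):
        out.append(Profile(levels=dict(zip(scheme.names, combo))))
    return out
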