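"""Willingness-to-adopt (WTA) ratios, currency conversion, reporting.

WTA for an attribute is -beta / delta where delta is the cost
coefficient (marginal utility of money on the scaled-cost axis).  Values
are back-transformed to CFAF via the scheme's cost scale and optionally
to USD at a fixed exchange rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data import AttributeScheme

__all__ = [
    "DEFAULT_RATE_CFAF_PER_USD",
    "WTAReport",
    "wta",
    "convert_currency",
    "wta_table",
]

DEFAULT_RATE_CFAF_PER_USD = 606.73
NEAR_ZERO_COST = 1e-8


def wta(beta_attr: float, delta_cost: float) -> float:
    """Marginal rate of substitution -beta/delta, in scaled cost units."""
    if delta_cost == 0:
        raise ZeroDivisionError("cost coefficient is zero; WTA undefined")
    if abs(delta_cost) < NEAR_ZERO_COST:
        warnings.warn(
            f"cost coefficient {delta_cost:.3g} is near zero; WTA is unstable"
        )
    return -beta_attr / delta_cost


def convert_currency(amount_cfaf: float, rate_cfaf_per_usd: float = DEFAULT_RATE_CFAF_PER_USD) -> float:
    """CFAF -> USD at a fixed rate, rounded half-up to 2 decimals."""
    if not rate_cfaf_per_usd > 0:
        raise ValueError("exchange rate must be > 0")
    usd = Decimal(repr(float(amount_cfaf))) / Decimal(repr(float(rate_cfaf_per_usd)))
    return float(usd.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class WTAReport:
    table: pd.DataFrame  # class, attribute, wta_cost_units, wta_cfaf, wta_usd, se_cfaf, rank
    rate_cfaf_per_usd: float
    cost_scale: float
    has_se: bool

    def for_class(self, label) -> pd.DataFrame:
        return self.table[self.table["class"] == label].reset_index(drop=True)


def _class_blocks(fit, scheme: AttributeScheme):
    """Yield (label, coef vector, cov block or None) per class of a fit."""
    cov = getattr(fit, "cov", None)
    params = fit.params
    beta = getattr(params, "beta", None)
    if beta is not None and np.ndim(beta) == 2:  # latent-class fit
        S, p = beta.shape
        for s in range(S):
            block = None
            if cov is not None and cov.shape[0] >= S * p:
                sl = slice(s * p, (s + 1) * p)
                block = cov[sl, sl]
            yield f"class_{s + 1}", beta[s], block
    else:  # MNL or EAA fit: single coefficient vector
        coefs = beta if beta is not None else fit.params
        coefs = np.asarray(coefs, dtype=float)
        p = len(coefs)
        block = cov[:p, :p] if cov is not None else None
        yield "all", coefs, block


def wta_table(
    fit,
    scheme: AttributeScheme,
    rate_cfaf_per_usd: float = DEFAULT_RATE_CFAF_PER_USD,
) -> WTAReport:
    """WTA per non-cost attribute per class, ranked by |WTA| within class.

    Standard errors come from the delta method on the (attribute, cost)
    coefficient covariance block when the fit carries a covariance;
    otherwise they are omitted with ``has_se=False``.
    """
    columns = tuple(getattr(fit, "columns", ()) or fit.params.columns)
    cost_name = scheme.cost_attribute.name
    if cost_name not in columns:
        raise KeyError(f"fit has no cost coefficient column {cost_name!r}")
    cost_idx = columns.index(cost_name)
    attr_names = [a.name for a in scheme.binary_attributes]
    rows = []
    has_se = True
    for label, coefs, cov in _class_blocks(fit, scheme):
        delta = coefs[cost_idx]
        for name in attr_names:
            j = columns.index(name)
            w_units = wta(coefs[j], delta)
            w_cfaf = w_units * scheme.cost_scale
            se_cfaf = np.nan
            if cov is not None:
                g = np.zeros(len(coefs))
                g[j] = -1.0 / delta
                g[cost_idx] = coefs[j] / delta**2
                var = float(g @ cov @ g)
                se_cfaf = np.sqrt(max(var, 0.0)) * scheme.cost_scale
            else:
                has_se = False
            rows.append(
                {
                    "class": label,
                    "attribute": name,
                    "wta_cost_units": w_units,
                    "wta_cfaf": w_cfaf,
                    "wta_usd": convert_currency(w_cfaf, rate_cfaf_per_usd),
                    "se_cfaf": se_cfaf,
                }
            )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table.groupby("class")["wta_cfaf"]
        .transform(lambda s: s.abs().rank(ascending=False, method="first"))
        .astype(int)
    )
    table = table.sort_values(["class", "rank"]).reset_index(drop=True)
    if not has_se:
        warnings.warn("fit carries no covariance; WTA standard errors omitted")
    return WTAReport(
        table=table,
        rate_cfaf_per_usd=rate_cfaf_per_usd,
        cost_scale=scheme.cost_scale,
        has_se=has_se,
    )
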