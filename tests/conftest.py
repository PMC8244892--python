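import numpy as np
import pandas as pd
import pytest

from agrichoice.data import (
    Attribute,
    AttributeScheme,
    ChoiceDataset,
    default_scheme,
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def tiny_scheme():
    """Two binary attributes plus a two-level cost, no interactions."""
    return AttributeScheme(
        attributes=(
            Attribute("a", "binary", ("no", "yes")),
            Attribute("b", "binary", ("no", "yes")),
            Attribute("cost", "monetary", (0.0, 1.0)),
        ),
        cost_scale=1.0,
    )


@pytest.fixture(scope="session")
def mini_scheme():
    """One binary attribute plus cost: 3-column design matrix."""
    return AttributeScheme(
        attributes=(
            Attribute("a", "binary", ("no", "yes")),
            Attribute("cost", "monetary", (0.0, 1.0, 2.0)),
        ),
        cost_scale=1.0,
    )


def make_choice_frame(scheme, situations, covariates=None):
    """Build a long-format frame from a list of situations.

    Each situation is (respondent_id, plot_id, situation_id,
    [(levels dict, status_quo, chosen), ...]).
    """
    rows = []
    for rid, pid, sid, alts in situations:
        for aid, (levels, sq, chosen) in enumerate(alts):
            row = {
                "respondent_id": rid,
                "plot_id": pid,
                "situation_id": sid,
                "alternative_id": aid,
                "status_quo": sq,
                "chosen": chosen,
            }
            row.update(levels)
            if covariates:
                row.update(covariates.get((rid, pid), {}))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_dataset(scheme):
    """1 plot x 4 situations x 5 alternatives = 20 rows."""
    rng = np.random.default_rng(0)
    situations = []
    for sid in range(4):
        alts = []
        for j in range(4):
            levels = {a.name: int(rng.integers(2)) for a in scheme.binary_attributes}
            levels["cost"] = float(rng.choice(scheme.cost_levels))
            alts.append((levels, 0, 1 if j == 0 else 0))
        sq_levels = {a.name: 0 for a in scheme.binary_attributes}
        sq_levels["cost"] = 0.0
        alts.append((sq_levels, 1, 0))
        situations.append((0, 0, sid, alts))
    df = make_choice_frame(scheme, situations)
    return ChoiceDataset.from_frame(df, scheme)
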