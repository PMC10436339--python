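"""Shared fixtures: published reference statistics and cohort builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ohp.io import item_column, validate_cohort
from ohp.profiling import CohortThresholds
from ohp.scoring import N_ITEMS

# Published whole-cohort summary statistics of the reference study (n=100).
PUBLISHED_STATS = dict(
    ts_mean=76.09, ts_sd=14.59,
    tp_mean=38.02, tp_sd=9.77,
    tm_mean=-37.99, tm_sd=11.94,
)

# Published banding cutoffs derived from the stats above.
PUBLISHED_CUTOFFS = dict(
    ts_hi=90.68, ts_lo=61.50,
    tp_hi=47.79, tp_lo=28.25,
    tm_hi=-49.93, tm_lo=-26.05,
)

# The five published worked-example participants: (T+, T-) -> profile.
WORKED_EXAMPLES = [
    (51.0, -50.0, "liberal"),
    (23.0, -18.0, "conservative"),
    (31.5, -36.0, "neutral"),
    (60.0, -22.0, "positive_alliesthesia"),
    (23.0, -64.0, "negative_alliesthesia"),
]


@pytest.fixture
def published_thresholds() -> CohortThresholds:
    return CohortThresholds(**PUBLISHED_STATS)


def items_for_totals(t_plus: float, t_minus: float) -> list[float]:
    """A 14-item half-step score vector with the given positive/negative totals.

    Fills greedily with +/-9 entries plus one remainder item per valence;
    valid whenever each total is attainable with at most 7 items per
    valence (all published examples are).
    """
    def fill(total: float) -> list[float]:
        sign = 1.0 if total >= 0 else -1.0
        mag = abs(total)
        out = [sign * 9.0] * int(mag // 9)
        rem = round(mag - 9 * len(out), 1)
        if rem:
            out.append(sign * rem)
        return out

    scores = fill(t_plus) + fill(t_minus)
    assert len(scores) <= N_ITEMS, "totals not representable in 14 items"
    scores += [0.0] * (N_ITEMS - len(scores))
    return scores


def cohort_frame(score_rows: list[list[float]], *, sexes: list[str] | None = None,
                 self_smell: list[float] | None = None) -> pd.DataFrame:
    """Build a validated wide cohort table from raw item-score rows."""
    n = len(score_rows)
    df = pd.DataFrame({
        "id": [f"p{i + 1:03d}" for i in range(n)],
        "sex": sexes if sexes is not None else ["U"] * n,
        "age": [np.nan] * n,
        "self_smell": self_smell if self_smell is not None else [np.nan] * n,
    })
    for j in range(N_ITEMS):
        df[item_column(j + 1)] = [row[j] for row in score_rows]
    return validate_cohort(df)


@pytest.fixture
def worked_example_cohort() -> pd.DataFrame:
    """The five published participants as full item vectors."""
    return cohort_frame([items_for_totals(tp, tm) for tp, tm, _ in WORKED_EXAMPLES])


def random_halfstep_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """n x 14 matrix of uniform random scores on the legal half-step grid."""
    return rng.integers(-18, 19, size=(n, N_ITEMS)) / 2.0
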