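"""Cohort-normed banding and six-way hedonic profile classification.

Each of the three totals (TS, T+, T-) is banded against the reference
cohort's mean +/- SD into *high*, *medium* and *low*.  "High" and "low"
are strict inequalities, so boundary values fall in the closed *medium*
interval.  For T- (which is <= 0) "high" means *more negative*: a
respondent with a strongly negative T- rated the unpleasant items
strongly.

Profiles over the (TS, T+, T-) band triple:

========================  =========================
liberal                   (high,   high, high)
conservative              (low,    low,  low)
neutral                   (medium, medium, medium)
positive_alliesthesia     (medium, high, low)
negative_alliesthesia     (medium, low,  high)
other                     any of the remaining 22 triples
========================  =========================

The liberal/conservative labels echo the response-criterion vocabulary of
Signal Detection Theory; the alliesthesia profiles describe a hedonic
shift toward (positive) or away from (negative) pleasantness on both
valences at once.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .scoring import HedonicScores

__all__ = [
    "PROFILE_LABELS",
    "NAMED_BAND_TRIPLES",
    "CohortThresholds",
    "derive_thresholds",
    "band",
    "classify",
    "classify_cohort",
    "profile_census",
]

PROFILE_LABELS = (
    "liberal",
    "conservative",
    "neutral",
    "positive_alliesthesia",
    "negative_alliesthesia",
    "other",
)

# (ts_band, tp_band, tm_band) -> label; every other triple is "other".
NAMED_BAND_TRIPLES = {
    ("high", "high", "high"): "liberal",
    ("low", "low", "low"): "conservative",
    ("medium", "medium", "medium"): "neutral",
    ("medium", "high", "low"): "positive_alliesthesia",
    ("medium", "low", "high"): "negative_alliesthesia",
}


@dataclass(frozen=True)
class CohortThresholds:
    """Mean +/- SD cutoffs for TS, T+ and T- from a reference cohort.

    For TS and T+ larger is "high": ``hi = mean + sd``, ``lo = mean - sd``.
    For T- more negative is "high": ``tm_hi = mean - sd`` (the more
    negative cutoff) and ``tm_lo = mean + sd``.
    """

    ts_mean: float
    ts_sd: float
    tp_mean: float
    tp_sd: float
    tm_mean: float
    tm_sd: float

    @property
    def ts_hi(self) -> float:
        return self.ts_mean + self.ts_sd

    @property
    def ts_lo(self) -> float:
        return self.ts_mean - self.ts_sd

    @property
    def tp_hi(self) -> float:
        return self.tp_mean + self.tp_sd

    @property
    def tp_lo(self) -> float:
        return self.tp_mean - self.tp_sd

    @property
    def tm_hi(self) -> float:
        """The more-negative T- cutoff (beyond it T- is 'high')."""
        return self.tm_mean - self.tm_sd

    @property
    def tm_lo(self) -> float:
        return self.tm_mean + self.tm_sd

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(ts_hi=self.ts_hi, ts_lo=self.ts_lo, tp_hi=self.tp_hi,
                 tp_lo=self.tp_lo, tm_hi=self.tm_hi, tm_lo=self.tm_lo)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortThresholds":
        return cls(ts_mean=d["ts_mean"], ts_sd=d["ts_sd"],
                   tp_mean=d["tp_mean"], tp_sd=d["tp_sd"],
                   tm_mean=d["tm_mean"], tm_sd=d["tm_sd"])


def derive_thresholds(
    cohort_scores: Union[pd.DataFrame, Iterable[HedonicScores]],
    *,
    ddof: int = 1,
) -> CohortThresholds:
    """Compute mean +/- SD banding cutoffs from a cohort's hedonic scores.

    ``cohort_scores`` is either a DataFrame with ``ts, t_plus, t_minus``
    columns (see :func:`ohp.io.attach_scores`) or an iterable of
    :class:`HedonicScores`.  The sample SD (``ddof=1``) is the default;
    ``ddof=0`` switches to the population convention.
    """
    if isinstance(cohort_scores, pd.DataFrame):
        ts = cohort_scores["ts"].to_numpy(dtype=float)
        tp = cohort_scores["t_plus"].to_numpy(dtype=float)
        tm = cohort_scores["t_minus"].to_numpy(dtype=float)
    else:
        triples = [(s.ts, s.t_plus, s.t_minus) for s in cohort_scores]
        if not triples:
            raise ValueError("empty cohort")
        ts, tp, tm = (np.asarray(col, dtype=float) for col in zip(*triples))
    if ts.size < 2:
        raise ValueError("need at least 2 respondents for an SD")
    return CohortThresholds(
        ts_mean=float(ts.mean()), ts_sd=float(ts.std(ddof=ddof)),
        tp_mean=float(tp.mean()), tp_sd=float(tp.std(ddof=ddof)),
        tm_mean=float(tm.mean()), tm_sd=float(tm.std(ddof=ddof)),
    )


def band(value: float, hi: float, lo: float,
         polarity: str = "larger_is_high") -> str:
    """Assign *high* / *medium* / *low* relative to two cutoffs.

    ``polarity="larger_is_high"`` (TS, T+): high iff ``value > hi``, low
    iff ``value < lo``.  ``polarity="more_negative_is_high"`` (T-): the
    same rule on the negated axis, so high iff ``value < hi`` where ``hi``
    is the more negative cutoff.  Boundary values are *medium* — the
    medium band is the closed interval.
    """
    if polarity == "more_negative_is_high":
        value, hi, lo = -value, -hi, -lo
    elif polarity != "larger_is_high":
        raise ValueError(f"unknown polarity {polarity!r}")
    if lo > hi:
        raise ValueError("cutoffs out of order: lo > hi on the banding axis")
    if value > hi:
        return "high"
    if value < lo:
        return "low"
    return "medium"


def band_triple(scores: HedonicScores, thresholds: CohortThresholds) -> tuple[str, str, str]:
    """The (TS, T+, T-) band triple for one respondent."""
    return (
        band(scores.ts, thresholds.ts_hi, thresholds.ts_lo),
        band(scores.t_plus, thresholds.tp_hi, thresholds.tp_lo),
        band(scores.t_minus, thresholds.tm_hi, thresholds.tm_lo,
             polarity="more_negative_is_high"),
    )


def classify(scores: HedonicScores, thresholds: CohortThresholds) -> str:
    """Map one respondent's scores to a profile label."""
    return NAMED_BAND_TRIPLES.get(band_triple(scores, thresholds), "other")


def classify_cohort(scored: pd.DataFrame, thresholds: CohortThresholds) -> pd.DataFrame:
    """Band and classify every respondent in a scored cohort table.

    Expects ``ts, t_plus, t_minus`` columns; returns a copy with
    ``ts_band, tp_band, tm_band, profile`` appended.
    """
    out = scored.copy()
    triples = [
        band_triple(HedonicScores.from_totals(tp, tm), thresholds)
        for tp, tm in zip(out["t_plus"], out["t_minus"])
    ]
    out["ts_band"], out["tp_band"], out["tm_band"] = map(list, zip(*triples)) if triples else ([], [], [])
    out["profile"] = [NAMED_BAND_TRIPLES.get(t, "other") for t in triples]
    return out


def profile_census(
    scored: pd.DataFrame,
    thresholds: CohortThresholds,
    *,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Count respondents per profile, overall or per sex.

    Returns a DataFrame indexed by profile label (all six labels always
    present) with a ``count`` column, plus one column per sex code when
    ``by_sex`` is set.  Counts always partition the cohort: they sum to n.
    """
    if scored.empty:
        raise ValueError("empty cohort")
    labeled = scored if "profile" in scored.columns else classify_cohort(scored, thresholds)
    counts = labeled["profile"].value_counts()
    census = pd.DataFrame(
        {"count": [int(counts.get(lbl, 0)) for lbl in PROFILE_LABELS]},
        index=pd.Index(PROFILE_LABELS, name="profile"),
    )
    if by_sex:
        for sex, grp in labeled.groupby("sex"):
            c = grp["profile"].value_counts()
            census[f"count_{sex}"] = [int(c.get(lbl, 0)) for lbl in PROFILE_LABELS]
    return census
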