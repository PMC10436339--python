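"""Scoring of the 14-item odor hedonic questionnaire.

Each item is rated on a dashed line from -9 ("extremely unpleasant") through
0 ("neutral") to +9 ("extremely pleasant").  Dashes mark whole numbers and
the space between two dashes counts as half a number, so legal scores are
the 37 half-integer values {-9.0, -8.5, ..., +8.5, +9.0}.  Half-integers are
dyadic rationals, hence exactly representable as floats: all the score
identities below hold bit-exactly.

Per-respondent aggregates:

* ``TS``   — total score, the sum of absolute item scores, in [0, 126];
* ``T+``   — sum of the positively rated items (>= 0);
* ``T-``   — sum of the negatively rated items (<= 0);
* ``delta``— hedonic balance ``T+ + T-`` (the signed sum of all items).

By construction ``TS = T+ - T-`` and ``delta = T+ + T-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "N_ITEMS",
    "SCORE_MIN",
    "SCORE_MAX",
    "TS_MAX",
    "ItemResponse",
    "Respondent",
    "HedonicScores",
    "ValidationError",
    "score_from_dash",
    "validate_score",
    "compute_hedonic_scores",
]

N_ITEMS = 14
SCORE_MIN = -9.0
SCORE_MAX = 9.0
TS_MAX = N_ITEMS * SCORE_MAX  # 126

VALENCES = ("positive", "negative", "neutral")
SEXES = ("M", "F", "U")


class ValidationError(ValueError):
    """A response or respondent violates the instrument's constraints."""


def validate_score(score: float, *, item_id: Optional[int] = None) -> float:
    """Check that ``score`` lies on the legal half-step grid in [-9, +9].

    Returns the score as a float.  Raises :class:`ValidationError` naming
    the offending item when ``item_id`` is given.
    """
    where = f" (item {item_id})" if item_id is not None else ""
    s = float(score)
    if not (SCORE_MIN <= s <= SCORE_MAX):
        raise ValidationError(f"score {s} outside [-9, +9]{where}")
    if (2 * s) != int(2 * s):
        raise ValidationError(f"score {s} is not a multiple of 0.5{where}")
    return s


def score_from_dash(valence: str, dash_index: int, half_step: bool = False) -> float:
    """Convert a raw dash-line mark to a signed hedonic score.

    Parameters
    ----------
    valence
        ``"positive"``, ``"negative"`` or ``"neutral"`` — which side of the
        neutral dash the cross was placed on.
    dash_index
        The dash the cross sits on (1..9 away from neutral), or 0 for the
        neutral dash itself.
    half_step
        True when the cross sits in the space *beyond* ``dash_index``,
        adding 0.5 to the magnitude.  There is no space beyond the ninth
        dash, so ``half_step`` is illegal with ``dash_index == 9``.  A
        cross in the space between the neutral dash and the first dash of
        a valence is ``dash_index=0, half_step=True`` and scores +/-0.5
        (a bare cross *on* the neutral dash is the neutral valence); this
        makes valid marks a bijection onto the 37 legal scores.

    A cross on the third negative dash scores -3; between the third and
    fourth negative dash, -3.5; on the neutral dash, 0.
    """
    if valence not in VALENCES:
        raise ValidationError(f"unknown valence {valence!r}")
    dash_index = int(dash_index)
    if valence == "neutral":
        if dash_index != 0 or half_step:
            raise ValidationError(
                "neutral valence requires dash_index=0 and half_step=False"
            )
        return 0.0
    if not (0 <= dash_index <= 9):
        raise ValidationError(
            f"dash_index {dash_index} out of range 0..9 for {valence} valence"
        )
    if dash_index == 0 and not half_step:
        raise ValidationError(
            "a cross on the neutral dash must use valence='neutral'"
        )
    if half_step and dash_index == 9:
        raise ValidationError("no half step beyond the ninth dash")
    magnitude = dash_index + (0.5 if half_step else 0.0)
    return magnitude if valence == "positive" else -magnitude


@dataclass(frozen=True)
class ItemResponse:
    """One item's score for one respondent."""

    item_id: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= int(self.item_id) <= N_ITEMS):
            raise ValidationError(f"item_id {self.item_id} not in 1..{N_ITEMS}")
        object.__setattr__(self, "score", validate_score(self.score, item_id=self.item_id))

    @classmethod
    def from_dash(cls, item_id: int, valence: str, dash_index: int,
                  half_step: bool = False) -> "ItemResponse":
        try:
            score = score_from_dash(valence, dash_index, half_step)
        except ValidationError as exc:
            raise ValidationError(f"item {item_id}: {exc}") from exc
        return cls(item_id=item_id, score=score)


@dataclass(frozen=True)
class HedonicScores:
    """Per-respondent aggregate hedonic scores."""

    ts: float
    t_plus: float
    t_minus: float
    delta: float

    def __post_init__(self) -> None:
        if self.ts != self.t_plus - self.t_minus:
            raise ValidationError("TS must equal T+ - T-")
        if self.delta != self.t_plus + self.t_minus:
            raise ValidationError("delta must equal T+ + T-")
        if not (0.0 <= self.ts <= TS_MAX):
            raise ValidationError(f"TS {self.ts} outside [0, {TS_MAX:g}]")

    @classmethod
    def from_totals(cls, t_plus: float, t_minus: float) -> "HedonicScores":
        """Build from the two signed totals; TS and delta follow by identity."""
        return cls(ts=t_plus - t_minus, t_plus=t_plus, t_minus=t_minus,
                   delta=t_plus + t_minus)


def compute_hedonic_scores(items: Iterable[ItemResponse | float]) -> HedonicScores:
    """Aggregate exactly 14 item responses into :class:`HedonicScores`.

    ``items`` may be :class:`ItemResponse` objects (each item_id 1..14
    exactly once) or a plain length-14 sequence of scores ordered by item.
    Missing or duplicate items are rejected; there is no imputation, since
    the TS range [0, 126] presumes a complete response set.
    """
    items = list(items)
    if items and isinstance(items[0], ItemResponse):
        seen: dict[int, float] = {}
        for it in items:
            if not isinstance(it, ItemResponse):
                raise ValidationError("mixed ItemResponse and scalar inputs")
            if it.item_id in seen:
                raise ValidationError(f"duplicate response for item {it.item_id}")
            seen[it.item_id] = it.score
        missing = sorted(set(range(1, N_ITEMS + 1)) - set(seen))
        if missing:
            raise ValidationError(f"missing responses for items {missing}")
        scores = [seen[i] for i in range(1, N_ITEMS + 1)]
    else:
        if len(items) != N_ITEMS:
            raise ValidationError(f"expected {N_ITEMS} item scores, got {len(items)}")
        scores = [validate_score(s, item_id=i + 1) for i, s in enumerate(items)]

    t_plus = sum(s for s in scores if s > 0)
    t_minus = sum(s for s in scores if s < 0)
    return HedonicScores.from_totals(t_plus=float(t_plus), t_minus=float(t_minus))


@dataclass
class Respondent:
    """One participant: demographics plus a complete 14-item response set."""

    respondent_id: str
    items: Sequence[float] = field(default_factory=tuple)
    sex: str = "U"
    age: Optional[float] = None
    self_smell: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"respondent {self.respondent_id}: sex must be one of {SEXES}"
            )
        if len(self.items) != N_ITEMS:
            raise ValidationError(
                f"respondent {self.respondent_id}: expected {N_ITEMS} items, "
                f"got {len(self.items)}"
            )
        self.items = tuple(
            validate_score(s, item_id=i + 1) for i, s in enumerate(self.items)
        )
        if self.self_smell is not None:
            self.self_smell = validate_score(self.self_smell)

    def hedonic_scores(self) -> HedonicScores:
        return compute_hedonic_scores(self.items)
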