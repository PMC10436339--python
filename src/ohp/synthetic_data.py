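"""Synthetic respondent cohorts with the instrument's statistical structure.

The generator draws each item score from a normal distribution truncated
to [-9, +9] and quantized to the half-step response grid.  Default item
means are the published per-sex means of the 14 items; per-item spreads
follow a linear spread model in which strongly hedonic items (large
|mean|) are answered homogeneously and weakly hedonic items diversely —
the across-item anticorrelation between |mean| and SD that real cohorts
show.  The self-rated sense of smell is generated as a rank-coupled
signal with a configurable Spearman correlation to the total score.

Cohorts can optionally contain *planted* profile classes (liberal,
conservative, neutral, positive/negative alliesthesia) whose item models
are shifted by :func:`plant_profile`, for recovery experiments against
norms from an unplanted reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .io import ITEM_COLUMNS, item_column, validate_cohort
from .scoring import N_ITEMS

__all__ = [
    "MEN_ITEM_MEANS",
    "WOMEN_ITEM_MEANS",
    "ItemModel",
    "CohortSpec",
    "default_sd",
    "default_item_models",
    "sample_item_score",
    "plant_profile",
    "generate_cohort",
]

# Published per-sex item means (items 1..14).
MEN_ITEM_MEANS = (4.63, -2.18, -3.42, -6.10, 2.90, 7.02, 2.26,
                  -5.48, -3.41, 4.03, 5.15, 0.51, 5.02, -6.86)
WOMEN_ITEM_MEANS = (4.24, -2.72, -5.65, -6.3, 1.81, 7.44, 1.17,
                    -7.04, -5.27, 4.41, 6.20, 1.92, 4.21, -8.23)

# Linear spread model sd = a - b*|mean|, clipped to [SD_FLOOR, SD_CEIL].
# Anchored to the two published whole-population extremes: the strongest
# items (|mean| 7.23) have sd 2.03 and the weakest (|mean| ~1.7) sd 5.56.
_SD_SLOPE = (5.56 - 2.03) / (7.23 - 1.715)
_SD_INTERCEPT = 2.03 + 7.23 * _SD_SLOPE
SD_FLOOR = 0.8
SD_CEIL = 6.0

PLANTABLE_LABELS = (
    "liberal", "conservative", "neutral",
    "positive_alliesthesia", "negative_alliesthesia",
)


def default_sd(mean: float) -> float:
    """Item SD implied by the spread model for a given item mean."""
    return float(np.clip(_SD_INTERCEPT - _SD_SLOPE * abs(mean), SD_FLOOR, SD_CEIL))


@dataclass(frozen=True)
class ItemModel:
    """Generating distribution of one item: N(mean, sd) truncated and gridded."""

    item_id: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (1 <= self.item_id <= N_ITEMS):
            raise ValueError(f"item_id {self.item_id} not in 1..{N_ITEMS}")
        if not (-9.0 <= self.mean <= 9.0):
            raise ValueError(f"item mean {self.mean} outside [-9, 9]")
        if self.sd <= 0:
            raise ValueError("item sd must be positive")


def default_item_models(sex: Optional[str] = None) -> tuple[ItemModel, ...]:
    """Default item models for ``sex`` 'M', 'F' or None (pooled).

    Pooled means are the unweighted average of the men's and women's means
    (the reference cohort is balanced 50/50); SDs come from the spread
    model.
    """
    if sex == "M":
        means = MEN_ITEM_MEANS
    elif sex == "F":
        means = WOMEN_ITEM_MEANS
    elif sex is None or sex == "U":
        means = tuple((m + w) / 2 for m, w in zip(MEN_ITEM_MEANS, WOMEN_ITEM_MEANS))
    else:
        raise ValueError(f"unknown sex {sex!r}")
    return tuple(
        ItemModel(item_id=i + 1, mean=m, sd=default_sd(m)) for i, m in enumerate(means)
    )


def _round_half_step(x: np.ndarray) -> np.ndarray:
    """Round to the nearest multiple of 0.5, ties away from zero."""
    return np.sign(x) * np.floor(np.abs(x) * 2 + 0.5) / 2


def _sample_grid_scores(mean: float, sd: float, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws on [-9, 9], quantized to the half-step grid."""
    out = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        draws = rng.normal(mean, sd, size=pending.size)
        ok = (draws >= -9.0) & (draws <= 9.0)
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
    return _round_half_step(out)


def sample_item_score(model: ItemModel, rng: np.random.Generator) -> float:
    """Draw a single score from an item model."""
    if model.sd <= 0:
        raise ValueError("item sd must be positive")
    return float(_sample_grid_scores(model.mean, model.sd, 1, rng)[0])


_GRID = np.arange(-18, 19) / 2.0  # the 37 legal scores


def _item_pmf(mean: float, sd: float) -> np.ndarray:
    """Exact pmf of a sampled score over the 37-value grid.

    The sampling scheme is a normal truncated to [-9, 9] rounded half away
    from zero, so grid value s collects the truncated mass of
    [s - 0.25, s + 0.25) on the positive side (mirrored for negative, with
    the half-open edge toward zero; the boundary cells extend to +-9).
    """
    lower = _GRID - 0.25
    upper = _GRID + 0.25
    lower[0], upper[-1] = -9.0, 9.0
    cdf = norm.cdf(np.concatenate([lower[:1], upper]), loc=mean, scale=sd)
    p = np.diff(cdf)
    z = norm.cdf(9.0, mean, sd) - norm.cdf(-9.0, mean, sd)
    return p / z


def _expected_totals(models: Sequence[ItemModel]) -> tuple[float, float]:
    """Exact model-implied expected (T+, T-) under truncation + quantization."""
    tp = tm = 0.0
    for m in models:
        p = _item_pmf(m.mean, m.sd)
        tp += float(np.sum(p * np.maximum(_GRID, 0.0)))
        tm += float(np.sum(p * np.minimum(_GRID, 0.0)))
    return tp, tm


def _scaled(base: Sequence[ItemModel], f_pos: float, f_neg: float,
            sd_div: float) -> tuple[ItemModel, ...]:
    """Scale positive-mean items by f_pos and negative-mean items by f_neg."""
    out = []
    for m in base:
        f = f_pos if m.mean > 0 else f_neg if m.mean < 0 else 1.0
        mean = float(np.clip(m.mean * f, -9.0, 9.0))
        out.append(replace(m, mean=mean, sd=m.sd / sd_div))
    return tuple(out)


def _solve_scale(objective, lo: float = 1e-3, hi: float = 4.0) -> float:
    """Root of a monotone scale objective, clipped to the bracket."""
    flo, fhi = objective(lo), objective(hi)
    if flo * fhi > 0:
        return lo if abs(flo) < abs(fhi) else hi
    return float(brentq(objective, lo, hi, xtol=1e-6))


def plant_profile(
    base: Sequence[ItemModel],
    label: str,
    intensity: float,
) -> tuple[ItemModel, ...]:
    """Shift a set of item models so sampled respondents express a profile.

    ``intensity`` >= 1 controls how strongly the profile is expressed;
    ``intensity = 1`` returns the models unchanged.  Item-mean magnitudes
    are scaled per valence group (signs never flip; magnitudes cap at 9)
    and every SD is divided by ``intensity``: a planted respondent
    expresses the profile consistently across items, which is what makes
    the class recoverable against reference norms.

    * liberal -- every |mean| scaled up by ``intensity``;
    * conservative -- every |mean| scaled down by ``intensity``;
    * positive_alliesthesia -- positive means scaled up by ``intensity``;
      negative means shrunk toward 0 by the factor that keeps the expected
      total score TS at the base cohort's expected TS (alliesthesia shifts
      the hedonic balance, not the total hedonic output, so TS stays
      mid-band while T+ rises and |T-| falls);
    * negative_alliesthesia -- the mirror image;
    * neutral -- both valence groups rescaled so the expected T+ and T-
      equal the base cohort's expected totals (the centres of the medium
      bands), compensating for the narrower planted spread.

    Expected totals are computed exactly for the truncated, grid-quantized
    sampling distribution.
    """
    if label not in PLANTABLE_LABELS:
        raise ValueError(
            f"cannot plant label {label!r}; must be one of {PLANTABLE_LABELS}"
        )
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    if intensity == 1.0:
        return tuple(base)

    tp0, tm0 = _expected_totals(base)
    ts0 = tp0 - tm0

    if label == "liberal":
        return _scaled(base, intensity, intensity, intensity)
    if label == "conservative":
        return _scaled(base, 1.0 / intensity, 1.0 / intensity, intensity)

    if label == "neutral":
        # Alternate the two one-dimensional solves; coupling across
        # valence groups is weak, so two sweeps suffice.
        f_pos = f_neg = 1.0
        for _ in range(2):
            f_pos = _solve_scale(lambda f: _expected_totals(
                _scaled(base, f, f_neg, intensity))[0] - tp0)
            f_neg = _solve_scale(lambda f: _expected_totals(
                _scaled(base, f_pos, f, intensity))[1] - tm0)
        return _scaled(base, f_pos, f_neg, intensity)

    if label == "positive_alliesthesia":
        f_neg = _solve_scale(lambda f: np.subtract(*_expected_totals(
            _scaled(base, intensity, f, intensity))) - ts0, hi=1.5)
        return _scaled(base, intensity, f_neg, intensity)

    # negative_alliesthesia
    f_pos = _solve_scale(lambda f: np.subtract(*_expected_totals(
        _scaled(base, f, intensity, intensity))) - ts0, hi=1.5)
    return _scaled(base, f_pos, intensity, intensity)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``profile_plan`` is a list of ``(label, count, intensity)`` triples;
    the first ``sum(counts)`` respondents are planted (sex assignment is
    randomized, so planting is independent of sex).  ``self_smell_rho`` is
    the target Spearman correlation between the self-rating and TS.
    """

    n: int = 100
    sex_ratio: float = 0.5
    seed: int = 0
    male_models: tuple[ItemModel, ...] = field(
        default_factory=lambda: default_item_models("M"))
    female_models: tuple[ItemModel, ...] = field(
        default_factory=lambda: default_item_models("F"))
    profile_plan: tuple[tuple[str, int, float], ...] = ()
    self_smell_rho: float = 0.23
    age_mean: float = 22.9
    age_sd: float = 1.4

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        planted = sum(count for _, count, _ in self.profile_plan)
        if planted > self.n:
            raise ValueError("profile_plan counts exceed cohort size")
        for label, count, intensity in self.profile_plan:
            if label not in PLANTABLE_LABELS:
                raise ValueError(f"cannot plant label {label!r}")
            if count < 0 or intensity <= 0:
                raise ValueError("plan counts must be >= 0 and intensities > 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table, fully reproducible from ``spec.seed``.

    Returns a validated wide cohort DataFrame (``id, sex, age, self_smell,
    item01..item14``) plus a ``planted`` column holding the planted profile
    label, or an empty string for unplanted respondents.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols = {c: np.empty(0) for c in ITEM_COLUMNS}
    if n == 0:
        df = pd.DataFrame({"id": [], "sex": [], "age": [], "self_smell": [], **cols})
        df["planted"] = []
        return df

    n_male = int(round(n * spec.sex_ratio))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)

    planted = np.array([""] * n, dtype=object)
    assignment: list[Optional[tuple[str, float]]] = [None] * n
    pos = 0
    for label, count, intensity in spec.profile_plan:
        for _ in range(count):
            planted[pos] = label
            assignment[pos] = (label, intensity)
            pos += 1

    model_for: list[tuple[ItemModel, ...]] = []
    plan_models: dict[tuple[str, float, str], tuple[ItemModel, ...]] = {}
    for i in range(n):
        base = spec.male_models if sexes[i] == "M" else spec.female_models
        if assignment[i] is None:
            model_for.append(base)
        else:
            label, intensity = assignment[i]
            key = (label, intensity, sexes[i])
            if key not in plan_models:
                plan_models[key] = plant_profile(base, label, intensity)
            model_for.append(plan_models[key])

    scores = np.empty((n, N_ITEMS))
    # Group respondents sharing a model set so draws vectorize per item.
    groups: dict[int, list[int]] = {}
    for i, models in enumerate(model_for):
        groups.setdefault(id(models), []).append(i)
    uniq = {id(m): m for m in model_for}
    for gid in sorted(groups, key=lambda g: groups[g][0]):
        idx = np.array(groups[gid])
        models = uniq[gid]
        for j, m in enumerate(models):
            scores[idx, j] = _sample_grid_scores(m.mean, m.sd, idx.size, rng)

    ages = np.clip(np.round(rng.normal(spec.age_mean, spec.age_sd, n)), 19, 26)

    ts = np.abs(scores).sum(axis=1)
    self_smell = _coupled_self_smell(ts, spec.self_smell_rho, rng)

    df = pd.DataFrame({
        "id": [f"r{i + 1:04d}" for i in range(n)],
        "sex": sexes,
        "age": ages,
        "self_smell": self_smell,
        **{item_column(j + 1): scores[:, j] for j in range(N_ITEMS)},
    })
    df = validate_cohort(df)
    df["planted"] = planted
    return df


def _coupled_self_smell(ts: np.ndarray, rho_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Self-rated smell on the grid, rank-coupled to TS.

    A Gaussian-copula blend: the normal scores of the TS ranks are mixed
    with independent noise at the latent Pearson correlation that maps to
    the target Spearman correlation (rho_latent = 2 sin(pi rho_s / 6)),
    then shifted to a mildly positive self-rating scale (mean 3, sd 3) and
    quantized.
    """
    n = ts.size
    if n == 1:
        z_ts = np.zeros(1)
    else:
        ranks = pd.Series(ts).rank(method="average").to_numpy()
        z_ts = norm.ppf((ranks - 0.5) / n)
    rho_l = 2 * np.sin(np.pi * rho_s / 6)
    latent = rho_l * z_ts + np.sqrt(1 - rho_l ** 2) * rng.normal(size=n)
    return _round_half_step(np.clip(3.0 + 3.0 * latent, -9.0, 9.0))
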