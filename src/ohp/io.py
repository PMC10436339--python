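"""Reading and writing respondent tables and norm files.

The canonical cohort table is a pandas DataFrame with one row per
respondent and columns ``id, sex, age, self_smell, item01..item14``.
Sex is coded ``M`` / ``F`` / ``U``; ``age`` and ``self_smell`` may be
missing (NaN).  Item scores are half-integers in [-9, +9] and survive a
CSV round trip exactly.

An alternative long ("raw dash") form carries one row per (respondent,
item) with columns ``id, item, valence, dash, half`` and is converted to
the wide table through :func:`ohp.scoring.score_from_dash`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .scoring import N_ITEMS, SEXES, ValidationError, score_from_dash, validate_score

__all__ = [
    "ITEM_COLUMNS",
    "COHORT_COLUMNS",
    "item_column",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_dash_csv",
    "attach_scores",
]

ITEM_COLUMNS = tuple(f"item{i:02d}" for i in range(1, N_ITEMS + 1))
COHORT_COLUMNS = ("id", "sex", "age", "self_smell") + ITEM_COLUMNS


def item_column(item_id: int) -> str:
    """Column name for a 1-based item id (``item01`` .. ``item14``)."""
    return f"item{int(item_id):02d}"


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a wide cohort table and return it with canonical columns.

    Checks column presence, unique ids, legal sex codes, and that every
    item score sits on the half-step grid in [-9, +9].  Errors name the
    offending respondent and item so data-entry mistakes are findable.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    df = df.loc[:, list(COHORT_COLUMNS)].copy()
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate respondent ids {dupes}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"illegal sex codes for respondents {df.loc[bad_sex, 'id'].tolist()}"
        )
    for col in ITEM_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            rid = df.loc[np.isnan(vals), "id"].iloc[0]
            raise ValidationError(f"respondent {rid}: missing score in {col}")
        on_grid = (np.abs(vals) <= 9.0) & (2 * vals == np.round(2 * vals))
        if not on_grid.all():
            rid = df.loc[~on_grid, "id"].iloc[0]
            val = vals[~on_grid][0]
            raise ValidationError(
                f"respondent {rid}: {col} score {val} not on the half-step "
                f"grid in [-9, +9]"
            )
        df[col] = vals
    df["self_smell"] = [
        np.nan if pd.isna(v) else validate_score(v) for v in df["self_smell"]
    ]
    return df


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a wide cohort CSV."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    return validate_cohort(df)


def write_cohort_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table to CSV, preserving half-integer scores exactly."""
    out = df.loc[:, [c for c in COHORT_COLUMNS if c in df.columns]]
    out.to_csv(path, index=False)


def read_dash_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a long raw-dash CSV (`id, item, valence, dash, half`) as a wide table.

    Demographics are not carried by the raw form; sex is set to ``U`` and
    age / self_smell are left missing.
    """
    long = pd.read_csv(path, dtype={"id": str, "valence": str})
    required = {"id", "item", "valence", "dash", "half"}
    missing = required - set(long.columns)
    if missing:
        raise ValidationError(f"dash table missing columns {sorted(missing)}")
    rows = {}
    for rec in long.itertuples(index=False):
        try:
            score = score_from_dash(rec.valence, int(rec.dash), bool(rec.half))
        except ValidationError as exc:
            raise ValidationError(
                f"respondent {rec.id}, item {rec.item}: {exc}"
            ) from exc
        rows.setdefault(rec.id, {})[int(rec.item)] = score
    records = []
    for rid, items in rows.items():
        missing_items = sorted(set(range(1, N_ITEMS + 1)) - set(items))
        if missing_items:
            raise ValidationError(f"respondent {rid}: missing items {missing_items}")
        rec = {"id": rid, "sex": "U", "age": np.nan, "self_smell": np.nan}
        rec.update({item_column(i): items[i] for i in range(1, N_ITEMS + 1)})
        records.append(rec)
    return validate_cohort(pd.DataFrame.from_records(records))


def attach_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Append per-respondent ``ts, t_plus, t_minus, delta`` columns.

    TS is the sum of absolute item scores; T+ / T- the positive / negative
    parts; delta the signed sum.  Half-integer arithmetic is exact in
    float64, so TS = T+ - T- and delta = T+ + T- hold bit-exactly.
    """
    scores = df.loc[:, list(ITEM_COLUMNS)].to_numpy(dtype=float)
    out = df.copy()
    out["t_plus"] = np.where(scores > 0, scores, 0.0).sum(axis=1)
    out["t_minus"] = np.where(scores < 0, scores, 0.0).sum(axis=1)
    out["ts"] = out["t_plus"] - out["t_minus"]
    out["delta"] = out["t_plus"] + out["t_minus"]
    return out


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
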