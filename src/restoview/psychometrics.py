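"""Scoring of the Indoor Restorative Characteristic Scale (IRCS).

The IRCS has 11 items rated 1–5: four Being Away, four Fascination and three
Extent items; reverse-keyed items (Extent only) are inverted as ``6 - x``
before averaging.  Each subscale score is the mean of its items and the
overall restorativeness score is the mean of the three subscale scores.
Participant-level scores are aggregated to per-photo means and sample
standard deviations, which are the unit of the downstream modeling.

Which Extent items are reverse-keyed is configurable through the scale
definition JSON; the packaged default flags EX2 and EX3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from restoview.exceptions import ValidationError

__all__ = [
    "ScaleItem",
    "ScaleDefinition",
    "IRCSResponse",
    "SubscaleScores",
    "PhotoRatingSummary",
    "default_scale",
    "reverse_score",
    "score_ircs",
    "score_restorative_experience",
    "score_ratings_table",
    "aggregate_by_photo",
    "correlate",
]

SUBSCALES = ("BeingAway", "Fascination", "Extent")
_EXPECTED_COUNTS = {"BeingAway": 4, "Fascination": 4, "Extent": 3}


@dataclass(frozen=True)
class ScaleItem:
    item_id: str
    subscale: str
    reverse: bool = False


@dataclass(frozen=True)
class ScaleDefinition:
    """The 11-item scale layout with per-item reverse flags."""

    items: tuple

    def __post_init__(self) -> None:
        counts = {s: 0 for s in SUBSCALES}
        for it in self.items:
            if it.subscale not in counts:
                raise ValidationError(f"unknown subscale {it.subscale!r}")
            counts[it.subscale] += 1
            if it.reverse and it.subscale != "Extent":
                raise ValidationError("reverse flags are only allowed on Extent items")
        if counts != _EXPECTED_COUNTS:
            raise ValidationError(
                f"expected 4 BeingAway / 4 Fascination / 3 Extent items, got {counts}"
            )

    @property
    def item_ids(self) -> tuple:
        return tuple(it.item_id for it in self.items)

    def items_of(self, subscale: str) -> tuple:
        return tuple(it for it in self.items if it.subscale == subscale)

    @classmethod
    def from_json(cls, path) -> "ScaleDefinition":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: Mapping) -> "ScaleDefinition":
        items = tuple(
            ScaleItem(d["item_id"], d["subscale"], bool(d.get("reverse", False)))
            for d in payload["items"]
        )
        return cls(items)


def default_scale() -> ScaleDefinition:
    """The packaged IRCS layout (reverse flags on EX2 and EX3)."""
    payload = json.loads(
        resources.files("restoview.data").joinpath("ircs_scale.json").read_text("utf-8")
    )
    return ScaleDefinition._from_payload(payload)


@dataclass(frozen=True)
class IRCSResponse:
    """One participant's complete 11-item rating of one photograph."""

    participant_id: str
    photo_id: str
    responses: Mapping  # item_id -> int in [1, 5]


@dataclass(frozen=True)
class SubscaleScores:
    being_away: float
    fascination: float
    extent: float
    overall: float

    def __post_init__(self) -> None:
        expected = (self.being_away + self.fascination + self.extent) / 3.0
        if abs(self.overall - expected) > 1e-9:
            raise ValidationError("overall must equal the mean of the three subscale scores")


@dataclass(frozen=True)
class PhotoRatingSummary:
    photo_id: str
    n_raters: int
    means: Mapping  # score name -> mean
    sds: Mapping  # score name -> sample SD (0 when n = 1)


def reverse_score(x: int) -> int:
    """Invert a 1–5 response: 6 - x."""
    if not float(x).is_integer() or not 1 <= x <= 5:
        raise ValidationError(f"response must be an integer in [1, 5], got {x!r}")
    return 6 - int(x)


def _validated_response(resp: IRCSResponse, scale: ScaleDefinition) -> dict:
    missing = [i for i in scale.item_ids if i not in resp.responses]
    if missing:
        raise ValidationError(
            f"participant {resp.participant_id}, photo {resp.photo_id}: missing items {missing}"
        )
    out = {}
    for it in scale.items:
        x = resp.responses[it.item_id]
        if not float(x).is_integer() or not 1 <= x <= 5:
            raise ValidationError(
                f"item {it.item_id}: response must be an integer in [1, 5], got {x!r}"
            )
        out[it.item_id] = reverse_score(int(x)) if it.reverse else int(x)
    return out


def score_ircs(resp: IRCSResponse, scale: ScaleDefinition | None = None) -> SubscaleScores:
    """Score one response: item means per subscale, overall = mean of subscale means."""
    if scale is None:
        scale = default_scale()
    keyed = _validated_response(resp, scale)
    means = {}
    for sub in SUBSCALES:
        vals = [keyed[it.item_id] for it in scale.items_of(sub)]
        means[sub] = float(np.mean(vals))
    overall = float(np.mean(list(means.values())))
    return SubscaleScores(means["BeingAway"], means["Fascination"], means["Extent"], overall)


def score_restorative_experience(responses: Sequence[int]) -> float:
    """Mean of the five restorative-experience items."""
    if len(responses) != 5:
        raise ValidationError(f"expected 5 responses, got {len(responses)}")
    for x in responses:
        if not float(x).is_integer() or not 1 <= x <= 5:
            raise ValidationError(f"response must be an integer in [1, 5], got {x!r}")
    return float(np.mean([int(x) for x in responses]))


SCORE_COLUMNS = ("overall", "being_away", "fascination", "extent")


def score_ratings_table(ratings: pd.DataFrame, scale: ScaleDefinition | None = None) -> pd.DataFrame:
    """Score a long-format ratings table to per-(participant, photo) scores.

    ``ratings`` needs columns participant_id, photo_id, item_id, response.
    Incomplete (participant, photo) blocks raise; there is no imputation.
    """
    if scale is None:
        scale = default_scale()
    required = {"participant_id", "photo_id", "item_id", "response"}
    if not required.issubset(ratings.columns):
        raise ValidationError(f"ratings table must have columns {sorted(required)}")
    wide = ratings.pivot_table(
        index=["participant_id", "photo_id"], columns="item_id", values="response",
        aggfunc="first",
    )
    missing_items = [i for i in scale.item_ids if i not in wide.columns]
    if missing_items:
        raise ValidationError(f"ratings contain no responses for items {missing_items}")
    wide = wide[list(scale.item_ids)]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index[0]
        raise ValidationError(f"incomplete response block for {bad}")
    vals = wide.to_numpy(dtype=float)
    if np.any(vals != np.round(vals)) or vals.min() < 1 or vals.max() > 5:
        raise ValidationError("responses must be integers in [1, 5]")
    keyed = vals.copy()
    for j, it in enumerate(scale.items):
        if it.reverse:
            keyed[:, j] = 6 - keyed[:, j]
    out = pd.DataFrame(index=wide.index)
    cols = {s: [j for j, it in enumerate(scale.items) if it.subscale == s] for s in SUBSCALES}
    out["being_away"] = keyed[:, cols["BeingAway"]].mean(axis=1)
    out["fascination"] = keyed[:, cols["Fascination"]].mean(axis=1)
    out["extent"] = keyed[:, cols["Extent"]].mean(axis=1)
    out["overall"] = (out["being_away"] + out["fascination"] + out["extent"]) / 3.0
    return out.reset_index()


def aggregate_by_photo(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-photo mean and sample SD (n-1; 0 when n = 1) of each score column.

    ``scores`` is the output of :func:`score_ratings_table` (optionally with a
    ``restorative_experience`` column).  Rows come back sorted by photo_id.
    """
    if len(scores) == 0:
        raise ValidationError("no scores to aggregate")
    score_cols = [c for c in scores.columns if c not in ("participant_id", "photo_id")]
    grouped = scores.groupby("photo_id", sort=True)
    out = pd.DataFrame({"n_raters": grouped.size()})
    for c in score_cols:
        out[f"{c}_mean"] = grouped[c].mean()
        out[f"{c}_sd"] = grouped[c].std(ddof=1).fillna(0.0)
    return out.reset_index()


def correlate(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlate needs two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
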