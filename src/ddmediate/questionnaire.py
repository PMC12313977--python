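"""Emotion Regulation Questionnaire (ERQ) scoring and reliability.

The ERQ has ten items on 7-point Likert scales (1 = strongly disagree,
7 = strongly agree): six items form the cognitive-reappraisal subscale and
four the expressive-suppression subscale.  Subscales are scored as item
sums (reappraisal 6-42, suppression 4-28); higher scores indicate more
habitual use of that strategy.  No items are reverse-keyed.

Internal consistency is assessed with Cronbach's alpha,

    alpha = K/(K-1) * (1 - sum_i var(item_i) / var(total)),

using n-1 sample variances throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Standard ERQ item assignment (1-based item numbers).
REAPPRAISAL_ITEMS = (1, 3, 5, 7, 8, 10)
SUPPRESSION_ITEMS = (2, 4, 6, 9)

ITEM_COLUMNS = [f"item_{i}" for i in range(1, 11)]
LIKERT_RANGE = (1, 7)


class QuestionnaireError(ValueError):
    pass


@dataclass(frozen=True)
class ItemMap:
    """Assignment of the ten ERQ items to the two subscales (6/4 split)."""

    reappraisal: tuple[int, ...] = REAPPRAISAL_ITEMS
    suppression: tuple[int, ...] = SUPPRESSION_ITEMS

    def __post_init__(self) -> None:
        if len(self.reappraisal) != 6 or len(self.suppression) != 4:
            raise QuestionnaireError("item map must assign 6 + 4 items")
        all_items = sorted(self.reappraisal + self.suppression)
        if all_items != list(range(1, 11)):
            raise QuestionnaireError("item map must partition items 1..10")


@dataclass(frozen=True)
class ERQResponses:
    subject_id: str
    items: np.ndarray  # ten responses, 1..7
    item_map: ItemMap = field(default_factory=ItemMap)

    def __post_init__(self) -> None:
        arr = np.asarray(self.items)
        if arr.shape != (10,):
            raise QuestionnaireError(
                f"subject {self.subject_id}: expected 10 items, got {arr.shape}"
            )
        if np.isnan(arr.astype(float)).any():
            raise QuestionnaireError(
                f"subject {self.subject_id}: missing item responses"
            )
        arr = arr.astype(int)
        if (arr < LIKERT_RANGE[0]).any() or (arr > LIKERT_RANGE[1]).any():
            raise QuestionnaireError(
                f"subject {self.subject_id}: responses outside {LIKERT_RANGE}"
            )
        object.__setattr__(self, "items", arr)


@dataclass(frozen=True)
class SubscaleScores:
    reappraisal: int
    suppression: int

    def __post_init__(self) -> None:
        if not 6 <= self.reappraisal <= 42:
            raise QuestionnaireError("reappraisal score outside [6, 42]")
        if not 4 <= self.suppression <= 28:
            raise QuestionnaireError("suppression score outside [4, 28]")


def score_subscales(responses: ERQResponses) -> SubscaleScores:
    """Sum-score both subscales from one subject's item responses."""
    items = responses.items
    m = responses.item_map
    reap = int(sum(items[i - 1] for i in m.reappraisal))
    supp = int(sum(items[i - 1] for i in m.suppression))
    return SubscaleScores(reappraisal=reap, suppression=supp)


def score_item_table(
    items: pd.DataFrame, item_map: ItemMap = ItemMap()
) -> pd.DataFrame:
    """Score a subjects x items table (columns item_1..item_10).

    Returns a frame with subject_id, reappraisal, suppression.
    """
    missing = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise QuestionnaireError(f"missing item columns: {missing}")
    rows = []
    for r in items.itertuples():
        resp = ERQResponses(
            subject_id=str(r.subject_id),
            items=np.array([getattr(r, c) for c in ITEM_COLUMNS]),
            item_map=item_map,
        )
        s = score_subscales(resp)
        rows.append(
            {
                "subject_id": resp.subject_id,
                "reappraisal": s.reappraisal,
                "suppression": s.suppression,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a subjects x items matrix of one subscale.

    Requires at least 2 items, 3 subjects, and nonzero variance of the
    total score.  Uses n-1 variances, which makes the degenerate case of
    perfectly duplicated items exactly alpha = 1.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise QuestionnaireError("item_matrix must be 2-D (subjects x items)")
    n, k = X.shape
    if k < 2:
        raise QuestionnaireError("alpha needs at least 2 items")
    if n < 3:
        raise QuestionnaireError("alpha needs at least 3 subjects")
    if np.isnan(X).any():
        raise QuestionnaireError("item_matrix contains missing values")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise QuestionnaireError(
            "total-score variance is zero; alpha is undefined"
        )
    item_vars = np.var(X, axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def read_items(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise QuestionnaireError("item CSV must have a subject_id column")
    return frame


def subscale_matrix(
    items: pd.DataFrame, subscale: str, item_map: ItemMap = ItemMap()
) -> np.ndarray:
    """Extract the subjects x items matrix of one subscale."""
    idx = getattr(item_map, subscale)
    return items[[f"item_{i}" for i in idx]].to_numpy(dtype=float)
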