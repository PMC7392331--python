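"""Preference shares and comparison with actual budget allocations.

Mean best-worst scores are shifted to a positive scale anchored at zero
(subtracting the minimum score, so the least-preferred item sits at 0)
and normalized by their cumulative sum, yielding a percentage
preference share per item that sums to 100.  These shares and their
ranks are then set against the sectors' actual shares of the national
budget to quantify the misalignment between stated preferences and
allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountResult, _rank_desc


@dataclass
class BudgetComparison:
    """Per-item preference vs budget comparison.

    ``table`` columns: item_id, label, score, pref_share_pct,
    budget_share_pct, pref_rank, budget_rank, rank_diff
    (budget_rank - pref_rank; positive = budget under-ranks the item
    relative to preferences), share_diff (pref - budget, percentage
    points).
    """

    table: pd.DataFrame


def _as_scores(scores) -> pd.Series:
    if isinstance(scores, CountResult):
        return scores.scores()
    s = pd.Series(scores, dtype=float)
    return s


def preference_shares(scores, anchor_epsilon: float = 0.0) -> pd.Series:
    """Percentage preference share per item.

    d_j = s_j - (min_k s_k - anchor_epsilon); p_j = 100 * d_j / sum(d).
    With the default anchor_epsilon=0 the minimum-score item gets
    exactly 0%.  Raises if all scores are equal (zero shifted mass).
    """
    s = _as_scores(scores)
    if anchor_epsilon < 0:
        raise ValueError("anchor_epsilon must be >= 0")
    d = s - (s.min() - anchor_epsilon)
    total = d.sum()
    if total <= 0:
        raise ValueError(
            "all scores are equal; preference shares are undefined "
            "(zero total shifted mass)"
        )
    return 100.0 * d / total


def compare_with_budget(
    scores,
    budget_shares: Mapping[str, float | None],
    budget_ranks: Mapping[str, int] | None = None,
    labels: Mapping[str, str] | None = None,
    anchor_epsilon: float = 0.0,
) -> BudgetComparison:
    """Compare preference shares/ranks against budget shares/ranks.

    ``budget_shares`` maps item_id -> percent of the national budget;
    shares need not sum to 100 (budgets include unlisted lines).  When
    ``budget_ranks`` is None, all items must have a budget share and
    ranks are computed by descending share (ties by item order);
    otherwise the supplied ranks are used and missing shares are
    tolerated (their share_diff is NaN) — the case when only a subset
    of published budget figures is available.
    """
    s = _as_scores(scores)
    p = preference_shares(s, anchor_epsilon=anchor_epsilon)
    g = pd.Series(
        [budget_shares.get(i) for i in s.index], index=s.index, dtype=float
    )
    if budget_ranks is None:
        missing = list(s.index[g.isna()])
        if missing:
            raise ValueError(
                f"missing budget share for items: {missing}; supply "
                "budget_ranks to compare with partial budget data"
            )
        b_rank = pd.Series(_rank_desc(g.to_numpy()), index=s.index)
    else:
        b_rank = pd.Series(
            [budget_ranks.get(i) for i in s.index],
            index=s.index,
            dtype="Int64",
        )
    p_rank = pd.Series(_rank_desc(p.to_numpy()), index=s.index)
    labels = dict(labels) if labels is not None else {}
    table = pd.DataFrame(
        {
            "item_id": s.index,
            "label": [labels.get(i, i) for i in s.index],
            "score": s.to_numpy(),
            "pref_share_pct": p.to_numpy(),
            "budget_share_pct": g.to_numpy(),
            "pref_rank": p_rank.to_numpy(),
            "budget_rank": b_rank.to_numpy(),
            "rank_diff": (b_rank - p_rank).to_numpy(),
            "share_diff": (p - g).to_numpy(),
        }
    ).reset_index(drop=True)
    return BudgetComparison(table=table)
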