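"""Count-based best-minus-worst scoring with t-tests.

The mean best-worst score of item j is s_j = (B_j - W_j) / (r * n),
where B_j and W_j are the times item j was chosen best and worst over
all respondents, r is the number of appearances per respondent (4 in
the budget-sector survey: each sector appears in 4 of the 16 tasks) and
n the number of respondents.  s_j lies in [-1, 1] and the scores sum to
zero over items on any complete response set.  With respondent-level
data, s_j is also the mean of the per-respondent scores
b_ij = (best_ij - worst_ij)/r, which supplies a standard error and a
one-sample t-test against zero, and a two-sample test between strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseSet


@dataclass
class CountResult:
    """Per-item tallies, scores and tests.

    ``table`` columns: item_id, label, best, worst, score, se, t, p,
    rank (1 = highest score).  se/t/p are NaN when computed from
    aggregate counts only.
    """

    table: pd.DataFrame
    n: int
    r: int

    def scores(self) -> pd.Series:
        return self.table.set_index("item_id")["score"]

    def ranking(self) -> list[str]:
        """Item ids ordered by rank (best first)."""
        return list(self.table.sort_values("rank")["item_id"])


@dataclass
class StratumComparison:
    """Per-item two-sample t-test between two strata.

    ``table`` columns: item_id, label, score_<a>, se_<a>, score_<b>,
    se_<b>, t, df, p (Welch by default).
    """

    table: pd.DataFrame
    stratum_a: str
    stratum_b: str
    pooled: bool


def _uniform_r(responses: ResponseSet) -> int:
    from .design import validate_design

    diag = validate_design(responses.design)
    if not diag.frequency_balanced:
        raise ValueError(
            "count scoring requires a frequency-balanced design (uniform "
            "appearances per item); this design is unbalanced"
        )
    return int(responses.design.appearances_per_item)


def best_worst_counts(responses: ResponseSet) -> pd.DataFrame:
    """Exact per-item best/worst tallies (columns best, worst, indexed
    by item_id in catalogue order)."""
    J = len(responses.catalogue)
    idx = {iid: j for j, iid in enumerate(responses.catalogue.ids)}
    df = responses.responses
    b = np.bincount(df["best"].map(idx).to_numpy(int), minlength=J)
    w = np.bincount(df["worst"].map(idx).to_numpy(int), minlength=J)
    return pd.DataFrame(
        {"best": b, "worst": w},
        index=pd.Index(responses.catalogue.ids, name="item_id"),
    )


def respondent_scores(responses: ResponseSet) -> pd.DataFrame:
    """Per-respondent score matrix b_ij = (best_ij - worst_ij)/r,
    respondents in rows (first-appearance order), items in columns."""
    r = _uniform_r(responses)
    J = len(responses.catalogue)
    idx = {iid: j for j, iid in enumerate(responses.catalogue.ids)}
    df = responses.responses
    rid = pd.Categorical(
        df["respondent_id"], categories=responses.respondent_ids
    )
    ri = rid.codes.astype(int)
    n = len(rid.categories)
    mat = np.zeros((n, J))
    np.add.at(mat, (ri, df["best"].map(idx).to_numpy(int)), 1.0)
    np.add.at(mat, (ri, df["worst"].map(idx).to_numpy(int)), -1.0)
    mat /= r
    return pd.DataFrame(
        mat, index=list(rid.categories), columns=responses.catalogue.ids
    )


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    """Ranks 1..J, 1 = largest; ties broken by position (catalogue order)."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def mean_bw_scores(
    data: ResponseSet | pd.DataFrame | Mapping[str, tuple[int, int]],
    n: int | None = None,
    r: int | None = None,
    labels: Mapping[str, str] | None = None,
) -> CountResult:
    """Mean best-worst scores s_j = (B_j - W_j)/(r*n) with SE/t/p.

    Pass a ResponseSet for the full respondent-level analysis (SE from
    the spread of per-respondent scores, t with n-1 df, two-sided p),
    or aggregate (best, worst) counts with explicit ``n`` and ``r`` —
    scores and ranks only, SE/t/p reported as NaN since the respondent-
    level spread is then unknown.
    """
    if isinstance(data, ResponseSet):
        counts = best_worst_counts(data)
        n = data.n_respondents
        r = _uniform_r(data)
        if n == 0:
            raise ValueError("no respondents")
        per = respondent_scores(data).to_numpy()
        score = per.mean(axis=0)
        if n > 1:
            se = per.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            se = np.full(per.shape[1], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = score / se
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        label_map = dict(zip(data.catalogue.ids, data.catalogue.labels))
    else:
        if n is None or r is None:
            raise ValueError("aggregate counts require explicit n and r")
        if n <= 0 or r <= 0:
            raise ValueError("n and r must be positive")
        if isinstance(data, pd.DataFrame):
            counts = data[["best", "worst"]].copy()
        else:
            counts = pd.DataFrame.from_dict(
                dict(data), orient="index", columns=["best", "worst"]
            )
            counts.index.name = "item_id"
        score = (
            counts["best"].to_numpy() - counts["worst"].to_numpy()
        ) / (r * n)
        se = np.full(len(counts), np.nan)
        t = np.full(len(counts), np.nan)
        p = np.full(len(counts), np.nan)
        label_map = dict(labels) if labels is not None else {}
    table = pd.DataFrame(
        {
            "item_id": counts.index,
            "label": [label_map.get(i, i) for i in counts.index],
            "best": counts["best"].to_numpy(int),
            "worst": counts["worst"].to_numpy(int),
            "score": score,
            "se": se,
            "t": t,
            "p": p,
            "rank": _rank_desc(np.asarray(score, float)),
        }
    ).reset_index(drop=True)
    return CountResult(table=table, n=int(n), r=int(r))


def compare_strata(
    responses: ResponseSet,
    stratum_a: str,
    stratum_b: str,
    pooled: bool = False,
) -> StratumComparison:
    """Per-item two-sample t-test on respondent-level scores.

    Welch (unequal-variance) by default; ``pooled=True`` uses the
    classic equal-variance test.
    """
    strata = responses.strata()
    per = respondent_scores(responses)
    out = {}
    for label in (stratum_a, stratum_b):
        members = strata.index[strata == label]
        if len(members) < 2:
            raise ValueError(
                f"stratum {label!r} has {len(members)} respondents; "
                "need at least 2 for a variance"
            )
        out[label] = per.loc[members]
    a, b = out[stratum_a].to_numpy(), out[stratum_b].to_numpy()
    res = stats.ttest_ind(a, b, axis=0, equal_var=pooled)
    label_map = dict(zip(responses.catalogue.ids, responses.catalogue.labels))
    na, nb = len(a), len(b)
    table = pd.DataFrame(
        {
            "item_id": per.columns,
            "label": [label_map.get(i, i) for i in per.columns],
            f"score_{stratum_a}": a.mean(axis=0),
            f"se_{stratum_a}": a.std(axis=0, ddof=1) / np.sqrt(na),
            f"score_{stratum_b}": b.mean(axis=0),
            f"se_{stratum_b}": b.std(axis=0, ddof=1) / np.sqrt(nb),
            "t": res.statistic,
            "df": res.df,
            "p": res.pvalue,
        }
    )
    return StratumComparison(
        table=table, stratum_a=stratum_a, stratum_b=stratum_b, pooled=pooled
    )
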