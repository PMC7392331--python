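"""Respondent best-worst response data and its long-format expansion.

The sequential conditional logit treats each recorded choice as two
stacked choice occasions: a *best* stage over the task's k items, and a
*worst* stage over the k-1 items left after the best is removed, with
the item utilities entering the worst stage negated.  ``ChoiceLong``
holds that stacked representation as integer arrays (plus a long-format
CSV export for interoperability with external conditional-logit
routines).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import Design, ItemCatalogue

RESPONSES_COLUMNS = ["respondent_id", "stratum", "task_id", "best", "worst"]


class ResponseValidationError(ValueError):
    """Raised when a response record violates the task structure."""


@dataclass
class ResponseSet:
    """Validated best/worst responses tied to a design and catalogue.

    ``responses`` has columns respondent_id, stratum, task_id (1-based
    int), best, worst (item ids).  Invariants checked on construction:
    best != worst, both belong to the task's item set, and each
    (respondent, task) pair appears at most once.
    """

    catalogue: ItemCatalogue
    design: Design
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.responses
        missing = [c for c in RESPONSES_COLUMNS if c not in df.columns]
        if missing:
            raise ResponseValidationError(f"missing columns: {missing}")
        self.responses = df = df.reset_index(drop=True)
        if df.empty:
            return
        known = set(self.catalogue.ids)
        for col in ("best", "worst"):
            bad = df.index[~df[col].isin(known)]
            if len(bad):
                row = int(bad[0])
                raise ResponseValidationError(
                    f"row {row}: unknown item_id {df.loc[row, col]!r} in "
                    f"column {col!r}"
                )
        eq = df.index[df["best"] == df["worst"]]
        if len(eq):
            row = int(eq[0])
            raise ResponseValidationError(
                f"row {row}: best and worst are both {df.loc[row, 'best']!r}"
            )
        tmax = self.design.n_tasks
        bad_task = df.index[(df["task_id"] < 1) | (df["task_id"] > tmax)]
        if len(bad_task):
            row = int(bad_task[0])
            raise ResponseValidationError(
                f"row {row}: task_id {df.loc[row, 'task_id']} outside 1..{tmax}"
            )
        dup = df.duplicated(subset=["respondent_id", "task_id"])
        if dup.any():
            row = int(df.index[dup][0])
            raise ResponseValidationError(
                f"row {row}: duplicate (respondent, task) pair "
                f"({df.loc[row, 'respondent_id']!r}, {df.loc[row, 'task_id']})"
            )
        # membership of best/worst in the task's item set
        codes = self.design.codes()
        idx = {iid: j for j, iid in enumerate(self.catalogue.ids)}
        ti = df["task_id"].to_numpy(dtype=int) - 1
        for col in ("best", "worst"):
            chosen = df[col].map(idx).to_numpy(dtype=int)
            member = (codes[ti] == chosen[:, None]).any(axis=1)
            if not member.all():
                row = int(np.flatnonzero(~member)[0])
                raise ResponseValidationError(
                    f"row {row}: item {df.loc[row, col]!r} not in task "
                    f"{df.loc[row, 'task_id']}"
                )

    def __len__(self) -> int:
        return len(self.responses)

    @property
    def respondent_ids(self) -> list[str]:
        return list(dict.fromkeys(self.responses["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return self.responses["respondent_id"].nunique()

    def strata(self) -> pd.Series:
        """Stratum label per respondent (first occurrence wins)."""
        return self.responses.groupby("respondent_id", sort=False)[
            "stratum"
        ].first()

    def is_complete(self) -> bool:
        """True iff every respondent answered every task exactly once."""
        if self.responses.empty:
            return True
        counts = self.responses.groupby("respondent_id", sort=False)[
            "task_id"
        ].count()
        return bool((counts == self.design.n_tasks).all())

    def subset(self, stratum: str) -> "ResponseSet":
        sub = self.responses[self.responses["stratum"] == stratum]
        if sub.empty:
            raise ValueError(f"no respondents in stratum {stratum!r}")
        return ResponseSet(self.catalogue, self.design, sub.copy())


@dataclass
class ChoiceLong:
    """Stacked best/worst choice groups in array form.

    One best-stage group of k alternatives (weight +1) and one
    worst-stage group of k-1 alternatives (weight -1) per response
    record.  ``*_items`` hold catalogue codes, ``*_chosen`` the within-
    group position of the chosen alternative.
    """

    catalogue: ItemCatalogue
    respondent_ids: np.ndarray  # (N,) object/str
    task_ids: np.ndarray  # (N,) int
    best_items: np.ndarray  # (N, k) int codes
    best_chosen: np.ndarray  # (N,) position in 0..k-1
    worst_items: np.ndarray  # (N, k-1) int codes
    worst_chosen: np.ndarray  # (N,) position in 0..k-2

    @property
    def n_records(self) -> int:
        return len(self.best_chosen)

    @property
    def k(self) -> int:
        return self.best_items.shape[1]

    @property
    def n_rows(self) -> int:
        """Total long-format rows: one per alternative per stage."""
        return self.n_records * (2 * self.k - 1)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV layout: respondent_id, task_id, stage, group_id,
        item_id, weight, chosen — one row per alternative."""
        ids = np.asarray(self.catalogue.ids, dtype=object)
        k = self.k
        N = self.n_records
        blocks = []
        for stage, items, chosen, weight, goff in (
            ("best", self.best_items, self.best_chosen, 1, 0),
            ("worst", self.worst_items, self.worst_chosen, -1, 1),
        ):
            m = items.shape[1]
            blocks.append(
                pd.DataFrame(
                    {
                        "respondent_id": np.repeat(self.respondent_ids, m),
                        "task_id": np.repeat(self.task_ids, m),
                        "stage": stage,
                        "group_id": np.repeat(np.arange(N) * 2 + goff, m),
                        "item_id": ids[items.ravel()],
                        "weight": weight,
                        "chosen": (
                            np.arange(m)[None, :] == chosen[:, None]
                        ).astype(int).ravel(),
                    }
                )
            )
        out = pd.concat(blocks, ignore_index=True)
        return out.sort_values(
            ["group_id"], kind="stable", ignore_index=True
        )


def expand_to_choice_long(
    responses: ResponseSet, allow_incomplete: bool = False
) -> ChoiceLong:
    """Expand best/worst records into stacked sequential choice groups.

    Per record over task items S with best b and worst w: a best-stage
    group over S with b chosen, and a worst-stage group over S \\ {b}
    with w chosen.  Raises if the ResponseSet is incomplete unless
    ``allow_incomplete`` (expansion then proceeds per available task).
    """
    if not allow_incomplete and not responses.is_complete():
        raise ValueError(
            "ResponseSet is incomplete (not every respondent answered "
            "every task); pass allow_incomplete=True to expand anyway"
        )
    df = responses.responses
    codes = responses.design.codes()
    idx = {iid: j for j, iid in enumerate(responses.catalogue.ids)}
    ti = df["task_id"].to_numpy(dtype=int) - 1
    best = df["best"].map(idx).to_numpy(dtype=int)
    worst = df["worst"].map(idx).to_numpy(dtype=int)
    best_items = codes[ti]  # (N, k)
    k = best_items.shape[1]
    best_chosen = np.argmax(best_items == best[:, None], axis=1)
    keep = best_items != best[:, None]
    worst_items = best_items[keep].reshape(-1, k - 1)
    worst_chosen = np.argmax(worst_items == worst[:, None], axis=1)
    return ChoiceLong(
        catalogue=responses.catalogue,
        respondent_ids=df["respondent_id"].to_numpy(dtype=object),
        task_ids=df["task_id"].to_numpy(dtype=int),
        best_items=best_items,
        best_chosen=best_chosen,
        worst_items=worst_items,
        worst_chosen=worst_chosen,
    )


def collapse_from_long(
    long: ChoiceLong,
    design: Design,
    strata: Mapping[str, str] | None = None,
) -> ResponseSet:
    """Recover the best/worst records from a ChoiceLong (inverse of
    :func:`expand_to_choice_long`)."""
    ids = np.asarray(long.catalogue.ids, dtype=object)
    best = ids[long.best_items[np.arange(long.n_records), long.best_chosen]]
    worst = ids[
        long.worst_items[np.arange(long.n_records), long.worst_chosen]
    ]
    rid = long.respondent_ids
    stratum = (
        pd.Series(rid).map(dict(strata)).to_numpy(dtype=object)
        if strata is not None
        else np.full(long.n_records, "all", dtype=object)
    )
    df = pd.DataFrame(
        {
            "respondent_id": rid,
            "stratum": stratum,
            "task_id": long.task_ids,
            "best": best,
            "worst": worst,
        }
    )
    return ResponseSet(long.catalogue, design, df)


def read_responses(
    path: str | Path, design: Design, catalogue: ItemCatalogue
) -> ResponseSet:
    """Read and validate a responses CSV
    (``respondent_id,stratum,task_id,best,worst``)."""
    df = pd.read_csv(
        path,
        dtype={
            "respondent_id": str,
            "stratum": str,
            "best": str,
            "worst": str,
        },
    )
    missing = [c for c in RESPONSES_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseValidationError(
            f"responses CSV missing columns: {missing}"
        )
    df["task_id"] = df["task_id"].astype(int)
    return ResponseSet(catalogue, design, df[RESPONSES_COLUMNS])


def write_responses(responses: ResponseSet, path: str | Path) -> None:
    responses.responses[RESPONSES_COLUMNS].to_csv(path, index=False)


def write_table(result, out_path: str | Path) -> None:
    """Serialize a result table as CSV with stable column order.

    Accepts any object exposing a ``table`` DataFrame attribute (count,
    fit and comparison results) or a plain DataFrame.  Floats are
    written in shortest-exact form; reading back with
    ``pd.read_csv(..., float_precision="round_trip")`` returns
    identical values.
    """
    table = getattr(result, "table", result)
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(result).__name__} as a table")
    table.to_csv(out_path, index=False)
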