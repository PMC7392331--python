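"""Balanced best-worst scaling choice-task designs.

A BWS design assigns each of T choice tasks a subset of k items from a
catalogue of J items.  The designs built here are *frequency balanced*:
every item appears exactly r = T*k/J times across tasks, so every item
has the same number of opportunities to be chosen best or worst.  On top
of frequency balance, the generator minimizes the spread of pairwise
co-occurrence counts by a seeded greedy construction followed by a
pairwise swap descent, approximating the orthogonal main-effects designs
used in stated-preference surveys.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DesignConfigurationError(ValueError):
    """Raised when (J, k, T) cannot yield a frequency-balanced design."""


@dataclass(frozen=True)
class Item:
    """One catalogue entry: a stable id, display label, and optionally the
    item's share of the national budget (percent) for budget alignment."""

    item_id: str
    label: str
    budget_share_pct: float | None = None


@dataclass(frozen=True)
class ItemCatalogue:
    """Ordered item catalogue; the order is canonical for all coding."""

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if not ids:
            raise ValueError("catalogue must contain at least one item")
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        if any(not i for i in ids):
            raise ValueError("item_ids must be non-empty")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    def index(self, item_id: str) -> int:
        try:
            return self.ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item_id: {item_id!r}") from None

    def budget_shares(self) -> dict[str, float | None]:
        return {it.item_id: it.budget_share_pct for it in self.items}

    @classmethod
    def from_generic(cls, J: int) -> "ItemCatalogue":
        """A catalogue of J placeholder items (i01, i02, ...)."""
        width = len(str(J))
        return cls(
            tuple(
                Item(f"i{j + 1:0{width}d}", f"item {j + 1}") for j in range(J)
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemCatalogue":
        df = pd.read_csv(path, dtype={"item_id": str, "label": str})
        required = {"item_id", "label"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"catalogue CSV must have columns {sorted(required)}"
            )
        has_budget = "budget_share_pct" in df.columns
        items = []
        for row in df.itertuples(index=False):
            share = None
            if has_budget and pd.notna(row.budget_share_pct):
                share = float(row.budget_share_pct)
            items.append(Item(row.item_id, row.label, share))
        return cls(tuple(items))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "item_id": self.ids,
                "label": self.labels,
                "budget_share_pct": [it.budget_share_pct for it in self.items],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class Design:
    """T tasks of k item ids each, over the given catalogue."""

    catalogue: ItemCatalogue
    tasks: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("design must contain at least one task")
        k = len(self.tasks[0])
        for t, task in enumerate(self.tasks, start=1):
            if len(task) != k:
                raise ValueError(f"task {t} has {len(task)} items, expected {k}")
            if len(set(task)) != k:
                raise ValueError(f"task {t} contains duplicate items")
            for item in task:
                self.catalogue.index(item)  # raises KeyError if unknown

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def items_per_task(self) -> int:
        return len(self.tasks[0])

    @property
    def appearances_per_item(self) -> float:
        """r = T*k / J; integral for frequency-balanced designs."""
        return self.n_tasks * self.items_per_task / len(self.catalogue)

    def task_items(self, task_id: int) -> tuple[str, ...]:
        """Items of a 1-based task id."""
        return self.tasks[task_id - 1]

    def codes(self) -> np.ndarray:
        """(T, k) int array of catalogue indices."""
        idx = {iid: j for j, iid in enumerate(self.catalogue.ids)}
        return np.array([[idx[i] for i in task] for task in self.tasks])

    @classmethod
    def from_csv(cls, path: str | Path, catalogue: ItemCatalogue) -> "Design":
        df = pd.read_csv(path, dtype=str)
        item_cols = [c for c in df.columns if c.startswith("item_")]
        if "task_id" not in df.columns or not item_cols:
            raise ValueError(
                "design CSV must have columns task_id,item_1,...,item_k"
            )
        df = df.sort_values("task_id", key=lambda s: s.astype(int))
        tasks = tuple(
            tuple(row[c] for c in item_cols) for _, row in df.iterrows()
        )
        return cls(catalogue, tasks)

    def to_csv(self, path: str | Path) -> None:
        k = self.items_per_task
        cols = {"task_id": list(range(1, self.n_tasks + 1))}
        for j in range(k):
            cols[f"item_{j + 1}"] = [task[j] for task in self.tasks]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class DesignDiagnostics:
    """Tallied balance diagnostics for a design (report, not enforcement)."""

    appearance_counts: pd.Series  # item_id -> count
    cooccurrence: pd.DataFrame  # J x J symmetric, zero diagonal
    positional_frequency: pd.DataFrame  # item x within-task position
    frequency_balanced: bool
    cooccurrence_min: int = field(init=False)
    cooccurrence_max: int = field(init=False)
    cooccurrence_range: int = field(init=False)

    def __post_init__(self) -> None:
        off = _offdiag(self.cooccurrence.to_numpy())
        self.cooccurrence_min = int(off.min())
        self.cooccurrence_max = int(off.max())
        self.cooccurrence_range = int(off.max() - off.min())


def _offdiag(mat: np.ndarray) -> np.ndarray:
    return mat[~np.eye(mat.shape[0], dtype=bool)]


def _cooccurrence(codes: np.ndarray, J: int) -> np.ndarray:
    C = np.zeros((J, J), dtype=int)
    for task in codes:
        for a, b in itertools.combinations(task, 2):
            C[a, b] += 1
            C[b, a] += 1
    return C


def _greedy_fill(J: int, k: int, T: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded greedy construction of a frequency-balanced (T, k) code array.

    Items with the most appearances still owed are placed first (at most k
    items can be owed as many appearances as there are tasks left, so this
    rule can never strand an item); among those, items that co-occur least
    with the task so far are preferred, random tie-break, then item order.
    """
    r = T * k // J
    remaining = np.full(J, r, dtype=int)
    C = np.zeros((J, J), dtype=int)
    tasks = np.empty((T, k), dtype=int)
    for t in range(T):
        tiebreak = rng.permutation(J)
        chosen: list[int] = []
        for _ in range(k):
            best_item = -1
            best_key = None
            for j in range(J):
                if remaining[j] == 0 or j in chosen:
                    continue
                cooc = int(C[j, chosen].sum()) if chosen else 0
                key = (-remaining[j], cooc, tiebreak[j], j)
                if best_key is None or key < best_key:
                    best_key = key
                    best_item = j
            chosen.append(best_item)
            remaining[best_item] -= 1
        chosen_sorted = sorted(chosen)  # canonical catalogue order in task
        for a, b in itertools.combinations(chosen_sorted, 2):
            C[a, b] += 1
            C[b, a] += 1
        tasks[t] = chosen_sorted
    return tasks


def _swap_descent(codes: np.ndarray, J: int) -> np.ndarray:
    """First-improvement pairwise swap descent on the co-occurrence range.

    Swapping one item between two tasks preserves appearance counts.  A
    swap is accepted iff it strictly reduces (range, sum of squares) of
    the off-diagonal co-occurrence counts, so descent terminates.
    """
    codes = codes.copy()
    T = codes.shape[0]
    C = _cooccurrence(codes, J)

    def objective(mat: np.ndarray) -> tuple[int, int]:
        off = _offdiag(mat)
        return int(off.max() - off.min()), int((off**2).sum())

    current = objective(C)
    improved = True
    while improved:
        improved = False
        for t1 in range(T):
            for t2 in range(t1 + 1, T):
                s1, s2 = set(codes[t1]), set(codes[t2])
                for a in sorted(s1 - s2):
                    for b in sorted(s2 - s1):
                        # tentatively swap a (task t1) with b (task t2)
                        for x, others, sign in (
                            (a, s1 - {a}, -1),
                            (b, s1 - {a}, +1),
                            (b, s2 - {b}, -1),
                            (a, s2 - {b}, +1),
                        ):
                            for o in others:
                                C[x, o] += sign
                                C[o, x] += sign
                        cand = objective(C)
                        if cand < current:
                            codes[t1] = sorted((s1 - {a}) | {b})
                            codes[t2] = sorted((s2 - {b}) | {a})
                            current = cand
                            improved = True
                            break
                        # revert
                        for x, others, sign in (
                            (a, s1 - {a}, +1),
                            (b, s1 - {a}, -1),
                            (b, s2 - {b}, +1),
                            (a, s2 - {b}, -1),
                        ):
                            for o in others:
                                C[x, o] += sign
                                C[o, x] += sign
                    if improved:
                        break
                if improved:
                    break
            if improved:
                break
    return codes


def generate_design(
    items: ItemCatalogue | Sequence[str] | int,
    k: int,
    T: int,
    seed: int = 0,
) -> Design:
    """Generate a frequency-balanced design of T tasks of k items.

    Parameters
    ----------
    items
        Catalogue, sequence of item ids, or item count J (generic ids).
    k
        Items shown per choice task (4 in the budget-sector survey).
    T
        Number of choice tasks (16 in the budget-sector survey).
    seed
        Seeds the greedy tie-break; the result is deterministic given
        (items, k, T, seed).

    Raises
    ------
    DesignConfigurationError
        If k > J, k < 2, or T*k is not divisible by J (exact balance is
        then impossible).
    """
    if isinstance(items, int):
        catalogue = ItemCatalogue.from_generic(items)
    elif isinstance(items, ItemCatalogue):
        catalogue = items
    else:
        catalogue = ItemCatalogue(tuple(Item(i, i) for i in items))
    J = len(catalogue)
    if k < 2 or k > J:
        raise DesignConfigurationError(
            f"need 2 <= k <= J, got k={k}, J={J}"
        )
    if (T * k) % J != 0:
        raise DesignConfigurationError(
            f"T*k must be divisible by J for equal appearances: "
            f"T={T}, k={k}, J={J}, T*k={T * k}"
        )
    rng = np.random.default_rng(seed)
    codes = _greedy_fill(J, k, T, rng)
    codes = _swap_descent(codes, J)
    ids = catalogue.ids
    tasks = tuple(tuple(ids[j] for j in task) for task in codes)
    return Design(catalogue, tasks)


def validate_design(design: Design) -> DesignDiagnostics:
    """Tally appearance counts, co-occurrences and positional frequencies.

    ``frequency_balanced`` is True iff every item appears exactly
    r = T*k/J times.  For a frequency-balanced design each co-occurrence
    row sums to r*(k-1).
    """
    J = len(design.catalogue)
    k = design.items_per_task
    codes = design.codes()
    counts = np.bincount(codes.ravel(), minlength=J)
    C = _cooccurrence(codes, J)
    pos = np.zeros((J, k), dtype=int)
    for task in codes:
        for p, j in enumerate(task):
            pos[j, p] += 1
    ids = design.catalogue.ids
    r = design.appearances_per_item
    return DesignDiagnostics(
        appearance_counts=pd.Series(counts, index=ids, name="appearances"),
        cooccurrence=pd.DataFrame(C, index=ids, columns=ids),
        positional_frequency=pd.DataFrame(
            pos, index=ids, columns=[f"pos_{p + 1}" for p in range(k)]
        ),
        frequency_balanced=bool(
            float(r).is_integer() and np.all(counts == int(r))
        ),
    )
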