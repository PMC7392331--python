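"""Simulate best-worst responses under the sequential choice model.

Each respondent carries a latent utility v_j per item (stratum mean
plus optional independent normal heterogeneity).  Within a task with
item set S the best item is drawn with probability softmax(v) over S,
and the worst from S minus the best with probability softmax(-v) —
the exact generative counterpart of the sequential conditional logit
fitted by :mod:`bwspref.clogit`, so parameter recovery on simulated
data is a direct test of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ResponseSet
from .design import Design, ItemCatalogue


@dataclass
class Stratum:
    """A respondent subgroup with its mean utility vector."""

    label: str
    n: int
    utilities: np.ndarray  # length J, one mean utility per catalogue item

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, dtype=float)
        if self.n < 0:
            raise ValueError(f"stratum {self.label!r}: n must be >= 0")
        if not np.all(np.isfinite(self.utilities)):
            raise ValueError(f"stratum {self.label!r}: utilities must be finite")


@dataclass
class SimulationScenario:
    """Design, strata and heterogeneity for one simulated survey.

    Utilities are identified only up to an additive constant; the
    simulator centers each stratum's vector to sum to zero before use,
    mirroring effects-coding identification, so simulated truth is
    directly comparable to fitted estimates.
    """

    catalogue: ItemCatalogue
    design: Design
    strata: list[Stratum]
    heterogeneity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        J = len(self.catalogue)
        for s in self.strata:
            if len(s.utilities) != J:
                raise ValueError(
                    f"stratum {s.label!r}: expected {J} utilities, "
                    f"got {len(s.utilities)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationScenario":
        """Load a scenario file: catalogue/design CSV paths, strata
        (label, n, utilities), sigma, seed; relative paths resolve
        against the scenario file's directory."""
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent
        catalogue = ItemCatalogue.from_csv(base / cfg["catalogue"])
        design = Design.from_csv(base / cfg["design"], catalogue)
        strata = [
            Stratum(s["label"], int(s["n"]), np.asarray(s["utilities"], float))
            for s in cfg["strata"]
        ]
        return cls(
            catalogue=catalogue,
            design=design,
            strata=strata,
            heterogeneity_sd=float(cfg.get("sigma", 0.0)),
            seed=int(cfg.get("seed", 0)),
        )


def _simulate_one(
    v: np.ndarray, codes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Best/worst catalogue codes for one respondent across all tasks."""
    U = v[codes]  # (T, k)
    # best: softmax(U) row-wise, inverse-CDF sampling
    P = np.exp(U - U.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    u1 = rng.random(len(codes))
    b_pos = (P.cumsum(axis=1) < u1[:, None]).sum(axis=1)
    b_pos = np.minimum(b_pos, codes.shape[1] - 1)
    # worst: softmax(-U) over remaining items
    Q = np.exp(-(U - U.min(axis=1, keepdims=True)))
    Q[np.arange(len(codes)), b_pos] = 0.0
    Q /= Q.sum(axis=1, keepdims=True)
    u2 = rng.random(len(codes))
    w_pos = (Q.cumsum(axis=1) < u2[:, None]).sum(axis=1)
    w_pos = np.minimum(w_pos, codes.shape[1] - 1)
    rows = np.arange(len(codes))
    return codes[rows, b_pos], codes[rows, w_pos]


def simulate_choice_arrays(
    scenario: SimulationScenario,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate and return (respondent frame, best codes, worst codes).

    The respondent frame has one row per respondent (respondent_id,
    stratum); the code arrays are (n_respondents, T) catalogue indices.
    Each respondent consumes an independent child seed sequence, so the
    output is reproducible and unaffected by stratum reordering of other
    respondents.
    """
    codes = scenario.design.codes()
    T = scenario.design.n_tasks
    total = sum(s.n for s in scenario.strata)
    streams = np.random.SeedSequence(scenario.seed).spawn(total)
    best = np.empty((total, T), dtype=int)
    worst = np.empty((total, T), dtype=int)
    rows = []
    i = 0
    for stratum in scenario.strata:
        v0 = stratum.utilities - stratum.utilities.mean()
        for j in range(stratum.n):
            rng = np.random.default_rng(streams[i])
            v = v0
            if scenario.heterogeneity_sd > 0:
                v = v0 + rng.normal(0, scenario.heterogeneity_sd, len(v0))
            best[i], worst[i] = _simulate_one(v, codes, rng)
            rows.append((f"{stratum.label}-{j + 1:04d}", stratum.label))
            i += 1
    frame = pd.DataFrame(rows, columns=["respondent_id", "stratum"])
    return frame, best, worst


def simulate_responses(scenario: SimulationScenario) -> ResponseSet:
    """Simulate a complete ResponseSet (every respondent, every task)."""
    frame, best, worst = simulate_choice_arrays(scenario)
    T = scenario.design.n_tasks
    n = len(frame)
    ids = np.asarray(scenario.catalogue.ids, dtype=object)
    df = pd.DataFrame(
        {
            "respondent_id": np.repeat(
                frame["respondent_id"].to_numpy(dtype=object), T
            ),
            "stratum": np.repeat(frame["stratum"].to_numpy(dtype=object), T),
            "task_id": np.tile(np.arange(1, T + 1), n),
            "best": ids[best.ravel()],
            "worst": ids[worst.ravel()],
        }
    )
    return ResponseSet(scenario.catalogue, scenario.design, df)
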