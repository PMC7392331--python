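"""Published constants from the Uganda budget-sector BWS survey.

A 2017 survey of 432 households (217 urban, 215 rural) in Mukono
district elicited preferences over the 16 Uganda national-budget
sectors: 16 choice tasks of 4 sectors each, one best and one worst
choice per task.  This module packages the published per-sector tallies
(overall and by stratum), the published conditional-logit estimates,
and the 2017-18 national-budget shares and ranks quoted for a subset of
sectors — everything needed to reproduce the published score tables and
the preference-vs-budget comparison without the raw survey data.  Only
printed values are packaged; nothing is fabricated for unprinted cells
(those are None/NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Item, ItemCatalogue

N_OVERALL = 432
N_URBAN = 217
N_RURAL = 215
APPEARANCES_PER_RESPONDENT = 4  # each sector appears in 4 of the 16 tasks
N_TASKS = 16
ITEMS_PER_TASK = 4

# (item_id, label, published 2017-18 budget share %, published budget rank)
# Budget shares/ranks were quoted for 9 of the 16 sectors; the rest are None.
_SECTORS: list[tuple[str, str, float | None, int | None]] = [
    ("health", "Health", 6.4, 6),
    ("water_env", "Water and Environment", 4.6, 10),
    ("education", "Education", 21.3, 2),
    ("agriculture", "Agriculture", 6.1, 7),
    ("works_transport", "Works and Transport", 22.1, 1),
    ("social_dev", "Social Development", 1.5, 11),
    ("security", "Security", 10.0, 3),
    ("energy_mineral", "Energy and Mineral Development", None, None),
    ("public_sector_mgmt", "Public Sector Management", None, None),
    ("accountability", "Accountability", None, None),
    ("justice_law_order", "Justice, Law, and Order", 7.2, 4),
    ("ict", "Information and Communication Technology", 0.3, 16),
    ("lands_housing", "Lands, Housing, and Urban Development", None, None),
    ("tourism_trade", "Tourism, Trade, and Industry", None, None),
    ("public_admin", "Public Administration", None, None),
    ("legislature", "Legislature", None, None),
]

#: The 16 sectors in the survey's canonical enumeration order.
CATALOGUE = ItemCatalogue(
    tuple(Item(i, lab, share) for i, lab, share, _ in _SECTORS)
)

#: Published national-budget rank where quoted (1 = largest share).
BUDGET_RANKS: dict[str, int] = {
    i: rank for i, _, _, rank in _SECTORS if rank is not None
}

#: Published national-budget share (%) where quoted.
BUDGET_SHARES: dict[str, float] = {
    i: share for i, _, share, _ in _SECTORS if share is not None
}

# Published best/worst tallies: item_id -> (Best, Worst).
OVERALL_COUNTS: dict[str, tuple[int, int]] = {
    "health": (1417, 45),
    "water_env": (1025, 169),
    "education": (903, 128),
    "agriculture": (903, 218),
    "works_transport": (608, 244),
    "social_dev": (649, 326),
    "security": (502, 312),
    "energy_mineral": (159, 388),
    "public_sector_mgmt": (154, 470),
    "accountability": (133, 508),
    "justice_law_order": (65, 494),
    "ict": (166, 608),
    "lands_housing": (68, 589),
    "tourism_trade": (59, 609),
    "public_admin": (46, 871),
    "legislature": (55, 933),
}

URBAN_COUNTS: dict[str, tuple[int, int]] = {
    "health": (744, 17),
    "water_env": (515, 84),
    "education": (457, 51),
    "agriculture": (433, 92),
    "social_dev": (341, 164),
    "works_transport": (283, 125),
    "security": (249, 164),
    "energy_mineral": (80, 168),
    "public_sector_mgmt": (87, 244),
    "accountability": (69, 254),
    "ict": (83, 268),
    "justice_law_order": (38, 240),
    "lands_housing": (34, 285),
    "tourism_trade": (32, 292),
    "public_admin": (13, 485),
    "legislature": (14, 539),
}

RURAL_COUNTS: dict[str, tuple[int, int]] = {
    "health": (673, 28),
    "water_env": (510, 85),
    "education": (446, 77),
    "agriculture": (470, 126),
    "social_dev": (308, 162),
    "works_transport": (325, 119),
    "security": (253, 148),
    "energy_mineral": (79, 220),
    "public_sector_mgmt": (67, 226),
    "accountability": (64, 254),
    "ict": (83, 340),
    "justice_law_order": (27, 254),
    "lands_housing": (34, 304),
    "tourism_trade": (27, 317),
    "public_admin": (33, 386),
    "legislature": (41, 394),
}

# Published mean best-worst scores as printed (3 dp), overall sample,
# in the published row order (which is also descending-score order).
PUBLISHED_OVERALL_SCORES: dict[str, float] = {
    "health": 0.793,
    "water_env": 0.495,
    "education": 0.448,
    "agriculture": 0.396,
    "works_transport": 0.210,
    "social_dev": 0.186,
    "security": 0.109,
    "energy_mineral": -0.132,
    "public_sector_mgmt": -0.182,
    "accountability": -0.217,
    "justice_law_order": -0.248,
    "ict": -0.255,
    "lands_housing": -0.301,
    "tourism_trade": -0.318,
    "public_admin": -0.477,
    "legislature": -0.508,
}

PUBLISHED_URBAN_SCORES: dict[str, float] = {
    "health": 0.837,
    "water_env": 0.496,
    "education": 0.467,
    "agriculture": 0.392,
    "social_dev": 0.203,
    "works_transport": 0.182,
    "security": 0.097,
    "energy_mineral": -0.101,
    "public_sector_mgmt": -0.180,
    "accountability": -0.213,
    "ict": -0.213,
    "justice_law_order": -0.232,
    "lands_housing": -0.289,
    "tourism_trade": -0.299,
    "public_admin": -0.543,
    "legislature": -0.604,
}

PUBLISHED_RURAL_SCORES: dict[str, float] = {
    "health": 0.750,
    "water_env": 0.494,
    "education": 0.429,
    "agriculture": 0.400,
    "social_dev": 0.169,
    "works_transport": 0.239,
    "security": 0.122,
    "energy_mineral": -0.163,
    "public_sector_mgmt": -0.184,
    "accountability": -0.220,
    "ict": -0.298,
    "justice_law_order": -0.263,
    "lands_housing": -0.313,
    "tourism_trade": -0.337,
    "public_admin": -0.410,
    "legislature": -0.410,
}

# Published sequential conditional-logit estimates (utility units) and
# their standard errors, by sample.  Reproducing these exact numbers
# requires the study's raw choice data; here they serve as reference
# values and as the true utilities for parameter-recovery simulations.
CLOGIT_ESTIMATES: dict[str, dict[str, tuple[float, float]]] = {
    "overall": {
        "health": (3.027, 0.064),
        "education": (1.831, 0.053),
        "agriculture": (1.686, 0.056),
        "water_env": (1.611, 0.054),
        "works_transport": (1.256, 0.056),
        "social_dev": (1.100, 0.054),
        "security": (0.556, 0.056),
        "energy_mineral": (-0.587, 0.083),
        "ict": (-0.731, 0.084),
        "public_sector_mgmt": (-0.980, 0.084),
        "accountability": (-0.993, 0.090),
        "justice_law_order": (-1.336, 0.121),
        "lands_housing": (-1.471, 0.119),
        "tourism_trade": (-1.600, 0.127),
        "legislature": (-1.655, 0.131),
        "public_admin": (-1.713, 0.143),
    },
    "urban": {
        "health": (3.333, 0.099),
        "education": (1.907, 0.077),
        "agriculture": (1.656, 0.080),
        "water_env": (1.643, 0.078),
        "social_dev": (1.183, 0.078),
        "works_transport": (1.165, 0.081),
        "security": (0.569, 0.082),
        "energy_mineral": (-0.523, 0.116),
        "ict": (-0.661, 0.120),
        "public_sector_mgmt": (-0.815, 0.114),
        "accountability": (-0.911, 0.127),
        "justice_law_order": (-1.164, 0.160),
        "lands_housing": (-1.412, 0.169),
        "tourism_trade": (-1.449, 0.174),
        "public_admin": (-2.228, 0.265),
        "legislature": (-2.293, 0.254),
    },
    "rural": {
        "health": (2.822, 0.083),
        "education": (1.802, 0.071),
        "agriculture": (1.766, 0.071),
        "water_env": (1.605, 0.070),
        "works_transport": (1.354, 0.073),
        "social_dev": (1.057, 0.072),
        "security": (0.540, 0.076),
        "energy_mineral": (-0.605, 0.112),
        "ict": (-0.724, 0.114),
        "accountability": (-1.064, 0.125),
        "public_sector_mgmt": (-1.164, 0.123),
        "legislature": (-1.308, 0.153),
        "public_admin": (-1.357, 0.169),
        "lands_housing": (-1.473, 0.185),
        "justice_law_order": (-1.530, 0.166),
        "tourism_trade": (-1.720, 0.185),
    },
}


def counts_frame(sample: str = "overall") -> pd.DataFrame:
    """Published (best, worst) tallies as a DataFrame in catalogue order."""
    src = {
        "overall": OVERALL_COUNTS,
        "urban": URBAN_COUNTS,
        "rural": RURAL_COUNTS,
    }[sample]
    return pd.DataFrame(
        [src[i] for i in CATALOGUE.ids],
        index=pd.Index(CATALOGUE.ids, name="item_id"),
        columns=["best", "worst"],
    )


def sample_size(sample: str = "overall") -> int:
    return {"overall": N_OVERALL, "urban": N_URBAN, "rural": N_RURAL}[sample]


def clogit_utilities(sample: str = "overall") -> np.ndarray:
    """Published logit estimates as a centered utility vector in
    catalogue order (the natural truth for recovery simulations)."""
    est = CLOGIT_ESTIMATES[sample]
    v = np.array([est[i][0] for i in CATALOGUE.ids])
    return v - v.mean()


def label_map() -> dict[str, str]:
    return dict(zip(CATALOGUE.ids, CATALOGUE.labels))
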