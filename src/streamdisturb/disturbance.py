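"""Human-disturbance scoring for stream sites.

Three indices summarise human pressure on a sampled stream reach:

* **LDI** (Local Disturbance Index) — a proximity-weighted tally, in the
  W1_hall style, of eleven categories of human disturbance observed along
  in-stream transects and the riparian zone.
* **CDI** (Catchment Disturbance Index) — a weighted sum of catchment
  land-use percentages, ``4 * %urban + 2 * %(agriculture+pasture)``,
  ranging 0 (no human land use) to 400 (catchment fully urbanised).
* **IDI** (Integrated Disturbance Index) — the Euclidean combination of
  the normalised local and catchment indices, used to classify sites into
  low / medium / high disturbance levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DISTURBANCE_CATEGORIES",
    "PROXIMITY_CODES",
    "ProximityWeights",
    "LandUseProfile",
    "DisturbanceLevel",
    "DisturbanceScores",
    "compute_ldi",
    "compute_cdi",
    "compute_idi",
    "classify_disturbance",
    "score_sites",
]

#: The eleven disturbance categories tallied for the LDI.
DISTURBANCE_CATEGORIES: tuple[str, ...] = (
    "buildings",
    "channel_revetment",
    "pavement",
    "roads",
    "pipes",
    "trash_landfill",
    "parks_lawns",
    "row_crop_agriculture",
    "pasture",
    "logging",
    "mining",
)

#: Proximity codes: 0 = absent, B = in channel/margin, C = < 10 m, P = > 10 m.
PROXIMITY_CODES: tuple[str, ...] = ("0", "B", "C", "P")

DEFAULT_N_TRANSECTS = 5


@dataclass(frozen=True)
class ProximityWeights:
    """Weights applied to the proximity codes when accumulating the LDI.

    Closer disturbance weighs more: ``w_B >= w_C >= w_P >= 0``.
    """

    w_B: float = 1.5
    w_C: float = 1.0
    w_P: float = 0.667

    def __post_init__(self) -> None:
        if not (self.w_B >= self.w_C >= self.w_P >= 0):
            raise ValueError(
                "proximity weights must satisfy w_B >= w_C >= w_P >= 0, got "
                f"w_B={self.w_B}, w_C={self.w_C}, w_P={self.w_P}"
            )

    def as_mapping(self) -> dict[str, float]:
        return {"0": 0.0, "B": self.w_B, "C": self.w_C, "P": self.w_P}


@dataclass(frozen=True)
class LandUseProfile:
    """Catchment land-use/cover composition, in percent of catchment area.

    ``agri_pasture_pct`` pools agriculture, pasture and silviculture.  The
    three classes need not sum to 100 (other cover classes may exist) but
    may not exceed it beyond rounding tolerance.
    """

    urban_pct: float
    agri_pasture_pct: float
    forest_pct: float = 0.0

    _SUM_TOL = 0.5  # rounding slack on percentages summing past 100

    def __post_init__(self) -> None:
        for name in ("urban_pct", "agri_pasture_pct", "forest_pct"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or v > 100:
                raise ValueError(f"{name} must be in [0, 100], got {v!r}")
        total = self.urban_pct + self.agri_pasture_pct + self.forest_pct
        if total > 100 + self._SUM_TOL:
            raise ValueError(
                f"land-use percentages sum to {total:.2f} > 100"
            )


class DisturbanceLevel(str, Enum):
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


@dataclass(frozen=True)
class DisturbanceScores:
    """Bundle of the three indices for one site."""

    ldi: float
    cdi: float
    idi: float
    idi_clamped: float
    level: DisturbanceLevel


def _coerce_tally(grid) -> np.ndarray:
    """Return an (n_categories, n_transects) array of proximity codes.

    Accepts a DataFrame (rows = categories), a nested sequence, or an object
    array.  Missing cells (None / NaN / empty string) are treated as absent
    with a warning, since the field protocol records presence only.
    """
    if isinstance(grid, pd.DataFrame):
        arr = grid.to_numpy(dtype=object)
    else:
        arr = np.asarray(grid, dtype=object)
    if arr.ndim != 2:
        raise ValueError(f"tally grid must be 2-D, got shape {arr.shape}")
    out = np.empty(arr.shape, dtype=object)
    n_missing = 0
    for idx, cell in np.ndenumerate(arr):
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            n_missing += 1
            out[idx] = "0"
            continue
        code = str(cell).strip().upper()
        if code in ("", "NAN"):
            n_missing += 1
            code = "0"
        if code not in PROXIMITY_CODES:
            raise ValueError(
                f"unknown proximity code {cell!r} at category row {idx[0]}, "
                f"transect {idx[1]} (expected one of {PROXIMITY_CODES})"
            )
        out[idx] = code
    if n_missing:
        warnings.warn(
            f"{n_missing} missing tally cell(s) treated as absent",
            stacklevel=3,
        )
    return out


def compute_ldi(tally, weights: ProximityWeights | None = None) -> float:
    """Local Disturbance Index for one site.

    Parameters
    ----------
    tally
        Grid of proximity codes, one row per disturbance category (11 in the
        field protocol) and one column per transect (5 in the protocol).
    weights
        Proximity weighting; defaults to the W1_hall convention
        (B=1.5, C=1.0, P=0.667).

    Returns
    -------
    float
        Sum over categories of the transect-mean code weight.  Zero iff no
        disturbance was recorded anywhere.
    """
    weights = weights or ProximityWeights()
    grid = _coerce_tally(tally)
    n_cat, n_transects = grid.shape
    if n_cat != len(DISTURBANCE_CATEGORIES):
        raise ValueError(
            f"expected {len(DISTURBANCE_CATEGORIES)} disturbance categories, "
            f"got {n_cat}"
        )
    if n_transects < 1:
        raise ValueError("tally must cover at least one transect")
    wmap = weights.as_mapping()
    numeric = np.vectorize(wmap.__getitem__, otypes=[float])(grid)
    return float(numeric.mean(axis=1).sum())


def compute_cdi(land_use: LandUseProfile | None = None, *,
                urban_pct: float | None = None,
                agri_pasture_pct: float | None = None) -> float:
    """Catchment Disturbance Index: ``4 * %urban + 2 * %(agri+pasture)``."""
    if land_use is None:
        land_use = LandUseProfile(urban_pct=float(urban_pct),
                                  agri_pasture_pct=float(agri_pasture_pct))
    return 4.0 * land_use.urban_pct + 2.0 * land_use.agri_pasture_pct


#: Normalisation variants for the IDI.  ``printed`` follows the published
#: formula (LDI/5, CDI/300) literally, in which case the raw index can exceed
#: 1 (CDI reaches 400); ``cdi400_rescaled`` divides CDI by its true maximum
#: and rescales by sqrt(2) so the index is bounded in [0, 1].
IDI_VARIANTS = ("printed", "cdi400_rescaled")


def compute_idi(
    ldi: float,
    cdi: float,
    *,
    variant: str = "printed",
    thresholds: tuple[float, float] = (0.10, 0.20),
) -> DisturbanceScores:
    """Integrated Disturbance Index from the local and catchment indices.

    ``printed`` variant: ``IDI = sqrt((LDI/5)^2 + (CDI/300)^2)``.
    ``cdi400_rescaled`` variant: ``sqrt((LDI/5)^2 + (CDI/400)^2) / sqrt(2)``.

    Both the raw value and a [0, 1]-clamped value are reported; the level is
    classified from the raw value.
    """
    ldi = float(ldi)
    cdi = float(cdi)
    if ldi < 0:
        raise ValueError(f"LDI must be non-negative, got {ldi}")
    if not 0 <= cdi <= 400:
        raise ValueError(f"CDI must be in [0, 400], got {cdi}")
    if variant == "printed":
        idi = math.hypot(ldi / 5.0, cdi / 300.0)
    elif variant == "cdi400_rescaled":
        idi = math.hypot(ldi / 5.0, cdi / 400.0) / math.sqrt(2.0)
    else:
        raise ValueError(f"unknown IDI variant {variant!r}; use one of {IDI_VARIANTS}")
    return DisturbanceScores(
        ldi=ldi,
        cdi=cdi,
        idi=idi,
        idi_clamped=min(idi, 1.0),
        level=classify_disturbance(idi, thresholds=thresholds),
    )


def classify_disturbance(
    idi: float, thresholds: tuple[float, float] = (0.10, 0.20)
) -> DisturbanceLevel:
    """Three-level disturbance class from the IDI.

    LOW for ``idi < thresholds[0]``, MEDIUM for
    ``thresholds[0] <= idi < thresholds[1]``, HIGH otherwise.  The default
    bounds (0.10, 0.20) close the gaps left by the published "< 0.09 /
    0.10–0.19 / > 0.2" wording so that every non-negative value classifies.
    """
    idi = float(idi)
    if idi < 0:
        raise ValueError(f"IDI must be non-negative, got {idi}")
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError(f"thresholds must satisfy 0 < low < high, got {thresholds}")
    if idi < lo:
        return DisturbanceLevel.LOW
    if idi < hi:
        return DisturbanceLevel.MEDIUM
    return DisturbanceLevel.HIGH


def score_sites(
    tallies: pd.DataFrame,
    land_use: pd.DataFrame,
    *,
    weights: ProximityWeights | None = None,
    variant: str = "printed",
    thresholds: tuple[float, float] = (0.10, 0.20),
) -> pd.DataFrame:
    """Score every site: LDI, CDI, IDI (raw and clamped) and level.

    Parameters
    ----------
    tallies
        Long-format tally table: columns ``site_id``, ``category`` and one
        column per transect holding proximity codes.
    land_use
        Site table with columns ``site_id``, ``urban_pct``,
        ``agri_pasture_pct`` and optionally ``forest_pct``.

    Returns
    -------
    DataFrame indexed by site_id with columns ldi, cdi, idi, idi_clamped,
    level.
    """
    required = {"site_id", "category"}
    if not required.issubset(tallies.columns):
        raise ValueError(f"tally table must have columns {sorted(required)}")
    transect_cols = [c for c in tallies.columns if c not in required]
    if not transect_cols:
        raise ValueError("tally table has no transect columns")
    lu = land_use.set_index("site_id")
    rows = []
    for site, sub in tallies.groupby("site_id", sort=True):
        grid = (
            sub.set_index("category")
            .reindex(DISTURBANCE_CATEGORIES)[transect_cols]
        )
        if grid.isna().all(axis=1).any():
            missing = grid.index[grid.isna().all(axis=1)].tolist()
            raise ValueError(f"site {site}: missing tally categories {missing}")
        ldi = compute_ldi(grid, weights)
        if site not in lu.index:
            raise ValueError(f"site {site} has tallies but no land-use row")
        profile = LandUseProfile(
            urban_pct=float(lu.loc[site, "urban_pct"]),
            agri_pasture_pct=float(lu.loc[site, "agri_pasture_pct"]),
            forest_pct=float(lu.loc[site].get("forest_pct", 0.0)),
        )
        scores = compute_idi(
            ldi, compute_cdi(profile), variant=variant, thresholds=thresholds
        )
        rows.append(
            {
                "site_id": site,
                "ldi": scores.ldi,
                "cdi": scores.cdi,
                "idi": scores.idi,
                "idi_clamped": scores.idi_clamped,
                "level": scores.level.value,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")
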