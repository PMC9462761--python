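"""Rapid Habitat Diversity Assessment (RHDA) scoring.

The RHDA is a 22-parameter visual bioassessment protocol: the first ten
parameters rate signs of human pressure in the reach, the remaining twelve
rate environmental characteristics of the site.  The per-site habitat
diversity score is the total across parameters, averaged over observers
when more than one sheet was filled for a site.

Per-parameter score ranges are configurable; the shipped default scores
every parameter 0-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["RHDAConfig", "RHDASheet", "HabitatScore", "validate_sheet", "score_rhda"]

N_PARAMETERS = 22


@dataclass(frozen=True)
class RHDAConfig:
    """Per-parameter maxima and labels for the 22 RHDA parameters."""

    param_max: tuple[float, ...] = (5.0,) * N_PARAMETERS
    labels: tuple[str, ...] = tuple(
        [f"human_pressure_{i:02d}" for i in range(1, 11)]
        + [f"environmental_{i:02d}" for i in range(11, 23)]
    )

    def __post_init__(self) -> None:
        if len(self.param_max) != N_PARAMETERS:
            raise ValueError(
                f"config must define {N_PARAMETERS} parameter maxima, "
                f"got {len(self.param_max)}"
            )
        if len(self.labels) != N_PARAMETERS:
            raise ValueError(f"config must define {N_PARAMETERS} labels")
        if any(m <= 0 for m in self.param_max):
            raise ValueError("every parameter maximum must be positive")

    @property
    def total_max(self) -> float:
        return float(sum(self.param_max))


@dataclass(frozen=True)
class RHDASheet:
    """One observer's filled protocol sheet for one site."""

    scores: tuple[float, ...]
    observer_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))


@dataclass(frozen=True)
class HabitatScore:
    """Per-site habitat-diversity total (observer mean of sheet totals)."""

    total: float
    n_observers: int


def validate_sheet(sheet: RHDASheet, config: RHDAConfig | None = None) -> list[str]:
    """Return the list of invariant violations for a sheet (empty iff valid).

    The validator reports, never raises: each violation names the parameter
    index (1-based, matching the field sheet) and the reason.
    """
    config = config or RHDAConfig()
    violations: list[str] = []
    if len(sheet.scores) != N_PARAMETERS:
        violations.append(
            f"expected {N_PARAMETERS} parameters, got {len(sheet.scores)}"
        )
        return violations
    for i, (score, mx, label) in enumerate(
        zip(sheet.scores, config.param_max, config.labels), start=1
    ):
        if not np.isfinite(score):
            violations.append(f"parameter {i} ({label}): non-finite score {score!r}")
        elif score < 0:
            violations.append(f"parameter {i} ({label}): negative score {score}")
        elif score > mx:
            violations.append(
                f"parameter {i} ({label}): score {score} exceeds maximum {mx}"
            )
    return violations


def score_rhda(
    sheets: Sequence[RHDASheet], config: RHDAConfig | None = None
) -> HabitatScore:
    """Habitat-diversity score for one site from one or more observer sheets.

    Each sheet's total is the sum of its 22 parameter scores; the site score
    is the arithmetic mean across observers (so multi-observer sites can have
    fractional totals).
    """
    config = config or RHDAConfig()
    if len(sheets) == 0:
        raise ValueError("at least one RHDA sheet is required")
    totals = []
    for k, sheet in enumerate(sheets):
        violations = validate_sheet(sheet, config)
        if violations:
            who = sheet.observer_id or f"sheet {k}"
            raise ValueError(f"invalid RHDA sheet ({who}): " + "; ".join(violations))
        totals.append(sum(sheet.scores))
    return HabitatScore(total=float(np.mean(totals)), n_observers=len(sheets))
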