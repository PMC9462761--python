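"""Assemblage-structure metrics.

Per-site diversity structure (richness, abundance, Shannon H, Simpson
dominance, Pielou/Joule equitability, non-native:native abundance ratio)
and the per-species occupancy-based restrictedness rarity metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityProfile",
    "diversity_profile",
    "diversity_table",
    "restrictedness",
    "validate_abundance",
]


@dataclass(frozen=True)
class DiversityProfile:
    """Diversity structure of one site's assemblage.

    ``equitability`` is undefined (None) for a single-species assemblage;
    ``nnabu`` is undefined when no native individuals occur.  Shannon H is
    reported in nats by default.
    """

    richness: int
    abundance: int
    shannon: float
    simpson_dominance: float
    equitability: float | None
    nnabu: float | None


def validate_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a site x species abundance matrix and return it as integers."""
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("abundance matrix needs at least one site and one species")
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate site ids: {dups}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValueError(f"duplicate species ids: {dups}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("abundance matrix must be numeric")
    if not np.isfinite(values).all():
        raise ValueError("abundance matrix contains non-finite cells")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at site {matrix.index[i]!r}, "
            f"species {matrix.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"fractional count at site {matrix.index[i]!r}, "
            f"species {matrix.columns[j]!r}"
        )
    return matrix.astype(int)


def diversity_profile(
    counts,
    origin=None,
    *,
    log_base: float = math.e,
) -> DiversityProfile:
    """Diversity profile of a single site.

    Parameters
    ----------
    counts
        One site's species counts (Series or 1-D array), non-negative.
    origin
        Optional per-species origin labels (``"NATIVE"`` / ``"NON_NATIVE"``,
        aligned with ``counts``) used for the non-native:native abundance
        ratio NNAbu.
    log_base
        Base for Shannon diversity; natural log (nats) by default.

    Notes
    -----
    With :math:`p_i` the relative abundance of present species,
    :math:`H = -\\sum p_i \\log p_i`, Simpson dominance
    :math:`D = \\sum p_i^2`, and Pielou equitability
    :math:`J = H / \\log S` for richness :math:`S > 1`.
    """
    if isinstance(counts, pd.Series):
        values = counts.to_numpy(dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
    if values.ndim != 1:
        raise ValueError("counts must be one site's 1-D vector")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("site has no individuals (all-zero counts)")
    present = values[values > 0]
    richness = int(present.size)
    p = present / total
    log = np.log(p) / math.log(log_base)
    shannon = float(-(p * log).sum())
    simpson = float((p * p).sum())
    if richness > 1:
        equitability = shannon / (math.log(richness) / math.log(log_base))
    else:
        equitability = None
    nnabu = None
    if origin is not None:
        origin = np.asarray(
            origin.to_numpy() if isinstance(origin, pd.Series) else origin,
            dtype=object,
        )
        if origin.shape != values.shape:
            raise ValueError("origin labels must align with counts")
        labels = np.array([str(o).upper() for o in origin])
        native_total = values[labels == "NATIVE"].sum()
        nonnative_total = values[labels == "NON_NATIVE"].sum()
        if native_total > 0:
            nnabu = float(nonnative_total / native_total)
        else:
            warnings.warn("no native individuals at site; NNAbu undefined",
                          stacklevel=2)
    return DiversityProfile(
        richness=richness,
        abundance=int(round(total)),
        shannon=shannon,
        simpson_dominance=simpson,
        equitability=equitability,
        nnabu=nnabu,
    )


def diversity_table(
    matrix: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
    *,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Per-site diversity profiles for a site x species abundance matrix.

    ``attributes``, if given, must carry an ``origin`` column indexed (or
    keyed by a ``species_id`` column) by species id.
    """
    matrix = validate_abundance(matrix)
    origin = None
    if attributes is not None:
        attrs = attributes
        if "species_id" in attrs.columns:
            attrs = attrs.set_index("species_id")
        missing = [s for s in matrix.columns if s not in attrs.index]
        if missing:
            raise ValueError(f"species without origin attribute: {missing}")
        origin = attrs.loc[matrix.columns, "origin"]
    rows = {}
    for site in matrix.index:
        prof = diversity_profile(matrix.loc[site], origin, log_base=log_base)
        rows[site] = {
            "richness": prof.richness,
            "abundance": prof.abundance,
            "shannon": prof.shannon,
            "simpson_dominance": prof.simpson_dominance,
            "equitability": prof.equitability,
            "nnabu": prof.nnabu,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site_id"
    return out


def restrictedness(matrix: pd.DataFrame) -> pd.Series:
    """Occupancy-based restrictedness, one value per species.

    For species *i* occupying :math:`K_i` of :math:`K` sites,
    :math:`R_i = 1 - K_i / K`: 0 for a ubiquitous species, approaching 1 for
    a species restricted to a single site (0.96 at 1 of 25 sites).  The
    metric depends on occupancy only, so abundance and presence/absence
    inputs give identical values; a species never observed scores 1 with a
    warning.
    """
    matrix = validate_abundance(matrix)
    k_total = matrix.shape[0]
    occupancy = (matrix.to_numpy() > 0).sum(axis=0)
    if (occupancy == 0).any():
        absent = matrix.columns[occupancy == 0].tolist()
        warnings.warn(
            f"species never observed (restrictedness = 1): {absent}",
            stacklevel=2,
        )
    return pd.Series(
        1.0 - occupancy / k_total, index=matrix.columns, name="restrictedness"
    )
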