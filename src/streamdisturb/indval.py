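"""Indicator-species analysis (IndVal) with permutation inference.

The indicator value of a species for a site group combines *specificity*
(A: how concentrated the species' abundance is in the group) and *fidelity*
(B: how frequently it occurs within the group).  The default statistic is
the square root of the group-size-corrected product (the IndVal.g
convention), so a perfect indicator — present at every site of one group
and nowhere else — scores exactly 1.  Significance is assessed by permuting
the site-to-group labels while holding the abundance matrix fixed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import validate_abundance

__all__ = [
    "indval_components",
    "indval_stat",
    "indval_test",
    "IndicatorSpeciesAnalysis",
    "IndicatorResults",
]


def _check_groups(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    missing = [s for s in matrix.index if s not in groups.index]
    if missing:
        raise ValueError(f"sites without a group assignment: {missing}")
    groups = groups.loc[matrix.index].astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two site groups")
    small = counts[counts < 2]
    if len(small):
        warnings.warn(
            f"groups with fewer than 2 sites degrade permutation power: "
            f"{small.index.tolist()}",
            stacklevel=3,
        )
    return groups


def _group_structure(groups: pd.Series) -> tuple[list[str], np.ndarray]:
    """Ordered group labels and the per-site integer group index."""
    labels = sorted(groups.unique())
    index = {g: i for i, g in enumerate(labels)}
    return labels, np.array([index[g] for g in groups], dtype=int)


def _stats_for_labels(
    X: np.ndarray,
    P: np.ndarray,
    g_idx: np.ndarray,
    n_groups: int,
    member_sets: list[np.ndarray],
    *,
    corrected: bool,
    sqrt_stat: bool,
) -> np.ndarray:
    """IndVal statistic for every (target set, species) pair.

    ``member_sets`` lists, per target (single group or combination), the
    boolean group-membership vector over the ``n_groups`` groups.  Returns
    an (n_targets, n_species) array.
    """
    onehot = np.eye(n_groups)[g_idx]                  # n_sites x n_groups
    sizes = onehot.sum(axis=0)                        # group sizes
    sums = onehot.T @ X                               # n_groups x n_species
    pres = onehot.T @ P                               # group presence counts
    means = sums / sizes[:, None]
    stats = np.empty((len(member_sets), X.shape[1]))
    for t, members in enumerate(member_sets):
        if corrected:
            # pooled mean over the member groups vs per-group means outside
            inside = sums[members].sum(axis=0) / sizes[members].sum()
            outside = means[~members].sum(axis=0)
        else:
            inside = sums[members].sum(axis=0)
            outside = sums[~members].sum(axis=0)
        denom = inside + outside
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, inside / denom, 0.0)
        B = pres[members].sum(axis=0) / sizes[members].sum()
        AB = A * B
        stats[t] = np.sqrt(AB) if sqrt_stat else AB
    return stats


def indval_components(
    matrix: pd.DataFrame,
    groups: pd.Series,
    species: str,
    target_group: str,
    *,
    group_size_corrected: bool = True,
) -> tuple[float, float]:
    """Specificity A and fidelity B of one species for one group.

    A is the species' mean abundance in the target group over the sum of
    its per-group mean abundances (the group-size-corrected convention;
    with ``group_size_corrected=False`` raw group totals are used).  B is
    the fraction of target-group sites where the species occurs.  A species
    with zero total abundance returns (0, 0) with a warning.
    """
    matrix = validate_abundance(matrix)
    groups = _check_groups(matrix, groups)
    if species not in matrix.columns:
        raise KeyError(f"unknown species {species!r}")
    labels, g_idx = _group_structure(groups)
    if target_group not in labels:
        raise KeyError(f"unknown group {target_group!r}")
    x = matrix[species].to_numpy(dtype=float)
    if x.sum() == 0:
        warnings.warn(f"species {species!r} has zero total abundance",
                      stacklevel=2)
        return 0.0, 0.0
    members = np.zeros(len(labels), dtype=bool)
    members[labels.index(target_group)] = True
    stats = _stats_for_labels(
        x[:, None], (x > 0).astype(float)[:, None], g_idx, len(labels),
        [members], corrected=group_size_corrected, sqrt_stat=False,
    )
    # recover A and B separately for reporting
    in_mask = np.array([labels[i] == target_group for i in g_idx])
    B = float((x[in_mask] > 0).mean())
    AB = float(stats[0, 0])
    A = AB / B if B > 0 else 0.0
    return A, B


def indval_stat(A: float, B: float, convention: str = "sqrt") -> float:
    """Combine specificity and fidelity into the indicator value.

    ``sqrt`` (default) returns ``sqrt(A*B)``, matching the 0-1 scale of the
    IndVal.g convention; ``raw`` returns the plain product.
    """
    if not (0 <= A <= 1 and 0 <= B <= 1):
        raise ValueError(f"A and B must be in [0, 1], got A={A}, B={B}")
    if convention == "sqrt":
        return float(np.sqrt(A * B))
    if convention == "raw":
        return float(A * B)
    raise ValueError(f"unknown convention {convention!r}; use 'sqrt' or 'raw'")


class IndicatorSpeciesAnalysis:
    """Indicator-species model for an abundance matrix and a site grouping.

    Parameters
    ----------
    matrix
        Site x species abundance DataFrame.
    groups
        Mapping (Series or dict) of site id to group label, e.g. the
        LOW/MEDIUM/HIGH disturbance levels.
    convention
        ``"sqrt"`` (default, IndVal.g style) or ``"raw"``
        (Dufrene-Legendre product).
    group_size_corrected
        Use per-group mean abundances in the specificity term (default) so
        unequal group sizes do not bias A; ``False`` uses raw totals.
    combinations
        Also search combinations of groups (e.g. LOW+MEDIUM) as candidate
        targets, not just single groups.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        groups,
        *,
        convention: str = "sqrt",
        group_size_corrected: bool = True,
        combinations: bool = False,
    ) -> None:
        if convention not in ("sqrt", "raw"):
            raise ValueError(f"unknown convention {convention!r}")
        self.matrix = validate_abundance(matrix)
        self.groups = _check_groups(self.matrix, groups)
        self.convention = convention
        self.group_size_corrected = group_size_corrected
        self.combinations = combinations
        self.group_labels, self._g_idx = _group_structure(self.groups)
        self._targets = self._build_targets()

    def _build_targets(self) -> list[tuple[str, np.ndarray]]:
        n = len(self.group_labels)
        targets = []
        max_size = n - 1 if self.combinations else 1
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(range(n), size):
                members = np.zeros(n, dtype=bool)
                members[list(combo)] = True
                name = "+".join(self.group_labels[i] for i in combo)
                targets.append((name, members))
        return targets

    def fit(self, n_perm: int = 999, seed: int | None = None) -> "IndicatorResults":
        """Run the group search and the label-permutation test.

        The p-value for each species uses the max-statistic null: the best
        observed statistic is compared with the best statistic over targets
        under each random relabelling, with the (b+1)/(n_perm+1) estimator
        and ties counted as exceedances.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        X = self.matrix.to_numpy(dtype=float)
        P = (X > 0).astype(float)
        member_sets = [m for _, m in self._targets]
        kwargs = dict(corrected=self.group_size_corrected,
                      sqrt_stat=self.convention == "sqrt")
        observed = _stats_for_labels(
            X, P, self._g_idx, len(self.group_labels), member_sets, **kwargs
        )
        best_t = observed.argmax(axis=0)
        best_stat = observed.max(axis=0)
        exceed = np.zeros(X.shape[1])
        for _ in range(n_perm):
            perm_idx = rng.permutation(self._g_idx)
            perm = _stats_for_labels(
                X, P, perm_idx, len(self.group_labels), member_sets, **kwargs
            )
            exceed += perm.max(axis=0) >= best_stat - 1e-12
        p = (exceed + 1.0) / (n_perm + 1.0)

        rows = []
        species = list(self.matrix.columns)
        for j, sp in enumerate(species):
            target_name, members = self._targets[best_t[j]]
            A, B = self._components_for(X[:, j], members)
            rows.append(
                {
                    "species": sp,
                    "group": target_name,
                    "A": A,
                    "B": B,
                    "stat": float(best_stat[j]),
                    "p": float(p[j]),
                }
            )
        table = (
            pd.DataFrame(rows)
            .sort_values(["group", "stat"], ascending=[True, False])
            .reset_index(drop=True)
        )
        return IndicatorResults(model=self, table=table, n_perm=n_perm, seed=seed)

    def _components_for(self, x: np.ndarray, members: np.ndarray) -> tuple[float, float]:
        onehot = np.eye(len(self.group_labels))[self._g_idx]
        sizes = onehot.sum(axis=0)
        sums = onehot.T @ x
        if self.group_size_corrected:
            inside = sums[members].sum() / sizes[members].sum()
            outside = (sums / sizes)[~members].sum()
        else:
            inside = sums[members].sum()
            outside = sums[~members].sum()
        denom = inside + outside
        A = float(inside / denom) if denom > 0 else 0.0
        in_sites = members[self._g_idx]
        B = float((x[in_sites] > 0).mean())
        return A, B


@dataclass
class IndicatorResults:
    """Fitted indicator-species table.

    ``table`` has one row per species: best group (or combination),
    specificity A, fidelity B, the indicator statistic, and the permutation
    p-value, sorted by group then descending statistic.
    """

    model: IndicatorSpeciesAnalysis
    table: pd.DataFrame
    n_perm: int
    seed: int | None

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha].reset_index(drop=True)

    def summary(self, alpha: float = 0.05) -> str:
        sig = self.significant(alpha)
        lines = [
            "Indicator species analysis",
            f"  sites: {self.model.matrix.shape[0]}  "
            f"species: {self.model.matrix.shape[1]}  "
            f"groups: {len(self.model.group_labels)}",
            f"  statistic: {self.model.convention} "
            f"({'group-size corrected' if self.model.group_size_corrected else 'raw totals'})"
            f"{', with group combinations' if self.model.combinations else ''}",
            f"  permutations: {self.n_perm}   significant at alpha={alpha}: {len(sig)}",
            "",
            sig.to_string(index=False, float_format=lambda v: f"{v:.3f}")
            if len(sig)
            else "  (no significant indicators)",
        ]
        return "\n".join(lines)


def indval_test(
    matrix: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    combinations: bool = False,
    convention: str = "sqrt",
    group_size_corrected: bool = True,
) -> pd.DataFrame:
    """Functional wrapper: fit an :class:`IndicatorSpeciesAnalysis` and
    return its results table."""
    model = IndicatorSpeciesAnalysis(
        matrix,
        groups,
        convention=convention,
        group_size_corrected=group_size_corrected,
        combinations=combinations,
    )
    return model.fit(n_perm=n_perm, seed=seed).table
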