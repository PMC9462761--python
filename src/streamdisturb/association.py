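"""Environmental cross-correlation screen and disturbance-trend tests.

``spearman_screen`` produces the pairwise Spearman correlation matrix among
land use, habitat diversity, disturbance and productivity variables, with
tie-corrected p-values and a significance mask.  ``trend_test`` is a
permutation test for a monotone trend of an assemblage metric along the
disturbance gradient (Spearman rho of metric vs log IDI, with the
least-squares slope reported alongside).  The trend test deliberately
recovers direction of effect only; it does not fit the mixed models used
for coefficient estimation on field data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

__all__ = ["CorrelationMatrix", "spearman_screen", "TrendTestResult", "trend_test"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman rho, p-values, and a significance mask at alpha."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    def to_long(self) -> pd.DataFrame:
        """Long-format table: variable1, variable2, rho, p, significant."""
        rows = []
        cols = list(self.rho.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {
                        "variable1": a,
                        "variable2": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "significant": bool(self.significant.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def spearman_screen(
    table: pd.DataFrame,
    *,
    log_transform: bool = False,
    alpha: float = 0.05,
    log_offset: float = 0.01,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations among environment variables.

    ``log_transform`` applies ``log(x + offset-for-zeros)`` before ranking,
    mirroring the conventional scale standardisation; Spearman is invariant
    to strictly increasing transforms, so this only matters for downstream
    consumers of the transformed table.  Constant variables yield NaN rho
    (flagged with a warning); their p is NaN and they are never significant.
    """
    if table.shape[0] < 4:
        raise ValueError("need at least 4 sites for the correlation screen")
    X = table.to_numpy(dtype=float)
    if log_transform:
        if (X < 0).any():
            raise ValueError("log transform requires non-negative variables")
        X = np.log(np.where(X == 0, log_offset, X))
    cols = list(table.columns)
    n = len(cols)
    rho = np.eye(n)
    p = np.zeros((n, n))
    constant = [c for j, c in enumerate(cols) if np.std(X[:, j]) == 0]
    if constant:
        warnings.warn(f"constant variables (rho undefined): {constant}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns emit RuntimeWarnings
        for i in range(n):
            for j in range(i + 1, n):
                r, pv = spearmanr(X[:, i], X[:, j])
                rho[i, j] = rho[j, i] = r
                p[i, j] = p[j, i] = pv
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha) & rho_df.notna()
    np.fill_diagonal(sig.values, False)
    return CorrelationMatrix(rho=rho_df, p=p_df, significant=sig, alpha=alpha)


@dataclass(frozen=True)
class TrendTestResult:
    """Monotone-trend test of an assemblage metric against the IDI."""

    slope: float
    rho: float
    p: float
    n_perm: int


def trend_test(
    metric,
    idi,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    log_idi: bool = True,
    log_offset: float = 1e-3,
) -> TrendTestResult:
    """Permutation trend test of a per-site metric along the IDI gradient.

    Reports the Spearman rho between metric and (log-transformed) IDI, the
    least-squares slope on the same scale, and a two-sided permutation
    p-value obtained by shuffling the metric across sites
    ((b+1)/(n_perm+1) estimator, ties counted as exceedances).
    """
    y = np.asarray(metric, dtype=float)
    x = np.asarray(idi, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("metric and idi must be equal-length 1-D vectors")
    if y.size < 5:
        raise ValueError("need at least 5 sites for the trend test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("zero variance in metric or IDI")
    if log_idi:
        if (x < 0).any():
            raise ValueError("IDI must be non-negative")
        x = np.log(np.where(x == 0, log_offset, x))
    slope = float(np.polyfit(x, y, 1)[0])

    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho_obs = float(np.mean(rx * ry))

    rng = np.random.default_rng(seed)
    n = y.size
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rho_perm = (rx[perms] * ry).mean(axis=1)
    exceed = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
    p = (exceed + 1) / (n_perm + 1)
    return TrendTestResult(slope=slope, rho=rho_obs, p=float(p), n_perm=n_perm)
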