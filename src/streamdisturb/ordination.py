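"""Constrained ordination of community composition on environmental gradients.

Implements distance-based redundancy analysis (dbRDA): the site dissimilarity
matrix (Bray-Curtis on square-root-transformed counts, by convention) is
embedded by principal coordinates analysis, the coordinates are regressed on
the explanatory variables, and the fitted values are eigen-decomposed into
constrained axes.  Inference is by free permutation of the site rows of the
response.  A collinearity pre-screen (pairwise Spearman, then variance
inflation factors) reduces the explanatory table before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "bray_curtis",
    "variance_inflation",
    "select_variables",
    "DistanceRDA",
    "DistanceRDAResults",
]

_EIG_TOL = 1e-9


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Site x site Bray-Curtis dissimilarity from an abundance matrix.

    ``d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)`` on (optionally square-root
    transformed) counts.  The square-root transform damps the influence of
    the most abundant species.
    """
    if transform not in ("sqrt", "none"):
        raise ValueError(f"unknown transform {transform!r}; use 'sqrt' or 'none'")
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundance matrix has negative cells")
    zero_rows = X.sum(axis=1) == 0
    if zero_rows.any():
        bad = matrix.index[zero_rows].tolist()
        raise ValueError(f"all-zero site rows (Bray-Curtis undefined): {bad}")
    if transform == "sqrt":
        X = np.sqrt(X)
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def _spearman_matrix(env: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    arr = env.to_numpy(dtype=float)
    if arr.shape[1] == 2:  # spearmanr returns scalars for two columns
        r, pv = spearmanr(arr[:, 0], arr[:, 1])
        return (
            np.array([[1.0, r], [r, 1.0]]),
            np.array([[0.0, pv], [pv, 0.0]]),
        )
    rho, p = spearmanr(arr, axis=0)
    return np.asarray(rho), np.asarray(p)


def variance_inflation(env: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) of each variable regressed,
    with intercept, on all the others."""
    if env.shape[1] < 2:
        raise ValueError("VIF needs at least two variables")
    X = np.column_stack([np.ones(len(env)), env.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits emit divide warnings
        vals = [variance_inflation_factor(X, j + 1) for j in range(env.shape[1])]
    return pd.Series(vals, index=env.columns, name="vif")


def select_variables(
    env: pd.DataFrame,
    r_max: float = 0.7,
    vif_max: float = 10.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[dict]]:
    """Collinearity screen for the explanatory table.

    Stage 1 drops one variable from every Spearman pair with |rho| >= r_max
    and p < alpha; from each offending pair the variable with the larger
    mean absolute correlation to all others is removed (ties broken
    alphabetically).  Stage 2 then iteratively removes the variable with the
    highest variance inflation factor while any VIF exceeds ``vif_max``.

    Returns the reduced table and an exclusion log recording each dropped
    variable and its trigger.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two explanatory variables")
    if env.shape[0] < 3:
        raise ValueError("need at least three sites")
    log: list[dict] = []
    keep = env.copy()

    while keep.shape[1] >= 2:
        rho, p = _spearman_matrix(keep)
        n = keep.shape[1]
        iu = np.triu_indices(n, k=1)
        flagged = (np.abs(rho[iu]) >= r_max) & (p[iu] < alpha)
        if not flagged.any():
            break
        mean_abs = (np.abs(rho).sum(axis=0) - 1.0) / (n - 1)
        candidates = set()
        for a, b in zip(iu[0][flagged], iu[1][flagged]):
            candidates.add(a)
            candidates.add(b)
        drop_idx = max(
            sorted(candidates, key=lambda i: keep.columns[i]),
            key=lambda i: mean_abs[i],
        )
        name = keep.columns[drop_idx]
        partner_scores = [
            (keep.columns[b] if a == drop_idx else keep.columns[a], rho[a, b])
            for a, b in zip(iu[0][flagged], iu[1][flagged])
            if drop_idx in (a, b)
        ]
        log.append(
            {
                "variable": name,
                "stage": "spearman",
                "reason": "; ".join(
                    f"|rho|={abs(r):.3f} with {other}" for other, r in partner_scores
                ),
            }
        )
        keep = keep.drop(columns=[name])

    while keep.shape[1] >= 2:
        vifs = variance_inflation(keep).to_numpy()
        if not (vifs > vif_max).any():
            break
        worst = int(np.nanargmax(vifs))
        name = keep.columns[worst]
        log.append(
            {"variable": name, "stage": "vif", "reason": f"VIF={vifs[worst]:.2f}"}
        )
        keep = keep.drop(columns=[name])

    if keep.shape[1] == 0:
        raise ValueError(f"all variables excluded; log: {log}")
    return keep, log


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _principal_coordinates(D: np.ndarray, sqrt_correction: bool) -> tuple[np.ndarray, float, float]:
    """PCoA embedding of a dissimilarity matrix.

    Returns the coordinates on positive-eigenvalue axes, the retained
    (positive) inertia, and the discarded negative inertia.  With
    ``sqrt_correction`` the analysis embeds sqrt(d), which is Euclidean for
    Bray-Curtis and leaves no negative eigenvalues.
    """
    if sqrt_correction:
        D = np.sqrt(D)
    G = _gower_center(D)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > _EIG_TOL * scale
    neg_inertia = float(-eigval[eigval < -_EIG_TOL * scale].sum())
    Y = eigvec[:, pos] * np.sqrt(eigval[pos])
    return Y, float(eigval[pos].sum()), neg_inertia


def _hat_matrix(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def _constrained_decomposition(Y: np.ndarray, H: np.ndarray) -> tuple:
    fitted = H @ Y
    resid = Y - fitted
    Uf, sf, _ = np.linalg.svd(fitted, full_matrices=False)
    Ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
    scale = max(sf.max(initial=0.0), sr.max(initial=0.0), 1.0)
    kf = sf > _EIG_TOL * scale
    kr = sr > _EIG_TOL * scale
    return sf[kf] ** 2, sr[kr] ** 2, Uf[:, kf] * sf[kf], Ur[:, kr] * sr[kr]


class DistanceRDA:
    """dbRDA model: a site dissimilarity matrix constrained by environment.

    Parameters
    ----------
    dist
        Square symmetric dissimilarity DataFrame (sites x sites).
    env
        Explanatory table (sites x variables), rows aligned with ``dist``.
    sqrt_correction
        Embed the square root of the dissimilarities, which is Euclidean
        for Bray-Curtis and avoids negative PCoA eigenvalues.  Off by
        default; negative-eigenvalue axes are then dropped from the
        regression step and their inertia reported.
    """

    def __init__(self, dist: pd.DataFrame, env: pd.DataFrame, *,
                 sqrt_correction: bool = False) -> None:
        dist = pd.DataFrame(dist)
        D = dist.to_numpy(dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        env = pd.DataFrame(env)
        if list(env.index) != list(dist.index):
            if set(env.index) != set(dist.index):
                raise ValueError("env rows do not match dissimilarity sites")
            env = env.loc[dist.index]
        if env.isna().any().any():
            raise ValueError("env table has missing cells")
        n, q = env.shape
        if n <= q + 1:
            raise ValueError(
                f"need n_sites > n_variables + 1 (got n={n}, q={q})"
            )
        self.dist = dist
        self.env = env
        self.sqrt_correction = sqrt_correction

    @classmethod
    def from_abundance(
        cls,
        matrix: pd.DataFrame,
        env: pd.DataFrame,
        *,
        transform: str = "sqrt",
        sqrt_correction: bool = False,
    ) -> "DistanceRDA":
        """Build the model from a site x species abundance matrix via
        Bray-Curtis dissimilarity."""
        return cls(bray_curtis(matrix, transform=transform), env,
                   sqrt_correction=sqrt_correction)

    def fit(self) -> "DistanceRDAResults":
        Y, pos_inertia, neg_inertia = _principal_coordinates(
            self.dist.to_numpy(dtype=float), self.sqrt_correction
        )
        X = self.env.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = self.env.columns[sd == 0].tolist()
            raise ValueError(f"constant explanatory variables: {bad}")
        Xs = Xc / sd
        rank = np.linalg.matrix_rank(Xs)
        if rank < Xs.shape[1]:
            raise ValueError(
                "explanatory table is rank-deficient after selection; "
                "remove collinear variables first"
            )
        H = _hat_matrix(Xs)
        eig_c, eig_u, scores_c, scores_u = _constrained_decomposition(Y, H)
        with np.errstate(invalid="ignore"):
            biplot = np.array(
                [
                    [np.corrcoef(Xs[:, j], scores_c[:, k])[0, 1]
                     for k in range(scores_c.shape[1])]
                    for j in range(Xs.shape[1])
                ]
            )
        return DistanceRDAResults(
            model=self,
            pcoa_coords=Y,
            total_inertia=pos_inertia,
            negative_inertia=neg_inertia,
            eig_constrained=eig_c,
            eig_unconstrained=eig_u,
            site_scores=pd.DataFrame(
                scores_c,
                index=self.dist.index,
                columns=[f"dbRDA{k+1}" for k in range(scores_c.shape[1])],
            ),
            biplot_scores=pd.DataFrame(
                biplot,
                index=self.env.columns,
                columns=[f"dbRDA{k+1}" for k in range(scores_c.shape[1])],
            ),
            _X=Xs,
            _H=H,
        )


@dataclass
class DistanceRDAResults:
    """Fitted dbRDA: eigenvalues, scores, and permutation tests."""

    model: DistanceRDA
    pcoa_coords: np.ndarray
    total_inertia: float
    negative_inertia: float
    eig_constrained: np.ndarray
    eig_unconstrained: np.ndarray
    site_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    _X: np.ndarray = field(repr=False, default=None)
    _H: np.ndarray = field(repr=False, default=None)

    @property
    def n_sites(self) -> int:
        return self.pcoa_coords.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self._X))

    @property
    def constrained_inertia(self) -> float:
        return float(self.eig_constrained.sum())

    @property
    def proportion_explained(self) -> pd.Series:
        """Per constrained axis, fraction of total (positive) inertia."""
        return pd.Series(
            self.eig_constrained / self.total_inertia,
            index=[f"dbRDA{k+1}" for k in range(len(self.eig_constrained))],
        )

    def r_squared(self, adjusted: bool = False) -> float:
        r2 = self.constrained_inertia / self.total_inertia
        if not adjusted:
            return float(r2)
        n, q = self.n_sites, self.rank
        return float(1.0 - (1.0 - r2) * (n - 1) / (n - q - 1))

    def _pseudo_f(self, H: np.ndarray, q: int, Y: np.ndarray) -> float:
        fitted_ss = float(np.sum((H @ Y) ** 2))
        resid_ss = float(np.sum(Y**2)) - fitted_ss
        df_resid = self.n_sites - q - 1
        return (fitted_ss / q) / (resid_ss / df_resid)

    def permutation_test(
        self, by: str = "axis", n_perm: int = 999, seed: int | None = None
    ) -> pd.DataFrame:
        """Permutation tests for the fitted constraints.

        ``by="axis"`` tests the overall model and then each constrained
        axis, comparing each observed axis pseudo-F with the same-rank axis
        under free row permutation of the response coordinates.
        ``by="margin"`` tests each explanatory variable with all others
        retained (partial F), and also reports the variable's standalone
        adjusted r-squared.  p-values use the (b+1)/(n_perm+1) estimator.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if by not in ("axis", "margin"):
            raise ValueError(f"unknown test mode {by!r}; use 'axis' or 'margin'")
        rng = np.random.default_rng(seed)
        Y = self.pcoa_coords
        n, q = self.n_sites, self.rank
        df_resid = n - q - 1

        if by == "axis":
            resid_ms = (self.total_inertia - self.constrained_inertia) / df_resid
            f_global = (self.constrained_inertia / q) / resid_ms
            exceed_g = 0
            for _ in range(n_perm):
                Yp = Y[rng.permutation(n)]
                fit_ss = np.sum((self._H @ Yp) ** 2)
                resid_ms_p = (np.sum(Yp**2) - fit_ss) / df_resid
                exceed_g += (fit_ss / q) / resid_ms_p >= f_global - 1e-12
            rows = [
                {"term": "model", "df": q, "pseudo_F": float(f_global),
                 "p": (exceed_g + 1) / (n_perm + 1)}
            ]
            # sequential axis tests: axis k is tested with the preceding
            # constrained axes partialled out of both response and constraints,
            # so a dominant first axis does not inflate later axes
            scores = self.site_scores.to_numpy()
            X = self._X
            for k, lam in enumerate(self.eig_constrained):
                if k == 0:
                    Yk, Xk = Y, X
                else:
                    Hp = _hat_matrix(scores[:, :k])
                    Yk = Y - Hp @ Y
                    Xk = X - Hp @ X
                Hk = _hat_matrix(Xk)
                f_obs = lam / resid_ms
                exceed = 0
                for _ in range(n_perm):
                    Yp = Yk[rng.permutation(n)]
                    fitted = Hk @ Yp
                    lam1 = np.linalg.svd(fitted, compute_uv=False)[0] ** 2
                    fit_ss = float(np.sum(fitted**2))
                    resid_ms_p = (np.sum(Yp**2) - fit_ss) / df_resid
                    exceed += lam1 / resid_ms_p >= f_obs - 1e-12
                rows.append(
                    {"term": f"dbRDA{k+1}", "df": 1, "pseudo_F": float(f_obs),
                     "p": (exceed + 1) / (n_perm + 1)}
                )
            return pd.DataFrame(rows)

        # by == "margin": partial F for each variable given all others
        X = self._X
        full_ss = self.constrained_inertia
        rows = []
        for j, name in enumerate(self.model.env.columns):
            others = np.delete(X, j, axis=1)
            H_red = (
                _hat_matrix(others) if others.shape[1] else np.zeros((n, n))
            )
            red_ss = float(np.sum((H_red @ Y) ** 2))
            resid_ms = (self.total_inertia - full_ss) / df_resid
            f_obs = (full_ss - red_ss) / 1.0 / resid_ms

            H_j = _hat_matrix(X[:, [j]])
            alone_ss = float(np.sum((H_j @ Y) ** 2))
            r2_alone = alone_ss / self.total_inertia
            r2_adj = 1.0 - (1.0 - r2_alone) * (n - 1) / (n - 2)

            exceed = 0
            for _ in range(n_perm):
                Yp = Y[rng.permutation(n)]
                full_p = float(np.sum((self._H @ Yp) ** 2))
                red_p = float(np.sum((H_red @ Yp) ** 2))
                resid_ms_p = (np.sum(Yp**2) - full_p) / df_resid
                fp = (full_p - red_p) / resid_ms_p
                exceed += fp >= f_obs - 1e-12
            rows.append(
                {
                    "term": name,
                    "df": 1,
                    "r2_adjusted": float(r2_adj),
                    "pseudo_F": float(f_obs),
                    "p": (exceed + 1) / (n_perm + 1),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        prop = self.proportion_explained
        lines = [
            "Distance-based redundancy analysis",
            f"  sites: {self.n_sites}   constraints: {self.model.env.shape[1]} "
            f"(rank {self.rank})",
            f"  total inertia (positive axes): {self.total_inertia:.4f}",
            f"  discarded negative inertia:    {self.negative_inertia:.4f}",
            f"  constrained inertia: {self.constrained_inertia:.4f} "
            f"(R2={self.r_squared():.4f}, adj R2={self.r_squared(adjusted=True):.4f})",
            "  proportion explained by constrained axes:",
        ]
        for name, v in prop.items():
            lines.append(f"    {name}: {100 * v:.2f}%")
        return "\n".join(lines)
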