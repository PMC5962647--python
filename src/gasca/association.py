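"""Variable-variable association maps.

Two constructions of the J x J symmetric association map M used to find
groups of related variables:

* **MEDA map** — derived from a rank-Q principal-component model of a
  (column-centered) source matrix.  Writing ``x_l`` for the l-th centered
  column and ``e_l^Q`` for its residual under the rank-Q reconstruction,

      m_lj = {x_l' x_j + e_l' e_j} * |x_l' x_j - e_l' e_j| / (s2_l * s2_j)

  with ``s2_j = x_j' x_j``.  At Q = rank(X) the residuals vanish and the map
  reduces to the signed squared Pearson correlation; at smaller Q the missing-
  data logic attenuates associations that live only in the residual noise.

* **Spearman map** — rank correlation of the columns of an effect matrix,
  with entries whose two-sided P value exceeds a significance level forced to
  zero so that chance associations do not seed spurious groups.

Both maps are returned as :class:`AssociationMap`; anything square and
symmetric (e.g. a mutual-information matrix computed elsewhere) can be wrapped
in the same container and fed to the grouping stage.
"""

from __future__ import annotations

import itertools

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ConfigError, DataError

__all__ = ["AssociationMap", "meda_map", "select_meda_rank", "spearman_map"]


@dataclass
class AssociationMap:
    """J x J symmetric association map between variables.

    ``M`` is a DataFrame with identical index and columns (variable names),
    entries in [-1, 1].  ``method`` records how it was built ("meda",
    "spearman", or "external"); ``params`` the construction parameters.
    """

    M: pd.DataFrame
    method: str
    source_effect: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = self.M.to_numpy(dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ConfigError("association map must be square")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ConfigError("association map must be symmetric")
        if np.nanmax(np.abs(A)) > 1 + 1e-9:
            raise ConfigError("association map entries must lie in [-1, 1]")

    @property
    def n_vars(self) -> int:
        return self.M.shape[0]

    @property
    def variable_names(self) -> list[str]:
        return [str(c) for c in self.M.columns]

    def values(self) -> np.ndarray:
        return self.M.to_numpy(dtype=float)


def _as_centered_array(X_src) -> tuple[np.ndarray, list[str]]:
    if isinstance(X_src, pd.DataFrame):
        names = [str(c) for c in X_src.columns]
        A = X_src.to_numpy(dtype=float)
    else:
        A = np.asarray(X_src, dtype=float)
        names = [f"v{j}" for j in range(A.shape[1])]
    col_means = A.mean(axis=0)
    scale = np.abs(A).max() or 1.0
    if np.abs(col_means).max() > 1e-8 * scale:
        A = A - col_means
    return A, names


def meda_map(X_src, Q: int) -> AssociationMap:
    """Missing-data-style association map from a rank-Q component model.

    Parameters
    ----------
    X_src
        Column-centered N x J matrix (DataFrame or array); centering is
        applied defensively if the column means are not already zero.
    Q
        Number of latent components, 1 <= Q <= rank(X_src).
    """
    A, names = _as_centered_array(X_src)
    s2 = np.einsum("ij,ij->j", A, A)
    zero = [names[j] for j in np.flatnonzero(s2 == 0)]
    if zero:
        raise DataError(f"zero-variance variable(s) {zero}; cannot build MEDA map")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    if not 1 <= Q <= rank:
        raise ConfigError(f"Q={Q} outside [1, rank={rank}] of the source matrix")
    recon = (U[:, :Q] * s[:Q]) @ Vt[:Q]
    E = A - recon
    G = A.T @ A
    Ge = E.T @ E
    M = (G + Ge) * np.abs(G - Ge) / np.outer(s2, s2)
    M = (M + M.T) / 2.0
    np.clip(M, -1.0, 1.0, out=M)
    df = pd.DataFrame(M, index=names, columns=names)
    return AssociationMap(M=df, method="meda", params={"rank": int(Q)})


def select_meda_rank(
    X_src,
    folds: int = 5,
    max_rank: int | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the MEDA model rank by column-wise k-fold cross-validation.

    Variables are assigned to ``folds`` folds round-robin.  For each candidate
    rank Q the loadings of the full-data PCA are used to predict the held-out
    columns of every observation by known-data regression (scores estimated
    from the observed columns only, least squares), and the mean squared
    prediction error over all held-out entries is recorded.  The returned rank
    minimizes this error curve (smallest rank on ties); the full curve is
    returned alongside for inspection.
    """
    if folds < 2:
        raise ConfigError("need at least 2 folds")
    A, _ = _as_centered_array(X_src)
    n, j = A.shape
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    if rank == 0:
        raise DataError("source matrix has rank 0; cannot select a model rank")
    if max_rank is None:
        max_rank = rank
    max_rank = min(max_rank, rank)
    V = Vt.T
    fold_of = np.arange(j) % min(folds, j)
    errors = np.empty(max_rank)
    for q in range(1, max_rank + 1):
        P = V[:, :q]
        press = 0.0
        for f in np.unique(fold_of):
            miss = fold_of == f
            obs = ~miss
            Po, Pm = P[obs], P[miss]
            # scores from observed columns only (known-data regression)
            T_hat = np.linalg.lstsq(Po, A[:, obs].T, rcond=None)[0].T
            pred = T_hat @ Pm.T
            press += float(np.sum((A[:, miss] - pred) ** 2))
        errors[q - 1] = press / (n * j)
    best = int(np.argmin(errors)) + 1
    return best, errors


def _exact_spearman_pvalues(R: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation P values for Spearman rho, small N.

    Enumerates all permutations of one column's ranks against the other's and
    counts |rho_perm| >= |rho_obs|.  Vectorized over permutations; intended
    only for N < 10 where the t approximation is unreliable.
    """
    n, j = R.shape
    perms = np.array(list(itertools.permutations(range(n))))
    pv = np.ones((j, j))
    Rc = R - R.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Rc, Rc))
    for a in range(j):
        ra = Rc[:, a]
        if norms[a] == 0:
            continue
        ra_perm = ra[perms]  # (n!, n)
        for b in range(a + 1, j):
            if norms[b] == 0:
                continue
            rho_perm = ra_perm @ Rc[:, b] / (norms[a] * norms[b])
            obs = abs(corr[a, b])
            pv[a, b] = pv[b, a] = np.mean(np.abs(rho_perm) >= obs - 1e-12)
    return pv


def spearman_map(
    X_eff,
    alpha: float = 0.01,
    bh_correct: bool = False,
    source_effect: str | None = None,
) -> AssociationMap:
    """Significance-filtered Spearman rank-correlation map.

    Entries are Spearman's rho (Pearson correlation of average ranks) when the
    two-sided P value is at or below ``alpha``, otherwise 0; the diagonal is
    1.  Constant columns cannot be ranked meaningfully: their row and column
    are zeroed with a warning.  ``bh_correct`` applies Benjamini-Hochberg
    across the J(J-1)/2 pairs before filtering (off by default: the plain
    per-pair rule is the reference behavior).
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if isinstance(X_eff, pd.DataFrame):
        names = [str(c) for c in X_eff.columns]
        A = X_eff.to_numpy(dtype=float)
    else:
        A = np.asarray(X_eff, dtype=float)
        names = [f"v{j}" for j in range(A.shape[1])]
    n, j = A.shape
    if n < 3:
        raise DataError("need at least 3 observations for a rank correlation")
    R = np.apply_along_axis(stats.rankdata, 0, A)  # average ranks on ties
    sd = R.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            "constant column(s) "
            f"{[names[k] for k in np.flatnonzero(const)]}: associations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(R, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    if n >= 10:
        r = np.clip(corr, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        pv = 2 * special.stdtr(n - 2, -np.abs(t))
    else:
        pv = _exact_spearman_pvalues(R, corr)
    np.fill_diagonal(pv, 0.0)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(j, k=1)
        adj = multipletests(pv[iu], method="fdr_bh")[1]
        pv[iu] = adj
        pv.T[iu] = adj
    M = np.where(pv <= alpha, corr, 0.0)
    M[const, :] = 0.0
    M[:, const] = 0.0
    np.fill_diagonal(M, 1.0)
    df = pd.DataFrame(M, index=names, columns=names)
    return AssociationMap(
        M=df,
        method="spearman",
        source_effect=source_effect,
        params={"alpha": float(alpha), "bh_correct": bool(bh_correct)},
    )
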