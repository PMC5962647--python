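"""Dense PCA and group-wise PCA (GPCA).

``fit_pca`` is the ordinary principal-component factorization X = T P' + E
via the singular value decomposition of the column-centered matrix.

``fit_gpca`` replaces the dense loadings with group-wise sparse ones: at each
step, a candidate loading is computed for every group of associated variables
(the leading right singular vector of the current working matrix restricted
to the group's columns, zero-padded to full length); only the candidate with
the largest explained variance — the score sum of squares on the working
matrix — is retained, the working matrix is deflated by the rank-1
score-loading product, and the procedure repeats.  Every component therefore
has non-zero loadings on exactly one group, which is what makes the model
directly interpretable: a component IS a group of correlated variables.

Because the sparse loadings are generally not orthogonal, the reported scores
are the extraction-time scores (current matrix times loading), not scores
re-regressed on the final loading set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .grouping import GroupSet

__all__ = ["ComponentModel", "fit_pca", "fit_gpca"]


@dataclass
class ComponentModel:
    """Scores/loadings factorization with optional group-wise sparsity.

    ``sparsity`` records, per component, the index of the group owning its
    non-zero loadings, or ``"dense"`` for ordinary PCA components.
    ``explained_variance`` is each component's score sum of squares at
    extraction time.
    """

    loadings: pd.DataFrame  # J x H
    scores: pd.DataFrame  # N x H
    explained_variance: np.ndarray
    sparsity: list[int | str]
    centering: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def nonzero_variables(self, component: int) -> list[str]:
        col = self.loadings.iloc[:, component]
        return [str(i) for i in col.index[col != 0]]


def _names(X_src):
    if isinstance(X_src, pd.DataFrame):
        return (
            [str(c) for c in X_src.columns],
            [str(i) for i in X_src.index],
            X_src.to_numpy(dtype=float),
        )
    A = np.asarray(X_src, dtype=float)
    return (
        [f"v{j}" for j in range(A.shape[1])],
        [f"obs{i}" for i in range(A.shape[0])],
        A,
    )


def _fix_sign(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i = int(np.argmax(np.abs(p)))
    if p[i] < 0:
        return -p, -t
    return p, t


def _wrap(var_names, obs_names, P, T, ev, sparsity, centering) -> ComponentModel:
    h = P.shape[1]
    comp_names = [f"PC{k + 1}" for k in range(h)]
    return ComponentModel(
        loadings=pd.DataFrame(P, index=var_names, columns=comp_names),
        scores=pd.DataFrame(T, index=obs_names, columns=comp_names),
        explained_variance=np.asarray(ev, dtype=float),
        sparsity=list(sparsity),
        centering=np.asarray(centering, dtype=float),
    )


def fit_pca(X_src, H: int, center: bool = True) -> ComponentModel:
    """Ordinary PCA with H components of the (centered) matrix.

    Loadings are the leading right singular vectors, scores their projections;
    explained variances (squared singular values) are non-increasing.  Raises
    if H exceeds the rank of the centered matrix.
    """
    var_names, obs_names, A = _names(X_src)
    mu = A.mean(axis=0) if center else np.zeros(A.shape[1])
    Ac = A - mu
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    if not 1 <= H <= rank:
        raise ConfigError(f"H={H} outside [1, rank={rank}]")
    P = Vt[:H].T.copy()
    T = Ac @ P
    for k in range(H):
        P[:, k], T[:, k] = _fix_sign(P[:, k], T[:, k])
    return _wrap(var_names, obs_names, P, T, s[:H] ** 2, ["dense"] * H, mu)


def fit_gpca(
    X_src,
    groups: GroupSet,
    H: int,
    center: bool = True,
    reuse_groups: bool = True,
) -> ComponentModel:
    """Group-wise PCA: per-group candidate loadings, keep the best, deflate.

    Parameters
    ----------
    X_src
        N x J data matrix (an effect matrix in the ASCA context).
    groups
        Groups of associated variables; each extracted component's non-zero
        loadings lie entirely inside one group.
    H
        Number of components requested; fewer are returned (with a warning)
        if the remaining candidates explain no variance.
    reuse_groups
        If False, a group already owning a component is not a candidate again.
    """
    if H < 1:
        raise ConfigError("H must be >= 1")
    if len(groups) == 0:
        raise ConfigError("empty group set: nothing to fit")
    var_names, obs_names, A = _names(X_src)
    j = A.shape[1]
    for g in groups:
        if max(g) >= j:
            raise ConfigError(f"group {g} indexes beyond the {j} variables")
    mu = A.mean(axis=0) if center else np.zeros(j)
    work = A - mu

    P_cols, T_cols, evs, owners = [], [], [], []
    used: set[int] = set()
    for _ in range(H):
        best_ev, best_p, best_k = -1.0, None, -1
        for k, g in enumerate(groups):
            if not reuse_groups and k in used:
                continue
            idx = np.asarray(g)
            sub = work[:, idx]
            _, s, Vt = np.linalg.svd(sub, full_matrices=False)
            if s.size == 0 or s[0] == 0:
                continue
            ev = float(s[0] ** 2)  # score sum of squares of the candidate
            if ev > best_ev + 1e-15:
                p = np.zeros(j)
                p[idx] = Vt[0]
                best_ev, best_p, best_k = ev, p, k
        if best_p is None or best_ev <= 1e-12:
            warnings.warn(
                f"stopping after {len(P_cols)} components: remaining candidates "
                "explain no variance",
                stacklevel=2,
            )
            break
        t = work @ best_p
        best_p, t = _fix_sign(best_p, t)
        work = work - np.outer(t, best_p)
        P_cols.append(best_p)
        T_cols.append(t)
        evs.append(best_ev)
        owners.append(best_k)
        used.add(best_k)
    if not P_cols:
        raise ConfigError("no component could be extracted (all-zero matrix?)")
    P = np.column_stack(P_cols)
    T = np.column_stack(T_cols)
    return _wrap(var_names, obs_names, P, T, evs, owners, mu)
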