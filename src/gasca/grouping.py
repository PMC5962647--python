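"""Group identification on an association map.

Given a symmetric association map M and a threshold gamma, a group S_k is a
set of variables in which every pair satisfies |m_lj| > gamma — a clique of
the thresholded association graph.  The identification is a deterministic
seeded greedy: each variable seeds a candidate group that grows by adding, at
every step, the variable with the best worst-case association to the current
members; identical groups are deduplicated, groups below the minimum size and
groups strictly contained in another kept group are dropped.  Overlapping
groups are allowed.

The default minimum group size is ceil(sqrt(J)) — the aim is groups of
correlated variables, not singletons or pairs — but it is configurable, and
for small planted structures a smaller value is appropriate.

``gamma_sweep`` tabulates group count and size statistics over a grid of
thresholds, the standard diagnostic for choosing gamma by inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationMap
from .exceptions import ConfigError

__all__ = ["GroupSet", "identify_groups", "gamma_sweep", "default_min_size"]


def default_min_size(n_vars: int) -> int:
    """Conservative default minimum group size, ceil(sqrt(J))."""
    return int(math.ceil(math.sqrt(n_vars)))


@dataclass
class GroupSet:
    """The groups S_1..S_K of mutually associated variables at threshold gamma.

    ``groups`` holds sorted tuples of variable indices into the source map's
    variable list; every pair inside a group exceeds ``gamma`` in absolute
    association, every group has at least ``min_size`` members, and no group
    is a subset of another.
    """

    groups: list[tuple[int, ...]]
    gamma: float
    min_size: int
    variable_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def named(self) -> list[list[str]]:
        return [[self.variable_names[i] for i in g] for g in self.groups]

    def to_records(self) -> list[dict]:
        return [
            {
                "group_id": k,
                "variable_indices": list(g),
                "variable_names": [self.variable_names[i] for i in g]
                if self.variable_names
                else None,
                "size": len(g),
            }
            for k, g in enumerate(self.groups)
        ]


def _grow_group(A: np.ndarray, seed: int, gamma: float) -> tuple[int, ...]:
    """Greedy clique growth from one seed variable.

    Repeatedly adds the candidate maximizing the minimum |m| to all current
    members (lowest index on ties) among candidates whose associations to
    every member exceed gamma.
    """
    j = A.shape[0]
    members = [seed]
    in_group = np.zeros(j, dtype=bool)
    in_group[seed] = True
    # min |m| from each variable to the current members
    min_assoc = A[seed].copy()
    while True:
        eligible = ~in_group & (min_assoc > gamma)
        if not eligible.any():
            break
        cand = np.flatnonzero(eligible)
        best = cand[int(np.argmax(min_assoc[cand]))]
        members.append(int(best))
        in_group[best] = True
        np.minimum(min_assoc, A[best], out=min_assoc)
    return tuple(sorted(int(m) for m in members))


def identify_groups(
    map: AssociationMap,
    gamma: float,
    min_size: int | None = None,
) -> GroupSet:
    """Find groups of variables pairwise associated above gamma.

    Parameters
    ----------
    map
        Symmetric association map.
    gamma
        Threshold on |m|, 0 <= gamma < 1.
    min_size
        Smallest group size kept; defaults to ceil(sqrt(J)).

    Returns
    -------
    GroupSet
        Deduplicated groups, each maximal under the greedy expansion (no
        remaining variable can be added without breaking the pairwise
        threshold), in deterministic order.
    """
    if not 0 <= gamma < 1:
        raise ConfigError("gamma must lie in [0, 1)")
    j = map.n_vars
    if min_size is None:
        min_size = default_min_size(j)
    if not 1 <= min_size <= j:
        raise ConfigError(f"min_size must lie in [1, {j}]")
    A = np.abs(map.values())
    np.fill_diagonal(A, np.inf)  # a variable is always associated with itself
    raw = {_grow_group(A, seed, gamma) for seed in range(j)}
    kept = sorted((g for g in raw if len(g) >= min_size), key=lambda g: (-len(g), g))
    # drop strict subsets of another kept group
    final: list[tuple[int, ...]] = []
    for g in kept:
        gs = set(g)
        if not any(gs < set(h) for h in final):
            final.append(g)
    final.sort()
    return GroupSet(
        groups=final,
        gamma=float(gamma),
        min_size=int(min_size),
        variable_names=map.variable_names,
    )


def gamma_sweep(
    map: AssociationMap,
    gammas,
    min_size: int | None = None,
) -> pd.DataFrame:
    """Group count and size statistics over a grid of thresholds.

    Returns one row per gamma with columns ``gamma``, ``n_groups``,
    ``median_size``, ``min_size_found``, ``max_size`` (NaN sizes when no group
    survives).  Used to pick gamma: a good threshold yields few groups of
    moderate size rather than many singleton-ish ones.
    """
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    if gammas.size == 0:
        raise ConfigError("empty gamma grid")
    rows = []
    for g in gammas:
        gs = identify_groups(map, float(g), min_size=min_size)
        sizes = gs.sizes()
        rows.append(
            {
                "gamma": float(g),
                "n_groups": len(gs),
                "median_size": float(np.median(sizes)) if sizes else float("nan"),
                "min_size_found": min(sizes) if sizes else float("nan"),
                "max_size": max(sizes) if sizes else float("nan"),
            }
        )
    return pd.DataFrame(rows)
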