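"""Permutation validation of multivariate effects.

Before fitting per-effect component models it must be checked that an effect
(or interaction) matrix reflects real population structure rather than
sampling noise: fitting a model to a non-significant effect matrix just
models noise.  The classical multivariate F test is unavailable when J > N,
so significance is assessed by permutation.

The test statistic is the Frobenius sum of squares of the effect matrix.  The
null distribution is obtained by permuting the observation rows against the
design labels and re-estimating the effect each time; for a two-way
interaction the default is a restricted permutation — rows of the
main-effects-removed matrix are permuted and only the interaction is
re-estimated — which preserves the main effects under the null (raw-row
permutation is available behind a flag).

The reported P value uses the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm), so the smallest attainable
value is 1/(1 + n_perm) — e.g. 0.0001 at 10^4 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anova import DesignedDataset, decompose, effect_key, validate_design
from .exceptions import ConfigError, DesignError

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    """Outcome of a permutation test for one effect."""

    effect: str
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    permutation_mode: str = "rows"

    def __repr__(self) -> str:  # compact: the null array is large
        return (
            f"PermutationResult(effect={self.effect!r}, "
            f"observed={self.observed_statistic:.6g}, p={self.p_value:.4g}, "
            f"n_perm={self.n_perm})"
        )


def _level_codes(design, factor):
    labels = design[factor].astype(str)
    levels = sorted(labels.unique())
    lut = {lv: i for i, lv in enumerate(levels)}
    return np.array([lut[v] for v in labels]), len(levels)


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    G = np.zeros((n_levels, codes.size))
    G[codes, np.arange(codes.size)] = 1.0
    return G


def _main_effect_ssq(Xc: np.ndarray, G: np.ndarray, counts: np.ndarray) -> float:
    """SSQ of a main-effect matrix from globally centered data.

    Equals sum_a n_a * ||levelmean_a - grandmean||^2, computed from per-level
    row sums (G is the level indicator matrix).
    """
    sums = G @ Xc
    return float(np.sum(sums**2 / counts[:, None]))


def _interaction_ssq(
    Zc: np.ndarray,
    Gcell: np.ndarray,
    a_of_cell: np.ndarray,
    b_of_cell: np.ndarray,
    Ga_cell: np.ndarray,
    Gb_cell: np.ndarray,
    n_a: int,
    n_b: int,
    reps: int,
) -> float:
    """SSQ of the two-way interaction estimated from (centered) Zc."""
    cell_sums = Gcell @ Zc
    cell_means = cell_sums / reps
    a_means = (Ga_cell @ cell_sums) / (reps * n_b)
    b_means = (Gb_cell @ cell_sums) / (reps * n_a)
    grand = Zc.mean(axis=0)
    inter = cell_means - a_means[a_of_cell] - b_means[b_of_cell] + grand
    return float(reps * np.sum(inter**2))


def permutation_test(
    dataset: DesignedDataset,
    effect: str | tuple[str, ...],
    n_perm: int = 9999,
    seed: int = 0,
    interaction_mode: str = "restricted",
) -> PermutationResult:
    """Permutation test of one effect's multivariate significance.

    Parameters
    ----------
    dataset
        Balanced designed dataset.
    effect
        A factor name, or a 2-tuple of factor names for their interaction.
    n_perm
        Number of permutations, at least 99.
    seed
        Seed for the permutation stream; results are deterministic given it.
    interaction_mode
        "restricted" (default): permute rows of the main-effects-removed
        matrix and re-estimate only the interaction.  "raw": permute rows of
        the centered data directly.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    dataset = validate_design(dataset)
    key = effect_key(effect)
    factors = key.split(":")
    unknown = [f for f in factors if f not in dataset.factor_names]
    if unknown:
        raise DesignError(f"unknown factor(s) {unknown} in effect {key!r}")
    if len(factors) > 2:
        raise ConfigError(
            "permutation validation implemented for main effects and two-way "
            f"interactions; got {key!r}"
        )
    decomp = decompose(dataset, include_interactions=True)
    if key not in decomp.effects:
        raise DesignError(f"effect {key!r} not in decomposition")
    observed = decomp.ssq[key]
    rng = np.random.default_rng(seed)
    X = dataset.X.to_numpy(dtype=float)
    n = X.shape[0]
    null = np.empty(n_perm)

    if len(factors) == 1:
        codes, n_levels = _level_codes(dataset.design, factors[0])
        G = _indicator(codes, n_levels)
        counts = G.sum(axis=1)
        Xc = X - X.mean(axis=0)
        for b in range(n_perm):
            perm = rng.permutation(n)
            null[b] = _main_effect_ssq(Xc[perm], G, counts)
        mode = "rows"
    else:
        fa, fb = factors
        ca, n_a = _level_codes(dataset.design, fa)
        cb, n_b = _level_codes(dataset.design, fb)
        cell_codes = ca * n_b + cb
        a_of_cell = np.repeat(np.arange(n_a), n_b)
        b_of_cell = np.tile(np.arange(n_b), n_a)
        Gcell = _indicator(cell_codes, n_a * n_b)
        Ga_cell = _indicator(a_of_cell, n_a)
        Gb_cell = _indicator(b_of_cell, n_b)
        reps = dataset.replicates
        if interaction_mode == "restricted":
            base = (
                X
                - X.mean(axis=0)
                - decomp.effects[fa].to_numpy()
                - decomp.effects[fb].to_numpy()
            )
        elif interaction_mode == "raw":
            base = X - X.mean(axis=0)
        else:
            raise ConfigError(f"unknown interaction_mode {interaction_mode!r}")
        for b in range(n_perm):
            perm = rng.permutation(n)
            null[b] = _interaction_ssq(
                base[perm], Gcell, a_of_cell, b_of_cell, Ga_cell, Gb_cell,
                n_a, n_b, reps,
            )
        mode = interaction_mode
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(
        effect=key,
        observed_statistic=observed,
        null_statistics=null,
        p_value=p,
        n_perm=int(n_perm),
        seed=int(seed),
        permutation_mode=mode,
    )
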