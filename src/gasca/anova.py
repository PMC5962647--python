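"""Balanced multi-way ANOVA partition of a multivariate feature table.

The central object is the decomposition

    X = 1 m^T + sum_i X_i + E

where ``m`` is the vector of grand means, each effect matrix ``X_i`` holds the
level-mean (or cell-mean, for interactions) deviations for one factor or
factor interaction, and ``E`` collects the replicate variation the model does
not explain.  For a balanced design (every combination of factor levels
observed the same number ``R`` of times) the terms are mutually orthogonal and
the total sum of squares partitions additively, which is what makes the
per-effect component models downstream meaningful.

Effects are estimated as marginal-mean contrasts: a main-effect row is
``level mean - grand mean`` and an interaction row is the cell mean corrected
for all lower-order terms by inclusion-exclusion.  Unbalanced designs are
rejected rather than approximated.

Also provided here are the two preprocessing steps commonly applied to
metabolomics feature tables before decomposition: per-variable median
normalization, and imputation of missing cells by the design-cell mean plus a
normal perturbation with the cell variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError

__all__ = [
    "DesignedDataset",
    "EffectDecomposition",
    "validate_design",
    "impute_missing",
    "median_normalize",
    "decompose",
    "ssq_table",
    "effect_residual_matrix",
    "effect_key",
]


def effect_key(effect: str | tuple[str, ...]) -> str:
    """Canonical string identifier for an effect term.

    Main effects are named by their factor (``"light"``); interactions join
    the factor names with ``":"`` (``"light:time"``).
    """
    if isinstance(effect, str):
        return effect
    return ":".join(effect)


def _effect_factors(effect: str | tuple[str, ...]) -> tuple[str, ...]:
    if isinstance(effect, str):
        return tuple(effect.split(":"))
    return tuple(effect)


@dataclass
class DesignedDataset:
    """A feature table plus the factor levels of a designed experiment.

    Parameters
    ----------
    X
        Observations x variables numeric table.  The index holds observation
        ids, the columns variable names.
    design
        One row per observation (same index as ``X``), one column per factor,
        categorical level labels as strings.
    """

    X: pd.DataFrame
    design: pd.DataFrame
    replicates: int | None = None
    level_counts: dict[str, int] | None = None

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    @property
    def observation_ids(self) -> list[str]:
        return [str(i) for i in self.X.index]

    @property
    def factor_names(self) -> list[str]:
        return [str(c) for c in self.design.columns]

    def levels(self, factor: str) -> list[str]:
        if factor not in self.design.columns:
            raise DesignError(f"unknown factor {factor!r}")
        return sorted(self.design[factor].astype(str).unique())


def validate_design(dataset: DesignedDataset) -> DesignedDataset:
    """Check balance and completeness; annotate R and level counts.

    Returns the dataset with ``replicates`` and ``level_counts`` filled in.

    Raises
    ------
    DesignError
        If the design is unbalanced (the offending cells are named), a factor
        has a single level, or the feature/design indexes disagree.
    DataError
        If the feature table contains missing or non-numeric values.
    """
    X, design = dataset.X, dataset.design
    if not X.index.equals(design.index):
        raise DesignError("feature table and design table have different observation ids")
    if X.index.has_duplicates:
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise DesignError(f"duplicate observation ids: {dups}")
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise DesignError("need at least 2 observations and 2 variables")
    values = X.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataError("feature table contains non-numeric values")
    if np.isnan(values).any():
        n_miss = int(np.isnan(values).sum())
        raise DataError(
            f"feature table contains {n_miss} missing values; "
            "run impute_missing before validation"
        )
    level_counts: dict[str, int] = {}
    for f in dataset.factor_names:
        k = design[f].astype(str).nunique()
        if k < 2:
            raise DesignError(f"factor {f!r} has a single level")
        level_counts[f] = k
    cells = design.astype(str).groupby(dataset.factor_names, observed=False).size()
    n_cells = int(np.prod(list(level_counts.values())))
    present = cells[cells > 0]
    if len(present) != n_cells or present.nunique() != 1:
        bad = cells[cells != cells.max()]
        raise DesignError(
            "unbalanced design: cells with deviating replicate counts: "
            + ", ".join(f"{idx}={n}" for idx, n in bad.items())
        )
    dataset.replicates = int(present.iloc[0])
    dataset.level_counts = level_counts
    return dataset


def impute_missing(
    X_raw: pd.DataFrame,
    design: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Impute missing feature values within design cells.

    Each missing entry is replaced by the mean of its design cell (the
    observations sharing all factor levels) for that variable, plus a draw
    from Normal(0, cell variance).  The cell variance is the unbiased (n-1)
    sample variance of the non-missing values.  Non-missing entries are
    returned untouched; the result is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = X_raw.copy().astype(float)
    factors = list(design.columns)
    cell_labels = design.astype(str)
    values = out.to_numpy()
    for cell, idx in cell_labels.groupby(factors, observed=True).groups.items():
        rows = out.index.get_indexer(idx)
        block = values[rows]
        mask = np.isnan(block)
        if not mask.any():
            continue
        has_missing = mask.any(axis=0)
        n_obs = (~mask).sum(axis=0)
        empty = has_missing & (n_obs == 0)
        if empty.any():
            var = out.columns[np.flatnonzero(empty)[0]]
            raise DataError(
                f"all values missing for variable {var!r} in cell {cell}; cannot impute"
            )
        thin = has_missing & (n_obs == 1)
        if thin.any():
            var = out.columns[np.flatnonzero(thin)[0]]
            raise DataError(
                f"only one value for variable {var!r} in cell {cell}; "
                "need >=2 non-missing values to estimate the cell variance"
            )
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(block, axis=0)
            sd = np.sqrt(np.nanvar(block, axis=0, ddof=1))
        draws = rng.normal(0.0, 1.0, size=block.shape)
        fill = mu[None, :] + sd[None, :] * draws
        block[mask] = fill[mask]
        values[rows] = block
    return pd.DataFrame(values, index=out.index, columns=out.columns)


def median_normalize(X_raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each variable by the median of all its measurements.

    After normalization every column has median exactly 1, putting variables
    measured on very different abundance scales on a common footing.

    Raises
    ------
    DataError
        If a variable's median is zero (division impossible); the variable is
        named in the message.
    """
    medians = X_raw.median(axis=0)
    zero = medians.index[medians == 0].tolist()
    if zero:
        raise DataError(f"zero median for variable(s) {zero}; cannot median-normalize")
    return X_raw / medians


@dataclass
class EffectDecomposition:
    """Result of the balanced ANOVA partition.

    ``effects`` maps canonical effect keys (see :func:`effect_key`) to N x J
    effect matrices; ``ssq`` holds the sum-of-squares bookkeeping for the
    terms ``"mean"``, each effect, and ``"residual"``.
    """

    dataset: DesignedDataset
    grand_mean: pd.Series
    effects: dict[str, pd.DataFrame]
    residual: pd.DataFrame
    ssq: dict[str, float]
    terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def effect_names(self) -> list[str]:
        return list(self.effects)

    def degrees_of_freedom(self, effect: str | tuple[str, ...]) -> int:
        """Model degrees of freedom of a term: prod over its factors of (levels-1)."""
        key = effect_key(effect)
        if key not in self.effects:
            raise DesignError(f"unknown effect {key!r}")
        counts = self.dataset.level_counts or {}
        return int(np.prod([counts[f] - 1 for f in self.terms[key]]))


def _resolve_terms(
    dataset: DesignedDataset,
    include_interactions: bool | list[tuple[str, ...]],
) -> list[tuple[str, ...]]:
    factors = dataset.factor_names
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    if include_interactions is True:
        terms += [tuple(c) for c in itertools.combinations(factors, 2)]
    elif include_interactions is False:
        pass
    else:
        for t in include_interactions:
            t = tuple(t)
            unknown = [f for f in t if f not in factors]
            if unknown:
                raise DesignError(f"interaction {t} names unknown factor(s) {unknown}")
            if len(t) < 2 or len(set(t)) != len(t):
                raise DesignError(f"invalid interaction term {t}")
            terms.append(tuple(f for f in factors if f in t))
    return terms


def decompose(
    dataset: DesignedDataset,
    include_interactions: bool | list[tuple[str, ...]] = True,
) -> EffectDecomposition:
    """Partition X into grand mean, effect matrices and residual.

    Parameters
    ----------
    dataset
        A validated balanced dataset (``validate_design`` is called if the
        replicate annotation is absent).
    include_interactions
        ``True`` for all two-way interactions, ``False`` for main effects
        only, or an explicit list of factor tuples (any order of interaction;
        higher orders are estimated by full inclusion-exclusion).
    """
    if dataset.replicates is None:
        dataset = validate_design(dataset)
    X = dataset.X.astype(float)
    design = dataset.design.astype(str)
    terms = _resolve_terms(dataset, include_interactions)

    grand = X.mean(axis=0)
    centered_mean = pd.DataFrame(
        np.tile(grand.to_numpy(), (len(X), 1)), index=X.index, columns=X.columns
    )

    cell_means: dict[tuple[str, ...], pd.DataFrame] = {(): centered_mean}

    def mean_over(subset: tuple[str, ...]) -> pd.DataFrame:
        if subset not in cell_means:
            by = [design[f] for f in subset]
            cell_means[subset] = X.groupby(by, observed=True).transform("mean")
        return cell_means[subset]

    effects: dict[str, pd.DataFrame] = {}
    term_map: dict[str, tuple[str, ...]] = {}
    for t in terms:
        acc = pd.DataFrame(0.0, index=X.index, columns=X.columns)
        for r in range(len(t) + 1):
            sign = (-1) ** (len(t) - r)
            for sub in itertools.combinations(t, r):
                acc += sign * mean_over(sub)
        key = effect_key(t)
        effects[key] = acc
        term_map[key] = t

    residual = X - centered_mean
    for eff in effects.values():
        residual = residual - eff

    n = len(X)
    ssq = {"mean": float(n * np.sum(grand.to_numpy() ** 2))}
    for key, eff in effects.items():
        ssq[key] = float(np.sum(eff.to_numpy() ** 2))
    ssq["residual"] = float(np.sum(residual.to_numpy() ** 2))
    ssq["total"] = float(np.sum(X.to_numpy() ** 2))

    return EffectDecomposition(
        dataset=dataset,
        grand_mean=grand,
        effects=effects,
        residual=residual,
        ssq=ssq,
        terms=term_map,
    )


def ssq_table(decomp: EffectDecomposition) -> pd.Series:
    """Fraction of the total (uncentered) sum of squares per model term.

    The mean term is reported against the raw total, so for typical
    positive-abundance data it dominates; the fractions sum to 1 for a
    balanced design by orthogonality of the partition.
    """
    total = decomp.ssq["total"]
    order = ["mean", *decomp.effect_names, "residual"]
    return pd.Series({k: decomp.ssq[k] / total for k in order}, name="ssq_fraction")


def effect_residual_matrix(
    decomp: EffectDecomposition, effect: str | tuple[str, ...]
) -> pd.DataFrame:
    """Residual-augmented matrix for one effect: X minus mean and all OTHER terms.

    Equals ``effects[effect] + residual``; for a one-way design this is simply
    the column-centered data.  This is the matrix used both to project scores
    (so replicate variation is visible) and, optionally, to build association
    maps for effects whose effect matrix alone is too degenerate to correlate.
    """
    key = effect_key(effect)
    if key not in decomp.effects:
        raise DesignError(
            f"unknown effect {key!r}; available: {decomp.effect_names}"
        )
    return decomp.effects[key] + decomp.residual
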