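"""ASCA and GASCA model orchestration.

An ASCA model partitions the data by the design (ANOVA), then fits a dense
PCA to each effect matrix.  A GASCA model replaces the dense PCA with
group-wise PCA, inserting two steps per effect: build a variable association
map, and identify groups of associated variables at a user-chosen threshold
gamma; every component of the resulting model then loads on exactly one
group.

Because an effect matrix holds level means, replicate variation is invisible
in its scores.  It is recovered by projecting the residual-augmented matrix
onto the loadings:

    Y_i = (X_i + E) P_i = T_i + E P_i

so that the level centroids of Y_i coincide with the effect scores T_i while
individual observations scatter around them.

Association-map sources.  For a factor with three or more levels the default
map is the significance-filtered Spearman correlation of the effect matrix,
which is intrinsically low noise.  A factor with two levels (or any term with
a single model degree of freedom) produces an effect matrix whose columns
take only two values, so its correlations are a ±1 pattern dictated by the
design, not the data; for such terms the map must be built from the
residual-augmented matrix, where the MEDA construction is the appropriate
noise-attenuating choice.  Both routes can be requested explicitly per
effect.

By default every effect is screened by the permutation test before fitting:
effects whose multivariate significance exceeds ``alpha`` are reported but
not modeled (there is nothing but noise to model), unless ``force=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .anova import (
    DesignedDataset,
    EffectDecomposition,
    decompose,
    effect_residual_matrix,
    validate_design,
)
from .association import AssociationMap, meda_map, select_meda_rank, spearman_map
from .components import ComponentModel, fit_gpca, fit_pca
from .exceptions import ConfigError
from .grouping import GroupSet, identify_groups
from .validation import PermutationResult, permutation_test

__all__ = ["EffectConfig", "EffectModel", "GascaModel", "fit", "project_scores"]


@dataclass
class EffectConfig:
    """Per-effect fitting configuration.

    gamma
        Association threshold for group identification (required in gasca
        mode).
    n_components
        Components to extract; default min(model df, number of groups) in
        gasca mode, min(model df, rank) in asca mode.
    map_method
        "spearman" (effect matrix) or "meda" (residual-augmented matrix);
        default chosen by the degeneracy rule described in the module
        docstring.
    min_size
        Minimum group size; default ceil(sqrt(J)).
    meda_rank
        Rank Q of the MEDA model; default selected by column-wise
        cross-validation (capped at 10).
    spearman_alpha
        Per-pair significance level of the correlation filter.
    """

    gamma: float | None = None
    n_components: int | None = None
    map_method: str | None = None
    min_size: int | None = None
    meda_rank: int | None = None
    spearman_alpha: float = 0.01


@dataclass
class EffectModel:
    """Fitted per-effect results inside a :class:`GascaModel`."""

    effect: str
    components: ComponentModel | None
    projected_scores: pd.DataFrame | None
    association: AssociationMap | None = None
    groups: GroupSet | None = None
    permutation: PermutationResult | None = None
    fitted: bool = True
    note: str = ""


@dataclass
class GascaModel:
    """A fitted ASCA or GASCA model: decomposition plus per-effect models."""

    decomposition: EffectDecomposition
    per_effect: dict[str, EffectModel]
    mode: str
    config: dict = field(default_factory=dict)

    @property
    def effect_names(self) -> list[str]:
        return list(self.per_effect)

    def excluded_effects(self) -> dict[str, float]:
        """Effects screened out by the permutation test, with their P values."""
        return {
            k: m.permutation.p_value
            for k, m in self.per_effect.items()
            if not m.fitted and m.permutation is not None
        }


def project_scores(
    decomp: EffectDecomposition,
    effect: str | tuple[str, ...],
    loadings,
) -> pd.DataFrame:
    """Project the residual-augmented matrix onto a loading set.

    Returns ``(X_i + E) P`` as an observations x components DataFrame.  The
    level centroids of the result equal the effect-matrix scores ``X_i P``
    because the residual has zero mean within every design cell.
    """
    aug = effect_residual_matrix(decomp, effect)
    if isinstance(loadings, pd.DataFrame):
        P = loadings.to_numpy(dtype=float)
        comp_names = [str(c) for c in loadings.columns]
    else:
        P = np.asarray(loadings, dtype=float)
        comp_names = [f"PC{k + 1}" for k in range(P.shape[1])]
    if P.ndim != 2 or P.shape[0] != aug.shape[1]:
        raise ConfigError(
            f"loading matrix shape {P.shape} does not match {aug.shape[1]} variables"
        )
    Y = aug.to_numpy(dtype=float) @ P
    return pd.DataFrame(Y, index=aug.index, columns=comp_names)


def _is_degenerate(decomp: EffectDecomposition, key: str) -> bool:
    """True when the term has a single model degree of freedom.

    Such an effect matrix is rank <= 1 with two-valued columns (e.g. a
    two-level factor), so correlations computed from it are +/-1 by design.
    """
    return decomp.degrees_of_freedom(key) == 1


def _build_map(
    decomp: EffectDecomposition, key: str, cfg: EffectConfig
) -> AssociationMap:
    method = cfg.map_method
    if method is None:
        method = "meda" if _is_degenerate(decomp, key) else "spearman"
    if method == "spearman":
        if _is_degenerate(decomp, key):
            raise ConfigError(
                f"effect {key!r} has a single degree of freedom: its effect-matrix "
                "correlations are a ±1 design artifact; use map_method='meda' "
                "(association from the residual-augmented matrix) instead"
            )
        amap = spearman_map(
            decomp.effects[key], alpha=cfg.spearman_alpha, source_effect=key
        )
    elif method == "meda":
        source = effect_residual_matrix(decomp, key)
        q = cfg.meda_rank
        if q is None:
            max_rank = min(10, min(source.shape) - 1)
            q, _ = select_meda_rank(source, folds=5, max_rank=max_rank)
        amap = meda_map(source, Q=q)
        amap.source_effect = key
    else:
        raise ConfigError(f"unknown map_method {method!r}")
    return amap


def fit(
    dataset: DesignedDataset,
    mode: str = "gasca",
    config: dict[str, EffectConfig] | EffectConfig | None = None,
    include_interactions: bool | list[tuple[str, ...]] = True,
    validate: bool = True,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    force: bool = False,
) -> GascaModel:
    """Fit an ASCA or GASCA model.

    Parameters
    ----------
    dataset
        Balanced designed dataset.
    mode
        "asca" (dense PCA per effect) or "gasca" (group-wise).
    config
        Either a single :class:`EffectConfig` applied to every effect, or a
        mapping from effect key to a per-effect config.  In gasca mode every
        fitted effect needs a gamma.
    include_interactions
        Passed to :func:`gasca.anova.decompose`.
    validate, n_perm, alpha
        Screen each effect with the permutation test at level ``alpha`` before
        fitting; non-significant effects are reported but not modeled.
    force
        Fit every effect regardless of the screening outcome.
    seed
        Seed for the permutation streams (one derived stream per effect).
    """
    if mode not in ("asca", "gasca"):
        raise ConfigError(f"unknown mode {mode!r}")
    dataset = validate_design(dataset)
    decomp = decompose(dataset, include_interactions=include_interactions)

    def cfg_for(key: str) -> EffectConfig:
        if config is None:
            return EffectConfig()
        if isinstance(config, EffectConfig):
            return config
        return config.get(key, EffectConfig())

    perm_results: dict[str, PermutationResult] = {}
    if validate:
        ss = np.random.SeedSequence(seed)
        for i, key in enumerate(decomp.effect_names):
            sub_seed = int(ss.spawn(len(decomp.effect_names))[i].generate_state(1)[0] % (2**31))
            perm_results[key] = permutation_test(
                dataset, key, n_perm=n_perm, seed=sub_seed
            )

    per_effect: dict[str, EffectModel] = {}
    for key in decomp.effect_names:
        cfg = cfg_for(key)
        perm = perm_results.get(key)
        if perm is not None and perm.p_value > alpha and not force:
            per_effect[key] = EffectModel(
                effect=key,
                components=None,
                projected_scores=None,
                permutation=perm,
                fitted=False,
                note=f"not significant (p={perm.p_value:.4g} > {alpha}); not fitted",
            )
            continue
        X_eff = decomp.effects[key]
        df = decomp.degrees_of_freedom(key)
        rank = int(np.linalg.matrix_rank(X_eff.to_numpy()))
        if mode == "asca":
            h = cfg.n_components or max(1, min(df, rank))
            h = min(h, rank)
            comp = fit_pca(X_eff, H=h, center=False)
            per_effect[key] = EffectModel(
                effect=key,
                components=comp,
                projected_scores=project_scores(decomp, key, comp.loadings),
                permutation=perm,
            )
        else:
            if cfg.gamma is None:
                raise ConfigError(
                    f"gasca mode requires gamma for effect {key!r}; inspect "
                    "gamma_sweep output to choose one"
                )
            amap = _build_map(decomp, key, cfg)
            groups = identify_groups(amap, gamma=cfg.gamma, min_size=cfg.min_size)
            if len(groups) == 0:
                per_effect[key] = EffectModel(
                    effect=key,
                    components=None,
                    projected_scores=None,
                    association=amap,
                    groups=groups,
                    permutation=perm,
                    fitted=False,
                    note=f"no variable group found at gamma={cfg.gamma}",
                )
                continue
            h = cfg.n_components or max(1, min(df, len(groups)))
            comp = fit_gpca(X_eff, groups, H=h, center=False)
            per_effect[key] = EffectModel(
                effect=key,
                components=comp,
                projected_scores=project_scores(decomp, key, comp.loadings),
                association=amap,
                groups=groups,
                permutation=perm,
            )

    snapshot = {
        "mode": mode,
        "alpha": alpha,
        "n_perm": n_perm if validate else None,
        "seed": seed,
        "force": force,
        "per_effect": {
            k: asdict(cfg_for(k)) for k in decomp.effect_names
        },
    }
    return GascaModel(
        decomposition=decomp, per_effect=per_effect, mode=mode, config=snapshot
    )
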