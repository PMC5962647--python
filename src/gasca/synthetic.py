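"""Synthetic factorial datasets with planted group structure.

The generator emulates the kind of designed metabolomics experiment the
method targets: a balanced factorial layout in which a small group of
correlated variables responds to one factor, another group to a second
factor, and the remaining variables are uninformative noise.

The default specification is a two-factor design with four and three levels,
eight replicates per cell (96 observations), 50 variables, and two disjoint
planted groups of five variables each: variables 0-4 respond to the first
factor, variables 5-9 to the second, both with level-dependent mean shifts of
three noise standard deviations and within-group noise correlation 0.9
(induced by a shared latent term per observation).  Both factors are
overwhelmingly significant under the permutation test at this effect size.

``simulate_null`` produces pure standard-normal data on a balanced layout,
the reference input for type-I-error studies of the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import DesignedDataset, validate_design
from .exceptions import ConfigError

__all__ = ["PlantedGroup", "SimulationSpec", "simulate_planted", "simulate_null"]


@dataclass
class PlantedGroup:
    """One planted group of co-responding, correlated variables.

    effect_size is the half-range of the level-dependent mean shift in noise
    standard deviations: level offsets are effect_size * linspace(-1, 1, L),
    shared by all group members.  correlation is the target within-group
    correlation of the noise part, induced by a shared latent normal term.
    """

    factor: int
    variables: tuple[int, ...]
    effect_size: float = 3.0
    correlation: float = 0.9


@dataclass
class SimulationSpec:
    """Full specification of a planted-structure simulation."""

    levels: tuple[int, ...] = (4, 3)
    replicates: int = 8
    n_vars: int = 50
    planted: list[PlantedGroup] = field(
        default_factory=lambda: [
            PlantedGroup(factor=0, variables=tuple(range(0, 5))),
            PlantedGroup(factor=1, variables=tuple(range(5, 10))),
        ]
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(lv < 2 for lv in self.levels):
            raise ConfigError("every factor needs at least 2 levels")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        seen: set[int] = set()
        for g in self.planted:
            if g.factor >= len(self.levels):
                raise ConfigError(f"planted group references unknown factor {g.factor}")
            if max(g.variables, default=-1) >= self.n_vars or min(
                g.variables, default=0
            ) < 0:
                raise ConfigError("planted variable index out of range")
            if not 0 <= g.correlation < 1:
                raise ConfigError("within-group correlation must lie in [0, 1)")
            overlap = seen & set(g.variables)
            if overlap:
                raise ConfigError(
                    f"planted variable sets overlap on {sorted(overlap)}"
                )
            seen |= set(g.variables)

    @property
    def n_obs(self) -> int:
        return int(np.prod(self.levels)) * self.replicates


def _factor_labels(levels: tuple[int, ...], replicates: int) -> pd.DataFrame:
    """Balanced full-factorial label table, replicates fastest."""
    names = [f"factor{i + 1}" for i in range(len(levels))]
    grids = np.meshgrid(*[np.arange(lv) for lv in levels], indexing="ij")
    cols = {}
    for i, (name, g) in enumerate(zip(names, grids)):
        codes = np.repeat(g.ravel(), replicates)
        prefix = chr(ord("a") + i)
        cols[name] = [f"{prefix}{c + 1}" for c in codes]
    n = int(np.prod(levels)) * replicates
    index = [f"obs{k + 1:04d}" for k in range(n)]
    return pd.DataFrame(cols, index=index)


def level_offsets(n_levels: int, effect_size: float) -> np.ndarray:
    """Planted per-level mean shifts: effect_size * linspace(-1, 1, L)."""
    return effect_size * np.linspace(-1.0, 1.0, n_levels)


def simulate_planted(
    spec: SimulationSpec | None = None,
) -> tuple[DesignedDataset, dict]:
    """Generate a balanced dataset with planted group-wise structure.

    Returns the dataset and a ground-truth record with, per planted group,
    the owning factor, the member variables and the level offsets, plus the
    exact noiseless signal matrix (for oracle checks of the decomposition).
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    design = _factor_labels(spec.levels, spec.replicates)
    n, j = spec.n_obs, spec.n_vars

    X = rng.normal(0.0, 1.0, size=(n, j))
    signal = np.zeros((n, j))
    truth_groups = []
    factor_codes = {
        i: design.iloc[:, i].str[1:].astype(int).to_numpy() - 1
        for i in range(len(spec.levels))
    }
    for g in spec.planted:
        idx = np.asarray(g.variables)
        # correlated noise: shared latent per observation + independent part
        latent = rng.normal(0.0, 1.0, size=n)
        X[:, idx] = (
            np.sqrt(g.correlation) * latent[:, None]
            + np.sqrt(1.0 - g.correlation) * X[:, idx]
        )
        offsets = level_offsets(spec.levels[g.factor], g.effect_size)
        shift = offsets[factor_codes[g.factor]]
        signal[:, idx] += shift[:, None]
        truth_groups.append(
            {
                "factor": f"factor{g.factor + 1}",
                "variables": [int(v) for v in idx],
                "variable_names": [f"v{v + 1}" for v in idx],
                "level_offsets": [float(o) for o in offsets],
                "effect_size": float(g.effect_size),
                "correlation": float(g.correlation),
            }
        )
    X = spec.noise_sd * X + spec.noise_sd * signal

    var_names = [f"v{k + 1}" for k in range(j)]
    dataset = DesignedDataset(
        X=pd.DataFrame(X, index=design.index, columns=var_names),
        design=design,
    )
    validate_design(dataset)
    truth = {
        "groups": truth_groups,
        "noise_sd": float(spec.noise_sd),
        "signal": pd.DataFrame(
            spec.noise_sd * signal, index=design.index, columns=var_names
        ),
        "n_obs": n,
        "seed": int(spec.seed),
    }
    return dataset, truth


def simulate_null(
    levels: tuple[int, ...] = (4, 3),
    replicates: int = 8,
    n_vars: int = 50,
    seed: int = 0,
) -> DesignedDataset:
    """Balanced design with pure Normal(0, 1) features (no effects at all)."""
    spec = SimulationSpec(
        levels=tuple(levels),
        replicates=replicates,
        n_vars=n_vars,
        planted=[],
        seed=seed,
    )
    dataset, _ = simulate_planted(spec)
    return dataset
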