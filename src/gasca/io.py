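"""Reading and writing feature/design tables and fitted-model bundles.

Feature tables are CSV/TSV with the observation id in the first column and
variable names in the header; design tables carry the same ids plus one
column of categorical level labels per factor.  Observations are aligned by
id, not by row order.  A fitted model is serialized as a directory of plain
CSV/JSON files listed in a ``manifest.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import DesignedDataset, decompose, ssq_table
from .exceptions import DataError
from .model import GascaModel, project_scores

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_bundle",
    "reproject_bundle",
]


def _read_table(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate observation ids {dups}")
    return df


def read_dataset(
    features_path,
    design_path,
    sep: str = ",",
    na_values: tuple[str, ...] = ("", "NA"),
) -> DesignedDataset:
    """Read and id-align a feature table and a design table.

    Missing feature cells ("" or "NA") are read as NaN so they can be imputed
    downstream; non-numeric cells raise with the offending row and column
    named.
    """
    X = pd.read_csv(features_path, sep=sep, index_col=0, na_values=list(na_values),
                    keep_default_na=False)
    X.index = X.index.astype(str)
    if X.index.has_duplicates:
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise DataError(f"{features_path}: duplicate observation ids {dups}")
    for col in X.columns:
        if not np.issubdtype(X[col].dtype, np.number):
            bad = X[col][pd.to_numeric(X[col], errors="coerce").isna() & X[col].notna()]
            if len(bad):
                raise DataError(
                    f"{features_path}: non-numeric value {bad.iloc[0]!r} at "
                    f"row {bad.index[0]!r}, column {col!r}"
                )
            X[col] = pd.to_numeric(X[col], errors="coerce")
    design = _read_table(design_path, sep).astype(str)
    if set(X.index) != set(design.index):
        only_x = sorted(set(X.index) - set(design.index))[:5]
        only_d = sorted(set(design.index) - set(X.index))[:5]
        raise DataError(
            "observation ids differ between feature and design tables "
            f"(only in features: {only_x}; only in design: {only_d})"
        )
    design = design.loc[X.index]
    return DesignedDataset(X=X, design=design)


def write_dataset(
    dataset: DesignedDataset, features_path, design_path, sep: str = ","
) -> None:
    dataset.X.to_csv(features_path, sep=sep, index_label="observation")
    dataset.design.to_csv(design_path, sep=sep, index_label="observation")


def save_model(model: GascaModel, directory) -> Path:
    """Serialize a fitted model to a directory with a manifest.

    Layout: the input tables, per-term effect matrices and SSQ table, and for
    every fitted effect its loadings, scores, projected scores, association
    map, groups and permutation report.  Returns the directory path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    decomp = model.decomposition
    ds = decomp.dataset
    files: dict[str, str] = {}

    def put(df: pd.DataFrame, name: str, index_label="observation"):
        df.to_csv(directory / name, index_label=index_label)
        files[name] = name

    write_dataset(ds, directory / "features.csv", directory / "design.csv")
    files["features.csv"] = "features.csv"
    files["design.csv"] = "design.csv"
    put(ssq_table(decomp).to_frame(), "ssq.csv", index_label="term")
    effects_meta = {}
    for key, eff in decomp.effects.items():
        safe = key.replace(":", "_x_")
        put(eff, f"effect_{safe}.csv")
        effects_meta[key] = f"effect_{safe}.csv"
    put(decomp.residual, "residual.csv")

    per_effect_meta = {}
    for key, em in model.per_effect.items():
        safe = key.replace(":", "_x_")
        meta: dict = {"fitted": em.fitted, "note": em.note}
        if em.permutation is not None:
            meta["permutation"] = {
                "p_value": em.permutation.p_value,
                "observed_statistic": em.permutation.observed_statistic,
                "n_perm": em.permutation.n_perm,
                "seed": em.permutation.seed,
                "mode": em.permutation.permutation_mode,
            }
        if em.association is not None:
            put(em.association.M, f"map_{safe}.csv", index_label="variable")
            meta["association"] = {
                "file": f"map_{safe}.csv",
                "method": em.association.method,
                "params": em.association.params,
            }
        if em.groups is not None:
            gname = f"groups_{safe}.json"
            (directory / gname).write_text(
                json.dumps(
                    {
                        "gamma": em.groups.gamma,
                        "min_size": em.groups.min_size,
                        "groups": em.groups.to_records(),
                    },
                    indent=1,
                )
            )
            files[gname] = gname
            meta["groups"] = gname
        if em.components is not None:
            put(em.components.loadings, f"loadings_{safe}.csv", index_label="variable")
            put(em.components.scores, f"scores_{safe}.csv")
            put(em.projected_scores, f"projected_{safe}.csv")
            meta["components"] = {
                "loadings": f"loadings_{safe}.csv",
                "scores": f"scores_{safe}.csv",
                "projected_scores": f"projected_{safe}.csv",
                "explained_variance": [
                    float(v) for v in em.components.explained_variance
                ],
                "sparsity": [
                    s if isinstance(s, str) else int(s) for s in em.components.sparsity
                ],
            }
        per_effect_meta[key] = meta

    manifest = {
        "tool": "gasca",
        "version": __version__,
        "mode": model.mode,
        "config": model.config,
        "files": files,
        "effects": effects_meta,
        "per_effect": per_effect_meta,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_bundle(directory) -> dict:
    """Load a saved model bundle (manifest plus the tables it lists)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    for name in manifest["files"].values():
        if not (directory / name).exists():
            raise DataError(f"bundle incomplete: {name} missing")
    dataset = read_dataset(directory / "features.csv", directory / "design.csv")
    out = {"manifest": manifest, "dataset": dataset, "per_effect": {}}
    for key, meta in manifest["per_effect"].items():
        entry = dict(meta)
        if "components" in meta:
            entry["loadings"] = pd.read_csv(
                directory / meta["components"]["loadings"], index_col=0
            )
            entry["projected_scores"] = pd.read_csv(
                directory / meta["components"]["projected_scores"], index_col=0
            )
        out["per_effect"][key] = entry
    return out


def reproject_bundle(bundle: dict) -> dict[str, float]:
    """Recompute projected scores from a loaded bundle; return max abs deviation.

    Re-decomposes the stored data and projects the stored loadings; a faithful
    bundle reproduces the stored projections to numerical precision.
    """
    dataset = bundle["dataset"]
    decomp = decompose(dataset)
    devs = {}
    for key, entry in bundle["per_effect"].items():
        if "loadings" not in entry:
            continue
        Y = project_scores(decomp, key, entry["loadings"])
        stored = entry["projected_scores"]
        devs[key] = float(np.max(np.abs(Y.to_numpy() - stored.to_numpy())))
    return devs
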