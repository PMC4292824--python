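"""Configuration, TSV I/O and dataset alignment for the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .posthoc import SurvivalData
from .prep import GenomicMatrix
from .riskmetrics import RiskFactorTable

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_genomic_matrix",
    "write_genomic_matrix",
    "read_clinical_table",
    "intersect_cases",
]


class ConfigError(ValueError):
    """Invalid or missing configuration keys."""


_KNOWN_KEYS = {
    "genomic", "clinical", "mutations", "survival", "gene_sets", "output_dir",
    "m", "n_restarts", "B", "seed",
    "median_min", "mad_min", "top_k", "min_class_fraction", "ridge_penalty",
    "scenario",
}

_REQUIRED_BY_COMMAND = {
    "prep": ["genomic", "output_dir"],
    "cluster": ["genomic", "clinical", "m", "output_dir"],
    "test-het": ["genomic", "clinical", "output_dir"],
    "test-k": ["genomic", "clinical", "m", "output_dir"],
    "posthoc": ["genomic", "clinical", "output_dir"],
    "simulate": ["scenario", "output_dir"],
}

_DEFAULTS = {
    "m": 2,
    "n_restarts": 100,
    "B": 1000,
    "seed": 0,
    "median_min": 5.0,
    "mad_min": 1.25,
    "top_k": 1000,
    "min_class_fraction": 0.05,
    "ridge_penalty": 1e-4,
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(raw=raw, path=path)

    def require(self, command: str) -> None:
        missing = [k for k in _REQUIRED_BY_COMMAND[command] if k not in self.raw]
        if missing:
            raise ConfigError(f"missing required config keys for {command}: {missing}")

    def get(self, key: str, default=None):
        if key in self.raw:
            return self.raw[key]
        if key in _DEFAULTS:
            return _DEFAULTS[key]
        return default

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: failed to parse TSV: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids: {dupes[:5]}")
    return df


def read_genomic_matrix(
    path,
    orientation: str = "samples_x_features",
    platform: str = "expression",
) -> GenomicMatrix:
    """Read a TSV matrix with a header row and leading ID column."""
    if orientation not in ("samples_x_features", "features_x_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)].tolist()
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns: {non_numeric[:5]}")
    if orientation == "features_x_samples":
        df = df.T
    return GenomicMatrix(df.astype(float), platform)


def write_genomic_matrix(M: GenomicMatrix, path) -> None:
    M.values.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical_table(
    path,
    categorical: dict[str, list[str]],
    continuous: list[str],
    dropna: bool = True,
) -> tuple[RiskFactorTable, int]:
    """Read the clinical TSV; returns the complete-case table and the
    number of incomplete rows dropped."""
    df = _read_tsv(path)
    cols = list(categorical) + list(continuous)
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing clinical columns: {missing_cols}")
    n0 = len(df)
    if dropna:
        df = df.dropna(subset=cols)
    return RiskFactorTable(df, categorical, continuous), n0 - len(df)


def intersect_cases(
    genomic: GenomicMatrix,
    clinical: pd.DataFrame,
    clinical_cols: list[str] | None = None,
    mutations: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
) -> tuple[dict, dict]:
    """Complete-case intersection of all supplied inputs on sample ids.

    Returns ``(aligned, report)`` where ``aligned`` holds the row-subset
    inputs in a common id order and ``report`` counts the drops per reason.
    """
    gen_ids = pd.Index(genomic.sample_ids)
    report = {"genomic_input": len(gen_ids), "clinical_input": len(clinical)}

    cols = clinical_cols or clinical.columns.tolist()
    complete = clinical.dropna(subset=[c for c in cols if c in clinical.columns])
    report["clinical_incomplete"] = len(clinical) - len(complete)

    common = gen_ids.intersection(complete.index)
    report["unmatched_genomic"] = int(len(gen_ids) - len(common))
    report["unmatched_clinical"] = int(len(complete) - len(common))

    tables = {"mutations": mutations, "survival": survival}
    for name, tab in tables.items():
        if tab is not None:
            report[f"{name}_input"] = len(tab)
            before = len(common)
            common = common.intersection(tab.dropna().index)
            report[f"dropped_vs_{name}"] = int(before - len(common))
    if len(common) == 0:
        raise ValueError("empty case intersection across inputs")
    report["aligned"] = int(len(common))

    aligned = {
        "genomic": GenomicMatrix(genomic.values.loc[common], genomic.platform,
                                 genomic.chromosome),
        "clinical": complete.loc[common],
    }
    if mutations is not None:
        aligned["mutations"] = mutations.loc[common]
    if survival is not None:
        sdf = survival.loc[common]
        aligned["survival"] = SurvivalData(
            time=sdf["time"].to_numpy(dtype=float),
            event=sdf["event"].to_numpy(dtype=int),
        )
    return aligned, report
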