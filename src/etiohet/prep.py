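"""Genomic matrix preprocessing: filtering, standardization, merging and
feature selection."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "GenomicMatrix",
    "filter_expression",
    "standardize_and_merge",
    "top_variable_features",
]

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "23", "24"}


@dataclasses.dataclass(frozen=True)
class GenomicMatrix:
    """Samples x features matrix for one genomic platform.

    ``values`` is indexed by sample id with feature ids as columns;
    ``chromosome`` (optional) maps feature id to chromosome name.
    """

    values: pd.DataFrame
    platform: str
    chromosome: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("expression", "methylation", "copy_number"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("matrix entries must be finite")

    @property
    def sample_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def feature_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _mad(x: np.ndarray) -> np.ndarray:
    """Raw median absolute deviation per column (no consistency factor)."""
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def filter_expression(
    M: GenomicMatrix,
    counts: pd.DataFrame,
    median_min: float = 5.0,
    mad_min: float = 1.25,
) -> tuple[GenomicMatrix, dict]:
    """Drop low-abundance and low-variability expression features.

    A feature is retained when its median on the count scale is at least
    ``median_min`` AND the MAD of its analysis-scale values is at least
    ``mad_min``.  Returns the filtered matrix and a report of removals per
    rule (a feature failing both rules counts under the median rule).
    """
    feats = M.values.columns
    if not feats.isin(counts.columns).all():
        missing = feats[~feats.isin(counts.columns)].tolist()
        raise ValueError(f"features absent from count matrix: {missing[:5]}")
    med = counts[feats].median(axis=0).to_numpy(dtype=float)
    mad = _mad(M.values.to_numpy(dtype=float))
    keep_med = med >= median_min
    keep_mad = mad >= mad_min
    keep = keep_med & keep_mad
    if not keep.any():
        raise ValueError("all features removed by expression filters")
    report = {
        "input_features": len(feats),
        "removed_low_median": int((~keep_med).sum()),
        "removed_low_mad": int((keep_med & ~keep_mad).sum()),
        "retained": int(keep.sum()),
    }
    out = GenomicMatrix(M.values.loc[:, keep], M.platform,
                        None if M.chromosome is None else M.chromosome[feats[keep]])
    return out, report


def standardize_and_merge(panels: list[GenomicMatrix]) -> GenomicMatrix:
    """Standardize each panel feature-wise and merge on common features.

    Features are z-scored (mean 0, SD 1, population SD) across each panel's
    samples.  Zero-variance features are dropped with a warning before
    intersecting.  Sex-chromosome features are excluded whenever chromosome
    annotation is available.
    """
    if not panels:
        raise ValueError("no panels supplied")
    platform = panels[0].platform
    if any(p.platform != platform for p in panels):
        raise ValueError("panels must share a platform type")

    standardized: list[pd.DataFrame] = []
    chrom: dict = {}
    for p in panels:
        vals = p.values
        sd = vals.std(axis=0, ddof=0)
        dead = sd.index[sd == 0]
        if len(dead):
            warnings.warn(f"dropping {len(dead)} zero-variance features", stacklevel=2)
            vals = vals.drop(columns=dead)
            sd = sd.drop(dead)
        standardized.append((vals - vals.mean(axis=0)) / sd)
        if p.chromosome is not None:
            chrom.update(p.chromosome.to_dict())

    common = standardized[0].columns
    for df in standardized[1:]:
        common = common.intersection(df.columns)
    if chrom:
        common = common[[chrom.get(f) not in SEX_CHROMOSOMES for f in common]]
    if len(common) == 0:
        raise ValueError("no common features across panels after filtering")

    merged = pd.concat([df[common] for df in standardized], axis=0)
    if merged.index.has_duplicates:
        raise ValueError("panels share sample ids; cannot merge")
    ann = pd.Series({f: chrom[f] for f in common if f in chrom}) if chrom else None
    return GenomicMatrix(merged, platform, ann)


def top_variable_features(M: GenomicMatrix, k: int = 1000, measure: str = "sd") -> GenomicMatrix:
    """Keep the k most variable features (default measure: SD).

    Ties are broken deterministically by feature-id order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if measure == "sd":
        score = M.values.std(axis=0, ddof=0)
    elif measure == "mad":
        score = pd.Series(_mad(M.values.to_numpy(dtype=float)), index=M.values.columns)
    else:
        raise ValueError(f"unknown variability measure {measure!r}")
    if k >= M.shape[1]:
        return M
    order = score.sort_values(ascending=False, kind="stable")
    keep = order.index[:k]
    keep = [f for f in M.values.columns if f in set(keep)]  # preserve input order
    return GenomicMatrix(M.values[keep], M.platform,
                         None if M.chromosome is None else M.chromosome[keep])
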