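"""Synthetic populations and case-only datasets with known sub-type
structure.

The risk model is a multinomial logit on the covariates: individual i has
sub-type incidence rates r_ji = exp(log_baseline_j + x_i . beta_j), so the
exact membership probabilities u_ji = r_ji / r_i, the class proportions and
the population heterogeneity D are all available in closed form as oracles.
Cases arise by risk-biased sampling: individual i becomes a case with
probability proportional to its total risk r_i, and its sub-type is drawn
from u_ji.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .posthoc import SurvivalData
from .prep import GenomicMatrix
from .riskmetrics import RiskFactorTable

__all__ = [
    "CategoricalCovariate",
    "ContinuousCovariate",
    "ScenarioConfig",
    "SyntheticTruth",
    "rates_for",
    "generate_population",
    "sample_cases",
    "generate_genomic",
    "generate_mutations",
    "generate_survival",
]


@dataclasses.dataclass(frozen=True)
class CategoricalCovariate:
    """Population distribution and per-sub-type log-rate effects.

    ``effects`` has shape (m, n_levels); column 0 (the reference level)
    should be zero.
    """

    levels: Sequence[str]
    pop_freqs: Sequence[float]
    effects: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.pop_freqs, dtype=float)
        eff = np.asarray(self.effects, dtype=float)
        object.__setattr__(self, "effects", eff)
        if len(freqs) != len(self.levels) or eff.shape[1] != len(self.levels):
            raise ValueError("levels, pop_freqs and effects disagree on level count")
        if np.any(freqs < 0) or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("pop_freqs must be a probability vector")


@dataclasses.dataclass(frozen=True)
class ContinuousCovariate:
    mean: float
    sd: float
    effects: np.ndarray  # length m, log-rate slope per sub-type

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    m: int
    n_population: int
    n_cases: int
    log_baseline: np.ndarray  # length m
    categorical: Mapping[str, CategoricalCovariate] = dataclasses.field(default_factory=dict)
    continuous: Mapping[str, ContinuousCovariate] = dataclasses.field(default_factory=dict)
    # genomic block
    n_features: int = 100
    signal_fraction: float = 0.2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    # optional second planted partition (own block of signal features)
    second_partition_classes: int = 0
    second_effect_size: float = 0.0
    second_signal_fraction: float = 0.0
    # mutations / survival
    mutation_freqs: np.ndarray | None = None  # genes x m
    hazards: np.ndarray | None = None  # length m
    censor_tmax: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lb = np.asarray(self.log_baseline, dtype=float)
        object.__setattr__(self, "log_baseline", lb)
        if self.m < 1 or len(lb) != self.m:
            raise ValueError("log_baseline must have length m >= 1")
        if self.n_population < 1 or self.n_cases < 1 or self.n_features < 1:
            raise ValueError("dimensions must be positive")
        for name, cov in self.categorical.items():
            if cov.effects.shape[0] != self.m:
                raise ValueError(f"covariate {name!r} effects must have m rows")
        for name, cov in self.continuous.items():
            if len(cov.effects) != self.m:
                raise ValueError(f"covariate {name!r} effects must have length m")
        if not (0 <= self.signal_fraction <= 1 and 0 <= self.second_signal_fraction <= 1):
            raise ValueError("signal fractions must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    covariates: pd.DataFrame
    r: np.ndarray  # n x m incidence rates
    config: ScenarioConfig

    @property
    def u(self) -> np.ndarray:
        return self.r / self.r.sum(axis=1, keepdims=True)


def rates_for(cfg: ScenarioConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Exact per-individual sub-type rates for given covariate rows."""
    n = len(covariates)
    log_r = np.tile(cfg.log_baseline, (n, 1))
    for name, cov in cfg.categorical.items():
        idx = pd.Categorical(covariates[name].astype(str),
                             categories=list(map(str, cov.levels))).codes
        if (idx < 0).any():
            raise ValueError(f"covariate {name!r} has values outside its levels")
        log_r += cov.effects.T[idx]
    for name, cov in cfg.continuous.items():
        x = covariates[name].to_numpy(dtype=float)
        log_r += np.outer(x, cov.effects)
    r = np.exp(log_r)
    if not np.all(np.isfinite(r)) or np.all(r == 0):
        raise ValueError("degenerate rate matrix")
    return r


def generate_population(cfg: ScenarioConfig, seed: int | None = None) -> SyntheticTruth:
    """Draw a population of covariates and compute its exact rate matrix."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    data = {}
    for name, cov in cfg.categorical.items():
        data[name] = rng.choice(list(map(str, cov.levels)), size=cfg.n_population,
                                p=np.asarray(cov.pop_freqs, dtype=float))
    for name, cov in cfg.continuous.items():
        data[name] = rng.normal(cov.mean, cov.sd, size=cfg.n_population)
    covariates = pd.DataFrame(data, index=[f"ind{i}" for i in range(cfg.n_population)])
    r = rates_for(cfg, covariates)
    return SyntheticTruth(covariates=covariates, r=r, config=cfg)


def sample_cases(
    truth: SyntheticTruth,
    N: int,
    seed: int,
    replace: bool = False,
) -> tuple[RiskFactorTable, np.ndarray]:
    """Risk-biased case sampling.

    Individual i is sampled with probability proportional to r_i; the
    sampled case's sub-type is drawn from its membership probabilities.
    Returns the case risk-factor table (case ids ``case0..``) and the true
    sub-type labels.
    """
    n = truth.r.shape[0]
    if not replace and N > n:
        raise ValueError("cannot sample more cases than individuals without replacement")
    rng = np.random.default_rng(seed)
    ri = truth.r.sum(axis=1)
    p = ri / ri.sum()
    idx = rng.choice(n, size=N, replace=replace, p=p)
    u = truth.u[idx]
    labels = np.array([rng.choice(truth.config.m, p=row) for row in u])
    cfg = truth.config
    df = truth.covariates.iloc[idx].copy()
    df.index = [f"case{i}" for i in range(N)]
    risk = RiskFactorTable(
        data=df,
        categorical={name: list(map(str, cov.levels)) for name, cov in cfg.categorical.items()},
        continuous=list(cfg.continuous),
    )
    return risk, labels


def generate_genomic(
    labels: np.ndarray,
    cfg: ScenarioConfig,
    seed: int,
    second_labels: np.ndarray | None = None,
) -> GenomicMatrix:
    """Gaussian noise with per-sub-type mean shifts on signal features.

    The signal features are split evenly among the sub-types; sub-type j is
    shifted by ``effect_size`` on its own slice.  When ``second_labels`` is
    given, an independent block of ``second_signal_fraction`` features
    carries shifts of ``second_effect_size`` for that partition (used for
    the G-versus-D* divergence scenario).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    N = len(labels)
    p = cfg.n_features
    X = rng.normal(0.0, cfg.noise_sd, size=(N, p))
    n_signal = int(round(cfg.signal_fraction * p))
    if n_signal and cfg.effect_size:
        per = max(1, n_signal // cfg.m)
        for j in range(cfg.m):
            lo, hi = j * per, min((j + 1) * per, n_signal)
            if lo >= hi:
                break
            X[labels == j, lo:hi] += cfg.effect_size
    if second_labels is not None:
        second_labels = np.asarray(second_labels)
        n2 = int(round(cfg.second_signal_fraction * p))
        m2 = cfg.second_partition_classes or len(np.unique(second_labels))
        if n2 and cfg.second_effect_size:
            start = n_signal
            per = max(1, n2 // m2)
            for j in range(m2):
                lo = start + j * per
                hi = min(start + (j + 1) * per, start + n2, p)
                if lo >= hi:
                    break
                X[second_labels == j, lo:hi] += cfg.second_effect_size
    df = pd.DataFrame(X, index=[f"case{i}" for i in range(N)],
                      columns=[f"g{k}" for k in range(p)])
    return GenomicMatrix(df, "expression")


def generate_mutations(labels: np.ndarray, cfg: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Bernoulli mutation matrix with per-sub-type gene frequencies."""
    if cfg.mutation_freqs is None:
        raise ValueError("config has no mutation frequencies")
    freqs = np.asarray(cfg.mutation_freqs, dtype=float)  # genes x m
    if freqs.shape[1] != cfg.m:
        raise ValueError("mutation_freqs must have one column per sub-type")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    probs = freqs.T[labels]  # N x genes
    muts = (rng.random(probs.shape) < probs).astype(int)
    return pd.DataFrame(muts, index=[f"case{i}" for i in range(len(labels))],
                        columns=[f"mut{k}" for k in range(freqs.shape[0])])


def generate_survival(labels: np.ndarray, cfg: ScenarioConfig, seed: int) -> SurvivalData:
    """Exponential survival with per-sub-type hazards, uniform censoring."""
    if cfg.hazards is None:
        raise ValueError("config has no survival hazards")
    hz = np.asarray(cfg.hazards, dtype=float)
    if len(hz) != cfg.m or np.any(hz <= 0):
        raise ValueError("hazards must be positive, one per sub-type")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(1.0 / hz[labels])
    t_cens = rng.uniform(0.0, cfg.censor_tmax, size=len(labels))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-12)  # guard strictly positive
    return SurvivalData(time=time, event=event)
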