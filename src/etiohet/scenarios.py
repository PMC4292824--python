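"""Packaged synthetic scenarios used by the acceptance checks and examples.

Each builder returns everything needed to run the pipeline end to end with
known ground truth: the case risk-factor table, the genomic matrix and the
planted labels.
"""

from __future__ import annotations

import numpy as np

from .riskmetrics import RiskFactorTable
from .synthdata import (
    CategoricalCovariate,
    ScenarioConfig,
    generate_genomic,
    generate_population,
    sample_cases,
)

__all__ = [
    "null_dataset",
    "planted_three_subtypes",
    "orthogonal_partitions",
]


def null_dataset(seed: int, n_cases: int = 200, n_features: int = 100):
    """Risk factors independent of the genomic structure (pure noise X)."""
    cfg = ScenarioConfig(
        m=2,
        n_population=4 * n_cases,
        n_cases=n_cases,
        log_baseline=np.log([0.01, 0.01]),
        categorical={
            "smoking": CategoricalCovariate(
                levels=["never", "former", "current"],
                pop_freqs=[0.5, 0.3, 0.2],
                effects=np.zeros((2, 3)),
            ),
            "gender": CategoricalCovariate(
                levels=["male", "female"],
                pop_freqs=[0.6, 0.4],
                effects=np.zeros((2, 2)),
            ),
        },
        n_features=n_features,
        effect_size=0.0,
        seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    s_pop, s_case, s_gen = (int(x) for x in ss.generate_state(3))
    truth = generate_population(cfg, seed=s_pop)
    risk, labels = sample_cases(truth, n_cases, seed=s_case)
    X = generate_genomic(labels, cfg, seed=s_gen).to_array()
    return X, risk, labels


def planted_three_subtypes(seed: int, n_cases: int = 240, n_features: int = 150):
    """Three sub-types with genomic mean shifts and distinct risk profiles."""
    cfg = ScenarioConfig(
        m=3,
        n_population=8 * n_cases,
        n_cases=n_cases,
        log_baseline=np.log([0.01, 0.01, 0.01]),
        categorical={
            "smoking": CategoricalCovariate(
                levels=["never", "former", "current"],
                pop_freqs=[0.4, 0.3, 0.3],
                effects=np.array([
                    [0.0, 0.0, 0.0],
                    [0.0, 1.2, 2.0],
                    [0.0, -1.2, -2.0],
                ]),
            ),
            "hypertension": CategoricalCovariate(
                levels=["no", "yes"],
                pop_freqs=[0.5, 0.5],
                effects=np.array([[0.0, 0.0], [0.0, -1.5], [0.0, 1.5]]),
            ),
        },
        n_features=n_features,
        signal_fraction=0.2,
        effect_size=3.0,
        seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    s_pop, s_case, s_gen = (int(x) for x in ss.generate_state(3))
    truth = generate_population(cfg, seed=s_pop)
    risk, labels = sample_cases(truth, n_cases, seed=s_case)
    X = generate_genomic(labels, cfg, seed=s_gen).to_array()
    return X, risk, labels


def orthogonal_partitions(seed: int, n_cases: int = 200, n_features: int = 100):
    """Two orthogonal planted 2-partitions; only one is risk-associated.

    Partition A carries the larger genomic signal (highest G) but is
    independent of the risk factors; partition B carries a weaker genomic
    signal and a strong covariate shift.  Returns
    (X, risk, labels_A, labels_B).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    cfg = ScenarioConfig(
        m=2,
        n_population=8 * n_cases,
        n_cases=n_cases,
        log_baseline=np.log([0.01, 0.01]),
        categorical={
            # symmetric effects keep the case class proportions near 1:1
            "smoking": CategoricalCovariate(
                levels=["never", "former", "current"],
                pop_freqs=[0.4, 0.3, 0.3],
                effects=np.array([[0.0, -0.8, -1.5], [0.0, 0.8, 1.5]]),
            ),
            "hypertension": CategoricalCovariate(
                levels=["no", "yes"],
                pop_freqs=[0.5, 0.5],
                effects=np.array([[0.0, -1.0], [0.0, 1.0]]),
            ),
        },
        n_features=n_features,
        signal_fraction=0.3,       # block B: risk-linked partition
        effect_size=2.0,
        second_partition_classes=2,
        second_signal_fraction=0.3,  # block A: higher-variance partition
        second_effect_size=2.2,
        seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    s_pop, s_case, s_gen = (int(x) for x in ss.generate_state(3))
    truth = generate_population(cfg, seed=s_pop)
    risk, labels_B = sample_cases(truth, n_cases, seed=s_case)
    labels_A = rng.permutation(np.repeat([0, 1], n_cases // 2))
    M = generate_genomic(labels_B, cfg, seed=s_gen, second_labels=labels_A)
    return M.to_array(), risk, labels_A, labels_B
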