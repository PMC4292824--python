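"""Permutation tests for the presence of heterogeneity and for the number
of sub-types.

Both tests re-pair the risk-factor rows with the genomic rows by random
permutation, which defines the absence of a true signal: the partitions of
the genomic matrix are unchanged by the permutation, so the ensemble of
k-means local maxima is computed once and re-scored against each permuted
pairing with the full restart budget implicit.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .hetclust import (
    SolutionEnsemble,
    _one_hot,
    run_restarted_kmeans,
    score_ensemble,
    select_solution,
)
from .riskmetrics import RiskFactorTable, _dstar_batch

__all__ = ["PermutationTestResult", "heterogeneity_test", "incremental_test"]


@dataclasses.dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    null_draws: np.ndarray
    p_value: float
    B: int
    seed: int
    config_echo: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_draws", np.asarray(self.null_draws, dtype=float))
        if len(self.null_draws) != self.B:
            raise ValueError("null_draws must have length B")

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "null_draws": self.null_draws.tolist(),
            "config_echo": self.config_echo,
        }


def _perm_pvalue(observed: float, null_draws: np.ndarray) -> float:
    return float((1 + np.sum(null_draws >= observed)) / (1 + len(null_draws)))


def _admissible(ensemble: SolutionEnsemble):
    return [s for s in ensemble.solutions if s.admissible and s.D_star is not None]


def _max_dstar_draws(
    solutions,
    Z: np.ndarray,
    ridge: float,
    perms: np.ndarray,
) -> np.ndarray:
    """Optimal D* over the ensemble for each row re-pairing of Z.

    ``perms`` is n_draws x n (a row of ``arange(n)`` is the identity
    pairing).  Re-pairing Z rows by ``perm`` is equivalent to carrying the
    one-hot labels through the inverse permutation, which lets all draws of
    one solution share the design matrix in a single batched fit.
    Admissibility depends only on class sizes and is unchanged by
    permutation, so only previously admissible solutions are re-scored;
    fits that fail to converge are skipped for that draw.
    """
    n_draws, n = perms.shape
    inv = np.empty_like(perms)
    rows = np.arange(n)
    for b in range(n_draws):
        inv[b, perms[b]] = rows
    best = np.full(n_draws, -np.inf)
    for sol in solutions:
        Y = _one_hot(sol.labels)
        Ys = Y[inv]  # n_draws x n x m
        d = _dstar_batch(Z, Ys, ridge=ridge)
        best = np.fmax(best, d)
    if not np.all(np.isfinite(best)):
        raise RuntimeError("no solution could be scored under some permutation")
    return best


def _prepare(X, risk, m, n_restarts, seed, min_class_fraction, ridge):
    ens = run_restarted_kmeans(X, m=m, n_restarts=n_restarts, seed=seed)
    score_ensemble(ens, risk, min_class_fraction=min_class_fraction, ridge_penalty=ridge)
    sols = _admissible(ens)
    if not sols:
        raise ValueError(f"no admissible scored solutions for m={m}")
    return ens, sols


def heterogeneity_test(
    X: np.ndarray,
    risk: RiskFactorTable,
    m: int = 2,
    B: int = 1000,
    n_restarts: int = 100,
    seed: int = 0,
    min_class_fraction: float = 0.05,
    ridge_penalty: float = 1e-4,
) -> PermutationTestResult:
    """Test for the presence of etiologic heterogeneity.

    The observed statistic is the optimal (maximal admissible) D* for the
    ``m``-class analysis on the real genomic/risk pairing; the null draws
    permute the pairing and recompute the optimum.
    """
    if B < 19:
        raise ValueError("need B >= 19 permutations")
    ss = np.random.SeedSequence(seed)
    km_seed, perm_seed = (int(s) for s in ss.generate_state(2))
    ens, sols = _prepare(X, risk, m, n_restarts, km_seed, min_class_fraction, ridge_penalty)
    observed = select_solution(ens, "max_D_star").D_star

    Xd, _ = risk.design_matrix()
    Z = np.column_stack([np.ones(len(Xd)), Xd])
    rng = np.random.default_rng(perm_seed)
    perms = np.stack([rng.permutation(Z.shape[0]) for _ in range(B)])
    null = _max_dstar_draws(sols, Z, ridge_penalty, perms)
    return PermutationTestResult(
        observed=float(observed),
        null_draws=null,
        p_value=_perm_pvalue(float(observed), null),
        B=B,
        seed=seed,
        config_echo={"m": m, "n_restarts": n_restarts,
                     "min_class_fraction": min_class_fraction,
                     "ridge_penalty": ridge_penalty},
    )


def incremental_test(
    X: np.ndarray,
    risk: RiskFactorTable,
    m_small: int = 2,
    B: int = 1000,
    n_restarts: int = 100,
    seed: int = 0,
    min_class_fraction: float = 0.05,
    ridge_penalty: float = 1e-4,
) -> PermutationTestResult:
    """Test whether ``m_small + 1`` sub-types add significant heterogeneity.

    The observed statistic is the difference of the optimal D* values for
    the two class counts; each permutation recomputes both optima on the
    permuted pairing and takes the difference.
    """
    if m_small < 2:
        raise ValueError("need m_small >= 2")
    if B < 19:
        raise ValueError("need B >= 19 permutations")
    ss = np.random.SeedSequence(seed)
    seed_small, seed_big, perm_seed = (int(s) for s in ss.generate_state(3))
    _, sols_small = _prepare(X, risk, m_small, n_restarts, seed_small,
                             min_class_fraction, ridge_penalty)
    _, sols_big = _prepare(X, risk, m_small + 1, n_restarts, seed_big,
                           min_class_fraction, ridge_penalty)

    Xd, _ = risk.design_matrix()
    Z = np.column_stack([np.ones(len(Xd)), Xd])
    identity = np.arange(Z.shape[0])[None, :]
    observed = float(_max_dstar_draws(sols_big, Z, ridge_penalty, identity)[0]
                     - _max_dstar_draws(sols_small, Z, ridge_penalty, identity)[0])

    rng = np.random.default_rng(perm_seed)
    perms = np.stack([rng.permutation(Z.shape[0]) for _ in range(B)])
    null = (_max_dstar_draws(sols_big, Z, ridge_penalty, perms)
            - _max_dstar_draws(sols_small, Z, ridge_penalty, perms))
    return PermutationTestResult(
        observed=float(observed),
        null_draws=null,
        p_value=_perm_pvalue(float(observed), null),
        B=B,
        seed=seed,
        config_echo={"m_small": m_small, "m_big": m_small + 1,
                     "n_restarts": n_restarts,
                     "min_class_fraction": min_class_fraction,
                     "ridge_penalty": ridge_penalty},
    )
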