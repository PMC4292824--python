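"""Candidate partition generation and supervised solution selection.

Restarted k-means produces an ensemble of local-maximum partitions of the
genomic profiles; each is scored both by the between-cluster dissimilarity
``G`` (the quantity k-means itself maximizes) and by the case-only
heterogeneity statistic ``D*`` obtained from the risk-factor model, and a
solution is selected under either criterion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from sklearn.cluster import KMeans
from threadpoolctl import threadpool_limits

from .riskmetrics import (
    MembershipMatrix,
    RiskFactorTable,
    compute_D_star,
    _dstar_batch,
    _fit_multinomial_core,
)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    classes, y = np.unique(labels, return_inverse=True)
    Y = np.zeros((len(y), len(classes)))
    Y[np.arange(len(y)), y] = 1.0
    return Y

__all__ = [
    "ClusterSolution",
    "SolutionEnsemble",
    "canonicalize_labels",
    "run_restarted_kmeans",
    "compute_G",
    "score_ensemble",
    "select_solution",
    "random_benchmark",
]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber classes by order of first appearance (0-based)."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping)
        out[i] = mapping[key]
    return out


@dataclasses.dataclass
class ClusterSolution:
    labels: np.ndarray
    m: int
    G: float
    D_star: float | None = None
    seeds: list[int] = dataclasses.field(default_factory=list)
    admissible: bool = True
    unscored_reason: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.array_equal(self.labels, canonicalize_labels(self.labels)):
            raise ValueError("labels must be in canonical first-appearance form")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        sizes = np.bincount(self.labels, minlength=self.m)
        if sizes.min() < 1:
            raise ValueError("every class must be non-empty")

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.m)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "m": self.m,
            "G": self.G,
            "D_star": self.D_star,
            "seeds": list(self.seeds),
            "admissible": self.admissible,
            "unscored_reason": self.unscored_reason,
        }


@dataclasses.dataclass
class SolutionEnsemble:
    solutions: list[ClusterSolution]
    n_restarts: int
    X_fingerprint: str

    def __post_init__(self) -> None:
        keys = {sol.labels.tobytes() for sol in self.solutions}
        if len(keys) != len(self.solutions):
            raise ValueError("ensemble contains duplicate partitions")
        if len(self.solutions) > self.n_restarts:
            raise ValueError("more unique solutions than restarts")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_restarts": self.n_restarts,
                "X_fingerprint": self.X_fingerprint,
                "solutions": [sol.to_dict() for sol in self.solutions],
            },
            sort_keys=True,
        )


def fingerprint_matrix(X: np.ndarray) -> str:
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    h = hashlib.sha256()
    h.update(str(X.shape).encode())
    h.update(X.tobytes())
    return h.hexdigest()


def compute_G(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster sum of squares: sum_j n_j * ||mean_j - mean||^2."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match number of samples")
    grand = X.mean(axis=0)
    G = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        diff = X[mask].mean(axis=0) - grand
        G += mask.sum() * float(diff @ diff)
    return G


def _polish_to_local_maximum(X: np.ndarray, labels: np.ndarray, m: int) -> np.ndarray:
    """Single-point reassignment passes until no move increases G.

    Lloyd fixed points need not be stable to individual reassignments
    (moving a point changes the centroids); this exchange polish makes
    every returned partition a genuine local maximum of the between-cluster
    dissimilarity.  Uses the exact within-SS change for moving x from
    cluster a (size n_a) to b: n_b/(n_b+1)*||x-c_b||^2 - n_a/(n_a-1)*||x-c_a||^2.
    """
    labels = labels.copy()
    n = X.shape[0]
    sizes = np.bincount(labels, minlength=m).astype(float)
    centroids = np.stack([X[labels == j].mean(axis=0) for j in range(m)])
    rows = np.arange(n)
    for _ in range(100 * n):  # each move strictly decreases WSS; terminates
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)  # n x m
        own = labels
        removal = sizes[own] / np.maximum(sizes[own] - 1, 1e-12) * d2[rows, own]
        addition = sizes[None, :] / (sizes[None, :] + 1) * d2
        gain = removal[:, None] - addition  # WSS decrease if moved
        gain[rows, own] = -np.inf
        gain[sizes[own] <= 1] = -np.inf  # never empty a cluster
        i, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[i, b] <= 1e-9:
            break
        a = labels[i]
        centroids[a] = (centroids[a] * sizes[a] - X[i]) / (sizes[a] - 1)
        centroids[b] = (centroids[b] * sizes[b] + X[i]) / (sizes[b] + 1)
        sizes[a] -= 1
        sizes[b] += 1
        labels[i] = b
    return labels


def run_restarted_kmeans(
    X: np.ndarray,
    m: int,
    n_restarts: int,
    seed: int,
    max_iter: int = 500,
) -> SolutionEnsemble:
    """Run k-means from ``n_restarts`` random initializations.

    Each restart runs Lloyd's algorithm to a fixed point from a random
    initialization (empty clusters are re-seeded internally at the farthest
    points, sklearn's documented rule), then single-point exchange passes
    until no reassignment improves G, so every solution is a genuine local
    maximum.  Partitions are canonicalized and deduplicated; every restart
    seed leading to a partition is recorded on that solution.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if m < 2:
        raise ValueError("need m >= 2")
    if m >= n:
        raise ValueError("need more samples than clusters")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if n_restarts < 1:
        raise ValueError("need at least one restart")

    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    seen: dict[bytes, ClusterSolution] = {}
    # single-threaded: parallel OpenMP reductions reorder float sums and
    # break the bitwise-reproducibility contract of the ensemble
    with threadpool_limits(limits=1):
        for rs in child_seeds:
            km = KMeans(
                n_clusters=m,
                init="random",
                n_init=1,
                max_iter=max_iter,
                tol=1e-12,
                algorithm="lloyd",
                random_state=int(rs),
            )
            labels = _polish_to_local_maximum(X, km.fit_predict(X), m)
            labels = canonicalize_labels(labels)
            key = labels.tobytes()
            if key in seen:
                seen[key].seeds.append(int(rs))
            else:
                seen[key] = ClusterSolution(
                    labels=labels, m=m, G=compute_G(X, labels), seeds=[int(rs)]
                )
    solutions = sorted(seen.values(), key=lambda s: (-s.G, s.seeds[0]))
    return SolutionEnsemble(
        solutions=solutions, n_restarts=n_restarts, X_fingerprint=fingerprint_matrix(X)
    )


def _dstar_for_labels(
    Z: np.ndarray, labels: np.ndarray, ridge: float, max_iter: int = 200
) -> float:
    """Fit the membership model on a prebuilt intercept-bearing design."""
    classes, y = np.unique(labels, return_inverse=True)
    m = len(classes)
    Y = np.zeros((len(y), m))
    Y[np.arange(len(y)), y] = 1.0
    _, P, converged, _ = _fit_multinomial_core(Z, Y, ridge=ridge, max_iter=max_iter)
    if not converged:
        raise RuntimeError("membership model did not converge")
    pi = Y.mean(axis=0)
    return compute_D_star(MembershipMatrix(u=P, pi=pi))


def score_ensemble(
    ensemble: SolutionEnsemble,
    risk: RiskFactorTable,
    min_class_fraction: float = 0.05,
    ridge_penalty: float = 1e-4,
) -> SolutionEnsemble:
    """Attach D* to every admissible solution in the ensemble (in place).

    Solutions with any class below ``min_class_fraction`` of the cases are
    marked inadmissible and left unscored.  A model-fit failure marks the
    solution unscored with its reason; the rest of the ensemble proceeds.
    """
    X_design, _ = risk.design_matrix()
    Z = np.column_stack([np.ones(len(X_design)), X_design])
    n = Z.shape[0]
    admissible: list[ClusterSolution] = []
    for sol in ensemble.solutions:
        if len(sol.labels) != n:
            raise ValueError("risk table does not cover the clustered samples")
        if sol.class_sizes.min() < min_class_fraction * n:
            sol.admissible = False
            sol.unscored_reason = "class below min_class_fraction"
        else:
            sol.admissible = True
            admissible.append(sol)
    if admissible:
        Ys = np.stack([_one_hot(sol.labels) for sol in admissible])
        dstars = _dstar_batch(Z, Ys, ridge=ridge_penalty)
        for sol, d in zip(admissible, dstars):
            if np.isnan(d):
                sol.D_star = None
                sol.unscored_reason = "fit failed: membership model did not converge"
            else:
                sol.D_star = float(d)
                sol.unscored_reason = None
    return ensemble


def select_solution(ensemble: SolutionEnsemble, criterion: str = "max_D_star") -> ClusterSolution:
    """Pick the admissible scored solution maximizing the criterion.

    Ties are broken by larger G, then by smaller first restart seed.
    """
    if criterion not in ("max_D_star", "max_G"):
        raise ValueError(f"unknown criterion {criterion!r}")
    pool = [s for s in ensemble.solutions if s.admissible and (criterion == "max_G" or s.D_star is not None)]
    if not pool:
        raise ValueError("no admissible scored solutions to select from")

    def key(s: ClusterSolution):
        primary = s.D_star if criterion == "max_D_star" else s.G
        return (primary, s.G, -min(s.seeds))

    return max(pool, key=key)


def random_benchmark(
    X: np.ndarray,
    risk: RiskFactorTable,
    m: int,
    n_draws: int,
    seed: int,
    ridge_penalty: float = 1e-4,
) -> list[tuple[float, float]]:
    """(G, D*) pairs for uniformly random label assignments.

    Benchmarks the G values expected in the absence of genuine cluster
    structure and the D* values expected when sub-types carry no
    risk-factor signal; suitable for the diagnostic scatter alongside the
    k-means local maxima.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    X_design, _ = risk.design_matrix()
    Z = np.column_stack([np.ones(n), X_design])
    rng = np.random.default_rng(seed)
    all_labels = []
    for _ in range(n_draws):
        while True:
            labels = rng.integers(0, m, size=n)
            if len(np.unique(labels)) == m:
                break
        all_labels.append(canonicalize_labels(labels))
    Ys = np.stack([_one_hot(lab) for lab in all_labels])
    dstars = _dstar_batch(Z, Ys, ridge=ridge_penalty)
    return [(compute_G(X, lab), float(d)) for lab, d in zip(all_labels, dstars)]
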