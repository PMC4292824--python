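"""Heterogeneity statistics and the case-only sub-type membership model.

The central quantities are the coefficient of variation of individual
disease risks ``K``, its per-sub-type analogues ``K_j``, the normalized
covariances ``K_jk``, the population heterogeneity measure ``D`` and its
case-only counterpart ``D*``.  ``D*`` is computed from fitted sub-type
membership probabilities obtained by multinomial (polytomous) logistic
regression of candidate sub-type labels on the risk factors.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskFactorTable",
    "MembershipMatrix",
    "SubtypeModel",
    "HeterogeneityComponents",
    "RankError",
    "fit_subtype_model",
    "compute_D_star",
    "compute_K",
    "compute_components",
]


class RankError(ValueError):
    """Raised when the dummy-coded design matrix is rank deficient."""


@dataclasses.dataclass(frozen=True)
class RiskFactorTable:
    """Per-case covariates used to predict sub-type membership.

    Parameters
    ----------
    data:
        One row per case, indexed by case identifier.
    categorical:
        Mapping of column name to its ordered vocabulary of levels.  The
        first declared level is the dummy-coding reference.
    continuous:
        Names of continuous columns (standardized before fitting).
    """

    data: pd.DataFrame
    categorical: Mapping[str, Sequence[str]]
    continuous: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate case identifiers: {list(dupes)[:5]}")
        cols = list(self.categorical) + list(self.continuous)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        sub = self.data[cols]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad}; apply complete-case filtering first")
        for col, levels in self.categorical.items():
            observed = set(self.data[col].astype(str))
            extra = observed - set(map(str, levels))
            if extra:
                raise ValueError(f"column {col!r} has values outside its vocabulary: {sorted(extra)}")

    @property
    def n_cases(self) -> int:
        return len(self.data)

    @property
    def case_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dummy-coded design (no intercept column).

        Categorical columns are coded against their first declared level;
        continuous columns are standardized to mean 0, SD 1 (population SD).
        """
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for col, levels in self.categorical.items():
            vals = self.data[col].astype(str).to_numpy()
            for level in list(map(str, levels))[1:]:
                blocks.append((vals == level).astype(float))
                names.append(f"{col}[{level}]")
        for col in self.continuous:
            x = self.data[col].to_numpy(dtype=float)
            sd = x.std()
            if sd == 0:
                blocks.append(np.zeros_like(x))
            else:
                blocks.append((x - x.mean()) / sd)
            names.append(col)
        if not blocks:
            return np.empty((self.n_cases, 0)), []
        return np.column_stack(blocks), names

    def subset(self, rows: np.ndarray) -> "RiskFactorTable":
        return RiskFactorTable(self.data.iloc[rows], self.categorical, self.continuous)


@dataclasses.dataclass(frozen=True)
class MembershipMatrix:
    """Per-case sub-type probabilities ``u`` with class proportions ``pi``."""

    u: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "pi", pi)
        if u.ndim != 2 or pi.ndim != 1 or u.shape[1] != pi.shape[0]:
            raise ValueError("u must be N x m and pi length m")
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("membership probabilities outside [0, 1]")
        if not np.allclose(u.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if np.any(pi <= 0):
            raise ValueError("class proportions must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1")

    @property
    def n_cases(self) -> int:
        return self.u.shape[0]

    @property
    def n_subtypes(self) -> int:
        return self.u.shape[1]


@dataclasses.dataclass(frozen=True)
class SubtypeModel:
    """Fitted multinomial-logit model of sub-type membership.

    ``coefficients`` has one row per non-reference class and columns
    ``["(intercept)"] + feature_names``.  ``standard_errors`` (same shape)
    comes from the observed information of the *unpenalized* likelihood at
    the optimum and is ``None`` when that information matrix is singular.
    """

    coefficients: np.ndarray
    feature_names: list[str]
    classes: np.ndarray
    reference_class: int
    ridge_penalty: float
    converged: bool
    n_iter: int
    standard_errors: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X])
        eta = np.zeros((len(X), len(self.classes)))
        other = [k for k in range(len(self.classes)) if k != self.reference_class]
        eta[:, other] = Z @ self.coefficients.T
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p


@dataclasses.dataclass(frozen=True)
class HeterogeneityComponents:
    mu: float
    mu_j: np.ndarray
    v: float
    v_j: np.ndarray
    c_jk: np.ndarray
    K: float
    K_j: np.ndarray
    K_jk: np.ndarray
    pi: np.ndarray
    D: float
    D_star: float


# ---------------------------------------------------------------------------
# multinomial-logit core (Newton with step halving; ridge on slopes only)
# ---------------------------------------------------------------------------

def _nll(Z: np.ndarray, Y: np.ndarray, B: np.ndarray, ridge: float) -> float:
    eta = np.zeros((Z.shape[0], Y.shape[1]))
    eta[:, 1:] = Z @ B.T
    mx = eta.max(axis=1)
    lse = mx + np.log(np.exp(eta - mx[:, None]).sum(axis=1))
    nll = float(lse.sum() - (eta * Y).sum())
    nll += 0.5 * ridge * float((B[:, 1:] ** 2).sum())
    return nll


def _fit_multinomial_core(
    Z: np.ndarray,
    Y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Newton fit of a multinomial logit with class 0 as reference.

    Z includes the intercept column; Y is N x m one-hot.  Returns
    (coefficients B of shape (m-1, d), probabilities P, converged, n_iter).
    The ridge penalty applies to slope coefficients only.
    """
    n, d = Z.shape
    m = Y.shape[1]
    q = m - 1
    B = np.zeros((q, d))
    pen_mask = np.ones(d)
    pen_mask[0] = 0.0  # intercept unpenalized
    nll = _nll(Z, Y, B, ridge)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        eta = np.zeros((n, m))
        eta[:, 1:] = Z @ B.T
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)

        G = (P[:, 1:] - Y[:, 1:]).T @ Z + ridge * B * pen_mask  # (q, d)
        gnorm = np.abs(G).max()
        if gnorm < tol * max(1.0, n):
            converged = True
            break

        # block Hessian: H[(j,a),(k,b)] = sum_i Z_ia Z_ib P_ji (d_jk - P_ki)
        H = np.empty((q * d, q * d))
        for j in range(q):
            for k in range(j, q):
                w = P[:, j + 1] * ((1.0 if j == k else 0.0) - P[:, k + 1])
                blk = (Z * w[:, None]).T @ Z
                H[j * d:(j + 1) * d, k * d:(k + 1) * d] = blk
                if k != j:
                    H[k * d:(k + 1) * d, j * d:(j + 1) * d] = blk.T
        H[np.arange(q * d), np.arange(q * d)] += ridge * np.tile(pen_mask, q)

        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(q * d), G.ravel()).reshape(q, d)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, G.ravel(), rcond=None)[0].reshape(q, d)

        # step halving on the penalized objective
        alpha = 1.0
        for _ in range(40):
            B_new = B - alpha * step
            nll_new = _nll(Z, Y, B_new, ridge)
            if nll_new <= nll + 1e-12:
                break
            alpha *= 0.5
        else:
            converged = gnorm < 1e-4 * max(1.0, n)
            break
        if abs(nll - nll_new) < tol * max(1.0, abs(nll)) and np.abs(alpha * step).max() < 1e-8:
            B = B_new
            nll = nll_new
            converged = True
            break
        B = B_new
        nll = nll_new

    eta = np.zeros((n, m))
    eta[:, 1:] = Z @ B.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    return B, P, converged, it


def _fit_multinomial_batch(
    Z: np.ndarray,
    Ys: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of many multinomial logits sharing one design matrix.

    Z is n x d (with intercept column); Ys is nb x n x m one-hot.  All
    problems are iterated together with per-problem step halving; returns
    (P of shape nb x n x m, converged mask of shape nb).  Used by the
    permutation machinery where thousands of small fits share Z.
    """
    nb, n, m = Ys.shape
    d = Z.shape[1]
    q = m - 1
    Bc = np.zeros((nb, q, d))
    pen = np.zeros(q * d)
    pen_mask = np.ones(d)
    pen_mask[0] = 0.0
    pen[:] = ridge * np.tile(pen_mask, q)
    eye = 1e-12 * np.eye(q * d)

    def probs(Bc):
        eta = np.zeros((nb, n, m))
        eta[:, :, 1:] = np.einsum("bqd,nd->bnq", Bc, Z)
        eta -= eta.max(axis=2, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=2, keepdims=True)
        return eta, P

    def nll_of(Bc):
        eta = np.zeros((nb, n, m))
        eta[:, :, 1:] = np.einsum("bqd,nd->bnq", Bc, Z)
        mx = eta.max(axis=2)
        lse = mx + np.log(np.exp(eta - mx[..., None]).sum(axis=2))
        out = lse.sum(axis=1) - (eta * Ys).sum(axis=(1, 2))
        out += 0.5 * ridge * (Bc[:, :, 1:] ** 2).sum(axis=(1, 2))
        return out

    nll = nll_of(Bc)
    converged = np.zeros(nb, dtype=bool)
    for _ in range(max_iter):
        _, P = probs(Bc)
        G = np.einsum("bnq,nd->bqd", P[:, :, 1:] - Ys[:, :, 1:], Z)
        G += ridge * Bc * pen_mask
        gmax = np.abs(G).max(axis=(1, 2))
        converged |= gmax < tol * max(1.0, n)
        if converged.all():
            break
        H = np.empty((nb, q * d, q * d))
        for j in range(q):
            for k in range(j, q):
                delta = 1.0 if j == k else 0.0
                w = P[:, :, j + 1] * (delta - P[:, :, k + 1])
                blk = np.einsum("bn,nd,ne->bde", w, Z, Z)
                H[:, j * d:(j + 1) * d, k * d:(k + 1) * d] = blk
                if k != j:
                    H[:, k * d:(k + 1) * d, j * d:(j + 1) * d] = blk.transpose(0, 2, 1)
        H[:, np.arange(q * d), np.arange(q * d)] += pen
        try:
            step = np.linalg.solve(H + eye, G.reshape(nb, -1, 1))[..., 0].reshape(nb, q, d)
        except np.linalg.LinAlgError:
            step = np.stack([
                np.linalg.lstsq(H[b], G[b].ravel(), rcond=None)[0].reshape(q, d)
                for b in range(nb)
            ])
        step[converged] = 0.0
        alpha = np.ones(nb)
        for _ in range(40):
            Bc_new = Bc - alpha[:, None, None] * step
            nll_new = nll_of(Bc_new)
            bad = (nll_new > nll + 1e-12) & ~converged
            if not bad.any():
                break
            alpha[bad] *= 0.5
        Bc = Bc_new
        nll = np.minimum(nll, nll_new)
    _, P = probs(Bc)
    return P, converged


def _dstar_batch(Z: np.ndarray, Ys: np.ndarray, ridge: float, max_iter: int = 100) -> np.ndarray:
    """D* for many label sets sharing one design; NaN where not converged."""
    P, converged = _fit_multinomial_batch(Z, Ys, ridge=ridge, max_iter=max_iter)
    pi = Ys.mean(axis=1)  # nb x m
    dev = (P - pi[:, None, :]) ** 2 / pi[:, None, :]
    out = dev.sum(axis=2).mean(axis=1)
    out[~converged] = np.nan
    return out


def _standard_errors(Z: np.ndarray, P: np.ndarray) -> np.ndarray | None:
    """SEs from the unpenalized observed information at the fitted probabilities."""
    n, d = Z.shape
    q = P.shape[1] - 1
    H = np.empty((q * d, q * d))
    for j in range(q):
        for k in range(j, q):
            w = P[:, j + 1] * ((1.0 if j == k else 0.0) - P[:, k + 1])
            blk = (Z * w[:, None]).T @ Z
            H[j * d:(j + 1) * d, k * d:(k + 1) * d] = blk
            if k != j:
                H[k * d:(k + 1) * d, j * d:(j + 1) * d] = blk.T
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag < 0):
        return None
    return np.sqrt(diag).reshape(q, d)


def fit_subtype_model(
    risk: RiskFactorTable,
    labels: np.ndarray,
    ridge_penalty: float = 1e-4,
    min_class_size: int = 2,
    max_iter: int = 200,
) -> tuple[SubtypeModel, MembershipMatrix]:
    """Fit the polytomous logistic regression of sub-type labels on risk factors.

    Returns the fitted model together with the membership matrix whose rows
    are the fitted probabilities and whose ``pi`` are the empirical class
    fractions of ``labels``.

    Raises
    ------
    RankError
        If the dummy-coded design (with intercept) is rank deficient.
    ValueError
        If a class is empty or smaller than ``min_class_size``.
    """
    labels = np.asarray(labels)
    if len(labels) != risk.n_cases:
        raise ValueError("labels and risk table must align")
    classes, y = np.unique(labels, return_inverse=True)
    m = len(classes)
    if m < 2:
        raise ValueError("need at least 2 sub-types")
    counts = np.bincount(y, minlength=m)
    if counts.min() < max(1, min_class_size):
        small = classes[counts < max(1, min_class_size)]
        raise ValueError(f"classes below min_class_size={min_class_size}: {list(small)}")

    X, names = risk.design_matrix()
    Z = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise RankError("design matrix is rank deficient after dummy coding")

    Y = np.zeros((len(y), m))
    Y[np.arange(len(y)), y] = 1.0
    B, P, converged, n_iter = _fit_multinomial_core(Z, Y, ridge=ridge_penalty, max_iter=max_iter)
    se = _standard_errors(Z, P) if ridge_penalty == 0 and converged else None
    model = SubtypeModel(
        coefficients=B,
        feature_names=names,
        classes=classes,
        reference_class=0,
        ridge_penalty=ridge_penalty,
        converged=converged,
        n_iter=n_iter,
        standard_errors=se,
    )
    pi = counts / counts.sum()
    mem = MembershipMatrix(u=P, pi=pi)
    return model, mem


# ---------------------------------------------------------------------------
# heterogeneity statistics
# ---------------------------------------------------------------------------

def compute_D_star(mem: MembershipMatrix) -> float:
    """Case-only heterogeneity: mean over cases of sum_j (u_ji - pi_j)^2 / pi_j.

    Bounded by 0 <= D* <= m - 1, with the upper bound attained by hard
    labels on equally sized classes.
    """
    dev = (mem.u - mem.pi) ** 2 / mem.pi
    return float(dev.sum(axis=1).mean())


def compute_K(r: np.ndarray) -> float:
    """Coefficient of variation of risks (population variance convention)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("risks must be strictly positive")
    mu = r.mean()
    v = (r ** 2).mean() - mu ** 2
    return float(np.sqrt(max(v, 0.0)) / mu)


def compute_components(population_risks: np.ndarray) -> HeterogeneityComponents:
    """Full decomposition of the heterogeneity measure for a population.

    Parameters
    ----------
    population_risks:
        n x m matrix of per-individual, per-sub-type incidence rates
        ``r_ji`` (rows are individuals).  Entries must be non-negative with
        strictly positive row sums and strictly positive sub-type means.

    Computes D three ways and checks agreement to 1e-10:
    as the excess of the class-weighted mean of the K_j^2 over K^2, via the
    covariance expansion, and via the per-individual membership-deviation
    form weighted by (r_i / mu)^2.
    """
    r = np.asarray(population_risks, dtype=float)
    if r.ndim != 2:
        raise ValueError("population_risks must be n x m")
    if np.any(r < 0):
        raise ValueError("risks must be non-negative")
    n, m = r.shape
    ri = r.sum(axis=1)
    if np.any(ri <= 0):
        raise ValueError("row sums of risks must be strictly positive")

    mu_j = r.mean(axis=0)
    if np.any(mu_j <= 0):
        raise ValueError("every sub-type must have positive mean risk")
    mu = float(ri.mean())
    v_j = (r ** 2).mean(axis=0) - mu_j ** 2
    v = float((ri ** 2).mean() - mu ** 2)
    c_jk = (r.T @ r) / n - np.outer(mu_j, mu_j)

    K = float(np.sqrt(max(v, 0.0)) / mu)
    K_j = np.sqrt(np.maximum(v_j, 0.0)) / mu_j
    K_jk = c_jk / np.outer(mu_j, mu_j)
    pi = mu_j / mu

    D1 = float(pi @ (K_j ** 2) - K ** 2)

    # covariance expansion: D = sum_j K_j^2 pi_j (1 - pi_j) - sum_{j != k} K_jk pi_j pi_k
    off = K_jk * np.outer(pi, pi)
    D2 = float((K_j ** 2 * pi * (1 - pi)).sum() - (off.sum() - np.trace(off)))

    # membership-deviation form with risk weights (r_i / mu)^2
    u = r / ri[:, None]
    dev = ((u - pi) ** 2 / pi).sum(axis=1)
    D3 = float(((ri / mu) ** 2 * dev).mean())

    if not (abs(D1 - D2) <= 1e-10 * max(1.0, abs(D1)) and abs(D1 - D3) <= 1e-10 * max(1.0, abs(D1))):
        raise ArithmeticError(
            f"heterogeneity decompositions disagree: {D1!r}, {D2!r}, {D3!r}"
        )

    D_star = float(dev.mean())
    return HeterogeneityComponents(
        mu=mu, mu_j=mu_j, v=v, v_j=v_j, c_jk=c_jk,
        K=K, K_j=K_j, K_jk=K_jk, pi=pi, D=D1, D_star=D_star,
    )
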