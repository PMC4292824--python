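"""Post-hoc characterization of selected sub-types: risk profiles,
mutation associations, cross-platform congruence, competitive gene-set
enrichment and survival."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .prep import GenomicMatrix
from .riskmetrics import RiskFactorTable

__all__ = [
    "CongruenceResult",
    "GeneSetCollection",
    "SurvivalData",
    "risk_profile_table",
    "mutation_association",
    "align_labels",
    "congruence_test",
    "gsea_competitive",
    "survival_summary",
    "read_gmt",
]


@dataclasses.dataclass(frozen=True)
class CongruenceResult:
    confusion: np.ndarray
    alignment: np.ndarray
    congruent: int
    expected_random: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        aligned = self.confusion[:, self.alignment]
        if int(np.trace(aligned)) != self.congruent:
            raise ValueError("congruent must equal the trace of the aligned confusion")


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def filter_sizes(self, min_size: int = 2, max_size: int = 10_000) -> "GeneSetCollection":
        return GeneSetCollection({
            name: s for name, s in self.sets.items() if min_size <= len(s) <= max_size
        })


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated gene-set file (name, description, members...)."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected name, description, >=1 member")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets)


@dataclasses.dataclass(frozen=True)
class SurvivalData:
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if np.any(time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if len(time) != len(event):
            raise ValueError("time and event must align")


def risk_profile_table(labels: np.ndarray, risk: RiskFactorTable) -> pd.DataFrame:
    """Within-sub-type relative frequencies of each categorical factor
    (percent, summing to 100 per factor per class) and medians of the
    continuous covariates."""
    labels = np.asarray(labels)
    if len(labels) != risk.n_cases:
        raise ValueError("labels and risk table must align")
    classes = np.unique(labels)
    rows = []
    for col, levels in risk.categorical.items():
        vals = risk.data[col].astype(str).to_numpy()
        for level in map(str, levels):
            entry = {"factor": col, "level": level}
            for cls in classes:
                mask = labels == cls
                entry[f"subtype_{cls}"] = 100.0 * (vals[mask] == level).mean()
            rows.append(entry)
    for col in risk.continuous:
        vals = risk.data[col].to_numpy(dtype=float)
        entry = {"factor": col, "level": "median"}
        for cls in classes:
            entry[f"subtype_{cls}"] = float(np.median(vals[labels == cls]))
        rows.append(entry)
    out = pd.DataFrame(rows)
    sizes = {f"subtype_{cls}": int((labels == cls).sum()) for cls in classes}
    out.attrs["class_sizes"] = sizes
    return out


def mutation_association(
    labels: np.ndarray,
    mutations: pd.DataFrame,
    min_mutated: int = 1,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-gene mutation frequencies by sub-type with an association p-value.

    For each gene the m x 2 (sub-type by mutated/wild-type) table is tested
    by chi-square; when any expected count is below 5 and the table is 2x2
    the two-sided Fisher exact test is used instead (``method`` can force
    ``"chi2"`` or ``"fisher"``).  Genes mutated in fewer than ``min_mutated``
    cases are reported untested.
    """
    labels = np.asarray(labels)
    vals = mutations.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mutation matrix must be binary 0/1")
    if len(labels) != len(mutations):
        raise ValueError("labels and mutation matrix must align")
    classes = np.unique(labels)
    m = len(classes)
    rows = []
    for gene in mutations.columns:
        g = mutations[gene].to_numpy(dtype=int)
        entry: dict = {"gene": gene, "n_mutated": int(g.sum())}
        table = np.zeros((m, 2), dtype=float)
        for idx, cls in enumerate(classes):
            mask = labels == cls
            table[idx, 0] = g[mask].sum()
            table[idx, 1] = mask.sum() - g[mask].sum()
            entry[f"subtype_{cls}_pct"] = 100.0 * g[mask].mean()
        if g.sum() < min_mutated:
            entry.update(p_value=np.nan, test="untested")
            rows.append(entry)
            continue
        use = method
        if use == "auto":
            expected = stats.contingency.expected_freq(table)
            use = "fisher" if (expected < 5).any() and m == 2 else "chi2"
        if use == "fisher":
            if m != 2:
                raise ValueError("fisher test only available for 2 sub-types")
            _, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                entry.update(p_value=np.nan, test="untested")
                rows.append(entry)
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        entry.update(p_value=float(p), test=use)
        rows.append(entry)
    return pd.DataFrame(rows)


def _confusion(labels_A: np.ndarray, labels_B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a_classes, a = np.unique(labels_A, return_inverse=True)
    b_classes, b = np.unique(labels_B, return_inverse=True)
    m = max(len(a_classes), len(b_classes))  # pad with dummy classes
    conf = np.zeros((m, m), dtype=int)
    np.add.at(conf, (a, b), 1)
    return conf, a_classes, b_classes


def align_labels(labels_A: np.ndarray, labels_B: np.ndarray) -> CongruenceResult:
    """Optimal permutation of B's classes maximizing agreement with A.

    Solved exactly by linear-sum assignment on the confusion matrix.
    """
    labels_A = np.asarray(labels_A)
    labels_B = np.asarray(labels_B)
    if len(labels_A) != len(labels_B):
        raise ValueError("label vectors must align")
    conf, _, _ = _confusion(labels_A, labels_B)
    row, col = linear_sum_assignment(-conf)
    alignment = np.empty(len(col), dtype=int)
    alignment[row] = col
    congruent = int(conf[row, col].sum())
    return CongruenceResult(confusion=conf, alignment=alignment, congruent=congruent)


def congruence_test(
    labels_A: np.ndarray,
    labels_B: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> CongruenceResult:
    """Congruence count with its independence expectation and permutation p.

    ``expected_random`` is the aligned-marginal independence expectation
    sum_j a_j * b_{sigma(j)} / N; the p-value permutes ``labels_B`` and
    re-aligns on each draw.
    """
    labels_A = np.asarray(labels_A)
    labels_B = np.asarray(labels_B)
    base = align_labels(labels_A, labels_B)
    n = len(labels_A)
    a_marg = base.confusion.sum(axis=1)
    b_marg = base.confusion.sum(axis=0)
    expected = float((a_marg * b_marg[base.alignment]).sum() / n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm_congruent = align_labels(labels_A, rng.permutation(labels_B)).congruent
        if perm_congruent >= base.congruent:
            hits += 1
    p = (1 + hits) / (1 + B)
    return CongruenceResult(
        confusion=base.confusion,
        alignment=base.alignment,
        congruent=base.congruent,
        expected_random=expected,
        p_value=p,
    )


def gsea_competitive(
    X: GenomicMatrix,
    labels: np.ndarray,
    sets: GeneSetCollection,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Competitive gene-set enrichment per sub-type.

    For each sub-type k a two-sample t-statistic per gene (sub-type k vs
    the rest; Welch by default) ranks the genes, and a two-sided Wilcoxon
    rank-sum test compares the ranks of in-set genes against the complement.
    A Bonferroni-adjusted p across the tested sets is reported alongside.
    """
    labels = np.asarray(labels)
    vals = X.to_array()
    if len(labels) != vals.shape[0]:
        raise ValueError("labels must align with samples")
    genes = np.array(X.feature_ids)
    tested = {name: s & set(genes) for name, s in sets.sets.items()}
    tested = {name: s for name, s in tested.items() if s and len(s) < len(genes)}
    if not tested:
        raise ValueError("no testable gene sets (need non-empty set and complement)")
    rows = []
    n_sets = len(tested)
    for cls in np.unique(labels):
        mask = labels == cls
        t_stat, _ = stats.ttest_ind(vals[mask], vals[~mask], axis=0, equal_var=equal_var)
        t_stat = np.nan_to_num(t_stat, nan=0.0)
        for name, members in tested.items():
            in_set = np.isin(genes, list(members))
            res = stats.mannwhitneyu(t_stat[in_set], t_stat[~in_set],
                                     alternative="two-sided")
            rows.append({
                "subtype": cls,
                "gene_set": name,
                "set_size": int(in_set.sum()),
                "p_value": float(res.pvalue),
                "p_bonferroni": float(min(1.0, res.pvalue * n_sets)),
            })
    return pd.DataFrame(rows)


def _harrell_c(time: np.ndarray, event: np.ndarray, risk_score: np.ndarray) -> float:
    """Concordance over informative pairs.

    A usable pair has distinct times with the earlier subject an observed
    event; it is concordant when the earlier failure has the higher risk
    score.  Pairs with tied risk scores are uninformative and excluded; with
    no informative pairs the c-index is 0.5 by convention.
    """
    order = np.argsort(time, kind="stable")
    t, e, s = time[order], event[order], risk_score[order]
    conc = disc = 0
    for i in range(len(t)):
        if not e[i]:
            continue
        later = t > t[i]
        conc += int(np.sum(s[later] < s[i]))
        disc += int(np.sum(s[later] > s[i]))
    if conc + disc == 0:
        return 0.5
    return conc / (conc + disc)


def survival_summary(labels: np.ndarray, surv: SurvivalData) -> dict:
    """Kaplan-Meier curves per sub-type, the m-sample log-rank test and a
    concordance index.

    The c-index is computed from the linear predictor of a proportional
    hazards fit on sub-type indicator covariates (informative pairs only;
    predictor ties are excluded); with a single sub-type it is 0.5 by
    convention.
    """
    labels = np.asarray(labels)
    if len(labels) != len(surv.time):
        raise ValueError("labels and survival data must align")
    if surv.event.sum() < 1:
        raise ValueError("need at least one event")
    classes = np.unique(labels)
    curves = {}
    for cls in classes:
        mask = labels == cls
        km = KaplanMeierFitter()
        km.fit(surv.time[mask], surv.event[mask], label=str(cls))
        sf = km.survival_function_
        curves[cls] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })

    if len(classes) == 1:
        return {"curves": curves, "logrank_stat": 0.0, "logrank_p": 1.0, "c_index": 0.5}

    lr = multivariate_logrank_test(surv.time, labels, surv.event)
    df = pd.DataFrame({"time": surv.time, "event": surv.event})
    for cls in classes[1:]:
        df[f"subtype_{cls}"] = (labels == cls).astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    lp = cph.predict_log_partial_hazard(df).to_numpy()
    cidx = float(_harrell_c(surv.time, surv.event, lp))
    return {
        "curves": curves,
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "c_index": cidx,
    }
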