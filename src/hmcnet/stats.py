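"""Confusion-matrix metrics, fold aggregation, and the Friedman/Nemenyi
model-comparison harness.

Classification metrics are one-vs-rest per class (TP/FP/TN/FN), macro
(unweighted) averaged over the three classes; fold aggregates are arithmetic
mean +/- sample standard deviation (n-1 denominator).  Model comparison over
cross-validation folds uses the rank-based Friedman test (chi-square
approximation, k-1 degrees of freedom) with the Nemenyi post-hoc test on the
studentized-range distribution, summarized by the critical difference

    CD = q_alpha * sqrt(k (k + 1) / (6 N))

for k models over N folds.  ``Q_ALPHA_REPORTED = 2.949`` reproduces the
published comparison; the standard two-tailed Nemenyi value for k = 4 at
alpha = 0.05 is ``Q_ALPHA_NEMENYI_K4 ~= 2.569`` and is shipped alongside.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .errors import InputError, NumericError

logger = logging.getLogger(__name__)

#: q_alpha used in the published critical-difference computation (k=4, alpha=.05).
Q_ALPHA_REPORTED = 2.949
#: Standard two-tailed Nemenyi critical value for k=4, alpha=.05
#: (studentized range quantile / sqrt(2)).
Q_ALPHA_NEMENYI_K4 = float(sps.studentized_range.ppf(0.95, 4, np.inf) / np.sqrt(2))

METRIC_COLUMNS = ["accuracy", "sensitivity", "specificity", "precision", "f1", "auc"]


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise InputError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class ``c`` against the rest."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise InputError(f"labels must lie in [0, {n_classes})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        logger.warning("zero denominator in %s; returning 0", name)
        return 0.0
    return num / den


@dataclass
class MetricsResult:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    zero_denominator_flags: list[str] = field(default_factory=list)


def classification_metrics(cm: ConfusionMatrix) -> MetricsResult:
    """One-vs-rest accuracy/sensitivity/specificity/precision/F1 per class,
    macro-averaged; zero-denominator cases return 0 and are flagged."""
    if cm.total == 0:
        raise InputError("confusion matrix is all zeros")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for c in range(cm.n_classes):
        tp, fp, tn, fn = cm.one_vs_rest(c)
        sens = _safe_div(tp, tp + fn, f"sensitivity[{c}]", flags)
        spec = _safe_div(tn, tn + fp, f"specificity[{c}]", flags)
        prec = _safe_div(tp, tp + fp, f"precision[{c}]", flags)
        f1 = _safe_div(2 * prec * sens, prec + sens, f"f1[{c}]", flags)
        per_class[str(c)] = {
            "accuracy": (tp + tn) / cm.total,
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
        }
    macro = {
        m: float(np.mean([per_class[str(c)][m] for c in range(cm.n_classes)]))
        for m in ("accuracy", "sensitivity", "specificity", "precision", "f1")
    }
    overall_accuracy = float(np.trace(cm.counts) / cm.total)
    return MetricsResult(per_class, macro, overall_accuracy, flags)


def auc_macro(y_true, probabilities) -> float:
    """Macro one-vs-rest ROC AUC via the rank statistic; classes absent from
    ``y_true`` are skipped with a logged flag."""
    y_true = np.asarray(y_true)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or len(p) != len(y_true):
        raise InputError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise InputError("probability rows must sum to 1")
    aucs = []
    for c in range(p.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            logger.warning("class %d absent from y_true (or only class); skipped in AUC", c)
            continue
        aucs.append(roc_auc_score(pos, p[:, c]))
    if not aucs:
        raise InputError("no class with both positives and negatives present")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# fold aggregation
# ---------------------------------------------------------------------------

def aggregate_folds(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean +/- sample standard deviation (ddof=1) per metric column,
    rounded to ``decimals`` for reporting."""
    metrics = [c for c in table.columns if c != "fold"]
    if len(table) < 2:
        raise InputError("need at least 2 folds to aggregate")
    if table[metrics].isna().any().any():
        raise InputError("missing fold values")
    mean = table[metrics].mean()
    sd = table[metrics].std(ddof=1)
    return pd.DataFrame(
        {"mean": mean.round(decimals), "sd": sd.round(decimals)}
    )


# ---------------------------------------------------------------------------
# Friedman / Nemenyi / critical difference
# ---------------------------------------------------------------------------

def _check_matrix(accuracy_matrix) -> np.ndarray:
    m = np.asarray(accuracy_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InputError(f"need an (N folds x k models) matrix with N, k >= 2, got {m.shape}")
    if not np.isfinite(m).all():
        raise InputError("accuracy matrix contains non-finite entries")
    return m


def average_ranks(accuracy_matrix) -> np.ndarray:
    """Mean rank per model (rank 1 = best, i.e. highest score; ties averaged)."""
    m = _check_matrix(accuracy_matrix)
    ranks = np.vstack([sps.rankdata(-row) for row in m])
    return ranks.mean(axis=0)


def friedman(accuracy_matrix, method: str = "chisq") -> tuple[float, float]:
    """Friedman test over N folds x k models.

    chi2_F = 12N/(k(k+1)) * sum R_bar_j^2 - 3N(k+1); p from the chi-square
    distribution with k-1 df (``method='chisq'``), or by exhaustive
    permutation of within-fold rankings for small problems
    (``method='exact'``, k!^N <= 2e6).
    """
    m = _check_matrix(accuracy_matrix)
    n, k = m.shape
    rbar = average_ranks(m)
    stat = 12.0 * n / (k * (k + 1)) * float((rbar**2).sum()) - 3.0 * n * (k + 1)
    if method == "chisq":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        total = math.factorial(k) ** n
        if total > 2_000_000:
            raise InputError(f"exact permutation infeasible for k!^N = {total}")
        perms = list(itertools.permutations(range(1, k + 1)))
        count = 0
        for combo in itertools.product(perms, repeat=n):
            r = np.mean(combo, axis=0)
            s = 12.0 * n / (k * (k + 1)) * float((r**2).sum()) - 3.0 * n * (k + 1)
            if s >= stat - 1e-12:
                count += 1
        p = count / total
    else:
        raise InputError(f"unknown method {method!r}")
    return float(stat), p


def nemenyi(accuracy_matrix) -> np.ndarray:
    """Pairwise Nemenyi p-values: z = (R_i - R_j)/sqrt(k(k+1)/(6N)), p from
    the upper tail of the studentized-range distribution at z*sqrt(2)."""
    m = _check_matrix(accuracy_matrix)
    n, k = m.shape
    rbar = average_ranks(m)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(rbar[i] - rbar[j]) / se
            pij = float(sps.studentized_range.sf(z * np.sqrt(2), k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


def critical_difference(k: int, n: int, q_alpha: float = Q_ALPHA_REPORTED) -> float:
    """CD = q_alpha * sqrt(k(k+1)/(6N))."""
    if k < 2 or n < 1:
        raise InputError(f"need k >= 2 models and N >= 1 folds, got k={k}, N={n}")
    if q_alpha < 0:
        raise InputError("q_alpha must be >= 0")
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * n)))


@dataclass
class RankSummary:
    models: list[str]
    k: int
    n: int
    average_ranks: np.ndarray
    friedman_stat: float
    friedman_p: float
    nemenyi_p: np.ndarray
    q_alpha: float
    cd: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "models": self.models,
                "k": self.k,
                "n": self.n,
                "average_ranks": np.round(self.average_ranks, 6).tolist(),
                "friedman_stat": round(self.friedman_stat, 6),
                "friedman_p": self.friedman_p,
                "nemenyi_p": np.round(self.nemenyi_p, 6).tolist(),
                "q_alpha": self.q_alpha,
                "cd": round(self.cd, 6),
            },
            indent=2,
        )


def rank_summary(
    accuracy_matrix, model_names=None, q_alpha: float = Q_ALPHA_REPORTED
) -> RankSummary:
    m = _check_matrix(accuracy_matrix)
    n, k = m.shape
    names = list(model_names) if model_names is not None else [f"model{i}" for i in range(k)]
    if len(names) != k:
        raise InputError(f"{len(names)} names for {k} models")
    stat, p = friedman(m)
    return RankSummary(
        models=names,
        k=k,
        n=n,
        average_ranks=average_ranks(m),
        friedman_stat=stat,
        friedman_p=p,
        nemenyi_p=nemenyi(m),
        q_alpha=q_alpha,
        cd=critical_difference(k, n, q_alpha),
    )


@dataclass
class CDDiagram:
    """Plot-ready critical-difference structure: models sorted by average
    rank; pairs whose rank gap reaches CD are significant; the remaining
    (gap < CD) pairs define connectivity groups."""

    models: list[str]  # sorted by rank, ascending (best first)
    ranks: np.ndarray  # same order
    cd: float
    significant_pairs: list[tuple[str, str]]
    groups: list[list[str]]  # connected components of the gap < CD relation

    def to_json(self) -> str:
        group_id = {}
        for gid, grp in enumerate(self.groups):
            for name in grp:
                group_id[name] = gid
        return json.dumps(
            {
                "cd": round(self.cd, 6),
                "entries": [
                    {"model": m, "rank": float(r), "group": group_id[m]}
                    for m, r in zip(self.models, self.ranks)
                ],
                "significant_pairs": self.significant_pairs,
            },
            indent=2,
        )


def cd_diagram(ranks, cd: float, model_names=None) -> CDDiagram:
    ranks = np.asarray(ranks, dtype=float)
    names = list(model_names) if model_names is not None else [f"model{i}" for i in range(len(ranks))]
    order = np.argsort(ranks, kind="stable")
    sorted_names = [names[i] for i in order]
    sorted_ranks = ranks[order]
    k = len(ranks)
    adj = {nm: set() for nm in sorted_names}
    significant = []
    for i in range(k):
        for j in range(i + 1, k):
            gap = abs(sorted_ranks[i] - sorted_ranks[j])
            if gap < cd:
                adj[sorted_names[i]].add(sorted_names[j])
                adj[sorted_names[j]].add(sorted_names[i])
            else:  # gap >= CD: significant at the chosen level (boundary counts)
                significant.append((sorted_names[i], sorted_names[j]))
    groups, seen = [], set()
    for nm in sorted_names:
        if nm in seen:
            continue
        comp, stack = [], [nm]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(adj[cur] - seen)
        groups.append(sorted(comp, key=sorted_names.index))
    return CDDiagram(sorted_names, sorted_ranks, float(cd), significant, groups)


def render_cd_diagram(diagram: CDDiagram, path) -> None:
    """Minimal matplotlib rendering of the CD diagram (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 1.2 + 0.4 * len(diagram.models)))
    for y, (name, rank) in enumerate(zip(diagram.models, diagram.ranks)):
        ax.plot([rank], [y], "ko")
        ax.annotate(f"{name} ({rank:.2f})", (rank, y), textcoords="offset points",
                    xytext=(8, -3), fontsize=9)
    lo = float(min(diagram.ranks))
    ax.plot([lo, lo + diagram.cd], [-0.6, -0.6], "r-", lw=2)
    ax.annotate(f"CD = {diagram.cd:.2f}", (lo, -0.6), textcoords="offset points",
                xytext=(0, 6), color="r", fontsize=9)
    ax.set_ylim(-1, len(diagram.models))
    ax.set_xlabel("average rank (lower is better)")
    ax.get_yaxis().set_visible(False)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# fold-table IO
# ---------------------------------------------------------------------------

def read_fold_table(path) -> pd.DataFrame:
    """CSV with header fold,accuracy,sensitivity,specificity,precision,f1,auc
    (a subset of metric columns is allowed)."""
    df = pd.read_csv(path)
    if "fold" not in df.columns:
        raise InputError(f"{path}: missing 'fold' column")
    return df


def write_fold_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
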