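"""Discriminative evaluation of gene sets between sample classes.

Covers gene-wise Z-normalization, per-gene pooled-variance t-tests, the
one-sided two-sample Kolmogorov-Smirnov test for a left shift of a selected
set's p-value distribution against a background, grid selection of the
marker count, and cumulative multivariate logistic-regression classification
under repeated stratified cross-validation with random-feature baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Inverse ridge strength for the logistic classifier.  A small fixed penalty
#: keeps coefficients finite on linearly separable data without materially
#: shrinking them on realistic inputs.
LOGISTIC_C = 1.0

DEFAULT_COUNT_GRID = tuple(range(10, 101, 10))


@dataclass
class PValueSet:
    """Per-gene t statistics and two-sided p-values for a two-class contrast.

    ``table`` columns: gene, t, p, zero_variance (flag); genes with zero
    pooled variance have undefined tests recorded as t=0, p=1 and flagged.
    """

    table: pd.DataFrame
    n1: int
    n2: int

    def pvalues(self, genes: Sequence[str] | None = None) -> pd.Series:
        s = self.table.set_index("gene")["p"]
        return s if genes is None else s.loc[list(genes)]


@dataclass
class AccuracyCurve:
    """Mean classification accuracy over a feature-count grid.

    For random baselines the 95% confidence bounds of the repeat means are
    populated; otherwise they equal the mean.  ``degenerate_ci`` flags curves
    built from a single repeat, whose interval carries no information.
    """

    table: pd.DataFrame  # columns: k, mean_acc, ci_lo, ci_hi
    source: str = "bridge"
    degenerate_ci: bool = False


def zscore_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise Z-score transform: each row to mean 0, population SD 1.

    Constant rows (zero SD) become all-zeros and are logged.  Idempotent.
    """
    if len(expr.samples) < 2:
        raise ValueError("Z-score normalization needs >=2 samples")
    values = expr.values.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    if flat.any():
        logger.info("%d constant gene rows set to zero during Z-normalization", int(flat.sum()))
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns),
        expr.sample_class.copy(),
    )


def per_gene_t_tests(
    expr: ExpressionMatrix, class_a: Sequence[str], class_b: Sequence[str]
) -> PValueSet:
    """Two-sided pooled-variance (Student) t-test for every gene.

    p-values come from the t distribution with n1 + n2 - 2 degrees of
    freedom.  Both classes need at least two samples.
    """
    class_a, class_b = list(class_a), list(class_b)
    if len(class_a) < 2 or len(class_b) < 2:
        raise ValueError("each class needs >=2 samples for a t-test")
    a = expr.values[class_a].to_numpy(dtype=float)
    b = expr.values[class_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    zero_var = ~np.isfinite(t)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    table = pd.DataFrame(
        {"gene": expr.values.index, "t": t, "p": p, "zero_variance": zero_var}
    ).reset_index(drop=True)
    return PValueSet(table, len(class_a), len(class_b))


def ks_shift_test(
    selected_p: Sequence[float], background_p: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample KS test for a left shift of the selected p-values.

    Alternative: the selected values are stochastically smaller than the
    background (their empirical CDF lies above it), i.e. the selected genes
    are more discriminative.  Returns the D+ statistic and its asymptotic
    p-value.
    """
    selected = np.asarray(list(selected_p), dtype=float)
    background = np.asarray(list(background_p), dtype=float)
    if selected.size == 0 or background.size == 0:
        raise ValueError("both p-value samples must be non-empty")
    res = stats.ks_2samp(selected, background, alternative="greater", method="asymp")
    return float(res.statistic), float(res.pvalue)


def choose_marker_count(
    ranked_genes: Sequence[str],
    pvalues: Mapping[str, float] | pd.Series,
    background_p: Sequence[float],
    grid: Sequence[int] = DEFAULT_COUNT_GRID,
) -> tuple[int, pd.DataFrame]:
    """Pick the top-k marker count whose p-values shift most against background.

    For each k on the grid the KS left-shift test compares the top-k ranked
    genes' p-values with the background distribution; the k with the minimal
    KS p wins (ties to the smallest k).  Returns (best_k, per-k table).
    """
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty marker-count grid")
    ranked_genes = list(ranked_genes)
    if len(ranked_genes) < max(grid):
        raise ValueError(
            f"ranking covers {len(ranked_genes)} genes but grid needs {max(grid)}"
        )
    pv = pd.Series(pvalues)
    rows = []
    for k in grid:
        top = ranked_genes[:k]
        d_plus, p = ks_shift_test(pv.loc[top].to_numpy(), background_p)
        rows.append((k, d_plus, p))
    table = pd.DataFrame(rows, columns=["k", "d_plus", "ks_p"])
    best = int(table.loc[table["ks_p"].idxmin(), "k"])  # idxmin takes first == smallest k
    return best, table


def _binary_labels(labels: pd.Series | Mapping[str, str], samples: Sequence[str]) -> np.ndarray:
    y = pd.Series(labels).loc[list(samples)]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (y == classes[1]).to_numpy(dtype=int)


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, repeats: int, rng: np.random.Generator
) -> float:
    """Mean held-out accuracy of ridge-logistic classification under
    repeated stratified k-fold CV; accuracy = correct / total per repeat."""
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    accs = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        correct = 0
        for train, test in skf.split(X, y):
            clf = LogisticRegression(C=LOGISTIC_C, max_iter=2000)
            clf.fit(X[train], y[train])
            correct += int((clf.predict(X[test]) == y[test]).sum())
        accs.append(correct / len(y))
    return float(np.mean(accs))


def cumulative_classification_cv(
    expr: ExpressionMatrix,
    ranked_genes: Sequence[str],
    labels: pd.Series | Mapping[str, str],
    grid: Sequence[int] | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> AccuracyCurve:
    """Accuracy of cumulative top-k feature sets under repeated stratified CV.

    For each feature count k, a logistic-regression classifier is fit on the
    top-k ranked genes' expression within each training fold; accuracy is
    correct/total pooled over folds, averaged over repeats.
    """
    ranked_genes = [g for g in ranked_genes if g in expr.values.index]
    if not ranked_genes:
        raise ValueError("no ranked genes present in the expression matrix")
    if grid is None:
        grid = [k for k in DEFAULT_COUNT_GRID if k <= len(ranked_genes)] or [len(ranked_genes)]
    if any(k < 1 for k in grid):
        raise ValueError("feature counts must be >= 1")
    samples = expr.samples
    y = _binary_labels(labels, samples)
    rng = np.random.default_rng(seed)
    rows = []
    for k in sorted(set(int(k) for k in grid)):
        genes = sorted(ranked_genes[:k])  # order within the set is irrelevant
        X = expr.values.loc[genes, samples].to_numpy(dtype=float).T
        acc = _cv_accuracy(X, y, folds, repeats, np.random.default_rng(rng.integers(2**31 - 1)))
        rows.append((k, acc, acc, acc))
    return AccuracyCurve(pd.DataFrame(rows, columns=["k", "mean_acc", "ci_lo", "ci_hi"]))


def random_feature_baseline(
    expr: ExpressionMatrix,
    labels: pd.Series | Mapping[str, str],
    grid: Sequence[int],
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    cv_repeats: int = 1,
) -> AccuracyCurve:
    """Random-gene baseline accuracies with a 95% CI over repeated draws.

    Per grid point, ``repeats`` random gene sets (drawn without replacement)
    are each scored by the same CV scheme; the normal-approximation 95%
    confidence interval of the repeat means is reported.
    """
    samples = expr.samples
    y = _binary_labels(labels, samples)
    all_genes = np.array(expr.genes)
    rng = np.random.default_rng(seed)
    degenerate = repeats < 2
    if degenerate:
        logger.warning("random baseline with %d repeat(s): CI is degenerate", repeats)
    rows = []
    for k in sorted(set(int(k) for k in grid)):
        if k > len(all_genes):
            raise ValueError(f"cannot draw {k} genes from {len(all_genes)}")
        means = []
        for _ in range(repeats):
            genes = list(rng.choice(all_genes, size=k, replace=False))
            X = expr.values.loc[sorted(genes), samples].to_numpy(dtype=float).T
            means.append(
                _cv_accuracy(X, y, folds, cv_repeats, np.random.default_rng(rng.integers(2**31 - 1)))
            )
        means = np.asarray(means)
        m = float(means.mean())
        half = 0.0 if degenerate else 1.96 * float(means.std(ddof=1)) / np.sqrt(repeats)
        rows.append((k, m, m - half, m + half))
    return AccuracyCurve(
        pd.DataFrame(rows, columns=["k", "mean_acc", "ci_lo", "ci_hi"]),
        source="random",
        degenerate_ci=degenerate,
    )
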