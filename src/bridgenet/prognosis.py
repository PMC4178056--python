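"""Survival-based evaluation of marker gene sets.

Two routes: (1) unsupervised — hierarchical clustering of patients on their
marker-gene expression, Kaplan-Meier curves and the log-rank test across the
resulting subgroups; (2) supervised — a correlation-to-reference classifier
whose reference profile is the mean expression of the poorest-prognosis
training subgroup and whose correlation threshold is selected by repeated
five-fold cross-validation minimizing the held-out log-rank p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(-0.95, 0.951, 0.05), 2))


class PrognosticError(ValueError):
    pass


@dataclass
class SurvivalCohort:
    """Per-sample follow-up and the marker-restricted expression sub-matrix.

    ``survival`` is indexed by sample with columns ``time`` (months) and
    ``event`` (1 = relapse/death observed, 0 = censored).  ``expression`` is
    genes x samples; its samples must be a subset of the survival samples.
    ``covariates`` optionally holds categorical per-sample columns (mutation
    status and the like) usable as grouping labels.
    """

    survival: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.survival.index.duplicated().any():
            raise PrognosticError("duplicated sample ids in survival table")
        missing = [s for s in self.expression.columns if s not in self.survival.index]
        if missing:
            raise PrognosticError(f"expression samples missing survival records: {missing[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def subset(self, samples: Sequence[str]) -> "SurvivalCohort":
        samples = list(samples)
        return SurvivalCohort(
            self.survival.loc[samples],
            self.expression[samples],
            None if self.covariates is None else self.covariates.loc[samples],
        )


@dataclass
class PrognosticModel:
    """Correlation-to-reference prognostic classifier.

    ``reference_profile`` is the mean marker-gene expression of the
    poorest-prognosis training subgroup; a test patient is called ``poor``
    when the Pearson correlation of their marker-gene vector with the
    reference exceeds ``threshold``.
    """

    reference_profile: pd.Series
    threshold: float
    markers: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise PrognosticError(f"threshold must be in [-1, 1]: {self.threshold}")
        if set(self.reference_profile.index) != set(self.markers):
            raise PrognosticError("reference profile must cover exactly the marker genes")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "threshold": float(self.threshold),
            "markers": list(self.markers),
            "reference_profile": {g: float(v) for g, v in self.reference_profile.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrognosticModel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            reference_profile=pd.Series(payload["reference_profile"], dtype=float),
            threshold=float(payload["threshold"]),
            markers=list(payload["markers"]),
            provenance=payload.get("provenance", {}),
        )


def hierarchical_subgroups(
    expression: pd.DataFrame, k: int = 3, method: str = "complete"
) -> pd.Series:
    """Cut a Euclidean agglomerative tree over patients into k subgroups.

    ``expression`` is genes x samples (Z-normalized upstream); patients are
    clustered on the Euclidean distance between their expression vectors.
    Labels are integers 1..k, deterministic for a given input.
    """
    if k < 2:
        raise PrognosticError("k must be >= 2")
    samples = list(expression.columns)
    if len(samples) < k:
        raise PrognosticError(f"need >= {k} samples to form {k} subgroups")
    X = expression.to_numpy(dtype=float).T
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=samples, name="subgroup")


def km_estimate(
    survival: pd.DataFrame, labels: pd.Series | Mapping[str, object]
) -> dict[object, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per group.

    Returns, per group label, a frame with columns ``time`` and ``survival``
    (the step function evaluated at the observed times).  With zero
    censoring the curve equals the empirical survival function.
    """
    labels = pd.Series(labels)
    if labels.empty:
        raise PrognosticError("no group labels given")
    curves: dict[object, pd.DataFrame] = {}
    for group in sorted(pd.unique(labels)):
        samples = labels.index[labels == group]
        if len(samples) == 0:
            raise PrognosticError(f"empty group {group!r}")
        sub = survival.loc[samples]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[group] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def logrank_test(
    survival: pd.DataFrame, labels: pd.Series | Mapping[str, object]
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    Observed-minus-expected event counts across event times with the
    standard hypergeometric variance; k-1 degrees of freedom.
    """
    labels = pd.Series(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise PrognosticError("log-rank test needs >=2 groups")
    sub = survival.loc[labels.index]
    res = multivariate_logrank_test(sub["time"], labels, sub["event"])
    return float(res.test_statistic), float(res.p_value)


def identify_poorest_group(
    survival: pd.DataFrame, labels: pd.Series | Mapping[str, object]
) -> object:
    """Group with minimal restricted-mean survival (area under KM).

    The restriction horizon is the largest follow-up time observed in every
    group, so all areas are compared on a common support; ties go to the
    smallest group id.
    """
    labels = pd.Series(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise PrognosticError("need >=2 groups")
    horizon = min(survival.loc[labels.index[labels == g], "time"].max() for g in groups)
    best_group, best_rms = None, np.inf
    for g in groups:
        sub = survival.loc[labels.index[labels == g]]
        kmf = KaplanMeierFitter().fit(sub["time"], event_observed=sub["event"])
        rms = float(restricted_mean_survival_time(kmf, t=max(horizon, np.finfo(float).eps)))
        if rms < best_rms - 1e-12:
            best_group, best_rms = g, rms
    return best_group


def build_reference_profile(
    cohort: SurvivalCohort, markers: Sequence[str], k: int = 3, method: str = "complete"
) -> tuple[pd.Series, pd.Series, object]:
    """Cluster the cohort on its markers and average the poorest subgroup.

    Returns (reference profile over markers, subgroup labels, poorest id).
    """
    markers = [m for m in markers if m in cohort.expression.index]
    if len(markers) < 1:
        raise PrognosticError("no marker genes present in the cohort expression")
    sub_expr = cohort.expression.loc[markers]
    labels = hierarchical_subgroups(sub_expr, k=k, method=method)
    poorest = identify_poorest_group(cohort.survival, labels)
    poor_samples = labels.index[labels == poorest]
    profile = sub_expr[list(poor_samples)].mean(axis=1)
    return profile, labels, poorest


def classify_by_correlation(
    cohort: SurvivalCohort, model: PrognosticModel
) -> pd.Series:
    """Label each patient poor/good by correlation with the reference profile.

    Pearson correlation between the patient's marker-gene vector and the
    reference; strictly greater than the threshold means ``poor``.  Markers
    absent from the test expression are dropped pairwise (logged); fewer
    than 3 shared markers is an error.
    """
    shared = [g for g in model.markers if g in cohort.expression.index]
    dropped = set(model.markers) - set(shared)
    if dropped:
        logger.info("%d marker genes absent from test expression dropped", len(dropped))
    if len(shared) < 3:
        raise PrognosticError("fewer than 3 shared marker genes; correlation meaningless")
    ref = model.reference_profile.loc[shared].to_numpy(dtype=float)
    X = cohort.expression.loc[shared].to_numpy(dtype=float)
    rs = _pearson_to_reference(X, ref)
    labels = np.where(rs > model.threshold, "poor", "good")
    return pd.Series(labels, index=cohort.expression.columns, name="prognosis")


def _pearson_to_reference(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X (genes x patients) against ref."""
    xc = X - X.mean(axis=0, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (rc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * rc[:, None]).sum(axis=0) / denom
    return np.where(np.isfinite(r), r, 0.0)


def _two_group_logrank_p(times: np.ndarray, events: np.ndarray, in_group1: np.ndarray) -> float:
    """Vectorized two-group log-rank p-value for the threshold sweep.

    Same statistic as :func:`logrank_test` (verified against it in the test
    suite); implemented directly because the cross-validated threshold search
    evaluates the test once per grid point per repeat.
    """
    order = np.argsort(times, kind="mergesort")
    t, e, g1 = times[order], events[order], in_group1[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 1.0
    left = np.searchsorted(t, event_times, side="left")
    n = len(t)
    at_risk = n - left
    g1_cum = np.concatenate([[0], np.cumsum(g1)])
    n1_at_risk = g1.sum() - g1_cum[left]
    # per-event-time death counts, total and in group 1
    right = np.searchsorted(t, event_times, side="right")
    e_cum = np.concatenate([[0], np.cumsum(e)])
    d = e_cum[right] - e_cum[left]
    e1_cum = np.concatenate([[0], np.cumsum(e * g1)])
    d1 = e1_cum[right] - e1_cum[left]
    frac = n1_at_risk / at_risk
    observed = d1.sum()
    expected = (d * frac).sum()
    denom = np.where(at_risk > 1, at_risk - 1, 1)
    var = (d * frac * (1 - frac) * (at_risk - d) / denom)
    var_total = var[at_risk > 1].sum()
    if var_total <= 0:
        return 1.0
    chi2 = (observed - expected) ** 2 / var_total
    from scipy.stats import chi2 as chi2_dist

    return float(chi2_dist.sf(chi2, df=1))


def cv_select_threshold(
    cohort: SurvivalCohort,
    markers: Sequence[str],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    k_clusters: int = 3,
    method: str = "complete",
) -> tuple[float, list[float]]:
    """Cross-validated selection of the correlation threshold.

    Per repeat: a random ``folds``-fold split of the training cohort; within
    each fold the reference profile is rebuilt from the fold's training
    portion (re-clustering and poorest-group identification on that portion
    alone), and held-out patients get their correlation to that reference.
    Held-out assignments are pooled across folds; for every grid threshold a
    two-group log-rank p is computed on the pooled poor/good split, and the
    repeat's best threshold is the argmin (ties to the smaller threshold).
    The returned threshold is the mean of the per-repeat bests.
    """
    grid = sorted(float(t) for t in grid)
    if not grid or grid[0] < -1 or grid[-1] > 1:
        raise PrognosticError("threshold grid must be non-empty and within [-1, 1]")
    samples = np.array(cohort.samples)
    if len(samples) < folds:
        raise PrognosticError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    best_thresholds: list[float] = []
    n_skipped = 0
    for rep in range(repeats):
        rep_rng = np.random.default_rng(rng.integers(2**31 - 1))
        order = rep_rng.permutation(len(samples))
        fold_ids = np.arange(len(samples)) % folds
        assignment = np.empty(len(samples), dtype=int)
        assignment[order] = fold_ids
        pooled_r = np.empty(len(samples))
        ok = True
        for f in range(folds):
            train_mask = assignment != f
            train = cohort.subset(samples[train_mask])
            try:
                profile, _, _ = build_reference_profile(
                    train, markers, k=k_clusters, method=method
                )
            except PrognosticError:
                ok = False
                break
            shared = [g for g in profile.index if g in cohort.expression.index]
            X = cohort.expression.loc[shared, samples[~train_mask]].to_numpy(dtype=float)
            pooled_r[~train_mask] = _pearson_to_reference(
                X, profile.loc[shared].to_numpy(dtype=float)
            )
        if not ok:
            n_skipped += 1
            logger.info("repeat %d skipped: fold produced an empty poor group", rep)
            continue
        sub_surv = cohort.survival.loc[list(samples)]
        times = sub_surv["time"].to_numpy(dtype=float)
        events = sub_surv["event"].to_numpy(dtype=int)
        best_p, best_t = np.inf, None
        for t in grid:
            poor = pooled_r > t
            if poor.all() or not poor.any():
                p = 1.0
            else:
                p = _two_group_logrank_p(times, events, poor)
            if p < best_p - 1e-15:
                best_p, best_t = p, t
        best_thresholds.append(best_t if best_t is not None else grid[0])
    if repeats and n_skipped > repeats / 2:
        raise PrognosticError(f"{n_skipped}/{repeats} repeats skipped; cohort too degenerate")
    if not best_thresholds:
        raise PrognosticError("no successful repeats")
    return float(np.mean(best_thresholds)), best_thresholds


def train_prognostic_model(
    cohort: SurvivalCohort,
    markers: Sequence[str],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    k_clusters: int = 3,
    method: str = "complete",
) -> PrognosticModel:
    """Full supervised training: reference profile from the whole training
    cohort's poorest subgroup, threshold from cross-validation."""
    threshold, _ = cv_select_threshold(
        cohort, markers, grid=grid, folds=folds, repeats=repeats, seed=seed,
        k_clusters=k_clusters, method=method,
    )
    profile, labels, poorest = build_reference_profile(
        cohort, markers, k=k_clusters, method=method
    )
    return PrognosticModel(
        reference_profile=profile,
        threshold=threshold,
        markers=list(profile.index),
        provenance={
            "seed": seed, "repeats": repeats, "folds": folds,
            "k_clusters": k_clusters, "linkage": method,
            "poorest_group": int(poorest), "n_train": len(cohort.samples),
        },
    )


def evaluate_prognosis(
    cohort: SurvivalCohort, labels: pd.Series | Mapping[str, object]
) -> tuple[float, dict[object, pd.DataFrame]]:
    """Log-rank p and KM curves for a labelled test cohort."""
    labels = pd.Series(labels)
    if labels.nunique() < 2:
        raise PrognosticError("evaluation needs >=2 distinct labels")
    _, p = logrank_test(cohort.survival, labels)
    curves = km_estimate(cohort.survival, labels)
    return p, curves
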