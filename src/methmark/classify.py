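"""Marker-combination classification with ROC thresholding.

Logistic regression on one to three marker beta values (additive
covariates only), ROC construction with one operating point per
distinct score, AUC by trapezoid (equal to the Mann-Whitney statistic
with ties counted 1/2), Youden and fixed-specificity operating-point
selection, iterated stratified 50/50 split validation, and
cross-combination comparison (Friedman over cancer-type blocks plus
Bonferroni-adjusted pairwise Wilcoxon signed-rank tests).

The classification rule everywhere is: predicted probability (or
score) >= threshold => called tumor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticModel",
    "RocCurve",
    "PerformanceRecord",
    "ComparisonResult",
    "fit_logistic",
    "build_roc",
    "auc",
    "youden_threshold",
    "threshold_at_specificity",
    "evaluate_at_threshold",
    "split_validation",
    "compare_combinations",
    "marker_combinations",
]


def marker_combinations(markers) -> list[tuple[str, ...]]:
    """All non-empty marker subsets (7 for three markers)."""
    markers = list(markers)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(markers) + 1):
        out.extend(_combinations(markers, size))
    return out


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class LogisticModel:
    """Fitted additive logistic model over marker beta values."""

    intercept: float
    coefficients: np.ndarray  # log-odds per unit beta, one per marker
    marker_names: list[str]
    converged: bool = True
    separation: bool = False
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.marker_names),):
            raise ValueError("coefficient count must equal marker count")

    def predict(self, features) -> np.ndarray:
        """Predicted tumor probability per row of ``features``."""
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept + X @ self.coefficients
        return special.expit(eta)

    def to_json(self, threshold: float | None = None, **metadata) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": dict(zip(self.marker_names, self.coefficients.tolist())),
            "marker_names": self.marker_names,
            "converged": self.converged,
            "separation": self.separation,
        }
        if threshold is not None:
            payload["threshold"] = threshold
        payload.update(metadata)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> tuple["LogisticModel", float | None]:
        payload = json.loads(text)
        model = cls(
            intercept=payload["intercept"],
            coefficients=np.array(
                [payload["coefficients"][m] for m in payload["marker_names"]]
            ),
            marker_names=list(payload["marker_names"]),
            converged=payload.get("converged", True),
            separation=payload.get("separation", False),
        )
        return model, payload.get("threshold")


def fit_logistic(features, labels, marker_names=None, max_iter: int = 200) -> LogisticModel:
    """Maximum-likelihood logistic fit, additive terms only.

    Rows with missing feature values are dropped (and counted in the
    log).  On perfect separation the iteration-capped fit is returned
    with ``separation=True``; its score ranking is still valid for ROC
    analysis.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if marker_names is None:
        marker_names = [f"m{i + 1}" for i in range(X.shape[1])]
    keep = ~np.isnan(X).any(axis=1)
    if not keep.all():
        logger.info("fit_logistic: dropping %d rows with missing features", (~keep).sum())
        X, y = X[keep], y[keep]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")

    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=max_iter, disp=0)
        except Exception:  # perfect separation or singular Hessian
            res = sm.Logit(y, design).fit(method="bfgs", maxiter=max_iter, disp=0)

    params = np.asarray(res.params, dtype=float)
    scores = design @ params
    case_min = scores[y == 1].min()
    control_max = scores[y == 0].max()
    separation = bool(case_min > control_max)
    stderr = None
    try:
        stderr = np.asarray(res.bse, dtype=float)
        if np.isnan(stderr).any():
            stderr = None
    except Exception:
        pass
    return LogisticModel(
        intercept=float(params[0]),
        coefficients=params[1:],
        marker_names=list(marker_names),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        stderr=stderr,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    """Operating points ordered by increasing threshold.

    Each distinct score contributes one cut; the endpoints (threshold
    at the minimum score = everyone positive, threshold above the
    maximum = everyone negative) are always present.  Thresholds
    between distinct scores are placed at the midpoint of the gap.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.specificity = np.asarray(self.specificity, dtype=float)
        if np.any(np.diff(self.sensitivity) > 1e-12):
            raise ValueError("sensitivity must be non-increasing in threshold")


def build_roc(scores, labels) -> RocCurve:
    """ROC over all distinct-score cuts with the rule score >= t => positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size > 1:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        hi = uniq[-1] + (uniq[-1] - uniq[0]) / 2.0
        thresholds = np.concatenate([[uniq[0]], mids, [hi]])
    else:
        thresholds = np.array([uniq[0], uniq[0] + 0.5])
    case = np.sort(scores[labels])
    control = np.sort(scores[~labels])
    # fraction of scores >= t via searchsorted on the sorted class scores
    sens = 1.0 - np.searchsorted(case, thresholds, side="left") / case.size
    spec = np.searchsorted(control, thresholds, side="left") / control.size
    return RocCurve(thresholds, sens, spec)


def auc(roc: RocCurve) -> float:
    """Trapezoid area under the ROC curve."""
    fpr = 1.0 - roc.specificity
    return float(-np.trapezoid(roc.sensitivity, fpr))  # fpr decreases with threshold


def youden_threshold(roc: RocCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the higher
    threshold.  A degenerate curve (max J == 0) is flagged with a
    warning; the most specific operating point is returned.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.lexsort((roc.thresholds, roc.specificity, np.round(j, 15)))[-1]
    if j[best] <= 1e-12:
        warnings.warn("degenerate ROC: Youden's J is 0 everywhere", stacklevel=2)
    return float(roc.thresholds[best])


def threshold_at_specificity(roc: RocCurve, target: float = 0.95) -> float:
    """Smallest threshold whose specificity reaches the target.

    Maximizes sensitivity subject to specificity >= target (specificity
    is non-decreasing in the threshold, so the smallest qualifying
    threshold is the most sensitive one).
    """
    if target > 1.0:
        raise ValueError("target specificity cannot exceed 1")
    ok = np.nonzero(roc.specificity >= target)[0]
    if ok.size == 0:  # cannot happen: the all-negative endpoint has spec 1
        raise ValueError("no operating point reaches the target specificity")
    return float(roc.thresholds[ok[0]])


def evaluate_at_threshold(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    positive = scores >= threshold
    sens = positive[labels].mean() if labels.any() else float("nan")
    spec = (~positive[~labels]).mean() if (~labels).any() else float("nan")
    return float(sens), float(spec)


# ---------------------------------------------------------------------------
# performance records and validation


@dataclass(frozen=True)
class PerformanceRecord:
    """One assay's operating characteristics on one cohort."""

    marker_combination: tuple[str, ...]
    cohort: str
    sensitivity: float
    specificity: float
    auc: float
    threshold: float
    training_only: bool = False

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _stratified_split(labels, train_frac, rng):
    """Index split stratified by class; odd classes floor/ceil split."""
    labels = np.asarray(labels, dtype=bool)
    train_idx = []
    test_idx = []
    for cls in (True, False):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise ValueError("class too small to stratify")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split_validation(
    features,
    labels,
    marker_names=None,
    n_iter: int = 5,
    train_frac: float = 0.5,
    seed: int = 0,
    stratified: bool = True,
    cohort: str = "",
) -> pd.DataFrame:
    """Iterated random 50/50 split validation.

    Per iteration: fit + Youden threshold on the training half, evaluate
    sensitivity/specificity/AUC on both halves.  Returns a tidy frame
    with one row per (iteration, split); summarize with
    :func:`summarize_validation`.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=bool)
    ss = np.random.SeedSequence(seed)
    rows = []
    for it, child in enumerate(ss.spawn(n_iter), start=1):
        rng = np.random.default_rng(child)
        if stratified:
            tr, te = _stratified_split(y, train_frac, rng)
        else:
            perm = rng.permutation(y.size)
            n_train = int(round(train_frac * y.size))
            tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        model = fit_logistic(X[tr], y[tr], marker_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roc_train = build_roc(model.predict(X[tr]), y[tr])
            thr = youden_threshold(roc_train)
        for split, idx in (("train", tr), ("test", te)):
            scores = model.predict(X[idx])
            sens, spec = evaluate_at_threshold(scores, y[idx], thr)
            rows.append(
                {
                    "cohort": cohort,
                    "iteration": it,
                    "split": split,
                    "sensitivity": sens,
                    "specificity": spec,
                    "auc": auc(build_roc(scores, y[idx])),
                    "threshold": thr,
                }
            )
    return pd.DataFrame(rows)


def summarize_validation(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of sensitivity/specificity/AUC per split."""
    return (
        records.groupby("split")[["sensitivity", "specificity", "auc"]]
        .agg(["mean", "std"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# cross-combination comparison


@dataclass
class ComparisonResult:
    """Friedman + pairwise Wilcoxon comparison of marker combinations."""

    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame  # columns: combo_a, combo_b, p_raw, p_bonferroni
    n_blocks: int = 0


def compare_combinations(auc_table: pd.DataFrame) -> ComparisonResult:
    """Compare combinations across cancer-type blocks.

    ``auc_table``: one row per marker combination, one column per block
    (cancer type); cells are AUCs.  Friedman test treats blocks as
    repeated measures; all pairwise Wilcoxon signed-rank tests are
    Bonferroni-adjusted (p_adj = min(1, p * n_comparisons)).
    """
    if auc_table.isna().any().any():
        raise ValueError("AUC table has missing cells")
    if auc_table.shape[0] < 2 or auc_table.shape[1] < 2:
        raise ValueError("need >=2 combinations and >=2 blocks")
    rows = [auc_table.loc[c].to_numpy(float) for c in auc_table.index]
    if all(np.allclose(r, rows[0]) for r in rows[1:]):
        stat, p = 0.0, 1.0  # identical treatments: no evidence of any effect
    else:
        stat, p = stats.friedmanchisquare(*rows)
    combos = list(auc_table.index)
    n_pairs = len(combos) * (len(combos) - 1) // 2
    pair_rows = []
    for a, b in _combinations(combos, 2):
        diff = auc_table.loc[a].to_numpy(float) - auc_table.loc[b].to_numpy(float)
        if np.allclose(diff, 0.0):
            p_raw = 1.0
        else:
            p_raw = float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)
        pair_rows.append(
            {
                "combo_a": a,
                "combo_b": b,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * n_pairs),
            }
        )
    return ComparisonResult(float(stat), float(p), pd.DataFrame(pair_rows), auc_table.shape[1])
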