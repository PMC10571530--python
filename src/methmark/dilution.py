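"""In-silico dilution of tumor DNA into white-blood-cell background.

Plasma is mimicked by mixing, probe-wise, each tumor sample's beta
value with a randomly matched white-blood-cell (WBC) sample's beta
value at a target tumor-DNA fraction f:

    mixed = f * beta_tumor + (1 - f) * beta_wbc

All tumors (every cancer type) are pooled into a single case class
against the WBC controls; at each fraction of the schedule a logistic
model per marker combination is evaluated with stratified k-fold
cross-validation (AUC from out-of-fold scores; accuracy and Cohen's
kappa per fold at the training-fold Youden threshold).  A common
threshold chosen at the 10% fraction is then applied per cancer type
to report type-specific sensitivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from .classify import (
    LogisticModel,
    auc,
    build_roc,
    evaluate_at_threshold,
    fit_logistic,
    marker_combinations,
    youden_threshold,
)
from .io import BetaMatrix, annotations_by_role

__all__ = [
    "DilutionSpec",
    "MixedMatrix",
    "match_blood",
    "mix_beta",
    "mixed_matrix",
    "dilution_series_performance",
    "per_type_sensitivity",
]

#: Tumor-DNA fraction schedule used throughout (100% down to 1%).
DEFAULT_FRACTIONS = (1.0, 0.999, 0.99, 0.90, 0.75, 0.50, 0.25, 0.10, 0.01)


@dataclass(frozen=True)
class DilutionSpec:
    """Fraction schedule, pairing seed, and CV fold count."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    seed: int = 0
    k_folds: int = 10

    def __post_init__(self):
        if len(set(self.fractions)) != len(self.fractions):
            raise ValueError("fractions must be distinct")
        for f in self.fractions:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"fraction {f} outside (0, 1]")
            if f < 0.01:
                warnings.warn(
                    f"fraction {f} below the 1% floor; single-probe beta mixing "
                    "is not expected to be informative there",
                    stacklevel=2,
                )


@dataclass
class MixedMatrix:
    """Marker x tumor-sample mixed betas at one fraction, with provenance."""

    fraction: float
    marker_probes: list[str]
    tumor_ids: list[str]
    wbc_match: list[str]  # matched blood sample per tumor column
    values: np.ndarray

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tumor_id": self.tumor_ids, "wbc_id": self.wbc_match, "fraction": self.fraction}
        )


def match_blood(tumor_ids, wbc_ids, seed: int = 0) -> list[str]:
    """Uniform random with-replacement match of a blood sample per tumor."""
    tumor_ids, wbc_ids = list(tumor_ids), list(wbc_ids)
    if not wbc_ids:
        raise ValueError("empty WBC sample set")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.integers(0, len(wbc_ids), size=len(tumor_ids))
    return [wbc_ids[i] for i in draws]


def mix_beta(tumor_beta, wbc_beta, f: float):
    """Affine mixture f * tumor + (1 - f) * wbc, elementwise."""
    tumor_beta = np.asarray(tumor_beta, dtype=float)
    wbc_beta = np.asarray(wbc_beta, dtype=float)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction {f} outside [0, 1]")
    for name, arr in (("tumor", tumor_beta), ("wbc", wbc_beta)):
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError(f"{name} beta values outside [0, 1]")
    return f * tumor_beta + (1.0 - f) * wbc_beta


def mixed_matrix(
    marker_probes,
    tumor_matrix: BetaMatrix,
    wbc_matrix: BetaMatrix,
    pairing: list[str],
    f: float,
) -> MixedMatrix:
    """Mix the designated marker probes of every tumor with its matched blood."""
    t_pos = {s: j for j, s in enumerate(tumor_matrix.sample_ids)}
    w_pos = {s: j for j, s in enumerate(wbc_matrix.sample_ids)}
    tp = [tumor_matrix.probe_ids.index(p) for p in marker_probes]
    wp = [wbc_matrix.probe_ids.index(p) for p in marker_probes]
    wbc_cols = [w_pos[s] for s in pairing]
    tumor_vals = tumor_matrix.values[np.ix_(tp, range(len(tumor_matrix.sample_ids)))]
    wbc_vals = wbc_matrix.values[np.ix_(wp, wbc_cols)]
    return MixedMatrix(
        fraction=f,
        marker_probes=list(marker_probes),
        tumor_ids=list(tumor_matrix.sample_ids),
        wbc_match=list(pairing),
        values=mix_beta(tumor_vals, wbc_vals, f),
    )


def _cv_performance(X, y, marker_names, k_folds, seed):
    """Stratified k-fold CV: pooled out-of-fold AUC, per-fold accuracy/kappa."""
    if k_folds > min((y == 1).sum(), (y == 0).sum()):
        raise ValueError("k larger than the smallest class")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    acc, kappa = [], []
    for tr, te in skf.split(X, y):
        model = fit_logistic(X[tr], y[tr], marker_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = youden_threshold(build_roc(model.predict(X[tr]), y[tr]))
        scores = model.predict(X[te])
        oof[te] = scores
        pred = scores >= thr
        acc.append(float((pred == y[te].astype(bool)).mean()))
        kappa.append(float(cohen_kappa_score(y[te].astype(bool), pred)))
    return (
        auc(build_roc(oof, y.astype(bool))),
        float(np.mean(acc)),
        float(np.std(acc, ddof=1)),
        float(np.mean(kappa)),
        float(np.std(kappa, ddof=1)),
        oof,
    )


def dilution_series_performance(
    marker_probes: dict[str, str],
    tumor_matrix: BetaMatrix,
    wbc_matrix: BetaMatrix,
    spec: DilutionSpec = DilutionSpec(),
) -> tuple[pd.DataFrame, list[str]]:
    """Pooled tumor-vs-WBC performance across the fraction schedule.

    ``marker_probes`` maps marker name -> probe id.  One blood pairing
    is drawn (from ``spec.seed``) and reused across all fractions so
    the series is comparable.  Returns (per-fraction/per-combination
    table, pairing).
    """
    markers = list(marker_probes)
    probes = [marker_probes[m] for m in markers]
    pairing = match_blood(tumor_matrix.sample_ids, wbc_matrix.sample_ids, spec.seed)
    w_pos = {s: j for j, s in enumerate(wbc_matrix.sample_ids)}
    wbc_rows = [wbc_matrix.probe_ids.index(p) for p in probes]
    X_wbc = wbc_matrix.values[np.ix_(wbc_rows, range(len(wbc_matrix.sample_ids)))].T

    rows = []
    for f in spec.fractions:
        mm = mixed_matrix(probes, tumor_matrix, wbc_matrix, pairing, f)
        X_tumor = mm.values.T
        X_all = np.vstack([X_tumor, X_wbc])
        y = np.concatenate([np.ones(X_tumor.shape[0]), np.zeros(X_wbc.shape[0])])
        for combo in marker_combinations(markers):
            cols = [markers.index(m) for m in combo]
            auc_cv, acc_m, acc_sd, kap_m, kap_sd, _ = _cv_performance(
                X_all[:, cols], y, list(combo), spec.k_folds, spec.seed
            )
            rows.append(
                {
                    "fraction": f,
                    "combination": "+".join(combo),
                    "auc": auc_cv,
                    "accuracy_mean": acc_m,
                    "accuracy_sd": acc_sd,
                    "kappa_mean": kap_m,
                    "kappa_sd": kap_sd,
                }
            )
    return pd.DataFrame(rows), pairing


def fit_common_model(
    marker_probes: dict[str, str],
    tumor_matrix: BetaMatrix,
    wbc_matrix: BetaMatrix,
    pairing: list[str],
    f: float = 0.10,
) -> tuple[LogisticModel, float]:
    """Fit the pooled model at one fraction and pick its Youden threshold."""
    markers = list(marker_probes)
    probes = [marker_probes[m] for m in markers]
    mm = mixed_matrix(probes, tumor_matrix, wbc_matrix, pairing, f)
    wbc_rows = [wbc_matrix.probe_ids.index(p) for p in probes]
    X_wbc = wbc_matrix.values[np.ix_(wbc_rows, range(len(wbc_matrix.sample_ids)))].T
    X_all = np.vstack([mm.values.T, X_wbc])
    y = np.concatenate([np.ones(mm.values.shape[1]), np.zeros(X_wbc.shape[0])]).astype(bool)
    model = fit_logistic(X_all, y, markers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = youden_threshold(build_roc(model.predict(X_all), y))
    return model, thr


def per_type_sensitivity(
    model: LogisticModel,
    threshold: float,
    marker_probes: dict[str, str],
    tumor_matrix: BetaMatrix,
    wbc_matrix: BetaMatrix,
    pairing: list[str],
    annotations,
    f: float = 0.10,
) -> pd.DataFrame:
    """Per-cancer-type sensitivity of one common model + threshold.

    The model (trained on the pooled cohort at the 10% fraction) is
    applied unchanged to each type's mixed tumors; specificity is the
    fraction of WBC samples called negative.  Rows: one per cancer
    type, one "ALL" pooled row, one "WBC" specificity row.
    """
    markers = model.marker_names
    probes = [marker_probes[m] for m in markers]
    mm = mixed_matrix(probes, tumor_matrix, wbc_matrix, pairing, f)
    scores_tumor = model.predict(mm.values.T)
    type_of = {}
    for a in annotations:
        if a.cohort_role == "tumor":
            type_of[a.sample_id] = a.cancer_type
    types = sorted({type_of.get(s) for s in tumor_matrix.sample_ids})
    if None in types:
        raise ValueError("tumor sample missing from annotations")

    rows = []
    positive = scores_tumor >= threshold
    for ct in types:
        mask = np.array([type_of[s] == ct for s in tumor_matrix.sample_ids])
        rows.append(
            {
                "cohort": ct,
                "n": int(mask.sum()),
                "sensitivity": float(positive[mask].mean()),
                "specificity": np.nan,
            }
        )
    rows.append(
        {
            "cohort": "ALL",
            "n": int(positive.size),
            "sensitivity": float(positive.mean()),
            "specificity": np.nan,
        }
    )
    wbc_rows = [wbc_matrix.probe_ids.index(p) for p in probes]
    X_wbc = wbc_matrix.values[np.ix_(wbc_rows, range(len(wbc_matrix.sample_ids)))].T
    spec = float((model.predict(X_wbc) < threshold).mean())
    rows.append({"cohort": "WBC", "n": X_wbc.shape[0], "sensitivity": np.nan, "specificity": spec})
    return pd.DataFrame(rows)
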