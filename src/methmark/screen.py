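"""Differential-methylation probe discovery.

One cancer type at a time, every probe is tested tumor vs. normal: the
screen keeps probes whose absolute difference in both mean and median
beta value exceeds a cutoff (default 0.4) and whose t-test and Wilcoxon
rank-sum p-values stay significant after Bonferroni correction.  For
cohorts where the Wilcoxon constraint would leave nothing, it can be
auto-relaxed (flagged), mirroring how rank tests lose power in small or
tied cohorts.

Also provides the tumor/non-tumor cell-line dichotomization test
(median beta above a small cutoff, Fisher exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, annotations_by_role

__all__ = [
    "ProbeStats",
    "ScreenCriteria",
    "compute_probe_stats",
    "select_probes",
    "cell_line_test",
    "probe_stats_frame",
]


@dataclass(frozen=True)
class ProbeStats:
    """Per-probe tumor-vs-normal screen quantities for one cancer type."""

    probe_id: str
    cancer_type: str
    mean_tumor: float
    mean_normal: float
    median_tumor: float
    median_normal: float
    t_p: float
    wilcoxon_p: float

    @property
    def delta_mean(self) -> float:
        return self.mean_tumor - self.mean_normal

    @property
    def delta_median(self) -> float:
        return self.median_tumor - self.median_normal


@dataclass(frozen=True)
class ScreenCriteria:
    """Selection rule for the probe screen.

    delta: minimum absolute mean AND median difference (strict ">").
    alpha: significance level after Bonferroni correction.
    bonferroni_n: family size; None = number of probes with computable
        statistics in the cancer type (an explicit value, e.g. the
        nominal array size 485512, may be supplied instead).
    require_wilcoxon: demand Wilcoxon significance too; if that leaves
        zero probes the constraint is dropped automatically and the
        relaxation flag is set.
    hypermethylated_only: restrict to tumor-hypermethylated probes
        (positive differences); by default direction is ignored.
    """

    delta: float = 0.4
    alpha: float = 0.05
    bonferroni_n: int | None = None
    require_wilcoxon: bool = True
    hypermethylated_only: bool = False

    def __post_init__(self):
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _two_sample_pvalues(tumor: np.ndarray, normal: np.ndarray):
    """Welch t and Wilcoxon rank-sum (normal approx., tie-corrected) p-values.

    Rows are probes; NaNs are excluded pairwise.  Degenerate rows (all
    ties, or fewer than two values in a class) get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(tumor, normal, axis=1, equal_var=False, nan_policy="omit")
        t_p = np.asarray(t_res.pvalue, dtype=float)
        w_res = stats.mannwhitneyu(
            tumor, normal, axis=1, alternative="two-sided", nan_policy="omit", method="asymptotic"
        )
        w_p = np.asarray(w_res.pvalue, dtype=float)
    t_p = np.where(np.isnan(t_p), 1.0, t_p)
    w_p = np.where(np.isnan(w_p), 1.0, np.minimum(w_p, 1.0))
    return t_p, w_p


def compute_probe_stats(
    matrix: BetaMatrix, annotations, cancer_type: str, pooled_t: bool = False
) -> list[ProbeStats]:
    """Tumor-vs-normal statistics for every probe of one cancer type.

    Uses the Welch (unequal-variance) t-test by default; ``pooled_t``
    switches to the pooled-variance form.  Wilcoxon uses the rank-sum
    normal approximation with tie correction.  Missing values are
    excluded per probe.
    """
    tumor_ids = annotations_by_role(annotations, "tumor", cancer_type)
    normal_ids = annotations_by_role(annotations, "normal_tissue", cancer_type)
    if not tumor_ids or not normal_ids:
        raise ValueError(f"cancer type {cancer_type!r} absent from annotations")
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError(f"need >=2 tumor and >=2 normal samples for {cancer_type}")

    pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    tumor = matrix.values[:, [pos[s] for s in tumor_ids]]
    normal = matrix.values[:, [pos[s] for s in normal_ids]]

    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(tumor, axis=1)
        mean_n = np.nanmean(normal, axis=1)
        median_t = np.nanmedian(tumor, axis=1)
        median_n = np.nanmedian(normal, axis=1)

    if pooled_t:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(tumor, normal, axis=1, equal_var=True, nan_policy="omit")
            t_p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
            w_res = stats.mannwhitneyu(
                tumor, normal, axis=1, alternative="two-sided",
                nan_policy="omit", method="asymptotic",
            )
            w_p = np.where(np.isnan(w_res.pvalue), 1.0, np.minimum(w_res.pvalue, 1.0))
    else:
        t_p, w_p = _two_sample_pvalues(tumor, normal)

    return [
        ProbeStats(
            probe_id=matrix.probe_ids[i],
            cancer_type=cancer_type,
            mean_tumor=float(mean_t[i]),
            mean_normal=float(mean_n[i]),
            median_tumor=float(median_t[i]),
            median_normal=float(median_n[i]),
            t_p=float(t_p[i]),
            wilcoxon_p=float(w_p[i]),
        )
        for i in range(len(matrix.probe_ids))
    ]


def select_probes(stats_list, criteria: ScreenCriteria = ScreenCriteria()):
    """Apply the conjunctive screen; returns (selected, wilcoxon_relaxed).

    A probe passes iff |delta mean| > delta AND |delta median| > delta
    AND Bonferroni-corrected t p < alpha AND (corrected Wilcoxon p <
    alpha, unless relaxed).  If ``require_wilcoxon`` and nothing passes,
    the Wilcoxon constraint is dropped and the relaxation flag returned
    as True.
    """
    stats_list = list(stats_list)
    if not stats_list:
        raise ValueError("empty probe statistics")
    n_tests = criteria.bonferroni_n or len(stats_list)

    def passes(s: ProbeStats, use_wilcoxon: bool) -> bool:
        dm, dmed = s.delta_mean, s.delta_median
        if criteria.hypermethylated_only and (dm <= 0 or dmed <= 0):
            return False
        if not (abs(dm) > criteria.delta and abs(dmed) > criteria.delta):
            return False
        if min(1.0, s.t_p * n_tests) >= criteria.alpha:
            return False
        if use_wilcoxon and min(1.0, s.wilcoxon_p * n_tests) >= criteria.alpha:
            return False
        return True

    if criteria.require_wilcoxon:
        selected = [s for s in stats_list if passes(s, True)]
        if selected:
            return selected, False
        relaxed = [s for s in stats_list if passes(s, False)]
        return relaxed, bool(relaxed)  # flag only when relaxation recovered probes
    return [s for s in stats_list if passes(s, False)], False


def cell_line_test(median_betas, is_tumor, cutoff: float = 0.02):
    """Dichotomize cell lines at a median-beta cutoff and Fisher-test.

    A line is positive iff its median beta is strictly greater than
    ``cutoff``.  Returns (2x2 table as [[tumor_pos, tumor_neg],
    [normal_pos, normal_neg]], two-sided Fisher exact p).
    """
    median_betas = np.asarray(median_betas, dtype=float)
    is_tumor = np.asarray(is_tumor, dtype=bool)
    if median_betas.shape != is_tumor.shape:
        raise ValueError("median_betas and is_tumor must align")
    if is_tumor.all() or (~is_tumor).all():
        raise ValueError("need at least one line in each class")
    positive = median_betas > cutoff
    table = np.array(
        [
            [int((positive & is_tumor).sum()), int((~positive & is_tumor).sum())],
            [int((positive & ~is_tumor).sum()), int((~positive & ~is_tumor).sum())],
        ]
    )
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    return table, float(p)


def probe_stats_frame(stats_list, selected=None, relaxed: bool | None = None) -> pd.DataFrame:
    """Tabulate probe statistics (and selection status) for export."""
    sel = {s.probe_id for s in selected} if selected is not None else None
    rows = []
    for s in stats_list:
        row = {
            "probe_id": s.probe_id,
            "cancer_type": s.cancer_type,
            "mean_tumor": s.mean_tumor,
            "mean_normal": s.mean_normal,
            "median_tumor": s.median_tumor,
            "median_normal": s.median_normal,
            "delta_mean": s.delta_mean,
            "delta_median": s.delta_median,
            "t_p": s.t_p,
            "wilcoxon_p": s.wilcoxon_p,
        }
        if sel is not None:
            row["selected"] = s.probe_id in sel
            row["wilcoxon_relaxed"] = bool(relaxed)
        rows.append(row)
    return pd.DataFrame(rows)
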