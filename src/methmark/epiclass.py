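"""Read-level plasma classification via dual methylation-density /
epiallele-fraction thresholds.

Tumor-derived cell-free DNA is extremely dilute, but the reads it
contributes carry a distinctive epiallele signature: a high fraction of
methylated CpGs *within* each read, against a background of mostly
unmethylated reads.  The classifier therefore sets two thresholds per
marker region:

- ``md_min``: minimum per-read methylation density (fraction of
  methylated CpGs among the in-region CpGs the read covers), and
- ``ef_min``: minimum epiallele fraction (fraction of a sample's reads
  whose density is at or above ``md_min``).

A sample is positive iff its epiallele fraction at ``md_min`` is at
least ``ef_min`` (both comparisons inclusive).  Training solves for the
two thresholds simultaneously by exhaustive search over the finite
candidate grid {0} + observed read densities x {0} + achievable
epiallele fractions — any threshold outside this set classifies the
training data identically to some member, so the search is exact.

Among equally optimal pairs the lowest ``md_min`` (then the highest
``ef_min``) is returned: the lowest density threshold retains the most
tumor-derived (often partially methylated) reads on unseen samples and
tracks the boundary between the background and tumor read populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amplicon import combine_any_k
from .classify import PerformanceRecord, auc, build_roc
from .io import MethylRead, ReadSet

__all__ = [
    "EpiclassThresholds",
    "SampleRegionSummary",
    "OBJECTIVES",
    "methylation_density",
    "epiallele_fraction",
    "classify_sample",
    "summarize_readset",
    "train_thresholds",
    "evaluate_split_cv",
    "train_only_evaluation",
]

OBJECTIVES = (
    "max_specificity_then_sensitivity",
    "max_youden",
    "max_sensitivity_then_specificity",
)


@dataclass(frozen=True)
class EpiclassThresholds:
    """The trained (md_min, ef_min) pair for one marker region."""

    md_min: float
    ef_min: float
    objective: str
    region: str

    def __post_init__(self):
        if not (0.0 <= self.md_min <= 1.0 and 0.0 <= self.ef_min <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class SampleRegionSummary:
    """Per-read methylation densities of one sample over one region."""

    sample_id: str
    region: str
    densities: np.ndarray

    def __post_init__(self):
        self.densities = np.sort(np.asarray(self.densities, dtype=float))
        if self.densities.size and (
            self.densities[0] < 0.0 or self.densities[-1] > 1.0
        ):
            raise ValueError("densities must lie in [0, 1]")

    @property
    def n_reads(self) -> int:
        return int(self.densities.size)


def methylation_density(read: MethylRead) -> float:
    """Fraction of methylated CpGs among the read's in-region CpGs."""
    if len(read.calls) == 0:
        raise ValueError(f"read {read.read_id} covers no in-region CpGs")
    return sum(read.calls) / len(read.calls)


def summarize_readset(readset: ReadSet, region: str) -> SampleRegionSummary:
    """Collapse a sample's reads over one region to a density multiset."""
    reads = readset.reads.get(region, [])
    return SampleRegionSummary(
        readset.sample_id, region, np.array([methylation_density(r) for r in reads])
    )


def epiallele_fraction(summary: SampleRegionSummary, md_min: float) -> float:
    """Fraction of reads with density at or above ``md_min``."""
    if summary.n_reads == 0:
        raise ValueError(f"sample {summary.sample_id}: no reads in {summary.region}")
    # densities are kept sorted; count reads >= md_min
    i = np.searchsorted(summary.densities, md_min, side="left")
    return float((summary.n_reads - i) / summary.n_reads)


def classify_sample(summary: SampleRegionSummary, thresholds: EpiclassThresholds) -> bool:
    """Positive iff the epiallele fraction at md_min reaches ef_min."""
    return epiallele_fraction(summary, thresholds.md_min) >= thresholds.ef_min


def _ef_matrix(summaries, md_candidates):
    """Rows: samples; columns: epiallele fraction at each md candidate."""
    out = np.empty((len(summaries), md_candidates.size))
    for i, s in enumerate(summaries):
        idx = np.searchsorted(s.densities, md_candidates, side="left")
        out[i] = (s.n_reads - idx) / s.n_reads
    return out


def _objective_key(objective: str, sens: np.ndarray, spec: np.ndarray):
    if objective == "max_specificity_then_sensitivity":
        return np.stack([spec, sens])
    if objective == "max_sensitivity_then_specificity":
        return np.stack([sens, spec])
    if objective == "max_youden":
        return np.stack([sens + spec])
    raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")


def train_thresholds(
    cases,
    controls,
    region: str,
    objective: str = "max_specificity_then_sensitivity",
) -> tuple[EpiclassThresholds, pd.DataFrame]:
    """Exhaustive exact search for the optimal (md_min, ef_min) pair.

    ``cases`` / ``controls`` are :class:`SampleRegionSummary` lists for
    one region.  Returns the trained thresholds plus the full objective
    surface (one row per candidate pair with its training sensitivity
    and specificity) for heatmap-style inspection.
    """
    cases, controls = list(cases), list(controls)
    if not cases or not controls:
        raise ValueError("need at least one case and one control")
    all_d = np.concatenate([s.densities for s in cases + controls])
    md_candidates = np.unique(np.concatenate([[0.0], all_d]))
    ef_case = _ef_matrix(cases, md_candidates)
    ef_ctrl = _ef_matrix(controls, md_candidates)

    best = None  # (objective key tuple, -md, ef, md)
    surface_rows = []
    for j, md in enumerate(md_candidates):
        col_case = ef_case[:, j]
        col_ctrl = ef_ctrl[:, j]
        ef_candidates = np.unique(np.concatenate([[0.0], col_case, col_ctrl]))
        sc = np.sort(col_case)
        st = np.sort(col_ctrl)
        # positive iff EF >= ef: sens/spec for every candidate at once
        sens = 1.0 - np.searchsorted(sc, ef_candidates, side="left") / sc.size
        spec = np.searchsorted(st, ef_candidates, side="left") / st.size
        keys = _objective_key(objective, sens, spec)
        for i, ef in enumerate(ef_candidates):
            surface_rows.append(
                {
                    "md_min": float(md),
                    "ef_min": float(ef),
                    "sensitivity": float(sens[i]),
                    "specificity": float(spec[i]),
                }
            )
            cand = (tuple(np.round(keys[:, i], 12)), -float(md), float(ef))
            if best is None or cand > best:
                best = cand
    _, neg_md, ef = best
    thresholds = EpiclassThresholds(-neg_md, ef, objective, region)
    return thresholds, pd.DataFrame(surface_rows)


def _performance(summaries_case, summaries_ctrl, thresholds) -> tuple[float, float]:
    sens = float(np.mean([classify_sample(s, thresholds) for s in summaries_case]))
    spec = float(np.mean([not classify_sample(s, thresholds) for s in summaries_ctrl]))
    return sens, spec


def train_only_evaluation(
    cases,
    controls,
    regions,
    objective: str = "max_specificity_then_sensitivity",
) -> tuple[pd.DataFrame, dict[str, EpiclassThresholds]]:
    """Train and evaluate on the same samples (no held-out validation).

    Mirrors small-cohort usage where every sample is training data; all
    output rows carry ``training_only=True`` as an overfitting caveat.
    Per-marker thresholds are trained independently, then combined with
    the any-k rule.
    """
    regions = list(regions)
    rows = []
    trained: dict[str, EpiclassThresholds] = {}
    calls: dict[str, dict[str, bool]] = {}
    for region in regions:
        sc = [summarize_readset(r, region) for r in cases]
        st = [summarize_readset(r, region) for r in controls]
        thr, _ = train_thresholds(sc, st, region, objective)
        trained[region] = thr
        sens, spec = _performance(sc, st, thr)
        calls[region] = {
            s.sample_id: classify_sample(s, thr) for s in sc + st
        }
        rows.append(
            {
                "assay": region,
                "sensitivity": sens,
                "specificity": spec,
                "md_min": thr.md_min,
                "ef_min": thr.ef_min,
                "training_only": True,
            }
        )
    if len(regions) > 1:
        case_ids = {r.sample_id for r in cases}
        for k, label in ((1, "any-one"), (2, "any-two")):
            if k > len(regions):
                continue
            combined, _ = combine_any_k(calls, k)
            sens = float(np.mean([combined[s] for s in combined if s in case_ids]))
            spec = float(np.mean([not combined[s] for s in combined if s not in case_ids]))
            rows.append(
                {
                    "assay": f"{label}:" + "+".join(regions),
                    "sensitivity": sens,
                    "specificity": spec,
                    "md_min": np.nan,
                    "ef_min": np.nan,
                    "training_only": True,
                }
            )
    return pd.DataFrame(rows), trained


def evaluate_split_cv(
    cases,
    controls,
    regions,
    n_iter: int = 5,
    objective: str = "max_specificity_then_sensitivity",
    seed: int = 0,
) -> pd.DataFrame:
    """Iterated half-split validation of the dual-threshold classifier.

    Cases and controls are each randomly halved per iteration (odd
    cohorts split floor/ceil); per-marker thresholds are trained on one
    half and applied to the other.  Combination calls use the any-one
    and any-two rules over the per-marker calls.  The ``ef_auc`` column
    reports the held-out AUC of the epiallele-fraction statistic at the
    trained ``md_min`` (threshold-free discrimination).
    """
    cases, controls = list(cases), list(controls)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >=2 samples per class")
    regions = list(regions)
    ss = np.random.SeedSequence(seed)
    rows = []
    for it, child in enumerate(ss.spawn(n_iter), start=1):
        rng = np.random.default_rng(child)
        perm_case = rng.permutation(len(cases))
        perm_ctrl = rng.permutation(len(controls))
        half_case = len(cases) // 2
        half_ctrl = len(controls) // 2
        train_cases = [cases[i] for i in perm_case[:half_case]]
        test_cases = [cases[i] for i in perm_case[half_case:]]
        train_ctrls = [controls[i] for i in perm_ctrl[:half_ctrl]]
        test_ctrls = [controls[i] for i in perm_ctrl[half_ctrl:]]

        calls: dict[str, dict[str, bool]] = {}
        for region in regions:
            thr, _ = train_thresholds(
                [summarize_readset(r, region) for r in train_cases],
                [summarize_readset(r, region) for r in train_ctrls],
                region,
                objective,
            )
            tc = [summarize_readset(r, region) for r in test_cases]
            tt = [summarize_readset(r, region) for r in test_ctrls]
            sens, spec = _performance(tc, tt, thr)
            ef_scores = np.array(
                [epiallele_fraction(s, thr.md_min) for s in tc + tt]
            )
            labels = np.array([True] * len(tc) + [False] * len(tt))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ef_auc = auc(build_roc(ef_scores, labels))
            except ValueError:
                ef_auc = np.nan
            calls[region] = {
                s.sample_id: classify_sample(s, thr) for s in tc + tt
            }
            rows.append(
                {
                    "iteration": it,
                    "assay": region,
                    "sensitivity": sens,
                    "specificity": spec,
                    "md_min": thr.md_min,
                    "ef_min": thr.ef_min,
                    "ef_auc": ef_auc,
                }
            )
        if len(regions) > 1:
            case_ids = {r.sample_id for r in test_cases}
            for k, label in ((1, "any-one"), (2, "any-two")):
                if k > len(regions):
                    continue
                combined, _ = combine_any_k(calls, k)
                sens = float(np.mean([combined[s] for s in combined if s in case_ids]))
                spec = float(
                    np.mean([not combined[s] for s in combined if s not in case_ids])
                )
                rows.append(
                    {
                        "iteration": it,
                        "assay": f"{label}:" + "+".join(regions),
                        "sensitivity": sens,
                        "specificity": spec,
                        "md_min": np.nan,
                        "ef_min": np.nan,
                        "ef_auc": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def summarize_cv(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- 1 SD of held-out sensitivity/specificity per assay."""
    return (
        records.groupby("assay")[["sensitivity", "specificity"]]
        .agg(["mean", "std"])
        .reset_index()
    )


def performance_record(
    row, combination: tuple[str, ...], cohort: str, training_only: bool
) -> PerformanceRecord:
    """Adapt a result row to the shared performance-record type."""
    return PerformanceRecord(
        marker_combination=combination,
        cohort=cohort,
        sensitivity=float(row["sensitivity"]),
        specificity=float(row["specificity"]),
        auc=float(row.get("ef_auc", np.nan)),
        threshold=float(row.get("ef_min", np.nan)),
        training_only=training_only,
    )
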