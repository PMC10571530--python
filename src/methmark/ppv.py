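"""Positive-predictive-value projection for screening.

For a screening test applied to a population where the disease arises
at incidence f (a fraction of 1), Bayes' rule gives

    PPV = sens * f / (sens * f + (1 - spec) * (1 - f))

Multi-cancer aggregation replaces the numerator term by the
incidence-weighted sum of per-type sensitivities, sum_i sens_i * f_i,
and the healthy fraction by 1 - sum_i f_i:

    PPV_all = S / (S + (1 - spec) * (1 - F)),
    S = sum_i sens_i * f_i,  F = sum_i f_i

which reduces to the single-type form when all sensitivities are equal
(then S = s * F).  Incidence is used rather than prevalence: in a
repeatedly screened population the test confronts newly arising cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RocCurve, threshold_at_specificity, youden_threshold

__all__ = [
    "IncidenceTable",
    "PpvResult",
    "ppv",
    "aggregate_multi_cancer_ppv",
    "ppv_at_policy",
]


@dataclass
class IncidenceTable:
    """Per-cancer-type screening incidence as a fraction of 1."""

    incidence: dict[str, float]

    def __post_init__(self):
        for ct, f in self.incidence.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"incidence for {ct} must be in (0, 1), got {f}")

    @classmethod
    def from_per_100k(cls, rates: dict[str, float]) -> "IncidenceTable":
        """Convert age-adjusted rates per 100,000 to fractions of 1."""
        return cls({ct: r / 100_000.0 for ct, r in rates.items()})

    @classmethod
    def read(cls, path) -> "IncidenceTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_per_100k(dict(zip(df["cancer_type"], df["rate_per_100k"].astype(float))))

    def total(self) -> float:
        return float(sum(self.incidence.values()))


@dataclass(frozen=True)
class PpvResult:
    """A PPV with the inputs that produced it."""

    scope: str  # cancer type or "ALL"
    ppv: float
    sensitivity: float | dict[str, float]
    specificity: float
    incidence: float  # aggregate incidence for scope "ALL"
    threshold_policy: str = "youden"

    def __post_init__(self):
        if not 0.0 <= self.ppv <= 1.0:
            raise ValueError(f"PPV {self.ppv} outside [0, 1]")


def ppv(
    sensitivity: float,
    specificity: float,
    incidence: float,
    scope: str = "",
    threshold_policy: str = "youden",
) -> PpvResult:
    """Closed-form single-type PPV."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    if not 0.0 <= incidence < 1.0:
        raise ValueError(f"incidence {incidence} outside [0, 1)")
    numer = sensitivity * incidence
    denom = numer + (1.0 - specificity) * (1.0 - incidence)
    value = 0.0 if numer == 0.0 else numer / denom
    return PpvResult(scope, value, sensitivity, specificity, incidence, threshold_policy)


def aggregate_multi_cancer_ppv(
    per_type_sensitivities: dict[str, float],
    specificity: float,
    incidences: IncidenceTable,
    threshold_policy: str = "youden",
) -> PpvResult:
    """Multi-cancer PPV with incidence-weighted sensitivities."""
    missing = set(incidences.incidence) - set(per_type_sensitivities)
    if missing:
        raise ValueError(f"sensitivity missing for types: {sorted(missing)}")
    if not 0.0 <= specificity <= 1.0:
        raise ValueError("specificity outside [0, 1]")
    F = incidences.total()
    if F >= 1.0:
        raise ValueError("aggregate incidence >= 1")
    S = sum(per_type_sensitivities[ct] * f for ct, f in incidences.incidence.items())
    denom = S + (1.0 - specificity) * (1.0 - F)
    value = 0.0 if S == 0.0 else S / denom
    return PpvResult(
        "ALL",
        value,
        dict(per_type_sensitivities),
        specificity,
        F,
        threshold_policy,
    )


POLICIES = ("youden", "fixed_specificity")


def ppv_at_policy(
    rocs: dict[str, RocCurve],
    policy: str,
    incidence: float,
    target_specificity: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """PPV per marker combination under a thresholding policy.

    ``rocs`` maps combination label -> ROC of its pooled classifier.
    Policy ``youden`` maximizes J; ``fixed_specificity`` takes the most
    sensitive operating point with specificity >= target.  Returns a
    per-combination table plus summary statistics (median and
    quartiles across combinations).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    rows = []
    for combo, roc in rocs.items():
        if policy == "youden":
            thr = youden_threshold(roc)
        else:
            thr = threshold_at_specificity(roc, target_specificity)
        i = int(np.argmin(np.abs(roc.thresholds - thr)))
        sens, spec = float(roc.sensitivity[i]), float(roc.specificity[i])
        res = ppv(sens, spec, incidence, scope="ALL", threshold_policy=policy)
        rows.append(
            {
                "combination": combo,
                "policy": policy,
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
                "ppv": res.ppv,
            }
        )
    df = pd.DataFrame(rows)
    q1, med, q3 = np.percentile(df["ppv"], [25, 50, 75])
    return df, {"median": float(med), "q1": float(q1), "q3": float(q3)}


def compare_policies(ppv_a, ppv_b) -> float:
    """Paired Wilcoxon signed-rank p between two policies' PPVs."""
    diff = np.asarray(ppv_a, dtype=float) - np.asarray(ppv_b, dtype=float)
    if np.allclose(diff, 0.0):
        return 1.0
    return float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)
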