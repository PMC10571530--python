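"""Amplicon-sequencing assay logic.

A targeted bisulfite amplicon reports, per sample and marker, the mean
methylation percentage across the CpGs of the amplified region plus the
aligned read count.  Classification uses the max-normal rule: the
threshold is the maximum mean methylation observed among normal
samples, and a sample is called positive only if it is strictly above
that — which makes the training-set specificity 100% by construction.
Markers are combined with an any-k rule (positive iff at least k member
markers are positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "AmpliconSample",
    "QcRule",
    "DEFAULT_QC_RULE",
    "qc_filter",
    "max_normal_threshold",
    "classify_amplicon",
    "combine_any_k",
    "single_cpg_reanalysis",
]


@dataclass(frozen=True)
class AmpliconSample:
    """Per-sample, per-marker amplicon summary."""

    sample_id: str
    marker: str
    tissue_label: str  # "tumor" | "normal"
    read_count: int
    mean_methylation: float  # percent, [0, 100]
    per_cpg: tuple[float, ...] | None = None  # percent per CpG position

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError(f"{self.sample_id}/{self.marker}: negative read count")
        if not 0.0 <= self.mean_methylation <= 100.0:
            raise ValueError(
                f"{self.sample_id}/{self.marker}: mean methylation outside [0, 100]"
            )


@dataclass(frozen=True)
class QcRule:
    """Per-marker minimum aligned read count.

    The deeper-sequenced marker uses 500 reads; shallower amplicons use
    a proportionally lower cutoff of 19 reads.
    """

    min_reads: dict[str, int]

    def __post_init__(self):
        if any(v <= 0 for v in self.min_reads.values()):
            raise ValueError("read-count minima must be positive")

    def minimum(self, marker: str) -> int:
        if marker not in self.min_reads:
            raise KeyError(f"no QC rule for marker {marker!r}")
        return self.min_reads[marker]


DEFAULT_QC_RULE = QcRule({"ZNF154": 500, "TLX1": 19, "GALR1": 19})


def qc_filter(samples, rule: QcRule) -> tuple[list[AmpliconSample], pd.DataFrame]:
    """Drop samples whose read count is below the marker's minimum.

    A sample is retained iff ``read_count >= minimum`` (exclusion is
    "count < cutoff").  Returns the retained samples and an exclusion
    log with one row per dropped sample.
    """
    kept: list[AmpliconSample] = []
    dropped: list[dict] = []
    for s in samples:
        minimum = rule.minimum(s.marker)
        if s.read_count >= minimum:
            kept.append(s)
        else:
            dropped.append(
                {
                    "sample_id": s.sample_id,
                    "marker": s.marker,
                    "read_count": s.read_count,
                    "minimum": minimum,
                    "reason": f"read count {s.read_count} < {minimum}",
                }
            )
    log = pd.DataFrame(dropped, columns=["sample_id", "marker", "read_count", "minimum", "reason"])
    return kept, log


def max_normal_threshold(samples, marker: str | None = None) -> float:
    """Classification threshold = max mean methylation among normals.

    ``samples`` should already have passed QC.  Positivity downstream is
    strictly greater than the returned value, so every training normal
    is negative (100% training specificity).
    """
    values = [
        s.mean_methylation
        for s in samples
        if s.tissue_label == "normal" and (marker is None or s.marker == marker)
    ]
    if not values:
        raise ValueError("no QC-passing normal samples to set a threshold")
    return max(values)


def classify_amplicon(samples, threshold: float, marker: str | None = None) -> dict[str, bool]:
    """Positivity call per sample id: strictly above the threshold."""
    return {
        s.sample_id: s.mean_methylation > threshold
        for s in samples
        if marker is None or s.marker == marker
    }


def combine_any_k(calls_per_marker: dict[str, dict[str, bool]], k: int):
    """Combine per-marker calls: positive iff >= k member markers positive.

    Only samples with a call for every marker enter (the assay requires
    passing the read-count limit for all markers).  Returns the combined
    call per sample and Venn membership counts keyed by the sorted tuple
    of positive markers.
    """
    markers = sorted(calls_per_marker)
    if k > len(markers):
        raise ValueError(f"k={k} exceeds {len(markers)} markers")
    if k < 1:
        raise ValueError("k must be >= 1")
    common = set.intersection(*(set(calls_per_marker[m]) for m in markers))
    combined: dict[str, bool] = {}
    venn: dict[tuple[str, ...], int] = {}
    for size in range(len(markers) + 1):
        for subset in combinations(markers, size):
            venn[subset] = 0
    for sid in sorted(common):
        positive = tuple(m for m in markers if calls_per_marker[m][sid])
        combined[sid] = len(positive) >= k
        venn[positive] += 1
    return combined, venn


def single_cpg_reanalysis(samples, cpg_index: int) -> tuple[float, dict[str, bool]]:
    """Max-normal classification using only the designated CpG.

    ``cpg_index`` selects the position of the array-designated CpG
    within each sample's per-CpG vector.  Returns (threshold, calls).
    """

    def value(s: AmpliconSample) -> float:
        if s.per_cpg is None or not 0 <= cpg_index < len(s.per_cpg):
            raise ValueError(
                f"{s.sample_id}/{s.marker}: designated CpG index {cpg_index} absent"
            )
        return s.per_cpg[cpg_index]

    normals = [value(s) for s in samples if s.tissue_label == "normal"]
    if not normals:
        raise ValueError("no normal samples")
    threshold = max(normals)
    calls = {s.sample_id: value(s) > threshold for s in samples}
    return threshold, calls


def read_amplicon_table(path) -> list[AmpliconSample]:
    """Read the amplicon TSV (sample, marker, tissue, read_count, mean_pct
    and optional per-CpG percent columns cpg1..cpgN)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cpg_cols = [c for c in df.columns if c.startswith("cpg")]
    samples = []
    for rec in df.itertuples(index=False):
        per_cpg = tuple(float(getattr(rec, c)) for c in cpg_cols) if cpg_cols else None
        samples.append(
            AmpliconSample(
                sample_id=str(rec.sample_id),
                marker=str(rec.marker),
                tissue_label=str(rec.tissue),
                read_count=int(rec.read_count),
                mean_methylation=float(rec.mean_pct),
                per_cpg=per_cpg,
            )
        )
    return samples


def amplicon_table(samples) -> pd.DataFrame:
    n_cpgs = max((len(s.per_cpg) for s in samples if s.per_cpg), default=0)
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "marker": s.marker,
            "tissue": s.tissue_label,
            "read_count": s.read_count,
            "mean_pct": s.mean_methylation,
        }
        if s.per_cpg:
            row.update({f"cpg{i + 1}": v for i, v in enumerate(s.per_cpg)})
        rows.append(row)
    cols = ["sample_id", "marker", "tissue", "read_count", "mean_pct"]
    cols += [f"cpg{i + 1}" for i in range(n_cpgs)]
    return pd.DataFrame(rows, columns=cols)


def sensitivity(calls: dict[str, bool], tumor_ids) -> float:
    """Fraction of tumor samples called positive."""
    tumor_ids = [t for t in tumor_ids if t in calls]
    if not tumor_ids:
        raise ValueError("no tumor samples among calls")
    return sum(calls[t] for t in tumor_ids) / len(tumor_ids)
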