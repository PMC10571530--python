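"""Seeded generators for synthetic methylation cohorts and plasma reads.

The generators emulate the statistical structure the downstream
analyses assume, so every pipeline stage can be exercised without any
external download:

- :func:`gen_beta_cohorts` draws per-cohort beta-value matrices with
  planted tumor-vs-normal differential markers and an optional elevated
  white-blood-cell background (the behaviour that degrades a marker in
  diluted plasma even when its tumor/normal contrast is strong).
- :func:`gen_plasma_readsets` draws read-level plasma data where a
  tumor-derived fraction of reads carries high within-read methylation
  density over a low-density background — the dilute epiallele
  structure the read-level classifier is designed for.
- :func:`gen_amplicon_samples` draws per-sample amplicon summaries
  (mean methylation percent, read counts) for the max-normal-threshold
  assay.

One global seed is expanded into independent substreams via
``numpy.random.SeedSequence`` so stages can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSample
from .io import BetaMatrix, MethylRead, ReadSet, RegionSet, SampleAnnotation

__all__ = [
    "PlantedMarker",
    "ArraySimConfig",
    "ReadSimConfig",
    "gen_beta_cohorts",
    "gen_plasma_readsets",
    "gen_amplicon_samples",
]


def _check_beta_params(name, params):
    a, b = params
    if a <= 0 or b <= 0:
        raise ValueError(f"{name}: Beta parameters must be positive, got ({a}, {b})")
    return float(a), float(b)


@dataclass(frozen=True)
class PlantedMarker:
    """A probe with cohort-specific beta laws.

    ``Beta(a, b)`` has mean a/(a+b); e.g. tumor Beta(8, 2) vs normal
    Beta(2, 8) plants a mean differential of 0.6.
    """

    probe_index: int
    tumor: tuple[float, float]
    normal: tuple[float, float]
    wbc: tuple[float, float]

    def __post_init__(self):
        _check_beta_params("tumor", self.tumor)
        _check_beta_params("normal", self.normal)
        _check_beta_params("wbc", self.wbc)


@dataclass
class ArraySimConfig:
    """Configuration for the array-cohort generator.

    Defaults follow the study geometry scaled to desk size: several
    cancer types with tumor and adjacent-normal cohorts, one shared
    white-blood-cell cohort, markers planted on a flat Beta(2, 2)
    background that is identically distributed across cohorts.
    """

    n_cancer_types: int = 3
    n_tumor: int = 50  # per cancer type
    n_normal: int = 50  # per cancer type
    n_wbc: int = 100
    n_probes: int = 1000
    planted_markers: list[PlantedMarker] = field(default_factory=list)
    background: tuple[float, float] = (2.0, 2.0)
    assign_stages: bool = False
    seed: int = 0

    def __post_init__(self):
        _check_beta_params("background", self.background)
        for m in self.planted_markers:
            if not 0 <= m.probe_index < self.n_probes:
                raise ValueError(f"planted probe index {m.probe_index} >= n_probes")


_STAGES = ("I", "II", "III", "IV")


def gen_beta_cohorts(config: ArraySimConfig) -> tuple[BetaMatrix, list[SampleAnnotation]]:
    """Draw a beta matrix plus annotations; deterministic given the seed.

    Planted probes are drawn from their cohort-specific Beta laws (the
    WBC law applies to the shared blood cohort); every other probe is
    drawn i.i.d. from the background law in all cohorts.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_marked, rng_stage = (np.random.default_rng(s) for s in ss.spawn(3))

    types = [f"CT{i + 1:02d}" for i in range(config.n_cancer_types)]
    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    cohorts: list[tuple[str, str]] = []  # (role, cancer_type or "")
    for ct in types:
        for i in range(config.n_tumor):
            sid = f"{ct}_T{i + 1:03d}"
            stage = _STAGES[rng_stage.integers(len(_STAGES))] if config.assign_stages else None
            sample_ids.append(sid)
            annotations.append(SampleAnnotation(sid, "tumor", ct, stage))
            cohorts.append(("tumor", ct))
        for i in range(config.n_normal):
            sid = f"{ct}_N{i + 1:03d}"
            sample_ids.append(sid)
            annotations.append(SampleAnnotation(sid, "normal_tissue", ct))
            cohorts.append(("normal_tissue", ct))
    for i in range(config.n_wbc):
        sid = f"WBC_{i + 1:04d}"
        sample_ids.append(sid)
        annotations.append(SampleAnnotation(sid, "wbc"))
        cohorts.append(("wbc", ""))

    n_samples = len(sample_ids)
    a_bg, b_bg = config.background
    values = rng_bg.beta(a_bg, b_bg, size=(config.n_probes, n_samples))
    role_of = np.array([c[0] for c in cohorts])
    for marker in config.planted_markers:
        row = np.empty(n_samples)
        for role, params in (
            ("tumor", marker.tumor),
            ("normal_tissue", marker.normal),
            ("wbc", marker.wbc),
        ):
            mask = role_of == role
            row[mask] = rng_marked.beta(params[0], params[1], size=mask.sum())
        values[marker.probe_index] = row

    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    return BetaMatrix(probe_ids, sample_ids, values), annotations


@dataclass
class ReadSimConfig:
    """Configuration for the plasma read-set generator.

    ``tumor_read_fraction`` (rho) is the probability that a case read is
    tumor-derived; tumor reads methylate each CpG with probability
    ``p_hi``, background reads with ``p_lo``.  Controls have rho = 0 by
    construction.
    """

    n_case: int = 30
    n_control: int = 30
    reads_per_sample: int = 200
    cpgs_per_region: int = 20
    tumor_read_fraction: float = 0.2
    p_hi: float = 0.9
    p_lo: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_lo <= self.p_hi <= 1.0:
            raise ValueError("need 0 <= p_lo <= p_hi <= 1")
        if not 0.0 <= self.tumor_read_fraction <= 1.0:
            raise ValueError("tumor_read_fraction must be in [0, 1]")


def gen_plasma_readsets(config: ReadSimConfig, regions: RegionSet) -> list[ReadSet]:
    """Draw case/control read sets over the given marker regions.

    CpG positions are evenly spaced inside each window; every read
    covers all of them (reads clipped to the region, as after ingest).
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_case + config.n_control)
    readsets: list[ReadSet] = []
    labels = ["case"] * config.n_case + ["control"] * config.n_control
    for i, label in enumerate(labels):
        rng = np.random.default_rng(streams[i])
        sid = f"{'P' if label == 'case' else 'H'}{i + 1:03d}"
        rs = ReadSet(sid, label)
        rho = config.tumor_read_fraction if label == "case" else 0.0
        for region in regions:
            span = region.end - region.start
            step = max(1, span // (config.cpgs_per_region + 1))
            positions = tuple(
                region.start + (j + 1) * step for j in range(config.cpgs_per_region)
            )
            is_tumor = rng.random(config.reads_per_sample) < rho
            p = np.where(is_tumor, config.p_hi, config.p_lo)
            calls = rng.random((config.reads_per_sample, config.cpgs_per_region)) < p[:, None]
            reads = [
                MethylRead(
                    f"{sid}_{region.name}_r{j + 1:04d}",
                    region.name,
                    positions,
                    tuple(int(c) for c in calls[j]),
                )
                for j in range(config.reads_per_sample)
            ]
            rs.reads[region.name] = reads
        readsets.append(rs)
    return readsets


def gen_amplicon_samples(
    n_tumor: int,
    n_normal: int,
    markers=("GALR1", "TLX1", "ZNF154"),
    tumor_level: tuple[float, float] = (60.0, 15.0),
    normal_level: tuple[float, float] = (5.0, 3.0),
    mean_read_count: int = 2000,
    n_cpgs: int = 20,
    seed: int = 0,
) -> list[AmpliconSample]:
    """Draw per-sample amplicon summaries for each marker.

    Mean methylation percent is drawn from a truncated normal per
    tissue class (``(mean, sd)`` in percent); per-CpG percentages are
    jittered around the sample mean; read counts are Poisson around
    ``mean_read_count`` so QC filtering has something to act on.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples: list[AmpliconSample] = []
    for tissue, n, (mu, sd) in (
        ("tumor", n_tumor, tumor_level),
        ("normal", n_normal, normal_level),
    ):
        for i in range(n):
            sid = f"{'T' if tissue == 'tumor' else 'N'}{i + 1:03d}"
            for marker in markers:
                level = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
                per_cpg = np.clip(rng.normal(level, 5.0, size=n_cpgs), 0.0, 100.0)
                mean_pct = float(per_cpg.mean())
                samples.append(
                    AmpliconSample(
                        sample_id=sid,
                        marker=marker,
                        tissue_label=tissue,
                        read_count=int(rng.poisson(mean_read_count)),
                        mean_methylation=mean_pct,
                        per_cpg=tuple(float(v) for v in per_cpg),
                    )
                )
    return samples
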