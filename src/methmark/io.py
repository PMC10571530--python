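"""Domain types and readers/writers for methylation data.

Containers
----------
:class:`BetaMatrix`
    Probes x samples matrix of methylation beta values (fractions in
    [0, 1]; NaN marks a masked/missing data point).
:class:`SampleAnnotation`
    Cohort role (tumor / normal tissue / white blood cell), cancer type,
    and optional tumor stage per sample.
:class:`RegionSet`
    Marker windows on the genome plus the designated array-probe
    position inside each window.
:class:`MethylRead` / :class:`ReadSet`
    Per-read CpG methylation calls over a marker region, grouped per
    sample, as produced by bisulfite sequencing.

Coordinates are stored 0-based half-open internally (BED convention);
readers accept 1-based inclusive input via a flag and convert on
ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "BetaMatrix",
    "SampleAnnotation",
    "Region",
    "RegionSet",
    "MethylRead",
    "ReadSet",
    "DEFAULT_MARKER_REGIONS",
    "default_regions",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotations",
    "write_annotations",
    "read_regions",
    "write_regions",
    "read_reads",
    "write_reads",
    "read_reads_sam",
]

#: Marker windows from the discovery analysis (hg19, converted to
#: 0-based half-open) with the designated 450K probe position of each
#: marker (0-based position of the CpG cytosine).
DEFAULT_MARKER_REGIONS = (
    ("GALR1", "chr18", 74961137, 74962794, 74962133, "cg03502002"),
    ("TLX1", "chr10", 102894119, 102895708, 102895043, "cg14861089"),
    ("ZNF154", "chr19", 58211992, 58220837, 58220493, "cg21790626"),
)


class ValidationError(ValueError):
    """Raised when an input violates a structural constraint."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# ---------------------------------------------------------------------------
# beta matrices


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float matrix, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def probe_values(self, probe_id: str, sample_ids=None) -> np.ndarray:
        """Beta values of one probe, optionally restricted to samples."""
        i = self.probe_ids.index(probe_id)
        row = self.values[i]
        if sample_ids is None:
            return row
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        return row[[pos[s] for s in sample_ids]]

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])


def _header_lines(seed=None) -> list[str]:
    lines = [f"# methmark {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def read_beta_matrix(path) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe id, one column per sample).

    Missing cells must be encoded ``NA``; any non-missing value outside
    [0, 1] raises :class:`ValidationError`, a row with the wrong number
    of fields raises :class:`ParseError` naming the line.
    """
    header = None
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {len(header) + 1}"
                )
            probe_ids.append(fields[0])
            row = []
            for tok in fields[1:]:
                if tok == "NA":
                    row.append(np.nan)
                    continue
                try:
                    val = float(tok)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad value {tok!r}") from exc
                if not 0.0 <= val <= 1.0:
                    raise ValidationError(
                        f"{path}: line {lineno}: beta value {val} outside [0, 1]"
                    )
                row.append(val)
            rows.append(row)
    if header is None:
        raise ParseError(f"{path}: empty file")
    return BetaMatrix(probe_ids, list(header), np.array(rows, dtype=float).reshape(len(probe_ids), len(header)))


def write_beta_matrix(matrix: BetaMatrix, path, seed=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed):
            fh.write(line + "\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample annotations

COHORT_ROLES = ("tumor", "normal_tissue", "wbc")


@dataclass(frozen=True)
class SampleAnnotation:
    """Cohort membership of one sample."""

    sample_id: str
    cohort_role: str  # tumor | normal_tissue | wbc
    cancer_type: str | None = None  # e.g. BRCA, COAD; None only for wbc
    stage: str | None = None  # e.g. "I"

    def __post_init__(self) -> None:
        if self.cohort_role not in COHORT_ROLES:
            raise ValidationError(f"unknown cohort_role {self.cohort_role!r}")
        if self.cohort_role != "wbc" and not self.cancer_type:
            raise ValidationError(
                f"sample {self.sample_id}: cancer_type required for role {self.cohort_role}"
            )


def read_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            SampleAnnotation(
                sample_id=rec.sample_id,
                cohort_role=rec.cohort_role,
                cancer_type=rec.cancer_type or None,
                stage=getattr(rec, "stage", "") or None,
            )
        )
    return out


def write_annotations(annotations, path, seed=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed):
            fh.write(line + "\n")
        fh.write("sample_id\tcohort_role\tcancer_type\tstage\n")
        for a in annotations:
            fh.write(
                f"{a.sample_id}\t{a.cohort_role}\t{a.cancer_type or ''}\t{a.stage or ''}\n"
            )


def annotations_by_role(annotations, role: str, cancer_type: str | None = None) -> list[str]:
    """Sample ids with the given role (and cancer type, if given)."""
    return [
        a.sample_id
        for a in annotations
        if a.cohort_role == role and (cancer_type is None or a.cancer_type == cancer_type)
    ]


# ---------------------------------------------------------------------------
# marker regions


@dataclass(frozen=True)
class Region:
    """A marker window, 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int
    probe_position: int  # 0-based position of the designated array CpG
    probe_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"region {self.name}: start {self.start} >= end {self.end}")
        if not self.start <= self.probe_position < self.end:
            raise ValidationError(
                f"region {self.name}: designated probe position outside window"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class RegionSet:
    """Named collection of marker windows."""

    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate region names")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def default_regions() -> RegionSet:
    """The three built-in marker windows (GALR1, TLX1, ZNF154)."""
    return RegionSet(
        [Region(name, chrom, s, e, p, probe) for name, chrom, s, e, p, probe in DEFAULT_MARKER_REGIONS]
    )


def read_regions(path, one_based: bool = False) -> RegionSet:
    """Read a BED-like region file.

    Columns: chrom, start, end, name, designated probe position.  With
    ``one_based=True`` the coordinates are interpreted as 1-based
    inclusive (as printed in publications) and converted to the internal
    0-based half-open convention.
    """
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >=5 columns")
            chrom, start, end, name, probe_pos = fields[:5]
            start, end, probe_pos = int(start), int(end), int(probe_pos)
            if one_based:
                start -= 1
                probe_pos -= 1
            regions.append(Region(name, chrom, start, end, probe_pos))
    return RegionSet(regions)


def write_regions(regions: RegionSet, path, seed=None) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for line in _header_lines(seed):
            fh.write(line + "\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.probe_position}\n")


# ---------------------------------------------------------------------------
# read-level methylation calls


@dataclass(frozen=True)
class MethylRead:
    """One sequencing read's CpG methylation calls inside a region."""

    read_id: str
    region_name: str
    cpg_positions: tuple[int, ...]
    calls: tuple[int, ...]  # 1 = methylated

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.cpg_positions):
            raise ValidationError(
                f"read {self.read_id}: {len(self.calls)} calls for "
                f"{len(self.cpg_positions)} positions"
            )
        if len(self.cpg_positions) < 1:
            raise ValidationError(f"read {self.read_id}: no CpG positions")
        if any(c not in (0, 1) for c in self.calls):
            raise ValidationError(f"read {self.read_id}: calls must be 0/1")


@dataclass
class ReadSet:
    """All retained reads of one sample, grouped by region."""

    sample_id: str
    label: str  # "case" | "control"
    reads: dict[str, list[MethylRead]] = field(default_factory=dict)

    def regions(self) -> list[str]:
        return sorted(self.reads)

    def n_reads(self, region_name: str | None = None) -> int:
        if region_name is not None:
            return len(self.reads.get(region_name, []))
        return sum(len(v) for v in self.reads.values())


def _dedupe_and_clip(reads, regions: RegionSet | None):
    """Clip reads to in-region CpGs, drop empty ones, remove duplicates.

    Duplicate = identical (region, positions, calls) within a sample, as
    after PCR-duplicate removal.  Returns (kept, n_dropped_out_of_region,
    n_duplicates).
    """
    seen = set()
    kept: list[MethylRead] = []
    n_empty = 0
    n_dup = 0
    for read in reads:
        if regions is not None:
            try:
                region = regions.get(read.region_name)
            except KeyError:
                n_empty += 1
                continue
            pairs = [
                (p, c)
                for p, c in zip(read.cpg_positions, read.calls)
                if region.contains(p)
            ]
            if not pairs:
                n_empty += 1
                continue
            read = MethylRead(
                read.read_id,
                read.region_name,
                tuple(p for p, _ in pairs),
                tuple(c for _, c in pairs),
            )
        key = (read.region_name, read.cpg_positions, read.calls)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(read)
    return kept, n_empty, n_dup


def read_reads(path, regions: RegionSet | None = None) -> list[ReadSet]:
    """Read the tabular read dialect.

    Columns: sample_id, label, region, read_id, comma-separated CpG
    positions (0-based), call string of 0/1.  Reads are clipped to
    in-region CpGs (any overlap retains the read), reads with zero
    in-region CpGs are dropped, and duplicates are removed.
    """
    per_sample: dict[str, ReadSet] = {}
    raw: dict[str, list[MethylRead]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns")
            sample_id, label, region, read_id, pos_str, call_str = fields
            positions = tuple(int(p) for p in pos_str.split(","))
            if len(call_str) != len(positions):
                raise ParseError(
                    f"{path}: line {lineno}: call string length {len(call_str)} "
                    f"does not match {len(positions)} positions"
                )
            calls = tuple(int(c) for c in call_str)
            if sample_id not in per_sample:
                per_sample[sample_id] = ReadSet(sample_id, label)
                raw[sample_id] = []
            raw[sample_id].append(MethylRead(read_id, region, positions, calls))
    for sample_id, reads in raw.items():
        kept, _, _ = _dedupe_and_clip(reads, regions)
        rs = per_sample[sample_id]
        for read in kept:
            rs.reads.setdefault(read.region_name, []).append(read)
    return list(per_sample.values())


def write_reads(readsets, path, seed=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed):
            fh.write(line + "\n")
        fh.write("sample_id\tlabel\tregion\tread_id\tcpg_positions\tcalls\n")
        for rs in readsets:
            for region_name in rs.regions():
                for read in rs.reads[region_name]:
                    pos = ",".join(str(p) for p in read.cpg_positions)
                    calls = "".join(str(c) for c in read.calls)
                    fh.write(
                        f"{rs.sample_id}\t{rs.label}\t{region_name}\t{read.read_id}\t{pos}\t{calls}\n"
                    )


def read_reads_sam(path, regions: RegionSet, sample_id: str, label: str = "case") -> ReadSet:
    """Extract region-overlapping reads from a SAM/BAM with Bismark calls.

    Uses the Bismark ``XM`` tag: ``Z``/``z`` mark methylated/unmethylated
    CpG-context cytosines, one character per aligned read base.  A read is
    assigned to every region it overlaps with at least one CpG call;
    calls outside the window are clipped.  Insertions/soft-clips have no
    reference coordinate and are skipped.
    """
    import pysam

    raw: list[MethylRead] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not aln.has_tag("XM"):
                continue
            xm = aln.get_tag("XM")
            ref_positions = aln.get_reference_positions(full_length=True)
            chrom = aln.reference_name
            calls: list[tuple[int, int]] = []
            for ref_pos, state in zip(ref_positions, xm):
                if ref_pos is None:
                    continue
                if state == "Z":
                    calls.append((ref_pos, 1))
                elif state == "z":
                    calls.append((ref_pos, 0))
            for region in regions:
                if region.chrom != chrom:
                    continue
                pairs = [(p, c) for p, c in calls if region.contains(p)]
                if pairs:
                    raw.append(
                        MethylRead(
                            aln.query_name,
                            region.name,
                            tuple(p for p, _ in pairs),
                            tuple(c for _, c in pairs),
                        )
                    )
    kept, _, _ = _dedupe_and_clip(raw, None)
    rs = ReadSet(sample_id, label)
    for read in kept:
        rs.reads.setdefault(read.region_name, []).append(read)
    return rs


# ---------------------------------------------------------------------------
# result serialization helpers


def write_json(obj, path, seed=None) -> None:
    payload = {"tool": "methmark", "version": __version__}
    if seed is not None:
        payload["seed"] = seed
    payload["result"] = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_table(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed):
            fh.write(line + "\n")
    df.to_csv(path, sep="\t", index=False, mode="a")
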