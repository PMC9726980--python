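"""Somatic-mutation data model and I/O for multi-region tumour cohorts.

The central objects are :class:`MutationRecord` (one somatic variant with
per-region read support), :class:`RegionSample` (one sequenced tumour region
with its pathology carcinoma content and computational purity),
:class:`CnvSegment` (copy-number segment with a log2-ratio gain/loss call)
and :class:`PresenceMatrix` (mutation x region detection matrix, the
substrate for trunk/branch classification).

Coordinates are 1-based inclusive throughout (VCF/MAF convention); SEG input
is treated the same way.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = (
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "synonymous",
    "noncoding",
)

#: The five non-silent categories counted in heterogeneity analyses.
NONSILENT_CLASSES = frozenset(
    ("nonsynonymous", "stopgain", "stoploss", "frameshift_indel", "nonframeshift_indel")
)

TUMOUR_SITES = ("oesophagus", "hypopharynx")


class FormatError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class MutationRecord:
    """One somatic variant and its read support in every sequenced region."""

    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    functional_class: str
    channel96: int | None = None  # SNVs only; indels carry None
    per_region: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise FormatError(f"unknown functional class: {self.functional_class!r}")
        for region, (alt_reads, total_reads) in self.per_region.items():
            if not 0 <= alt_reads <= total_reads:
                raise FormatError(
                    f"{self.key}: alt_reads {alt_reads} > total_reads "
                    f"{total_reads} in region {region}"
                )
        if self.channel96 is not None and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise FormatError(f"{self.key}: channel96 set on a non-SNV record")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def vaf(self, region_id: str) -> float:
        a, t = self.per_region[region_id]
        return a / t if t else 0.0


@dataclass
class RegionSample:
    """One sequenced tumour region.

    ``carcinoma_content`` is the pathologist's estimate used for region
    filtering; ``purity`` is the computational estimate used in CCF
    calculations. They are deliberately distinct fields.
    """

    patient_id: str
    tumour_site: str
    region_id: str
    purity: float
    carcinoma_content: float

    def __post_init__(self) -> None:
        if self.tumour_site not in TUMOUR_SITES:
            raise FormatError(f"unknown tumour site: {self.tumour_site!r}")
        if not 0.0 < self.purity <= 1.0:
            raise FormatError(f"purity must be in (0, 1]: {self.purity}")
        if not 0.0 <= self.carcinoma_content <= 1.0:
            raise FormatError(
                f"carcinoma_content must be in [0, 1]: {self.carcinoma_content}"
            )


@dataclass
class CnvSegment:
    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    log2_ratio: float
    call: str | None = None  # gain / loss / neutral

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )


@dataclass
class PresenceMatrix:
    """Boolean detection matrix: rows = mutation keys, columns = regions."""

    mutations: list[str]
    regions: list[str]
    present: np.ndarray  # bool, |mutations| x |regions|

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.mutations), len(self.regions)):
            raise ValueError("presence matrix dimensions do not match key lists")

    def row(self, mutation_key: str) -> np.ndarray:
        return self.present[self.mutations.index(mutation_key)]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_MAF_FIXED_COLUMNS = ["Patient", "Chrom", "Pos", "Ref", "Alt", "Gene", "Class"]


def read_mutation_table(path: str | Path, format: str = "maf") -> list[MutationRecord]:
    """Read somatic mutations from a MAF-like TSV or a multi-sample VCF.

    The MAF-like layout has fixed columns Patient, Chrom, Pos, Ref, Alt,
    Gene, Class, an optional Channel96 column, and per-region read counts as
    paired ``<region>_alt`` / ``<region>_tot`` columns. Malformed rows are
    rejected with line-number diagnostics; duplicate (patient, chrom, pos,
    ref, alt) keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "maf":
        return _read_maf(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown mutation-table format: {format!r}")


def _read_maf(path: Path) -> list[MutationRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _MAF_FIXED_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        region_ids = sorted(
            {c[:-4] for c in header if c.endswith("_alt")}
            & {c[:-4] for c in header if c.endswith("_tot")}
        )
        if not region_ids:
            raise FormatError(f"{path}: no '<region>_alt'/'<region>_tot' column pairs")
        has_channel = "Channel96" in header

        records: list[MutationRecord] = []
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                pos = int(row["Pos"])
                if pos < 1:
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:{lineno}: malformed coordinate Pos={row.get('Pos')!r}"
                ) from None
            per_region: dict[str, tuple[int, int]] = {}
            for rid in region_ids:
                try:
                    a = int(row[f"{rid}_alt"])
                    t = int(row[f"{rid}_tot"])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}:{lineno}: non-integer read counts for region {rid}"
                    ) from None
                per_region[rid] = (a, t)
            channel: int | None = None
            if has_channel and row["Channel96"] not in ("", ".", "NA", None):
                channel = int(row["Channel96"])
            try:
                rec = MutationRecord(
                    patient_id=row["Patient"],
                    chrom=row["Chrom"],
                    pos=pos,
                    ref=row["Ref"],
                    alt=row["Alt"],
                    gene=row["Gene"],
                    functional_class=row["Class"],
                    channel96=channel,
                    per_region=per_region,
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            dup_key = (rec.patient_id, rec.key)
            if dup_key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate variant {rec.key} "
                    f"for patient {rec.patient_id}"
                )
            seen.add(dup_key)
            records.append(rec)
    return records


def _read_vcf(path: Path) -> list[MutationRecord]:
    """VCF with per-sample AD (ref,alt depths); samples are region ids.

    Patient id is taken from the ``##patient=`` header line when present,
    otherwise from the file stem. Functional class comes from INFO/CLASS
    (default noncoding); gene from INFO/GENE.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    patient = Path(path).stem
    for hr in vcf.header.records:
        if hr.key == "patient" and hr.value:
            patient = hr.value
    records: list[MutationRecord] = []
    seen: set[str] = set()
    for rec in vcf:
        for alt in rec.alts or ():
            per_region: dict[str, tuple[int, int]] = {}
            for sample in rec.samples.values():
                ad = sample.get("AD")
                if ad is None or ad[0] is None:
                    per_region[sample.name] = (0, 0)
                else:
                    per_region[sample.name] = (int(ad[1]), int(sum(ad)))
            mut = MutationRecord(
                patient_id=patient,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                gene=str(rec.info.get("GENE", ".")),
                functional_class=str(rec.info.get("CLASS", "noncoding")),
                per_region=per_region,
            )
            if mut.key in seen:
                raise FormatError(f"{path}: duplicate variant {mut.key}")
            seen.add(mut.key)
            records.append(mut)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records as the MAF-like TSV accepted by :func:`read_mutation_table`."""
    region_ids = sorted({r for rec in records for r in rec.per_region})
    cols = _MAF_FIXED_COLUMNS + ["Channel96"]
    for rid in region_ids:
        cols += [f"{rid}_alt", f"{rid}_tot"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            row = [
                rec.patient_id, rec.chrom, rec.pos, rec.ref, rec.alt,
                rec.gene, rec.functional_class,
                "." if rec.channel96 is None else rec.channel96,
            ]
            for rid in region_ids:
                a, t = rec.per_region.get(rid, (0, 0))
                row += [a, t]
            writer.writerow(row)


def read_region_table(path: str | Path) -> list[RegionSample]:
    """Region metadata TSV: patient_id, tumour_site, region_id, purity, carcinoma_content."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "tumour_site", "region_id", "purity", "carcinoma_content"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        RegionSample(
            patient_id=str(r.patient_id),
            tumour_site=str(r.tumour_site),
            region_id=str(r.region_id),
            purity=float(r.purity),
            carcinoma_content=float(r.carcinoma_content),
        )
        for r in df.itertuples()
    ]


def write_region_table(regions: Sequence[RegionSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "tumour_site": r.tumour_site,
                "region_id": r.region_id,
                "purity": r.purity,
                "carcinoma_content": r.carcinoma_content,
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[CnvSegment]:
    """SEG format: ID, chrom, loc.start, loc.end, num.mark, seg.mean."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 6:
        raise FormatError(f"{path}: SEG file needs 6 columns, found {df.shape[1]}")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            CnvSegment(
                region_id=str(r[0]),
                chrom=str(r[1]),
                start=int(r[2]),
                end=int(r[3]),
                log2_ratio=float(r[5]),
            )
        )
    return out


def write_seg(segments: Sequence[CnvSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"])
        for s in segments:
            writer.writerow([s.region_id, s.chrom, s.start, s.end, 0, s.log2_ratio])


# ---------------------------------------------------------------------------
# Filters and derived structures
# ---------------------------------------------------------------------------


def filter_nonsilent(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Keep non-silent mutations: nonsynonymous, stop gain/loss and indels.

    Synonymous and noncoding records are dropped; input order is preserved.
    """
    out = []
    for rec in records:
        if rec.functional_class not in FUNCTIONAL_CLASSES:
            raise FormatError(f"unknown functional class: {rec.functional_class!r}")
        if rec.functional_class in NONSILENT_CLASSES:
            out.append(rec)
    return out


def filter_regions(
    regions: Iterable[RegionSample], min_content: float = 0.30
) -> list[RegionSample]:
    """Keep regions whose pathology carcinoma content is >= ``min_content``.

    The boundary is inclusive: a region at exactly the threshold is retained.
    """
    kept = [r for r in regions if r.carcinoma_content >= min_content]
    if not kept:
        logger.warning("filter_regions: no region passed min_content=%s", min_content)
    return kept


def build_presence_matrix(
    records: Sequence[MutationRecord],
    regions: Sequence[RegionSample],
    min_alt_reads: int = 3,
    min_vaf: float = 0.05,
    allow_extra_regions: bool = True,
) -> PresenceMatrix:
    """Call per-region mutation presence from read counts.

    A mutation is present in a region when ``alt_reads >= min_alt_reads`` and
    ``alt/total >= min_vaf`` (both boundaries inclusive). Mutations detected
    in no retained region are dropped (counted in the log), so the returned
    matrix has no all-false row. Counts for regions not in ``regions`` are
    ignored (they typically belong to regions removed by the carcinoma
    content filter); pass ``allow_extra_regions=False`` to treat them as an
    error instead.
    """
    region_ids = [r.region_id for r in regions]
    region_set = set(region_ids)
    if not allow_extra_regions:
        for rec in records:
            unknown = set(rec.per_region) - region_set
            if unknown:
                raise KeyError(f"{rec.key}: unknown region ids {sorted(unknown)}")
    keys: list[str] = []
    rows: list[list[bool]] = []
    dropped = 0
    for rec in records:
        row = []
        for rid in region_ids:
            a, t = rec.per_region.get(rid, (0, 0))
            row.append(a >= min_alt_reads and t > 0 and a / t >= min_vaf)
        if any(row):
            keys.append(rec.key)
            rows.append(row)
        else:
            dropped += 1
    if dropped:
        logger.info(
            "build_presence_matrix: dropped %d mutations absent from every "
            "retained region", dropped,
        )
    matrix = (
        np.array(rows, dtype=bool)
        if rows
        else np.zeros((0, len(region_ids)), dtype=bool)
    )
    return PresenceMatrix(mutations=keys, regions=region_ids, present=matrix)


def call_cnv(
    segments: Iterable[CnvSegment],
    gain_thresh: float = 1.0,
    loss_thresh: float = -1.0,
) -> list[CnvSegment]:
    """Assign gain/loss/neutral calls from segment log2 ratios.

    Gains are strictly above ``gain_thresh`` and losses strictly below
    ``loss_thresh`` ("above 1 or below -1 after log2 transformation"); a
    ratio exactly at a threshold is neutral.
    """
    out = []
    for seg in segments:
        if not math.isfinite(seg.log2_ratio):
            raise ValueError(
                f"non-finite log2 ratio at {seg.chrom}:{seg.start}-{seg.end}"
            )
        if seg.log2_ratio > gain_thresh:
            call = "gain"
        elif seg.log2_ratio < loss_thresh:
            call = "loss"
        else:
            call = "neutral"
        out.append(
            CnvSegment(
                region_id=seg.region_id,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                log2_ratio=seg.log2_ratio,
                call=call,
            )
        )
    return out
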