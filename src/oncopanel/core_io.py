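"""Shared domain types and readers/writers for the formats the pipeline touches.

Conventions
-----------
All internal region arithmetic is 0-based half-open (BED convention).
VCF positions are 1-based and are converted only at the VCF boundary.
BED coordinates are never shifted on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)


class OncopanelError(Exception):
    """Base class for all package errors."""


class ParseError(OncopanelError):
    """A file could not be parsed."""


class ConfigError(OncopanelError):
    """A configuration or resource table is invalid."""


class ValidationError(OncopanelError):
    """Input data violates a documented invariant."""


# ---------------------------------------------------------------------------
# Enums
# ---------------------------------------------------------------------------


class Role(str, Enum):
    tumor = "tumor"
    control = "control"
    reference = "reference"


class RegionKind(str, Enum):
    on_target = "on_target"
    off_target_bin = "off_target_bin"
    snp_probe = "snp_probe"


class Effect(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    synonymous = "synonymous"
    splicing = "splicing"
    intronic_nonsplicing = "intronic_nonsplicing"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    promoter = "promoter"
    other = "other"


class DbStatus(str, Enum):
    none = "none"
    artifact = "artifact"
    benign = "benign"


class FunctionalClass(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    VUS = "VUS"
    likely_benign = "likely_benign"
    benign = "benign"
    unclassified = "unclassified"


class Priority(str, Enum):
    prioritized = "prioritized"
    deprioritized = "deprioritized"


class TierCategory(str, Enum):
    """Clinical implication: therapy, diagnosis, prognosis, resistance."""

    T = "T"
    D = "D"
    P = "P"
    R = "R"


class TierLevel(str, Enum):
    """I = guideline-backed evidence; II = literature/database-backed."""

    I = "I"
    II = "II"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SampleMeta(BaseModel):
    """Per-sample metadata.

    ``tumor_cellularity`` is the pathologist-estimated fraction of tumor
    cells in the specimen; non-tumor infiltration is its complement.
    ``din`` is the DNA Integrity Number (fragment-size-based quality score;
    FFPE material is typically degraded and scores low).
    """

    sample_id: str
    role: Role = Role.tumor
    tumor_cellularity: float = Field(1.0, ge=0.0, le=1.0)
    din: float = Field(0.0, ge=0.0)
    tissue: str = ""

    @property
    def infiltration(self) -> float:
        """Fraction of non-tumor cells (1 - tumor cellularity)."""
        return 1.0 - self.tumor_cellularity


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One panel target; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    gene: str = ""
    kind: RegionKind = RegionKind.on_target

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"target {self.name or self.chrom}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    """Per-target mean depths for one sample, aligned to the panel BED order."""

    sample_id: str
    targets: tuple[TargetRegion, ...]
    depths: np.ndarray  # float, same length as targets

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.depths) != len(self.targets):
            raise ValidationError(
                f"{self.sample_id}: {len(self.depths)} depths for "
                f"{len(self.targets)} targets"
            )
        if np.any(self.depths < 0):
            raise ValidationError(f"{self.sample_id}: negative depth")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.targets == other.targets
            and np.allclose(self.depths, other.depths, rtol=0, atol=1e-9)
        )


@dataclass(frozen=True)
class TierAnnotation:
    category: TierCategory
    level: TierLevel

    def __str__(self) -> str:
        return f"{self.category.value}-{self.level.value}"


@dataclass
class VariantRecord:
    """One small variant (one ALT allele), annotated upstream.

    ``pos`` keeps the VCF 1-based convention.  ``popmax_af`` is ``None``
    when the annotation is missing — never 0, because absence of population
    evidence must not fire the benignity filter.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: Effect = Effect.other
    vaf: float = 0.0
    depth: int = 0
    popmax_af: float | None = None
    internal_db_status: DbStatus = DbStatus.none
    functional_class: FunctionalClass = FunctionalClass.unclassified
    protein_change: str = ""
    exon: int | None = None
    quality_pass: bool = True
    priority: Priority = Priority.prioritized
    deprioritization_reasons: list[str] = field(default_factory=list)
    tiers: list[TierAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.key()}: VAF {self.vaf} outside [0,1]")
        if self.depth < 0:
            raise ValidationError(f"{self.key()}: negative depth")

    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for matching across call sets."""
        return (self.chrom, self.pos, self.ref, self.alt)


class RunMetrics(BaseModel):
    """Sequencing-run and per-sample coverage quality metrics."""

    q30_pct: float = Field(ge=0, le=100)
    clusters_pf_pct: float = Field(ge=0, le=100)
    n_reads: int = Field(ge=0)
    mean_coverage: float = Field(0.0, ge=0)
    uniformity_pct: float = Field(0.0, ge=0, le=100)
    dp100_pct: float = Field(0.0, ge=0, le=100)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


class VcfAnnotationConfig(BaseModel):
    """Maps VCF FORMAT/INFO field names onto VariantRecord attributes.

    The annotator that produced the VCF is deliberately unconstrained; the
    defaults match the files the synthetic generator writes.
    """

    sample: str | None = None  # tumor sample name; default: first sample
    vaf_format: str = "AF"
    depth_format: str = "DP"
    allele_depth_format: str = "AD"
    gene_info: str = "GENE"
    effect_info: str = "EFFECT"
    popmax_info: str = "POPMAX_AF"
    db_status_info: str = "DB_STATUS"
    functional_class_info: str = "FUNC_CLASS"
    protein_change_info: str = "PCHANGE"
    exon_info: str = "EXON"

    @field_validator("vaf_format", "depth_format")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("field name must be non-empty")
        return v


def _info_scalar(variant, key: str, alt_index: int):
    val = variant.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, tuple):
        return val[alt_index] if alt_index < len(val) else None
    return val


def read_variants(
    path: str | Path, annotations: VcfAnnotationConfig | None = None
) -> list[VariantRecord]:
    """Read a VCF 4.x file into one :class:`VariantRecord` per ALT allele.

    VAF source preference: FORMAT/<vaf_format> of the tumor sample, falling
    back to allele depths (alt / (ref+alt)) when absent.  The chosen source
    is logged once per file.
    """
    from cyvcf2 import VCF

    cfg = annotations or VcfAnnotationConfig()
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc

    samples = list(vcf.samples)
    if cfg.sample is not None:
        if cfg.sample not in samples:
            raise ConfigError(f"{path}: sample {cfg.sample!r} not in VCF ({samples})")
        s_idx = samples.index(cfg.sample)
    else:
        s_idx = 0

    records: list[VariantRecord] = []
    vaf_source_logged = False
    for variant in vcf:
        alts = variant.ALT or []
        for alt_index, alt in enumerate(alts):
            vaf, source = _extract_vaf(variant, cfg, s_idx, alt_index, samples)
            if vaf is None:
                raise ConfigError(
                    f"{path}:{variant.CHROM}:{variant.POS}: no VAF derivable from "
                    f"FORMAT/{cfg.vaf_format} or FORMAT/{cfg.allele_depth_format}"
                )
            if not vaf_source_logged:
                logger.info("%s: VAF taken from %s", path, source)
                vaf_source_logged = True
            depth = _extract_depth(variant, cfg, s_idx)
            if depth is None:
                raise ConfigError(
                    f"{path}:{variant.CHROM}:{variant.POS}: no depth in "
                    f"FORMAT/{cfg.depth_format}"
                )
            popmax = _info_scalar(variant, cfg.popmax_info, alt_index)
            effect_raw = _info_scalar(variant, cfg.effect_info, alt_index)
            db_raw = _info_scalar(variant, cfg.db_status_info, alt_index)
            func_raw = _info_scalar(variant, cfg.functional_class_info, alt_index)
            exon_raw = _info_scalar(variant, cfg.exon_info, alt_index)
            records.append(
                VariantRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    gene=str(_info_scalar(variant, cfg.gene_info, alt_index) or ""),
                    effect=Effect(effect_raw) if effect_raw else Effect.other,
                    vaf=float(np.clip(vaf, 0.0, 1.0)),
                    depth=int(depth),
                    popmax_af=None if popmax is None else float(popmax),
                    internal_db_status=DbStatus(db_raw) if db_raw else DbStatus.none,
                    functional_class=(
                        FunctionalClass(func_raw)
                        if func_raw
                        else FunctionalClass.unclassified
                    ),
                    protein_change=str(
                        _info_scalar(variant, cfg.protein_change_info, alt_index) or ""
                    ),
                    exon=None if exon_raw is None else int(exon_raw),
                    quality_pass=(variant.FILTER is None or variant.FILTER == "PASS"),
                )
            )
    return records


def _extract_vaf(variant, cfg, s_idx, alt_index, samples):
    if samples:
        try:
            af = variant.format(cfg.vaf_format)
        except KeyError:
            af = None
        if af is not None:
            val = af[s_idx]
            val = val[alt_index] if np.ndim(val) else val
            if np.isfinite(val):
                return float(val), f"FORMAT/{cfg.vaf_format}"
        try:
            ad = variant.format(cfg.allele_depth_format)
        except KeyError:
            ad = None
        if ad is not None:
            row = np.asarray(ad[s_idx], dtype=float)
            total = row.sum()
            if total > 0 and alt_index + 1 < len(row):
                return float(row[alt_index + 1] / total), (
                    f"FORMAT/{cfg.allele_depth_format}"
                )
    # site-level INFO fallback for sample-free VCFs
    val = _info_scalar(variant, cfg.vaf_format, alt_index)
    if val is not None:
        return float(val), f"INFO/{cfg.vaf_format}"
    return None, None


def _extract_depth(variant, cfg, s_idx):
    try:
        dp = variant.format(cfg.depth_format)
    except KeyError:
        dp = None
    if dp is not None:
        val = np.asarray(dp[s_idx]).ravel()[0]
        if val >= 0:
            return int(val)
    val = variant.INFO.get(cfg.depth_format)
    return None if val is None else int(val)


# ---------------------------------------------------------------------------
# BED / TSV readers
# ---------------------------------------------------------------------------


def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read a 3–6 column BED into panel targets, preserving file order.

    Columns beyond chrom/start/end are interpreted as name, gene, kind.
    Overlapping regions are kept as-is (no merging).
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            gene = parts[4] if len(parts) > 4 else ""
            kind = RegionKind(parts[5]) if len(parts) > 5 else RegionKind.on_target
            regions.append(TargetRegion(chrom, start, end, name, gene, kind))
    return regions


def read_coverage(path: str | Path, targets: Sequence[TargetRegion]) -> CoverageProfile:
    """Read a per-target mean-depth TSV (sample_id, target, mean_depth).

    Every panel target must appear exactly once; the returned profile is
    re-aligned to the panel's target order regardless of row order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "target": str})
    required = {"sample_id", "target", "mean_depth"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise ParseError(f"{path}: no coverage rows")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValidationError(f"{path}: expected one sample, found {list(sample_ids)}")
    dup = df["target"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate targets {sorted(df.loc[dup, 'target'].unique())}"
        )
    by_name = dict(zip(df["target"], df["mean_depth"]))
    missing = [t.name for t in targets if t.name not in by_name]
    if missing:
        raise ValidationError(f"{path}: missing targets {missing}")
    depths = np.array([float(by_name[t.name]) for t in targets])
    if np.any(depths < 0):
        bad = [t.name for t, d in zip(targets, depths) if d < 0]
        raise ValidationError(f"{path}: negative depth for {bad}")
    return CoverageProfile(str(sample_ids[0]), tuple(targets), depths)


def write_coverage(profile: CoverageProfile, path: str | Path) -> None:
    """Write a coverage profile in the TSV layout :func:`read_coverage` expects."""
    pd.DataFrame(
        {
            "sample_id": profile.sample_id,
            "target": [t.name for t in profile.targets],
            "mean_depth": profile.depths,
        }
    ).to_csv(path, sep="\t", index=False)


def write_targets(targets: Iterable[TargetRegion], path: str | Path) -> None:
    """Write panel targets as 6-column BED."""
    with open(path, "w") as fh:
        for t in targets:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\t{t.gene}\t{t.kind.value}\n"
            )


# ---------------------------------------------------------------------------
# Generic report writing (round-trip stable)
# ---------------------------------------------------------------------------


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Serialize a stage output to JSON or TSV.

    Dispatches on the object type; every writer has a matching reader so
    ``read_report(write_report(x)) == x`` for the domain types.
    """
    path = Path(path)
    if format == "json":
        payload = to_jsonable(results)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        frame = _to_frame(results)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown report format {format!r}")


def to_jsonable(obj):
    """Recursively convert domain objects to JSON-serializable structures."""
    from oncopanel import cnv_caller, msi_caller  # deferred: avoid import cycle

    if isinstance(obj, CoverageProfile):
        return {
            "_type": "CoverageProfile",
            "sample_id": obj.sample_id,
            "targets": [to_jsonable(t) for t in obj.targets],
            "depths": [float(d) for d in obj.depths],
        }
    if isinstance(obj, TargetRegion):
        return {
            "chrom": obj.chrom,
            "start": obj.start,
            "end": obj.end,
            "name": obj.name,
            "gene": obj.gene,
            "kind": obj.kind.value,
        }
    if isinstance(obj, msi_caller.MsiResult):
        return {
            "_type": "MsiResult",
            "sample_id": obj.sample_id,
            "n_valid": obj.n_valid,
            "n_unstable": obj.n_unstable,
            "fraction": obj.instability_fraction,
            "class": obj.msi_class.value,
            "markers": [
                {
                    "marker_id": c.marker_id,
                    "coverage": c.coverage,
                    "valid": c.valid,
                    "statistic": c.statistic,
                    "unstable": c.unstable,
                }
                for c in obj.marker_calls
            ],
        }
    if isinstance(obj, cnv_caller.CnvEvent):
        return {
            "chrom": obj.chrom,
            "start": obj.start,
            "end": obj.end,
            "direction": obj.direction.value,
            "n_targets": obj.n_targets,
            "size_bp": obj.size_bp,
            "event_log2": obj.event_log2,
            "copy_number": obj.copy_number,
            "score": obj.score,
            "score_class": obj.score_class.value,
            "sex_chromosome": obj.sex_chromosome,
        }
    if isinstance(obj, VariantRecord):
        return {
            "chrom": obj.chrom,
            "pos": obj.pos,
            "ref": obj.ref,
            "alt": obj.alt,
            "gene": obj.gene,
            "effect": obj.effect.value,
            "vaf": obj.vaf,
            "depth": obj.depth,
            "popmax_af": obj.popmax_af,
            "internal_db_status": obj.internal_db_status.value,
            "functional_class": obj.functional_class.value,
            "priority": obj.priority.value,
            "deprioritization_reasons": list(obj.deprioritization_reasons),
            "tiers": [str(t) for t in obj.tiers],
        }
    if isinstance(obj, BaseModel):
        return obj.model_dump(mode="json")
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Enum):
        return obj.value
    return obj


def _to_frame(results) -> pd.DataFrame:
    from oncopanel import cnv_caller

    if isinstance(results, list):
        if not results:
            # header-only events table
            return pd.DataFrame(
                columns=[
                    "chrom",
                    "start",
                    "end",
                    "direction",
                    "n_targets",
                    "size_bp",
                    "event_log2",
                    "copy_number",
                    "score",
                    "score_class",
                    "sex_chromosome",
                ]
            )
        if isinstance(results[0], (cnv_caller.CnvEvent, VariantRecord)):
            return pd.DataFrame([to_jsonable(r) for r in results])
    if isinstance(results, CoverageProfile):
        return pd.DataFrame(
            {
                "sample_id": results.sample_id,
                "target": [t.name for t in results.targets],
                "mean_depth": results.depths,
            }
        )
    raise ConfigError(f"cannot render {type(results).__name__} as TSV")


def read_events(path: str | Path):
    """Read a CNV events TSV written by :func:`write_report`."""
    from oncopanel.cnv_caller import CnvDirection, CnvEvent, ScoreClass

    df = pd.read_csv(path, sep="\t")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            CnvEvent(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                direction=CnvDirection(row.direction),
                n_targets=int(row.n_targets),
                event_log2=float(row.event_log2),
                copy_number=float(row.copy_number),
                score=float(row.score),
                score_class=ScoreClass(row.score_class),
                sex_chromosome=bool(row.sex_chromosome),
            )
        )
    return events


def read_coverage_report(path: str | Path) -> CoverageProfile:
    """Read a CoverageProfile JSON written by :func:`write_report`."""
    data = json.loads(Path(path).read_text())
    if data.get("_type") != "CoverageProfile":
        raise ParseError(f"{path}: not a CoverageProfile report")
    targets = tuple(
        TargetRegion(
            t["chrom"], t["start"], t["end"], t["name"], t["gene"], RegionKind(t["kind"])
        )
        for t in data["targets"]
    )
    return CoverageProfile(data["sample_id"], targets, np.array(data["depths"]))


# ---------------------------------------------------------------------------
# Lightweight format validation (CLI support)
# ---------------------------------------------------------------------------


def validate_file(path: str | Path) -> dict:
    """Best-effort schema check of a VCF/BED/TSV input; returns a report dict."""
    path = Path(path)
    report: dict = {"path": str(path), "ok": False, "kind": None, "detail": ""}
    suffix = path.suffix.lower()
    try:
        if suffix in {".vcf", ".gz"}:
            n = len(read_variants(path))
            report.update(ok=True, kind="vcf", detail=f"{n} variant records")
        elif suffix == ".bed":
            n = len(read_targets(path))
            report.update(ok=True, kind="bed", detail=f"{n} regions")
        elif suffix in {".tsv", ".txt"}:
            df = pd.read_csv(path, sep="\t")
            report.update(
                ok=True, kind="tsv", detail=f"{len(df)} rows, columns {list(df.columns)}"
            )
        else:
            report["detail"] = f"unrecognized extension {suffix!r}"
    except OncopanelError as exc:
        report["detail"] = str(exc)
    return report
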