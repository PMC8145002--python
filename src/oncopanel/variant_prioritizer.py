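"""Somatic-variant deprioritization, clinical tiering and pharmacogenetics.

Deprioritization flags (never deletes) variants that fail technical-quality
or benignity-likelihood filters so that only high-confidence calls reach
manual review: coverage <= 20, tumor VAF <= 0.05, internal-database
artifact/benign status, population frequency >= 0.02, or an effect class
with negligible pathogenic potential (exonic synonymous, intronic
non-splicing).  All boundary comparisons are inclusive.

Pathogenic and likely-pathogenic variants are then annotated with clinical
tiers — therapy (T), diagnosis (D), prognosis (P), resistance (R), at
evidence level I (guideline-backed) or II (literature-backed) — by matching
against an editable knowledge table.  A separate 10-SNP table drives
pharmacogenetic genotype reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from oncopanel.core_io import (
    ConfigError,
    DbStatus,
    Effect,
    FunctionalClass,
    Priority,
    TierAnnotation,
    TierCategory,
    TierLevel,
    VariantRecord,
)

# Deprioritization rule identifiers, recorded per record for provenance.
RULE_LOW_DEPTH = "LOW_DEPTH"
RULE_LOW_VAF = "LOW_VAF"
RULE_DB_ARTIFACT = "DB_ARTIFACT"
RULE_DB_BENIGN = "DB_BENIGN"
RULE_POP_FREQUENT = "POP_FREQUENT"
RULE_BENIGN_EFFECT = "BENIGN_EFFECT"


class FilterConfig(BaseModel):
    """Thresholds for the deprioritization rules (all boundaries inclusive)."""

    min_depth_exclusive: int = Field(20, ge=0)
    max_vaf_exclusive: float = Field(0.05, ge=0.0, le=1.0)
    popmax_benign_af: float = Field(0.02, ge=0.0, le=1.0)
    benign_effects: set[Effect] = Field(
        default_factory=lambda: {Effect.synonymous, Effect.intronic_nonsplicing}
    )
    honor_internal_db: bool = True


def apply_filters(
    variants: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> list[VariantRecord]:
    """Set ``priority``/``deprioritization_reasons`` on every record.

    A record is deprioritized iff at least one rule fires; every firing
    rule id is recorded, so the outcome is independent of evaluation
    order and the call is idempotent.  A missing population frequency
    never fires the population rule.
    """
    cfg = cfg or FilterConfig()
    for v in variants:
        reasons: list[str] = []
        if v.depth <= cfg.min_depth_exclusive:
            reasons.append(RULE_LOW_DEPTH)
        if v.vaf <= cfg.max_vaf_exclusive:
            reasons.append(RULE_LOW_VAF)
        if cfg.honor_internal_db:
            if v.internal_db_status == DbStatus.artifact:
                reasons.append(RULE_DB_ARTIFACT)
            elif v.internal_db_status == DbStatus.benign:
                reasons.append(RULE_DB_BENIGN)
        if v.popmax_af is not None and v.popmax_af >= cfg.popmax_benign_af:
            reasons.append(RULE_POP_FREQUENT)
        if v.effect in cfg.benign_effects:
            reasons.append(RULE_BENIGN_EFFECT)
        v.deprioritization_reasons = reasons
        v.priority = Priority.deprioritized if reasons else Priority.prioritized
    return list(variants)


# ---------------------------------------------------------------------------
# Clinical tiering
# ---------------------------------------------------------------------------


class MatchKind(str, Enum):
    hotspot_aa = "hotspot_aa"
    exon_region = "exon_region"
    gene_level = "gene_level"
    fusion = "fusion"
    msi_status = "msi_status"


@dataclass(frozen=True)
class KnowledgeEntry:
    gene: str
    match_kind: MatchKind
    match_value: str
    tumor_type: str
    tiers: tuple[TierAnnotation, ...]

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ConfigError(f"{self.gene} {self.match_value}: tiers must be non-empty")


def _parse_tiers(text: str) -> tuple[TierAnnotation, ...]:
    tiers = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        cat, _, level = part.partition(":")
        tiers.append(TierAnnotation(TierCategory(cat.strip()), TierLevel(level.strip())))
    return tuple(tiers)


def load_knowledge_table(path: str | Path) -> list[KnowledgeEntry]:
    """Load the actionability knowledge TSV
    (gene, match_kind, match_value, tumor_type, tiers as ``T:I;P:II``)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(
                KnowledgeEntry(
                    gene=row.gene,
                    match_kind=MatchKind(row.match_kind),
                    match_value=row.match_value,
                    tumor_type=row.tumor_type,
                    tiers=_parse_tiers(row.tiers),
                )
            )
        except (ValueError, ConfigError) as exc:
            raise ConfigError(f"{path}: row {i}: {exc}") from exc
    return entries


def default_knowledge_table() -> list[KnowledgeEntry]:
    """The bundled default actionability table."""
    from importlib.resources import files

    return load_knowledge_table(files("oncopanel.resources") / "knowledge_table.tsv")


_LEVEL_ORDER = {TierLevel.I: 0, TierLevel.II: 1}


def _collapse_best(tiers: Iterable[TierAnnotation]) -> list[TierAnnotation]:
    """Keep the best (lowest) evidence level per category."""
    best: dict[TierCategory, TierAnnotation] = {}
    for t in tiers:
        cur = best.get(t.category)
        if cur is None or _LEVEL_ORDER[t.level] < _LEVEL_ORDER[cur.level]:
            best[t.category] = t
    return [best[c] for c in TierCategory if c in best]


def _tumor_type_matches(entry_type: str, tumor_type: str) -> bool:
    return entry_type.lower() in ("any", "") or entry_type.lower() == tumor_type.lower()


def _variant_matches(variant: VariantRecord, entry: KnowledgeEntry) -> bool:
    if entry.gene != variant.gene:
        return False
    if entry.match_kind == MatchKind.hotspot_aa:
        # exact change ("V600E") or codon prefix ("G12" matches G12D, G12V, ...)
        pc = variant.protein_change
        return bool(pc) and (pc == entry.match_value or pc.startswith(entry.match_value))
    if entry.match_kind == MatchKind.exon_region:
        tokens = entry.match_value.lower().split()
        exon_no = next((int(t) for t in tokens if t.isdigit()), None)
        if exon_no is None or variant.exon != exon_no:
            return False
        if "del" in tokens:
            return variant.effect in (Effect.inframe_indel, Effect.frameshift)
        return True
    # gene_level / fusion / msi_status entries match non-SNV findings,
    # handled by the dedicated helpers below.
    return False


def assign_tiers(
    variant: VariantRecord,
    tumor_type: str,
    kb: Sequence[KnowledgeEntry],
) -> list[TierAnnotation]:
    """Tier annotations for one small variant.

    Only pathogenic / likely-pathogenic variants are tiered; everything
    else gets an empty list.  Matching entries' tiers are unioned and
    collapsed to the best level per category.
    """
    if variant.functional_class not in (
        FunctionalClass.pathogenic,
        FunctionalClass.likely_pathogenic,
    ):
        return []
    matched = [
        t
        for e in kb
        if _tumor_type_matches(e.tumor_type, tumor_type) and _variant_matches(variant, e)
        for t in e.tiers
    ]
    tiers = _collapse_best(matched)
    variant.tiers = tiers
    return tiers


def assign_tiers_gene_level(
    gene: str,
    alteration: str,
    tumor_type: str,
    kb: Sequence[KnowledgeEntry],
) -> list[TierAnnotation]:
    """Tiers for a gene-level finding (e.g. ``amplification``, ``deletion``,
    ``biallelic loss``) or a fusion (gene given as ``EML4-ALK``)."""
    matched = [
        t
        for e in kb
        if e.match_kind in (MatchKind.gene_level, MatchKind.fusion)
        and e.gene == gene
        and e.match_value.lower() == alteration.lower()
        and _tumor_type_matches(e.tumor_type, tumor_type)
        for t in e.tiers
    ]
    return _collapse_best(matched)


# ---------------------------------------------------------------------------
# Pharmacogenetics
# ---------------------------------------------------------------------------

N_PGX_SNPS = 10
PGX_HOM_ALT_VAF = 0.85
PGX_HET_VAF = 0.15


class PgxCall(str, Enum):
    ref_ref = "ref/ref"
    ref_alt = "ref/alt"
    alt_alt = "alt/alt"
    no_call = "no_call"


@dataclass(frozen=True)
class PgxDef:
    rsid: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    drug: str
    evidence_level: str


@dataclass(frozen=True)
class PgxGenotype:
    rsid: str
    genotype: PgxCall


def load_pgx_table(path: str | Path) -> list[PgxDef]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    defs = [
        PgxDef(
            rsid=str(r.rsid),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            drug=str(r.drug),
            evidence_level=str(r.evidence_level),
        )
        for r in df.itertuples(index=False)
    ]
    if len(defs) != N_PGX_SNPS:
        raise ConfigError(
            f"{path}: pharmacogenetic table must have exactly {N_PGX_SNPS} rows, "
            f"got {len(defs)}"
        )
    return defs


def default_pgx_table() -> list[PgxDef]:
    """The bundled default 10-SNP pharmacogenetic definition table."""
    from importlib.resources import files

    return load_pgx_table(files("oncopanel.resources") / "pgx_snps.tsv")


def pgx_genotypes(
    variants: Sequence[VariantRecord],
    defs: Sequence[PgxDef],
    position_depths: Mapping[tuple[str, int], int] | None = None,
    hom_alt_vaf: float = PGX_HOM_ALT_VAF,
    het_vaf: float = PGX_HET_VAF,
    min_depth: int = 20,
) -> list[PgxGenotype]:
    """Genotype the 10 pharmacogenetic positions from a (preferably
    germline) variant table.

    VAF bands: alt/alt at VAF >= 0.85, ref/alt at 0.15 <= VAF < 0.85,
    ref/ref below 0.15.  A position absent from the variant table is
    ref/ref when ``position_depths`` shows covering evidence (depth >=
    ``min_depth``), otherwise no-call.
    """
    if len(defs) != N_PGX_SNPS:
        raise ConfigError(
            f"pharmacogenetic table must have exactly {N_PGX_SNPS} rows, got {len(defs)}"
        )
    by_site = {(v.chrom, v.pos, v.ref, v.alt): v for v in variants}
    out = []
    for d in defs:
        v = by_site.get((d.chrom, d.pos, d.ref, d.alt))
        if v is not None:
            if v.vaf >= hom_alt_vaf:
                call = PgxCall.alt_alt
            elif v.vaf >= het_vaf:
                call = PgxCall.ref_alt
            else:
                call = PgxCall.ref_ref
        else:
            depth = (position_depths or {}).get((d.chrom, d.pos), 0)
            call = PgxCall.ref_ref if depth >= min_depth else PgxCall.no_call
        out.append(PgxGenotype(d.rsid, call))
    return out


# ---------------------------------------------------------------------------
# Case summary
# ---------------------------------------------------------------------------


@dataclass
class CaseSummary:
    case_id: str
    tumor_type: str
    n_pathogenic_prioritized: int
    pathogenic_positive: bool
    actionable: bool
    tiers: list[TierAnnotation]
    genes_by_class: dict[str, set[str]]  # alteration class -> affected genes
    msi_class: str | None = None
    n_pgx_variant_carrier: bool = False


def summarize_case(
    case_id: str,
    tumor_type: str,
    variants: Sequence[VariantRecord],
    cnv_events: Sequence = (),
    msi_result=None,
    pgx: Sequence[PgxGenotype] = (),
    kb: Sequence[KnowledgeEntry] | None = None,
) -> CaseSummary:
    """Roll one patient case up into pathogenic/actionable flags and
    per-gene alteration classes for cohort frequency tables.

    A case is pathogenic-positive iff it has at least one prioritized
    pathogenic/likely-pathogenic small variant; actionable iff any finding
    (variant, CNV, fusion, MSI status) carries a tier annotation.
    """
    from oncopanel.cnv_caller import CnvDirection

    kb = list(kb) if kb is not None else []
    tiers: list[TierAnnotation] = []
    genes_by_class: dict[str, set[str]] = {"SNV": set(), "CNV": set()}

    pathogenic = [
        v
        for v in variants
        if v.priority == Priority.prioritized
        and v.functional_class
        in (FunctionalClass.pathogenic, FunctionalClass.likely_pathogenic)
    ]
    for v in pathogenic:
        if v.gene:
            genes_by_class["SNV"].add(v.gene)
        tiers.extend(assign_tiers(v, tumor_type, kb) if kb else v.tiers)

    for ev in cnv_events:
        gene = getattr(ev, "gene", "") or ""
        if gene:
            genes_by_class["CNV"].add(gene)
            alteration = (
                "amplification" if ev.direction == CnvDirection.gain else "deletion"
            )
            tiers.extend(assign_tiers_gene_level(gene, alteration, tumor_type, kb))

    if msi_result is not None and kb:
        status = getattr(msi_result, "msi_class", None)
        status_value = getattr(status, "value", status)
        for e in kb:
            if (
                e.match_kind == MatchKind.msi_status
                and e.match_value == status_value
                and _tumor_type_matches(e.tumor_type, tumor_type)
            ):
                tiers.extend(e.tiers)

    collapsed = _collapse_best(tiers)
    return CaseSummary(
        case_id=case_id,
        tumor_type=tumor_type,
        n_pathogenic_prioritized=len(pathogenic),
        pathogenic_positive=len(pathogenic) > 0,
        actionable=len(collapsed) > 0,
        tiers=collapsed,
        genes_by_class={k: v for k, v in genes_by_class.items()},
        msi_class=getattr(getattr(msi_result, "msi_class", None), "value", None),
        n_pgx_variant_carrier=any(
            g.genotype in (PgxCall.ref_alt, PgxCall.alt_alt) for g in pgx
        ),
    )
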