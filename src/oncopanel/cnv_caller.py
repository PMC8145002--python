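"""Purity-aware CNV calling from per-target coverage log2 ratios.

Model
-----
A tumor specimen is a two-population mixture of tumor cells at cellularity
``c`` carrying ``CN`` copies of a region and normal cells at ``1 - c``
carrying 2 copies, so the expected coverage log2 ratio of the region against
a diploid reference is::

    r(CN, c) = log2( (c * CN + (1 - c) * 2) / 2 )

The caller normalizes per-target depths by median-of-ratios against a panel
of normals, forms maximal runs of adjacent targets strictly beyond the gain
(+0.3) or loss (-0.4) thresholds, inverts the mixture model to estimate the
purity-corrected copy number of each event, and attaches a 0-10 credibility
SCORE combining ratio magnitude, event size, member-target concordance and
neighborhood context.  Events scoring strictly above 8 are high-confidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from oncopanel.core_io import (
    CoverageProfile,
    SampleMeta,
    TargetRegion,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}

GAIN_LOG2_DEFAULT = 0.3
LOSS_LOG2_DEFAULT = -0.4


class CnvDirection(str, Enum):
    gain = "gain"
    loss = "loss"
    cnloh = "cnloh"


class ScoreClass(str, Enum):
    high = "high"
    medium = "medium"
    low = "low"


@dataclass(frozen=True)
class CnvThresholds:
    """Per-target log2-ratio calling thresholds (strict inequalities)."""

    gain_log2: float = GAIN_LOG2_DEFAULT
    loss_log2: float = LOSS_LOG2_DEFAULT

    def __post_init__(self) -> None:
        if not self.gain_log2 > 0 > self.loss_log2:
            raise ValidationError(
                f"thresholds must satisfy gain > 0 > loss, got "
                f"({self.gain_log2}, {self.loss_log2})"
            )


@dataclass
class Log2RatioProfile:
    """Per-target coverage log2 ratios for one sample.

    Targets that failed normalization are absent, never NaN.
    """

    sample_id: str
    targets: tuple[TargetRegion, ...]
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.ratios) != len(self.targets):
            raise ValidationError("ratio/target length mismatch")
        if not np.all(np.isfinite(self.ratios)):
            raise ValidationError("log2 ratios must be finite")


@dataclass
class CnvEvent:
    """A called gain/loss/cnLOH region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    direction: CnvDirection
    n_targets: int
    event_log2: float
    copy_number: float
    score: float = 0.0
    score_class: ScoreClass = ScoreClass.low
    sex_chromosome: bool = False
    member_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValidationError("event size must be >= 1 bp")
        if self.n_targets < 1:
            raise ValidationError("event must span >= 1 target")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.direction.value)


# ---------------------------------------------------------------------------
# Purity-mixture model
# ---------------------------------------------------------------------------


def expected_log2_ratio(copy_number: float, tumor_cellularity: float) -> float:
    """Expected coverage log2 ratio of a region at ``copy_number`` total
    copies in the tumor fraction of a sample with the given cellularity.

    Diploid (CN=2) always maps to 0 regardless of purity.
    """
    c = tumor_cellularity
    if not 0 < c <= 1:
        raise ValidationError(f"tumor_cellularity must be in (0,1], got {c}")
    if copy_number < 0:
        raise ValidationError(f"copy_number must be >= 0, got {copy_number}")
    mix = c * copy_number + (1 - c) * 2.0
    if mix <= 0:
        # only reachable at c=1, CN=0: a fully clonal homozygous deletion
        return -math.inf
    return math.log2(mix / 2.0)


def estimate_copy_number(event_log2: float, tumor_cellularity: float) -> float:
    """Invert the purity mixture: the copy number whose expected log2 ratio
    equals ``event_log2`` at the given cellularity, floored at 0."""
    c = tumor_cellularity
    if not 0 < c <= 1:
        raise ValidationError(f"tumor_cellularity must be in (0,1], got {c}")
    cn = (2.0 ** (event_log2 + 1.0) - 2.0 * (1.0 - c)) / c
    return max(cn, 0.0)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_coverage(
    sample: CoverageProfile, reference_set: Sequence[CoverageProfile]
) -> Log2RatioProfile:
    """Median-of-ratios normalization against a panel of normals.

    Each profile is first scaled to fractional coverage (depth / sample
    median depth); the per-target reference level is the median fractional
    coverage across the panel; the ratio is log2(sample / reference).
    Targets with zero reference median or zero sample depth are dropped
    and logged.
    """
    if len(reference_set) < 2:
        raise ValidationError(
            f"need >= 2 reference profiles, got {len(reference_set)}"
        )
    for ref in reference_set:
        if ref.targets != sample.targets:
            raise ValidationError(
                f"reference {ref.sample_id} target set differs from sample"
            )
    sample_median = float(np.median(sample.depths))
    if sample_median <= 0:
        raise ValidationError(f"{sample.sample_id}: sample median depth is 0")

    sample_frac = sample.depths / sample_median
    ref_fracs = []
    for ref in reference_set:
        med = float(np.median(ref.depths))
        if med <= 0:
            raise ValidationError(f"reference {ref.sample_id}: median depth is 0")
        ref_fracs.append(ref.depths / med)
    ref_median = np.median(np.vstack(ref_fracs), axis=0)

    keep = (ref_median > 0) & (sample_frac > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [t.name for t, k in zip(sample.targets, keep) if not k]
        logger.warning(
            "%s: dropped %d target(s) with zero coverage during normalization: %s",
            sample.sample_id,
            n_dropped,
            dropped,
        )
    targets = tuple(t for t, k in zip(sample.targets, keep) if k)
    ratios = np.log2(sample_frac[keep] / ref_median[keep])
    return Log2RatioProfile(sample.sample_id, targets, ratios)


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------


def call_events(
    profile: Log2RatioProfile,
    meta: SampleMeta,
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[CnvEvent]:
    """Call CNV events as maximal runs of adjacent same-chromosome targets
    all strictly beyond a threshold.

    Targets at exactly a threshold never trigger a call.  The event log2
    is the median of member-target ratios (robust to single-target
    outliers) and the copy number is the purity-corrected estimate at the
    sample's tumor cellularity.
    """
    if len(profile.targets) == 0:
        raise ValidationError("empty log2-ratio profile")
    events: list[CnvEvent] = []
    run_dir: CnvDirection | None = None
    run_idx: list[int] = []

    def flush() -> None:
        nonlocal run_idx, run_dir
        if run_dir is not None and run_idx:
            events.append(_make_event(profile, run_idx, run_dir, meta))
        run_idx, run_dir = [], None

    prev_chrom: str | None = None
    for i, (target, ratio) in enumerate(zip(profile.targets, profile.ratios)):
        if ratio > thresholds.gain_log2:
            direction = CnvDirection.gain
        elif ratio < thresholds.loss_log2:
            direction = CnvDirection.loss
        else:
            direction = None
        if direction != run_dir or target.chrom != prev_chrom:
            flush()
            run_dir = direction
        if direction is not None:
            run_idx.append(i)
        prev_chrom = target.chrom
    flush()

    for event in events:
        score_event(event, profile, thresholds, events)
    return events


def _make_event(
    profile: Log2RatioProfile,
    idx: list[int],
    direction: CnvDirection,
    meta: SampleMeta,
) -> CnvEvent:
    targets = [profile.targets[i] for i in idx]
    ratios = profile.ratios[idx]
    event_log2 = float(np.median(ratios))
    cellularity = meta.tumor_cellularity if meta.tumor_cellularity > 0 else 1.0
    chrom = targets[0].chrom
    return CnvEvent(
        chrom=chrom,
        start=targets[0].start,
        end=targets[-1].end,
        direction=direction,
        n_targets=len(idx),
        event_log2=event_log2,
        copy_number=estimate_copy_number(event_log2, cellularity),
        sex_chromosome=chrom in SEX_CHROMOSOMES,
        member_names=tuple(t.name for t in targets),
    )


# ---------------------------------------------------------------------------
# Credibility SCORE
# ---------------------------------------------------------------------------

SCORE_WEIGHTS = {"magnitude": 0.4, "size": 0.3, "concordance": 0.2, "context": 0.1}
SCORE_SIZE_FLOOR_BP = 500       # events at/below this size contribute 0
SCORE_SIZE_SATURATION_DECADES = 3.0  # saturates at 0.5 Mb
SCORE_CONTEXT_WINDOW_BP = 1_000_000
HIGH_SCORE_BOUND = 8.0          # high-confidence strictly above this
MEDIUM_SCORE_BOUND = 4.0


def score_event(
    event: CnvEvent,
    profile: Log2RatioProfile,
    thresholds: CnvThresholds = CnvThresholds(),
    events: Sequence[CnvEvent] | None = None,
    magnitude: float | None = None,
) -> CnvEvent:
    """Attach the 0-10 credibility SCORE to ``event`` (mutates and returns it).

    score = 10 * (0.4*A + 0.3*B + 0.2*C + 0.1*D) with
      A  ratio magnitude relative to twice its calling threshold, capped at 1
      B  log10(size/500bp)/3, clipped to [0,1] (saturates at 0.5 Mb)
      C  fraction of member targets individually beyond the threshold
      D  1 if no opposite-direction event within 1 Mb, else 0
    Classes: high iff score > 8, medium iff 4 < score <= 8, low otherwise.
    """
    member_idx = [
        i for i, t in enumerate(profile.targets) if t.name in set(event.member_names)
    ]
    if not member_idx and event.direction != CnvDirection.cnloh:
        member_idx = [
            i
            for i, t in enumerate(profile.targets)
            if t.chrom == event.chrom and t.start < event.end and t.end > event.start
        ]
        if not member_idx:
            raise ValidationError(
                f"event {event.chrom}:{event.start}-{event.end} does not overlap "
                "the profile"
            )

    thr = (
        thresholds.gain_log2
        if event.direction == CnvDirection.gain
        else thresholds.loss_log2
    )
    if magnitude is not None:
        a = min(magnitude, 1.0)
    else:
        a = min(abs(event.event_log2) / (2.0 * abs(thr)), 1.0)

    b = float(
        np.clip(
            math.log10(event.size_bp / SCORE_SIZE_FLOOR_BP)
            / SCORE_SIZE_SATURATION_DECADES
            if event.size_bp > SCORE_SIZE_FLOOR_BP
            else 0.0,
            0.0,
            1.0,
        )
    )

    if event.direction == CnvDirection.gain:
        concordant = profile.ratios[member_idx] > thresholds.gain_log2
        c = float(np.mean(concordant))
    elif event.direction == CnvDirection.loss:
        concordant = profile.ratios[member_idx] < thresholds.loss_log2
        c = float(np.mean(concordant))
    else:
        c = 1.0  # cnLOH members are deviated SNPs by construction

    d = 1.0
    opposite = {
        CnvDirection.gain: CnvDirection.loss,
        CnvDirection.loss: CnvDirection.gain,
        CnvDirection.cnloh: None,
    }[event.direction]
    if opposite is not None and events:
        for other in events:
            if other is event or other.direction != opposite:
                continue
            if other.chrom != event.chrom:
                continue
            gap = max(other.start - event.end, event.start - other.end, 0)
            if gap <= SCORE_CONTEXT_WINDOW_BP:
                d = 0.0
                break

    w = SCORE_WEIGHTS
    score = 10.0 * (
        w["magnitude"] * a + w["size"] * b + w["concordance"] * c + w["context"] * d
    )
    event.score = score
    event.score_class = (
        ScoreClass.high
        if score > HIGH_SCORE_BOUND
        else ScoreClass.medium
        if score > MEDIUM_SCORE_BOUND
        else ScoreClass.low
    )
    return event


# ---------------------------------------------------------------------------
# Copy-neutral LOH
# ---------------------------------------------------------------------------

CNLOH_MIN_RUN = 10
CNLOH_BAF_DEVIATION = 0.15
CNLOH_NEUTRAL_BAND = 0.1


def detect_cnloh(
    snp_bafs: Sequence[tuple[TargetRegion, float]],
    profile: Log2RatioProfile,
    min_run: int = CNLOH_MIN_RUN,
    baf_deviation: float = CNLOH_BAF_DEVIATION,
    neutral_band: float = CNLOH_NEUTRAL_BAND,
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[CnvEvent]:
    """Flag copy-neutral LOH from SNP B-allele fractions.

    A cnLOH event is a maximal run of >= ``min_run`` consecutive SNPs (in
    genomic order, same chromosome) whose BAF deviates from 0.5 by more
    than ``baf_deviation`` while every overlapping coverage target stays
    within the copy-neutral band ``|log2 ratio| <= neutral_band``.

    SNPs must be pre-restricted to loci heterozygous in the matched
    control; homozygous germline SNPs would otherwise mimic LOH.
    """
    events: list[CnvEvent] = []
    run: list[tuple[TargetRegion, float]] = []
    prev_chrom: str | None = None

    def flush() -> None:
        nonlocal run
        if len(run) >= min_run:
            ev = _cnloh_event(run, profile, neutral_band, thresholds)
            if ev is not None:
                events.append(ev)
        run = []

    for region, baf in snp_bafs:
        deviated = abs(baf - 0.5) > baf_deviation
        if not deviated or region.chrom != prev_chrom:
            flush()
        if deviated:
            run.append((region, baf))
        prev_chrom = region.chrom
    flush()
    return events


def _cnloh_event(
    run: list[tuple[TargetRegion, float]],
    profile: Log2RatioProfile,
    neutral_band: float,
    thresholds: CnvThresholds,
) -> CnvEvent | None:
    chrom = run[0][0].chrom
    start, end = run[0][0].start, run[-1][0].end
    overlap_ratios = [
        r
        for t, r in zip(profile.targets, profile.ratios)
        if t.chrom == chrom and t.start < end and t.end > start
    ]
    if any(abs(r) > neutral_band for r in overlap_ratios):
        return None  # copy-number change, not copy-neutral
    mean_dev = float(np.mean([abs(b - 0.5) for _, b in run]))
    event = CnvEvent(
        chrom=chrom,
        start=start,
        end=end,
        direction=CnvDirection.cnloh,
        n_targets=len(run),
        event_log2=float(np.mean(overlap_ratios)) if overlap_ratios else 0.0,
        copy_number=2.0,
        sex_chromosome=chrom in SEX_CHROMOSOMES,
        member_names=tuple(t.name for t, _ in run),
    )
    return score_event(event, profile, thresholds, magnitude=mean_dev / 0.5)


# ---------------------------------------------------------------------------
# Limit of detection
# ---------------------------------------------------------------------------


def lod_curve(
    thresholds: CnvThresholds = CnvThresholds(),
    infiltration_grid: Iterable[float] = (0.0, 0.25, 0.5, 0.75),
    max_cn: int = 100,
) -> pd.DataFrame:
    """Detectability limits of integer copy numbers across non-tumor
    infiltration levels.

    For each infiltration ``f`` (cellularity ``c = 1 - f``): the minimum
    detectable gain is the smallest integer CN > 2 whose expected log2
    ratio strictly exceeds the gain threshold; the deletion limit is the
    largest integer CN < 2 whose expected ratio is strictly below the loss
    threshold (``None`` when no integer qualifies).
    """
    rows = []
    for f in infiltration_grid:
        if not 0 <= f < 1:
            raise ValidationError(f"infiltration must be in [0,1), got {f}")
        c = 1.0 - f
        min_gain = None
        for cn in range(3, max_cn + 1):
            if expected_log2_ratio(cn, c) > thresholds.gain_log2:
                min_gain = cn
                break
        max_del = None
        for cn in (1, 0):
            if expected_log2_ratio(cn, c) < thresholds.loss_log2:
                max_del = cn
                break
        rows.append(
            {
                "infiltration": f,
                "min_detectable_gain_cn": min_gain,
                "max_detectable_deletion_cn": max_del,
            }
        )
    return pd.DataFrame(rows)
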