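"""Microsatellite-instability classification from marker repeat-length
histograms against a baseline of microsatellite-stable (MSS) samples.

The assay genotypes 110 microsatellite markers distributed across the
genome.  For each marker a baseline repeat-length distribution is built
from MSS reference samples; a test sample's marker is *unstable* when its
normalized length distribution deviates from the baseline by more than the
marker's threshold (the largest deviation seen within the baseline set plus
a safety margin).  The instability fraction — unstable markers over valid
(adequately covered) markers — is banded into MSS, inconclusive, MSI-L and
MSI-H; a sample with fewer than 99 valid markers is a no-call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from oncopanel.core_io import ConfigError, ParseError, ValidationError

N_PANEL_MARKERS = 110
MIN_VALID_MARKERS = 99
MIN_MARKER_COVERAGE = 30
BASELINE_MARGIN = 0.05
MIN_REFERENCE_SAMPLES = 3

# Instability-fraction bands, half-open with inclusive lower bounds.  The
# printed two-decimal band edges (0.17 | 0.18-0.20 | 0.21-0.30 | >=0.31)
# are closed so that every exact fraction (e.g. 31/99) classifies
# deterministically while each printed endpoint keeps its printed class.
MSS_UPPER = 0.18
MSI_L_LOWER = 0.21
MSI_H_LOWER = 0.31


class MsiClass(str, Enum):
    MSS = "MSS"
    inconclusive = "inconclusive"
    MSI_L = "MSI_L"
    MSI_H = "MSI_H"
    no_call = "no_call"


@dataclass(frozen=True)
class MsiMarkerDef:
    """One microsatellite marker locus (0-based half-open)."""

    marker_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str
    reference_length: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.marker_id}: end must exceed start")
        if self.reference_length < 1:
            raise ValidationError(f"{self.marker_id}: reference_length must be >= 1")


@dataclass
class MarkerHistogram:
    """Read support per observed repeat length at one marker."""

    marker_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for length, n in self.counts.items():
            if length < 0 or n < 0:
                raise ValidationError(
                    f"{self.marker_id}: negative length or count ({length}: {n})"
                )

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def normalized(self) -> dict[int, float]:
        total = self.coverage
        if total == 0:
            return {}
        return {length: n / total for length, n in self.counts.items()}


def tv_distance(p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """Total-variation distance between two length distributions, in [0,1]."""
    support = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in support)


@dataclass
class BaselineMarker:
    distribution: dict[int, float]
    instability_threshold: float


@dataclass
class MsiBaseline:
    """Per-marker MSS reference distributions and instability thresholds."""

    markers: dict[str, BaselineMarker]
    n_reference_samples: int
    margin: float = BASELINE_MARGIN

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reference_samples": self.n_reference_samples,
            "margin": self.margin,
            "markers": {
                mid: {
                    "distribution": {str(k): v for k, v in m.distribution.items()},
                    "instability_threshold": m.instability_threshold,
                }
                for mid, m in self.markers.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MsiBaseline":
        data = json.loads(Path(path).read_text())
        markers = {
            mid: BaselineMarker(
                distribution={int(k): v for k, v in m["distribution"].items()},
                instability_threshold=m["instability_threshold"],
            )
            for mid, m in data["markers"].items()
        }
        return cls(markers, data["n_reference_samples"], data.get("margin", BASELINE_MARGIN))


@dataclass
class MarkerCall:
    marker_id: str
    coverage: int
    valid: bool
    statistic: float
    unstable: bool


@dataclass
class MsiResult:
    sample_id: str
    marker_calls: list[MarkerCall]
    n_valid: int
    n_unstable: int
    instability_fraction: float | None
    fraction_exact: Fraction | None
    msi_class: MsiClass


# ---------------------------------------------------------------------------
# Baseline construction
# ---------------------------------------------------------------------------


def build_baseline(
    references: Sequence[Mapping[str, MarkerHistogram]],
    margin: float = BASELINE_MARGIN,
    min_coverage: int = MIN_MARKER_COVERAGE,
) -> MsiBaseline:
    """Build the MSS baseline from >= 3 reference samples.

    Per marker: the baseline distribution is the mean of the normalized
    reference histograms, and the instability threshold is the largest
    deviation statistic any reference sample shows against that mean, plus
    ``margin`` (capped at 1) — so every baseline sample self-classifies
    stable with room to spare.
    """
    if len(references) < MIN_REFERENCE_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_REFERENCE_SAMPLES} reference samples, got {len(references)}"
        )
    marker_ids = set(references[0])
    for i, ref in enumerate(references[1:], start=2):
        if set(ref) != marker_ids:
            diff = sorted(marker_ids.symmetric_difference(set(ref)))
            raise ValidationError(f"reference sample #{i} marker set differs: {diff}")
    for ref in references:
        for mid, hist in ref.items():
            if hist.coverage < min_coverage:
                raise ValidationError(
                    f"reference marker {mid}: coverage {hist.coverage} below "
                    f"validity threshold {min_coverage}"
                )

    markers: dict[str, BaselineMarker] = {}
    for mid in sorted(marker_ids):
        norms = [ref[mid].normalized() for ref in references]
        support = sorted(set().union(*norms))
        mean = {k: float(np.mean([n.get(k, 0.0) for n in norms])) for k in support}
        max_dev = max(tv_distance(n, mean) for n in norms)
        markers[mid] = BaselineMarker(
            distribution=mean,
            instability_threshold=min(max_dev + margin, 1.0),
        )
    return MsiBaseline(markers, n_reference_samples=len(references), margin=margin)


# ---------------------------------------------------------------------------
# Per-marker calls and classification
# ---------------------------------------------------------------------------


def marker_stability(
    observed: MarkerHistogram,
    baseline: MsiBaseline,
    min_coverage: int = MIN_MARKER_COVERAGE,
) -> MarkerCall:
    """Score one marker against the baseline.

    The deviation statistic is the total-variation distance between the
    observed normalized histogram and the baseline distribution.  Markers
    under the coverage threshold are invalid: they carry ``unstable=False``
    and are excluded from fraction denominators.
    """
    if observed.marker_id not in baseline.markers:
        raise ConfigError(f"marker {observed.marker_id!r} not in baseline")
    ref = baseline.markers[observed.marker_id]
    valid = observed.coverage >= min_coverage
    statistic = tv_distance(observed.normalized(), ref.distribution)
    unstable = bool(valid and statistic > ref.instability_threshold)
    return MarkerCall(observed.marker_id, observed.coverage, valid, statistic, unstable)


def instability_fraction(calls: Sequence[MarkerCall]) -> Fraction:
    """Unstable over valid markers, as an exact rational."""
    n_valid = sum(c.valid for c in calls)
    if n_valid == 0:
        raise ValidationError("no valid markers: instability fraction undefined")
    n_unstable = sum(c.unstable for c in calls)
    return Fraction(n_unstable, n_valid)


def classify_msi(
    fraction: float | Fraction,
    n_valid: int,
    min_valid: int = MIN_VALID_MARKERS,
) -> MsiClass:
    """Band an instability fraction into an MSI class.

    no-call below ``min_valid`` valid markers; otherwise
    MSS [0, 0.18) | inconclusive [0.18, 0.21) | MSI-L [0.21, 0.31) | MSI-H [0.31, 1].
    """
    f = float(fraction)
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"instability fraction {f} outside [0,1]")
    if n_valid < min_valid:
        return MsiClass.no_call
    if f < MSS_UPPER:
        return MsiClass.MSS
    if f < MSI_L_LOWER:
        return MsiClass.inconclusive
    if f < MSI_H_LOWER:
        return MsiClass.MSI_L
    return MsiClass.MSI_H


def call_msi(
    sample_id: str,
    histograms: Mapping[str, MarkerHistogram],
    baseline: MsiBaseline,
    min_coverage: int = MIN_MARKER_COVERAGE,
    min_valid: int = MIN_VALID_MARKERS,
) -> MsiResult:
    """Full per-sample MSI determination: score every baseline marker,
    compute the instability fraction over valid markers and classify."""
    calls = []
    for mid in sorted(baseline.markers):
        if mid not in histograms:
            calls.append(MarkerCall(mid, 0, False, 0.0, False))
            continue
        calls.append(marker_stability(histograms[mid], baseline, min_coverage))
    n_valid = sum(c.valid for c in calls)
    n_unstable = sum(c.unstable for c in calls)
    if n_valid == 0:
        return MsiResult(sample_id, calls, 0, 0, None, None, MsiClass.no_call)
    frac = Fraction(n_unstable, n_valid)
    return MsiResult(
        sample_id,
        calls,
        n_valid,
        n_unstable,
        float(frac),
        frac,
        classify_msi(frac, n_valid, min_valid),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_marker_defs(path: str | Path) -> list[MsiMarkerDef]:
    """Read marker definitions TSV (marker_id, chrom, start, end,
    repeat_unit, reference_length)."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "chrom", "start", "end", "repeat_unit", "reference_length"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        MsiMarkerDef(
            marker_id=str(r.marker_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            repeat_unit=str(r.repeat_unit),
            reference_length=int(r.reference_length),
        )
        for r in df.itertuples(index=False)
    ]


def default_marker_defs() -> list[MsiMarkerDef]:
    """The bundled default 110-marker definition set."""
    from importlib.resources import files

    return read_marker_defs(files("oncopanel.resources") / "msi_markers.tsv")


def read_histograms(path: str | Path) -> dict[str, MarkerHistogram]:
    """Read one sample's marker histograms TSV
    (sample_id, marker_id, repeat_length, read_count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "marker_id", "repeat_length", "read_count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out: dict[str, MarkerHistogram] = {}
    for mid, group in df.groupby("marker_id", sort=False):
        counts = {
            int(l): int(n)
            for l, n in zip(group["repeat_length"], group["read_count"])
        }
        out[str(mid)] = MarkerHistogram(str(mid), counts)
    return out


def write_histograms(
    sample_id: str, histograms: Mapping[str, MarkerHistogram], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": sample_id,
            "marker_id": mid,
            "repeat_length": length,
            "read_count": n,
        }
        for mid, hist in histograms.items()
        for length, n in sorted(hist.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
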