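"""Promoter signal-area quantification and methylation group comparison.

The region statistic treats a signal track as a step function: the total
peak area within a region is the sum over track segments of (overlap width
with the region) x (signal value).  Segments partially overlapping the
region contribute only their clipped width, which makes the statistic
independent of how the track is binned.  Group comparisons (area by
molecular subtype, per-probe methylation beta by subtype) use the
tie-corrected Kruskal-Wallis test with Holm adjustment across probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .integration_stats import TestResult, holm_adjust, kruskal_wallis
from .io_core import FormatError, GenomicRegion, ParameterError


class SignalSegment(NamedTuple):
    """A constant-valued track interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    value: float


#: Promoter CpG probes closest to the transcription start site, the default
#: subset for methylation comparisons.
DEFAULT_PROMOTER_PROBES = ("cg14552260", "cg14339556", "cg13912011")


@dataclass(frozen=True)
class BetaValue:
    """One sample's methylation fraction at one array probe."""

    sample_id: str
    probe_id: str
    beta: float
    subtype: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta {self.beta} outside [0, 1]")


def _validated_track(track: Iterable[SignalSegment], chrom: str | None) -> list[SignalSegment]:
    segments = sorted(
        (SignalSegment(*s) for s in track), key=lambda s: (s.chrom, s.start, s.end)
    )
    for seg in segments:
        if seg.end <= seg.start:
            raise FormatError(f"segment end <= start: {seg}")
        if seg.value < 0:
            raise FormatError(f"negative signal value: {seg}")
    for prev, cur in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise FormatError(f"overlapping segments: {prev} and {cur}")
    if chrom is not None:
        segments = [s for s in segments if s.chrom == chrom]
    return segments


def peak_area(track: Iterable[SignalSegment], region: GenomicRegion) -> float:
    """Total signal area (coordinate units x signal) of a track in a region.

    area = sum over segments of clip(segment, region).width x value.
    An empty track has area 0.  Overlapping segments are rejected.
    """
    area = 0.0
    for seg in _validated_track(track, region.chrom):
        overlap = min(seg.end, region.end) - max(seg.start, region.start)
        if overlap > 0:
            area += overlap * seg.value
    return area


def areas_by_sample(
    tracks: Mapping[str, Iterable[SignalSegment]], region: GenomicRegion
) -> dict[str, float]:
    """Peak area of each sample's track over one region."""
    return {sample: peak_area(track, region) for sample, track in tracks.items()}


def compare_area_by_group(
    areas: Mapping[str, float], groups: Mapping[str, str]
) -> TestResult:
    """Kruskal-Wallis comparison of per-sample areas across subtype groups."""
    missing = set(areas) - set(groups)
    if missing:
        raise ParameterError(f"samples with no group label: {sorted(missing)}")
    by_group: dict[str, list[float]] = {}
    for sample, area in areas.items():
        by_group.setdefault(groups[sample], []).append(area)
    if len(by_group) < 2:
        raise ParameterError("compare_area_by_group: need >= 2 groups")
    return kruskal_wallis(list(by_group.values()))


def compare_beta_by_group(
    betas: pd.DataFrame | Iterable[BetaValue],
    probes: Sequence[str] = DEFAULT_PROMOTER_PROBES,
) -> pd.DataFrame:
    """Per-probe Kruskal-Wallis of beta values across subtypes, Holm-adjusted.

    Accepts a tidy DataFrame (sample_id, probe_id, beta, subtype) or an
    iterable of :class:`BetaValue`.  Probes absent from the data are skipped;
    an empty probe subset yields an empty result.
    """
    if not isinstance(betas, pd.DataFrame):
        betas = pd.DataFrame([vars(b) for b in betas])
    if len(betas) and (betas["beta"].lt(0).any() or betas["beta"].gt(1).any()):
        raise ParameterError("beta values must be in [0, 1]")
    rows = []
    for probe in probes:
        sub = betas[betas["probe_id"] == probe]
        if sub.empty:
            continue
        groups = [g["beta"].tolist() for _, g in sub.groupby("subtype", sort=True)]
        if len(groups) < 2:
            raise ParameterError(f"probe {probe}: need >= 2 subtypes represented")
        res = kruskal_wallis(groups)
        rows.append({"probe_id": probe, "H": res.statistic, "p": res.p_value, "n": res.n})
    result = pd.DataFrame(rows, columns=["probe_id", "H", "p", "n"])
    if len(result):
        result["p_holm"] = holm_adjust(result["p"].tolist())
    else:
        result["p_holm"] = pd.Series(dtype=float)
    return result
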