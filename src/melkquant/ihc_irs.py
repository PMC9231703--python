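"""ImmunoReactive Score (IRS) computation and cohort summaries.

The IRS multiplies a staining intensity grade (0 negative, 1+ weak,
2+ moderate, 3+ strong) by a percent-positive bin score (0: 0%, 1: 1-10%,
2: 11-50%, 3: 51-80%, 4: > 80%), giving a combined score of 0-12.  Scores
0-3 are negative (none/low expression); 4-12 are positive (4-8 moderate,
> 8 high).  Scores are computed per tissue core and per cellular
compartment (nuclear / cytoplasmic); cytoplasmic staining can only occur in
cores that also show nuclear staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

import pandas as pd

from .io_core import ParameterError, RunConfig, round_half_up

TISSUE_CLASSES = ("benign", "DCIS", "IDC", "metastasis")
#: Classes entering the ordered three-class comparisons; metastases are
#: summarized but not compared.
COMPARED_CLASSES = ("benign", "DCIS", "IDC")
IRS_CATEGORIES = ("none", "low", "moderate", "high")


def _as_int_percent(percent_positive) -> int:
    """Percent-positive values are visually estimated integers; reject others."""
    if isinstance(percent_positive, bool) or not isinstance(percent_positive, Integral):
        if isinstance(percent_positive, float) and percent_positive.is_integer():
            percent_positive = int(percent_positive)
        else:
            raise ParameterError(
                f"percent_positive must be an integer 0-100, got {percent_positive!r}"
            )
    value = int(percent_positive)
    if not 0 <= value <= 100:
        raise ParameterError(f"percent_positive {value} outside 0-100")
    return value


def percent_score(percent_positive, config: RunConfig | None = None) -> int:
    """Bin an integer percent-positive into the 0-4 IRS percent score."""
    config = config or RunConfig()
    value = _as_int_percent(percent_positive)
    edges = config.percent_bin_edges  # (0, 10, 50, 80, 100) by default
    if value == 0:
        return 0
    for score, upper in enumerate(edges[1:], start=1):
        if value <= upper:
            return score
    raise ParameterError(f"percent_positive {value} exceeds top bin edge")  # pragma: no cover


@dataclass(frozen=True)
class IRSResult:
    """One compartment's IRS: percent bin, combined score, category, call."""

    intensity: int
    percent_score: int
    combined: int
    category: str
    positive: bool


def irs(intensity: int, percent_positive, config: RunConfig | None = None) -> IRSResult:
    """Combined IRS = intensity grade x percent score, with banding."""
    config = config or RunConfig()
    if isinstance(intensity, bool) or not isinstance(intensity, Integral):
        raise ParameterError(f"intensity grade must be an integer 0-3, got {intensity!r}")
    intensity = int(intensity)
    if not 0 <= intensity <= 3:
        raise ParameterError(f"intensity grade {intensity} outside 0-3")
    pscore = percent_score(percent_positive, config)
    combined = intensity * pscore
    if combined == 0:
        category = "none"
    elif combined <= config.irs_low_max:
        category = "low"
    elif combined <= config.irs_moderate_max:
        category = "moderate"
    else:
        category = "high"
    return IRSResult(
        intensity=intensity, percent_score=pscore, combined=combined,
        category=category, positive=combined >= config.irs_positive_min,
    )


@dataclass(frozen=True)
class IHCCore:
    """One tissue core's scores for both compartments."""

    core_id: str
    tissue_class: str
    nuclear_intensity: int
    nuclear_percent: int
    cytoplasmic_intensity: int = 0
    cytoplasmic_percent: int = 0

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ParameterError(
                f"unknown tissue_class {self.tissue_class!r}; expected one of {TISSUE_CLASSES}"
            )
        for comp in ("nuclear", "cytoplasmic"):
            inten = getattr(self, f"{comp}_intensity")
            pct = _as_int_percent(getattr(self, f"{comp}_percent"))
            object.__setattr__(self, f"{comp}_percent", pct)
            if not 0 <= int(inten) <= 3:
                raise ParameterError(f"{comp} intensity {inten} outside 0-3")
            if inten == 0 and pct != 0:
                raise ParameterError(
                    f"core {self.core_id}: {comp} intensity 0 with nonzero percent"
                )
        if self.cytoplasmic_percent > 0 and self.nuclear_percent == 0:
            raise ParameterError(
                f"core {self.core_id}: cytoplasmic staining without nuclear staining"
            )

    def result(self, compartment: str, config: RunConfig | None = None) -> IRSResult:
        if compartment not in ("nuclear", "cytoplasmic"):
            raise ParameterError(f"unknown compartment {compartment!r}")
        return irs(
            getattr(self, f"{compartment}_intensity"),
            getattr(self, f"{compartment}_percent"),
            config,
        )


def score_cores(cores, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-core, per-compartment IRS table."""
    config = config or RunConfig()
    rows = []
    for core in cores:
        for comp in ("nuclear", "cytoplasmic"):
            res = core.result(comp, config)
            rows.append({
                "core_id": core.core_id, "tissue_class": core.tissue_class,
                "compartment": comp, "intensity": res.intensity,
                "percent_score": res.percent_score, "combined": res.combined,
                "category": res.category, "positive": res.positive,
            })
    return pd.DataFrame(rows)


def cohort_summary(cores, compartment: str, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-tissue-class positivity and percent-positive summaries.

    Positivity is the fraction of cores whose compartment IRS is positive
    (combined >= 4), reported with its numerator/denominator and the percent
    rounded to whole numbers; percent-positive mean and SD are rounded to two
    decimals, matching the precision used in reporting.
    """
    config = config or RunConfig()
    cores = list(cores)
    if not cores:
        raise ParameterError("cohort_summary: no cores")
    for core in cores:
        if core.tissue_class not in TISSUE_CLASSES:  # defensive; IHCCore validates
            raise ParameterError(f"unknown tissue_class {core.tissue_class!r}")
    rows = []
    for tissue_class in TISSUE_CLASSES:
        members = [c for c in cores if c.tissue_class == tissue_class]
        if not members:
            continue
        results = [c.result(compartment, config) for c in members]
        percents = [getattr(c, f"{compartment}_percent") for c in members]
        n = len(members)
        n_pos = sum(r.positive for r in results)
        mean = sum(percents) / n
        sd = (sum((p - mean) ** 2 for p in percents) / (n - 1)) ** 0.5 if n > 1 else 0.0
        rows.append({
            "tissue_class": tissue_class, "n": n, "n_positive": n_pos,
            "positivity": f"{n_pos}/{n}",
            "positivity_pct": round_half_up(100 * n_pos / n, 0),
            "percent_mean": round_half_up(mean, 2),
            "percent_sd": round_half_up(sd, 2),
        })
    return pd.DataFrame(rows)
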