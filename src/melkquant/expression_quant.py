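"""Relative expression quantification by the comparative-Ct (ddCt) method.

RQ = 2^(-ddCt), where ddCt = (Ct_target - Ct_reference)_sample -
(Ct_target - Ct_reference)_calibrator.  The reference is an endogenous
control transcript (18S rRNA in the study this emulates) and the calibrator
a baseline sample (HMEC).  RQ values are banded as high (>= 50), moderate
(20 to < 50), low (> 1 to < 20) or baseline (<= 1).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_core import ParameterError, RunConfig, round_half_up

RQ_BANDS = ("high", "moderate", "low", "baseline")


@dataclass(frozen=True)
class CtTable:
    """Replicate Ct values for the 2x2 ddCt design (condition x role).

    Every cell needs >= 2 finite, positive Ct values.
    """

    sample_target: tuple[float, ...]
    sample_reference: tuple[float, ...]
    calibrator_target: tuple[float, ...]
    calibrator_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("sample_target", "sample_reference",
                     "calibrator_target", "calibrator_reference"):
            values = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, values)
            if len(values) < 2:
                raise ParameterError(f"CtTable.{name}: need >= 2 replicates, got {len(values)}")
            if any(not math.isfinite(v) or v <= 0 for v in values):
                raise ParameterError(f"CtTable.{name}: Ct values must be finite and > 0")


@dataclass(frozen=True)
class RQResult:
    """A relative-quantification estimate with replicate spread and band."""

    rq: float
    sd: float
    delta_delta_ct: float
    band: str | None = None

    def rounded(self, precision: int = 2) -> tuple[float, float]:
        return round_half_up(self.rq, precision), round_half_up(self.sd, precision)


def delta_delta_ct(ct: CtTable, sd_method: str = "replicate_rq") -> RQResult:
    """Estimate the fold change 2^(-ddCt) from a replicate Ct table.

    ddCt uses cell means.  The spread is, by default, the sample standard
    deviation of per-replicate RQ values formed by pairing replicate i across
    the four design cells (extra replicates beyond the shortest cell are
    ignored); ``sd_method="propagated"`` instead propagates the per-cell Ct
    standard errors through the exponential.
    """
    dct_sample = statistics.fmean(ct.sample_target) - statistics.fmean(ct.sample_reference)
    dct_cal = statistics.fmean(ct.calibrator_target) - statistics.fmean(ct.calibrator_reference)
    ddct = dct_sample - dct_cal
    rq = 2.0 ** (-ddct)

    if sd_method == "replicate_rq":
        n = min(len(ct.sample_target), len(ct.sample_reference),
                len(ct.calibrator_target), len(ct.calibrator_reference))
        per_rep = [
            2.0 ** (-(
                (ct.sample_target[i] - ct.sample_reference[i])
                - (ct.calibrator_target[i] - ct.calibrator_reference[i])
            ))
            for i in range(n)
        ]
        sd = statistics.stdev(per_rep) if n >= 2 else 0.0
    elif sd_method == "propagated":
        var_ddct = sum(
            statistics.variance(cell) / len(cell)
            for cell in (ct.sample_target, ct.sample_reference,
                         ct.calibrator_target, ct.calibrator_reference)
        )
        sd = rq * math.log(2.0) * math.sqrt(var_ddct)
    else:
        raise ParameterError(f"unknown sd_method {sd_method!r}")
    return RQResult(rq=rq, sd=sd, delta_delta_ct=ddct)


def classify_rq(rq: float, config: RunConfig | None = None) -> str:
    """Band an RQ value: high / moderate / low / baseline (<= 1)."""
    config = config or RunConfig()
    if not math.isfinite(rq) or rq <= 0:
        raise ParameterError(f"RQ must be positive and finite, got {rq}")
    if rq >= config.rq_high_min:
        return "high"
    if rq >= config.rq_moderate_min:
        return "moderate"
    if rq > config.rq_baseline_max:
        return "low"
    return "baseline"


def quantify(ct: CtTable, config: RunConfig | None = None) -> RQResult:
    """ddCt estimation plus banding in one step."""
    config = config or RunConfig()
    result = delta_delta_ct(ct, sd_method=config.rq_sd_method)
    return RQResult(rq=result.rq, sd=result.sd, delta_delta_ct=result.delta_delta_ct,
                    band=classify_rq(result.rq, config))


def quantify_table(tables: Mapping[str, CtTable], config: RunConfig | None = None) -> pd.DataFrame:
    """One RQ/SD/band row per sample, rounded for reporting."""
    config = config or RunConfig()
    rows = []
    for sample_id, ct in tables.items():
        res = quantify(ct, config)
        rq, sd = res.rounded(config.rq_precision)
        rows.append({"sample_id": sample_id, "rq": rq, "sd": sd, "band": res.band})
    return pd.DataFrame(rows)
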