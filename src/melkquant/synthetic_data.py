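"""Synthetic input generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and emits
data with the statistical structure the consuming stage assumes: clonal
cell populations with integer probe counts and symmetric miscount noise,
replicate Ct values around a true fold change, ordinal IHC intensity /
percent-positive draws differing by tissue class, piecewise-constant signal
tracks with rectangular peaks, and bivariate log2 CN / log2 expression with
a target within-subtype Pearson correlation plus subtype shifts.

One global seed expands into independent per-stage substreams salted by the
stage name, so adding or reordering stages never perturbs another stage's
draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fish_scoring import CellSignalCount, ClonePattern
from .expression_quant import CtTable
from .ihc_irs import IHCCore
from .io_core import GenomicRegion, ParameterError
from .epigenomics import SignalSegment

__all__ = [
    "ClonePattern", "IHCGroupModel", "DEFAULT_IHC_MODELS",
    "simulate_fish_population", "simulate_qpcr", "simulate_ihc_cohort",
    "simulate_signal_track", "simulate_cn_expression",
]


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-salted substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


# ---------------------------------------------------------------------------
# FISH cell populations
# ---------------------------------------------------------------------------

def simulate_fish_population(
    clones: Sequence[ClonePattern],
    n_cells: int,
    miscount_rate: float = 0.0,
    seed: int = 0,
) -> list[CellSignalCount]:
    """Draw per-cell probe counts from a clonal mixture with miscount noise.

    Each cell's clone is drawn by the clone fractions (which must sum to 1);
    with probability ``miscount_rate`` each probe count is independently
    perturbed by +/-1 (floored at 0), emulating spot over/under-counting.
    """
    clones = list(clones)
    if not clones:
        raise ParameterError("simulate_fish_population: empty clone list")
    fractions = np.array([c.fraction for c in clones], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ParameterError(
            f"simulate_fish_population: clone fractions sum to {fractions.sum()}, not 1"
        )
    if not 0.0 <= miscount_rate < 0.5:
        raise ParameterError("simulate_fish_population: miscount_rate must be in [0, 0.5)")
    if n_cells < 1:
        raise ParameterError("simulate_fish_population: n_cells must be positive")

    rng = _rng(seed, "fish")
    assignments = rng.choice(len(clones), size=n_cells, p=fractions)
    gene = np.array([clones[k].gene_copies for k in assignments], dtype=int)
    cep = np.array([clones[k].cep_copies for k in assignments], dtype=int)
    for counts in (gene, cep):
        hit = rng.random(n_cells) < miscount_rate
        shift = rng.choice([-1, 1], size=n_cells)
        counts += np.where(hit, shift, 0)
        np.maximum(counts, 0, out=counts)
    return [CellSignalCount(int(g), int(c)) for g, c in zip(gene, cep)]


# ---------------------------------------------------------------------------
# qPCR replicate tables
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_fold_change: float,
    base_ct: float = 20.0,
    replicate_sd: float = 0.05,
    n_reps: int = 4,
    seed: int = 0,
    target_offset: float = 3.0,
) -> CtTable:
    """Replicate Ct values whose ddCt recovers ``true_fold_change``.

    Reference Cts sit at ``base_ct``; target Cts at ``base_ct +
    target_offset``, with the sample's target shifted by -log2(fold change);
    Gaussian replicate noise of ``replicate_sd`` cycles is added everywhere.
    With zero noise the downstream RQ equals the fold change exactly.
    Quadruplicate reactions are the default design.
    """
    if not (math.isfinite(true_fold_change) and true_fold_change > 0):
        raise ParameterError("simulate_qpcr: fold change must be positive and finite")
    if replicate_sd < 0:
        raise ParameterError("simulate_qpcr: replicate_sd must be >= 0")
    if n_reps < 2:
        raise ParameterError("simulate_qpcr: need n_reps >= 2")
    rng = _rng(seed, "qpcr")

    def _cell(center: float) -> tuple[float, ...]:
        noise = rng.normal(0.0, replicate_sd, n_reps) if replicate_sd > 0 else np.zeros(n_reps)
        return tuple(float(center + e) for e in noise)

    shift = math.log2(true_fold_change)
    return CtTable(
        sample_target=_cell(base_ct + target_offset - shift),
        sample_reference=_cell(base_ct),
        calibrator_target=_cell(base_ct + target_offset),
        calibrator_reference=_cell(base_ct),
    )


# ---------------------------------------------------------------------------
# IHC cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IHCGroupModel:
    """Score-generating model for one tissue class.

    Nuclear intensity is drawn from ``nuclear_intensity_probs`` (grades
    0-3); nuclear percent-positive from a normal(percent_mean, percent_sd)
    rounded and clipped to integers 1-100 (0 whenever intensity is 0).
    Cytoplasmic staining is positive (IRS >= 4) with probability
    ``cyto_positive_p``; positive cores draw a moderate/strong intensity
    with >= 11% positivity, negative stained cores a weak pattern below the
    positivity threshold, and cytoplasmic staining never occurs without
    nuclear staining.
    """

    tissue_class: str
    nuclear_intensity_probs: tuple[float, float, float, float]
    percent_mean: float
    percent_sd: float
    cyto_positive_p: float

    def __post_init__(self) -> None:
        probs = np.array(self.nuclear_intensity_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError("nuclear_intensity_probs must be 4 nonnegative values summing to 1")
        if not 0.0 <= self.cyto_positive_p <= 1.0:
            raise ParameterError("cyto_positive_p must be in [0, 1]")
        if self.percent_sd < 0:
            raise ParameterError("percent_sd must be >= 0")


#: Default cohort conditions emulating the study tissue classes: nuclear
#: percent-positive mean +/- SD of 64.85 +/- 32.89 (benign), 69.0 +/- 41.34
#: (DCIS) and 87.18 +/- 24.6 (IDC), with cytoplasmic positivity rates
#: 1/33, 4/10 and 17/39 respectively.
DEFAULT_IHC_MODELS = (
    IHCGroupModel("benign", (0.05, 0.35, 0.45, 0.15), 64.85, 32.89, 1 / 33),
    IHCGroupModel("DCIS", (0.05, 0.25, 0.45, 0.25), 69.0, 41.34, 4 / 10),
    IHCGroupModel("IDC", (0.02, 0.18, 0.45, 0.35), 87.18, 24.6, 17 / 39),
)


def _draw_percent(rng: np.random.Generator, mean: float, sd: float) -> int:
    value = int(round(rng.normal(mean, sd))) if sd > 0 else int(round(mean))
    return int(min(100, max(1, value)))


def simulate_ihc_cohort(
    models: Sequence[IHCGroupModel],
    n_per_group: int,
    seed: int = 0,
) -> list[IHCCore]:
    """Draw scored tissue cores from per-class ordinal models."""
    models = list(models)
    if not models:
        raise ParameterError("simulate_ihc_cohort: empty model list")
    if n_per_group < 1:
        raise ParameterError("simulate_ihc_cohort: n_per_group must be >= 1")
    rng = _rng(seed, "ihc")
    cores: list[IHCCore] = []
    counter = 0
    for model in models:
        probs = np.asarray(model.nuclear_intensity_probs, dtype=float)
        stained = probs[1:] / probs[1:].sum() if probs[1:].sum() > 0 else None
        for _ in range(n_per_group):
            counter += 1
            cyto_positive = rng.random() < model.cyto_positive_p
            if cyto_positive and stained is not None:
                # cytoplasmic staining implies nuclear staining in this cohort
                nuc_int = 1 + int(rng.choice(3, p=stained))
            else:
                nuc_int = int(rng.choice(4, p=probs))
            nuc_pct = 0 if nuc_int == 0 else _draw_percent(rng, model.percent_mean,
                                                           model.percent_sd)
            if nuc_pct == 0 or not cyto_positive:
                # Negative cytoplasm: unstained, or weak staining below the
                # positivity threshold (combined <= 3).
                if nuc_pct > 0 and rng.random() < 0.3:
                    cyt_int, cyt_pct = 1, int(rng.integers(1, 51))  # score 1 or 2
                else:
                    cyt_int, cyt_pct = 0, 0
            else:
                cyt_int = int(rng.choice([2, 3]))
                cyt_pct = _draw_percent(rng, max(model.percent_mean - 20, 30.0),
                                        model.percent_sd / 2 if model.percent_sd else 0.0)
                cyt_pct = max(cyt_pct, 11)  # percent score >= 2 -> combined >= 4
            cores.append(IHCCore(
                core_id=f"core{counter:04d}", tissue_class=model.tissue_class,
                nuclear_intensity=nuc_int, nuclear_percent=nuc_pct,
                cytoplasmic_intensity=cyt_int, cytoplasmic_percent=cyt_pct,
            ))
    return cores


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def simulate_signal_track(
    region: GenomicRegion,
    peaks: Sequence[tuple[GenomicRegion, float]],
    bin_width: int = 25,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SignalSegment]:
    """Tile a region with constant-value bins carrying rectangular peaks.

    Breakpoints are placed at every peak boundary so bins never straddle a
    peak edge; each piece is subdivided into bins of width <= ``bin_width``.
    Inside peaks the value is the peak height plus truncated-at-zero
    Gaussian noise; outside it is truncated noise alone.
    """
    if bin_width < 1:
        raise ParameterError("simulate_signal_track: bin_width must be >= 1")
    if noise_sd < 0:
        raise ParameterError("simulate_signal_track: noise_sd must be >= 0")
    peaks = [(GenomicRegion(p.chrom, p.start, p.end), float(h)) for p, h in peaks]
    for p, h in peaks:
        if p.chrom != region.chrom or p.start < region.start or p.end > region.end:
            raise ParameterError(f"peak {p} outside region {region}")
        if h < 0:
            raise ParameterError("peak heights must be >= 0")
    ordered = sorted(peaks, key=lambda ph: ph[0].start)
    for (a, _), (b, _) in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ParameterError(f"overlapping peak intervals {a} and {b}")

    rng = _rng(seed, "track")
    breaks = sorted({region.start, region.end}
                    | {p.start for p, _ in ordered} | {p.end for p, _ in ordered})
    segments: list[SignalSegment] = []
    for lo, hi in zip(breaks, breaks[1:]):
        height = next((h for p, h in ordered if p.start <= lo and hi <= p.end), 0.0)
        pos = lo
        while pos < hi:
            end = min(pos + bin_width, hi)
            noise = abs(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            segments.append(SignalSegment(region.chrom, pos, end, max(height + noise, 0.0)))
            pos = end
    return segments


# ---------------------------------------------------------------------------
# Copy-number / expression tables
# ---------------------------------------------------------------------------

#: Default subtype conditions: basal-like tumors carry the copy-number gain
#: and the expression increase relative to the other subtypes.
DEFAULT_SUBTYPE_EFFECTS: dict[str, tuple[float, float]] = {
    "basal": (0.4, 1.0),
    "luminal_A": (0.0, 0.0),
    "luminal_B": (0.0, 0.3),
    "HER2": (0.1, 0.2),
}
DEFAULT_SUBTYPE_PROPORTIONS: dict[str, float] = {
    "basal": 0.3, "luminal_A": 0.4, "luminal_B": 0.2, "HER2": 0.1,
}


def simulate_cn_expression(
    n: int = 135,
    target_r: float = 0.5,
    subtype_effects: Mapping[str, tuple[float, float]] | None = None,
    proportions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample (subtype, log2 CN, log2 expression) with target correlation.

    Within each subtype, (log2_cn, log2_expr) is a standard bivariate normal
    with correlation ``target_r``; per-subtype (CN shift, expression shift)
    pairs are then added.  The default size (n = 135) and correlation
    (r = 0.5) mirror a cell-line-panel scale analysis.
    """
    if n < 10:
        raise ParameterError("simulate_cn_expression: need n >= 10")
    if not -1.0 < target_r < 1.0:
        raise ParameterError(f"simulate_cn_expression: target_r {target_r} outside (-1, 1)")
    effects = dict(subtype_effects if subtype_effects is not None else DEFAULT_SUBTYPE_EFFECTS)
    props = dict(proportions if proportions is not None else
                 {k: v for k, v in DEFAULT_SUBTYPE_PROPORTIONS.items() if k in effects})
    if set(props) != set(effects):
        raise ParameterError("simulate_cn_expression: proportions/effects subtype mismatch")
    weights = np.array([props[s] for s in effects], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ParameterError("simulate_cn_expression: proportions must be >= 0 and sum to 1")

    rng = _rng(seed, "cn_expression")
    labels = list(effects)
    assignment = rng.choice(len(labels), size=n, p=weights)
    cov = np.array([[1.0, target_r], [target_r, 1.0]])
    base = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    shifts = np.array([effects[labels[k]] for k in assignment])
    values = base + shifts
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "subtype": [labels[k] for k in assignment],
        "log2_cn": values[:, 0],
        "log2_expr": values[:, 1],
    })
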