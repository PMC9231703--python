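"""Dual-probe FISH copy-number summarization and interpretation.

Each scored nucleus carries an integer count of gene-probe spots (MELK) and
centromere-probe spots (CEP9).  The centromere probe distinguishes true gene
amplification from whole-chromosome-9 gain (polysomy): a mean gene-to-
centromere ratio >= 2.0 calls amplification, while balanced/unbalanced and
low/high polysomy are read off the most representative clone's integer
pattern.  Chromosome-9 rearrangements (structural alterations, "SA") are a
cytogenetic annotation supplied by the caller, never inferred from counts.

Classification rules and label wording reproduce the published cell-line
summary table; see ``docs/methods.md`` for the rendering conventions,
including the one mixed-level polysomy case printed without a level word.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .io_core import ParameterError, RunConfig, round_half_up


class CellSignalCount(NamedTuple):
    """Probe spot counts for one scored nucleus."""

    gene_signals: int
    cep_signals: int


@dataclass(frozen=True)
class ClonePattern:
    """A (gene, centromere) signal pattern and its population fraction."""

    gene_copies: int
    cep_copies: int
    fraction: float

    def __post_init__(self) -> None:
        if self.gene_copies < 0 or self.cep_copies < 0:
            raise ParameterError("clone copy numbers must be nonnegative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError(f"clone fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class FishSummary:
    """Aggregated per-sample FISH statistics (reported, i.e. rounded, scale).

    ``mean_gene``/``mean_cep``/``ratio`` are the reported values rounded
    half-up to the configured precision; the unrounded means are retained in
    ``raw_mean_gene``/``raw_mean_cep``.  ``major_clones`` ranks distinct
    signal patterns by observed frequency (ties broken by ascending pattern).
    """

    n_cells: int
    mean_gene: float
    mean_cep: float
    ratio: float
    major_clones: tuple[ClonePattern, ...]
    raw_mean_gene: float = field(repr=False, default=0.0)
    raw_mean_cep: float = field(repr=False, default=0.0)

    @property
    def top_clone(self) -> ClonePattern:
        return self.major_clones[0]


POLYSOMY_LEVELS = ("none", "disomy", "low", "high")
BALANCE_STATES = ("balanced", "unbalanced", "not_applicable")


@dataclass(frozen=True)
class FishCall:
    """Categorical interpretation of a :class:`FishSummary`.

    When ``amplified`` the polysomy fields describe the centromere (CEP9)
    status; otherwise they describe the gene pattern of the top major clone.
    ``label`` renders the call in the wording used for reporting.
    """

    amplified: bool
    polysomy_level: str
    balance: str
    cep_hemizygous_deletion: bool
    structural_alteration: bool
    label: str


def summarize_cells(
    cells: Iterable[CellSignalCount],
    precision: int = 1,
    ratio_from_rounded: bool = True,
) -> FishSummary:
    """Aggregate per-cell probe counts into means, ratio and clone ranking.

    The ratio is computed from the rounded reported means by default (the
    convention the published table follows); ``ratio_from_rounded=False``
    uses the unrounded means instead.
    """
    cells = [CellSignalCount(int(c[0]), int(c[1])) for c in cells]
    if not cells:
        raise ParameterError("summarize_cells: empty cell collection")
    if any(c.gene_signals < 0 or c.cep_signals < 0 for c in cells):
        raise ParameterError("summarize_cells: negative signal count")
    n = len(cells)
    raw_gene = sum(c.gene_signals for c in cells) / n
    raw_cep = sum(c.cep_signals for c in cells) / n
    if raw_cep == 0:
        raise ParameterError("summarize_cells: all CEP counts are zero; ratio undefined")
    mean_gene = round_half_up(raw_gene, precision)
    mean_cep = round_half_up(raw_cep, precision)
    num, den = (mean_gene, mean_cep) if ratio_from_rounded else (raw_gene, raw_cep)
    ratio = round_half_up(num / den, precision)

    counts = Counter(cells)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    clones = tuple(
        ClonePattern(pattern.gene_signals, pattern.cep_signals, count / n)
        for pattern, count in ranked
    )
    return FishSummary(
        n_cells=n, mean_gene=mean_gene, mean_cep=mean_cep, ratio=ratio,
        major_clones=clones, raw_mean_gene=raw_gene, raw_mean_cep=raw_cep,
    )


def _copy_level(copies: int, config: RunConfig) -> str:
    """Map an integer copy number to none/disomy/low/high."""
    if copies >= config.high_polysomy_min_copies:
        return "high"
    if copies == config.low_polysomy_copies:
        return "low"
    if copies == config.disomy_copies:
        return "disomy"
    return "none"


def _with_sa(core: str, sa: bool) -> str:
    if not sa:
        return core
    # Acronym-led labels keep their case after the "SA, " prefix.
    head = core if core.startswith(("CEP", "MELK")) else core[0].lower() + core[1:]
    return f"SA, {head}"


def classify_fish(
    summary: FishSummary,
    structural_alteration: bool = False,
    config: RunConfig | None = None,
) -> FishCall:
    """Interpret a FISH summary as amplification / polysomy / deletion.

    Amplification is called on the reported mean ratio (>= 2.0 by default);
    the centromere status is still reported alongside.  All other categories
    are decided from the top major clone's integer pattern: the gene count
    sets the level (2 disomy, 3 low polysomy, >= 4 high polysomy), equality
    of gene and centromere counts sets balance, and a single centromere
    signal with >= 2 gene signals is a CEP9 hemizygous deletion.
    """
    config = config or RunConfig()
    if not summary.major_clones:
        raise ParameterError("classify_fish: summary has no major clones")
    top = min(
        (c for c in summary.major_clones if c.fraction == summary.top_clone.fraction),
        key=lambda c: (c.gene_copies, c.cep_copies),
    )
    g, c = top.gene_copies, top.cep_copies
    if g == 0 and c == 0:
        raise ParameterError("classify_fish: major clone 0:0 is uninterpretable")
    sa = bool(structural_alteration)

    if summary.ratio >= config.amplification_ratio:
        cep_level = _copy_level(c, config)
        gene_level = _copy_level(g, config)
        ampl_word = "High ampl" if gene_level == "high" else "Ampl"
        cep_word = {
            "high": "CEP9 high polysomy", "low": "CEP9 low polysomy",
            "disomy": "CEP9 disomy", "none": "CEP9 loss",
        }[cep_level]
        return FishCall(
            amplified=True, polysomy_level=cep_level, balance="not_applicable",
            cep_hemizygous_deletion=(c == 1 and g >= 2), structural_alteration=sa,
            label=_with_sa(f"{ampl_word}; {cep_word}", sa),
        )

    if c == 1 and g >= 2:
        return FishCall(
            amplified=False, polysomy_level=_copy_level(g, config),
            balance="not_applicable", cep_hemizygous_deletion=True,
            structural_alteration=sa, label=_with_sa("CEP9 hemizygous deletion", sa),
        )

    level = _copy_level(g, config)
    balance = "balanced" if g == c else "unbalanced"
    if level == "none":
        core = "MELK loss" if g == 0 else "MELK monosomy"
    elif level == "disomy":
        core = "Disomy balanced" if balance == "balanced" else "Unbalanced disomy"
    else:
        cep_level = _copy_level(c, config)
        if cep_level != level and c - g >= 2:
            # Mixed-level polysomy (e.g. clone 3:5): rendered without a level word.
            core = f"{balance.capitalize()} polysomy"
        else:
            core = f"{level.capitalize()} {balance} polysomy"
    return FishCall(
        amplified=False, polysomy_level=level, balance=balance,
        cep_hemizygous_deletion=False, structural_alteration=sa,
        label=_with_sa(core, sa),
    )


def score_sample(
    cells: Iterable[CellSignalCount],
    structural_alteration: bool = False,
    config: RunConfig | None = None,
) -> tuple[FishSummary, FishCall]:
    """Summarize then classify one sample's cells."""
    config = config or RunConfig()
    summary = summarize_cells(
        cells, precision=config.fish_precision,
        ratio_from_rounded=config.ratio_from_rounded_means,
    )
    return summary, classify_fish(summary, structural_alteration, config)


def score_table(
    groups: Mapping[str, Iterable[CellSignalCount]],
    sa_flags: Mapping[str, bool] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every sample and lay the results out as one row per sample."""
    config = config or RunConfig()
    sa_flags = sa_flags or {}
    rows = []
    for sample_id, cells in groups.items():
        summary, call = score_sample(cells, sa_flags.get(sample_id, False), config)
        top = summary.top_clone
        rows.append({
            "sample_id": sample_id,
            "n_cells": summary.n_cells,
            "mean_gene": summary.mean_gene,
            "mean_cep": summary.mean_cep,
            "ratio": summary.ratio,
            "major_clone": f"{top.gene_copies}:{top.cep_copies}",
            "major_clone_percent": round_half_up(100 * top.fraction, 0),
            "interpretation": call.label,
        })
    return pd.DataFrame(rows)
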