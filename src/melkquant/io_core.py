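"""Tabular/genomic IO, run configuration, logging, and the command-line front end.

All genomic intervals are 0-based half-open internally (the bedGraph
convention).  Genome-browser style coordinates (1-based, inclusive, with
thousands separators, e.g. ``chr9:36,571,990-36,574,891``) are converted on
input when explicitly requested.

Reported means/ratios are rounded half-up (the convention used for the
printed summary tables), not banker's rounding; :func:`round_half_up` is the
single rounding primitive used throughout the package.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import re
import sys
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import click
import pandas as pd
import yaml

if TYPE_CHECKING:  # imported lazily at runtime to avoid module cycles
    from .epigenomics import SignalSegment
    from .expression_quant import CtTable
    from .fish_scoring import CellSignalCount
    from .ihc_irs import IHCCore

logger = logging.getLogger("melkquant")


def configure_logging(verbose: bool = False) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A malformed input file; the message names the offending row/line."""


class FormatError(PipelineError):
    """Structurally valid input violating a format invariant (e.g. overlaps)."""


class ParameterError(PipelineError, ValueError):
    """Invalid argument to an operation or generator."""


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    ``round(2.5)`` in Python is 2 (banker's rounding); summary tables in this
    field round 2.5 up, so 0.85 -> 0.9 at one decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Genomic region
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)[-–](?P<end>[\d,]+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ParameterError(f"region end ({self.end}) must exceed start ({self.start})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @classmethod
    def from_string(cls, text: str, one_based: bool = False) -> "GenomicRegion":
        """Parse ``chrom:start-end``; commas and en-dashes are tolerated.

        With ``one_based=True`` the coordinates are interpreted browser-style
        (1-based inclusive) and converted to 0-based half-open.
        """
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ParseError(f"cannot parse region {text!r}; expected chrom:start-end")
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", ""))
        if one_based:
            start -= 1
        return cls(m.group("chrom"), start, end)


#: The MELK promoter window quantified for histone-mark signal area,
#: hg19 chr9:36,571,990-36,574,891 in browser coordinates.
MELK_PROMOTER_REGION = GenomicRegion.from_string("chr9:36,571,990-36,574,891", one_based=True)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every classification threshold in the pipeline, with study defaults.

    Defaults reproduce the published cutoffs exactly: FISH amplification at a
    gene:centromere ratio of 2.0, low polysomy at 3 copies and high at >= 4,
    RQ expression bands at 50/20/1, IRS positivity at a combined score of 4,
    and the printed percent-positive bins.
    """

    # FISH
    amplification_ratio: float = 2.0
    disomy_copies: int = 2
    low_polysomy_copies: int = 3
    high_polysomy_min_copies: int = 4
    fish_precision: int = 1
    ratio_from_rounded_means: bool = True
    # qPCR / RQ
    rq_high_min: float = 50.0
    rq_moderate_min: float = 20.0
    rq_baseline_max: float = 1.0
    rq_precision: int = 2
    rq_sd_method: str = "replicate_rq"  # or "propagated"
    # IRS
    irs_positive_min: int = 4
    irs_low_max: int = 3
    irs_moderate_max: int = 8
    percent_bin_edges: tuple = (0, 10, 50, 80, 100)
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.amplification_ratio <= 0:
            raise ParameterError("amplification_ratio must be positive")
        if not (self.disomy_copies < self.low_polysomy_copies < self.high_polysomy_min_copies):
            raise ParameterError("FISH copy thresholds must be strictly increasing")
        if not (0 < self.rq_baseline_max < self.rq_moderate_min < self.rq_high_min):
            raise ParameterError("RQ band cutoffs must satisfy 0 < baseline < moderate < high")
        if not (0 < self.irs_low_max < self.irs_moderate_max <= 12):
            raise ParameterError("IRS band cutoffs out of order")
        if self.irs_positive_min != self.irs_low_max + 1:
            raise ParameterError("IRS positive threshold must sit directly above the low band")
        edges = tuple(self.percent_bin_edges)
        if edges[0] != 0 or edges[-1] != 100 or list(edges) != sorted(set(edges)):
            raise ParameterError("percent_bin_edges must increase from 0 to 100")
        if self.rq_sd_method not in ("replicate_rq", "propagated"):
            raise ParameterError(f"unknown rq_sd_method {self.rq_sd_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value YAML file; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ParseError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        if "percent_bin_edges" in raw:
            raw = dict(raw, percent_bin_edges=tuple(raw["percent_bin_edges"]))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["percent_bin_edges"] = list(data["percent_bin_edges"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ("sample_id", "cell_id", "gene_signals", "cep_signals")


def read_cell_counts(path: str | Path) -> dict[str, list["CellSignalCount"]]:
    """Read a per-nucleus probe-count TSV into per-sample cell lists.

    Expects columns sample_id, cell_id, gene_signals, cep_signals; counts must
    be nonnegative integers.  Grouping preserves file order; malformed rows
    raise :class:`ParseError` naming the row.
    """
    from .fish_scoring import CellSignalCount

    groups: dict[str, list[CellSignalCount]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_CELL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            counts = []
            for col in ("gene_signals", "cep_signals"):
                text = (row[col] or "").strip()
                try:
                    value = int(text)
                except ValueError:
                    raise ParseError(f"{path} row {rownum}: non-integer {col} {text!r}") from None
                if value < 0:
                    raise ParseError(f"{path} row {rownum}: negative {col} ({value})")
                counts.append(value)
            groups.setdefault(row["sample_id"].strip(), []).append(
                CellSignalCount(gene_signals=counts[0], cep_signals=counts[1])
            )
    return groups


def write_cell_counts(groups: Mapping[str, Iterable["CellSignalCount"]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CELL_COLUMNS)
        for sample_id, cells in groups.items():
            for i, cell in enumerate(cells, start=1):
                writer.writerow([sample_id, f"c{i}", cell.gene_signals, cell.cep_signals])


def read_bedgraph(path: str | Path) -> dict[str, list["SignalSegment"]]:
    """Read a 4-column bedGraph into per-chromosome sorted segment lists.

    Track-definition, browser and comment lines are skipped.  Segments on one
    chromosome must not overlap and values must be nonnegative.
    """
    from .epigenomics import SignalSegment

    per_chrom: dict[str, list[SignalSegment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path} line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, start_s, end_s, value_s = parts
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                raise ParseError(f"{path} line {lineno}: malformed coordinates/value") from None
            if end <= start:
                raise FormatError(f"{path} line {lineno}: end ({end}) <= start ({start})")
            if value < 0:
                raise FormatError(f"{path} line {lineno}: negative signal value {value}")
            per_chrom.setdefault(chrom, []).append(SignalSegment(chrom, start, end, value))
    for chrom, segments in per_chrom.items():
        segments.sort(key=lambda s: (s.start, s.end))
        for prev, cur in zip(segments, segments[1:]):
            if cur.start < prev.end:
                raise FormatError(
                    f"{path}: overlapping segments on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )
    return per_chrom


def write_bedgraph(per_chrom: Mapping[str, Iterable["SignalSegment"]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in per_chrom:
            for seg in per_chrom[chrom]:
                fh.write(f"{chrom}\t{seg.start}\t{seg.end}\t{seg.value:g}\n")


def read_ct_table(path: str | Path) -> dict[str, "CtTable"]:
    """Read a long-format qPCR Ct TSV into one :class:`CtTable` per sample.

    Columns: sample_id, condition (sample|calibrator), role (target|reference),
    replicate, ct.  Calibrator rows are shared across every sample in the file.
    """
    from .expression_quant import CtTable

    df = read_table(path, required=("sample_id", "condition", "role", "replicate", "ct"))
    bad_cond = set(df["condition"]) - {"sample", "calibrator"}
    if bad_cond:
        raise ParseError(f"{path}: unknown condition value(s) {sorted(bad_cond)}")
    bad_role = set(df["role"]) - {"target", "reference"}
    if bad_role:
        raise ParseError(f"{path}: unknown role value(s) {sorted(bad_role)}")

    def _cts(sub: pd.DataFrame) -> list[float]:
        return [float(v) for v in sub.sort_values("replicate")["ct"]]

    cal = df[df["condition"] == "calibrator"]
    if cal.empty:
        raise ParseError(f"{path}: no calibrator rows")
    cal_target = _cts(cal[cal["role"] == "target"])
    cal_reference = _cts(cal[cal["role"] == "reference"])

    tables: dict[str, CtTable] = {}
    samples = df[df["condition"] == "sample"]
    for sample_id, sub in samples.groupby("sample_id", sort=False):
        tables[str(sample_id)] = CtTable(
            sample_target=_cts(sub[sub["role"] == "target"]),
            sample_reference=_cts(sub[sub["role"] == "reference"]),
            calibrator_target=cal_target,
            calibrator_reference=cal_reference,
        )
    if not tables:
        raise ParseError(f"{path}: no sample rows")
    return tables


def read_ihc_table(path: str | Path) -> list["IHCCore"]:
    """Read a long-format IHC score TSV (one row per core x compartment)."""
    from .ihc_irs import IHCCore

    df = read_table(
        path, required=("core_id", "tissue_class", "compartment", "intensity", "percent_positive")
    )
    cores: list[IHCCore] = []
    for core_id, sub in df.groupby("core_id", sort=False):
        classes = set(sub["tissue_class"])
        if len(classes) != 1:
            raise ParseError(f"{path}: core {core_id} has conflicting tissue_class values")
        values = {}
        for _, row in sub.iterrows():
            comp = str(row["compartment"])
            if comp not in ("nuclear", "cytoplasmic"):
                raise ParseError(f"{path}: core {core_id}: unknown compartment {comp!r}")
            values[comp] = (int(row["intensity"]), row["percent_positive"])
        nuc = values.get("nuclear", (0, 0))
        cyt = values.get("cytoplasmic", (0, 0))
        cores.append(
            IHCCore(
                core_id=str(core_id),
                tissue_class=str(classes.pop()),
                nuclear_intensity=nuc[0],
                nuclear_percent=nuc[1],
                cytoplasmic_intensity=cyt[0],
                cytoplasmic_percent=cyt[1],
            )
        )
    return cores


SUBTYPES = ("basal", "luminal_A", "luminal_B", "HER2", "normal_like", "other")


def read_sample_records(path: str | Path) -> pd.DataFrame:
    """Read the per-sample subtype / log2 CN / log2 expression table."""
    df = read_table(path, required=("sample_id", "subtype", "log2_cn", "log2_expr"))
    bad = set(df["subtype"]) - set(SUBTYPES)
    if bad:
        raise ParseError(f"{path}: unknown subtype label(s) {sorted(bad)}")
    for col in ("log2_cn", "log2_expr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{path}: non-numeric or missing values in {col}")
        df[col] = vals.astype(float)
    return df


def read_beta_table(path: str | Path) -> pd.DataFrame:
    """Read a methylation beta-value TSV (sample_id, probe_id, beta, subtype)."""
    df = read_table(path, required=("sample_id", "probe_id", "beta", "subtype"))
    betas = pd.to_numeric(df["beta"], errors="coerce")
    if betas.isna().any() or (betas < 0).any() or (betas > 1).any():
        raise FormatError(f"{path}: beta values must be in [0, 1]")
    df["beta"] = betas.astype(float)
    return df


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------
# Analysis modules are imported inside each command so that importing io_core
# (which they depend on for config/rounding) stays cycle-free.

def _load_config(path: str | None) -> RunConfig:
    return RunConfig.from_yaml(path) if path else RunConfig()


@click.group()
@click.option("--verbose", is_flag=True, help="Debug logging to stderr.")
def main(verbose: bool) -> None:
    """MELK gene-dosage and expression quantification pipeline."""
    configure_logging(verbose)


@main.command("fish-score")
@click.option("--cells", "cells_path", required=True, type=click.Path(exists=True))
@click.option("--sa", "sa_path", type=click.Path(exists=True),
              help="Optional TSV (sample_id, structural_alteration) of cytogenetic SA flags.")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_fish_score(cells_path, sa_path, config_path, out_path) -> None:
    """Summarize and classify dual-probe FISH counts per sample."""
    from .fish_scoring import score_table

    config = _load_config(config_path)
    groups = read_cell_counts(cells_path)
    sa_flags: dict[str, bool] = {}
    if sa_path:
        sa_df = read_table(sa_path, required=("sample_id", "structural_alteration"))
        sa_flags = {
            str(r.sample_id): bool(int(r.structural_alteration)) for r in sa_df.itertuples()
        }
    logger.info("fish-score: %d samples from %s", len(groups), cells_path)
    write_table(score_table(groups, sa_flags, config), out_path)


@main.command("rq")
@click.option("--ct", "ct_path", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_rq(ct_path, config_path, out_path) -> None:
    """ddCt relative quantification with expression banding."""
    from .expression_quant import quantify_table

    config = _load_config(config_path)
    tables = read_ct_table(ct_path)
    logger.info("rq: %d samples from %s", len(tables), ct_path)
    write_table(quantify_table(tables, config), out_path)


@main.command("irs")
@click.option("--cores", "cores_path", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path(),
              help="Per-core IRS table output.")
@click.option("--summary-out", "summary_path", type=click.Path(),
              help="Optional per-tissue-class summary table output.")
def cli_irs(cores_path, config_path, out_path, summary_path) -> None:
    """ImmunoReactive Score per core, plus optional cohort summaries."""
    from .ihc_irs import cohort_summary, score_cores

    config = _load_config(config_path)
    cores = read_ihc_table(cores_path)
    logger.info("irs: %d cores from %s", len(cores), cores_path)
    write_table(score_cores(cores, config), out_path)
    if summary_path:
        parts = []
        for compartment in ("nuclear", "cytoplasmic"):
            summary = cohort_summary(cores, compartment, config)
            summary.insert(0, "compartment", compartment)
            parts.append(summary)
        write_table(pd.concat(parts, ignore_index=True), summary_path)


@main.command("peak-area")
@click.option("--track", "track_path", required=True, type=click.Path(exists=True))
@click.option("--region", "region_text", default=None,
              help="chrom:start-end; default is the MELK promoter window.")
@click.option("--browser-coords", is_flag=True,
              help="Interpret --region as 1-based inclusive browser coordinates.")
@click.option("--sample-id", default=None, help="Label for the output row.")
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_peak_area(track_path, region_text, browser_coords, sample_id, out_path) -> None:
    """Total signal area (width x height) of a track within a region."""
    from .epigenomics import peak_area

    if region_text:
        region = GenomicRegion.from_string(region_text, one_based=browser_coords)
    else:
        region = MELK_PROMOTER_REGION
    per_chrom = read_bedgraph(track_path)
    track = per_chrom.get(region.chrom, [])
    area = peak_area(track, region)
    logger.info("peak-area: %s %s:%d-%d area=%g", track_path, region.chrom, region.start,
                region.end, area)
    write_table(
        pd.DataFrame(
            [{
                "sample_id": sample_id or Path(track_path).stem,
                "chrom": region.chrom, "start": region.start, "end": region.end,
                "area": area,
            }]
        ),
        out_path,
    )


@main.command("correlate")
@click.option("--samples", "samples_path", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_correlate(samples_path, config_path, out_path) -> None:
    """Copy-number/expression correlation and subtype comparison report."""
    from .integration_stats import cn_expression_report

    _load_config(config_path)
    records = read_sample_records(samples_path)
    report = cn_expression_report(records)
    logger.info("correlate: n=%d overall r=%.3f", len(records), report["overall"]["r"])
    write_json(report, out_path)


@main.command("compare-groups")
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--value-col", default="value", show_default=True)
@click.option("--group-col", default="group", show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_compare_groups(table_path, value_col, group_col, out_path) -> None:
    """Kruskal-Wallis across groups plus Holm-adjusted pairwise rank-sum tests."""
    from itertools import combinations

    from .integration_stats import PAIRWISE_NOTE, holm_adjust, kruskal_wallis, wilcoxon_rank_sum

    df = read_table(table_path, required=(value_col, group_col))
    labels = list(dict.fromkeys(df[group_col]))
    groups = [df.loc[df[group_col] == g, value_col].astype(float).tolist() for g in labels]
    kw = kruskal_wallis(groups)
    pairs = list(combinations(range(len(labels)), 2))
    raw = [wilcoxon_rank_sum(groups[i], groups[j]).p_value for i, j in pairs]
    adj = holm_adjust(raw)
    report = {
        "note": PAIRWISE_NOTE,
        "kruskal_wallis": {"H": kw.statistic, "p": kw.p_value, "n": kw.n},
        "pairwise": [
            {"a": labels[i], "b": labels[j], "p": p, "p_holm": q}
            for (i, j), p, q in zip(pairs, raw, adj)
        ],
    }
    write_json(report, out_path)


@main.group("simulate")
def cli_simulate() -> None:
    """Synthetic-data generators emulating each pipeline input."""


@cli_simulate.command("fish")
@click.option("--clones", default="2:2:1.0", show_default=True,
              help="Comma-separated gene:cep:fraction triples.")
@click.option("--n-cells", default=100, show_default=True)
@click.option("--miscount-rate", default=0.05, show_default=True)
@click.option("--sample-id", default="S1", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_simulate_fish(clones, n_cells, miscount_rate, sample_id, seed, out_path) -> None:
    from .synthetic_data import ClonePattern, simulate_fish_population

    parsed = []
    for triple in clones.split(","):
        g, c, f = triple.split(":")
        parsed.append(ClonePattern(int(g), int(c), float(f)))
    logger.info("simulate fish: clones=%s n=%d miscount=%g seed=%d",
                clones, n_cells, miscount_rate, seed)
    cells = simulate_fish_population(parsed, n_cells, miscount_rate, seed)
    write_cell_counts({sample_id: cells}, out_path)


@cli_simulate.command("qpcr")
@click.option("--fold-change", default=50.0, show_default=True)
@click.option("--base-ct", default=20.0, show_default=True)
@click.option("--replicate-sd", default=0.05, show_default=True)
@click.option("--n-reps", default=4, show_default=True)
@click.option("--sample-id", default="S1", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_simulate_qpcr(fold_change, base_ct, replicate_sd, n_reps, sample_id, seed,
                      out_path) -> None:
    from .synthetic_data import simulate_qpcr

    ct = simulate_qpcr(fold_change, base_ct, replicate_sd, n_reps, seed)
    rows = []
    for condition, role, values in (
        ("sample", "target", ct.sample_target),
        ("sample", "reference", ct.sample_reference),
        ("calibrator", "target", ct.calibrator_target),
        ("calibrator", "reference", ct.calibrator_reference),
    ):
        sid = sample_id if condition == "sample" else "calibrator"
        for i, v in enumerate(values, start=1):
            rows.append({"sample_id": sid, "condition": condition, "role": role,
                         "replicate": i, "ct": repr(v)})
    logger.info("simulate qpcr: fold=%g sd=%g reps=%d seed=%d",
                fold_change, replicate_sd, n_reps, seed)
    write_table(pd.DataFrame(rows), out_path)


@cli_simulate.command("ihc")
@click.option("--n-per-group", default=40, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_simulate_ihc(n_per_group, seed, out_path) -> None:
    from .synthetic_data import DEFAULT_IHC_MODELS, simulate_ihc_cohort

    cores = simulate_ihc_cohort(DEFAULT_IHC_MODELS, n_per_group, seed)
    rows = []
    for core in cores:
        for comp, inten, pct in (
            ("nuclear", core.nuclear_intensity, core.nuclear_percent),
            ("cytoplasmic", core.cytoplasmic_intensity, core.cytoplasmic_percent),
        ):
            rows.append({"core_id": core.core_id, "tissue_class": core.tissue_class,
                         "compartment": comp, "intensity": inten, "percent_positive": pct})
    logger.info("simulate ihc: n_per_group=%d seed=%d", n_per_group, seed)
    write_table(pd.DataFrame(rows), out_path)


@cli_simulate.command("track")
@click.option("--region", "region_text", default="chr9:36571989-36574891", show_default=True,
              help="0-based half-open unless --browser-coords is given.")
@click.option("--browser-coords", is_flag=True)
@click.option("--peaks", default="36572500-36573500:8.0", show_default=True,
              help="Comma-separated start-end:height peak specs (same coordinate style).")
@click.option("--bin-width", default=25, show_default=True)
@click.option("--noise-sd", default=0.5, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_simulate_track(region_text, browser_coords, peaks, bin_width, noise_sd, seed,
                       out_path) -> None:
    from .synthetic_data import simulate_signal_track

    region = GenomicRegion.from_string(region_text, one_based=browser_coords)
    parsed = []
    for spec in peaks.split(","):
        coords, height = spec.rsplit(":", 1)
        start_s, end_s = coords.split("-")
        start, end = int(start_s), int(end_s)
        if browser_coords:
            start -= 1
        parsed.append((GenomicRegion(region.chrom, start, end), float(height)))
    segments = simulate_signal_track(region, parsed, bin_width, noise_sd, seed)
    logger.info("simulate track: %d segments seed=%d", len(segments), seed)
    write_bedgraph({region.chrom: segments}, out_path)


@cli_simulate.command("cn-expr")
@click.option("--n", default=135, show_default=True)
@click.option("--target-r", default=0.5, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cli_simulate_cn_expr(n, target_r, seed, out_path) -> None:
    from .synthetic_data import simulate_cn_expression

    df = simulate_cn_expression(n=n, target_r=target_r, seed=seed)
    logger.info("simulate cn-expr: n=%d target_r=%g seed=%d", n, target_r, seed)
    write_table(df.round(6), out_path)


if __name__ == "__main__":  # pragma: no cover
    main()
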