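"""Statistical tests for copy-number/expression integration.

The tests are implemented here directly — rank assignment, tie corrections,
the Holm step-down — so that their behavior is itself under test; scipy
supplies only the reference distributions (Student t, chi-square, standard
normal) used to convert statistics to p-values, and midranks via
``scipy.stats.rankdata``.

Pairwise ordinal group comparisons use the two-sided Wilcoxon rank-sum test
with Holm adjustment (a deliberate stand-in for cumulative link mixed
models; see :data:`PAIRWISE_NOTE`).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _t

from .io_core import ParameterError

PAIRWISE_NOTE = (
    "Pairwise group comparisons use two-sided Wilcoxon rank-sum tests with "
    "Holm step-down adjustment (in place of cumulative link mixed models)."
)


@dataclass(frozen=True)
class TestResult:
    """A named statistic with its two-sided p-value and sample size."""

    name: str
    statistic: float
    p_value: float
    n: int
    ties_corrected: bool = False
    extra: dict = field(default_factory=dict)


def _as_float_array(values, label: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{label}: expected a 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{label}: values must be finite")
    return arr


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if len(x) != len(y):
        raise ParameterError(f"pearson_r: length mismatch ({len(x)} vs {len(y)})")
    n = len(x)
    if n < 3:
        raise ParameterError("pearson_r: need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0:
        raise ParameterError("pearson_r: x has zero variance")
    if ssy == 0.0:
        raise ParameterError("pearson_r: y has zero variance")
    r = float(np.clip(xc @ yc / math.sqrt(ssx * ssy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_t.sf(abs(t_stat), n - 2))
    return TestResult("pearson_r", r, min(p, 1.0), n, extra={"df": n - 2})


# ---------------------------------------------------------------------------
# Kendall's tau-b
# ---------------------------------------------------------------------------

def _tie_sizes(values: np.ndarray) -> list[int]:
    return [c for c in Counter(values.tolist()).values() if c > 1]


def kendall_tau_b(x, y) -> TestResult:
    """Kendall's tau-b with tie correction; p by the normal approximation.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D count concordant
    and discordant pairs, n0 = n(n-1)/2, and n1/n2 are the within-x and
    within-y tie pair counts.  The variance of C - D under the null uses the
    standard tie-adjusted expansion.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if len(x) != len(y):
        raise ParameterError(f"kendall_tau_b: length mismatch ({len(x)} vs {len(y)})")
    n = len(x)
    if n < 2:
        raise ParameterError("kendall_tau_b: need n >= 2")
    if np.all(x == x[0]):
        raise ParameterError("kendall_tau_b: all x values tied; tau undefined")
    if np.all(y == y[0]):
        raise ParameterError("kendall_tau_b: all y values tied; tau undefined")

    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[i] - x[j])
    sy = np.sign(y[i] - y[j])
    prod = sx * sy
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    s = concordant - discordant

    n0 = n * (n - 1) // 2
    xt = _tie_sizes(x)
    yt = _tie_sizes(y)
    n1 = sum(t * (t - 1) // 2 for t in xt)
    n2 = sum(t * (t - 1) // 2 for t in yt)
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))

    # tie-adjusted null variance of S (C - D)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in xt)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in yt)
    v1 = (sum(t * (t - 1) for t in xt) * sum(u * (u - 1) for u in yt)) / (2.0 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = (
            sum(t * (t - 1) * (t - 2) for t in xt)
            * sum(u * (u - 1) * (u - 2) for u in yt)
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        p = 1.0
    else:
        z = s / math.sqrt(var_s)
        p = min(1.0, 2.0 * float(_norm.sf(abs(z))))
    return TestResult("kendall_tau_b", tau, p, n,
                      ties_corrected=bool(n1 or n2), extra={"S": s})


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of t^3 - t on the pooled sample."""
    return float(sum(t**3 - t for t in _tie_sizes(pooled)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value.

    When every pooled observation is tied the tie-correction denominator
    vanishes; by convention H = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ParameterError("kruskal_wallis: need >= 2 groups")
    arrays = []
    for g, values in enumerate(groups):
        arr = _as_float_array(values, f"group {g}")
        if len(arr) == 0:
            raise ParameterError(f"kruskal_wallis: group {g} is empty")
        arrays.append(arr)
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    if n_total < 3:
        raise ParameterError("kruskal_wallis: need total n >= 3")
    ranks = rankdata(pooled)
    h = 0.0
    offset = 0
    for arr in arrays:
        r = ranks[offset:offset + len(arr)]
        h += r.sum() ** 2 / len(arr)
        offset += len(arr)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    tie_term = _tie_term(pooled)
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    ties = tie_term > 0
    if correction <= 0.0:  # all observations identical
        return TestResult("kruskal_wallis", 0.0, 1.0, n_total, ties_corrected=True,
                          extra={"df": len(groups) - 1})
    h /= correction
    h = max(h, 0.0)
    df = len(groups) - 1
    p = float(_chi2.sf(h, df))
    return TestResult("kruskal_wallis", h, p, n_total, ties_corrected=ties, extra={"df": df})


#: Total sample size up to which the exact permutation distribution is
#: enumerated by default (C(16, 8) = 12870 assignments at worst).
_EXACT_LIMIT = 16


def wilcoxon_rank_sum(a, b, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on two samples.

    ``method="auto"`` (default) enumerates the exact permutation
    distribution of the rank sum (on midranks, so ties are handled) when the
    total sample size is at most 16, and otherwise uses the tie-corrected
    normal approximation with a 0.5 continuity correction.  ``"exact"`` and
    ``"normal"`` force either route (exact is limited to total n <= 24).
    """
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("wilcoxon_rank_sum: both samples must be nonempty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    ties = _tie_term(pooled) > 0

    if method == "auto":
        method = "exact" if n <= _EXACT_LIMIT else "normal"
    if method == "exact":
        if n > 24:
            raise ParameterError("wilcoxon_rank_sum: exact method limited to total n <= 24")
        observed_dev = abs(w - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= observed_dev - 1e-9:
                count += 1
        return TestResult("wilcoxon_rank_sum", w, count / total, n,
                          ties_corrected=ties, extra={"method": "exact"})
    if method != "normal":
        raise ParameterError(f"unknown method {method!r}")

    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return TestResult("wilcoxon_rank_sum", w, 1.0, n, ties_corrected=True,
                          extra={"method": "normal", "z": 0.0})
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_norm.sf(z)))
    return TestResult("wilcoxon_rank_sum", w, p, n, ties_corrected=ties,
                      extra={"method": "normal", "z": z})


def two_sample_t(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t test, two-sided."""
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("two_sample_t: need n >= 2 in each sample")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ParameterError("two_sample_t: zero variance in both samples")
    sa, sb = va / len(a), vb / len(b)
    se = math.sqrt(sa + sb)
    t_stat = (float(a.mean()) - float(b.mean())) / se
    df = (sa + sb) ** 2 / (
        (sa**2 / (len(a) - 1) if sa else 0.0) + (sb**2 / (len(b) - 1) if sb else 0.0)
    )
    p = min(1.0, 2.0 * float(_t.sf(abs(t_stat), df)))
    return TestResult("two_sample_t", t_stat, p, len(a) + len(b), extra={"df": df})


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order.

    Sorted ascending, the i-th (1-based) p is multiplied by m - i + 1, a
    running maximum enforces monotonicity, and values are capped at 1.
    """
    p = list(p_values)
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ParameterError("holm_adjust: p-values must lie in [0, 1]")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def cn_expression_report(records: pd.DataFrame, reference_subtype: str = "basal") -> dict:
    """Pooled CN/expression correlation plus subtype comparisons.

    Input needs columns subtype, log2_cn, log2_expr.  Reports the pooled
    Pearson correlation, a Kruskal-Wallis test of each variable across
    subtypes, and Holm-adjusted pairwise rank-sum tests of the reference
    subtype (basal by default) against every other subtype.
    """
    required = {"subtype", "log2_cn", "log2_expr"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"cn_expression_report: missing column(s) {sorted(missing)}")
    subtypes = list(dict.fromkeys(records["subtype"]))
    if len(subtypes) < 2:
        raise ParameterError("cn_expression_report: need >= 2 subtypes")

    overall = pearson_r(records["log2_cn"], records["log2_expr"])
    report: dict = {
        "note": PAIRWISE_NOTE,
        "overall": {"r": overall.statistic, "p": overall.p_value, "n": overall.n},
        "group_tests": {},
        "pairwise": {},
    }
    others = [s for s in subtypes if s != reference_subtype]
    if not others or len(others) == len(subtypes):
        raise ParameterError(
            f"cn_expression_report: reference subtype {reference_subtype!r} absent"
        )
    for var in ("log2_cn", "log2_expr"):
        groups = [records.loc[records["subtype"] == s, var].tolist() for s in subtypes]
        kw = kruskal_wallis(groups)
        report["group_tests"][var] = {"H": kw.statistic, "p": kw.p_value, "df": kw.extra["df"]}
        ref = records.loc[records["subtype"] == reference_subtype, var].tolist()
        raw = [
            wilcoxon_rank_sum(ref, records.loc[records["subtype"] == s, var].tolist()).p_value
            for s in others
        ]
        adj = holm_adjust(raw)
        report["pairwise"][var] = [
            {"reference": reference_subtype, "other": s, "p": p, "p_holm": q}
            for s, p, q in zip(others, raw, adj)
        ]
    return report
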