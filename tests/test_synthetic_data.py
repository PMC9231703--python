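"""Generators: determinism, parameter recovery, and consuming-stage contracts."""

import collections

import numpy as np
import pytest

from melkquant import (
    CellSignalCount,
    ClonePattern,
    GenomicRegion,
    IHCGroupModel,
    ParameterError,
    classify_rq,
    delta_delta_ct,
    irs,
    peak_area,
    pearson_r,
    simulate_cn_expression,
    simulate_fish_population,
    simulate_ihc_cohort,
    simulate_qpcr,
    simulate_signal_track,
)
from melkquant.synthetic_data import DEFAULT_IHC_MODELS


# ---------------------------------------------------------------------------
# FISH populations
# ---------------------------------------------------------------------------

def test_single_clone_no_noise_is_pure():
    cells = simulate_fish_population([ClonePattern(2, 2, 1.0)], 100, 0.0, seed=3)
    assert cells == [CellSignalCount(2, 2)] * 100


def test_modal_clone_frequency_recovered():
    clones = [ClonePattern(3, 4, 0.8), ClonePattern(2, 2, 0.2)]
    cells = simulate_fish_population(clones, 10000, 0.0, seed=42)
    freq = collections.Counter(cells)
    modal, count = freq.most_common(1)[0]
    assert modal == CellSignalCount(3, 4)
    assert abs(count / 10000 - 0.8) < 0.02


def test_seed_determinism_and_stream_independence():
    clones = [ClonePattern(3, 3, 0.5), ClonePattern(2, 2, 0.5)]
    assert simulate_fish_population(clones, 500, 0.1, seed=42) == \
        simulate_fish_population(clones, 500, 0.1, seed=42)
    assert simulate_fish_population(clones, 500, 0.1, seed=42) != \
        simulate_fish_population(clones, 500, 0.1, seed=43)


def test_miscount_noise_perturbs_by_at_most_one():
    cells = simulate_fish_population([ClonePattern(3, 3, 1.0)], 2000, 0.3, seed=0)
    genes = {c.gene_signals for c in cells}
    assert genes <= {2, 3, 4}
    assert len(genes) > 1  # noise actually fired
    assert min(c.cep_signals for c in cells) >= 0


def test_fish_parameter_errors():
    with pytest.raises(ParameterError):
        simulate_fish_population([], 10)
    with pytest.raises(ParameterError):
        simulate_fish_population([ClonePattern(2, 2, 0.5)], 10)  # fractions != 1
    with pytest.raises(ParameterError):
        simulate_fish_population([ClonePattern(2, 2, 1.0)], 10, miscount_rate=0.5)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def test_null_fold_change_recovers_unity_exactly():
    ct = simulate_qpcr(1.0, replicate_sd=0.0, n_reps=4, seed=0)
    res = delta_delta_ct(ct)
    assert res.rq == 1.0 and res.delta_delta_ct == 0.0


def test_noisy_fold_change_recovered_within_ten_percent():
    ct = simulate_qpcr(50.0, replicate_sd=0.05, n_reps=4, seed=9)
    assert 45.0 <= delta_delta_ct(ct).rq <= 55.0


def test_published_value_recovered_noise_free():
    ct = simulate_qpcr(381.55, replicate_sd=0.0, n_reps=4, seed=0)
    res = delta_delta_ct(ct)
    assert res.rq == pytest.approx(381.55, rel=1e-12)
    assert classify_rq(res.rq) == "high"


def test_qpcr_parameter_errors():
    with pytest.raises(ParameterError):
        simulate_qpcr(0.0)
    with pytest.raises(ParameterError):
        simulate_qpcr(2.0, replicate_sd=-0.1)
    with pytest.raises(ParameterError):
        simulate_qpcr(2.0, n_reps=1)


# ---------------------------------------------------------------------------
# IHC cohorts
# ---------------------------------------------------------------------------

def test_all_negative_model_yields_zero_scores():
    model = IHCGroupModel("benign", (1.0, 0.0, 0.0, 0.0), 50.0, 10.0, 0.0)
    cores = simulate_ihc_cohort([model], 50, seed=2)
    assert all(c.result("nuclear").combined == 0 for c in cores)
    assert all(c.result("cytoplasmic").combined == 0 for c in cores)


def test_cytoplasmic_positivity_rates_recovered():
    """Empirical positivity tracks the class rates (1/33 benign vs 17/39 IDC)."""
    cores = simulate_ihc_cohort(DEFAULT_IHC_MODELS, 10000, seed=8)
    by_class = collections.defaultdict(list)
    for core in cores:
        by_class[core.tissue_class].append(core.result("cytoplasmic").positive)
    assert abs(np.mean(by_class["benign"]) - 1 / 33) < 0.02
    assert abs(np.mean(by_class["IDC"]) - 17 / 39) < 0.02
    assert abs(np.mean(by_class["DCIS"]) - 4 / 10) < 0.02


def test_generated_cores_satisfy_scoring_invariants():
    for core in simulate_ihc_cohort(DEFAULT_IHC_MODELS, 300, seed=1):
        # IHCCore validates on construction; exercise the IRS path too
        irs(core.nuclear_intensity, core.nuclear_percent)
        irs(core.cytoplasmic_intensity, core.cytoplasmic_percent)
        if core.cytoplasmic_percent > 0:
            assert core.nuclear_percent > 0


def test_ihc_determinism_and_errors():
    a = simulate_ihc_cohort(DEFAULT_IHC_MODELS, 20, seed=5)
    b = simulate_ihc_cohort(DEFAULT_IHC_MODELS, 20, seed=5)
    assert a == b
    with pytest.raises(ParameterError):
        simulate_ihc_cohort([], 10)
    with pytest.raises(ParameterError):
        IHCGroupModel("benign", (0.5, 0.5, 0.5, 0.0), 50, 10, 0.1)


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def test_single_rectangle_area_exact():
    region = GenomicRegion("chr9", 0, 1000)
    peak = (GenomicRegion("chr9", 200, 500), 8.0)
    track = simulate_signal_track(region, [peak], bin_width=1, noise_sd=0.0, seed=0)
    assert peak_area(track, region) == pytest.approx(8.0 * 300, rel=1e-12)


def test_no_peaks_no_noise_is_flat_zero():
    region = GenomicRegion("chr9", 0, 500)
    track = simulate_signal_track(region, [], bin_width=50, noise_sd=0.0, seed=0)
    assert peak_area(track, region) == 0.0


def test_two_disjoint_peaks_areas_add():
    region = GenomicRegion("chr9", 0, 1000)
    p1 = (GenomicRegion("chr9", 100, 300), 5.0)
    p2 = (GenomicRegion("chr9", 600, 650), 2.0)
    both = simulate_signal_track(region, [p1, p2], bin_width=37, noise_sd=0.0, seed=0)
    assert peak_area(both, region) == pytest.approx(5.0 * 200 + 2.0 * 50, rel=1e-12)


def test_track_bins_tile_region_without_overlap():
    region = GenomicRegion("chr9", 10, 473)
    peak = (GenomicRegion("chr9", 100, 217), 4.0)
    track = simulate_signal_track(region, [peak], bin_width=25, noise_sd=0.3, seed=7)
    assert track[0].start == region.start and track[-1].end == region.end
    for prev, cur in zip(track, track[1:]):
        assert cur.start == prev.end
    assert all(seg.end - seg.start <= 25 for seg in track)
    assert all(seg.value >= 0 for seg in track)


def test_overlapping_peaks_rejected():
    region = GenomicRegion("chr9", 0, 1000)
    with pytest.raises(ParameterError):
        simulate_signal_track(region, [(GenomicRegion("chr9", 100, 300), 5.0),
                                       (GenomicRegion("chr9", 200, 400), 2.0)])
    with pytest.raises(ParameterError):
        simulate_signal_track(region, [(GenomicRegion("chr9", 900, 1100), 5.0)])


# ---------------------------------------------------------------------------
# CN / expression
# ---------------------------------------------------------------------------

def test_within_subtype_correlation_recovered():
    df = simulate_cn_expression(n=2000, target_r=0.5, seed=1,
                                subtype_effects={"other": (0.0, 0.0)},
                                proportions={"other": 1.0})
    r = pearson_r(df["log2_cn"], df["log2_expr"]).statistic
    assert 0.45 <= r <= 0.55


def test_null_correlation_near_zero():
    df = simulate_cn_expression(n=10000, target_r=0.0, seed=2,
                                subtype_effects={"other": (0.0, 0.0)},
                                proportions={"other": 1.0})
    assert abs(pearson_r(df["log2_cn"], df["log2_expr"]).statistic) < 0.05


def test_single_subtype_zero_shift_marginals_centered():
    df = simulate_cn_expression(n=5000, target_r=0.3, seed=3,
                                subtype_effects={"other": (0.0, 0.0)},
                                proportions={"other": 1.0})
    assert abs(df["log2_cn"].mean()) < 0.05
    assert abs(df["log2_expr"].mean()) < 0.05


def test_subtype_shifts_applied():
    df = simulate_cn_expression(n=4000, target_r=0.5, seed=4)
    means = df.groupby("subtype")["log2_expr"].mean()
    assert means["basal"] > means["luminal_A"] + 0.5


def test_cn_expression_parameter_errors_and_determinism():
    with pytest.raises(ParameterError):
        simulate_cn_expression(n=5)
    with pytest.raises(ParameterError):
        simulate_cn_expression(n=100, target_r=1.0)
    with pytest.raises(ParameterError):
        simulate_cn_expression(n=100, proportions={"basal": 1.0})
    a = simulate_cn_expression(n=50, seed=11)
    b = simulate_cn_expression(n=50, seed=11)
    assert a.equals(b)
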