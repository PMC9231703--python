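"""Shared fixtures: published cell-line summary rows and population builders."""

from __future__ import annotations

import hypothesis
import pytest

from melkquant import CellSignalCount

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("suite")


def build_population(mean_gene, mean_cep, clones=(), n=100):
    """Construct an integer cell population with exact target means.

    ``clones`` is a list of (gene, cep, fraction) patterns assigned first;
    the remaining cells absorb the leftover totals as evenly as possible so
    that the population's means equal ``mean_gene``/``mean_cep`` exactly
    (targets x n must be integral).
    """
    total_g, total_c = round(mean_gene * n), round(mean_cep * n)
    assert abs(total_g - mean_gene * n) < 1e-9 and abs(total_c - mean_cep * n) < 1e-9
    cells: list[tuple[int, int]] = []
    for g, c, fraction in clones:
        cells.extend([(g, c)] * round(fraction * n))
    rem = n - len(cells)
    rg = total_g - sum(g for g, _ in cells)
    rc = total_c - sum(c for _, c in cells)
    assert rem >= 0 and rg >= 0 and rc >= 0
    if rem:
        base_g, extra_g = divmod(rg, rem)
        base_c, extra_c = divmod(rc, rem)
        for i in range(rem):
            cells.append((base_g + (1 if i < extra_g else 0),
                          base_c + (1 if i < extra_c else 0)))
    return [CellSignalCount(g, c) for g, c in cells]


# Published per-cell-line FISH summary rows: printed means, ratio (1 dp), the
# most representative clone(s), the structural-alteration annotation, and the
# printed interpretation.  The SKBR3 row is excluded (its printed ratio is
# inconsistent with its printed means) as is the hybridization control.
TABLE1_FISH = [
    # (cell_line, mean_gene, mean_cep, ratio, clones[(g, c, fraction)...], sa, interpretation)
    ("HCC70", 8.9, 10.6, 0.8, [(9, 10, 0.55)], False, "High unbalanced polysomy"),
    ("BT549", 6.4, 7.7, 0.8, [(6, 8, 0.19), (8, 9, 0.15)], False, "High unbalanced polysomy"),
    ("UACC3199", 4.0, 4.0, 1.0, [(4, 4, 0.65)], False, "High balanced polysomy"),
    ("HCC1187", 3.0, 2.9, 1.0, [(3, 3, 0.90)], False, "Low balanced polysomy"),
    ("MDAMB231", 3.2, 3.1, 1.0, [(3, 3, 0.85)], False, "Low balanced polysomy"),
    ("HCC1954", 3.1, 3.8, 0.8, [(3, 4, 0.80)], False, "Low unbalanced polysomy"),
    ("BT20", 2.0, 3.0, 0.7, [(2, 3, 0.82)], True, "SA, unbalanced disomy"),
    ("HCC1937", 3.8, 3.8, 1.0, [(4, 4, 0.63)], False, "High balanced polysomy"),
    ("HCC1500", 2.0, 2.1, 1.0, [(2, 2, 0.80)], False, "Disomy balanced"),
    ("HCC1428", 3.8, 3.8, 1.0, [(4, 4, 0.73)], False, "High balanced polysomy"),
    ("T47D", 2.0, 1.2, 1.7, [(2, 1, 0.77)], True, "SA, CEP9 hemizygous deletion"),
    ("MCF7", 3.0, 3.0, 1.0, [(3, 3, 0.80)], False, "Low balanced polysomy"),
    ("ZR7530", 3.0, 3.0, 1.0, [(3, 3, 0.88)], False, "Low balanced polysomy"),
    ("HCC2185", 29.1, 5.3, 5.5, [], False, "High ampl; CEP9 high polysomy"),
    ("HCC202", 3.0, 5.1, 0.6, [(3, 5, 0.58)], False, "Unbalanced polysomy"),
]

# Published RQ values with their expression band.
TABLE1_RQ = [
    ("HCC70", 381.55, "high"),
    ("UACC3199", 86.04, "high"),
    ("HCC1187", 57.38, "high"),
    ("MDAMB231", 44.18, "moderate"),
    ("HCC1954", 41.29, "moderate"),
    ("BT20", 38.36, "moderate"),
    ("HCC1937", 34.51, "moderate"),
    ("HCC1500", 29.11, "moderate"),
    ("HCC1428", 50.78, "high"),
    ("T47D", 27.43, "moderate"),
    ("MCF7", 12.90, "low"),
    ("ZR7530", 19.05, "low"),
    ("HCC2185", 265.44, "high"),
    ("HCC202", 28.07, "moderate"),
    ("SKBR3", 5.09, "low"),
    ("HMEC", 1.00, "baseline"),
]


@pytest.fixture(scope="session")
def table1_fish():
    return TABLE1_FISH


@pytest.fixture(scope="session")
def table1_rq():
    return TABLE1_RQ


@pytest.fixture(scope="session")
def population_builder():
    return build_population
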