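import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metdiv import diversity as dv
from metdiv.exceptions import DegenerateDataError, ValidationError

from conftest import make_cells


def shannon_oracle(p):
    """Independent direct-summation Shannon (pure-python math loop)."""
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def simpson_oracle(p):
    return sum(pi * pi for pi in p)


@pytest.mark.parametrize("p,h,d", [
    ((1 / 3, 1 / 3, 1 / 3), math.log(3), 1 / 3),
    ((1.0, 0.0, 0.0), 0.0, 1.0),
    ((0.5, 0.25, 0.25), 1.0397207708399179, 0.375),
    ((0.5, 0.5, 0.0), math.log(2), 0.5),
])
def test_index_closed_forms(p, h, d):
    assert dv.shannon(p) == pytest.approx(h, abs=1e-12)
    assert dv.simpson(p) == pytest.approx(d, abs=1e-12)


def test_indices_match_direct_summation_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        p = rng.dirichlet([1, 1, 1])
        assert dv.shannon(p) == pytest.approx(shannon_oracle(p), abs=1e-12)
        assert dv.simpson(p) == pytest.approx(simpson_oracle(p), abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=3))
def test_index_bounds_and_permutation_invariance(raw):
    p = np.array(raw) / sum(raw)
    h, d = dv.shannon(p), dv.simpson(p)
    assert 0.0 <= h <= math.log(3) + 1e-12
    assert 1 / 3 - 1e-12 <= d <= 1.0
    for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
        assert dv.shannon(p[perm]) == pytest.approx(h, abs=1e-12)
        assert dv.simpson(p[perm]) == pytest.approx(d, abs=1e-12)


def test_dominance_equivalence():
    # H = 0 iff D = 1 iff one class has everything
    one_hot = np.array([0.0, 1.0, 0.0])
    assert dv.shannon(one_hot) == 0.0 and dv.simpson(one_hot) == 1.0
    mixed = np.array([0.999, 0.0005, 0.0005])
    assert dv.shannon(mixed) > 0.0 and dv.simpson(mixed) < 1.0


def test_composition_counts():
    comp = dv.composition(make_cells({"cancer": 2, "lymphocyte": 1, "stromal": 1}))
    np.testing.assert_allclose(comp.p, [0.5, 0.25, 0.25])
    assert comp.n_cells == 4


def test_composition_empty_section_errors():
    with pytest.raises(ValidationError):
        dv.composition(make_cells({"cancer": 0}))


def test_composition_reported_mean_counts():
    # mean per-class counts of a section: cancer 362417, lym 67433, stromal 92861
    comp = dv.composition(
        ["cancer"] * 362417 + ["lymphocyte"] * 67433 + ["stromal"] * 92861)
    np.testing.assert_allclose(comp.p, [0.6933, 0.1290, 0.1777], atol=1e-4)


def test_section_diversity_plugin_estimate():
    rng = np.random.default_rng(5)
    counts = rng.multinomial(100_000, [0.6, 0.2, 0.2])
    cells = make_cells(dict(zip(["cancer", "lymphocyte", "stromal"], counts)))
    sd = dv.section_diversity(cells)
    analytic = -(0.6 * math.log(0.6) + 2 * 0.2 * math.log(0.2))
    assert sd.shannon == pytest.approx(analytic, abs=0.005)
    assert sd.simpson == pytest.approx(0.44, abs=0.01)


def test_all_cancer_section():
    sd = dv.section_diversity(make_cells({"cancer": 50}))
    assert sd.shannon == 0.0 and sd.simpson == 1.0


def _section_rows(hs, sites, extra=None):
    rows = pd.DataFrame({
        "patient_id": "P1",
        "section_id": [f"S{i}" for i in range(len(hs))],
        "site": sites,
        "n_cells": 100,
        "p_cancer": 0.5, "p_lymphocyte": 0.25, "p_stromal": 0.25,
        "shannon": hs, "simpson": 0.4,
    })
    if extra:
        for k, v in extra.items():
            rows[k] = v
    return rows


def test_patient_profile_arithmetic():
    rows = _section_rows([0.2, 0.9, 1.1], ["ovary", "omentum", "peritoneum"])
    prof = dv.patient_profile(rows)
    assert prof.metdiv == pytest.approx(1.0)
    assert prof.metdiv_incl_ovary == pytest.approx(0.73333, abs=1e-5)
    assert prof.shannon_sd == pytest.approx(0.141421, abs=1e-5)
    assert prof.n_sites == 3
    assert prof.ovary_shannon == pytest.approx(0.2)


def test_patient_profile_single_metastasis():
    prof = dv.patient_profile(_section_rows([0.5, 0.7], ["ovary", "omentum"]))
    assert prof.metdiv == pytest.approx(0.7)
    assert np.isnan(prof.shannon_sd)


def test_patient_profile_order_invariance():
    rows = _section_rows([0.2, 0.9, 1.1], ["ovary", "omentum", "peritoneum"])
    shuffled = rows.iloc[[2, 0, 1]].reset_index(drop=True)
    assert dv.patient_profile(rows) == dv.patient_profile(shuffled)


def test_patient_profile_two_ovaries_error():
    with pytest.raises(ValidationError, match="ovary"):
        dv.patient_profile(_section_rows([0.2, 0.3], ["ovary", "ovary"]))


def test_patient_profile_no_metastasis_warns_nan():
    with pytest.warns(UserWarning, match="MetDiv undefined"):
        prof = dv.patient_profile(_section_rows([0.2], ["ovary"]))
    assert np.isnan(prof.metdiv)


def test_metdiv_invariant_to_cell_duplication():
    # proportions are scale-free: duplicating a section's cells changes nothing
    cells = make_cells({"cancer": 30, "lymphocyte": 10, "stromal": 10})
    doubled = pd.concat([cells, cells], ignore_index=True)
    assert dv.section_diversity(cells).shannon == pytest.approx(
        dv.section_diversity(doubled).shannon, abs=1e-12)


def test_compare_ovary_vs_metastases_extremes():
    base = pd.DataFrame({
        "ovary_stromal_ratio": [0.1, 0.2, 0.3, 0.4],
        "mean_met_stromal_ratio": [0.1, 0.2, 0.3, 0.4],
        "ovary_lym_ratio": [0.1, 0.2, 0.3, 0.4],
        "mean_met_lym_ratio": [0.9, 0.8, 0.7, 0.6],
    })
    r, p, n = dv.compare_ovary_vs_metastases(base, "stromal")
    assert r == pytest.approx(1.0) and n == 4
    r, _, _ = dv.compare_ovary_vs_metastases(base, "lymphocyte")
    assert r == pytest.approx(-1.0)
    with pytest.raises(DegenerateDataError):
        dv.compare_ovary_vs_metastases(base.iloc[:2], "stromal")


def test_compare_ovary_sampling_distribution():
    # bivariate normal with rho=0.3 at n=61: mean Pearson r-hat near 0.3
    rng = np.random.default_rng(8)
    rs = []
    cov = [[1, 0.3], [0.3, 1]]
    for _ in range(500):
        xy = rng.multivariate_normal([0.3, 0.3], np.array(cov) * 0.01, size=61)
        prof = pd.DataFrame({"ovary_stromal_ratio": xy[:, 0],
                             "mean_met_stromal_ratio": xy[:, 1]})
        rs.append(dv.compare_ovary_vs_metastases(prof, "stromal")[0])
    assert np.mean(rs) == pytest.approx(0.3, abs=0.02)


def test_index_agreement_monotone_gradient():
    ts = np.linspace(0.5, 0.99, 30)
    df = pd.DataFrame({
        "shannon": [dv.shannon([t, 1 - t, 0]) for t in ts],
        "simpson": [dv.simpson([t, 1 - t, 0]) for t in ts],
    })
    res = dv.index_agreement(df)
    assert abs(res["spearman_h_vs_d"]) == pytest.approx(1.0)
    assert res["pearson_h_vs_d"] < 0 < res["pearson_h_vs_1md"]


def test_index_agreement_degenerate():
    df = pd.DataFrame({"shannon": [0.5] * 5, "simpson": [0.4] * 5})
    with pytest.raises(DegenerateDataError):
        dv.index_agreement(df)
    with pytest.raises(DegenerateDataError):
        dv.index_agreement(df.iloc[:2])


def test_index_agreement_random_compositions():
    rng = np.random.default_rng(12)
    ps = rng.dirichlet([1, 1, 1], size=192)
    df = pd.DataFrame({"shannon": [dv.shannon(p) for p in ps],
                       "simpson": [dv.simpson(p) for p in ps]})
    assert dv.index_agreement(df)["abs_pearson"] > 0.9


def test_shannon_simplex_field():
    field = dv.shannon_simplex_field(4)
    assert len(field) == 15  # triangular lattice (g+1)(g+2)/2
    center = field[(field.iloc[:, :3] == 0.25).sum(axis=1) == 2]
    vertex = field[field["p_cancer"] == 1.0]
    assert vertex["shannon"].iloc[0] == 0.0
    edge_mid = field[(field["p_cancer"] == 0.5) & (field["p_lymphocyte"] == 0.5)]
    assert edge_mid["shannon"].iloc[0] == pytest.approx(math.log(2), abs=1e-12)
    full = dv.shannon_simplex_field(2)
    mid = full[(full["p_cancer"] == 0.5) & (full["p_stromal"] == 0.5)]
    assert mid["shannon"].iloc[0] == pytest.approx(math.log(2), abs=1e-12)
    with pytest.raises(ValidationError):
        dv.shannon_simplex_field(1)


def test_section_table_matches_per_section_computation(small_cohort):
    table = dv.section_table(small_cohort.cells)
    # spot-check three sections against the single-section path
    for sid in table["section_id"].iloc[[0, len(table) // 2, -1]]:
        sub = small_cohort.cells[small_cohort.cells["section_id"] == sid]
        sd = dv.section_diversity(sub)
        row = table[table["section_id"] == sid].iloc[0]
        assert row["shannon"] == pytest.approx(sd.shannon, abs=1e-12)
        assert row["simpson"] == pytest.approx(sd.simpson, abs=1e-12)
        assert row["n_cells"] == sd.composition.n_cells
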