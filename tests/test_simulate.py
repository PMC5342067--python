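import math

import numpy as np
import pandas as pd
import pytest

from metdiv import simulate as sim
from metdiv.diversity import section_table
from metdiv.exceptions import ConfigError


def test_cohort_seed_determinism(small_config):
    a = sim.generate_cohort(small_config)
    b = sim.generate_cohort(small_config)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    pd.testing.assert_frame_equal(a.clinical, b.clinical)
    pd.testing.assert_frame_equal(a.truth_sections, b.truth_sections)
    pd.testing.assert_frame_equal(a.truth_patients, b.truth_patients)


def test_with_cells_false_same_truth(small_config):
    full = sim.generate_cohort(small_config, with_cells=True)
    fast = sim.generate_cohort(small_config, with_cells=False)
    assert fast.cells is None
    pd.testing.assert_frame_equal(full.clinical, fast.clinical)
    pd.testing.assert_frame_equal(full.truth_patients, fast.truth_patients)


def test_every_patient_has_ovary_plus_metastasis(small_cohort):
    per_patient = small_cohort.truth_sections.groupby("patient_id")["site"]
    for _, sites in per_patient:
        assert (sites == "ovary").sum() == 1
        assert (sites != "ovary").sum() >= 1


def test_generate_section_determinism_and_errors():
    cfg = sim.CohortConfig(count_scale=0.001, seed=0)
    a = sim.generate_section("omentum", cfg, seed=42)
    b = sim.generate_section("omentum", cfg, seed=42)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["cell_class"]).issubset({"cancer", "lymphocyte", "stromal"})
    assert a["x"].between(0, cfg.section_size_um).all()
    with pytest.raises(ConfigError, match="unknown site"):
        sim.generate_section("liver", cfg, seed=1)


def test_degenerate_prior_gives_single_class():
    cfg = sim.CohortConfig(count_scale=0.001, seed=0)
    cfg.composition_priors["omentum"] = (1e6, 1e-3, 1e-3)
    cells = sim.generate_section("omentum", cfg, seed=3)
    assert (cells["cell_class"] == "cancer").all()


def test_lymph_node_richer_in_lymphocytes_than_omentum():
    cfg = sim.CohortConfig(count_scale=0.001, seed=0)
    props = {}
    for site in ("lymph_node", "omentum"):
        vals = []
        for s in range(60):
            cells = sim.generate_section(site, cfg, seed=1000 + s if site == "omentum" else s)
            vals.append((cells["cell_class"] == "lymphocyte").mean())
        props[site] = np.mean(vals)
    assert props["lymph_node"] > props["omentum"]


def test_cells_per_section_sampler_scaling():
    rng = np.random.default_rng(0)
    cfg_full = sim.CohortConfig(count_scale=1.0)
    draws = [sim.cells_per_section_sampler(cfg_full, "cancer", rng) for _ in range(2000)]
    assert np.mean(draws) == pytest.approx(362_417, rel=0.1)
    cfg_desk = sim.CohortConfig(count_scale=0.01)
    rng = np.random.default_rng(0)
    desk = [sim.cells_per_section_sampler(cfg_desk, "cancer", rng) for _ in range(2000)]
    assert np.mean(desk) == pytest.approx(3624, rel=0.1)


def test_cells_per_section_sampler_zero_variance():
    cfg = sim.CohortConfig(count_scale=1.0)
    cfg.cells_per_section["cancer"]["sigma"] = 0.0
    rng = np.random.default_rng(1)
    draws = {sim.cells_per_section_sampler(cfg, "cancer", rng) for _ in range(10)}
    assert draws == {362_417}


def test_sites_per_patient_support_and_median():
    cfg = sim.CohortConfig(n_patients=300, seed=5)
    co = sim.generate_cohort(cfg, with_cells=False)
    k = co.truth_sections.groupby("patient_id").size()
    assert k.between(2, 5).all()
    assert np.median(k) == 3


def test_composition_recovery_large_section():
    # empirical class proportions converge to the generating mixture
    cfg = sim.CohortConfig(count_scale=0.2, seed=0)  # ~1e5 cells
    cells = sim.generate_section("peritoneum", cfg, seed=77)
    # replay the generator's mixture draw for the same seed
    rng = np.random.default_rng(77)
    p_true = rng.dirichlet(np.asarray(cfg.composition_priors["peritoneum"]))
    emp = cells["cell_class"].value_counts(normalize=True)
    phat = np.array([emp.get(c, 0.0) for c in sim.CELL_CLASSES])
    assert len(cells) > 50_000
    assert np.abs(phat - p_true).max() < 0.01


def test_truth_composition_matches_measured(small_cohort):
    # measured section compositions should track the generating mixtures
    meas = section_table(small_cohort.cells).set_index("section_id")
    truth = small_cohort.truth_sections.set_index("section_id")
    dev = (meas[["p_cancer", "p_lymphocyte", "p_stromal"]].to_numpy()
           - truth[["true_p_cancer", "true_p_lymphocyte", "true_p_stromal"]
                   ].loc[meas.index].to_numpy())
    # ~1000 cells/section at this scale: sampling noise ~ 3*sqrt(.25/1000)
    assert np.abs(dev).max() < 0.08
    assert np.abs(dev).mean() < 0.02


def test_no_censoring_config_all_events():
    cfg = sim.CohortConfig(n_patients=40, seed=2)
    cfg.survival_model.censoring_fraction = 0.0
    cfg.survival_model.admin_censor_months = math.inf
    co = sim.generate_cohort(cfg, with_cells=False)
    assert (co.clinical["os_event"] == 1).all()
    assert (co.clinical["pfs_event"] == 1).all()
    assert (co.clinical["pfs_months"] <= co.clinical["os_months"]).all()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        sim.CohortConfig(n_patients=0).validate()
    cfg = sim.CohortConfig()
    cfg.survival_model.median_os = -1
    with pytest.raises(ConfigError, match="median"):
        cfg.validate()
    cfg2 = sim.CohortConfig()
    cfg2.site_frequencies = {"omentum": 0.5}
    with pytest.raises(ConfigError, match="sum to 1"):
        cfg2.validate()
    cfg3 = sim.CohortConfig()
    cfg3.composition_priors["ovary"] = (1.0, -1.0, 1.0)
    with pytest.raises(ConfigError, match="positive"):
        cfg3.validate()


def test_config_yaml_round_trip(tmp_path, small_config):
    path = tmp_path / "cfg.yaml"
    small_config.save(path)
    back = sim.CohortConfig.load(path)
    assert back.to_dict() == small_config.to_dict()


def test_high_group_fraction(small_cohort):
    frac = (small_cohort.truth_patients["true_group"] == "high").mean()
    assert 0.1 <= frac <= 0.3  # ~18% by default


def test_generate_annotations_shape_and_labels():
    ann = sim.generate_annotations(seed=0)
    assert len(ann) == 4633
    assert (ann["expert_class"] == "cancer").sum() == 2668
    assert set(ann["predicted_class"]) <= {"cancer", "lymphocyte", "stromal"}
    # classifier emulation should be decent but imperfect
    acc = (ann["expert_class"] == ann["predicted_class"]).mean()
    assert 0.7 < acc < 0.95


def test_generate_fov_scores():
    auto, expert = sim.generate_fov_scores(seed=1)
    assert len(auto) == len(expert) == 24
    np.testing.assert_allclose(auto.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(expert.sum(axis=1), 1.0, atol=1e-9)
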