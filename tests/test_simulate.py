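"""Synthetic litter generator: determinism, moments, scenarios."""

import dataclasses
import math

import numpy as np
import pytest

from hornwise.io import dataset_to_frame, write_study_table
from hornwise.simulate import (
    SimulationConfig,
    position_for_index,
    power_experiment,
    scenario_gd4_like,
    scenario_rmd_masked,
    simulate_study,
)
from hornwise.positions import Position


def noiseless_config(**kw):
    base = dict(
        n_dams_per_group={"control": 3},
        maternal_weight_sd_g=0.0,
        dam_effect_sd_g=0.0,
        fetal_noise_sd_g=0.0,
        placental_noise_sd_g=0.0,
        horn_multipliers={"R": 1.0, "L": 1.0},
        position_multipliers={
            (s, p.value): 1.0 for s in ("R", "L") for p in Position
        },
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_degenerate_generator_is_exact():
    ds = simulate_study(noiseless_config(), seed=3)
    weights = {f.fetal_weight_g for d in ds.dams for f in d.all_feti()}
    assert weights == {2.62}
    placentas = {f.placental_weight_g for d in ds.dams for f in d.all_feti()}
    assert placentas == {0.52}


def test_same_seed_gives_byte_identical_csv(tmp_path):
    cfg = scenario_gd4_like()
    f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_study_table(simulate_study(cfg, seed=9), f1)
    write_study_table(simulate_study(cfg, seed=9), f2)
    assert f1.read_bytes() == f2.read_bytes()
    write_study_table(simulate_study(cfg, seed=10), tmp_path / "c.csv")
    assert f1.read_bytes() != (tmp_path / "c.csv").read_bytes()


def test_grand_mean_matches_configured_baseline():
    cfg = SimulationConfig(n_dams_per_group={"control": 50})
    ds = simulate_study(cfg, seed=21)
    w = np.array([f.fetal_weight_g for d in ds.dams for f in d.all_feti()])
    dam_means = [np.mean([f.fetal_weight_g for f in d.all_feti()]) for d in ds.dams]
    se = np.std(dam_means, ddof=1) / math.sqrt(len(dam_means))
    # multipliers average near 1, so the grand mean sits at the baseline
    assert abs(w.mean() - cfg.baseline_fetal_mean_g) < 3 * se + 0.03


def test_generator_moments_within_monte_carlo_error():
    cfg = SimulationConfig(n_dams_per_group={"control": 60})
    ds = simulate_study(cfg, seed=4)
    maternal = np.array([d.maternal_gd20_weight_g for d in ds.dams])
    assert abs(maternal.mean() - 330.0) < 3 * 20.0 / math.sqrt(len(maternal))
    placentas = np.array([f.placental_weight_g for d in ds.dams for f in d.all_feti()])
    assert abs(placentas.mean() - 0.52) < 3 * 0.05 / math.sqrt(placentas.size)
    sizes = [len(d.horn(s)) for d in ds.dams for s in d.horns]
    assert set(sizes) <= {4, 5, 6, 7, 8}
    assert abs(np.mean(sizes) - 6.0) < 3 * np.std(sizes) / math.sqrt(len(sizes))


def test_position_for_index_mirrors_analysis_mapping():
    assert [position_for_index(i, 5) for i in range(1, 6)] == [
        Position.OE, Position.NOE, Position.MD, Position.NCE, Position.CE
    ]
    assert [position_for_index(i, 7) for i in (3, 4, 5)] == [Position.MD] * 3


def test_gd4_scenario_structure():
    cfg = scenario_gd4_like()
    assert set(cfg.effect_matrix) == {
        ("gd4", "R", "OE"), ("gd4", "R", "NOE"), ("gd4", "R", "MD"), ("gd4", "R", "NCE")
    }
    assert all(v == pytest.approx(0.45) for v in cfg.effect_matrix.values())
    assert cfg.effect_matrix.get(("gd4", "L", "CE"), 0.0) == 0.0
    assert cfg.n_dams_per_group == {"control": 20, "gd4": 6}
    masked = scenario_rmd_masked()
    assert set(masked.effect_matrix) == {("gd4", "R", "MD")}


def test_config_yaml_round_trip(tmp_path):
    cfg = scenario_gd4_like(reduction=0.3, n_exposed=8)
    f = tmp_path / "cfg.yaml"
    cfg.to_yaml(f)
    back = SimulationConfig.from_yaml(f)
    assert back == cfg


@pytest.mark.parametrize(
    "kw",
    [
        dict(effect_matrix={("g", "R", "MD"): 1.5}),
        dict(horn_multipliers={"R": -1.0, "L": 1.0}),
        dict(litter_sizes=(0, 4)),
        dict(fetal_placental_correlation=2.0),
        dict(litter_sizes=(4, 5), litter_size_probs=(0.6, 0.6)),
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        SimulationConfig(**kw)


def test_placental_correlation_knob():
    cfg = SimulationConfig(
        n_dams_per_group={"control": 40}, fetal_placental_correlation=0.8
    )
    ds = simulate_study(cfg, seed=8)
    fw = np.array([f.fetal_weight_g for d in ds.dams for f in d.all_feti()])
    pw = np.array([f.placental_weight_g for d in ds.dams for f in d.all_feti()])
    # correlation of the noise parts; dam effects dilute it slightly
    assert np.corrcoef(fw, pw)[0, 1] > 0.4
    ds0 = simulate_study(SimulationConfig(n_dams_per_group={"control": 40}), seed=8)
    fw0 = np.array([f.fetal_weight_g for d in ds0.dams for f in d.all_feti()])
    pw0 = np.array([f.placental_weight_g for d in ds0.dams for f in d.all_feti()])
    assert abs(np.corrcoef(fw0, pw0)[0, 1]) < 0.15


def test_power_experiment_single_replicate_is_binary():
    res = power_experiment(scenario_rmd_masked(), n_replicates=1, seed=5)
    assert set(res.rejections["rejections"]) <= {0, 1}
    assert (res.rejections["n_replicates"] == 1).all()


def test_power_experiment_reproducible():
    cfg = scenario_rmd_masked()
    r1 = power_experiment(cfg, n_replicates=5, seed=17)
    r2 = power_experiment(cfg, n_replicates=5, seed=17)
    assert r1.rejections.equals(r2.rejections)
    assert r1.cell_mean_ratio == r2.cell_mean_ratio


def test_detection_rate_monotone_in_effect_size():
    """Larger injected reductions are detected more often at the RMD."""
    rates = []
    for reduction in (0.0, 0.2, 0.45):
        cfg = scenario_gd4_like(reduction=reduction, positions=("MD",)) \
            if reduction else scenario_gd4_like(reduction=0.0, positions=())
        res = power_experiment(cfg, n_replicates=80, seed=303)
        sub = res.rejections.query(
            "method == 'positional' and horn_side == 'R' and position == 'MD'"
        )
        rates.append(float(sub["rejection_rate"].iloc[0]))
    assert rates[0] < rates[1] < rates[2]
    assert rates[0] <= 0.1 and rates[2] >= 0.9
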