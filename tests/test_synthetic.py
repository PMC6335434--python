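"""Synthetic study generator: determinism, planted truth, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from exoantigen.config import SimulationConfig
from exoantigen.errors import ConfigurationError
from exoantigen.quant import fold_changes_by_group
from exoantigen.synthetic import (
    planted_ids,
    simulate_cdc,
    simulate_proteomics,
    simulate_serology,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_proteomics(small_config)
        b = simulate_proteomics(small_config)
        pd.testing.assert_frame_equal(a.cell_counts, b.cell_counts)
        pd.testing.assert_frame_equal(a.ig_counts, b.ig_counts)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.particles, b.particles)
        assert a.truth == b.truth
        pd.testing.assert_frame_equal(
            simulate_serology(small_config), simulate_serology(small_config)
        )
        pd.testing.assert_frame_equal(
            simulate_cdc(small_config), simulate_cdc(small_config)
        )

    def test_distinct_seeds_differ(self, small_config):
        for seed_pair in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9),
                          (10, 11), (12, 13), (14, 15), (16, 17), (18, 19)]:
            a = simulate_proteomics(dataclasses.replace(small_config, seed=seed_pair[0]))
            b = simulate_proteomics(dataclasses.replace(small_config, seed=seed_pair[1]))
            assert not a.ig_counts.equals(b.ig_counts)


class TestInvariantsAndTruth:
    def test_counts_are_nonnegative_integers_with_noise(self, small_study):
        for matrix in (small_study.cell_counts, small_study.ig_counts):
            values = matrix.to_numpy()
            assert (values >= 0).all()
            assert np.array_equal(values, np.rint(values))
        assert (small_study.intensities.to_numpy() >= 0).all()

    def test_truth_consistency(self, small_config, small_study):
        truth = small_study.truth
        assert len(truth.antigen_ids) == small_config.n_planted_antigens
        assert set(truth.antigen_ids) <= set(small_study.ig_counts.index)
        assert set(truth.unique_to_case_ids) <= set(truth.antigen_ids)
        assert set(truth.contaminant_ids).isdisjoint(truth.antigen_ids)

    def test_noise_free_surface_ratio_is_exact(self, small_config):
        cfg = dataclasses.replace(small_config, nb_dispersion=0.0)
        sim = simulate_proteomics(cfg)
        meta = sim.cell_meta
        surface = meta.index[meta.compartment == "exo_surface"]
        cargo = meta.index[meta.compartment == "exo_cargo"]
        for antigen in sim.truth.antigen_ids:
            ratio = (sim.cell_counts.loc[antigen, surface].mean()
                     / sim.cell_counts.loc[antigen, cargo].mean())
            assert ratio == pytest.approx(cfg.surface_fold, abs=1e-9)

    def test_non_planted_ig_ratio_centered_at_one(self, small_config):
        # Monte-Carlo over 20 seeds: background case/control ratios are
        # multiplicatively centered at 1 (case and control pools are
        # exchangeable for non-planted proteins, so E[log ratio] = 0; the
        # plain mean of ratios carries the usual Jensen bias upward).
        means = []
        for seed in range(20):
            sim = simulate_proteomics(dataclasses.replace(small_config, seed=seed))
            meta = sim.ig_meta
            fc = fold_changes_by_group(
                sim.ig_counts,
                list(meta.index[meta.group == "case"]),
                list(meta.index[meta.group == "control"]),
            )
            background = fc.index.difference(
                list(sim.truth.antigen_ids) + list(sim.truth.contaminant_ids)
            )
            ratios = fc.loc[background, "ratio"].to_numpy()
            ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
            means.append(np.log(ratios).mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) <= 3 * se

    def test_planted_case_effect_present_in_ig_pools(self, small_study, small_config):
        meta = small_study.ig_meta
        fc = fold_changes_by_group(
            small_study.ig_counts,
            list(meta.index[meta.group == "case"]),
            list(meta.index[meta.group == "control"]),
        )
        planted_ratios = fc.loc[list(small_study.truth.antigen_ids), "ratio"]
        assert planted_ratios.median() > 2.0  # planted at case_ratio 3.0

    def test_unique_to_case_have_zero_control_intensity(self, small_study):
        meta = small_study.intensity_meta
        controls = meta.index[meta.group == "control"]
        block = small_study.intensities.loc[
            list(small_study.truth.unique_to_case_ids), controls
        ]
        assert (block.to_numpy() == 0).all()

    def test_particle_diameters_match_configured_distribution(self, small_study,
                                                              small_config):
        diam = small_study.particles["diameter_nm"]
        assert abs(diam.mean() - small_config.particle_mean_nm) < 2.0
        assert (diam > 0).all()


class TestSerologySimulation:
    def test_sets_have_distinct_scales(self, small_config):
        table = simulate_serology(small_config)
        spread = table.groupby("set")["intensity"].std()
        assert spread["set2"] > 2 * spread["set1"]

    def test_planted_ids_consistent_across_stages(self, small_config):
        sim = simulate_proteomics(small_config)
        serology_antigens = set(simulate_serology(small_config)["antigen_id"])
        assert set(sim.truth.antigen_ids) <= serology_antigens
        assert tuple(planted_ids(small_config)) == sim.truth.antigen_ids


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_proteins": 0},
        {"nb_dispersion": -0.1},
        {"surface_fold": 1.0},
        {"case_ratio": 0.5},
        {"n_planted_antigens": 10_000},
        {"cdc_doses": (1.0, 2.5)},          # missing dose 0
        {"cdc_doses": (0.0, -1.0)},         # negative dose
        {"serology_set_sizes": ((5, 2, 0), (5, 5, 0))},  # too few controls
        {"compartments": ("TCE", "TCE")},   # duplicate labels
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path, small_config):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(small_config.to_dict()))
        loaded = SimulationConfig.from_yaml(path)
        assert loaded.n_proteins == small_config.n_proteins
        assert tuple(loaded.compartments) == tuple(small_config.compartments)
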