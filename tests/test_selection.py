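"""Filter-cascade rules, boundary strictness and planted-truth recovery."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from exoantigen.config import SimulationConfig, Thresholds
from exoantigen.errors import ConfigurationError, DataError
from exoantigen.quant import (
    count_particles_in_window,
    normalize_by_particles,
    quantile_normalize,
)
from exoantigen.selection import (
    ExclusionLists,
    FilterCascadeReport,
    compartment_enrichment,
    default_marker_sets,
    full_cascade,
    ig_bound_cascade,
    marker_qc,
    plasma_exosome_elevation,
    select_detected,
)
from exoantigen.synthetic import evaluate_recovery, simulate_proteomics


def _matrix(rows: dict, columns) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).astype(float)


class TestSelectDetected:
    def test_inclusive_boundary_at_five(self):
        m = _matrix({"p": [5.0]}, ["pool1"])
        selected, _ = select_detected(m, min_count=5, min_samples=1, strict=False)
        assert selected == {"p"}

    def test_strict_rule_two_of_six(self):
        m = _matrix({"keep": [6, 6, 0, 0, 0, 0], "drop": [6, 5, 5, 5, 5, 5]},
                    [f"line{i}" for i in range(1, 7)])
        selected, _ = select_detected(m, min_count=5, min_samples=2, strict=True)
        assert selected == {"keep"}  # "drop" has only one strict exceedance

    def test_min_samples_validation(self):
        m = _matrix({"p": [5.0]}, ["s1"])
        with pytest.raises(ConfigurationError):
            select_detected(m, min_samples=0)
        with pytest.raises(ConfigurationError):
            select_detected(m, min_samples=2)


class TestIgBoundCascade:
    def _counts(self, rows):
        return _matrix(rows, ["case1", "case2", "ctrl1", "ctrl2"])

    def test_subthreshold_ratio_removed(self):
        m = self._counts({"p": [6.0, 6.0, 4.5, 4.5]})  # ratio 1.333 < 1.5
        report = ig_bound_cascade(m, ["case1", "case2"], ["ctrl1", "ctrl2"])
        stage = {s.name: s for s in report.stages}["ig_case_control_ratio"]
        assert "p" not in stage.survivors

    def test_boundary_ratio_retained(self):
        m = self._counts({"p": [6.0, 6.0, 4.0, 4.0]})  # ratio 1.5 inclusive
        report = ig_bound_cascade(m, ["case1", "case2"], ["ctrl1", "ctrl2"])
        assert "p" in report.survivors

    def test_ig_chain_prefix_removed_regardless_of_counts(self):
        m = self._counts({"IGKC": [500.0, 500.0, 10.0, 10.0],
                          "GENE1": [30.0, 30.0, 10.0, 10.0]})
        report = ig_bound_cascade(
            m, ["case1", "case2"], ["ctrl1", "ctrl2"],
            exclusions=ExclusionLists.default(),
        )
        assert "IGKC" not in report.survivors
        assert "GENE1" in report.survivors

    def test_missing_evidence_row_fails_expression_stage(self):
        m = self._counts({"known": [30, 30, 10, 10], "unknown": [30, 30, 10, 10]})
        evidence = pd.DataFrame(
            {"fpkm_line1": [5.0], "tcga_log2": [8.0], "oncomine_hits": [3]},
            index=["known"],
        )
        report = ig_bound_cascade(m, ["case1", "case2"], ["ctrl1", "ctrl2"],
                                  evidence=evidence)
        assert report.survivors == ("known",)
        assert report.annotations["overexpressed_in_external_datasets"] == ["known"]

    def test_requires_both_groups(self):
        m = self._counts({"p": [6, 6, 4, 4]})
        with pytest.raises(DataError):
            ig_bound_cascade(m, [], ["ctrl1"])


class TestCompartmentEnrichment:
    def _study(self, surface, cargo, tee):
        columns, values = [], []
        for line in ("line1", "line2"):
            for comp, level in (("TCE", 10.0), ("cell_surface", 10.0), ("TEE", tee),
                                ("exo_surface", surface), ("exo_cargo", cargo)):
                columns.append(f"{line}|{comp}")
                values.append(level)
        matrix = pd.DataFrame([values], index=["p"], columns=columns)
        return matrix

    def _run(self, matrix, compartment_meta):
        th = Thresholds(cell_line_detect_min_lines=2)
        return compartment_enrichment(
            matrix, compartment_meta, target="exo_surface",
            references=("exo_cargo", "TEE"), fold=1.25, thresholds=th,
        )[0]

    def test_enriched_over_both_references(self, compartment_meta):
        assert self._run(self._study(13.0, 10.0, 10.0), compartment_meta) == {"p"}

    def test_below_fold_not_enriched(self, compartment_meta):
        assert self._run(self._study(12.0, 10.0, 10.0), compartment_meta) == set()

    def test_conjunction_over_all_references(self, compartment_meta):
        # 13 vs cargo 10 passes but 13 vs TEE 11 is 1.18 < 1.25
        assert self._run(self._study(13.0, 10.0, 11.0), compartment_meta) == set()

    def test_unknown_compartment_rejected(self, compartment_meta):
        with pytest.raises(DataError):
            compartment_enrichment(
                self._study(13, 10, 10), compartment_meta,
                target="mitochondria", references=("TEE",),
            )


class TestPlasmaElevation:
    def _table(self, case, control):
        data = {f"case{i}": v for i, v in enumerate(case)}
        data.update({f"ctrl{i}": v for i, v in enumerate(control)})
        return pd.DataFrame(data, index=["p"]).astype(float)

    def _run(self, table):
        cases = [c for c in table.columns if c.startswith("case")]
        ctrls = [c for c in table.columns if c.startswith("ctrl")]
        return plasma_exosome_elevation(table, cases, ctrls, fold=2.5)[0]

    def test_above_fold_elevated(self):
        assert self._run(self._table([5.1, 5.1], [2.0, 2.0])) == {"p"}

    def test_at_or_below_fold_not_elevated(self):
        assert self._run(self._table([5.0, 5.0], [2.0, 2.0])) == set()
        assert self._run(self._table([4.8, 4.8], [2.0, 2.0])) == set()

    def test_case_only_protein_qualifies_via_inf(self):
        assert self._run(self._table([3.0, 3.0], [0.0, 0.0])) == {"p"}

    def test_detection_in_min_samples_required(self):
        table = self._table([9.0, 0.0], [0.0, 0.0])  # detected once only
        assert self._run(table) == set()


class TestMarkerQc:
    def test_default_lists_match_shipped_panels(self):
        markers, depleted = default_marker_sets()
        assert markers == {"CD81", "CD9", "FLOT1", "FLOT2", "PDCD6IP", "SDCBP",
                           "TSG101"}
        assert depleted == {"CANX", "CYC1", "GOLGA2", "HSP90B1"}

    def _qc_matrix(self, exo_level, cell_level, compartment_meta, rng):
        markers, depleted = default_marker_sets()
        rows = {}
        for i, sym in enumerate(sorted(markers)):
            rows[sym] = [
                (exo_level + i if meta.compartment.startswith(("TEE", "exo"))
                 else cell_level + i)
                for meta in compartment_meta.itertuples()
            ]
        for i, sym in enumerate(sorted(depleted)):
            rows[sym] = [10.0 + i + 0.1 * rng.random()
                         for _ in range(len(compartment_meta))]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=compartment_meta.index
        )

    def test_clear_enrichment_passes_qc(self, compartment_meta, rng):
        m = self._qc_matrix(100.0, 10.0, compartment_meta, rng)
        report = marker_qc(m, compartment_meta)
        assert report.passed
        assert report.marker_p == pytest.approx(1 / comb(14, 7))

    def test_identical_distributions_do_not_pass(self, compartment_meta, rng):
        # one-sided enrichment p is 0.5 when exosome and cell values coincide
        m = self._qc_matrix(10.0, 10.0, compartment_meta, rng)
        report = marker_qc(m, compartment_meta)
        assert report.marker_p >= 0.5
        assert not report.passed

    def test_missing_markers_reported(self, compartment_meta):
        m = pd.DataFrame(
            [[1.0] * len(compartment_meta)], index=["CD9"],
            columns=compartment_meta.index,
        )
        report = marker_qc(m, compartment_meta)
        assert "CD81" in report.missing_markers
        assert not report.passed

    def test_no_marker_found_is_an_error(self, compartment_meta):
        m = pd.DataFrame([[1.0] * len(compartment_meta)], index=["XYZ"],
                         columns=compartment_meta.index)
        with pytest.raises(DataError):
            marker_qc(m, compartment_meta)


class TestCascadeProperties:
    def test_report_enforces_subset_invariant(self):
        report = FilterCascadeReport()
        report.add_stage("a", "rule", 1, {"x", "y"})
        with pytest.raises(DataError):
            report.add_stage("b", "rule", 1, {"z"})

    def test_counts_monotone_on_simulated_study(self, small_config, small_study):
        report = _run_full_cascade(small_study)
        counts = [s.n_surviving for s in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cascade_invariant_to_row_and_column_permutation(self, small_study):
        rng = np.random.default_rng(3)
        base = _run_full_cascade(small_study)
        shuffled = small_study
        ig = shuffled.ig_counts.sample(frac=1.0, random_state=11)
        ig = ig[list(rng.permutation(ig.columns))]
        cell = shuffled.cell_counts.sample(frac=1.0, random_state=12)
        permuted = _run_full_cascade(shuffled, ig_override=ig, cell_override=cell)
        assert permuted.survivors == base.survivors


def _run_full_cascade(sim, ig_override=None, cell_override=None):
    th = Thresholds()
    ig = quantile_normalize(ig_override if ig_override is not None else sim.ig_counts)
    cell = quantile_normalize(
        cell_override if cell_override is not None else sim.cell_counts
    )
    counts = count_particles_in_window(sim.particles, 30, 200)
    normed = normalize_by_particles(sim.intensities, counts)
    ig_meta, i_meta = sim.ig_meta, sim.intensity_meta
    return full_cascade(
        ig,
        list(ig_meta.index[ig_meta.group == "case"]),
        list(ig_meta.index[ig_meta.group == "control"]),
        cell, sim.cell_meta, normed,
        list(i_meta.index[i_meta.group == "case"]),
        list(i_meta.index[i_meta.group == "control"]),
        evidence=sim.evidence, exclusions=ExclusionLists.default(), thresholds=th,
    )


def test_noise_free_cascade_recovers_planted_set_exactly(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, nb_dispersion=0.0, seed=21)
    sim = simulate_proteomics(cfg)
    report = _run_full_cascade(sim)
    precision, recall = evaluate_recovery(report.survivors, sim.truth)
    assert precision == 1.0 and recall == 1.0
    assert set(report.survivors) == set(sim.truth.antigen_ids)
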