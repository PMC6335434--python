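"""Candidate-antigen selection cascades.

The discovery logic is a sequence of printed filter rules applied to
quantile-normalized spectral counts and particle-normalized MS1 intensities:

* detection in the immunoglobulin-bound fraction (>= 5 normalized MS2 counts),
* a case/control mean-count ratio of 1.5 or greater (Inf qualifies),
* confirmed gene expression in the cell-line panel and the tumor RNA-seq set,
* removal of Ig chains, acute-phase proteins and abundant plasma proteins,
* >1.25-fold surfaceome enrichment versus both cargo and total-extract
  compartments (with >5 counts in at least two of six cell lines),
* >2.5-fold case/control elevation in particle-normalized plasma-exosome
  intensities.

Each rule is logged as a stage of a :class:`FilterCascadeReport`, whose
surviving sets are nested and whose counts are non-increasing by
construction, so the provenance of every surviving candidate is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CELL_COMPARTMENTS, EXOSOME_COMPARTMENTS, Thresholds
from .errors import ConfigurationError, DataError
from .quant import fold_changes_by_group
from .stats import mann_whitney

IG_CHAIN_PREFIXES = ("IGH", "IGK", "IGL", "IGJ")


def _load_symbol_list(name: str) -> frozenset:
    text = resources.files("exoantigen.data").joinpath(name).read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class ExclusionLists:
    """Gene symbols removed from candidate lists regardless of abundance."""

    ig_chain_prefixes: tuple = IG_CHAIN_PREFIXES
    acute_phase: frozenset = frozenset()
    abundant_plasma: frozenset = frozenset()

    @classmethod
    def default(cls) -> "ExclusionLists":
        """Packaged editable lists plus the Ig-chain symbol prefixes."""
        return cls(
            acute_phase=_load_symbol_list("acute_phase_proteins.txt"),
            abundant_plasma=_load_symbol_list("abundant_plasma_proteins.txt"),
        )

    def is_excluded(self, symbol: str) -> bool:
        return (
            symbol.upper().startswith(self.ig_chain_prefixes)
            or symbol in self.acute_phase
            or symbol in self.abundant_plasma
        )


def default_marker_sets() -> tuple[frozenset, frozenset]:
    """(exosome-enriched markers, exosome-depleted endomembrane proteins)."""
    return (
        _load_symbol_list("exosome_markers.txt"),
        _load_symbol_list("depleted_markers.txt"),
    )


@dataclass(frozen=True)
class FilterStage:
    name: str
    rule: str
    threshold: float | str
    n_input: int
    n_surviving: int
    survivors: tuple

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rule": self.rule,
            "threshold": self.threshold,
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "survivors": list(self.survivors),
        }


@dataclass
class FilterCascadeReport:
    """Ordered record of selection rules with nested surviving sets."""

    stages: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def add_stage(self, name: str, rule: str, threshold, survivors: Iterable[str]):
        survivors = tuple(sorted(set(survivors)))
        if self.stages:
            previous = set(self.stages[-1].survivors)
            if not set(survivors) <= previous:
                raise DataError(
                    f"stage {name!r} survivors are not a subset of the previous stage"
                )
            n_input = len(previous)
        else:
            n_input = len(survivors)
        self.stages.append(FilterStage(
            name=name, rule=rule, threshold=threshold,
            n_input=n_input, n_surviving=len(survivors), survivors=survivors,
        ))
        return self.stages[-1]

    @property
    def survivors(self) -> tuple:
        return self.stages[-1].survivors if self.stages else ()

    def counts(self) -> list:
        return [(s.name, s.n_input, s.n_surviving) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "annotations": self.annotations,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def select_detected(
    matrix: pd.DataFrame,
    min_count: float = 5.0,
    min_samples: int = 1,
    strict: bool = False,
    samples: Sequence[str] | None = None,
) -> tuple[set, FilterStage]:
    """Proteins whose count clears ``min_count`` in at least ``min_samples`` columns.

    ``strict`` switches the per-column comparison from inclusive (``>=``,
    "at least five counts") to strict (``>``, ">5 counts"); the two rules are
    distinct in the cascade and must not be conflated.
    """
    if min_samples < 1:
        raise ConfigurationError("min_samples must be at least 1")
    sub = matrix if samples is None else matrix[list(samples)]
    if min_samples > sub.shape[1]:
        raise ConfigurationError(
            f"min_samples={min_samples} exceeds the {sub.shape[1]} columns considered"
        )
    hits = (sub > min_count) if strict else (sub >= min_count)
    selected = set(sub.index[hits.sum(axis=1) >= min_samples])
    op = ">" if strict else ">="
    stage = FilterStage(
        name="detection",
        rule=f"count {op} {min_count} in >= {min_samples} sample(s)",
        threshold=min_count,
        n_input=sub.shape[0],
        n_surviving=len(selected),
        survivors=tuple(sorted(selected)),
    )
    return selected, stage


def confirmed_expression(
    evidence: pd.DataFrame,
    candidates: Iterable[str],
    fpkm_min: float = 1.0,
    tcga_log2_min: float = 1.0,
) -> set:
    """Genes with cell-line and tumor RNA-seq support for expression.

    Default rule: FPKM >= ``fpkm_min`` in at least one profiled cell line AND
    TCGA log2 normalized count >= ``tcga_log2_min``. Candidates missing from
    the evidence table fail (no confirmation available).
    """
    fpkm_cols = [c for c in evidence.columns if c.startswith("fpkm_")]
    if not fpkm_cols or "tcga_log2" not in evidence.columns:
        raise DataError("evidence table needs fpkm_* columns and tcga_log2")
    confirmed = set()
    for gene in candidates:
        if gene not in evidence.index:
            continue
        row = evidence.loc[gene]
        if (row[fpkm_cols] >= fpkm_min).any() and row["tcga_log2"] >= tcga_log2_min:
            confirmed.add(gene)
    return confirmed


def ig_bound_cascade(
    ig_matrix: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    evidence: pd.DataFrame | None = None,
    exclusions: ExclusionLists | None = None,
    thresholds: Thresholds = Thresholds(),
) -> FilterCascadeReport:
    """Prioritize immunoglobulin-bound antigens from pooled case/control counts.

    Stages: inclusive detection (>= min_ms2 in any pool), case/control mean
    ratio >= ig_ratio (Inf passes), expression confirmation (skipped when no
    evidence table is given), and exclusion-list removal. Survivors are
    annotated, without filtering, with whether at least
    ``thresholds.oncomine_min_hits`` external expression datasets reported
    tumor overexpression.
    """
    case_samples, control_samples = list(case_samples), list(control_samples)
    if not case_samples or not control_samples:
        raise DataError("cascade requires at least one case and one control pool")
    report = FilterCascadeReport()

    detected, _ = select_detected(
        ig_matrix, min_count=thresholds.min_ms2,
        min_samples=thresholds.ig_detect_min_pools, strict=False,
    )
    report.add_stage(
        "ig_detection",
        f"count >= {thresholds.min_ms2} normalized MS2 in >= "
        f"{thresholds.ig_detect_min_pools} pool(s)",
        thresholds.min_ms2, detected,
    )

    fc = fold_changes_by_group(ig_matrix.loc[sorted(detected)], case_samples, control_samples)
    ratio_pass = set(fc.index[(fc["ratio"] >= thresholds.ig_ratio) & fc["ratio"].notna()])
    report.add_stage(
        "ig_case_control_ratio",
        f"case/control mean count ratio >= {thresholds.ig_ratio} (Inf qualifies)",
        thresholds.ig_ratio, ratio_pass,
    )

    if evidence is not None:
        expressed = confirmed_expression(
            evidence, ratio_pass,
            fpkm_min=thresholds.fpkm_min, tcga_log2_min=thresholds.tcga_log2_min,
        )
        report.add_stage(
            "expression_confirmation",
            f"FPKM >= {thresholds.fpkm_min} in >= 1 cell line and TCGA log2 "
            f">= {thresholds.tcga_log2_min}",
            thresholds.fpkm_min, expressed,
        )
    if exclusions is not None:
        kept = {g for g in report.survivors if not exclusions.is_excluded(g)}
        report.add_stage(
            "exclusion_lists",
            "remove Ig chains, acute-phase and abundant plasma proteins",
            "membership", kept,
        )

    if evidence is not None and "oncomine_hits" in evidence.columns:
        hits = evidence["oncomine_hits"].reindex(report.survivors).fillna(0)
        report.annotations["overexpressed_in_external_datasets"] = sorted(
            hits.index[hits >= thresholds.oncomine_min_hits]
        )
    return report


def compartment_profiles(
    matrix: pd.DataFrame, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein mean normalized count per compartment across cell lines.

    ``sample_meta`` is indexed by column name with at least ``compartment``
    (and optionally ``cell_line``) columns.
    """
    if "compartment" not in sample_meta.columns:
        raise DataError("sample metadata must carry a 'compartment' column")
    missing = [c for c in matrix.columns if c not in sample_meta.index]
    if missing:
        raise DataError(f"samples without metadata: {missing}")
    groups = sample_meta.loc[matrix.columns, "compartment"]
    return matrix.T.groupby(groups.to_numpy()).mean().T


def compartment_enrichment(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    target: str,
    references: Sequence[str],
    fold: float = 1.25,
    thresholds: Thresholds = Thresholds(),
) -> tuple[set, FilterStage]:
    """Proteins enriched in ``target`` over EVERY reference compartment.

    The rule is a conjunction: the target-compartment mean across cell lines
    must strictly exceed ``fold`` times each reference-compartment mean.
    Candidates must additionally be detected with > min_ms2 counts in at
    least ``cell_line_detect_min_lines`` of the cell lines (strict
    inequality) within the target compartment.
    """
    if fold <= 1:
        raise ConfigurationError("enrichment fold must exceed 1")
    compartments = set(sample_meta["compartment"])
    unknown = ({target} | set(references)) - compartments
    if unknown:
        raise DataError(f"unknown compartment label(s): {sorted(unknown)}")
    if target in references:
        raise ConfigurationError("target compartment cannot be its own reference")

    profiles = compartment_profiles(matrix, sample_meta)
    target_cols = sample_meta.index[sample_meta["compartment"] == target]
    detected, _ = select_detected(
        matrix, min_count=thresholds.min_ms2,
        min_samples=thresholds.cell_line_detect_min_lines, strict=True,
        samples=list(target_cols),
    )
    enriched = detected.copy()
    for ref in references:
        with np.errstate(invalid="ignore"):
            passing = profiles.index[profiles[target] > fold * profiles[ref]]
        enriched &= set(passing)
    stage = FilterStage(
        name=f"{target}_enrichment",
        rule=(f"mean({target}) > {fold} x mean(ref) for all of {list(references)}; "
              f"> {thresholds.min_ms2} counts in >= "
              f"{thresholds.cell_line_detect_min_lines} cell lines"),
        threshold=fold,
        n_input=matrix.shape[0],
        n_surviving=len(enriched),
        survivors=tuple(sorted(enriched)),
    )
    return enriched, stage


def plasma_exosome_elevation(
    normalized_intensities: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    min_samples: int = 2,
    fold: float = 2.5,
) -> tuple[set, FilterStage]:
    """Proteins elevated in case plasma exosomes after particle normalization.

    Detection requires a positive intensity in at least ``min_samples``
    samples overall; elevation requires a case/control mean ratio strictly
    above ``fold``, with Inf (case-only proteins) qualifying.
    """
    case_samples, control_samples = list(case_samples), list(control_samples)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise DataError("need at least two case and two control plasma samples")
    detected = normalized_intensities.index[
        (normalized_intensities > 0).sum(axis=1) >= min_samples
    ]
    fc = fold_changes_by_group(
        normalized_intensities.loc[detected], case_samples, control_samples
    )
    elevated = set(fc.index[(fc["ratio"] > fold) & fc["ratio"].notna()])
    stage = FilterStage(
        name="plasma_exosome_elevation",
        rule=(f"detected in >= {min_samples} samples; particle-normalized "
              f"case/control mean ratio > {fold} (Inf qualifies)"),
        threshold=fold,
        n_input=normalized_intensities.shape[0],
        n_surviving=len(elevated),
        survivors=tuple(sorted(elevated)),
    )
    return elevated, stage


@dataclass(frozen=True)
class MarkerQcReport:
    """Exosome-marker enrichment QC for a compartment-profiled matrix."""

    marker_p: float            # one-sided: markers higher in exosome compartments
    depleted_p: float          # one-sided: depleted set higher in exosome compartments
    missing_markers: tuple
    missing_depleted: tuple
    passed: bool
    marker_means: pd.DataFrame


def marker_qc(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    markers: Iterable[str] | None = None,
    depleted: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> MarkerQcReport:
    """Check that canonical exosome markers are exosome-enriched and the
    endomembrane set is not.

    Per marker, mean counts are formed over exosome compartments and over
    cell compartments; the two per-marker mean vectors are compared by a
    one-sided Mann-Whitney test (exosome greater). QC passes when the marker
    set is significantly enriched and the depleted set is not.
    """
    if markers is None or depleted is None:
        default_markers, default_depleted = default_marker_sets()
        markers = default_markers if markers is None else markers
        depleted = default_depleted if depleted is None else depleted
    markers, depleted = sorted(set(markers)), sorted(set(depleted))
    if not markers:
        raise DataError("marker set is empty")
    profiles = compartment_profiles(matrix, sample_meta)
    exo_comps = [c for c in EXOSOME_COMPARTMENTS if c in profiles.columns]
    cell_comps = [c for c in CELL_COMPARTMENTS if c in profiles.columns]
    if not exo_comps or not cell_comps:
        raise DataError("matrix must cover both exosome and cell compartments")

    def _group_means(symbols):
        present = [s for s in symbols if s in profiles.index]
        missing = tuple(s for s in symbols if s not in profiles.index)
        exo = profiles.loc[present, exo_comps].mean(axis=1)
        cell = profiles.loc[present, cell_comps].mean(axis=1)
        return exo, cell, missing

    exo_m, cell_m, missing_markers = _group_means(markers)
    if exo_m.empty:
        raise DataError(f"none of the markers were found in the data: {markers}")
    marker_p = mann_whitney(exo_m, cell_m, alternative="greater").p_value
    exo_d, cell_d, missing_depleted = _group_means(depleted)
    depleted_p = (
        mann_whitney(exo_d, cell_d, alternative="greater").p_value
        if not exo_d.empty else float("nan")
    )
    passed = (
        marker_p < alpha
        and not missing_markers
        and (np.isnan(depleted_p) or depleted_p >= alpha)
    )
    means = pd.DataFrame({
        "exosome_mean": pd.concat([exo_m, exo_d]),
        "cell_mean": pd.concat([cell_m, cell_d]),
        "set": ["marker"] * len(exo_m) + ["depleted"] * len(exo_d),
    })
    return MarkerQcReport(
        marker_p=float(marker_p), depleted_p=float(depleted_p),
        missing_markers=missing_markers, missing_depleted=missing_depleted,
        passed=bool(passed), marker_means=means,
    )


def full_cascade(
    ig_matrix: pd.DataFrame,
    ig_case: Sequence[str],
    ig_control: Sequence[str],
    cell_matrix: pd.DataFrame,
    cell_meta: pd.DataFrame,
    normalized_intensities: pd.DataFrame,
    plasma_case: Sequence[str],
    plasma_control: Sequence[str],
    evidence: pd.DataFrame | None = None,
    exclusions: ExclusionLists | None = None,
    thresholds: Thresholds = Thresholds(),
) -> FilterCascadeReport:
    """The complete discovery cascade across all three data types.

    Runs the Ig-bound prioritization, then intersects with exosome-surfaceome
    enrichment from the cell-line study, then with plasma-exosome elevation.
    Expression/exclusion stages are included only when their inputs are given.
    """
    report = ig_bound_cascade(
        ig_matrix, ig_case, ig_control,
        evidence=evidence, exclusions=exclusions, thresholds=thresholds,
    )
    enriched, _ = compartment_enrichment(
        cell_matrix, cell_meta, target="exo_surface",
        references=("exo_cargo", "TEE"),
        fold=thresholds.surface_fold, thresholds=thresholds,
    )
    report.add_stage(
        "exosome_surface_enrichment",
        f"exo_surface mean > {thresholds.surface_fold} x mean of exo_cargo and TEE",
        thresholds.surface_fold, set(report.survivors) & enriched,
    )
    elevated, _ = plasma_exosome_elevation(
        normalized_intensities, plasma_case, plasma_control,
        min_samples=thresholds.plasma_min_samples, fold=thresholds.plasma_fold,
    )
    report.add_stage(
        "plasma_exosome_elevation",
        f"particle-normalized case/control ratio > {thresholds.plasma_fold}",
        thresholds.plasma_fold, set(report.survivors) & elevated,
    )
    return report
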