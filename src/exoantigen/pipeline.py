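"""End-to-end orchestration with provenance reporting.

``run_pipeline`` executes every stage whose inputs are present in the input
directory — quantile normalization, marker QC, the Ig-bound cascade,
surfaceome enrichment, plasma elevation, list overlaps, serology merging and
testing, and the decoy dose-response — and collects thresholds, per-stage
survivor counts and summary statistics into a ``ProvenanceReport`` that
round-trips through JSON. Stages with missing inputs are skipped and logged;
skipping never alters the thresholds applied downstream.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cdc import decoy_dose_response
from .config import RunConfig
from .errors import DataError
from .io import read_study
from .quant import count_particles_in_window, normalize_by_particles, quantile_normalize
from .selection import (
    ExclusionLists,
    FilterCascadeReport,
    compartment_enrichment,
    ig_bound_cascade,
    marker_qc,
    plasma_exosome_elevation,
)
from .serology import antigen_performance, standardize_and_merge_sets
from .stats import hypergeometric_overlap

logger = logging.getLogger("exoantigen")


@dataclass
class ProvenanceReport:
    """Serializable record of one pipeline run."""

    version: str
    seed: int
    thresholds: dict
    stages_run: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)
    cascade: dict | None = None
    marker_qc: dict | None = None
    surface_enrichment: dict | None = None
    plasma_elevation: dict | None = None
    overlap: dict | None = None
    serology: dict | None = None
    cdc: dict | None = None
    timestamps: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ProvenanceReport":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_markdown(self) -> str:
        lines = [
            "# Pipeline provenance report",
            "",
            f"- version: {self.version}",
            f"- seed: {self.seed}",
            f"- stages run: {', '.join(self.stages_run) or 'none'}",
            f"- stages skipped: {', '.join(self.stages_skipped) or 'none'}",
            "",
            "## Thresholds",
            "",
        ]
        lines += [f"- {k}: {v}" for k, v in self.thresholds.items()]
        for name in ("cascade", "marker_qc", "surface_enrichment",
                     "plasma_elevation", "overlap", "serology", "cdc"):
            section = getattr(self, name)
            if section is None:
                continue
            lines += ["", f"## {name}", "", "```json",
                      json.dumps(section, indent=2, default=str), "```"]
        return "\n".join(lines) + "\n"


def _group_samples(meta: pd.DataFrame, group: str) -> list:
    return list(meta.index[meta["group"] == group])


def run_pipeline(config: RunConfig) -> ProvenanceReport:
    """Run every stage supported by the files under ``config.input_dir``."""
    thresholds = config.thresholds
    report = ProvenanceReport(
        version=__version__, seed=config.seed, thresholds=thresholds.to_dict()
    )
    report.timestamps["started"] = datetime.datetime.now().isoformat()
    data = read_study(config.input_dir)
    if data["ig_counts"] is not None and data["ig_counts"].empty:
        raise DataError("Ig-bound count matrix is empty")
    if data["cell_counts"] is not None and data["cell_counts"].empty:
        raise DataError("cell-line count matrix is empty")

    def skip(stage: str, why: str) -> None:
        logger.info("skipping %s: %s", stage, why)
        report.stages_skipped.append(stage)

    # --- normalization -----------------------------------------------------
    ig_norm = cell_norm = None
    if data["ig_counts"] is not None:
        ig_norm = quantile_normalize(data["ig_counts"])
    if data["cell_counts"] is not None:
        cell_norm = quantile_normalize(data["cell_counts"])
    if ig_norm is not None or cell_norm is not None:
        report.stages_run.append("quantile_normalization")

    # --- marker QC ----------------------------------------------------------
    if cell_norm is not None and data["cell_meta"] is not None:
        try:
            qc = marker_qc(cell_norm, data["cell_meta"], alpha=thresholds.alpha)
        except DataError as exc:
            skip("marker_qc", str(exc))
        else:
            report.marker_qc = {
                "marker_p": qc.marker_p, "depleted_p": qc.depleted_p,
                "missing_markers": list(qc.missing_markers), "passed": qc.passed,
            }
            report.stages_run.append("marker_qc")
    else:
        skip("marker_qc", "cell-line matrix or metadata absent")

    # --- Ig-bound cascade ----------------------------------------------------
    cascade: FilterCascadeReport | None = None
    if ig_norm is not None and data["ig_meta"] is not None:
        cascade = ig_bound_cascade(
            ig_norm,
            _group_samples(data["ig_meta"], "case"),
            _group_samples(data["ig_meta"], "control"),
            evidence=data["evidence"],
            exclusions=ExclusionLists.default(),
            thresholds=thresholds,
        )
        report.stages_run.append("ig_bound_cascade")
    else:
        skip("ig_bound_cascade", "Ig-bound matrix or metadata absent")

    # --- surfaceome enrichment ----------------------------------------------
    surface_set = None
    if cell_norm is not None and data["cell_meta"] is not None:
        surface_set, stage = compartment_enrichment(
            cell_norm, data["cell_meta"], target="exo_surface",
            references=("exo_cargo", "TEE"),
            fold=thresholds.surface_fold, thresholds=thresholds,
        )
        report.surface_enrichment = stage.to_dict()
        report.stages_run.append("surface_enrichment")
        if cascade is not None:
            cascade.add_stage(
                "exosome_surface_enrichment", stage.rule, stage.threshold,
                set(cascade.survivors) & surface_set,
            )
    else:
        skip("surface_enrichment", "cell-line matrix or metadata absent")

    # --- plasma elevation -----------------------------------------------------
    elevated = None
    if (data["intensities"] is not None and data["intensity_meta"] is not None
            and data["particles"] is not None):
        window = thresholds.particle_window_nm
        counts = count_particles_in_window(data["particles"], *window)
        normalized = normalize_by_particles(data["intensities"], counts)
        elevated, stage = plasma_exosome_elevation(
            normalized,
            _group_samples(data["intensity_meta"], "case"),
            _group_samples(data["intensity_meta"], "control"),
            min_samples=thresholds.plasma_min_samples,
            fold=thresholds.plasma_fold,
        )
        report.plasma_elevation = stage.to_dict()
        report.stages_run.append("plasma_elevation")
        if cascade is not None:
            cascade.add_stage(
                "plasma_exosome_elevation", stage.rule, stage.threshold,
                set(cascade.survivors) & elevated,
            )
    else:
        skip("plasma_elevation", "intensities, metadata or particle table absent")

    if cascade is not None:
        report.cascade = cascade.to_dict()

    # --- overlap of Ig-bound candidates with plasma-exosome proteome ----------
    if cascade is not None and elevated is not None:
        names = [s.name for s in cascade.stages]
        base = ("exclusion_lists" if "exclusion_lists" in names
                else "ig_case_control_ratio")
        ig_survivors = set(cascade.stages[names.index(base)].survivors)
        detected_plasma = elevated
        overlap = hypergeometric_overlap(
            len(ig_survivors & detected_plasma), len(ig_survivors),
            len(detected_plasma), thresholds.universe_size,
        )
        report.overlap = dataclasses.asdict(overlap)
        report.stages_run.append("overlap")
    else:
        skip("overlap", "needs both the Ig-bound cascade and plasma elevation")

    # --- serology --------------------------------------------------------------
    if data["serology"] is not None:
        merged = standardize_and_merge_sets(data["serology"])
        perf = antigen_performance(merged)
        report.serology = {
            "n_antigens": int(perf.shape[0]),
            "n_auc_above_0.6": int((perf["auc"] > 0.6).sum()),
            "top": perf.head(10).to_dict(orient="records"),
        }
        report.stages_run.append("serology")
    else:
        skip("serology", "serology table absent")

    # --- CDC decoy -------------------------------------------------------------
    if data["cdc"] is not None:
        decoy = decoy_dose_response(data["cdc"], readout="absorbance",
                                    seed=config.seed)
        report.cdc = decoy.to_dict()
        report.stages_run.append("cdc_decoy")
    else:
        skip("cdc_decoy", "CDC table absent")

    report.timestamps["finished"] = datetime.datetime.now().isoformat()
    return report


def write_report(report: ProvenanceReport, out_dir: str | Path) -> Path:
    """JSON + Markdown renderings plus per-stage cascade TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / "provenance.json")
    (out / "provenance.md").write_text(report.to_markdown())
    if report.cascade is not None:
        rows = [
            {k: v for k, v in stage.items() if k != "survivors"}
            for stage in report.cascade["stages"]
        ]
        pd.DataFrame(rows).to_csv(out / "cascade_stages.tsv", sep="\t", index=False)
    return out
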