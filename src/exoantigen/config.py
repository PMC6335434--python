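"""Configuration objects for the synthetic study and the analysis pipeline.

``SimulationConfig`` pins down every knob of the synthetic multi-compartment
study (cohort sizes, planted effect sizes, noise levels); ``Thresholds`` and
``RunConfig`` carry the selection-rule cutoffs used throughout the filter
cascades. Both are plain dataclasses loadable from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError

#: The five proteomic compartments profiled per cell line: total cell
#: extract, biotinylated cell surface, total exosome extract, exosome
#: surfaceome, and exosome cargo (column flow-through).
COMPARTMENTS = ("TCE", "cell_surface", "TEE", "exo_surface", "exo_cargo")

#: Compartments belonging to exosomes vs. whole cells, used by marker QC.
EXOSOME_COMPARTMENTS = ("TEE", "exo_surface", "exo_cargo")
CELL_COMPARTMENTS = ("TCE", "cell_surface")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic antigen-discovery study.

    The defaults mirror the structure of a six-cell-line exosome profiling
    study with pooled immunoglobulin-bound plasma fractions, six case and six
    control plasma-exosome samples, three serology cohorts, and a
    dose-response complement-cytotoxicity experiment.

    Count noise follows a negative binomial whose dispersion parameter is
    the biological coefficient of variation of the latent abundance
    (``var = mu + (d * mu)**2`` with ``d = nb_dispersion``); ``d = 0`` is
    treated as the exact noise-free limit (counts equal their expectations).
    """

    n_proteins: int = 2000
    n_planted_antigens: int = 25
    n_cell_lines: int = 6
    compartments: Sequence[str] = COMPARTMENTS
    n_case_pools: int = 8
    n_control_pools: int = 8
    surface_fold: float = 2.0       # planted surface/cargo enrichment
    case_ratio: float = 3.0         # planted Ig-bound and plasma case/control ratio
    nb_dispersion: float = 0.2
    baseline_mean_counts: float = 30.0
    intensity_sigma: float = 0.15   # log-normal scale of MS1 intensities
    particle_mean_nm: float = 110.0  # plasma exosome diameter
    particle_sd_nm: float = 16.0
    cell_line_particle_mean_nm: float = 82.0
    cell_line_particle_sd_nm: float = 3.0
    n_tracked_particles: int = 1500
    n_plasma_cases: int = 6
    n_plasma_controls: int = 6
    n_unique_to_case: int = 3       # planted antigens absent from control plasma
    include_contaminants: bool = True
    n_expression_lines: int = 11

    # serology cohorts: (cases, healthy, pancreatitis) per set
    serology_set_sizes: Sequence[Sequence[int]] = ((10, 10, 10), (13, 13, 0), (42, 50, 50))
    serology_set_locations: Sequence[float] = (1000.0, 3000.0, 500.0)
    serology_set_scales: Sequence[float] = (200.0, 600.0, 120.0)
    serology_effect: float = 2.0    # planted case shift, healthy-control SD units
    n_serology_background: int = 25

    # complement-dependent cytotoxicity experiment
    decoy_strength: float = 1.0     # per-microgram inhibition coefficient
    cdc_doses: Sequence[float] = (0.0, 1.0, 2.5)
    cdc_replicates: int = 3
    cdc_noise: float = 0.05         # relative (fraction-of-signal) noise SD
    cdc_baseline_cytotoxicity: float = 40.0  # percent lysis at dose 0

    seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = {
            "n_proteins": self.n_proteins,
            "n_planted_antigens": self.n_planted_antigens,
            "n_cell_lines": self.n_cell_lines,
            "n_case_pools": self.n_case_pools,
            "n_control_pools": self.n_control_pools,
            "n_tracked_particles": self.n_tracked_particles,
            "n_plasma_cases": self.n_plasma_cases,
            "n_plasma_controls": self.n_plasma_controls,
            "cdc_replicates": self.cdc_replicates,
        }
        for name, value in positive_ints.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_planted_antigens > self.n_proteins:
            raise ConfigurationError("n_planted_antigens cannot exceed n_proteins")
        if self.n_unique_to_case > self.n_planted_antigens:
            raise ConfigurationError("n_unique_to_case cannot exceed n_planted_antigens")
        if len(set(self.compartments)) != len(self.compartments):
            raise ConfigurationError("compartment labels must be unique")
        if self.surface_fold <= 1:
            raise ConfigurationError("surface_fold must exceed 1")
        if self.case_ratio <= 1:
            raise ConfigurationError("case_ratio must exceed 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.baseline_mean_counts <= 0:
            raise ConfigurationError("baseline_mean_counts must be positive")
        if self.intensity_sigma < 0:
            raise ConfigurationError("intensity_sigma must be non-negative")
        if self.decoy_strength < 0:
            raise ConfigurationError("decoy_strength must be non-negative")
        if len(self.cdc_doses) < 2 or 0.0 not in tuple(self.cdc_doses):
            raise ConfigurationError("cdc_doses needs at least two doses including 0")
        if any(d < 0 for d in self.cdc_doses):
            raise ConfigurationError("exosome doses must be non-negative")
        if len(self.serology_set_sizes) < 2:
            raise ConfigurationError("at least two serology sets are required")
        for i, (n_case, n_healthy, n_panc) in enumerate(self.serology_set_sizes, start=1):
            if n_healthy < 3:
                raise ConfigurationError(
                    f"serology set #{i} has {n_healthy} healthy controls; at least 3 required"
                )
            if n_case < 1 or n_panc < 0:
                raise ConfigurationError(f"invalid group sizes in serology set #{i}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["compartments"] = list(self.compartments)
        d["serology_set_sizes"] = [list(s) for s in self.serology_set_sizes]
        for key in ("serology_set_locations", "serology_set_scales", "cdc_doses"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class Thresholds:
    """Selection-rule cutoffs, all overridable and echoed into reports.

    Inequality strictness matters and is enforced exactly as stated by each
    rule: Ig-bound detection is inclusive (>= min_ms2 counts), cell-line
    detection is strict (> min_ms2 in >= 2 lines), fold-change rules on the
    ratio side are "1.5 or greater" (inclusive) for the Ig-bound ratio and
    strict for the >1.25 surface and >2.5 plasma rules.
    """

    min_ms2: float = 5.0
    ig_detect_min_pools: int = 1
    cell_line_detect_min_lines: int = 2
    ig_ratio: float = 1.5
    surface_fold: float = 1.25
    plasma_fold: float = 2.5
    plasma_min_samples: int = 2
    ig_chain_fold: float = 3.5
    ic50_nm: float = 500.0
    peptide_min_len: int = 12
    peptide_max_len: int = 34
    particle_window_nm: Sequence[float] = (30.0, 200.0)
    universe_size: int = 17611
    fpkm_min: float = 1.0
    tcga_log2_min: float = 1.0
    oncomine_min_hits: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_ms2", "ig_ratio", "surface_fold", "plasma_fold",
                     "ig_chain_fold", "ic50_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        low, high = self.particle_window_nm
        if not 0 < low < high:
            raise ConfigurationError("particle window must satisfy 0 < low < high")
        if self.peptide_min_len > self.peptide_max_len:
            raise ConfigurationError("peptide_min_len must not exceed peptide_max_len")
        if self.universe_size < 1:
            raise ConfigurationError("universe_size must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["particle_window_nm"] = list(self.particle_window_nm)
        return d


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run: where inputs live, cutoffs, seed, outputs."""

    input_dir: Path
    output_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        try:
            input_dir = Path(raw.pop("input_dir"))
            output_dir = Path(raw.pop("output_dir"))
        except KeyError as exc:
            raise ConfigurationError(f"run config missing required key: {exc}") from exc
        seed = int(raw.pop("seed", 0))
        if raw:
            raise ConfigurationError(f"unknown run config keys: {sorted(raw)}")
        return cls(input_dir=input_dir, output_dir=output_dir,
                   thresholds=thresholds, seed=seed)
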