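"""Synthetic multi-compartment antigen-discovery study with planted truth.

The generator emulates the structure of the real study at desk scale:

* six cell lines profiled over five compartments (total cell extract, cell
  surface, total exosome extract, exosome surfaceome, exosome cargo) with
  negative-binomial MS2 spectral counts;
* pooled immunoglobulin-bound case/control plasma fractions;
* plasma-exosome MS1 intensities for individual case/control samples with
  nanoparticle-tracking diameter tables supplying per-sample particle
  denominators;
* three protein-microarray serology cohorts with set-specific location and
  scale shifts;
* a complement-cytotoxicity experiment where exosome dose inhibits lysis
  through a saturating decoy model ``cytotoxicity(dose) = c0 / (1 + s*dose)``.

A configurable number of planted antigens carry a surface-enrichment fold,
an immunoglobulin-bound and plasma case/control ratio, and a serology case
effect; a subset is additionally absent from control plasma to exercise the
"Inf" fold-change path, and a handful of contaminant proteins (Ig chains,
abundant plasma proteins) are case-elevated without surface enrichment to
exercise the exclusion stage. Ground truth is returned so recovery can be
scored exactly.

Count noise: Gamma-Poisson (negative binomial) with the dispersion parameter
interpreted as the biological coefficient of variation, so
``var = mu + (d*mu)**2``. ``d = 0`` is implemented as the exact noise-free
limit: every readout equals its expectation, so planted ratios are recovered
bit-exactly. All randomness flows from one master seed
through per-stage child generators keyed by stage name, so adding a stage
never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import CELL_COMPARTMENTS, EXOSOME_COMPARTMENTS, SimulationConfig
from .errors import ConfigurationError
from .quant import count_particles_in_window

PARTICLE_WINDOW_NM = (30.0, 200.0)

#: Contaminant symbols planted when include_contaminants is on: Ig chains
#: (case-elevated, as in real Ig-bound fractions) plus acute-phase/abundant
#: plasma proteins; none is surface-enriched and all sit on exclusion lists.
CONTAMINANT_SYMBOLS = ("IGKC", "IGHG1", "IGHG3", "IGLC2", "ALB", "CRP", "HP", "FGA")

#: Canonical exosome markers (enriched in exosome compartments) and
#: endomembrane proteins (enriched in cell compartments), included so the
#: marker-panel QC has something to measure. Neither set is case-elevated.
MARKER_SYMBOLS = ("CD81", "CD9", "FLOT1", "FLOT2", "PDCD6IP", "SDCBP", "TSG101")
DEPLETED_SYMBOLS = ("CANX", "CYC1", "GOLGA2", "HSP90B1")
MARKER_COMPARTMENT_FOLD = 5.0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator derived deterministically from (master seed, stage name)."""
    digest = hashlib.sha256(stage.encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), child]))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
               integer: bool = True) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws around ``mean``.

    ``dispersion`` is the biological coefficient of variation of the latent
    abundance (the square root of the quadratic NB dispersion), so the
    marginal variance is ``mu + (dispersion*mu)**2`` and the extra-Poisson
    noise vanishes proportionally as dispersion -> 0. Exactly 0 is the
    deterministic limit: the expectations themselves are returned, making
    planted fold changes recoverable bit-exactly.
    """
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ConfigurationError("negative mean count requested")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be non-negative")
    if dispersion == 0:
        return mean.copy()
    r = 1.0 / dispersion**2
    p = r / (r + mean)
    draws = rng.negative_binomial(r, p)
    return draws.astype(float) if not integer else draws


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted effects, for recovery scoring."""

    antigen_ids: tuple
    unique_to_case_ids: tuple      # absent from control plasma (Inf path)
    contaminant_ids: tuple
    surface_fold: float
    case_ratio: float
    serology_effect: float
    decoy_strength: float

    def to_dict(self) -> dict:
        return {
            "antigen_ids": list(self.antigen_ids),
            "unique_to_case_ids": list(self.unique_to_case_ids),
            "contaminant_ids": list(self.contaminant_ids),
            "surface_fold": self.surface_fold,
            "case_ratio": self.case_ratio,
            "serology_effect": self.serology_effect,
            "decoy_strength": self.decoy_strength,
        }


@dataclass(frozen=True)
class SimulatedProteomics:
    """All proteomic tables of one synthetic study."""

    cell_counts: pd.DataFrame      # protein x (cell line, compartment)
    cell_meta: pd.DataFrame        # sample_id -> cell_line, compartment, group
    ig_counts: pd.DataFrame        # protein x Ig-bound pool
    ig_meta: pd.DataFrame
    intensities: pd.DataFrame      # protein x plasma sample (MS1)
    intensity_meta: pd.DataFrame
    particles: pd.DataFrame        # long form: sample_id, diameter_nm
    evidence: pd.DataFrame         # gene expression evidence per protein
    truth: PlantedTruth


def _special_symbols(config: SimulationConfig) -> tuple:
    symbols = MARKER_SYMBOLS + DEPLETED_SYMBOLS
    if config.include_contaminants:
        symbols = symbols + CONTAMINANT_SYMBOLS
    return symbols


def protein_ids(config: SimulationConfig) -> list:
    """Deterministic protein identifier list; markers, endomembrane proteins
    and contaminants replace the tail of the generic symbols."""
    n = config.n_proteins
    ids = [f"GENE{i:05d}" for i in range(1, n + 1)]
    special = _special_symbols(config)
    n_special = min(len(special), n - config.n_planted_antigens)
    for j, symbol in enumerate(special[:n_special]):
        ids[n - n_special + j] = symbol
    return ids


def planted_ids(config: SimulationConfig) -> tuple:
    """Planted antigen identifiers, a seed-determined sample of the eligible ids."""
    ids = protein_ids(config)
    n_special = sum(1 for i in ids if i in _special_symbols(config))
    eligible = ids[: len(ids) - n_special]
    rng = stage_rng(config.seed, "planted")
    chosen = rng.choice(len(eligible), size=config.n_planted_antigens, replace=False)
    return tuple(eligible[i] for i in sorted(chosen))


def _baseline_means(config: SimulationConfig, ids: list, planted: tuple) -> pd.Series:
    """Per-protein baseline abundance (expected control spectral counts).

    Background proteins span a broad log-normal dynamic range; planted
    antigens and contaminants are seeded near the scale center so the ground
    truth consists of detectable proteins, as in any discovery set.
    """
    rng = stage_rng(config.seed, "baselines")
    base = config.baseline_mean_counts
    lam = base * rng.lognormal(mean=0.0, sigma=0.75, size=len(ids))
    lam = pd.Series(lam, index=ids)
    special = list(planted) + [i for i in ids if i in _special_symbols(config)]
    lam.loc[special] = base * rng.lognormal(mean=0.0, sigma=0.25, size=len(special))
    return lam


def simulate_proteomics(config: SimulationConfig) -> SimulatedProteomics:
    """Generate the full proteomic arm of the synthetic study."""
    ids = protein_ids(config)
    planted = planted_ids(config)
    contaminants = tuple(i for i in ids if i in CONTAMINANT_SYMBOLS)
    unique_to_case = planted[: config.n_unique_to_case]
    lam = _baseline_means(config, ids, planted)
    is_planted = pd.Series(False, index=ids)
    is_planted[list(planted)] = True
    is_case_elevated = is_planted.copy()
    is_case_elevated[list(contaminants)] = True
    d = config.nb_dispersion

    # --- cell-line compartment matrix -------------------------------------
    rng = stage_rng(config.seed, "cell_lines")
    lines = [f"line{i}" for i in range(1, config.n_cell_lines + 1)]
    columns, means = [], []
    surface_compartments = ("exo_surface", "cell_surface")
    is_marker = pd.Series(np.isin(ids, MARKER_SYMBOLS), index=ids)
    is_depleted = pd.Series(np.isin(ids, DEPLETED_SYMBOLS), index=ids)
    meta_rows = []
    for line in lines:
        for comp in config.compartments:
            comp_factor = np.where(
                is_planted.to_numpy() & (comp in surface_compartments),
                config.surface_fold, 1.0,
            )
            if comp in EXOSOME_COMPARTMENTS:
                comp_factor = np.where(
                    is_marker.to_numpy(), MARKER_COMPARTMENT_FOLD, comp_factor
                )
            if comp in CELL_COMPARTMENTS:
                comp_factor = np.where(
                    is_depleted.to_numpy(), MARKER_COMPARTMENT_FOLD, comp_factor
                )
            columns.append(f"{line}|{comp}")
            means.append(lam.to_numpy() * comp_factor)
            meta_rows.append({"sample_id": f"{line}|{comp}", "cell_line": line,
                              "compartment": comp, "group": "cell_line"})
    mean_matrix = np.column_stack(means)
    cell_counts = pd.DataFrame(
        _nb_counts(rng, mean_matrix, d), index=ids, columns=columns
    )
    cell_meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # --- Ig-bound pools ----------------------------------------------------
    rng = stage_rng(config.seed, "ig_pools")
    ig_cols, ig_means, ig_meta_rows = [], [], []
    for i in range(1, config.n_case_pools + 1):
        ig_cols.append(f"case_pool{i}")
        ig_means.append(lam.to_numpy() * np.where(is_case_elevated, config.case_ratio, 1.0))
        ig_meta_rows.append({"sample_id": ig_cols[-1], "pool": ig_cols[-1],
                             "compartment": "ig_bound", "group": "case"})
    for i in range(1, config.n_control_pools + 1):
        ig_cols.append(f"control_pool{i}")
        ig_means.append(lam.to_numpy())
        ig_meta_rows.append({"sample_id": ig_cols[-1], "pool": ig_cols[-1],
                             "compartment": "ig_bound", "group": "control"})
    ig_counts = pd.DataFrame(
        _nb_counts(rng, np.column_stack(ig_means), d), index=ids, columns=ig_cols
    )
    ig_meta = pd.DataFrame(ig_meta_rows).set_index("sample_id")

    # --- plasma-exosome particle tables -----------------------------------
    rng = stage_rng(config.seed, "particles")
    plasma_samples = (
        [f"plasma_case{i}" for i in range(1, config.n_plasma_cases + 1)]
        + [f"plasma_control{i}" for i in range(1, config.n_plasma_controls + 1)]
    )
    particle_rows = []
    for sample in plasma_samples:
        n_tracked = int(rng.poisson(config.n_tracked_particles)) if d > 0 \
            else config.n_tracked_particles
        diam = rng.normal(config.particle_mean_nm, config.particle_sd_nm, size=n_tracked)
        diam = np.abs(diam)  # reflect the rare negative draw
        particle_rows.append(pd.DataFrame({"sample_id": sample, "diameter_nm": diam}))
    particles = pd.concat(particle_rows, ignore_index=True)
    window_counts = count_particles_in_window(particles, *PARTICLE_WINDOW_NM)

    # --- plasma-exosome MS1 intensities -----------------------------------
    # Raw intensities scale with each sample's exosome yield (its in-window
    # particle count), which particle normalization later removes exactly.
    rng = stage_rng(config.seed, "intensities")
    sigma = config.intensity_sigma if d > 0 else 0.0
    base_intensity = lam.to_numpy() * 1.0e4 / config.baseline_mean_counts
    intensity_cols = {}
    meta_rows = []
    for sample in plasma_samples:
        is_case = sample.startswith("plasma_case")
        effect = np.where(is_case_elevated, config.case_ratio, 1.0) if is_case \
            else np.ones(len(ids))
        if not is_case:
            zero_mask = np.isin(ids, unique_to_case)
            effect = np.where(zero_mask, 0.0, effect)
        noise = np.exp(rng.normal(0.0, sigma, size=len(ids))) if sigma > 0 else 1.0
        scale = window_counts[sample] / config.n_tracked_particles
        intensity_cols[sample] = base_intensity * effect * noise * scale
        meta_rows.append({"sample_id": sample, "compartment": "plasma_exosome",
                          "group": "case" if is_case else "control"})
    intensities = pd.DataFrame(intensity_cols, index=ids)
    intensity_meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # --- expression evidence ----------------------------------------------
    rng = stage_rng(config.seed, "evidence")
    expressed = rng.random(len(ids)) < 0.9
    expressed |= is_case_elevated.to_numpy()  # planted truth is always expressed
    n_lines = config.n_expression_lines
    fpkm = np.where(
        expressed[:, None],
        rng.lognormal(np.log(20.0), 1.0, size=(len(ids), n_lines)),
        rng.lognormal(np.log(0.05), 0.5, size=(len(ids), n_lines)),
    )
    tcga = np.where(
        expressed,
        rng.normal(8.0, 1.5, size=len(ids)).clip(min=1.5),
        rng.normal(0.3, 0.2, size=len(ids)).clip(min=0.0),
    )
    hits = np.where(
        is_planted.to_numpy(),
        rng.binomial(8, 0.6, size=len(ids)),
        rng.binomial(8, 0.15, size=len(ids)),
    )
    evidence = pd.DataFrame(
        fpkm, index=ids, columns=[f"fpkm_line{i}" for i in range(1, n_lines + 1)]
    )
    evidence["tcga_log2"] = tcga
    evidence["oncomine_hits"] = hits

    truth = PlantedTruth(
        antigen_ids=planted, unique_to_case_ids=tuple(unique_to_case),
        contaminant_ids=contaminants,
        surface_fold=config.surface_fold, case_ratio=config.case_ratio,
        serology_effect=config.serology_effect, decoy_strength=config.decoy_strength,
    )
    return SimulatedProteomics(
        cell_counts=cell_counts, cell_meta=cell_meta,
        ig_counts=ig_counts, ig_meta=ig_meta,
        intensities=intensities, intensity_meta=intensity_meta,
        particles=particles, evidence=evidence, truth=truth,
    )


def simulate_serology(config: SimulationConfig) -> pd.DataFrame:
    """Three-cohort protein-array study in long form.

    Each set applies its own location/scale transform to a shared latent
    reactivity scale on which planted antigens carry a ``serology_effect``-SD
    case shift; chronic-pancreatitis samples behave like controls. Columns:
    ``antigen_id, sample_id, intensity, set, group``.
    """
    rng = stage_rng(config.seed, "serology")
    planted = planted_ids(config)
    ids = protein_ids(config)
    n_cont = len(CONTAMINANT_SYMBOLS) if config.include_contaminants else 0
    background_pool = [i for i in ids[: len(ids) - n_cont] if i not in set(planted)]
    background = list(rng.choice(
        background_pool, size=min(config.n_serology_background, len(background_pool)),
        replace=False,
    ))
    antigens = list(planted) + background
    antigen_offset = rng.normal(0.0, 0.5, size=len(antigens))
    rows = []
    for s, ((n_case, n_healthy, n_panc), loc, scale) in enumerate(
        zip(config.serology_set_sizes, config.serology_set_locations,
            config.serology_set_scales), start=1,
    ):
        groups = (["case"] * n_case + ["healthy"] * n_healthy
                  + ["pancreatitis"] * n_panc)
        for j, group in enumerate(groups, start=1):
            sample = f"set{s}_{group}{j:02d}"
            latent = antigen_offset + rng.normal(0.0, 1.0, size=len(antigens))
            if group == "case":
                latent = latent + np.where(
                    np.isin(antigens, planted), config.serology_effect, 0.0
                )
            intensity = loc + scale * latent
            rows.append(pd.DataFrame({
                "antigen_id": antigens, "sample_id": sample,
                "intensity": intensity, "set": f"set{s}", "group": group,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_cdc(config: SimulationConfig) -> pd.DataFrame:
    """Dose-titrated CDC experiment, tidy per-well table with both readouts.

    Cytotoxicity follows the saturating decoy model
    ``cyto(dose) = c0 / (1 + decoy_strength * dose)`` (percent lysis). Plate
    wells report absorbance (spontaneous wells define 100% viability; total
    lysis wells bound the assay); imaging wells report dead-cell counts with
    the complement-only background included per dose. Multiplicative noise
    with relative SD ``cdc_noise`` perturbs every well independently.
    """
    if any(dose < 0 for dose in config.cdc_doses):
        raise ConfigurationError("exosome doses must be non-negative")
    rng = stage_rng(config.seed, "cdc")
    c0 = config.cdc_baseline_cytotoxicity
    a0 = 1.2               # spontaneous-well absorbance, arbitrary units
    dead_background = 50.0  # complement-only dead cells per field
    dead_gain = 1000.0      # dead cells per 100% cytotoxicity

    def jitter(size=None):
        if config.cdc_noise == 0:
            return 1.0 if size is None else np.ones(size)
        return 1.0 + rng.normal(0.0, config.cdc_noise, size=size)

    rows = []
    for dose in config.cdc_doses:
        cyto = c0 / (1.0 + config.decoy_strength * dose)
        for rep in range(1, config.cdc_replicates + 1):
            spont = a0 * jitter()
            exp_abs = a0 * (1.0 - cyto / 100.0) * jitter()
            rows += [
                {"serum_group": "case", "dose_ug": dose, "replicate": rep,
                 "time_h": 2.0, "readout_type": "absorbance", "value": spont,
                 "well_role": "spontaneous"},
                {"serum_group": "case", "dose_ug": dose, "replicate": rep,
                 "time_h": 2.0, "readout_type": "absorbance", "value": exp_abs,
                 "well_role": "experimental"},
                {"serum_group": "case", "dose_ug": dose, "replicate": rep,
                 "time_h": 2.0, "readout_type": "absorbance",
                 "value": 0.08 * a0 * jitter(), "well_role": "total_lysis"},
            ]
            dead_spont = dead_background * jitter()
            dead_exp = (dead_background + dead_gain * cyto / 100.0) * jitter()
            rows += [
                {"serum_group": "case", "dose_ug": dose, "replicate": rep,
                 "time_h": 6.0, "readout_type": "dead_count",
                 "value": float(np.rint(dead_spont)), "well_role": "spontaneous"},
                {"serum_group": "case", "dose_ug": dose, "replicate": rep,
                 "time_h": 6.0, "readout_type": "dead_count",
                 "value": float(np.rint(dead_exp)), "well_role": "experimental"},
            ]
    return pd.DataFrame(rows)


def evaluate_recovery(selected: Iterable[str], truth: PlantedTruth) -> tuple[float, float]:
    """(precision, recall) of a selected set against the planted antigens."""
    selected = set(selected)
    planted = set(truth.antigen_ids)
    if not selected:
        return (float("nan"), 0.0)
    tp = len(selected & planted)
    return tp / len(selected), tp / len(planted)
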