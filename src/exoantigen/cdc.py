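"""Complement-dependent cytotoxicity (CDC) readouts and decoy dose-response.

Tumor-derived exosomes displaying surface antigens can sequester cytotoxic
autoantibodies, attenuating complement-mediated lysis of tumor cells. The
experiment titrates exosome dose into serum + complement wells and measures
either plate-reader viability (absorbance relative to antibody-independent
spontaneous-lysis wells) or live-imaging dead-cell counts (spontaneous
counts subtracted, expressed as fold change versus the no-exosome control).
Dose dependence is assessed both by pairwise unpaired t-tests against dose 0
and by a seeded permutation test on the Spearman correlation of dose with
cytotoxicity, since pairwise tests alone do not establish a trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss

from .errors import DataError
from .stats import t_test_unpaired

EPSILON = 1e-9

WELL_ROLES = ("experimental", "spontaneous", "control", "control_spontaneous",
              "total_lysis")


def percent_viability(experimental: float, spontaneous: float) -> float:
    """(experimental / spontaneous) x 100; may exceed 100."""
    experimental = float(experimental)
    spontaneous = float(spontaneous)
    if spontaneous <= 0:
        raise DataError(f"spontaneous absorbance must be positive, got {spontaneous}")
    if experimental < 0:
        raise DataError("experimental absorbance must be non-negative")
    return 100.0 * experimental / spontaneous


def live_imaging_cytotoxicity(
    dead_exp: float,
    dead_spont: float,
    dead_ctrl: float,
    dead_ctrl_spont: float,
    eps: float = EPSILON,
) -> float:
    """Background-subtracted dead-cell fold change versus the no-exosome control.

    Spontaneous (complement-only) dead-cell counts are subtracted from both
    the experimental condition and the serum-plus-complement control;
    negative differences are floored at 0 and a zero control difference is
    guarded by ``eps`` with a warning. The control condition itself scores 1.
    """
    numerator = max(float(dead_exp) - float(dead_spont), 0.0)
    denominator = float(dead_ctrl) - float(dead_ctrl_spont)
    if denominator <= 0:
        warnings.warn(
            "control dead-cell count does not exceed its spontaneous well; "
            "denominator floored at eps"
        )
        denominator = eps
    return numerator / denominator


@dataclass(frozen=True)
class DecoyResult:
    """Per-dose cytotoxicity estimates and dose-dependence tests."""

    doses: tuple
    cytotoxicity_mean: tuple       # per dose, percent (plate) or fold (imaging)
    cytotoxicity_sd: tuple
    pairwise_p: dict               # dose -> unpaired t-test p vs dose 0
    trend_rho: float               # Spearman rho of dose vs per-well cytotoxicity
    trend_p: float                 # one-sided permutation p for a decreasing trend
    monotone_decreasing: bool
    per_well: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "doses": list(self.doses),
            "cytotoxicity_mean": list(self.cytotoxicity_mean),
            "cytotoxicity_sd": list(self.cytotoxicity_sd),
            "pairwise_p_vs_dose0": {str(k): v for k, v in self.pairwise_p.items()},
            "trend_rho": self.trend_rho,
            "trend_p": self.trend_p,
            "monotone_decreasing": self.monotone_decreasing,
        }


def _plate_cytotoxicity(experiment: pd.DataFrame) -> pd.DataFrame:
    """Per-(dose, replicate) percent cytotoxicity from absorbance wells."""
    rows = []
    sub = experiment[experiment["readout_type"] == "absorbance"]
    for (dose, rep), block in sub.groupby(["dose_ug", "replicate"]):
        exp_wells = block.loc[block["well_role"] == "experimental", "value"]
        spont_wells = block.loc[block["well_role"] == "spontaneous", "value"]
        if exp_wells.empty:
            continue
        if spont_wells.empty:
            raise DataError(f"missing spontaneous well for dose {dose}, replicate {rep}")
        viability = percent_viability(exp_wells.mean(), spont_wells.mean())
        rows.append({"dose_ug": dose, "replicate": rep,
                     "cytotoxicity": 100.0 - viability})
    return pd.DataFrame(rows)


def _imaging_cytotoxicity(experiment: pd.DataFrame) -> pd.DataFrame:
    """Per-(dose, replicate) dead-cell fold change versus the dose-0 control."""
    sub = experiment[experiment["readout_type"] == "dead_count"]
    ctrl = sub[sub["dose_ug"] == 0]
    ctrl_exp = ctrl.loc[ctrl["well_role"] == "experimental", "value"]
    ctrl_spont = ctrl.loc[ctrl["well_role"] == "spontaneous", "value"]
    if ctrl_exp.empty or ctrl_spont.empty:
        raise DataError("imaging analysis requires dose-0 control and spontaneous wells")
    dead_ctrl, dead_ctrl_spont = ctrl_exp.mean(), ctrl_spont.mean()
    rows = []
    for (dose, rep), block in sub.groupby(["dose_ug", "replicate"]):
        exp_wells = block.loc[block["well_role"] == "experimental", "value"]
        spont_wells = block.loc[block["well_role"] == "spontaneous", "value"]
        if exp_wells.empty:
            continue
        if spont_wells.empty:
            raise DataError(f"missing spontaneous well for dose {dose}, replicate {rep}")
        fold = live_imaging_cytotoxicity(
            exp_wells.mean(), spont_wells.mean(), dead_ctrl, dead_ctrl_spont
        )
        rows.append({"dose_ug": dose, "replicate": rep, "cytotoxicity": fold})
    return pd.DataFrame(rows)


def decoy_dose_response(
    experiment: pd.DataFrame,
    readout: str = "absorbance",
    n_permutations: int = 999,
    seed: int | None = None,
) -> DecoyResult:
    """Quantify dose-dependent inhibition of CDC by titrated exosomes.

    ``experiment`` is tidy with columns ``dose_ug, replicate, readout_type,
    value, well_role``. Per-well cytotoxicity is 100 - percent viability for
    plate assays, or the background-subtracted dead-cell fold change for
    imaging. Reported are per-dose means and SDs, Welch t-tests of each dose
    against dose 0, a one-sided permutation p-value for a decreasing
    Spearman trend of cytotoxicity with dose, and a monotonicity flag.
    """
    required = {"dose_ug", "replicate", "readout_type", "value", "well_role"}
    missing = required - set(experiment.columns)
    if missing:
        raise DataError(f"experiment table missing column(s): {sorted(missing)}")
    if (experiment["dose_ug"] < 0).any():
        raise DataError("exosome doses must be non-negative")
    per_well = (
        _plate_cytotoxicity(experiment) if readout == "absorbance"
        else _imaging_cytotoxicity(experiment)
    )
    if per_well.empty:
        raise DataError(f"no {readout!r} experimental wells found")
    doses = np.sort(per_well["dose_ug"].unique())
    if doses.size < 2:
        raise DataError("dose-response needs at least two doses")
    counts = per_well.groupby("dose_ug")["replicate"].count()
    if (counts < 2).any():
        raise DataError("each dose needs at least two replicates")

    grouped = per_well.groupby("dose_ug")["cytotoxicity"]
    means = grouped.mean().reindex(doses)
    sds = grouped.std(ddof=1).reindex(doses)
    baseline = per_well.loc[per_well["dose_ug"] == doses[0], "cytotoxicity"]
    pairwise = {}
    for dose in doses[1:]:
        values = per_well.loc[per_well["dose_ug"] == dose, "cytotoxicity"]
        pairwise[float(dose)] = t_test_unpaired(baseline, values, alternative="two-sided")

    dose_vec = per_well["dose_ug"].to_numpy(dtype=float)
    cyto_vec = per_well["cytotoxicity"].to_numpy(dtype=float)
    observed = _spearman(dose_vec, cyto_vec)
    rng = np.random.default_rng(seed)
    # Permuting response midranks is equivalent to permuting responses and
    # re-ranking, so the trend statistic vectorizes over permutations.
    rx = ss.rankdata(dose_vec)
    ry = ss.rankdata(cyto_vec)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        trend_p = 1.0
    else:
        perms = rng.permuted(
            np.broadcast_to(ry, (n_permutations, ry.size)).copy(), axis=1
        )
        rho_perm = (perms - ry.mean()) @ rx_c / denom
        hits = int((rho_perm <= observed + 1e-12).sum())  # as-or-more decreasing
        trend_p = (1 + hits) / (1 + n_permutations)
    monotone = bool(np.all(np.diff(means.to_numpy()) <= 0))
    return DecoyResult(
        doses=tuple(float(d) for d in doses),
        cytotoxicity_mean=tuple(float(m) for m in means),
        cytotoxicity_sd=tuple(float(s) for s in sds),
        pairwise_p=pairwise,
        trend_rho=float(observed),
        trend_p=float(trend_p),
        monotone_decreasing=monotone,
        per_well=per_well,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via midranks; 0 when either vector is constant."""
    rx, ry = ss.rankdata(x), ss.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])
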