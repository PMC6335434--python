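"""Autoantibody serology: cross-cohort standardization, ROC, bead assays.

Protein-microarray cohorts measured on different days or platforms carry
set-specific location/scale effects. Because each set is small, sets are
merged by standardizing each antigen within each set to the healthy
controls of that set (mean 0, SD 1), after which case/control discrimination
is assessed by Mann-Whitney tests and ROC analysis. Bead-based (Luminex)
exosome reactivity is scored as log2 of the exosome-bead over uncoated-bead
median fluorescence intensity; the anti-Ig bead normalization factor cancels
in that ratio and is retained as a QC column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.metrics import roc_curve

from .errors import DataError
from .stats import bh_fdr, mann_whitney

HEALTHY = "healthy"
REQUIRED_COLUMNS = ("antigen_id", "sample_id", "intensity", "set", "group")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int


def _check_long_format(data: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(data.columns)
    if missing:
        raise DataError(f"serology table missing column(s): {sorted(missing)}")
    if not np.isfinite(data["intensity"]).all():
        raise DataError("serology intensities must be finite")


def standardize_and_merge_sets(
    data: pd.DataFrame, control_group: str = HEALTHY
) -> pd.DataFrame:
    """Merge cohort sets onto a common healthy-control z-score scale.

    For each (set, antigen), the healthy-control mean is subtracted and the
    healthy-control sample (n-1) standard deviation divides the residual.
    The input is long-form with columns ``antigen_id, sample_id, intensity,
    set, group``; the output adds a ``standardized`` column and keeps all
    labels. At least two controls with non-zero spread are required per
    (set, antigen); violations name the offender.
    """
    _check_long_format(data)
    out = data.copy()
    out["standardized"] = np.nan
    for (set_label, antigen), idx in out.groupby(["set", "antigen_id"]).groups.items():
        block = out.loc[idx]
        controls = block.loc[block["group"] == control_group, "intensity"]
        if len(controls) < 2:
            raise DataError(
                f"set {set_label!r}, antigen {antigen!r}: "
                f"{len(controls)} healthy controls (need >= 2)"
            )
        sd = controls.std(ddof=1)
        if sd == 0:
            raise DataError(
                f"set {set_label!r}, antigen {antigen!r}: zero control variance"
            )
        out.loc[idx, "standardized"] = (block["intensity"] - controls.mean()) / sd
    return out


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the midrank structural components."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = ss.rankdata(combined)
    tx = ss.rankdata(cases)
    ty = ss.rankdata(controls)
    v01 = (tz[:m] - tx) / n            # per-case placement values
    v10 = 1.0 - (tz[m:] - ty) / m      # per-control placement values
    auc = v01.mean()
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_analysis(
    scores,
    is_case,
    alternative: str = "two-sided",
    ci_level: float = 0.95,
    bootstrap: int | None = None,
    seed: int | None = None,
) -> RocResult:
    """ROC AUC with confidence interval and a Mann-Whitney p versus AUC = 0.5.

    The AUC is the trapezoidal area under the empirical ROC curve with the
    cases-higher orientation and equals U/(n1*n2). The confidence interval
    uses the DeLong variance by default; pass ``bootstrap`` for a stratified
    bootstrap interval instead (seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(is_case, dtype=bool)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must align")
    if labels.all() or not labels.any():
        raise DataError("both classes must be present")
    cases, controls = scores[labels], scores[~labels]

    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    auc_trapz = float(np.trapezoid(tpr, fpr))
    rank = mann_whitney(cases, controls, alternative=alternative)
    auc, var = _delong_variance(cases, controls)

    z = ss.norm.ppf(0.5 + ci_level / 2)
    if bootstrap:
        rng = np.random.default_rng(seed)
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            c = rng.choice(cases, size=len(cases), replace=True)
            h = rng.choice(controls, size=len(controls), replace=True)
            reps[b] = mann_whitney(c, h).auc
        lo, hi = np.quantile(reps, [(1 - ci_level) / 2, 0.5 + ci_level / 2])
    else:
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    lo, hi = float(np.clip(lo, 0, auc)), float(np.clip(hi, auc, 1))
    assert abs(auc_trapz - rank.auc) < 1e-9, "trapezoidal AUC deviates from U/(n1*n2)"
    return RocResult(auc=float(auc), ci_low=lo, ci_high=hi,
                     p_value=rank.p_value, n_cases=len(cases), n_controls=len(controls))


def antigen_performance(
    merged: pd.DataFrame,
    case_group: str = "case",
    control_group: str = HEALTHY,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-antigen case-versus-control discrimination on the merged z scale.

    Returns one row per antigen with AUC, DeLong CI, Mann-Whitney p and BH
    FDR across antigens.
    """
    if "standardized" not in merged.columns:
        raise DataError("run standardize_and_merge_sets first")
    rows = []
    for antigen, block in merged.groupby("antigen_id"):
        sub = block[block["group"].isin([case_group, control_group])]
        labels = sub["group"] == case_group
        if labels.all() or not labels.any():
            continue
        res = roc_analysis(sub["standardized"], labels, alternative=alternative)
        rows.append({
            "antigen_id": antigen, "auc": res.auc,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p": res.p_value, "n_cases": res.n_cases, "n_controls": res.n_controls,
        })
    if not rows:
        raise DataError("no antigen had both cases and controls")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def luminex_score(panel: pd.DataFrame) -> pd.DataFrame:
    """Score bead-based exosome reactivity per sample.

    Expects columns ``mfi_exosome, mfi_uncoated, mfi_anti_ig``. The reported
    score is log2(MFI_exosome / MFI_uncoated); normalizing both bead channels
    by the anti-Ig bead MFI leaves this ratio unchanged, so the anti-Ig
    normalized intermediate is returned alongside as ``exo_over_anti_ig``
    for QC rather than entering the score.
    """
    required = {"mfi_exosome", "mfi_uncoated", "mfi_anti_ig"}
    missing = required - set(panel.columns)
    if missing:
        raise DataError(f"Luminex panel missing column(s): {sorted(missing)}")
    if (panel["mfi_uncoated"] <= 0).any() or (panel["mfi_anti_ig"] <= 0).any():
        raise DataError("uncoated and anti-Ig bead MFIs must be positive")
    if (panel["mfi_exosome"] < 0).any():
        raise DataError("exosome bead MFI must be non-negative")
    out = panel.copy()
    out["exo_over_anti_ig"] = out["mfi_exosome"] / out["mfi_anti_ig"]
    out["score"] = np.log2(out["mfi_exosome"] / out["mfi_uncoated"])
    return out
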