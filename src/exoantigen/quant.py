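"""Normalization and fold-change primitives for label-free proteomics.

Spectral-count matrices are quantile-normalized so every sample shares the
same count distribution; plasma-exosome MS1 intensities are divided by the
number of 30-200 nm particles measured per sample; and case/control ratios
follow the "Inf" convention: a protein seen only in cases is reported as
infinitely elevated rather than smoothed with a pseudocount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

INF = float("inf")

#: Sentinel statuses for case/control ratios.
FINITE, INFINITE, UNDEFINED = "finite", "inf", "undefined"


@dataclass(frozen=True)
class FoldChange:
    """Case/control ratio of group means for one protein.

    ``ratio`` is ``case_mean / control_mean`` when the control mean is
    positive, ``inf`` when only the case mean is positive, and ``nan``
    (status ``"undefined"``) when both means are zero. ``inf`` sorts above
    every finite ratio, so proteins unique to cases always pass a fold
    threshold.
    """

    protein_id: str
    case_mean: float
    control_mean: float
    ratio: float

    @property
    def status(self) -> str:
        if np.isnan(self.ratio):
            return UNDEFINED
        if np.isinf(self.ratio):
            return INFINITE
        return FINITE

    def passes(self, fold: float, inclusive: bool = False) -> bool:
        """Whether the ratio clears ``fold`` (strict by default); undefined never passes."""
        if self.status == UNDEFINED:
            return False
        return self.ratio >= fold if inclusive else self.ratio > fold


def quantile_normalize(matrix: pd.DataFrame, ties: str = "stable") -> pd.DataFrame:
    """Force every column of ``matrix`` onto the common mean distribution.

    The reference distribution is the row-wise mean of the column-sorted
    input. With ``ties="stable"`` (default) tied values are ranked by row
    order, so every column's output multiset equals the reference exactly —
    the definitional contract that all columns share an identical sorted
    value vector afterwards. With ``ties="mean"`` each within-column tie
    block instead receives the mean of the reference values it spans (equal
    inputs stay equal, at the cost of the exact-multiset property on tied
    data). Row and column order are preserved; a single-column matrix is
    returned unchanged with a warning.
    """
    if ties not in ("stable", "mean"):
        raise DataError(f"unknown tie policy {ties!r}; use 'stable' or 'mean'")
    if matrix.empty:
        raise DataError("cannot quantile-normalize an empty matrix")
    if matrix.shape[1] == 1:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return matrix.astype(float).copy()
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError("matrix contains missing values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="mergesort")
        if ties == "stable":
            out[order, j] = reference
            continue
        sorted_col = values[order, j]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            out[order[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def count_particles_in_window(
    particles: pd.DataFrame, low_nm: float = 30.0, high_nm: float = 200.0
) -> pd.Series:
    """Count tracked particles with diameter in the closed window [low, high] nm.

    ``particles`` is long-form with columns ``sample_id`` and ``diameter_nm``
    (one tracked particle per row). Samples present in the table but with no
    particle inside the window count 0.
    """
    if not (0 < low_nm < high_nm):
        raise ConfigurationError(
            f"invalid particle window [{low_nm}, {high_nm}]: need 0 < low < high"
        )
    for col in ("sample_id", "diameter_nm"):
        if col not in particles.columns:
            raise DataError(f"particle table missing column {col!r}")
    if (particles["diameter_nm"] <= 0).any():
        raise DataError("particle diameters must be positive")
    in_window = particles["diameter_nm"].between(low_nm, high_nm)  # closed interval
    counts = in_window.groupby(particles["sample_id"]).sum().astype(int)
    counts.name = "particles_in_window"
    return counts


def normalize_by_particles(
    intensities: pd.DataFrame, particle_counts: pd.Series
) -> pd.DataFrame:
    """Divide each sample's MS1 intensities by its in-window particle count.

    Every column of ``intensities`` must have a positive count; the offending
    sample is named otherwise. Within-sample intensity ratios are unchanged.
    """
    missing = [s for s in intensities.columns if s not in particle_counts.index]
    if missing:
        raise DataError(f"no particle count for sample(s): {missing}")
    counts = particle_counts.reindex(intensities.columns)
    bad = counts[counts <= 0]
    if not bad.empty:
        raise DataError(f"non-positive particle count for sample(s): {list(bad.index)}")
    return intensities.astype(float).div(counts, axis=1)


def fold_change(
    case_values,
    control_values,
    protein_id: str = "",
    pseudocount: float = 0.0,
) -> FoldChange:
    """Case/control ratio of arithmetic means with the Inf/undefined sentinels.

    No pseudocount is applied by default; pass ``pseudocount > 0`` to smooth
    both means explicitly (this disables the Inf sentinel for that call).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise DataError("fold_change requires at least one case and one control value")
    if (case < 0).any() or (control < 0).any():
        raise DataError("abundance values must be non-negative")
    case_mean = case.mean() + pseudocount
    control_mean = control.mean() + pseudocount
    if control_mean > 0:
        ratio = case_mean / control_mean
    elif case_mean > 0:
        ratio = INF
    else:
        ratio = float("nan")
    return FoldChange(protein_id=protein_id, case_mean=float(case_mean),
                      control_mean=float(control_mean), ratio=float(ratio))


def fold_changes_by_group(
    matrix: pd.DataFrame, case_samples, control_samples, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Row-wise :func:`fold_change` for a protein x sample matrix.

    Returns a frame indexed by protein with columns ``case_mean``,
    ``control_mean``, ``ratio`` (inf/nan sentinels preserved) and ``status``.
    """
    case_samples = [s for s in case_samples]
    control_samples = [s for s in control_samples]
    if not case_samples or not control_samples:
        raise DataError("need at least one case and one control sample")
    case_mean = matrix[case_samples].mean(axis=1) + pseudocount
    control_mean = matrix[control_samples].mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = case_mean / control_mean
    ratio = ratio.where(control_mean > 0, other=np.where(case_mean > 0, INF, np.nan))
    status = pd.Series(FINITE, index=matrix.index)
    status[np.isinf(ratio)] = INFINITE
    status[ratio.isna()] = UNDEFINED
    return pd.DataFrame(
        {"case_mean": case_mean, "control_mean": control_mean,
         "ratio": ratio, "status": status}
    )
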