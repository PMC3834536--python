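"""Detection filtering, prevalence filtering, quantile normalization and
tumor/nontumor log-ratios for spotted-cDNA ("4k") and strand-specific
oligo ("44k") array designs.

Detection follows the negative-control rule: on each array the threshold is
the mean plus ``k_sd`` standard deviations of the negative-control probe
intensities (k_sd = 3 for the 4k design, 2 for the 44k design), and a probe
is detected where its intensity is strictly above the threshold. The 44k
design additionally requires detection in a minimum number of arrays of at
least one sample group. Prevalence filtering then keeps probes detected in
at least ``min_frac`` (default 90%) of the arrays of *both* compared groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionRule:
    """Negative-control detection threshold parameters.

    k_sd: multiplier on the negative-control SD (3 for 4k, 2 for 44k).
    min_arrays: minimum arrays above threshold for group-scoped detection
        (44k: 3 of 4).
    scope: "per-array" (4k) or "per-group" (44k).
    """

    k_sd: float = 3.0
    min_arrays: int = 1
    scope: str = "per-array"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.min_arrays < 1:
            raise ValueError("min_arrays must be >= 1")
        if self.scope not in ("per-array", "per-group"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class PrevalenceRule:
    """Minimum detection fraction required in each compared group."""

    min_frac: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.min_frac <= 1):
            raise ValueError("min_frac must be in (0, 1]")


def detection_thresholds(
    intensities: pd.DataFrame, negcontrol_ids: Iterable[str], rule: DetectionRule
) -> pd.Series:
    """Per-array detection threshold: negcontrol mean + k_sd * SD (ddof=1)."""
    neg_ids = pd.Index(negcontrol_ids)
    missing = neg_ids.difference(intensities.index)
    if len(missing):
        raise ValueError(f"negative-control ids absent from matrix: {list(missing)[:5]}")
    if len(neg_ids) < 2:
        raise ValueError("need >= 2 negative controls to estimate the SD")
    neg = intensities.loc[neg_ids]
    return neg.mean(axis=0) + rule.k_sd * neg.std(axis=0, ddof=1)


def detect_expressed(
    intensities: pd.DataFrame,
    negcontrol_ids: Iterable[str],
    rule: DetectionRule,
    sample_groups: pd.Series | None = None,
) -> pd.DataFrame | pd.Series:
    """Apply the negative-control detection rule.

    Returns a probe x array boolean mask for scope="per-array"; for
    scope="per-group" returns a per-probe boolean Series that is True when
    the probe is detected in >= ``rule.min_arrays`` arrays of at least one
    group of ``sample_groups``.
    """
    thresholds = detection_thresholds(intensities, negcontrol_ids, rule)
    mask = intensities.gt(thresholds, axis=1)
    for arr in intensities.columns:
        logger.debug("array %s detection threshold %.4f", arr, thresholds[arr])
    if rule.scope == "per-array":
        return mask
    if sample_groups is None:
        raise ValueError("per-group detection needs sample_groups")
    groups = pd.Series(sample_groups)
    expressed = pd.Series(False, index=intensities.index)
    for _, cols in groups.groupby(groups):
        expressed |= mask[cols.index].sum(axis=1) >= rule.min_arrays
    return expressed


def filter_by_prevalence(
    mask: pd.DataFrame, sample_groups: pd.Series, rule: PrevalenceRule
) -> pd.Index:
    """Probes detected in >= min_frac of the arrays of BOTH groups.

    A probe falling below the cut in either group is excluded.
    """
    groups = pd.Series(sample_groups)
    unassigned = pd.Index(mask.columns).difference(groups.index)
    if len(unassigned):
        raise ValueError(f"samples without a group: {list(unassigned)}")
    keep = pd.Series(True, index=mask.index)
    n_groups = 0
    for name, cols in groups.groupby(groups):
        cols_here = [c for c in mask.columns if c in cols.index]
        if not cols_here:
            raise ValueError(f"group {name!r} has no arrays in the matrix")
        n_groups += 1
        frac = mask[cols_here].mean(axis=1)
        keep &= frac >= rule.min_frac
    if n_groups == 0:
        raise ValueError("no sample groups given")
    return mask.index[keep]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array onto the common (row-mean-of-sorted) distribution.

    Within-array rank order is preserved; ties receive the average of the
    target quantiles (interpolated at the average rank), which keeps the
    transform idempotent on tie-free data. A single-column matrix is
    returned unchanged.
    """
    if matrix.isna().any().any():
        raise ValueError("missing values are not allowed before normalization")
    if matrix.shape[1] < 2:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    positions = np.arange(1, values.shape[0] + 1, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = _average_ranks(values[:, j])
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def log2_ratio(
    intensities: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-pair log2(tumor/nontumor) matrix.

    ``pairs`` is a sequence of (tumor_column, nontumor_column); output
    columns are named after the tumor column. Nonpositive intensities are
    rejected naming the offending probe and sample.
    """
    out = {}
    for t_col, n_col in pairs:
        for col in (t_col, n_col):
            col_vals = intensities[col]
            bad = col_vals[col_vals <= 0]
            if len(bad):
                raise ValueError(
                    f"nonpositive intensity for probe {bad.index[0]!r} in sample {col!r}"
                )
        out[t_col] = np.log2(intensities[t_col].to_numpy()) - np.log2(
            intensities[n_col].to_numpy()
        )
    return pd.DataFrame(out, index=intensities.index)
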