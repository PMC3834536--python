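"""Permutation signatures of malignancy and survival.

Two selection procedures are implemented:

* The malignancy signature: a one-class SAM analysis of paired tumor/
  nontumor log2 ratios (d_i = r_i / (s_i + s0), permutation null by random
  sign flips of the pairs, asymmetric delta threshold chosen as the
  smallest delta whose estimated FDR is at or below the cutoff), wrapped in
  a leave-one-pair-out consensus: the final signature keeps probes selected
  in 100% of the leave-one-out datasets whose mean linear fold change is at
  least 1.5-fold.

* The survival signature: a two-class unpaired SAM run (FDR < 10%)
  intersected with the Golub signal-to-noise score P(g) = (mu1 - mu2) /
  (sigma1 + sigma2) at permutation p < 0.01, with samples ordered by the
  Pearson correlation of their signature profile to the mean profile of the
  deceased group.

The permutation FDR follows the original SAM recipe: for a threshold delta
the cut points are the extreme observed d values whose deviation from the
permutation-averaged order statistics exceeds delta, and the FDR is the
average count of permuted d values beyond the cuts across permutations,
divided by the observed count (the null proportion pi0 is conservatively
set to 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_S0_FLOOR = 1e-8


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# d-statistic and fudge factor


def _one_class_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired design: r = mean log-ratio, s = SD / sqrt(n)."""
    n = X.shape[1]
    if n < 2:
        raise ValueError("one-class SAM needs >= 2 pairs")
    r = X.mean(axis=1)
    s = X.std(axis=1, ddof=1) / np.sqrt(n)
    return r, s


def _two_class_stats(
    X: np.ndarray, group_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired design: r = mean_A - mean_B, s = pooled standard error."""
    group_a = np.asarray(group_a, dtype=bool)
    n_a = int(group_a.sum())
    n_b = int((~group_a).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("two-class SAM needs >= 2 samples per group")
    xa, xb = X[:, group_a], X[:, ~group_a]
    r = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled = ss / (n_a + n_b - 2)
    s = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    return r, s


def _design_stats(X, design, labels):
    X = np.asarray(X, dtype=float)
    if design == "one_class":
        return _one_class_stats(X)
    if design == "two_class":
        if labels is None:
            raise ValueError("two_class design needs labels")
        return _two_class_stats(X, labels)
    raise ValueError(f"unknown design {design!r}")


def sam_d_statistic(X, design: str, labels=None, s0: float = 0.0) -> np.ndarray:
    """SAM relative difference d_i = r_i / (s_i + s0)."""
    r, s = _design_stats(X, design, labels)
    return r / (s + s0)


def choose_s0(X, design: str, labels=None) -> float:
    """Fudge factor minimizing the coefficient of variation of d.

    Candidates are the {0, 5, ..., 100}-th percentiles of the s_i
    distribution. For each candidate the probes are windowed by s_i
    quantiles, the median absolute deviation of d is taken per window, and
    the candidate minimizing the CV of those spreads is returned — the
    published SAM tuning recipe.
    """
    r, s = _design_stats(X, design, labels)
    if np.all(s <= 0):
        logger.warning("all s_i are zero; using floor s0 = %g", _S0_FLOOR)
        return _S0_FLOOR
    if np.ptp(s) == 0:
        logger.info("all s_i equal; any percentile equivalent, returning the 0th")
        return float(np.percentile(s, 0))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    n_windows = int(min(100, max(2, len(s) // 5)))
    windows = np.array_split(order, n_windows)
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, r / (s + s0), 0.0)
        spreads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64 for w in windows]
        )
        mean = spreads.mean()
        if mean == 0:
            continue
        cv = spreads.std(ddof=1) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


# ---------------------------------------------------------------------------
# permutation machinery


def _sign_flip_matrix(n_pairs: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """One-class null: 2^n sign assignments, enumerated when feasible."""
    if 2**n_pairs <= n_perm:
        grid = np.array(
            np.meshgrid(*[[1.0, -1.0]] * n_pairs, indexing="ij")
        ).reshape(n_pairs, -1).T
        return grid
    return rng.choice([1.0, -1.0], size=(n_perm, n_pairs))


def _perm_d_one_class(X, s0, n_perm, rng) -> np.ndarray:
    n = X.shape[1]
    signs = _sign_flip_matrix(n, n_perm, rng)
    M = signs @ X.T / n  # B x P permuted means
    meansq = (X**2).mean(axis=1)
    var = np.clip((meansq[None, :] - M**2) * n / (n - 1), 0.0, None)
    s = np.sqrt(var / n)
    return M / (s + s0)


def _perm_d_two_class(X, group_a, s0, n_perm, rng) -> np.ndarray:
    group_a = np.asarray(group_a, dtype=bool)
    n = len(group_a)
    n_a = int(group_a.sum())
    n_b = n - n_a
    L = np.zeros((n_perm, n))
    for b in range(n_perm):
        L[b, rng.permutation(n)[:n_a]] = 1.0
    sum_all = X.sum(axis=1)
    sumsq_all = (X**2).sum(axis=1)
    sa = L @ X.T  # B x P
    sqa = L @ (X**2).T
    ma = sa / n_a
    mb = (sum_all[None, :] - sa) / n_b
    ssa = sqa - n_a * ma**2
    ssb = (sumsq_all[None, :] - sqa) - n_b * mb**2
    pooled = np.clip(ssa + ssb, 0.0, None) / (n_a + n_b - 2)
    s = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    return (ma - mb) / (s + s0)


@dataclass
class SamResult:
    """Per-probe SAM table plus the global selection parameters."""

    table: pd.DataFrame  # columns: d, r, s, selected
    s0: float
    delta: float
    fdr: float  # estimated FDR (fraction) at the chosen delta
    n_perm: int
    cut_low: float
    cut_up: float

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    @property
    def q_percent(self) -> float:
        return 100.0 * self.fdr


def sam_select(
    X,
    design: str,
    labels=None,
    n_perm: int = 1000,
    fdr_cut: float = 0.05,
    s0: float | None = None,
    seed=None,
    max_delta_grid: int = 64,
) -> SamResult:
    """Select probes by SAM permutation FDR.

    ``X`` is a probe x sample DataFrame (one_class: per-pair log ratios;
    two_class: expression with boolean ``labels`` marking group A). The
    smallest asymmetric threshold delta with estimated FDR <= ``fdr_cut``
    is used; an empty selection is returned when nothing is selectable.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    Xv = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    r, s = _design_stats(Xv, design, labels)
    if s0 is None:
        s0 = choose_s0(Xv, design, labels)
    d = r / (s + s0)
    if design == "one_class":
        D = _perm_d_one_class(Xv, s0, n_perm, rng)
    else:
        D = _perm_d_two_class(Xv, labels, s0, n_perm, rng)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    D.sort(axis=1)
    dbar = D.mean(axis=0)
    diff = d_sorted - dbar

    def evaluate(delta: float):
        up = (diff >= delta) & (dbar >= 0)
        lo = (-diff >= delta) & (dbar <= 0)
        cut_up = d_sorted[up].min() if up.any() else np.inf
        cut_low = d_sorted[lo].max() if lo.any() else -np.inf
        sel_sorted = (d_sorted >= cut_up) | (d_sorted <= cut_low)
        n_obs = int(sel_sorted.sum())
        if n_obs == 0:
            fdr = 0.0
        else:
            # average count of falsely significant genes across the
            # permutations, as in the published SAM recipe (pi0 = 1)
            null_counts = (D >= cut_up).sum(axis=1) + (D <= cut_low).sum(axis=1)
            fdr = min(1.0, float(null_counts.mean()) / n_obs)
        return fdr, cut_low, cut_up, sel_sorted

    # smallest delta with estimated FDR <= cutoff, on the full candidate set
    # of |d - dbar| values; a coarse quantile scan brackets the boundary and
    # an exact scan inside the bracket refines it
    candidates = np.unique(np.abs(diff))
    sentinel = np.abs(diff).max() + 1.0  # guarantees an (empty) selection
    coarse = candidates
    if len(coarse) > max_delta_grid:
        coarse = np.unique(np.quantile(candidates, np.linspace(0, 1, max_delta_grid)))
    coarse = np.append(coarse, sentinel)

    chosen = None
    prev = -np.inf
    for delta in coarse:
        fdr, cut_low, cut_up, sel_sorted = evaluate(delta)
        if fdr <= fdr_cut:
            for fine in candidates[(candidates > prev) & (candidates < delta)]:
                f_fdr, f_low, f_up, f_sel = evaluate(fine)
                if f_fdr <= fdr_cut:
                    chosen = (float(fine), f_fdr, f_low, f_up, f_sel)
                    break
            if chosen is None:
                chosen = (float(delta), fdr, cut_low, cut_up, sel_sorted)
            break
        prev = delta
    assert chosen is not None  # sentinel delta always yields FDR 0
    delta, fdr, cut_low, cut_up, sel_sorted = chosen
    selected = np.zeros(len(d), dtype=bool)
    selected[order] = sel_sorted
    table = pd.DataFrame({"d": d, "r": r, "s": s, "selected": selected}, index=index)
    logger.info(
        "SAM %s: s0=%.4g delta=%.4g fdr=%.3f selected=%d/%d",
        design, s0, delta, fdr, int(selected.sum()), len(d),
    )
    return SamResult(table, float(s0), delta, fdr, n_perm, float(cut_low), float(cut_up))


# ---------------------------------------------------------------------------
# leave-one-out consensus


@dataclass
class LooConsensus:
    """Consensus over leave-one-pair-out SAM runs plus the fold-change rule."""

    table: pd.DataFrame  # presence_frac, mean_fc, final
    full_result: SamResult
    loo_results: list = field(default_factory=list)

    @property
    def final(self) -> pd.Index:
        return self.table.index[self.table["final"]]


def signed_fold_change(mean_log2_ratio: np.ndarray) -> np.ndarray:
    """Geometric-mean linear fold change with sign conveying direction.

    2^m for m >= 0; -(2^|m|) for m < 0 (the signed-linear convention used
    in the printed tables; |fc| >= 1 always).
    """
    m = np.asarray(mean_log2_ratio, dtype=float)
    return np.where(m >= 0, 2.0**m, -(2.0 ** (-m)))


def finalize_consensus(
    presence_frac: np.ndarray, mean_fc: np.ndarray, fc_min: float = 1.5
) -> np.ndarray:
    """The consensus rule: in 100% of leave-one-out sets AND |fc| >= fc_min."""
    presence_frac = np.asarray(presence_frac, dtype=float)
    mean_fc = np.asarray(mean_fc, dtype=float)
    return (presence_frac == 1.0) & (np.abs(mean_fc) >= fc_min)


def leave_one_out_signature(
    pair_ratios: pd.DataFrame,
    fdr_cut: float = 0.05,
    fc_min: float = 1.5,
    n_perm: int = 1000,
    seed=None,
) -> LooConsensus:
    """Run SAM on the full matrix and each leave-one-pair-out submatrix.

    final = selected in 100% of the leave-one-out runs AND mean linear fold
    change (from the full data) of at least ``fc_min``.
    """
    n_pairs = pair_ratios.shape[1]
    if n_pairs < 3:
        raise ValueError("need >= 3 pairs for a leave-one-out consensus")
    seeds = _seed_seq(seed).spawn(n_pairs + 1)
    full = sam_select(
        pair_ratios, "one_class", n_perm=n_perm, fdr_cut=fdr_cut, seed=seeds[0]
    )
    loo_results = []
    presence = np.zeros(len(pair_ratios), dtype=int)
    for i in range(n_pairs):
        sub = pair_ratios.drop(columns=pair_ratios.columns[i])
        res = sam_select(sub, "one_class", n_perm=n_perm, fdr_cut=fdr_cut, seed=seeds[i + 1])
        loo_results.append(res)
        presence += res.table["selected"].to_numpy(dtype=int)
        logger.info("leave-one-out %s: %d selected", pair_ratios.columns[i], len(res.selected))
    presence_frac = presence / n_pairs
    mean_fc = signed_fold_change(pair_ratios.mean(axis=1).to_numpy())
    final = finalize_consensus(presence_frac, mean_fc, fc_min)
    table = pd.DataFrame(
        {"presence_frac": presence_frac, "mean_fc": mean_fc, "final": final},
        index=pair_ratios.index,
    )
    return LooConsensus(table, full, loo_results)


# ---------------------------------------------------------------------------
# Golub discrimination score and the survival signature


@dataclass
class GolubResult:
    table: pd.DataFrame  # score, p, selected, excluded

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def _golub_scores(X: np.ndarray, group_a: np.ndarray) -> np.ndarray:
    xa, xb = X[:, group_a], X[:, ~group_a]
    denom = xa.std(axis=1, ddof=1) + xb.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (xa.mean(axis=1) - xb.mean(axis=1)) / denom, np.nan)


def golub_select(
    X, labels, n_perm: int = 1000, p_cut: float = 0.01, seed=None
) -> GolubResult:
    """Signal-to-noise score P(g) = (mu1 - mu2)/(sigma1 + sigma2).

    Permutation p-value: fraction of label shuffles with |P_perm| >= |P_obs|,
    with (b + 1)/(m + 1) smoothing. Genes with sigma1 + sigma2 = 0 are
    excluded and flagged.
    """
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    Xv = np.asarray(X, dtype=float)
    group_a = np.asarray(labels, dtype=bool)
    if min(group_a.sum(), (~group_a).sum()) < 2:
        raise ValueError("both classes need >= 2 samples")
    rng = np.random.default_rng(seed)
    obs = _golub_scores(Xv, group_a)
    excluded = ~np.isfinite(obs)
    if excluded.any():
        logger.warning(
            "%d genes with zero pooled SD excluded from the Golub analysis",
            int(excluded.sum()),
        )
    exceed = np.zeros(len(obs), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(len(group_a))
        p_scores = _golub_scores(Xv, group_a[perm])
        with np.errstate(invalid="ignore"):
            exceed += np.abs(p_scores) >= np.abs(obs)
    p = (exceed + 1) / (n_perm + 1)
    p[excluded] = np.nan
    selected = np.zeros(len(obs), dtype=bool)
    ok = ~excluded
    selected[ok] = p[ok] < p_cut
    table = pd.DataFrame(
        {"score": obs, "p": p, "selected": selected, "excluded": excluded}, index=index
    )
    return GolubResult(table)


@dataclass
class SurvivalSignature:
    genes: pd.Index
    ordered_samples: list
    sample_correlations: pd.Series
    sam: SamResult
    golub: GolubResult


def survival_signature(
    X_tumors: pd.DataFrame,
    outcome_labels,
    sam_fdr: float = 0.10,
    golub_p: float = 0.01,
    n_perm: int = 1000,
    seed=None,
) -> SurvivalSignature:
    """Two-class SAM (FDR < sam_fdr) intersected with Golub (p < golub_p).

    ``outcome_labels`` marks the deceased group (boolean, or the strings
    "dead"/"alive"). Samples are ordered by Pearson correlation of their
    signature-gene profile with the mean profile of the deceased group.
    """
    labels = pd.Series(outcome_labels, index=X_tumors.columns)
    if labels.dtype == object:
        bad = set(labels.unique()) - {"dead", "alive"}
        if bad:
            raise ValueError(f"unknown outcome labels: {bad}")
        dead = (labels == "dead").to_numpy()
    else:
        dead = labels.to_numpy(dtype=bool)
    seeds = _seed_seq(seed).spawn(2)
    sam = sam_select(
        X_tumors, "two_class", labels=dead, n_perm=n_perm, fdr_cut=sam_fdr, seed=seeds[0]
    )
    golub = golub_select(X_tumors, dead, n_perm=n_perm, p_cut=golub_p, seed=seeds[1])
    genes = sam.selected.intersection(golub.selected)
    if len(genes) == 0:
        logger.warning("survival signature: empty SAM/Golub intersection")
        corr = pd.Series(np.nan, index=X_tumors.columns)
        return SurvivalSignature(genes, list(X_tumors.columns), corr, sam, golub)
    profile = X_tumors.loc[genes]
    dead_mean = profile.loc[:, dead].mean(axis=1)
    if len(genes) >= 2:
        corr = profile.corrwith(dead_mean, axis=0)
    else:
        corr = pd.Series(np.nan, index=X_tumors.columns)
    ordered = list(corr.sort_values(ascending=False, kind="stable").index)
    return SurvivalSignature(genes, ordered, corr, sam, golub)
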