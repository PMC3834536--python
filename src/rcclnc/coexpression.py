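"""Cis/trans Spearman co-expression of antisense lncRNAs and mRNAs, and a
GO module map over the trans-correlated partners.

Cis pairs (lncRNA vs the mRNA of its own host locus) pass at strictly
|rho| > 0.5 with p < 0.05; trans pairs (lncRNA vs mRNAs of other loci,
restricted to the 20% most abundant lncRNAs) pass at inclusively
|rho| >= 0.7 with p < 0.05 — the two cutoffs follow the printed
inequalities literally. p-values use the t approximation with n - 2 df.
The module map scores, per (lncRNA, GO term), the hypergeometric
enrichment of the term's genes among the lncRNA's correlated mRNAs,
Bonferroni-corrected over the terms tested for that lncRNA, signed by the
majority correlation direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _rank_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, M)


def _row_standardize(R: np.ndarray) -> np.ndarray:
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, R / norm, np.nan)


def spearman_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Spearman rho between rows of A and rows of B.

    Average ranks row-wise, then the Pearson product — identical to
    pairwise :func:`spearman` including tie handling. Constant rows give
    NaN.
    """
    Za = _row_standardize(_rank_rows(np.asarray(A, dtype=float)))
    Zb = _row_standardize(_rank_rows(np.asarray(B, dtype=float)))
    return np.clip(Za @ Zb.T, -1.0, 1.0)


def t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho*sqrt((n-2)/(1-rho^2))."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


@dataclass(frozen=True)
class CorrelationRecord:
    lnc_id: str
    partner_id: str
    rho: float
    p: float
    mode: str  # cis | trans

    @property
    def direction(self) -> str:
        return "direct" if self.rho > 0 else "inverse"


def _records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.lnc_id,
                "partner_id": r.partner_id,
                "rho": r.rho,
                "p": r.p,
                "mode": r.mode,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["lnc_id", "partner_id", "rho", "p", "mode", "direction"],
    )


def cis_correlation(
    lnc_expr: pd.DataFrame,
    host_expr: pd.DataFrame,
    locus_map: dict,
    rho_cut: float = 0.5,
    p_cut: float = 0.05,
    n_total: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation of each lncRNA with its own host-locus mRNA.

    Rows of the two expression tables are transcripts, columns tissues;
    only lncRNAs present in both tables (i.e. detected in all tissues)
    enter. A pair passes at strictly |rho| > rho_cut and p < p_cut.
    Summary reports the passing fraction of ``n_total`` (defaults to the
    full lncRNA table size).
    """
    records: list[CorrelationRecord] = []
    n_tested = 0
    for lnc_id in lnc_expr.index:
        host = locus_map.get(lnc_id)
        if host is None:
            logger.warning("no host locus mapped for %s; pair skipped", lnc_id)
            continue
        if host not in host_expr.index:
            continue
        try:
            rho, p = spearman(lnc_expr.loc[lnc_id], host_expr.loc[host])
        except ValueError:
            logger.warning("constant expression for pair (%s, %s); skipped", lnc_id, host)
            continue
        n_tested += 1
        if abs(rho) > rho_cut and p < p_cut:
            records.append(CorrelationRecord(lnc_id, host, rho, p, "cis"))
    n_total = n_total if n_total is not None else len(lnc_expr)
    summary = {
        "n_tested": n_tested,
        "n_passing": len(records),
        "fraction_of_total": len(records) / n_total if n_total else float("nan"),
    }
    return _records_frame(records), summary


def select_top_abundant(expr: pd.DataFrame, frac: float = 0.2) -> pd.Index:
    """The floor(frac * N) most abundant transcripts (mean across arrays).

    Boundary ties are broken by id order and logged.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    abundance = expr.mean(axis=1)
    k = int(math.floor(frac * len(expr)))
    # deterministic tie-break: among equal abundances keep id order
    order = sorted(expr.index, key=lambda i: (-abundance[i], str(i)))
    if 0 < k < len(order) and abundance[order[k - 1]] == abundance[order[k]]:
        logger.info("abundance tie at the %d-th boundary broken by id order", k)
    return pd.Index(order[:k])


def trans_correlation(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    locus_map: dict | None = None,
    rho_cut: float = 0.7,
    p_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """All-pairs lncRNA x mRNA Spearman screen outside the host locus.

    Pairs sharing a locus (per ``locus_map``) are excluded; a pair passes
    at inclusively |rho| >= rho_cut and p < p_cut.
    """
    n = lnc_expr.shape[1]
    if n != mrna_expr.shape[1]:
        raise ValueError("lncRNA and mRNA tables must share the tissue columns")
    rho = spearman_matrix(lnc_expr.to_numpy(), mrna_expr.to_numpy())
    p = t_approx_p(rho, n)
    with np.errstate(invalid="ignore"):
        mask = (np.abs(rho) >= rho_cut) & (p < p_cut) & np.isfinite(rho)
    records: list[CorrelationRecord] = []
    lnc_index = list(lnc_expr.index)
    mrna_index = list(mrna_expr.index)
    for i, j in np.argwhere(mask):
        lnc_id, mrna_id = lnc_index[i], mrna_index[j]
        if (locus_map or {}).get(lnc_id) == mrna_id:
            continue  # same locus: cis territory, excluded from trans
        records.append(
            CorrelationRecord(lnc_id, mrna_id, float(rho[i, j]), float(p[i, j]), "trans")
        )
    frame = _records_frame(records)
    n_lnc = frame["lnc_id"].nunique()
    n_partners = frame["partner_id"].nunique()
    summary = {
        "n_lnc_with_partner": n_lnc,
        "n_partner_mrnas": n_partners,
        "mean_partners_per_lnc": mean_partners_per_lnc(n_partners, n_lnc)
        if n_lnc
        else float("nan"),
    }
    return frame, summary


def mean_partners_per_lnc(n_partner_mrnas: int, n_lnc: int, decimals: int = 1) -> float:
    """Average distinct partner mRNAs per correlated lncRNA, rounded."""
    if n_lnc <= 0:
        raise ValueError("n_lnc must be positive")
    scale = 10**decimals
    return math.floor(n_partner_mrnas / n_lnc * scale + 0.5) / scale


@dataclass(frozen=True)
class ModuleMapCell:
    lnc_id: str
    go_term: str
    enrichment_p: float  # Bonferroni-adjusted
    sign: int  # +1 majority direct, -1 majority inverse, 0 not enriched


def go_module_map(
    records: pd.DataFrame,
    annotation: dict,
    background: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """lncRNA x GO-term enrichment map over trans-correlated partners.

    ``annotation`` maps gene -> set of GO terms. Per (lncRNA, term):
    hypergeometric upper-tail p for the overlap between the lncRNA's
    correlated mRNAs and the term's genes, within ``background``;
    Bonferroni correction over the terms tested per lncRNA. ``sign`` is +1
    (majority of the overlapping mRNAs directly correlated), -1 (majority
    inverse), or 0 when not enriched; direction ties resolve to the side
    with the larger mean |rho| and are logged.
    """
    if not annotation:
        raise ValueError("empty GO annotation")
    background = set(background)
    term_genes: dict[str, set] = {}
    for gene, terms in annotation.items():
        if gene not in background:
            raise ValueError(f"annotated gene {gene!r} missing from background")
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N = len(background)
    cells: list[ModuleMapCell] = []
    for lnc_id, grp in records.groupby("lnc_id", sort=True):
        correlated = set(grp["partner_id"]) & background
        n_draw = len(correlated)
        if n_draw == 0:
            continue
        terms = sorted(term_genes)
        n_tests = len(terms)
        rho_by_gene = dict(zip(grp["partner_id"], grp["rho"]))
        for term in terms:
            K = len(term_genes[term])
            overlap = correlated & term_genes[term]
            k = len(overlap)
            p_raw = float(sps.hypergeom.sf(k - 1, N, K, n_draw))
            p_adj = min(1.0, p_raw * n_tests)
            sign = 0
            if p_adj < alpha and k > 0:
                rhos = np.array([rho_by_gene[g] for g in overlap])
                n_direct = int((rhos > 0).sum())
                n_inverse = int((rhos < 0).sum())
                if n_direct > n_inverse:
                    sign = 1
                elif n_inverse > n_direct:
                    sign = -1
                else:
                    mean_dir = np.abs(rhos[rhos > 0]).mean() if n_direct else 0.0
                    mean_inv = np.abs(rhos[rhos < 0]).mean() if n_inverse else 0.0
                    sign = 1 if mean_dir >= mean_inv else -1
                    logger.info(
                        "direction tie for (%s, %s) resolved by mean |rho|", lnc_id, term
                    )
            cells.append(ModuleMapCell(lnc_id, term, p_adj, sign))
    return pd.DataFrame(
        [
            {"lnc_id": c.lnc_id, "go_term": c.go_term, "enrichment_p": c.enrichment_p, "sign": c.sign}
            for c in cells
        ],
        columns=["lnc_id", "go_term", "enrichment_p", "sign"],
    )
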