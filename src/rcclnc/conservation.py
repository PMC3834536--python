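"""Tissue specificity and evolutionary conservation statistics.

Tissue specificity uses the fraction-of-expression statistic: a
transcript's FPKM in one tissue divided by its summed FPKM over all
tissues (F.E.T.); a transcript with max F.E.T. >= 0.5 is called
tissue-specific, and specificity rates of lncRNAs versus protein-coding
mRNAs are compared by a two-sided Fisher exact test.

Conservation is assessed by interval overlap (>= 1 bp, half-open):
against conserved-element tracks with Fisher tests versus each random
control set; against per-species expressed-cDNA tracks (hit matrix and
the fraction of queries hit in >= 1 species); and against a
lifted-to-human foreign interval set for syntenic expression overlap,
with overlap lengths and a Fisher test against a null query set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)


@dataclass
class FetRow:
    """Per-transcript fraction of expression in each tissue."""

    fet: np.ndarray
    max_fet: float
    specific: bool  # max_fet >= 0.5
    expressed: bool  # total FPKM > 0


def fraction_expression(fpkm_row) -> FetRow:
    """F.E.T. vector: fpkm_t / sum(fpkm); all-zero rows flagged not expressed."""
    vals = np.asarray(fpkm_row, dtype=float)
    if (vals < 0).any():
        raise ValueError("negative FPKM")
    total = vals.sum()
    if total == 0:
        return FetRow(np.full_like(vals, np.nan), float("nan"), False, False)
    fet = vals / total
    max_fet = float(fet.max())
    return FetRow(fet, max_fet, max_fet >= 0.5, True)


def fet_table(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise F.E.T. over a transcripts x tissues FPKM table."""
    rows = {}
    for tid in fpkm.index:
        fr = fraction_expression(fpkm.loc[tid])
        rows[tid] = {"max_fet": fr.max_fet, "specific": fr.specific, "expressed": fr.expressed}
    return pd.DataFrame.from_dict(rows, orient="index").loc[fpkm.index]


def specificity_fisher(lnc_flags, mrna_flags) -> tuple[float, float]:
    """Fisher exact test of tissue-specificity rates, lncRNA vs mRNA.

    Two-sided, on the 2x2 table [specific, not] x [lncRNA, mRNA].
    """
    lnc = np.asarray(lnc_flags, dtype=bool)
    mrna = np.asarray(mrna_flags, dtype=bool)
    if len(lnc) == 0 or len(mrna) == 0:
        raise ValueError("both flag lists must be non-empty")
    table = [
        [int(lnc.sum()), int((~lnc).sum())],
        [int(mrna.sum()), int((~mrna).sum())],
    ]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class ConservationSummary:
    n_overlapping: int
    n_total: int
    control_overlapping: list
    fisher_p: list  # one p per random control set
    overlap_lengths: pd.Series  # bp of each overlapping query covered


def _overlap_flags(queries, index: IntervalIndex) -> np.ndarray:
    return np.array([index.count_overlaps(q) > 0 for q in queries], dtype=bool)


def conservation_enrichment(
    queries: list[GenomicInterval],
    element_track: list[GenomicInterval],
    random_sets: list[list[GenomicInterval]],
) -> ConservationSummary:
    """Overlap of queries with conserved elements vs random control sets.

    Per control set a two-sided Fisher test on
    [overlapping, non-overlapping] x [query, random]. An empty element
    track yields zero counts and p = 1 throughout.
    """
    n_total = len(queries)
    if not element_track:
        return ConservationSummary(
            0, n_total, [0] * len(random_sets), [1.0] * len(random_sets),
            pd.Series(dtype=int),
        )
    index = IntervalIndex(element_track)
    flags = _overlap_flags(queries, index)
    n_overlap = int(flags.sum())
    lengths = {}
    for q, hit in zip(queries, flags):
        if hit:
            lengths[q.name or f"{q.chrom}:{q.start}-{q.end}"] = index.overlap_bp(q)
    ctrl_counts, ps = [], []
    for ctrl in random_sets:
        c = int(_overlap_flags(ctrl, index).sum())
        ctrl_counts.append(c)
        _, p = sps.fisher_exact(
            [[n_overlap, n_total - n_overlap], [c, len(ctrl) - c]],
            alternative="two-sided",
        )
        ps.append(float(p))
    return ConservationSummary(n_overlap, n_total, ctrl_counts, ps, pd.Series(lengths, dtype=int))


def expression_conservation(
    queries: list[GenomicInterval], species_tracks: dict[str, list[GenomicInterval]]
) -> tuple[pd.DataFrame, float]:
    """Boolean hit matrix (query x species) and fraction with >= 1 hit."""
    if not species_tracks:
        raise ValueError("need at least one species track")
    names = [q.name or f"{q.chrom}:{q.start}-{q.end}" for q in queries]
    hits = {}
    for species in sorted(species_tracks):
        index = IntervalIndex(species_tracks[species])
        hits[species] = _overlap_flags(queries, index)
    frame = pd.DataFrame(hits, index=names)
    frac = float(frame.any(axis=1).mean()) if len(frame) else 0.0
    return frame, frac


@dataclass
class SyntenicOverlap:
    overlapping: list  # query names with >= 1 bp overlap
    overlap_lengths: pd.Series
    fisher_p: float
    n_query: int
    n_null: int
    n_query_hit: int
    n_null_hit: int


def syntenic_overlap(
    queries: list[GenomicInterval],
    mapped_foreign: list[GenomicInterval],
    null_queries: list[GenomicInterval],
) -> SyntenicOverlap:
    """Queries intersecting a lifted foreign interval set, vs a null set.

    ``mapped_foreign`` must already be on the query assembly. The Fisher
    test compares the query overlap count with the null-query count,
    two-sided.
    """
    index = IntervalIndex(mapped_foreign)
    flags = _overlap_flags(queries, index)
    lengths = {}
    names = []
    for q, hit in zip(queries, flags):
        if hit:
            name = q.name or f"{q.chrom}:{q.start}-{q.end}"
            names.append(name)
            lengths[name] = index.overlap_bp(q)
    null_hits = int(_overlap_flags(null_queries, index).sum())
    n_q, n_n = len(queries), len(null_queries)
    n_q_hit = int(flags.sum())
    p = synteny_fisher_p(n_q_hit, n_q, null_hits, n_n)
    return SyntenicOverlap(names, pd.Series(lengths, dtype=int), p, n_q, n_n, n_q_hit, null_hits)


def synteny_fisher_p(n_query_hit: int, n_query: int, n_null_hit: int, n_null: int) -> float:
    """Two-sided Fisher p for overlap counts vs a null query set."""
    _, p = sps.fisher_exact(
        [
            [n_query_hit, n_query - n_query_hit],
            [n_null_hit, n_null - n_null_hit],
        ],
        alternative="two-sided",
    )
    return float(p)
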