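"""Concordance bookkeeping for the published signature tables.

Fold changes here are signed linear values: the sign conveys the
direction of change in tumor versus nontumor (negative printed values
mean down-regulated), the magnitude the linear fold change. They are
never mixed with log2 ratios without explicit conversion.

Two transcribed fixtures ship with the package: the 40-lncRNA
malignancy-signature table (29 intronic lncRNAs with host-gene
fold-change annotations, 11 lincRNAs) and the per-study concordance
counts of the 217-gene protein-coding signature against nine public
ccRCC microarray studies.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_HOST_FC_RE = re.compile(r"^(-?\d+(?:\.\d+)?)(?:\s*\((\d+)/(\d+)\))?$")


@dataclass(frozen=True)
class SignedGene:
    gene_id: str
    fold_change: float  # signed linear; sign = direction in tumor

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"zero fold change for {self.gene_id}")


@dataclass(frozen=True)
class ConcordanceReport:
    n_common: int
    n_concordant: int

    @property
    def pct_concordance(self) -> float:
        return report_fraction(self.n_concordant, self.n_common, decimals=1)


@dataclass(frozen=True)
class HostFoldChange:
    """Parsed host-gene fold-change cell, e.g. '**2.56 (5/5)**' or 'n.d.'.

    The (x/y) suffix and bold/asterisk markup are retained as metadata
    only; they do not enter the |FC| > 1.5 alteration rule.
    """

    value: float | None  # None for n.d. / absent
    n_altered_studies: int | None
    n_detected_studies: int | None
    bold: bool
    starred: bool
    raw: str


def parse_host_fold_change(raw: str) -> HostFoldChange:
    text = raw.strip()
    bold = text.startswith("**") and text.endswith("**")
    core = text.strip("*").strip()
    starred = text.rstrip().endswith("*") and not bold
    if core in ("n.d.", "-", "", "n.a."):
        return HostFoldChange(None, None, None, bold, starred, raw)
    m = _HOST_FC_RE.match(core)
    if not m:
        raise ValueError(f"unparseable host fold-change cell: {raw!r}")
    value = float(m.group(1))
    x = int(m.group(2)) if m.group(2) else None
    y = int(m.group(3)) if m.group(3) else None
    return HostFoldChange(value, x, y, bold, starred, raw)


def _data_path(name: str):
    return resources.files("rcclnc").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """The transcribed 40-lncRNA signature table, host cells parsed."""
    with resources.as_file(_data_path("table1.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype={"fdr_pct": float, "lnc_fold_change": float})
    parsed = frame["host_fold_change_raw"].map(parse_host_fold_change)
    frame["host_fold_change"] = [p.value for p in parsed]
    frame["host_n_altered_studies"] = [p.n_altered_studies for p in parsed]
    frame["host_n_detected_studies"] = [p.n_detected_studies for p in parsed]
    frame["host_bold"] = [p.bold for p in parsed]
    frame["host_starred"] = [p.starred for p in parsed]
    frame["is_intronic"] = frame["lnc_type"] == "Intronic"
    return frame


def load_table2() -> pd.DataFrame:
    """Per-study common/concordant gene counts of the 217-gene signature."""
    with resources.as_file(_data_path("table2.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def classify_regulation(entries: list[SignedGene] | list[float]) -> tuple[int, int]:
    """(n_up, n_down) by fold-change sign; zero fold changes are rejected."""
    if len(entries) == 0:
        raise ValueError("empty entry list")
    fcs = [e.fold_change if isinstance(e, SignedGene) else float(e) for e in entries]
    if any(fc == 0 for fc in fcs):
        raise ValueError("zero fold change cannot be classified")
    n_up = sum(fc > 0 for fc in fcs)
    return n_up, len(fcs) - n_up


def host_gene_concordance(
    pairs: list[tuple[float, float | None]], fc_min: float = 1.5
) -> tuple[int, int, int]:
    """Classify host-gene alteration relative to the lncRNA direction.

    ``pairs`` holds (lncRNA fold change, host fold change or None).
    A host counts as altered iff |host FC| is strictly greater than
    ``fc_min``; among altered hosts, concordant means same sign as the
    lncRNA. Missing hosts are skipped. Returns
    (n_altered, n_concordant, n_inverse).
    """
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    n_altered = n_concordant = 0
    for lnc_fc, host_fc in pairs:
        if host_fc is None:
            continue
        if abs(host_fc) > fc_min:
            n_altered += 1
            if (lnc_fc > 0) == (host_fc > 0):
                n_concordant += 1
    return n_altered, n_concordant, n_altered - n_concordant


def study_concordance(
    signature: list[SignedGene], study: list[SignedGene]
) -> ConcordanceReport:
    """Shared genes and sign agreement between two signed gene lists."""
    sig = {g.gene_id: g.fold_change for g in signature}
    st = {g.gene_id: g.fold_change for g in study}
    common = set(sig) & set(st)
    concordant = sum((sig[g] > 0) == (st[g] > 0) for g in common)
    return ConcordanceReport(len(common), concordant)


def report_fraction(
    numerator: int, denominator: int, decimals: int = 1, mode: str = "half_away"
) -> float:
    """Percentage 100*num/den rounded to ``decimals``.

    mode="half_away" (default) rounds half away from zero;
    mode="trunc" truncates toward zero — the legacy style some printed
    figures use.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    pct = 100.0 * numerator / denominator
    scale = 10**decimals
    if mode == "half_away":
        return math.floor(pct * scale + 0.5) / scale
    if mode == "trunc":
        return math.floor(pct * scale) / scale
    raise ValueError(f"unknown rounding mode {mode!r}")


def table1_regulation_counts() -> tuple[int, int]:
    """(n_up, n_down) over the 40 transcribed lncRNA fold changes."""
    t1 = load_table1()
    return classify_regulation(list(t1["lnc_fold_change"]))


def table1_host_concordance(fc_min: float = 1.5) -> tuple[int, int, int]:
    """Host-gene concordance over the 29 intronic rows of the fixture."""
    t1 = load_table1()
    intronic = t1[t1["is_intronic"]]
    pairs = [
        (row.lnc_fold_change, None if pd.isna(row.host_fold_change) else row.host_fold_change)
        for row in intronic.itertuples()
    ]
    return host_gene_concordance(pairs, fc_min=fc_min)


def table2_concordance() -> pd.DataFrame:
    """Recompute each study's concordance percentage from its counts."""
    t2 = load_table2()
    t2 = t2.copy()
    t2["pct_recomputed"] = [
        ConcordanceReport(int(r.n_common), int(r.n_concordant)).pct_concordance
        for r in t2.itertuples()
    ]
    return t2
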