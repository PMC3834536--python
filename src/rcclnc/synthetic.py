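"""Synthetic-data generator with planted ground truth.

Every input the analysis pipeline consumes is generated here, emulating
the study design the methods were built for: paired tumor/nontumor
log-normal array intensities (11 pairs by default) with plant-derived
negative-control probes and a planted >= 1.5-fold differentially
expressed lncRNA subset; survival-discriminative probes among the tumor
samples; a toy genome of host genes whose introns contain antisense
lncRNA intervals; mark tracks (CAGE-like with RPKM scores, CpG-like,
histone-like) concentrated near a planted subset of lncRNA TSSs over a
uniform background; per-tissue FPKM tables with planted tissue-specific
rows; cross-tissue expression with planted cis-correlated lncRNA/host
pairs and trans modules; and conserved-element plus per-species cDNA
tracks overlapping a planted lncRNA subset at an elevated rate.

One global seed drives ordered sub-seeds per generator, so each stage is
reproducible independently and identical configs are byte-identical
after serialization. No nucleotide sequence is simulated — intervals
only, since no downstream stage reads sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

LOG2_1P5 = math.log2(1.5)

DEFAULT_PROBE_COUNTS = {
    "intronic_antisense": 722,
    "lincRNA": 262,
    "protein_coding": 2371,
    "negative_control": 100,
}

_CLASS_PREFIX = {
    "intronic_antisense": "LNC",
    "lincRNA": "LINC",
    "protein_coding": "PC",
    "negative_control": "NEG",
}

# log2 background means; controls sit well below expressed probes so the
# mean + k*SD detection rule has headroom
_MU_EXPRESSED = 10.0
_MU_CONTROL = 6.0
_PROBE_EFFECT_SD = 1.0
_PATIENT_EFFECT_SD = 0.3


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    seed: int = 0
    n_pairs: int = 11
    n_probes_by_class: dict = field(default_factory=lambda: dict(DEFAULT_PROBE_COUNTS))
    frac_de: float = 0.05
    planted_log2fc: float = 1.0
    frac_survival: float = 0.05
    n_tissues: int = 4
    frac_cis: float = 0.22
    frac_marked: float = 0.5
    mark_decay_bp: int = 500
    frac_conserved: float = 0.6
    conservation_bg_rate: float = 0.05
    frac_tissue_specific: float = 0.3
    mrna_specific_rate: float = 0.1
    genome_length_bp: int = 40_000_000
    n_chroms: int = 4
    noise_sd: float = 0.5
    n_corr_samples: int = 16  # pseudo-tissue columns for correlation screens
    n_trans_modules: int = 5
    trans_module_size: int = 8
    n_species: int = 4

    def __post_init__(self) -> None:
        fracs = {
            "frac_de": self.frac_de,
            "frac_survival": self.frac_survival,
            "frac_cis": self.frac_cis,
            "frac_marked": self.frac_marked,
            "frac_conserved": self.frac_conserved,
            "conservation_bg_rate": self.conservation_bg_rate,
            "frac_tissue_specific": self.frac_tissue_specific,
            "mrna_specific_rate": self.mrna_specific_rate,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.planted_log2fc < LOG2_1P5:
            raise ConfigError("planted_log2fc must be >= log2(1.5)")
        if self.n_pairs < 3:
            raise ConfigError("n_pairs must be >= 3")
        if self.n_tissues < 2:
            raise ConfigError("n_tissues must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if any(v < 0 for v in self.n_probes_by_class.values()):
            raise ConfigError("probe counts must be non-negative")
        if self.n_probes_by_class.get("negative_control", 0) < 2:
            raise ConfigError("need >= 2 negative-control probes")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Ordered per-stage sub-streams of the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "study": np.random.default_rng(children[0]),
            "genome": np.random.default_rng(children[1]),
            "tissue": np.random.default_rng(children[2]),
        }


@dataclass
class PlantedTruth:
    """Ground truth planted into the generated data."""

    de_probes: dict = field(default_factory=dict)  # probe id -> +1 / -1
    survival_probes: set = field(default_factory=set)
    cis_pairs: dict = field(default_factory=dict)  # lnc id -> (host mRNA id, sign)
    trans_modules: dict = field(default_factory=dict)  # lnc id -> set of mRNA ids
    marked_tss: set = field(default_factory=set)
    conserved_lnc: set = field(default_factory=set)
    tissue_specific_lnc: set = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "de_probes": {k: int(v) for k, v in sorted(self.de_probes.items())},
            "survival_probes": sorted(self.survival_probes),
            "cis_pairs": {k: [v[0], int(v[1])] for k, v in sorted(self.cis_pairs.items())},
            "trans_modules": {k: sorted(v) for k, v in sorted(self.trans_modules.items())},
            "marked_tss": sorted(self.marked_tss),
            "conserved_lnc": sorted(self.conserved_lnc),
            "tissue_specific_lnc": sorted(self.tissue_specific_lnc),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class ExpressionStudy:
    """Probe x sample intensities plus probe and sample annotations."""

    intensities: pd.DataFrame  # linear scale
    probes: pd.DataFrame  # index probe id; columns probe_class, host_gene
    samples: pd.DataFrame  # index sample id; patient, tissue_status, survival_status

    @property
    def negcontrol_ids(self) -> pd.Index:
        return self.probes.index[self.probes["probe_class"] == "negative_control"]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        tumors = self.samples[self.samples["tissue_status"] == "tumor"]
        out = []
        for sid, row in tumors.iterrows():
            partner = self.samples[
                (self.samples["patient"] == row["patient"])
                & (self.samples["tissue_status"] == "nontumor")
            ]
            if len(partner):
                out.append((sid, partner.index[0]))
        return out

    @property
    def tumor_samples(self) -> pd.Index:
        return self.samples.index[self.samples["tissue_status"] == "tumor"]


def _probe_ids(config: SimConfig) -> dict[str, list[str]]:
    return {
        cls: [f"{_CLASS_PREFIX[cls]}_{i:04d}" for i in range(n)]
        for cls, n in config.n_probes_by_class.items()
    }


def generate_expression_study(config: SimConfig) -> tuple[ExpressionStudy, PlantedTruth]:
    """Paired tumor/nontumor intensities with planted effects and truth sets."""
    rng = config.rngs()["study"]
    ids = _probe_ids(config)
    lnc_ids = ids.get("intronic_antisense", [])
    linc_ids = ids.get("lincRNA", [])
    all_lnc = lnc_ids + linc_ids
    probe_ids = [pid for cls in sorted(ids) for pid in ids[cls]]
    classes = {pid: cls for cls in ids for pid in ids[cls]}

    n_probes = len(probe_ids)
    tumor_cols = [f"T{i + 1:02d}" for i in range(config.n_pairs)]
    nontumor_cols = [f"N{i + 1:02d}" for i in range(config.n_pairs)]
    columns = tumor_cols + nontumor_cols

    is_control = np.array([classes[p] == "negative_control" for p in probe_ids])
    mu = np.where(is_control, _MU_CONTROL, _MU_EXPRESSED)
    probe_effect = np.where(is_control, 0.0, rng.normal(0.0, _PROBE_EFFECT_SD, n_probes))
    baseline = mu + probe_effect

    patient_effect = rng.normal(0.0, _PATIENT_EFFECT_SD, config.n_pairs)
    log2 = np.empty((n_probes, len(columns)))
    for j, _ in enumerate(columns):
        pair = j % config.n_pairs
        log2[:, j] = baseline + patient_effect[pair] + rng.normal(0.0, config.noise_sd, n_probes)

    truth = PlantedTruth()

    # planted tumor/nontumor differential expression among lncRNA probes
    n_de = int(round(config.frac_de * len(all_lnc)))
    de_choice = sorted(rng.choice(len(all_lnc), size=n_de, replace=False)) if n_de else []
    for idx in de_choice:
        pid = all_lnc[idx]
        direction = int(rng.choice([-1, 1]))
        truth.de_probes[pid] = direction
        row = probe_ids.index(pid)
        log2[row, : config.n_pairs] += direction * config.planted_log2fc

    # survival outcome on the tumor samples, with planted discriminative probes
    n_tumors = config.n_pairs
    n_dead = n_tumors // 2
    dead_idx = set(rng.choice(n_tumors, size=n_dead, replace=False).tolist())
    survival_status = {}
    for i, col in enumerate(tumor_cols):
        survival_status[col] = "dead" if i in dead_idx else "alive"
    candidates = [p for p in all_lnc if p not in truth.de_probes]
    n_surv = int(round(config.frac_survival * len(all_lnc)))
    n_surv = min(n_surv, len(candidates))
    surv_choice = sorted(rng.choice(len(candidates), size=n_surv, replace=False)) if n_surv else []
    for idx in surv_choice:
        pid = candidates[idx]
        truth.survival_probes.add(pid)
        row = probe_ids.index(pid)
        direction = int(rng.choice([-1, 1]))
        for i, col in enumerate(tumor_cols):
            if i in dead_idx:
                log2[row, i] += direction * config.planted_log2fc

    # remaining planted subsets (ids only; realized by the later generators)
    hosts = {pid: f"GENE_{i:04d}" for i, pid in enumerate(lnc_ids)}
    n_cis = int(round(config.frac_cis * len(lnc_ids)))
    cis_choice = sorted(rng.choice(len(lnc_ids), size=n_cis, replace=False)) if n_cis else []
    for idx in cis_choice:
        pid = lnc_ids[idx]
        truth.cis_pairs[pid] = (f"MRNA_{idx:04d}", int(rng.choice([-1, 1])))

    non_cis = [p for p in lnc_ids if p not in truth.cis_pairs]
    n_modules = min(config.n_trans_modules, len(non_cis))
    module_lncs = (
        [non_cis[i] for i in sorted(rng.choice(len(non_cis), size=n_modules, replace=False))]
        if n_modules
        else []
    )
    mrna_ids = [f"MRNA_{i:04d}" for i in range(len(lnc_ids))]
    cis_hosts = {host for host, _ in truth.cis_pairs.values()}
    for lnc in module_lncs:
        # module members must not be hosts of cis-planted pairs, or the
        # module factor would overwrite the planted cis correlation
        pool = [
            m for m in mrna_ids
            if m not in cis_hosts and m != f"MRNA_{lnc_ids.index(lnc):04d}"
        ]
        size = min(config.trans_module_size, len(pool))
        members = sorted(rng.choice(len(pool), size=size, replace=False))
        truth.trans_modules[lnc] = {pool[i] for i in members}

    n_marked = int(round(config.frac_marked * len(lnc_ids)))
    marked = sorted(rng.choice(len(lnc_ids), size=n_marked, replace=False)) if n_marked else []
    truth.marked_tss = {lnc_ids[i] for i in marked}

    n_cons = int(round(config.frac_conserved * len(lnc_ids)))
    cons = sorted(rng.choice(len(lnc_ids), size=n_cons, replace=False)) if n_cons else []
    truth.conserved_lnc = {lnc_ids[i] for i in cons}

    n_spec = int(round(config.frac_tissue_specific * len(lnc_ids)))
    spec = sorted(rng.choice(len(lnc_ids), size=n_spec, replace=False)) if n_spec else []
    truth.tissue_specific_lnc = {lnc_ids[i] for i in spec}

    intensities = pd.DataFrame(2.0**log2, index=probe_ids, columns=columns)
    probes = pd.DataFrame(
        {
            "probe_class": [classes[p] for p in probe_ids],
            "host_gene": [hosts.get(p) for p in probe_ids],
        },
        index=probe_ids,
    )
    sample_rows = []
    for i, col in enumerate(tumor_cols):
        sample_rows.append((col, f"P{i + 1:02d}", "tumor", survival_status[col]))
    for i, col in enumerate(nontumor_cols):
        sample_rows.append((col, f"P{i + 1:02d}", "nontumor", None))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "patient", "tissue_status", "survival_status"]
    ).set_index("sample")
    return ExpressionStudy(intensities, probes, samples), truth


# ---------------------------------------------------------------------------
# genomic context


@dataclass
class GenomicContext:
    genome: dict[str, int]
    annotation: pd.DataFrame  # per lncRNA probe: host gene, intervals, TSS
    marks: dict[str, list[GenomicInterval]]

    def lnc_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, r.lnc_start, r.lnc_end, r.lnc_strand, name=pid)
            for pid, r in self.annotation.iterrows()
        ]

    def tss_positions(self) -> list[tuple[str, int]]:
        return [(r.chrom, r.tss) for _, r in self.annotation.iterrows()]


def generate_genomic_context(
    config: SimConfig, truth: PlantedTruth
) -> tuple[GenomicContext, dict[str, list[GenomicInterval]]]:
    """Toy genome: host genes with intronic antisense lncRNAs, plus marks.

    Each lncRNA interval lies wholly inside an intron of its host gene;
    for lncRNAs in ``truth.marked_tss`` every track receives one mark at
    an Exponential(mark_decay_bp) distance from the TSS; background marks
    are uniform over the genome. CAGE-like marks carry an RPKM score.
    """
    rng = config.rngs()["genome"]
    lnc_ids = _probe_ids(config).get("intronic_antisense", [])
    n_lnc = len(lnc_ids)
    if n_lnc == 0:
        raise GenerationError("no intronic antisense probes configured")
    chrom_len = config.genome_length_bp // config.n_chroms
    genome = {f"chr{c + 1}": chrom_len for c in range(config.n_chroms)}
    per_chrom = math.ceil(n_lnc / config.n_chroms)
    slot = chrom_len // per_chrom
    if slot < 3000:
        raise GenerationError(
            f"genome too small: slot of {slot} bp cannot hold a gene with an "
            "intronic lncRNA; increase genome_length_bp"
        )
    gene_len = min(20_000, slot * 3 // 4)
    rows = []
    for i, pid in enumerate(lnc_ids):
        chrom = f"chr{i // per_chrom + 1}"
        within = (i % per_chrom) * slot
        gene_start = within + int(rng.integers(0, max(1, slot - gene_len)))
        gene_end = gene_start + gene_len
        gene_strand = "+" if rng.random() < 0.5 else "-"
        intron_start = gene_start + gene_len // 4
        intron_end = gene_end - gene_len // 4
        lnc_len = int(rng.integers(250, 601))
        lnc_start = intron_start + int(rng.integers(0, intron_end - intron_start - lnc_len))
        lnc_end = lnc_start + lnc_len
        lnc_strand = "-" if gene_strand == "+" else "+"
        tss = lnc_start if lnc_strand == "+" else lnc_end - 1
        rows.append(
            (pid, f"GENE_{i:04d}", chrom, gene_start, gene_end, gene_strand,
             intron_start, intron_end, lnc_start, lnc_end, lnc_strand, tss)
        )
    annotation = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "host_gene", "chrom", "gene_start", "gene_end", "gene_strand",
            "intron_start", "intron_end", "lnc_start", "lnc_end", "lnc_strand", "tss",
        ],
    ).set_index("probe_id")

    marks: dict[str, list[GenomicInterval]] = {}
    chroms = sorted(genome)
    for track, scored in (("cage", True), ("cpg", False), ("histone", False)):
        intervals: list[GenomicInterval] = []
        for pid in lnc_ids:
            if pid not in truth.marked_tss:
                continue
            row = annotation.loc[pid]
            d = int(rng.exponential(config.mark_decay_bp))
            side = -1 if rng.random() < 0.5 else 1
            length = int(rng.integers(100, 301))
            center = int(row.tss) + side * d
            start = max(0, min(center - length // 2, genome[row.chrom] - length))
            score = 1.0 + float(rng.exponential(5.0)) if scored else None
            intervals.append(GenomicInterval(row.chrom, start, start + length, score=score))
        n_bg = n_lnc  # one background mark per lncRNA keeps tracks dense but diffuse
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(100, 301))
            start = int(rng.integers(0, genome[chrom] - length))
            score = float(2.0 ** rng.normal(0.0, 1.0)) if scored else None
            intervals.append(GenomicInterval(chrom, start, start + length, score=score))
        marks[track] = intervals
    context = GenomicContext(genome, annotation, marks)
    return context, marks


# ---------------------------------------------------------------------------
# tissue panel and conservation tracks


@dataclass
class TissuePanel:
    """Cross-tissue tables: FPKM for specificity, expression for correlation."""

    fpkm: pd.DataFrame  # lnc + mRNA rows x n_tissues columns
    lnc_expr: pd.DataFrame  # lnc rows x n_corr_samples pseudo-tissue columns
    mrna_expr: pd.DataFrame  # mRNA rows x n_corr_samples columns
    locus_map: dict  # lnc id -> host mRNA id
    go_annotation: dict  # mRNA id -> set of GO-style terms


def generate_tissue_and_conservation(
    config: SimConfig, truth: PlantedTruth, context: GenomicContext | None = None
) -> tuple[TissuePanel, dict[str, list[GenomicInterval]], dict[str, list[GenomicInterval]]]:
    """Per-tissue FPKM, correlated expression, conserved and cDNA tracks.

    Tissue-specific rows carry >= 50% of their FPKM in one tissue;
    conserved lncRNAs overlap a conserved element (others at the
    background rate); species cDNA tracks hit conserved lncRNAs at an
    elevated rate. ``context`` supplies the lncRNA intervals the tracks
    are placed against; when omitted it is generated from the config.
    """
    rng = config.rngs()["tissue"]
    if context is None:
        context, _ = generate_genomic_context(config, truth)
    annotation = context.annotation
    lnc_ids = list(annotation.index)
    mrna_ids = [f"MRNA_{i:04d}" for i in range(len(lnc_ids))]
    locus_map = {pid: f"MRNA_{i:04d}" for i, pid in enumerate(lnc_ids)}

    # --- FPKM table for the specificity statistic
    tissues = [f"tissue_{t + 1}" for t in range(config.n_tissues)]

    def specific_row() -> np.ndarray:
        dominant = int(rng.integers(0, config.n_tissues))
        share = rng.uniform(0.6, 0.95)
        rest = rng.dirichlet(np.ones(config.n_tissues - 1)) * (1 - share)
        fet = np.insert(rest, dominant, share)
        return fet * float(2.0 ** rng.normal(5.0, 1.0))

    def diffuse_row() -> np.ndarray:
        fet = rng.dirichlet(np.full(config.n_tissues, 5.0))
        return fet * float(2.0 ** rng.normal(5.0, 1.0))

    fpkm_rows = {}
    for pid in lnc_ids:
        fpkm_rows[pid] = (
            specific_row() if pid in truth.tissue_specific_lnc else diffuse_row()
        )
    for mid in mrna_ids:
        fpkm_rows[mid] = (
            specific_row() if rng.random() < config.mrna_specific_rate else diffuse_row()
        )
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=tissues)

    # --- cross-tissue expression with planted cis pairs and trans modules
    n_cols = config.n_corr_samples
    cols = [f"pool_{c + 1}" for c in range(n_cols)]
    mrna_mat = rng.normal(8.0, 2.0, size=(len(mrna_ids), n_cols))
    lnc_mat = rng.normal(8.0, 2.0, size=(len(lnc_ids), n_cols))
    mrna_pos = {m: i for i, m in enumerate(mrna_ids)}
    for i, pid in enumerate(lnc_ids):
        pair = truth.cis_pairs.get(pid)
        if pair is None:
            continue
        host, sign = pair
        h = mrna_mat[mrna_pos[host]]
        lnc_mat[i] = 8.0 + sign * (h - h.mean()) + rng.normal(0.0, 0.5, n_cols)
    for lnc, members in truth.trans_modules.items():
        factor = rng.normal(0.0, 1.0, n_cols)
        li = lnc_ids.index(lnc)
        lnc_mat[li] = 8.0 + 2.0 * factor + rng.normal(0.0, 0.3, n_cols)
        for m in sorted(members):
            mrna_mat[mrna_pos[m]] = 8.0 + 2.0 * factor + rng.normal(0.0, 0.3, n_cols)
    lnc_expr = pd.DataFrame(lnc_mat, index=lnc_ids, columns=cols)
    mrna_expr = pd.DataFrame(mrna_mat, index=mrna_ids, columns=cols)

    # --- GO-style annotation: one planted term per trans module + noise terms
    go_annotation: dict[str, set] = {m: set() for m in mrna_ids}
    for k, (lnc, members) in enumerate(sorted(truth.trans_modules.items())):
        term = f"GO:module_{k:02d}"
        for m in members:
            go_annotation[m].add(term)
    for j in range(10):
        term = f"GO:background_{j:02d}"
        size = int(rng.integers(10, 40))
        for idx in rng.choice(len(mrna_ids), size=min(size, len(mrna_ids)), replace=False):
            go_annotation[mrna_ids[idx]].add(term)

    # --- conserved elements and species cDNA tracks
    genome = context.genome
    chroms = sorted(genome)
    elements: list[GenomicInterval] = []
    for pid in lnc_ids:
        hit = pid in truth.conserved_lnc or rng.random() < config.conservation_bg_rate
        if not hit:
            continue
        row = annotation.loc[pid]
        length = int(min(200, row.lnc_end - row.lnc_start))
        start = int(row.lnc_start) + int(rng.integers(0, row.lnc_end - row.lnc_start - length + 1))
        elements.append(GenomicInterval(row.chrom, start, start + length))
    for _ in range(len(lnc_ids) // 4):  # scattered background elements
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(50, 300))
        start = int(rng.integers(0, genome[chrom] - length))
        elements.append(GenomicInterval(chrom, start, start + length))
    conserved_tracks = {"phastcons": elements}

    species_tracks: dict[str, list[GenomicInterval]] = {}
    species = [f"species_{s + 1}" for s in range(config.n_species)] + ["mouse"]
    for sp in species:
        hit_rate = 0.15 if sp == "mouse" else 0.5
        track: list[GenomicInterval] = []
        for pid in lnc_ids:
            conserved = pid in truth.conserved_lnc
            p_hit = hit_rate if conserved else config.conservation_bg_rate / 2
            if rng.random() >= p_hit:
                continue
            row = annotation.loc[pid]
            length = int(rng.integers(100, 400))
            center = int((row.lnc_start + row.lnc_end) // 2)
            start = max(0, center - length // 2)
            track.append(GenomicInterval(row.chrom, start, start + length))
        species_tracks[sp] = track

    panel = TissuePanel(fpkm, lnc_expr, mrna_expr, locus_map, go_annotation)
    return panel, conserved_tracks, species_tracks


# ---------------------------------------------------------------------------
# bundle + serialization


@dataclass
class SyntheticDataset:
    config: SimConfig
    study: ExpressionStudy
    truth: PlantedTruth
    context: GenomicContext
    tissue: TissuePanel
    conserved_tracks: dict
    species_tracks: dict

    def save(self, outdir) -> None:
        """Write every table as TSV/BED/JSON under ``outdir``."""
        from .intervals import write_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.study.intensities.to_csv(out / "intensities.tsv", sep="\t", float_format="%.6f")
        self.study.probes.to_csv(out / "probes.tsv", sep="\t")
        self.study.samples.to_csv(out / "samples.tsv", sep="\t")
        self.context.annotation.to_csv(out / "annotation.tsv", sep="\t")
        write_bed(out / "lnc_intervals.bed", self.context.lnc_intervals())
        for name, track in sorted(self.context.marks.items()):
            write_bed(out / f"mark_{name}.bed", track)
        for name, track in sorted(self.conserved_tracks.items()):
            write_bed(out / f"conserved_{name}.bed", track)
        for name, track in sorted(self.species_tracks.items()):
            write_bed(out / f"cdna_{name}.bed", track)
        self.tissue.fpkm.to_csv(out / "fpkm.tsv", sep="\t", float_format="%.6f")
        self.tissue.lnc_expr.to_csv(out / "lnc_tissue_expr.tsv", sep="\t", float_format="%.6f")
        self.tissue.mrna_expr.to_csv(out / "mrna_tissue_expr.tsv", sep="\t", float_format="%.6f")
        (out / "truth.json").write_text(self.truth.to_json())
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)


def generate_all(config: SimConfig) -> SyntheticDataset:
    """Run the three generators in order under their sub-seeds."""
    study, truth = generate_expression_study(config)
    context, _ = generate_genomic_context(config, truth)
    tissue, conserved, species = generate_tissue_and_conservation(config, truth, context)
    return SyntheticDataset(config, study, truth, context, tissue, conserved, species)
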