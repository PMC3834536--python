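"""End-to-end orchestration over the synthetic cohort plus the bundled
worked-example tables.

``run_all`` executes simulate -> preprocess -> signatures -> coexpression
-> genomic context -> specificity/conservation -> concordance, writing a
machine-readable JSON summary (every headline statistic) and a
human-readable report. All thresholds default to the published values
(detection mean + 3 SD, 90% prevalence, SAM FDR 5%/10%, 1.5-fold,
Golub p 0.01, cis |rho| > 0.5 / trans |rho| >= 0.7 at p < 0.05,
top-20% abundance, F.E.T. 0.5, 10 kb window, 1 kb bins, 10 controls,
1000 permutations); overrides are recorded in the run log. A single seed
drives every source of randomness.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import concordance, conservation, coexpression, genomic, preprocess, signatures
from .intervals import GenomicInterval, overlap_count
from .synthetic import SimConfig, generate_all

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "rcclnc_out"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    fdr_malignancy: float = 0.05
    fdr_survival: float = 0.10
    fc_min: float = 1.5
    golub_p: float = 0.01
    cis_rho: float = 0.5
    trans_rho: float = 0.7
    corr_p: float = 0.05
    abundance_frac: float = 0.2
    fet_cut: float = 0.5
    max_dist: int = 10_000
    bin_size: int = 1000
    n_controls: int = 10
    n_perm: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    defaults = PipelineConfig()
    for key, value in asdict(config).items():
        if key not in ("seed", "outdir", "sim") and value != getattr(defaults, key):
            logger.warning("threshold override: %s = %r", key, value)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}

    # --- simulate
    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    data = generate_all(sim_cfg)
    data.save(out / "synthetic")
    logger.info("simulate: %d probes x %d arrays", *data.study.intensities.shape)

    # --- preprocess (spotted-array rules: mean + 3 SD, 90% prevalence)
    study = data.study
    rule = preprocess.DetectionRule(k_sd=3.0, scope="per-array")
    mask = preprocess.detect_expressed(study.intensities, study.negcontrol_ids, rule)
    groups = study.samples["tissue_status"]
    retained = preprocess.filter_by_prevalence(mask, groups, preprocess.PrevalenceRule(0.9))
    retained = retained.difference(study.negcontrol_ids)
    normalized = preprocess.quantile_normalize(study.intensities.loc[retained])
    ratios = preprocess.log2_ratio(normalized, study.pairs)
    summary["preprocess"] = {
        "n_probes": int(study.intensities.shape[0]),
        "n_retained": int(len(retained)),
    }

    # --- malignancy signature (lncRNA probes only)
    lnc_classes = ("intronic_antisense", "lincRNA")
    lnc_retained = [p for p in retained if study.probes.loc[p, "probe_class"] in lnc_classes]
    loo = signatures.leave_one_out_signature(
        ratios.loc[lnc_retained],
        fdr_cut=config.fdr_malignancy,
        fc_min=config.fc_min,
        n_perm=config.n_perm,
        seed=seeds[0],
    )
    final = set(loo.final)
    truth_de = set(data.truth.de_probes)
    sens = len(final & truth_de) / len(truth_de) if truth_de else float("nan")
    fdp = len(final - truth_de) / len(final) if final else 0.0
    summary["malignancy"] = {
        "n_final": len(final),
        "n_planted": len(truth_de),
        "sensitivity": sens,
        "false_discovery_proportion": fdp,
        "full_run_selected": int(len(loo.full_result.selected)),
    }
    loo.table.to_csv(out / "malignancy_signature.tsv", sep="\t")

    # --- survival signature on tumors
    tumors = study.tumor_samples
    outcome = study.samples.loc[tumors, "survival_status"]
    surv = signatures.survival_signature(
        np.log2(normalized[tumors]).loc[lnc_retained],
        outcome,
        sam_fdr=config.fdr_survival,
        golub_p=config.golub_p,
        n_perm=config.n_perm,
        seed=seeds[1],
    )
    truth_surv = set(data.truth.survival_probes)
    hit = set(surv.genes) & truth_surv
    summary["survival"] = {
        "n_genes": int(len(surv.genes)),
        "n_planted": len(truth_surv),
        "sensitivity": len(hit) / len(truth_surv) if truth_surv else float("nan"),
        "ordered_samples": surv.ordered_samples,
    }

    # --- co-expression across the tissue panel
    panel = data.tissue
    cis_records, cis_summary = coexpression.cis_correlation(
        panel.lnc_expr, panel.mrna_expr, panel.locus_map,
        rho_cut=config.cis_rho, p_cut=config.corr_p,
    )
    truth_cis = set(data.truth.cis_pairs)
    cis_hits = set(cis_records["lnc_id"]) & truth_cis
    top = coexpression.select_top_abundant(panel.lnc_expr, frac=config.abundance_frac)
    trans_records, trans_summary = coexpression.trans_correlation(
        panel.lnc_expr.loc[top], panel.mrna_expr, panel.locus_map,
        rho_cut=config.trans_rho, p_cut=config.corr_p,
    )
    module_map = coexpression.go_module_map(
        trans_records, panel.go_annotation, set(panel.mrna_expr.index)
    )
    summary["coexpression"] = {
        "cis": {**cis_summary,
                "sensitivity": len(cis_hits) / len(truth_cis) if truth_cis else float("nan")},
        "n_top_abundant": int(len(top)),
        "trans": trans_summary,
        "n_enriched_module_cells": int((module_map["sign"] != 0).sum()) if len(module_map) else 0,
    }
    cis_records.to_csv(out / "cis_records.tsv", sep="\t", index=False)
    trans_records.to_csv(out / "trans_records.tsv", sep="\t", index=False)
    module_map.to_csv(out / "module_map.tsv", sep="\t", index=False)

    # --- TSS-proximity mark enrichment vs random controls
    context = data.context
    tss = context.tss_positions()
    lnc_iv = context.lnc_intervals()
    lengths = [len(iv) for iv in lnc_iv]
    exclusions = [
        GenomicInterval(r.chrom, max(0, r.gene_start - 1000), r.gene_start + 1)
        for _, r in context.annotation.iterrows()
    ]
    controls = genomic.make_random_controls(
        lengths, context.genome, exclusions, n_sets=config.n_controls,
        seed=seeds[2],
    )
    marks_summary = {}
    for name, track in sorted(context.marks.items()):
        use = genomic.filter_by_score(track, 1.0) if name == "cage" else track
        qd = genomic.distance_distribution(tss, use, config.max_dist, config.bin_size)
        ctrl_ds = [
            genomic.distance_distribution(
                [(iv.chrom, iv.start) for iv in ctrl], use, config.max_dist, config.bin_size
            )
            for ctrl in controls
        ]
        ks = genomic.ks_enrichment_test(qd, ctrl_ds)
        # broad marks additionally get an overlap count per lncRNA interval
        _, overlap_totals = overlap_count(lnc_iv, use)
        marks_summary[name] = {
            "n_within_window": int(len(qd.distances)),
            "n_no_mark": qd.n_no_mark,
            "max_ks_p": ks["max_p"],
            "all_controls_reject": ks["all_reject"],
            "histogram": qd.histogram.tolist(),
            "histogram_5kb": qd.restricted(5000).histogram.tolist(),
            "n_lnc_with_overlap": overlap_totals["n_with_overlap"],
        }
    summary["genomic_marks"] = marks_summary

    # --- specificity and conservation
    fet = conservation.fet_table(panel.fpkm)
    lnc_ids = list(context.annotation.index)
    mrna_ids = [panel.locus_map[p] for p in lnc_ids]
    _, spec_p = conservation.specificity_fisher(
        fet.loc[lnc_ids, "specific"], fet.loc[mrna_ids, "specific"]
    )
    cons = conservation.conservation_enrichment(
        lnc_iv, data.conserved_tracks["phastcons"], controls
    )
    hits, frac_expr_cons = conservation.expression_conservation(lnc_iv, data.species_tracks)
    non_conserved = [iv for iv in lnc_iv if iv.name not in data.truth.conserved_lnc]
    syn = conservation.syntenic_overlap(
        lnc_iv, data.species_tracks["mouse"], non_conserved
    )
    summary["specificity_conservation"] = {
        "lnc_specific_rate": float(fet.loc[lnc_ids, "specific"].mean()),
        "mrna_specific_rate": float(fet.loc[mrna_ids, "specific"].mean()),
        "specificity_fisher_p": spec_p,
        "conserved_overlap_frac": cons.n_overlapping / cons.n_total,
        "conservation_max_fisher_p": max(cons.fisher_p),
        "expression_conserved_frac": frac_expr_cons,
        "syntenic_n_overlap": syn.n_query_hit,
        "syntenic_fisher_p": syn.fisher_p,
    }

    # --- worked-example concordance tables
    n_up, n_down = concordance.table1_regulation_counts()
    host = concordance.table1_host_concordance(fc_min=config.fc_min)
    t2 = concordance.table2_concordance()
    summary["concordance"] = {
        "table1_n_up": n_up,
        "table1_n_down": n_down,
        "host_altered": host[0],
        "host_concordant": host[1],
        "host_inverse": host[2],
        "table2_pct": dict(zip(t2["study"], t2["pct_recomputed"])),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_report(out / "report.txt", summary)
    return summary


def _flatten(prefix: str, obj, lines: list[str]) -> None:
    if isinstance(obj, dict):
        for k in sorted(obj):
            _flatten(f"{prefix}.{k}" if prefix else str(k), obj[k], lines)
    else:
        lines.append(f"{prefix}\t{obj}")


def _write_report(path, summary: dict) -> None:
    lines: list[str] = []
    _flatten("", summary, lines)
    Path(path).write_text("\n".join(lines) + "\n")


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="rcclnc-pipeline",
        description="Run the full synthetic-cohort analysis pipeline.",
    )
    parser.add_argument("--config", help="YAML pipeline config file")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--out", default=None, help="output directory")
    parser.add_argument("-v", "--verbose", action="store_true")
    args = parser.parse_args(argv)
    logging.basicConfig(
        level=logging.INFO if args.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    try:
        config = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
        if args.seed is not None:
            config.seed = args.seed
        if args.out is not None:
            config.outdir = args.out
        run_all(config)
    except Exception as exc:  # pragma: no cover - exercised via CLI tests
        print(f"pipeline failed: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
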