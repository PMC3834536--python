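"""Tissue specificity (F.E.T.) and conservation-overlap enrichment.

Computes the fraction-of-expression statistic over a 4-tissue FPKM table
(specific = max F.E.T. >= 0.5), compares lncRNA vs mRNA specificity rates
by Fisher's exact test, and tests conserved-element overlap of the lncRNA
intervals against 10 random control sets.
"""

from rcclnc import conservation, genomic
from rcclnc.synthetic import SimConfig, generate_all

cfg = SimConfig(
    seed=5,
    n_probes_by_class={
        "intronic_antisense": 300, "lincRNA": 0,
        "protein_coding": 0, "negative_control": 10,
    },
    frac_tissue_specific=0.3, frac_conserved=0.6,
    genome_length_bp=20_000_000,
)
data = generate_all(cfg)

fet = conservation.fet_table(data.tissue.fpkm)
lnc_ids = list(data.context.annotation.index)
mrna_ids = [data.tissue.locus_map[p] for p in lnc_ids]
odds, p = conservation.specificity_fisher(
    fet.loc[lnc_ids, "specific"], fet.loc[mrna_ids, "specific"]
)
print(f"tissue-specific lncRNAs : {fet.loc[lnc_ids, 'specific'].mean():.0%}")
print(f"tissue-specific mRNAs   : {fet.loc[mrna_ids, 'specific'].mean():.0%}")
print(f"Fisher exact            : OR={odds:.1f}, p={p:.2e}")

ivs = data.context.lnc_intervals()
controls = genomic.make_random_controls(
    [len(iv) for iv in ivs], data.context.genome, n_sets=10, seed=5
)
cons = conservation.conservation_enrichment(
    ivs, data.conserved_tracks["phastcons"], controls
)
print(f"lncRNAs overlapping conserved elements : "
      f"{cons.n_overlapping}/{cons.n_total} "
      f"(controls: {min(cons.control_overlapping)}-{max(cons.control_overlapping)})")
print(f"worst Fisher p across 10 controls      : {max(cons.fisher_p):.2e}")

hits, frac = conservation.expression_conservation(ivs, data.species_tracks)
print(f"expressed in >=1 other species         : {frac:.0%}")
# The planted 60% conserved subset drives overlap far above the ~5%
# background seen in the random controls, mirroring the enrichment logic
# used for conserved-element and cross-species expression comparisons.
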