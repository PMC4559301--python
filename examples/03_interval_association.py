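"""Spatial association of DMRs with repeat classes via interval permutation.

For each repeat class, the observed Jaccard overlap and relative-distance
distribution of the DMR intervals are compared to 1000 genome-wide
repositionings (lengths and chromosomes preserved); positive relationships
mean the DMRs sit on or near the features more than chance allows.
"""

import medipdmr as m

cfg = m.SimConfig(n_chromosomes=2, chrom_length=300_000,
                  n_dmr_hypo=60, n_dmr_hyper=20, seed=11)
genome, annotation, matrix, truth, samples = m.simulate_study(cfg)
sizes = {c: len(s) for c, s in genome.items()}
dmrs = truth.planted_dmrs[["chrom", "start", "end"]]

print("query: planted DMRs (hypo ones biased into SINEs)")
print(f"{'class':>6} {'jaccard':>9} {'jac p':>9} {'relation':>9} {'KS p':>9}")
for cls in ("SINE", "LINE", "LTR"):
    ref = annotation.repeats_of_class(cls)
    sa = m.permutation_association(dmrs, ref, sizes, n_perm=1000, seed=11,
                                   query_name="DMRs", reference_name=cls)
    print(f"{cls:>6} {sa.jaccard_observed:9.4f} {sa.jaccard_p:9.4f} "
          f"{sa.jaccard_relationship:>9} {sa.ks_p:9.4f}")

comp = m.overlap_composition(dmrs, annotation)
print(f"\nDMR overlap composition: {comp['repeat']:.0%} repeats, "
      f"{comp['gene']:.0%} genes, {comp['CpGi']:.0%} CpG islands")
print("repeat families among repeat-overlapping DMRs:",
      {k: round(v, 2) for k, v in comp["repeat_families"].items() if v > 0})
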