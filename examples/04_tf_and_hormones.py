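"""Classify TF families and find hormone-pathway divergence.

TF families are scored by upregulated members (log2fc >= 2) per stage;
families with >= 5 members in some stage are significant, and a family
with >= 3 more members in early (S1-S2) than late (S3-S5) stages of
exactly one genotype is genotype-stage preferential.  Hormone genes are
clustered jointly across genotypes; a gene whose SN and LGR profiles
land in different clusters is divergent.
"""

import seedcomp as sc

dataset = sc.generate_dataset(sc.SimConfig(seed=7))
annotation = sc.matrix.validate_annotation(dataset.annotation)
det = sc.call_degs(dataset.genes)

fc = sc.family_stage_counts(det, annotation, fc_min=2.0)
print("upregulated members per family/genotype/stage:")
print(fc.counts)

pref = sc.classify_preferential(fc)
flagged = pref[pref.genotype_stage_preferential & (pref.label != "none")]
for row in flagged.itertuples():
    print(f"{row.family}: {row.genotype}-{row.label} preferential")

opp = sc.detect_opposite_pattern(fc)
for row in opp.itertuples():
    print(f"{row.family}: opposite pattern at {row.stage} "
          f"(max in {row.max_genotype}, min in {row.min_genotype})")

profiles = sc.build_hormone_profiles(dataset.genes, annotation)
n_per = profiles.groupby("pathway").size()
k_map = {p: max(2, int(n) // 6) for p, n in n_per.items()}
assignments = sc.cluster_hormone_genes(profiles, k_map, seed=7)
divergent = sc.divergent_genes(assignments)
print("divergent hormone genes per pathway:",
      {p: len(v) for p, v in sorted(divergent.items())})
# Divergent genes are candidates for grain-size variation: the same gene
# follows a different temporal program in the two genotypes.
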