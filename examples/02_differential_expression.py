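"""Call DEGs/DEMs of each seed stage against flag leaf.

Thresholds follow the study: genes FPKM >= 1, |log2fc| >= 1, q <= 0.05;
miRNAs TPM >= 50, |log2fc| >= 2, q <= 0.05.
"""

import seedcomp as sc

dataset = sc.generate_dataset(sc.SimConfig(seed=7))

gene_det = sc.call_degs(dataset.genes)                      # gene thresholds
mirna_det = sc.call_degs(dataset.mirnas,
                         thresholds=sc.MIRNA_THRESHOLDS)    # DEM thresholds

for genotype in ("SN", "LGR"):
    sub = gene_det[(gene_det.genotype == genotype) & gene_det.significant]
    print(f"{genotype}: {sub.feature_id.nunique()} DEGs over the five stages")

spec = sc.stage_specific_sets(gene_det, fc_min=1.0)
common = sc.common_all_stage_sets(gene_det)
print("SN S3 up-specific genes:", len(spec[("SN", "S3", "up")]))
print("SN up-in-all-stages genes:", len(common[("SN", "up")]))
# Stage-specific = significant in exactly one stage with log2fc below the
# cut elsewhere; common = significant in the same direction in all five.

seed_spec = sc.seed_specific_features(dataset.genes, "SN")
print("SN seed-specific genes (FPKM >= 1 in a stage, < 1 in leaf):",
      len(seed_spec))
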