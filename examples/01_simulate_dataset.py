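"""Generate a synthetic two-genotype seed-development dataset.

Two genotypes (small-grained SN, large-grained LGR), five seed stages
plus flag leaf, three replicates, with a planted one-stage developmental
lag of LGR and known differential structure.
"""

import seedcomp as sc

config = sc.SimConfig(seed=7)
dataset = sc.generate_dataset(config)
paths = sc.write_dataset(dataset, "scratch/example_dataset")

print(f"gene matrix: {dataset.genes.values.shape[0]} genes x "
      f"{dataset.genes.values.shape[1]} samples (FPKM)")
print(f"miRNA matrix: {dataset.mirnas.values.shape[0]} miRNAs (TPM)")
print(f"planted lag: {dataset.truth.lag} stage "
      f"(LGR runs one stage behind SN)")
n_ss = sum(len(v) for per in dataset.truth.stage_specific["SN"].values()
           for v in per.values())
print(f"planted stage-specific DEGs (SN): {n_ss}")
print(f"planted miRNA-target modules: {len(dataset.truth.modules)}")
print(f"files written under: {paths['genes'].parent}")
# The ground-truth JSON lists every planted gene class, so each
# downstream analysis can be scored against what was actually planted.
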