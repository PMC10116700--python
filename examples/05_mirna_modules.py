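"""Mine anti-correlated miRNA-target modules.

A module pairs a miRNA up (down) in all five stages of a genotype with a
predicted target down (up) in all five stages of the same genotype;
opposite-regulation modules cross genotypes over same/comparable stage
pairs.
"""

import seedcomp as sc
from seedcomp.mirna import all_stage_dems, extract_modules, opposite_modules

dataset = sc.generate_dataset(sc.SimConfig(seed=7))
gene_det = sc.call_degs(dataset.genes)
mirna_det = sc.call_degs(dataset.mirnas, thresholds=sc.MIRNA_THRESHOLDS)

dems = all_stage_dems(mirna_det)
for (genotype, direction), ids in sorted(dems.items()):
    print(f"{genotype} {direction}-in-all-stages miRNAs: {len(ids)}")

modules = extract_modules(dems, dataset.targets, gene_det)
print(f"\nall-stage modules: {len(modules)} "
      f"({int(modules.common_both_genotypes.sum())} rows shared by both "
      "genotypes)")
print(modules.head(5).to_string(index=False))

cs = sc.StagePairing(pairs=[tuple(p) for p in dataset.truth.comparable_chain],
                     kind="CS", offset=dataset.truth.lag)
opp = opposite_modules(
    mirna_det[mirna_det.genotype == "SN"],
    mirna_det[mirna_det.genotype == "LGR"],
    gene_det[gene_det.genotype == "SN"],
    gene_det[gene_det.genotype == "LGR"],
    {"SS": sc.same_stage_pairing(), "CS": cs}, dataset.targets)
print(f"\nopposite-regulation modules: {len(opp)}")
print(opp.to_string(index=False))
# Each row is a (miRNA, target) pair whose differential-expression calls
# oppose each other across the two genotypes' aligned stages.
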