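"""Align the two genotypes' stages by DEG-set similarity.

Percent similarity is Jaccard x 100 on per-stage DEG sets (signed by
direction).  Each LGR stage is paired with its most similar SN stage;
with the planted one-stage lag the chain SN S1-LGR S2 ... SN S4-LGR S5
should be recovered.
"""

import seedcomp as sc
from seedcomp.core import DIRECTIONS, SEED_STAGES

dataset = sc.generate_dataset(sc.SimConfig(seed=7))
det = sc.call_degs(dataset.genes)
sig = sc.significant_sets(det)

sets = {g: {(s, d): sig.get((g, s, d), set())
            for s in SEED_STAGES for d in DIRECTIONS}
        for g in ("SN", "LGR")}
sims = sc.similarity_matrix(sets["SN"], sets["LGR"])
print("combined percent-similarity matrix (rows SN, cols LGR):")
print(sims["combined"].round(1))

pairing = sc.assign_comparable_stages(sims["combined"])
print(f"\ndetected offset: {pairing.offset} (consistent={pairing.consistent})")
print("comparable stages:", " ".join(f"SN {a}-LGR {b}"
                                     for a, b in pairing.pairs))
# The off-diagonal maxima mean each LGR stage resembles the *previous*
# SN stage: LGR's developmental program runs one stage late.

cons = sc.consecutive_similarity(sets["LGR"])
print("\nLGR consecutive-stage similarity (up-DEGs):")
print(cons[["from_stage", "to_stage", "up"]].round(1).to_string(index=False))
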