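"""Cross-genotype stage alignment from DEG-set similarity.

Percent similarity between two DEG sets is Jaccard x 100 by default
(|A n B| / |A u B|), computed per direction; the combined similarity
pools signed elements (gene, direction) so that a gene up in one stage
and down in another never matches itself.  Each stage of the second
genotype is assigned the most similar stage of the first; when the
argmaxes form a consistent offset the comparable-stage (CS) chain is
reported, mirroring the observation that each large-grain stage tracks
the preceding small-grain stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import DIRECTIONS, DOWN, SEED_STAGES, UP

StageSets = Mapping[tuple[str, str], set]  # (stage, direction) -> feature set


def percent_similarity(set_a: set, set_b: set, mode: str = "jaccard") -> float:
    """Percent similarity of two feature sets; 0 when both are empty.

    mode "jaccard": 100*|A n B|/|A u B| (default, symmetric);
    mode "of_b": 100*|A n B|/|B| (overlap relative to the second set).
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    if mode == "jaccard":
        denom = len(a | b)
    elif mode == "of_b":
        denom = len(b)
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    return 100.0 * inter / denom if denom else 0.0


def _signed(sets: StageSets, stage: str) -> set:
    out = set()
    for d in DIRECTIONS:
        out |= {(f, d) for f in sets.get((stage, d), ())}
    return out


def similarity_matrix(
    sets_a: StageSets,
    sets_b: StageSets,
    stages: Sequence[str] = SEED_STAGES,
    mode: str = "jaccard",
) -> dict[str, pd.DataFrame]:
    """Stage x stage percent-similarity matrices: 'up', 'down', 'combined'.

    Rows are stages of genotype A, columns stages of genotype B.
    """
    out: dict[str, pd.DataFrame] = {}
    for d in DIRECTIONS:
        out[d] = pd.DataFrame(
            [[percent_similarity(sets_a.get((sa, d), set()),
                                 sets_b.get((sb, d), set()), mode)
              for sb in stages] for sa in stages],
            index=list(stages), columns=list(stages))
    out["combined"] = pd.DataFrame(
        [[percent_similarity(_signed(sets_a, sa), _signed(sets_b, sb), mode)
          for sb in stages] for sa in stages],
        index=list(stages), columns=list(stages))
    return out


@dataclass
class StagePairing:
    """Ordered (stage_a, stage_b) pairs with their pairing kind."""

    pairs: list[tuple[str, str]]
    kind: str  # "SS" or "CS"
    offset: int | None = None
    consistent: bool = True
    best_match: dict[str, str] = field(default_factory=dict)


def same_stage_pairing(stages: Sequence[str] = SEED_STAGES) -> StagePairing:
    return StagePairing(pairs=[(s, s) for s in stages], kind="SS", offset=0)


def assign_comparable_stages(combined: pd.DataFrame) -> StagePairing:
    """Assign each B stage the most similar A stage and extract the CS chain.

    Ties break toward the earlier A stage.  The offset is the most common
    (stage index B - stage index A) over the per-stage argmaxes; the chain
    is flagged consistent when every B stage that can realise that offset
    does.  Offset 0 yields the identity pairing.
    """
    stages = list(combined.index)
    best: dict[str, str] = {}
    offsets: list[int] = []
    for j, sb in enumerate(combined.columns):
        col = combined[sb]
        sa = col.idxmax()  # first occurrence -> earlier stage on ties
        best[sb] = sa
        offsets.append(j - stages.index(sa))
    counts = Counter(offsets)
    top = max(counts.values())
    offset = min(d for d, c in counts.items() if c == top)
    consistent = all(
        offsets[j] == offset for j in range(len(stages)) if j - offset >= 0
    ) and offset >= 0
    if offset >= 0:
        pairs = [(stages[i], stages[i + offset])
                 for i in range(len(stages) - offset)]
    else:
        pairs = [(best[sb], sb) for sb in stages]
    return StagePairing(pairs=pairs, kind="CS", offset=offset,
                        consistent=consistent, best_match=best)


def consecutive_similarity(
    sets: StageSets,
    stages: Sequence[str] = SEED_STAGES,
    mode: str = "jaccard",
) -> pd.DataFrame:
    """Percent similarity of DEG sets between consecutive stages of one genotype."""
    rows = []
    for s1, s2 in zip(stages, stages[1:]):
        row = {"from_stage": s1, "to_stage": s2}
        for d in DIRECTIONS:
            row[d] = percent_similarity(sets.get((s1, d), set()),
                                        sets.get((s2, d), set()), mode)
        row["combined"] = percent_similarity(_signed(sets, s1),
                                             _signed(sets, s2), mode)
        rows.append(row)
    return pd.DataFrame(rows)


def opposite_regulation(
    sets_a: StageSets,
    sets_b: StageSets,
    pairing: StagePairing,
) -> dict[tuple[str, str], dict[str, set]]:
    """Oppositely regulated features per stage pair.

    For pair (a, b): ``upA_downB`` holds features significant-up in A stage a
    and significant-down in B stage b; ``upB_downA`` mirrored.
    """
    out: dict[tuple[str, str], dict[str, set]] = {}
    for a, b in pairing.pairs:
        if a not in SEED_STAGES or b not in SEED_STAGES:
            raise ValueError(f"unknown stage in pairing: {(a, b)!r}")
        out[(a, b)] = {
            "upA_downB": sets_a.get((a, UP), set()) & sets_b.get((b, DOWN), set()),
            "upB_downA": sets_b.get((b, UP), set()) & sets_a.get((a, DOWN), set()),
        }
    return out
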