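"""Shared vocabulary for the staged seed-development design.

Samples follow the study layout: two genotypes, five seed developmental
stages (S1..S5, spanning 0-29 days after pollination) plus flag leaf as
the vegetative control tissue, with biological replicates.  Sample names
in expression matrices are ``<genotype>_<tissue>_<replicate>``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

SEED_STAGES: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
CONTROL_TISSUE: str = "Leaf"
TISSUES: tuple[str, ...] = SEED_STAGES + (CONTROL_TISSUE,)

HORMONE_PATHWAYS: tuple[str, ...] = (
    "auxin", "ABA", "GA", "CK", "BR", "ethylene", "JA", "SA",
)
HORMONE_CATEGORIES: tuple[str, ...] = (
    "biosynthesis", "signal transduction", "degradation", "response",
)

#: Paper-derived default k for hormone co-expression clustering, per pathway.
DEFAULT_HORMONE_K: dict[str, int] = {
    "auxin": 13, "ABA": 10, "GA": 10, "CK": 9,
    "BR": 10, "ethylene": 15, "JA": 8, "SA": 9,
}

QTL_TRAITS: tuple[str, ...] = (
    "grain length", "grain width", "grain length/width ratio", "grain weight",
)

UP = "up"
DOWN = "down"
DIRECTIONS: tuple[str, str] = (UP, DOWN)


class SampleInfo(NamedTuple):
    genotype: str
    tissue: str
    replicate: int


def parse_sample_name(name: str, tissues: Sequence[str] = TISSUES) -> SampleInfo:
    """Parse ``<genotype>_<tissue>_<replicate>`` into its components.

    The genotype token may itself contain underscores; the tissue and
    replicate are taken from the right.  Unknown tissues are rejected so
    that typos like ``S6`` surface immediately.
    """
    parts = name.split("_")
    if len(parts) < 3:
        raise ValueError(f"sample name {name!r} is not <genotype>_<tissue>_<rep>")
    rep_token, tissue = parts[-1], parts[-2]
    try:
        replicate = int(rep_token)
    except ValueError:
        raise ValueError(f"sample name {name!r}: replicate {rep_token!r} is not an integer") from None
    if tissue not in tissues:
        raise ValueError(f"sample name {name!r}: unknown stage/tissue {tissue!r}")
    genotype = "_".join(parts[:-2])
    if not genotype:
        raise ValueError(f"sample name {name!r}: empty genotype")
    return SampleInfo(genotype, tissue, replicate)


def sample_name(genotype: str, tissue: str, replicate: int) -> str:
    return f"{genotype}_{tissue}_{replicate}"
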