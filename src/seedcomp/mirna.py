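"""miRNA family grouping and miRNA-target anti-correlation module mining.

"Negative correlation in expression patterns" is operationalised as
opposed significant differential-expression calls: an all-stage module
pairs a miRNA up (down) in all five seed stages with a predicted target
down (up) in all five stages of the same genotype; an opposite-
regulation module pairs a miRNA up in one genotype's stage and down in
the other's same/comparable stage with a target regulated the other way
round in both.  Target predictions are an input table; pairs whose
target is absent from the gene DE table are skipped.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import pandas as pd

from .core import DOWN, SEED_STAGES, UP
from .stages import StagePairing

logger = logging.getLogger(__name__)

_MIRNA_RE = re.compile(
    r"^osa-miR(?P<family>\d+)(?P<variant>[a-z]*)"
    r"(?:[.-](?P<rest>.*))?$"
)


def parse_family(mirna_id: str) -> tuple[int, str]:
    """Family number and arm from an osa-miR identifier.

    "osa-miR396a-3p" -> (396, "3p"); "osa-miR1432" -> (1432, "unspecified").
    Malformed identifiers raise rather than defaulting to family 0.
    """
    m = _MIRNA_RE.match(mirna_id)
    if not m:
        raise ValueError(f"malformed miRNA identifier {mirna_id!r}")
    family = int(m.group("family"))
    rest = m.group("rest") or ""
    arm = "unspecified"
    for token in rest.split("."):
        for sub in token.split("-"):
            if sub in ("5p", "3p"):
                arm = sub
    return family, arm


def genotype_specific_families(
    expressed: Mapping[str, set[str]],
) -> dict[str, set[int]]:
    """Families whose expressed members all belong to a single genotype.

    ``expressed`` maps genotype -> set of miRNA IDs passing the TPM
    threshold there.  A family with expressed members in both genotypes
    is common; one with none is reported nowhere.
    """
    genotypes = list(expressed)
    family_presence: dict[int, set[str]] = {}
    for g in genotypes:
        for mid in expressed[g]:
            fam, _ = parse_family(mid)
            family_presence.setdefault(fam, set()).add(g)
    out: dict[str, set[int]] = {g: set() for g in genotypes}
    for fam, present in family_presence.items():
        if len(present) == 1:
            out[next(iter(present))].add(fam)
    return out


def all_stage_dems(
    det: pd.DataFrame, stages=SEED_STAGES
) -> dict[tuple[str, str], set[str]]:
    """miRNAs significant in the same direction in all five stages.

    Keys (genotype, 'up'|'down').  Identical to the common-to-all-stages
    rule for genes but computed at DEM thresholds upstream.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for genotype in det["genotype"].unique():
        sub = det[det["genotype"] == genotype]
        dirn = sub.pivot(index="feature_id", columns="stage", values="direction")
        stages_present = [s for s in stages if s in dirn.columns]
        complete = len(stages_present) == len(stages)
        for d in (UP, DOWN):
            if complete:
                hit = (dirn[stages_present] == d).all(axis=1)
                out[(genotype, d)] = set(dirn.index[hit])
            else:
                out[(genotype, d)] = set()
    return out


MODULE_COLUMNS = ["mirna_id", "gene_id", "genotype", "category"]


def _direction_pivot(det: pd.DataFrame, genotype: str) -> pd.DataFrame:
    sub = det[det["genotype"] == genotype]
    return sub.pivot(index="feature_id", columns="stage", values="direction")


def extract_modules(
    dems: Mapping[tuple[str, str], set[str]],
    targets: pd.DataFrame,
    gene_det: pd.DataFrame,
    stages=SEED_STAGES,
) -> pd.DataFrame:
    """All-stage anti-correlated miRNA-target modules per genotype.

    For each all-stage up miRNA, emit its predicted targets that are
    significant-down in all five stages of the same genotype (and the
    mirror).  Modules holding in both genotypes with the same miRNA
    direction are additionally flagged common-both-genotypes.
    """
    genotypes = sorted({g for g, _ in dems})
    gene_dirs = {g: _direction_pivot(gene_det, g) for g in genotypes}
    known_targets = set(gene_det["feature_id"])
    rows = []
    for genotype in genotypes:
        dirn = gene_dirs[genotype]
        complete = all(s in dirn.columns for s in stages)
        for mdir, tdir in ((UP, DOWN), (DOWN, UP)):
            for mirna in sorted(dems.get((genotype, mdir), ())):
                for gene in targets.loc[targets["mirna_id"] == mirna, "gene_id"]:
                    if gene not in known_targets:
                        logger.warning(
                            "target %s of %s absent from gene DE table; pair skipped",
                            gene, mirna)
                        continue
                    if complete and (dirn.loc[gene, list(stages)] == tdir).all():
                        rows.append({"mirna_id": mirna, "gene_id": gene,
                                     "genotype": genotype,
                                     "category": f"{mdir}-all-stages"})
    modules = pd.DataFrame(rows, columns=MODULE_COLUMNS)
    if not modules.empty and len(genotypes) > 1:
        key = modules["mirna_id"] + "\t" + modules["gene_id"] + "\t" + modules["category"]
        counts = key.value_counts()
        modules["common_both_genotypes"] = key.map(counts) == len(genotypes)
    else:
        modules["common_both_genotypes"] = False
    return modules


def opposite_modules(
    mirna_det_a: pd.DataFrame,
    mirna_det_b: pd.DataFrame,
    gene_det_a: pd.DataFrame,
    gene_det_b: pd.DataFrame,
    pairings: Mapping[str, StagePairing],
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """Opposite-regulation modules over same-stage and comparable-stage pairs.

    For pair (a, b) of genotype A and B stages: emit (miRNA, target) when
    the miRNA is up in B stage b and down in A stage a while the target is
    down in B stage b and up in A stage a -- and the genotype-mirrored
    variant.  ``pairings`` maps kind ("SS"/"CS") to a StagePairing.
    """
    ga = mirna_det_a["genotype"].iloc[0]
    gb = mirna_det_b["genotype"].iloc[0]
    mdir = {ga: _direction_pivot(mirna_det_a, ga),
            gb: _direction_pivot(mirna_det_b, gb)}
    gdir = {ga: _direction_pivot(gene_det_a, ga),
            gb: _direction_pivot(gene_det_b, gb)}
    known_targets = set(gene_det_a["feature_id"]) & set(gene_det_b["feature_id"])
    rows = []
    for kind, pairing in pairings.items():
        for a, b in pairing.pairs:
            for up_g, up_s, down_g, down_s in (
                (gb, b, ga, a),  # up in B, down in A
                (ga, a, gb, b),  # mirrored
            ):
                up_m = mdir[up_g]
                down_m = mdir[down_g]
                cand = [m for m in up_m.index
                        if up_s in up_m.columns and down_s in down_m.columns
                        and up_m.loc[m, up_s] == UP
                        and m in down_m.index
                        and down_m.loc[m, down_s] == DOWN]
                for mirna in cand:
                    for gene in targets.loc[targets["mirna_id"] == mirna,
                                            "gene_id"]:
                        if gene not in known_targets:
                            logger.warning(
                                "target %s of %s absent from gene DE tables; "
                                "pair skipped", gene, mirna)
                            continue
                        if (gdir[up_g].loc[gene, up_s] == DOWN
                                and gdir[down_g].loc[gene, down_s] == UP):
                            rows.append({
                                "mirna_id": mirna, "gene_id": gene,
                                "kind": kind,
                                "up_genotype": up_g, "up_stage": up_s,
                                "down_genotype": down_g, "down_stage": down_s,
                                "category": f"opposite-{kind}",
                            })
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "kind",
                                       "up_genotype", "up_stage",
                                       "down_genotype", "down_stage",
                                       "category"])


def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError("target table needs columns mirna_id, gene_id")
    return df
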