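"""Overlay of candidate gene lists onto grain-size QTL genomic intervals.

Coordinates are 1-based inclusive throughout (rice annotation
convention).  A gene hits a QTL when its full span lies inside the
interval on the same chromosome ("located within"); an any-overlap mode
is available.  BED export converts to 0-based half-open coordinates at
the boundary only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

QTL_COLUMNS = ["qtl_id", "chrom", "start", "end", "trait"]


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"qtl_id": str, "chrom": str})
    missing = [c for c in QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"QTL table missing columns: {missing}")
    if (df["start"] > df["end"]).any():
        raise ValueError("QTL table has start > end")
    return df


def genes_in_qtls(
    annotation: pd.DataFrame,
    qtls: pd.DataFrame,
    mode: str = "containment",
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene-QTL hits; a gene may hit multiple QTLs.

    mode "containment": gene start >= QTL start and gene end <= QTL end;
    mode "overlap": intervals intersect.  Genes without coordinates are
    skipped with a warning.  Returns columns gene_id, qtl_id, chrom.
    """
    if mode not in ("containment", "overlap"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    coords = annotation[["gene_id", "chrom", "start", "end"]].copy()
    if genes is not None:
        genes = set(genes)
        coords = coords[coords["gene_id"].isin(genes)]
    missing = coords["chrom"].isna() | coords["start"].isna() | coords["end"].isna()
    for gid in coords.loc[missing, "gene_id"]:
        logger.warning("gene %s has no coordinates; skipped in QTL overlay", gid)
    coords = coords[~missing]
    merged = coords.merge(qtls[QTL_COLUMNS], on="chrom", suffixes=("", "_qtl"))
    if mode == "containment":
        hit = (merged["start"] >= merged["start_qtl"]) & (
            merged["end"] <= merged["end_qtl"])
    else:
        hit = (merged["start"] <= merged["end_qtl"]) & (
            merged["end"] >= merged["start_qtl"])
    out = merged.loc[hit, ["gene_id", "qtl_id", "chrom"]]
    return out.sort_values(["gene_id", "qtl_id"]).reset_index(drop=True)


def aggregate_candidates(
    sources: Mapping[str, Iterable[str]],
    hits: pd.DataFrame,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-source summary of QTL-resident candidates and their union.

    ``sources`` maps an analysis tag (stage-specific, TF, hormone, ...) to
    its candidate gene list.  Returns (summary table, deduplicated union
    of hit genes across sources).
    """
    hit_genes = set(hits["gene_id"])
    rows = []
    union: set[str] = set()
    for tag, genes in sources.items():
        genes = set(genes)
        in_qtl = genes & hit_genes
        union |= in_qtl
        rows.append({"source": tag, "genes_tested": len(genes),
                     "genes_in_qtls": len(in_qtl)})
    summary = pd.DataFrame(rows, columns=["source", "genes_tested",
                                          "genes_in_qtls"])
    return summary, union


def hits_to_bed(hits: pd.DataFrame, annotation: pd.DataFrame,
                path: str | Path) -> None:
    """Write hit genes as BED (0-based half-open): start-1, end."""
    coords = annotation.set_index("gene_id")
    with open(path, "w") as fh:
        for _, row in hits.drop_duplicates("gene_id").iterrows():
            g = coords.loc[row["gene_id"]]
            fh.write(f"{g['chrom']}\t{int(g['start']) - 1}\t{int(g['end'])}"
                     f"\t{row['gene_id']}\n")
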