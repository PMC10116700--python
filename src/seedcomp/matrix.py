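"""Expression matrices, annotation tables and the basic abundance filters.

Matrices hold nonnegative normalized abundance (FPKM for genes, TPM for
miRNAs), features in rows and samples in columns.  "Expressed" is always
evaluated on the replicate mean per (genotype, tissue): a feature counts
as expressed when that mean reaches the threshold (inclusive) in at least
one tissue of interest.  Seed specificity additionally requires the flag
leaf mean to stay strictly below the threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CONTROL_TISSUE,
    HORMONE_CATEGORIES,
    HORMONE_PATHWAYS,
    SEED_STAGES,
    TISSUES,
    SampleInfo,
    parse_sample_name,
)

ANNOTATION_COLUMNS = [
    "gene_id", "tf_family", "hormone_pathway", "hormone_category",
    "chrom", "start", "end", "is_te",
]


@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix with its sample design."""

    values: pd.DataFrame
    unit: str  # "FPKM" or "TPM"
    design: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ValueError(f"unknown abundance unit {self.unit!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        infos = [parse_sample_name(str(c)) for c in self.values.columns]
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.values.columns[np.where(~np.isfinite(vals))[1][0]]
            raise ValueError(f"non-finite abundance in column {bad!r}")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at feature {idx[r]!r}, sample "
                f"{self.values.columns[c]!r}"
            )
        self.design = pd.DataFrame(infos, index=self.values.columns,
                                   columns=["genotype", "tissue", "replicate"])

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design["genotype"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def tissues(self) -> list[str]:
        present = set(self.design["tissue"])
        return [t for t in TISSUES if t in present]

    def samples_for(self, genotype: str, tissue: str) -> list[str]:
        d = self.design
        mask = (d["genotype"] == genotype) & (d["tissue"] == tissue)
        return list(d.index[mask])

    def replicate_values(self, genotype: str, tissue: str) -> np.ndarray:
        """Replicate abundance as an (n_replicates, n_features) array."""
        cols = self.samples_for(genotype, tissue)
        if not cols:
            raise KeyError(f"no samples for genotype {genotype!r}, tissue {tissue!r}")
        return self.values[cols].to_numpy(dtype=float).T

    def tissue_means(self, genotype: str) -> pd.DataFrame:
        """Replicate-mean abundance, features x tissues, for one genotype."""
        out = {}
        for t in self.tissues:
            cols = self.samples_for(genotype, t)
            if cols:
                out[t] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.unit)


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def filter_expressed(
    matrix: ExpressionMatrix,
    threshold: float,
    scope: Sequence[str] | None = None,
    genotype: str | None = None,
) -> set[str]:
    """Features whose mean abundance reaches ``threshold`` in >= 1 scope tissue.

    ``scope`` defaults to all tissues present; ``genotype=None`` pools over
    genotypes (expressed anywhere).  The comparison is inclusive (>=).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    scope = list(scope) if scope is not None else matrix.tissues
    if not scope:
        raise ValueError("empty tissue scope")
    genotypes = [genotype] if genotype is not None else matrix.genotypes
    expressed: set[str] = set()
    for g in genotypes:
        means = matrix.tissue_means(g)
        cols = [t for t in scope if t in means.columns]
        if not cols:
            raise ValueError(f"scope {scope!r} has no samples for genotype {g!r}")
        hit = (means[cols] >= threshold).any(axis=1)
        expressed.update(means.index[hit])
    return expressed


def seed_specific_features(
    matrix: ExpressionMatrix,
    genotype: str,
    seed_stages: Sequence[str] = SEED_STAGES,
    control_tissue: str = CONTROL_TISSUE,
    threshold: float = 1.0,
) -> set[str]:
    """Features expressed in >= 1 seed stage but strictly below threshold in leaf.

    Mirrors the seed-specific rule: mean >= threshold in any seed stage of
    the genotype AND mean < threshold (strict) in its control tissue.
    """
    if control_tissue in seed_stages:
        raise ValueError("control tissue must not be a seed stage")
    means = matrix.tissue_means(genotype)
    in_seed = (means[list(seed_stages)] >= threshold).any(axis=1)
    below_control = means[control_tissue] < threshold
    return set(means.index[in_seed & below_control])


def replicate_correlation(matrix: ExpressionMatrix, genotype: str) -> pd.DataFrame:
    """Pairwise Pearson r between replicates of each tissue of one genotype.

    Zero-variance replicates yield r = NaN (flagged, never silently 0).
    Returns a long table (tissue, sample_a, sample_b, r).
    """
    rows = []
    for tissue in matrix.tissues:
        cols = matrix.samples_for(genotype, tissue)
        if len(cols) < 2:
            raise ValueError(f"need >= 2 replicates for {genotype} {tissue}")
        data = matrix.values[cols].to_numpy(dtype=float)
        centered = data - data.mean(axis=0)
        sd = centered.std(axis=0)
        for i, j in itertools.combinations(range(len(cols)), 2):
            if sd[i] == 0 or sd[j] == 0:
                r = np.nan
            else:
                r = float(np.dot(centered[:, i], centered[:, j])
                          / (len(data) * sd[i] * sd[j]))
            rows.append((tissue, cols[i], cols[j], r))
    return pd.DataFrame(rows, columns=["tissue", "sample_a", "sample_b", "r"])


def read_annotation(path: str | Path, drop_te: bool = True) -> pd.DataFrame:
    """Load the gene annotation table; TE-flagged genes are dropped by default.

    Columns: gene_id, tf_family, hormone_pathway, hormone_category, chrom,
    start, end, is_te.  Missing optional fields are empty strings / NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str},
                     keep_default_na=True)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    return validate_annotation(df, drop_te=drop_te)


def validate_annotation(df: pd.DataFrame, drop_te: bool = True) -> pd.DataFrame:
    df = df.copy()
    df["is_te"] = df["is_te"].fillna(False).astype(bool)
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene IDs in annotation")
    hp = df["hormone_pathway"].dropna()
    bad = set(hp) - set(HORMONE_PATHWAYS) - {""}
    if bad:
        raise ValueError(f"unknown hormone pathway: {sorted(bad)}")
    hc = df["hormone_category"].dropna()
    bad = set(hc) - set(HORMONE_CATEGORIES) - {""}
    if bad:
        raise ValueError(f"unknown hormone category: {sorted(bad)}")
    has_coord = df["start"].notna() & df["end"].notna()
    if (df.loc[has_coord, "start"] > df.loc[has_coord, "end"]).any():
        raise ValueError("annotation has start > end")
    if drop_te:
        df = df[~df["is_te"]].reset_index(drop=True)
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
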