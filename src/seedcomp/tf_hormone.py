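"""TF-family stage counts and hormone-pathway co-expression divergence.

TF families are scored by how many member genes are significantly
upregulated with log2fc >= 2 in each seed stage of each genotype.
A family is significant when some stage reaches >= 5 upregulated members;
it is early/late preferential in a genotype when the smallest early
(S1-S2) count exceeds the largest late (S3-S5) count by >= 3 (or the
mirror), and genotype-stage preferential when exactly one genotype
carries such a label.  Hormone-pathway genes are clustered jointly
across genotypes by k-means on z-scored log2(FPKM+1) tissue profiles;
a gene is divergent when its two genotype profiles land in different
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import (
    CONTROL_TISSUE,
    DEFAULT_HORMONE_K,
    SEED_STAGES,
    TISSUES,
    UP,
)
from .matrix import ExpressionMatrix

EARLY_STAGES = ("S1", "S2")
LATE_STAGES = ("S3", "S4", "S5")


@dataclass
class FamilyCounts:
    """Per family x genotype x stage counts of upregulated member genes."""

    counts: pd.DataFrame  # index (family, genotype), columns stages
    members: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)

    def row(self, family: str, genotype: str) -> pd.Series:
        return self.counts.loc[(family, genotype)]


def family_stage_counts(
    det: pd.DataFrame,
    annotation: pd.DataFrame,
    fc_min: float = 2.0,
    stages=SEED_STAGES,
) -> FamilyCounts:
    """Count significant-up members with log2fc >= fc_min per family and stage.

    Genes without a TF-family annotation are ignored.
    """
    fam = annotation.loc[annotation["tf_family"].notna()
                         & (annotation["tf_family"] != ""),
                         ["gene_id", "tf_family"]]
    sub = det.merge(fam, left_on="feature_id", right_on="gene_id")
    hit = sub[sub["significant"] & (sub["direction"] == UP)
              & (sub["log2fc"] >= fc_min)]
    genotypes = list(det["genotype"].unique())
    families = list(fam["tf_family"].unique())
    idx = pd.MultiIndex.from_product([families, genotypes],
                                     names=["family", "genotype"])
    counts = pd.DataFrame(0, index=idx, columns=list(stages))
    members: dict[tuple[str, str, str], set[str]] = {}
    for (f, g, s), grp in hit.groupby(["tf_family", "genotype", "stage"]):
        genes = set(grp["feature_id"])
        counts.loc[(f, g), s] = len(genes)
        members[(f, g, s)] = genes
    return FamilyCounts(counts=counts, members=members)


def significant_families(
    fc: FamilyCounts, min_members: int = 5
) -> pd.DataFrame:
    """Families reaching >= min_members upregulated genes in some stage.

    Returns one row per family with per-genotype significance and the
    one-genotype-only flag (significant in exactly one genotype).
    """
    maxima = fc.counts.max(axis=1).unstack("genotype")
    sig = maxima >= min_members
    out = pd.DataFrame({
        f"significant_{g}": sig[g] for g in sig.columns
    })
    out["one_genotype_only"] = sig.sum(axis=1) == 1
    out.index.name = "family"
    return out.reset_index()


def classify_preferential(
    fc: FamilyCounts,
    margin: int = 3,
    early=EARLY_STAGES,
    late=LATE_STAGES,
) -> pd.DataFrame:
    """Early/late stage preference per family and genotype.

    Early-preferential: min(early counts) - max(late counts) >= margin;
    late mirrored.  A family is genotype-stage preferential when exactly
    one genotype has a non-"none" label.
    """
    rows = []
    for (family, genotype), counts in fc.counts.iterrows():
        e = counts[list(early)]
        l = counts[list(late)]
        if e.min() - l.max() >= margin:
            label = "early"
        elif l.min() - e.max() >= margin:
            label = "late"
        else:
            label = "none"
        rows.append({"family": family, "genotype": genotype, "label": label})
    labels = pd.DataFrame(rows)
    n_labeled = labels[labels["label"] != "none"].groupby("family").size()
    preferential = labels["family"].map(n_labeled).fillna(0).astype(int) == 1
    labels["genotype_stage_preferential"] = preferential
    return labels


def detect_opposite_pattern(fc: FamilyCounts) -> pd.DataFrame:
    """Families where a stage is the unique argmax in one genotype and the
    unique argmin in the other (ties disqualify)."""
    rows = []
    counts = fc.counts
    families = counts.index.get_level_values("family").unique()
    genotypes = counts.index.get_level_values("genotype").unique()
    for family in families:
        for g_max in genotypes:
            for g_min in genotypes:
                if g_max == g_min:
                    continue
                cmax = counts.loc[(family, g_max)]
                cmin = counts.loc[(family, g_min)]
                for s in counts.columns:
                    if ((cmax[s] > cmax.drop(s)).all()
                            and (cmin[s] < cmin.drop(s)).all()):
                        rows.append({"family": family, "stage": s,
                                     "max_genotype": g_max,
                                     "min_genotype": g_min})
    return pd.DataFrame(rows, columns=["family", "stage", "max_genotype",
                                       "min_genotype"])


def build_hormone_profiles(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    tissues=TISSUES,
) -> pd.DataFrame:
    """log2(FPKM+1) tissue profiles for hormone-annotated genes.

    One row per (gene, genotype); columns: pathway, category and the
    ordered tissue values.
    """
    horm = annotation.loc[annotation["hormone_pathway"].notna()
                          & (annotation["hormone_pathway"] != ""),
                          ["gene_id", "hormone_pathway", "hormone_category"]]
    horm = horm[horm["gene_id"].isin(matrix.feature_ids)]
    rows = []
    for genotype in matrix.genotypes:
        means = matrix.tissue_means(genotype)
        logm = np.log2(means[list(tissues)] + 1.0)
        for _, r in horm.iterrows():
            rows.append({"gene_id": r["gene_id"], "genotype": genotype,
                         "pathway": r["hormone_pathway"],
                         "category": r["hormone_category"],
                         **logm.loc[r["gene_id"]].to_dict()})
    return pd.DataFrame(rows)


def cluster_hormone_genes(
    profiles: pd.DataFrame,
    k_per_pathway: dict[str, int] | None = None,
    seed: int = 0,
    n_init: int = 100,
    tissues=TISSUES,
) -> pd.DataFrame:
    """Joint k-means over both genotypes' z-scored profiles, per pathway.

    Each gene contributes one point per genotype so that cross-genotype
    divergence ("same gene, different cluster") is defined in a shared
    cluster space.  Zero-variance profiles z-score to the zero vector.
    """
    if k_per_pathway is None:
        k_per_pathway = DEFAULT_HORMONE_K
    cols = list(tissues)
    out = []
    for pathway, grp in profiles.groupby("pathway", sort=True):
        k = k_per_pathway.get(pathway, 2)
        if k > len(grp):
            raise ValueError(
                f"k={k} exceeds the {len(grp)} profiles of pathway {pathway!r}")
        x = grp[cols].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    random_state=seed)
        labels = km.fit_predict(z)
        res = grp[["gene_id", "genotype", "pathway", "category"]].copy()
        res["cluster"] = labels
        out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["gene_id", "genotype", "pathway", "category", "cluster"])


def divergent_genes(assignments: pd.DataFrame) -> dict[str, set[str]]:
    """Genes whose two genotype profiles fall in different clusters."""
    out: dict[str, set[str]] = {}
    for pathway, grp in assignments.groupby("pathway"):
        piv = grp.pivot(index="gene_id", columns="genotype", values="cluster")
        complete = piv.dropna()
        diverged = complete[complete.nunique(axis=1) > 1]
        out[pathway] = set(diverged.index)
    return out


def higher_expression_counts(
    matrix: ExpressionMatrix,
    genes,
    annotation: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    delta: float = 0.5,
    stages=SEED_STAGES,
) -> pd.DataFrame:
    """Per-stage counts of genes with higher expression in one genotype.

    A gene counts toward a genotype in a stage when its log2(FPKM+1)
    exceeds the other genotype's by >= delta (inclusive); smaller
    differences count for neither.  Counts are grouped by hormone
    pathway and functional category.
    """
    genes = [g for g in genes if g in matrix.feature_ids]
    la = np.log2(matrix.tissue_means(genotype_a).loc[genes, list(stages)] + 1.0)
    lb = np.log2(matrix.tissue_means(genotype_b).loc[genes, list(stages)] + 1.0)
    diff = la - lb
    ann = annotation.set_index("gene_id")
    rows = []
    meta = pd.DataFrame({
        "pathway": ann.reindex(genes)["hormone_pathway"],
        "category": ann.reindex(genes)["hormone_category"],
    })
    for (pathway, category), grp in meta.groupby(["pathway", "category"],
                                                 dropna=False):
        d = diff.loc[grp.index]
        for s in stages:
            rows.append({
                "pathway": pathway, "category": category, "stage": s,
                f"higher_in_{genotype_a}": int((d[s] >= delta).sum()),
                f"higher_in_{genotype_b}": int((d[s] <= -delta).sum()),
            })
    return pd.DataFrame(rows)
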