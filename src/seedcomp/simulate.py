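"""Synthetic two-genotype staged expression datasets with known ground truth.

The generator emulates the study design: two genotypes x five seed
developmental stages plus flag leaf x replicates, FPKM for genes and TPM
for miRNAs, with multiplicative log-normal replicate noise (Gaussian on
the log2 scale).  Structure is planted so every downstream rule has a
known answer:

* a one-stage developmental lag of genotype B: lagged program genes show
  at stage s the genotype-A mean of stage s-1 (stage S1 falls back to the
  flag-leaf baseline), so cross-genotype DEG-set similarity peaks at the
  planted offset;
* stage-specific and common-to-all-stages DEGs, seed-specific genes,
  TF families with prescribed per-stage upregulated-member counts,
  hormone-pathway genes with a divergent fraction, anti-correlated
  miRNA-target modules (including opposite-regulation modules across
  same/comparable stages), genotype-specific miRNA families, and a gene
  subset placed fully inside emitted QTL intervals.

Housekeeping genes are flat across tissues so that similarity is driven
by the planted differential program.  Baselines are drawn so that means
straddle the expression thresholds (FPKM 1, TPM 50) and exercise
boundary behaviour.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CONTROL_TISSUE, DOWN, HORMONE_CATEGORIES, HORMONE_PATHWAYS, \
    QTL_TRAITS, SEED_STAGES, UP, sample_name
from .matrix import ANNOTATION_COLUMNS, ExpressionMatrix


def default_tf_family_spec(genotypes=("SN", "LGR")) -> dict:
    """Scaled-down per-family per-stage planted upregulated-member counts.

    Covers the qualitative patterns of interest: early-preferential in one
    genotype (MADS-like), late-preferential in the other (bZIP-like), an
    opposite min/max pattern (PHD-like), a one-genotype-only family
    (WRKY-like) and a family below the significance cut (ARF-like).
    """
    a, b = genotypes
    return {
        "MADS": {a: [7, 6, 1, 1, 1], b: [3, 4, 5, 4, 3]},
        "bZIP": {a: [2, 2, 2, 2, 2], b: [1, 2, 6, 7, 6]},
        "PHD": {a: [5, 4, 0, 4, 5], b: [2, 3, 8, 3, 2]},
        "WRKY": {a: [6, 5, 5, 4, 4], b: [2, 2, 2, 2, 2]},
        "ARF": {a: [2, 3, 4, 3, 2], b: [3, 4, 4, 4, 3]},
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 2000
    n_mirnas: int = 300
    n_replicates: int = 3
    stages: tuple = SEED_STAGES
    control_tissue: str = CONTROL_TISSUE
    genotypes: tuple = ("SN", "LGR")
    noise_sd: float = 0.25
    lag: int = 1
    frac_stage_specific: float = 0.15
    frac_common: float = 0.05
    frac_seed_specific: float = 0.05
    frac_module_pairs: float = 0.10  # of n_mirnas
    n_opposite_genes: int = 20
    n_opposite_modules: int = 4
    n_qtl: int = 10
    n_qtl_resident: int = 25
    n_te_genes: int = 20
    tf_family_spec: dict = field(default_factory=dict)
    hormone_spec: dict = field(
        default_factory=lambda: {"genes_per_pathway": 12,
                                 "divergent_fraction": 0.3})

    def __post_init__(self) -> None:
        if len(self.genotypes) != 2:
            raise ValueError("exactly two genotypes required")
        if not self.tf_family_spec:
            self.tf_family_spec = default_tf_family_spec(self.genotypes)
        for name in ("n_genes", "n_mirnas", "n_replicates", "n_qtl",
                     "n_qtl_resident", "n_te_genes", "n_opposite_genes",
                     "n_opposite_modules"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2 and self.n_genes > 0:
            raise ValueError("need >= 2 replicates")
        if self.lag not in (0, 1):
            raise ValueError("lag must be 0 or 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("frac_stage_specific", "frac_common",
                     "frac_seed_specific", "frac_module_pairs"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        unknown = [s for s in self.stages if s not in SEED_STAGES]
        if unknown or tuple(self.stages) != SEED_STAGES[:len(self.stages)]:
            raise ValueError(f"unknown stage labels: {list(self.stages)!r}")
        if self.control_tissue in self.stages:
            raise ValueError("control tissue must not be a seed stage")

    @property
    def n_stage_specific(self) -> int:
        return round(self.frac_stage_specific * self.n_genes)

    @property
    def n_common(self) -> int:
        return round(self.frac_common * self.n_genes)

    @property
    def n_seed_specific(self) -> int:
        return round(self.frac_seed_specific * self.n_genes)

    @property
    def n_modules(self) -> int:
        return round(self.frac_module_pairs * self.n_mirnas)


@dataclass
class GroundTruth:
    """Planted structure serialized alongside the dataset."""

    lag: int
    genotypes: list
    comparable_chain: list
    stage_specific: dict   # genotype -> stage -> direction -> [genes]
    common_all: dict       # direction -> [genes]
    seed_specific: dict    # genotype -> [genes]
    tf_counts: dict        # family -> genotype -> [counts per stage]
    hormone_divergent: dict  # pathway -> [genes]
    modules: list          # [{mirna, gene, genotypes, direction}]
    opposite_genes: list   # [{gene, kind, a_stage, b_stage}]
    opposite_modules: list  # [{mirna, gene, kind, a_stage, b_stage}]
    qtl_resident: list
    specific_mirna_families: dict  # genotype -> [family numbers]
    flat_genes: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class Dataset:
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    annotation: pd.DataFrame
    targets: pd.DataFrame
    qtls: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


# mean abundance archetypes (FPKM / TPM); chosen so fold changes clear the
# study thresholds with margin while baselines straddle the expressed cuts
_SS_LOW, _SS_HIGH = 2.0, 16.0
_COMMON_LOW, _COMMON_HIGH = 3.0, 24.0
_SEEDSPEC_LEAF, _SEEDSPEC_STAGE = 0.2, 5.0
_TF_LOW, _TF_HIGH = 4.0, 40.0
_OPP_LOW, _OPP_HIGH = 3.0, 30.0
_MIR_LOW, _MIR_HIGH = 20.0, 400.0
_MIR_DOWN_LOW = 15.0
_TARGET_LOW, _TARGET_HIGH = 2.0, 40.0


def _lagged(profile_a: np.ndarray, lag: int, n_stages: int) -> np.ndarray:
    """Genotype-B profile: stage s takes A's stage s-lag; S1 falls back to leaf."""
    if lag == 0:
        return profile_a.copy()
    out = profile_a.copy()
    leaf = profile_a[n_stages]
    out[1:n_stages] = profile_a[0:n_stages - 1]
    out[0] = leaf
    return out


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate the full synthetic dataset with its ground truth."""
    stages = list(config.stages)
    n_stages = len(stages)
    tissues = stages + [config.control_tissue]
    ga, gb = config.genotypes
    root = np.random.SeedSequence(config.seed)
    rng_struct, rng_gene, rng_mirna, rng_coord = (
        np.random.default_rng(s) for s in root.spawn(4))

    gene_ids: list[str] = []
    prof_a: list[np.ndarray] = []
    prof_b: list[np.ndarray] = []
    gene_class: list[str] = []

    def add_gene(profile_a, profile_b, cls) -> str:
        gid = f"LOC_Os{len(gene_ids) % 12 + 1:02d}g{10000 + 10 * len(gene_ids)}"
        gene_ids.append(gid)
        prof_a.append(np.asarray(profile_a, dtype=float))
        prof_b.append(np.asarray(profile_b, dtype=float))
        gene_class.append(cls)
        return gid

    def flat(level: float) -> np.ndarray:
        return np.full(n_stages + 1, level)

    def stage_profile(low: float, high: float, stage_idx: int,
                      direction: str) -> np.ndarray:
        """Leaf/other stages at one level, the focal stage at the other."""
        base, peak = (low, high) if direction == UP else (high, low)
        p = np.full(n_stages + 1, base)
        p[stage_idx] = peak
        return p

    # --- stage-specific DEGs (lagged program genes) -----------------------
    stage_specific: dict[str, dict[str, dict[str, list[str]]]] = {
        g: {s: {UP: [], DOWN: []} for s in stages} for g in (ga, gb)}
    n_slots = n_stages * 2
    per_slot = [config.n_stage_specific // n_slots] * n_slots
    for i in range(config.n_stage_specific % n_slots):
        per_slot[i] += 1
    slot = 0
    for si, s in enumerate(stages):
        for d in (UP, DOWN):
            for _ in range(per_slot[slot]):
                pa = stage_profile(_SS_LOW, _SS_HIGH, si, d)
                pb = _lagged(pa, config.lag, n_stages)
                gid = add_gene(pa, pb, "stage_specific")
                stage_specific[ga][s][d].append(gid)
                if si + config.lag < n_stages:
                    stage_specific[gb][stages[si + config.lag]][d].append(gid)
            slot += 1

    # --- common-to-all-stages DEGs (unlagged) -----------------------------
    common_all: dict[str, list[str]] = {UP: [], DOWN: []}
    for i in range(config.n_common):
        d = UP if i % 2 == 0 else DOWN
        low, high = (_COMMON_LOW, _COMMON_HIGH)
        p = np.full(n_stages + 1, high if d == UP else low)
        p[n_stages] = low if d == UP else high
        gid = add_gene(p, p, "common")
        common_all[d].append(gid)

    # --- seed-specific genes (lagged; expressed in seed, silent in leaf) --
    seed_specific_genes: list[str] = []
    for _ in range(config.n_seed_specific):
        pa = np.full(n_stages + 1, _SEEDSPEC_STAGE)
        pa[n_stages] = _SEEDSPEC_LEAF
        pb = _lagged(pa, config.lag, n_stages)
        seed_specific_genes.append(add_gene(pa, pb, "seed_specific"))

    # --- TF family members per planted count slot -------------------------
    tf_rows: list[tuple[str, str]] = []  # (gene_id, family)
    for family, per_geno in config.tf_family_spec.items():
        for genotype, counts in per_geno.items():
            if len(counts) != n_stages:
                raise ValueError(
                    f"tf_family_spec[{family!r}][{genotype!r}] needs "
                    f"{n_stages} stage counts")
            for si, count in enumerate(counts):
                for _ in range(count):
                    p_active = stage_profile(_TF_LOW, _TF_HIGH, si, UP)
                    p_flat = flat(_TF_LOW)
                    pa, pb = ((p_active, p_flat) if genotype == ga
                              else (p_flat, p_active))
                    gid = add_gene(pa, pb, "tf")
                    tf_rows.append((gid, family))

    # --- hormone-pathway genes -------------------------------------------
    hormone_rows: list[tuple[str, str, str]] = []
    hormone_divergent: dict[str, list[str]] = {p: [] for p in HORMONE_PATHWAYS}
    hs = config.hormone_spec
    per_pathway = int(hs.get("genes_per_pathway", 0))
    div_frac = float(hs.get("divergent_fraction", 0.0))
    ramp_up = np.linspace(0.6, 1.6, n_stages)
    # non-divergent archetypes kept well apart (in z-profile space) from the
    # divergent ramps so joint clustering separates shape, not noise
    shapes = [1.0 + 0.5 * np.sin(np.linspace(0, np.pi, n_stages)),
              1.3 - 0.5 * np.sin(np.linspace(0, np.pi, n_stages))]
    for pathway in HORMONE_PATHWAYS:
        n_div = round(div_frac * per_pathway)
        for i in range(per_pathway):
            base = rng_struct.uniform(12.0, 28.0)
            category = HORMONE_CATEGORIES[i % len(HORMONE_CATEGORIES)]
            if i < n_div:
                pa = np.append(base * ramp_up, base)
                pb = np.append(base * ramp_up[::-1], base)
            else:
                shape = shapes[i % len(shapes)]
                pa = np.append(base * shape, base)
                pb = pa.copy()
            gid = add_gene(pa, pb, "hormone")
            hormone_rows.append((gid, pathway, category))
            if i < n_div:
                hormone_divergent[pathway].append(gid)

    # --- oppositely regulated genes across SS / CS pairs ------------------
    opposite_genes: list[dict] = []
    for i in range(config.n_opposite_genes):
        if i % 2 == 0:  # same-stage pair
            si_a = si_b = 2 if n_stages > 2 else 0
            kind = "SS"
        else:           # comparable-stage pair (A stage s, B stage s+lag)
            si_a = 1 if n_stages > 2 else 0
            si_b = min(si_a + config.lag, n_stages - 1)
            kind = "CS"
        pa = stage_profile(_OPP_LOW, _OPP_HIGH, si_a, UP)
        pb = stage_profile(_OPP_LOW, _OPP_HIGH, si_b, DOWN)
        gid = add_gene(pa, pb, "opposite")
        opposite_genes.append({"gene": gid, "kind": kind,
                               "a_stage": stages[si_a],
                               "b_stage": stages[si_b]})

    # --- miRNA-target modules --------------------------------------------
    mirna_ids: list[str] = []
    mprof_a: list[np.ndarray] = []
    mprof_b: list[np.ndarray] = []

    def add_mirna(mid, pa, pb) -> str:
        mirna_ids.append(mid)
        mprof_a.append(np.asarray(pa, dtype=float))
        mprof_b.append(np.asarray(pb, dtype=float))
        return mid

    def mirna_all_stage(direction: str) -> np.ndarray:
        p = np.full(n_stages + 1,
                    _MIR_HIGH if direction == UP else _MIR_DOWN_LOW)
        p[n_stages] = _MIR_LOW if direction == UP else _MIR_HIGH
        return p

    modules: list[dict] = []
    target_pairs: list[tuple[str, str]] = []
    fam_serial = 4000
    for i in range(config.n_modules):
        mdir = UP if i % 2 == 0 else DOWN
        tdir = DOWN if mdir == UP else UP
        which = ("both", ga, gb)[i % 3]
        mid = f"osa-miR{fam_serial + i}"
        active = mirna_all_stage(mdir)
        inactive = flat(100.0)
        ma = active if which in ("both", ga) else inactive
        mb = active if which in ("both", gb) else inactive
        add_mirna(mid, ma, mb)
        t_active = np.full(n_stages + 1,
                           _TARGET_LOW if tdir == DOWN else _TARGET_HIGH)
        t_active[n_stages] = _TARGET_HIGH if tdir == DOWN else _TARGET_LOW
        t_flat = flat(_TARGET_HIGH if tdir == DOWN else _TARGET_LOW)
        ta = t_active if which in ("both", ga) else t_flat
        tb = t_active if which in ("both", gb) else t_flat
        gid = add_gene(ta, tb, "module_target")
        target_pairs.append((mid, gid))
        modules.append({
            "mirna": mid, "gene": gid, "direction": mdir,
            "genotypes": [ga, gb] if which == "both" else [which]})

    # --- opposite-regulation miRNA-target modules -------------------------
    opposite_modules: list[dict] = []
    for i in range(config.n_opposite_modules):
        if i % 2 == 0:
            si_a = si_b = 2 if n_stages > 2 else 0
            kind = "SS"
        else:
            si_a = 1 if n_stages > 2 else 0
            si_b = min(si_a + config.lag, n_stages - 1)
            kind = "CS"
        mid = f"osa-miR{5000 + i}"
        # miRNA: down in A stage a, up in B stage b
        ma = np.full(n_stages + 1, _MIR_HIGH)
        ma[si_a] = _MIR_DOWN_LOW
        mb = np.full(n_stages + 1, _MIR_LOW)
        mb[si_b] = _MIR_HIGH
        add_mirna(mid, ma, mb)
        # target: up in A stage a, down in B stage b
        ta = stage_profile(_OPP_LOW, _OPP_HIGH, si_a, UP)
        tb = stage_profile(_OPP_LOW, _OPP_HIGH, si_b, DOWN)
        gid = add_gene(ta, tb, "opposite_module_target")
        target_pairs.append((mid, gid))
        opposite_modules.append({"mirna": mid, "gene": gid, "kind": kind,
                                 "a_stage": stages[si_a],
                                 "b_stage": stages[si_b]})

    # --- genotype-specific miRNA families (skipped if budget is tight) ----
    specific_families = {ga: [1848, 1874], gb: [2118, 5504, 1432]}
    n_specific_members = 2 * sum(len(v) for v in specific_families.values())
    if config.n_mirnas - len(mirna_ids) < n_specific_members:
        specific_families = {ga: [], gb: []}
    for genotype, fams in specific_families.items():
        for fam in fams:
            for letter in ("a", "b"):
                mid = f"osa-miR{fam}{letter}"
                present, absent = flat(120.0), flat(5.0)
                pa, pb = ((present, absent) if genotype == ga
                          else (absent, present))
                add_mirna(mid, pa, pb)

    # --- near-miss DEM decoys (up in all but the last stage) --------------
    decoy_ids = []
    for i in range(min(10, max(config.n_mirnas - len(mirna_ids), 0))):
        mid = f"osa-miR{6000 + i}"
        p = np.full(n_stages + 1, _MIR_HIGH)
        p[n_stages - 1] = _MIR_LOW
        p[n_stages] = _MIR_LOW
        add_mirna(mid, p, p)
        decoy_ids.append(mid)

    # --- remaining miRNAs: flat, straddling the TPM threshold -------------
    serial = 0
    while len(mirna_ids) < config.n_mirnas:
        fam = 300 + serial // 3
        letter = "abc"[serial % 3]
        arm = ("", "-5p", "-3p")[serial % 3]
        level = float(np.exp(rng_struct.normal(np.log(90.0), 0.9)))
        add_mirna(f"osa-miR{fam}{letter}{arm}", flat(level), flat(level))
        serial += 1
    if len(mirna_ids) > config.n_mirnas:
        raise ValueError(
            f"planted miRNA structure needs {len(mirna_ids)} miRNAs; "
            f"n_mirnas={config.n_mirnas} is too small")

    # --- decoy target pairs ----------------------------------------------
    flat_gene_ids: list[str] = []
    n_flat = config.n_genes - len(gene_ids) - config.n_te_genes
    if n_flat < 0:
        raise ValueError(
            f"planted gene structure needs {len(gene_ids) + config.n_te_genes}"
            f" genes; n_genes={config.n_genes} is too small")
    for _ in range(n_flat):
        level = float(np.exp(rng_struct.normal(np.log(3.0), 1.5)))
        flat_gene_ids.append(add_gene(flat(level), flat(level), "flat"))
    te_ids = [add_gene(flat(2.0), flat(2.0), "te")
              for _ in range(config.n_te_genes)]

    for i, mid in enumerate(decoy_ids):
        if modules:
            target_pairs.append((mid, modules[i % len(modules)]["gene"]))
    for i in range(min(10, len(flat_gene_ids))):
        if modules:
            target_pairs.append((modules[i % len(modules)]["mirna"],
                                 flat_gene_ids[i]))
    generic = [m for m in mirna_ids if m.startswith("osa-miR3")]
    for i in range(min(20, len(generic), len(flat_gene_ids))):
        target_pairs.append((generic[i], flat_gene_ids[-(i + 1)]))

    # --- QTL intervals and coordinates ------------------------------------
    qtl_rows = []
    for i in range(config.n_qtl):
        chrom = f"chr{i % 12 + 1}"
        start = 500_000 + 10_000 * i
        end = start + 1_500_000
        qtl_rows.append({
            "qtl_id": f"qGS{i + 1}", "chrom": chrom, "start": start,
            "end": end, "trait": QTL_TRAITS[i % len(QTL_TRAITS)],
            "lod": round(float(rng_coord.uniform(2.5, 13.0)), 2),
            "pve": round(float(rng_coord.uniform(1.5, 30.0)), 2),
        })
    qtls = pd.DataFrame(qtl_rows,
                        columns=["qtl_id", "chrom", "start", "end", "trait",
                                 "lod", "pve"])

    candidate_pool = (
        [g for s in stages for d in (UP, DOWN)
         for g in stage_specific[ga][s][d]]
        + [g for g, _ in tf_rows]
        + [g for p in HORMONE_PATHWAYS for g in hormone_divergent[p]]
        + [m["gene"] for m in modules]
        + [o["gene"] for o in opposite_genes]
    )
    n_resident = min(config.n_qtl_resident, len(candidate_pool))
    if config.n_qtl == 0:
        n_resident = 0
    resident = list(rng_coord.choice(candidate_pool, size=n_resident,
                                     replace=False)) if n_resident else []

    coords: dict[str, tuple[str, int, int]] = {}
    for gid in resident:
        q = qtl_rows[int(rng_coord.integers(len(qtl_rows)))]
        start = int(rng_coord.integers(q["start"], q["end"] - 2000))
        coords[gid] = (q["chrom"], start, start + 1999)
    no_coord = set(gene_ids[-3:]) - set(resident) if len(gene_ids) >= 3 else set()
    for gid in gene_ids:
        if gid in coords or gid in no_coord:
            continue
        chrom = f"chr{int(rng_coord.integers(1, 13))}"
        start = int(rng_coord.integers(5_000_000, 30_000_000))
        coords[gid] = (chrom, start, start + 1999)

    tf_map = dict(tf_rows)
    horm_map = {g: (p, c) for g, p, c in hormone_rows}
    te_set = set(te_ids)
    ann_rows = []
    for gid in gene_ids:
        chrom, start, end = coords.get(gid, ("", np.nan, np.nan))
        pathway, category = horm_map.get(gid, ("", ""))
        ann_rows.append({
            "gene_id": gid, "tf_family": tf_map.get(gid, ""),
            "hormone_pathway": pathway, "hormone_category": category,
            "chrom": chrom, "start": start, "end": end,
            "is_te": gid in te_set,
        })
    annotation = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)

    # --- assemble matrices with replicate noise ---------------------------
    def build_matrix(ids, profiles_a, profiles_b, rng, unit) -> ExpressionMatrix:
        cols, data = [], []
        for genotype, profiles in ((ga, profiles_a), (gb, profiles_b)):
            means = (np.vstack(profiles) if profiles
                     else np.empty((0, n_stages + 1)))
            for ti, tissue in enumerate(tissues):
                noise = rng.normal(0.0, config.noise_sd,
                                   size=(len(ids), config.n_replicates))
                vals = means[:, ti:ti + 1] * np.exp2(noise)
                for r in range(config.n_replicates):
                    cols.append(sample_name(genotype, tissue, r + 1))
                    data.append(vals[:, r])
        frame = pd.DataFrame(
            np.column_stack(data) if data else
            np.empty((len(ids), 0)),
            index=pd.Index(ids, name="feature_id"), columns=cols)
        return ExpressionMatrix(frame, unit)

    genes = build_matrix(gene_ids, prof_a, prof_b, rng_gene, "FPKM")
    mirnas = build_matrix(mirna_ids, mprof_a, mprof_b, rng_mirna, "TPM")

    chain = [[stages[i], stages[i + config.lag]]
             for i in range(n_stages - config.lag)]
    truth = GroundTruth(
        lag=config.lag,
        genotypes=[ga, gb],
        comparable_chain=chain,
        stage_specific={g: {s: {d: sorted(v) for d, v in dd.items()}
                            for s, dd in ss.items()}
                        for g, ss in stage_specific.items()},
        common_all={d: sorted(v) for d, v in common_all.items()},
        seed_specific={g: sorted(seed_specific_genes) for g in (ga, gb)},
        tf_counts={f: {g: list(c) for g, c in per.items()}
                   for f, per in config.tf_family_spec.items()},
        hormone_divergent={p: sorted(v) for p, v in hormone_divergent.items()},
        modules=modules,
        opposite_genes=opposite_genes,
        opposite_modules=opposite_modules,
        qtl_resident=sorted(resident),
        specific_mirna_families=specific_families,
        flat_genes=sorted(flat_gene_ids),
    )
    targets = pd.DataFrame(target_pairs, columns=["mirna_id", "gene_id"])
    return Dataset(genes=genes, mirnas=mirnas, annotation=annotation,
                   targets=targets, qtls=qtls, truth=truth, config=config)


FILE_NAMES = {
    "genes": "genes_fpkm.tsv",
    "mirnas": "mirnas_tpm.tsv",
    "annotation": "annotation.tsv",
    "targets": "targets.tsv",
    "qtls": "qtls.tsv",
    "truth": "ground_truth.json",
}


def write_dataset(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write all tables as TSV plus the ground-truth JSON; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FILE_NAMES.items()}
    dataset.genes.values.to_csv(paths["genes"], sep="\t",
                                index_label="feature_id", float_format="%.6g")
    dataset.mirnas.values.to_csv(paths["mirnas"], sep="\t",
                                 index_label="feature_id", float_format="%.6g")
    dataset.annotation.to_csv(paths["annotation"], sep="\t", index=False,
                              float_format="%.0f")
    dataset.targets.to_csv(paths["targets"], sep="\t", index=False)
    dataset.qtls.to_csv(paths["qtls"], sep="\t", index=False)
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
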