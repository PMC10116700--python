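"""Config-driven orchestration of the full comparative pipeline.

A run consumes either a simulate block (synthetic data with ground
truth) or paths to on-disk input tables, applies the expression filters,
differential expression at the study thresholds, stage alignment,
TF-family and hormone analyses, miRNA-target module mining and the QTL
overlay, and writes every result table plus one machine-readable
``summary.json``.  Reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import de, matrix, mirna, qtl, simulate, stages, tf_hormone
from .core import CONTROL_TISSUE, DIRECTIONS, DOWN, SEED_STAGES, UP

logger = logging.getLogger(__name__)

_THRESHOLD_DEFAULTS: dict[str, float] = {
    "gene_fc_min": 1.0,
    "mirna_fc_min": 2.0,
    "q_max": 0.05,
    "gene_expr_min": 1.0,
    "mirna_expr_min": 50.0,
    "tf_fc_min": 2.0,
    "delta": 0.5,
    "preferential_margin": 3.0,
    "min_members": 5.0,
}


@dataclass
class PipelineConfig:
    """Validated run configuration; exactly one of inputs or simulate."""

    seed: int = 0
    simulate: simulate.SimConfig | None = None
    inputs: dict[str, str] | None = None
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_THRESHOLD_DEFAULTS))
    similarity_mode: str = "jaccard"
    overlay_mode: str = "containment"
    hormone_k: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' required")
        for key, value in self.thresholds.items():
            if key not in _THRESHOLD_DEFAULTS:
                raise ValueError(f"unknown threshold {key!r}")
            if value <= 0:
                raise ValueError(f"threshold {key!r} must be positive")
        for key, default in _THRESHOLD_DEFAULTS.items():
            self.thresholds.setdefault(key, default)
        if self.similarity_mode not in ("jaccard", "of_b"):
            raise ValueError(f"unknown similarity_mode {self.similarity_mode!r}")
        if self.overlay_mode not in ("containment", "overlap"):
            raise ValueError(f"unknown overlay_mode {self.overlay_mode!r}")


_KNOWN_KEYS = {"seed", "simulate", "inputs", "thresholds", "similarity_mode",
               "overlay_mode", "hormone_k"}
_INPUT_KEYS = {"genes", "mirnas", "annotation", "targets", "qtls"}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Normalize a YAML file (or pre-parsed dict) into a PipelineConfig."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ValueError("config key 'seed': expected an integer")
        kwargs["seed"] = raw["seed"]
    if raw.get("simulate") is not None:
        sim = raw["simulate"]
        if not isinstance(sim, dict):
            raise ValueError("config key 'simulate': expected a mapping")
        sim = dict(sim)
        sim.setdefault("seed", kwargs.get("seed", 0))
        valid = {f.name for f in dataclasses.fields(simulate.SimConfig)}
        bad = set(sim) - valid
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        kwargs["simulate"] = simulate.SimConfig(**sim)
    if raw.get("inputs") is not None:
        inputs = raw["inputs"]
        if not isinstance(inputs, dict) or set(inputs) != _INPUT_KEYS:
            raise ValueError(f"config key 'inputs' needs exactly {sorted(_INPUT_KEYS)}")
        kwargs["inputs"] = {k: str(v) for k, v in inputs.items()}
    if "thresholds" in raw:
        th = raw["thresholds"]
        if not isinstance(th, dict):
            raise ValueError("config key 'thresholds': expected a mapping")
        kwargs["thresholds"] = {k: float(v) for k, v in th.items()}
    for key in ("similarity_mode", "overlay_mode"):
        if key in raw:
            kwargs[key] = str(raw[key])
    if "hormone_k" in raw and raw["hormone_k"] is not None:
        kwargs["hormone_k"] = {str(k): int(v)
                               for k, v in raw["hormone_k"].items()}
    return PipelineConfig(**kwargs)


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    genes = matrix.read_expression_matrix(paths["genes"], "FPKM")
    mirnas = matrix.read_expression_matrix(paths["mirnas"], "TPM")
    annotation = matrix.read_annotation(paths["annotation"])
    targets = mirna.read_target_table(paths["targets"])
    qtls = qtl.read_qtl_table(paths["qtls"])
    return genes, mirnas, annotation, targets, qtls, None


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; write result tables and summary.json under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    summary: dict[str, Any] = {"seed": cfg.seed}

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name)

    try:
        with stage("load"):
            if cfg.simulate is not None:
                dataset = simulate.generate_dataset(cfg.simulate)
                simulate.write_dataset(dataset, out / "dataset")
                genes, mirnas_mat = dataset.genes, dataset.mirnas
                annotation = matrix.validate_annotation(dataset.annotation)
                targets, qtls = dataset.targets, dataset.qtls
            else:
                genes, mirnas_mat, annotation, targets, qtls, dataset = \
                    _load_inputs(cfg)
        ga, gb = genes.genotypes[:2]
        summary["genotypes"] = [ga, gb]

        with stage("filters"):
            expressed = {g: sorted(matrix.filter_expressed(
                genes, th["gene_expr_min"], genotype=g)) for g in (ga, gb)}
            seed_spec = {g: sorted(matrix.seed_specific_features(
                genes, g, threshold=th["gene_expr_min"])) for g in (ga, gb)}
            qc = pd.concat([matrix.replicate_correlation(genes, g)
                            .assign(genotype=g) for g in (ga, gb)])
            qc.to_csv(out / "replicate_correlation.tsv", sep="\t", index=False)
            summary["expressed_genes"] = {g: len(v) for g, v in expressed.items()}
            summary["seed_specific_genes"] = {g: len(v)
                                              for g, v in seed_spec.items()}

        with stage("differential_expression"):
            gene_th = de.Thresholds(th["gene_fc_min"], th["q_max"],
                                    th["gene_expr_min"])
            mirna_th = de.Thresholds(th["mirna_fc_min"], th["q_max"],
                                     th["mirna_expr_min"])
            gene_det = de.call_degs(genes, thresholds=gene_th)
            mirna_det = de.call_degs(mirnas_mat, thresholds=mirna_th)
            de.write_de_table(gene_det, out / "de_genes.tsv")
            de.write_de_table(mirna_det, out / "de_mirnas.tsv")
            sig = de.significant_sets(gene_det)
            summary["deg_counts"] = {
                g: {s: {d: len(sig.get((g, s, d), ())) for d in DIRECTIONS}
                    for s in SEED_STAGES} for g in (ga, gb)}
            specific = de.stage_specific_sets(gene_det, fc_min=th["gene_fc_min"])
            common = de.common_all_stage_sets(gene_det)
            summary["stage_specific_counts"] = {
                g: {s: {d: len(specific[(g, s, d)]) for d in DIRECTIONS}
                    for s in SEED_STAGES} for g in (ga, gb)}
            summary["common_all_counts"] = {
                g: {d: len(common[(g, d)]) for d in DIRECTIONS}
                for g in (ga, gb)}

        with stage("stage_comparison"):
            sets_a = {(s, d): sig.get((ga, s, d), set())
                      for s in SEED_STAGES for d in DIRECTIONS}
            sets_b = {(s, d): sig.get((gb, s, d), set())
                      for s in SEED_STAGES for d in DIRECTIONS}
            sims = stages.similarity_matrix(sets_a, sets_b,
                                            mode=cfg.similarity_mode)
            for key, df in sims.items():
                df.to_csv(out / f"similarity_{key}.tsv", sep="\t",
                          index_label="stage")
            cs = stages.assign_comparable_stages(sims["combined"])
            ss = stages.same_stage_pairing()
            summary["comparable_stages"] = {
                "offset": cs.offset, "consistent": cs.consistent,
                "pairs": [list(p) for p in cs.pairs]}
            cons = {g: stages.consecutive_similarity(
                {(s, d): sig.get((g, s, d), set())
                 for s in SEED_STAGES for d in DIRECTIONS},
                mode=cfg.similarity_mode) for g in (ga, gb)}
            pd.concat([cons[g].assign(genotype=g) for g in (ga, gb)]).to_csv(
                out / "consecutive_similarity.tsv", sep="\t", index=False)
            opposite = {}
            for pairing in (ss, cs):
                opposite[pairing.kind] = stages.opposite_regulation(
                    sets_a, sets_b, pairing)
            opp_rows = []
            for kind, by_pair in opposite.items():
                for (a, b), d in by_pair.items():
                    for direction, genes_set in d.items():
                        for gid in sorted(genes_set):
                            opp_rows.append({"kind": kind, "stage_a": a,
                                             "stage_b": b,
                                             "pattern": direction,
                                             "gene_id": gid})
            pd.DataFrame(opp_rows, columns=["kind", "stage_a", "stage_b",
                                            "pattern", "gene_id"]).to_csv(
                out / "opposite_regulation.tsv", sep="\t", index=False)
            summary["opposite_regulation_counts"] = {
                kind: sum(len(d["upA_downB"]) + len(d["upB_downA"])
                          for d in by_pair.values())
                for kind, by_pair in opposite.items()}

        with stage("tf_families"):
            fc = tf_hormone.family_stage_counts(gene_det, annotation,
                                                fc_min=th["tf_fc_min"])
            fc.counts.to_csv(out / "tf_family_counts.tsv", sep="\t")
            sig_fam = tf_hormone.significant_families(
                fc, min_members=int(th["min_members"]))
            pref = tf_hormone.classify_preferential(
                fc, margin=int(th["preferential_margin"]))
            opp_fam = tf_hormone.detect_opposite_pattern(fc)
            sig_fam.to_csv(out / "tf_significant.tsv", sep="\t", index=False)
            pref.to_csv(out / "tf_preferential.tsv", sep="\t", index=False)
            opp_fam.to_csv(out / "tf_opposite_pattern.tsv", sep="\t",
                           index=False)
            pref_fams = sorted(set(
                pref.loc[pref["genotype_stage_preferential"], "family"]))
            summary["tf"] = {
                "significant_families": sorted(set(
                    sig_fam.loc[sig_fam[[c for c in sig_fam.columns
                                         if c.startswith("significant_")]]
                                .any(axis=1), "family"])),
                "preferential_families": pref_fams,
                "opposite_pattern_families": sorted(set(opp_fam["family"])),
            }
            tf_candidates = sorted({g for (fam, _, _), members in
                                    fc.members.items()
                                    if fam in pref_fams for g in members})

        with stage("hormones"):
            profiles = tf_hormone.build_hormone_profiles(genes, annotation)
            if profiles.empty:
                divergent, horm_counts = {}, pd.DataFrame()
            else:
                n_per = profiles.groupby("pathway").size()
                # the catalog k values assume hundreds of profiles; cap k so
                # small catalogs keep several profiles per cluster
                k_map = dict(cfg.hormone_k) if cfg.hormone_k else {
                    p: min(tf_hormone.DEFAULT_HORMONE_K.get(p, 2),
                           max(2, int(n) // 6))
                    for p, n in n_per.items()}
                assignments = tf_hormone.cluster_hormone_genes(
                    profiles, k_map, seed=cfg.seed)
                assignments.to_csv(out / "hormone_clusters.tsv", sep="\t",
                                   index=False)
                divergent = tf_hormone.divergent_genes(assignments)
                div_union = sorted(set().union(*divergent.values())
                                   if divergent else set())
                horm_counts = tf_hormone.higher_expression_counts(
                    genes, div_union, annotation, ga, gb, delta=th["delta"])
                horm_counts.to_csv(out / "hormone_higher_expression.tsv",
                                   sep="\t", index=False)
            summary["hormone_divergent_counts"] = {
                p: len(v) for p, v in sorted(divergent.items())}

        with stage("mirna_modules"):
            expressed_mirnas = {g: matrix.filter_expressed(
                mirnas_mat, th["mirna_expr_min"], genotype=g)
                for g in (ga, gb)}
            spec_fams = mirna.genotype_specific_families(expressed_mirnas)
            summary["mirna"] = {
                "expressed": {g: len(v) for g, v in expressed_mirnas.items()},
                "specific_families": {g: sorted(v)
                                      for g, v in spec_fams.items()},
            }
            dems = mirna.all_stage_dems(mirna_det)
            modules = mirna.extract_modules(dems, targets, gene_det)
            modules.to_csv(out / "modules.tsv", sep="\t", index=False)
            opp_mods = mirna.opposite_modules(
                mirna_det[mirna_det["genotype"] == ga],
                mirna_det[mirna_det["genotype"] == gb],
                gene_det[gene_det["genotype"] == ga],
                gene_det[gene_det["genotype"] == gb],
                {"SS": ss, "CS": cs}, targets)
            opp_mods.to_csv(out / "opposite_modules.tsv", sep="\t",
                            index=False)
            summary["mirna"]["all_stage_dems"] = {
                f"{g}_{d}": len(dems.get((g, d), ()))
                for g in (ga, gb) for d in DIRECTIONS}
            summary["mirna"]["module_count"] = int(len(modules))
            summary["mirna"]["opposite_module_count"] = int(len(opp_mods))

        with stage("qtl_overlay"):
            sources = {
                "stage_specific": sorted(set().union(
                    *[specific[(g, s, d)] for g in (ga, gb)
                      for s in SEED_STAGES for d in DIRECTIONS])),
                "tf": tf_candidates,
                "hormone": sorted(set().union(*divergent.values())
                                  if divergent else set()),
                "mirna_target": sorted(set(modules["gene_id"])
                                       | set(opp_mods["gene_id"])),
                "opposite": sorted({r["gene_id"] for r in opp_rows}),
            }
            all_candidates = sorted(set().union(*map(set, sources.values())))
            hits = qtl.genes_in_qtls(annotation, qtls, mode=cfg.overlay_mode,
                                     genes=all_candidates)
            hits.to_csv(out / "qtl_hits.tsv", sep="\t", index=False)
            qtl_summary, union = qtl.aggregate_candidates(sources, hits)
            qtl_summary.to_csv(out / "qtl_candidate_summary.tsv", sep="\t",
                               index=False)
            summary["qtl"] = {
                "n_qtls": int(len(qtls)),
                "per_source": {r["source"]: int(r["genes_in_qtls"])
                               for _, r in qtl_summary.iterrows()},
                "candidate_union": len(union),
            }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {_StageTimer.current!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


class _StageTimer:
    """Context manager logging stage wall time; tracks the active stage name."""

    current: str | None = None

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> "_StageTimer":
        _StageTimer.current = self.name
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc) -> None:
        logger.info("stage %s finished in %.2fs", self.name,
                    time.perf_counter() - self.t0)
        if exc[0] is None:
            _StageTimer.current = None
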