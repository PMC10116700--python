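"""Thresholded differential expression of seed stages against flag leaf.

Each genotype's five seed stages are contrasted against its own flag
leaf.  Effect size is the log2 fold change of replicate-mean abundance
with a pseudocount; evidence is a Welch two-sample t-test on
log2(abundance + 1) replicate values, Benjamini-Hochberg adjusted across
features within each (genotype, stage) contrast.  A feature is a
DEG/DEM when q <= q_max, |log2fc| >= fc_min and it is expressed
(mean >= expr_min) in the stage or the control; all comparisons are
inclusive.  Defaults follow the study: genes fc_min=1, expr_min=1 FPKM;
miRNAs fc_min=2, expr_min=50 TPM; q_max=0.05 for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CONTROL_TISSUE, DOWN, SEED_STAGES, UP
from .matrix import ExpressionMatrix

DE_COLUMNS = ["feature_id", "genotype", "stage", "log2fc", "p", "q",
              "significant", "direction"]


@dataclass(frozen=True)
class Thresholds:
    fc_min: float = 1.0
    q_max: float = 0.05
    expr_min: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.q_max <= 0 or self.expr_min <= 0:
            raise ValueError("all thresholds must be positive")


GENE_THRESHOLDS = Thresholds(fc_min=1.0, q_max=0.05, expr_min=1.0)
MIRNA_THRESHOLDS = Thresholds(fc_min=2.0, q_max=0.05, expr_min=50.0)


def log2_fold_change(mean_stage, mean_control, pseudocount: float = 1.0):
    """log2((mean_stage + c) / (mean_control + c)); finite for all inputs >= 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(mean_stage, dtype=float)
    b = np.asarray(mean_control, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("means must be nonnegative")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return out if out.ndim else float(out)


def de_test(stage_replicates, control_replicates) -> float | np.ndarray:
    """Two-sided Welch t-test p-value between two replicate groups.

    Accepts 1-D vectors or (n_replicates, n_features) arrays; values are
    tested as given (callers pass log2-transformed abundance).  When both
    groups have zero variance the test statistic is undefined; we return
    p = 1 for identical means and p = 0 otherwise.
    """
    a = np.asarray(stage_replicates, dtype=float)
    b = np.asarray(control_replicates, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] < 2:
        raise ValueError("stage group needs >= 2 replicates")
    if b.shape[0] < 2:
        raise ValueError("control group needs >= 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # near-identical replicate groups trigger a scipy precision warning;
        # the degenerate cases are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p if p.size > 1 else float(p.ravel()[0])


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q in [p, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    control_tissue: str = CONTROL_TISSUE,
    thresholds: Thresholds = GENE_THRESHOLDS,
    pseudocount: float = 1.0,
    stages=SEED_STAGES,
) -> pd.DataFrame:
    """Differential-expression table: one row per feature x genotype x stage.

    BH adjustment is applied across features within each (genotype, stage)
    contrast.  ``significant`` requires q <= q_max, |log2fc| >= fc_min and
    mean >= expr_min in the stage or in the control.
    """
    if control_tissue not in matrix.tissues:
        raise ValueError(f"control tissue {control_tissue!r} absent from matrix")
    frames = []
    for genotype in matrix.genotypes:
        ctrl = matrix.replicate_values(genotype, control_tissue)
        ctrl_log = np.log2(ctrl + 1.0)
        ctrl_mean = ctrl.mean(axis=0)
        for stage in stages:
            reps = matrix.replicate_values(genotype, stage)
            stage_mean = reps.mean(axis=0)
            lfc = log2_fold_change(stage_mean, ctrl_mean, pseudocount)
            p = np.atleast_1d(de_test(np.log2(reps + 1.0), ctrl_log))
            q = adjust_bh(p)
            expressed = (stage_mean >= thresholds.expr_min) | (
                ctrl_mean >= thresholds.expr_min)
            sig = (q <= thresholds.q_max) & (np.abs(lfc) >= thresholds.fc_min) & expressed
            direction = np.where(~sig, "none", np.where(lfc > 0, UP, DOWN))
            frames.append(pd.DataFrame({
                "feature_id": matrix.feature_ids,
                "genotype": genotype,
                "stage": stage,
                "log2fc": lfc,
                "p": p,
                "q": q,
                "significant": sig,
                "direction": direction,
            }))
    det = pd.concat(frames, ignore_index=True)
    det.attrs["fc_min"] = thresholds.fc_min
    return det


def significant_sets(det: pd.DataFrame) -> dict[tuple[str, str, str], set[str]]:
    """Per (genotype, stage, direction) sets of significant features."""
    out: dict[tuple[str, str, str], set[str]] = {}
    sig = det[det["significant"]]
    for (g, s, d), grp in sig.groupby(["genotype", "stage", "direction"]):
        out[(g, s, d)] = set(grp["feature_id"])
    return out


def _pivots(det: pd.DataFrame, genotype: str):
    sub = det[det["genotype"] == genotype]
    lfc = sub.pivot(index="feature_id", columns="stage", values="log2fc")
    sig = sub.pivot(index="feature_id", columns="stage", values="significant")
    dirn = sub.pivot(index="feature_id", columns="stage", values="direction")
    return lfc, sig.astype(bool), dirn


def stage_specific_sets(
    det: pd.DataFrame,
    fc_min: float | None = None,
    stages=SEED_STAGES,
) -> dict[tuple[str, str, str], set[str]]:
    """Stage-specific DEG/DEM sets per (genotype, stage, direction).

    Up-specific to stage s: significant-up in s AND log2fc < fc_min in every
    other stage (only the fold-change condition elsewhere); down mirrored
    (log2fc > -fc_min elsewhere).
    """
    if fc_min is None:
        fc_min = det.attrs.get("fc_min", 1.0)
    out: dict[tuple[str, str, str], set[str]] = {}
    for genotype in det["genotype"].unique():
        lfc, sig, dirn = _pivots(det, genotype)
        for s in stages:
            others = [t for t in stages if t != s]
            up = (sig[s] & (dirn[s] == UP) & (lfc[others] < fc_min).all(axis=1))
            down = (sig[s] & (dirn[s] == DOWN) & (lfc[others] > -fc_min).all(axis=1))
            out[(genotype, s, UP)] = set(lfc.index[up])
            out[(genotype, s, DOWN)] = set(lfc.index[down])
    return out


def common_all_stage_sets(
    det: pd.DataFrame, stages=SEED_STAGES
) -> dict[tuple[str, str], set[str]]:
    """Features significant in the same direction in all five stages."""
    out: dict[tuple[str, str], set[str]] = {}
    for genotype in det["genotype"].unique():
        _, sig, dirn = _pivots(det, genotype)
        stages_present = [s for s in stages if s in sig.columns]
        up = (sig[stages_present] & (dirn[stages_present] == UP)).all(axis=1)
        down = (sig[stages_present] & (dirn[stages_present] == DOWN)).all(axis=1)
        if len(stages_present) < len(stages):
            up[:] = False
            down[:] = False
        out[(genotype, UP)] = set(sig.index[up])
        out[(genotype, DOWN)] = set(sig.index[down])
    return out


def write_de_table(det: pd.DataFrame, path: str | Path) -> None:
    det.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    det = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    det["significant"] = det["significant"].astype(bool)
    return det
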