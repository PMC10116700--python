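import itertools

import numpy as np
import pandas as pd
import pytest

import seedcomp as sc
from seedcomp.core import SEED_STAGES, TISSUES, UP
from seedcomp.tf_hormone import FamilyCounts

from conftest import matrix_from_means


def counts_table(per_family):
    """FamilyCounts from {family: {genotype: [c1..c5]}}."""
    idx = pd.MultiIndex.from_tuples(
        [(f, g) for f, per in per_family.items() for g in per],
        names=["family", "genotype"])
    rows = [per_family[f][g] for f, g in idx]
    return FamilyCounts(counts=pd.DataFrame(rows, index=idx,
                                            columns=list(SEED_STAGES)))


class TestFamilyStageCounts:
    @staticmethod
    def det_and_annotation():
        rows = []
        for gene, fam in [("m1", "MADS"), ("m2", "MADS"), ("m3", "MADS"),
                          ("w1", "WRKY"), ("x1", "")]:
            for s in SEED_STAGES:
                lfc = 2.1 if s == "S1" else 0.1
                if gene == "w1":
                    lfc = 1.9 if s == "S1" else 0.1  # below the TF cut
                rows.append({"feature_id": gene, "genotype": "SN",
                             "stage": s, "log2fc": lfc, "p": 0.001,
                             "q": 0.001, "significant": lfc > 1,
                             "direction": UP if lfc > 1 else "none"})
        det = pd.DataFrame(rows)
        ann = pd.DataFrame([
            {"gene_id": g, "tf_family": f, "hormone_pathway": "",
             "hormone_category": "", "chrom": "chr1", "start": 1, "end": 2,
             "is_te": False}
            for g, f in [("m1", "MADS"), ("m2", "MADS"), ("m3", "MADS"),
                         ("w1", "WRKY"), ("x1", "")]])
        return det, ann

    def test_counts_members_at_threshold(self):
        det, ann = self.det_and_annotation()
        fc = sc.family_stage_counts(det, ann, fc_min=2.0)
        assert fc.row("MADS", "SN")["S1"] == 3
        assert fc.row("MADS", "SN")["S2"] == 0

    def test_below_threshold_and_unannotated_not_counted(self):
        det, ann = self.det_and_annotation()
        fc = sc.family_stage_counts(det, ann, fc_min=2.0)
        assert fc.row("WRKY", "SN")["S1"] == 0  # log2fc 1.9 < 2
        assert set(fc.counts.index.get_level_values("family")) == {"MADS",
                                                                   "WRKY"}


class TestSignificantFamilies:
    def test_five_members_in_one_stage_significant(self):
        fc = counts_table({"A": {"SN": [0, 0, 5, 0, 0], "LGR": [0] * 5},
                           "B": {"SN": [4, 4, 4, 4, 4], "LGR": [0] * 5}})
        out = sc.significant_families(fc).set_index("family")
        assert bool(out.loc["A", "significant_SN"])
        assert not bool(out.loc["B", "significant_SN"])  # max 4 < 5

    def test_one_genotype_only_flag(self):
        fc = counts_table({"A": {"SN": [6, 0, 0, 0, 0], "LGR": [1] * 5},
                           "B": {"SN": [6, 0, 0, 0, 0],
                                 "LGR": [0, 0, 7, 0, 0]}})
        out = sc.significant_families(fc).set_index("family")
        assert bool(out.loc["A", "one_genotype_only"])
        assert not bool(out.loc["B", "one_genotype_only"])


class TestClassifyPreferential:
    def test_printed_mads_worked_example(self):
        fc = counts_table({"MADS": {"SN": [25, 22, 18, 14, 9],
                                    "LGR": [16, 17, 16, 13, 14]}})
        out = sc.classify_preferential(fc)
        by = out.set_index(["family", "genotype"])
        assert by.loc[("MADS", "SN"), "label"] == "early"  # 22 - 18 = 4 >= 3
        assert by.loc[("MADS", "LGR"), "label"] == "none"  # 16 - 16 = 0
        assert out["genotype_stage_preferential"].all()

    def test_zero_margin_is_none(self):
        fc = counts_table({"F": {"SN": [5, 5, 5, 5, 5]}})
        assert sc.classify_preferential(fc)["label"].iloc[0] == "none"

    def test_margin_boundary_of_three(self):
        fc = counts_table({"F": {"SN": [0, 0, 3, 4, 5]}})
        assert sc.classify_preferential(fc)["label"].iloc[0] == "late"

    def test_labels_in_both_genotypes_not_preferential(self):
        fc = counts_table({"F": {"SN": [9, 9, 0, 0, 0],
                                 "LGR": [8, 7, 1, 0, 0]}})
        out = sc.classify_preferential(fc)
        assert (out["label"] == "early").all()
        assert not out["genotype_stage_preferential"].any()

    def test_invariant_to_permuting_late_counts(self):
        base = [10, 9, 1, 3, 2]
        labels = set()
        for perm in itertools.permutations(base[2:]):
            fc = counts_table({"F": {"SN": base[:2] + list(perm)}})
            labels.add(sc.classify_preferential(fc)["label"].iloc[0])
        assert labels == {"early"}

    def test_early_late_mutually_exclusive(self, default_gene_det,
                                           default_dataset):
        ann = sc.matrix.validate_annotation(default_dataset.annotation)
        fc = sc.family_stage_counts(default_gene_det, ann)
        out = sc.classify_preferential(fc)
        assert set(out["label"]) <= {"early", "late", "none"}
        # a family/genotype row carries exactly one label by construction
        assert out.groupby(["family", "genotype"]).size().max() == 1


class TestOppositePattern:
    def test_constructed_extrema(self):
        fc = counts_table({"F": {"SN": [5, 6, 1, 5, 7],
                                 "LGR": [2, 3, 9, 4, 3]}})
        out = sc.detect_opposite_pattern(fc)
        assert len(out) == 1
        assert out.iloc[0]["stage"] == "S3"
        assert out.iloc[0]["min_genotype"] == "SN"

    def test_flat_counts_none(self):
        fc = counts_table({"F": {"SN": [3] * 5, "LGR": [3] * 5}})
        assert sc.detect_opposite_pattern(fc).empty

    def test_ties_disqualify(self):
        fc = counts_table({"F": {"SN": [1, 6, 1, 5, 7],
                                 "LGR": [2, 3, 9, 4, 3]}})
        assert sc.detect_opposite_pattern(fc).empty  # min tied S1/S3

    def test_exhaustive_toy_matches_brute_force(self):
        rng = np.random.default_rng(11)
        per_family = {f"F{i}": {"SN": list(rng.integers(0, 6, 5)),
                                "LGR": list(rng.integers(0, 6, 5))}
                      for i in range(4)}
        fc = counts_table(per_family)
        got = {(r.family, r.stage, r.max_genotype, r.min_genotype)
               for r in sc.detect_opposite_pattern(fc).itertuples()}
        expect = set()
        for fam, per in per_family.items():
            for gmax, gmin in (("SN", "LGR"), ("LGR", "SN")):
                cmax, cmin = per[gmax], per[gmin]
                for i, s in enumerate(SEED_STAGES):
                    others = [j for j in range(5) if j != i]
                    if (all(cmax[i] > cmax[j] for j in others)
                            and all(cmin[i] < cmin[j] for j in others)):
                        expect.add((fam, s, gmax, gmin))
        assert got == expect


class TestHormoneClustering:
    @staticmethod
    def archetype_profiles():
        rows = []
        up = np.linspace(1, 3, 6)
        down = up[::-1]
        for i in range(4):
            for genotype in ("SN", "LGR"):
                vec = up if i < 2 else down
                rows.append({"gene_id": f"h{i}", "genotype": genotype,
                             "pathway": "auxin", "category": "response",
                             **{t: v + 0.01 * i for t, v in
                                zip(TISSUES, vec)}})
        return pd.DataFrame(rows)

    def test_planted_archetypes_recovered(self):
        prof = self.archetype_profiles()
        out = sc.cluster_hormone_genes(prof, {"auxin": 2}, seed=0)
        by_gene = out.groupby("gene_id")["cluster"].first()
        assert by_gene["h0"] == by_gene["h1"]
        assert by_gene["h2"] == by_gene["h3"]
        assert by_gene["h0"] != by_gene["h2"]

    def test_k_one_single_cluster(self):
        prof = self.archetype_profiles()
        out = sc.cluster_hormone_genes(prof, {"auxin": 1}, seed=0)
        assert out["cluster"].nunique() == 1

    def test_k_exceeding_profiles_rejected(self):
        prof = self.archetype_profiles()
        with pytest.raises(ValueError, match="auxin"):
            sc.cluster_hormone_genes(prof, {"auxin": 99}, seed=0)

    def test_identical_profiles_never_divergent(self):
        prof = self.archetype_profiles()
        out = sc.cluster_hormone_genes(prof, {"auxin": 2}, seed=0)
        assert sc.divergent_genes(out) == {"auxin": set()}

    def test_deterministic_under_fixed_seed(self):
        prof = self.archetype_profiles()
        a = sc.cluster_hormone_genes(prof, {"auxin": 2}, seed=3)
        b = sc.cluster_hormone_genes(prof, {"auxin": 2}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_divergent_recovered(self, default_dataset):
        ds = default_dataset
        ann = sc.matrix.validate_annotation(ds.annotation)
        profiles = sc.build_hormone_profiles(ds.genes, ann)
        n_per = profiles.groupby("pathway").size()
        k_map = {p: max(2, int(n) // 6) for p, n in n_per.items()}
        out = sc.cluster_hormone_genes(profiles, k_map, seed=42)
        divergent = sc.divergent_genes(out)
        planted = ds.truth.hormone_divergent
        tp = sum(len(set(planted[p]) & divergent.get(p, set()))
                 for p in planted)
        total = sum(len(v) for v in planted.values())
        assert tp / total >= 0.9


class TestHigherExpression:
    @staticmethod
    def build(delta_fpkm):
        means_sn = pd.DataFrame(3.0, index=["g1"], columns=list(TISSUES))
        means_lgr = means_sn.copy()
        means_sn.loc["g1", "S1"] = delta_fpkm
        m = matrix_from_means({"SN": means_sn, "LGR": means_lgr},
                              noise_sd=0.0)
        ann = pd.DataFrame([{"gene_id": "g1", "tf_family": "",
                             "hormone_pathway": "auxin",
                             "hormone_category": "response", "chrom": "chr1",
                             "start": 1, "end": 2, "is_te": False}])
        return m, ann

    def count_at_s1(self, fpkm):
        m, ann = self.build(fpkm)
        out = sc.higher_expression_counts(m, ["g1"], ann, "SN", "LGR")
        row = out[out.stage == "S1"].iloc[0]
        return row["higher_in_SN"], row["higher_in_LGR"]

    def test_clear_difference_counted(self):
        # log2(3+1)=2; SN at log2 2.6 -> diff 0.6 favours SN
        assert self.count_at_s1(2 ** 2.6 - 1) == (1, 0)

    def test_sub_delta_difference_counted_for_neither(self):
        assert self.count_at_s1(2 ** 2.4 - 1) == (0, 0)

    def test_exact_half_log2_counted(self):
        # difference exactly 0.5 is inclusive
        assert self.count_at_s1(2 ** 2.5 - 1) == (1, 0)

    def test_counts_bounded_by_gene_set(self, default_dataset):
        ds = default_dataset
        ann = sc.matrix.validate_annotation(ds.annotation)
        genes = [g for v in ds.truth.hormone_divergent.values() for g in v]
        out = sc.higher_expression_counts(ds.genes, genes, ann, "SN", "LGR")
        per_stage = out.groupby("stage")[
            ["higher_in_SN", "higher_in_LGR"]].sum().sum(axis=1)
        assert (per_stage <= len(genes)).all()
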