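import numpy as np
import pandas as pd
import pytest

import seedcomp as sc
from seedcomp.core import DOWN, SEED_STAGES, UP
from seedcomp.mirna import all_stage_dems, extract_modules, opposite_modules


class TestParseFamily:
    @pytest.mark.parametrize("mirna_id,expected", [
        ("osa-miR396a-3p", (396, "3p")),
        ("osa-miR1432", (1432, "unspecified")),
        ("osa-miR408-5p", (408, "5p")),
        ("osa-miR2118b", (2118, "unspecified")),
        ("osa-miR167i-3p", (167, "3p")),
    ])
    def test_examples(self, mirna_id, expected):
        assert sc.parse_family(mirna_id) == expected

    @pytest.mark.parametrize("bad", ["miRX", "osa-miR", "ath-miR396a", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError, match="malformed"):
            sc.parse_family(bad)


class TestGenotypeSpecificFamilies:
    def test_single_member_single_genotype(self):
        out = sc.genotype_specific_families(
            {"SN": {"osa-miR1848a"}, "LGR": set()})
        assert out == {"SN": {1848}, "LGR": set()}

    def test_family_in_both_is_common(self):
        out = sc.genotype_specific_families(
            {"SN": {"osa-miR396a"}, "LGR": {"osa-miR396b"}})
        assert out == {"SN": set(), "LGR": set()}

    def test_unexpressed_family_in_neither(self):
        out = sc.genotype_specific_families({"SN": set(), "LGR": set()})
        assert out == {"SN": set(), "LGR": set()}

    def test_planted_families_recovered(self, default_dataset):
        ds = default_dataset
        expressed = {g: sc.filter_expressed(ds.mirnas, 50.0, genotype=g)
                     for g in ("SN", "LGR")}
        out = sc.genotype_specific_families(expressed)
        planted = ds.truth.specific_mirna_families
        for g in ("SN", "LGR"):
            assert set(planted[g]) <= out[g]


def det_from_directions(calls, genotype="SN"):
    """DE table from {feature: [direction per stage]} with 'u','d',None."""
    rows = []
    for feature, dirs in calls.items():
        for s, d in zip(SEED_STAGES, dirs):
            sig = d is not None
            lfc = 0.0 if not sig else (2.5 if d == "u" else -2.5)
            rows.append({"feature_id": feature, "genotype": genotype,
                         "stage": s, "log2fc": lfc, "p": 0.001, "q": 0.001,
                         "significant": sig,
                         "direction": "none" if not sig else
                         (UP if d == "u" else DOWN)})
    return pd.DataFrame(rows)


class TestAllStageDems:
    def test_five_of_five_up(self):
        det = det_from_directions({"m1": ["u"] * 5, "m2": ["u"] * 4 + [None]})
        dems = all_stage_dems(det)
        assert dems[("SN", UP)] == {"m1"}  # 4/5 excluded
        assert dems[("SN", DOWN)] == set()

    def test_up_and_down_disjoint(self, default_mirna_det):
        dems = all_stage_dems(default_mirna_det)
        for g in ("SN", "LGR"):
            assert not (dems[(g, UP)] & dems[(g, DOWN)])

    def test_empty_table_handled(self):
        det = det_from_directions({"m1": [None] * 5})
        dems = all_stage_dems(det)
        assert dems[("SN", UP)] == set() and dems[("SN", DOWN)] == set()


class TestExtractModules:
    def test_constructed_module_emitted(self):
        mirna_det = det_from_directions({"osa-miR1": ["u"] * 5})
        gene_det = det_from_directions({"t1": ["d"] * 5, "t2": ["d"] * 4 + [None]})
        targets = pd.DataFrame({"mirna_id": ["osa-miR1", "osa-miR1"],
                                "gene_id": ["t1", "t2"]})
        out = extract_modules(all_stage_dems(mirna_det), targets, gene_det)
        assert list(out["gene_id"]) == ["t1"]  # 4-of-5 target rejected
        assert out["category"].iloc[0] == "up-all-stages"

    def test_missing_target_skipped_with_warning(self, caplog):
        mirna_det = det_from_directions({"osa-miR1": ["u"] * 5})
        gene_det = det_from_directions({"t1": ["d"] * 5})
        targets = pd.DataFrame({"mirna_id": ["osa-miR1"],
                                "gene_id": ["absent"]})
        with caplog.at_level("WARNING"):
            out = extract_modules(all_stage_dems(mirna_det), targets, gene_det)
        assert out.empty
        assert "absent" in caplog.text

    def test_modules_subset_of_target_table(self, default_dataset,
                                            default_gene_det,
                                            default_mirna_det):
        ds = default_dataset
        out = extract_modules(all_stage_dems(default_mirna_det),
                              ds.targets, default_gene_det)
        table_pairs = set(map(tuple, ds.targets.values))
        assert set(zip(out["mirna_id"], out["gene_id"])) <= table_pairs
        assert len(out) <= 2 * len(ds.targets)  # at most one row per genotype

    def test_matches_brute_force_on_random_toy(self):
        rng = np.random.default_rng(17)
        mirnas = [f"osa-miR{7000 + i}" for i in range(20)]
        genes = [f"g{i}" for i in range(30)]
        mcalls, gcalls = {}, {}
        for m in mirnas:
            mcalls[m] = [rng.choice(["u", "d", None]) for _ in range(5)]
        for g in genes:
            gcalls[g] = [rng.choice(["u", "d", None]) for _ in range(5)]
        pairs = [(m, g) for m in mirnas for g in genes
                 if rng.random() < 0.2]
        targets = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
        mirna_det = det_from_directions(mcalls)
        gene_det = det_from_directions(gcalls)
        out = extract_modules(all_stage_dems(mirna_det), targets, gene_det)
        got = set(zip(out["mirna_id"], out["gene_id"], out["category"]))
        expect = set()
        for m, g in pairs:  # nested-loop enumeration oracle
            for md, td in (("u", "d"), ("d", "u")):
                if (all(x == md for x in mcalls[m])
                        and all(x == td for x in gcalls[g])):
                    expect.add((m, g, f"{'up' if md == 'u' else 'down'}-all-stages"))
        assert got == expect


class TestOppositeModules:
    @staticmethod
    def build_case(mirna_ok=True, target_ok=True):
        # miRNA up in LGR S3, down in SN S3; target mirrored
        m_sn = det_from_directions({"osa-miR9000": [None] * 5},
                                   genotype="SN")
        m_sn.loc[m_sn.stage == "S3", ["significant", "direction", "log2fc"]] = \
            [True, DOWN, -2.5] if mirna_ok else [False, "none", 0.0]
        m_lgr = det_from_directions({"osa-miR9000": [None] * 5},
                                    genotype="LGR")
        m_lgr.loc[m_lgr.stage == "S3",
                  ["significant", "direction", "log2fc"]] = [True, UP, 2.5]
        g_sn = det_from_directions({"t1": [None] * 5}, genotype="SN")
        g_sn.loc[g_sn.stage == "S3",
                 ["significant", "direction", "log2fc"]] = \
            [True, UP, 1.5] if target_ok else [False, "none", 0.0]
        g_lgr = det_from_directions({"t1": [None] * 5}, genotype="LGR")
        g_lgr.loc[g_lgr.stage == "S3",
                  ["significant", "direction", "log2fc"]] = [True, DOWN, -1.5]
        targets = pd.DataFrame({"mirna_id": ["osa-miR9000"],
                                "gene_id": ["t1"]})
        return m_sn, m_lgr, g_sn, g_lgr, targets

    def test_constructed_ss_module(self):
        m_sn, m_lgr, g_sn, g_lgr, targets = self.build_case()
        out = opposite_modules(m_sn, m_lgr, g_sn, g_lgr,
                               {"SS": sc.same_stage_pairing()}, targets)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["category"] == "opposite-SS"
        assert row["up_genotype"] == "LGR" and row["up_stage"] == "S3"

    def test_mirna_met_but_target_not_opposite(self):
        m_sn, m_lgr, g_sn, g_lgr, targets = self.build_case(target_ok=False)
        out = opposite_modules(m_sn, m_lgr, g_sn, g_lgr,
                               {"SS": sc.same_stage_pairing()}, targets)
        assert out.empty

    def test_matches_brute_force_on_small_instance(self):
        rng = np.random.default_rng(23)
        mirnas = [f"osa-miR{8000 + i}" for i in range(8)]
        genes = [f"g{i}" for i in range(10)]
        calls = {}
        for geno in ("SN", "LGR"):
            for f in mirnas + genes:
                calls[(f, geno)] = [rng.choice(["u", "d", None])
                                    for _ in range(5)]
        m_sn = det_from_directions({m: calls[(m, "SN")] for m in mirnas}, "SN")
        m_lgr = det_from_directions({m: calls[(m, "LGR")] for m in mirnas},
                                    "LGR")
        g_sn = det_from_directions({g: calls[(g, "SN")] for g in genes}, "SN")
        g_lgr = det_from_directions({g: calls[(g, "LGR")] for g in genes},
                                    "LGR")
        pairs = [(m, g) for m in mirnas for g in genes if rng.random() < 0.3]
        targets = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
        cs_pairs = [("S1", "S2"), ("S2", "S3"), ("S3", "S4"), ("S4", "S5")]
        pairings = {"SS": sc.same_stage_pairing(),
                    "CS": sc.StagePairing(pairs=cs_pairs, kind="CS", offset=1)}
        out = opposite_modules(m_sn, m_lgr, g_sn, g_lgr, pairings, targets)
        got = set(zip(out["mirna_id"], out["gene_id"], out["kind"],
                      out["up_genotype"], out["up_stage"]))
        si = {s: i for i, s in enumerate(SEED_STAGES)}
        expect = set()
        for kind, plist in (("SS", [(s, s) for s in SEED_STAGES]),
                            ("CS", cs_pairs)):
            for a, b in plist:
                for m, g in pairs:
                    # up in LGR b, down in SN a; target opposite
                    if (calls[(m, "LGR")][si[b]] == "u"
                            and calls[(m, "SN")][si[a]] == "d"
                            and calls[(g, "LGR")][si[b]] == "d"
                            and calls[(g, "SN")][si[a]] == "u"):
                        expect.add((m, g, kind, "LGR", b))
                    if (calls[(m, "SN")][si[a]] == "u"
                            and calls[(m, "LGR")][si[b]] == "d"
                            and calls[(g, "SN")][si[a]] == "d"
                            and calls[(g, "LGR")][si[b]] == "u"):
                        expect.add((m, g, kind, "SN", a))
        assert got == expect

    def test_planted_opposite_modules_recovered(self, default_dataset,
                                                default_gene_det,
                                                default_mirna_det):
        ds = default_dataset
        cs = sc.StagePairing(
            pairs=[tuple(p) for p in ds.truth.comparable_chain], kind="CS",
            offset=ds.truth.lag)
        out = opposite_modules(
            default_mirna_det[default_mirna_det.genotype == "SN"],
            default_mirna_det[default_mirna_det.genotype == "LGR"],
            default_gene_det[default_gene_det.genotype == "SN"],
            default_gene_det[default_gene_det.genotype == "LGR"],
            {"SS": sc.same_stage_pairing(), "CS": cs}, ds.targets)
        got = set(zip(out["mirna_id"], out["gene_id"]))
        planted = {(m["mirna"], m["gene"]) for m in ds.truth.opposite_modules}
        assert planted <= got
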