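"""Cross-link quantitation, distance mapping and assembly scoring."""

import numpy as np
import pandas as pd
import pytest

from oligoscope import clms, oligomer, synth
from oligoscope.clms import (
    CrossLinkFeature,
    classify_quant,
    distance_table,
    evaluate_assemblies,
    load_crosslinks,
    map_distance,
)
from oligoscope.structio import StructureModel, symmetry_expand


def _feature(pa="A", ra=1, pb="B", rb=2, control=(100.0,), rna=(100.0,)):
    return CrossLinkFeature(pa, ra, pb, rb,
                            {"control": np.array(control, float),
                             "rna": np.array(rna, float)})


SCHEMA = {
    "protein_a": "ProteinA", "residue_a": "ResidueA",
    "protein_b": "ProteinB", "residue_b": "ResidueB",
    "charge": "Charge", "modification": "Modification",
    "conditions": {"control": ["control_1", "control_2", "control_3"],
                   "rna": ["rna_1", "rna_2", "rna_3"]},
}


class TestLoad:
    def _df(self):
        return pd.DataFrame([{
            "ProteinA": "A", "ResidueA": 5, "ProteinB": "B", "ResidueB": 9,
            "Charge": 3, "Modification": "",
            "control_1": 10.0, "control_2": 11.0, "control_3": 9.0,
            "rna_1": 30.0, "rna_2": 33.0, "rna_3": 27.0}])

    def test_single_row_parse(self, tmp_path):
        p = tmp_path / "xl.csv"
        self._df().to_csv(p, index=False)
        feats = load_crosslinks(p, SCHEMA)
        assert len(feats) == 1
        f = feats[0]
        assert (f.protein_a, f.residue_a, f.protein_b, f.residue_b) == ("A", 5, "B", 9)
        np.testing.assert_allclose(f.intensities["rna"], [30, 33, 27])

    def test_column_order_irrelevant(self, tmp_path):
        df = self._df()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        df[list(df.columns[::-1])].to_csv(p2, index=False)
        f1, f2 = load_crosslinks(p1, SCHEMA)[0], load_crosslinks(p2, SCHEMA)[0]
        assert f1.key() == f2.key()
        np.testing.assert_allclose(f1.intensities["control"], f2.intensities["control"])

    def test_duplicate_rows_merged_summed(self, tmp_path):
        df = pd.concat([self._df(), self._df()], ignore_index=True)
        p = tmp_path / "dup.csv"
        df.to_csv(p, index=False)
        with pytest.warns(UserWarning, match="duplicate"):
            feats = load_crosslinks(p, SCHEMA)
        assert len(feats) == 1
        np.testing.assert_allclose(feats[0].intensities["control"], [20, 22, 18])

    def test_generator_round_trip(self, fixture_structure, tmp_path):
        df, truth = synth.gen_crosslink_table(fixture_structure, n_true=6, n_decoy=3,
                                              seed=2)
        p = tmp_path / "gen.csv"
        df.to_csv(p, index=False)
        feats = load_crosslinks(p, truth.params["schema"])
        assert len(feats) == 9
        for f in feats:
            assert f.intensities["control"].shape == (3,)
            assert f.intensities["rna"].shape == (3,)


def brute_force_classify(features, t=2.0, min_rep=2):
    """Independent reimplementation of the fold-change rule."""
    out = []
    for f in features:
        a = [v for v in f.intensities["control"] if np.isfinite(v) and v > 0]
        b = [v for v in f.intensities["rna"] if np.isfinite(v) and v > 0]
        if a and b:
            fc = (sum(b) / len(b)) / (sum(a) / len(a))
            out.append("B-enriched" if fc >= t else
                       "A-enriched" if fc <= 1 / t else "common")
        elif len(b) >= min_rep and not a:
            out.append("B-enriched")
        elif len(a) >= min_rep and not b:
            out.append("A-enriched")
        else:
            out.append("unquantified")
    return out


class TestClassify:
    def test_equal_means_common(self):
        qc = classify_quant([_feature(control=(100, 90, 110), rna=(90, 100, 110))],
                            "control", "rna")
        row = qc.table.iloc[0]
        assert row["category"] == "common" and row["fold_change"] == pytest.approx(1.0)

    def test_fc_2p5_rna_enriched(self):
        qc = classify_quant([_feature(control=(100,), rna=(250,))], "control", "rna")
        row = qc.table.iloc[0]
        assert row["category"] == "B-enriched"
        assert row["fold_change"] == pytest.approx(2.5)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(13)
        feats = []
        for _ in range(200):
            ctl = rng.lognormal(10, 1.5, 3)
            r = rng.lognormal(10, 1.5, 3)
            # plant random missingness
            ctl[rng.random(3) < 0.25] = np.nan
            r[rng.random(3) < 0.25] = np.nan
            feats.append(_feature(control=ctl, rna=r))
        qc = classify_quant(feats, "control", "rna")
        assert qc.table["category"].tolist() == brute_force_classify(feats)

    def test_condition_swap_symmetry(self):
        rng = np.random.default_rng(14)
        feats = [_feature(control=rng.lognormal(10, 1, 3), rna=rng.lognormal(10, 1, 3))
                 for _ in range(50)]
        fwd = classify_quant(feats, "control", "rna").table["category"]
        rev = classify_quant(feats, "rna", "control").table["category"]
        swap = {"A-enriched": "B-enriched", "B-enriched": "A-enriched"}
        assert rev.tolist() == [swap.get(c, c) for c in fwd]

    def test_scaling_both_conditions_leaves_fc(self):
        f = _feature(control=(100, 120, 80), rna=(300, 280, 320))
        fc1 = classify_quant([f], "control", "rna").table["fold_change"][0]
        f2 = _feature(control=(700, 840, 560), rna=(2100, 1960, 2240))
        fc2 = classify_quant([f2], "control", "rna").table["fold_change"][0]
        assert fc1 == pytest.approx(fc2)

    def test_one_condition_only_detection(self):
        only_b = _feature(control=(np.nan, np.nan, np.nan), rna=(50, 60, 55))
        qc = classify_quant([only_b], "control", "rna")
        row = qc.table.iloc[0]
        assert row["category"] == "B-enriched" and row["flag"] == "detected-only-in-B"
        assert np.isinf(row["fold_change"])

    def test_planted_recovery(self, fixture_structure):
        fcs = [4.0] * 5 + [0.25] * 5 + [1.0] * 10
        df, truth = synth.gen_crosslink_table(
            fixture_structure, n_true=15, n_decoy=5, fold_changes=fcs,
            replicate_cv=0.2, seed=5)
        feats = _feats_from_df(df, truth.params["schema"])
        qc = classify_quant(feats, "control", "rna")
        cats = qc.table["category"]
        assert (cats[:5] == "B-enriched").sum() + (cats[5:10] == "A-enriched").sum() >= 9
        assert cats.tolist() == brute_force_classify(feats)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classify_quant([_feature()], "control", "phage")


def _feats_from_df(df, schema, tmpdir=None):
    import os
    import tempfile
    fd, path = tempfile.mkstemp(suffix=".csv")
    os.close(fd)
    try:
        df.to_csv(path, index=False)
        return load_crosslinks(path, schema)
    finally:
        os.unlink(path)


class TestMapDistance:
    def test_same_residue_zero(self, fixture_structure):
        f = CrossLinkFeature("A", 1, "A", 1, {"c": np.array([1.0])})
        r = map_distance(f, [fixture_structure])
        assert r.distance == pytest.approx(0.0) and r.satisfied

    def test_unresolvable_site_reported_not_fatal(self, fixture_structure):
        f = CrossLinkFeature("Z", 1, "A", 1, {"c": np.array([1.0])})
        r = map_distance(f, [fixture_structure])
        assert r.distance is None and "unresolvable" in r.error

    def _crystal(self):
        """Two-atom P2₁-like crystal where the pair is short only via a mate."""
        ops = [(np.eye(3), np.zeros(3)),
               (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))]
        return StructureModel(
            chain=np.array(["A", "B"]), resnum=np.array([1, 1]),
            resname=np.array(["ALA", "ALA"]), atom_name=np.array(["CA", "CA"]),
            element=np.array(["C", "C"]),
            # A near origin, B near the far face: mate of B lands near A
            xyz=np.array([[1.0, 1.0, 1.0], [-2.0, 16.0, -2.0]]),
            occupancy=np.ones(2),
            cell=(30.0, 30.0, 30.0, 90.0, 90.0, 90.0), symmetry_ops=ops)

    def test_symmetry_strictly_shortens_and_matches_brute_force(self):
        m = self._crystal()
        f = CrossLinkFeature("A", 1, "B", 1, {"c": np.array([1.0])})
        r_id = map_distance(f, [m], use_symmetry=False)
        r_sym = map_distance(f, [m], use_symmetry=True)
        assert r_sym.distance < r_id.distance
        # brute force: min over every op x [-2,2]^3 shift of |A - B_copy|
        copies = symmetry_expand(m, m.xyz[0], r_id.distance)
        brute = min(np.linalg.norm(m.xyz[0] - c.xyz[1]) for c in copies)
        assert r_sym.distance == pytest.approx(brute, abs=1e-9)
        assert "sym" in r_sym.copy_label

    def test_more_copies_never_increase_min_distance(self, fixture_structure):
        f = CrossLinkFeature("A", 5, "B", 40, {"c": np.array([1.0])})
        d1 = map_distance(f, [fixture_structure]).distance
        shifted = fixture_structure.transformed(np.eye(3), np.array([30.0, 0, 0]))
        d2 = map_distance(f, [fixture_structure, shifted]).distance
        assert d2 <= d1 + 1e-12

    def test_homodimer_ambiguity_minimum_over_assignments(self, fixture_structure):
        # map protein 'P' onto both chains; min over the 2x2 chain assignments
        f = CrossLinkFeature("P", 3, "P", 50, {"c": np.array([1.0])})
        cmap = {"P": ["A", "B"]}
        r = map_distance(f, [fixture_structure], chain_map=cmap)
        cands = []
        for ca in "AB":
            for cb in "AB":
                fa = CrossLinkFeature(ca, 3, cb, 50, {"c": np.array([1.0])})
                cands.append(map_distance(fa, [fixture_structure]).distance)
        assert r.distance == pytest.approx(min(cands))


class TestSatisfactionConstruction:
    def test_planted_links_satisfied_at_cutoff(self, fixture_structure):
        df, truth = synth.gen_crosslink_table(fixture_structure, n_true=10, n_decoy=0,
                                              cutoff=24.0, seed=7)
        feats = _feats_from_df(df, truth.params["schema"])
        dt = distance_table(feats, [fixture_structure], cutoff=24.0)
        assert dt["satisfied"].all()
        # at half the cutoff not all planted links can remain satisfied
        dt12 = distance_table(feats, [fixture_structure], cutoff=12.0)
        planted = [ft["distance"] for ft in truth.params["features"]]
        expect_all = all(d <= 12.0 for d in planted)
        assert dt12["satisfied"].all() == expect_all


class TestEvaluateAssemblies:
    def test_identical_assemblies_identical_tables(self, fixture_structure):
        df, truth = synth.gen_crosslink_table(fixture_structure, n_true=8, n_decoy=2,
                                              seed=8)
        feats = _feats_from_df(df, truth.params["schema"])
        tab = evaluate_assemblies(feats, {"m1": fixture_structure,
                                          "m2": fixture_structure})
        assert tab["n_satisfied"].nunique() == 1
        assert tab["fraction_satisfied"].nunique() == 1

    def test_lateral_assembly_flips_intercopy_links(self, fixture_structure):
        """Heterodimer-style links too long within one copy become satisfied
        between adjacent copies of a lateral two-copy assembly."""
        # step along the unit's principal axis so the copies pack laterally
        X = fixture_structure.xyz - fixture_structure.xyz.mean(0)
        axis = np.linalg.eigh(X.T @ X)[1][:, -1]
        rise = 36.0
        assembly, rep = oligomer.build_lateral_oligomer(
            fixture_structure, n_copies=2, rise=rise, axis=axis)
        assert not rep.failed
        # plant links (chain A residue, chain B residue) that are >24 A inside
        # one copy but <=24 A between copies
        A = fixture_structure.xyz[fixture_structure.chain == "A"]
        B = fixture_structure.xyz[fixture_structure.chain == "B"]
        t = rise * axis
        feats = []
        for ri in range(len(A)):
            for rj in range(len(B)):
                d0 = np.linalg.norm(A[ri] - B[rj])
                d_step = min(np.linalg.norm(A[ri] - B[rj] - t),
                             np.linalg.norm(A[ri] - B[rj] + t))
                if d0 > 24.0 and d_step <= 24.0:
                    feats.append(CrossLinkFeature("N45", ri + 1, "N90", rj + 1,
                                                  {"c": np.array([1.0])}))
            if len(feats) >= 6:
                break
        assert len(feats) >= 3
        cmap_mono = {"N45": ["A"], "N90": ["B"]}
        cmap_lat = {"N45": ["A", "A2"], "N90": ["B", "B2"]}
        tab = evaluate_assemblies(
            feats,
            {"monomer": fixture_structure, "lateral": assembly},
            chain_maps={"monomer": cmap_mono, "lateral": cmap_lat})
        sat = dict(zip(tab["assembly"], tab["fraction_satisfied"]))
        assert sat["monomer"] == 0.0
        assert sat["lateral"] == 1.0
        assert tab.iloc[0]["assembly"] == "lateral"

    def test_ranking_invariant_under_feature_permutation(self, fixture_structure):
        df, truth = synth.gen_crosslink_table(fixture_structure, n_true=8, n_decoy=4,
                                              seed=9)
        feats = _feats_from_df(df, truth.params["schema"])
        shifted = fixture_structure.transformed(np.eye(3), np.array([100.0, 0, 0]))
        both = {"a": fixture_structure, "b": shifted}
        t1 = evaluate_assemblies(feats, both)
        rng = np.random.default_rng(16)
        perm = list(rng.permutation(len(feats)))
        t2 = evaluate_assemblies([feats[i] for i in perm], both)
        assert t1["assembly"].tolist() == t2["assembly"].tolist()

    def test_requires_two_assemblies(self, fixture_structure):
        with pytest.raises(ValueError):
            evaluate_assemblies([], {"only": fixture_structure})
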