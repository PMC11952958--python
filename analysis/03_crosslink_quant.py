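#!/usr/bin/env python
"""Quantitative cross-link analysis on the planted table.

Classifies features by fold change (RNA-enriched / control-enriched / common),
maps every feature onto the fixture structure as Cα–Cα restraints at the 24 Å
EDC contract, and scores a single copy against a lateral two-copy assembly
with links planted across the copy interface. Writes
results/clms_summary.json and results/crosslink_distances.tsv.
"""

import json
from pathlib import Path

import numpy as np

from oligoscope import clms, oligomer
from oligoscope.clms import CrossLinkFeature
from oligoscope.structio import read_structure

ROOT = Path(__file__).resolve().parents[1]


def main():
    inputs = ROOT / "results" / "inputs"
    truths = json.loads((inputs / "truth.json").read_text())
    schema = truths["crosslinks"]["params"]["schema"]
    feats = clms.load_crosslinks(inputs / "crosslinks.csv", schema)
    model = read_structure(inputs / "fixture.pdb")

    qc = clms.classify_quant(feats, "control", "rna")
    planted = truths["crosslinks"]["params"]["features"]
    planted_up = sum(1 for f in planted if f["fold_change"] >= 2)
    found_up = int((qc.table["category"] == "B-enriched").sum())

    dt = clms.distance_table(feats, [model], cutoff=24.0)
    dt.to_csv(ROOT / "results" / "crosslink_distances.tsv", sep="\t", index=False)

    # lateral assembly comparison on links planted across the interface
    X = model.xyz - model.xyz.mean(0)
    axis = np.linalg.eigh(X.T @ X)[1][:, -1]
    assembly, rep = oligomer.build_lateral_oligomer(model, 2, rise=36.0, axis=axis)
    A = model.xyz[model.chain == "A"]
    B = model.xyz[model.chain == "B"]
    t = 36.0 * axis
    inter = []
    for ri in range(len(A)):
        for rj in range(len(B)):
            if np.linalg.norm(A[ri] - B[rj]) > 24.0 and min(
                    np.linalg.norm(A[ri] - B[rj] - t),
                    np.linalg.norm(A[ri] - B[rj] + t)) <= 24.0:
                inter.append(CrossLinkFeature("N45", ri + 1, "N90", rj + 1,
                                              {"c": np.array([1.0])}))
        if len(inter) >= 8:
            break
    tab = clms.evaluate_assemblies(
        inter, {"single_copy": model, "lateral_dimer": assembly},
        chain_maps={"single_copy": {"N45": ["A"], "N90": ["B"]},
                    "lateral_dimer": {"N45": ["A", "A2"], "N90": ["B", "B2"]}})

    summary = {
        "category_counts": qc.counts(),
        "planted_rna_enriched": planted_up,
        "recovered_rna_enriched": found_up,
        "distance_satisfied_at_24A": int(dt["satisfied"].fillna(False).sum()),
        "n_features": len(feats),
        "assembly_comparison": tab.drop(columns=["distances"]).to_dict("records"),
        "assembly_clashes": rep.n_clashes,
    }
    (ROOT / "results" / "clms_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"categories: {qc.counts()}")
    print(f"recovered {found_up}/{planted_up} planted RNA-enriched features")
    best = tab.iloc[0]
    print(f"assembly ranking: {best['assembly']} satisfies "
          f"{best['fraction_satisfied']:.0%} of interface links; the single "
          f"copy satisfies {tab.iloc[-1]['fraction_satisfied']:.0%} — links "
          "impossible within one copy are explained by lateral oligomerization")


if __name__ == "__main__":
    main()
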