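"""Quantitative cross-linking mass spectrometry analysis.

Cross-linking features (unique cross-linked peptide observations with MS1
replicate areas per condition) are classified by fold change into
condition-enriched and common classes, mapped onto structural models as
Cα–Cα distance restraints — optionally searching crystallographic symmetry
mates for the shortest realizable distance — and used to score competing
assembly hypotheses.

EDC is a zero-length coupling chemistry; following common practice the
restraint is operationalized as a Cα–Cα distance of at most 24 Å
(configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import (
    ResidueAddress,
    ResidueLookupError,
    StructureModel,
    residue_anchor,
    symmetry_expand,
)

DEFAULT_CUTOFF = 24.0  # Å, Cα–Cα allowance for EDC cross-links


@dataclass
class CrossLinkFeature:
    """One quantified cross-linking feature."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    intensities: dict            # condition -> np.ndarray of areas (NaN = missing)
    chemistry: str = "EDC"
    charge: int | None = None
    modification: str = ""

    def key(self):
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b,
                self.charge, self.modification)

    def detected(self, condition: str) -> int:
        """Number of replicates with a positive, non-missing area."""
        v = np.asarray(self.intensities.get(condition, []), float)
        return int(np.sum(np.nan_to_num(v, nan=0.0) > 0))

    def mean_area(self, condition: str) -> float:
        v = np.asarray(self.intensities.get(condition, []), float)
        v = v[np.isfinite(v) & (v > 0)]
        return float(v.mean()) if v.size else np.nan


@dataclass
class QuantClassification:
    table: pd.DataFrame          # feature_index, fold_change, category, flag
    condition_a: str
    condition_b: str
    fold_threshold: float
    min_replicates: int

    def counts(self) -> dict:
        return self.table["category"].value_counts().to_dict()


@dataclass
class DistanceReport:
    feature: CrossLinkFeature
    distance: float | None
    satisfied: bool | None
    copy_label: str = ""
    model_id: str = ""
    error: str = ""


def load_crosslinks(path, schema: dict) -> list[CrossLinkFeature]:
    """Load a Skyline-style cross-link export.

    ``schema`` names the columns:
    ``{"protein_a": col, "residue_a": col, "protein_b": col, "residue_b": col,
    "conditions": {label: [intensity columns]}, "charge": col?, "modification": col?}``.
    Duplicate (sites, charge, modification) rows are merged by summing areas.
    Rows whose residue fields do not parse are collected as errors, not fatal.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = [schema[k] for k in ("protein_a", "residue_a", "protein_b", "residue_b")]
    missing = [c for c in required if c not in df.columns]
    for cond, cols in schema["conditions"].items():
        missing += [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    feats: dict[tuple, CrossLinkFeature] = {}
    errors = []
    for i, row in df.iterrows():
        try:
            ra = int(row[schema["residue_a"]])
            rb = int(row[schema["residue_b"]])
        except (TypeError, ValueError):
            errors.append((i, "unparseable residue number"))
            continue
        intens = {
            cond: np.array([pd.to_numeric(row[c], errors="coerce") for c in cols], float)
            for cond, cols in schema["conditions"].items()
        }
        f = CrossLinkFeature(
            protein_a=str(row[schema["protein_a"]]),
            residue_a=ra,
            protein_b=str(row[schema["protein_b"]]),
            residue_b=rb,
            intensities=intens,
            charge=int(row[schema["charge"]]) if schema.get("charge") in df.columns else None,
            modification=str(row[schema["modification"]]) if schema.get("modification") in df.columns else "",
        )
        if f.key() in feats:
            warnings.warn(f"duplicate feature {f.key()}: areas summed")
            prev = feats[f.key()]
            for cond in prev.intensities:
                prev.intensities[cond] = np.nansum(
                    [prev.intensities[cond], f.intensities[cond]], axis=0)
        else:
            feats[f.key()] = f
    if errors:
        warnings.warn(f"{len(errors)} rows skipped: {errors[:5]}")
    return list(feats.values())


def classify_quant(features: list[CrossLinkFeature], condition_a: str,
                   condition_b: str, fold_threshold: float = 2.0,
                   min_replicates: int = 2) -> QuantClassification:
    """Fold-change classification of features across two conditions.

    FC = mean(non-missing B) / mean(non-missing A); B-enriched when
    FC ≥ threshold, A-enriched when FC ≤ 1/threshold, otherwise common.
    Features detected in only one condition in at least ``min_replicates``
    replicates are assigned to that condition's enriched class with an
    infinite/zero FC and a presence/absence flag; all other partial
    detections are unquantified. Missing values are never imputed.
    """
    for f in features:
        for cond in (condition_a, condition_b):
            if cond not in f.intensities:
                raise ValueError(f"condition {cond!r} absent from feature {f.key()}")
    rows = []
    for i, f in enumerate(features):
        na, nb = f.detected(condition_a), f.detected(condition_b)
        ma, mb = f.mean_area(condition_a), f.mean_area(condition_b)
        flag = ""
        if na > 0 and nb > 0:
            fc = mb / ma
            if fc >= fold_threshold:
                cat = "B-enriched"
            elif fc <= 1.0 / fold_threshold:
                cat = "A-enriched"
            else:
                cat = "common"
        elif nb >= min_replicates and na == 0:
            fc, cat, flag = np.inf, "B-enriched", "detected-only-in-B"
        elif na >= min_replicates and nb == 0:
            fc, cat, flag = 0.0, "A-enriched", "detected-only-in-A"
        else:
            fc, cat, flag = np.nan, "unquantified", "insufficient-detection"
        rows.append({"feature_index": i, "fold_change": fc, "category": cat,
                     "flag": flag,
                     "mean_a": ma, "mean_b": mb, "n_a": na, "n_b": nb})
    table = pd.DataFrame(rows)
    return QuantClassification(table, condition_a, condition_b,
                               fold_threshold, min_replicates)


def _anchor_candidates(model: StructureModel, protein: str, resnum: int,
                       chain_map: dict | None):
    """All candidate anchor coordinates for a (protein, residue) site.

    ``chain_map`` maps protein labels to lists of chain ids; default is the
    protein label itself as a single chain. Homodimeric ambiguity (several
    chains for one protein) yields several candidates; callers minimize over
    all assignments.
    """
    chains = (chain_map or {}).get(protein, [protein])
    out = []
    for ch in chains:
        try:
            xyz, _ = residue_anchor(model, ResidueAddress(ch, resnum))
            out.append((ch, xyz))
        except ResidueLookupError:
            continue
    return out


def map_distance(feature: CrossLinkFeature, models: list[StructureModel],
                 use_symmetry: bool = False, cutoff: float = DEFAULT_CUTOFF,
                 chain_map: dict | None = None) -> DistanceReport:
    """Minimal Cα–Cα distance of a cross-link over models (and symmetry mates).

    With symmetry enabled, site B is searched across all crystallographic
    copies with atoms within the identity-copy distance of site A — any mate
    improving on the identity distance necessarily lies within that radius —
    so the reported distance is the true minimum over the lattice.
    """
    best = (np.inf, "", "")
    for mi, model in enumerate(models):
        cand_a = _anchor_candidates(model, feature.protein_a, feature.residue_a, chain_map)
        cand_b = _anchor_candidates(model, feature.protein_b, feature.residue_b, chain_map)
        if not cand_a or not cand_b:
            continue
        for cha, xa in cand_a:
            for chb, xb in cand_b:
                d = float(np.linalg.norm(xa - xb))
                if d < best[0]:
                    best = (d, f"model{mi}:{cha}-{chb}", model.model_id)
        if use_symmetry and model.cell is not None:
            for cha, xa in cand_a:
                radius = min(best[0], 1e6)
                copies = symmetry_expand(model, xa, radius)
                for cp in copies:
                    if cp.is_identity:
                        continue
                    # copies preserve atom order, so anchor indices carry over
                    for chb, _ in cand_b:
                        idx = _anchor_index(model, chb, feature.residue_b)
                        if idx is None:
                            continue
                        d = float(np.linalg.norm(xa - cp.xyz[idx]))
                        if d < best[0]:
                            tag = f"model{mi}:{cha}-{chb} sym op{cp.op_index} shift{cp.lattice_shift}"
                            best = (d, tag, model.model_id)
    if not np.isfinite(best[0]):
        return DistanceReport(feature, None, None,
                              error="sites unresolvable in every supplied model")
    return DistanceReport(feature, best[0], best[0] <= cutoff, best[1], best[2])


def _anchor_index(model: StructureModel, chain: str, resnum: int):
    mask = (model.chain == chain) & (model.resnum == resnum) & (model.atom_name == "CA")
    idx = np.where(mask)[0]
    if idx.size == 0:
        mask = (model.chain == chain) & (model.resnum == resnum)
        idx = np.where(mask)[0]
    return int(idx[0]) if idx.size else None


def distance_table(features, models, **kw) -> pd.DataFrame:
    reports = [map_distance(f, models, **kw) for f in features]
    return pd.DataFrame(
        {
            "protein_a": [r.feature.protein_a for r in reports],
            "residue_a": [r.feature.residue_a for r in reports],
            "protein_b": [r.feature.protein_b for r in reports],
            "residue_b": [r.feature.residue_b for r in reports],
            "distance": [r.distance for r in reports],
            "satisfied": [r.satisfied for r in reports],
            "copy": [r.copy_label for r in reports],
            "error": [r.error for r in reports],
        }
    )


def evaluate_assemblies(features: list[CrossLinkFeature],
                        assemblies: dict,
                        cutoff: float = DEFAULT_CUTOFF,
                        chain_maps: dict | None = None) -> pd.DataFrame:
    """Score competing assembly models against a cross-link set.

    ``assemblies`` maps assembly names to a StructureModel (or list of
    models); ``chain_maps`` optionally maps assembly name → chain map.
    Returns one row per assembly with satisfied counts/fractions, ranked by
    satisfied fraction (ties broken by the mean distance of violated links).
    """
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies to compare")
    rows = []
    for name, model in assemblies.items():
        models = model if isinstance(model, list) else [model]
        cmap = (chain_maps or {}).get(name)
        reports = [map_distance(f, models, cutoff=cutoff, chain_map=cmap)
                   for f in features]
        dists = np.array([r.distance if r.distance is not None else np.nan
                          for r in reports])
        sat = np.array([bool(r.satisfied) for r in reports])
        viol = dists[~sat & np.isfinite(dists)]
        rows.append({
            "assembly": name,
            "n_features": len(features),
            "n_mapped": int(np.isfinite(dists).sum()),
            "n_satisfied": int(sat.sum()),
            "fraction_satisfied": float(sat.sum() / len(features)) if features else np.nan,
            "mean_violated_distance": float(viol.mean()) if viol.size else 0.0,
            "distances": dists,
        })
    df = pd.DataFrame(rows).sort_values(
        ["fraction_satisfied", "mean_violated_distance"],
        ascending=[False, True], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
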