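"""Config-driven pipeline runner.

A pipeline is a YAML document::

    seed: 7
    stages:
      - name: apo_curve
        stage: synth_curve
        shape: sphere
        params: {radius: 50}
      - name: guinier
        stage: guinier
        curve: apo_curve

Stages execute in order; each stage reads earlier stages' outputs by name,
contributes a JSON-serializable summary to the report, and may stash Python
objects in the run context for later stages. The report embeds the seed and
a hash of the canonical config so that reruns are verifiable; identical
config + seed give an identical report.

Unknown stage types and unknown stage keys are rejected before execution —
silent misconfiguration is the main failure mode of multi-stage analyses.
"""

from __future__ import annotations

import hashlib
import inspect
import json

import numpy as np
import yaml

from . import clms, oligomer, saxs, synth, varcons

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class PipelineError(ValueError):
    pass


class PipelineConfig:
    """Validated pipeline configuration (ordered stages + global seed)."""

    TOP_KEYS = {"seed", "stages"}
    STAGE_META = {"name", "stage"}

    def __init__(self, doc: dict):
        unknown = set(doc) - self.TOP_KEYS
        if unknown:
            raise PipelineError(f"unknown top-level keys: {sorted(unknown)}")
        self.seed = int(doc.get("seed", 0))
        stages = doc.get("stages")
        if not stages:
            raise PipelineError("config must declare a non-empty 'stages' list")
        self.stages = []
        names = set()
        for i, st in enumerate(stages):
            if "stage" not in st:
                raise PipelineError(f"stage #{i}: missing 'stage' type")
            kind = st["stage"]
            if kind not in STAGE_REGISTRY:
                raise PipelineError(
                    f"stage #{i}: unknown stage type {kind!r} "
                    f"(known: {sorted(STAGE_REGISTRY)})")
            name = st.get("name", f"{kind}_{i}")
            if name in names:
                raise PipelineError(f"duplicate stage name {name!r}")
            names.add(name)
            params = {k: v for k, v in st.items() if k not in self.STAGE_META}
            sig = inspect.signature(STAGE_REGISTRY[kind])
            allowed = set(sig.parameters) - {"ctx", "seed"}
            bad = set(params) - allowed
            if bad:
                raise PipelineError(
                    f"stage {name!r} ({kind}): unknown keys {sorted(bad)} "
                    f"(allowed: {sorted(allowed)})")
            self.stages.append((name, kind, params))
        self.doc = doc

    def config_hash(self) -> str:
        canon = json.dumps(self.doc, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh))


def _get(ctx, key, what):
    if key not in ctx:
        raise PipelineError(f"stage input {key!r} ({what}) not produced by any earlier stage")
    return ctx[key]


# ---------------------------------------------------------------- stages

def _stage_synth_curve(ctx, seed, shape="sphere", params=None, noise_rel=0.01):
    curve, truth = synth.gen_curve(shape, params or {"radius": 50.0},
                                   noise_rel=noise_rel, seed=seed)
    return curve, {"shape": shape, "truth": truth.params}


def _stage_guinier(ctx, seed, curve):
    c = _get(ctx, curve, "ScatteringCurve")
    g = saxs.guinier_fit(c)
    return g, {"rg": g.Rg, "i0": g.I0, "n_points": g.n_points,
               "qmax_rg": g.qmax_rg, "ok": g.ok}


def _stage_estimate_dmax(ctx, seed, curve, scan_lo=60.0, scan_hi=140.0, scan_step=5.0):
    c = _get(ctx, curve, "ScatteringCurve")
    grid = np.arange(scan_lo, scan_hi + scan_step / 2, scan_step)
    dmax, pd_, table = saxs.estimate_dmax(c, grid)
    return pd_, {"dmax": dmax, "chi2": None if pd_ is None else pd_.chi2,
                 "scan": table}

def _stage_kratky(ctx, seed, curve, guinier):
    c = _get(ctx, curve, "ScatteringCurve")
    g = _get(ctx, guinier, "GuinierResult")
    x, y = saxs.dimensionless_kratky(c, g.Rg, g.I0)
    i = int(np.argmax(y))
    return (x, y), {"peak_x": float(x[i]), "peak_y": float(y[i])}


def _stage_mw(ctx, seed, curve, guinier):
    c = _get(ctx, curve, "ScatteringCurve")
    g = _get(ctx, guinier, "GuinierResult")
    return None, saxs.mw_from_curve(c, g)


def _stage_synth_structure(ctx, seed, n_residues=60, n_chains=2):
    m = synth.gen_fixture_structure(n_residues, n_chains, seed=seed)
    return m, {"n_atoms": m.n_atoms, "chains": m.chains()}


def _stage_synth_crosslinks(ctx, seed, structure, n_true=10, n_decoy=5,
                            fold_changes=None, replicate_cv=0.2):
    m = _get(ctx, structure, "StructureModel")
    df, truth = synth.gen_crosslink_table(m, n_true, n_decoy,
                                          fold_changes=fold_changes,
                                          replicate_cv=replicate_cv, seed=seed)
    ctx["_xl_schema"] = truth.params["schema"]
    return df, {"n_features": len(df), "truth": truth.params}


def _stage_classify_quant(ctx, seed, table, condition_a="control",
                          condition_b="rna", fold_threshold=2.0):
    df = _get(ctx, table, "crosslink table")
    feats = _features_from_df(df, ctx["_xl_schema"])
    qc = clms.classify_quant(feats, condition_a, condition_b, fold_threshold)
    ctx[f"_features_{table}"] = feats
    return qc, {"counts": qc.counts(), "threshold": fold_threshold}


def _features_from_df(df, schema):
    import tempfile, os
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        df.to_csv(fh, index=False)
        path = fh.name
    try:
        return clms.load_crosslinks(path, schema)
    finally:
        os.unlink(path)


def _stage_map_distances(ctx, seed, table, structure, cutoff=24.0):
    feats = ctx.get(f"_features_{table}") or _features_from_df(
        _get(ctx, table, "crosslink table"), ctx["_xl_schema"])
    m = _get(ctx, structure, "StructureModel")
    dt = clms.distance_table(feats, [m], cutoff=cutoff)
    return dt, {"n": len(dt), "n_satisfied": int(dt["satisfied"].sum()),
                "cutoff": cutoff}


def _stage_synth_variants(ctx, seed, protein_length=400, domains=None,
                          baseline_rate=0.2):
    domains = [tuple(d) for d in (domains or [])]
    vs, truth = synth.gen_variant_track(protein_length, domains, baseline_rate, seed)
    ctx["_variant_length"] = protein_length
    return vs, {"n_variants": len(vs), "truth": truth.params}


def _stage_depletion(ctx, seed, variants, domain):
    vs = _get(ctx, variants, "VariantSet")
    res = varcons.depletion_ratio(vs, tuple(domain), ctx["_variant_length"])
    return res, {"ratio": res.ratio, "v_d": res.v_d, "v_p": res.v_p, "ok": res.ok}


def _stage_synth_masses(ctx, seed, stoichiometries, m_protein=110.0, m_rna=34.6,
                        mass_sigma=8.0, n=2000):
    stoi = [((int(a), int(b)), float(f)) for (a, b), f in
            [(tuple(s[0]), s[1]) for s in stoichiometries]]
    ev, truth = synth.gen_mass_events(stoi, m_protein, m_rna, mass_sigma, n, seed)
    ctx["_mass_units"] = (m_protein, m_rna)
    return ev, {"n_events": len(ev), "truth": truth.params}


def _stage_fit_peaks(ctx, seed, events, n_components=None):
    ev = _get(ctx, events, "mass events")
    peaks = oligomer.fit_mass_peaks(ev, n_components, seed=seed)
    return peaks, {"peaks": [{"mass": p.mass, "width": p.width,
                              "abundance": p.abundance} for p in peaks]}


def _stage_assign_stoichiometry(ctx, seed, peaks, max_copies=5, tolerance=10.0):
    pk = _get(ctx, peaks, "MassPeak list")
    m_p, m_r = ctx.get("_mass_units", (110.0, 34.6))
    asg = oligomer.assign_stoichiometry(pk, m_p, m_r, max_copies, tolerance)
    return asg, {"assignments": [
        None if a is None else {"n_protein": a.n_protein, "n_rna": a.n_rna,
                                "residual": a.residual} for a in asg]}


def _stage_footprint(ctx, seed, observations):
    fi = oligomer.footprint_interval([tuple(o) for o in observations])
    return fi, {"low_bp": fi.low, "high_bp": fi.high, "empty": fi.empty}


def _stage_synth_beads(ctx, seed, n_strings=20, beads_per_string=5,
                       spacing_mu=165.0, spacing_sigma=10.0):
    pms, truth = synth.gen_bead_strings(n_strings, beads_per_string,
                                        spacing_mu, spacing_sigma, seed=seed)
    return pms, {"truth": truth.params}


def _stage_bead_stats(ctx, seed, measurements):
    pms = _get(ctx, measurements, "ParticleMeasurementSet")
    st = oligomer.bead_string_stats(pms)
    return st, {"interparticle": st.interparticle, "length": st.length,
                "width": st.width}


STAGE_REGISTRY = {
    "synth_curve": _stage_synth_curve,
    "guinier": _stage_guinier,
    "estimate_dmax": _stage_estimate_dmax,
    "kratky": _stage_kratky,
    "mw": _stage_mw,
    "synth_structure": _stage_synth_structure,
    "synth_crosslinks": _stage_synth_crosslinks,
    "classify_quant": _stage_classify_quant,
    "map_distances": _stage_map_distances,
    "synth_variants": _stage_synth_variants,
    "depletion": _stage_depletion,
    "synth_masses": _stage_synth_masses,
    "fit_peaks": _stage_fit_peaks,
    "assign_stoichiometry": _stage_assign_stoichiometry,
    "footprint": _stage_footprint,
    "synth_beads": _stage_synth_beads,
    "bead_stats": _stage_bead_stats,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a validated pipeline; returns the JSON-serializable report."""
    ctx: dict = {}
    report = {"config_hash": config.config_hash(), "seed": config.seed,
              "stages": {}}
    for name, kind, params in config.stages:
        func = STAGE_REGISTRY[kind]
        try:
            obj, summary = func(ctx, config.seed, **params)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} ({kind}) failed: {exc}") from exc
        ctx[name] = obj
        report["stages"][name] = {"stage": kind, **_jsonable(summary)}
    return report
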