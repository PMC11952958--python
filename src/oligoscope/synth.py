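"""Synthetic ground-truth data for every analysis stage.

Each generator emulates one class of experimental input — noisy scattering
curves, SEC frame stacks, fixture structures with crystallographic symmetry,
two-condition cross-link intensity tables with planted fold changes and
planted true/decoy distances, variant tracks with planted per-domain
depletion, mass-photometry event mixtures, and jittered bead-on-string
layouts — and returns the data together with a machine-readable truth record
holding the planted parameters.

Reproducibility: one global seed fans out to independent per-generator
streams via ``numpy.random.SeedSequence(seed, spawn_key=(crc32(name),))``,
so scenarios compose without correlated noise and every output is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import saxs
from .oligomer import ParticleMeasurementSet
from .structio import StructureModel
from .varcons import VariantSet

SPHERE_RG_FACTOR = np.sqrt(3.0 / 5.0)   # Rg of a uniform sphere = R·sqrt(3/5)


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of a global seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class TruthRecord:
    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------- scattering

def dumbbell_curve(q, radius: float, separation: float, i0: float = 1.0):
    """Two identical uniform spheres with centers ``separation`` apart.

    I(q) = 2·F(q)²·(1 + sin(qd)/(qd)), normalized to I(0)=i0.
    """
    x = np.asarray(q, float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(x > 0, 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3, 1.0)
        qd = np.asarray(q, float) * separation
        cross = np.where(qd > 0, np.sin(qd) / qd, 1.0)
    return i0 * 0.5 * amp ** 2 * (1.0 + cross)


def dumbbell_rg(radius: float, separation: float) -> float:
    """Rg² of two equal spheres = Rg_sphere² + (d/2)²."""
    return float(np.sqrt(0.6 * radius ** 2 + (separation / 2.0) ** 2))


def gen_curve(shape: str, params: dict, q=None, noise_rel: float = 0.01,
              noise_floor: float | None = None, seed: int = 0):
    """Synthetic scattering curve with Gaussian noise and a known truth record.

    ``shape``: 'sphere' (params: radius, i0), 'dumbbell' (radius, separation,
    i0) or 'structure' (model: StructureModel). σ(q) = max(rel·I(q), floor);
    the default floor is rel·I(0)·1e-3.
    """
    rng = stream(seed, f"curve:{shape}")
    q = np.arange(0.005, 0.305, 0.0025) if q is None else np.asarray(q, float)
    if shape == "sphere":
        R = float(params["radius"])
        i0 = float(params.get("i0", 1.0))
        I = saxs.sphere_curve(q, R, i0)
        truth = {"rg": R * SPHERE_RG_FACTOR, "dmax": 2 * R, "i0": i0, "radius": R}
    elif shape == "dumbbell":
        R, d = float(params["radius"]), float(params["separation"])
        i0 = float(params.get("i0", 1.0))
        I = dumbbell_curve(q, R, d, i0)
        truth = {"rg": dumbbell_rg(R, d), "dmax": 2 * R + d, "i0": i0,
                 "radius": R, "separation": d}
    elif shape == "structure":
        model: StructureModel = params["model"]
        base = saxs.debye_curve(model, q, bead=params.get("bead", "residue"))
        i0 = float(params.get("i0", base.I[0]))
        I = base.I * (i0 / base.I.max())
        from .structio import max_pairwise_distance
        truth = {"dmax": max_pairwise_distance(model), "i0": i0}
    else:
        raise ValueError(f"unknown shape {shape!r}")
    floor = noise_rel * max(I.max(), 1e-300) * 1e-3 if noise_floor is None else noise_floor
    sigma = np.maximum(noise_rel * np.abs(I), floor)
    I_noisy = I + rng.normal(0.0, sigma) if noise_rel > 0 else I.copy()
    curve = saxs.ScatteringCurve(q, I_noisy, sigma, {"shape": shape})
    return curve, TruthRecord(f"curve:{shape}", seed, {**truth, "noise_rel": noise_rel})


def gen_sec_frames(shape: str, params: dict, n_sample: int = 10, n_buffer: int = 10,
                   buffer_level: float = 0.05, noise_rel: float = 0.01, seed: int = 0):
    """SEC frame stack: buffer frames around a flat background, sample frames
    with the particle signal added. Returns (frames, buffer_ids, sample_ids, truth)."""
    rng = stream(seed, "sec_frames")
    clean, truth = gen_curve(shape, params, noise_rel=0.0, seed=seed)
    q = clean.q
    bg = buffer_level * clean.I.max() * np.ones_like(q)
    sigma = np.maximum(noise_rel * (clean.I + bg), 1e-3 * noise_rel * clean.I.max())
    frames = []
    for _ in range(n_buffer):
        frames.append(saxs.ScatteringCurve(q, bg + rng.normal(0, sigma), sigma))
    for _ in range(n_sample):
        frames.append(saxs.ScatteringCurve(q, clean.I + bg + rng.normal(0, sigma), sigma))
    truth.params["buffer_level"] = buffer_level
    return frames, list(range(n_buffer)), list(range(n_buffer, n_buffer + n_sample)), truth


# ---------------------------------------------------------------- structures

def gen_fixture_structure(n_residues: int = 60, n_chains: int = 2, seed: int = 0,
                          cell: tuple | None = None,
                          spacegroup_ops: list | None = None) -> StructureModel:
    """Compact Cα-only fixture 'protein': seeded self-avoiding-ish random walk.

    Consecutive Cα at 3.8 Å; the walk is biased back toward the centroid so
    the chain stays globular. Chains are labelled A, B, ...
    """
    rng = stream(seed, "fixture_structure")
    chains, resnums, xyz = [], [], []
    for ci in range(n_chains):
        origin = rng.normal(0, 8.0, 3)
        pos = origin.copy()
        for ri in range(n_residues):
            chains.append(chr(ord("A") + ci))
            resnums.append(ri + 1)
            xyz.append(pos.copy())
            step = rng.normal(0, 1.0, 3) - 0.08 * (pos - origin)
            step = 3.8 * step / np.linalg.norm(step)
            pos = pos + step
    n = len(xyz)
    return StructureModel(
        chain=np.array(chains),
        resnum=np.array(resnums, int),
        resname=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        xyz=np.array(xyz),
        occupancy=np.ones(n),
        cell=cell,
        symmetry_ops=spacegroup_ops,
    )


# ---------------------------------------------------------------- cross-links

def gen_crosslink_table(model: StructureModel, n_true: int = 10, n_decoy: int = 5,
                        conditions=("control", "rna"), fold_changes=None,
                        replicate_cv: float = 0.2, n_replicates: int = 3,
                        cutoff: float = 24.0, base_area: float = 1e6,
                        seed: int = 0):
    """Two-condition cross-link table with planted distances and fold changes.

    True links are sampled from Cα pairs ≤ ``cutoff`` Å, decoys from pairs
    beyond it. Replicate areas are log-normal around condition means set by
    the planted per-feature fold change (condition[1] over condition[0]);
    ``fold_changes`` is a list per feature (default all 1.0). Returns
    ``(DataFrame, truth)``; the frame has the schema the loader consumes.
    """
    rng = stream(seed, "crosslinks")
    ca = model.atom_name == "CA"
    idx = np.where(ca)[0]
    d = squareform(pdist(model.xyz[idx]))
    iu = np.triu_indices(len(idx), k=1)
    pair_d = d[iu]
    short = np.where(pair_d <= cutoff)[0]
    long = np.where(pair_d > cutoff)[0]
    if len(short) < n_true or len(long) < n_decoy:
        raise ValueError(
            f"not enough residue pairs: {len(short)} ≤cutoff (need {n_true}), "
            f"{len(long)} >cutoff (need {n_decoy})")
    pick_t = rng.choice(short, n_true, replace=False)
    pick_d = rng.choice(long, n_decoy, replace=False)
    picks = np.concatenate([pick_t, pick_d])
    is_true = np.array([True] * n_true + [False] * n_decoy)
    fold_changes = np.ones(len(picks)) if fold_changes is None else np.asarray(fold_changes, float)
    if len(fold_changes) != len(picks):
        raise ValueError("fold_changes must have one entry per feature")

    sdlog = np.sqrt(np.log(1.0 + replicate_cv ** 2))
    rows, truth_feats = [], []
    cond_a, cond_b = conditions
    for fi, (pi, fc) in enumerate(zip(picks, fold_changes)):
        a_i, b_i = idx[iu[0][pi]], idx[iu[1][pi]]
        mean_a = base_area
        mean_b = base_area * fc
        row = {
            "ProteinA": str(model.chain[a_i]), "ResidueA": int(model.resnum[a_i]),
            "ProteinB": str(model.chain[b_i]), "ResidueB": int(model.resnum[b_i]),
            "Charge": 3, "Modification": "",
        }
        for r in range(n_replicates):
            row[f"{cond_a}_{r + 1}"] = mean_a * rng.lognormal(-0.5 * sdlog ** 2, sdlog)
            row[f"{cond_b}_{r + 1}"] = mean_b * rng.lognormal(-0.5 * sdlog ** 2, sdlog)
        rows.append(row)
        truth_feats.append({
            "index": fi, "distance": float(pair_d[pi]), "is_true": bool(is_true[fi]),
            "fold_change": float(fc),
        })
    df = pd.DataFrame(rows)
    schema = {
        "protein_a": "ProteinA", "residue_a": "ResidueA",
        "protein_b": "ProteinB", "residue_b": "ResidueB",
        "charge": "Charge", "modification": "Modification",
        "conditions": {c: [f"{c}_{r + 1}" for r in range(n_replicates)] for c in conditions},
    }
    truth = TruthRecord("crosslinks", seed, {
        "features": truth_feats, "cutoff": cutoff, "replicate_cv": replicate_cv,
        "conditions": list(conditions), "schema": schema,
    })
    return df, truth


# ---------------------------------------------------------------- variants

def rate_factor_for_ratio(target_ratio: float, protein_length: int,
                          domain_length: int) -> float:
    """Rate multiplier that plants an *expected* V_d/V_p equal to ``target_ratio``.

    V_d/V_p compares the domain to the whole protein (domain included), so a
    rate multiplier f yields an expected ratio f·L/(f·L_d + (L−L_d)), not f
    itself. Inverting: f = t·(L−L_d)/(L − t·L_d).
    """
    L, Ld = protein_length, domain_length
    t = target_ratio
    if not (0 < t and t * Ld < L):
        raise ValueError("target ratio out of attainable range for this domain")
    return t * (L - Ld) / (L - t * Ld)


def gen_variant_track(protein_length: int, domains=None, baseline_rate: float = 0.2,
                      seed: int = 0):
    """Variant set with planted per-domain depletion.

    Per-residue variant counts are Poisson with rate baseline × factor inside
    each (label, start, end, factor) domain. Returns (VariantSet, truth); the
    truth record carries, for each domain, the analytically *expected*
    V_d/V_p under those rates (mean domain rate over mean whole-protein
    rate), which is the quantity the depletion analysis recovers. Use
    :func:`rate_factor_for_ratio` to plant a target ratio directly.
    """
    if baseline_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = stream(seed, "variants")
    rates = np.full(protein_length, baseline_rate)
    domains = domains or []
    for label, s, e, factor in domains:
        rates[s - 1:e] = baseline_rate * factor
    counts = rng.poisson(rates)
    recs = []
    for pos, c in enumerate(counts, start=1):
        for k in range(c):
            recs.append((pos, f"X{k + 1}", frozenset(), "synthetic"))
    vs = VariantSet.from_records("synthetic", recs)
    mean_rate = rates.mean()
    expected = [
        {"label": label,
         "expected_ratio": float(rates[s - 1:e].mean() / mean_rate) if mean_rate > 0 else np.nan}
        for label, s, e, factor in domains
    ]
    truth = TruthRecord("variants", seed, {
        "length": protein_length, "baseline_rate": baseline_rate,
        "domains": [list(d) for d in domains], "expected_ratios": expected,
        "total_variants": int(counts.sum()),
    })
    return vs, truth


# ---------------------------------------------------------------- masses

def gen_mass_events(stoichiometries, m_protein: float, m_rna: float,
                    mass_sigma: float = 8.0, n: int = 2000, seed: int = 0):
    """Mass-photometry events from a mixture of (n_protein, n_rna) species.

    ``stoichiometries``: list of ((np, nr), fraction); fractions must sum to 1.
    """
    fracs = np.array([f for _, f in stoichiometries], float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = stream(seed, "mass_events")
    means = np.array([np_ * m_protein + nr * m_rna for (np_, nr), _ in stoichiometries])
    comp = rng.choice(len(means), size=n, p=fracs)
    events = rng.normal(means[comp], mass_sigma)
    truth = TruthRecord("mass_events", seed, {
        "species": [{"n_protein": int(s[0]), "n_rna": int(s[1]),
                     "fraction": float(f), "mass": float(m)}
                    for (s, f), m in zip(stoichiometries, means)],
        "mass_sigma": mass_sigma, "n": n,
    })
    return events, truth


# ---------------------------------------------------------------- bead strings

def gen_bead_strings(n_strings: int = 20, beads_per_string: int = 5,
                     spacing_mu: float = 165.0, spacing_sigma: float = 10.0,
                     length_mu: float = 160.0, length_sigma: float = 15.0,
                     width_mu: float = 95.0, width_sigma: float = 10.0,
                     units: str = "angstrom", seed: int = 0):
    """Jittered collinear bead-on-string layouts (micrograph-annotation style)."""
    for v in (spacing_mu, length_mu, width_mu):
        if v <= 0:
            raise ValueError("scales must be positive")
    rng = stream(seed, "bead_strings")
    strings = []
    for _ in range(n_strings):
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        start = rng.uniform(0, 5000.0, 2)
        centers = [start]
        for _ in range(beads_per_string - 1):
            gap = max(rng.normal(spacing_mu, spacing_sigma), 1.0)
            centers.append(centers[-1] + gap * u)
        strings.append({
            "centers": np.array(centers),
            "lengths": np.maximum(rng.normal(length_mu, length_sigma, beads_per_string), 1.0),
            "widths": np.maximum(rng.normal(width_mu, width_sigma, beads_per_string), 1.0),
        })
    pms = ParticleMeasurementSet(strings, units)
    truth = TruthRecord("bead_strings", seed, {
        "spacing_mu": spacing_mu, "spacing_sigma": spacing_sigma,
        "length_mu": length_mu, "width_mu": width_mu,
        "n_strings": n_strings, "beads_per_string": beads_per_string,
    })
    return pms, truth
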