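"""Stoichiometry, footprint and oligomer geometry.

Covers the quantitative side of the oligomerization story: masses of protein
and dsRNA components, Gaussian-mixture detection of mass-photometry peaks,
integer (protein, RNA) composition assignment, the steric footprint interval
implied by maximal occupancy observations, construction of lateral oligomer
models with clash checks, and bead-on-string particle statistics from
annotated micrograph measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy.spatial import cKDTree

from .structio import StructureModel, concat_models

RNA_NT_MASS = 320.5        # Da per nucleotide residue, average (sequence-exact alternative: sum monomer masses)
A_FORM_RISE = 2.81         # Å per bp, A-form duplex helical rise
CLASH_CUTOFF = 2.5         # Å, heavy-atom clash threshold


@dataclass
class MassPeak:
    mass: float              # kDa
    width: float             # kDa (Gaussian sigma)
    abundance: float         # mixing fraction

    def __post_init__(self):
        if self.mass <= 0 or self.width < 0:
            raise ValueError("mass must be > 0 and width >= 0")


@dataclass
class StoichiometryAssignment:
    n_protein: int
    n_rna: int
    predicted_mass: float    # kDa
    residual: float          # kDa, signed (peak - predicted)
    within_tolerance: bool

    def __post_init__(self):
        if self.n_protein < 0 or self.n_rna < 0 or (self.n_protein == 0 and self.n_rna == 0):
            raise ValueError("copy numbers must be non-negative and not both zero")


@dataclass
class ParticleMeasurementSet:
    """Bead-on-string annotations: ordered bead centers plus per-bead size."""

    strings: list            # each: dict(centers=(n,2) array, lengths=(n,), widths=(n,))
    units: str = "angstrom"  # or "nm"

    def __post_init__(self):
        if self.units not in ("angstrom", "nm"):
            raise ValueError("units must be declared as 'angstrom' or 'nm'")
        for s in self.strings:
            if len(s["centers"]) < 1:
                raise ValueError("each string needs at least one bead")

    def scale(self) -> float:
        return 10.0 if self.units == "nm" else 1.0


def component_mass(protein_seq: str | None = None, rna_bp: int | None = None,
                   tag_seq: str = "", nt_mass: float = RNA_NT_MASS,
                   end_correction: float = 0.0) -> float:
    """Mass (kDa) of a protein chain or a dsRNA duplex.

    Protein: average-isotope mass from the one-letter sequence (free-chain
    convention, one water per chain), with an optional tag sequence appended.
    dsRNA: 2 × bp × ``nt_mass`` (default 320.5 Da/nt average) plus an
    ``end_correction`` in Da. Exactly one of protein_seq / rna_bp is required.
    """
    if (protein_seq is None) == (rna_bp is None):
        raise ValueError("give exactly one of protein_seq or rna_bp")
    if protein_seq is not None:
        seq = (protein_seq + tag_seq).upper()
        bad = sorted(set(seq) - set("ACDEFGHIKLMNPQRSTVWY"))
        if bad:
            raise ValueError(f"unknown residue letters: {bad}")
        return molecular_weight(seq, seq_type="protein") / 1000.0
    if rna_bp <= 0:
        raise ValueError("duplex length must be positive")
    return (2.0 * rna_bp * nt_mass + end_correction) / 1000.0


def fit_mass_peaks(events, n_components: int | None = None,
                   max_components: int = 6, seed: int = 0) -> list[MassPeak]:
    """Gaussian-mixture peak detection in a mass-photometry event list.

    ``n_components=None`` selects the component count in 1..max_components by
    BIC. Peaks are returned sorted by mass.
    """
    events = np.asarray(events, float).reshape(-1, 1)
    if events.size == 0:
        raise ValueError("no mass events supplied")
    from sklearn.mixture import GaussianMixture
    if n_components is None:
        if len(events) < 50:
            raise ValueError("auto peak count needs at least 50 events")
        best, best_bic = None, np.inf
        for k in range(1, max_components + 1):
            gm = GaussianMixture(k, random_state=seed, n_init=3).fit(events)
            bic = gm.bic(events)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        gm = best
    else:
        gm = GaussianMixture(n_components, random_state=seed, n_init=3).fit(events)
    if not gm.converged_:
        raise RuntimeError(f"mixture fit did not converge (k={gm.n_components})")
    order = np.argsort(gm.means_.ravel())
    return [MassPeak(float(gm.means_.ravel()[i]),
                     float(np.sqrt(gm.covariances_.ravel()[i])),
                     float(gm.weights_[i])) for i in order]


def assign_stoichiometry(peaks: list[MassPeak] | list[float], m_protein: float,
                         m_rna: float, max_copies: int = 5,
                         tolerance: float = 10.0) -> list[StoichiometryAssignment | None]:
    """Assign each mass peak an integer (n_protein, n_rna) composition.

    Enumerates all copy numbers up to ``max_copies``; the best assignment
    minimizes |predicted − peak|, ties broken by fewer total copies then fewer
    protein copies. Peaks with no composition within ``tolerance`` kDa yield
    None ("unassigned").
    """
    if m_protein <= 0 or m_rna <= 0:
        raise ValueError("component masses must be positive")
    out = []
    for pk in peaks:
        mass = pk.mass if isinstance(pk, MassPeak) else float(pk)
        best = None
        for np_ in range(max_copies + 1):
            for nr in range(max_copies + 1):
                if np_ == 0 and nr == 0:
                    continue
                pred = np_ * m_protein + nr * m_rna
                res = mass - pred
                key = (abs(res), np_ + nr, np_)
                if abs(res) <= tolerance and (best is None or key < best[0]):
                    best = (key, StoichiometryAssignment(np_, nr, pred, res, True))
        out.append(best[1] if best else None)
    return out


@dataclass
class FootprintInterval:
    low: float               # bp, exclusive
    high: float              # bp, inclusive
    empty: bool
    per_observation: list = field(default_factory=list)

    def midpoint(self):
        return None if self.empty else 0.5 * (self.low + self.high)

    def to_angstrom(self, rise: float = A_FORM_RISE):
        return None if self.empty else (self.low * rise, self.high * rise)


def pairs_from_complexes(n_complexes: int) -> int:
    """Complexes bind as sandwiching pairs across the duplex; pairs = ⌈n/2⌉."""
    return -(-n_complexes // 2)


def footprint_interval(observations) -> FootprintInterval:
    """Steric footprint per bound pair from maximal-occupancy observations.

    Each observation ``(L, k)`` — at most ``k`` pairs fit a duplex of ``L``
    bp — constrains the footprint f to L/(k+1) < f ≤ L/k. The result is the
    intersection over observations; inconsistent observations produce an
    empty interval with diagnostics, not an exception.
    """
    obs = [(float(L), int(k)) for L, k in observations]
    if not obs or any(k < 1 for _, k in obs):
        raise ValueError("need at least one observation with pairs >= 1")
    per = [{"duplex_bp": L, "max_pairs": k,
            "low": L / (k + 1), "high": L / k} for L, k in obs]
    low = max(p["low"] for p in per)
    high = min(p["high"] for p in per)
    return FootprintInterval(low=low, high=high, empty=low >= high,
                             per_observation=per)


@dataclass
class ClashReport:
    n_clashes: int
    min_intercopy_distance: float
    failed: bool             # identity/degenerate transform


def build_lateral_oligomer(unit: StructureModel, n_copies: int = 2,
                           rotation: np.ndarray | None = None,
                           translation: np.ndarray | None = None,
                           rise: float | None = None,
                           axis=(1.0, 0.0, 0.0),
                           clash_cutoff: float = CLASH_CUTOFF):
    """Lateral oligomer: n copies of a unit related by a repeated rigid step.

    The step is either an explicit (rotation, translation) or a pure ``rise``
    (Å) along ``axis``. Returns ``(assembly, ClashReport)`` where the clash
    report counts inter-copy heavy-atom pairs closer than ``clash_cutoff``
    and gives the minimal inter-copy distance. An identity step returns the
    assembly with the failure flag set.
    """
    if n_copies < 2:
        raise ValueError("need at least 2 copies")
    if rise is not None:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        rotation = np.eye(3)
        translation = rise * axis
    if rotation is None or translation is None:
        raise ValueError("give either (rotation, translation) or rise+axis")
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    if abs(np.linalg.det(rotation)) < 1e-12:
        raise ValueError("rotation must be invertible")

    copies = [unit]
    R, t = np.eye(3), np.zeros(3)
    for _ in range(n_copies - 1):
        R, t = rotation @ R, rotation @ t + translation
        copies.append(unit.transformed(R, t))

    heavy = unit.heavy_mask()
    n_clash, dmin = 0, np.inf
    for i in range(n_copies):
        tree = cKDTree(copies[i].xyz[heavy])
        for j in range(i + 1, n_copies):
            d, _ = tree.query(copies[j].xyz[heavy], k=1)
            dmin = min(dmin, float(d.min()))
            n_clash += int(np.sum(d < clash_cutoff))
    identity_step = np.allclose(rotation, np.eye(3)) and np.allclose(translation, 0.0)
    report = ClashReport(n_clashes=n_clash, min_intercopy_distance=dmin,
                         failed=identity_step or n_clash > 0)
    return concat_models(copies), report


@dataclass
class BeadStringStats:
    interparticle: dict      # mean/median/sd/n over pooled consecutive gaps (Å)
    length: dict
    width: dict


def _summary(x) -> dict:
    x = np.asarray(x, float)
    if x.size == 0:
        return {"mean": np.nan, "median": np.nan, "sd": np.nan, "n": 0}
    return {"mean": float(x.mean()), "median": float(np.median(x)),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0, "n": int(x.size)}


def bead_string_stats(measurements: ParticleMeasurementSet) -> BeadStringStats:
    """Pooled interparticle-distance, bead-length and bead-width statistics (Å).

    Consecutive center-to-center distances within each string are pooled;
    strings with a single bead contribute size statistics only.
    """
    s = measurements.scale()
    gaps, lengths, widths = [], [], []
    for st in measurements.strings:
        c = np.asarray(st["centers"], float) * s
        if len(c) >= 2:
            gaps.extend(np.linalg.norm(np.diff(c, axis=0), axis=1))
        lengths.extend(np.asarray(st["lengths"], float) * s)
        widths.extend(np.asarray(st["widths"], float) * s)
    return BeadStringStats(_summary(gaps), _summary(lengths), _summary(widths))
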