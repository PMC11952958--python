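"""Solution scattering analysis.

Implements the standard SEC-SAXS reduction and interpretation chain:

* frame averaging and solvent subtraction,
* Guinier analysis, I(q) ≈ I0·exp(-q²Rg²/3) at low q,
* the real-space pair-distance distribution P(r) by regularized indirect
  Fourier transform (non-negative, zero-anchored histogram basis with
  second-difference smoothing),
* D_max estimation by scanning the IFT over candidate maximum dimensions,
* dimensionless Kratky transforms,
* molecular weight via the volume-of-correlation invariant,
* coarse-grained theoretical curves from coordinates (Debye sum), and
* sparse multi-state fitting of candidate model curves to data.

Units: q in Å⁻¹, distances in Å, masses in kDa. Intensities are on an
arbitrary relative scale unless stated otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .structio import StructureModel

__all__ = [
    "ScatteringCurve", "GuinierResult", "PairDistribution", "MultiStateFit",
    "read_curve", "write_curve", "reduce_sec_frames", "guinier_fit",
    "pr_ift", "estimate_dmax", "dimensionless_kratky", "mw_from_curve",
    "pr_from_structure", "debye_curve", "multi_state_fit", "sphere_curve",
    "sphere_pr",
]


@dataclass
class ScatteringCurve:
    """One scattering profile: q (Å⁻¹, strictly increasing), I, σ."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.I = np.asarray(self.I, float)
        self.sigma = np.asarray(self.sigma, float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.q[-1] > 2.0:
            warnings.warn(
                "qmax > 2 Å⁻¹ — input may be in nm⁻¹; divide q by 10 if so"
            )

    def __len__(self):
        return len(self.q)


@dataclass
class GuinierResult:
    Rg: float
    I0: float
    q_range: tuple[float, float]
    qmin_rg: float
    qmax_rg: float
    n_points: int
    residual_rms: float
    ok: bool = True
    message: str = ""


@dataclass
class PairDistribution:
    """P(r) on a uniform r grid from 0 to Dmax, zero-anchored, non-negative."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    alpha: float
    chi2: float

    def i0(self) -> float:
        """Forward-scattering intensity implied by P(r): I(0) = 4π∫p dr."""
        return float(4.0 * np.pi * np.trapezoid(self.p, self.r))

    def rg(self) -> float:
        """Real-space radius of gyration: Rg² = ∫r²p dr / (2∫p dr)."""
        m0 = np.trapezoid(self.p, self.r)
        m2 = np.trapezoid(self.p * self.r**2, self.r)
        return float(np.sqrt(m2 / (2.0 * m0)))


@dataclass
class MultiStateFit:
    indices: tuple[int, ...]
    weights: np.ndarray
    scale: float
    chi2: float
    per_size: dict = field(default_factory=dict)  # size -> (indices, weights, chi2)
    selected_size: int = 0


# ---------------------------------------------------------------- I/O

def read_curve(path, metadata: dict | None = None) -> ScatteringCurve:
    """Read a whitespace-delimited 3-column (q, I, σ) text file.

    '#' comments and non-numeric header lines are tolerated.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                vals = [float(x) for x in parts[:3]]
            except ValueError:
                continue
            if len(vals) == 2:
                vals.append(0.0)
            if len(vals) >= 3:
                rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no numeric (q, I, sigma) rows found")
    arr = np.array(rows, float)
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], metadata or {})


def write_curve(curve: ScatteringCurve, path) -> None:
    header = "q(1/A) I sigma"
    np.savetxt(path, np.column_stack([curve.q, curve.I, curve.sigma]), header=header)


# ---------------------------------------------------------------- reduction

def reduce_sec_frames(frames: list[ScatteringCurve], buffer_ids, sample_ids):
    """Average sample frames, average buffer frames, subtract.

    σ is propagated in quadrature divided by frame counts. Also returns the
    per-frame total-intensity elution profile (sum of I over q per frame).

    Returns
    -------
    (ScatteringCurve, np.ndarray)
        The subtracted curve and the elution profile over all frames.
    """
    buffer_ids, sample_ids = list(buffer_ids), list(sample_ids)
    if not buffer_ids or not sample_ids:
        raise ValueError("buffer and sample frame sets must be non-empty")
    if set(buffer_ids) & set(sample_ids):
        raise ValueError("buffer and sample frame sets must be disjoint")
    q0 = frames[0].q
    for f in frames:
        if len(f.q) != len(q0) or not np.allclose(f.q, q0, rtol=0, atol=1e-12):
            raise ValueError("frames are not on a common q grid (no silent interpolation)")

    def _mean(ids):
        I = np.mean([frames[i].I for i in ids], axis=0)
        var = np.sum([frames[i].sigma ** 2 for i in ids], axis=0) / len(ids) ** 2
        return I, var

    Is, vs = _mean(sample_ids)
    Ib, vb = _mean(buffer_ids)
    out = ScatteringCurve(q0, Is - Ib, np.sqrt(vs + vb),
                          {"n_sample": len(sample_ids), "n_buffer": len(buffer_ids)})
    elution = np.array([f.I.sum() for f in frames])
    return out, elution


# ---------------------------------------------------------------- Guinier

def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 100) -> GuinierResult:
    """Weighted Guinier fit of ln I vs q² on the largest self-consistent low-q window.

    The window [q_min, q_max] is iterated so that q_max·Rg ≤ ``qrg_limit``.
    """
    pos = curve.I > 0
    q, I = curve.q[pos], curve.I[pos]
    sig = np.where(curve.sigma[pos] > 0, curve.sigma[pos], np.median(curve.sigma[pos][curve.sigma[pos] > 0]) if (curve.sigma[pos] > 0).any() else 1.0)

    def _fit(n):
        x, y = q[:n] ** 2, np.log(I[:n])
        w = (I[:n] / sig[:n]) ** 2  # var(ln I) = (sigma/I)^2
        W = np.sum(w)
        xb, yb = np.sum(w * x) / W, np.sum(w * y) / W
        sxx = np.sum(w * (x - xb) ** 2)
        if sxx == 0:
            return None
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        intercept = yb - slope * xb
        return slope, intercept

    n = len(q)
    for _ in range(max_iter):
        if n < min_points:
            return GuinierResult(np.nan, np.nan, (np.nan, np.nan), np.nan, np.nan, 0,
                                 np.nan, ok=False,
                                 message="fewer than min_points in a consistent Guinier window")
        res = _fit(n)
        if res is None or res[0] >= 0:
            return GuinierResult(np.nan, np.nan, (q[0], q[n - 1]), np.nan, np.nan, n,
                                 np.nan, ok=False,
                                 message="non-negative Guinier slope (rising or flat low-q)")
        slope, intercept = res
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        if n_new >= n:
            break
        n = n_new
    slope, intercept = _fit(n)
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    resid = np.log(I[:n]) - (intercept + slope * q[:n] ** 2)
    return GuinierResult(
        Rg=rg, I0=i0, q_range=(float(q[0]), float(q[n - 1])),
        qmin_rg=float(q[0] * rg), qmax_rg=float(q[n - 1] * rg),
        n_points=n, residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


# ---------------------------------------------------------------- IFT / P(r)

def _ift_matrices(q: np.ndarray, dmax: float, n_bins: int):
    r = np.linspace(0.0, dmax, n_bins)
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    A = 4.0 * np.pi * dr * K          # I(q) = A @ p, trapezoid ≈ rectangle on uniform grid
    return r, dr, A


def _second_difference(n_free: int) -> np.ndarray:
    """Second-difference operator on the full p vector with zero endpoints.

    Acting on the n_free interior unknowns; curvature rows at the two
    boundaries see the implicit zeros, which pins p smoothly to 0 at r=0 and
    r=Dmax.
    """
    n_full = n_free + 2
    D = np.zeros((n_full - 2, n_full))
    for i in range(n_full - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D[:, 1:-1]


def pr_ift(curve: ScatteringCurve, dmax: float, alpha: float | None = None,
           n_bins: int = 101) -> PairDistribution:
    """P(r) by regularized indirect Fourier transform.

    Solves min ‖(I − A·p)/σ‖² + α‖D₂p‖² subject to p ≥ 0 and p(0)=p(Dmax)=0
    on a uniform ``n_bins``-point r grid, with A the sin(qr)/(qr) histogram
    kernel. ``alpha=None`` selects α by the L-curve corner over a log grid.
    """
    if alpha is not None and alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(curve.sigma <= 0):
        raise ValueError("curve must carry positive uncertainties for IFT")
    if dmax < 2.0 * np.pi / curve.q[-1]:
        warnings.warn("Dmax below the resolution limit 2π/qmax; result will be unstable")
    if alpha is None:
        alpha = select_alpha(curve, dmax, n_bins=n_bins)

    r, dr, A = _ift_matrices(curve.q, dmax, n_bins)
    Ai = A[:, 1:-1]                       # endpoint bins pinned to zero
    Aw = Ai / curve.sigma[:, None]
    yw = curve.I / curve.sigma
    D2 = _second_difference(Ai.shape[1])
    # scale-free regularization: alpha multiplies the ratio of operator norms
    lam = np.sqrt(alpha) * np.linalg.norm(Aw) / max(np.linalg.norm(D2), 1e-300)
    M = np.vstack([Aw, lam * D2])
    b = np.concatenate([yw, np.zeros(D2.shape[0])])
    p_free, _ = nnls(M, b)
    p = np.zeros(n_bins)
    p[1:-1] = p_free
    resid = (curve.I - Ai @ p_free) / curve.sigma
    chi2 = float(np.sum(resid ** 2) / max(len(curve) - 1, 1))
    return PairDistribution(r=r, p=p, dmax=float(dmax), alpha=float(alpha), chi2=chi2)


def select_alpha(curve: ScatteringCurve, dmax: float, n_bins: int = 101,
                 grid=None) -> float:
    """L-curve corner choice of the smoothing weight α.

    Scans log-spaced α, records (log residual norm, log seminorm) and returns
    the point of maximum curvature (maximum distance from the chord between
    the endpoints of the L-curve).
    """
    grid = np.logspace(-6, 2, 9) if grid is None else np.asarray(grid, float)
    r, dr, A = _ift_matrices(curve.q, dmax, n_bins)
    Ai = A[:, 1:-1]
    Aw = Ai / curve.sigma[:, None]
    yw = curve.I / curve.sigma
    D2 = _second_difference(Ai.shape[1])
    norm_ratio = np.linalg.norm(Aw) / max(np.linalg.norm(D2), 1e-300)
    pts = []
    for a in grid:
        lam = np.sqrt(a) * norm_ratio
        M = np.vstack([Aw, lam * D2])
        b = np.concatenate([yw, np.zeros(D2.shape[0])])
        p, _ = nnls(M, b)
        rn = np.linalg.norm(Aw @ p - yw)
        sn = np.linalg.norm(D2 @ p)
        pts.append((np.log10(max(rn, 1e-300)), np.log10(max(sn, 1e-300))))
    pts = np.array(pts)
    a0, a1 = pts[0], pts[-1]
    chord = a1 - a0
    nc = np.linalg.norm(chord)
    if nc == 0:
        return float(grid[len(grid) // 2])
    # distance from chord; corner = farthest point
    rel = pts - a0
    d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / nc
    return float(grid[int(np.argmax(d))])


def estimate_dmax(curve: ScatteringCurve, scan_grid, alpha: float | None = None,
                  tol_factor: float = 1.05, n_bins: int = 101):
    """Scan candidate Dmax values and pick the smallest acceptable one.

    A candidate qualifies when its constrained-fit χ² is within ``tol_factor``
    of the scan minimum and the unconstrained (sign-free) smoothed solution is
    non-negative near Dmax within 5% of its own peak. Returns
    ``(dmax, PairDistribution, scan_table)``; on failure dmax is None and the
    scan table carries the diagnostics.
    """
    scan_grid = np.asarray(sorted(scan_grid), float)
    if alpha is None:
        alpha = select_alpha(curve, float(scan_grid[len(scan_grid) // 2]), n_bins=n_bins)
    fits, tail_ok = [], []
    for dm in scan_grid:
        pd = pr_ift(curve, dm, alpha=alpha, n_bins=n_bins)
        fits.append(pd)
        tail_ok.append(_unconstrained_tail_ok(curve, dm, alpha, n_bins))
    chi2 = np.array([f.chi2 for f in fits])
    best = chi2.min()
    table = [{"dmax": float(dm), "chi2": float(c), "tail_ok": bool(t)}
             for dm, c, t in zip(scan_grid, chi2, tail_ok)]
    for i, dm in enumerate(scan_grid):
        if chi2[i] <= tol_factor * best and tail_ok[i]:
            return float(dm), fits[i], table
    return None, None, table


def _unconstrained_tail_ok(curve, dmax, alpha, n_bins, frac: float = 0.05) -> bool:
    r, dr, A = _ift_matrices(curve.q, dmax, n_bins)
    Ai = A[:, 1:-1]
    Aw = Ai / curve.sigma[:, None]
    yw = curve.I / curve.sigma
    D2 = _second_difference(Ai.shape[1])
    lam = np.sqrt(alpha) * np.linalg.norm(Aw) / max(np.linalg.norm(D2), 1e-300)
    M = np.vstack([Aw, lam * D2])
    b = np.concatenate([yw, np.zeros(D2.shape[0])])
    p, *_ = np.linalg.lstsq(M, b, rcond=None)
    tail = p[-max(2, n_bins // 20):]
    return bool(tail.min() >= -frac * max(p.max(), 1e-300))


# ---------------------------------------------------------------- transforms

def dimensionless_kratky(curve: ScatteringCurve, rg: float, i0: float):
    """(qRg, (qRg)²·I/I0) — compactness diagnostic; no smoothing applied."""
    if rg <= 0 or i0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    x = curve.q * rg
    y = x ** 2 * curve.I / i0
    return x, y


# Rambo–Tainer volume-of-correlation mass law for proteins:
#   Vc = I(0) / ∫ q·I(q) dq,  QR = Vc²/Rg,  MW(Da) = QR / 0.1231
VC_PROTEIN_CONSTANT = 0.1231
VC_QMAX = 0.3  # Å⁻¹, integration cutoff of the published calibration

# For an ideal uniform sphere the law has a closed form: ∫x·Φ²(x)dx = 9/4, so
# Vc = 4R²/9, QR = (4R²/9)²/(R√(3/5)) and MW(Da) = R³/0.4827. Equating this to
# (4π/3)R³/v gives the sphere-equivalent apparent specific volume of the
# protein calibration, v ≈ 2.02 Å³/Da (hydrated envelope, not dry volume).
VC_SPHERE_APPARENT_VOLUME = (4.0 * np.pi / 3.0) * (
    (9.0 / 4.0) ** 2 * np.sqrt(0.6) * VC_PROTEIN_CONSTANT)


def sphere_radius_for_mass(mw_kda: float,
                           volume_per_da: float = VC_SPHERE_APPARENT_VOLUME) -> float:
    """Radius (Å) of the uniform sphere representing a protein of ``mw_kda``.

    Default volume convention is the Vc-calibration-consistent apparent
    volume (see :data:`VC_SPHERE_APPARENT_VOLUME`).
    """
    V = mw_kda * 1000.0 * volume_per_da
    return (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)


def mw_from_curve(curve: ScatteringCurve, guinier: GuinierResult,
                  method: str = "vc", i0_per_kda: float | None = None,
                  q_cutoff: float = VC_QMAX) -> dict:
    """Molecular weight estimate from a scattering curve.

    ``method='vc'`` (default): the volume-of-correlation power law for
    proteins, scale-invariant. ``method='absolute_i0'``: MW = I0 / i0_per_kda
    for data on an absolute (calibrated) scale.

    Returns a dict with the estimate (kDa), the method and every constant used.
    """
    if not guinier.ok:
        raise ValueError("valid Guinier result required")
    if method == "absolute_i0":
        if not i0_per_kda or i0_per_kda <= 0:
            raise ValueError("absolute_i0 mode needs a positive i0_per_kda calibration")
        return {"mw_kda": guinier.I0 / i0_per_kda, "method": "absolute_i0",
                "i0_per_kda": i0_per_kda}
    if method != "vc":
        raise ValueError(f"unknown method {method!r}")
    sel = curve.q <= q_cutoff
    q, I = curve.q[sel], curve.I[sel]
    coverage = float(q[-1] / q_cutoff) if len(q) else 0.0
    if coverage < 0.9:
        warnings.warn(f"q-range covers only {coverage:.0%} of the Vc cutoff {q_cutoff} Å⁻¹")
    # extend 0..qmin with the Guinier model
    q_lo = np.linspace(0, q[0], 50)
    I_lo = guinier.I0 * np.exp(-(q_lo * guinier.Rg) ** 2 / 3.0)
    integral = np.trapezoid(q_lo * I_lo, q_lo) + np.trapezoid(q * I, q)
    vc = guinier.I0 / integral
    qr = vc ** 2 / guinier.Rg
    mw_kda = qr / VC_PROTEIN_CONSTANT / 1000.0
    return {
        "mw_kda": float(mw_kda), "method": "vc", "vc": float(vc), "qr": float(qr),
        "constant": VC_PROTEIN_CONSTANT, "q_cutoff": q_cutoff,
        "note": "protein power law; underestimates protein-RNA complexes",
    }


# ---------------------------------------------------------------- from coordinates

def pr_from_structure(model: StructureModel, bin_width: float = 1.0,
                      include_hydrogens: bool = False) -> PairDistribution:
    """Normalized pair-distance histogram of a model; Dmax is the exact maximum."""
    sel = model.heavy_mask() if not include_hydrogens else np.ones(model.n_atoms, bool)
    pts = model.xyz[sel]
    if len(pts) < 2:
        raise ValueError("need at least 2 atoms")
    from scipy.spatial.distance import pdist
    d = pdist(pts)
    dmax = float(d.max())
    n_bins = max(int(np.ceil(dmax / bin_width)) + 1, 2)
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    hist, _ = np.histogram(d, bins=edges)
    r = 0.5 * (edges[:-1] + edges[1:])
    p = hist / (hist.sum() * bin_width)
    return PairDistribution(r=r, p=p, dmax=dmax, alpha=0.0, chi2=0.0)


def _bead_coordinates(model: StructureModel, bead: str = "residue") -> np.ndarray:
    if bead == "atom":
        return model.xyz[model.heavy_mask()]
    coords = []
    for ch, rn in model.residues():
        mask = (model.chain == ch) & (model.resnum == rn)
        ca = mask & (model.atom_name == "CA")
        coords.append(model.xyz[ca][0] if ca.any() else model.xyz[mask].mean(axis=0))
    return np.array(coords)


def debye_curve(model: StructureModel, q: np.ndarray, bead: str = "residue",
                form_factor: float = 1.0) -> ScatteringCurve:
    """Coarse-grained Debye curve: I(q) = ΣᵢΣⱼ f² sin(q dᵢⱼ)/(q dᵢⱼ).

    One bead per residue at the Cα (residue centroid when Cα is absent), or
    one per heavy atom with ``bead='atom'``. Constant form factor.
    """
    q = np.asarray(q, float)
    pts = _bead_coordinates(model, bead)
    n = len(pts)
    from scipy.spatial.distance import pdist
    I = np.full(len(q), float(n) * form_factor ** 2)
    if n > 1:
        d = pdist(pts)
        qd = np.outer(q, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qd > 0, np.sin(qd) / qd, 1.0)
        I = form_factor ** 2 * (n + 2.0 * sinc.sum(axis=1))
    return ScatteringCurve(q, I, np.full(len(q), 1e-6 * max(I.max(), 1.0)),
                           {"bead": bead, "n_beads": n})


# ---------------------------------------------------------------- analytic shapes

def sphere_curve(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Intensity of a uniform sphere: I = I0·[3(sin x − x cos x)/x³]², x = qR."""
    x = np.asarray(q, float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(x > 0, 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3, 1.0)
    return i0 * amp ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Unnormalized P(r) of a uniform sphere of radius R (Dmax = 2R)."""
    r = np.asarray(r, float)
    x = r / (2.0 * radius)
    p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    return np.where((r >= 0) & (r <= 2 * radius), p, 0.0)


# ---------------------------------------------------------------- multi-state

def _nnls_mixture(y, sig, comps):
    Aw = (comps / sig).T
    w, _ = nnls(Aw, y / sig)
    resid = (y - comps.T @ w) / sig
    chi2 = float(np.sum(resid ** 2) / max(len(y) - 1, 1))
    return w, chi2


def multi_state_fit(exp: ScatteringCurve, candidates: list[ScatteringCurve],
                    max_states: int = 3, rel_tol: float = 0.05) -> MultiStateFit:
    """Sparse mixture fit of candidate model curves to an experimental curve.

    For every candidate subset of size ≤ ``max_states`` solves non-negative
    coefficients minimizing reduced χ² (N−1 degrees of freedom, the FoXS
    convention); the global scale is the coefficient sum and the weights their
    normalization. Reports the best subset per size and selects the smallest
    size whose χ² is within ``rel_tol`` of the global best.
    """
    if max_states > len(candidates):
        warnings.warn("max_states exceeds candidate count; clamping")
        max_states = len(candidates)
    comps = []
    for c in candidates:
        if len(c.q) != len(exp.q) or not np.allclose(c.q, exp.q):
            warnings.warn("candidate resampled onto the experimental q grid")
            comps.append(np.interp(exp.q, c.q, c.I))
        else:
            comps.append(c.I)
    comps = np.asarray(comps)
    per_size: dict[int, tuple] = {}
    for k in range(1, max_states + 1):
        best = None
        for subset in itertools.combinations(range(len(candidates)), k):
            w, chi2 = _nnls_mixture(exp.I, exp.sigma, comps[list(subset)])
            if best is None or chi2 < best[2]:
                best = (subset, w, chi2)
        per_size[k] = best
    global_best = min(v[2] for v in per_size.values())
    # absolute slack keeps degenerate perfect fits (chi2 ~ 0) from inflating size
    sel = min(k for k, v in per_size.items()
              if v[2] <= (1 + rel_tol) * global_best + 1e-9)
    subset, w, chi2 = per_size[sel]
    scale = float(w.sum())
    weights = w / scale if scale > 0 else w
    return MultiStateFit(indices=tuple(subset), weights=weights, scale=scale,
                         chi2=chi2, per_size=per_size, selected_size=sel)
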