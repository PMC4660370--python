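"""Small-angle X-ray scattering analysis chain.

Implements the standard solution-scattering toolbox for deciding the
oligomeric state of a particle from its curve I(q):

* concentration normalization and extrapolation to infinite dilution,
* Guinier fit  ln I = ln I0 - q² Rg² / 3  with automatic low-q window,
* pair-distance distribution p(r) by regularized indirect Fourier
  transform (smoothness-penalized non-negative least squares),
* Dmax estimation from the decay of p(r),
* Porod invariant Q = ∫ q² I dq and Porod volume Vp = 2π² I0 / Q with the
  empirical 0.6 Da·Å⁻³ volume-to-mass conversion,
* Debye-equation theoretical profiles from coarse bead models,
* tetramer/octamer classification from the mass estimate.

q is in Å⁻¹ and distances in Å throughout.  Intensities are arbitrary
units; every derived structural quantity is invariant under I -> c·I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize, stats

from .exceptions import EstimationError, InvalidParameterError, ValidationError

__all__ = [
    "POROD_MASS_DA_PER_A3",
    "ScatteringCurve",
    "GuinierResult",
    "PofR",
    "PorodResult",
    "BeadModel",
    "OligomerState",
    "OligomerCall",
    "extrapolate_infinite_dilution",
    "guinier_fit",
    "ift_pofr",
    "estimate_dmax",
    "porod_volume",
    "mw_from_porod",
    "sphere_form_factor",
    "debye_profile",
    "fit_profile_scale",
    "classify_oligomer",
]

#: Empirical Porod-volume to mass conversion for globular proteins.
POROD_MASS_DA_PER_A3 = 0.6

#: Guinier validity limit q·Rg for globular particles.
QRG_MAX = 1.3


@dataclass
class ScatteringCurve:
    """One subtracted scattering curve (q, I, σ)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    concentration: Optional[float] = None  # mg/mL

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValidationError("q and intensity must be 1-D, equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing and > 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma must match q")
            if np.any(self.sigma <= 0):
                raise ValidationError("sigma must be > 0 where present")

    def scaled(self, factor: float) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(), self.intensity * factor,
            None if self.sigma is None else self.sigma * factor,
            self.concentration,
        )


@dataclass
class GuinierResult:
    Rg: float
    Rg_se: float
    I0: float
    I0_se: float
    window: Tuple[float, float]  # (q_min, q_max) used
    n_points: int
    qRg_max: float


@dataclass
class PofR:
    r: np.ndarray
    p: np.ndarray
    Dmax: float
    Rg_pr: float
    I0_pr: float
    lambda_reg: float


@dataclass
class PorodResult:
    Q_invariant: float
    Vp: float  # Å³
    mw_est_kDa: float  # integer-rounded
    flags: List[str] = field(default_factory=list)


class OligomerState(str, Enum):
    TETRAMER = "tetramer"
    OCTAMER = "octamer"
    OTHER = "other"


@dataclass
class OligomerCall:
    state: OligomerState
    mw_est_kDa: float
    mw_ratio: float  # mw_est / tetramer mass


@dataclass
class BeadModel:
    """Coarse-grained model: spheres with volume-proportional weights."""

    centers: np.ndarray  # (N, 3) Å
    radii: np.ndarray  # (N,) Å
    scattering_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.centers.shape != (len(self.radii), 3):
            raise ValidationError("centers must be (N, 3) matching radii")
        if np.any(self.radii <= 0) or not np.all(np.isfinite(self.centers)):
            raise ValidationError("radii must be > 0 and coordinates finite")
        if self.scattering_weights is None:
            self.scattering_weights = (4.0 / 3.0) * np.pi * self.radii ** 3
        else:
            self.scattering_weights = np.asarray(self.scattering_weights,
                                                 dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.radii)

    def geometric_dmax(self) -> float:
        d = np.linalg.norm(self.centers[:, None] - self.centers[None], axis=-1)
        return float((d + self.radii[:, None] + self.radii[None, :]).max())

    def exact_rg(self) -> float:
        """Volume-weighted radius of gyration of the sphere assembly."""
        w = self.scattering_weights
        com = (w[:, None] * self.centers).sum(0) / w.sum()
        d2 = ((self.centers - com) ** 2).sum(1)
        return float(np.sqrt((w * (0.6 * self.radii ** 2 + d2)).sum() / w.sum()))

    def total_volume(self) -> float:
        return float((4.0 / 3.0) * np.pi * (self.radii ** 3).sum())

    def scaled(self, factor: float) -> "BeadModel":
        """Uniform dilation: all coordinates and radii scaled by ``factor``."""
        return BeadModel(self.centers * factor, self.radii * factor)

    def rotated_z(self, angle_rad: float) -> "BeadModel":
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return BeadModel(self.centers @ R.T, self.radii.copy(),
                         self.scattering_weights.copy())


# ---------------------------------------------------------------------------
# concentration series


def extrapolate_infinite_dilution(series: Sequence[ScatteringCurve]
                                  ) -> ScatteringCurve:
    """Extrapolate a concentration series to infinite dilution.

    Normalizes each curve by its concentration and, per q, fits
    I(q)/c = a(q) + b(q)·c, returning the intercept a(q) with the
    propagated standard error as sigma.  With a single curve the
    normalized curve is returned unchanged (flagged via ``concentration``
    left set).
    """
    if not series:
        raise ValidationError("empty concentration series")
    for c in series:
        if c.concentration is None or c.concentration <= 0:
            raise ValidationError("every curve needs a positive concentration")
    concs = np.array([c.concentration for c in series])
    if len(np.unique(concs)) == 1:
        ref = series[0]
        return ScatteringCurve(
            ref.q.copy(), ref.intensity / ref.concentration,
            None if ref.sigma is None else ref.sigma / ref.concentration,
            concentration=ref.concentration,
        )
    # common q grid: intersection range on the first curve's grid
    qlo = max(c.q[0] for c in series)
    qhi = min(c.q[-1] for c in series)
    q = series[0].q[(series[0].q >= qlo) & (series[0].q <= qhi)]
    Y = np.empty((len(series), len(q)))
    W = np.ones_like(Y)
    for i, cur in enumerate(series):
        y = np.interp(q, cur.q, cur.intensity) / cur.concentration
        Y[i] = y
        if cur.sigma is not None:
            s = np.interp(q, cur.q, cur.sigma) / cur.concentration
            W[i] = 1.0 / s ** 2
    x = concs[:, None] * np.ones_like(Y)
    # weighted straight-line intercept per q column
    Sw = W.sum(0)
    Sx = (W * x).sum(0)
    Sy = (W * Y).sum(0)
    Sxx = (W * x * x).sum(0)
    Sxy = (W * x * Y).sum(0)
    delta = Sw * Sxx - Sx ** 2
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    var_intercept = Sxx / delta
    return ScatteringCurve(q, intercept, np.sqrt(var_intercept),
                           concentration=None)


# ---------------------------------------------------------------------------
# Guinier analysis


def _runs_test_p(residuals: np.ndarray) -> float:
    """Two-sided Wald–Wolfowitz runs-test p-value on residual signs."""
    signs = residuals > 0
    n1 = int(signs.sum())
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 1 + 2 * n1 * n2 / (n1 + n2)
    var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
           / ((n1 + n2) ** 2 * (n1 + n2 - 1)))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return 2 * stats.norm.sf(abs(z))


def guinier_fit(curve: ScatteringCurve, qrg_max: float = QRG_MAX,
                min_points: int = 8, runs_p_min: float = 0.01
                ) -> GuinierResult:
    """Guinier fit with automatic low-q window selection.

    Iteratively selects the largest window with q·Rg ≤ ``qrg_max`` (≥
    ``min_points`` points), then shrinks from the high-q end until the
    residuals show no systematic trend (runs test at ``runs_p_min``).
    """
    q, I = curve.q, curve.intensity
    pos = I > 0
    q, I = q[pos], I[pos]
    sig = curve.sigma[pos] if curve.sigma is not None else None
    if len(q) < min_points:
        raise EstimationError("too few positive-intensity points",
                              details={"n": int(len(q))})
    y = np.log(I)
    w = (I / sig) ** 2 if sig is not None else np.ones_like(y)  # 1/var(ln I)
    scan = []

    def wfit(n):
        x2 = q[:n] ** 2
        W = w[:n]
        Sw, Sx = W.sum(), (W * x2).sum()
        Sy, Sxx = (W * y[:n]).sum(), (W * x2 * x2).sum()
        Sxy = (W * x2 * y[:n]).sum()
        delta = Sw * Sxx - Sx ** 2
        slope = (Sw * Sxy - Sx * Sy) / delta
        inter = (Sxx * Sy - Sx * Sxy) / delta
        var_slope, var_inter = Sw / delta, Sxx / delta
        return slope, inter, var_slope, var_inter

    # iterate window so that q_max * Rg <= qrg_max
    n = min(len(q), max(min_points, 10))
    rg = None
    for _ in range(60):
        slope, inter, vs, vi = wfit(n)
        if slope >= 0:
            n = max(min_points, n - 1)
            continue
        rg = math.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, qrg_max / rg, side="right"))
        n_new = min(max(n_new, min_points), len(q))
        if n_new == n:
            break
        n = n_new
    if rg is None:
        raise EstimationError("no admissible Guinier window (slope ≥ 0)",
                              details={"scan": scan})

    # shrink until residuals pass the runs test
    while n >= min_points:
        slope, inter, vs, vi = wfit(n)
        if slope >= 0:
            break
        rg = math.sqrt(-3.0 * slope)
        resid = y[:n] - (inter + slope * q[:n] ** 2)
        # negligible residuals (exact model): no trend to detect
        p_runs = 1.0 if float(np.abs(resid).max()) < 1e-10 else _runs_test_p(resid)
        scan.append((n, rg, p_runs))
        if p_runs >= runs_p_min and q[n - 1] * rg <= qrg_max * 1.0001:
            rg_se = 3.0 / (2.0 * rg) * math.sqrt(vs)
            I0 = math.exp(inter)
            return GuinierResult(
                Rg=rg, Rg_se=rg_se, I0=I0, I0_se=I0 * math.sqrt(vi),
                window=(float(q[0]), float(q[n - 1])), n_points=n,
                qRg_max=float(q[n - 1] * rg),
            )
        n -= 1
    raise EstimationError("no admissible Guinier window", details={"scan": scan})


# ---------------------------------------------------------------------------
# indirect Fourier transform


def _ift_system(q, I, sigma, Dmax, n_r):
    r = np.linspace(0.0, Dmax, n_r)
    dr = r[1] - r[0]
    rj = r[1:-1]  # interior nodes; endpoints pinned to zero
    qr = np.outer(q, rj)
    kern = np.where(qr == 0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
    A = 4.0 * np.pi * dr * kern
    w = 1.0 / sigma if sigma is not None else np.ones_like(q)
    Aw = A * w[:, None]
    Iw = I * w
    # curvature operator with implicit zero endpoints
    m = len(rj)
    D = np.zeros((m, m))
    idx = np.arange(m)
    D[idx, idx] = -2.0
    D[idx[:-1], idx[:-1] + 1] = 1.0
    D[idx[1:], idx[1:] - 1] = 1.0
    return r, Aw, Iw, D


def _solve_pinned(Aw, Iw, D, lam):
    stacked = np.vstack([Aw, math.sqrt(lam) * D])
    rhs = np.concatenate([Iw, np.zeros(D.shape[0])])
    p_int, _ = optimize.nnls(stacked, rhs)
    return p_int


def ift_pofr(curve: ScatteringCurve, Dmax: float,
             lambda_reg: float | str = "auto", n_r: int = 101) -> PofR:
    """Pair-distance distribution by regularized indirect Fourier transform.

    Solves  min ‖(A·p − I)/σ‖² + λ‖p″‖²  subject to p ≥ 0 and
    p(0) = p(Dmax) = 0, where A is the kernel 4π·sin(qr)/(qr) integrated on
    a uniform r grid.  ``lambda_reg="auto"`` picks λ at the L-curve corner.
    """
    if Dmax <= 0:
        raise InvalidParameterError("Dmax must be > 0")
    if curve.q[-1] * Dmax <= math.pi:
        raise ValidationError("q range too short for this Dmax "
                              "(need q_max·Dmax > π)")
    if isinstance(lambda_reg, (int, float)) and lambda_reg <= 0:
        raise InvalidParameterError(
            "λ=0 leaves the system ill-conditioned; pass λ>0 or 'auto'")
    r, Aw, Iw, D = _ift_system(curve.q, curve.intensity, curve.sigma,
                               Dmax, n_r)
    lam_ref = (np.linalg.norm(Aw) / np.linalg.norm(D)) ** 2
    if lambda_reg == "auto":
        lams = lam_ref * np.logspace(-6, 0, 7)
        pts = []
        for lam in lams:
            p_int = _solve_pinned(Aw, Iw, D, lam)
            res = np.linalg.norm(Aw @ p_int - Iw)
            pen = np.linalg.norm(D @ p_int)
            pts.append((math.log(max(res, 1e-300)),
                        math.log(max(pen, 1e-300))))
        lam = lams[_lcurve_corner(np.array(pts))]
    else:
        lam = float(lambda_reg) * lam_ref
    p_int = _solve_pinned(Aw, Iw, D, lam)
    p = np.concatenate([[0.0], p_int, [0.0]])
    norm = np.trapezoid(p, r)
    if norm <= 0:
        raise EstimationError("IFT produced an all-zero p(r)")
    rg_pr = math.sqrt(np.trapezoid(r ** 2 * p, r) / (2.0 * norm))
    return PofR(r=r, p=p, Dmax=float(Dmax), Rg_pr=rg_pr,
                I0_pr=4.0 * np.pi * norm, lambda_reg=float(lam / lam_ref))


def _lcurve_corner(pts: np.ndarray) -> int:
    """Index of maximum curvature along a discretized L-curve."""
    if len(pts) < 3:
        return len(pts) // 2
    x, y = pts[:, 0], pts[:, 1]
    best, best_k = -np.inf, len(pts) // 2
    for k in range(1, len(pts) - 1):
        a = pts[k] - pts[k - 1]
        b = pts[k + 1] - pts[k]
        cross = a[0] * b[1] - a[1] * b[0]
        denom = (np.linalg.norm(a) * np.linalg.norm(b)
                 * np.linalg.norm(pts[k + 1] - pts[k - 1]))
        if denom == 0:
            continue
        curv = 2 * abs(cross) / denom
        if curv > best:
            best, best_k = curv, k
    return best_k


def estimate_dmax(curve: ScatteringCurve,
                  candidates: Optional[Sequence[float]] = None,
                  tail_frac: float = 0.05, peak_frac: float = 0.01,
                  full_output: bool = False):
    """Estimate Dmax by scanning candidate values through the IFT.

    Accepts the smallest candidate whose p(r) has decayed to ≤ ``peak_frac``
    of its peak over the terminal ``tail_frac`` of [0, Dmax].  If no
    candidate passes, the best-scoring one is returned with a flag.
    """
    if candidates is None:
        rg = guinier_fit(curve).Rg
        candidates = np.geomspace(1.5 * rg, 4.5 * rg, 14)
    scan = []
    chosen = None
    prev_fail = None

    def score_at(D):
        pr = ift_pofr(curve, D, lambda_reg="auto")
        tail = pr.r >= (1.0 - tail_frac) * D
        return float(pr.p[tail].max() / pr.p.max())

    for D in candidates:
        if curve.q[-1] * D <= math.pi:
            continue
        try:
            score = score_at(D)
        except (EstimationError, ValidationError):
            continue
        scan.append((float(D), score))
        if score <= peak_frac:
            chosen = float(D)
            break
        prev_fail = float(D)
    if chosen is not None and prev_fail is not None:
        # bisect between the last failing and first passing candidate
        lo, hi = prev_fail, chosen
        for _ in range(4):
            mid = 0.5 * (lo + hi)
            try:
                s = score_at(mid)
            except (EstimationError, ValidationError):
                lo = mid
                continue
            scan.append((mid, s))
            if s <= peak_frac:
                hi = mid
            else:
                lo = mid
        chosen = hi
    flagged = chosen is None
    if flagged:
        if not scan:
            raise EstimationError("no candidate Dmax could be evaluated")
        chosen = min(scan, key=lambda t: t[1])[0]
    if full_output:
        return chosen, {"flagged": flagged, "scan": scan}
    return chosen


# ---------------------------------------------------------------------------
# Porod analysis


def porod_volume(curve: ScatteringCurve, guinier: GuinierResult,
                 q_cut: float = 0.25, tail_window: float = 0.05
                 ) -> PorodResult:
    """Porod invariant and volume: Vp = 2π² I0 / Q, Q = ∫ q² I dq.

    The integral is assembled from an analytic Guinier extension on
    [0, q_min], the data trapezoid on [q_min, q_cut], and a fitted
    A·q⁻⁴ Porod tail beyond q_cut.
    """
    q, I = curve.q, curve.intensity
    flags: List[str] = []
    I0, Rg = guinier.I0, guinier.Rg
    # analytic low-q extension
    low, _ = integrate.quad(lambda x: x * x * I0 * math.exp(-x * x * Rg * Rg / 3.0),
                            0.0, q[0])
    hi_data = min(q_cut, q[-1])
    m = q <= hi_data
    data_part = float(np.trapezoid(q[m] ** 2 * I[m], q[m]))
    # Porod tail: A from <I q^4> just below the cutoff
    tw = (q >= hi_data - tail_window) & (q <= hi_data)
    A = float(np.mean(I[tw] * q[tw] ** 4)) if tw.sum() >= 3 else -1.0
    if A > 0:
        tail = A / hi_data
    else:
        tail = 0.0
        flags.append("porod_tail_skipped_negative_fit")
    Q = low + data_part + tail
    Vp = 2.0 * math.pi ** 2 * I0 / Q
    return PorodResult(Q_invariant=Q, Vp=Vp, mw_est_kDa=mw_from_porod(Vp),
                       flags=flags)


def mw_from_porod(Vp: float) -> float:
    """Mass estimate in kDa (integer-rounded) from a Porod volume in Å³."""
    if Vp < 0:
        raise InvalidParameterError("Vp must be ≥ 0")
    return float(round(Vp * POROD_MASS_DA_PER_A3 / 1000.0))


# ---------------------------------------------------------------------------
# Debye profiles from bead models


def sphere_form_factor(q: np.ndarray, R: float) -> np.ndarray:
    """Normalized sphere scattering amplitude 3(sin x − x cos x)/x³, x=qR."""
    x = np.asarray(q, dtype=float) * R
    out = np.ones_like(x)
    # series below x=0.05 avoids catastrophic cancellation in sin x − x cos x
    small = np.abs(x) < 0.05
    xs = x[small]
    out[small] = 1.0 - xs ** 2 / 10.0 + xs ** 4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl ** 3
    return out


def debye_profile(model: BeadModel, q: np.ndarray,
                  bin_width: float = 0.5) -> ScatteringCurve:
    """Theoretical I(q) by the Debye equation over bead pairs.

    I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q dᵢⱼ)/(q dᵢⱼ), with fᵢ = wᵢ·Φ(qRᵢ) (sphere
    amplitudes).  Cross terms are accelerated by histogramming pair
    distances per radius-class pair (bin width ``bin_width``, each bin
    represented by its weighted mean distance).
    """
    q = np.asarray(q, dtype=float)
    w = model.scattering_weights
    radii = model.radii
    classes = np.unique(radii)
    famp = {R: sphere_form_factor(q, R) for R in classes}
    I = np.zeros_like(q)
    # self terms
    for R in classes:
        sel = radii == R
        I += famp[R] ** 2 * float((w[sel] ** 2).sum())
    # cross terms, histogrammed per class pair
    for a in range(len(classes)):
        for b in range(a, len(classes)):
            Ra, Rb = classes[a], classes[b]
            ia = np.where(radii == Ra)[0]
            ib = np.where(radii == Rb)[0]
            if Ra == Rb:
                if len(ia) < 2:
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                d = np.linalg.norm(model.centers[ia[iu]] - model.centers[ia[ju]],
                                   axis=1)
                wp = 2.0 * w[ia[iu]] * w[ia[ju]]
            else:
                d = np.linalg.norm(model.centers[ia][:, None]
                                   - model.centers[ib][None], axis=-1).ravel()
                wp = 2.0 * np.outer(w[ia], w[ib]).ravel()
            if d.size == 0:
                continue
            nbins = max(int(np.ceil(d.max() / bin_width)), 1)
            edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
            wsum, _ = np.histogram(d, bins=edges, weights=wp)
            dsum, _ = np.histogram(d, bins=edges, weights=wp * d)
            nz = wsum > 0
            dbar = dsum[nz] / wsum[nz]
            qd = np.outer(q, dbar)
            sinc = np.where(qd == 0, 1.0, np.sin(qd) / np.where(qd == 0, 1.0, qd))
            I += famp[Ra] * famp[Rb] * (sinc @ wsum[nz])
    return ScatteringCurve(q, I)


def fit_profile_scale(experimental: ScatteringCurve,
                      theoretical: ScatteringCurve) -> Tuple[float, float]:
    """Weighted least-squares scale of a theoretical curve onto data.

    Returns ``(scale, reduced_chi2)``; the theoretical curve is interpolated
    onto the experimental q grid over the overlapping range.
    """
    qlo = max(experimental.q[0], theoretical.q[0])
    qhi = min(experimental.q[-1], theoretical.q[-1])
    if qlo >= qhi:
        raise ValidationError("no q overlap between curves")
    m = (experimental.q >= qlo) & (experimental.q <= qhi)
    qe = experimental.q[m]
    Ie = experimental.intensity[m]
    if experimental.sigma is None:
        raise ValidationError("experimental curve needs sigma")
    se = experimental.sigma[m]
    It = np.interp(qe, theoretical.q, theoretical.intensity)
    wt = 1.0 / se ** 2
    scale = float((wt * Ie * It).sum() / (wt * It * It).sum())
    chi2 = float((((Ie - scale * It) / se) ** 2).sum())
    dof = max(len(qe) - 1, 1)
    return scale, chi2 / dof


def classify_oligomer(mw_est_kDa: float, monomer_mass_kDa: float
                      ) -> OligomerCall:
    """Tetramer/octamer call from the mass estimate.

    ratio = mw_est / (4·monomer); tetramer for ratio ∈ [0.8, 1.3), octamer
    for ratio ∈ [1.6, 2.4], otherwise "other" (no forced call in the gap).
    """
    if monomer_mass_kDa <= 0:
        raise InvalidParameterError("monomer mass must be > 0")
    ratio = mw_est_kDa / (4.0 * monomer_mass_kDa)
    if 0.8 <= ratio < 1.3:
        state = OligomerState.TETRAMER
    elif 1.6 <= ratio <= 2.4:
        state = OligomerState.OCTAMER
    else:
        state = OligomerState.OTHER
    return OligomerCall(state=state, mw_est_kDa=mw_est_kDa, mw_ratio=ratio)
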