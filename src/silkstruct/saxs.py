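"""Small-angle scattering analysis of the lamellar stack and fibril
bundle: Kratky transform, harmonic long-period peaks, the 1D electron
density correlation function K(z), long-period strain, Scherrer bundle
thickness, and assembly of time-resolved deformation series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .mechanics import StressStrainCurve, stage_segmentation
from .profiles import KIND_Q, Profile1D

__all__ = [
    "LongPeriodResult",
    "CorrelationResult",
    "ScherrerResult",
    "DeformationSeries",
    "kratky_transform",
    "find_harmonic_peaks",
    "correlation_function",
    "long_period_strain",
    "scherrer_thickness",
    "fit_equatorial_peak",
    "complementary_phase_thickness",
    "assemble_deformation_series",
]


def kratky_transform(profile: Profile1D) -> Profile1D:
    """Replot I(q) as q²I(q) versus q to enhance the harmonic peaks."""
    if profile.kind != KIND_Q:
        raise ValueError("Kratky transform requires a q profile")
    return Profile1D(
        profile.abscissa.copy(),
        profile.abscissa**2 * profile.intensity,
        kind=KIND_Q,
        wavelength=profile.wavelength,
        meta=dict(profile.meta, representation="kratky"),
    )


# ---------------------------------------------------------------------------
# harmonic peak analysis
# ---------------------------------------------------------------------------

@dataclass
class LongPeriodResult:
    """Harmonic peak inventory.  ``lp_1st`` is the true period averaged
    over assigned orders; ``lp_2nd``/``lp_3rd`` are the apparent
    spacings 2π/q₂ and 2π/q₃."""

    peak_positions_q: list      # [(order or None, q_nm^-1), ...]
    lp_1st: float
    lp_2nd: float | None
    lp_3rd: float | None
    ratio_2nd_3rd: float | None
    warnings: list = field(default_factory=list)


def _gauss_lin(x, center, sigma, area, b0, b1):
    return (
        area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        + b0 + b1 * (x - x.mean())
    )


def _refine_peak(q, intensity, idx, halfwidth):
    """Sub-grid peak centre via a Gaussian+linear fit in a local window;
    falls back to a parabolic 3-point refinement."""
    lo = np.searchsorted(q, q[idx] - halfwidth)
    hi = np.searchsorted(q, q[idx] + halfwidth)
    xs, ys = q[lo:hi], intensity[lo:hi]
    if xs.size >= 6:
        amp0 = max(ys.max() - ys.min(), 1e-12)
        sig0 = max(halfwidth / 4.0, q[1] - q[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _gauss_lin, xs, ys,
                    p0=[q[idx], sig0, amp0 * sig0 * np.sqrt(2 * np.pi),
                        ys.min(), 0.0],
                    maxfev=5000,
                )
            c = float(popt[0])
            if xs[0] < c < xs[-1]:
                return c, abs(float(popt[1])), abs(float(popt[2]))
        except RuntimeError:
            pass
    if 0 < idx < len(q) - 1:
        y0, y1, y2 = intensity[idx - 1:idx + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return (
                q[idx] + 0.5 * (y0 - y2) / denom * (q[1] - q[0]),
                np.nan, np.nan,
            )
    return float(q[idx]), np.nan, np.nan


def find_harmonic_peaks(kratky: Profile1D, max_order=8,
                        prominence=None, ratio_tol=0.10) -> LongPeriodResult:
    """Detect harmonic peaks in a Kratky profile and assign integer
    orders by the nearest-integer ratio to the first peak.

    Peak centres are refined by local Gaussian fits of the underlying
    I(q) (the Kratky curve divided by q²), which removes the small
    centre shift the q² weighting introduces.
    """
    q = kratky.abscissa
    y = kratky.intensity
    if prominence is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        prominence = 3.0 * mad if mad > 0 else 0.01 * float(np.max(y))
    idxs, _ = signal.find_peaks(y, prominence=prominence)
    if idxs.size == 0:
        raise ValueError("no harmonic peaks found")
    idxs = idxs[:max_order]

    base_i = y / np.clip(q, 1e-9, None) ** 2  # back to I(q) for refinement
    if idxs.size >= 2:
        halfwidth = 0.35 * float(np.min(np.diff(q[idxs])))
    else:
        halfwidth = 20.0 * (q[1] - q[0])
    centers = [ _refine_peak(q, base_i, i, halfwidth)[0] for i in idxs ]

    warns = []
    q1 = centers[0]
    assigned = []
    for c in centers:
        n = int(round(c / q1))
        if n < 1 or abs(c / (n * q1) - 1.0) > ratio_tol:
            assigned.append((None, c))
            warns.append(f"peak at q={c:.4f} nm^-1 inconsistent with harmonics")
        else:
            assigned.append((n, c))

    by_order = {n: c for n, c in assigned if n is not None}
    # true period from orders >= 2 when available (more precise)
    use = {n: c for n, c in by_order.items() if n >= 2} or by_order
    lp_1st = float(np.mean([2 * np.pi * n / c for n, c in use.items()]))
    lp_2nd = 2 * np.pi / by_order[2] if 2 in by_order else None
    lp_3rd = 2 * np.pi / by_order[3] if 3 in by_order else None
    ratio = lp_2nd / lp_3rd if (lp_2nd and lp_3rd) else None
    return LongPeriodResult(
        peak_positions_q=assigned, lp_1st=lp_1st, lp_2nd=lp_2nd,
        lp_3rd=lp_3rd, ratio_2nd_3rd=ratio, warnings=warns,
    )


# ---------------------------------------------------------------------------
# correlation function
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    z: np.ndarray
    K: np.ndarray
    Q: float                 # invariant, K(0)
    Lp: float                # first maximum of K at z > 0 (nm)
    d_pI: float              # core thickness of phase I (nm)
    d_pI_mean: float         # mean thickness of phase I (nm)
    phase2_thickness: float  # Lp − ⟨d_pI⟩ (nm)
    phase1_fraction: float
    phase_labels: dict = field(default_factory=lambda: {
        "phase1": "amorphous", "phase2": "crystalline"})
    details: dict = field(default_factory=dict)


def _first_extrema(z, K, prominence):
    """Indices of the self-correlation minimum and the long-period
    maximum of K at z > 0.

    The maximum is located as the highest local maximum beyond the
    initial descent (truncating the measured harmonics to a few orders
    leaves small ripples in K that must not be mistaken for the
    long-period peak); the minimum is the deepest point before it.
    """
    imins, _ = signal.find_peaks(-K, prominence=prominence)
    imaxs, _ = signal.find_peaks(K, prominence=prominence)
    if imins.size == 0 or imaxs.size == 0:
        return None, None
    first_min = int(imins[0])
    cand = imaxs[imaxs > first_min]
    if cand.size == 0:
        return first_min, None
    imax = int(cand[np.argmax(K[cand])])
    imin = int(np.argmin(K[:imax]))
    return imin, imax


def correlation_function(profile: Profile1D, z_max=100.0, nz=2001,
                         background="none", lowq_points=10,
                         porod_fraction=0.1) -> CorrelationResult:
    """Electron density correlation function K(z) ∝ ∫q²I(q)cos(zq)dq
    and the standard two-phase decomposition.

    The integrand is extrapolated to q = 0 with a quadratic through the
    first points and extended beyond q_max with a damped Porod q⁻⁴ tail
    before numerical quadrature.  The long period is the first local
    maximum of K; the linear-region construction against the
    first-minimum baseline gives the phase-I core thickness and the
    zero crossing (via the two-phase relation z₀ = φ(1−φ)L_p) the mean
    thickness.
    """
    if profile.kind != KIND_Q:
        raise ValueError("correlation_function requires a q profile")
    q = profile.abscissa.copy()
    intensity = profile.intensity.copy()
    if background == "constant":
        intensity = intensity - float(np.median(intensity[int(0.9 * q.size):]))

    # tail sanity: the signal must have decayed at the window edge
    tail = intensity[int(0.95 * q.size):]
    if np.mean(tail) > 0.05 * np.max(intensity):
        raise ValueError(
            "intensity has not decayed at q_max; subtract the background "
            "or extend the q window"
        )

    dq = q[1] - q[0]
    # q→0 extrapolation: quadratic I ≈ c0 + c2·q² through the first points
    head_q, head_i = q[:lowq_points], intensity[:lowq_points]
    coef = np.polyfit(head_q**2, head_i, 1)
    q_low = np.arange(0.0, q[0], dq)
    i_low = np.clip(coef[1] + coef[0] * q_low**2, 0.0, None)

    # Porod extension: damped B/q⁴ tail beyond q_max
    ptail = slice(int((1 - porod_fraction) * q.size), None)
    porod_b = max(float(np.median(q[ptail] ** 4 * intensity[ptail])), 0.0)
    q_hi = np.arange(q[-1] + dq, 3.0 * q[-1], dq)
    damp = np.exp(-(q_hi - q[-1]) / (0.25 * q[-1]))
    i_hi = porod_b / q_hi**4 * damp

    qq = np.concatenate([q_low, q, q_hi])
    ii = np.concatenate([i_low, intensity, i_hi])

    z = np.linspace(0.0, z_max, nz)
    integrand = qq**2 * ii
    K = np.trapezoid(integrand[None, :] * np.cos(z[:, None] * qq[None, :]),
                     qq, axis=1)
    Q = float(K[0])
    if Q <= 0:
        raise ValueError("non-positive invariant; profile looks empty")

    prom = 0.002 * Q
    imin, imax = _first_extrema(z, K, prom)
    if imax is None:
        raise ValueError(f"no correlation maximum found within z_max={z_max}")
    # parabolic refinement of the long-period maximum
    y0, y1, y2 = K[imax - 1:imax + 2]
    denom = y0 - 2 * y1 + y2
    Lp = float(z[imax] + (0.5 * (y0 - y2) / denom * (z[1] - z[0])
                          if denom != 0 else 0.0))

    K_min = float(K[imin])
    drop = Q - K_min
    upper = Q - 0.2 * drop
    lower = Q - 0.8 * drop
    zone = (np.arange(K.size) < imin) & (K <= upper) & (K >= lower)
    if zone.sum() < 2:
        raise ValueError("too few points in the linear self-correlation region")
    slope, icpt = np.polyfit(z[zone], K[zone], 1)
    if slope >= 0:
        raise ValueError("linear region is not descending")
    # flat baseline: mean K over the central half of the inter-extremum
    # plateau (averages out the harmonic-truncation ripples)
    lo_b = imin + (imax - imin) // 4
    hi_b = imax - (imax - imin) // 4
    K_base = float(np.mean(K[lo_b:hi_b + 1])) if hi_b > lo_b else K_min
    d_core = float((K_base - icpt) / slope)
    z0 = float(-icpt / slope)  # zero crossing of the linear fit
    disc = max(0.0, 1.0 - 4.0 * z0 / Lp)
    phi = (1.0 - np.sqrt(disc)) / 2.0
    d_mean = float(phi * Lp)
    return CorrelationResult(
        z=z, K=K, Q=Q, Lp=Lp, d_pI=d_core, d_pI_mean=d_mean,
        phase2_thickness=float(Lp - d_mean), phase1_fraction=float(phi),
        details={
            "first_minimum_z": float(z[imin]),
            "first_minimum_K": K_min,
            "linear_slope": float(slope),
            "linear_intercept": float(icpt),
            "zero_crossing_z": z0,
            "porod_constant": porod_b,
        },
    )


def complementary_phase_thickness(long_period, phase1_thickness):
    """Thickness of the second phase of the lamellar pair:
    L_p − d_phase1 (nm)."""
    if not (0 < phase1_thickness < long_period):
        raise ValueError("phase1 thickness must lie inside the long period")
    return long_period - phase1_thickness


def long_period_strain(lp_1st_series):
    """Percent strain of the long period relative to the first
    (unloaded) value: 100·(L_p − L_p0)/L_p0."""
    lp = np.asarray(lp_1st_series, dtype=float)
    if lp.size == 0:
        raise ValueError("empty series")
    if lp[0] == 0:
        raise ValueError("zero reference long period")
    return (lp - lp[0]) / lp[0] * 100.0


# ---------------------------------------------------------------------------
# Scherrer bundle thickness
# ---------------------------------------------------------------------------

@dataclass
class ScherrerResult:
    beta_obs: float     # rad (FWHM in 2θ)
    beta_instr: float   # rad
    beta: float         # rad, corrected
    theta: float        # rad, half scattering angle
    wavelength: float   # nm
    k_factor: float
    d: float            # nm


def fit_equatorial_peak(profile: Profile1D):
    """Gaussian+linear fit of the dominant peak; returns
    (center_q, fwhm_q)."""
    q, y = profile.abscissa, profile.intensity
    idx = int(np.argmax(y))
    # window: where the peak falls below 10% of its height above baseline
    base = float(np.median(y))
    height = y[idx] - base
    above = y - base > 0.1 * height
    lo = idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = idx
    while hi < y.size - 1 and above[hi + 1]:
        hi += 1
    lo = max(lo - 3, 0)
    hi = min(hi + 4, y.size)
    xs, ys = q[lo:hi], y[lo:hi]
    sig0 = max((xs[-1] - xs[0]) / 6.0, q[1] - q[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            _gauss_lin, xs, ys,
            p0=[q[idx], sig0, height * sig0 * np.sqrt(2 * np.pi), base, 0.0],
            maxfev=5000,
        )
    center, sigma = float(popt[0]), abs(float(popt[1]))
    return center, sigma * 2.0 * np.sqrt(2.0 * np.log(2.0))


def scherrer_thickness(peak_center_q, fwhm_obs_q, instrumental_fwhm_q,
                       wavelength, k_factor=0.9) -> ScherrerResult:
    """Bundle thickness d = K·λ/(β·cosθ) from an equatorial peak.

    All FWHM inputs are in q units (nm⁻¹) and are converted to angular
    widths with the supplied wavelength; the instrumental width is
    removed in quadrature (β = √(β_obs² − β_instr²)).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if fwhm_obs_q <= instrumental_fwhm_q:
        raise ValueError(
            "observed width does not exceed the instrumental width; "
            "size unresolvable"
        )
    theta = float(np.arcsin(peak_center_q * wavelength / (4.0 * np.pi)))
    to_angle = wavelength / (2.0 * np.pi * np.cos(theta))  # dq → d(2θ) rad
    beta_obs = fwhm_obs_q * to_angle
    beta_instr = instrumental_fwhm_q * to_angle
    beta = float(np.sqrt(beta_obs**2 - beta_instr**2))
    d = k_factor * wavelength / (beta * np.cos(theta))
    return ScherrerResult(
        beta_obs=float(beta_obs), beta_instr=float(beta_instr), beta=beta,
        theta=theta, wavelength=wavelength, k_factor=k_factor, d=float(d),
    )


# ---------------------------------------------------------------------------
# time-resolved deformation series
# ---------------------------------------------------------------------------

@dataclass
class DeformationSeries:
    """Joined per-frame structural and mechanical record."""

    frames: pd.DataFrame
    stages: dict = field(default_factory=dict)
    yield_strain_percent: float | None = None
    fracture_strain_percent: float | None = None


def assemble_deformation_series(frame_data, tensile_log,
                                frame_interval=9.0) -> DeformationSeries:
    """Join per-frame WAXD/SAXS results with the tensile log.

    Parameters
    ----------
    frame_data : DataFrame
        Columns ``time`` (s), ``d002`` (Å), ``orientation_index``,
        ``lp_2nd`` and ``lp_3rd`` (nm); optional ``lp_1st`` (computed as
        3·lp_3rd when absent, the true period being derived from the
        third-order scattering).
    tensile_log : DataFrame
        Columns ``time`` (s), ``strain_percent``, ``stress_gpa``.
    frame_interval : float
        Frame cadence in s; frames whose timestamps fall outside the
        tensile log by more than half this interval are rejected.
    """
    frames = pd.DataFrame(frame_data).copy()
    log = pd.DataFrame(tensile_log)
    required = {"time", "d002", "orientation_index", "lp_2nd", "lp_3rd"}
    missing = required - set(frames.columns)
    if missing:
        raise ValueError(f"frame data missing columns: {sorted(missing)}")

    tol = frame_interval / 2.0
    t0, t1 = float(log["time"].iloc[0]), float(log["time"].iloc[-1])
    bad = frames.index[(frames["time"] < t0 - tol) | (frames["time"] > t1 + tol)]
    if len(bad):
        raise ValueError(
            "frame timestamps misaligned with the tensile log beyond "
            f"half a frame interval: frames {list(bad)}"
        )

    frames["bulk_strain"] = np.interp(frames["time"], log["time"],
                                      log["strain_percent"])
    frames["stress"] = np.interp(frames["time"], log["time"], log["stress_gpa"])
    if "lp_1st" not in frames.columns:
        frames["lp_1st"] = 3.0 * frames["lp_3rd"]
    from .waxd import crystal_strain

    frames["crystal_strain"] = crystal_strain(frames["d002"].to_numpy())
    frames["lp_strain"] = long_period_strain(frames["lp_1st"].to_numpy())
    frames["lp_ratio_2nd_3rd"] = frames["lp_2nd"] / frames["lp_3rd"]

    yield_pct = None
    frac_pct = None
    stages: dict = {}
    if len(log) >= 3:
        curve = StressStrainCurve(
            (log["strain_percent"].to_numpy() - log["strain_percent"].iloc[0])
            / 100.0,
            log["stress_gpa"].to_numpy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = stage_segmentation(curve)
        frac_pct = b.fracture_strain * 100.0
        if b.yield_strain is not None:
            yield_pct = b.yield_strain * 100.0
        stages = {k: (v[0] * 100.0, v[1] * 100.0) for k, v in b.stages.items()}

    order = ["time", "bulk_strain", "stress", "d002", "crystal_strain",
             "orientation_index", "lp_2nd", "lp_3rd", "lp_1st", "lp_strain",
             "lp_ratio_2nd_3rd"]
    frames = frames[order + [c for c in frames.columns if c not in order]]
    return DeformationSeries(frames=frames, stages=stages,
                             yield_strain_percent=yield_pct,
                             fracture_strain_percent=frac_pct)
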