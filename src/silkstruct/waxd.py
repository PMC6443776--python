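"""Wide-angle diffraction analysis: crystallinity by Gaussian peak
deconvolution, orthorhombic unit-cell indexing, crystal strain from the
002 spacing, and azimuthal orientation of the equatorial 200 reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .profiles import KIND_TWO_THETA, FiberDiagram, Profile1D

__all__ = [
    "UnitCell",
    "CrystallinityResult",
    "OrientationResult",
    "FittedPeak",
    "BETA_SHEET_REFLECTIONS",
    "d_spacing",
    "two_theta_from_d",
    "d_from_two_theta",
    "reflection_positions",
    "scan_two_theta_profile",
    "fit_crystallinity",
    "solve_unit_cell",
    "crystal_strain",
    "orientation_index",
    "azimuthal_profile",
]

# crystalline reflections used for the β-sheet profile deconvolution;
# (102) and (300) overlap and are handled as one composite peak by default
BETA_SHEET_REFLECTIONS = [
    ("200", [(2, 0, 0)]),
    ("210", [(2, 1, 0)]),
    ("211", [(2, 1, 1)]),
    ("002", [(0, 0, 2)]),
    ("102+300", [(1, 0, 2), (3, 0, 0)]),
    ("202", [(2, 0, 2)]),
]

# amorphous-halo search window, expressed as fixed d-spacings (nm) so it
# rescales with the profile's wavelength (equals 15°-25° 2θ for Cu-Kα)
AMORPHOUS_D_WINDOW_NM = (0.35617, 0.59069)


@dataclass
class UnitCell:
    """Rectangular (orthorhombic) unit cell, axes in Å; c is the fibre axis."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell axes must be positive")

    def d_spacing(self, h, k, l):
        """d_hkl in Å for the orthogonal cell."""
        inv_d2 = (h / self.a) ** 2 + (k / self.b) ** 2 + (l / self.c) ** 2
        if inv_d2 <= 0:
            raise ValueError("h, k, l may not all be zero")
        return inv_d2 ** -0.5


def d_spacing(cell: UnitCell, h, k, l):
    return cell.d_spacing(h, k, l)


def two_theta_from_d(d_angstrom, wavelength_nm):
    """Bragg 2θ (degrees) from a d-spacing in Å."""
    s = (wavelength_nm * 10.0) / (2.0 * np.asarray(d_angstrom, dtype=float))
    if np.any(s >= 1.0):
        raise ValueError("d-spacing unresolvable at this wavelength")
    return np.rad2deg(2.0 * np.arcsin(s))


def d_from_two_theta(two_theta_deg, wavelength_nm):
    """d-spacing in Å from Bragg 2θ in degrees."""
    theta = np.deg2rad(np.asarray(two_theta_deg, dtype=float)) / 2.0
    return (wavelength_nm * 10.0) / (2.0 * np.sin(theta))


def reflection_positions(cell: UnitCell, wavelength_nm,
                         reflections=BETA_SHEET_REFLECTIONS,
                         composite_single=True):
    """2θ positions (degrees) of the crystalline reflections.

    Composite entries (overlapping planes) yield the mean position when
    ``composite_single``; otherwise each plane is listed separately.
    """
    out = []
    for label, hkls in reflections:
        tts = [two_theta_from_d(cell.d_spacing(*hkl), wavelength_nm) for hkl in hkls]
        if composite_single or len(tts) == 1:
            out.append((label, float(np.mean(tts))))
        else:
            for hkl, tt in zip(hkls, tts):
                out.append(("%d%d%d" % hkl, float(tt)))
    return out


@dataclass
class FittedPeak:
    center: float
    sigma: float
    area: float
    label: str


@dataclass
class CrystallinityResult:
    Xc: float   # percent
    Ic: float   # summed crystalline area
    Ia: float   # amorphous area
    fitted_peaks: list
    baseline: tuple = (0.0, 0.0)
    cost: float = 0.0

    def as_dict(self):
        return {
            "Xc_percent": self.Xc,
            "Ic": self.Ic,
            "Ia": self.Ia,
            "baseline": list(self.baseline),
            "peaks": [
                {"label": p.label, "center_deg": p.center,
                 "sigma_deg": p.sigma, "area": p.area}
                for p in self.fitted_peaks
            ],
        }


def _gauss(x, center, sigma, area):
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def fit_crystallinity(profile: Profile1D, cell: UnitCell, wavelength=None,
                      amorphous_window=None, baseline="linear",
                      composite_single=True) -> CrystallinityResult:
    """Deconvolve a 2θ profile into six crystalline Gaussians (centres
    fixed from the unit cell) plus one free amorphous Gaussian.

    Crystallinity Xc = 100·Ic/(Ic+Ia) with Ic/Ia the summed fitted areas
    of the crystalline/amorphous components.  A linear baseline is fitted
    jointly unless ``baseline="none"``.
    """
    if profile.kind != KIND_TWO_THETA:
        raise ValueError("fit_crystallinity requires a 2θ profile")
    lam = wavelength if wavelength is not None else profile.wavelength
    positions = reflection_positions(cell, lam, composite_single=composite_single)
    x = profile.abscissa
    y = profile.intensity
    for label, tt in positions:
        if not (x[0] <= tt <= x[-1]):
            raise ValueError(
                f"profile does not cover the {label} reflection at {tt:.2f} deg"
            )

    if amorphous_window is None:
        d_lo, d_hi = AMORPHOUS_D_WINDOW_NM
        amorphous_window = (
            float(two_theta_from_d(d_hi * 10.0, lam)),
            float(two_theta_from_d(d_lo * 10.0, lam)),
        )
    aw_lo, aw_hi = amorphous_window
    aw_lo = max(aw_lo, x[0])
    aw_hi = min(aw_hi, x[-1])

    ymin = float(np.min(y))
    centers = np.array([tt for _, tt in positions])
    ncr = centers.size

    # deterministic initialisation: widths 0.5 deg, areas from local height
    sig0 = 0.5
    amp0 = np.clip(np.interp(centers, x, y) - ymin, 1e-6, None)
    area0 = amp0 * sig0 * np.sqrt(2 * np.pi)
    a_center0 = float(np.clip(x[np.argmax(y)], aw_lo, aw_hi))
    a_sigma0 = 3.0 * lam / 0.15418  # scale the halo width with wavelength
    a_area0 = max((np.max(y) - ymin) * a_sigma0 * np.sqrt(2 * np.pi) * 0.5, 1e-6)

    use_baseline = baseline == "linear"

    def model(params):
        areas = params[:ncr]
        sigmas = params[ncr:2 * ncr]
        a_c, a_s, a_a = params[2 * ncr:2 * ncr + 3]
        out = _gauss(x[:, None], centers[None, :], sigmas[None, :],
                     areas[None, :]).sum(axis=1)
        out = out + _gauss(x, a_c, a_s, a_a)
        if use_baseline:
            b0, b1 = params[-2:]
            out = out + b0 + b1 * (x - x[0])
        return out

    p0 = np.concatenate([
        area0, np.full(ncr, sig0), [a_center0, a_sigma0, a_area0],
        [ymin, 0.0] if use_baseline else [],
    ])
    lo = np.concatenate([
        np.zeros(ncr), np.full(ncr, 0.05), [aw_lo, 0.3 * a_sigma0, 0.0],
        [-np.inf, -np.inf] if use_baseline else [],
    ])
    hi = np.concatenate([
        np.full(ncr, np.inf), np.full(ncr, 3.0),
        [aw_hi, 4.0 * a_sigma0, np.inf],
        [np.inf, np.inf] if use_baseline else [],
    ])
    p0 = np.clip(p0, lo, hi)

    res = optimize.least_squares(
        lambda p: model(p) - y, p0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
    )
    if not res.success:
        raise RuntimeError(f"crystallinity fit did not converge: {res.message}")

    p = res.x
    peaks = [
        FittedPeak(center=float(c), sigma=float(p[ncr + i]), area=float(p[i]),
                   label=positions[i][0])
        for i, (c,) in enumerate(zip(centers))
    ]
    a_c, a_s, a_a = p[2 * ncr:2 * ncr + 3]
    peaks.append(FittedPeak(center=float(a_c), sigma=float(a_s),
                            area=float(a_a), label="amorphous"))
    Ic = float(np.sum(p[:ncr]))
    Ia = float(a_a)
    total = Ic + Ia
    Xc = 100.0 * Ic / total if total > 0 else 0.0
    bl = tuple(p[-2:]) if use_baseline else (0.0, 0.0)
    return CrystallinityResult(Xc=Xc, Ic=Ic, Ia=Ia, fitted_peaks=peaks,
                               baseline=bl, cost=float(res.cost))


def solve_unit_cell(d200, d210, d002) -> UnitCell:
    """Rectangular cell (Å) from the 200, 210, and 002 d-spacings (Å)."""
    if min(d200, d210, d002) <= 0:
        raise ValueError("d-spacings must be positive")
    a = 2.0 * d200
    c = 2.0 * d002
    inv_b2 = 1.0 / d210**2 - 4.0 / a**2
    if inv_b2 <= 0:
        raise ValueError("inconsistent spacings: require d210 < d200")
    return UnitCell(a=a, b=inv_b2 ** -0.5, c=c)


def crystal_strain(d002_series):
    """Percent crystal strain of each frame relative to the first
    (unloaded) d002 value: 100·(d − d0)/d0."""
    d = np.asarray(d002_series, dtype=float)
    if d.size == 0:
        raise ValueError("empty series")
    if d[0] == 0:
        raise ValueError("zero reference spacing")
    return (d - d[0]) / d[0] * 100.0


# ---------------------------------------------------------------------------
# 2D fibre-diagram operations
# ---------------------------------------------------------------------------

def scan_two_theta_profile(diagram: FiberDiagram, two_theta_range=(10.0, 37.0),
                           azimuth_range=(-180.0, 0.0), bin_width=0.1) -> Profile1D:
    """Azimuthally integrated radial profile: mean intensity per 2θ bin
    over the requested azimuthal wedge.

    Empty bins are flagged in ``meta['interpolated_bins']`` and filled by
    linear interpolation from their neighbours.
    """
    tt = diagram.two_theta_map()
    az = diagram.azimuth_map()
    lo, hi = two_theta_range
    if hi > float(np.max(tt)):
        raise ValueError("requested 2θ range exceeds detector coverage")
    a0, a1 = min(azimuth_range), max(azimuth_range)
    sel = (tt >= lo) & (tt < hi) & (az >= a0) & (az <= a1)
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    idx = np.floor((tt[sel] - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, nbins - 1)
    sums = np.bincount(idx, weights=diagram.image[sel], minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    centers = lo + (np.arange(nbins) + 0.5) * bin_width
    prof = np.full(nbins, np.nan)
    np.divide(sums, counts, out=prof, where=counts > 0)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        good = counts > 0
        prof[~good] = np.interp(centers[~good], centers[good], prof[good])
    return Profile1D(centers, prof, kind=KIND_TWO_THETA,
                     wavelength=diagram.wavelength,
                     meta={"interpolated_bins": empty.tolist(),
                           "azimuth_range": [a0, a1]})


def azimuthal_profile(diagram: FiberDiagram, two_theta, ring_halfwidth=1.0,
                      az_bin=1.0):
    """Mean intensity versus azimuth on the ring |2θ − t| ≤ halfwidth.

    Returns (azimuth bin centres in degrees over (−180, 180], profile).
    """
    tt = diagram.two_theta_map()
    az = diagram.azimuth_map()
    sel = np.abs(tt - two_theta) <= ring_halfwidth
    nbins = int(round(360.0 / az_bin))
    idx = np.floor((az[sel] + 180.0) / az_bin).astype(int)
    idx = np.clip(idx, 0, nbins - 1)
    sums = np.bincount(idx, weights=diagram.image[sel], minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    centers = -180.0 + (np.arange(nbins) + 0.5) * az_bin
    prof = np.full(nbins, np.nan)
    np.divide(sums, counts, out=prof, where=counts > 0)
    good = counts > 0
    if not good.all():
        prof[~good] = np.interp(centers[~good], centers[good], prof[good],
                                period=360.0)
    return centers, prof


@dataclass
class OrientationResult:
    fwhm: float    # degrees
    index: float   # (180 − FWHM)/180
    warning: str | None = None


def _interp_half_crossing(xs, ys, half, direction):
    """Walk from the profile maximum (index 0 of xs/ys) outward and
    linearly interpolate the first crossing below ``half``; ties broken
    toward the wider side (the farther bracketing sample)."""
    for i in range(1, len(ys)):
        if ys[i] <= half:
            if ys[i - 1] == ys[i]:
                return xs[i]
            t = (ys[i - 1] - half) / (ys[i - 1] - ys[i])
            return xs[i - 1] + t * (xs[i] - xs[i - 1])
    return xs[-1]


def orientation_index(diagram: FiberDiagram, two_theta=None,
                      ring_halfwidth=1.0, az_bin=1.0) -> OrientationResult:
    """Orientation index (180 − FWHM)/180 of the azimuthal spread of the
    equatorial reflection at ``two_theta`` (default: the 2θ of the
    brightest pixel on the equator)."""
    if two_theta is None:
        tt = diagram.two_theta_map()
        az = diagram.azimuth_map()
        on_eq = np.abs(np.minimum(np.abs(az), 180.0 - np.abs(az))) <= 2.0
        two_theta = float(tt[on_eq][np.argmax(diagram.image[on_eq])])
    centers, prof = azimuthal_profile(diagram, two_theta, ring_halfwidth, az_bin)
    pmin, pmax = float(np.min(prof)), float(np.max(prof))
    # flatness: compare the profile's range with the bin-to-bin noise
    # (pixel-sampling noise), estimated robustly from adjacent differences
    diffs = np.diff(prof)
    noise = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) \
        / np.sqrt(2.0)
    if pmax <= 0 or (pmax - pmin) < max(8.0 * noise,
                                        0.02 * max(pmax, 1e-300)):
        return OrientationResult(fwhm=180.0, index=0.0,
                                 warning="no discernible azimuthal peak")
    # centre the profile on the peak nearest the equator (az 0 or ±180)
    kmax = int(np.argmax(prof))
    rolled = np.roll(prof, -kmax)
    half = pmin + 0.5 * (pmax - pmin)
    n = len(prof)
    dist = np.arange(n) * az_bin
    walk_right = rolled
    walk_left = np.concatenate(([rolled[0]], rolled[:0:-1]))
    right = _interp_half_crossing(dist, walk_right, half, +1)
    left = _interp_half_crossing(dist, walk_left, half, -1)
    fwhm = float(min(right + left, 180.0))
    return OrientationResult(fwhm=fwhm, index=max(0.0, (180.0 - fwhm) / 180.0))
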