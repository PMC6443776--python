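"""Tensile mechanics: cross-section geometry, stress conversion, and
property extraction from engineering stress–strain curves.

Stress is carried in GPa and strain as dimensionless engineering strain
throughout; toughness is reported in MJ·m⁻³ (1 GPa × unit strain =
1000 MJ·m⁻³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CrossSection",
    "StressStrainCurve",
    "TensileProperties",
    "CrystalModulusFit",
    "StageBoundaries",
    "cross_section_area",
    "bundle_area_from_mass",
    "force_to_stress",
    "tensile_properties",
    "crystal_modulus",
    "stage_segmentation",
]

GPA_STRAIN_TO_MJ_M3 = 1000.0  # 1 GPa·(unit strain) = 1000 MJ/m^3


@dataclass
class CrossSection:
    """Elliptical filament cross-section with tilt correction.

    The measured projection of the major axis is ``L_a_apparent`` =
    L_a·cos(tilt); the per-filament area follows
    ``area = π/(4·axial_ratio·cos²(tilt)) · L_a_apparent²``.
    All lengths in μm, area in μm².
    """

    L_a: float
    L_b: float
    L_a_apparent: float
    tilt_theta: float  # degrees
    axial_ratio: float
    area: float  # per filament, μm²
    n_filaments: int = 2

    @property
    def total_area(self):
        return self.n_filaments * self.area


def cross_section_area(L_a_apparent, tilt_theta=10.37, axial_ratio=1.70,
                       n_filaments=2):
    """Per-filament elliptical area from the apparent major-axis length.

    Parameters
    ----------
    L_a_apparent : float
        Major axis measured in projection (μm).
    tilt_theta : float
        Tilt of the major axis out of the viewing plane, degrees; must
        be < 90.
    axial_ratio : float
        Major/minor axial ratio of the ellipse.
    """
    if L_a_apparent <= 0 or axial_ratio <= 0:
        raise ValueError("L_a_apparent and axial_ratio must be positive")
    if not (0 <= tilt_theta < 90):
        raise ValueError("tilt_theta must be in [0, 90) degrees")
    ct = np.cos(np.deg2rad(tilt_theta))
    area = np.pi / (4.0 * axial_ratio * ct**2) * L_a_apparent**2
    L_a = L_a_apparent / ct
    return CrossSection(
        L_a=L_a,
        L_b=L_a / axial_ratio,
        L_a_apparent=L_a_apparent,
        tilt_theta=tilt_theta,
        axial_ratio=axial_ratio,
        area=area,
        n_filaments=n_filaments,
    )


def bundle_area_from_mass(mass_mg, length_mm, density_g_cm3):
    """Bundle cross-section (μm²) from mass, length, and density.

    Alternative estimator for fibre bundles where individual
    cross-sections cannot be measured: area = mass/(length·density).
    """
    if mass_mg <= 0 or length_mm <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass, length, and density must be positive")
    volume_cm3 = (mass_mg * 1e-3) / density_g_cm3
    area_cm2 = volume_cm3 / (length_mm * 0.1)
    return area_cm2 * 1e8  # cm² → μm²


@dataclass
class StressStrainCurve:
    """Engineering stress–strain record (strain dimensionless, stress GPa)."""

    strain: np.ndarray
    stress: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1D arrays of equal length")
        if self.strain.size and abs(self.strain[0]) > 1e-12:
            raise ValueError("strain must start at 0")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be non-decreasing")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress must be finite")


@dataclass
class TensileProperties:
    modulus: float        # GPa
    strength: float       # GPa, stress at fracture
    extensibility: float  # strain at fracture
    toughness: float      # MJ/m^3
    fracture_index: int = -1


def force_to_stress(force_n, cross_section: CrossSection):
    """Convert a force series (N) to stress (GPa) using the total
    cross-section (``n_filaments`` × per-filament area, μm²)."""
    total = cross_section.total_area
    if total <= 0:
        raise ValueError("total cross-sectional area must be positive")
    # N/μm² = 1e12 Pa = 1000 GPa
    return np.asarray(force_n, dtype=float) / total * 1000.0


def _fracture_index(stress, threshold=0.95):
    """Index of the fracture point: last sample at >= threshold of the
    global stress maximum (tolerates gradual bundle-style drops)."""
    smax = float(np.max(stress))
    if smax <= 0:
        return len(stress) - 1
    idx = np.nonzero(stress >= threshold * smax)[0]
    return int(idx[-1])


def _integrate_to(strain, stress, eps_end):
    """Trapezoidal ∫σdε from 0 to eps_end (GPa·strain), interpolating the
    end point so that stage-wise integrals are exactly additive."""
    s = np.asarray(strain)
    y = np.asarray(stress)
    if eps_end <= s[0]:
        return 0.0
    i = int(np.searchsorted(s, eps_end, side="right"))
    xs = s[:i]
    ys = y[:i]
    if eps_end > xs[-1]:
        y_end = float(np.interp(eps_end, s, y))
        xs = np.append(xs, eps_end)
        ys = np.append(ys, y_end)
    return float(np.trapezoid(ys, xs))


def tensile_properties(curve: StressStrainCurve,
                       elastic_fit_window=(0.002, 0.015),
                       modulus_mode="window",
                       fracture_threshold=0.95) -> TensileProperties:
    """Modulus, strength, extensibility, and toughness from a curve.

    ``modulus_mode="window"`` fits a least-squares line over the strain
    window (default 0.2%–1.5%); ``"tangent"`` uses the first 10 samples
    from the origin instead.
    """
    eps, sig = curve.strain, curve.stress
    if eps.size < 3:
        raise ValueError("curve too short")
    if modulus_mode == "window":
        lo, hi = elastic_fit_window
        mask = (eps >= lo) & (eps <= hi)
        if mask.sum() < 2:
            raise ValueError("elastic fit window outside data")
        slope = np.polyfit(eps[mask], sig[mask], 1)[0]
    elif modulus_mode == "tangent":
        n = min(10, eps.size)
        slope = np.polyfit(eps[1:n], sig[1:n], 1)[0]
    else:
        raise ValueError(f"unknown modulus_mode {modulus_mode!r}")

    ifrac = _fracture_index(sig, fracture_threshold)
    toughness = _integrate_to(eps, sig, eps[ifrac]) * GPA_STRAIN_TO_MJ_M3
    return TensileProperties(
        modulus=float(slope),
        strength=float(sig[ifrac]),
        extensibility=float(eps[ifrac]),
        toughness=toughness,
        fracture_index=ifrac,
    )


@dataclass
class CrystalModulusFit:
    slope: float           # GPa
    intercept: float       # GPa
    stderr: float          # GPa
    r_squared: float
    nonlinear: bool        # True when the linear model fits poorly


def crystal_modulus(stress_gpa, crystal_strain_percent, r2_threshold=0.98):
    """OLS slope of stress against crystal strain (strain as fraction).

    The crystal strain series is given in percent, as produced by the
    WAXD stage, and is converted to a fraction before regression so the
    slope is a modulus in GPa.
    """
    sig = np.asarray(stress_gpa, dtype=float)
    ec = np.asarray(crystal_strain_percent, dtype=float) / 100.0
    if sig.size < 3 or sig.size != ec.size:
        raise ValueError("need >= 3 paired stress / crystal-strain points")
    if np.ptp(ec) == 0:
        raise ValueError("crystal strain is constant; modulus undefined")
    res = stats.linregress(ec, sig)
    r2 = float(res.rvalue**2)
    return CrystalModulusFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        r_squared=r2,
        nonlinear=r2 < r2_threshold,
    )


@dataclass
class StageBoundaries:
    """Deformation stages: I = initial elastic, II = strain hardening,
    III = post-fracture tail (when recorded)."""

    yield_strain: float | None
    fracture_strain: float
    fracture_index: int
    modulus: float
    stages: dict = field(default_factory=dict)


def stage_segmentation(curve: StressStrainCurve,
                       elastic_fit_window=(0.002, 0.015),
                       offset=0.002,
                       fracture_threshold=0.95) -> StageBoundaries:
    """Locate the yield and fracture points of a stress–strain curve.

    The yield point uses the standard offset construction: the first
    intersection of the curve with the elastic line displaced by
    ``offset`` strain.  A curve that never crosses the offset line is
    treated as purely elastic (stage II empty, warning).
    """
    eps, sig = curve.strain, curve.stress
    lo, hi = elastic_fit_window
    mask = (eps >= lo) & (eps <= hi)
    if mask.sum() < 2:
        raise ValueError("elastic fit window outside data")
    modulus = float(np.polyfit(eps[mask], sig[mask], 1)[0])

    ifrac = _fracture_index(sig, fracture_threshold)
    frac_strain = float(eps[ifrac])

    # offset-line crossing, searched beyond the fit window
    yield_strain = None
    f = sig - modulus * (eps - offset)
    search = np.nonzero(eps > hi)[0]
    for j in search:
        if j == 0 or j > ifrac:
            continue
        if f[j] <= 0 < f[j - 1]:
            # linear interpolation of the sign change
            t = f[j - 1] / (f[j - 1] - f[j])
            yield_strain = float(eps[j - 1] + t * (eps[j] - eps[j - 1]))
            break
    if yield_strain is not None:
        # refine: intersect the elastic line with a local fit of the
        # hardening branch, removing the bias of the offset construction
        lo_h = yield_strain
        hi_h = min(yield_strain + 0.25 * (eps[ifrac] - yield_strain), eps[ifrac])
        mask_h = (eps >= lo_h) & (eps <= hi_h)
        if mask_h.sum() >= 2:
            h_slope, h_icpt = np.polyfit(eps[mask_h], sig[mask_h], 1)
            if modulus - h_slope > 0.05 * modulus:
                cross = h_icpt / (modulus - h_slope)
                if 0 < cross <= yield_strain:
                    yield_strain = float(cross)
    if yield_strain is None:
        warnings.warn("no yield point detected; curve treated as purely elastic")

    stages = {}
    if yield_strain is not None:
        stages["I"] = (0.0, yield_strain)
        stages["II"] = (yield_strain, frac_strain)
    else:
        stages["I"] = (0.0, frac_strain)
    if ifrac < eps.size - 1:
        stages["III"] = (frac_strain, float(eps[-1]))
    return StageBoundaries(
        yield_strain=yield_strain,
        fracture_strain=frac_strain,
        fracture_index=ifrac,
        modulus=modulus,
        stages=stages,
    )


def stage_toughness(curve: StressStrainCurve, boundaries: StageBoundaries):
    """Per-stage ∫σdε in MJ/m³; stage integrals add up to the total."""
    out = {}
    for name, (a, b) in boundaries.stages.items():
        if name == "III":
            continue
        out[name] = (
            _integrate_to(curve.strain, curve.stress, b)
            - _integrate_to(curve.strain, curve.stress, a)
        ) * GPA_STRAIN_TO_MJ_M3
    return out
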