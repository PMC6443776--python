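"""Forward models for every input the analysis stages consume.

Each generator records its ground-truth parameters in the ``meta`` block
of the object it returns, so downstream operations can be tested by
parameter recovery without any experimental data:

* two-phase lamellar meridional SAXS with up to 8 harmonic orders,
* an equatorial fibril-packing peak with finite-bundle broadening,
* β-sheet WAXD 2θ profiles and 2D fibre diagrams with known
  crystallinity and azimuthal orientation spread,
* piecewise-linear (elastic + strain-hardening) stress–strain curves,
* heavy-chain fibroin-like sequences with polyalanine-block /
  non-polyalanine-block tandem repeats.

Seeded runs are bit-reproducible; the seed affects only the noise, never
the recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import GPA_STRAIN_TO_MJ_M3, StressStrainCurve
from .profiles import KIND_Q, KIND_TWO_THETA, FiberDiagram, Profile1D
from .waxd import UnitCell, reflection_positions

__all__ = [
    "LamellarModelParams",
    "WaxdModelParams",
    "WaxdPeak",
    "TensileModelParams",
    "SequenceModelParams",
    "DEFAULT_CELL",
    "generate_saxs_meridional",
    "generate_saxs_equatorial",
    "generate_waxd_profile",
    "generate_fiber_diagram",
    "generate_stress_strain",
    "generate_sequences",
    "default_waxd_params",
]

#: β-sheet cell used by the default synthetic WAXD inventory (Å)
DEFAULT_CELL = UnitCell(a=9.39, b=9.50, c=6.98)

Q_GRID = (0.02, 2.0, 2000)        # SAXS q-grid: min, max (nm⁻¹), points
TWO_THETA_GRID = (10.0, 37.0, 1350)  # WAXD grid: min, max (deg), points

CU_KALPHA_NM = 0.15418
MO_KALPHA_NM = 0.071073


def _q_axis():
    lo, hi, n = Q_GRID
    return np.linspace(lo, hi, n)


def _two_theta_axis():
    lo, hi, n = TWO_THETA_GRID
    return np.linspace(lo, hi, n)


def _gauss(x, center, sigma, area):
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def _apply_poisson(intensity, mean_counts, rng):
    """Poisson noise at a stated mean-count scale, returned on the
    original intensity scale."""
    mean_i = float(np.mean(intensity))
    if mean_i <= 0:
        return intensity
    scale = mean_counts / mean_i
    return rng.poisson(np.clip(intensity * scale, 0, None)) / scale


# ---------------------------------------------------------------------------
# lamellar (meridional) SAXS
# ---------------------------------------------------------------------------

@dataclass
class LamellarModelParams:
    """Two-phase lamellar stack: period ``long_period`` (nm) of which a
    fraction ``phase1_fraction`` is phase I."""

    long_period: float = 38.5
    phase1_fraction: float = 15.7 / 38.5
    n_orders: int = 5
    peak_width_sigma: float = 0.015   # nm⁻¹
    background_level: float = 0.0
    noise: str | None = None          # None | "poisson"
    mean_counts: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.phase1_fraction < 1.0):
            raise ValueError("phase1_fraction must be in (0, 1)")
        if self.long_period <= 0:
            raise ValueError("long_period must be positive")
        if not (1 <= self.n_orders <= 8):
            raise ValueError("n_orders must be in 1..8")
        if self.peak_width_sigma <= 0:
            raise ValueError("peak_width_sigma must be positive")


def square_wave_envelope(order, phase1_fraction):
    """Fourier intensity envelope of an ideal two-phase square wave:
    |c_n|² = [sin(nπφ)/(nπ)]²."""
    n = np.asarray(order, dtype=float)
    return (np.sin(n * np.pi * phase1_fraction) / (n * np.pi)) ** 2


def generate_saxs_meridional(params: LamellarModelParams,
                             wavelength=0.0709) -> Profile1D:
    """I(q) of a two-phase lamellar stack with harmonic peaks at
    qₙ = 2πn/L_p.

    The Kratky-space (q²I) integrated intensity of order n follows the
    square-wave Fourier envelope [sin(nπφ)/(nπ)]²; the corresponding
    I(q) peak areas therefore carry the 1/qₙ² one-dimensional Lorentz
    factor, which makes the cosine-transform correlation function of the
    generated profile agree with the direct autocorrelation of the
    generating square-wave density profile.
    """
    q = _q_axis()
    rng = np.random.default_rng(params.seed)
    orders = np.arange(1, params.n_orders + 1)
    qn = 2.0 * np.pi * orders / params.long_period
    env = square_wave_envelope(orders, params.phase1_fraction)
    suppressed = orders[env < 1e-12 * max(env.max(), 1e-300)]
    areas = env / qn**2
    intensity = np.full_like(q, float(params.background_level))
    for qc, a in zip(qn, areas):
        intensity += _gauss(q, qc, params.peak_width_sigma, a)
    truth = {
        "long_period_nm": params.long_period,
        "phase1_fraction": params.phase1_fraction,
        "phase1_thickness_nm": params.phase1_fraction * params.long_period,
        "phase2_thickness_nm": (1 - params.phase1_fraction) * params.long_period,
        "orders": orders.tolist(),
        "peak_positions_q": qn.tolist(),
        "kratky_envelope": env.tolist(),
        "suppressed_orders": suppressed.tolist(),
        "background_level": params.background_level,
    }
    if params.noise == "poisson":
        intensity = _apply_poisson(intensity, params.mean_counts, rng)
    return Profile1D(q, intensity, kind=KIND_Q, wavelength=wavelength,
                     meta={"truth": truth})


def generate_saxs_equatorial(bundle_thickness=150.0, fibril_spacing=4.7,
                             wavelength=CU_KALPHA_NM, instrumental_fwhm=0.0,
                             k_factor=0.9, amplitude=1.0,
                             background_level=0.0, noise=None,
                             mean_counts=1e4, seed=0) -> Profile1D:
    """Single equatorial fibril-packing peak at q = 2π/spacing whose
    FWHM is the quadrature sum of the finite-bundle (Scherrer) width and
    the instrumental broadening, both in nm⁻¹."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if fibril_spacing <= 0:
        raise ValueError("fibril_spacing must be positive")
    if bundle_thickness < fibril_spacing:
        raise ValueError("bundle_thickness must be >= fibril_spacing")
    q = _q_axis()
    qc = 2.0 * np.pi / fibril_spacing
    # Scherrer FWHM expressed in q: Δq = 2πK/d (independent of λ and θ)
    size_fwhm = 0.0 if np.isinf(bundle_thickness) else \
        2.0 * np.pi * k_factor / bundle_thickness
    fwhm_q = float(np.hypot(size_fwhm, instrumental_fwhm))
    sigma = fwhm_q / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_eval = max(sigma, 2.0 * (q[1] - q[0]))  # keep the peak resolvable
    intensity = background_level + _gauss(q, qc, sigma_eval, amplitude)
    if noise == "poisson":
        intensity = _apply_poisson(intensity, mean_counts,
                                   np.random.default_rng(seed))
    truth = {
        "bundle_thickness_nm": bundle_thickness,
        "fibril_spacing_nm": fibril_spacing,
        "peak_position_q": qc,
        "size_fwhm_q": size_fwhm,
        "instrumental_fwhm_q": instrumental_fwhm,
        "observed_fwhm_q": fwhm_q,
        "k_factor": k_factor,
    }
    return Profile1D(q, intensity, kind=KIND_Q, wavelength=wavelength,
                     meta={"truth": truth})


# ---------------------------------------------------------------------------
# WAXD
# ---------------------------------------------------------------------------

@dataclass
class WaxdPeak:
    """One diffraction component: position/width in degrees 2θ, ``chi``
    is the azimuth of the reflection from the meridian (90° = equator),
    None meaning isotropic."""

    center: float
    sigma: float
    area: float
    label: str = ""
    chi: float | None = 90.0


@dataclass
class WaxdModelParams:
    crystalline_peaks: list
    amorphous_peak: WaxdPeak
    crystallinity_true: float | None = None
    wavelength: float = CU_KALPHA_NM
    orientation_fwhm: float = 20.0   # degrees, azimuthal spread
    background_level: float = 0.0
    noise: str | None = None
    mean_counts: float = 1e4
    seed: int = 0

    def __post_init__(self):
        for p in list(self.crystalline_peaks) + [self.amorphous_peak]:
            if p.area < 0:
                raise ValueError("negative peak areas are not allowed")
            if p.sigma <= 0:
                raise ValueError("peak sigmas must be positive")
        ac = sum(p.area for p in self.crystalline_peaks)
        if self.crystallinity_true is None:
            total = ac + self.amorphous_peak.area
            self.crystallinity_true = ac / total if total > 0 else 0.0
        else:
            xc = self.crystallinity_true
            if not (0.0 <= xc <= 1.0):
                raise ValueError("crystallinity_true must be in [0, 1]")
            if xc == 0.0:
                if ac > 0:
                    raise ValueError(
                        "crystallinity_true=0 inconsistent with crystalline area"
                    )
            else:
                # rescale the amorphous area so Ac/(Ac+Aa) == crystallinity_true
                self.amorphous_peak.area = ac * (1.0 - xc) / xc


def default_waxd_params(crystallinity_true=0.44, cell: UnitCell = DEFAULT_CELL,
                        wavelength=CU_KALPHA_NM, orientation_fwhm=20.0,
                        seed=0, noise=None, mean_counts=1e4,
                        background_level=0.0) -> WaxdModelParams:
    """Seven-peak β-sheet inventory at the cell positions, with the
    amorphous halo scaled to the requested crystallinity."""
    positions = dict(reflection_positions(cell, wavelength))
    # relative areas and azimuth angles (from the meridian) per reflection
    inventory = [
        ("200", 30.0, 0.45, 90.0),
        ("210", 25.0, 0.50, 90.0),
        ("211", 12.0, 0.60, None),   # mixed index: broad azimuth placement
        ("002", 18.0, 0.50, 0.0),
        ("102+300", 10.0, 0.80, 70.0),
        ("202", 8.0, 0.70, 45.0),
    ]
    peaks = [
        WaxdPeak(center=positions[lbl], sigma=s, area=a, label=lbl, chi=chi)
        for lbl, a, s, chi in inventory
    ]
    # resolve the mixed-index azimuths from the cell geometry: cosχ = l·d/c
    chi_map = {"211": (2, 1, 1), "202": (2, 0, 2)}
    for pk in peaks:
        if pk.label in chi_map:
            h, k, l = chi_map[pk.label]
            d_nm = cell.d_spacing(h, k, l) / 10.0
            pk.chi = float(np.rad2deg(np.arccos(
                np.clip(l * d_nm / (cell.c / 10.0), -1.0, 1.0))))
    amorphous = WaxdPeak(center=20.6 * wavelength / CU_KALPHA_NM, sigma=3.5,
                         area=1.0, label="amorphous", chi=None)
    return WaxdModelParams(
        crystalline_peaks=peaks,
        amorphous_peak=amorphous,
        crystallinity_true=crystallinity_true,
        wavelength=wavelength,
        orientation_fwhm=orientation_fwhm,
        background_level=background_level,
        noise=noise,
        mean_counts=mean_counts,
        seed=seed,
    )


def generate_waxd_profile(params: WaxdModelParams) -> Profile1D:
    """Sum-of-Gaussians 2θ profile on the 10–37° grid; the recorded
    ground-truth crystallinity equals crystalline/total area exactly."""
    x = _two_theta_axis()
    lo, hi = x[0], x[-1]
    for p in params.crystalline_peaks:
        if not (lo <= p.center <= hi):
            raise ValueError(f"peak {p.label or p.center} outside the 2θ window")
    intensity = np.full_like(x, float(params.background_level))
    for p in list(params.crystalline_peaks) + [params.amorphous_peak]:
        intensity += _gauss(x, p.center, p.sigma, p.area)
    if params.noise == "poisson":
        intensity = _apply_poisson(intensity, params.mean_counts,
                                   np.random.default_rng(params.seed))
    ac = sum(p.area for p in params.crystalline_peaks)
    aa = params.amorphous_peak.area
    truth = {
        "crystallinity_true": params.crystallinity_true,
        "crystalline_area": ac,
        "amorphous_area": aa,
        "peaks": [
            {"label": p.label, "center": p.center, "sigma": p.sigma,
             "area": p.area}
            for p in list(params.crystalline_peaks) + [params.amorphous_peak]
        ],
        "background_level": params.background_level,
    }
    return Profile1D(x, intensity, kind=KIND_TWO_THETA,
                     wavelength=params.wavelength, meta={"truth": truth})


def _wrapped_azimuth_weight(az_deg, centers, fwhm):
    """Azimuthal weight: wrapped Gaussians at ``centers``, normalised to
    unit circular mean so azimuthal averaging recovers the 1D profile.
    ``fwhm >= 180`` or empty centers → isotropic (weight 1)."""
    if fwhm >= 180.0 or not centers:
        return np.ones_like(az_deg)
    sigma = max(fwhm, 0.5) / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def unnorm(a):
        out = np.zeros_like(a, dtype=float)
        for c in centers:
            for off in (-360.0, 0.0, 360.0):
                out += np.exp(-0.5 * ((a - c + off) / sigma) ** 2)
        return out

    fine = np.arange(-180.0, 180.0, 0.05)
    mean = float(np.mean(unnorm(fine)))
    return unnorm(az_deg) / mean


def generate_fiber_diagram(params: WaxdModelParams, image_shape=(1024, 1024),
                           beam_center=None, pixel_size=0.1,
                           camera_distance=60.0) -> FiberDiagram:
    """2D fibre diagram: each reflection sits on its 2θ ring with a
    Gaussian azimuthal profile of FWHM ``params.orientation_fwhm`` about
    its ideal azimuth (equatorial reflections about the equator, etc.).

    Azimuthal weights are normalised to unit circular mean, so a full
    azimuthal scan of the image reproduces the generating 1D profile.
    """
    nrow, ncol = image_shape
    if beam_center is None:
        beam_center = ((ncol - 1) / 2.0, (nrow - 1) / 2.0)
    diagram = FiberDiagram(
        image=np.zeros(image_shape), beam_center=beam_center,
        pixel_size=pixel_size, camera_distance=camera_distance,
        wavelength=params.wavelength,
    )
    tt = diagram.two_theta_map()
    az = diagram.azimuth_map()
    image = np.full(image_shape, float(params.background_level))
    for p in list(params.crystalline_peaks) + [params.amorphous_peak]:
        radial = _gauss(tt, p.center, p.sigma, p.area)
        if p.chi is None:
            weight = 1.0
        else:
            chi = p.chi
            if abs(chi - 90.0) < 1e-9:          # equatorial
                centers = [0.0, 180.0]
            elif abs(chi) < 1e-9:                # meridional
                centers = [90.0, -90.0]
            else:                                # four-quadrant spots
                centers = [90.0 - chi, 90.0 + chi, -90.0 + chi, -90.0 - chi]
            weight = _wrapped_azimuth_weight(az, centers,
                                             params.orientation_fwhm)
        image += radial * weight
    diagram.image = image
    diagram.meta = {"truth": {
        "orientation_fwhm_deg": params.orientation_fwhm,
        "orientation_index": max(0.0, (180.0 - params.orientation_fwhm) / 180.0),
        "crystallinity_true": params.crystallinity_true,
    }}
    return diagram


# ---------------------------------------------------------------------------
# tensile curves
# ---------------------------------------------------------------------------

@dataclass
class TensileModelParams:
    """Piecewise-linear elastic + strain-hardening stress model."""

    modulus: float = 28.1          # GPa
    yield_strain: float = 0.033
    hardening_slope: float = 5.0   # GPa
    fracture_strain: float = 0.32
    noise_sd: float = 0.0          # GPa
    n_points: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.modulus <= 0:
            raise ValueError("modulus must be positive")
        if not (0.0 < self.yield_strain <= self.fracture_strain):
            raise ValueError("require 0 < yield_strain <= fracture_strain")


def generate_stress_strain(params: TensileModelParams) -> StressStrainCurve:
    """σ(ε) = E·ε for ε ≤ ε_y, then σ_y + h·(ε − ε_y) to fracture.

    The strain grid includes the yield point exactly, so trapezoidal
    integration of the noiseless curve matches the closed-form toughness
    to machine precision.
    """
    eps = np.linspace(0.0, params.fracture_strain, params.n_points)
    eps = np.unique(np.append(eps, params.yield_strain))
    sigma_y = params.modulus * params.yield_strain
    stress = np.where(
        eps <= params.yield_strain,
        params.modulus * eps,
        sigma_y + params.hardening_slope * (eps - params.yield_strain),
    )
    strength = float(stress[-1])
    toughness_gpa = (
        0.5 * params.modulus * params.yield_strain**2
        + sigma_y * (params.fracture_strain - params.yield_strain)
        + 0.5 * params.hardening_slope
        * (params.fracture_strain - params.yield_strain) ** 2
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        stress = stress + rng.normal(0.0, params.noise_sd, size=stress.shape)
    truth = {
        "modulus_gpa": params.modulus,
        "yield_strain": params.yield_strain,
        "hardening_slope_gpa": params.hardening_slope,
        "strength_gpa": strength,
        "extensibility": params.fracture_strain,
        "toughness_mj_m3": toughness_gpa * GPA_STRAIN_TO_MJ_M3,
    }
    return StressStrainCurve(eps, stress, meta={"truth": truth})


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceModelParams:
    """Tandem-repeat architecture: each ~160-residue motif is a
    polyalanine block (PAB) followed by a non-polyalanine block (NPAB)
    that carries a short bulky-residue insert."""

    n_motifs: int = 5
    pab_length: int = 22
    npab_pre_insert_length: int = 45
    insert_length: int = 6
    npab_post_insert_length: int = 87
    gx_fraction: float = 0.5    # tile mix in the post-insert segment
    seed: int = 0

    def __post_init__(self):
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        for name in ("pab_length", "npab_pre_insert_length", "insert_length",
                     "npab_post_insert_length"):
            if getattr(self, name) < 0 or (name == "pab_length"
                                           and self.pab_length < 1):
                raise ValueError(f"{name} must be positive")

    @property
    def motif_length(self):
        return (self.pab_length + self.npab_pre_insert_length
                + self.insert_length + self.npab_post_insert_length)


# composition weights echoing the dipeptide/tripeptide chemistry:
# Gly-X with X Ala:Ser 60:40, Gly-Gly-X with X Ala:Tyr 60:40
GX_X_CHOICES = ("A", "S")
GX_X_WEIGHTS = (0.6, 0.4)
GGX_X_CHOICES = ("A", "Y")
GGX_X_WEIGHTS = (0.6, 0.4)
INSERT_CHOICES = ("S", "V", "Y")


def _gx_segment(length, rng):
    """Gly-X tiling of the requested length.  The final residue is forced
    to G or A so the segment never abuts the insert with an S/V/Y."""
    out = []
    while len(out) < length:
        out.append("G")
        if len(out) < length:
            out.append(rng.choice(GX_X_CHOICES, p=GX_X_WEIGHTS))
    seq = out[:length]
    if seq and seq[-1] == "S":
        seq[-1] = "A"
    return "".join(seq)


def _mixed_segment(length, gx_fraction, rng):
    """Mix of Gly-X and Gly-Gly-X tiles, chosen tile by tile.  The final
    residue is forced to G so the segment never extends a following
    polyalanine run."""
    out = []
    while len(out) < length:
        if rng.random() < gx_fraction:
            out.append("G")
            out.append(rng.choice(GX_X_CHOICES, p=GX_X_WEIGHTS))
        else:
            out.extend(["G", "G"])
            out.append(rng.choice(GGX_X_CHOICES, p=GGX_X_WEIGHTS))
    seq = out[:length]
    if seq and seq[-1] == "A":
        seq[-1] = "G"
    return "".join(seq)


def generate_sequences(params: SequenceModelParams, seq_id="synthetic_hfib"):
    """Build a tandem-repeat protein plus its ground-truth annotation.

    Returns ``(records, annotation)`` where ``records`` is a list with a
    single Bio.SeqRecord and ``annotation`` carries 1-based inclusive
    block coordinates for every generated motif.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(params.seed)
    chunks = []
    motifs = []
    pos = 0  # 0-based running offset
    for i in range(params.n_motifs):
        pab = "A" * params.pab_length
        pre = _gx_segment(params.npab_pre_insert_length, rng)
        insert = "".join(rng.choice(INSERT_CHOICES, size=params.insert_length))
        post = _mixed_segment(params.npab_post_insert_length, params.gx_fraction,
                              rng)
        motif_seq = pab + pre + insert + post
        start = pos + 1
        rec = {
            "index": i + 1,
            "pab_span": [start, start + params.pab_length - 1],
            "npab_span": [start + params.pab_length,
                          start + params.motif_length - 1],
            "motif_length": params.motif_length,
        }
        if params.insert_length > 0:
            ins0 = start + params.pab_length + params.npab_pre_insert_length
            rec["insert_span"] = [ins0, ins0 + params.insert_length - 1]
        else:
            rec["insert_span"] = None
        motifs.append(rec)
        chunks.append(motif_seq)
        pos += params.motif_length
    sequence = "".join(chunks)
    annotation = {
        "n_motifs": params.n_motifs,
        "motif_length": params.motif_length,
        "sequence_length": len(sequence),
        "motifs": motifs,
        "params": {
            "pab_length": params.pab_length,
            "npab_pre_insert_length": params.npab_pre_insert_length,
            "insert_length": params.insert_length,
            "npab_post_insert_length": params.npab_post_insert_length,
            "gx_fraction": params.gx_fraction,
            "seed": params.seed,
        },
    }
    record = SeqRecord(Seq(sequence), id=seq_id,
                       description="synthetic tandem-repeat fibroin")
    return [record], annotation
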