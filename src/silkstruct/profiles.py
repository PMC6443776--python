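"""Core scattering data containers and their plain-text / TIFF I/O.

Two containers are shared by every analysis stage:

* :class:`Profile1D` — a one-dimensional scattering trace, either a
  wide-angle ``2θ`` profile (degrees) or a small-angle ``q`` profile
  (nm⁻¹), always carrying the wavelength it was measured with.
* :class:`FiberDiagram` — a 2D detector image plus the geometry needed
  to map pixels to scattering angles (beam centre, pixel size, camera
  distance, wavelength).

Profiles are written as two-column delimited text with ``#`` header
lines; diagrams as 32-bit float TIFF with a JSON geometry sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Profile1D", "FiberDiagram", "q_from_two_theta", "two_theta_from_q"]

#: abscissa kinds understood by Profile1D
KIND_TWO_THETA = "two_theta"
KIND_Q = "q"


def q_from_two_theta(two_theta_deg, wavelength_nm):
    """Scattering vector q = (4π/λ)·sin(θ) in nm⁻¹ from 2θ in degrees."""
    theta = np.deg2rad(np.asarray(two_theta_deg, dtype=float)) / 2.0
    return 4.0 * np.pi / wavelength_nm * np.sin(theta)


def two_theta_from_q(q_nm, wavelength_nm):
    """Inverse of :func:`q_from_two_theta`; returns degrees."""
    q = np.asarray(q_nm, dtype=float)
    s = q * wavelength_nm / (4.0 * np.pi)
    if np.any(s > 1.0):
        raise ValueError("q out of range for this wavelength")
    return np.rad2deg(2.0 * np.arcsin(s))


@dataclass
class Profile1D:
    """A 1D scattering trace with abscissa metadata.

    Parameters
    ----------
    abscissa : array
        Strictly increasing; 2θ in degrees or q in nm⁻¹ per ``kind``.
    intensity : array
        Same length as ``abscissa``; must be finite.
    kind : {"two_theta", "q"}
    wavelength : float
        Wavelength in nm used to record the profile.
    meta : dict
        Free-form provenance (e.g. generator ground truth).
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: str
    wavelength: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in (KIND_TWO_THETA, KIND_Q):
            raise ValueError(f"unknown abscissa kind {self.kind!r}")
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.intensity.shape:
            raise ValueError("abscissa and intensity must be 1D arrays of equal length")
        if self.abscissa.size >= 2 and not np.all(np.diff(self.abscissa) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")

    # -- I/O ------------------------------------------------------------

    def write(self, path):
        path = Path(path)
        unit = "deg" if self.kind == KIND_TWO_THETA else "nm^-1"
        lines = [
            f"# kind: {self.kind}",
            f"# wavelength_nm: {self.wavelength:.8g}",
            f"# columns: abscissa({unit}) intensity",
        ]
        if self.meta:
            lines.append("# meta: " + json.dumps(self.meta, sort_keys=True))
        body = "\n".join(
            f"{x:.10g} {y:.10g}" for x, y in zip(self.abscissa, self.intensity)
        )
        path.write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def read(cls, path):
        path = Path(path)
        kind = None
        wavelength = None
        meta: dict = {}
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                payload = line[1:].strip()
                if payload.startswith("kind:"):
                    kind = payload.split(":", 1)[1].strip()
                elif payload.startswith("wavelength_nm:"):
                    wavelength = float(payload.split(":", 1)[1])
                elif payload.startswith("meta:"):
                    meta = json.loads(payload.split(":", 1)[1])
                continue
            parts = line.split()
            rows.append((float(parts[0]), float(parts[1])))
        if kind is None or wavelength is None:
            raise ValueError(f"{path}: missing kind/wavelength header")
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], kind=kind, wavelength=wavelength, meta=meta)


@dataclass
class FiberDiagram:
    """2D detector image with geometry for pixel → (2θ, azimuth) mapping.

    ``beam_center`` is (col, row) in pixels; ``pixel_size`` and
    ``camera_distance`` are in mm; ``wavelength`` in nm.  The fibre axis
    is vertical by default, so the equator runs horizontally and the
    azimuth is measured counter-clockwise from the +x (equatorial)
    direction, in (−180°, 180°].
    """

    image: np.ndarray
    beam_center: tuple
    pixel_size: float
    camera_distance: float
    wavelength: float
    fibre_axis: str = "vertical"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if not (self.camera_distance > 0):
            raise ValueError("camera_distance must be positive")
        if self.fibre_axis not in ("vertical", "horizontal"):
            raise ValueError("fibre_axis must be 'vertical' or 'horizontal'")
        cx, cy = self.beam_center
        nrow, ncol = self.image.shape
        if not (0 <= cx < ncol and 0 <= cy < nrow):
            raise ValueError("beam center outside image")

    # -- geometry maps ---------------------------------------------------

    def _pixel_offsets(self):
        cx, cy = self.beam_center
        nrow, ncol = self.image.shape
        x = (np.arange(ncol) - cx)[None, :] * self.pixel_size
        # image row 0 at top; +y points up on the detector
        y = (cy - np.arange(nrow))[:, None] * self.pixel_size
        if self.fibre_axis == "horizontal":
            x, y = y, -x  # rotate so the fibre axis is treated as vertical
        return x, y

    def two_theta_map(self):
        """Per-pixel scattering angle 2θ in degrees."""
        x, y = self._pixel_offsets()
        r = np.hypot(x, y)
        return np.rad2deg(np.arctan2(r, self.camera_distance))

    def azimuth_map(self):
        """Per-pixel azimuth in degrees, CCW from the equator, (−180, 180]."""
        x, y = self._pixel_offsets()
        return np.rad2deg(np.arctan2(y + np.zeros_like(x), x + np.zeros_like(y)))

    # -- I/O ------------------------------------------------------------

    def write(self, path):
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.image.astype(np.float32))
        sidecar = {
            "beam_center": list(self.beam_center),
            "pixel_size_mm": self.pixel_size,
            "camera_distance_mm": self.camera_distance,
            "wavelength_nm": self.wavelength,
            "fibre_axis": self.fibre_axis,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, path):
        import tifffile

        path = Path(path)
        image = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            image=image,
            beam_center=tuple(sidecar["beam_center"]),
            pixel_size=sidecar["pixel_size_mm"],
            camera_distance=sidecar["camera_distance_mm"],
            wavelength=sidecar["wavelength_nm"],
            fibre_axis=sidecar.get("fibre_axis", "vertical"),
            meta=sidecar.get("meta", {}),
        )
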