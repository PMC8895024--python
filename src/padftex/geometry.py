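"""Detector geometry, q calibration, polar remapping and file I/O.

Unit conventions used throughout the package:

* scattering-vector magnitude ``q`` in inverse nanometres,
* real-space distances ``r`` in nanometres,
* X-ray wavelength in angstroms,
* sample-to-detector distance in metres,
* pixel size in micrometres,
* ring radii on the detector in millimetres.

The azimuth ``phi`` is measured from the +x axis, counter-clockwise,
in radians internally (degrees only at CLI surfaces).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "DetectorGeometry",
    "PolarGrid",
    "PolarPattern",
    "q_of_radius",
    "radius_of_q",
    "calibrate_distance",
    "polar_remap",
    "beam_area_ratio",
    "measure_ring_radius",
    "read_image",
    "write_image",
    "read_geometry",
    "write_geometry",
    "read_polar_stack",
    "write_polar_stack",
    "default_polar_grid",
]

#: 1 angstrom^-1 expressed in nm^-1
_INV_ANGSTROM_TO_INV_NM = 10.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry for a small-angle scattering experiment.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in angstroms.
    distance : float
        Sample-to-detector distance in metres.
    pixel_size : float
        Square pixel edge in micrometres.
    beam_centre : tuple of float
        Beam centre ``(x, y)`` in fractional pixel coordinates.
    image_shape : tuple of int
        Detector image shape ``(ny, nx)``.
    """

    wavelength: float
    distance: float
    pixel_size: float
    beam_centre: tuple[float, float]
    image_shape: tuple[int, int]
    azimuth_origin: str = "+x,ccw"

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ny, nx = self.image_shape
        cx, cy = self.beam_centre
        if not (0 <= cx < nx and 0 <= cy < ny):
            raise ValueError("beam_centre must lie inside the image bounds")

    def with_distance(self, distance: float) -> "DetectorGeometry":
        return replace(self, distance=distance)


@dataclass(frozen=True)
class PolarGrid:
    """Polar (q, phi) sampling grid.

    ``q_values`` is strictly increasing (nm^-1); ``phi_values`` holds the
    ``n_phi`` uniform azimuth bin centres ``i * 2*pi/n_phi``; ``n_phi``
    must be even.
    """

    q_values: np.ndarray
    n_phi: int
    phi_values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        if q.ndim != 1 or q.size < 1:
            raise ValueError("q_values must be a 1-D array")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_values must be strictly increasing")
        if self.n_phi < 2 or self.n_phi % 2 != 0:
            raise ValueError("n_phi must be even and >= 2")
        object.__setattr__(self, "q_values", q)
        object.__setattr__(
            self, "phi_values", np.arange(self.n_phi) * (2.0 * np.pi / self.n_phi)
        )

    @property
    def n_q(self) -> int:
        return int(self.q_values.size)

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.n_phi


@dataclass
class PolarPattern:
    """One exposure's intensity on a (q, phi) grid.

    ``mask`` is boolean with ``True`` marking *masked* (invalid) bins.
    ``mean_subtracted`` is set once the per-q angular mean has been
    removed (see :func:`padftex.correlate.subtract_angular_mean`).
    """

    intensity: np.ndarray
    grid: PolarGrid
    mask: np.ndarray | None = None
    mean_subtracted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (self.grid.n_q, self.grid.n_phi)
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid {expected}"
            )
        if self.mask is None:
            self.mask = np.zeros(expected, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != expected:
                raise ValueError("mask shape does not match grid")
        valid = self.intensity[~self.mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("unmasked intensity must be finite")

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, ``True`` where the bin is usable."""
        return ~self.mask


# ---------------------------------------------------------------------------
# Forward / inverse geometry
# ---------------------------------------------------------------------------

def q_of_radius(radius: float | np.ndarray, geom: DetectorGeometry) -> float | np.ndarray:
    """Scattering-vector magnitude (nm^-1) at a detector radius (mm).

    Uses the exact flat-detector relation
    ``q = (4*pi/lambda) * sin(atan(radius/distance) / 2)``.
    """
    radius = np.asarray(radius, dtype=float)
    if np.any(radius < 0):
        raise ValueError("radius must be non-negative")
    radius_m = radius * 1e-3
    two_theta = np.arctan2(radius_m, geom.distance)
    q_inv_angstrom = (4.0 * np.pi / geom.wavelength) * np.sin(0.5 * two_theta)
    out = q_inv_angstrom * _INV_ANGSTROM_TO_INV_NM
    return float(out) if out.ndim == 0 else out


def radius_of_q(q: float | np.ndarray, geom: DetectorGeometry) -> float | np.ndarray:
    """Detector radius (mm) at scattering-vector magnitude ``q`` (nm^-1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    sin_theta = q / _INV_ANGSTROM_TO_INV_NM * geom.wavelength / (4.0 * np.pi)
    if np.any(sin_theta >= 1.0):
        raise ValueError("q is beyond the back-scattering limit for this wavelength")
    two_theta = 2.0 * np.arcsin(sin_theta)
    out = geom.distance * np.tan(two_theta) * 1e3
    return float(out) if out.ndim == 0 else out


def calibrate_distance(ring_radius: float, d_spacing: float, wavelength: float) -> float:
    """Sample-to-detector distance (m) from a calibrant ring.

    Parameters
    ----------
    ring_radius : float
        Measured ring radius on the detector, in mm.
    d_spacing : float
        Calibrant lattice spacing in angstroms (e.g. silver behenate
        d001 = 58.380 A).
    wavelength : float
        X-ray wavelength in angstroms.

    Returns
    -------
    float
        The unique distance such that the ring radius maps onto
        ``q = 2*pi/d_spacing``; exact inverse of :func:`q_of_radius`.
    """
    if ring_radius <= 0:
        raise ValueError("ring_radius must be positive")
    if d_spacing <= wavelength / 2.0:
        raise ValueError("non-physical calibrant: d_spacing must exceed wavelength/2")
    theta = math.asin(wavelength / (2.0 * d_spacing))
    return ring_radius * 1e-3 / math.tan(2.0 * theta)


def measure_ring_radius(
    image: np.ndarray,
    beam_centre: tuple[float, float],
    pixel_size: float,
    threshold_frac: float = 0.5,
) -> float:
    """Intensity-weighted centroid radius (mm) of a single diffraction ring.

    Pixels above ``threshold_frac`` of the image maximum contribute with
    their intensity as weight; suitable for calibrant frames that carry
    one dominant ring.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    cx, cy = beam_centre
    yy, xx = np.mgrid[0:ny, 0:nx]
    radii = np.hypot(xx - cx, yy - cy)
    sel = image >= threshold_frac * image.max()
    weight = image[sel].sum()
    if weight <= 0:
        raise ValueError("no intensity above threshold; cannot measure ring")
    radius_px = float((image[sel] * radii[sel]).sum() / weight)
    return radius_px * pixel_size * 1e-3


def beam_area_ratio(
    large_beam: tuple[float, float], small_beam: tuple[float, float]
) -> float:
    """Cross-sectional area ratio of two rectangular beams (same units).

    Worked example: a 25 x 250 um beam versus a 2 x 2 um microfocus beam
    gives a factor ``(25 * 250) / (2 * 2) = 1562.5``, i.e. the microbeam
    illuminates ~1500x less area (and proportionally fewer domains).
    """
    a = large_beam[0] * large_beam[1]
    b = small_beam[0] * small_beam[1]
    if a <= 0 or b <= 0:
        raise ValueError("beam dimensions must be positive")
    return a / b


# ---------------------------------------------------------------------------
# Polar remapping
# ---------------------------------------------------------------------------

def default_polar_grid(geom: DetectorGeometry, n_phi: int = 360) -> PolarGrid:
    """Polar grid whose q bin width is ~one pixel at the detector edge."""
    ny, nx = geom.image_shape
    cx, cy = geom.beam_centre
    edge = max(cx, nx - 1 - cx, cy, ny - 1 - cy)
    r_max_mm = edge * geom.pixel_size * 1e-3
    q_max = q_of_radius(r_max_mm, geom)
    n_q = max(2, int(round(edge)))
    dq = q_max / n_q
    q = dq * (np.arange(n_q) + 0.5)
    return PolarGrid(q_values=q, n_phi=n_phi)


def polar_remap(
    image: np.ndarray,
    geom: DetectorGeometry,
    grid: PolarGrid,
    mask: np.ndarray | None = None,
) -> PolarPattern:
    """Resample a detector image onto a (q, phi) grid.

    Bilinear interpolation at each polar bin centre; a polar bin is
    flagged masked when more than 50% of its (interpolated) footprint is
    masked or falls outside the detector.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(geom.image_shape):
        raise ValueError("image shape does not match geometry")
    if mask is None:
        mask = np.zeros_like(image, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if mask.all():
        raise ValueError("empty pattern: image is fully masked")

    radius_mm = radius_of_q(grid.q_values, geom)
    radius_px = np.asarray(radius_mm) / (geom.pixel_size * 1e-3)
    cx, cy = geom.beam_centre
    # sample coordinates: rows are q, columns are phi
    xs = cx + np.outer(radius_px, np.cos(grid.phi_values))
    ys = cy + np.outer(radius_px, np.sin(grid.phi_values))
    coords = np.stack([ys.ravel(), xs.ravel()])

    filled = np.where(mask, 0.0, image)
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    good = ndimage.map_coordinates(
        (~mask).astype(float), coords, order=1, mode="constant", cval=0.0
    )
    shape = (grid.n_q, grid.n_phi)
    vals = vals.reshape(shape)
    good = good.reshape(shape)
    out_mask = good <= 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(out_mask, 0.0, vals / np.where(good > 0, good, 1.0))
    if out_mask.all():
        raise ValueError("empty pattern: no polar bin has unmasked support")
    return PolarPattern(intensity=intensity, grid=grid, mask=out_mask)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a detector frame from TIFF."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        return np.asarray(tifffile.imread(path))
    except Exception as exc:  # pragma: no cover - depends on corrupt input
        raise ValueError(f"could not parse TIFF {path}: {exc}") from exc


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    tifffile.imwrite(os.fspath(path), np.asarray(image))


def write_geometry(path: str | os.PathLike, geom: DetectorGeometry) -> None:
    """Write geometry as a plain-text key=value config."""
    with open(path, "w") as fh:
        fh.write(f"wavelength = {geom.wavelength!r}\n")
        fh.write(f"distance = {geom.distance!r}\n")
        fh.write(f"pixel_size = {geom.pixel_size!r}\n")
        fh.write(f"beam_centre_x = {geom.beam_centre[0]!r}\n")
        fh.write(f"beam_centre_y = {geom.beam_centre[1]!r}\n")
        fh.write(f"image_ny = {geom.image_shape[0]}\n")
        fh.write(f"image_nx = {geom.image_shape[1]}\n")


def read_geometry(path: str | os.PathLike) -> DetectorGeometry:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"geometry file not found: {path}")
    kv: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            kv[key] = float(value)
    try:
        return DetectorGeometry(
            wavelength=kv["wavelength"],
            distance=kv["distance"],
            pixel_size=kv["pixel_size"],
            beam_centre=(kv["beam_centre_x"], kv["beam_centre_y"]),
            image_shape=(int(kv["image_ny"]), int(kv["image_nx"])),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing geometry key {exc}") from exc


def write_polar_stack(
    path: str | os.PathLike,
    patterns: list[PolarPattern],
    truth: dict[str, np.ndarray] | None = None,
    meta: dict | None = None,
) -> None:
    """Write a stack of polar patterns to HDF5.

    Layout: ``/intensity [n_d, n_q, n_phi]``, ``/mask`` (True = masked),
    ``/q``, ``/phi``, optional ``/truth/*`` ground-truth arrays and
    ``/meta`` attributes.
    """
    if not patterns:
        raise ValueError("cannot write an empty stack")
    grid = patterns[0].grid
    for p in patterns[1:]:
        if p.grid.n_q != grid.n_q or p.grid.n_phi != grid.n_phi:
            raise ValueError("all patterns must share one grid")
    with h5py.File(os.fspath(path), "w") as fh:
        fh.create_dataset(
            "intensity", data=np.stack([p.intensity for p in patterns])
        )
        fh.create_dataset("mask", data=np.stack([p.mask for p in patterns]))
        fh.create_dataset("q", data=grid.q_values)
        fh.create_dataset("phi", data=grid.phi_values)
        g = fh.create_group("meta")
        for key, val in (meta or {}).items():
            g.attrs[key] = val
        if truth:
            t = fh.create_group("truth")
            for key, val in truth.items():
                t.create_dataset(key, data=np.asarray(val))


def read_polar_stack(
    path: str | os.PathLike,
) -> tuple[list[PolarPattern], dict[str, np.ndarray], dict]:
    """Inverse of :func:`write_polar_stack` (lossless round trip)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"polar stack not found: {path}")
    try:
        with h5py.File(path, "r") as fh:
            intensity = fh["intensity"][...]
            mask = fh["mask"][...]
            q = fh["q"][...]
            n_phi = fh["phi"].shape[0]
            meta = dict(fh["meta"].attrs) if "meta" in fh else {}
            truth = {}
            if "truth" in fh:
                truth = {k: fh["truth"][k][...] for k in fh["truth"]}
    except OSError as exc:
        raise ValueError(f"could not parse HDF5 {path}: {exc}") from exc
    grid = PolarGrid(q_values=q, n_phi=int(n_phi))
    patterns = [
        PolarPattern(intensity=intensity[k], grid=grid, mask=mask[k].astype(bool))
        for k in range(intensity.shape[0])
    ]
    return patterns, truth, meta
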