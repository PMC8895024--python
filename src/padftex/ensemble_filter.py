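"""Ensemble curation: radial profiles, phase identification, lattice
filtering, profile agreement and azimuthal orientation mapping.

The pipeline reduces each exposure to a 1D intensity-versus-q profile,
keeps hexagonal-phase exposures whose lattice parameter sits within a
tolerance of the ensemble average, scores each profile against the
ensemble mean with an L1 agreement factor, and fits the azimuthal
intensity around the strongest ring to locate any twofold orientation
preference.  Per-exposure fits are arranged into orientation maps over
the scan grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .geometry import PolarPattern

__all__ = [
    "ProfileRecord",
    "OrientationFit",
    "OrientationMap",
    "radial_profile",
    "identify_phase",
    "lattice_filter",
    "profile_agreement",
    "azimuthal_orientation_fit",
    "build_orientation_map",
]

SQRT3 = float(np.sqrt(3.0))


@dataclass
class ProfileRecord:
    """Reduced 1D record for one exposure."""

    exposure_id: int
    profile: np.ndarray
    q_values: np.ndarray
    peak_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase: str = "unclassified"
    lattice_a: float = float("nan")
    r_k: float = float("nan")
    keep: bool = True


@dataclass
class OrientationFit:
    """Twofold azimuthal orientation fit result (angles in degrees)."""

    magnitude: float
    phi_max_deg: float
    ok: bool


@dataclass
class OrientationMap:
    """Scan-grid maps of modulation magnitude and peak angle (degrees,
    folded to [0, 180)); ``omitted`` marks unusable pixels."""

    magnitude: np.ndarray
    phi_max_deg: np.ndarray
    omitted: np.ndarray


def radial_profile(p: PolarPattern) -> np.ndarray:
    """Azimuthal mean over unmasked bins per q; fully masked rows are NaN."""
    valid = p.valid
    counts = valid.sum(axis=1)
    sums = np.where(valid, p.intensity, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def identify_phase(
    profile: np.ndarray,
    q_values: np.ndarray,
    tolerance: float = 0.02,
    prominence_frac: float = 0.05,
    min_separation: int = 3,
) -> tuple[str, float]:
    """Classify a radial profile by its peak-position ratios.

    Local maxima above ``prominence_frac`` of the profile maximum (and
    at least ``min_separation`` bins apart) are detected; the profile is
    hexagonal when peaks at ratios 1 : sqrt(3) (: 2) are present within
    ``tolerance``.  Returns ``(label, lattice parameter)`` with
    ``a = 4*pi/(sqrt(3)*q10)``; the lattice parameter is NaN unless the
    phase is hexagonal.  Missing higher orders are allowed as long as
    both the (10) and (11) peaks are found.
    """
    profile = np.asarray(profile, dtype=float)
    finite = np.nan_to_num(profile, nan=0.0)
    if finite.max() <= 0:
        return "empty", float("nan")
    peaks, _props = find_peaks(
        finite,
        prominence=prominence_frac * finite.max(),
        distance=min_separation,
    )
    if peaks.size == 0:
        return "empty", float("nan")
    q_peaks = np.asarray(q_values, dtype=float)[peaks]
    # try the strongest peak first: the (10) reflection dominates
    q_peaks = q_peaks[np.argsort(-finite[peaks])]
    for q10 in q_peaks:
        ratios = q_peaks / q10
        has_11 = np.any(np.abs(ratios - SQRT3) <= tolerance * SQRT3)
        if has_11:
            a = 4.0 * np.pi / (SQRT3 * q10)
            return "hexagonal", float(a)
    return "unknown", float("nan")


def lattice_filter(
    records: list[ProfileRecord], tolerance: float = 0.05
) -> list[ProfileRecord]:
    """Iteratively drop lattice-parameter outliers.

    The mean lattice parameter over kept hexagonal records is computed,
    records deviating by more than ``tolerance`` (relative) are dropped,
    and the procedure repeats until the keep set is stable.  The result
    does not depend on record order.
    """
    hexes = [r for r in records if r.phase == "hexagonal" and np.isfinite(r.lattice_a)]
    if not hexes:
        raise ValueError("no hexagonal records to filter")
    for r in records:
        r.keep = r in hexes
    while True:
        kept = [r for r in hexes if r.keep]
        if not kept:
            raise ValueError("no consistent ensemble: all records dropped")
        mean_a = float(np.mean([r.lattice_a for r in kept]))
        changed = False
        for r in hexes:
            keep = abs(r.lattice_a - mean_a) / mean_a <= tolerance
            if keep != r.keep:
                r.keep = keep
                changed = True
        if not changed:
            return records


def profile_agreement(profile: np.ndarray, reference: np.ndarray) -> float:
    """L1 profile agreement factor ``sum|I - ref| / sum(ref)``.

    Zero for identical profiles; equals ``|c - 1|`` for a profile that
    is ``c`` times the reference.
    """
    profile = np.asarray(profile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if profile.shape != reference.shape:
        raise ValueError("profile and reference must share a q grid")
    good = np.isfinite(profile) & np.isfinite(reference)
    norm = np.abs(reference[good]).sum()
    if norm == 0:
        raise ValueError("zero-norm reference profile")
    return float(np.abs(profile[good] - reference[good]).sum() / norm)


def azimuthal_orientation_fit(
    ring: np.ndarray,
    mask: np.ndarray | None = None,
    degree: int = 6,
    min_bins: int = 14,
) -> OrientationFit:
    """Magnitude and peak angle of a twofold azimuthal modulation.

    The ring profile (uniform bins over [0, 360) degrees) is folded to
    [0, 180), cyclically shifted so the coarse maximum sits mid-range
    (which keeps the fit well behaved near the fold boundary), and
    interpolated with a least-squares polynomial of ``degree``.  The
    fitted peak angle is the polynomial argmax mapped back to the
    original frame; the magnitude is ``(max - min) / mean`` of the
    polynomial.  Flat or degenerate rings are flagged not-ok.
    """
    ring = np.asarray(ring, dtype=float)
    n = ring.size
    if n % 2 != 0:
        raise ValueError("ring must have an even number of azimuth bins")
    half = n // 2
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    valid = ~np.asarray(mask, dtype=bool)

    num = np.where(valid, ring, 0.0)[:half] + np.where(valid, ring, 0.0)[half:]
    cnt = valid[:half].astype(int) + valid[half:].astype(int)
    good = cnt > 0
    if good.sum() < min_bins:
        return OrientationFit(float("nan"), float("nan"), ok=False)
    folded = np.where(good, num / np.maximum(cnt, 1), np.nan)

    # centre the coarse maximum to avoid split peaks at the fold boundary
    coarse = int(np.nanargmax(folded))
    shift = half // 2 - coarse
    rolled = np.roll(folded, shift)
    angles = np.arange(half) * (180.0 / half)
    sel = np.isfinite(rolled)
    try:
        poly = np.polynomial.Polynomial.fit(angles[sel], rolled[sel], deg=degree)
    except np.linalg.LinAlgError:
        return OrientationFit(float("nan"), float("nan"), ok=False)
    dense = np.linspace(0.0, 180.0 - 1e-9, 4 * half)
    values = poly(dense)
    mean = values.mean()
    if mean == 0:
        return OrientationFit(float("nan"), float("nan"), ok=False)
    magnitude = float((values.max() - values.min()) / mean)
    phi = float((dense[np.argmax(values)] - shift * (180.0 / half)) % 180.0)
    if magnitude < 1e-6:
        return OrientationFit(magnitude, float("nan"), ok=False)
    return OrientationFit(magnitude, phi, ok=True)


def build_orientation_map(
    fits: list[OrientationFit], shape: tuple[int, int]
) -> OrientationMap:
    """Arrange per-exposure fits (raster order) into scan-grid maps."""
    ny, nx = shape
    if len(fits) != ny * nx:
        raise ValueError("number of fits does not match the scan shape")
    magnitude = np.full(ny * nx, np.nan)
    phi = np.full(ny * nx, np.nan)
    omitted = np.ones(ny * nx, dtype=bool)
    for i, fit in enumerate(fits):
        if fit.ok:
            magnitude[i] = fit.magnitude
            phi[i] = fit.phi_max_deg
            omitted[i] = False
    return OrientationMap(
        magnitude=magnitude.reshape(shape),
        phi_max_deg=phi.reshape(shape),
        omitted=omitted.reshape(shape),
    )
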