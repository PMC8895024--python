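"""Synthetic textured diffraction ensembles.

Two rendering schemes are provided:

* ``rings`` — a smooth powder-like ring profile whose azimuthal
  intensity is modulated by a pole density (uniform, twofold sinusoidal
  or twofold periodic Lorentzian) with a per-exposure random peak angle.
* ``domains`` — a sparse sum of ``n_domains`` single-crystal 2D
  hexagonal patterns, each contributing Gaussian Bragg spots at its
  symmetry-equivalent azimuths, with in-plane orientations drawn from
  the pole density.

All orientations live in the detector plane; the simulator is strictly
two-dimensional.  Every exposure draws its own peak angle ``phi_max``
uniformly on [0, 2pi), so the ensemble is microtextured but carries no
macroscopic texture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import PolarGrid, PolarPattern

__all__ = [
    "HexLattice2D",
    "OrientationModel",
    "SimConfig",
    "pole_density",
    "sample_orientations",
    "domain_pattern",
    "ring_modulation_pattern",
    "hex_ring_profile",
    "simulate_ensemble",
]

_TABLE_SIZE = 4096


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to [-pi, pi)."""
    return np.angle(np.exp(1j * np.asarray(angle, dtype=float)))


@dataclass(frozen=True)
class HexLattice2D:
    """2D hexagonal lattice reflection list.

    ``a`` is the lattice parameter in nm; ``q10 = 4*pi/(sqrt(3)*a)``.
    ``peak_list`` holds ``(label, q, azimuthal offsets, rel. intensity)``
    with (10)-family peaks at multiples of 60 degrees and (11)-family
    peaks rotated by 30 degrees.
    """

    a: float
    intensities: dict = field(
        default_factory=lambda: {"10": 1.0, "11": 0.4, "20": 0.15}
    )

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("lattice parameter must be positive")
        unknown = set(self.intensities) - {"10", "11", "20"}
        if unknown:
            raise ValueError(f"unknown reflection labels: {sorted(unknown)}")

    @property
    def q10(self) -> float:
        return 4.0 * np.pi / (np.sqrt(3.0) * self.a)

    @property
    def peak_list(self) -> list[tuple[str, float, np.ndarray, float]]:
        sixfold = np.deg2rad(np.arange(0, 360, 60, dtype=float))
        ratio = {"10": 1.0, "11": np.sqrt(3.0), "20": 2.0}
        offset0 = {"10": 0.0, "11": np.pi / 6.0, "20": 0.0}
        return [
            (label, ratio[label] * self.q10, sixfold + offset0[label], rel)
            for label, rel in self.intensities.items()
        ]

    @staticmethod
    def from_q10(q10: float, **kwargs) -> "HexLattice2D":
        return HexLattice2D(a=4.0 * np.pi / (np.sqrt(3.0) * q10), **kwargs)


@dataclass(frozen=True)
class OrientationModel:
    """Pole-distribution family for in-plane crystal orientations.

    kind
        ``uniform``, ``sinusoidal`` (twofold, amplitude ``epsilon``) or
        ``lorentzian`` (twofold periodic, half-width ``gamma`` radians).
    epsilon
        Deviation-from-uniformity amplitude; the sinusoidal density is
        ``(1 + 2*eps*cos 2(phi - phi_max)) / 2pi`` and requires
        ``eps <= 1/2`` for non-negativity.
    gamma
        Half-width of the periodic Lorentzian peaks (at ``phi_max`` and
        ``phi_max + pi``); the density is normalized numerically.
    """

    kind: str = "uniform"
    epsilon: float = 0.0
    gamma: float = 0.35

    def __post_init__(self) -> None:
        if self.kind not in {"uniform", "sinusoidal", "lorentzian"}:
            raise ValueError(f"unknown orientation model kind: {self.kind!r}")
        if self.kind == "sinusoidal":
            if not 0.0 <= self.epsilon <= 0.5:
                raise ValueError(
                    "sinusoidal epsilon must lie in [0, 1/2] (density >= 0)"
                )
        if self.kind == "lorentzian" and self.gamma <= 0:
            raise ValueError("lorentzian gamma must be positive")


def pole_density(
    model: OrientationModel, phi: float | np.ndarray, phi_max: float = 0.0
) -> float | np.ndarray:
    """Pole probability density (per radian) at azimuth ``phi``.

    All densities integrate to 1 over [0, 2pi) and the textured families
    are twofold periodic: ``density(phi) == density(phi + pi)``.
    """
    phi = np.asarray(phi, dtype=float)
    if model.kind == "uniform":
        out = np.full(phi.shape, 1.0 / (2.0 * np.pi))
    elif model.kind == "sinusoidal":
        out = (1.0 + 2.0 * model.epsilon * np.cos(2.0 * (phi - phi_max))) / (
            2.0 * np.pi
        )
    else:
        out = _lorentzian_raw(phi - phi_max, model.gamma) / _lorentzian_norm(
            model.gamma
        )
    return float(out) if out.ndim == 0 else out


def _lorentzian_raw(delta: np.ndarray, gamma: float) -> np.ndarray:
    total = np.zeros(np.shape(delta))
    for peak in (0.0, np.pi):
        d = _wrap(np.asarray(delta) - peak)
        total = total + 1.0 / (1.0 + (d / gamma) ** 2)
    return total


def _lorentzian_norm(gamma: float) -> float:
    # dense trapezoid quadrature over one period
    grid = np.linspace(0.0, 2.0 * np.pi, _TABLE_SIZE + 1)
    return float(np.trapezoid(_lorentzian_raw(grid, gamma), grid))


def sample_orientations(
    model: OrientationModel,
    n: int,
    phi_max: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. orientations from the pole density.

    Sampling is by inverse-CDF lookup on a 4096-point table, so results
    are reproducible for a given generator or seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    u = rng.random(n)
    if model.kind == "uniform":
        return u * 2.0 * np.pi
    grid = np.linspace(0.0, 2.0 * np.pi, _TABLE_SIZE + 1)
    dens = pole_density(model, grid, phi_max=0.0)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    draws = np.interp(u, cdf, grid)
    return np.mod(draws + phi_max, 2.0 * np.pi)


def _azimuthal_combs(
    centres: np.ndarray,
    phi_values: np.ndarray,
    sigma_phi: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of wrapped Gaussians at ``centres`` evaluated on ``phi_values``."""
    delta = _wrap(phi_values[None, :] - centres[:, None])
    peaks = np.exp(-0.5 * (delta / sigma_phi) ** 2)
    if weights is not None:
        peaks = peaks * weights[:, None]
    return peaks.sum(axis=0)


def _clamped_sigma_phi(sigma_phi: float, grid: PolarGrid) -> float:
    half_bin = 0.5 * grid.dphi
    if sigma_phi < half_bin:
        warnings.warn(
            f"sigma_phi={sigma_phi:.4g} rad is below half an azimuth bin; "
            f"clamping to {half_bin:.4g}",
            stacklevel=3,
        )
        return half_bin
    return sigma_phi


def domain_pattern(
    lattice: HexLattice2D,
    orientation: float,
    grid: PolarGrid,
    sigma_q: float = 0.05,
    sigma_phi: float = np.deg2rad(2.0),
) -> PolarPattern:
    """Diffraction pattern of a single hexagonal domain.

    A sum of Gaussian peaks at ``(q_hk, offset + orientation)`` over the
    reflection families; the (10) ring carries six peaks.
    """
    if sigma_q <= 0 or sigma_phi <= 0:
        raise ValueError("peak widths must be positive")
    sigma_phi = _clamped_sigma_phi(sigma_phi, grid)
    intensity = _render_domains(
        lattice, np.array([orientation]), grid, sigma_q, sigma_phi
    )
    return PolarPattern(intensity=intensity, grid=grid,
                        meta={"orientation": float(orientation)})


def _render_domains(
    lattice: HexLattice2D,
    orientations: np.ndarray,
    grid: PolarGrid,
    sigma_q: float,
    sigma_phi: float,
    model: OrientationModel | None = None,
    phi_max: float = 0.0,
) -> np.ndarray:
    """Sum of domain patterns for many orientations (vectorized).

    When a textured ``model`` is given, every Bragg spot is weighted by
    ``2*pi * pole_density(spot azimuth)``: the exposure-averaged ring
    intensity then follows the pole distribution directly, which is what
    couples a twofold pole density to the sixfold-symmetric (10) comb
    and produces the quadratic-in-``n_domains`` texture term on top of
    the linear self term.  A uniform model gives unit weights.
    """
    q = grid.q_values
    out = np.zeros((grid.n_q, grid.n_phi))
    weighted = model is not None and model.kind != "uniform"
    for _label, q_hk, offsets, rel in lattice.peak_list:
        radial = rel * np.exp(-0.5 * ((q - q_hk) / sigma_q) ** 2)
        if not np.any(radial > 1e-12):
            continue
        centres = (orientations[:, None] + offsets[None, :]).ravel()
        weights = None
        if weighted:
            weights = 2.0 * np.pi * np.asarray(
                pole_density(model, centres, phi_max)
            )
        comb = _azimuthal_combs(centres, grid.phi_values, sigma_phi, weights)
        out += np.outer(radial, comb)
    return out


def hex_ring_profile(
    lattice: HexLattice2D, q_values: np.ndarray, sigma_q: float = 0.05
) -> np.ndarray:
    """Smooth hexagonal-phase powder profile on a q grid (ratios 1:sqrt3:2)."""
    q = np.asarray(q_values, dtype=float)
    out = np.zeros_like(q)
    for _label, q_hk, _offsets, rel in lattice.peak_list:
        out += rel * np.exp(-0.5 * ((q - q_hk) / sigma_q) ** 2)
    return out


def ring_modulation_pattern(
    ring_profile: np.ndarray,
    model: OrientationModel,
    phi_max: float,
    grid: PolarGrid,
    rng: np.random.Generator | None = None,
    photon_scale: float | None = None,
) -> PolarPattern:
    """Ring pattern with azimuthal texture modulation.

    ``I(q, phi) = ring_profile(q) * 2pi * pole_density(phi; phi_max)``,
    optionally Poisson-sampled at ``photon_scale`` expected total counts.
    """
    profile = np.asarray(ring_profile, dtype=float)
    if profile.shape != (grid.n_q,):
        raise ValueError("ring_profile must match the q grid")
    if np.any(profile < 0):
        raise ValueError("ring_profile must be non-negative")
    modulation = 2.0 * np.pi * np.asarray(pole_density(model, grid.phi_values, phi_max))
    intensity = np.outer(profile, modulation)
    if photon_scale is not None:
        if rng is None:
            rng = np.random.default_rng()
        total = intensity.sum()
        if total <= 0:
            raise ValueError("cannot apply Poisson noise to an all-zero pattern")
        scale = photon_scale / total
        intensity = rng.poisson(intensity * scale).astype(float) / scale
    return PolarPattern(intensity=intensity, grid=grid, meta={"phi_max": float(phi_max)})


@dataclass(frozen=True)
class SimConfig:
    """Ensemble simulation parameters.

    ``n_domains`` is the number of crystals illuminated per exposure
    (the texture term grows like its square, the nanostructure term
    linearly); ``n_patterns`` the number of exposures.
    """

    n_domains: int = 10
    n_patterns: int = 100
    sigma_q: float = 0.05
    sigma_phi: float = np.deg2rad(2.0)
    mode: str = "domains"
    photon_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if self.sigma_q <= 0 or self.sigma_phi <= 0:
            raise ValueError("peak widths must be positive")
        if self.mode not in {"rings", "domains"}:
            raise ValueError("mode must be 'rings' or 'domains'")


def simulate_ensemble(
    config: SimConfig,
    lattice: HexLattice2D,
    model: OrientationModel,
    grid: PolarGrid,
) -> tuple[list[PolarPattern], dict[str, np.ndarray]]:
    """Simulate a textured diffraction ensemble with ground truth.

    Every exposure draws a fresh ``phi_max`` uniformly on [0, 2pi).  In
    ``domains`` mode each exposure sums ``n_domains`` single-crystal
    patterns with orientations drawn from the pole density; in ``rings``
    mode each exposure is one modulated ring pattern.  Randomness flows
    from ``config.seed`` through per-exposure child generators, so any
    single frame is reproducible.

    Returns the pattern stack and a truth table with per-exposure
    ``phi_max`` (and domain ``orientations`` in domains mode).
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_patterns)
    sigma_phi = _clamped_sigma_phi(config.sigma_phi, grid)

    patterns: list[PolarPattern] = []
    phi_max_truth = np.empty(config.n_patterns)
    orientations_truth = (
        np.empty((config.n_patterns, config.n_domains))
        if config.mode == "domains"
        else None
    )
    ring_profile = (
        hex_ring_profile(lattice, grid.q_values, config.sigma_q)
        if config.mode == "rings"
        else None
    )

    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        phi_max = rng.uniform(0.0, 2.0 * np.pi)
        phi_max_truth[k] = phi_max
        if config.mode == "rings":
            p = ring_modulation_pattern(
                ring_profile, model, phi_max, grid,
                rng=rng, photon_scale=config.photon_scale,
            )
        else:
            orientations = sample_orientations(
                model, config.n_domains, phi_max=phi_max, rng=rng
            )
            orientations_truth[k] = orientations
            intensity = _render_domains(
                lattice, orientations, grid, config.sigma_q, sigma_phi,
                model=model, phi_max=phi_max,
            )
            if config.photon_scale is not None:
                total = intensity.sum()
                scale = config.photon_scale / total
                intensity = rng.poisson(intensity * scale).astype(float) / scale
            p = PolarPattern(intensity=intensity, grid=grid,
                             meta={"phi_max": phi_max})
        p.meta["exposure"] = k
        patterns.append(p)

    truth: dict[str, np.ndarray] = {"phi_max": phi_max_truth}
    if orientations_truth is not None:
        truth["orientations"] = orientations_truth
    return patterns, truth
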