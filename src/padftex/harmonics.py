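"""Legendre/spherical-harmonic analysis of correlation volumes.

This module extracts the even-order harmonic matrices ``B_l(q, q')``
from an angular correlation volume by least squares (SVD pseudo-inverse
of the Legendre design matrix), synthesizes correlations back from
them, and implements the texture theory: pole-spectrum coefficients
``Q_l``, predicted texture and nanostructure contributions with their
``n_c**2`` versus ``n_c`` scalings, the balance ratio between them, and
the sparse-ensemble scaling experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import eval_legendre

from .correlate import CorrelationVolume, average_correlations, correlate_pattern, subtract_angular_mean
from .geometry import PolarGrid
from .simulate import (
    HexLattice2D,
    OrientationModel,
    SimConfig,
    pole_density,
    simulate_ensemble,
)

__all__ = [
    "read_bl",
    "write_bl",
    "BlMatrices",
    "PoleSpectrum",
    "BalanceReport",
    "ScalingResult",
    "legendre_design",
    "correlation_to_bl",
    "bl_to_correlation",
    "bl_power",
    "pole_to_ql",
    "predict_texture_bl",
    "predict_nanostructure_bl",
    "balance_ratio",
    "ring_texture_components",
    "ring_local_maxima",
    "tune_lorentzian_width",
    "scaling_experiment",
]

# Scale constant tying the azimuthal pole-spectrum coefficients to the
# measured harmonic matrices: for a twofold sinusoidal modulation the
# ensemble correlation is exactly (Q_2**2 * 3/8) * P_2-synthesized, so
# predictions and measurements share one convention.
_TEXTURE_SCALE = 3.0 / 8.0


@dataclass
class BlMatrices:
    """Even-order harmonic matrices ``B_l(q, q')``.

    ``matrices[i]`` corresponds to ``l_values[i]``; every matrix is
    symmetric in ``q <-> q'``.  ``provenance`` is one of ``measured``,
    ``predicted_texture`` or ``predicted_nanostructure``.
    """

    l_values: np.ndarray
    matrices: np.ndarray
    q_values: np.ndarray
    provenance: str = "measured"

    def __post_init__(self) -> None:
        self.l_values = np.asarray(self.l_values, dtype=int)
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        if np.any(self.l_values % 2 != 0):
            raise ValueError("only even l orders are supported")
        n_q = self.q_values.size
        if self.matrices.shape != (self.l_values.size, n_q, n_q):
            raise ValueError("matrices must have shape (n_l, n_q, n_q)")

    def matrix(self, l: int) -> np.ndarray:
        idx = np.nonzero(self.l_values == l)[0]
        if idx.size == 0:
            raise KeyError(f"l={l} not present")
        return self.matrices[idx[0]]

    def scaled(self, factor: float, provenance: str | None = None) -> "BlMatrices":
        return BlMatrices(
            l_values=self.l_values.copy(),
            matrices=self.matrices * factor,
            q_values=self.q_values.copy(),
            provenance=provenance or self.provenance,
        )


@dataclass
class PoleSpectrum:
    """Even-order Legendre coefficients of the pole-density modulation."""

    l_values: np.ndarray
    q_l: np.ndarray
    model: OrientationModel | None = None

    def coefficient(self, l: int) -> float:
        idx = np.nonzero(np.asarray(self.l_values) == l)[0]
        if idx.size == 0:
            raise KeyError(f"l={l} not present")
        return float(self.q_l[idx[0]])


@dataclass
class BalanceReport:
    """Texture-versus-nanostructure angular power balance at ``n_c``."""

    power_c: float
    power_t: float
    n_c: float
    ratio: float
    crossover_nc: float


# ---------------------------------------------------------------------------
# Legendre design and inversion
# ---------------------------------------------------------------------------

def legendre_design(
    dphi_values: np.ndarray,
    l_values: np.ndarray,
    mapping: str = "smallangle",
    q: float | None = None,
    wavelength: float | None = None,
) -> np.ndarray:
    """Design matrix of Legendre polynomials on an angle grid.

    Entry ``(i, j)`` is ``P_{l_j}(cos theta3d(dphi_i))``.  With the
    default small-angle mapping ``theta3d = dphi``; with ``ewald`` the
    out-of-plane tilt ``sin(alpha) = q * lambda / 4 pi`` of the Ewald
    sphere is applied (``q`` in nm^-1, ``wavelength`` in angstroms):
    ``cos theta3d = sin^2(alpha) + cos^2(alpha) * cos(dphi)``.
    """
    dphi = np.asarray(dphi_values, dtype=float)
    ls = np.asarray(l_values, dtype=int)
    if mapping == "smallangle":
        x = np.cos(dphi)
    elif mapping == "ewald":
        if q is None or wavelength is None:
            raise ValueError("ewald mapping requires q and wavelength")
        wavelength_nm = wavelength / 10.0
        sin_a = q * wavelength_nm / (4.0 * np.pi)
        if abs(sin_a) >= 1.0:
            raise ValueError("q beyond Ewald-sphere limit")
        cos2 = 1.0 - sin_a**2
        x = sin_a**2 + cos2 * np.cos(dphi)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return np.stack([eval_legendre(l, x) for l in ls], axis=1)


def correlation_to_bl(
    vol: CorrelationVolume,
    l_max: int = 12,
    svd_cutoff: float = 1e-6,
    mapping: str = "smallangle",
    wavelength: float | None = None,
) -> BlMatrices:
    """Extract even-order ``B_l(q, q')`` from a correlation volume.

    Per (q, q') the least-squares Legendre coefficients are obtained
    through an SVD pseudo-inverse with singular values below
    ``svd_cutoff`` times the largest discarded.  The result is
    symmetrized in ``q <-> q'``.
    """
    if l_max % 2 != 0:
        raise ValueError("l_max must be even")
    if vol.n_phi < 2 * l_max:
        raise ValueError("n_phi must be at least 2 * l_max")
    ls = np.arange(0, l_max + 1, 2)
    dphi = vol.dphi_values

    def solve(values: np.ndarray, design: np.ndarray) -> np.ndarray:
        s = np.linalg.svd(design, compute_uv=False)
        if not np.any(s > svd_cutoff * s[0]):
            raise ValueError("design matrix entirely below the SVD cutoff")
        pinv = np.linalg.pinv(design, rcond=svd_cutoff)
        return values @ pinv.T

    n_q = vol.n_q
    coeffs = np.empty((n_q, n_q, ls.size))
    if mapping == "smallangle" and vol.valid.all():
        design = legendre_design(dphi, ls)
        coeffs = solve(vol.values.reshape(n_q * n_q, -1), design).reshape(
            n_q, n_q, ls.size
        )
    else:
        for i in range(n_q):
            for j in range(n_q):
                design = legendre_design(
                    dphi,
                    ls,
                    mapping=mapping,
                    q=float(np.sqrt(vol.q_values[i] * vol.q_values[j])),
                    wavelength=wavelength,
                )
                good = vol.valid[i, j]
                if not good.any():
                    coeffs[i, j] = 0.0
                    continue
                coeffs[i, j] = solve(vol.values[i, j][good], design[good])
    matrices = np.transpose(coeffs, (2, 0, 1))
    matrices = 0.5 * (matrices + np.transpose(matrices, (0, 2, 1)))
    return BlMatrices(
        l_values=ls, matrices=matrices, q_values=vol.q_values, provenance="measured"
    )


def bl_to_correlation(
    bl: BlMatrices,
    n_phi: int,
    mapping: str = "smallangle",
    wavelength: float | None = None,
) -> CorrelationVolume:
    """Synthesize ``C(q, q', dphi) = sum_l B_l(q, q') P_l(cos theta3d)``."""
    dphi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    if mapping == "smallangle":
        design = legendre_design(dphi, bl.l_values)
        values = np.einsum("lij,dl->ijd", bl.matrices, design)
    else:
        n_q = bl.q_values.size
        values = np.empty((n_q, n_q, n_phi))
        for i in range(n_q):
            for j in range(n_q):
                design = legendre_design(
                    dphi,
                    bl.l_values,
                    mapping=mapping,
                    q=float(np.sqrt(bl.q_values[i] * bl.q_values[j])),
                    wavelength=wavelength,
                )
                values[i, j] = design @ bl.matrices[:, i, j]
    return CorrelationVolume(
        values=values,
        q_values=bl.q_values,
        n_d=1,
        mean_subtracted=bool(np.all(bl.l_values != 0) or True),
    )


def bl_power(bl: BlMatrices) -> pd.DataFrame:
    """Per-order angular power and fractions relative to l = 2.

    ``power_l = sum_{q,q'} B_l(q,q')**2``; fractions exclude l = 0
    (removed by mean subtraction).
    """
    powers = np.sum(bl.matrices**2, axis=(1, 2))
    ls = bl.l_values
    idx2 = np.nonzero(ls == 2)[0]
    if idx2.size == 0 or powers[idx2[0]] == 0:
        raise ValueError("l = 2 power is zero or absent; fractions undefined")
    p2 = powers[idx2[0]]
    frac = np.where(ls == 0, np.nan, powers / p2)
    return pd.DataFrame({"l": ls, "power": powers, "fraction_of_l2": frac})


def write_bl(path, bl: BlMatrices) -> None:
    """HDF5 layout: /bl/l{l} matrices, /q, provenance attribute."""
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("bl")
        for i, l in enumerate(bl.l_values):
            grp.create_dataset(f"l{int(l)}", data=bl.matrices[i])
        fh.create_dataset("q", data=bl.q_values)
        fh.attrs["provenance"] = bl.provenance


def read_bl(path) -> BlMatrices:
    import h5py

    with h5py.File(path, "r") as fh:
        ls = sorted(int(k[1:]) for k in fh["bl"])
        mats = np.stack([fh["bl"][f"l{l}"][...] for l in ls])
        return BlMatrices(
            l_values=np.array(ls), matrices=mats, q_values=fh["q"][...],
            provenance=str(fh.attrs.get("provenance", "measured")),
        )


# ---------------------------------------------------------------------------
# Texture theory
# ---------------------------------------------------------------------------

def pole_to_ql(
    model: OrientationModel, l_max: int = 12, n_points: int = 4096
) -> PoleSpectrum:
    """Even-order Legendre spectrum of the pole-density modulation.

    The dimensionless modulation ``2*pi*density(phi) - 1`` is projected
    onto ``P_l(cos phi)`` by least squares on a dense uniform azimuth
    grid (>= 512 points).  A uniform model gives all zeros; a twofold
    sinusoidal model populates l = 2 only (cos 2phi lies exactly in the
    span of P_0 and P_2).
    """
    if n_points < 512:
        raise ValueError("n_points must be >= 512")
    ls = np.arange(0, l_max + 1, 2)
    phi = np.arange(n_points) * (2.0 * np.pi / n_points)
    modulation = 2.0 * np.pi * np.asarray(pole_density(model, phi, 0.0)) - 1.0
    design = legendre_design(phi, ls)
    coef, *_ = np.linalg.lstsq(design, modulation, rcond=None)
    coef[np.abs(coef) < 1e-12] = 0.0
    return PoleSpectrum(l_values=ls, q_l=coef, model=model)


def predict_texture_bl(
    spectrum: PoleSpectrum,
    ring_profile: np.ndarray,
    q_values: np.ndarray,
    n_c: float,
) -> BlMatrices:
    """Predicted preferred-orientation contribution.

    ``B_t,l(q, q') = (3/8) * n_c**2 * Q_l**2 * I0(q) * I0(q')`` for
    l >= 2, with ``I0`` the isotropic single-domain ring profile.  The
    scale constant makes the prediction exact for twofold sinusoidal
    modulations, so measured and predicted matrices are comparable.
    The quadratic ``n_c`` dependence is what lets a weak orientation
    preference dominate when many domains are illuminated.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    profile = np.asarray(ring_profile, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    if profile.shape != q_values.shape:
        raise ValueError("ring_profile must match q_values")
    outer = np.outer(profile, profile)
    ls = np.asarray(spectrum.l_values, dtype=int)
    mats = np.zeros((ls.size, q_values.size, q_values.size))
    for i, l in enumerate(ls):
        if l == 0:
            continue
        mats[i] = _TEXTURE_SCALE * (n_c**2) * spectrum.q_l[i] ** 2 * outer
    return BlMatrices(
        l_values=ls, matrices=mats, q_values=q_values,
        provenance="predicted_texture",
    )


def predict_nanostructure_bl(single_domain_bl: BlMatrices, n_c: float) -> BlMatrices:
    """Predicted nanostructure contribution: ``n_c`` times the single-domain
    harmonic matrices (linear in the number of illuminated domains)."""
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    return single_domain_bl.scaled(float(n_c), provenance="predicted_nanostructure")


def _angular_power(bl: BlMatrices) -> float:
    """Total angular power, linear in the B_l matrices (trace over q of
    the l >= 2 orders)."""
    total = 0.0
    for i, l in enumerate(bl.l_values):
        if l == 0:
            continue
        total += float(np.abs(np.trace(bl.matrices[i])))
    return total


def balance_ratio(
    texture_bl: BlMatrices, nanostructure_bl: BlMatrices, n_c: float
) -> BalanceReport:
    """Balance of texture and nanostructure angular powers at ``n_c``.

    Both inputs must be predictions evaluated at the same ``n_c``.  The
    ratio ``power_t / power_c`` grows linearly with ``n_c`` (quadratic
    over linear term), so the crossover count solves ``ratio = 1``.
    """
    power_t = _angular_power(texture_bl)
    power_c = _angular_power(nanostructure_bl)
    if power_c == 0:
        raise ValueError("zero nanostructure power; ratio undefined")
    ratio = power_t / power_c
    crossover = np.inf if ratio == 0 else n_c / ratio
    return BalanceReport(
        power_c=power_c, power_t=power_t, n_c=n_c, ratio=ratio,
        crossover_nc=crossover,
    )


# ---------------------------------------------------------------------------
# Sparse-ensemble scaling experiment
# ---------------------------------------------------------------------------

def ring_texture_components(
    ring_corr: np.ndarray,
    comb_period_deg: float = 60.0,
    exclusion_deg: float = 10.0,
) -> tuple[float, float]:
    """Split a (10)-ring correlation row into texture and comb components.

    The smooth texture part is the order-2 cosine amplitude fitted on
    azimuth lags away from the 60-degree comb peaks; the nanostructure
    part is the mean height of the comb peaks (multiples of 60 degrees,
    excluding 0) after removing the fitted smooth component.
    """
    n = ring_corr.size
    dphi_deg = np.arange(n) * (360.0 / n)
    frac = np.abs(((dphi_deg + comb_period_deg / 2) % comb_period_deg)
                  - comb_period_deg / 2)
    away = frac > exclusion_deg
    if away.sum() < 8:
        raise ValueError("exclusion window leaves too few angles")
    rad = np.deg2rad(dphi_deg)
    design = np.stack(
        [np.ones(n), np.cos(2 * rad), np.sin(2 * rad)], axis=1
    )
    coef, *_ = np.linalg.lstsq(design[away], ring_corr[away], rcond=None)
    texture = float(coef[1])
    residual = ring_corr - design @ coef
    peak_angles = np.arange(comb_period_deg, 360.0, comb_period_deg)
    idx = np.rint(peak_angles / (360.0 / n)).astype(int) % n
    nano = float(residual[idx].mean())
    return texture, nano


def ring_local_maxima(
    ring_corr: np.ndarray,
    interval_deg: tuple[float, float] = (10.0, 350.0),
    prominence_frac: float = 0.1,
) -> np.ndarray:
    """Angles (degrees) of prominent local maxima of a ring correlation.

    Only lags strictly inside ``interval_deg`` are considered;
    prominence is relative to the correlation range on that interval.
    """
    from scipy.signal import find_peaks

    ring_corr = np.asarray(ring_corr, dtype=float)
    n = ring_corr.size
    deg = np.arange(n) * (360.0 / n)
    lo, hi = interval_deg
    sel = (deg > lo) & (deg < hi)
    window = ring_corr[sel]
    span = window.max() - window.min()
    if span <= 0:
        return np.empty(0)
    peaks, _ = find_peaks(window, prominence=prominence_frac * span)
    return deg[sel][peaks]


def tune_lorentzian_width(
    target_fraction: float,
    lattice: HexLattice2D,
    grid: PolarGrid,
    l_max: int = 8,
    sigma_q: float = 0.06,
    bounds: tuple[float, float] = (0.05, 2.0),
) -> OrientationModel:
    """Lorentzian half-width whose ring-mode l = 4 power fraction hits a
    target.

    The ring-mode ensemble correlation is independent of the per-exposure
    peak angle, so a single noise-free pattern determines the harmonic
    content exactly; the width is found by bisection on the monotone
    (decreasing) l = 4 fraction.
    """
    from scipy.optimize import brentq

    from .simulate import hex_ring_profile, ring_modulation_pattern

    profile = hex_ring_profile(lattice, grid.q_values, sigma_q)

    def frac4(gamma: float) -> float:
        model = OrientationModel(kind="lorentzian", gamma=gamma)
        p = ring_modulation_pattern(profile, model, 0.0, grid)
        vol = average_correlations([subtract_angular_mean(p)])
        table = bl_power(correlation_to_bl(vol, l_max=l_max))
        return float(table.loc[table["l"] == 4, "fraction_of_l2"].iloc[0])

    gamma = brentq(lambda g: frac4(g) - target_fraction, *bounds, xtol=1e-4)
    return OrientationModel(kind="lorentzian", gamma=float(gamma))


@dataclass
class ScalingResult:
    """Fitted log-log exponents of the texture and nanostructure
    correlation components versus domain count."""

    texture_exponent: float
    nanostructure_exponent: float
    table: pd.DataFrame = field(repr=False, default=None)


def scaling_experiment(
    nc_list: list[int],
    model: OrientationModel,
    reps: int = 200,
    seed: int = 0,
    lattice: HexLattice2D | None = None,
    grid: PolarGrid | None = None,
    sigma_phi: float = np.deg2rad(2.0),
) -> ScalingResult:
    """Measure how texture and nanostructure correlations scale with n_c.

    For each domain count, ``reps`` sparse-domain exposures are
    simulated (per-exposure random peak angle), ensemble-correlated on
    the (10) ring, and split into the smooth order-2 texture component
    and the 60-degree-comb nanostructure component.  Log-log slopes of
    component versus domain count are returned; theory predicts 2 for
    texture and 1 for nanostructure.
    """
    if len(set(nc_list)) < 3:
        raise ValueError("need at least 3 distinct n_c values")
    if lattice is None:
        lattice = HexLattice2D(a=5.0, intensities={"10": 1.0})
    if grid is None:
        grid = PolarGrid(q_values=np.array([lattice.q10]), n_phi=360)
    iq10 = int(np.argmin(np.abs(grid.q_values - lattice.q10)))

    rows = []
    master = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0]) for s in master.spawn(len(nc_list))]
    for nc, sub in zip(nc_list, sub_seeds):
        config = SimConfig(
            n_domains=int(nc), n_patterns=reps, sigma_phi=sigma_phi,
            mode="domains", seed=sub,
        )
        patterns, _truth = simulate_ensemble(config, lattice, model, grid)
        vol = average_correlations(
            [subtract_angular_mean(p) for p in patterns]
        )
        texture, nano = ring_texture_components(vol.values[iq10, iq10])
        rows.append({"n_c": nc, "texture": texture, "nanostructure": nano})
    table = pd.DataFrame(rows)

    def fit(column: str) -> float:
        vals = table[column].to_numpy()
        if np.any(vals <= 0):
            return float("nan")
        slope, _ = np.polyfit(np.log(table["n_c"]), np.log(vals), 1)
        return float(slope)

    return ScalingResult(
        texture_exponent=fit("texture"),
        nanostructure_exponent=fit("nanostructure"),
        table=table,
    )
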