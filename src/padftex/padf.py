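"""Real-space pair-angle distribution functions.

The q-space harmonic matrices ``B_l(q, q')`` are carried to real space
with a spherical Bessel transform applied to both variables, and the
volume ``Theta(r, r', theta)`` is assembled as the Legendre-weighted
sum over even orders.  The overall scale of the volume is arbitrary;
outputs are normalized to ``max |Theta| = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, spherical_jn

from .harmonics import BlMatrices, legendre_design

__all__ = [
    "PADFVolume",
    "sbt_matrix",
    "bl_qq_to_rr",
    "assemble_padf",
    "padf_from_blqq",
    "slice_requal",
    "blrr_profile",
]


@dataclass
class PADFVolume:
    """Pair-angle distribution volume ``Theta(r, r', theta)``.

    ``volume`` has shape ``(n_r, n_r, n_theta)``; ``bl_rr`` holds the
    per-order real-space matrices it was assembled from.  ``r_min_resolved``
    marks the transform resolution bound ``2*pi/q_max`` below which
    diagonal features are not trustworthy.
    """

    r_values: np.ndarray
    theta_values: np.ndarray
    volume: np.ndarray
    bl_rr: BlMatrices | None = None
    r_min_resolved: float = 0.0

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.theta_values = np.asarray(self.theta_values, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n_r = self.r_values.size
        if self.volume.shape != (n_r, n_r, self.theta_values.size):
            raise ValueError("volume must have shape (n_r, n_r, n_theta)")


def sbt_matrix(l: int, q_values: np.ndarray, r_values: np.ndarray) -> np.ndarray:
    """Spherical Bessel transform matrix for order ``l``.

    Entry ``(i, j) = j_l(q_j * r_i) * q_j**2 * w_j`` with trapezoid
    weights ``w_j`` on the q grid; applying it to both sides of a
    ``B_l(q, q')`` matrix performs the double radial transform.
    """
    q = np.asarray(q_values, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if q.ndim != 1 or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    w = np.empty_like(q)
    if q.size == 1:
        w[:] = 1.0
    else:
        w[1:-1] = 0.5 * (q[2:] - q[:-2])
        w[0] = 0.5 * (q[1] - q[0])
        w[-1] = 0.5 * (q[-1] - q[-2])
    return spherical_jn(l, np.outer(r, q)) * (q**2 * w)


def bl_qq_to_rr(bl: BlMatrices, r_values: np.ndarray) -> BlMatrices:
    """Transform harmonic matrices to real space: ``M_l B_l M_l^T``.

    Symmetry in the two radial variables is preserved exactly.
    """
    r = np.asarray(r_values, dtype=float)
    out = np.empty((bl.l_values.size, r.size, r.size))
    for i, l in enumerate(bl.l_values):
        m = sbt_matrix(int(l), bl.q_values, r)
        out[i] = m @ bl.matrices[i] @ m.T
    return BlMatrices(
        l_values=bl.l_values.copy(), matrices=out, q_values=r,
        provenance=bl.provenance,
    )


def padf_from_blqq(
    bl: BlMatrices,
    r_values: np.ndarray,
    theta_values: np.ndarray | None = None,
) -> PADFVolume:
    """Full q-space-to-real-space chain for measured harmonic matrices.

    Performs the double radial transform and Legendre assembly, and
    stamps the volume with the resolution bound ``2*pi/q_max`` so the
    strongest-diagonal search ignores sub-resolution radii.
    """
    out = assemble_padf(bl_qq_to_rr(bl, r_values), theta_values)
    out.r_min_resolved = 2.0 * np.pi / float(np.max(bl.q_values))
    return out


def assemble_padf(
    bl_rr: BlMatrices,
    theta_values: np.ndarray | None = None,
    include_l0: bool = False,
    normalize: bool = True,
) -> PADFVolume:
    """Assemble ``Theta(r, r', theta) = sum_l B_l(r, r') P_l(cos theta)``.

    Even orders only; l = 0 is omitted by default because mean-subtracted
    correlations carry no isotropic term.  When ``normalize`` the volume
    is scaled to ``max |Theta| = 1`` (the absolute scale is arbitrary).
    """
    if theta_values is None:
        theta_values = np.linspace(0.0, np.pi, 181)
    theta = np.asarray(theta_values, dtype=float)
    keep = np.ones(bl_rr.l_values.size, dtype=bool)
    if not include_l0:
        keep &= bl_rr.l_values != 0
    legendre = np.stack(
        [eval_legendre(int(l), np.cos(theta)) for l in bl_rr.l_values[keep]], axis=0
    )
    volume = np.einsum("lij,lt->ijt", bl_rr.matrices[keep], legendre)
    scale = np.max(np.abs(volume))
    if normalize and scale > 0:
        volume = volume / scale
    return PADFVolume(
        r_values=bl_rr.q_values,  # radial grid of the real-space matrices
        theta_values=theta,
        volume=volume,
        bl_rr=bl_rr,
    )


def slice_requal(padf: PADFVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Diagonal slice ``Theta(r = r', theta)`` and its strongest row.

    Returns ``(slice, profile, i_r)`` where ``slice`` has shape
    ``(n_r, n_theta)``, ``profile`` is the theta profile at the r bin of
    maximum diagonal intensity and ``i_r`` its index.  Rows below the
    ``r_min_resolved`` bound of the volume are excluded from the
    strongest-row search (but kept in the slice).
    """
    n_r = padf.r_values.size
    diag = padf.volume[np.arange(n_r), np.arange(n_r), :]
    allowed = padf.r_values >= padf.r_min_resolved
    if not allowed.any():
        allowed = np.ones(n_r, dtype=bool)
    strength = np.where(allowed, np.max(np.abs(diag), axis=1), -np.inf)
    i_r = int(np.argmax(strength))
    return diag, diag[i_r], i_r


def blrr_profile(padf: PADFVolume) -> dict[int, np.ndarray]:
    """Per-order diagonals ``B_l(r = r)`` normalized to the l = 2 peak.

    Returns curves for every l >= 2 present, each divided by
    ``max |B_2(r, r)|``.
    """
    if padf.bl_rr is None:
        raise ValueError("volume carries no per-order matrices")
    bl = padf.bl_rr
    diags = {
        int(l): np.diagonal(bl.matrices[i]).copy()
        for i, l in enumerate(bl.l_values)
        if l >= 2
    }
    if 2 not in diags or np.max(np.abs(diags[2])) == 0:
        raise ValueError("l = 2 diagonal absent or zero")
    norm = np.max(np.abs(diags[2]))
    return {l: d / norm for l, d in diags.items()}
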