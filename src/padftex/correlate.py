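"""Mean-subtracted angular intensity correlations and ensemble averaging.

For each exposure ``k`` the angular mean is removed per q ring and the
same-exposure angular cross-correlation

``C_k(q, q', dphi) = (1/n_valid) * sum_phi I~(q, phi) I~(q', phi + dphi)``

is accumulated over azimuth pairs where both bins are unmasked.  The
ensemble correlation volume is the arithmetic mean over exposures.
Correlations are computed by circular (FFT) convolution; equality with
the direct double sum is a standing unit test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import PolarGrid, PolarPattern

__all__ = [
    "PolarPattern",
    "CorrelationVolume",
    "subtract_angular_mean",
    "correlate_pattern",
    "average_correlations",
    "write_correlation",
    "read_correlation",
]


@dataclass
class CorrelationVolume:
    """Ensemble-averaged angular correlation C(q, q', dphi).

    ``values`` has shape ``(n_q, n_q, n_phi)``; ``valid`` is False where
    no valid azimuth pair ever contributed.  ``n_d`` records the number
    of exposures averaged.
    """

    values: np.ndarray
    q_values: np.ndarray
    n_d: int
    mean_subtracted: bool = True
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must have shape (n_q, n_q, n_phi)")
        if self.values.shape[0] != self.q_values.size:
            raise ValueError("q_values length does not match values")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)

    @property
    def n_q(self) -> int:
        return self.values.shape[0]

    @property
    def n_phi(self) -> int:
        return self.values.shape[2]

    @property
    def dphi_values(self) -> np.ndarray:
        return np.arange(self.n_phi) * (2.0 * np.pi / self.n_phi)

    def diagonal(self, iq: int) -> np.ndarray:
        """C(q_i, q_i, dphi) row."""
        return self.values[iq, iq]


def subtract_angular_mean(p: PolarPattern) -> PolarPattern:
    """Remove the per-q angular mean over unmasked bins.

    Masked bins are set to zero; a fully masked q row is flagged masked
    everywhere (and excluded downstream).
    """
    valid = p.valid
    counts = valid.sum(axis=1)
    sums = np.where(valid, p.intensity, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    out = np.where(valid, p.intensity - means[:, None], 0.0)
    mask = p.mask.copy()
    mask[counts == 0, :] = True
    return PolarPattern(
        intensity=out,
        grid=p.grid,
        mask=mask,
        mean_subtracted=True,
        meta=dict(p.meta),
    )


def _cross_correlate_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs circular cross-correlation along the last axis.

    Returns ``out[i, j, d] = sum_phi a[i, phi] * b[j, phi + d]``.
    """
    n = a.shape[1]
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    spec = np.conj(fa)[:, None, :] * fb[None, :, :]
    return np.fft.irfft(spec, n=n, axis=2)


def correlate_pattern(p: PolarPattern) -> CorrelationVolume:
    """Same-exposure correlation grid of a mean-subtracted pattern.

    Normalization is per valid angular pair (mask aware), which makes
    masked and unmasked ensembles comparable.  Entries with zero valid
    pairs are flagged invalid.
    """
    if not p.mean_subtracted:
        raise ValueError("correlate_pattern expects a mean-subtracted pattern")
    data = np.where(p.valid, p.intensity, 0.0)
    num = _cross_correlate_rows(data, data)
    if not p.mask.any():
        counts = np.full(num.shape, float(p.grid.n_phi))
    else:
        valid = p.valid.astype(float)
        counts = np.rint(_cross_correlate_rows(valid, valid))
    ok = counts > 0.5
    values = np.where(ok, num / np.maximum(counts, 1.0), 0.0)
    return CorrelationVolume(
        values=values,
        q_values=p.grid.q_values,
        n_d=1,
        mean_subtracted=True,
        valid=ok,
    )


def average_correlations(stack: list[PolarPattern]) -> CorrelationVolume:
    """Ensemble-averaged correlation volume over exposures.

    Each exposure contributes its per-valid-pair-normalized correlation;
    the average at each (q, q', dphi) runs over the exposures for which
    that entry was valid.
    """
    if not stack:
        raise ValueError("empty stack")
    total = None
    count = None
    q_values = stack[0].grid.q_values
    for p in stack:
        if p.grid.q_values.shape != q_values.shape or not np.allclose(
            p.grid.q_values, q_values
        ):
            raise ValueError("all patterns must share one q grid")
        c = correlate_pattern(p)
        if total is None:
            total = np.where(c.valid, c.values, 0.0)
            count = c.valid.astype(np.int64)
        else:
            total += np.where(c.valid, c.values, 0.0)
            count += c.valid
    ok = count > 0
    values = np.where(ok, total / np.maximum(count, 1), 0.0)
    return CorrelationVolume(
        values=values,
        q_values=q_values,
        n_d=len(stack),
        mean_subtracted=True,
        valid=ok,
    )


def write_correlation(path: str | os.PathLike, vol: CorrelationVolume) -> None:
    """HDF5 layout: /corr [n_q, n_q, n_phi], /q, /dphi, /n_d, /valid."""
    with h5py.File(os.fspath(path), "w") as fh:
        fh.create_dataset("corr", data=vol.values)
        fh.create_dataset("q", data=vol.q_values)
        fh.create_dataset("dphi", data=vol.dphi_values)
        fh.create_dataset("n_d", data=vol.n_d)
        fh.create_dataset("valid", data=vol.valid)
        fh.attrs["mean_subtracted"] = vol.mean_subtracted


def read_correlation(path: str | os.PathLike) -> CorrelationVolume:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"correlation file not found: {path}")
    with h5py.File(path, "r") as fh:
        return CorrelationVolume(
            values=fh["corr"][...],
            q_values=fh["q"][...],
            n_d=int(fh["n_d"][()]),
            mean_subtracted=bool(fh.attrs.get("mean_subtracted", True)),
            valid=fh["valid"][...].astype(bool) if "valid" in fh else None,
        )
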