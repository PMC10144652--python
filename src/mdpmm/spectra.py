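"""Binned, Gaussian-broadened CD and UV spectra from per-frame PMM records.

Per transition k, the vertical excitation frequencies collected over the
trajectory are histogrammed into bins of middle value nu_ref; each occupied
bin carries its frame count n(nu_ref) and the bin-mean rotational strength
<R_k> (cgs).  The molar CD band of the 0->k transition is

    d_eps_0k(nu) = sum_bins <R_k> * nu / 2.296e-39 * n(nu_ref)/N
                   * exp(-(nu-nu_ref)^2 / (2 sigma^2)) / sqrt(2 pi sigma^2)

and the full spectrum is the sum over transitions.  The Gaussian supplies
the broadening of the classical vibrations that the vertical-transition
picture discards; sigma is a user input.  The UV absorption analogue
replaces <R_k> with the bin-mean dipole strength <|mu_0k|^2> and the
prefactor with the companion constant 9.184e-39.

Frequencies are wavenumbers (cm^-1) internally; curves also expose a
wavelength axis in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import units
from .electronic import ValidationError
from .pmm import PerturbedRecord

__all__ = [
    "BinTable",
    "SpectrumCurve",
    "bin_transitions",
    "cd_curve",
    "uv_curve",
    "combine_spectra",
    "wavelength_window",
    "transition_weight_report",
]


@dataclass
class BinTable:
    """Per-transition occupancy bins of vertical excitation frequencies.

    ``bin_centers[k]``, ``bin_counts[k]`` and ``bin_mean[k]`` list the
    occupied bins of transition k (0-based over excited states).  ``bin_mean``
    is the bin-average rotational strength for CD, or dipole strength for UV,
    in cgs.  ``n_frames`` is the total frame count N in the band weights.
    """

    bin_centers: list[np.ndarray]
    bin_counts: list[np.ndarray]
    bin_mean: list[np.ndarray]
    n_frames: int
    bin_width: float  # cm^-1

    @property
    def n_transitions(self) -> int:
        return len(self.bin_centers)


@dataclass
class SpectrumCurve:
    """A molar CD (or extinction) curve on a fixed wavenumber grid."""

    grid: np.ndarray            # cm^-1
    values: np.ndarray          # delta-eps or eps, M^-1 cm^-1
    sigma: float                # cm^-1
    n_frames: int = 0
    label: str = ""
    kind: str = "cd"            # "cd" or "uv"
    per_transition: np.ndarray | None = None  # (n_k, n_grid)
    weights: np.ndarray | None = None         # set by combine_spectra

    @property
    def wavelength_nm(self) -> np.ndarray:
        return units.cm1_to_nm(self.grid)


def bin_transitions(records: Iterable[PerturbedRecord],
                    bin_width: float = 200.0,
                    k_max: int | None = None,
                    quantity: str = "R") -> BinTable:
    """Histogram per-transition excitation frequencies over a trajectory.

    ``bin_width`` is in cm^-1; bin edges are aligned to integer multiples of
    it so that the binning is independent of frame order.  ``quantity`` picks
    the bin-averaged observable: ``"R"`` (rotational strength, for CD) or
    ``"D"`` (dipole strength, for UV).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if quantity not in ("R", "D"):
        raise ValidationError(f"unknown quantity {quantity!r}")
    # streaming accumulation: per transition, {bin index: [count, value sum]}
    acc: list[dict[int, list]] = []
    N = 0
    for rec in records:
        n_avail = rec.excitation_freqs.shape[0]
        if k_max is None:
            k_max = n_avail
        if k_max > n_avail:
            raise ValidationError(
                f"k_max={k_max} exceeds available transitions ({n_avail})")
        if not acc:
            acc = [dict() for _ in range(k_max)]
        freqs = rec.excitation_freqs[:k_max] * units.HARTREE_CM1
        vals = (rec.rot_strengths if quantity == "R"
                else rec.dipole_strengths)[:k_max]
        idx = np.floor(freqs / bin_width).astype(int)
        for k in range(k_max):
            slot = acc[k].setdefault(int(idx[k]), [0, 0.0])
            slot[0] += 1
            slot[1] += vals[k]
        N += 1
    if N == 0:
        raise ValidationError("no records to bin")
    centers, counts, means = [], [], []
    for k in range(k_max):
        keys = np.array(sorted(acc[k]))
        cnt = np.array([acc[k][b][0] for b in keys])
        s = np.array([acc[k][b][1] for b in keys])
        centers.append((keys + 0.5) * bin_width)
        counts.append(cnt)
        means.append(s / cnt)
    return BinTable(bin_centers=centers, bin_counts=counts, bin_mean=means,
                    n_frames=N, bin_width=bin_width)


def _broadened(table: BinTable, sigma: float, grid: np.ndarray,
               prefactor: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.asarray(grid, float)
    norm = 1.0 / np.sqrt(2.0 * np.pi * sigma**2)
    per_k = np.zeros((table.n_transitions, grid.size))
    for k in range(table.n_transitions):
        for nu_ref, n, mean in zip(table.bin_centers[k],
                                   table.bin_counts[k],
                                   table.bin_mean[k]):
            per_k[k] += (mean * grid / prefactor
                         * (n / table.n_frames)
                         * np.exp(-((grid - nu_ref) ** 2) / (2 * sigma**2))
                         * norm)
    return per_k.sum(axis=0), per_k


def cd_curve(table: BinTable, sigma: float, grid: np.ndarray,
             label: str = "", keep_per_transition: bool = True
             ) -> SpectrumCurve:
    """Molar circular dichroism delta-eps(nu) from a rotational-strength
    bin table; sigma and grid in cm^-1."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    total, per_k = _broadened(table, sigma, grid, units.CD_PREFACTOR)
    return SpectrumCurve(grid=np.asarray(grid, float), values=total,
                         sigma=sigma, n_frames=table.n_frames, label=label,
                         kind="cd",
                         per_transition=per_k if keep_per_transition else None)


def uv_curve(table: BinTable, sigma: float, grid: np.ndarray,
             label: str = "", keep_per_transition: bool = True
             ) -> SpectrumCurve:
    """Molar extinction eps(nu) from a dipole-strength bin table."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    for means in table.bin_mean:
        if np.any(means < 0):
            raise ValidationError(
                "negative dipole strength in bin table (upstream bug)")
    total, per_k = _broadened(table, sigma, grid, units.UV_PREFACTOR)
    return SpectrumCurve(grid=np.asarray(grid, float), values=total,
                         sigma=sigma, n_frames=table.n_frames, label=label,
                         kind="uv",
                         per_transition=per_k if keep_per_transition else None)


def combine_spectra(curves: Sequence[SpectrumCurve],
                    weights: Sequence[float],
                    label: str = "combined") -> SpectrumCurve:
    """Pointwise probability-weighted sum of spectra on a common grid."""
    if len(curves) != len(weights):
        raise ValidationError("one weight per curve required")
    if not curves:
        raise ValidationError("no curves to combine")
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != grid.shape or not np.allclose(c.grid, grid):
            raise ValidationError("curves are on different grids")
    w = np.asarray(weights, float)
    values = np.einsum("c,cg->g", w, np.stack([c.values for c in curves]))
    return SpectrumCurve(grid=grid.copy(), values=values,
                         sigma=curves[0].sigma,
                         n_frames=sum(c.n_frames for c in curves),
                         label=label, kind=curves[0].kind, weights=w)


def wavelength_window(curve: SpectrumCurve,
                      lo_nm: float = 160.0,
                      hi_nm: float = 220.0) -> SpectrumCurve:
    """Restrict a curve to a wavelength window (the experimentally sampled
    spectral domain; defaults 160-220 nm)."""
    if not lo_nm < hi_nm:
        raise ValidationError("need lo_nm < hi_nm")
    lam = curve.wavelength_nm
    keep = (lam >= lo_nm) & (lam <= hi_nm)
    if not np.any(keep):
        raise ValidationError(
            f"window {lo_nm}-{hi_nm} nm does not overlap the grid")
    return SpectrumCurve(
        grid=curve.grid[keep], values=curve.values[keep], sigma=curve.sigma,
        n_frames=curve.n_frames, label=curve.label, kind=curve.kind,
        per_transition=(curve.per_transition[:, keep]
                        if curve.per_transition is not None else None),
        weights=curve.weights)


def transition_weight_report(curve: SpectrumCurve,
                             floor: float = 1.0) -> list[tuple[int, float]]:
    """Maximum |intensity| per transition, keeping those above ``floor``
    (M^-1 cm^-1).  Returns (transition index from 1, max intensity) pairs."""
    if curve.per_transition is None:
        raise ValidationError("curve carries no per-transition components")
    out = []
    for k, band in enumerate(curve.per_transition, start=1):
        peak = float(np.abs(band).max())
        if peak > floor:
            out.append((k, peak))
    return out
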