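"""Electric-field estimation from stimulation-band artifacts on a planar
multielectrode array, plus generic log-normal fitting and principal-axes
ellipsoid summaries of field samples.

The stimulation artifact recorded at each electrode scales with the local
potential, so the spatial gradient of the per-channel mean cycle-peak
voltage across the array is an estimate of the electric field: neighbouring
electrodes along both axes give orthogonal difference quotients (ΔV / pitch)
that are combined by vector addition into field magnitudes in mV/mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core import Recording, StimProtocol
from .permtest import grubbs
from .summarize import median_ci

__all__ = [
    "FieldEstimate",
    "isolate_stim_band",
    "cycle_peaks",
    "planar_field",
    "summarize_field",
    "fit_lognormal",
    "ellipsoid_summary",
    "LognormalFit",
    "EllipsoidSummary",
]


def isolate_stim_band(
    recording: Recording, stim_frequency: float, half_width: float = 1.0
) -> Recording:
    """Zero-phase band-pass around the stimulation frequency.

    4th-order Butterworth applied forward-backward (no phase distortion);
    a tone at the stimulation frequency is preserved within 1% while content
    at 3× the frequency is attenuated by ≥ 40 dB.
    """
    if stim_frequency >= recording.rate / 2:
        raise ValueError("stimulation frequency must be below Nyquist")
    if half_width >= stim_frequency:
        raise ValueError("half_width must be below the stimulation frequency")
    sos = signal.butter(
        4,
        [stim_frequency - half_width, stim_frequency + half_width],
        btype="bandpass",
        fs=recording.rate,
        output="sos",
    )
    out = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.copy(samples=out)


def cycle_peaks(filtered: Recording, protocol: StimProtocol) -> np.ndarray:
    """Per-channel mean peak |V| over each stimulation cycle (µV).

    Cycle boundaries come from the protocol (onset + k/f); fewer than 10
    whole cycles triggers a warning, as the mean is then noisy.
    """
    n_cycles = protocol.n_cycles()
    if n_cycles < 10:
        warnings.warn("fewer than 10 stimulation cycles; peak estimate is unstable")
    rate = filtered.rate
    peaks = np.zeros((filtered.n_channels, n_cycles))
    for k in range(n_cycles):
        t_start = protocol.onset + k / protocol.frequency
        t_stop = protocol.onset + (k + 1) / protocol.frequency
        a = int(np.round(t_start * rate))
        b = max(int(np.round(t_stop * rate)), a + 1)
        b = min(b, filtered.n_samples)
        if a >= b:
            peaks[:, k] = np.nan
            continue
        peaks[:, k] = np.max(np.abs(filtered.samples[:, a:b]), axis=1)
    return np.nanmean(peaks, axis=1)


@dataclass
class FieldEstimate:
    """Planar field estimate from cycle-peak voltages on a regular grid.

    ``grad_x[i, j]`` is the difference quotient between columns j and j+1 in
    row i (µV/mm); ``grad_y`` analogously between rows.  ``magnitudes`` holds
    the combined field at each interior lattice cell in mV/mm: within the
    cell bounded by four electrodes, the x- and y-components are the means of
    the two parallel edge gradients and are combined as √(Ex² + Ey²).
    """

    peaks: np.ndarray  # (rows, cols) µV
    grad_x: np.ndarray  # (rows, cols-1) µV/mm
    grad_y: np.ndarray  # (rows-1, cols) µV/mm
    magnitudes: np.ndarray  # (rows-1, cols-1) mV/mm
    pitch: float  # mm


def planar_field(peaks: np.ndarray, pitch: float = 0.5) -> FieldEstimate:
    """Field magnitudes from a grid of mean cycle-peak voltages.

    ``peaks`` is a (rows, cols) array in µV (NaN marks a missing channel;
    cells touching it are skipped, i.e. NaN in the output).  Requires at
    least a 2×2 grid of valid peaks.
    """
    pk = np.asarray(peaks, dtype=float)
    if pk.ndim != 2 or pk.shape[0] < 2 or pk.shape[1] < 2:
        raise ValueError("peaks must form at least a 2x2 grid")
    gx = np.diff(pk, axis=1) / pitch  # µV/mm
    gy = np.diff(pk, axis=0) / pitch
    ex = 0.5 * (gx[:-1, :] + gx[1:, :])  # cell means, (rows-1, cols-1)
    ey = 0.5 * (gy[:, :-1] + gy[:, 1:])
    mag = np.hypot(ex, ey) / 1000.0  # µV/mm -> mV/mm
    return FieldEstimate(peaks=pk, grad_x=gx, grad_y=gy, magnitudes=mag, pitch=pitch)


def peaks_to_grid(peaks_flat: np.ndarray, geometry: list[tuple[int, int]]) -> np.ndarray:
    """Arrange per-channel peak values onto the array grid (NaN where absent)."""
    rows = 1 + max(g[0] for g in geometry)
    cols = 1 + max(g[1] for g in geometry)
    grid = np.full((rows, cols), np.nan)
    for val, (r, c) in zip(peaks_flat, geometry):
        grid[r, c] = val
    return grid


def summarize_field(
    magnitudes: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Median field with a 95% CI after Grubbs outlier removal.

    Returns (median, ci_lower, ci_upper) in the units of the input.  Fewer
    than three samples skip the outlier step with a warning.
    """
    vals = np.asarray(magnitudes, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size >= 3:
        vals, _ = grubbs(vals, alpha=alpha)
    else:
        warnings.warn("fewer than 3 field samples; outlier removal skipped")
    return median_ci(vals)


@dataclass(frozen=True)
class LognormalFit:
    shape: float
    location: float
    scale: float


def fit_lognormal(samples: np.ndarray) -> LognormalFit:
    """Maximum-likelihood three-parameter log-normal fit of field samples."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3 or np.all(x == x[0]):
        raise ValueError("log-normal fit requires a non-degenerate sample")
    shape, loc, scale = stats.lognorm.fit(x)
    if shape <= 0 or scale <= 0:
        raise ValueError("degenerate log-normal fit")
    return LognormalFit(shape=float(shape), location=float(loc), scale=float(scale))


@dataclass
class EllipsoidSummary:
    radii: np.ndarray  # descending, factor × std along each principal axis
    axes: np.ndarray  # (3, 3), rows are unit axis directions
    center: np.ndarray
    degenerate: bool


def ellipsoid_summary(points: np.ndarray, factor: float = 1.96) -> EllipsoidSummary:
    """Principal-axes ellipsoid summary of a 3-D point cloud.

    Eigen-decomposes the covariance of the points; the axis radii are
    ``factor`` × the standard deviation of the cloud along each principal
    axis (1.96 encompasses ~95% of a Gaussian spread).  This summarizes the
    cloud's extent, not the geometric boundary.  A rank-deficient cloud is
    flagged degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] < 10:
        raise ValueError("at least 10 points are required")
    center = pts.mean(axis=0)
    cov = np.cov(pts - center, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    if degenerate:
        warnings.warn("rank-deficient point cloud; ellipsoid axes degenerate")
    radii = factor * np.sqrt(np.clip(evals, 0.0, None))
    return EllipsoidSummary(radii=radii, axes=evecs.T, center=center, degenerate=degenerate)
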