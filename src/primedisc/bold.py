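"""Shared BOLD primitives: the 4-D container, the canonical haemodynamic
kernel, event regressors and drift bases."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "VolumeSeries",
    "hrf_kernel",
    "event_regressor",
    "cosine_drift_basis",
    "ellipsoid_mask",
    "smooth_map",
]


@dataclass
class VolumeSeries:
    """A 4-D scalar field over concatenated runs.

    ``data`` has shape (nx, ny, nz, n_runs * volumes_per_run); ``mask`` is
    the 3-D analysis mask; the affine is diagonal in the voxel size.
    """

    data: np.ndarray
    tr_s: float
    n_runs: int
    volumes_per_run: int
    voxel_size_mm: float
    mask: np.ndarray
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.data.shape[-1] != self.n_runs * self.volumes_per_run:
            raise ValueError("time axis does not match runs x volumes_per_run")
        if self.affine is None:
            self.affine = np.diag(
                [self.voxel_size_mm] * 3 + [1.0]
            )

    @property
    def grid(self):
        return self.data.shape[:3]

    def run_data(self, run: int) -> np.ndarray:
        """Voxels x time matrix for one 0-based run, masked."""
        sl = self.run_slice(run)
        return self.data[..., sl][self.mask]

    def run_slice(self, run: int) -> slice:
        if not 0 <= run < self.n_runs:
            raise IndexError(f"run {run} outside 0..{self.n_runs - 1}")
        start = run * self.volumes_per_run
        return slice(start, start + self.volumes_per_run)


def _gamma_pdf(t, shape):
    # unit-scale gamma density, stable for large shapes
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(
        (shape - 1) * np.log(t[pos]) - t[pos] - gammaln(shape)
    )
    return out


def hrf_kernel(
    tr_ms: float,
    oversampling: int = 16,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    ratio: float = 6.0,
    length_s: float = 32.0,
):
    """Double-gamma haemodynamic response, unit peak.

    The positive lobe is a unit-scale gamma density with its mode at
    ``peak_delay_s`` (6 s), the undershoot a gamma with mode at 16 s scaled
    by 1/ratio, truncated at 32 s.  Returns ``(kernel, dt_s)`` with the
    kernel sampled every ``tr_s / oversampling`` seconds.
    """
    if tr_ms <= 0:
        raise ValueError("tr must be > 0")
    dt = tr_ms / 1000.0 / oversampling
    t = np.arange(0.0, length_s, dt)
    # gamma(shape, scale=1) has its mode at shape - 1
    h = _gamma_pdf(t, peak_delay_s + 1.0) - _gamma_pdf(
        t, undershoot_delay_s + 1.0
    ) / ratio
    h = h / h.max()
    return h, dt


def event_regressor(
    onsets_s,
    durations_s,
    amplitudes,
    n_scans: int,
    tr_s: float,
    oversampling: int = 16,
    kernel=None,
):
    """Convolve amplitude-weighted event boxcars with the canonical kernel.

    Returns the regressor sampled at scan times (length ``n_scans``).
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    durations_s = np.broadcast_to(
        np.asarray(durations_s, dtype=float), onsets_s.shape
    )
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets_s.shape)
    if kernel is None:
        kernel, dt = hrf_kernel(tr_s * 1000.0, oversampling)
    else:
        kernel, dt = kernel
    n_fine = int(np.ceil(n_scans * tr_s / dt)) + len(kernel)
    neural = np.zeros(n_fine)
    for on, dur, amp in zip(onsets_s, durations_s, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        if i0 >= n_fine:
            continue
        neural[i0:min(i1, n_fine)] += amp
    conv = np.convolve(neural, kernel)[:n_fine]
    scan_idx = np.round(np.arange(n_scans) * tr_s / dt).astype(int)
    return conv[scan_idx]


def cosine_drift_basis(n_scans: int, tr_s: float, highpass_s: float = 128.0):
    """Discrete-cosine low-frequency set for a high-pass cutoff (columns)."""
    t = np.arange(n_scans)
    order = int(np.floor(2.0 * n_scans * tr_s / highpass_s))
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (t + 0.5) * j / n_scans)
        for j in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def ellipsoid_mask(grid) -> np.ndarray:
    """Inscribed-ellipsoid 'brain' mask for a voxel grid."""
    nx, ny, nz = grid
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    return (
        ((x - cx) / (nx / 2.0)) ** 2
        + ((y - cy) / (ny / 2.0)) ** 2
        + ((z - cz) / (nz / 2.0)) ** 2
    ) <= 1.0


def smooth_map(map3d: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian smoothing with the kernel given as FWHM in millimetres.

    NaNs (out-of-mask voxels) are treated as missing via normalised
    convolution and restored afterwards.
    """
    from scipy.ndimage import gaussian_filter

    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    nan = np.isnan(map3d)
    filled = np.where(nan, 0.0, map3d)
    num = gaussian_filter(filled, sigma)
    den = gaussian_filter((~nan).astype(float), sigma)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[nan] = np.nan
    return out
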