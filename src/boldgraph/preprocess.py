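"""Post-registration resting-state preprocessing.

Initial volume dropping, nuisance regression (six motion parameters, white
matter, CSF), spatial smoothing, temporal bandpass (0.01-0.08 Hz), Power-style
framewise displacement, motion scrubbing (censored volume plus one before and
two after), and subject-level motion exclusion.

The default stage order is: drop initial volumes -> nuisance regression ->
spatial smoothing -> temporal bandpass -> scrubbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, ndimage

__all__ = [
    "PreprocessConfig",
    "CensorMask",
    "framewise_displacement",
    "censor_mask",
    "nuisance_regression",
    "bandpass",
    "spatial_smooth",
    "motion_exclusion_flag",
    "apply_censor",
    "preprocess_series",
]


@dataclass
class PreprocessConfig:
    n_initial_dropped: int = 10
    fd_threshold: float = 0.5          # mm
    scrub_before: int = 1
    scrub_after: int = 2
    band_low: float = 0.01             # Hz
    band_high: float = 0.08            # Hz
    smooth_fwhm: float = 6.0           # mm
    fd_rotation_radius: float = 50.0   # mm
    exclusion_translation: float = 2.5 # mm
    exclusion_rotation: float = 2.5    # degrees
    filter_type: str = "butterworth"   # or "fft"

    def validate(self, tr: float | None = None) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if tr is not None and self.band_high >= 0.5 / tr:
            raise ValueError(
                f"band_high {self.band_high} Hz is at/above Nyquist "
                f"{0.5 / tr:.4g} Hz for TR {tr} s")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        for name in ("n_initial_dropped", "scrub_before", "scrub_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.filter_type not in ("butterworth", "fft"):
            raise ValueError("filter_type must be 'butterworth' or 'fft'")


@dataclass
class CensorMask:
    keep: np.ndarray  # boolean per volume

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())


def framewise_displacement(motion: np.ndarray, rotation_radius: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    Sum of absolute backward differences of the six rigid-body parameters,
    with rotations (radians) converted to arc length on a sphere of
    ``rotation_radius`` mm. FD(0) = 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be time x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least two volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor_mask(fd: np.ndarray, config: PreprocessConfig | None = None) -> CensorMask:
    """Volumes to drop: every FD exceedance (strictly > threshold) censors
    itself, ``scrub_before`` predecessors and ``scrub_after`` successors,
    clipped at the series boundaries."""
    config = config or PreprocessConfig()
    fd = np.asarray(fd, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD contains non-finite values")
    t = len(fd)
    keep = np.ones(t, dtype=bool)
    for i in np.flatnonzero(fd > config.fd_threshold):
        lo = max(0, i - config.scrub_before)
        hi = min(t, i + config.scrub_after + 1)
        keep[lo:hi] = False
    return CensorMask(keep=keep)


def apply_censor(series: np.ndarray, mask: CensorMask, axis: int = 0) -> np.ndarray:
    """Delete censored volumes (no interpolation); idempotent on the result."""
    return np.compress(mask.keep, series, axis=axis)


def _with_intercept(confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] == 1:
        confounds = confounds.T
    return np.column_stack([np.ones(confounds.shape[0]), confounds])


def nuisance_regression(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``series`` on ``confounds`` + intercept.

    Raises if the augmented confound matrix is rank deficient, naming the
    collinear columns.
    """
    series = np.asarray(series, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] == 1:
        confounds = confounds.T
    # constant columns duplicate the intercept; drop them rather than fail
    confounds = confounds[:, np.ptp(confounds, axis=0) > 0]
    x = _with_intercept(confounds) if confounds.shape[1] else np.ones((len(series), 1))
    if series.shape[0] != x.shape[0]:
        raise ValueError("series and confounds disagree on the number of volumes")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns whose removal restores full column rank
        bad = [c - 1 for c in range(1, x.shape[1])
               if np.linalg.matrix_rank(np.delete(x, c, axis=1)) == rank]
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, series, rcond=None)
    return series - x @ beta


def bandpass(series: np.ndarray, tr: float, config: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase temporal bandpass along axis 0.

    Default realization is a forward-backward order-4 Butterworth; an ideal
    FFT brick-wall filter is available via ``config.filter_type = 'fft'``.
    Both remove the zero-frequency component.
    """
    config = config or PreprocessConfig()
    config.validate(tr=tr)
    series = np.asarray(series, dtype=float)
    fs = 1.0 / tr
    if config.filter_type == "fft":
        freqs = np.fft.rfftfreq(series.shape[0], d=tr)
        spec = np.fft.rfft(series, axis=0)
        band = (freqs >= config.band_low) & (freqs <= config.band_high)
        spec[~band] = 0.0
        return np.fft.irfft(spec, n=series.shape[0], axis=0)
    sos = signal.butter(4, [config.band_low, config.band_high], btype="band", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def spatial_smooth(volume4d: np.ndarray, voxel_size: float | tuple = 1.0,
                   fwhm: float = 6.0) -> np.ndarray:
    """Per-volume 3D Gaussian smoothing with kernel width given as FWHM in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(volume4d, dtype=float).copy()
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vs
    vol = np.asarray(volume4d, dtype=float)
    return ndimage.gaussian_filter(vol, sigma=tuple(sigma_vox) + (0.0,), mode="nearest")


def motion_exclusion_flag(motion: np.ndarray, config: PreprocessConfig | None = None) -> bool:
    """True if the subject moved too much relative to the reference (first) volume:
    any |translation| > 2.5 mm or any |rotation| > 2.5 degrees by default."""
    config = config or PreprocessConfig()
    motion = np.asarray(motion, dtype=float)
    rel = motion - motion[0]
    max_trans = np.abs(rel[:, :3]).max()
    max_rot_deg = np.degrees(np.abs(rel[:, 3:]).max())
    return bool(max_trans > config.exclusion_translation
                or max_rot_deg > config.exclusion_rotation)


def preprocess_series(series: np.ndarray, motion: np.ndarray, tr: float,
                      nuisance: np.ndarray | None = None,
                      config: PreprocessConfig | None = None,
                      volume4d: np.ndarray | None = None,
                      voxel_size: float = 3.0):
    """Run the default chain on one subject's multivariate series.

    ``series`` is time x K (ROI series or flattened voxel series). If
    ``volume4d`` is given it is smoothed and used instead of ``series`` for
    the voxel path. Returns ``(clean_series, censor, fd)`` where ``censor``
    covers the retained (post-drop) volumes.
    """
    config = config or PreprocessConfig()
    config.validate(tr=tr)
    d = config.n_initial_dropped
    motion = np.asarray(motion, dtype=float)[d:]
    confs = [motion]
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] < nuis.shape[1]:
            nuis = nuis.T
        confs.append(nuis[d:])
    confounds = np.column_stack(confs)

    if volume4d is not None:
        vol = np.asarray(volume4d, dtype=float)[..., d:]
        shape3 = vol.shape[:3]
        series = vol.reshape(-1, vol.shape[-1]).T  # time x voxels
    else:
        series = np.asarray(series, dtype=float)[d:]
        shape3 = None

    series = nuisance_regression(series, confounds)
    if shape3 is not None:
        vol = spatial_smooth(series.T.reshape(shape3 + (series.shape[0],)),
                             voxel_size, config.smooth_fwhm)
        series = vol.reshape(-1, vol.shape[-1]).T
    series = bandpass(series, tr, config)
    fd = framewise_displacement(motion, config.fd_rotation_radius)
    censor = censor_mask(fd, config)
    clean = apply_censor(series, censor)
    if shape3 is not None:
        clean = clean.T.reshape(shape3 + (clean.shape[0],))
    return clean, censor, fd
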