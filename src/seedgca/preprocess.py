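"""Temporal preprocessing for resting-state BOLD signals.

Implements the stages applied to every voxel before directed-connectivity
estimation: dropping dummy volumes, head-motion quality control, nuisance
regression against motion parameters and white-matter / CSF mean signals,
zero-phase band-pass filtering (default 0.01-0.08 Hz), linear detrending,
and optional isotropic Gaussian smoothing.

All temporal operations act along axis 0 and accept either a bare
``numpy`` array (1-D series or 2-D ``(T, V)`` stack) or a
:class:`TimeSeries`; they return the same kind of object they were given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TimeSeries",
    "MotionTrace",
    "MotionDecision",
    "PreprocessConfig",
    "discard_initial",
    "motion_summary",
    "motion_exclusion",
    "extract_mean_series",
    "regress_nuisance",
    "bandpass_filter",
    "detrend_linear",
    "smooth_gaussian",
    "preprocess_voxelwise",
]

#: FWHM (mm) -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class TimeSeries:
    """One regularly sampled signal (seed, voxel, or nuisance regressor).

    Parameters
    ----------
    samples
        Ordered real-valued vector, arbitrary BOLD units.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    """

    samples: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("TimeSeries.samples must be 1-dimensional")
        if self.samples.size < 3:
            raise ValueError("TimeSeries needs at least 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("TimeSeries contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``translations`` is an ``(L, 3)`` array in millimetres and
    ``rotations`` an ``(L, 3)`` array in degrees, one row per volume.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("motion trace needs 3 translation and 3 rotation columns")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translations and rotations must have equal length")
        if self.translations.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 volumes")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def as_design(self) -> np.ndarray:
        """Six-column ``(L, 6)`` regressor matrix (translations then rotations)."""
        return np.hstack([self.translations, self.rotations])

    def drop_initial(self, n: int) -> "MotionTrace":
        """Drop the first ``n`` rows, in lockstep with discarded volumes."""
        if n < 0 or n >= self.n_volumes - 1:
            raise ValueError("cannot drop that many motion rows")
        return MotionTrace(self.translations[n:], self.rotations[n:])


@dataclass
class MotionDecision:
    """Outcome of the head-motion exclusion rule."""

    exclude: bool
    offending_axis: str | None = None
    volume_index: int | None = None
    value: float | None = None


@dataclass
class PreprocessConfig:
    """Settings for the per-voxel cleaning pipeline.

    Defaults are the canonical study settings: discard 5 dummy volumes,
    0.01-0.08 Hz pass band, 8 mm FWHM kernel (application off by default for
    phantom runs), +-1.5 mm / +-1.5 degree motion limits, and nuisance
    regression against the 6 motion parameters plus WM and CSF means.
    """

    n_discard: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    smoothing_fwhm_mm: float = 8.0
    apply_smoothing: bool = False
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    motion_limit_mm: float = 1.5
    motion_limit_deg: float = 1.5
    use_motion_regressors: bool = True
    use_wm_regressor: bool = True
    use_csf_regressor: bool = True

    def validate(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not (0.0 <= self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError(
                f"pass band [{self.band_low_hz}, {self.band_high_hz}] Hz must sit "
                f"inside [0, Nyquist={nyquist:g}) Hz"
            )
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be non-negative")


def _unwrap(series):
    """Return (array, tr_or_None, rewrap) for array / TimeSeries inputs."""
    if isinstance(series, TimeSeries):
        return series.samples, series.tr_seconds, (
            lambda s: TimeSeries(s, series.tr_seconds)
        )
    arr = np.asarray(series, dtype=float)
    return arr, None, (lambda s: s)


def discard_initial(volume: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` time points of a 4-D ``(X, Y, Z, T)`` volume."""
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) volume")
    n_t = volume.shape[3]
    if not (0 <= n_discard < n_t):
        raise ValueError(f"n_discard={n_discard} out of range for T={n_t}")
    return volume[..., n_discard:]


def motion_summary(trace: MotionTrace) -> tuple[float, float]:
    """Mean frame-to-frame displacement of a motion trace.

    Returns ``(translation_mm, rotation_deg)`` where each is the average over
    volumes ``i = 2..L`` of the Euclidean norm of the step
    ``(x_i - x_{i-1}, y_i - y_{i-1}, z_i - z_{i-1})``, computed separately on
    the three translations (mm) and on the three rotation angles (degrees).
    Invariant to a constant offset of the whole trace.
    """
    dt = np.diff(trace.translations, axis=0)
    dr = np.diff(trace.rotations, axis=0)
    trans = float(np.mean(np.linalg.norm(dt, axis=1)))
    rot = float(np.mean(np.linalg.norm(dr, axis=1)))
    return trans, rot


_AXIS_NAMES = ("x", "y", "z", "pitch", "roll", "yaw")


def motion_exclusion(
    trace: MotionTrace, limits: tuple[float, float] = (1.5, 1.5)
) -> MotionDecision:
    """Apply the head-motion exclusion rule.

    A subject is excluded iff any translation parameter exceeds
    ``limits[0]`` mm in absolute value, or any rotation angle exceeds
    ``limits[1]`` degrees.  The comparison is strict: a maximum of exactly
    the limit is retained.  The first offending axis/volume is reported.
    """
    params = trace.as_design()
    bounds = np.array([limits[0]] * 3 + [limits[1]] * 3)
    over = np.abs(params) > bounds
    if not over.any():
        return MotionDecision(exclude=False)
    vol_idx, axis_idx = np.argwhere(over)[0]
    return MotionDecision(
        exclude=True,
        offending_axis=_AXIS_NAMES[axis_idx],
        volume_index=int(vol_idx),
        value=float(params[vol_idx, axis_idx]),
    )


def extract_mean_series(
    volume: np.ndarray, mask: np.ndarray, tr_seconds: float = 2.0
) -> TimeSeries:
    """Unweighted mean over in-mask voxels at every time point (ROI series)."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) volume")
    if mask.shape != volume.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {volume.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    return TimeSeries(volume[mask].mean(axis=0), tr_seconds)


def regress_nuisance(series, regressors):
    """OLS residuals of ``series`` on an intercept plus the given regressors.

    ``series`` may be a 1-D array, a ``(T, V)`` stack, or a
    :class:`TimeSeries`; every regressor must have length ``T``.  Residuals
    are orthogonal to the intercept and every regressor.  A rank-deficient
    (collinear) regressor set is handled by the minimum-norm least-squares
    solution and triggers a warning.
    """
    data, _, rewrap = _unwrap(series)
    y = data if data.ndim == 2 else data[:, None]
    n_t = y.shape[0]
    cols = [np.ones(n_t)]
    for reg in regressors:
        r, _, _ = _unwrap(reg)
        if r.ndim != 1 or r.size != n_t:
            raise ValueError("every regressor must be 1-D with the series' length")
        cols.append(r)
    design = np.column_stack(cols)
    # normal equations are fast for the small design; fall back to the
    # minimum-norm lstsq solution when the regressor set is collinear
    gram = design.T @ design
    rank = np.linalg.matrix_rank(gram)
    if rank < design.shape[1]:
        warnings.warn(
            "collinear nuisance regressors: using minimum-norm solution",
            stacklevel=2,
        )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        beta = np.linalg.solve(gram, design.T @ y)
    resid = y - design @ beta
    out = resid[:, 0] if data.ndim == 1 else resid
    return rewrap(out)


def bandpass_filter(series, low_hz: float, high_hz: float, tr_seconds: float | None = None,
                    transition_hz: float = 0.005):
    """Zero-phase band-pass filter via an rFFT magnitude mask.

    Frequencies inside ``[low_hz, high_hz]`` are preserved; content outside
    is suppressed, with raised-cosine transition bands of width
    ``transition_hz`` on either edge (clipped at 0 and Nyquist).  The
    output has the same length as the input and no phase shift.
    """
    data, tr_attr, rewrap = _unwrap(series)
    tr = tr_seconds if tr_seconds is not None else tr_attr
    if tr is None:
        raise ValueError("tr_seconds required when filtering a bare array")
    nyquist = 0.5 / tr
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:g} Hz"
        )
    n_t = data.shape[0]
    freqs = np.fft.rfftfreq(n_t, d=tr)
    gain = np.zeros_like(freqs)
    lo0, lo1 = max(low_hz - transition_hz, 0.0), low_hz
    hi0, hi1 = high_hz, min(high_hz + transition_hz, nyquist)
    gain[(freqs >= lo1) & (freqs <= hi0)] = 1.0
    ramp_up = (freqs > lo0) & (freqs < lo1)
    if lo1 > lo0:
        gain[ramp_up] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp_up] - lo0) / (lo1 - lo0)))
    ramp_dn = (freqs > hi0) & (freqs < hi1)
    if hi1 > hi0:
        gain[ramp_dn] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp_dn] - hi0) / (hi1 - hi0)))
    spec = np.fft.rfft(data, axis=0)
    shape = (-1,) + (1,) * (data.ndim - 1)
    filtered = np.fft.irfft(spec * gain.reshape(shape), n=n_t, axis=0)
    return rewrap(filtered)


def detrend_linear(series):
    """Remove the best-fitting straight line (intercept + slope * t) by OLS."""
    data, _, rewrap = _unwrap(series)
    n_t = data.shape[0]
    t = np.arange(n_t, dtype=float)
    t -= t.mean()
    centered = data - data.mean(axis=0)
    slope = np.tensordot(t, centered, axes=(0, 0)) / (t @ t)
    resid = centered - np.multiply.outer(t, slope)
    return rewrap(resid)


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> np.ndarray:
    """Per-timepoint isotropic 3-D Gaussian smoothing of a 4-D volume.

    ``sigma`` per axis is ``fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size``.
    ``fwhm_mm = 0`` is the identity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) volume")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / vs for vs in voxel_size_mm]
    out = np.empty_like(volume)
    for t in range(volume.shape[3]):
        out[..., t] = ndimage.gaussian_filter(volume[..., t], sigma=sigma_vox)
    return out


def preprocess_voxelwise(
    volume: np.ndarray,
    trace: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    brain_mask: np.ndarray,
    config: PreprocessConfig,
    tr_seconds: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Full per-voxel cleaning pipeline.

    Stages, in order: discard initial volumes (motion rows dropped in
    lockstep) -> optional Gaussian smoothing -> nuisance regression
    (6 motion parameters + WM mean + CSF mean, per config flags) ->
    band-pass filter -> linear detrend.  WM/CSF mean regressors are
    extracted from the *unsmoothed* post-discard data.  Voxels outside the
    brain mask are zeroed; constant (zero-variance) in-brain voxels are
    passed through as zeros and flagged.

    Returns ``(cleaned_volume, flagged_mask)`` where ``flagged_mask`` marks
    degenerate in-brain voxels.
    """
    config.validate(tr_seconds)
    volume = np.asarray(volume, dtype=float)
    brain = np.asarray(brain_mask).astype(bool)
    if brain.shape != volume.shape[:3]:
        raise ValueError("brain mask grid does not match volume grid")

    vol = discard_initial(volume, config.n_discard) if config.n_discard else volume
    motion = trace.drop_initial(config.n_discard) if config.n_discard else trace
    if motion.n_volumes != vol.shape[3]:
        raise ValueError(
            f"motion rows ({motion.n_volumes}) do not match volumes ({vol.shape[3]}) "
            "after discard alignment"
        )

    regressors: list[np.ndarray] = []
    if config.use_motion_regressors:
        regressors.extend(motion.as_design().T)
    if config.use_wm_regressor:
        regressors.append(extract_mean_series(vol, wm_mask, tr_seconds).samples)
    if config.use_csf_regressor:
        regressors.append(extract_mean_series(vol, csf_mask, tr_seconds).samples)

    if config.apply_smoothing and config.smoothing_fwhm_mm > 0:
        vol = smooth_gaussian(vol, config.smoothing_fwhm_mm, config.voxel_size_mm)

    data = vol[brain].T  # (T, V)
    const = np.ptp(data, axis=0) == 0
    flagged3d = np.zeros(brain.shape, dtype=bool)
    if const.any():
        idx = np.argwhere(brain)
        flagged3d[tuple(idx[const].T)] = True

    cleaned = regress_nuisance(data, regressors) if regressors else data - data.mean(axis=0)
    cleaned = bandpass_filter(cleaned, config.band_low_hz, config.band_high_hz, tr_seconds)
    cleaned = detrend_linear(cleaned)
    cleaned[:, const] = 0.0

    out = np.zeros_like(vol)
    out[brain] = cleaned.T
    return out, flagged3d
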