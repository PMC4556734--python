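"""Time-series preprocessing: despiking, confound regression, band-pass.

The time-series stage of the analysis pipeline: an 8-column nuisance basis
(six rigid-body realignment parameters plus mean CSF and white-matter
signals) is expanded to 32 regressors (base, backward-difference
derivatives, and the squares of both), regressed out by ordinary least
squares, and the residuals are band-pass filtered with an ideal
frequency-domain mask (0.01 Hz high-pass, optional 0.1 Hz low-pass).
Optional despiking clips excursions beyond 4 median absolute deviations
from a running median before anything else.

The stage order is despike -> regress -> filter; regressing before
filtering avoids re-introducing confound energy inside the passband.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass configuration.

    ``lowpass_hz=None`` disables the low-pass, reproducing the task-evoked
    ("no low-pass") analysis variant.
    """

    highpass_hz: float = 0.01
    lowpass_hz: float | None = 0.1
    sampling_interval: float = 2.0
    despike: bool = False

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        nyquist = 0.5 / self.sampling_interval
        if self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")
        if self.lowpass_hz is not None:
            if self.lowpass_hz <= self.highpass_hz:
                raise ValueError("lowpass_hz must exceed highpass_hz")
            if self.lowpass_hz >= nyquist:
                raise ValueError(
                    f"lowpass_hz must be below the Nyquist frequency {nyquist} Hz"
                )


def expand_confounds(base: np.ndarray) -> np.ndarray:
    """Expand a T x K nuisance basis to T x 4K regressors.

    Columns are ordered [base | backward-difference derivative (first row
    zero) | base^2 | derivative^2]. With the standard 8-column basis this
    yields the 32-regressor confound model.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    if base.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to expand confounds")
    deriv = np.vstack([np.zeros((1, base.shape[1])), np.diff(base, axis=0)])
    return np.hstack([base, deriv, base**2, deriv**2])


def _dedupe_columns(x: np.ndarray) -> np.ndarray:
    """Drop exact duplicate columns, keeping first occurrences in order."""
    _, first = np.unique(x.round(decimals=15), axis=1, return_index=True)
    return x[:, np.sort(first)]


def regress_confounds(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize node time series against a confound matrix.

    An intercept is always included; exact duplicate confound columns are
    dropped. Raises if the de-duplicated design is rank deficient, naming
    the offending columns, or if there are at least as many regressors as
    timepoints. Residuals are orthogonal to every confound column.
    """
    ts = np.asarray(ts, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if ts.shape[0] != confounds.shape[0]:
        raise ValueError("time series and confounds must share T")
    confounds = _dedupe_columns(confounds)
    # constant columns are absorbed by the always-included intercept
    confounds = confounds[:, np.ptp(confounds, axis=0) != 0]
    T = ts.shape[0]
    design = np.hstack([np.ones((T, 1)), confounds])
    if design.shape[1] >= T:
        raise ValueError(
            f"{design.shape[1]} regressors (incl. intercept) for only {T} timepoints"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase the rank, greedily
        offending = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.hstack([kept, design[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                offending.append(j - 1)  # confound-column index
            else:
                kept = cand
        raise ValueError(
            f"rank-deficient confound matrix; redundant columns: {offending}"
        )
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def despike_timeseries(ts: np.ndarray, window: int = 7, n_mads: float = 4.0) -> np.ndarray:
    """Clip excursions beyond ``n_mads`` MADs of a per-node running median.

    The running median uses a centred window (nearest-edge padding); the MAD
    is computed per node over the whole series of residuals from that median.
    Values outside the band are shrunk to the band edge.
    """
    ts = np.asarray(ts, dtype=float)
    med = median_filter(ts, size=(window, 1), mode="nearest")
    resid = ts - med
    mad = np.median(np.abs(resid), axis=0)
    bound = n_mads * mad
    return med + np.clip(resid, -bound, bound)


def bandpass_filter(ts: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Ideal (DFT-mask) band-pass filter of each node's series.

    Frequency bins strictly below ``highpass_hz`` (including DC, so the mean
    is removed) or above ``lowpass_hz`` are zeroed; the filter is zero-phase
    and idempotent. With ``spec.despike`` the running-median clip is applied
    first.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if ts.shape[0] < 16:
        raise ValueError("need at least 16 timepoints to band-pass filter")
    if spec.despike:
        ts = despike_timeseries(ts)
    spectrum = np.fft.rfft(ts, axis=0)
    freqs = np.fft.rfftfreq(ts.shape[0], d=spec.sampling_interval)
    mask = freqs >= spec.highpass_hz
    if spec.lowpass_hz is not None:
        mask &= freqs <= spec.lowpass_hz
    spectrum[~mask] = 0.0
    return np.fft.irfft(spectrum, n=ts.shape[0], axis=0)


def preprocess_timeseries(
    ts: np.ndarray, confound_base: np.ndarray, spec: FilterSpec
) -> np.ndarray:
    """Full time-series stage: despike -> expand+regress confounds -> filter."""
    if spec.despike:
        ts = despike_timeseries(np.asarray(ts, dtype=float))
    resid = regress_confounds(ts, expand_confounds(confound_base))
    return bandpass_filter(
        resid,
        FilterSpec(
            highpass_hz=spec.highpass_hz,
            lowpass_hz=spec.lowpass_hz,
            sampling_interval=spec.sampling_interval,
            despike=False,
        ),
    )
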