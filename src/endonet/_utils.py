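"""Shared numeric helpers: deterministic rounding, seeding, band-limited noise."""

from __future__ import annotations

import hashlib

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for edge-count and hub-count rounding so that e.g. a 20% density on
    258 nodes retains round(0.2 * 33153) = 6631 edges regardless of the
    platform's banker's-rounding behaviour.
    """
    if x >= 0:
        return int(np.floor(x + 0.5))
    return int(np.ceil(x - 0.5))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed and a stage name.

    Hash-based so that changing one stage's consumption of randomness (for
    example the permutation count in QC) never perturbs another stage.
    Result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def bandlimited_series(
    rng: np.random.Generator,
    n_timepoints: int,
    n_series: int,
    sampling_interval: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Unit-variance Gaussian series restricted to a frequency band.

    White Gaussian noise is projected onto the DFT bins with
    low_hz <= f <= high_hz and standardized column-wise to zero mean and unit
    variance. This is the "intrinsic" fluctuation band of resting fMRI at the
    configured sampling interval, so an ideal band-pass of the same band is
    non-destructive for these signals.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints for band-limited noise")
    white = rng.standard_normal((n_timepoints, n_series))
    spectrum = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_timepoints, d=sampling_interval)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError(
            f"no DFT bin falls in [{low_hz}, {high_hz}] Hz for "
            f"T={n_timepoints}, dt={sampling_interval}"
        )
    spectrum[~keep] = 0.0
    series = np.fft.irfft(spectrum, n=n_timepoints, axis=0)
    series -= series.mean(axis=0)
    sd = series.std(axis=0)
    sd[sd == 0] = 1.0
    return series / sd
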