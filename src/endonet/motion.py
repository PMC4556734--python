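"""Head-motion quality control.

Framewise displacement (FD) summarises instantaneous head motion as the sum
of absolute backward differences of the six rigid-body realignment
parameters, with the three rotations converted to arc displacement at a
50 mm radius. Motion can masquerade as connectivity structure: it inflates
correlations between nearby nodes and deflates them between distant ones.
The diagnostics here quantify that signature — per-edge correlations between
functional connectivity and a subject-level motion scalar, their
distance-ordered moving average, and the slope of a straight-line fit — and
calibrate it against an empirical null obtained by permuting the
subject-to-motion assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import round_half_away

DEFAULT_ROTATION_RADIUS_MM = 50.0


def _check_realignment(realignment: np.ndarray) -> np.ndarray:
    realignment = np.asarray(realignment, dtype=float)
    if realignment.ndim != 2 or realignment.shape[1] != 6:
        raise ValueError(
            "realignment must be T x 6 (3 translations mm, 3 rotations rad), "
            f"got shape {realignment.shape}"
        )
    if realignment.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to form differences")
    return realignment


def framewise_displacement(
    realignment: np.ndarray, radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Per-timepoint framewise displacement in mm, with a leading zero.

    FD_t = sum_i |Delta trans_i| + radius * sum_i |Delta rot_i|, so the
    series depends only on parameter differences and is invariant to constant
    offsets of any realignment column.
    """
    realignment = _check_realignment(realignment)
    deltas = np.abs(np.diff(realignment, axis=0))
    fd = deltas[:, :3].sum(axis=1) + radius * deltas[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


@dataclass(frozen=True)
class MotionSummary:
    """Subject-level motion scalars (all in mm)."""

    mean_fd: float
    max_fd: float
    max_spike: float

    def scalar(self, which: str) -> float:
        try:
            return getattr(self, which)
        except AttributeError:
            raise ValueError(f"unknown motion scalar {which!r}") from None


def motion_summary(
    realignment: np.ndarray, radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> MotionSummary:
    """Mean/maximum FD and the maximum single-parameter spike.

    ``max_spike`` is the largest absolute one-step change in any individual
    location parameter, with rotations converted to mm at ``radius``.
    """
    realignment = _check_realignment(realignment)
    fd = framewise_displacement(realignment, radius)[1:]
    deltas = np.abs(np.diff(realignment, axis=0))
    deltas[:, 3:] *= radius
    return MotionSummary(
        mean_fd=float(fd.mean()),
        max_fd=float(fd.max()),
        max_spike=float(deltas.max()),
    )


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return x / sd_safe


def edgewise_motion_correlation(fc_stack: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Pearson r between each edge's FC and a subject motion scalar.

    Parameters
    ----------
    fc_stack:
        S x M matrix of per-subject, per-edge connectivity values.
    motion:
        Length-S vector of subject-level motion scalars.

    Edges whose FC is constant across subjects have no defined correlation
    and are reported as 0.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if fc_stack.ndim != 2 or motion.shape != (fc_stack.shape[0],):
        raise ValueError("fc_stack must be S x M and motion length S")
    n_subjects = fc_stack.shape[0]
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(motion) == 0:
        raise ValueError("motion scalar is constant across subjects")
    z_fc = _standardize_columns(fc_stack)
    z_m = (motion - motion.mean()) / motion.std()
    r = z_m @ z_fc / n_subjects
    r[fc_stack.std(axis=0) == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class EdgeMotionProfile:
    """Distance-resolved FC-motion correlation profile.

    ``slope_per_m`` is the OLS slope of the per-edge correlations against
    inter-node distance, fitted per mm and reported per metre.
    """

    distances: np.ndarray  # sorted ascending, mm
    edge_r: np.ndarray  # correlations in distance order
    moving_average: np.ndarray
    mean_r: float
    slope_per_m: float
    intercept: float
    window: int


def distance_profile(
    edge_r: np.ndarray,
    distances: np.ndarray,
    window_fraction: float = 0.05,
    fit_on: str = "raw",
) -> EdgeMotionProfile:
    """Moving average of edge correlations over distance, plus a linear fit.

    Edges are sorted by distance; the moving-average window is
    round(window_fraction * M) edges (minimum 3), centred, shrinking at the
    boundaries. The slope is fitted by OLS on the raw per-edge correlations
    by default (``fit_on="moving_average"`` fits the smoothed curve instead).
    """
    edge_r = np.asarray(edge_r, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if edge_r.shape != distances.shape or edge_r.ndim != 1:
        raise ValueError("edge_r and distances must be equal-length vectors")
    if edge_r.size < 3:
        raise ValueError("need at least 3 edges")
    if not 0 < window_fraction <= 0.5:
        raise ValueError("window_fraction must lie in (0, 0.5]")
    if fit_on not in ("raw", "moving_average"):
        raise ValueError("fit_on must be 'raw' or 'moving_average'")

    order = np.argsort(distances, kind="stable")
    dist_sorted = distances[order]
    r_sorted = edge_r[order]
    window = max(3, round_half_away(window_fraction * edge_r.size))
    moving = (
        pd.Series(r_sorted).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    target = r_sorted if fit_on == "raw" else moving
    if np.ptp(dist_sorted) == 0:
        slope, intercept = 0.0, float(target.mean())
    else:
        fit = sps.linregress(dist_sorted, target)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return EdgeMotionProfile(
        distances=dist_sorted,
        edge_r=r_sorted,
        moving_average=moving,
        mean_r=float(r_sorted.mean()),
        slope_per_m=slope * 1000.0,
        intercept=intercept,
        window=window,
    )


@dataclass(frozen=True)
class PermutationResult:
    """Permutation-null assessment of FC-motion coupling.

    p-values use the add-one estimator p = (1 + #{|null| >= |observed|}) /
    (1 + n_perm), so the smallest attainable p with 100 permutations is
    1/101.
    """

    observed_mean_r: float
    observed_slope_per_m: float
    p_mean: float
    p_slope: float
    null_mean_r: np.ndarray
    null_slope_per_m: np.ndarray
    n_permutations: int


def permutation_null(
    fc_stack: np.ndarray,
    motion: np.ndarray,
    distances: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permute the subject-to-motion assignment to calibrate the profile.

    For each permutation the mean edgewise correlation and the fitted
    distance slope are recomputed; two-sided empirical p-values compare the
    observed statistics with the null distributions. Deterministic per seed.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    motion = np.asarray(motion, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_subjects, n_edges = fc_stack.shape
    if distances.shape != (n_edges,):
        raise ValueError("distances must have one entry per edge")
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(motion) == 0:
        raise ValueError("motion scalar is constant across subjects")

    z_fc = _standardize_columns(fc_stack)
    const_edges = fc_stack.std(axis=0) == 0
    z_m = (motion - motion.mean()) / motion.std()

    d_centered = distances - distances.mean()
    d_ss = float((d_centered**2).sum())

    def _stats(z_motion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # z_motion: P x S standardized motion rows -> (mean r, slope/m) per row
        r = z_motion @ z_fc / n_subjects
        r[:, const_edges] = 0.0
        mean_r = r.mean(axis=1)
        if d_ss == 0:
            slope = np.zeros(r.shape[0])
        else:
            slope = (r - r.mean(axis=1, keepdims=True)) @ d_centered / d_ss
        return mean_r, slope * 1000.0

    obs_mean, obs_slope = _stats(z_m[None, :])
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n_subjects)), axis=1)
    null_mean, null_slope = _stats(z_m[perms])

    p_mean = (1 + int((np.abs(null_mean) >= abs(obs_mean[0])).sum())) / (1 + n_perm)
    p_slope = (1 + int((np.abs(null_slope) >= abs(obs_slope[0])).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_mean_r=float(obs_mean[0]),
        observed_slope_per_m=float(obs_slope[0]),
        p_mean=p_mean,
        p_slope=p_slope,
        null_mean_r=null_mean,
        null_slope_per_m=null_slope,
        n_permutations=n_perm,
    )
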