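"""Synthetic cohort generation.

Generates multi-subject region-of-interest time series with the statistical
structure the downstream analysis assumes: three matched groups (controls,
unaffected siblings, and an autism-spectrum group) of equal size whose
global functional connectivity is graded CON > SIB > ASC.

Each subject's signal follows a factor model

    x_it = g * h_i * F_t + w * G_t^(net(i)) + c1 * U_t + c2 * V_t + eps_it

where F is a global factor shared by all nodes, G^(k) is a factor shared by
the nodes of network k, U and V are nuisance (CSF-like and white-matter-like)
signals, and eps is white Gaussian noise. The per-node multipliers h_i
(drawn once per cohort, shared by all subjects) give every cohort a stable,
heterogeneous strength profile — the hub structure that group-average
strength templates and the node disruption index rely on; setting
``node_coupling_spread = 0`` recovers the homogeneous model. All factors are unit-variance
Gaussian series band-limited to 0.01-0.1 Hz at the configured sampling
interval, so an ideal band-pass of that band leaves the signal intact. The
group loading g is the single knob that produces the hypoconnectivity
gradient; the implied noiseless covariance is positive semidefinite by
construction.

Head motion is simulated as a cumulative random walk on the six rigid-body
parameters with optional persistent spikes, and an optional motion artifact
adds a spatially correlated component scaled by framewise displacement whose
inter-node sharing decays as exp(-distance / scale), producing the
characteristic distance-dependent corruption of connectivity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from ._utils import bandlimited_series
from .motion import framewise_displacement
from .parcellation import Parcellation

_FLOAT_FMT = "%.12g"
_REALIGNMENT_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class MotionDesign:
    """Parameters of the simulated head-motion process.

    walk_sd_trans / walk_sd_rot are the per-step standard deviations of the
    random walk on translations (mm) and rotations (rad). Spikes occur
    independently per timepoint with probability ``spike_rate`` and shift one
    translation parameter by ``spike_scale`` mm from that frame onward.
    ``artifact_gain`` couples framewise displacement to an injected shared
    signal whose inter-node correlation decays as
    exp(-distance / artifact_distance_scale); a gain of 0 yields
    motion-independent data.
    """

    walk_sd_trans: float = 0.02
    walk_sd_rot: float = 4e-4
    spike_rate: float = 0.02
    spike_scale: float = 0.5
    artifact_gain: float = 0.0
    artifact_distance_scale: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        for name in (
            "walk_sd_trans",
            "walk_sd_rot",
            "spike_scale",
            "artifact_gain",
            "artifact_distance_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortDesign:
    """Study design of a simulated three-group cohort.

    Defaults emulate the matched design of the analysis: 14 subjects per
    group, TR = 2 s, and a global-coupling gradient CON > SIB > ASC.
    """

    n_per_group: int = 14
    groups: tuple[str, ...] = ("CON", "SIB", "ASC")
    global_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"CON": 0.8, "SIB": 0.6, "ASC": 0.4}
    )
    within_network_loading: float = 0.5
    node_coupling_spread: float = 0.5
    confound_loadings: tuple[float, float] = (0.2, 0.2)
    noise_sd: float = 1.0
    n_timepoints: int = 300
    sampling_interval: float = 2.0
    condition: str = "rest"
    motion: MotionDesign = field(default_factory=MotionDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        missing = [g for g in self.groups if g not in self.global_coupling]
        if missing:
            raise ValueError(f"groups without a global coupling: {missing}")
        for g, v in self.global_coupling.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"global coupling for {g} must be finite and >= 0")
        if self.within_network_loading < 0 or not np.isfinite(
            self.within_network_loading
        ):
            raise ValueError("within_network_loading must be finite and >= 0")
        if not 0 <= self.node_coupling_spread < 1:
            raise ValueError("node_coupling_spread must lie in [0, 1)")


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated (or loaded) subject.

    ``truth`` holds the generating parameters and nuisance series so that
    recovery can be verified downstream; it is empty for loaded real data.
    """

    subject_id: str
    group: str
    timeseries: np.ndarray  # T x N
    realignment: np.ndarray  # T x 6
    condition: str = "rest"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        ra = np.asarray(self.realignment, dtype=float)
        if ts.ndim != 2 or ra.ndim != 2 or ra.shape[1] != 6:
            raise ValueError("timeseries must be T x N and realignment T x 6")
        if ts.shape[0] != ra.shape[0]:
            raise ValueError("timeseries and realignment must share T")
        if not (np.isfinite(ts).all() and np.isfinite(ra).all()):
            raise ValueError("non-finite values in subject data")
        object.__setattr__(self, "timeseries", ts)
        object.__setattr__(self, "realignment", ra)


def generate_motion_trace(T: int, design: MotionDesign, seed: int) -> np.ndarray:
    """Simulate a T x 6 realignment trace (3 translations mm, 3 rotations rad).

    Each parameter follows a cumulative Gaussian random walk starting at 0.
    Spikes are persistent level shifts of magnitude ``spike_scale`` (random
    sign) applied to one randomly chosen translation parameter, so each spike
    produces exactly one framewise step of that magnitude.
    """
    if T < 2:
        raise ValueError("need T >= 2 (no frame-to-frame derivative otherwise)")
    rng = np.random.default_rng(seed)
    steps = np.zeros((T, 6))
    steps[1:, :3] = rng.normal(0.0, design.walk_sd_trans, size=(T - 1, 3))
    steps[1:, 3:] = rng.normal(0.0, design.walk_sd_rot, size=(T - 1, 3))
    spike_frames = np.flatnonzero(rng.random(T - 1) < design.spike_rate) + 1
    for t in spike_frames:
        param = rng.integers(0, 3)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        steps[t, param] += sign * design.spike_scale
    return np.cumsum(steps, axis=0)


def _artifact_mixing(parc: Parcellation, scale: float) -> np.ndarray:
    """Cholesky factor of the exp(-d/scale) spatial correlation kernel."""
    if scale <= 0:
        return np.eye(parc.n_nodes)
    kernel = np.exp(-parc.distance_matrix() / scale)
    kernel[np.diag_indices_from(kernel)] += 1e-8
    return linalg.cholesky(kernel, lower=True)


def generate_cohort(parc: Parcellation, design: CohortDesign) -> list[SubjectRecord]:
    """Simulate all subjects of a cohort under the factor model.

    Subjects are ordered by group (in ``design.groups`` order). Identical
    seeds and designs yield bit-identical cohorts.
    """
    networks = parc.networks
    net_index = {name: k for k, name in enumerate(networks)}
    node_net = np.array([net_index[str(lab)] for lab in parc.labels])
    c1, c2 = design.confound_loadings
    mixing = (
        _artifact_mixing(parc, design.motion.artifact_distance_scale)
        if design.motion.artifact_gain > 0
        else None
    )

    n_subjects = design.n_per_group * len(design.groups)
    seeds = np.random.SeedSequence(design.seed).spawn(n_subjects + 1)
    # Per-node multiplier on the global coupling, shared by every subject of
    # the cohort. Real strength profiles are heterogeneous and stable across
    # individuals (hubs); without this the group-average strength template
    # would carry no node-level signal and the NDI would be uninformative.
    profile_rng = np.random.default_rng(seeds[-1])
    node_coupling = 1.0 + design.node_coupling_spread * profile_rng.uniform(
        -1.0, 1.0, parc.n_nodes
    )
    subjects: list[SubjectRecord] = []
    idx = 0
    T = design.n_timepoints
    for group in design.groups:
        g = float(design.global_coupling[group])
        for _ in range(design.n_per_group):
            child = seeds[idx]
            rng = np.random.default_rng(child)
            motion_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
            realignment = generate_motion_trace(T, design.motion, motion_seed)

            factors = bandlimited_series(
                rng, T, 1 + len(networks) + 2, design.sampling_interval
            )
            global_factor = factors[:, 0]
            network_factors = factors[:, 1 : 1 + len(networks)]
            confounds = factors[:, 1 + len(networks) :]

            ts = (
                g * node_coupling[None, :] * global_factor[:, None]
                + design.within_network_loading * network_factors[:, node_net]
                + c1 * confounds[:, [0]]
                + c2 * confounds[:, [1]]
                + rng.normal(0.0, design.noise_sd, size=(T, parc.n_nodes))
            )
            if mixing is not None:
                fd = framewise_displacement(realignment)
                shared = rng.standard_normal((T, parc.n_nodes)) @ mixing.T
                ts = ts + design.motion.artifact_gain * fd[:, None] * shared

            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    timeseries=ts,
                    realignment=realignment,
                    condition=design.condition,
                    truth={
                        "global_coupling": g,
                        "within_network_loading": design.within_network_loading,
                        "node_coupling": node_coupling,
                        "confound_loadings": (c1, c2),
                        "confounds": confounds,
                        "noise_sd": design.noise_sd,
                    },
                )
            )
            idx += 1
    return subjects


# ---------------------------------------------------------------------------
# Text serialization (TSV + JSON manifest); round-trips at 12 significant
# digits.
# ---------------------------------------------------------------------------


def write_timeseries(path: str | Path, ts: np.ndarray, parc: Parcellation) -> None:
    frame = pd.DataFrame(ts, columns=[f"node_{i}" for i in parc.node_ids])
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(float)


def write_realignment(path: str | Path, realignment: np.ndarray) -> None:
    frame = pd.DataFrame(realignment, columns=list(_REALIGNMENT_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_realignment(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")[list(_REALIGNMENT_COLUMNS)].to_numpy(float)


def write_cohort(
    directory: str | Path,
    subjects: Sequence[SubjectRecord],
    parc: Parcellation,
    design: CohortDesign | None = None,
) -> Path:
    """Write a cohort as TSV files plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    parc.to_tsv(directory / "parcellation.tsv")
    entries = []
    for sub in subjects:
        ts_name = f"{sub.subject_id}_timeseries.tsv"
        ra_name = f"{sub.subject_id}_realignment.tsv"
        write_timeseries(directory / ts_name, sub.timeseries, parc)
        write_realignment(directory / ra_name, sub.realignment)
        entry = {
            "subject_id": sub.subject_id,
            "group": sub.group,
            "condition": sub.condition,
            "timeseries": ts_name,
            "realignment": ra_name,
        }
        if "confounds" in sub.truth:
            cf_name = f"{sub.subject_id}_confounds.tsv"
            pd.DataFrame(
                sub.truth["confounds"], columns=["csf_like", "wm_like"]
            ).to_csv(directory / cf_name, sep="\t", index=False, float_format=_FLOAT_FMT)
            entry["confounds"] = cf_name
        entries.append(entry)
    manifest = {
        "parcellation": "parcellation.tsv",
        "subjects": entries,
        "seed": None if design is None else design.seed,
        "design": None if design is None else _design_to_jsonable(design),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def _design_to_jsonable(design: CohortDesign) -> dict:
    out = dataclasses.asdict(design)
    out["global_coupling"] = dict(design.global_coupling)
    return out


def read_cohort(directory: str | Path) -> tuple[list[SubjectRecord], Parcellation]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    parc = Parcellation.from_tsv(directory / manifest["parcellation"])
    subjects = []
    for entry in manifest["subjects"]:
        truth = {}
        if "confounds" in entry:
            truth["confounds"] = pd.read_csv(
                directory / entry["confounds"], sep="\t"
            ).to_numpy(float)
        subjects.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                group=entry["group"],
                timeseries=read_timeseries(directory / entry["timeseries"]),
                realignment=read_realignment(directory / entry["realignment"]),
                condition=entry["condition"],
                truth=truth,
            )
        )
    return subjects, parc
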