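"""Brain parcellations: node centroids and functional-network labels.

A parcellation partitions the brain into regions of interest (nodes), each
with a 3-D centroid in millimetres and a functional-network label. The
analyses downstream operate on a 258-node scheme obtained from a 264-node
scheme split into 14 functional networks after excluding six nodes; of the
14 networks, 9 are analysed for hub topography (the auditory, two
somatomotor and two functionally imprecise networks are excluded).

The packaged 264-node parcellation is a synthetic stand-in: centroids are
sampled inside a brain-scale ellipsoid, not real MNI coordinates. Only
relative distances matter for the distance-dependent artifact model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: The 14 canonical functional-network names. The first nine are the ones
#: analysed for hub topography; the remaining five (auditory, two
#: somatomotor, memory retrieval, unassigned) are excluded from hub counts.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "default_mode",
    "visual",
    "frontoparietal",
    "cingulo_opercular",
    "salience",
    "dorsal_attention",
    "ventral_attention",
    "subcortical",
    "cerebellar",
    "auditory",
    "somatomotor_hand",
    "somatomotor_mouth",
    "memory_retrieval",
    "uncertain",
)

ANALYZED_NETWORKS: tuple[str, ...] = CANONICAL_NETWORKS[:9]

#: Semi-axes (mm) of the ellipsoid used for synthetic centroid sampling,
#: roughly brain-scale in x (left-right), y (anterior-posterior), z.
ELLIPSOID_SEMI_AXES = (70.0, 85.0, 60.0)

_DEFAULT_PARCELLATION_RESOURCE = "parcellation264_synthetic.tsv"


@dataclass(frozen=True)
class Parcellation:
    """Immutable set of nodes with centroids and network labels.

    Attributes
    ----------
    node_ids:
        Unique integer node identifiers, shape (N,).
    centroids:
        Node centroids in mm, shape (N, 3).
    labels:
        Functional-network label per node, shape (N,).
    """

    node_ids: np.ndarray
    centroids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_ids, dtype=int)
        cen = np.asarray(self.centroids, dtype=float)
        lab = np.asarray(self.labels, dtype=object)
        if ids.ndim != 1 or cen.shape != (ids.size, 3) or lab.shape != ids.shape:
            raise ValueError("inconsistent parcellation field shapes")
        if np.unique(ids).size != ids.size:
            raise ValueError("node ids must be unique")
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "centroids", cen)
        object.__setattr__(self, "labels", lab)

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels, in canonical order then alphabetical."""
        present = set(self.labels.tolist())
        ordered = [n for n in CANONICAL_NETWORKS if n in present]
        ordered += sorted(present - set(CANONICAL_NETWORKS))
        return tuple(ordered)

    @property
    def analyzed_mask(self) -> np.ndarray:
        """Boolean mask of nodes belonging to the nine analysed networks."""
        return np.isin(self.labels.astype(str), ANALYZED_NETWORKS)

    def network_indices(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.labels.astype(str) == network)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between centroids, mm, shape (N, N)."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def subset(self, mask: np.ndarray) -> "Parcellation":
        mask = np.asarray(mask, dtype=bool)
        return Parcellation(self.node_ids[mask], self.centroids[mask], self.labels[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "network": self.labels.astype(str),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Parcellation":
        return cls(
            frame["node_id"].to_numpy(int),
            frame[["x", "y", "z"]].to_numpy(float),
            frame["network"].to_numpy(object),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def generate_parcellation(n_nodes: int, n_networks: int, seed: int) -> Parcellation:
    """Sample a synthetic parcellation: ellipsoid centroids, near-equal networks.

    Centroids are drawn uniformly inside a brain-scale ellipsoid
    (semi-axes 70 x 85 x 60 mm) by rejection sampling. Nodes are assigned to
    ``n_networks`` networks with sizes differing by at most one, in a
    seed-determined random arrangement. Deterministic for a fixed seed.
    """
    if n_nodes < 1 or n_networks < 1:
        raise ValueError("n_nodes and n_networks must be positive")
    if n_networks > n_nodes:
        raise ValueError("cannot have more networks than nodes")
    if n_networks > len(CANONICAL_NETWORKS):
        raise ValueError(f"at most {len(CANONICAL_NETWORKS)} networks supported")
    rng = np.random.default_rng(seed)
    semi = np.asarray(ELLIPSOID_SEMI_AXES)

    centroids = np.empty((0, 3))
    while centroids.shape[0] < n_nodes:
        cand = rng.uniform(-1.0, 1.0, size=(2 * n_nodes, 3))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        centroids = np.vstack([centroids, cand * semi])
    centroids = centroids[:n_nodes]

    base, extra = divmod(n_nodes, n_networks)
    sizes = np.full(n_networks, base)
    sizes[:extra] += 1
    labels = np.repeat(np.asarray(CANONICAL_NETWORKS[:n_networks], dtype=object), sizes)
    labels = labels[rng.permutation(n_nodes)]
    return Parcellation(np.arange(n_nodes), centroids, labels)


def load_default_parcellation(apply_exclusions: bool = True) -> Parcellation:
    """Load the packaged synthetic 264-node parcellation.

    With ``apply_exclusions`` (the default) the six nodes flagged as falling
    outside the usable field of view are dropped, leaving the 258 analysis
    nodes. Node ids of the retained nodes keep their original values.
    """
    with resources.files("endonet.data").joinpath(
        _DEFAULT_PARCELLATION_RESOURCE
    ).open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    if apply_exclusions:
        frame = frame[frame["excluded"] == 0]
    return Parcellation.from_frame(frame.reset_index(drop=True))
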