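"""Network parcellation and the canonical connectivity-feature ordering.

Network-level functional connectivity is summarised by one value per
within-network connection (n values) plus one value per unordered
between-network pair (n(n-1)/2 values).  For the default 18-network
parcellation this yields 18 + 153 = 171 features.

Canonical ordering: within-network features for networks 1..n first, then
between-network pairs (i, j), i < j, in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default 18 intrinsic networks with a 7-cluster grouping (fronto-parietal,
#: motor/visuospatial, emotion/interoception, audition/speech, visual,
#: cerebellum, default-mode).  The names follow the usual whole-brain
#: ICA-network nomenclature; the cluster assignment is the package's synthetic
#: stand-in for a hierarchical clustering of the networks.
DEFAULT_NETWORKS: tuple[tuple[str, str], ...] = (
    ("left-fronto-parietal", "fronto-parietal"),
    ("middle-frontal-parietal", "fronto-parietal"),
    ("supplementary-motor", "motor/visuospatial"),
    ("right-fronto-parietal", "fronto-parietal"),
    ("cingulo-opercular", "emotion/interoception"),
    ("lateral-temporal", "audition/speech"),
    ("lateral-occipital", "visual"),
    ("basal-ganglia", "emotion/interoception"),
    ("sensorimotor-mouth", "motor/visuospatial"),
    ("midbrain", "emotion/interoception"),
    ("sensorimotor-hand", "motor/visuospatial"),
    ("cerebellum", "cerebellum"),
    ("medial-visual", "visual"),
    ("orbitofrontal", "emotion/interoception"),
    ("auditory", "audition/speech"),
    ("medial-prefrontal-default", "default-mode"),
    ("precuneus-default", "default-mode"),
    ("superior-parietal", "motor/visuospatial"),
)

CLUSTER_NAMES: tuple[str, ...] = (
    "fronto-parietal",
    "motor/visuospatial",
    "emotion/interoception",
    "audition/speech",
    "visual",
    "cerebellum",
    "default-mode",
)


@dataclass(frozen=True)
class AtlasSpec:
    """A network parcellation: names, per-network voxel counts, cluster map.

    Parameters
    ----------
    network_names
        One label per network, in canonical order.
    voxels_per_network
        Number of voxels belonging to each network (>= 2 each, since a
        within-network connectivity value needs at least one voxel pair).
    cluster_of
        Cluster label of each network.
    """

    network_names: tuple[str, ...]
    voxels_per_network: tuple[int, ...]
    cluster_of: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.network_names)
        if n < 2:
            raise ValueError("an atlas needs at least 2 networks")
        if len(self.voxels_per_network) != n:
            raise ValueError("voxels_per_network must have one entry per network")
        if any(v < 2 for v in self.voxels_per_network):
            raise ValueError("every network needs at least 2 voxels")
        if len(self.cluster_of) != n:
            raise ValueError("cluster_of must assign every network to a cluster")

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def n_voxels(self) -> int:
        return int(sum(self.voxels_per_network))

    @property
    def n_features(self) -> int:
        n = self.n_networks
        return n + n * (n - 1) // 2

    @property
    def n_within(self) -> int:
        return self.n_networks

    @property
    def n_between(self) -> int:
        n = self.n_networks
        return n * (n - 1) // 2

    @property
    def clusters(self) -> tuple[str, ...]:
        """Distinct cluster labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cluster_of:
            seen.setdefault(c, None)
        return tuple(seen)

    # -- canonical feature ordering -------------------------------------

    def feature_pairs(self) -> list[tuple[int, int]]:
        """Network index pair of every feature; (i, i) marks within-network."""
        n = self.n_networks
        pairs = [(i, i) for i in range(n)]
        pairs.extend((i, j) for i in range(n) for j in range(i + 1, n))
        return pairs

    def feature_labels(self) -> list[str]:
        labels = [f"within:{name}" for name in self.network_names]
        names = self.network_names
        n = self.n_networks
        labels.extend(
            f"between:{names[i]}|{names[j]}"
            for i in range(n)
            for j in range(i + 1, n)
        )
        return labels

    def feature_index(self, i: int, j: int | None = None) -> int:
        """Canonical index of the within-network (j is None or j == i) or
        between-network feature for networks ``i`` and ``j`` (0-based)."""
        n = self.n_networks
        if j is None or j == i:
            if not 0 <= i < n:
                raise IndexError(f"network index {i} out of range")
            return i
        a, b = (i, j) if i < j else (j, i)
        if not (0 <= a < b < n):
            raise IndexError(f"network pair ({i}, {j}) out of range")
        # offset of pair (a, b) among lexicographic pairs i<j
        return n + a * n - a * (a + 1) // 2 + (b - a - 1)

    def feature_of_index(self, idx: int) -> tuple[str, int, int]:
        """Inverse of :meth:`feature_index`: returns (kind, i, j)."""
        pairs = self.feature_pairs()
        if not 0 <= idx < len(pairs):
            raise IndexError(f"feature index {idx} out of range")
        i, j = pairs[idx]
        return ("within" if i == j else "between", i, j)

    def voxel_network(self) -> np.ndarray:
        """Voxel -> network id map for a stacked voxel x frame matrix."""
        return np.repeat(
            np.arange(self.n_networks), np.asarray(self.voxels_per_network)
        )

    def between_mask(self) -> np.ndarray:
        """Boolean mask over canonical features selecting between-network ones."""
        mask = np.zeros(self.n_features, dtype=bool)
        mask[self.n_networks:] = True
        return mask


def make_atlas(
    n_networks: int = 18, voxels_per_network: int = 24, seed: int | None = None
) -> AtlasSpec:
    """Build an :class:`AtlasSpec`.

    With 18 networks the default named parcellation and its 7-cluster
    grouping are used; otherwise networks get generic names and are assigned
    round-robin to at most 7 clusters.  ``seed`` is accepted for interface
    symmetry with the other generators; the atlas itself is deterministic.
    """
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    if voxels_per_network < 2:
        raise ValueError("voxels_per_network must be >= 2")
    if n_networks == len(DEFAULT_NETWORKS):
        names = tuple(name for name, _ in DEFAULT_NETWORKS)
        clusters = tuple(cluster for _, cluster in DEFAULT_NETWORKS)
    else:
        names = tuple(f"net{i + 1:02d}" for i in range(n_networks))
        k = min(n_networks, len(CLUSTER_NAMES))
        clusters = tuple(CLUSTER_NAMES[i % k] for i in range(n_networks))
    return AtlasSpec(
        network_names=names,
        voxels_per_network=tuple([voxels_per_network] * n_networks),
        cluster_of=clusters,
    )
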