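"""Reduction of a read-cluster partition to two bipolar groups.

Given the MAP clusters of a segment, clusters whose mean methylation is
site-wise at most ``delta`` form the hypo-methylated candidate group and
clusters site-wise at least ``1 - delta`` form the hyper-methylated candidate
group; by construction the candidate means are separated by at least
``1 - 2*delta`` at every CpG site.  Reads of the remaining clusters are
allocated to the nearer candidate mean (Euclidean distance, ties to the hypo
side).  When candidates cannot be formed — typically at low coverage — a
2-means clustering of the cluster means serves as fallback.

Internally group 1 is always the hyper-methylated side, so that the tested
difference ``mean(G1) - mean(G2)`` is positive under bipolarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .dpm import ClusterPartition, _as_reads

__all__ = [
    "BipolarGroups",
    "form_candidate_groups",
    "reduce_to_bipolar_groups",
    "kmeans_fallback_groups",
]

PROV_CANDIDATE = "candidate"
PROV_ASSIGNED = "distance-assigned"
PROV_KMEANS = "kmeans"


@dataclass
class BipolarGroups:
    """Two read groups: G1 (hyper-methylated) and G2 (hypo-methylated)."""

    g1_members: np.ndarray  # read indices, hyper side
    g2_members: np.ndarray  # read indices, hypo side
    g1_mean: np.ndarray  # final mean over all of G1
    g2_mean: np.ndarray
    h1: np.ndarray | None  # hyper candidate-group mean (None for fallback)
    h2: np.ndarray | None  # hypo candidate-group mean
    provenance: np.ndarray  # (m,) strings: candidate / distance-assigned / kmeans
    delta: float | None
    method: str  # "delta" | "kmeans"

    def __post_init__(self) -> None:
        self.g1_members = np.asarray(self.g1_members, dtype=np.int64)
        self.g2_members = np.asarray(self.g2_members, dtype=np.int64)
        if self.g1_members.size == 0 or self.g2_members.size == 0:
            raise ValueError("both bipolar groups must be nonempty")
        if np.intersect1d(self.g1_members, self.g2_members).size:
            raise ValueError("groups must be disjoint")
        m = self.g1_members.size + self.g2_members.size
        if self.provenance.shape != (m,) and self.provenance.size != m:
            raise ValueError("provenance must cover every read")

    @property
    def m(self) -> int:
        return self.g1_members.size + self.g2_members.size


def form_candidate_groups(
    partition: ClusterPartition, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Read indices of the hyper and hypo candidate groups.

    A cluster is a hyper candidate iff every entry of its mean is
    ``>= 1 - delta``, a hypo candidate iff every entry is ``<= delta``.
    Returns ``(hyper_indices, hypo_indices)``; either may be empty.
    """
    if not (0.0 < delta < 0.5):
        raise ValueError("delta must lie in (0, 0.5)")
    means = partition.cluster_means
    hypo_clusters = np.where((means <= delta).all(axis=1))[0]
    hyper_clusters = np.where((means >= 1.0 - delta).all(axis=1))[0]
    hyper_idx = np.where(np.isin(partition.labels, hyper_clusters))[0]
    hypo_idx = np.where(np.isin(partition.labels, hypo_clusters))[0]
    return hyper_idx, hypo_idx


def reduce_to_bipolar_groups(
    reads,
    hyper_candidates: np.ndarray,
    hypo_candidates: np.ndarray,
    delta: float | None = None,
) -> BipolarGroups:
    """Allocate non-candidate reads to the nearer candidate group.

    Candidate reads are never reassigned; each remaining read joins the group
    whose candidate mean (h1 hyper / h2 hypo) is closer in Euclidean distance,
    with exact ties resolved to the hypo side (the conservative choice: it
    weakens apparent separation).  Final group means are recomputed over the
    full groups.
    """
    reads = _as_reads(reads)
    hyper_candidates = np.asarray(hyper_candidates, dtype=np.int64)
    hypo_candidates = np.asarray(hypo_candidates, dtype=np.int64)
    if hyper_candidates.size == 0 or hypo_candidates.size == 0:
        raise ValueError("both candidate groups must be nonempty (fallback required)")
    m = reads.shape[0]
    h1 = reads[hyper_candidates].mean(axis=0)
    h2 = reads[hypo_candidates].mean(axis=0)

    provenance = np.full(m, PROV_ASSIGNED, dtype=object)
    provenance[hyper_candidates] = PROV_CANDIDATE
    provenance[hypo_candidates] = PROV_CANDIDATE

    assigned = np.zeros(m, dtype=bool)
    assigned[hyper_candidates] = True
    assigned[hypo_candidates] = True
    rest = np.where(~assigned)[0]

    g1 = list(hyper_candidates)
    g2 = list(hypo_candidates)
    if rest.size:
        d1 = np.linalg.norm(reads[rest] - h1, axis=1)
        d2 = np.linalg.norm(reads[rest] - h2, axis=1)
        to_hyper = d1 < d2  # ties (d1 == d2) go to the hypo group
        g1.extend(rest[to_hyper])
        g2.extend(rest[~to_hyper])

    g1 = np.sort(np.asarray(g1, dtype=np.int64))
    g2 = np.sort(np.asarray(g2, dtype=np.int64))
    return BipolarGroups(
        g1_members=g1,
        g2_members=g2,
        g1_mean=reads[g1].mean(axis=0),
        g2_mean=reads[g2].mean(axis=0),
        h1=h1,
        h2=h2,
        provenance=provenance,
        delta=delta,
        method="delta",
    )


def kmeans_fallback_groups(
    reads,
    partition: ClusterPartition,
    seed: int = 0,
    restarts: int = 10,
    weighted: bool = False,
) -> BipolarGroups | None:
    """Form bipolar groups by 2-means on the cluster means.

    Used when candidate groups cannot be formed (small read counts or no
    cluster passing the delta criterion).  Each cluster mean counts once
    (set ``weighted=True`` to weight by cluster size); reads inherit their
    cluster's 2-means side, and the side with the larger overall mean
    methylation is the hyper group.

    Returns ``None`` when the segment is trivially non-bipolar (fewer than
    two clusters, or all cluster means identical); the caller should then
    short-circuit to p = 1.
    """
    reads = _as_reads(reads)
    if partition.k < 2:
        return None
    means = partition.cluster_means
    if np.allclose(means, means[0]):
        return None
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    weights = partition.cluster_sizes.astype(float) if weighted else None
    side = km.fit_predict(means, sample_weight=weights)
    if side.min() == side.max():  # degenerate: one side empty
        return None
    center_level = np.array([km.cluster_centers_[s].mean() for s in (0, 1)])
    hyper_side = int(np.argmax(center_level))  # ties -> side 1 is hypo
    read_side = side[partition.labels]
    g1 = np.where(read_side == hyper_side)[0]
    g2 = np.where(read_side != hyper_side)[0]
    provenance = np.full(reads.shape[0], PROV_KMEANS, dtype=object)
    return BipolarGroups(
        g1_members=g1,
        g2_members=g2,
        g1_mean=reads[g1].mean(axis=0),
        g2_mean=reads[g2].mean(axis=0),
        h1=None,
        h2=None,
        provenance=provenance,
        delta=None,
        method="kmeans",
    )
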