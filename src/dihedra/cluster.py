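"""Greedy maximum-neighbor (Daura/gromos) clustering of conformational
ensembles on the C-alpha RMSD metric, with a retention filter on cluster
size and representative extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch_rmsd, pairwise_ca_rmsd
from .synthetic import Ensemble

__all__ = [
    "Cluster",
    "ClusterSet",
    "kabsch_rmsd",
    "daura_cluster",
    "retain_clusters",
    "cluster_ensemble",
]


@dataclass(frozen=True)
class Cluster:
    representative: int  # structure index
    members: tuple[int, ...]  # includes the representative

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Disjoint clusters covering all input structures, in formation order
    (sizes are non-increasing by construction of the greedy algorithm)."""

    clusters: list[Cluster]
    cutoff: float
    n_structures: int
    source: str = ""
    retained: list[bool] | None = None

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def representatives(self, retained_only: bool = False) -> list[int]:
        if retained_only:
            if self.retained is None:
                raise ValueError("retention filter has not been applied")
            return [
                c.representative
                for c, keep in zip(self.clusters, self.retained)
                if keep
            ]
        return [c.representative for c in self.clusters]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            rows.append(
                {
                    "cluster": i,
                    "representative": c.representative,
                    "size": c.size,
                    "fraction": c.size / self.n_structures,
                    "retained": None if self.retained is None else self.retained[i],
                }
            )
        return pd.DataFrame(rows)


def daura_cluster(
    rmsd_or_ensemble: np.ndarray | Ensemble,
    cutoff: float = 2.0,
    source: str = "",
) -> ClusterSet:
    """Cluster structures by the greedy maximum-neighbor algorithm.

    At each iteration the structure with the greatest number of neighbors
    (pairwise RMSD <= cutoff) among the remaining pool becomes a cluster
    representative; it and its neighbors are removed, and the neighbor counts
    of the shrinking pool are recomputed.  Ties in the neighbor count are
    broken by the lowest structure index, which makes the output independent
    of input order.

    Parameters
    ----------
    rmsd_or_ensemble : (n, n) RMSD matrix or Ensemble
        If an ensemble is given, its C-alpha pairwise RMSD matrix is computed.
    cutoff : float
        Neighbor cutoff in Angstrom.
    """
    if isinstance(rmsd_or_ensemble, Ensemble):
        matrix = pairwise_ca_rmsd(rmsd_or_ensemble.ca_stack())
        if not source:
            source = rmsd_or_ensemble.name
    else:
        matrix = np.asarray(rmsd_or_ensemble, dtype=float)
    n = matrix.shape[0]
    if n == 0:
        raise ValueError("need at least one structure")
    adjacency = matrix <= cutoff
    np.fill_diagonal(adjacency, False)

    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero((adjacency[rep] & remaining) | (np.arange(n) == rep))[0]
        clusters.append(Cluster(representative=rep, members=tuple(int(m) for m in members)))
        remaining[members] = False
    return ClusterSet(clusters=clusters, cutoff=cutoff, n_structures=n, source=source)


def retain_clusters(cs: ClusterSet, min_fraction: float = 0.02) -> ClusterSet:
    """Flag clusters holding at least ``min_fraction`` of all structures.

    A cluster at exactly the threshold is retained (only clusters with
    *less* than the threshold fraction are discarded).
    """
    flags = [c.size / cs.n_structures >= min_fraction for c in cs.clusters]
    if not any(flags):
        warnings.warn(
            f"no cluster reaches the retention threshold of {min_fraction:.1%}",
            stacklevel=2,
        )
    return ClusterSet(
        clusters=list(cs.clusters),
        cutoff=cs.cutoff,
        n_structures=cs.n_structures,
        source=cs.source,
        retained=flags,
    )


def cluster_ensemble(
    ensemble: Ensemble, cutoff: float = 2.0, min_fraction: float = 0.02
) -> ClusterSet:
    """Cluster an ensemble and apply the retention filter in one step."""
    return retain_clusters(daura_cluster(ensemble, cutoff=cutoff), min_fraction)
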