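"""Binding-site clustering and ligand ranking on human serum albumin.

Each candidate ligand comes with a predicted binding site: a set of HSA
residues (numbering per PDB entry 1UOR, chain A, 585 residues). Sites are
encoded as ascending residue-number series and compared with dynamic time
warping (DTW), so two sites score as close when their residues occupy
nearby stretches of the chain even if the residue counts differ. The DTW
distance matrix is clustered agglomeratively (average linkage by default)
and cut into ``k`` groups.

Within a cluster of ``n`` ligands, the frequency of a residue, ``f_aa``, is
the number of member ligands whose site contains that residue. A ligand's
rank is

    R = sum over cluster residues r of  (f_aa(r) / n) * k(r),

where ``k(r)`` is 1 if the residue is present in the ligand's own site and
0 otherwise. High-``R`` ligands carry the residues most shared across the
cluster and serve as its representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "BindingSite",
    "ClusterModel",
    "ClusterStats",
    "RankEntry",
    "site_to_series",
    "dtw_distance",
    "distance_matrix",
    "hierarchical_cluster",
    "residue_frequency",
    "rank_ligands",
    "select_representatives",
]

#: HSA chain length; valid residue numbers are 1..585 (PDB 1UOR chain A).
N_HSA_RESIDUES = 585

NUMBERING_SCHEME = "PDB-1UOR-A"


@dataclass(frozen=True)
class BindingSite:
    """Predicted binding site of one ligand on HSA.

    ``residues`` maps residue number (1..585) to an amino-acid code
    (one- or three-letter; the code is carried through for reporting and
    plays no role in the distance). ``true_cluster`` is an optional planted
    label written by the synthetic generator for recovery tests only; the
    clustering code never reads it.
    """

    ligand_id: str
    residues: tuple[tuple[int, str], ...]
    numbering: str = NUMBERING_SCHEME
    true_cluster: int | None = None

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.residues]
        if len(set(numbers)) != len(numbers):
            raise ValueError(f"site {self.ligand_id!r}: duplicate residue numbers")
        for n in numbers:
            if not 1 <= n <= N_HSA_RESIDUES:
                raise ValueError(
                    f"site {self.ligand_id!r}: residue {n} outside 1..{N_HSA_RESIDUES}"
                )

    @property
    def residue_numbers(self) -> frozenset[int]:
        return frozenset(n for n, _ in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def site_to_series(site: BindingSite) -> np.ndarray:
    """Encode a site as its strictly increasing residue-number series."""
    if len(site) == 0:
        raise ValueError(f"site {site.ligand_id!r} is empty")
    return np.sort(np.array([n for n, _ in site.residues], dtype=float))


def dtw_distance(s1: Sequence[float], s2: Sequence[float]) -> float:
    """Classic DTW distance between two number series.

    Local cost |x - y|; symmetric step pattern (match, insert, delete each
    add one local cost term); endpoints anchored; no warping window and no
    path-length normalisation.
    """
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty series")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, n):
        row = acc[i - 1]
        for j in range(1, m):
            acc[i, j] = cost[i, j] + min(row[j - 1], row[j], acc[i, j - 1])
    return float(acc[-1, -1])


def distance_matrix(sites: Sequence[BindingSite]) -> np.ndarray:
    """Pairwise DTW distance matrix over binding sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    series = [site_to_series(s) for s in sites]
    n = len(series)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(series[i], series[j])
    return d


@dataclass
class ClusterStats:
    """Per-cluster bookkeeping for the ranking formula.

    ``n``: number of member ligands; ``a``: number of distinct residues
    across member sites; ``freq``: residue number -> f_aa (count of member
    ligands whose site contains the residue).
    """

    n: int
    a: int
    freq: dict[int, int]

    def percentages(self) -> dict[int, float]:
        """f_aa expressed as 100 * f_aa / n per residue."""
        return {r: 100.0 * f / self.n for r, f in self.freq.items()}


@dataclass
class ClusterModel:
    """Result of clustering a collection of binding sites."""

    sites: list[BindingSite]
    distances: np.ndarray
    linkage_matrix: np.ndarray
    k: int
    labels: dict[str, int]  # ligand_id -> cluster id, 1..k
    cluster_stats: dict[int, ClusterStats] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[BindingSite]:
        return [s for s in self.sites if self.labels[s.ligand_id] == cluster_id]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "labels": dict(self.labels),
            "cluster_stats": {
                str(c): {"n": st.n, "a": st.a, "freq": {str(r): f for r, f in st.freq.items()}}
                for c, st in self.cluster_stats.items()
            },
        }


def hierarchical_cluster(
    sites: Sequence[BindingSite],
    k: int,
    method: str = "average",
    distances: np.ndarray | None = None,
) -> ClusterModel:
    """Agglomerative clustering of sites on the DTW distance matrix.

    The dendrogram is cut to exactly ``k`` flat clusters and cluster ids are
    relabelled 1..k in decreasing cluster size (ties broken by the smallest
    member index), so output labelling is deterministic.
    """
    sites = list(sites)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sites):
        raise ValueError(f"k={k} exceeds number of sites ({len(sites)})")
    d = distance_matrix(sites) if distances is None else np.asarray(distances, float)
    z = linkage(squareform(d, checks=False), method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust can return fewer clusters only on exact distance ties;
        # fall back to cutting at a height between merges
        heights = np.concatenate([[0.0], z[:, 2]])
        cut = heights[len(sites) - k]
        raw = fcluster(z, t=cut, criterion="distance")
    labels = _relabel_by_size(raw)
    model = ClusterModel(
        sites=sites,
        distances=d,
        linkage_matrix=z,
        k=k,
        labels={s.ligand_id: int(c) for s, c in zip(sites, labels)},
    )
    for c in range(1, k + 1):
        members = model.members(c)
        freq, n, a = residue_frequency(members)
        model.cluster_stats[c] = ClusterStats(n=n, a=a, freq=freq)
    return model


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    first_index = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_index[c]))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[c] for c in raw])


def residue_frequency(
    members: Sequence[BindingSite],
) -> tuple[dict[int, int], int, int]:
    """Residue frequencies f_aa within a cluster.

    Returns ``(freq, n, a)``: ``freq[r]`` counts member ligands whose site
    contains residue ``r`` (presence, not multiplicity); ``n`` is the member
    count; ``a`` the number of distinct residues.
    """
    if not members:
        raise ValueError("cluster must have at least one member")
    freq: dict[int, int] = {}
    for site in members:
        for r in site.residue_numbers:
            freq[r] = freq.get(r, 0) + 1
    return freq, len(members), len(freq)


@dataclass(frozen=True)
class RankEntry:
    ligand_id: str
    cluster: int
    R: float


def rank_ligands(
    members: Sequence[BindingSite],
    freq: Mapping[int, int],
    n: int,
    cluster_id: int = 0,
) -> list[RankEntry]:
    """Rank cluster members: R = sum of f_aa/n over residues in the site.

    Sorted by R descending, ties broken by ligand_id ascending.
    """
    entries = []
    for site in members:
        present = site.residue_numbers
        missing = present - set(freq)
        if missing:
            raise ValueError(
                f"ligand {site.ligand_id!r} has residues absent from the cluster "
                f"frequency table (not a member?): {sorted(missing)[:5]}"
            )
        r_val = sum(freq[r] for r in present) / n
        entries.append(RankEntry(site.ligand_id, cluster_id, float(r_val)))
    return sorted(entries, key=lambda e: (-e.R, e.ligand_id))


def rank_all(model: ClusterModel) -> dict[int, list[RankEntry]]:
    """Rank every cluster of a fitted model."""
    out = {}
    for c, st in model.cluster_stats.items():
        out[c] = rank_ligands(model.members(c), st.freq, st.n, cluster_id=c)
    return out


def select_representatives(
    ranks: Sequence[RankEntry], top_m: int
) -> list[RankEntry]:
    """Top-m entries of one cluster's rank list (already tie-broken)."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    ordered = sorted(ranks, key=lambda e: (-e.R, e.ligand_id))
    return ordered[:top_m]
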