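"""Agglomerative clustering of contigs within each super-cluster.

The distance between two clusters is

    1 - R_ab / min(R_a, R_b)   if their expression ratio is constant
    1                          if the ratio test rejects, or R_ab = 0

Clustering repeatedly merges the closest pair, updates the shared-read
counts through the equivalence-class store (which realises the
inclusion–exclusion linkage exactly) and recomputes distances — and re-runs
the ratio test — for pairs involving the merged cluster.  It stops when the
minimum distance exceeds the distance threshold, or when only one cluster
remains.  Pairs at distance exactly 1 are never merged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from contigclust.alignment_io import ExperimentDesign
from contigclust.ratio_test import (
    DEFAULT_P_VALUE,
    d_threshold,
    lrt_statistic,
    pseudocounts,
)
from contigclust.readmodel import (
    EqClassStore,
    SuperCluster,
    build_superclusters,
    condition_counts,
)

__all__ = ["ClusterParams", "ClusterState", "pair_distance", "cluster_supercluster", "run_all"]


@dataclass(frozen=True)
class ClusterParams:
    """Knobs for the clustering engine."""

    d_threshold: float = 0.3
    test_enabled: bool = True
    p_value: float = DEFAULT_P_VALUE
    D_threshold: float | None = None  # explicit override of the p-value-derived threshold

    def stat_threshold(self, n_conditions: int) -> float:
        if self.D_threshold is not None:
            return self.D_threshold
        return d_threshold(n_conditions, self.p_value)


@dataclass
class ClusterState:
    """Evolving partition of one super-cluster.

    ``members`` maps each live cluster id to its original contigs;
    ``distances`` stores only pairs with R_ab > 0 (absent pairs are at the
    maximum distance 1 by definition).
    """

    store: EqClassStore
    design: ExperimentDesign
    params: ClusterParams
    members: dict[str, frozenset[str]] = field(default_factory=dict)
    distances: dict[tuple[str, str], float] = field(default_factory=dict)
    _next_id: int = 0

    @property
    def live_ids(self) -> set[str]:
        return set(self.members)

    def fresh_id(self) -> str:
        self._next_id += 1
        return f"\x00m{self._next_id}"  # NUL prefix cannot collide with contig names

    def pair_key(self, a: str, b: str) -> tuple[str, str]:
        """Deterministic tie-break key: the pair's smallest member contigs."""
        ma, mb = min(self.members[a]), min(self.members[b])
        return (ma, mb) if ma <= mb else (mb, ma)


def pair_distance(state: ClusterState, a: str, b: str) -> float:
    """Shared-read distance between two live clusters, with ratio-test override."""
    r_ab = state.store.shared_count([a, b])
    if r_ab == 0:
        return 1.0
    if state.params.test_enabled and state.design.n_conditions >= 2:
        ra, rb, rab = condition_counts(state.store, a, b, state.design)
        # r_aij in the pseudocount formula excludes fragments shared with b
        ra_excl = [x - s for x, s in zip(ra, rab)]
        rb_excl = [x - s for x, s in zip(rb, rab)]
        pc = pseudocounts(ra_excl, rb_excl, rab)
        res = lrt_statistic(pc, state.params.stat_threshold(state.design.n_conditions))
        if res.reject:
            return 1.0
    r_a = state.store.shared_count([a])
    r_b = state.store.shared_count([b])
    return 1.0 - r_ab / min(r_a, r_b)


def _init_state(
    sc: SuperCluster, design: ExperimentDesign, params: ClusterParams
) -> ClusterState:
    store = sc.substore(len(design.samples))
    state = ClusterState(store=store, design=design, params=params)
    state.members = {cid: frozenset([cid]) for cid in sc.member_ids}
    pairs: set[frozenset[str]] = set()
    for key, _ in store.items():
        if len(key) > 1:
            pairs.update(frozenset(p) for p in itertools.combinations(key, 2))
    for pair in pairs:
        a, b = sorted(pair)
        state.distances[(a, b)] = pair_distance(state, a, b)
    return state


def _min_pair(state: ClusterState) -> tuple[tuple[str, str], float] | None:
    best = None
    for pair, dist in state.distances.items():
        cand = (dist, state.pair_key(*pair))
        if best is None or cand < best[0]:
            best = (cand, pair)
    if best is None:
        return None
    return best[1], best[0][0]


def cluster_supercluster(
    sc: SuperCluster, design: ExperimentDesign, params: ClusterParams
) -> list[frozenset[str]]:
    """Cluster one super-cluster; returns blocks of original contig ids.

    Deterministic: ties on the minimum distance are broken by the pair whose
    (lexicographically smallest member contig, then the other side's
    smallest member) sorts first.  Blocks are returned sorted by their
    smallest contig.
    """
    state = _init_state(sc, design, params)
    while len(state.members) > 1:
        found = _min_pair(state)
        if found is None:
            break
        (a, b), dist = found
        if dist > params.d_threshold or dist >= 1.0:
            break
        new_id = state.fresh_id()
        state.store.merge_clusters(a, b, new_id)
        state.members[new_id] = state.members.pop(a) | state.members.pop(b)
        for pair in [p for p in state.distances if a in p or b in p]:
            del state.distances[pair]
        for other in state.members:
            if other == new_id:
                continue
            if state.store.shared_count([new_id, other]) > 0:
                key = tuple(sorted((new_id, other)))
                state.distances[key] = pair_distance(state, new_id, other)
    blocks = sorted(state.members.values(), key=min)
    return blocks


def run_all(
    store: EqClassStore, design: ExperimentDesign, params: ClusterParams
) -> list[list[frozenset[str]]]:
    """Cluster every super-cluster of a filtered store.

    Returns, per super-cluster (sorted by smallest member contig), the list
    of final blocks.  Contigs in different super-clusters are never
    co-clustered.
    """
    return [
        cluster_supercluster(sc, design, params)
        for sc in build_superclusters(store)
    ]
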