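"""Equivalence-class store: the single source of truth for all read counts.

Fragments with identical contig sets are collapsed into one equivalence
class carrying a per-sample count vector.  Every quantity the clustering
engine needs — the total reads on a cluster, reads shared by a pair or
triple of clusters, and per-condition replicate counts — is computed by
summation over classes whose key is a superset of the query.  Because of
this representation the inclusion–exclusion merge updates

    R_a' = R_a + R_b - R_ab
    R_a'c = R_ac + R_bc - R_abc

hold exactly, by construction, after :meth:`EqClassStore.merge_clusters`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

from contigclust.alignment_io import ExperimentDesign, FragmentRecord

__all__ = [
    "EqClassStore",
    "SuperCluster",
    "build_eqclasses",
    "filter_low_coverage",
    "build_superclusters",
    "condition_counts",
]


class EqClassStore:
    """Maps contig-set keys to per-sample fragment-count vectors.

    Keys reference *current cluster ids*: initially contig ids, later also
    synthetic ids introduced by merges.  A reverse index (cluster id -> keys
    containing it) backs all superset-sum queries.
    """

    def __init__(self, n_samples: int):
        if n_samples < 1:
            raise ValueError("need at least one sample")
        self.n_samples = n_samples
        self._classes: dict[frozenset[str], np.ndarray] = {}
        self._index: dict[str, set[frozenset[str]]] = {}

    # -- construction -------------------------------------------------

    def add(self, key: frozenset[str] | set[str], counts: Iterable[int]) -> None:
        """Add (or accumulate into) the class with the given key."""
        key = frozenset(key)
        if not key:
            raise ValueError("empty class key")
        vec = np.asarray(list(counts), dtype=np.int64)
        if vec.shape != (self.n_samples,):
            raise ValueError(f"count vector must have length {self.n_samples}")
        if (vec < 0).any():
            raise ValueError("negative count")
        if key in self._classes:
            self._classes[key] += vec
        else:
            self._classes[key] = vec
            for cid in key:
                self._index.setdefault(cid, set()).add(key)

    def _remove(self, key: frozenset[str]) -> np.ndarray:
        vec = self._classes.pop(key)
        for cid in key:
            keys = self._index[cid]
            keys.discard(key)
            if not keys:
                del self._index[cid]
        return vec

    # -- queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._classes)

    def items(self) -> Iterator[tuple[frozenset[str], np.ndarray]]:
        return iter(self._classes.items())

    @property
    def live_ids(self) -> set[str]:
        return set(self._index)

    def total_fragments(self) -> np.ndarray:
        """Per-sample fragment totals over all classes."""
        if not self._classes:
            return np.zeros(self.n_samples, dtype=np.int64)
        return np.sum(list(self._classes.values()), axis=0)

    def keys_containing(self, ids: Iterable[str]) -> set[frozenset[str]]:
        """Keys that are supersets of ``ids``.  Unknown id -> KeyError."""
        ids = list(ids)
        if not ids:
            raise ValueError("empty query")
        keysets = []
        for cid in ids:
            if cid not in self._index:
                raise KeyError(f"unknown cluster id {cid!r}")
            keysets.append(self._index[cid])
        out = set(min(keysets, key=len))
        for ks in keysets:
            out &= ks
        return out

    def sample_counts(self, ids: Iterable[str]) -> np.ndarray:
        """Per-sample totals over classes whose key contains every id in ``ids``."""
        keys = self.keys_containing(ids)
        out = np.zeros(self.n_samples, dtype=np.int64)
        for k in keys:
            out += self._classes[k]
        return out

    def shared_count(self, ids: Iterable[str]) -> int:
        """R over a cluster-id set: total fragments mapping to all of them.

        ``shared_count({a})`` is R_a, ``shared_count({a,b})`` is R_ab and
        ``shared_count({a,b,c})`` is R_abc.
        """
        return int(self.sample_counts(ids).sum())

    def contig_total(self, cid: str) -> int:
        return self.shared_count([cid])

    # -- mutation -----------------------------------------------------

    def merge_clusters(self, a: str, b: str, new_id: str) -> None:
        """Relabel clusters ``a`` and ``b`` as ``new_id`` in every class key.

        Classes whose keys become identical are summed.  Afterwards
        ``shared_count({new_id})`` equals R_a + R_b - R_ab and, for any other
        live cluster c, ``shared_count({new_id, c})`` equals
        R_ac + R_bc - R_abc (inclusion–exclusion on the underlying read sets).
        """
        if a == b:
            raise ValueError("cannot merge a cluster with itself")
        for cid in (a, b):
            if cid not in self._index:
                raise KeyError(f"unknown cluster id {cid!r}")
        if new_id in self._index:
            raise ValueError(f"new id {new_id!r} already live")
        touched = self._index[a] | self._index[b]
        for key in list(touched):
            vec = self._remove(key)
            self.add((key - {a, b}) | {new_id}, vec)

    def copy(self) -> "EqClassStore":
        out = EqClassStore(self.n_samples)
        for key, vec in self._classes.items():
            out.add(key, vec)
        return out


@dataclass(frozen=True)
class SuperCluster:
    """A connected component of contigs linked by shared reads.

    Carries the equivalence classes fully contained in its members, so each
    super-cluster can be processed independently.
    """

    member_ids: frozenset[str]
    classes: Mapping[frozenset[str], np.ndarray]

    def substore(self, n_samples: int) -> EqClassStore:
        store = EqClassStore(n_samples)
        for key, vec in self.classes.items():
            store.add(key, vec)
        return store


def build_eqclasses(
    fragments: Iterable[FragmentRecord], design: ExperimentDesign
) -> EqClassStore:
    """Collapse a fragment stream into an equivalence-class store."""
    store = EqClassStore(len(design.samples))
    idx = {s: i for i, s in enumerate(design.samples)}
    vec = np.zeros(len(design.samples), dtype=np.int64)
    for frag in fragments:
        if frag.sample_id not in idx:
            raise KeyError(f"fragment {frag.fragment_id!r} references unknown sample {frag.sample_id!r}")
        vec[:] = 0
        vec[idx[frag.sample_id]] = 1
        store.add(frag.contig_ids, vec)
    return store


def filter_low_coverage(
    store: EqClassStore, min_fragments: int = 10
) -> tuple[EqClassStore, set[str]]:
    """Drop contigs whose total fragment count is below ``min_fragments``.

    Removed contigs are deleted from class keys; classes left with an empty
    key are dropped and their fragments discarded (they cannot be assigned).
    ``min_fragments = 0`` disables filtering.  Idempotent: contigs surviving
    one pass keep their totals, so a second pass at the same threshold is a
    no-op.
    """
    if min_fragments <= 0:
        return store, set()
    removed = {c for c in store.live_ids if store.contig_total(c) < min_fragments}
    if not removed:
        return store, removed
    out = EqClassStore(store.n_samples)
    for key, vec in store.items():
        kept = key - removed
        if kept:
            out.add(kept, vec)
    return out, removed


def build_superclusters(store: EqClassStore) -> list[SuperCluster]:
    """Group contigs into connected components of the read-sharing graph.

    Two contigs are linked when they co-occur in at least one equivalence
    class.  Returned components are sorted by their smallest member id, and
    each carries the classes fully contained in it (every class is, since
    components are unions of class keys).
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(store.live_ids)
    for key, _ in store.items():
        members = sorted(key)
        graph.add_edges_from(zip(members, members[1:]))
    out = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        classes = {
            key: vec.copy() for key, vec in store.items() if key <= members
        }
        out.append(SuperCluster(members, classes))
    out.sort(key=lambda sc: min(sc.member_ids))
    return out


def condition_counts(
    store: EqClassStore, a: str, b: str, design: ExperimentDesign
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-condition, per-replicate counts (r_aij, r_bij, r_abij).

    Each return value is a list over design.conditions of integer arrays,
    one entry per replicate sample in that condition.  r_aij counts every
    fragment mapping to ``a`` (shared ones included); r_abij counts fragments
    mapping to both, so r_abij <= min(r_aij, r_bij) holds elementwise.
    """
    if a == b:
        raise ValueError("a and b must differ")
    per_sample_a = store.sample_counts([a])
    per_sample_b = store.sample_counts([b])
    per_sample_ab = store.sample_counts([a, b])
    r_a, r_b, r_ab = [], [], []
    for cond in design.conditions:
        reps = [design.sample_index(s) for s in design.replicates(cond)]
        r_a.append(per_sample_a[reps])
        r_b.append(per_sample_b[reps])
        r_ab.append(per_sample_ab[reps])
    return r_a, r_b, r_ab
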