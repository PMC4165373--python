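import itertools

import numpy as np
import pytest

from conftest import make_store, random_classes, store_from_classes
from contigclust.alignment_io import ExperimentDesign, FragmentRecord
from contigclust.readmodel import (
    build_eqclasses,
    build_superclusters,
    condition_counts,
    filter_low_coverage,
)


class TestBuildEqclasses:
    def test_aggregation(self, two_cond_design):
        frags = [
            FragmentRecord("r1", "s1", frozenset({"c1"})),
            FragmentRecord("r2", "s1", frozenset({"c1"})),
        ]
        store = build_eqclasses(frags, two_cond_design)
        assert len(store) == 1
        assert store.sample_counts(["c1"]).tolist() == [2, 0]

    def test_cross_sample_class(self, two_cond_design):
        frags = [
            FragmentRecord("r1", "s1", frozenset({"c1", "c2"})),
            FragmentRecord("r2", "s2", frozenset({"c1", "c2"})),
        ]
        store = build_eqclasses(frags, two_cond_design)
        assert store.sample_counts(["c1", "c2"]).tolist() == [1, 1]

    def test_totals(self, two_cond_design):
        frags = [
            FragmentRecord("r1", "s1", frozenset({"a"})),
            FragmentRecord("r2", "s1", frozenset({"a", "b"})),
            FragmentRecord("r3", "s2", frozenset({"b"})),
            FragmentRecord("r4", "s2", frozenset({"a", "b"})),
            FragmentRecord("r5", "s1", frozenset({"a"})),
        ]
        store = build_eqclasses(frags, two_cond_design)
        assert int(store.total_fragments().sum()) == 5
        assert len(store) == 3

    def test_unknown_sample_fatal(self, two_cond_design):
        frags = [FragmentRecord("r1", "nope", frozenset({"a"}))]
        with pytest.raises(KeyError):
            build_eqclasses(frags, two_cond_design)


class TestFilter:
    def test_low_coverage_removed(self):
        store = make_store(1, [({"lo"}, [5]), ({"hi"}, [50])])
        out, removed = filter_low_coverage(store, 10)
        assert removed == {"lo"}
        assert out.live_ids == {"hi"}

    def test_boundary_retained_at_threshold(self):
        # "less than 10" removed: exactly 10 fragments survive
        store = make_store(1, [({"c"}, [10])])
        out, removed = filter_low_coverage(store, 10)
        assert removed == set()

    def test_disabled(self):
        store = make_store(1, [({"lo"}, [1])])
        out, removed = filter_low_coverage(store, 0)
        assert out is store and removed == set()

    def test_key_shrinks_counts_unchanged(self):
        store = make_store(1, [({"keep"}, [40]), ({"keep", "drop"}, [3])])
        out, removed = filter_low_coverage(store, 10)
        assert removed == {"drop"}
        assert out.sample_counts(["keep"]).tolist() == [43]

    def test_orphan_class_dropped(self):
        store = make_store(1, [({"a"}, [2]), ({"b"}, [50])])
        out, _ = filter_low_coverage(store, 10)
        assert out.live_ids == {"b"}
        assert int(out.total_fragments().sum()) == 50

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        store = store_from_classes(random_classes(rng, 6, 2, 8, max_count=8), 2)
        once, _ = filter_low_coverage(store, 10)
        twice, removed2 = filter_low_coverage(once, 10)
        assert removed2 == set()
        assert dict(twice.items()).keys() == dict(once.items()).keys()


class TestSuperclusters:
    def test_components(self):
        store = make_store(1, [({"a", "b"}, [1]), ({"b", "c"}, [2]), ({"d"}, [3])])
        scs = build_superclusters(store)
        assert [sc.member_ids for sc in scs] == [frozenset("abc"), frozenset("d")]

    def test_all_singletons(self):
        store = make_store(1, [({"a"}, [1]), ({"b"}, [1])])
        assert [sc.member_ids for sc in build_superclusters(store)] == [
            frozenset("a"),
            frozenset("b"),
        ]

    def test_classes_partitioned(self):
        store = make_store(1, [({"a", "b"}, [1]), ({"c"}, [2])])
        scs = build_superclusters(store)
        total = sum(sum(int(v.sum()) for v in sc.classes.values()) for sc in scs)
        assert total == int(store.total_fragments().sum())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find(self, seed):
        rng = np.random.default_rng(seed)
        classes = random_classes(rng, 8, 1, 6)
        store = store_from_classes(classes, 1)

        parent = {c: c for c in store.live_ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for key in classes:
            members = sorted(key)
            for u, v in zip(members, members[1:]):
                parent[find(u)] = find(v)
        expected = {}
        for c in store.live_ids:
            expected.setdefault(find(c), set()).add(c)
        got = {sc.member_ids for sc in build_superclusters(store)}
        assert got == {frozenset(v) for v in expected.values()}


class TestSharedCount:
    def test_hand_enumeration(self):
        store = make_store(1, [({"a"}, [4]), ({"a", "b"}, [3])])
        assert store.shared_count(["a"]) == 7
        assert store.shared_count(["a", "b"]) == 3
        assert store.shared_count(["b"]) == 3

    def test_disjoint_pair_zero(self):
        store = make_store(1, [({"a"}, [4]), ({"b"}, [3])])
        assert store.shared_count(["a", "b"]) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_superset_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        store = store_from_classes(random_classes(rng, 5, 2, 10), 2)
        ids = sorted(store.live_ids)
        for a, b in itertools.combinations(ids, 2):
            assert store.shared_count([a, b]) <= min(
                store.shared_count([a]), store.shared_count([b])
            )

    def test_unknown_id_fatal(self):
        store = make_store(1, [({"a"}, [4])])
        with pytest.raises(KeyError):
            store.shared_count(["nope"])


class TestConditionCounts:
    def test_single_contig(self, two_cond_design):
        store = make_store(2, [({"a"}, [3, 0]), ({"b"}, [1, 1])])
        r_a, r_b, r_ab = condition_counts(store, "a", "b", two_cond_design)
        assert [x.tolist() for x in r_a] == [[3], [0]]
        assert [x.tolist() for x in r_ab] == [[0], [0]]

    def test_full_sharing(self, two_cond_design):
        store = make_store(2, [({"a", "b"}, [2, 5])])
        r_a, r_b, r_ab = condition_counts(store, "a", "b", two_cond_design)
        assert [x.tolist() for x in r_a] == [x.tolist() for x in r_ab]
        assert [x.tolist() for x in r_b] == [x.tolist() for x in r_ab]

    @pytest.mark.parametrize("seed", range(5))
    def test_against_fragment_recount(self, seed, four_sample_design):
        # oracle: regenerate fragments one by one and recount directly
        rng = np.random.default_rng(seed)
        classes = random_classes(rng, 4, 4, 8, max_count=6)
        store = store_from_classes(classes, 4)
        frags = []
        for key, vec in classes.items():
            for si, n in enumerate(vec):
                sample = four_sample_design.samples[si]
                frags.extend((key, sample) for _ in range(int(n)))
        for a, b in itertools.combinations(sorted(store.live_ids), 2):
            r_a, r_b, r_ab = condition_counts(store, a, b, four_sample_design)
            for ci, cond in enumerate(four_sample_design.conditions):
                for ji, s in enumerate(four_sample_design.replicates(cond)):
                    na = sum(1 for key, smp in frags if a in key and smp == s)
                    nb = sum(1 for key, smp in frags if b in key and smp == s)
                    nab = sum(
                        1 for key, smp in frags if a in key and b in key and smp == s
                    )
                    assert r_a[ci][ji] == na
                    assert r_b[ci][ji] == nb
                    assert r_ab[ci][ji] == nab
                    assert nab <= min(na, nb)


class TestMergeClusters:
    def test_linkage_example(self):
        # R_a=10, R_b=8, R_ab=3 -> merged total 15
        store = make_store(1, [({"a"}, [7]), ({"b"}, [5]), ({"a", "b"}, [3])])
        store.merge_clusters("a", "b", "m")
        assert store.shared_count(["m"]) == 15

    def test_disjoint_union(self):
        store = make_store(1, [({"a"}, [4]), ({"b"}, [6])])
        store.merge_clusters("a", "b", "m")
        assert store.shared_count(["m"]) == 10

    def test_pair_linkage_example(self):
        # R_ac=4, R_bc=2, R_abc=1 -> R_m,c = 5
        store = make_store(
            1,
            [
                ({"a", "c"}, [3]),
                ({"b", "c"}, [1]),
                ({"a", "b", "c"}, [1]),
                ({"c"}, [2]),
            ],
        )
        assert store.shared_count(["a", "c"]) == 4
        assert store.shared_count(["b", "c"]) == 2
        store.merge_clusters("a", "b", "m")
        assert store.shared_count(["m", "c"]) == 5

    def test_merge_self_fatal(self):
        store = make_store(1, [({"a"}, [1])])
        with pytest.raises(ValueError):
            store.merge_clusters("a", "a", "m")

    def test_merge_unknown_fatal(self):
        store = make_store(1, [({"a"}, [1]), ({"b"}, [1])])
        with pytest.raises(KeyError):
            store.merge_clusters("a", "zzz", "m")

    @pytest.mark.parametrize("seed", range(20))
    def test_linkage_equations_random(self, seed):
        rng = np.random.default_rng(seed)
        classes = random_classes(rng, 5, 2, 10)
        store = store_from_classes(classes, 2)
        ids = sorted(store.live_ids)
        a, b = rng.choice(ids, size=2, replace=False).tolist()
        others = [c for c in ids if c not in (a, b)]
        r_a = store.shared_count([a])
        r_b = store.shared_count([b])
        r_ab = store.shared_count([a, b])
        pair_expect = {
            c: store.shared_count([a, c])
            + store.shared_count([b, c])
            - store.shared_count([a, b, c])
            for c in others
        }
        before = int(store.total_fragments().sum())
        store.merge_clusters(a, b, "merged")
        assert store.shared_count(["merged"]) == r_a + r_b - r_ab
        for c in others:
            assert store.shared_count(["merged", c]) == pair_expect[c]
        assert int(store.total_fragments().sum()) == before
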