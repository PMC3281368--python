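"""Threshold clustering and override-rule tests."""
import numpy as np
import pytest

from its2repeats.distances import DistanceMatrix
from its2repeats.grouping import UNGROUPED, cluster_groups, group_units
from its2repeats.simulate import SimulationConfig, generate_dataset
from its2repeats.detect import find_repeat_array


def dmatrix_from(labels, pairs, default=0.3):
    n = len(labels)
    values = np.full((n, n), default)
    np.fill_diagonal(values, 0.0)
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), d in pairs.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = d
    return DistanceMatrix(labels=labels, values=values)


def components_oracle(dm, threshold):
    """Brute-force BFS connected components of the threshold graph."""
    n = len(dm.labels)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for w in range(n):
                if w != v and dm.values[v, w] < threshold:
                    stack.append(w)
        seen |= comp
        comps.append(frozenset(dm.labels[i] for i in comp))
    return set(comps)


class TestBaseRule:
    def test_all_zero_distances_single_group(self):
        labels = [f"u{i}" for i in range(5)]
        dm = DistanceMatrix(labels=labels, values=np.zeros((5, 5)))
        asg = cluster_groups(dm, threshold=0.1)
        assert asg.n_groups == 1 and asg.n_ungrouped == 0

    def test_matches_component_oracle_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            n = int(rng.integers(5, 40))
            vals = rng.uniform(0.02, 0.3, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            labels = [f"u{i}" for i in range(n)]
            dm = DistanceMatrix(labels=labels, values=vals)
            asg = cluster_groups(dm, threshold=0.1)
            oracle = components_oracle(dm, 0.1)
            got = set()
            for g in range(1, asg.n_groups + 1):
                got.add(frozenset(asg.members(g)))
            for u, g in asg.assignment.items():
                if g is None:
                    got.add(frozenset({u}))
            assert got == oracle

    def test_singletons_end_up_ungrouped(self):
        labels = ["a", "b", "lone"]
        dm = dmatrix_from(labels, {("a", "b"): 0.02})
        asg = cluster_groups(dm, threshold=0.1)
        assert asg.assignment["lone"] is None
        assert asg.label("lone") == UNGROUPED

    def test_group_ids_contiguous_from_one(self):
        labels = ["a", "b", "x", "c", "d"]
        dm = dmatrix_from(labels, {("a", "b"): 0.01, ("c", "d"): 0.01})
        asg = cluster_groups(dm, threshold=0.1)
        assert sorted({g for g in asg.assignment.values() if g}) == [1, 2]
        assert asg.assignment["a"] == 1  # first in label order

    def test_threshold_must_be_positive(self):
        dm = dmatrix_from(["a", "b"], {})
        with pytest.raises(ValueError):
            cluster_groups(dm, threshold=0.0)


class TestOverrides:
    def test_merge_near_threshold_unit_with_supported_clade(self):
        # x sits just above the threshold from a group but forms a strongly
        # supported clade with part of it -> merged, and the event is logged
        labels = ["a", "b", "x"]
        dm = dmatrix_from(labels, {("a", "b"): 0.02, ("a", "x"): 0.109, ("b", "x"): 0.12})
        supports = {frozenset({"b", "x"}): 95.0}
        asg = cluster_groups(dm, threshold=0.1, tree_with_support=supports)
        assert asg.assignment["x"] == asg.assignment["a"]
        assert [e.kind for e in asg.overrides] == ["merge"]

    def test_merge_requires_sufficient_support(self):
        labels = ["a", "b", "x"]
        dm = dmatrix_from(labels, {("a", "b"): 0.02, ("a", "x"): 0.109, ("b", "x"): 0.12})
        supports = {frozenset({"b", "x"}): 50.0}
        asg = cluster_groups(dm, threshold=0.1, tree_with_support=supports)
        assert asg.assignment["x"] is None

    def test_merge_blocked_for_deeply_divergent_unit(self):
        # high support alone is not enough: a unit far beyond the threshold
        # neighbourhood stays ungrouped
        labels = ["a", "b", "x"]
        dm = dmatrix_from(labels, {("a", "b"): 0.02, ("a", "x"): 0.35, ("b", "x"): 0.4})
        supports = {frozenset({"b", "x"}): 99.0}
        asg = cluster_groups(dm, threshold=0.1, tree_with_support=supports)
        assert asg.assignment["x"] is None

    def test_split_subthreshold_link_between_supported_clades(self):
        labels = ["a", "b", "c", "d"]
        dm = dmatrix_from(
            labels,
            {("a", "b"): 0.02, ("c", "d"): 0.02, ("b", "c"): 0.08},
        )
        supports = {frozenset({"a", "b"}): 96.0, frozenset({"c", "d"}): 97.0}
        asg = cluster_groups(dm, threshold=0.1, tree_with_support=supports)
        assert asg.n_groups == 2
        assert asg.assignment["a"] == asg.assignment["b"]
        assert asg.assignment["c"] == asg.assignment["d"]
        assert asg.assignment["a"] != asg.assignment["c"]
        assert any(e.kind == "split" for e in asg.overrides)

    def test_no_split_without_support(self):
        labels = ["a", "b", "c", "d"]
        dm = dmatrix_from(
            labels, {("a", "b"): 0.02, ("c", "d"): 0.02, ("b", "c"): 0.08}
        )
        asg = cluster_groups(dm, threshold=0.1)
        assert asg.n_groups == 1


class TestEndToEnd:
    def test_two_planted_groups_recovered(self):
        cfg = SimulationConfig(
            seed=5, species_codes=("X",), units_per_species=(6,), n_groups=2,
            within_group_divergence=0.02, between_group_divergence=0.2,
            unit_pattern=[[1, 1, 1, 2, 2, 2]],
        )
        records, truth = generate_dataset(cfg)
        array = find_repeat_array(records[0])
        res = group_units(array.units, bootstrap=50, seed=1)
        assert res.assignment.n_groups == 2
        assert res.assignment.n_ungrouped == 0
        truth_groups = {u.name: u.group for u in truth.records["X"].units}
        by_id = {}
        for unit, gid in res.assignment.assignment.items():
            by_id.setdefault(gid, set()).add(truth_groups[unit])
        # each recovered group maps onto exactly one planted group
        assert all(len(v) == 1 for v in by_id.values())

    def test_default_conditions_give_nine_groups_seven_ungrouped(self, fig1_units):
        res = group_units(fig1_units, bootstrap=100, seed=7)
        assert res.assignment.n_groups == 9
        assert res.assignment.n_ungrouped == 7
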