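import math

import numpy as np
import pytest

from ontopop.evaluation import (
    CohesivenessAnnotation,
    cohesiveness,
    correlate_structure,
    granularity,
    path_distance,
    percent_reduction,
    precision_report,
    read_cohesiveness_annotations,
    run_experiment,
)
from ontopop.graph import InstanceRecord, OntoClass, Ontology, UnknownIdError
from ontopop.population import MapperConfig, MappingResult
from ontopop.synthetic import SyntheticSpec, generate_embeddings, generate_ontology, label_vectors


def mk_result(iid, cid):
    return MappingResult(iid, cid, 0.0, 0.0, 0.0)


def tree_fixture():
    """r -> (a, b); a -> (a1, a2); instances under the leaves and b."""
    return Ontology(
        classes=[
            OntoClass("r", "root"),
            OntoClass("a", "left", frozenset({"r"})),
            OntoClass("b", "right", frozenset({"r"})),
            OntoClass("a1", "leaf one", frozenset({"a"})),
            OntoClass("a2", "leaf two", frozenset({"a"})),
        ],
        instances=[
            InstanceRecord("i1", "x", frozenset({"a1"})),
            InstanceRecord("i2", "x", frozenset({"a2"})),
            InstanceRecord("i3", "x", frozenset({"b"})),
            InstanceRecord("i4", "x", frozenset({"b", "a1"})),
        ],
    )


class TestPrecision:
    def test_all_correct(self):
        ont = tree_fixture()
        results = [mk_result("i1", "a1"), mk_result("i2", "a2"), mk_result("i3", "b")]
        rep = precision_report(results, ont)
        assert rep.precision == 1.0 and rep.tp == 3 and rep.fp == 0

    def test_two_of_three(self):
        ont = tree_fixture()
        results = [mk_result("i1", "a1"), mk_result("i2", "a1"), mk_result("i3", "b")]
        rep = precision_report(results, ont)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.tp + rep.fp == rep.n_candidates == 3

    def test_multi_parent_membership(self):
        ont = tree_fixture()
        rep = precision_report([mk_result("i4", "b")], ont)
        assert rep.tp == 1
        rep2 = precision_report([mk_result("i4", "a1")], ont)
        assert rep2.tp == 1  # either true parent counts

    def test_unknown_instance(self):
        with pytest.raises(UnknownIdError):
            precision_report([mk_result("zzz", "a1")], tree_fixture())

    def test_distances_zero_iff_tp(self):
        ont = tree_fixture()
        results = [mk_result("i1", "a1"), mk_result("i2", "a1"), mk_result("i3", "r")]
        rep = precision_report(results, ont)
        assert [d == 0 for d in rep.distances] == [True, False, False]
        assert rep.distance_histogram.get(0, 0) == rep.tp

    def test_per_class_precision(self):
        ont = tree_fixture()
        results = [mk_result("i1", "a1"), mk_result("i2", "a1")]
        rep = precision_report(results, ont)
        assert rep.per_class_precision["a1"] == 1.0
        assert rep.per_class_precision["a2"] == 0.0

    def test_precision_is_mean_indicator(self):
        ont = tree_fixture()
        results = [mk_result("i1", "a2"), mk_result("i2", "a2"), mk_result("i3", "a1")]
        rep = precision_report(results, ont)
        indicators = [ont.instances[r.instance_id].parent_ids >= {r.predicted_class_id} for r in results]
        assert rep.precision == pytest.approx(np.mean(indicators))

    def test_tree_distance_bound(self):
        # on a tree every wrong prediction is >= 1 hop; siblings are 2
        ont = tree_fixture()
        results = [mk_result("i1", "a2"), mk_result("i2", "a1"), mk_result("i3", "b")]
        rep = precision_report(results, ont)
        assert rep.mean_distance >= 2 * (1 - rep.precision) - 1e-12


class TestPathDistance:
    def test_exact_hit(self):
        assert path_distance(tree_fixture(), "a1", {"a1"}) == 0

    def test_sibling_two_hops(self):
        assert path_distance(tree_fixture(), "a1", {"a2"}) == 2

    def test_diamond_siblings(self, diamond):
        assert path_distance(diamond, "B", {"C"}) == 2

    def test_min_over_parents(self):
        assert path_distance(tree_fixture(), "a1", {"a2", "a"}) == 1

    def test_unknown_ids(self):
        with pytest.raises(UnknownIdError):
            path_distance(tree_fixture(), "zz", {"a"})
        with pytest.raises(UnknownIdError):
            path_distance(tree_fixture(), "a", {"zz"})

    def test_undirected_bfs_oracle(self):
        # brute-force BFS on the undirected adjacency built by hand
        ont = generate_ontology(SyntheticSpec(n_classes=12, multi_parent_prob=0.3, rng_seed=2))
        adj = {c: set() for c in ont.classes}
        for c in ont.classes.values():
            for p in c.parent_ids:
                adj[c.id].add(p)
                adj[p].add(c.id)

        def bfs(src, dst):
            from collections import deque

            seen, q = {src}, deque([(src, 0)])
            while q:
                node, d = q.popleft()
                if node == dst:
                    return d
                for nb in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        q.append((nb, d + 1))
            raise AssertionError("disconnected")

        ids = sorted(ont.classes)
        for a in ids[:6]:
            for b in ids[-6:]:
                assert path_distance(ont, a, {b}) == bfs(a, b)


class TestGranularity:
    def test_leaf_with_three_instances(self):
        ont = Ontology(
            classes=[OntoClass("r", "root"), OntoClass("x", "leaf", frozenset({"r"}))],
            instances=[InstanceRecord(f"i{k}", "y", frozenset({"x"})) for k in range(3)],
        )
        assert granularity(ont, "x") == 3.0

    def test_subtree_ratio(self):
        # superclass a: classes {a, a1, a2, a3} and 8 distinct instances
        classes = [
            OntoClass("r", "root"),
            OntoClass("a", "super", frozenset({"r"})),
            OntoClass("a1", "s1", frozenset({"a"})),
            OntoClass("a2", "s2", frozenset({"a"})),
            OntoClass("a3", "s3", frozenset({"a1"})),
        ]
        instances = [InstanceRecord(f"i{k}", "y", frozenset({["a1", "a2", "a3"][k % 3]})) for k in range(8)]
        ont = Ontology(classes, instances)
        assert granularity(ont, "a") == pytest.approx(8 / 4)

    def test_instanceless_subtree(self):
        ont = Ontology(classes=[OntoClass("r", "root"), OntoClass("x", "leaf", frozenset({"r"}))])
        assert granularity(ont, "x") == 0.0

    def test_multi_parent_instance_counted_once(self):
        ont = tree_fixture()
        # subtree of a: {a, a1, a2}; instances i1, i2, i4 (i4 via a1) distinct
        assert granularity(ont, "a") == pytest.approx(3 / 3)

    def test_unknown_id(self):
        with pytest.raises(UnknownIdError):
            granularity(tree_fixture(), "zz")


class TestCohesiveness:
    def test_cheese_worked_example(self):
        ann = CohesivenessAnnotation(
            "cheese food product by organism",
            {
                "cow cheese": True,
                "goat cheese": True,
                "sheep cheese": True,
                "buffalo milk cheese": True,
                "blue cheese": False,
            },
        )
        assert cohesiveness(ann) == pytest.approx(0.8)

    def test_all_correct(self):
        assert cohesiveness(CohesivenessAnnotation("s", {"a": True, "b": True})) == 1.0

    def test_none_correct(self):
        assert cohesiveness(CohesivenessAnnotation("s", {"a": False})) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohesiveness(CohesivenessAnnotation("s", {}))

    def test_read_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("sup\tsub1\t1\nsup\tsub2\t0\nother\tx\t1\n", "utf-8")
        anns = {a.superclass_id: a for a in read_cohesiveness_annotations(p)}
        assert cohesiveness(anns["sup"]) == 0.5
        assert cohesiveness(anns["other"]) == 1.0

    def test_read_tsv_malformed(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("sup\tsub1\tmaybe\n", "utf-8")
        with pytest.raises(ValueError):
            read_cohesiveness_annotations(p)


class TestRunExperiment:
    def setup_method(self):
        self.spec = SyntheticSpec(n_classes=15, instances_mean=4, noise_sigma=0.3, dim=6, rng_seed=5)
        self.ont = generate_ontology(self.spec)
        table, _ = generate_embeddings(self.ont, self.spec)
        self.vectors = label_vectors(self.ont, table)

    def test_single_repeat_equals_single_run(self):
        summ = run_experiment(self.ont, vectors=self.vectors, n_repeats=1, base_seed=3)
        assert summ.n_repeats == 1
        assert summ.mean_precision == summ.per_repeat_precision[0]
        assert summ.pooled_precision == pytest.approx(summ.mean_precision)

    def test_rerun_reproduces_lists(self):
        a = run_experiment(self.ont, vectors=self.vectors, n_repeats=3, base_seed=3)
        b = run_experiment(self.ont, vectors=self.vectors, n_repeats=3, base_seed=3)
        assert a.per_repeat_precision == b.per_repeat_precision
        assert a.per_repeat_mean_distance == b.per_repeat_mean_distance

    def test_random_method_expected_precision(self):
        # single-parent ontology: uniform assignment hits with prob 1/|targets|
        spec = SyntheticSpec(n_classes=20, instances_mean=6, multi_parent_prob=0.0, rng_seed=9)
        ont = generate_ontology(spec)
        summ = run_experiment(
            ont, config=MapperConfig(method="random"), n_seed=1, n_repeats=20, base_seed=0
        )
        n_targets = len(ont.target_class_ids())
        expected = 1 / n_targets
        n_total = sum(len(ont.instances) - n_targets for _ in range(20))
        se = math.sqrt(expected * (1 - expected) / n_total)
        assert abs(summ.pooled_precision - expected) < 3 * se + 1e-9

    def test_n_repeats_zero_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(self.ont, vectors=self.vectors, n_repeats=0)


class TestCorrelate:
    def test_identity_r_one(self):
        m = {"a": 0.1, "b": 0.4, "c": 0.9}
        r, p = correlate_structure(m, m)
        assert r == pytest.approx(1.0)

    def test_negated_r_minus_one(self):
        prec = {"a": 0.1, "b": 0.4, "c": 0.9}
        r, _ = correlate_structure(prec, {k: -v for k, v in prec.items()})
        assert r == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        prec = {"a": 0.2, "b": 0.5, "c": 0.55, "d": 0.7, "e": 0.9}
        metric = {"a": 1.0, "b": 2.5, "c": 2.0, "d": 4.0, "e": 3.5}
        x = np.array([prec[k] for k in sorted(prec)])
        y = np.array([metric[k] for k in sorted(metric)])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r, p = correlate_structure(prec, metric)
        assert r == pytest.approx(expected)
        assert 0.0 <= p <= 1.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate_structure({"a": 1, "b": 2}, {"a": 1, "b": 2})

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            correlate_structure({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})

    def test_intersects_keys(self):
        prec = {"a": 0.1, "b": 0.4, "c": 0.9, "zzz": 0.5}
        metric = {"a": 0.1, "b": 0.4, "c": 0.9, "yyy": 0.5}
        r, _ = correlate_structure(prec, metric)
        assert r == pytest.approx(1.0)


class TestPercentReduction:
    def test_printed_headline(self):
        assert percent_reduction(5.16, 2.91) == pytest.approx(43.6)

    def test_no_rounding_option(self):
        assert percent_reduction(4.0, 3.0, ndigits=None) == pytest.approx(25.0)

    def test_zero_baseline(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)
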