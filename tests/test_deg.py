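import itertools

import numpy as np
import pandas as pd
import pytest

from tfnet.deg import (
    DegCall,
    ExpressionMatrix,
    call_degs,
    cluster_expression,
    crucial_counts,
    ddct,
    deg_sets,
    noise_probabilities,
    noise_probability,
    relative_expression,
    select_crucial,
    threshold_sweep,
    venn_summary,
)


def _matrix(values, conditions, control="control"):
    """values: gene -> list per sample; conditions: per-sample labels."""
    samples = [f"s{i}" for i in range(len(conditions))]
    frame = pd.DataFrame(values, index=samples).T
    meta = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(len(conditions)))},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(frame, meta, control)


class TestRelativeExpression:
    def test_equal_means_zero(self):
        m = _matrix({"g": [5.0, 5.0, 5.0, 5.0]},
                    ["control", "control", "t", "t"])
        rel = relative_expression(m)
        assert rel.values.at["g", "t"] == pytest.approx(0.0)

    def test_fourfold_large_values(self):
        m = _matrix({"g": [1000.0, 1000.0, 4000.0, 4000.0]},
                    ["control", "control", "t", "t"])
        rel = relative_expression(m)
        assert rel.values.at["g", "t"] == pytest.approx(2.0, abs=1e-2)

    def test_pseudocount_validation(self):
        m = _matrix({"g": [1.0, 1.0]}, ["control", "t"])
        with pytest.raises(ValueError):
            relative_expression(m, pseudocount=0)

    def test_planted_log2fc_recovered(self, expression_bundle):
        matrix, truth = expression_bundle
        rel = relative_expression(matrix)
        for gene, per_t in truth["de_signs"].items():
            for t, sign in per_t.items():
                assert rel.values.at[gene, t] * sign > 1.0  # right direction, large


class TestNoiseProbability:
    def _toy(self):
        return _matrix(
            {
                "flat": [10.0, 10.0, 10.0, 10.0],
                "mid": [10.0, 12.0, 30.0, 26.0],
                "big": [5.0, 5.5, 200.0, 210.0],
            },
            ["control", "control", "t", "t"],
        )

    @staticmethod
    def _oracle(matrix, treatment, pseudocount=1.0):
        """Brute-force enumeration of every replicate pair."""
        noise = []
        for cond in matrix.conditions:
            cols = matrix.samples_for(cond)
            for a_col, b_col in itertools.combinations(cols, 2):
                for g in matrix.values.index:
                    a = matrix.values.at[g, a_col]
                    b = matrix.values.at[g, b_col]
                    noise.append(
                        (
                            abs(np.log2((a + pseudocount) / (b + pseudocount))),
                            abs(a - b),
                        )
                    )
        means = matrix.condition_means()
        probs = {}
        for g in matrix.values.index:
            t, c = means.at[g, treatment], means.at[g, matrix.control]
            m = abs(np.log2((t + pseudocount) / (c + pseudocount)))
            d = abs(t - c)
            probs[g] = sum(1 for mn, dn in noise if mn < m and dn < d) / len(noise)
        return probs

    def test_identical_gene_probability_zero(self):
        probs = noise_probability(self._toy(), "t")
        assert probs["flat"] == 0.0

    def test_dominating_gene_probability_one(self):
        probs = noise_probability(self._toy(), "t")
        assert probs["big"] == 1.0

    def test_matches_bruteforce_oracle(self):
        m = self._toy()
        oracle = self._oracle(m, "t")
        probs = noise_probability(m, "t")
        for g in m.values.index:
            assert probs[g] == pytest.approx(oracle[g])

    def test_oracle_on_random_fixture(self, rng):
        vals = {
            f"g{i}": list(rng.uniform(1, 100, size=6)) for i in range(8)
        }
        m = _matrix(vals, ["control"] * 3 + ["t"] * 3)
        oracle = self._oracle(m, "t")
        probs = noise_probability(m, "t")
        for g in m.values.index:
            assert probs[g] == pytest.approx(oracle[g])

    def test_single_replicates_error(self):
        m = _matrix({"g": [1.0, 2.0]}, ["control", "t"])
        with pytest.raises(ValueError):
            noise_probability(m, "t")

    def test_monotone_in_m_and_d(self, rng):
        m = self._toy()
        probs = noise_probability(m, "t")
        # flat < mid < big in both (M, D): probabilities must be ordered
        assert probs["flat"] <= probs["mid"] <= probs["big"]


class TestCallDegs:
    def _rel_probs(self, fc, p):
        rel = relative_expression(
            _matrix({"g": [1.0, 1.0, 1.0, 1.0]}, ["control", "control", "t", "t"])
        )
        rel.values.at["g", "t"] = fc
        probs = pd.DataFrame({"t": [p]}, index=["g"])
        return rel, probs

    def test_probability_below_threshold(self):
        rel, probs = self._rel_probs(3.0, 0.59)
        calls = call_degs(rel, probs)
        assert not calls[0].is_deg

    def test_boundary_inclusive(self):
        rel, probs = self._rel_probs(-1.2, 0.6)
        (call,) = call_degs(rel, probs)
        assert call.is_deg and call.direction == "down"

    def test_fc_boundary_switch(self):
        rel, probs = self._rel_probs(1.0, 0.9)
        assert call_degs(rel, probs)[0].is_deg
        assert not call_degs(rel, probs, fc_inclusive=False)[0].is_deg

    def test_monotone_in_thresholds(self, expression_bundle):
        matrix, _ = expression_bundle
        rel = relative_expression(matrix)
        probs = noise_probabilities(matrix)
        counts = []
        for p0 in (0.3, 0.5, 0.7, 0.9):
            calls = call_degs(rel, probs, p0, 1.0)
            counts.append(sum(c.is_deg for c in calls))
        assert counts == sorted(counts, reverse=True)
        counts_fc = []
        for fc0 in (0.5, 1.0, 1.5, 2.0):
            calls = call_degs(rel, probs, 0.6, fc0)
            counts_fc.append(sum(c.is_deg for c in calls))
        assert counts_fc == sorted(counts_fc, reverse=True)

    def test_planted_de_recall(self, expression_bundle):
        matrix, truth = expression_bundle
        rel = relative_expression(matrix)
        probs = noise_probabilities(matrix)
        calls = call_degs(rel, probs, 0.6, 1.0)
        called = {(c.gene_id, c.treatment) for c in calls if c.is_deg}
        planted = {
            (g, t) for g, per in truth["de_signs"].items() for t in per
        }
        assert planted, "fixture must plant DE genes"
        recall = len(planted & called) / len(planted)
        assert recall >= 0.9


def test_threshold_sweep_shape(expression_bundle):
    matrix, _ = expression_bundle
    rel = relative_expression(matrix)
    probs = noise_probabilities(matrix)
    sweep = threshold_sweep(rel, probs, prob_grid=(0.5, 0.8))
    assert set(sweep.columns) == {"prob_threshold", "treatment", "up", "down"}
    assert len(sweep) == 2 * len(rel.values.columns)


class TestVenn:
    def _calls(self):
        # 10-gene fixture over 3 treatments with known memberships
        spec = {
            "g1": {"a"}, "g2": {"a"}, "g3": {"b"}, "g4": {"a", "b"},
            "g5": {"a", "b", "c"}, "g6": {"c"}, "g7": set(), "g8": {"b", "c"},
            "g9": {"c"}, "g10": set(),
        }
        calls = []
        for g, ts in spec.items():
            for t in ("a", "b", "c"):
                calls.append(DegCall(g, t, 0.9, 2.0, t in ts))
        return calls, spec

    def test_bruteforce_set_algebra(self):
        calls, spec = self._calls()
        summary = venn_summary(calls)
        # independent oracle: direct set enumeration
        oracle = {}
        for g, ts in spec.items():
            if ts:
                key = tuple(sorted(ts))
                oracle[key] = oracle.get(key, 0) + 1
        assert summary["class_counts"] == oracle
        assert summary["unique_deg_total"] == sum(oracle.values())

    def test_non_deg_gene_excluded(self):
        calls, spec = self._calls()
        summary = venn_summary(calls)
        flat = {g for g, ts in spec.items() if not ts}
        assert summary["unique_deg_total"] == 10 - len(flat)

    def test_class_counts_sum_to_distinct_degs(self, expression_bundle):
        matrix, _ = expression_bundle
        rel = relative_expression(matrix)
        probs = noise_probabilities(matrix)
        calls = call_degs(rel, probs)
        summary = venn_summary(calls)
        distinct = len({c.gene_id for c in calls if c.is_deg})
        assert sum(summary["class_counts"].values()) == distinct

    def test_per_family_totals(self):
        calls, spec = self._calls()
        fams = {g: ("F1" if g in {"g1", "g2", "g3"} else "F2") for g in spec}
        summary = venn_summary(calls, fams)
        assert summary["unique_deg_per_family"] == {"F1": 3, "F2": 5}


class TestCrucial:
    def test_empty_terms_error(self):
        with pytest.raises(ValueError):
            select_crucial([], {}, [])

    def test_deg_without_annotation_not_crucial(self):
        calls = [DegCall("g", "t", 0.9, 2.0, True)]
        out = select_crucial(calls, {}, ["response to stress"])
        assert not out[0].is_crucial

    def test_keyword_and_exact_matching(self):
        calls = [
            DegCall("g1", "t", 0.9, 2.0, True),
            DegCall("g2", "t", 0.9, 2.0, True),
            DegCall("g3", "t", 0.9, 2.0, False),
        ]
        annotations = {
            "g1": {"GO:0006950"},
            "g2": {"response to cold stimulus"},
            "g3": {"GO:0006950"},
        }
        out = select_crucial(
            calls, annotations, ["GO:0006950", "response to cold"]
        )
        flags = {c.gene_id: c.is_crucial for c in out}
        assert flags == {"g1": True, "g2": True, "g3": False}

    def test_counts(self):
        calls = [
            DegCall("g1", "cold", 0.9, 2.0, True, True),
            DegCall("g2", "cold", 0.9, 2.0, True, True),
            DegCall("g2", "heat", 0.9, 2.0, True, True),
        ]
        counts = crucial_counts(calls, {"g1": "F1", "g2": "F2"})
        assert counts["per_treatment"] == {"cold": 2, "heat": 1}
        assert counts["total"] == 2
        assert counts["per_family"] == {"F1": 1, "F2": 1}


class TestDdct:
    @pytest.mark.parametrize("dct,expected", [(0, 1.0), (1, 0.5), (-2, 4.0)])
    def test_analytic(self, dct, expected):
        assert ddct(dct) == pytest.approx(expected)

    def test_nonfinite(self):
        with pytest.raises(ValueError):
            ddct(float("nan"))


class TestClusterExpression:
    def test_identical_rows_merge_at_zero(self):
        rel = relative_expression(
            _matrix(
                {"a": [8, 8, 32, 32, 2, 2], "b": [8, 8, 32, 32, 2, 2]},
                ["control", "control", "t1", "t1", "t2", "t2"],
            )
        )
        out = cluster_expression(rel)
        assert out["gene_linkage"][0, 2] == pytest.approx(0.0)

    def test_self_tau_distance_zero(self):
        from tfnet.deg import _kendall_distance_matrix

        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        dist = _kendall_distance_matrix(x)
        assert dist[0, 1] == pytest.approx(0.0)
        assert dist[0, 0] == 0.0

    def test_archetype_recovery(self, expression_bundle):
        matrix, truth = expression_bundle
        rel = relative_expression(matrix)
        out = cluster_expression(rel)
        # genes from the same planted cluster should be contiguous enough
        # that the two most distinct archetypes never interleave at the
        # first merge heights; check identical-cluster genes merge first
        clusters = truth["clusters"]
        order = out["gene_order"]
        assert set(order) == set(rel.values.index)


def test_expression_matrix_validation():
    with pytest.raises(ValueError, match="negative"):
        _matrix({"g": [-1.0, 1.0]}, ["control", "t"])
    with pytest.raises(ValueError, match="control"):
        _matrix({"g": [1.0, 1.0]}, ["a", "b"])
    samples = ["s0", "s1"]
    frame = pd.DataFrame({"s0": [1.0], "s1": [1.0]}, index=["g"])
    frame = pd.concat([frame, frame])  # duplicate gene ids
    meta = pd.DataFrame(
        {"condition": ["control", "t"], "replicate": [1, 1]}, index=samples
    )
    with pytest.raises(ValueError, match="duplicate"):
        ExpressionMatrix(frame, meta)
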