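"""Hierarchy construction, case aggregation, MBD scoring, classification."""

import numpy as np
import pytest

from preterm_fahp import (
    ConsistencyError,
    ExpertCaseJudgment,
    FuzzyPairwiseMatrix,
    HierarchyError,
    JudgmentError,
    TFN,
    ZeroJudgmentWarning,
    aggregate_case,
    assess_case,
    build_hierarchy,
    classify,
    mbd,
    preterm_hierarchy,
    rank_cases,
    round_half_up,
)
from preterm_fahp.model import CaseAssessment, Dimension, Factor, RiskHierarchy

MBD_EXAMPLE = 0.36120376


def all_equal_matrix(labels):
    one = TFN(1, 1, 1)
    n = len(labels)
    return FuzzyPairwiseMatrix(labels, [[one] * n for _ in range(n)])


def judgment(case, expert, labels_by_factor):
    return ExpertCaseJudgment(case, expert, dict(labels_by_factor))


class TestBuildHierarchy:
    def test_all_equal_panel_gives_uniform_weights(self):
        dims = [f"d{j}" for j in range(6)]
        dim_matrix = all_equal_matrix(dims)
        factor_matrices = {
            d: all_equal_matrix([f"{d}_f{i}" for i in range(3)]) for d in dims
        }
        h = build_hierarchy(dim_matrix, factor_matrices)
        assert list(h.dimension_weights().values()) == pytest.approx(
            [1 / 6] * 6
        )
        for d in h.dimensions:
            assert [f.local_weight for f in d.factors] == pytest.approx(
                [1 / 3] * 3
            )
        assert list(h.global_weights().values()) == pytest.approx(
            [1 / 18] * 18
        )
        assert set(h.audit["consistency"]) == {"dimensions", *dims}

    def test_missing_factor_matrix_rejected(self):
        dims = ["d0", "d1"]
        with pytest.raises(HierarchyError, match="missing factor matrices"):
            build_hierarchy(
                all_equal_matrix(dims),
                {"d0": all_equal_matrix(["a", "b"])},
            )

    def test_inconsistent_matrix_rejected_unless_forced(self):
        cycle = [[1, 3, 1 / 3], [1 / 3, 1, 3], [3, 1 / 3, 1]]
        dim_matrix = FuzzyPairwiseMatrix(
            ["d0", "d1", "d2"],
            [[TFN(v, v, v) for v in row] for row in cycle],
        )
        factor_matrices = {
            d: all_equal_matrix([f"{d}a", f"{d}b"])
            for d in ("d0", "d1", "d2")
        }
        with pytest.raises(ConsistencyError, match="CR"):
            build_hierarchy(dim_matrix, factor_matrices)
        h = build_hierarchy(dim_matrix, factor_matrices, force=True)
        assert not h.audit["consistency"]["dimensions"].consistent


class TestPackagedHierarchy:
    def test_dimension_weights_as_published(self):
        h = preterm_hierarchy()
        weights = [d.weight for d in h.dimensions]
        assert weights == [0.339, 0.306, 0.166, 0.1342, 0.042, 0.0115]
        assert abs(sum(weights) - 0.9987) < 1e-6
        assert all(w1 > w2 for w1, w2 in zip(weights, weights[1:]))

    def test_dimension_importance_ordering(self):
        h = preterm_hierarchy()
        names = [d.name for d in h.dimensions]
        assert names.index("information_during_pregnancy") == 0
        assert names.index("medical_history_previous_pregnancies") == 1
        assert names.index("clinical_medical_history") == 2
        assert names.index("gynecological_obstetric_history") == 3
        assert names.index("behavioral_lifestyle") == 4
        assert names.index("socio_personal_economic") == 5

    def test_local_weights_normalized(self):
        h = preterm_hierarchy()
        for d in h.dimensions:
            assert sum(f.local_weight for f in d.factors) == pytest.approx(1)

    def test_hierarchy_rejects_bad_weight_sums(self):
        with pytest.raises(HierarchyError, match="sum to"):
            RiskHierarchy(
                goal="bad",
                dimensions=(
                    Dimension("a", 0.3, (Factor("f", 1.0),)),
                    Dimension("b", 0.2, (Factor("g", 1.0),)),
                ),
            )


class TestAggregateCase:
    def test_single_expert_is_identity(self, case_scale):
        agg = aggregate_case(
            [judgment("c1", "e1", {"f": "medium"})], case_scale
        )
        assert agg[0].e_agg.as_tuple() == pytest.approx((0.4, 0.4, 0.4))
        assert agg[0].degree == pytest.approx(0.4)

    def test_min_geomean_max(self, case_scale):
        js = [
            judgment("c1", "e1", {"f": "low"}),
            judgment("c1", "e2", {"f": "medium"}),
            judgment("c1", "e3", {"f": "very_high"}),
        ]
        agg = aggregate_case(js, case_scale)
        # (0.2 * 0.4 * 0.8)^(1/3) = 0.4 exactly
        assert agg[0].e_agg.as_tuple() == pytest.approx((0.2, 0.4, 0.8))
        assert agg[0].degree == pytest.approx(0.4)

    def test_unanimous_panel_idempotent(self, case_scale):
        js = [
            judgment("c1", f"e{i}", {"f": "high"}) for i in range(35)
        ]
        agg = aggregate_case(js, case_scale)
        assert agg[0].e_agg.as_tuple() == pytest.approx((0.6, 0.6, 0.6))

    def test_mixed_zero_judgment_floored_with_warning(self, case_scale):
        js = [
            judgment("c1", "e1", {"f": "none"}),
            judgment("c1", "e2", {"f": "medium"}),
        ]
        with pytest.warns(ZeroJudgmentWarning):
            agg = aggregate_case(js, case_scale)
        assert agg[0].e_agg.a == pytest.approx(1e-6)
        assert agg[0].e_agg.m > 0

    def test_unanimous_zero_panel_stays_zero(self, case_scale):
        js = [judgment("c1", f"e{i}", {"f": "none"}) for i in range(5)]
        agg = aggregate_case(js, case_scale)
        assert agg[0].e_agg.as_tuple() == (0.0, 0.0, 0.0)

    def test_centroid_defuzzification(self, case_scale):
        js = [
            judgment("c1", "e1", {"f": "low"}),
            judgment("c1", "e2", {"f": "very_high"}),
        ]
        agg = aggregate_case(js, case_scale, defuzz="centroid")
        e = agg[0].e_agg
        assert agg[0].degree == pytest.approx((e.a + e.m + e.b) / 3)

    def test_mismatched_factor_sets_rejected(self, case_scale):
        js = [
            judgment("c1", "e1", {"f": "low"}),
            judgment("c1", "e2", {"g": "low"}),
        ]
        with pytest.raises(JudgmentError, match="same factor set"):
            aggregate_case(js, case_scale)

    def test_mixed_cases_rejected(self, case_scale):
        js = [
            judgment("c1", "e1", {"f": "low"}),
            judgment("c2", "e1", {"f": "low"}),
        ]
        with pytest.raises(JudgmentError, match="several cases"):
            aggregate_case(js, case_scale)


class TestMbd:
    def test_bounds(self, uniform_hierarchy):
        names = uniform_hierarchy.factor_names
        assert mbd(uniform_hierarchy, {f: 1.0 for f in names}) == (
            pytest.approx(1.0)
        )
        assert mbd(uniform_hierarchy, {f: 0.0 for f in names}) == 0.0

    def test_constant_degrees_pass_through(self, uniform_hierarchy):
        names = uniform_hierarchy.factor_names
        assert mbd(uniform_hierarchy, {f: 0.4 for f in names}) == (
            pytest.approx(0.4)
        )

    def test_missing_factor_listed(self, uniform_hierarchy):
        degrees = {f: 0.5 for f in uniform_hierarchy.factor_names}
        degrees.pop("f3_1")
        with pytest.raises(JudgmentError, match="f3_1"):
            mbd(uniform_hierarchy, degrees)

    def test_out_of_range_degree_rejected(self, uniform_hierarchy):
        degrees = {f: 0.5 for f in uniform_hierarchy.factor_names}
        degrees["f0_0"] = 1.2
        with pytest.raises(JudgmentError, match="outside"):
            mbd(uniform_hierarchy, degrees)

    def test_random_properties(self, case_scale):
        """Convexity bounds, monotonicity and permutation invariance."""
        rng = np.random.default_rng(314)
        for _ in range(50):
            n_dims = int(rng.integers(2, 7))
            dims = []
            dw = rng.dirichlet(np.ones(n_dims))
            for j in range(n_dims):
                n_f = int(rng.integers(1, 5))
                fw = rng.dirichlet(np.ones(n_f))
                dims.append(
                    Dimension(
                        f"d{j}",
                        float(dw[j]),
                        tuple(
                            Factor(f"d{j}_f{i}", float(fw[i]))
                            for i in range(n_f)
                        ),
                    )
                )
            h = RiskHierarchy(goal="rand", dimensions=tuple(dims))
            names = list(h.factor_names)
            degrees = {f: float(rng.uniform(0, 1)) for f in names}
            score = mbd(h, degrees)
            vals = list(degrees.values())
            assert min(vals) - 1e-12 <= score <= max(vals) + 1e-12
            # monotone in every degree
            bump = dict(degrees)
            target = names[int(rng.integers(len(names)))]
            bump[target] = min(1.0, bump[target] + 0.1)
            assert mbd(h, bump) >= score - 1e-12
            # insensitive to dict ordering
            shuffled = dict(
                (k, degrees[k])
                for k in rng.permutation(names)
            )
            assert mbd(h, shuffled) == pytest.approx(score, abs=1e-15)


class TestClassify:
    def test_worked_example(self, case_scale):
        cls = classify(MBD_EXAMPLE, case_scale)
        assert round_half_up(cls.fuzzified["low"], 2) == 0.19
        assert round_half_up(cls.fuzzified["medium"], 2) == 0.81
        assert cls.diagnosis == "medium"

    def test_modal_point(self, case_scale):
        cls = classify(0.4, case_scale)
        assert cls.fuzzified["medium"] == 1.0
        assert cls.diagnosis == "medium"

    def test_tie_breaks_toward_higher_risk(self, case_scale):
        cls = classify(0.5, case_scale)
        assert cls.fuzzified["medium"] == pytest.approx(0.5)
        assert cls.fuzzified["high"] == pytest.approx(0.5)
        assert cls.diagnosis == "high"


class TestAssessCase:
    def test_all_none_single_expert(self, uniform_hierarchy, case_scale):
        js = [
            judgment(
                "c1", "e1",
                {f: "none" for f in uniform_hierarchy.factor_names},
            )
        ]
        a = assess_case(uniform_hierarchy, js, case_scale)
        assert a.mbd == 0.0
        assert a.diagnosis == "none"

    def test_all_medium_single_expert(self, uniform_hierarchy, case_scale):
        js = [
            judgment(
                "c1", "e1",
                {f: "medium" for f in uniform_hierarchy.factor_names},
            )
        ]
        a = assess_case(uniform_hierarchy, js, case_scale)
        assert a.mbd == pytest.approx(0.4)
        assert a.diagnosis == "medium"

    def test_overall_column_is_ignored(self, uniform_hierarchy, case_scale):
        labels = {f: "medium" for f in uniform_hierarchy.factor_names}
        labels["overall"] = "extreme"
        a = assess_case(
            uniform_hierarchy, [judgment("c1", "e1", labels)], case_scale
        )
        assert a.mbd == pytest.approx(0.4)

    def test_unknown_factor_rejected(self, uniform_hierarchy, case_scale):
        labels = {f: "medium" for f in uniform_hierarchy.factor_names}
        labels["mystery"] = "low"
        with pytest.raises(JudgmentError, match="mystery"):
            assess_case(
                uniform_hierarchy, [judgment("c1", "e1", labels)], case_scale
            )

    def test_packaged_hierarchy_low_medium_panel_bounds(self, case_scale):
        """A panel concentrated on low/medium labels keeps MBD in [0.2, 0.6]."""
        h = preterm_hierarchy()
        rng = np.random.default_rng(99)
        js = []
        for e in range(35):
            labels = {
                f: ("low" if rng.random() < 0.5 else "medium")
                for f in h.factor_names
            }
            js.append(judgment("c1", f"e{e}", labels))
        a = assess_case(h, js, case_scale)
        assert 0.2 <= a.mbd <= 0.6


class TestRankCases:
    @staticmethod
    def _assessment(case_id, score):
        return CaseAssessment(
            case_id=case_id, judgments=(), mbd=score,
            fuzzified={}, diagnosis="n/a",
        )

    def test_descending_order(self):
        ranked = rank_cases(
            [
                self._assessment("a", 0.2),
                self._assessment("b", 0.8),
                self._assessment("c", 0.5),
            ]
        )
        assert [a.case_id for a in ranked] == ["b", "c", "a"]

    def test_ties_keep_input_order(self):
        ranked = rank_cases(
            [self._assessment(c, 0.4) for c in ("x", "y", "z")]
        )
        assert [a.case_id for a in ranked] == ["x", "y", "z"]

    def test_matches_index_sort_oracle_on_153_cases(self):
        rng = np.random.default_rng(153)
        scores = rng.uniform(0, 1, size=153)
        cases = [
            self._assessment(f"case_{i:03d}", float(s))
            for i, s in enumerate(scores)
        ]
        ranked = rank_cases(cases)
        oracle = sorted(
            range(153), key=lambda i: (-scores[i], i)
        )
        assert [a.case_id for a in ranked] == [
            f"case_{i:03d}" for i in oracle
        ]
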