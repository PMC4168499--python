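import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physiofuse import (
    Case,
    CaseLibrary,
    FeatureVector,
    FuzzyTriangle,
    WeightVector,
    case_similarity,
    classify_k2,
    local_fuzzy_similarity,
    reference_case_library,
    retrieve,
)
from oracles import quadrature_triangle_similarity


def make_case(cid, values, solution=None, names=None):
    names = names or tuple(f"f{i}" for i in range(len(values)))
    return Case(case_id=cid, features=FeatureVector(names, np.array(values, float)), solution=solution)


class TestFuzzyTriangle:
    def test_area_equals_half_width(self):
        assert FuzzyTriangle(3.0, 1.5).area == 1.5

    def test_membership_peaks_at_center(self):
        t = FuzzyTriangle(2.0, 1.0)
        assert t.membership(2.0) == 1.0
        assert t.membership(3.0) == 0.0
        assert t.membership(2.5) == pytest.approx(0.5)


class TestLocalFuzzySimilarity:
    def test_identical_values_give_one(self):
        assert local_fuzzy_similarity(1.7, 1.7) == 1.0

    def test_disjoint_supports_give_zero(self):
        # supports [0.5, 1.5] and [5, 15] do not overlap
        assert local_fuzzy_similarity(1.0, 10.0) == 0.0

    def test_hand_computed_overlap(self):
        # triangles T(1, 0.5) and T(1.5, 0.75): overlap area 0.225,
        # similarity max(0.225/0.5, 0.225/0.75) = 0.45
        assert local_fuzzy_similarity(1.0, 1.5) == pytest.approx(0.45, abs=1e-12)

    def test_agrees_with_quadrature(self):
        assert local_fuzzy_similarity(1.0, 1.5) == pytest.approx(
            quadrature_triangle_similarity(1.0, 1.5), abs=1e-9
        )

    @given(
        st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
        st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
    )
    @settings(derandomize=True, max_examples=150)
    def test_symmetric_and_bounded(self, a, b):
        s1 = local_fuzzy_similarity(a, b)
        s2 = local_fuzzy_similarity(b, a)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert 0.0 <= s1 <= 1.0

    def test_non_increasing_with_separation(self):
        sims = [local_fuzzy_similarity(10.0, 10.0 + d) for d in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(sims, sims[1:]))

    def test_zero_value_uses_library_spread_fallback(self):
        with_fallback = local_fuzzy_similarity(0.0, 0.5, fallback_half_width=2.0)
        assert 0.0 < with_fallback < 1.0

    def test_zero_value_without_fallback_is_crisp(self):
        assert local_fuzzy_similarity(0.0, 0.0) == 1.0
        assert local_fuzzy_similarity(0.0, 0.5) == 0.0


class TestCaseSimilarity:
    def test_identical_cases_give_one(self):
        c = make_case("a", [1.5, -2.0, 30.0])
        s = make_case("b", [1.5, -2.0, 30.0])
        assert case_similarity(c, s) == pytest.approx(1.0)

    def test_weighted_mix_of_locals(self):
        # locals are {1, 0} with weights {3, 1} -> 0.75
        c = make_case("a", [2.0, 1.0])
        s = make_case("b", [2.0, 100.0])
        w = WeightVector({"f0": 3.0, "f1": 1.0})
        assert case_similarity(c, s, w) == pytest.approx(0.75, abs=1e-12)

    def test_invariant_under_weight_rescaling(self):
        c = make_case("a", [2.0, 3.0])
        s = make_case("b", [2.5, 2.0])
        w1 = WeightVector({"f0": 1.0, "f1": 4.0})
        w2 = WeightVector({"f0": 10.0, "f1": 40.0})
        assert case_similarity(c, s, w1) == pytest.approx(case_similarity(c, s, w2), abs=1e-12)

    def test_bounded_by_local_extremes(self, rng):
        for _ in range(20):
            vals_c = rng.uniform(0.5, 5, 4)
            vals_s = rng.uniform(0.5, 5, 4)
            c, s = make_case("a", vals_c), make_case("b", vals_s)
            locals_ = [local_fuzzy_similarity(x, y) for x, y in zip(vals_c, vals_s)]
            sim = case_similarity(c, s)
            assert min(locals_) - 1e-12 <= sim <= max(locals_) + 1e-12

    def test_schema_mismatch_rejected(self):
        c = make_case("a", [1.0], names=("x",))
        s = make_case("b", [1.0], names=("y",))
        with pytest.raises(ValueError, match="schema"):
            case_similarity(c, s)


class TestRetrieve:
    @pytest.fixture
    def library(self):
        lib = CaseLibrary(schema=("f0", "f1"))
        lib.add(make_case("c1", [1.0, 2.0], "Relaxed"))
        lib.add(make_case("c2", [5.0, 6.0], "Stressed"))
        lib.add(make_case("c3", [1.1, 2.1], "Relaxed"))
        return lib

    def test_exact_duplicate_ranks_first(self, library):
        res = retrieve(make_case("q", [5.0, 6.0]), library, k=2)
        assert res.ranked[0][0] == "c2"
        assert res.ranked[0][1] == pytest.approx(1.0)

    def test_k_beyond_size_returns_all(self, library):
        res = retrieve(make_case("q", [1.0, 2.0]), library, k=10)
        assert len(res.ranked) == 3

    def test_is_a_permutation_of_candidates(self, library):
        res = retrieve(make_case("q", [2.0, 3.0]), library, k=3)
        assert sorted(cid for cid, _, _ in res.ranked) == ["c1", "c2", "c3"]

    def test_query_id_excluded_for_leave_one_out(self, library):
        res = retrieve(make_case("c1", [1.0, 2.0]), library, k=3)
        assert "c1" not in [cid for cid, _, _ in res.ranked]

    def test_ties_broken_by_ascending_case_id(self):
        lib = CaseLibrary(schema=("f0",))
        lib.add(make_case("b", [3.0], "Relaxed"))
        lib.add(make_case("a", [3.0], "Stressed"))
        res = retrieve(make_case("q", [3.0]), lib, k=2)
        assert [cid for cid, _, _ in res.ranked] == ["a", "b"]


class TestClassifyK2:
    def test_agreeing_neighbors(self):
        lib = CaseLibrary(schema=("f0",))
        lib.add(make_case("r1", [1.0], "Relaxed"))
        lib.add(make_case("r2", [1.1], "Relaxed"))
        lib.add(make_case("s1", [9.0], "Stressed"))
        cls = classify_k2(make_case("q", [1.05]), lib)
        assert cls.predicted == "Relaxed" and not cls.split_vote

    def test_split_vote_predicts_top1(self):
        lib = CaseLibrary(schema=("f0",))
        lib.add(make_case("s1", [2.0], "Stressed"))
        lib.add(make_case("r1", [2.4], "Relaxed"))
        lib.add(make_case("r2", [9.0], "Relaxed"))
        cls = classify_k2(make_case("q", [2.0]), lib)
        assert cls.predicted == "Stressed" and cls.split_vote

    def test_duplicate_of_stressed_case(self):
        lib = CaseLibrary(schema=("f0", "f1"))
        lib.add(make_case("s1", [4.0, 4.0], "Stressed"))
        lib.add(make_case("r1", [1.0, 1.0], "Relaxed"))
        lib.add(make_case("r2", [1.2, 1.2], "Relaxed"))
        assert classify_k2(make_case("q", [4.0, 4.0]), lib).predicted == "Stressed"

    def test_unlabeled_library_case_rejected(self):
        lib = CaseLibrary(schema=("f0",))
        lib.add(make_case("c1", [1.0], "Relaxed"))
        lib.add(make_case("c2", [2.0]))
        lib.add(make_case("c3", [3.0], "Stressed"))
        with pytest.raises(ValueError, match="unlabeled"):
            classify_k2(make_case("q", [1.0]), lib)


class TestReferenceLibraryRetrieval:
    def test_known_similarity_ordering(self):
        lib = reference_case_library()
        query = Case(case_id="q", features=lib.cases[0].features)
        sims = {
            c.case_id: case_similarity(query, c, lib.weights, feature_sd=lib.feature_sd())
            for c in lib.cases
        }
        assert sims["case14"] > sims["case13"]
        assert sims["case14"] > sims["case15"]
        assert sims["case13"] > sims["case15"]

    def test_top2_and_bottom2(self):
        lib = reference_case_library()
        query = Case(case_id="q", features=lib.cases[0].features)
        ranked = [cid for cid, _, _ in retrieve(query, lib, k=4).ranked]
        assert ranked[:2] == ["case4", "case14"]
        assert set(ranked[2:]) == {"case13", "case15"}


class TestLibraryPersistence:
    def test_json_round_trip(self, tmp_path):
        lib = reference_case_library()
        path = tmp_path / "lib.json"
        lib.to_json(path)
        back = CaseLibrary.from_json(path)
        assert back.schema == lib.schema
        assert back.case_ids == lib.case_ids
        for a, b in zip(lib.cases, back.cases):
            assert a.solution == b.solution
            np.testing.assert_allclose(a.features.values, b.features.values, rtol=1e-15)

    def test_csv_round_trip(self, tmp_path):
        lib = reference_case_library()
        path = tmp_path / "lib.csv"
        lib.to_csv(path)
        back = CaseLibrary.from_csv(path)
        assert back.schema == lib.schema
        for a, b in zip(lib.cases, back.cases):
            np.testing.assert_allclose(a.features.values, b.features.values, rtol=1e-15)
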