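import math

import numpy as np
import pytest

from physiofuse import (
    Case,
    CaseLibrary,
    ChannelWeights,
    ConfusionMatrix,
    FeatureVector,
    derive_channel_weights,
    fuse_similarities,
    leave_one_out,
    metrics,
)
from physiofuse.cbr import local_fuzzy_similarity
from physiofuse.fusion import _report_from_outcomes, fused_ranking
from physiofuse.cbr import Classification

CHANNELS = ("HR", "RR", "FT", "CO2", "SPO2")


def make_case(cid, value, solution=None, name="x"):
    return Case(cid, FeatureVector((name,), np.array([value], float)), solution)


class TestFuseSimilarities:
    def test_constant_similarities_pass_through(self):
        w = ChannelWeights({c: v for c, v in zip(CHANNELS, (3, 1, 7, 2, 9))})
        sims = {c: 0.8 for c in CHANNELS}
        assert fuse_similarities(sims, w) == pytest.approx(0.8)

    def test_weighted_average_example(self):
        w = ChannelWeights({c: v for c, v in zip(CHANNELS, (2, 1, 1, 1, 1))})
        sims = {c: 0.0 for c in CHANNELS}
        sims["HR"] = 1.0
        assert fuse_similarities(sims, w) == pytest.approx(2 / 6)

    def test_equal_weights_reduce_to_mean(self, rng):
        w = ChannelWeights.equal(CHANNELS)
        sims = {c: float(v) for c, v in zip(CHANNELS, rng.uniform(0, 1, 5))}
        assert fuse_similarities(sims, w) == pytest.approx(np.mean(list(sims.values())), abs=1e-12)

    def test_bounded_by_channel_extremes(self, rng):
        for _ in range(20):
            w = ChannelWeights({c: int(v) for c, v in zip(CHANNELS, rng.integers(1, 11, 5))})
            sims = {c: float(v) for c, v in zip(CHANNELS, rng.uniform(0, 1, 5))}
            fused = fuse_similarities(sims, w)
            assert min(sims.values()) - 1e-12 <= fused <= max(sims.values()) + 1e-12

    def test_mismatched_channels_rejected(self):
        w = ChannelWeights({"HR": 1, "RR": 1})
        with pytest.raises(ValueError, match="differ"):
            fuse_similarities({"HR": 0.5}, w)

    def test_weights_outside_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            ChannelWeights({"HR": 0})
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            ChannelWeights({"HR": 11})


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionMatrix(tp=6, fp=0, tn=8, fn=2))
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(0.875)

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=5, fp=0, tn=7, fn=0))
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0

    def test_no_positives_flags_sensitivity(self):
        m = metrics(ConfusionMatrix(tp=0, fp=1, tn=4, fn=0))
        assert math.isnan(m["sensitivity"]) and not math.isnan(m["specificity"])


class TestDeriveChannelWeights:
    def test_equal_accuracies_give_equal_weights(self):
        w = derive_channel_weights({c: 0.8 for c in CHANNELS})
        assert len(set(w.weights.values())) == 1

    def test_linear_rescale_of_accuracy_totals(self):
        accs = {"HR": 0.75, "RR": 0.875, "FT": 0.75, "CO2": 0.8125, "SPO2": 0.75}
        w = derive_channel_weights(accs)
        assert w.weights["RR"] == 10
        assert w.weights["HR"] == w.weights["FT"] == w.weights["SPO2"] == 1
        assert w.weights["CO2"] == round(1 + 9 * 0.5)  # halfway up the range
        assert all(1 <= v <= 10 for v in w.weights.values())

    def test_single_channel_gets_max_weight(self):
        assert derive_channel_weights({"HR": 0.6}).weights["HR"] == 10

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_channel_weights({})


def toy_libraries():
    """Three stored recordings, one feature per channel."""
    values = {
        "HR": {"case1": 70.0, "case2": 80.0, "case3": 71.0},
        "RR": {"case1": 0.25, "case2": 0.35, "case3": 0.26},
        "FT": {"case1": 30.0, "case2": 28.0, "case3": 30.5},
        "CO2": {"case1": 5.0, "case2": 4.5, "case3": 5.1},
        "SPO2": {"case1": 97.0, "case2": 96.0, "case3": 97.2},
    }
    labels = {"case1": "Relaxed", "case2": "Stressed", "case3": "Relaxed"}
    libs = {}
    for ch, by_case in values.items():
        lib = CaseLibrary(schema=(f"{ch}.x",))
        for cid, v in by_case.items():
            lib.add(make_case(cid, v, labels[cid], name=f"{ch}.x"))
        libs[ch] = lib
    return libs, values


class TestFusedRanking:
    def test_identical_query_ranks_first_with_similarity_one(self):
        libs, values = toy_libraries()
        query = {
            ch: make_case("q", values[ch]["case2"], name=f"{ch}.x") for ch in libs
        }
        ranked = fused_ranking(query, libs, ChannelWeights.equal(libs))
        assert ranked[0][0] == "case2"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_matches_hand_computation_of_local_weighted_fusion(self):
        libs, values = toy_libraries()
        w = ChannelWeights({"HR": 2, "RR": 1, "FT": 1, "CO2": 1, "SPO2": 1})
        query = {ch: make_case("q", values[ch]["case1"], name=f"{ch}.x") for ch in libs}
        ranked = {cid: sim for cid, sim, _ in fused_ranking(query, libs, w)}
        sds = {ch: libs[ch].feature_sd() for ch in libs}
        for cid in ("case1", "case2", "case3"):
            num = den = 0.0
            for ch in libs:
                local = local_fuzzy_similarity(
                    values[ch]["case1"], values[ch][cid],
                    fallback_half_width=sds[ch][f"{ch}.x"],
                )
                num += w.weights[ch] * local
                den += w.weights[ch]
            assert ranked[cid] == pytest.approx(num / den, abs=1e-12)

    def test_missing_case_id_in_one_library_rejected(self):
        libs, values = toy_libraries()
        libs["FT"] = CaseLibrary(schema=("FT.x",))
        libs["FT"].add(make_case("case1", 30.0, "Relaxed", name="FT.x"))
        libs["FT"].add(make_case("case2", 28.0, "Stressed", name="FT.x"))
        query = {ch: make_case("q", 1.0, name=f"{ch}.x") for ch in libs}
        with pytest.raises(ValueError, match="case_id sets differ"):
            fused_ranking(query, libs, ChannelWeights.equal(libs))


class TestLeaveOneOut:
    def test_well_separated_classes_are_fully_recovered(self):
        lib = CaseLibrary(schema=("x",))
        for i in range(8):
            lib.add(make_case(f"r{i}", 1.0 + 0.01 * i, "Relaxed"))
        for i in range(8):
            lib.add(make_case(f"s{i}", 100.0 + 0.5 * i, "Stressed"))
        report = leave_one_out(lib)
        assert report.total_accuracy == 1.0
        assert report.confusion.tp == 8 and report.confusion.tn == 8

    def test_singleton_class_cannot_be_correct_and_is_flagged(self):
        lib = CaseLibrary(schema=("x",))
        lib.add(make_case("s1", 5.0, "Stressed"))
        lib.add(make_case("r1", 1.0, "Relaxed"))
        lib.add(make_case("r2", 1.1, "Relaxed"))
        report = leave_one_out(lib)
        assert report.accuracy_by_class["Stressed"] == 0.0
        assert any("Stressed" in f for f in report.flags)

    def test_counts_sum_to_cases(self):
        lib = CaseLibrary(schema=("x",))
        for i in range(5):
            lib.add(make_case(f"r{i}", 1.0 + i, "Relaxed"))
        for i in range(4):
            lib.add(make_case(f"s{i}", 3.5 + i, "Stressed"))
        report = leave_one_out(lib)
        cm = report.confusion
        assert cm.tp + cm.fp + cm.tn + cm.fn == len(lib)

    def test_per_class_rates_combine_to_total(self):
        # 8 queries all correct plus 8 queries 6-of-8 correct -> 87.5% overall
        def cls(label):
            return Classification(predicted=label, evidence=(("x", 1.0, label), ("y", 0.9, label)), split_vote=False)

        outcomes = [(f"r{i}", "Relaxed", cls("Relaxed")) for i in range(8)]
        outcomes += [(f"s{i}", "Stressed", cls("Stressed")) for i in range(6)]
        outcomes += [(f"s{i+6}", "Stressed", cls("Relaxed")) for i in range(2)]
        report = _report_from_outcomes(outcomes)
        assert report.accuracy_by_class["Relaxed"] == 1.0
        assert report.accuracy_by_class["Stressed"] == 0.75
        assert report.total_accuracy == pytest.approx(0.875)
        assert report.confusion.tp == 6 and report.confusion.fn == 2

    def test_decision_level_deterministic_report(self):
        libs, values = toy_libraries()
        r1 = leave_one_out(libs)
        r2 = leave_one_out(libs)
        assert r1.to_dict() == r2.to_dict()
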