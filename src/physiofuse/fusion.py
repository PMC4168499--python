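"""End-to-end classification pipelines and leave-one-out evaluation.

Decision-level fusion: a query recording is compared with every stored
recording separately in each of five per-channel case libraries; the five
channel similarities are combined by a weighted average (weights 1..10
derived from per-channel classification accuracy); the fused ranking then
drives k-nearest-neighbor classification.

Data-level fusion: the five channels are fused up front into one
entropy-vs-scale profile and classified against a single library of
profiles with equal feature weights.

Evaluation is leave-one-out with K=2 retrieval. A query counts as correctly
classified when its true class matches one of the two retrieved cases; the
confusion matrix is built from the top-1 point predictions (Stressed is the
positive class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cbr import Case, CaseLibrary, Classification, WeightVector, case_similarity, classify_k2
from .features import FeatureVector, build_channel_case
from .mmse import EmbeddingConfig, mmse_profile
from .signal_model import MultichannelRecording

__all__ = [
    "ChannelWeights",
    "ConfusionMatrix",
    "EvaluationReport",
    "fuse_similarities",
    "fused_ranking",
    "classify_decision_level",
    "classify_data_level",
    "leave_one_out",
    "metrics",
    "derive_channel_weights",
    "build_decision_level_libraries",
    "build_data_level_library",
]

POSITIVE_CLASS = "Stressed"
NEGATIVE_CLASS = "Relaxed"


@dataclass(frozen=True)
class ChannelWeights:
    """Integer per-channel weights in 1..10 for decision-level fusion."""

    weights: dict

    def __post_init__(self) -> None:
        w = {k: int(v) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        if not w:
            raise ValueError("channel weight map is empty")
        if any(not 1 <= v <= 10 for v in w.values()):
            raise ValueError(f"channel weights must lie in [1, 10], got {w}")

    @classmethod
    def equal(cls, channels) -> "ChannelWeights":
        return cls({c: 1 for c in channels})

    @property
    def channels(self) -> set:
        return set(self.weights)


def fuse_similarities(sims: dict, w: ChannelWeights) -> float:
    """Weighted average sum(w_c * s_c) / sum(w_c) over matching channels."""
    if set(sims) != w.channels:
        raise ValueError(f"channel sets differ: {sorted(sims)} vs {sorted(w.channels)}")
    num = sum(w.weights[c] * float(sims[c]) for c in sims)
    den = sum(w.weights.values())
    fused = num / den
    if not -1e-12 <= fused <= 1 + 1e-12:
        raise ValueError(f"fused similarity {fused} outside [0, 1]")
    return float(min(max(fused, 0.0), 1.0))


def _check_aligned(libs: dict) -> list[str]:
    """Validate that the per-channel libraries index the same recordings
    with consistent labels; returns the shared case_id list."""
    channels = sorted(libs)
    id_sets = {ch: set(libs[ch].case_ids) for ch in channels}
    reference = id_sets[channels[0]]
    for ch in channels[1:]:
        if id_sets[ch] != reference:
            raise ValueError(
                f"case_id sets differ between channel libraries "
                f"{channels[0]} and {ch}"
            )
    labels: dict = {}
    for ch in channels:
        for c in libs[ch].cases:
            if c.case_id in labels and labels[c.case_id] != c.solution:
                raise ValueError(f"conflicting labels for case {c.case_id!r}")
            labels[c.case_id] = c.solution
    return sorted(reference)


def fused_ranking(
    query_cases: dict,
    libs: dict,
    w: ChannelWeights,
    exclude_id: str | None = None,
) -> list[tuple[str, float, str | None]]:
    """Per-stored-recording fusion of channel similarities, ranked descending
    (ties broken by ascending case_id)."""
    if set(query_cases) != set(libs):
        raise ValueError("query channels do not match the libraries' channels")
    if set(libs) != w.channels:
        raise ValueError("channel weights do not match the libraries' channels")
    case_ids = _check_aligned(libs)
    sds = {ch: libs[ch].feature_sd() for ch in libs}
    by_id = {ch: {c.case_id: c for c in libs[ch].cases} for ch in libs}
    rows = []
    for cid in case_ids:
        if cid == exclude_id:
            continue
        sims = {
            ch: case_similarity(
                query_cases[ch],
                by_id[ch][cid],
                libs[ch].weights,
                fuzz=libs[ch].fuzz,
                feature_sd=sds[ch],
            )
            for ch in libs
        }
        label = by_id[sorted(libs)[0]][cid].solution
        rows.append((cid, fuse_similarities(sims, w), label))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


def _classify_ranking(ranked) -> Classification:
    if len(ranked) < 2:
        raise ValueError("need at least 2 candidate cases for K=2 retrieval")
    if any(r[2] is None for r in ranked[:2]):
        raise ValueError("retrieved cases are unlabeled")
    top = tuple(ranked[:2])
    return Classification(
        predicted=top[0][2], evidence=top, split_vote=len({t[2] for t in top}) > 1
    )


def extract_query_cases(rec: MultichannelRecording, case_id: str = "query") -> dict:
    """Per-channel feature cases from a recording (decision-level problem part)."""
    return {
        ch.name: Case(case_id=case_id, features=build_channel_case(ch), solution=None)
        for ch in rec.channels
    }


def classify_decision_level(
    query_rec: MultichannelRecording,
    libs: dict,
    w: ChannelWeights | None = None,
) -> tuple[Classification, list]:
    """Decision-level pipeline for one query recording.

    Features are extracted per channel, each channel's similarity to every
    stored recording is computed in its own library, the similarities are
    fused into one ranking, and the K=2 rule classifies the query.
    Returns the classification and the full fused ranking.
    """
    w = w or ChannelWeights.equal(libs.keys())
    query_cases = extract_query_cases(query_rec)
    missing = set(libs) - set(query_cases)
    if missing:
        raise ValueError(f"query recording lacks channels {sorted(missing)}")
    query_cases = {ch: query_cases[ch] for ch in libs}
    ranked = fused_ranking(query_cases, libs, w)
    return _classify_ranking(ranked), ranked


def classify_data_level(
    query_rec: MultichannelRecording,
    lib: CaseLibrary,
    cfg: EmbeddingConfig | None = None,
    eps_max: int = 9,
) -> tuple[Classification, list]:
    """Data-level pipeline: entropy profile -> equal-weight CBR retrieval."""
    profile = mmse_profile(query_rec, cfg=cfg, eps_max=eps_max)
    feats = FeatureVector.from_dict(profile.as_feature_dict())
    if tuple(feats.names) != lib.schema:
        raise ValueError(
            f"profile features {feats.names} do not match library schema {lib.schema}"
        )
    query = Case(case_id="query", features=feats, solution=None)
    cls = classify_k2(query, lib)
    ranked = retrieve_all(query, lib)
    return cls, ranked


def retrieve_all(query: Case, lib: CaseLibrary) -> list:
    from .cbr import retrieve

    return list(retrieve(query, lib, k=len(lib)).ranked)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with Stressed as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy
    (TP+TN)/(P+N); a zero denominator flags that metric as NaN."""
    sens = cm.tp / cm.positives if cm.positives > 0 else math.nan
    spec = cm.tn / cm.negatives if cm.negatives > 0 else math.nan
    acc = (cm.tp + cm.tn) / cm.total if cm.total > 0 else math.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


@dataclass
class EvaluationReport:
    """Leave-one-out outcome: per-case records, per-class and total accuracy
    under the lenient K=2 rule, top-1 accuracy, confusion matrix, metrics."""

    records: list = field(default_factory=list)
    accuracy_by_class: dict = field(default_factory=dict)
    total_accuracy: float = math.nan
    top1_accuracy: float = math.nan
    confusion: ConfusionMatrix | None = None
    metric_values: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "accuracy_by_class": self.accuracy_by_class,
            "total_accuracy": self.total_accuracy,
            "top1_accuracy": self.top1_accuracy,
            "confusion": None
            if self.confusion is None
            else {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "metrics": self.metric_values,
            "flags": self.flags,
        }

    def render_text(self) -> str:
        lines = ["Leave-one-out evaluation (K=2)", "-" * 34]
        for rec in self.records:
            ev = ", ".join(f"{cid}({lbl} {sim:.3f})" for cid, sim, lbl in rec["evidence"])
            mark = "ok " if rec["correct"] else "MISS"
            lines.append(f"{mark} {rec['query_id']:>8} true={rec['true']:<8} top2: {ev}")
        lines.append("")
        for klass, acc in self.accuracy_by_class.items():
            lines.append(f"{klass:>8} accuracy: {acc * 100:.1f}%")
        lines.append(f"   total accuracy: {self.total_accuracy * 100:.1f}%")
        lines.append(f"   top-1 accuracy: {self.top1_accuracy * 100:.1f}%")
        if self.confusion is not None:
            cm = self.confusion
            lines.append(f"confusion: TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn}")
            m = self.metric_values
            lines.append(
                "sensitivity={sensitivity:.3f} specificity={specificity:.3f} "
                "accuracy={accuracy:.3f}".format(**m)
            )
        for flag in self.flags:
            lines.append(f"note: {flag}")
        return "\n".join(lines)


def _report_from_outcomes(outcomes: list) -> EvaluationReport:
    """Assemble the report from (query_id, true_class, Classification)."""
    records = []
    per_class: dict = {}
    flags: list = []
    tp = fp = tn = fn = 0
    top1_hits = 0
    for query_id, true_class, cls in outcomes:
        evidence_classes = {t[2] for t in cls.evidence}
        correct = true_class in evidence_classes
        records.append(
            {
                "query_id": query_id,
                "true": true_class,
                "predicted": cls.predicted,
                "evidence": [list(t) for t in cls.evidence],
                "split_vote": cls.split_vote,
                "correct": bool(correct),
            }
        )
        per_class.setdefault(true_class, []).append(correct)
        if cls.predicted == true_class:
            top1_hits += 1
        if true_class == POSITIVE_CLASS:
            tp += cls.predicted == POSITIVE_CLASS
            fn += cls.predicted != POSITIVE_CLASS
        else:
            tn += cls.predicted != POSITIVE_CLASS
            fp += cls.predicted == POSITIVE_CLASS
    counts = {k: len(v) for k, v in per_class.items()}
    for klass, n in counts.items():
        if n < 2:
            flags.append(f"class {klass!r} has only {n} case(s); leave-one-out leaves "
                         f"{n - 1} same-class candidate(s)")
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    n_total = len(outcomes)
    return EvaluationReport(
        records=records,
        accuracy_by_class={k: float(np.mean(v)) for k, v in per_class.items()},
        total_accuracy=sum(r["correct"] for r in records) / n_total,
        top1_accuracy=top1_hits / n_total,
        confusion=cm,
        metric_values=metrics(cm),
        flags=flags,
    )


def leave_one_out(
    lib_or_libs,
    channel_weights: ChannelWeights | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation over a case library.

    Pass a single :class:`CaseLibrary` (data-level profiles, or any one
    per-channel library) or a dict of five aligned per-channel libraries
    (decision-level; ``channel_weights`` defaults to equal).
    """
    if isinstance(lib_or_libs, dict):
        libs = lib_or_libs
        w = channel_weights or ChannelWeights.equal(libs.keys())
        case_ids = _check_aligned(libs)
        if len(case_ids) < 3:
            raise ValueError("need at least 3 labeled cases for leave-one-out")
        first = libs[sorted(libs)[0]]
        labels = {c.case_id: c.solution for c in first.cases}
        by_id = {ch: {c.case_id: c for c in libs[ch].cases} for ch in libs}
        outcomes = []
        for cid in case_ids:
            query_cases = {ch: by_id[ch][cid] for ch in libs}
            ranked = fused_ranking(query_cases, libs, w, exclude_id=cid)
            outcomes.append((cid, labels[cid], _classify_ranking(ranked)))
        return _report_from_outcomes(outcomes)

    lib: CaseLibrary = lib_or_libs
    if len(lib) < 3:
        raise ValueError("need at least 3 labeled cases for leave-one-out")
    outcomes = []
    for c in lib.cases:
        query = Case(case_id=c.case_id, features=c.features, solution=None)
        outcomes.append((c.case_id, c.solution, classify_k2(query, lib)))
    return _report_from_outcomes(outcomes)


def derive_channel_weights(per_channel_accuracy: dict) -> ChannelWeights:
    """Map per-channel accuracies in [0, 1] onto integer weights 1..10 by
    linear rescaling (min accuracy -> 1, max -> 10, rounded); equal
    accuracies map to equal weights."""
    if not per_channel_accuracy:
        raise ValueError("empty accuracy map")
    accs = {k: float(v) for k, v in per_channel_accuracy.items()}
    if any(not 0 <= v <= 1 for v in accs.values()):
        raise ValueError("accuracies must lie in [0, 1]")
    lo, hi = min(accs.values()), max(accs.values())
    if hi == lo:
        return ChannelWeights({k: 10 for k in accs})
    return ChannelWeights(
        {k: int(round(1 + 9 * (v - lo) / (hi - lo))) for k, v in accs.items()}
    )


# --- library construction helpers ---------------------------------------


def build_decision_level_libraries(
    recordings: list[MultichannelRecording],
    case_ids: list[str] | None = None,
    fuzz: float = 0.5,
) -> dict:
    """Five aligned per-channel case libraries from labeled recordings."""
    if case_ids is None:
        case_ids = [f"case{i + 1}" for i in range(len(recordings))]
    libs: dict = {}
    for rec, cid in zip(recordings, case_ids):
        for ch in rec.channels:
            fv = build_channel_case(ch)
            case = Case(case_id=cid, features=fv, solution=rec.label)
            if ch.name not in libs:
                libs[ch.name] = CaseLibrary(schema=fv.names, fuzz=fuzz)
            libs[ch.name].add(case)
    return libs


def build_data_level_library(
    recordings: list[MultichannelRecording],
    cfg: EmbeddingConfig | None = None,
    eps_max: int = 9,
    case_ids: list[str] | None = None,
    fuzz: float = 0.5,
) -> CaseLibrary:
    """One library of entropy profiles (features F1..F<eps_max>)."""
    if case_ids is None:
        case_ids = [f"case{i + 1}" for i in range(len(recordings))]
    lib: CaseLibrary | None = None
    for rec, cid in zip(recordings, case_ids):
        profile = mmse_profile(rec, cfg=cfg, eps_max=eps_max)
        fv = FeatureVector.from_dict(profile.as_feature_dict())
        if lib is None:
            lib = CaseLibrary(schema=fv.names, fuzz=fuzz)
        lib.add(Case(case_id=cid, features=fv, solution=rec.label))
    if lib is None:
        raise ValueError("no recordings supplied")
    return lib
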