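"""Fuzzy-similarity case-based reasoning: cases, libraries, retrieval.

Local similarity between two feature values replaces each crisp value by a
unit-height triangular membership function fuzzified by a fixed fraction of
the value on each side; the similarity is the overlap area of the two
triangles normalized by each triangle's own area, taking the larger of the
two ratios. Case similarity is the weight-normalized sum of local
similarities. Retrieval ranks a library by case similarity; classification
reads the top-ranked labeled case.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureVector

__all__ = [
    "FuzzyTriangle",
    "Case",
    "WeightVector",
    "CaseLibrary",
    "RetrievalResult",
    "Classification",
    "local_fuzzy_similarity",
    "case_similarity",
    "retrieve",
    "classify_k2",
]

CLASSES = ("Stressed", "Relaxed")

#: Values closer to zero than this get their triangle width from the
#: library's feature spread instead of the value itself.
ZERO_GUARD = 1e-12


@dataclass(frozen=True)
class FuzzyTriangle:
    """Unit-height triangle centered at ``center`` with support
    [center - half_width, center + half_width]; its area is ``half_width``."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be > 0")

    @property
    def area(self) -> float:
        return self.half_width

    def membership(self, x) -> np.ndarray:
        return np.clip(1.0 - np.abs(np.asarray(x, dtype=float) - self.center) / self.half_width, 0.0, None)


def _overlap_area(t1: FuzzyTriangle, t2: FuzzyTriangle) -> float:
    """Exact area under min(mu1, mu2).

    Both membership functions are piecewise linear, so the minimum is linear
    between consecutive breakpoints once segment crossings are included;
    the trapezoid rule is then exact.
    """
    lo = max(t1.center - t1.half_width, t2.center - t2.half_width)
    hi = min(t1.center + t1.half_width, t2.center + t2.half_width)
    if hi <= lo:
        return 0.0
    knots = {lo, hi}
    for t in (t1, t2):
        for x in (t.center - t.half_width, t.center, t.center + t.half_width):
            if lo < x < hi:
                knots.add(x)
    pts = sorted(knots)
    # insert crossings of the two linear pieces inside each interval
    refined = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        f1a, f1b = t1.membership([a, b])
        f2a, f2b = t2.membership([a, b])
        d_a, d_b = f1a - f2a, f1b - f2b
        if d_a * d_b < 0:
            refined.append(a + (b - a) * d_a / (d_a - d_b))
        refined.append(b)
    xs = np.array(refined)
    ys = np.minimum(t1.membership(xs), t2.membership(xs))
    return float(np.trapezoid(ys, xs))


def local_fuzzy_similarity(
    cf: float,
    sf: float,
    fuzz: float = 0.5,
    fallback_half_width: float | None = None,
) -> float:
    """Triangle-overlap similarity of two feature values, in [0, 1].

    Each value is fuzzified by ``fuzz`` times its magnitude on each side.
    For a (near-)zero value the width degenerates; ``fallback_half_width``
    (typically the library SD of the feature) substitutes, and with no
    fallback the comparison falls back to crisp equality.
    Returns max(om/m1, om/m2) where om is the overlap area and m1, m2 the
    triangle areas; equals 1 iff the values coincide, 0 iff the triangles
    are disjoint.
    """
    if not fuzz > 0:
        raise ValueError("fuzz fraction must be > 0")
    if math.isnan(cf) or math.isnan(sf):
        raise ValueError("cannot compare undefined (NaN) feature values")
    hw_c = fuzz * abs(cf)
    hw_s = fuzz * abs(sf)
    if hw_c <= ZERO_GUARD or hw_s <= ZERO_GUARD:
        if fallback_half_width is not None and fallback_half_width > ZERO_GUARD:
            hw_c = hw_c if hw_c > ZERO_GUARD else fuzz * fallback_half_width
            hw_s = hw_s if hw_s > ZERO_GUARD else fuzz * fallback_half_width
        else:
            return 1.0 if cf == sf else 0.0
    t_c = FuzzyTriangle(cf, hw_c)
    t_s = FuzzyTriangle(sf, hw_s)
    if cf == sf and hw_c == hw_s:
        return 1.0
    om = _overlap_area(t_c, t_s)
    return min(max(om / t_c.area, om / t_s.area), 1.0)


@dataclass(frozen=True)
class Case:
    """Problem part (features) plus solution part (class label, or None for
    an unlabeled query)."""

    case_id: str
    features: FeatureVector
    solution: str | None = None

    def __post_init__(self) -> None:
        if self.solution is not None and self.solution not in CLASSES:
            raise ValueError(
                f"case {self.case_id!r}: solution must be one of {CLASSES} or None"
            )
        if np.any(np.isnan(self.features.values)):
            raise ValueError(f"case {self.case_id!r}: features contain undefined values")


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-feature weights; similarity uses the sum-normalized
    view, so rescaling all weights by a positive constant changes nothing."""

    weights: dict

    def __post_init__(self) -> None:
        w = {k: float(v) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative")
        if not any(v > 0 for v in w.values()):
            raise ValueError("at least one weight must be positive")

    @classmethod
    def equal(cls, names) -> "WeightVector":
        return cls({n: 1.0 for n in names})

    def normalized(self, names) -> np.ndarray:
        try:
            w = np.array([self.weights[n] for n in names], dtype=float)
        except KeyError as exc:
            raise ValueError(f"weight vector missing feature {exc.args[0]!r}") from exc
        total = w.sum()
        if total <= 0:
            raise ValueError("weights over the requested features sum to zero")
        return w / total


@dataclass
class CaseLibrary:
    """Cases sharing one feature schema, with retrieval weights and the
    fuzzification fraction used for local similarity."""

    schema: tuple[str, ...]
    cases: list[Case] = field(default_factory=list)
    weights: WeightVector | None = None
    fuzz: float = 0.5

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        if self.weights is None:
            self.weights = WeightVector.equal(self.schema)
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        for c in self.cases:
            if tuple(c.features.names) != self.schema:
                raise ValueError(
                    f"case {c.case_id!r} schema {c.features.names} != library schema {self.schema}"
                )

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    def add(self, case: Case) -> None:
        """Retain step: append a confirmed case."""
        if case.case_id in self.case_ids:
            raise ValueError(f"duplicate case_id {case.case_id!r}")
        if tuple(case.features.names) != self.schema:
            raise ValueError("case schema does not match library schema")
        self.cases.append(case)

    def feature_sd(self) -> dict:
        """Per-feature sample SD across cases, the zero-value width fallback."""
        if len(self.cases) < 2:
            return {n: None for n in self.schema}
        mat = np.vstack([c.features.values for c in self.cases])
        sds = mat.std(axis=0, ddof=1)
        return {n: (float(s) if s > 0 else None) for n, s in zip(self.schema, sds)}

    # --- persistence -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": list(self.schema),
            "weights": self.weights.weights,
            "fuzz": self.fuzz,
            "cases": [
                {
                    "case_id": c.case_id,
                    "class": c.solution,
                    "features": c.features.as_dict(),
                }
                for c in self.cases
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CaseLibrary":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        schema = tuple(payload["schema"])
        cases = [
            Case(
                case_id=str(entry["case_id"]),
                features=FeatureVector(schema, np.array([entry["features"][n] for n in schema])),
                solution=entry.get("class"),
            )
            for entry in payload["cases"]
        ]
        weights = WeightVector(payload["weights"]) if payload.get("weights") else None
        return cls(schema=schema, cases=cases, weights=weights, fuzz=payload.get("fuzz", 0.5))

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "class", *self.schema])
            for c in self.cases:
                writer.writerow(
                    [c.case_id, c.solution or "", *(format(v, ".17g") for v in c.features.values)]
                )

    @classmethod
    def from_csv(cls, path) -> "CaseLibrary":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header[:2] != ["case_id", "class"]:
                raise ValueError("case-library CSV must start with case_id,class columns")
            schema = tuple(header[2:])
            cases = []
            for row in reader:
                if not row:
                    continue
                cases.append(
                    Case(
                        case_id=row[0],
                        features=FeatureVector(schema, np.array([float(v) for v in row[2:]])),
                        solution=row[1] or None,
                    )
                )
        return cls(schema=schema, cases=cases)


def case_similarity(
    c: Case,
    s: Case,
    w: WeightVector | None = None,
    fuzz: float = 0.5,
    feature_sd: dict | None = None,
) -> float:
    """Weight-normalized sum of local fuzzy similarities, in [0, 1]."""
    if tuple(c.features.names) != tuple(s.features.names):
        raise ValueError("cases have different feature schemas")
    names = c.features.names
    w = w or WeightVector.equal(names)
    wn = w.normalized(names)
    sd = feature_sd or {}
    locals_ = np.array(
        [
            local_fuzzy_similarity(cv, sv, fuzz=fuzz, fallback_half_width=sd.get(name))
            for name, cv, sv in zip(names, c.features.values, s.features.values)
        ]
    )
    return float(np.dot(wn, locals_))


@dataclass(frozen=True)
class RetrievalResult:
    """Similarity ranking over library cases, descending; ties broken by
    ascending case_id for determinism."""

    ranked: tuple
    k: int

    @property
    def top(self):
        return self.ranked[: self.k]


@dataclass(frozen=True)
class Classification:
    """Point prediction (top-1 class) plus the top-k evidence."""

    predicted: str
    evidence: tuple  # (case_id, similarity, class) triples
    split_vote: bool


def retrieve(query: Case, lib: CaseLibrary, k: int = 2) -> RetrievalResult:
    """Rank the library by case similarity to the query.

    A stored case with the query's own case_id is excluded, which gives
    leave-one-out behavior for free.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = [c for c in lib.cases if c.case_id != query.case_id]
    if not candidates:
        raise ValueError("library holds no candidate cases for this query")
    sd = lib.feature_sd()
    scored = [
        (c.case_id, case_similarity(query, c, lib.weights, fuzz=lib.fuzz, feature_sd=sd), c.solution)
        for c in candidates
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return RetrievalResult(ranked=tuple(scored), k=min(k, len(scored)))


def classify_k2(query: Case, lib: CaseLibrary) -> Classification:
    """Retrieve the top two cases; predict the top-1 class and keep both as
    evidence for the lenient "one of the two" correctness rule."""
    labeled = [c for c in lib.cases if c.case_id != query.case_id]
    if any(c.solution is None for c in labeled):
        raise ValueError("library contains unlabeled cases; cannot classify")
    if len(labeled) < 2:
        raise ValueError("need at least 2 labeled candidate cases")
    result = retrieve(query, lib, k=2)
    top = result.top
    classes = {t[2] for t in top}
    return Classification(predicted=top[0][2], evidence=top, split_vote=len(classes) > 1)
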