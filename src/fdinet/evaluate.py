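"""Link-removal evaluation protocols and ranking metrics.

The central device: because every node in the graph is a chemical, any
subnetwork can serve as ground truth.  A seeded fraction of links (default
30%) is removed, the scorers re-predict on the remaining graph, and the
removed links are the positives.  Four harnesses are provided:

1. remove 30% of drug-drug similarity links; every method is scored on
   recovering them;
2. ground truth from an external known drug-drug interaction list: the
   removable links are the graph's DD edges that are also reported
   interactions, and recovery of those is measured;
3. remove 30% of *all* (DD, FF, FD) links and measure recovery;
4. a gold-standard list of literature food-drug pairs, held out of the graph
   entirely, scored by the fraction of pairs recovered among food-level
   predictions.

Metrics: precision@top-k for k = 1%, 2%, 5% of the ranked list (k =
ceil(percent * n), so k >= 1); and a threshold sweep from the minimum to
the maximum predicted score in steps of 0.1, counting at each threshold
TP (held-out links predicted with score > threshold), FP, FN (held-out
links below threshold or never predicted) and TN, from which ROC and
precision-recall areas are integrated by the trapezoid rule.

Each protocol repeats over seeded splits (default 10) and reports mean and
standard deviation.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from fdinet.graph_build import HomogeneousGraph
from fdinet.link_prediction import Prediction, predict

DD_ONLY = "DD_only"
ALL_LINKS = "all_links"
TOP_PERCENTS = (1, 2, 5)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the link-removal protocol."""

    fraction_removed: float = 0.3
    scope: str = DD_ONLY
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_removed < 1.0:
            raise ValueError("fraction_removed must lie strictly in (0, 1)")
        if self.scope not in (DD_ONLY, ALL_LINKS):
            raise ValueError(f"scope must be {DD_ONLY!r} or {ALL_LINKS!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvalReport:
    """Per-repeat metrics and their mean +/- sd for one method."""

    method: str
    evaluation_id: int
    per_repeat: list[dict] = field(default_factory=list)

    def _series(self, key: str) -> list[float]:
        return [r[key] for r in self.per_repeat if r.get(key) is not None]

    def summary(self) -> dict:
        out: dict = {"method": self.method, "evaluation": self.evaluation_id,
                     "repeats": len(self.per_repeat)}
        keys = sorted({k for r in self.per_repeat for k in r})
        for key in keys:
            values = self._series(key)
            if not values:
                continue
            out[f"{key}_mean"] = float(statistics.fmean(values))
            out[f"{key}_sd"] = float(statistics.stdev(values)) if len(values) > 1 else 0.0
        return out


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _eligible_edges(graph: HomogeneousGraph, scope: str) -> list[tuple[str, str]]:
    edges = []
    for u, v, d in graph.non_bridge_edges():
        if scope == DD_ONLY and d.get("subnetwork") != "DD":
            continue
        edges.append((u, v) if u < v else (v, u))
    return sorted(edges)


def split_links(
    graph: HomogeneousGraph,
    spec: SplitSpec,
    repeat_index: int = 0,
) -> tuple[HomogeneousGraph, set[tuple[str, str]]]:
    """Remove a seeded random fraction of eligible links.

    Returns the train graph (original minus the removed links, nodes kept)
    and the removed (test) link set.  Bridges are never eligible; with scope
    ``DD_only`` every FF and FD link stays in train.  The split is a pure
    function of (seed, repeat_index).
    """
    eligible = _eligible_edges(graph, spec.scope)
    if len(eligible) < 2:
        raise EvaluationError(f"need >= 2 eligible links, found {len(eligible)}")
    n_test = int(round(spec.fraction_removed * len(eligible)))
    n_test = max(1, n_test)
    if n_test >= len(eligible):
        raise EvaluationError("fraction_removed would remove every eligible link")
    rng = np.random.default_rng([spec.seed, repeat_index])
    idx = rng.choice(len(eligible), size=n_test, replace=False)
    test = {eligible[i] for i in idx}
    train = graph.copy()
    train.graph.remove_edges_from(test)
    return train, test


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def precision_at_top(
    ranked: Sequence[Prediction],
    test_links: set[tuple[str, str]],
    percent: float,
) -> float:
    """Fraction of held-out links among the top ``percent``% of the ranking.

    The window is k = ceil(percent/100 * n), guaranteeing k >= 1.
    """
    if not ranked:
        raise EvaluationError("ranked prediction list is empty")
    k = math.ceil(percent / 100.0 * len(ranked))
    hits = sum(1 for p in ranked[:k] if p.pair in test_links)
    return hits / k


def confusion_sweep(
    ranked: Sequence[Prediction],
    test_links: set[tuple[str, str]],
    step: float = 0.1,
) -> tuple[list[ConfusionCounts], float | None, float | None]:
    """Threshold sweep from the minimum to the maximum predicted score.

    At each threshold t (min score, then +``step`` up to and including the
    maximum): TP = held-out links predicted with score > t; FP = other
    predictions with score > t; FN = held-out links with score <= t plus
    held-out links never predicted; TN = other predictions with score <= t.
    ROC area is trapezoidal over (FPR, TPR); precision-recall area is
    trapezoidal over (recall, precision) with undefined-precision points
    (TP + FP = 0) dropped.  A degenerate sweep (all scores equal) returns
    counts with both areas None.
    """
    if not ranked:
        raise EvaluationError("ranked prediction list is empty")
    scores = [p.score for p in ranked]
    if not all(math.isfinite(s) for s in scores):
        raise EvaluationError("non-finite prediction score")
    lo, hi = min(scores), max(scores)
    thresholds = [lo]
    t = lo
    while t + step < hi - 1e-12:
        t += step
        thresholds.append(t)
    if hi > lo:
        thresholds.append(hi)

    predicted_pairs = {p.pair for p in ranked}
    missed = len(test_links - predicted_pairs)  # known links never proposed
    counts = []
    roc_points = []
    pr_points = []
    for t in thresholds:
        tp = sum(1 for p in ranked if p.pair in test_links and p.score > t)
        fp = sum(1 for p in ranked if p.pair not in test_links and p.score > t)
        fn = sum(1 for p in ranked if p.pair in test_links and p.score <= t) + missed
        tn = sum(1 for p in ranked if p.pair not in test_links and p.score <= t)
        counts.append(ConfusionCounts(threshold=t, tp=tp, fp=fp, tn=tn, fn=fn))
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        roc_points.append((fpr, tpr))
        if tp + fp:
            pr_points.append((tpr, tp / (tp + fp)))  # (recall, precision)

    if len(thresholds) < 2:
        return counts, None, None
    # the sweep's strict ">" never classifies everything positive, so the
    # (1, 1) ROC corner is anchored explicitly (as is (0, 0)), the usual
    # ROC endpoint convention
    auc = _trapezoid(roc_points + [(0.0, 0.0), (1.0, 1.0)])
    prc = _trapezoid(pr_points) if len(pr_points) >= 2 else None
    return counts, auc, prc


def _trapezoid(points: list[tuple[float, float]]) -> float:
    # points sorted by (x, y) trace the monotone sweep curve; vertical
    # runs (duplicate x) contribute zero width
    pts = sorted(points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


# ---------------------------------------------------------------------------
# Food-level aggregation
# ---------------------------------------------------------------------------

def aggregate_food_level(
    predictions: Iterable[Prediction],
    node_foods: Mapping[str, str],
) -> list[dict]:
    """Collapse compound-level food-drug predictions to food level.

    ``node_foods`` maps food-compound node ids to their food id.  For each
    (food, drug) pair the maximum compound-level score is reported together
    with the contributing compound nodes, best first.
    """
    groups: dict[tuple[str, str], list[Prediction]] = {}
    for p in predictions:
        a_food, b_food = node_foods.get(p.node_a), node_foods.get(p.node_b)
        if (a_food is None) == (b_food is None):
            continue  # not a food-compound/drug pair
        food_id = a_food or b_food
        drug = p.node_b if a_food else p.node_a
        groups.setdefault((food_id, drug), []).append(p)
    table = []
    for (food_id, drug), preds in sorted(groups.items()):
        preds.sort(key=lambda p: (-p.score, p.node_a, p.node_b))
        table.append(
            {
                "food_id": food_id,
                "drug": drug,
                "score": preds[0].score,
                "compounds": [
                    p.node_a if node_foods.get(p.node_a) else p.node_b for p in preds
                ],
            }
        )
    table.sort(key=lambda r: (-r["score"], r["food_id"], r["drug"]))
    return table


# ---------------------------------------------------------------------------
# Evaluation harnesses
# ---------------------------------------------------------------------------

def _repeat_metrics(
    ranked: list[Prediction], test: set[tuple[str, str]]
) -> dict:
    row: dict = {}
    for pct in TOP_PERCENTS:
        row[f"precision_top{pct}"] = precision_at_top(ranked, test, pct)
    _, auc, prc = confusion_sweep(ranked, test)
    row["auc"] = auc
    row["prc"] = prc
    predicted = {p.pair for p in ranked}
    row["matched_links"] = len(test & predicted)
    row["test_links"] = len(test)
    return row


def run_evaluation(
    graph: HomogeneousGraph,
    evaluation_id: int,
    methods: Sequence[str],
    split: SplitSpec | None = None,
    known_ddi: set[tuple[str, str]] | None = None,
    gold_standard: Sequence[tuple[str, str]] | None = None,
    node_foods: Mapping[str, str] | None = None,
) -> list[EvalReport]:
    """Run one of the four link-removal evaluation harnesses.

    1: remove DD similarity links, recover them (all methods).
    2: like 1, but the removable/recoverable links are the graph's DD edges
       confirmed by the external ``known_ddi`` list.
    3: remove links of any type (scope ``all_links``), recover them.
    4: score recovery of the held-out ``gold_standard`` (food_id, drug)
       pairs among food-level aggregated predictions; requires
       ``node_foods`` (food-compound node id -> food id).
    """
    if evaluation_id not in (1, 2, 3, 4):
        raise EvaluationError(f"unknown evaluation id {evaluation_id}")
    split = split or SplitSpec()
    if evaluation_id == 3 and split.scope != ALL_LINKS:
        split = SplitSpec(split.fraction_removed, ALL_LINKS, split.repeats, split.seed)
    if evaluation_id == 2 and known_ddi is None:
        raise EvaluationError("evaluation 2 requires a known-DDI list")
    if evaluation_id == 4 and (gold_standard is None or node_foods is None):
        raise EvaluationError("evaluation 4 requires a gold-standard list and node_foods")

    if evaluation_id == 4:
        return [_run_gold_standard(graph, m, gold_standard, node_foods) for m in methods]

    reports = []
    for method in methods:
        report = EvalReport(method=method, evaluation_id=evaluation_id)
        for r in range(split.repeats):
            train, test = split_links(graph, split, repeat_index=r)
            if evaluation_id == 2:
                test = test & known_ddi
                if not test:
                    raise EvaluationError(
                        "no removed link is a known interaction; enlarge the list"
                    )
            ranked = predict(train, method)
            if not ranked:
                report.per_repeat.append(
                    {f"precision_top{p}": 0.0 for p in TOP_PERCENTS}
                    | {"matched_links": 0, "test_links": len(test)}
                )
                continue
            report.per_repeat.append(_repeat_metrics(ranked, test))
        reports.append(report)
    return reports


def _run_gold_standard(
    graph: HomogeneousGraph,
    method: str,
    gold_standard: Sequence[tuple[str, str]],
    node_foods: Mapping[str, str],
) -> EvalReport:
    """Recovery rate of held-out literature (food, drug) pairs.

    Any graph edge joining the gold pair's drug to a compound of the gold
    pair's food is removed before inference (the pairs are hidden from all
    training); recovery means the (food, drug) pair appears in the
    food-level aggregation of the method's predictions.
    """
    gold = {(f, d) for f, d in gold_standard}
    train = graph.copy()
    to_drop = [
        (u, v)
        for u, v, _ in train.non_bridge_edges()
        for (fu, fv) in [(node_foods.get(u), node_foods.get(v))]
        if (fu and (fu, v) in gold) or (fv and (fv, u) in gold)
    ]
    train.graph.remove_edges_from(to_drop)
    ranked = predict(train, method, fdi_only=True)
    table = aggregate_food_level(ranked, node_foods)
    predicted_pairs = {(row["food_id"], row["drug"]) for row in table}
    recovered = gold & predicted_pairs
    report = EvalReport(method=method, evaluation_id=4)
    report.per_repeat.append(
        {
            "recovery_rate": len(recovered) / len(gold) if gold else 0.0,
            "matched_links": len(recovered),
            "test_links": len(gold),
        }
    )
    return report


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

def read_pairs_tsv(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column TSV (with header) of undirected pairs, canonicalized."""
    pairs = set()
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")[:2]
            pairs.add((a, b) if a < b else (b, a))
    return pairs


def write_report_tsv(reports: Sequence[EvalReport], path: str | Path) -> None:
    keys: list[str] = []
    for rep in reports:
        for row in rep.per_repeat:
            for k in row:
                if k not in keys:
                    keys.append(k)
    with open(path, "w") as fh:
        fh.write("method\tevaluation\trepeat\t" + "\t".join(keys) + "\n")
        for rep in reports:
            for i, row in enumerate(rep.per_repeat):
                values = "\t".join(
                    "" if row.get(k) is None else repr(row.get(k)) for k in keys
                )
                fh.write(f"{rep.method}\t{rep.evaluation_id}\t{i}\t{values}\n")
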