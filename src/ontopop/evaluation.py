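"""Success metrics, structural metrics, and repeated-skeleton experiments.

Precision counts a mapped candidate as a true positive when the predicted
class is one of its ground-truth parents; the hop distance is the shortest
undirected path between the predicted class and the nearest true parent, so a
correct assignment scores 0 and a sibling misassignment scores 2.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .graph import Ontology, UnknownIdError, make_skeleton
from .population import MapperConfig, MappingResult, map_all

__all__ = [
    "EvalReport",
    "CohesivenessAnnotation",
    "ExperimentSummary",
    "precision_report",
    "path_distance",
    "granularity",
    "cohesiveness",
    "read_cohesiveness_annotations",
    "run_experiment",
    "correlate_structure",
    "percent_reduction",
    "compare_methods",
]

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    n_candidates: int
    tp: int
    fp: int
    precision: float
    distances: List[int]
    mean_distance: float
    distance_histogram: Dict[int, int]
    per_class_precision: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "tp": self.tp,
            "fp": self.fp,
            "precision": self.precision,
            "mean_distance": self.mean_distance,
            "distance_histogram": {str(k): v for k, v in sorted(self.distance_histogram.items())},
            "per_class_precision": dict(sorted(self.per_class_precision.items())),
        }


@dataclass(frozen=True)
class CohesivenessAnnotation:
    """Manual correct/incorrect judgments for the direct subclasses of one superclass."""

    superclass_id: str
    judgments: Mapping[str, bool]


@dataclass
class ExperimentSummary:
    n_repeats: int
    per_repeat_precision: List[float]
    per_repeat_mean_distance: List[float]
    mean_precision: float
    mean_distance: float
    rng_base_seed: int
    # pooled over all candidates of all repeats (second aggregation path)
    pooled_precision: float = float("nan")
    pooled_mean_distance: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "per_repeat_precision": self.per_repeat_precision,
            "per_repeat_mean_distance": self.per_repeat_mean_distance,
            "mean_precision": self.mean_precision,
            "mean_distance": self.mean_distance,
            "pooled_precision": self.pooled_precision,
            "pooled_mean_distance": self.pooled_mean_distance,
            "rng_base_seed": self.rng_base_seed,
        }


# ---------------------------------------------------------------------------
# Success metrics
# ---------------------------------------------------------------------------

def path_distance(ontology: Ontology, predicted: str, truth_parents) -> int:
    """Shortest undirected hop count from the predicted class to any true parent."""
    if predicted not in ontology.classes:
        raise UnknownIdError(predicted)
    truth = set(truth_parents)
    for t in truth:
        if t not in ontology.classes:
            raise UnknownIdError(t)
    if predicted in truth:
        return 0
    g = ontology.class_graph().to_undirected(as_view=True)
    lengths = nx.single_source_shortest_path_length(g, predicted)
    return min(lengths[t] for t in truth)


def precision_report(results: Sequence[MappingResult], ontology: Ontology) -> EvalReport:
    """Score a full mapping run: precision, hop distances, per-class precision.

    A result is a TP iff its predicted class is a member of the instance's
    ground-truth parent set; per-class precision is computed over ground-truth
    classes with at least one candidate.
    """
    g = ontology.class_graph().to_undirected(as_view=True)
    # one BFS per distinct predicted class, reused across candidates
    dist_cache: Dict[str, Dict[str, int]] = {}
    tp = 0
    distances: List[int] = []
    per_class: Dict[str, List[int]] = {}
    for r in results:
        if r.instance_id not in ontology.instances:
            raise UnknownIdError(r.instance_id)
        truth = ontology.instances[r.instance_id].parent_ids
        hit = r.predicted_class_id in truth
        tp += hit
        if hit:
            d = 0
        else:
            if r.predicted_class_id not in dist_cache:
                dist_cache[r.predicted_class_id] = nx.single_source_shortest_path_length(
                    g, r.predicted_class_id
                )
            lengths = dist_cache[r.predicted_class_id]
            d = min(lengths[t] for t in truth)
        distances.append(d)
        for t in truth:
            per_class.setdefault(t, []).append(int(hit))
    n = len(results)
    fp = n - tp
    return EvalReport(
        n_candidates=n,
        tp=tp,
        fp=fp,
        precision=tp / n if n else float("nan"),
        distances=distances,
        mean_distance=float(np.mean(distances)) if distances else float("nan"),
        distance_histogram=dict(Counter(distances)),
        per_class_precision={c: float(np.mean(v)) for c, v in per_class.items()},
    )


# ---------------------------------------------------------------------------
# Structural metrics
# ---------------------------------------------------------------------------

def granularity(ontology: Ontology, superclass_id: str) -> float:
    """Distinct instances in the superclass's descendant subtree per class in it."""
    sub = ontology.descendants_of(superclass_id)  # includes the superclass itself
    inst = {i.id for i in ontology.instances.values() if i.parent_ids & sub}
    return len(inst) / len(sub)


def cohesiveness(annotation: CohesivenessAnnotation) -> float:
    """Fraction of judged direct subclasses marked correct."""
    if not annotation.judgments:
        raise ValueError("cohesiveness requires at least one judged subclass")
    vals = list(annotation.judgments.values())
    return sum(vals) / len(vals)


def read_cohesiveness_annotations(path) -> List[CohesivenessAnnotation]:
    """Read `superclass_id<TAB>subclass_id<TAB>correct{0,1}` TSV rows."""
    judged: Dict[str, Dict[str, bool]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("0", "1"):
                raise ValueError(f"{path}:{ln}: expected `super<TAB>sub<TAB>0|1`")
            judged.setdefault(parts[0], {})[parts[1]] = parts[2] == "1"
    return [CohesivenessAnnotation(s, j) for s, j in sorted(judged.items())]


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_experiment(
    ontology: Ontology,
    vectors=None,
    tokenized_labels=None,
    config: MapperConfig = MapperConfig(),
    n_seed: int = 2,
    n_repeats: int = 1,
    base_seed: int = 0,
) -> ExperimentSummary:
    """Repeat seed -> map -> evaluate; repeat r uses rng_seed = base_seed + r."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    precisions: List[float] = []
    mean_dists: List[float] = []
    total_tp = 0
    total_n = 0
    all_dists: List[int] = []
    for r in range(n_repeats):
        seed = base_seed + r
        skeleton = make_skeleton(ontology, n_seed=n_seed, rng_seed=seed)
        cfg = MapperConfig(
            alpha=config.alpha,
            similarity=config.similarity,
            method=config.method,
            rng_seed=seed,
            pairwise_only=config.pairwise_only,
        )
        results = map_all(skeleton, vectors=vectors, tokenized_labels=tokenized_labels, config=cfg)
        report = precision_report(results, ontology)
        precisions.append(report.precision)
        mean_dists.append(report.mean_distance)
        total_tp += report.tp
        total_n += report.n_candidates
        all_dists.extend(report.distances)
    return ExperimentSummary(
        n_repeats=n_repeats,
        per_repeat_precision=precisions,
        per_repeat_mean_distance=mean_dists,
        mean_precision=float(np.mean(precisions)),
        mean_distance=float(np.mean(mean_dists)),
        pooled_precision=total_tp / total_n if total_n else float("nan"),
        pooled_mean_distance=float(np.mean(all_dists)) if all_dists else float("nan"),
        rng_base_seed=base_seed,
    )


def compare_methods(
    ontology: Ontology,
    vectors=None,
    tokenized_labels=None,
    methods: Sequence[str] = ("embedding", "jaccard", "hamming", "random"),
    alpha: float = 0.8,
    similarity: str = "cosine",
    n_seed: int = 2,
    n_repeats: int = 10,
    base_seed: int = 0,
) -> "pd.DataFrame":
    """Method-comparison table (method, average precision, average distance).

    Adds a two-sided Wilcoxon signed-rank p-value of each method's per-repeat
    precision against the first method (paired by repeat).
    """
    import pandas as pd

    summaries: Dict[str, ExperimentSummary] = {}
    for method in methods:
        cfg = MapperConfig(alpha=alpha, similarity=similarity, method=method)
        summaries[method] = run_experiment(
            ontology,
            vectors=vectors,
            tokenized_labels=tokenized_labels,
            config=cfg,
            n_seed=n_seed,
            n_repeats=n_repeats,
            base_seed=base_seed,
        )
    ref = methods[0]
    rows = []
    for method, summ in summaries.items():
        if method == ref or n_repeats < 2:
            pval = float("nan")
        else:
            x = np.array(summaries[ref].per_repeat_precision)
            y = np.array(summ.per_repeat_precision)
            if np.allclose(x, y):
                pval = 1.0
            else:
                pval = float(stats.wilcoxon(x, y).pvalue)  # Wilcoxon signed-rank, two-sided
        rows.append(
            {
                "method": method,
                "average_precision": summ.mean_precision,
                "average_distance": summ.mean_distance,
                "pooled_precision": summ.pooled_precision,
                "wilcoxon_p_vs_" + ref: pval,
            }
        )
    return pd.DataFrame(rows)


def correlate_structure(
    per_superclass_precision: Mapping[str, float],
    per_superclass_metric: Mapping[str, float],
) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) over superclasses present in both maps."""
    keys = sorted(set(per_superclass_precision) & set(per_superclass_metric))
    if len(keys) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(keys)}")
    x = np.array([per_superclass_precision[k] for k in keys], dtype=float)
    y = np.array([per_superclass_metric[k] for k in keys], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the paired samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def percent_reduction(baseline: float, value: float, ndigits: Optional[int] = 1) -> float:
    """Relative reduction of ``value`` vs ``baseline`` in percent."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    out = (baseline - value) / baseline * 100.0
    return round(out, ndigits) if ndigits is not None else out
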