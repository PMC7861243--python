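"""Candidate-to-class mapping: embedding scorer plus non-embedding baselines.

Each candidate instance is scored against every target class with

    score(c; i) = alpha * score_siblings(c; i) + (1 - alpha) * score_parent(c; i)

where ``score_siblings`` compares the instance's label vector with the
centroid of the class's seed-instance vectors and ``score_parent`` compares it
with the class's own label vector.  The predicted class is the argmax; ties
break to the lexicographically smallest class id.  Jaccard and Hamming
baselines reuse the same convex combination with a set/string similarity in
place of the vector similarity; the random baseline draws a target class
uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .embeddings import LabelVector
from .graph import SeededSkeleton

__all__ = [
    "MapperConfig",
    "MappingResult",
    "cosine_sim",
    "euclidean_sim",
    "score_siblings",
    "score_parent",
    "jaccard_sim",
    "hamming_sim",
    "map_instance",
    "map_all",
    "write_mapping",
]

log = logging.getLogger(__name__)

METHODS = ("embedding", "jaccard", "hamming", "random")
SIMILARITIES = ("cosine", "euclidean")


@dataclass(frozen=True)
class MapperConfig:
    alpha: float = 0.8
    similarity: str = "cosine"
    method: str = "embedding"
    rng_seed: int = 0
    # score a class by the best single pairwise similarity (seeds + label)
    # instead of the alpha combination; only meaningful for jaccard/hamming
    pairwise_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.similarity not in SIMILARITIES:
            raise ValueError(f"similarity must be one of {SIMILARITIES}, got {self.similarity!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass(frozen=True)
class MappingResult:
    instance_id: str
    predicted_class_id: str
    score: float
    score_siblings: float
    score_parent: float
    fallback: bool = False
    tie: bool = False
    runner_up_score: float = float("-inf")


# ---------------------------------------------------------------------------
# Similarities
# ---------------------------------------------------------------------------

def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def euclidean_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Negative Euclidean distance; comparable only within one run (argmax-safe)."""
    return -float(np.linalg.norm(np.asarray(u, dtype=float) - np.asarray(v, dtype=float)))


def _sim(u: np.ndarray, v: np.ndarray, config: MapperConfig) -> float:
    return cosine_sim(u, v) if config.similarity == "cosine" else euclidean_sim(u, v)


def score_siblings(instance_vec: LabelVector, seed_vecs: Sequence[LabelVector], config: MapperConfig) -> float:
    """Similarity of the instance vector to the centroid of the seed vectors."""
    if not seed_vecs:
        raise ValueError("seed vector list is empty")
    if instance_vec.vector is None or any(s.vector is None for s in seed_vecs):
        raise ValueError("undefined label vector in score_siblings")
    centroid = np.mean([s.vector for s in seed_vecs], axis=0)
    return _sim(instance_vec.vector, centroid, config)


def score_parent(instance_vec: LabelVector, class_vec: LabelVector, config: MapperConfig) -> float:
    """Similarity of the instance vector to the class's own label vector."""
    if instance_vec.vector is None or class_vec.vector is None:
        raise ValueError("undefined label vector in score_parent")
    return _sim(instance_vec.vector, class_vec.vector, config)


def jaccard_sim(tokens_a, tokens_b) -> float:
    """|A n B| / |A u B| on token sets; 0 when both are empty."""
    a, b = set(tokens_a), set(tokens_b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def hamming_sim(a: str, b: str) -> float:
    """Positional string similarity with a length-difference penalty.

    1 - (mismatches over the shorter length + |len(a)-len(b)|) / max(len),
    and 1.0 when both strings are empty.
    """
    if not a and not b:
        return 1.0
    short = min(len(a), len(b))
    mismatches = sum(1 for x, y in zip(a, b) if x != y)
    return 1.0 - (mismatches + abs(len(a) - len(b))) / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

class _ClassScorer:
    """Precomputed per-class data for scoring one skeleton under one config."""

    def __init__(
        self,
        skeleton: SeededSkeleton,
        config: MapperConfig,
        vectors: Optional[Mapping[str, LabelVector]] = None,
        tokenized_labels: Optional[Mapping[str, object]] = None,
    ) -> None:
        self.config = config
        self.skeleton = skeleton
        self.class_ids = sorted(skeleton.target_class_ids)
        ont = skeleton.ontology
        if config.method == "embedding":
            if vectors is None:
                raise ValueError("embedding method requires label vectors")
            self.centroids: Dict[str, Optional[np.ndarray]] = {}
            self.class_vecs: Dict[str, Optional[np.ndarray]] = {}
            for c in self.class_ids:
                seeds = [vectors[s] for s in skeleton.seeds.get(c, ())]
                defined = [s.vector for s in seeds if s.vector is not None]
                self.centroids[c] = np.mean(defined, axis=0) if defined else None
                cv = vectors.get(c)
                self.class_vecs[c] = cv.vector if cv is not None and cv.vector is not None else None
            self.vectors = vectors
        elif config.method in ("jaccard", "hamming"):
            if tokenized_labels is None:
                raise ValueError(f"{config.method} method requires tokenized labels")
            self.tokenized = tokenized_labels
            self.labels = ont.labels()

    def _string_sims(self, instance_id: str, class_id: str) -> Tuple[float, float, List[float]]:
        """(sibling score, parent score, raw per-comparison sims) for baselines."""
        cfg = self.config
        if cfg.method == "jaccard":
            inst = set(self.tokenized[instance_id].tokens)
            seed_sims = [
                jaccard_sim(inst, self.tokenized[s].tokens)
                for s in sorted(self.skeleton.seeds.get(class_id, ()))
            ]
            par = jaccard_sim(inst, self.tokenized[class_id].tokens)
        else:  # hamming on raw lower-cased labels
            inst = self.labels[instance_id].lower()
            seed_sims = [
                hamming_sim(inst, self.labels[s].lower())
                for s in sorted(self.skeleton.seeds.get(class_id, ()))
            ]
            par = hamming_sim(inst, self.labels[class_id].lower())
        sib = float(np.mean(seed_sims)) if seed_sims else float("-inf")
        return sib, par, seed_sims + [par]

    def score_class(self, instance_id: str, class_id: str) -> Tuple[float, float, float]:
        """Return (combined score, sibling term, parent term) or -inf if unscorable."""
        cfg = self.config
        if cfg.method == "embedding":
            iv = self.vectors.get(instance_id)
            if iv is None or iv.vector is None:
                return float("-inf"), float("-inf"), float("-inf")
            sib = par = float("-inf")
            centroid = self.centroids[class_id]
            cvec = self.class_vecs[class_id]
            if centroid is not None and np.linalg.norm(centroid) > 0:
                sib = _sim(iv.vector, centroid, cfg)
            if cvec is not None and np.linalg.norm(cvec) > 0:
                par = _sim(iv.vector, cvec, cfg)
            if cfg.alpha == 1.0:
                return sib, sib, par
            if cfg.alpha == 0.0:
                return par, sib, par
            if sib == float("-inf") or par == float("-inf"):
                return float("-inf"), sib, par
            return cfg.alpha * sib + (1 - cfg.alpha) * par, sib, par
        sib, par, raw = self._string_sims(instance_id, class_id)
        if cfg.pairwise_only:
            return max(raw), sib, par
        if sib == float("-inf"):
            return par if cfg.alpha < 1.0 else float("-inf"), sib, par
        return cfg.alpha * sib + (1 - cfg.alpha) * par, sib, par


def _argmax_class(scorer: _ClassScorer, instance_id: str) -> Optional[MappingResult]:
    """Best-scoring class for one candidate, or None if nothing is scorable."""
    best: Optional[MappingResult] = None
    runner = float("-inf")
    for c in scorer.class_ids:  # sorted => deterministic lexicographic ties
        s, sib, par = scorer.score_class(instance_id, c)
        if s == float("-inf"):
            continue
        if best is None or s > best.score:
            runner = best.score if best is not None else float("-inf")
            best = MappingResult(instance_id, c, s, sib, par)
        elif s == best.score:
            best = replace(best, tie=True, runner_up_score=s)
        elif s > runner:
            runner = s
    if best is not None and not best.tie:
        best = replace(best, runner_up_score=runner)
    return best


def map_instance(
    instance_id: str,
    skeleton: SeededSkeleton,
    vectors: Mapping[str, LabelVector],
    config: MapperConfig,
    _scorer: Optional[_ClassScorer] = None,
    _rng: Optional[np.random.Generator] = None,
) -> MappingResult:
    """Assign one candidate to its argmax target class.

    A candidate whose label vector is undefined (or that no class can score)
    falls back to a uniformly random target class with ``fallback=True``.
    """
    if instance_id not in skeleton.candidates:
        raise ValueError(f"{instance_id!r} is not a candidate of this skeleton")
    scorer = _scorer or _ClassScorer(skeleton, config, vectors=vectors)
    result = _argmax_class(scorer, instance_id)
    if result is None:
        rng = _rng if _rng is not None else np.random.default_rng(config.rng_seed)
        c = scorer.class_ids[rng.integers(len(scorer.class_ids))]
        return MappingResult(instance_id, c, float("nan"), float("nan"), float("nan"), fallback=True)
    return result


def map_all(
    skeleton: SeededSkeleton,
    vectors: Optional[Mapping[str, LabelVector]] = None,
    tokenized_labels: Optional[Mapping[str, object]] = None,
    config: MapperConfig = MapperConfig(),
) -> List[MappingResult]:
    """Map every candidate of the skeleton; one result per candidate."""
    candidates = sorted(skeleton.candidates)
    rng = np.random.default_rng(config.rng_seed)
    if config.method == "random":
        class_ids = sorted(skeleton.target_class_ids)
        draws = rng.integers(len(class_ids), size=len(candidates))
        return [
            MappingResult(i, class_ids[k], float("nan"), float("nan"), float("nan"), fallback=True)
            for i, k in zip(candidates, draws)
        ]
    scorer = _ClassScorer(skeleton, config, vectors=vectors, tokenized_labels=tokenized_labels)
    out = []
    for i in candidates:
        out.append(map_instance(i, skeleton, vectors or {}, config, _scorer=scorer, _rng=rng))
    n_fallback = sum(r.fallback for r in out)
    if n_fallback:
        log.info("%d/%d candidates assigned by random fallback", n_fallback, len(out))
    return out


def write_mapping(results: Sequence[MappingResult], path) -> None:
    """Mapping TSV: instance, predicted class, score terms, fallback flag."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\tpredicted_class_id\tscore\tscore_siblings\tscore_parent\tfallback\n")
        for r in results:
            fh.write(
                f"{r.instance_id}\t{r.predicted_class_id}\t{r.score:.8g}\t"
                f"{r.score_siblings:.8g}\t{r.score_parent:.8g}\t{int(r.fallback)}\n"
            )
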