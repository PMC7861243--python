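"""Synthetic ontologies and clustered embeddings for fully offline testing.

Generated labels use an alphabet that passes the preprocessing pipeline
untouched (no vowels that could trigger lemmatization suffix rules, no
stop-words, length >= 3), so fixtures exercise the same label -> tokens ->
vectors path as real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .embeddings import EmbeddingTable, LabelVector, label_vector
from .graph import InstanceRecord, OntoClass, Ontology
from .text import PipelineConfig, tokenize_labels

__all__ = ["SyntheticSpec", "generate_ontology", "generate_embeddings", "label_vectors"]

# no 'e'/'s' (lemmatizer suffixes), no vowels (stop-words), 16 symbols
_ALPHABET = "bcdfghjkmpqrtvwz"


def _enc(n: int, width: int = 3) -> str:
    digits = []
    while n:
        digits.append(_ALPHABET[n % len(_ALPHABET)])
        n //= len(_ALPHABET)
    while len(digits) < width:
        digits.append(_ALPHABET[0])
    return "".join(reversed(digits))


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 20
    max_depth: int = 4
    branching: float = 3.0
    multi_parent_prob: float = 0.0
    instances_mean: float = 3.0
    instances_dispersion: float = 1.0
    dim: int = 8
    centroid_separation: float = 0.5
    noise_sigma: float = 0.0
    vocab_tokens_per_label: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError("multi_parent_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.centroid_separation < 0:
            raise ValueError("centroid_separation must be >= 0")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.vocab_tokens_per_label < 1:
            raise ValueError("vocab_tokens_per_label must be >= 1")


def _label_tokens(prefix: str, idx: int, count: int) -> List[str]:
    return [f"{prefix}{_enc(idx)}{_enc(t)}" for t in range(count)]


def generate_ontology(spec: SyntheticSpec) -> Ontology:
    """Grow a single-root DAG, then attach instances to random classes.

    Each class is created with a Poisson(branching) child capacity; new
    classes attach to a uniformly chosen class with free capacity and depth
    below ``max_depth`` (capacity is relaxed if the frontier saturates, so any
    n_classes is feasible for branching > 0).  Second parents are added with
    probability ``multi_parent_prob`` among non-descendants only.
    """
    if spec.n_classes > 1 and spec.branching <= 0:
        raise ValueError("branching must be > 0 when n_classes > 1")
    rng = np.random.default_rng(spec.rng_seed)

    class_ids = [f"C{_enc(k)}" for k in range(spec.n_classes)]
    parents: Dict[str, set] = {class_ids[0]: set()}
    depth = {class_ids[0]: 0}
    capacity = {class_ids[0]: max(1, int(rng.poisson(spec.branching)))}
    for k in range(1, spec.n_classes):
        eligible = [c for c in class_ids[:k] if capacity[c] > 0 and depth[c] < spec.max_depth]
        if not eligible:
            relaxable = [c for c in class_ids[:k] if depth[c] < spec.max_depth]
            if not relaxable:
                raise ValueError("infeasible spec: every class is at max_depth")
            bump = relaxable[int(rng.integers(len(relaxable)))]
            capacity[bump] += 1
            eligible = [bump]
        parent = eligible[int(rng.integers(len(eligible)))]
        cid = class_ids[k]
        parents[cid] = {parent}
        depth[cid] = depth[parent] + 1
        capacity[parent] -= 1
        capacity[cid] = int(rng.poisson(spec.branching))

    # optional second parents, never creating a cycle
    if spec.multi_parent_prob > 0:
        descendants: Dict[str, set] = {c: set() for c in class_ids}
        order = sorted(class_ids, key=lambda c: -depth[c])
        for c in order:
            for p in parents[c]:
                descendants[p] |= descendants[c] | {c}
        for cid in class_ids[1:]:
            if rng.random() >= spec.multi_parent_prob:
                continue
            forbidden = descendants[cid] | parents[cid] | {cid}
            pool = [c for c in class_ids if c not in forbidden]
            if not pool:
                continue
            extra = pool[int(rng.integers(len(pool)))]
            parents[cid].add(extra)
            # keep descendant closure current for later iterations
            stack = [extra]
            seen = set()
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                descendants[node] |= descendants[cid] | {cid}
                stack.extend(parents[node])

    classes = [
        OntoClass(cid, " ".join(_label_tokens("cls", k, spec.vocab_tokens_per_label)), frozenset(parents[cid]))
        for k, cid in enumerate(class_ids)
    ]

    instances: List[InstanceRecord] = []
    idx = 0
    for cid in class_ids:
        if spec.instances_dispersion > 1.0:
            # gamma-Poisson mixture (negative binomial with the given overdispersion)
            shape = spec.instances_mean / (spec.instances_dispersion - 1.0)
            lam = rng.gamma(shape, spec.instances_dispersion - 1.0)
        else:
            lam = spec.instances_mean
        for _ in range(int(rng.poisson(lam))):
            iid = f"I{_enc(idx, width=4)}"
            pids = {cid}
            if spec.multi_parent_prob > 0 and rng.random() < spec.multi_parent_prob:
                others = [c for c in class_ids if c != cid]
                if others:
                    pids.add(others[int(rng.integers(len(others)))])
            instances.append(
                InstanceRecord(iid, " ".join(_label_tokens("ins", idx, spec.vocab_tokens_per_label)), frozenset(pids))
            )
            idx += 1
    return Ontology(classes, instances)


def generate_embeddings(ontology: Ontology, spec: SyntheticSpec) -> Tuple[EmbeddingTable, Dict[str, Tuple[str, ...]]]:
    """Per-class centroids plus isotropic noise around them.

    Every class gets a unit-vector centroid with pairwise Euclidean
    separation >= ``centroid_separation`` (all centroids coincide when the
    separation is 0).  Class-label tokens sit at their class centroid and
    instance-label tokens at the centroid of the instance's primary (smallest
    id) parent, both perturbed by N(0, noise_sigma^2 I).
    """
    if spec.dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(spec.rng_seed + 10_007)
    class_ids = sorted(ontology.classes)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    centroids: Dict[str, np.ndarray] = {}
    if spec.centroid_separation == 0.0:
        shared = unit(rng.normal(size=spec.dim))
        centroids = {c: shared for c in class_ids}
    else:
        placed: List[np.ndarray] = []
        for c in class_ids:
            for attempt in range(10_000):
                cand = unit(rng.normal(size=spec.dim))
                if all(np.linalg.norm(cand - p) >= spec.centroid_separation for p in placed):
                    break
            else:
                raise RuntimeError(
                    f"cannot place {len(class_ids)} centroids at separation "
                    f"{spec.centroid_separation} in dim {spec.dim}"
                )
            placed.append(cand)
            centroids[c] = cand

    vectors: Dict[str, np.ndarray] = {}
    assignment: Dict[str, Tuple[str, ...]] = {}

    def emit(xid: str, label: str, centroid: np.ndarray) -> None:
        tokens = tuple(label.split(" "))
        assignment[xid] = tokens
        for t in tokens:
            noise = rng.normal(scale=spec.noise_sigma, size=spec.dim) if spec.noise_sigma > 0 else 0.0
            vectors[t] = centroid + noise

    for cid in class_ids:
        emit(cid, ontology.classes[cid].label, centroids[cid])
    for iid in sorted(ontology.instances):
        primary = min(ontology.instances[iid].parent_ids)
        emit(iid, ontology.instances[iid].label, centroids[primary])

    table = EmbeddingTable(
        dim=spec.dim,
        vectors=vectors,
        training_meta={"synthetic": True, "rng_seed": spec.rng_seed, "noise_sigma": spec.noise_sigma},
    )
    return table, assignment


def label_vectors(
    ontology: Ontology,
    table: EmbeddingTable,
    config: PipelineConfig | None = None,
) -> Dict[str, LabelVector]:
    """Tokenize every label through the real text pipeline and average."""
    tokenized = tokenize_labels(ontology, config)
    return {xid: label_vector(tl, table) for xid, tl in tokenized.items()}
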