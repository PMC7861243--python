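import math

import numpy as np
import pytest

from ontopop.graph import InstanceRecord, OntoClass, Ontology


@pytest.fixture
def diamond():
    """A -> (B, C) -> D with one instance under D."""
    return Ontology(
        classes=[
            OntoClass("A", "root food"),
            OntoClass("B", "left branch", frozenset({"A"})),
            OntoClass("C", "right branch", frozenset({"A"})),
            OntoClass("D", "diamond bottom", frozenset({"B", "C"})),
        ],
        instances=[InstanceRecord("i1", "item one", frozenset({"D"}))],
    )


@pytest.fixture
def chain3():
    """Root -> c1 -> c2 -> c3, single-parent chain."""
    return Ontology(
        classes=[
            OntoClass("r", "root"),
            OntoClass("c1", "one", frozenset({"r"})),
            OntoClass("c2", "two", frozenset({"c1"})),
            OntoClass("c3", "three", frozenset({"c2"})),
        ]
    )


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the code paths they check)
# ---------------------------------------------------------------------------

def dfs_has_cycle(parent_map):
    """White/grey/black DFS cycle detector over child->parent edges."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in parent_map}

    def visit(n):
        color[n] = GREY
        for p in parent_map[n]:
            if color[p] == GREY:
                return True
            if color[p] == WHITE and visit(p):
                return True
        color[n] = BLACK
        return False

    return any(color[n] == WHITE and visit(n) for n in parent_map)


def enumerate_paths(parent_map, start, root):
    """All directed child->parent paths from start to root, by backtracking."""
    paths = []

    def walk(node, acc):
        if node == root:
            paths.append(tuple(acc))
            return
        for p in sorted(parent_map[node]):
            walk(p, acc + [p])

    walk(start, [start])
    return paths


def brute_cosine(u, v):
    num = sum(a * b for a, b in zip(u, v))
    den = math.sqrt(sum(a * a for a in u)) * math.sqrt(sum(b * b for b in v))
    return num / den


def brute_force_assign(skeleton, vectors, alpha):
    """Per-candidate, per-class double loop with plain-math cosine scoring."""
    out = {}
    classes = sorted(skeleton.target_class_ids)
    for iid in sorted(skeleton.candidates):
        iv = vectors[iid].vector
        best_c, best_s = None, -float("inf")
        for c in classes:
            seeds = [vectors[s].vector for s in sorted(skeleton.seeds[c])]
            centroid = [sum(col) / len(seeds) for col in zip(*seeds)]
            sib = brute_cosine(list(iv), centroid)
            par = brute_cosine(list(iv), list(vectors[c].vector))
            s = alpha * sib + (1 - alpha) * par
            if s > best_s:  # first (lexicographically smallest) class wins ties
                best_c, best_s = c, s
        out[iid] = best_c
    return out


def nearest_centroid_assign(skeleton, vectors):
    """Independent alpha=1 rule: cosine to the seed centroid only."""
    out = {}
    for iid in sorted(skeleton.candidates):
        iv = np.asarray(vectors[iid].vector)
        best_c, best_s = None, -float("inf")
        for c in sorted(skeleton.target_class_ids):
            seeds = np.stack([vectors[s].vector for s in sorted(skeleton.seeds[c])])
            centroid = seeds.mean(axis=0)
            s = float(iv @ centroid / (np.linalg.norm(iv) * np.linalg.norm(centroid)))
            if s > best_s:
                best_c, best_s = c, s
        out[iid] = best_c
    return out


def nearest_class_label_assign(skeleton, vectors):
    """Independent alpha=0 rule: cosine to the class's own label vector only."""
    out = {}
    for iid in sorted(skeleton.candidates):
        iv = np.asarray(vectors[iid].vector)
        best_c, best_s = None, -float("inf")
        for c in sorted(skeleton.target_class_ids):
            cv = np.asarray(vectors[c].vector)
            s = float(iv @ cv / (np.linalg.norm(iv) * np.linalg.norm(cv)))
            if s > best_s:
                best_c, best_s = c, s
        out[iid] = best_c
    return out


def random_noisy_skeleton(rng_seed, n_classes=8, sigma=0.3, instances_mean=4.0, n_seed=2):
    """Small randomized fixture: noisy clustered vectors + a seeded skeleton."""
    from ontopop.graph import make_skeleton
    from ontopop.synthetic import SyntheticSpec, generate_embeddings, generate_ontology, label_vectors

    spec = SyntheticSpec(
        n_classes=n_classes,
        instances_mean=instances_mean,
        noise_sigma=sigma,
        dim=6,
        rng_seed=rng_seed,
    )
    ontology = generate_ontology(spec)
    if not ontology.instances:
        return None
    table, _ = generate_embeddings(ontology, spec)
    vectors = label_vectors(ontology, table)
    skeleton = make_skeleton(ontology, n_seed=n_seed, rng_seed=rng_seed)
    if not skeleton.candidates:
        return None
    return skeleton, vectors
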