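"""Multi-parent ontology DAG: data model, TSV I/O, structural analytics, seeding.

The ontology is a rooted DAG of classes (child -> parent edges) plus a set of
instances, each attached to one or more parent classes.  All traversal helpers
are documented against the child->parent storage convention.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Set

import networkx as nx
import numpy as np

__all__ = [
    "OntoClass",
    "InstanceRecord",
    "Ontology",
    "SeededSkeleton",
    "OntologyError",
    "CycleError",
    "DanglingParentError",
    "DuplicateIdError",
    "RootError",
    "UnknownIdError",
    "read_ontology",
    "write_ontology",
    "depth_of",
    "paths_to_root",
    "instances_per_class",
    "make_skeleton",
]


class OntologyError(ValueError):
    """Base class for structural validation failures."""


class CycleError(OntologyError):
    """The class graph contains a directed cycle."""


class DanglingParentError(OntologyError):
    """A parent id does not resolve to any class."""


class DuplicateIdError(OntologyError):
    """The same id was declared more than once."""


class RootError(OntologyError):
    """The class graph has zero roots or more than one root."""


class UnknownIdError(OntologyError, KeyError):
    """A queried id is not present in the ontology."""


@dataclass(frozen=True)
class OntoClass:
    id: str
    label: str
    parent_ids: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.label:
            raise OntologyError(f"class {self.id!r} has an empty label")


@dataclass(frozen=True)
class InstanceRecord:
    id: str
    label: str
    parent_ids: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.parent_ids:
            raise OntologyError(f"instance {self.id!r} has no parent classes")
        if not self.label:
            raise OntologyError(f"instance {self.id!r} has an empty label")


class Ontology:
    """Validated rooted multi-parent class DAG with instance assignments.

    Parameters
    ----------
    classes, instances
        The class and instance records.  Validation runs on construction:
        unique ids, resolvable parents, acyclicity, exactly one parentless
        class (the root).
    """

    def __init__(self, classes: Iterable[OntoClass], instances: Iterable[InstanceRecord] = ()) -> None:
        self.classes: Dict[str, OntoClass] = {}
        for c in classes:
            if c.id in self.classes:
                raise DuplicateIdError(f"duplicate class id {c.id!r}")
            self.classes[c.id] = c
        self.instances: Dict[str, InstanceRecord] = {}
        for i in instances:
            if i.id in self.instances or i.id in self.classes:
                raise DuplicateIdError(f"duplicate id {i.id!r}")
            self.instances[i.id] = i
        self.root_id = self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> str:
        for c in self.classes.values():
            for p in c.parent_ids:
                if p not in self.classes:
                    raise DanglingParentError(f"class {c.id!r} has unknown parent {p!r}")
        for i in self.instances.values():
            for p in i.parent_ids:
                if p not in self.classes:
                    raise DanglingParentError(f"instance {i.id!r} has unknown parent {p!r}")
        roots = [c.id for c in self.classes.values() if not c.parent_ids]
        if len(roots) != 1:
            raise RootError(f"expected exactly one root class, found {len(roots)}: {sorted(roots)}")
        g = self.class_graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"class graph contains a cycle: {cyc}")
        # single root + acyclic + resolvable parents => every class reaches root,
        # but assert it explicitly so the invariant is load-bearing, not implied.
        reach = set(nx.ancestors(g, roots[0])) | {roots[0]}  # nodes with a path to root
        if reach != set(self.classes):
            raise OntologyError(f"classes not connected to root: {sorted(set(self.classes) - reach)}")
        return roots[0]

    # -- views ------------------------------------------------------------
    def class_graph(self) -> "nx.DiGraph":
        """Directed class graph with child -> parent edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for c in self.classes.values():
            for p in c.parent_ids:
                g.add_edge(c.id, p)
        return g

    def instances_of(self, class_id: str) -> Set[str]:
        """Instance ids whose ground-truth parents contain ``class_id``."""
        if class_id not in self.classes:
            raise UnknownIdError(class_id)
        return {i.id for i in self.instances.values() if class_id in i.parent_ids}

    def target_class_ids(self) -> Set[str]:
        """Classes with at least one instance (eligible to receive candidates)."""
        out: Set[str] = set()
        for i in self.instances.values():
            out |= i.parent_ids
        return out

    def descendants_of(self, class_id: str) -> Set[str]:
        """All classes having ``class_id`` as an ancestor, plus itself."""
        if class_id not in self.classes:
            raise UnknownIdError(class_id)
        # child->parent edges: descendants are ancestors in the stored direction
        return set(nx.ancestors(self.class_graph(), class_id)) | {class_id}

    def labels(self) -> Dict[str, str]:
        out = {cid: c.label for cid, c in self.classes.items()}
        out.update({iid: i.label for iid, i in self.instances.items()})
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Ontology(|C|={len(self.classes)}, |I|={len(self.instances)}, root={self.root_id!r})"


@dataclass
class SeededSkeleton:
    """An ontology whose target classes expose a few seed instances.

    ``seeds[c]`` holds min(n_seed, |I_c|) instance ids drawn without
    replacement from I_c; every instance seeded for *any* class is removed
    from ``candidates`` globally so no held-out instance ever leaks a label.
    """

    ontology: Ontology
    n_seed: int
    seeds: Dict[str, FrozenSet[str]]
    candidates: FrozenSet[str]
    target_class_ids: FrozenSet[str]
    rng_seed: int

    def __post_init__(self) -> None:
        seed_union = self.seed_union()
        all_ids = set(self.ontology.instances)
        if seed_union & set(self.candidates):
            raise OntologyError("seed/candidate overlap")
        if seed_union | set(self.candidates) != all_ids:
            raise OntologyError("seeds and candidates do not partition the instance set")

    def seed_union(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.seeds.values():
            out |= s
        return out


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_ontology(edges_path, labels_path) -> Ontology:
    """Read the two-file TSV dialect into a validated :class:`Ontology`.

    Edges file (no header): ``child_id<TAB>parent_id<TAB>kind`` with kind in
    {class, instance}; multi-parent children repeat the child line.  The root
    class appears with an empty parent field.  Labels file: ``id<TAB>label``.
    """
    labels: Dict[str, str] = {}
    with open(labels_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(f"{labels_path}:{ln}: expected 2 fields, got {len(parts)}")
            if parts[0] in labels:
                raise DuplicateIdError(f"{labels_path}:{ln}: duplicate id {parts[0]!r}")
            labels[parts[0]] = parts[1]

    class_parents: Dict[str, Set[str]] = {}
    inst_parents: Dict[str, Set[str]] = {}
    with open(edges_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OntologyError(f"{edges_path}:{ln}: expected 3 fields, got {len(parts)}")
            child, parent, kind = parts
            if kind == "class":
                bucket = class_parents
            elif kind == "instance":
                bucket = inst_parents
            else:
                raise OntologyError(f"{edges_path}:{ln}: unknown kind {kind!r}")
            if child in (class_parents if bucket is inst_parents else inst_parents):
                raise DuplicateIdError(f"{edges_path}:{ln}: id {child!r} used as both class and instance")
            parents = bucket.setdefault(child, set())
            if parent:
                parents.add(parent)

    classes = [
        OntoClass(cid, labels.get(cid, cid), frozenset(ps)) for cid, ps in class_parents.items()
    ]
    instances = [
        InstanceRecord(iid, labels.get(iid, iid), frozenset(ps)) for iid, ps in inst_parents.items()
    ]
    return Ontology(classes, instances)


def write_ontology(ontology: Ontology, edges_path, labels_path) -> None:
    """Emit the same TSV dialect ``read_ontology`` consumes, byte-stably."""
    with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
        for cid in sorted(ontology.classes):
            parents = sorted(ontology.classes[cid].parent_ids)
            if not parents:
                fh.write(f"{cid}\t\tclass\n")
            for p in parents:
                fh.write(f"{cid}\t{p}\tclass\n")
        for iid in sorted(ontology.instances):
            for p in sorted(ontology.instances[iid].parent_ids):
                fh.write(f"{iid}\t{p}\tinstance\n")
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        for xid, label in sorted(ontology.labels().items()):
            fh.write(f"{xid}\t{label}\n")


# ---------------------------------------------------------------------------
# Structural analytics
# ---------------------------------------------------------------------------

def depth_of(ontology: Ontology, class_id: str) -> int:
    """Minimum number of edges from ``class_id`` up to the root (root = 0)."""
    if class_id not in ontology.classes:
        raise UnknownIdError(class_id)
    depth = 0
    frontier = {class_id}
    seen = set(frontier)
    while ontology.root_id not in frontier:
        nxt: Set[str] = set()
        for c in frontier:
            nxt |= ontology.classes[c].parent_ids
        nxt -= seen
        seen |= nxt
        frontier = nxt
        depth += 1
    return depth


def paths_to_root(ontology: Ontology, class_id: str) -> int:
    """Count of distinct directed child->parent paths to the root (root = 1)."""
    if class_id not in ontology.classes:
        raise UnknownIdError(class_id)
    memo: Dict[str, int] = {ontology.root_id: 1}

    def count(c: str) -> int:
        if c not in memo:
            memo[c] = sum(count(p) for p in ontology.classes[c].parent_ids)
        return memo[c]

    return count(class_id)


def instances_per_class(ontology: Ontology) -> Dict[str, int]:
    """|I_c| per class; multi-parent instances count once in every parent."""
    counts = {cid: 0 for cid in ontology.classes}
    for inst in ontology.instances.values():
        for p in inst.parent_ids:
            counts[p] += 1
    return counts


def class_depths(ontology: Ontology) -> Dict[str, int]:
    """Minimum depth for every class in one pass (BFS down from root)."""
    children: Dict[str, List[str]] = {cid: [] for cid in ontology.classes}
    for c in ontology.classes.values():
        for p in c.parent_ids:
            children[p].append(c.id)
    depths = {ontology.root_id: 0}
    q = deque([ontology.root_id])
    while q:
        c = q.popleft()
        for ch in children[c]:
            if ch not in depths:
                depths[ch] = depths[c] + 1
                q.append(ch)
    return depths


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def make_skeleton(ontology: Ontology, n_seed: int, rng_seed: int) -> SeededSkeleton:
    """Draw ``min(n_seed, |I_c|)`` uniform seeds per target class.

    Target classes (those with at least one instance) are visited in sorted
    order so the draw is deterministic given ``rng_seed``.  An instance seeded
    under any class is excluded from the candidate pool entirely.
    """
    if n_seed < 1:
        raise ValueError(f"n_seed must be >= 1, got {n_seed}")
    rng = np.random.default_rng(rng_seed)
    targets = sorted(ontology.target_class_ids())
    members: Dict[str, List[str]] = {c: [] for c in targets}
    for inst in sorted(ontology.instances.values(), key=lambda i: i.id):
        for p in inst.parent_ids:
            members[p].append(inst.id)
    seeds: Dict[str, FrozenSet[str]] = {}
    for c in targets:
        pool = members[c]
        k = min(n_seed, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False)
        seeds[c] = frozenset(pool[j] for j in chosen)
    seed_union = set().union(*seeds.values()) if seeds else set()
    candidates = frozenset(set(ontology.instances) - seed_union)
    return SeededSkeleton(
        ontology=ontology,
        n_seed=n_seed,
        seeds=seeds,
        candidates=candidates,
        target_class_ids=frozenset(targets),
        rng_seed=rng_seed,
    )
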