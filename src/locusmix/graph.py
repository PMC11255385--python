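"""Admixture graphs and the drift variance-covariance matrix.

A population graph is a rooted tree of drift branches augmented with
directed migration edges carrying no length.  Each migration edge ``i``
is *open* with probability ``w_i`` (the mixture proportion); a binary
configuration ``b`` of open/closed edges resolves the graph into a
single-parent forest, and the drift covariance of the arcsine-transformed
leaf allele frequencies is

    W(c, w) = sum_k c_k J_k,      [J_k]_{mn} = p_{mk} p_{nk},

where ``p_{mk}`` is the probability that branch ``k`` lies on the
root-to-leaf path of population ``m`` when each edge is opened
independently with probability ``w_i``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Branch",
    "MigrationEdge",
    "PopulationGraph",
    "GraphError",
    "parse_graph",
    "parse_and_validate",
    "expand_bidirectional",
    "resolve_configuration",
    "configuration_probability",
    "branch_inclusion_probabilities",
    "branch_inclusion_enumerated",
    "drift_covariance",
]

#: hard cap on migration edges for exhaustive 2^I enumeration
DEFAULT_MAX_EDGES = 12


class GraphError(ValueError):
    """Raised for structurally invalid population graphs."""


@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    length: float | None = None

    @property
    def name(self) -> str:
        return f"{self.parent}->{self.child}"


@dataclass(frozen=True)
class MigrationEdge:
    id: str
    source: str
    target: str


@dataclass
class PopulationGraph:
    """Rooted admixture graph: drift branches plus lengthless migration edges."""

    root: str
    branches: list[Branch]
    migration_edges: list[MigrationEdge] = field(default_factory=list)
    leaves: dict[str, str] = field(default_factory=dict)  # node -> population label

    def __post_init__(self) -> None:
        self._parent = {b.child: b.parent for b in self.branches}
        self._branch_index = {(b.parent, b.child): k for k, b in enumerate(self.branches)}
        self._mig_by_target = {e.target: i for i, e in enumerate(self.migration_edges)}

    # -- basic accessors -------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.branches)

    @property
    def I(self) -> int:
        return len(self.migration_edges)

    @property
    def M(self) -> int:
        return len(self.leaves)

    @property
    def populations(self) -> list[str]:
        """Population labels in a fixed order (sorted)."""
        return sorted(self.leaves.values())

    @property
    def nodes(self) -> set[str]:
        out = {self.root}
        for b in self.branches:
            out.add(b.parent)
            out.add(b.child)
        return out

    def tree_parent(self, node: str) -> str | None:
        return self._parent.get(node)

    def branch_lengths(self) -> np.ndarray:
        return np.array(
            [np.nan if b.length is None else b.length for b in self.branches], float
        )

    def with_branch_lengths(self, c: np.ndarray) -> "PopulationGraph":
        c = np.asarray(c, float)
        if c.shape != (self.K,):
            raise GraphError(f"dimension error: expected {self.K} branch lengths")
        new = [replace(b, length=float(ci)) for b, ci in zip(self.branches, c)]
        return PopulationGraph(self.root, new, list(self.migration_edges), dict(self.leaves))

    # -- validation ------------------------------------------------------
    def validate(self, max_edges: int = DEFAULT_MAX_EDGES) -> None:
        nodes = self.nodes
        if self.root in self._parent:
            raise GraphError("cyclic graph: root has a tree parent")
        children_seen: dict[str, int] = {}
        for b in self.branches:
            children_seen[b.child] = children_seen.get(b.child, 0) + 1
        for child, cnt in children_seen.items():
            if cnt > 1:
                raise GraphError(f"cyclic graph: node {child!r} has multiple tree parents")
        for n in nodes - {self.root}:
            if n not in self._parent:
                raise GraphError(f"dangling edge: node {n!r} has no tree parent")
        for e in self.migration_edges:
            if e.source not in nodes or e.target not in nodes:
                raise GraphError(f"dangling edge: migration {e.id!r} uses unknown node")
            if e.target not in self._parent:
                raise GraphError(
                    f"dangling edge: migration target {e.target!r} has no tree parent"
                )
        targets = [e.target for e in self.migration_edges]
        if len(set(targets)) != len(targets):
            raise GraphError("dangling edge: multiple migration edges share a target node")
        labels = list(self.leaves.values())
        if len(set(labels)) != len(labels):
            raise GraphError("label clash: duplicate population label")
        for leaf in self.leaves:
            if leaf not in nodes:
                raise GraphError(f"dangling edge: leaf node {leaf!r} not in graph")
        if self.I > max_edges:
            raise GraphError("too many migration edges")
        # every configuration must resolve to an acyclic single-parent forest
        for bits in itertools.product((0, 1), repeat=self.I):
            parent = self._effective_parents(np.array(bits))
            for start in self.leaves:
                seen = set()
                node = start
                while node is not None and node != self.root:
                    if node in seen:
                        raise GraphError(
                            f"cyclic graph: configuration {bits} creates a cycle"
                        )
                    seen.add(node)
                    node = parent.get(node)

    def _effective_parents(self, b: np.ndarray) -> dict[str, str]:
        parent = dict(self._parent)
        for i, e in enumerate(self.migration_edges):
            if b[i]:
                parent[e.target] = e.source
        return parent


# ---------------------------------------------------------------------------
# parsing

def parse_graph(text: str, *, auto_expand: bool = True,
                max_edges: int = DEFAULT_MAX_EDGES) -> PopulationGraph:
    """Parse the plain-text graph format and validate the result.

    Records (one per line, ``#`` starts a comment)::

        ROOT <name>
        NODE <name>                       # optional declaration
        BRANCH <parent> <child> [length]
        MIG <id> <source> <target>
        LEAF <node> <population>

    With ``auto_expand`` (default), a pair of opposed migration edges
    between the same two branches is rewritten via
    :func:`expand_bidirectional` before validation.
    """
    root = None
    branches: list[Branch] = []
    migs: list[MigrationEdge] = []
    leaves: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0].upper()
        try:
            if kind == "ROOT":
                if root is not None:
                    raise GraphError("cyclic graph: more than one ROOT record")
                root = parts[1]
            elif kind == "NODE":
                pass  # declaration only; nodes are implied by edges
            elif kind == "BRANCH":
                length = float(parts[3]) if len(parts) > 3 else None
                branches.append(Branch(parts[1], parts[2], length))
            elif kind == "MIG":
                migs.append(MigrationEdge(parts[1], parts[2], parts[3]))
            elif kind == "LEAF":
                leaves[parts[1]] = parts[2]
            else:
                raise GraphError(f"unknown record {kind!r}")
        except IndexError as exc:
            raise GraphError(f"line {lineno}: malformed record {line!r}") from exc
    if root is None:
        raise GraphError("no ROOT record")
    graph = PopulationGraph(root, branches, migs, leaves)
    if auto_expand:
        graph = _expand_all_bidirectional(graph)
    graph.validate(max_edges=max_edges)
    return graph


def parse_and_validate(text: str, **kw) -> PopulationGraph:
    """Alias of :func:`parse_graph` (parse + full invariant validation)."""
    return parse_graph(text, **kw)


def _opposed_pairs(graph: PopulationGraph) -> list[tuple[int, int]]:
    """Indices of migration-edge pairs forming A->B / B->A between the same nodes
    or whose open/open configuration is mutually cyclic through shared nodes."""
    pairs = []
    for i, j in itertools.combinations(range(graph.I), 2):
        a, b = graph.migration_edges[i], graph.migration_edges[j]
        if a.source == b.target and a.target == b.source:
            pairs.append((i, j))
    return pairs


def _expand_all_bidirectional(graph: PopulationGraph) -> PopulationGraph:
    while True:
        pairs = _opposed_pairs(graph)
        if not pairs:
            return graph
        i, j = pairs[0]
        graph = expand_bidirectional(
            graph, (graph.migration_edges[i].id, graph.migration_edges[j].id)
        )


def expand_bidirectional(graph: PopulationGraph, pair: tuple[str, str]) -> PopulationGraph:
    """Orient a pair of opposed migration edges so no configuration cycles.

    The two edges run ``a -> b`` and ``b -> a``.  Node ``a`` is split by a
    zero-length branch ``a -> a*``: the first edge keeps its source ``a``
    (now *preceding*), while the second edge's target moves to ``a*``.
    With both edges open the resolved paths are then acyclic.  An edge
    pair that is not actually opposed is returned unchanged.
    """
    ids = {e.id: k for k, e in enumerate(graph.migration_edges)}
    try:
        i, j = ids[pair[0]], ids[pair[1]]
    except KeyError as exc:
        raise GraphError(f"dangling edge: unknown migration id in {pair}") from exc
    e1, e2 = graph.migration_edges[i], graph.migration_edges[j]
    if not (e1.source == e2.target and e1.target == e2.source):
        return graph  # already acyclic / not an opposed pair
    others = [
        e for k, e in enumerate(graph.migration_edges)
        if k not in (i, j) and {e.source, e.target} == {e1.source, e1.target}
    ]
    if others:
        raise GraphError("cannot orient bidirectional pair: more than two opposed edges")
    a = e1.source
    a_split = a + "*"
    if a_split in graph.nodes:
        raise GraphError(f"cannot orient bidirectional pair: node {a_split!r} exists")
    # children of a move below the zero-length split so that a precedes a*
    new_branches = []
    for b in graph.branches:
        new_branches.append(replace(b, parent=a_split) if b.parent == a else b)
    new_branches.append(Branch(a, a_split, 0.0))
    new_migs = []
    for k, e in enumerate(graph.migration_edges):
        if k == j:
            new_migs.append(replace(e, target=a_split))
        else:
            new_migs.append(e)
    new_leaves = dict(graph.leaves)
    if a in new_leaves:  # leaf stays at the bottom of the split
        new_leaves[a_split] = new_leaves.pop(a)
    return PopulationGraph(graph.root, new_branches, new_migs, new_leaves)


# ---------------------------------------------------------------------------
# configurations

def configuration_probability(w: np.ndarray, b: np.ndarray) -> float:
    """Probability of configuration ``b``: prod_i w_i^{b_i} (1-w_i)^{1-b_i}."""
    w = np.asarray(w, float)
    b = np.asarray(b)
    if w.shape != b.shape:
        raise GraphError("dimension error: configuration/rate length mismatch")
    return float(np.prod(np.where(b.astype(bool), w, 1.0 - w)))


def resolve_configuration(graph: PopulationGraph, b: np.ndarray) -> dict[str, set[str]]:
    """Root path of each leaf under configuration ``b``.

    Returns ``{population label: set of branch names}``.  Each migration
    target's effective parent is the migration source when its bit is 1
    (reached via the lengthless migration edge, so its incoming tree
    branch is bypassed) and its tree parent otherwise.  A leaf caught in
    a cycle away from the root resolves to the empty set (disconnected).
    """
    b = np.asarray(b)
    if b.shape != (graph.I,):
        raise GraphError("dimension error: configuration length mismatch")
    parent = graph._effective_parents(b)
    open_targets = {e.target for i, e in enumerate(graph.migration_edges) if b[i]}
    out: dict[str, set[str]] = {}
    for leaf, pop in graph.leaves.items():
        path: set[str] = set()
        node = leaf
        seen: set[str] = set()
        ok = True
        while node != graph.root:
            if node in seen or node not in parent:
                ok = False
                break
            seen.add(node)
            par = parent[node]
            if node not in open_targets:
                path.add(f"{par}->{node}")
            node = par
        out[pop] = path if ok else set()
    return out


# ---------------------------------------------------------------------------
# drift covariance

def branch_inclusion_enumerated(graph: PopulationGraph, w: np.ndarray,
                                max_edges: int = DEFAULT_MAX_EDGES) -> np.ndarray:
    """p_{mk} by exhaustive enumeration of all 2^I configurations (oracle path)."""
    w = np.asarray(w, float)
    if w.shape != (graph.I,):
        raise GraphError("dimension error: expected one rate per migration edge")
    if graph.I > max_edges:
        raise GraphError("too many migration edges")
    pops = graph.populations
    p = np.zeros((graph.M, graph.K))
    names = [br.name for br in graph.branches]
    idx = {n: k for k, n in enumerate(names)}
    for bits in itertools.product((0, 1), repeat=graph.I):
        bv = np.array(bits)
        prob = configuration_probability(w, bv)
        if prob == 0.0:
            continue
        paths = resolve_configuration(graph, bv)
        for m, pop in enumerate(pops):
            for name in paths[pop]:
                p[m, idx[name]] += prob
    return p


def branch_inclusion_probabilities(graph: PopulationGraph, w: np.ndarray) -> np.ndarray:
    """p_{mk} by mixture recursion over each leaf's ancestry (fast path).

    Walking up from a leaf, a migration target mixes its two possible
    parents with weights (w_i, 1-w_i); since a root path visits each node
    (hence each edge bit) at most once, linearity of expectation makes
    this recursion exact for the marginal inclusion probabilities.
    """
    w = np.asarray(w, float)
    if w.shape != (graph.I,):
        raise GraphError("dimension error: expected one rate per migration edge")
    names = {br.name: k for k, br in enumerate(graph.branches)}
    mig_by_target = {e.target: i for i, e in enumerate(graph.migration_edges)}
    cache: dict[str, dict[int, float]] = {}

    def above(node: str) -> dict[int, float]:
        """Expected inclusion of each branch on the path root..node (inclusive arrival)."""
        if node == graph.root:
            return {}
        if node in cache:
            return cache[node]
        tp = graph.tree_parent(node)
        tree_part = dict(above(tp))
        k = names[f"{tp}->{node}"]
        tree_part[k] = tree_part.get(k, 0.0) + 1.0
        if node in mig_by_target:
            i = mig_by_target[node]
            src_part = above(graph.migration_edges[i].source)
            mixed: dict[int, float] = {}
            for kk, v in tree_part.items():
                mixed[kk] = mixed.get(kk, 0.0) + (1.0 - w[i]) * v
            for kk, v in src_part.items():
                mixed[kk] = mixed.get(kk, 0.0) + w[i] * v
            cache[node] = mixed
        else:
            cache[node] = tree_part
        return cache[node]

    p = np.zeros((graph.M, graph.K))
    for m, pop in enumerate(graph.populations):
        leaf = next(n for n, lab in graph.leaves.items() if lab == pop)
        for k, v in above(leaf).items():
            p[m, k] = v
    return p


def drift_covariance(graph: PopulationGraph, c: np.ndarray, w: np.ndarray, *,
                     method: str = "recursion",
                     max_edges: int = DEFAULT_MAX_EDGES) -> np.ndarray:
    """Drift covariance W(c, w) = sum_k c_k p_k p_k' over branches.

    ``method`` is ``"recursion"`` (default, exact mixture recursion) or
    ``"enumeration"`` (explicit sum over all 2^I configurations; used as
    an internal oracle).  Negative branch lengths are accepted — the
    result may then be indefinite, which downstream emission code guards.
    """
    c = np.asarray(c, float)
    if c.shape != (graph.K,):
        raise GraphError(f"dimension error: expected {graph.K} branch lengths")
    if method == "recursion":
        p = branch_inclusion_probabilities(graph, w)
    elif method == "enumeration":
        p = branch_inclusion_enumerated(graph, w, max_edges=max_edges)
    else:
        raise ValueError(f"unknown method {method!r}")
    W = (p * c) @ p.T
    return 0.5 * (W + W.T)
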