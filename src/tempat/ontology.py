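"""Annotation DAG handling: loading, propagation, traversal order, grouping.

Gene Ontology terms form a directed acyclic graph in which a term may have
several parents and deeper terms are more specific.  Under the true-path
rule a gene annotated to a term is implicitly annotated to every ancestor
of that term.  The pattern search visits terms leaves-first (most specific
first) and, whenever a cluster is found at a term, deletes its genes from
all ancestors of that term so the cluster is reported at the most specific
annotation available; sibling terms are untouched.

Only ``is_a`` edges are traversed.  Flat gene sets (e.g. a curated pathway)
and unannotated genes are attached as pseudo-terms below a virtual root so
one traversal covers everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import heappush, heappop

import networkx as nx
from scipy.stats import fisher_exact

from .matrix import InvalidInputError

logger = logging.getLogger(__name__)

VIRTUAL_ROOT = "VIRTUAL:root"
UNANNOTATED_TERM = "SET:unannotated"


class MalformedOntologyError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """An is_a DAG with child-to-parent edges and max-depth-from-root levels."""

    graph: nx.DiGraph  # edge u -> v means "u is_a v" (v is a parent of u)
    names: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise MalformedOntologyError("ontology contains a cycle")
        self.depth = self._compute_depths()

    def _compute_depths(self) -> dict[str, int]:
        # depth = length of the longest child-to-parent path to a root
        depth: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(self.graph))):
            parents = list(self.graph.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of ``term`` (transitive parents)."""
        return set(nx.descendants(self.graph, term))

    def descendants(self, term: str) -> set[str]:
        return set(nx.ancestors(self.graph, term))

    def leaves(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}


def load_ontology(obo_source, namespace: str | None = "molecular_function") -> OntologyGraph:
    """Load an OBO file into an :class:`OntologyGraph`.

    Keeps only ``is_a`` edges and, when ``namespace`` is given, only terms of
    that namespace.  Obsolete terms are dropped by the OBO reader.
    """
    import obonet

    multigraph = obonet.read_obo(obo_source)
    g = nx.DiGraph()
    names: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if namespace is not None and data.get("namespace") not in (None, namespace):
            continue
        g.add_node(node)
        names[node] = data.get("name", node)
    for u, v, key in multigraph.edges(keys=True):
        if key == "is_a" and u in g and v in g:
            g.add_edge(u, v)
    return OntologyGraph(graph=g, names=names)


def single_node_ontology(term: str = "all") -> OntologyGraph:
    """The trivial one-term ontology (root and only leaf at once)."""
    g = nx.DiGraph()
    g.add_node(term)
    return OntologyGraph(graph=g, names={term: term})


def extend_with_gene_sets(
    ontology: OntologyGraph,
    gene_sets: dict[str, set[str]] | None = None,
    unannotated_genes: set[str] | None = None,
) -> tuple[OntologyGraph, dict[str, set[str]]]:
    """Attach flat gene sets and an unannotated pseudo-leaf below a virtual root.

    Returns the extended graph plus the direct annotations contributed by the
    pseudo-terms (``SET:<name>`` per flat set, plus ``SET:unannotated``).
    """
    g = ontology.graph.copy()
    names = dict(ontology.names)
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    g.add_node(VIRTUAL_ROOT)
    names[VIRTUAL_ROOT] = "virtual root"
    for r in roots:
        g.add_edge(r, VIRTUAL_ROOT)
    extra: dict[str, set[str]] = {}
    for name, genes in (gene_sets or {}).items():
        term = f"SET:{name}"
        g.add_node(term)
        g.add_edge(term, VIRTUAL_ROOT)
        names[term] = name
        extra[term] = set(genes)
    if unannotated_genes:
        g.add_node(UNANNOTATED_TERM)
        g.add_edge(UNANNOTATED_TERM, VIRTUAL_ROOT)
        names[UNANNOTATED_TERM] = "unannotated"
        extra[UNANNOTATED_TERM] = set(unannotated_genes)
    return OntologyGraph(graph=g, names=names), extra


@dataclass
class AnnotationMap:
    """Direct and true-path-propagated term-to-gene maps."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]

    def working_copy(self) -> dict[str, set[str]]:
        """A mutable copy of the propagated map (the pristine closure is kept)."""
        return {t: set(g) for t, g in self.propagated.items()}


def propagate_annotations(
    graph: OntologyGraph, direct_annotations: dict[str, set[str]]
) -> AnnotationMap:
    """True-path closure: a term inherits the genes of all its descendants."""
    direct: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for term, genes in direct_annotations.items():
        if term not in direct:
            logger.warning("skipping annotations to unknown term %s", term)
            continue
        direct[term] |= {str(g) for g in genes}
    propagated: dict[str, set[str]] = {}
    # children before parents: iterate a topological order of child->parent edges
    for term in nx.topological_sort(graph.graph):
        acc = set(direct[term])
        for child in graph.children(term):
            acc |= propagated[child]
        propagated[term] = acc
    return AnnotationMap(direct=direct, propagated=propagated)


def leaves_first_order(graph: OntologyGraph) -> list[str]:
    """Reverse-topological term order: every child precedes all its ancestors.

    Among simultaneously available terms, deeper terms come first; remaining
    ties break lexicographically on the term id, making the order unique.
    """
    remaining_children = {t: graph.graph.in_degree(t) for t in graph.nodes}
    heap: list[tuple[int, str]] = []
    for t, c in remaining_children.items():
        if c == 0:
            heappush(heap, (-graph.depth[t], t))
    order: list[str] = []
    while heap:
        _, term = heappop(heap)
        order.append(term)
        for parent in graph.parents(term):
            remaining_children[parent] -= 1
            if remaining_children[parent] == 0:
                heappush(heap, (-graph.depth[parent], parent))
    if len(order) != len(graph.nodes):
        raise MalformedOntologyError("ontology contains a cycle")
    return order


def remove_from_ancestors(
    annotation: AnnotationMap | dict[str, set[str]],
    graph: OntologyGraph,
    genes: set[str],
    node: str,
    inplace: bool = False,
) -> dict[str, set[str]]:
    """Delete ``genes`` from the propagated sets of every strict ancestor of ``node``.

    The node itself and its siblings keep the genes.  Accepts either an
    :class:`AnnotationMap` (its pristine ``propagated`` map is copied, never
    modified) or a mutable working map (modified in place when requested).
    """
    if node not in graph.nodes:
        raise InvalidInputError(f"unknown term {node}")
    if isinstance(annotation, AnnotationMap):
        working = annotation.working_copy()
    else:
        working = annotation if inplace else {t: set(g) for t, g in annotation.items()}
    for anc in graph.ancestors(node):
        if anc in working:
            working[anc] -= genes
    return working


def group_connected_terms(
    significant_terms: set[str], graph: OntologyGraph
) -> list[tuple[str, set[str]]]:
    """Group terms connected by ancestor/descendant paths; label by the most general.

    Two significant terms belong to the same group when one is an ancestor of
    the other in the full graph.  Each group is labeled by its minimum-depth
    member (lexicographically first on ties, which are logged).
    """
    terms = sorted(significant_terms)
    unknown = [t for t in terms if t not in graph.nodes]
    if unknown:
        raise InvalidInputError(f"terms not in graph: {unknown}")
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    term_set = set(terms)
    for t in terms:
        for anc in graph.ancestors(t) & term_set:
            ra, rb = find(t), find(anc)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for t in terms:
        groups.setdefault(find(t), set()).add(t)
    labeled = []
    for members in groups.values():
        min_depth = min(graph.depth[t] for t in members)
        candidates = sorted(t for t in members if graph.depth[t] == min_depth)
        if len(candidates) > 1:
            logger.info("group label tie at depth %d: %s", min_depth, candidates)
        labeled.append((candidates[0], members))
    labeled.sort(key=lambda x: x[0])
    return labeled


def fisher_enrichment(
    cluster_genes: set[str], group_genes: set[str], background_genes: set[str]
) -> float:
    """One-sided (over-representation) Fisher's exact p-value.

    2x2 table: membership in the cluster crossed with membership in the
    functional group, over the background universe.
    """
    if not background_genes:
        raise InvalidInputError("background gene set is empty")
    cluster = set(cluster_genes) & set(background_genes)
    group = set(group_genes) & set(background_genes)
    a = len(cluster & group)
    b = len(cluster - group)
    c = len(group - cluster)
    d = len(set(background_genes)) - a - b - c
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def read_annotations_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> direct term-to-gene map."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            direct.setdefault(term, set()).add(gene)
    return direct


def read_annotations_gaf(path) -> dict[str, set[str]]:
    """GAF 2.x reader: DB object id (column 2) and GO id (column 5)."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            gene, term = cols[1], cols[4]
            direct.setdefault(term, set()).add(gene)
    return direct


def read_gene_sets_gmt(path) -> dict[str, set[str]]:
    """GMT reader: set name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            sets[cols[0]] = {g for g in cols[2:] if g}
    return sets
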