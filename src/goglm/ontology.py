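"""Gene Ontology DAG handling and annotation propagation.

The Gene Ontology (GO) is a directed acyclic graph (DAG) of functional
terms in three namespaces: biological process (BP), cellular component
(CC) and molecular function (MF).  Parent terms describe more general
functions than their children, and a gene annotated to a term is
implicitly annotated to every ancestor of that term (the *true-path
rule*).  This module parses OBO ontology files and gene-to-term
association tables, propagates direct annotations up the DAG, and
provides the parent lookups and category-size filtering used by the
enrichment tests.

Parenthood follows ``is_a`` and ``part_of`` edges, which matches the
behaviour of the GO.db/org.*.db annotation packages most enrichment
tools are built on; other relations (``regulates`` and friends) are
ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: OBO namespace name -> two/three letter abbreviation used in reports.
NAMESPACE_ABBREV = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

#: Edge types that define parenthood.
PARENT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Structural or parse problem in an ontology or association file."""


class UnknownTermError(KeyError):
    """A term identifier not present in the loaded DAG."""


@dataclass
class GoTerm:
    """One ontology term.

    ``parent_ids`` holds the direct parents reachable via ``is_a`` or
    ``part_of`` edges.  Obsolete terms keep no parents and may carry no
    annotations.
    """

    term_id: str
    name: str = ""
    namespace: str = ""
    parent_ids: set[str] = field(default_factory=set)
    obsolete: bool = False


@dataclass
class GoDag:
    """A parsed ontology: term table plus the namespace roots."""

    terms: dict[str, GoTerm]
    roots: set[str]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> GoTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class AnnotationMap:
    """Gene annotations, before and after true-path propagation.

    Invariants: ``direct[t] <= propagated[t]`` and
    ``propagated[t] <= propagated[p]`` for every parent ``p`` of ``t``;
    ``universe`` is the union of all propagated sets.
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] | None = None
    universe: set[str] = field(default_factory=set)
    unknown_terms: set[str] = field(default_factory=set)

    def term_sizes(self) -> dict[str, int]:
        if self.propagated is None:
            raise ValueError("annotations have not been propagated yet")
        return {t: len(g) for t, g in self.propagated.items()}


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology file into a :class:`GoDag`.

    Only ``is_a`` and ``part_of`` edges become parent links.  The edge
    relation must be acyclic (a self-loop counts as a cycle).

    Raises
    ------
    OntologyError
        On malformed stanzas or a cyclic edge relation.
    """
    path = Path(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises plain ValueError on bad stanzas
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc

    terms: dict[str, GoTerm] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[node] = GoTerm(
            term_id=node,
            name=data.get("name", ""),
            namespace=NAMESPACE_ABBREV.get(
                data.get("namespace", ""), data.get("namespace", "")
            ),
            obsolete=obsolete,
        )

    # obonet stores edges child -> parent keyed by relation type.
    parent_graph = nx.DiGraph()
    parent_graph.add_nodes_from(terms)
    for child, parent, rel in graph.edges(keys=True):
        if rel not in PARENT_RELATIONS:
            continue
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        parent_graph.add_edge(child, parent)
        terms[child].parent_ids.add(parent)

    for term in terms.values():
        if term.term_id in term.parent_ids:
            raise OntologyError(f"self-loop at term {term.term_id}")
    if not nx.is_directed_acyclic_graph(parent_graph):
        cycle = nx.find_cycle(parent_graph)
        raise OntologyError(f"ontology edge relation is cyclic: {cycle}")

    roots = {
        t.term_id for t in terms.values() if not t.parent_ids and not t.obsolete
    }
    return GoDag(terms=terms, roots=roots)


def parse_associations(
    path: str | Path,
    dag: GoDag | None = None,
    strict: bool = False,
) -> AnnotationMap:
    """Read gene-to-term associations into a direct :class:`AnnotationMap`.

    Accepts either two-column tab-separated text (``gene_id<TAB>term_id``)
    or GAF 2.x (gene in column 2, GO accession in column 5; ``!`` comment
    lines skipped).  Duplicate pairs are deduplicated with a logged count.
    When a ``dag`` is supplied, pairs naming unknown or obsolete terms are
    dropped with a warning (``strict=True`` raises instead); the dropped
    term ids are recorded in ``unknown_terms``.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x row
                gene, term = fields[1], fields[4]
            elif len(fields) == 2:
                gene, term = fields
            else:
                raise OntologyError(
                    f"{path}:{lineno}: expected 2 columns or a GAF row, "
                    f"got {len(fields)} fields"
                )
            if not gene or not term:
                raise OntologyError(f"{path}:{lineno}: empty gene or term id")
            pairs.append((gene, term))

    if not pairs:
        raise OntologyError(f"association file {path} contains no pairs")

    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        logger.info("deduplicated %d repeated association pairs", n_dup)

    direct: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for gene, term in set(pairs):
        if dag is not None:
            missing = term not in dag
            obsolete = (not missing) and dag[term].obsolete
            if missing or obsolete:
                if strict:
                    raise UnknownTermError(
                        f"association names {'obsolete' if obsolete else 'unknown'}"
                        f" term {term}"
                    )
                unknown.add(term)
                continue
        direct.setdefault(term, set()).add(gene)

    if unknown:
        logger.warning(
            "dropped associations to %d unknown/obsolete terms", len(unknown)
        )
    return AnnotationMap(direct=direct, unknown_terms=unknown)


def propagate(dag: GoDag, ann: AnnotationMap) -> AnnotationMap:
    """Propagate direct annotations to all ancestors (true-path rule).

    ``propagated[t]`` becomes the union of the direct gene sets of ``t``
    and every descendant of ``t``.  The operation is idempotent: feeding
    a propagated map back in returns the same map.
    """
    if ann.direct is None:
        raise ValueError("direct annotation map is required")

    prop: dict[str, set[str]] = {
        t: set(ann.direct.get(t, ())) for t in dag.terms if not dag[t].obsolete
    }
    # Children must be processed before parents; edges run child -> parent,
    # so a topological order of that graph visits children first.
    order = _topological_child_first(dag)
    for term_id in order:
        genes = prop.get(term_id)
        if not genes:
            continue
        for parent in dag[term_id].parent_ids:
            prop[parent] |= genes

    universe: set[str] = set()
    for genes in prop.values():
        universe |= genes
    return AnnotationMap(
        direct=ann.direct,
        propagated=prop,
        universe=universe,
        unknown_terms=set(ann.unknown_terms),
    )


def _topological_child_first(dag: GoDag) -> list[str]:
    graph: dict[str, set[str]] = {
        t: set() for t in dag.terms if not dag[t].obsolete
    }
    for term in dag.terms.values():
        if term.obsolete:
            continue
        for parent in term.parent_ids:
            # parent depends on child: child ordered first
            graph.setdefault(parent, set()).add(term.term_id)
    return list(TopologicalSorter(graph).static_order())


def direct_parents(dag: GoDag, term_id: str) -> set[str]:
    """Direct parents of a term via is_a/part_of; empty for roots."""
    return set(dag[term_id].parent_ids)


def filter_by_size(ann: AnnotationMap, min_size: int) -> set[str]:
    """Terms whose propagated gene set has at least ``min_size`` genes.

    This filter controls which categories are *ranked and reported*; it
    never shrinks the gene universe used in the regressions.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be a positive integer, got {min_size}")
    if ann.propagated is None:
        raise ValueError("annotations must be propagated before size filtering")
    return {t for t, genes in ann.propagated.items() if len(genes) >= min_size}


def write_annotation_tsv(
    ann: AnnotationMap, path: str | Path, which: str = "propagated"
) -> None:
    """Export an annotation map as two-column ``term_id<TAB>gene_id`` text."""
    mapping = ann.propagated if which == "propagated" else ann.direct
    if mapping is None:
        raise ValueError(f"{which} map is not filled")
    with open(path, "w") as handle:
        for term_id in sorted(mapping):
            for gene in sorted(mapping[term_id]):
                handle.write(f"{gene}\t{term_id}\n")
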