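"""GO DAG handling: OBO parsing, ancestor-closure propagation, taxon constraints.

Propagation follows standard GO annotation practice: a term entails all of
its ancestors through ``is_a`` and ``part_of`` edges (``regulates`` and other
relationships do not propagate).  Taxon constraints (*never_in_taxon* /
*only_in_taxon*) attached to a term apply to all of its descendant terms:
predicting a child term entails the constrained parent, so the violation is
inherited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

from .ogdb import TaxonomyTree

logger = logging.getLogger(__name__)

PROPAGATING_RELATIONS = ("is_a", "part_of")

NEVER_IN = "never_in_taxon"
ONLY_IN = "only_in_taxon"


class OntologyError(Exception):
    pass


class GoDag:
    """Directed acyclic graph of GO terms with is_a/part_of edges.

    ``parents`` maps child term -> set of parent terms (propagating edges
    only).  Alternate ids resolve to their primary term; obsolete terms are
    known but excluded from propagation.
    """

    def __init__(
        self,
        parents: dict[str, set[str]],
        namespaces: Optional[dict[str, str]] = None,
        alt_ids: Optional[dict[str, str]] = None,
        obsolete: Optional[set[str]] = None,
        names: Optional[dict[str, str]] = None,
    ):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self.namespaces = dict(namespaces or {})
        self.alt_ids = dict(alt_ids or {})
        self.obsolete = set(obsolete or ())
        self.names = dict(names or {})
        for term, ps in parents.items():
            for p in ps:
                if p not in self.parents:
                    raise OntologyError(f"edge {term} -> {p} points outside the term set")
        g = nx.DiGraph((child, parent) for child, ps in self.parents.items() for parent in ps)
        g.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"cycle in ontology: {cycle}")
        self._graph = g
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids

    def resolve(self, term: str) -> str:
        """Map an alternate id to its primary term id."""
        if term in self.parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown GO term: {term}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of a (primary) term via propagating edges."""
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents[term])
            while stack:
                p = stack.pop()
                if p not in out:
                    out.add(p)
                    stack.extend(self.parents[p])
            cached = frozenset(out)
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        term = self.resolve(term)
        return frozenset(nx.ancestors(self._graph, term))  # graph edges point child->parent

    def roots(self) -> set[str]:
        return {t for t in self.parents if not self.parents[t] and t not in self.obsolete}


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2 file (subset: id, name, namespace, is_a,
    relationship part_of, alt_id, is_obsolete)."""
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    parents: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    names: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        parents.setdefault(term, set())
        if "name" in data:
            names[term] = data["name"]
        if "namespace" in data:
            namespaces[term] = data["namespace"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term)
    for child, parent, key in graph.edges(keys=True):
        if key in PROPAGATING_RELATIONS and child not in obsolete:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    return GoDag(parents, namespaces, alt_ids, obsolete, names)


def write_obo(dag: GoDag, path: str | Path, part_of_edges: Optional[set[tuple[str, str]]] = None) -> None:
    """Write the DAG as a minimal OBO 1.2 file (round-trips through parse_obo).

    Edges listed in ``part_of_edges`` are emitted as ``relationship: part_of``;
    everything else as ``is_a``.
    """
    part_of_edges = part_of_edges or set()
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in dag.alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: ogmap-synthetic\n\n")
        for term in sorted(dag.parents):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            fh.write(f"namespace: {dag.namespaces.get(term, 'biological_process')}\n")
            for alt in sorted(alt_by_primary.get(term, [])):
                fh.write(f"alt_id: {alt}\n")
            for parent in sorted(dag.parents[term]):
                if (term, parent) in part_of_edges:
                    fh.write(f"relationship: part_of {parent}\n")
                else:
                    fh.write(f"is_a: {parent}\n")
            if term in dag.obsolete:
                fh.write("is_obsolete: true\n")
            fh.write("\n")


def propagate(dag: GoDag, terms: Iterable[str]) -> set[str]:
    """Ancestor closure of a term set (terms plus all is_a/part_of ancestors).

    Alternate ids are resolved first; obsolete terms are dropped with a
    warning; unknown terms raise ``KeyError``.
    """
    out: set[str] = set()
    for term in terms:
        primary = dag.resolve(term)  # KeyError on unknown terms
        if primary in dag.obsolete:
            logger.warning("dropping obsolete term %s from propagation", primary)
            continue
        out.add(primary)
        out |= dag.ancestors(primary)
    return out


@dataclass(frozen=True)
class TaxonConstraint:
    term: str
    kind: str  # never_in_taxon | only_in_taxon
    taxid: int

    def __post_init__(self) -> None:
        if self.kind not in (NEVER_IN, ONLY_IN):
            raise ValueError(f"unknown constraint kind {self.kind!r}")


def load_taxon_constraints(path: str | Path) -> list[TaxonConstraint]:
    """Read a TSV of (term, kind, taxid) rows."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, kind, taxid = line.split("\t")
            out.append(TaxonConstraint(term, kind, int(taxid)))
    return out


def write_taxon_constraints(constraints: Iterable[TaxonConstraint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(constraints, key=lambda c: (c.term, c.kind, c.taxid)):
            fh.write(f"{c.term}\t{c.kind}\t{c.taxid}\n")


def violates_taxon_constraint(
    term: str,
    query_taxid: int,
    constraints: Iterable[TaxonConstraint],
    taxonomy: TaxonomyTree,
    dag: Optional[GoDag] = None,
) -> bool:
    """True iff assigning ``term`` to a protein of ``query_taxid`` breaks a constraint.

    A constraint on a term applies to the term itself and (when a DAG is
    supplied) to all of its descendant terms: the prediction entails every
    ancestor, so constraints are looked up over the ancestor-or-self set of
    the predicted term.
    """
    applicable = {term}
    if dag is not None and term in dag:
        primary = dag.resolve(term)
        applicable = {primary} | set(dag.ancestors(primary))
    for c in constraints:
        if c.term not in applicable:
            continue
        if c.kind == NEVER_IN and taxonomy.is_descendant(query_taxid, c.taxid):
            return True
        if c.kind == ONLY_IN and not taxonomy.is_descendant(query_taxid, c.taxid):
            return True
    return False
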