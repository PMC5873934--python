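"""Ontology graphs for the five plant ontologies (GO, TO, PO, GRO, EO).

Genes are screened against controlled vocabularies: the Gene Ontology for
molecular function/process/component, the Trait Ontology for phenotypic
traits, the Plant Ontology for anatomy, the Growth Ontology for developmental
stages and the Environment Ontology for growth regimens.  Each ontology is
held as a directed acyclic graph whose edges point from a term to its
``is_a`` / ``part_of`` parents (the "true-path" relations); term sets for a
stress or attribute are seed accessions plus their full descendant closure.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

ONTOLOGY_KEYS = ("GO", "TO", "PO", "GRO", "EO")

#: relations honoured for annotation propagation and term-set closure
TRUE_PATH_RELATIONS = frozenset({"is_a", "part_of"})

_ACCESSION_RE = re.compile(r"^(GO|TO|PO|GRO|EO):\d+$")


class OntologyError(ValueError):
    """Malformed OBO input or an ontology-level validation failure."""


def accession_prefix(term_id: str) -> str:
    """Return the ontology key encoded in an accession such as ``GO:0009414``."""
    prefix, _, rest = term_id.partition(":")
    if not rest or not _ACCESSION_RE.match(term_id):
        raise OntologyError(f"not a recognised ontology accession: {term_id!r}")
    return prefix


@dataclass
class OntologyTerm:
    """A single ontology term with its true-path parent links."""

    term_id: str
    name: str = ""
    ontology_key: str = ""
    namespace: str | None = None
    #: list of (relation, parent term_id); relation in TRUE_PATH_RELATIONS
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False


class OntologyGraph:
    """A DAG of terms for one ontology.

    Internally a :class:`networkx.DiGraph` with child -> parent edges
    labelled by relation.  Obsolete terms are dropped at construction and
    dangling parent references are skipped with a warning.
    """

    def __init__(self, ontology_key: str, terms: Iterable[OntologyTerm] = ()):
        self.ontology_key = ontology_key
        self.terms: dict[str, OntologyTerm] = {}
        self._g = nx.DiGraph()
        for t in terms:
            self.add_term(t)
        self.validate()

    def add_term(self, term: OntologyTerm) -> None:
        if term.obsolete:
            logger.warning("dropping obsolete term %s", term.term_id)
            return
        self.terms[term.term_id] = term
        self._g.add_node(term.term_id)

    def _link_parents(self) -> None:
        for term in self.terms.values():
            for relation, parent in term.parents:
                if relation not in TRUE_PATH_RELATIONS:
                    continue
                if parent not in self.terms:
                    logger.warning(
                        "dangling parent %s referenced by %s; edge skipped",
                        parent, term.term_id,
                    )
                    continue
                self._g.add_edge(term.term_id, parent, relation=relation)

    def validate(self) -> None:
        self._g.remove_edges_from(list(self._g.edges))
        self._link_parents()
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise OntologyError(f"cyclic parent relation: {cycle}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def topological_order(self) -> list[str]:
        """Terms ordered parents-before-children (roots first)."""
        return list(reversed(list(nx.topological_sort(self._g))))

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r} in {self.ontology_key} graph")

    def ancestors(
        self, term_id: str, relations: frozenset[str] | set[str] = TRUE_PATH_RELATIONS
    ) -> set[str]:
        """All terms reachable upward via the given relations, excluding self."""
        self._require(term_id)
        relations = frozenset(relations)
        if relations == TRUE_PATH_RELATIONS:
            return set(nx.descendants(self._g, term_id))
        sub = self._g.edge_subgraph(
            (u, v) for u, v, rel in self._g.edges(data="relation") if rel in relations
        )
        if term_id not in sub:
            return set()
        return set(nx.descendants(sub, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All terms from which ``term_id`` is reachable (children, grandchildren, ...)."""
        self._require(term_id)
        return set(nx.ancestors(self._g, term_id))


@dataclass
class TermSet:
    """Seed accessions for one stress/attribute label plus their closure."""

    ontology_key: str
    seed_ids: list[str]
    member_ids: set[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not set(self.seed_ids) <= self.member_ids:
            raise OntologyError(f"term set {self.label!r}: seeds not in member set")


def parse_obo(stream: TextIO | str) -> dict[str, OntologyGraph]:
    """Parse OBO 1.2/1.4 flat-file text into one graph per ontology key.

    Only ``is_a`` and ``relationship: part_of`` lines become parent edges;
    every other relationship type is ignored.  Obsolete terms are dropped.
    A stanza without an ``id`` line is a parse error naming the stanza line.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    _check_stanza_ids(text)
    if not text.strip() or "[Term]" not in text:
        return {}
    net = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    terms_by_key: dict[str, list[OntologyTerm]] = {}
    for term_id, data in net.nodes(data=True):
        if not data:
            # node created only by reference from another stanza
            logger.warning("term %s referenced but never defined", term_id)
            continue
        try:
            key = accession_prefix(term_id)
        except OntologyError:
            logger.warning("skipping term with unrecognised accession %r", term_id)
            continue
        parents: list[tuple[str, str]] = [("is_a", p) for p in data.get("is_a", [])]
        for rel in data.get("relationship", []):
            rel_name, _, target = rel.partition(" ")
            if rel_name == "part_of":
                parents.append(("part_of", target.strip()))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms_by_key.setdefault(key, []).append(
            OntologyTerm(
                term_id=term_id,
                name=data.get("name", ""),
                ontology_key=key,
                namespace=data.get("namespace"),
                parents=[] if obsolete else parents,
                obsolete=obsolete,
            )
        )
    return {key: OntologyGraph(key, terms) for key, terms in terms_by_key.items()}


def _check_stanza_ids(text: str) -> None:
    """Raise if a [Term] stanza lacks an id line, naming the offending line."""
    lines = text.splitlines()
    in_term = False
    stanza_line = 0
    has_id = True
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if in_term and not has_id:
                raise OntologyError(f"[Term] stanza at line {stanza_line} has no id")
            in_term = stripped == "[Term]"
            stanza_line = lineno
            has_id = False
        elif in_term and stripped.startswith("id:"):
            has_id = True
    if in_term and not has_id:
        raise OntologyError(f"[Term] stanza at line {stanza_line} has no id")


def parse_obo_single(stream: TextIO | str, ontology_key: str) -> OntologyGraph:
    """Parse OBO text expected to contain a single ontology."""
    graphs = parse_obo(stream)
    if not graphs:
        return OntologyGraph(ontology_key)
    if set(graphs) != {ontology_key}:
        raise OntologyError(
            f"expected only {ontology_key} accessions, found {sorted(graphs)}"
        )
    return graphs[ontology_key]


def build_term_set(
    graph: OntologyGraph,
    seed_ids: Iterable[str],
    label: str = "",
    closure: bool = True,
) -> TermSet:
    """Seeds plus (by default) all of their descendants, as one term set.

    The descendant closure captures every more specific term under a seed —
    e.g. "response to desiccation" under "response to water deprivation" —
    so genes annotated only at the specific level are still collected.
    """
    seed_ids = list(seed_ids)
    members: set[str] = set()
    for seed in seed_ids:
        if accession_prefix(seed) != graph.ontology_key:
            raise OntologyError(
                f"seed {seed} does not belong to ontology {graph.ontology_key}"
            )
        if seed not in graph:
            raise KeyError(f"seed {seed} not present in {graph.ontology_key} graph")
        members.add(seed)
        if closure:
            members |= graph.descendants(seed)
    return TermSet(
        ontology_key=graph.ontology_key,
        seed_ids=seed_ids,
        member_ids=members,
        label=label,
    )


class OntologyRegistry(dict):
    """Mapping ontology_key -> OntologyGraph for the five plant ontologies."""

    def graph_for(self, term_id: str) -> OntologyGraph:
        key = accession_prefix(term_id)
        if key not in self:
            raise KeyError(f"no {key} ontology loaded (needed for {term_id})")
        return self[key]

    @classmethod
    def from_obo(cls, *streams: TextIO | str) -> "OntologyRegistry":
        reg = cls()
        for stream in streams:
            for key, graph in parse_obo(stream).items():
                if key in reg:
                    raise OntologyError(f"ontology {key} loaded twice")
                reg[key] = graph
        return reg
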