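"""Phenotype-ontology handling and Lin semantic similarity.

Parses an OBO ontology into a rooted DAG of ``is_a`` relations, computes
term information content (IC) from the annotation frequencies of a proband
cohort, and provides Lin term-term similarity together with the symmetric
best-match-average set similarity used to compare proband phenotypes.

IC is defined on a corpus of *closed* annotation sets (each proband's term
set extended with all ancestors)::

    IC(t) = -ln(n_t / N)

where ``n_t`` is the number of probands whose closed set contains ``t`` and
``N`` is the corpus size.  Terms never annotated receive a floored count of
one so that IC stays finite for arbitrary query terms.  Lin similarity of
two terms is ``2 * IC(MICA) / (IC(t1) + IC(t2))`` with the MICA being the
most-informative common ancestor (a term counts as its own ancestor here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyError",
    "OntologyStructureError",
    "UnknownTermError",
    "OntologyGraph",
    "ICTable",
    "load_obo",
    "annotation_closure",
    "read_annotations",
    "compute_ic",
    "lin_similarity",
    "set_similarity",
]

#: identifier given to the synthetic root joining multiple OBO roots
VIRTUAL_ROOT = "VIRTUAL:ROOT"


class OntologyError(ValueError):
    """Base class for ontology input problems."""


class OntologyStructureError(OntologyError):
    """The ontology violates a structural invariant (e.g. a cycle)."""


class UnknownTermError(KeyError):
    """A term id is absent from the ontology (after alt-id resolution)."""

    def __init__(self, term_ids):
        self.term_ids = sorted(term_ids) if not isinstance(term_ids, str) else [term_ids]
        super().__init__("unknown term id(s): " + ", ".join(self.term_ids))


@dataclass
class OntologyGraph:
    """Rooted DAG of phenotype terms connected by ``is_a`` edges.

    ``parents`` maps each term to its direct ``is_a`` parents; the root has
    none.  Obsolete terms are absent and alternative ids resolve to their
    primary term through :meth:`resolve`.
    """

    terms: set
    name: dict
    parents: dict
    root: str
    alt_ids: dict = field(default_factory=dict)
    _ancestor_cache: dict = field(default_factory=dict, repr=False)
    _name_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._name_index:
            self._name_index = {v: k for k, v in self.name.items()}

    # -- lookups ---------------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_ids

    def resolve(self, term_or_name: str) -> str:
        """Resolve a primary id, alt id, or exact label to a primary id."""
        if term_or_name in self.terms:
            return term_or_name
        if term_or_name in self.alt_ids:
            return self.alt_ids[term_or_name]
        if term_or_name in self._name_index:
            return self._name_index[term_or_name]
        raise UnknownTermError(term_or_name)

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term`` (excluding the term itself)."""
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set = set()
        for p in self.parents[term]:
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def ancestors_or_self(self, term: str) -> frozenset:
        term = self.resolve(term)
        return self.ancestors(term) | {term}


def load_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped, alt ids are indexed, non-``is_a`` edges are
    ignored, and multiple roots are joined under a virtual root term.
    Raises :class:`OntologyStructureError` for cyclic ``is_a`` relations and
    :class:`OntologyError` for an empty ontology.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # malformed file
        raise OntologyError(f"could not parse OBO file {path!r}: {exc}") from exc
    nodes = [n for n, d in g.nodes(data=True) if not d.get("is_obsolete")]
    if not nodes:
        raise OntologyError(f"OBO file {path!r} contains no usable terms")

    terms = set(nodes)
    names = {n: g.nodes[n].get("name", n) for n in nodes}
    alt_ids: dict = {}
    for n in nodes:
        for alt in g.nodes[n].get("alt_id", []):
            alt_ids[alt] = n

    # obonet stores edges child -> parent keyed by relation type
    parents: dict = {n: set() for n in nodes}
    for child, parent, rel in g.edges(keys=True):
        if rel != "is_a":
            continue
        if child in terms and parent in terms:
            parents[child].add(parent)

    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    dag.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise OntologyStructureError(
            f"is_a cycle detected involving term {cycle[0][0]!r}"
        )

    roots = sorted(n for n in terms if not parents[n])
    if len(roots) == 1:
        root = roots[0]
    else:
        root = VIRTUAL_ROOT
        terms.add(root)
        names[root] = "virtual root"
        parents[root] = set()
        for r in roots:
            parents[r] = {root}

    return OntologyGraph(terms=terms, name=names, parents=parents, root=root,
                         alt_ids=alt_ids)


def annotation_closure(terms: Iterable[str], g: OntologyGraph) -> set:
    """Close a term set under the ancestor relation (idempotent)."""
    terms = set(terms)
    unknown = {t for t in terms if t not in g}
    if unknown:
        raise UnknownTermError(unknown)
    out: set = set()
    for t in terms:
        out |= g.ancestors_or_self(t)
    return out


def read_annotations(path) -> dict:
    """Read a two-column (proband_id, term_id) TSV into raw term sets."""
    annotations: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OntologyError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            annotations.setdefault(fields[0], set()).add(fields[1])
    return annotations


@dataclass
class ICTable:
    """Per-term information content (nats) over a proband corpus."""

    ic: dict
    n_probands: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise UnknownTermError(term) from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def compute_ic(
    annotations: Mapping[str, set],
    g: OntologyGraph,
    extra_counts: Mapping[str, int] | None = None,
) -> ICTable:
    """Information content of every ontology term from closed annotations.

    ``annotations`` must map proband id -> *closed* term set; a set that is
    not closed raises ``ValueError``.  ``extra_counts`` optionally supplies
    an external term-frequency table added on top of the cohort counts
    (with its total folded into ``N``).
    """
    if not annotations:
        raise OntologyError("IC requires at least one annotated proband")
    for pid, ts in annotations.items():
        closed = annotation_closure(ts, g)
        if closed != set(ts):
            raise ValueError(
                f"annotation set for proband {pid!r} is not closed under ancestors"
            )

    n = len(annotations)
    counts = {t: 0 for t in g.terms}
    for ts in annotations.values():
        for t in ts:
            counts[g.resolve(t)] += 1
    if extra_counts:
        n += max(extra_counts.values(), default=0)
        for t, c in extra_counts.items():
            counts[g.resolve(t)] += c

    ic = {}
    for t in g.terms:
        c = counts[t] if counts[t] > 0 else 1  # zero-frequency floor
        ic[t] = -math.log(c / n) if c < n else 0.0
    ic[g.root] = 0.0
    return ICTable(ic=ic, n_probands=n)


def _mica_ic(t1: str, t2: str, ic: ICTable, g: OntologyGraph) -> float:
    common = g.ancestors_or_self(t1) & g.ancestors_or_self(t2)
    if not common:
        return 0.0
    return max(ic[t] for t in common)


def lin_similarity(t1: str, t2: str, ic: ICTable, g: OntologyGraph) -> float:
    """Lin similarity ``2*IC(MICA) / (IC(t1) + IC(t2))`` in [0, 1].

    Identity is defined as 1 even for zero-IC terms; distinct terms whose
    only common ancestry carries zero IC score 0.
    """
    t1, t2 = g.resolve(t1), g.resolve(t2)
    if t1 == t2:
        return 1.0
    denom = ic[t1] + ic[t2]
    if denom <= 0.0:
        return 0.0
    value = 2.0 * _mica_ic(t1, t2, ic, g) / denom
    return min(max(value, 0.0), 1.0)


def set_similarity(a: Iterable[str], b: Iterable[str], ic: ICTable,
                   g: OntologyGraph) -> float:
    """Symmetric best-match-average similarity of two term sets.

    ``sym(a, b) = 0.5 * (mean_x max_y Lin(x, y) + mean_y max_x Lin(x, y))``
    """
    a = [g.resolve(t) for t in a]
    b = [g.resolve(t) for t in b]
    if not a or not b:
        raise OntologyError("set similarity requires two non-empty term sets")
    lin = {}
    for x in set(a):
        for y in set(b):
            lin[(x, y)] = lin_similarity(x, y, ic, g)
    fwd = sum(max(lin[(x, y)] for y in set(b)) for x in set(a)) / len(set(a))
    rev = sum(max(lin[(x, y)] for x in set(a)) for y in set(b)) / len(set(b))
    return 0.5 * (fwd + rev)
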