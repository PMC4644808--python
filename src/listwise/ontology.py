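"""Ontology handling: OBO parsing, ancestor closure and annotation propagation.

Genes are annotated to the most specific ontology term that applies; because
an annotation to a term implies all of its more general ancestors, gene
annotations are propagated upwards over ``is_a`` and ``part_of`` edges before
terms are turned into binary features.  ``regulates``-type relations are
deliberately not traversed (the standard propagation relations for GO-style
enrichment are ``is_a`` and ``part_of``).

Terms propagated to fewer than ``min_genes`` genes (default 2) are not
emitted as features: a category carried by a single gene can never be
meaningfully enriched.
"""

from __future__ import annotations

import io as _io
import os
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

from .core import DataType, FeatureMeta, FeatureTable, Theme

#: Relations traversed during ancestor closure / propagation.
PROPAGATION_RELATIONS = ("is_a", "part_of")

#: OBO namespace -> display theme for emitted term features.
NAMESPACE_THEMES: dict[str, Theme] = {
    "biological_process": Theme.GO_BP,
    "molecular_function": Theme.GO_MF,
    "cellular_component": Theme.GO_CC,
    "fission_yeast_phenotype": Theme.PHENOTYPES,
    "phenotype": Theme.PHENOTYPES,
}


@dataclass
class Ontology:
    """A parsed ontology: terms, labels, parent edges and obsolete ids.

    ``parents[t]`` is the set of ``(parent_id, relation)`` pairs for the
    traversed relations only.  ``alt_ids`` maps secondary ids to canonical
    ones; :meth:`resolve` applies that mapping.
    """

    terms: set[str]
    names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._anc_cache: dict[str, frozenset[str]] = {}

    def resolve(self, term: str) -> str:
        """Map an alt_id to its canonical term id (identity for primary ids)."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.terms

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` over is_a/part_of, excluding itself.

        Raises ``KeyError`` for unknown terms.  Memoized; safe to call
        repeatedly during propagation.
        """
        term = self.resolve(term)
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        return set(self._ancestors_cached(term))

    def _ancestors_cached(self, term: str) -> frozenset[str]:
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        # iterative post-order so deep ontologies do not hit recursion limits
        order: list[str] = []
        stack: list[tuple[str, bool]] = [(term, False)]
        on_path: set[str] = set()
        seen: set[str] = set()
        while stack:
            node, expanded = stack.pop()
            if expanded:
                on_path.discard(node)
                order.append(node)
                continue
            if node in self._anc_cache or node in seen:
                continue
            if node in on_path:
                raise ValueError(f"cycle in ontology involving {node!r}")
            on_path.add(node)
            seen.add(node)
            stack.append((node, True))
            for parent, _rel in self.parents.get(node, ()):
                stack.append((parent, False))
        for node in order:
            anc: set[str] = set()
            for parent, _rel in self.parents.get(node, ()):
                anc.add(parent)
                anc.update(self._anc_cache[parent])
            self._anc_cache[node] = frozenset(anc)
        return self._anc_cache[term]


def parse_obo(source: str | os.PathLike | TextIO) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    ``source`` may be a path, an open text handle, or the raw OBO text
    itself (detected by embedded newlines).  Obsolete terms are retained in
    ``obsolete`` but carry no parent edges.  A cyclic is_a/part_of graph is
    an error naming one cycle.
    """
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=False)

    onto = Ontology(terms=set())
    for term, data in graph.nodes(data=True):
        onto.terms.add(term)
        if "name" in data:
            onto.names[term] = data["name"]
        if "namespace" in data:
            onto.namespaces[term] = data["namespace"]
        if str(data.get("is_obsolete", "")).lower() == "true":
            onto.obsolete.add(term)
        for alt in data.get("alt_id", []):
            onto.alt_ids[alt] = term
    # obonet edges run child -> parent, keyed by relation
    check = nx.DiGraph()
    for child, parent, rel in graph.edges(keys=True):
        if rel not in PROPAGATION_RELATIONS:
            continue
        if child in onto.obsolete or parent in onto.obsolete:
            continue
        onto.parents.setdefault(child, set()).add((parent, rel))
        check.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(check):
        cycle = nx.find_cycle(check)
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"cyclic ontology graph: {path}")
    return onto


@dataclass
class AnnotationSet:
    """Direct gene annotations plus their closure over ancestor terms."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]


def propagate(
    ontology: Ontology, direct: Mapping[str, Iterable[str]]
) -> AnnotationSet:
    """Propagate direct term->genes annotations to all ancestor terms.

    ``propagated[t]`` is the union of the direct annotations of ``t`` and of
    every descendant of ``t``.  Annotations to obsolete terms are skipped
    with a warning; unknown terms raise ``KeyError``.
    """
    resolved: dict[str, set[str]] = {}
    for term, genes in direct.items():
        canonical = ontology.resolve(term)
        if canonical not in ontology.terms:
            raise KeyError(f"annotation to unknown term {term!r}")
        if canonical in ontology.obsolete:
            _warnings.warn(
                f"skipping annotation to obsolete term {term!r}", stacklevel=2
            )
            continue
        resolved.setdefault(canonical, set()).update(genes)

    prop: dict[str, set[str]] = {}
    for term, genes in resolved.items():
        prop.setdefault(term, set()).update(genes)
        for anc in ontology.ancestors(term):
            prop.setdefault(anc, set()).update(genes)
    return AnnotationSet(
        direct={t: frozenset(g) for t, g in resolved.items()},
        propagated={t: frozenset(g) for t, g in prop.items()},
    )


def terms_to_binary_features(
    ann: AnnotationSet,
    ontology: Ontology,
    min_genes: int = 2,
    fallback_theme: Theme = Theme.PHENOTYPES,
    source: str = "",
) -> FeatureTable:
    """Turn propagated term annotations into one binary feature per term.

    Terms whose propagated gene set holds fewer than ``min_genes`` genes are
    excluded.  The theme is derived from the term's OBO namespace where
    recognized (biological_process -> GO_BP etc.), else ``fallback_theme``.
    """
    table = FeatureTable()
    for term in sorted(ann.propagated):
        genes = ann.propagated[term]
        if len(genes) < min_genes:
            continue
        theme = NAMESPACE_THEMES.get(
            ontology.namespaces.get(term, ""), fallback_theme
        )
        meta = FeatureMeta(
            feature_id=term,
            name=ontology.names.get(term, term),
            theme=theme,
            data_type=DataType.BINARY,
            source=source or theme.value,
        )
        table.add_binary(meta, genes)
    return table


def read_gaf(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GAF 2.x annotation file into term -> gene-id sets.

    Column 2 is the gene id, column 5 the term id (1-based, tab-delimited);
    rows whose qualifier (column 4) contains ``NOT`` are skipped, as are
    ``!`` comment lines.
    """
    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise ValueError(f"GAF line with <5 columns: {line!r}")
            gene, qualifier, term = cols[1], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            direct.setdefault(term, set()).add(gene)
    return direct


def read_phaf(
    path: str | os.PathLike, gene_col: int = 1, term_col: int = 2
) -> dict[str, set[str]]:
    """Read a PHAF-style phenotype annotation file into term -> gene sets.

    Only the gene-id and term-id columns are used (0-based indices,
    configurable); ``#`` header/comment lines are skipped.
    """
    direct: dict[str, set[str]] = {}
    needed = max(gene_col, term_col) + 1
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < needed:
                raise ValueError(f"PHAF line with <{needed} columns: {line!r}")
            direct.setdefault(cols[term_col], set()).add(cols[gene_col])
    return direct
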