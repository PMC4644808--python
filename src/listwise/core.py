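"""Core data model: feature databases, query lists and backgrounds.

A feature database holds three kinds of per-gene information:

* **binary features** -- gene sets representing membership in a biological
  category (an ontology term, a phenotype, a published gene list);
* **metric features** -- sparse continuous per-gene quantities (transcript
  copy number, isoelectric point, ...); a gene absent from a metric feature
  has *no value*, which is never the same as zero;
* **pairwise features** -- undirected gene--gene relations such as physical
  or genetic interactions, held in :class:`InteractionNetwork`.

Binary and metric features live together in a :class:`FeatureTable`; each
feature carries a :class:`FeatureMeta` with a display *theme* and a source
string.  Themes only group the report for reading -- they never change how
any statistic is computed.

Gene identifiers are opaque, case-sensitive strings throughout.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Theme(str, Enum):
    """Display grouping of features into biological aspects."""

    GO_BP = "GO_BP"
    GO_MF = "GO_MF"
    GO_CC = "GO_CC"
    GENE_EXPRESSION = "GeneExpression"
    GENE_FEATURES = "GeneFeatures"
    INTERACTIONS = "Interactions"
    PHENOTYPES = "Phenotypes"
    PHENOTYPIC_PROFILES = "PhenotypicProfiles"
    PROTEIN_DOMAINS = "ProteinDomains"
    PROTEIN_FEATURES = "ProteinFeatures"
    PROTEIN_LOCALIZATIONS = "ProteinLocalizations"
    TRANSCRIPT_FEATURES = "TranscriptFeatures"
    USER_DEFINED = "UserDefined"


#: The three GO themes, selected jointly via the ``go_category`` run option.
GO_THEMES = frozenset({Theme.GO_BP, Theme.GO_MF, Theme.GO_CC})


class DataType(str, Enum):
    BINARY = "binary"
    METRIC = "metric"
    PAIRWISE = "pairwise"


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata: identity, display theme, data type and source."""

    feature_id: str
    name: str
    theme: Theme
    data_type: DataType
    source: str = ""


@dataclass
class FeatureTable:
    """Genes x features container for binary and metric features.

    ``binary`` maps feature id -> member gene set (membership means value 1,
    absence value 0).  ``metric`` maps feature id -> {gene -> value}; genes
    missing from the inner map have no value for that feature.
    """

    genes: list[str] = field(default_factory=list)
    binary: dict[str, frozenset[str]] = field(default_factory=dict)
    metric: dict[str, dict[str, float]] = field(default_factory=dict)
    meta: dict[str, FeatureMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._gene_set = set(self.genes)

    @property
    def gene_set(self) -> set[str]:
        return self._gene_set

    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta)

    @property
    def n_features(self) -> int:
        return len(self.meta)

    def _register_genes(self, gene_ids: Iterable[str]) -> None:
        for g in gene_ids:
            if g not in self._gene_set:
                self._gene_set.add(g)
                self.genes.append(g)

    def _check_new_id(self, feature_id: str) -> None:
        if feature_id in self.meta:
            raise ValueError(f"duplicate feature_id {feature_id!r}")

    def add_binary(self, meta: FeatureMeta, members: Iterable[str]) -> None:
        if meta.data_type is not DataType.BINARY:
            raise ValueError(f"{meta.feature_id!r}: data_type must be binary")
        self._check_new_id(meta.feature_id)
        members = frozenset(members)
        self._register_genes(sorted(members))
        self.binary[meta.feature_id] = members
        self.meta[meta.feature_id] = meta

    def add_metric(self, meta: FeatureMeta, values: Mapping[str, float]) -> None:
        if meta.data_type is not DataType.METRIC:
            raise ValueError(f"{meta.feature_id!r}: data_type must be metric")
        self._check_new_id(meta.feature_id)
        values = {g: float(v) for g, v in values.items()}
        self._register_genes(sorted(values))
        self.metric[meta.feature_id] = values
        self.meta[meta.feature_id] = meta


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected set of gene--gene pairs (pairwise data type).

    Each pair is stored once as a sorted 2-tuple; self-loops are excluded
    (the count of dropped loops is retained for reporting).
    """

    kind: str  # "physical" or "genetic"
    edges: frozenset[tuple[str, str]]
    name: str = ""
    source: str = ""
    self_loops_dropped: int = 0

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        kind: str,
        name: str | None = None,
        source: str = "",
    ) -> "InteractionNetwork":
        edges: set[tuple[str, str]] = set()
        loops = 0
        for a, b in pairs:
            if a == b:
                loops += 1
                continue
            edges.add((a, b) if a <= b else (b, a))
        return cls(
            kind=kind,
            edges=frozenset(edges),
            name=name if name is not None else f"interactions_{kind}",
            source=source,
            self_loops_dropped=loops,
        )

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass(frozen=True)
class Background:
    """The reference gene universe against which all statistics are computed."""

    genes: frozenset[str]
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


#: Pre-set background labels supported by the run configuration.
BACKGROUND_LABELS = (
    "protein_coding",
    "all_annotated",
    "ncRNA",
    "go_annotated",
    "phenotype_annotated",
    "non_essential",
    "custom",
)


@dataclass(frozen=True)
class QueryList:
    """A validated query gene list (the list *A* under test).

    ``dropped`` records identifiers removed during validation together with
    the reason; ``warnings`` carries soft diagnostics such as the small-list
    notice emitted for fewer than 10 retained genes.
    """

    genes: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def is_small(self) -> bool:
        return len(self.genes) < 10


def validate_query(
    raw_ids: Sequence[str] | QueryList, background: Background
) -> QueryList:
    """Deduplicate a raw identifier list and restrict it to the background.

    Identifiers absent from ``background`` are moved to ``dropped`` with
    reason ``"not_in_background"``.  Order of first appearance is preserved.
    A warning is attached (and emitted) when fewer than 10 genes remain.

    Raises ``ValueError`` when the input is empty or when every identifier
    was dropped.
    """
    if isinstance(raw_ids, QueryList):
        raw_ids = list(raw_ids.genes)
    if not raw_ids:
        raise ValueError("empty query list")
    seen: set[str] = set()
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for g in raw_ids:
        if g in seen:
            continue
        seen.add(g)
        if g in background.genes:
            kept.append(g)
        else:
            dropped.append((g, "not_in_background"))
    if not kept:
        raise ValueError("empty query after validation")
    warns: list[str] = []
    if len(kept) < 10:
        msg = f"small gene list: {len(kept)} genes (below 10)"
        warns.append(msg)
        _warnings.warn(msg, stacklevel=2)
    return QueryList(genes=tuple(kept), dropped=tuple(dropped), warnings=tuple(warns))


@dataclass
class Database:
    """A fully assembled database: one merged feature table, the pairwise
    networks, and named background gene universes."""

    table: FeatureTable
    networks: list[InteractionNetwork] = field(default_factory=list)
    backgrounds: dict[str, frozenset[str]] = field(default_factory=dict)

    def background(self, label: str) -> Background:
        if label in self.backgrounds:
            return Background(self.backgrounds[label], label)
        if label == "all_annotated":
            return Background(frozenset(self.table.genes), label)
        raise KeyError(f"unknown background label {label!r}")


def assemble_database(
    tables: Sequence[FeatureTable],
    networks: Sequence[InteractionNetwork] = (),
    backgrounds: Mapping[str, Iterable[str]] | None = None,
) -> Database:
    """Merge feature tables into a single table and bundle the networks.

    Feature ids must be disjoint across the input tables; a collision raises
    ``ValueError`` naming the offending id.  The merged gene order is the
    sorted union, so downstream reports are reproducible.
    """
    merged = FeatureTable()
    all_genes: set[str] = set()
    for t in tables:
        all_genes.update(t.genes)
    merged._register_genes(sorted(all_genes))
    for t in tables:
        for fid, meta in t.meta.items():
            if fid in merged.meta:
                raise ValueError(f"duplicate feature_id {fid!r} across tables")
            if meta.data_type is DataType.BINARY:
                merged.binary[fid] = t.binary[fid]
            else:
                merged.metric[fid] = dict(t.metric[fid])
            merged.meta[fid] = meta
    bgs = {
        label: frozenset(genes) for label, genes in (backgrounds or {}).items()
    }
    return Database(table=merged, networks=list(networks), backgrounds=bgs)
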