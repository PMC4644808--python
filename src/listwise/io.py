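"""Readers and writers for the plain-text exchange formats.

Formats handled: one-id-per-line gene lists, GMT-like tab-delimited gene
sets (set name followed by member ids), BioGRID-tab-style interaction files
(two interactor columns, configurable), feature tables in the tabular
layout with optional metadata rows (Feature name / Feature group /
Data type / Source) above the per-gene rows, a tab-delimited results
report, and a manifest-driven database directory.
"""

from __future__ import annotations

import csv
import json
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import ontology as _ontology
from .core import (
    Database,
    DataType,
    FeatureMeta,
    FeatureTable,
    InteractionNetwork,
    Theme,
    assemble_database,
)

_METADATA_ROWS = {"feature name", "feature group", "data type", "source"}


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a gene list: one id per line, ``#`` comments and blanks skipped."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            ids.append(s)
    if not ids:
        raise ValueError(f"empty gene list: {path}")
    return ids


def write_gene_list(ids: Iterable[str], path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in ids), encoding="utf-8")


def read_gene_sets_tab(
    path: str | os.PathLike,
    theme: Theme = Theme.USER_DEFINED,
    source: str = "user",
) -> FeatureTable:
    """Read GMT-like gene sets: ``set_name<TAB>gene1<TAB>gene2...`` per line.

    Each line becomes one binary feature. Duplicate set names are an error.
    """
    table = FeatureTable()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            name, members = cols[0], [c for c in cols[1:] if c]
            if name in table.meta:
                raise ValueError(f"duplicate set name {name!r} in {path}")
            meta = FeatureMeta(
                feature_id=name,
                name=name,
                theme=theme,
                data_type=DataType.BINARY,
                source=source,
            )
            table.add_binary(meta, members)
    return table


def write_gene_sets_tab(table: FeatureTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid in table.binary:
            fh.write("\t".join([fid, *sorted(table.binary[fid])]) + "\n")


def read_interactions_tab(
    path: str | os.PathLike,
    kind: str,
    columns: tuple[int, int] = (0, 1),
    name: str | None = None,
    source: str = "",
) -> InteractionNetwork:
    """Read a tab-delimited interaction file into an undirected network.

    ``columns`` gives the 0-based indices of the two interactor columns
    (defaults match the BioGRID tab format, interactors first). Duplicate
    and reversed pairs collapse to one edge; self-loops are dropped and
    counted.
    """
    ca, cb = columns
    needed = max(ca, cb) + 1
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < needed:
                raise ValueError(
                    f"interaction line with <{needed} columns: {line!r}"
                )
            pairs.append((cols[ca], cols[cb]))
    return InteractionNetwork.from_pairs(pairs, kind=kind, name=name, source=source)


def write_interactions_tab(
    network: InteractionNetwork, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def theme_from_label(label: str, default: Theme = Theme.GENE_FEATURES) -> Theme:
    """Map a free-text feature-group label to a :class:`Theme`.

    Accepts enum values verbatim and common spellings such as
    ``"GO Biological Process"`` or ``"Phenotypes (FYPO)"``.
    """
    try:
        return Theme(label)
    except ValueError:
        pass
    norm = re.sub(r"\(.*?\)", "", label).strip().lower()
    norm = re.sub(r"\s+", " ", norm)
    aliases = {
        "go biological process": Theme.GO_BP,
        "go molecular function": Theme.GO_MF,
        "go cellular component": Theme.GO_CC,
        "gene expression": Theme.GENE_EXPRESSION,
        "gene features": Theme.GENE_FEATURES,
        "genetic and physical interactions": Theme.INTERACTIONS,
        "interactions": Theme.INTERACTIONS,
        "phenotypes": Theme.PHENOTYPES,
        "phenotypic profiles": Theme.PHENOTYPIC_PROFILES,
        "protein domains": Theme.PROTEIN_DOMAINS,
        "protein features": Theme.PROTEIN_FEATURES,
        "protein localizations": Theme.PROTEIN_LOCALIZATIONS,
        "transcript features": Theme.TRANSCRIPT_FEATURES,
        "user defined": Theme.USER_DEFINED,
    }
    return aliases.get(norm, default)


def read_metric_table(
    path: str | os.PathLike,
    default_theme: Theme = Theme.GENE_FEATURES,
    source: str = "",
) -> FeatureTable:
    """Read a tabular feature file: header of feature ids, gene rows.

    The first column holds gene ids; empty cells are missing values.  Up to
    four optional metadata rows may follow the header, recognized by their
    first cell ("Feature name", "Feature group", "Data type", "Source");
    a Data type of categorical/binary turns that column into a binary
    feature (cell value 1 = member).  A non-numeric, non-empty data cell is
    an error reporting its row and column.
    """
    with open(path, encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"empty feature table: {path}")
    header = rows[0]
    fids = header[1:]
    names = dict(zip(fids, fids))
    groups: dict[str, str] = {}
    dtypes: dict[str, str] = {}
    sources: dict[str, str] = {fid: source for fid in fids}
    data_start = 1
    for row in rows[1:]:
        label = row[0].strip().lower() if row else ""
        if label not in _METADATA_ROWS:
            break
        data_start += 1
        vals = dict(zip(fids, row[1:]))
        if label == "feature name":
            names.update(vals)
        elif label == "feature group":
            groups.update(vals)
        elif label == "data type":
            dtypes.update(vals)
        elif label == "source":
            sources.update(vals)

    metric: dict[str, dict[str, float]] = {fid: {} for fid in fids}
    genes: list[str] = []
    for r, row in enumerate(rows[data_start:], start=data_start + 1):
        if not row or not row[0].strip():
            continue
        gene = row[0].strip()
        genes.append(gene)
        for c, fid in enumerate(fids, start=1):
            cell = row[c].strip() if c < len(row) else ""
            if not cell:
                continue
            try:
                metric[fid][gene] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {r}, column {c + 1} "
                    f"of {path}"
                ) from None

    table = FeatureTable()
    table._register_genes(genes)
    for fid in fids:
        theme = theme_from_label(groups.get(fid, ""), default_theme)
        binary = "binary" in dtypes.get(fid, "").lower() or "categor" in dtypes.get(
            fid, ""
        ).lower()
        meta = FeatureMeta(
            feature_id=fid,
            name=names.get(fid, fid),
            theme=theme,
            data_type=DataType.BINARY if binary else DataType.METRIC,
            source=sources.get(fid, source),
        )
        if binary:
            members = {g for g, v in metric[fid].items() if v == 1}
            table.add_binary(meta, members)
        else:
            table.add_metric(meta, metric[fid])
    return table


def write_metric_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write binary+metric features in the tabular layout with metadata rows."""
    fids = list(table.meta)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Feature ID", *fids])
        w.writerow(["Feature name", *[table.meta[f].name for f in fids]])
        w.writerow(["Feature group", *[table.meta[f].theme.value for f in fids]])
        w.writerow(
            [
                "Data type",
                *[
                    "Categorical/Binary"
                    if table.meta[f].data_type is DataType.BINARY
                    else "Metric"
                    for f in fids
                ],
            ]
        )
        w.writerow(["Source", *[table.meta[f].source for f in fids]])
        for gene in table.genes:
            row = [gene]
            for fid in fids:
                if table.meta[fid].data_type is DataType.BINARY:
                    row.append("1" if gene in table.binary[fid] else "0")
                else:
                    v = table.metric[fid].get(gene)
                    row.append("" if v is None else format(v, ".6g"))
            w.writerow(row)


@dataclass(frozen=True)
class ReportRow:
    """One significant feature in the results report."""

    theme: Theme
    feature_id: str
    feature_name: str
    source: str
    direction: str  # "over" | "under"
    raw_p: float
    corrected_p: float
    observed: float  # overlap count (categorical) or query mean (metric)
    expected: float  # expected overlap or background mean
    overlap_genes: tuple[str, ...] = ()  # categorical only
    n_interactions: int | None = None  # pairwise only


REPORT_COLUMNS = (
    "theme",
    "feature_id",
    "feature_name",
    "source",
    "direction",
    "raw_p",
    "corrected_p",
    "observed",
    "expected",
    "overlap_genes",
    "n_interactions",
)

_THEME_ORDER = {t: i for i, t in enumerate(Theme)}


def sort_report_rows(rows: Sequence[ReportRow]) -> list[ReportRow]:
    """Group rows by theme and rank by ascending raw p within each theme."""
    return sorted(
        rows, key=lambda r: (_THEME_ORDER[r.theme], r.raw_p, r.feature_id)
    )


def write_report(rows: Sequence[ReportRow], path: str | os.PathLike) -> None:
    """Write the tab-delimited report: header plus one line per significant
    feature, themes grouped and ranked by raw p-value."""
    rows = sort_report_rows(rows)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.theme.value,
                        r.feature_id,
                        r.feature_name,
                        r.source,
                        r.direction,
                        format(r.raw_p, ".6g"),
                        format(r.corrected_p, ".6g"),
                        format(r.observed, ".6g"),
                        format(r.expected, ".6g"),
                        ",".join(r.overlap_genes),
                        "" if r.n_interactions is None else str(r.n_interactions),
                    ]
                )
                + "\n"
            )


def read_report(path: str | os.PathLike) -> list[ReportRow]:
    rows: list[ReportRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise ValueError(f"unexpected report header in {path}")
        for line in fh:
            c = line.rstrip("\n").split("\t")
            rows.append(
                ReportRow(
                    theme=Theme(c[0]),
                    feature_id=c[1],
                    feature_name=c[2],
                    source=c[3],
                    direction=c[4],
                    raw_p=float(c[5]),
                    corrected_p=float(c[6]),
                    observed=float(c[7]),
                    expected=float(c[8]),
                    overlap_genes=tuple(g for g in c[9].split(",") if g),
                    n_interactions=None if c[10] == "" else int(c[10]),
                )
            )
    return rows


def load_database(db_dir: str | os.PathLike) -> Database:
    """Load a database directory described by its ``manifest.json``.

    The manifest may name an ontology block (OBO + GAF/PHAF annotation
    files), gene-set files with a theme, tabular feature files, interaction
    files with a kind, and background gene-list files keyed by label.
    """
    db_dir = Path(db_dir)
    manifest = json.loads((db_dir / "manifest.json").read_text())
    tables: list[FeatureTable] = []

    onto_cfg = manifest.get("ontology")
    if onto_cfg:
        onto = _ontology.parse_obo(db_dir / onto_cfg["obo"])
        direct: dict[str, set[str]] = {}
        if "gaf" in onto_cfg:
            for term, genes in _ontology.read_gaf(db_dir / onto_cfg["gaf"]).items():
                direct.setdefault(term, set()).update(genes)
        if "phaf" in onto_cfg:
            for term, genes in _ontology.read_phaf(
                db_dir / onto_cfg["phaf"]
            ).items():
                direct.setdefault(term, set()).update(genes)
        ann = _ontology.propagate(onto, direct)
        tables.append(
            _ontology.terms_to_binary_features(
                ann, onto, min_genes=int(onto_cfg.get("min_genes", 2))
            )
        )

    for entry in manifest.get("gene_sets", []):
        tables.append(
            read_gene_sets_tab(
                db_dir / entry["path"],
                theme=Theme(entry.get("theme", "UserDefined")),
                source=entry.get("source", ""),
            )
        )
    for entry in manifest.get("metric_tables", []):
        tables.append(
            read_metric_table(
                db_dir / entry["path"],
                default_theme=Theme(entry.get("theme", "GeneFeatures")),
                source=entry.get("source", ""),
            )
        )
    networks = [
        read_interactions_tab(
            db_dir / entry["path"],
            kind=entry["kind"],
            columns=tuple(entry.get("columns", (0, 1))),
            name=entry.get("name"),
            source=entry.get("source", ""),
        )
        for entry in manifest.get("interactions", [])
    ]
    backgrounds = {
        label: set(read_gene_list(db_dir / rel))
        for label, rel in manifest.get("backgrounds", {}).items()
    }
    db = assemble_database(tables, networks, backgrounds)
    if "genes" in manifest:
        db.table._register_genes(read_gene_list(db_dir / manifest["genes"]))
    return db
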