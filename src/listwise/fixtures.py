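"""Seedable synthetic databases with planted enrichment signal.

The generator builds toy databases -- an ontology with propagated
annotations, binary gene sets, metric features, interaction networks and
background lists -- entirely in memory, and can write them to disk in every
exchange dialect the readers understand.  Signal is planted relative to a
query *template* Q:

* a planted binary feature shares a stated fraction of Q's genes;
* a planted metric feature shifts the values of Q's genes by a stated
  number of standard deviations;
* a planted pairwise effect adds a stated number of interaction edges
  within Q.

Null binary features are uniform random gene sets; null metric features
are i.i.d. standard normal values (the rank-sum test is distribution-free,
so the normal choice is a convenience, not an assumption).  Everything is
deterministic under the spec seed.

:func:`fdr_calibration` uses replicate planted databases to measure the
realized false-discovery proportion of the Benjamini-Hochberg procedure.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .core import (
    Background,
    Database,
    DataType,
    FeatureMeta,
    FeatureTable,
    InteractionNetwork,
    Theme,
    assemble_database,
    validate_query,
)
from .engine import RunConfig, run_enrichment
from .ontology import parse_obo, propagate, read_gaf, terms_to_binary_features


@dataclass(frozen=True)
class PlantedEffect:
    """One planted signal: ``data_type`` in {binary, metric, pairwise}.

    ``effect`` means: binary -- fraction of the query template contained in
    the feature; metric -- mean shift of query genes in units of the null
    standard deviation; pairwise -- number of extra edges added within the
    template.
    """

    data_type: str
    effect: float
    size: int = 50  # binary feature size (genes); ignored otherwise

    def __post_init__(self) -> None:
        if self.data_type not in ("binary", "metric", "pairwise"):
            raise ValueError(f"unknown planted data_type {self.data_type!r}")
        if not math.isfinite(self.effect):
            raise ValueError("effect must be finite")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic database."""

    n_genes: int = 500
    n_null_binary: int = 200
    n_null_metric: int = 10
    planted: tuple[PlantedEffect, ...] = ()
    ontology_depth: int = 3
    seed: int = 0
    query_size: int = 50
    set_size: tuple[int, int] = (10, 50)  # null binary set-size range
    n_null_edges: int = 100  # random interaction edges
    n_ontology_terms: int = 15
    n_ontology_annotations: int = 40

    def __post_init__(self) -> None:
        if self.n_genes < 20:
            raise ValueError("n_genes must be at least 20")
        if not 0 < self.query_size <= self.n_genes:
            raise ValueError("query_size must lie in (0, n_genes]")


@dataclass
class Fixture:
    """A generated database plus the planted ground truth."""

    spec: FixtureSpec
    database: Database
    genes: tuple[str, ...]
    query_template: tuple[str, ...]
    planted_binary: tuple[str, ...] = ()
    planted_metric: tuple[str, ...] = ()
    planted_pairwise: tuple[str, ...] = ()
    out_dir: Path | None = None


def _random_obo(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """A random DAG ontology of the stated depth as OBO text."""
    n = spec.n_ontology_terms
    depth = max(1, spec.ontology_depth)
    levels = [min(i * n // depth, n - 1) for i in range(depth)] + [n]
    lines = ["format-version: 1.2", "ontology: toy", ""]
    level_of = {}
    for lvl in range(depth):
        for i in range(levels[lvl], levels[lvl + 1] if lvl + 1 < len(levels) else n):
            level_of[i] = lvl
    for i in range(n):
        term = f"TOY:{i:07d}"
        lines += [f"[Term]", f"id: {term}", f"name: toy term {i}",
                  "namespace: biological_process"]
        lvl = level_of.get(i, 0)
        prev = [j for j, l in level_of.items() if l == lvl - 1]
        if prev:
            for j in rng.choice(prev, size=min(len(prev), int(rng.integers(1, 3))),
                                replace=False):
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                parent = f"TOY:{int(j):07d}"
                if rel == "is_a":
                    lines.append(f"is_a: {parent} ! toy term {j}")
                else:
                    lines.append(f"relationship: part_of {parent} ! toy term {j}")
        lines.append("")
    return "\n".join(lines)


def _gaf_text(direct: dict[str, list[str]]) -> str:
    rows = []
    for term in sorted(direct):
        for gene in sorted(direct[term]):
            rows.append(
                "\t".join(
                    ["TOY", gene, gene, "", term, "TOY:ref", "IDA", "", "P",
                     "", "", "gene", "taxon:4896", "20150101", "TOY"]
                )
            )
    return "!gaf-version: 2.1\n" + "\n".join(rows) + ("\n" if rows else "")


def generate_database(
    spec: FixtureSpec, out_dir: str | os.PathLike | None = None
) -> Fixture:
    """Generate a synthetic database; optionally write it to ``out_dir``.

    The on-disk form exercises every reader dialect (OBO + GAF, gene-set
    tab files, tabular metric files, interaction files, background lists)
    plus a ``manifest.json`` recording the spec and seed; the same seed
    always yields byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    genes = tuple(f"g{i:04d}" for i in range(spec.n_genes))
    gene_arr = np.array(genes)
    template = tuple(
        sorted(rng.choice(gene_arr, size=spec.query_size, replace=False))
    )
    tset = set(template)
    others = np.array([g for g in genes if g not in tset])

    tables: list[FeatureTable] = []

    # --- ontology + annotations -> propagated binary term features
    obo_text = gaf_direct = None
    if spec.ontology_depth > 0 and spec.n_ontology_terms > 0:
        obo_text = _random_obo(spec, rng)
        onto = parse_obo(obo_text)
        annotatable = sorted(onto.terms)
        gaf_direct = {}
        for _ in range(spec.n_ontology_annotations):
            term = annotatable[int(rng.integers(len(annotatable)))]
            gene = genes[int(rng.integers(spec.n_genes))]
            gaf_direct.setdefault(term, []).append(gene)
        ann = propagate(onto, {t: set(g) for t, g in gaf_direct.items()})
        tables.append(
            terms_to_binary_features(ann, onto, min_genes=2, source="synthetic")
        )

    # --- planted features
    sets_table = FeatureTable()
    metric_table = FeatureTable()
    planted_binary: list[str] = []
    planted_metric: list[str] = []
    planted_edges: list[tuple[str, str]] = []
    planted_pairwise: list[str] = []
    for i, eff in enumerate(spec.planted):
        if eff.data_type == "binary":
            overlap = int(round(eff.effect * spec.query_size))
            outside = eff.size - overlap
            if not (0 <= overlap <= min(eff.size, spec.query_size)) or outside > len(
                others
            ):
                raise ValueError(
                    f"planted effect {eff.effect} infeasible for sizes"
                )
            members = list(rng.choice(np.array(template), overlap, replace=False))
            members += list(rng.choice(others, outside, replace=False))
            fid = f"planted_set_{i:03d}"
            sets_table.add_binary(
                FeatureMeta(fid, fid, Theme.GENE_EXPRESSION, DataType.BINARY,
                            "synthetic planted"),
                members,
            )
            planted_binary.append(fid)
        elif eff.data_type == "metric":
            vals = rng.standard_normal(spec.n_genes)
            vals[[g in tset for g in genes]] += eff.effect
            fid = f"planted_metric_{i:03d}"
            metric_table.add_metric(
                FeatureMeta(fid, fid, Theme.TRANSCRIPT_FEATURES, DataType.METRIC,
                            "synthetic planted"),
                dict(zip(genes, vals)),
            )
            planted_metric.append(fid)
        else:  # pairwise
            n_extra = int(eff.effect)
            made: set[tuple[str, str]] = set()
            while len(made) < n_extra:
                a, b = rng.choice(np.array(template), 2, replace=False)
                if a != b:
                    made.add((a, b) if a <= b else (b, a))
            planted_edges.extend(sorted(made))
            planted_pairwise.append(f"planted_pairwise_{i:03d}")

    # --- null binary features
    lo, hi = spec.set_size
    for i in range(spec.n_null_binary):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_arr, size=size, replace=False)
        fid = f"null_set_{i:04d}"
        sets_table.add_binary(
            FeatureMeta(fid, fid, Theme.GENE_EXPRESSION, DataType.BINARY,
                        "synthetic null"),
            members,
        )

    # --- null metric features
    for i in range(spec.n_null_metric):
        vals = rng.standard_normal(spec.n_genes)
        fid = f"null_metric_{i:04d}"
        metric_table.add_metric(
            FeatureMeta(fid, fid, Theme.TRANSCRIPT_FEATURES, DataType.METRIC,
                        "synthetic null"),
            dict(zip(genes, vals)),
        )

    if sets_table.n_features:
        tables.append(sets_table)
    if metric_table.n_features:
        tables.append(metric_table)

    # --- interaction network: random null edges plus planted clique edges
    networks = []
    if spec.n_null_edges > 0 or planted_edges:
        edges: set[tuple[str, str]] = set(planted_edges)
        while len(edges) < spec.n_null_edges + len(planted_edges):
            a, b = rng.choice(gene_arr, 2, replace=False)
            if a != b:
                edges.add((a, b) if a <= b else (b, a))
        networks.append(
            InteractionNetwork.from_pairs(
                sorted(edges), kind="physical", source="synthetic"
            )
        )

    backgrounds = {
        "protein_coding": set(genes),
        "all_annotated": set(genes),
        "non_essential": set(
            rng.choice(gene_arr, size=int(0.8 * spec.n_genes), replace=False)
        )
        | tset,
    }
    db = assemble_database(tables, networks, backgrounds)
    db.table._register_genes(genes)

    fx = Fixture(
        spec=spec,
        database=db,
        genes=genes,
        query_template=template,
        planted_binary=tuple(planted_binary),
        planted_metric=tuple(planted_metric),
        planted_pairwise=tuple(planted_pairwise),
    )
    if out_dir is not None:
        _write_fixture(fx, Path(out_dir), obo_text, gaf_direct,
                       sets_table, metric_table, networks, backgrounds)
        fx.out_dir = Path(out_dir)
    return fx


def _write_fixture(fx, out_dir, obo_text, gaf_direct, sets_table,
                   metric_table, networks, backgrounds) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": fx.spec.seed,
        "spec": dataclasses.asdict(fx.spec),
        "genes": "genes.txt",
        "gene_sets": [],
        "metric_tables": [],
        "interactions": [],
        "backgrounds": {},
        "planted": {
            "binary": list(fx.planted_binary),
            "metric": list(fx.planted_metric),
            "pairwise": list(fx.planted_pairwise),
            "query_template": "query_template.txt",
        },
    }
    _io.write_gene_list(fx.genes, out_dir / "genes.txt")
    _io.write_gene_list(fx.query_template, out_dir / "query_template.txt")
    if obo_text is not None:
        (out_dir / "ontology.obo").write_text(obo_text, encoding="utf-8")
        (out_dir / "annotations.gaf").write_text(
            _gaf_text(gaf_direct), encoding="utf-8"
        )
        manifest["ontology"] = {
            "obo": "ontology.obo",
            "gaf": "annotations.gaf",
            "min_genes": 2,
        }
    if sets_table.n_features:
        _io.write_gene_sets_tab(sets_table, out_dir / "gene_sets.tsv")
        manifest["gene_sets"].append(
            {"path": "gene_sets.tsv", "theme": "GeneExpression",
             "source": "synthetic"}
        )
    if metric_table.n_features:
        _io.write_metric_table(metric_table, out_dir / "metrics.tsv")
        manifest["metric_tables"].append(
            {"path": "metrics.tsv", "theme": "TranscriptFeatures",
             "source": "synthetic"}
        )
    for net in networks:
        fname = f"interactions_{net.kind}.tsv"
        _io.write_interactions_tab(net, out_dir / fname)
        manifest["interactions"].append(
            {"path": fname, "kind": net.kind, "columns": [0, 1],
             "source": "synthetic"}
        )
    bg_dir = out_dir / "backgrounds"
    bg_dir.mkdir(exist_ok=True)
    for label, members in backgrounds.items():
        _io.write_gene_list(sorted(members), bg_dir / f"{label}.txt")
        manifest["backgrounds"][label] = f"backgrounds/{label}.txt"
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def generate_query(
    fx: Fixture, kind: str, seed: int = 0, size: int | None = None
) -> list[str]:
    """A query gene list: the planted template, or a uniform null draw."""
    if kind == "planted":
        return list(fx.query_template)
    if kind != "null":
        raise ValueError(f"unknown query kind {kind!r}")
    rng = np.random.default_rng(seed)
    size = size if size is not None else fx.spec.query_size
    return sorted(rng.choice(np.array(fx.genes), size=size, replace=False))


# ---------------------------------------------------------------------------
# Calibration of the false-discovery proportion


def default_calibration_spec() -> FixtureSpec:
    """Conditions for FDR calibration: 500 genes, 2000 binary features
    (40 strongly planted, 1960 nulls), 50-gene planted queries."""
    return FixtureSpec(
        n_genes=500,
        n_null_binary=1960,
        n_null_metric=0,
        planted=tuple(PlantedEffect("binary", 0.6, size=50) for _ in range(40)),
        ontology_depth=0,
        n_null_edges=0,
        query_size=50,
    )


def fdr_calibration(
    n_replicates: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    spec: FixtureSpec | None = None,
) -> dict:
    """Mean false-discovery proportion of BH at ``alpha`` over replicate
    planted databases.

    Each replicate regenerates the database and its planted query under a
    fresh child seed, runs the full categorical enrichment with FDR
    correction, and scores the fraction of reported features that are
    nulls (0 when nothing is reported).  Returns the mean FDP, its Monte
    Carlo standard error, and bookkeeping counts.
    """
    base = spec if spec is not None else default_calibration_spec()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    fdps = np.zeros(n_replicates)
    n_reported = np.zeros(n_replicates, dtype=int)
    for r, s in enumerate(rep_seeds):
        fx = generate_database(dataclasses.replace(base, seed=int(s)))
        bg = fx.database.background("protein_coding")
        query = validate_query(list(fx.query_template), bg)
        cfg = RunConfig(correction="FDR", alpha=alpha, seed=int(s))
        result = run_enrichment(query, fx.database, cfg, background=bg)
        planted = set(fx.planted_binary)
        reported = [row.feature_id for row in result.rows]
        false = [fid for fid in reported if fid not in planted]
        n_reported[r] = len(reported)
        fdps[r] = len(false) / len(reported) if reported else 0.0
    return {
        "mean_fdp": float(fdps.mean()),
        "se": float(fdps.std(ddof=1) / math.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "mean_reported": float(n_reported.mean()),
        "alpha": alpha,
    }
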