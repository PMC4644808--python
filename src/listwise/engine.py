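"""Run orchestration: feature selection, testing, correction, reporting.

A run takes a validated query list, an assembled database and a
:class:`RunConfig`; every selected binary feature is tested with the
two-tailed Fisher's exact test, every metric feature with the two-sided
Wilcoxon rank-sum test, and (when enabled) every interaction network with
the permutation test.  All raw p-values are pooled into ONE correction
across the t tests actually performed; only features passing the corrected
criterion at alpha are reported, grouped by theme and ranked by raw p.

Deselecting themes (or GO sub-ontologies) shrinks t and therefore relaxes
the multiple-testing burden -- that is the intended way to gain power when
whole categories are not of interest.

Features that cannot be tested (empty set within the background, metric
values all missing on one side, interaction pool too small) are skipped
with a warning and excluded from t.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import fmean
from typing import Sequence

from . import stats as _stats
from .core import (
    GO_THEMES,
    Background,
    Database,
    DataType,
    QueryList,
    Theme,
)
from .io import ReportRow, sort_report_rows

_GO_KEEP = {
    "BP": {Theme.GO_BP},
    "MF": {Theme.GO_MF},
    "CC": {Theme.GO_CC},
    "all": set(GO_THEMES),
}


@dataclass(frozen=True)
class RunConfig:
    """Run parameters and their defaults.

    Defaults mirror the tool's standard workflow: protein-coding
    background, GO Biological Process only (Molecular Function and
    Cellular Component deselected), FDR correction at alpha 0.01, and no
    pairwise analysis (permutation testing is costly and, at 1000
    permutations, cannot survive correction anyway).
    """

    background: str = "protein_coding"
    go_category: str = "BP"  # BP | MF | CC | all
    correction: str = "FDR"  # FDR | Holm | Bonferroni
    alpha: float = 0.01
    run_pairwise: bool = False
    n_perm: int = 1000
    seed: int = 0
    themes_enabled: frozenset[Theme] = frozenset(Theme)
    min_set_size: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.go_category not in _GO_KEEP:
            raise ValueError(f"unknown go_category {self.go_category!r}")
        if self.correction not in ("FDR", "Holm", "Bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")

    def disable_themes(self, *themes: Theme) -> "RunConfig":
        return replace(
            self, themes_enabled=self.themes_enabled - frozenset(themes)
        )


def select_features(db: Database, config: RunConfig) -> tuple[list[str], int]:
    """Feature ids passing the theme / GO-category / pairwise selection.

    Returns the sorted candidate ids plus the candidate test count t
    (including enabled networks).  Binary features smaller than
    ``min_set_size`` over the database universe are excluded, consistent
    with the at-least-two-genes database filter.
    """
    go_keep = _GO_KEEP[config.go_category]
    ids: list[str] = []
    for fid in sorted(db.table.meta):
        m = db.table.meta[fid]
        if m.theme in GO_THEMES and m.theme not in go_keep:
            continue
        if m.theme not in config.themes_enabled:
            continue
        if (
            m.data_type is DataType.BINARY
            and len(db.table.binary[fid]) < config.min_set_size
        ):
            continue
        ids.append(fid)
    n_networks = (
        len(db.networks)
        if config.run_pairwise and Theme.INTERACTIONS in config.themes_enabled
        else 0
    )
    if not ids and n_networks == 0:
        raise ValueError("zero features selected")
    return ids, len(ids) + n_networks


@dataclass
class RunResult:
    """Outcome of one enrichment run.

    ``rows`` holds only the significant features (the report); ``details``
    holds one record per *tested* feature for :func:`explain`.  ``n_tests``
    is t, the number of p-values that entered the correction.
    """

    rows: list[ReportRow]
    n_tests: int
    config: RunConfig
    background_label: str
    n_query: int
    warnings: list[str] = field(default_factory=list)
    details: dict[str, dict] = field(default_factory=dict)


def run_enrichment(
    query: QueryList,
    db: Database,
    config: RunConfig,
    background: Background | None = None,
) -> RunResult:
    """Full enrichment run over every selected feature of the database.

    ``background`` defaults to the database background named by
    ``config.background`` (falling back to all database genes for the
    ``all_annotated`` label).  The query must already be validated against
    that background.
    """
    if background is None:
        background = db.background(config.background)
    A = query.gene_set
    if not A <= background.genes:
        raise ValueError("query list is not a subset of the background")
    nB = len(background.genes)
    nA = len(A)

    ids, _ = select_features(db, config)
    run_warnings: list[str] = list(query.warnings)
    tested: list[tuple[str, _stats.TestResult, dict]] = []
    skipped: list[str] = []

    for fid in ids:
        meta = db.table.meta[fid]
        if meta.data_type is DataType.BINARY:
            gb = db.table.binary[fid] & background.genes
            if not gb:
                skipped.append(fid)
                continue
            overlap = A & gb
            n11 = len(overlap)
            tbl = _stats.ContingencyTable(
                n11, len(gb) - n11, nA - n11, nB - nA - (len(gb) - n11)
            )
            res = _stats.fisher_twotailed(tbl)
            detail = {
                "data_type": "binary",
                "contingency": (tbl.n11, tbl.n12, tbl.n21, tbl.n22),
                "observed": float(n11),
                "expected": nA * len(gb) / nB,
                "overlap_genes": tuple(sorted(overlap)),
            }
        else:
            vals = db.table.metric[fid]
            x = [vals[g] for g in A if g in vals]
            y = [vals[g] for g in background.genes if g not in A and g in vals]
            if not x or not y:
                skipped.append(fid)
                continue
            res = _stats.wilcoxon_ranksum(x, y)
            detail = {
                "data_type": "metric",
                "observed": fmean(x),
                "expected": fmean(y),
                "group_sizes": (len(x), len(y)),
            }
        tested.append((fid, res, detail))

    if config.run_pairwise and Theme.INTERACTIONS in config.themes_enabled:
        for i, net in enumerate(db.networks):
            seed = (config.seed * 1000003 + i) % (2**31)
            res = _stats.permutation_interaction_test(
                A, net, background, n_perm=config.n_perm, seed=seed
            )
            if res.raw_p is None:
                skipped.append(net.name)
                run_warnings.extend(f"{net.name}: {w}" for w in res.warnings)
                continue
            detail = {
                "data_type": "pairwise",
                "observed": float(res.details["observed"]),
                "expected": res.details["perm_mean"],
                "n_interactions": res.details["observed"],
            }
            tested.append((net.name, res, detail))

    if skipped:
        run_warnings.append(
            f"skipped {len(skipped)} untestable feature(s): "
            + ", ".join(skipped[:10])
            + ("..." if len(skipped) > 10 else "")
        )

    t = len(tested)
    raw_ps = [res.raw_p for _, res, _ in tested]
    inp = _stats.CorrectionInput(raw_ps, t=t, alpha=config.alpha)
    if config.correction == "FDR":
        adjusted, flags = _stats.correct_bh_fdr(inp)
    elif config.correction == "Holm":
        adjusted = _stats.correct_holm(inp)
        flags = [p <= config.alpha for p in adjusted]
    else:
        adjusted = _stats.correct_bonferroni(inp)
        flags = [p <= config.alpha for p in adjusted]

    rows: list[ReportRow] = []
    details: dict[str, dict] = {}
    for (fid, res, detail), adj, sig in zip(tested, adjusted, flags):
        if fid in db.table.meta:
            meta = db.table.meta[fid]
            theme, name, source = meta.theme, meta.name, meta.source
        else:  # network
            net = next(n for n in db.networks if n.name == fid)
            theme, name, source = Theme.INTERACTIONS, fid, net.source
        detail.update(
            feature_id=fid,
            feature_name=name,
            theme=theme,
            source=source,
            raw_p=res.raw_p,
            corrected_p=float(adj),
            direction=res.direction,
            significant=bool(sig),
            warnings=list(res.warnings),
        )
        details[fid] = detail
        if sig:
            rows.append(
                ReportRow(
                    theme=theme,
                    feature_id=fid,
                    feature_name=name,
                    source=source,
                    direction=res.direction or "over",
                    raw_p=res.raw_p,
                    corrected_p=float(adj),
                    observed=detail["observed"],
                    expected=detail["expected"],
                    overlap_genes=detail.get("overlap_genes", ()),
                    n_interactions=detail.get("n_interactions"),
                )
            )

    return RunResult(
        rows=sort_report_rows(rows),
        n_tests=t,
        config=config,
        background_label=background.label,
        n_query=nA,
        warnings=run_warnings,
        details=details,
    )


def explain(result: RunResult, feature_id: str) -> dict:
    """Detailed record for one tested feature: contingency cells or group
    means, overlap genes, raw and corrected p, source.

    Raises ``KeyError`` for features that were not tested in this run.
    """
    if feature_id not in result.details:
        raise KeyError(f"feature {feature_id!r} was not tested in this run")
    return dict(result.details[feature_id])


def format_log(result: RunResult) -> str:
    """Human-readable run log: configuration, t, warnings."""
    cfg = result.config
    lines = [
        f"background\t{result.background_label}",
        f"query_size\t{result.n_query}",
        f"go_category\t{cfg.go_category}",
        f"correction\t{cfg.correction}",
        f"alpha\t{cfg.alpha}",
        f"run_pairwise\t{cfg.run_pairwise}",
        f"n_perm\t{cfg.n_perm}",
        f"seed\t{cfg.seed}",
        f"themes_enabled\t{','.join(sorted(t.value for t in cfg.themes_enabled))}",
        f"n_tests\t{result.n_tests}",
        f"n_significant\t{len(result.rows)}",
    ]
    lines.extend(f"warning\t{w}" for w in result.warnings)
    return "\n".join(lines) + "\n"
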