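"""Sequence- and annotation-derived metric features.

Computes the per-gene and per-protein quantities that feed the metric side
of the feature database: intron statistics and transcript length from gene
models, GC content of the first intron, absolute and relative chromosomal
distances from centromere and telomeres, protein molecular weight,
isoelectric point, net charge at pH 7, amino-acid composition, and the
fold index (a hydropathy/charge predictor of intrinsic disorder).

Coordinates are 1-based inclusive (Ensembl/GFF convention).  Gene position
for distance features is the midpoint of the gene span; the centromere
distance is measured to the nearest boundary of the centromere interval
(zero inside it).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bio_mw

from .core import DataType, FeatureMeta, FeatureTable, Theme

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS pepstats default pKa values; override via the ``pka`` argument
#: of :func:`net_charge` / :func:`isoelectric_point`.
EMBOSS_PKA = {
    "N_term": 8.6,
    "C_term": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered, non-overlapping exons on one chromosome."""

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(
            self, "exons", tuple(sorted(tuple(e) for e in self.exons))
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class ChromosomeMap:
    """Chromosome length and centromere interval; telomeres are the ends."""

    chromosome: str
    length: int
    centromere: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.centromere
        if not (1 <= s <= e <= self.length):
            raise ValueError(
                f"{self.chromosome}: centromere interval outside [1, length]"
            )


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.gene_id}: unknown amino-acid letter(s) {sorted(bad)}"
            )


def intron_features(g: GeneModel) -> dict[str, float | int | None]:
    """Intron number, average intron length and total transcript length.

    Introns are the gaps between consecutive exons; ``avg_intron_length``
    is None (missing) for intron-less genes.  Overlapping exons are an
    error.
    """
    gaps: list[int] = []
    for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
        if s2 <= e1:
            raise ValueError(f"{g.gene_id}: overlapping exons {e1}>={s2}")
        gaps.append(s2 - e1 - 1)
    total = sum(e - s + 1 for s, e in g.exons)
    return {
        "intron_number": len(gaps),
        "avg_intron_length": (sum(gaps) / len(gaps)) if gaps else None,
        "total_transcript_length": total,
    }


def introns(g: GeneModel) -> list[tuple[int, int]]:
    """Intron intervals (1-based inclusive), in chromosome order."""
    out = []
    for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
        if s2 <= e1 + 1:
            if s2 <= e1:
                raise ValueError(f"{g.gene_id}: overlapping exons")
            continue  # abutting exons leave no intron
        out.append((e1 + 1, s2 - 1))
    return out


def gc_content(seq: str) -> float | None:
    """Fraction (G+C)/(A+C+G+T); N bases are excluded from the denominator.

    Returns None (missing) for empty or all-N sequences.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected nucleotide letter(s) {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        return None
    return (seq.count("G") + seq.count("C")) / denom


def centromere_telomere_distances(
    g: GeneModel, c: ChromosomeMap
) -> dict[str, float]:
    """Absolute/relative distances of the gene midpoint from the centromere
    boundary and from the nearest chromosome end."""
    if g.chromosome != c.chromosome:
        raise ValueError(
            f"{g.gene_id} is on {g.chromosome}, map is for {c.chromosome}"
        )
    start, end = g.span
    if end > c.length or start < 1:
        raise ValueError(f"{g.gene_id}: gene beyond chromosome bounds")
    mid = (start + end) / 2.0
    cs, ce = c.centromere
    if cs <= mid <= ce:
        cen_abs = 0.0
    else:
        cen_abs = min(abs(mid - cs), abs(mid - ce))
    tel_abs = min(mid - 1, c.length - mid)
    return {
        "cen_dist_abs": cen_abs,
        "cen_dist_rel": cen_abs / c.length,
        "tel_dist_abs": tel_abs,
        "tel_dist_rel": tel_abs / c.length,
    }


def net_charge(
    seq: str, pH: float, pka: Mapping[str, float] = EMBOSS_PKA
) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    charge = 1.0 / (1.0 + 10 ** (pH - pka["N_term"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["C_term"] - pH))
    for aa in _POSITIVE:
        charge += seq.count(aa) / (1.0 + 10 ** (pH - pka[aa]))
    for aa in _NEGATIVE:
        charge -= seq.count(aa) / (1.0 + 10 ** (pka[aa] - pH))
    return charge


def isoelectric_point(
    seq: str, pka: Mapping[str, float] = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, pka) < 0:
        return lo
    if net_charge(seq, hi, pka) > 0:
        return hi
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_stats(p: ProteinRecord) -> dict[str, float]:
    """Molecular weight (average masses, Da), pI, charge at pH 7, length."""
    return {
        "protein_mw": float(_bio_mw(p.sequence, seq_type="protein")),
        "isoelectric_point": isoelectric_point(p.sequence),
        "charge_ph7": net_charge(p.sequence, 7.0),
        "protein_length": float(len(p.sequence)),
    }


def aa_composition(p: ProteinRecord) -> dict[str, float]:
    """Per-residue fractions over the 20 standard amino acids (sum to 1)."""
    n = len(p.sequence)
    return {aa: p.sequence.count(aa) / n for aa in AMINO_ACIDS}


def fold_index(p: ProteinRecord) -> float:
    """Whole-protein fold index: 2.785 <H> - |<R>| - 1.151.

    <H> is the mean Kyte-Doolittle hydropathy rescaled to [0, 1] and <R>
    the mean net charge (K, R = +1; D, E = -1).  Negative values predict
    intrinsically unfolded proteins.
    """
    n = len(p.sequence)
    mean_h = sum((KYTE_DOOLITTLE[a] + 4.5) / 9.0 for a in p.sequence) / n
    mean_r = (
        p.sequence.count("K")
        + p.sequence.count("R")
        - p.sequence.count("D")
        - p.sequence.count("E")
    ) / n
    return 2.785 * mean_h - abs(mean_r) - 1.151


# ---------------------------------------------------------------------------
# File readers and feature-table assembly


def read_gene_models(gff_path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GFF3 file (exons grouped by parent gene)."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = tuple(
            (e.start, e.end) for e in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = ((gene.start, gene.end),)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                biotype=gene.attributes.get("biotype", ["protein_coding"])[0],
            )
        )
    return models


def read_chromosome_maps(
    path: str | os.PathLike,
) -> dict[str, ChromosomeMap]:
    """Read chromosome maps from a TSV: chrom, length, cen_start, cen_end."""
    maps: dict[str, ChromosomeMap] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length, cs, ce = line.rstrip("\n").split("\t")[:4]
            maps[chrom] = ChromosomeMap(chrom, int(length), (int(cs), int(ce)))
    return maps


def read_proteins_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _first_intron(g: GeneModel) -> tuple[int, int] | None:
    iv = introns(g)
    if not iv:
        return None
    return iv[0] if g.strand == "+" else iv[-1]


def gene_feature_table(
    models: Iterable[GeneModel],
    chrom_maps: Mapping[str, ChromosomeMap] | None = None,
    genome: Mapping[str, str] | None = None,
    source: str = "computed",
) -> FeatureTable:
    """Assemble intron/transcript/position metric features for gene models.

    Distance features require ``chrom_maps``; first-intron GC requires the
    ``genome`` sequences.  Genes for which a quantity is undefined are
    simply absent from that feature.
    """
    specs = [
        ("intron_number", "Intron number", Theme.GENE_FEATURES),
        ("avg_intron_length", "Average intron length", Theme.GENE_FEATURES),
        (
            "total_transcript_length",
            "Total transcript length",
            Theme.TRANSCRIPT_FEATURES,
        ),
        ("gc_first_intron", "GC content of first intron", Theme.GENE_FEATURES),
        ("cen_dist_abs", "Distance from centromere (bp)", Theme.GENE_FEATURES),
        ("cen_dist_rel", "Relative distance from centromere", Theme.GENE_FEATURES),
        ("tel_dist_abs", "Distance from telomere (bp)", Theme.GENE_FEATURES),
        ("tel_dist_rel", "Relative distance from telomere", Theme.GENE_FEATURES),
    ]
    values: dict[str, dict[str, float]] = {fid: {} for fid, _, _ in specs}
    for g in models:
        feats = intron_features(g)
        for key in ("intron_number", "avg_intron_length", "total_transcript_length"):
            if feats[key] is not None:
                values[key][g.gene_id] = float(feats[key])
        if chrom_maps and g.chromosome in chrom_maps:
            for key, v in centromere_telomere_distances(
                g, chrom_maps[g.chromosome]
            ).items():
                values[key][g.gene_id] = v
        if genome and g.chromosome in genome:
            iv = _first_intron(g)
            if iv is not None:
                gc = gc_content(genome[g.chromosome][iv[0] - 1 : iv[1]])
                if gc is not None:
                    values["gc_first_intron"][g.gene_id] = gc
    table = FeatureTable()
    for fid, name, theme in specs:
        if not values[fid]:
            continue
        table.add_metric(
            FeatureMeta(fid, name, theme, DataType.METRIC, source), values[fid]
        )
    return table


def protein_feature_table(
    records: Iterable[ProteinRecord],
    include_composition: bool = True,
    source: str = "computed",
) -> FeatureTable:
    """Assemble protein metric features (MW, pI, charge, length, fold index,
    optionally the 20 amino-acid composition fractions)."""
    specs = {
        "protein_mw": "Molecular weight (Da)",
        "isoelectric_point": "Isoelectric point",
        "charge_ph7": "Net charge at pH 7",
        "protein_length": "Protein length (aa)",
        "fold_index": "Fold index",
    }
    values: dict[str, dict[str, float]] = {fid: {} for fid in specs}
    comp: dict[str, dict[str, float]] = {
        f"aa_frac_{aa}": {} for aa in AMINO_ACIDS
    }
    for p in records:
        for fid, v in protein_stats(p).items():
            values[fid][p.gene_id] = v
        values["fold_index"][p.gene_id] = fold_index(p)
        if include_composition:
            for aa, frac in aa_composition(p).items():
                comp[f"aa_frac_{aa}"][p.gene_id] = frac
    table = FeatureTable()
    for fid, name in specs.items():
        if values[fid]:
            table.add_metric(
                FeatureMeta(fid, name, Theme.PROTEIN_FEATURES, DataType.METRIC, source),
                values[fid],
            )
    if include_composition:
        for aa in AMINO_ACIDS:
            fid = f"aa_frac_{aa}"
            if comp[fid]:
                table.add_metric(
                    FeatureMeta(
                        fid,
                        f"Amino-acid fraction {aa}",
                        Theme.PROTEIN_FEATURES,
                        DataType.METRIC,
                        source,
                    ),
                    comp[fid],
                )
    return table
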