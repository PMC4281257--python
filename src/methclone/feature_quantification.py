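"""Region-stratified quantification of methylome placements.

Placements are counted against eight genomic feature classes: gene bodies,
exons, introns, two promoter windows upstream of the transcription start
(0-2 kb and 2-3 kb, strand-aware), transposon bodies, their 1 kb borders,
and a distal 49-51 kb upstream window used as background control.  A
placement increments a class once per owning feature it overlaps by at
least 1 bp; classes are independent, so one placement may count in several
(e.g. a read straddling an exon/intron junction counts in exon, intron and
gene body).  Hits are weighted by the read's copy count.

Per-gene body/promoter hit counts feed the two-fold methylation change
classification, and per-scaffold hit totals feed the methylation density
ranking used for the methylome-transcriptome dual match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io import Gene, Transposon
from .read_mapping import MethylRead, ReadPlacement

logger = logging.getLogger(__name__)

REGION_CLASSES = (
    "gene_body",
    "exon",
    "intron",
    "promoter_0_2kb",
    "promoter_2_3kb",
    "transposon_body",
    "transposon_border_1kb",
    "transposon_upstream_49_51kb",
)


@dataclass
class RegionIndex:
    """Interval trees per (region class, scaffold); data = (feature, strand)."""

    trees: dict[str, dict[str, IntervalTree]]
    scaffold_lengths: dict[str, int]

    def intervals(self, region_class: str):
        """All (scaffold, start, end, feature_id, strand) of one class."""
        for scaffold, tree in self.trees.get(region_class, {}).items():
            for iv in sorted(tree):
                yield (scaffold, iv.begin, iv.end, iv.data[0], iv.data[1])


@dataclass
class RegionCountTable:
    """Copy-count-weighted hits per region class and per owning feature."""

    class_totals: dict[tuple[str, str], int] = field(default_factory=dict)
    per_feature: dict[tuple[str, str, str], int] = field(default_factory=dict)
    variants: tuple[str, ...] = ()

    def hits(self, region_class: str, variant: str) -> int:
        return self.class_totals.get((region_class, variant), 0)

    def feature_hits(
        self, feature_id: str, region_class: str, variant: str
    ) -> int:
        return self.per_feature.get((feature_id, region_class, variant), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region_class": c, "variant": v, "hits": n}
            for (c, v), n in sorted(self.class_totals.items())
        ]
        return pd.DataFrame(
            rows, columns=["region_class", "variant", "hits"]
        )


@dataclass(frozen=True)
class GeneMethylationRecord:
    """Per-gene methylation hits and two-fold change class per region."""

    gene_id: str
    body_hits: dict[str, int]
    promoter_hits: dict[str, int]
    body_class: str
    promoter_class: str


def _clip(start: int, end: int, length: int) -> tuple[int, int]:
    return max(0, start), min(end, length)


def _add(trees, region_class, scaffold, start, end, feature_id, strand, length):
    start, end = _clip(start, end, length)
    if start < end:
        trees[region_class].setdefault(scaffold, IntervalTree()).addi(
            start, end, (feature_id, strand)
        )


def build_region_index(
    genes: list[Gene],
    transposons: list[Transposon],
    scaffold_lengths: dict[str, int],
    promoter_near: int = 2_000,
    promoter_far: int = 3_000,
    border: int = 1_000,
    distal_window: tuple[int, int] = (49_000, 51_000),
) -> RegionIndex:
    """Build all eight region classes from gene models and transposons.

    Promoter windows are measured upstream of the transcription start on
    the gene's strand; introns are the gene span minus its exons; the
    transposon border is the union of 1 kb flanks and the distal window
    lies 49-51 kb upstream (to the left when, as in BED, no strand is
    annotated).  All intervals are clipped at scaffold edges.
    """
    trees: dict[str, dict[str, IntervalTree]] = {
        c: {} for c in REGION_CLASSES
    }
    for g in genes:
        if g.scaffold not in scaffold_lengths:
            raise ValueError(
                f"gene {g.gene_id} references unknown scaffold {g.scaffold}"
            )
        L = scaffold_lengths[g.scaffold]
        if g.end > L:
            logger.warning("gene %s clipped at scaffold end", g.gene_id)
        _add(trees, "gene_body", g.scaffold, g.start, g.end, g.gene_id, g.strand, L)
        exons = list(g.exons)
        if not exons:
            logger.warning(
                "gene %s has no exons: treated as single-exon", g.gene_id
            )
            exons = [(g.start, g.end)]
        exons.sort()
        for s, e in exons:
            _add(trees, "exon", g.scaffold, s, e, g.gene_id, g.strand, L)
        # introns: gene span minus exon cover
        cursor = g.start
        for s, e in exons:
            if s > cursor:
                _add(
                    trees, "intron", g.scaffold, cursor, s, g.gene_id,
                    g.strand, L,
                )
            cursor = max(cursor, e)
        if cursor < g.end:
            _add(
                trees, "intron", g.scaffold, cursor, g.end, g.gene_id,
                g.strand, L,
            )
        if g.strand == "+":
            near = (g.start - promoter_near, g.start)
            far = (g.start - promoter_far, g.start - promoter_near)
        else:
            near = (g.end, g.end + promoter_near)
            far = (g.end + promoter_near, g.end + promoter_far)
        _add(trees, "promoter_0_2kb", g.scaffold, *near, g.gene_id, g.strand, L)
        _add(trees, "promoter_2_3kb", g.scaffold, *far, g.gene_id, g.strand, L)

    for t in transposons:
        if t.scaffold not in scaffold_lengths:
            raise ValueError(
                f"transposon {t.te_id} references unknown scaffold "
                f"{t.scaffold}"
            )
        L = scaffold_lengths[t.scaffold]
        if t.end > L:
            logger.warning("transposon %s clipped at scaffold end", t.te_id)
        _add(trees, "transposon_body", t.scaffold, t.start, t.end, t.te_id, ".", L)
        for s, e in ((t.start - border, t.start), (t.end, t.end + border)):
            _add(trees, "transposon_border_1kb", t.scaffold, s, e, t.te_id, ".", L)
        _add(
            trees,
            "transposon_upstream_49_51kb",
            t.scaffold,
            t.start - distal_window[1],
            t.start - distal_window[0],
            t.te_id,
            ".",
            L,
        )
    return RegionIndex(trees=trees, scaffold_lengths=dict(scaffold_lengths))


def count_by_region(
    placements: list[ReadPlacement],
    reads: list[MethylRead],
    index: RegionIndex,
) -> RegionCountTable:
    """Count copy-count-weighted placement hits per region class.

    Each (placement, owning feature) overlap of >=1 bp contributes the
    read's copy count; class totals are the sum of their per-feature
    breakdowns.
    """
    meta = {r.read_id: (r.variant, r.copy_count) for r in reads}
    table = RegionCountTable(
        variants=tuple(sorted({v for v, _ in meta.values()}))
    )
    for p in placements:
        variant, weight = meta[p.read_id]
        for region_class in REGION_CLASSES:
            tree = index.trees[region_class].get(p.scaffold_id)
            if tree is None:
                continue
            features = {iv.data[0] for iv in tree.overlap(p.start, p.end)}
            for fid in features:
                key = (fid, region_class, variant)
                table.per_feature[key] = table.per_feature.get(key, 0) + weight
                ckey = (region_class, variant)
                table.class_totals[ckey] = (
                    table.class_totals.get(ckey, 0) + weight
                )
    return table


def _fold_class(orange: int, green: int, fold: float, min_hits: int) -> str:
    if max(orange, green) < min_hits:
        return "insufficient"
    if green >= fold * orange:
        return "up2x_green"
    if orange >= fold * green:
        return "down2x_green"
    return "unchanged"


def classify_gene_methylation(
    table: RegionCountTable,
    gene_ids: list[str],
    fold: float = 2.0,
    min_hits: int = 5,
) -> list[GeneMethylationRecord]:
    """Two-fold (boundary inclusive) methylation change per gene and region.

    ``up2x_green`` when green >= fold x orange, ``down2x_green`` for the
    mirror, ``insufficient`` when neither variant reaches ``min_hits``.
    With a zero denominator the direction is assigned when the non-zero
    count reaches ``min_hits``.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    records = []
    for gene_id in gene_ids:
        body = {
            v: table.feature_hits(gene_id, "gene_body", v)
            for v in ("orange", "green")
        }
        prom = {
            v: table.feature_hits(gene_id, "promoter_0_2kb", v)
            for v in ("orange", "green")
        }
        records.append(
            GeneMethylationRecord(
                gene_id=gene_id,
                body_hits=body,
                promoter_hits=prom,
                body_class=_fold_class(
                    body["orange"], body["green"], fold, min_hits
                ),
                promoter_class=_fold_class(
                    prom["orange"], prom["green"], fold, min_hits
                ),
            )
        )
    return records


def rank_scaffolds(
    hits: pd.DataFrame, scaffold_lengths: dict[str, int]
) -> pd.DataFrame:
    """Rank scaffolds by methylation density.

    density = arithmetic mean of the two variants' hit totals divided by
    scaffold length; descending, ties broken by scaffold id.
    """
    rows = []
    for scaffold in hits.index:
        length = scaffold_lengths[scaffold]
        if length <= 0:
            raise ValueError(f"scaffold {scaffold} has non-positive length")
        mean_hits = float(hits.loc[scaffold].mean())
        rows.append(
            {
                "scaffold": scaffold,
                "mean_hits": mean_hits,
                "length": length,
                "density": mean_hits / length,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["density", "scaffold"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = frame.index + 1
    return frame


def log2_compartment_shift(table: RegionCountTable) -> dict[str, float]:
    """log2(green / orange) of total hits per region class (0 where a side
    is empty); a coarse global shift summary, not CpG-normalized."""
    import math

    out = {}
    for region_class in REGION_CLASSES:
        o = table.hits(region_class, "orange")
        g = table.hits(region_class, "green")
        out[region_class] = (
            math.log2(g / o) if o > 0 and g > 0 else float("nan")
        )
    return out


def cpg_normalized_hits(
    table: RegionCountTable,
    index: RegionIndex,
    scaffolds: dict[str, str],
) -> pd.DataFrame:
    """Optional sensitivity analysis: hits per CpG dinucleotide per class.

    Raw counts are deliberately not CpG-normalized by default; this helper
    reports hits / CpG for users who want the density-corrected view.
    """
    rows = []
    for region_class in REGION_CLASSES:
        cpg = 0
        for scaffold, start, end, _fid, _strand in index.intervals(
            region_class
        ):
            cpg += scaffolds[scaffold].count("CG", start, end)
        for variant in table.variants:
            hits = table.hits(region_class, variant)
            rows.append(
                {
                    "region_class": region_class,
                    "variant": variant,
                    "hits": hits,
                    "cpg": cpg,
                    "hits_per_cpg": hits / cpg if cpg else float("nan"),
                }
            )
    return pd.DataFrame(rows)
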