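"""Methylome-transcriptome dual match, concordance and report export.

Per scaffold, methylation direction (which variant has more hits) is
joined with the net expression direction (sign of summed calibrated
green-minus-orange gene reads on the scaffold).  A scaffold is concordant
when the two run inversely: more methylation in green with less
expression in green, or the mirror.  Concordance is the fraction of the
top-k most methylation-dense scaffolds that are concordant; scaffolds
with no expressed reads in either variant are excluded from the
denominator and reported separately.

:func:`run_pipeline` chains the whole analysis — mapping, region
quantification, SSH calibration, classification, cross lists, enrichment,
concordance, track export — from a manifest of input files, writing
deterministic TSV/BED/GFF3 reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import feature_quantification as fq
from . import go_enrichment as goe
from . import read_mapping as rm
from . import transcriptome_ssh as ssh
from ._seqindex import GenomeIndex
from .io import Gene, read_bed, read_fasta, read_gene2go, read_gff3

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """All analysis thresholds, at their standard defaults."""

    mismatch_fraction: float = 0.04
    promoter_near: int = 2_000
    promoter_far: int = 3_000
    border: int = 1_000
    distal_window: tuple[int, int] = (49_000, 51_000)
    strong_min: float = 20
    slight_min: float = 5
    fold: float = 2.0
    min_hits: int = 5
    alpha: float = 0.05
    copy_thresholds: tuple[int, ...] = (2, 5)
    copy_comparison: str = "ge"
    top_k: tuple[int, ...] = (500, 10_000)
    min_score: int = 50
    min_similarity: float = 0.9
    max_control_count: int = 15
    expression_stringency: str = "strong"
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("distal_window", "copy_thresholds", "top_k"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory results of one full pipeline run."""

    placements: dict[str, list[rm.ReadPlacement]]
    reads: dict[str, list[rm.MethylRead]]
    spectrum: rm.MultiplicitySpectrum
    occurrence: list[rm.OccurrenceClassTable]
    scaffold_hits: pd.DataFrame
    scaffold_correlation: float
    region_counts: fq.RegionCountTable
    gene_methylation: list[fq.GeneMethylationRecord]
    scaffold_ranks: pd.DataFrame
    calibration: ssh.CalibrationModel
    gene_expression: list[ssh.GeneExpressionRecord]
    cross_lists: list[goe.CrossList]
    enrichment: dict[str, pd.DataFrame]
    integration: pd.DataFrame
    concordance: dict[int, dict[str, float]]
    stage_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scaffold-level integration and concordance
# ---------------------------------------------------------------------------


def integrate_scaffolds(
    ranks: pd.DataFrame,
    scaffold_hits: pd.DataFrame,
    expression_records: list[ssh.GeneExpressionRecord],
    genes: list[Gene],
) -> pd.DataFrame:
    """Join methylation rank/direction with net expression per scaffold."""
    gene_scaffold = {g.gene_id: g.scaffold for g in genes}
    net: dict[str, float] = {}
    for record in expression_records:
        scaffold = gene_scaffold.get(record.gene_id)
        if scaffold is None:
            continue
        net[scaffold] = net.get(scaffold, 0.0) + (
            record.green_calibrated - record.orange_calibrated
        )
    expressed: dict[str, float] = {}
    for record in expression_records:
        scaffold = gene_scaffold.get(record.gene_id)
        if scaffold is None:
            continue
        expressed[scaffold] = (
            expressed.get(scaffold, 0.0)
            + record.green_calibrated
            + record.orange_calibrated
        )
    rows = []
    for row in ranks.itertuples(index=False):
        scaffold = row.scaffold
        green = int(scaffold_hits.loc[scaffold, "green"])
        orange = int(scaffold_hits.loc[scaffold, "orange"])
        meth_direction = (
            "green" if green > orange else "orange" if orange > green else "tie"
        )
        net_expr = net.get(scaffold, 0.0)
        expr_direction = (
            "green" if net_expr > 0 else "orange" if net_expr < 0 else "tie"
        )
        has_expression = expressed.get(scaffold, 0.0) > 0
        concordant = (
            meth_direction == "green" and expr_direction == "orange"
        ) or (meth_direction == "orange" and expr_direction == "green")
        rows.append(
            {
                "scaffold": scaffold,
                "rank": row.rank,
                "density": row.density,
                "meth_green": green,
                "meth_orange": orange,
                "meth_direction": meth_direction,
                "net_expression_green_minus_orange": net_expr,
                "expr_direction": expr_direction,
                "expressed": has_expression,
                "concordant": bool(concordant and has_expression),
            }
        )
    return pd.DataFrame(rows)


def concordance(
    integration: pd.DataFrame,
    top_k: int,
    include_silent: bool = False,
) -> dict[str, float]:
    """Fraction of the top-k methylation-ranked scaffolds with inverse
    methylation/expression directions.

    Expression-silent scaffolds are excluded from the denominator (and
    counted in ``n_silent``) unless ``include_silent`` is set.
    """
    if top_k <= 0:
        raise ValueError("top_k must be > 0")
    if top_k > len(integration):
        raise ValueError(
            f"top_k={top_k} exceeds the {len(integration)} ranked scaffolds"
        )
    top = integration.nsmallest(top_k, "rank")
    silent = int((~top["expressed"]).sum())
    denom = top_k if include_silent else top_k - silent
    n_concordant = int(top["concordant"].sum())
    return {
        "top_k": top_k,
        "n_concordant": n_concordant,
        "n_silent": silent,
        "n_considered": denom,
        "fraction": n_concordant / denom if denom else float("nan"),
    }


# ---------------------------------------------------------------------------
# track export
# ---------------------------------------------------------------------------


def export_tracks(
    placements: dict[str, list[rm.ReadPlacement]],
    reads: dict[str, list[rm.MethylRead]],
    expression_records: list[ssh.GeneExpressionRecord],
    genes: list[Gene],
    integration: pd.DataFrame,
    outdir,
) -> dict[str, Path]:
    """Decorated-scaffold track bundle: methylation BED and expression GFF3
    per variant plus a merged per-scaffold summary TSV, in deterministic
    (scaffold, start, id) order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for variant in sorted(placements):
        path = outdir / f"methylation_{variant}.bed"
        rm.write_placements_bed(placements[variant], reads[variant], path)
        paths[f"methylation_{variant}"] = path

    gene_by_id = {g.gene_id: g for g in genes}
    for variant in ("orange", "green"):
        path = outdir / f"expression_{variant}.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            rows = []
            for record in expression_records:
                gene = gene_by_id.get(record.gene_id)
                if gene is None:
                    continue
                count = getattr(record, f"{variant}_calibrated")
                rows.append((gene.scaffold, gene.start, gene.gene_id, gene, count))
            for scaffold, start, gene_id, gene, count in sorted(
                rows, key=lambda r: (r[0], r[1], r[2])
            ):
                fh.write(
                    f"{scaffold}\tmethclone\texpression\t{gene.start + 1}\t"
                    f"{gene.end}\t.\t{gene.strand}\t.\t"
                    f"ID={gene_id}.expr_{variant};read_count={count:g}\n"
                )
        paths[f"expression_{variant}"] = path

    summary_path = outdir / "scaffold_summary.tsv"
    integration.sort_values("scaffold").to_csv(
        summary_path, sep="\t", index=False
    )
    paths["scaffold_summary"] = summary_path
    return paths


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

MANIFEST_KEYS = (
    "scaffolds",
    "genes",
    "transposons",
    "gene2go",
    "go_dag",
    "methyl_reads_orange",
    "methyl_counts_orange",
    "methyl_reads_green",
    "methyl_counts_green",
    "contigs_orange",
    "contig_counts_orange",
    "contigs_green",
    "contig_counts_green",
)


def _place_unique(reads, index, mismatch_fraction):
    """Place each distinct sequence once and fan placements out per read."""
    by_sequence: dict[str, list[rm.MethylRead]] = {}
    for read in reads:
        by_sequence.setdefault(read.sequence, []).append(read)
    representatives = [
        rm.MethylRead(
            read_id=f"uniq_{i:07d}", sequence=seq, variant="orange"
        )
        for i, seq in enumerate(by_sequence)
    ]
    rep_placements = rm.place_reads(
        representatives, index, mismatch_fraction
    )
    by_rep: dict[str, list[rm.ReadPlacement]] = {}
    for p in rep_placements:
        by_rep.setdefault(p.read_id, []).append(p)
    out: dict[str, list[rm.ReadPlacement]] = {}
    for rep in representatives:
        placed = by_rep.get(rep.read_id, [])
        for member in by_sequence[rep.sequence]:
            fanned = [
                dataclasses.replace(p, read_id=member.read_id)
                for p in placed
            ]
            out.setdefault(member.variant, []).extend(fanned)
    return out


def run_pipeline(
    config: PipelineConfig,
    manifest: dict[str, str],
    outdir,
) -> PipelineResult:
    """Execute the full analysis from a manifest of input paths.

    Stages: mapping -> region quantification -> SSH calibration ->
    expression classification -> cross lists -> enrichment ->
    concordance -> track export.  Re-running with identical inputs and
    config reproduces byte-identical outputs.
    """
    missing = [key for key in MANIFEST_KEYS if key not in manifest]
    if missing:
        raise PipelineError(
            f"stage 'inputs': manifest missing {', '.join(missing)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage '{name}': {exc}") from exc

    scaffolds = _stage("genome", read_fasta, manifest["scaffolds"])
    genes = _stage("genes", read_gff3, manifest["genes"])
    transposons = _stage("transposons", read_bed, manifest["transposons"])
    gene2go = _stage("annotations", read_gene2go, manifest["gene2go"])
    dag = _stage("go_dag", goe.GODag.from_obo, manifest["go_dag"])
    index = GenomeIndex(scaffolds)
    lengths = {name: len(seq) for name, seq in scaffolds.items()}
    counts["scaffolds"] = len(scaffolds)
    counts["genes"] = len(genes)

    reads = {
        variant: _stage(
            "methylome_reads",
            rm.read_methyl_reads,
            manifest[f"methyl_reads_{variant}"],
            variant,
            manifest[f"methyl_counts_{variant}"],
        )
        for variant in ("orange", "green")
    }
    all_reads = reads["orange"] + reads["green"]
    placements = _stage(
        "mapping", _place_unique, all_reads, index, config.mismatch_fraction
    )
    placements.setdefault("orange", [])
    placements.setdefault("green", [])
    for variant in ("orange", "green"):
        counts[f"placements_{variant}"] = len(placements[variant])
        logger.info(
            "mapping: %d placements for %s", len(placements[variant]), variant
        )

    all_placements = placements["orange"] + placements["green"]
    spectrum = rm.multiplicity_spectrum(all_placements, all_reads)
    occurrence = [
        rm.occurrence_classes(
            reads["orange"], reads["green"], t, config.copy_comparison
        )
        for t in config.copy_thresholds
    ]
    scaffold_hits = rm.per_scaffold_hits(
        all_placements, all_reads, list(scaffolds)
    )
    if len(scaffold_hits) >= 3:
        correlation = rm.pearson_correlation(
            scaffold_hits["orange"].to_numpy(),
            scaffold_hits["green"].to_numpy(),
        )
    else:
        logger.warning("fewer than 3 scaffolds: correlation undefined")
        correlation = float("nan")

    region_index = _stage(
        "region_index",
        fq.build_region_index,
        genes,
        transposons,
        lengths,
        config.promoter_near,
        config.promoter_far,
        config.border,
        config.distal_window,
    )
    region_counts = _stage(
        "region_counts",
        fq.count_by_region,
        all_placements,
        all_reads,
        region_index,
    )
    gene_methylation = fq.classify_gene_methylation(
        region_counts,
        [g.gene_id for g in genes],
        config.fold,
        config.min_hits,
    )
    ranks = fq.rank_scaffolds(scaffold_hits, lengths)

    contigs = {
        variant: _stage(
            "ssh_contigs",
            ssh.read_ssh_contigs,
            manifest[f"contigs_{variant}"],
            manifest[f"contig_counts_{variant}"],
            variant,
        )
        for variant in ("orange", "green")
    }
    for variant in ("orange", "green"):
        _stage(
            "contig_assignment",
            ssh.assign_contigs,
            contigs[variant],
            index,
            region_index,
            config.mismatch_fraction,
            config.min_score,
        )
        counts[f"contigs_{variant}"] = len(contigs[variant])
    calibration = _stage(
        "calibration",
        ssh.find_internal_controls,
        contigs["orange"],
        contigs["green"],
        config.min_similarity,
        config.max_control_count,
    )
    counts["control_pairs"] = len(calibration.pairs)
    for variant in ("orange", "green"):
        ssh.calibrate(contigs[variant], calibration)
    gene_table = ssh.gene_expression_table(
        contigs["orange"] + contigs["green"]
    )
    expression = ssh.classify_expression(
        gene_table, config.strong_min, config.slight_min, config.fold
    )
    counts["expressed_genes"] = len(expression)

    cross_lists = goe.build_cross_lists(
        expression, gene_methylation, config.expression_stringency
    )
    closure = goe.propagate_annotations(gene2go, dag)
    background = {g.gene_id for g in genes}
    enrichment = {
        lst.list_id: goe.enrich(
            lst.genes, background, closure, dag, config.alpha
        )
        for lst in cross_lists
    }

    integration = integrate_scaffolds(ranks, scaffold_hits, expression, genes)
    concordances = {}
    for k in config.top_k:
        k_eff = min(k, len(integration))
        both = concordance(integration, k_eff)
        both["fraction_incl_silent"] = concordance(
            integration, k_eff, include_silent=True
        )["fraction"]
        concordances[k_eff] = both

    # ---- reports ----
    with open(outdir / "multiplicity_spectrum.tsv", "w") as fh:
        fh.write("variant\tlocations\tn_distinct_reads\n")
        for variant in sorted(spectrum.per_variant):
            for locations in sorted(spectrum.per_variant[variant]):
                fh.write(
                    f"{variant}\t{locations}\t"
                    f"{spectrum.per_variant[variant][locations]}\n"
                )
    with open(outdir / "occurrence_classes.tsv", "w") as fh:
        fh.write(
            "threshold\tcomparison\tshared\tonly_green\tonly_orange\t"
            "once_each\n"
        )
        for table in occurrence:
            fh.write(
                f"{table.threshold}\t{table.comparison}\t{table.shared}\t"
                f"{table.only_green}\t{table.only_orange}\t"
                f"{table.once_each}\n"
            )
    region_counts.to_frame().to_csv(
        outdir / "region_counts.tsv", sep="\t", index=False
    )
    with open(outdir / "gene_methylation.tsv", "w") as fh:
        fh.write(
            "gene_id\tbody_orange\tbody_green\tpromoter_orange\t"
            "promoter_green\tbody_class\tpromoter_class\n"
        )
        for record in gene_methylation:
            fh.write(
                f"{record.gene_id}\t{record.body_hits['orange']}\t"
                f"{record.body_hits['green']}\t"
                f"{record.promoter_hits['orange']}\t"
                f"{record.promoter_hits['green']}\t{record.body_class}\t"
                f"{record.promoter_class}\n"
            )
    with open(outdir / "calibration.tsv", "w") as fh:
        fh.write(f"# scale_factor\t{calibration.scale_factor:.6f}\n")
        fh.write(f"# method\t{calibration.method}\n")
        fh.write("orange_contig\tgreen_contig\tsimilarity\n")
        for orange_id, green_id, sim in sorted(calibration.pairs):
            fh.write(f"{orange_id}\t{green_id}\t{sim:.4f}\n")
    with open(outdir / "gene_expression.tsv", "w") as fh:
        fh.write(
            "gene_id\torange_raw\tgreen_raw\torange_calibrated\t"
            "green_calibrated\texpression_class\n"
        )
        for record in expression:
            fh.write(
                f"{record.gene_id}\t{record.orange_raw:g}\t"
                f"{record.green_raw:g}\t{record.orange_calibrated:.4f}\t"
                f"{record.green_calibrated:.4f}\t"
                f"{record.expression_class}\n"
            )
    enrich_dir = outdir / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    for list_id, frame in sorted(enrichment.items()):
        frame.to_csv(
            enrich_dir / f"{list_id}.tsv",
            sep="\t",
            index=False,
            float_format="%.6g",
        )
    with open(outdir / "concordance.tsv", "w") as fh:
        fh.write(
            "top_k\tn_concordant\tn_silent\tn_considered\tfraction\t"
            "fraction_incl_silent\n"
        )
        for k in sorted(concordances):
            c = concordances[k]
            fh.write(
                f"{c['top_k']}\t{c['n_concordant']}\t{c['n_silent']}\t"
                f"{c['n_considered']}\t{c['fraction']:.4f}\t"
                f"{c['fraction_incl_silent']:.4f}\n"
            )
    shift = fq.log2_compartment_shift(region_counts)
    with open(outdir / "log2_compartment_shift.tsv", "w") as fh:
        fh.write("region_class\tlog2_green_over_orange\n")
        for region_class in fq.REGION_CLASSES:
            fh.write(f"{region_class}\t{shift[region_class]:.4f}\n")
    export_tracks(
        placements, reads, expression, genes, integration, outdir / "tracks"
    )
    with open(outdir / "stage_counts.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for stage in sorted(counts):
            fh.write(f"{stage}\t{counts[stage]}\n")

    return PipelineResult(
        placements=placements,
        reads=reads,
        spectrum=spectrum,
        occurrence=occurrence,
        scaffold_hits=scaffold_hits,
        scaffold_correlation=correlation,
        region_counts=region_counts,
        gene_methylation=gene_methylation,
        scaffold_ranks=ranks,
        calibration=calibration,
        gene_expression=expression,
        cross_lists=cross_lists,
        enrichment=enrichment,
        integration=integration,
        concordance=concordances,
        stage_counts=counts,
    )
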