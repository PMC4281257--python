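"""SSH (suppression subtractive hybridization) transcriptome analysis.

Contigs from the two variants' SSH libraries are assigned to genes by
aligning them to the genome, the non-subtracted background — pairs of
near-identical contigs present at low counts in both libraries — is used
as internal control to calibrate the library sizes, and per-gene
differential expression is classified at the strong (>=20 reads vs 0),
slight (>=5 vs 0) and moderate (>= two-fold, both non-zero) levels.

Alignment is a gapless (Hamming) matcher built on the same seed-and-verify
index used by the methylome mapper: contig-to-genome assignment places the
whole contig within a mismatch cap, and contig-to-contig similarity scores
the best shared-k-mer diagonal.  The minimum score plays the role of the
classic aligner's e-value cutoff: a 100 bp exact match passes the default,
a diverged partial overlap does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqindex import GenomeIndex, encode, reverse_complement
from .feature_quantification import RegionIndex

logger = logging.getLogger(__name__)

EXPRESSION_CLASSES = (
    "strong_up_green",
    "strong_down_green",
    "slight_up_green",
    "slight_down_green",
    "moderate_up_green",
    "moderate_down_green",
    "unchanged",
)


class CalibrationError(ValueError):
    """No usable internal-control pairs; the caller must supply a factor."""


@dataclass
class SSHContig:
    """One assembled SSH contig with its library read count."""

    contig_id: str
    variant: str
    sequence: str
    read_count: int
    gene_id: str | None = None
    alignment_score: float | None = None
    calibrated_count: float | None = None

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError(
                f"contig {self.contig_id}: read_count must be >= 1"
            )

    @property
    def effective_count(self) -> float:
        return (
            self.calibrated_count
            if self.calibrated_count is not None
            else float(self.read_count)
        )


@dataclass
class CalibrationModel:
    """Internal-control pairs and the derived library scale factor."""

    pairs: list[tuple[str, str, float]]  # (orange id, green id, similarity)
    scale_factor: float
    method: str = "sum_ratio"


@dataclass(frozen=True)
class GeneExpressionRecord:
    gene_id: str
    orange_raw: float
    green_raw: float
    orange_calibrated: float
    green_calibrated: float
    expression_class: str


# ---------------------------------------------------------------------------
# contig-to-genome assignment
# ---------------------------------------------------------------------------


def assign_contigs(
    contigs: list[SSHContig],
    genome: dict[str, str] | GenomeIndex,
    region_index: RegionIndex,
    mismatch_fraction: float = 0.04,
    min_score: int = 50,
) -> list[SSHContig]:
    """Assign each contig to the gene owning its best genomic locus.

    The contig is matched full-length on both strands within the mismatch
    cap; score = matching bases of the best locus.  A contig is assigned
    when its best-scoring loci all fall in one gene (body or 0-2 kb
    promoter); contigs scoring below ``min_score``, hitting no gene, or
    tied between genes are left unassigned and logged.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    body_trees = region_index.trees["gene_body"]
    prom_trees = region_index.trees["promoter_0_2kb"]
    for contig in contigs:
        contig.gene_id = None
        contig.alignment_score = None
        L = len(contig.sequence)
        k = math.floor(mismatch_fraction * L)
        hits = []
        for seq in (contig.sequence, reverse_complement(contig.sequence)):
            hits.extend(index.find(encode(seq), k))
        if not hits:
            continue
        best_mism = min(h[2] for h in hits)
        score = L - best_mism
        contig.alignment_score = float(score)
        if score < min_score:
            continue
        best_loci = {
            (index.names[sc], start)
            for sc, start, mism in hits
            if mism == best_mism
        }
        genes_per_locus = []
        for scaffold, start in sorted(best_loci):
            body_tree = body_trees.get(scaffold)
            bodies = (
                {iv.data[0] for iv in body_tree.overlap(start, start + L)}
                if body_tree is not None
                else set()
            )
            if len(bodies) == 1:
                genes_per_locus.append(next(iter(bodies)))
                continue
            if len(bodies) > 1:
                genes_per_locus.append("__multiple__")
                continue
            prom_tree = prom_trees.get(scaffold)
            promoters = (
                {iv.data[0] for iv in prom_tree.overlap(start, start + L)}
                if prom_tree is not None
                else set()
            )
            if len(promoters) == 1:
                genes_per_locus.append(next(iter(promoters)))
            elif len(promoters) > 1:
                genes_per_locus.append("__multiple__")
            else:
                genes_per_locus.append(None)
        resolved = {g for g in genes_per_locus if g is not None}
        if resolved == {"__multiple__"} or len(resolved) > 1:
            logger.info(
                "contig %s ambiguous between genes; left unassigned",
                contig.contig_id,
            )
        elif len(resolved) == 1:
            contig.gene_id = next(iter(resolved))
    return contigs


# ---------------------------------------------------------------------------
# contig-to-contig similarity (gapless, best shared-k-mer diagonal)
# ---------------------------------------------------------------------------


def ungapped_similarity(a: str, b: str, q: int = 12) -> tuple[int, float]:
    """Best gapless alignment of two sequences over both orientations.

    Candidate diagonals come from shared q-mers; the best diagonal's
    overlap is scored by exact base matches.  Returns (score = matched
    bases, similarity = score / shorter sequence length).
    """
    best = (0, 0.0)
    for oriented in (b, reverse_complement(b)):
        result = _ungapped_one_orientation(a, oriented, q)
        if result[0] > best[0]:
            best = result
    return best


def _ungapped_one_orientation(a: str, b: str, q: int) -> tuple[int, float]:
    if len(a) < q or len(b) < q:
        return (0, 0.0)
    positions: dict[str, list[int]] = {}
    for i in range(len(a) - q + 1):
        positions.setdefault(a[i : i + q], []).append(i)
    diagonals: dict[int, int] = {}
    for j in range(len(b) - q + 1):
        for i in positions.get(b[j : j + q], ()):
            d = j - i
            diagonals[d] = diagonals.get(d, 0) + 1
    if not diagonals:
        return (0, 0.0)
    ea, eb = encode(a), encode(b)
    best_score = 0
    # evaluate the few most k-mer-supported diagonals exactly
    for d, _support in sorted(
        diagonals.items(), key=lambda kv: (-kv[1], kv[0])
    )[:5]:
        a_lo = max(0, -d)
        a_hi = min(len(a), len(b) - d)
        if a_hi <= a_lo:
            continue
        matches = int(
            np.count_nonzero(ea[a_lo:a_hi] == eb[a_lo + d : a_hi + d])
        )
        best_score = max(best_score, matches)
    return (best_score, best_score / min(len(a), len(b)))


def find_internal_controls(
    contigs_orange: list[SSHContig],
    contigs_green: list[SSHContig],
    min_similarity: float = 0.9,
    max_count: int = 15,
    q: int = 12,
    method: str = "sum_ratio",
) -> CalibrationModel:
    """Reciprocal-best low-count contig pairs and the library scale factor.

    Pairs must be mutual best matches by alignment score, with similarity
    >= ``min_similarity`` and both read counts <= ``max_count``; each
    contig joins at most one pair.  The scale factor (applied to green
    counts) is the ratio of summed orange to summed green control counts;
    ``method='median_ratio'`` uses the median per-pair orange/green ratio
    instead.
    """
    if not contigs_orange or not contigs_green:
        raise CalibrationError("both contig sets must be non-empty")
    if method not in ("sum_ratio", "median_ratio"):
        raise ValueError("method must be 'sum_ratio' or 'median_ratio'")

    # inverted q-mer index over green contigs, both orientations
    kmer_to_green: dict[str, set[int]] = {}
    for gi, contig in enumerate(contigs_green):
        for seq in (contig.sequence, reverse_complement(contig.sequence)):
            for i in range(len(seq) - q + 1):
                kmer_to_green.setdefault(seq[i : i + q], set()).add(gi)

    scores: dict[tuple[int, int], tuple[int, float]] = {}
    for oi, contig in enumerate(contigs_orange):
        candidates: set[int] = set()
        seq = contig.sequence
        for i in range(len(seq) - q + 1):
            candidates |= kmer_to_green.get(seq[i : i + q], set())
        for gi in candidates:
            scores[(oi, gi)] = ungapped_similarity(
                seq, contigs_green[gi].sequence, q
            )

    def _best(by: int) -> dict[int, int]:
        best: dict[int, tuple] = {}
        out: dict[int, int] = {}
        for (oi, gi), (score, _sim) in scores.items():
            key = oi if by == 0 else gi
            other = gi if by == 0 else oi
            other_contig = (
                contigs_green[other] if by == 0 else contigs_orange[other]
            )
            this_contig = (
                contigs_orange[key] if by == 0 else contigs_green[key]
            )
            # deterministic: higher score wins; score ties prefer the more
            # complete mutual alignment (smaller length difference, e.g.
            # overlapping contigs cut from the same gene), then contig id
            rank = (
                score,
                -abs(len(this_contig.sequence) - len(other_contig.sequence)),
                other_contig.contig_id,
            )
            if key not in best or rank > best[key]:
                best[key] = rank
                out[key] = other
        return out

    best_green_for_orange = _best(0)
    best_orange_for_green = _best(1)

    pairs, used_green = [], set()
    for oi in sorted(best_green_for_orange):
        gi = best_green_for_orange[oi]
        if best_orange_for_green.get(gi) != oi or gi in used_green:
            continue
        score, sim = scores[(oi, gi)]
        if sim < min_similarity:
            continue
        if (
            contigs_orange[oi].read_count > max_count
            or contigs_green[gi].read_count > max_count
        ):
            continue
        used_green.add(gi)
        pairs.append(
            (
                contigs_orange[oi].contig_id,
                contigs_green[gi].contig_id,
                sim,
            )
        )
    if not pairs:
        raise CalibrationError(
            "no internal-control pairs found; calibration is impossible -- "
            "supply a scale factor explicitly"
        )

    orange_by_id = {c.contig_id: c for c in contigs_orange}
    green_by_id = {c.contig_id: c for c in contigs_green}
    orange_counts = np.array(
        [orange_by_id[o].read_count for o, _g, _s in pairs], dtype=float
    )
    green_counts = np.array(
        [green_by_id[g].read_count for _o, g, _s in pairs], dtype=float
    )
    if green_counts.sum() == 0:
        raise CalibrationError("green control counts sum to zero")
    if method == "sum_ratio":
        factor = float(orange_counts.sum() / green_counts.sum())
    else:
        factor = float(np.median(orange_counts / green_counts))
    return CalibrationModel(pairs=pairs, scale_factor=factor, method=method)


def calibrate(
    contigs: list[SSHContig], model: CalibrationModel
) -> list[SSHContig]:
    """Apply the library scale factor: green counts are multiplied by it,
    orange counts pass through; calibrated counts stay real-valued."""
    if model.scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    for contig in contigs:
        contig.calibrated_count = (
            contig.read_count * model.scale_factor
            if contig.variant == "green"
            else float(contig.read_count)
        )
    return contigs


# ---------------------------------------------------------------------------
# gene-level aggregation and classification
# ---------------------------------------------------------------------------


def gene_expression_table(contigs: list[SSHContig]) -> pd.DataFrame:
    """Sum assigned contigs' raw and calibrated counts per gene."""
    acc: dict[str, dict[str, float]] = {}
    for contig in contigs:
        if contig.gene_id is None:
            continue
        row = acc.setdefault(
            contig.gene_id,
            {
                "orange_raw": 0.0,
                "green_raw": 0.0,
                "orange_calibrated": 0.0,
                "green_calibrated": 0.0,
            },
        )
        row[f"{contig.variant}_raw"] += contig.read_count
        row[f"{contig.variant}_calibrated"] += contig.effective_count
    frame = pd.DataFrame.from_dict(acc, orient="index").sort_index()
    frame.index.name = "gene_id"
    return frame


def classify_expression(
    gene_table: pd.DataFrame,
    strong_min: float = 20,
    slight_min: float = 5,
    fold: float = 2.0,
) -> list[GeneExpressionRecord]:
    """Classify per-gene differential expression from calibrated counts.

    strong: >= ``strong_min`` reads in one variant, zero in the other;
    slight: >= ``slight_min`` vs zero (and not strong); moderate: both
    non-zero, >= ``fold`` ratio, with the larger count >= ``slight_min``;
    otherwise unchanged.  Direction suffix names the higher variant.
    """
    records = []
    for gene_id, row in gene_table.iterrows():
        o = float(row["orange_calibrated"])
        g = float(row["green_calibrated"])
        if o < 0 or g < 0:
            raise ValueError(f"gene {gene_id}: negative counts")
        cls = "unchanged"
        if g >= strong_min and o == 0:
            cls = "strong_up_green"
        elif o >= strong_min and g == 0:
            cls = "strong_down_green"
        elif g >= slight_min and o == 0:
            cls = "slight_up_green"
        elif o >= slight_min and g == 0:
            cls = "slight_down_green"
        elif o > 0 and g > 0 and max(o, g) >= slight_min:
            if g >= fold * o:
                cls = "moderate_up_green"
            elif o >= fold * g:
                cls = "moderate_down_green"
        records.append(
            GeneExpressionRecord(
                gene_id=str(gene_id),
                orange_raw=float(row["orange_raw"]),
                green_raw=float(row["green_raw"]),
                orange_calibrated=o,
                green_calibrated=g,
                expression_class=cls,
            )
        )
    return records


def read_ssh_contigs(fasta_path, counts_path, variant: str) -> list[SSHContig]:
    from .io import read_fasta

    counts = pd.read_csv(counts_path, sep="\t")
    count_map = dict(zip(counts["contig_id"], counts["read_count"]))
    return [
        SSHContig(
            contig_id=name,
            variant=variant,
            sequence=seq,
            read_count=int(count_map[name]),
        )
        for name, seq in read_fasta(fasta_path).items()
    ]
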