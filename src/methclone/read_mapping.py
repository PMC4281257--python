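"""Placement of methyl-enriched reads on genome scaffolds.

MBD pull-down reads from the two clonal variants are matched against the
scaffolds on both strands, reporting *every* location within the mismatch
cap (no best-hit selection) so that multi-mapping repeat-derived reads keep
all their placements.  From the placements the module derives the
multiplicity spectrum (how many genomic locations each distinct read
sequence occupies), the occurrence-class partition of distinct sequences
between the variants, and copy-count-weighted per-scaffold hit vectors.

Distinct-sequence statistics (spectrum, occurrence classes) are unweighted;
per-scaffold hits weight each placement by the read's pyrosequencing copy
count ("hits").
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqindex import GenomeIndex, encode, reverse_complement

logger = logging.getLogger(__name__)

#: fraction of N bases above which a read is skipped outright
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class MethylRead:
    """One distinct methyl-enriched read with its pyrosequencing copy count."""

    read_id: str
    sequence: str
    variant: str
    copy_count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.copy_count < 1:
            raise ValueError(f"read {self.read_id}: copy_count must be >= 1")


@dataclass(frozen=True, order=True)
class ReadPlacement:
    """One genomic location of a read (0-based half-open, stranded)."""

    scaffold_id: str
    start: int
    end: int
    read_id: str
    strand: str
    mismatches: int


@dataclass
class MultiplicitySpectrum:
    """Per-variant histogram: genomic locations per distinct read sequence."""

    per_variant: dict[str, dict[int, int]] = field(default_factory=dict)

    def n_distinct(self, variant: str) -> int:
        return sum(self.per_variant.get(variant, {}).values())


@dataclass
class OccurrenceClassTable:
    """Partition of distinct sequences by copy count across the variants.

    ``shared`` / ``only_green`` / ``only_orange`` apply the copy-count rule
    at threshold ``t``; ``once_each`` counts sequences seen exactly once in
    each variant (reported separately, outside the three classes).
    """

    threshold: int
    comparison: str
    shared: int
    only_green: int
    only_orange: int
    once_each: int


def place_reads(
    reads: list[MethylRead],
    scaffolds: dict[str, str] | GenomeIndex,
    mismatch_fraction: float = 0.04,
) -> list[ReadPlacement]:
    """Place every read at every matching location on both strands.

    A location matches when its Hamming distance to the read is at most
    ``floor(mismatch_fraction * len(read))``.  All hits are retained.
    Reads with more than 10% N are skipped with a warning.
    """
    if not 0.0 <= mismatch_fraction <= 0.1:
        raise ValueError("mismatch_fraction must be in [0, 0.1]")
    index = (
        scaffolds
        if isinstance(scaffolds, GenomeIndex)
        else GenomeIndex(scaffolds)
    )
    placements: list[ReadPlacement] = []
    for read in reads:
        L = len(read.sequence)
        if read.sequence.upper().count("N") > MAX_N_FRACTION * L:
            logger.warning(
                "read %s skipped: >%.0f%% N", read.read_id, MAX_N_FRACTION * 100
            )
            continue
        k = math.floor(mismatch_fraction * L)
        for strand, seq in (
            ("+", read.sequence),
            ("-", reverse_complement(read.sequence)),
        ):
            for sc, start, mism in index.find(encode(seq), k):
                placements.append(
                    ReadPlacement(
                        scaffold_id=index.names[sc],
                        start=start,
                        end=start + L,
                        read_id=read.read_id,
                        strand=strand,
                        mismatches=mism,
                    )
                )
    return placements


def multiplicity_spectrum(
    placements: list[ReadPlacement], reads: list[MethylRead]
) -> MultiplicitySpectrum:
    """Histogram of genomic locations per distinct read sequence, per variant.

    Reads with zero placements are reported in bin 0.  Identical sequences
    submitted under several read ids are counted as one distinct sequence.
    """
    locs_by_read: dict[str, set] = {}
    for p in placements:
        locs_by_read.setdefault(p.read_id, set()).add(
            (p.scaffold_id, p.start, p.end, p.strand)
        )
    seen: dict[tuple[str, str], int] = {}
    for read in reads:
        key = (read.variant, read.sequence)
        n_locs = len(locs_by_read.get(read.read_id, ()))
        seen[key] = max(seen.get(key, 0), n_locs)
    spectrum = MultiplicitySpectrum()
    for (variant, _seq), n_locs in seen.items():
        hist = spectrum.per_variant.setdefault(variant, {})
        hist[n_locs] = hist.get(n_locs, 0) + 1
    return spectrum


def _counts_by_sequence(reads: list[MethylRead]) -> dict[str, int]:
    out: dict[str, int] = {}
    for read in reads:
        out[read.sequence] = out.get(read.sequence, 0) + read.copy_count
    return out


def occurrence_classes(
    reads_orange: list[MethylRead],
    reads_green: list[MethylRead],
    threshold: int,
    comparison: str = "ge",
) -> OccurrenceClassTable:
    """Classify distinct sequences by copy count across the two variants.

    With rule(c) = (c >= t) (default) or (c > t): a sequence is ``shared``
    when the rule holds in both variants, ``only_X`` when the rule holds in
    X and the count is zero in the other.  Sequences seen exactly once in
    each variant are tallied as ``once_each``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if comparison not in ("ge", "gt"):
        raise ValueError("comparison must be 'ge' or 'gt'")
    rule = (
        (lambda c: c >= threshold)
        if comparison == "ge"
        else (lambda c: c > threshold)
    )
    orange = _counts_by_sequence(reads_orange)
    green = _counts_by_sequence(reads_green)
    shared = only_green = only_orange = once_each = 0
    for seq in set(orange) | set(green):
        o, g = orange.get(seq, 0), green.get(seq, 0)
        if rule(o) and rule(g):
            shared += 1
        elif rule(g) and o == 0:
            only_green += 1
        elif rule(o) and g == 0:
            only_orange += 1
        if o == 1 and g == 1:
            once_each += 1
    return OccurrenceClassTable(
        threshold=threshold,
        comparison=comparison,
        shared=shared,
        only_green=only_green,
        only_orange=only_orange,
        once_each=once_each,
    )


def per_scaffold_hits(
    placements: list[ReadPlacement],
    reads: list[MethylRead],
    scaffold_ids: list[str],
) -> pd.DataFrame:
    """Copy-count-weighted hit totals per scaffold, one column per variant.

    Every placement of a read contributes the read's copy count; scaffolds
    with no placements appear with zero.
    """
    meta = {r.read_id: (r.variant, r.copy_count) for r in reads}
    variants = sorted({v for v, _ in meta.values()})
    acc: dict[tuple[str, str], int] = {}
    for p in placements:
        variant, weight = meta[p.read_id]
        key = (p.scaffold_id, variant)
        acc[key] = acc.get(key, 0) + weight
    table = pd.DataFrame(
        0, index=pd.Index(scaffold_ids, name="scaffold"), columns=variants
    )
    for (scaffold, variant), total in acc.items():
        table.loc[scaffold, variant] = total
    return table


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation; NaN (with warning) if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "correlation undefined for a constant vector", stacklevel=2
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# I/O: reads come as FASTA of distinct sequences + a copy-count TSV; the
# copy-count file is optional (every record then counts once).  Placements
# are exchanged as BED6 with name=read_id and score=copy_count.
# ---------------------------------------------------------------------------


def read_methyl_reads(
    fasta_path, variant: str, counts_path=None
) -> list[MethylRead]:
    from Bio import SeqIO

    counts: dict[str, int] = {}
    if counts_path is not None:
        table = pd.read_csv(counts_path, sep="\t")
        counts = dict(zip(table["read_id"], table["copy_count"]))
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        reads.append(
            MethylRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                variant=variant,
                copy_count=int(counts.get(rec.id, 1)),
            )
        )
    return reads


def write_placements_bed(
    placements: list[ReadPlacement],
    reads: list[MethylRead],
    path,
) -> None:
    """BED6 export: name=read_id, score=copy_count, deterministic order."""
    weight = {r.read_id: r.copy_count for r in reads}
    with open(path, "w") as fh:
        fh.write("# methclone placements: BED6, score = read copy count\n")
        for p in sorted(placements):
            fh.write(
                f"{p.scaffold_id}\t{p.start}\t{p.end}\t{p.read_id}\t"
                f"{weight.get(p.read_id, 1)}\t{p.strand}\n"
            )


def read_placements_bed(path) -> tuple[list[ReadPlacement], dict[str, int]]:
    """Inverse of :func:`write_placements_bed`.

    Returns the placements and the read_id -> copy_count map recovered from
    the score column (mismatch counts are not round-tripped through BED and
    read back as 0).
    """
    placements, weights = [], {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split(
                "\t"
            )[:6]
            placements.append(
                ReadPlacement(
                    scaffold_id=chrom,
                    start=int(start),
                    end=int(end),
                    read_id=name,
                    strand=strand,
                    mismatches=0,
                )
            )
            weights[name] = int(score)
    return placements, weights
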