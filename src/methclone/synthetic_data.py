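"""Synthetic two-variant methylome/transcriptome data with planted truth.

The generator emulates the study design the pipeline analyses: two clonal
aphid variants (*orange* and *green*) profiled by

* MBD pull-down of MseI fragments (methylome): genomic DNA is cut at every
  TTAA site (T^TAA), fragments overlapping methylation hot spots are
  captured with a configurable bias, and pyrosequencing copy counts are
  multinomial draws over the captured fragments;
* suppression subtractive hybridization (SSH) libraries (transcriptome):
  contigs drawn from gene sequences, with identical low-count contig pairs
  in both libraries (the non-subtracted background that serves as internal
  control) and high-count contigs from planted differentially expressed
  genes present in exactly one library.

Everything that downstream stages are meant to recover — repeat copy
numbers, hot-spot intervals, differential genes, enriched GO terms, control
contigs, the library-size multiplier — is serialized as machine-readable
:class:`PlantedTruth` next to the emitted files.

All randomness flows from one top-level seed; each stage derives a child
generator deterministically, so identical (config, seed) reproduces
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mcio
from .io import Gene, Transposon
from ._seqindex import reverse_complement
from .read_mapping import MethylRead

logger = logging.getLogger(__name__)

VARIANTS = ("orange", "green")

#: MseI recognition site and cut offset: T^TAA
MSEI_SITE = "TTAA"
MSEI_CUT_OFFSET = 1

GO_NAMESPACES = (
    "biological_process",
    "molecular_function",
    "cellular_component",
)


class ConfigurationError(ValueError):
    """An infeasible or inconsistent synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults describe the desk-scale analogue of the study: 50 scaffolds of
    100 kb, AT-rich sequence (GC 0.30), 20 genes and 10 transposons per
    scaffold, repeats planted at copy numbers 1/2/5/50, 2x10^5 methylome
    reads per variant with a 10x capture bias over 2 kb hot spots (70%
    shared between variants), 10% of genes strongly differentially
    expressed with inverse methylation-expression coupling 0.9, 100
    internal-control contig pairs and a 1.2x green library-size imbalance.
    """

    seed: int = 0
    n_scaffolds: int = 50
    scaffold_length: int = 100_000
    #: scaffold lengths are uniform in scaffold_length * (1 +/- spread);
    #: gene/transposon/hot-spot counts scale with each scaffold's length
    scaffold_length_spread: float = 0.6
    gc_fraction: float = 0.30
    n_genes_per_scaffold: int = 20
    n_transposons_per_scaffold: int = 10
    repeat_unit_length: int = 40
    repeat_copy_numbers: tuple[int, ...] = (1, 2, 5, 50)
    hotspot_density: float = 10.0  # hot spots per 100 kb
    hotspot_length: int = 2_000
    shared_hotspot_fraction: float = 0.7
    #: probability that a variant-specific hot spot follows its scaffold's
    #: methylation direction; 0.5 makes the variants' hot spots independent
    hotspot_direction_bias: float = 1.0
    reads_per_variant: int = 200_000
    fragment_capture_bias: float = 10.0
    min_fragment_length: int = 30
    de_gene_fraction: float = 0.20
    de_fold_change: float = 2.0
    methylation_expression_coupling: float = 0.9
    control_contig_count: int = 100
    control_count_range: tuple[int, int] = (4, 9)
    strong_read_floor: int = 20
    green_library_multiplier: float = 1.2
    contig_length_range: tuple[int, int] = (150, 400)
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    transposon_length_range: tuple[int, int] = (500, 2_000)
    go_term_count: int = 150
    planted_enriched_terms: int = 2

    def __post_init__(self):
        for name in (
            "gc_fraction",
            "shared_hotspot_fraction",
            "de_gene_fraction",
            "methylation_expression_coupling",
            "hotspot_direction_bias",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in (
            "n_scaffolds",
            "scaffold_length",
            "n_genes_per_scaffold",
            "n_transposons_per_scaffold",
            "repeat_unit_length",
            "reads_per_variant",
            "control_contig_count",
            "go_term_count",
            "planted_enriched_terms",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.de_fold_change < 1:
            raise ConfigurationError("de_fold_change must be >= 1")
        if not 0.0 <= self.scaffold_length_spread < 1.0:
            raise ConfigurationError(
                "scaffold_length_spread must be in [0, 1)"
            )
        if self.fragment_capture_bias <= 0:
            raise ConfigurationError("fragment_capture_bias must be > 0")
        if self.green_library_multiplier <= 0:
            raise ConfigurationError("green_library_multiplier must be > 0")
        if self.planted_enriched_terms > 0 and self.de_gene_fraction == 0:
            raise ConfigurationError(
                "planted_enriched_terms > 0 requires de_gene_fraction > 0: "
                "enriched terms are planted on differential genes"
            )
        if self.go_term_count and self.go_term_count < 3 + 2 * max(
            1, self.planted_enriched_terms
        ):
            raise ConfigurationError(
                "go_term_count too small to hold namespace roots and "
                "planted terms"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in (
            "repeat_copy_numbers",
            "control_count_range",
            "contig_length_range",
            "gene_length_range",
            "transposon_length_range",
        ):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedTruth:
    """Machine-readable ground truth serialized alongside the fixtures."""

    # variant -> [(scaffold, start, end, capture_weight)]
    hotspot_intervals: dict[str, list[tuple[str, int, int, float]]] = field(
        default_factory=dict
    )
    repeat_units: dict[str, str] = field(default_factory=dict)
    repeat_locations: dict[str, list[tuple[str, int]]] = field(
        default_factory=dict
    )
    # gene -> (direction of higher expression: 'green'|'orange', fold)
    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    # gene -> (region 'body'|'promoter', variant with higher methylation)
    methylation_shift_genes: dict[str, tuple[str, str]] = field(
        default_factory=dict
    )
    # term -> expression direction of the planted list ('green'|'orange')
    enriched_terms: dict[str, str] = field(default_factory=dict)
    # control contig base id -> (source gene, offset within gene, length)
    control_contigs: dict[str, tuple[str, int, int]] = field(
        default_factory=dict
    )
    scaffold_direction: dict[str, str] = field(default_factory=dict)
    library_multiplier: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["hotspot_intervals"] = {
            v: [tuple(x) for x in lst]
            for v, lst in raw["hotspot_intervals"].items()
        }
        raw["repeat_locations"] = {
            u: [tuple(x) for x in lst]
            for u, lst in raw["repeat_locations"].items()
        }
        for key in ("de_genes", "methylation_shift_genes", "control_contigs"):
            raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)


@dataclass
class GenomeBundle:
    """In-memory synthetic genome with annotations and planted truth."""

    config: SyntheticConfig
    scaffolds: dict[str, str]
    genes: list[Gene]
    transposons: list[Transposon]
    gene2go: dict[str, set[str]]
    go_terms: dict[str, tuple[str, str, tuple[str, ...]]]
    truth: PlantedTruth

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    def gene_sequence(self, gene: Gene) -> str:
        return self.scaffolds[gene.scaffold][gene.start : gene.end]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": outdir / "scaffolds.fa",
            "genes": outdir / "genes.gff3",
            "transposons": outdir / "transposons.bed",
            "gene2go": outdir / "gene2go.tsv",
            "go_dag": outdir / "go.obo",
            "truth": outdir / "truth.json",
            "config": outdir / "config.yaml",
        }
        mcio.write_fasta(self.scaffolds, paths["scaffolds"])
        mcio.write_gff3(self.genes, paths["genes"])
        mcio.write_bed(self.transposons, paths["transposons"])
        mcio.write_gene2go(self.gene2go, paths["gene2go"])
        mcio.write_obo(self.go_terms, paths["go_dag"])
        self.truth.to_json(paths["truth"])
        self.config.to_yaml(paths["config"])
        return paths


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), length, p=probs)


def _place_nonoverlapping(rng, scaffold_length, lengths) -> list[int]:
    """Random non-overlapping starts for features of the given lengths."""
    total = int(sum(lengths))
    n = len(lengths)
    free = scaffold_length - total
    if free < 0:
        raise ConfigurationError(
            f"infeasible packing: features need {total} bp but the scaffold "
            f"is {scaffold_length} bp"
        )
    if n == 0:
        return []
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts, pos = [], 0
    for gap, length in zip(gaps[:-1], lengths):
        pos += int(gap)
        starts.append(pos)
        pos += int(length)
    return starts


def _make_exons(rng, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """Split a gene span into >=2 exons separated by introns (>=20 bp each)."""
    length = end - start
    n_exons = int(rng.integers(2, 5))
    while n_exons > 2 and length < (2 * n_exons - 1) * 20:
        n_exons -= 1
    n_chunks = 2 * n_exons - 1
    if length < n_chunks * 20:
        return ((start, end),)
    extra = rng.multinomial(length - n_chunks * 20, np.full(n_chunks, 1.0 / n_chunks))
    sizes = extra + 20
    exons, pos = [], start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(size)))
        pos += int(size)
    return tuple(exons)


class _Occupied:
    """Per-scaffold registry of occupied intervals for rejection sampling."""

    def __init__(self):
        self._by_scaffold: dict[str, list[tuple[int, int]]] = {}

    def add(self, scaffold: str, start: int, end: int) -> None:
        insort(self._by_scaffold.setdefault(scaffold, []), (start, end))

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        # stored intervals are mutually disjoint, so only the neighbours of
        # the insertion point can overlap the query
        ivs = self._by_scaffold.get(scaffold, [])
        i = bisect_left(ivs, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(ivs) and ivs[j][0] < end and start < ivs[j][1]:
                return True
        return False


def generate_genome(config: SyntheticConfig) -> GenomeBundle:
    """Generate scaffolds, gene models, transposons, GO annotations and truth."""
    rng = _rng(config.seed, 0)
    names = [f"scaffold_{i:04d}" for i in range(config.n_scaffolds)]
    spread = config.scaffold_length_spread
    scaffold_len = {
        name: max(
            1,
            int(
                round(
                    config.scaffold_length
                    * float(rng.uniform(1 - spread, 1 + spread))
                )
            ),
        )
        for name in names
    }
    arrays = {
        name: _random_sequence(rng, scaffold_len[name], config.gc_fraction)
        for name in names
    }

    truth = PlantedTruth()
    occupied = _Occupied()
    genes: list[Gene] = []
    transposons: list[Transposon] = []

    # genes and transposons, packed without overlap on each scaffold;
    # per-scaffold counts scale with the scaffold's length
    for si, name in enumerate(names):
        scale = scaffold_len[name] / config.scaffold_length
        n_genes = int(round(config.n_genes_per_scaffold * scale))
        if config.n_genes_per_scaffold > 0 and spread > 0:
            n_genes = max(1, n_genes)
        n_te = int(round(config.n_transposons_per_scaffold * scale))
        gene_lengths = rng.integers(
            config.gene_length_range[0],
            config.gene_length_range[1] + 1,
            size=n_genes,
        )
        te_lengths = rng.integers(
            config.transposon_length_range[0],
            config.transposon_length_range[1] + 1,
            size=n_te,
        )
        kinds = ["gene"] * len(gene_lengths) + ["te"] * len(te_lengths)
        lengths = list(gene_lengths) + list(te_lengths)
        order = rng.permutation(len(kinds))
        kinds = [kinds[i] for i in order]
        lengths = [int(lengths[i]) for i in order]
        starts = _place_nonoverlapping(rng, scaffold_len[name], lengths)
        gi = ti = 0
        for kind, start, length in zip(kinds, starts, lengths):
            end = start + length
            occupied.add(name, start, end)
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    Gene(
                        gene_id=f"g{si:03d}_{gi:03d}",
                        scaffold=name,
                        start=start,
                        end=end,
                        strand=strand,
                        exons=_make_exons(rng, start, end),
                    )
                )
                gi += 1
            else:
                transposons.append(
                    Transposon(
                        te_id=f"te{si:03d}_{ti:03d}",
                        scaffold=name,
                        start=start,
                        end=end,
                    )
                )
                ti += 1

    # planted repeat units at exact copy numbers, in unoccupied space
    unit_len = config.repeat_unit_length
    for ri, copies in enumerate(config.repeat_copy_numbers):
        unit_id = f"repeat_{ri}"
        for _attempt in range(20):
            unit_arr = _random_sequence(rng, unit_len, config.gc_fraction)
            unit = unit_arr.tobytes().decode()
            background = sum(
                arrays[n].tobytes().decode().count(s)
                for n in names
                for s in (unit, reverse_complement(unit))
            )
            if background == 0 and unit not in truth.repeat_units.values():
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError(
                f"could not draw a unique repeat unit of {unit_len} bp"
            )
        locations = []
        for _copy in range(copies):
            for _try in range(10_000):
                name = names[int(rng.integers(len(names)))]
                if scaffold_len[name] < unit_len:
                    continue
                start = int(
                    rng.integers(0, scaffold_len[name] - unit_len + 1)
                )
                if not occupied.overlaps(name, start, start + unit_len):
                    break
            else:
                raise ConfigurationError(
                    "infeasible packing: no free space left for repeat "
                    f"unit {unit_id} ({copies} copies of {unit_len} bp)"
                )
            occupied.add(name, start, start + unit_len)
            arrays[name][start : start + unit_len] = unit_arr
            locations.append((name, start))
        truth.repeat_units[unit_id] = unit
        truth.repeat_locations[unit_id] = sorted(locations)

    scaffolds = {name: arrays[name].tobytes().decode() for name in names}

    # verify planted copy numbers against the finished sequence
    for unit_id, unit in truth.repeat_units.items():
        found = sum(scaffolds[n].count(unit) for n in names)
        if found != len(truth.repeat_locations[unit_id]):
            raise ConfigurationError(
                f"repeat {unit_id} occurs {found} times, expected "
                f"{len(truth.repeat_locations[unit_id])}"
            )

    # methylation hot spots: shared between variants or specific to one.
    # Each scaffold has a latent methylation direction; a specific hot spot
    # follows it with probability hotspot_direction_bias (0.5 = variants
    # fully independent).  Hot-spot lengths vary around the configured mean
    # so per-scaffold coverage imbalances are rarely exact ties.
    for name in names:
        truth.scaffold_direction[name] = (
            "green" if rng.random() < 0.5 else "orange"
        )
    for v in VARIANTS:
        truth.hotspot_intervals[v] = []
    def _draw_hotspot(scaffold_name: str):
        L = len(scaffolds[scaffold_name])
        length = int(
            rng.integers(
                max(1, config.hotspot_length // 2),
                config.hotspot_length * 3 // 2 + 1,
            )
        )
        start = int(rng.integers(0, max(1, L - 1)))
        return (
            scaffold_name,
            start,
            min(start + length, L),
            config.fragment_capture_bias,
        )

    for name in names:
        direction = truth.scaffold_direction[name]
        other = "orange" if direction == "green" else "green"
        n_hot = int(round(config.hotspot_density * len(scaffolds[name]) / 1e5))
        if n_hot == 0:
            continue
        # shared hot spots sit at the same coordinates in both variants;
        # each variant's specific hot spots are drawn independently
        # (Poisson counts, fresh positions), so at direction bias 0.5 the
        # two variants' specific methylation is fully independent
        n_shared = int(rng.binomial(n_hot, config.shared_hotspot_fraction))
        for _h in range(n_shared):
            interval = _draw_hotspot(name)
            for v in VARIANTS:
                truth.hotspot_intervals[v].append(interval)
        lam_specific = (1 - config.shared_hotspot_fraction) * n_hot
        n_direction = int(
            rng.poisson(2 * config.hotspot_direction_bias * lam_specific)
        )
        n_other = int(
            rng.poisson(2 * (1 - config.hotspot_direction_bias) * lam_specific)
        )
        for variant, n_specific in ((direction, n_direction), (other, n_other)):
            for _h in range(n_specific):
                truth.hotspot_intervals[variant].append(_draw_hotspot(name))

    # record genes whose body/promoter overlaps a variant-specific hot spot
    shared = set(truth.hotspot_intervals["orange"]) & set(
        truth.hotspot_intervals["green"]
    )
    def _union_coverage(ivs: list[tuple[int, int]], lo: int, hi: int) -> int:
        covered, cursor = 0, lo
        for s, e in sorted(ivs):
            s, e = max(s, cursor), min(e, hi)
            if s < e:
                covered += e - s
                cursor = e
        return covered

    # a gene counts as planted-shifted only when the specific hot-spot
    # coverage implies an expected capture fold comfortably above the
    # two-fold call threshold (x1.5 margin, so genes at the decision
    # boundary are not asserted as truth):
    # fold = (C*(bias-1) + R) / R for coverage C of region R
    shift_candidates: dict[str, set[tuple[str, str]]] = {}
    bias = config.fragment_capture_bias
    min_planted_fold = 2.0 * 1.5
    for variant in VARIANTS:
        specific = [
            iv for iv in truth.hotspot_intervals[variant] if iv not in shared
        ]
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for name, start, end, _w in specific:
            by_scaffold.setdefault(name, []).append((start, end))
        for gene in genes:
            ivs = by_scaffold.get(gene.scaffold, [])
            if not ivs:
                continue
            if gene.strand == "+":
                prom = (max(0, gene.start - 2000), gene.start)
            else:
                prom = (gene.end, gene.end + 2000)
            for region, (lo, hi) in (
                ("body", (gene.start, gene.end)),
                ("promoter", prom),
            ):
                length = hi - lo
                if length <= 0:
                    continue
                covered = _union_coverage(ivs, lo, hi)
                fold = (covered * (bias - 1) + length) / length
                if fold >= min_planted_fold:
                    shift_candidates.setdefault(gene.gene_id, set()).add(
                        (region, variant)
                    )
    # genes touched by specific hot spots of both variants have no
    # well-defined planted direction and are left out of the truth
    for gene_id, entries in shift_candidates.items():
        variants_hit = {v for _r, v in entries}
        if len(variants_hit) == 1:
            body_first = sorted(entries)  # 'body' sorts before 'promoter'
            truth.methylation_shift_genes[gene_id] = body_first[0]

    # planted differential expression, inversely coupled to methylation
    genes_by_scaffold: dict[str, list[Gene]] = {}
    for gene in genes:
        genes_by_scaffold.setdefault(gene.scaffold, []).append(gene)
    for name in names:
        pool = genes_by_scaffold.get(name, [])
        n_de = int(round(config.de_gene_fraction * len(pool)))
        if config.de_gene_fraction > 0 and pool:
            n_de = max(1, n_de)
        if not pool or n_de == 0:
            continue
        chosen = rng.choice(len(pool), size=min(n_de, len(pool)), replace=False)
        meth_dir = truth.scaffold_direction[name]
        inverse = "green" if meth_dir == "orange" else "orange"
        for idx in sorted(int(i) for i in chosen):
            direction = (
                inverse
                if rng.random() < config.methylation_expression_coupling
                else meth_dir
            )
            truth.de_genes[pool[idx].gene_id] = (
                direction,
                config.de_fold_change,
            )

    # GO DAG: one root per namespace, random is_a parents within namespace
    go_terms: dict[str, tuple[str, str, tuple[str, ...]]] = {}
    ids = [f"GO:{i + 1:07d}" for i in range(config.go_term_count)]
    by_namespace: dict[str, list[str]] = {ns: [] for ns in GO_NAMESPACES}
    for i, term_id in enumerate(ids):
        ns = GO_NAMESPACES[i % 3]
        if not by_namespace[ns]:
            parents: tuple[str, ...] = ()
        else:
            n_par = 1 if (rng.random() < 0.7 or len(by_namespace[ns]) < 2) else 2
            picks = rng.choice(len(by_namespace[ns]), size=n_par, replace=False)
            parents = tuple(sorted(by_namespace[ns][int(p)] for p in picks))
        go_terms[term_id] = (f"synthetic term {i + 1}", ns, parents)
        by_namespace[ns].append(term_id)

    # baseline annotations: 1-3 random non-root terms per gene
    non_root = [t for t in ids if go_terms[t][2]]
    gene2go: dict[str, set[str]] = {}
    for gene in genes:
        n_terms = int(rng.integers(1, 4))
        if non_root:
            picks = rng.choice(
                len(non_root), size=min(n_terms, len(non_root)), replace=False
            )
            gene2go[gene.gene_id] = {non_root[int(p)] for p in picks}
        else:
            gene2go[gene.gene_id] = {ids[0]} if ids else set()

    # planted enrichment: leaf terms annotated to most of one DE direction
    parents_used = {p for t in ids for p in go_terms[t][2]}
    leaves = [t for t in non_root if t not in parents_used]
    de_up = sorted(g for g, (d, _f) in truth.de_genes.items() if d == "green")
    de_down = sorted(
        g for g, (d, _f) in truth.de_genes.items() if d == "orange"
    )
    all_gene_ids = [g.gene_id for g in genes]
    for j in range(config.planted_enriched_terms):
        if not leaves or not (de_up or de_down):
            break
        term = leaves[int(rng.integers(len(leaves)))]
        leaves.remove(term)
        group = de_up if (j % 2 == 0 and de_up) or not de_down else de_down
        direction = "green" if group is de_up else "orange"
        for gene_id in group:
            if rng.random() < 0.8:
                gene2go[gene_id].add(term)
        for gene_id in all_gene_ids:
            if gene_id not in group and rng.random() < 0.05:
                gene2go[gene_id].add(term)
        truth.enriched_terms[term] = direction

    # internal-control contig sources: non-DE genes
    non_de = [g for g in genes if g.gene_id not in truth.de_genes]
    lo, hi = config.contig_length_range
    for ci in range(config.control_contig_count):
        if not non_de:
            break
        gene = non_de[int(rng.integers(len(non_de)))]
        glen = gene.end - gene.start
        length = int(rng.integers(lo, hi + 1))
        length = min(length, glen)
        offset = int(rng.integers(0, glen - length + 1))
        truth.control_contigs[f"ctrl_{ci:04d}"] = (
            gene.gene_id,
            offset,
            length,
        )

    return GenomeBundle(
        config=config,
        scaffolds=scaffolds,
        genes=genes,
        transposons=transposons,
        gene2go=gene2go,
        go_terms=go_terms,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# methylome read simulation
# ---------------------------------------------------------------------------


def msei_fragments(sequence: str) -> list[tuple[int, int]]:
    """Maximal intervals between successive MseI cuts (T^TAA), tiling the
    sequence: fragment ends/starts sit between the T and the TAA of each
    TTAA site."""
    cuts = []
    i = sequence.find(MSEI_SITE)
    while i != -1:
        cuts.append(i + MSEI_CUT_OFFSET)
        i = sequence.find(MSEI_SITE, i + 1)
    fragments, prev = [], 0
    for cut in cuts:
        fragments.append((prev, cut))
        prev = cut
    fragments.append((prev, len(sequence)))
    return fragments


def simulate_methylome_reads(
    bundle: GenomeBundle,
    truth: PlantedTruth,
    variant: str,
    seed: int,
) -> tuple[list[MethylRead], pd.DataFrame]:
    """Draw methylome reads for one variant.

    Fragments come from the MseI digest of every scaffold; fragments
    shorter than ``min_fragment_length`` are dropped (pyrosequencing
    read-length realism).  Each kept fragment has sampling weight 1,
    multiplied by ``fragment_capture_bias`` when it overlaps a hot spot of
    this variant; copy counts are one multinomial draw of
    ``reads_per_variant`` reads.  Emitted reads are fragment sequences on a
    random strand.

    Returns the reads plus a per-fragment table (scaffold, start, end,
    weight, copy count, orientation).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    config = bundle.config
    rng = _rng(seed, 1 if variant == "green" else 2)

    hotspots: dict[str, list[tuple[int, int]]] = {}
    for name, start, end, _w in truth.hotspot_intervals.get(variant, []):
        hotspots.setdefault(name, []).append((start, end))

    rows = []
    for name, seq in bundle.scaffolds.items():
        fragments = msei_fragments(seq)
        if len(fragments) == 1:
            logger.warning(
                "scaffold %s has no %s site: using it whole", name, MSEI_SITE
            )
        ivs = hotspots.get(name, [])
        for start, end in fragments:
            if end - start < config.min_fragment_length:
                continue
            hot = any(s < end and start < e for s, e in ivs)
            weight = config.fragment_capture_bias if hot else 1.0
            rows.append((name, start, end, weight))
    table = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "weight"]
    )
    if len(table) == 0:
        raise ConfigurationError(
            "no fragment survives min_fragment_length; nothing to sequence"
        )
    weights = table["weight"].to_numpy()
    counts = rng.multinomial(config.reads_per_variant, weights / weights.sum())
    flips = rng.random(len(table)) < 0.5
    table["copy_count"] = counts
    table["orientation"] = np.where(flips, "-", "+")

    reads = []
    for j, row in enumerate(table.itertuples(index=False)):
        if row.copy_count == 0:
            continue
        frag = bundle.scaffolds[row.scaffold][row.start : row.end]
        if row.orientation == "-":
            frag = reverse_complement(frag)
        reads.append(
            MethylRead(
                read_id=f"{variant}_r{j:06d}",
                sequence=frag,
                variant=variant,
                copy_count=int(row.copy_count),
            )
        )
    return reads, table


def write_methyl_reads(reads: list[MethylRead], fasta_path, tsv_path) -> None:
    """Distinct-read FASTA plus the copy-count side table."""
    mcio.write_fasta({r.read_id: r.sequence for r in reads}, fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("read_id\tcopy_count\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.copy_count}\n")


# ---------------------------------------------------------------------------
# SSH library simulation
# ---------------------------------------------------------------------------


def simulate_ssh_libraries(
    bundle: GenomeBundle,
    truth: PlantedTruth,
    seed: int,
    green_multiplier: float | None = None,
):
    """Per-variant SSH contig libraries with planted truth.

    Control contigs are identical sequences in both libraries with low,
    nearly equal counts; the green library's counts are globally scaled by
    ``green_multiplier`` (library-size imbalance, recorded in truth).
    Each planted differential gene contributes one high-count contig to the
    library of its planted direction only.
    """
    from .transcriptome_ssh import SSHContig

    config = bundle.config
    if config.de_gene_fraction == 0 and config.planted_enriched_terms > 0:
        raise ConfigurationError(
            "cannot plant enriched terms without differential genes"
        )
    mult = (
        config.green_library_multiplier
        if green_multiplier is None
        else float(green_multiplier)
    )
    if mult <= 0:
        raise ConfigurationError("library multiplier must be > 0")
    truth.library_multiplier = mult
    rng = _rng(seed, 3)
    genes_by_id = {g.gene_id: g for g in bundle.genes}
    libraries: dict[str, list[SSHContig]] = {v: [] for v in VARIANTS}

    def _scale_green(base: int) -> int:
        return max(1, int(math.floor(mult * base + 0.5)))

    lo, hi = config.control_count_range
    for cid in sorted(truth.control_contigs):
        gene_id, offset, length = truth.control_contigs[cid]
        gene = genes_by_id[gene_id]
        seq = bundle.gene_sequence(gene)[offset : offset + length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        base = int(rng.integers(lo, hi + 1))
        orange_count = max(1, base + int(rng.integers(-1, 2)))
        green_count = _scale_green(base + int(rng.integers(-1, 2)))
        libraries["orange"].append(
            SSHContig(
                contig_id=f"{cid}_orange",
                variant="orange",
                sequence=seq,
                read_count=orange_count,
            )
        )
        libraries["green"].append(
            SSHContig(
                contig_id=f"{cid}_green",
                variant="green",
                sequence=seq,
                read_count=green_count,
            )
        )

    clo, chi = config.contig_length_range
    for gene_id in sorted(truth.de_genes):
        direction, _fold = truth.de_genes[gene_id]
        gene = genes_by_id[gene_id]
        glen = gene.end - gene.start
        length = min(int(rng.integers(clo, chi + 1)), glen)
        offset = int(rng.integers(0, glen - length + 1))
        seq = bundle.gene_sequence(gene)[offset : offset + length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        # planted strong genes sit with a margin above the strong threshold
        # so the planted class stays well defined under calibration rounding
        base = int(
            rng.integers(
                config.strong_read_floor + config.strong_read_floor // 4,
                2 * config.strong_read_floor + 1,
            )
        )
        count = _scale_green(base) if direction == "green" else base
        libraries[direction].append(
            SSHContig(
                contig_id=f"de_{gene_id}",
                variant=direction,
                sequence=seq,
                read_count=count,
            )
        )
    return libraries


def simulate_study(
    config: SyntheticConfig,
    outdir,
    green_multiplier: float | None = None,
):
    """Generate and write the complete study: genome bundle, per-variant
    methylome reads and SSH libraries.

    Returns ``(bundle, manifest)`` where the manifest maps the pipeline's
    input keys to the written file paths (also saved as manifest.yaml).
    """
    outdir = Path(outdir)
    bundle = generate_genome(config)
    paths = bundle.write(outdir)
    manifest = {
        key: str(paths[key])
        for key in ("scaffolds", "genes", "transposons", "gene2go", "go_dag")
    }
    for variant in VARIANTS:
        reads, _table = simulate_methylome_reads(
            bundle, bundle.truth, variant, config.seed
        )
        fasta = outdir / f"methyl_{variant}.fa"
        tsv = outdir / f"methyl_{variant}.counts.tsv"
        write_methyl_reads(reads, fasta, tsv)
        manifest[f"methyl_reads_{variant}"] = str(fasta)
        manifest[f"methyl_counts_{variant}"] = str(tsv)
    libraries = simulate_ssh_libraries(
        bundle, bundle.truth, config.seed, green_multiplier
    )
    bundle.truth.to_json(paths["truth"])  # now includes the multiplier
    for variant in VARIANTS:
        fasta = outdir / f"contigs_{variant}.fa"
        tsv = outdir / f"contigs_{variant}.counts.tsv"
        write_ssh_library(libraries[variant], fasta, tsv)
        manifest[f"contigs_{variant}"] = str(fasta)
        manifest[f"contig_counts_{variant}"] = str(tsv)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return bundle, manifest


def write_ssh_library(contigs, fasta_path, tsv_path) -> None:
    mcio.write_fasta({c.contig_id: c.sequence for c in contigs}, fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("contig_id\tread_count\n")
        for c in contigs:
            fh.write(f"{c.contig_id}\t{c.read_count}\n")
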