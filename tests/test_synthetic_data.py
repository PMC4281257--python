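"""Generator contracts: determinism, fragment tiling, planted truth."""

import dataclasses

import numpy as np
import pytest

from methclone.io import read_gff3, write_gff3
from methclone.synthetic_data import (
    VARIANTS,
    ConfigurationError,
    PlantedTruth,
    SyntheticConfig,
    generate_genome,
    msei_fragments,
    simulate_methylome_reads,
    simulate_ssh_libraries,
)


def test_msei_cut_rule_hand_example():
    # "AATTAACC": TTAA at offset 2, cut between T and TAA
    assert msei_fragments("AATTAACC") == [(0, 3), (3, 8)]
    seq = "AATTAACC"
    frags = [seq[s:e] for s, e in msei_fragments(seq)]
    assert frags == ["AAT", "TAACC"]


def test_msei_fragments_tile_sequence():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 5000))
    frags = msei_fragments(seq)
    assert frags[0][0] == 0 and frags[-1][1] == len(seq)
    for (s1, e1), (s2, e2) in zip(frags, frags[1:]):
        assert e1 == s2  # ordered, non-overlapping, gap-free
    assert "".join(seq[s:e] for s, e in frags) == seq


def test_msei_no_site_single_fragment():
    assert msei_fragments("ACGCGCGC") == [(0, 8)]


def test_generate_genome_deterministic(small_config, tmp_path):
    b1 = generate_genome(small_config)
    b2 = generate_genome(dataclasses.replace(small_config))
    assert b1.scaffolds == b2.scaffolds
    assert b1.genes == b2.genes
    assert b1.truth.de_genes == b2.truth.de_genes
    # byte-identical serialized FASTA
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    from methclone.io import write_fasta

    write_fasta(b1.scaffolds, p1)
    write_fasta(b2.scaffolds, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_repeat_truth_exact_copy_numbers(small_bundle, small_config):
    truth = small_bundle.truth
    for unit_id, copies in zip(
        sorted(truth.repeat_units), small_config.repeat_copy_numbers
    ):
        locations = truth.repeat_locations[unit_id]
        assert len(locations) == copies
        unit = truth.repeat_units[unit_id]
        # genome-wide occurrence count equals the planted copy number
        found = sum(
            seq.count(unit) for seq in small_bundle.scaffolds.values()
        )
        assert found == copies
        for scaffold, start in locations:
            assert (
                small_bundle.scaffolds[scaffold][start : start + len(unit)]
                == unit
            )


def test_zero_genes_gives_header_only_gff(tmp_path):
    config = SyntheticConfig(
        seed=1,
        n_scaffolds=2,
        scaffold_length=5_000,
        scaffold_length_spread=0.0,
        n_genes_per_scaffold=0,
        n_transposons_per_scaffold=0,
        repeat_copy_numbers=(),
        control_contig_count=0,
        de_gene_fraction=0.0,
        planted_enriched_terms=0,
        reads_per_variant=100,
    )
    bundle = generate_genome(config)
    path = tmp_path / "genes.gff3"
    write_gff3(bundle.genes, path)
    lines = path.read_text().splitlines()
    assert lines == ["##gff-version 3"]


def test_infeasible_packing_raises():
    config = SyntheticConfig(
        seed=1,
        n_scaffolds=1,
        scaffold_length=2_000,
        scaffold_length_spread=0.0,
        n_genes_per_scaffold=10,
        reads_per_variant=100,
    )
    with pytest.raises(ConfigurationError, match="packing"):
        generate_genome(config)


def test_invalid_proportion_rejected():
    with pytest.raises(ConfigurationError, match="gc_fraction"):
        SyntheticConfig(gc_fraction=1.5)


def test_enriched_terms_require_de_genes():
    with pytest.raises(ConfigurationError, match="enriched"):
        SyntheticConfig(de_gene_fraction=0.0, planted_enriched_terms=1)


def test_truth_references_exist(small_bundle):
    truth = small_bundle.truth
    gene_ids = {g.gene_id for g in small_bundle.genes}
    assert set(truth.de_genes) <= gene_ids
    assert set(truth.methylation_shift_genes) <= gene_ids
    assert set(truth.enriched_terms) <= set(small_bundle.go_terms)
    for gene_id, _off, _len in truth.control_contigs.values():
        assert gene_id in gene_ids
    for variant in VARIANTS:
        for scaffold, start, end, _w in truth.hotspot_intervals[variant]:
            assert 0 <= start < end <= len(small_bundle.scaffolds[scaffold])


def test_truth_round_trips_through_json(small_bundle, tmp_path):
    path = tmp_path / "truth.json"
    small_bundle.truth.to_json(path)
    assert PlantedTruth.from_json(path) == small_bundle.truth


def test_gff3_round_trip(small_bundle, tmp_path):
    path = tmp_path / "genes.gff3"
    write_gff3(small_bundle.genes, path)
    recovered = sorted(read_gff3(path), key=lambda g: g.gene_id)
    original = sorted(small_bundle.genes, key=lambda g: g.gene_id)
    assert recovered == original


def test_read_copy_counts_conserved(small_bundle, small_config):
    reads, table = simulate_methylome_reads(
        small_bundle, small_bundle.truth, "green", small_config.seed
    )
    assert sum(r.copy_count for r in reads) == small_config.reads_per_variant
    assert table["copy_count"].sum() == small_config.reads_per_variant
    # all emitted fragments respect the length floor
    assert (
        (table["end"] - table["start"]) >= small_config.min_fragment_length
    ).all()


def test_hotspot_fragments_carry_capture_bias(small_bundle, small_config):
    _reads, table = simulate_methylome_reads(
        small_bundle, small_bundle.truth, "orange", small_config.seed
    )
    weights = set(table["weight"].unique())
    assert weights <= {1.0, small_config.fragment_capture_bias}
    hot = table[table["weight"] > 1]
    assert len(hot) > 0
    # every biased fragment overlaps an orange hot spot
    hotspots = {}
    for name, s, e, _w in small_bundle.truth.hotspot_intervals["orange"]:
        hotspots.setdefault(name, []).append((s, e))
    for row in hot.itertuples(index=False):
        assert any(
            s < row.end and row.start < e
            for s, e in hotspots.get(row.scaffold, [])
        )


def test_identical_fragment_weights_across_variants_when_fully_shared():
    config = SyntheticConfig(
        seed=3,
        n_scaffolds=3,
        scaffold_length=20_000,
        scaffold_length_spread=0.0,
        n_genes_per_scaffold=3,
        n_transposons_per_scaffold=1,
        shared_hotspot_fraction=1.0,
        reads_per_variant=20_000,
        control_contig_count=10,
        go_term_count=30,
        planted_enriched_terms=0,
        de_gene_fraction=0.1,
    )
    bundle = generate_genome(config)
    _ro, to = simulate_methylome_reads(bundle, bundle.truth, "orange", 3)
    _rg, tg = simulate_methylome_reads(bundle, bundle.truth, "green", 3)
    # fully shared hot spots: identical per-fragment expected weights, so
    # observed count differences stay within binomial sampling error
    assert (to["weight"] == tg["weight"]).all()
    p = to["weight"] / to["weight"].sum()
    expected = config.reads_per_variant * p
    sigma = np.sqrt(2 * config.reads_per_variant * p * (1 - p))
    diff = (to["copy_count"] - tg["copy_count"]).abs()
    assert (diff <= np.maximum(6 * sigma, 12)).all()


def test_ssh_control_pairs_identical_sequences(small_bundle, small_config):
    libs = simulate_ssh_libraries(
        small_bundle, small_bundle.truth, small_config.seed
    )
    by_id = {
        v: {c.contig_id: c for c in libs[v]} for v in VARIANTS
    }
    for cid in small_bundle.truth.control_contigs:
        orange = by_id["orange"][f"{cid}_orange"]
        green = by_id["green"][f"{cid}_green"]
        assert orange.sequence in (
            green.sequence,
            # either orientation may have been emitted
            green.sequence.translate(
                str.maketrans("ACGT", "TGCA")
            )[::-1],
        )


def test_ssh_library_multiplier_scales_green_controls(small_bundle):
    truth = small_bundle.truth
    libs = simulate_ssh_libraries(
        small_bundle, truth, seed=9, green_multiplier=2.0
    )
    assert truth.library_multiplier == 2.0
    control_ids = set(truth.control_contigs)
    orange_sum = sum(
        c.read_count
        for c in libs["orange"]
        if c.contig_id.rsplit("_", 1)[0] in control_ids
    )
    green_sum = sum(
        c.read_count
        for c in libs["green"]
        if c.contig_id.rsplit("_", 1)[0] in control_ids
    )
    assert green_sum / orange_sum == pytest.approx(2.0, rel=0.15)


def test_ssh_de_contigs_present_in_one_library_only(
    small_bundle, small_config
):
    libs = simulate_ssh_libraries(
        small_bundle, small_bundle.truth, small_config.seed
    )
    ids = {v: {c.contig_id for c in libs[v]} for v in VARIANTS}
    for gene_id, (direction, _fold) in small_bundle.truth.de_genes.items():
        other = "orange" if direction == "green" else "green"
        assert f"de_{gene_id}" in ids[direction]
        assert f"de_{gene_id}" not in ids[other]
        contig = next(
            c for c in libs[direction] if c.contig_id == f"de_{gene_id}"
        )
        assert contig.read_count >= 20
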