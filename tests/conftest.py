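"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (string
scanning, quadratic interval overlap, exhaustive subset enumeration) kept
separate from the package so they can arbitrate its optimized code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import pytest

from methclone.synthetic_data import SyntheticConfig, generate_genome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_placements(read: str, scaffolds: dict[str, str], max_mism: int):
    """All-positions, both-strand Hamming scan by plain string comparison."""
    hits = set()
    for strand, query in (("+", read), ("-", revcomp(read))):
        for name, seq in scaffolds.items():
            for start in range(len(seq) - len(query) + 1):
                window = seq[start : start + len(query)]
                mism = sum(
                    1
                    for a, b in zip(window, query)
                    if a != b or a == "N" or b == "N"
                )
                if mism <= max_mism:
                    hits.add((name, start, start + len(query), strand, mism))
    return hits


def oracle_overlap_hits(placements, intervals):
    """Quadratic placement-vs-interval overlap count.

    ``placements``: (scaffold, start, end, weight); ``intervals``:
    (scaffold, start, end, feature).  Returns {feature: weighted hits}.
    """
    counts: dict[str, int] = {}
    for p_scaffold, p_start, p_end, weight in placements:
        for i_scaffold, i_start, i_end, feature in intervals:
            if (
                p_scaffold == i_scaffold
                and p_start < i_end
                and i_start < p_end
            ):
                counts[feature] = counts.get(feature, 0) + weight
    return counts


def oracle_hypergeom_upper_tail(N: int, m: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) subsets."""
    marked = set(range(m))
    favourable = sum(
        1
        for subset in combinations(range(N), n)
        if len(marked.intersection(subset)) >= k
    )
    return favourable / comb(N, n)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast, fully featured bundle configuration reused across tests."""
    return SyntheticConfig(
        seed=42,
        n_scaffolds=5,
        scaffold_length=20_000,
        scaffold_length_spread=0.4,
        n_genes_per_scaffold=5,
        n_transposons_per_scaffold=2,
        reads_per_variant=30_000,
        control_contig_count=50,
        go_term_count=60,
        planted_enriched_terms=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_genome(small_config)
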