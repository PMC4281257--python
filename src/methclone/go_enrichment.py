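"""Hypergeometric GO-term enrichment over expression x methylation lists.

Gene lists are built by crossing differential-expression classes with
two-fold methylation change classes (gene body or promoter), then each GO
term is tested with the one-sided hypergeometric upper tail: with N
background genes of which m carry the term, the p-value of seeing k or
more annotated genes in a list of n is P(X >= k), X ~ Hypergeom(N, m, n).
Annotations are first closed under is_a ancestry (true-path rule) so m and
k are DAG-consistent.  Raw p-values against alpha are the primary flag;
Benjamini-Hochberg q-values are reported alongside but never silently
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NAMESPACES = (
    "biological_process",
    "molecular_function",
    "cellular_component",
)


@dataclass
class GODag:
    """A GO DAG restricted to id, name, namespace and is_a parents."""

    terms: dict[str, tuple[str, str, tuple[str, ...]]]

    def __post_init__(self):
        for term_id, (_name, namespace, parents) in self.terms.items():
            if namespace not in NAMESPACES:
                raise ValueError(
                    f"term {term_id}: unknown namespace {namespace!r}"
                )
            for parent in parents:
                if parent not in self.terms:
                    raise ValueError(
                        f"term {term_id}: parent {parent} not in DAG"
                    )
        self._assert_acyclic()
        self._ancestors_of = lru_cache(maxsize=None)(self._ancestors_uncached)

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(term: str) -> None:
            state[term] = 1
            for parent in self.terms[term][2]:
                s = state.get(parent, 0)
                if s == 1:
                    raise ValueError(f"cycle in DAG through {parent}")
                if s == 0:
                    visit(parent)
            state[term] = 2

        for term in self.terms:
            if state.get(term, 0) == 0:
                visit(term)

    @property
    def roots(self) -> dict[str, str]:
        """namespace -> root term id (a term with no parents)."""
        out = {}
        for term_id, (_n, namespace, parents) in self.terms.items():
            if not parents:
                out[namespace] = term_id
        return out

    def _ancestors_uncached(self, term_id: str) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self.terms[term_id][2])
        while stack:
            parent = stack.pop()
            if parent not in out:
                out.add(parent)
                stack.extend(self.terms[parent][2])
        return frozenset(out)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a ancestors of a term (excluding the term itself)."""
        return self._ancestors_of(term_id)

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    @classmethod
    def from_obo(cls, path) -> "GODag":
        """Parse an OBO file with obonet, keeping only is_a edges.

        Other relationship types (part_of, regulates, ...) are ignored
        with a warning.
        """
        import obonet

        graph = obonet.read_obo(str(path))
        dropped_relations: set[str] = set()
        terms: dict[str, tuple[str, str, tuple[str, ...]]] = {}
        for node, data in graph.nodes(data=True):
            parents = []
            for _child, parent, relation in graph.out_edges(node, keys=True):
                if relation == "is_a":
                    parents.append(parent)
                else:
                    dropped_relations.add(relation)
            terms[node] = (
                data.get("name", node),
                data.get("namespace", "biological_process"),
                tuple(sorted(parents)),
            )
        if dropped_relations:
            logger.warning(
                "ignoring non-is_a relationships: %s",
                ", ".join(sorted(dropped_relations)),
            )
        return cls(terms=terms)


def propagate_annotations(
    gene_to_terms: dict[str, set[str]], dag: GODag
) -> dict[str, set[str]]:
    """Close each gene's annotation set under is_a ancestry (true-path rule).

    Annotations to unknown terms are dropped with a warning.  Idempotent.
    """
    closure: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        closed: set[str] = set()
        for term in terms:
            if term not in dag.terms:
                logger.warning(
                    "gene %s annotated to unknown term %s: dropped",
                    gene,
                    term,
                )
                continue
            closed.add(term)
            closed |= dag.ancestors(term)
        closure[gene] = closed
    return closure


def hypergeometric_pvalue(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeom(N, m, n), including k itself.

    Computed through scipy's log-space survival function, stable up to
    N ~ 10^6.
    """
    if not 0 <= k:
        raise ValueError(f"k must be >= 0, got k={k}")
    if k > min(m, n):
        raise ValueError(f"k <= min(m, n) violated: k={k}, m={m}, n={n}")
    if m > N:
        raise ValueError(f"m <= N violated: m={m}, N={N}")
    if n > N:
        raise ValueError(f"n <= N violated: n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


@dataclass
class CrossList:
    """A gene list defined by an expression class and a methylation filter."""

    list_id: str
    expression: str  # 'up' or 'down' (green relative to orange)
    methylation: tuple[str, str] | None  # (region, 'up'|'down') or None
    genes: set[str] = field(default_factory=set)


_STRINGENCY = {
    "strong": ("strong",),
    "slight": ("strong", "slight"),
    "moderate": ("strong", "slight", "moderate"),
}


def build_cross_lists(
    expression_records,
    methylation_records,
    stringency: str = "strong",
) -> list[CrossList]:
    """The list family {up, down} x {no filter, meth up, meth down} x
    {body, promoter}.

    Stringency is cumulative: 'slight' includes strong genes, 'moderate'
    includes both.  Methylation directions refer to green vs orange
    (up = two-fold more methyl reads in green).
    """
    if stringency not in _STRINGENCY:
        raise ValueError(f"unknown stringency {stringency!r}")
    levels = _STRINGENCY[stringency]
    expr_genes = {"up": set(), "down": set()}
    for record in expression_records:
        for level in levels:
            for direction in ("up", "down"):
                if record.expression_class == f"{level}_{direction}_green":
                    expr_genes[direction].add(record.gene_id)
    meth_genes: dict[tuple[str, str], set[str]] = {
        (region, direction): set()
        for region in ("body", "promoter")
        for direction in ("up", "down")
    }
    for record in methylation_records:
        for region, cls in (
            ("body", record.body_class),
            ("promoter", record.promoter_class),
        ):
            if cls == "up2x_green":
                meth_genes[(region, "up")].add(record.gene_id)
            elif cls == "down2x_green":
                meth_genes[(region, "down")].add(record.gene_id)

    lists = []
    for direction in ("up", "down"):
        lists.append(
            CrossList(
                list_id=f"expr_{direction}",
                expression=direction,
                methylation=None,
                genes=set(expr_genes[direction]),
            )
        )
        for region in ("body", "promoter"):
            for meth_direction in ("up", "down"):
                selector = (region, meth_direction)
                lists.append(
                    CrossList(
                        list_id=f"expr_{direction}.meth_{meth_direction}"
                        f".{region}",
                        expression=direction,
                        methylation=selector,
                        genes=expr_genes[direction] & meth_genes[selector],
                    )
                )
    return lists


def enrich(
    genes: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    dag: GODag,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term with k >= 1 in the list.

    The background is restricted to genes carrying at least one
    annotation (the "automatically annotated" gene universe); list genes
    outside it are excluded and logged.  Results carry raw p-values, the
    enriched flag p < alpha, and BH q-values for reference.
    """
    annotated_background = {
        g for g in background if annotations.get(g)
    }
    query = genes & annotated_background
    dropped = len(genes) - len(query)
    if dropped:
        logger.info(
            "%d list genes outside the annotated background excluded",
            dropped,
        )
    if not query:
        logger.warning("empty query list: no enrichment computed")
        return _empty_result()

    N = len(annotated_background)
    n = len(query)
    term_m: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in annotated_background:
        in_query = gene in query
        for term in annotations[gene]:
            term_m[term] = term_m.get(term, 0) + 1
            if in_query:
                term_k[term] = term_k.get(term, 0) + 1

    rows = []
    for term in sorted(term_k):
        m, k = term_m[term], term_k[term]
        p = hypergeometric_pvalue(N, m, n, k)
        rows.append(
            {
                "term": term,
                "name": dag.name(term) if term in dag.terms else term,
                "namespace": (
                    dag.namespace(term) if term in dag.terms else ""
                ),
                "N": N,
                "m": m,
                "n": n,
                "k": k,
                "p_value": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["q_value"] = stats.false_discovery_control(
        frame["p_value"].to_numpy(), method="bh"
    )
    frame["enriched"] = frame["p_value"] < alpha
    return frame.sort_values(
        ["p_value", "term"], kind="stable"
    ).reset_index(drop=True)


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term",
            "name",
            "namespace",
            "N",
            "m",
            "n",
            "k",
            "p_value",
            "q_value",
            "enriched",
        ]
    )
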