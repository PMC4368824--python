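"""GO term-abundance analysis of a study set against a population.

Annotations are propagated up the is_a/part_of DAG (true-path rule),
optionally collapsed onto a GO-Slim layer, and each term observed in the
study set is tested for over-representation with the hypergeometric upper
tail.  Multiple-test adjustment (Benjamini–Hochberg by default; Bonferroni
and Hochberg switchable) is applied within each namespace separately, and a
term is significant when its adjusted p-value is strictly below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .formats_io import OntologyGraph

logger = logging.getLogger("egtcensus")

DEFAULT_ALPHA = 0.05
ADJUST_METHODS = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni", "hochberg": "simes-hochberg"}


@dataclass
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    k: int  # study genes annotated (after propagation)
    n: int  # study size
    K: int  # population genes annotated
    N: int  # population size
    p_raw: float
    p_adj: float
    significant: bool


def propagate(annotations: Mapping[str, set[str]], graph: OntologyGraph) -> dict[str, set[str]]:
    """Close every gene's term set under is_a/part_of ancestors (true-path
    rule); idempotent and never removes a term."""
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        closed: set[str] = set()
        for term in terms:
            if term not in closure_cache:
                closure_cache[term] = {term} | graph.ancestors(term)
            closed |= closure_cache[term]
        out[gene] = closed
    return out


def map_to_slim(terms: set[str], graph: OntologyGraph) -> set[str]:
    """Most-specific slim ancestors of a term set.

    A slim term is returned when it is reachable upward from an input term
    and no other returned slim term lies below it on the used paths (so a
    slim root is masked by a more specific slim ancestor).  Terms without a
    slim ancestor contribute nothing.
    """
    if not graph.slim:
        raise ValueError("ontology has no slim subset")
    hits: set[str] = set()
    for term in terms:
        lineage = ({term} | graph.ancestors(term)) & graph.slim
        if not lineage:
            logger.debug("term %s has no slim ancestor", term)
            continue
        hits |= lineage
    # drop slim terms that are ancestors of other selected slim terms
    return {t for t in hits if not any(t in graph.ancestors(o) for o in hits if o != t)}


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P[X ≥ k] for X ~ Hypergeometric(N population, K annotated, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Step-up adjusted p-values (Benjamini–Hochberg by default), input
    order preserved and values clipped to 1."""
    p = list(p)
    if any(x < 0 or x > 1 for x in p):
        raise ValueError("p-values must lie in [0,1]")
    if not p:
        return []
    _, adjusted, _, _ = multipletests(p, method=ADJUST_METHODS[method])
    return [float(x) for x in adjusted]


def enrich(
    study: set[str],
    population: set[str],
    annotations: Mapping[str, set[str]],
    graph: OntologyGraph,
    alpha: float = DEFAULT_ALPHA,
    use_slim: bool = False,
    adjust_method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Over-representation test for every term annotated in the study set.

    Adjustment is applied within each namespace separately; results are
    sorted by ascending adjusted p-value (ties by term id).
    """
    if not study:
        raise ValueError("study set is empty")
    offenders = study - population
    if offenders:
        raise ValueError(f"study genes outside population: {sorted(offenders)[:10]}")
    closed = propagate({g: annotations.get(g, set()) for g in population}, graph)
    if use_slim:
        closed = {g: map_to_slim(terms, graph) for g, terms in closed.items()}

    N = len(population)
    n = len(study)
    pop_counts: dict[str, int] = {}
    study_counts: dict[str, int] = {}
    for gene, terms in closed.items():
        in_study = gene in study
        for t in terms:
            pop_counts[t] = pop_counts.get(t, 0) + 1
            if in_study:
                study_counts[t] = study_counts.get(t, 0) + 1

    results: list[EnrichmentResult] = []
    for t, k in study_counts.items():
        results.append(EnrichmentResult(
            term=t, name=graph.names.get(t, t), namespace=graph.namespace[t],
            k=k, n=n, K=pop_counts[t], N=N,
            p_raw=hypergeom_upper(k, pop_counts[t], n, N),
            p_adj=1.0, significant=False,
        ))
    for ns in sorted({r.namespace for r in results}):
        ns_results = [r for r in results if r.namespace == ns]
        adjusted = bh_adjust([r.p_raw for r in ns_results], method=adjust_method)
        for r, p_adj in zip(ns_results, adjusted):
            r.p_adj = p_adj
            r.significant = p_adj < alpha
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


ENRICHMENT_COLUMNS = ["term", "name", "namespace", "k", "n", "K", "N",
                      "p_raw", "p_adj", "significant"]


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path,
                         adjust_method: str = "fdr_bh") -> None:
    with open(path, "w") as fh:
        fh.write(f"# adjustment: {adjust_method} (within namespace)\n")
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(f"{r.term}\t{r.name}\t{r.namespace}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                     f"{r.p_raw:.4g}\t{r.p_adj:.4g}\t{str(r.significant).lower()}\n")
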