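"""Gene-family trees and origin classification of nuclear genes.

For each gene family a distance matrix is computed from pairwise local
alignments (Kimura-corrected mismatch fractions), a neighbor-joining tree
is built, and the query gene is classified by the taxonomic composition of
its sister group: a strict majority of cyanobacterial leaves calls the gene
a cyanobacterial recruit, a sister group free of cyanobacteria calls it
non-cyanobacterial, and anything in between — including exact 50/50 splits —
is ambiguous.  Externally produced newick trees (e.g. ML trees) can be fed
straight into :func:`classify_origin`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .formats_io import SequenceRecord, TreeNode, read_newick
from .protein_homology import smith_waterman

logger = logging.getLogger("egtcensus")

KIMURA_CAP_D = 0.85   # mismatch fractions ≥ this are capped ...
KIMURA_CAP_DIST = 5.0  # ... at this distance


@dataclass
class OriginCall:
    """Per-gene origin classification with sister-clade support."""

    gene_id: str
    call: str  # cyanobacterial / non_cyanobacterial / ambiguous
    sister_cyano_fraction: float
    n_sister_leaves: int
    tree_id: str = ""


@dataclass
class CensusSummary:
    """The two census tables: nuclear recruits and plastid homologs."""

    n_cyano_recruits: int
    n_nuclear_with_plastid_homolog: int
    n_both: int
    n_plastid_proteins: int
    n_plastid_with_nuclear_homolog: int
    n_plastid_with_cyano_nuclear_homolog: int
    pct_recruits_expressed: float | None

    def validate(self) -> None:
        assert self.n_both <= min(self.n_cyano_recruits, self.n_nuclear_with_plastid_homolog)
        assert (self.n_plastid_with_cyano_nuclear_homolog
                <= self.n_plastid_with_nuclear_homolog
                <= self.n_plastid_proteins)


def kimura_distance(mismatch_fraction: float) -> float:
    """Kimura's protein distance −ln(1 − D − D²/5), capped for D ≥ 0.85."""
    if mismatch_fraction < 0:
        raise ValueError("mismatch fraction must be ≥ 0")
    if mismatch_fraction >= KIMURA_CAP_D:
        return KIMURA_CAP_DIST
    return -math.log(1.0 - mismatch_fraction - mismatch_fraction ** 2 / 5.0)


def protein_distance_matrix(family: Sequence[SequenceRecord]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Kimura-corrected distances from local alignments.

    D is the fraction of non-identical columns (including gaps) of the
    optimal local alignment of each pair.  Every pair must align; a pair
    with no positive-scoring alignment is an error naming the pair.
    """
    if len(family) < 3:
        raise ValueError("a family needs ≥ 3 proteins for a tree")
    ids = [rec.id for rec in family]
    n = len(family)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = smith_waterman(family[i], family[j])
            if aln is None:
                raise ValueError(f"no local alignment for pair ({ids[i]}, {ids[j]})")
            D = 1.0 - aln.identity_pct / 100.0
            dist[i, j] = dist[j, i] = kimura_distance(D)
    return dist, ids


def nj_tree(dist: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Classical neighbor joining; negative branch lengths clamped to 0.

    For an additive input matrix the unrooted topology of the result equals
    the generating tree's topology exactly.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if dist.shape[0] < 3:
        raise ValueError("≥ 3 taxa required")
    dm = DistanceMatrix(dist, list(ids))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return read_newick(str(tree).strip())


def _unrooted_adjacency(tree: TreeNode) -> tuple[dict[int, list[int]], dict[int, str]]:
    """Adjacency of the unrooted tree (root of degree 2 suppressed)."""
    adjacency: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    nodes: list[TreeNode] = []

    def visit(node: TreeNode, parent_idx: int | None) -> int:
        idx = len(nodes)
        nodes.append(node)
        adjacency[idx] = []
        if node.is_leaf:
            labels[idx] = node.label
        if parent_idx is not None:
            adjacency[idx].append(parent_idx)
            adjacency[parent_idx].append(idx)
        for child in node.children:
            visit(child, idx)
        return idx

    root_idx = visit(tree, None)
    if len(adjacency[root_idx]) == 2:  # suppress the rooting node
        a, b = adjacency[root_idx]
        adjacency[a] = [x for x in adjacency[a] if x != root_idx] + [b]
        adjacency[b] = [x for x in adjacency[b] if x != root_idx] + [a]
        del adjacency[root_idx]
    return adjacency, labels


def classify_origin(
    tree: TreeNode,
    query_leaf: str,
    groups: Mapping[str, str],
    tree_id: str = "",
) -> OriginCall:
    """Classify the query gene from its sister group in the unrooted tree.

    The query's attachment node splits the remaining leaves into candidate
    sister sides; the sister group is the side with the fewest leaves
    (ties broken by a canonical order on the sorted leaf labels, so the
    result is independent of how the input tree is rooted).  Same-species
    paralogs (taxon group "query") are excluded from composition counting.
    The call is cyanobacterial on a strict majority of cyanobacterial
    leaves, non-cyanobacterial when the sister group contains none, and
    ambiguous otherwise.
    """
    adjacency, labels = _unrooted_adjacency(tree)
    query_nodes = [idx for idx, lab in labels.items() if lab == query_leaf]
    if not query_nodes:
        raise ValueError(f"query leaf {query_leaf!r} absent from tree")
    query_idx = query_nodes[0]
    missing = [lab for lab in labels.values() if lab != query_leaf and lab not in groups]
    if missing:
        raise ValueError(f"leaves without taxon group: {sorted(missing)}")

    attach = adjacency[query_idx][0]

    def side_leaves(start: int, blocked: set[int]) -> list[str]:
        stack, seen, found = [start], set(blocked) | {start}, []
        if start in labels:
            found.append(labels[start])
        while stack:
            cur = stack.pop()
            for nxt in adjacency[cur]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                if nxt in labels:
                    found.append(labels[nxt])
                stack.append(nxt)
        return found

    sides = [side_leaves(nbr, {attach, query_idx})
             for nbr in adjacency[attach] if nbr != query_idx]
    min_size = min(len(s) for s in sides)
    # canonical tie-break keeps the choice independent of input rooting
    sister = max((s for s in sides if len(s) == min_size),
                 key=lambda s: tuple(sorted(s)))

    countable = [lab for lab in sister if groups[lab] != "query"]
    if not countable:
        logger.warning("sister group of %s holds only same-species paralogs", query_leaf)
        return OriginCall(gene_id=query_leaf, call="ambiguous",
                          sister_cyano_fraction=0.0, n_sister_leaves=len(sister),
                          tree_id=tree_id)
    n_cyano = sum(1 for lab in countable if groups[lab] == "cyanobacteria")
    fraction = n_cyano / len(countable)
    if fraction > 0.5:
        call = "cyanobacterial"
    elif n_cyano == 0:
        call = "non_cyanobacterial"
    else:
        call = "ambiguous"
    return OriginCall(gene_id=query_leaf, call=call, sister_cyano_fraction=fraction,
                      n_sister_leaves=len(countable), tree_id=tree_id)


def classify_family(
    family: Sequence[SequenceRecord],
    query_leaf: str,
    groups: Mapping[str, str],
    tree: TreeNode | None = None,
    tree_id: str = "",
) -> OriginCall:
    """Distance-matrix → NJ → classification for one family (or use a
    supplied tree, e.g. an externally computed ML tree)."""
    if tree is None:
        dist, ids = protein_distance_matrix(family)
        tree = nj_tree(dist, ids)
    return classify_origin(tree, query_leaf, groups, tree_id=tree_id)


def build_census(
    origin_calls: Sequence[OriginCall],
    nuc_vs_plastid_pairs: set[tuple[str, str]],
    plastid_proteins: Sequence[str],
    expression: Mapping[str, bool] | None = None,
) -> CensusSummary:
    """Set algebra over recruits, nuclear↔plastid homology and expression.

    ``nuc_vs_plastid_pairs`` holds (nuclear gene id, plastid protein id)
    homolog pairs.  Distinct gene ids are counted, not gene copies.
    pct_recruits_expressed is over recruits with expression assessed, or
    None when expression was assessed for no recruit.
    """
    recruits = {c.gene_id for c in origin_calls if c.call == "cyanobacterial"}
    nuclear_with_homolog = {n for n, _ in nuc_vs_plastid_pairs}
    plastid_set = set(plastid_proteins)
    plastid_with_homolog = {p for _, p in nuc_vs_plastid_pairs if p in plastid_set}
    plastid_with_cyano = {p for n, p in nuc_vs_plastid_pairs
                          if p in plastid_set and n in recruits}
    pct = None
    if expression:
        assessed = [g for g in recruits if g in expression]
        if assessed:
            pct = 100.0 * sum(expression[g] for g in assessed) / len(assessed)
    summary = CensusSummary(
        n_cyano_recruits=len(recruits),
        n_nuclear_with_plastid_homolog=len(nuclear_with_homolog),
        n_both=len(recruits & nuclear_with_homolog),
        n_plastid_proteins=len(plastid_set),
        n_plastid_with_nuclear_homolog=len(plastid_with_homolog),
        n_plastid_with_cyano_nuclear_homolog=len(plastid_with_cyano),
        pct_recruits_expressed=pct,
    )
    summary.validate()
    return summary


def write_origin_calls_tsv(calls: Sequence[OriginCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcall\tsister_cyano_fraction\tn_sister_leaves\ttree_id\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.call}\t{c.sister_cyano_fraction:.3f}\t"
                     f"{c.n_sister_leaves}\t{c.tree_id}\n")


def write_census_tsv(summary: CensusSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("table\tcolumn\tvalue\n")
        rows = [
            ("nuclear_recruits", "cyanobacterial_recruits", summary.n_cyano_recruits),
            ("nuclear_recruits", "nuclear_with_plastid_homolog",
             summary.n_nuclear_with_plastid_homolog),
            ("nuclear_recruits", "both", summary.n_both),
            ("plastid_proteins", "plastid_proteins", summary.n_plastid_proteins),
            ("plastid_proteins", "with_nuclear_homolog",
             summary.n_plastid_with_nuclear_homolog),
            ("plastid_proteins", "with_cyanobacterial_nuclear_homolog",
             summary.n_plastid_with_cyano_nuclear_homolog),
        ]
        if summary.pct_recruits_expressed is not None:
            rows.append(("expression", "pct_recruits_expressed",
                         f"{summary.pct_recruits_expressed:.1f}"))
        for table, column, value in rows:
            fh.write(f"{table}\t{column}\t{value}\n")
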