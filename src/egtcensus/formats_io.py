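"""Readers and writers for the external formats the census pipeline touches.

Everything downstream operates on the in-memory types defined here:
:class:`SequenceRecord` (FASTA), :class:`TreeNode` (newick) and
:class:`OntologyGraph` (OBO 1.2 + GAF 2.x).  All interval coordinates in the
package are 0-based, half-open, on the forward strand of the named sequence;
conversion to 1-based happens only when writing report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio import SeqIO

logger = logging.getLogger("egtcensus")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: Compartments a sequence can belong to.
COMPARTMENTS = ("nuclear", "plastid", "mitochondrial", "unknown")
#: Taxon groups used for sister-clade composition in origin classification.
TAXON_GROUPS = ("cyanobacteria", "other_bacteria", "reference_eukaryote", "query")


class FormatError(ValueError):
    """Raised on malformed or contract-violating input files."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with census metadata.

    The sequence is stored uppercase; the alphabet is validated against
    ``kind`` ("nucleotide": ACGTN, "protein": 20 amino acids + X/*).
    """

    id: str
    seq: str
    kind: str = "nucleotide"
    compartment: str = "unknown"
    species: str = ""
    taxon_group: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.seq):
            if ch not in alphabet:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} in sequence {self.id!r} "
                    f"(kind={self.kind})"
                )
        if self.compartment not in COMPARTMENTS:
            raise FormatError(f"unknown compartment {self.compartment!r}")
        if self.taxon_group is not None and self.taxon_group not in TAXON_GROUPS:
            raise FormatError(f"unknown taxon group {self.taxon_group!r}")

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(
    path: str | Path,
    kind: str = "nucleotide",
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The record id is the header token before the first whitespace; the
    remainder of the header line is kept as the free-text ``description``.
    ``metadata`` optionally maps record ids to field overrides
    (``compartment``, ``species``, ``taxon_group``); its keys must be a
    subset of the FASTA ids.

    Raises
    ------
    FormatError
        On an empty file, a duplicate id, or an illegal character.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        extra: Mapping[str, str] = metadata.get(entry.id, {}) if metadata else {}
        desc = entry.description[len(entry.id):].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                seq=str(entry.seq),
                kind=kind,
                compartment=extra.get("compartment", "unknown"),
                species=extra.get("species", ""),
                taxon_group=extra.get("taxon_group"),
                description=desc,
            )
        )
    if not records:
        raise FormatError(f"no FASTA entries found in {path}")
    if metadata:
        unknown = set(metadata) - seen
        if unknown:
            raise FormatError(f"metadata ids absent from FASTA: {sorted(unknown)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted tree node; leaves carry labels that map to sequence ids."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


class NewickError(FormatError):
    """Newick syntax error; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


def read_newick(text: str) -> TreeNode:
    """Parse a single newick statement into a :class:`TreeNode`.

    Multifurcations are allowed; leaf labels must be unique.  Branch lengths
    survive a write/read round trip to 6 significant digits.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("newick statement must end with ';'", len(text))
    pos = 0

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(text):
                    raise NewickError("unbalanced parentheses", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {text[pos]!r}", pos)
        # optional label ('...'-quoted labels may contain metacharacters)
        if pos < len(text) and text[pos] == "'":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] != "'":
                pos += 1
            if pos >= len(text):
                raise NewickError("unterminated quoted label", start)
            node.label = text[start:pos]
            pos += 1
        else:
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            label = text[start:pos].strip()
            if label:
                node.label = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            try:
                node.branch_length = float(text[start:pos])
            except ValueError:
                raise NewickError(f"bad branch length {text[start:pos]!r}", start) from None
            if node.branch_length < 0:
                raise NewickError("negative branch length", start)
        return node

    root = parse_clade()
    if pos >= len(text) or text[pos] != ";":
        raise NewickError("trailing characters before ';'", pos)
    labels = root.leaf_labels()
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate leaf label(s): {dup}")
    if any(lab is None for lab in labels):
        raise NewickError("unlabeled leaf", 0)
    return root


def write_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                body += node.label
        if node.branch_length is not None:
            body += f":{node.branch_length:.6g}"
        return body

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Gene Ontology: OBO 1.2 + GAF 2.x
# ---------------------------------------------------------------------------

NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass
class OntologyGraph:
    """A GO DAG restricted to is_a/part_of edges, with optional slim subset.

    ``graph`` is a :class:`networkx.DiGraph` with edges pointing child→parent,
    so a term's ancestors are its networkx *descendants*.
    """

    graph: nx.DiGraph
    names: dict[str, str]
    namespace: dict[str, str]
    slim: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise FormatError("ontology graph contains a cycle")
        missing = self.slim - set(self.graph.nodes)
        if missing:
            raise FormatError(f"slim terms absent from ontology: {sorted(missing)}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All is_a/part_of ancestors of ``term`` within its namespace."""
        ns = self.namespace[term]
        return {t for t in nx.descendants(self.graph, term) if self.namespace[t] == ns}


def read_ontology(
    obo_path: str | Path,
    gaf_path: str | Path,
    slim_ids: set[str] | None = None,
    exclude_iea: bool = False,
) -> tuple[OntologyGraph, dict[str, set[str]]]:
    """Read an OBO 1.2 ontology and a GAF 2.x annotation file.

    Obsolete terms are dropped (obonet default) with a logged count.  Only
    is_a and part_of relations are retained.  GAF rows with a NOT qualifier
    are dropped; rows referencing terms absent from the ontology are dropped
    with a warning.  Evidence codes are not filtered unless ``exclude_iea``
    is set (the electronic-annotation code IEA is then skipped).
    """
    raw = obonet.read_obo(str(obo_path), ignore_obsolete=True)
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    namespace: dict[str, str] = {}
    for term, data in raw.nodes(data=True):
        graph.add_node(term)
        names[term] = data.get("name", term)
        ns = data.get("namespace", "biological_process")
        namespace[term] = NAMESPACE_CODES.get(ns, ns)
    for child, parent, rel in raw.edges(keys=True):
        if rel in ("is_a", "part_of") and parent in graph:
            graph.add_edge(child, parent, relation=rel)
    ont = OntologyGraph(graph=graph, names=names, namespace=namespace, slim=set(slim_ids or ()))

    annotations: dict[str, set[str]] = {}
    n_dropped_unknown = 0
    n_dropped_not = 0
    with open(gaf_path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise FormatError(f"GAF row has {len(cols)} columns (≥7 required): {line!r}")
            gene, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                n_dropped_not += 1
                continue
            if exclude_iea and evidence == "IEA":
                continue
            if term not in ont.terms:
                logger.warning("GAF term %s absent from ontology; row dropped", term)
                n_dropped_unknown += 1
                continue
            annotations.setdefault(gene, set()).add(term)
    if n_dropped_unknown or n_dropped_not:
        logger.info(
            "GAF: dropped %d rows with unknown terms, %d NOT-qualified rows",
            n_dropped_unknown,
            n_dropped_not,
        )
    return ont, annotations
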