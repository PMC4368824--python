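"""Local sequence search with the census filters.

The search is a k-mer-prefiltered exact Smith–Waterman: candidate pairs must
share at least one exact k-mer, the surviving pairs are aligned optimally
under affine gap penalties (BLOSUM62 by default), and hits are filtered on a
Karlin–Altschul E-value (E = K·m·n·e^(−λS)) and percent identity.  Defaults
follow the census screen: E ≤ 1e−10 and identity ≥ 25 % for protein
searches.  Expression is qualified megablast-style: a gene counts as
expressed as soon as one EST alignment seeded by an exact 28-mer passes the
E-value threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import SequenceRecord, reverse_complement

logger = logging.getLogger("egtcensus")

# Karlin–Altschul parameters for the gapped BLOSUM62 regime (protein) and a
# simple match/mismatch nucleotide scheme; only the threshold decision uses
# them, and the thresholds themselves are configurable.
PROTEIN_LAMBDA = 0.267
PROTEIN_K = 0.041
NUCLEOTIDE_LAMBDA = 1.28
NUCLEOTIDE_K = 0.46

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_IDENTITY_PCT = 25.0
DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_PREFILTER_K = 4
EST_WORD_SIZE = 28

ROLES = ("recruit_screen", "nuclear_vs_plastid", "est_expression")


@dataclass
class LocalAlignment:
    """One optimal local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity_pct: float
    aln_len: int
    evalue: float


@dataclass
class HomologyTable:
    rows: list[LocalAlignment]
    role: str

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.query_id, r.subject_id) for r in self.rows}


def _aligner(kind: str, matrix: str | None, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    if kind == "protein":
        al.substitution_matrix = substitution_matrices.load(matrix or "BLOSUM62")
    else:
        al.match_score = 2
        al.mismatch_score = -3
    # a gap of length L costs gap_open + L·gap_extend
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def smith_waterman(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> LocalAlignment | None:
    """Optimal local alignment of two records under affine gap penalties.

    A gap of length L costs ``gap_open + L·gap_extend``.  Returns None when
    the optimum is ≤ 0.  The identity denominator is the number of alignment
    columns including gaps (the blastp identities/length convention).
    """
    if a.kind != b.kind:
        raise ValueError(f"mixed alphabets: {a.id} is {a.kind}, {b.id} is {b.kind}")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("affine penalties must be positive")
    al = _aligner(a.kind, matrix, gap_open, gap_extend)
    try:
        score = al.score(a.seq, b.seq)
    except ValueError as exc:  # residue outside the substitution matrix
        raise ValueError(f"cannot align {a.id} vs {b.id}: {exc}") from exc
    if score <= 0:
        return None
    aln = al.align(a.seq, b.seq)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    blocks_q, blocks_s = aln.aligned
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    return LocalAlignment(
        query_id=a.id,
        subject_id=b.id,
        score=int(score),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        identity_pct=100.0 * counts.identities / aln_len,
        aln_len=aln_len,
        evalue=0.0,
    )


def evalue(score: int, m: int, n: int, lambda_: float = PROTEIN_LAMBDA,
           K: float = PROTEIN_K) -> float:
    """Karlin–Altschul expected hit count E = K·m·n·e^(−λS)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be ≥ 1")
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return K * m * n * math.exp(-lambda_ * score)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    role: str = "recruit_screen",
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    prefilter_k: int = DEFAULT_PREFILTER_K,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> HomologyTable:
    """All-vs-all local search with E-value and identity filters.

    Pairs sharing no exact ``prefilter_k``-mer are skipped.  Retained rows
    satisfy evalue ≤ max_evalue and identity ≥ min_identity_pct; per query
    they are sorted by ascending evalue, ties by descending score then
    subject id.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    if not subjects:
        raise ValueError("subject set must be non-empty")
    if not queries:
        warnings.warn("empty query set; returning empty table")
        return HomologyTable(rows=[], role=role)
    is_protein = queries[0].kind == "protein"
    lam = PROTEIN_LAMBDA if is_protein else NUCLEOTIDE_LAMBDA
    K = PROTEIN_K if is_protein else NUCLEOTIDE_K

    subject_kmers = [(s, _kmer_set(s.seq, prefilter_k)) for s in subjects]
    rows: list[LocalAlignment] = []
    for q in queries:
        q_kmers = _kmer_set(q.seq, prefilter_k)
        q_rows: list[LocalAlignment] = []
        for s, s_kmers in subject_kmers:
            if q_kmers.isdisjoint(s_kmers):
                continue
            aln = smith_waterman(q, s, gap_open=gap_open, gap_extend=gap_extend)
            if aln is None:
                continue
            aln.evalue = evalue(aln.score, len(q.seq), len(s.seq), lam, K)
            if aln.evalue <= max_evalue and aln.identity_pct >= min_identity_pct:
                q_rows.append(aln)
        q_rows.sort(key=lambda r: (r.evalue, -r.score, r.subject_id))
        rows.extend(q_rows)
    logger.info("homology search (%s): %d queries vs %d subjects -> %d rows",
                role, len(queries), len(subjects), len(rows))
    return HomologyTable(rows=rows, role=role)


def est_expressed(
    gene: SequenceRecord,
    ests: Sequence[SequenceRecord],
    word_size: int = EST_WORD_SIZE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> bool:
    """Megablast-style expression call: true iff ≥ 1 EST hit passes.

    Both the sense and antisense strand of the gene are screened; a
    candidate EST must share an exact ``word_size``-mer, and the resulting
    local alignment must pass ``max_evalue``.
    """
    if gene.kind != "nucleotide":
        raise ValueError("expression qualification needs a nucleotide gene")
    if not ests:
        raise ValueError(f"expression not assessable for {gene.id}: empty EST library")
    strands = [gene.seq, reverse_complement(gene.seq)]
    strand_kmers = [_kmer_set(s, word_size) for s in strands]
    al = _aligner("nucleotide", None, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    for est in ests:
        est_kmers = _kmer_set(est.seq, word_size)
        for seq, kmers in zip(strands, strand_kmers):
            if kmers.isdisjoint(est_kmers):
                continue
            score = al.score(seq, est.seq)
            if score > 0 and evalue(int(score), len(seq), len(est.seq),
                                    NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K) <= max_evalue:
                return True
    return False


HOMOLOGY_COLUMNS = ["query", "subject", "score", "evalue", "identity_pct",
                    "aln_len", "q_start", "q_end", "s_start", "s_end"]


def write_homology_tsv(table: HomologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HOMOLOGY_COLUMNS) + "\n")
        for r in table.rows:
            fh.write(f"{r.query_id}\t{r.subject_id}\t{r.score}\t{r.evalue:.3g}\t"
                     f"{r.identity_pct:.2f}\t{r.aln_len}\t{r.q_start}\t{r.q_end}\t"
                     f"{r.s_start}\t{r.s_end}\n")
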