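"""Detection of organelle-derived insertions in a nuclear genome.

The detector follows a seed–chain–align design: exact shared words of a
configurable size (default 50 bp) anchor candidate regions, colinear anchors
are chained, each chained span is globally aligned to obtain a percent
identity, and hits are filtered (identity strictly > 80%, length ≥ 50 bp by
default).  From the retained hits the module derives the three summaries of
an endosymbiotic-transfer census: the *exchange rate* (percentage of
organelle positions covered by at least one nuclear insertion), a per-
position copy-number/coverage profile, and a size-class histogram of the
insertions (NUPTs for plastid donors, NUMTs for mitochondrial donors).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats_io import SequenceRecord, reverse_complement

logger = logging.getLogger("egtcensus")

DEFAULT_WORD_SIZE = 50
DEFAULT_MIN_IDENTITY_PCT = 80.0
DEFAULT_MIN_LENGTH = 50
DEFAULT_MAX_JOIN_GAP = 100

#: Size-class bin edges and their report labels (upper bin open).
SIZE_BINS: list[tuple[int, float, str]] = [
    (50, 100, "50–99"),
    (100, 200, "-199"),
    (200, 300, "-299"),
    (300, 400, "-399"),
    (400, 500, "-499"),
    (500, 1000, "-999"),
    (1000, float("inf"), "≥1000"),
]


@dataclass
class Anchor:
    """An exact shared word: nuclear[n_pos:n_pos+w] matches the organelle.

    For strand '+' the match is to organelle[o_pos:o_pos+w]; for strand '−'
    it is to the reverse complement of that interval.
    """

    n_pos: int
    o_pos: int
    strand: str


@dataclass
class InsertionHit:
    """One organelle→nuclear transferred segment (a putative NUPT/NUMT)."""

    organelle_id: str
    o_start: int
    o_end: int
    nuclear_id: str
    n_start: int
    n_end: int
    strand: str
    identity_pct: float
    class_: str = "NUPT"

    @property
    def length(self) -> int:
        return self.o_end - self.o_start

    def validate(self, organelle_len: int, nuclear_len: int) -> None:
        if not (0 <= self.o_start < self.o_end <= organelle_len):
            raise ValueError(f"organelle interval [{self.o_start},{self.o_end}) out of bounds")
        if not (0 <= self.n_start < self.n_end <= nuclear_len):
            raise ValueError(f"nuclear interval [{self.n_start},{self.n_end}) out of bounds")


@dataclass
class CoverageProfile:
    """Per-position insertion depth over an organelle genome.

    ``depth[i]`` counts the retained hits whose organelle interval contains
    position ``i`` — the copy number of that organelle region in the nuclear
    genome.  The exchange rate is the percentage of positions with depth ≥ 1.
    """

    organelle_id: str
    depth: np.ndarray
    exchange_rate_pct: float


@dataclass
class SizeHistogram:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word_size + 1):
        word = seq[i : i + word_size]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def find_seed_matches(
    nuclear: SequenceRecord,
    organelle: SequenceRecord,
    word_size: int = DEFAULT_WORD_SIZE,
    circular: bool = False,
) -> list[Anchor]:
    """Report every exact shared word between nuclear and organelle.

    The nuclear forward strand is scanned against the organelle forward
    strand (strand '+') and reverse complement (strand '−'); anchors are
    complete (every shared word is reported) and words containing N never
    match.  With ``circular`` the organelle is padded with its first
    ``word_size − 1`` bases so words crossing the origin of a circular
    genome can seed.
    """
    if nuclear.kind != "nucleotide" or organelle.kind != "nucleotide":
        raise ValueError("seed matching requires nucleotide sequences")
    if word_size < 8:
        raise ValueError("word_size must be ≥ 8")
    if word_size > min(len(nuclear), len(organelle)):
        warnings.warn("word_size exceeds a sequence length; no anchors possible")
        return []

    org_len = len(organelle.seq)
    org_fwd = organelle.seq + (organelle.seq[: word_size - 1] if circular else "")
    index: dict[str, list[tuple[int, str]]] = {}
    for i in range(len(org_fwd) - word_size + 1):
        word = org_fwd[i : i + word_size]
        if "N" in word:
            continue
        index.setdefault(word, []).append((i % org_len, "+"))
    org_rev = reverse_complement(organelle.seq)
    org_rev = org_rev + (org_rev[: word_size - 1] if circular else "")
    for i in range(len(org_rev) - word_size + 1):
        word = org_rev[i : i + word_size]
        if "N" in word:
            continue
        # position of the word's start on the organelle forward strand
        o_pos = (org_len - word_size - i) % org_len
        index.setdefault(word, []).append((o_pos, "-"))

    anchors: list[Anchor] = []
    nseq = nuclear.seq
    for n_pos in range(len(nseq) - word_size + 1):
        word = nseq[n_pos : n_pos + word_size]
        hits = index.get(word)
        if hits is None:
            continue
        if "N" in word:
            continue
        for o_pos, strand in hits:
            anchors.append(Anchor(n_pos=n_pos, o_pos=o_pos, strand=strand))
    return anchors


def _align_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two strings."""
    if a == b:
        return 100.0
    result = edlib.align(a, b, task="path", mode="NW")
    cigar = result["cigar"]
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return 100.0 * matches / columns


def chain_and_align(
    anchors: Sequence[Anchor],
    nuclear: SequenceRecord,
    organelle: SequenceRecord,
    word_size: int = DEFAULT_WORD_SIZE,
    max_join_gap: int = DEFAULT_MAX_JOIN_GAP,
    band_frac: float = 0.2,
    class_: str = "NUPT",
) -> list[InsertionHit]:
    """Chain colinear anchors and align each chained span.

    Anchors on the same strand are joined when the gap between consecutive
    word starts is ≤ ``max_join_gap + word_size`` on both coordinates and the
    organelle coordinate advances consistently with the strand; chains are
    maximal under this rule.  Each chain's spanned nuclear and organelle
    regions are globally aligned (banded edit-distance alignment) and the
    identity is the fraction of matched columns over all alignment columns.
    Ties in chain membership are resolved deterministically: anchors are
    consumed in nuclear-coordinate order and attach to the chain with the
    leftmost organelle start among those satisfying the gap rule.
    """
    del band_frac  # band chosen internally by the aligner
    hits: list[InsertionHit] = []
    max_step = max_join_gap + word_size
    for strand in ("+", "-"):
        strand_anchors = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (a.n_pos, a.o_pos),
        )
        # active chains: [last_n, last_o, first_n, first_o]
        chains: list[list[int]] = []
        closed: list[list[int]] = []
        for a in strand_anchors:
            best = None
            for ch in chains:
                n_step = a.n_pos - ch[0]
                if n_step > max_step:
                    continue  # candidate for closing later
                if n_step <= 0:
                    continue
                o_step = (a.o_pos - ch[1]) if strand == "+" else (ch[1] - a.o_pos)
                if o_step <= 0 or o_step > max_step:
                    continue
                if best is None or ch[3] < best[3]:
                    best = ch
            if best is not None:
                best[0], best[1] = a.n_pos, a.o_pos
            else:
                chains.append([a.n_pos, a.o_pos, a.n_pos, a.o_pos])
            # retire chains that can no longer be extended
            still = []
            for ch in chains:
                if a.n_pos - ch[0] > max_step:
                    closed.append(ch)
                else:
                    still.append(ch)
            chains = still
        closed.extend(chains)

        for last_n, last_o, first_n, first_o in closed:
            n_start, n_end = first_n, last_n + word_size
            if strand == "+":
                o_start, o_end = first_o, last_o + word_size
            else:
                o_start, o_end = last_o, first_o + word_size
            n_seq = nuclear.seq[n_start:n_end]
            o_seq = organelle.seq[o_start:o_end]
            if strand == "-":
                o_seq = reverse_complement(o_seq)
            identity = _align_identity(n_seq, o_seq)
            hits.append(
                InsertionHit(
                    organelle_id=organelle.id,
                    o_start=o_start,
                    o_end=o_end,
                    nuclear_id=nuclear.id,
                    n_start=n_start,
                    n_end=n_end,
                    strand=strand,
                    identity_pct=identity,
                    class_=class_,
                )
            )
    hits.sort(key=lambda h: (h.nuclear_id, h.n_start, h.o_start, h.strand))
    return hits


def filter_hits(
    hits: Iterable[InsertionHit],
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[InsertionHit]:
    """Retain hits with identity strictly above the threshold and length ≥ min."""
    return [
        h for h in hits if h.identity_pct > min_identity_pct and h.length >= min_length
    ]


def coverage_profile(hits: Sequence[InsertionHit], organelle: SequenceRecord) -> CoverageProfile:
    """Per-position depth (copy number) and exchange rate over the organelle."""
    n = len(organelle.seq)
    delta = np.zeros(n + 1, dtype=np.int64)
    for h in hits:
        if h.organelle_id != organelle.id:
            raise ValueError(f"hit references {h.organelle_id!r}, not {organelle.id!r}")
        if not (0 <= h.o_start < h.o_end <= n):
            raise ValueError(f"hit interval [{h.o_start},{h.o_end}) outside organelle of length {n}")
        delta[h.o_start] += 1
        delta[h.o_end] -= 1
    depth = np.cumsum(delta[:-1])
    exchange = round(100.0 * int((depth > 0).sum()) / n, 2)
    return CoverageProfile(organelle_id=organelle.id, depth=depth, exchange_rate_pct=exchange)


def size_histogram(hits: Sequence[InsertionHit]) -> SizeHistogram:
    """Bin retained hits by length into the census size classes."""
    counts = {label: 0 for _, _, label in SIZE_BINS}
    for h in hits:
        if h.length < SIZE_BINS[0][0]:
            raise ValueError(f"hit of length {h.length} below minimum; filter hits first")
        for lo, hi, label in SIZE_BINS:
            if lo <= h.length < hi:
                counts[label] += 1
                break
    return SizeHistogram(counts=counts)


def detect_insertions(
    nuclear_contigs: Sequence[SequenceRecord],
    organelle: SequenceRecord,
    word_size: int = DEFAULT_WORD_SIZE,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_join_gap: int = DEFAULT_MAX_JOIN_GAP,
    class_: str = "NUPT",
    circular: bool = False,
) -> list[InsertionHit]:
    """Full seed→chain→align→filter pass over a multi-contig nuclear genome."""
    retained: list[InsertionHit] = []
    for contig in nuclear_contigs:
        anchors = find_seed_matches(contig, organelle, word_size=word_size, circular=circular)
        raw = chain_and_align(
            anchors, contig, organelle, word_size=word_size,
            max_join_gap=max_join_gap, class_=class_,
        )
        retained.extend(filter_hits(raw, min_identity_pct, min_length))
    logger.info(
        "insertion census: %d contigs vs %s -> %d retained hits",
        len(nuclear_contigs), organelle.id, len(retained),
    )
    return retained


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "nuclear_id", "n_start", "n_end", "organelle_id", "o_start", "o_end",
    "strand", "length", "identity_pct", "class",
]


def write_hits_tsv(hits: Sequence[InsertionHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HIT_COLUMNS)
        for h in hits:
            w.writerow([
                h.nuclear_id, h.n_start, h.n_end, h.organelle_id, h.o_start,
                h.o_end, h.strand, h.length, f"{h.identity_pct:.2f}", h.class_,
            ])


def write_hits_bed(hits: Sequence[InsertionHit], path: str | Path) -> None:
    """6-column BED of the hits on the nuclear genome (score = identity×10)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            name = f"{h.class_}:{h.organelle_id}:{h.o_start}-{h.o_end}"
            w.writerow([h.nuclear_id, h.n_start, h.n_end, name,
                        int(round(h.identity_pct * 10)), h.strand])


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "depth"])
        for i, d in enumerate(profile.depth):
            w.writerow([i, int(d)])


def write_histogram_tsv(hist: SizeHistogram, path: str | Path, exchange_pct: float | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        labels = [label for _, _, label in SIZE_BINS]
        header = ["Exchange"] + labels if exchange_pct is not None else labels
        w.writerow(header)
        row = [f"{exchange_pct:.2f}"] if exchange_pct is not None else []
        w.writerow(row + [hist.counts[label] for label in labels])
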