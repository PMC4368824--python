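"""Ground-truth generators for every input the census pipeline consumes.

Each generator is deterministic under a fixed seed and returns a
machine-readable truth table next to the generated data, so detection,
classification, enrichment and expression stages can all be scored against
a known answer without downloading anything.

Divergence model for implanted organelle fragments
--------------------------------------------------
Real organelle insertions do not diverge uniformly: recently transferred
segments keep long conserved runs interrupted by divergent patches, and
their edges erode first.  The generator mimics this with a three-part
placement model for the planted substitutions of an implant of length L:

* up to 12 bp at each edge may be fully substituted ("edge erosion"),
* the remainder of the divergence is drawn inside interior *hotspot*
  windows that alternate with conserved windows of at least the seed word
  size (50 bp), spaced so that consecutive conserved windows are at most
  140 bp apart,
* implants planted below 75 % identity are too diverged for this mosaic
  structure; their substitutions are placed uniformly at random instead.

The mosaic guarantees that every implant of planted identity ≥ 75 % retains
an intact seed word within 25 bp of each boundary and intact words at most
140 bp apart, i.e. such implants are detectable *by construction* with the
pipeline's word size of 50 — while heavily diverged implants (≤ 70 %
identity) contain essentially no exact 50-mer and are invisible, matching
the behaviour of word-50 seeding on uniformly diverged sequence.
Substituted bases are drawn uniformly over the three alternatives and no
indels are introduced, so the planted identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import SequenceRecord, TreeNode, reverse_complement, write_newick

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AMINO = "ACDEFGHIKLMNPQRSTVWY"

SEED_WORD = 50          # word size the detector seeds with
EDGE_EROSION_MAX = 12   # max fully-substituted bases per implant edge
CONSERVED_WIN = 50      # conserved window width in the mosaic
HOT_WIN = 90            # hotspot window width in the mosaic
MIN_NUCLEAR_GAP = 200   # minimum spacing between implants on the nuclear genome


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AMINO), size=n))


def _substitute(seq: list[str], positions: np.ndarray, rng: np.random.Generator) -> None:
    for p in positions:
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        seq[p] = choices[rng.integers(3)]


@dataclass
class ImplantTruth:
    """Truth row for one implanted organelle fragment copy."""

    nuclear_id: str
    n_start: int
    n_end: int
    o_start: int
    o_end: int
    strand: str
    planted_identity_pct: float
    copy_index: int
    sub_positions: tuple[int, ...] = ()  # offsets within the implant

    @property
    def length(self) -> int:
        return self.o_end - self.o_start


def _mosaic_positions(length: int, n_subs: int, rng: np.random.Generator) -> np.ndarray | None:
    """Clustered substitution offsets for a moderately diverged implant.

    Returns None when the mosaic cannot hold ``n_subs`` (the caller then
    falls back to uniform placement).
    """
    edge = min(n_subs, 2 * EDGE_EROSION_MAX)
    k1, k2 = edge // 2, edge - edge // 2
    positions = list(range(k1)) + list(range(length - k2, length))
    remaining = n_subs - edge
    core_lo, core_hi = k1, length - k2
    # conserved windows anchor the core edges, then repeat every
    # CONSERVED_WIN + HOT_WIN bases; hot positions are everything else.
    conserved = np.zeros(length, dtype=bool)
    start = core_lo
    while start + CONSERVED_WIN <= core_hi:
        conserved[start : start + CONSERVED_WIN] = True
        start += CONSERVED_WIN + HOT_WIN
    conserved[max(core_lo, core_hi - CONSERVED_WIN) : core_hi] = True
    hot = np.flatnonzero(~conserved[core_lo:core_hi]) + core_lo
    if remaining > len(hot):
        return None
    if remaining:
        positions.extend(rng.choice(hot, size=remaining, replace=False).tolist())
    return np.asarray(sorted(positions), dtype=np.int64)


def gen_genome_with_implants(
    organelle_len: int = 150_000,
    nuclear_len: int = 1_000_000,
    n_implants: int = 100,
    length_range: tuple[int, int] = (50, 3000),
    identity_range: tuple[float, float] = (60.0, 100.0),
    max_copies: int = 1,
    seed: int = 0,
    nuclear_id: str = "nuc1",
    organelle_id: str = "org1",
) -> tuple[SequenceRecord, SequenceRecord, list[ImplantTruth]]:
    """Generate a nuclear genome carrying implanted organelle fragments.

    The organelle is i.i.d. uniform ACGT.  Each implant copies a random
    organelle interval, substitutes bases down to a planted identity drawn
    from ``identity_range`` (see the module docstring for the placement
    model), reverse-complements with probability 0.5, and overwrites a
    non-overlapping nuclear location (≥ 200 bp apart from other implants).
    With ``max_copies`` > 1, each implant event places 1..max_copies copies
    of the *same* organelle interval at distinct nuclear locations, each
    with an independent substitution draw.
    """
    rng = np.random.default_rng(seed)
    organelle_seq = _random_dna(rng, organelle_len)

    events = []
    total_len = 0
    n_copies_total = 0
    for _ in range(n_implants):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        identity = float(rng.uniform(identity_range[0], identity_range[1]))
        o_start = int(rng.integers(0, organelle_len - length + 1))
        copies = int(rng.integers(1, max_copies + 1))
        events.append((o_start, length, identity, copies))
        total_len += length * copies
        n_copies_total += copies

    needed = total_len + MIN_NUCLEAR_GAP * (n_copies_total + 1)
    if needed > nuclear_len:
        raise ValueError(
            f"infeasible packing: implants need {needed} bp, nuclear genome is {nuclear_len} bp"
        )

    # random non-overlapping placement: shuffle copy order, distribute the
    # free space over the gaps
    copy_list = []
    for event_idx, (o_start, length, identity, copies) in enumerate(events):
        for c in range(copies):
            copy_list.append((event_idx, c))
    order = rng.permutation(len(copy_list))
    free = nuclear_len - total_len - MIN_NUCLEAR_GAP * (n_copies_total + 1)
    extra = rng.multinomial(free, np.full(n_copies_total + 1, 1.0 / (n_copies_total + 1)))

    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def _avoid(base: str, forbidden: str | None) -> str:
        if forbidden is None or base != forbidden:
            return base
        return [b for b in "ACGT" if b != forbidden][rng.integers(3)]

    nuclear_parts: list[str] = []
    truths: list[ImplantTruth] = []
    cursor = 0
    pending_forbidden: str | None = None  # keeps planted boundaries sharp
    for slot, idx in enumerate(order):
        event_idx, copy_idx = copy_list[idx]
        o_start, length, identity, _ = events[event_idx]
        gap = MIN_NUCLEAR_GAP + int(extra[slot])
        gap_seq = _random_dna(rng, gap)
        gap_seq = _avoid(gap_seq[0], pending_forbidden) + gap_seq[1:]
        nuclear_parts.append(gap_seq)
        cursor += gap

        n_subs = int(round((1.0 - identity / 100.0) * length))
        fragment = list(organelle_seq[o_start : o_start + length])
        if n_subs:
            positions = None
            if 100.0 * (length - n_subs) / length >= 75.0:
                positions = _mosaic_positions(length, n_subs, rng)
            if positions is None:
                positions = np.sort(rng.choice(length, size=n_subs, replace=False))
            _substitute(fragment, positions, rng)
            sub_positions = tuple(int(p) for p in positions)
        else:
            sub_positions = ()
        strand = "+" if rng.random() < 0.5 else "-"
        implant_seq = "".join(fragment)
        if strand == "-":
            implant_seq = reverse_complement(implant_seq)
        # a flank base that continues the organelle match would blur the
        # planted boundary; force a mismatch on both sides
        o_end = o_start + length
        if strand == "+":
            left_forbidden = organelle_seq[o_start - 1] if o_start > 0 else None
            pending_forbidden = organelle_seq[o_end] if o_end < organelle_len else None
        else:
            left_forbidden = (complement[organelle_seq[o_end]]
                              if o_end < organelle_len else None)
            pending_forbidden = (complement[organelle_seq[o_start - 1]]
                                 if o_start > 0 else None)
        if nuclear_parts[-1]:
            nuclear_parts[-1] = nuclear_parts[-1][:-1] + _avoid(nuclear_parts[-1][-1],
                                                                left_forbidden)
        nuclear_parts.append(implant_seq)
        truths.append(
            ImplantTruth(
                nuclear_id=nuclear_id,
                n_start=cursor,
                n_end=cursor + length,
                o_start=o_start,
                o_end=o_start + length,
                strand=strand,
                planted_identity_pct=100.0 * (length - n_subs) / length,
                copy_index=copy_idx,
                sub_positions=sub_positions,
            )
        )
        cursor += length
    tail = nuclear_len - cursor
    tail_seq = _random_dna(rng, tail)
    if tail_seq:
        tail_seq = _avoid(tail_seq[0], pending_forbidden) + tail_seq[1:]
    nuclear_parts.append(tail_seq)

    nuclear = SequenceRecord(id=nuclear_id, seq="".join(nuclear_parts), kind="nucleotide",
                             compartment="nuclear")
    organelle = SequenceRecord(id=organelle_id, seq=organelle_seq, kind="nucleotide",
                               compartment="plastid")
    truths.sort(key=lambda t: t.n_start)
    return nuclear, organelle, truths


def implant_coverage_truth(truths: list[ImplantTruth], organelle_len: int,
                           min_identity_pct: float = 80.0, min_length: int = 50) -> float:
    """Planted exchange rate: % of organelle positions covered by implants
    that pass the census filters (planted identity strictly above the
    threshold, length ≥ min_length)."""
    covered = np.zeros(organelle_len, dtype=bool)
    for t in truths:
        if t.planted_identity_pct > min_identity_pct and t.length >= min_length:
            covered[t.o_start : t.o_end] = True
    return round(100.0 * covered.sum() / organelle_len, 2)


# ---------------------------------------------------------------------------
# Protein families with known donor lineage
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    family_id: str
    true_tree: TreeNode
    donor: str  # cyanobacterial / eukaryotic / bacterial_other / mixed
    query_gene_id: str


DONOR_GROUP = {
    "cyanobacterial": "cyanobacteria",
    "eukaryotic": "reference_eukaryote",
    "bacterial_other": "other_bacteria",
}


def _random_bifurcating(labels: list[str], rng: np.random.Generator,
                        bl_range: tuple[float, float]) -> TreeNode:
    nodes = [TreeNode(label=lab, branch_length=float(rng.uniform(*bl_range)))
             for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]],
                          branch_length=float(rng.uniform(*bl_range)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _evolve(seq: str, branch_length: float, rate: float, rng: np.random.Generator) -> str:
    n_sub = rng.poisson(rate * branch_length * len(seq))
    if n_sub == 0:
        return seq
    chars = list(seq)
    for p in rng.integers(0, len(seq), size=n_sub):
        alternatives = [a for a in _AMINO if a != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def gen_families(
    n_families: int = 10,
    taxa_per_group: int = 3,
    tree_depth: float = 0.3,
    subst_rate: float = 0.5,
    seed: int = 0,
    protein_len: int = 150,
    donors: tuple[str, ...] = ("cyanobacterial", "eukaryotic", "bacterial_other"),
    mixed_sister: bool = False,
) -> tuple[dict[str, list[SequenceRecord]], dict[str, str], list[FamilyTruth]]:
    """Evolve protein families on known trees with a known donor per query.

    Each family has monophyletic cyanobacterial / other-bacterial /
    reference-eukaryote clades; the query gene is attached as sister to a
    random leaf inside the donor clade (so the true sister group is pure).
    With ``mixed_sister`` the query is instead attached to a planted
    two-leaf cherry of one cyanobacterial and one eukaryotic leaf — a case
    that must be classified ambiguous.  Sequences evolve from a random
    ancestral protein by Poisson(rate × branch length × length) uniform
    amino-acid substitutions.

    Returns (families: family_id → records, leaf → taxon group, truths).
    """
    rng = np.random.default_rng(seed)
    bl = (0.2 * tree_depth, tree_depth)
    families: dict[str, list[SequenceRecord]] = {}
    groups: dict[str, str] = {}
    truths: list[FamilyTruth] = []
    group_prefix = {"cyanobacteria": "CY", "other_bacteria": "OB", "reference_eukaryote": "RE"}

    for f in range(n_families):
        fam = f"fam{f:03d}"
        donor = "mixed" if mixed_sister else donors[f % len(donors)]
        leaf_groups: dict[str, str] = {}
        clades = []
        query_id = f"{fam}_Q"
        for grp, prefix in group_prefix.items():
            labels = [f"{fam}_{prefix}{i}" for i in range(taxa_per_group)]
            for lab in labels:
                leaf_groups[lab] = grp
            if mixed_sister and grp == "cyanobacteria":
                labels = labels[1:]  # one cyano leaf moves into the cherry
            if mixed_sister and grp == "reference_eukaryote":
                labels = labels[1:]
            clades.append(_random_bifurcating(labels, rng, bl))
        if mixed_sister:
            cherry = TreeNode(children=[
                TreeNode(label=f"{fam}_CY0", branch_length=float(rng.uniform(*bl))),
                TreeNode(label=f"{fam}_RE0", branch_length=float(rng.uniform(*bl))),
            ], branch_length=float(rng.uniform(*bl)))
            attach_to = cherry
            clades.append(cherry)
        else:
            donor_grp = DONOR_GROUP[donor]
            donor_clade = clades[list(group_prefix).index(donor_grp)]
            attach_to = rng.choice(donor_clade.leaves())
        # graft the query as sister to the attachment node; the planted
        # mixed cherry keeps a firm stem so its quartet is resolvable
        query_leaf = TreeNode(label=query_id, branch_length=float(rng.uniform(*bl)) * 0.5)
        sibling_bl = (float(rng.uniform(0.5, 1.0)) * tree_depth if mixed_sister
                      else float(rng.uniform(*bl)) * 0.5)
        sibling = TreeNode(label=attach_to.label, children=attach_to.children,
                           branch_length=sibling_bl)
        attach_to.label = None
        attach_to.children = [query_leaf, sibling]
        leaf_groups[query_id] = "query"

        root = clades[0]
        for clade in clades[1:]:
            root = TreeNode(children=[root, clade], branch_length=float(rng.uniform(*bl)))
        root.branch_length = None

        ancestral = _random_protein(rng, protein_len)
        records: list[SequenceRecord] = []

        def evolve_down(node: TreeNode, seq: str) -> None:
            seq = _evolve(seq, node.branch_length or 0.0, subst_rate, rng)
            if node.is_leaf:
                records.append(SequenceRecord(
                    id=node.label, seq=seq, kind="protein",
                    taxon_group=leaf_groups[node.label],
                ))
            else:
                for child in node.children:
                    evolve_down(child, seq)

        evolve_down(root, ancestral)
        records.sort(key=lambda r: r.id)
        families[fam] = records
        groups.update(leaf_groups)
        truths.append(FamilyTruth(family_id=fam, true_tree=root, donor=donor,
                                  query_gene_id=query_id))
    return families, groups, truths


def tree_distance_matrix(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Additive path-length distance matrix of a tree (test oracle input)."""
    leaves = tree.leaf_labels()
    index = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}
        below: dict[str, float] = {}
        child_maps = []
        for child in node.children:
            cm = {lab: d + (child.branch_length or 0.0) for lab, d in walk(child).items()}
            child_maps.append(cm)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for la, da in child_maps[a].items():
                    for lb, db in child_maps[b].items():
                        dist[index[la], index[lb]] = dist[index[lb], index[la]] = da + db
        for cm in child_maps:
            below.update(cm)
        return below

    walk(tree)
    return dist, leaves


def random_additive_matrix(n_taxa: int, rng: np.random.Generator,
                           bl_range: tuple[float, float] = (0.1, 1.0)
                           ) -> tuple[np.ndarray, list[str], TreeNode]:
    """A random bifurcating tree plus its exactly additive distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    tree = _random_bifurcating(labels, rng, bl_range)
    tree.branch_length = None
    dist, ids = tree_distance_matrix(tree)
    return dist, ids, tree


# ---------------------------------------------------------------------------
# GO universe with planted enrichment
# ---------------------------------------------------------------------------

@dataclass
class GoUniverseTruth:
    planted_terms: list[str]
    study_fold: dict[str, float]
    slim_terms: list[str]


def gen_go_universe(
    n_genes: int = 1000,
    n_terms: int = 60,
    planted: list[tuple[str, float]] | None = None,
    study_frac: float = 0.1,
    seed: int = 0,
    n_slim: int = 8,
    genes_per_planted_term: int = 50,
    mean_terms_per_gene: float = 2.0,
) -> tuple[str, str, list[str], GoUniverseTruth]:
    """Random GO-like DAG + GAF + study list with planted term enrichment.

    ``planted`` lists (term id, study_fold) pairs; a gene annotated to a
    planted term enters the study set with probability
    ``study_fold × study_frac`` (so the expected study count of a planted
    term with K genes is fold × study_frac × K).  fold = 1 for every term
    gives a null universe.  Returns (OBO text, GAF text, study gene list,
    truth).
    """
    rng = np.random.default_rng(seed)
    planted = planted or []
    for term, fold in planted:
        if fold < 1:
            raise ValueError("study_fold must be ≥ 1")
        if fold * study_frac > 1.0:
            raise ValueError(
                f"fold {fold} with study fraction {study_frac} implies inclusion "
                "probability > 1; infeasible"
            )

    root = "GO:0000001"
    slim = [f"GO:{i + 2:07d}" for i in range(n_slim)]
    leaves = [f"GO:{i + 2 + n_slim:07d}" for i in range(n_terms - 1 - n_slim)]
    lines = ["format-version: 1.2", "ontology: synthetic", ""]

    def stanza(term: str, name: str, parents: list[str], part_of: list[str] = ()) -> None:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {name}")
        lines.append("namespace: biological_process")
        for p in parents:
            lines.append(f"is_a: {p} ! parent")
        for p in part_of:
            lines.append(f"relationship: part_of {p} ! parent")
        lines.append("")

    stanza(root, "biological_process", [])
    for t in slim:
        stanza(t, f"slim term {t}", [root])
    for t in leaves:
        parents = [slim[int(rng.integers(len(slim)))]]
        part_of: list[str] = []
        if rng.random() < 0.2:  # diamond: a second parent
            other = slim[int(rng.integers(len(slim)))]
            if other not in parents:
                part_of.append(other)
        stanza(t, f"leaf term {t}", parents, part_of)
    obo_text = "\n".join(lines)

    genes = [f"gene{i:05d}" for i in range(n_genes)]
    planted_ids = [t for t, _ in planted]
    for t in planted_ids:
        if t not in leaves:
            raise ValueError(f"planted term {t} is not a leaf term of this universe")
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    # planted terms get exactly genes_per_planted_term genes each
    unassigned = list(genes)
    rng.shuffle(unassigned)
    planted_genes: dict[str, list[str]] = {}
    cursor = 0
    for t in planted_ids:
        chunk = unassigned[cursor : cursor + genes_per_planted_term]
        cursor += genes_per_planted_term
        planted_genes[t] = chunk
        for g in chunk:
            annotations[g].add(t)
    free_leaves = [t for t in leaves if t not in planted_ids]
    for g in genes:
        n_extra = max(0, int(rng.poisson(mean_terms_per_gene)))
        for _ in range(n_extra):
            annotations[g].add(free_leaves[int(rng.integers(len(free_leaves)))])
        if not annotations[g]:
            annotations[g].add(free_leaves[int(rng.integers(len(free_leaves)))])

    gaf_rows = ["!gaf-version: 2.2"]
    for g in genes:
        for t in sorted(annotations[g]):
            gaf_rows.append("\t".join([
                "SYN", g, g, "", t, "SYN:0000000", "IEA", "", "P",
                g, "", "protein", "taxon:0000", "20150101", "SYN", "", "",
            ]))
    gaf_text = "\n".join(gaf_rows)

    fold_of = dict(planted)
    study: list[str] = []
    in_study: set[str] = set()
    for t in planted_ids:
        p_in = fold_of[t] * study_frac
        for g in planted_genes[t]:
            if g not in in_study and rng.random() < p_in:
                in_study.add(g)
                study.append(g)
    target = int(round(study_frac * n_genes))
    rest = [g for g in genes if g not in in_study]
    rng.shuffle(rest)
    while len(study) < target and rest:
        study.append(rest.pop())
    study.sort()

    truth = GoUniverseTruth(planted_terms=planted_ids, study_fold=fold_of, slim_terms=slim)
    return obo_text, gaf_text, study, truth


# ---------------------------------------------------------------------------
# EST libraries
# ---------------------------------------------------------------------------

def gen_ests(
    genes: list[SequenceRecord],
    expressed_frac: float = 0.7,
    fragment_len_range: tuple[int, int] = (100, 300),
    seed: int = 0,
    mutation_rate: float = 0.005,
) -> tuple[list[SequenceRecord], dict[str, bool]]:
    """EST fragments covering a known subset of genes.

    Each expressed gene contributes 1–3 fragments copied from a random
    interval; light substitutions may be applied but the first 50 bp of
    every fragment stay exact so a megablast-style word seed always exists.
    Fragments are emitted on a random strand.
    """
    if not 0.0 <= expressed_frac <= 1.0:
        raise ValueError("expressed_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    ests: list[SequenceRecord] = []
    truth: dict[str, bool] = {}
    for gene in genes:
        expressed = bool(rng.random() < expressed_frac)
        truth[gene.id] = expressed
        if not expressed:
            continue
        for frag_idx in range(int(rng.integers(1, 4))):
            flen = int(rng.integers(fragment_len_range[0],
                                    min(fragment_len_range[1], len(gene.seq)) + 1))
            start = int(rng.integers(0, len(gene.seq) - flen + 1))
            frag = list(gene.seq[start : start + flen])
            n_mut = rng.poisson(mutation_rate * max(0, flen - 50))
            if n_mut:
                positions = 50 + rng.choice(flen - 50, size=min(n_mut, flen - 50),
                                            replace=False)
                _substitute(frag, positions, rng)
            seq = "".join(frag)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            ests.append(SequenceRecord(id=f"{gene.id}_est{frag_idx}", seq=seq,
                                       kind="nucleotide"))
    return ests, truth


# ---------------------------------------------------------------------------
# Truth-table serialization
# ---------------------------------------------------------------------------

def write_implant_truth_tsv(truths: list[ImplantTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("nuclear_id\tn_start\tn_end\to_start\to_end\tstrand\t"
                 "planted_identity_pct\tcopy_index\n")
        for t in truths:
            fh.write(f"{t.nuclear_id}\t{t.n_start}\t{t.n_end}\t{t.o_start}\t{t.o_end}\t"
                     f"{t.strand}\t{t.planted_identity_pct:.2f}\t{t.copy_index}\n")


def write_family_truth_tsv(truths: list[FamilyTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tquery_gene_id\tdonor\ttrue_tree\n")
        for t in truths:
            fh.write(f"{t.family_id}\t{t.query_gene_id}\t{t.donor}\t"
                     f"{write_newick(t.true_tree)}\n")
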