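# Methods

`egtcensus` re-implements, as one tested pipeline, the classic census of
endosymbiotic gene transfer (EGT) in photosynthetic eukaryotes: how much
organelle DNA sits in the nuclear genome (NUPTs/NUMTs), which nuclear genes
descend from the cyanobacterial endosymbiont, whether those recruits are
expressed, what functional fingerprint they carry (GO-term abundance,
rendered as Voronoi treemaps), and how variable genome-level measures are
across phylogenetic groups. Every stage can be exercised on synthetic data
with known ground truth; nothing requires a download.

## Insertion census (NUPT/NUMT detection)

**Model.** An organelle→nuclear insertion is a nuclear segment homologous to
a contiguous organelle interval on either strand. Detection is
seed–chain–align:

1. *Seeding.* Every exact shared word of `word_size` bases (default 50, the
   stringent setting used for genome-scale BLAST/NUCMER screens of organelle
   insertions) between the nuclear forward strand and the organelle forward
   or reverse-complement strand becomes an anchor. Words containing N never
   match. A `circular` flag pads the organelle with its first
   `word_size − 1` bases so matches crossing the origin of a circular genome
   can seed; by default organelles are treated as linear, which only affects
   hits spanning the origin.
2. *Chaining.* Anchors on the same strand are joined while both the nuclear
   and organelle start-coordinate steps stay within
   `max_join_gap + word_size` (default 100 + 50) and the organelle
   coordinate advances consistently with the strand. Chains are maximal
   under this rule. Anchors are consumed in nuclear order; an anchor
   extendable into several chains attaches to the one with the leftmost
   organelle start, making output deterministic.
3. *Alignment.* Each chain's spanned nuclear and organelle regions are
   globally aligned with a banded edit-distance alignment (edlib, NW mode);
   percent identity is matched columns over all alignment columns of the
   optimal alignment. Only the identity percentage is consumed downstream,
   which is why an edit-distance optimum (rather than a bespoke scoring
   scheme) is the pragmatic choice.
4. *Filtering.* Hits are retained when identity is **strictly greater** than
   `min_identity_pct` (default 80) and length ≥ `min_length` (default 50).

**Summaries.** The *exchange rate* is the percentage of organelle positions
covered by ≥1 retained hit (reported to 0.01%). The per-position depth is
the *copy number* of that organelle region in the nuclear genome. The size
histogram bins retained hits at 50–99, 100–199, …, 500–999, ≥1000 bp.
Overlapping hits are *not* merged before counting (each maximal chain is one
countable insertion) while coverage uses the interval union — the two
summaries are deliberately not derivable from each other.

**Known limitation.** With a 50 bp exact-word seed, insertions whose
divergence is spread uniformly (e.g. ancient transfers at ≤75 % identity)
contain essentially no seed and are invisible; this is inherent to the
word-size choice, not to the implementation, and is mirrored exactly by the
synthetic generator (below).

## Protein homology and expression

BLASTP-style search is implemented as k-mer-prefiltered exact
Smith–Waterman: candidate pairs must share one exact 4-mer; survivors are
aligned optimally under affine gaps (BLOSUM62; a gap of length L costs
`gap_open + L·gap_extend`, defaults 11/1) via Biopython's `PairwiseAligner`,
which computes the exact DP optimum. One best alignment per pair is kept
(no sub-optimal HSPs) because all downstream filters operate per pair.
Significance uses the Karlin–Altschul form `E = K·m·n·e^(−λS)` with fixed
constants (λ=0.267, K=0.041 for the gapped BLOSUM62 regime; λ=1.28, K=0.46
for nucleotides). λ and K are deliberately not fitted: only the threshold
decision matters and both thresholds (`E ≤ 1e−10`, identity ≥ 25 %) are
directly configurable. Identity uses alignment columns including gaps as
the denominator (the blastp identities/length convention).

Expression is qualified, not quantified: a gene is *expressed* as soon as
one EST alignment seeded by an exact 28-mer (megablast-style) passes the
E-value threshold; both gene strands are screened because EST orientation
is arbitrary. The EST step's E-value threshold defaults to the same 1e−10
as the protein screen and is exposed in the API.

## Origin classification

Each gene family yields a distance matrix from pairwise local alignments:
`D` = fraction of non-identical columns, corrected with Kimura's protein
distance `d = −ln(1 − D − D²/5)` and capped at 5.0 for `D ≥ 0.85`. Trees
come from classical neighbor joining (scikit-bio, negative branch lengths
clamped to zero) — a deliberately desk-scale stand-in for ML tree
inference; externally computed ML trees in newick are accepted as drop-in
input, since the classification logic is a tree *consumer*.

The tree is read unrooted. The query leaf's attachment node splits the
remaining leaves into candidate sides; the *sister group* is the side with
the fewest leaves. Size ties are broken by a canonical order on the sorted
leaf labels (greatest tuple wins) so the call is deterministic and
independent of input rooting; ties are a degenerate corner and the reported
`sister_cyano_fraction` lets users re-threshold regardless. Same-species
paralog leaves are excluded from composition counting (recent duplicates
carry no donor signal). The call is **cyanobacterial** on a strict majority
(>0.5) of cyanobacterial leaves among counted sister leaves,
**non-cyanobacterial** when the sister contains none, and **ambiguous**
otherwise — including exact 50/50 mixtures.

Census tables are set algebra over three relations: recruit calls,
nuclear↔plastid homolog pairs, and expression calls. Distinct gene ids are
counted, never gene copies. The expressed-recruit percentage is computed
over recruits whose expression was actually assessed.

## GO-term abundance

Annotations are propagated to all is_a/part_of ancestors within the term's
namespace (true-path rule), optionally collapsed to the most-specific
GO-Slim ancestors (a slim root is masked by a more specific slim ancestor
on the same path). Each term annotated in the study set is tested with the
hypergeometric upper tail P[X ≥ k] (over-representation only — the census
asks which functions are enriched among recruits). Multiple-test
adjustment is Benjamini–Hochberg FDR by default, applied within each
namespace separately, with Bonferroni and Hochberg as switches; the method
is recorded in the output header. Significance is strict: `p_adj < alpha`
(default 0.05). The background defaults to all annotated genes and can be
overridden by file; GAF evidence codes are not filtered unless IEA
exclusion is requested.

## Voronoi treemaps

Cells are an additively weighted (power) Voronoi diagram inside a convex
container, computed by clipping the container with the power bisector
half-plane of every site pair (with a distance-sorted early-exit: a site
whose bisector lies beyond every current cell vertex cannot cut the cell).
Areas are driven to the weight proportions by alternating Lloyd centroid
moves with an additive update of each power weight proportional to the
cell's area deficit — a damped gradient step on the concave area-capacity
objective of power diagrams. The step size starts at 0.8 of the container
area scale and backs off 10 % whenever the worst relative error increases.
Iteration stops when every cell's relative area error is within
`max_area_error` (default 1 %) or after `max_iterations` (default 500;
cells are then flagged non-converged rather than silently accepted).
Multiplicative weight rescaling was tried first and stalled far from
tolerance; the additive update converges reliably for ≤50 cells and is the
design the package ships.

Coincident equal-weight sites are separated by a seeded 1e−9 jitter.
Hierarchical layouts recurse into each parent polygon; an internal term
heavier than its children gets an explicit residual cell. Cell weight
defaults to the study gene count per term (the figure encodes abundance);
coloring is a viridis ramp over −log10(p_adj) clipped to
[−log10(α), 10], with a flat light-grey band for non-significant cells
(strict `p_adj < α` rule) and neutral grey for terms without a result. SVG
output is plain formatted text, byte-identical for identical seeds and
inputs.

## Genome group statistics

Per (phylogenetic group, compartment) cell: arithmetic mean and relative
standard deviation (RSD = 100 × sd/mean) of genome length, protein count,
RNA count and coding fraction. The sample (n−1) standard deviation is used
and stated in the output header; a single-genome cell reports RSD 0 with a
warning; empty cells are absent, never imputed. RSD is scale-free, so the
unit of length (bp vs Mbp) is immaterial.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under a seed and emit truth tables.

**Implanted genomes.** The organelle is i.i.d. uniform ACGT; implants copy
an organelle interval, substitute bases down to a planted identity,
reverse-complement half the time, and overwrite non-overlapping nuclear
slots ≥200 bp apart. Substitution *positions* follow a mosaic model:
implants at ≥75 % planted identity erode up to 12 bp at each edge and place
remaining divergence in interior hotspots that alternate with conserved
≥50 bp windows spaced ≤140 bp apart — emulating the patchy conservation of
recent transfers, and guaranteeing by construction that such implants carry
intact seed words near both boundaries. Implants below 75 % identity
scatter substitutions uniformly, which makes them (correctly) invisible to
word-50 seeding. Substituted bases are uniform over the three alternatives
and no indels are introduced, so planted identity is exact; the nuclear
base flanking each implant is forced to mismatch the organelle
continuation, keeping planted boundaries sharp. Real genomes differ in
composition (isochores, repeats, real indel processes); passing these tests
shows the detector's bookkeeping and guarantees are correct under the
stated divergence model, not that the word-50 screen recovers arbitrarily
diverged real insertions.

**Protein families.** A random ancestral protein evolves along a random
bifurcating tree with monophyletic cyanobacterial / other-bacterial /
eukaryote clades by Poisson(rate × branch length × length) uniform
amino-acid replacements (no JTT bias — topology recovery needs additive-ish
distances, not realistic exchangeabilities). The query attaches as sister
to a leaf of the donor clade, or, in mixed-sister mode, to a planted
cyanobacterium+eukaryote cherry whose stem is kept ≥0.5 × tree depth so the
quartet is resolvable. Classification guarantees are stated for the
low-divergence regime (tree depth 0.2 substitutions/site, 300-residue
proteins), where NJ reliably recovers the planted topology.

**GO universes.** A single-namespace DAG with a slim layer and occasional
diamond parents; planted terms have a fixed gene count K and their genes
enter the study set with probability fold × study_frac (so the spec-level
design N=1000, K=50, n≈100, fold=5 gives E[k]=25). fold=1 everywhere gives
the null universes used for calibration.

**EST libraries.** Expressed genes contribute 1–3 fragments on random
strands with light (0.5 %) substitutions that spare the first 50 bp, so a
28-mer seed always survives.

## Problem sizes used in tests and in the acceptance script

Full-scale detection runs at 1 Mb nuclear / 150 kb organelle / 100
implants; exchange-rate replication uses 20 seeds at 250 kb / 30 kb / 25
implants; alignment and topology oracles use 200 pairs (≤40 aa) and 100
6-taxon matrices; enrichment calibration uses 200 null and 100 planted
universes of 1,000 genes; treemap convergence uses 100 runs of 5–50 cells.
These sizes make every guarantee measurable in minutes on one core while
keeping each estimate's sampling error well inside the asserted tolerance.

## Numerical and degenerate-input choices

* Interval coordinates are 0-based half-open on the forward strand
  throughout; conversion happens only in report writers.
* `find_seed_matches` with a word longer than either sequence warns and
  returns nothing; an empty anchor list chains to an empty hit list.
* `hypergeom_upper` validates count consistency and is exact to ≤1e−12
  against direct enumeration for N ≤ 12.
* Power-diagram cells partition the container to ~1e−9 relative area; empty
  cells are returned as empty polygons and flagged through non-convergence
  rather than dropped.
* The newick parser reports the character offset of syntax errors, accepts
  quoted labels, and round-trips branch lengths to 6 significant digits.
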