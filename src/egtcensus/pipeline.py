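"""End-to-end orchestration of the census from a single YAML config.

Stages run in method order — insertion census per organelle, protein
homology, origin classification, expression, census summary, GO enrichment,
treemap, genome group statistics — each emitting a TSV (or SVG) under the
output directory and one structured log line with its input/output row
counts.  Re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    formats_io,
    genome_group_stats,
    go_enrichment,
    insertion_census,
    origin_phylogeny,
    protein_homology,
    voronoi_treemap,
)

logger = logging.getLogger("egtcensus")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    nuclear_fasta: Path | None = None
    plastid_fasta: Path | None = None
    mitochondrial_fasta: Path | None = None
    nuclear_proteins_fasta: Path | None = None
    plastid_proteins_fasta: Path | None = None
    families_dir: Path | None = None
    groups_tsv: Path | None = None
    trees_dir: Path | None = None
    est_fasta: Path | None = None
    gene_fasta: Path | None = None
    obo: Path | None = None
    gaf: Path | None = None
    slim_ids: Path | None = None
    background: Path | None = None
    study: Path | None = None  # explicit study list; default = recruit calls
    genome_metadata_tsv: Path | None = None
    word_size: int = 50
    min_identity: float = 80.0
    min_length: int = 50
    max_evalue: float = 1e-10
    min_protein_identity: float = 25.0
    alpha: float = 0.05
    _path_fields = ("nuclear_fasta", "plastid_fasta", "mitochondrial_fasta",
                    "nuclear_proteins_fasta", "plastid_proteins_fasta", "families_dir",
                    "groups_tsv", "trees_dir", "est_fasta", "gene_fasta", "obo", "gaf",
                    "slim_ids", "background", "study", "genome_metadata_tsv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{**known, "out_dir": Path(raw["out_dir"])})
        for name in cls._path_fields:
            value = getattr(cfg, name)
            if value is not None:
                setattr(cfg, name, Path(value))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in self._path_fields:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {value}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.word_size < 8 or self.min_length < 1 or not 0 <= self.min_identity <= 100:
            raise ValueError("census thresholds out of range")


@dataclass
class StageResult:
    name: str
    outputs: list[Path] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def run(config: PipelineConfig) -> list[StageResult]:
    """Run every stage the config provides inputs for; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[StageResult] = []

    def stage(name: str):
        res = StageResult(name=name)
        manifest.append(res)
        return res

    try:
        nuclear = None
        if config.nuclear_fasta:
            nuclear = formats_io.read_fasta(config.nuclear_fasta, kind="nucleotide")

        for organelle_path, cls in ((config.plastid_fasta, "NUPT"),
                                    (config.mitochondrial_fasta, "NUMT")):
            if organelle_path is None or nuclear is None:
                continue
            res = stage(f"insertion_census_{cls}")
            organelle = formats_io.read_fasta(organelle_path, kind="nucleotide")[0]
            hits = insertion_census.detect_insertions(
                nuclear, organelle, word_size=config.word_size,
                min_identity_pct=config.min_identity, min_length=config.min_length,
                class_=cls)
            profile = insertion_census.coverage_profile(hits, organelle)
            hist = insertion_census.size_histogram(hits)
            paths = [out / f"{cls.lower()}_hits.tsv", out / f"{cls.lower()}_hits.bed",
                     out / f"{cls.lower()}_coverage.tsv", out / f"{cls.lower()}_histogram.tsv"]
            insertion_census.write_hits_tsv(hits, paths[0])
            insertion_census.write_hits_bed(hits, paths[1])
            insertion_census.write_coverage_tsv(profile, paths[2])
            insertion_census.write_histogram_tsv(hist, paths[3],
                                                 exchange_pct=profile.exchange_rate_pct)
            res.outputs = paths
            res.counts = {"hits": len(hits), "exchange_pct_x100":
                          int(round(profile.exchange_rate_pct * 100))}
            logger.info("stage %s: %d hits, exchange %.2f%%", res.name, len(hits),
                        profile.exchange_rate_pct)

        nuc_vs_plastid = None
        if config.nuclear_proteins_fasta and config.plastid_proteins_fasta:
            res = stage("nuclear_vs_plastid_homology")
            nuc_prot = formats_io.read_fasta(config.nuclear_proteins_fasta, kind="protein")
            pla_prot = formats_io.read_fasta(config.plastid_proteins_fasta, kind="protein")
            nuc_vs_plastid = protein_homology.search(
                nuc_prot, pla_prot, role="nuclear_vs_plastid",
                min_identity_pct=config.min_protein_identity,
                max_evalue=config.max_evalue)
            path = out / "nuclear_vs_plastid.tsv"
            protein_homology.write_homology_tsv(nuc_vs_plastid, path)
            res.outputs = [path]
            res.counts = {"pairs": len(nuc_vs_plastid.rows)}

        calls = []
        if config.families_dir and config.groups_tsv:
            res = stage("origin_classification")
            groups = _read_groups(config.groups_tsv)
            trees = {}
            if config.trees_dir:
                for tree_path in sorted(Path(config.trees_dir).glob("*.nwk")):
                    trees[tree_path.stem] = formats_io.read_newick(tree_path.read_text())
            for fam_path in sorted(Path(config.families_dir).glob("*.fasta")):
                family = formats_io.read_fasta(fam_path, kind="protein")
                query = next((r.id for r in family if groups.get(r.id) == "query"), None)
                if query is None:
                    raise ValueError(f"family {fam_path.stem} has no query-group member")
                fam_groups = {r.id: groups[r.id] for r in family if r.id != query}
                fam_groups[query] = "query"
                calls.append(origin_phylogeny.classify_family(
                    family, query, fam_groups, tree=trees.get(fam_path.stem),
                    tree_id=fam_path.stem))
            path = out / "origin_calls.tsv"
            origin_phylogeny.write_origin_calls_tsv(calls, path)
            res.outputs = [path]
            res.counts = {"families": len(calls),
                          "cyanobacterial": sum(c.call == "cyanobacterial" for c in calls)}

        expression = None
        if config.gene_fasta and config.est_fasta:
            res = stage("expression")
            genes = formats_io.read_fasta(config.gene_fasta, kind="nucleotide")
            ests = formats_io.read_fasta(config.est_fasta, kind="nucleotide")
            expression = {g.id: protein_homology.est_expressed(g, ests,
                                                               max_evalue=config.max_evalue)
                          for g in genes}
            path = out / "expression.tsv"
            with open(path, "w") as fh:
                fh.write("gene_id\texpressed\n")
                for gid in sorted(expression):
                    fh.write(f"{gid}\t{str(expression[gid]).lower()}\n")
            res.outputs = [path]
            res.counts = {"genes": len(expression),
                          "expressed": sum(expression.values())}

        if calls or nuc_vs_plastid:
            res = stage("census_summary")
            pairs = nuc_vs_plastid.pairs() if nuc_vs_plastid else set()
            plastid_ids = ([r.id for r in formats_io.read_fasta(
                config.plastid_proteins_fasta, kind="protein")]
                if config.plastid_proteins_fasta else [])
            summary = origin_phylogeny.build_census(calls, pairs, plastid_ids, expression)
            path = out / "census_summary.tsv"
            origin_phylogeny.write_census_tsv(summary, path)
            res.outputs = [path]
            res.counts = {"recruits": summary.n_cyano_recruits}

        if config.obo and config.gaf:
            res = stage("go_enrichment")
            slim = set()
            if config.slim_ids:
                slim = {line.strip() for line in open(config.slim_ids) if line.strip()}
            graph, annotations = formats_io.read_ontology(config.obo, config.gaf,
                                                          slim_ids=slim)
            population = (
                {line.strip() for line in open(config.background) if line.strip()}
                if config.background else set(annotations))
            if config.study:
                study = {line.strip() for line in open(config.study) if line.strip()}
            else:
                study = {c.gene_id for c in calls if c.call == "cyanobacterial"} & population
                if not study:
                    study = population  # degenerate but well-defined fallback
            results = go_enrichment.enrich(study, population, annotations, graph,
                                           alpha=config.alpha, use_slim=bool(slim))
            path = out / "enrichment.tsv"
            go_enrichment.write_enrichment_tsv(results, path)
            res.outputs = [path]
            res.counts = {"terms": len(results),
                          "significant": sum(r.significant for r in results)}

            res = stage("voronoi_treemap")
            top = [r for r in results if r.k > 0]
            if slim:
                top = [r for r in top if r.term in slim]
            if top:
                root = voronoi_treemap.WeightedTerm(
                    term="root", weight=float(sum(r.k for r in top)),
                    children=[voronoi_treemap.WeightedTerm(term=r.term, weight=float(r.k))
                              for r in top])
                layout_cfg = voronoi_treemap.LayoutConfig(seed=config.seed)
                cells = voronoi_treemap.layout_hierarchy(root, layout_cfg)
                voronoi_treemap.color_by_significance(cells, results, alpha=config.alpha)
                svg_path = out / "treemap.svg"
                svg_path.write_text(voronoi_treemap.render_svg(cells))
                tsv_path = out / "treemap_cells.tsv"
                voronoi_treemap.write_cells_tsv(cells, tsv_path)
                res.outputs = [svg_path, tsv_path]
                res.counts = {"cells": len(cells)}

        if config.genome_metadata_tsv:
            res = stage("genome_group_stats")
            measures = genome_group_stats.read_measures_tsv(config.genome_metadata_tsv)
            table = genome_group_stats.group_table(measures)
            path = out / "group_stats.tsv"
            genome_group_stats.write_group_table_tsv(table, path)
            res.outputs = [path]
            res.counts = {"cells": len(table)}
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        stage_name = manifest[-1].name if manifest else "validation"
        (failed / "STAGE").write_text(stage_name + "\n")
        logger.exception("pipeline aborted in stage %s", stage_name)
        raise

    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("stage\toutput\tcounts\n")
        for res in manifest:
            counts = ";".join(f"{k}={v}" for k, v in sorted(res.counts.items()))
            for p in res.outputs:
                fh.write(f"{res.name}\t{p.name}\t{counts}\n")
    return manifest


def build_synthetic_workspace(workdir: str | Path, seed: int = 42) -> PipelineConfig:
    """Write a small, fully synthetic input set plus a ready-to-run config.

    Emulates one query species: a nuclear contig with implanted plastome
    fragments, protein families with known donors, plastid/nuclear protein
    sets, an EST library, a GO universe with one planted enriched term, and
    a genome metadata table.  Deterministic under the seed.
    """
    from . import synthetic_data as sd

    d = Path(workdir)
    d.mkdir(parents=True, exist_ok=True)
    nuclear, organelle, _ = sd.gen_genome_with_implants(
        organelle_len=20_000, nuclear_len=150_000, n_implants=12,
        length_range=(60, 1200), identity_range=(85, 100), seed=seed)
    formats_io.write_fasta([nuclear], d / "nuclear.fasta")
    formats_io.write_fasta([organelle], d / "plastid.fasta")

    families, groups, _ = sd.gen_families(n_families=6, seed=seed)
    fam_dir = d / "families"
    fam_dir.mkdir(exist_ok=True)
    for fam, records in families.items():
        formats_io.write_fasta(records, fam_dir / f"{fam}.fasta")
    with open(d / "groups.tsv", "w") as fh:
        fh.write("leaf_id\ttaxon_group\n")
        for leaf in sorted(groups):
            fh.write(f"{leaf}\t{groups[leaf]}\n")

    nuc_prot = [r for fam in families.values() for r in fam if r.taxon_group == "query"]
    pla_prot = [formats_io.SequenceRecord(
        id=f"pla_{fam}", kind="protein",
        seq=next(r.seq for r in records if r.taxon_group == "cyanobacteria"))
        for fam, records in families.items()]
    formats_io.write_fasta(nuc_prot, d / "nuclear_proteins.fasta")
    formats_io.write_fasta(pla_prot, d / "plastid_proteins.fasta")

    genes = [formats_io.SequenceRecord(id=r.id, kind="nucleotide",
                                       seq=nuclear.seq[i * 800 : i * 800 + 600])
             for i, r in enumerate(nuc_prot)]
    ests, _ = sd.gen_ests(genes, expressed_frac=0.8, seed=seed)
    formats_io.write_fasta(genes, d / "genes.fasta")
    formats_io.write_fasta(ests, d / "ests.fasta")

    obo, gaf, study, go_truth = sd.gen_go_universe(
        planted=[("GO:0000010", 5.0)], seed=seed)
    (d / "universe.obo").write_text(obo)
    (d / "annotations.gaf").write_text(gaf)
    (d / "study.txt").write_text("\n".join(study) + "\n")
    (d / "slim.txt").write_text("\n".join(go_truth.slim_terms) + "\n")

    with open(d / "genome_metadata.tsv", "w") as fh:
        fh.write("species\tgroup\tcompartment\tlength_bp\tn_proteins\tn_rnas\t"
                 "coding_fraction\n")
        fh.write("query_sp\tAngiosperms\tplastid\t150000\t85\t40\t0.55\n")
        fh.write("sister_sp\tAngiosperms\tplastid\t160000\t80\t42\t0.52\n")
        fh.write("outgroup_sp\tChlorophyta\tplastid\t120000\t70\t35\t0.60\n")

    config = PipelineConfig(
        out_dir=d / "out", seed=seed,
        nuclear_fasta=d / "nuclear.fasta", plastid_fasta=d / "plastid.fasta",
        nuclear_proteins_fasta=d / "nuclear_proteins.fasta",
        plastid_proteins_fasta=d / "plastid_proteins.fasta",
        families_dir=fam_dir, groups_tsv=d / "groups.tsv",
        est_fasta=d / "ests.fasta", gene_fasta=d / "genes.fasta",
        obo=d / "universe.obo", gaf=d / "annotations.gaf",
        slim_ids=d / "slim.txt", study=d / "study.txt",
        genome_metadata_tsv=d / "genome_metadata.tsv")
    with open(d / "config.yaml", "w") as fh:
        for name in config._path_fields + ("out_dir",):
            value = getattr(config, name)
            if value is not None:
                fh.write(f"{name}: {value}\n")
        fh.write(f"seed: {seed}\n")
    return config


def _read_groups(path: Path) -> dict[str, str]:
    groups = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("leaf_id"):
            raise ValueError("groups table must have a 'leaf_id\\ttaxon_group' header")
        for line in fh:
            if line.strip():
                leaf, group = line.rstrip("\n").split("\t")[:2]
                groups[leaf] = group
    return groups
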