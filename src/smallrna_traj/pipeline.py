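"""End-to-end orchestration: simulate -> quant -> map-loci -> de -> targets
-> enrich, with a hash-stable JSON run manifest.

Each stage is also runnable standalone from the previous stage's serialized
outputs (see :mod:`smallrna_traj.cli`); ``run_pipeline`` wires them together
for a single config and collects per-record errors instead of aborting.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import diffexpr, enrichment, paralogs, quant, simulate, targets
from .fold import classify_hairpin, fold_hairpin
from .io import read_fasta
from .seqs import to_dna

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"  # fixed float formatting keeps the manifest hash-stable


class ConfigError(ValueError):
    """A RunConfig that fails schema validation."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    reads_dir: Path | None = None
    genome: Path | None = None
    gff: Path | None = None
    refs_dir: Path | None = None
    terms: Path | None = None
    adapter: str | None = None
    min_overlap: int = 8
    min_cpm: float = 2.0
    max_gap: int = 10_000
    flank: int = 60
    seeds: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "outdir" not in raw:
            raise ConfigError("config field 'outdir' is required")
        kwargs = dict(raw)
        for key in ("outdir", "reads_dir", "genome", "gff", "refs_dir", "terms"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.simulate is None:
            missing = [
                name
                for name in ("reads_dir", "genome", "gff", "refs_dir")
                if getattr(self, name) is None
            ]
            if missing:
                raise ConfigError(
                    "config needs either a 'simulate' block or input paths; "
                    f"missing: {missing}"
                )
            for name in ("reads_dir", "genome", "gff", "refs_dir", "terms"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"missing input: {name} = {p}")
            if self.adapter is None:
                raise ConfigError("adapter is required for real-data runs")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage in dependency order; returns the in-memory results.

    Writes all stage tables under ``cfg.outdir`` and a ``manifest.json``
    hashing every output with the parameters that produced it.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    errors: list[dict] = []

    # --- stage 0: inputs (simulated or supplied) ---------------------------
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        if "family_specs" in sim_kwargs:
            sim_kwargs["family_specs"] = tuple(
                simulate.FamilySpec(**fs) for fs in sim_kwargs["family_specs"]
            )
        sim_config = simulate.SimConfig(**sim_kwargs)
        sim_dir = outdir / "sim"
        logger.info("simulating study under %s", sim_dir)
        truth = simulate.generate_genome(sim_config, sim_dir)
        simulate.generate_libraries(sim_config, truth, sim_dir)
        simulate.write_references(sim_config, sim_dir / "refs", truth)
        genome = truth.scaffolds
        design = truth.design
        reads_dir = sim_dir / "reads"
        gff_path = sim_dir / "annotation.gff3"
        refs_dir = sim_dir / "refs"
        terms_path = sim_dir / "refs" / "terms.tsv"
        adapter = sim_config.adapter
        seed_seqs = list(cfg.seeds)
        if not seed_seqs and sim_config.site_family is not None:
            fam = sim_config.site_family
            seed_seqs = [fam.seed_7mer, fam.seed_6mer]
        results["truth"] = truth
        results["sim_config"] = sim_config
    else:
        genome = read_fasta(cfg.genome)
        design = pd.read_csv(Path(cfg.reads_dir) / "design.tsv", sep="\t")
        reads_dir = Path(cfg.reads_dir)
        gff_path = Path(cfg.gff)
        refs_dir = Path(cfg.refs_dir)
        terms_path = cfg.terms
        adapter = cfg.adapter
        seed_seqs = list(cfg.seeds)
        truth = None
    results["design"] = design

    # --- stage 1: quantification ------------------------------------------
    logger.info("quantifying %d libraries", len(design))
    raw = quant.quantify_reads_dir(reads_dir, design, adapter, cfg.min_overlap)
    norm = quant.normalize_and_filter(raw, cfg.min_cpm)
    references = quant.load_references(refs_dir)
    annot = quant.annotate_tags(list(norm.index), references)
    lengths_reads = quant.length_distribution(raw, mode="reads")
    lengths_unique = quant.length_distribution(raw, mode="unique")
    top = quant.top_contributors(norm, annot, design, k=10)
    qdir = outdir / "quant"
    _write(norm, qdir / "normalized_matrix.tsv")
    _write(annot, qdir / "annotation.tsv")
    _write(lengths_reads, qdir / "length_distribution_reads.tsv")
    _write(lengths_unique, qdir / "length_distribution_unique.tsv")
    _write(top, qdir / "top_contributors.tsv", index=False)
    _write(
        quant.annotation_summary(annot, raw.loc[norm.index]),
        qdir / "annotation_summary.tsv",
    )
    results.update(
        raw=raw,
        norm=norm,
        annotation=annot,
        lengths_reads=lengths_reads,
        lengths_unique=lengths_unique,
        top_contributors=top,
    )

    # --- stage 2: paralog loci ---------------------------------------------
    mirna_refs = references.get("miRNA", {})
    canonical = {
        name: seq for name, seq in mirna_refs.items() if ".iso" not in name
    }
    loci: list[paralogs.GenomicLocus] = []
    locus_names: list[str] = []
    for name in sorted(canonical):
        for locus in paralogs.find_perfect_matches(canonical[name], genome):
            loci.append(locus)
            locus_names.append(name)
    clusters = paralogs.cluster_loci(loci, max_gap=cfg.max_gap)
    fold_rows = []
    for locus, name in zip(loci, locus_names):
        window = paralogs.extract_precursor(locus, genome, flank=cfg.flank)
        fold = fold_hairpin(window)
        classify_hairpin(fold)
        offset = window.find(to_dna(locus.mature))
        arm = paralogs.assign_arm(
            fold, offset if offset >= 0 else 0, len(locus.mature)
        )
        fold_rows.append(
            {
                "ref_name": name,
                "scaffold": locus.scaffold,
                "start": locus.start,
                "end": locus.end,
                "strand": locus.strand,
                "arm": arm,
                "n_pairs": fold.n_pairs,
                "longest_stem_run": fold.longest_stem_run,
                "paired_fraction": fold.paired_fraction,
                "is_hairpin": fold.is_hairpin,
                "structure": fold.structure,
                "window": fold.sequence,
            }
        )
    folds = pd.DataFrame(fold_rows)
    ldir = outdir / "loci"
    ldir.mkdir(parents=True, exist_ok=True)
    (ldir / "loci.bed").write_text(paralogs.loci_to_bed(loci, locus_names))
    _write(folds, ldir / "hairpins.tsv", index=False)
    cluster_df = pd.DataFrame(
        {
            "cluster_id": c.cluster_id,
            "name": c.name,
            "scaffold": c.scaffold,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "n_loci": len(c.loci),
        }
        for c in clusters
    )
    _write(cluster_df, ldir / "clusters.tsv", index=False)
    results.update(loci=loci, locus_names=locus_names, clusters=clusters, folds=folds)

    # --- stage 3: differential expression ----------------------------------
    mirna_tags = annot.index[annot["category"] == "miRNA"]
    mirna_norm = norm.loc[norm.index.intersection(mirna_tags)]
    de_frames = []
    for stage in design["stage"].unique():
        try:
            de_frames.append(
                diffexpr.stage_ttest(mirna_norm, design, stage, alpha=cfg.alpha)
            )
        except ValueError as exc:  # e.g. too few replicates in a subset design
            errors.append({"stage": stage, "error": str(exc)})
    de = pd.concat(de_frames) if de_frames else pd.DataFrame()
    centered, _medians = diffexpr.median_center(mirna_norm)
    ddir = outdir / "de"
    _write(de, ddir / "de_records.tsv")
    _write(centered, ddir / "centered_matrix.tsv")
    if len(mirna_norm) >= 2:
        clust = diffexpr.hcluster(mirna_norm)
        (ddir / "dendrogram.nwk").write_text(clust.newick + "\n")
        results["hclust"] = clust
    membership = {
        tag: annot.loc[tag, "ref_name"].split(".iso")[0] for tag in mirna_norm.index
    }
    profiles = diffexpr.paralog_totals(mirna_norm, membership, design)
    _write(profiles, ddir / "paralog_profiles.tsv")
    results.update(de=de, centered=centered, paralog_profiles=profiles)

    # --- stage 4: target scanning ------------------------------------------
    utrs, utr_errors = targets.infer_three_prime_utrs(gff_path)
    errors.extend(utr_errors)
    seed_objs = [
        targets.Seed(f"seed{len(s)}mer", s) for s in seed_seqs
    ]
    all_sites: list[targets.SeedSite] = []
    utr_rows = []
    for utr in utrs:
        seq = targets.extract_utr_sequence(utr, genome)
        utr_rows.append(
            {
                "gene": utr.gene_id,
                "transcript": utr.transcript_id,
                "utr_length": utr.length,
            }
        )
        for seed in seed_objs:
            all_sites.extend(targets.scan_seed_sites(seq, seed, utr.transcript_id))
    utr_df = pd.DataFrame(utr_rows, columns=["gene", "transcript", "utr_length"])
    per_tx, gene_counts = targets.count_sites(all_sites, utrs)
    tdir = outdir / "targets"
    _write(utr_df, tdir / "utr_lengths.tsv", index=False)
    _write(per_tx, tdir / "transcript_sites.tsv", index=False)
    _write(gene_counts, tdir / "gene_sites.tsv", index=False)
    results.update(utrs=utrs, utr_df=utr_df, transcript_sites=per_tx, gene_sites=gene_counts)

    six_col = [
        s.name for s in seed_objs if s.k == 6
    ]
    if len(gene_counts) and six_col and six_col[0] in gene_counts.columns:
        target_genes = set(
            gene_counts.loc[gene_counts[six_col[0]] >= 1, "gene"]
        )
    elif len(gene_counts):
        target_genes = set(gene_counts["gene"])
    else:
        target_genes = set()
    results["target_genes"] = target_genes

    if truth is not None:
        profile = targets.stage_target_profile(
            target_genes, truth.expressed_by_stage, truth.de_genes_by_stage
        )
        _write(profile, tdir / "stage_target_profile.tsv", index=False)
        results["stage_target_profile"] = profile

    lengths_by_gene = utr_df.groupby("gene")["utr_length"].max()
    counts_by_gene = pd.Series(0, index=lengths_by_gene.index, dtype=int)
    if len(gene_counts) and six_col and six_col[0] in gene_counts.columns:
        counts_by_gene.update(gene_counts.set_index("gene")[six_col[0]])
    nonzero_utr = lengths_by_gene > 0
    try:
        f_stat, anova_p = targets.utr_length_anova(
            lengths_by_gene[nonzero_utr], counts_by_gene[nonzero_utr]
        )
        results["utr_anova"] = {"F": f_stat, "p": anova_p}
        (tdir / "utr_length_anova.json").write_text(
            json.dumps({"F": f_stat, "p": anova_p}, indent=2) + "\n"
        )
    except ValueError as exc:
        errors.append({"stage": "utr_anova", "error": str(exc)})

    # --- stage 5: enrichment ------------------------------------------------
    if terms_path is not None and Path(terms_path).exists():
        term_map = enrichment.load_term_map(terms_path)
        universe = set(lengths_by_gene[nonzero_utr].index)
        query = target_genes & universe
        enrich = enrichment.hypergeom_enrich(query, term_map, universe, cfg.alpha)
        _write(enrich, outdir / "enrich" / "enrichment.tsv", index=False)
        results["enrichment"] = enrich

    # --- manifest -----------------------------------------------------------
    if errors:
        _write(pd.DataFrame(errors), outdir / "errors.tsv", index=False)
    results["errors"] = errors
    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "parameters": {
            "seed": cfg.seed,
            "adapter": adapter,
            "min_overlap": cfg.min_overlap,
            "min_cpm": cfg.min_cpm,
            "max_gap": cfg.max_gap,
            "flank": cfg.flank,
            "seeds": seed_seqs,
            "alpha": cfg.alpha,
            "simulate": cfg.simulate,
        },
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
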