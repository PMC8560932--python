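"""End-to-end orchestration: simulate/read -> call -> filter -> haplotype ->
clades -> names -> recombinants -> effects -> k-mer colocalization -> geography.

Every stage logs its input/output counts so the site funnel (raw -> called ->
filtered -> haplotypes) is auditable, writes its table under the output
directory, and contributes to one summary JSON.  Any stage failure aborts
with the stage name; outputs written so far are retained and listed in a
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo as geo_mod
from . import haplotyping as hap
from . import kmer_lineage as kmer
from . import phylo
from . import protein_effects as pe
from . import synthetic_data as synth
from .variant_core import (
    CallThresholds,
    GenotypeMatrix,
    LocusDefinition,
    apply_site_filters,
    call_genotypes,
    find_duplicates,
    read_vcf_region,
)

log = logging.getLogger("gluhap")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative configuration for a full run; CLI flags override fields."""

    simulate: bool = True
    panel: synth.PanelConfig = field(default_factory=synth.PanelConfig)
    # file-mode inputs
    vcf: str | None = None
    metadata: str | None = None
    genomewide: str | None = None
    gene_models: str | None = None  # JSON written by a simulate run, or GFF3+FASTA
    genome_fasta: str | None = None
    kmer_bins: str | None = None
    kmer_gene: str | None = None  # "chrom:start-end"
    locus: LocusDefinition | None = None
    # stage settings (numeric defaults follow the emulated study)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    maf_min: float = 0.01
    miss_max: float = 0.90
    k_major: int = 3
    k_sub: int = 15
    linkage: str = "complete"
    newick: str | None = None
    clade_table: str | None = None
    minority_fraction: float = 0.5
    identity_min: float = 0.998
    margin_fraction: float = kmer.DEFAULT_MARGIN_FRACTION
    bin_size: int = kmer.DEFAULT_BIN_SIZE
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "panel" in kwargs and kwargs["panel"] is not None:
            panel = {
                k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["panel"].items()
            }
            kwargs["panel"] = synth.PanelConfig(**panel)
        if "thresholds" in kwargs and kwargs["thresholds"] is not None:
            kwargs["thresholds"] = CallThresholds(**kwargs["thresholds"])
        if "locus" in kwargs and kwargs["locus"] is not None:
            kwargs["locus"] = LocusDefinition.from_dict(kwargs["locus"])
        return cls(**kwargs)


def _load_gene_models(config: RunConfig) -> dict[str, pe.GeneModel] | None:
    if config.gene_models is None:
        return None
    p = Path(config.gene_models)
    if p.suffix == ".json":
        with open(p) as fh:
            return {k: pe.GeneModel.from_dict(v) for k, v in json.load(fh).items()}
    if config.genome_fasta is None:
        raise PipelineError("GFF3 gene models need genome_fasta for the CDS sequences")
    return pe.gene_models_from_gff(p, config.genome_fasta)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, write module outputs plus ``summary.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary: dict = {"seed": config.seed}
    current_stage = "setup"

    def _emit(path: Path):
        written.append(str(path.relative_to(out)))

    def _manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump({"written": written, "last_stage": current_stage}, fh, indent=2)

    try:
        # ---------------------------------------------------------- inputs
        truth = None
        if config.simulate:
            current_stage = "simulate"
            panel = dataclasses.replace(config.panel, seed=config.seed)
            vcf_text, metadata, truth = synth.simulate_panel(panel)
            vcf_path = out / "panel.vcf"
            vcf_path.write_text(vcf_text)
            _emit(vcf_path)
            metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
            _emit(out / "metadata.tsv")
            truth.write(out)
            for f in ("truth_samples.tsv", "truth_sites.tsv", "truth_genomewide.tsv"):
                _emit(out / f)
            with open(out / "gene_models.json", "w") as fh:
                json.dump(
                    {g.gene_id: g.to_dict() for g in (truth.gene_x, truth.gene_y)}, fh
                )
            _emit(out / "gene_models.json")
            with open(out / "locus.json", "w") as fh:
                json.dump(truth.locus.to_dict(), fh)
            _emit(out / "locus.json")
            locus = truth.locus
            gene_models = {"Glu-D1x": truth.gene_x, "Glu-D1y": truth.gene_y}
            genomewide = truth.genomewide
            log.info("simulate: %d samples, %d sites", metadata.shape[0], truth.sites.shape[0])
        else:
            current_stage = "inputs"
            for name in ("vcf", "metadata"):
                val = getattr(config, name)
                if val is None or not Path(val).exists():
                    raise PipelineError(f"missing input {name}: {val}")
            if config.locus is None:
                raise PipelineError("file mode requires a locus definition")
            locus = config.locus
            vcf_path = Path(config.vcf)
            metadata = pd.read_csv(config.metadata, sep="\t")
            gene_models = _load_gene_models(config)
            genomewide = (
                pd.read_csv(config.genomewide, sep="\t") if config.genomewide else None
            )

        # ---------------------------------------------------------- extract + call
        current_stage = "extract"
        records = read_vcf_region(vcf_path, locus)
        summary["n_sites_raw"] = len(records.sites)
        summary["n_samples"] = len(records.samples)
        log.info("extract: %d records in locus windows", len(records.sites))

        current_stage = "call"
        m = call_genotypes(records, config.thresholds)
        m.to_tsv(out / "genotype_matrix_raw.tsv")
        _emit(out / "genotype_matrix_raw.tsv")

        current_stage = "filter"
        mf = apply_site_filters(m, config.maf_min, config.miss_max)
        mf.to_tsv(out / "genotype_matrix_filtered.tsv")
        _emit(out / "genotype_matrix_filtered.tsv")
        mf.sites_to_bed(out / "sites_filtered.bed")
        _emit(out / "sites_filtered.bed")
        summary["n_sites_filtered"] = mf.n_sites
        log.info("filter: %d -> %d sites", m.n_sites, mf.n_sites)

        # ---------------------------------------------------------- haplotypes
        current_stage = "haplotype"
        px = hap.group_haplotypes(mf, ("coding-x",))
        py = hap.group_haplotypes(mf, ("coding-y",))
        combined = hap.combine_subunits(px, py)
        px_full = hap.group_haplotypes(mf, ("coding-x", "flank-x"))
        py_full = hap.group_haplotypes(mf, ("coding-y", "flank-y"))
        combined_full = hap.combine_subunits(px_full, py_full)
        added = hap.flank_consistency(combined, combined_full)
        summary.update(
            n_x_haplotypes=px.n_haplotypes,
            n_y_haplotypes=py.n_haplotypes,
            n_combined_haplotypes=combined.n_haplotypes,
            n_added_by_flanks=added,
            n_ambiguous_combined=len(combined.ambiguous_samples()),
        )
        log.info(
            "haplotype: x=%d y=%d combined=%d (+%d with flanks)",
            px.n_haplotypes, py.n_haplotypes, combined.n_haplotypes, added,
        )

        # ---------------------------------------------------------- clades
        current_stage = "clades"
        A = phylo.additive_relationship(mf)
        D = phylo.distance_from_A(A)
        D.write(str(out / "genetic_distances.tsv"))
        _emit(out / "genetic_distances.tsv")
        if config.clade_table:
            sample_clades = phylo.CladePartition.from_tsv(config.clade_table)
        elif config.newick:
            tree = phylo.read_newick(Path(config.newick).read_text())
            td = tree.tip_tip_distances()
            dendro = phylo.hierarchical_cluster(td, config.linkage)
            k_sub = min(config.k_sub, len(dendro.labels))
            sample_clades = phylo.cut_clades(dendro, min(config.k_major, k_sub), k_sub)
        else:
            dendro = phylo.hierarchical_cluster(D, config.linkage)
            k_sub = min(config.k_sub, len(dendro.labels))
            sample_clades = phylo.cut_clades(dendro, min(config.k_major, k_sub), k_sub)
        sample_clades.to_tsv(out / "clades_samples.tsv")
        _emit(out / "clades_samples.tsv")
        x_clades = phylo.clades_for_haplotypes(px, sample_clades)
        y_clades = phylo.clades_for_haplotypes(py, sample_clades)
        x_clades.to_tsv(out / "clades_x.tsv")
        y_clades.to_tsv(out / "clades_y.tsv")
        _emit(out / "clades_x.tsv")
        _emit(out / "clades_y.tsv")

        current_stage = "names"
        names_x = hap.assign_names(px, x_clades, "x")
        names_y = hap.assign_names(py, y_clades, "y")
        names_c = hap.combined_names(combined, names_x, names_y)
        px.to_tsv(out / "haplotypes_x.tsv", names_x.names)
        py.to_tsv(out / "haplotypes_y.tsv", names_y.names)
        combined.to_tsv(out / "haplotypes_combined.tsv", names_c.names)
        for f in ("haplotypes_x.tsv", "haplotypes_y.tsv", "haplotypes_combined.tsv"):
            _emit(out / f)

        current_stage = "recombinants"
        recombinants = hap.detect_recombinants(
            combined, x_clades, y_clades, config.minority_fraction
        )
        hap.recombinants_to_tsv(recombinants, out / "recombinants.tsv")
        _emit(out / "recombinants.tsv")
        summary["recombinants"] = [r.sample for r in recombinants]
        summary["n_recombinants"] = len(recombinants)
        log.info("recombinants: %d flagged", len(recombinants))

        current_stage = "duplicates"
        if genomewide is not None:
            groups = find_duplicates(genomewide, identity_min=config.identity_min)
            dup_groups = [g for g in groups if len(g) > 1]
            summary["duplicate_groups"] = dup_groups
            log.info("duplicates: %d group(s)", len(dup_groups))
        else:
            summary["duplicate_groups"] = None

        # ---------------------------------------------------------- effects
        current_stage = "effects"
        if gene_models:
            effects = []
            for region, gene in (("coding-x", "Glu-D1x"), ("coding-y", "Glu-D1y")):
                if gene not in gene_models:
                    continue
                sub = mf.restrict_regions((region,))
                effects.extend(pe.classify_effects(gene_models[gene], sub.sites))
            pe.effects_to_tsv(effects, out / "effects.tsv")
            _emit(out / "effects.tsv")
            summary["effects"] = pe.effect_tally(effects)
            summary["cysteine"] = pe.cysteine_audit(effects)
            # per-haplotype protein sequences for external phylogenetics
            for region, gene, part, names in (
                ("coding-x", "Glu-D1x", px, names_x),
                ("coding-y", "Glu-D1y", py, names_y),
            ):
                if gene not in gene_models:
                    continue
                sub = mf.restrict_regions((region,))
                fasta = out / f"proteins_{region[-1]}.fasta"
                with open(fasta, "w") as fh:
                    for hap_id, vec in part.haplotypes.items():
                        cds = pe.build_haplotype_cds(gene_models[gene], vec, sub.sites)
                        fh.write(f">{names[hap_id]}\n{pe.translate_cds(cds)}\n")
                _emit(fasta)
        else:
            summary["effects"] = None
            summary["cysteine"] = None

        # ---------------------------------------------------------- k-mer bins
        current_stage = "kmer"
        margin = kmer.margin_for(config.bin_size, config.margin_fraction)
        if config.simulate:
            bs = config.bin_size
            (gx_s, _), (_, gy_e) = locus.gene_x, locus.gene_y
            locus_bins = range((gx_s - 1) // bs, (gy_e - 1) // bs + 1)
            planted = {b: "L3" for b in locus_bins}
            planted.update({100: "L1", 101: "L1", 200: "L2", 201: "L2"})
            n_bins = (gy_e - 1) // bs + 5
            bins = synth.simulate_kmer_bins(
                n_bins, bs, planted, seed=config.seed, chrom=locus.chrom
            )
            gene_interval = (locus.chrom, gx_s, gy_e)
        elif config.kmer_bins:
            bins = kmer.read_bin_counts(config.kmer_bins)
            if not config.kmer_gene:
                raise PipelineError("kmer_bins given without kmer_gene (chrom:start-end)")
            chrom, span = config.kmer_gene.split(":")
            s, e = (int(v) for v in span.split("-"))
            gene_interval = (chrom, s, e)
        else:
            bins = None
        if bins is not None:
            classified = kmer.classify_bins(bins, margin)
            kmer.classification_to_bed(classified, out / "kmer_bins.bed", config.bin_size)
            _emit(out / "kmer_bins.bed")
            call = kmer.colocalize_gene(classified, *gene_interval, bin_size=config.bin_size)
            summary["kmer"] = {
                "gene_call": call.consensus,
                "margin": margin,
                "n_assigned_bins": int((classified["assigned"] != kmer.UNASSIGNED).sum()),
            }
            log.info("kmer: gene colocalizes with %s", call.consensus)
        else:
            summary["kmer"] = None

        # ---------------------------------------------------------- geography
        current_stage = "geo"
        if metadata is not None and {"lat", "lon"} <= set(metadata.columns):
            dgeo = geo_mod.geographic_distance_matrix(metadata)
            dgeo = dgeo.filter(D.ids)
            res = geo_mod.mantel(D, dgeo, n_perm=config.n_perm, seed=config.seed)
            res.to_json(out / "geo_mantel.json")
            _emit(out / "geo_mantel.json")
            summary["mantel"] = {"r": res.r, "p": res.p, "n_perm": res.n_perm}
            log.info("geo: Mantel r=%.3f p=%.4g", res.r, res.p)
        else:
            summary["mantel"] = None

        current_stage = "summary"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _emit(out / "summary.json")
        _manifest()
        return summary
    except PipelineError:
        _manifest()
        raise
    except Exception as exc:
        _manifest()
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc
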