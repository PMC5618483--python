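"""End-to-end orchestration of the analysis stages.

Stages run in dependency order on a shared state: generate -> identify /
structure / properties / scan -> phylo -> express -> network.  Each stage
writes plain-text outputs (TSV / FASTA / Newick / SIF) into the output
directory and contributes record counts to a JSON run report.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
from Bio.Seq import Seq

from . import simulate
from .align import ScoringScheme
from .expression import ddct, foldchange_profiles, fpkm, induced_set, zscore_by_gene
from .identify import identify_family, load_signatures
from .network import build_network, correlation_matrices, export_network, network_stats
from .phylo import (assign_groups, bootstrap_supports, mean_pairwise_identity,
                    nj_tree, pdistance_matrix, progressive_msa)
from .promoter import extract_promoter, hits_to_frame, load_catalog, scan, summarize
from .properties import property_table
from .simulate import GeneratorConfig, gen_expression, gen_genome, gen_qpcr
from .structure import structure_summary

log = logging.getLogger(__name__)

STAGES = ("generate", "identify", "structure", "properties", "scan",
          "phylo", "express", "network")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 42
    outdir: str = "snrkfam_run"
    stages: tuple[str, ...] = STAGES
    e_threshold: float = 1e-5
    fc_min: float = 2.0
    alpha: float = 0.05
    pcc_positive: float = 0.5
    pcc_strong: float = 0.8
    pcc_negative: float = -0.5
    bootstrap_B: int = 1000
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        self.generator.seed = self.seed

    def validate(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("E-value threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_min <= 0:
            raise ValueError("fold-change cutoff must be positive")
        if not -1 <= self.pcc_negative <= self.pcc_positive <= self.pcc_strong <= 1:
            raise ValueError("PCC thresholds must be ordered")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _require(state: dict, key: str, stage: str, needed_by: str) -> Any:
    if key not in state:
        raise DependencyError(
            f"stage '{needed_by}' requires outputs of stage '{stage}'")
    return state[key]


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}
    report: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "e_threshold": config.e_threshold, "fc_min": config.fc_min,
            "alpha": config.alpha, "pcc": [config.pcc_positive,
                                           config.pcc_strong,
                                           config.pcc_negative],
            "bootstrap_B": config.bootstrap_B,
            "generator": asdict(config.generator),
        },
        "stages": {},
    }
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        counts = _STAGE_FUNCS[stage](config, state, outdir)
        report["stages"][stage] = {
            "records": counts, "seconds": round(time.perf_counter() - t0, 2)}
        log.info("stage %s done (%.1fs)", stage, time.perf_counter() - t0)
    report["files"] = {
        p.name: hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir()) if p.is_file()
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_generate(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = gen_genome(config.generator)
    state["syn"] = syn
    paths = simulate.write_fixture_set(syn, config.generator, outdir)
    state["paths"] = paths
    return {"family_genes": len(syn.truth.planted_genes),
            "decoys": len(syn.truth.decoys),
            "files": len(paths)}


def _candidates_from_models(syn: simulate.SyntheticGenome) -> dict[str, str]:
    out = {}
    for model in syn.models:
        cds = model.cds_sequence(syn.genome)
        out[model.gene_id] = str(Seq(cds).translate()).rstrip("*")
    return out


def _stage_identify(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "identify")
    candidates = _candidates_from_models(syn)
    refs = syn.references
    result = identify_family(
        refs.queries, candidates, refs.proteomes, refs.family_labels,
        ScoringScheme(), config.e_threshold, load_signatures())
    state["family"] = result.family
    state["candidates"] = candidates
    result.screen.hits.to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
    fam = pd.DataFrame({
        "gene": result.family,
        "domains": [result.domain_annotations[g].table_style()
                    for g in result.family],
    })
    fam.to_csv(outdir / "identified_family.tsv", sep="\t", index=False)
    return result.stage_counts


def _stage_structure(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "structure")
    family = state.get("family", syn.truth.family_ids)
    models = [m for m in syn.models if m.gene_id in set(family)]
    summary = structure_summary(models)
    summary.to_csv(outdir / "structure_summary.tsv", sep="\t", index=False)
    return {"models": len(models)}


def _stage_properties(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "properties")
    family = state.get("family", syn.truth.family_ids)
    peptides = {g: syn.proteins[g] for g in family}
    table = property_table(peptides)
    table.to_csv(outdir / "protein_properties.tsv", sep="\t", index=False)
    return {"proteins": len(table)}


def _stage_scan(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "scan")
    catalog = load_catalog()
    family = state.get("family", syn.truth.family_ids)
    models = {m.gene_id: m for m in syn.models}
    hits = []
    for gene in family:
        window = extract_promoter(syn.genome, models[gene],
                                  config.generator.promoter_length)
        hits.extend(scan(window, catalog, gene))
    hits_to_frame(hits).to_csv(outdir / "promoter_hits.tsv", sep="\t",
                               index=False)
    groups = syn.truth.group_of()
    summary = summarize(hits, {g: groups.get(g, 0) for g in family})
    summary.to_csv(outdir / "promoter_summary.tsv", sep="\t", index=False)
    state["promoter_summary"] = summary
    return {"hits": len(hits), "abre_genes": int(summary.has_ABRE.sum())}


def _stage_phylo(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "phylo")
    family = state.get("family", syn.truth.family_ids)
    peptides = {g: syn.proteins[g] for g in family}
    peptides.update(syn.references.queries)
    msa = progressive_msa(peptides)
    (outdir / "alignment.fasta").write_text(msa.to_fasta())
    tree, _ = bootstrap_supports(msa, B=config.bootstrap_B, seed=config.seed)
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    assignment = assign_groups(tree, syn.references.groups)
    table = pd.DataFrame([
        {"gene": g, "group": grp,
         "clade_consistent": not assignment.inconsistent.get(g, False)}
        for g, grp in sorted(assignment.groups.items())
    ])
    table.to_csv(outdir / "phylo_groups.tsv", sep="\t", index=False)
    state["groups"] = assignment
    state["mean_identity"] = mean_pairwise_identity(
        progressive_msa({g: syn.proteins[g] for g in family}))
    return {"taxa": len(msa.ids),
            "group_sizes": {str(k): v
                            for k, v in sorted(assignment.sizes().items())},
            "mean_family_identity_pct": round(100 * state["mean_identity"], 1)}


def _stage_express(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    syn = _require(state, "syn", "generate", "express")
    counts, lengths, totals = gen_expression(config.generator, syn.truth)
    fk = fpkm(counts, lengths, totals)
    fk.rename_axis("gene").to_csv(outdir / "fpkm.tsv", sep="\t")
    z, constant = zscore_by_gene(fk)
    z.rename_axis("gene").to_csv(outdir / "zscores.tsv", sep="\t")
    ct = gen_qpcr(config.generator, syn.truth)
    fc = ddct(ct, simulate.REFERENCE_GENE)
    fc.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    induced = induced_set(fc, config.fc_min, config.alpha)
    state["fpkm"] = fk
    state["foldchanges"] = fc
    return {"genes": len(fk), "constant_genes": len(constant),
            "induced": {k: sorted(v) for k, v in sorted(induced.items())}}


def _stage_network(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    fk = _require(state, "fpkm", "express", "network")
    fc = _require(state, "foldchanges", "express", "network")
    out: dict[str, Any] = {}
    r, p = correlation_matrices(fk)
    edges = build_network(r, p, config.pcc_positive, config.pcc_strong,
                          config.pcc_negative, config.alpha,
                          n_samples=fk.shape[1])
    export_network(edges, outdir, "network_tissue",
                   formats=("sif", "attributes", "graphml", "json"))
    out["tissue"] = network_stats(edges)
    for trt in sorted(fc.treatment.unique()):
        profiles = foldchange_profiles(fc, trt)
        if profiles.shape[1] < 3:
            continue
        r, p = correlation_matrices(profiles)
        edges = build_network(r, p, config.pcc_positive, config.pcc_strong,
                              config.pcc_negative, config.alpha,
                              n_samples=profiles.shape[1])
        tag = trt.replace("/", "_").replace(" ", "_")
        export_network(edges, outdir, f"network_{tag}",
                       formats=("sif", "attributes", "json"))
        out[trt] = network_stats(edges)
    return out


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "identify": _stage_identify,
    "structure": _stage_structure,
    "properties": _stage_properties,
    "scan": _stage_scan,
    "phylo": _stage_phylo,
    "express": _stage_express,
    "network": _stage_network,
}
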