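"""End-to-end orchestration of the screening protocol from a single config.

Stages, in protocol order: per-ontology screening with ortholog fallback →
enrichment gate → cross-stress Venn partition → differential-expression
integration (intersection of screened candidates with up-regulated genes;
union behind a flag) → QTL co-localization.  Stages whose inputs are not
configured are skipped.  A JSON manifest records the config hash, seed and
per-stage record counts; rerunning with identical inputs reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import associations as assoc_mod
from . import enrichment as enrich_mod
from . import expression as expr_mod
from . import qtl as qtl_mod
from . import screening as screen_mod
from .comparative import venn_partition
from .ontology import OntologyRegistry, TermSet, accession_prefix, build_term_set

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated paths, term-set seeds and thresholds for one run."""

    ontologies: list[Path] = field(default_factory=list)
    associations: Path | None = None
    orthologs: Path | None = None
    expression: Path | None = None
    sample_meta: Path | None = None
    qtls: Path | None = None
    gene_loci: Path | None = None
    term_seeds: dict = field(default_factory=dict)  # key -> {label: [accessions]}
    target_species: str = "sorghum"
    screen_alpha: float = 0.01
    attribute_alpha: float = 0.05
    de_alpha: float = 0.01
    fold_threshold: float = 2.0
    evalue_max: float = 1e-10
    de_contrast: tuple[str, str, str] = ("treatment", "stress", "control")
    de_integration: str = "intersection"  # or "union"
    output_dir: Path = Path("stressprio_out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        kwargs = {}
        for key in ("associations", "orthologs", "expression", "sample_meta",
                    "qtls", "gene_loci"):
            if raw.get(key):
                kwargs[key] = base / raw[key]
        if raw.get("ontologies"):
            kwargs["ontologies"] = [base / p for p in raw["ontologies"]]
        for key in ("target_species", "screen_alpha", "attribute_alpha",
                    "de_alpha", "fold_threshold", "evalue_max", "seed",
                    "de_integration", "term_seeds"):
            if key in raw:
                kwargs[key] = raw[key]
        if raw.get("de_contrast"):
            kwargs["de_contrast"] = tuple(raw["de_contrast"])
        if raw.get("output_dir"):
            kwargs["output_dir"] = base / raw["output_dir"]
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for alpha in (self.screen_alpha, self.attribute_alpha, self.de_alpha):
            if not 0 < alpha <= 1:
                raise ConfigError(f"threshold {alpha} outside (0, 1]")
        if self.fold_threshold < 1:
            raise ConfigError("fold threshold must be >= 1")
        for p in [*self.ontologies, self.associations, self.orthologs,
                  self.expression, self.sample_meta, self.qtls, self.gene_loci]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured file does not exist: {p}")


def default_term_seeds() -> dict:
    """The shipped per-ontology stress/attribute seed accessions."""
    text = resources.files("stressprio").joinpath("data/term_sets.yaml").read_text()
    return yaml.safe_load(text)


def build_term_sets(
    registry: OntologyRegistry, term_seeds: dict, closure: bool = True
) -> dict[str, TermSet]:
    """One merged TermSet per ontology key from per-label seed accessions.

    Seeds are routed to the graph matching their accession prefix; seeds
    whose ontology is not loaded or whose accession is absent from the
    graph are skipped with a warning (snapshots are often partial).
    """
    out: dict[str, TermSet] = {}
    for key, labels in term_seeds.items():
        members: set[str] = set()
        seeds: list[str] = []
        for label, accessions in labels.items():
            for acc in accessions:
                prefix = accession_prefix(acc)
                graph = registry.get(prefix)
                if graph is None or acc not in graph:
                    logger.warning("seed %s (%s/%s) not in loaded ontologies; "
                                   "skipped", acc, key, label)
                    continue
                ts = build_term_set(graph, [acc], label=label, closure=closure)
                members |= ts.member_ids
                seeds.append(acc)
        if seeds:
            out[key] = TermSet(ontology_key=key, seed_ids=seeds,
                               member_ids=members, label=key)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    candidates: list[str] | None = None
    try:
        if config.ontologies and config.associations:
            candidates = _stage_screen_enrich(config, outdir, manifest)
        if config.expression and config.sample_meta:
            candidates = _stage_de(config, outdir, manifest, candidates)
        if config.qtls and config.gene_loci:
            _stage_colocalize(config, outdir, manifest)
    except Exception as exc:
        manifest["error"] = {"stage": manifest.get("current_stage", "unknown"),
                             "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest.pop("current_stage", None)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_screen_enrich(config, outdir, manifest) -> list[str]:
    manifest["current_stage"] = "screen"
    registry = OntologyRegistry.from_obo(
        *[Path(p).read_text() for p in config.ontologies]
    )
    assoc = assoc_mod.read_associations(str(config.associations))
    assoc = assoc_mod.propagate(assoc, registry)
    seeds = config.term_seeds or default_term_seeds()
    term_sets = build_term_sets(registry, seeds)
    term_sets = {k: v for k, v in term_sets.items() if k in registry}
    if not term_sets:
        raise ConfigError("no configured term set matches a loaded ontology")
    orthologs = None
    if config.orthologs:
        orthologs = assoc_mod.OrthologMap.read(str(config.orthologs))
    if orthologs is None or len(orthologs) == 0:
        # placeholder pair so the transfer stage runs as a no-op
        orthologs = assoc_mod.OrthologMap.from_pairs(
            [("sorghum", "_none_", "rice", "_none_")]
        )
    per_key, matrix, report = screen_mod.collect_per_ontology(
        assoc, orthologs, term_sets, config.target_species
    )
    matrix.to_tsv(outdir / "support_matrix.tsv")
    survivors = screen_mod.all_ontology_filter(matrix, set(term_sets))
    report.all_ontology_pass = len(survivors)
    report.to_frame().to_csv(outdir / "screen_report.tsv", sep="\t", index=False)
    manifest["stages"]["screen"] = {
        "merged_unique": report.merged_unique,
        "all_ontology_pass": len(survivors),
    }
    # enrichment gate on the merged candidate list
    manifest["current_stage"] = "enrich"
    study = survivors if survivors else sorted(matrix.genes)
    species_bg = assoc[assoc.species == config.target_species]
    table = enrich_mod.enrich(
        study, species_bg, alpha=config.screen_alpha, correct=True
    )
    table.to_tsv(outdir / "enrichment.tsv")
    sig_terms = set(table.significant.term_id)
    gated = sorted(
        set(species_bg[species_bg.term_id.isin(sig_terms)].gene_id) & set(study)
    )
    manifest["stages"]["enrich"] = {
        "terms_tested": len(table.rows),
        "terms_significant": len(sig_terms),
        "genes_passing_gate": len(gated),
    }
    pd.Series(gated).to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                            header=["gene_id"])
    return gated


def _stage_de(config, outdir, manifest, candidates) -> list[str]:
    manifest["current_stage"] = "de"
    matrix = expr_mod.ExpressionMatrix.read(
        str(config.expression), str(config.sample_meta)
    )
    results = expr_mod.run_de(
        matrix, config.de_contrast, alpha=config.de_alpha,
        fold_threshold=config.fold_threshold,
    )
    results.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    up = sorted(results[results["class"] == "up"].gene_id)
    counts = expr_mod.volcano_classify(
        results, config.de_alpha, config.fold_threshold
    )
    manifest["stages"]["de"] = dict(counts)
    if candidates is not None:
        if config.de_integration == "union":
            integrated = sorted(set(candidates) | set(up))
        else:
            integrated = sorted(set(candidates) & set(up))
        manifest["stages"]["de"]["integrated"] = len(integrated)
        pd.Series(integrated).to_csv(
            outdir / "integrated_candidates.tsv", sep="\t", index=False,
            header=["gene_id"],
        )
        return integrated
    return up


def _stage_colocalize(config, outdir, manifest) -> None:
    manifest["current_stage"] = "colocalize"
    genes = qtl_mod.read_gene_loci(str(config.gene_loci))
    qtls = qtl_mod.read_qtl_regions(str(config.qtls))
    result = qtl_mod.colocalize(genes, qtls)
    result.to_tsv(outdir / "colocalization.tsv")
    manifest["stages"]["colocalize"] = {
        "assignments": result.grand_total,
        "unique_genes": len(result.unique_genes),
        "per_qtl": result.per_qtl_counts,
    }
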