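"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of (spec, seed): random ontology DAGs
that parse through the OBO reader, association/ortholog snapshots with
exactly planted term enrichments and a configurable transitive-only
fraction, two-group expression matrices with planted up-regulated genes
(Gaussian noise on the log2 scale, exponentiated to a linear RPKM-like
scale), and QTL/gene-locus scenarios with known containment ground truth.

The default DE condition matches the emulated two-group microarray/RNA-seq
designs: n = 5 samples per group, planted log2 fold change 3 (an 8-fold
change, comfortably past the 2-fold gate), unit-variance log-scale noise.
One global seed fans out to fixed per-generator substreams so adding a
generator never perturbs existing fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

# fixed substream ids: appending new generators must not disturb old ones
_STREAMS = {"ontology": 1, "associations": 2, "expression": 3, "qtl": 4,
            "alignment": 5}


class SpecError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class SimulationSpec:
    """Parameters for one synthetic scenario; defaults are the study conditions."""

    seed: int = 0
    # ontology
    n_terms: int = 50
    max_parents: int = 2
    ontology_key: str = "GO"
    # associations / planted enrichment
    n_genes: int = 1000
    n_study: int = 50
    planted_study_coverage: int = 40
    planted_background_coverage: int = 100
    annotation_density: float = 0.05
    transitive_fraction: float = 0.0
    species: tuple[str, ...] = ("sorghum", "maize", "rice", "arabidopsis")
    # differential expression
    de_n_genes: int = 1000
    de_n_planted: int = 50
    de_log2fc: float = 3.0
    de_noise_sd: float = 1.0
    de_n_per_group: int = 5
    de_baseline_log2: float = 5.0
    # QTL scenario
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    n_qtls: int = 5
    genes_inside_per_qtl: int = 4
    genes_outside: int = 20

    def __post_init__(self) -> None:
        for frac in (self.annotation_density, self.transitive_fraction):
            if not 0 <= frac <= 1:
                raise SpecError("fractions must lie in [0, 1]")
        if self.planted_study_coverage > self.n_study:
            raise SpecError("planted study coverage exceeds study-set size")
        if self.planted_background_coverage > self.n_genes:
            raise SpecError("planted background coverage exceeds universe size")
        if self.planted_study_coverage > self.planted_background_coverage:
            raise SpecError("study coverage exceeds background coverage")
        if self.de_n_per_group < 2:
            raise SpecError("need >=2 samples per group")
        if self.de_n_planted > self.de_n_genes:
            raise SpecError("more planted genes than genes")


def gen_ontology(spec: SimulationSpec) -> str:
    """Random DAG-shaped OBO text: term i's parents are drawn from terms < i."""
    rng = _rng(spec.seed, "ontology")
    key = spec.ontology_key
    lines = ["format-version: 1.2", ""]
    for i in range(spec.n_terms):
        term_id = f"{key}:{i + 1:07d}"
        lines += [f"[Term]", f"id: {term_id}", f"name: synthetic term {i + 1}"]
        if i > 0:
            n_par = int(rng.integers(1, min(spec.max_parents, i) + 1))
            parents = rng.choice(i, size=n_par, replace=False)
            for p in sorted(parents):
                lines.append(f"is_a: {key}:{int(p) + 1:07d}")
        lines.append("")
    return "\n".join(lines)


def term_ids(spec: SimulationSpec) -> list[str]:
    return [f"{spec.ontology_key}:{i + 1:07d}" for i in range(spec.n_terms)]


def gene_ids(n: int, prefix: str = "g") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def gen_associations(spec: SimulationSpec) -> dict[str, object]:
    """Association + ortholog TSV text with an exactly planted enrichment.

    The planted term annotates exactly ``planted_background_coverage``
    universe genes, of which exactly ``planted_study_coverage`` are study
    genes (counts, not probabilities).  A ``transitive_fraction`` of
    sorghum annotations is removed from sorghum and placed on a rice
    ortholog instead, reachable only through the ortholog map.
    """
    rng = _rng(spec.seed, "associations")
    genes = gene_ids(spec.n_genes, "Sb")
    study = genes[: spec.n_study]
    terms = term_ids(spec)
    planted = terms[-1]
    other_terms = terms[:-1]
    rows: list[tuple] = []
    # planted term: exact coverages
    in_study = list(rng.choice(study, size=spec.planted_study_coverage,
                               replace=False))
    outside_pool = genes[spec.n_study:]
    n_outside = spec.planted_background_coverage - spec.planted_study_coverage
    outside = list(rng.choice(outside_pool, size=n_outside, replace=False))
    for g in in_study + outside:
        rows.append((g, "sorghum", planted, spec.ontology_key))
    # background noise annotations
    if other_terms and spec.annotation_density > 0:
        for g in genes:
            n_ann = rng.binomial(len(other_terms), spec.annotation_density)
            if n_ann == 0:
                n_ann = 1  # keep every gene in the background universe
            for t in rng.choice(other_terms, size=n_ann, replace=False):
                rows.append((g, "sorghum", t, spec.ontology_key))
    df = pd.DataFrame(rows, columns=["gene_id", "species", "term_id",
                                     "ontology_key"]).drop_duplicates()
    # reroute a fraction of sorghum annotations through rice orthologs
    ortho_rows = []
    if spec.transitive_fraction > 0:
        sorghum_genes = sorted(set(df.gene_id))
        n_trans = int(round(spec.transitive_fraction * len(sorghum_genes)))
        transit = set(
            rng.choice(sorghum_genes, size=n_trans, replace=False)
        )
        moved = df.gene_id.isin(transit)
        rerouted = df[moved].copy()
        rerouted["species"] = "rice"
        rice_names = {g: f"Os_{g}" for g in transit}
        rerouted["gene_id"] = [rice_names[g] for g in rerouted.gene_id]
        df = pd.concat([df[~moved], rerouted], ignore_index=True)
        ortho_rows = [("sorghum", g, "rice", rice_names[g]) for g in sorted(transit)]
    assoc_tsv = df.to_csv(sep="\t", index=False)
    ortho_df = pd.DataFrame(ortho_rows, columns=["species_a", "gene_a",
                                                 "species_b", "gene_b"])
    truth = {
        "planted_term": planted,
        "study_genes": sorted(study),
        "k": spec.planted_study_coverage,
        "K": spec.planted_background_coverage,
        "n": spec.n_study,
        "N": spec.n_genes,
    }
    return {
        "associations_tsv": assoc_tsv,
        "orthologs_tsv": ortho_df.to_csv(sep="\t", index=False),
        "truth": truth,
    }


def gen_expression(spec: SimulationSpec) -> dict[str, object]:
    """Two-group expression matrix with planted up-regulated genes.

    Log2 expression is baseline + noise; planted genes gain ``de_log2fc``
    in the stress group.  Values are exponentiated to the linear scale.
    ``de_log2fc=0`` yields a null matrix for type-I-error checks.
    """
    rng = _rng(spec.seed, "expression")
    n_g, n_s = spec.de_n_genes, spec.de_n_per_group
    genes = gene_ids(n_g, "Sb")
    planted = genes[: spec.de_n_planted]
    control_cols = [f"ctrl_{i + 1}" for i in range(n_s)]
    stress_cols = [f"stress_{i + 1}" for i in range(n_s)]
    log2 = spec.de_baseline_log2 + rng.normal(
        0.0, spec.de_noise_sd, size=(n_g, 2 * n_s)
    )
    log2[: spec.de_n_planted, n_s:] += spec.de_log2fc
    values = pd.DataFrame(
        np.exp2(log2), index=pd.Index(genes, name="gene_id"),
        columns=control_cols + stress_cols,
    )
    meta = pd.DataFrame({
        "sample_id": control_cols + stress_cols,
        "tissue": "leaf",
        "treatment": ["control"] * n_s + ["stress"] * n_s,
        "genotype": "wt",
    }).set_index("sample_id")
    return {
        "values": values,
        "sample_meta": meta,
        "truth": {"planted_up": planted, "log2fc": spec.de_log2fc},
    }


def gen_qtl_scenario(spec: SimulationSpec) -> dict[str, object]:
    """QTL + gene-locus tables with known containment assignments."""
    rng = _rng(spec.seed, "qtl")
    if spec.n_qtls == 0:
        empty_q = pd.DataFrame(columns=["qtl_id", "trait", "chrom",
                                        "start", "end", "ref"])
        empty_g = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        return {"qtls_tsv": empty_q.to_csv(sep="\t", index=False),
                "genes_tsv": empty_g.to_csv(sep="\t", index=False),
                "truth": {}}
    # QTLs are striped across chromosomes into disjoint slots so that the
    # emitted ground truth equals containment output by construction
    per_chrom = -(-spec.n_qtls // spec.n_chromosomes)  # ceil
    slot_len = spec.chromosome_length // per_chrom
    qtl_len = slot_len // 2
    if qtl_len < 10:
        raise SpecError("QTL length infeasible for chromosome length")
    qtl_rows, gene_rows, truth = [], [], {}
    gene_counter = 0
    for qi in range(spec.n_qtls):
        chrom = f"chr{qi % spec.n_chromosomes + 1}"
        slot = qi // spec.n_chromosomes
        start = slot * slot_len + 1 + int(rng.integers(0, slot_len - qtl_len))
        end = start + qtl_len - 1
        qtl_id = f"Q{qi + 1}"
        qtl_rows.append((qtl_id, f"trait_{qi % 3 + 1}", chrom, start, end, "syn"))
        inside = []
        for _ in range(spec.genes_inside_per_qtl):
            g_start = int(rng.integers(start, end - 5))
            g_end = int(rng.integers(g_start, end))
            gid = f"Sg{gene_counter:05d}"
            gene_counter += 1
            gene_rows.append((gid, chrom, g_start, g_end))
            inside.append(gid)
        truth[qtl_id] = sorted(inside)
    # distractor genes placed on a chromosome beyond those carrying QTLs
    far_chrom = f"chr{spec.n_chromosomes + 1}"
    for _ in range(spec.genes_outside):
        g_start = int(rng.integers(1, spec.chromosome_length - 100))
        gid = f"Sg{gene_counter:05d}"
        gene_counter += 1
        gene_rows.append((gid, far_chrom, g_start, g_start + 99))
    qtl_df = pd.DataFrame(qtl_rows, columns=["qtl_id", "trait", "chrom",
                                             "start", "end", "ref"])
    gene_df = pd.DataFrame(gene_rows, columns=["gene_id", "chrom",
                                               "start", "end"])
    return {
        "qtls_tsv": qtl_df.to_csv(sep="\t", index=False),
        "genes_tsv": gene_df.to_csv(sep="\t", index=False),
        "truth": truth,
    }


def gen_alignment(
    n_per_cluster: int = 3,
    n_sites: int = 100,
    within: float = 0.01,
    between: float = 0.45,
    seed: int = 0,
) -> "object":
    """Two well-separated sequence clusters for bootstrap/NJ checks.

    Each cluster descends from its own random ancestral protein; sites
    mutate with probability ``within`` inside a cluster, and the two
    ancestors differ at a ``between`` fraction of sites.
    """
    from .phylo import Alignment

    rng = _rng(seed, "alignment")
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    anc1 = rng.choice(aa, size=n_sites)
    anc2 = anc1.copy()
    flip = rng.random(n_sites) < between
    anc2[flip] = rng.choice(aa, size=int(flip.sum()))
    taxa, rows = [], []
    for ci, anc in enumerate((anc1, anc2)):
        for i in range(n_per_cluster):
            seq = anc.copy()
            mut = rng.random(n_sites) < within
            seq[mut] = rng.choice(aa, size=int(mut.sum()))
            taxa.append(f"c{ci + 1}_t{i + 1}")
            rows.append("".join(seq))
    return Alignment(taxa=taxa, rows=rows)


def gen_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """Exact additive metric of a random binary tree with positive edges.

    Built independently of any tree-construction code: each leaf's root
    path is a list of (edge id, length); the leaf-to-leaf distance is the
    sum of both path lengths minus twice the shared prefix.  Any correct
    neighbor-joining implementation must reproduce this metric exactly.
    """
    from .phylo import DistanceMatrix

    labels = [f"T{i}" for i in range(n_taxa)]
    clusters = [{l: []} for l in labels]  # leaf -> [(edge_id, length)]
    edge_id = 0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        ci, cj = clusters[i], clusters[j]
        li, lj = rng.uniform(0.1, 2.0, size=2)
        merged = {}
        for leaf, path in ci.items():
            merged[leaf] = path + [(edge_id, li)]
        for leaf, path in cj.items():
            merged[leaf] = path + [(edge_id + 1, lj)]
        edge_id += 2
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    paths = clusters[0]
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            pa = dict(paths[labels[a]])
            pb = dict(paths[labels[b]])
            shared = set(pa) & set(pb)
            dist = (sum(pa.values()) + sum(pb.values())
                    - 2 * sum(pa[e] for e in shared))
            d[a, b] = d[b, a] = dist
    return DistanceMatrix(taxa=labels, d=d)


def write_scenario(spec: SimulationSpec, outdir: str | Path) -> Path:
    """Write a self-contained input directory plus a truth.json manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ontology.obo").write_text(gen_ontology(spec))
    assoc = gen_associations(spec)
    (outdir / "associations.tsv").write_text(assoc["associations_tsv"])
    (outdir / "orthologs.tsv").write_text(assoc["orthologs_tsv"])
    expr = gen_expression(spec)
    expr["values"].to_csv(outdir / "expression.tsv", sep="\t")
    expr["sample_meta"].to_csv(outdir / "samples.tsv", sep="\t")
    qtl = gen_qtl_scenario(spec)
    (outdir / "qtls.tsv").write_text(qtl["qtls_tsv"])
    (outdir / "gene_loci.tsv").write_text(qtl["genes_tsv"])
    truth = {
        "spec": asdict(spec),
        "enrichment": assoc["truth"],
        "expression": expr["truth"],
        "qtl": qtl["truth"],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
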