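"""Gene–term associations: loading, true-path propagation, ortholog transfer.

An association links a gene of some species to an ontology term.  Two kinds
of provenance are tracked:

``direct``
    the gene itself is annotated to the term in the source snapshot;
``transitive``
    the annotation was transferred from an ortholog in another species
    (e.g. a rice gene annotated to a drought regimen term lends that
    annotation to its unannotated sorghum ortholog).

Tables are plain pandas DataFrames with a fixed column contract so every
downstream stage (screening, enrichment) can index by gene or by term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .ontology import OntologyRegistry, TermSet, accession_prefix, OntologyError

logger = logging.getLogger(__name__)

#: column contract for an association table
COLUMNS = ["gene_id", "species", "term_id", "ontology_key",
           "provenance", "source_species", "source_gene", "evidence"]

DIRECT = "direct"
TRANSITIVE = "transitive"


class AssociationError(ValueError):
    pass


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object") for c in COLUMNS})


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = None
    df["species"] = df["species"].str.lower()
    df = df[COLUMNS].drop_duplicates(
        subset=["gene_id", "species", "term_id", "provenance", "source_species",
                "source_gene"]
    )
    return df.reset_index(drop=True)


def read_associations(stream: TextIO | str) -> pd.DataFrame:
    """Read a GAF-like TSV of ``gene_id  species  term_id  ontology_key [evidence]``.

    Rows whose accession prefix contradicts the declared ontology_key are
    rejected with a warning; more than 50% rejected rows is a file error.
    Exact duplicates are collapsed (count logged).
    """
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "species", "term_id", "ontology_key"}
    missing = required - set(df.columns)
    if missing:
        raise AssociationError(f"association file missing columns: {sorted(missing)}")
    if "evidence" not in df.columns:
        df["evidence"] = None
    if df.empty:
        return _empty_table()

    def _prefix_ok(row) -> bool:
        try:
            return accession_prefix(row.term_id) == row.ontology_key
        except OntologyError:
            return False

    ok = df.apply(_prefix_ok, axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d rows with accession/ontology_key mismatch", n_bad)
        if n_bad > 0.5 * len(df):
            raise AssociationError(
                f"{n_bad}/{len(df)} rows rejected: accession prefixes do not "
                "match the declared ontology_key"
            )
        df = df[ok]
    df["provenance"] = DIRECT
    df["source_species"] = None
    df["source_gene"] = None
    n_before = len(df)
    df = _normalise(df)
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("collapsed %d exact-duplicate association rows", n_dup)
    return df


@dataclass
class OrthologMap:
    """Symmetric many-to-many orthology pairs between species."""

    pairs: pd.DataFrame  # columns species_a gene_a species_b gene_b [homology_type]

    @classmethod
    def read(cls, stream: TextIO | str,
             homology_type: str | None = None) -> "OrthologMap":
        df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
        required = {"species_a", "gene_a", "species_b", "gene_b"}
        missing = required - set(df.columns)
        if missing:
            raise AssociationError(f"ortholog file missing columns: {sorted(missing)}")
        if homology_type is not None and "homology_type" in df.columns:
            df = df[df["homology_type"] == homology_type]
        for col in ("species_a", "species_b"):
            df[col] = df[col].str.lower()
        return cls(pairs=df.reset_index(drop=True))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, str, str]]
    ) -> "OrthologMap":
        df = pd.DataFrame(pairs, columns=["species_a", "gene_a", "species_b", "gene_b"])
        df["species_a"] = df["species_a"].str.lower()
        df["species_b"] = df["species_b"].str.lower()
        return cls(pairs=df)

    def orthologs_of(self, species: str, gene: str) -> list[tuple[str, str]]:
        """(species, gene) partners of the given gene, from either column."""
        species = species.lower()
        p = self.pairs
        fwd = p[(p.species_a == species) & (p.gene_a == gene)]
        rev = p[(p.species_b == species) & (p.gene_b == gene)]
        out = {(s, g) for s, g in zip(fwd.species_b, fwd.gene_b)}
        out |= {(s, g) for s, g in zip(rev.species_a, rev.gene_a)}
        return sorted(out)

    def partners_into(self, target_species: str) -> pd.DataFrame:
        """All pairs rewritten as (target_gene, source_species, source_gene)."""
        target_species = target_species.lower()
        p = self.pairs
        fwd = p[p.species_a == target_species].rename(
            columns={"gene_a": "target_gene", "species_b": "source_species",
                     "gene_b": "source_gene"}
        )[["target_gene", "source_species", "source_gene"]]
        rev = p[p.species_b == target_species].rename(
            columns={"gene_b": "target_gene", "species_a": "source_species",
                     "gene_a": "source_gene"}
        )[["target_gene", "source_species", "source_gene"]]
        return pd.concat([fwd, rev]).drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


def propagate(assoc: pd.DataFrame, registry: OntologyRegistry) -> pd.DataFrame:
    """Close a table upward: annotate each gene to all ancestors of its terms.

    Implements the true-path rule: an annotation to a term implies annotation
    to every is_a/part_of ancestor, with the same provenance.  Unknown terms
    are dropped with a warning.  The result is a fixed point — propagating
    twice changes nothing.
    """
    if assoc.empty:
        return _normalise(assoc)
    rows = []
    dropped = 0
    # cache ancestor sets per term to keep this linear in distinct terms
    anc_cache: dict[str, set[str]] = {}
    for row in assoc.itertuples(index=False):
        key = row.ontology_key
        graph = registry.get(key)
        if graph is None or row.term_id not in graph:
            dropped += 1
            continue
        rows.append(row)
        if row.term_id not in anc_cache:
            anc_cache[row.term_id] = graph.ancestors(row.term_id)
        for anc in anc_cache[row.term_id]:
            rows.append(row._replace(term_id=anc))
    if dropped:
        logger.warning("propagate: dropped %d records with unknown terms", dropped)
    out = pd.DataFrame(rows, columns=list(assoc.columns))
    return _normalise(out)


def genes_for_terms(
    assoc: pd.DataFrame, term_set: TermSet, species: str
) -> pd.DataFrame:
    """Genes of a species with at least one association to a member term.

    Returns a frame indexed by gene_id with the supporting terms and the
    provenance flags (``direct``/``transitive``) aggregated per gene.
    Expects a propagated table.
    """
    if not term_set.member_ids:
        raise AssociationError(f"term set {term_set.label!r} is empty")
    species = species.lower()
    hit = assoc[
        (assoc.species == species) & (assoc.term_id.isin(term_set.member_ids))
    ]
    if hit.empty:
        return pd.DataFrame(columns=["terms", "provenances"])
    grouped = hit.groupby("gene_id").agg(
        terms=("term_id", lambda s: frozenset(s)),
        provenances=("provenance", lambda s: frozenset(s)),
    )
    return grouped.sort_index()


def transfer_transitive(
    assoc: pd.DataFrame,
    orthologs: OrthologMap,
    target_species: str,
    term_set: TermSet,
) -> tuple[pd.DataFrame, dict]:
    """Transfer member-term annotations to target-species genes via orthologs.

    For each target gene *lacking direct association* to the term set, every
    annotation of an ortholog (any source species) to a member term becomes a
    transitive record on the target gene.  Genes already directly associated
    receive nothing; direct records are never modified or removed.

    Returns the augmented table and a summary dict with counts of directly
    supported, transitively supported and unresolved target genes.
    """
    if len(orthologs) == 0:
        raise AssociationError("ortholog map is empty")
    target_species = target_species.lower()
    member = assoc[assoc.term_id.isin(term_set.member_ids)]
    direct_target = set(
        member[(member.species == target_species) & (member.provenance == DIRECT)]
        .gene_id
    )
    partners = orthologs.partners_into(target_species)
    # source annotations to member terms, keyed by (source_species, source_gene)
    src = member[member.species != target_species][
        ["species", "gene_id", "term_id", "ontology_key", "provenance"]
    ]
    src = src[src.provenance == DIRECT]
    merged = partners.merge(
        src, left_on=["source_species", "source_gene"],
        right_on=["species", "gene_id"],
    )
    merged = merged[~merged.target_gene.isin(direct_target)]
    new = pd.DataFrame({
        "gene_id": merged.target_gene,
        "species": target_species,
        "term_id": merged.term_id,
        "ontology_key": merged.ontology_key,
        "provenance": TRANSITIVE,
        "source_species": merged.source_species,
        "source_gene": merged.source_gene,
        "evidence": None,
    })
    out = _normalise(pd.concat([assoc, new], ignore_index=True))
    transitive_genes = set(new.gene_id)
    all_target = set(partners.target_gene) | direct_target
    summary = {
        "n_direct": len(direct_target),
        "n_transitive": len(transitive_genes),
        "n_unresolved": len(all_target - direct_target - transitive_genes),
    }
    return out, summary
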