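"""Step-wise screening: per-ontology collection, merge/dedup, all-ontology gate.

The screening funnel collects, for each of the five ontologies, the target
species' genes supported (directly or through an ortholog) by that
ontology's stress term set; merges the per-ontology sets into one unique
list; and finally keeps only genes supported by *every* required ontology
group.  The survivors feed the enrichment gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .associations import (
    DIRECT, TRANSITIVE, OrthologMap, genes_for_terms, transfer_transitive,
)
from .ontology import TermSet

PROVENANCE_CODES = {DIRECT: "D", TRANSITIVE: "T", None: "."}


class ScreeningError(ValueError):
    pass


@dataclass
class SupportMatrix:
    """Boolean gene × ontology support grid with per-cell provenance.

    ``support.loc[g, k]`` is True iff gene ``g`` has at least one surviving
    association for ontology group ``k``; ``provenance.loc[g, k]`` is
    ``"D"`` (direct), ``"T"`` (transitive only) or ``"."`` (none).
    """

    support: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.support.index)

    @property
    def ontology_keys(self) -> list[str]:
        return list(self.support.columns)

    def to_tsv(self, path_or_buf) -> None:
        self.provenance.to_csv(path_or_buf, sep="\t", index_label="gene_id")


@dataclass
class ScreenReport:
    """Per-step funnel counts for one screening run."""

    per_ontology_identified: dict[str, int] = field(default_factory=dict)
    per_ontology_transferred: dict[str, int] = field(default_factory=dict)
    merged_unique: int = 0
    all_ontology_pass: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ontology": k,
             "identified": self.per_ontology_identified[k],
             "transitive": self.per_ontology_transferred.get(k, 0)}
            for k in sorted(self.per_ontology_identified)
        ]
        return pd.DataFrame(rows)


def collect_per_ontology(
    assoc: pd.DataFrame,
    orthologs: OrthologMap,
    term_sets: Mapping[str, TermSet],
    target_species: str,
) -> tuple[dict[str, pd.DataFrame], SupportMatrix, ScreenReport]:
    """Per-ontology gene collection with ortholog fallback.

    For each ontology key, the gene set is ``genes_for_terms`` on the table
    augmented by ``transfer_transitive`` for that key's term set.  Genes
    with neither direct nor transitive support for a key read False in the
    support matrix there.
    """
    if not term_sets:
        raise ScreeningError("no term sets configured")
    for key, ts in term_sets.items():
        if ts is None:
            raise ScreeningError(f"missing term set for ontology key {key!r}")
    per_key: dict[str, pd.DataFrame] = {}
    report = ScreenReport()
    for key in sorted(term_sets):
        ts = term_sets[key]
        augmented, summary = transfer_transitive(
            assoc, orthologs, target_species, ts
        )
        per_key[key] = genes_for_terms(augmented, ts, target_species)
        report.per_ontology_identified[key] = len(per_key[key])
        report.per_ontology_transferred[key] = summary["n_transitive"]
    _, matrix = merge_unique({k: set(v.index) for k, v in per_key.items()},
                             provenance_frames=per_key)
    report.merged_unique = len(matrix.genes)
    return per_key, matrix, report


def merge_unique(
    per_ontology_sets: Mapping[str, set],
    provenance_frames: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[list[str], SupportMatrix]:
    """Union of the per-ontology sets, deduplicated, with support annotation."""
    keys = sorted(per_ontology_sets)
    universe = sorted(set().union(*per_ontology_sets.values())) if keys else []
    support = pd.DataFrame(
        {k: [g in per_ontology_sets[k] for g in universe] for k in keys},
        index=pd.Index(universe, name="gene_id"),
    )
    prov = pd.DataFrame(".", index=support.index, columns=keys)
    for k in keys:
        for g in universe:
            if g not in per_ontology_sets[k]:
                continue
            code = "D"
            if provenance_frames is not None and g in provenance_frames[k].index:
                provs = provenance_frames[k].loc[g, "provenances"]
                code = "D" if DIRECT in provs else "T"
            prov.loc[g, k] = code
    return universe, SupportMatrix(support=support, provenance=prov)


def all_ontology_filter(matrix: SupportMatrix, required_keys: set[str]) -> list[str]:
    """Genes supported by every required ontology group, lexicographically ordered."""
    if not required_keys:
        raise ScreeningError("required_keys must not be empty")
    unknown = set(required_keys) - set(matrix.ontology_keys)
    if unknown:
        raise ScreeningError(f"required keys not in matrix: {sorted(unknown)}")
    mask = matrix.support[sorted(required_keys)].all(axis=1)
    return sorted(matrix.support.index[mask])
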