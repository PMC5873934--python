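"""Gene–QTL co-localization and best-BLAST-hit selection.

A gene co-localizes with a QTL when its locus falls inside the QTL's
genomic interval (containment, the default) or merely intersects it
(overlap mode).  Coordinates are 1-based inclusive; chromosome labels are
normalized (``Chr 1`` -> ``chr1``).  Alignment-based assignment for
species without direct coordinates keeps one best hit per query, ranked by
bit score, then e-value, identity, alignment length, and subject id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .comparative import percentage_report

logger = logging.getLogger(__name__)


class IntervalError(ValueError):
    pass


def normalize_chrom(chrom: str) -> str:
    """``Chr 1`` / ``chr01`` / ``1`` -> ``chr1``."""
    s = str(chrom).strip().lower().replace(" ", "").replace("_", "")
    m = re.match(r"^(?:chr(?:omosome)?)?0*(\w+)$", s)
    return f"chr{m.group(1)}" if m else s


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise IntervalError(
                f"{self.gene_id}: invalid interval {self.start}-{self.end}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class QTLRegion:
    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise IntervalError(
                f"{self.qtl_id}: invalid interval {self.start}-{self.end}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


def read_gene_loci(stream, fmt: str = "tsv") -> list[GeneLocus]:
    """Gene loci from TSV (1-based) or BED (0-based half-open, converted)."""
    if fmt == "bed":
        df = pd.read_csv(stream, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "gene_id"],
                         usecols=range(4))
        return [GeneLocus(r.gene_id, r.chrom, int(r.start) + 1, int(r.end))
                for r in df.itertuples(index=False)]
    df = pd.read_csv(stream, sep="\t", comment="#")
    return [GeneLocus(r.gene_id, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def read_qtl_regions(stream) -> list[QTLRegion]:
    df = pd.read_csv(stream, sep="\t", comment="#", dtype={"qtl_id": str})
    ids = list(df["qtl_id"])
    if len(ids) != len(set(ids)):
        raise IntervalError("duplicate qtl_id in QTL table")
    return [QTLRegion(r.qtl_id, r.trait, r.chrom, int(r.start), int(r.end),
                      getattr(r, "ref", ""))
            for r in df.itertuples(index=False)]


@dataclass
class ColocalizationResult:
    """Per-QTL gene assignments plus totals."""

    assignments: pd.DataFrame   # columns qtl_id, trait, gene_id
    per_qtl_counts: dict[str, int]

    @property
    def grand_total(self) -> int:
        """Assignments counted per (QTL, gene) pair."""
        return int(sum(self.per_qtl_counts.values()))

    @property
    def unique_genes(self) -> set[str]:
        return set(self.assignments.gene_id)

    def to_tsv(self, path_or_buf) -> None:
        self.assignments.to_csv(path_or_buf, sep="\t", index=False)


def colocalize(
    genes: Sequence[GeneLocus],
    qtls: Sequence[QTLRegion],
    mode: str = "containment",
) -> ColocalizationResult:
    """Assign genes to QTLs by genomic position.

    containment (default): q.start <= g.start and g.end <= q.end;
    overlap: the intervals intersect.  A gene inside several QTLs is
    assigned to each.  Output ordered by (qtl_id, gene_id).
    """
    if mode not in ("containment", "overlap"):
        raise IntervalError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    counts: dict[str, int] = {}
    for q in qtls:
        n = 0
        for g in by_chrom.get(q.chrom, []):
            if g.start > q.end:
                break
            if mode == "containment":
                hit = q.start <= g.start and g.end <= q.end
            else:
                hit = g.end >= q.start and g.start <= q.end
            if hit:
                rows.append({"qtl_id": q.qtl_id, "trait": q.trait,
                             "gene_id": g.gene_id})
                n += 1
        counts[q.qtl_id] = n
    df = pd.DataFrame(rows, columns=["qtl_id", "trait", "gene_id"])
    df = df.sort_values(["qtl_id", "gene_id"], kind="mergesort").reset_index(drop=True)
    return ColocalizationResult(assignments=df, per_qtl_counts=counts)


BLAST6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bit_score",
]


def read_blast6(stream) -> pd.DataFrame:
    """12-column BLAST tabular (outfmt 6) reader."""
    return pd.read_csv(stream, sep="\t", comment="#", header=None,
                       names=BLAST6_COLUMNS)


def best_hits(hits: pd.DataFrame, evalue_max: float = 1e-10) -> pd.DataFrame:
    """One best hit per query, after discarding hits with evalue > threshold.

    Ranking (total order): descending bit score, ascending e-value,
    descending % identity, descending alignment length, lexicographic
    subject id.  Invariant under input row permutation.
    """
    surv = hits[hits.evalue <= evalue_max].copy()
    if surv.empty:
        return surv
    surv = surv.sort_values(
        by=["bit_score", "evalue", "pct_identity", "aln_length", "subject_id"],
        ascending=[False, True, False, False, True],
        kind="mergesort",
    )
    out = surv.drop_duplicates(subset="query_id", keep="first")
    return out.sort_values("query_id", kind="mergesort").reset_index(drop=True)


def summarize_by_trait(
    result: ColocalizationResult,
    trait_categories: Mapping[str, str],
    per_qtl_totals: Mapping[str, int] | None = None,
    qtls: Sequence[QTLRegion] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-category gene counts and percentage of the grand total.

    When the full gene lists are not carried (only per-QTL totals are
    published), pass ``per_qtl_totals`` to roll those up instead of the
    assignment rows.  Unmapped traits fall into ``other`` with a warning.
    """
    trait_by_qtl: dict[str, str] = {}
    if not result.assignments.empty:
        trait_by_qtl.update(
            result.assignments.drop_duplicates("qtl_id")
            .set_index("qtl_id")["trait"].to_dict()
        )
    if qtls is not None:
        trait_by_qtl.update({q.qtl_id: q.trait for q in qtls})
    counts: dict[str, int] = {}
    if per_qtl_totals is not None:
        source = per_qtl_totals.items()
    else:
        source = result.per_qtl_counts.items()
    for qtl_id, n in source:
        trait = trait_by_qtl.get(qtl_id)
        if trait is None:
            continue
        category = trait_categories.get(trait)
        if category is None:
            logger.warning("trait %r not mapped to a category; using 'other'", trait)
            category = "other"
        counts[category] = counts.get(category, 0) + n
    total = sum(counts.values())
    cats = sorted(counts)
    pcts = percentage_report([counts[c] for c in cats], total, decimals)
    return pd.DataFrame({
        "category": cats,
        "count": [counts[c] for c in cats],
        "percent": pcts,
    })
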