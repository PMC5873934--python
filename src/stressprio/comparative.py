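"""Cross-stress and cross-species set algebra.

Venn partitioning decomposes named gene sets (e.g. drought, salt, cold,
heat, oxidative) into disjoint membership regions; multistress
classification labels each focal-set gene by how many stresses share it;
orthology classes label genes by the species in which their orthologs
occur, using the 14-subclass naming scheme (SOM = sorghum orthologs in
maize, SOMR = shared in maize and rice, a ``Sorghum_`` prefix marks
additionally sorghum-specific occurrence, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd


class ComparativeError(ValueError):
    pass


@dataclass
class VennPartition:
    """Disjoint decomposition of named sets by membership pattern.

    ``regions`` maps a frozenset of labels to the sorted genes belonging to
    exactly those sets.  Regions partition the universe.
    """

    names: list[str]
    regions: dict[frozenset, list[str]]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out.update(genes)
        return out

    def region(self, *labels: str) -> list[str]:
        return self.regions.get(frozenset(labels), [])

    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            genes = self.regions[key]
            rows.append({
                "region": "+".join(sorted(key)),
                "count": len(genes),
                "genes": ",".join(genes),
            })
        return pd.DataFrame(rows)


def venn_partition(members: Mapping[str, set]) -> VennPartition:
    """Assign each gene to the region matching its membership bit-vector.

    All 2^n - 1 non-empty label subsets are reported, empty ones with
    count 0.
    """
    names = list(members)
    if len(names) != len(set(names)):
        raise ComparativeError("duplicate set labels")
    if not 2 <= len(names) <= 8:
        raise ComparativeError("venn partitioning needs 2..8 sets")
    regions: dict[frozenset, list[str]] = {}
    # enumerate all non-empty subsets so empty regions appear explicitly
    for bits in range(1, 2 ** len(names)):
        key = frozenset(n for i, n in enumerate(names) if bits >> i & 1)
        regions[key] = []
    universe = set().union(*members.values())
    for gene in sorted(universe):
        key = frozenset(n for n in names if gene in members[n])
        regions[key].append(gene)
    return VennPartition(names=names, regions=regions)


def multistress_classify(partition: VennPartition, focal: str) -> dict[str, str]:
    """Classify focal-set genes by breadth of stress sharing.

    1 set -> specific, 2 -> dual, 3 -> triple, all sets -> universal;
    intermediate breadths above three in >4-set partitions are labelled
    ``multi``.
    """
    if focal not in partition.names:
        raise ComparativeError(f"focal label {focal!r} not in partition")
    n_total = len(partition.names)
    out: dict[str, str] = {}
    for key, genes in partition.regions.items():
        if focal not in key:
            continue
        breadth = len(key)
        if breadth == n_total:
            cls = "universal"
        elif breadth == 1:
            cls = "specific"
        elif breadth == 2:
            cls = "dual"
        elif breadth == 3:
            cls = "triple"
        else:
            cls = "multi"
        for g in genes:
            out[g] = cls
    return out


def percentage_report(
    numerators: Sequence[int], denominator: int, decimals: int = 1
) -> list[float]:
    """100*num/den rounded half-away-from-zero to ``decimals`` places.

    Half-away-from-zero matches the reporting convention in which
    31.54 prints as 32 and 21.89 as 21.9.
    """
    if denominator <= 0:
        raise ComparativeError("denominator must be positive")
    if any(n < 0 for n in numerators):
        raise ComparativeError("numerators must be non-negative")
    quant = Decimal(1).scaleb(-decimals)
    out = []
    for num in numerators:
        pct = Decimal(100) * Decimal(num) / Decimal(denominator)
        out.append(float(pct.quantize(quant, rounding=ROUND_HALF_UP)))
    return out


#: species order used in class acronyms: Maize, Rice, Arabidopsis
_SPECIES_ORDER = (("maize", "M"), ("rice", "R"), ("arabidopsis", "A"))

#: the 14 subclasses of the cross-species legend; the {sorghum, maize}
#: vector has no legend label and is invalid by construction.
ORTHOLOGY_CLASSES = (
    "Sorghum", "SOA", "SOM", "SOR", "SOMA", "SOMR", "SORA", "SOMRA",
    "Sorghum_SOA", "Sorghum_SOR", "Sorghum_SOMA", "Sorghum_SOMR",
    "Sorghum_SORA", "Sorghum_SOMRA",
)


def orthology_class(gene_id: str, species_presence: Mapping[str, bool]) -> str:
    """Deterministic subclass label from the species-membership bit-vector.

    ``species_presence`` must cover keys ``sorghum`` (sorghum-specific
    occurrence), ``maize``, ``rice`` and ``arabidopsis``.
    """
    presence = {k.lower(): bool(v) for k, v in species_presence.items()}
    required = {"sorghum", "maize", "rice", "arabidopsis"}
    missing = required - set(presence)
    if missing:
        raise ComparativeError(f"presence map missing species: {sorted(missing)}")
    letters = "".join(code for sp, code in _SPECIES_ORDER if presence[sp])
    sorghum = presence["sorghum"]
    if not sorghum and not letters:
        raise ComparativeError(
            f"gene {gene_id}: all-false presence vector (gene must occur somewhere)"
        )
    if not letters:
        return "Sorghum"
    label = f"Sorghum_SO{letters}" if sorghum else f"SO{letters}"
    if label not in ORTHOLOGY_CLASSES:
        raise ComparativeError(
            f"gene {gene_id}: membership vector {label!r} has no defined subclass"
        )
    return label
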