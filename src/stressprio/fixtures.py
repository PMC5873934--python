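"""Bundled reference data: the sorghum drought-QTL table and study aggregates.

The co-localization table transcribes a published set of 22 sorghum QTLs
for drought-related traits (grain yield, stay-green, flowering time, seed
dormancy, shoot/root dry weight, nodal root angle, total leaf area), each
with one representative co-localized gene locus and the total number of
candidate genes found inside the QTL.  Four representative-gene coordinates
were truncated in print (leading digits dropped); they are restored here
and flagged in the ``corrected`` column.

``STUDY_AGGREGATES`` carries the printed summary counts of the same study
(per-stress candidate totals, per-species QTL-associated gene counts, GO
functional-classification counts) used as inputs to the arithmetic
reporting checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .qtl import ColocalizationResult, GeneLocus, QTLRegion, colocalize

# columns: qtl_id trait chrom start end ref gene_id gene_start gene_end total corrected
_QTL_TABLE = """\
qtl_id	trait	chrom	start	end	ref	gene_id	gene_start	gene_end	total	corrected
QYLD1.2	grain yield	Chr 1	11145830	12704841	ref048	Sb01g012195	11188494	11188718	1	no
QYLD1.3	grain yield	Chr 1	11203256	21602500	ref048	Sb01g012230	11244033	11246659	8	no
QSDW1	shoot dry weight	Chr 1	59861427	64432960	ref047	Sb01g036220	59863444	59868128	6	no
QGI-1	seed dormancy	Chr 1	52962744	55721536	ref049	Sb01g030510	52963286	52964344	13	no
QYLD2.1	grain yield	Chr 2	63084956	63712593	ref048	Sb02g027900	63173883	63174687	6	yes
QRDW1_2	root dry weight	Chr 2	71995008	77001005	ref047	Sb02g037700	71999473	72002734	8	no
qGI-3	seed dormancy	Chr 3	68132731	72423918	ref049	Sb03g040510	68140707	68142336	9	no
QSPAD4.1	stay-green	Chr 4	6803028	10119054	ref048	Sb04g006830	6853756	6858575	26	no
QYLD4.1	grain yield	Chr 4	45937548	62339532	ref048	Sb04g019670	45942011	45943013	10	no
qFv/Fm4.1	stay-green	Chr 4	64497114	65560043	ref048	Sb04g034665	64501979	64504340	18	yes
qGI-4	seed dormancy	Chr 4	57546281	58537697	ref049	Sb04g027660	57562353	57564270	8	no
QRA1_5	nodal root angle	Chr 5	13413924	45779999	ref047	Sb05g007450	13463573	13469204	6	no
qFT6.1	flowering time	Chr 6	1402697	40763291	ref048	Sb06g001033	1479485	1483300	7	no
QYLD6.1	grain yield	Chr 6	50360463	52945337	ref048	Sb06g020970	50361776	50364655	3	yes
qGI-6	seed dormancy	Chr 6	54128269	59786660	ref049	Sb06g025130	54128281	54131608	8	no
qGI-7	seed dormancy	Chr 7	59065206	60579009	ref049	Sb07g024070	59081442	59086488	7	no
QRA1_8	nodal root angle	Chr 8	8067699	41591844	ref047	Sb08g005781	8160471	8161062	3	no
QTLA1_8	total leaf area	Chr 8	47817803	48269890	ref047	Sb08g017820	47829763	47830809	3	no
QRDW1_8	root dry weight	Chr 8	48269890	50970340	ref047	Sb08g018270	48273154	48279810	4	yes
qFT9.1	flowering time	Chr 9	4719436	7580762	ref048	Sb09g004180	4910985	4919916	5	no
qGI-9	seed dormancy	Chr 9	57746020	58246041	ref049	Sb09g028980	57747092	57747957	3	no
QRA1_10	nodal root angle	Chr 10	57494967	58573866	ref048	Sb10g027700	57507083	57508898	7	no
"""

#: trait -> reporting category used in the published per-category rollup
TRAIT_CATEGORIES = {
    "seed dormancy": "seed dormancy",
    "grain yield": "yield-related",
    "flowering time": "yield-related",
    "stay-green": "yield-related",
    "shoot dry weight": "drought adaptation",
    "root dry weight": "drought adaptation",
    "nodal root angle": "drought adaptation",
    "total leaf area": "drought adaptation",
}

#: printed summary counts from the same study, used as arithmetic inputs
STUDY_AGGREGATES = {
    # candidate genes per stress (GO biological-process based)
    "stress_counts": {
        "drought": 169, "salt": 352, "cold": 221, "heat": 92, "oxidative": 282,
    },
    # QTL-associated target genes per species
    "qtl_species_counts": {"maize": 21, "rice": 82},
    # GO functional classification: genes in the metabolic-process group
    # out of all classified annotated sequences
    "go_classification": {"metabolic_process": 227, "classified_total": 2357},
}


@dataclass
class Table3Fixture:
    """The packaged QTL/gene reference table, parsed into domain objects."""

    qtls: list[QTLRegion]
    gene_loci: list[GeneLocus]
    expected_totals: dict[str, int]
    trait_categories: dict[str, str]
    corrected_genes: list[str]

    def colocalize_representatives(self, mode: str = "containment") -> ColocalizationResult:
        return colocalize(self.gene_loci, self.qtls, mode=mode)


def load_table3_fixture() -> Table3Fixture:
    """Parse the bundled 22-row QTL table."""
    df = pd.read_csv(io.StringIO(_QTL_TABLE), sep="\t")
    qtls = [
        QTLRegion(r.qtl_id, r.trait, r.chrom, int(r.start), int(r.end), r.ref)
        for r in df.itertuples(index=False)
    ]
    loci = [
        GeneLocus(r.gene_id, r.chrom, int(r.gene_start), int(r.gene_end))
        for r in df.itertuples(index=False)
    ]
    totals = {r.qtl_id: int(r.total) for r in df.itertuples(index=False)}
    corrected = [r.gene_id for r in df.itertuples(index=False) if r.corrected == "yes"]
    return Table3Fixture(
        qtls=qtls,
        gene_loci=loci,
        expected_totals=totals,
        trait_categories=dict(TRAIT_CATEGORIES),
        corrected_genes=corrected,
    )
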