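# Methods

This note documents the models, statistics and design choices behind
`stressprio`, the sizes at which the shipped tests and the acceptance
script exercise them, and what the synthetic data does and does not show
about real inputs.

## Ontology model and screening

Each of the five plant ontologies (GO, TO, PO, GRO, EO) is held as a
directed acyclic graph with child → parent edges for the two true-path
relations, `is_a` and `part_of`; all other OBO relationship types are
ignored. This is the standard closure convention: an annotation to a term
implies annotation to every `is_a`/`part_of` ancestor, and a stress term
set (seed accessions plus descendant closure) captures genes annotated at
any level of specificity below a seed. Obsolete terms are dropped with a
warning rather than remapped via `replaced_by`, and dangling parent
references (common in partial snapshots) are skipped with a warning.
Descendant closure of seeds is a flag, default on; with closure off a
term set is exactly its seeds.

The shipped default term-set configuration (`data/term_sets.yaml`) lists
the stress/attribute seed accessions per ontology group. A few trait
labels are annotated with GO accessions in the published source table;
the loader routes every accession to the graph matching its prefix, so
mixed-prefix seed lists work as published.

Ortholog-transitive transfer gives a target-species gene every member-term
annotation of its orthologs, but only when the gene has **no direct
association to the term set** — precedence is per (gene, term set), not
per term, and direct records are never modified. Orthology is
many-to-many; an optional `homology_type` filter (default off) restricts
to one-to-one pairs. Screening then requires, per ontology group, at
least one surviving association to the group's term set ("support");
requiring every listed term instead would empty the candidate set (e.g.
no gene occupies all seven growth stages at once). The final gate keeps
genes supported by **all** required ontology groups, in lexicographic
order for reproducibility.

## Enrichment

Over-representation of a term with `K` background and `k` study
annotations, in a study of `n` genes from a background of `N`, is the
hypergeometric upper tail `P(X ≥ k)`, computed by summing exact log-pmf
terms (log-sum-exp); values at or below the support's lower bound return
exactly 1. This matches one-sided Fisher's exact and agrees with direct
combinatorial enumeration to ≥ 10 significant digits (verified on the
full grid N ≤ 12). Multiple testing uses Benjamini–Hochberg step-up
(Benjamini–Yekutieli behind a flag), delegated to statsmodels. The
background universe defaults to all genes of the target species present
in the propagated association table and can be overridden by an explicit
universe file — the published analyses rarely state their background, and
this is the single largest source of irreproducibility in enrichment
p-values, which is why the shipped checks use planted synthetic
enrichments rather than published p-values. Default gates: q < 0.01 for
the pipeline screen, 0.05 for per-attribute analyses.

## Differential expression

Expression values are linear-scale (RPKM/FPKM-like). The two-group test
is Welch's unequal-variance *t* (pooled-variance behind a flag), run on
log₂-transformed values: expression noise is approximately Gaussian on
the log scale, so that is the scale on which a parametric *t*-test is
calibrated. The fold change is always the ratio of linear-scale group
means, guarded by a pseudo-count ε = 1e−9 against zero means. A gene is
`up` when its (BH-adjusted, togglable) p-value beats α **and**
log₂FC ≥ log₂(fold threshold); `down` symmetrically; otherwise `ns`.
Defaults mirror the emulated study designs: α = 0.01, 2-fold gate,
n = 5 samples per group. Degenerate rows (both groups constant) return
t = 0, p = 1 when equal and p ≈ 0 with a sign when unequal, rather than
raising.

Calibration and power, measured by the test suite on the synthetic
generator at the default conditions (log₂FC = 3, σ = 1 on the log₂
scale, n = 5, α = 0.01): the null type-I rate is within 3 binomial
standard errors of 0.05 over 2000 genes, and the per-gene detection
rate agrees with the noncentral-*t* closed form — about 0.87 at pooled
df = 8, empirically ≈ 0.83 for Welch (whose estimated df falls below 8
when sample variances differ by chance). Detection at these conditions
is therefore high but not near-certain; designs needing > 0.9 power at
α = 0.01 require a larger n or a stronger effect.

## Comparative set algebra

Venn partitioning assigns each gene of 2–8 named sets to the unique
region matching its membership bit-vector; all 2ⁿ − 1 regions are
reported (empty ones with count 0), regions are disjoint and their sizes
sum to the universe. Multistress classes count the labels in a focal
gene's region: 1 → specific, 2 → dual, 3 → triple, all → universal
(breadths of 4 in a 5+-set partition are labelled `multi`). Percentages
are rounded half-away-from-zero at the requested precision, which is the
convention of the published tables this mirrors (21.89 → 21.9,
31.54 → 32); banker's rounding would break .x5 boundary cases.

The cross-species orthology labels form a fixed 14-subclass scheme over
the occurrence bit-vector (sorghum-specific, maize, rice, *Arabidopsis*):
`SOM`, `SOR`, `SOA`, their pairwise and triple combinations, `Sorghum`,
and `Sorghum_`-prefixed variants. The scheme defines no label for the
{sorghum-specific, maize-only} vector, so that vector (and the all-false
vector) raises a validation error rather than inventing a label.

## QTL co-localization and best hits

Coordinates are 1-based inclusive; chromosome labels are normalized
(`Chr 1` → `chr1`); BED input (0-based half-open) is converted on read.
Default assignment is full containment (`q.start ≤ g.start` and
`g.end ≤ q.end`), matching the "falls within" criterion; overlap mode is
provided because boundary-straddling genes are biologically plausible,
and containment output is always a subset of overlap output. A gene
inside several (overlapping) QTLs is assigned to each; the deduplicated
gene count is reported alongside the per-assignment total. Best-hit
selection over BLAST outfmt-6 tables discards hits above the e-value
ceiling (default 1e−10) and ranks the rest by descending bit score,
ascending e-value, descending % identity, descending alignment length,
then subject id — a total order, so the result is invariant under input
row permutation.

The bundled 22-row sorghum drought-QTL reference table carries one
representative gene locus and the published per-QTL candidate total per
row (only representatives' coordinates were published, so the totals are
metadata rather than synthesized loci). Four representative coordinates
were truncated in the printed source (leading digits dropped); the
fixture restores the evident digits and flags those rows in a
`corrected` column. One QTL's citation tag disagrees with its trait
family in the source; categories are assigned by trait name.

## Phylogenetics

Pairwise distances are the fraction of mismatching aligned positions;
complete gap deletion (default, matching "gaps excluded") drops every
column with a gap in any row, pairwise deletion drops per-pair gapped
columns. The optional Kimura protein correction
`d = −ln(1 − p − 0.2p²)` compensates for multiple substitutions;
saturated pairs (argument ≤ 0) are capped with a warning. The p-distance
is a pseudo-metric (symmetric, zero diagonal); the triangle inequality
is not guaranteed after correction.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion `Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·)` with the usual
limb-length formulas and a final three-cluster closed form. Ties in Q are
broken lexicographically by the clusters' smallest leaf labels, making
the topology deterministic. Negative limb lengths are clamped to zero
with the deficit moved to the sibling edge (raw lengths behind a flag).
On additive matrices the reconstructed tree's path metric reproduces the
input exactly; the test suite verifies < 1e−9 error over 100 random
binary trees of up to 8 taxa, which is the primary correctness oracle.
Bootstrap resamples alignment columns with replacement (seeded NumPy
generator, fully reproducible), rebuilds the tree per replicate, and
scores each internal bipartition of the point-estimate tree by its
replicate frequency on the 0..n_reps scale; edges below a configurable
floor (default 5% of replicates) can be collapsed on output. Identical
sequences for all taxa yield a star tree with a degenerate flag.
Serialization wraps dendropy, so Newick quoting and parsing round-trip
losslessly (lengths to 6 decimals).

## Synthetic data

Every generator is a pure function of (spec, seed); one global seed fans
out to fixed per-generator substreams so adding a generator never
perturbs existing fixtures. Ontologies are random DAGs (each term's
parents drawn from earlier terms). Association snapshots plant one term
with **exact** study/background coverages (40/50 study vs 100/1000
background by default) plus density-controlled noise annotations, and
can reroute a fraction of annotations through rice orthologs so they are
reachable only transitively. Expression matrices put Gaussian noise
(σ = 1) on log₂ values around a baseline of 5 and add the planted log₂FC
(default 3 ≈ 8-fold) to the stress group before exponentiating —
emulating two-group stress/control designs with ≥ 2-fold planted
up-regulation. QTL scenarios stripe disjoint QTL slots across
chromosomes with genes placed strictly inside (plus distractors on a
QTL-free chromosome), so containment ground truth is exact by
construction.

What the generator does **not** emulate: mean–variance trends and count
noise of real RNA-seq, correlated genes, batch effects, incomplete or
biased ontology annotation, paralog-confounded orthology, or realistic
genome structure. Passing tests therefore demonstrate correctness of the
algorithms and calibration under their stated assumptions, not
robustness to those real-data complications.

## Problem sizes

The shipped suite and acceptance script run at desk scale, chosen to
exercise every stage with tight statistical bounds: 200 planted
enrichment simulations of 300 genes × 20 terms; 2000 null genes and 1000
genes / 50 planted for DE; 100 random trees (≤ 8 taxa) and 200 bootstrap
replicates on a 6-taxon, 100-site alignment; the 22-row QTL reference
table. Published headline counts that depend on 2017-era database
snapshots (candidate totals per ontology, enrichment p-values, Venn
region sizes, the 493-peptide tree) are not reproducible from code alone
and are out of scope; the procedure, not the snapshot, is what the
package reproduces.
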