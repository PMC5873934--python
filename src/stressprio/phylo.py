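"""Distance-based protein phylogenetics: p-distance, NJ, bootstrap, Newick.

Distances are percent sequence divergence (fraction of mismatching aligned
positions, gapped columns excluded) with an optional Kimura protein
correction d = -ln(1 - p - 0.2 p^2) compensating for multiple
substitutions.  Trees come from Saitou–Nei neighbor joining:

    Q(i,j) = (r - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

joining the minimum-Q pair each round, with the standard limb-length
formulas.  Negative limb lengths are clamped to zero with the deficit
moved to the sibling edge (raw lengths available behind a flag).  Bootstrap
supports count how often each internal bipartition of the point-estimate
tree recurs across trees built from column-resampled alignments.

The tree object wraps a :class:`dendropy.Tree`, so Newick/Nexus I/O,
quoting and bipartition hashing come from dendropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"


class PhyloError(ValueError):
    pass


@dataclass
class Alignment:
    """Aligned amino-acid sequences of equal length."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise PhyloError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise PhyloError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError(f"unequal row lengths: {sorted(lengths)}")
        if self.rows and len(self.rows[0]) < 1:
            raise PhyloError("empty alignment rows")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def read_fasta(cls, stream) -> "Alignment":
        taxa, rows, label, chunks = [], [], None, []
        if isinstance(stream, str):
            import io
            stream = io.StringIO(stream)
        for line in stream:
            line = line.rstrip()
            if line.startswith(">"):
                if label is not None:
                    taxa.append(label)
                    rows.append("".join(chunks))
                label, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if label is not None:
            taxa.append(label)
            rows.append("".join(chunks))
        return cls(taxa=taxa, rows=rows)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        return Alignment(
            taxa=list(self.taxa),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match taxa")
        if not np.isfinite(self.d).all():
            raise PhyloError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("non-zero diagonal")
        if np.any(self.d < 0):
            raise PhyloError("negative distances")


def pdistance(aln: Alignment, gap_mode: str = "complete") -> DistanceMatrix:
    """Fraction of mismatching positions over comparable columns.

    complete mode drops every column with a gap in any row; pairwise mode
    drops columns gapped in either member of each pair.
    """
    if len(aln.taxa) < 2:
        raise PhyloError("need >=2 taxa")
    arr = np.array([list(r) for r in aln.rows])
    n = len(aln.taxa)
    d = np.zeros((n, n))
    if gap_mode == "complete":
        keep = ~(arr == GAP).any(axis=0)
        if not keep.any():
            raise PhyloError("no gap-free columns remain under complete deletion")
        sub = arr[:, keep]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(sub[i] != sub[j])
    elif gap_mode == "pairwise":
        gaps = arr == GAP
        for i in range(n):
            for j in range(i + 1, n):
                keep = ~(gaps[i] | gaps[j])
                if not keep.any():
                    raise PhyloError(
                        f"no comparable columns for pair "
                        f"({aln.taxa[i]}, {aln.taxa[j]})"
                    )
                d[i, j] = d[j, i] = np.mean(arr[i, keep] != arr[j, keep])
    else:
        raise PhyloError(f"unknown gap_mode {gap_mode!r}")
    return DistanceMatrix(taxa=list(aln.taxa), d=d)


def kimura_correct(p: float) -> float:
    """Kimura (1983) protein distance d = -ln(1 - p - 0.2 p^2)."""
    arg = 1.0 - p - 0.2 * p * p
    if p < 0:
        raise PhyloError("proportion must be >= 0")
    if arg <= 0:
        raise PhyloError(f"distance saturated at p={p}: correction undefined")
    return float(-np.log(arg))


def correct_matrix(D: DistanceMatrix, cap: float = 10.0) -> DistanceMatrix:
    """Apply the Kimura correction elementwise; saturated cells capped."""
    n = len(D.taxa)
    out = np.zeros_like(D.d)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = kimura_correct(D.d[i, j])
            except PhyloError:
                logger.warning(
                    "saturated distance %s-%s capped at %g",
                    D.taxa[i], D.taxa[j], cap,
                )
                out[i, j] = out[j, i] = cap
    return DistanceMatrix(taxa=list(D.taxa), d=out)


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating seed node) with optional supports."""

    tree: dendropy.Tree
    n_bootstrap: int = 0
    star: bool = False

    @property
    def taxa(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the tree's additive metric)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return DistanceMatrix(taxa=[t.label for t in taxa], d=d)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, each as the smaller-side label set."""
        out = set()
        all_taxa = frozenset(self.taxa)
        self.tree.encode_bipartitions()
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is None or edge.head_node.is_leaf():
                continue
            if edge.tail_node is None:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(min(side, all_taxa - side, key=sorted))
        return out


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Saitou–Nei NJ with deterministic lexicographic tie-breaking.

    Exact on additive matrices: the returned tree's path metric reproduces
    the input.  Ties in Q are broken by the lexicographically smallest
    (cluster key, cluster key) pair, where a cluster's key is its smallest
    leaf label.
    """
    n = len(D.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs >=3 taxa")
    tns = dendropy.TaxonNamespace(sorted(D.taxa))
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[int, dendropy.Node] = {}
    keys: dict[int, str] = {}
    for idx, label in enumerate(D.taxa):
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes[idx] = node
        keys[idx] = label
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.d[i, j])

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(i, j) - rowsum[i] - rowsum[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, (i, j))
                if best is None or cand < best:
                    best = cand
        _, _, (i, j) = best
        dij = get(i, j)
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation: closed-form limb lengths
    a, b, c = sorted(active, key=lambda k: keys[k])
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if clamp_negative:
        la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = length
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative limb to 0, moving the deficit to the sibling edge."""
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def bootstrap(
    aln: Alignment,
    n_reps: int,
    seed: int,
    gap_mode: str = "complete",
    correction: bool = False,
    support_floor: float = 0.05,
    collapse: bool = False,
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate (seeded).  The
    support of an internal edge is the number of replicate trees containing
    the same bipartition, on the 0..n_reps scale, stored as the internal
    node label.  With ``collapse`` True, edges supported in fewer than
    ``support_floor`` of replicates are contracted.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")

    def build(a: Alignment) -> PhyloTree:
        D = pdistance(a, gap_mode=gap_mode)
        if correction:
            D = correct_matrix(D)
        return neighbor_joining(D)

    base_D = pdistance(aln, gap_mode=gap_mode)
    if np.allclose(base_D.d, 0):
        # all sequences identical: topology is arbitrary, report a star tree
        tns = dendropy.TaxonNamespace(sorted(aln.taxa))
        tree = dendropy.Tree(taxon_namespace=tns)
        root = dendropy.Node()
        for label in sorted(aln.taxa):
            child = dendropy.Node(taxon=tns.get_taxon(label))
            root.add_child(child)
            child.edge.length = 0.0
        tree.seed_node = root
        tree.is_rooted = False
        return PhyloTree(tree=tree, n_bootstrap=n_reps, star=True)

    point = build(aln)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        rep_tree = build(aln.resample_columns(rng))
        for bip in rep_tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1

    all_taxa = frozenset(point.taxa)
    floor_count = support_floor * n_reps
    to_collapse = []
    for edge in point.tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.is_leaf() or edge.tail_node is None:
            continue
        side = frozenset(l.taxon.label for l in head.leaf_iter())
        if not 1 < len(side) < len(all_taxa) - 1:
            continue
        bip = min(side, all_taxa - side, key=sorted)
        support = counts.get(bip, 0)
        head.label = str(support)
        if collapse and support < floor_count:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return PhyloTree(tree=point.tree, n_bootstrap=n_reps)


def write_newick(tree: PhyloTree, stream=None) -> str:
    """Serialize as Newick, branch lengths to 6 decimals, supports as labels."""
    text = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    if stream is not None:
        stream.write(text)
    return text


def read_newick(text: str) -> PhyloTree:
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)
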