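"""Distance-based phylogenetics: neighbor joining, bootstrap support,
outgroup rooting, the informative-sites significance-threshold table, and
cross-partition cluster comparison.

Trees are :class:`dendropy.Tree` objects.  Internal-node bootstrap supports
live in a ``support`` attribute on nodes (fraction in [0, 1]) and are
round-tripped through Newick as internal node labels.  NJ is implemented
here (negative branch lengths clamped to zero with the deficit logged);
dendropy supplies the tree container, Newick I/O and Robinson–Foulds
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .align import ALPHABET, _IDX, AlignParams
from .seqio import GAP, Alignment

logger = logging.getLogger("prodomainkit")


class TreeError(ValueError):
    """Invalid input to a tree operation."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal, keyed by taxa ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise TreeError(f"matrix shape {self.matrix.shape} != ({n},{n})")
        if not np.allclose(self.matrix, self.matrix.T):
            raise TreeError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise TreeError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise TreeError("distance matrix has negative entries")


def distance_matrix(aln: Alignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances over columns where both rows are ungapped (and not X).

    ``p_distance``: mismatch fraction.  ``blosum_scoredist``: a normalized
    score-derived distance, 1 - 2 S(a,b) / (S(a,a) + S(b,b)), floored at 0.
    """
    if aln.n_rows < 3:
        raise TreeError("distance_matrix requires >= 3 rows")
    if model not in ("p_distance", "blosum_scoredist"):
        raise TreeError(f"unknown distance model {model!r}")
    n = aln.n_rows
    enc = np.array(
        [[_IDX[ch] if ch in _IDX else -1 for ch in row] for row in aln.matrix],
        dtype=int,
    )
    valid = (enc >= 0) & (enc != _IDX["X"])
    blosum = AlignParams().score_matrix
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                raise TreeError(
                    f"rows {aln.row_ids[i]!r} and {aln.row_ids[j]!r} share no "
                    "ungapped columns"
                )
            a, b = enc[i][both], enc[j][both]
            if model == "p_distance":
                d = float(np.mean(a != b))
            else:
                s_ab = float(blosum[a, b].sum())
                s_aa = float(blosum[a, a].sum())
                s_bb = float(blosum[b, b].sum())
                d = max(0.0, 1.0 - 2.0 * s_ab / (s_aa + s_bb))
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(list(aln.row_ids), dm)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("NJ: negative branch length %.4g clamped to 0 (%s)", length, context)
        return 0.0
    return float(length)


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining; returns an unrooted dendropy Tree.

    Deterministic: Q-matrix ties broken by lowest (i, j) index pair.  Negative
    branch lengths are clamped to zero with the deficit logged.
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError("nj requires >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # ties: lowest flat index == lowest (i, j)
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = _clamp(li, f"join {i},{j}")
        nj_.edge.length = _clamp(lj, f"join {i},{j}")
        # distances from the new node to remaining actives
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final three-way join: three-point formulas
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = dendropy.Node()
    for idx, length in ((a, 0.5 * (dab + dac - dbc)),
                        (b, 0.5 * (dab + dbc - dac)),
                        (c, 0.5 * (dac + dbc - dab))):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = _clamp(length, "final join")
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset[str]) -> dict:
    """Map canonical unrooted bipartition -> node, for internal edges only."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        comp = all_taxa - side
        if not comp or not side:
            continue
        key = min(tuple(sorted(side)), tuple(sorted(comp)))
        out[frozenset(key)] = node
    return out


def bootstrap_support(
    aln: Alignment,
    model: str = "p_distance",
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports on internal edges.

    Supports are fractions of column-resampled replicates containing the same
    unrooted bipartition; deterministic given ``seed``.
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    tree = nj(distance_matrix(aln, model))
    all_taxa = frozenset(aln.row_ids)
    main_bips = _bipartitions(tree, all_taxa)
    counts = {bip: 0 for bip in main_bips}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(row[c] for c in cols) for row in aln.matrix]
        rep = Alignment(list(aln.row_ids), rows)
        rep_tree = nj(distance_matrix(rep, model))
        for bip in _bipartitions(rep_tree, all_taxa):
            if bip in counts:
                counts[bip] += 1
    for bip, node in main_bips.items():
        node.support = counts[bip] / n_reps
    for leaf in tree.leaf_node_iter():
        leaf.support = 1.0
    return tree


# ---------------------------------------------------------------------------
# Newick I/O (supports as internal node labels)
# ---------------------------------------------------------------------------

def to_newick(tree: dendropy.Tree) -> str:
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = f"{sup:.3f}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return from_newick(fh.read())


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted RF (symmetric-difference) distance between two trees."""
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=ns,
                          preserve_underscores=True)
    b = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=ns,
                          preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# Rooting and clade queries
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: dendropy.Tree, taxon_id: str) -> dendropy.Tree:
    """Root on the edge leading to the outgroup leaf (original tree untouched)."""
    rooted = from_newick(to_newick(tree))
    node = rooted.find_node_with_taxon_label(taxon_id)
    if node is None:
        raise TreeError(f"outgroup taxon {taxon_id!r} not in tree")
    length = node.edge.length or 0.0
    rooted.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


THRESHOLD_TABLE = ((150, 0.95), (100, 0.85), (50, 0.65), (25, 0.50))


def significance_threshold(n_informative: int) -> float:
    """Support needed for a node to be called significant, given the number of
    informative positions in the underlying alignment.

    Piecewise: >150 -> 0.95; 100-150 -> 0.85; 50-100 -> 0.65; 25-50 -> 0.50.
    Boundary counts take the lower (more lenient) band's threshold.
    """
    if n_informative < 25:
        raise TreeError(
            f"insufficient informative positions ({n_informative} < 25)"
        )
    for bound, threshold in THRESHOLD_TABLE:
        if n_informative > bound:
            return threshold
        if n_informative == bound:
            # exactly on a boundary: lower band, logged
            logger.info(
                "significance_threshold: boundary count %d resolved leniently",
                n_informative,
            )
    return 0.50


def clade_query(
    tree: dendropy.Tree,
    taxa_set: Iterable[str],
    ignore: Optional[Iterable[str]] = None,
) -> dict:
    """Is ``taxa_set`` exactly the leaf set of some rooted clade?

    Returns {"present_as_clade": bool, "support": float}; support is the MRCA
    edge's support (of the smallest containing clade when absent).  Singletons
    are present with support 1.0 by convention.
    """
    taxa = set(taxa_set)
    ignored = set(ignore or ())
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = taxa - tree_taxa
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if len(taxa) == 1:
        return {"present_as_clade": True, "support": 1.0}
    mrca = tree.mrca(taxon_labels=sorted(taxa))
    clade_leaves = _leafset(mrca) - ignored
    present = clade_leaves == taxa
    support = getattr(mrca, "support", None)
    if support is None:
        support = 1.0 if mrca.parent_node is None else 0.0
    return {"present_as_clade": present, "support": float(support)}


@dataclass
class ClusterComparison:
    """Per named cluster, per partition: clade presence/support/significance."""

    table: dict[str, dict[str, dict]] = field(default_factory=dict)
    prodomain_only: list[str] = field(default_factory=list)


PARTITIONS = ("prodomain", "ligand", "full_length", "cystine_knot")


def compare_partitions(
    partition_trees: Mapping[str, dendropy.Tree],
    named_clusters: Mapping[str, Sequence[str]],
    thresholds: Optional[Mapping[str, float]] = None,
    allowed_drops: Optional[Iterable[str]] = None,
) -> ClusterComparison:
    """Tabulate clade presence of each named cluster in each partition's tree
    and flag clusters present in the prodomain tree but absent from both the
    ligand and full-length trees.
    """
    drops = set(allowed_drops or ())
    leafsets = {
        p: {l.taxon.label for l in t.leaf_node_iter()} - drops
        for p, t in partition_trees.items()
    }
    ref = None
    for p, ls in leafsets.items():
        if ref is None:
            ref = ls
        elif ls != ref:
            raise TreeError(
                f"partition {p!r} leaf set differs beyond allowed drops: "
                f"{sorted(ls ^ ref)}"
            )
    result = ClusterComparison()
    for name, taxa in named_clusters.items():
        row: dict[str, dict] = {}
        for part, tree in partition_trees.items():
            q = clade_query(tree, taxa)
            entry = dict(q)
            if thresholds and part in thresholds:
                entry["significant_at_threshold"] = q["support"] >= thresholds[part]
            row[part] = entry
        result.table[name] = row
        if (
            row.get("prodomain", {}).get("present_as_clade")
            and "ligand" in row and not row["ligand"]["present_as_clade"]
            and "full_length" in row and not row["full_length"]["present_as_clade"]
        ):
            result.prodomain_only.append(name)
    return result
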