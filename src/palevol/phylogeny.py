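"""Neighbor-joining phylogenies from distance matrices, with bootstrap support.

The agglomeration follows the Saitou-Nei Q criterion and is exact on
additive matrices.  Ties in the Q minimization are broken by the
lexicographically lowest label pair so results are platform-independent;
negative branch lengths arising from non-additive noise are clamped to zero
with the deficit transferred to the sibling edge (standard practice).
Trees are held as :mod:`dendropy` trees, so newick I/O and rerooting come
for free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from palevol.errors import NoDataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ParameterError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ParameterError("distance matrix is not symmetric (tolerance 1e-12)")
        if np.any(np.diag(self.d) != 0.0):
            raise ParameterError("distance matrix diagonal must be exactly zero")
        if np.any(self.d < 0.0):
            raise ParameterError("distances must be nonnegative")
        self.d = (self.d + self.d.T) / 2.0

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(header, np.array(rows))


def build_distance_matrix(
    ids: Sequence[str], rows: Sequence[str], deletion_policy: str = "complete"
) -> DistanceMatrix:
    """p-distance matrix from aligned rows.

    ``complete`` drops every column containing a gap or ``N`` in any row
    before comparing (the usual convention for tree building); ``pairwise``
    drops columns per pair.
    """
    ids = list(ids)
    arr = np.array([list(r.upper()) for r in rows])
    valid = np.isin(arr, list("ACGT"))
    n = len(ids)
    d = np.zeros((n, n))
    if deletion_policy == "complete":
        keep = valid.all(axis=0)
        if not keep.any():
            raise NoDataError("complete deletion removed every column")
        arr = arr[:, keep]
        valid = valid[:, keep]
    elif deletion_policy != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nn = int(both.sum())
            if nn == 0:
                raise NoDataError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            p = float((arr[i, both] != arr[j, both]).sum()) / nn
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


@dataclass
class PhyloTree:
    """A (by default unrooted) tree with branch lengths and optional supports."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxon_labels(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of taxon labels.

        Each internal edge contributes the side of the split that does not
        contain the alphabetically first taxon, making the representation
        invariant to rooting.
        """
        labels = set(self.taxon_labels)
        ref = min(labels)
        out: set[frozenset] = set()
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic distances between all leaf pairs."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.taxon_labels)
        n = len(labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(labels, d)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative NJ branch lengths, transferring the deficit to the sibling."""
    if li < 0.0:
        lj += li
        li = 0.0
        logger.debug("negative NJ branch clamped to 0; deficit moved to sibling")
    if lj < 0.0:
        li += lj
        lj = 0.0
        logger.debug("negative NJ branch clamped to 0; deficit moved to sibling")
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Requires at least three taxa.  The output is unrooted (trifurcating
    seed node); for three taxa the branch lengths are the three-point
    formulas.
    """
    n = len(dm)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    keys: list[str] = []          # min leaf label per active node, for tie-breaking
    for lab in dm.labels:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nodes.append(nd)
        keys.append(lab)
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-10 * max(1.0, abs(qmin)):
                    key = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to the remaining ones
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            d[new_idx, k] = d[k, new_idx] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three-point join
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    seed = dendropy.Node()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        seed.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=seed)
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(
    aln: Mapping[str, str],
    n_reps: int = 100,
    seed: Optional[int] = None,
    deletion_policy: str = "complete",
) -> PhyloTree:
    """NJ tree with site-resampled bootstrap supports.

    Supports are the percentage of replicate trees containing each internal
    bipartition of the point-estimate tree, written as internal node labels
    and collected in ``PhyloTree.supports``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    ids = list(aln)
    rows = [aln[i] for i in ids]
    point = nj_tree(build_distance_matrix(ids, rows, deletion_policy))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = len(rows[0])
    arr = np.array([list(r) for r in rows])
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj_tree(build_distance_matrix(ids, rep_rows, deletion_policy))
        except NoDataError:
            continue
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    point.supports = supports
    # annotate internal nodes
    labels = set(point.taxon_labels)
    ref = min(labels)
    for node in point.tree.preorder_node_iter():
        if node.is_leaf() or node is point.tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if side in supports:
            node.label = str(int(round(supports[side])))
    return point


def root_with_outgroup(ptree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root a tree on the pendant edge of the named outgroup taxon."""
    tree = ptree.tree.clone(depth=1)
    node = tree.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise ParameterError(f"outgroup {outgroup_label!r} not found in tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return PhyloTree(tree, dict(ptree.supports))
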