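"""Distance-tree construction: neighbor joining, midpoint rooting,
column-resampling bootstrap, and newick serialization.

Trees are held as :class:`skbio.TreeNode` objects.  Neighbor joining is
implemented here rather than delegated so that its tie-breaking (smallest
leaf-label pair on equal Q criteria) and its treatment of negative
branch-length estimates (clamped to zero, deficit moved to the sibling)
are deterministic and documented; scikit-bio's own implementation serves
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
from skbio import TreeNode

from .distances import (
    DistanceMatrix,
    SaturationError,
    encode_matrix,
    matrix_from_codes,
)
from .io import BarcodeSequence

log = logging.getLogger(__name__)


class TreeSizeError(ValueError):
    """Fewer than three taxa."""


class DegenerateTreeError(ValueError):
    """Tree has no positive branch length to root on."""


def nj_tree(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on the Q criterion.

    Returns an unrooted tree (trifurcating root node).  For an additive
    input matrix the leaf-to-leaf path lengths reproduce the matrix
    exactly.  Ties in the Q criterion are broken toward the
    lexicographically smallest pair of subtree labels; negative branch
    estimates are clamped to zero with the deficit added to the sibling.
    """
    n = len(m.ids)
    if n < 3:
        raise TreeSizeError(f"neighbor joining needs >= 3 taxa, got {n}")
    d = m.values.astype(float).copy()
    nodes = [TreeNode(name=name) for name in m.ids]
    # tie-break label: smallest leaf name within each active subtree
    labels = list(m.ids)

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        i, j = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((labels[ab[0]], labels[ab[1]]))),
        )
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, labels[i], labels[j])
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        du = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [x for x in range(k) if x not in (i, j)]
        d_new = np.empty((k - 1, k - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [
            min(labels[i], labels[j])]
        d = d_new

    # final three-point join
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = dab - la
    lc = dac - la
    root = TreeNode(children=[a, b, c])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return root


def _clamp_pair(li, lj, name_i, name_j):
    if li < 0.0:
        log.info("clamping negative branch %.3g on %s", li, name_i)
        lj += li
        li = 0.0
    if lj < 0.0:
        log.info("clamping negative branch %.3g on %s", lj, name_j)
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    total = sum(n.length or 0.0 for n in tree.traverse() if n.length)
    if total <= 0.0:
        raise DegenerateTreeError("all branch lengths are zero")
    return tree.root_at_midpoint()


def tree_bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial leaf bipartitions induced by internal edges."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(frozenset((side, leaves - side)))
    return parts


def bootstrap_support(
    seqs: list[BarcodeSequence],
    metric: str = "k2p",
    b: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``b`` times; each
    replicate matrix is rebuilt and its NJ tree's bipartitions collected.
    The support of an internal edge is the percentage of completed
    replicates containing the same bipartition (replicates with a
    saturated pair are skipped with a warning).  Internal node names of
    the returned tree carry the integer support.
    """
    if b < 1:
        raise ValueError("bootstrap needs at least one replicate")
    ids = [s.id for s in seqs]
    codes = encode_matrix(seqs)
    tree = nj_tree(matrix_from_codes(codes, ids, metric))
    leaves = frozenset(ids)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    n_cols = codes.shape[1]
    completed = 0
    for rep in range(b):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_m = matrix_from_codes(codes[:, cols], ids, metric)
        except SaturationError as err:
            log.warning("bootstrap replicate %d skipped: %s", rep, err)
            continue
        completed += 1
        for part in tree_bipartitions(nj_tree(rep_m)):
            counts[part] = counts.get(part, 0) + 1
    if completed == 0:
        raise SaturationError("every bootstrap replicate saturated")
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            part = frozenset((side, leaves - side))
            node.name = str(round(100.0 * counts.get(part, 0) / completed))
    return tree


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize with branch lengths at fixed significant digits."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            s += node.name or ""
        if node.length is not None:
            s += f":{node.length:.{precision}g}"
        return s

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, precision) + "\n")


def read_newick(source) -> TreeNode:
    """Parse newick text or a file path into a tree."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(_io.StringIO(source))
    return TreeNode.read(str(source))
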