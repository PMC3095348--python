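"""Domain-column phylogenies: p-distance, neighbor joining, bootstrap, rooting.

The tree-building workflow mirrors classical distance analysis of a protein
family: restrict the alignment to the homologous domain columns (TEH + CRF
core + AP2 for CRF proteins), compute uncorrected p-distances with pairwise
deletion of gapped columns, agglomerate with the Saitou–Nei neighbor-joining
algorithm, attach bootstrap support to internal edges by column resampling,
and root on a designated outgroup.  Trees are :class:`dendropy.Tree` objects
and serialize to Newick with branch lengths to six decimals and integer
bootstrap supports as internal-node labels.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .architecture import ArchitectureCall, CRF_CATEGORIES
from .motif_profile import DomainKind
from .seq_io import AlignedBlock, GAP

logger = logging.getLogger(__name__)

#: Bootstrap supports below this percentage are annotated ``below_threshold``.
SUPPORT_DISPLAY_THRESHOLD = 50

#: Domain kinds whose columns enter the phylogenetic alignment.
TREE_DOMAIN_KINDS = (DomainKind.TEH, DomainKind.CRF_CORE, DomainKind.AP2)


def extract_domain_alignment(
    alignment: AlignedBlock, calls: Sequence[ArchitectureCall]
) -> AlignedBlock:
    """Restrict an alignment to CRF rows and their domain columns.

    Hit coordinates (sequence residue space) are lifted to alignment columns
    through each row's gap structure; the union of the TEH/CRF-core/AP2 spans
    over all CRF calls is returned in original column order.  Rows whose call
    is not a CRF category are excluded.
    """
    crf_calls = [c for c in calls if c.category in CRF_CATEGORIES]
    rows = {rid: res for rid, res in alignment.rows}
    cols: set[int] = set()
    keep_ids = set()
    for call in crf_calls:
        if call.seq_id not in rows:
            raise ValueError(f"CRF call {call.seq_id!r} is absent from the alignment")
        keep_ids.add(call.seq_id)
        res = rows[call.seq_id]
        col_of_residue = [i for i, ch in enumerate(res) if ch != GAP]
        for hit in call.evidence:
            if hit.kind not in TREE_DOMAIN_KINDS:
                continue
            if hit.end > len(col_of_residue):
                raise ValueError(
                    f"hit [{hit.start}, {hit.end}) on {call.seq_id!r} exceeds the "
                    f"{len(col_of_residue)} residues present in its alignment row"
                )
            cols.update(col_of_residue[hit.start : hit.end])
    ordered = sorted(cols)
    kept_rows = tuple(
        (rid, "".join(res[c] for c in ordered))
        for rid, res in alignment.rows
        if rid in keep_ids
    )
    return AlignedBlock(kept_rows)


def p_distance(block: AlignedBlock) -> DistanceMatrix:
    """Uncorrected p-distance with pairwise deletion of gapped columns.

    ``d(i, j)`` is the fraction of differing residues among columns where
    neither row is gapped.  A pair with no comparable columns is an error.
    """
    if block.n_rows < 2:
        raise ValueError("need at least 2 rows to compute distances")
    ids = list(block.ids)
    arrs = [
        np.frombuffer(res.encode("ascii"), dtype=np.uint8) for _, res in block.rows
    ]
    gap_code = ord(GAP)
    n = len(arrs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = (arrs[i] != gap_code) & (arrs[j] != gap_code)
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            diff = int((arrs[i][comparable] != arrs[j][comparable]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, ids=ids)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; Q ties are
    broken toward the lexicographically smallest taxon pair (each cluster
    represented by its smallest member label).  Negative branch lengths are
    clamped to 0 with the deficit transferred to the sister branch so the
    joined pair's path length is preserved.  The result is an unrooted tree
    with a single degree-3 basal node.
    """
    taxa = list(dm.ids)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(taxa)
    D: dict[int, dict[int, float]] = {
        i: {j: float(dm[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    nodes: dict[int, dendropy.Node] = {}
    rep: dict[int, str] = {}
    for i, label in enumerate(taxa):
        nodes[i] = dendropy.Node(taxon=tns.get_taxon(label))
        rep[i] = label
    active = list(range(n))
    next_id = n

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                key = tuple(sorted((rep[i], rep[j])))
                if best_q is None or q < best_q[0] - 1e-12 or (
                    abs(q - best_q[0]) <= 1e-12 and key < best_q[1]
                ):
                    best_q = (q, key)
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = D[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        u = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        D[next_id] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[next_id][k] = duk
            D[k][next_id] = duk
        nodes[next_id] = u
        rep[next_id] = min(rep[i], rep[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final three-point join onto the basal degree-3 node
    x, y, z = active
    center = dendropy.Node()
    lx = 0.5 * (D[x][y] + D[x][z] - D[y][z])
    ly = 0.5 * (D[x][y] + D[y][z] - D[x][z])
    lz = 0.5 * (D[x][z] + D[y][z] - D[x][y])
    for k, lk in ((x, lx), (y, ly), (z, lz)):
        nodes[k].edge.length = max(lk, 0.0)
        center.add_child(nodes[k])
    tree = dendropy.Tree(seed_node=center, taxon_namespace=tns)
    tree.is_rooted = False
    return tree


def _splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as canonical leaf sets.

    Each split is the side not containing the lexicographically smallest
    taxon, so splits compare across trees on the same leaf set regardless of
    orientation.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = frozenset(leaves - below) if anchor in below else frozenset(below)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    block: AlignedBlock, n_reps: int, rng_seed: int
) -> dendropy.Tree:
    """NJ tree of the block with bootstrap support on internal edges.

    Each pseudoreplicate resamples ``n_cols`` columns with replacement and
    reruns p-distance + neighbor joining; the tree built on the original
    block is annotated with each internal edge's bipartition frequency as an
    integer percent (node ``label`` and ``support`` annotation).  Supports
    below :data:`SUPPORT_DISPLAY_THRESHOLD` carry a ``below_threshold``
    annotation, mirroring the convention of printing only supports found in
    at least half the replicates.  A replicate in which some pair has no
    comparable columns is redrawn (counted in the tree's ``n_redrawn``
    annotation and logged).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    base = neighbor_joining(p_distance(block))
    rng = np.random.default_rng(rng_seed)
    counts: dict[frozenset, int] = {}
    n_redrawn = 0
    for _ in range(n_reps):
        while True:
            cols = rng.integers(0, block.n_cols, size=block.n_cols)
            resampled = block.columns([int(c) for c in cols])
            try:
                dm = p_distance(resampled)
            except ValueError:
                n_redrawn += 1
                if n_redrawn > 1000 * n_reps:
                    raise RuntimeError(
                        "bootstrap resampling keeps producing incomparable pairs"
                    )
                continue
            break
        for split in _splits(neighbor_joining(dm)):
            counts[split] = counts.get(split, 0) + 1
    if n_redrawn:
        logger.info("bootstrap: redrew %d replicates with incomparable pairs", n_redrawn)

    leaves = {lf.taxon.label for lf in base.leaf_node_iter()}
    anchor = min(leaves)
    for node in base.preorder_node_iter():
        if node is base.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = frozenset(leaves - below) if anchor in below else frozenset(below)
        if not 2 <= len(side) <= len(leaves) - 2:
            continue
        support = int(round(100 * counts.get(side, 0) / n_reps))
        node.label = str(support)
        node.annotations["support"] = support
        node.annotations["below_threshold"] = support < SUPPORT_DISPLAY_THRESHOLD
    base.annotations["n_redrawn"] = n_redrawn
    return base


NON_MONOPHYLETIC_OUTGROUP = "NON_MONOPHYLETIC_OUTGROUP"


def root_on_outgroup(
    tree: dendropy.Tree, outgroup_taxa: Iterable[str]
) -> dendropy.Tree:
    """Root a tree on the edge subtending the outgroup.

    If the outgroup is monophyletic in the unrooted tree, the root splits the
    subtending edge's length equally.  Otherwise the root is placed on the
    edge above the smallest side containing every outgroup taxon and a
    ``NON_MONOPHYLETIC_OUTGROUP`` warning is recorded in the tree's
    annotations.
    """
    outgroup = set(outgroup_taxa)
    if not outgroup:
        raise ValueError("outgroup_taxa must be non-empty")
    tree = tree.clone(depth=1)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = outgroup - leaves
    if unknown:
        raise ValueError(f"unknown outgroup taxa: {sorted(unknown)}")
    if not leaves - outgroup:
        raise ValueError("outgroup covers every leaf; nothing to root against")

    # Each non-seed node's edge induces the split {below} | {rest}.
    best_node = None
    best_size = None
    warn = False
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        for side in (below, leaves - below):
            if outgroup <= side:
                if best_size is None or len(side) < best_size or (
                    len(side) == best_size
                    and best_node is not None
                    and sorted(side) < sorted(_side_of(best_node, tree, leaves, outgroup))
                ):
                    best_size = len(side)
                    best_node = node
    assert best_node is not None
    chosen_side = _side_of(best_node, tree, leaves, outgroup)
    if chosen_side != outgroup:
        warn = True

    edge = best_node.edge
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    if warn:
        tree.annotations["warnings"] = NON_MONOPHYLETIC_OUTGROUP
        logger.warning("outgroup not monophyletic; rooted above its smallest containing clade")
    return tree


def _side_of(node, tree, leaves, outgroup):
    below = {lf.taxon.label for lf in node.leaf_iter()}
    candidates = [s for s in (below, leaves - below) if outgroup <= s]
    return min(candidates, key=len)


def write_newick(tree: dendropy.Tree, stream: IO[str]) -> None:
    """Serialize a tree to Newick.

    Branch lengths print to six decimals; internal-node labels (bootstrap
    supports) are written verbatim; the string ends with ``;``.
    """

    def fmt(node: dendropy.Node) -> str:
        if node.is_leaf():
            s = node.taxon.label if node.taxon else (node.label or "")
        else:
            s = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")"
            s += node.label or ""
        if node is not tree.seed_node and node.edge.length is not None:
            s += f":{node.edge.length:.6f}"
        return s

    stream.write(fmt(tree.seed_node) + ";\n")


def read_newick(stream: IO[str] | str) -> dendropy.Tree:
    """Parse Newick, keeping internal-node labels as labels (not taxa)."""
    data = stream if isinstance(stream, str) else stream.read()
    return dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
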