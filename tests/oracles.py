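"""Independent brute-force oracles and fixture builders for the test suite.

Everything here is deliberately naive (position-by-position loops, explicit
path sums) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from crfkit.seq_io import AA20, AlignedBlock


def naive_pattern_matches(
    residues: str, positions, required_idx, max_mismatches: int
) -> list[tuple[int, int]]:
    """All (start, mismatches) windows matching a degenerate pattern."""
    L = len(positions)
    out = []
    for start in range(len(residues) - L + 1):
        mismatches = 0
        ok = True
        for p, allowed in enumerate(positions):
            if allowed is None:
                continue
            hit = residues[start + p] in allowed
            if p in required_idx:
                if not hit:
                    ok = False
                    break
            elif not hit:
                mismatches += 1
                if mismatches > max_mismatches:
                    ok = False
                    break
        if ok:
            out.append((start, mismatches))
    return out


def naive_profile_hits(residues: str, profile) -> list[tuple[int, float]]:
    """Window scores >= threshold with best-score/leftmost overlap pruning."""
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    L = profile.length
    scored = []
    for start in range(len(residues) - L + 1):
        total = 0.0
        for p in range(L):
            idx = aa_index.get(residues[start + p])
            if idx is not None:
                total += float(profile.scores[p, idx])
        if total >= profile.threshold:
            scored.append((start, total))
    kept: list[tuple[int, float]] = []
    for start, total in sorted(scored, key=lambda t: (-t[1], t[0])):
        if any(start < k + L and k < start + L for k, _ in kept):
            continue
        kept.append((start, total))
    return sorted(kept)


def random_binary_tree(rng: np.random.Generator, labels, blen_lo=0.05, blen_hi=2.0):
    """Random unrooted binary tree via random joins.

    Returns ``(splits, dist)`` where ``splits`` is the set of canonical
    non-trivial bipartitions (the side not containing the smallest label) and
    ``dist`` maps frozenset({a, b}) to the leaf-to-leaf path length.
    """
    labels = list(labels)
    # cluster state: list of (leaf_set, {leaf: distance to cluster root})
    clusters = [({lab}, {lab: 0.0}) for lab in labels]
    dist: dict[frozenset, float] = {}
    splits: list[set] = []
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (set_i, d_i) = clusters.pop(j)
        (set_j, d_j) = clusters.pop(i)
        li = float(rng.uniform(blen_lo, blen_hi))
        lj = float(rng.uniform(blen_lo, blen_hi))
        for a, da in d_i.items():
            for b, db in d_j.items():
                dist[frozenset((a, b))] = da + li + db + lj
        merged = set_i | set_j
        d = {a: da + li for a, da in d_i.items()}
        d.update({b: db + lj for b, db in d_j.items()})
        clusters.append((merged, d))
        splits.append(set(merged))
    (set_i, d_i), (set_j, d_j) = clusters
    bridge = float(rng.uniform(blen_lo, blen_hi))
    for a, da in d_i.items():
        for b, db in d_j.items():
            dist[frozenset((a, b))] = da + db + bridge
    all_leaves = set(labels)
    anchor = min(all_leaves)
    canonical = set()
    for s in splits:
        side = all_leaves - s if anchor in s else s
        if 2 <= len(side) <= len(all_leaves) - 2:
            canonical.add(frozenset(side))
    return canonical, dist


def tree_splits(tree) -> set[frozenset]:
    """Canonical non-trivial bipartitions of a dendropy tree."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = frozenset(leaves - below) if anchor in below else frozenset(below)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def patristic(tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths computed by explicit root-path sums."""
    paths = {}
    for lf in tree.leaf_node_iter():
        path = {}
        node, acc = lf, 0.0
        while node is not tree.seed_node:
            acc += node.edge.length or 0.0
            node = node.parent_node
            path[id(node)] = acc
        paths[lf.taxon.label] = path
    out = {}
    labels = sorted(paths)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            shared = [n for n in paths[a] if n in paths[b]]
            best = min(paths[a][n] + paths[b][n] for n in shared)
            out[frozenset((a, b))] = best
    return out


def edge_lengths_by_split(tree) -> dict[frozenset, float]:
    """Edge lengths keyed by the canonical bipartition each edge induces."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = frozenset(leaves - below) if anchor in below else frozenset(below)
        out[side] = out.get(side, 0.0) + (node.edge.length or 0.0)
    return out


def congruent_block(rng: np.random.Generator, n_copies: int = 20) -> tuple[AlignedBlock, set[frozenset]]:
    """Gap-free 8-taxon block whose every column supports one binary tree.

    The tree is a caterpillar on T1..T8; each internal edge gets ``n_copies``
    homoplasy-free marker columns (one residue on one side, another on the
    other), so any column resample that touches every marker class yields
    distances additive on the same topology.
    """
    taxa = [f"T{i}" for i in range(1, 9)]
    # caterpillar splits: {T1,T2}, {T1,T2,T3}, ..., {T1..T6}
    split_sides = [set(taxa[: k + 2]) for k in range(5)]
    columns = []
    for side in split_sides:
        for _ in range(n_copies):
            a, b = rng.choice(len(AA20), size=2, replace=False)
            columns.append({t: (AA20[a] if t in side else AA20[b]) for t in taxa})
    # pendant signal so every leaf has positive length variation
    for t in taxa:
        for _ in range(n_copies // 4):
            a, b = rng.choice(len(AA20), size=2, replace=False)
            columns.append({u: (AA20[a] if u == t else AA20[b]) for u in taxa})
    rows = tuple((t, "".join(col[t] for col in columns)) for t in taxa)
    anchor = min(taxa)
    canonical = {
        frozenset(set(taxa) - s if anchor in s else s) for s in split_sides
    }
    return AlignedBlock(rows), canonical
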