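"""Per-window neighbor-joining trees, topology classification, and
discordance-block calling.

Windows with at least ``min_segregating`` segregating sites get a D_A distance
matrix over the taxon groups, a Saitou-Nei neighbor-joining tree, and a
topology class determined by rooting on the outgroup and asking which two
ingroups are sisters:

* ``species_concordant`` — the two chromosomes of the same species cluster
  (``ingroup_B``, ``ingroup_C``; e.g. DperST with DperSR);
* ``discordant`` — the focal chromosome clusters across the species boundary
  (``ingroup_A``, ``ingroup_C``; e.g. DpseST with DperSR);
* ``other`` — the remaining quartet.

Bootstrap support resamples sites within the window; windows below the support
threshold stay in the output as ``unclassified`` so that block calling can
treat them as run breakers explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import divergence

log = logging.getLogger("ancinv")

CLASS_CONCORDANT = "species_concordant"
CLASS_DISCORDANT = "discordant"
CLASS_OTHER = "other"
CLASS_UNCLASSIFIED = "unclassified"
ROLE_NAMES = ("ingroup_A", "ingroup_B", "ingroup_C", "outgroup")


# ---------------------------------------------------------------------------
# distance matrices


def distance_matrix(table, groups, window, min_segregating=10):
    """Symmetric D_A matrix over ``groups`` for one window.

    Returns (matrix, n_segregating) or raises WindowSkipped when the window
    has fewer than ``min_segregating`` segregating sites.
    """
    mask = table.window_mask(*window)
    n_seg = int(divergence.segregating_mask(table, groups, mask).sum())
    if n_seg < min_segregating:
        raise WindowSkipped(
            f"window {window[0]}:{window[1]}-{window[2]} has {n_seg} < {min_segregating} segregating sites"
        )
    k = len(groups)
    D = np.zeros((k, k))
    freqs = [table.freqs(g)[mask] for g in groups]
    for i in range(k):
        for j in range(i + 1, k):
            usable = ~np.isnan(freqs[i]) & ~np.isnan(freqs[j])
            D[i, j] = D[j, i] = divergence.da_from_freqs(freqs[i][usable], freqs[j][usable])
    return D, n_seg


class WindowSkipped(ValueError):
    pass


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("children", "key", "leaves")

    def __init__(self, children=(), key=None, leaves=None):
        self.children = list(children)  # (child, branch_length)
        self.key = key
        self.leaves = leaves


def _leaf(label):
    return _Node(key=label, leaves=frozenset([label]))


def neighbor_joining(D, labels):
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of node keys, where a node's key is its smallest leaf label.
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch so pairwise path lengths are preserved.  Returns an
    unrooted tree as an ``NJTree``.
    """
    D = np.array(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 3:
        raise ValueError("distance matrix must be square with >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    nodes = [_leaf(l) for l in labels]
    D = D.copy()
    while len(nodes) > 3:
        n = len(nodes)
        R = D.sum(axis=1)
        Q = (n - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (tuple(sorted((nodes[i].key, nodes[j].key))), i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if Q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin))
        ]
        _, i, j = min(cands)
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj, D[i, j])
        new = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            key=min(nodes[i].key, nodes[j].key),
            leaves=nodes[i].leaves | nodes[j].leaves,
        )
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.column_stack([D, np.append(dnew[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [new]
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        b0 = max(0.0, 0.5 * (d01 + d02 - d12))
        b1 = max(0.0, 0.5 * (d01 + d12 - d02))
        b2 = max(0.0, 0.5 * (d02 + d12 - d01))
        root = _Node(
            children=[(nodes[0], b0), (nodes[1], b1), (nodes[2], b2)],
            key=min(nd.key for nd in nodes),
            leaves=nodes[0].leaves | nodes[1].leaves | nodes[2].leaves,
        )
    else:
        root = _Node(
            children=[(nodes[0], 0.5 * D[0, 1]), (nodes[1], 0.5 * D[0, 1])],
            key=min(nodes[0].key, nodes[1].key),
            leaves=nodes[0].leaves | nodes[1].leaves,
        )
    return NJTree(root)


def _clamp_pair(li, lj, total):
    if li < 0:
        return 0.0, max(total, 0.0)
    if lj < 0:
        return max(total, 0.0), 0.0
    return li, lj


@dataclass
class NJTree:
    root: _Node

    def newick(self):
        def render(node):
            if not node.children:
                return str(node.key)
            inner = ",".join(f"{render(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return render(self.root) + ";"

    @property
    def labels(self):
        return sorted(self.root.leaves)

    def bipartitions(self):
        """Non-trivial splits as frozensets of leaf labels (smaller side)."""
        out = set()
        all_leaves = self.root.leaves

        def walk(node):
            for child, _ in node.children:
                if child.children:
                    side = child.leaves
                    if 1 < len(side) < len(all_leaves) - 1:
                        other = all_leaves - side
                        out.add(min(frozenset(side), frozenset(other), key=lambda s: (len(s), sorted(s))))
                    walk(child)

        walk(self.root)
        return out

    def leaf_distances(self):
        """Pairwise path lengths between leaves, as a dict keyed by frozenset."""
        dists = {}

        def walk(node):
            # returns {leaf: distance to node}
            if not node.children:
                return {node.key: 0.0}
            below = []
            for child, bl in node.children:
                sub = walk(child)
                below.append({leaf: d + bl for leaf, d in sub.items()})
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for la, da in below[a].items():
                        for lb, db in below[b].items():
                            dists[frozenset((la, lb))] = da + db
            merged = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dists


# ---------------------------------------------------------------------------
# topology classification


def classify_topology(tree, roles):
    """Classify a 4-taxon tree after rooting on the outgroup.

    ``tree`` may be a newick string or an NJTree containing exactly the four
    role-bearing taxa.  ``roles`` maps role names (ingroup_A, ingroup_B,
    ingroup_C, outgroup) to taxon labels.
    """
    for r in ROLE_NAMES:
        if r not in roles:
            raise ValueError(f"missing role {r!r}")
    newick = tree.newick() if isinstance(tree, NJTree) else tree
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    expect = {roles[r] for r in ROLE_NAMES}
    if labels != expect:
        raise ValueError(f"tree taxa {sorted(labels)} != role taxa {sorted(expect)}")
    og = t.find_node_with_taxon_label(roles["outgroup"])
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    ingroups = {roles["ingroup_A"], roles["ingroup_B"], roles["ingroup_C"]}
    sisters = None
    for node in t.preorder_internal_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if len(leaves) == 2 and leaves <= ingroups:
            sisters = leaves
            break
    if sisters is None:
        raise ValueError("unresolved quartet: no ingroup cherry after outgroup rooting")
    return _class_from_sisters(sisters, roles)


def _class_from_sisters(sisters, roles):
    if sisters == {roles["ingroup_B"], roles["ingroup_C"]}:
        return CLASS_CONCORDANT
    if sisters == {roles["ingroup_A"], roles["ingroup_C"]}:
        return CLASS_DISCORDANT
    return CLASS_OTHER


def _classes_from_matrices(D, roles, order):
    """Vectorized 4-taxon NJ classification.

    ``D``: (n, 4, 4) distance matrices with taxa in ``order``.  The unrooted
    4-taxon topology is fixed by the first NJ cherry (minimum of the Q
    criterion); the sister pair after outgroup rooting is the ingroup pair on
    the side of the internal edge away from the outgroup.
    """
    D = np.asarray(D, float)
    single = D.ndim == 2
    if single:
        D = D[None]
    R = D.sum(axis=2)
    Q = 2.0 * D - R[:, :, None] - R[:, None, :]
    iu = np.triu_indices(4, k=1)
    qpairs = Q[:, iu[0], iu[1]]  # (n, 6)
    choice = qpairs.argmin(axis=1)
    og = order.index(roles["outgroup"])
    classes = np.empty(len(D), dtype=object)
    for pidx in range(6):
        sel = choice == pidx
        if not sel.any():
            continue
        i, j = iu[0][pidx], iu[1][pidx]
        cherry = {order[i], order[j]}
        if roles["outgroup"] in cherry:
            sisters = {order[k] for k in range(4) if k not in (i, j)}
        else:
            sisters = cherry
        classes[sel] = _class_from_sisters(sisters, roles)
    return classes[0] if single else classes


# ---------------------------------------------------------------------------
# bootstrap support


def bootstrap_support(table, window, roles, n_reps=10_000, seed=0, min_segregating=10):
    """Fraction of site-bootstrap NJ replicates matching the point topology.

    Sites within the window are resampled with replacement; each replicate's
    D_A matrix is classified with the same NJ rule as the point estimate.
    Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = [roles[r] for r in ROLE_NAMES]
    D, _ = distance_matrix(table, order, window, min_segregating)
    point = _classes_from_matrices(D, roles, order)
    mask = table.window_mask(*window)
    F = np.column_stack([table.freqs(g)[mask] for g in order])
    F = F[~np.isnan(F).any(axis=1)]
    if len(F) == 0:
        raise ValueError("no sites usable across all four taxa")
    rng = np.random.default_rng(seed)
    classes = _bootstrap_classes(F, roles, order, n_reps, rng)
    return float(np.mean(classes == point)), point


def _bootstrap_classes(F, roles, order, n_reps, rng):
    n_sites = len(F)
    idx = rng.integers(0, n_sites, size=(n_reps, n_sites))
    iu = np.triu_indices(4, k=1)
    # per-site D_A terms for each of the 6 pairs
    terms = np.empty((n_sites, 6))
    for k, (i, j) in enumerate(zip(*iu)):
        terms[:, k] = 1.0 - (np.sqrt(F[:, i] * F[:, j]) + np.sqrt((1 - F[:, i]) * (1 - F[:, j])))
    boot = terms[idx].mean(axis=1)  # (n_reps, 6)
    D = np.zeros((n_reps, 4, 4))
    D[:, iu[0], iu[1]] = boot
    D[:, iu[1], iu[0]] = boot
    return _classes_from_matrices(D, roles, order)


# ---------------------------------------------------------------------------
# window scan and blocks


def tree_scan(
    table,
    roles,
    window_len=10_000,
    min_segregating=10,
    n_boot=10_000,
    support_threshold=0.75,
    seed=0,
):
    """Build, classify and bootstrap a tree for every window.

    Returns a DataFrame with one row per window: coordinates, class (or
    ``unclassified`` when support < threshold, ``skipped`` below the
    segregating-site rule), bootstrap support, segregating-site count and the
    point-estimate newick string.
    """
    order = [roles[r] for r in ROLE_NAMES]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, start, end in divergence.iter_windows(table, window_len):
        mask = table.window_mask(chrom, start, end)
        if not mask.any():
            continue
        win = (chrom, start, end)
        try:
            D, n_seg = distance_matrix(table, order, win, min_segregating)
        except WindowSkipped as exc:
            log.debug(str(exc))
            rows.append(
                dict(chrom=chrom, start=start, end=end, cls="skipped", support=np.nan,
                     n_segregating=int(mask.sum()), newick="")
            )
            continue
        tree = neighbor_joining(D, order)
        support, point = bootstrap_support(
            table, win, roles, n_reps=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
            min_segregating=min_segregating,
        )
        cls = point if support >= support_threshold else CLASS_UNCLASSIFIED
        rows.append(
            dict(chrom=chrom, start=start, end=end, cls=cls, support=support,
                 n_segregating=n_seg, newick=tree.newick())
        )
    return pd.DataFrame(rows)


@dataclass
class DiscordanceBlock:
    chrom: str
    start: int
    end: int
    n_windows: int
    cls: str


def call_blocks(window_trees, min_run=3):
    """Maximal runs of >= ``min_run`` consecutive windows sharing a class.

    Skipped and unclassified windows break runs.  Input must be sorted by
    coordinate (tree_scan output is).
    """
    blocks = []
    run = []
    valid = {CLASS_CONCORDANT, CLASS_DISCORDANT, CLASS_OTHER}

    def flush():
        if len(run) >= min_run:
            blocks.append(
                DiscordanceBlock(
                    chrom=run[0]["chrom"],
                    start=int(run[0]["start"]),
                    end=int(run[-1]["end"]),
                    n_windows=len(run),
                    cls=run[0]["cls"],
                )
            )
        run.clear()

    prev = None
    for row in window_trees.to_dict("records"):
        breaks = (
            row["cls"] not in valid
            or (prev is not None and (row["chrom"] != prev["chrom"] or row["cls"] != prev["cls"]))
        )
        if breaks:
            flush()
        if row["cls"] in valid:
            run.append(row)
        prev = row
    flush()
    return blocks


def blocks_to_frame(blocks):
    return pd.DataFrame([b.__dict__ for b in blocks], columns=["chrom", "start", "end", "n_windows", "cls"])
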