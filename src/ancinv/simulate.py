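"""Structured-coalescent simulator: the test bed with known truth.

Two generators are provided:

* per-locus pairwise difference counts under the Iso/IM/IIM histories that the
  likelihood module fits (a fast vectorized two-lineage chain in the same
  mutational-unit convention), and
* per-window four-taxon allele-frequency tables under species histories with
  an ancestrally segregating, recombination-suppressed "inversion" deme, via a
  general epoch-wise Gillespie coalescent plus infinite-sites mutations.

Inversion suppression is modeled as reduced lineage exchange between
arrangement demes — a per-window "gene flux" knob that is 1 away from the
breakpoints and 0 at them — rather than explicit recombination.  All
randomness flows from a single seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SiteTable, CORE_COLUMNS, group_columns

log = logging.getLogger("ancinv")


# ---------------------------------------------------------------------------
# demography


@dataclass
class Epoch:
    """One backwards-time epoch: ends at ``end`` (np.inf for the last), demes
    with relative sizes (pair coalescence rate k(k-1)/(2 size)), a backwards
    migration rate dict {(from_deme, to_deme): rate per lineage}, and a
    ``merge`` map applied on entry (lineages in key deme move to value deme)."""

    end: float
    sizes: dict
    mig: dict = field(default_factory=dict)
    merge: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.sizes.values()):
            raise ValueError("deme sizes must be > 0")
        for (a, b), rate in self.mig.items():
            if rate < 0 or a == b:
                raise ValueError("migration rates must be >= 0 with no self-moves")


@dataclass
class Demography:
    epochs: list

    def __post_init__(self):
        ends = [e.end for e in self.epochs]
        if any(e2 <= e1 for e1, e2 in zip(ends, ends[1:])):
            raise ValueError("epoch end times must strictly increase")
        if not np.isinf(ends[-1]):
            raise ValueError("last epoch must be infinite")
        last = self.epochs[-1]
        if len(last.sizes) > 1 and not last.mig:
            raise ValueError("final epoch must have one deme or a connecting migration matrix")


class Node:
    __slots__ = ("label", "time", "children", "deme")

    def __init__(self, label=None, time=0.0, children=(), deme=None):
        self.label = label
        self.time = time
        self.children = list(children)
        self.deme = deme

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n)
        return out

    def newick(self):
        def render(n, parent_time):
            if not n.children:
                return f"{n.label}:{parent_time - n.time:.8g}"
            inner = ",".join(render(c, n.time) for c in n.children)
            return f"({inner}):{parent_time - n.time:.8g}"

        inner = ",".join(render(c, self.time) for c in self.children)
        return f"({inner});"


def sample_gene_tree(demography, samples, rng):
    """Backwards structured-coalescent simulation to the MRCA.

    ``samples`` is a list of (label, deme) pairs.  Exponential waiting times
    for within-deme coalescence (rate k(k-1)/(2 size)) and per-lineage
    migration; epoch boundaries respected.
    """
    lineages = [Node(label=l, time=0.0, deme=d) for l, d in samples]
    if len(lineages) < 2:
        raise ValueError("need >= 2 lineages")
    t = 0.0
    ei = 0
    epochs = demography.epochs
    applied_merge = [False] * len(epochs)

    def apply_merge(i):
        if not applied_merge[i]:
            for ln in lineages:
                ln.deme = epochs[i].merge.get(ln.deme, ln.deme)
            applied_merge[i] = True

    apply_merge(0)
    while len(lineages) > 1:
        ep = epochs[ei]
        counts = {}
        for ln in lineages:
            if ln.deme not in ep.sizes:
                raise ValueError(f"lineage in unknown deme {ln.deme!r} for epoch {ei}")
            counts[ln.deme] = counts.get(ln.deme, 0) + 1
        coal_rates = {d: k * (k - 1) / (2.0 * ep.sizes[d]) for d, k in counts.items() if k >= 2}
        mig_rates = {
            (a, b): counts.get(a, 0) * rate for (a, b), rate in ep.mig.items() if counts.get(a, 0)
        }
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        if total == 0:
            if np.isinf(ep.end):
                raise RuntimeError("lineages stranded in a non-ergodic final epoch")
            t = ep.end
            ei += 1
            apply_merge(ei)
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= ep.end:
            t = ep.end
            ei += 1
            apply_merge(ei)
            continue
        t += dt
        u = rng.uniform(0, total)
        acc = 0.0
        event = None
        for d, rate in sorted(coal_rates.items()):
            acc += rate
            if u < acc:
                event = ("coal", d)
                break
        if event is None:
            for (a, b), rate in sorted(mig_rates.items()):
                acc += rate
                if u < acc:
                    event = ("mig", a, b)
                    break
        if event[0] == "coal":
            d = event[1]
            members = [i for i, ln in enumerate(lineages) if ln.deme == d]
            i, j = rng.choice(members, size=2, replace=False)
            parent = Node(time=t, children=[lineages[i], lineages[j]], deme=d)
            lineages = [ln for k, ln in enumerate(lineages) if k not in (i, j)] + [parent]
        else:
            _, a, b = event
            members = [i for i, ln in enumerate(lineages) if ln.deme == a]
            lineages[rng.choice(members)].deme = b
    return lineages[0]


def drop_mutations(root, rate, r=1.0, rng=None):
    """Infinite-sites Poisson mutations: returns a list of (frozenset of tip
    labels carrying the derived allele), one entry per mutation.  ``rate`` is
    the expected mutations per unit branch length at relative rate 1."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = rng or np.random.default_rng()
    patterns = []

    def walk(node):
        tips = []
        for child in node.children:
            sub = walk(child)
            blen = node.time - child.time
            n_mut = rng.poisson(rate * r * blen)
            for _ in range(n_mut):
                patterns.append(frozenset(sub))
            tips.extend(sub)
        return tips if node.children else [node.label]

    walk(root)
    return patterns


def pair_path_length(root, a, b):
    """Path length between tips labelled a and b: 2 * (t_mrca - tip time)."""
    times = pairwise_tmrca(root)
    return 2.0 * times[frozenset((a, b))]


def pairwise_tmrca(root):
    """TMRCA for every tip pair, keyed by frozenset of labels."""
    out = {}

    def walk(node):
        if not node.children:
            return [node.label]
        below = [walk(c) for c in node.children]
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a in below[i]:
                    for b in below[j]:
                        out[frozenset((a, b))] = node.time
        return [l for sub in below for l in sub]

    walk(root)
    return out


# ---------------------------------------------------------------------------
# per-locus pairwise difference datasets (vectorized)


def simulate_pair_times(params, cls, n, rng):
    """Coalescence times (mutational units) of ``n`` independent pairs under
    a ModelParams history, by an event-loop over the two-lineage chain.

    Independent of the likelihood module's matrix-exponential machinery: this
    is the simulation side of the cross-oracle.
    """
    from .iim import _START_STATE

    p = params
    state = np.full(n, _START_STATE[cls])
    times = np.full(n, np.nan)
    t = np.zeros(n)

    # isolation epoch [0, t1): only within states can coalesce
    if p.t1 > 0:
        for st, theta in ((0, p.theta1), (1, p.theta2)):
            sel = state == st
            if sel.any():
                e = rng.exponential(theta, size=int(sel.sum()))
                done = e < p.t1
                idx = np.flatnonzero(sel)
                times[idx[done]] = e[done]
        t[:] = p.t1

    # migration epoch [t1, t0)
    if p.t0 > p.t1:
        m1 = p.m1 / p.theta1
        m2 = p.m2 / p.theta1
        # per-state total rates and event tables
        tot = np.array([2 * m1 + 1.0 / p.theta1, 2 * m2 + 1.0 / p.theta2, m1 + m2])
        active = np.isnan(times)
        cur = np.full(n, p.t1)
        while active.any():
            idx = np.flatnonzero(active)
            st = state[idx]
            rates = tot[st]
            zero = rates == 0
            if zero.any():  # inert split state with no migration: jump to t0
                active[idx[zero]] = False
                idx, st, rates = idx[~zero], st[~zero], rates[~zero]
                if len(idx) == 0:
                    break
            dt = rng.exponential(1.0 / rates)
            tnew = cur[idx] + dt
            crossed = tnew >= p.t0
            active[idx[crossed]] = False
            idx, st, tnew = idx[~crossed], st[~crossed], tnew[~crossed]
            if len(idx) == 0:
                continue
            cur[idx] = tnew
            u = rng.uniform(size=len(idx)) * tot[st]
            # state 0: coalesce w.p. (1/theta1)/tot0 else -> split
            # state 1: coalesce w.p. (1/theta2)/tot1 else -> split
            # state 2: -> state 1 w.p. m1/tot2 else -> state 0
            for s_id, coal_rate in ((0, 1.0 / p.theta1), (1, 1.0 / p.theta2)):
                sel = st == s_id
                if sel.any():
                    coal = u[sel] < coal_rate
                    ii = idx[sel]
                    times[ii[coal]] = tnew[sel][coal]
                    active[ii[coal]] = False
                    state[ii[~coal]] = 2
            sel = st == 2
            if sel.any():
                to1 = u[sel] < m1  # lineage in pop1 jumps to pop2 -> both in 2
                ii = idx[sel]
                state[ii[to1]] = 1
                state[ii[~to1]] = 0

    # ancestral epoch
    remaining = np.isnan(times)
    times[remaining] = p.t0 + rng.exponential(p.theta_anc, size=int(remaining.sum()))
    return times


def make_locus_dataset(params, n_per_class, rate_dispersion=0.0, seed=0, locus_len=500):
    """Simulate a per-locus pairwise-difference table under ``params``.

    ``n_per_class`` is an int (same for all three classes) or a dict.  Locus
    relative rates are unit-mean gamma with the given squared coefficient of
    variation (0 means all 1).  Returns (loci DataFrame, truth DataFrame).
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in ("within_pop1", "within_pop2", "between")}
    loci, truth = [], []
    for cls in ("within_pop1", "within_pop2", "between"):
        n = int(n_per_class.get(cls, 0))
        if n == 0:
            continue
        if rate_dispersion > 0:
            shape = 1.0 / rate_dispersion
            r = rng.gamma(shape, scale=1.0 / shape, size=n)
            r = np.maximum(r, 1e-6)
        else:
            r = np.ones(n)
        t = simulate_pair_times(params, cls, n, rng)
        s = rng.poisson(r * t)
        for i in range(n):
            loci.append(
                {"id": f"{cls}_{i}", "cls": cls, "s": int(s[i]), "r": float(r[i]), "length": locus_len}
            )
            truth.append({"id": f"{cls}_{i}", "cls": cls, "coal_time": float(t[i])})
    return pd.DataFrame(loci), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# four-taxon window datasets


GROUPS = ("DpseST", "DperST", "DperSR", "outgroup")
DEFAULT_ROLES = {
    "ingroup_A": "DpseST",
    "ingroup_B": "DperST",
    "ingroup_C": "DperSR",
    "outgroup": "outgroup",
}


@dataclass
class InversionScenario:
    """Species history with an inversion segregating in the ancestral
    population.

    Times increase into the past: the species split at ``t0``, the inversion
    origin at ``t_inv > t0`` (it arose in the common ancestor), the outgroup
    split at ``t_out > t_inv``.  ``DperST`` carries the derived inversion;
    ``DperSR`` and ``DpseST`` carry the ancestral arrangement.  Per window,
    exchange between arrangement demes (and introgression between the species)
    is scaled by a suppression weight: 1 in collinear windows, 0 at
    breakpoints.
    """

    t0: float = 1.0
    t_inv: float = 3.0
    t_out: float = 8.0
    deme_size: float = 0.25
    species_mig: float = 1.0
    arrangement_mig: float = 12.0

    def __post_init__(self):
        if not (self.t_out > self.t_inv > self.t0 > 0):
            raise ValueError("require t_out > t_inv > t0 > 0")

    def demography(self, weight):
        """Epoch structure for one window at suppression weight in [0, 1]."""
        if not (0 <= weight <= 1):
            raise ValueError("weight must be in [0, 1]")
        sz = self.deme_size
        am = self.arrangement_mig * weight
        sm = self.species_mig * weight
        e1 = Epoch(
            end=self.t0,
            sizes={"pse": sz, "perST": sz, "perSR": sz, "out": sz},
            mig={
                ("perST", "perSR"): am,  # arrangement exchange within D. persimilis
                ("perSR", "perST"): am,
                ("pse", "perSR"): sm,  # post-split introgression between the species
                ("perSR", "pse"): sm,
                ("pse", "perST"): sm,
                ("perST", "pse"): sm,
            },
        )
        e2 = Epoch(
            end=self.t_inv,
            sizes={"std": sz, "inv": sz, "out": sz},
            mig={("std", "inv"): am, ("inv", "std"): am},
            merge={"pse": "std", "perSR": "std", "perST": "inv"},
        )
        e3 = Epoch(end=self.t_out, sizes={"anc": 1.0, "out": sz}, merge={"std": "anc", "inv": "anc"})
        e4 = Epoch(end=np.inf, sizes={"root": 1.0}, merge={"anc": "root", "out": "root"})
        return Demography([e1, e2, e3, e4])


def breakpoint_weight_profile(n_windows, breakpoint_windows):
    """Suppression weights: 0 for windows in ``breakpoint_windows``, else 1."""
    w = np.ones(n_windows)
    w[list(breakpoint_windows)] = 0.0
    return w


def _window_samples(n_per_group, groups=GROUPS):
    demes = {"DpseST": "pse", "DperST": "perST", "DperSR": "perSR", "outgroup": "out"}
    return [(f"{g}_{i}", demes[g]) for g in groups for i in range(n_per_group)]


def true_topology_class(tree, n_per_group, roles=DEFAULT_ROLES):
    """Topology class implied by the realized genealogy: the ingroup pair with
    the smallest mean between-group TMRCA is called sisters."""
    from .phylogeny import _class_from_sisters

    tm = pairwise_tmrca(tree)
    ing = [roles["ingroup_A"], roles["ingroup_B"], roles["ingroup_C"]]
    means = {}
    for i in range(3):
        for j in range(i + 1, 3):
            vals = [
                tm[frozenset((f"{ing[i]}_{a}", f"{ing[j]}_{b}"))]
                for a in range(n_per_group)
                for b in range(n_per_group)
            ]
            means[(ing[i], ing[j])] = np.mean(vals)
    sisters = set(min(means, key=means.get))
    return _class_from_sisters(sisters, roles)


def make_window_dataset(
    scenario,
    n_windows,
    breakpoint_windows=(),
    window_len=10_000,
    n_per_group=4,
    mut_rate=3.0,
    seed=0,
    chrom="XR",
):
    """Per-window four-taxon allele frequencies plus a truth record.

    One gene tree per window with exchange between arrangement demes scaled by
    the window's suppression weight; infinite-sites mutations at ``mut_rate``
    expected mutations per unit branch length are converted to per-group
    allele counts at uniform-random window positions.  Returns (SiteTable,
    truth DataFrame with weight, true class, and pair TMRCA summaries).
    """
    rng = np.random.default_rng(seed)
    weights = breakpoint_weight_profile(n_windows, breakpoint_windows)
    samples = _window_samples(n_per_group)
    group_of = {lbl: lbl.rsplit("_", 1)[0] for lbl, _ in samples}
    n_group = {g: n_per_group for g in GROUPS}
    rows, truth = [], []
    for w in range(n_windows):
        dem = scenario.demography(weights[w])
        tree = sample_gene_tree(dem, samples, rng)
        patterns = drop_mutations(tree, mut_rate, rng=rng)
        k = min(len(patterns), window_len)
        positions = rng.choice(window_len, size=min(k, window_len), replace=False)
        positions = np.sort(positions) + w * window_len + 1  # 1-based
        for pat, pos in zip(patterns, positions):
            rec = {"chrom": chrom, "pos": int(pos), "ref": "A", "alt": "T"}
            for g in GROUPS:
                alt = sum(1 for lbl in pat if group_of[lbl] == g)
                rec[f"{g}_ref"] = n_group[g] - alt
                rec[f"{g}_alt"] = alt
                rec[f"{g}_dp"] = n_group[g]
                rec[f"{g}_gq"] = 99
            rows.append(rec)
        tm = pairwise_tmrca(tree)

        def mean_tmrca(g1, g2):
            return float(
                np.mean(
                    [
                        tm[frozenset((f"{g1}_{a}", f"{g2}_{b}"))]
                        for a in range(n_per_group)
                        for b in range(n_per_group)
                    ]
                )
            )

        truth.append(
            {
                "window": w,
                "chrom": chrom,
                "start": w * window_len,
                "end": (w + 1) * window_len,
                "weight": weights[w],
                "true_class": true_topology_class(tree, n_per_group),
                "tmrca_pse_perSR": mean_tmrca("DpseST", "DperSR"),
                "tmrca_pse_perST": mean_tmrca("DpseST", "DperST"),
                "tmrca_perST_perSR": mean_tmrca("DperST", "DperSR"),
                "n_sites": k,
            }
        )
    df = pd.DataFrame(rows, columns=CORE_COLUMNS + group_columns(list(GROUPS)))
    table = SiteTable(df, list(GROUPS), {"source": "simulated", "seed": seed})
    return table, pd.DataFrame(truth)


def random_additive_matrix(n_taxa, rng):
    """Random binary tree with U(0.1, 2) branch lengths, returned as its
    additive leaf-pair distance matrix plus the set of non-trivial splits.

    Built by sequential random joins with explicit path bookkeeping — no
    tree-reconstruction code involved — so it serves as an independent oracle
    for distance-based tree builders.  Returns (labels, matrix, splits) where
    splits are canonical frozensets (smaller side of each bipartition).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = {l: ({l}, {l: 0.0}) for l in labels}  # leafset, distance-to-leaf maps
    splits = set()
    active = list(labels)
    dist = {}
    while len(active) > 2:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        (la, da), (lb, db) = nodes[a], nodes[b]
        ba, bb = rng.uniform(0.1, 2.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + ba + dy + bb
        new_leaves = la | lb
        name = f"n{len(nodes)}"
        nodes[name] = (
            new_leaves,
            {**{x: d + ba for x, d in da.items()}, **{y: d + bb for y, d in db.items()}},
        )
        if 1 < len(new_leaves) < n_taxa - 1:
            splits.add(frozenset(new_leaves))
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [name]
    (la, da), (lb, db) = nodes[active[0]], nodes[active[1]]
    blen = rng.uniform(0.1, 2.0)
    for x, dx in da.items():
        for y, dy in db.items():
            dist[frozenset((x, y))] = dx + dy + blen
    D = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                D[i, j] = dist[frozenset((x, y))]
    canon = {
        min(frozenset(s), frozenset(set(labels) - s), key=lambda q: (len(q), sorted(q)))
        for s in splits
    }
    return labels, D, canon


def ils_window_classes(delta_t, n_windows, split_time=0.2, mut_rate=60.0, seed=0, roles=DEFAULT_ROLES):
    """Inferred topology classes for windows under a clean species tree.

    Species tree ((DperST, DperSR), DpseST, outgroup) with internal branch
    ``delta_t`` (coalescent units, deme size 1) between the two splits and one
    lineage per taxon.  Classification runs the same D_A + neighbor-joining
    rule as the window scan, on per-pair mutation-count distances (for 0/1
    frequencies D_A reduces to the normalized Hamming distance).  The fraction
    of non-concordant windows follows the lineage-sorting law (2/3)e^(-delta_t).
    """
    from .phylogeny import _classes_from_matrices

    rng = np.random.default_rng(seed)
    t_join = split_time + delta_t
    t_out = t_join + 7.0
    epochs = [Epoch(end=split_time, sizes={"A": 1.0, "B": 1.0, "C": 1.0, "O": 1.0})]
    if delta_t > 0:
        epochs.append(Epoch(end=t_join, sizes={"A": 1.0, "B": 1.0, "O": 1.0}, merge={"C": "B"}))
        merge3 = {"B": "A"}
    else:
        merge3 = {"B": "A", "C": "A"}
    epochs.append(Epoch(end=t_out, sizes={"A": 1.0, "O": 1.0}, merge=merge3))
    epochs.append(Epoch(end=np.inf, sizes={"root": 1.0}, merge={"A": "root", "O": "root"}))
    dem = Demography(epochs)
    labels = [roles["ingroup_A"], roles["ingroup_B"], roles["ingroup_C"], roles["outgroup"]]
    samples = list(zip(labels, ["A", "B", "C", "O"]))
    order = labels
    D = np.zeros((n_windows, 4, 4))
    for w in range(n_windows):
        tree = sample_gene_tree(dem, samples, rng)
        patterns = drop_mutations(tree, mut_rate, rng=rng)
        n_sites = max(len(patterns), 1)
        for i in range(4):
            for j in range(i + 1, 4):
                diff = sum(1 for pat in patterns if (order[i] in pat) != (order[j] in pat))
                D[w, i, j] = D[w, j, i] = diff / n_sites
    return _classes_from_matrices(D, roles, order)
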