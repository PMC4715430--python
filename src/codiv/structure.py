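"""Hierarchical AMOVA, NJ trees, the genealogical sorting index, and Mantel IBD.

The AMOVA decomposes squared pairwise genetic distances into among-region,
among-locale-within-region and within-locale components with the standard
unequal-sample-size coefficients, and tests each Phi statistic with its own
permutation scheme: individuals among locales (Phi_ST), individuals among
locales within regions (Phi_SC), and whole locales among regions (Phi_CT).
Distances can be supplied at the haplotype level together with a per-individual
haplotype index, which keeps heavily dereplicated OTUs cheap.

Trees are neighbor-joining on K2P distances by default (externally produced
newick genealogies are accepted anywhere a tree is needed); the GSI is a
topology-only statistic normalised so that 1 means the focal group is
monophyletic and 0 means its tips are maximally dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats as sps

from .errors import ValidationError

# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    ssd_among_regions: float
    ssd_among_locales_within_regions: float
    ssd_within_locales: float
    df_among_regions: int
    df_among_locales: int
    df_within: int
    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float | None
    p_ct: float | None
    p_sc: float | None
    p_st: float | None
    n_permutations: int


def _amova_ssd(
    sq: np.ndarray, unit_idx: np.ndarray, loc_idx: np.ndarray, reg_of_loc: np.ndarray,
    n_loc: int, n_reg: int,
) -> tuple[float, float, float, np.ndarray]:
    """SSD decomposition from the haplotype squared-distance matrix.

    ``unit_idx`` maps individuals to rows of ``sq``; group sums of squared
    distances are quadratic forms in per-group haplotype count vectors.
    """
    n_hap = sq.shape[0]
    counts = np.zeros((n_loc, n_hap))
    np.add.at(counts, (loc_idx, unit_idx), 1.0)
    sizes = counts.sum(axis=1)
    total_counts = counts.sum(axis=0)
    N = sizes.sum()

    q_tot = total_counts @ sq @ total_counts
    ssd_total = q_tot / (2.0 * N)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_loc = np.einsum("ph,hk,pk->p", counts, sq, counts)
        ssd_wp = float(np.sum(np.where(sizes > 0, q_loc / (2.0 * sizes), 0.0)))
    ssd_regions_total = 0.0
    for g in range(n_reg):
        cg = counts[reg_of_loc == g].sum(axis=0)
        ng = cg.sum()
        if ng > 0:
            ssd_regions_total += (cg @ sq @ cg) / (2.0 * ng)
    ssd_ap = ssd_regions_total - ssd_wp
    ssd_ag = ssd_total - ssd_ap - ssd_wp
    return float(ssd_ag), float(ssd_ap), float(ssd_wp), sizes


def _amova_components(
    sq: np.ndarray, unit_idx: np.ndarray, loc_idx: np.ndarray, reg_of_loc: np.ndarray,
    n_loc: int, n_reg: int,
) -> tuple[float, float, float, float, float, float]:
    """(ssd_ag, ssd_ap, ssd_wp, sigma2_a, sigma2_b, sigma2_c)."""
    ssd_ag, ssd_ap, ssd_wp, sizes = _amova_ssd(
        sq, unit_idx, loc_idx, reg_of_loc, n_loc, n_reg
    )
    present = sizes > 0
    P = int(present.sum())
    G = int(len(np.unique(reg_of_loc[present])))
    N = float(sizes.sum())
    region_sizes = np.array(
        [sizes[reg_of_loc == g].sum() for g in range(n_reg)], dtype=float
    )
    region_sizes = region_sizes[region_sizes > 0]
    sum_np2 = float(np.sum(sizes**2))
    sum_np2_by_region = 0.0
    for g in range(n_reg):
        mask = (reg_of_loc == g) & present
        if mask.any():
            sum_np2_by_region += float(np.sum(sizes[mask] ** 2) / sizes[mask].sum())
    n_prime = (N - sum_np2_by_region) / (P - G) if P > G else np.nan
    n_dprime = (sum_np2_by_region - sum_np2 / N) / (G - 1) if G > 1 else np.nan
    n_tprime = (N - float(np.sum(region_sizes**2)) / N) / (G - 1) if G > 1 else np.nan

    ms_wp = ssd_wp / (N - P) if N > P else 0.0
    sigma2_c = ms_wp
    ms_ap = ssd_ap / (P - G) if P > G else 0.0
    sigma2_b = (ms_ap - sigma2_c) / n_prime if P > G else 0.0
    ms_ag = ssd_ag / (G - 1) if G > 1 else 0.0
    sigma2_a = (ms_ag - sigma2_c - n_dprime * sigma2_b) / n_tprime if G > 1 else 0.0
    return ssd_ag, ssd_ap, ssd_wp, sigma2_a, sigma2_b, sigma2_c


def _phis(sa: float, sb: float, sc: float) -> tuple[float | None, float | None, float | None]:
    tot = sa + sb + sc
    phi_ct = sa / tot if tot > 0 else None
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else None
    phi_st = (sa + sb) / tot if tot > 0 else None
    return phi_ct, phi_sc, phi_st


def amova(
    dist: np.ndarray,
    locales: np.ndarray,
    region_of: dict[str, str],
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    hap_idx: np.ndarray | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA with three permutation schemes.

    ``dist`` holds raw (unsquared) distances among units; ``hap_idx`` maps each
    individual to a unit row (default: one individual per row).  ``locales``
    labels individuals and ``region_of`` maps locale -> region.
    """
    dist = np.asarray(dist, dtype=float)
    sq = dist**2
    locales = np.asarray(locales)
    if hap_idx is None:
        hap_idx = np.arange(len(locales))
        if dist.shape[0] != len(locales):
            raise ValidationError("dist rows must match individuals when hap_idx absent")
    hap_idx = np.asarray(hap_idx)
    loc_names, loc_idx = np.unique(locales, return_inverse=True)
    sizes = np.bincount(loc_idx, minlength=len(loc_names))
    if np.any(sizes == 0):
        raise ValidationError("empty locale after subsetting")
    if len(loc_names) < 2:
        raise ValidationError("amova requires >= 2 locales")
    reg_names = sorted(set(region_of[l] for l in loc_names))
    reg_of_loc = np.array([reg_names.index(region_of[l]) for l in loc_names])
    n_loc, n_reg = len(loc_names), len(reg_names)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ssd_ag, ssd_ap, ssd_wp, sa, sb, sc = _amova_components(
        sq, hap_idx, loc_idx, reg_of_loc, n_loc, n_reg
    )
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)
    N, P, G = len(locales), n_loc, n_reg

    def perm_phis(perm_loc_idx: np.ndarray, perm_reg_of_loc: np.ndarray):
        comp = _amova_components(
            sq, hap_idx, perm_loc_idx, perm_reg_of_loc, n_loc, n_reg
        )
        return _phis(*comp[3:])

    c_st = c_sc = c_ct = 0
    n_st = n_sc = n_ct = 0
    work = loc_idx.copy()
    for _ in range(B):
        # Phi_ST: individuals among locales ignoring regions
        if phi_st is not None:
            rng.shuffle(work)
            p = perm_phis(work, reg_of_loc)[2]
            if p is not None:
                n_st += 1
                if p >= phi_st:
                    c_st += 1
        # Phi_SC: individuals among locales within their region
        if phi_sc is not None:
            within = loc_idx.copy()
            for g in range(n_reg):
                mask = np.isin(loc_idx, np.nonzero(reg_of_loc == g)[0])
                vals = within[mask]
                rng.shuffle(vals)
                within[mask] = vals
            p = perm_phis(within, reg_of_loc)[1]
            if p is not None:
                n_sc += 1
                if p >= phi_sc:
                    c_sc += 1
        # Phi_CT: whole locales among regions (preserving region locale counts)
        if phi_ct is not None:
            perm_regions = reg_of_loc.copy()
            rng.shuffle(perm_regions)
            p = perm_phis(loc_idx, perm_regions)[0]
            if p is not None:
                n_ct += 1
                if p >= phi_ct:
                    c_ct += 1

    def pval(count: int, total: int, obs) -> float | None:
        if obs is None or total == 0:
            return None
        return (1 + count) / (total + 1)

    return AmovaResult(
        ssd_among_regions=ssd_ag,
        ssd_among_locales_within_regions=ssd_ap,
        ssd_within_locales=ssd_wp,
        df_among_regions=G - 1,
        df_among_locales=P - G,
        df_within=N - P,
        sigma2_a=sa,
        sigma2_b=sb,
        sigma2_c=sc,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_ct=pval(c_ct, n_ct, phi_ct),
        p_sc=pval(c_sc, n_sc, phi_sc),
        p_st=pval(c_st, n_st, phi_st),
        n_permutations=B,
    )


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(ids: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    Q-criterion joins; ties resolved by the smallest (i, j) index pair in the
    current matrix; negative branch lengths are clamped to zero with the
    deficit moved to the sister branch.  The final three clusters are attached
    to an unresolved root (the conventional unrooted NJ output); callers that
    need a rooted tree midpoint-root it.
    """
    dist = np.asarray(dist, dtype=float)
    m = len(ids)
    if m < 3:
        raise ValidationError("nj_tree requires >= 3 tips")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in ids:
        taxon = dendropy.Taxon(label=label)
        tns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    D = dist.copy()
    active = list(range(m))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        Q[np.tril_indices(k)] = np.inf
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: smallest (i, j)
        ai, aj = active[i], active[j]
        dij = D[ai, aj]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (ai, aj):
                continue
            D[new_idx, a] = D[a, new_idx] = (D[ai, a] + D[aj, a] - dij) / 2.0
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    root = dendropy.Node()
    if len(active) == 3:
        ai, aj, ak = active
        la = (D[ai, aj] + D[ai, ak] - D[aj, ak]) / 2.0
        lb = (D[ai, aj] + D[aj, ak] - D[ai, ak]) / 2.0
        lc = (D[ai, ak] + D[aj, ak] - D[ai, aj]) / 2.0
        for node, length in zip((nodes[ai], nodes[aj], nodes[ak]), (la, lb, lc)):
            root.add_child(node)
            node.edge.length = max(length, 0.0)
    else:  # two clusters remain (even tip count path)
        ai, aj = active
        for node in (nodes[ai], nodes[aj]):
            root.add_child(node)
            node.edge.length = D[ai, aj] / 2.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def expand_tips(tree: dendropy.Tree, copies: dict[str, list[str]]) -> dendropy.Tree:
    """Replace each tip with a zero-length binary caterpillar of its copies.

    Used to expand a haplotype tree into an individual-level genealogy; the
    GSI is topology-only, so zero branch lengths are harmless.
    """
    tree = tree.clone(depth=1)
    for leaf in list(tree.leaf_node_iter()):
        labels = copies.get(leaf.taxon.label)
        if labels is None or len(labels) == 1:
            if labels is not None:
                leaf.taxon.label = labels[0]
            continue
        node = leaf
        node.taxon = None
        remaining = list(labels)
        while len(remaining) > 2:
            tip_label = remaining.pop()
            tip = dendropy.Node(taxon=dendropy.Taxon(label=tip_label))
            tip.edge.length = 0.0
            inner = dendropy.Node()
            inner.edge.length = 0.0
            node.add_child(tip)
            node.add_child(inner)
            node = inner
        for tip_label in remaining:
            tip = dendropy.Node(taxon=dendropy.Taxon(label=tip_label))
            tip.edge.length = 0.0
            node.add_child(tip)
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# genealogical sorting index


@dataclass
class GsiResult:
    group: str
    gs_observed: float | None
    gsi: float | None
    p_value: float | None
    n_permutations: int
    missing_reason: str | None = None


class _TreeIndex:
    """Static arrays for O(n) GSI evaluation and label permutation."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.index = {id(node): i for i, node in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1, dtype=np.int64)
        self.is_leaf = np.zeros(len(nodes), dtype=bool)
        self.degree = np.zeros(len(nodes), dtype=np.int64)
        self.labels: list[str | None] = [None] * len(nodes)
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = self.index[id(node.parent_node)]
                self.degree[i] += 1
            children = node.child_nodes()
            self.degree[i] += len(children)
            if not children:
                self.is_leaf[i] = True
                self.labels[i] = node.taxon.label if node.taxon else None
        self.postorder = np.arange(len(nodes))  # postorder_node_iter order
        self.leaf_indices = {
            label: i for i, label in enumerate(self.labels) if label is not None
        }
        internal = ~self.is_leaf
        self.sum_all = int(np.sum(self.degree[internal] - 2))

    def gs(self, group_leaves: np.ndarray) -> float:
        """gs = k / sum over the minimal connecting subtree of (degree - 2)."""
        n_nodes = len(self.parent)
        cnt = np.zeros(n_nodes, dtype=np.int64)
        cnt[group_leaves] = 1
        k = len(group_leaves)
        parent = self.parent
        for i in range(n_nodes):  # postorder: children precede parents
            p = parent[i]
            if p >= 0:
                cnt[p] += cnt[i]
        full_child = np.zeros(n_nodes, dtype=bool)
        hits = np.nonzero(cnt == k)[0]
        for i in hits:
            if parent[i] >= 0:
                full_child[parent[i]] = True
        internal = ~self.is_leaf
        in_u = internal & (cnt >= 1) & ~((cnt == k) & full_child)
        denom = int(np.sum(self.degree[in_u] - 2))
        if denom == 0:
            return np.inf
        return k / denom


def gsi_test(
    tree: dendropy.Tree,
    group_of: dict[str, str],
    group: str,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> GsiResult:
    """Genealogical sorting index of ``group`` on a rooted tree.

    gsi = (gs - gs_min) / (gs_max - gs_min) with gs_max the monophyly value
    and gs_min the value when the group's minimal connecting subtree spans
    every internal node; significance permutes group labels over tips
    preserving the group size.
    """
    idx = _TreeIndex(tree)
    tips = [label for label in idx.leaf_indices if label in group_of]
    group_tips = [t for t in tips if group_of[t] == group]
    k = len(group_tips)
    if k < 2:
        raise ValidationError(f"group {group!r} needs >= 2 tips")
    missing = set(group_of) - set(idx.leaf_indices)
    if missing:
        raise ValidationError(f"tips absent from tree: {sorted(missing)[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gs_min = k / idx.sum_all if idx.sum_all > 0 else np.inf
    gs_max = k / (k - 1)
    if not np.isfinite(gs_min) or gs_max <= gs_min:
        return GsiResult(group, None, None, None, B, "degenerate tree (gs_max == gs_min)")

    leaf_arr = np.array([idx.leaf_indices[t] for t in tips])
    obs_leaves = np.array([idx.leaf_indices[t] for t in group_tips])

    def gsi_of(leaves: np.ndarray) -> float:
        gs = idx.gs(leaves)
        val = (gs - gs_min) / (gs_max - gs_min)
        return float(min(max(val, 0.0), 1.0))

    observed = gsi_of(obs_leaves)
    count = 0
    for _ in range(B):
        perm = rng.choice(leaf_arr, size=k, replace=False)
        if gsi_of(perm) >= observed:
            count += 1
    p = (1 + count) / (B + 1)
    return GsiResult(group, idx.gs(obs_leaves), observed, p, B)


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def mantel_test(
    gen: np.ndarray,
    geo: np.ndarray,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """One-tailed Mantel test of genetic vs geographic distances.

    Pearson correlation of the upper triangles; the null jointly permutes the
    rows/columns of one matrix.  One-tailed because isolation by distance
    predicts a positive correlation.
    """
    gen = np.asarray(gen, dtype=float)
    geo = np.asarray(geo, dtype=float)
    k = gen.shape[0]
    if gen.shape != geo.shape or gen.shape != (k, k):
        raise ValidationError("matrices must be square and matching")
    if k < 3:
        raise ValidationError("Mantel test undefined for fewer than 3 locales")
    iu = np.triu_indices(k, 1)
    x, y = gen[iu], geo[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate (constant) distance matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs = float(sps.pearsonr(x, y).statistic)
    count = 0
    for _ in range(B):
        perm = rng.permutation(k)
        xp = gen[np.ix_(perm, perm)][iu]
        if float(sps.pearsonr(xp, y).statistic) >= r_obs:
            count += 1
    return MantelResult(r_obs, (1 + count) / (B + 1), B)
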