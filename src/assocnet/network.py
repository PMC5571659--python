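"""Trait-locus association networks, Inter-LD, key nodes, allele stacking.

The link strength between two SALs is the normalized between-locus LD

    Inter-LD = 1/2 * ( LD(S1, S2) / PmaxLD(S1) + LD(S1, S2) / PmaxLD(S2) )

where LD(S1, S2) is the mean pairwise r2 between all member SNPs of the two
loci, and PmaxLD(S) is the maximum over member SNPs of that SNP's mean r2 to
all member SNPs of S (self pairs included).  SALs from different traits that
overlap are merged into one node, which is how pleiotropic loci surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .genotypes import GenotypeMatrix, GenotypeError, pairwise_r2
from .sal import Sal, sal_overlap

__all__ = [
    "InterLdEdge",
    "StackingCurve",
    "pmax_ld",
    "inter_ld",
    "build_network",
    "key_nodes",
    "allele_stacking",
    "write_graphml",
    "write_sif",
]


@dataclass(frozen=True)
class InterLdEdge:
    sal_a: Sal
    sal_b: Sal
    cross_ld: float
    pmax_a: float
    pmax_b: float
    inter_ld: float


@dataclass
class StackingCurve:
    """Mean trait value by favorable-allele count."""

    table: pd.DataFrame  # columns: k, n_accessions, mean, sd
    slope: float
    slope_se: float
    slope_p: float
    n_used: int


def pmax_ld(sal: Sal, G: GenotypeMatrix, include_self: bool = True) -> float:
    """Maximum over member SNPs of the mean r2 of that SNP to all members."""
    if not sal.members:
        raise GenotypeError("SAL has no members")
    R = pairwise_r2(G, sal.members)
    if not include_self:
        np.fill_diagonal(R, np.nan)
        means = np.nanmean(R, axis=1) if R.shape[0] > 1 else np.ones(1)
    else:
        means = R.mean(axis=1)
    return float(means.max())


def _cross_ld(members_a, members_b, G) -> float:
    from .genotypes import _r2_vectors

    va = [G.dosage(v) for v in members_a]
    vb = [G.dosage(v) for v in members_b]
    vals = [_r2_vectors(x, y) for x in va for y in vb]
    return float(np.mean(vals))


def inter_ld(a: Sal, b: Sal, G: GenotypeMatrix, include_self: bool = True) -> InterLdEdge:
    if not a.members or not b.members:
        raise GenotypeError("SALs must be non-empty")
    cross = _cross_ld(a.members, b.members, G)
    pa = pmax_ld(a, G, include_self=include_self)
    pb = pmax_ld(b, G, include_self=include_self)
    value = 0.5 * (cross / pa + cross / pb)
    return InterLdEdge(a, b, cross, pa, pb, value)


def _merge_overlapping(sals, G):
    """Union-find merge of SALs that satisfy sal_overlap, across traits."""
    parent = list(range(len(sals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sals)):
        for j in range(i + 1, len(sals)):
            if sal_overlap(sals[i], sals[j], G):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(sals)):
        groups.setdefault(find(i), []).append(sals[i])
    return list(groups.values())


def build_network(sals, G: GenotypeMatrix, edge_min: float = 0.4,
                  use_raw_cross_ld: bool = False) -> nx.Graph:
    """Trait-locus network: trait nodes, merged SAL nodes, Inter-LD edges.

    SAL-SAL edges are kept iff Inter-LD >= ``edge_min`` (or, behind the flag,
    raw cross-locus mean r2 >= ``edge_min``).  The node score of a SAL is the
    lowest P value among its merged constituents.
    """
    sals = sorted(sals, key=lambda s: (s.chrom, s.start, s.trait))
    net = nx.Graph()
    merged = _merge_overlapping(sals, G)
    merged.sort(key=lambda grp: (grp[0].chrom, grp[0].start))
    nodes = []
    for grp in merged:
        best = min(grp, key=lambda s: s.min_p)
        name = f"SAL_{best.peak}"
        member_union = sorted(
            {v for s in grp for v in s.members}, key=lambda v: G.variant_index(v)
        )
        traits = sorted({s.trait for s in grp})
        net.add_node(name, kind="sal", score=float(best.min_p), peak=best.peak,
                     chrom=best.chrom, members=member_union, traits=traits)
        for t in traits:
            if t not in net:
                net.add_node(t, kind="trait")
            net.add_edge(t, name, kind="membership")
        nodes.append((name, member_union))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            (na, ma), (nb, mb) = nodes[i], nodes[j]
            cross = _cross_ld(ma, mb, G)
            if use_raw_cross_ld:
                w = cross
            else:
                pa = _pmax_members(ma, G)
                pb = _pmax_members(mb, G)
                w = 0.5 * (cross / pa + cross / pb)
            if w >= edge_min:
                net.add_edge(na, nb, kind="inter_ld", inter_ld=float(w), cross_ld=float(cross))
    return net


def _pmax_members(members, G) -> float:
    R = pairwise_r2(G, members)
    return float(R.mean(axis=1).max())


def key_nodes(net: nx.Graph, min_traits: int = 2) -> list:
    """SAL nodes linked to >= ``min_traits`` traits directly or through their
    own SAL-SAL edges, ranked by trait count then by association score."""
    out = []
    for node, data in net.nodes(data=True):
        if data.get("kind") != "sal":
            continue
        traits = {v for v in net.neighbors(node) if net.nodes[v].get("kind") == "trait"}
        for v in net.neighbors(node):
            if net.nodes[v].get("kind") == "sal":
                traits |= {
                    t for t in net.neighbors(v) if net.nodes[t].get("kind") == "trait"
                }
        if len(traits) >= min_traits:
            out.append((node, len(traits), data.get("score", 1.0)))
    out.sort(key=lambda x: (-x[1], x[2], x[0]))
    return [name for name, _, _ in out]


def allele_stacking(G: GenotypeMatrix, loci, y) -> StackingCurve:
    """Mean trait value against the number of stacked favorable homozygous loci.

    ``loci`` is a list of (variant_id, favorable) pairs with favorable in
    {"alt", "ref"}.  Accessions missing a call at any stacked locus are
    excluded; the favorable count at one locus is 1 iff the accession is
    homozygous for the favorable allele.
    """
    if not loci:
        raise GenotypeError("empty stacked-locus list")
    y = np.asarray(y, dtype=float)
    counts = np.zeros(G.n_accessions)
    ok = np.ones(G.n_accessions, dtype=bool)
    for vid, fav in loci:
        g = G.dosage(vid)
        ok &= ~np.isnan(g)
        target = 2.0 if fav == "alt" else 0.0
        counts += (g == target).astype(float)
    counts, yv = counts[ok], y[ok]
    rows = []
    for k in range(len(loci) + 1):
        sel = counts == k
        vals = yv[sel]
        rows.append(
            {
                "k": k,
                "n_accessions": int(sel.sum()),
                "mean": float(vals.mean()) if sel.any() else np.nan,
                "sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
            }
        )
    if np.unique(counts).size > 1:
        res = stats.linregress(counts, yv)
        slope, se, pval = float(res.slope), float(res.stderr), float(res.pvalue)
    else:
        slope, se, pval = np.nan, np.nan, np.nan
    return StackingCurve(pd.DataFrame(rows), slope, se, pval, int(ok.sum()))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    for _, data in g.nodes(data=True):
        for key in ("members", "traits"):
            if key in data:
                data[key] = ",".join(data[key])
    nx.write_graphml(g, path)


def write_sif(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in net.edges(data=True):
            fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\n")
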