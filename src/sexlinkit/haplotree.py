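"""MSR haplotype extraction, p-distances, neighbor-joining and haplogroups.

Because males are hemizygous across the male-specific region, each male's
calls over MSR sites define a single haplotype directly, without phasing.
Pairwise p-distances (base differences per jointly-called polymorphic site)
feed a Saitou-Nei neighbor-joining tree; the deepest internal edge splits the
haplotypes into two haplogroups, and outgroup alleles at informative sites
decide which haplogroup carries the ancestral state.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_qc import MISSING, VariantTable

__all__ = [
    "HaplotypeMatrix",
    "TreeNode",
    "HaplogroupPartition",
    "extract_haplotypes",
    "p_distance_matrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "split_haplogroups",
    "ancestral_assignment",
]

NO_CALL = "N"


@dataclass
class HaplotypeMatrix:
    """Per-male allele vectors over MSR sites ('N' marks a missing call)."""

    males: list[str]
    sites: list[int]  # 1-based positions on the sdY contig
    alleles: np.ndarray  # (n_males, n_sites) of single-character strings

    def __post_init__(self) -> None:
        if self.alleles.shape != (len(self.males), len(self.sites)):
            raise ValueError("allele matrix shape does not match males x sites")

    def called(self) -> np.ndarray:
        return self.alleles != NO_CALL

    def resample_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            males=list(self.males),
            sites=[self.sites[i] for i in idx],
            alleles=self.alleles[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alleles, index=self.males, columns=self.sites)


def extract_haplotypes(
    table: VariantTable,
    males: Sequence[str],
    site_call_min: float = 0.75,
    max_male_missing: float = 0.50,
) -> HaplotypeMatrix:
    """Build hemizygous haplotypes from male genotypes at MSR sites.

    Hom-ref calls yield the reference base, hom-alt the alternate base.  A
    heterozygous call violates the hemizygosity contract: it is flagged with
    a warning and set missing.  Sites called in fewer than ``site_call_min``
    of males are dropped first; males missing more than ``max_male_missing``
    of the surviving sites are then dropped.
    """
    sub = table.subset_samples(list(males))
    gt = sub.gt
    het = gt == 1
    if het.any():
        warnings.warn(
            f"{int(het.sum())} heterozygous MSR calls set missing (hemizygosity contract)",
            stacklevel=2,
        )
    ref = sub.sites["ref"].to_numpy(str)
    alt = sub.sites["alt"].to_numpy(str)
    alleles = np.full(gt.shape, NO_CALL, dtype="<U1")
    alleles[gt == 0] = np.broadcast_to(ref[:, None], gt.shape)[gt == 0]
    alleles[gt == 2] = np.broadcast_to(alt[:, None], gt.shape)[gt == 2]
    alleles = alleles.T  # males x sites

    called = alleles != NO_CALL
    site_keep = called.mean(axis=0) >= site_call_min
    if not site_keep.any():
        raise ValueError("all sites dropped by the call-rate filter")
    alleles = alleles[:, site_keep]
    sites = [int(p) for p in sub.sites.loc[site_keep, "pos"]]
    male_missing = (alleles == NO_CALL).mean(axis=1)
    male_keep = male_missing <= max_male_missing
    return HaplotypeMatrix(
        males=[m for m, k in zip(males, male_keep) if k],
        sites=sites,
        alleles=alleles[male_keep],
    )


def p_distance_matrix(hm: HaplotypeMatrix) -> pd.DataFrame:
    """Pairwise p-distance: differing / jointly-called sites (pairwise deletion).

    Entries with zero jointly-called sites are NaN and flagged with a warning.
    """
    if len(hm.males) < 2:
        raise ValueError("need at least two males")
    called = hm.called()
    n = len(hm.males)
    d = np.zeros((n, n))
    undefined = 0
    for i, j in itertools.combinations(range(n), 2):
        both = called[i] & called[j]
        m = int(both.sum())
        if m == 0:
            d[i, j] = d[j, i] = np.nan
            undefined += 1
            continue
        diff = int((hm.alleles[i, both] != hm.alleles[j, both]).sum())
        d[i, j] = d[j, i] = diff / m
    if undefined:
        warnings.warn(f"{undefined} pairs share no called sites (distance undefined)", stacklevel=2)
    return pd.DataFrame(d, index=hm.males, columns=hm.males)


# ----------------------------------------------------------------------
@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary internal root."""

    name: str = ""
    length: float = 0.0  # branch to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.6g}"

        return fmt(self, True) + ";"


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties fall to the lowest (row, column) index pair in the input
    order.  Negative branch lengths are clamped to zero.  Requires a
    symmetric, zero-diagonal matrix with at least three taxa and no
    undefined entries.
    """
    d = dist.to_numpy(dtype=float, copy=True)
    labels = list(dist.index)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")
    if len(labels) < 3:
        raise ValueError("need at least three taxa")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")

    nodes: list[TreeNode] = [TreeNode(name=str(lab)) for lab in labels]
    active = list(range(len(labels)))
    D = d.copy()

    while len(active) > 2:
        n = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]

        # grow matrix with the new node's distances
        new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active  # j is the most recently created internal node
    nodes[i].length = max(D[i, j], 0.0)
    root = nodes[j]
    root.children.append(nodes[i])
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset[str], float]:
    """Non-trivial splits of the unrooted tree, mapped to their edge length.

    Each internal edge is represented by the canonical (lexicographically
    smaller) side of the leaf bipartition it induces.
    """
    all_leaves = frozenset(tree.leaves())

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        return min(side, other, key=lambda s: (len(s), sorted(s)))

    out: dict[frozenset[str], float] = {}

    def walk(node: TreeNode) -> frozenset[str]:
        below = frozenset(node.leaves())
        for c in node.children:
            walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            key = canon(below)
            out[key] = max(out.get(key, 0.0), node.length)
        return below

    for c in tree.children:
        walk(c)
    return out


def bootstrap_support(
    hm: HaplotypeMatrix,
    tree: TreeNode | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Site-resampling bootstrap supports (%) for the full-data tree's splits.

    Resamples sites with replacement, rebuilds distances and the NJ tree per
    replicate, and reports for each internal bipartition of the reference
    tree the percentage of replicates containing it.  Also annotates the
    reference tree in place.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(hm.sites) < 2:
        warnings.warn("bootstrap over a single site is degenerate", stacklevel=2)
    if tree is None:
        tree = nj_tree(p_distance_matrix(hm))
    ref_splits = bipartitions(tree)
    counts = {split: 0 for split in ref_splits}
    rng = np.random.default_rng(seed)
    n_sites = len(hm.sites)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = hm.resample_sites(idx)
        dmat = p_distance_matrix(rep)
        if np.isnan(dmat.to_numpy()).any():
            continue
        rep_splits = bipartitions(nj_tree(dmat))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}

    all_leaves = frozenset(tree.leaves())

    def annotate(node: TreeNode) -> None:
        for c in node.children:
            annotate(c)
        below = frozenset(node.leaves())
        if 1 < len(below) < len(all_leaves) - 1:
            key = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            if key in supports:
                node.support = supports[key]

    for c in tree.children:
        annotate(c)
    return supports


# ----------------------------------------------------------------------
@dataclass
class HaplogroupPartition:
    group1: frozenset[str]
    group2: frozenset[str]
    within1: float
    within2: float
    between: float

    def __post_init__(self) -> None:
        if self.group1 & self.group2 or not self.group1 or not self.group2:
            raise ValueError("haplogroups must be disjoint and non-empty")

    def group_of(self, male: str) -> int:
        return 1 if male in self.group1 else 2


def _mean_pairwise(dist: pd.DataFrame, a: Sequence[str], b: Sequence[str]) -> float:
    vals = dist.loc[list(a), list(b)].to_numpy(float)
    if list(a) == list(b):
        iu = np.triu_indices(len(a), k=1)
        vals = vals[iu]
    return float(np.nanmean(vals)) if vals.size else float("nan")


def split_haplogroups(tree: TreeNode, dist: pd.DataFrame) -> HaplogroupPartition:
    """Partition leaves by removing the longest internal edge of the tree.

    Within- and between-group values are mean pairwise p-distances from
    ``dist`` (pairwise deletion).  A two-leaf tree splits into singletons; a
    star tree (no internal edge) is an error.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least two leaves")
    if len(leaves) == 2:
        g1, g2 = frozenset([leaves[0]]), frozenset([leaves[1]])
        return HaplogroupPartition(g1, g2, 0.0, 0.0, float(dist.loc[leaves[0], leaves[1]]))
    splits = bipartitions(tree)
    if not splits:
        raise ValueError("star tree: no internal edge to cut")
    side = max(splits, key=lambda s: (splits[s], sorted(s)))
    g1 = frozenset(side)
    g2 = frozenset(leaves) - g1
    return HaplogroupPartition(
        g1,
        g2,
        _mean_pairwise(dist, sorted(g1), sorted(g1)) if len(g1) > 1 else 0.0,
        _mean_pairwise(dist, sorted(g2), sorted(g2)) if len(g2) > 1 else 0.0,
        _mean_pairwise(dist, sorted(g1), sorted(g2)),
    )


def ancestral_assignment(
    partition: HaplogroupPartition,
    hm: HaplotypeMatrix,
    outgroup_alleles: Mapping[int, str],
) -> tuple[int | None, pd.DataFrame]:
    """Decide which haplogroup carries the ancestral state from outgroup alleles.

    A site is informative when both haplogroups are fixed (unanimous among
    called alleles) for different bases and an outgroup allele is available.
    The ancestral haplogroup is the one matching the outgroup at a strict
    majority of informative sites (1 or 2); a tie or no informative sites
    returns None.  Outgroup positions absent from the matrix are ignored.
    """
    frame = hm.to_frame()
    rows = []
    votes = {1: 0, 2: 0}
    g1 = [m for m in hm.males if m in partition.group1]
    g2 = [m for m in hm.males if m in partition.group2]
    for pos, allele in sorted(outgroup_alleles.items()):
        if pos not in frame.columns:
            continue
        col = frame[pos]

        def fixed_allele(members: Sequence[str]) -> str | None:
            called = [col[m] for m in members if col[m] != NO_CALL]
            if not called or len(set(called)) != 1:
                return None
            return called[0]

        a1, a2 = fixed_allele(g1), fixed_allele(g2)
        informative = a1 is not None and a2 is not None and a1 != a2
        match = None
        if informative:
            if allele == a1:
                match = 1
            elif allele == a2:
                match = 2
            if match is not None:
                votes[match] += 1
        rows.append(
            {
                "pos": pos,
                "outgroup": allele,
                "hg1_allele": a1 or NO_CALL,
                "hg2_allele": a2 or NO_CALL,
                "informative": informative,
                "matches": match,
            }
        )
    report = pd.DataFrame(rows, columns=["pos", "outgroup", "hg1_allele", "hg2_allele", "informative", "matches"])
    if votes[1] == votes[2]:
        return None, report
    return (1 if votes[1] > votes[2] else 2), report
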