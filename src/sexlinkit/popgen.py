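"""Population diversity and divergence statistics.

Windowed nucleotide diversity (pi), reference-allele-frequency correlation,
per-site Weir & Cockerham (1984) F_ST with a neighbor-joining dendrogram of
pairwise means, composite LD on genotype dosages, greedy LD pruning, and a
classical-MDS "PCA of genetic distance".
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .haplotree import TreeNode, nj_tree
from .variant_qc import MISSING, VariantTable

__all__ = [
    "MonomorphicSiteError",
    "windowed_pi",
    "allele_frequencies",
    "reference_allele_freq",
    "raf_correlation",
    "wc_fst",
    "fst_dendrogram",
    "ld_r2",
    "ld_prune",
    "pca_distance",
]


class MonomorphicSiteError(ValueError):
    """LD is undefined for a site with no variation among compared samples."""


# ----------------------------------------------------------------------
def _pop_arrays(table: VariantTable, samples: Sequence[str]) -> np.ndarray:
    idx = [table.samples.index(s) for s in samples]
    return table.gt[:, idx]


def windowed_pi(
    table: VariantTable,
    pop_samples: Sequence[str],
    window_bp: int = 20_000,
    step_bp: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per base pair.

    Per-site diversity is ``c (n - c) / (n (n - 1) / 2)`` with ``c`` the alt
    allele count among ``n`` called alleles; a window's value is the sum over
    its variants divided by the full window length (monomorphic and missing
    positions contribute zero).  Windows of ``window_bp`` advance by
    ``step_bp`` along each chromosome.
    """
    if step_bp > window_bp:
        raise ValueError("step must not exceed window size")
    if not len(pop_samples):
        raise ValueError("empty population")
    gt = _pop_arrays(table, pop_samples)
    called = gt != MISSING
    n = 2 * called.sum(axis=1)
    c = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(n >= 2, c * (n - c) / np.maximum(n * (n - 1) / 2.0, 1e-300), 0.0)

    lengths = chrom_lengths or table.contig_lengths
    rows = []
    for chrom, sub in table.sites.groupby("chrom", sort=True, observed=True):
        pos = sub["pos"].to_numpy()
        vals = pi_site[sub.index.to_numpy()]
        length = lengths.get(chrom, int(pos.max()) if len(pos) else window_bp)
        start = 1
        while start <= max(length - window_bp + 1, 1):
            end = start + window_bp - 1
            in_win = (pos >= start) & (pos <= end)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "value": float(vals[in_win].sum() / window_bp),
                    "n_variants": int(in_win.sum()),
                }
            )
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_variants"])


# ----------------------------------------------------------------------
def allele_frequencies(table: VariantTable, samples: Sequence[str]) -> pd.Series:
    """Alternate-allele frequency per site among called genotypes."""
    gt = _pop_arrays(table, samples)
    called = gt != MISSING
    n = 2 * called.sum(axis=1)
    c = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n > 0, c / np.maximum(n, 1), np.nan)
    return pd.Series(freq, index=pd.MultiIndex.from_frame(table.sites[["chrom", "pos"]]))


def reference_allele_freq(table: VariantTable, samples: Sequence[str]) -> pd.Series:
    """Frequency of the reference-assembly allele per site."""
    return 1.0 - allele_frequencies(table, samples)


def raf_correlation(
    raf_a: pd.Series, raf_b: pd.Series, n_bins: int = 20
) -> tuple[np.ndarray, float, float]:
    """Compare reference-allele frequencies between two populations.

    Returns the 2-D bin-count matrix over shared sites, the squared Pearson
    correlation r^2 of the per-SNP RAF pairs, and the raw Pearson r.
    """
    shared = raf_a.index.intersection(raf_b.index)
    a = raf_a.loc[shared].to_numpy(float)
    b = raf_b.loc[shared].to_numpy(float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no shared sites with defined frequencies")
    hist, _, _ = np.histogram2d(a, b, bins=n_bins, range=[[0, 1], [0, 1]])
    r = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else np.nan
    return hist, float(r**2), r


# ----------------------------------------------------------------------
def wc_fst(
    table: VariantTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    method: str = "average",
) -> tuple[pd.Series, float, float]:
    """Weir & Cockerham (1984) two-population theta-hat per site.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed from sample sizes,
    allele frequencies and observed heterozygosities; theta = a / (a + b + c).
    Sites need >= 2 called diploids in each population and a defined
    denominator to contribute.  ``method='average'`` returns the unweighted
    mean of per-site estimates (with its sample standard error);
    ``method='ratio'`` returns the ratio-of-sums estimate.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least two samples")
    r = 2.0
    comps = []
    for samples in (pop_a, pop_b):
        gt = _pop_arrays(table, samples)
        called = gt != MISSING
        n_i = called.sum(axis=1).astype(float)  # diploid count
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, gt, 0).sum(axis=1) / np.maximum(2 * n_i, 1)
            h_i = (gt == 1).sum(axis=1) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    usable = (n1 >= 2) & (n2 >= 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(usable & (np.abs(denom) > 1e-300), a / denom, np.nan)

    idx = pd.MultiIndex.from_frame(table.sites[["chrom", "pos"]])
    per_site = pd.Series(theta, index=idx, name="theta")
    defined = per_site.dropna()
    if len(defined) == 0:
        raise ValueError("no site has a defined F_ST estimate")
    if method == "average":
        mean = float(defined.mean())
        se = float(defined.std(ddof=1) / np.sqrt(len(defined))) if len(defined) > 1 else np.nan
    elif method == "ratio":
        ok = usable & np.isfinite(denom) & (np.abs(denom) > 1e-300)
        mean = float(a[ok].sum() / denom[ok].sum())
        se = np.nan
    else:
        raise ValueError("method must be 'average' or 'ratio'")
    return per_site, mean, se


def fst_dendrogram(fst_matrix: pd.DataFrame) -> TreeNode:
    """Neighbor-joining dendrogram from a pairwise mean-F_ST distance matrix."""
    m = fst_matrix.to_numpy(float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("F_ST matrix must be square and symmetric")
    if (m < 0).any():
        raise ValueError("F_ST distances must be non-negative")
    if m.shape[0] < 3:
        raise ValueError("need at least three populations")
    return nj_tree(fst_matrix)


# ----------------------------------------------------------------------
def ld_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of 0/1/2 dosage vectors.

    NaNs are handled by pairwise-complete deletion.  A site monomorphic among
    the compared samples makes r^2 undefined and raises
    :class:`MonomorphicSiteError`.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need at least two pairwise-complete samples")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise MonomorphicSiteError("r^2 undefined for a monomorphic site")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r^2 between all rows of x and all rows of y (NaNs mean-imputed)."""

    def prep(m):
        m = m.astype(float)
        mu = np.nanmean(m, axis=1, keepdims=True)
        m = np.where(np.isnan(m), mu, m) - mu
        norm = np.sqrt((m**2).sum(axis=1, keepdims=True))
        return m / np.where(norm == 0, np.nan, norm)

    return (prep(x) @ prep(y).T) ** 2


def ld_prune(
    dosage: pd.DataFrame,
    window_snps: int = 500,
    step_snps: int = 5,
    r2_max: float = 0.3,
) -> list[int]:
    """Greedy sliding-window LD pruning over genomically ordered sites.

    Within each window, while any kept pair exceeds ``r2_max`` the later site
    of the currently worst pair is removed; windows advance by ``step_snps``.
    Returns positional indices (into the row order) of the kept sites.
    """
    if window_snps < 2:
        raise ValueError("window must span at least two SNPs")
    values = dosage.to_numpy(float)
    n = values.shape[0]
    kept = np.ones(n, dtype=bool)
    start = 0
    while start < n:
        idx = np.arange(start, min(start + window_snps, n))
        idx = idx[kept[idx]]
        if len(idx) > 1:
            r2 = _pairwise_r2(values[idx], values[idx])
            np.fill_diagonal(r2, 0.0)
            r2 = np.nan_to_num(r2)
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                drop = max(i, j)  # remove the later site of the worst pair
                kept[idx[drop]] = False
                r2[drop, :] = 0.0
                r2[:, drop] = 0.0
        if start + window_snps >= n:
            break
        start += step_snps
    return [int(i) for i in np.flatnonzero(kept)]


# ----------------------------------------------------------------------
def pca_distance(
    dosage: pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of the pairwise allele-sharing distance between samples.

    The distance between samples i and j is the mean over pairwise-complete
    sites of |dosage_i - dosage_j| / 2.  Double-centering of -D^2/2 followed
    by eigendecomposition yields the coordinates; variance fractions are each
    positive eigenvalue over their sum.  Columns of ``dosage`` are samples.
    """
    samples = list(dosage.columns)
    if len(samples) < 3:
        raise ValueError("need at least three samples")
    m = dosage.to_numpy(float).T  # samples x sites
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(m[i] - m[i + 1 :]) / 2.0
        D[i, i + 1 :] = np.nanmean(diff, axis=1)
    D = D + D.T
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    total = vals[pos].sum()
    k = min(n_components, int(pos.sum()))
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    frame = pd.DataFrame(
        coords, index=samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    var_frac = vals[:k] / total if total > 0 else np.zeros(k)
    return frame, var_frac
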