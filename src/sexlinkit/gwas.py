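"""Case-control GWAS for genotypic sex, with QC, pedigree checks and intervals.

Genotypic sex (GSEX) is assigned from three sdY presence/absence assays; the
binary trait is regressed on SNP dosage (ordinary least squares, matching a
case-control allelic association), and per-chromosome critical intervals are
delineated from the top 0.5% of associated SNPs, gated on a genome-wide
Bonferroni-significant peak.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CriticalInterval",
    "assign_gsex",
    "qc_genotype_matrix",
    "grm_vanraden1",
    "additive_relationship",
    "pedigree_check",
    "assoc_linear",
    "critical_intervals",
]

MAX_NEG_LOG10_P = 320.0  # beyond float64 underflow; reported as a capped score


def assign_gsex(assay_calls: Sequence[bool]) -> str:
    """Sex from three sdY assays: all positive -> male, all negative -> female.

    Mixed signals are uninterpretable and yield 'missing'.
    """
    calls = list(assay_calls)
    if len(calls) != 3:
        raise ValueError("expected exactly three sdY assay calls")
    if all(calls):
        return "male"
    if not any(calls):
        return "female"
    return "missing"


# ----------------------------------------------------------------------
def qc_genotype_matrix(
    geno: pd.DataFrame,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    max_sample_missing: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample and SNP quality control on a sites x samples dosage matrix.

    Order of operations: samples with more than ``max_sample_missing``
    missingness are dropped, then SNPs with call rate below ``min_call_rate``,
    then SNPs with minor allele frequency below ``min_maf``.
    """
    log: dict[str, int] = {}
    sample_missing = geno.isna().mean(axis=0)
    bad_samples = sample_missing > max_sample_missing
    log["samples_removed"] = int(bad_samples.sum())
    geno = geno.loc[:, ~bad_samples]

    call_rate = geno.notna().mean(axis=1)
    keep = call_rate >= min_call_rate
    log["low_call_rate_snps"] = int((~keep).sum())
    geno = geno.loc[keep]

    freq = geno.mean(axis=1, skipna=True) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= min_maf
    log["low_maf_snps"] = int((~keep).sum())
    geno = geno.loc[keep]
    if geno.empty or geno.shape[1] == 0:
        raise ValueError("quality control removed everything")
    return geno, log


# ----------------------------------------------------------------------
def grm_vanraden1(geno: pd.DataFrame) -> pd.DataFrame:
    """Genomic relationship matrix, VanRaden method 1.

    Missing dosages are mean-imputed per SNP and allele frequencies are taken
    from the data: Z = M - 2p and G = Z'Z / (2 sum p_k (1 - p_k)), where rows
    of ``geno`` are SNPs and columns samples.
    """
    m = geno.to_numpy(float)
    p = np.nanmean(m, axis=1) / 2.0
    m = np.where(np.isnan(m), (2 * p)[:, None], m)
    z = m - (2 * p)[:, None]
    denom = 2.0 * float(np.sum(p * (1 - p)))
    if denom <= 0:
        raise ValueError("all sites monomorphic: GRM denominator is zero")
    g = z.T @ z / denom
    return pd.DataFrame(g, index=geno.columns, columns=geno.columns)


def additive_relationship(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Numerator relationship matrix A by the tabular method.

    ``pedigree`` columns: animal, sire, dam (unknown parents as '0', '', NaN
    or None).  Animals are processed parents-first; A_ij for j with parents
    (s, d) is (A_is + A_id)/2 and A_jj = 1 + A_sd/2.
    """
    ped = pedigree[["animal", "sire", "dam"]].astype(object).copy()

    def norm(v):
        return None if v in (0, "0", "", None) or (isinstance(v, float) and math.isnan(v)) else str(v)

    ped["sire"] = ped["sire"].map(norm)
    ped["dam"] = ped["dam"].map(norm)
    ped["animal"] = ped["animal"].astype(str)
    known = set(ped["animal"])
    for col in ("sire", "dam"):
        stray = set(p for p in ped[col] if p is not None) - known
        if stray:
            raise ValueError(f"parents absent from pedigree: {sorted(stray)[:3]}")

    # topological order: parents before offspring
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str) -> None:
        if state.get(a) == 2:
            return
        if state.get(a) == 1:
            raise ValueError("pedigree contains a cycle")
        state[a] = 1
        for p in parents[a]:
            if p is not None:
                visit(p)
        state[a] = 2
        order.append(a)

    for a in parents:
        visit(a)

    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = parents[a]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        A[i, i] = 1.0 + (A[si, di] / 2.0 if si is not None and di is not None else 0.0)
        for b in order:
            j = idx[b]
            if j >= i:
                continue
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    out = pd.DataFrame(A, index=order, columns=order)
    original = [str(a) for a in pedigree["animal"]]
    return out.loc[original, original]


def pedigree_check(
    pedigree: pd.DataFrame,
    G: pd.DataFrame,
    diff_threshold: float = 0.25,
    min_flags: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Flag animals whose genomic and pedigree relationships disagree.

    A pair (i != j) is inconsistent when |A_ij - G_ij| > ``diff_threshold``;
    an animal is flagged when it participates in at least ``min_flags``
    inconsistent pairs.  Diagonals are never compared.
    """
    animals = [str(a) for a in G.index]
    missing = set(animals) - set(str(a) for a in pedigree["animal"])
    if missing:
        raise ValueError(f"animals in G absent from pedigree: {sorted(missing)[:3]}")
    A = additive_relationship(pedigree).loc[animals, animals].to_numpy()
    Gm = G.loc[animals, animals].to_numpy(float)
    diff = np.abs(A - Gm)
    np.fill_diagonal(diff, 0.0)
    bad = diff > diff_threshold
    counts = bad.sum(axis=1)
    flagged = [a for a, c in zip(animals, counts) if c >= min_flags]
    iu = np.triu_indices(len(animals), k=1)
    pairs = pd.DataFrame(
        {
            "a": np.asarray(animals)[iu[0]],
            "b": np.asarray(animals)[iu[1]],
            "A": A[iu],
            "G": Gm[iu],
            "inconsistent": bad[iu],
        }
    )
    return flagged, pairs


# ----------------------------------------------------------------------
def assoc_linear(
    geno: pd.DataFrame,
    phenotype: pd.Series,
    logistic: bool = False,
) -> pd.DataFrame:
    """Per-SNP association of a binary trait with allele dosage.

    Ordinary least squares of the 0/1 phenotype on dosage with an intercept;
    the p-value comes from the slope's t statistic with per-SNP
    pairwise-complete samples.  Monomorphic SNPs are omitted.  Bonferroni and
    Benjamini-Hochberg adjusted p-values are reported alongside.  With
    ``logistic=True`` a per-SNP logistic regression (Wald test) is used
    instead.
    """
    samples = [s for s in geno.columns if s in phenotype.index]
    if len(samples) < 3:
        raise ValueError("need at least three phenotyped samples")
    y_all = phenotype.loc[samples].to_numpy(float)
    if not set(np.unique(y_all[~np.isnan(y_all)])) <= {0.0, 1.0}:
        raise ValueError("phenotype must be coded 0/1")
    x_all = geno[samples].to_numpy(float)

    rows = []
    if logistic:
        import statsmodels.api as sm

        for k in range(x_all.shape[0]):
            x = x_all[k]
            ok = ~(np.isnan(x) | np.isnan(y_all))
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                continue
            X = sm.add_constant(x[ok])
            try:
                fit = sm.Logit(y_all[ok], X).fit(disp=0, maxiter=100)
                beta, p = float(fit.params[1]), float(fit.pvalues[1])
            except Exception:
                continue
            rows.append((k, beta, p, int(ok.sum())))
    else:
        ok = ~np.isnan(x_all) & ~np.isnan(y_all)[None, :]
        n = ok.sum(axis=1).astype(float)
        x = np.where(ok, x_all, 0.0)
        y = np.where(ok, y_all[None, :], 0.0)
        sx, sy = x.sum(axis=1), y.sum(axis=1)
        sxx, sxy, syy = (x * x).sum(axis=1), (x * y).sum(axis=1), (y * y).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Sxx = sxx - sx**2 / n
            Sxy = sxy - sx * sy / n
            Syy = syy - sy**2 / n
            beta = Sxy / Sxx
            rss = np.maximum(Syy - beta * Sxy, 0.0)
            df = n - 2
            se = np.sqrt(rss / np.maximum(df, 1) / Sxx)
            t = beta / se
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        usable = (n >= 3) & (Sxx > 0)
        p = np.where(p <= 0, np.nextafter(0, 1), p)  # cap at the float floor
        for k in np.flatnonzero(usable):
            rows.append((int(k), float(beta[k]), float(p[k]), int(n[k])))

    if not rows:
        raise ValueError("no testable SNPs")
    k_idx = [r[0] for r in rows]
    sites = geno.index[k_idx]
    out = pd.DataFrame(
        {
            "chrom": [sites[i][0] for i in range(len(k_idx))],
            "pos": [int(sites[i][1]) for i in range(len(k_idx))],
            "beta": [r[1] for r in rows],
            "p": [r[2] for r in rows],
            "n_used": [r[3] for r in rows],
        }
    )
    out["neg_log10_p"] = np.minimum(-np.log10(out["p"]), MAX_NEG_LOG10_P)
    out["p_bonf"] = np.minimum(out["p"] * len(out), 1.0)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
@dataclass
class CriticalInterval:
    """Chromosome-specific span of the most strongly associated SNPs."""

    chrom: str
    start: int
    stop: int
    peak: int
    threshold: float
    n_snps: int

    def __post_init__(self) -> None:
        if not (self.start <= self.peak <= self.stop):
            raise ValueError("peak must lie inside the interval")
        if self.n_snps < 1:
            raise ValueError("interval must contain at least one SNP")


def critical_intervals(
    results: pd.DataFrame,
    top_frac: float = 0.005,
    genomewide_alpha: float = 0.05,
) -> list[CriticalInterval]:
    """Critical intervals from chromosome-specific top-0.5% thresholds.

    Per chromosome the threshold is the p-value of the ceil(top_frac * n)-th
    best SNP and the interval spans the passing SNPs (min to max position,
    peak at the best SNP).  A chromosome is reported only when its peak
    survives a genome-wide Bonferroni correction at ``genomewide_alpha``.
    """
    if results.empty:
        raise ValueError("no association results")
    n_total = len(results)
    bonf = genomewide_alpha / n_total
    out: list[CriticalInterval] = []
    for chrom, sub in results.groupby("chrom", sort=True, observed=True):
        n_top = math.ceil(top_frac * len(sub))
        threshold = float(np.sort(sub["p"].to_numpy())[n_top - 1])
        passing = sub[sub["p"] <= threshold]
        peak_row = sub.loc[sub["p"].idxmin()]
        if float(peak_row["p"]) > bonf:
            continue
        out.append(
            CriticalInterval(
                chrom=str(chrom),
                start=int(passing["pos"].min()),
                stop=int(passing["pos"].max()),
                peak=int(peak_row["pos"]),
                threshold=threshold,
                n_snps=len(passing),
            )
        )
    return out
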