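"""Variant-table container, site/genotype filters and concordance analysis.

Filtering follows the variant-calling conventions of the study design: sites
with mapping quality below 50 are dropped, genotypes with fewer than 5
supporting reads are set missing, and only biallelic SNPs are retained.
Double-haploid females provide an orthogonal artifact screen: a DH genome
carries two identical chromosome sets, so any heterozygous call in one marks
a genotyping artifact (typically a collapsed paralog) and the position is
removed genome-wide.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantTable",
    "ConcordanceReport",
    "filter_variants",
    "double_haploid_filter",
    "genotype_concordance",
    "downsample_depths",
]

MISSING = -1  # genotype code for missing; 0/1/2 are alt-allele dosages


@dataclass
class VariantTable:
    """Per-site, per-sample genotype calls with allele depths and site quality.

    ``sites`` columns: chrom, pos (1-based), ref, alt, mq (extra columns are
    carried along).  ``gt`` holds alt-allele dosage codes 0/1/2 with -1 for
    missing; ``ad_ref``/``ad_alt``/``dp`` are read counts, all shaped
    (n_sites, n_samples).
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        for name in ("gt", "ad_ref", "ad_alt", "dp"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n_sites, n_samples)}")
        if n_sites and int(self.sites["pos"].min()) < 1:
            raise ValueError("positions are 1-based (pos >= 1)")
        if ((self.ad_ref + self.ad_alt) > self.dp).any():
            raise ValueError("ad_ref + ad_alt exceeds dp")
        self.sites = self.sites.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sort(self) -> "VariantTable":
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.take(order)

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            dp=self.dp[idx],
            contig_lengths=dict(self.contig_lengths),
        )

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return self.take(np.flatnonzero(mask))

    def subset_samples(self, samples: Sequence[str]) -> "VariantTable":
        idx = [self.samples.index(s) for s in samples]
        return VariantTable(
            sites=self.sites.copy(),
            samples=list(samples),
            gt=self.gt[:, idx],
            ad_ref=self.ad_ref[:, idx],
            ad_alt=self.ad_alt[:, idx],
            dp=self.dp[:, idx],
            contig_lengths=dict(self.contig_lengths),
        )

    def dosage(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        """Alt-allele dosage matrix (NaN for missing), indexed by (chrom, pos)."""
        cols = list(self.samples) if samples is None else list(samples)
        idx = [self.samples.index(s) for s in cols]
        d = self.gt[:, idx].astype(float)
        d[d == MISSING] = np.nan
        return pd.DataFrame(
            d, index=pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]]), columns=cols
        )

    # --- VCF round-trip -------------------------------------------------
    def to_vcf(self, path: str | Path) -> None:
        header = pysam.VariantHeader()
        lengths = dict(self.contig_lengths)
        for chrom in self.sites["chrom"].unique():
            header.contigs.add(str(chrom), length=lengths.get(chrom))
        header.info.add("MQ", 1, "Float", "RMS mapping quality")
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
        header.formats.add("DP", 1, "Integer", "Read depth")
        for s in self.samples:
            header.add_sample(s)
        gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None,)}
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for i in range(self.n_sites):
                row = self.sites.iloc[i]
                rec = out.new_record(
                    contig=str(row["chrom"]),
                    start=int(row["pos"]) - 1,
                    alleles=(str(row["ref"]), str(row["alt"])),
                )
                rec.info["MQ"] = float(row["mq"])
                for j, s in enumerate(self.samples):
                    rec.samples[s]["GT"] = gt_map[int(self.gt[i, j])]
                    rec.samples[s]["AD"] = (int(self.ad_ref[i, j]), int(self.ad_alt[i, j]))
                    rec.samples[s]["DP"] = int(self.dp[i, j])
                out.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "VariantTable":
        rows, gt, ad_ref, ad_alt, dp = [], [], [], [], []
        with pysam.VariantFile(str(path)) as fh:
            samples = list(fh.header.samples)
            lengths = {
                name: rec.length
                for name, rec in fh.header.contigs.items()
                if rec.length is not None
            }
            for rec in fh:
                alts = rec.alts or ()
                alt = alts[0] if alts else "."
                rows.append(
                    (rec.contig, rec.pos, rec.ref, alt, float(rec.info.get("MQ", np.nan)))
                )
                g_row, ar_row, aa_row, dp_row = [], [], [], []
                for s in samples:
                    call = rec.samples[s]
                    alleles = call.get("GT", (None,))
                    if alleles is None or any(a is None for a in alleles):
                        g_row.append(MISSING)
                    else:
                        g_row.append(int(sum(alleles)))
                    ad = call.get("AD", (0, 0)) or (0, 0)
                    ar_row.append(int(ad[0] or 0))
                    aa_row.append(int(ad[1] or 0) if len(ad) > 1 else 0)
                    dp_row.append(int(call.get("DP", 0) or 0))
                gt.append(g_row)
                ad_ref.append(ar_row)
                ad_alt.append(aa_row)
                dp.append(dp_row)
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "mq"])
        return cls(
            sites=sites,
            samples=samples,
            gt=np.asarray(gt, dtype=np.int8),
            ad_ref=np.asarray(ad_ref, dtype=np.int32),
            ad_alt=np.asarray(ad_alt, dtype=np.int32),
            dp=np.asarray(dp, dtype=np.int32),
            contig_lengths=lengths,
        )


# ----------------------------------------------------------------------
_BASES = {"A", "C", "G", "T"}


def filter_variants(
    table: VariantTable,
    min_mq: float = 50,
    min_dp: int = 5,
    biallelic_only: bool = True,
) -> tuple[VariantTable, dict[str, int]]:
    """Site and genotype quality filters.

    Removes sites with mapping quality below ``min_mq`` and (optionally)
    anything that is not a biallelic SNP; genotypes with depth below
    ``min_dp`` are set missing, and sites left with no called genotype are
    dropped.  Returns the filtered table and a removal log.
    """
    if min_mq < 0 or min_dp < 0:
        raise ValueError("thresholds must be non-negative")
    log: dict[str, int] = {}

    keep = (table.sites["mq"] >= min_mq).to_numpy()
    log["low_mq_sites"] = int((~keep).sum())
    table = table.subset_sites(keep)

    if biallelic_only:
        ref_ok = table.sites["ref"].isin(_BASES)
        alt_ok = table.sites["alt"].isin(_BASES)
        snp = (ref_ok & alt_ok).to_numpy()
        log["non_biallelic_snp_sites"] = int((~snp).sum())
        table = table.subset_sites(snp)
    else:
        log["non_biallelic_snp_sites"] = 0

    gt = table.gt.copy()
    low = (table.dp < min_dp) & (gt != MISSING)
    log["low_dp_genotypes"] = int(low.sum())
    gt[low] = MISSING
    table = dataclasses.replace(table, gt=gt)

    any_called = (table.gt != MISSING).any(axis=1)
    log["all_missing_sites"] = int((~any_called).sum())
    table = table.subset_sites(any_called)
    return table, log


def double_haploid_filter(
    table: VariantTable, dh_samples: Sequence[str]
) -> tuple[VariantTable, list[tuple[str, int]]]:
    """Remove every position heterozygous in any double-haploid sample.

    DH samples themselves are dropped from the surviving table.  Returns the
    filtered table and the removed (chrom, pos) list.
    """
    if not len(dh_samples):
        raise ValueError("dh_samples must be non-empty")
    missing = set(dh_samples) - set(table.samples)
    if missing:
        raise ValueError(f"DH samples absent from table: {sorted(missing)}")
    idx = [table.samples.index(s) for s in dh_samples]
    bad = (table.gt[:, idx] == 1).any(axis=1)
    removed = [
        (str(c), int(p))
        for c, p in table.sites.loc[bad, ["chrom", "pos"]].itertuples(index=False)
    ]
    survivors = [s for s in table.samples if s not in set(dh_samples)]
    return table.subset_sites(~bad).subset_samples(survivors), removed


# ----------------------------------------------------------------------
@dataclass
class ConcordanceReport:
    n_overlap_loci: int
    n_compared_genotypes: int
    n_concordant: int
    per_locus: pd.DataFrame

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_compared_genotypes


def _as_dosage_frame(obj) -> pd.DataFrame:
    """Coerce a VariantTable or a site-keyed dosage DataFrame to a common form."""
    if isinstance(obj, VariantTable):
        d = obj.dosage()
        d.index = pd.MultiIndex.from_frame(obj.sites[["chrom", "pos", "ref", "alt"]])
        return d
    df = obj.copy()
    if not isinstance(df.index, pd.MultiIndex) or df.index.nlevels != 4:
        raise ValueError("dosage frame must be indexed by (chrom, pos, ref, alt)")
    return df.astype(float)


def genotype_concordance(table_a, table_b) -> ConcordanceReport:
    """Compare two genotype sources at loci matched by position and alleles.

    Loci are matched on (chrom, pos) with identical ref/alt; both sources are
    compared as 0/1/2 alt dosages over shared samples, skipping pairs where
    either call is missing.  Symmetric in its two inputs.
    """
    a = _as_dosage_frame(table_a)
    b = _as_dosage_frame(table_b)
    shared_samples = [s for s in a.columns if s in set(b.columns)]
    if not shared_samples:
        raise ValueError("no shared samples")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no overlapping loci with identical alleles")
    a = a.loc[common, shared_samples]
    b = b.loc[common, shared_samples]
    both = a.notna().to_numpy() & b.notna().to_numpy()
    agree = (a.to_numpy() == b.to_numpy()) & both
    per_locus = pd.DataFrame(
        {
            "n_compared": both.sum(axis=1),
            "n_concordant": agree.sum(axis=1),
        },
        index=common,
    )
    n_comp = int(both.sum())
    if n_comp == 0:
        raise ValueError("no jointly called genotypes to compare")
    return ConcordanceReport(
        n_overlap_loci=len(common),
        n_compared_genotypes=n_comp,
        n_concordant=int(agree.sum()),
        per_locus=per_locus,
    )


# ----------------------------------------------------------------------
def downsample_depths(
    table: VariantTable,
    fraction: float,
    seed: int,
    min_dp: int = 5,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> VariantTable:
    """Binomially thin allele depths and re-call genotypes at the lower depth.

    Each of ad_ref/ad_alt is thinned independently at ``fraction`` and dp is
    recomputed as their sum.  Genotypes are re-called: missing below
    ``min_dp``, hom-ref below the het band, hom-alt above it, het inside.
    ``fraction=1`` leaves the table unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return table
    rng = np.random.default_rng(seed)
    ad_ref = rng.binomial(table.ad_ref, fraction).astype(np.int32)
    ad_alt = rng.binomial(table.ad_alt, fraction).astype(np.int32)
    dp = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_alt = np.where(dp > 0, ad_alt / np.maximum(dp, 1), 0.0)
    gt = np.where(frac_alt < het_band[0], 0, np.where(frac_alt > het_band[1], 2, 1))
    gt = np.where(dp < min_dp, MISSING, gt).astype(np.int8)
    return dataclasses.replace(table, gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp)
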