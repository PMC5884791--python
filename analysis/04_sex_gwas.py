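#!/usr/bin/env python
"""Case-control GWAS for genotypic sex on a large single-population cohort.

Assigns GSEX from the three sdY probe assays, filters the genotype matrix
(call rate >= 90%, MAF >= 1%, sample missingness <= 5%), verifies the
pedigree against the VanRaden genomic relationship matrix, regresses GSEX
on SNP dosage, and delineates chromosome-specific critical intervals from
the top 0.5% of associated SNPs gated on a genome-wide Bonferroni peak.
"""
from pathlib import Path

import pandas as pd

from sexlinkit import gwas, synthetic_data as sd
from sexlinkit.config import SimConfig

ROOT = Path(__file__).resolve().parents[1]
SEED = 2018

# GWAS-scale design: one large genotyped population, distinct from the small
# whole-genome-sequencing panel used by the read-level analyses
GWAS_CFG = dict(pop_sizes={"TAS": 800}, n_dh_females=0)


def main() -> None:
    cfg = SimConfig(seed=SEED, **GWAS_CFG)
    pop = sd.simulate_population(cfg)
    table = sd.simulate_variant_table(cfg, pop)
    array, assays = sd.simulate_array_genotypes(cfg, table, pop.truth)

    gsex = {a: gwas.assign_gsex(row) for a, row in assays.iterrows()}
    sheet = pop.sample_sheet.set_index("animal")
    concord = (sheet["PSEX"] == sheet["GSEX"]).mean()
    pheno = pd.Series(
        {a: 1.0 if s == "male" else 0.0 for a, s in gsex.items() if s != "missing"}
    )

    dosage = pop.dosage_frame(samples=list(pheno.index), contig_sites=False)
    geno, qc_log = gwas.qc_genotype_matrix(dosage)

    ped = sheet.reset_index()[["animal", "sire", "dam"]]
    G = gwas.grm_vanraden1(geno)
    flagged, _ = gwas.pedigree_check(ped, G)

    assoc = gwas.assoc_linear(geno, pheno)
    intervals = gwas.critical_intervals(assoc)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    top = assoc.sort_values("p").head(25)
    top.to_csv(results / "04_assoc_top25.tsv", sep="\t", index=False)
    iv_out = pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "stop": iv.stop,
                "peak": iv.peak,
                "size_bp": iv.stop - iv.start + 1,
                "threshold": f"{iv.threshold:.3e}",
                "n_snps": iv.n_snps,
            }
            for iv in intervals
        ]
    )
    iv_out.to_csv(results / "04_critical_intervals.tsv", sep="\t", index=False)

    print(f"Animals genotyped: {len(gsex)}; PSEX/GSEX concordance: {concord:.1%}")
    print(f"Matrix QC: {qc_log}")
    print(f"Pedigree-vs-GRM flagged animals: {len(flagged)}")
    print(iv_out.to_string(index=False))
    print(
        f"\n{len(intervals)} chromosomes carry Bonferroni-significant association"
        " peaks. Three correspond to the planted sdY anchors (Ssa02/03/06);"
        " any extra peaks sit on homeologs of Ssa02 and are examined for"
        " leakage in the next stage."
    )


if __name__ == "__main__":
    main()
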