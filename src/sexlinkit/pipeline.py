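"""End-to-end synthetic analysis: simulate -> qc -> gwas -> leakage -> msr -> tree.

Thin orchestration over the stage modules, used by the command-line
interface, the numbered analysis scripts and the end-to-end tests.  Each
stage's result is returned under a stable key so drivers can report or
persist whichever pieces they need.
"""
from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import gwas, haplotree, leakage, msr, popgen, synthetic_data, variant_qc
from .config import SDY_CONTIG, SimConfig


def run_pipeline(config: SimConfig, skip_alignments: bool = False) -> dict[str, Any]:
    """Run every analysis stage on a freshly simulated cohort."""
    out: dict[str, Any] = {"config": config}

    pop = synthetic_data.simulate_population(config)
    truth = pop.truth
    out["population"] = pop
    out["truth"] = truth

    # --- variant QC -----------------------------------------------------
    table = synthetic_data.simulate_variant_table(config, pop)
    filtered, filter_log = variant_qc.filter_variants(table)
    filtered, dh_removed = variant_qc.double_haploid_filter(filtered, truth.dh_samples)
    out["variant_table"] = filtered
    out["qc_log"] = filter_log
    out["dh_removed"] = dh_removed

    array, assays = synthetic_data.simulate_array_genotypes(config, table, truth)
    out["array_concordance"] = variant_qc.genotype_concordance(filtered, array)

    # --- GWAS on genotypic sex ------------------------------------------
    gsex_assigned = {a: gwas.assign_gsex(row) for a, row in assays.iterrows()}
    pheno = pd.Series(
        {a: 1.0 if s == "male" else 0.0 for a, s in gsex_assigned.items() if s != "missing"}
    )
    dosage = pop.dosage_frame(
        samples=[s for s in pop.samples if s not in set(truth.dh_samples)],
        contig_sites=False,
    )
    geno, geno_log = gwas.qc_genotype_matrix(dosage)
    assoc = gwas.assoc_linear(geno, pheno)
    intervals = gwas.critical_intervals(assoc)
    out["gsex"] = gsex_assigned
    out["assoc"] = assoc
    out["intervals"] = intervals

    # --- homeolog leakage ------------------------------------------------
    hmap = leakage.HomeologMap(list(config.homeolog_pairs))
    out["leakage"] = leakage.classify_leakage(intervals, hmap, geno, assoc)

    # --- MSR junction, lineages, hemizygosity ----------------------------
    if not skip_alignments:
        records = synthetic_data.simulate_alignments(config, truth)
        male_prof = msr.depth_profile(records, SDY_CONTIG, samples=truth.seq_males)
        female_prof = msr.depth_profile(records, SDY_CONTIG, samples=truth.seq_females)
        junction = msr.detect_junction(male_prof, female_prof)
        lineage_calls = [
            msr.classify_sex_lineage(
                records, m, junction, config.insert_mean, config.insert_sd, SDY_CONTIG
            )
            for m in truth.seq_males
        ]
        out["records"] = records
        out["junction"] = junction
        out["lineage_calls"] = lineage_calls
    else:
        records = None
        out["junction"] = None
        out["lineage_calls"] = []

    # the MSR/haplotype stages mirror the sequencing study: only the
    # sequenced panel contributes calls on the sdY contig
    males = list(truth.seq_males)
    females = list(truth.seq_females)
    baf = msr.compute_baf(table, SDY_CONTIG)
    msr_sites = msr.define_msr_sites(table, males, females, contig=SDY_CONTIG)
    out["msr_sites"] = msr_sites
    if msr_sites:
        frac, ratios = msr.hemizygosity_report(
            baf,
            msr_sites,
            males,
            records=records,
            contig=SDY_CONTIG,
            msr_start=config.msr_start,
            junction=out["junction"],
        )
        out["baf_homozygous_fraction"] = frac
        out["msr_depth_ratio"] = ratios

    # --- MSR haplotypes ---------------------------------------------------
    contig_mask = (
        (table.sites["chrom"] == SDY_CONTIG)
        & table.sites["pos"].isin([p for _, p in msr_sites])
    ).to_numpy()
    hm = haplotree.extract_haplotypes(table.subset_sites(contig_mask), males)
    dist = haplotree.p_distance_matrix(hm)
    tree = haplotree.nj_tree(dist)
    supports = haplotree.bootstrap_support(hm, tree, n_replicates=1000, seed=config.seed)
    partition = haplotree.split_haplogroups(tree, dist)
    ancestral, og_report = haplotree.ancestral_assignment(partition, hm, pop.outgroup_alleles)
    out.update(
        haplotypes=hm,
        distances=dist,
        tree=tree,
        bootstrap=supports,
        haplogroups=partition,
        ancestral=ancestral,
        outgroup_report=og_report,
    )
    return out
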