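#!/usr/bin/env python
"""Delineate the male-specific region and assign sex lineages from mate pairs.

Builds male and female depth profiles over the sdY contig, detects the
MSR-MFCR boundary as the change-point where female depth resumes, then
classifies each sequenced male: junction-spanning proper pairs mark a
cassette anchored in the contiguous contig sequence (SL-02-like), while
orphan reads adjacent to the junction whose mates land on another
chromosome mark a translocated cassette.  B-allele frequencies over MSR
sites test male hemizygosity.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from sexlinkit import msr, synthetic_data as sd
from sexlinkit.config import SDY_CONTIG, SimConfig

ROOT = Path(__file__).resolve().parents[1]
SEED = 2018


def main() -> None:
    cfg = SimConfig(seed=SEED)
    pop = sd.simulate_population(cfg)
    truth = pop.truth
    records = sd.simulate_alignments(cfg, truth)
    table = sd.simulate_variant_table(cfg, pop)

    male_prof = msr.depth_profile(records, SDY_CONTIG, samples=truth.seq_males)
    female_prof = msr.depth_profile(records, SDY_CONTIG, samples=truth.seq_females)
    junction = msr.detect_junction(male_prof, female_prof)

    calls = []
    for m in truth.seq_males:
        c = msr.classify_sex_lineage(records, m, junction, cfg.insert_mean, cfg.insert_sd)
        calls.append(
            {
                "animal": m,
                "true_lineage": truth.lineage_by_male[m],
                "call": c.call,
                "candidates": ",".join(c.candidates) or "-",
                "spanning_pairs": c.spanning_pairs,
                "orphans": ";".join(f"{k}:{v}" for k, v in sorted(c.orphan_tally.items())) or "-",
            }
        )
    calls_out = pd.DataFrame(calls)

    baf = msr.compute_baf(table, SDY_CONTIG)
    msr_sites = msr.define_msr_sites(table, truth.seq_males, truth.seq_females, contig=SDY_CONTIG)
    frac, ratios = msr.hemizygosity_report(
        baf, msr_sites, truth.seq_males, records=records,
        msr_start=cfg.msr_start, junction=junction,
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    calls_out.to_csv(results / "06_lineage_calls.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [
            ("detected junction (bp)", junction),
            ("true junction (bp)", truth.junction_pos),
            ("MSR sites defined", len(msr_sites)),
            ("male BAF in {0,1}", round(frac, 4)),
            ("mean MSR/genome depth ratio", round(float(np.mean(list(ratios.values()))), 3)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(results / "06_junction_summary.tsv", sep="\t", index=False)

    print(summary.to_string(index=False))
    print()
    print(calls_out.to_string(index=False))
    print(
        f"\nThe boundary is detected at {junction} bp"
        f" ({junction - truth.junction_pos:+d} bp from truth). Males carry the"
        " MSR at half their genome-wide depth and show only 0/1 B-allele"
        " frequencies across it — both hallmarks of a single-copy (XY-like)"
        " male region. Spanning-pair and orphan-read architecture separates"
        " anchored SL-02 males from translocated SL-03/SL-06 males, though the"
        " orphan tallies alone cannot distinguish Ssa03 from Ssa06."
    )


if __name__ == "__main__":
    main()
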