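import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from oracles import per_site_pi, wc_theta_scalar
from sexlinkit import popgen
from sexlinkit import synthetic_data as sd
from sexlinkit.config import SimConfig


# ---------------------------------------------------------------- pi
def test_windowed_pi_hand_value():
    """One site with 5 alt among 10 alleles in a 20 kb window: (25/45)/20000."""
    table = make_table(
        [("c1", 100, "A", "C", 60.0)],
        [f"s{i}" for i in range(5)],
        [[1, 1, 1, 1, 1]],  # five hets: c = 5 of n = 10
        contig_lengths={"c1": 20_000},
    )
    out = popgen.windowed_pi(table, table.samples, window_bp=20_000, step_bp=20_000)
    assert out.loc[0, "value"] == pytest.approx((25 / 45) / 20_000, rel=1e-12)
    assert out.loc[0, "value"] == pytest.approx(per_site_pi([1] * 5) / 20_000, rel=1e-12)


def test_windows_without_variants_and_fixed_sites_are_zero():
    table = make_table(
        [("c1", 100, "A", "C", 60.0)],
        ["s1", "s2"],
        [[2, 2]],  # fixed alternate: contributes zero
        contig_lengths={"c1": 40_000},
    )
    out = popgen.windowed_pi(table, table.samples, window_bp=20_000, step_bp=20_000)
    assert (out["value"] == 0).all()
    assert out.loc[1, "n_variants"] == 0


def test_pi_scales_inversely_with_window_length():
    table = make_table(
        [("c1", 100, "A", "C", 60.0)],
        ["s1", "s2"],
        [[1, 1]],
        contig_lengths={"c1": 40_000},
    )
    w20 = popgen.windowed_pi(table, table.samples, 20_000, 20_000).loc[0, "value"]
    w40 = popgen.windowed_pi(table, table.samples, 40_000, 40_000).loc[0, "value"]
    assert w20 == pytest.approx(2 * w40)


def test_pi_rejects_step_larger_than_window(default_table):
    with pytest.raises(ValueError):
        popgen.windowed_pi(default_table, default_table.samples, 10_000, 20_000)


# ---------------------------------------------------------------- W&C F_ST
def _random_toy_table(rng, n_sites=100, n_a=8, n_b=12):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    gt = rng.integers(0, 3, size=(n_sites, len(samples)))
    rows = [("c1", i + 1, "A", "C", 60.0) for i in range(n_sites)]
    return make_table(rows, samples, gt), samples[:n_a], samples[n_a:]


def test_wc_fst_matches_scalar_oracle_exactly():
    rng = np.random.default_rng(2024)
    table, pa, pb = _random_toy_table(rng)
    per_site, _, _ = popgen.wc_fst(table, pa, pb)
    ai = [table.samples.index(s) for s in pa]
    bi = [table.samples.index(s) for s in pb]
    for k in range(table.n_sites):
        expected = wc_theta_scalar(list(table.gt[k, ai]), list(table.gt[k, bi]))
        got = per_site.iloc[k]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_fixed_difference_gives_theta_one():
    table = make_table(
        [("c1", 1, "A", "C", 60.0)],
        ["a1", "a2", "b1", "b2"],
        [[0, 0, 2, 2]],
    )
    per_site, mean, _ = popgen.wc_fst(table, ["a1", "a2"], ["b1", "b2"])
    assert mean == pytest.approx(1.0)


def test_monomorphic_site_excluded():
    table = make_table(
        [("c1", 1, "A", "C", 60.0), ("c1", 2, "A", "C", 60.0)],
        ["a1", "a2", "b1", "b2"],
        [[0, 0, 0, 0], [0, 0, 2, 2]],
    )
    per_site, _, _ = popgen.wc_fst(table, ["a1", "a2"], ["b1", "b2"])
    assert np.isnan(per_site.iloc[0]) and per_site.iloc[1] == pytest.approx(1.0)


def test_theta_invariant_under_population_swap_and_allele_relabel():
    rng = np.random.default_rng(7)
    table, pa, pb = _random_toy_table(rng, n_sites=50)
    a_first, _, _ = popgen.wc_fst(table, pa, pb)
    b_first, _, _ = popgen.wc_fst(table, pb, pa)
    pd.testing.assert_series_equal(a_first, b_first)
    flipped = make_table(
        [tuple(r) for r in table.sites[["chrom", "pos", "ref", "alt", "mq"]].itertuples(index=False)],
        table.samples,
        np.where(table.gt == -1, -1, 2 - table.gt),
    )
    f_per, _, _ = popgen.wc_fst(flipped, pa, pb)
    np.testing.assert_allclose(f_per.to_numpy(), a_first.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------- RAF
def test_raf_of_population_with_itself_is_diagonal():
    idx = pd.MultiIndex.from_tuples([("c1", i) for i in range(100)])
    raf = pd.Series(np.linspace(0.05, 0.95, 100), index=idx)
    hist, r2, r = popgen.raf_correlation(raf, raf)
    assert r2 == pytest.approx(1.0)
    off_diag = hist.sum() - np.trace(hist)
    assert off_diag == 0


def test_independent_frequencies_are_uncorrelated():
    rng = np.random.default_rng(11)
    idx = pd.MultiIndex.from_tuples([("c1", i) for i in range(10_000)])
    a = pd.Series(rng.uniform(0, 1, 10_000), index=idx)
    b = pd.Series(rng.uniform(0, 1, 10_000), index=idx)
    _, r2, _ = popgen.raf_correlation(a, b)
    assert r2 < 0.02


def test_anticorrelated_frequencies_fill_the_antidiagonal():
    idx = pd.MultiIndex.from_tuples([("c1", i) for i in range(100)])
    a = pd.Series(np.linspace(0.01, 0.99, 100), index=idx)
    hist, r2, r = popgen.raf_correlation(a, 1 - a, n_bins=10)
    assert r2 == pytest.approx(1.0)
    assert r < 0
    assert hist[0, -1] > 0 and hist[0, 0] == 0


# ---------------------------------------------------------------- dendrogram
def test_three_population_dendrogram_solves_three_point_equations():
    d = pd.DataFrame(
        [[0.0, 0.041, 0.178], [0.041, 0.0, 0.172], [0.178, 0.172, 0.0]],
        index=["TAS", "NA", "EU"],
        columns=["TAS", "NA", "EU"],
    )
    tree = popgen.fst_dendrogram(d)
    lengths = {}
    for child in tree.children:
        for name in child.leaves():
            if child.is_leaf:
                lengths[name] = child.length
            else:
                lengths[name] = child.children[0].length if child.children else 0.0
    by_leaf = {}

    def collect(node, acc):
        if node.is_leaf:
            by_leaf[node.name] = node.length + acc
        for c in node.children:
            collect(c, 0.0)

    collect(tree, 0.0)
    # three-point closed form: a = (dAB + dAC - dBC) / 2 etc.
    assert by_leaf["TAS"] == pytest.approx((0.041 + 0.178 - 0.172) / 2, abs=1e-12)
    assert by_leaf["NA"] == pytest.approx((0.041 + 0.172 - 0.178) / 2, abs=1e-12)
    assert by_leaf["EU"] == pytest.approx((0.178 + 0.172 - 0.041) / 2, abs=1e-12)


def test_dendrogram_rejects_asymmetry():
    d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError):
        popgen.fst_dendrogram(d)


def test_zero_distance_matrix_gives_zero_branch_lengths():
    d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    tree = popgen.fst_dendrogram(d)

    def total(node):
        return node.length + sum(total(c) for c in node.children)

    assert total(tree) == 0.0


# ---------------------------------------------------------------- LD
def test_ld_r2_trivial_cases():
    assert popgen.ld_r2([0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2]) == pytest.approx(1.0)
    assert popgen.ld_r2([0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]) == pytest.approx(1.0)


def test_ld_r2_monomorphic_is_signaled():
    with pytest.raises(popgen.MonomorphicSiteError):
        popgen.ld_r2([1, 1, 1, 1], [0, 1, 2, 1])


def test_ld_r2_independent_sites_near_zero():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 3, 1000).astype(float)
    y = rng.integers(0, 3, 1000).astype(float)
    assert popgen.ld_r2(x, y) < 0.01


def test_ld_prune_removes_duplicate_adjacent_sites():
    rng = np.random.default_rng(5)
    base = rng.integers(0, 3, size=(1, 200)).astype(float)
    dosage = pd.DataFrame(np.vstack([base, base]), index=[("c1", 1), ("c1", 2)])
    kept = popgen.ld_prune(dosage, window_snps=10, step_snps=1)
    assert kept == [0]


def test_ld_prune_keeps_independent_sites():
    rng = np.random.default_rng(6)
    dosage = pd.DataFrame(rng.integers(0, 3, size=(30, 500)).astype(float))
    kept = popgen.ld_prune(dosage, window_snps=10, step_snps=1)
    assert kept == list(range(30))


def test_ld_prune_drops_one_of_each_mirrored_pair():
    pairs = [dict(chrom_a="Ssa02", start_a=1, end_a=250_000,
                  chrom_b="Ssa05", start_b=250_001, end_b=500_000, rho=1.0)]
    cfg = SimConfig(seed=8, homeolog_pairs=pairs, homeolog_mirror_fraction=1.0,
                    snps_per_chrom=100, pop_sizes={"TAS": 60})
    pop = sd.simulate_population(cfg)
    frame = pop.dosage_frame()
    keep = (
        pop.sites["kind"].isin(["background", "mirror"])
        & (pop.sites["sd_index"] == -1)  # mirrors of sd-block sites have no
        & pop.sites["chrom"].isin(["Ssa02", "Ssa05"])  # partner in this subset
    ).to_numpy()
    sub = frame[keep]
    n_mirror = int((pop.sites.loc[keep, "kind"] == "mirror").sum())
    kept = popgen.ld_prune(sub, window_snps=len(sub), step_snps=len(sub))
    assert len(kept) <= len(sub) - n_mirror


# ---------------------------------------------------------------- PCA / MDS
def test_duplicated_sample_has_identical_coordinates():
    rng = np.random.default_rng(9)
    m = rng.integers(0, 3, size=(100, 5)).astype(float)
    m = np.column_stack([m, m[:, 0]])
    dosage = pd.DataFrame(m, columns=[f"s{i}" for i in range(6)])
    coords, frac = popgen.pca_distance(dosage)
    np.testing.assert_allclose(coords.loc["s0"], coords.loc["s5"], atol=1e-9)
    assert frac.sum() <= 1.0 + 1e-9


def test_pca_separates_diverged_populations():
    cfg = SimConfig(seed=10, pop_sizes={"TAS": 20, "EU": 20},
                    fst_drift={"TAS": 0.1, "EU": 0.1}, snps_per_chrom=800)
    pop = sd.simulate_population(cfg)
    frame = pop.dosage_frame(
        samples=[s for s in pop.samples if not s.startswith("DH")], contig_sites=False
    )
    coords, _ = popgen.pca_distance(frame)
    tas = coords.loc[[s for s in coords.index if s.startswith("TAS")], "PC1"]
    eu = coords.loc[[s for s in coords.index if s.startswith("EU")], "PC1"]
    assert max(tas.min(), eu.min()) > min(tas.max(), eu.max()) or max(
        eu.min(), tas.min()
    ) > min(eu.max(), tas.max())  # no overlap on axis 1


def test_mds_recovers_one_dimensional_allele_sharing_distances():
    """A single-site dosage matrix embeds exactly on one axis."""
    dosage = pd.DataFrame([[0.0, 1.0, 2.0, 2.0]], columns=list("abcd"))
    coords, _ = popgen.pca_distance(dosage, n_components=3)
    got = np.abs(
        coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :]
    )
    got = np.sqrt((got**2).sum(-1))
    expected = np.abs(
        dosage.to_numpy().T - dosage.to_numpy()
    ) / 2.0  # |d_i - d_j| / 2 at the single site
    np.testing.assert_allclose(got, expected, atol=1e-9)
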