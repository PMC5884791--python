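import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from oracles import best_quartet_lstsq, random_additive_tree
from sexlinkit import haplotree as ht
from sexlinkit.config import SDY_CONTIG
from sexlinkit.synthetic_data import simulate_msr_haplotypes


# ---------------------------------------------------------------- extraction
def _msr_table(gt_rows, n_males):
    males = [f"m{i}" for i in range(n_males)]
    sites = [(SDY_CONTIG, 1_000 * (k + 3), "A", "C", 60.0) for k in range(len(gt_rows))]
    return make_table(sites, males, gt_rows), males


def test_low_call_rate_site_dropped():
    # site 1: called in 7/10 males (70%) -> dropped; site 2: 8/10 -> kept
    row70 = [2] * 7 + [-1] * 3
    row80 = [2] * 8 + [-1] * 2
    table, males = _msr_table([row70, row80], 10)
    hm = ht.extract_haplotypes(table, males)
    assert hm.sites == [4_000]


def test_male_with_excess_missingness_dropped():
    rows = [[2] * 9 + [-1] for _ in range(10)]  # male 9 missing at 100% of sites
    table, males = _msr_table(rows, 10)
    hm = ht.extract_haplotypes(table, males)
    assert "m9" not in hm.males and len(hm.males) == 9


def test_het_msr_call_flagged_and_set_missing():
    rows = [[2, 1, 0, 2, 2, 0, 2, 0, 2, 2]]
    table, males = _msr_table(rows, 10)
    with pytest.warns(UserWarning, match="heterozygous"):
        hm = ht.extract_haplotypes(table, males, max_male_missing=1.0)
    assert hm.alleles[hm.males.index("m1"), 0] == ht.NO_CALL


def test_all_sites_dropped_is_an_error():
    rows = [[-1] * 10]
    table, males = _msr_table(rows, 10)
    with pytest.raises(ValueError):
        ht.extract_haplotypes(table, males)


# ---------------------------------------------------------------- p-distance
def _hm(seqs, sites=None):
    males = [f"m{i}" for i in range(len(seqs))]
    alleles = np.array([list(s) for s in seqs], dtype="<U1")
    return ht.HaplotypeMatrix(
        males=males, sites=sites or list(range(1, alleles.shape[1] + 1)), alleles=alleles
    )


def test_p_distance_identical_and_half():
    hm = _hm(["ACGTACGTACGTACGTACGTAC", "ACGTACGTACGटACGTACGTAC".replace("ट", "T")])
    d = ht.p_distance_matrix(hm)
    assert d.iloc[0, 1] == 0.0
    hm2 = _hm(["A" * 22, "A" * 11 + "C" * 11])
    d2 = ht.p_distance_matrix(hm2)
    assert d2.iloc[0, 1] == pytest.approx(0.5)


def test_p_distance_pairwise_deletion():
    hm = _hm(["ACGT", "ANGA"])
    hm.alleles[1, 1] = ht.NO_CALL
    d = ht.p_distance_matrix(hm)
    assert d.iloc[0, 1] == pytest.approx(1 / 3)  # 1 difference over 3 joint sites


def test_p_distance_random_sequences_near_three_quarters():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACGT"), 4_000)) for _ in range(2)]
    d = ht.p_distance_matrix(_hm(seqs))
    assert d.iloc[0, 1] == pytest.approx(0.75, abs=0.03)


def test_p_distance_premetric_properties():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(5)]
    d = ht.p_distance_matrix(_hm(seqs)).to_numpy()
    np.testing.assert_allclose(d, d.T)
    assert (np.diag(d) == 0).all()
    for i, j, k in itertools.permutations(range(5), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_disjoint_calls_signaled():
    hm = _hm(["AC", "AC"])
    hm.alleles[0] = ["A", ht.NO_CALL]
    hm.alleles[1] = [ht.NO_CALL, "C"]
    with pytest.warns(UserWarning, match="no called sites"):
        d = ht.p_distance_matrix(hm)
    assert np.isnan(d.iloc[0, 1])


# ---------------------------------------------------------------- NJ
def test_quartet_recovery_against_exhaustive_least_squares():
    rng = np.random.default_rng(2)
    for _ in range(20):
        tips = rng.uniform(0.1, 1.0, 4)
        internal = rng.uniform(0.1, 1.0)
        d = np.zeros((4, 4))
        # true topology: (0,1) | (2,3)
        for i, j in itertools.combinations(range(4), 2):
            extra = 0.0 if {i, j} in ({0, 1}, {2, 3}) else internal
            d[i, j] = d[j, i] = tips[i] + tips[j] + extra
        cherry, lengths, _ = best_quartet_lstsq(d)
        assert cherry == frozenset({0, 1})
        frame = pd.DataFrame(d, index=list("ABCD"), columns=list("ABCD"))
        tree = ht.nj_tree(frame)
        splits = ht.bipartitions(tree)
        assert frozenset({"A", "B"}) in splits
        assert splits[frozenset({"A", "B"})] == pytest.approx(lengths["internal"], abs=1e-9)


def test_three_taxon_closed_form():
    d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"),
                     columns=list("ABC"), dtype=float)
    tree = ht.nj_tree(d)
    by_leaf = {c.name: c.length for c in tree.children if c.is_leaf}
    for c in tree.children:
        if not c.is_leaf:
            for g in c.children:
                by_leaf[g.name] = g.length + c.length
    # direct tip lengths solving the three-point equations: a=1, b=2, c=3
    lengths = {}

    def walk(node, acc):
        if node.is_leaf:
            lengths[node.name] = acc + node.length
        for ch in node.children:
            walk(ch, 0.0)

    walk(tree, 0.0)
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(3)
    for _ in range(5):
        D = random_additive_tree(10, rng)
        frame = pd.DataFrame(D, index=[f"t{i}" for i in range(10)],
                             columns=[f"t{i}" for i in range(10)])
        tree = ht.nj_tree(frame)
        # additivity: NJ must reproduce the input distances exactly
        got = _tree_distances(tree)
        for i in range(10):
            for j in range(i + 1, 10):
                assert got[(f"t{i}", f"t{j}")] == pytest.approx(D[i, j], abs=1e-9)


def _tree_distances(tree):
    adj = {}

    def walk(node):
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length, c))
            adj.setdefault(id(c), []).append((id(node), c.length, node))
            walk(c)

    walk(tree)
    names = {}

    def collect(node):
        if node.is_leaf:
            names[id(node)] = node.name
        for c in node.children:
            collect(c)

    collect(tree)
    out = {}
    for start, sname in names.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w, _node in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other, oname in names.items():
            if oname > sname:
                out[(sname, oname)] = dist[other]
    return out


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(4)
    D = random_additive_tree(8, rng)
    names = [f"t{i}" for i in range(8)]
    frame = pd.DataFrame(D, index=names, columns=names)
    perm = list(rng.permutation(names))
    tree_a = ht.nj_tree(frame)
    tree_b = ht.nj_tree(frame.loc[perm, perm])
    assert set(ht.bipartitions(tree_a)) == set(ht.bipartitions(tree_b))


def test_nj_matches_scikit_bio_topology():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    names = [f"t{i}" for i in range(9)]
    D = random_additive_tree(9, rng)
    D = (D + D.T) / 2.0  # exact symmetry for the strict skbio validator
    dist = pd.DataFrame(D, index=names, columns=names)
    ours = set(ht.bipartitions(ht.nj_tree(dist)))
    dm = skbio.DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
    sk_tree = skbio.tree.nj(dm)
    theirs = set()
    leaves = frozenset(dist.index)
    for node in sk_tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(leaves) - 1:
            theirs.add(min(below, leaves - below, key=lambda s: (len(s), sorted(s))))
    assert ours == theirs


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        ht.nj_tree(pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("ab"), columns=list("ab")))
    with pytest.raises(ValueError):
        ht.nj_tree(pd.DataFrame(np.zeros((2, 2)), index=list("ab"), columns=list("ab")))


# ---------------------------------------------------------------- bootstrap
def test_bootstrap_supports_clear_split():
    hm, truth, _ = simulate_msr_haplotypes(6, 6, divergent_fraction=0.5,
                                           within_flip=0.0, seed=6)
    tree = ht.nj_tree(ht.p_distance_matrix(hm))
    supports = ht.bootstrap_support(hm, tree, n_replicates=300, seed=1)
    split = frozenset(m for m, g in truth.items() if g == "HG-1")
    leaves = frozenset(hm.males)
    key = min(split, leaves - split, key=lambda s: (len(s), sorted(s)))
    assert supports[key] >= 99.0


def test_bootstrap_deterministic_for_seed():
    hm, _, _ = simulate_msr_haplotypes(4, 4, seed=7)
    tree = ht.nj_tree(ht.p_distance_matrix(hm))
    a = ht.bootstrap_support(hm, tree, n_replicates=50, seed=3)
    b = ht.bootstrap_support(hm, tree, n_replicates=50, seed=3)
    assert a == b


def test_bootstrap_single_site_flagged():
    hm = _hm(["A", "C", "A", "C"])
    tree = ht.nj_tree(ht.p_distance_matrix(hm))
    with pytest.warns(UserWarning, match="degenerate"):
        ht.bootstrap_support(hm, tree, n_replicates=10, seed=0)


# ---------------------------------------------------------------- haplogroups
def test_split_recovers_planted_haplogroups():
    hm, truth, _ = simulate_msr_haplotypes(5, 7, seed=8)
    dist = ht.p_distance_matrix(hm)
    part = ht.split_haplogroups(ht.nj_tree(dist), dist)
    groups = [{truth[m] for m in part.group1}, {truth[m] for m in part.group2}]
    assert all(len(g) == 1 for g in groups)
    assert part.between >= max(part.within1, part.within2)


def test_two_leaf_split():
    hm = _hm(["AAAA", "ACCC"])
    dist = ht.p_distance_matrix(hm)
    tree = ht.TreeNode(children=[ht.TreeNode(name="m0"), ht.TreeNode(name="m1")])
    part = ht.split_haplogroups(tree, dist)
    assert part.between == pytest.approx(0.75)
    assert part.group1 | part.group2 == {"m0", "m1"}


# ---------------------------------------------------------------- ancestral
def _partitioned_hm():
    hm, truth, div = simulate_msr_haplotypes(5, 5, within_flip=0.0, seed=9)
    dist = ht.p_distance_matrix(hm)
    part = ht.split_haplogroups(ht.nj_tree(dist), dist)
    return hm, truth, div, part


def test_unanimous_outgroup_match_assigns_ancestral_group():
    hm, truth, div, part = _partitioned_hm()
    frame = hm.to_frame()
    hg2_male = next(m for m, g in truth.items() if g == "HG-2")
    outgroup = {p: frame.loc[hg2_male, p] for p in div[:4]}
    winner, report = ht.ancestral_assignment(part, hm, outgroup)
    group = part.group1 if winner == 1 else part.group2
    assert {truth[m] for m in group} == {"HG-2"}
    assert report["informative"].sum() == 4
    assert (report.loc[report["informative"], "matches"] == winner).all()


def test_no_informative_sites_is_undetermined():
    hm, truth, div, part = _partitioned_hm()
    frame = hm.to_frame()
    shared = [p for p in hm.sites if p not in div]
    outgroup = {p: frame.iloc[0][p] for p in shared[:3]}
    winner, report = ht.ancestral_assignment(part, hm, outgroup)
    assert winner is None and report["informative"].sum() == 0


def test_tied_votes_are_undetermined():
    hm, truth, div, part = _partitioned_hm()
    frame = hm.to_frame()
    hg1_male = next(m for m, g in truth.items() if g == "HG-1")
    hg2_male = next(m for m, g in truth.items() if g == "HG-2")
    outgroup = {div[0]: frame.loc[hg2_male, div[0]], div[1]: frame.loc[hg2_male, div[1]],
                div[2]: frame.loc[hg1_male, div[2]], div[3]: frame.loc[hg1_male, div[3]]}
    winner, _ = ht.ancestral_assignment(part, hm, outgroup)
    assert winner is None


def test_unknown_outgroup_positions_ignored():
    hm, truth, div, part = _partitioned_hm()
    winner, report = ht.ancestral_assignment(part, hm, {999_999: "A"})
    assert winner is None and len(report) == 0
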