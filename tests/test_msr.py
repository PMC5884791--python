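import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from sexlinkit import msr
from sexlinkit.config import SDY_CONTIG
from sexlinkit.msr import _RECORD_COLUMNS


def _recset(rows, lengths=None):
    records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    lengths = lengths or {SDY_CONTIG: 20_000, "Ssa02": 500_000, "Ssa03": 500_000, "Ssa06": 500_000}
    return msr.AlignmentRecordSet(records=records, contig_lengths=lengths)


def _row(sample, contig, pos, mate_contig=None, mate_pos=None, read_len=150,
         mapq=60, is_reverse=False, is_read1=True, tlen=400, proper=True, qname=None):
    mate_contig = mate_contig or contig
    mate_pos = mate_pos if mate_pos is not None else pos + 250
    return (qname or f"{sample}:{pos}", sample, contig, pos, mapq, is_reverse,
            is_read1, read_len, mate_contig, mate_pos, tlen, proper)


# ---------------------------------------------------------------- depth
def test_single_read_depth_vector():
    rec = _recset([_row("s1", SDY_CONTIG, 1)])
    prof = msr.depth_profile(rec, SDY_CONTIG, samples=["s1"])
    d = prof.depth["s1"]
    assert d[:150].sum() == 150 and d[150:].sum() == 0


def test_no_reads_gives_zero_vector():
    rec = _recset([_row("s1", "Ssa02", 10)])
    prof = msr.depth_profile(rec, SDY_CONTIG, samples=["s1"])
    assert prof.depth["s1"].sum() == 0


def test_unknown_contig_rejected():
    rec = _recset([_row("s1", SDY_CONTIG, 1)])
    with pytest.raises(KeyError):
        rec.on_contig("chrUn")


def test_simulated_coverage_matches_poisson_mean(default_cfg, default_pop, panel_records):
    sample = default_pop.truth.seq_females[0]
    prof = msr.depth_profile(panel_records, "Ssa02", samples=[sample])
    window = prof.depth[sample][500:19_000]
    assert abs(window.mean() - default_cfg.coverage_mean) < 1.0


# ---------------------------------------------------------------- junction
def _step_profiles(junction, length=20_000, male_low=20.0, male_high=40.0, female_high=40.0):
    male = np.full(length, male_high)
    male[:junction] = male_low
    female = np.full(length, female_high)
    female[:junction] = 0.0
    return [male], [female]


def test_junction_found_on_clean_step():
    males, females = _step_profiles(13_333)
    j = msr.detect_junction(males, females)
    assert abs(j - 13_333) <= 100


def test_junction_shift_equivariance():
    males, females = _step_profiles(13_333)
    j0 = msr.detect_junction(males, females)
    delta = 1_500
    males2 = [np.roll(males[0], delta)]
    females2 = [np.roll(females[0], delta)]
    males2[0][:delta] = males[0][0]
    females2[0][:delta] = females[0][0]
    j1 = msr.detect_junction(males2, females2)
    assert j1 == j0 + delta


def test_no_junction_when_sexes_have_equal_coverage():
    male = [np.full(20_000, 40.0)]
    female = [np.full(20_000, 40.0)]
    with pytest.raises(msr.JunctionNotFoundError):
        msr.detect_junction(male, female)


def test_no_junction_when_females_have_no_coverage():
    male = [np.full(20_000, 40.0)]
    female = [np.zeros(20_000)]
    with pytest.raises(msr.JunctionNotFoundError):
        msr.detect_junction(male, female)


# ---------------------------------------------------------------- lineage
def test_six_orphans_split_four_two_gives_both_candidates():
    """Four mates on the Ssa03 proxy and two on Ssa06: both chromosomes
    remain candidates, mirroring a translocated-male read pattern."""
    junction = 13_333
    rows = []
    for i in range(4):
        rows.append(_row("m", SDY_CONTIG, junction - 200 - i * 10, "Ssa03", 100_000,
                         proper=False, qname=f"o{i}"))
    for i in range(2):
        rows.append(_row("m", SDY_CONTIG, junction - 500 - i * 10, "Ssa06", 400_000,
                         proper=False, qname=f"p{i}"))
    call = msr.classify_sex_lineage(_recset(rows), "m", junction, 400, 50)
    assert call.call == "translocated"
    assert call.candidates == ("Ssa03", "Ssa06")
    assert call.orphan_tally == {"Ssa03": 4, "Ssa06": 2}


def test_ten_spanning_pairs_give_anchored_call():
    junction = 13_333
    rows = []
    for i in range(10):
        s = junction - 200 - i
        e = s + 399
        rows.append(_row("m", SDY_CONTIG, s, mate_pos=e - 149, tlen=400,
                         is_reverse=False, is_read1=True, qname=f"sp{i}"))
        rows.append(_row("m", SDY_CONTIG, e - 149, mate_pos=s, tlen=-400,
                         is_reverse=True, is_read1=False, qname=f"sp{i}"))
    call = msr.classify_sex_lineage(_recset(rows), "m", junction, 400, 50)
    assert call.call == "anchored" and call.spanning_pairs == 10


def test_no_msr_reads_gives_unassigned():
    rows = [_row("m", SDY_CONTIG, 15_000)]
    call = msr.classify_sex_lineage(_recset(rows), "m", 13_333, 400, 50)
    assert call.call == "unassigned" and call.candidates == ()


def test_low_mapq_reads_ignored():
    junction = 13_333
    rows = [
        _row("m", SDY_CONTIG, junction - 300, "Ssa03", 1_000, proper=False, mapq=5,
             qname=f"q{i}")
        for i in range(5)
    ]
    call = msr.classify_sex_lineage(_recset(rows), "m", junction, 400, 50)
    assert call.call == "unassigned"


# ---------------------------------------------------------------- BAF
def test_baf_values_from_allele_depths():
    table = make_table(
        [(SDY_CONTIG, 7_640, "A", "C", 60.0)],
        ["m1"],
        [[2]],
        dp=[[15]],
        ad_alt=[[14]],
    )
    baf = msr.compute_baf(table, SDY_CONTIG)
    assert baf.iloc[0, 0] == pytest.approx(14 / 15, abs=5e-4)  # 0.933


def test_baf_zero_one_and_undefined():
    table = make_table(
        [(SDY_CONTIG, 1, "A", "C", 60.0), (SDY_CONTIG, 2, "A", "C", 60.0),
         (SDY_CONTIG, 3, "A", "C", 60.0)],
        ["m1"],
        [[0], [2], [-1]],
        dp=[[20], [20], [0]],
        ad_alt=[[0], [20], [0]],
    )
    baf = msr.compute_baf(table)
    assert baf.iloc[0, 0] == 0.0
    assert baf.iloc[1, 0] == 1.0
    assert np.isnan(baf.iloc[2, 0])


def test_baf_rejects_ad_exceeding_dp():
    table = make_table(
        [(SDY_CONTIG, 1, "A", "C", 60.0)], ["m1"], [[2]], dp=[[10]], ad_alt=[[11]]
    )
    table.ad_ref[:] = 0
    with pytest.raises(ValueError):
        msr.compute_baf(table)


# ---------------------------------------------------------------- MSR sites
def _presence_table(n_males=100, female_called=0, male_frac=1.0):
    males = [f"m{i}" for i in range(n_males)]
    females = ["f1", "f2"]
    samples = males + females
    n_called_males = int(round(male_frac * n_males))
    dp_row = [20] * n_called_males + [0] * (n_males - n_called_males)
    dp_row += [20] * female_called + [0] * (2 - female_called)
    gt_row = [2 if d else -1 for d in dp_row]
    table = make_table(
        [(SDY_CONTIG, 5_000, "A", "C", 60.0)],
        samples,
        [gt_row],
        dp=[dp_row],
        ad_alt=[[d for d in dp_row]],
    )
    return table, males, females


@pytest.mark.parametrize(
    "female_called,male_frac,expected",
    [
        (0, 1.0, True),
        (1, 1.0, False),  # called in one female: excluded
        (0, 0.94, False),  # below the 95% male-presence boundary
        (0, 0.95, True),
    ],
)
def test_msr_site_definition_boundaries(female_called, male_frac, expected):
    table, males, females = _presence_table(
        female_called=female_called, male_frac=male_frac
    )
    sites = msr.define_msr_sites(table, males, females)
    assert (len(sites) == 1) is expected


# ---------------------------------------------------------------- hemizygosity
def test_hemizygosity_fraction_counts_exact_zero_one():
    idx = pd.MultiIndex.from_tuples(
        [(SDY_CONTIG, i + 1) for i in range(300)], names=["chrom", "pos"]
    )
    values = np.ones((300, 1))
    values[0, 0] = 0.933  # one genotype carrying a stray read
    baf = pd.DataFrame(values, index=idx, columns=["m1"])
    frac, _ = msr.hemizygosity_report(
        baf, [(SDY_CONTIG, i + 1) for i in range(300)], ["m1"]
    )
    assert frac == pytest.approx(299 / 300)


def test_hemizygosity_requires_sites():
    baf = pd.DataFrame()
    with pytest.raises(ValueError):
        msr.hemizygosity_report(baf, [], ["m1"])


def test_male_depth_ratio_close_to_half(default_cfg, default_pop, default_table, panel_records):
    truth = default_pop.truth
    baf = msr.compute_baf(default_table, SDY_CONTIG)
    sites = [(SDY_CONTIG, p) for p in truth.msr_sites]
    _, ratios = msr.hemizygosity_report(
        baf, sites, truth.seq_males, records=panel_records,
        msr_start=default_cfg.msr_start, junction=truth.junction_pos,
    )
    mean_ratio = np.mean(list(ratios.values()))
    assert abs(mean_ratio - 0.5) < 0.05


# ---------------------------------------------------------------- SAM round trip
def test_sam_round_trip(tmp_path, default_cfg, default_pop):
    from sexlinkit import synthetic_data as sd

    truth = default_pop.truth
    rec = sd.simulate_alignments(
        default_cfg, truth, samples=[truth.seq_males[0]], contigs=[SDY_CONTIG]
    )
    path = tmp_path / "out.sam"
    rec.to_sam(path)
    back = msr.AlignmentRecordSet.from_sam(path)
    assert len(back.records) == len(rec.records)
    for col in ("contig", "pos", "mapq", "mate_contig", "mate_pos", "proper", "read_len"):
        np.testing.assert_array_equal(
            back.records[col].to_numpy(), rec.records[col].to_numpy(), err_msg=col
        )
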