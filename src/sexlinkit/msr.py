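"""Male-specific region (MSR) delineation and hemizygosity analysis.

Males carry a single copy of the chromosomal segment containing the sdY
master sex gene, so on the sdY-bearing contig their read depth halves across
the MSR while females drop to zero.  The boundary with the male-female common
region (MFCR, present in both sexes) is recovered as a change-point in the
female/male depth ratio.  Mate-pair architecture around that junction then
distinguishes males whose cassette is anchored in the contiguous reference
sequence (SL-02-like, junction-spanning proper pairs) from males carrying a
translocated cassette (orphan reads whose mates land on another chromosome).
B-allele frequency over MSR sites provides the hemizygosity test: a
single-copy region can only show BAF values of exactly 0 or 1.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "AlignmentRecordSet",
    "DepthProfile",
    "LineageCall",
    "JunctionNotFoundError",
    "depth_profile",
    "genomewide_mean_depth",
    "detect_junction",
    "classify_sex_lineage",
    "compute_baf",
    "define_msr_sites",
    "hemizygosity_report",
]

_RECORD_COLUMNS = [
    "qname",
    "sample",
    "contig",
    "pos",
    "mapq",
    "is_reverse",
    "is_read1",
    "read_len",
    "mate_contig",
    "mate_pos",
    "tlen",
    "proper",
]


class JunctionNotFoundError(RuntimeError):
    """No change-point satisfying the low/high depth-ratio contract exists."""


@dataclass
class AlignmentRecordSet:
    """Paired-end read placements (already mapped; 1-based leftmost positions).

    ``records`` columns: qname, sample, contig, pos, mapq, is_reverse,
    is_read1, read_len, mate_contig, mate_pos, tlen, proper.
    """

    records: pd.DataFrame
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in _RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"alignment records missing columns: {missing}")
        if len(self.records) and int(self.records["pos"].min()) < 1:
            raise ValueError("alignment positions are 1-based (pos >= 1)")

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.records[self.records["sample"] == sample]

    def on_contig(self, contig: str) -> pd.DataFrame:
        if contig not in self.contig_lengths:
            raise KeyError(f"unknown contig {contig!r}")
        return self.records[self.records["contig"] == contig]

    # --- SAM round-trip -------------------------------------------------
    def to_sam(self, path: str | Path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": int(length)}
                for name, length in self.contig_lengths.items()
            ],
            "RG": [{"ID": s, "SM": s} for s in self.samples],
        }
        order = {name: i for i, name in enumerate(self.contig_lengths)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for row in self.records.itertuples(index=False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = row.qname
                a.flag = (
                    0x1
                    | (0x2 if row.proper else 0)
                    | (0x10 if row.is_reverse else 0x20)
                    | (0x40 if row.is_read1 else 0x80)
                )
                a.reference_id = order[row.contig]
                a.reference_start = int(row.pos) - 1
                a.mapping_quality = int(row.mapq)
                a.cigarstring = f"{int(row.read_len)}M"
                a.next_reference_id = order[row.mate_contig]
                a.next_reference_start = int(row.mate_pos) - 1
                a.template_length = int(row.tlen)
                a.query_sequence = None
                a.set_tag("RG", row.sample)
                out.write(a)

    @classmethod
    def from_sam(cls, path: str | Path) -> "AlignmentRecordSet":
        rows = []
        with pysam.AlignmentFile(str(path), "r") as fh:
            lengths = dict(zip(fh.references, fh.lengths))
            for a in fh:
                rows.append(
                    (
                        a.query_name,
                        a.get_tag("RG") if a.has_tag("RG") else "NA",
                        a.reference_name,
                        a.reference_start + 1,
                        a.mapping_quality,
                        a.is_reverse,
                        a.is_read1,
                        a.query_length or a.infer_query_length() or 0,
                        a.next_reference_name,
                        a.next_reference_start + 1,
                        a.template_length,
                        a.is_proper_pair,
                    )
                )
        records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
        return cls(records=records, contig_lengths={k: int(v) for k, v in lengths.items()})


@dataclass
class DepthProfile:
    """Per-base depth vectors over one contig plus genome-wide mean depths."""

    contig: str
    depth: dict[str, np.ndarray]  # sample -> vector of length contig_length
    genome_mean: dict[str, float]  # sample -> mean depth over aligned footprint

    def mean_vector(self, samples: Sequence[str] | None = None) -> np.ndarray:
        keys = list(self.depth) if samples is None else list(samples)
        return np.mean([self.depth[s] for s in keys], axis=0)


def _depth_vector(sub: pd.DataFrame, length: int) -> np.ndarray:
    depth = np.zeros(length + 2, dtype=np.int64)  # 1-based; slot 0 unused
    if len(sub):
        start = sub["pos"].to_numpy(np.int64)
        end = np.minimum(start + sub["read_len"].to_numpy(np.int64), length + 1)
        np.add.at(depth, start, 1)
        np.add.at(depth, end, -1)
        depth = np.cumsum(depth)
    return depth[1 : length + 1]


def depth_profile(
    records: AlignmentRecordSet,
    contig: str,
    samples: Sequence[str] | None = None,
    min_mapq: int = 20,
) -> DepthProfile:
    """Per-base coverage on ``contig`` for each sample (reads with mapq >= cut)."""
    sub = records.on_contig(contig)
    sub = sub[sub["mapq"] >= min_mapq]
    if samples is None:
        samples = records.samples
    if not len(records.records[records.records["sample"].isin(samples)]):
        raise ValueError(f"no records for requested samples on {contig!r}")
    length = records.contig_lengths[contig]
    depth = {
        s: _depth_vector(sub[sub["sample"] == s], length).astype(float) for s in samples
    }
    gmean = genomewide_mean_depth(records, samples=samples, min_mapq=min_mapq)
    return DepthProfile(contig=contig, depth=depth, genome_mean=gmean)


def genomewide_mean_depth(
    records: AlignmentRecordSet,
    samples: Sequence[str] | None = None,
    min_mapq: int = 20,
    exclude: Sequence[str] = (),
) -> dict[str, float]:
    """Mean depth per sample over the aligned footprint of all contigs.

    The footprint of a contig is [min start, max end] of its reads, so a
    simulation that covers only a window of each chromosome is averaged over
    the covered span rather than diluted by untouched sequence.
    """
    if samples is None:
        samples = records.samples
    sub = records.records[records.records["mapq"] >= min_mapq]
    sub = sub[sub["proper"]]  # stray orphan mates would distort the footprint
    sub = sub[~sub["contig"].isin(exclude)]
    out: dict[str, float] = {}
    for s in samples:
        ssub = sub[sub["sample"] == s]
        total_bp = 0
        total_span = 0
        for contig, csub in ssub.groupby("contig", observed=True):
            lo = int(csub["pos"].min())
            hi = int((csub["pos"] + csub["read_len"]).max()) - 1
            hi = min(hi, records.contig_lengths.get(contig, hi))
            total_bp += int(csub["read_len"].sum())
            total_span += hi - lo + 1
        out[s] = total_bp / total_span if total_span else 0.0
    return out


# ----------------------------------------------------------------------
def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(float)
    kernel = np.ones(width)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def detect_junction(
    male_profiles: DepthProfile | Sequence[np.ndarray],
    female_profiles: DepthProfile | Sequence[np.ndarray],
    smooth_bp: int = 201,
    min_run_bp: int = 500,
    low_max: float = 0.25,
    high_min: float = 0.5,
    eps: float = 1e-9,
    ratio_cap: float = 2.0,
) -> int:
    """Locate the MSR-MFCR boundary from male vs female depth.

    The female/male mean-depth ratio is smoothed by a centered moving average
    and fit with a two-segment piecewise-constant model.  Among split points
    whose left segment is low (mean < ``low_max``), right segment is high
    (mean > ``high_min``) and both segments span at least ``min_run_bp``, the
    split minimizing total squared error is returned as the last base of the
    low (male-specific) segment.
    """

    def _vectors(profiles):
        if isinstance(profiles, DepthProfile):
            return list(profiles.depth.values())
        return [np.asarray(v, dtype=float) for v in profiles]

    male = _vectors(male_profiles)
    female = _vectors(female_profiles)
    if not male or not female:
        raise ValueError("need at least one male and one female profile")
    mm = np.mean(male, axis=0)
    mf = np.mean(female, axis=0)
    # capped so that near-zero male depth at contig edges cannot dominate
    ratio = np.minimum(mf / np.maximum(mm, eps), ratio_cap)
    y = _smooth(ratio, smooth_bp)
    n = y.size
    if n < 2 * min_run_bp:
        raise JunctionNotFoundError("profile shorter than twice the minimum run")

    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    k = np.arange(min_run_bp, n - min_run_bp + 1)  # split after base k (1-based)
    left_n = k.astype(float)
    right_n = (n - k).astype(float)
    left_sum = s1[k]
    right_sum = s1[n] - left_sum
    left_mean = left_sum / left_n
    right_mean = right_sum / right_n
    sse = (s2[k] - left_sum**2 / left_n) + (s2[n] - s2[k] - right_sum**2 / right_n)
    valid = (left_mean < low_max) & (right_mean > high_min)
    if not valid.any():
        raise JunctionNotFoundError(
            "no split separates a low (MSR) segment from a high (MFCR) segment"
        )
    best = k[valid][np.argmin(sse[valid])]
    return int(best)


# ----------------------------------------------------------------------
@dataclass
class LineageCall:
    """Sex-lineage evidence for one male from mate-pair architecture."""

    animal: str
    call: str  # 'anchored' | 'translocated' | 'unassigned'
    candidates: tuple[str, ...] = ()
    spanning_pairs: int = 0
    orphan_tally: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.call == "translocated" and not self.candidates:
            raise ValueError("translocated call requires a candidate chromosome set")


def classify_sex_lineage(
    records: AlignmentRecordSet,
    animal: str,
    junction: int,
    insert_mean: float = 400.0,
    insert_sd: float = 50.0,
    contig: str = "sdY_contig",
    min_span_pairs: int = 3,
    orphan_window_bp: int = 2_000,
    min_orphans: int = 2,
    min_mapq: int = 20,
    span_margin_bp: int | None = None,
) -> LineageCall:
    """Classify one male as anchored (SL-02-like) or translocated.

    A junction-spanning pair has its mates on opposite sides of the junction
    in FR orientation with an implied insert within ``insert_mean +/- 3 sd``
    and both reads at or above ``min_mapq``; the implied fragment must cross
    the junction by ``span_margin_bp`` on each side (default: half a read
    length) so that a small error in the estimated junction cannot turn
    ordinary one-sided pairs into spanning evidence.  Failing the
    spanning-pair criterion, reads inside the MSR within ``orphan_window_bp``
    of the junction whose mates map to a different contig vote for candidate
    chromosomes; any chromosome collecting >= ``min_orphans`` mates enters
    the candidate set.
    """
    sub = records.on_contig(contig)
    sub = sub[(sub["sample"] == animal) & (sub["mapq"] >= min_mapq)]

    same = sub[sub["mate_contig"] == contig]
    left = np.minimum(same["pos"], same["mate_pos"])
    right = np.maximum(same["pos"], same["mate_pos"])
    implied = right + same["read_len"] - left
    if span_margin_bp is None:
        read_len = int(same["read_len"].max()) if len(same) else 150
        span_margin_bp = read_len // 2
    fr_ok = np.where(same["pos"] <= same["mate_pos"], ~same["is_reverse"], same["is_reverse"])
    spans = (
        (left <= junction - span_margin_bp)
        & (right + same["read_len"] - 1 >= junction + span_margin_bp)
        & (np.abs(implied - insert_mean) <= 3 * insert_sd)
        & same["proper"]
        & fr_ok
    )
    n_span = int(same.loc[spans, "qname"].nunique())

    window_lo = junction - orphan_window_bp
    orphans = sub[
        (sub["pos"] >= window_lo)
        & (sub["pos"] <= junction)
        & (sub["mate_contig"] != contig)
    ]
    tally = orphans["mate_contig"].value_counts().to_dict()

    if n_span >= min_span_pairs:
        return LineageCall(animal, "anchored", (), n_span, tally)
    candidates = tuple(sorted(c for c, n in tally.items() if n >= min_orphans))
    if candidates:
        return LineageCall(animal, "translocated", candidates, n_span, tally)
    return LineageCall(animal, "unassigned", (), n_span, tally)


# ----------------------------------------------------------------------
def compute_baf(table, contig: str | None = None) -> pd.DataFrame:
    """B-allele frequency (alt depth / total depth) per site and sample.

    Returns a DataFrame indexed by (chrom, pos) with one column per sample;
    entries are NaN where depth is zero (BAF undefined).
    """
    mask = np.ones(len(table.sites), dtype=bool)
    if contig is not None:
        mask = (table.sites["chrom"] == contig).to_numpy()
    ad_alt = table.ad_alt[mask].astype(float)
    dp = table.dp[mask].astype(float)
    if (ad_alt > dp).any():
        raise ValueError("alternate allele depth exceeds total depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(dp > 0, ad_alt / dp, np.nan)
    idx = pd.MultiIndex.from_frame(table.sites.loc[mask, ["chrom", "pos"]])
    return pd.DataFrame(baf, index=idx, columns=table.samples)


def define_msr_sites(
    table,
    males: Sequence[str],
    females: Sequence[str],
    contig: str | None = None,
    male_presence_min: float = 0.95,
    min_dp: int = 5,
) -> list[tuple[str, int]]:
    """Sites called (dp >= min_dp) in no female and in >= 95% of males."""
    if not len(males) or not len(females):
        raise ValueError("need at least one male and one female")
    mask = np.ones(len(table.sites), dtype=bool)
    if contig is not None:
        mask = (table.sites["chrom"] == contig).to_numpy()
    midx = [table.samples.index(s) for s in males]
    fidx = [table.samples.index(s) for s in females]
    called = table.dp >= min_dp
    female_absent = ~called[:, fidx].any(axis=1)
    male_presence = called[:, midx].mean(axis=1)
    keep = mask & female_absent & (male_presence >= male_presence_min)
    return [
        (str(c), int(p))
        for c, p in table.sites.loc[keep, ["chrom", "pos"]].itertuples(index=False)
    ]


def hemizygosity_report(
    baf: pd.DataFrame,
    msr_sites: Sequence[tuple[str, int]],
    males: Sequence[str],
    records: AlignmentRecordSet | None = None,
    contig: str = "sdY_contig",
    msr_start: int = 2_001,
    junction: int | None = None,
    min_mapq: int = 20,
) -> tuple[float, dict[str, float]]:
    """Fraction of male MSR genotypes with BAF exactly 0 or 1, plus depth ratios.

    Membership in {0, 1} is exact (no tolerance): a single stray read moves a
    genotype out of the homozygous classes.  When ``records`` is given, the
    per-male ratio of mean MSR depth to genome-wide mean depth is reported
    (expected ~0.5 for a hemizygous region).
    """
    if not len(msr_sites):
        raise ValueError("no MSR sites defined")
    idx = pd.MultiIndex.from_tuples(msr_sites, names=["chrom", "pos"])
    sub = baf.loc[baf.index.isin(idx), list(males)]
    values = sub.to_numpy(float)
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("no defined BAF values at MSR sites")
    homo = (values == 0.0) | (values == 1.0)
    fraction = float(homo[defined].sum() / defined.sum())

    ratios: dict[str, float] = {}
    if records is not None:
        end = junction if junction is not None else max(p for _, p in msr_sites)
        prof = depth_profile(records, contig, samples=list(males), min_mapq=min_mapq)
        gmean = genomewide_mean_depth(
            records, samples=list(males), min_mapq=min_mapq, exclude=(contig,)
        )
        for s in males:
            msr_mean = float(prof.depth[s][msr_start - 1 : end].mean())
            g = gmean[s]
            ratios[s] = msr_mean / g if g else float("nan")
    return fraction, ratios
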