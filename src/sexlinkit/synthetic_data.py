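"""Synthetic cohort generator for sex-determination analyses.

Generates every input the downstream stages consume — reference sequences, a
structured multi-population genotype matrix, mapped paired-end alignment
records around the MSR-MFCR junction, a variant table with allele depths,
array genotypes with sdY presence assays, and a ground-truth record — with
the statistical structure the analyses assume:

* three populations drifted from a common ancestor (Balding-Nichols model);
* three male-heterogametic sex lineages, each anchoring the sdY cassette to a
  haplotype block on its own chromosome;
* homeologous (residually tetrasomic) chromosome blocks whose genotypes are
  correlated across chromosomes, producing non-syntenic LD;
* double-haploid females, homozygous everywhere except planted artifact
  sites that mimic collapsed paralogs;
* male read depth halving across the MSR, junction-spanning proper pairs for
  cassette-anchored (SL-02-like) males and junction-adjacent orphan reads
  with mates on the cassette's host chromosome for translocated lineages.

All randomness flows from ``SimConfig.seed`` through fixed per-stage
substreams, so identical configurations give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .config import SDY_CONTIG, ConfigError, SdLocus, SimConfig, TruthRecord, write_truth
from .haplotree import NO_CALL, HaplotypeMatrix
from .msr import AlignmentRecordSet, _RECORD_COLUMNS
from .variant_qc import MISSING, VariantTable

__all__ = [
    "PopulationSim",
    "build_reference",
    "write_reference",
    "simulate_population",
    "simulate_alignments",
    "simulate_variant_table",
    "simulate_array_genotypes",
    "simulate_msr_haplotypes",
    "simulate_all",
    "write_truth",
]

# fixed substream offsets; each stage draws from its own child generator
_S_REF, _S_POP, _S_ALN, _S_VCF, _S_ARR = range(5)
_BASES = np.array(["A", "C", "G", "T"])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ----------------------------------------------------------------------
def build_reference(config: SimConfig) -> list[SeqRecord]:
    """Random reference: one sequence per chromosome plus the sdY contig."""
    if config.msr_end > config.sdy_contig_length_bp:
        raise ConfigError("sdY contig shorter than the MSR interval")
    rng = _rng(config, _S_REF)
    records = []
    for name, length in config.contig_lengths.items():
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    return records


def write_reference(records: Sequence[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        seqio_write(list(records), fh, "fasta")


# ----------------------------------------------------------------------
@dataclass
class PopulationSim:
    """Genotypes, sample sheet and truth for one simulated cohort."""

    sites: pd.DataFrame  # chrom, pos, ref, alt, kind
    samples: list[str]
    genotypes: np.ndarray  # (n_sites, n_samples) int8 dosage, -1 missing
    sample_sheet: pd.DataFrame
    truth: TruthRecord
    outgroup_alleles: dict[int, str]

    def dosage_frame(
        self, samples: Sequence[str] | None = None, contig_sites: bool = True
    ) -> pd.DataFrame:
        cols = list(self.samples) if samples is None else list(samples)
        idx = [self.samples.index(s) for s in cols]
        d = self.genotypes[:, idx].astype(float)
        d[d == MISSING] = np.nan
        frame = pd.DataFrame(
            d,
            index=pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]]),
            columns=cols,
        )
        if not contig_sites:
            frame = frame[frame.index.get_level_values(0) != SDY_CONTIG]
        return frame


def _haplotype_alleles(
    rng: np.random.Generator,
    groups: Sequence[str],  # 'HG-1' or 'HG-2' per male
    n_sites: int,
    divergent_fraction: float,
    within_flip: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Hemizygous MSR haplotypes as 0 (ancestral/ref) / 1 (derived/alt) codes.

    HG-2 descends from the ancestral haplotype (all-reference); HG-1 carries
    the alternate allele at a ``divergent_fraction`` of sites.  Each male's
    haplotype then flips state at each site with probability ``within_flip``
    (within-haplogroup diversity).
    """
    n_div = int(round(divergent_fraction * n_sites))
    divergent = np.zeros(n_sites, dtype=bool)
    divergent[rng.choice(n_sites, size=n_div, replace=False)] = True
    base = {"HG-2": np.zeros(n_sites, dtype=np.int8), "HG-1": divergent.astype(np.int8)}
    out = np.empty((len(groups), n_sites), dtype=np.int8)
    for i, g in enumerate(groups):
        flips = rng.random(n_sites) < within_flip
        out[i] = np.where(flips, 1 - base[g], base[g])
    return out, divergent


def simulate_msr_haplotypes(
    n_hg1: int,
    n_hg2: int,
    n_sites: int = 22,
    divergent_fraction: float = 0.8,
    within_flip: float = 0.03,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, dict[str, str], list[int]]:
    """Standalone two-haplogroup MSR haplotype matrix (for recovery studies)."""
    rng = np.random.default_rng(seed)
    males = [f"HG1_{i + 1:02d}" for i in range(n_hg1)] + [
        f"HG2_{i + 1:02d}" for i in range(n_hg2)
    ]
    groups = ["HG-1"] * n_hg1 + ["HG-2"] * n_hg2
    codes, divergent = _haplotype_alleles(rng, groups, n_sites, divergent_fraction, within_flip)
    ref = _BASES[rng.integers(0, 4, n_sites)]
    alt = np.array([_BASES[_BASES != r][rng.integers(0, 3)] for r in ref])
    alleles = np.where(codes == 0, ref[None, :], alt[None, :]).astype("<U1")
    positions = sorted(rng.choice(np.arange(2_001, 13_334), size=n_sites, replace=False).tolist())
    hm = HaplotypeMatrix(males=males, sites=[int(p) for p in positions], alleles=alleles)
    truth = dict(zip(males, groups))
    div_positions = [int(p) for p, d in zip(positions, divergent) if d]
    return hm, truth, div_positions


# ----------------------------------------------------------------------
def simulate_population(config: SimConfig) -> PopulationSim:
    """Genotype matrix, sample sheet and ground truth for the full cohort."""
    rng = _rng(config, _S_POP)
    pops = list(config.pop_sizes)

    # --- samples, sexes, lineages -------------------------------------
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    gsex: dict[str, str] = {}
    for pop in pops:
        size = config.pop_sizes[pop]
        ids = [f"{pop}_{i + 1:03d}" for i in range(size)]
        male_idx = set(rng.choice(size, size=size // 2, replace=False).tolist())
        for i, s in enumerate(ids):
            samples.append(s)
            pop_of[s] = pop
            gsex[s] = "male" if i in male_idx else "female"
    dh_samples = [f"DH_{i + 1:02d}" for i in range(config.n_dh_females)]
    for s in dh_samples:
        samples.append(s)
        pop_of[s] = pops[0]
        gsex[s] = "female"

    males = [s for s in samples if gsex[s] == "male"]
    lineage_by_male: dict[str, str] = {}
    if config.sd_loci:
        props = np.array([sl.proportion for sl in config.sd_loci])
        draws = rng.choice(len(config.sd_loci), size=len(males), p=props)
        lineage_by_male = {m: config.sd_loci[k].lineage for m, k in zip(males, draws)}

    psex = {}
    flips = rng.random(len(samples)) < config.psex_discordance_rate
    for s, flip in zip(samples, flips):
        truth_sex = gsex[s]
        psex[s] = ({"male": "female", "female": "male"}[truth_sex] if flip else truth_sex)

    # --- site catalogue -------------------------------------------------
    rows: list[tuple] = []  # (chrom, pos, kind, sd_index)
    taken: set[tuple[str, int]] = set()

    def add_site(chrom: str, pos: int, kind: str, sd_index: int = -1) -> bool:
        key = (chrom, int(pos))
        if key in taken:
            return False
        taken.add(key)
        rows.append((chrom, int(pos), kind, sd_index))
        return True

    for k, sl in enumerate(config.sd_loci):
        half = config.sd_block_snps // 2
        span = config.sd_block_span_bp // 2
        lo = max(1, sl.pos - span)
        hi = min(config.chrom_length_bp, sl.pos + span)
        add_site(sl.chrom, sl.pos, "sd", k)
        left = rng.choice(np.arange(lo, sl.pos), size=max(half - 1, 0), replace=False)
        right = rng.choice(np.arange(sl.pos + 1, hi + 1), size=config.sd_block_snps - half, replace=False)
        for p in np.concatenate([left, right]):
            add_site(sl.chrom, int(p), "sd", k)

    for chrom in config.chrom_names:
        pos = rng.choice(np.arange(1, config.chrom_length_bp + 1), size=config.snps_per_chrom, replace=False)
        for p in np.sort(pos):
            add_site(chrom, int(p), "background")

    for i in range(config.n_artifact_sites):
        chrom = config.chrom_names[i % len(config.chrom_names)]
        while not add_site(chrom, int(rng.integers(1, config.chrom_length_bp + 1)), "artifact"):
            pass

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "kind", "sd_index"])

    # --- ancestral and per-population frequencies -----------------------
    n_sites = len(sites)
    anc = rng.uniform(0.05, 0.95, n_sites)
    sd_mask = (sites["kind"] == "sd").to_numpy()
    anc[sd_mask] = rng.uniform(*config.sd_marker_freq_range, int(sd_mask.sum()))
    pop_freq: dict[str, np.ndarray] = {}
    for pop in pops:
        F = config.fst_drift.get(pop, 0.0)
        if F <= 0:
            pop_freq[pop] = anc.copy()
        else:
            shape = (1 - F) / F
            pop_freq[pop] = rng.beta(anc * shape, (1 - anc) * shape)
    pmat = np.column_stack([pop_freq[pop_of[s]] for s in samples])

    # --- genotypes -------------------------------------------------------
    geno = rng.binomial(2, pmat).astype(np.int8)
    dh_cols = np.array([samples.index(s) for s in dh_samples], dtype=int)
    if len(dh_cols):
        geno[:, dh_cols] = (2 * rng.binomial(1, pmat[:, dh_cols])).astype(np.int8)

    # sdY cassette carriers: one haplotype bears the marker allele at every
    # site of the lineage's anchor block (dosage = 1 + Bernoulli(p))
    for k, sl in enumerate(config.sd_loci):
        block = np.flatnonzero((sites["sd_index"] == k).to_numpy())
        carrier_cols = np.array(
            [samples.index(m) for m in males if lineage_by_male.get(m) == sl.lineage],
            dtype=int,
        )
        if len(carrier_cols):
            sub_p = pmat[np.ix_(block, carrier_cols)]
            geno[np.ix_(block, carrier_cols)] = (1 + rng.binomial(1, sub_p)).astype(np.int8)

    artifact_mask = (sites["kind"] == "artifact").to_numpy()
    geno[artifact_mask, :] = 1  # collapsed paralogs look heterozygous in everyone

    # --- homeolog mirroring ---------------------------------------------
    mirror_rows: list[tuple] = []
    mirror_geno: list[np.ndarray] = []
    for hp in config.homeolog_pairs:
        in_block = (
            (sites["chrom"] == hp.chrom_a)
            & (sites["pos"] >= hp.start_a)
            & (sites["pos"] <= hp.end_a)
            & sites["kind"].isin(["background", "sd"])
        ).to_numpy()
        src_idx = np.flatnonzero(in_block)
        is_sd = sites["kind"].to_numpy()[src_idx] == "sd"
        chosen = is_sd | (rng.random(len(src_idx)) < config.homeolog_mirror_fraction)
        for i in src_idx[chosen]:
            pos_b = hp.partner_position(int(sites.at[i, "pos"]))
            if pos_b > config.chrom_length_bp or (hp.chrom_b, pos_b) in taken:
                continue
            taken.add((hp.chrom_b, pos_b))
            copy = rng.random(len(samples)) < hp.rho
            fresh = rng.binomial(2, pmat[i]).astype(np.int8)
            if len(dh_cols):
                fresh[dh_cols] = (2 * rng.binomial(1, pmat[i, dh_cols])).astype(np.int8)
            mirror_rows.append((hp.chrom_b, pos_b, "mirror", int(sites.at[i, "sd_index"])))
            mirror_geno.append(np.where(copy, geno[i], fresh).astype(np.int8))
    if mirror_rows:
        sites = pd.concat(
            [sites, pd.DataFrame(mirror_rows, columns=sites.columns)], ignore_index=True
        )
        geno = np.vstack([geno, np.array(mirror_geno, dtype=np.int8)])

    # --- sdY contig sites -------------------------------------------------
    msr_positions = np.sort(
        rng.choice(np.arange(config.msr_start, config.msr_end + 1), size=config.n_msr_snps, replace=False)
    )
    mfcr_space = np.concatenate(
        [
            np.arange(1, config.msr_start),
            np.arange(config.msr_end + 1, config.sdy_contig_length_bp + 1),
        ]
    )
    mfcr_positions = np.sort(rng.choice(mfcr_space, size=config.n_mfcr_snps, replace=False))

    groups = [("HG-2" if lineage_by_male[m] == "SL-02" else "HG-1") for m in males]
    codes, divergent = _haplotype_alleles(
        rng, groups, config.n_msr_snps, config.msr_divergent_fraction, config.msr_within_flip
    )
    msr_geno = np.full((config.n_msr_snps, len(samples)), MISSING, dtype=np.int8)
    male_cols = np.array([samples.index(m) for m in males], dtype=int)
    msr_geno[:, male_cols] = (2 * codes.T).astype(np.int8)  # hemizygous: rendered hom

    mfcr_p = rng.uniform(0.05, 0.95, config.n_mfcr_snps)
    mfcr_geno = rng.binomial(2, mfcr_p[:, None] * np.ones((1, len(samples)))).astype(np.int8)
    if len(dh_cols):
        mfcr_geno[:, dh_cols] = (
            2 * rng.binomial(1, np.repeat(mfcr_p[:, None], len(dh_cols), axis=1))
        ).astype(np.int8)

    contig_rows = [(SDY_CONTIG, int(p), "msr", -1) for p in msr_positions] + [
        (SDY_CONTIG, int(p), "mfcr", -1) for p in mfcr_positions
    ]
    sites = pd.concat([sites, pd.DataFrame(contig_rows, columns=sites.columns)], ignore_index=True)
    geno = np.vstack([geno, msr_geno, mfcr_geno])

    # ref/alt bases
    ref_idx = rng.integers(0, 4, len(sites))
    alt_shift = rng.integers(1, 4, len(sites))
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[(ref_idx + alt_shift) % 4]

    # outgroup alleles: ancestral (HG-2 / reference) state at a site subset
    div_pos = msr_positions[divergent]
    nondiv_pos = msr_positions[~divergent]
    n_inf = min(config.n_outgroup_informative, len(div_pos))
    n_other = min(config.n_outgroup_sites - n_inf, len(nondiv_pos))
    chosen_pos = np.concatenate(
        [
            rng.choice(div_pos, size=n_inf, replace=False),
            rng.choice(nondiv_pos, size=n_other, replace=False),
        ]
    )
    ref_by_pos = dict(
        zip(sites.loc[sites["chrom"] == SDY_CONTIG, "pos"], sites.loc[sites["chrom"] == SDY_CONTIG, "ref"])
    )
    outgroup = {int(p): str(ref_by_pos[p]) for p in sorted(chosen_pos)}

    # --- final ordering ---------------------------------------------------
    chrom_order = {c: i for i, c in enumerate(list(config.chrom_names) + [SDY_CONTIG])}
    order = sites.assign(_c=sites["chrom"].map(chrom_order)).sort_values(
        ["_c", "pos"], kind="mergesort"
    ).index.to_numpy()
    sites = sites.iloc[order].reset_index(drop=True)[["chrom", "pos", "ref", "alt", "kind", "sd_index"]]
    geno = geno[order]

    # --- sample sheet and truth -------------------------------------------
    sheet = pd.DataFrame(
        {
            "animal": samples,
            "population": [pop_of[s] for s in samples],
            "PSEX": [psex[s] for s in samples],
            "GSEX": [gsex[s] for s in samples],
            "sire": "0",
            "dam": "0",
            "SL_SSR": [lineage_by_male.get(s, "nd") for s in samples],
        }
    )

    tas = pops[0]
    tas_males = [s for s in samples if pop_of[s] == tas and gsex[s] == "male"]
    tas_females = [
        s for s in samples if pop_of[s] == tas and gsex[s] == "female" and s not in dh_samples
    ]
    if len(tas_males) < config.n_seq_males or len(tas_females) < config.n_seq_females:
        raise ConfigError("first population too small for the sequencing panel")

    truth = TruthRecord(
        junction_pos=config.msr_end,
        lineage_by_male=lineage_by_male,
        true_sd_loci=[(sl.chrom, sl.pos) for sl in config.sd_loci],
        artifact_sites=[
            (str(c), int(p))
            for c, p in sites.loc[sites["kind"] == "artifact", ["chrom", "pos"]].itertuples(index=False)
        ],
        homeolog_pairs=list(config.homeolog_pairs),
        gsex=gsex,
        psex=psex,
        dh_samples=dh_samples,
        seq_males=tas_males[: config.n_seq_males],
        seq_females=tas_females[: config.n_seq_females],
        msr_sites=[int(p) for p in msr_positions],
        haplogroup_by_male=dict(zip(males, groups)),
        ancestral_haplogroup="HG-2",
    )
    return PopulationSim(
        sites=sites,
        samples=samples,
        genotypes=geno,
        sample_sheet=sheet,
        truth=truth,
        outgroup_alleles=outgroup,
    )


# ----------------------------------------------------------------------
class _RecordBuffer:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, qname, sample, contig, pos, mapq, is_reverse, is_read1, read_len,
            mate_contig, mate_pos, tlen, proper) -> None:
        self.rows.append(
            (qname, sample, contig, int(pos), int(mapq), bool(is_reverse), bool(is_read1),
             int(read_len), mate_contig, int(mate_pos), int(tlen), bool(proper))
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_RECORD_COLUMNS)


def _fragments(rng, lo: int, hi: int, coverage: float, read_len: int,
               insert_mean: float, insert_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Fragment (start, insert) pairs fully inside [lo, hi] at given coverage."""
    span = hi - lo + 1
    n = rng.poisson(span * coverage / (2.0 * read_len))
    ins = np.clip(np.round(rng.normal(insert_mean, insert_sd, n)).astype(int), 2 * read_len, span)
    start = rng.integers(lo, hi + 1, n)
    start = np.minimum(start, hi - ins + 1)
    return start, ins


def _emit_segment_pairs(buf, rng, sample, contig, tag, lo, hi, coverage,
                        read_len, insert_mean, insert_sd, mapq=60) -> None:
    start, ins = _fragments(rng, lo, hi, coverage, read_len, insert_mean, insert_sd)
    for i, (s, L) in enumerate(zip(start, ins)):
        e = s + L - 1
        q = f"{sample}|{tag}|{i}"
        r2_pos = e - read_len + 1
        buf.add(q, sample, contig, s, mapq, False, True, read_len, contig, r2_pos, L, True)
        buf.add(q, sample, contig, r2_pos, mapq, True, False, read_len, contig, s, -L, True)


def _emit_joined_mfcr_pairs(buf, rng, sample, config, tag, coverage, mapq=60) -> None:
    """Pairs from an MSR-less chromosome copy: the two MFCR flanks are joined.

    Reads map back to reference coordinates; a read straddling the joint is
    split into one piece per flank (mimicking clipped alignment), so female
    depth resumes at full height immediately after the junction.
    """
    left_len = config.msr_start - 1
    right_len = config.sdy_contig_length_bp - config.msr_end
    joined = left_len + right_len
    rl = config.read_len
    start, ins = _fragments(rng, 1, joined, coverage, rl, config.insert_mean, config.insert_sd)

    def mapped(u: int) -> int:
        return u if u <= left_len else config.msr_end + (u - left_len)

    for i, (s, L) in enumerate(zip(start, ins)):
        e = s + L - 1
        q = f"{sample}|{tag}|{i}"
        reads = [(s, True, False), (e - rl + 1, False, True)]
        starts = {True: mapped(s), False: mapped(e - rl + 1)}
        for u, is_read1, is_rev in reads:
            mate_pos = starts[not is_read1]
            u_end = u + rl - 1
            if u <= left_len < u_end:  # split at the joint
                len1 = left_len - u + 1
                buf.add(q, sample, SDY_CONTIG, mapped(u), mapq, is_rev, is_read1, len1,
                        SDY_CONTIG, mate_pos, L, True)
                buf.add(q, sample, SDY_CONTIG, config.msr_end + 1, mapq, is_rev, is_read1,
                        rl - len1, SDY_CONTIG, mate_pos, L, True)
            else:
                buf.add(q, sample, SDY_CONTIG, mapped(u), mapq, is_rev, is_read1, rl,
                        SDY_CONTIG, mate_pos, L, True)


def _emit_cassette_pairs(buf, rng, sample, config, lineage_chrom, anchor_pos,
                         coverage, mapq=60) -> None:
    """Pairs from a translocated MSR cassette hosted on ``lineage_chrom``.

    Fragments extending past the junction put the mate onto the host
    chromosome (or, for a configured minority, onto its homeolog partner),
    producing orphan reads inside the MSR adjacent to the junction.
    """
    rl = config.read_len
    start, ins = _fragments(
        rng, config.msr_start, config.msr_end + int(config.insert_mean),
        coverage, rl, config.insert_mean, config.insert_sd,
    )
    partner = config.homeolog_partner(lineage_chrom) or lineage_chrom
    for i, (s, L) in enumerate(zip(start, ins)):
        if s > config.msr_end:
            continue
        e = s + L - 1
        q = f"{sample}|cassette|{i}"
        if e <= config.msr_end:  # ordinary pair inside the MSR
            r2 = e - rl + 1
            buf.add(q, sample, SDY_CONTIG, s, mapq, False, True, rl, SDY_CONTIG, r2, L, True)
            buf.add(q, sample, SDY_CONTIG, r2, mapq, True, False, rl, SDY_CONTIG, s, -L, True)
        else:  # breakpoint fragment: mate lands on the host chromosome
            len1 = min(rl, config.msr_end - s + 1)
            mate_chrom = partner if rng.random() < config.orphan_minority_fraction else lineage_chrom
            mate_pos = min(anchor_pos + (e - config.msr_end), config.chrom_length_bp)
            buf.add(q, sample, SDY_CONTIG, s, mapq, False, True, len1, mate_chrom, mate_pos, 0, False)
            buf.add(q, sample, mate_chrom, mate_pos, mapq, True, False, rl, SDY_CONTIG, s, 0, False)


def simulate_alignments(
    config: SimConfig,
    truth: TruthRecord,
    samples: Sequence[str] | None = None,
    contigs: Sequence[str] | None = None,
) -> AlignmentRecordSet:
    """Mapped paired-end records for the sequencing panel.

    Per chromosome copy the MFCR is covered at half the total coverage; males
    add one MSR copy at half coverage.  SL-02 males carry the cassette in the
    contiguous contig arrangement (junction-spanning pairs); SL-03/SL-06
    males carry it translocated (orphan reads near the junction).  Each
    chromosome also receives a fully covered background window used for
    genome-wide depth normalisation.
    """
    rng = _rng(config, _S_ALN)
    if samples is None:
        samples = list(truth.seq_males) + list(truth.seq_females)
    unknown = [s for s in samples if s not in truth.gsex]
    if unknown:
        raise KeyError(f"samples absent from truth: {unknown}")
    if contigs is None:
        contigs = [SDY_CONTIG] + list(config.chrom_names)

    anchor_by_lineage = {
        sl.lineage: (sl.chrom, sl.pos) for sl in config.sd_loci
    }
    half = config.coverage_mean / 2.0
    buf = _RecordBuffer()
    for sample in samples:
        sex = truth.gsex[sample]
        if SDY_CONTIG in contigs:
            if sex == "female":
                _emit_joined_mfcr_pairs(buf, rng, sample, config, "x1", half)
                _emit_joined_mfcr_pairs(buf, rng, sample, config, "x2", half)
                if config.female_msr_noise > 0:
                    _emit_segment_pairs(
                        buf, rng, sample, SDY_CONTIG, "noise", config.msr_start,
                        config.msr_end, config.female_msr_noise * config.coverage_mean,
                        config.read_len, config.insert_mean, config.insert_sd,
                    )
            else:
                lineage = truth.lineage_by_male[sample]
                if lineage == "SL-02":
                    _emit_joined_mfcr_pairs(buf, rng, sample, config, "x1", half)
                    _emit_segment_pairs(
                        buf, rng, sample, SDY_CONTIG, "y", 1, config.sdy_contig_length_bp,
                        half, config.read_len, config.insert_mean, config.insert_sd,
                    )
                else:
                    _emit_joined_mfcr_pairs(buf, rng, sample, config, "x1", half)
                    _emit_joined_mfcr_pairs(buf, rng, sample, config, "x2", half)
                    chrom, anchor = anchor_by_lineage[lineage]
                    _emit_cassette_pairs(buf, rng, sample, config, chrom, anchor, half)
        for chrom in config.chrom_names:
            if chrom in contigs:
                hi = min(config.background_window_bp, config.chrom_length_bp)
                _emit_segment_pairs(
                    buf, rng, sample, chrom, f"bg|{chrom}", 1, hi, config.coverage_mean,
                    config.read_len, config.insert_mean, config.insert_sd,
                )
    return AlignmentRecordSet(records=buf.frame(), contig_lengths=config.contig_lengths)


# ----------------------------------------------------------------------
def simulate_variant_table(config: SimConfig, pop: PopulationSim) -> VariantTable:
    """Render the cohort genotypes as calls with allele depths and site MQ.

    Depth is Poisson at the configured coverage, halved for males across MSR
    sites and zero for females there; alternate-allele depth follows the
    genotype (0.5 for hets, the sequencing error rate for homozygotes); DH
    females stay homozygous except at planted artifact sites.
    """
    rng = _rng(config, _S_VCF)
    sites, samples = pop.sites, pop.samples
    n_sites, n_samples = len(sites), len(samples)
    gt = pop.genotypes.copy()

    dp = rng.poisson(config.coverage_mean, size=(n_sites, n_samples)).astype(np.int32)
    msr_rows = np.flatnonzero((sites["kind"] == "msr").to_numpy())
    male_cols = np.array(
        [i for i, s in enumerate(samples) if pop.truth.gsex[s] == "male"], dtype=int
    )
    female_cols = np.array([i for i in range(n_samples) if i not in set(male_cols)], dtype=int)
    if len(msr_rows):
        dp[np.ix_(msr_rows, male_cols)] = rng.poisson(
            config.coverage_mean / 2.0, size=(len(msr_rows), len(male_cols))
        )
        dp[np.ix_(msr_rows, female_cols)] = 0

    gt[dp == 0] = MISSING
    # a sequencing error reads as the *other* called allele only when the
    # substituted base matches it: one of three possible substitutions
    err = config.seq_error_rate / 3.0
    ad_alt = np.where(
        gt == 1,
        rng.binomial(dp, 0.5),
        np.where(gt == 2, dp - rng.binomial(dp, err), rng.binomial(dp, err)),
    ).astype(np.int32)
    ad_alt[gt == MISSING] = 0
    dp_eff = dp.copy()
    ad_ref = np.where(gt == MISSING, 0, dp_eff - ad_alt).astype(np.int32)

    mq = rng.normal(58.0, 3.0, n_sites)
    # artifact (collapsed-paralog) sites map confidently — that is precisely
    # why they need the double-haploid screen rather than an MQ filter
    low = (rng.random(n_sites) < config.low_mq_fraction) & (
        sites["kind"] != "artifact"
    ).to_numpy()
    mq[low] = rng.normal(35.0, 4.0, int(low.sum()))
    mq[(sites["kind"] == "artifact").to_numpy()] = np.maximum(
        mq[(sites["kind"] == "artifact").to_numpy()], 50.0
    )
    out_sites = sites[["chrom", "pos", "ref", "alt"]].copy()
    out_sites["mq"] = np.clip(mq, 0.0, 70.0).round(2)
    out_sites["kind"] = sites["kind"].to_numpy()

    return VariantTable(
        sites=out_sites,
        samples=list(samples),
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp_eff,
        contig_lengths=config.contig_lengths,
    )


# ----------------------------------------------------------------------
def simulate_array_genotypes(
    config: SimConfig, table: VariantTable, truth: TruthRecord
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Array genotypes for a subset of chromosomal sites, plus sdY assay calls.

    Each exported genotype flips to a different dosage class with probability
    ``array_error_rate``.  The three sdY probe assays are positive exactly for
    cassette carriers (no assay noise by default).
    """
    rng = _rng(config, _S_ARR)
    on_chrom = np.flatnonzero((table.sites["chrom"] != SDY_CONTIG).to_numpy())
    n_pick = min(config.n_array_sites, len(on_chrom))
    pick = np.sort(rng.choice(on_chrom, size=n_pick, replace=False))
    dosage = table.gt[pick].astype(float)
    dosage[dosage == MISSING] = np.nan
    flip = (rng.random(dosage.shape) < config.array_error_rate) & ~np.isnan(dosage)
    shift = rng.integers(1, 3, size=dosage.shape)
    dosage = np.where(flip, (dosage + shift) % 3, dosage)
    idx = pd.MultiIndex.from_frame(table.sites.iloc[pick][["chrom", "pos", "ref", "alt"]])
    array = pd.DataFrame(dosage, index=idx, columns=table.samples)

    animals = list(truth.gsex)
    positive = np.array([truth.gsex[a] == "male" for a in animals])
    assays = pd.DataFrame(
        {f"sdY_assay_{k}": positive for k in (1, 2, 3)}, index=animals
    )
    return array, assays


# ----------------------------------------------------------------------
def simulate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    reference = build_reference(config)
    paths["reference"] = outdir / "reference.fa"
    write_reference(reference, paths["reference"])

    pop = simulate_population(config)
    paths["sample_sheet"] = outdir / "samples.tsv"
    pop.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    table = simulate_variant_table(config, pop)
    paths["vcf"] = outdir / "variants.vcf"
    table.to_vcf(paths["vcf"])

    records = simulate_alignments(config, pop.truth)
    paths["sam"] = outdir / "alignments.sam"
    records.to_sam(paths["sam"])

    array, assays = simulate_array_genotypes(config, table, pop.truth)
    paths["array"] = outdir / "array_genotypes.tsv"
    array.to_csv(paths["array"], sep="\t")
    paths["assays"] = outdir / "sdy_assays.tsv"
    assays.to_csv(paths["assays"], sep="\t")

    paths["outgroup"] = outdir / "outgroup_alleles.tsv"
    pd.Series(pop.outgroup_alleles, name="allele").rename_axis("pos").to_csv(
        paths["outgroup"], sep="\t"
    )

    from .leakage import HomeologMap

    paths["homeologs"] = outdir / "homeologs.bed"
    HomeologMap(list(config.homeolog_pairs)).to_bed(paths["homeologs"])

    paths["truth"] = outdir / "truth.json"
    write_truth(pop.truth, paths["truth"])
    return paths
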