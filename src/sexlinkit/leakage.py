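"""Association-signal leakage between homeologous chromosome blocks.

Roughly a quarter of the salmon genome shows delayed rediploidization after
the salmonid whole-genome duplication, so duplicated (homeologous) blocks on
different chromosomes retain correlated allele frequencies.  A sufficiently
strong GWAS signal inside such a block reappears ("leaks") on the partner
block.  This module scans for non-syntenic LD and classifies critical
intervals as true loci versus leakage artifacts: an interval is leakage when
it overlaps the homeolog partner of an already-retained, stronger interval
and the two intervals share enough high-LD SNP pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import HomeologPair
from .gwas import CriticalInterval
from .popgen import _pairwise_r2

__all__ = [
    "HomeologMap",
    "nonsyntenic_ld_scan",
    "classify_leakage",
]


@dataclass
class HomeologMap:
    """Pairs of non-syntenic duplicated intervals (1-based inclusive)."""

    pairs: list[HomeologPair]

    def partner_intervals(self, chrom: str, start: int, stop: int):
        """Intervals homeologous to any part of [start, stop] on ``chrom``.

        Yields (partner_chrom, partner_start, partner_stop) projections.
        """
        for hp in self.pairs:
            for (ca, sa, ea), (cb, sb, _eb) in (
                ((hp.chrom_a, hp.start_a, hp.end_a), (hp.chrom_b, hp.start_b, hp.end_b)),
                ((hp.chrom_b, hp.start_b, hp.end_b), (hp.chrom_a, hp.start_a, hp.end_a)),
            ):
                if chrom == ca and start <= ea and stop >= sa:
                    lo = max(start, sa)
                    hi = min(stop, ea)
                    yield cb, sb + (lo - sa), sb + (hi - sa)

    # --- BED round-trip (0-based half-open; pair id in the name column) ---
    def to_bed(self, path: str | Path) -> None:
        lines = []
        for k, hp in enumerate(self.pairs):
            lines.append(f"{hp.chrom_a}\t{hp.start_a - 1}\t{hp.end_a}\tpair{k}_A\t{hp.rho:g}")
            lines.append(f"{hp.chrom_b}\t{hp.start_b - 1}\t{hp.end_b}\tpair{k}_B\t{hp.rho:g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "HomeologMap":
        halves: dict[str, dict[str, tuple]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, *rest = line.split("\t")
            pair_id, side = name.rsplit("_", 1)
            rho = float(rest[0]) if rest else 0.9
            halves.setdefault(pair_id, {})[side] = (chrom, int(start) + 1, int(end), rho)
        pairs = []
        for pair_id, sides in sorted(halves.items()):
            if set(sides) != {"A", "B"}:
                raise ValueError(f"homeolog pair {pair_id} missing a side")
            (ca, sa, ea, rho), (cb, sb, eb, _) = sides["A"], sides["B"]
            pairs.append(HomeologPair(ca, sa, ea, cb, sb, eb, rho))
        return cls(pairs)


# ----------------------------------------------------------------------
def nonsyntenic_ld_scan(
    dosage: pd.DataFrame,
    chrom_pair: tuple[str, str],
    r2_min: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """All inter-chromosomal SNP pairs with r^2 at or above ``r2_min``.

    ``dosage`` is a sites x samples matrix indexed by (chrom, pos).  Returns
    the pair list (site_a, site_b, r2) and per-chromosome counts of distinct
    sites participating in at least one reported pair.
    """
    chrom_a, chrom_b = chrom_pair
    if chrom_a == chrom_b:
        raise ValueError("chromosomes must differ for a non-syntenic scan")
    chroms = dosage.index.get_level_values(0)
    sub_a = dosage[chroms == chrom_a]
    sub_b = dosage[chroms == chrom_b]
    if sub_a.empty or sub_b.empty:
        raise ValueError("both chromosomes must carry sites")
    r2 = _pairwise_r2(sub_a.to_numpy(float), sub_b.to_numpy(float))
    r2 = np.nan_to_num(r2)
    ii, jj = np.nonzero(r2 >= r2_min)
    pairs = pd.DataFrame(
        {
            "chrom_a": chrom_a,
            "pos_a": sub_a.index.get_level_values(1)[ii].astype(int),
            "chrom_b": chrom_b,
            "pos_b": sub_b.index.get_level_values(1)[jj].astype(int),
            "r2": r2[ii, jj],
        }
    ).sort_values(["pos_a", "pos_b"], ignore_index=True)
    counts = {
        chrom_a: int(pd.unique(pairs["pos_a"]).size),
        chrom_b: int(pd.unique(pairs["pos_b"]).size),
        "n_pairs": len(pairs),
    }
    return pairs, counts


# ----------------------------------------------------------------------
def _interval_sites(dosage: pd.DataFrame, interval: CriticalInterval) -> pd.DataFrame:
    chroms = dosage.index.get_level_values(0)
    pos = dosage.index.get_level_values(1)
    mask = (chroms == interval.chrom) & (pos >= interval.start) & (pos <= interval.stop)
    return dosage[mask]


def classify_leakage(
    intervals: Sequence[CriticalInterval],
    homeolog_map: HomeologMap,
    dosage: pd.DataFrame,
    results: pd.DataFrame,
    r2_min: float = 0.2,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Label critical intervals as true_locus, leakage or unresolved.

    Intervals are processed strongest-first: by the summed significance of
    the interval's threshold-passing SNPs, then by peak significance, then
    by position.  The aggregate leads because it concentrates over many
    SNPs: a true locus carries independently strong supporting SNPs,
    whereas a leaked interval's are damped copies, so the aggregate orders
    source before mirror even when single-site noise lets one mirror SNP
    out-peak the source peak.  An interval is
    *leakage* when (i) it overlaps the homeolog partner projection of an
    already-retained interval and (ii) at least ``min_pairs`` SNP pairs
    between the two intervals reach r^2 >= ``r2_min``; *unresolved* when (i)
    holds but (ii) fails, or when two partnered intervals are exactly tied
    on both strength components; *true_locus* otherwise.
    """

    def strength(iv: CriticalInterval) -> tuple[float, float]:
        at_peak = results[(results["chrom"] == iv.chrom) & (results["pos"] == iv.peak)]
        if at_peak.empty:
            raise ValueError(f"interval peak {iv.chrom}:{iv.peak} absent from results")
        span = results[
            (results["chrom"] == iv.chrom)
            & (results["pos"] >= iv.start)
            & (results["pos"] <= iv.stop)
            & (results["p"] <= iv.threshold)
        ]
        return float(span["neg_log10_p"].sum()), float(at_peak["neg_log10_p"].max())

    scored = sorted(
        ((strength(iv), iv) for iv in intervals),
        key=lambda t: (-t[0][0], -t[0][1], t[1].chrom, t[1].peak),
    )
    labels: dict[int, str] = {}
    evidence: dict[int, dict] = {}
    retained: list[tuple[float, CriticalInterval]] = []
    for score, iv in scored:
        label = "true_locus"
        info = {"partner_of": None, "n_high_ld_pairs": 0}
        for r_score, r_iv in retained:
            overlaps = any(
                pc == iv.chrom and ps <= iv.stop and pe >= iv.start
                for pc, ps, pe in homeolog_map.partner_intervals(
                    r_iv.chrom, r_iv.start, r_iv.stop
                )
            )
            if not overlaps:
                continue
            a = _interval_sites(dosage, r_iv)
            b = _interval_sites(dosage, iv)
            n_pairs = 0
            if not a.empty and not b.empty:
                r2 = np.nan_to_num(_pairwise_r2(a.to_numpy(float), b.to_numpy(float)))
                n_pairs = int((r2 >= r2_min).sum())
            info = {"partner_of": f"{r_iv.chrom}:{r_iv.start}-{r_iv.stop}", "n_high_ld_pairs": n_pairs}
            if score == r_score:
                label = "unresolved"
                labels[id(r_iv)] = "unresolved"
            elif n_pairs >= min_pairs:
                label = "leakage"
            else:
                label = "unresolved"
            break
        labels[id(iv)] = label
        evidence[id(iv)] = info
        if label == "true_locus":
            retained.append((score, iv))

    rows = []
    for score, iv in scored:
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "stop": iv.stop,
                "peak": iv.peak,
                "peak_neg_log10_p": score[1],
                "sum_neg_log10_p": score[0],
                "label": labels[id(iv)],
                **evidence[id(iv)],
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)
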