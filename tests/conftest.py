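import numpy as np
import pandas as pd
import pytest

from sexlinkit import msr, synthetic_data as sd
from sexlinkit.config import SDY_CONTIG, SimConfig
from sexlinkit.variant_qc import VariantTable


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=123)


@pytest.fixture(scope="session")
def default_pop(default_cfg):
    return sd.simulate_population(default_cfg)


@pytest.fixture(scope="session")
def default_table(default_cfg, default_pop):
    return sd.simulate_variant_table(default_cfg, default_pop)


@pytest.fixture(scope="session")
def panel_records(default_cfg, default_pop):
    """Alignments for the default sequencing panel (all contigs)."""
    return sd.simulate_alignments(default_cfg, default_pop.truth)


def make_table(
    sites_rows,
    samples,
    gt,
    dp=None,
    ad_alt=None,
    contig_lengths=None,
) -> VariantTable:
    """Hand-build a small VariantTable.

    ``sites_rows``: list of (chrom, pos, ref, alt, mq); genotype codes use -1
    for missing.  Depth defaults to 30 with allele depths consistent with the
    genotype.
    """
    sites = pd.DataFrame(sites_rows, columns=["chrom", "pos", "ref", "alt", "mq"])
    gt = np.asarray(gt, dtype=np.int8)
    if dp is None:
        dp = np.full(gt.shape, 30, dtype=np.int32)
        dp[gt == -1] = 0
    else:
        dp = np.asarray(dp, dtype=np.int32)
    if ad_alt is None:
        ad_alt = np.zeros(gt.shape, dtype=np.int32)
        ad_alt[gt == 1] = (dp[gt == 1] // 2).astype(np.int32)
        ad_alt[gt == 2] = dp[gt == 2]
    else:
        ad_alt = np.asarray(ad_alt, dtype=np.int32)
    ad_ref = np.where(gt == -1, 0, dp - ad_alt).astype(np.int32)
    return VariantTable(
        sites=sites,
        samples=list(samples),
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
        contig_lengths=contig_lengths or {},
    )
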