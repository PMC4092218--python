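"""Published reference values for the Large White teat-number GWAS setting.

The proprietary reference cohort (936 genotyped pigs, PorcineSNP60 chip)
is not redistributable, but its printed summary numbers are, and several
internal-consistency checks run against them: the post-QC SNP count, the
prior inclusion probability, and the per-region genetic-variance summary
for the 39 reported QTL regions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "SNPS_PRE_QC",
    "SNPS_POST_QC",
    "PI1",
    "HERITABILITY",
    "TRAIT_MEAN",
    "TRAIT_SD",
    "GENOTYPE_CLASS_MEANS_TOP_QTL",
    "load_reported_regions",
    "expected_slab_snps_per_cycle",
]

SNPS_PRE_QC = 64_232
SNPS_POST_QC = 42_654
PI1 = 0.001
HERITABILITY = 0.42
TRAIT_MEAN = 15.3
TRAIT_SD = 0.94
# genotype-class phenotype means (AA, AG, GG) at the top QTL's lead SNP,
# the reported overdominance pattern
GENOTYPE_CLASS_MEANS_TOP_QTL = (15.16, 15.45, 15.37)


def load_reported_regions() -> pd.DataFrame:
    """The 39 reported QTL regions with per-region % genetic variance."""
    with resources.files("teatqtl.data").joinpath("reported_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def expected_slab_snps_per_cycle(n_snps: int = SNPS_POST_QC, pi1: float = PI1) -> float:
    """Expected number of SNPs per MCMC cycle in the large-effect component.

    Under a fixed Bernoulli(pi1) inclusion prior the per-cycle count of
    slab SNPs is Binomial(p, pi1) with mean p * pi1 — about 42 for a
    ~42.7k-SNP chip at pi1 = 0.001.
    """
    if n_snps < 0 or not 0.0 < pi1 < 1.0:
        raise ValueError("need n_snps >= 0 and pi1 in (0, 1)")
    return float(n_snps * pi1)
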