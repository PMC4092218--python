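"""Parameter-recovery and null-calibration scenario runner.

Drives the full stack — synthetic cohort, BLUP, deregression, QC, sampler,
region calling, variance partition — on the default desk-scale study
conditions and scores the result against the simulated truth: which
planted QTL fall inside called regions, how the estimated region variance
compares with the planted shares, and how many (spurious) regions a
zero-QTL genome yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .deregress import deregress_cohort
from .mcmc import BVSConfig, run_chain
from .qc import filter_snps, impute_and_center
from .regions import QTLRegion, call_regions, merge_regions_by_ld, snp_results

__all__ = ["ScenarioResult", "run_scenario", "null_cohort_config"]


@dataclass
class ScenarioResult:
    """Outcome of one end-to-end synthetic run scored against the truth."""

    seed: int
    regions: list[QTLRegion]
    snp_table: pd.DataFrame = field(repr=False)
    qtl_snp_ids: tuple[str, ...]
    qtl_true_share_pct: dict[str, float]  # planted % of additive genetic variance
    qtl_recovered: dict[str, bool]
    qtl_position: dict[str, tuple[str, int]]  # chromosome, bp of each causal locus
    qtl_region: dict[str, str | None]  # region_id holding each recovered QTL
    region_est_pct: dict[str, float]
    n_bf_strong: int
    n_bf_decisive: int
    n_regions: int
    n_regions_decisive: int
    weights: pd.DataFrame = field(repr=False, default=None)
    gelman_rubin: float | None = None

    @property
    def n_recovered(self) -> int:
        return sum(self.qtl_recovered.values())

    @property
    def recovered_true_pct(self) -> float:
        return sum(
            v for q, v in self.qtl_true_share_pct.items() if self.qtl_recovered[q]
        )

    @property
    def estimated_region_pct_total(self) -> float:
        return sum(self.region_est_pct.values())


def null_cohort_config(seed: int) -> CohortConfig:
    """Smaller zero-QTL genome for null-calibration runs."""
    return CohortConfig(
        seed=seed,
        qtl_variance_shares=(),
        n_founders=300,
        n_sires_per_generation=30,
        n_dams_per_generation=150,
        n_snps=1600,
        n_genotyped_young=500,
        n_low_call_rate_snps=10,
        n_unmapped_snps=8,
    )


def run_scenario(
    seed: int,
    cohort_config: CohortConfig | None = None,
    bvs_config: BVSConfig | None = None,
    bf_threshold: float = 10.0,
    min_snps: int = 2,
    recovery_margin_bp: int = 200_000,
) -> ScenarioResult:
    """Run the pipeline on a synthetic cohort and score truth recovery.

    A planted QTL counts as recovered when its position falls inside a
    called region's bounds extended by ``recovery_margin_bp`` (one LD block:
    the flanking significant markers can sit on one side of the causal
    locus).  Region-variance estimates come from the grouped posterior
    samples of the main run.
    """
    cfg = cohort_config if cohort_config is not None else CohortConfig(seed=seed)
    cohort = simulate_cohort(cfg)

    panel = set(cohort.genotypes.animals)
    ebv_panel = cohort.ebv[cohort.ebv["animal_id"].isin(panel)]
    debv = deregress_cohort(ebv_panel, h2=cfg.h2, c=0.5)
    weights = debv.merge(ebv_panel[["animal_id", "offspring_count"]], on="animal_id")

    filtered, _ = filter_snps(cohort.genotypes, cohort.snp_map)
    keep = [a for a in filtered.animals if a in set(debv["animal_id"])]
    filtered = filtered.subset(animals=keep)
    debv = debv.set_index("animal_id").loc[keep].reset_index()
    X = impute_and_center(filtered)

    bvs = bvs_config or BVSConfig.desk_scale(seed=seed + 1, n_chains=1)
    summary = run_chain(
        debv["debv"].to_numpy(),
        X,
        debv["weight"].to_numpy(),
        bvs,
        diagnostics=bvs.n_chains >= 2,
    )

    qc_map = cohort.snp_map.set_index("snp_id").loc[filtered.snps].reset_index()
    results = snp_results(summary, qc_map, genotypes=filtered)
    called = call_regions(results, bf_threshold=bf_threshold, min_snps=min_snps)
    merged = merge_regions_by_ld(called, filtered, r2_threshold=0.7)
    decisive = call_regions(results, bf_threshold=100.0, min_snps=min_snps)

    # two-pass grouped re-estimation: region variances free of the
    # selection prior's shrinkage (each region gets its own component)
    region_est_pct: dict[str, float] = {}
    if merged:
        from .mcmc import grouped_variance_shares

        col_of = {s: j for j, s in enumerate(filtered.snps)}
        group_of = np.full(len(filtered.snps), len(merged), dtype=np.int64)
        for g, reg in enumerate(merged):
            for s in reg.member_snp_ids:
                group_of[col_of[s]] = g
        shares = grouped_variance_shares(
            debv["debv"].to_numpy(),
            X,
            debv["weight"].to_numpy(),
            group_of,
            n_groups=len(merged) + 1,
            seed=seed + 7,
        )
        region_est_pct = {
            reg.region_id: float(shares[g] * 100.0) for g, reg in enumerate(merged)
        }

    smap = cohort.snp_map.set_index("snp_id")
    sigma2_a = cfg.h2 * cfg.phenotype_sd**2
    true_share: dict[str, float] = {}
    recovered: dict[str, bool] = {}
    position: dict[str, tuple[str, int]] = {}
    holding_region: dict[str, str | None] = {}
    freqs = np.nanmean(cohort.genotypes_full.dosage, axis=0) / 2.0
    snp_col = {s: j for j, s in enumerate(cohort.genotypes_full.snps)}
    for q, eff in zip(
        cohort.architecture.qtl_snp_ids, cohort.architecture.qtl_effects
    ):
        p_f = freqs[snp_col[q]]
        true_share[q] = float(2.0 * p_f * (1.0 - p_f) * eff**2 / sigma2_a * 100.0)
        chrom = str(smap.loc[q, "chromosome"])
        pos = int(smap.loc[q, "position_bp"])
        position[q] = (chrom, pos)
        holding_region[q] = next(
            (
                r.region_id
                for r in merged
                if r.chromosome == chrom
                and r.start_bp - recovery_margin_bp <= pos <= r.end_bp + recovery_margin_bp
            ),
            None,
        )
        recovered[q] = holding_region[q] is not None

    bf = results["bayes_factor"].to_numpy()
    return ScenarioResult(
        seed=seed,
        regions=merged,
        snp_table=results,
        qtl_snp_ids=cohort.architecture.qtl_snp_ids,
        qtl_true_share_pct=true_share,
        qtl_recovered=recovered,
        qtl_position=position,
        qtl_region=holding_region,
        region_est_pct=region_est_pct,
        n_bf_strong=int((bf > 10.0).sum()),
        n_bf_decisive=int((bf > 100.0).sum()),
        n_regions=len(merged),
        n_regions_decisive=len(decisive),
        weights=weights,
        gelman_rubin=summary.gelman_rubin_deviance,
    )
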