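"""Bayes factors, QTL region calling, LD merging and variance partitioning.

Turns posterior inclusion frequencies into per-SNP Bayes factors, clusters
significant SNPs into candidate QTL regions (inter-SNP gap below 2 Mb, at
least two significant members by default), merges distant regions whose
top SNPs sit in strong LD (r2 > 0.7), partitions the genetic variance over
regions and chromosomes from the retained posterior samples, and provides
the per-SNP diagnostics reported alongside such regions (allele
substitution effect, mode-of-gene-action classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = [
    "QTLRegion",
    "VariancePartition",
    "bayes_factor",
    "snp_results",
    "call_regions",
    "ld_r2",
    "merge_regions_by_ld",
    "partition_variance",
    "allele_substitution_effect",
    "classify_gene_action",
]

BF_STRONG = 10.0
BF_DECISIVE = 100.0


def bayes_factor(
    p_hat: float | np.ndarray, pi1: float, n_samples: int
) -> float | np.ndarray:
    """Bayes factor as posterior odds of inclusion over prior odds.

    BF = [p_hat / (1 - p_hat)] / [pi1 / (1 - pi1)].  An estimated p_hat of
    exactly 1 (every retained cycle included the SNP) is capped at
    1 - 1/(2 n_samples) before forming the odds, so a finite BF is
    reported; by convention BF > 10 is 'strong' and BF > 100 'decisive'
    evidence.
    """
    if not 0.0 < pi1 < 1.0:
        raise ValueError(f"pi1 must be in (0, 1), got {pi1}")
    p = np.asarray(p_hat, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_hat must be in [0, 1]")
    cap = 1.0 - 1.0 / (2.0 * n_samples)
    p = np.minimum(p, cap)
    bf = (p / (1.0 - p)) / (pi1 / (1.0 - pi1))
    return float(bf) if np.isscalar(p_hat) or np.ndim(p_hat) == 0 else bf


def snp_results(
    summary,
    snp_map: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Per-SNP result table: p_hat, BF, posterior effect, MAF, coordinates.

    ``summary`` is a :class:`~teatqtl.mcmc.PosteriorSummary` whose SNP order
    matches ``snp_map`` (and ``genotypes`` when given, for the MAF column).
    Rows come back sorted by chromosome then position.
    """
    if len(snp_map) != len(summary.p_hat):
        raise ValueError("snp_map and posterior summary have different SNP counts")
    df = snp_map.copy().reset_index(drop=True)
    df["p_hat"] = summary.p_hat
    df["bayes_factor"] = bayes_factor(summary.p_hat, summary.config.pi1, summary.n_kept)
    df["posterior_mean_effect"] = summary.beta_mean
    df["posterior_sd_effect"] = summary.beta_sd
    if genotypes is not None:
        from .qc import compute_maf

        maf = {s: compute_maf(genotypes.column(s)) for s in df["snp_id"]}
        df["maf"] = df["snp_id"].map(maf)
    return df.sort_values(
        ["chromosome", "position_bp"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class QTLRegion:
    """A called QTL region: flanking significant SNPs and members."""

    region_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    member_snp_ids: tuple[str, ...]
    top_snp_id: str
    top_bf: float
    pct_genetic_variance: float | None = None
    allele_substitution_effect: float | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start must not exceed end")


def call_regions(
    results: pd.DataFrame,
    bf_threshold: float = BF_STRONG,
    max_gap_bp: int = 2_000_000,
    min_snps: int = 2,
) -> list[QTLRegion]:
    """Cluster significant SNPs into candidate QTL regions.

    Per chromosome, SNPs with BF above ``bf_threshold`` are single-linkage
    clustered: consecutive significant SNPs closer than ``max_gap_bp`` join
    the same cluster.  Clusters with at least ``min_snps`` members become
    regions whose bounds are the outermost significant members; the top SNP
    has the maximum BF (ties -> smaller position).  ``min_snps=1`` admits
    single-SNP regions.
    """
    required = {"snp_id", "chromosome", "position_bp", "bayes_factor"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    for _, grp in results.groupby("chromosome", sort=False):
        if not grp["position_bp"].is_monotonic_increasing:
            raise ValueError("results must be sorted by chromosome and position")

    regions: list[QTLRegion] = []
    sig = results[results["bayes_factor"] > bf_threshold]
    k = 0
    for chrom, grp in sig.groupby("chromosome", sort=False):
        grp = grp.reset_index(drop=True)
        cluster: list[int] = []
        clusters: list[list[int]] = []
        for i in range(len(grp)):
            if cluster and grp.loc[i, "position_bp"] - grp.loc[i - 1, "position_bp"] >= max_gap_bp:
                clusters.append(cluster)
                cluster = []
            cluster.append(i)
        if cluster:
            clusters.append(cluster)
        for idx in clusters:
            if len(idx) < min_snps:
                continue
            sub = grp.loc[idx]
            k += 1
            top = sub.sort_values(
                ["bayes_factor", "position_bp"], ascending=[False, True], kind="mergesort"
            ).iloc[0]
            regions.append(
                QTLRegion(
                    region_id=f"Q{k:03d}",
                    chromosome=str(chrom),
                    start_bp=int(sub["position_bp"].min()),
                    end_bp=int(sub["position_bp"].max()),
                    member_snp_ids=tuple(sub["snp_id"]),
                    top_snp_id=str(top["snp_id"]),
                    top_bf=float(top["bayes_factor"]),
                )
            )
    return regions


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared sample correlation of two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float).ravel()
    b = np.asarray(dosage_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("dosage vectors differ in length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cannot compute r2 for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def merge_regions_by_ld(
    regions: Sequence[QTLRegion],
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.7,
    method: str = "top_snp",
) -> list[QTLRegion]:
    """Merge same-chromosome regions in strong LD despite a large gap.

    Two regions are joined when the r2 between them exceeds
    ``r2_threshold`` — measured between their top SNPs (``method="top_snp"``,
    the default) or as the maximum over all member pairs
    (``method="max_pairwise"``).  Merging runs to a fixed point via
    union-find, so the result is independent of input order.
    """
    if method not in ("top_snp", "max_pairwise"):
        raise ValueError(f"unknown method {method!r}")
    regions = list(regions)
    parent = list(range(len(regions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if regions[i].chromosome != regions[j].chromosome:
                continue
            if method == "top_snp":
                r2 = ld_r2(
                    genotypes.column(regions[i].top_snp_id),
                    genotypes.column(regions[j].top_snp_id),
                )
            else:
                r2 = max(
                    ld_r2(genotypes.column(a), genotypes.column(b))
                    for a in regions[i].member_snp_ids
                    for b in regions[j].member_snp_ids
                )
            if r2 > r2_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[QTLRegion]] = {}
    for i, reg in enumerate(regions):
        groups.setdefault(find(i), []).append(reg)

    merged: list[QTLRegion] = []
    for members in groups.values():
        members = sorted(members, key=lambda r: r.start_bp)
        if len(members) == 1:
            merged.append(members[0])
            continue
        all_snps = tuple(s for r in members for s in r.member_snp_ids)
        best = max(members, key=lambda r: (r.top_bf, -r.start_bp))
        merged.append(
            QTLRegion(
                region_id="+".join(r.region_id for r in members),
                chromosome=members[0].chromosome,
                start_bp=min(r.start_bp for r in members),
                end_bp=max(r.end_bp for r in members),
                member_snp_ids=all_snps,
                top_snp_id=best.top_snp_id,
                top_bf=best.top_bf,
            )
        )
    merged.sort(key=lambda r: (r.chromosome, r.start_bp))
    return merged


@dataclass
class VariancePartition:
    """Genetic-variance shares per region and per chromosome (percent)."""

    region_pct: pd.DataFrame  # region_id, chromosome, pct_genetic_variance
    chromosome: pd.DataFrame  # chromosome, total_pct, region_pct, rest_pct, null_expected_pct
    total_genetic_variance: float
    n_samples: int
    region_pct_by_id: dict[str, float] = field(repr=False, default_factory=dict)


def partition_variance(
    summary,
    dosage_matrix: np.ndarray,
    regions: Sequence[QTLRegion],
    snp_map: pd.DataFrame,
) -> VariancePartition:
    """Partition the genetic variance over QTL regions and chromosomes.

    For each retained posterior sample the genetic values g = X beta and
    the group values g_r = X_r beta_r are formed; a region's share is the
    across-sample mean of Var(g_r) / Var(g) x 100.  Chromosome totals add
    the non-member ("rest") SNP group on that chromosome.  The null
    expectation per chromosome is the mean single-SNP variance among
    null-assigned SNPs (gamma = 0) times the chromosome's SNP count —
    proportional to SNP count, the no-QTL baseline.
    """
    B = np.asarray(summary.beta_samples, dtype=float)
    G = np.asarray(summary.gamma_samples)
    if B.size == 0:
        raise ValueError("no retained posterior samples")
    X = np.asarray(dosage_matrix, dtype=float)
    S, p = B.shape
    if X.shape[1] != p or len(snp_map) != p:
        raise ValueError("dosage matrix / snp_map / samples disagree on SNP count")

    Xc = X - X.mean(axis=0)
    g_tot = Xc @ B.T  # (n, S)
    var_tot = g_tot.var(axis=0)
    var_tot = np.where(var_tot > 0, var_tot, np.nan)

    snp_ids = snp_map["snp_id"].to_numpy(dtype=object)
    col_of = {s: j for j, s in enumerate(snp_ids)}
    chroms = snp_map["chromosome"].to_numpy(dtype=object)

    region_rows = []
    region_pct_by_id = {}
    member_idx_by_chrom: dict[str, set[int]] = {}
    for reg in regions:
        idx = np.array([col_of[s] for s in reg.member_snp_ids], dtype=int)
        member_idx_by_chrom.setdefault(reg.chromosome, set()).update(idx.tolist())
        g_r = Xc[:, idx] @ B[:, idx].T
        pct = float(np.nanmean(g_r.var(axis=0) / var_tot) * 100.0)
        region_rows.append((reg.region_id, reg.chromosome, pct))
        region_pct_by_id[reg.region_id] = pct
    region_df = pd.DataFrame(
        region_rows, columns=["region_id", "chromosome", "pct_genetic_variance"]
    )

    # per-SNP single-locus variance under the null assignment, per sample
    vx = Xc.var(axis=0)
    null_mask = G == 0
    null_counts = null_mask.sum(axis=1)
    per_snp_null = (vx[None, :] * B**2 * null_mask).sum(axis=1) / np.maximum(null_counts, 1)
    mean_null_share = np.nanmean(per_snp_null / var_tot)

    chrom_rows = []
    for chrom in pd.unique(chroms):
        on_chrom = np.nonzero(chroms == chrom)[0]
        members = np.array(sorted(member_idx_by_chrom.get(chrom, set())), dtype=int)
        rest = np.setdiff1d(on_chrom, members)
        def group_pct(idx: np.ndarray) -> float:
            if idx.size == 0:
                return 0.0
            g = Xc[:, idx] @ B[:, idx].T
            return float(np.nanmean(g.var(axis=0) / var_tot) * 100.0)
        reg_pct = float(
            region_df.loc[region_df["chromosome"] == chrom, "pct_genetic_variance"].sum()
        )
        rest_pct = group_pct(rest)
        chrom_rows.append(
            (
                str(chrom),
                reg_pct + rest_pct,
                reg_pct,
                rest_pct,
                float(mean_null_share * 100.0 * len(on_chrom)),
            )
        )
    chrom_df = pd.DataFrame(
        chrom_rows,
        columns=["chromosome", "total_pct", "region_pct", "rest_pct", "null_expected_pct"],
    )
    return VariancePartition(
        region_pct=region_df,
        chromosome=chrom_df,
        total_genetic_variance=float(np.nanmean(var_tot)),
        n_samples=S,
        region_pct_by_id=region_pct_by_id,
    )


def allele_substitution_effect(
    phenotypes: np.ndarray,
    dosage_column: np.ndarray,
    fixed_effects: pd.DataFrame | None = None,
) -> float:
    """Regression coefficient of phenotype on allele dosage.

    Ordinary least squares of the phenotype on the dosage column plus an
    intercept and the given categorical fixed effects (e.g. sex and farm).
    The coefficient is reported for the dosage as coded by the caller;
    code the minor allele to follow the convention that the minor allele
    is counted.
    """
    y = np.asarray(phenotypes, dtype=float).ravel()
    x = np.asarray(dosage_column, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("phenotype and dosage lengths differ")
    parts = [np.ones((y.size, 1)), x[:, None]]
    if fixed_effects is not None:
        for col in fixed_effects.columns:
            dummies = pd.get_dummies(
                fixed_effects[col].astype(str), prefix=col, drop_first=True
            )
            parts.append(dummies.to_numpy(dtype=float))
    design = np.hstack(parts)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design: dosage or a fixed effect is confounded"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[1])


def classify_gene_action(
    mean_aa: float, mean_ab: float, mean_bb: float, epsilon: float = 0.25
) -> str:
    """Classify gene action from the three genotype-class phenotype means.

    With a = half the homozygote range and d = heterozygote deviation from
    the homozygote midpoint, the dominance ratio |d/a| is: <= epsilon
    additive, > 1 overdominant (heterozygote outside the homozygote range),
    within epsilon of 1 dominant, otherwise partial-dominant.  Equal
    homozygote means with d = 0 are additive by convention.
    """
    a = 0.5 * (mean_bb - mean_aa)
    d = mean_ab - 0.5 * (mean_aa + mean_bb)
    if a == 0.0:
        return "additive" if d == 0.0 else "overdominant"
    ratio = abs(d / a)
    if ratio <= epsilon:
        return "additive"
    if ratio > 1.0:
        return "overdominant"
    if ratio >= 1.0 - epsilon:
        return "dominant"
    return "partial-dominant"
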