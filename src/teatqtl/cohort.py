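"""Synthetic pedigreed, genotyped and phenotyped pig cohorts.

Generates everything the downstream association pipeline consumes:

* a multi-farm pedigree with heavily used sires (progeny-tested animals)
  next to young animals without offspring — the two information classes
  that later separate in the deregression weights;
* SNP genotypes with LD-block structure, obtained by gene dropping founder
  haplotypes through the pedigree with recombination;
* a counted trait (number of teats, NTE) driven by a handful of QTL plus a
  pedigree polygenic background, rounded and left-truncated the way a
  minimum-teat-count culling rule skews real recording schemes;
* pedigree BLUP (animal model) EBVs with exact reliabilities from the
  inverse of the mixed-model coefficient matrix.

All randomness flows through a single integer seed; the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

__all__ = [
    "UNKNOWN_PARENT",
    "TraitArchitecture",
    "CohortConfig",
    "Cohort",
    "simulate_pedigree",
    "build_snp_map",
    "simulate_genotypes",
    "simulate_phenotypes",
    "pedigree_blup",
    "relationship_matrix",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """Simulated genetic truth for a counted trait.

    Parameters
    ----------
    qtl_snp_ids : ordered QTL marker ids (subset of the simulated map).
    qtl_effects : additive allele-substitution effects, trait units.
    h2 : narrow-sense heritability of the latent trait.
    mean : latent trait mean.
    phenotype_sd : total latent SD.
    truncation_min : minimum recorded count (culling rule).
    qtl_dominance : optional dominance deviations, trait units.
    """

    qtl_snp_ids: tuple[str, ...]
    qtl_effects: np.ndarray
    h2: float
    mean: float = 15.3
    phenotype_sd: float = 0.94
    truncation_min: int = 14
    qtl_dominance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"h2 must be in [0, 1], got {self.h2}")
        if len(self.qtl_snp_ids) != len(self.qtl_effects):
            raise ConfigurationError("qtl_snp_ids and qtl_effects length mismatch")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_founders: int = 500,
    n_generations: int = 2,
    offspring_per_mating: int | Callable[[np.random.Generator], int] | None = None,
    n_farms: int = 17,
    seed: int = 0,
    n_sires_per_generation: int = 50,
    n_dams_per_generation: int = 250,
    sire_usage_concentration: float = 0.3,
) -> pd.DataFrame:
    """Simulate a multi-farm pedigree with heavy-tailed sire usage.

    Founders (generation 0) have unknown parents.  Each later generation
    mates a limited set of dams, each once, to sires drawn with Dirichlet
    weights (``sire_usage_concentration`` < 1 concentrates matings on a few
    sires, so some sires accumulate dozens to hundreds of offspring while
    most animals leave none).

    Returns a DataFrame with columns ``animal_id, sire_id, dam_id,
    generation, sex, farm`` in topological order (parents precede
    offspring).  Unknown parents are coded ``"0"``.
    """
    if n_founders < 2:
        raise ConfigurationError("n_founders must be >= 2")
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    if n_farms < 1:
        raise ConfigurationError("n_farms must be >= 1")
    rng = np.random.default_rng(seed)

    if offspring_per_mating is None:
        def draw_litter(r: np.random.Generator) -> int:
            return int(r.poisson(4))
    elif callable(offspring_per_mating):
        draw_litter = offspring_per_mating
    else:
        fixed = int(offspring_per_mating)
        if fixed <= 0:
            raise ConfigurationError("offspring_per_mating must be positive")

        def draw_litter(r: np.random.Generator) -> int:
            return fixed

    rows: list[tuple[str, str, str, int, str, str]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    n_males = n_founders // 2
    farms = [f"F{k + 1:02d}" for k in range(n_farms)]
    males: list[str] = []
    females: list[str] = []
    for i in range(n_founders):
        aid = new_id()
        sex = "M" if i < n_males else "F"
        farm = farms[int(rng.integers(n_farms))]
        rows.append((aid, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, sex, farm))
        (males if sex == "M" else females).append(aid)

    farm_of = {r[0]: r[5] for r in rows}

    for gen in range(1, n_generations + 1):
        if not males or not females:
            break
        sires = list(rng.choice(males, size=min(n_sires_per_generation, len(males)), replace=False))
        dams = list(rng.choice(females, size=min(n_dams_per_generation, len(females)), replace=False))
        usage = rng.dirichlet(np.full(len(sires), sire_usage_concentration))
        next_males: list[str] = []
        next_females: list[str] = []
        for dam in dams:
            sire = sires[int(rng.choice(len(sires), p=usage))]
            for _ in range(draw_litter(rng)):
                aid = new_id()
                sex = "M" if rng.random() < 0.5 else "F"
                farm = farm_of[dam]
                rows.append((aid, sire, dam, gen, sex, farm))
                farm_of[aid] = farm
                (next_males if sex == "M" else next_females).append(aid)
        males, females = next_males, next_females

    return pd.DataFrame(
        rows, columns=["animal_id", "sire_id", "dam_id", "generation", "sex", "farm"]
    )


def validate_pedigree(pedigree: pd.DataFrame) -> None:
    """Check topological order and parent self-reference.

    Raises ``ValueError`` if an animal appears before one of its parents or
    is its own ancestor (detected via the ordering requirement).
    """
    seen: set[str] = set()
    for aid, sire, dam in zip(
        pedigree["animal_id"], pedigree["sire_id"], pedigree["dam_id"]
    ):
        for parent in (sire, dam):
            if parent != UNKNOWN_PARENT and parent not in seen:
                raise ValueError(
                    f"pedigree not in topological order: parent {parent} of "
                    f"{aid} not seen yet"
                )
        if aid in seen:
            raise ValueError(f"duplicate animal_id {aid}")
        seen.add(aid)


# ---------------------------------------------------------------------------
# SNP map and genotypes
# ---------------------------------------------------------------------------


def build_snp_map(
    n_snps: int = 5250,
    n_chromosomes: int = 5,
    spacing_bp: int = 40_000,
    n_unmapped: int = 0,
) -> pd.DataFrame:
    """Evenly spaced SNP map over ``n_chromosomes`` autosomes.

    The last ``n_unmapped`` SNPs are placed on chromosome ``"0"`` at
    position 0, the convention for markers without a physical position
    (those are dropped by QC when ``require_position`` is on).
    """
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    per_chrom = (n_snps - n_unmapped) // n_chromosomes
    rows = []
    k = 0
    for c in range(1, n_chromosomes + 1):
        n_c = per_chrom if c < n_chromosomes else (n_snps - n_unmapped) - per_chrom * (n_chromosomes - 1)
        for j in range(n_c):
            k += 1
            rows.append((f"SNP{k:06d}", str(c), (j + 1) * spacing_bp))
    for _ in range(n_unmapped):
        k += 1
        rows.append((f"SNP{k:06d}", "0", 0))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


@dataclass
class GenotypeMatrix:
    """Animal-by-SNP allele dosages.

    ``dosage`` counts copies of the alternate (B) allele per SNP: 0, 1 or 2,
    with ``NaN`` for missing calls (allowed only pre-QC).
    """

    animals: np.ndarray
    snps: np.ndarray
    dosage: np.ndarray  # (n_animals, n_snps) float32, NaN = missing

    def __post_init__(self) -> None:
        self.animals = np.asarray(self.animals, dtype=object)
        self.snps = np.asarray(self.snps, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.float32)
        if self.dosage.shape != (len(self.animals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.animals)} animals x {len(self.snps)} SNPs"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, animals: Sequence[str] | None = None, snps: Sequence[str] | None = None) -> "GenotypeMatrix":
        a_idx = np.arange(self.n_animals)
        s_idx = np.arange(self.n_snps)
        if animals is not None:
            pos = {a: i for i, a in enumerate(self.animals)}
            a_idx = np.array([pos[a] for a in animals], dtype=int)
        if snps is not None:
            pos = {s: i for i, s in enumerate(self.snps)}
            s_idx = np.array([pos[s] for s in snps], dtype=int)
        return GenotypeMatrix(
            self.animals[a_idx], self.snps[s_idx], self.dosage[np.ix_(a_idx, s_idx)]
        )

    def column(self, snp_id: str) -> np.ndarray:
        j = int(np.nonzero(self.snps == snp_id)[0][0])
        return self.dosage[:, j]


def _haldane_recomb_prob(distance_bp: np.ndarray) -> np.ndarray:
    # 1 cM ~ 1 Mb; Haldane map function, no interference
    morgans = distance_bp / 1e8
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def simulate_genotypes(
    pedigree: pd.DataFrame,
    snp_map: pd.DataFrame,
    founder_maf_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    ld_block_length_bp: int = 400_000,
    seed: int = 0,
    block_correlation: float = 0.995,
    block_maf_jitter: float = 0.015,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Gene-drop genotypes through a pedigree.

    Founder haplotypes are drawn from a Gaussian-copula block model: within
    each LD block of ``ld_block_length_bp`` a shared latent factor (loading
    ``block_correlation``) correlates the alleles, and block members share
    a base allele frequency (jittered by ``block_maf_jitter``), producing
    the high within-block r2 and similar within-block MAFs of real
    haplotype blocks, with (near) independence across blocks.  Unmapped
    SNPs (chromosome ``"0"``) each form their own block.  Non-founder
    haplotypes are inherited with recombination (Haldane, 1 cM ~ 1 Mb).

    ``founder_maf_distribution(rng, size)`` draws the per-block base MAFs.
    ``missing_rate`` masks calls at random (pre-QC missingness).
    """
    if len(snp_map) == 0:
        raise ConfigurationError("snp_map is empty")
    validate_pedigree(pedigree)
    rng = np.random.default_rng(seed)
    p = len(snp_map)
    n = len(pedigree)

    if founder_maf_distribution is None:
        def founder_maf_distribution(r: np.random.Generator, size: int) -> np.ndarray:
            return r.uniform(0.02, 0.5, size=size)

    chrom = snp_map["chromosome"].to_numpy(dtype=object)
    pos = snp_map["position_bp"].to_numpy(dtype=np.int64)
    # block index: new block at chromosome change or block-length boundary
    block_id = np.zeros(p, dtype=np.int64)
    b = 0
    for j in range(1, p):
        if chrom[j] != chrom[j - 1] or chrom[j] == "0" or (
            pos[j] // ld_block_length_bp != pos[j - 1] // ld_block_length_bp
        ):
            b += 1
        block_id[j] = b
    n_blocks = b + 1

    base_maf = np.asarray(founder_maf_distribution(rng, n_blocks), dtype=float)
    freqs = base_maf[block_id] + rng.normal(0.0, block_maf_jitter, size=p)
    freqs = np.clip(freqs, 1e-3, 1 - 1e-3)

    from scipy.stats import norm

    thresh = norm.ppf(freqs)
    rho = float(block_correlation)
    ortho = np.sqrt(1.0 - rho * rho)

    n_founders = int((pedigree["sire_id"] == UNKNOWN_PARENT).sum())
    # haplotypes coded 0/1 (1 = B allele); two per animal
    hap = np.zeros((n, 2, p), dtype=np.uint8)
    for i in range(n_founders):
        for h in range(2):
            z_block = rng.standard_normal(n_blocks)[block_id]
            eps = rng.standard_normal(p)
            hap[i, h] = (rho * z_block + ortho * eps < thresh).astype(np.uint8)

    # recombination probability between adjacent SNPs; independent across
    # chromosomes and around unmapped SNPs
    gap = np.empty(p)
    gap[0] = np.inf
    same = (chrom[1:] == chrom[:-1]) & (chrom[1:] != "0")
    gap[1:] = np.where(same, pos[1:] - pos[:-1], np.inf)
    rec = np.where(np.isinf(gap), 0.5, _haldane_recomb_prob(gap))

    index = {a: i for i, a in enumerate(pedigree["animal_id"])}
    sires = pedigree["sire_id"].to_numpy(dtype=object)
    dams = pedigree["dam_id"].to_numpy(dtype=object)
    for i in range(n_founders, n):
        for h, parent in enumerate((sires[i], dams[i])):
            pi = index[parent]
            cross = rng.random(p) < rec
            source = (np.cumsum(cross) + rng.integers(2)) % 2
            hap[i, h] = hap[pi, source, np.arange(p)]

    dosage = (hap[:, 0, :] + hap[:, 1, :]).astype(np.float32)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    return GenotypeMatrix(
        pedigree["animal_id"].to_numpy(dtype=object),
        snp_map["snp_id"].to_numpy(dtype=object),
        dosage,
    )


def mendelian_errors(genotypes: GenotypeMatrix, pedigree: pd.DataFrame) -> int:
    """Count (trio, SNP) pairs whose dosages violate Mendelian inheritance.

    A child dosage is compatible when it can be written as one allele from
    each parent: e.g. parents (0, 0) cannot give a child 1 or 2; parents
    (0, 2) must give 1.  Missing calls in the trio are skipped.
    """
    index = {a: i for i, a in enumerate(genotypes.animals)}
    errors = 0
    for _, row in pedigree.iterrows():
        if row["sire_id"] == UNKNOWN_PARENT or row["dam_id"] == UNKNOWN_PARENT:
            continue
        if row["animal_id"] not in index:
            continue
        c = genotypes.dosage[index[row["animal_id"]]]
        s = genotypes.dosage[index[row["sire_id"]]]
        d = genotypes.dosage[index[row["dam_id"]]]
        ok = ~(np.isnan(c) | np.isnan(s) | np.isnan(d))
        # allele a parent can transmit: dosage 0 -> {0}, 1 -> {0,1}, 2 -> {1}
        s_lo, s_hi = (s > 1.5).astype(int), (s > 0.5).astype(int)
        d_lo, d_hi = (d > 1.5).astype(int), (d > 0.5).astype(int)
        lo = s_lo + d_lo
        hi = s_hi + d_hi
        bad = ok & ((c < lo - 0.5) | (c > hi + 0.5))
        errors += int(bad.sum())
    return errors


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    architecture: TraitArchitecture,
    pedigree: pd.DataFrame,
    sex_effect: float = 0.1,
    farm_effects: dict[str, float] | None = None,
    seed: int = 0,
    phenotype_from_generation: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Counted phenotypes plus true breeding values.

    Latent value = mean + sex effect + farm effect + QTL sum + pedigree
    polygenic value + environmental noise, with the polygenic and noise
    variances scaled so Var(genetic) / Var(latent) equals the requested h2.
    Recorded counts are the latent values rounded and left-truncated at
    ``truncation_min`` (the culling rule that skews the distribution).
    Animals born before ``phenotype_from_generation`` carry no record.

    Returns ``(phenotypes, true_breeding_values)``; TBVs cover every
    pedigree animal.
    """
    arch = architecture
    if not 0.0 <= arch.h2 <= 1.0:
        raise ConfigurationError(f"h2 must be in [0, 1], got {arch.h2}")
    rng = np.random.default_rng(seed)
    missing_qtl = [q for q in arch.qtl_snp_ids if q not in set(genotypes.snps)]
    if missing_qtl:
        raise ConfigurationError(f"QTL ids not in genotype matrix: {missing_qtl}")

    n = genotypes.n_animals
    sigma2_p = arch.phenotype_sd**2
    sigma2_a = arch.h2 * sigma2_p
    sigma2_e = (1.0 - arch.h2) * sigma2_p

    if len(arch.qtl_snp_ids) > 0:
        sub = genotypes.subset(snps=list(arch.qtl_snp_ids))
        Xq = np.asarray(sub.dosage, dtype=float)
        if np.isnan(Xq).any():
            col_mean = np.nanmean(Xq, axis=0)
            idx = np.where(np.isnan(Xq))
            Xq[idx] = col_mean[idx[1]]
        Xq = Xq - Xq.mean(axis=0)
        qtl_g = Xq @ arch.qtl_effects
        if arch.qtl_dominance is not None:
            het = (np.abs(np.asarray(sub.dosage, dtype=float) - 1.0) < 0.5).astype(float)
            qtl_g = qtl_g + (het - het.mean(axis=0)) @ np.asarray(arch.qtl_dominance, dtype=float)
    else:
        qtl_g = np.zeros(n)
    var_qtl = float(np.var(qtl_g))
    sigma2_u = max(sigma2_a - var_qtl, 0.0)

    # polygenic values by dropping through the pedigree
    index = {a: i for i, a in enumerate(pedigree["animal_id"])}
    u = np.zeros(len(pedigree))
    sires = pedigree["sire_id"].to_numpy(dtype=object)
    dams = pedigree["dam_id"].to_numpy(dtype=object)
    sd_f = np.sqrt(sigma2_u)
    sd_m = np.sqrt(0.5 * sigma2_u)
    for i in range(len(pedigree)):
        s, d = sires[i], dams[i]
        if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
            u[i] = rng.normal(0.0, sd_f)
        else:
            us = u[index[s]] if s != UNKNOWN_PARENT else 0.0
            ud = u[index[d]] if d != UNKNOWN_PARENT else 0.0
            u[i] = 0.5 * (us + ud) + rng.normal(0.0, sd_m)

    ped_order = np.array([index[a] for a in genotypes.animals])
    tbv = qtl_g + u[ped_order]

    if farm_effects is None:
        farm_effects = {}
    ped_ix = pedigree.set_index("animal_id")
    sex = ped_ix.loc[genotypes.animals, "sex"].to_numpy(dtype=object)
    farm = ped_ix.loc[genotypes.animals, "farm"].to_numpy(dtype=object)
    gen = ped_ix.loc[genotypes.animals, "generation"].to_numpy()

    sex_term = np.where(sex == "M", +0.5 * sex_effect, -0.5 * sex_effect)
    farm_term = np.array([farm_effects.get(f, 0.0) for f in farm])
    farm_term = farm_term - farm_term.mean() if len(farm_term) else farm_term

    latent = arch.mean + sex_term + farm_term + tbv + rng.normal(0.0, np.sqrt(sigma2_e), n)
    counts = np.maximum(np.rint(latent).astype(int), arch.truncation_min)

    keep = gen >= phenotype_from_generation
    phenotypes = pd.DataFrame(
        {
            "animal_id": genotypes.animals[keep],
            "nte": counts[keep],
            "sex": sex[keep],
            "farm": farm[keep],
        }
    )
    tbv_all = pd.Series(
        tbv, index=pd.Index(genotypes.animals, name="animal_id"), name="tbv"
    )
    return phenotypes, tbv_all


# ---------------------------------------------------------------------------
# Pedigree BLUP (animal model)
# ---------------------------------------------------------------------------


def relationship_matrix(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method (with inbreeding)."""
    validate_pedigree(pedigree)
    n = len(pedigree)
    index = {a: i for i, a in enumerate(pedigree["animal_id"])}
    A = np.zeros((n, n))
    sires = pedigree["sire_id"].to_numpy(dtype=object)
    dams = pedigree["dam_id"].to_numpy(dtype=object)
    for i in range(n):
        s = index.get(sires[i], -1) if sires[i] != UNKNOWN_PARENT else -1
        d = index.get(dams[i], -1) if dams[i] != UNKNOWN_PARENT else -1
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            pidx = s if s >= 0 else d
            A[i, :i] = 0.5 * A[pidx, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def _fixed_design(records: pd.DataFrame, columns: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    parts = [np.ones((len(records), 1))]
    names = ["intercept"]
    for col in columns:
        dummies = pd.get_dummies(records[col].astype(str), prefix=col, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    X = np.hstack(parts)
    # rank check with per-column attribution
    rank = 0
    kept: list[np.ndarray] = []
    for k in range(X.shape[1]):
        trial = np.column_stack(kept + [X[:, k]]) if kept else X[:, [k]]
        r = np.linalg.matrix_rank(trial)
        if r == rank:
            raise ValueError(
                f"fixed-effects design is singular: column '{names[k]}' is "
                "confounded with the preceding columns"
            )
        rank = r
        kept.append(X[:, k])
    return X, names


def pedigree_blup(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    h2: float,
    fixed_effect_columns: Sequence[str] = ("sex", "farm"),
    response: str = "nte",
) -> pd.DataFrame:
    """Single-trait animal-model BLUP with exact reliabilities.

    Solves Henderson's mixed-model equations with the pedigree numerator
    relationship matrix; the variance ratio is lambda = (1 - h2) / h2.
    Prediction-error variances come from the dense inverse of the
    coefficient matrix, so reliability r2_i = 1 - PEV_i / sigma2_a is exact
    (no approximation).  Parent-average EBV and reliability
    (r2_sire + r2_dam) / 4 are attached for the deregression step; unknown
    parents contribute zero.

    Returns a DataFrame with columns ``animal_id, ebv, reliability_i,
    pa_ebv, reliability_pa, offspring_count`` covering every pedigree
    animal.
    """
    if not 0.0 < h2 < 1.0:
        raise ConfigurationError(f"h2 must be in (0, 1), got {h2}")
    validate_pedigree(pedigree)
    animals = pedigree["animal_id"].to_numpy(dtype=object)
    index = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    lam = (1.0 - h2) / h2

    offspring = np.zeros(n, dtype=int)
    for col in ("sire_id", "dam_id"):
        for parent, cnt in pedigree[col].value_counts().items():
            if parent != UNKNOWN_PARENT and parent in index:
                offspring[index[parent]] += cnt

    records = phenotypes[phenotypes["animal_id"].isin(index)].reset_index(drop=True)
    if len(records) == 0:
        out = pd.DataFrame(
            {
                "animal_id": animals,
                "ebv": 0.0,
                "reliability_i": 0.0,
                "pa_ebv": 0.0,
                "reliability_pa": 0.0,
                "offspring_count": offspring,
            }
        )
        return out

    y = records[response].to_numpy(dtype=float)
    X, _ = _fixed_design(records, fixed_effect_columns)
    nf = X.shape[1]
    Z = np.zeros((len(records), n))
    for r, a in enumerate(records["animal_id"]):
        Z[r, index[a]] = 1.0

    A = relationship_matrix(pedigree)
    Ainv = np.linalg.inv(A)

    M = np.zeros((nf + n, nf + n))
    M[:nf, :nf] = X.T @ X
    M[:nf, nf:] = X.T @ Z
    M[nf:, :nf] = M[:nf, nf:].T
    M[nf:, nf:] = Z.T @ Z + lam * Ainv
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    Minv = np.linalg.inv(M)
    sol = Minv @ rhs
    ebv = sol[nf:]
    # PEV_i = Cinv_ii * sigma2_e; r2 = 1 - PEV/sigma2_a = 1 - Cinv_ii * lambda
    diag = np.diag(Minv)[nf:]
    rel = np.clip(1.0 - diag * lam, 0.0, 1.0 - 1e-12)

    pa_ebv = np.zeros(n)
    rel_pa = np.zeros(n)
    sires = pedigree["sire_id"].to_numpy(dtype=object)
    dams = pedigree["dam_id"].to_numpy(dtype=object)
    for i in range(n):
        es = ebv[index[sires[i]]] if sires[i] != UNKNOWN_PARENT else 0.0
        ed = ebv[index[dams[i]]] if dams[i] != UNKNOWN_PARENT else 0.0
        rs = rel[index[sires[i]]] if sires[i] != UNKNOWN_PARENT else 0.0
        rd = rel[index[dams[i]]] if dams[i] != UNKNOWN_PARENT else 0.0
        pa_ebv[i] = 0.5 * (es + ed)
        rel_pa[i] = 0.25 * (rs + rd)

    return pd.DataFrame(
        {
            "animal_id": animals,
            "ebv": ebv,
            "reliability_i": rel,
            "pa_ebv": pa_ebv,
            "reliability_pa": rel_pa,
            "offspring_count": offspring,
        }
    )


# ---------------------------------------------------------------------------
# Whole-cohort convenience generator
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Default study conditions for the synthetic cohort.

    Defaults emulate the kind of cohort dense-SNP pig GWAS are run on:
    ~1,000 genotyped animals from a multi-farm pedigree with progeny-tested
    sires, ~5,000 post-QC SNPs in LD blocks, a counted teat-number trait
    with mean 15.3, SD 0.94, left-truncated at 14, h2 = 0.42, five QTL on a
    polygenic background.
    """

    n_founders: int = 500
    n_generations: int = 2
    n_farms: int = 17
    n_sires_per_generation: int = 50
    n_dams_per_generation: int = 250
    n_snps: int = 5250
    n_chromosomes: int = 5
    snp_spacing_bp: int = 40_000
    ld_block_length_bp: int = 400_000
    block_correlation: float = 0.995
    block_maf_jitter: float = 0.015
    n_unmapped_snps: int = 20
    missing_rate: float = 0.002
    n_low_call_rate_snps: int = 25
    low_call_rate: float = 0.88
    qtl_variance_shares: tuple[float, ...] = (0.15, 0.11, 0.08, 0.06, 0.05)
    h2: float = 0.42
    mean: float = 15.3
    phenotype_sd: float = 0.94
    truncation_min: int = 14
    sex_effect: float = 0.1
    farm_effect_sd: float = 0.1
    n_genotyped_young: int = 900
    # causal loci are not themselves on the chip (the usual situation on a
    # ~40k panel); their LD-block neighbours carry the association jointly,
    # which is what makes multi-SNP regions form
    qtl_on_chip: bool = False
    seed: int = 0


@dataclass
class Cohort:
    """Bundle of everything the pipeline consumes, plus the simulated truth."""

    pedigree: pd.DataFrame
    snp_map: pd.DataFrame
    genotypes: GenotypeMatrix  # genotyped panel only, with pre-QC missingness
    genotypes_full: GenotypeMatrix  # complete matrix over the whole pedigree
    phenotypes: pd.DataFrame
    architecture: TraitArchitecture
    tbv: pd.Series
    ebv: pd.DataFrame
    config: CohortConfig = field(repr=False, default=None)


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Run the full generator: pedigree, genotypes, phenotypes, BLUP EBVs.

    The genotyped panel is every sire used in the pedigree plus a random
    sample of final-generation animals (no offspring), reproducing the two
    reliability classes that drive the deregression-weight split.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)

    pedigree = simulate_pedigree(
        n_founders=cfg.n_founders,
        n_generations=cfg.n_generations,
        n_farms=cfg.n_farms,
        seed=int(seeds[0]),
        n_sires_per_generation=cfg.n_sires_per_generation,
        n_dams_per_generation=cfg.n_dams_per_generation,
    )
    snp_map = build_snp_map(
        n_snps=cfg.n_snps,
        n_chromosomes=cfg.n_chromosomes,
        spacing_bp=cfg.snp_spacing_bp,
        n_unmapped=cfg.n_unmapped_snps,
    )
    genotypes_full = simulate_genotypes(
        pedigree,
        snp_map,
        ld_block_length_bp=cfg.ld_block_length_bp,
        seed=int(seeds[1]),
        block_correlation=cfg.block_correlation,
        block_maf_jitter=cfg.block_maf_jitter,
    )

    # QTL: mapped, common SNPs, spread over chromosomes; effect sizes from
    # the requested shares of the additive genetic variance
    arch_rng = np.random.default_rng(int(seeds[2]))
    mapped = snp_map[snp_map["chromosome"] != "0"]
    freqs = np.nanmean(genotypes_full.dosage, axis=0) / 2.0
    sigma2_a = cfg.h2 * cfg.phenotype_sd**2
    qtl_ids: list[str] = []
    qtl_effects: list[float] = []
    chroms = mapped["chromosome"].unique()
    for k, share in enumerate(cfg.qtl_variance_shares):
        chrom = chroms[k % len(chroms)]
        cand = mapped[mapped["chromosome"] == chrom]["snp_id"].to_numpy()
        cand_idx = np.array([np.nonzero(snp_map["snp_id"].to_numpy() == s)[0][0] for s in cand])
        common = cand[(freqs[cand_idx] > 0.15) & (freqs[cand_idx] < 0.85)]
        common = [s for s in common if s not in qtl_ids]
        snp = common[int(arch_rng.integers(len(common)))]
        j = int(np.nonzero(snp_map["snp_id"].to_numpy() == snp)[0][0])
        p_f = freqs[j]
        a = np.sqrt(share * sigma2_a / (2.0 * p_f * (1.0 - p_f)))
        qtl_ids.append(snp)
        qtl_effects.append(float(a * arch_rng.choice([-1.0, 1.0])))

    architecture = TraitArchitecture(
        qtl_snp_ids=tuple(qtl_ids),
        qtl_effects=np.array(qtl_effects),
        h2=cfg.h2,
        mean=cfg.mean,
        phenotype_sd=cfg.phenotype_sd,
        truncation_min=cfg.truncation_min,
    )

    farm_rng = np.random.default_rng(int(seeds[3]))
    farms = sorted(pedigree["farm"].unique())
    farm_effects = {f: float(farm_rng.normal(0.0, cfg.farm_effect_sd)) for f in farms}

    phenotypes, tbv = simulate_phenotypes(
        genotypes_full,
        architecture,
        pedigree,
        sex_effect=cfg.sex_effect,
        farm_effects=farm_effects,
        seed=int(seeds[3]),
    )

    ebv = pedigree_blup(phenotypes, pedigree, h2=cfg.h2)

    # genotyped panel: all sires + sampled no-offspring final-generation animals
    panel_rng = np.random.default_rng(int(seeds[4]))
    sire_set = set(pedigree["sire_id"]) - {UNKNOWN_PARENT}
    last_gen = pedigree["generation"].max()
    parents = set(pedigree["sire_id"]) | set(pedigree["dam_id"])
    young = pedigree[
        (pedigree["generation"] == last_gen) & ~pedigree["animal_id"].isin(parents)
    ]["animal_id"].to_numpy(dtype=object)
    n_young = min(cfg.n_genotyped_young, len(young))
    panel = sorted(sire_set) + sorted(
        panel_rng.choice(young, size=n_young, replace=False).tolist()
    )
    panel = [a for a in pedigree["animal_id"] if a in set(panel)]

    panel_snps = (
        list(genotypes_full.snps)
        if cfg.qtl_on_chip
        else [s for s in genotypes_full.snps if s not in set(qtl_ids)]
    )
    genotypes = genotypes_full.subset(animals=panel, snps=panel_snps)
    dosage = genotypes.dosage.copy()
    if cfg.missing_rate > 0:
        mask = panel_rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    if cfg.n_low_call_rate_snps > 0:
        chrom_of = dict(zip(snp_map["snp_id"], snp_map["chromosome"]))
        mapped_idx = np.array(
            [j for j, s in enumerate(genotypes.snps) if chrom_of[s] != "0"]
        )
        bad = panel_rng.choice(mapped_idx, size=cfg.n_low_call_rate_snps, replace=False)
        for j in bad:
            mask = panel_rng.random(dosage.shape[0]) < (1.0 - cfg.low_call_rate)
            dosage[mask, j] = np.nan
    genotypes = GenotypeMatrix(genotypes.animals, genotypes.snps, dosage)

    return Cohort(
        pedigree=pedigree,
        snp_map=snp_map,
        genotypes=genotypes,
        genotypes_full=genotypes_full,
        phenotypes=phenotypes,
        architecture=architecture,
        tbv=tbv,
        ebv=ebv,
        config=cfg,
    )
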