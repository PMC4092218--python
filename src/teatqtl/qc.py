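"""SNP and animal quality control for dosage matrices.

Filters mirror standard Beadchip practice: an optional per-SNP GenCall
score cut, removal of markers without a physical position, a call-rate
floor and a minor-allele-frequency floor, applied in that order with each
removed SNP attributed to the first filter it fails.  An animal-level
call-rate filter runs before the SNP filters.  After QC, residual missing
calls are mean-imputed so the sampler sees a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = ["QCReport", "compute_maf", "compute_call_rate", "filter_snps", "impute_and_center"]

FILTER_ORDER = ("gencall", "position", "call_rate", "maf")


class ConfigurationError(ValueError):
    pass


@dataclass
class QCReport:
    n_input_snps: int
    n_removed_by_filter: dict[str, int]
    n_retained: int
    snp_stats: pd.DataFrame = field(repr=False)  # snp_id, maf, call_rate, removed_by
    n_input_animals: int = 0
    n_removed_animals: int = 0

    def __post_init__(self) -> None:
        total = self.n_retained + sum(self.n_removed_by_filter.values())
        if total != self.n_input_snps:
            raise ValueError("QC accounting broken: retained + removed != input")


def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency from dosages, missing calls excluded."""
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: column is entirely missing")
    p = obs.mean() / 2.0
    return float(min(p, 1.0 - p))


def compute_call_rate(dosage_column: np.ndarray) -> float:
    col = np.asarray(dosage_column, dtype=float)
    return float(1.0 - np.isnan(col).mean())


def filter_snps(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    require_position: bool = True,
    gencall_column: pd.Series | None = None,
    min_gencall: float = 0.7,
    min_animal_call_rate: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP quality filters and return the retained matrix.

    Thresholds default to the conventional Beadchip values (GenCall 0.7,
    call rate 0.95, MAF 0.01).  ``gencall_column`` is an optional per-SNP
    score, indexed by snp_id; when absent the GenCall filter is a
    pass-through.  Removals are attributed to the first failing filter in
    the order gencall -> position -> call rate -> MAF.  Animals below
    ``min_animal_call_rate`` are removed first (set to 0 to disable).
    """
    for name, value in (
        ("min_call_rate", min_call_rate),
        ("min_maf", min_maf),
        ("min_gencall", min_gencall),
        ("min_animal_call_rate", min_animal_call_rate),
    ):
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
    map_ids = set(snp_map["snp_id"])
    missing_from_map = [s for s in genotypes.snps if s not in map_ids]
    if missing_from_map:
        raise ValueError(f"snp_map does not cover SNPs: {missing_from_map[:5]}")

    n_input_animals = genotypes.n_animals
    dosage = genotypes.dosage
    animal_cr = 1.0 - np.isnan(dosage).mean(axis=1)
    keep_animals = animal_cr >= min_animal_call_rate
    if not keep_animals.all():
        genotypes = GenotypeMatrix(
            genotypes.animals[keep_animals], genotypes.snps, dosage[keep_animals]
        )
        dosage = genotypes.dosage

    info = snp_map.set_index("snp_id")
    removed_by: list[str | None] = []
    counts = {name: 0 for name in FILTER_ORDER}
    mafs = np.full(genotypes.n_snps, np.nan)
    call_rates = np.zeros(genotypes.n_snps)
    for j, snp in enumerate(genotypes.snps):
        col = dosage[:, j]
        call_rates[j] = compute_call_rate(col)
        if call_rates[j] > 0:
            mafs[j] = compute_maf(col)
        fail: str | None = None
        if gencall_column is not None and float(gencall_column.get(snp, 1.0)) < min_gencall:
            fail = "gencall"
        elif require_position and (
            str(info.loc[snp, "chromosome"]) == "0" or int(info.loc[snp, "position_bp"]) <= 0
        ):
            fail = "position"
        elif call_rates[j] < min_call_rate:
            fail = "call_rate"
        elif np.isnan(mafs[j]) or mafs[j] < min_maf:
            fail = "maf"
        removed_by.append(fail)
        if fail is not None:
            counts[fail] += 1

    keep = np.array([f is None for f in removed_by])
    stats = pd.DataFrame(
        {
            "snp_id": genotypes.snps,
            "maf": mafs,
            "call_rate": call_rates,
            "removed_by": [f or "" for f in removed_by],
        }
    )
    filtered = GenotypeMatrix(
        genotypes.animals, genotypes.snps[keep], dosage[:, keep]
    )
    report = QCReport(
        n_input_snps=len(removed_by),
        n_removed_by_filter=counts,
        n_retained=int(keep.sum()),
        snp_stats=stats,
        n_input_animals=n_input_animals,
        n_removed_animals=int(n_input_animals - genotypes.n_animals),
    )
    return filtered, report


def impute_and_center(
    genotypes: GenotypeMatrix, center: bool = False
) -> np.ndarray:
    """Mean-impute residual missing dosages; optionally center columns.

    Non-missing entries are never touched by imputation.  Returns a float64
    matrix ready for the sampler.
    """
    X = np.asarray(genotypes.dosage, dtype=np.float64).copy()
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = means[idx[1]]
    if center:
        X -= X.mean(axis=0)
    return X
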