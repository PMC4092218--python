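"""Readers and writers for the pipeline's plain-text formats.

Tab-separated tables for pedigree, phenotypes, EBVs, dEBVs and per-SNP
results; genotypes either as PLINK text ped/map or as a dosage-TSV dialect
(animals x SNPs, header row of SNP ids, ``NA`` for missing).  Readers
reject malformed records rather than coercing them; every writer produces
files its reader round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_plink",
    "write_plink",
    "read_snp_map",
    "write_snp_map",
    "read_table",
    "write_table",
    "RunManifest",
    "file_sha256",
]

MISSING_TSV = "NA"


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TSV)
    return path


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str, "chromosome": str, "snp_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> Path:
    return write_table(snp_map[["snp_id", "chromosome", "position_bp"]], path)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=("snp_id", "chromosome", "position_bp"))
    df["position_bp"] = df["position_bp"].astype(np.int64)
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"{path}: duplicate snp_id {dup}")
    mapped = df[df["chromosome"] != "0"]
    bad = mapped.groupby("chromosome")["position_bp"].apply(
        lambda s: not s.is_monotonic_increasing
    )
    if bad.any():
        df = pd.concat(
            [
                df[df["chromosome"] != "0"].sort_values(
                    ["chromosome", "position_bp"], kind="mergesort"
                ),
                df[df["chromosome"] == "0"],
            ]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Dosage TSV dialect
# ---------------------------------------------------------------------------


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(genotypes.dosage, columns=genotypes.snps)
    df.insert(0, "animal_id", genotypes.animals)
    with np.errstate(invalid="ignore"):
        for c in genotypes.snps:
            df[c] = df[c].map(lambda v: MISSING_TSV if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)
    return path


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "animal_id" not in df.columns:
        raise ValueError(f"{path}: first column must be animal_id")
    animals = df["animal_id"].to_numpy(dtype=object)
    snps = np.array([c for c in df.columns if c != "animal_id"], dtype=object)
    raw = df[snps].to_numpy(dtype=object)
    dosage = np.empty(raw.shape, dtype=np.float32)
    for (i, j), v in np.ndenumerate(raw):
        if v == MISSING_TSV or v is None or (isinstance(v, float) and np.isnan(v)):
            dosage[i, j] = np.nan
        elif v in ("0", "1", "2"):
            dosage[i, j] = float(v)
        else:
            raise ValueError(
                f"{path}: invalid dosage {v!r} for SNP {snps[j]} (expected 0/1/2/NA)"
            )
    return GenotypeMatrix(animals, snps, dosage)


# ---------------------------------------------------------------------------
# PLINK text ped/map
# ---------------------------------------------------------------------------

_ALLELES = ("A", "B")  # writer codes dosage as count of "B"


def write_plink(
    genotypes: GenotypeMatrix, snp_map: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path]:
    """Write text .ped/.map; dosage is the count of allele 'B'."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    order = {s: i for i, s in enumerate(genotypes.snps)}
    snp_map = snp_map[snp_map["snp_id"].isin(order)].copy()
    snp_map = snp_map.sort_values("snp_id", key=lambda s: s.map(order), kind="mergesort")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in snp_map.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    ped_path = prefix.with_suffix(".ped")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(genotypes.animals):
            fields = ["FAM", str(animal), "0", "0", "0", "-9"]
            for d in genotypes.dosage[i]:
                if np.isnan(d):
                    fields.extend(["0", "0"])
                elif d == 0:
                    fields.extend(["A", "A"])
                elif d == 1:
                    fields.extend(["A", "B"])
                else:
                    fields.extend(["B", "B"])
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read text .ped/.map into dosages.

    Dosage counts the lexicographically later of the (at most two) observed
    alleles at each SNP; ``0 0`` is missing.  A third allele at any SNP is
    a format error naming that SNP.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}: malformed map line: {line.rstrip()}")
            map_rows.append((parts[1], parts[0], int(parts[3])))
    snp_map = pd.DataFrame(map_rows, columns=["snp_id", "chromosome", "position_bp"])
    p = len(snp_map)

    animals = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * p:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * p} fields "
                    f"({p} SNPs in {map_path}), got {len(parts)}"
                )
            animals.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(animals), p, 2)

    dosage = np.empty((len(animals), p), dtype=np.float32)
    snp_ids = snp_map["snp_id"].to_numpy(dtype=object)
    for j in range(p):
        col = alleles[:, j, :]
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if len(observed) > 2:
            raise ValueError(
                f"{ped_path}: SNP {snp_ids[j]} has more than two alleles: {observed}"
            )
        counted = observed[-1] if observed else "B"
        for i in range(len(animals)):
            a1, a2 = col[i]
            if a1 == "0" or a2 == "0":
                dosage[i, j] = np.nan
            else:
                dosage[i, j] = (a1 == counted) + (a2 == counted)
    return (
        GenotypeMatrix(np.array(animals, dtype=object), snp_ids, dosage),
        snp_map,
    )


def read_genotypes(
    path: str | Path, format: str = "dosage_tsv"
) -> tuple[GenotypeMatrix, pd.DataFrame | None]:
    """Read genotypes in either supported format.

    ``plink_pedmap`` expects ``path`` to be the ped/map prefix and returns
    the map as well; ``dosage_tsv`` returns ``(matrix, None)`` (the map
    travels separately).
    """
    if format == "plink_pedmap":
        return read_plink(path)
    if format == "dosage_tsv":
        return read_dosage_tsv(path), None
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(
    genotypes: GenotypeMatrix,
    path: str | Path,
    format: str = "dosage_tsv",
    snp_map: pd.DataFrame | None = None,
):
    if format == "plink_pedmap":
        if snp_map is None:
            raise ValueError("plink_pedmap needs a snp_map")
        return write_plink(genotypes, snp_map, path)
    if format == "dosage_tsv":
        return write_dosage_tsv(genotypes, path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, output hashes, timings."""

    version: str
    config: dict
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings_s: dict = field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
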