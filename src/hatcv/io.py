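"""Reading and writing the plain-text formats: genotype tables, VCF,
phenotype tables, kinship matrices, and fold assignments.

All tabular formats are TSV (CSV accepted on read).  Individuals are
always harmonized by id join, never by row position, so shuffled inputs
give identical results.  Kinship matrices are written with 17 significant
digits so a write/read round-trip is bit-exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import FoldAssignment
from .kinship import GenotypeMatrix, KinshipEigen, code_genotypes


def _read_table(path) -> pd.DataFrame:
    # sniff TSV vs CSV; round_trip parsing keeps write/read bit-exact
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_genotypes(path, missing_policy: str = "mean",
                   coding: str = "auto") -> GenotypeMatrix:
    """Genotype table: first column individual id, header row marker ids,
    cells in {-1,0,1} or {0,1,2} (auto-detected by value range)."""
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = [str(c) for c in df.columns[1:]]
    calls = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy()
    return code_genotypes(calls, ids, markers,
                          missing_policy=missing_policy, coding=coding)


def read_vcf(path, missing_policy: str = "mean") -> GenotypeMatrix:
    """VCF genotypes as allele dosages (multi-allelic sites rejected).

    Phased and unphased calls are equivalent; missing GTs follow the
    coding missing policy.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, markers = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site at {var.CHROM}:{var.POS}")
        d = var.gt_types.astype(float)  # 0,1,2 = hom-ref,het,hom-alt; 3 = .
        d[d == 3] = np.nan
        rows.append(d)
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    if not rows:
        raise ValueError("VCF contains no variants")
    dosage = np.vstack(rows).T  # individuals x markers
    return code_genotypes(dosage, ids, markers,
                          missing_policy=missing_policy, coding="dosage")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: columns id, trait(s), optional covariates."""
    df = _read_table(path)
    df = df.rename(columns={df.columns[0]: "id"})
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype file")
    return df


def write_kinship(path, kin: KinshipEigen) -> None:
    ids = kin.individual_ids or [f"ind{i + 1}" for i in range(kin.n)]
    df = pd.DataFrame(kin.A, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_kinship(path) -> KinshipEigen:
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    A = df.iloc[:, 1:].to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("kinship matrix is not square")
    return KinshipEigen(A=A, a=float(np.trace(A)) / A.shape[0],
                        individual_ids=ids)


def write_folds(path, folds: FoldAssignment, ids) -> None:
    pd.DataFrame({"id": ids, "fold": folds.assignment + 1}).to_csv(
        path, sep="\t", index=False)


def read_folds(path, ids) -> FoldAssignment:
    """Replay an external partition, harmonized to the given id order."""
    df = _read_table(path)
    df["id"] = df["id"].astype(str)
    mapping = dict(zip(df["id"], df["fold"].astype(int)))
    missing = [i for i in ids if i not in mapping]
    if missing:
        raise ValueError(f"fold file lacks ids: {missing[:5]}")
    labels = np.array([mapping[i] for i in ids]) - 1
    return FoldAssignment(n=len(ids), K=int(labels.max()) + 1,
                          assignment=labels)


def align(geno_or_kin, pheno: pd.DataFrame):
    """Harmonize genotype/kinship and phenotype tables by id join.

    Returns (object restricted and reordered to the common ids, pheno
    subset in the same order).  Raises listing mismatched ids when the
    intersection is empty.
    """
    ids_g = geno_or_kin.individual_ids
    if ids_g is None:
        raise ValueError("genotype/kinship object lacks individual ids")
    common = [i for i in ids_g if i in set(pheno["id"])]
    if not common:
        only_g = [i for i in ids_g if i not in set(pheno["id"])][:5]
        only_p = [i for i in pheno["id"] if i not in set(ids_g)][:5]
        raise ValueError(f"no shared individual ids between genotype and "
                         f"phenotype files (genotype-only: {only_g}, "
                         f"phenotype-only: {only_p})")
    pos = {i: j for j, i in enumerate(ids_g)}
    idx = np.array([pos[i] for i in common])
    if isinstance(geno_or_kin, GenotypeMatrix):
        sub = GenotypeMatrix(common, list(geno_or_kin.marker_ids),
                             geno_or_kin.codes[idx])
    else:
        sub = geno_or_kin.subset(idx)
    ph = pheno.set_index("id").loc[common].reset_index()
    return sub, ph


def write_genotypes(path, geno: GenotypeMatrix) -> None:
    df = pd.DataFrame(geno.codes, index=geno.individual_ids,
                      columns=geno.marker_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")
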