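"""Tab-delimited (and minimal VCF) readers and writers.

All tables are plain TSV with a header row; writers can prepend ``#``
comment lines carrying run metadata (config hash, seed) and readers skip
them. The genotype dosage matrix is written rows=individuals with the id in
the first column, plus a ``<stem>.variants.tsv`` sidecar holding each
column's counted and other allele (a bare dosage matrix cannot carry allele
orientation).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import GRPSVector
from .simulate import GenotypeMatrix


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_summary_stats(sumstats: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(sumstats, path, meta)


def read_summary_stats(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_phenotypes(pheno: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(pheno, path, meta)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_covariates(covars: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(covars, path, meta)


def read_covariates(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_scores(grps: GRPSVector, path, meta: dict | None = None) -> None:
    _write_tsv(grps.to_frame(), path, meta)


def read_scores(path) -> GRPSVector:
    df = _read_tsv(path)
    pts = df["pt"].unique()
    if len(pts) != 1:
        raise ValueError("score file mixes multiple thresholds")
    return GRPSVector(
        individual_ids=df["individual_id"].to_numpy(),
        score=df["score"].to_numpy(dtype=float),
        pt_threshold=float(pts[0]),
        n_variants_used=0,
        standardized=bool(np.isclose(df["score"].mean(), 0, atol=1e-6)),
    )


def write_genotypes(genotypes: GenotypeMatrix, path, meta: dict | None = None) -> None:
    path = Path(path)
    mat = pd.DataFrame(
        genotypes.dosage,
        columns=genotypes.variants["variant_id"].to_numpy(),
    )
    mat.insert(0, "individual_id", genotypes.individual_ids)
    _write_tsv(mat, path, meta)
    sidecar = path.with_suffix(".variants.tsv")
    _write_tsv(genotypes.variants, sidecar, meta)


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    mat = _read_tsv(path)
    variants = _read_tsv(path.with_suffix(".variants.tsv"))
    ids = mat["individual_id"].to_numpy()
    dosage = mat.drop(columns="individual_id").to_numpy(dtype=float)
    return GenotypeMatrix(individual_ids=ids, variants=variants, dosage=dosage)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal sites-by-sample VCF with a DS (dosage) FORMAT field.

    REF is the other allele and ALT the counted allele, so DS counts ALT
    copies; positions are synthetic (1-based variant index on chr1).
    """
    path = Path(path)
    ids = list(genotypes.individual_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n"
        )
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            ds = genotypes.dosage[:, j]
            vals = "\t".join("." if np.isnan(d) else f"{d:g}" for d in ds)
            fh.write(
                f"1\t{j + 1}\t{row.variant_id}\t{row.other_allele}\t{row.counted_allele}"
                f"\t.\t.\t.\tDS\t{vals}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a dosage VCF (DS format field) via cyvcf2."""
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    records = []
    cols = []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        cols.append(ds)
        records.append((var.ID, var.ALT[0], var.REF))
    variants = pd.DataFrame(records, columns=["variant_id", "counted_allele", "other_allele"])
    dosage = np.column_stack(cols) if cols else np.empty((len(ids), 0))
    return GenotypeMatrix(individual_ids=ids, variants=variants, dosage=dosage)
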