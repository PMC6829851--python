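"""File formats: PLINK 1 binary genotypes, TSV dialects, visit records.

TSV dialect throughout: tab-separated, header required, UTF-8, missing "NA".
The PLINK reader/writer speaks the v1.00 SNP-major .bed format bit-exactly:
magic bytes 0x6c 0x1b, mode byte 0x01, then ceil(n/4) bytes per SNP with two
bits per genotype (00 = two minor alleles, 01 = missing, 10 = heterozygous,
11 = zero minor alleles), individuals packed low bits first.
"""
from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotype import SurvivalPhenotype

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_plink", "write_plink",
    "read_phenotype", "write_phenotype",
    "read_covariates", "build_survival_phenotype",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01
# 2-bit code -> allele count (NaN = missing); index by code value
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes(G: GenotypeMatrix, path, format: str = "tsv",
                    **kwargs) -> None:
    if format == "tsv":
        df = pd.DataFrame(G.values, columns=G.snp_ids)
        df.insert(0, "id", G.individual_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "plink":
        write_plink(G, path, **kwargs)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes(path, format: str = "tsv", ploidy: int = 2) -> GenotypeMatrix:
    """Read an allele-count matrix from TSV or a PLINK .bed/.bim/.fam triple.

    For ``format="plink"`` pass the prefix (or any of the three file names).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        ids = df["id"].to_numpy()
        snp_ids = np.array([c for c in df.columns if c != "id"])
        vals = df[snp_ids].to_numpy(float)
        return GenotypeMatrix(vals, snp_ids, ids, ploidy=ploidy)
    if format == "plink":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam (PLINK 1, SNP-major). Requires diploid counts."""
    if G.ploidy != 2:
        raise ValueError("PLINK bed encodes diploid genotypes")
    prefix = Path(prefix)
    n, m = G.n_individuals, G.n_snps
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    vals = G.values.T  # SNP-major
    codes[vals == 2] = 0b00
    codes[vals == 1] = 0b10
    codes[vals == 0] = 0b11
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for i in range(4):
        chunk = codes[:, i::4]
        packed[:, : chunk.shape[1]] |= chunk << (2 * i)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": np.asarray(G.chrom), "snp_id": G.snp_ids, "cm": 0,
        "pos": np.asarray(G.pos), "a1": "A", "a2": "B",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame({
        "fid": G.individual_ids, "iid": G.individual_ids,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(str(prefix).removesuffix(".bed").removesuffix(".bim")
                  .removesuffix(".fam"))
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError("not a PLINK .bed file (bad magic bytes)")
    if raw[2] != _BED_SNP_MAJOR:
        raise ValueError("only SNP-major .bed files are supported")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * n_bytes:
        raise ValueError(
            f".bed payload is {len(body)} bytes; .bim/.fam imply {m * n_bytes}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    for i in range(4):
        codes[:, i::4] = (body >> (2 * i)) & 0b11
    vals = _BED_DECODE[codes[:, :n]].T  # individuals x SNPs
    return GenotypeMatrix(vals, bim["snp_id"].to_numpy(),
                          fam["iid"].to_numpy(), ploidy=2,
                          chrom=bim["chrom"].to_numpy(),
                          pos=bim["pos"].to_numpy())


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------

def write_phenotype(pheno: SurvivalPhenotype, path) -> None:
    pheno.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype(path) -> SurvivalPhenotype:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return SurvivalPhenotype.from_frame(df)


def read_covariates(path) -> pd.DataFrame:
    """Covariate TSV (id, sex, pc1..pcK, ...), indexed by individual id."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index("id")


# ---------------------------------------------------------------------------
# visit records -> survival phenotype
# ---------------------------------------------------------------------------

def build_survival_phenotype(visits: pd.DataFrame, target_code: str):
    """Derive (entry, exit, status] from raw visit/diagnosis-date records.

    A *case* received ``target_code`` on at least two distinct dates; the
    event age is the **second** distinct code date (a single code is treated
    as a potential false positive).  A *control* never received the code and
    is censored at the age of the last visit.  Individuals with the code on
    exactly one date match neither definition and are excluded.  Entry is
    the age at the first visit ever.

    ``visits`` columns: ``id``, ``date``; ``code`` (NA when the visit has no
    diagnosis of interest); and either ``birthdate`` or ``age`` per visit.
    Returns ``(SurvivalPhenotype, labels, exclusions)`` where ``labels`` is
    a Series (id -> "case"/"control") and ``exclusions`` logs dropped
    individuals with reasons.
    """
    df = visits.copy()
    if "age" not in df.columns:
        if "birthdate" not in df.columns:
            raise ValueError("visits need either an 'age' or 'birthdate' column")
        df["date"] = pd.to_datetime(df["date"])
        df["birthdate"] = pd.to_datetime(df["birthdate"])
        df["age"] = (df["date"] - df["birthdate"]).dt.days / DAYS_PER_YEAR
    # distinctness of code dates is judged on the calendar date when one is
    # recorded (ages may be rounded), else on the age itself
    sort_key = "date" if "date" in df.columns else "age"
    if (df["age"] < 0).any():
        raise ValueError("negative ages in visit records")
    rows, labels, excl = [], {}, []
    for ind, sub in df.sort_values(["id", sort_key]).groupby("id", sort=False):
        entry = float(sub["age"].iloc[0])
        has_code = sub["code"].astype("string") == str(target_code)
        code_dates = sub.loc[has_code, sort_key].unique()
        if len(code_dates) == 0:
            exit_age = float(sub["age"].iloc[-1])
            status, label = 0, "control"
        elif len(code_dates) == 1:
            excl.append({"id": ind, "reason": "single_code_date"})
            continue
        else:
            second = np.sort(code_dates)[1]
            exit_age = float(sub.loc[sub[sort_key] == second, "age"].iloc[0])
            status, label = 1, "case"
        if exit_age <= entry:
            excl.append({"id": ind, "reason": "exit_not_after_entry"})
            continue
        rows.append({"id": ind, "entry_age": entry, "exit_age": exit_age,
                     "event": status})
        labels[ind] = label
    out = pd.DataFrame(rows)
    if len(out) == 0:
        raise ValueError("no usable individuals in visit records")
    pheno = SurvivalPhenotype.from_frame(out)
    return pheno, pd.Series(labels, name="label"), pd.DataFrame(excl)
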