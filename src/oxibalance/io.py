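"""Reading and writing cohort tables (CSV/TSV, minimal VCF).

Participant and genotype tables are UTF-8 delimited text with a header
row.  Genotypes are dosage-coded (0/1/2 variant alleles, blank or NA for
missing); a minimal VCF v4.2 with GT-only FORMAT is accepted as an
alternative genotype source and produced as an optional export.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import SchemaError
from .simulate import ALL_COMPONENTS, CATEGORICAL_COMPONENTS, SyntheticCohort

logger = logging.getLogger(__name__)

#: Columns every participant table must provide, with their parsed dtypes.
PARTICIPANT_SCHEMA = {
    "participant_id": "string",
    "study": "category",
    "sex": "category",
    "age": "float",
    "fip": "float",
    "bmi": "float",
    "total_energy": "float",
    "education": "string",
    "hrt_current": "boolean",
    "nsaid_regular": "boolean",
    "ffq_missing_fraction": "float",
    "supplemental_carotene": "float",
    "race_white": "boolean",
}

_NUMERIC = {k for k, v in PARTICIPANT_SCHEMA.items() if v == "float"}
_BOOLEAN = {k for k, v in PARTICIPANT_SCHEMA.items() if v == "boolean"}


def _parse_float(s):
    # float() is correctly rounded, unlike the csv fast-path parsers,
    # so simulate -> write -> read round-trips bit-exactly
    try:
        return float(s)
    except (TypeError, ValueError):
        return np.nan


_NA_STRINGS = {"", "na", "nan", "<na>", "none", "null", "."}


def _coerce_numeric(df: pd.DataFrame, col: str) -> None:
    coerced = df[col].map(_parse_float)
    stripped = df[col].astype(str).str.strip().str.lower()
    bad = coerced.isna() & df[col].notna() & ~stripped.isin(_NA_STRINGS)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{col}: {n_bad} unparseable value(s) set to missing", stacklevel=3)
    df[col] = coerced


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _coerce_boolean(df: pd.DataFrame, col: str) -> None:
    s = df[col].astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=df.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    bad = out.isna() & df[col].notna() & (s != "") & (s != "nan") & (s != "<na>")
    if int(bad.sum()):
        warnings.warn(
            f"{col}: {int(bad.sum())} unparseable value(s) set to missing", stacklevel=3
        )
    df[col] = out


def read_participants(path) -> pd.DataFrame:
    """Read and type-check a participant table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    missing = set(PARTICIPANT_SCHEMA) - set(df.columns)
    if missing:
        raise SchemaError(f"participant table missing columns: {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise SchemaError(f"duplicated participant ids: {dups[:5]}")
    for col in df.columns:
        if col in _NUMERIC or (col in ALL_COMPONENTS and col not in CATEGORICAL_COMPONENTS):
            _coerce_numeric(df, col)
        elif col in _BOOLEAN:
            _coerce_boolean(df, col)
    neg_fip = df["fip"].notna() & (df["fip"] <= 0)
    if neg_fip.any():
        warnings.warn(f"fip: {int(neg_fip.sum())} non-positive value(s) set to missing")
        df.loc[neg_fip, "fip"] = np.nan
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Read a dosage-coded genotype table (participant_id + rsID columns)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "participant_id" not in df.columns:
        raise SchemaError("genotype table missing column: participant_id")
    if df["participant_id"].duplicated().any():
        raise SchemaError("duplicated participant ids in genotype table")
    df["participant_id"] = df["participant_id"].astype(str)
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~df[col].isin([0.0, 1.0, 2.0])
        if bad.any():
            warnings.warn(f"{col}: {int(bad.sum())} dosage value(s) outside 0/1/2 set to missing")
            df.loc[bad, col] = np.nan
    return df


def read_snp_meta(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"rsid", "gene", "pathway"} - set(df.columns)
    if missing:
        raise SchemaError(f"SNP metadata missing columns: {sorted(missing)}")
    bad = ~df["pathway"].isin(["AE", "BER"])
    if bad.any():
        raise SchemaError(
            f"SNP metadata: unknown pathway values {sorted(df.loc[bad, 'pathway'].unique())}"
        )
    return df


def read_cohort(participants_path, genotypes_path, snp_meta_path):
    """Read a cohort: typed participant records plus the genotype matrix.

    Genotypes may be a delimited dosage table or a minimal VCF (by
    extension ``.vcf``).  Participant/genotype tables are joined on
    ``participant_id``; a genotype column must exist for every SNP in
    the metadata table.
    """
    participants = read_participants(participants_path)
    if str(genotypes_path).endswith(".vcf"):
        genotypes = read_genotypes_vcf(genotypes_path)
    else:
        genotypes = read_genotypes(genotypes_path)
    snp_meta = read_snp_meta(snp_meta_path)
    missing_snps = set(snp_meta["rsid"]) - set(genotypes.columns)
    if missing_snps:
        raise SchemaError(f"genotype table missing SNPs: {sorted(missing_snps)[:5]}")
    return participants, genotypes, snp_meta


_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Import genotypes from a VCF; GT "0/1" becomes dosage 1, "./." missing."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data = {"participant_id": samples}
    for variant in vcf:
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        data[rsid] = [_GT_TO_DOSAGE[g] for g in variant.gt_types]
    vcf.close()
    return pd.DataFrame(data)


_DOSAGE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 (GT-only), one sample column per participant."""
    snps = [c for c in genotypes.columns if c != "participant_id"]
    samples = genotypes["participant_id"].tolist()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for pos, rsid in enumerate(snps, start=1):
            gts = [
                _DOSAGE_TO_GT.get(v, "./.") if pd.notna(v) else "./."
                for v in genotypes[rsid]
            ]
            fh.write(f"1\t{pos}\t{rsid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_cohort(cohort: SyntheticCohort, outdir, vcf: bool = False) -> dict:
    """Write a simulated cohort as CSV (participants, genotypes, SNP metadata).

    Returns a mapping of artifact name to file path.  With ``vcf=True``
    the genotypes are additionally exported as a minimal VCF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.csv",
        "genotypes": outdir / "genotypes.csv",
        "snp_meta": outdir / "snp_meta.csv",
        "truth_expected_log_fip": outdir / "truth_expected_log_fip.csv",
    }
    cohort.participants.to_csv(paths["participants"], index=False)
    cohort.genotypes.to_csv(paths["genotypes"], index=False)
    cohort.snp_meta.to_csv(paths["snp_meta"], index=False)
    cohort.expected_log_fip.rename_axis("participant_id").to_csv(
        paths["truth_expected_log_fip"]
    )
    if vcf:
        paths["genotypes_vcf"] = outdir / "genotypes.vcf"
        write_genotypes_vcf(cohort.genotypes, paths["genotypes_vcf"])
    logger.info("wrote cohort to %s", outdir)
    return {k: str(v) for k, v in paths.items()}
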