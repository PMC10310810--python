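"""Readers and writers for the plain-text exchange formats.

Two genotype formats are supported: a minimal unphased GT-only VCF 4.2
(missing calls as ``./.``) and a TSV dosage matrix (rows = variants,
columns = subjects). Phenotype/covariate, biomarker and expression tables
are TSV keyed by subject identifier, with PLINK-style integer coding for
phenotype (1=control, 2=case) and sex (1=male, 2=female).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, VARIANT_COLUMNS


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
_GT_DECODE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}


def write_vcf(geno: GenotypeDataset, path) -> None:
    """Write a minimal GT-only VCF 4.2 file (unphased; ``./.`` = missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.subject_ids))
            + "\n"
        )
        meta = geno.variant_meta
        for j, vid in enumerate(geno.variant_ids):
            row = meta.iloc[j]
            gts = "\t".join(
                _GT_CODE.get(d, "./.") for d in geno.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, subject_meta: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a minimal GT-only VCF into a :class:`GenotypeDataset`.

    Dosage is the alt-allele count of the GT field; ``./.`` maps to
    missing. Malformed records raise :class:`ParseError` naming the line.
    If ``subject_meta`` is omitted, phenotype/age/sex are filled with NaN.
    """
    subjects: list[str] = []
    ids: list[str] = []
    meta_rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    seen: set[str] = set()
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ParseError(f"line {lineno}: VCF header has no sample columns")
                subjects = fields[9:]
                header_seen = True
                continue
            if not header_seen:
                raise ParseError(f"line {lineno}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(subjects):
                raise ParseError(
                    f"line {lineno}: expected {9 + len(subjects)} columns, got {len(fields)}"
                )
            chrom, pos, vid, ref, alt = fields[:5]
            if vid in seen:
                raise ParseError(f"line {lineno}: duplicate variant identifier {vid!r}")
            seen.add(vid)
            try:
                pos_i = int(pos)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer POS {pos!r}") from None
            if fields[8].split(":")[0] != "GT":
                raise ParseError(f"line {lineno}: FORMAT must begin with GT")
            try:
                dos = np.array(
                    [_GT_DECODE[g.split(":")[0].replace("|", "/")] for g in fields[9:]]
                )
            except KeyError as exc:
                raise ParseError(
                    f"line {lineno}: unrecognized genotype {exc.args[0]!r}"
                ) from None
            ids.append(vid)
            meta_rows.append((chrom, pos_i, ref, alt))
            dosage_rows.append(dos)
    if not header_seen:
        raise ParseError("line 1: no #CHROM header found")
    variant_meta = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS, index=ids)
    if subject_meta is None:
        subject_meta = pd.DataFrame(
            {"phenotype": np.nan, "age": np.nan, "sex": np.nan}, index=subjects
        )
    dosages = (
        np.array(dosage_rows).T if dosage_rows else np.empty((len(subjects), 0))
    )
    return GenotypeDataset(dosages, variant_meta, subject_meta)


def write_dosage_tsv(geno: GenotypeDataset, path) -> None:
    """TSV dosage matrix: one row per variant, meta columns then one
    column per subject (missing = NA)."""
    df = geno.variant_meta[VARIANT_COLUMNS].copy()
    df.index.name = "variant_id"
    body = pd.DataFrame(
        geno.dosages.T, index=geno.variant_ids, columns=geno.subject_ids
    )
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, subject_meta: pd.DataFrame | None = None) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse dosage TSV: {exc}") from exc
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"dosage TSV lacks column {col!r}")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate variant identifier {dup!r}")
    subjects = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[subjects].to_numpy(dtype=float).T
    if subject_meta is None:
        subject_meta = pd.DataFrame(
            {"phenotype": np.nan, "age": np.nan, "sex": np.nan}, index=subjects
        )
    return GenotypeDataset(dosages, df[VARIANT_COLUMNS], subject_meta)


def write_pheno_tsv(geno: GenotypeDataset, path) -> None:
    out = geno.subject_meta[["phenotype", "age", "sex"]].copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_pheno_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    for col in ("phenotype", "age", "sex"):
        if col not in df.columns:
            raise ParseError(f"phenotype TSV lacks column {col!r}")
    return df


def write_table_tsv(table: pd.DataFrame, path) -> None:
    """Biomarker / expression tables keyed by subject_id."""
    out = table.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_gwas_tsv(results: pd.DataFrame, geno: GenotypeDataset, path) -> None:
    """Association output: CHR POS SNP A1 A2 OR L95 U95 BETA SE P N FLAG."""
    meta = geno.variant_meta.loc[results["variant"]]
    out = pd.DataFrame(
        {
            "CHR": meta["chrom"].to_numpy(),
            "POS": meta["pos"].to_numpy(),
            "SNP": results["variant"].to_numpy(),
            "A1": meta["alt"].to_numpy(),
            "A2": meta["ref"].to_numpy(),
            "OR": results["or_"].to_numpy(),
            "L95": results["l95"].to_numpy(),
            "U95": results["u95"].to_numpy(),
            "BETA": results["beta"].to_numpy(),
            "SE": results["se"].to_numpy(),
            "P": results["p"].to_numpy(),
            "N": results["n_used"].to_numpy(),
            "FLAG": results["flag"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
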