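"""Reading and writing genotype datasets and result tables.

Supported formats: VCF 4.x (plain or gzipped, via cyvcf2), PLINK text
PED/MAP, BED export for interval results, TSV for all tabular results, and
a sample-to-population mapping TSV (columns ``sample_id``, ``population``,
``group``).
"""

from __future__ import annotations

import os
from collections import Counter

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, ValidationError


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained.  The counted allele is ALT, so
    dosage is the ALT-allele count; ``./.`` and half-calls become missing;
    phased and unphased separators are treated alike.  Variants are sorted
    per chromosome by position.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises plain OSError on bad headers
        raise ParseError(f"cannot parse VCF header of {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    dup = [s for s, k in Counter(sample_ids).items() if k > 1]
    if dup:
        raise ValidationError(f"duplicate sample IDs in VCF: {dup}")

    rows, dosages = [], []
    for rec_no, rec in enumerate(vcf, start=1):
        ref, alts = rec.REF, rec.ALT
        if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
            continue  # non-SNP or non-biallelic
        gt = np.array([g[:2] for g in rec.genotypes], dtype=np.int64)
        dos = gt.sum(axis=1).astype(np.int8)
        dos[(gt < 0).any(axis=1)] = MISSING
        rows.append(
            {
                "snp_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chromosome": str(rec.CHROM),
                "position_bp": int(rec.POS),
                "allele_a": alts[0],
                "allele_b": ref,
            }
        )
        dosages.append(dos)
    vcf.close()
    if not rows:
        raise ParseError(f"no biallelic SNP records in {path}")

    variants = pd.DataFrame(rows)
    dosage = np.stack(dosages, axis=1)
    order = _sort_order(variants)
    samples = pd.DataFrame({"sample_id": sample_ids})
    return GenotypeMatrix(samples, variants.iloc[order], dosage[:, order])


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (allele_b as REF, allele_a as ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chromosome_labels():
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + list(gm.sample_ids)) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, var in gm.variants.iterrows():
            calls = "\t".join(gt_code[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{var.chromosome}\t{var.position_bp}\t{var.snp_id}\t"
                f"{var.allele_b}\t{var.allele_a}\t.\t.\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

_VALID_ALLELES = set("ACGT0")


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair.

    The counted allele per SNP is the minor allele determined from the file
    (lexicographic tie-break); ``0 0`` is a missing call; the family ID
    column is ingested as the population label.
    """
    variants = _read_map(map_path)
    m = len(variants)

    sample_rows, geno_rows = [], []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path} line {line_no}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} MAP rows), found {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            alleles = fields[6:]
            bad = sorted(set(alleles) - _VALID_ALLELES)
            if bad:
                raise ParseError(
                    f"{ped_path} line {line_no}: non-ACGT0 allele codes {bad}"
                )
            sample_rows.append({"sample_id": iid, "population": fid})
            geno_rows.append(alleles)
    if not sample_rows:
        raise ParseError(f"{ped_path}: no samples")

    alleles = np.array(geno_rows).reshape(len(geno_rows), m, 2)
    dosage = np.empty((len(sample_rows), m), dtype=np.int8)
    allele_a, allele_b = [], []
    for j in range(m):
        a_j = alleles[:, j, :]
        counts = Counter(a_j.ravel().tolist())
        counts.pop("0", None)
        if len(counts) > 2:
            raise ParseError(
                f"{ped_path}: SNP {variants['snp_id'].iloc[j]} has "
                f"{len(counts)} alleles (biallelic expected)"
            )
        # minor by count, lexicographic tie-break; monomorphic SNPs get the
        # (unobserved) '0' placeholder so dosage is 0 and MAF 0.
        ranked = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) == 2:
            minor, major = ranked[0][0], ranked[1][0]
        elif len(ranked) == 1:
            minor, major = "0", ranked[0][0]
        else:
            minor, major = "0", "0"
        allele_a.append(minor)
        allele_b.append(major)
        miss = (a_j == "0").any(axis=1)
        dosage[:, j] = (a_j == minor).sum(axis=1)
        dosage[miss, j] = MISSING

    variants = variants.assign(allele_a=allele_a, allele_b=allele_b)
    order = _sort_order(variants)
    return GenotypeMatrix(
        pd.DataFrame(sample_rows), variants.iloc[order], dosage[:, order]
    )


def _read_map(map_path: str) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{map_path} line {line_no}: expected 4 columns")
            rows.append(
                {
                    "snp_id": fields[1],
                    "chromosome": fields[0],
                    "position_bp": int(fields[3]),
                }
            )
    if not rows:
        raise ParseError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows)


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> tuple[str, str]:
    """Write PLINK text files ``<prefix>.ped`` / ``<prefix>.map``."""
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    with open(map_path, "w") as fh:
        for _, var in gm.variants.iterrows():
            fh.write(f"{var.chromosome}\t{var.snp_id}\t0\t{var.position_bp}\n")
    # dosage d of allele_a -> d copies of allele_a, 2-d of allele_b
    aa = gm.variants["allele_a"].to_numpy()
    bb = gm.variants["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in gm.samples.iterrows():
            parts = [str(srow.population or "0"), str(srow.sample_id), "0", "0", "0", "-9"]
            for j in range(gm.n_snps):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    parts += ["0", "0"]
                else:
                    pair = [aa[j]] * d + [bb[j]] * (2 - d)
                    parts += pair
            fh.write(" ".join(parts) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Sample map and result tables
# ---------------------------------------------------------------------------

def read_sample_map(path: str) -> pd.DataFrame:
    """Read a sample->population TSV (sample_id, population[, group])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise ParseError(f"{path}: needs columns sample_id, population")
    if "group" not in df.columns:
        df["group"] = None
    return df


def apply_sample_map(gm: GenotypeMatrix, sample_map: pd.DataFrame) -> GenotypeMatrix:
    """Attach population/group labels from a sample map to a cohort."""
    merged = gm.samples[["sample_id"]].merge(sample_map, on="sample_id", how="left")
    samples = gm.samples.copy()
    samples["population"] = merged["population"].fillna(samples["population"])
    samples["group"] = merged["group"]
    return GenotypeMatrix(samples, gm.variants, gm.dosage)


def write_table(records, path: str) -> None:
    """Write any tabular result (DataFrame or list of dicts) as TSV.

    An empty record list with known columns yields a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def intervals_to_bed(records, path: str, extra_columns: tuple[str, ...] = ()) -> None:
    """Export interval records (ROH segments or islands) as BED.

    Internal coordinates are 1-based closed; BED is 0-based half-open, so a
    segment [start_bp, end_bp] becomes ``start_bp-1`` .. ``end_bp``.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            extras = "".join(f"\t{row[c]}" for c in extra_columns if c in row)
            fh.write(
                f"{row['chromosome']}\t{int(row['start_bp']) - 1}\t"
                f"{int(row['end_bp'])}{extras}\n"
            )


def _sort_order(variants: pd.DataFrame) -> np.ndarray:
    """Stable order: chromosomes in order of first appearance, positions ascending."""
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(variants["chromosome"]))}
    keys = variants["chromosome"].map(chrom_rank).to_numpy()
    return np.lexsort((variants["position_bp"].to_numpy(), keys))
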