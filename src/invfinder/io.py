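"""Reading and writing datasets, plus the genotype-level filters.

Genotypes come either as a VCF (v4.x, biallelic SNP records, GT field) or
as a 0/1/2 TSV matrix; SNP map, individual metadata and pedigree are TSVs
keyed by snp_id / individual_id.  All TSVs are tab-separated with a header
row; '.' or 'NA' denote missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from invfinder.datatypes import (
    INDIVIDUAL_COLUMNS,
    LOCUS_COLUMNS,
    MISSING,
    GenotypeMatrix,
    Pedigree,
)

log = logging.getLogger(__name__)

_NA = ["", ".", "NA"]


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False, **kw)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# genotype parsing
# ---------------------------------------------------------------------------

def _read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, meta = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        meta.append((snp_id, var.CHROM, var.POS))
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    if n_dropped:
        log.warning("dropped %d non-biallelic/non-SNP records from %s", n_dropped, path)
    calls = np.stack(rows, axis=1)  # individuals x loci
    loci = pd.DataFrame(meta, columns=["snp_id", "contig", "contig_pos"])
    return calls, loci, samples


def _read_genotype_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """0/1/2 matrix TSV: first column snp_id, remaining columns individuals."""
    df = read_tsv(path)
    snp_ids = df.iloc[:, 0].astype(str)
    samples = list(df.columns[1:])
    calls = df.iloc[:, 1:].to_numpy(dtype=float).T
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    loci = pd.DataFrame(
        {"snp_id": snp_ids, "contig": pd.NA, "contig_pos": pd.NA}
    )
    return calls, loci, samples


def load_dataset(
    genotype_path: str | Path,
    map_path: str | Path,
    metadata_path: str | Path,
    pedigree_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, Pedigree | None]:
    """Load genotypes (VCF or TSV), annotate SNPs from the linkage map and
    attach individual metadata.  Unmapped SNPs are dropped with a logged
    count; SNPs present in the map but not genotyped are ignored.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix in {".vcf", ".gz", ".bcf"}:
        calls, loci, samples = _read_vcf(genotype_path)
    else:
        calls, loci, samples = _read_genotype_tsv(genotype_path)

    snp_map = read_tsv(map_path, dtype={"snp_id": str, "contig": str})
    required = {"snp_id", "contig", "contig_pos", "linkage_group", "cm_position"}
    if missing := required - set(snp_map.columns):
        raise ValueError(f"map file missing columns: {sorted(missing)}")
    if snp_map["snp_id"].duplicated().any():
        raise ValueError("duplicated snp_id in map file")
    neg = snp_map["cm_position"] < 0
    if neg.any():
        raise ValueError("cm_position must be non-negative")

    merged = loci[["snp_id"]].merge(
        snp_map, on="snp_id", how="left", suffixes=("", "_map")
    )
    # contig/contig_pos from the map win when the genotype file lacks them
    for col in ("contig", "contig_pos"):
        if col in loci and loci[col].notna().any():
            merged[col] = loci[col].to_numpy()
    mapped = merged["linkage_group"].notna().to_numpy()
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        log.info("dropping %d unmapped SNPs (%d retained)", n_unmapped, mapped.sum())
    if not mapped.any():
        raise ValueError("no genotyped SNP is present in the linkage map")
    calls = calls[:, mapped]
    loci = merged.loc[mapped, LOCUS_COLUMNS].reset_index(drop=True)
    loci["linkage_group"] = loci["linkage_group"].astype(int)
    loci["cm_position"] = loci["cm_position"].astype(float)

    meta = read_tsv(metadata_path, dtype={"individual_id": str})
    for col in INDIVIDUAL_COLUMNS:
        if col not in meta.columns:
            meta[col] = pd.NA
    meta = meta.set_index("individual_id")
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"individuals without metadata: {unknown[:5]}")
    individuals = meta.loc[samples].reset_index()[INDIVIDUAL_COLUMNS]

    gm = GenotypeMatrix(calls, loci, individuals)
    ped = None
    if pedigree_path is not None:
        ped = Pedigree(read_tsv(pedigree_path, dtype=str))
    return gm, ped


def write_dataset(gm: GenotypeMatrix, out_dir: str | Path, stem: str = "dataset") -> dict:
    """Write genotypes as VCF plus map/metadata TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / f"{stem}.vcf",
        "map": out_dir / f"{stem}.map.tsv",
        "metadata": out_dir / f"{stem}.meta.tsv",
    }
    _write_vcf(gm, paths["genotypes"])
    write_tsv(gm.loci, paths["map"])
    write_tsv(gm.individuals, paths["metadata"])
    return {k: str(v) for k, v in paths.items()}


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    # order records by contig then position for a well-formed VCF
    loci = gm.loci.copy()
    loci["_col"] = np.arange(len(loci))
    contig = loci["contig"].fillna("chrUn")
    pos = loci["contig_pos"].fillna(0).astype(int)
    order = np.lexsort((pos.to_numpy(), contig.to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(contig.to_numpy()[order]):
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(gm.individual_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in order:
            row = loci.iloc[j]
            gts = "\t".join(_GT[int(g)] for g in gm.calls[:, row["_col"]])
            fh.write(
                f"{contig.iloc[j]}\t{pos.iloc[j]}\t{row['snp_id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# genotype-level filters
# ---------------------------------------------------------------------------

def filter_genotypes(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    min_called: int = 20,
    max_individual_missing: float = 0.5,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the study's genotype-level filters, in order:

    1. drop individuals with missing fraction > ``max_individual_missing``;
    2. drop sites called in fewer than ``min_called`` remaining individuals;
    3. drop sites with minor allele frequency <= ``maf_min``.

    Returns the filtered matrix and a report of counts removed per step.
    The operation is idempotent: re-filtering changes nothing.
    """
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    report: dict = {
        "input_individuals": gm.n_individuals,
        "input_sites": gm.n_loci,
    }

    miss_frac = gm.missing_mask().mean(axis=1)
    keep_ind = miss_frac <= max_individual_missing
    report["individuals_removed_missing"] = int((~keep_ind).sum())
    if not keep_ind.any():
        raise ValueError("all individuals removed by missingness filter")
    gm = gm.take_individuals(np.flatnonzero(keep_ind))

    n_called = (~gm.missing_mask()).sum(axis=0)
    keep_called = n_called >= min_called
    report["sites_removed_call_rate"] = int((~keep_called).sum())
    gm = gm.take_loci(np.flatnonzero(keep_called))

    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf > maf_min
    report["sites_removed_maf"] = int((~keep_maf).sum())
    if not keep_maf.any():
        raise ValueError("all sites removed by filters")
    gm = gm.take_loci(np.flatnonzero(keep_maf))

    report["output_individuals"] = gm.n_individuals
    report["output_sites"] = gm.n_loci
    for key, value in report.items():
        log.info("filter_genotypes: %s = %d", key, value)
    return gm, report
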