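"""Core containers: genotype matrices, pedigrees and simulation truth.

Genotypes are stored as alternate-allele counts (0/1/2) in an int8 matrix
with an explicit missing sentinel; they are never imputed at this layer.
Locus and individual metadata live in pandas DataFrames so they can be
filtered, joined and written as TSV without bespoke machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1

LOCUS_COLUMNS = ["snp_id", "contig", "contig_pos", "linkage_group", "cm_position"]
INDIVIDUAL_COLUMNS = [
    "individual_id",
    "source",
    "transect_distance",
    "family_id",
    "parent_role",
]

SOURCES = {"transect", "family_parent", "family_offspring"}


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup) > 0:
        raise ValueError(f"duplicated {what}: {sorted(set(dup))[:5]}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype matrix with metadata.

    Parameters
    ----------
    calls
        int8 array of shape (n_individuals, n_loci); entries in {0, 1, 2}
        count copies of the alternate allele, ``MISSING`` marks no-calls.
    loci
        DataFrame with columns ``snp_id, contig, contig_pos,
        linkage_group, cm_position`` (one row per column of ``calls``).
        ``linkage_group``/``cm_position`` may be NaN for unmapped SNPs.
    individuals
        DataFrame with columns ``individual_id, source, transect_distance,
        family_id, parent_role`` (one row per row of ``calls``).
    """

    calls: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n_ind, n_loc = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError(
                f"calls has {n_ind} rows but {len(self.individuals)} individuals"
            )
        if len(self.loci) != n_loc:
            raise ValueError(f"calls has {n_loc} columns but {len(self.loci)} loci")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        _check_unique(self.loci["snp_id"], "snp_id")
        _check_unique(self.individuals["individual_id"], "individual_id")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.loci["snp_id"])

    @property
    def individual_ids(self) -> pd.Index:
        return pd.Index(self.individuals["individual_id"])

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- subsetting ------------------------------------------------------
    def take_individuals(self, row_idx) -> "GenotypeMatrix":
        row_idx = np.asarray(row_idx)
        return GenotypeMatrix(
            self.calls[row_idx],
            self.loci.copy(),
            self.individuals.iloc[row_idx].reset_index(drop=True),
        )

    def take_loci(self, col_idx) -> "GenotypeMatrix":
        col_idx = np.asarray(col_idx)
        return GenotypeMatrix(
            self.calls[:, col_idx],
            self.loci.iloc[col_idx].reset_index(drop=True),
            self.individuals.copy(),
        )

    def select_individuals(self, ids) -> "GenotypeMatrix":
        pos = self.individual_ids.get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown individual ids: {missing[:5]}")
        return self.take_individuals(pos)

    def loci_in_interval(
        self, linkage_group: int, start_cm: float, end_cm: float
    ) -> np.ndarray:
        """Column indices of mapped SNPs inside [start_cm, end_cm] on a LG."""
        lg = self.loci["linkage_group"].to_numpy()
        cm = self.loci["cm_position"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            inside = (lg == linkage_group) & (cm >= start_cm) & (cm <= end_cm)
        return np.flatnonzero(inside)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over called individuals."""
        called = self.calls != MISSING
        counts = np.where(called, self.calls, 0).sum(axis=0)
        n = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, counts / n, np.nan)


@dataclass
class Pedigree:
    """Full-sib family structure; families may share a parent and either
    parent may be unavailable (ungenotyped)."""

    families: pd.DataFrame  # family_id, mother_id, father_id, offspring_id rows

    def __post_init__(self) -> None:
        required = {"family_id", "mother_id", "father_id", "offspring_id"}
        missing = required - set(self.families.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        parents = set(self.families["mother_id"].dropna()) | set(
            self.families["father_id"].dropna()
        )
        offspring = set(self.families["offspring_id"])
        overlap = parents & offspring
        if overlap:
            raise ValueError(f"ids are both parent and offspring: {sorted(overlap)[:5]}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.families["family_id"].unique())

    def family(self, family_id: str) -> dict:
        rows = self.families[self.families["family_id"] == family_id]
        if rows.empty:
            raise KeyError(f"unknown family {family_id!r}")
        mother = rows["mother_id"].iloc[0]
        father = rows["father_id"].iloc[0]
        return {
            "family_id": family_id,
            "mother_id": None if pd.isna(mother) else mother,
            "father_id": None if pd.isna(father) else father,
            "offspring_ids": list(rows["offspring_id"]),
        }


@dataclass
class SimulationTruth:
    """Ground truth emitted by the synthetic hybrid-zone generator.

    Sufficient to score every pipeline stage: true karyotypes, planted
    intervals and cline parameters, arrangement-conditional allele
    frequencies, and crossover positions per simulated meiosis.
    """

    inversions: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: inversion_id, linkage_group, start_cm, end_cm, n_arrangements,
    #          centre, width, p_crab, p_wave, divergence, diversity_ratio
    karyotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: individual_id, inversion_id, arrangement_a, arrangement_b
    allele_freqs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: snp_id, arrangement (background = "-"), freq
    crossovers: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: offspring_id, parent_id, linkage_group, position_cm

    def karyotype_codes(self, inversion_id: str) -> pd.Series:
        """Copies of the derived arrangement per individual (diallelic case)."""
        rows = self.karyotypes[self.karyotypes["inversion_id"] == inversion_id]
        code = (rows["arrangement_a"] != "R").astype(int) + (
            rows["arrangement_b"] != "R"
        ).astype(int)
        return pd.Series(code.to_numpy(), index=rows["individual_id"].to_numpy())
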