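"""Analysis configuration: every downstream threshold with its default.

Defaults are the values used in the original hybrid-zone study; each is a
plain field so a YAML config file can override any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # -- genotype-level filters -----------------------------------------
    maf_min: float = 0.05  # sites with MAF <= maf_min dropped
    min_called: int = 20  # minimum called individuals per site
    max_individual_missing: float = 0.5  # individuals above this dropped

    # -- LD network ------------------------------------------------------
    ld_min_complete_pairs: int = 10  # pairwise-complete individuals for r2
    ld_threshold_step: float = 0.01  # cluster-tree threshold grid
    e_min: int = 30  # |E|min, minimum edge count of a cluster
    min_snps: int = 32  # minimum SNPs per retained cluster
    min_median_r2: float = 0.3  # minimum median intracluster LD
    composite_r2: bool = False  # Burrows' composite r2 instead of EM

    # -- karyotype calling -----------------------------------------------
    pc1_min_variance: float = 0.10  # PC1 variance fraction for acceptance
    max_intermediate_fraction: float = 0.05
    intermediate_sd: float = 3.0  # pooled within-group SDs for "intermediate"
    kmeans_restarts: int = 10
    scale_pca: bool = False  # variance-scale columns before PCA
    crab_end_window: float = 10.0  # metres defining the Crab end

    # -- diversity --------------------------------------------------------
    effective_region_length: float = 120.0  # bp per probe region
    alpha: float = 0.05

    # -- recombination ----------------------------------------------------
    segregation_p: float = 1e-3  # exact binomial distortion threshold
    min_parent_call_rate: float = 0.5  # parent karyotype requires >=50% calls
    large_gap_cm: float = 20.0  # flag informative-marker gaps beyond this

    # -- clines ------------------------------------------------------------
    cline_starts: int = 8  # multi-start optimizer initializations
    daic_min: float = 10.0  # dAIC for model selection
    deviance_min: float = 0.10  # minimum deviance explained for "clinal"
    profile_centre_grid: tuple = (85.0, 100.0, 1.0)  # start, stop, step (m)
    profile_logwidth_grid: tuple = (0.0, 4.0, 0.2)  # log-metres grid

    # -- bookkeeping -------------------------------------------------------
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)  # genotype/map/metadata/pedigree

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
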