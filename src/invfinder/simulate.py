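"""Synthetic hybrid-zone generator with planted inversions.

Generates unphased SNP genotypes for individuals along a 1-D transect,
with karyotypes drawn from true arrangement-frequency clines (local
Hardy–Weinberg), inside-inversion alleles drawn from
arrangement-conditional frequencies (the derived arrangement is seeded
from a single haplotype, so its diversity is reduced), a smooth clinal
or constant background elsewhere, and full-sib families whose meioses
follow a Poisson/no-interference crossover model with recombination
suppressed inside inversions when the parent is heterokaryotypic
(double-crossover and gene-conversion leakage at configurable rates).

No coalescent machinery is used: arrangement haplotypes come from
explicit per-arrangement allele-frequency vectors, which is fast and
sufficient to produce the LD, PCA and diversity signatures the
detection pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invfinder.clines import cline_predict
from invfinder.datatypes import (
    INDIVIDUAL_COLUMNS,
    MISSING,
    GenotypeMatrix,
    Pedigree,
    SimulationTruth,
)

__all__ = [
    "InversionSpec",
    "SimConfig",
    "FamilySpec",
    "SimulatedTransect",
    "simulate_transect",
    "simulate_families",
    "emulate_paper_design",
]


@dataclass
class InversionSpec:
    inversion_id: str
    linkage_group: int
    start_cm: float
    end_cm: float
    centre: float = 92.0  # cline centre of the derived arrangement (m)
    width: float = 10.0  # cline width (m)
    p_crab: float = 0.05  # derived-arrangement frequency at the Crab end
    p_wave: float = 0.95  # ... and at the Wave end
    n_arrangements: int = 2
    divergence: float = 0.6  # |f_R - f_A| target per inside SNP
    diversity_ratio: float = 0.5  # fraction of inside SNPs polymorphic in A
    # second derived arrangement (n_arrangements == 3)
    centre2: float | None = None
    width2: float | None = None
    p_crab2: float = 0.0
    p_wave2: float = 0.0


@dataclass
class SimConfig:
    n_individuals: int = 373
    transect_length: float = 152.0
    n_linkage_groups: int = 17
    markers_per_lg: int = 120
    lg_span_cm: float = 60.0
    snps_per_contig: int = 3
    inversions: list[InversionSpec] = field(default_factory=list)
    background_clinal_fraction: float = 0.05
    missing_rate: float = 0.02
    error_rate: float = 0.002
    rng_seed: int = 0

    def validate(self) -> None:
        for inv in self.inversions:
            if not (0 <= inv.start_cm < inv.end_cm <= self.lg_span_cm):
                raise ValueError(f"{inv.inversion_id}: interval outside LG span")
            if not (1 <= inv.linkage_group <= self.n_linkage_groups):
                raise ValueError(f"{inv.inversion_id}: bad linkage group")
            for p in (inv.p_crab, inv.p_wave, inv.p_crab2, inv.p_wave2):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{inv.inversion_id}: frequency outside [0,1]")


@dataclass
class SimulatedTransect:
    """Genotypes + haplotype-level internals needed to derive families."""

    gm: GenotypeMatrix
    truth: SimulationTruth
    config: SimConfig
    haplotypes: np.ndarray  # n x 2 x S int8 alleles (pre-error)
    hap_arrangements: dict  # inversion_id -> n x 2 array of labels
    freq_tables: dict  # per-SNP frequency model (see _build_freqs)


# ---------------------------------------------------------------------------
# marker map and frequency models
# ---------------------------------------------------------------------------

def _build_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for lg in range(1, config.n_linkage_groups + 1):
        cms = np.linspace(0.0, config.lg_span_cm, config.markers_per_lg)
        for i, cm in enumerate(cms):
            contig = f"ctg{lg}_{i // config.snps_per_contig}"
            rows.append(
                (
                    f"snp{lg}_{i}",
                    contig,
                    (i % config.snps_per_contig) * 40 + 10,
                    lg,
                    round(float(cm), 4),
                )
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "contig", "contig_pos", "linkage_group", "cm_position"]
    )


def _build_freqs(config: SimConfig, loci: pd.DataFrame, rng: np.random.Generator) -> dict:
    """Per-SNP frequency model.

    Background SNPs: constant frequency, or a shallow cline for a
    ``background_clinal_fraction`` subset (emulating the clinal SNPs of
    a hybrid zone).  Inside-inversion SNPs get one frequency per
    arrangement: ancestral f_R, and derived frequencies displaced by
    ~``divergence`` with a (1 − diversity_ratio) share fixed at the
    seeding-haplotype allele.
    """
    S = len(loci)
    base = rng.uniform(0.05, 0.95, S)
    clinal = rng.random(S) < config.background_clinal_fraction
    cl_centre = rng.uniform(
        0.3 * config.transect_length, 0.7 * config.transect_length, S
    )
    cl_width = rng.uniform(10.0, 40.0, S)
    cl_lo = rng.uniform(0.05, 0.45, S)
    cl_hi = rng.uniform(0.55, 0.95, S)

    inv_cols: dict[str, np.ndarray] = {}
    inv_freqs: dict[str, dict[str, np.ndarray]] = {}
    lg_arr = loci["linkage_group"].to_numpy()
    cm_arr = loci["cm_position"].to_numpy(dtype=float)
    for inv in config.inversions:
        cols = np.flatnonzero(
            (lg_arr == inv.linkage_group)
            & (cm_arr >= inv.start_cm)
            & (cm_arr <= inv.end_cm)
        )
        inv_cols[inv.inversion_id] = cols
        derived = ["A"] if inv.n_arrangements == 2 else ["A1", "A2"]
        freqs = _arrangement_freqs(
            base[cols], derived, inv.divergence, inv.diversity_ratio, rng
        )
        base[cols] = freqs["R"]
        inv_freqs[inv.inversion_id] = freqs
    return {
        "base": base,
        "clinal": clinal,
        "cl_centre": cl_centre,
        "cl_width": cl_width,
        "cl_lo": cl_lo,
        "cl_hi": cl_hi,
        "inv_cols": inv_cols,
        "inv_freqs": inv_freqs,
    }


def _arrangement_freqs(
    f_base: np.ndarray,
    derived: list[str],
    divergence: float,
    diversity_ratio: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Arrangement-conditional allele frequencies for inside SNPs.

    A ``divergence`` fraction of SNPs is arrangement-diagnostic: nearly
    fixed (freq < 0.05 or > 0.95) with at least two arrangements
    carrying opposite alleles — the signature that suppressed
    recombination preserves and that the LD scan detects; mean
    |f_R − f_A| over inside SNPs ≈ divergence.  Other SNPs share the
    background frequency across arrangements.  Each derived arrangement
    descends from one seeding haplotype: a (1 − diversity_ratio) share
    of its SNPs is fixed at the seed allele exactly, so
    diversity_ratio = 0 gives π = 0 within that arrangement
    (pre-error).
    """
    labels = ["R"] + derived
    S = f_base.shape[0]
    diag = rng.random(S) < divergence
    lo = rng.uniform(0.0, 0.05, (len(labels), S))
    hi = rng.uniform(0.95, 1.0, (len(labels), S))
    pattern = rng.integers(0, 2, (len(labels), S))
    same = pattern.min(axis=0) == pattern.max(axis=0)
    while same.any():  # diagnostic SNPs must distinguish >= 2 arrangements
        pattern[:, same] = rng.integers(0, 2, (len(labels), int(same.sum())))
        same = pattern.min(axis=0) == pattern.max(axis=0)
    freqs: dict[str, np.ndarray] = {}
    for ai, lab in enumerate(labels):
        f = f_base.copy()
        f[diag] = np.where(pattern[ai], hi[ai], lo[ai])[diag]
        freqs[lab] = f
    for lab in derived:
        f = freqs[lab]
        seed_allele = (rng.random(S) < f).astype(float)
        mono = rng.random(S) >= diversity_ratio
        freqs[lab] = np.where(mono, seed_allele, f)
    return freqs


def _background_freq_at(freq_tables: dict, x: np.ndarray) -> np.ndarray:
    """(n, S) ancestral/background allele frequency at positions x."""
    base = freq_tables["base"]
    n, S = len(x), len(base)
    F = np.broadcast_to(base, (n, S)).copy()
    cl = freq_tables["clinal"]
    if cl.any():
        z = -4.0 * (x[:, None] - freq_tables["cl_centre"][cl][None, :]) / (
            freq_tables["cl_width"][cl][None, :]
        )
        lo = freq_tables["cl_lo"][cl][None, :]
        hi = freq_tables["cl_hi"][cl][None, :]
        F[:, cl] = lo + (hi - lo) / (1.0 + np.exp(z))
    return F


# ---------------------------------------------------------------------------
# transect simulation
# ---------------------------------------------------------------------------

def _arrangement_probs(inv: InversionSpec, x: np.ndarray) -> np.ndarray:
    """(n, n_arr) per-position arrangement probabilities (R first)."""
    p1 = cline_predict(
        x,
        {"centre": inv.centre, "width": inv.width, "p_crab": inv.p_crab, "p_wave": inv.p_wave},
    )
    if inv.n_arrangements == 2:
        return np.stack([1.0 - p1, p1], axis=1)
    p2 = cline_predict(
        x,
        {
            "centre": inv.centre2 if inv.centre2 is not None else inv.centre,
            "width": inv.width2 if inv.width2 is not None else inv.width,
            "p_crab": inv.p_crab2,
            "p_wave": inv.p_wave2,
        },
    )
    total = np.clip(p1 + p2, None, 1.0)
    scale = np.where(p1 + p2 > 0, total / np.maximum(p1 + p2, 1e-12), 1.0)
    p1, p2 = p1 * scale, p2 * scale
    return np.stack([1.0 - p1 - p2, p1, p2], axis=1)


def simulate_transect(
    config: SimConfig, seed: int | None = None
) -> SimulatedTransect:
    """Simulate transect individuals with planted inversions.

    Individuals are placed uniformly on [0, L]; per inversion each of an
    individual's two haplotypes draws an arrangement from the true cline
    (karyotype ~ Binomial(2, p(x)) in the diallelic case); haplotype
    alleles come from per-arrangement frequencies inside inversions and
    from the background model elsewhere; missingness and genotype errors
    are applied last.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    n, L = config.n_individuals, config.transect_length
    x = np.sort(rng.uniform(0.0, L, n))
    loci = _build_map(config)
    S = len(loci)
    freq_tables = _build_freqs(config, loci, rng)

    F_bg = _background_freq_at(freq_tables, x)
    hap = np.empty((n, 2, S), dtype=np.int8)
    for h in (0, 1):
        hap[:, h, :] = (rng.random((n, S)) < F_bg).astype(np.int8)

    hap_arr: dict[str, np.ndarray] = {}
    kary_rows = []
    freq_rows = []
    for inv in config.inversions:
        cols = freq_tables["inv_cols"][inv.inversion_id]
        freqs = freq_tables["inv_freqs"][inv.inversion_id]
        labels = ["R"] + (["A"] if inv.n_arrangements == 2 else ["A1", "A2"])
        probs = _arrangement_probs(inv, x)
        cum = np.cumsum(probs, axis=1)
        draws = rng.random((n, 2))
        arr_idx = (draws[:, :, None] > cum[:, None, :]).sum(axis=2)
        arr_idx = np.minimum(arr_idx, len(labels) - 1)
        lab_arr = np.array(labels, dtype=object)[arr_idx]
        hap_arr[inv.inversion_id] = lab_arr
        for h in (0, 1):
            for ai, lab in enumerate(labels):
                sel = arr_idx[:, h] == ai
                if not sel.any():
                    continue
                f = freqs[lab]
                hap[np.flatnonzero(sel)[:, None], h, cols[None, :]] = (
                    rng.random((int(sel.sum()), len(cols))) < f
                ).astype(np.int8)
        for i in range(n):
            kary_rows.append(
                (f"ind{i}", inv.inversion_id, lab_arr[i, 0], lab_arr[i, 1])
            )
        for lab in labels:
            for c, fr in zip(cols, freqs[lab]):
                freq_rows.append((loci["snp_id"].iloc[c], inv.inversion_id, lab, fr))

    G = hap.sum(axis=1).astype(np.int8)
    G = _apply_noise(G, config, rng)

    individuals = pd.DataFrame(
        {
            "individual_id": [f"ind{i}" for i in range(n)],
            "source": "transect",
            "transect_distance": x,
            "family_id": pd.NA,
            "parent_role": pd.NA,
        }
    )[INDIVIDUAL_COLUMNS]
    gm = GenotypeMatrix(G, loci, individuals)
    truth = SimulationTruth(
        inversions=pd.DataFrame(
            [
                {
                    "inversion_id": v.inversion_id,
                    "linkage_group": v.linkage_group,
                    "start_cm": v.start_cm,
                    "end_cm": v.end_cm,
                    "n_arrangements": v.n_arrangements,
                    "centre": v.centre,
                    "width": v.width,
                    "p_crab": v.p_crab,
                    "p_wave": v.p_wave,
                    "divergence": v.divergence,
                    "diversity_ratio": v.diversity_ratio,
                }
                for v in config.inversions
            ]
        ),
        karyotypes=pd.DataFrame(
            kary_rows,
            columns=["individual_id", "inversion_id", "arrangement_a", "arrangement_b"],
        ),
        allele_freqs=pd.DataFrame(
            freq_rows, columns=["snp_id", "inversion_id", "arrangement", "freq"]
        ),
    )
    return SimulatedTransect(
        gm=gm,
        truth=truth,
        config=config,
        haplotypes=hap,
        hap_arrangements=hap_arr,
        freq_tables=freq_tables,
    )


def _apply_noise(
    G: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    G = G.copy()
    if config.error_rate > 0:
        err = rng.random(G.shape) < config.error_rate
        if err.any():
            # symmetric miscall: replace with one of the two other codes
            shift = rng.integers(1, 3, size=int(err.sum()))
            G[err] = ((G[err] + shift) % 3).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = MISSING
    return G


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    family_id: str
    n_offspring: int
    mother_karyotypes: dict | None = None  # inversion_id -> (lab_a, lab_b)
    father_karyotypes: dict | None = None
    father_id: str | None = None  # reuse an existing father (shared sire)
    mother_genotyped: bool = True
    mother_position: float = 150.0  # Wave-end mothers, as in the crosses
    father_position: float = 150.0


@dataclass
class _Parent:
    individual_id: str
    position: float
    haplotypes: np.ndarray  # 2 x S
    arrangements: dict  # inversion_id -> (lab_hap0, lab_hap1)


def _draw_parent(
    sim: SimulatedTransect,
    pid: str,
    position: float,
    karyotypes: dict | None,
    rng: np.random.Generator,
) -> _Parent:
    cfg = sim.config
    ft = sim.freq_tables
    S = sim.gm.n_loci
    F_bg = _background_freq_at(ft, np.array([position]))[0]
    hap = (rng.random((2, S)) < F_bg).astype(np.int8)
    arrangements: dict[str, tuple] = {}
    for inv in cfg.inversions:
        cols = ft["inv_cols"][inv.inversion_id]
        freqs = ft["inv_freqs"][inv.inversion_id]
        labels = ["R"] + (["A"] if inv.n_arrangements == 2 else ["A1", "A2"])
        if karyotypes and inv.inversion_id in karyotypes:
            labs = tuple(karyotypes[inv.inversion_id])
        else:
            probs = _arrangement_probs(inv, np.array([position]))[0]
            labs = tuple(rng.choice(labels, size=2, p=probs / probs.sum()))
        for h, lab in enumerate(labs):
            if lab not in freqs:
                raise ValueError(
                    f"parent karyotype {lab!r} inconsistent with "
                    f"{inv.inversion_id} ({labels})"
                )
            hap[h, cols] = (rng.random(len(cols)) < freqs[lab]).astype(np.int8)
        arrangements[inv.inversion_id] = labs
    return _Parent(pid, position, hap, arrangements)


def _meiosis(
    parent: _Parent,
    sim: SimulatedTransect,
    rng: np.random.Generator,
    double_crossover_rate: float,
    gene_conversion_rate: float,
) -> tuple[np.ndarray, dict, list]:
    """One gamete: crossovers Poisson(map length in Morgans), positions
    uniform on the cM scale (no interference); crossovers inside an
    inversion are rejected when the parent is heterokaryotypic there,
    except double-crossover leakage; gene conversion copies single loci
    across at a per-locus rate."""
    cfg = sim.config
    loci = sim.gm.loci
    lg_arr = loci["linkage_group"].to_numpy()
    cm_arr = loci["cm_position"].to_numpy(dtype=float)
    S = sim.gm.n_loci
    gamete = np.empty(S, dtype=np.int8)
    gamete_arr: dict[str, str] = {}
    events: list[tuple[int, float]] = []
    het_intervals: dict[int, list[tuple[float, float, str]]] = {}
    reversed_intervals: dict[int, list[tuple[float, float]]] = {}
    for inv in cfg.inversions:
        a, b = parent.arrangements[inv.inversion_id]
        if a != b:
            het_intervals.setdefault(inv.linkage_group, []).append(
                (inv.start_cm, inv.end_cm, inv.inversion_id)
            )
        elif a != "R":
            # homokaryotype for a derived arrangement: free recombination,
            # but in the reversed gene order relative to the reference map
            reversed_intervals.setdefault(inv.linkage_group, []).append(
                (inv.start_cm, inv.end_cm)
            )
    for lg in range(1, cfg.n_linkage_groups + 1):
        cols = np.flatnonzero(lg_arr == lg)
        span = cfg.lg_span_cm
        n_co = rng.poisson(span / 100.0)
        pos = np.sort(rng.uniform(0.0, span, n_co))
        blocked = het_intervals.get(lg, [])
        kept = []
        for p in pos:
            inside = any(s <= p <= e for s, e, _ in blocked)
            if not inside:
                kept.append(p)
            elif rng.random() < double_crossover_rate:
                # leakage: a tight double crossover inside the inversion
                kept.extend([p, min(p + 1e-3, span)])
        kept = np.asarray(sorted(kept))
        start = int(rng.integers(0, 2))
        cm_lg = cm_arr[cols].copy()
        # phase is evaluated in the parent's own gene order: inside an
        # inversion carried in two derived copies, marker coordinates
        # are reflected (crossovers there behave as in the reversed map)
        for s, e in reversed_intervals.get(lg, []):
            inside = (cm_lg >= s) & (cm_lg <= e)
            cm_lg[inside] = s + e - cm_lg[inside]
        phase = (start + np.searchsorted(kept, cm_lg, side="right")) % 2
        gamete[cols] = parent.haplotypes[0, cols] * (phase == 0) + parent.haplotypes[
            1, cols
        ] * (phase == 1)
        # per-locus gene conversion across haplotypes
        if gene_conversion_rate > 0:
            gc = rng.random(len(cols)) < gene_conversion_rate
            if gc.any():
                other = 1 - phase[gc]
                gamete[cols[gc]] = parent.haplotypes[other, cols[gc]]
        events.extend((lg, float(p)) for p in kept)
        # arrangement transmitted per inversion on this LG
        for inv in cfg.inversions:
            if inv.linkage_group != lg:
                continue
            mid = 0.5 * (inv.start_cm + inv.end_cm)
            ph = (start + int(np.searchsorted(kept, mid, side="right"))) % 2
            gamete_arr[inv.inversion_id] = parent.arrangements[inv.inversion_id][ph]
    return gamete, gamete_arr, events


def simulate_families(
    sim: SimulatedTransect,
    family_specs: list[FamilySpec],
    seed: int = 0,
    double_crossover_rate: float = 1e-4,
    gene_conversion_rate: float = 1e-5,
) -> tuple[GenotypeMatrix, Pedigree, SimulationTruth]:
    """Simulate full-sib families from the transect's frequency model.

    Returns the family genotype matrix (parents + offspring; an
    ungenotyped parent has all calls missing), the pedigree, and truth
    with crossover positions per meiosis and offspring karyotypes."""
    rng = np.random.default_rng(seed)
    cfg = sim.config
    parents: dict[str, _Parent] = {}
    rows, ids, meta_rows, ped_rows = [], [], [], []
    kary_rows, xo_rows = [], []

    def ensure_parent(pid, position, kary):
        if pid not in parents:
            parents[pid] = _draw_parent(sim, pid, position, kary, rng)
        return parents[pid]

    for spec in family_specs:
        mid = f"{spec.family_id}_mother"
        fid = spec.father_id or f"{spec.family_id}_father"
        mother = ensure_parent(mid, spec.mother_position, spec.mother_karyotypes)
        father = ensure_parent(fid, spec.father_position, spec.father_karyotypes)
        for pid, parent, role, genotyped in (
            (mid, mother, "mother", spec.mother_genotyped),
            (fid, father, "father", True),
        ):
            if pid not in ids:
                ids.append(pid)
                g = parent.haplotypes.sum(axis=0).astype(np.int8)
                if not genotyped:
                    g = np.full_like(g, MISSING)
                rows.append(g)
                meta_rows.append(
                    (pid, "family_parent", np.nan, spec.family_id, role)
                )
                for inv in cfg.inversions:
                    a, b = parent.arrangements[inv.inversion_id]
                    kary_rows.append((pid, inv.inversion_id, a, b))
        for k in range(spec.n_offspring):
            oid = f"{spec.family_id}_off{k}"
            gm_g, gm_arr, gm_ev = _meiosis(
                mother, sim, rng, double_crossover_rate, gene_conversion_rate
            )
            gf_g, gf_arr, gf_ev = _meiosis(
                father, sim, rng, double_crossover_rate, gene_conversion_rate
            )
            ids.append(oid)
            rows.append((gm_g + gf_g).astype(np.int8))
            meta_rows.append((oid, "family_offspring", np.nan, spec.family_id, pd.NA))
            ped_rows.append((spec.family_id, mid, fid, oid))
            for inv in cfg.inversions:
                kary_rows.append(
                    (
                        oid,
                        inv.inversion_id,
                        gm_arr[inv.inversion_id],
                        gf_arr[inv.inversion_id],
                    )
                )
            for lg, p in gm_ev:
                xo_rows.append((oid, mid, lg, p))
            for lg, p in gf_ev:
                xo_rows.append((oid, fid, lg, p))

    calls = np.vstack(rows)
    individuals = pd.DataFrame(
        meta_rows,
        columns=["individual_id", "source", "transect_distance", "family_id", "parent_role"],
    )[INDIVIDUAL_COLUMNS]
    gm = GenotypeMatrix(calls, sim.gm.loci.copy(), individuals)
    ped = Pedigree(
        pd.DataFrame(ped_rows, columns=["family_id", "mother_id", "father_id", "offspring_id"])
    )
    truth = SimulationTruth(
        inversions=sim.truth.inversions.copy(),
        karyotypes=pd.DataFrame(
            kary_rows,
            columns=["individual_id", "inversion_id", "arrangement_a", "arrangement_b"],
        ),
        crossovers=pd.DataFrame(
            xo_rows, columns=["offspring_id", "parent_id", "linkage_group", "position_cm"]
        ),
    )
    return gm, ped, truth


# ---------------------------------------------------------------------------
# study-shaped fixture
# ---------------------------------------------------------------------------

def paper_like_inversions() -> list[InversionSpec]:
    """Planted inversions mirroring the study's layout: clusters on 11
    of 17 linkage groups, including overlapping (three-arrangement)
    regions on LG6 and LG14, with clinal centres in the mid-80s to high
    90s metres and widths from a few metres to a few tens of metres."""
    specs = [
        InversionSpec("INV1.1", 1, 0.0, 4.0, centre=90, width=12, p_crab=0.3, p_wave=0.8),
        InversionSpec("INV1.2", 1, 44.0, 52.0, centre=95, width=20, p_crab=0.2, p_wave=0.6),
        InversionSpec("INV2.1", 2, 0.0, 14.0, centre=88, width=8, p_crab=0.1, p_wave=0.9),
        InversionSpec("INV4.1", 4, 1.0, 6.0, centre=92, width=10, p_crab=0.05, p_wave=0.95),
        InversionSpec(
            "INV6.1", 6, 8.0, 29.0, centre=92, width=6, p_crab=0.02, p_wave=0.55,
            n_arrangements=3, centre2=90.0, width2=15.0, p_crab2=0.05, p_wave2=0.40,
        ),
        InversionSpec("INV7.1", 7, 36.0, 42.0, centre=96, width=14, p_crab=0.2, p_wave=0.7),
        InversionSpec("INV9.1", 9, 18.0, 42.0, centre=86, width=25, p_crab=0.35, p_wave=0.75),
        InversionSpec("INV10.1", 10, 0.5, 5.0, centre=99, width=9, p_crab=0.1, p_wave=0.98),
        InversionSpec("INV11.1", 11, 50.0, 56.0, centre=91, width=18, p_crab=0.3, p_wave=0.65),
        InversionSpec("INV12.1", 12, 3.0, 30.0, centre=84, width=3, p_crab=0.15, p_wave=0.85),
        InversionSpec(
            "INV14.1", 14, 0.5, 12.0, centre=92, width=36, p_crab=0.1, p_wave=0.8,
            n_arrangements=3, centre2=94.0, width2=20.0, p_crab2=0.05, p_wave2=0.15,
        ),
        InversionSpec("INV17.1", 17, 47.0, 59.0, centre=93, width=11, p_crab=0.02, p_wave=0.9),
    ]
    return specs


def paper_like_families() -> list[FamilySpec]:
    """Four Wave-ecotype full-sib families (8, 21, 12 and 11 offspring);
    the first three share the same father and one mother is
    ungenotyped."""
    return [
        FamilySpec("fam1", 8, father_id="shared_father"),
        FamilySpec("fam2", 21, father_id="shared_father", mother_genotyped=False),
        FamilySpec("fam3", 12, father_id="shared_father"),
        FamilySpec("fam4", 11),
    ]


def emulate_paper_design(
    seed: int = 0, scale: float = 1.0
) -> tuple[SimulatedTransect, GenotypeMatrix, Pedigree, SimulationTruth]:
    """Study-shaped fixture bundle at a configurable marker-density
    scale: 373 transect individuals over 152 m, 17 linkage groups with
    ~40k mapped SNPs at scale=1, planted inversions on 11 LGs (two
    three-arrangement regions), and the four full-sib families."""
    markers_per_lg = max(int(round(40000 / 17 * scale)), 40)
    cfg = SimConfig(
        n_individuals=373,
        markers_per_lg=markers_per_lg,
        inversions=paper_like_inversions(),
        rng_seed=seed,
    )
    sim = simulate_transect(cfg, seed=seed)
    fam_gm, ped, fam_truth = simulate_families(
        sim, paper_like_families(), seed=seed + 1
    )
    return sim, fam_gm, ped, fam_truth
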