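"""Family-based recombination analysis.

Full-sib families give direct evidence for inversions: crossovers are
absent inside a rearranged region when the informative parent carries
both arrangements (heterokaryotype), and when a parent is homokaryotypic
for the alternative arrangement its offspring's haplotype switches are
more parsimonious under the reversed gene order.

The analysis proceeds per parent: keep markers heterozygous in exactly
that parent (QC'd for Mendelian errors and segregation distortion),
phase the parent's two haplotypes by minimizing switch counts summed
over offspring, call each haplotype switch as a crossover, discard
events supported only by a single SNP or by consecutive SNPs within one
contig (conservative), and classify offspring haplotypes by gene-order
parsimony with the candidate block reversed or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from invfinder.datatypes import MISSING, GenotypeMatrix

__all__ = [
    "CrossoverEvent",
    "infer_parent_karyotypes",
    "informative_sites_qc",
    "transmitted_alleles",
    "call_crossovers",
    "orientation_classify",
    "suppression_summary",
]


@dataclass
class CrossoverEvent:
    family_id: str
    parent_id: str
    offspring_id: str
    linkage_group: int
    left_cm: float
    right_cm: float
    left_snp: str
    right_snp: str
    left_contig: str
    right_contig: str
    inside_soc: str | None = None  # soc_id if fully inside a candidate
    large_gap: bool = False  # flanking-marker gap > threshold


# ---------------------------------------------------------------------------
# parent karyotypes
# ---------------------------------------------------------------------------

def infer_parent_karyotypes(
    gm_joint: GenotypeMatrix,
    candidates: list,
    parent_ids: list[str],
    seed: int = 0,
    restarts: int = 10,
    min_call_rate: float = 0.5,
    crab_end_window: float = 10.0,
) -> pd.DataFrame:
    """Karyotype of each parent at each candidate, via joint PCA +
    k-means over transect and family samples together.

    Parents genotyped at fewer than ``min_call_rate`` of the SOC SNPs
    get NA.  Returns a parent x soc_id table of labels (RR/RA/AA or the
    three-arrangement labels).
    """
    from invfinder import karyotype as kt

    rows_parent = gm_joint.individual_ids.get_indexer(parent_ids)
    if (rows_parent < 0).any():
        raise KeyError("parent id missing from joint matrix")
    dist = gm_joint.individuals["transect_distance"].to_numpy(dtype=float)

    out = {}
    for cand in candidates:
        soc = cand.soc if hasattr(cand, "soc") else cand
        cols = gm_joint.loci_in_interval(soc.linkage_group, soc.start_cm, soc.end_cm)
        k = getattr(cand, "k", 3) if hasattr(cand, "k") else 3
        pca = kt.region_pca(gm_joint, soc.linkage_group, soc.start_cm, soc.end_cm)
        assignment = kt.assign_groups(
            pca, k=k, restarts=restarts, seed=seed, soc_id=soc.soc_id
        )
        labelled = kt.orient_and_label(
            assignment, pca, dist, crab_end_window=crab_end_window
        )
        labels = {}
        for pid, row in zip(parent_ids, rows_parent):
            called = (gm_joint.calls[row, cols] != MISSING).mean() if cols.size else 0.0
            if called < min_call_rate:
                labels[pid] = "NA"
            else:
                labels[pid] = labelled.labels.get(int(labelled.group[row]), "NA")
        out[soc.soc_id] = labels
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# informative markers
# ---------------------------------------------------------------------------

def informative_sites_qc(
    gm: GenotypeMatrix,
    family: dict,
    segregation_p: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Per-parent informative marker sets for one full-sib family.

    A marker is informative for a parent when that parent is
    heterozygous and the other parent is homozygous (markers
    heterozygous in both parents are excluded).  If the other parent is
    ungenotyped at a site, its homozygous genotype is imputed from the
    offspring when they carry only one of its alleles; sites where
    offspring show both are excluded.  Markers with any
    Mendelian-impossible offspring genotype, or failing an exact
    binomial test of 1:1 transmission at ``segregation_p``, are removed.
    """
    off_ids = family["offspring_ids"]
    if not off_ids:
        raise ValueError(f"family {family['family_id']} has no genotyped offspring")
    off_rows = gm.individual_ids.get_indexer(off_ids)
    off_rows = off_rows[off_rows >= 0]
    if off_rows.size == 0:
        raise ValueError(f"family {family['family_id']} has no genotyped offspring")
    G_off = gm.calls[off_rows]

    def parent_row(pid):
        if pid is None:
            return None
        pos = gm.individual_ids.get_indexer([pid])[0]
        return None if pos < 0 else pos

    rows = {"mother": parent_row(family["mother_id"]), "father": parent_row(family["father_id"])}
    genos = {
        role: (gm.calls[r] if r is not None else np.full(gm.n_loci, MISSING, dtype=np.int8))
        for role, r in rows.items()
    }

    out: dict[str, np.ndarray] = {}
    for role, other in (("mother", "father"), ("father", "mother")):
        pid = family[f"{role}_id"]
        if pid is None or rows[role] is None:
            continue
        gp = genos[role].astype(int)
        go = genos[other].astype(int)
        focal_het = gp == 1
        other_geno = _resolve_other_parent(go, G_off)
        informative = focal_het & (other_geno >= 0) & (other_geno != 1)
        cols = np.flatnonzero(informative)
        keep = []
        for c in cols:
            t = _transmitted(G_off[:, c], other_geno[c])
            valid = t >= 0
            n = int(valid.sum())
            if n == 0:
                continue
            # Mendelian check: impossible offspring genotype at a
            # het x hom site (e.g. hom for the allele the hom parent lacks)
            if _mendel_impossible(G_off[:, c], other_geno[c]):
                continue
            k = int(t[valid].sum())
            if stats.binomtest(k, n, 0.5).pvalue < segregation_p:
                continue
            keep.append(c)
        out[pid] = np.asarray(keep, dtype=int)
    return out


def _resolve_other_parent(go: np.ndarray, G_off: np.ndarray) -> np.ndarray:
    """Other-parent genotype per site; -9 where unusable.

    Missing other-parent calls are imputed as homozygous when offspring
    genotypes are consistent with only one transmitted allele."""
    out = go.copy()
    missing = go == MISSING
    if missing.any():
        has0 = ((G_off == 0) & True).any(axis=0)
        has2 = (G_off == 2).any(axis=0)
        # offspring hom-ref present -> other parent transmitted ref;
        # hom-alt present -> transmitted alt; both -> other parent het
        imput = np.full(go.shape, -9)
        imput[has0 & ~has2] = 0
        imput[has2 & ~has0] = 2
        imput[~has0 & ~has2] = -9  # only hets: cannot resolve
        out = np.where(missing, imput, out)
    out = np.where(out == MISSING, -9, out)
    return out


def _transmitted(g_off: np.ndarray, other_hom: int) -> np.ndarray:
    """Allele transmitted by the focal (het) parent per offspring:
    1 = alt, 0 = ref, -9 = missing/inconsistent."""
    a = other_hom // 2  # allele contributed by the hom parent (0 or 1)
    t = g_off.astype(int) - a
    t[(g_off == MISSING) | (t < 0) | (t > 1)] = -9
    return t


def _mendel_impossible(g_off: np.ndarray, other_hom: int) -> bool:
    called = g_off != MISSING
    if other_hom == 0:
        return bool((g_off[called] == 2).any())
    return bool((g_off[called] == 0).any())


# ---------------------------------------------------------------------------
# crossover calling
# ---------------------------------------------------------------------------

def _phase_and_assign(T: np.ndarray) -> np.ndarray:
    """Greedy minimal-switch phasing of the focal parent.

    T: offspring x markers transmitted-allele matrix (1/0/-9), markers
    in working order.  Returns H: offspring x markers haplotype
    assignment (1, 2 or -9).  The parent's phase is seeded at the first
    marker and each subsequent marker's orientation is chosen to
    minimize the number of offspring switching haplotype.
    """
    n_off, n_mark = T.shape
    H = np.full_like(T, -9)
    state = np.full(n_off, -9)
    for m in range(n_mark):
        t = T[:, m]
        obs = t >= 0
        # orientation o: hap1 carries allele o at this marker
        costs = []
        for o in (0, 1):
            h = np.where(t == o, 1, 2)
            switches = int(((state >= 0) & obs & (h != state)).sum())
            costs.append(switches)
        o = 0 if costs[0] <= costs[1] else 1
        h = np.where(t == o, 1, 2)
        H[obs, m] = h[obs]
        state = np.where(obs, h, state)
    return H


def _runs(h: np.ndarray, contigs: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of constant haplotype over non-missing markers:
    (start_idx, end_idx, hap) with indices into the marker order."""
    idx = np.flatnonzero(h >= 0)
    runs = []
    for i in idx:
        if runs and h[i] == runs[-1][2]:
            runs[-1] = (runs[-1][0], i, runs[-1][2])
        else:
            runs.append((i, i, int(h[i])))
    return runs


def _filter_runs(
    runs: list[tuple[int, int, int]], h: np.ndarray, contigs: np.ndarray
) -> list[tuple[int, int, int]]:
    """Drop runs supported only by a single SNP or only by consecutive
    SNPs within one contig (possible genotyping artefacts), merging
    their neighbours; iterate until stable."""

    def removable(run) -> bool:
        s, e, _ = run
        members = [i for i in range(s, e + 1) if h[i] >= 0]
        if len(members) == 1:
            return True
        return len(set(contigs[members])) == 1

    runs = list(runs)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        # remove the weakest removable run first (fewest supporting SNPs)
        cands = [r for r in runs if removable(r)]
        if not cands:
            break
        weakest = min(cands, key=lambda r: sum(1 for i in range(r[0], r[1] + 1) if h[i] >= 0))
        i = runs.index(weakest)
        runs.pop(i)
        changed = True
        # merge now-adjacent runs with the same haplotype
        j = 1
        while j < len(runs):
            if runs[j][2] == runs[j - 1][2]:
                runs[j - 1] = (runs[j - 1][0], runs[j][1], runs[j][2])
                runs.pop(j)
            else:
                j += 1
    return runs


def call_crossovers(
    gm: GenotypeMatrix,
    family_id: str,
    parent_id: str,
    offspring_ids: list[str],
    informative_cols: np.ndarray,
    linkage_group: int,
    order: np.ndarray | None = None,
    large_gap_cm: float = 20.0,
    count_only: bool = False,
    filter_events: bool = True,
):
    """Call crossovers for one parent on one linkage group.

    ``informative_cols`` are column indices of this parent's informative
    markers; ``order`` optionally permutes them (used to test reversed
    gene orders), defaulting to map order (cM, then contig/position).
    Each haplotype switch between consecutive retained runs is one
    event; events are filtered per the conservative single-SNP /
    single-contig rule unless ``filter_events`` is off.  ``count_only``
    returns just the per-offspring event counts (used by orientation
    parsimony, which compares raw switch counts because the filter is
    not invariant to reordering the markers).
    """
    loci = gm.loci
    on_lg = informative_cols[
        loci["linkage_group"].to_numpy()[informative_cols] == linkage_group
    ]
    if on_lg.size < 2:
        raise ValueError(
            f"<2 informative markers for {parent_id} on LG{linkage_group}"
        )
    cm = loci["cm_position"].to_numpy(dtype=float)[on_lg]
    contig = loci["contig"].to_numpy()[on_lg].astype(str)
    pos = loci["contig_pos"].to_numpy()[on_lg]
    if order is None:
        order = np.lexsort((pos, contig, cm))
    cols = on_lg[order]
    cm_o = cm[order]
    contig_o = contig[order]
    snp_o = loci["snp_id"].to_numpy()[cols]

    off_rows = gm.individual_ids.get_indexer(offspring_ids)
    keep = off_rows >= 0
    off_rows = off_rows[keep]
    kept_ids = [i for i, k in zip(offspring_ids, keep) if k]
    other_geno = _infer_other_from_offspring(gm.calls[off_rows][:, cols])
    T = _transmitted_matrix(gm.calls[off_rows][:, cols], other_geno)

    H = _phase_and_assign(T)
    counts = np.zeros(len(kept_ids), dtype=int)
    events: list[CrossoverEvent] = []
    for j, oid in enumerate(kept_ids):
        runs = _runs(H[j], contig_o)
        if filter_events:
            runs = _filter_runs(runs, H[j], contig_o)
        counts[j] = max(len(runs) - 1, 0)
        if count_only:
            continue
        for (s1, e1, _), (s2, e2, _) in zip(runs[:-1], runs[1:]):
            left = max(i for i in range(s1, e1 + 1) if H[j, i] >= 0)
            right = min(i for i in range(s2, e2 + 1) if H[j, i] >= 0)
            events.append(
                CrossoverEvent(
                    family_id=family_id,
                    parent_id=parent_id,
                    offspring_id=oid,
                    linkage_group=int(linkage_group),
                    left_cm=float(cm_o[left]),
                    right_cm=float(cm_o[right]),
                    left_snp=str(snp_o[left]),
                    right_snp=str(snp_o[right]),
                    left_contig=str(contig_o[left]),
                    right_contig=str(contig_o[right]),
                    large_gap=bool(abs(cm_o[right] - cm_o[left]) > large_gap_cm),
                )
            )
    if count_only:
        return counts
    return events, counts


def _infer_other_from_offspring(G_off: np.ndarray) -> np.ndarray:
    """Per-marker hom genotype of the non-focal parent, inferred from
    offspring (used when markers were pre-filtered as informative)."""
    has0 = (G_off == 0).any(axis=0)
    has2 = (G_off == 2).any(axis=0)
    out = np.full(G_off.shape[1], -9)
    out[has0 & ~has2] = 0
    out[has2 & ~has0] = 2
    out[~has0 & ~has2] = 0  # only hets seen: either hom works, pick ref
    return out


def _transmitted_matrix(G_off: np.ndarray, other_geno: np.ndarray) -> np.ndarray:
    T = np.full(G_off.shape, -9, dtype=int)
    for c in range(G_off.shape[1]):
        if other_geno[c] < 0:
            continue
        T[:, c] = _transmitted(G_off[:, c], int(other_geno[c]))
    return T


# ---------------------------------------------------------------------------
# orientation parsimony
# ---------------------------------------------------------------------------

def reversed_block_order(
    gm: GenotypeMatrix,
    informative_cols: np.ndarray,
    linkage_group: int,
    start_cm: float,
    end_cm: float,
) -> np.ndarray:
    """Marker permutation with the [start_cm, end_cm] block reversed,
    relative to the reference (map) order.  Reversing twice restores the
    reference order exactly."""
    loci = gm.loci
    on_lg = informative_cols[
        loci["linkage_group"].to_numpy()[informative_cols] == linkage_group
    ]
    cm = loci["cm_position"].to_numpy(dtype=float)[on_lg]
    contig = loci["contig"].to_numpy()[on_lg].astype(str)
    pos = loci["contig_pos"].to_numpy()[on_lg]
    ref = np.lexsort((pos, contig, cm))
    inside = (cm[ref] >= start_cm) & (cm[ref] <= end_cm)
    out = ref.copy()
    out[inside] = ref[inside][::-1]
    return out


def orientation_classify(
    gm: GenotypeMatrix,
    family_id: str,
    parent_id: str,
    offspring_ids: list[str],
    informative_cols: np.ndarray,
    soc,
) -> pd.DataFrame:
    """Classify each offspring haplotype as more consistent with the
    reference gene order (R) or the reversed-block order (A).

    Crossover counts are computed under both orders; the call is the
    order with fewer events, or 'uninformative' on a tie (haplotypes
    needing two crossovers under one order may need only one under the
    other)."""
    counts_r = call_crossovers(
        gm, family_id, parent_id, offspring_ids, informative_cols,
        soc.linkage_group, order=None, count_only=True, filter_events=False,
    )
    rev = reversed_block_order(
        gm, informative_cols, soc.linkage_group, soc.start_cm, soc.end_cm
    )
    counts_a = call_crossovers(
        gm, family_id, parent_id, offspring_ids, informative_cols,
        soc.linkage_group, order=rev, count_only=True, filter_events=False,
    )
    call = np.where(
        counts_r < counts_a, "R", np.where(counts_a < counts_r, "A", "uninformative")
    )
    return pd.DataFrame(
        {
            "offspring_id": offspring_ids[: len(counts_r)],
            "soc_id": soc.soc_id,
            "crossovers_under_R": counts_r,
            "crossovers_under_A": counts_a,
            "call": call,
        }
    )


# ---------------------------------------------------------------------------
# suppression summary
# ---------------------------------------------------------------------------

def _karyotype_class(label: str) -> str:
    if label in ("RR",):
        return "RR"
    if label in ("AA", "A1A1", "A2A2"):
        return "AA"
    if label in ("RA", "RA1", "RA2", "A1A2"):
        return "RA"
    return "NA"


def suppression_summary(
    events: list[CrossoverEvent],
    parent_karyotypes: pd.DataFrame,
    candidates: list,
    cases: pd.DataFrame,
) -> pd.DataFrame:
    """Tabulate crossover events by parent karyotype class (RR/RA/AA)
    and region class (inside a candidate vs collinear).

    ``cases`` lists every evaluable parent x offspring x SOC
    combination (columns parent_id, offspring_id, soc_id); an event
    counts as inside a SOC only when both flanking markers fall within
    the candidate interval (events spanning a boundary are collinear,
    conservatively).
    """
    socs = {
        (c.soc if hasattr(c, "soc") else c).soc_id: (c.soc if hasattr(c, "soc") else c)
        for c in candidates
    }

    def event_soc(ev: CrossoverEvent) -> str | None:
        for sid, soc in socs.items():
            if (
                soc.linkage_group == ev.linkage_group
                and soc.start_cm <= ev.left_cm
                and ev.right_cm <= soc.end_cm
            ):
                return sid
        return None

    records = []
    for _, case in cases.iterrows():
        sid = case["soc_id"]
        label = parent_karyotypes.loc[case["parent_id"], sid]
        kclass = _karyotype_class(label)
        if kclass == "NA":
            continue
        n_inside = sum(
            1
            for ev in events
            if ev.parent_id == case["parent_id"]
            and ev.offspring_id == case["offspring_id"]
            and event_soc(ev) == sid
        )
        records.append((kclass, "inside_soc", sid, 1, n_inside))
        lg = socs[sid].linkage_group
        n_col = sum(
            1
            for ev in events
            if ev.parent_id == case["parent_id"]
            and ev.offspring_id == case["offspring_id"]
            and ev.linkage_group == lg
            and event_soc(ev) is None
        )
        records.append((kclass, "collinear", sid, 1, n_col))
    df = pd.DataFrame(
        records,
        columns=["parent_karyotype", "region_class", "soc_id", "n_cases", "n_events"],
    )
    if df.empty:
        return pd.DataFrame(
            columns=["parent_karyotype", "region_class", "n_cases", "n_events"]
        )
    return (
        df.groupby(["parent_karyotype", "region_class"], as_index=False)[
            ["n_cases", "n_events"]
        ]
        .sum()
        .sort_values(["parent_karyotype", "region_class"])
        .reset_index(drop=True)
    )
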