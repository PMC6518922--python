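"""Within-linkage-group LD and single-outlier cluster (SOC) extraction.

Candidate rearrangements are found as clusters of SNPs in unusually high
mutual LD.  Pairwise r² is estimated by EM over the 9-cell two-locus
genotype table (maximum-likelihood haplotype frequencies from unphased
diploids), a single-linkage cluster tree is grown over a descending grid
of r² thresholds, and clusters whose change-in-median-LD statistic (λ)
stands out are extracted as SOCs.  A sweep over the stringency parameter
φ with the study's overlap-resolution rules yields the final candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invfinder.datatypes import MISSING, GenotypeMatrix

__all__ = [
    "LDMatrix",
    "ClusterTree",
    "SOC",
    "pairwise_r2",
    "build_cluster_tree",
    "extract_socs",
    "phi_sweep_select",
    "soc_interval",
    "detect_socs",
]


# ---------------------------------------------------------------------------
# pairwise r2 by EM
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise r² within one linkage group.

    Undefined pairs (too few pairwise-complete individuals, or a
    monomorphic member) are NaN.
    """

    linkage_group: int
    snp_ids: list
    r2: np.ndarray
    cm_positions: np.ndarray | None = None
    contigs: np.ndarray | None = None

    def defined_fraction(self) -> float:
        off = ~np.eye(len(self.snp_ids), dtype=bool)
        return float(np.isfinite(self.r2[off]).mean()) if off.any() else 1.0


def _cell_counts(G: np.ndarray) -> list[list[np.ndarray]]:
    """9 SxS matrices n[a][b] of individuals with genotypes (a, b) per pair."""
    ind = [(G == g).astype(np.float64) for g in (0, 1, 2)]
    return [[ind[a].T @ ind[b] for b in range(3)] for a in range(3)]


def _em_haplotype_r2(
    n: list[list[np.ndarray]], max_iter: int = 200, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM for two-locus haplotype frequencies over all pairs.

    Returns (r2, pA, pB) where pA/pB are alt-allele frequencies on the
    pairwise-complete individuals.  The only latent quantity is the phase
    of double heterozygotes; EM is run from three initializations of the
    double-het split and the solution with the highest multinomial
    likelihood is kept per pair.
    """
    N = sum(n[a][b] for a in range(3) for b in range(3))
    with np.errstate(invalid="ignore", divide="ignore"):
        # allele counts at each locus of the pair
        cA = sum((a) * n[a][b] for a in range(3) for b in range(3))
        cB = sum((b) * n[a][b] for a in range(3) for b in range(3))
        pA = cA / (2 * N)
        pB = cB / (2 * N)

    twoN = 2 * N
    # fixed haplotype-count contributions (everything except double hets)
    base11 = 2 * n[2][2] + n[2][1] + n[1][2]
    base10 = 2 * n[2][0] + n[2][1] + n[1][0]
    base01 = 2 * n[0][2] + n[1][2] + n[0][1]
    base00 = 2 * n[0][0] + n[0][1] + n[1][0]
    ndh = n[1][1]

    best_ll = np.full(N.shape, -np.inf)
    best_p11 = np.full(N.shape, np.nan)
    for f0 in (0.01, 0.5, 0.99):
        f = np.full(N.shape, f0)
        with np.errstate(invalid="ignore", divide="ignore"):
            for _ in range(max_iter):
                p11 = (base11 + f * ndh) / twoN
                p10 = (base10 + (1 - f) * ndh) / twoN
                p01 = (base01 + (1 - f) * ndh) / twoN
                p00 = (base00 + f * ndh) / twoN
                num = p11 * p00
                den = num + p10 * p01
                f_new = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
                delta = np.nanmax(np.abs(f_new - f)) if f.size else 0.0
                f = f_new
                if delta < tol:
                    break
            p11 = (base11 + f * ndh) / twoN
            p10 = (base10 + (1 - f) * ndh) / twoN
            p01 = (base01 + (1 - f) * ndh) / twoN
            p00 = (base00 + f * ndh) / twoN
            ll = _pair_loglik(n, p11, p10, p01, p00)
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_p11 = np.where(better, p11, best_p11)

    with np.errstate(invalid="ignore", divide="ignore"):
        D = best_p11 - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0), np.nan)
    return r2, pA, pB


def _pair_loglik(n, p11, p10, p01, p00) -> np.ndarray:
    """Multinomial log-likelihood of the 9-cell table under random union
    of gametes with the given haplotype frequencies."""
    probs = {
        (2, 2): p11 * p11,
        (2, 1): 2 * p11 * p10,
        (2, 0): p10 * p10,
        (1, 2): 2 * p11 * p01,
        (1, 1): 2 * p11 * p00 + 2 * p10 * p01,
        (1, 0): 2 * p10 * p00,
        (0, 2): p01 * p01,
        (0, 1): 2 * p01 * p00,
        (0, 0): p00 * p00,
    }
    ll = np.zeros_like(p11)
    for (a, b), pr in probs.items():
        ll += n[a][b] * np.log(np.maximum(pr, 1e-300))
    return ll


def pairwise_r2(
    gm: GenotypeMatrix,
    linkage_group: int,
    min_complete_pairs: int = 10,
    composite: bool = False,
) -> LDMatrix:
    """r² between all SNP pairs on one linkage group.

    EM maximum-likelihood haplotype frequencies from unphased genotypes
    over pairwise-complete individuals; pairs with fewer than
    ``min_complete_pairs`` complete individuals or a monomorphic member
    are flagged undefined (NaN).  ``composite=True`` switches to the
    genotypic (Burrows-style) correlation, which needs no phase model.
    """
    cols = np.flatnonzero(gm.loci["linkage_group"].to_numpy() == linkage_group)
    if cols.size == 0:
        raise ValueError(f"linkage group {linkage_group} absent from map")
    if cols.size < 2:
        raise ValueError(f"need >=2 SNPs on linkage group {linkage_group}")
    sub = gm.loci.iloc[cols]
    G = gm.calls[:, cols]

    if composite:
        r2 = _composite_r2(G)
        n = (~((G[:, :, None] == MISSING) | (G[:, None, :] == MISSING))).sum(0)
        pA = None
    else:
        counts = _cell_counts(G)
        n = sum(counts[a][b] for a in range(3) for b in range(3))
        r2, pA, pB = _em_haplotype_r2(counts)
        mono = (pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1)
        r2 = np.where(mono, np.nan, r2)
    r2 = np.where(n >= min_complete_pairs, r2, np.nan)
    np.fill_diagonal(r2, 1.0)
    r2 = np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return LDMatrix(
        linkage_group=int(linkage_group),
        snp_ids=list(sub["snp_id"]),
        r2=r2,
        cm_positions=sub["cm_position"].to_numpy(dtype=float),
        contigs=sub["contig"].to_numpy(),
    )


def _composite_r2(G: np.ndarray) -> np.ndarray:
    X = np.where(G == MISSING, np.nan, G).astype(float)
    df = pd.DataFrame(X)
    corr = df.corr(min_periods=2).to_numpy()
    return corr * corr


# ---------------------------------------------------------------------------
# single-linkage cluster tree over descending thresholds
# ---------------------------------------------------------------------------

@dataclass
class MergeEvent:
    threshold: float  # grid threshold at which the merge happens
    child_nodes: tuple[int, int]
    node: int  # id of the merged cluster
    members: np.ndarray  # SNP indices of the merged cluster
    child_members: tuple[np.ndarray, np.ndarray]
    child_lambda: tuple[float, float]  # change-in-median-LD per child
    child_edges: tuple[int, int]  # |E| per child at this threshold
    child_median: tuple[float, float]
    merged_median: float


@dataclass
class ClusterTree:
    """Merge history of single-linkage agglomeration on r² thresholds.

    Thresholds are non-increasing along the merge sequence and member
    sets are nested.  Each merge records, for both child clusters, the
    statistic λ = (median intra-cluster r² before the merge − median
    after) × child size, and the child's edge count |E| (pairs with
    r² ≥ the merge threshold).
    """

    n_snps: int
    snp_ids: list
    merges: list[MergeEvent] = field(default_factory=list)
    working_r2: np.ndarray | None = None  # undefined pairs as 0


def build_cluster_tree(ldm: LDMatrix, threshold_step: float = 0.01) -> ClusterTree:
    """Single-linkage agglomeration over descending r² thresholds.

    Edges are processed in decreasing r², quantized down to the threshold
    grid (1.0 → 0 in ``threshold_step`` decrements); ties are broken by
    smaller SNP index.  Undefined r² is treated as 0.
    """
    S = len(ldm.snp_ids)
    W = np.where(np.isfinite(ldm.r2), ldm.r2, 0.0)
    if S == 1:
        return ClusterTree(n_snps=1, snp_ids=list(ldm.snp_ids), working_r2=W)
    if not np.isfinite(ldm.r2[~np.eye(S, dtype=bool)]).any() and S > 1:
        raise ValueError("all off-diagonal r2 entries are undefined")

    iu, ju = np.triu_indices(S, k=1)
    w = W[iu, ju]
    # descending weight, ties by smaller first index then second
    order = np.lexsort((ju, iu, -w))
    thresholds = np.floor(w / threshold_step + 1e-9) * threshold_step

    parent = np.arange(2 * S - 1)
    node_of = np.arange(S)  # current tree-node id of each root component
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(S)}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = ClusterTree(n_snps=S, snp_ids=list(ldm.snp_ids), working_r2=W)
    next_node = S
    for e in order:
        a, b = find(iu[e]), find(ju[e])
        if a == b:
            continue
        t = max(thresholds[e], 0.0)
        na, nb = node_of[a], node_of[b]
        ma, mb = members[na], members[nb]
        merged = np.concatenate([ma, mb])
        med_a = _median_intra(W, ma)
        med_b = _median_intra(W, mb)
        med_m = _median_intra(W, merged)
        lam_a = max(med_a - med_m, 0.0) * len(ma) if len(ma) > 1 else 0.0
        lam_b = max(med_b - med_m, 0.0) * len(mb) if len(mb) > 1 else 0.0
        tree.merges.append(
            MergeEvent(
                threshold=float(t),
                child_nodes=(int(na), int(nb)),
                node=next_node,
                members=merged,
                child_members=(ma, mb),
                child_lambda=(float(lam_a), float(lam_b)),
                child_edges=(_edge_count(W, ma, t), _edge_count(W, mb, t)),
                child_median=(float(med_a), float(med_b)),
                merged_median=float(med_m),
            )
        )
        root = a
        parent[b] = a
        node_of[root] = next_node
        members[next_node] = merged
        del members[na], members[nb]
        next_node += 1
    return tree


def _median_intra(W: np.ndarray, members: np.ndarray) -> float:
    if len(members) < 2:
        return np.nan
    sub = W[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(np.median(sub[iu]))


def _edge_count(W: np.ndarray, members: np.ndarray, t: float) -> int:
    if len(members) < 2:
        return 0
    sub = W[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return int((sub[iu] >= t).sum())


# ---------------------------------------------------------------------------
# SOC extraction and the phi sweep
# ---------------------------------------------------------------------------

@dataclass
class SOC:
    """Single-outlier cluster: a candidate rearrangement."""

    soc_id: str
    linkage_group: int
    snp_ids: list
    n_snps: int
    n_contigs: int
    median_r2: float
    phi_at_extraction: int
    start_cm: float = np.nan
    end_cm: float = np.nan
    size_cm: float = np.nan
    snp_indices: np.ndarray | None = None

    def snp_set(self) -> frozenset:
        return frozenset(self.snp_ids)


def extract_socs(
    tree: ClusterTree,
    phi: int,
    e_min: int = 30,
    min_snps: int = 32,
    min_median_r2: float = 0.3,
    linkage_group: int = 0,
    contigs: np.ndarray | None = None,
) -> list[SOC]:
    """Extract single-outlier clusters at stringency φ.

    A cluster is extracted at the merge where it disappears if its λ
    exceeds the level implied by φ (λ × 10 > φ, the integer stringency
    scale) and it has at least ``e_min`` internal edges at that
    threshold.  A qualifying cluster that contains a previously
    extracted cluster is a compound-outlier cluster and is never
    emitted.  Extracted clusters are then filtered to ``min_snps`` and
    ``min_median_r2``.
    """
    socs, _ = _extract_socs_counted(
        tree, phi, e_min, min_snps, min_median_r2, linkage_group, contigs
    )
    return socs


def _extract_socs_counted(
    tree: ClusterTree,
    phi: int,
    e_min: int,
    min_snps: int,
    min_median_r2: float,
    linkage_group: int,
    contigs: np.ndarray | None,
) -> tuple[list[SOC], int]:
    """extract_socs plus the count of clusters extracted before the
    size/median filters (the φ sweep continues while this is > 0)."""
    if phi < 0:
        raise ValueError("phi must be a non-negative integer")
    extracted_nodes: set[int] = set()
    n_extracted = 0
    socs: list[SOC] = []
    W = tree.working_r2
    for ev in tree.merges:
        for side in (0, 1):
            node = ev.child_nodes[side]
            mem = ev.child_members[side]
            lam = ev.child_lambda[side]
            if len(mem) < 2:
                continue
            if lam * 10.0 <= phi or ev.child_edges[side] < e_min:
                continue
            compound = _contains_extracted(tree, node, extracted_nodes)
            extracted_nodes.add(node)
            if compound:
                continue
            n_extracted += 1
            med = _median_intra(W, mem)
            if len(mem) < min_snps or med < min_median_r2:
                continue
            snps = [tree.snp_ids[i] for i in mem]
            n_contigs = (
                len(pd.unique(contigs[mem])) if contigs is not None else len(snps)
            )
            socs.append(
                SOC(
                    soc_id="",
                    linkage_group=linkage_group,
                    snp_ids=snps,
                    n_snps=len(snps),
                    n_contigs=n_contigs,
                    median_r2=med,
                    phi_at_extraction=int(phi),
                    snp_indices=np.sort(mem),
                )
            )
    return socs, n_extracted


def _contains_extracted(tree: ClusterTree, node: int, extracted: set[int]) -> bool:
    if not extracted:
        return False
    stack = [node]
    children = {ev.node: ev.child_nodes for ev in tree.merges}
    while stack:
        cur = stack.pop()
        if cur in extracted:
            return True
        if cur in children:
            stack.extend(children[cur])
    return False


def phi_sweep_select(
    tree: ClusterTree,
    e_min: int = 30,
    min_snps: int = 32,
    min_median_r2: float = 0.3,
    linkage_group: int = 0,
    contigs: np.ndarray | None = None,
    max_phi: int = 300,
) -> list[SOC]:
    """Sweep φ = 0, 1, 2, … until no clusters are extracted at all
    (retained or not), then resolve overlaps among the union of
    retained SOCs.

    Among SOCs sharing SNPs across φ values the one with the smaller
    number of SNPs (and higher median LD) is retained, EXCEPT when two
    SNP-disjoint overlapping SOCs fuse into a single larger SOC at
    higher φ, in which case the merged SOC replaces both.
    """
    collected: list[SOC] = []
    for phi in range(max_phi + 1):
        socs, n_extracted = _extract_socs_counted(
            tree, phi, e_min, min_snps, min_median_r2, linkage_group, contigs
        )
        if n_extracted == 0:
            break
        collected.extend(socs)

    # deduplicate identical SNP sets, keeping the smallest phi
    by_set: dict[frozenset, SOC] = {}
    for soc in collected:
        key = soc.snp_set()
        if key not in by_set or soc.phi_at_extraction < by_set[key].phi_at_extraction:
            by_set[key] = soc
    unique = list(by_set.values())

    # overlap components
    kept: list[SOC] = []
    unassigned = list(range(len(unique)))
    adj = {
        i: {
            j
            for j in range(len(unique))
            if j != i and unique[i].snp_set() & unique[j].snp_set()
        }
        for i in range(len(unique))
    }
    seen: set[int] = set()
    for i in unassigned:
        if i in seen:
            continue
        comp = _component(i, adj)
        seen |= comp
        group = [unique[j] for j in comp]
        kept.append(_resolve_overlap(group))
    return sorted(kept, key=lambda s: (min(s.snp_indices) if s.snp_indices is not None else 0))


def _component(start: int, adj: dict) -> set[int]:
    comp, stack = set(), [start]
    while stack:
        cur = stack.pop()
        if cur in comp:
            continue
        comp.add(cur)
        stack.extend(adj[cur])
    return comp


def _resolve_overlap(group: list[SOC]) -> SOC:
    if len(group) == 1:
        return group[0]
    # merge exception: two SNP-disjoint members that both overlap a larger
    # member extracted at higher phi -> keep the fused cluster
    for c in group:
        others = [s for s in group if s is not c]
        disjoint_pairs = [
            (a, b)
            for i, a in enumerate(others)
            for b in others[i + 1 :]
            if not (a.snp_set() & b.snp_set())
            and (a.snp_set() & c.snp_set())
            and (b.snp_set() & c.snp_set())
        ]
        if disjoint_pairs and c.phi_at_extraction > max(
            p for a, b in disjoint_pairs for p in (a.phi_at_extraction, b.phi_at_extraction)
        ):
            return c
    # default rule: smallest SNP count; ties by higher median LD
    return min(group, key=lambda s: (s.n_snps, -s.median_r2))


def soc_interval(soc: SOC, snp_map: pd.DataFrame) -> tuple[float, float, float]:
    """Map interval of a SOC: extremes of member-SNP cM positions.

    ``snp_map`` needs columns snp_id and cm_position.
    """
    cm = snp_map.set_index("snp_id")["cm_position"]
    missing = [s for s in soc.snp_ids if s not in cm.index]
    if missing:
        raise KeyError(f"unmapped member SNPs: {missing[:5]}")
    pos = cm.loc[soc.snp_ids].to_numpy(dtype=float)
    start, end = float(np.min(pos)), float(np.max(pos))
    return start, end, end - start


def detect_socs(gm: GenotypeMatrix, config) -> list[SOC]:
    """Full LD-network scan: per linkage group, r² → cluster tree → φ
    sweep → interval annotation.  SOC ids are LGC<lg>.<k> ordered by
    start position."""
    socs: list[SOC] = []
    for lg in sorted(gm.loci["linkage_group"].dropna().unique()):
        lg = int(lg)
        cols = np.flatnonzero(gm.loci["linkage_group"].to_numpy() == lg)
        if cols.size < 2:
            continue
        ldm = pairwise_r2(
            gm,
            lg,
            min_complete_pairs=config.ld_min_complete_pairs,
            composite=config.composite_r2,
        )
        try:
            tree = build_cluster_tree(ldm, threshold_step=config.ld_threshold_step)
        except ValueError:
            continue
        found = phi_sweep_select(
            tree,
            e_min=config.e_min,
            min_snps=config.min_snps,
            min_median_r2=config.min_median_r2,
            linkage_group=lg,
            contigs=ldm.contigs,
        )
        lg_map = pd.DataFrame(
            {"snp_id": ldm.snp_ids, "cm_position": ldm.cm_positions}
        )
        for k, soc in enumerate(
            sorted(found, key=lambda s: soc_interval(s, lg_map)[0]), start=1
        ):
            soc.start_cm, soc.end_cm, soc.size_cm = soc_interval(soc, lg_map)
            soc.soc_id = f"LGC{lg}.{k}"
            socs.append(soc)
    return socs
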