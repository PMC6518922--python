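"""Karyotype assignment within candidate rearrangements.

For each SOC, a PCA over ALL SNPs inside its map interval (not just the
high-LD members) separates individuals into karyotype groups: two
homokaryotype clusters at the extremes of PC1 and heterokaryotypes in
between, or six groups on PC1/PC2 when three arrangements segregate.
Groups are found by k-means (best of ``restarts`` runs by between-SS
fraction), candidates are filtered on PC1 variance and on the rarity of
intermediate individuals, and arrangements are oriented against the
Crab end of the transect (R = most common arrangement there).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from invfinder.datatypes import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "KaryotypeAssignment",
    "CandidateInversion",
    "region_pca",
    "assign_groups",
    "candidate_filter",
    "orient_and_label",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # individuals x components
    variance_fraction: np.ndarray  # non-increasing, sums to <= 1
    loadings: np.ndarray  # SNPs x components


@dataclass
class KaryotypeAssignment:
    soc_id: str
    k: int
    group: np.ndarray  # group index per individual (0..k-1)
    between_ss_fraction: float
    manual_override: bool = False
    labels: dict = field(default_factory=dict)  # group index -> e.g. "RR"
    copies: np.ndarray | None = None  # copies of arrangement A (diallelic)


@dataclass
class CandidateInversion:
    soc: object
    pca: PCAResult
    assignment: KaryotypeAssignment
    status: str  # accepted | rejected_pc1 | rejected_intermediates
    intermediate_fraction: float = 0.0


def region_pca(
    gm: GenotypeMatrix,
    linkage_group: int,
    start_cm: float,
    end_cm: float,
    rows: np.ndarray | None = None,
    scale: bool = False,
    n_components: int = 2,
) -> PCAResult:
    """PCA on mean-imputed, column-centred genotype codes of all SNPs in
    [start_cm, end_cm] on a linkage group.

    Columns are centred but not variance-scaled by default, so rare SNPs
    do not dominate; ``scale=True`` switches to correlation-style PCA.
    """
    cols = gm.loci_in_interval(linkage_group, start_cm, end_cm)
    if cols.size < 3:
        raise ValueError(
            f"interval [{start_cm}, {end_cm}] on LG{linkage_group} has "
            f"{cols.size} SNPs (need >= 3)"
        )
    X = gm.calls[:, cols].astype(float)
    if rows is not None:
        X = X[np.asarray(rows)]
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    total_var = (X**2).sum()
    if total_var <= 0:
        raise ValueError("no variance in the region (all columns constant)")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    varfrac = (s**2) / total_var
    return PCAResult(
        scores=scores, variance_fraction=varfrac[:k], loadings=Vt[:k].T
    )


def assign_groups(
    pca: PCAResult,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    soc_id: str = "",
    manual_boundaries: list[float] | None = None,
) -> KaryotypeAssignment:
    """k-means on PC1 (k=3) or PC1+PC2 jointly (k=6), keeping the run
    with the highest between-SS / total-SS over ``restarts`` restarts.

    ``manual_boundaries`` supports the manual-override path: PC1 cut
    points defining the groups directly (used when no k-means run
    reflects the visible structure).
    """
    if k not in (3, 6):
        raise ValueError("k must be 3 or 6")
    X = pca.scores[:, :1] if k == 3 else pca.scores[:, :2]
    if manual_boundaries is not None:
        cuts = np.sort(np.asarray(manual_boundaries, dtype=float))
        group = np.digitize(pca.scores[:, 0], cuts)
        bss = _between_ss_fraction(X, group)
        return KaryotypeAssignment(
            soc_id=soc_id,
            k=int(np.unique(group).size),
            group=group,
            between_ss_fraction=bss,
            manual_override=True,
        )
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct score points")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    bss = _between_ss_fraction(X, km.labels_)
    return KaryotypeAssignment(
        soc_id=soc_id, k=k, group=km.labels_, between_ss_fraction=bss
    )


def _between_ss_fraction(X: np.ndarray, labels: np.ndarray) -> float:
    grand = X.mean(axis=0)
    total = ((X - grand) ** 2).sum()
    if total <= 0:
        return 0.0
    within = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(1.0 - within / total)


def candidate_filter(
    soc,
    pca: PCAResult,
    assignment: KaryotypeAssignment,
    pc1_min: float = 0.10,
    max_intermediate_fraction: float = 0.05,
    intermediate_sd: float = 3.0,
) -> CandidateInversion:
    """Accept a candidate only if PC1 explains at least ``pc1_min`` of
    the variance and intermediate individuals are rare.

    An individual is "intermediate" when its score lies farther than
    ``intermediate_sd`` pooled within-group standard deviations from its
    group centroid, in the direction of an adjacent centroid.
    """
    if pca.variance_fraction[0] < pc1_min:
        return CandidateInversion(soc, pca, assignment, "rejected_pc1")
    frac = _intermediate_fraction(pca, assignment, intermediate_sd)
    if frac > max_intermediate_fraction:
        return CandidateInversion(
            soc, pca, assignment, "rejected_intermediates", intermediate_fraction=frac
        )
    return CandidateInversion(soc, pca, assignment, "accepted", intermediate_fraction=frac)


def _intermediate_fraction(
    pca: PCAResult, assignment: KaryotypeAssignment, n_sd: float
) -> float:
    # robust centres and spread: medians and MAD, so that the
    # intermediates themselves cannot mask the rule by inflating the SD
    dims = 1 if assignment.k == 3 else 2
    X = pca.scores[:, :dims]
    labels = assignment.group
    groups = np.unique(labels)
    centroids = np.vstack([np.median(X[labels == g], axis=0) for g in groups])
    residuals = np.concatenate(
        [
            np.linalg.norm(X[labels == g] - centroids[i], axis=1)
            for i, g in enumerate(groups)
        ]
    )
    pooled_sd = 1.4826 * float(np.median(residuals))
    if pooled_sd == 0:
        pooled_sd = float(residuals.std())
    if pooled_sd == 0:
        return 0.0
    n_intermediate = 0
    for j in range(len(X)):
        gi = np.flatnonzero(groups == labels[j])[0]
        c = centroids[gi]
        d = np.linalg.norm(X[j] - c)
        if d <= n_sd * pooled_sd:
            continue
        # displaced toward some other centroid?
        v = X[j] - c
        for i in range(len(groups)):
            if i == gi:
                continue
            u = centroids[i] - c
            nu = np.linalg.norm(u)
            if nu > 0 and np.dot(v, u) / nu > 0:
                n_intermediate += 1
                break
    return n_intermediate / len(X)


def orient_and_label(
    assignment: KaryotypeAssignment,
    pca: PCAResult,
    transect_distances: np.ndarray,
    crab_end_window: float = 10.0,
) -> KaryotypeAssignment:
    """Identify heterokaryotype group(s) and orient arrangements.

    k=3: the middle group by mean PC1 is the heterokaryotype; among the
    two homokaryotype groups, R is the arrangement more frequent among
    individuals within ``crab_end_window`` metres of the Crab end.
    k=6: homokaryotype groups are the vertices of the PC1/PC2 triangle
    (the three centroids spanning the largest area); each heterokaryotype
    group pairs the two homokaryotypes whose midpoint its centroid is
    nearest to.  Labels use R/A1/A2 with R the most common arrangement at
    the Crab end.
    """
    labels = assignment.group
    distances = np.asarray(transect_distances, dtype=float)
    in_window = distances <= crab_end_window
    if not np.isfinite(distances).any():
        raise ValueError("no transect individuals with distances present")

    if assignment.k == 3 or len(np.unique(labels)) == 3:
        return _orient_three(assignment, pca, in_window)
    return _orient_six(assignment, pca, in_window)


def _orient_three(assignment, pca, in_window) -> KaryotypeAssignment:
    labels = assignment.group
    groups = np.unique(labels)
    means = np.array([pca.scores[labels == g, 0].mean() for g in groups])
    order = np.argsort(means)
    if not (means[order[0]] < means[order[1]] < means[order[2]]):
        raise ValueError(
            f"ambiguous middle group: PC1 group means {np.sort(means)} not distinct"
        )
    low, mid, high = groups[order]
    # arrangement counts at the Crab end: low-group arrangement vs high-group
    n_low = 2 * np.sum((labels == low) & in_window) + np.sum((labels == mid) & in_window)
    n_high = 2 * np.sum((labels == high) & in_window) + np.sum((labels == mid) & in_window)
    r_group, a_group = (low, high) if n_low >= n_high else (high, low)
    label_map = {int(r_group): "RR", int(mid): "RA", int(a_group): "AA"}
    copies = np.select(
        [labels == r_group, labels == mid, labels == a_group], [0, 1, 2]
    )
    return KaryotypeAssignment(
        soc_id=assignment.soc_id,
        k=assignment.k,
        group=labels,
        between_ss_fraction=assignment.between_ss_fraction,
        manual_override=assignment.manual_override,
        labels=label_map,
        copies=copies.astype(int),
    )


def _orient_six(assignment, pca, in_window) -> KaryotypeAssignment:
    labels = assignment.group
    groups = np.unique(labels)
    if len(groups) != 6:
        raise ValueError(f"expected 6 groups, found {len(groups)}")
    X = pca.scores[:, :2]
    centroids = np.vstack([X[labels == g].mean(axis=0) for g in groups])
    # homokaryotypes = the centroid triple spanning the largest triangle
    best_area, best_trip = -1.0, None
    for trip in itertools.combinations(range(6), 3):
        a, b, c = centroids[list(trip)]
        u, v = b - a, c - a
        area = abs(u[0] * v[1] - u[1] * v[0]) / 2.0
        if area > best_area:
            best_area, best_trip = area, trip
    hom_idx = list(best_trip)
    het_idx = [i for i in range(6) if i not in hom_idx]
    # het group -> pair of homokaryotypes by nearest midpoint
    pair_of: dict[int, tuple[int, int]] = {}
    for h in het_idx:
        best_d, best_pair = np.inf, None
        for i, j in itertools.combinations(hom_idx, 2):
            mid = (centroids[i] + centroids[j]) / 2.0
            d = np.linalg.norm(centroids[h] - mid)
            if d < best_d:
                best_d, best_pair = d, (i, j)
        pair_of[h] = best_pair
    if len({frozenset(p) for p in pair_of.values()}) != 3:
        raise ValueError("heterokaryotype groups do not pair the three vertices uniquely")
    # arrangement frequencies at the Crab end
    arr_count = {i: 0 for i in hom_idx}
    for gi, g in enumerate(groups):
        sel = (labels == g) & in_window
        n = int(sel.sum())
        if gi in hom_idx:
            arr_count[gi] += 2 * n
        else:
            a, b = pair_of[gi]
            arr_count[a] += n
            arr_count[b] += n
    ranked = sorted(hom_idx, key=lambda i: -arr_count[i])
    arr_name = {ranked[0]: "R", ranked[1]: "A1", ranked[2]: "A2"}
    label_map: dict[int, str] = {}
    for gi, g in enumerate(groups):
        if gi in hom_idx:
            a = arr_name[gi]
            label_map[int(g)] = f"{a}{a}"
        else:
            rank = {"R": 0, "A1": 1, "A2": 2}
            a, b = sorted(
                (arr_name[pair_of[gi][0]], arr_name[pair_of[gi][1]]),
                key=rank.__getitem__,
            )
            label_map[int(g)] = f"{a}{b}"
    return KaryotypeAssignment(
        soc_id=assignment.soc_id,
        k=assignment.k,
        group=labels,
        between_ss_fraction=assignment.between_ss_fraction,
        manual_override=assignment.manual_override,
        labels=label_map,
    )


def arrangement_copies(labelled: KaryotypeAssignment, arrangement: str) -> np.ndarray:
    """Copies of one arrangement per individual from group labels
    (works for both the 3- and 6-group labellings)."""
    out = np.zeros(len(labelled.group), dtype=int)
    for g, lab in labelled.labels.items():
        out[labelled.group == g] = sum(h == arrangement for h in _split_label(lab))
    return out


def _split_label(lab: str) -> list[str]:
    # labels like "RR", "RA", "AA", "RA1", "A1A2", "A2A2"
    return re.findall(r"A[12]|A|R", lab)
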