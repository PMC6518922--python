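"""LD estimation and single-outlier-cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from invfinder import ld_network as ld
from invfinder.config import AnalysisConfig
from invfinder.datatypes import MISSING
from invfinder.simulate import InversionSpec, SimConfig, simulate_transect

from conftest import make_gm


# ---------------------------------------------------------------------------
# r2 by EM
# ---------------------------------------------------------------------------

def grid_search_r2(g1, g2, step=1e-3):
    """Independent oracle: maximize the multinomial likelihood of the
    9-cell genotype table over the haplotype frequency p11 on a grid
    (locally refined so the comparison is not limited by grid spacing),
    with allele frequencies at their observed values."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    n = len(g1)
    pA, pB = g1.sum() / (2 * n), g2.sum() / (2 * n)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1

    def loglik(p11):
        p10, p01 = pA - p11, pB - p11
        p00 = 1 - pA - pB + p11
        if min(p11, p10, p01, p00) < -1e-12:
            return -np.inf
        probs = {
            (2, 2): p11**2, (2, 1): 2 * p11 * p10, (2, 0): p10**2,
            (1, 2): 2 * p11 * p01, (1, 1): 2 * p11 * p00 + 2 * p10 * p01,
            (1, 0): 2 * p10 * p00, (0, 2): p01**2, (0, 1): 2 * p01 * p00,
            (0, 0): p00**2,
        }
        return sum(
            counts[a, b] * np.log(max(probs[(a, b)], 1e-300))
            for a in range(3) for b in range(3)
        )

    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    grid = np.arange(lo, hi + step / 2, step)
    best = grid[int(np.argmax([loglik(v) for v in grid]))]
    fine = np.arange(max(lo, best - step), min(hi, best + step) + 5e-7, 1e-6)
    best = fine[int(np.argmax([loglik(v) for v in fine]))]
    D = best - pA * pB
    den = pA * (1 - pA) * pB * (1 - pB)
    return D * D / den


class TestPairwiseR2:
    def test_duplicated_snp_gives_r2_one(self, rng):
        g = rng.integers(0, 3, size=(40, 1)).astype(np.int8)
        gm = make_gm(np.hstack([g, g]))
        ldm = ld.pairwise_r2(gm, 1)
        assert ldm.r2[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_near_zero(self, rng):
        g = rng.binomial(2, 0.5, size=(10_000, 2)).astype(np.int8)
        ldm = ld.pairwise_r2(make_gm(g), 1)
        assert ldm.r2[0, 1] < 0.01

    def test_em_equals_grid_search_oracle(self, rng):
        """EM r² matches the grid-search likelihood maximizer to 1e-3 on
        random 20-individual two-SNP tables."""
        n_checked = 0
        while n_checked < 100:
            G = rng.integers(0, 3, size=(20, 2)).astype(np.int8)
            pA = G[:, 0].mean() / 2
            pB = G[:, 1].mean() / 2
            if not (0 < pA < 1 and 0 < pB < 1):
                continue
            ldm = ld.pairwise_r2(make_gm(G), 1)
            assert ldm.r2[0, 1] == pytest.approx(
                grid_search_r2(G[:, 0], G[:, 1]), abs=1e-3
            )
            n_checked += 1

    def test_few_complete_pairs_undefined(self, rng):
        G = rng.integers(0, 3, size=(12, 2)).astype(np.int8)
        G[:5, 0] = MISSING  # only 7 pairwise-complete individuals
        ldm = ld.pairwise_r2(make_gm(G), 1, min_complete_pairs=10)
        assert np.isnan(ldm.r2[0, 1])

    def test_symmetry_and_range(self, rng):
        G = rng.integers(-1, 3, size=(60, 15)).astype(np.int8)
        ldm = ld.pairwise_r2(make_gm(G), 1)
        assert np.allclose(ldm.r2, ldm.r2.T, equal_nan=True)
        finite = ldm.r2[np.isfinite(ldm.r2)]
        assert ((finite >= 0) & (finite <= 1)).all()
        assert np.allclose(np.diag(ldm.r2), 1.0)

    def test_absent_linkage_group_raises(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(20, 4)).astype(np.int8))
        with pytest.raises(ValueError):
            ld.pairwise_r2(gm, 99)


# ---------------------------------------------------------------------------
# cluster tree
# ---------------------------------------------------------------------------

def _ldm_from_matrix(R):
    S = len(R)
    return ld.LDMatrix(
        1,
        [f"s{i}" for i in range(S)],
        R,
        cm_positions=np.arange(S, dtype=float),
        contigs=np.array([f"c{i}" for i in range(S)]),
    )


class TestClusterTree:
    def test_matches_scipy_single_linkage(self, rng):
        """Merge member sets and thresholds agree with agglomerative
        single-linkage run on distance 1 - r²."""
        for _ in range(50):
            S = int(rng.integers(4, 16))
            A = rng.random((S, S))
            R = (A + A.T) / 2
            np.fill_diagonal(R, 1.0)
            tree = ld.build_cluster_tree(_ldm_from_matrix(R), threshold_step=1e-9)
            Z = hierarchy.linkage(squareform(1.0 - R, checks=False), method="single")
            clusters = {i: frozenset([i]) for i in range(S)}
            oracle = []
            for k, (a, b, d, _) in enumerate(Z):
                m = clusters[int(a)] | clusters[int(b)]
                clusters[S + k] = m
                oracle.append((1.0 - d, m))
            ours = [
                (m.threshold, frozenset(int(i) for i in m.members)) for m in tree.merges
            ]
            key = lambda t: (-round(t[0], 8), sorted(t[1]))
            for (t1, m1), (t2, m2) in zip(sorted(ours, key=key), sorted(oracle, key=key)):
                assert m1 == m2
                assert t1 == pytest.approx(t2, abs=1e-8)

    def test_block_diagonal_merges_only_at_zero(self):
        R = np.zeros((10, 10))
        R[:5, :5] = 1.0
        R[5:, 5:] = 1.0
        np.fill_diagonal(R, 1.0)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        final = tree.merges[-1]
        assert final.threshold == 0.0
        assert {len(m) for m in final.child_members} == {5}
        # all earlier merges happen at threshold 1
        assert all(m.threshold == pytest.approx(1.0) for m in tree.merges[:-1])

    def test_single_snp_degenerate_tree(self):
        ldm = ld.LDMatrix(1, ["s0"], np.ones((1, 1)))
        tree = ld.build_cluster_tree(ldm)
        assert tree.merges == []

    def test_thresholds_non_increasing_and_members_nested(self, rng):
        A = rng.random((20, 20))
        R = (A + A.T) / 2
        np.fill_diagonal(R, 1.0)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        thresholds = [m.threshold for m in tree.merges]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))
        for m in tree.merges:
            assert set(m.child_members[0]) | set(m.child_members[1]) == set(m.members)
            assert not set(m.child_members[0]) & set(m.child_members[1])


# ---------------------------------------------------------------------------
# SOC extraction, phi sweep, intervals
# ---------------------------------------------------------------------------

def _clique_matrix(rng, n_clique=40, n_bg=500, r_in=0.95, r_bg=0.02, r_cross=None):
    """Near-clique on a weak background; ``r_cross`` below ``r_bg`` keeps
    the background self-cohesive so the clique dissolves in one merge."""
    S = n_clique + n_bg
    R = np.full((S, S), r_bg) + rng.uniform(0, 0.01, (S, S))
    R = (R + R.T) / 2
    if r_cross is not None:
        R[:n_clique, n_clique:] = r_cross
        R[n_clique:, :n_clique] = r_cross
    R[:n_clique, :n_clique] = r_in
    np.fill_diagonal(R, 1.0)
    return R


class TestExtractSocs:
    def test_planted_clique_found_at_phi_zero(self, rng):
        """A 40-SNP near-clique on a 500-SNP low-LD background yields
        exactly one SOC containing (at least) 38 of the planted SNPs."""
        R = _clique_matrix(rng)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        socs = ld.extract_socs(tree, phi=0)
        assert len(socs) == 1
        planted = {f"s{i}" for i in range(40)}
        assert len(set(socs[0].snp_ids) & planted) >= 38

    def test_min_snps_filter(self, rng):
        """A qualifying cluster of 31 SNPs is rejected; 32 passes."""
        R31 = _clique_matrix(rng, n_clique=31, n_bg=100, r_bg=0.05, r_cross=0.01)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R31))
        assert ld.extract_socs(tree, phi=0, min_snps=32) == []
        R32 = _clique_matrix(rng, n_clique=32, n_bg=100, r_bg=0.05, r_cross=0.01)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R32))
        socs = ld.extract_socs(tree, phi=0, min_snps=32)
        assert len(socs) == 1
        assert socs[0].n_snps == 32

    def test_low_median_r2_rejected(self, rng):
        """A cluster with median r² = 0.29 fails the 0.3 threshold."""
        R = _clique_matrix(rng, r_in=0.29)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        assert ld.extract_socs(tree, phi=0, min_median_r2=0.3) == []
        socs = ld.extract_socs(tree, phi=0, min_median_r2=0.28)
        assert len(socs) == 1

    def test_negative_phi_raises(self, rng):
        R = _clique_matrix(rng, n_bg=50)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        with pytest.raises(ValueError):
            ld.extract_socs(tree, phi=-1)


class TestPhiSweep:
    def test_idempotent_when_stable_across_phi(self, rng):
        R = _clique_matrix(rng, n_bg=200)
        tree = ld.build_cluster_tree(_ldm_from_matrix(R))
        socs = ld.phi_sweep_select(tree)
        assert len(socs) == 1

    def test_nested_clusters_keep_tighter_core(self, rng):
        """A tight 40-SNP core inside a loose 80-SNP shell: the smaller,
        higher-median-LD cluster is retained."""
        S = 80 + 300
        R = np.full((S, S), 0.01)
        R[np.ix_(range(80, S), range(80, S))] = 0.04  # cohesive background
        R[:80, :80] = 0.45
        R[:40, :40] = 0.95
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        socs = ld.phi_sweep_select(ld.build_cluster_tree(_ldm_from_matrix(R)))
        assert len(socs) == 1
        core = {f"s{i}" for i in range(40)}
        assert socs[0].n_snps < 80
        assert len(set(socs[0].snp_ids) & core) >= 38
        assert socs[0].median_r2 > 0.9

    def test_disjoint_overlapping_clusters_fused_at_higher_phi(self):
        """Two SNP-disjoint clusters that fuse into one larger cluster at
        higher φ are replaced by the merged cluster."""
        # construct SOCs directly to exercise the overlap-resolution rule
        a = ld.SOC("", 1, [f"s{i}" for i in range(40)], 40, 40, 0.9, 0)
        b = ld.SOC("", 1, [f"s{i}" for i in range(40, 80)], 40, 40, 0.85, 0)
        merged = ld.SOC("", 1, [f"s{i}" for i in range(80)], 80, 80, 0.6, 2)
        kept = ld._resolve_overlap([a, b, merged])
        assert kept is merged

    def test_smaller_cluster_wins_overlap(self):
        small = ld.SOC("", 1, [f"s{i}" for i in range(40)], 40, 40, 0.9, 1)
        big = ld.SOC("", 1, [f"s{i}" for i in range(60)], 60, 60, 0.5, 0)
        assert ld._resolve_overlap([small, big]) is small


class TestSocInterval:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([0.34, 5.0, 14.21], (0.34, 14.21, 13.87)),
            ([1.03, 1.2, 1.51], (1.03, 1.51, 0.48)),
            ([2.0, 2.0, 2.0], (2.0, 2.0, 0.0)),
        ],
    )
    def test_interval_from_extreme_positions(self, positions, expected):
        soc = ld.SOC("x", 1, [f"s{i}" for i in range(len(positions))],
                     len(positions), 1, 0.9, 0)
        snp_map = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(positions))],
             "cm_position": positions}
        )
        start, end, size = ld.soc_interval(soc, snp_map)
        assert (start, end) == (expected[0], expected[1])
        assert size == pytest.approx(expected[2])

    def test_unmapped_member_raises(self):
        soc = ld.SOC("x", 1, ["s0", "missing"], 2, 1, 0.9, 0)
        snp_map = pd.DataFrame({"snp_id": ["s0"], "cm_position": [1.0]})
        with pytest.raises(KeyError):
            ld.soc_interval(soc, snp_map)


class TestFalsePositiveControl:
    def test_no_socs_on_collinear_simulation(self):
        """Fully collinear data (no planted inversion, no clinal
        structure) yields no SOC on 10 linkage groups."""
        cfg = SimConfig(
            n_individuals=200, n_linkage_groups=10, markers_per_lg=40,
            inversions=[], background_clinal_fraction=0.0,
        )
        sim = simulate_transect(cfg, seed=99)
        socs = ld.detect_socs(sim.gm, AnalysisConfig())
        assert socs == []

    def test_planted_inversion_detected(self):
        cfg = SimConfig(
            n_individuals=300, n_linkage_groups=2, markers_per_lg=118,
            inversions=[InversionSpec("inv1", 1, 5.0, 38.0, divergence=0.6)],
        )
        sim = simulate_transect(cfg, seed=3)
        socs = ld.detect_socs(sim.gm, AnalysisConfig())
        assert len(socs) == 1
        assert socs[0].linkage_group == 1
        assert socs[0].n_snps >= 32
        assert socs[0].median_r2 >= 0.3
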