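"""PCA-based karyotype grouping, candidate filtering and orientation."""

import numpy as np
import pytest

from invfinder import karyotype as kt
from invfinder.simulate import InversionSpec, SimConfig, simulate_transect

from conftest import make_gm


def _ideal_inversion_gm(rng, n_per_group=40, n_snps=20):
    """Two fixed haplotype classes + heterozygotes: genotypes 0/1/2."""
    blocks = [
        np.zeros((n_per_group, n_snps)),
        np.ones((n_per_group, n_snps)),
        2 * np.ones((n_per_group, n_snps)),
    ]
    calls = np.vstack(blocks).astype(np.int8)
    # a little noise so columns are not perfectly collinear
    flip = rng.random(calls.shape) < 0.02
    calls[flip] = rng.integers(0, 3, size=int(flip.sum()))
    dist = np.concatenate(
        [rng.uniform(0, 30, n_per_group), rng.uniform(60, 90, n_per_group),
         rng.uniform(120, 152, n_per_group)]
    )
    return make_gm(calls, distances=dist)


class TestRegionPca:
    def test_heterokaryotypes_at_pc1_midpoint(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        n = 40
        m0 = pca.scores[:n, 0].mean()
        m1 = pca.scores[n:2 * n, 0].mean()
        m2 = pca.scores[2 * n:, 0].mean()
        span = abs(m2 - m0)
        assert abs(m1 - (m0 + m2) / 2) <= 0.05 * span

    def test_matches_eigendecomposition_oracle(self, rng):
        """Scores and variance fractions equal a direct eigendecomposition
        of the covariance matrix (up to sign)."""
        calls = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        gm = make_gm(calls)
        pca = kt.region_pca(gm, 1, 0.0, 100.0, n_components=3)
        X = calls.astype(float)
        X -= X.mean(axis=0)
        cov = X.T @ X / 1.0  # total scatter; eigvals proportional
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        assert pca.variance_fraction[:3] == pytest.approx(
            (w / w.sum())[:3], abs=1e-10
        )
        for k in range(3):
            s_oracle = X @ v[:, k]
            dot = abs(np.dot(s_oracle, pca.scores[:, k]))
            assert dot == pytest.approx(
                np.linalg.norm(s_oracle) * np.linalg.norm(pca.scores[:, k]), rel=1e-9
            )

    def test_zero_variance_region_raises(self):
        calls = np.ones((20, 5), dtype=np.int8)
        gm = make_gm(calls)
        with pytest.raises(ValueError):
            kt.region_pca(gm, 1, 0.0, 100.0)

    def test_variance_fractions_sorted(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(40, 15)).astype(np.int8))
        pca = kt.region_pca(gm, 1, 0.0, 100.0, n_components=5)
        vf = pca.variance_fraction
        assert all(a >= b for a, b in zip(vf, vf[1:]))
        assert vf.sum() <= 1 + 1e-12


class TestAssignGroups:
    def test_well_separated_clusters_are_stable(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        ref = kt.assign_groups(pca, k=3, seed=0)
        for seed in (1, 2, 3):
            a = kt.assign_groups(pca, k=3, seed=seed)
            # same partition up to label permutation
            for g in np.unique(ref.group):
                members = ref.group == g
                assert len(np.unique(a.group[members])) == 1
        assert ref.between_ss_fraction > 0.95

    def test_best_of_restarts_dominates_single_runs(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        best = kt.assign_groups(pca, k=3, restarts=10, seed=0)
        singles = [
            kt.assign_groups(pca, k=3, restarts=1, seed=s).between_ss_fraction
            for s in range(5)
        ]
        assert best.between_ss_fraction >= max(singles) - 1e-12

    def test_manual_override_boundaries(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        scores = np.sort(pca.scores[:, 0])
        cuts = [scores[40] + 1e-6, scores[80] + 1e-6]
        a = kt.assign_groups(pca, k=3, manual_boundaries=cuts)
        assert a.manual_override
        assert len(np.unique(a.group)) == 3

    def test_too_few_distinct_points_raises(self):
        pca = kt.PCAResult(
            scores=np.zeros((10, 2)), variance_fraction=np.array([1.0]),
            loadings=np.zeros((5, 2)),
        )
        with pytest.raises(ValueError):
            kt.assign_groups(pca, k=3)


class TestCandidateFilter:
    def test_low_pc1_variance_rejected(self, rng):
        """A region where PC1 explains 6.6% of variance is rejected."""
        pca = kt.PCAResult(
            scores=rng.normal(size=(50, 2)),
            variance_fraction=np.array([0.066, 0.05]),
            loadings=np.zeros((5, 2)),
        )
        a = kt.KaryotypeAssignment("x", 3, rng.integers(0, 3, 50), 0.9)
        cand = kt.candidate_filter(None, pca, a)
        assert cand.status == "rejected_pc1"

    def test_ideal_three_clusters_accepted(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        a = kt.assign_groups(pca, k=3, seed=0)
        cand = kt.candidate_filter(None, pca, a)
        assert cand.status == "accepted"
        assert cand.intermediate_fraction <= 0.05

    def test_many_recombinant_intermediates_rejected(self, rng):
        """10% of individuals with intermediate scores between the
        homokaryotype and heterokaryotype clusters fail the default
        threshold (a constructed recombinant-rich region)."""
        scores = np.concatenate([
            rng.normal(-10, 0.05, 40), rng.normal(0, 0.05, 40),
            rng.normal(10, 0.05, 40), np.full(12, -5.0),
        ])
        group = np.concatenate([
            np.zeros(40, int), np.ones(40, int), np.full(40, 2, int),
            np.zeros(12, int),  # recombinants carried by the nearest cluster
        ])
        pca = kt.PCAResult(
            scores=scores[:, None], variance_fraction=np.array([0.5]),
            loadings=np.zeros((5, 1)),
        )
        a = kt.KaryotypeAssignment("x", 3, group, 0.9)
        cand = kt.candidate_filter(None, pca, a)
        assert cand.status == "rejected_intermediates"
        assert cand.intermediate_fraction >= 12 / 132 - 1e-9


class TestOrientAndLabel:
    def test_middle_group_is_heterokaryotype(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        a = kt.assign_groups(pca, k=3, seed=0)
        lab = kt.orient_and_label(
            a, pca, gm.individuals["transect_distance"].to_numpy()
        )
        mids = {g: pca.scores[lab.group == g, 0].mean() for g in np.unique(lab.group)}
        het_group = [g for g, l in lab.labels.items() if l == "RA"][0]
        assert sorted(mids, key=mids.get)[1] == het_group

    def test_crab_end_majority_is_reference(self, rng):
        gm = _ideal_inversion_gm(rng)
        pca = kt.region_pca(gm, 1, 0.0, 100.0)
        a = kt.assign_groups(pca, k=3, seed=0)
        lab = kt.orient_and_label(
            a, pca, gm.individuals["transect_distance"].to_numpy(),
            crab_end_window=10.0,
        )
        # individuals at distance <= 10 are genotype-0 rows by construction
        in_window = gm.individuals["transect_distance"].to_numpy() <= 10.0
        rr_group = [g for g, l in lab.labels.items() if l == "RR"][0]
        counts = np.bincount(lab.group[in_window], minlength=3)
        assert np.argmax(counts) == rr_group
        assert (lab.copies[lab.group == rr_group] == 0).all()

    def test_three_arrangement_six_groups_match_truth(self):
        cfg = SimConfig(
            n_individuals=400, n_linkage_groups=1, markers_per_lg=150,
            lg_span_cm=80.0,
            inversions=[InversionSpec(
                "inv1", 1, 10.0, 50.0, divergence=0.7, n_arrangements=3,
                centre=92, width=10, p_crab=0.05, p_wave=0.5,
                centre2=90, width2=15, p_crab2=0.05, p_wave2=0.45,
            )],
        )
        sim = simulate_transect(cfg, seed=5)
        pca = kt.region_pca(sim.gm, 1, 10.0, 50.0)
        a = kt.assign_groups(pca, k=6, seed=0)
        lab = kt.orient_and_label(
            a, pca, sim.gm.individuals["transect_distance"].to_numpy()
        )
        tk = sim.truth.karyotypes.set_index("individual_id")
        rank = {"R": 0, "A1": 1, "A2": 2}
        true_lab = np.array([
            "".join(sorted(
                [tk.loc[i, "arrangement_a"], tk.loc[i, "arrangement_b"]],
                key=rank.__getitem__,
            ))
            for i in sim.gm.individual_ids
        ])
        pred = np.array([lab.labels[int(g)] for g in lab.group])
        # the A1/A2 naming is arbitrary: score both assignments
        swap = {"RR": "RR", "RA1": "RA2", "RA2": "RA1", "A1A1": "A2A2",
                "A2A2": "A1A1", "A1A2": "A1A2"}
        acc = max(
            (pred == true_lab).mean(),
            (np.vectorize(swap.get)(pred) == true_lab).mean(),
        )
        assert acc >= 0.99

    def test_hardy_weinberg_group_proportions(self):
        """Karyotype group counts match Binomial(2, p) within exact
        binomial bounds at a position of known arrangement frequency."""
        from scipy.stats import binom
        cfg = SimConfig(
            n_individuals=600, n_linkage_groups=1, markers_per_lg=60,
            inversions=[InversionSpec("inv1", 1, 5.0, 45.0, divergence=0.6,
                                      p_crab=0.4, p_wave=0.4, width=30.0)],
        )
        sim = simulate_transect(cfg, seed=11)
        copies = sim.truth.karyotype_codes("inv1").to_numpy()
        n = len(copies)
        n_carrier_alleles = copies.sum()
        lo, hi = binom.ppf([0.025, 0.975], 2 * n, 0.4)
        assert lo <= n_carrier_alleles <= hi
        # heterozygote count consistent with HW at the realized frequency
        p_hat = n_carrier_alleles / (2 * n)
        lo, hi = binom.ppf([0.025, 0.975], n, 2 * p_hat * (1 - p_hat))
        assert lo <= (copies == 1).sum() <= hi
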