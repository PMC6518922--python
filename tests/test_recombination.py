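"""Informative markers, crossover calling, orientation parsimony and
recombination suppression."""

import numpy as np
import pandas as pd
import pytest

from invfinder import recombination as rc
from invfinder.datatypes import MISSING, GenotypeMatrix
from invfinder.simulate import (
    FamilySpec,
    InversionSpec,
    SimConfig,
    simulate_families,
    simulate_transect,
)

from conftest import make_gm


def family_gm(offspring_calls, mother, father, contigs=None, cm=None):
    """GenotypeMatrix with mother, father and offspring rows."""
    calls = np.vstack([mother, father, offspring_calls]).astype(np.int8)
    n_off = len(offspring_calls)
    gm = make_gm(calls, contigs=contigs, cm=cm, source="family_offspring")
    ids = ["mom", "dad"] + [f"o{k}" for k in range(n_off)]
    gm.individuals["individual_id"] = ids
    gm.individuals.loc[:1, "source"] = "family_parent"
    return gm


def fam_dict(gm):
    return {
        "family_id": "fam",
        "mother_id": "mom",
        "father_id": "dad",
        "offspring_ids": [i for i in gm.individual_ids if i.startswith("o")],
    }


class TestInformativeSites:
    def test_double_het_excluded(self):
        mother = np.array([1, 1, 0])
        father = np.array([1, 0, 1])
        off = np.tile([1, 0, 1], (6, 1))
        gm = family_gm(off, mother, father)
        inf = rc.informative_sites_qc(gm, fam_dict(gm))
        assert 0 not in inf["mom"] and 0 not in inf["dad"]
        assert 1 in inf["mom"]
        assert 2 in inf["dad"]

    def test_mendelian_impossible_site_removed(self):
        mother = np.array([1, 1])
        father = np.array([0, 0])
        off = np.tile([1, 1], (6, 1))
        off[0, 0] = 2  # impossible: hom-alt with a hom-ref father
        gm = family_gm(off, mother, father)
        inf = rc.informative_sites_qc(gm, fam_dict(gm))
        assert 0 not in inf["mom"]
        assert 1 in inf["mom"]

    def test_segregation_distortion_removed(self):
        """A 20:1 transmission ratio at n=21 offspring fails the exact
        binomial 1:1 test at p < 1e-3."""
        mother = np.array([1, 1])
        father = np.array([0, 0])
        off = np.ones((21, 2), dtype=int)
        off[0, 0] = 0  # site 0: 20 alt vs 1 ref transmissions
        off[:10, 1] = 0  # site 1: balanced
        gm = family_gm(off, mother, father)
        inf = rc.informative_sites_qc(gm, fam_dict(gm))
        assert 0 not in inf["mom"]
        assert 1 in inf["mom"]

    def test_family_without_offspring_raises(self):
        gm = family_gm(np.zeros((1, 2)), np.array([1, 1]), np.array([0, 0]))
        fam = fam_dict(gm)
        fam["offspring_ids"] = []
        with pytest.raises(ValueError):
            rc.informative_sites_qc(gm, fam)


def _phased_family(n_markers=20, n_off=8, switch_at=None, contigs=None):
    """Mother het everywhere, father hom-ref; offspring transmitted
    haplotypes are explicit, with optional switch positions per
    offspring (crossovers between marker i-1 and i)."""
    mother = np.ones(n_markers, dtype=int)
    father = np.zeros(n_markers, dtype=int)
    off = np.zeros((n_off, n_markers), dtype=int)
    switch_at = switch_at or {}
    for j in range(n_off):
        hap = np.zeros(n_markers, dtype=int)  # 0 -> transmits hap1 allele (= 1)
        for pos in switch_at.get(j, []):
            hap[pos:] = 1 - hap[pos:]
        # hap state 0 transmits allele 1, state 1 transmits allele 0
        off[j] = np.where(hap == 0, 1, 0)
    contigs = contigs or [f"c{i}" for i in range(n_markers)]
    return family_gm(off, mother, father, contigs=contigs), np.arange(n_markers)


class TestCallCrossovers:
    def test_no_switch_no_events(self):
        gm, cols = _phased_family()
        ev, counts = rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        assert ev == []
        assert (counts == 0).all()

    def test_known_crossovers_recovered_exactly(self):
        switches = {0: [5], 1: [3, 12], 2: [17]}
        gm, cols = _phased_family(switch_at=switches)
        ev, counts = rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        assert counts[0] == 1 and counts[1] == 2 and counts[2] == 1
        assert (counts[3:] == 0).all()
        by_off = {}
        for e in ev:
            by_off.setdefault(e.offspring_id, []).append((e.left_cm, e.right_cm))
        # the event interval brackets the true position (between markers)
        assert by_off["o0"] == [(4.0, 5.0)]
        assert by_off["o1"] == [(2.0, 3.0), (11.0, 12.0)]

    def test_single_snp_island_filtered(self):
        """An island of opposite phase supported by one SNP is removed:
        zero events."""
        switches = {0: [8, 9]}  # single-marker island at index 8
        gm, cols = _phased_family(switch_at=switches)
        ev, counts = rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        assert counts[0] == 0

    def test_single_contig_island_filtered(self):
        """Consecutive opposite-phase SNPs all in one contig are removed."""
        contigs = [f"c{i}" for i in range(20)]
        contigs[8] = contigs[9] = contigs[10] = "cX"
        switches = {0: [8, 11]}  # 3-marker island within contig cX
        gm, cols = _phased_family(switch_at=switches, contigs=contigs)
        ev, counts = rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        assert counts[0] == 0

    def test_too_few_informative_markers_raises(self):
        gm, cols = _phased_family(n_markers=2)
        with pytest.raises(ValueError):
            rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"],
                               np.array([0]), 1)

    def test_count_invariant_to_haplotype_relabelling(self):
        """Flipping which parental haplotype is 'hap 1' leaves total
        event counts unchanged (phase is chosen to minimize switches)."""
        switches = {0: [5], 2: [4, 9]}
        gm, cols = _phased_family(switch_at=switches)
        _, counts = rc.call_crossovers(gm, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        flipped = gm.calls.copy()
        m = flipped[0] == 1  # mother stays het; swap offspring transmitted allele
        off_rows = slice(2, None)
        flipped[off_rows] = np.where(
            flipped[off_rows] == 1, 1, 2 - flipped[off_rows]
        )  # 0 <-> 2 among offspring = relabelled transmission
        gm2 = GenotypeMatrix(flipped, gm.loci.copy(), gm.individuals.copy())
        _, counts2 = rc.call_crossovers(gm2, "fam", "mom", fam_dict(gm)["offspring_ids"], cols, 1)
        assert (counts == counts2).all()


class TestReversedOrder:
    def test_double_reversal_is_identity(self):
        gm, cols = _phased_family()
        rev = rc.reversed_block_order(gm, cols, 1, 5.0, 12.0)
        # applying the same reflection to the reversed order restores it
        ref = np.lexsort((gm.loci["contig_pos"].to_numpy()[cols],
                          gm.loci["contig"].to_numpy()[cols].astype(str),
                          gm.loci["cm_position"].to_numpy()[cols]))
        twice = rev.copy()
        cm = gm.loci["cm_position"].to_numpy()[cols]
        inside = (cm[ref] >= 5.0) & (cm[ref] <= 12.0)
        twice[inside] = rev[inside][::-1]
        assert (twice == ref).all()

    def test_extra_switches_collapse_under_reversal(self):
        """A single crossover inside an inverted block appears, in the
        reference order, as opposite phases anchored to opposite flanks
        (three switches); reversing the block collapses it to one, so
        the call is A.  Offspring without crossovers keep the phasing
        anchored and stay uninformative."""
        switches = {j: [5, 10, 15] for j in range(4)}  # o0..o3 recombinant
        gm, cols = _phased_family(switch_at=switches)

        class Soc:
            soc_id = "LGC1.1"
            linkage_group = 1
            start_cm = 5.0
            end_cm = 14.0

        oc = rc.orientation_classify(gm, "fam", "mom",
                                     fam_dict(gm)["offspring_ids"], cols, Soc)
        rec = oc.iloc[:4]
        assert (rec["crossovers_under_A"] < rec["crossovers_under_R"]).all()
        assert (rec["call"] == "A").all()
        assert (oc.iloc[4:]["call"] == "uninformative").all()

    def test_no_switches_uninformative(self):
        gm, cols = _phased_family()

        class Soc:
            soc_id = "LGC1.1"
            linkage_group = 1
            start_cm = 5.0
            end_cm = 14.0

        oc = rc.orientation_classify(gm, "fam", "mom",
                                     fam_dict(gm)["offspring_ids"], cols, Soc)
        assert (oc["call"] == "uninformative").all()


class TestSuppression:
    def test_heterokaryotype_parent_zero_inside_events(self):
        cfg = SimConfig(
            n_individuals=60, n_linkage_groups=1, markers_per_lg=120,
            lg_span_cm=80.0, missing_rate=0.0, error_rate=0.0,
            inversions=[InversionSpec("inv1", 1, 10.0, 50.0,
                                      divergence=0.4, diversity_ratio=0.8)],
        )
        sim = simulate_transect(cfg, seed=21)
        spec = FamilySpec("fam", 40, mother_karyotypes={"inv1": ("R", "A")},
                          father_karyotypes={"inv1": ("R", "R")})
        gm, ped, truth = simulate_families(sim, [spec], seed=22,
                                           double_crossover_rate=0.0,
                                           gene_conversion_rate=0.0)
        fam = ped.family("fam")
        inf = rc.informative_sites_qc(gm, fam)
        ev, _ = rc.call_crossovers(gm, "fam", fam["mother_id"],
                                   fam["offspring_ids"], inf[fam["mother_id"]], 1)
        inside = [e for e in ev if e.left_cm >= 10.0 and e.right_cm <= 50.0]
        assert inside == []

    def test_summary_counts_cases_and_events(self):
        events = [
            rc.CrossoverEvent("f", "p1", "o1", 1, 12.0, 14.0, "a", "b", "ca", "cb"),
            rc.CrossoverEvent("f", "p1", "o1", 1, 55.0, 58.0, "c", "d", "cc", "cd"),
        ]
        pk = pd.DataFrame({"LGC1.1": {"p1": "AA"}})

        class Soc:
            soc_id = "LGC1.1"
            linkage_group = 1
            start_cm = 10.0
            end_cm = 50.0

        cases = pd.DataFrame(
            {"parent_id": ["p1", "p1"], "offspring_id": ["o1", "o2"],
             "soc_id": ["LGC1.1", "LGC1.1"]}
        )
        summary = rc.suppression_summary(events, pk, [Soc], cases)
        row = summary.set_index(["parent_karyotype", "region_class"])
        assert row.loc[("AA", "inside_soc"), "n_cases"] == 2
        assert row.loc[("AA", "inside_soc"), "n_events"] == 1
        assert row.loc[("AA", "collinear"), "n_events"] == 1

    def test_poisson_crossover_rate_homokaryotypes(self):
        """Called event counts for homokaryotype parents stay within
        exact Poisson bounds of the map-length expectation (calling is
        conservative, so only the upper bound is sharp)."""
        from scipy.stats import poisson
        cfg = SimConfig(
            n_individuals=60, n_linkage_groups=1, markers_per_lg=200,
            lg_span_cm=100.0, missing_rate=0.0, error_rate=0.0, inversions=[],
        )
        sim = simulate_transect(cfg, seed=31)
        spec = FamilySpec("fam", 100)
        gm, ped, truth = simulate_families(sim, [spec], seed=32)
        n_true = len(truth.crossovers)
        # 200 meioses x 1 Morgan
        lo, hi = poisson.ppf([0.025, 0.975], 200 * 1.0)
        assert lo <= n_true <= hi
        fam = ped.family("fam")
        inf = rc.informative_sites_qc(gm, fam)
        n_called = 0
        for pid, cols in inf.items():
            ev, _ = rc.call_crossovers(gm, "fam", pid, fam["offspring_ids"], cols, 1)
            n_called += len(ev)
        assert n_called <= hi
        assert n_called >= 0.3 * n_true  # sparse informative markers miss some
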