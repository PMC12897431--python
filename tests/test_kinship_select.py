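"""IBS kinship, family clustering and mating plans."""

import numpy as np
import pytest

from breedkit.genodata import MISSING
from breedkit.kinship_select import (
    NoCrossFamilyPairError,
    cluster_families,
    exclude_high_froh,
    ibs_matrix,
    propose_matings,
)
from breedkit.popstats import site_ho
from breedkit.simpop import (
    SimConfig,
    mendelian_offspring,
    simulate_families,
    simulate_frequencies,
)
from conftest import make_matrix
from oracles import ibs_pair_oracle


@pytest.fixture(scope="module")
def family_cohort():
    cfg = SimConfig(
        seed=23, n_breeds=2, fst=0.15, n_markers=800, n_chromosomes=2,
        chrom_length_bp=10_000_000, samples_per_breed=5,
    )
    panel, markers, _ = simulate_frequencies(cfg)
    g, s, truth = simulate_families(panel, cfg, markers, n_families=7, sibs_per_family=4)
    return g, s, truth


class TestIbs:
    def test_identical_and_opposite(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        ibs = ibs_matrix(g)
        assert ibs.similarity[0, 1] == pytest.approx(1.0)
        # s0 vs s2: |0-2|=2, |1-1|=0, |2-0|=2 -> mean (0+2+0)/2/3
        assert ibs.similarity[0, 2] == pytest.approx(1 / 3)
        g2 = make_matrix([[0, 0], [2, 2]])
        assert ibs_matrix(g2).similarity[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force_with_missing(self, rng):
        dosage = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        dosage[rng.random((10, 50)) < 0.1] = MISSING
        g = make_matrix(dosage)
        ibs = ibs_matrix(g)
        for i in range(10):
            for j in range(10):
                assert ibs.similarity[i, j] == pytest.approx(
                    ibs_pair_oracle(dosage[i], dosage[j]), abs=1e-12
                )

    def test_marker_permutation_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        g = make_matrix(dosage)
        perm = rng.permutation(40)
        g2 = make_matrix(dosage[:, perm])
        np.testing.assert_allclose(
            ibs_matrix(g).similarity, ibs_matrix(g2).similarity, atol=1e-12
        )

    def test_decreasing_in_hamming_distance(self):
        base = np.zeros(60, dtype=np.int8)
        rows = [base.copy() for _ in range(4)]
        rows[1][:5] = 2
        rows[2][:20] = 2
        rows[3][:40] = 2
        ibs = ibs_matrix(make_matrix(np.vstack(rows)))
        sims = [ibs.similarity[0, k] for k in (1, 2, 3)]
        assert sims[0] > sims[1] > sims[2]


class TestClustering:
    def test_sib_group_recovery_two_families(self):
        cfg = SimConfig(
            seed=29, n_breeds=1, fst=0.2, n_markers=600, n_chromosomes=2,
            chrom_length_bp=10_000_000, samples_per_breed=2,
        )
        panel, markers, _ = simulate_frequencies(cfg)
        g, s, truth = simulate_families(panel, cfg, markers, n_families=2, sibs_per_family=6)
        fam = cluster_families(ibs_matrix(g), 2)
        # perfect recovery up to label permutation
        truth_ids = truth.set_index("sample_id")["family_id"]
        found = fam.to_frame().set_index("sample_id")["family_id"]
        mapping = {}
        ok = True
        for sid in truth_ids.index:
            t, f = truth_ids[sid], found[sid]
            mapping.setdefault(t, f)
            ok &= mapping[t] == f
        assert ok and fam.n_families == 2

    def test_singletons_and_single_family(self, family_cohort):
        g, _, _ = family_cohort
        ibs = ibs_matrix(g)
        singles = cluster_families(ibs, len(g.samples))
        assert singles.n_families == len(g.samples)
        one = cluster_families(ibs, 1)
        assert one.n_families == 1

    def test_seven_family_recovery(self, family_cohort):
        g, _, truth = family_cohort
        fam = cluster_families(ibs_matrix(g), 7)
        truth_ids = truth.set_index("sample_id")["family_id"]
        found = fam.to_frame().set_index("sample_id")["family_id"]
        # members of a true family always share a cluster
        for t in range(1, 8):
            members = truth_ids[truth_ids == t].index
            assert found[members].nunique() == 1


class TestExclusion:
    def test_strict_threshold(self):
        ids = np.array(["a", "b", "c"], dtype=object)
        froh = {"a": 0.31, "b": 0.30, "c": 0.05}
        kept = exclude_high_froh(ids, froh)
        assert list(kept) == ["b", "c"]

    def test_matches_filter_recount(self, rng):
        ids = np.array([f"s{i}" for i in range(50)], dtype=object)
        froh = {f"s{i}": float(rng.random() * 0.6) for i in range(50)}
        kept = set(exclude_high_froh(ids, froh, 0.3))
        assert kept == {k for k, v in froh.items() if v <= 0.3}


class TestMatings:
    def test_two_families_two_pairs(self):
        from breedkit.kinship_select import FamilyAssignment

        fam = FamilyAssignment(
            sample_ids=np.array(["s1", "d1", "s2", "d2"], dtype=object),
            family_id=np.array([1, 1, 2, 2]),
            n_families=2,
        )
        sexes = {"s1": "M", "d1": "F", "s2": "M", "d2": "F"}
        plan = propose_matings(fam, sexes, dams_per_sire=1)
        assert len(plan) == 2
        assert (plan.pairs["sire_family"] != plan.pairs["dam_family"]).all()

    def test_single_family_blocked(self):
        from breedkit.kinship_select import FamilyAssignment

        fam = FamilyAssignment(
            sample_ids=np.array(["a", "b"], dtype=object),
            family_id=np.array([1, 1]),
            n_families=1,
        )
        with pytest.raises(NoCrossFamilyPairError):
            propose_matings(fam, {"a": "M", "b": "F"})

    def test_seven_family_plan_covers_sire_families_with_low_kinship(self, family_cohort):
        g, s, truth = family_cohort
        ibs = ibs_matrix(g)
        fam = cluster_families(ibs, 7)
        sexes = dict(zip(map(str, s.sample_id), s.sex))
        # founders are labelled M/F per family; sibs randomized
        plan = propose_matings(fam, sexes, ibs=ibs, dams_per_sire=2)
        fam_of = fam.family_of()
        sire_fams_with_eligible = {
            fam_of[x] for x in map(str, s.sample_id) if sexes.get(x) == "M"
        }
        assert set(plan.pairs["sire_family"]) == sire_fams_with_eligible
        assert (plan.pairs["sire_family"] != plan.pairs["dam_family"]).all()
        n = len(g.samples)
        pop_mean_ibs = ibs.similarity[np.triu_indices(n, 1)].mean()
        assert plan.pairs["pair_ibs"].mean() < pop_mean_ibs

    def test_froh_excluded_animals_absent(self, family_cohort):
        g, s, _ = family_cohort
        ibs = ibs_matrix(g)
        fam = cluster_families(ibs, 7)
        sexes = dict(zip(map(str, s.sample_id), s.sex))
        froh = {str(x): 0.0 for x in s.sample_id}
        victim = str(s.sample_id[0])
        froh[victim] = 0.5
        plan = propose_matings(fam, sexes, froh, ibs)
        assert victim not in set(plan.pairs["sire_id"]) | set(plan.pairs["dam_id"])


class TestOffspringDiversity:
    def test_planned_matings_raise_offspring_heterozygosity(self):
        """Cross-family matings beat random within-family matings on mean
        offspring Ho (single-generation Mendelian simulation)."""
        cfg = SimConfig(
            seed=31, n_breeds=1, fst=0.25, n_markers=500, n_chromosomes=2,
            chrom_length_bp=10_000_000, samples_per_breed=2,
        )
        panel, markers, _ = simulate_frequencies(cfg)
        g, s, truth = simulate_families(panel, cfg, markers, n_families=6, sibs_per_family=2)
        ibs = ibs_matrix(g)
        fam = cluster_families(ibs, 6)
        sexes = dict(zip(map(str, s.sample_id), s.sex))
        plan = propose_matings(fam, sexes, ibs=ibs, dams_per_sire=2)
        idx = {str(x): i for i, x in enumerate(g.samples)}
        rng = np.random.default_rng(32)

        def offspring_ho(pairs):
            hos = []
            for sire, dam in pairs:
                for _ in range(3):
                    child = mendelian_offspring(
                        g.dosage[idx[sire]], g.dosage[idx[dam]], rng
                    )
                    hos.append((child == 1).mean())
            return float(np.mean(hos))

        planned = offspring_ho(list(zip(plan.pairs["sire_id"], plan.pairs["dam_id"])))
        # random within-family matings (founder sire x dam of same family)
        within = offspring_ho(
            [(f"F{k}_sire", f"F{k}_dam") for k in range(1, 7)]
        )
        assert planned > within
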