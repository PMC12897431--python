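"""Supervised-admixture estimation: EM behaviour, purity calls, validation."""

import numpy as np
import pytest

from breedkit.gbc import (
    BreedFrequencyPanel,
    ancestry_loglik,
    evaluate_assignment,
    fit_ancestry,
    fit_ancestry_matrix,
    panel_frequencies,
    purity_call,
    split_train_test,
)
from breedkit.genodata import MISSING
from breedkit.simpop import SimConfig, simulate_frequencies, simulate_panel
from conftest import make_matrix


def toy_panel(K=3, M=50, seed=0, eps=1e-4):
    rng = np.random.default_rng(seed)
    freqs = np.clip(rng.uniform(0.05, 0.95, (K, M)), eps, 1 - eps)
    return BreedFrequencyPanel(
        breeds=np.array([f"B{k}" for k in range(K)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(M)], dtype=object),
        freqs=freqs,
    )


class TestFitAncestry:
    def test_k1_returns_point_simplex(self):
        panel = toy_panel(K=1)
        est = fit_ancestry(np.ones(50, dtype=np.int8), panel)
        assert est.q.tolist() == [1.0]
        assert est.converged

    def test_identical_frequencies_leave_uniform_q(self):
        base = toy_panel(K=1).freqs
        panel = BreedFrequencyPanel(
            breeds=np.array(["X", "Y", "Z"], dtype=object),
            marker_ids=np.array([f"m{j}" for j in range(50)], dtype=object),
            freqs=np.vstack([base] * 3),
        )
        g = np.random.default_rng(1).binomial(2, base[0]).astype(np.int8)
        est = fit_ancestry(g, panel)
        np.testing.assert_allclose(est.q, 1 / 3, atol=1e-9)

    def test_no_overlap_raises(self):
        panel = toy_panel()
        with pytest.raises(ValueError, match="non-missing"):
            fit_ancestry(np.full(50, MISSING, dtype=np.int8), panel)

    def test_em_loglik_monotone_and_simplex_every_iteration(self):
        panel = toy_panel(K=4, M=200, seed=2)
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.6 * panel.freqs[0] + 0.4 * panel.freqs[2]).astype(np.int8)
        g[rng.random(200) < 0.05] = MISSING
        est = fit_ancestry(g, panel, track_loglik=True)
        trace = est.loglik_trace
        assert (np.diff(trace) >= -1e-9).all()
        assert est.q.min() >= 0
        assert est.q.sum() == pytest.approx(1.0, abs=1e-8)

    def test_marker_order_permutation_invariance(self):
        panel = toy_panel(K=3, M=100, seed=4)
        rng = np.random.default_rng(5)
        g = rng.binomial(2, panel.freqs[1]).astype(np.int8)
        est = fit_ancestry(g, panel)
        perm = rng.permutation(100)
        panel_p = BreedFrequencyPanel(
            breeds=panel.breeds, marker_ids=panel.marker_ids[perm], freqs=panel.freqs[:, perm]
        )
        est_p = fit_ancestry(g[perm], panel_p)
        np.testing.assert_allclose(est.q, est_p.q, atol=1e-10)

    def test_purebred_and_even_admixture_recovery(self):
        """q recovery at K=5, FST=0.15, M=1000, averaged over seeded replicates."""
        err_pure, err_adm = [], []
        for rep in range(10):
            cfg = SimConfig(
                seed=900 + rep, n_breeds=5, fst=0.15, n_markers=1000,
                n_chromosomes=5, chrom_length_bp=50_000_000, samples_per_breed=1,
            )
            panel, _, _ = simulate_frequencies(cfg)
            rng = np.random.default_rng(950 + rep)
            gp = rng.binomial(2, panel.freqs[2]).astype(np.int8)
            est = fit_ancestry(gp, panel)
            err_pure.append(1.0 - est.q[2])
            m = 1000
            k = np.where(rng.random((2, m)) < 0.5, 0, 1)
            a = (rng.random((2, m)) < panel.freqs[k, np.arange(m)]).sum(axis=0)
            est2 = fit_ancestry(a.astype(np.int8), panel)
            err_adm.append(max(abs(est2.q[0] - 0.5), abs(est2.q[1] - 0.5)))
        assert np.mean(err_pure) <= 0.05
        assert np.mean(err_adm) <= 0.05


class TestPurity:
    def test_calls(self):
        panel = toy_panel(K=25)
        q = np.zeros(25)
        q[0] = 1.0
        from breedkit.gbc import AncestryEstimate

        pure = AncestryEstimate(q=q, loglik=0.0, n_iter=1, converged=True, breeds=panel.breeds)
        assert purity_call(pure) == "pure"
        uniform = AncestryEstimate(
            q=np.full(25, 1 / 25), loglik=0.0, n_iter=1, converged=True, breeds=panel.breeds
        )
        assert purity_call(uniform) == "admixed"

    def test_f1_hybrids_never_called_pure(self):
        cfg = SimConfig(
            seed=77, n_breeds=5, fst=0.15, n_markers=1000, n_chromosomes=5,
            chrom_length_bp=50_000_000, samples_per_breed=1,
        )
        panel, _, _ = simulate_frequencies(cfg)
        rng = np.random.default_rng(78)
        m = 1000
        for _ in range(10):
            a1 = (rng.random(m) < panel.freqs[0]).astype(np.int8)
            a2 = (rng.random(m) < panel.freqs[1]).astype(np.int8)
            est = fit_ancestry(a1 + a2, panel)
            assert purity_call(est, 0.95) == "admixed"


class TestPanelFrequencies:
    def test_single_breed_matches_site_freq_with_clamping(self):
        g = make_matrix([[0, 1, 2], [2, 1, 2]])
        panel = panel_frequencies(g, np.array(["B", "B"]))
        np.testing.assert_allclose(panel.freqs[0], [0.5, 0.5, 1 - 1e-4])

    def test_monomorphic_clamped_not_zero(self):
        g = make_matrix([[0, 2], [0, 2]])
        panel = panel_frequencies(g, np.array(["B", "B"]))
        assert panel.freqs[0, 0] == pytest.approx(1e-4)
        assert panel.freqs[0, 1] == pytest.approx(1 - 1e-4)

    def test_matches_recount(self, five_breed_panel, rng):
        g, s, _, _ = five_breed_panel
        panel = panel_frequencies(g, s.breed_label)
        k = list(panel.breeds).index("B03")
        cols = rng.choice(g.n_markers, 20, replace=False)
        sub = g.dosage[np.asarray(s.breed_label) == "B03"]
        for j in cols:
            d = sub[:, j]
            d = d[d != MISSING]
            expected = np.clip(d.sum() / (2 * d.size), 1e-4, 1 - 1e-4)
            assert panel.freqs[k, j] == pytest.approx(expected)


class TestSplitAndAssignment:
    def test_split_fraction_one_all_train(self):
        ids = np.array([f"s{i}" for i in range(10)], dtype=object)
        labels = np.array(["A"] * 10)
        train, test = split_train_test(ids, labels, 1.0, seed=1)
        assert len(train) == 10 and len(test) == 0

    def test_split_stratified_7_3(self):
        ids = np.array([f"s{i}" for i in range(30)], dtype=object)
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        train, test = split_train_test(ids, labels, 0.7, seed=2)
        assert len(train) == 21 and len(test) == 9
        for b in "ABC":
            assert sum(1 for t in train if labels[list(ids).index(t)] == b) == 7

    def test_split_union_disjoint_and_seeded(self, rng):
        ids = np.array([f"s{i}" for i in range(57)], dtype=object)
        labels = rng.choice(["A", "B", "C"], 57)
        t1, v1 = split_train_test(ids, labels, 0.7, seed=9)
        t2, v2 = split_train_test(ids, labels, 0.7, seed=9)
        assert set(t1) | set(v1) == set(ids)
        assert not (set(t1) & set(v1))
        assert list(t1) == list(t2) and list(v1) == list(v2)

    def test_admixture_assignment_accuracy(self, five_breed_panel):
        g, s, _, _ = five_breed_panel
        train, test = split_train_test(g.samples, s.breed_label, 0.7, seed=4)
        acc = evaluate_assignment("admixture", g, s.breed_label, train, test)
        assert acc >= 0.95

    def test_label_permuted_accuracy_near_chance(self, five_breed_panel):
        g, s, _, _ = five_breed_panel
        rng = np.random.default_rng(11)
        shuffled = rng.permutation(np.asarray(s.breed_label))
        train, test = split_train_test(g.samples, shuffled, 0.7, seed=5)
        acc = evaluate_assignment("admixture", g, shuffled, train, test)
        assert acc < 0.45  # chance is 1/5

    def test_classifiers_run_and_beat_chance(self, five_breed_panel):
        g, s, _, _ = five_breed_panel
        train, test = split_train_test(g.samples, s.breed_label, 0.7, seed=6)
        for method in ("rf", "mlp"):
            acc = evaluate_assignment(method, g, s.breed_label, train, test, seed=0)
            assert acc > 0.6

    def test_unknown_method_rejected(self, five_breed_panel):
        g, s, _, _ = five_breed_panel
        with pytest.raises(ValueError, match="unknown method"):
            evaluate_assignment("svm", g, s.breed_label, g.samples[:5], g.samples[5:10])
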