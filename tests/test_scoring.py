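"""Deviation scores: oracle equivalence, null behavior, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from clonmem.scoring import (DeviationScorer, ExpectedCounts,
                             activated_fraction, bag_motif_families,
                             condition_summary, deviation_scores,
                             downsampled_ks, expected_counts,
                             sample_background_sets, select_program_genes)
from clonmem.simulate import SimulationConfig, simulate_multiome


def _dense_deviation_oracle(X, ann, backgrounds):
    """Brute-force dense recomputation of the background z-scores."""
    X = np.asarray(X, dtype=float)
    E = ExpectedCounts(X).dense()

    def raw(w):
        return (X @ w - E @ w) / (E @ w)

    out = np.empty((X.shape[0], ann.shape[1]))
    for a in range(ann.shape[1]):
        w = ann[:, a]
        members = np.flatnonzero(w)
        y = raw(w)
        yb = []
        for b in range(backgrounds.shape[1]):
            wb = np.zeros(X.shape[1])
            for f in members:
                wb[backgrounds[f, b]] += w[f]
            yb.append(raw(wb))
        yb = np.asarray(yb)
        out[:, a] = (y - yb.mean(axis=0)) / yb.std(axis=0, ddof=1)
    return out


class TestExpectedCounts:
    def test_uniform_matrix(self):
        e = expected_counts(np.ones((4, 5)))
        assert np.allclose(e.dense(), 1.0)

    def test_single_cell_holds_all_reads(self):
        X = np.zeros((3, 4))
        X[1] = [5, 1, 2, 2]
        e = expected_counts(X)
        assert np.allclose(e.dense()[1], [5, 1, 2, 2])
        assert np.allclose(e.dense()[[0, 2]], 0.0)

    def test_matches_outer_product_oracle(self, rng):
        X = rng.poisson(2.0, size=(3, 4)) + 1
        e = expected_counts(X)
        depths = X.sum(axis=1)
        totals = X.sum(axis=0)
        assert np.allclose(e.dense(),
                           np.outer(depths, totals) / X.sum())
        w = rng.random(4)
        assert np.allclose(e.dot(w), e.dense() @ w)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(np.zeros((2, 2)))


class TestBackgroundSets:
    def test_single_bin_uniform_excluding_self(self, rng):
        X = rng.poisson(3, size=(10, 30)) + 1
        bg = sample_background_sets(X, np.array([4]), n_bins=1,
                                    n_background=500, seed=0)
        assert 4 not in bg[4]
        assert set(bg[4]) <= set(range(30)) - {4}
        # uniform draw covers most of the bin at 500 draws over 29 mates
        assert len(set(bg[4])) > 20

    def test_two_gene_bins_force_bin_mate(self, rng):
        # 40 genes, 20 bins -> bins of exactly 2; background is the bin-mate
        means = np.arange(40, dtype=float) + 1
        X = np.tile(means, (5, 1))
        bg = sample_background_sets(X, None, n_bins=20, n_background=250,
                                    seed=0)
        for f in range(40):
            mate = f + 1 if f % 2 == 0 else f - 1
            assert set(bg[f]) == {mate}

    def test_default_parameters(self, rng):
        X = rng.poisson(3, size=(20, 600)) + 1
        bg = sample_background_sets(X, np.array([0]))
        assert bg.shape[1] == 250


class TestDeviationScores:
    def test_zero_when_counts_equal_expectation(self):
        X = np.ones((4, 6))
        ann = np.zeros((6, 2))
        ann[[0, 1], 0] = 1
        ann[[2], 1] = 1
        bg = sample_background_sets(X, np.flatnonzero(ann.sum(axis=1)),
                                    n_bins=1, n_background=5, seed=0)
        sc = deviation_scores(X, ann, bg)
        assert np.allclose(sc.to_numpy(), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3.0, size=(10, 20)) + 1
        ann = np.zeros((20, 3))
        ann[[0, 5], 0] = 1
        ann[[7, 8, 9], 1] = 1
        ann[:, 2] = rng.random(20) * (rng.random(20) < 0.4)  # weighted set
        ann[0, 2] = 0.5
        bg = sample_background_sets(X, np.flatnonzero(ann.sum(axis=1)),
                                    n_bins=4, n_background=25, seed=seed)
        ours = deviation_scores(X, ann, bg).to_numpy()
        oracle = _dense_deviation_oracle(X, ann, bg)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_sparse_and_dense_agree(self, rng):
        X = rng.poisson(1.0, size=(8, 15)) + 1
        ann = np.zeros((15, 1))
        ann[[2, 3], 0] = 1
        bg = sample_background_sets(X, np.array([2, 3]), n_bins=3,
                                    n_background=10, seed=1)
        a = deviation_scores(sparse.csr_matrix(X), ann, bg).to_numpy()
        b = deviation_scores(X, ann, bg).to_numpy()
        assert np.allclose(a, b)

    def test_planted_condition_shift_detected_monotonically(self):
        means = {}
        for shift in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(seed=31, n_samples=2,
                                   conditions=("control", "colitis"),
                                   n_cells_per_sample=200,
                                   n_clones_per_sample=10,
                                   n_peaks=400, n_genes=50, n_families=4,
                                   condition_shift_per_family=(shift, 0, 0, 0))
            cells, pk, _, ann, _ = simulate_multiome(cfg)
            scorer = DeviationScorer(annotation=ann["peak_families"],
                                     n_background=50, n_bins=10,
                                     random_state=0,
                                     family_names=ann["family_ids"])
            sc = scorer.fit(pk).transform(pk)
            exposed = (cells["condition"] == "colitis").to_numpy()
            means[shift] = (sc.loc[exposed, "family_0"].mean()
                            - sc.loc[~exposed, "family_0"].mean())
        assert means[0.0] < means[0.5] < means[1.0]
        assert means[1.0] > 0.5

    def test_permutation_invariance(self, rng):
        X = rng.poisson(3.0, size=(10, 20)) + 1
        ann = np.zeros((20, 1))
        ann[[0, 5], 0] = 1
        bg = sample_background_sets(X, np.array([0, 5]), n_bins=2,
                                    n_background=20, seed=2)
        base = deviation_scores(X, ann, bg).to_numpy()
        perm = rng.permutation(10)
        permuted = deviation_scores(X[perm], ann, bg).to_numpy()
        assert np.allclose(permuted, base[perm])


class TestBagging:
    def _q(self, names, entries):
        q = pd.DataFrame(1.0, index=names, columns=names)
        for a, b, v in entries:
            q.loc[a, b] = q.loc[b, a] = v
        return q

    def test_all_dissimilar_singletons(self):
        names = ["A", "B", "C"]
        fams = bag_motif_families(self._q(names, []),
                                  pd.Series([3, 2, 1], index=names))
        assert fams == {"A": "A", "B": "B", "C": "C"}

    def test_leader_by_variability(self):
        names = ["A", "B"]
        fams = bag_motif_families(self._q(names, [("A", "B", 0.01)]),
                                  pd.Series({"A": 2.0, "B": 1.0}))
        assert fams == {"A": "A", "B": "A"}

    def test_greedy_chain_split(self):
        names = ["A", "B", "C"]
        q = self._q(names, [("A", "B", 0.01), ("B", "C", 0.01)])
        fams = bag_motif_families(q, pd.Series({"A": 3.0, "B": 2.0, "C": 1.0}))
        assert fams == {"A": "A", "B": "A", "C": "C"}


class TestConditionSummary:
    def _toy(self, shift, n_cells=300, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        scores = []
        for j, (sample, cond) in enumerate(
                [("S1", "control"), ("S2", "control"), ("S3", "control"),
                 ("S4", "exposed"), ("S5", "exposed"), ("S6", "exposed")]):
            mu = shift if cond == "exposed" else 0.0
            scores.append(rng.normal(mu, 1.0, size=(n_cells, 2)))
            rows += [{"sample": sample, "condition": cond}] * n_cells
        return (pd.DataFrame(np.vstack(scores), columns=["f1", "f2"]),
                pd.DataFrame(rows))

    def test_null_change_near_zero(self):
        sc, meta = self._toy(0.0)
        out = condition_summary(sc, meta, control="control", min_cells=100)
        assert out["change"].abs().max() < 0.2

    def test_planted_shift_recovered_and_significant(self):
        sc, meta = self._toy(1.0, seed=1)
        out = condition_summary(sc, meta, control="control", min_cells=100)
        exposed = out[out["condition"] == "exposed"]
        assert exposed["change"].mean() == pytest.approx(1.0, abs=0.2)
        assert (exposed["p_value"] < 0.01).all()

    def test_bh_adjustment_matches_step_up_oracle(self):
        # hand computation of Benjamini-Hochberg on (0.001, 0.02, 0.9)
        from statsmodels.stats.multitest import multipletests
        fdr = multipletests([0.001, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(fdr, [0.003, 0.03, 0.9])

    def test_small_samples_excluded(self):
        sc, meta = self._toy(0.0, n_cells=300, seed=2)
        # shrink one control sample below the floor; it must vanish
        drop = meta["sample"] == "S1"
        keep = ~(drop & (np.arange(len(meta)) % 2 == 0))
        out = condition_summary(sc[keep], meta[keep], control="control",
                                min_cells=200)
        assert "S1" not in set(out["sample"])
        assert {"S2", "S3", "S4", "S5", "S6"} <= set(out["sample"])

    def test_all_samples_too_small_raises(self):
        sc, meta = self._toy(0.0, n_cells=10)
        with pytest.raises(ValueError):
            condition_summary(sc, meta, control="control", min_cells=200)


class TestActivatedFraction:
    def test_zero_scores(self):
        s = pd.Series(np.zeros(10))
        samples = pd.Series(["A"] * 10)
        assert activated_fraction(s, samples).loc["A"] == 0.0

    def test_strict_threshold_boundary(self):
        s = pd.Series([1.4, 1.5, 1.6, 2.0])
        samples = pd.Series(["A"] * 4)
        assert activated_fraction(s, samples).loc["A"] == 0.5

    def test_recovers_planted_high_memory_fraction(self):
        cfg = SimulationConfig(seed=33, n_samples=2,
                               conditions=("control", "colitis"),
                               n_cells_per_sample=2000,
                               n_clones_per_sample=100, n_families=1,
                               icc_per_family=0.05,
                               high_memory_fraction=0.1, delta_high=4.0,
                               n_peaks=50, n_genes=20)
        cells, _, _, _, truth = simulate_multiome(cfg)
        lat = pd.Series(truth["latent_scores"][:, 0])
        frac = activated_fraction(lat, cells["sample"], threshold=1.5)
        # exposed-minus-control removes the baseline noise exceedance of the
        # unit-variance null (P[N(0,1) > 1.5] ~ 6.7%, present in both arms)
        assert frac["S1"] - frac["S0"] == pytest.approx(0.1, abs=0.05)


class TestDownsampledKS:
    def test_disjoint_supports(self):
        s = pd.Series(np.r_[np.zeros(600), np.ones(600)])
        cond = pd.Series(["a"] * 600 + ["b"] * 600)
        stat, p, flagged = downsampled_ks(s, cond, "a", "b", n=500, seed=0)
        assert stat == 1.0 and not flagged

    def test_null_p_uniform_over_seeds(self, rng):
        s = pd.Series(rng.normal(size=2000))
        cond = pd.Series(["a", "b"] * 1000)
        ps = [downsampled_ks(s, cond, "a", "b", n=500, seed=k)[1]
              for k in range(40)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_location_shift_power(self, rng):
        hits = 0
        for k in range(20):
            s = pd.Series(np.r_[rng.normal(0, 1, 800),
                                rng.normal(0.5, 1, 800)])
            cond = pd.Series(["a"] * 800 + ["b"] * 800)
            _, p, _ = downsampled_ks(s, cond, "a", "b", n=500, seed=k)
            hits += p < 1e-6
        assert hits >= 19

    def test_small_arm_flagged(self):
        s = pd.Series(np.r_[np.zeros(100), np.ones(600)])
        cond = pd.Series(["a"] * 100 + ["b"] * 600)
        assert downsampled_ks(s, cond, "a", "b", n=500)[2]


class TestProgramGenes:
    def test_top_k_and_ties(self):
        w = pd.Series({"gB": 0.5, "gA": 0.5, "gC": 0.3, "gD": 0.1})
        assert select_program_genes(w, k=3) == ["gA", "gB", "gC"]

    def test_k_larger_than_gene_count(self):
        w = pd.Series({"g1": 0.2, "g2": 0.8})
        assert select_program_genes(w, k=150) == ["g2", "g1"]
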