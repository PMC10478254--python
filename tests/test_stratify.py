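"""Ward clustering against brute-force and scipy oracles; cut and labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from stresstrata.io import Direction, ExpressionMatrix, GenePanel, PanelEntry
from stresstrata.stratify import (
    StandardizedMatrix,
    cut_rescaled,
    label_strata,
    rescaled_heights,
    ward_cluster,
    zscore_standardize,
)


def _std_from_points(X: np.ndarray) -> StandardizedMatrix:
    """Wrap raw points (samples × features) without re-standardizing."""
    df = pd.DataFrame(
        X.T,
        index=[f"g{i}" for i in range(X.shape[1])],
        columns=[f"s{j}" for j in range(X.shape[0])],
    )
    return StandardizedMatrix(df)


def brute_force_ward(X: np.ndarray):
    """Greedy ΔSSE agglomeration recomputed from raw points at every step.

    Independent oracle: no Lance–Williams recurrence; each candidate merge's
    height is (n_i n_j / (n_i + n_j))·‖mean_i − mean_j‖² from scratch.
    """
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                na, nb = len(ca), len(cb)
                delta = (
                    na * nb / (na + nb)
                    * float(np.sum((X[ca].mean(0) - X[cb].mean(0)) ** 2))
                )
                la, lb = min(ca), min(cb)
                if la > lb:
                    la, lb = lb, la
                cand = (delta, la, lb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        delta, _, _, a, b = best
        merged = clusters[a] + clusters[b]
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), delta))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


class TestZscore:
    def test_simple_example(self):
        m = ExpressionMatrix(
            pd.DataFrame([[2.0, 4.0, 6.0]], index=["IL6"], columns=list("abc"))
        )
        panel = GenePanel([PanelEntry("IL6", Direction.UP)])
        std = zscore_standardize(m, panel)
        assert np.allclose(std.z_values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_gene_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0]], index=["IL6"], columns=list("abc"))
        )
        panel = GenePanel([PanelEntry("IL6", Direction.UP)])
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_standardize(m, panel)

    def test_rows_have_mean_zero_unit_sd(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.gamma(2, 10, size=(3, 12)),
                index=["IL6", "BDNF", "SOD2"],
                columns=[f"s{i}" for i in range(12)],
            )
        )
        panel = GenePanel(
            [PanelEntry("IL6", Direction.UP), PanelEntry("BDNF", Direction.DOWN),
             PanelEntry("SOD2", Direction.UP)]
        )
        z = zscore_standardize(m, panel).z_values.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestWard:
    def test_one_dimensional_example(self):
        d = ward_cluster(_std_from_points(np.array([[0.0], [1.0], [10.0]])))
        heights = d.heights()
        assert heights[0] == pytest.approx(0.5)
        assert heights[1] == pytest.approx(2 * 1 / 3 * 9.5**2)  # 60.1667
        assert d.merges[0].left == 0 and d.merges[0].right == 1

    def test_duplicate_points_merge_at_zero(self):
        d = ward_cluster(_std_from_points(np.array([[1.0, 2.0], [1.0, 2.0]])))
        assert d.heights()[0] == 0.0

    def test_heights_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(3, 12), 4))
            h = ward_cluster(_std_from_points(X)).heights()
            assert np.all(np.diff(h) >= -1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, int(rng.integers(2, 5))))
            dendro = ward_cluster(_std_from_points(X))
            oracle = brute_force_ward(X)
            for merge, (oa, ob, oh) in zip(dendro.merges, oracle):
                assert {dendro.leaves_under(merge.left),
                        dendro.leaves_under(merge.right)} == {oa, ob}
                assert merge.height == pytest.approx(oh, rel=1e-9)

    def test_matches_scipy_ward_heights(self):
        # scipy reports d = sqrt(2 * ΔSSE) for Ward linkage
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 5))
        mine = ward_cluster(_std_from_points(X)).heights()
        scipy_h = linkage(X, method="ward")[:, 2]
        assert np.allclose(np.sort(mine), np.sort(scipy_h**2 / 2.0), rtol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_cluster(_std_from_points(np.array([[1.0]])))


class TestCut:
    def test_worked_example(self):
        d = ward_cluster(_std_from_points(np.array([[0.0], [1.0], [10.0]])))
        rs = rescaled_heights(d)
        assert rs[0] == pytest.approx(25 * 0.5 / (2 / 3 * 9.5**2))
        assert rs[1] == pytest.approx(25.0)
        part = cut_rescaled(d, 20)
        assert part["s0"] == part["s1"] != part["s2"]

    def test_threshold_25_single_cluster(self):
        rng = np.random.default_rng(3)
        d = ward_cluster(_std_from_points(rng.normal(size=(8, 3))))
        assert len(set(cut_rescaled(d, 25).values())) == 1

    def test_tiny_threshold_all_singletons(self):
        rng = np.random.default_rng(4)
        d = ward_cluster(_std_from_points(rng.normal(size=(6, 3))))
        assert len(set(cut_rescaled(d, 1e-9).values())) == 6

    def test_degenerate_dendrogram_warns_single_cluster(self):
        X = np.ones((3, 2))
        d = ward_cluster(_std_from_points(X))
        with pytest.warns(UserWarning, match="degenerate"):
            part = cut_rescaled(d, 20)
        assert len(set(part.values())) == 1

    def test_threshold_out_of_range(self):
        d = ward_cluster(_std_from_points(np.array([[0.0], [1.0]])))
        with pytest.raises(ValueError):
            cut_rescaled(d, 0)
        with pytest.raises(ValueError):
            cut_rescaled(d, 26)

    def test_cumulative_schedule_is_monotone_rescaling(self):
        rng = np.random.default_rng(5)
        d = ward_cluster(_std_from_points(rng.normal(size=(10, 3))))
        rs = rescaled_heights(d, "cumulative")
        assert rs[-1] == pytest.approx(25.0)
        assert np.all(np.diff(rs) >= 0)


class TestLabeling:
    def _panel(self):
        return GenePanel(
            [PanelEntry("U1", Direction.UP), PanelEntry("U2", Direction.UP),
             PanelEntry("D1", Direction.DOWN), PanelEntry("V1", Direction.VARIABLE)]
        )

    def _std(self):
        # cluster {a,b}: up genes high, down gene low; {c,d} mirrored
        z = pd.DataFrame(
            [[1, 1, -1, -1], [1, 1, -1, -1], [-1, -1, 1, 1], [5, -5, 5, -5]],
            index=["U1", "U2", "D1", "V1"],
            columns=list("abcd"),
            dtype=float,
        )
        return StandardizedMatrix(z)

    def test_concordant_cluster_is_hsr(self):
        part = {"a": 0, "b": 0, "c": 1, "d": 1}
        lab = label_strata(part, self._std(), self._panel())
        assert lab.assignment == {"a": "HSR", "b": "HSR", "c": "LSR", "d": "LSR"}
        assert lab.concordance[0] > lab.concordance[1]

    def test_invariant_to_cluster_id_relabeling(self):
        lab1 = label_strata({"a": 0, "b": 0, "c": 1, "d": 1}, self._std(), self._panel())
        lab2 = label_strata({"a": 7, "b": 7, "c": 2, "d": 2}, self._std(), self._panel())
        assert lab1.assignment == lab2.assignment

    def test_wrong_cluster_count_errors(self):
        with pytest.raises(ValueError, match="adjust"):
            label_strata({"a": 0, "b": 1, "c": 2, "d": 2}, self._std(), self._panel())

    def test_exact_tie_errors(self):
        z = pd.DataFrame(
            [[1, -1, -1, 1], [-1, 1, 1, -1]],
            index=["U1", "D1"], columns=list("abcd"), dtype=float,
        )
        std = StandardizedMatrix(z)
        panel = GenePanel([PanelEntry("U1", Direction.UP), PanelEntry("D1", Direction.DOWN)])
        with pytest.raises(ValueError, match="tie"):
            label_strata({"a": 0, "b": 0, "c": 1, "d": 1}, std, panel)

    def test_requires_up_and_down_genes(self):
        panel = GenePanel([PanelEntry("U1", Direction.UP)])
        z = pd.DataFrame([[1, 1, -1, -1]], index=["U1"], columns=list("abcd"), dtype=float)
        with pytest.raises(ValueError, match="UP and one DOWN"):
            label_strata({"a": 0, "b": 0, "c": 1, "d": 1}, StandardizedMatrix(z), panel)


class TestRecoveryOnSyntheticCohorts:
    def test_strata_recover_latent_groups(self):
        from sklearn.metrics import adjusted_rand_score

        from stresstrata.io import default_stress_panel
        from stresstrata.simulate import CohortSpec, generate_cohort

        panel = default_stress_panel()
        aris, correct = [], 0
        n_seeds = 15
        for seed in range(100, 100 + n_seeds):
            matrix, _, truth = generate_cohort(
                CohortSpec(rng_seed=seed, n_background_genes=7)
            )
            sz = [s for s, g in truth.items() if g.startswith("SZ")]
            std = zscore_standardize(matrix.subset_samples(sz), panel)
            part = cut_rescaled(ward_cluster(std), 20)
            aris.append(
                adjusted_rand_score([truth[s] for s in sz], [part[s] for s in sz])
            )
            if len(set(part.values())) == 2:
                lab = label_strata(part, std, panel)
                acc = np.mean(
                    [(lab.assignment[s] == "HSR") == (truth[s] == "SZ_HSR") for s in sz]
                )
                correct += acc > 0.5
        assert np.mean(aris) >= 0.8
        assert correct / n_seeds >= 0.9
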