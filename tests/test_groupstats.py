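import numpy as np
import pandas as pd
import pytest

import eegnets as e
from eegnets.groupstats import AlignmentError, rank_sum_p


class TestWilcoxonRank:
    def test_identical_multisets_p_one(self):
        assert e.wilcoxon_rank([1, 2, 2, 5], [1, 2, 2, 5]) == 1.0

    def test_separated_samples_exact(self):
        # 20 arrangements of ranks; only {1,2,3} and {4,5,6} are as extreme
        assert e.wilcoxon_rank([1, 2, 3], [10, 11, 12]) == pytest.approx(2 / 20)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            e.wilcoxon_rank([], [1, 2])

    def test_exact_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            a = rng.standard_normal(5)
            b = rng.standard_normal(6)
            ours = e.wilcoxon_rank(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_vs_normal_approximation_band(self, rng):
        """For pooled n ≤ 12 the asymptotic p stays within 0.05 of exact."""
        for _ in range(30):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            exact = e.wilcoxon_rank(a, b)
            approx = float(rank_sum_p(a, b))
            assert abs(exact - approx) < 0.05

    def test_type_i_error_calibration(self):
        """Null rejection rate at 0.05 stays in the binomial 99% band."""
        g = np.random.default_rng(99)
        a = g.standard_normal((2000, 25))
        b = g.standard_normal((2000, 25))
        rate = (rank_sum_p(a, b) < 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < band + 0.005


def make_metric_table(values_by_node, k_values, windows, trials, jitter=0.0,
                      seed=0):
    """Long-format local metric table with per-node base values."""
    g = np.random.default_rng(seed)
    rows = []
    for t in range(trials):
        for w in windows:
            for k in k_values:
                for node, base in values_by_node.items():
                    v = base + jitter * g.standard_normal()
                    rows.append((t, w, k, node, v, v / 10.0, v * 2.0))
    return pd.DataFrame(
        rows, columns=["trial", "window_start_ms", "k", "node",
                       "degree", "clustering", "betweenness"]
    )


class TestCompareConditions:
    cfg = e.ComparisonConfig(density_grid=(20, 30, 40), min_densities=3,
                             n_electrodes=4)

    def test_bonferroni_threshold(self):
        assert e.ComparisonConfig().bonferroni_alpha == pytest.approx(0.0025)

    def test_identical_conditions_nothing_significant(self):
        nodes = {"a": 3.0, "b": 4.0, "c": 5.0, "d": 6.0}
        ta = make_metric_table(nodes, (20, 30, 40), (0.0, 43.3), 12, 0.5, 1)
        tb = make_metric_table(nodes, (20, 30, 40), (0.0, 43.3), 12, 0.5, 2)
        sig = e.compare_conditions(ta, tb, self.cfg)
        assert not sig.local.robust_pass.any()

    def test_shifted_node_detected_with_direction(self):
        nodes = {"a": 3.0, "b": 4.0, "c": 5.0, "d": 6.0}
        ta = make_metric_table(nodes, (20, 30, 40), (0.0,), 20, 0.3, 3)
        nodes_b = dict(nodes, a=9.0)
        tb = make_metric_table(nodes_b, (20, 30, 40), (0.0,), 20, 0.3, 4)
        sig = e.compare_conditions(ta, tb, self.cfg, condition_names=("X", "Y"))
        hit = sig.local[(sig.local.electrode == "a") & (sig.local.metric == "degree")]
        assert hit.robust_pass.all()
        assert (hit.direction == "Y").all()
        others = sig.local[sig.local.electrode != "a"]
        assert not others.robust_pass.any()

    def test_robust_requires_min_densities(self):
        """Structural invariant: robust ⇒ ≥ min_densities Bonferroni passes."""
        nodes = {"a": 3.0, "b": 4.0, "c": 5.0, "d": 6.0}
        ta = make_metric_table(nodes, (20, 30, 40), (0.0,), 15, 0.4, 5)
        tb = make_metric_table(dict(nodes, b=8.0), (20, 30, 40), (0.0,), 15, 0.4, 6)
        sig = e.compare_conditions(ta, tb, self.cfg)
        counts = sig.local.groupby(["electrode", "metric", "window_start_ms"]).agg(
            n_bonf=("bonferroni_pass", "sum"), any_robust=("robust_pass", "any")
        )
        bad = counts[counts.any_robust & (counts.n_bonf < self.cfg.min_densities)]
        assert bad.empty

    def test_p_above_bonferroni_boundary_fails(self):
        """A p-value of 0.0026 misses the 0.05/20 = 0.0025 cutoff everywhere."""
        cfg = e.ComparisonConfig()
        assert not 0.0026 < cfg.bonferroni_alpha
        local = pd.DataFrame(
            {
                "electrode": ["F7"] * 7,
                "metric": ["degree"] * 7,
                "window_start_ms": [0.0] * 7,
                "k": list(cfg.density_grid),
                "p": [0.0026] * 7,
            }
        )
        local["bonferroni_pass"] = local["p"] < cfg.bonferroni_alpha
        assert not local.bonferroni_pass.any()

    def test_mismatched_grids_rejected(self):
        nodes = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        ta = make_metric_table(nodes, (20, 30), (0.0,), 5, 0.1, 7)
        tb = make_metric_table(nodes, (20, 40), (0.0,), 5, 0.1, 8)
        with pytest.raises(AlignmentError):
            e.compare_conditions(ta, tb, self.cfg)


class TestFirstNeighbors:
    def _net(self, edges, condition, labels=("a", "b", "c", "d")):
        adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
        for i, j in edges:
            adj[i, j] = adj[j, i] = 1
        return e.FunctionalNetwork(adjacency=adj, k=len(edges),
                                   labels=list(labels), condition=condition)

    def test_complete_graphs_count_everything(self):
        full = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        nets = [self._net(full, "BM") for _ in range(10)]
        tab = e.first_neighbors(nets, "a")
        assert (tab["count_BM"] == 10).all()

    def test_isolated_target_zero(self):
        nets = [self._net([(1, 2)], "BM") for _ in range(5)]
        tab = e.first_neighbors(nets, "a")
        assert (tab["count_BM"] == 0).all()

    def test_planted_tally(self, rng):
        """Counts equal a direct tally over a random planted edge collection."""
        labels = ("a", "b", "c", "d")
        nets = []
        expected = {"BM": np.zeros(4, int), "SM": np.zeros(4, int)}
        all_pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        for n in range(60):
            cond = "BM" if n % 2 else "SM"
            chosen = [all_pairs[i] for i in rng.choice(6, size=3, replace=False)]
            nets.append(self._net(chosen, cond))
            for i, j in chosen:
                if i == 0:
                    expected[cond][j] += 1
                elif j == 0:
                    expected[cond][i] += 1
        tab = e.first_neighbors(nets, "a")
        for cond in ("BM", "SM"):
            np.testing.assert_array_equal(tab[f"count_{cond}"], expected[cond][1:])

    def test_unknown_target(self):
        nets = [self._net([(0, 1)], "BM")]
        with pytest.raises(KeyError):
            e.first_neighbors(nets, "Qz")


class TestBaselineCheck:
    grid = (20, 30, 40)
    cfg = e.ComparisonConfig(density_grid=grid, min_densities=3)
    wc = e.WindowConfig(fs=600.0)

    def _null_pair(self, seed):
        ts = e.generate_trials(e.SynthConfig(n_trials=8, epoch_s=0.45, seed=seed))
        return ts.condition("BM"), ts.condition("SM")

    def test_null_baseline_clean(self):
        hits = 0
        for seed in (0, 1, 2):
            a, b = self._null_pair(seed)
            sig = e.baseline_check(a, b, self.cfg, self.wc)
            hits += int(sig.local.robust_pass.any())
        assert hits == 0

    def test_positive_control_detected(self):
        eff = e.EffectSpec(condition="SM")
        ts = e.generate_trials(
            e.SynthConfig(n_trials=20, epoch_s=0.45, seed=0, effect=eff)
        )
        sig = e.baseline_check(ts.condition("BM"), ts.condition("SM"),
                               self.cfg, self.wc, condition_names=("BM", "SM"))
        f7 = sig.local[(sig.local.electrode == "F7") & (sig.local.metric == "degree")]
        assert f7.robust_pass.any()

    def test_empty_rejected(self):
        a, b = self._null_pair(3)
        with pytest.raises(AlignmentError):
            e.baseline_check(a.select(np.zeros(a.n_trials, bool)), b, self.cfg, self.wc)
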