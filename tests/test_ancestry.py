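"""Reference panels and the supervised-clustering EM."""

import io

import numpy as np
import pytest

from popassign.ancestry import (
    EmConfig,
    ReferencePanel,
    ancestry_tables,
    build_reference_panel,
    loglikelihood,
    read_ancestry_results,
    supervised_em,
    write_ancestry_outputs,
)
from popassign.data import MISSING
from popassign.simulate import SimulationConfig, simulate_study

from conftest import make_dataset


def make_panel(freqs, populations=None):
    freqs = np.asarray(freqs, dtype=float)
    K, M = freqs.shape
    populations = populations or [f"P{k + 1}" for k in range(K)]
    return ReferencePanel(populations, [f"m{j + 1}" for j in range(M)],
                          freqs, np.zeros((K, M), dtype=np.int64),
                          np.zeros((K, M), dtype=np.int64))


def grid_search_q1(g, f1, f2, step=1e-4):
    """1-D likelihood maximisation oracle for K=2."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    freqs = np.vstack([f1, f2])
    best, best_ll = 0.0, -np.inf
    for q1 in grid:
        ll = loglikelihood(g, np.array([q1, 1 - q1]), freqs)
        if ll > best_ll:
            best, best_ll = q1, ll
    return best


class TestReferencePanel:
    def test_laplace_formula(self):
        # population fixed for the other allele: y=0 over n=30 -> f = 1/32
        g = np.zeros((15, 1), dtype=np.int8)
        panel = build_reference_panel(make_dataset(g), min_individuals=15)
        assert panel.freqs[0, 0] == pytest.approx(1 / 32)
        assert panel.allele_counts[0, 0] == 0
        assert panel.allele_totals[0, 0] == 30

    def test_laplace_formula_partial_counts(self):
        # y=3 counted copies among n=10 alleles -> f = 4/12
        g = np.array([[2], [1], [0], [0], [0]], dtype=np.int8)
        panel = build_reference_panel(make_dataset(g), min_individuals=1)
        assert panel.freqs[0, 0] == pytest.approx(4 / 12)

    def test_no_calls_gives_symmetric_prior(self):
        g = np.full((15, 1), MISSING, dtype=np.int8)
        ds = make_dataset(g, alleles=("0", "0"))
        panel = build_reference_panel(ds, min_individuals=15)
        assert panel.freqs[0, 0] == pytest.approx(0.5)

    def test_small_populations_excluded(self):
        g = np.ones((20, 2), dtype=np.int8)
        pops = ["BIG"] * 16 + ["SMALL"] * 4
        panel = build_reference_panel(make_dataset(g, populations=pops),
                                      min_individuals=15)
        assert panel.populations == ["BIG"]
        assert panel.excluded == {"SMALL": 4}

    def test_no_qualifying_population_errors(self):
        with pytest.raises(ValueError, match="floor"):
            build_reference_panel(make_dataset(np.ones((3, 1))),
                                  min_individuals=15)

    def test_frequencies_strictly_interior(self):
        g = np.vstack([np.full((15, 1), 2, dtype=np.int8),
                       np.zeros((15, 1), dtype=np.int8)])
        pops = ["P1"] * 15 + ["P2"] * 15
        panel = build_reference_panel(make_dataset(g, populations=pops))
        assert (panel.freqs > 0).all() and (panel.freqs < 1).all()


class TestLoglikelihood:
    def test_single_population_is_binomial(self):
        f = np.array([[0.3, 0.7, 0.5]])
        g = np.array([2, 1, 0])
        expected = sum(gm * np.log(fm) + (2 - gm) * np.log(1 - fm)
                       for gm, fm in zip(g, f[0]))
        assert loglikelihood(g, np.array([1.0]), f) == pytest.approx(expected)

    def test_all_missing_is_zero(self):
        f = np.array([[0.3], [0.6]])
        assert loglikelihood(np.array([MISSING]), np.array([0.5, 0.5]), f) == 0.0

    def test_two_population_hand_expansion(self):
        f = np.array([[0.2, 0.8, 0.5], [0.6, 0.4, 0.9]])
        q = np.array([0.3, 0.7])
        g = np.array([2, 0, 1])
        a = q @ f
        b = q @ (1 - f)
        expected = (2 * np.log(a[0]) + 0 * np.log(b[0])) \
            + (0 * np.log(a[1]) + 2 * np.log(b[1])) \
            + (np.log(a[2]) + np.log(b[2]))
        assert loglikelihood(g, q, f) == pytest.approx(expected, abs=1e-12)


class TestSupervisedEm:
    def test_single_population_immediate(self):
        panel = make_panel([[0.3, 0.6]])
        res = supervised_em(np.array([[1, 2]]), panel)
        assert res.q.tolist() == [[1.0]]
        assert res.converged.all() and res.iterations[0] == 0

    def test_identical_frequencies_flat_likelihood(self):
        panel = make_panel([[0.3, 0.6], [0.3, 0.6]])
        res = supervised_em(np.array([[1, 2]]), panel,
                            EmConfig(epsilon=1e-6))
        assert res.q[0] == pytest.approx([0.5, 0.5])
        assert res.iterations[0] == 1 and res.converged[0]

    def test_strong_signal_matches_grid_search(self):
        f1 = np.full(100, 0.9)
        f2 = np.full(100, 0.1)
        panel = make_panel(np.vstack([f1, f2]))
        g = np.full((1, 100), 2)
        res = supervised_em(g, panel, EmConfig(epsilon=1e-6))
        assert res.q[0, 0] >= 0.99
        oracle = grid_search_q1(g[0], f1, f2, step=1e-3)
        assert res.q[0, 0] == pytest.approx(oracle, abs=2e-3)

    def test_interior_optimum_matches_grid_search(self):
        rng = np.random.default_rng(7)
        f1 = rng.uniform(0.1, 0.9, 300)
        f2 = rng.uniform(0.1, 0.9, 300)
        true_f = 0.6 * f1 + 0.4 * f2
        g = rng.binomial(2, true_f)[None, :]
        panel = make_panel(np.vstack([f1, f2]))
        res = supervised_em(g, panel, EmConfig(epsilon=1e-8))
        oracle = grid_search_q1(g[0], f1, f2, step=1e-4)
        assert res.q[0, 0] == pytest.approx(oracle, abs=1e-3)

    def test_loglikelihood_monotone_and_simplex(self):
        rng = np.random.default_rng(11)
        panel = make_panel(rng.uniform(0.05, 0.95, size=(3, 60)))
        g = rng.integers(0, 3, size=(8, 60))
        res = supervised_em(g, panel, EmConfig(epsilon=1e-7),
                            return_trace=True)
        for trace in res.trace:
            assert (np.diff(trace) >= -1e-8).all()
        assert np.abs(res.q.sum(axis=1) - 1).max() < 1e-9

    def test_missing_loci_dropped_per_query(self):
        panel = make_panel([[0.9, 0.5], [0.1, 0.5]])
        g = np.array([[2, MISSING]])
        res = supervised_em(g, panel, EmConfig(epsilon=1e-8))
        full = supervised_em(np.array([[2]]),
                             make_panel([[0.9], [0.1]]),
                             EmConfig(epsilon=1e-8))
        assert res.q[0] == pytest.approx(full.q[0], abs=1e-9)

    def test_all_missing_query_signalled(self):
        panel = make_panel([[0.4], [0.6]])
        with pytest.raises(ValueError, match="no genotyped loci"):
            supervised_em(np.array([[MISSING]]), panel)

    def test_dataset_input_aligned_by_marker_id(self):
        ds = make_dataset([[2, 0]] * 15)
        panel = build_reference_panel(ds)
        reordered = ds.take(marker_indices=[1, 0])
        res = supervised_em(reordered, panel)
        assert res.q.shape == (15, 1)

    def test_epsilon_validation(self):
        with pytest.raises(ValueError):
            EmConfig(epsilon=0.0)


class TestParameterRecovery:
    def test_known_admixture_recovered(self):
        """Simulated queries with designed ancestry are recovered by EM."""
        cfg = SimulationConfig(
            n_populations=3, n_individuals=20, n_markers=3000, fst=0.1,
            admixed=[((0.6, 0.3, 0.1), 10)], seed=5)
        ds, _, truth = simulate_study(cfg)
        panel = build_reference_panel(ds.select_populations(
            {"POP01", "POP02", "POP03"}))
        queries = ds.select_populations({"ADM01"})
        res = supervised_em(queries, panel, EmConfig(epsilon=1e-4))
        q_true = np.vstack([truth[s] for s in res.sample_ids])
        assert np.abs(res.q - q_true).mean() < 0.05


class TestReports:
    def _result(self):
        panel = make_panel([[0.9] * 50, [0.1] * 50], ["PA", "PB"])
        g = np.vstack([np.full(50, 2), np.full(50, 0)])
        return supervised_em(g, panel, EmConfig(epsilon=1e-6))

    def test_summary_names_top_population(self):
        res = self._result()
        results, summary = ancestry_tables(res)
        top = summary[(summary["sample"] == res.sample_ids[0])
                      & (summary["rank"] == 1)].iloc[0]
        assert top["population"] == "PA"
        assert top["ancestry"] > 0.9
        assert list(results.columns[1:3]) == ["PA", "PB"]

    def test_round_trip_recovers_q(self):
        res = self._result()
        buf_r, buf_s = io.StringIO(), io.StringIO()
        write_ancestry_outputs(res, buf_r, buf_s)
        buf_r.seek(0)
        frame = read_ancestry_results(buf_r)
        q = frame[["PA", "PB"]].to_numpy()
        assert np.abs(q - res.q).max() < 1e-6
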