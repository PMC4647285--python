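"""Quality-filter cascade and the exact Hardy-Weinberg test."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

from popassign.data import MISSING
from popassign.qc import (
    QcConfig,
    call_rate_filter,
    hwe_exact_test,
    hwe_filter,
    maf_filter,
    run_qc,
    write_selection_summary,
)

from conftest import make_dataset


def hwe_oracle(n_hom_counted, n_het, n_hom_other):
    """Independent full-enumeration exact test via the closed-form
    conditional probability P(h | n, nA) = n! 2^h nA! nB! /
    (nAA! h! nBB! (2n)!), computed with log-gamma."""
    n = n_hom_counted + n_het + n_hom_other
    n_a = 2 * n_hom_counted + n_het
    n_b = 2 * n - n_a
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    if hs.size == 0:
        hs = np.array([0])
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logp = (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(hs + 1)
            - gammaln(n_bb + 1) + hs * np.log(2)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp)
    raw_total = float(probs.sum())  # closed form sums to 1 analytically
    probs /= probs.sum()
    p_obs = probs[hs == n_het][0]
    return float(min(probs[probs <= p_obs * (1 + 1e-10)].sum(), 1.0)), \
        raw_total


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 25) == 1.0
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_extreme_homozygote_excess(self):
        # 10 AA + 10 GG with zero heterozygotes: wildly out of equilibrium
        p = hwe_exact_test(10, 0, 10)
        oracle, _ = hwe_oracle(10, 0, 10)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p < 1e-5

    def test_small_table_matches_enumeration(self):
        p = hwe_exact_test(1, 2, 1)
        oracle, _ = hwe_oracle(1, 2, 1)
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_enumeration_oracle(self, n2, n1, n0):
        """p-value equals the log-gamma enumeration for random tables, and
        the conditional distribution is conserved."""
        if n2 + n1 + n0 == 0:
            return
        oracle, total = hwe_oracle(n2, n1, n0)
        assert hwe_exact_test(n2, n1, n0) == pytest.approx(oracle, abs=1e-12)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_bounds(self):
        for args in [(5, 10, 5), (0, 1, 0), (3, 0, 0), (2, 2, 2)]:
            p = hwe_exact_test(*args)
            assert 0.0 < p <= 1.0


class TestCallRateFilter:
    def test_default_order_individuals_first(self, callrate_dataset):
        out, summary = call_rate_filter(callrate_dataset, QcConfig())
        assert out.shape == (2, 4)
        assert out.sample_ids == ["s1", "s3"]
        assert [s.name for s in summary.stages] == [
            "individual_call_rate", "marker_call_rate"]
        assert summary.stages[0].removed_samples == ["s2", "s4"]
        assert summary.stages[1].removed_markers == []

    def test_reversed_order(self, callrate_dataset):
        cfg = QcConfig(reverse_call_rate_order=True)
        out, summary = call_rate_filter(callrate_dataset, cfg)
        assert out.shape == (3, 2)
        assert out.sample_ids == ["s1", "s2", "s3"]
        assert out.marker_ids == ["m3", "m4"]
        assert summary.stages[0].removed_markers == ["m1", "m2"]
        assert summary.stages[1].removed_samples == ["s4"]

    def test_complete_matrix_unchanged(self):
        ds = make_dataset(np.ones((3, 3)))
        out, _ = call_rate_filter(ds, QcConfig())
        assert out.shape == (3, 3)

    def test_everything_removed_warns_not_raises(self):
        ds = make_dataset(np.full((2, 2), MISSING), alleles=("0", "0"))
        out, summary = call_rate_filter(ds, QcConfig())
        assert out.n_samples == 0
        assert summary.warnings


class TestHweFilter:
    def test_equilibrium_marker_retained(self):
        ds = make_dataset([[2], [1], [1], [0]])
        out, _ = hwe_filter(ds, QcConfig())
        assert out.n_markers == 1

    def test_outlying_marker_removed(self):
        # 10 AA + 10 GG, no hets: oracle p < 1e-6 < 0.001
        g = np.array([[2]] * 10 + [[0]] * 10)
        ds = make_dataset(g)
        assert hwe_oracle(10, 0, 10)[0] < 0.001
        out, summary = hwe_filter(ds, QcConfig())
        assert out.n_markers == 0
        assert summary.stages[0].removed_markers == ["m1"]

    def test_zero_threshold_removes_nothing(self):
        g = np.array([[2]] * 10 + [[0]] * 10)
        ds = make_dataset(g)
        out, _ = hwe_filter(ds, QcConfig(hwe_p_threshold=0.0))
        assert out.n_markers == 1

    def test_per_population_mode(self):
        # two populations each fixed for opposite alleles: pooled counts
        # fail HWE (Wahlund effect) while each population is monomorphic
        g = np.array([[2]] * 20 + [[0]] * 20)
        pops = ["P1"] * 20 + ["P2"] * 20
        ds = make_dataset(g, populations=pops)
        pooled, _ = hwe_filter(ds, QcConfig())
        per_pop, _ = hwe_filter(ds, QcConfig(hwe_per_population=True))
        assert pooled.n_markers == 0
        assert per_pop.n_markers == 1


class TestMafFilter:
    def test_rare_but_kept(self):
        # 10 diploids, one copy of the minor allele: MAF 0.05 >= 0.01
        g = np.array([[1]] + [[2]] * 9)
        out, _ = maf_filter(make_dataset(g), QcConfig())
        assert out.n_markers == 1

    def test_monomorphic_removed(self):
        g = np.array([[2]] * 10)
        out, _ = maf_filter(make_dataset(g), QcConfig())
        assert out.n_markers == 0

    def test_balanced_kept_at_any_threshold(self):
        g = np.array([[2]] * 5 + [[0]] * 5)
        out, _ = maf_filter(make_dataset(g), QcConfig(min_maf=0.5))
        assert out.n_markers == 1


class TestRunQc:
    def test_all_disabled_is_identity(self, callrate_dataset):
        cfg = QcConfig(enable_call_rate=False, enable_hwe=False,
                       enable_maf=False)
        out, summary = run_qc(callrate_dataset, cfg)
        assert out.shape == callrate_dataset.shape
        assert summary.stages == []

    def test_stage_counts_compose(self, callrate_dataset):
        out, summary = run_qc(callrate_dataset, QcConfig())
        names = [s.name for s in summary.stages]
        assert names == ["individual_call_rate", "marker_call_rate", "hwe",
                         "maf"]
        # call-rate stages reproduce the hand enumeration
        assert (summary.stages[1].n_samples_out,
                summary.stages[1].n_markers_out) == (2, 4)
        # and downstream HWE/MAF act on the (2, 4) survivors
        assert summary.stages[2].n_samples_in == 2
        assert summary.stages[2].n_markers_in == 4
        assert out.n_samples == 2

    def test_counts_non_increasing(self, callrate_dataset):
        _, summary = run_qc(callrate_dataset, QcConfig())
        for s in summary.stages:
            assert s.n_samples_out <= s.n_samples_in
            assert s.n_markers_out <= s.n_markers_in

    def test_idempotent_on_fixture(self, callrate_dataset):
        once, _ = run_qc(callrate_dataset, QcConfig())
        twice, summary = run_qc(once, QcConfig())
        assert twice.shape == once.shape
        assert np.array_equal(twice.genotypes, once.genotypes)
        assert all(not s.removed_samples and not s.removed_markers
                   for s in summary.stages)

    def test_selection_summary_tsv(self, callrate_dataset, tmp_path):
        _, summary = run_qc(callrate_dataset, QcConfig())
        path = tmp_path / "selection.txt"
        write_selection_summary(summary, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[:3] == ["stage", "samples_before",
                                            "samples_after"]
        assert len(lines) == 1 + len(summary.stages)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcConfig(min_maf=1.5)
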