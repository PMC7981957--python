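"""Concordance, r-squared, leave-one-out and coverage/budget arithmetic."""

import itertools

import numpy as np
import pytest

from lowpasskit.impute import HMMParams, forward_backward
from lowpasskit.likelihood import array_likelihood_matrix
from lowpasskit.metrics import (
    ConcordanceCounts,
    VariantSet,
    bin_r2_by_maf,
    classify_sites,
    cohort_maf,
    concordance_report,
    expected_covered_sites,
    imputation_r2,
    leave_one_out_r2,
    npa,
    ppa,
    sequencing_budget,
)
from lowpasskit.panel_io import NO_CALL, GenotypeCalls

from conftest import make_panel
from hmm_oracle import random_instance


def _cohort(sites, rows):
    return [
        GenotypeCalls(sites=sites, calls=np.asarray(r, dtype=np.int8), sample=f"i{k}")
        for k, r in enumerate(rows)
    ]


class TestClassification:
    def test_perfect_agreement(self):
        t = np.array([0, 1, 2, 0, 1, 0])
        c = classify_sites(t, t.copy())
        assert c.fn == c.fp == 0
        assert c.tp + c.tn == 6

    def test_toy_ten_variant_sites(self):
        truth = np.array([1] * 10 + [0] * 0)
        test = truth.copy()
        test[8] = NO_CALL
        test[9] = 2  # discordant non-ref
        c = classify_sites(truth, test)
        assert (c.tp, c.fn, c.no_calls_at_truth_variant) == (8, 1, 1)
        assert c.mismatch_nonref == 1
        assert ppa(c) == pytest.approx(100 * 8 / 9)

    def test_het_called_hom_alt_is_fn_not_fp(self):
        c = classify_sites(np.array([1]), np.array([2]))
        assert (c.fn, c.fp) == (1, 0)

    def test_truth_no_call_sites_excluded(self):
        c = classify_sites(np.array([NO_CALL, NO_CALL, 0]), np.array([2, NO_CALL, 0]))
        assert c.n_truth_variant == 0 and c.n_truth_ref == 1 and c.tn == 1

    def test_partition_identity_exhaustive(self):
        """Every 3-site truth/test pair partitions into the six tallies."""
        alphabet = [0, 1, 2, NO_CALL]
        for truth in itertools.product(alphabet, repeat=3):
            t = np.asarray(truth)
            n_var = int((t > 0).sum())
            n_ref = int((t == 0).sum())
            for test in itertools.product(alphabet, repeat=3):
                c = classify_sites(t, np.asarray(test))
                assert c.n_truth_variant == n_var
                assert c.n_truth_ref == n_ref


class TestAgreementRates:
    def test_ppa_quotient(self):
        assert ppa(ConcordanceCounts(tp=8, fn=1)) == pytest.approx(88.888888, abs=1e-4)
        assert ppa(ConcordanceCounts(tp=5, fn=0)) == 100.0
        assert ppa(ConcordanceCounts()) is None

    def test_npa_quotient(self):
        assert npa(ConcordanceCounts(tn=19, fp=1)) == pytest.approx(95.0)
        assert npa(ConcordanceCounts(tn=3, fp=0)) == 100.0
        assert npa(ConcordanceCounts()) is None


class TestConcordanceReport:
    def test_perfect_single_individual(self, small_panel):
        calls = [0, 1, 2, 0, 1]
        truth = _cohort(small_panel.sites, [calls])
        report = concordance_report(truth, _cohort(small_panel.sites, [calls]))
        for rep in report.values():
            if rep.n_sites and rep.ppa_pct is not None:
                assert rep.ppa_pct == 100.0
            if rep.n_sites and rep.npa_pct is not None:
                assert rep.npa_pct == 100.0
            assert rep.mean_no_calls == 0.0

    def test_rare_threshold_is_five_copies(self, small_panel):
        # 6 diploids: site 0 carries exactly 5 alt copies, site 1 carries 6.
        rows = [
            [2, 2, 0, 0, 0],
            [1, 2, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ]
        truth = _cohort(small_panel.sites, rows)
        report = concordance_report(truth, truth, rare_threshold_copies=5)
        # rare stratum includes site 0 (5 copies) and the monomorphic sites
        assert report["all:rare"].n_sites == 4
        assert report["all:common"].n_sites == 1

    def test_subset_stratification(self, small_panel):
        rows = [[0, 1, 2, 0, 1]] * 3
        truth = _cohort(small_panel.sites, rows)
        subset = VariantSet(members=frozenset({("1", 100), ("1", 5000)}), label="ADME")
        report = concordance_report(truth, truth, subset=subset)
        assert report["ADME:all"].n_sites == 2
        assert set(report) == {
            f"{s}:{f}" for s in ("all", "ADME") for f in ("all", "rare", "common")
        }

    def test_order_invariance(self, small_panel):
        rows = [[0, 1, 2, 0, NO_CALL], [1, 1, 0, 2, 0], [2, 0, 0, 1, 1]]
        test_rows = [[0, 1, 1, 0, NO_CALL], [1, NO_CALL, 0, 2, 0], [2, 0, 1, 1, 1]]
        truth = _cohort(small_panel.sites, rows)
        test = _cohort(small_panel.sites, test_rows)
        fwd = concordance_report(truth, test)["all:all"]
        rev = concordance_report(truth[::-1], test[::-1])["all:all"]
        assert fwd.ppa_pct == pytest.approx(rev.ppa_pct)
        assert fwd.npa_pct == pytest.approx(rev.npa_pct)


class TestImputationR2:
    def test_perfect_dosage(self):
        truth = np.array([[0, 1], [1, 2], [2, 0], [0, 1], [1, 0]])
        r2 = imputation_r2(truth.astype(float), truth)
        np.testing.assert_allclose(r2, 1.0)

    def test_printed_five_sample_example(self):
        truth = np.array([[0], [1], [2], [0], [1]])
        dosage = np.array([[0.1], [0.8], [1.9], [0.0], [1.2]])
        assert imputation_r2(dosage, truth)[0] == pytest.approx(0.9657, abs=1e-4)

    def test_constant_dosage_flagged_zero(self):
        truth = np.array([[0], [1], [2]])
        dosage = np.full((3, 1), 0.7)
        assert imputation_r2(dosage, truth)[0] == 0.0

    def test_monomorphic_truth_is_nan(self):
        truth = np.zeros((4, 1), dtype=int)
        dosage = np.array([[0.1], [0.2], [0.0], [0.3]])
        assert np.isnan(imputation_r2(dosage, truth)[0])

    def test_no_call_samples_excluded(self):
        truth = np.array([[0], [1], [2], [NO_CALL]])
        dosage = np.array([[0.0], [1.0], [2.0], [55.0]])
        assert imputation_r2(dosage, truth)[0] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, size=(30, 4))
        dosage = truth + rng.normal(0, 0.3, size=truth.shape)
        base = imputation_r2(dosage, truth)
        scaled = imputation_r2(0.25 * dosage + 1.0, truth)
        np.testing.assert_allclose(base, scaled, atol=1e-12)


class TestMafBinning:
    def test_single_bin_mean(self):
        table = bin_r2_by_maf(np.array([1.0, 0.5]), np.array([0.3, 0.4]), (0.0, 0.5))
        assert table.bins[0].mean_r2 == pytest.approx(0.75)
        assert table.bins[0].n_variants == 2

    def test_edge_value_belongs_to_lower_bin(self):
        """Left-open bins (lo, hi]: a MAF equal to an edge closes that bin."""
        table = bin_r2_by_maf(
            np.array([0.8]), np.array([0.01]), (0.0, 0.005, 0.01, 0.5)
        )
        assert [b.n_variants for b in table.bins] == [0, 1, 0]

    def test_empty_bins_reported(self):
        table = bin_r2_by_maf(np.array([0.9]), np.array([0.4]), (0.0, 0.1, 0.2, 0.5))
        assert [b.n_variants for b in table.bins] == [0, 0, 1]
        assert np.isnan(table.bins[0].mean_r2)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_r2_by_maf(np.array([1.0]), np.array([0.1]), (0.0, 0.2, 0.1))

    def test_nan_r2_excluded(self):
        table = bin_r2_by_maf(
            np.array([np.nan, 0.6]), np.array([0.3, 0.3]), (0.0, 0.5)
        )
        assert table.bins[0].n_variants == 1
        assert table.bins[0].mean_r2 == pytest.approx(0.6)


class TestLeaveOneOut:
    def test_masked_rerun_equivalence(self):
        """Single-pass LOO dosages equal explicit flat-likelihood re-runs."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            panel, gls, rho, theta = random_instance(rng)
            params = HMMParams(rho=rho, theta=theta)
            res = forward_backward(gls, panel, params, compute_loo=True)
            for m in range(panel.M):
                masked = gls.copy()
                masked[m] = 1.0
                rerun = forward_backward(masked, panel, params)
                assert res.loo_dosages[m] == pytest.approx(rerun.dosages[m], abs=1e-10)

    def test_masked_site_has_zero_influence(self):
        """Permuting a site's own observed call never changes its LOO dosage."""
        rng = np.random.default_rng(22)
        panel, _, rho, theta = random_instance(rng, max_K=4, max_M=4)
        params = HMMParams(rho=rho, theta=theta)
        calls = rng.integers(0, 3, size=panel.M).astype(np.int8)
        base = forward_backward(
            array_likelihood_matrix(calls, 0.01), panel, params, compute_loo=True
        )
        for m in range(panel.M):
            for g in (0, 1, 2, NO_CALL):
                mutated = calls.copy()
                mutated[m] = g
                res = forward_backward(
                    array_likelihood_matrix(mutated, 0.01), panel, params,
                    compute_loo=True,
                )
                assert res.loo_dosages[m] == pytest.approx(
                    base.loo_dosages[m], abs=1e-12
                )

    def test_perfect_template_limit(self):
        """Haplotypes present verbatim in the panel are recovered exactly."""
        alleles = np.array(
            [
                [0, 1, 0, 1, 1, 0],
                [1, 0, 1, 0, 0, 1],
                [0, 0, 1, 1, 0, 0],
                [1, 1, 0, 0, 1, 1],
            ],
            dtype=np.uint8,
        )
        panel = make_panel(alleles, positions=[10, 20, 30, 40, 50, 60])
        params = HMMParams(rho=1e-9, theta=0.0)
        cohort = []
        for i, j in [(0, 1), (2, 3), (0, 2), (1, 3), (0, 3)]:
            g = (alleles[i] + alleles[j]).astype(np.int8)
            cohort.append(GenotypeCalls(sites=panel.sites, calls=g, sample=f"i{i}{j}"))
        r2 = leave_one_out_r2(cohort, panel, params, epsilon=0.0)
        polymorphic = ~np.isnan(r2)
        assert polymorphic.any()
        np.testing.assert_allclose(r2[polymorphic], 1.0, atol=1e-6)


class TestCoverageArithmetic:
    def test_expected_covered_sites_at_low_pass(self):
        covered = expected_covered_sites(0.4, 84.7e6)
        assert covered == pytest.approx(27.93e6, rel=1e-3)
        assert round(covered / 1e6) == 28

    def test_limits(self):
        assert expected_covered_sites(0.0, 1e6) == 0.0
        assert expected_covered_sites(50.0, 1e6) == pytest.approx(1e6)

    def test_budget_reads_and_bases(self):
        budget = sequencing_budget(0.1, genome_length=3.3e9, read_length=150)
        assert budget.n_reads == pytest.approx(2.2e6)
        assert budget.total_bases == pytest.approx(330e6)

    def test_budget_cost_scaling(self):
        assert sequencing_budget(0.4).cost == pytest.approx(13.33, abs=0.01)
        assert sequencing_budget(30.0).cost == pytest.approx(1000.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_covered_sites(-0.1, 10)
        with pytest.raises(ValueError):
            sequencing_budget(0.0)


def test_cohort_maf_ignores_no_calls(small_panel):
    rows = [[0, 1, NO_CALL, 2, 0], [1, 1, 2, NO_CALL, 0]]
    maf = cohort_maf(_cohort(small_panel.sites, rows))
    np.testing.assert_allclose(maf, [0.25, 0.5, 0.0, 0.0, 0.0])
    # sites 2 and 3 use only the called individual: 2/2 alt -> MAF 0
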