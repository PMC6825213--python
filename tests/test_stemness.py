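"""Limiting-dilution estimation and HiL-IC lineage calling."""

import math

import numpy as np
import pandas as pd
import pytest

from bctrace import (
    StemnessError,
    call_hilic,
    expected_engraftment_prob,
    fit_limiting_dilution,
    overlap_with_core,
    score_mouse_positive,
)


def design(doses, tested, positive):
    return pd.DataFrame({"dose": doses, "tested": tested, "positive": positive})


def loglik(f, d):
    lam = f * d["dose"].to_numpy()
    p = 1.0 - np.exp(-lam)
    with np.errstate(divide="ignore"):
        ll = d["positive"].to_numpy() * np.log(p) - (
            d["tested"].to_numpy() - d["positive"].to_numpy()
        ) * lam
    return float(ll.sum())


class TestPositivity:
    @pytest.mark.parametrize(
        "tibia, marrow, positive",
        [
            (0.006, 0.0, True),  # just over 0.5% in the injected tibia
            (0.005, 0.005, False),  # boundary is strict
            (0.0, 0.0, False),
            (0.0, 0.2, True),
            (None, 0.01, True),
        ],
    )
    def test_threshold_either_site(self, tibia, marrow, positive):
        assert score_mouse_positive(tibia, marrow) is positive

    def test_both_missing_errors(self):
        with pytest.raises(StemnessError, match="missing"):
            score_mouse_positive(None, None)


class TestLimitingDilution:
    def test_single_dose_closed_form(self):
        res = fit_limiting_dilution(design([100], [12], [6]))
        assert res.f_hat == pytest.approx(math.log(2) / 100, abs=1e-9)
        assert res.ci_lower < res.f_hat < res.ci_upper
        assert 1.0 / res.f_hat == pytest.approx(144.27, abs=0.01)

    def test_all_negative_boundary(self):
        res = fit_limiting_dilution(design([100, 1000], [6, 6], [0, 0]))
        assert res.f_hat == 0.0 and res.ci_lower == 0.0
        assert res.all_negative
        assert 0.0 < res.ci_upper < math.inf
        assert math.isinf(res.cells_per_lic)

    def test_all_positive_boundary(self):
        res = fit_limiting_dilution(design([100, 1000], [6, 6], [6, 6]))
        assert res.all_positive and math.isinf(res.f_hat)
        assert 0.0 < res.ci_lower < math.inf

    def test_multi_dose_mle_matches_grid_oracle(self):
        d = design([100, 1000], [6, 6], [2, 5])
        grid = np.exp(np.linspace(np.log(1e-6), np.log(0.5), 200_001))
        lls = [loglik(f, d) for f in grid]
        f_grid = grid[int(np.argmax(lls))]
        res = fit_limiting_dilution(d)
        assert res.f_hat == pytest.approx(f_grid, rel=1e-3)

    def test_profile_ci_hits_the_chi2_threshold(self):
        d = design([10_000, 1000, 100, 10], [6, 6, 6, 6], [6, 4, 1, 0])
        res = fit_limiting_dilution(d)
        drop = 3.841458820694124 / 2.0  # chi2(1) 95% quantile / 2
        for bound in (res.ci_lower, res.ci_upper):
            assert loglik(bound, d) == pytest.approx(
                res.log_likelihood - drop, abs=1e-6
            )
        assert res.ci_lower <= res.f_hat <= res.ci_upper
        if res.wald_lower is not None:
            assert res.wald_lower < res.f_hat < res.wald_upper

    def test_matches_reference_elda_implementation(self):
        """The frequency estimate agrees with the R statmod ELDA fit."""
        import subprocess

        d = design([100, 1000, 10_000], [6, 6, 6], [1, 4, 6])
        script = (
            "suppressMessages(library(statmod));"
            "out <- elda(response=c(1,4,6), dose=c(100,1000,10000),"
            " tested=c(6,6,6));"
            "cat(1/out$CI[1,'Estimate'])"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        f_ref = float(proc.stdout.strip().split()[-1])
        res = fit_limiting_dilution(d)
        assert res.f_hat == pytest.approx(f_ref, rel=0.01)

    @pytest.mark.parametrize(
        "bad",
        [
            design([], [], []),
            design([0], [6], [1]),
            design([100], [6], [7]),
            design([100], [0], [0]),
        ],
        ids=["empty", "zero_dose", "positive_gt_tested", "no_mice"],
    )
    def test_invalid_designs_error(self, bad):
        with pytest.raises(StemnessError):
            fit_limiting_dilution(bad)


class TestExpectedEngraftment:
    def test_even_mode_derived_value(self):
        freqs = pd.Series(np.full(250, 1 / 250), index=range(250))
        out = expected_engraftment_prob(1e-3, 1e4, freqs, mode="even")
        assert out["lambda"].iloc[0] == pytest.approx(0.04)
        assert out["establishment_prob"].iloc[0] == pytest.approx(
            1.0 - math.exp(-0.04)
        )

    def test_proportional_mode_derived_value(self):
        # Lambda = f * dose = 10; clone at frequency 0.05 has lambda 0.5
        freqs = pd.Series([0.05, 0.95], index=["a", "b"])
        out = expected_engraftment_prob(1e-3, 10_000, freqs)
        assert out.loc["a", "lambda"] == pytest.approx(0.5)
        assert out.loc["a", "establishment_prob"] == pytest.approx(
            1.0 - math.exp(-0.5), abs=1e-12
        )

    def test_zero_lambda_gives_zero_probability(self):
        freqs = pd.Series([1.0, 0.0], index=["a", "b"])
        out = expected_engraftment_prob(0.0, 100, freqs)
        assert (out["establishment_prob"] == 0.0).all()

    def test_unknown_mode_and_bad_frequencies_error(self):
        freqs = pd.Series([0.5, 0.5])
        with pytest.raises(StemnessError, match="mode"):
            expected_engraftment_prob(1e-3, 100, freqs, mode="sideways")
        with pytest.raises(StemnessError, match="sum"):
            expected_engraftment_prob(1e-3, 100, pd.Series([0.5, 0.2]))


def engraft_table(presence_by_clone, n_mice):
    return pd.DataFrame(
        {c: v for c, v in presence_by_clone.items()},
        index=[f"m{i}" for i in range(n_mice)],
    )


class TestHiLIC:
    def test_hand_computed_binomial_tail(self):
        # P(X >= 4 | n=7, p=0.1) = sum_{j=4..7} C(7,j) 0.1^j 0.9^(7-j)
        table = engraft_table({"a": [1, 1, 1, 1, 0, 0, 0]}, 7)
        calls = call_hilic(table, pd.Series({"a": 0.1}))
        assert calls.loc["a", "tail_p"] == pytest.approx(0.0027280, abs=1e-6)
        assert bool(calls.loc["a", "hilic"])

    def test_never_established_is_never_hilic(self):
        table = engraft_table({"a": [0, 0, 0]}, 3)
        calls = call_hilic(table, pd.Series({"a": 0.001}))
        assert calls.loc["a", "tail_p"] == 1.0
        assert not bool(calls.loc["a", "hilic"])

    def test_saturated_expectation_not_hilic(self):
        table = engraft_table({"a": [1, 1, 1]}, 3)
        calls = call_hilic(table, pd.Series({"a": 1.0}))
        assert calls.loc["a", "tail_p"] == pytest.approx(1.0)
        assert not bool(calls.loc["a", "hilic"])

    @staticmethod
    def _tail(k, m, p):
        presence = [1] * k + [0] * (m - k)
        table = engraft_table({"a": presence}, m)
        return float(call_hilic(table, pd.Series({"a": p})).loc["a", "tail_p"])

    def test_monotone_in_k_and_p_by_enumeration(self):
        for m in range(1, 11):
            for p in (0.05, 0.2, 0.5, 0.9):
                tails = [self._tail(k, m, p) for k in range(1, m + 1)]
                assert all(a >= b for a, b in zip(tails, tails[1:]))
            for k in range(1, m + 1):
                by_p = [self._tail(k, m, p) for p in (0.1, 0.3, 0.7)]
                assert all(a <= b for a, b in zip(by_p, by_p[1:]))

    def test_poisson_binomial_matches_binomial_when_probs_equal(self):
        table = engraft_table({"a": [1, 1, 0, 0, 0, 0, 1]}, 7)
        table.index.name = "mouse_id"
        scalar = call_hilic(table, pd.Series({"a": 0.3}))
        per_mouse = pd.DataFrame({"a": [0.3] * 7}, index=table.index)
        hetero = call_hilic(table, per_mouse)
        assert hetero.loc["a", "tail_p"] == pytest.approx(
            scalar.loc["a", "tail_p"], rel=1e-12
        )

    def test_established_exceeding_mice_errors(self):
        table = engraft_table({"a": [1, 2]}, 2)
        with pytest.raises(StemnessError):
            call_hilic(table, pd.Series({"a": 0.1}))


class TestOverlap:
    def test_counts_and_identities(self):
        out = overlap_with_core(["A", "B", "C", "D"], ["A", "B", "E"])
        assert out["overlap"] == ["A", "B"]
        assert (out["n_overlap"], out["n_hilic_only"], out["n_core_only"]) == (2, 2, 1)

    def test_identical_and_disjoint(self):
        full = overlap_with_core(["A"], ["A"])
        assert full["n_overlap"] == 1 and full["n_hilic_only"] == 0
        none = overlap_with_core(["A"], ["B"])
        assert none["n_overlap"] == 0

    def test_universe_violation_errors(self):
        with pytest.raises(StemnessError, match="universe"):
            overlap_with_core(["A"], ["B"], universe=["A"])
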