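from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_two_sided, brute_upper_tail
from exprdriver.enrichment import (
    CallerParams,
    FunctionalCall,
    RecurrenceSummary,
    call_functional_mutations,
    calls_table,
    fisher_exact_2x2,
    hypergeometric_tail,
    mutation_enrichment_p,
    permutation_null_p,
    recurrence_table,
    scan_neighbor_sizes,
    summarize_recurrence,
)
from exprdriver.io import ExpressionMatrix, MutationMatrix
from exprdriver.similarity import NeighborSet


class TestHypergeometricTail:
    def test_certain_event_is_one(self):
        assert hypergeometric_tail(4, 4, 4, 4) == 1.0

    def test_k_zero_covers_whole_support(self):
        assert hypergeometric_tail(0, 3, 5, 10) == 1.0

    def test_enumeration_example(self):
        # brute-force pmf summation for (k=2, n=3, K=3, N=10) gives 22/120
        expected = brute_upper_tail(2, 3, 3, 10)
        assert expected == Fraction(11, 60)
        assert hypergeometric_tail(2, 3, 3, 10) == pytest.approx(float(expected))

    @pytest.mark.parametrize(
        "k,n,K,N", [(5, 4, 6, 10), (2, 3, 1, 10), (1, 11, 5, 10), (1, 3, 11, 10)]
    )
    def test_inconsistent_arguments_raise(self, k, n, K, N):
        with pytest.raises(ValueError):
            hypergeometric_tail(k, n, K, N)

    def test_deep_tail_stays_positive(self):
        p = hypergeometric_tail(30, 30, 60, 600)
        assert 0 < p < 1e-30

    @given(
        st.integers(min_value=2, max_value=25).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=1, max_value=N),
                st.integers(min_value=1, max_value=N),
            )
        )
    )
    def test_monotone_nonincreasing_in_k(self, margins):
        N, K, n = margins
        lo = max(0, n + K - N)
        ps = [hypergeometric_tail(k, n, K, N) for k in range(lo, min(n, K) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestFisherExact:
    def test_no_association_two_sided_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5, sided="two_sided") == 1.0

    def test_one_sided_matches_tail_on_grid(self):
        for N in range(2, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        p_f = fisher_exact_2x2(
                            k, n - k, K - k, N - n - K + k, sided="greater"
                        )
                        p_h = hypergeometric_tail(k, n, K, N)
                        assert p_f == pytest.approx(p_h, abs=1e-12)

    def test_two_sided_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            expected = float(brute_two_sided(a, b, c, d))
            assert fisher_exact_2x2(a, b, c, d, sided="two_sided") == pytest.approx(
                expected, rel=1e-9
            )

    def test_degenerate_margin_warns_p_one(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            p = fisher_exact_2x2(0, 0, 3, 5, sided="greater")
        assert p == 1.0
        assert "degenerate" in caplog.text

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(1, -1, 2, 3)

    def test_unknown_sided_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(1, 1, 1, 1, sided="both")


def _cohort(mut_rows, patients):
    genes = [f"g{i}" for i in range(len(mut_rows))]
    return MutationMatrix(
        pd.DataFrame(np.array(mut_rows, dtype=np.int8), index=genes, columns=patients)
    )


def _nset(patient, members, callable_=True):
    return NeighborSet(
        patient_id=patient,
        neighbors=tuple((m, 1.0 if m == patient else 0.8) for m in members),
        n=len(members),
        r_min=0.6,
        callable=callable_,
    )


class TestMutationEnrichment:
    def test_private_mutation_p_equals_n_over_N(self):
        # K=1 (focal only): P[X >= 1] = 1 - C(N-n, n)... algebraically n/N
        patients = [f"P{i}" for i in range(10)]
        mut = _cohort([[1] + [0] * 9], patients)
        ns = _nset("P0", ["P0", "P1", "P2"])
        call = mutation_enrichment_p("P0", "g0", ns, mut)
        assert call.p_value == pytest.approx(3 / 10)
        assert call.k == 1 and call.K == 1 and call.n == 3 and call.N == 10

    def test_fully_mutated_neighborhood_hits_enumeration_oracle(self):
        patients = [f"P{i}" for i in range(12)]
        row = [1, 1, 1] + [0] * 9
        mut = _cohort([row], patients)
        ns = _nset("P0", ["P0", "P1", "P2"])
        call = mutation_enrichment_p("P0", "g0", ns, mut)
        expected = float(brute_upper_tail(3, 3, 3, 12))
        assert call.p_value == pytest.approx(expected)
        assert call.is_functional  # 1/220 < 0.01

    def test_uncallable_neighborhood_gives_nan(self):
        patients = [f"P{i}" for i in range(6)]
        mut = _cohort([[1, 0, 0, 0, 0, 0]], patients)
        ns = _nset("P0", ["P0"], callable_=False)
        call = mutation_enrichment_p("P0", "g0", ns, mut)
        assert np.isnan(call.p_value)
        assert not call.is_functional

    def test_wildtype_patient_rejected(self):
        patients = [f"P{i}" for i in range(6)]
        mut = _cohort([[0, 1, 0, 0, 0, 0]], patients)
        ns = _nset("P0", ["P0", "P1"])
        with pytest.raises(ValueError, match="does not carry"):
            mutation_enrichment_p("P0", "g0", ns, mut)


class TestPermutationNull:
    def test_same_seed_is_deterministic(self):
        patients = [f"P{i}" for i in range(30)]
        row = np.zeros(30, dtype=int)
        row[:6] = 1
        mut = _cohort([row], patients)
        p1 = permutation_null_p("P0", "g0", mut, n=8, observed_k=3, n_perm=500, seed=5)
        p2 = permutation_null_p("P0", "g0", mut, n=8, observed_k=3, n_perm=500, seed=5)
        assert p1 == p2

    def test_conditional_draws_with_private_mutation_tie_every_time(self):
        # K=1 and the focal patient in every draw: count >= 1 always
        patients = [f"P{i}" for i in range(20)]
        row = np.zeros(20, dtype=int)
        row[0] = 1
        mut = _cohort([row], patients)
        p = permutation_null_p(
            "P0", "g0", mut, n=5, observed_k=1, n_perm=500, seed=1,
            condition_on_focal=True,
        )
        assert p == 1.0

    def test_converges_to_analytic_tail(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            N = int(rng.integers(40, 120))
            K = int(rng.integers(2, N // 3))
            n = int(rng.integers(5, 25))
            k_obs = int(rng.integers(1, min(n, K) + 1))
            patients = [f"P{i}" for i in range(N)]
            row = np.zeros(N, dtype=int)
            row[rng.choice(N, K, replace=False)] = 1
            mut = _cohort([row], patients)
            focal = patients[int(np.flatnonzero(row)[0])]
            p_emp = permutation_null_p(
                focal, "g0", mut, n=n, observed_k=k_obs, n_perm=20000,
                seed=int(rng.integers(2**31)),
            )
            p_ana = hypergeometric_tail(k_obs, n, K, N)
            assert abs(p_emp - p_ana) < 0.01

    def test_too_few_permutations_rejected(self):
        patients = [f"P{i}" for i in range(10)]
        mut = _cohort([[1] * 10], patients)
        with pytest.raises(ValueError):
            permutation_null_p("P0", "g0", mut, n=3, observed_k=1, n_perm=50)


class TestCaller:
    def test_no_call_on_wildtype_and_carrier_flag(self, default_cohort, default_calls):
        mut = default_cohort.mutations.data
        for call in default_calls.calls:
            assert mut.at[call.gene, call.patient_id] == 1

    def test_private_mutation_never_functional_when_n_over_N_exceeds_alpha(self):
        # K=1 bounds p at n/N = 10/50 >> 0.01
        rng = np.random.default_rng(2)
        n_pat = 50
        patients = [f"P{i:02d}" for i in range(n_pat)]
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(30, n_pat)),
                index=[f"f{i}" for i in range(30)],
                columns=patients,
            )
        )
        row = np.zeros(n_pat, dtype=np.int8)
        row[0] = 1
        mut = _cohort([row], patients)
        params = CallerParams(k_biomarkers=30, n=10, r_min=-1.0, n_min=2)
        res = call_functional_mutations(expr, mut, params)
        assert all(not c.is_functional for c in res.calls if c.gene == "g0")

    def test_patient_permutation_invariance(self):
        rng = np.random.default_rng(12)
        cfg_patients = [f"P{i:02d}" for i in range(40)]
        expr_values = rng.normal(size=(60, 40))
        mut_values = (rng.random((8, 40)) < 0.2).astype(np.int8)
        expr = ExpressionMatrix(
            pd.DataFrame(expr_values, index=[f"f{i}" for i in range(60)],
                         columns=cfg_patients)
        )
        mut = MutationMatrix(
            pd.DataFrame(mut_values, index=[f"g{i}" for i in range(8)],
                         columns=cfg_patients)
        )
        params = CallerParams(k_biomarkers=60, n=6, r_min=-1.0, n_min=2)
        base = call_functional_mutations(expr, mut, params)

        perm = rng.permutation(40)
        expr_p = ExpressionMatrix(expr.data.iloc[:, perm])
        mut_p = MutationMatrix(mut.data.iloc[:, perm])
        shuffled = call_functional_mutations(expr_p, mut_p, params)

        as_set = lambda res: {
            (c.patient_id, c.gene, c.k, c.n, c.K, c.N, round(c.p_value, 12),
             c.is_functional)
            for c in res.calls
        }
        assert as_set(base) == as_set(shuffled)

    def test_misaligned_cohort_rejected(self, default_cohort):
        expr = default_cohort.expression
        mut = MutationMatrix(default_cohort.mutations.data.iloc[:, ::-1])
        with pytest.raises(ValueError, match="align"):
            call_functional_mutations(expr, mut)

    def test_uncallable_patients_reported_not_called(self, default_cohort, default_calls):
        called_patients = {c.patient_id for c in default_calls.calls}
        assert set(default_calls.skipped_patients).isdisjoint(called_patients)
        assert len(default_calls.skipped_patients) > 0  # noise-only patients

    def test_bh_correction_is_more_conservative(self, default_cohort):
        res_bh = call_functional_mutations(
            default_cohort.expression,
            default_cohort.mutations,
            CallerParams(correction="bh"),
        )
        res_raw = call_functional_mutations(
            default_cohort.expression, default_cohort.mutations, CallerParams()
        )
        n_bh = sum(c.is_functional for c in res_bh.calls)
        n_raw = sum(c.is_functional for c in res_raw.calls)
        assert n_bh <= n_raw


def test_scan_mode_reports_each_neighborhood_size():
    rng = np.random.default_rng(31)
    patients = [f"P{i:02d}" for i in range(30)]
    expr = ExpressionMatrix(
        pd.DataFrame(rng.normal(size=(40, 30)), index=[f"f{i}" for i in range(40)],
                     columns=patients)
    )
    mut = MutationMatrix(
        pd.DataFrame((rng.random((5, 30)) < 0.3).astype(np.int8),
                     index=[f"g{i}" for i in range(5)], columns=patients)
    )
    params = CallerParams(k_biomarkers=40, r_min=-1.0, n_min=3)
    scan = scan_neighbor_sizes(expr, mut, params, n_values=(5, 8, 12))
    assert set(scan) == {5, 8, 12}
    for n, result in scan.items():
        assert all(c.n == n for c in result.calls)


class TestRecurrenceSummary:
    def test_percentage_arithmetic(self):
        assert RecurrenceSummary("gX", 175, 123).percentage == 70.3
        assert RecurrenceSummary("gY", 188, 107).percentage == 56.9
        assert RecurrenceSummary("gZ", 20, 0).percentage == 0.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            RecurrenceSummary("g", 5, 6)

    def test_summarize_sorted_by_functional_count(self):
        patients = ["P0", "P1", "P2", "P3"]
        mut = _cohort([[1, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]], patients)
        calls = [
            FunctionalCall("P0", "g0", 3, 5, 3, 4, 0.001, True),
            FunctionalCall("P1", "g0", 3, 5, 3, 4, 0.001, True),
            FunctionalCall("P0", "g1", 1, 5, 2, 4, 0.5, False),
        ]
        summaries = summarize_recurrence(calls, mut)
        assert [s.gene for s in summaries] == ["g0", "g1", "g2"]
        assert summaries[0].functional_count == 2
        assert summaries[0].somatic_count == 3
        table = recurrence_table(summaries)
        assert list(table.columns) == ["gene", "somatic", "functional", "percentage"]

    def test_calls_table_columns(self, default_calls):
        table = calls_table(default_calls.calls)
        assert list(table.columns) == [
            "patient", "gene", "k", "n", "K", "N", "p", "functional",
        ]
        assert (table["k"] >= 1).all()  # focal inclusion guarantees k >= 1
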