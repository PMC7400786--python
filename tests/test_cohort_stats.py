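import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from chtriage.cohort_stats import (
    ch_prevalence_by_age,
    compare_vaf_by_origin,
    rank_sum_test,
)
from chtriage.datasets import call_from_vaf
from chtriage.synthetic_data import SimConfig, simulate_truths
from chtriage.triage import CompartmentCallSet, triage_patient


class TestRankSumExamples:
    def test_complete_separation_small(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.10)  # 2 of the C(6,3)=20 assignments

    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = rank_sum_test(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p >= 0.99

    def test_two_singletons(self):
        u, p = rank_sum_test([1.0], [2.0])
        assert u == 0.0
        assert p == 1.0  # both assignments are equally extreme

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestRankSumOracle:
    def test_matches_scipy_exact_all_sizes_to_8(self, rng):
        for n_a in range(1, 9):
            for n_b in range(1, 9):
                a = rng.normal(size=n_a).tolist()
                b = rng.normal(size=n_b).tolist()
                u, p = rank_sum_test(a, b)
                res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
                assert u == pytest.approx(res.statistic)
                assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_matches_scipy_asymptotic_large(self, rng):
        a = rng.normal(size=30).tolist()
        b = rng.normal(loc=0.5, size=25).tolist()
        u, p = rank_sum_test(a, b)
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_ties_against_enumeration(self):
        # independent enumeration over raw value permutations, with ties
        a, b = [1.0, 1.0, 2.0], [1.0, 3.0, 3.0]
        u_obs, p = rank_sum_test(a, b)
        from itertools import combinations

        from scipy.stats import rankdata

        pooled = np.array(a + b)
        n_a = len(a)
        center = n_a * len(b) / 2.0

        def u_of(idx):
            ranks = rankdata(pooled)
            return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

        devs = [abs(u_of(idx) - center) for idx in combinations(range(6), 3)]
        expected = sum(d >= abs(u_obs - center) - 1e-9 for d in devs) / len(devs)
        assert p == pytest.approx(expected)


class TestRankSumProperties:
    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
        st.lists(st.integers(0, 20), min_size=1, max_size=6),
        st.integers(-50, 50),
    )
    def test_swap_and_shift_invariance(self, a, b, shift):
        a = [float(x) for x in a]
        b = [float(x) for x in b]
        u_ab, p_ab = rank_sum_test(a, b)
        u_ba, p_ba = rank_sum_test(b, a)
        assert u_ba == pytest.approx(len(a) * len(b) - u_ab)
        assert p_ab == pytest.approx(p_ba)
        u_s, p_s = rank_sum_test([x + shift for x in a], [x + shift for x in b])
        assert u_s == pytest.approx(u_ab)
        assert p_s == pytest.approx(p_ab)

    def test_branches_agree_at_crossover(self, rng):
        # exact enumeration vs normal approximation at the smallest
        # approximate sample size
        from chtriage.cohort_stats import _exact_two_sided_p, _normal_two_sided_p

        for _ in range(20):
            a = rng.normal(size=9).tolist()
            b = rng.normal(loc=rng.uniform(-1, 1), size=9).tolist()
            assert _exact_two_sided_p(a, b) == pytest.approx(
                _normal_two_sided_p(a, b), abs=0.01
            )


def _triage_from_vafs(patient, tumor_vafs, ch_pbc_plasma, plasma_td_vafs):
    tumor_calls = [
        call_from_vaf(patient, "chr1", 10 + i, "A", "T", "TP53", "tumor", v)
        for i, v in enumerate(tumor_vafs)
    ]
    plasma_calls = [
        call_from_vaf(patient, "chr1", 10 + i, "A", "T", "TP53", "plasma", v)
        for i, v in enumerate(plasma_td_vafs)
    ]
    pbc_calls = []
    for j, (v_pbc, v_tumor, v_plasma) in enumerate(ch_pbc_plasma):
        pos = 500 + j
        pbc_calls.append(call_from_vaf(patient, "chr1", pos, "C", "G", "TP53", "pbc", v_pbc))
        if v_tumor:
            tumor_calls.append(
                call_from_vaf(patient, "chr1", pos, "C", "G", "TP53", "tumor", v_tumor)
            )
        if v_plasma:
            plasma_calls.append(
                call_from_vaf(patient, "chr1", pos, "C", "G", "TP53", "plasma", v_plasma)
            )
    return triage_patient(
        CompartmentCallSet(patient_id=patient, compartment="tumor", calls=tumor_calls),
        CompartmentCallSet(patient_id=patient, compartment="pbc", calls=pbc_calls),
        CompartmentCallSet(
            patient_id=patient, compartment="plasma", calls=plasma_calls,
            timepoint_label="preop",
        ),
    )


class TestCompareVafByOrigin:
    def test_infiltration_suppresses_tumor_compartment_ch(self):
        # leukocyte infiltration 5%, tumor clone VAF ~30%: significant in
        # >= 95% of 200 seeded replicates
        config = SimConfig(
            n_patients=20,
            tumor_leukocyte_infiltration=0.05,
            tumor_clone_vaf_range_pct=(20.0, 45.0),
            ch_age_midpoint=40.0,  # most patients carry a blood clone
        )
        hits = 0
        for seed in range(200):
            config.seed = seed
            tumor_derived, ch = [], []
            for truth in simulate_truths(config):
                for clone in truth.tumor_clones:
                    tumor_derived.append(clone.vaf_pct)
                for clone in truth.ch_clones:
                    ch.append(config.tumor_leukocyte_infiltration * clone.vaf_pct)
            if not tumor_derived or not ch:
                continue
            _, p = rank_sum_test(tumor_derived, ch)
            hits += p < 0.05
        assert hits >= 190

    def test_shared_plasma_distribution_not_significant(self):
        # ctDNA plasma VAF distribution configured identical to the blood-clone
        # plasma VAF distribution: non-significant in >= 90% of replicates
        config = SimConfig(
            n_patients=30,
            ch_age_midpoint=40.0,
            ch_vaf_range_pct=(0.05, 1.5),
            tumor_clone_vaf_range_pct=(30.0, 30.0 + 1e-9),
            plasma_tumor_fraction_by_stage={
                s: (0.05 / 30.0, 1.5 / 30.0) for s in ("I", "II", "III", "IV")
            },
        )
        non_sig = 0
        n_rep = 100
        for seed in range(n_rep):
            config.seed = seed
            ctdna, ch = [], []
            for truth in simulate_truths(config):
                for clone in truth.tumor_clones:
                    ctdna.append(truth.plasma_tumor_fraction * clone.vaf_pct)
                for clone in truth.ch_clones:
                    ch.append(clone.vaf_pct)
            _, p = rank_sum_test(ctdna, ch)
            non_sig += p >= 0.05
        assert non_sig >= 0.90 * n_rep

    def test_two_singleton_groups_run_exact(self):
        cohort = [_triage_from_vafs("P1", [20.0], [(0.2, 0.1, 0.3)], [0.5])]
        cmp_ = compare_vaf_by_origin(cohort, "tumor")
        assert cmp_.method == "exact"
        assert 0 <= cmp_.p_value <= 1

    def test_unknown_excluded_from_plasma_comparison(self):
        cohort = [
            _triage_from_vafs(
                "P1", [20.0], [(0.2, None, 0.3)], plasma_td_vafs=[0.5]
            )
        ]
        # add a plasma-only variant; it must not enter either group
        cmp_ = compare_vaf_by_origin(cohort, "plasma")
        assert len(cmp_.values_a) == 1  # the concordant variant only
        assert len(cmp_.values_b) == 1

    def test_empty_group_rejected(self):
        cohort = [_triage_from_vafs("P1", [20.0], [], [0.5])]
        with pytest.raises(ValueError, match="CH"):
            compare_vaf_by_origin(cohort, "tumor")


class TestChPrevalenceByAge:
    def test_all_old_patients_carry_ch(self):
        cohort = []
        for i in range(5):
            t = _triage_from_vafs(f"P{i}", [10.0], [(0.2, None, 0.3)], [])
            t.age = 82 + i
            cohort.append(t)
        (bin80,) = [b for b in ch_prevalence_by_age(cohort) if b.low == 80]
        assert bin80.prevalence_pct == 100.0

    def test_empty_bin_reported_blank(self):
        ages = [45, 78]
        cohort = []
        for i, age in enumerate(ages):
            t = _triage_from_vafs(f"P{i}", [10.0], [], [])
            t.age = age
            cohort.append(t)
        bins = {b.low: b for b in ch_prevalence_by_age(cohort)}
        assert bins[50].n_patients == 0
        assert bins[50].prevalence_pct is None

    def test_unknown_age_excluded(self):
        t1 = _triage_from_vafs("P1", [10.0], [], [])
        t1.age = 55
        t2 = _triage_from_vafs("P2", [10.0], [], [])  # no age
        bins = ch_prevalence_by_age([t1, t2])
        assert sum(b.n_patients for b in bins) == 1

    def test_logistic_curve_recovery_at_n500(self):
        # simulator truth vs the configured logistic, three sigma per decade
        config = SimConfig(seed=11, n_patients=500, ch_age_midpoint=70.0, ch_age_slope=0.1)
        truths = simulate_truths(config)
        cohort = []
        for truth in truths:
            ch = [(c.vaf_pct, None, c.vaf_pct) for c in truth.ch_clones]
            t = _triage_from_vafs(truth.patient_id, [10.0], ch, [])
            t.age = truth.age
            cohort.append(t)
        truth_by_id = {t.patient_id: t for t in truths}
        for b in ch_prevalence_by_age(cohort):
            if b.n_patients < 20:
                continue
            members = [
                truth_by_id[t.patient_id]
                for t in cohort
                if b.low <= t.age < b.high
            ]
            probs = [config.ch_probability(m.age) for m in members]
            expected = 100.0 * sum(probs) / len(probs)
            sigma = 100.0 * math.sqrt(sum(p * (1 - p) for p in probs)) / len(probs)
            assert abs(b.prevalence_pct - expected) <= 3 * sigma + 1e-9

    def test_no_ages_rejected(self):
        with pytest.raises(ValueError):
            ch_prevalence_by_age([_triage_from_vafs("P1", [10.0], [], [])])
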