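import math

import numpy as np
import pytest

from retroburst import (DatingConfig, LTRCandidate, ClassifiedElement,
                        date_all, estimate_age, kimura2p)
from retroburst.simulate import (_k80_substitution_probs, evolve_sequence,
                                 indices_to_str, random_sequence)

# frozen from a 20-digit sympy evaluation of -1/2*ln((1-2P-Q)*sqrt(1-2Q))
ORACLE_K = {
    (0.03, 0.01): 0.041336023246797577,
    (0.01, 0.005): 0.015171487955520298,
    (0.1, 0.05): 0.170181165140347039,
    (0.2, 0.1): 0.402359478108525094,
    (0.05, 0.2): 0.306043877910863860,
}


def _alignment_with(P, Q, n=1000):
    """Gap-free alignment with exact transition/transversion proportions."""
    ts, tv = round(P * n), round(Q * n)
    a = "A" * n
    b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
    return a, b


class TestKimura2P:
    def test_identical_sequences(self):
        k = kimura2p("ACGTACGT", "ACGTACGT")
        assert (k.P, k.Q, k.K, k.saturated) == (0.0, 0.0, 0.0, False)

    @pytest.mark.parametrize("P,Q", sorted(ORACLE_K))
    def test_closed_form_matches_high_precision_oracle(self, P, Q):
        k = kimura2p(*_alignment_with(P, Q))
        assert k.P == pytest.approx(P) and k.Q == pytest.approx(Q)
        assert k.K == pytest.approx(ORACLE_K[(P, Q)], abs=1e-12)

    def test_saturation_at_half_transitions(self):
        a, b = _alignment_with(0.5, 0.0)
        k = kimura2p(a, b)
        assert k.saturated and k.K is None

    def test_gap_and_ambiguity_columns_excluded(self):
        k = kimura2p("ACG-TN", "ACGAT-")
        assert k.columns == 4  # only the fully resolved ACGT columns count
        assert k.K == 0.0

    def test_zero_usable_columns_is_error_not_saturation(self):
        with pytest.raises(ValueError, match="usable"):
            kimura2p("NNN---", "NN-NNN")

    def test_k_dominates_p_distance_on_grid(self):
        """Substitution correction can only inflate the raw mismatch fraction."""
        for P in np.arange(0.0, 0.45, 0.05):
            for Q in np.arange(0.0, 0.45, 0.05):
                if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0 or P + Q > 0.9:
                    continue
                k = kimura2p(*_alignment_with(round(P, 2), round(Q, 2)))
                if not k.saturated:
                    assert k.K >= k.P + k.Q - 1e-12

    def test_matches_markov_chain_simulation(self):
        """K2P re-estimates the simulating branch length within MC error."""
        rng = np.random.default_rng(21)
        L, d, kappa = 200_000, 0.03, 2.0
        anc = random_sequence(L, 0.5, rng)
        a = evolve_sequence(anc, d / 2, kappa, rng)
        b = evolve_sequence(anc, d / 2, kappa, rng)
        k = kimura2p(indices_to_str(a), indices_to_str(b))
        se = math.sqrt(d / L)
        assert k.K == pytest.approx(d, abs=4 * se)
        # and the realised P, Q match the K80 closed-form expectations
        p_ts, p_tv = _k80_substitution_probs(d, kappa)
        assert k.P == pytest.approx(p_ts, abs=4 * math.sqrt(p_ts / L))
        assert k.Q == pytest.approx(p_tv, abs=4 * math.sqrt(p_tv / L))


class TestEstimateAge:
    def test_printed_young_element_age(self):
        assert estimate_age(0.0028) == pytest.approx(0.2)

    def test_young_boundary(self):
        assert estimate_age(0.028) == pytest.approx(2.0)

    def test_zero_distance_zero_age(self):
        assert estimate_age(0.0) == 0.0

    def test_monotone_in_k(self):
        ks = np.linspace(0, 0.2, 50)
        ages = [estimate_age(k) for k in ks]
        assert all(x < y for x, y in zip(ages, ages[1:]))

    def test_custom_rate(self):
        assert estimate_age(0.0028, DatingConfig(mutation_rate=1.4e-8)) == \
            pytest.approx(0.1)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_age(-0.01)


def _fake_classified(chrom, ltr5, ltr3, genome):
    start, end = ltr5[0], ltr3[1]
    cand = LTRCandidate("E1", chrom, start, end, ltr5[0], ltr5[1],
                        ltr3[0], ltr3[1], 90.0, None, 100.0)
    return ClassifiedElement(cand, [], True, "Gypsy", "+", False)


class TestDateAll:
    def test_empty_input(self):
        assert date_all([], {"chr1": "ACGT"}) == []

    def test_saturated_element_flagged_not_dropped(self):
        genome = {"chr1": "A" * 200 + "T" * 500 + "G" * 200}
        el = _fake_classified("chr1", (0, 200), (700, 900), genome)
        aged = date_all([el], genome)
        assert len(aged) == 1
        assert aged[0].saturated and aged[0].age_mya is None

    def test_age_recovery_unbiased_over_replicates(self):
        """estimate_age(kimura2p(align(evolve(L, T)))) is unbiased for T (3 SE)."""
        rng = np.random.default_rng(23)
        mu, kappa, T, L, n = 7e-9, 2.0, 1.5, 1000, 200
        d = mu * T * 1e6
        ests = []
        from retroburst import ltr_pair_identity
        for _ in range(n):
            anc = random_sequence(L, 0.38, rng)
            a = evolve_sequence(anc, d, kappa, rng)
            b = evolve_sequence(anc, d, kappa, rng)
            _, aln = ltr_pair_identity(indices_to_str(a), indices_to_str(b))
            k = kimura2p(str(aln[0]), str(aln[1]))
            ests.append(estimate_age(k.K))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / math.sqrt(n)
        assert abs(ests.mean() - T) < 3 * se

    def test_pipeline_ages_track_truth(self, small_result):
        truth = small_result.truth.set_index("element_id")
        from retroburst.pipeline import match_candidates_to_truth
        mapping = match_candidates_to_truth(small_result.candidates,
                                            small_result.truth)
        for a in small_result.aged:
            tid = mapping.get(a.element_id)
            if tid is None or a.saturated:
                continue
            true_age = truth.loc[tid].true_age_mya
            # binomial sampling tolerance on K at the aligned LTR length
            se_k = math.sqrt(max(a.K, 1e-4) / a.aligned_columns)
            tol = 4 * se_k / (2 * 7e-9) / 1e6
            assert a.age_mya == pytest.approx(true_age, abs=tol)
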