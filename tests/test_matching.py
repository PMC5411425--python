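import itertools

import numpy as np
import pytest

from synkey.errors import InvalidInputError, ShapeError
from synkey.joints import N_JOINTS
from synkey.matching import (
    JointMask,
    MASK_PRESETS,
    bin_slices,
    chance_baseline,
    joint_correlation,
    pair_synergies,
    shift_values,
    shifted_summed_correlation,
    shuffle_joint_profile,
    verify,
)
from synkey.synergy import SynergySet

L = 151
ALL = JointMask.preset("all")


def synergy_set(arrays):
    arr = np.asarray(arrays, dtype=float)
    n = arr.shape[0]
    return SynergySet(
        synergies=arr,
        singular_values=np.linspace(2, 1, n),
        variance_fractions=np.full(n, 1 / n),
    )


def smooth_synergies(rng, n, length=L):
    t = np.arange(length)
    out = np.zeros((n, N_JOINTS, length))
    for i in range(n):
        for j in range(N_JOINTS):
            c = rng.uniform(20, length - 20)
            w = rng.uniform(8, 20)
            out[i, j] = rng.normal() * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


class TestMasks:
    def test_presets_have_documented_sizes(self):
        assert len(JointMask.preset("all")) == 10
        assert len(JointMask.preset("mcp_only")) == 5
        assert len(JointMask.preset("pip_only")) == 5
        for name in MASK_PRESETS:
            if name.startswith("minus_"):
                assert len(JointMask.preset(name)) == 8

    def test_empty_or_bad_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            JointMask(included=())
        with pytest.raises(InvalidInputError):
            JointMask.preset("nope")


class TestJointCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=L)
        assert joint_correlation(a, a) == pytest.approx(1.0)
        assert joint_correlation(a, -a) == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 7.0, 8.0])
        # Closed form: r = cov(a,b) / (sd(a) sd(b)), computed by hand.
        am, bm = a - a.mean(), b - b.mean()
        expected = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert joint_correlation(a, b) == pytest.approx(expected)

    def test_zero_variance_gives_zero_not_nan(self, rng):
        assert joint_correlation(np.ones(10), rng.normal(size=10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            joint_correlation(np.ones(5), np.ones(6))


class TestShiftedSummedCorrelation:
    def test_identical_synergy_scores_the_mask_size(self, rng):
        syn = smooth_synergies(rng, 1)[0]
        score = shifted_summed_correlation(syn, syn, ALL)
        assert score.summed_correlation == pytest.approx(10.0)
        assert score.shift == 0

    def test_recovers_a_known_delay(self, rng):
        syn = smooth_synergies(rng, 1)[0]
        delayed = np.zeros_like(syn)
        delayed[:, 7:] = syn[:, :-7]
        score = shifted_summed_correlation(syn, delayed, ALL)
        unshifted = sum(joint_correlation(syn[j], delayed[j]) for j in range(10))
        assert score.summed_correlation >= unshifted
        assert score.shift == -7  # shifting the entry back by 7 re-aligns it

    def test_single_joint_mask_reduces_to_joint_correlation(self, rng):
        a, b = smooth_synergies(rng, 2)
        mask = JointMask(included=(2,), name="I_MCP")
        score = shifted_summed_correlation(a, b, mask)
        assert -1.0 <= score.summed_correlation <= 1.0
        # Oracle: exhaustive scan over all shifts of the single joint.
        best = -np.inf
        for s in range(-20, 21):
            shifted = np.zeros(L)
            if s >= 0:
                shifted[s:] = b[2, : L - s] if s else b[2]
            else:
                shifted[:s] = b[2, -s:]
            best = max(best, joint_correlation(a[2], shifted))
        assert score.summed_correlation == pytest.approx(best)

    def test_tie_breaks_toward_zero_shift(self):
        # A constant-zero entry scores 0 at every shift; the tie-break rule
        # must return the unshifted interpretation.
        a = np.tile(np.sin(np.arange(L) / 7.0), (N_JOINTS, 1))
        score = shifted_summed_correlation(a, np.zeros_like(a), ALL)
        assert score.shift == 0

    def test_shift_order_prefers_small_then_negative(self):
        s = shift_values(3)
        assert list(s) == [0, -1, 1, -2, 2, -3, 3]

    def test_sign_flip_flips_the_correlation_at_fixed_shift(self, rng):
        # At a fixed alignment, negating the entry negates every per-joint
        # correlation.  (With the shift search active the maximum moves to a
        # different shift, so the identity holds only shift-wise.)
        a = smooth_synergies(rng, 1)[0]
        plus = shifted_summed_correlation(a, a, ALL, max_shift=0)
        minus = shifted_summed_correlation(a, -a, ALL, max_shift=0)
        assert minus.summed_correlation == pytest.approx(-plus.summed_correlation)


def brute_force_greedy(template, entry, mask, max_shift=20):
    """Independent oracle: nested-loop greedy pairing with its own Pearson."""

    def pearson(u, v):
        um, vm = u - u.mean(), v - v.mean()
        den = np.sqrt((um**2).sum() * (vm**2).sum())
        return 0.0 if den == 0 else float((um * vm).sum() / den)

    def best_shift_score(a, b):
        best = -np.inf
        for s in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
            total = 0.0
            for j in mask.included:
                shifted = np.zeros(b.shape[1])
                if s >= 0:
                    shifted[s:] = b[j, : b.shape[1] - s] if s else b[j]
                else:
                    shifted[:s] = b[j, -s:]
                total += pearson(a[j], shifted)
            if total > best:
                best = total
        return best

    pairs = []
    available = list(range(entry.n))
    for t in range(min(template.n, entry.n)):
        scores = [best_shift_score(template.synergies[t], entry.synergies[e]) for e in available]
        k = int(np.argmax(scores))
        pairs.append((t + 1, available[k] + 1, scores[k]))
        del available[k]
    return pairs


class TestPairSynergies:
    def test_identity_pairing_on_identical_sets(self, rng):
        s = synergy_set(smooth_synergies(rng, 4))
        match = pair_synergies(s, s, ALL)
        for i, p in enumerate(match.pairs):
            assert (p.template_index, p.entry_index) == (i + 1, i + 1)
            assert p.summed_correlation == pytest.approx(10.0)

    def test_reversed_entry_order_recovers_partners(self, rng):
        arr = smooth_synergies(rng, 3)
        template = synergy_set(arr)
        entry = synergy_set(arr[::-1])
        match = pair_synergies(template, entry, ALL)
        assert [(p.template_index, p.entry_index) for p in match.pairs] == [
            (1, 3), (2, 2), (3, 1)
        ]
        oracle = brute_force_greedy(template, entry, ALL)
        for p, (t, e, score) in zip(match.pairs, oracle):
            assert (p.template_index, p.entry_index) == (t, e)
            assert p.summed_correlation == pytest.approx(score)

    def test_matches_brute_force_on_random_sets(self, rng):
        template = synergy_set(smooth_synergies(rng, 4))
        entry = synergy_set(smooth_synergies(rng, 4))
        match = pair_synergies(template, entry, ALL)
        oracle = brute_force_greedy(template, entry, ALL)
        for p, (t, e, score) in zip(match.pairs, oracle):
            assert (p.template_index, p.entry_index) == (t, e)
            assert p.summed_correlation == pytest.approx(score)

    def test_partial_map_with_fewer_entries(self, rng):
        template = synergy_set(smooth_synergies(rng, 2))
        entry = synergy_set(smooth_synergies(rng, 1))
        assert len(pair_synergies(template, entry, ALL).pairs) == 1

    def test_hungarian_mode_never_scores_below_greedy_total(self, rng):
        template = synergy_set(smooth_synergies(rng, 4))
        entry = synergy_set(smooth_synergies(rng, 4))
        greedy = pair_synergies(template, entry, ALL, method="greedy")
        optimal = pair_synergies(template, entry, ALL, method="hungarian")
        assert optimal.total_score >= greedy.total_score - 1e-9


class TestChanceBaseline:
    def test_last_bin_length_matches_protocol(self):
        slices = bin_slices(151, bins=8, bin_length=20)
        assert len(slices) == 8
        assert slices[-1].stop - slices[-1].start == 11

    def test_identity_permutation_preserves_profile(self, rng):
        x = rng.normal(size=L)
        out = shuffle_joint_profile(x, permutation=np.arange(8))
        assert np.array_equal(out, x)

    def test_invalid_binning_rejected(self):
        with pytest.raises(InvalidInputError):
            bin_slices(151, bins=4, bin_length=20)  # does not cover L
        with pytest.raises(InvalidInputError):
            bin_slices(151, bins=9, bin_length=20)  # empty last bin

    def test_white_noise_chance_mean_is_near_zero(self, rng):
        # Analytic null: the Pearson correlation of independent noise has
        # zero mean, so the summed chance score over 10 joints is centred on
        # 0 up to the max-over-shifts selection bias; 3 standard errors.
        template = synergy_set(rng.normal(size=(1, N_JOINTS, L)))
        entry = synergy_set(rng.normal(size=(1, N_JOINTS, L)))
        draws = chance_baseline(template, entry, ALL, draws=200, seed=4, max_shift=0)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se + 0.05

    def test_structured_signal_beats_chance(self, rng):
        arr = smooth_synergies(rng, 3)
        template = synergy_set(arr)
        draws = chance_baseline(template, template, ALL, draws=60, seed=9)
        true_score = pair_synergies(template, template, ALL).pairs[0].summed_correlation
        assert draws.mean() + 2 * draws.std() < true_score


class TestVerify:
    def test_identical_entry_accepted_below_100(self, rng):
        s = synergy_set(smooth_synergies(rng, 2))
        result = verify(s, s, ALL, T_m=99.9)
        assert result.accepted and result.score_percent == pytest.approx(100.0)

    def test_score_equal_to_threshold_is_rejected(self, rng):
        s = synergy_set(smooth_synergies(rng, 2))
        result = verify(s, s, ALL, T_m=result_score_of(s))
        assert not result.accepted

    def test_percent_scaling_across_masks(self, rng):
        s = synergy_set(smooth_synergies(rng, 2))
        for name in ("all", "mcp_only", "minus_pinky"):
            r = verify(s, s, JointMask.preset(name), T_m=50.0)
            assert r.score_percent == pytest.approx(100.0)

    def test_invalid_indices_rejected(self, rng):
        s = synergy_set(smooth_synergies(rng, 2))
        with pytest.raises(InvalidInputError):
            verify(s, s, ALL, synergy_indices={3})

    def test_noise_degrades_expected_score_monotonically(self, rng):
        base = smooth_synergies(rng, 2)
        template = synergy_set(base)
        means = []
        for amp in (0.0, 0.5, 2.0):
            scores = []
            for rep in range(5):
                noisy = base + amp * rng.normal(size=base.shape) * np.abs(base).max()
                scores.append(
                    verify(template, synergy_set(noisy), ALL, T_m=0).score_percent
                )
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


def result_score_of(s):
    return verify(s, s, ALL, T_m=0.0).score_percent
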