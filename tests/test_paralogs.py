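"""Paralog-combination inference against a brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

from allelemine.io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING
from allelemine.paralogs import (
    DEFAULT_AB_TOLERANCE,
    CombinationHypothesis,
    ObservedPattern,
    ParalogError,
    allele_balance,
    allele_balance_flag,
    call_paralog_haplotype,
    enumerate_consistent_combinations,
    filter_het_calls,
    predict_pattern,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: string predictions, no shared code path


def oracle_predict(combo: dict, signature) -> tuple[str, tuple]:
    """Predict the observable pattern of a multiset by raw string logic."""
    rows = [signature.alleles[n] for n, k in sorted(combo.items()) for _ in range(k)]
    ref = signature.ref_allele
    calls, abs_ = [], []
    for i in range(len(ref)):
        col = [r[i] for r in rows]
        n_ref = sum(b == ref[i] for b in col)
        n_alt = len(col) - n_ref
        if n_ref and n_alt:
            calls.append("H")
            abs_.append(n_alt / n_ref)
        elif n_alt:
            calls.append("A")
            abs_.append(None)
        else:
            calls.append("R")
            abs_.append(None)
    return "".join(calls), tuple(abs_)


def oracle_enumerate(observed: str, obs_ab, depth, signature, max_total):
    """All multisets whose string prediction matches the observed calls."""
    names = sorted(signature.alleles)
    out = []
    for total in range(1, max_total + 1):
        for picks in itertools.combinations_with_replacement(names, total):
            combo: dict = {}
            for n in picks:
                combo[n] = combo.get(n, 0) + 1
            if combo in out:
                continue
            calls, pred_ab = oracle_predict(combo, signature)
            ok = all(
                o == "." or o == c for o, c in zip(observed, calls)
            )
            if not ok:
                continue
            devs = [
                abs(math.log(oa / pa))
                for o, oa, pa in zip(observed, obs_ab, pred_ab)
                if o == "H" and oa is not None and pa is not None
            ]
            if devs and sum(devs) / len(devs) > DEFAULT_AB_TOLERANCE:
                continue
            out.append(combo)
    return out


def pattern_from_string(observed: str, obs_ab=None, depth=None, depth_per_copy=60):
    # depth 60 divides evenly by every copy count <= 6, so the AD-derived
    # allele balances reproduce the intended ratios exactly
    code = {"R": GT_HOM_REF, "A": GT_HOM_ALT, "H": GT_HET, ".": GT_MISSING}
    calls = np.array([code[c] for c in observed], dtype=np.int8)
    npos = len(observed)
    adr = np.zeros(npos, dtype=np.int32)
    ada = np.zeros(npos, dtype=np.int32)
    for i, c in enumerate(observed):
        if c == "R":
            adr[i] = depth_per_copy
        elif c == "A":
            ada[i] = depth_per_copy
        elif c == "H":
            ab = obs_ab[i] if obs_ab is not None and obs_ab[i] is not None else 1.0
            adr[i] = depth_per_copy
            ada[i] = int(round(depth_per_copy * ab))
    return ObservedPattern("s", calls, adr, ada, depth_multiplier=depth)


def exact_pattern(combo, signature, depth_per_copy=60):
    """Noise-free observed pattern a given truth combination would produce."""
    calls, abs_ = oracle_predict(combo, signature)
    total = sum(combo.values())
    return pattern_from_string(
        calls, obs_ab=abs_, depth=float(total), depth_per_copy=depth_per_copy
    )


# ---------------------------------------------------------------------------


class TestAlleleBalance:
    def test_equal_representation_is_one(self):
        assert allele_balance(10, 10) == 1.0

    def test_simple_ratio(self):
        assert allele_balance(20, 4) == pytest.approx(0.2)

    def test_no_reference_reads_is_undefined_and_flagged(self):
        assert math.isnan(allele_balance(0, 15))
        assert allele_balance_flag(0, 15) == "hom-alt-support"
        assert allele_balance_flag(0, 0) == "no-coverage"


class TestHetFilter:
    def test_low_balance_het_demoted(self):
        p = ObservedPattern(
            "s",
            np.array([GT_HET], dtype=np.int8),
            np.array([20]),
            np.array([4]),  # AB = 0.2 < 0.25
        )
        out = filter_het_calls(p)
        assert out.calls[0] == GT_MISSING and out.n_demoted == 1

    def test_balanced_het_retained(self):
        p = ObservedPattern(
            "s", np.array([GT_HET], dtype=np.int8), np.array([10]), np.array([10])
        )
        out = filter_het_calls(p)
        assert out.calls[0] == GT_HET and out.n_demoted == 0

    def test_homozygous_calls_untouched(self):
        p = ObservedPattern(
            "s",
            np.array([GT_HOM_REF, GT_HOM_ALT], dtype=np.int8),
            np.array([20, 0]),
            np.array([1, 20]),
        )
        out = filter_het_calls(p)
        assert list(out.calls) == [GT_HOM_REF, GT_HOM_ALT]

    def test_symmetric_mode_demotes_inflated_balance(self):
        p = ObservedPattern(
            "s", np.array([GT_HET], dtype=np.int8), np.array([3]), np.array([30])
        )
        assert filter_het_calls(p).calls[0] == GT_HET
        assert filter_het_calls(p, symmetric=True).calls[0] == GT_MISSING

    def test_raising_threshold_never_adds_het_calls(self, rng):
        """Monotonicity: het count is non-increasing in min_ab."""
        n = 50
        p = ObservedPattern(
            "s",
            np.full(n, GT_HET, dtype=np.int8),
            rng.integers(1, 40, n).astype(np.int32),
            rng.integers(0, 40, n).astype(np.int32),
        )
        counts = [
            int((filter_het_calls(p, min_ab=t).calls == GT_HET).sum())
            for t in (0.05, 0.25, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPredictPattern:
    def test_reference_singleton_is_all_hom_ref(self, signature):
        hyp = predict_pattern({"morex_CBF2a": 1}, signature)
        assert (hyp.predicted_calls == GT_HOM_REF).all()
        assert hyp.total_copies == 1

    def test_two_paralogs_het_exactly_where_rows_differ(self, signature):
        hyp = predict_pattern({"nure_CBF2a": 1, "nure_CBF2b": 1}, signature)
        a, b = signature.alleles["nure_CBF2a"], signature.alleles["nure_CBF2b"]
        ref = signature.ref_allele
        for i, (x, y) in enumerate(zip(a, b)):
            if x == y == ref[i]:
                assert hyp.predicted_calls[i] == GT_HOM_REF
            elif x != y:
                assert hyp.predicted_calls[i] == GT_HET
                assert hyp.predicted_ab[i] == pytest.approx(1.0)
            else:
                assert hyp.predicted_calls[i] == GT_HOM_ALT

    def test_shared_alternative_allele_is_hom_alt_without_balance(self, signature):
        hyp = predict_pattern({"nure_CBF2b": 1, "CBF2ab_fusion": 1}, signature)
        i = 0  # offset 63: both carry the alternative base
        assert hyp.predicted_calls[i] == GT_HOM_ALT
        assert math.isnan(hyp.predicted_ab[i])

    def test_multiset_permutation_invariance(self, signature):
        h1 = predict_pattern({"nure_CBF2a": 2, "nure_CBF2b": 1}, signature)
        h2 = predict_pattern({"nure_CBF2b": 1, "nure_CBF2a": 2}, signature)
        np.testing.assert_array_equal(h1.predicted_calls, h2.predicted_calls)
        np.testing.assert_array_equal(
            np.nan_to_num(h1.predicted_ab), np.nan_to_num(h2.predicted_ab)
        )
        assert h1.combo == h2.combo

    def test_unknown_paralog_rejected(self, signature):
        with pytest.raises(ParalogError, match="unknown paralog"):
            predict_pattern({"nonesuch": 1}, signature)


class TestEnumerate:
    def test_all_reference_pattern_has_unique_single_copy_answer(self, signature):
        p = pattern_from_string("RRRRRR", depth=1.0)
        hyps = enumerate_consistent_combinations(p, signature, max_total_copies=3)
        assert hyps[0].combo == (("morex_CBF2a", 1),)
        assert hyps[0].score == max(h.score for h in hyps)
        # no other single-copy explanation ties at depth 1
        tied = [h for h in hyps if h.score == hyps[0].score]
        assert len(tied) == 1

    def test_fusion_plus_reference_is_ambiguous_with_two_singles(self, signature):
        truth = {"CBF2ab_fusion": 1, "morex_CBF2a": 1}
        p = exact_pattern(truth, signature)
        hyps = enumerate_consistent_combinations(p, signature)
        top_labels = {h.label for h in hyps if h.score == hyps[0].score}
        assert "CBF2ab_fusion+morex_CBF2a" in top_labels
        assert "nure_CBF2a+nure_CBF2b" in top_labels
        for h in hyps:
            if h.label in top_labels:
                assert set(h.ambiguous_with) == top_labels - {h.label}

    def test_inconsistent_pattern_yields_empty_list(self, signature):
        # het at a position where no paralog pair can produce one alone
        p = pattern_from_string("HRRRRR", obs_ab=[1.0, None, None, None, None, None])
        hyps = enumerate_consistent_combinations(p, signature, max_total_copies=1)
        assert hyps == []

    @pytest.mark.parametrize("max_total", [2, 3])
    def test_matches_brute_force_oracle_on_random_patterns(
        self, signature, rng, max_total
    ):
        """Implementation and oracle agree on every truth-derived pattern."""
        names = sorted(signature.alleles)
        for _ in range(30):
            combo = {}
            for n in rng.choice(names, size=rng.integers(1, 3), replace=False):
                combo[str(n)] = int(rng.integers(1, 3))
            if sum(combo.values()) > max_total:
                continue
            calls, abs_ = oracle_predict(combo, signature)
            p = pattern_from_string(calls, obs_ab=abs_, depth=float(sum(combo.values())))
            got = {h.combo for h in enumerate_consistent_combinations(p, signature, max_total)}
            want = {
                tuple(sorted(c.items()))
                for c in oracle_enumerate(calls, abs_, None, signature, max_total)
            }
            assert got == want


class TestCallParalogHaplotype:
    def test_identical_patterns_get_identical_labels(self, signature):
        truth = {"morex_CBF2a": 1, "nure_CBF2b": 1}
        c1 = call_paralog_haplotype(exact_pattern(truth, signature), signature)
        c2 = call_paralog_haplotype(exact_pattern(truth, signature), signature)
        assert c1.haplotype_label == c2.haplotype_label == "morex_CBF2a+nure_CBF2b"
        assert c1.status == "resolved"

    def test_all_missing_pattern_is_unresolved(self, signature):
        p = pattern_from_string("......")
        call = call_paralog_haplotype(p, signature)
        assert call.status == "unresolved" and call.haplotype_label is None

    def test_depth_unsupported_extra_copies_unresolved(self, signature):
        # het pattern implies two copies, but read depth says one
        truth = {"nure_CBF2a": 1, "nure_CBF2b": 1}
        calls, abs_ = oracle_predict(truth, signature)
        p = pattern_from_string(calls, obs_ab=abs_, depth=1.0)
        call = call_paralog_haplotype(p, signature, depth_consistency=0.75)
        assert call.status == "unresolved"

    def test_low_balance_het_demotions_counted(self, signature):
        truth = {"nure_CBF2a": 1, "nure_CBF2b": 1}
        calls, abs_ = oracle_predict(truth, signature)
        bad_ab = [0.1 if c == "H" else None for c in calls]
        p = pattern_from_string(calls, obs_ab=bad_ab, depth=2.0)
        call = call_paralog_haplotype(p, signature)
        assert call.n_demoted == calls.count("H")

    def test_truth_recovered_or_in_ambiguous_set(self, signature, rng):
        """Round trip over every distinct truth multiset of ≤3 copies."""
        names = sorted(signature.alleles)
        for total in (1, 2, 3):
            for picks in itertools.combinations_with_replacement(names, total):
                combo: dict = {}
                for n in picks:
                    combo[n] = combo.get(n, 0) + 1
                p = exact_pattern(combo, signature)
                call = call_paralog_haplotype(p, signature, max_total_copies=3)
                label = "+".join(
                    n if k == 1 else f"{n}x{k}" for n, k in sorted(combo.items())
                )
                assert call.status != "unresolved"
                assert label == call.haplotype_label or label in call.ambiguous_with
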